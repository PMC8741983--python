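# Methods

`mirwave` implements the computational core of a developmental small-RNA /
mRNA time-course analysis: annotation filtering of microRNA hairpin read
stacks, 5p/3p arm-usage statistics, cross-genome family profiling,
expression normalization and fuzzy clustering, adjacent-stage
negative-binomial contrasts (the two-wave zygotic genome activation
analysis), and seed-match target prediction with enrichment statistics.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Study design emulated by the simulator

The synthetic-data module mirrors a size-separated embryonic RNA-seq
design: seven time-points spanning embryogenesis, four replicates per
time-point for the small-RNA libraries and two for the large (mRNA /
lncRNA) libraries. All generators are driven by one `SimulationConfig`
whose `rng_seed` fully determines every output (RNG streams are salted
per generator with fixed integer salts — nothing depends on process
state).

**Read stacks.** Each simulated precursor is flank (5 nt) + 5p mature
(22 nt) + loop + 3p mature (22 nt) + flank, with per-arm read depth, loop
length and 5′-end homogeneity set per stack. The 5′-jitter law is a
categorical distribution over offsets {−2, −1, 0, +1, +2}; it is realized
by largest-remainder quotas rather than multinomial draws so that a stack
requested at modal fraction 0.49 or 0.50 sits *exactly* at the filter
boundary — the truth table records the realized modal fraction and the
verdict derived from it. Multinomial sampling would randomly flip planted
verdicts at the boundary and make exact-recovery tests meaningless.

**Count matrices.** Mean trajectories follow five archetypes: maternal
decay (geometric, half-life one time-point), a first zygotic wave peaking
at the second time-point, mid and late Gaussian peaks, and a flat null.
Default archetype proportions (26/15/20/39%) follow the cluster
proportions observed in a seven-stage crustacean embryogenesis course.
Counts are Gamma–Poisson with var = μ + αμ² (default α = 0.1); per-sample
library sizes are drawn uniformly from `library_size_range` and the mean
matrix is rescaled so each column's expected sum equals its drawn size.
Planted activations multiply the mean trajectory by `fold_change_planted`
(default 8) from a chosen time-point onward, i.e. an activation between
two adjacent stages. Per-feature base abundances are log-normal
(σ = 0.8), so a matrix contains both well- and poorly-powered features.

**Archetype profiles.** `gen_archetype_profiles` emits z-scored archetype
trajectories plus isotropic Gaussian noise (default SD 0.3 per
time-point) — the profile-space counterpart of the count simulator, used
to probe clustering without count noise. 0.3 keeps planted features at
roughly the ≥ 0.6 membership level of the cluster exemplars the generator
emulates. The closest archetype pair (maternal vs first wave) sits at
center distance 2.25 versus ≈ 4.5 for every other pair, so at much larger
noise the four-cluster structure genuinely collapses to three.

**Genomes and UTRs.** Homolog planting inserts substitution-only mutated
copies (⌊(1−identity)·L⌋ substitutions at uniform positions, either
strand) into i.i.d. uniform background genomes at non-overlapping
positions. UTR planting inserts either the full reverse complement of a
mature sequence (strongly pairing site) or an 8mer seed site, then
rejection-samples the background until no unintended canonical 6mer site
exists for *any* input miRNA.

What the simulator does **not** model: sequencing errors and quality
values, adapter artifacts, mappability and multi-mapping, genome repeat
structure, GC and length biases, correlated biological replicates, and
isomiR 3′ heterogeneity. Passing recovery tests therefore demonstrate
algorithmic correctness under the declared generative model, not
robustness to every artifact of real libraries.

## Candidate filtering

A hairpin passes when (i) both mature arms carry ≥ 10 reads, (ii) the
loop between the annotated arms is ≥ 8 nt, and (iii) on each arm at least
50% of assigned reads share the modal 5′ end. All thresholds are
inclusive ("at least"). Precursors flagged as conserved homologs are
rescued despite failures, with the violated rules still reported. Reads
are assigned to the arm covering ≥ 50% of the read (majority overlap);
reads overlapping neither arm sufficiently are excluded from both arms'
statistics; an arm with zero assigned reads has modal fraction 0 so arm
support fails before homogeneity. Contaminant removal is blacklist
substring matching with a Hamming budget (default ≤ 3 mismatches),
mirroring a short-read aligner run with a 3-mismatch tolerance without
the external dependency. The positional base-frequency summary is
computed over distinct read sequences; reads shorter than the 22-nt logo
window contribute only to the positions they cover and columns are
renormalized.

## Arm usage

Relative arm usage is rau = log2((N5′+1)/(N3′+1)), replicates summed
per time-point before the ratio. The pseudocount 1 on both arms keeps
the quantity finite and antisymmetric at zero counts; rau is computed
as a difference of logs so antisymmetry holds bit-exactly. A twofold
dominance band (|rau| ≥ 1) separates dominant from codominant
time-points; a developmental switch requires a 5′-dominant and a
3′-dominant time-point in one profile. Between species, pooled
whole-dataset counts give one rau per species; a pair is switched when
signs differ and exceeds the conventional tenfold boundary when
|rau_a − rau_b| ≥ log2 10 ≈ 3.3219.

## Homology search and family profiling

The search is seed-and-extend: exact 4-mers shared between query and
genome (both strands) define diagonal windows, each extended by
affine-gap Smith–Waterman (match +2, mismatch −3, gap open −5, extend −2;
a gap of length L costs −5 −2(L−1)). Hits are accepted by three
deterministic thresholds replacing E-values: alignment score ≥ 25
(≈ 13 exact matched bases, suppressing random micro-alignments),
identity ≥ 0.30 over the aligned columns, and query coverage ≥ 0.25.
The coverage floor is deliberately permissive: the local-alignment
optimum of a 70%-identity homolog occasionally trims to a
high-identity core below half the query length, and any alignment of
score s spans at least s/2 columns, so with full-length plantings at
identity ≥ 0.7 (score ≥ 0.5 L) recovery at coverage 0.25 is guaranteed.
Overlapping candidate alignments on the same contig and strand are
resolved greedily by descending score.

Families are assigned in two stages: a precursor whose dominant mature
aligns to a catalog mature at ≥ 70% identity joins that catalog family
(conserved); the rest are grouped by identical extended seed (mature
nt 2–8) into novel families. The family × species matrix counts
non-overlapping hit loci per family and species; species are clustered
from (binarized) column profiles by complete-linkage hierarchical
clustering under Euclidean distance, species sorted lexicographically
beforehand so ties resolve deterministically. Newick branch lengths are
the differences of merge heights along each edge, so root-to-leaf path
length equals the root merge height. The conservation summary reports
families shared with ≥ 1 other species, clade-restricted families, the
core set (shared families not restricted to the focal clade) and
focal-species-unique families.

## Expression dynamics

Size factors are median-of-ratios: per sample, the median over features
nonzero in all samples of count / geometric mean. Replicates are averaged
*after* normalization to per-time-point values used by the expressed
filter (≥ 10 normalized counts in ≥ 1 time-point, inclusive), the
Spearman time-point correlation matrix (average ranks for ties; constant
profiles reported missing), and per-feature z-scores (constant features
get all-zero z-scores and are excluded from clustering).

Fuzzy c-means follows Bezdek's alternating optimization with fuzzifier
m = 2, tolerance 1e-6 on the maximum membership change, and ≤ 1000
iterations. Because the objective has local optima, each fit runs 5
seeded restarts and keeps the lowest final objective (a single random
initialization was observed to land in clearly inferior optima). A
feature exactly at a center takes membership 1 there. Cluster counts are
chosen by the elbow method, operationalized as the maximum second
difference of the **log** objective over k = 2…10: absolute second
differences systematically select the smallest interior k whenever
cluster separations are hierarchical (the first split always removes the
most variance), whereas the log-curve curvature marks where relative
improvement collapses. A curve with no positive curvature returns the
smallest k, flagged. Cluster composition (novel vs conserved members) is
tested per cluster against the expressed-population ratio with a
df = 1 chi-squared statistic, no continuity correction; expected cells
below 1 attach a warning. The asymptotic χ² p-value is coarse for
cluster sizes ≲ 10.

## Differential expression

Each adjacent-stage contrast is a Wald test of log2 fold change on
normalized counts, log2FC = log2((mean_b + ½)/(mean_a + ½)) (the ½
pseudocount bounds fold changes of features absent in one stage).
The per-group variance is an empirical-Bayes compromise between the
feature's own sample variance s² (n_g − 1 df) and the variance implied by
a parametric mean-dispersion trend α(μ) = a₀ + a₁/μ fitted across
features (prior, `MODERATION_PRIOR_DF` = 12 df):

    v_g = (d0 · (μ_g + α_trend μ_g²) + (n_g−1) · s²_g) / (d0 + n_g − 1)

The delta-method SE of the log2FC uses v_g, and the statistic is referred
to a t distribution with d0 + residual df. Three alternatives were
evaluated and rejected: per-feature variance with a normal reference is
anticonservative at 4 replicates (≈ 9.5% of null p below 0.05);
per-feature variance with a residual-df t reference is calibrated but
loses power against the study's stringent padj ≤ 0.001 threshold (the
moment SE has ≈ 58% CV at 6 df); a pure trend variance with a normal
reference is powerful but anticonservative at high dispersion because the
group means of a negative binomial at n = 4 are still skewed. The
moderated estimator with d0 = 12 holds the false-positive rate at
0.03–0.07 across dispersions 0.01–0.5, keeps null p-values uniform, and
detects planted 8-fold activations at μ ≥ 100 with full power. d0 is
exposed as `prior_df`; supplying an explicit dispersion series switches
to the purely model-based NB variance. Features with zero normalized
counts in both groups are excluded from testing and from the
Benjamini–Hochberg denominator. `estimate_dispersion` retains the
classical zero-clipped method-of-moments definition for reporting.

The two-wave summary counts features with log2FC ≥ 1.5 and padj ≤ 0.001
per contrast and feature class and labels each class wave1 / wave2 /
both / neither by which contrasts show at least one activated feature —
the pattern of interest being protein-coding genes activating in both
waves while microRNAs activate almost exclusively in the second.

## Target prediction and targeting statistics

Canonical seed sites are exact reverse complements of miRNA nt 2–7 in
the UTR, typed by the m8 match (UTR base 5′ of the core pairing nt 8) and
the A1 anchor (an A opposite nt 1, regardless of complementarity):
6mer, 7mer-m8, 7mer-A1, 8mer; G:U is not accepted in site typing.
Duplex free energy is a dynamic program over intermolecular base pairs
(Watson–Crick and G:U, no intramolecular structure): consecutive pairs
add a nearest-neighbor stack free energy at 37 °C (Watson–Crick values
from the standard Xia/Turner measurement set; G:U-containing stacks
carry representative wobble values of the same family, including the
destabilizing tandem-wobble motifs); interrupted helices pay
3.0 + 0.3/nt, each side capped at 10 nt; a duplex with no stacked pair
has ΔG = 0, so ΔG ≤ 0 always. The energy is evaluated on the site plus a
5′ flank of one mature length. Because the absolute scale of any
simplified energy model differs from any other predictor's internals,
the −10 kcal/mol cutoff should be read as a cutoff *on this model's
scale*.

An interaction passes when ≥ 2 sites survive the strict energy cutoff
(ΔG < −10 exactly fails at −10.0), and both partners are expressed
(≥ 10 normalized counts in ≥ 1 time-point); co-expression at the same
time-point is deliberately not required. Per-cluster enrichment of
targeted mRNAs uses hypergeometric tails on the population of clustered
mRNAs with UTRs — upper tail P(X ≥ q) for over-representation, lower
tail for under — reporting the smaller tail with its direction and
Bonferroni adjustment over clusters. Targeting burden (distinct miRNAs
per mRNA; sites per UTR) is compared between cluster pairs with
two-sided Mann–Whitney tests: exact p by a rank-sum convolution DP
(average ranks doubled to integers; two-sided p = min(1, 2·min(lower,
upper tail))) whenever C(n+m, n) ≤ 2·10⁵, otherwise the tie-corrected
normal approximation; Bonferroni over pairs within each metric. Pairs
where either cluster has fewer than two targeted mRNAs are skipped with
a note.

## Numerical conventions and degenerate inputs

- All thresholds phrased "at least / below" in the filtering and
  targeting rules are inclusive/strict exactly as stated above; boundary
  behavior is covered by tests.
- Alignment traceback ties prefer, in order, a fresh start, a diagonal
  (match) predecessor, then a query gap; both the implementation and the
  test oracle share this convention.
- `compute_rau` uses log2(a) − log2(b) so antisymmetry is exact in
  floating point.
- Empty read sets, all-missing profiles, single-species matrices,
  all-zero features, constant replicate vectors, and UTRs too short for
  requested plantings raise informative errors rather than propagating
  NaNs.

## Problem sizes used in tests and the acceptance script

The shipped test-suite and `scripts/acceptance.py` exercise the pipeline
at desk scale, chosen to probe each method's operating regime: 500 read
stacks spanning every rule boundary; a 10⁴-pair arm-usage grid; planted
homologs at identities {1.0, 0.95, 0.85, 0.7} in 8–20 random 10-kb
genomes with a full Smith–Waterman oracle cross-check; 1000 archetype
profiles for clustering; 2000-feature null and 1000-feature planted
count matrices over 5–50 seeds for calibration and power; and exact
enumeration cross-checks for the hypergeometric and Mann–Whitney paths.

## Known limitations

- The homology search reports local alignments; paralog families with
  internal duplications can merge into one locus under the non-overlap
  rule, and copy numbers in highly repetitive regions are not meaningful.
- The duplex energy model omits initiation, dangling ends, terminal AU
  penalties and intramolecular structure; energies are comparable within
  this model only.
- The DE module is a two-group Wald pipeline, not a full GLM: no
  between-contrast shrinkage of fold changes, no outlier (Cook's)
  handling, no independent filtering. Divergence from any full-featured
  NB framework is expected in edge cases.
- The chi-squared composition test is asymptotic; for small clusters the
  reported p-values are approximate (a warning flags expected cells
  below 1).
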
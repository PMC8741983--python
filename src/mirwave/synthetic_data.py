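"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates a size-separated developmental RNA-seq study:
seven embryonic time-points, four small-library replicates (microRNAs)
and two large-library replicates (mRNAs / lncRNAs) per time-point.
It produces

* hairpin precursors with aligned small-read stacks (controlled per-arm
  depth, 5'-end jitter and loop length),
* negative-binomial count matrices whose mean trajectories follow five
  developmental archetypes (maternal decay, first-wave zygotic peak at
  the second time-point, mid peak, late peak, flat null),
* random-background genomes with planted precursor homologs at
  controlled identity and copy number,
* 3'UTRs with planted canonical seed sites of controlled strength,

together with a :class:`TruthTable` recording every planted entity so
downstream modules can be tested for exact recovery.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .preprocess_filter import PrecursorCandidate

NUCLEOTIDES = np.array(list("ACGU"))

#: Archetype shape functions over time-point index t (0-based), length T.
ARCHETYPES = ("maternal", "wave1", "mid", "late", "flat")

#: Default archetype mix: observed cluster proportions in a seven-stage
#: crustacean embryogenesis time course (maternal 26%, first zygotic wave
#: 15%, mid 20%, late 39%).
DEFAULT_ARCHETYPE_FRACTIONS = {
    "maternal": 0.26,
    "wave1": 0.15,
    "mid": 0.20,
    "late": 0.39,
}

_COMPLEMENT = str.maketrans("ACGUT", "UGCAA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Shared knobs for all generators; ``rng_seed`` fully determines output."""

    rng_seed: int = 0
    n_timepoints: int = 7
    n_replicates_small: int = 4
    n_replicates_large: int = 2
    nb_dispersion: float = 0.1
    archetype_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_FRACTIONS)
    )
    fold_change_planted: float = 8.0
    library_size_range: Tuple[int, int] = (50_000, 150_000)

    def __post_init__(self) -> None:
        if self.n_timepoints < 1 or self.n_replicates_small < 1 or self.n_replicates_large < 1:
            raise ValueError("time-point and replicate counts must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.fold_change_planted <= 0:
            raise ValueError("fold_change_planted must be positive")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("library_size_range must be increasing positive integers")
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        total = float(sum(self.archetype_fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions must sum to 1, got {total}")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.rng_seed, salt))

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["archetype_fractions"] = dict(d["archetype_fractions"])
        d["library_size_range"] = list(d["library_size_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["library_size_range"] = tuple(d["library_size_range"])
        return cls(**d)


@dataclass
class TruthTable:
    """Planted ground truth; each generator fills the fields it owns."""

    features: Optional[pd.DataFrame] = None          # archetype / planted LFC per feature
    library_multipliers: Optional[pd.Series] = None  # per-sample depth multiplier
    stack_verdicts: Optional[pd.DataFrame] = None    # intended filter verdict per precursor
    arm_ratios: Optional[pd.DataFrame] = None        # planted 5p/3p depth per precursor
    homologs: Optional[pd.DataFrame] = None          # planted genome copies
    utr_sites: Optional[pd.DataFrame] = None         # planted seed sites / targeted flags

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {}
        for name in ("features", "stack_verdicts", "arm_ratios", "homologs", "utr_sites"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = df.to_dict(orient="list")
        if self.library_multipliers is not None:
            payload["library_multipliers"] = self.library_multipliers.to_dict()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# hairpin read stacks
# ---------------------------------------------------------------------------

@dataclass
class StackSpec:
    """Requested properties of one simulated precursor read stack."""

    precursor_id: str
    depth_5p: int = 50
    depth_3p: int = 50
    modal_5prime_fraction: float = 0.9
    loop_length: int = 10
    conserved: bool = False
    mature_length: int = 22

    def __post_init__(self) -> None:
        if self.loop_length < 0:
            raise ValueError(f"{self.precursor_id}: loop length must be >= 0")
        if not 0.0 < self.modal_5prime_fraction <= 1.0:
            raise ValueError("modal_5prime_fraction must be in (0, 1]")
        if self.depth_5p < 0 or self.depth_3p < 0:
            raise ValueError("arm depths must be non-negative")


_JITTER_OFFSETS = (0, -1, 1, -2, 2)  # modal position first, then flanks
_FLANK = 5  # precursor flank so that +/-2 jitter stays in bounds


def _quota_offsets(depth: int, modal_fraction: float) -> List[int]:
    """Largest-remainder realization of the categorical 5'-offset law.

    The modal offset (0) receives round(fraction * depth) reads; the rest
    are split as evenly as possible over the four flanking offsets.  The
    realized stack therefore hits the requested modal fraction exactly
    (up to integer rounding), which keeps planted verdicts exact at the
    50% homogeneity boundary.
    """
    if depth == 0:
        return []
    n_modal = int(round(modal_fraction * depth))
    n_modal = min(max(n_modal, 0), depth)
    rest = depth - n_modal
    base, extra = divmod(rest, 4)
    counts = {0: n_modal}
    for i, off in enumerate(_JITTER_OFFSETS[1:]):
        counts[off] = base + (1 if i < extra else 0)
    offsets: List[int] = []
    for off in _JITTER_OFFSETS:
        offsets.extend([off] * counts[off])
    return offsets


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def gen_hairpin_readstacks(
    config: SimulationConfig,
    specs: Optional[Sequence[StackSpec]] = None,
    n_precursors: int = 50,
) -> Tuple[List[PrecursorCandidate], pd.DataFrame, TruthTable]:
    """Simulate precursors plus aligned read stacks and the intended verdicts.

    Without an explicit ``specs`` list, ``n_precursors`` stacks are drawn
    with a mix of clean passes and single-rule failures.
    """
    rng = config.rng(salt=1)
    if specs is None:
        specs = _default_stack_specs(rng, n_precursors)

    precursors: List[PrecursorCandidate] = []
    read_rows: List[Tuple] = []
    truth_rows: List[Dict] = []

    for spec in specs:
        m = spec.mature_length
        seq = _random_seq(rng, 2 * _FLANK + 2 * m + spec.loop_length)
        s5 = _FLANK
        e5 = s5 + m
        s3 = e5 + spec.loop_length
        e3 = s3 + m
        prec = PrecursorCandidate(
            precursor_id=spec.precursor_id,
            sequence=seq,
            mature5p=(s5, e5),
            mature3p=(s3, e3),
            conserved_flag=spec.conserved,
        )
        precursors.append(prec)

        realized_modal: Dict[str, float] = {}
        for arm, depth, start0 in (("5p", spec.depth_5p, s5), ("3p", spec.depth_3p, s3)):
            offsets = _quota_offsets(depth, spec.modal_5prime_fraction)
            rng.shuffle(offsets)
            if offsets:
                counts = pd.Series(offsets).value_counts()
                realized_modal[arm] = counts.max() / float(depth)
            else:
                realized_modal[arm] = 0.0
            for k, off in enumerate(offsets):
                start = start0 + int(off)
                end = min(start + m, len(seq))
                read_rows.append(
                    (f"{spec.precursor_id}_{arm}_{k}", spec.precursor_id,
                     start, end, seq[start:end])
                )

        reasons = []
        if spec.depth_5p < 10 or spec.depth_3p < 10:
            reasons.append("arm_support")
        if spec.loop_length < 8:
            reasons.append("loop_length")
        if min(realized_modal["5p"], realized_modal["3p"]) < 0.5:
            reasons.append("five_prime_heterogeneity")
        accepted = not reasons or spec.conserved
        truth_rows.append(
            dict(
                precursor_id=spec.precursor_id,
                accepted=accepted,
                reasons=",".join(reasons),
                rescued_by_conservation=bool(reasons) and spec.conserved,
                depth_5p=spec.depth_5p,
                depth_3p=spec.depth_3p,
                loop_length=spec.loop_length,
                modal_fraction_5p=realized_modal["5p"],
                modal_fraction_3p=realized_modal["3p"],
            )
        )

    reads = pd.DataFrame(
        read_rows, columns=["read_id", "precursor_id", "start", "end", "sequence"]
    )
    truth = TruthTable(stack_verdicts=pd.DataFrame(truth_rows))
    return precursors, reads, truth


def _default_stack_specs(rng: np.random.Generator, n: int) -> List[StackSpec]:
    specs = []
    for i in range(n):
        kind = rng.integers(0, 5)
        depth5 = depth3 = int(rng.integers(20, 200))
        frac = 0.9
        loop = int(rng.integers(8, 30))
        if kind == 1:    # arm-support failure
            depth3 = int(rng.integers(0, 10))
        elif kind == 2:  # loop failure
            loop = int(rng.integers(0, 8))
        elif kind == 3:  # heterogeneity failure
            depth5 = depth3 = 100
            frac = 0.3
        conserved = kind == 4 and bool(rng.integers(0, 2))
        if kind == 4 and conserved:
            depth3 = 5  # rescued despite failing arm support
        specs.append(
            StackSpec(
                precursor_id=f"phc-sim-{i:04d}",
                depth_5p=depth5,
                depth_3p=depth3,
                modal_5prime_fraction=frac,
                loop_length=loop,
                conserved=conserved,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def archetype_trajectory(archetype: str, n_timepoints: int) -> np.ndarray:
    """Relative (max = 1) mean trajectory of one developmental archetype."""
    t = np.arange(n_timepoints, dtype=float)
    if archetype == "maternal":
        shape = 0.5 ** t                       # geometric decay, half-life 1 tp
    elif archetype == "wave1":
        shape = np.exp(-0.5 * ((t - 1.0) / 0.8) ** 2)
    elif archetype == "mid":
        mid = (n_timepoints - 1) / 2.0
        shape = np.exp(-0.5 * ((t - mid) / 1.0) ** 2)
    elif archetype == "late":
        shape = np.exp(-0.5 * ((t - (n_timepoints - 1)) / 1.2) ** 2)
    elif archetype == "flat":
        shape = np.ones_like(t)
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    return shape / shape.max()


@dataclass
class CountData:
    """A counts matrix plus its sample and feature sheets."""

    counts: pd.DataFrame          # features x samples, integer
    samples: pd.DataFrame         # sample_id, time_point, replicate
    features: pd.DataFrame        # feature_id, feature_class, conservation


def gen_count_matrix(
    config: SimulationConfig,
    feature_class: str = "mirna",
    n_features: int = 500,
    n_planted_up: int = 0,
    up_between: Tuple[int, int] = (1, 2),
    base_mean: float = 200.0,
    novel_fraction: float = 0.5,
) -> Tuple[CountData, TruthTable]:
    """Simulate a negative-binomial count matrix with archetype trajectories.

    ``n_planted_up`` flat features are additionally up-regulated by
    ``config.fold_change_planted`` from time-point index ``up_between[1]``
    onward (an activation between the two adjacent stages in
    ``up_between``); variance follows var = mu + alpha * mu^2.
    """
    class_salt = {"mirna": 2, "mrna": 3, "lncrna": 4}
    if feature_class not in class_salt:
        raise ValueError(f"unknown feature class {feature_class!r}")
    rng = config.rng(salt=class_salt[feature_class])
    T = config.n_timepoints
    n_rep = config.n_replicates_small if feature_class == "mirna" else config.n_replicates_large
    a, b = up_between
    if not (0 <= a < b < T):
        raise ValueError("up_between must be an increasing pair of time-point indices")

    names = list(config.archetype_fractions)
    probs = np.array([config.archetype_fractions[k] for k in names], dtype=float)
    archetypes = list(rng.choice(names, size=n_features, p=probs / probs.sum()))
    planted_lfc = np.zeros(n_features)
    if n_planted_up > 0:
        idx = rng.choice(n_features, size=min(n_planted_up, n_features), replace=False)
        for i in idx:
            archetypes[i] = "flat"
            planted_lfc[i] = np.log2(config.fold_change_planted)

    base = np.exp(rng.normal(np.log(base_mean), 0.8, size=n_features))
    mu_t = np.empty((n_features, T))
    for i, arch in enumerate(archetypes):
        traj = archetype_trajectory(arch, T) * base[i]
        if planted_lfc[i] > 0:
            traj = traj.copy()
            traj[b:] *= config.fold_change_planted
        mu_t[i] = np.maximum(traj, 0.05)

    sample_ids, tp_of_sample = [], []
    for t in range(T):
        for r in range(n_rep):
            sample_ids.append(f"S{t + 1}_r{r + 1}")
            tp_of_sample.append(t)
    lo, hi = config.library_size_range
    lib_sizes = rng.integers(lo, hi + 1, size=len(sample_ids)).astype(float)

    mu = mu_t[:, tp_of_sample]
    # scale each column so its expected sum equals the drawn library size
    mu = mu * (lib_sizes / mu.sum(axis=0))[None, :]
    alpha = config.nb_dispersion
    if alpha > 1e-12:
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    feature_ids = [f"{feature_class}-{i:05d}" for i in range(n_features)]
    conservation = rng.choice(
        ["novel", "conserved"], size=n_features, p=[novel_fraction, 1 - novel_fraction]
    )
    counts_df = pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                             columns=sample_ids)
    samples = pd.DataFrame(
        {"sample_id": sample_ids,
         "time_point": [t + 1 for t in tp_of_sample],
         "replicate": [int(s.split("_r")[1]) for s in sample_ids]}
    )
    features = pd.DataFrame(
        {"feature_id": feature_ids, "feature_class": feature_class,
         "conservation": conservation}
    )
    truth = TruthTable(
        features=pd.DataFrame(
            {"feature_id": feature_ids, "archetype": archetypes,
             "planted_lfc": planted_lfc, "conservation": conservation,
             "base_mean": base}
        ),
        library_multipliers=pd.Series(lib_sizes / lib_sizes.mean(), index=sample_ids),
    )
    return CountData(counts_df, samples, features), truth


def gen_archetype_profiles(
    config: SimulationConfig,
    n_features: int = 1000,
    noise_sd: float = 0.3,
    archetypes: Sequence[str] = ("maternal", "wave1", "mid", "late"),
) -> Tuple[pd.DataFrame, TruthTable]:
    """Z-score expression profiles drawn directly from the archetypes.

    Each feature is a z-scored archetype trajectory plus isotropic
    Gaussian noise of standard deviation ``noise_sd`` — the clean
    profile-space counterpart of :func:`gen_count_matrix`, used to probe
    clustering and elbow behaviour without count noise.
    """
    rng = config.rng(salt=5)
    T = config.n_timepoints
    centers = {}
    for arch in archetypes:
        traj = archetype_trajectory(arch, T)
        sd = traj.std()
        if sd == 0:
            raise ValueError(f"archetype {arch!r} is constant; not usable here")
        centers[arch] = (traj - traj.mean()) / sd
    labels = [archetypes[i] for i in rng.integers(0, len(archetypes), n_features)]
    X = np.array([centers[a] for a in labels]) + rng.normal(0, noise_sd, (n_features, T))
    ids = [f"profile-{i:05d}" for i in range(n_features)]
    profiles = pd.DataFrame(X, index=pd.Index(ids, name="feature_id"),
                            columns=[f"tp{t + 1}" for t in range(T)])
    truth = TruthTable(features=pd.DataFrame({"feature_id": ids, "archetype": labels}))
    return profiles, truth


# ---------------------------------------------------------------------------
# genomes with planted homologs
# ---------------------------------------------------------------------------

@dataclass
class HomologPlant:
    """One planted precursor family in one species' genome."""

    species_id: str
    precursor_id: str
    copies: int = 1
    identity: float = 1.0
    strand: Optional[str] = None  # '+', '-', or None for random

    def __post_init__(self) -> None:
        if not 0.0 < self.identity <= 1.0:
            raise ValueError("identity must be in (0, 1]")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> Tuple[str, int]:
    n_sub = int(np.floor((1.0 - identity) * len(seq)))
    if n_sub == 0:
        return seq, 0
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for p in pos:
        alternatives = [c for c in "ACGU" if c != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars), n_sub


def gen_genomes_with_homologs(
    config: SimulationConfig,
    precursors: Sequence[PrecursorCandidate],
    plan: Sequence[HomologPlant],
    genome_length: int = 10_000,
) -> Tuple[Dict[str, str], TruthTable]:
    """Random-background genomes with planted precursor copies.

    Each plant inserts ``copies`` substitution-mutated copies of the
    precursor at non-overlapping random positions (either strand); the
    truth table records coordinates, strand and realized identity.
    """
    if not precursors:
        raise ValueError("need at least one precursor")
    rng = config.rng(salt=3)
    by_id = {p.precursor_id: p for p in precursors}
    species = sorted({pl.species_id for pl in plan})
    genomes: Dict[str, str] = {}
    rows: List[Dict] = []
    for sp in species:
        genome = list(_random_seq(rng, genome_length))
        occupied: List[Tuple[int, int]] = []
        for pl in [p for p in plan if p.species_id == sp]:
            if pl.precursor_id not in by_id:
                raise ValueError(f"unknown precursor {pl.precursor_id!r} in plan")
            src = by_id[pl.precursor_id].sequence
            for _ in range(pl.copies):
                mutated, n_sub = _mutate(rng, src, pl.identity)
                strand = pl.strand or ("+" if rng.integers(0, 2) == 0 else "-")
                insert = mutated if strand == "+" else reverse_complement(mutated)
                for _attempt in range(1000):
                    start = int(rng.integers(0, genome_length - len(insert)))
                    end = start + len(insert)
                    if all(end <= s or start >= e for s, e in occupied):
                        break
                else:
                    raise RuntimeError("could not place homolog without overlap")
                genome[start:end] = list(insert)
                occupied.append((start, end))
                rows.append(
                    dict(species_id=sp, contig="chr1", start=start, end=end,
                         strand=strand, precursor_id=pl.precursor_id,
                         identity=1.0 - n_sub / len(src))
                )
        genomes[sp] = "".join(genome)
    truth = TruthTable(homologs=pd.DataFrame(
        rows, columns=["species_id", "contig", "start", "end", "strand",
                       "precursor_id", "identity"]))
    return genomes, truth


# ---------------------------------------------------------------------------
# UTRs with planted seed sites
# ---------------------------------------------------------------------------

@dataclass
class SitePlant:
    """Planted target sites of one microRNA in one UTR."""

    mirna_id: str
    utr_id: str
    n_sites: int = 2
    perfect: bool = True  # full-length complement (strongly pairing) vs seed-only


def gen_utr_targets(
    config: SimulationConfig,
    mirnas: Mapping[str, str],
    plan: Sequence[SitePlant],
    utr_ids: Optional[Sequence[str]] = None,
    utr_length: int = 2000,
) -> Tuple[Dict[str, str], TruthTable]:
    """UTRs with planted canonical seed sites and clean background.

    Background sequence is rejection-sampled so that no UTR contains an
    unintended canonical 6mer site (reverse complement of miRNA nt 2-7)
    for *any* input microRNA.  ``perfect`` plants insert the reverse
    complement of the full mature sequence (minimal duplex energy);
    seed-only plants insert an 8mer site.
    """
    for mid, seq in mirnas.items():
        if not 18 <= len(seq) <= 26:
            raise ValueError(f"mature sequence {mid!r} must be 18-26 nt")
    rng = config.rng(salt=4)
    if utr_ids is None:
        utr_ids = sorted({pl.utr_id for pl in plan})
    site_words = {mid: reverse_complement(seq[1:7]) for mid, seq in mirnas.items()}

    utrs: Dict[str, str] = {}
    rows: List[Dict] = []
    for uid in utr_ids:
        plants = [pl for pl in plan if pl.utr_id == uid]
        inserts: List[Tuple[str, str, bool]] = []
        for pl in plants:
            if pl.mirna_id not in mirnas:
                raise ValueError(f"unknown miRNA {pl.mirna_id!r} in plan")
            mat = mirnas[pl.mirna_id]
            if pl.perfect:
                ins = reverse_complement(mat)
            else:  # 8mer: seed complement (nt 2-8) followed by an A opposite nt 1
                ins = reverse_complement(mat[1:8]) + "A"
            inserts.extend([(pl.mirna_id, ins, pl.perfect)] * pl.n_sites)
        needed = sum(len(i[1]) + 2 for i in inserts)
        if needed > utr_length:
            raise ValueError(f"UTR {uid!r} too short for requested sites")

        utr, placements = _build_clean_utr(rng, utr_length, inserts, site_words)
        utrs[uid] = utr
        for (mid, start, end, perfect) in placements:
            rows.append(dict(utr_id=uid, mirna_id=mid, start=start, end=end,
                             perfect=perfect))
    sites = pd.DataFrame(rows, columns=["utr_id", "mirna_id", "start", "end", "perfect"])
    # targeted flag: >=2 strongly pairing sites planted for the pair
    if len(sites):
        targeted = (sites.groupby(["mirna_id", "utr_id"])
                    .agg(n_sites=("start", "size"), n_perfect=("perfect", "sum"))
                    .reset_index())
        targeted["targeted"] = targeted["n_perfect"] >= 2
    else:
        targeted = pd.DataFrame(
            columns=["mirna_id", "utr_id", "n_sites", "n_perfect", "targeted"])
    truth = TruthTable(utr_sites=sites, features=targeted)
    return utrs, truth


def _build_clean_utr(
    rng: np.random.Generator,
    length: int,
    inserts: List[Tuple[str, str, bool]],
    site_words: Mapping[str, str],
) -> Tuple[str, List[Tuple[int, int, int, bool]]]:
    """Random UTR with the inserts placed and no unintended canonical sites."""
    for _attempt in range(200):
        seq = list(_random_seq(rng, length))
        placements = []
        occupied: List[Tuple[int, int]] = []
        ok = True
        for mid, ins, perfect in inserts:
            for _try in range(500):
                start = int(rng.integers(1, length - len(ins) - 1))
                end = start + len(ins)
                if all(end + 8 <= s or start >= e + 8 for s, e in occupied):
                    break
            else:
                ok = False
                break
            seq[start:end] = list(ins)
            occupied.append((start, end))
            placements.append((mid, start, end, perfect))
        if not ok:
            continue
        utr = "".join(seq)
        # scrub unintended canonical sites by resampling the offending window
        for _round in range(200):
            dirty = False
            for mid, word in site_words.items():
                planted = [(s, e) for m, s, e, _p in placements if m == mid]
                pos = utr.find(word)
                while pos != -1:
                    inside = any(s <= pos and pos + 6 <= e for s, e in planted)
                    if not inside and not any(
                        s < pos + 6 and pos < e for s, e in occupied
                    ):
                        utr = (utr[:pos] + _random_seq(rng, 6) + utr[pos + 6:])
                        dirty = True
                        break
                    pos = utr.find(word, pos + 1)
                if dirty:
                    break
            if not dirty:
                return utr, placements
    raise RuntimeError("failed to build a clean UTR; relax the request")


# ---------------------------------------------------------------------------
# one-call simulation for the CLI
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, outdir: str | os.PathLike) -> None:
    """Write a complete synthetic input bundle (FASTA/TSV/JSON/YAML) to disk."""
    from . import io_utils

    os.makedirs(outdir, exist_ok=True)
    out = lambda name: os.path.join(str(outdir), name)  # noqa: E731
    config.to_yaml(out("config.yaml"))

    precursors, reads, truth_stacks = gen_hairpin_readstacks(config)
    io_utils.write_fasta(out("precursors.fa"), {p.precursor_id: p.sequence for p in precursors})
    io_utils.write_tsv(out("reads.tsv"), reads)
    gff_rows = []
    for p in precursors:
        attrs = f"ID={p.precursor_id}"
        if p.conserved_flag:
            attrs += ";conserved=1"
        gff_rows.append((p.precursor_id, "mirwave", "miRNA_primary_transcript",
                         1, len(p.sequence), ".", "+", ".", attrs))
        for arm, (s, e) in (("5p", p.mature5p), ("3p", p.mature3p)):
            gff_rows.append((p.precursor_id, "mirwave", "miRNA", s + 1, e, ".", "+",
                             ".", f"ID={p.precursor_id}-{arm};Parent={p.precursor_id}"))
    io_utils.write_gff3(out("precursors.gff3"), gff_rows)

    mirna, truth_mirna = gen_count_matrix(config, "mirna")
    mrna, truth_mrna = gen_count_matrix(config, "mrna")
    for name, data in (("mirna", mirna), ("mrna", mrna)):
        io_utils.write_tsv(out(f"counts_{name}.tsv"), data.counts.reset_index())
        io_utils.write_tsv(out(f"samples_{name}.tsv"), data.samples)
        io_utils.write_tsv(out(f"features_{name}.tsv"), data.features)

    plan = [HomologPlant("species_A", precursors[0].precursor_id, copies=2, identity=0.95),
            HomologPlant("species_B", precursors[0].precursor_id, copies=1, identity=0.85)]
    genomes, truth_gen = gen_genomes_with_homologs(config, precursors[:5], plan)
    for sp, seq in genomes.items():
        io_utils.write_fasta(out(f"genome_{sp}.fa"), {"chr1": seq})

    matures = {f"{p.precursor_id}-5p": p.sequence[p.mature5p[0]:p.mature5p[1]]
               for p in precursors[:5]}
    io_utils.write_fasta(out("matures.fa"), matures)
    site_plan = [SitePlant(list(matures)[0], "utr-0000", n_sites=2, perfect=True),
                 SitePlant(list(matures)[1], "utr-0001", n_sites=1, perfect=True)]
    utrs, truth_utr = gen_utr_targets(config, matures, site_plan)
    io_utils.write_fasta(out("utrs.fa"), utrs)

    truth_stacks.to_json(out("truth_stacks.json"))
    truth_mirna.to_json(out("truth_mirna.json"))
    truth_mrna.to_json(out("truth_mrna.json"))
    truth_gen.to_json(out("truth_genomes.json"))
    truth_utr.to_json(out("truth_utrs.json"))
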
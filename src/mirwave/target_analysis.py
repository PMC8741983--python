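"""MicroRNA target prediction and cluster-level targeting statistics.

Canonical seed sites (6mer, 7mer-A1, 7mer-m8, 8mer; Watson-Crick only)
are located by exhaustive scanning of each 3'UTR for the reverse
complement of miRNA nucleotides 2-7.  Each site's duplex free energy is
the minimum over intermolecular pairings (Watson-Crick and G:U, no
intramolecular structure) of the sum of nearest-neighbor stack energies
at 37 degC plus simple loop penalties.  An interaction passes when at
least ``min_sites`` sites survive a strict energy cutoff (default
below -10 kcal/mol) and both partners are expressed (>= 10 normalized
counts in >= 1 time-point).  Per expression cluster, over/under
representation of targeted mRNAs is assessed with hypergeometric tail
tests and targeting burden (distinct miRNAs per mRNA, sites per UTR)
with pairwise two-sided Mann-Whitney tests; both use Bonferroni
adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import reverse_complement

_VALID = set("ACGU")
_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def _normalize_rna(seq: str, what: str) -> str:
    seq = seq.upper().replace("T", "U")
    if set(seq) - _VALID:
        raise ValueError(f"{what} contains non-AUGC characters")
    return seq


# ---------------------------------------------------------------------------
# seed sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedSite:
    utr_id: str
    mirna_id: str
    site_type: str       # 6mer | 7mer-A1 | 7mer-m8 | 8mer
    start: int           # 0-based half-open span of the typed site on the UTR
    end: int


def find_seed_sites(
    mirna: str, utr: str, mirna_id: str = "mirna", utr_id: str = "utr"
) -> List[SeedSite]:
    """All canonical seed matches of one miRNA in one UTR.

    The 6mer core is the reverse complement of miRNA nt 2-7.  The match
    is upgraded to 7mer-m8 when the UTR base 5' of the core pairs with
    miRNA nt 8, to 7mer-A1 when the base 3' of the core is an A, and to
    8mer when both hold; each match is reported once with its most
    specific type.
    """
    mirna = _normalize_rna(mirna, "miRNA")
    utr = _normalize_rna(utr, "UTR")
    if len(mirna) < 8:
        raise ValueError("mature miRNA must be at least 8 nt")
    core = reverse_complement(mirna[1:7])
    comp_m8 = reverse_complement(mirna[7])
    sites = []
    pos = utr.find(core)
    while pos != -1:
        m8 = pos >= 1 and utr[pos - 1] == comp_m8
        a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if m8 and a1:
            site_type, start, end = "8mer", pos - 1, pos + 7
        elif m8:
            site_type, start, end = "7mer-m8", pos - 1, pos + 6
        elif a1:
            site_type, start, end = "7mer-A1", pos, pos + 7
        else:
            site_type, start, end = "6mer", pos, pos + 6
        sites.append(SeedSite(utr_id, mirna_id, site_type, start, end))
        pos = utr.find(core, pos + 1)
    return sites


# ---------------------------------------------------------------------------
# nearest-neighbor duplex energy
# ---------------------------------------------------------------------------

def _build_stack_table() -> Dict[Tuple[str, str, str, str], float]:
    """Stack free energies (kcal/mol, 37 degC) keyed by 5'WX3'/3'ZY5'.

    Watson-Crick stacks use the standard Xia et al. measurement set;
    G:U-containing stacks use representative wobble values of the same
    parameter family (including the destabilizing tandem-wobble motifs).
    Symmetry value(WX/ZY) = value(YZ/XW) is enforced by construction.
    """
    known = {
        ("A", "A", "U", "U"): -0.93,
        ("A", "U", "U", "A"): -1.10,
        ("U", "A", "A", "U"): -1.33,
        ("C", "U", "G", "A"): -2.08,
        ("C", "A", "G", "U"): -2.11,
        ("G", "U", "C", "A"): -2.24,
        ("G", "A", "C", "U"): -2.35,
        ("C", "G", "G", "C"): -2.36,
        ("G", "G", "C", "C"): -3.26,
        ("G", "C", "C", "G"): -3.42,
        # wobble-containing stacks
        ("A", "G", "U", "U"): -0.55,
        ("A", "U", "U", "G"): -1.36,
        ("C", "G", "G", "U"): -1.41,
        ("C", "U", "G", "G"): -2.11,
        ("G", "G", "C", "U"): -1.53,
        ("G", "U", "C", "G"): -2.51,
        ("G", "G", "U", "U"): +0.47,
        ("G", "U", "U", "G"): +0.30,
        ("U", "G", "G", "U"): -0.50,
    }
    table: Dict[Tuple[str, str, str, str], float] = {}
    pairs = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
    for (w, z) in pairs:
        for (x, y) in pairs:
            key = (w, x, z, y)
            sym = (y, z, x, w)
            if key in known:
                table[key] = known[key]
            elif sym in known:
                table[key] = known[sym]
            else:
                n_wobble = ((w, z) in {("G", "U"), ("U", "G")}) + \
                           ((x, y) in {("G", "U"), ("U", "G")})
                table[key] = -1.2 if n_wobble == 1 else +0.3
    return table


STACK_TABLE = _build_stack_table()

#: loop penalties for interrupted helices (kcal/mol)
LOOP_INIT = 3.0
LOOP_PER_NT = 0.3
MAX_LOOP = 10


@dataclass(frozen=True)
class DuplexEnergy:
    utr_id: str
    mirna_id: str
    start: int
    delta_g: float  # kcal/mol


def duplex_energy(mirna: str, utr_window: str) -> float:
    """Minimum free energy of the intermolecular miRNA:UTR duplex.

    Dynamic program over base pairs (miRNA 5'->3' against the window
    3'->5'); consecutive pairs add a nearest-neighbor stack energy,
    interrupted helices pay LOOP_INIT + LOOP_PER_NT per unpaired base
    (each side capped at MAX_LOOP).  A duplex with no stacked pair has
    energy 0.
    """
    a = _normalize_rna(mirna, "miRNA")
    b = _normalize_rna(utr_window, "window")
    if len(b) < 1 or len(a) < 1:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    INF = float("inf")
    # E[i][j]: best energy of a duplex whose 3'-most miRNA pair is (i, j)
    E = [[INF] * m for _ in range(n)]
    best = 0.0
    pairable = [[(a[i], b[j]) in _PAIRS for j in range(m)] for i in range(n)]
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if not pairable[i][j]:
                continue
            e = 0.0  # open a fresh helix at this pair
            for di in range(1, min(i, MAX_LOOP + 1) + 1):
                i_prev = i - di
                for dj in range(1, min(m - 1 - j, MAX_LOOP + 1) + 1):
                    j_prev = j + dj
                    prev = E[i_prev][j_prev]
                    if prev == INF:
                        continue
                    if di == 1 and dj == 1:
                        cost = STACK_TABLE[(a[i_prev], a[i], b[j_prev], b[j])]
                    else:
                        cost = LOOP_INIT + LOOP_PER_NT * (di - 1 + dj - 1)
                    if prev + cost < e:
                        e = prev + cost
            E[i][j] = e
            if e < best:
                best = e
    return best


def site_window(utr: str, site: SeedSite, mirna_length: int) -> str:
    """UTR window covering the site plus a flank of one mature length 5'."""
    start = max(0, site.start - mirna_length)
    return utr[start:site.end + 2][: mirna_length + (site.end - site.start) + 2]


# ---------------------------------------------------------------------------
# interaction filtering
# ---------------------------------------------------------------------------

@dataclass
class Interaction:
    mirna_id: str
    mrna_id: str
    sites: List[SeedSite] = field(default_factory=list)
    min_delta_g: float = 0.0
    n_sites: int = 0
    passes_filters: bool = False


def expressed_ids(tp_means: pd.DataFrame, threshold: float) -> set:
    return set(tp_means.index[(tp_means >= threshold).any(axis=1)])


def filter_interactions(
    sites: Sequence[SeedSite],
    energies: Mapping[Tuple[str, str, int], float],
    expr_mirna: pd.DataFrame,
    expr_mrna: pd.DataFrame,
    energy_cutoff: float = -10.0,
    expr_threshold: float = 10.0,
    min_sites: int = 2,
) -> List[Interaction]:
    """Apply the interaction filters.

    A site survives when its duplex energy is strictly below
    ``energy_cutoff``; an interaction passes when >= ``min_sites`` sites
    survive and both partners reach ``expr_threshold`` normalized counts
    in at least one time-point (expression tables are feature x
    time-point means).  Co-expression at the same time-point is not
    required.
    """
    ok_mirna = expressed_ids(expr_mirna, expr_threshold)
    ok_mrna = expressed_ids(expr_mrna, expr_threshold)
    grouped: Dict[Tuple[str, str], List[SeedSite]] = {}
    for site in sites:
        if site.mirna_id not in expr_mirna.index:
            raise ValueError(f"site references unknown miRNA {site.mirna_id!r}")
        if site.utr_id not in expr_mrna.index:
            raise ValueError(f"site references unknown mRNA {site.utr_id!r}")
        grouped.setdefault((site.mirna_id, site.utr_id), []).append(site)
    interactions = []
    for (mirna_id, mrna_id), site_list in sorted(grouped.items()):
        kept = []
        energies_kept = []
        for s in site_list:
            dg = energies[(s.utr_id, s.mirna_id, s.start)]
            if dg < energy_cutoff:
                kept.append(s)
                energies_kept.append(dg)
        passes = (
            len(kept) >= min_sites
            and mirna_id in ok_mirna
            and mrna_id in ok_mrna
        )
        interactions.append(
            Interaction(mirna_id, mrna_id, kept,
                        min(energies_kept) if energies_kept else 0.0,
                        len(kept), passes)
        )
    return interactions


def predict_interactions(
    mirnas: Mapping[str, str],
    utrs: Mapping[str, str],
    expr_mirna: pd.DataFrame,
    expr_mrna: pd.DataFrame,
    **filter_kwargs,
) -> Tuple[List[SeedSite], Dict[Tuple[str, str, int], float], List[Interaction]]:
    """Site scan + energy evaluation + filtering for all pairs."""
    sites: List[SeedSite] = []
    energies: Dict[Tuple[str, str, int], float] = {}
    for mirna_id in sorted(mirnas):
        mat = mirnas[mirna_id]
        for utr_id in sorted(utrs):
            for site in find_seed_sites(mat, utrs[utr_id], mirna_id, utr_id):
                sites.append(site)
                window = site_window(_normalize_rna(utrs[utr_id], "UTR"), site, len(mat))
                energies[(utr_id, mirna_id, site.start)] = duplex_energy(mat, window)
    interactions = filter_interactions(sites, energies, expr_mirna, expr_mrna,
                                       **filter_kwargs)
    return sites, energies, interactions


# ---------------------------------------------------------------------------
# enrichment and burden statistics
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    cluster: str
    q: int           # targeted mRNAs in the cluster
    m: int           # targeted mRNAs in the population
    n: int           # non-targeted mRNAs in the population
    k: int           # cluster size
    direction: str   # over | under
    pvalue: float
    padj: float


def hypergeom_upper(q: int, m: int, n: int, k: int) -> float:
    """P(X >= q) for X hypergeometric(m successes, n failures, k drawn)."""
    return float(stats.hypergeom.sf(q - 1, m + n, m, k))


def hypergeom_lower(q: int, m: int, n: int, k: int) -> float:
    return float(stats.hypergeom.cdf(q, m + n, m, k))


def targeting_enrichment(
    interactions: Sequence[Interaction],
    cluster_assignments: Mapping[str, str],
    utr_availability: Mapping[str, bool],
) -> List[EnrichmentResult]:
    """Hypergeometric enrichment of targeted mRNAs per expression cluster.

    The population is restricted to clustered mRNAs with an annotated
    UTR.  For each cluster the smaller of the upper tail P(X >= q) and
    lower tail P(X <= q) is reported with its direction; Bonferroni
    adjustment multiplies by the number of tested clusters.
    """
    population = [g for g, has in utr_availability.items()
                  if has and g in cluster_assignments]
    targeted = {i.mrna_id for i in interactions if i.passes_filters}
    m = sum(1 for g in population if g in targeted)
    n = len(population) - m
    clusters: Dict[str, List[str]] = {}
    for g in population:
        clusters.setdefault(cluster_assignments[g], []).append(g)
    tested = [c for c in sorted(clusters) if clusters[c]]
    results = []
    for cluster in tested:
        members = clusters[cluster]
        k = len(members)
        q = sum(1 for g in members if g in targeted)
        p_over = hypergeom_upper(q, m, n, k)
        p_under = hypergeom_lower(q, m, n, k)
        if p_over <= p_under:
            direction, p = "over", p_over
        else:
            direction, p = "under", p_under
        results.append(
            EnrichmentResult(cluster, q, m, n, k, direction, p,
                             min(1.0, p * len(tested)))
        )
    return results


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """U statistic of group x versus y with average-rank ties."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _exact_mw_pvalue(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p by rank-sum convolution (ties OK).

    p = min(1, 2 * min(P(U <= u), P(U >= u))) under the permutation null.
    Uses doubled average ranks so all sums are integers.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks2 = np.rint(2.0 * stats.rankdata(pooled)).astype(int)
    u_obs2 = int(round(2 * mann_whitney_u(x, y)))
    total = ranks2.sum()
    # dp[c] maps rank-sum2 -> number of subsets of size c with that sum
    dp: List[Dict[int, int]] = [dict() for _ in range(nx + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for c in range(min(nx, len(pooled)) - 1, -1, -1):
            if not dp[c]:
                continue
            nxt = dp[c + 1]
            for s, cnt in dp[c].items():
                nxt[s + r] = nxt.get(s + r, 0) + cnt
    dist = dp[nx]
    denom = comb(nx + ny, nx)
    offset = nx * (nx + 1)  # 2 * n(n+1)/2
    lower = sum(cnt for s, cnt in dist.items() if s - offset <= u_obs2)
    upper = sum(cnt for s, cnt in dist.items() if s - offset >= u_obs2)
    p = 2.0 * min(Fraction(lower, denom), Fraction(upper, denom))
    return float(min(1, p))


def mann_whitney_test(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 200_000
) -> Tuple[float, float]:
    """(U, two-sided p); exact when C(n+m, n) <= exact_limit, else the
    tie-corrected normal approximation."""
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    u = mann_whitney_u(x, y)
    if comb(len(x) + len(y), len(x)) <= exact_limit:
        return u, _exact_mw_pvalue(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def targeting_burden_tests(
    interactions: Sequence[Interaction],
    cluster_assignments: Mapping[str, str],
) -> pd.DataFrame:
    """Pairwise cluster comparisons of per-mRNA targeting burden.

    Metrics: (a) distinct targeting miRNAs per targeted mRNA, (b) total
    surviving sites per UTR.  Two-sided Mann-Whitney per cluster pair,
    Bonferroni over pairs within each metric; pairs where either cluster
    has fewer than two targeted mRNAs are skipped with a note.
    """
    per_mrna: Dict[str, Dict[str, float]] = {}
    for i in interactions:
        if not i.passes_filters:
            continue
        entry = per_mrna.setdefault(i.mrna_id, {"mirnas": 0, "sites": 0})
        entry["mirnas"] += 1
        entry["sites"] += i.n_sites
    values: Dict[str, Dict[str, List[float]]] = {}
    for mrna, metrics in per_mrna.items():
        cluster = cluster_assignments.get(mrna)
        if cluster is None:
            continue
        values.setdefault(cluster, {"mirnas": [], "sites": []})
        values[cluster]["mirnas"].append(metrics["mirnas"])
        values[cluster]["sites"].append(metrics["sites"])
    clusters = sorted(values)
    pairs = list(itertools.combinations(clusters, 2))
    rows = []
    for metric in ("mirnas", "sites"):
        n_pairs = len(pairs)
        for a, b in pairs:
            xa, xb = values[a][metric], values[b][metric]
            if len(xa) < 2 or len(xb) < 2:
                rows.append(dict(metric=metric, cluster_a=a, cluster_b=b,
                                 U=np.nan, pvalue=np.nan, padj=np.nan,
                                 note="skipped: fewer than two targeted mRNAs"))
                continue
            u, p = mann_whitney_test(xa, xb)
            rows.append(dict(metric=metric, cluster_a=a, cluster_b=b, U=u,
                             pvalue=p, padj=min(1.0, p * n_pairs), note=""))
    return pd.DataFrame(rows)


def sites_to_frame(
    sites: Sequence[SeedSite],
    energies: Optional[Mapping[Tuple[str, str, int], float]] = None,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "utr_id": [s.utr_id for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "mirna_id": [s.mirna_id for s in sites],
            "site_type": [s.site_type for s in sites],
        }
    )
    if energies is not None:
        df["delta_g"] = [energies[(s.utr_id, s.mirna_id, s.start)] for s in sites]
    return df
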
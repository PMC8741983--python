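"""MicroRNA family assignment, genome homology search and species profiling.

The homology search is a deterministic seed-and-extend local aligner:
exact ``word_size``-mer seeds on both strands are extended by affine-gap
Smith-Waterman on a window around the seeded region under BLASTN-style
scoring (+2 match, -3 mismatch, -5/-2 gaps).  Instead of E-values, hits
are accepted by three deterministic thresholds: alignment score,
identity over the aligned columns, and coverage of the query.  Accepted
hits per species are collapsed into a family x species copy-number
matrix, and species are clustered from (binarized) family profiles by
complete-linkage hierarchical clustering under Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .synthetic_data import reverse_complement


@dataclass
class HomologyHit:
    query_id: str
    species_id: str
    contig: str
    start: int            # 0-based half-open on the forward genome strand
    end: int
    strand: str           # '+' or '-'
    identity: float       # matches / aligned columns (gap columns included)
    coverage: float       # aligned query span / query length
    score: float


@dataclass
class MicroRNAFamily:
    family_id: str
    members: List[str] = field(default_factory=list)
    conserved: bool = False


# ---------------------------------------------------------------------------
# local alignment core (affine gaps, Smith-Waterman on a window)
# ---------------------------------------------------------------------------

def _sw_align(
    query: str,
    target: str,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> Optional[Tuple[float, int, int, int, int, int, int]]:
    """Best local alignment of query vs target.

    Returns (score, q_start, q_end, t_start, t_end, n_matches, n_columns)
    or None when no positive-scoring alignment exists.  A gap of length L
    costs gap_open + (L-1) * gap_extend.
    """
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return None
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)  # alignments ending in a match column
    X = np.full((n + 1, m + 1), NEG)  # ending in a gap in the query
    Y = np.full((n + 1, m + 1), NEG)  # ending in a gap in the target
    jj = np.arange(m, dtype=float)
    for i in range(1, n + 1):
        s = np.where(t == q[i - 1], match, mismatch)
        prev = np.maximum(0.0, np.maximum(M[i - 1, :-1],
                                          np.maximum(X[i - 1, :-1], Y[i - 1, :-1])))
        M[i, 1:] = prev + s
        Y[i, 1:] = np.maximum(M[i - 1, 1:] + gap_open, Y[i - 1, 1:] + gap_extend)
        # X[i, j] = max over j' <= j-1 of M[i, j'] + open + extend*(j-1-j'), as a scan
        base = M[i, :-1] + gap_open - gap_extend * jj
        X[i, 1:] = np.maximum.accumulate(base) + gap_extend * jj
    flat = int(np.argmax(M))
    bi, bj = divmod(flat, m + 1)
    best = float(M[bi, bj])
    if best <= 0:
        return None
    # traceback; optimal local alignments start and end on match columns
    i, j, state = bi, bj, "M"
    n_match = n_cols = 0
    qe, te = bi, bj
    eq = lambda a, b: abs(a - b) < 1e-9  # noqa: E731
    while i > 0 and j > 0:
        if state == "M":
            n_cols += 1
            hit = query[i - 1] == target[j - 1]
            if hit:
                n_match += 1
            rest = M[i, j] - (match if hit else mismatch)
            i, j = i - 1, j - 1
            if eq(rest, 0.0) and not (M[i, j] > 1e-9 and eq(rest, M[i, j])):
                break
            if eq(rest, M[i, j]):
                state = "M"
            elif eq(rest, X[i, j]):
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            n_cols += 1
            if eq(X[i, j], M[i, j - 1] + gap_open):
                state = "M"
            j -= 1
        else:
            n_cols += 1
            if eq(Y[i, j], M[i - 1, j] + gap_open):
                state = "M"
            i -= 1
    return best, i, qe, j, te, n_match, n_cols


# ---------------------------------------------------------------------------
# seed-and-extend search
# ---------------------------------------------------------------------------

def _seed_windows(query: str, genome: str, word_size: int, pad: int) -> List[Tuple[int, int]]:
    """Genome windows around diagonals that share an exact word with the query."""
    index: Dict[str, List[int]] = {}
    for q in range(len(query) - word_size + 1):
        index.setdefault(query[q:q + word_size], []).append(q)
    projections = []
    for g in range(len(genome) - word_size + 1):
        word = genome[g:g + word_size]
        for q in index.get(word, ()):
            projections.append(g - q)
    if not projections:
        return []
    projections.sort()
    qlen = len(query)
    windows: List[Tuple[int, int]] = []
    group_start = group_end = projections[0]
    for p in projections[1:]:
        if p - group_end <= qlen:
            group_end = p
        else:
            windows.append((group_start, group_end))
            group_start = group_end = p
    windows.append((group_start, group_end))
    spans = [(max(0, a - pad), min(len(genome), b + qlen + pad)) for a, b in windows]
    merged: List[Tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def search_genome(
    query: str,
    genome: Mapping[str, str] | str,
    word_size: int = 4,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    min_identity: float = 0.30,
    min_coverage: float = 0.25,
    min_score: float = 25.0,
    query_id: str = "query",
    species_id: str = "",
) -> List[HomologyHit]:
    """Seed-and-extend homolog search on both strands of a genome.

    Overlapping candidate alignments (same contig and strand) are
    resolved greedily by descending score; surviving alignments passing
    the identity and coverage thresholds are reported, coordinates always
    on the forward strand.
    """
    if len(query) < word_size:
        raise ValueError("query shorter than word_size")
    query = query.upper().replace("T", "U")
    contigs = {"chr1": genome} if isinstance(genome, str) else dict(genome)
    qlen = len(query)
    candidates: List[HomologyHit] = []
    for contig, seq in contigs.items():
        seq = seq.upper().replace("T", "U")
        for strand, q in (("+", query), ("-", reverse_complement(query))):
            for wstart, wend in _seed_windows(q, seq, word_size, pad=qlen):
                window = seq[wstart:wend]
                masked = list(window)
                while True:
                    aln = _sw_align(q, "".join(masked), match, mismatch,
                                    gap_open, gap_extend)
                    if aln is None or aln[0] < min_score:
                        break
                    score, qs, qe, ts, te, n_match, n_cols = aln
                    identity = n_match / n_cols if n_cols else 0.0
                    coverage = (qe - qs) / qlen
                    candidates.append(
                        HomologyHit(query_id, species_id, contig,
                                    wstart + ts, wstart + te, strand,
                                    identity, coverage, score)
                    )
                    for k in range(ts, te):
                        masked[k] = "N"
    # greedy overlap resolution by score (deterministic tie-break)
    candidates.sort(key=lambda h: (-h.score, h.contig, h.start, h.strand))
    kept: List[HomologyHit] = []
    for cand in candidates:
        clash = any(
            k.contig == cand.contig and k.strand == cand.strand
            and cand.start < k.end and k.start < cand.end
            for k in kept
        )
        if not clash:
            kept.append(cand)
    hits = [h for h in kept
            if h.identity >= min_identity and h.coverage >= min_coverage]
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def search_genomes(
    queries: Mapping[str, str],
    genomes_by_species: Mapping[str, Mapping[str, str] | str],
    **kwargs,
) -> List[HomologyHit]:
    hits = []
    for species_id in sorted(genomes_by_species):
        for query_id in sorted(queries):
            hits.extend(
                search_genome(queries[query_id], genomes_by_species[species_id],
                              query_id=query_id, species_id=species_id, **kwargs)
            )
    return hits


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

def _local_identity(a: str, b: str, match=2.0, mismatch=-3.0,
                    gap_open=-5.0, gap_extend=-2.0) -> int:
    """Matched columns of the best local alignment of a vs b."""
    aln = _sw_align(a, b, match, mismatch, gap_open, gap_extend)
    return aln[5] if aln else 0


def assign_families(
    matures: Mapping[str, str],
    catalog: Mapping[str, str],
    min_identity: float = 0.70,
) -> List[MicroRNAFamily]:
    """Group precursors into microRNA families.

    Stage 1: a precursor whose dominant mature sequence aligns to a
    catalog mature at >= ``min_identity`` identity (matched columns over
    the query mature length) joins that catalog family and is conserved.
    Stage 2: remaining precursors sharing an identical extended seed
    (mature nt 2-8) form novel families.
    """
    families: Dict[str, MicroRNAFamily] = {}
    novel_seeds: Dict[str, List[str]] = {}
    for pid in sorted(matures):
        mature = matures[pid].upper().replace("T", "U")
        if not mature:
            raise ValueError(f"precursor {pid!r} lacks a mature annotation")
        best_fam, best_idy = None, 0.0
        for fam in sorted(catalog):
            idy = _local_identity(mature, catalog[fam].upper().replace("T", "U")) / len(mature)
            if idy > best_idy:
                best_fam, best_idy = fam, idy
        if best_fam is not None and best_idy >= min_identity:
            entry = families.setdefault(best_fam, MicroRNAFamily(best_fam, [], True))
            entry.members.append(pid)
        else:
            novel_seeds.setdefault(mature[1:8], []).append(pid)
    for i, seed in enumerate(sorted(novel_seeds)):
        fam = MicroRNAFamily(f"novel-{i + 1:03d}", novel_seeds[seed], False)
        families[fam.family_id] = fam
    return [families[k] for k in sorted(families)]


# ---------------------------------------------------------------------------
# family matrix, species clustering, conservation summary
# ---------------------------------------------------------------------------

def build_family_matrix(
    hits: Sequence[HomologyHit],
    families: Sequence[MicroRNAFamily],
    species: Sequence[str],
) -> pd.DataFrame:
    """Family x species copy-number matrix from accepted hits.

    Copies are counted as non-overlapping genome loci: overlapping hits
    from different members of the same family collapse to one locus
    (best score wins, which the search already enforced per query; here
    cross-member overlaps are merged).
    """
    fam_of = {m: f.family_id for f in families for m in f.members}
    matrix = pd.DataFrame(
        0, index=[f.family_id for f in families], columns=list(species), dtype=int
    )
    grouped: Dict[Tuple[str, str, str, str], List[Tuple[int, int]]] = {}
    for h in hits:
        if h.species_id not in matrix.columns:
            raise ValueError(f"hit references unknown species {h.species_id!r}")
        if h.query_id not in fam_of:
            raise ValueError(f"hit query {h.query_id!r} belongs to no family")
        key = (fam_of[h.query_id], h.species_id, h.contig, h.strand)
        grouped.setdefault(key, []).append((h.start, h.end))
    for (fam, sp, _contig, _strand), intervals in grouped.items():
        intervals.sort()
        n_loci, cur_end = 0, -1
        for s, e in intervals:
            if s >= cur_end:
                n_loci += 1
                cur_end = e
            else:
                cur_end = max(cur_end, e)
        matrix.loc[fam, sp] += n_loci
    matrix.index.name = "family_id"
    return matrix


def cluster_species(
    matrix: pd.DataFrame, mode: str = "presence_absence"
) -> Tuple[str, np.ndarray]:
    """Complete-linkage Euclidean clustering of species profiles.

    Returns the Newick string (branch length = difference of merge
    heights along each edge) and the scipy linkage matrix.  Species are
    ordered lexicographically before clustering so ties resolve
    deterministically.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two species to cluster")
    if mode not in ("presence_absence", "copy_number"):
        raise ValueError(f"unknown mode {mode!r}")
    cols = sorted(matrix.columns)
    data = matrix[cols].to_numpy(dtype=float).T
    if mode == "presence_absence":
        data = (data > 0).astype(float)
    Z = hierarchy.linkage(data, method="complete", metric="euclidean")
    tree = hierarchy.to_tree(Z)

    def newick(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{cols[node.id]}:{length:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    nwk = f"({newick(tree.left, tree.dist)},{newick(tree.right, tree.dist)});"
    return nwk, Z


def summarize_conservation(
    matrix: pd.DataFrame,
    self_species: str,
    clade_map: Mapping[str, str],
) -> Dict[str, object]:
    """Conservation breadth of each family relative to the focal species.

    Reports families present in at least one other species, families
    restricted to each clade, the core set (shared families not
    restricted to the focal species' clade) and focal-species-unique
    families.
    """
    if self_species not in matrix.columns:
        raise ValueError(f"{self_species!r} not in matrix columns")
    missing = set(matrix.columns) - set(clade_map)
    if missing:
        raise ValueError(f"clade_map missing species: {sorted(missing)}")
    others = [c for c in matrix.columns if c != self_species]
    present = matrix > 0
    shared = sorted(matrix.index[present[others].any(axis=1)])
    unique = sorted(matrix.index[~present[others].any(axis=1)])

    clade_restricted: Dict[str, List[str]] = {}
    for clade in sorted(set(clade_map.values())):
        inside = [c for c in matrix.columns if clade_map[c] == clade]
        outside = [c for c in matrix.columns if clade_map[c] != clade]
        rows = present[inside].any(axis=1) & ~present[outside].any(axis=1)
        clade_restricted[clade] = sorted(matrix.index[rows])

    self_clade = clade_map[self_species]
    core = sorted(set(shared) - set(clade_restricted.get(self_clade, [])))
    return {
        "shared_with_other_species": shared,
        "clade_restricted": clade_restricted,
        "core_set": core,
        "unique_to_self": unique,
        "n_shared": len(shared),
        "n_core": len(core),
        "n_unique": len(unique),
    }


def hits_to_frame(hits: Sequence[HomologyHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query_id": [h.query_id for h in hits],
            "species_id": [h.species_id for h in hits],
            "contig": [h.contig for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "strand": [h.strand for h in hits],
            "identity": [h.identity for h in hits],
            "coverage": [h.coverage for h in hits],
            "score": [h.score for h in hits],
        }
    )
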
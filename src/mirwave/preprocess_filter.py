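"""Small-read preprocessing and microRNA candidate filtering.

Reads are size-selected (18-26 nt by default), de-contaminated against a
tRNA/rRNA blacklist by mismatch-tolerant substring matching, assigned to
precursor arms by majority overlap, and each precursor candidate is then
accepted or rejected by three rules:

* arm support - at least ``min_reads`` reads on *both* mature arms,
* loop length - at least ``min_loop`` nt between the mature arms,
* 5' homogeneity - at least ``min_homogeneity`` of each arm's reads
  sharing the modal 5' end.

Highly conserved candidates (known homologs in a reference catalog) are
rescued even when a rule fails.  All thresholds are inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

READ_COLUMNS = ["read_id", "precursor_id", "start", "end", "sequence"]


@dataclass(frozen=True)
class PrecursorCandidate:
    """Hairpin with annotated 5p/3p mature intervals (0-based half-open)."""

    precursor_id: str
    sequence: str
    mature5p: Tuple[int, int]
    mature3p: Tuple[int, int]
    conserved_flag: bool = False

    def __post_init__(self) -> None:
        s5, e5 = self.mature5p
        s3, e3 = self.mature3p
        if not (0 <= s5 < e5 <= s3 < e3 <= len(self.sequence)):
            raise ValueError(
                f"{self.precursor_id}: mature intervals must be ordered, "
                "non-overlapping and within the precursor"
            )

    @property
    def loop_length(self) -> int:
        return self.mature3p[0] - self.mature5p[1]


@dataclass
class ArmReadStats:
    arm: str                      # '5p' or '3p'
    read_count: int
    modal_5prime_fraction: float  # 0.0 when read_count == 0
    length_histogram: Dict[int, int] = field(default_factory=dict)


@dataclass
class FilterVerdict:
    precursor_id: str
    accepted: bool
    reasons: List[str] = field(default_factory=list)
    rescued_by_conservation: bool = False


def size_select(reads: pd.DataFrame, min_len: int = 18, max_len: int = 26) -> pd.DataFrame:
    """Keep reads with min_len <= length <= max_len (inclusive), order-stable."""
    if min_len < 0 or max_len < 0:
        raise ValueError("lengths must be non-negative")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if reads.empty:
        return reads.copy()
    lengths = reads["sequence"].str.len()
    return reads.loc[(lengths >= min_len) & (lengths <= max_len)].copy()


def _matches_with_mismatches(read: str, reference: str, max_mismatches: int) -> bool:
    n, m = len(read), len(reference)
    if n > m:
        return False
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(ref, n)
    return bool((np.sum(windows != r, axis=1) <= max_mismatches).any())


def exclude_contaminants(
    reads: pd.DataFrame, blacklist: Sequence[str], max_mismatches: int = 3
) -> pd.DataFrame:
    """Drop reads matching any blacklist sequence as a substring with
    at most ``max_mismatches`` mismatches (Hamming, no indels)."""
    blacklist = [b.upper().replace("T", "U") for b in blacklist]
    cache: Dict[str, bool] = {}

    def contaminated(seq: str) -> bool:
        seq = seq.upper().replace("T", "U")
        if seq not in cache:
            cache[seq] = any(
                _matches_with_mismatches(seq, b, max_mismatches) for b in blacklist
            )
        return cache[seq]

    keep = ~reads["sequence"].map(contaminated)
    return reads.loc[keep].copy()


def arm_stats(
    reads: pd.DataFrame,
    precursor: PrecursorCandidate,
    assignment_overlap: float = 0.5,
) -> Tuple[ArmReadStats, ArmReadStats]:
    """Assign reads to arms by fractional overlap and summarize each arm.

    A read is assigned to the arm whose mature interval covers at least
    ``assignment_overlap`` of the read's length; reads qualifying for
    neither arm are ignored.  The modal 5' fraction is the share of
    assigned reads starting at the arm's most frequent position (0 when
    the arm has no reads, so missing arms fail the support rule first).
    """
    sub = reads[reads["precursor_id"] == precursor.precursor_id]
    per_arm: Dict[str, List[Tuple[int, int]]] = {"5p": [], "3p": []}
    intervals = {"5p": precursor.mature5p, "3p": precursor.mature3p}
    for start, end in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
        length = end - start
        if length <= 0:
            continue
        best_arm, best_ov = None, 0
        for arm, (s, e) in intervals.items():
            ov = max(0, min(end, e) - max(start, s))
            if ov > best_ov:
                best_arm, best_ov = arm, ov
        if best_arm is not None and best_ov >= assignment_overlap * length:
            per_arm[best_arm].append((start, end))

    out = []
    for arm in ("5p", "3p"):
        assigned = per_arm[arm]
        n = len(assigned)
        if n:
            starts = Counter(s for s, _ in assigned)
            modal = max(starts.values()) / n
        else:
            modal = 0.0
        hist = Counter(e - s for s, e in assigned)
        out.append(ArmReadStats(arm, n, modal, dict(hist)))
    return out[0], out[1]


def filter_candidates(
    candidates: Sequence[PrecursorCandidate],
    stats: Mapping[str, Tuple[ArmReadStats, ArmReadStats]],
    min_reads: int = 10,
    min_loop: int = 8,
    min_homogeneity: float = 0.5,
) -> List[FilterVerdict]:
    """Apply the three annotation rules, with conservation rescue."""
    verdicts = []
    for cand in candidates:
        if cand.precursor_id not in stats:
            raise ValueError(f"no arm statistics for candidate {cand.precursor_id!r}")
        s5, s3 = stats[cand.precursor_id]
        reasons = []
        if s5.read_count < min_reads or s3.read_count < min_reads:
            reasons.append("arm_support")
        if cand.loop_length < min_loop:
            reasons.append("loop_length")
        if min(s5.modal_5prime_fraction, s3.modal_5prime_fraction) < min_homogeneity:
            reasons.append("five_prime_heterogeneity")
        rescued = bool(reasons) and cand.conserved_flag
        verdicts.append(
            FilterVerdict(
                precursor_id=cand.precursor_id,
                accepted=not reasons or cand.conserved_flag,
                reasons=reasons,
                rescued_by_conservation=rescued,
            )
        )
    return verdicts


def read_profile_summary(
    reads: pd.DataFrame, logo_length: int = 22
) -> Tuple[Dict[int, int], pd.DataFrame]:
    """Length distribution plus positional base frequencies.

    The length histogram counts every read; the 4 x ``logo_length``
    frequency matrix is computed over *distinct* read sequences (the
    non-redundant set), with reads shorter than ``logo_length``
    contributing only to the positions they cover and each column
    renormalized to sum to 1.
    """
    lengths = Counter(reads["sequence"].str.len().tolist())
    distinct = sorted(set(reads["sequence"].str.upper().str.replace("T", "U")))
    counts = np.zeros((4, logo_length))
    index = {"A": 0, "C": 1, "G": 2, "U": 3}
    for seq in distinct:
        for pos, base in enumerate(seq[:logo_length]):
            if base in index:
                counts[index[base], pos] += 1
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    matrix = pd.DataFrame(freqs, index=["A", "C", "G", "U"],
                          columns=[f"pos{p + 1}" for p in range(logo_length)])
    return dict(lengths), matrix


def load_precursors_gff3(
    gff: pd.DataFrame, sequences: Mapping[str, str]
) -> List[PrecursorCandidate]:
    """Build candidates from a GFF3 table (1-based inclusive) plus FASTA.

    Expects ``miRNA_primary_transcript`` features whose two ``miRNA``
    children (IDs ending in -5p/-3p) give the mature intervals on the
    precursor sequence; a ``conserved=1`` attribute on the hairpin marks
    a known homolog eligible for conservation rescue.
    """
    from .io_utils import gff3_attributes

    candidates = []
    hairpins = gff[gff["type"] == "miRNA_primary_transcript"]
    matures = gff[gff["type"] == "miRNA"]
    for _, row in hairpins.iterrows():
        attrs = gff3_attributes(row["attributes"])
        pid = attrs.get("ID", row["seqid"])
        children = matures[matures["attributes"].str.contains(f"Parent={pid}")]
        arm_iv: Dict[str, Tuple[int, int]] = {}
        for _, child in children.iterrows():
            cid = gff3_attributes(child["attributes"]).get("ID", "")
            arm = "5p" if cid.endswith("5p") else "3p"
            arm_iv[arm] = (int(child["start"]) - 1, int(child["end"]))
        if {"5p", "3p"} - set(arm_iv):
            raise ValueError(f"precursor {pid!r} lacks 5p/3p mature annotations")
        candidates.append(
            PrecursorCandidate(pid, sequences[pid], arm_iv["5p"], arm_iv["3p"],
                               conserved_flag=attrs.get("conserved") == "1")
        )
    return candidates


def verdicts_to_frame(verdicts: Sequence[FilterVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "precursor_id": [v.precursor_id for v in verdicts],
            "accepted": [v.accepted for v in verdicts],
            "reasons": [",".join(v.reasons) for v in verdicts],
            "rescued_by_conservation": [v.rescued_by_conservation for v in verdicts],
        }
    )
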
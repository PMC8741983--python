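"""Relative arm usage (5p vs 3p) and arm-switching classification.

For each precursor the relative arm usage is

    rau = log2((N5' + c) / (N3' + c))

with a pseudocount ``c = 1`` on both arms so that the ratio is finite and
antisymmetric for zero counts.  Positive values mean 5p dominance.  A
developmental switch is called when the dominant arm (|rau| above a
twofold band) flips sign across the time course; between species, a pair
is "switched" when the signs differ and flagged when the difference
exceeds the tenfold boundary (|rau_a - rau_b| >= log2(10)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


def compute_rau(n5, n3, pseudocount: float = 1.0):
    """log2((N5 + pseudocount) / (N3 + pseudocount)); vectorized."""
    n5 = np.asarray(n5, dtype=float)
    n3 = np.asarray(n3, dtype=float)
    if np.any(n5 < 0) or np.any(n3 < 0):
        raise ValueError("arm counts must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    # difference of logs rather than log of the ratio: antisymmetry
    # rau(a, b) == -rau(b, a) then holds bit-exactly
    out = np.log2(n5 + pseudocount) - np.log2(n3 + pseudocount)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class SwitchClassification:
    precursor_id: str
    category: str  # stable_5p | stable_3p | codominant | developmental_switch
    switch_timepoints: List[Tuple[int, int]] = field(default_factory=list)
    cross_species_tenfold: bool = False


def rau_profile(
    records: pd.DataFrame,
    pseudocount: float = 1.0,
    timepoints: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Precursor x time-point rau matrix; replicates summed before the ratio.

    ``records`` needs columns precursor_id, time_point, N5, N3 (one row
    per replicate).  (precursor, time-point) combinations absent from the
    input are reported as missing (NaN), not zero; pass ``timepoints`` to
    force the full set of expected columns.
    """
    summed = records.groupby(["precursor_id", "time_point"])[["N5", "N3"]].sum()
    rau = compute_rau(summed["N5"], summed["N3"], pseudocount)
    summed = summed.assign(rau=rau)
    wide = summed["rau"].unstack("time_point")
    if timepoints is not None:
        wide = wide.reindex(columns=list(timepoints))
    return wide


def classify_development(
    profile: pd.Series | np.ndarray,
    dominance_threshold: float = 1.0,
    precursor_id: str = "",
) -> SwitchClassification:
    """Classify one precursor's rau time course.

    Time-points inside the +/-threshold band are codominant.  A
    developmental switch requires a 5p-dominant and a 3p-dominant
    time-point in the same profile; the reported switch pairs are the
    consecutive dominant time-points between which the sign flips.
    """
    if isinstance(profile, pd.Series):
        timepoints = list(profile.index)
        values = profile.to_numpy(dtype=float)
    else:
        values = np.asarray(profile, dtype=float)
        timepoints = list(range(1, len(values) + 1))
    present = ~np.isnan(values)
    if present.sum() < 1:
        raise ValueError(f"profile for {precursor_id!r} has no observed time-points")

    dominant = [(tp, v) for tp, v, ok in zip(timepoints, values, present)
                if ok and abs(v) >= dominance_threshold]
    switches = [
        (a_tp, b_tp)
        for (a_tp, a_v), (b_tp, b_v) in zip(dominant, dominant[1:])
        if np.sign(a_v) != np.sign(b_v)
    ]
    if switches:
        category = "developmental_switch"
    elif not dominant:
        category = "codominant"
    else:
        mean_dom = float(np.mean([v for _, v in dominant]))
        category = "stable_5p" if mean_dom > 0 else "stable_3p"
    return SwitchClassification(precursor_id, category, switches)


def cross_species_switch(
    rau_a: float, rau_b: float, fold_boundary: float = 10.0
) -> Tuple[bool, bool]:
    """(switched, exceeds_tenfold) for one microRNA in two species."""
    if not (np.isfinite(rau_a) and np.isfinite(rau_b)):
        raise ValueError("rau values must be finite")
    switched = rau_a * rau_b < 0
    exceeds = abs(rau_a - rau_b) >= np.log2(fold_boundary)
    return bool(switched), bool(exceeds)


def pairwise_species_comparison(
    pooled: pd.DataFrame, fold_boundary: float = 10.0, pseudocount: float = 1.0
) -> pd.DataFrame:
    """All pairwise species comparisons from whole-dataset pooled counts.

    ``pooled`` needs columns precursor_id, species_id, N5, N3 (already
    pooled over samples within each species).
    """
    rau = pooled.assign(rau=compute_rau(pooled["N5"], pooled["N3"], pseudocount))
    wide = rau.pivot(index="precursor_id", columns="species_id", values="rau")
    rows = []
    species = list(wide.columns)
    for i, sp_a in enumerate(species):
        for sp_b in species[i + 1:]:
            for pid, row in wide.iterrows():
                a, b = row[sp_a], row[sp_b]
                if np.isnan(a) or np.isnan(b):
                    continue
                switched, tenfold = cross_species_switch(a, b, fold_boundary)
                rows.append(dict(precursor_id=pid, species_a=sp_a, species_b=sp_b,
                                 rau_a=a, rau_b=b, switched=switched,
                                 exceeds_tenfold=tenfold))
    return pd.DataFrame(rows)
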
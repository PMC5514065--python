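"""ER/HER2 subtype stratification from bimodal marker distributions.

Breast tumors are split into three clinical classes using two markers:
ERBB2 focal copy number (amplified vs not, i.e. HER2+ vs HER2-) and ESR1
expression (ER+ vs ER-).  Both markers are bimodal across primary tumors;
each split places the threshold at the density minimum (antimode) between
the two dominant modes of a kernel density estimate.  Samples missing
either marker are excluded.  Classes:

    HER2 high                 -> "HER2+"     (regardless of ER)
    HER2 low and ESR1 high    -> "ER+HER2-"
    HER2 low and ESR1 low     -> "ER-HER2-"
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import KDEConfig, estimate_density, find_peaks

__all__ = [
    "BimodalSplit",
    "NotBimodalError",
    "split_bimodal",
    "classify_samples",
    "CLASS_HER2",
    "CLASS_ER_POS",
    "CLASS_ER_NEG",
    "CLASS_NBS",
    "CLASS_EXCLUDED",
]

CLASS_HER2 = "HER2+"
CLASS_ER_POS = "ER+HER2-"
CLASS_ER_NEG = "ER-HER2-"
CLASS_NBS = "NBS"
CLASS_EXCLUDED = "excluded"


class NotBimodalError(ValueError):
    """Raised when a marker distribution has no two usable modes."""


@dataclass(frozen=True)
class BimodalSplit:
    """Two dominant modes of a marker distribution and the cut between them."""

    low_mode: float
    high_mode: float
    threshold: float
    assignment: pd.Series  # sample -> "low" | "high"

    def __post_init__(self) -> None:
        if not (self.low_mode < self.threshold < self.high_mode):
            raise ValueError("threshold must lie strictly between the modes")


def split_bimodal(values: pd.Series, config: KDEConfig | None = None) -> BimodalSplit:
    """Split values at the density minimum between the two tallest KDE peaks.

    Requires >= 10 finite values with nonzero spread.  If the density has
    more than two peaks, the two tallest define the modes and the threshold
    is the lowest density point between them.  A unimodal density raises
    :class:`NotBimodalError` (supply labels manually in that case).
    """
    config = config or KDEConfig()
    x = pd.Series(values).astype(float)
    finite = x[np.isfinite(x)]
    if len(finite) < 10:
        raise ValueError("need at least 10 finite marker values")
    if float(finite.max() - finite.min()) == 0.0:
        raise NotBimodalError("marker values have zero spread")
    curve = estimate_density(finite.to_numpy(), config)
    maxima, _ = find_peaks(curve, config.prominence_floor)
    if len(maxima) < 2:
        raise NotBimodalError("marker density has a single peak")
    top2 = sorted(sorted(maxima, key=lambda mh: mh[1], reverse=True)[:2])
    (low_x, _), (high_x, _) = top2
    between = (curve.grid > low_x) & (curve.grid < high_x)
    idx = np.nonzero(between)[0]
    threshold = float(curve.grid[idx[np.argmin(curve.density[idx])]])
    assignment = pd.Series(
        np.where(finite >= threshold, "high", "low"), index=finite.index, name="side"
    )
    return BimodalSplit(
        low_mode=float(low_x), high_mode=float(high_x), threshold=threshold,
        assignment=assignment,
    )


def classify_samples(
    markers: pd.DataFrame, config: KDEConfig | None = None
) -> tuple[pd.DataFrame, dict[str, BimodalSplit]]:
    """Assign ER/HER2 classes from a marker table.

    ``markers`` is indexed by sample_id with columns ``esr1_expr`` (log
    expression, median-adjusted upstream) and ``erbb2_focal_cn``.  Samples
    with either marker missing are excluded.  Returns the class table
    (columns: class) and the two fitted splits for reporting.
    """
    for col in ("esr1_expr", "erbb2_focal_cn"):
        if col not in markers.columns:
            raise ValueError(f"marker table lacks column {col!r}")
    usable = markers[["esr1_expr", "erbb2_focal_cn"]].astype(float)
    complete = usable.dropna()
    her2_split = split_bimodal(complete["erbb2_focal_cn"], config)
    er_split = split_bimodal(complete["esr1_expr"], config)
    classes = pd.Series(CLASS_EXCLUDED, index=markers.index, name="class")
    her2_high = her2_split.assignment == "high"
    er_high = er_split.assignment == "high"
    classes.loc[complete.index[her2_high]] = CLASS_HER2
    classes.loc[complete.index[~her2_high & er_high]] = CLASS_ER_POS
    classes.loc[complete.index[~her2_high & ~er_high]] = CLASS_ER_NEG
    table = classes.to_frame()
    return table, {"erbb2_focal_cn": her2_split, "esr1_expr": er_split}
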
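"""Dosage-compensation classes for monosomic-chromosome genes.

Each above-noise gene's mean mutant/parent expression ratio is rounded
half-away-from-zero to one decimal and banded:

    BELOW_RANGE  < 0.2      (lost loci; below the published bands)
    DOWN_2X      0.2 - 0.6  (down-regulated roughly twofold, as monosomy
                             alone would predict)
    PARTIAL      0.7 - 0.8  (between a twofold decrease and no change)
    DISOMIC      0.9 - 1.1  (fully compensated to the two-copy level)
    UP           1.2 - 2.1  (up-regulated above the disomic level)
    EXCESS       > 2.1      (extreme up-regulation, CAG1-like)

The bands live on a 0.1 grid with gaps (0.6->0.7, 0.8->0.9, 1.1->1.2),
which only partitions the positive reals after rounding; banding is
therefore applied to the rounded ratio.  Also provided: the 0.1-wide ratio
histogram, the positional scatter track with its three-way color rule, and
a permutation test for positional clustering of extreme genes.
"""

from __future__ import annotations

import warnings
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompensationClass",
    "classify_gene",
    "classify_ratios",
    "classify_table",
    "class_proportions",
    "ratio_histogram",
    "positional_track",
    "clustering_test",
]


class CompensationClass(str, Enum):
    BELOW_RANGE = "BELOW_RANGE"
    DOWN_2X = "DOWN_2X"
    PARTIAL = "PARTIAL"
    DISOMIC = "DISOMIC"
    UP = "UP"
    EXCESS = "EXCESS"


#: class by rounded-ratio decile index (ratio * 10, half away from zero)
_DECI_BANDS = (
    (2, CompensationClass.BELOW_RANGE),   # deci < 2
    (7, CompensationClass.DOWN_2X),       # 2..6
    (9, CompensationClass.PARTIAL),       # 7..8
    (12, CompensationClass.DISOMIC),      # 9..11
    (22, CompensationClass.UP),           # 12..21
)


def _round_deci(ratios: np.ndarray) -> np.ndarray:
    """Ratio * 10 rounded half away from zero (ratios are positive)."""
    return np.floor(ratios * 10.0 + 0.5).astype(int)


def classify_ratios(ratios: np.ndarray) -> np.ndarray:
    """Vectorized class labels for an array of positive mean ratios."""
    ratios = np.asarray(ratios, dtype=float)
    if np.any(~(ratios > 0)):
        raise ValueError("mean ratios must be positive")
    deci = _round_deci(ratios)
    labels = np.full(ratios.shape, CompensationClass.EXCESS.value, dtype=object)
    for upper, label in reversed(_DECI_BANDS):
        labels[deci < upper] = label.value
    out = np.empty(ratios.shape, dtype=object)
    out[...] = [CompensationClass(v) for v in labels.ravel()]
    return out


def classify_gene(mean_ratio: float) -> CompensationClass:
    """Class of a single gene from its mean mutant/parent ratio."""
    return classify_ratios(np.array([mean_ratio]))[0]


def rounded_ratio(mean_ratio: np.ndarray | float) -> np.ndarray | float:
    """Mean ratio rounded half away from zero to one decimal."""
    arr = np.asarray(mean_ratio, dtype=float)
    out = _round_deci(arr) / 10.0
    return float(out) if np.isscalar(mean_ratio) else out


def classify_table(
    gene_table: pd.DataFrame,
    annotation: pd.DataFrame,
    chromosome: str,
) -> pd.DataFrame:
    """Classification of every above-noise gene on one chromosome.

    ``gene_table`` is the per-gene expression table (mean_ratio, p_value,
    above_noise); ``annotation`` supplies coordinates (0-based half-open).
    Positions are gene midpoints in bp.
    """
    coords = annotation.set_index("gene_id")
    sub = gene_table[
        (gene_table["chromosome"] == chromosome) & gene_table["above_noise"]
    ]
    ratios = sub["mean_ratio"].to_numpy()
    out = pd.DataFrame({
        "gene_id": sub.index,
        "mean_ratio": ratios,
        "rounded_ratio": rounded_ratio(ratios),
        "comp_class": [c.value for c in classify_ratios(ratios)],
        "p_value": sub["p_value"].to_numpy(),
    })
    pos = (coords["start"] + coords["end"]) // 2
    out["position"] = out["gene_id"].map(pos)
    return out


def class_proportions(results: pd.DataFrame) -> pd.DataFrame:
    """Count and fraction per class over the classified genes."""
    if results.empty:
        raise ValueError("no classified genes")
    counts = results["comp_class"].value_counts()
    rows = []
    for cls in CompensationClass:
        n = int(counts.get(cls.value, 0))
        rows.append((cls.value, n, n / len(results)))
    return pd.DataFrame(rows, columns=["comp_class", "count", "fraction"])


def ratio_histogram(
    ratios: Sequence[float] | np.ndarray, bin_width: float = 0.1
) -> pd.DataFrame:
    """Histogram of ratios in left-closed right-open bins anchored at 0."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ratios = np.asarray(ratios, dtype=float)
    idx = np.floor(ratios / bin_width).astype(int)
    counts = np.bincount(idx, minlength=idx.max() + 1 if len(idx) else 0)
    return pd.DataFrame({
        "bin_left": np.arange(len(counts)) * bin_width,
        "bin_right": (np.arange(len(counts)) + 1) * bin_width,
        "count": counts,
    })


_RED = {CompensationClass.DOWN_2X.value, CompensationClass.BELOW_RANGE.value}


def positional_track(results: pd.DataFrame) -> pd.DataFrame:
    """(position, ratio, color) per gene for the positional scatter.

    Twofold-or-more diminished genes are red, twofold-or-more increased
    genes blue, everything in between green.  Genes lacking coordinates are
    dropped with a warning.
    """
    keep = results["position"].notna()
    if not keep.all():
        missing = results.loc[~keep, "gene_id"].tolist()
        warnings.warn(
            f"omitting {len(missing)} gene(s) with no coordinates: "
            f"{missing[:5]}"
        )
    sub = results[keep]
    color = np.where(
        sub["comp_class"].isin(_RED),
        "red",
        np.where(
            (sub["comp_class"] == CompensationClass.EXCESS.value)
            | (sub["rounded_ratio"] >= 2.0),
            "blue",
            "green",
        ),
    )
    return pd.DataFrame({
        "gene_id": sub["gene_id"].to_numpy(),
        "position": sub["position"].to_numpy(),
        "mean_ratio": sub["mean_ratio"].to_numpy(),
        "color": color,
    })


def _mean_nn_distance(positions: np.ndarray) -> float:
    pos = np.sort(positions.astype(float))
    gaps = np.diff(pos)
    left = np.concatenate(([np.inf], gaps))
    right = np.concatenate((gaps, [np.inf]))
    return float(np.minimum(left, right).mean())


def clustering_test(
    positions: np.ndarray,
    is_extreme: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for clustering of extreme (red/blue) genes.

    Statistic: mean nearest-neighbor distance (bp) among extreme genes.
    Null: the extreme labels are shuffled over the observed gene positions.
    Returns (p_value, observed_statistic); p uses the add-one estimator
    (number of permutations with a statistic <= observed, plus one, over
    n_permutations + 1) so it is never exactly zero.
    """
    positions = np.asarray(positions, dtype=float)
    is_extreme = np.asarray(is_extreme, dtype=bool)
    if positions.shape != is_extreme.shape:
        raise ValueError("positions and is_extreme must match")
    k = int(is_extreme.sum())
    if k < 2:
        raise ValueError("need >= 2 extreme genes for the clustering test")
    observed = _mean_nn_distance(positions[is_extreme])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.choice(positions.size, size=k, replace=False)
        if _mean_nn_distance(positions[perm]) <= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1), observed
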
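"""Expression-chip normalization and per-gene ratio statistics.

Turns raw probe-level signals from two strains (a disomic parent and a
monosomic mutant, hybridized to replicate single-dye chips) into
background-corrected, constant-total-scaled per-gene mutant/parent ratios
with paired t-tests and chromosome-level summaries.

Pipeline order: estimate the chip background as the median of exogenous
control probes; subtract it; flag genes whose mean corrected signal falls
below the noise threshold in either strain; rescale every chip so that the
total corrected signal of genes *off* the monosomic chromosome is constant
across chips; form per-gene ratios (non-positive signals replaced by 1)
averaged over paired hybridizations; test each gene with a paired t-test on
base-2 logs of the scaled signals, spots averaged within a chip first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ChipSignalMatrix, MUTANT, PARENT

__all__ = [
    "estimate_background",
    "correct_and_filter",
    "scale_chips",
    "gene_ratio",
    "gene_ratio_table",
    "per_gene_test",
    "per_gene_test_table",
    "build_gene_table",
    "chromosome_summary",
    "gc_anova",
]

NOISE_THRESHOLD = 200.0  # fluorescence units; matches the control-probe SD


def estimate_background(matrix: ChipSignalMatrix, chip_id: str) -> float:
    """Background of one chip: median raw signal of exogenous controls."""
    exo = matrix.probes.loc[
        matrix.probes["is_exogenous"].fillna(False).astype(bool), "probe_id"
    ]
    if exo.empty:
        raise ValueError(
            "no exogenous control probes: background is undefined"
        )
    return float(matrix.signals.loc[exo, chip_id].median())


def correct_and_filter(
    matrix: ChipSignalMatrix, noise_threshold: float = NOISE_THRESHOLD
) -> tuple[ChipSignalMatrix, pd.Series]:
    """Subtract per-chip background and flag above-noise genes.

    A gene is above noise only when its mean corrected signal (over chips
    and spots) reaches ``noise_threshold`` in *both* strains.  Corrected
    signals may be negative; the negative->1 rule is applied downstream
    when ratios are formed.
    """
    backgrounds = {c: estimate_background(matrix, c) for c in matrix.signals}
    corrected = matrix.signals.sub(pd.Series(backgrounds), axis=1)
    out = matrix.with_signals(corrected)

    gene_probes = matrix.probes[~matrix.probes["is_control"]]
    flags = {}
    for strain in (PARENT, MUTANT):
        cols = out.chip_ids(strain)
        per_gene = (
            corrected.loc[gene_probes["probe_id"], cols]
            .mean(axis=1)
            .groupby(gene_probes.set_index("probe_id")["gene_id"], sort=False)
            .mean()
        )
        flags[strain] = per_gene >= noise_threshold
    above_noise = flags[PARENT] & flags[MUTANT]
    above_noise.name = "above_noise"
    return out, above_noise


def scale_chips(
    matrix: ChipSignalMatrix, exclude_chromosome: str | None
) -> tuple[ChipSignalMatrix, pd.Series]:
    """Constant-total scaling on genes off the excluded chromosome.

    Each chip k is multiplied by C / T_k, where T_k is the summed corrected
    signal of all gene spots not on ``exclude_chromosome`` and C is the
    mean of the T_k.  After scaling every chip's non-excluded total equals
    C.  Monosomic-chromosome genes are excluded from the reference total
    because they are the ones expected to change; ``None`` normalizes by
    every gene instead (the variant reported to give very similar results).
    """
    mask = ~matrix.probes["is_control"]
    if exclude_chromosome is not None:
        chroms = matrix.probes["chromosome"].dropna().unique()
        if exclude_chromosome not in set(chroms):
            raise ValueError(
                f"chromosome {exclude_chromosome!r} not present in the "
                "probe table"
            )
        mask &= matrix.probes["chromosome"] != exclude_chromosome
    ref = matrix.probes[mask]["probe_id"]
    totals = matrix.signals.loc[ref].sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"non-positive reference total on chips {bad}")
    factors = totals.mean() / totals
    factors.name = "scale_factor"
    return matrix.with_signals(matrix.signals.mul(factors, axis=1)), factors


def _substitute_nonpositive(values: np.ndarray) -> np.ndarray:
    """The negative->1 rule: non-positive scaled signals are taken as 1."""
    return np.where(values > 0, values, 1.0)


def _paired_spot_ratios(matrix: ChipSignalMatrix) -> tuple[pd.Series, np.ndarray]:
    """Per-spot mutant/parent ratios paired by replicate index.

    Returns the gene id of each spot row and an array of shape
    (n_spots, n_pairs) of ratios after the negative->1 substitution.
    """
    gene_probes = matrix.probes[~matrix.probes["is_control"]]
    mut = matrix.signals.loc[
        gene_probes["probe_id"], matrix.chip_ids(MUTANT)
    ].to_numpy()
    par = matrix.signals.loc[
        gene_probes["probe_id"], matrix.chip_ids(PARENT)
    ].to_numpy()
    ratios = _substitute_nonpositive(mut) / _substitute_nonpositive(par)
    return gene_probes["gene_id"].reset_index(drop=True), ratios


def gene_ratio_table(matrix: ChipSignalMatrix) -> pd.DataFrame:
    """mean_ratio/median_ratio per gene over the J x pairs spot ratios."""
    gene_ids, ratios = _paired_spot_ratios(matrix)
    frame = pd.DataFrame(ratios)
    frame.insert(0, "gene_id", gene_ids)
    long = frame.melt(id_vars="gene_id", value_name="ratio")
    grouped = long.groupby("gene_id", sort=False)["ratio"]
    out = pd.DataFrame({
        "mean_ratio": grouped.mean(),
        "median_ratio": grouped.median(),
        "n_ratio_pairs": grouped.size(),
    })
    return out


def gene_ratio(matrix: ChipSignalMatrix, gene_id: str) -> tuple[float, float]:
    """(mean_ratio, median_ratio) for one gene; KeyError if absent."""
    table = gene_ratio_table(matrix)
    if gene_id not in table.index:
        raise KeyError(f"gene {gene_id!r} not in the signal matrix")
    row = table.loc[gene_id]
    return float(row["mean_ratio"]), float(row["median_ratio"])


def _per_chip_gene_log2(matrix: ChipSignalMatrix) -> pd.DataFrame:
    """log2 of per-(gene, chip) mean scaled signal, negatives -> 1 first.

    Spots within a chip are averaged before the log so that the paired
    t-test's replication unit is the chip pair: duplicate spotting raises
    ratio precision but not test degrees of freedom.
    """
    gene_probes = matrix.probes[~matrix.probes["is_control"]]
    sig = matrix.signals.loc[gene_probes["probe_id"]]
    per_gene = sig.groupby(
        gene_probes.set_index("probe_id")["gene_id"], sort=False
    ).mean()
    return np.log2(_substitute_nonpositive(per_gene.to_numpy())), per_gene.index


def per_gene_test_table(matrix: ChipSignalMatrix) -> pd.Series:
    """Two-sided paired t-test per gene on log2 scaled signals.

    Degenerate cases: all paired differences zero -> p = 1; zero variance
    with a nonzero mean difference -> p floored at machine epsilon.
    """
    log2sig, index = _per_chip_gene_log2(matrix)
    cols = list(matrix.signals.columns)
    mut_idx = [cols.index(c) for c in matrix.chip_ids(MUTANT)]
    par_idx = [cols.index(c) for c in matrix.chip_ids(PARENT)]
    if len(mut_idx) < 2 or len(mut_idx) != len(par_idx):
        raise ValueError("need >= 2 paired chips per strain for the t-test")
    d = log2sig[:, mut_idx] - log2sig[:, par_idx]
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    p[zero_var & (mean == 0)] = 1.0
    p[zero_var & (mean != 0)] = np.finfo(float).eps
    p = np.maximum(p, np.finfo(float).eps)
    return pd.Series(p, index=index, name="p_value")


def per_gene_test(matrix: ChipSignalMatrix, gene_id: str) -> float:
    pvals = per_gene_test_table(matrix)
    if gene_id not in pvals.index:
        raise KeyError(f"gene {gene_id!r} not in the signal matrix")
    return float(pvals[gene_id])


def build_gene_table(
    matrix: ChipSignalMatrix,
    exclude_chromosome: str | None,
    noise_threshold: float = NOISE_THRESHOLD,
    add_bh: bool = True,
) -> pd.DataFrame:
    """Run correction, scaling, ratios and tests; one row per gene.

    The optional ``q_value_bh`` column is a Benjamini-Hochberg adjustment
    provided for modern use on top of the raw per-gene p-values.
    """
    corrected, above_noise = correct_and_filter(matrix, noise_threshold)
    scaled, _ = scale_chips(corrected, exclude_chromosome)
    table = gene_ratio_table(scaled)
    table["p_value"] = per_gene_test_table(scaled)
    table["above_noise"] = above_noise
    gene_meta = (
        matrix.probes[~matrix.probes["is_control"]]
        .drop_duplicates("gene_id")
        .set_index("gene_id")
    )
    table.insert(0, "chromosome", gene_meta["chromosome"])
    if add_bh:
        from statsmodels.stats.multitest import multipletests

        table["q_value_bh"] = multipletests(
            table["p_value"].to_numpy(), method="fdr_bh"
        )[1]
    table.attrs["scaled_matrix"] = scaled
    return table


def chromosome_summary(
    gene_table: pd.DataFrame,
    scaled_matrix: ChipSignalMatrix | None = None,
    mode: str = "genes",
) -> pd.DataFrame:
    """Per-chromosome mean/median ratio, paired t-test p-value and counts.

    Below-noise genes are excluded from mean, median and p-value but kept
    in ``n_genes``.  ``mode="genes"`` (default) tests per-gene mean log2
    scaled signals, mutant vs parent, paired across genes; ``mode="spots"``
    pools the per-(gene, chip-pair) log2 differences instead.
    """
    if scaled_matrix is None:
        scaled_matrix = gene_table.attrs.get("scaled_matrix")
    if scaled_matrix is None:
        raise ValueError("chromosome_summary needs the scaled signal matrix")
    if mode not in ("genes", "spots"):
        raise ValueError(f"unknown mode {mode!r}")

    log2sig, index = _per_chip_gene_log2(scaled_matrix)
    cols = list(scaled_matrix.signals.columns)
    mut_idx = [cols.index(c) for c in scaled_matrix.chip_ids(MUTANT)]
    par_idx = [cols.index(c) for c in scaled_matrix.chip_ids(PARENT)]
    log2 = pd.DataFrame(log2sig, index=index)

    rows = []
    for chrom, sub in gene_table.groupby("chromosome", sort=False):
        keep = sub[sub["above_noise"]]
        if len(keep):
            lg = log2.loc[keep.index].to_numpy()
            if mode == "genes":
                x = lg[:, mut_idx].mean(axis=1)
                y = lg[:, par_idx].mean(axis=1)
            else:
                x = lg[:, mut_idx].ravel()
                y = lg[:, par_idx].ravel()
            if len(x) >= 2 and not np.allclose(x - y, (x - y)[0]):
                p = float(stats.ttest_rel(x, y).pvalue)
            else:
                p = 1.0 if np.allclose(x, y) else float(np.finfo(float).eps)
            rows.append((
                chrom,
                float(keep["mean_ratio"].mean()),
                float(keep["median_ratio"].median()),
                p,
                len(sub),
                len(keep),
            ))
        else:
            rows.append((chrom, np.nan, np.nan, np.nan, len(sub), 0))
    return pd.DataFrame(
        rows,
        columns=["chromosome", "mean", "median", "p_value", "n_genes",
                 "n_above_noise"],
    )


def gc_anova(
    gc: np.ndarray, log2_ratios: np.ndarray, n_bins: int = 10
) -> tuple[float, float]:
    """One-way ANOVA of log2 ratios across GC-content decile bins.

    Used to check that probe base composition does not drive the observed
    expression ratios.  Returns (F, p).
    """
    gc = np.asarray(gc, dtype=float)
    values = np.asarray(log2_ratios, dtype=float)
    if gc.shape != values.shape:
        raise ValueError("gc and log2_ratios must have the same length")
    keep = np.isfinite(gc) & np.isfinite(values)
    gc, values = gc[keep], values[keep]
    bins = pd.qcut(gc, q=n_bins, duplicates="drop")
    groups = [
        values[bins.codes == k]
        for k in range(len(bins.categories))
        if (bins.codes == k).sum() >= 2
    ]
    if len(groups) < 2:
        raise ValueError("need >= 2 GC bins with >= 2 probes each")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)
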
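"""Tiling-aCGH ratios and per-gene copy-number calls.

Two genomic DNAs (monosomic mutant vs disomic parent) are co-hybridized to
50-mer tiling arrays; the mutant/parent intensity ratio of each probe
estimates relative copy number.  Per-probe ratios are read according to
each array's dye orientation (a dye-swapped array has the labels
exchanged, so its ratio is inverted before averaging), averaged across
arrays in ratio space, then aggregated per gene over the probes tiling
fully inside the ORF.  Observed ratios are compressed toward 1 relative to
true copy ratios (dynamic-range compression), so a single-copy gene sits
near 0.5-0.6 rather than exactly 0.5; the discrete call bands reflect
that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .simulate import TilingProbeTable

__all__ = [
    "CopyCall",
    "CopyThresholds",
    "probe_ratios",
    "average_arrays",
    "gene_cgh_ratio",
    "call_copy_number",
    "call_copy_number_table",
    "chromosome_dna_profile",
]


class CopyCall(str, Enum):
    ABSENT = "ABSENT"
    POOR_HYBRIDIZATION = "POOR_HYBRIDIZATION"
    SINGLE = "SINGLE"
    AMBIGUOUS = "AMBIGUOUS"
    DUPLICATED_POSSIBLE = "DUPLICATED_POSSIBLE"
    DUPLICATED = "DUPLICATED"


@dataclass(frozen=True)
class CopyThresholds:
    """Upper bounds (exclusive) of the call bands, in ratio units.

    Defaults encode the observed bands: lost loci near 0, poor
    hybridization below 0.4, single copy 0.4-0.65, an ambiguous "around
    0.7" group, possibly-duplicated slightly below 0.8, and confidently
    duplicated from 0.9 up.  The source bands are verbal, so all cutoffs
    are configurable.
    """

    absent: float = 0.1
    poor_hybridization: float = 0.4
    single: float = 0.65
    ambiguous: float = 0.75
    duplicated_possible: float = 0.9

    def edges(self) -> list[tuple[float, CopyCall]]:
        return [
            (self.absent, CopyCall.ABSENT),
            (self.poor_hybridization, CopyCall.POOR_HYBRIDIZATION),
            (self.single, CopyCall.SINGLE),
            (self.ambiguous, CopyCall.AMBIGUOUS),
            (self.duplicated_possible, CopyCall.DUPLICATED_POSSIBLE),
        ]


def probe_ratios(table: TilingProbeTable) -> pd.DataFrame:
    """Per-probe mutant/parent ratio on each array, orientation-corrected.

    On a standard array the mutant channel is Cy5 and the parent Cy3; on a
    dye-swapped array the reverse.  Probes whose parent channel is zero on
    an array are NaN there; probes with no valid array are dropped with a
    warning.
    """
    swapped = table.arrays.set_index("array_id")["dye_swapped"]
    cols = {}
    for array_id, is_swapped in swapped.items():
        mut = table.cy3[array_id] if is_swapped else table.cy5[array_id]
        par = table.cy5[array_id] if is_swapped else table.cy3[array_id]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = mut.to_numpy() / par.to_numpy()
        r = np.where(par.to_numpy() > 0, r, np.nan)
        cols[array_id] = r
    out = pd.DataFrame(cols, index=table.cy3.index)
    dead = out.isna().all(axis=1)
    if dead.any():
        warnings.warn(
            f"dropping {int(dead.sum())} probe(s) with no valid array"
        )
        out = out[~dead]
    return out


def average_arrays(ratios: pd.DataFrame, log_space: bool = False) -> pd.DataFrame:
    """Average per-array probe ratios into one data point per probe.

    Default is the arithmetic mean in ratio space with log2 of the mean
    reported alongside; ``log_space=True`` averages log2 ratios instead
    (geometric mean), offered as a non-default variant.
    """
    if log_space:
        mean_log2 = np.log2(ratios).mean(axis=1, skipna=True)
        mean_ratio = np.exp2(mean_log2)
    else:
        mean_ratio = ratios.mean(axis=1, skipna=True)
        mean_log2 = np.log2(mean_ratio)
    return pd.DataFrame({
        "mean_ratio": mean_ratio,
        "mean_log2": mean_log2,
        "n_arrays": ratios.notna().sum(axis=1),
    })


def _align_probe_meta(probes: pd.DataFrame, index: pd.Index) -> pd.DataFrame:
    """Probe metadata rows matching ``index``, cheaply when order matches."""
    ids = probes["probe_id"]
    if len(ids) == len(index) and np.array_equal(ids.to_numpy(), index.to_numpy()):
        return probes
    return probes.set_index("probe_id").loc[index].reset_index()


def gene_cgh_ratio(
    probe_means: pd.DataFrame,
    probes: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene mean DNA ratio from ORF-internal tiling probes.

    A probe counts toward a gene only when its full [start, start+length)
    interval lies inside the ORF (containment, not overlap).  Genes with
    no interior probe are reported with n_probes_in_orf = 0 and NaN ratios
    (missing from the CGH chips) rather than dropped.
    """
    meta = _align_probe_meta(probes, probe_means.index)
    chrom_arr = meta["chromosome"].to_numpy()
    start_arr = meta["start"].to_numpy()
    len_arr = meta["length"].to_numpy()
    gene_of_probe = np.full(len(meta), None, dtype=object)
    for chrom, genes in annotation.groupby("chromosome", sort=False):
        genes = genes.sort_values("start")
        sel = chrom_arr == chrom
        if not sel.any():
            continue
        starts = start_arr[sel]
        g_start = genes["start"].to_numpy()
        g_end = genes["end"].to_numpy()
        idx = np.searchsorted(g_start, starts, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(starts.size, dtype=bool)
        inside[ok] = starts[ok] + len_arr[sel][ok] <= g_end[idx[ok]]
        gene_of_probe[sel] = np.where(
            inside, genes["gene_id"].to_numpy()[idx], None
        )

    hit = pd.notna(gene_of_probe)
    grouped = pd.Series(
        probe_means["mean_ratio"].to_numpy()[hit], index=gene_of_probe[hit]
    ).groupby(level=0, sort=False)
    agg = pd.DataFrame({
        "mean_ratio": grouped.mean(),
        "n_probes_in_orf": grouped.size(),
    })
    out = annotation[["gene_id", "chromosome"]].set_index("gene_id")
    out = out.join(agg)
    out["n_probes_in_orf"] = out["n_probes_in_orf"].fillna(0).astype(int)
    out["mean_log2"] = np.log2(out["mean_ratio"])
    return out[["chromosome", "mean_ratio", "mean_log2", "n_probes_in_orf"]]


def call_copy_number(
    mean_ratio: float, thresholds: CopyThresholds | None = None
) -> CopyCall:
    """Discrete copy-number call for one gene's mean DNA ratio."""
    if not np.isfinite(mean_ratio) or mean_ratio < 0:
        raise ValueError(f"invalid mean ratio {mean_ratio!r}")
    thresholds = thresholds or CopyThresholds()
    for upper, call in thresholds.edges():
        if mean_ratio < upper:
            return call
    return CopyCall.DUPLICATED


def call_copy_number_table(
    gene_ratios: pd.DataFrame, thresholds: CopyThresholds | None = None
) -> pd.DataFrame:
    """Calls for every gene with at least one ORF-internal probe."""
    present = gene_ratios[gene_ratios["n_probes_in_orf"] > 0]
    calls = [
        call_copy_number(r, thresholds) for r in present["mean_ratio"]
    ]
    return pd.DataFrame(
        {
            "copy_call": [c.value for c in calls],
            "mean_ratio": present["mean_ratio"],
        },
        index=present.index,
    )


def chromosome_dna_profile(
    probe_means: pd.DataFrame, probes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-probe log2 track and per-chromosome mean log2 ratio.

    For a monosomic chromosome with compression gamma the chromosome mean
    log2 sits at -gamma, strictly between -1 and 0; a disomic control
    chromosome sits at 0.
    """
    meta = _align_probe_meta(probes, probe_means.index)
    track = pd.DataFrame({
        "chromosome": meta["chromosome"].to_numpy(),
        "start": meta["start"].to_numpy(),
        "end": (meta["start"] + meta["length"]).to_numpy(),
        "mean_log2": probe_means["mean_log2"].to_numpy(),
    })
    summary = (
        track.groupby("chromosome", sort=False, observed=True)["mean_log2"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_log2", "size": "n_probes"})
    )
    return track, summary
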
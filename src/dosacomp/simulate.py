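"""Synthetic microarray data with planted aneuploidy.

Generates a toy diploid yeast-like genome in which one chromosome is
monosomic, then emits the three datasets the downstream pipeline consumes —
single-dye expression chips for two strains, two-channel tiling aCGH arrays
(including a dye swap), and semi-quantitative RT-PCR replicate ratios —
together with the planted per-gene truth used by recovery tests.

The stated world mirrors a custom 12K expression-chip design: eight
chromosomes with fixed gene counts, the monosomic chromosome's ORFs spotted
twice per chip, three replicate chips per strain, 544 control probes of
which 395 are exogenous (background-only), additive background noise with
SD ~200 fluorescence units, and a five-class mixture of dosage-compensation
states for monosomic genes.  aCGH arrays are 50-mer tilings at 35 bp
per-strand spacing whose log2 ratios are compressed toward 0 by a
multiplicative factor gamma (dynamic-range compression).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CghConfig",
    "SimConfig",
    "ChipSignalMatrix",
    "TilingProbeTable",
    "CompensationClassError",
    "simulate_genome",
    "simulate_expression_chips",
    "simulate_cgh_arrays",
    "simulate_rtpcr",
]

#: order of planted compensation classes; proportions/fold ranges follow it
CLASS_NAMES = ("down2x", "partial", "compensated", "up", "excess")

PARENT = "parent"
MUTANT = "mutant"

# fixed labeled offsets for deriving independent substreams from one master
# seed, so toggling one stage never perturbs another
_STAGE_KEYS = {"genome": 11, "expression": 23, "cgh": 37, "rtpcr": 53}


class CompensationClassError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_KEYS[stage],))
    )


@dataclass(frozen=True)
class CghConfig:
    """Tiling-aCGH layer of the simulation.

    probe_noise_sd is in log2 units per probe per array; compression_gamma
    multiplies the true log2 copy ratio (gamma=1 means no compression).
    zero_copy_ratio_floor stands in for the DNA ratio of a lost locus, whose
    true log2 ratio is -inf but whose observed signal sits at the
    hybridization background, i.e. a ratio near 0.
    """

    probe_length: int = 50
    probe_spacing: int = 35
    n_arrays: int = 3
    dye_swap_arrays: tuple[int, ...] = (2,)  # 0-based; default: third array
    compression_gamma: float = 0.85
    probe_noise_sd: float = 0.1
    base_intensity: float = 1000.0
    intensity_log_sd: float = 0.3
    zero_copy_ratio_floor: float = 0.02

    def validate(self) -> None:
        if self.probe_spacing <= 0:
            raise CompensationClassError("probe_spacing must be positive")
        if self.probe_length <= 0:
            raise CompensationClassError("probe_length must be positive")
        if not (0.0 < self.compression_gamma <= 1.0):
            raise CompensationClassError("compression_gamma must be in (0, 1]")
        if self.n_arrays < 1:
            raise CompensationClassError("need at least one aCGH array")
        if any(a < 0 or a >= self.n_arrays for a in self.dye_swap_arrays):
            raise CompensationClassError("dye_swap_arrays indices out of range")
        if not (0.0 < self.zero_copy_ratio_floor < 1.0):
            raise CompensationClassError("zero_copy_ratio_floor must be in (0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of the planted world.

    Defaults encode the stated experimental design: per-chromosome gene
    counts (1346, 966, 987, 745, 661, 507, 431, 406), Ch5 monosomy, twice-
    spotted Ch5 ORFs, 3 chips per strain, 544 controls of which 395
    exogenous, background SD 200, and the headline compensation mixture.
    The published mixture 15/40/40/6 sums to 101% (rounding); the default
    proportions split the "up" band into up (5%) and an excess tail (1%)
    so the vector is a true distribution.  Any user-supplied vector is
    renormalized to sum to 1.
    """

    n_chromosomes: int = 8
    chromosome_names: tuple[str, ...] = (
        "Ch1", "ChR", "Ch2", "Ch3", "Ch4", "Ch5", "Ch6", "Ch7",
    )
    genes_per_chromosome: tuple[int, ...] = (
        1346, 966, 987, 745, 661, 507, 431, 406,
    )
    monosomic_chromosome: str = "Ch5"
    class_proportions: tuple[float, ...] = (0.15, 0.40, 0.39, 0.05, 0.01)
    class_fold_ranges: tuple[tuple[float, float], ...] = (
        (0.35, 0.60), (0.65, 0.85), (0.90, 1.10), (1.15, 2.10), (2.2, 4.2),
    )
    n_duplicated_genes: int = 3
    n_lost_genes: int = 5
    chips_per_strain: int = 3
    duplicate_spotting: bool = True
    n_control_probes: int = 544
    n_exogenous: int = 395
    # log-location/scale (natural log) of parent-strain transcript levels;
    # median exp(8.6) ~ 5400 fluorescence units, a bright in-situ chip whose
    # genes sit well above the noise floor: the below-noise filter and the
    # negative->1 rule are exercised by tests that plant dim genes, not by
    # the default mixture
    baseline_log_mean: float = 8.6
    baseline_log_sd: float = 0.6
    noise_cv: float = 0.1
    background_mean: float = 500.0
    background_sd: float = 200.0
    # optional trans-effects on disomic chromosomes; off by default so the
    # constant-total normalization assumption holds exactly
    trans_effect_fraction: float = 0.0
    trans_fold_range: tuple[float, float] = (0.5, 2.0)
    gene_length_range: tuple[int, int] = (600, 2000)
    intergenic_gap_range: tuple[int, int] = (150, 600)
    probe_gc_range: tuple[float, float] = (0.30, 0.55)
    cgh: CghConfig = field(default_factory=CghConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chromosome_names) != self.n_chromosomes:
            raise CompensationClassError(
                "chromosome_names length must equal n_chromosomes"
            )
        if len(self.genes_per_chromosome) != self.n_chromosomes:
            raise CompensationClassError(
                "genes_per_chromosome length must equal n_chromosomes"
            )
        if self.monosomic_chromosome not in self.chromosome_names:
            raise CompensationClassError(
                f"monosomic chromosome {self.monosomic_chromosome!r} not in "
                f"chromosome_names"
            )
        if len(self.class_proportions) != len(CLASS_NAMES):
            raise CompensationClassError(
                f"class_proportions needs {len(CLASS_NAMES)} entries"
            )
        if len(self.class_fold_ranges) != len(CLASS_NAMES):
            raise CompensationClassError(
                f"class_fold_ranges needs {len(CLASS_NAMES)} entries"
            )
        total = float(sum(self.class_proportions))
        if total <= 0 or any(p < 0 for p in self.class_proportions):
            raise CompensationClassError("class_proportions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            object.__setattr__(
                self,
                "class_proportions",
                tuple(p / total for p in self.class_proportions),
            )
        for lo, hi in self.class_fold_ranges:
            if not (0 < lo <= hi):
                raise CompensationClassError("invalid class fold range")
        counts = (
            self.n_duplicated_genes, self.n_lost_genes, self.chips_per_strain,
            self.n_control_probes, self.n_exogenous,
        )
        if any(c < 0 for c in counts) or any(
            c < 0 for c in self.genes_per_chromosome
        ):
            raise CompensationClassError("all counts must be >= 0")
        if self.n_exogenous > self.n_control_probes:
            raise CompensationClassError(
                "n_exogenous cannot exceed n_control_probes"
            )
        mono = self.monosomic_gene_count
        if self.n_duplicated_genes + self.n_lost_genes > mono:
            raise CompensationClassError(
                "n_duplicated_genes + n_lost_genes exceeds the monosomic "
                f"chromosome's gene count ({mono})"
            )
        if self.noise_cv < 0 or self.background_sd < 0:
            raise CompensationClassError("noise scales must be >= 0")
        self.cgh.validate()

    @property
    def monosomic_gene_count(self) -> int:
        idx = self.chromosome_names.index(self.monosomic_chromosome)
        return self.genes_per_chromosome[idx]

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# genome + planted truth
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out genes and plant per-gene truth.

    Returns ``(annotation, truth)``.  ``annotation`` has one row per gene
    (gene_id, chromosome, start, end, strand; 0-based half-open).  ``truth``
    adds true_level (parent-strain mean fluorescence), comp_class,
    true_fold (mutant/parent transcript ratio), copy_parent/copy_mutant and
    probe_gc.  Exactly ``n_lost_genes`` monosomic genes carry copy 0 and
    fold 0 ("lost"), and exactly ``n_duplicated_genes`` carry copy 2 with a
    compensated expression fold.
    """
    rng = _stage_rng(config.seed, "genome")
    frames = []
    for chrom, n_genes in zip(config.chromosome_names, config.genes_per_chromosome):
        lengths = rng.integers(*config.gene_length_range, size=n_genes)
        gaps = rng.integers(*config.intergenic_gap_range, size=n_genes)
        starts = np.cumsum(gaps) + np.concatenate(([0], np.cumsum(lengths)[:-1]))
        frames.append(pd.DataFrame({
            "gene_id": [f"{chrom}_g{i + 1:04d}" for i in range(n_genes)],
            "chromosome": chrom,
            "start": starts,
            "end": starts + lengths,
            "strand": np.where(rng.random(n_genes) < 0.5, "+", "-"),
        }))
    annotation = pd.concat(frames, ignore_index=True)

    n_total = len(annotation)
    truth = annotation.copy()
    truth["true_level"] = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_total)
    )
    truth["comp_class"] = "not_applicable"
    truth["true_fold"] = 1.0
    truth["copy_parent"] = 2
    truth["copy_mutant"] = 2
    truth["probe_gc"] = rng.uniform(*config.probe_gc_range, size=n_total)

    # optional trans-effects on disomic chromosomes (off by default)
    if config.trans_effect_fraction > 0:
        off = truth.index[truth["chromosome"] != config.monosomic_chromosome]
        n_trans = int(round(config.trans_effect_fraction * len(off)))
        picked = rng.choice(off, size=n_trans, replace=False)
        truth.loc[picked, "true_fold"] = rng.uniform(
            *config.trans_fold_range, size=n_trans
        )

    mono_idx = truth.index[
        truth["chromosome"] == config.monosomic_chromosome
    ].to_numpy()
    props = np.asarray(config.class_proportions)
    cls = rng.choice(len(CLASS_NAMES), size=mono_idx.size, p=props)
    folds = np.empty(mono_idx.size)
    for k, (lo, hi) in enumerate(config.class_fold_ranges):
        mask = cls == k
        # half-open draws keep planted folds strictly inside each class band
        folds[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
    truth.loc[mono_idx, "comp_class"] = np.asarray(CLASS_NAMES)[cls]
    truth.loc[mono_idx, "true_fold"] = folds
    truth.loc[mono_idx, "copy_mutant"] = 1

    shuffled = rng.permutation(mono_idx)
    lost = shuffled[: config.n_lost_genes]
    truth.loc[lost, "comp_class"] = "lost"
    truth.loc[lost, "true_fold"] = 0.0
    truth.loc[lost, "copy_mutant"] = 0

    if config.n_duplicated_genes:
        remaining = shuffled[config.n_lost_genes:]
        comp = remaining[
            (truth.loc[remaining, "comp_class"] == "compensated").to_numpy()
        ]
        dup = comp[: config.n_duplicated_genes]
        if dup.size < config.n_duplicated_genes:
            extra = remaining[~np.isin(remaining, dup)][
                : config.n_duplicated_genes - dup.size
            ]
            lo, hi = config.class_fold_ranges[CLASS_NAMES.index("compensated")]
            truth.loc[extra, "true_fold"] = rng.uniform(lo, hi, size=extra.size)
            dup = np.concatenate([dup, extra])
        truth.loc[dup, "comp_class"] = "compensated"
        truth.loc[dup, "copy_mutant"] = 2
    return annotation, truth


# ---------------------------------------------------------------------------
# expression chips
# ---------------------------------------------------------------------------

@dataclass
class ChipSignalMatrix:
    """Probe-level signals for a set of single-dye expression chips.

    probes: one row per spot (probe_id, gene_id, chromosome, spot,
    is_control, is_exogenous, probe_gc).  chips: one row per chip (chip_id,
    strain, replicate).  signals: DataFrame indexed by probe_id with one
    column per chip_id, in raw fluorescence units (or corrected/scaled
    units downstream).
    """

    probes: pd.DataFrame
    chips: pd.DataFrame
    signals: pd.DataFrame

    def with_signals(self, signals: pd.DataFrame) -> "ChipSignalMatrix":
        return ChipSignalMatrix(self.probes, self.chips, signals)

    @property
    def spots_per_gene(self) -> pd.Series:
        """J: number of spots per gene per chip."""
        gene_probes = self.probes[~self.probes["is_control"]]
        return gene_probes.groupby("gene_id", sort=False).size()

    def chip_ids(self, strain: str) -> list[str]:
        sel = self.chips[self.chips["strain"] == strain]
        return sel.sort_values("replicate")["chip_id"].tolist()


def _lognormal_noise(
    rng: np.random.Generator, cv: float, size: tuple[int, ...]
) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    # mean-one parameterization: E[noise] = 1 for every cv
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def simulate_expression_chips(
    truth: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> ChipSignalMatrix:
    """Emit raw spot signals for both strains.

    signal = background_draw + true_level * fold * lognormal(1, noise_cv),
    with fold = true_fold on mutant chips and 1 on parent chips.  Monosomic
    genes occupy two spots per chip when duplicate_spotting; control probes
    carry background only.  Background draws are Normal(background_mean,
    background_sd) clipped at zero (fluorescence is non-negative).
    """
    rng = _stage_rng(config.seed if seed is None else seed, "expression")

    spot_counts = np.where(
        (truth["chromosome"] == config.monosomic_chromosome)
        & config.duplicate_spotting,
        2,
        1,
    )
    gene_rows = truth.loc[truth.index.repeat(spot_counts)].reset_index(drop=True)
    gene_rows["spot"] = gene_rows.groupby("gene_id", sort=False).cumcount() + 1

    probes = pd.DataFrame({
        "probe_id": [
            f"{g}_s{s}" for g, s in zip(gene_rows["gene_id"], gene_rows["spot"])
        ],
        "gene_id": gene_rows["gene_id"],
        "chromosome": gene_rows["chromosome"],
        "spot": gene_rows["spot"],
        "is_control": False,
        "is_exogenous": False,
        "probe_gc": gene_rows["probe_gc"],
    })
    ctrl = pd.DataFrame({
        "probe_id": [f"ctrl_{i + 1:04d}" for i in range(config.n_control_probes)],
        "gene_id": pd.NA,
        "chromosome": pd.NA,
        "spot": 1,
        "is_control": True,
        "is_exogenous": [
            i < config.n_exogenous for i in range(config.n_control_probes)
        ],
        "probe_gc": rng.uniform(
            *config.probe_gc_range, size=config.n_control_probes
        ),
    })
    probes = pd.concat([probes, ctrl], ignore_index=True)

    chips = pd.DataFrame(
        [
            (f"{strain[0].upper()}{r + 1}", strain, r + 1)
            for strain in (PARENT, MUTANT)
            for r in range(config.chips_per_strain)
        ],
        columns=["chip_id", "strain", "replicate"],
    )

    n_probes, n_chips = len(probes), len(chips)
    level = np.zeros(n_probes)
    gene_mask = ~probes["is_control"].to_numpy()
    level[gene_mask] = gene_rows["true_level"].to_numpy()
    fold = np.ones(n_probes)
    fold[gene_mask] = gene_rows["true_fold"].to_numpy()

    mutant_chip = (chips["strain"] == MUTANT).to_numpy()
    expected = level[:, None] * np.where(mutant_chip[None, :], fold[:, None], 1.0)
    noise = _lognormal_noise(rng, config.noise_cv, (n_probes, n_chips))
    if config.background_sd > 0:
        background = np.clip(
            rng.normal(
                config.background_mean, config.background_sd, (n_probes, n_chips)
            ),
            0.0,
            None,
        )
    else:
        background = np.full((n_probes, n_chips), float(config.background_mean))
    raw = background + expected * noise

    signals = pd.DataFrame(
        raw, index=pd.Index(probes["probe_id"], name="probe_id"),
        columns=chips["chip_id"],
    )
    return ChipSignalMatrix(probes, chips, signals)


# ---------------------------------------------------------------------------
# tiling aCGH arrays
# ---------------------------------------------------------------------------

@dataclass
class TilingProbeTable:
    """Two-channel tiling-array intensities.

    probes: probe_id, chromosome, start, length, strand, gene_id (NA for
    probes not fully inside an ORF).  arrays: array_id, dye_swapped.  cy3 /
    cy5: DataFrames indexed by probe_id with one column per array.  On a
    standard-orientation array the mutant DNA is in Cy5 and the parent in
    Cy3; a dye-swapped array has the labels exchanged.
    """

    probes: pd.DataFrame
    arrays: pd.DataFrame
    cy3: pd.DataFrame
    cy5: pd.DataFrame


def _tile_chromosome(
    length: int, spacing: int, probe_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Probe start positions on both strands; per-strand spacing."""
    plus = np.arange(0, max(length - probe_len, 0) + 1, spacing)
    minus = np.arange(spacing // 2, max(length - probe_len, 0) + 1, spacing)
    starts = np.concatenate([plus, minus])
    strands = np.concatenate(
        [np.full(plus.size, "+"), np.full(minus.size, "-")]
    )
    order = np.argsort(starts, kind="stable")
    return starts[order], strands[order]


def _map_probes_to_genes(
    starts: np.ndarray, probe_len: int, genes: pd.DataFrame
) -> np.ndarray:
    """gene row index for probes fully inside an ORF, else -1.

    Assumes genes are non-overlapping and sorted by start within the
    chromosome (true by construction).
    """
    g_start = genes["start"].to_numpy()
    g_end = genes["end"].to_numpy()
    idx = np.searchsorted(g_start, starts, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(starts.size, dtype=bool)
    inside[ok] = starts[ok] + probe_len <= g_end[idx[ok]]
    return np.where(inside, idx, -1)


def simulate_cgh_arrays(
    truth: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
    chromosomes: Sequence[str] | None = None,
) -> TilingProbeTable:
    """Emit two-channel tiling-aCGH intensities for all arrays.

    For each probe the observed log2(mutant/parent) is
    ``compression_gamma * log2(copy_mutant / copy_parent) + N(0, sd)``;
    probes fully inside an ORF use that gene's planted copy numbers, other
    probes the chromosomal copy number.  Lost loci (copy 0) hybridize at
    the background floor, i.e. a small positive ratio rather than -inf.
    """
    cfg = config.cgh
    cfg.validate()
    rng = _stage_rng(config.seed if seed is None else seed, "cgh")
    chroms = list(chromosomes or config.chromosome_names)

    cols: dict[str, list[np.ndarray]] = {
        k: [] for k in ("probe_id", "chromosome", "start", "strand", "gene_id")
    }
    log2_true = []
    for chrom in chroms:
        genes = truth[truth["chromosome"] == chrom].sort_values("start")
        length = int(genes["end"].max()) + 400 if len(genes) else 0
        starts, strands = _tile_chromosome(
            length, cfg.probe_spacing, cfg.probe_length
        )
        gidx = _map_probes_to_genes(starts, cfg.probe_length, genes)
        chrom_copy = 1 if chrom == config.monosomic_chromosome else 2
        copy_mut = np.where(
            gidx >= 0, genes["copy_mutant"].to_numpy()[gidx], chrom_copy
        ).astype(float)
        copy_par = np.where(
            gidx >= 0, genes["copy_parent"].to_numpy()[gidx], 2
        ).astype(float)
        ratio = np.where(
            copy_mut > 0, copy_mut / copy_par, cfg.zero_copy_ratio_floor
        )
        log2_true.append(cfg.compression_gamma * np.log2(ratio))
        cols["probe_id"].append(np.char.add(
            f"{chrom}_t", np.arange(1, starts.size + 1).astype("U7")
        ))
        cols["chromosome"].append(np.full(starts.size, chrom, dtype=object))
        cols["start"].append(starts)
        cols["strand"].append(strands)
        cols["gene_id"].append(np.where(
            gidx >= 0, genes["gene_id"].to_numpy()[gidx], None
        ))
    # string/categorical dtypes: plain object columns at this row count make
    # pandas block consolidation the pipeline bottleneck
    probes = pd.DataFrame({
        "probe_id": pd.array(np.concatenate(cols["probe_id"]), dtype="string"),
        "chromosome": pd.Categorical(np.concatenate(cols["chromosome"])),
        "start": np.concatenate(cols["start"]),
        "length": cfg.probe_length,
        "strand": pd.Categorical(np.concatenate(cols["strand"])),
        "gene_id": np.concatenate(cols["gene_id"]),
    })
    mu = np.concatenate(log2_true)

    arrays = pd.DataFrame({
        "array_id": [f"cgh{a + 1}" for a in range(cfg.n_arrays)],
        "dye_swapped": [a in cfg.dye_swap_arrays for a in range(cfg.n_arrays)],
    })
    n_probes = len(probes)
    cy3 = np.empty((n_probes, cfg.n_arrays))
    cy5 = np.empty((n_probes, cfg.n_arrays))
    for a in range(cfg.n_arrays):
        noise = (
            rng.normal(0.0, cfg.probe_noise_sd, n_probes)
            if cfg.probe_noise_sd > 0
            else 0.0
        )
        r = np.exp2(mu + noise)
        base = cfg.base_intensity * np.exp(
            rng.normal(0.0, cfg.intensity_log_sd, n_probes)
        )
        if arrays.loc[a, "dye_swapped"]:
            cy3[:, a] = base * r  # mutant in Cy3
            cy5[:, a] = base
        else:
            cy5[:, a] = base * r  # mutant in Cy5
            cy3[:, a] = base
    index = pd.Index(probes["probe_id"], name="probe_id")
    return TilingProbeTable(
        probes,
        arrays,
        pd.DataFrame(cy3, index=index, columns=arrays["array_id"]),
        pd.DataFrame(cy5, index=index, columns=arrays["array_id"]),
    )


# ---------------------------------------------------------------------------
# RT-PCR replicates
# ---------------------------------------------------------------------------

def simulate_rtpcr(
    truth: pd.DataFrame,
    gene_ids: Sequence[str],
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> Mapping[str, list[float]]:
    """Replicate mutant/parent ratios per gene, each true_fold * lognormal."""
    rng = _stage_rng(seed, "rtpcr")
    folds = truth.set_index("gene_id")["true_fold"]
    missing = [g for g in gene_ids if g not in folds.index]
    if missing:
        raise KeyError(f"unknown gene ids: {missing}")
    out: dict[str, list[float]] = {}
    for gene in gene_ids:
        noise = _lognormal_noise(rng, noise_cv, (n_replicates,))
        out[gene] = list(float(folds[gene]) * noise)
    return out
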
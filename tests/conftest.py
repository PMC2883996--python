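"""Shared fixtures: configurations, one cached default run, tiny matrices."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import dosacomp as dc


@pytest.fixture(scope="session")
def default_config() -> dc.SimConfig:
    return dc.SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_genome(default_config):
    return dc.simulate_genome(default_config)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default world (cached: ~10 s)."""
    return dc.run_pipeline(seed=1)


def small_config(**overrides) -> dc.SimConfig:
    """Reduced genome (80 monosomic genes) for fast statistical tests."""
    base = dict(
        genes_per_chromosome=(60, 40, 40, 40, 40, 80, 40, 40),
        n_duplicated_genes=1,
        n_lost_genes=2,
        seed=0,
    )
    base.update(overrides)
    return dc.SimConfig(**base)


def noiseless_config(**overrides) -> dc.SimConfig:
    """No spot noise and a flat background: ratios equal planted folds."""
    base = dict(noise_cv=0.0, background_sd=0.0, background_mean=300.0)
    base.update(overrides)
    return small_config(**base)


def null_config(**overrides) -> dc.SimConfig:
    """All monosomic genes fully compensated at fold exactly 1 (true null)."""
    base = dict(
        class_proportions=(0.0, 0.0, 1.0, 0.0, 0.0),
        class_fold_ranges=(
            (0.35, 0.60), (0.65, 0.85), (1.0, 1.0), (1.15, 2.10), (2.2, 4.2),
        ),
        n_duplicated_genes=0,
        n_lost_genes=0,
    )
    base.update(overrides)
    return replace(dc.SimConfig(), **base)


@pytest.fixture
def tiny_matrix_factory():
    """Build a ChipSignalMatrix from explicit per-probe signals.

    ``genes`` maps gene_id -> (chromosome, n_spots); ``signals`` is an
    array of shape (n_gene_spots + n_controls, 2 * n_replicates) with
    parent chips first; ``n_controls`` rows at the bottom are exogenous
    controls.
    """

    def build(genes, signals, n_controls=0, n_replicates=None):
        signals = np.asarray(signals, dtype=float)
        n_rep = n_replicates or signals.shape[1] // 2
        rows = []
        for gene_id, (chrom, n_spots) in genes.items():
            for s in range(1, n_spots + 1):
                rows.append((f"{gene_id}_s{s}", gene_id, chrom, s, False, False))
        for i in range(n_controls):
            rows.append((f"ctrl_{i + 1}", None, None, 1, True, True))
        probes = pd.DataFrame(
            rows,
            columns=["probe_id", "gene_id", "chromosome", "spot",
                     "is_control", "is_exogenous"],
        )
        probes["probe_gc"] = 0.4
        chips = pd.DataFrame(
            [(f"P{r + 1}", "parent", r + 1) for r in range(n_rep)]
            + [(f"M{r + 1}", "mutant", r + 1) for r in range(n_rep)],
            columns=["chip_id", "strain", "replicate"],
        )
        frame = pd.DataFrame(
            signals,
            index=pd.Index(probes["probe_id"], name="probe_id"),
            columns=chips["chip_id"],
        )
        return dc.ChipSignalMatrix(probes, chips, frame)

    return build
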
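"""Joint expression x copy-number verdicts and the final report bundle.

A gene on the monosomic chromosome whose transcript sits at the disomic
level may be genuinely dosage-compensated (one DNA copy, restored
expression) or simply duplicated (two copies, no compensation needed); the
aCGH copy call separates the two.  The decision table below encodes that
interpretation; RT-PCR concordance checks that independent replicate
ratios agree with the array ratios.
"""

from __future__ import annotations

import json
import logging
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cgh import CopyCall
from .classify import CompensationClass, classify_gene

__all__ = [
    "Verdict",
    "integrate_gene",
    "integrate_table",
    "implied_verdicts",
    "rtpcr_mean_ratio",
    "concordance_check",
    "concordance_table",
    "write_report",
]

logger = logging.getLogger("dosacomp")


class Verdict(str, Enum):
    COMPENSATED_SINGLE_COPY = "COMPENSATED_SINGLE_COPY"
    DUPLICATION_NOT_COMPENSATION = "DUPLICATION_NOT_COMPENSATION"
    UNCOMPENSATED_MONOSOMIC = "UNCOMPENSATED_MONOSOMIC"
    PARTIAL_COMPENSATION = "PARTIAL_COMPENSATION"
    INDIRECT_UPREGULATION = "INDIRECT_UPREGULATION"
    LOST = "LOST"
    INDETERMINATE = "INDETERMINATE"


_BY_CLASS_SINGLE = {
    CompensationClass.DISOMIC: Verdict.COMPENSATED_SINGLE_COPY,
    CompensationClass.DOWN_2X: Verdict.UNCOMPENSATED_MONOSOMIC,
    CompensationClass.PARTIAL: Verdict.PARTIAL_COMPENSATION,
    CompensationClass.UP: Verdict.INDIRECT_UPREGULATION,
    CompensationClass.EXCESS: Verdict.INDIRECT_UPREGULATION,
}


def integrate_gene(
    expr_class: CompensationClass | str | None,
    copy_call: CopyCall | str | None,
) -> Verdict:
    """Verdict from one gene's expression class and copy call.

    Decision table: a lost locus is LOST whatever its expression; a
    disomic-level transcript from one copy is compensated, from two copies
    a duplication; down/partial/up classes on a single copy map to the
    corresponding monosomic interpretations; anything else (ambiguous or
    poor-hybridization calls, missing inputs) is INDETERMINATE.
    """
    # an absent locus is LOST whatever its transcript looks like (a lost
    # gene is below noise on the expression chips, so its class is missing
    # by construction)
    if copy_call is not None and CopyCall(copy_call) is CopyCall.ABSENT:
        return Verdict.LOST
    if expr_class is None or copy_call is None:
        return Verdict.INDETERMINATE
    expr_class = CompensationClass(expr_class)
    copy_call = CopyCall(copy_call)
    if copy_call is CopyCall.SINGLE:
        return _BY_CLASS_SINGLE.get(expr_class, Verdict.INDETERMINATE)
    if copy_call in (CopyCall.DUPLICATED, CopyCall.DUPLICATED_POSSIBLE):
        if expr_class is CompensationClass.DISOMIC:
            return Verdict.DUPLICATION_NOT_COMPENSATION
    return Verdict.INDETERMINATE


def integrate_table(
    classification: pd.DataFrame, copy_calls: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene verdicts for the union of classified and called genes."""
    expr = classification.set_index("gene_id")
    genes = expr.index.union(copy_calls.index)
    rows = []
    for gene in genes:
        cls = expr["comp_class"].get(gene)
        call = copy_calls["copy_call"].get(gene)
        verdict = integrate_gene(cls, call)
        reason = ""
        if verdict is Verdict.INDETERMINATE:
            if cls is None:
                reason = "no expression class (below noise or unclassified)"
            elif call is None:
                reason = "no copy-number call (gene missing from CGH chips)"
            else:
                reason = f"uninformative pair ({cls}, {call})"
        rows.append((gene, cls, call, verdict.value, reason))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "comp_class", "copy_call", "verdict", "reason"],
    ).set_index("gene_id")


_TRUTH_VERDICT = {
    "down2x": Verdict.UNCOMPENSATED_MONOSOMIC,
    "partial": Verdict.PARTIAL_COMPENSATION,
    "up": Verdict.INDIRECT_UPREGULATION,
    "excess": Verdict.INDIRECT_UPREGULATION,
    "lost": Verdict.LOST,
}


def implied_verdicts(truth: pd.DataFrame) -> pd.Series:
    """Verdict implied by each planted (comp_class, copy_mutant) truth."""
    out = []
    for cls, copies in zip(truth["comp_class"], truth["copy_mutant"]):
        if cls == "compensated":
            v = (
                Verdict.DUPLICATION_NOT_COMPENSATION
                if copies == 2
                else Verdict.COMPENSATED_SINGLE_COPY
            )
        else:
            v = _TRUTH_VERDICT.get(cls, Verdict.INDETERMINATE)
        out.append(v.value)
    return pd.Series(out, index=truth.index, name="implied_verdict")


def rtpcr_mean_ratio(replicates: Sequence[float]) -> float:
    """Arithmetic mean of replicate RT-PCR ratios."""
    replicates = list(replicates)
    if not replicates:
        raise ValueError("no RT-PCR replicates")
    if any(r <= 0 for r in replicates):
        raise ValueError("RT-PCR replicate ratios must be positive")
    return float(np.mean(replicates))


def concordance_check(
    array_ratio: float, rtpcr_mean: float, log2_tol: float = 0.5
) -> bool:
    """Do the array and RT-PCR ratios agree?

    Agreement: same compensation class, or |log2 difference| <= log2_tol.
    """
    if array_ratio <= 0 or rtpcr_mean <= 0:
        raise ValueError("ratios must be positive")
    same_class = classify_gene(array_ratio) == classify_gene(rtpcr_mean)
    close = abs(np.log2(array_ratio) - np.log2(rtpcr_mean)) <= log2_tol
    return bool(same_class or close)


def concordance_table(
    array_ratios: Mapping[str, float],
    rtpcr: Mapping[str, Sequence[float]],
    log2_tol: float = 0.5,
) -> pd.DataFrame:
    rows = []
    for gene, reps in rtpcr.items():
        mean = rtpcr_mean_ratio(reps)
        arr = array_ratios.get(gene)
        agree = (
            concordance_check(arr, mean, log2_tol) if arr is not None else None
        )
        rows.append((
            gene, arr, ";".join(f"{r:.3g}" for r in reps), mean, agree,
        ))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "array_ratio", "rtpcr_replicates", "rtpcr_mean",
                 "agree"],
    ).set_index("gene_id")


def _tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def write_report(
    outdir: str | Path,
    *,
    chromosome_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    classification: pd.DataFrame,
    proportions: pd.DataFrame,
    copy_calls: pd.DataFrame,
    verdicts: pd.DataFrame,
    concordance: pd.DataFrame | None = None,
    config_echo: Mapping | None = None,
    seed: int | None = None,
) -> Path:
    """Write the flat per-gene TSVs plus a machine-readable summary.

    The summary (report.json) carries the chromosome-level table, class
    proportions, copy-call and verdict counts, the concordance tally, the
    configuration echo, the seed, and the package version; reruns with the
    same config and seed are byte-identical.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _tsv(chromosome_table, outdir / "chromosome_summary.tsv", index=False)
    _tsv(gene_table, outdir / "gene_expression.tsv")
    _tsv(classification, outdir / "classification.tsv", index=False)
    _tsv(copy_calls, outdir / "copy_calls.tsv")
    _tsv(verdicts, outdir / "verdicts.tsv")
    if concordance is not None:
        _tsv(concordance, outdir / "concordance.tsv")

    summary = {
        "software_version": __version__,
        "seed": seed,
        "config": dict(config_echo) if config_echo else None,
        "chromosome_summary": json.loads(
            chromosome_table.to_json(orient="records", double_precision=10)
        ),
        "class_proportions": json.loads(
            proportions.to_json(orient="records", double_precision=10)
        ),
        "copy_call_counts": verdict_counts(copy_calls["copy_call"]),
        "verdict_counts": verdict_counts(verdicts["verdict"]),
        "concordance": (
            {
                "n": int(len(concordance)),
                "n_agree": int(concordance["agree"].fillna(False).sum()),
            }
            if concordance is not None
            else None
        ),
    }
    path = outdir / "report.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("report written to %s", path)
    return path


def verdict_counts(labels: pd.Series) -> dict[str, int]:
    counts = labels.value_counts().sort_index()
    return {str(k): int(v) for k, v in counts.items()}


def run_pipeline(
    config=None,
    seed: int | None = None,
    outdir: str | Path | None = None,
    rtpcr_genes: Sequence[str] | None = None,
    n_rtpcr_replicates: int = 3,
    rtpcr_noise_cv: float = 0.05,
):
    """Simulate one dataset and run every stage; optionally write the report.

    Returns a dict with the planted truth, the per-gene expression table,
    the chromosome summary, the monosomic-chromosome classification and
    class proportions, the per-gene copy calls, the joint verdicts, the
    RT-PCR concordance table, and the fraction of monosomic genes whose
    verdict matches the one implied by the planted truth.
    """
    from . import cgh as cgh_mod
    from . import classify as classify_mod
    from . import expression as expr_mod
    from . import simulate as sim_mod

    config = config or sim_mod.SimConfig()
    if seed is not None:
        config = config.with_seed(seed)
    logger.info("simulating genome (seed=%d)", config.seed)
    annotation, truth = sim_mod.simulate_genome(config)
    matrix = sim_mod.simulate_expression_chips(truth, config)
    cgh_table = sim_mod.simulate_cgh_arrays(truth, config)

    gene_table = expr_mod.build_gene_table(
        matrix, exclude_chromosome=config.monosomic_chromosome
    )
    chromosome_table = expr_mod.chromosome_summary(gene_table)
    classification = classify_mod.classify_table(
        gene_table, annotation, config.monosomic_chromosome
    )
    proportions = classify_mod.class_proportions(classification)

    ratios = cgh_mod.probe_ratios(cgh_table)
    probe_means = cgh_mod.average_arrays(ratios)
    gene_ratios = cgh_mod.gene_cgh_ratio(probe_means, cgh_table.probes, annotation)
    mono_ratios = gene_ratios[
        gene_ratios["chromosome"] == config.monosomic_chromosome
    ]
    copy_calls = cgh_mod.call_copy_number_table(mono_ratios)
    verdicts = integrate_table(classification, copy_calls)

    mono_truth = truth[
        truth["chromosome"] == config.monosomic_chromosome
    ].set_index("gene_id")
    implied = implied_verdicts(mono_truth)
    joined = verdicts.join(implied, how="right")
    matched = (joined["verdict"] == joined["implied_verdict"]).fillna(False)
    recovery = float(matched.mean())
    logger.info(
        "verdict recovery on %s: %.1f%% of %d genes",
        config.monosomic_chromosome, 100 * recovery, len(joined),
    )

    rtpcr_genes = list(
        rtpcr_genes
        if rtpcr_genes is not None
        else classification["gene_id"].head(21)
    )
    rtpcr = sim_mod.simulate_rtpcr(
        truth, rtpcr_genes, n_rtpcr_replicates, rtpcr_noise_cv,
        seed=config.seed,
    )
    array_ratios = classification.set_index("gene_id")["mean_ratio"].to_dict()
    concordance = concordance_table(array_ratios, rtpcr)

    results = {
        "config": config,
        "annotation": annotation,
        "truth": truth,
        "gene_table": gene_table,
        "chromosome_table": chromosome_table,
        "classification": classification,
        "proportions": proportions,
        "probe_means": probe_means,
        "gene_cgh_ratios": gene_ratios,
        "copy_calls": copy_calls,
        "verdicts": verdicts,
        "concordance": concordance,
        "verdict_recovery": recovery,
    }
    if outdir is not None:
        from .io import config_to_dict

        write_report(
            outdir,
            chromosome_table=chromosome_table,
            gene_table=gene_table.drop(columns=[], errors="ignore"),
            classification=classification,
            proportions=proportions,
            copy_calls=copy_calls,
            verdicts=verdicts,
            concordance=concordance,
            config_echo=config_to_dict(config),
            seed=config.seed,
        )
    return results
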
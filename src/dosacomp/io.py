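"""Readers and writers: GFF3, TSV signal tables, bedGraph/BED, YAML config,
and a minimal GEO series-matrix parser.

All tables are plain tab-separated text with header rows.  Coordinates are
0-based half-open in memory; GFF3 output converts to 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .simulate import CghConfig, ChipSignalMatrix, SimConfig, TilingProbeTable

__all__ = [
    "write_gff3",
    "read_gff3",
    "write_expression_matrix",
    "read_expression_matrix",
    "write_cgh_table",
    "read_cgh_table",
    "write_bedgraph",
    "write_classification_bed",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "dump_config",
    "read_series_matrix",
]


# -- GFF3 -------------------------------------------------------------------

def write_gff3(annotation: pd.DataFrame, path: str | Path) -> Path:
    """Write gene features; start/end converted to 1-based inclusive."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\tdosacomp\tgene\t{row.start + 1}\t"
                f"{row.end}\t.\t{row.strand}\t.\t"
                f"ID={row.gene_id};Name={row.gene_id}\n"
            )
    return path


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Gene annotation as (gene_id, chromosome, start, end, strand),
    0-based half-open."""
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    df = df[df["Feature"] == "gene"]
    out = pd.DataFrame({
        "gene_id": df["ID"].astype(str),
        "chromosome": df["Chromosome"].astype(str),
        "start": df["Start"].astype(int),
        "end": df["End"].astype(int),
        "strand": df["Strand"].astype(str),
    })
    return out.sort_values(["chromosome", "start"]).reset_index(drop=True)


# -- expression chips -------------------------------------------------------

def write_expression_matrix(
    matrix: ChipSignalMatrix, outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    signals = matrix.probes.merge(
        matrix.signals, left_on="probe_id", right_index=True
    )
    paths = {
        "signals": outdir / "expression_signals.tsv",
        "chips": outdir / "expression_chips.tsv",
    }
    signals.to_csv(paths["signals"], sep="\t", index=False, float_format="%.10g")
    matrix.chips.to_csv(paths["chips"], sep="\t", index=False)
    return paths


def read_expression_matrix(outdir: str | Path) -> ChipSignalMatrix:
    outdir = Path(outdir)
    signals = pd.read_csv(outdir / "expression_signals.tsv", sep="\t")
    chips = pd.read_csv(outdir / "expression_chips.tsv", sep="\t")
    meta_cols = [
        "probe_id", "gene_id", "chromosome", "spot", "is_control",
        "is_exogenous", "probe_gc",
    ]
    probes = signals[meta_cols].copy()
    values = signals.set_index("probe_id")[chips["chip_id"].tolist()]
    return ChipSignalMatrix(probes, chips, values)


# -- tiling aCGH ------------------------------------------------------------

def write_cgh_table(table: TilingProbeTable, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wide = table.probes.copy()
    for array_id in table.arrays["array_id"]:
        wide[f"{array_id}_cy3"] = table.cy3[array_id].to_numpy()
        wide[f"{array_id}_cy5"] = table.cy5[array_id].to_numpy()
    paths = {
        "probes": outdir / "cgh_probes.tsv",
        "arrays": outdir / "cgh_arrays.tsv",
    }
    wide.to_csv(paths["probes"], sep="\t", index=False, float_format="%.10g")
    table.arrays.to_csv(paths["arrays"], sep="\t", index=False)
    return paths


def read_cgh_table(outdir: str | Path) -> TilingProbeTable:
    outdir = Path(outdir)
    wide = pd.read_csv(outdir / "cgh_probes.tsv", sep="\t")
    arrays = pd.read_csv(outdir / "cgh_arrays.tsv", sep="\t")
    meta_cols = ["probe_id", "chromosome", "start", "length", "strand", "gene_id"]
    probes = wide[meta_cols].copy()
    index = pd.Index(wide["probe_id"], name="probe_id")
    cy3 = pd.DataFrame(
        {a: wide[f"{a}_cy3"].to_numpy() for a in arrays["array_id"]}, index=index
    )
    cy5 = pd.DataFrame(
        {a: wide[f"{a}_cy5"].to_numpy() for a in arrays["array_id"]}, index=index
    )
    return TilingProbeTable(probes, arrays, cy3, cy5)


# -- genome-browser tracks --------------------------------------------------

def write_bedgraph(track: pd.DataFrame, path: str | Path) -> Path:
    """Per-probe log2 DNA-ratio track (chrom, start, end, value)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write('track type=bedGraph name="dosacomp_cgh_log2"\n')
        for row in track.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.start}\t{row.end}\t"
                f"{row.mean_log2:.6g}\n"
            )
    return path


def write_classification_bed(
    results: pd.DataFrame, annotation: pd.DataFrame, path: str | Path
) -> Path:
    """BED-compatible classification track; score = ratio x 1000."""
    coords = annotation.set_index("gene_id")
    path = Path(path)
    with path.open("w") as fh:
        for row in results.itertuples(index=False):
            c = coords.loc[row.gene_id]
            score = int(round(row.mean_ratio * 1000))
            fh.write(
                f"{c['chromosome']}\t{c['start']}\t{c['end']}\t"
                f"{row.gene_id}\t{score}\t{c['strand']}\t{row.comp_class}\n"
            )
    return path


# -- configuration ----------------------------------------------------------

def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cgh"] = dataclasses.asdict(config.cgh)
    return _plain(d)


def _plain(obj):
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _tuplize(value):
    if isinstance(value, list):
        return tuple(_tuplize(v) for v in value)
    return value


def config_from_dict(data: Mapping) -> SimConfig:
    data = dict(data)
    cgh = data.pop("cgh", None)
    kwargs = {k: _tuplize(v) for k, v in data.items()}
    if cgh is not None:
        kwargs["cgh"] = CghConfig(**{k: _tuplize(v) for k, v in cgh.items()})
    return SimConfig(**kwargs)


def load_config(path: str | Path) -> SimConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_config(config: SimConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))
    return path


# -- GEO series matrix ------------------------------------------------------

def read_series_matrix(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Parse a GEO series-matrix text file.

    Returns (table, metadata): the table is probes x samples with the
    ID_REF column as index; metadata maps the '!' header keys to lists of
    values.  Only the plain-text format is supported (no gzip), which is
    enough to map deposited expression-chip series onto a signal matrix.
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line[1:].partition("\t")
                values = [v.strip('"') for v in rest.split("\t")] if rest else []
                meta.setdefault(key, []).extend(values)
    if not table_lines:
        raise ValueError(f"no series-matrix table found in {path}")
    from io import StringIO

    table = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t")
    table.columns = [str(c).strip('"') for c in table.columns]
    first = table.columns[0]
    table[first] = table[first].astype(str).str.strip('"')
    return table.set_index(first), meta
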
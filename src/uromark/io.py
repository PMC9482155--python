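"""Readers and writers for the file formats the pipeline touches.

All conversions between external dialects (1-based bismark coverage,
1-based GFF3) and the internal 0-based half-open convention happen
here and nowhere else.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
import pyranges as pr

from .types import (
    CohortTable,
    DmrCandidate,
    MethylationCalls,
    TssAnnotation,
    ValidationError,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_coverage_file(
    path: PathLike, dialect: str = "bismark_cov", sample_id: str | None = None
) -> MethylationCalls:
    """Read a bismark-style coverage file into :class:`MethylationCalls`.

    The ``bismark_cov`` dialect is tab-separated with 1-based inclusive
    coordinates: chrom, start, end, methylation %, methylated count,
    unmethylated count.  The percentage column is ignored in favour of
    the raw counts; coordinates are shifted to 0-based; duplicate
    positions (e.g. strand-split extractor output) are merged by
    summing counts.
    """
    if dialect != "bismark_cov":
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    path = Path(path)
    if sample_id is None:
        sample_id = path.name
        for suffix in (".gz", ".cov", ".txt", ".tsv"):
            if sample_id.endswith(suffix):
                sample_id = sample_id[: -len(suffix)]
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start = int(fields[1])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if n_meth < 0 or n_unmeth < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative count"
                )
            records.append((fields[0], start - 1, n_meth, n_unmeth))
    return MethylationCalls.from_records(sample_id, records)


def write_coverage_file(calls: MethylationCalls, path: PathLike) -> None:
    """Write :class:`MethylationCalls` in the bismark_cov dialect
    (1-based inclusive, single-base intervals)."""
    df = calls.records
    cov = df["n_meth"] + df["n_unmeth"]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"] + 1,
            "end": df["pos"] + 1,
            "pct": (100.0 * df["n_meth"] / cov).round(6),
            "n_meth": df["n_meth"],
            "n_unmeth": df["n_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_tss(path: PathLike, format: str = "BED6") -> TssAnnotation:
    """Read gene annotations and extract strand-resolved TSS positions.

    BED6 is 0-based half-open; GFF3 is 1-based inclusive (pyranges
    converts on read).  The TSS is the interval start on '+' and
    end - 1 on '-'.  Features without a strand are rejected: a TSS is
    undefined without one.
    """
    fmt = format.upper()
    if fmt == "BED6":
        gr = pr.read_bed(str(path))
        df = gr.df
        name_col = "Name" if "Name" in df.columns else None
    elif fmt == "GFF3":
        gr = pr.read_gff3(str(path))
        df = gr.df
        name_col = next(
            (c for c in ("ID", "gene_id", "Name") if c in df.columns), None
        )
    else:
        raise ValueError(f"unknown TSS format {format!r}")
    if "Strand" not in df.columns or df["Strand"].isin(["+", "-"]).ne(True).any():
        raise ValidationError(f"{path}: feature without strand; TSS undefined")
    tss_pos = df["Start"].where(df["Strand"] == "+", df["End"] - 1)
    entries = pd.DataFrame(
        {
            "chrom": df["Chromosome"].astype(str),
            "tss_pos": tss_pos.astype(int),
            "strand": df["Strand"].astype(str),
            "gene_id": df[name_col].astype(str) if name_col else ".",
        }
    ).reset_index(drop=True)
    return TssAnnotation(entries)


def read_cohort(path: PathLike) -> CohortTable:
    """Read a tab-delimited cohort table with header columns
    sample_id, group, stage, grade, age followed by marker columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("stage", "grade"):
        if col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), None)
    return CohortTable(df)


def write_cohort(table: CohortTable, path: PathLike) -> None:
    table.rows.to_csv(path, sep="\t", index=False, na_rep="")


def write_candidates_bed(
    candidates: Iterable[DmrCandidate], path: PathLike
) -> None:
    """Write candidates as BED6 (0-based half-open); the score column
    carries the number of source windows."""
    rows = []
    for i, c in enumerate(candidates, start=1):
        rows.append(
            (c.chrom, c.start, c.end, f"dmr_{i:04d}", len(c.source_windows), ".")
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_candidates_bed(path: PathLike) -> list[DmrCandidate]:
    """Read intervals back from a candidates BED (source windows and
    TSS annotation are not round-tripped)."""
    gr = pr.read_bed(str(path))
    df = gr.df.sort_values(["Chromosome", "Start"])
    return [
        DmrCandidate(chrom=str(r.Chromosome), start=int(r.Start), end=int(r.End))
        for r in df.itertuples()
    ]


def write_report(summary: dict, path: PathLike, format: str = "json") -> None:
    """Write a flat report dict as JSON or two-column TSV."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(summary, indent=2, default=_jsonable) + "\n")
    elif format == "tsv":
        flat = _flatten(summary)
        with open(path, "w") as fh:
            for key, value in flat.items():
                fh.write(f"{key}\t{value}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _jsonable(obj):
    if hasattr(obj, "item"):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _flatten(d: dict, prefix: str = "") -> dict:
    out: dict = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, prefix=f"{key}."))
        else:
            out[key] = v
    return out
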
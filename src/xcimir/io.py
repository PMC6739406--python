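"""Readers and writers for every external table format.

Canonical dialects (documented in docs/formats.md):

* TSV, UTF-8, header row required — escape calls, symbol map, tissue table,
  target interactions, qPCR Ct values;
* GFF3 (1-based inclusive externally; 0-based half-open in memory);
* GMT for pathway gene sets;
* JSON for stage reports.

Loading is tolerant: unparseable rows are rejected with a logged warning,
unless more than half of the rows fail, in which case the file is assumed
to be the wrong one and loading aborts.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
from gffutils.feature import feature_from_line

from .models import (
    Dataset,
    DataError,
    EscapeCall,
    FormatError,
    GeneSet,
    GenomicFeature,
    Kind,
    QpcrSample,
    Strand,
    TargetInteraction,
    TissueEscapeRecord,
)

log = logging.getLogger("xcimir")

#: fraction of bad rows above which loading aborts instead of warning
MAX_BAD_ROW_FRACTION = 0.5

_GFF_KIND = {
    "gene": Kind.GENE,
    "protein_coding_gene": Kind.GENE,
    "miRNA": Kind.MIRNA,
    "pre_miRNA": Kind.MIRNA,
    "miRNA_primary_transcript": Kind.MIRNA,
}

_STRAND_IN = {"+": Strand.PLUS, "-": Strand.MINUS, ".": Strand.UNKNOWN, "?": Strand.UNKNOWN}
_STRAND_OUT = {Strand.PLUS: "+", Strand.MINUS: "-", Strand.UNKNOWN: "."}


def _read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return df


def _guard_bad_rows(path: Path | str, n_bad: int, n_total: int) -> None:
    if n_total and n_bad / n_total > MAX_BAD_ROW_FRACTION:
        raise FormatError(
            f"{path}: {n_bad}/{n_total} rows unparseable — wrong file or dialect?"
        )


def read_escape_table(path: str | Path, dialect: Dataset | str) -> list[EscapeCall]:
    """Read per-gene escape calls in either source dialect.

    Carrel-style tables need columns ``gene`` and ``n_expressing`` (optional
    ``n_lines``, default 9); cotton-style tables need ``gene`` and
    ``xi_xa_ratio``. Categories are left ``unknown``: classification is a
    separate step.
    """
    dialect = Dataset(dialect)
    value_col = "n_expressing" if dialect is Dataset.CARREL else "xi_xa_ratio"
    df = _read_tsv(path, ["gene", value_col])
    calls: list[EscapeCall] = []
    n_bad = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            if dialect is Dataset.CARREL:
                n_lines = int(getattr(row, "n_lines", 9) or 9)
                calls.append(
                    EscapeCall(
                        gene_id=row.gene,
                        dataset=dialect,
                        n_expressing=int(row.n_expressing),
                        n_lines=n_lines,
                    )
                )
            else:
                calls.append(
                    EscapeCall(
                        gene_id=row.gene,
                        dataset=dialect,
                        xi_xa_ratio=float(row.xi_xa_ratio),
                    )
                )
        except (ValueError, TypeError) as exc:
            n_bad += 1
            log.warning("%s line %d rejected: %s", path, i, exc)
    _guard_bad_rows(path, n_bad, len(df))
    return calls


def read_gff3(path: str | Path, kind_filter: Kind | str | None = None) -> list[GenomicFeature]:
    """Read gene / miRNA features from a GFF3 file.

    External 1-based inclusive coordinates are converted to internal 0-based
    half-open ones. Records whose type is not a recognized gene or miRNA
    type are skipped silently; malformed or inverted records are rejected
    with a warning.
    """
    kind_filter = Kind(kind_filter) if kind_filter is not None else None
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    feats: list[GenomicFeature] = []
    n_bad = n_rows = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        n_rows += 1
        try:
            f = feature_from_line(line)
            kind = _GFF_KIND.get(f.featuretype)
            if kind is None:
                continue
            if f.start > f.end:
                raise ValueError(f"start {f.start} > end {f.end}")
            fid = f.attributes.get("ID", f.attributes.get("Name", [None]))[0]
            if not fid:
                raise ValueError("no ID/Name attribute")
            feats.append(
                GenomicFeature(
                    feature_id=fid,
                    kind=kind,
                    chrom=f.seqid,
                    start=f.start - 1,
                    end=f.end,
                    strand=_STRAND_IN.get(f.strand, Strand.UNKNOWN),
                )
            )
        except Exception as exc:  # gffutils raises bare exceptions on bad lines
            n_bad += 1
            log.warning("%s line %d rejected: %s", path, lineno, exc)
    _guard_bad_rows(path, n_bad, n_rows)
    if kind_filter is not None:
        feats = [f for f in feats if f.kind is kind_filter]
    return feats


def write_gff3(features: Iterable[GenomicFeature], path: str | Path, source: str = "xcimir") -> None:
    """Write features back to GFF3 (1-based inclusive)."""
    typemap = {Kind.GENE: "gene", Kind.MIRNA: "miRNA"}
    lines = ["##gff-version 3"]
    for f in features:
        lines.append(
            "\t".join(
                [
                    f.chrom,
                    source,
                    typemap[f.kind],
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    _STRAND_OUT[f.strand],
                    ".",
                    f"ID={f.feature_id};Name={f.feature_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read pathway gene sets from a GMT file (name, description, members...)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path} line {lineno}: GMT needs name, description, >=1 member")
        name, members = parts[0], [g for g in parts[2:] if g]
        if name in seen:
            raise DataError(f"{path}: duplicate gene-set name {name!r}")
        seen.add(name)
        sets.append(GeneSet(name=name, members=frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, "na", *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_targets(path: str | Path) -> list[TargetInteraction]:
    """Read a validated miRNA→target interaction table.

    Columns: ``mir_id``, ``gene``, optional ``evidence``. Repeated
    (mir_id, gene) pairs are collapsed to the first occurrence.
    """
    df = _read_tsv(path, ["mir_id", "gene"])
    out: list[TargetInteraction] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.mir_id, row.gene)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            TargetInteraction(
                mir_id=row.mir_id, gene=row.gene, evidence=getattr(row, "evidence", "")
            )
        )
    return out


def read_tissue_table(path: str | Path) -> list[TissueEscapeRecord]:
    """Read the per-(gene, tissue) escape-evidence table.

    Columns: ``gene``, ``tissue``, ``expressed`` (true/false), ``logfc``
    (may be empty when not expressed).
    """
    df = _read_tsv(path, ["gene", "tissue", "expressed", "logfc"])
    records: list[TissueEscapeRecord] = []
    n_bad = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            expressed = str(row.expressed).strip().lower() in {"true", "1", "yes"}
            logfc = float(row.logfc) if str(row.logfc).strip() else None
            records.append(
                TissueEscapeRecord(
                    gene=row.gene, tissue=row.tissue, expressed=expressed, logfc=logfc
                )
            )
        except (ValueError, TypeError) as exc:
            n_bad += 1
            log.warning("%s line %d rejected: %s", path, i, exc)
    _guard_bad_rows(path, n_bad, len(df))
    return records


def read_qpcr(path: str | Path) -> list[QpcrSample]:
    """Read replicate Ct values, one row per (sample, assay, replicate).

    Columns: ``sample_id``, ``group``, ``assay``, ``replicate`` (index),
    ``ct``. A duplicated (sample, assay, replicate) triple is an error.
    """
    df = _read_tsv(path, ["sample_id", "group", "assay", "replicate", "ct"])
    seen: set[tuple[str, str, str]] = set()
    grouped: dict[tuple[str, str, str], list[float]] = {}
    for row in df.itertuples(index=False):
        key = (row.sample_id, row.assay, str(row.replicate))
        if key in seen:
            raise DataError(f"{path}: duplicate replicate {key}")
        seen.add(key)
        grouped.setdefault((row.sample_id, row.group, row.assay), []).append(float(row.ct))
    return [
        QpcrSample(sample_id=s, group=g, assay=a, ct_replicates=cts)
        for (s, g, a), cts in grouped.items()
    ]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a stage result to JSON or TSV, byte-stable for fixed input.

    JSON handles any dataclass/dict/list nesting (sets are sorted); TSV
    expects a list of flat records.
    """
    payload = _jsonable(report)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        if not isinstance(payload, list):
            raise FormatError("TSV rendering needs a list of records")
        pd.DataFrame(payload).to_csv(path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())
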
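"""Escape calling, gene-symbol normalization, and dataset reconciliation.

Two public escape-call dialects are supported:

* hybrid-line counts ("carrel"): a gene expressed in at least ``escape_min``
  of the tested human/rodent somatic-cell hybrid lines (default 7 of 9)
  escapes XCI; at most ``inactive_max`` (default 2) is inactivated;
  anything in between is a variable escaper;
* Xi/Xa ratios ("cotton"): a gene whose inactive-X expression is at least
  ``escape_ratio_min`` (default 0.10, the conventional cut-off) of its
  active-X expression escapes; otherwise it is inactivated. This dialect
  has no variable tier.

Raw identifiers from either source are normalized against an HGNC-style
symbol map (approved / alias / previous / withdrawn) before the two
escaper lists are reconciled by set algebra.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

from .models import (
    Category,
    ConfigError,
    Dataset,
    DialectError,
    EscapeCall,
    FormatError,
    MappingStatus,
    ReconcileReport,
    SymbolMapping,
)

log = logging.getLogger("xcimir")


def classify_carrel(
    call: EscapeCall, escape_min: int = 7, inactive_max: int = 2
) -> Category:
    """Classify a hybrid-line escape call.

    ``n_expressing >= escape_min`` → escape; ``<= inactive_max`` →
    inactivated; in between → variable escape. Boundaries are inclusive.
    """
    if call.dataset is not Dataset.CARREL:
        raise DialectError(f"{call.gene_id}: classify_carrel needs a carrel call")
    if not 0 <= inactive_max < escape_min <= call.n_lines:
        raise ValueError(
            f"need 0 <= inactive_max < escape_min <= n_lines "
            f"(got {inactive_max}, {escape_min}, {call.n_lines})"
        )
    if call.n_expressing >= escape_min:
        return Category.ESCAPE
    if call.n_expressing <= inactive_max:
        return Category.INACTIVATED
    return Category.VARIABLE


def classify_cotton(call: EscapeCall, escape_ratio_min: float = 0.10) -> Category:
    """Classify an Xi/Xa-ratio escape call (inclusive at the threshold)."""
    if call.dataset is not Dataset.COTTON:
        raise DialectError(f"{call.gene_id}: classify_cotton needs a cotton call")
    if not escape_ratio_min > 0:
        raise ValueError("escape_ratio_min must be > 0")
    if call.xi_xa_ratio < 0:
        raise ValueError(f"{call.gene_id}: negative Xi/Xa ratio")
    return Category.ESCAPE if call.xi_xa_ratio >= escape_ratio_min else Category.INACTIVATED


def classify_calls(
    calls: list[EscapeCall],
    escape_min: int = 7,
    inactive_max: int = 2,
    escape_ratio_min: float = 0.10,
) -> list[EscapeCall]:
    """Assign a category to every call in place (dialect dispatched per call)."""
    for call in calls:
        if call.dataset is Dataset.CARREL:
            call.category = classify_carrel(call, escape_min, inactive_max)
        else:
            call.category = classify_cotton(call, escape_ratio_min)
    return calls


class SymbolMap:
    """HGNC-style symbol lookup: approved, alias, previous, withdrawn.

    Approved symbols win over alias/previous entries with the same spelling;
    withdrawn entries resolve to nothing.
    """

    def __init__(self, entries: dict[str, tuple[MappingStatus, str | None]]):
        if not entries:
            raise ConfigError("symbol map is empty")
        self._entries = entries

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SymbolMap":
        """Load from a TSV with columns input_id, status, approved_symbol."""
        path = Path(path)
        if not path.exists():
            raise FormatError(f"{path}: no such file")
        entries: dict[str, tuple[MappingStatus, str | None]] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for col in ("input_id", "status", "approved_symbol"):
                if reader.fieldnames is None or col not in reader.fieldnames:
                    raise FormatError(f"{path}: missing mandatory column {col!r}")
            for row in reader:
                status = MappingStatus(row["status"])
                approved = row["approved_symbol"] or None
                prev = entries.get(row["input_id"])
                # approved entries take precedence over same-spelled aliases
                if prev is not None and prev[0] is MappingStatus.APPROVED:
                    continue
                entries[row["input_id"]] = (status, approved)
        return cls(entries)

    def lookup(self, raw_id: str) -> SymbolMapping:
        entry = self._entries.get(raw_id)
        if entry is None:
            return SymbolMapping(input_id=raw_id, status=MappingStatus.UNMATCHED)
        status, approved = entry
        if status is MappingStatus.WITHDRAWN:
            return SymbolMapping(input_id=raw_id, status=status)
        return SymbolMapping(input_id=raw_id, status=status, approved_symbol=approved)


def normalize_symbols(
    raw_ids: list[str], symbol_map: SymbolMap
) -> tuple[list[str], list[SymbolMapping]]:
    """Resolve raw gene identifiers to approved symbols.

    Approved, alias and previous identifiers resolve; withdrawn and
    unmatched ones are dropped. The output is deduplicated in
    first-occurrence order; two raw identifiers collapsing onto one
    approved symbol are logged and collapsed. Every input identifier gets
    exactly one entry in the mapping log.
    """
    valid: list[str] = []
    seen: set[str] = set()
    mapping_log: list[SymbolMapping] = []
    for raw in raw_ids:
        m = symbol_map.lookup(raw)
        mapping_log.append(m)
        if m.approved_symbol is None:
            continue
        if m.approved_symbol in seen:
            log.info("symbol collapse: %s -> %s (already present)", raw, m.approved_symbol)
            continue
        seen.add(m.approved_symbol)
        valid.append(m.approved_symbol)
    return valid, mapping_log


def reconcile(set_a: set[str], set_b: set[str]) -> ReconcileReport:
    """Intersect and unite two normalized escaper lists.

    The report carries all five derived sets and satisfies
    |union| = |A| + |B| - |A∩B| by construction.
    """
    set_a, set_b = set(set_a), set(set_b)
    return ReconcileReport(
        set_a=set_a,
        set_b=set_b,
        intersection=set_a & set_b,
        union=set_a | set_b,
        only_a=set_a - set_b,
        only_b=set_b - set_a,
    )
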
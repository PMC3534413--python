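"""Record-level data model for protein-interaction datasets and plain-text I/O.

The interaction dialect is a fixed 10-column TSV, a deliberately small subset
of what consolidated interaction indices (iRefIndex-style MITAB exports)
carry: an ordered interactor list, whether the record is a true binary
observation or an n-ary ("complex") one, provenance (source database,
publication, detection method), two optional interaction-confidence scores
produced by external scoring services, and a flag for computationally
predicted interactions.  Canonical protein identifiers are opaque strings;
any sequence-based canonicalisation is assumed to have happened upstream.

Missing confidence scores are a first-class state (empty field), distinct
from 0.0: a score filter cannot certify reliability for a record that was
never scored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "InteractionRecord",
    "Interactome",
    "LabelSet",
    "PathwayTable",
    "Violation",
    "ParseError",
    "ValidationError",
    "DIALECT_COLUMNS",
    "read_mitab_dialect",
    "write_mitab_dialect",
    "validate_interactome",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
]

DIALECT_COLUMNS = (
    "record_id",
    "interactors",
    "record_kind",
    "hub_index",
    "source_db",
    "pmid",
    "detection_method",
    "mi_intact",
    "mi_psicquic",
    "predicted",
)

BINARY = "binary"
COMPLEX = "complex"


class ParseError(ValueError):
    """A malformed row in an input file; the message names the line number."""


class ValidationError(ValueError):
    """Input violates a dataset-level invariant (e.g. duplicate record IDs)."""


@dataclass(frozen=True)
class InteractionRecord:
    """One database record: an observed interaction among >= 2 proteins.

    ``hub_index`` is a 0-based index into ``interactors`` naming the bait /
    hub protein of an n-ary record; ``None`` means no hub was annotated and
    the first interactor is used by convention wherever a hub is needed.
    """

    record_id: str
    interactors: tuple[str, ...]
    record_kind: str = BINARY
    hub_index: Optional[int] = None
    source_db: str = ""
    pmid: str = ""
    detection_method: str = ""
    mi_intact: Optional[float] = None
    mi_psicquic: Optional[float] = None
    predicted: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "interactors", tuple(self.interactors))

    @property
    def hub(self) -> str:
        """The hub protein: ``interactors[hub_index]``, defaulting to index 0."""
        return self.interactors[self.hub_index or 0]

    def with_fields(self, **kwargs) -> "InteractionRecord":
        return replace(self, **kwargs)


@dataclass
class Interactome:
    """A list of interaction records plus the protein universe they span."""

    records: list[InteractionRecord] = field(default_factory=list)

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for rec in self.records:
            out.update(rec.interactors)
        return out

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def by_id(self) -> dict[str, InteractionRecord]:
        return {rec.record_id: rec for rec in self.records}

    def record_ids(self) -> set[str]:
        return {rec.record_id for rec in self.records}


@dataclass
class LabelSet:
    """Named binary node labels, e.g. drug_target / disease / withdrawn_dt.

    Sets may overlap: a drug target is not necessarily a disease protein.
    """

    labels: dict[str, set[str]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> set[str]:
        return self.labels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.labels

    def get(self, name: str, default: Optional[set[str]] = None) -> Optional[set[str]]:
        return self.labels.get(name, default)

    def names(self) -> list[str]:
        return sorted(self.labels)


@dataclass
class PathwayTable:
    """Pathway membership: pathway ID -> member protein set (+ description)."""

    pathways: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for members in self.pathways.values():
            out.update(members)
        return out


@dataclass(frozen=True)
class Violation:
    record_id: str
    rule: str
    message: str


# ---------------------------------------------------------------------------
# interaction dialect I/O


def _parse_score(token: str, column: str, lineno: int) -> Optional[float]:
    if token == "":
        return None
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: {column} is not a number: {token!r}")
    if not 0.0 <= value <= 1.0:
        raise ParseError(f"line {lineno}: {column}={value} outside [0, 1]")
    return value


def _parse_row(row: Sequence[str], lineno: int) -> InteractionRecord:
    if len(row) != len(DIALECT_COLUMNS):
        raise ParseError(
            f"line {lineno}: expected {len(DIALECT_COLUMNS)} columns, got {len(row)}"
        )
    (rid, inter, kind, hub, db, pmid, method, mi_i, mi_p, pred) = row
    if not rid:
        raise ParseError(f"line {lineno}: empty record_id")
    interactors = tuple(inter.split("|")) if inter else ()
    if any(p == "" for p in interactors) or not interactors:
        raise ParseError(f"line {lineno}: empty interactor ID in {inter!r}")
    if kind not in (BINARY, COMPLEX):
        raise ParseError(f"line {lineno}: unknown record_kind {kind!r}")
    if kind == BINARY and len(interactors) != 2:
        raise ParseError(
            f"line {lineno}: binary record has {len(interactors)} interactors"
        )
    if kind == COMPLEX and len(interactors) < 3:
        raise ParseError(
            f"line {lineno}: complex record has {len(interactors)} interactors"
        )
    hub_index: Optional[int] = None
    if hub != "":
        try:
            hub_index = int(hub)
        except ValueError:
            raise ParseError(f"line {lineno}: hub_index not an integer: {hub!r}")
        if not 0 <= hub_index < len(interactors):
            raise ParseError(f"line {lineno}: hub_index {hub_index} out of range")
    if pred not in ("0", "1"):
        raise ParseError(f"line {lineno}: predicted must be 0 or 1, got {pred!r}")
    return InteractionRecord(
        record_id=rid,
        interactors=interactors,
        record_kind=kind,
        hub_index=hub_index,
        source_db=db,
        pmid=pmid,
        detection_method=method,
        mi_intact=_parse_score(mi_i, "mi_intact", lineno),
        mi_psicquic=_parse_score(mi_p, "mi_psicquic", lineno),
        predicted=pred == "1",
    )


def read_mitab_dialect(path: str | Path) -> Interactome:
    """Read the 10-column interaction dialect into an :class:`Interactome`.

    Raises :class:`ParseError` (naming the line) on malformed rows and
    :class:`ValidationError` on duplicate record IDs.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("line 1: empty file, expected header")
        if tuple(header) != DIALECT_COLUMNS:
            raise ParseError(f"line 1: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            rec = _parse_row(row, lineno)
            if rec.record_id in seen:
                raise ValidationError(
                    f"line {lineno}: duplicate record_id {rec.record_id!r}"
                )
            seen.add(rec.record_id)
            records.append(rec)
    return Interactome(records)


def _format_score(value: Optional[float]) -> str:
    return "" if value is None else repr(value)


def write_mitab_dialect(interactome: Interactome, path: str | Path) -> None:
    """Write an Interactome as the dialect TSV; read(write(X)) == X."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(DIALECT_COLUMNS)
        for rec in interactome.records:
            writer.writerow(
                [
                    rec.record_id,
                    "|".join(rec.interactors),
                    rec.record_kind,
                    "" if rec.hub_index is None else str(rec.hub_index),
                    rec.source_db,
                    rec.pmid,
                    rec.detection_method,
                    _format_score(rec.mi_intact),
                    _format_score(rec.mi_psicquic),
                    "1" if rec.predicted else "0",
                ]
            )


def validate_interactome(interactome: Interactome) -> list[Violation]:
    """Check all record-level invariants; violations are data, not exceptions."""
    out: list[Violation] = []
    seen: set[str] = set()
    for rec in interactome.records:
        rid = rec.record_id
        if rid in seen:
            out.append(Violation(rid, "unique_record_id", f"duplicate record_id {rid!r}"))
        seen.add(rid)
        n = len(rec.interactors)
        if rec.record_kind == BINARY and n != 2:
            out.append(Violation(rid, "binary_arity", f"binary record with {n} interactors"))
        elif rec.record_kind == COMPLEX and n < 3:
            out.append(Violation(rid, "complex_arity", f"complex record with {n} interactors"))
        elif rec.record_kind not in (BINARY, COMPLEX):
            out.append(Violation(rid, "record_kind", f"unknown kind {rec.record_kind!r}"))
        if any(p == "" for p in rec.interactors):
            out.append(Violation(rid, "interactor_id", "empty interactor ID"))
        if rec.hub_index is not None and not 0 <= rec.hub_index < n:
            out.append(Violation(rid, "hub_index", f"hub_index {rec.hub_index} out of range"))
        for name, score in (("mi_intact", rec.mi_intact), ("mi_psicquic", rec.mi_psicquic)):
            if score is not None and not 0.0 <= score <= 1.0:
                out.append(Violation(rid, "score_range", f"{name}={score} outside [0, 1]"))
    return out


# ---------------------------------------------------------------------------
# label and pathway files


def read_labels(path: str | Path) -> LabelSet:
    """Read a 2-column TSV ``protein_id<TAB>label_name`` into a LabelSet."""
    labels: dict[str, set[str]] = {}
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 2 or not row[0] or not row[1]:
                raise ParseError(f"line {lineno}: expected 'protein_id<TAB>label_name'")
            labels.setdefault(row[1], set()).add(row[0])
    return LabelSet(labels)


def write_labels(labels: LabelSet, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for name in sorted(labels.labels):
            for protein in sorted(labels.labels[name]):
                writer.writerow([protein, name])


def read_gmt(path: str | Path) -> PathwayTable:
    """Read GMT pathway membership (``id<TAB>description<TAB>member...``)."""
    table = PathwayTable()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: GMT row needs id, description, >=1 member")
            pid, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if pid in table.pathways:
                raise ValidationError(f"line {lineno}: duplicate pathway ID {pid!r}")
            if not members:
                raise ParseError(f"line {lineno}: pathway {pid!r} has no members")
            table.pathways[pid] = set(members)
            table.descriptions[pid] = desc
    return table


def write_gmt(table: PathwayTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for pid in sorted(table.pathways):
            desc = table.descriptions.get(pid, "")
            members = sorted(table.pathways[pid])
            fh.write("\t".join([pid, desc, *members]) + "\n")
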
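"""Sequence and table I/O.

Reads the external formats every stage consumes (FASTA for the parental
V-lambda segment, the pseudogene donor array, sequenced clones and replicated
plasmid products; a YAML architecture config for the lesion plasmids) and
writes the deterministic TSV/JSON report tables the pipeline emits.

Coordinates are 0-based half-open throughout the package; report writers add
1-based columns for human reading where relevant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO

from .errors import DataError, ParseError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str, *, where: str) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise DataError(
            f"{where}: non-ACGTN characters {sorted(bad)!r}; other IUPAC codes "
            "are rejected rather than coerced"
        )
    return seq


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusReference:
    """The parental locus every clone is compared against (0-based, half-open)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"reference {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", _validate_dna(self.sequence, where=f"reference {self.id!r}"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PseudogeneDonor:
    id: str
    sequence: str
    reverse: bool = False  # donor stored in reverse orientation relative to the parent

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_dna(self.sequence, where=f"donor {self.id!r}"))


class PseudogeneDB:
    """Ordered collection of gene-conversion donor segments with unique ids."""

    def __init__(self, donors: Iterable[PseudogeneDonor]):
        self.donors = list(donors)
        if not self.donors:
            raise DataError("pseudogene database must contain at least one donor")
        ids = [d.id for d in self.donors]
        if len(set(ids)) != len(ids):
            raise DataError("pseudogene database: duplicate donor ids")

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str]]) -> "PseudogeneDB":
        return cls(PseudogeneDonor(i, s) for i, s in records)

    def __iter__(self):
        return iter(self.donors)

    def __len__(self) -> int:
        return len(self.donors)


@dataclass
class CloneSet:
    """Sequenced V-lambda segments from one clonally expanded line."""

    reference_id: str
    clones: list[tuple[str, str]]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.clones]
        if len(set(ids)) != len(ids):
            raise DataError(f"clone set {self.label!r}: duplicate clone ids")


@dataclass
class ProductSet:
    """Replicated lesion-plasmid reads to be classified against one architecture."""

    architecture_id: str
    reads: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.reads]
        if len(set(ids)) != len(ids):
            raise DataError(f"product set {self.architecture_id!r}: duplicate read ids")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered (id, upper-case sequence) pairs.

    The id is the first whitespace-delimited header token.  Wrapped lines are
    concatenated.  Duplicate ids, empty records and non-ACGTN characters raise.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"FASTA file not found: {path}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise ParseError(f"{path}: record {idx}: empty header")
        seq = str(rec.seq).replace(" ", "").replace("-", "")
        if not seq:
            raise ParseError(f"{path}: record {idx} ({rec.id!r}): empty sequence")
        seq = _validate_dna(seq, where=f"{path} record {idx} ({rec.id!r})")
        if rec.id in seen:
            raise ParseError(f"{path}: record {idx}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Lesion-plasmid architecture config
# ---------------------------------------------------------------------------


def load_architecture(path: str | Path):
    """Load and validate a lesion-plasmid architecture from a YAML config.

    Required keys: ``id``, ``arrangement`` (staggered|opposing), ``reference``,
    ``top_site`` and ``bottom_site`` (two-int half-open intervals), ``marker``
    and ``accurate`` dinucleotides; ``spacer`` for the staggered arrangement.
    """
    from .lesionbypass import LesionPlasmidArchitecture  # local import avoids a cycle

    path = Path(path)
    if not path.exists():
        raise ParseError(f"architecture config not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - yaml's message is adequate
        raise ParseError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ParseError(f"{path}: config must be a mapping")
    required = {"id", "arrangement", "reference", "top_site", "bottom_site"}
    missing = required - set(raw)
    if missing:
        raise ParseError(f"{path}: missing keys {sorted(missing)}")
    try:
        top = (int(raw["top_site"][0]), int(raw["top_site"][1]))
        bottom = (int(raw["bottom_site"][0]), int(raw["bottom_site"][1]))
    except (TypeError, ValueError, IndexError) as exc:
        raise ParseError(f"{path}: lesion sites must be two-integer intervals") from exc
    return LesionPlasmidArchitecture(
        id=str(raw["id"]),
        arrangement=str(raw["arrangement"]),
        reference=_validate_dna(str(raw["reference"]), where=f"{path} reference"),
        top_site=top,
        bottom_site=bottom,
        marker=str(raw.get("marker", "GC")).upper(),
        accurate=str(raw.get("accurate", "AA")).upper(),
        spacer=int(raw["spacer"]) if "spacer" in raw else None,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_FLOAT_FMT = "{:.6f}"


def _fmt(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return _FLOAT_FMT.format(value)
    return str(value)


def write_report(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    fmt: str = "tsv",
    provenance: Mapping[str, object] | None = None,
    columns: Sequence[str] | None = None,
) -> None:
    """Write result rows as a TSV or JSON report.

    Output is bit-stable for identical input: fixed column order (the first
    row's key order unless ``columns`` is given), floats at fixed precision,
    sorted provenance keys.  ``provenance`` is written as ``#`` header lines
    (TSV) or under a ``"provenance"`` key (JSON).
    """
    if fmt not in ("tsv", "json"):
        raise ValueError(f"unknown report format {fmt!r}")
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    for i, row in enumerate(rows):
        if set(row.keys()) != set(columns):
            raise DataError(f"report row {i}: heterogeneous columns")
    path = Path(path)
    if fmt == "tsv":
        lines: list[str] = []
        if provenance:
            for key in sorted(provenance):
                lines.append(f"# {key}: {provenance[key]}")
        lines.append("\t".join(columns))
        for row in rows:
            lines.append("\t".join(_fmt(row[c]) for c in columns))
        path.write_text("\n".join(lines) + "\n")
    else:
        payload: dict[str, object] = {"rows": [{c: row[c] for c in columns} for row in rows]}
        if provenance:
            payload["provenance"] = {k: provenance[k] for k in sorted(provenance)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def read_report_json(path: str | Path) -> list[dict]:
    payload = json.loads(Path(path).read_text())
    return payload["rows"]
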
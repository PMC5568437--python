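"""Reading and writing sequences, metadata and tabular results.

Protein input is plain multi-record FASTA (conceptual translations are
accepted: a single trailing ``*`` stop is stripped).  Per-sequence metadata
travels in a sidecar tab-separated file rather than being packed into FASTA
headers, keeping the FASTA standard-compliant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: residues accepted after normalization: the 20 standard amino acids plus
#: the ambiguity codes X, B and Z (which never participate in motif matching)
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY") | frozenset("XBZ")

WEB_ARCHITECTURES = ("orb", "cobweb", "sheet", "none", "unknown")

METADATA_COLUMNS = ("species", "family", "spidroin_label", "web_architecture")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA or metadata input."""


@dataclass
class SequenceRecord:
    """One protein sequence plus optional biological metadata.

    ``residues`` is an uppercase amino-acid string; ``metadata`` may carry
    species, family, spidroin_label and web_architecture keys.
    """

    id: str
    description: str = ""
    residues: str = ""
    metadata: dict | None = None

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str, entry_id: str = "<sequence>") -> str:
    """Uppercase, strip whitespace/digits and a single trailing stop.

    Raises :class:`FastaFormatError` on characters outside the amino-acid
    alphabet (``J``, ``O``, ``U`` and non-letters are rejected).
    """
    cleaned = "".join(c for c in raw if not c.isspace() and not c.isdigit())
    cleaned = cleaned.upper()
    if cleaned.endswith("*"):
        cleaned = cleaned[:-1]
    if not cleaned:
        raise FastaFormatError(f"entry {entry_id!r} has an empty sequence")
    bad = sorted(set(cleaned) - ALLOWED_RESIDUES)
    if bad:
        raise FastaFormatError(
            f"entry {entry_id!r} contains invalid residue(s) {''.join(bad)!r}"
        )
    return cleaned


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Load a multi-record FASTA file into :class:`SequenceRecord` objects.

    Records come back in file order with residues normalized.  An entry with
    an empty sequence, or a duplicated identifier, is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(entry.seq), entry.id or "<unnamed>")
        if entry.id in seen:
            raise FastaFormatError(f"duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        records.append(
            SequenceRecord(id=entry.id, description=entry.description, residues=residues)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping residues at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


@dataclass
class MetadataTable:
    """Per-sequence annotations keyed by sequence id.

    ``rows[id]`` maps column name to value.  ``web_architecture`` is always
    one of :data:`WEB_ARCHITECTURES`; ids absent from the table are treated
    as ``unknown``.  Optional ``rep_start``/``rep_end`` columns (1-based
    inclusive in the file) supply user repetitive-domain bounds, exposed via
    :meth:`domain_bounds` as 0-based half-open coordinates.
    """

    rows: dict[str, dict] = field(default_factory=dict)

    def architecture(self, seq_id: str) -> str:
        row = self.rows.get(seq_id)
        if row is None:
            return "unknown"
        return row.get("web_architecture", "unknown")

    def get(self, seq_id: str) -> dict:
        return self.rows.get(seq_id, {})

    def domain_bounds(self, seq_id: str) -> tuple[int, int] | None:
        row = self.rows.get(seq_id)
        if not row:
            return None
        start, end = row.get("rep_start"), row.get("rep_end")
        if start is None or end is None:
            return None
        return int(start) - 1, int(end)  # 1-based inclusive -> 0-based half-open


def read_metadata(path: str | Path) -> MetadataTable:
    """Parse a tab-separated metadata file with at least an ``id`` column.

    Unrecognized web-architecture strings are mapped to ``unknown`` with a
    logged warning; a missing id column or duplicate ids are format errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FastaFormatError(f"{path}: empty metadata file")
        header = header_line.split("\t")
        if "id" not in header:
            raise FastaFormatError(f"{path}: metadata file lacks an 'id' column")
        rows: dict[str, dict] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            values = line.split("\t")
            row = dict(zip(header, values))
            seq_id = row.pop("id", "").strip()
            if not seq_id:
                raise FastaFormatError(f"{path}:{lineno}: row without id")
            if seq_id in rows:
                raise FastaFormatError(f"{path}: duplicate metadata id {seq_id!r}")
            arch = row.get("web_architecture", "unknown").strip().lower() or "unknown"
            if arch not in WEB_ARCHITECTURES:
                logger.warning(
                    "metadata id %s: unrecognized web_architecture %r mapped to 'unknown'",
                    seq_id,
                    arch,
                )
                arch = "unknown"
            row["web_architecture"] = arch
            rows[seq_id] = row
    return MetadataTable(rows=rows)


def _format_value(value) -> object:
    if isinstance(value, bool):
        return value
    if isinstance(value, float):
        return f"{value:.4f}"
    return value


def write_table(
    rows: Sequence[Mapping],
    path: str | Path,
    format: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Write result rows as TSV or JSON with deterministic column order.

    Column order follows the first row's key order (or an explicit
    ``columns`` schema, which also lets an empty row list produce a
    header-only file); floats are rendered with four decimal places.
    """
    path = Path(path)
    rows = list(rows)
    if columns is None:
        columns = []
        for row in rows:
            for key in row:
                if key not in columns:
                    columns.append(key)
    else:
        columns = list(columns)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(columns) + "\n")
            for row in rows:
                fh.write(
                    "\t".join(str(_format_value(row.get(c, ""))) for c in columns) + "\n"
                )
    elif format == "json":
        payload = [
            {c: _format_value(row.get(c)) for c in columns if c in row} for row in rows
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown table format {format!r}")
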
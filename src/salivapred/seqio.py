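"""Reading and writing the plain-text formats the pipeline touches.

FASTA goes through Biopython; annotation tables and all tabular outputs are
tab-separated text with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import AA_SET

log = logging.getLogger(__name__)

#: residue-handling policies for read_fasta
POLICIES = ("reject", "strip")


@dataclass
class Annotations:
    """Optional per-protein evidence used for training-set construction."""

    family_ids: list[str] = field(default_factory=list)
    saliva_evidence: bool = False
    peptide_count: int = 0

    def __post_init__(self) -> None:
        if self.peptide_count < 0:
            raise ValueError("peptide_count must be non-negative")


@dataclass
class ProteinRecord:
    """An accession plus a validated canonical amino-acid sequence."""

    id: str
    sequence: str
    annotations: Annotations | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        bad = set(self.sequence) - AA_SET
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical residue(s) {sorted(bad)} in sequence"
            )


def read_fasta(path: str | Path, policy: str = "reject") -> list[ProteinRecord]:
    """Parse a FASTA file into validated records.

    The id is the header token before the first whitespace; sequences are
    uppercased. ``policy`` controls non-canonical residues: ``"reject"``
    raises, ``"strip"`` silently removes them.
    """
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        seq = str(entry.seq).upper()
        bad = set(seq) - AA_SET
        if bad:
            if policy == "reject":
                raise ValueError(
                    f"{path}: record {rid!r} contains non-canonical residue(s) "
                    f"{sorted(bad)}; rerun with the relaxed policy to strip them"
                )
            seq = "".join(c for c in seq if c in AA_SET)
        records.append(ProteinRecord(id=rid, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    entries = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(entries)


def read_annotations(path: str | Path) -> dict[str, Annotations]:
    """Read the per-protein annotation TSV (id, family_ids, saliva_evidence,
    peptide_count); family ids are semicolon-separated, missing optional
    fields default to empty/false/0."""
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty annotation file")
        header = header_line.rstrip("\n").split("\t")
        if "id" not in header:
            raise ValueError(f"{path}: annotation header must contain an 'id' column")
        col = {name: i for i, name in enumerate(header)}
        out: dict[str, Annotations] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                rid = fields[col["id"]]
                fam_raw = fields[col["family_ids"]] if "family_ids" in col else ""
                families = [f for f in fam_raw.split(";") if f]
                sal_raw = fields[col["saliva_evidence"]] if "saliva_evidence" in col else "0"
                if sal_raw not in ("0", "1", ""):
                    raise ValueError(f"saliva_evidence must be 0/1, got {sal_raw!r}")
                pep_raw = fields[col["peptide_count"]] if "peptide_count" in col else "0"
                peptides = int(pep_raw) if pep_raw else 0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if not rid:
                raise ValueError(f"{path}:{lineno}: empty id")
            out[rid] = Annotations(
                family_ids=families,
                saliva_evidence=sal_raw == "1",
                peptide_count=peptides,
            )
    return out


def attach_annotations(
    records: Sequence[ProteinRecord], annotations: Mapping[str, Annotations]
) -> list[ProteinRecord]:
    """Return records with annotations attached where available."""
    out = []
    for r in records:
        ann = annotations.get(r.id)
        out.append(ProteinRecord(r.id, r.sequence, ann))
    return out


def _format_cell(value) -> str:
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, ".8g")
    return str(value)


def write_table(rows: Sequence[Sequence], path: str | Path) -> None:
    """Write rectangular rows (first row = header) as newline-terminated TSV."""
    rows = list(rows)
    if not rows:
        raise ValueError("write_table requires at least a header row")
    width = len(rows[0])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, row in enumerate(rows):
            if len(row) != width:
                raise ValueError(f"row {i} has {len(row)} fields, expected {width}")
            fh.write("\t".join(_format_cell(v) for v in row) + "\n")


def read_table(path: str | Path) -> list[list[str]]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line != "\n"]
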
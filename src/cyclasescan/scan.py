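"""Proteome scanning: FASTA I/O, candidate tables, protein statistics,
TSV/GFF3 report writers.

All coordinates in this module are 1-based inclusive protein-residue
coordinates, the convention used when citing residues such as S1053 or
M1066 of a receptor kinase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import (
    CANONICAL_SET,
    MetalBindingResult,
    MotifMatch,
    MotifPattern,
    check_metal_binding,
    find_matches,
    score_match,
)

logger = logging.getLogger(__name__)

# Standard average (isotope-abundance-weighted) residue masses in daltons,
# i.e. the mass each amino acid contributes inside a peptide chain.  Add one
# water (18.0153 Da) for the free peptide.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}
WATER_MASS = 18.0153


class FastaFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: identifier, free-text description, residue string."""

    id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class ProteinStats:
    length: int
    average_mass: float  # daltons


@dataclass
class CandidateRow:
    seq_id: str
    match: MotifMatch
    protein_length: int
    fragment_mass: float | None = None  # Da; None if non-canonical residues


@dataclass
class CandidateTable:
    rows: list

    def __len__(self):
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([_row_dict(r) for r in self.rows], columns=_TSV_COLUMNS)


def read_fasta(path) -> list:
    """Read a protein multi-FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased, whitespace-joined across wrapped lines, and a
    single trailing ``*`` (stop) is stripped.  Duplicate identifiers, empty
    sequences, non-alphabetic residues and non-FASTA leading content are
    rejected with descriptive errors.
    """
    with open(path) as fh:
        lead = fh.read(4096).lstrip()
        if lead and not lead.startswith(">"):
            raise FastaFormatError(
                f"{path}: not FASTA (first non-blank character is {lead[0]!r})"
            )
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        if not seq.isalpha():
            bad = next(c for c in seq if not c.isalpha())
            raise FastaFormatError(
                f"{path}: record {rec.id!r} contains non-alphabetic character {bad!r}"
            )
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(ProteinRecord(id=rec.id, description=desc, sequence=seq))
    if not records and lead:
        raise FastaFormatError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as FASTA, sequences wrapped at ``width`` columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def protein_stats(record: ProteinRecord, residue_range=None) -> ProteinStats:
    """Length and average molecular mass of a protein or 1-based inclusive
    fragment ``(start, end)``.

    Mass is the sum of standard average residue masses plus one water;
    non-canonical residues in the range make the mass undefined and raise.
    """
    seq = record.sequence
    if residue_range is None:
        start, end = 1, len(seq)
    else:
        start, end = residue_range
    if start < 1 or end > len(seq):
        raise ValueError(
            f"range {start}..{end} outside sequence of length {len(seq)}"
        )
    if start > end:
        raise ValueError(f"empty range {start}..{end} (start > end)")
    fragment = seq[start - 1 : end]
    mass = WATER_MASS
    for i, res in enumerate(fragment, start=start):
        if res not in CANONICAL_SET:
            raise ValueError(
                f"non-canonical residue {res!r} at position {i}: mass undefined"
            )
        mass += AVERAGE_RESIDUE_MASS[res]
    return ProteinStats(length=end - start + 1, average_mass=mass)


def _fragment_mass_or_none(fragment: str) -> float | None:
    if any(r not in CANONICAL_SET for r in fragment):
        return None
    return WATER_MASS + sum(AVERAGE_RESIDUE_MASS[r] for r in fragment)


def _metal_anchor(match: MotifMatch) -> int:
    # expanded position 14 when the match spans it, else the match end
    return match.start + 13 if match.length >= 14 else match.end


def scan_proteome(
    records,
    patterns,
    max_mismatch: int = 0,
    all_expansions: bool = False,
    require_metal: bool = False,
) -> CandidateTable:
    """Run every pattern over every record and assemble a candidate table.

    Each match gets the downstream [D/E] metal-binding check anchored at
    expanded motif position 14 and a composite score.  Rows lacking the
    metal residue are dropped when ``require_metal``.  Row order is
    (record order, start, pattern name) so outputs are diffable.
    """
    if not patterns:
        raise ValueError("patterns must be nonempty")
    rows = []
    for record in records:
        record_rows = []
        for pattern in patterns:
            for m in find_matches(
                pattern,
                record.sequence,
                max_mismatch=max_mismatch,
                all_expansions=all_expansions,
                seq_id=record.id,
            ):
                try:
                    m.metal = check_metal_binding(record.sequence, _metal_anchor(m))
                except IndexError:
                    m.metal = MetalBindingResult(found=False)
                m.score = score_match(m.diagnostics, m.metal)
                if require_metal and not m.metal.found:
                    continue
                record_rows.append(
                    CandidateRow(
                        seq_id=record.id,
                        match=m,
                        protein_length=len(record.sequence),
                        fragment_mass=_fragment_mass_or_none(m.matched),
                    )
                )
        record_rows.sort(key=lambda r: (r.match.start, r.match.length, r.match.pattern_name))
        logger.debug("%s: %d candidate(s)", record.id, len(record_rows))
        rows.extend(record_rows)
    logger.info(
        "scanned %d record(s) with %d pattern(s): %d candidate row(s)",
        len(list(records)) if not hasattr(records, "__len__") else len(records),
        len(patterns),
        len(rows),
    )
    return CandidateTable(rows=rows)


_TSV_COLUMNS = [
    "seq_id",
    "pattern",
    "start",
    "end",
    "matched_seq",
    "mismatches",
    "constrained_satisfied",
    "metal_offset",
    "metal_residue",
    "score",
    "protein_length",
]


def _row_dict(row: CandidateRow) -> dict:
    m = row.match
    metal = m.metal or MetalBindingResult(found=False)
    return {
        "seq_id": row.seq_id,
        "pattern": m.pattern_name,
        "start": m.start,
        "end": m.end,
        "matched_seq": m.matched,
        "mismatches": m.diagnostics.mismatch_count,
        "constrained_satisfied": (
            f"{m.diagnostics.n_satisfied_constrained}/{m.diagnostics.n_constrained}"
        ),
        "metal_offset": metal.offset if metal.found else "",
        "metal_residue": metal.residue if metal.found else "",
        "score": f"{(m.score if m.score is not None else 0.0):.6f}",
        "protein_length": row.protein_length,
    }


def write_tsv(table: CandidateTable, path) -> None:
    """Write a candidate table as TSV (header always present)."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False)


def write_gff3(table: CandidateTable, path, source: str = "cyclasescan") -> None:
    """Write candidates as GFF3 ``polypeptide_motif`` features.

    Coordinates are 1-based inclusive per the GFF3 standard; attributes carry
    the pattern name, mismatch count and metal offset (``.`` when absent).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in table.rows:
            m = row.match
            metal = m.metal or MetalBindingResult(found=False)
            attrs = (
                f"Name={m.pattern_name};mismatches={m.diagnostics.mismatch_count};"
                f"metal_offset={metal.offset if metal.found else '.'}"
            )
            fields = [
                row.seq_id,
                source,
                "polypeptide_motif",
                str(m.start),
                str(m.end),
                f"{(m.score if m.score is not None else 0.0):.6f}",
                ".",
                ".",
                attrs,
            ]
            fh.write("\t".join(fields) + "\n")


def read_tsv(path) -> pd.DataFrame:
    """Re-read a TSV report (round-trip helper)."""
    return pd.read_csv(
        path, sep="\t", dtype={"metal_offset": "object", "metal_residue": "object"}
    )
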
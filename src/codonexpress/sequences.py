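"""Coding-sequence and expression-record types.

A dataset here is a set of synonymous codon encodings of one protein:
every record is an in-frame DNA (or RNA) sequence of identical length,
paired with a measured expression level and, optionally, precomputed
minimum-free-energy (MFE) covariates. Sequences are normalized to
uppercase DNA (U -> T) on construction; anything outside {A,C,G,T}
is a hard error — these are designed constructs, not reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "CodingSequence",
    "ExpressionRecord",
    "InvalidSequenceError",
    "DatasetError",
    "standard_genetic_code",
    "synonymous_groups",
    "read_fasta",
    "read_expression_table",
    "read_dataset",
    "write_fasta",
    "write_expression_table",
]

_VALID = frozenset("ACGT")


class InvalidSequenceError(ValueError):
    """A sequence violates the coding-sequence invariants."""


class DatasetError(ValueError):
    """Sequences and expression records cannot be aligned."""


def normalize_nucleotides(raw: str) -> str:
    """Uppercase and convert RNA to DNA (U -> T); reject anything else."""
    seq = raw.strip().upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise InvalidSequenceError(
            f"invalid characters {sorted(bad)} in sequence (only A/C/G/T/U allowed)"
        )
    return seq


@dataclass(frozen=True)
class CodingSequence:
    """One codon encoding of a protein: identifier + in-frame nucleotides.

    The nucleotide string is read in frame from position 1; its length
    must be a positive multiple of 3.
    """

    identifier: str
    nucleotides: str

    def __post_init__(self) -> None:
        norm = normalize_nucleotides(self.nucleotides)
        object.__setattr__(self, "nucleotides", norm)
        if len(norm) == 0 or len(norm) % 3 != 0:
            raise InvalidSequenceError(
                f"{self.identifier!r}: length {len(norm)} is not a positive multiple of 3"
            )

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codons(self) -> list[str]:
        s = self.nucleotides
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def translate(self, code: Mapping[str, str] | None = None) -> str:
        """Amino-acid string under ``code`` (stops rendered as '*')."""
        code = standard_genetic_code() if code is None else code
        return "".join(code[c] for c in self.codons())


@dataclass(frozen=True)
class ExpressionRecord:
    """Measured expression (arbitrary, protein-specific units) plus optional MFE covariates.

    ``mfe_whole`` is the folding minimum free energy of the whole mRNA,
    ``mfe_window`` that of a short 5' window (both kcal/mol); either may be
    absent when the feature configuration does not request it. Expression
    must be positive so absolute percentage errors are defined.
    """

    identifier: str
    expression: float
    mfe_whole: float | None = None
    mfe_window: float | None = None

    def __post_init__(self) -> None:
        if not self.expression > 0:
            raise ValueError(
                f"{self.identifier!r}: expression must be positive, got {self.expression}"
            )


def standard_genetic_code() -> dict[str, str]:
    """Codon -> amino-acid map for the NCBI standard code (table 1).

    The three stop codons map to '*', forming a single synonymous group.
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


def synonymous_groups(code: Mapping[str, str]) -> dict[str, list[str]]:
    """Amino acid -> sorted list of its synonymous codons."""
    groups: dict[str, list[str]] = {}
    for codon, aa in code.items():
        groups.setdefault(aa, []).append(codon)
    return {aa: sorted(cs) for aa, cs in groups.items()}


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read coding sequences; the identifier is the first token of the header."""
    seqs = [
        CodingSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique([s.identifier for s in seqs], str(path))
    return seqs


def write_fasta(path: str | Path, seqs: Iterable[CodingSequence]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.identifier}\n{s.nucleotides}\n")


def read_expression_table(path: str | Path) -> tuple[list[ExpressionRecord], list[CodingSequence] | None]:
    """Read a CSV with columns id, [sequence], expression, [mfe_whole], [mfe_window].

    Returns the expression records and, when a ``sequence`` column is present,
    the coding sequences parsed from it (otherwise None).
    """
    df = pd.read_csv(path)
    required = {"id", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetError(f"{path}: missing required columns {sorted(missing)}")
    _check_unique(df["id"].astype(str).tolist(), str(path))
    records = []
    for _, row in df.iterrows():
        records.append(
            ExpressionRecord(
                identifier=str(row["id"]),
                expression=float(row["expression"]),
                mfe_whole=_opt_float(row, "mfe_whole"),
                mfe_window=_opt_float(row, "mfe_window"),
            )
        )
    seqs = None
    if "sequence" in df.columns:
        seqs = [
            CodingSequence(str(row["id"]), str(row["sequence"]))
            for _, row in df.iterrows()
        ]
    return records, seqs


def write_expression_table(path: str | Path, records: Iterable[ExpressionRecord]) -> None:
    rows = [
        {
            "id": r.identifier,
            "expression": r.expression,
            "mfe_whole": r.mfe_whole,
            "mfe_window": r.mfe_window,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dataset(
    table_path: str | Path, fasta_path: str | Path | None = None
) -> tuple[list[CodingSequence], list[ExpressionRecord]]:
    """Load and align sequences with expression records, preserving table row order.

    Sequences come from ``fasta_path`` when given, else from the table's
    ``sequence`` column. Identifiers must match one-to-one.
    """
    records, table_seqs = read_expression_table(table_path)
    if fasta_path is not None:
        seqs = read_fasta(fasta_path)
    elif table_seqs is not None:
        seqs = table_seqs
    else:
        raise DatasetError(
            f"{table_path}: no 'sequence' column and no FASTA file supplied"
        )
    by_id = {s.identifier: s for s in seqs}
    missing = [r.identifier for r in records if r.identifier not in by_id]
    if missing:
        raise DatasetError(f"identifiers in table but not in sequences: {missing}")
    extra = set(by_id) - {r.identifier for r in records}
    if extra:
        raise DatasetError(f"identifiers in sequences but not in table: {sorted(extra)}")
    aligned = [by_id[r.identifier] for r in records]
    lengths = {s.n_codons for s in aligned}
    if len(lengths) > 1:
        raise DatasetError(
            f"all sequences must share one length; found codon counts {sorted(lengths)}"
        )
    return aligned, records


def _opt_float(row: pd.Series, col: str) -> float | None:
    if col not in row.index:
        return None
    v = row[col]
    if pd.isna(v):
        return None
    return float(v)


def _check_unique(ids: list[str], where: str) -> None:
    seen: set[str] = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})
    if dups:
        raise DatasetError(f"{where}: duplicate identifiers {dups}")
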
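"""Multiple sequence alignment container and family-level admission checks.

Columns are 0-based internally; every report written to disk uses 1-based
positions (the alignment-position convention).  The residue alphabet after
normalisation is the 20 standard amino acids plus ``-`` (gap) and ``X``
(unknown); ambiguity codes B, Z, J and the rare U/O are collapsed to ``X``
because they carry no covariation signal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + GAP + UNKNOWN

#: integer codes: 0..19 amino acids, 20 gap, 21 unknown
GAP_CODE = 20
UNKNOWN_CODE = 21

_CODE = {c: i for i, c in enumerate(ALPHABET)}
_REMAP = str.maketrans(
    {".": "-", "B": "X", "Z": "X", "J": "X", "U": "X", "O": "X", "*": "X"}
)


class AlignmentError(ValueError):
    """Raised for malformed or empty alignment input."""


def _normalize_row(seq: str) -> str:
    return seq.upper().translate(_REMAP)


@dataclass
class Alignment:
    """An aligned protein family: ``N`` sequences by ``L`` columns."""

    ids: list[str]
    rows: list[str]
    _codes: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no sequences")
        L = len(self.rows[0])
        if L == 0:
            raise AlignmentError("alignment has zero columns")
        norm = []
        for rid, row in zip(self.ids, self.rows):
            row = _normalize_row(row)
            if len(row) != L:
                raise AlignmentError(
                    f"ragged alignment: sequence {rid!r} has length "
                    f"{len(row)}, expected {L}"
                )
            bad = set(row) - set(ALPHABET)
            if bad:
                raise AlignmentError(f"illegal characters {bad!r} in {rid!r}")
            if row.count(GAP) == L:
                raise AlignmentError(f"sequence {rid!r} is all gaps")
            norm.append(row)
        self.rows = norm

    @property
    def N(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    @property
    def codes(self) -> np.ndarray:
        """(N, L) uint8 matrix; 0..19 residues, 20 gap, 21 unknown."""
        if self._codes is None:
            arr = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            ).reshape(self.N, self.L)
            lut = np.zeros(128, dtype=np.uint8)
            for ch, i in _CODE.items():
                lut[ord(ch)] = i
            self._codes = lut[arr]
        return self._codes

    def column(self, col: int) -> str:
        if not 0 <= col < self.L:
            raise IndexError(f"column {col} out of range [0, {self.L})")
        return "".join(row[col] for row in self.rows)

    def row_for(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None


@dataclass
class FamilyRecord:
    """One protein family: alignment plus its structural representative."""

    family_id: str
    alignment: Alignment
    representative_id: str
    structure_path: Optional[Path] = None
    chain: str = "A"
    go_labels: Optional[set[tuple[str, str]]] = None

    def __post_init__(self) -> None:
        if self.representative_id not in self.alignment.ids:
            raise ValueError(
                f"representative {self.representative_id!r} not in alignment"
            )


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read an alignment from ``path`` in ``fasta`` or ``stockholm`` format."""
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if path.stat().st_size == 0:
        raise AlignmentError(f"{path} is empty")
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise AlignmentError(f"no sequences parsed from {path}")
    return Alignment(
        ids=[r.id for r in records], rows=[str(r.seq) for r in records]
    )


def write_alignment(a: Alignment, path, format: str = "fasta") -> None:
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format {format!r}")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(a.ids, a.rows)
    )
    AlignIO.write(msa, str(path), format)


@dataclass
class ValidationReport:
    family_id: str
    N: int
    L: int
    passed: bool
    reasons: list[str]


def validate_family(
    a: Alignment,
    min_length: int = 100,
    min_sequences: int = 51,
    family_id: str = "",
) -> ValidationReport:
    """Admission check: alignment length >= 100 columns and > 50 sequences."""
    reasons = []
    if a.L < min_length:
        reasons.append("length")
    if a.N < min_sequences:
        reasons.append("depth")
    return ValidationReport(family_id, a.N, a.L, not reasons, reasons)


def gapless_columns(a: Alignment) -> set[int]:
    """Columns with no gap character in any sequence."""
    return set(np.nonzero(~(a.codes == GAP_CODE).any(axis=0))[0].tolist())


def column_gap_fraction(a: Alignment, col: int) -> float:
    if not 0 <= col < a.L:
        raise IndexError(f"column {col} out of range [0, {a.L})")
    return float((a.codes[:, col] == GAP_CODE).mean())


def write_validation_report(
    reports: Iterable[ValidationReport], path
) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tN\tL\tpass\treasons\n")
        for r in reports:
            fh.write(
                f"{r.family_id}\t{r.N}\t{r.L}\t{int(r.passed)}\t"
                f"{','.join(r.reasons)}\n"
            )
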
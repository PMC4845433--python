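"""Reading and validating protein sequences, pair lists and feature matrices.

Proteins come in as FASTA over the standard 20-letter amino-acid alphabet;
labelled pairs come in as two/three-column delimited text (id_a, id_b,
label in {0,1}); feature matrices go out as plain CSV so they can be
inspected or fed back in without re-encoding.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Symbols that occur in real databases but are outside the 20-letter
#: alphabet (ambiguity codes, selenocysteine/pyrrolysine, stops, gaps).
NONSTANDARD = frozenset("BJOUXZ*-.")

#: How to handle nonstandard residues: remove the symbols, drop the whole
#: record, or refuse the file.
POLICIES = ("strip", "reject-record", "error")


class SequenceError(ValueError):
    """A sequence violates the amino-acid alphabet contract."""


class PairValidationError(ValueError):
    """A pair list references unknown proteins or has malformed labels."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier with its validated amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise SequenceError(
                f"protein {self.id!r}: non-alphabet symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairRecord:
    """An ordered protein pair with its interaction label (1/0)."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise PairValidationError(
                f"pair ({self.id_a}, {self.id_b}): label must be 0 or 1, "
                f"got {self.label!r}"
            )


def sanitize(sequence: str, policy: str = "strip") -> str | None:
    """Uppercase a raw sequence and apply the nonstandard-residue policy.

    Returns the cleaned sequence, or None when policy == "reject-record"
    and the sequence contains nonstandard symbols.  Idempotent.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    seq = sequence.upper().replace(" ", "").replace("\n", "")
    bad = set(seq) - _AA_SET
    if not bad:
        return seq
    unknown = bad - NONSTANDARD
    if unknown:
        raise SequenceError(f"symbols {sorted(unknown)} are not amino-acid codes")
    if policy == "error":
        raise SequenceError(f"nonstandard residues {sorted(bad)} present")
    if policy == "reject-record":
        return None
    return "".join(c for c in seq if c in _AA_SET)


def read_fasta(
    path: str | Path,
    min_length: int = 1,
    policy: str = "strip",
) -> list[ProteinRecord]:
    """Load protein records from a FASTA file.

    Records shorter than ``min_length`` (after sanitization) are dropped;
    nonstandard residues are handled per ``policy``.  Counts of affected
    records are reported through a warning and the module logger.

    Raises FileNotFoundError for a missing file and SequenceError when the
    file yields no usable record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_nonstandard = 0
    n_short = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        cleaned = sanitize(raw, policy=policy)
        if cleaned is None:  # reject-record policy
            n_nonstandard += 1
            continue
        if len(cleaned) != len(raw.replace(" ", "")):
            n_nonstandard += 1
        if len(cleaned) < min_length or not cleaned:
            n_short += 1
            continue
        if rec.id in seen:
            raise SequenceError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=cleaned))
    if n_nonstandard or n_short:
        msg = (
            f"{path.name}: {n_nonstandard} record(s) with nonstandard residues "
            f"(policy={policy}), {n_short} record(s) below min_length={min_length}"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not records:
        raise SequenceError(f"no usable protein records in {path}")
    return records


def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_pairs(
    path: str | Path,
    proteins: Iterable[ProteinRecord],
) -> list[PairRecord]:
    """Load labelled pairs from delimited text (id_a, id_b, label).

    Tab or comma delimited, auto-detected from the first line; an optional
    header row is detected by a non-numeric third column.  Every id must
    resolve to a loaded protein.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pair file not found: {path}")
    known = {p.id for p in proteins}
    pairs: list[PairRecord] = []
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        warnings.warn(f"{path.name}: empty pair file", stacklevel=2)
        return pairs
    delim = _detect_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    start = 0
    if (
        rows
        and len(rows[0]) >= 3
        and not rows[0][2].strip().lstrip("+-").isdigit()
        and rows[0][0].strip() not in known
    ):
        start = 1  # header row
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 3:
            raise PairValidationError(f"{path.name} line {i}: expected 3 columns")
        id_a, id_b, raw_label = (c.strip() for c in row[:3])
        for pid in (id_a, id_b):
            if pid not in known:
                raise PairValidationError(
                    f"{path.name} line {i}: unknown protein id {pid!r}"
                )
        try:
            label = int(raw_label)
        except ValueError:
            raise PairValidationError(
                f"{path.name} line {i}: malformed label {raw_label!r}"
            ) from None
        pairs.append(PairRecord(id_a=id_a, id_b=id_b, label=label))
    return pairs


def write_pairs(pairs: Sequence[PairRecord], path: str | Path) -> None:
    """Write pairs as tab-separated id_a, id_b, label."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")


def write_fasta(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA."""
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n{p.sequence}\n")


def write_feature_matrix(
    matrix: np.ndarray,
    path: str | Path,
    labels: Sequence[int] | None = None,
) -> None:
    """Write one sample per row as CSV, optionally with a final label column.

    Values are written with 17 significant digits so a read-back reproduces
    the float64 matrix exactly.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValueError("feature matrix must be a non-empty 2-D array")
    if labels is not None:
        labels = np.asarray(labels, dtype=float).reshape(-1, 1)
        if labels.shape[0] != matrix.shape[0]:
            raise ValueError("labels length must match number of rows")
        matrix = np.hstack([matrix, labels])
    np.savetxt(path, matrix, delimiter=",", fmt="%.17g")


def read_feature_matrix(
    path: str | Path,
    has_labels: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a CSV feature matrix; returns (matrix, labels-or-None)."""
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if has_labels:
        return data[:, :-1], data[:, -1].astype(int)
    return data, None
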
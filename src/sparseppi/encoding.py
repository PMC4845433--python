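"""Global encoding (GE) of amino-acid sequences, plus the 2-mer baseline.

The descriptor reduces the 20 amino acids to six physicochemical classes
(aliphatic, aromatic, polar, positive, negative, special conformations),
binarizes the sequence under the ten possible 3-vs-3 class splits that keep
the aliphatic class positive, prefix-partitions each binary "characteristic
sequence" into L nested subsequences, and summarizes every subsequence by
its composition (fraction of 0s and 1s) and transition (number of adjacent
bit switches).  A protein becomes a 10*L*3 vector (150 at the default L=5);
a pair of proteins is the concatenation of its two protein vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seq_io import AMINO_ACIDS, ProteinRecord

#: Six physicochemical amino-acid classes.  Histidine goes with the
#: positively charged residues (the classic basic / exchange-group
#: placement); without it the six classes would cover only 19 residues.
CLASSES: dict[int, frozenset[str]] = {
    1: frozenset("AVLIMC"),   # aliphatic
    2: frozenset("FWY"),      # aromatic
    3: frozenset("STNQ"),     # polar
    4: frozenset("KRH"),      # positively charged
    5: frozenset("DE"),       # negatively charged
    6: frozenset("GP"),       # special conformations
}

_CLASS_OF: dict[str, int] = {
    aa: c for c, members in CLASSES.items() for aa in members
}

#: The ten canonical transformation modes: positive class triples, in the
#: fixed enumeration order that makes feature vectors reproducible.
MODES: tuple[frozenset[int], ...] = tuple(
    frozenset(t)
    for t in [
        (1, 2, 3), (1, 2, 4), (1, 2, 5), (1, 2, 6),
        (1, 3, 4), (1, 3, 5), (1, 3, 6),
        (1, 4, 5), (1, 4, 6),
        (1, 5, 6),
    ]
)

#: All 400 ordered residue pairs in lexicographic order (2-mer baseline).
DIMERS: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)
_DIMER_INDEX = {d: i for i, d in enumerate(DIMERS)}


@dataclass(frozen=True)
class CharacteristicSequence:
    """Binary sequence of one protein under one transformation mode."""

    bits: str
    mode_index: int  # 1-based, into MODES
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.bits)


def classify_residue(symbol: str) -> int:
    """Return the physicochemical class index (1..6) of an amino acid."""
    try:
        return _CLASS_OF[symbol]
    except KeyError:
        raise ValueError(
            f"{symbol!r} is not a standard amino-acid symbol"
        ) from None


def _class_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([_CLASS_OF[c] for c in sequence], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"{e.args[0]!r} is not a standard amino-acid symbol") from None


def binarize(
    record: ProteinRecord | str,
    mode: frozenset[int] | Sequence[int],
    mode_index: int = 0,
) -> CharacteristicSequence:
    """Map a protein to its binary characteristic sequence under one mode.

    Position i is '1' iff the class of residue i belongs to the mode's
    positive class triple.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    source = record.id if isinstance(record, ProteinRecord) else ""
    if not seq:
        raise ValueError("cannot binarize an empty sequence")
    positive = frozenset(mode)
    if len(positive) != 3 or not positive <= {1, 2, 3, 4, 5, 6}:
        raise ValueError(f"mode must be 3 class indices from 1..6, got {sorted(positive)}")
    classes = _class_indices(seq)
    bits = np.isin(classes, list(positive)).astype(np.uint8)
    return CharacteristicSequence(
        bits="".join("1" if b else "0" for b in bits),
        mode_index=mode_index,
        source_id=source,
    )


def prefix_lengths(n: int, L: int) -> list[int]:
    """Lengths floor(k*n/L) of the L nested prefix subsequences."""
    if L < 1:
        raise ValueError(f"L must be a positive integer, got {L}")
    if n < L:
        raise ValueError(
            f"sequence length n={n} is shorter than L={L}; "
            "every subsequence must be non-empty"
        )
    return [(k * n) // L for k in range(1, L + 1)]


def partition(bits: CharacteristicSequence | str, L: int) -> list[str]:
    """Split a characteristic sequence into its L prefix subsequences.

    Subsequence k holds the first floor(k*n/L) symbols; the last one is the
    full sequence and each is a prefix of the next.
    """
    s = bits.bits if isinstance(bits, CharacteristicSequence) else bits
    return [s[:p] for p in prefix_lengths(len(s), L)]


def composition(bits: str) -> tuple[float, float]:
    """Fractions (f0, f1) of '0' and '1' in a binary string; f0 + f1 = 1."""
    if not bits:
        raise ValueError("composition of an empty string is undefined")
    n = len(bits)
    ones = bits.count("1")
    return (n - ones) / n, ones / n


def switch_counts(bits: str) -> tuple[int, int]:
    """Counts of '1'->'0' and '0'->'1' adjacent switches, separately."""
    if not bits:
        raise ValueError("transition of an empty string is undefined")
    n10 = sum(1 for a, b in zip(bits, bits[1:]) if a == "1" and b == "0")
    n01 = sum(1 for a, b in zip(bits, bits[1:]) if a == "0" and b == "1")
    return n10, n01


def transition(bits: str) -> int:
    """Total number of adjacent bit switches ('1-0' plus '0-1')."""
    n10, n01 = switch_counts(bits)
    return n10 + n01


@dataclass(frozen=True)
class GlobalEncoder:
    """Configurable GE encoder.

    Parameters
    ----------
    L : number of nested prefix subsequences per characteristic sequence.
        The protein vector has 10*L*3 entries; L=5 gives the canonical 150.
    normalize_transition : divide each switch count by (subsequence
        length - 1), turning it into a switch frequency.  Off by default:
        the raw count is the canonical descriptor.
    """

    L: int = 5
    normalize_transition: bool = False

    @property
    def n_features(self) -> int:
        return 10 * self.L * 3

    def encode(self, record: ProteinRecord | str) -> np.ndarray:
        """Encode one protein into its 10*L*3 GE feature vector.

        Per mode (canonical order), per subsequence (k = 1..L), the triple
        [f0, f1, transition] is emitted.
        """
        seq = record.sequence if isinstance(record, ProteinRecord) else record
        n = len(seq)
        plen = prefix_lengths(n, self.L)
        classes = _class_indices(seq)
        out = np.empty(self.n_features)
        pos = 0
        for mode in MODES:
            bits = np.isin(classes, list(mode)).astype(np.int64)
            cum_ones = np.cumsum(bits)
            # switches[i] == 1 iff bits[i] != bits[i+1]
            cum_switch = np.concatenate(
                ([0], np.cumsum(bits[:-1] != bits[1:]))
            )
            for p in plen:
                ones = cum_ones[p - 1]
                f1 = ones / p
                t = float(cum_switch[p - 1])
                if self.normalize_transition and p > 1:
                    t /= p - 1
                out[pos : pos + 3] = (1.0 - f1, f1, t)
                pos += 3
        return out

    def encode_pair(
        self, a: ProteinRecord | str, b: ProteinRecord | str
    ) -> np.ndarray:
        """Concatenated pair vector encode(a) || encode(b) (2*10*L*3)."""
        return np.concatenate([self.encode(a), self.encode(b)])

    def encode_pairs(
        self,
        pairs: Sequence,
        proteins: Sequence[ProteinRecord],
    ) -> tuple[np.ndarray, np.ndarray]:
        """Encode a pair dataset into (X, y): rows are pair vectors.

        Each protein is encoded once and cached; pairs reference proteins
        by id.
        """
        by_id = {p.id: p for p in proteins}
        cache: dict[str, np.ndarray] = {}

        def vec(pid: str) -> np.ndarray:
            if pid not in cache:
                cache[pid] = self.encode(by_id[pid])
            return cache[pid]

        X = np.array([np.concatenate([vec(p.id_a), vec(p.id_b)]) for p in pairs])
        y = np.array([p.label for p in pairs], dtype=int)
        return X, y


def encode_protein(record: ProteinRecord | str, L: int = 5) -> np.ndarray:
    """Functional shorthand for GlobalEncoder(L).encode."""
    return GlobalEncoder(L=L).encode(record)


def encode_pair(
    a: ProteinRecord | str, b: ProteinRecord | str, L: int = 5
) -> np.ndarray:
    """Functional shorthand for GlobalEncoder(L).encode_pair."""
    return GlobalEncoder(L=L).encode_pair(a, b)


def encode_2mer(record: ProteinRecord | str) -> np.ndarray:
    """Baseline descriptor: 400 normalized ordered-dimer frequencies.

    Entry for dimer d is count(d) / (n - 1); entries sum to 1 for any
    sequence of length >= 2.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if len(seq) < 2:
        raise ValueError("2-mer descriptor needs a sequence of length >= 2")
    out = np.zeros(400)
    for i in range(len(seq) - 1):
        out[_DIMER_INDEX[seq[i : i + 2]]] += 1.0
    return out / (len(seq) - 1)


def encode_pair_2mer(
    a: ProteinRecord | str, b: ProteinRecord | str
) -> np.ndarray:
    """800-entry concatenated 2-mer pair vector."""
    return np.concatenate([encode_2mer(a), encode_2mer(b)])


def standardize_columns(
    X: np.ndarray, mean: np.ndarray | None = None, std: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optional per-column standardization (off by default in pipelines).

    Returns (Xs, mean, std); constant columns keep std 1 to avoid 0/0.
    """
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
    if std is None:
        std = X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
    return (X - mean) / std, mean, std
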
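"""Seven-residue C-terminal tail sequences and their one-hot encoding.

An ER retention/retrieval sequence (ERS) is modelled here as the last seven
residues of a protein, written N-to-C.  Positions are labelled -7..-1, with
-1 the extreme C-terminal residue (string index 6).  Tails are restricted to
the 20 natural amino acids; anything else (X, U, B, stop symbols, gaps) is
rejected rather than recoded.

The one-hot representation is a 7x20 binary matrix: row i encodes the residue
at string index i, columns follow the fixed alphabetical one-letter ordering
``ACDEFGHIKLMNPQRSTVWY``.  Serialized models depend on this column order, so
it is defined once here and nowhere else.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

#: Canonical residue alphabet; column order of every one-hot matrix.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}
N_RESIDUES: int = len(ALPHABET)
TAIL_LENGTH: int = 7

#: Position labels -7..-1 in the order of string indices 0..6.
POSITIONS: tuple[int, ...] = tuple(range(-TAIL_LENGTH, 0))


class TailError(ValueError):
    """Base class for tail validation failures."""


class TailLengthError(TailError):
    """Raised when a tail is not exactly seven residues long."""


class TailAlphabetError(TailError):
    """Raised when a tail contains a character outside the 20-letter alphabet."""


class TailSequence(str):
    """A validated seven-residue tail over the 20 natural amino acids.

    Subclasses :class:`str`, so tails hash, sort and compare like plain
    strings.  Construction validates; lowercase input is uppercased silently,
    every other deviation raises.
    """

    __slots__ = ()

    def __new__(cls, raw: str) -> "TailSequence":
        s = str(raw).upper()
        if len(s) != TAIL_LENGTH:
            raise TailLengthError(
                f"tail must have exactly {TAIL_LENGTH} residues, got {len(s)}: {raw!r}"
            )
        for ch in s:
            if ch not in AA_TO_INDEX:
                raise TailAlphabetError(
                    f"tail {raw!r} contains non-natural residue {ch!r}"
                )
        return super().__new__(cls, s)

    def residue_at(self, position: int) -> str:
        """Residue at a -7..-1 position label (-1 = C-terminus)."""
        if not -TAIL_LENGTH <= position <= -1:
            raise IndexError(f"position must be in -7..-1, got {position}")
        return self[position + TAIL_LENGTH]


def validate_tail(raw: str) -> TailSequence:
    """Validate ``raw`` as a seven-residue tail; raise :class:`TailError` otherwise."""
    return TailSequence(raw)


def is_valid_tail(raw: str) -> bool:
    try:
        TailSequence(raw)
    except TailError:
        return False
    return True


def position_to_index(position: int) -> int:
    """Map a -7..-1 position label to a string/matrix row index 0..6."""
    if not -TAIL_LENGTH <= position <= -1:
        raise IndexError(f"position must be in -7..-1, got {position}")
    return position + TAIL_LENGTH


def encode_one_hot(tail: TailSequence | str) -> np.ndarray:
    """One-hot encode a tail as a 7x20 float matrix with a single 1 per row."""
    t = validate_tail(tail)
    m = np.zeros((TAIL_LENGTH, N_RESIDUES))
    for i, aa in enumerate(t):
        m[i, AA_TO_INDEX[aa]] = 1.0
    return m


def encode_indices(tails: Iterable[TailSequence | str]) -> np.ndarray:
    """Encode tails as an (n, 7) integer matrix of alphabet indices.

    This is the compact equivalent of stacking one-hot matrices and is what
    the recurrent model consumes internally.
    """
    rows = [[AA_TO_INDEX[aa] for aa in validate_tail(t)] for t in tails]
    return np.asarray(rows, dtype=np.int64).reshape(-1, TAIL_LENGTH)


def decode_one_hot(matrix: np.ndarray) -> TailSequence:
    """Invert :func:`encode_one_hot`.

    Raises
    ------
    ValueError
        If the matrix is not 7x20, is non-binary, or any row does not sum
        to exactly one.
    """
    m = np.asarray(matrix)
    if m.shape != (TAIL_LENGTH, N_RESIDUES):
        raise ValueError(f"expected shape (7, 20), got {m.shape}")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("one-hot matrix must contain only 0s and 1s")
    row_sums = m.sum(axis=1)
    if not (row_sums == 1).all():
        bad = int(np.flatnonzero(row_sums != 1)[0])
        raise ValueError(f"row {bad} sums to {row_sums[bad]}, expected exactly 1")
    letters = [ALPHABET[int(j)] for j in m.argmax(axis=1)]
    return TailSequence("".join(letters))


def read_tail_lines(path) -> list[TailSequence]:
    """Read tails from plain text, one 7-mer per line; blank lines ignored."""
    tails = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                tails.append(validate_tail(line))
    return tails


def write_tail_lines(path, tails: Sequence[TailSequence | str]) -> None:
    with open(path, "w") as fh:
        for t in tails:
            fh.write(str(validate_tail(t)) + "\n")
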
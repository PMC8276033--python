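"""PAM250 similarity scores and position probability matrices for tails.

Two descriptive statistics accompany the predictive model:

* a peptide similarity score — for two aligned seven-residue tails, the sum
  of PAM250 substitution scores over positions -7..-1.  Scored against the
  reference ``KKKKDEL`` (the per-position most dominant residues of the
  original training batch), low scores flag ER-retention sequences divergent
  from the canonical motif (e.g. LIGSLEL, CIHSPDL).
* a position probability matrix (PPM) — per-position residue frequencies
  across a set of tails, the data behind a probability-unit sequence logo.
  Rendering is out of scope; the matrix is emitted as a table.

The bundled PAM250 is the standard NCBI integer log-odds table as shipped
with Biopython; any square substitution matrix in the usual text format
(e.g. a BLOSUM file) can be loaded as a drop-in replacement.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .tails import ALPHABET, POSITIONS, TAIL_LENGTH, TailSequence, validate_tail

DEFAULT_REFERENCE = "KKKKDEL"


@dataclasses.dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer substitution scores over the 20-letter alphabet."""

    name: str
    scores: dict[tuple[str, str], int]

    def __post_init__(self):
        for a in ALPHABET:
            for b in ALPHABET:
                if (a, b) not in self.scores:
                    raise ValueError(f"{self.name}: missing entry for pair ({a},{b})")
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise ValueError(f"{self.name}: asymmetric at ({a},{b})")

    def score(self, a: str, b: str) -> int:
        return self.scores[(a, b)]

    @classmethod
    def from_biopython(cls, array, name: str) -> "SubstitutionMatrix":
        scores = {
            (a, b): int(array[a, b]) for a in ALPHABET for b in ALPHABET
        }
        return cls(name=name, scores=scores)

    @classmethod
    def from_text(cls, path, name: str | None = None) -> "SubstitutionMatrix":
        """Load from standard square-matrix text (as distributed with
        alignment toolkits)."""
        arr = substitution_matrices.read(str(path))
        return cls.from_biopython(arr, name or str(path))


@lru_cache(maxsize=4)
def load_matrix(name: str = "PAM250") -> SubstitutionMatrix:
    """Load a named matrix bundled with Biopython (PAM250 by default)."""
    return SubstitutionMatrix.from_biopython(substitution_matrices.load(name), name)


def similarity_score(
    a: TailSequence | str,
    b: TailSequence | str,
    matrix: SubstitutionMatrix | None = None,
) -> int:
    """Sum of substitution scores over the seven aligned positions.

    Symmetric in its arguments; identical tails score the sum of the
    matrix's diagonal entries for their residues.
    """
    matrix = matrix or load_matrix()
    ta, tb = validate_tail(a), validate_tail(b)
    return sum(matrix.score(x, y) for x, y in zip(ta, tb))


def rank_by_divergence(
    tails: Sequence[TailSequence | str],
    reference: TailSequence | str = DEFAULT_REFERENCE,
    matrix: SubstitutionMatrix | None = None,
) -> pd.DataFrame:
    """Rank tails by ascending similarity to the reference (most divergent
    first); ties break lexicographically."""
    if not len(tails):
        raise ValueError("no tails to rank")
    matrix = matrix or load_matrix()
    ref = validate_tail(reference)
    rows = sorted(
        ((str(validate_tail(t)), similarity_score(t, ref, matrix)) for t in tails),
        key=lambda r: (r[1], r[0]),
    )
    return pd.DataFrame(rows, columns=["tail", "similarity_to_reference"])


@dataclasses.dataclass
class PositionProbabilityMatrix:
    """Per-position residue frequencies; rows are positions -7..-1."""

    table: pd.DataFrame  # index: -7..-1 labels; columns: ALPHABET
    n_sequences: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="position")


def position_probability_matrix(
    tails: Iterable[TailSequence | str],
) -> PositionProbabilityMatrix:
    """Count residues per position and normalise each position to sum 1."""
    validated = [validate_tail(t) for t in tails]
    if not validated:
        raise ValueError("no tails supplied")
    counts = np.zeros((TAIL_LENGTH, len(ALPHABET)))
    col = {aa: j for j, aa in enumerate(ALPHABET)}
    for t in validated:
        for i, aa in enumerate(t):
            counts[i, col[aa]] += 1
    probs = counts / len(validated)
    table = pd.DataFrame(probs, index=list(POSITIONS), columns=list(ALPHABET))
    return PositionProbabilityMatrix(table=table, n_sequences=len(validated))
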
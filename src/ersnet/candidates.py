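"""Candidate tail generation, scoring, and validation-batch assembly.

The candidate space is built from a training batch: for each of the seven
positions, the residues whose relative frequency meets a threshold form that
position's allowed set, and the Cartesian product of the seven sets is the
permutation library (the original study's library of this kind held 463,736
sequences).  Candidates are scored by ensemble mean ("RNN score"), ranked,
and assembled — together with proteome-derived tails — into a validation
batch stratified into predicted-strong and predicted-weak classes.

Enumeration is streaming and deterministically lexicographic (position -7
varies slowest), so proteome-scale candidate streams are resumable and
diffable.
"""

from __future__ import annotations

import dataclasses
import heapq
import itertools
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .ensemble import EnsembleModel, ensemble_predict
from .model import SecretionRecord
from .proteome import TailCatalog
from .tails import ALPHABET, POSITIONS, TAIL_LENGTH, TailSequence, validate_tail


@dataclasses.dataclass(frozen=True)
class PositionResidueSets:
    """Per-position allowed residue sets (-7..-1), alphabetically sorted."""

    sets: tuple[str, ...]  # 7 sorted strings of residues
    frequency_threshold: float

    def __post_init__(self):
        if len(self.sets) != TAIL_LENGTH:
            raise ValueError(f"need {TAIL_LENGTH} residue sets, got {len(self.sets)}")
        for pos, s in zip(POSITIONS, self.sets):
            if not s:
                raise ValueError(f"empty residue set at position {pos}")
            if any(aa not in ALPHABET for aa in s):
                raise ValueError(f"non-natural residue in set at position {pos}")

    @property
    def n_candidates(self) -> int:
        out = 1
        for s in self.sets:
            out *= len(s)
        return out

    def to_json_obj(self) -> list[str]:
        return list(self.sets)


class EmptyPositionSetError(ValueError):
    """Raised when the frequency threshold leaves a position with no residues."""


class InfeasibleBatchError(ValueError):
    """Raised when a validation-batch stratum cannot be filled as requested."""


def _tails_of(records: Iterable) -> list[TailSequence]:
    out = []
    for r in records:
        out.append(validate_tail(r.tail if isinstance(r, SecretionRecord) else r))
    return out


def high_frequency_sets(
    records: Sequence[SecretionRecord | TailSequence | str], threshold: float
) -> PositionResidueSets:
    """Residues reaching relative frequency >= threshold at each position.

    ``threshold`` is a required frequency in (0, 1]; there is no magic
    default because the original study does not state one (its permutation
    count only pins the product of the set sizes).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    tails = _tails_of(records)
    if not tails:
        raise ValueError("no records supplied")
    n = len(tails)
    sets = []
    for i, pos in enumerate(POSITIONS):
        counts: dict[str, int] = {}
        for t in tails:
            counts[t[i]] = counts.get(t[i], 0) + 1
        keep = sorted(aa for aa, c in counts.items() if c / n >= threshold)
        if not keep:
            raise EmptyPositionSetError(
                f"no residue reaches frequency {threshold} at position {pos}"
            )
        sets.append("".join(keep))
    return PositionResidueSets(sets=tuple(sets), frequency_threshold=threshold)


def enumerate_candidates(sets: PositionResidueSets) -> Iterator[TailSequence]:
    """Stream the full Cartesian product in lexicographic order (-7 slowest).

    Yields each candidate exactly once; nothing is materialised, so the
    caller can consume proteome-scale libraries lazily.
    """
    for combo in itertools.product(*sets.sets):
        yield TailSequence("".join(combo))


def rank_candidates(
    candidates: Iterable[TailSequence | str],
    ensemble: EnsembleModel,
    top_n: int | None = None,
    chunk_size: int = 2048,
) -> pd.DataFrame:
    """Score candidates by ensemble mean and rank them.

    Descending score, ties broken lexicographically by tail; with ``top_n``
    only the best n rows are kept (streaming partial sort, identical to the
    head of the full sort).
    """
    heap: list[tuple] = []  # min-heap of sort keys when top_n is set
    rows: list[tuple] = []
    it = iter(candidates)
    counter = itertools.count()
    while True:
        chunk = list(itertools.islice(it, chunk_size))
        if not chunk:
            break
        means, _ = ensemble_predict(ensemble, chunk)
        for t, s in zip(chunk, means):
            # sort key: higher score first, then lexicographic tail
            key = (float(s), _NegStr(str(t)))
            if top_n is None:
                rows.append((key, str(t), float(s)))
            elif len(heap) < top_n:
                heapq.heappush(heap, (key, next(counter), str(t), float(s)))
            elif key > heap[0][0]:
                heapq.heapreplace(heap, (key, next(counter), str(t), float(s)))
    if top_n is not None:
        rows = [(k, t, s) for k, _, t, s in heap]
    rows.sort(key=lambda r: r[0], reverse=True)
    return pd.DataFrame(
        {"tail": [t for _, t, _ in rows], "score": [s for _, _, s in rows]}
    )


class _NegStr(str):
    """String with inverted ordering, so (score, _NegStr(tail)) sorts
    descending-score / ascending-tail under a single reverse sort."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


@dataclasses.dataclass
class CandidateBatch:
    """A selected validation batch: tail, score, source and predicted class."""

    table: pd.DataFrame  # columns: tail, score, source, predicted_class
    parameters: dict


def assemble_validation_batch(
    ranked: pd.DataFrame,
    proteome_tails: TailCatalog | set,
    first_batch: Iterable[TailSequence | str],
    n_strong: int,
    n_weak: int,
    strong_cutoff: float,
    weak_cutoff: float,
    artificial_fraction: float,
    exclude: Iterable[TailSequence | str] = (),
) -> CandidateBatch:
    """Select a stratified validation batch from ranked candidates.

    Tails present in ``proteome_tails`` are labelled ``human``, the rest
    ``artificial``.  First-batch tails and explicit exclusions (the stand-in
    for manual synthesisability judgements) are never selected.  The strong
    stratum takes tails with score >= strong_cutoff in descending-score
    order; the weak stratum takes score <= weak_cutoff in ascending-score
    order.  Within each stratum, round(artificial_fraction * n) slots go to
    artificial tails and the rest to human ones; an unfillable quota raises
    :class:`InfeasibleBatchError` naming the stratum and source.
    """
    if strong_cutoff <= weak_cutoff:
        raise ValueError("strong_cutoff must exceed weak_cutoff")
    if not 0.0 <= artificial_fraction <= 1.0:
        raise ValueError("artificial_fraction must be in [0, 1]")
    banned = {str(validate_tail(t)) for t in first_batch}
    banned |= {str(validate_tail(t)) for t in exclude}
    is_human = (
        (lambda t: t in proteome_tails.entries)
        if isinstance(proteome_tails, TailCatalog)
        else (lambda t: t in proteome_tails)
    )

    df = ranked[~ranked["tail"].isin(banned)].drop_duplicates("tail")
    strong = df[df["score"] >= strong_cutoff]
    weak = df[df["score"] <= weak_cutoff].iloc[::-1]  # ascending score

    selected = []
    for stratum, pool, n_total in (("strong", strong, n_strong), ("weak", weak, n_weak)):
        n_art = int(round(artificial_fraction * n_total))
        quotas = {"artificial": n_art, "human": n_total - n_art}
        taken = {"artificial": 0, "human": 0}
        for _, row in pool.iterrows():
            src = "human" if is_human(row["tail"]) else "artificial"
            if taken[src] < quotas[src]:
                taken[src] += 1
                selected.append(
                    (row["tail"], float(row["score"]), src, stratum)
                )
            if taken == quotas:
                break
        for src in ("artificial", "human"):
            if taken[src] < quotas[src]:
                raise InfeasibleBatchError(
                    f"cannot fill {stratum} stratum: need {quotas[src]} {src} "
                    f"tails, found {taken[src]}"
                )
    table = pd.DataFrame(
        selected, columns=["tail", "score", "source", "predicted_class"]
    )
    params = {
        "n_strong": n_strong,
        "n_weak": n_weak,
        "strong_cutoff": strong_cutoff,
        "weak_cutoff": weak_cutoff,
        "artificial_fraction": artificial_fraction,
        "n_excluded": len(banned),
    }
    return CandidateBatch(table=table, parameters=params)
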
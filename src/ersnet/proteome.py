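"""Proteome scanning: extract C-terminal seven-residue tails from protein FASTA.

Given a protein catalog (e.g. a RefSeq proteome), each sequence is stripped of
a trailing stop symbol ``*``, its last seven residues are taken, and tails
containing non-natural residues are discarded.  Surviving tails are aggregated
into a :class:`TailCatalog` mapping each unique tail to the proteins carrying
it, together with rejection counters so the attrition is fully accounted for.

The non-natural-residue filter applies to the extracted 7-mer only: an
ambiguity code elsewhere in a protein does not discard an otherwise clean tail.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .tails import TailSequence, TailError, TailLengthError, validate_tail


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One protein FASTA entry. ``sequence`` may contain ambiguity codes or '*'."""

    id: str
    description: str
    sequence: str


class DuplicateIdError(ValueError):
    """Raised when a FASTA file contains the same accession twice."""


@dataclasses.dataclass
class TailCatalog:
    """Unique tails mapped to the protein ids that carry them, plus counters."""

    entries: dict[TailSequence, list[str]] = dataclasses.field(default_factory=dict)
    n_retained: int = 0
    n_rejected_length: int = 0
    n_rejected_alphabet: int = 0

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    @property
    def n_input(self) -> int:
        return self.n_retained + self.n_rejected_length + self.n_rejected_alphabet

    def __contains__(self, tail) -> bool:
        return str(tail).upper() in self.entries

    def counters(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_unique": self.n_unique,
            "n_rejected_length": self.n_rejected_length,
            "n_rejected_alphabet": self.n_rejected_alphabet,
        }


def read_fasta(source) -> list[ProteinRecord]:
    """Parse protein FASTA into records; order preserved, whitespace removed.

    ``source`` is a path or open text handle.  Duplicate ids raise
    :class:`DuplicateIdError` so tail-to-protein maps stay unambiguous.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(id=rec.id, description=rec.description, sequence=str(rec.seq))
        )
    return records


def extract_tails(
    records: Iterable[ProteinRecord], tail_length: int = 7
) -> TailCatalog:
    """Extract C-terminal ``tail_length``-mers, filter, and aggregate.

    Per record: strip one trailing ``'*'``, take the last ``tail_length``
    residues, reject (and count) records that are too short or whose tail
    contains a residue outside the 20-letter alphabet.
    """
    catalog = TailCatalog()
    for rec in records:
        seq = rec.sequence.upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if len(seq) < tail_length:
            catalog.n_rejected_length += 1
            continue
        raw = seq[-tail_length:]
        try:
            tail = validate_tail(raw)
        except TailLengthError:  # only reachable for tail_length != 7
            catalog.n_rejected_length += 1
            continue
        except TailError:
            catalog.n_rejected_alphabet += 1
            continue
        catalog.entries.setdefault(tail, []).append(rec.id)
        catalog.n_retained += 1
    return catalog


def catalog_to_table(catalog: TailCatalog) -> pd.DataFrame:
    """Tabulate a catalog: one row per unique tail.

    Deterministic order: descending protein count, then lexicographic tail.
    ``protein_ids`` keeps the original FASTA order, semicolon-joined on write.
    """
    rows = [
        {"tail": str(t), "n_proteins": len(ids), "protein_ids": list(ids)}
        for t, ids in catalog.entries.items()
    ]
    df = pd.DataFrame(rows, columns=["tail", "n_proteins", "protein_ids"])
    if len(df):
        df = df.sort_values(
            ["n_proteins", "tail"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df


def write_catalog_tsv(catalog: TailCatalog, path) -> None:
    df = catalog_to_table(catalog)
    df = df.assign(protein_ids=df["protein_ids"].map(";".join))
    df.to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> TailCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    catalog = TailCatalog()
    for _, row in df.iterrows():
        ids = row["protein_ids"].split(";") if row["protein_ids"] else []
        tail = validate_tail(row["tail"])
        catalog.entries[tail] = ids
        catalog.n_retained += len(ids)
    return catalog


def tails_of(catalog: TailCatalog) -> Sequence[TailSequence]:
    return list(catalog.entries)
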
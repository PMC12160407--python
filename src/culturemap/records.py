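"""Identified nucleotide records for isolate and community ASV sets."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A single identified nucleotide sequence (an ASV representative).

    Attributes
    ----------
    id : str
        Record identifier, unique within a :class:`SequenceSet`.
    sequence : str
        Uppercase nucleotide string over ``{A, C, G, T, N}``.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for record {self.id!r} is empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class SequenceSet:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    def __init__(self, records: Iterable[SequenceRecord] = ()) -> None:
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: SequenceRecord) -> None:
        if record.id in self._records:
            raise ValueError(f"duplicate sequence id: {record.id!r}")
        self._records[record.id] = record

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SequenceSet":
        return cls(SequenceRecord(i, s.upper()) for i, s in pairs)

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._records

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._records[seq_id]

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self._records == other._records
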
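"""Core domain types for TCR repertoire screening.

A *clone* is a rearranged TCR beta chain identified by its CDR3 amino-acid
sequence plus V/J gene calls; a *repertoire* is one sample's multiset of
clones; a *pool* is a bag of CDR3 sequences aggregated across many donors
(e.g. an HCMV-negative healthy reference used for negative training
examples and as the risk-score denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

#: symbols that mark a non-functional junction (stop codon / frameshift / ambiguity)
NONFUNCTIONAL_SYMBOLS = frozenset("*_X")

CloneKey = tuple[str, str, str]  # (v_gene, cdr3_aa, j_gene)


class RepertoireFormatError(ValueError):
    """A repertoire table is missing required columns or is malformed."""


class EmptyRepertoireWarning(UserWarning):
    """A repertoire contained no usable rows after parsing or filtering."""


@dataclass(frozen=True)
class TcrClone:
    """A single TCR beta clone with its abundance.

    ``count`` is the number of templates/reads (bulk) or cells
    (single-cell) supporting the clone.
    """

    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int
    productive: bool = True

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")

    @property
    def key(self) -> CloneKey:
        return (self.v_gene, self.cdr3_aa, self.j_gene)


@dataclass
class Repertoire:
    """One sample's TCR repertoire, keyed by (v_gene, cdr3_aa, j_gene)."""

    sample_id: str
    subject_id: str
    tissue: str  # "PBMC" or "TIL"
    clones: dict[CloneKey, TcrClone] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tissue not in ("PBMC", "TIL"):
            raise ValueError(f"tissue must be 'PBMC' or 'TIL', got {self.tissue!r}")

    @classmethod
    def from_clones(
        cls, clones: Iterable[TcrClone], sample_id: str, subject_id: str, tissue: str
    ) -> "Repertoire":
        """Build a repertoire, merging clones with identical identity (counts summed)."""
        merged: dict[CloneKey, TcrClone] = {}
        for clone in clones:
            prev = merged.get(clone.key)
            if prev is None:
                merged[clone.key] = clone
            else:
                merged[clone.key] = replace(prev, count=prev.count + clone.count)
        return cls(sample_id=sample_id, subject_id=subject_id, tissue=tissue, clones=merged)

    def __len__(self) -> int:
        return len(self.clones)

    def __iter__(self) -> Iterator[TcrClone]:
        return iter(self.clones.values())

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clones.values())

    @property
    def unique_sequences(self) -> set[str]:
        """Distinct CDR3 amino-acid sequences ('sequence level')."""
        return {c.cdr3_aa for c in self.clones.values()}

    def counts(self) -> list[int]:
        """Clone counts in arbitrary but stable (insertion) order."""
        return [c.count for c in self.clones.values()]

    def subset(self, keys: Iterable[CloneKey]) -> "Repertoire":
        keys = set(keys)
        return Repertoire(
            sample_id=self.sample_id,
            subject_id=self.subject_id,
            tissue=self.tissue,
            clones={k: v for k, v in self.clones.items() if k in keys},
        )


@dataclass(frozen=True)
class TcrPool:
    """A reference set of CDR3 sequences pooled across donors.

    Membership queries are exact string matches on cdr3_aa. ``serostatus``
    optionally records per-donor HCMV status used when the pool is built
    from individual donors (seropositive donors are excluded upstream).
    """

    label: str
    sequences: frozenset[str]
    n_donors: int = 0

    def __contains__(self, cdr3_aa: str) -> bool:
        return cdr3_aa in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)
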
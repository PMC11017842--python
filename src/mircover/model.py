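"""Core data types shared by every analysis stage.

The central object is the interaction-evidence table: one record per
(miRNA, gene, source) assertion, tagged with its source class
(experimentally validated vs. computationally predicted), the direction of
the reported effect, and a confidence in [0, 1].  Gene symbols are stored
uppercase and miRNA identifiers are compared case-insensitively, because
public miRNA resources mix capitalisation styles ("Hsa-miR" vs "hsa-miR").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Tuple


class SourceClass(enum.Enum):
    """Whether an interaction record is experimentally validated or predicted."""

    VALIDATED = "validated"
    PREDICTED = "predicted"


class Direction(enum.Enum):
    """Reported direction of the interaction evidence."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


def canonical_gene(symbol: str) -> str:
    return symbol.strip().upper()


def canonical_mirna(mirna_id: str) -> str:
    return mirna_id.strip().lower()


class GeneSet:
    """Ordered set of unique gene symbols (stored uppercase).

    Parameters
    ----------
    genes
        Iterable of gene symbols.  Symbols are stripped and upper-cased;
        duplicates (after case-folding) and empty symbols are errors.
    """

    def __init__(self, genes: Iterable[str]):
        seen: Dict[str, None] = {}
        for raw in genes:
            sym = canonical_gene(raw)
            if not sym:
                raise ValueError("empty gene symbol in gene set")
            if sym in seen:
                raise ValueError(f"duplicate gene symbol: {sym}")
            seen[sym] = None
        if not seen:
            raise ValueError("gene set must be non-empty")
        self._genes: Tuple[str, ...] = tuple(seen)

    @property
    def genes(self) -> Tuple[str, ...]:
        return self._genes

    def __contains__(self, symbol: str) -> bool:
        return canonical_gene(symbol) in set(self._genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSet) and self._genes == other._genes

    def __repr__(self) -> str:
        return f"GeneSet({list(self._genes)!r})"


@dataclass(frozen=True)
class EvidenceRecord:
    """One (miRNA, gene, source) interaction assertion."""

    mirna_id: str
    gene_id: str
    source_name: str
    source_class: SourceClass
    direction: Direction
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(
                f"confidence {self.confidence} outside [0, 1] for "
                f"({self.mirna_id}, {self.gene_id}, {self.source_name})"
            )

    @property
    def key(self) -> Tuple[str, str, str]:
        """Case-folded (miRNA, gene, source) identity used for uniqueness."""
        return (
            canonical_mirna(self.mirna_id),
            canonical_gene(self.gene_id),
            self.source_name,
        )


@dataclass
class EvidenceTable:
    """A collection of evidence records with table-wide uniqueness.

    ``provenance`` maps source names to free-text descriptions and is
    carried through unchanged.
    """

    records: List[EvidenceRecord] = field(default_factory=list)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValueError(
                    f"duplicate evidence record for {rec.key}; tallies would be ambiguous"
                )
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EvidenceRecord]:
        return iter(self.records)

    def mirna_ids(self) -> List[str]:
        """Distinct miRNA ids in first-appearance order (canonical case-folded)."""
        out: Dict[str, str] = {}
        for rec in self.records:
            out.setdefault(canonical_mirna(rec.mirna_id), rec.mirna_id)
        return list(out.values())


_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def normalize_rna(seq: str) -> str:
    """Upper-case a nucleotide string and map T to U.

    Raises ``ValueError`` for empty sequences or characters outside
    {A, C, G, U, T}.
    """
    s = seq.strip().upper().replace("T", "U")
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU(T) characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, G<->C)."""
    return "".join(_RNA_COMPLEMENT[c] for c in reversed(seq))


class SequenceSet:
    """Mapping of identifiers to RNA-normalised sequences with a role tag.

    ``role`` is ``"mirna"`` or ``"utr"``; it only labels what the set holds,
    all sequences are stored 5'→3' in the RNA alphabet.
    """

    ROLES = ("mirna", "utr")

    def __init__(self, entries: Mapping[str, str], role: str):
        if role not in self.ROLES:
            raise ValueError(f"role must be one of {self.ROLES}, got {role!r}")
        self.role = role
        self._entries: Dict[str, str] = {}
        for name, seq in entries.items():
            if name in self._entries:
                raise ValueError(f"duplicate sequence id: {name}")
            self._entries[name] = normalize_rna(seq)
        if not self._entries:
            raise ValueError("sequence set must be non-empty")

    @property
    def entries(self) -> Dict[str, str]:
        return dict(self._entries)

    def __getitem__(self, name: str) -> str:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SequenceSet)
            and self.role == other.role
            and self._entries == other._entries
        )
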
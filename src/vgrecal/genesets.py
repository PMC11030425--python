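"""Gene set and annotation-term containers."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .vg import normalize_gene_id

__all__ = ["GeneSet", "TermAnnotation"]


@dataclass(frozen=True)
class GeneSet:
    """A named set of genes; ids version-stripped, duplicates collapsed."""

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        norm = frozenset(normalize_gene_id(g) for g in self.genes)
        if not norm:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", norm)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def subtract(self, *others: "GeneSet") -> "GeneSet":
        """This set minus all genes appearing in any of the others.

        The standard background-construction rule: the universe minus every
        foreground set under study.
        """
        removed = frozenset().union(*(o.genes for o in others)) if others else frozenset()
        return GeneSet(self.name, self.genes - removed)


@dataclass(frozen=True)
class TermAnnotation:
    """An annotation term (e.g. a GO term) with its associated genes."""

    term_id: str
    name: str
    genes: frozenset[str]
    namespace: str = field(default="default")

    def __post_init__(self):
        if not self.term_id:
            raise ValidationError("term id must be non-empty")
        norm = frozenset(normalize_gene_id(g) for g in self.genes)
        if not norm:
            raise ValidationError(f"term {self.term_id!r} has no genes")
        object.__setattr__(self, "genes", norm)

    def as_gene_set(self) -> GeneSet:
        return GeneSet(self.term_id, self.genes)
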
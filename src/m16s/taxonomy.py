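"""Taxonomic lineages for 16S reference sequences and reads.

Every reference (and every read derived from it) carries a five-rank
lineage, phylum through genus, in the style of RDP database exports.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Rank names in fixed hierarchical order (coarsest first).
RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True, slots=True)
class TaxonomyLineage:
    """Ordered rank labels phylum -> genus attached to a sequence.

    Labels are non-empty strings and must not contain the ``;`` separator
    used by the on-disk header dialect.
    """

    phylum: str
    class_: str
    order: str
    family: str
    genus: str

    def __post_init__(self) -> None:
        for rank, label in zip(RANKS, self.labels()):
            if not label:
                raise ValueError(f"empty label for rank {rank!r}")
            if ";" in label:
                raise ValueError(f"label {label!r} for rank {rank!r} contains ';'")

    def labels(self) -> tuple[str, str, str, str, str]:
        """All five labels, coarsest rank first."""
        return (self.phylum, self.class_, self.order, self.family, self.genus)

    def rank(self, rank: str) -> str:
        """Label at *rank* (one of ``phylum, class, order, family, genus``)."""
        try:
            i = RANKS.index(rank)
        except ValueError:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None
        return self.labels()[i]

    def __str__(self) -> str:
        return ";".join(self.labels())

    @classmethod
    def from_string(cls, text: str) -> "TaxonomyLineage":
        """Parse a ``;``-joined five-rank lineage, tolerating a ``Root;`` prefix."""
        parts = text.strip().split(";")
        if parts and parts[0].strip().lower() == "root":
            parts = parts[1:]
        if len(parts) != len(RANKS):
            raise ValueError(
                f"expected {len(RANKS)} rank labels, got {len(parts)} in {text!r}"
            )
        return cls(*(p.strip() for p in parts))
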
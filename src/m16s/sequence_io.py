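"""Taxonomy-labelled FASTA input/output and reference-pool manipulation.

The on-disk dialect is plain FASTA whose header line carries the record id
and a five-rank lineage separated by a tab::

    >seq001<TAB>Proteobacteria;Alphaproteobacteria;Rhizobiales;Rhizobiaceae;Rhizobium
    ACGT...

Multi-line sequence bodies are accepted on input; output is written with
one line per sequence. Reads additionally encode provenance after the
lineage (see :func:`write_reads_fasta`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .taxonomy import TaxonomyLineage


@dataclass(frozen=True, slots=True)
class ReferenceSequence:
    """A full-length, taxonomy-labelled 16S reference sequence."""

    id: str
    lineage: TaxonomyLineage
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"reference {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, slots=True)
class ShortRead:
    """A simulated short read with its source reference and technology tag.

    ``technology`` is ``"SG"`` (shotgun) or ``"AMP"`` (amplicon); ``strand``
    is ``"+"`` or ``"-"`` relative to the reference forward strand.
    """

    id: str
    source_id: str
    lineage: TaxonomyLineage
    seq: str
    technology: str
    strand: str

    def __post_init__(self) -> None:
        if self.technology not in ("SG", "AMP"):
            raise ValueError(f"technology must be SG or AMP, got {self.technology!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return len(self.seq)


class FastaParseError(ValueError):
    """Raised on a malformed taxonomy-FASTA header or duplicate id."""


def parse_taxonomy_fasta(path: str | os.PathLike) -> list[ReferenceSequence]:
    """Read taxonomy-labelled references, preserving file order.

    Raises :class:`FastaParseError` (naming the offending record) on a
    header without a tab-separated five-rank lineage or on a duplicate id.
    """
    records: list[ReferenceSequence] = []
    seen: set[str] = set()
    with open(path) as fh:
        for n, (header, seq) in enumerate(SimpleFastaParser(fh), start=1):
            parts = header.split("\t")
            if len(parts) < 2:
                raise FastaParseError(
                    f"record {n} ({header.split()[0] if header else '?'}): "
                    "header lacks tab-separated lineage"
                )
            rec_id = parts[0].strip()
            try:
                lineage = TaxonomyLineage.from_string(parts[1])
            except ValueError as exc:
                raise FastaParseError(f"record {n} ({rec_id}): {exc}") from exc
            if rec_id in seen:
                raise FastaParseError(f"record {n}: duplicate id {rec_id!r}")
            seen.add(rec_id)
            records.append(ReferenceSequence(rec_id, lineage, seq.upper()))
    return records


def write_taxonomy_fasta(records: Iterable[ReferenceSequence], path: str | os.PathLike) -> None:
    """Write references in the taxonomy-FASTA dialect, one sequence line each."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\t{rec.lineage}\n{rec.seq}\n")


def write_reads_fasta(reads: Iterable[ShortRead], path: str | os.PathLike) -> None:
    """Write reads as FASTA; the header carries lineage and provenance."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f">{r.id}\t{r.lineage}\tsource={r.source_id};"
                f"tech={r.technology};strand={r.strand}\n{r.seq}\n"
            )


def parse_reads_fasta(path: str | os.PathLike) -> list[ShortRead]:
    """Read back a reads FASTA written by :func:`write_reads_fasta`."""
    reads: list[ShortRead] = []
    with open(path) as fh:
        for n, (header, seq) in enumerate(SimpleFastaParser(fh), start=1):
            parts = header.split("\t")
            if len(parts) < 3:
                raise FastaParseError(f"read record {n}: header lacks provenance field")
            meta = dict(kv.split("=", 1) for kv in parts[2].split(";"))
            reads.append(
                ShortRead(
                    id=parts[0].strip(),
                    source_id=meta["source"],
                    lineage=TaxonomyLineage.from_string(parts[1]),
                    seq=seq.upper(),
                    technology=meta["tech"],
                    strand=meta["strand"],
                )
            )
    return reads


def filter_by_length(
    refs: Sequence[ReferenceSequence], min_len: int
) -> list[ReferenceSequence]:
    """Keep references at least *min_len* bp long, preserving order.

    This is the only RDP-style quality filter applicable to bare FASTA
    input (the database's strain/source/quality flags are metadata).
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [r for r in refs if len(r) >= min_len]


def balanced_subset(
    refs: Sequence[ReferenceSequence],
    n_taxa: int,
    n_per_taxon: int,
    rank: str = "genus",
    seed: int = 0,
) -> list[ReferenceSequence]:
    """Draw a taxonomically balanced subset: *n_taxa* labels at *rank*,
    each represented by exactly *n_per_taxon* sequences.

    Selection is seeded uniform sampling without replacement, reproducible
    for a fixed seed. Raises ``ValueError`` listing the deficit when the
    pool cannot support the request.
    """
    by_label: dict[str, list[ReferenceSequence]] = {}
    for r in refs:
        by_label.setdefault(r.lineage.rank(rank), []).append(r)

    eligible = sorted(lab for lab, members in by_label.items() if len(members) >= n_per_taxon)
    if len(eligible) < n_taxa:
        short = sorted(set(by_label) - set(eligible))
        raise ValueError(
            f"need {n_taxa} {rank} labels with >= {n_per_taxon} sequences each, "
            f"found {len(eligible)} (of {len(by_label)} total; "
            f"{len(short)} labels are under-populated)"
        )

    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_taxa, replace=False)
    out: list[ReferenceSequence] = []
    for i in sorted(chosen):
        members = by_label[eligible[i]]
        picks = rng.choice(len(members), size=n_per_taxon, replace=False)
        out.extend(members[j] for j in sorted(picks))
    return out
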
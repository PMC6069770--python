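"""Shotgun and amplicon short-read simulation from 16S references.

Emulates the Grinder-style Illumina MiSeq setup: read lengths uniform in
``center ± halfwidth`` bp, per-position error following a quartic
polynomial in the sequencing cycle (a percentage, capped at 100%), and an
80/20 substitution/indel split. Amplicon reads are confined to the region
delimited by a degenerate primer pair (V3-V4 in the intended use) and can
be primer-trimmed by exact IUPAC prefix/suffix matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from .sequence_io import ReferenceSequence, ShortRead

#: V3-V4 primer pair used throughout (IUPAC degenerate, 5'->3').
DEFAULT_FORWARD_PRIMER = "CCTACGGGAGGCAGCAG"
DEFAULT_REVERSE_PRIMER = "CCGTCAATTCMTTTRAGT"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True, slots=True)
class MutationModel:
    """Position-dependent error model.

    The per-position error *percentage* at 1-based read position ``i`` is
    ``base_rate + quartic_coeff * i**4``; probabilities are this divided by
    100 and capped at 1. ``substitution_fraction`` of mutations are
    substitutions, the rest split evenly between insertions and deletions.
    Read lengths are uniform over ``read_len_center ± read_len_halfwidth``.
    """

    base_rate: float = 3e-3
    quartic_coeff: float = 3.3e-8
    substitution_fraction: float = 0.8
    read_len_center: int = 250
    read_len_halfwidth: int = 10

    def __post_init__(self) -> None:
        if self.base_rate < 0 or self.quartic_coeff < 0:
            raise ValueError("polynomial coefficients must be non-negative")
        if not 0.0 <= self.substitution_fraction <= 1.0:
            raise ValueError("substitution_fraction must be in [0, 1]")
        if not self.read_len_center > self.read_len_halfwidth >= 0:
            raise ValueError("require read_len_center > read_len_halfwidth >= 0")

    @property
    def max_read_len(self) -> int:
        return self.read_len_center + self.read_len_halfwidth

    @property
    def min_read_len(self) -> int:
        return self.read_len_center - self.read_len_halfwidth


ZERO_MUTATION = MutationModel(base_rate=0.0, quartic_coeff=0.0)

_IUPAC_OK = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True, slots=True)
class PrimerPair:
    """Degenerate PCR primer pair; ``reverse`` is 5'->3' on the opposite strand."""

    forward: str = DEFAULT_FORWARD_PRIMER
    reverse: str = DEFAULT_REVERSE_PRIMER

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise ValueError(f"{name} primer is empty")
            bad = set(p.upper()) - _IUPAC_OK
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC characters {sorted(bad)}")


class AmpliconSpan(NamedTuple):
    """Half-open interval on the reference forward strand, primer sites included."""

    start: int
    end: int


class MutationEvent(NamedTuple):
    position: int  # 1-based position along the read (sequencing cycle)
    kind: str  # "sub" | "ins" | "del"
    before: str
    after: str


def iupac_regex(primer: str) -> re.Pattern[str]:
    """Compile a degenerate primer to a regex of IUPAC character classes."""
    parts = []
    for c in primer.upper():
        opts = ambiguous_dna_values[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def reads_per_reference(ref_len: int, coverage: float, mean_read_len: int) -> int:
    """Number of reads drawn from one reference: ``coverage * L / read_len``,
    rounded half-up."""
    if ref_len <= 0 or mean_read_len <= 0:
        raise ValueError("ref_len and mean_read_len must be positive")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    x = coverage * ref_len / mean_read_len
    return int(np.floor(x + 0.5))


def mutation_probability(pos: int | np.ndarray, model: MutationModel) -> float | np.ndarray:
    """Per-position mutation probability at 1-based read position *pos*.

    The polynomial gives a percentage; the probability is capped at 1
    (the quartic term exceeds 100% late in a 250 bp read).
    """
    pos = np.asarray(pos)
    if np.any(pos < 1):
        raise ValueError("positions are 1-based")
    pct = model.base_rate + model.quartic_coeff * pos.astype(float) ** 4
    p = np.minimum(pct / 100.0, 1.0)
    return float(p) if p.ndim == 0 else p


def apply_mutations(
    seq: str, model: MutationModel, rng: np.random.Generator
) -> tuple[str, list[MutationEvent]]:
    """Mutate *seq* position by position under *model*.

    Each 1-based position mutates independently with
    :func:`mutation_probability`; a mutation is a substitution to a
    uniformly chosen different base with probability
    ``substitution_fraction``, otherwise an insertion (uniform base added
    after the position) or a deletion, with equal probability. Indels are
    not length-compensated.
    """
    if not seq:
        raise ValueError("sequence is empty")
    n = len(seq)
    p = mutation_probability(np.arange(1, n + 1), model)
    hit = rng.random(n) < p
    out: list[str] = []
    log: list[MutationEvent] = []
    for i, base in enumerate(seq):
        if not hit[i]:
            out.append(base)
            continue
        if rng.random() < model.substitution_fraction:
            alt = [b for b in "ACGT" if b != base]  # non-ACGT bases can go to any base
            new = alt[rng.integers(len(alt))]
            out.append(new)
            log.append(MutationEvent(i + 1, "sub", base, new))
        elif rng.random() < 0.5:
            ins = str(_BASES[rng.integers(4)])
            out.append(base)
            out.append(ins)
            log.append(MutationEvent(i + 1, "ins", base, base + ins))
        else:
            log.append(MutationEvent(i + 1, "del", base, ""))
    return "".join(out), log


def locate_amplicon(ref: ReferenceSequence, primers: PrimerPair) -> AmpliconSpan | None:
    """First IUPAC-compatible amplicon on the forward strand, or ``None``.

    Searches for the forward primer, then for the reverse complement of
    the reverse primer downstream of it; the returned half-open span
    covers both primer sites.
    """
    fwd = iupac_regex(primers.forward).search(ref.seq)
    if fwd is None:
        return None
    rev_site = iupac_regex(reverse_complement(primers.reverse)).search(ref.seq, fwd.end())
    if rev_site is None:
        return None
    return AmpliconSpan(fwd.start(), rev_site.end())


def _draw_read(
    template: str,
    offset: int,
    model: MutationModel,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Pick a read window inside *template*; returns (subseq, start, length)."""
    max_len = min(model.max_read_len, len(template))
    min_len = min(model.min_read_len, len(template))
    length = int(rng.integers(min_len, max_len + 1))
    start = int(rng.integers(0, len(template) - length + 1))
    return template[start : start + length], offset + start, length


def simulate_shotgun(
    refs: Sequence[ReferenceSequence],
    coverage: float,
    model: MutationModel = MutationModel(),
    seed: int = 0,
) -> list[ShortRead]:
    """Simulate shotgun reads uniformly along each reference, both strands.

    Each reference contributes :func:`reads_per_reference` reads; read
    length is uniform in ``center ± halfwidth``, start uniform over valid
    positions, strand uniform (minus-strand reads are reverse
    complemented), and mutations are applied along the read. Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    reads: list[ShortRead] = []
    for ref in refs:
        if len(ref) < model.max_read_len:
            raise ValueError(
                f"reference {ref.id!r} is {len(ref)} bp, shorter than the "
                f"maximum read length {model.max_read_len}"
            )
        n = reads_per_reference(len(ref), coverage, model.read_len_center)
        for j in range(n):
            sub, _, _ = _draw_read(ref.seq, 0, model, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                sub = reverse_complement(sub)
            mutated, _ = apply_mutations(sub, model, rng)
            reads.append(
                ShortRead(
                    id=f"{ref.id}_sg_{j}",
                    source_id=ref.id,
                    lineage=ref.lineage,
                    seq=mutated,
                    technology="SG",
                    strand=strand,
                )
            )
    return reads


def trim_primers(seq: str, primers: PrimerPair) -> str:
    """Remove a leading forward-primer match and a trailing match of the
    reverse primer's reverse complement (exact IUPAC matching, no
    mismatches — mutated primer bases survive, as with real trimmers)."""
    m = iupac_regex(primers.forward).match(seq)
    if m:
        seq = seq[m.end() :]
    tail = re.compile(iupac_regex(reverse_complement(primers.reverse)).pattern + "$")
    m = tail.search(seq)
    if m:
        seq = seq[: m.start()]
    return seq


def simulate_amplicon(
    refs: Sequence[ReferenceSequence],
    primers: PrimerPair = PrimerPair(),
    coverage: float = 13.0,
    model: MutationModel = MutationModel(),
    seed: int = 0,
    trim: bool = True,
) -> tuple[list[ShortRead], list[str]]:
    """Simulate amplicon reads from the primer-delimited span of each
    reference; returns ``(reads, lost_reference_ids)``.

    References without a primer match contribute no reads and are
    reported in the lost list. Reads are forward-orientation (amplicon
    sequencing is primer-anchored); if the span is shorter than the read
    length the read is truncated to the span. With ``trim``, primer
    sequences are removed from read ends by exact IUPAC matching.
    """
    rng = np.random.default_rng(seed)
    reads: list[ShortRead] = []
    lost: list[str] = []
    for ref in refs:
        if len(ref) < model.max_read_len:
            raise ValueError(
                f"reference {ref.id!r} is {len(ref)} bp, shorter than the "
                f"maximum read length {model.max_read_len}"
            )
        span = locate_amplicon(ref, primers)
        if span is None:
            lost.append(ref.id)
            continue
        amplicon = ref.seq[span.start : span.end]
        n = reads_per_reference(len(ref), coverage, model.read_len_center)
        for j in range(n):
            sub, _, _ = _draw_read(amplicon, span.start, model, rng)
            mutated, _ = apply_mutations(sub, model, rng)
            if trim:
                mutated = trim_primers(mutated, primers)
            reads.append(
                ShortRead(
                    id=f"{ref.id}_amp_{j}",
                    source_id=ref.id,
                    lineage=ref.lineage,
                    seq=mutated,
                    technology="AMP",
                    strand="+",
                )
            )
    return reads, lost
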
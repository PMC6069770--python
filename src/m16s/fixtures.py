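"""Synthetic 16S-like reference pools with a known nested taxonomy.

The generator builds a root gene of alternating conserved and variable
blocks (mimicking the nine hypervariable regions of real 16S genes),
plants the amplicon primer pair verbatim in the conserved blocks flanking
a designated "V3-V4" region, then derives genus ancestors from the root
and species from each genus ancestor by i.i.d. substitutions confined to
the variable blocks. Conserved blocks — primer sites included — are never
mutated, so amplicon coordinates are exact by construction. Divergence is
substitution-only so that block coordinates stay aligned; read-level
indels come from the simulator, not from the references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import reverse_complement

from Bio.Data.IUPACData import ambiguous_dna_values

from .simulate import PrimerPair
from .sequence_io import ReferenceSequence
from .taxonomy import TaxonomyLineage

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True, slots=True)
class FixtureSpec:
    """Geometry and divergence parameters of a synthetic reference pool.

    Divergences are per-site substitution fractions applied to variable
    blocks only: ``genus_divergence`` from the root to each genus
    ancestor, ``species_divergence`` from the ancestor to each species.
    Within-genus sequences are therefore more similar than between-genus
    ones whenever ``species_divergence < genus_divergence``.
    """

    n_genera: int = 10
    species_per_genus: int = 10
    genera_per_family: int = 3
    families_per_order: int = 2
    orders_per_class: int = 2
    seq_len: int = 1500
    n_variable_regions: int = 9
    variable_len: int = 80
    genus_divergence: float = 0.12
    species_divergence: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.species_divergence <= 1 and 0 <= self.genus_divergence <= 1):
            raise ValueError("divergences must lie in [0, 1]")
        if self.species_divergence >= self.genus_divergence and self.genus_divergence > 0:
            raise ValueError("require species_divergence < genus_divergence")
        for name in ("n_genera", "species_per_genus", "genera_per_family",
                     "families_per_order", "orders_per_class"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def generate_binary_patterns(
    n_per_class: int = 1000,
    length: int = 64,
    gap: int = 3,
    noise_bits: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Three-class binary-pattern task probing pattern detection on arrays.

    Class 0 carries a 5-bit motif, class 1 a motif at Hamming distance 1
    from it, and class 2 the two motifs joined by *gap* zeros; the motif
    is planted at a uniformly random admissible offset in an otherwise
    zero vector of *length* bits, and *noise_bits* random positions are
    flipped. Returns ``(X, y)`` with ``X`` float32 of shape
    ``(3 * n_per_class, length)``.
    """
    motif_a = np.array([1, 0, 1, 1, 0], dtype=np.float32)
    motif_b = motif_a.copy()
    motif_b[3] = 0.0  # Hamming distance 1
    motif_c = np.concatenate([motif_a, np.zeros(gap, dtype=np.float32), motif_b])
    rng = np.random.default_rng(seed)
    X = np.zeros((3 * n_per_class, length), dtype=np.float32)
    y = np.repeat(np.arange(3), n_per_class)
    rng.shuffle(y)
    for i, cls in enumerate(y):
        motif = (motif_a, motif_b, motif_c)[cls]
        start = rng.integers(0, length - motif.size + 1)
        X[i, start:start + motif.size] = motif
        if noise_bits:
            flip = rng.choice(length, size=noise_bits, replace=False)
            X[i, flip] = 1.0 - X[i, flip]
    return X, y


def generate_taxonomy(spec: FixtureSpec) -> list[TaxonomyLineage]:
    """One lineage per genus, nested by integer division of the genus index
    (so genus -> family -> order -> class are exact functions)."""
    lineages = []
    for g in range(spec.n_genera):
        fam = g // spec.genera_per_family
        order = fam // spec.families_per_order
        cls = order // spec.orders_per_class
        lineages.append(
            TaxonomyLineage(
                phylum="Synthophyla",
                class_=f"Class{cls:02d}",
                order=f"Order{order:02d}",
                family=f"Family{fam:02d}",
                genus=f"Genus{g:03d}",
            )
        )
    return lineages


def _mutate_sites(seq: np.ndarray, mask: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Substitute a *rate* fraction of the positions where *mask* is set,
    each to a uniformly chosen different base."""
    out = seq.copy()
    sites = np.flatnonzero(mask & (rng.random(seq.size) < rate))
    for i in sites:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def _concrete_instance(iupac: str, rng: np.random.Generator) -> np.ndarray:
    """Resolve each degenerate IUPAC position to a concrete base."""
    out = []
    for c in iupac.upper():
        opts = ambiguous_dna_values[c]
        out.append(opts if len(opts) == 1 else opts[rng.integers(len(opts))])
    return np.frombuffer("".join(out).encode(), dtype=np.uint8)


def _layout(spec: FixtureSpec, primers: PrimerPair):
    """Block layout: conserved_len per block, variable-block start offsets."""
    n_var = spec.n_variable_regions
    var_total = n_var * spec.variable_len
    n_cons = n_var + 1
    cons_total = spec.seq_len - var_total
    cons_len = cons_total // n_cons
    min_cons = max(len(primers.forward), len(primers.reverse)) + 2
    if cons_len < min_cons:
        raise ValueError(
            f"seq_len={spec.seq_len} too small: need >= "
            f"{var_total + n_cons * min_cons} bp for {n_var} variable blocks "
            f"of {spec.variable_len} bp with primer-hosting conserved blocks"
        )
    starts = [cons_len * (i + 1) + spec.variable_len * i for i in range(n_var)]
    return cons_len, starts


def generate_references(
    spec: FixtureSpec, primers: PrimerPair = PrimerPair()
) -> list[ReferenceSequence]:
    """Generate ``n_genera * species_per_genus`` labelled references.

    The forward primer is embedded at the end of the conserved block
    preceding variable block 2 (0-based) and the reverse-complemented
    reverse primer at the start of the conserved block following variable
    block 3, so the amplicon spans two variable regions plus the conserved
    block between them, like the real V3-V4 target. Reproducible for a
    fixed ``spec.seed``.
    """
    if spec.n_variable_regions < 4:
        raise ValueError("need at least 4 variable regions to host the amplicon")
    cons_len, var_starts = _layout(spec, primers)
    rng = np.random.default_rng(spec.seed)

    root = _BASES[rng.integers(4, size=spec.seq_len)]
    # variable-site mask
    var_mask = np.zeros(spec.seq_len, dtype=bool)
    for s in var_starts:
        var_mask[s:s + spec.variable_len] = True

    # degenerate primer positions are resolved to one concrete instance
    # (the same for every reference, since primer sites sit in conserved blocks)
    fwd = _concrete_instance(primers.forward, rng)
    rev_site = _concrete_instance(reverse_complement(primers.reverse), rng)
    # forward primer ends right where variable block 2 starts
    f_start = var_starts[2] - len(fwd)
    root[f_start:var_starts[2]] = fwd
    # reverse site begins right after variable block 3 ends
    r_start = var_starts[3] + spec.variable_len
    root[r_start:r_start + len(rev_site)] = rev_site

    lineages = generate_taxonomy(spec)
    refs: list[ReferenceSequence] = []
    for g, lineage in enumerate(lineages):
        ancestor = _mutate_sites(root, var_mask, spec.genus_divergence, rng)
        for s in range(spec.species_per_genus):
            seq = _mutate_sites(ancestor, var_mask, spec.species_divergence, rng)
            refs.append(
                ReferenceSequence(
                    id=f"ref_g{g:03d}_s{s:02d}",
                    lineage=lineage,
                    seq=seq.tobytes().decode("ascii"),
                )
            )
    return refs
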
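"""Synthetic ChIP and control fragment sets over a toy repeat-family genome.

Fragment centers are drawn from a mixture of a genome-wide uniform background
and per-element enrichment components (triangular windows around fixed
element-relative offsets, emulating promoter-proximal occupancy peaks).
Fragment lengths are uniform on a 200-500 bp range, matching the size range
of sonicated chromatin analyzed in ChIP experiments.  Enrichment components
are placed on full-length copies only: solo-LTR remnants receive signal
exclusively through the shared-sequence candidate lists, which is precisely
the read-assignment ambiguity the downstream profiler must cope with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fragments import FragmentAlignment
from .genome import GenomeModel

__all__ = [
    "EnrichmentComponent",
    "EnrichmentSpec",
    "simulate_fragments",
    "simulate_control",
]


@dataclass(frozen=True)
class EnrichmentComponent:
    """Element-relative peak: center offset (bp), weight, triangular half-width (bp)."""

    center: int
    weight: float
    spread: int = 50

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("component weight must be nonnegative")
        if self.spread < 0:
            raise ValueError("component spread must be nonnegative")


@dataclass(frozen=True)
class EnrichmentSpec:
    components: tuple[EnrichmentComponent, ...] = ()
    background_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.background_weight < 0:
            raise ValueError("background_weight must be nonnegative")
        total = self.background_weight + sum(c.weight for c in self.components)
        if total <= 0:
            raise ValueError("total mixture weight must be positive")


BACKGROUND_ONLY = EnrichmentSpec(components=(), background_weight=1.0)


def simulate_fragments(
    genome: GenomeModel,
    spec: EnrichmentSpec,
    n_fragments: int,
    frag_len_range: tuple[int, int] = (200, 500),
    seed: int = 0,
    sample: str = "IP",
) -> list[FragmentAlignment]:
    """Draw ``n_fragments`` fragments and attach their candidate-locus lists.

    Deterministic for a given seed.  Every fragment's true locus is a member
    of its own candidate list; fragments crossing an element/background
    junction are unique by construction.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be >= 0")
    lmin, lmax = frag_len_range
    if lmin <= 0 or lmin > lmax:
        raise ValueError(f"invalid frag_len_range {frag_len_range}")
    if not genome.chrom_lengths:
        raise ValueError("genome has no chromosomes")
    full = genome.full_copies
    for comp in spec.components:
        for e in full:
            if not (0 <= comp.center < e.length):
                raise ValueError(
                    f"component center {comp.center} outside element {e.copy_id}"
                )

    # mixture entries: index 0 = background, then (copy, component) pairs
    entries: list[tuple] = [("bg", None)]
    weights = [spec.background_weight]
    for e in full:
        for comp in spec.components:
            entries.append((e, comp))
            weights.append(comp.weight)
    probs = np.asarray(weights, dtype=float)
    probs /= probs.sum()

    rng = np.random.default_rng(seed)
    which = rng.choice(len(entries), size=n_fragments, p=probs)
    lengths = rng.integers(lmin, lmax + 1, size=n_fragments)
    # draw all per-fragment variates up front so the stream layout is fixed
    u_genome = rng.integers(0, genome.total_length, size=n_fragments)
    tri = rng.triangular(-1.0, 0.0, 1.0, size=n_fragments)

    chroms = list(genome.chrom_lengths)
    cum = np.cumsum([genome.chrom_lengths[c] for c in chroms])

    out: list[FragmentAlignment] = []
    for i in range(n_fragments):
        length = int(lengths[i])
        entry = entries[which[i]]
        if entry[0] == "bg":
            ci = int(np.searchsorted(cum, u_genome[i], side="right"))
            chrom = chroms[ci]
            center = int(u_genome[i]) - (int(cum[ci - 1]) if ci else 0)
        else:
            e, comp = entry
            rel = int(round(comp.center + tri[i] * comp.spread))
            rel = min(max(rel, 0), e.length - 1)
            chrom = e.chrom
            center = e.start + rel if e.strand == "+" else e.end - 1 - rel
        clen = genome.chrom_lengths[chrom]
        start = min(max(center - length // 2, 0), clen - length)
        cands = genome.candidate_loci(chrom, start, length)
        host = genome.containing_element(chrom, start, length)
        true_strand = host.strand if host is not None else "+"
        true_index = cands.index((chrom, start, true_strand))
        out.append(
            FragmentAlignment(
                fragment_id=f"{sample}-{i:07d}",
                sample=sample,
                length=length,
                candidates=tuple(cands),
                true_index=true_index,
            )
        )
    return out


def simulate_control(
    genome: GenomeModel,
    n_fragments: int,
    frag_len_range: tuple[int, int] = (200, 500),
    seed: int = 0,
    sample: str = "control",
) -> list[FragmentAlignment]:
    """Untagged-control fragments: uniform background, no enrichment."""
    return simulate_fragments(
        genome, BACKGROUND_ONLY, n_fragments, frag_len_range, seed, sample=sample
    )
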
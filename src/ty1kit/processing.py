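"""Fragment processing: duplicate removal, random multimapper assignment,
fragment pileup, and untagged-control normalization.

The order of operations matters and is deliberate: duplicates are collapsed
*before* random assignment, keyed on (length, candidate set).  PCR duplicates
of the same molecule share identical mapping ambiguity, so deduplicating on
the post-assignment locus would stochastically retain duplicates that happened
to be assigned to different copies.  The alternative order (assign first,
dedup on assigned endpoints) is available via ``order="assign-first"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fragments import FragmentAlignment
from .genome import GenomeModel

__all__ = [
    "CoverageTrack",
    "dedup_fragments",
    "assign_multimappers",
    "compute_coverage",
    "per_million",
    "normalize_to_control",
    "process_fragments",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass
class CoverageTrack:
    """Per-base-pair occupancy, one dense float vector per chromosome."""

    data: dict[str, np.ndarray]
    sample: str
    total_fragments: int
    scale: str = "raw"  # "raw" | "per-million" | "ratio"

    def sum(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}


def dedup_fragments(
    fragments: Sequence[FragmentAlignment], on: str = "candidates"
) -> list[FragmentAlignment]:
    """Collapse duplicate fragments, keeping the first occurrence (stable order).

    Two fragments are duplicates iff they have identical length and identical
    candidate sets (order-insensitive).  With ``on="assigned"`` the key is the
    assigned locus instead (requires assigned fragments).
    """
    if on not in ("candidates", "assigned"):
        raise ValueError("on must be 'candidates' or 'assigned'")
    seen: set = set()
    out: list[FragmentAlignment] = []
    for f in fragments:
        if on == "candidates":
            key = (f.length, frozenset(f.candidates))
        else:
            key = (f.length, f.assigned_locus)
        if key not in seen:
            seen.add(key)
            out.append(f)
    return out


def assign_multimappers(
    fragments: Sequence[FragmentAlignment], seed: int = 0
) -> list[FragmentAlignment]:
    """Assign every fragment uniformly at random among its candidate loci.

    Input is not mutated; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    out: list[FragmentAlignment] = []
    for f in fragments:
        k = len(f.candidates)
        idx = 0 if k == 1 else int(rng.integers(0, k))
        out.append(f.with_assigned(idx))
    return out


def _chrom_lengths_of(genome: GenomeModel | Mapping[str, int]) -> dict[str, int]:
    if isinstance(genome, GenomeModel):
        return dict(genome.chrom_lengths)
    return dict(genome)


def compute_coverage(
    fragments: Sequence[FragmentAlignment],
    genome: GenomeModel | Mapping[str, int],
    sample: str | None = None,
) -> CoverageTrack:
    """Fragment pileup: each fragment adds 1 over its assigned interval.

    The raw track sum equals the summed lengths of the assigned fragments.
    """
    chrom_lengths = _chrom_lengths_of(genome)
    # difference-array accumulation, then cumulative sum per chromosome
    diffs = {c: np.zeros(n + 1, dtype=np.float64) for c, n in chrom_lengths.items()}
    label = sample
    for f in fragments:
        chrom, start, _ = f.assigned_locus
        if chrom not in diffs:
            raise ValueError(f"{f.fragment_id}: unknown chromosome {chrom!r}")
        end = start + f.length
        if start < 0 or end > chrom_lengths[chrom]:
            raise ValueError(
                f"{f.fragment_id}: interval [{start}, {end}) outside {chrom} "
                f"(length {chrom_lengths[chrom]})"
            )
        diffs[chrom][start] += 1.0
        diffs[chrom][end] -= 1.0
        if label is None:
            label = f.sample
    data = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return CoverageTrack(
        data=data, sample=label or "", total_fragments=len(fragments), scale="raw"
    )


def per_million(track: CoverageTrack) -> CoverageTrack:
    """Depth normalization: coverage per million assigned fragments."""
    if track.total_fragments <= 0:
        raise ValueError("track has no fragments; cannot depth-normalize")
    factor = 1e6 / track.total_fragments
    return CoverageTrack(
        data={c: v * factor for c, v in track.data.items()},
        sample=track.sample,
        total_fragments=track.total_fragments,
        scale="per-million",
    )


def normalize_to_control(
    ip: CoverageTrack,
    control: CoverageTrack,
    pseudocount: float = 0.5,
    mode: str = "ratio",
) -> CoverageTrack:
    """Normalize an IP track to an untagged control.

    Both tracks are scaled to coverage per million fragments; ``ratio`` mode
    then forms (ip + pseudocount) / (control + pseudocount) per base pair,
    ``subtract`` mode forms ip - control.  The pseudocount is in per-million
    coverage units.
    """
    if mode not in ("ratio", "subtract"):
        raise ValueError("mode must be 'ratio' or 'subtract'")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if ip.chrom_lengths() != control.chrom_lengths():
        raise ValueError("IP and control tracks cover different chromosomes")
    ip_pm = per_million(ip) if ip.scale == "raw" else ip
    ct_pm = per_million(control) if control.scale == "raw" else control
    data: dict[str, np.ndarray] = {}
    for chrom, ipv in ip_pm.data.items():
        ctv = ct_pm.data[chrom]
        if mode == "subtract":
            data[chrom] = ipv - ctv
        else:
            if pseudocount == 0 and (ctv == 0).any():
                raise ValueError(
                    f"control coverage is zero at some positions on {chrom}; "
                    "use a positive pseudocount"
                )
            data[chrom] = (ipv + pseudocount) / (ctv + pseudocount)
    return CoverageTrack(
        data=data,
        sample=f"{ip.sample}/{control.sample}" if mode == "ratio" else ip.sample,
        total_fragments=ip.total_fragments,
        scale="ratio",
    )


def process_fragments(
    fragments: Sequence[FragmentAlignment],
    genome: GenomeModel | Mapping[str, int],
    seed: int = 0,
    order: str = "dedup-first",
) -> tuple[CoverageTrack, list[FragmentAlignment]]:
    """Dedup + assign + pileup in one call; returns (raw track, assigned fragments)."""
    if order == "dedup-first":
        frs = assign_multimappers(dedup_fragments(fragments), seed=seed)
    elif order == "assign-first":
        frs = dedup_fragments(assign_multimappers(fragments, seed=seed), on="assigned")
    else:
        raise ValueError("order must be 'dedup-first' or 'assign-first'")
    return compute_coverage(frs, genome), frs


# ---------------------------------------------------------------------------
# bedGraph I/O (0-based half-open, run-length merged)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, values in track.data.items():
            if len(values) == 0:
                continue
            breaks = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(values)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{values[s]:.6g}\n")


def read_bedgraph(
    path,
    chrom_lengths: Mapping[str, int],
    sample: str = "",
    total_fragments: int = 0,
    scale: str = "ratio",
) -> CoverageTrack:
    data = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split("\t")
            data[chrom][int(s) : int(e)] = float(v)
    return CoverageTrack(
        data=data, sample=sample, total_fragments=total_fragments, scale=scale
    )
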
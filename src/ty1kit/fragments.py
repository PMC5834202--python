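"""Sequenced-fragment alignments with explicit multimapping candidate lists.

A fragment is an unstranded genomic interval of known length; instead of a
single mapped position it carries the list of loci it maps to equally well
(identical sequence).  ``assigned`` is set only after random assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "FragmentAlignment",
    "write_fragments_tsv",
    "read_fragments_tsv",
    "write_loci_bed",
]

Locus = tuple[str, int, str]


@dataclass(frozen=True)
class FragmentAlignment:
    fragment_id: str
    sample: str
    length: int
    candidates: tuple[Locus, ...]
    assigned: int | None = None
    true_index: int | None = None  # ground truth, set by the simulator only

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.fragment_id}: length must be positive")
        if not self.candidates:
            raise ValueError(f"{self.fragment_id}: candidate list is empty")
        for idx, name in ((self.assigned, "assigned"), (self.true_index, "true_index")):
            if idx is not None and not (0 <= idx < len(self.candidates)):
                raise ValueError(f"{self.fragment_id}: {name} index out of range")

    @property
    def assigned_locus(self) -> Locus:
        if self.assigned is None:
            raise ValueError(f"{self.fragment_id}: fragment has not been assigned")
        return self.candidates[self.assigned]

    @property
    def true_locus(self) -> Locus | None:
        return None if self.true_index is None else self.candidates[self.true_index]

    def with_assigned(self, index: int) -> "FragmentAlignment":
        return replace(self, assigned=index)


def _fmt_locus(locus: Locus) -> str:
    return f"{locus[0]}:{locus[1]}:{locus[2]}"


def _parse_locus(text: str) -> Locus:
    chrom, start, strand = text.rsplit(":", 2)
    return (chrom, int(start), strand)


def write_fragments_tsv(fragments: Iterable[FragmentAlignment], path) -> None:
    """Columns: fragment_id, sample, length, candidates (semicolon-separated
    chrom:start:strand), assigned, true_index ('.' when unset)."""
    with open(path, "w") as fh:
        fh.write("fragment_id\tsample\tlength\tcandidates\tassigned\ttrue_index\n")
        for f in fragments:
            cand = ";".join(_fmt_locus(c) for c in f.candidates)
            a = "." if f.assigned is None else str(f.assigned)
            t = "." if f.true_index is None else str(f.true_index)
            fh.write(f"{f.fragment_id}\t{f.sample}\t{f.length}\t{cand}\t{a}\t{t}\n")


def read_fragments_tsv(path) -> list[FragmentAlignment]:
    out: list[FragmentAlignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            a = parts[col["assigned"]] if "assigned" in col else "."
            t = parts[col["true_index"]] if "true_index" in col else "."
            out.append(
                FragmentAlignment(
                    fragment_id=parts[col["fragment_id"]],
                    sample=parts[col["sample"]],
                    length=int(parts[col["length"]]),
                    candidates=tuple(
                        _parse_locus(c) for c in parts[col["candidates"]].split(";")
                    ),
                    assigned=None if a == "." else int(a),
                    true_index=None if t == "." else int(t),
                )
            )
    return out


def write_loci_bed(
    fragments: Sequence[FragmentAlignment], path, which: str = "assigned"
) -> None:
    """BED6 of assigned (or true) fragment intervals; score = candidate count."""
    if which not in ("assigned", "true"):
        raise ValueError("which must be 'assigned' or 'true'")
    with open(path, "w") as fh:
        for f in fragments:
            locus = f.assigned_locus if which == "assigned" else f.true_locus
            if locus is None:
                raise ValueError(f"{f.fragment_id}: no true locus recorded")
            chrom, start, strand = locus
            fh.write(
                f"{chrom}\t{start}\t{start + f.length}\t{f.fragment_id}\t{len(f.candidates)}\t{strand}\n"
            )
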
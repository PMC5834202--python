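"""Toy genomes carrying a repeated LTR-retrotransposon family.

The genome model captures the one structural fact that makes repeat-family
ChIP analysis hard: full-length elements are (near-)identical to each other,
and their long terminal repeats (LTRs) are additionally identical to the 5'
LTR, the 3' LTR, and every solo-LTR remnant in the genome.  A sequencing
fragment that lies wholly inside a shared region therefore maps equally well
to every copy of that region, and this ambiguity is recorded explicitly as
``identity_groups`` rather than rediscovered by sequence search.

Coordinates are 0-based, half-open throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ElementCopy",
    "IdentityMember",
    "IdentityGroup",
    "GenomeModel",
    "build_toy_genome",
    "write_fasta",
    "read_fasta",
    "write_elements_bed",
    "read_elements_bed",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_KMER_K = 32  # uniqueness screened at k=32; implies uniqueness at any k >= 32


@dataclass(frozen=True)
class ElementCopy:
    """One genomic copy of the element family (full-length or solo LTR)."""

    chrom: str
    start: int
    end: int
    strand: str
    copy_class: str  # "full" | "solo_ltr"
    copy_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.copy_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.copy_id}: strand must be '+' or '-'")
        if self.copy_class not in ("full", "solo_ltr"):
            raise ValueError(f"{self.copy_id}: unknown copy_class {self.copy_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IdentityMember:
    """Maps an interval of a group's canonical sequence into one copy.

    The canonical interval [canon_start, canon_end) is identical, base for
    base, to the copy-relative interval starting at ``copy_rel_start`` (copy
    coordinates run 5'->3' of the element regardless of genomic strand).
    """

    copy_id: str
    canon_start: int
    canon_end: int
    copy_rel_start: int


@dataclass(frozen=True)
class IdentityGroup:
    name: str
    canon_len: int
    members: tuple[IdentityMember, ...]


@dataclass
class GenomeModel:
    """Chromosome sizes, element copies, and their sequence-identity structure."""

    chrom_lengths: dict[str, int]
    elements: list[ElementCopy]
    ltr_len: int
    tss_offset: int = 238
    internal_tss_offset: int = 1000
    tes_offset: int = 0
    identity_groups: list[IdentityGroup] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict | None = None
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        seen_ids: set[str] = set()
        by_chrom: dict[str, list[ElementCopy]] = {}
        for e in self.elements:
            if e.copy_id in seen_ids:
                raise ValueError(f"duplicate copy_id {e.copy_id!r}")
            seen_ids.add(e.copy_id)
            if e.chrom not in self.chrom_lengths:
                raise ValueError(f"{e.copy_id}: unknown chromosome {e.chrom!r}")
            if e.end > self.chrom_lengths[e.chrom]:
                raise ValueError(f"{e.copy_id}: extends past end of {e.chrom}")
            if e.copy_class == "full":
                if e.length < 2 * self.ltr_len:
                    raise ValueError(f"{e.copy_id}: full copy shorter than two LTRs")
                if not (self.tss_offset < self.internal_tss_offset < e.length):
                    raise ValueError(f"{e.copy_id}: TSS offsets inconsistent with length")
            else:
                if e.length > self.ltr_len:
                    raise ValueError(f"{e.copy_id}: solo LTR longer than ltr_len")
            by_chrom.setdefault(e.chrom, []).append(e)
        if self.tss_offset >= self.ltr_len:
            raise ValueError("tss_offset must lie inside the 5' LTR")
        for chrom, elems in by_chrom.items():
            elems = sorted(elems, key=lambda e: e.start)
            for a, b in zip(elems, elems[1:]):
                if b.start < a.end:
                    raise ValueError(f"elements {a.copy_id} and {b.copy_id} overlap on {chrom}")

    # -- convenience --------------------------------------------------------

    @property
    def full_copies(self) -> list[ElementCopy]:
        return [e for e in self.elements if e.copy_class == "full"]

    @property
    def solo_copies(self) -> list[ElementCopy]:
        return [e for e in self.elements if e.copy_class == "solo_ltr"]

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def copy_by_id(self, copy_id: str) -> ElementCopy:
        self._ensure_index()
        return self._index["by_id"][copy_id]

    # -- candidate loci -----------------------------------------------------

    def _ensure_index(self) -> None:
        if self._index is not None:
            return
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[ElementCopy]]] = {}
        for chrom in self.chrom_lengths:
            elems = sorted(
                (e for e in self.elements if e.chrom == chrom), key=lambda e: e.start
            )
            starts = np.array([e.start for e in elems], dtype=np.int64)
            ends = np.array([e.end for e in elems], dtype=np.int64)
            by_chrom[chrom] = (starts, ends, elems)
        groups_of: dict[str, list[tuple[IdentityGroup, IdentityMember]]] = {}
        for g in self.identity_groups:
            for m in g.members:
                groups_of.setdefault(m.copy_id, []).append((g, m))
        self._index = {
            "by_chrom": by_chrom,
            "by_id": {e.copy_id: e for e in self.elements},
            "groups_of": groups_of,
        }

    def containing_element(self, chrom: str, start: int, length: int) -> ElementCopy | None:
        """The element copy whose interval fully contains [start, start+length)."""
        self._ensure_index()
        starts, ends, elems = self._index["by_chrom"][chrom]
        i = int(np.searchsorted(starts, start, side="right")) - 1
        if i >= 0 and start >= starts[i] and start + length <= ends[i]:
            return elems[i]
        return None

    def candidate_loci(self, chrom: str, start: int, length: int) -> list[tuple[str, int, str]]:
        """All genomic loci whose sequence is identical to [start, start+length).

        Fragments that are not wholly contained in an element map uniquely
        (background sequence is unique by construction); fragments wholly
        inside a shared identity interval list the corresponding position in
        every other copy of that interval.  Sorted by (chrom, start, strand).
        """
        if length <= 0:
            raise ValueError("fragment length must be positive")
        host = self.containing_element(chrom, start, length)
        if host is None:
            return [(chrom, start, "+")]
        # element-relative interval, 5'->3' of the element
        if host.strand == "+":
            a = start - host.start
        else:
            a = host.end - (start + length)
        b = a + length
        self._ensure_index()
        by_id = self._index["by_id"]
        found: set[tuple[str, int, str]] = set()
        for group, member in self._index["groups_of"].get(host.copy_id, []):
            ca = member.canon_start + (a - member.copy_rel_start)
            cb = ca + length
            if a < member.copy_rel_start or cb > member.canon_end:
                continue  # fragment not wholly within this member's interval
            for m2 in group.members:
                if ca < m2.canon_start or cb > m2.canon_end:
                    continue
                a2 = m2.copy_rel_start + (ca - m2.canon_start)
                tgt = by_id[m2.copy_id]
                if tgt.strand == "+":
                    g = tgt.start + a2
                else:
                    g = tgt.end - a2 - length
                found.add((tgt.chrom, int(g), tgt.strand))
        if not found:
            # contained in an element but outside every shared interval
            # cannot happen with the standard groups, but stay safe
            found.add((chrom, start, host.strand))
        return sorted(found)


# ---------------------------------------------------------------------------
# construction


def _build_identity_groups(
    full: Sequence[ElementCopy], solo: Sequence[ElementCopy], element_len: int, ltr_len: int
) -> list[IdentityGroup]:
    body_members = tuple(
        IdentityMember(e.copy_id, 0, element_len, 0) for e in full
    )
    ltr_members: list[IdentityMember] = []
    for e in full:
        ltr_members.append(IdentityMember(e.copy_id, 0, ltr_len, 0))
        ltr_members.append(IdentityMember(e.copy_id, 0, ltr_len, element_len - ltr_len))
    for e in solo:
        # solo LTRs are prefixes of the canonical LTR
        ltr_members.append(IdentityMember(e.copy_id, 0, e.length, 0))
    groups = [IdentityGroup("element_body", element_len, body_members)]
    if ltr_members:
        groups.append(IdentityGroup("ltr", ltr_len, tuple(ltr_members)))
    return groups


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def _decode(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode()


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def _kmer_codes(codes: np.ndarray, k: int = _KMER_K) -> np.ndarray:
    """2-bit-pack every k-mer of a coded sequence into a uint64 (exact for k<=32)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | c64[j : j + n]
    return out


def _place_on_chromosomes(
    lengths: Sequence[int],
    chrom_lengths: Mapping[str, int],
    gap: int,
    rng: np.random.Generator,
    max_retries: int,
) -> list[tuple[str, int]]:
    """Uniform-ish placement with a minimum gap between elements and edges.

    Elements are assigned to chromosomes (capacity permitting) and laid out
    left to right with random slack distributed between them, which places
    every configuration in one pass instead of rejection-sampling intervals.
    """
    n = len(lengths)
    chroms = list(chrom_lengths)
    for _ in range(max_retries):
        order = rng.permutation(n)
        assignment: dict[str, list[int]] = {c: [] for c in chroms}
        used = {c: gap for c in chroms}  # leading gap
        ok = True
        for idx in order:
            need = lengths[idx] + gap
            open_chroms = [c for c in chroms if used[c] + need <= chrom_lengths[c]]
            if not open_chroms:
                ok = False
                break
            weights = np.array(
                [chrom_lengths[c] - used[c] for c in open_chroms], dtype=float
            )
            c = open_chroms[rng.choice(len(open_chroms), p=weights / weights.sum())]
            assignment[c].append(int(idx))
            used[c] += need
        if not ok:
            continue
        placements: list[tuple[str, int] | None] = [None] * n
        for c in chroms:
            idxs = assignment[c]
            if not idxs:
                continue
            k = len(idxs)
            slack = chrom_lengths[c] - sum(lengths[i] for i in idxs) - (k + 1) * gap
            w = rng.random(k + 1)
            extra = np.floor(w / w.sum() * slack).astype(int)
            pos = gap + int(extra[0])
            for j, idx in enumerate(idxs):
                placements[idx] = (c, pos)
                pos += lengths[idx] + gap + int(extra[j + 1])
        return placements  # type: ignore[return-value]
    raise RuntimeError(
        f"could not place {n} elements with gap {gap} bp on chromosomes "
        f"{dict(chrom_lengths)} after {max_retries} attempts; "
        "increase chromosome lengths or reduce copy number"
    )


def build_toy_genome(
    n_full: int,
    n_solo: int,
    element_len: int = 5918,
    ltr_len: int = 334,
    chrom_template: Mapping[str, int] | None = None,
    seed: int = 0,
    *,
    min_frag_len: int = 200,
    max_frag_len: int = 500,
    solo_len_range: tuple[int, int | None] = (150, None),
    tss_offset: int = 238,
    internal_tss_offset: int = 1000,
    tes_offset: int = 0,
    max_retries: int = 100,
) -> tuple[GenomeModel, dict[str, str]]:
    """Build a genome with ``n_full`` identical full-length elements and
    ``n_solo`` solo-LTR remnants, plus a random background sequence that is
    guaranteed to share no k-mer of the minimum fragment length with the
    element (screened exactly at k=32, which is stricter).

    Returns the :class:`GenomeModel` and a dict of chromosome sequences.
    Deterministic for a given seed.
    """
    if n_full < 1:
        raise ValueError("n_full must be >= 1")
    if n_solo < 0:
        raise ValueError("n_solo must be >= 0")
    if element_len <= 2 * ltr_len:
        raise ValueError("element_len must exceed twice ltr_len")
    if not (tss_offset < internal_tss_offset < element_len):
        raise ValueError("require tss_offset < internal_tss_offset < element_len")
    if tss_offset >= ltr_len:
        raise ValueError("tss_offset must lie inside the 5' LTR")
    if min_frag_len < _KMER_K:
        raise ValueError(f"min_frag_len must be >= {_KMER_K}")

    rng = np.random.default_rng(seed)
    solo_hi = solo_len_range[1] if solo_len_range[1] is not None else ltr_len
    if not (1 <= solo_len_range[0] <= solo_hi <= ltr_len):
        raise ValueError("solo_len_range must lie within [1, ltr_len]")
    solo_lens = (
        rng.integers(solo_len_range[0], solo_hi + 1, size=n_solo).tolist()
        if n_solo
        else []
    )
    lengths = [element_len] * n_full + solo_lens
    gap = max_frag_len

    if chrom_template is None:
        needed = sum(lengths) + (len(lengths) + 1) * gap
        chrom_lengths = {"chrI": int(needed * 1.5) + 8000}
    else:
        chrom_lengths = dict(chrom_template)

    placements = _place_on_chromosomes(lengths, chrom_lengths, gap, rng, max_retries)
    strands = rng.choice(np.array(["+", "-"]), size=len(lengths))

    elements: list[ElementCopy] = []
    for i in range(n_full):
        chrom, start = placements[i]
        elements.append(
            ElementCopy(chrom, start, start + element_len, str(strands[i]), "full", f"full-{i + 1:03d}")
        )
    for j in range(n_solo):
        chrom, start = placements[n_full + j]
        elements.append(
            ElementCopy(
                chrom, start, start + solo_lens[j], str(strands[n_full + j]), "solo_ltr", f"solo-{j + 1:03d}"
            )
        )

    # one canonical element sequence; 3' LTR duplicates the 5' LTR
    elem_codes = rng.integers(0, 4, size=element_len, dtype=np.uint8)
    elem_codes[element_len - ltr_len :] = elem_codes[:ltr_len]
    forbidden = set(_kmer_codes(elem_codes).tolist())
    forbidden.update(_kmer_codes(_revcomp(elem_codes)).tolist())

    sequences: dict[str, str] = {}
    by_chrom: dict[str, list[ElementCopy]] = {}
    for e in elements:
        by_chrom.setdefault(e.chrom, []).append(e)
    for chrom, clen in chrom_lengths.items():
        bg = None
        for _ in range(max_retries):
            cand = rng.integers(0, 4, size=clen, dtype=np.uint8)
            hits = np.isin(_kmer_codes(cand), np.fromiter(forbidden, dtype=np.uint64))
            if not hits.any():
                bg = cand
                break
        if bg is None:
            raise RuntimeError(
                f"could not generate element-free background for {chrom} "
                f"after {max_retries} attempts"
            )
        for e in by_chrom.get(chrom, []):
            sub = elem_codes[: e.length].copy()
            if e.strand == "-":
                sub = _revcomp(sub)
            bg[e.start : e.end] = sub
        sequences[chrom] = _decode(bg)

    model = GenomeModel(
        chrom_lengths=chrom_lengths,
        elements=sorted(elements, key=lambda e: (e.chrom, e.start)),
        ltr_len=ltr_len,
        tss_offset=tss_offset,
        internal_tss_offset=internal_tss_offset,
        tes_offset=tes_offset,
        identity_groups=_build_identity_groups(
            [e for e in elements if e.copy_class == "full"],
            [e for e in elements if e.copy_class == "solo_ltr"],
            element_len,
            ltr_len,
        ),
    )
    return model, sequences


# ---------------------------------------------------------------------------
# serialization

_CLASS_SCORE = {"full": 1, "solo_ltr": 2}
_SCORE_CLASS = {v: k for k, v in _CLASS_SCORE.items()}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_elements_bed(model: GenomeModel, path) -> None:
    """BED6; name = copy_id, score encodes copy_class (1 full, 2 solo LTR)."""
    with open(path, "w") as fh:
        for e in model.elements:
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{e.copy_id}\t{_CLASS_SCORE[e.copy_class]}\t{e.strand}\n"
            )


def read_elements_bed(path) -> list[ElementCopy]:
    out: list[ElementCopy] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            out.append(
                ElementCopy(chrom, int(start), int(end), strand, _SCORE_CLASS[int(score)], name)
            )
    return out


def model_to_dict(model: GenomeModel) -> dict:
    return {
        "chrom_lengths": dict(model.chrom_lengths),
        "ltr_len": model.ltr_len,
        "tss_offset": model.tss_offset,
        "internal_tss_offset": model.internal_tss_offset,
        "tes_offset": model.tes_offset,
        "elements": [
            {
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "strand": e.strand,
                "copy_class": e.copy_class,
                "copy_id": e.copy_id,
            }
            for e in model.elements
        ],
        "identity_groups": [
            {
                "name": g.name,
                "canon_len": g.canon_len,
                "members": [
                    [m.copy_id, m.canon_start, m.canon_end, m.copy_rel_start]
                    for m in g.members
                ],
            }
            for g in model.identity_groups
        ],
    }


def model_from_dict(d: Mapping) -> GenomeModel:
    return GenomeModel(
        chrom_lengths=dict(d["chrom_lengths"]),
        elements=[ElementCopy(**e) for e in d["elements"]],
        ltr_len=d["ltr_len"],
        tss_offset=d["tss_offset"],
        internal_tss_offset=d["internal_tss_offset"],
        tes_offset=d["tes_offset"],
        identity_groups=[
            IdentityGroup(
                g["name"],
                g["canon_len"],
                tuple(IdentityMember(*m) for m in g["members"]),
            )
            for g in d["identity_groups"]
        ],
    )
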
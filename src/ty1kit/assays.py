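"""Retromobility frequency, blot densitometry, and semi-quantitative RT-PCR
fold arithmetic.

Retromobility is the fraction of cells in a culture that sustained a marked
retrotransposition event, measured as the ratio of event-derived (e.g. His+)
colony-forming units to total colony-forming units.  Cultures with no events
anywhere are reported as a censored *upper limit* equal to 1 over the total
CFU assayed across all biological replicates, never as zero frequency with
false precision.

The RT-PCR estimate combines two multiplicative factors: a per-cycle
amplification factor raised to the observed cycle offset between target and
reference, and a molar correction for amplicon length (equal mass signal of
a long and a short amplicon means a molar excess of the short species).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlateCount",
    "MobilityResult",
    "FoldChange",
    "FoldEstimate",
    "BandQuant",
    "cfu_in_culture",
    "mobility_frequency",
    "summarize_strain",
    "summarize_counts",
    "counts_from_table",
    "fold_change",
    "relative_level",
    "quantify_bands",
    "cycle_offset_fold",
    "molar_correction",
    "combined_abundance",
]


# ---------------------------------------------------------------------------
# retromobility frequency


@dataclass(frozen=True)
class PlateCount:
    strain: str
    bio_rep: int
    tech_rep: int
    plate_type: str  # "permissive" | "selective"
    colonies: int
    volume_plated_ul: float
    dilution_factor: float = 1.0
    culture_volume_ul: float = 1000.0

    def __post_init__(self) -> None:
        if self.plate_type not in ("permissive", "selective"):
            raise ValueError(f"unknown plate_type {self.plate_type!r}")
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")
        if self.volume_plated_ul <= 0 or self.culture_volume_ul <= 0:
            raise ValueError("volumes must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


def cfu_in_culture(count: PlateCount) -> float:
    """Whole-culture CFU implied by one plate:
    colonies x dilution_factor x (culture_volume / volume_plated)."""
    if count.plate_type == "permissive" and count.colonies == 0:
        raise ValueError(
            f"{count.strain} bio {count.bio_rep} tech {count.tech_rep}: "
            "zero colonies on the permissive plate; cell density unmeasurable"
        )
    return (
        count.colonies
        * count.dilution_factor
        * (count.culture_volume_ul / count.volume_plated_ul)
    )


def mobility_frequency(selective: PlateCount, permissive: PlateCount) -> float:
    """Per-culture frequency: event CFU over total CFU in the same culture."""
    key_s = (selective.strain, selective.bio_rep, selective.tech_rep)
    key_p = (permissive.strain, permissive.bio_rep, permissive.tech_rep)
    if key_s != key_p:
        raise ValueError(f"culture mismatch: {key_s} vs {key_p}")
    if selective.plate_type != "selective" or permissive.plate_type != "permissive":
        raise ValueError("expected one selective and one permissive plate count")
    if selective.colonies == 0:
        return 0.0
    return cfu_in_culture(selective) / cfu_in_culture(permissive)


@dataclass(frozen=True)
class MobilityResult:
    strain: str
    frequencies: tuple[float, ...]  # per-culture, in input order
    bio_means: tuple[float, ...]
    mean: float
    dispersion: float
    dispersion_type: str  # "sd" | "range"
    censored: bool
    upper_limit: float | None
    n_bio: int


def summarize_strain(
    counts: Iterable[PlateCount], pooling: str = "bio-mean"
) -> MobilityResult:
    """Summarize one strain's plate counts into a frequency estimate.

    Technical cultures are averaged within each biological replicate before
    the cross-replicate mean and dispersion (``pooling="pooled"`` instead
    treats all cultures as exchangeable).  Dispersion is the standard
    deviation for three or more biological replicates and the range (max -
    min) for exactly two.  If no selective plate in any culture shows a
    colony the result is censored, with upper limit 1 / (total permissive
    CFU across all replicates).
    """
    if pooling not in ("bio-mean", "pooled"):
        raise ValueError("pooling must be 'bio-mean' or 'pooled'")
    counts = list(counts)
    strains = {c.strain for c in counts}
    if len(strains) != 1:
        raise ValueError(f"expected counts for exactly one strain, got {sorted(strains)}")
    (strain,) = strains
    sel = {(c.bio_rep, c.tech_rep): c for c in counts if c.plate_type == "selective"}
    perm = {(c.bio_rep, c.tech_rep): c for c in counts if c.plate_type == "permissive"}
    if set(sel) != set(perm):
        raise ValueError(f"{strain}: selective and permissive cultures do not match")
    cultures = sorted(sel)
    n_bio = len({b for b, _ in cultures})
    if n_bio < 2:
        raise ValueError(f"{strain}: need >= 2 biological replicates, got {n_bio}")

    freqs = [mobility_frequency(sel[k], perm[k]) for k in cultures]
    by_bio: dict[int, list[float]] = {}
    for (b, _), f in zip(cultures, freqs):
        by_bio.setdefault(b, []).append(f)
    bio_means = [float(np.mean(v)) for _, v in sorted(by_bio.items())]

    values = bio_means if pooling == "bio-mean" else freqs
    mean = float(np.mean(values))
    if n_bio == 2:
        dispersion, dtype = float(max(values) - min(values)), "range"
    else:
        dispersion, dtype = float(np.std(values, ddof=1)), "sd"

    censored = all(sel[k].colonies == 0 for k in cultures)
    upper_limit = None
    if censored:
        total_cfu = sum(cfu_in_culture(perm[k]) for k in cultures)
        upper_limit = 1.0 / total_cfu
    return MobilityResult(
        strain=strain,
        frequencies=tuple(freqs),
        bio_means=tuple(bio_means),
        mean=mean,
        dispersion=dispersion,
        dispersion_type=dtype,
        censored=censored,
        upper_limit=upper_limit,
        n_bio=n_bio,
    )


def counts_from_table(df: pd.DataFrame) -> list[PlateCount]:
    cols = df.columns
    return [
        PlateCount(
            strain=str(r.strain),
            bio_rep=int(r.bio_rep),
            tech_rep=int(r.tech_rep),
            plate_type=str(r.plate_type),
            colonies=int(r.colonies),
            volume_plated_ul=float(r.volume_plated_ul),
            dilution_factor=float(r.dilution_factor),
            culture_volume_ul=float(r.culture_volume_ul)
            if "culture_volume_ul" in cols
            else 1000.0,
        )
        for r in df.itertuples()
    ]


def summarize_counts(df: pd.DataFrame, pooling: str = "bio-mean") -> pd.DataFrame:
    """Per-strain summary of a colony-count table (one row per strain)."""
    rows = []
    for strain, sub in df.groupby("strain", sort=True):
        r = summarize_strain(counts_from_table(sub), pooling=pooling)
        rows.append(
            {
                "strain": r.strain,
                "mean_frequency": r.mean,
                "dispersion": r.dispersion,
                "dispersion_type": r.dispersion_type,
                "censored": r.censored,
                "upper_limit": r.upper_limit if r.censored else np.nan,
                "n_bio": r.n_bio,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldChange:
    """a over b; a lower bound when b is only known as a censored upper limit."""

    value: float | None
    lower_bound: bool = False
    undefined: bool = False

    def __str__(self) -> str:
        if self.undefined:
            return "undefined"
        return f"> {self.value:g}" if self.lower_bound else f"{self.value:g}"


def fold_change(a: MobilityResult, b: MobilityResult) -> FoldChange:
    """Fold difference in mean frequency between strains a and b."""
    if a.censored and b.censored:
        return FoldChange(value=None, undefined=True)
    if a.mean <= 0 and not a.censored:
        raise ValueError(f"{a.strain}: numerator mean frequency must be positive")
    if b.censored:
        return FoldChange(value=a.mean / b.upper_limit, lower_bound=True)
    if b.mean <= 0:
        raise ValueError(f"{b.strain}: denominator mean frequency is zero but not censored")
    return FoldChange(value=a.mean / b.mean)


# ---------------------------------------------------------------------------
# blot densitometry


@dataclass(frozen=True)
class BandQuant:
    sample: str
    target_signal: float
    loading_signal: float
    reference_target: float
    reference_loading: float

    def __post_init__(self) -> None:
        for name in ("target_signal", "loading_signal", "reference_target", "reference_loading"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.sample}: {name} must be positive")


def relative_level(q: BandQuant) -> float:
    """(target / loading control), normalized to the reference sample's ratio."""
    return (q.target_signal / q.loading_signal) / (
        q.reference_target / q.reference_loading
    )


def quantify_bands(df: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Normalize a band-intensity table (sample, target_signal, loading_signal)
    to the named reference sample; adds a relative_level column."""
    ref = df[df["sample"] == reference]
    if len(ref) != 1:
        raise ValueError(f"expected exactly one reference row {reference!r}")
    rt = float(ref["target_signal"].iloc[0])
    rl = float(ref["loading_signal"].iloc[0])
    out = df.copy()
    out["relative_level"] = [
        relative_level(
            BandQuant(str(r.sample), float(r.target_signal), float(r.loading_signal), rt, rl)
        )
        for r in df.itertuples()
    ]
    return out


# ---------------------------------------------------------------------------
# semi-quantitative RT-PCR


@dataclass(frozen=True)
class FoldEstimate:
    cycle_fold: float
    molar_correction: float
    combined_fold: float
    percent_of_reference: float


def cycle_offset_fold(delta_cycles: float, efficiency: float = 2.0) -> float:
    """Abundance fold implied by the reference amplifying ``delta_cycles``
    earlier than the target, at a fixed per-cycle amplification factor."""
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1")
    if delta_cycles < 0:
        raise ValueError("delta_cycles must be >= 0")
    return float(efficiency**delta_cycles)


def molar_correction(ref_amplicon_len: float, target_amplicon_len: float) -> float:
    """Molar ratio implied by equal mass signal of amplicons of different length."""
    if ref_amplicon_len <= 0 or target_amplicon_len <= 0:
        raise ValueError("amplicon lengths must be positive")
    return float(target_amplicon_len / ref_amplicon_len)


def combined_abundance(
    delta_cycles: float,
    efficiency: float = 2.0,
    ref_len: float = 200.0,
    target_len: float = 3000.0,
) -> FoldEstimate:
    """Combined reference-over-target abundance fold and its inverse as a percent."""
    cf = cycle_offset_fold(delta_cycles, efficiency)
    mc = molar_correction(ref_len, target_len)
    combined = cf * mc
    return FoldEstimate(
        cycle_fold=cf,
        molar_correction=mc,
        combined_fold=combined,
        percent_of_reference=100.0 / combined,
    )


def rtpcr_table(df: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Apply the combined-abundance estimate to a table with columns
    sample, delta_cycles, ref_len, target_len."""
    rows = []
    for r in df.itertuples():
        est = combined_abundance(
            float(r.delta_cycles), efficiency, float(r.ref_len), float(r.target_len)
        )
        rows.append(
            {
                "sample": r.sample,
                "cycle_fold": est.cycle_fold,
                "molar_correction": est.molar_correction,
                "combined_fold": est.combined_fold,
                "percent_of_reference": est.percent_of_reference,
            }
        )
    return pd.DataFrame(rows)
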
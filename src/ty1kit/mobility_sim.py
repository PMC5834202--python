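"""Simulated colony counts for the retromobility (His+ frequency) assay.

Each strain is grown as ``n_biological`` independent colonies, each diluted
in quadruplicate (``n_technical``), giving 12 cultures per strain by default.
Per culture the total viable cell count is drawn around ``cfu_per_culture``
(Poisson), mobility events are binomial with the strain's true per-cell
frequency, and plate colony counts are binomial subsamples determined by the
plated volume and dilution factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["MobilitySimConfig", "simulate_mobility_counts"]

COUNT_COLUMNS = [
    "strain",
    "bio_rep",
    "tech_rep",
    "plate_type",
    "volume_plated_ul",
    "dilution_factor",
    "culture_volume_ul",
    "colonies",
]


@dataclass(frozen=True)
class MobilitySimConfig:
    true_frequency: Mapping[str, float]
    cfu_per_culture: float = 2e8
    n_biological: int = 3
    n_technical: int = 4
    culture_volume_ul: float = 1000.0
    permissive_volume_ul: float = 1.0   # 1 uL of a 1:1000 dilution
    permissive_dilution: float = 1000.0
    selective_volume_ul: float = 1000.0  # whole culture on selective plates
    selective_dilution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for strain, p in self.true_frequency.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{strain}: true_frequency must be in [0, 1]")
        if self.cfu_per_culture <= 0:
            raise ValueError("cfu_per_culture must be positive")
        if self.n_biological < 1 or self.n_technical < 1:
            raise ValueError("replicate counts must be positive")
        for name in ("culture_volume_ul", "permissive_volume_ul", "selective_volume_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.permissive_dilution < 1 or self.selective_dilution < 1:
            raise ValueError("dilution factors must be >= 1")


def _plated_fraction(volume_ul: float, dilution: float, culture_ul: float) -> float:
    f = volume_ul / (dilution * culture_ul)
    if not (0.0 < f <= 1.0):
        raise ValueError("plated fraction must be in (0, 1]")
    return f


def simulate_mobility_counts(config: MobilitySimConfig) -> pd.DataFrame:
    """One row per (strain, bio_rep, tech_rep, plate_type); deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    f_perm = _plated_fraction(
        config.permissive_volume_ul, config.permissive_dilution, config.culture_volume_ul
    )
    f_sel = _plated_fraction(
        config.selective_volume_ul, config.selective_dilution, config.culture_volume_ul
    )
    rows = []
    for strain, p in config.true_frequency.items():
        for bio in range(1, config.n_biological + 1):
            for tech in range(1, config.n_technical + 1):
                total = int(rng.poisson(config.cfu_per_culture))
                events = int(rng.binomial(total, p)) if total else 0
                perm = int(rng.binomial(total, f_perm)) if total else 0
                sel = int(rng.binomial(events, f_sel)) if events else 0
                rows.append(
                    (strain, bio, tech, "permissive",
                     config.permissive_volume_ul, config.permissive_dilution,
                     config.culture_volume_ul, perm)
                )
                rows.append(
                    (strain, bio, tech, "selective",
                     config.selective_volume_ul, config.selective_dilution,
                     config.culture_volume_ul, sel)
                )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)
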
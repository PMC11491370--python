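"""Dilution-plate density and zone-of-clearing assay arithmetic.

Soil *Streptomyces* densities are estimated from serial-dilution spread
plates: a known soil mass is shaken into suspension, diluted, and a small
volume plated; colony counts are back-calculated to CFU per gram of dry
soil.  Inhibitory phenotypes are scored on the same plates after an
indicator-strain overlay (a modified Herr's assay), so every plate carries
a total count and an inhibitory count.  Antibiotic resistance is scored by
disk diffusion, with each zone summarised as the mean of two right-angle
radial measurements from the colony or disk edge to the edge of clearing.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SuspensionSpec",
    "CountPlate",
    "ZoneMeasurement",
    "cfu_per_gram",
    "sample_density",
    "inhibitor_proportion",
    "zone_size",
    "resistance_profile",
]


@dataclass(frozen=True)
class SuspensionSpec:
    """Soil suspension recipe: grams of dry soil shaken into mL of water."""

    soil_mass_g: float = 5.0
    suspension_volume_ml: float = 25.0

    def __post_init__(self) -> None:
        if self.soil_mass_g <= 0 or self.suspension_volume_ml <= 0:
            raise ValueError("soil mass and suspension volume must be > 0")


@dataclass(frozen=True)
class CountPlate:
    """One spread plate: total colonies and colonies inhibiting the overlay."""

    sample_id: str
    overlay: str  # "none" or an indicator strain id (e.g. LK1324.2, DL87)
    plate_rep: int
    dilution: float  # dimensionless factor in (0, 1]
    plated_volume_ml: float
    total_colonies: int
    inhibitory_colonies: int

    def __post_init__(self) -> None:
        if not (0.0 < self.dilution <= 1.0):
            raise ValueError(
                f"plate {self.sample_id}/{self.overlay}/{self.plate_rep}: "
                f"dilution {self.dilution} outside (0, 1]"
            )
        if self.plated_volume_ml <= 0:
            raise ValueError("plated volume must be > 0")
        if self.total_colonies < 0 or self.inhibitory_colonies < 0:
            raise ValueError("colony counts must be non-negative")
        if self.inhibitory_colonies > self.total_colonies:
            raise ValueError(
                f"plate {self.sample_id}/{self.overlay}/{self.plate_rep}: "
                f"inhibitory colonies ({self.inhibitory_colonies}) exceed "
                f"total ({self.total_colonies})"
            )


@dataclass(frozen=True)
class ZoneMeasurement:
    """Paired right-angle radial measurements (mm) of one clearing zone."""

    subject_id: str  # isolate (resistance) or colony (inhibition) id
    context: str  # "inhibition" | "resistance"
    agent: str  # antibiotic or indicator-strain name
    rep: int
    radius1_mm: float
    radius2_mm: float

    def __post_init__(self) -> None:
        if self.radius1_mm < 0 or self.radius2_mm < 0:
            raise ValueError(f"zone radii must be >= 0 ({self.subject_id})")


def cfu_per_gram(
    count: float,
    dilution: float,
    plated_volume_ml: float,
    spec: SuspensionSpec = SuspensionSpec(),
) -> float:
    """Back-calculate colony-forming units per gram of dry soil.

    CFU/g = (count / (plated_volume x dilution)) x (suspension_volume / soil_mass).
    """
    if dilution <= 0:
        raise ValueError(f"dilution must be > 0, got {dilution}")
    if plated_volume_ml <= 0:
        raise ValueError(f"plated volume must be > 0, got {plated_volume_ml}")
    if count < 0:
        raise ValueError("colony count must be non-negative")
    per_ml = count / (plated_volume_ml * dilution)
    return per_ml * (spec.suspension_volume_ml / spec.soil_mass_g)


def inhibitor_proportion(total_density: float, inhibitor_density: float) -> float:
    """Fraction of the community that is inhibitory; NaN when total is 0.

    The total and inhibitor densities come from separate plate sets, so
    sampling noise can push the ratio above 1; such values are reported
    as-is with a warning rather than clipped.
    """
    if total_density < 0 or inhibitor_density < 0:
        raise ValueError("densities must be non-negative")
    if total_density == 0:
        logger.warning("inhibitor proportion undefined: total density is 0")
        return math.nan
    prop = inhibitor_density / total_density
    if prop > 1:
        logger.warning(
            "inhibitor proportion %.3f > 1 (likely counting noise between "
            "plate sets); reported unclipped",
            prop,
        )
    return prop


def sample_density(
    plates: list[CountPlate],
    spec: SuspensionSpec = SuspensionSpec(),
) -> pd.DataFrame:
    """Per-sample mean densities from replicate dilution plates.

    Each plate is converted to CFU/g before averaging so mixed dilutions are
    handled correctly.  The total density averages over every plate of the
    sample; inhibitor densities are averaged per overlay.  Returns one row
    per (sample, overlay) with columns ``total_cfu_per_g`` (sample-wide),
    ``inhibitor_cfu_per_g`` and ``inhibitor_proportion``, plus one
    ``overlay="all"`` row pooling the overlays.
    """
    if not plates:
        raise ValueError("no count plates provided")
    rows = []
    for p in plates:
        rows.append(
            {
                "sample_id": p.sample_id,
                "overlay": p.overlay,
                "total_cfu_per_g": cfu_per_gram(
                    p.total_colonies, p.dilution, p.plated_volume_ml, spec
                ),
                "inhibitor_cfu_per_g": cfu_per_gram(
                    p.inhibitory_colonies, p.dilution, p.plated_volume_ml, spec
                ),
            }
        )
    frame = pd.DataFrame(rows)
    out = []
    for sample_id, sub in frame.groupby("sample_id", sort=True):
        total = sub["total_cfu_per_g"].mean()
        for overlay, osub in sub.groupby("overlay", sort=True):
            inhib = osub["inhibitor_cfu_per_g"].mean()
            out.append(
                {
                    "sample_id": sample_id,
                    "overlay": overlay,
                    "total_cfu_per_g": total,
                    "inhibitor_cfu_per_g": inhib,
                    "inhibitor_proportion": inhibitor_proportion(total, inhib),
                }
            )
        pooled = sub["inhibitor_cfu_per_g"].mean()
        out.append(
            {
                "sample_id": sample_id,
                "overlay": "all",
                "total_cfu_per_g": total,
                "inhibitor_cfu_per_g": pooled,
                "inhibitor_proportion": inhibitor_proportion(total, pooled),
            }
        )
    return pd.DataFrame(out)


def zone_size(z: ZoneMeasurement) -> float:
    """Zone radius in mm: mean of the two right-angle measurements."""
    return 0.5 * (z.radius1_mm + z.radius2_mm)


def resistance_profile(
    zones: list[ZoneMeasurement],
    antibiotics: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Isolate x antibiotic matrix of mean zone radii over replicates.

    A larger mean zone means the isolate is more susceptible to that
    antibiotic.  Missing isolate-antibiotic combinations are NaN and logged.
    """
    if not zones:
        raise ValueError("no zone measurements provided")
    rows = [
        {"isolate_id": z.subject_id, "antibiotic": z.agent, "size_mm": zone_size(z)}
        for z in zones
    ]
    frame = pd.DataFrame(rows)
    matrix = frame.pivot_table(
        index="isolate_id", columns="antibiotic", values="size_mm", aggfunc="mean"
    )
    if antibiotics is not None:
        matrix = matrix.reindex(columns=list(antibiotics))
    n_missing = int(matrix.isna().sum().sum())
    if n_missing:
        logger.warning(
            "resistance profile: %d isolate-antibiotic combinations missing",
            n_missing,
        )
    matrix.columns.name = None
    return matrix
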
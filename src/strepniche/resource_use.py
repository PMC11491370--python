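"""Carbon-source resource-use phenotypes from Biolog absorbance plates.

Each isolate is profiled on 95 carbon sources; the water-control absorbance
is subtracted from every well, and a source counts as *used* when the
corrected absorbance strictly exceeds a threshold (default 0.01 AU590).
From the corrected profile we derive:

* **niche width** — the number of used sources (0-95);
* **growth efficiency** — the mean corrected absorbance over used sources
  (undefined when the width is zero);
* **niche overlap** — for an ordered pair of isolates (a, b),

  .. math::  \\bar\\omega_{a \\to b} = \\frac{1}{n}\\sum_{i \\in U(a)}
             \\frac{\\min(od_a(i),\\, od_b(i))}{od_a(i)},

  where :math:`U(a)` is a's set of used sources and :math:`n = |U(a)|`.
  The sum runs over a's used sources only, so the statistic is the fraction
  of a's realized niche matched by b: it is asymmetric
  (:math:`\\bar\\omega_{a\\to b} \\ne \\bar\\omega_{b\\to a}` in general),
  bounded in [0, 1], and equals 1 on the diagonal.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_design import ExperimentDesign, RawPlate

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_THRESHOLD",
    "ResourceProfile",
    "OverlapMatrix",
    "blank_correct",
    "call_resource_use",
    "profile_from_plate",
    "niche_width",
    "growth_efficiency",
    "niche_metrics_table",
    "niche_overlap",
    "overlap_matrix",
    "group_substrate_profile",
]

#: Use-call threshold in AU590: a source is used when corrected od > 0.01.
DEFAULT_THRESHOLD = 0.01


def blank_correct(raw: RawPlate) -> np.ndarray:
    """Subtract the water-control absorbance, clamping negatives to zero.

    Negative corrected values would represent less growth than the blank,
    which is unphysical and would break the min/ratio overlap formula, so
    they are clamped to 0.
    """
    return np.maximum(raw.absorbances - raw.water_control, 0.0)


def call_resource_use(
    od: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Boolean use calls: strictly greater than the threshold."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    od = np.asarray(od, dtype=float)
    if np.any(od < 0):
        raise ValueError("corrected absorbances must be non-negative")
    return od > threshold


@dataclass(frozen=True)
class ResourceProfile:
    """One isolate's blank-corrected absorbances and use calls."""

    isolate_id: str
    substrates: tuple[str, ...]
    od: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "od", od)
        if len(od) != len(self.substrates):
            raise ValueError(
                f"profile {self.isolate_id}: {len(od)} absorbances for "
                f"{len(self.substrates)} substrates"
            )
        if np.any(od < 0):
            raise ValueError(f"profile {self.isolate_id}: negative absorbance")

    @property
    def used(self) -> np.ndarray:
        return call_resource_use(self.od, self.threshold)


def profile_from_plate(
    raw: RawPlate, threshold: float = DEFAULT_THRESHOLD
) -> ResourceProfile:
    """Blank-correct a raw plate and wrap it as a ResourceProfile."""
    return ResourceProfile(
        isolate_id=raw.isolate_id,
        substrates=raw.substrates,
        od=blank_correct(raw),
        threshold=threshold,
    )


def niche_width(profile: ResourceProfile) -> int:
    """Number of used carbon sources."""
    return int(profile.used.sum())


def growth_efficiency(profile: ResourceProfile) -> float:
    """Mean corrected absorbance over used sources; NaN when width is 0.

    An empty used set yields NaN ("undefined") rather than 0, since a zero
    would bias treatment-group means downward.
    """
    used = profile.used
    if not used.any():
        return math.nan
    return float(profile.od[used].mean())


def niche_metrics_table(profiles: list[ResourceProfile]) -> pd.DataFrame:
    """Per-isolate niche width and growth efficiency."""
    return pd.DataFrame(
        {
            "isolate_id": [p.isolate_id for p in profiles],
            "niche_width": [niche_width(p) for p in profiles],
            "efficiency": [growth_efficiency(p) for p in profiles],
        }
    ).set_index("isolate_id")


def niche_overlap(a: ResourceProfile, b: ResourceProfile) -> float:
    """Asymmetric niche overlap of a toward b; NaN when a uses nothing."""
    if a.substrates != b.substrates:
        raise ValueError("profiles are on different substrate panels")
    used = a.used
    n = int(used.sum())
    if n == 0:
        logger.warning(
            "niche overlap undefined: isolate %s has niche width 0", a.isolate_id
        )
        return math.nan
    num = np.minimum(a.od[used], b.od[used])
    return float(np.mean(num / a.od[used]))


@dataclass
class OverlapMatrix:
    """All ordered-pair overlaps plus per-group summaries.

    ``matrix`` is indexed by isolate id (rows = a, columns = b);
    ``pairs`` is the long form restricted to within-group ordered pairs,
    and ``group_means`` averages those pairs per group (NaN for singleton
    groups).
    """

    matrix: pd.DataFrame
    pairs: pd.DataFrame
    group_means: pd.DataFrame
    group_level: str


def _overlap_matrix_values(
    od: np.ndarray, used: np.ndarray
) -> np.ndarray:
    """Vectorized ordered-pair overlap for an od matrix (isolates x wells)."""
    n_iso = od.shape[0]
    widths = used.sum(axis=1)
    out = np.full((n_iso, n_iso), np.nan)
    for a in range(n_iso):
        if widths[a] == 0:
            continue
        oda = od[a, used[a]]
        ratios = np.minimum(oda[None, :], od[:, used[a]]) / oda[None, :]
        out[a, :] = ratios.mean(axis=1)
    return out


def overlap_matrix(
    profiles: list[ResourceProfile],
    design: ExperimentDesign | None = None,
    group_level: str = "plant",
) -> OverlapMatrix:
    """Ordered-pair overlap matrix with within-group summaries.

    Overlap is summarised among isolates sharing the same origin group
    (default: the plant they were isolated from).  Group means average
    over all ordered pairs excluding self-pairs; singleton groups get a
    NaN mean and a log entry.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    panels = {p.substrates for p in profiles}
    if len(panels) != 1:
        raise ValueError("profiles are on different substrate panels")
    ids = [p.isolate_id for p in profiles]
    od = np.vstack([p.od for p in profiles])
    used = np.vstack([p.used for p in profiles])
    values = _overlap_matrix_values(od, used)
    matrix = pd.DataFrame(values, index=ids, columns=ids)

    if design is not None:
        labels = design.isolate_labels(ids)
        groups = labels[group_level]
    else:
        groups = pd.Series("all", index=ids)
        labels = pd.DataFrame(index=ids)

    pair_rows = []
    for group, members in groups.groupby(groups):
        member_ids = list(members.index)
        if len(member_ids) == 1:
            logger.warning(
                "overlap summary undefined for %s=%s (single isolate)",
                group_level,
                group,
            )
            continue
        for a in member_ids:
            for b in member_ids:
                if a == b:
                    continue
                pair_rows.append(
                    {
                        "a": a,
                        "b": b,
                        group_level: group,
                        "overlap": matrix.at[a, b],
                    }
                )
    pairs = pd.DataFrame(pair_rows, columns=["a", "b", group_level, "overlap"])
    if len(pairs):
        group_means = (
            pairs.groupby(group_level)["overlap"]
            .agg(mean_overlap="mean", n_pairs="count")
            .reset_index()
        )
    else:
        group_means = pd.DataFrame(columns=[group_level, "mean_overlap", "n_pairs"])
    if design is not None and len(group_means):
        # carry the treatment labels of each group for downstream ANOVA
        label_map = (
            pd.concat([design.samples, design.isolates])
            .drop_duplicates(subset=["plant"])
            .set_index("plant")[["richness", "fungicide"]]
        )
        if group_level == "plant":
            group_means = group_means.join(label_map, on="plant")
    return OverlapMatrix(
        matrix=matrix, pairs=pairs, group_means=group_means, group_level=group_level
    )


def group_substrate_profile(
    profiles: list[ResourceProfile],
    design: ExperimentDesign,
    level: str | list[str] = "richness",
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-substrate proportion of total resource use, by treatment group.

    Each isolate's corrected absorbances are first normalized to shares
    summing to 1; the group value is the mean share per substrate with a
    standard error (sd/sqrt(n)) across isolates.  With ``pooled=True``
    absorbances are instead pooled across the group before normalizing
    (no SE in that case).  Isolates with niche width 0 are excluded with a
    warning.
    """
    if not profiles:
        raise ValueError("no profiles provided")
    keep = []
    for p in profiles:
        if p.od.sum() <= 0 or niche_width(p) == 0:
            logger.warning(
                "excluding isolate %s from substrate profile (niche width 0)",
                p.isolate_id,
            )
            continue
        keep.append(p)
    if not keep:
        raise ValueError("no isolates with non-zero niche width")
    ids = [p.isolate_id for p in keep]
    substrates = keep[0].substrates
    od = np.vstack([p.od for p in keep])
    labels = design.isolate_labels(ids)
    if isinstance(level, str):
        level = [level]
    group_keys = labels[level].agg("|".join, axis=1)

    rows = []
    for group, members in group_keys.groupby(group_keys):
        idx = [ids.index(i) for i in members.index]
        sub = od[idx]
        if pooled:
            total = sub.sum()
            means = sub.sum(axis=0) / total
            ses = np.full(len(substrates), np.nan)
        else:
            shares = sub / sub.sum(axis=1, keepdims=True)
            means = shares.mean(axis=0)
            ses = (
                shares.std(axis=0, ddof=1) / math.sqrt(len(idx))
                if len(idx) > 1
                else np.zeros(len(substrates))
            )
        for s, m, se in zip(substrates, means, ses):
            rows.append(
                {
                    "group": group,
                    "substrate": s,
                    "mean_share": m,
                    "se": se,
                    "n_isolates": len(idx),
                }
            )
    return pd.DataFrame(rows)
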
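"""Synthetic hierarchical experiments for testing the analysis pipeline.

The generator emulates the structure of the field study: 2 plant-richness
whole plots x 2 fungicide subplots x 6 plants = 24 composite soil samples,
with 10 isolates drawn from each of 2 randomly chosen plants per subplot
(80 isolates).  Every treatment cell carries its own generating parameters
(nutrient means, density, inhibitor fraction, niche width, zone sizes), so
treatment effects of any size - including none - can be injected and later
recovered by the statistics.  The generating truth is stored alongside the
data.

Use calls are consistent by construction: a well generated as "used" gets a
corrected absorbance of threshold + |Normal| (strictly above the use
threshold almost surely), while "unused" wells are truncated at the
threshold, so recomputed niche widths match the stored truth exactly.

The phylogeny is a sequential random-attachment tree, not a birth-death
process: each isolate (in shuffled order) attaches as sister to a uniformly
chosen leaf, or - with probability ``tree_clustering`` - to a leaf from its
own richness group.  That is enough to create (or, at clustering 0, to
withhold) the group-level phylogenetic signal that UniFrac and PERMANOVA
are meant to detect.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import CountPlate, SuspensionSpec, ZoneMeasurement
from .io_design import (
    ExperimentDesign,
    RawPlate,
    SoilSample,
    N_SUBSTRATES,
    write_counts_table,
    write_design,
    write_plate_table,
    write_soil_table,
    write_zones_table,
)
from .resource_use import DEFAULT_THRESHOLD

__all__ = [
    "NUTRIENTS",
    "ANTIBIOTICS",
    "CellParams",
    "SimulationConfig",
    "SyntheticExperiment",
    "default_config",
    "null_config",
    "apply_richness_effect",
    "generate",
]

#: Soil nutrient fields and their physical bounds for truncation.
NUTRIENTS: dict[str, tuple[float, float]] = {
    "carbon_pct": (0.0, 100.0),
    "nitrogen_pct": (0.0, 100.0),
    "phosphorus_ppm": (0.0, np.inf),
    "potassium_ppm": (0.0, np.inf),
    "organic_matter_pct": (0.0, 100.0),
    "ph": (1e-6, 14.0 - 1e-6),
}

#: Disk-diffusion panel: nine clinical antibiotics.
ANTIBIOTICS = (
    "kanamycin",
    "streptomycin",
    "erythromycin",
    "vancomycin",
    "amoxicillin_clavulanate",
    "novobiocin",
    "chloramphenicol",
    "rifampin",
    "tetracycline",
)


@dataclass
class CellParams:
    """Generating parameters for one (richness, fungicide) treatment cell."""

    nutrient_means: dict[str, float]
    nutrient_sds: dict[str, float]
    density_log10_mean: float = 6.7  # log10 CFU/g
    density_log10_sd: float = 0.15
    inhibitor_fraction: float = 0.2
    niche_width_mean: float = 50.0  # expected used sources out of 95
    use_od_mean: float = 0.35  # AU590 above threshold for used wells
    od_sd: float = 0.1
    zone_mean_mm: dict[str, float] = field(
        default_factory=lambda: {ab: 6.0 for ab in ANTIBIOTICS}
    )
    zone_sd_mm: float = 1.5
    #: substrate index -> extra corrected absorbance; affected wells are
    #: forced "used" (used by the FDR-screen effect-injection tests)
    substrate_od_offsets: dict[int, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not (0.0 <= self.inhibitor_fraction <= 1.0):
            raise ValueError(
                f"inhibitor_fraction {self.inhibitor_fraction} outside [0, 1]"
            )
        if not (0.0 <= self.niche_width_mean <= N_SUBSTRATES):
            raise ValueError(
                f"niche_width_mean {self.niche_width_mean} outside [0, {N_SUBSTRATES}]"
            )
        for name, sd in list(self.nutrient_sds.items()) + [
            ("density_log10_sd", self.density_log10_sd),
            ("od_sd", self.od_sd),
            ("zone_sd_mm", self.zone_sd_mm),
        ]:
            if (sd if isinstance(sd, float) else float(sd)) < 0:
                raise ValueError(f"standard deviation {name} must be >= 0")
        missing = set(NUTRIENTS) - set(self.nutrient_means)
        if missing:
            raise ValueError(f"nutrient means missing {sorted(missing)}")


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment."""

    seed: int = 0
    richness_levels: tuple[str, str] = ("monoculture", "polyculture")
    fungicide_levels: tuple[str, str] = ("untreated", "treated")
    plants_per_subplot: int = 6
    isolation_plants_per_subplot: int = 2
    isolates_per_plant: int = 10
    water_od: float = 0.05
    use_threshold: float = DEFAULT_THRESHOLD
    dilution: float = 1e-3
    plated_volume_ml: float = 0.1
    plate_reps: int = 3
    indicators: tuple[str, ...] = ("LK1324.2", "DL87")
    zone_reps: int = 2
    tree_clustering: float = 0.7
    suspension: SuspensionSpec = field(default_factory=SuspensionSpec)
    cells: dict[tuple[str, str], CellParams] = field(default_factory=dict)

    def validate(self) -> None:
        if not (0.0 <= self.tree_clustering <= 1.0):
            raise ValueError("tree_clustering outside [0, 1]")
        if self.isolation_plants_per_subplot > self.plants_per_subplot:
            raise ValueError("more isolation plants than plants per subplot")
        if self.plants_per_subplot < 1 or self.isolates_per_plant < 1:
            raise ValueError("plants and isolates per plant must be >= 1")
        expected = {
            (r, f) for r in self.richness_levels for f in self.fungicide_levels
        }
        if set(self.cells) != expected:
            raise ValueError("cells must cover every (richness, fungicide) pair")
        for params in self.cells.values():
            params.validate()


def _base_cell(**overrides) -> CellParams:
    params = CellParams(
        nutrient_means={
            "carbon_pct": 0.70,
            "nitrogen_pct": 0.060,
            "phosphorus_ppm": 25.0,
            "potassium_ppm": 60.0,
            "organic_matter_pct": 1.50,
            "ph": 6.0,
        },
        nutrient_sds={
            "carbon_pct": 0.12,
            "nitrogen_pct": 0.010,
            "phosphorus_ppm": 5.0,
            "potassium_ppm": 10.0,
            "organic_matter_pct": 0.25,
            "ph": 0.20,
        },
    )
    for k, v in overrides.items():
        setattr(params, k, v)
    return params


def null_config(seed: int = 0) -> SimulationConfig:
    """A configuration with identical parameters in all four cells.

    With no treatment effect anywhere (and no phylogenetic clustering),
    every downstream test statistic is calibrated against its nominal null.
    """
    cfg = SimulationConfig(seed=seed, tree_clustering=0.0)
    cfg.cells = {
        (r, f): _base_cell()
        for r in cfg.richness_levels
        for f in cfg.fungicide_levels
    }
    return cfg


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-like defaults with qualitative treatment effects.

    Polyculture soils are richer (higher C, N, K, organic matter, pH) with
    the untreated subplot richest; monoculture supports more inhibitory
    isolates (further enriched under fungicide) and broader, more
    overlapping niches; fungicide narrows niches in monoculture but widens
    them in polyculture.  Magnitudes are plausible for sandy, nutrient-poor
    grassland soil and are not fitted to any field data.
    """
    cfg = SimulationConfig(seed=seed, tree_clustering=0.7)

    def nutrients(c, n, p, k, om, ph):
        return {
            "carbon_pct": c,
            "nitrogen_pct": n,
            "phosphorus_ppm": p,
            "potassium_ppm": k,
            "organic_matter_pct": om,
            "ph": ph,
        }

    cfg.cells = {
        ("monoculture", "untreated"): _base_cell(
            nutrient_means=nutrients(0.60, 0.050, 25.0, 50.0, 1.30, 5.70),
            density_log10_mean=6.9,
            inhibitor_fraction=0.25,
            niche_width_mean=55.0,
        ),
        ("monoculture", "treated"): _base_cell(
            nutrient_means=nutrients(0.62, 0.052, 25.0, 52.0, 1.35, 5.75),
            density_log10_mean=6.5,
            inhibitor_fraction=0.35,
            niche_width_mean=47.0,
        ),
        ("polyculture", "untreated"): _base_cell(
            nutrient_means=nutrients(0.95, 0.080, 26.0, 75.0, 1.95, 6.30),
            density_log10_mean=6.8,
            inhibitor_fraction=0.10,
            niche_width_mean=42.0,
        ),
        ("polyculture", "treated"): _base_cell(
            nutrient_means=nutrients(0.75, 0.062, 25.0, 72.0, 1.55, 6.00),
            density_log10_mean=6.9,
            inhibitor_fraction=0.11,
            niche_width_mean=48.0,
        ),
    }
    return cfg


def apply_richness_effect(
    config: SimulationConfig, nutrient: str, sd_units: float
) -> SimulationConfig:
    """Offset a nutrient's cell means by +/- ``sd_units`` within-cell SDs.

    Cells of the first richness level move up, cells of the second move
    down; used to inject a known richness effect for power checks.
    """
    cfg = dataclasses.replace(config)
    cfg.cells = {}
    first = config.richness_levels[0]
    for (r, f), params in config.cells.items():
        p = dataclasses.replace(
            params,
            nutrient_means=dict(params.nutrient_means),
            nutrient_sds=dict(params.nutrient_sds),
            zone_mean_mm=dict(params.zone_mean_mm),
            substrate_od_offsets=dict(params.substrate_od_offsets),
        )
        shift = sd_units * p.nutrient_sds[nutrient]
        p.nutrient_means[nutrient] += shift if r == first else -shift
        cfg.cells[(r, f)] = p
    return cfg


@dataclass
class SyntheticExperiment:
    """One generated experiment plus the truth that produced it."""

    design: ExperimentDesign
    soil: list[SoilSample]
    plates: list[RawPlate]
    counts: list[CountPlate]
    zones: list[ZoneMeasurement]
    tree: str  # newick text
    truth: dict
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_design(self.design, outdir / "design.csv")
        write_plate_table(self.plates, outdir / "plates.csv")
        write_soil_table(self.soil, outdir / "soil.csv")
        write_counts_table(self.counts, outdir / "counts.csv")
        write_zones_table(self.zones, outdir / "zones.csv")
        (outdir / "tree.nwk").write_text(self.tree)
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=1, sort_keys=True)
        )


# ---------------------------------------------------------------------------
# generation


class _TreeLeaf:
    __slots__ = ("label", "length", "group", "parent")

    def __init__(self, label, length, group):
        self.label, self.length, self.group = label, length, group
        self.parent = None


class _TreeNode:
    __slots__ = ("children", "length", "parent")

    def __init__(self, children, length):
        self.children, self.length = children, length
        self.parent = None
        for c in children:
            c.parent = self


def _simulate_tree(
    isolate_groups: list[tuple[str, str]],
    clustering: float,
    rng: np.random.Generator,
) -> str:
    """Rooted bifurcating newick via biased sequential leaf attachment."""

    def draw() -> float:
        return float(rng.exponential(0.05) + 0.005)

    order = rng.permutation(len(isolate_groups))
    items = [isolate_groups[i] for i in order]
    if len(items) < 2:
        raise ValueError("need at least two isolates for a tree")
    leaves = [
        _TreeLeaf(items[0][0], draw(), items[0][1]),
        _TreeLeaf(items[1][0], draw(), items[1][1]),
    ]
    root = _TreeNode(list(leaves), None)
    for label, group in items[2:]:
        same = [lf for lf in leaves if lf.group == group]
        pool = same if (same and rng.random() < clustering) else leaves
        target = pool[rng.integers(len(pool))]
        parent = target.parent
        new_leaf = _TreeLeaf(label, draw(), group)
        internal = _TreeNode([target, new_leaf], draw())
        internal.parent = parent
        parent.children[parent.children.index(target)] = internal
        leaves.append(new_leaf)

    def newick(node) -> str:
        if isinstance(node, _TreeLeaf):
            return f"{node.label}:{node.length:.6f}"
        inner = ",".join(newick(c) for c in node.children)
        if node.length is None:
            return f"({inner});"
        return f"({inner}):{node.length:.6f}"

    return newick(root)


def _make_design(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ExperimentDesign, dict[str, tuple[str, str]]]:
    sample_rows, isolate_rows = [], []
    plant_cells: dict[str, tuple[str, str]] = {}
    for r in config.richness_levels:
        for f in config.fungicide_levels:
            plants = [f"{r}.{f}.p{i + 1}" for i in range(config.plants_per_subplot)]
            for plant in plants:
                plant_cells[plant] = (r, f)
                sample_rows.append(
                    {"id": f"S.{plant}", "richness": r, "fungicide": f, "plant": plant}
                )
            chosen = rng.choice(
                config.plants_per_subplot,
                size=config.isolation_plants_per_subplot,
                replace=False,
            )
            for pi in sorted(chosen):
                plant = plants[pi]
                for j in range(config.isolates_per_plant):
                    isolate_rows.append(
                        {
                            "id": f"I.{plant}.{j + 1:02d}",
                            "richness": r,
                            "fungicide": f,
                            "plant": plant,
                        }
                    )
    samples = pd.DataFrame(sample_rows).set_index("id")
    isolates = pd.DataFrame(isolate_rows).set_index("id")
    return ExperimentDesign(samples, isolates), plant_cells


def generate(config: SimulationConfig) -> SyntheticExperiment:
    """Draw one complete experiment from the configured distributions.

    Reproducible: all randomness derives from ``config.seed`` through
    deterministic substreams (design, soil, plates, counts, zones, tree).
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_design, rng_soil, rng_plates, rng_counts, rng_zones, rng_tree = (
        np.random.default_rng(s) for s in streams
    )

    design, _ = _make_design(config, rng_design)

    soil: list[SoilSample] = []
    for sid, row in design.samples.iterrows():
        cell = config.cells[(row.richness, row.fungicide)]
        values = {}
        for name, (lo, hi) in NUTRIENTS.items():
            v = rng_soil.normal(cell.nutrient_means[name], cell.nutrient_sds[name])
            values[name] = round(float(np.clip(v, lo, hi)), 6)
        soil.append(
            SoilSample(
                sample_id=str(sid),
                richness=row.richness,
                fungicide=row.fungicide,
                plant=row.plant,
                carbon_pct=values["carbon_pct"],
                nitrogen_pct=values["nitrogen_pct"],
                phosphorus_ppm=values["phosphorus_ppm"],
                potassium_ppm=values["potassium_ppm"],
                organic_matter_pct=values["organic_matter_pct"],
                ph=values["ph"],
            )
        )

    substrates = [f"s{i + 1:03d}" for i in range(N_SUBSTRATES)]
    thr = config.use_threshold
    plates: list[RawPlate] = []
    truth_isolates: dict[str, dict] = {}
    for iid, row in design.isolates.iterrows():
        cell = config.cells[(row.richness, row.fungicide)]
        used = rng_plates.random(N_SUBSTRATES) < cell.niche_width_mean / N_SUBSTRATES
        # margins keep the strict >threshold call robust to the 6-decimal
        # measurement precision and the (water + od) - water round trip
        margin = 1e-5
        od_used = thr + margin + np.abs(
            rng_plates.normal(cell.use_od_mean, cell.od_sd, N_SUBSTRATES)
        )
        od_unused = np.minimum(
            rng_plates.normal(0.0, cell.od_sd, N_SUBSTRATES), thr - margin
        )
        od = np.where(used, od_used, od_unused)
        for idx, offset in cell.substrate_od_offsets.items():
            used[idx] = True
            od[idx] = thr + margin + offset + abs(
                rng_plates.normal(cell.use_od_mean, cell.od_sd)
            )
        # plate readers report a few decimals; 6 keeps CSV round trips exact
        raw = np.round(np.maximum(config.water_od + od, 0.0), 6)
        plates.append(
            RawPlate(
                isolate_id=str(iid),
                wells={s: float(v) for s, v in zip(substrates, raw)},
                water_control=config.water_od,
            )
        )
        truth_isolates[str(iid)] = {
            "used": [bool(u) for u in used],
            "niche_width": int(used.sum()),
        }

    spec = config.suspension
    plating_factor = (
        (spec.soil_mass_g / spec.suspension_volume_ml)
        * config.dilution
        * config.plated_volume_ml
    )
    counts: list[CountPlate] = []
    for sid, row in design.samples.iterrows():
        cell = config.cells[(row.richness, row.fungicide)]
        density = 10.0 ** rng_counts.normal(
            cell.density_log10_mean, cell.density_log10_sd
        )
        for overlay in config.indicators:
            for rep in range(1, config.plate_reps + 1):
                total = int(rng_counts.poisson(density * plating_factor))
                inhib = int(rng_counts.binomial(total, cell.inhibitor_fraction))
                counts.append(
                    CountPlate(
                        sample_id=str(sid),
                        overlay=overlay,
                        plate_rep=rep,
                        dilution=config.dilution,
                        plated_volume_ml=config.plated_volume_ml,
                        total_colonies=total,
                        inhibitory_colonies=inhib,
                    )
                )

    zones: list[ZoneMeasurement] = []
    for iid, row in design.isolates.iterrows():
        cell = config.cells[(row.richness, row.fungicide)]
        for ab in ANTIBIOTICS:
            mean = cell.zone_mean_mm.get(ab, 6.0)
            for rep in range(1, config.zone_reps + 1):
                r1, r2 = np.maximum(
                    rng_zones.normal(mean, cell.zone_sd_mm, 2), 0.0
                )
                zones.append(
                    ZoneMeasurement(
                        subject_id=str(iid),
                        context="resistance",
                        agent=ab,
                        rep=rep,
                        radius1_mm=round(float(r1), 3),
                        radius2_mm=round(float(r2), 3),
                    )
                )

    isolate_groups = [
        (str(iid), row.richness) for iid, row in design.isolates.iterrows()
    ]
    tree = _simulate_tree(isolate_groups, config.tree_clustering, rng_tree)

    truth = {
        "seed": config.seed,
        "cells": {
            f"{r}|{f}": {
                "nutrient_means": params.nutrient_means,
                "nutrient_sds": params.nutrient_sds,
                "density_log10_mean": params.density_log10_mean,
                "density_log10_sd": params.density_log10_sd,
                "inhibitor_fraction": params.inhibitor_fraction,
                "niche_width_mean": params.niche_width_mean,
                "use_od_mean": params.use_od_mean,
                "od_sd": params.od_sd,
                "zone_mean_mm": params.zone_mean_mm,
                "zone_sd_mm": params.zone_sd_mm,
                "substrate_od_offsets": {
                    str(k): v for k, v in params.substrate_od_offsets.items()
                },
            }
            for (r, f), params in config.cells.items()
        },
        "isolates": truth_isolates,
    }
    return SyntheticExperiment(
        design=design,
        soil=soil,
        plates=plates,
        counts=counts,
        zones=zones,
        tree=tree,
        truth=truth,
        config=config,
    )
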
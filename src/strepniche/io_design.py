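"""Experimental-design data model and tabular/tree input-output.

The study design is hierarchical: plant-richness whole plots (e.g.
monoculture vs. 16-species polyculture) contain paired fungicide subplots
(treated vs. untreated); within each subplot individual plants are sampled,
yielding composite soil samples, and *Streptomyces* isolates are collected
from a subset of those plants.  Every sample and isolate therefore carries a
(richness, fungicide, plant) triple, and all downstream statistics are keyed
on that triple.

All tables are UTF-8 CSV with a header row and decimal points.  The isolate
phylogeny is consumed as a rooted newick tree with branch lengths; tree
inference itself is outside this package.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .assays import CountPlate, ZoneMeasurement

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ExperimentDesign",
    "SoilSample",
    "RawPlate",
    "N_SUBSTRATES",
    "read_design",
    "read_plate_table",
    "read_soil_table",
    "read_counts_table",
    "read_zones_table",
    "read_tree",
    "write_design",
    "write_plate_table",
    "write_soil_table",
    "write_counts_table",
    "write_zones_table",
]

#: Number of carbon-source wells on a Biolog SF-P2 plate (plus one water control).
N_SUBSTRATES = 95


class ValidationError(ValueError):
    """An input table or tree violates a structural invariant."""


@dataclass(frozen=True)
class SoilSample:
    """Composite-sample soil nutrient vector with design labels."""

    sample_id: str
    richness: str
    fungicide: str
    plant: str
    carbon_pct: float
    nitrogen_pct: float
    phosphorus_ppm: float
    potassium_ppm: float
    organic_matter_pct: float
    ph: float

    def __post_init__(self) -> None:
        for name in ("carbon_pct", "nitrogen_pct", "organic_matter_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"soil sample {self.sample_id}: {name}={v} outside [0, 100]"
                )
        for name in ("phosphorus_ppm", "potassium_ppm"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"soil sample {self.sample_id}: {name} must be >= 0"
                )
        if not (0.0 < self.ph < 14.0):
            raise ValidationError(
                f"soil sample {self.sample_id}: pH={self.ph} outside (0, 14)"
            )


@dataclass(frozen=True)
class RawPlate:
    """One isolate's raw Biolog absorbance readings (AU590).

    ``wells`` maps carbon-source name to absorbance, in file order;
    ``water_control`` is the blank well used for correction.
    """

    isolate_id: str
    wells: dict[str, float]
    water_control: float

    def __post_init__(self) -> None:
        if len(self.wells) != N_SUBSTRATES:
            raise ValidationError(
                f"plate {self.isolate_id}: expected {N_SUBSTRATES} carbon-source "
                f"wells, found {len(self.wells)}"
            )
        if self.water_control < 0:
            raise ValidationError(
                f"plate {self.isolate_id}: negative water-control absorbance"
            )
        for name, v in self.wells.items():
            if v < 0:
                raise ValidationError(
                    f"plate {self.isolate_id}: negative absorbance in well {name!r}"
                )

    @property
    def substrates(self) -> tuple[str, ...]:
        return tuple(self.wells)

    @property
    def absorbances(self) -> np.ndarray:
        return np.array(list(self.wells.values()), dtype=float)


class ExperimentDesign:
    """Mapping of samples and isolates to the (richness, fungicide, plant) hierarchy.

    Parameters
    ----------
    samples, isolates
        DataFrames indexed by identifier with columns ``richness``,
        ``fungicide`` and ``plant``.
    """

    def __init__(self, samples: pd.DataFrame, isolates: pd.DataFrame):
        self.samples = samples.copy()
        self.isolates = isolates.copy()
        self._validate()

    def _validate(self) -> None:
        for name, frame in (("sample", self.samples), ("isolate", self.isolates)):
            if frame.index.has_duplicates:
                dup = frame.index[frame.index.duplicated()].unique().tolist()
                raise ValidationError(f"duplicate {name} identifiers: {dup}")
            missing = {"richness", "fungicide", "plant"} - set(frame.columns)
            if missing:
                raise ValidationError(f"{name} table missing columns {sorted(missing)}")
        both = pd.concat([self.samples, self.isolates])
        cells_per_plant = both.groupby("plant")[["richness", "fungicide"]].nunique()
        bad = cells_per_plant[(cells_per_plant > 1).any(axis=1)]
        if len(bad):
            raise ValidationError(
                f"plants assigned to more than one treatment cell: {bad.index.tolist()}"
            )
        for r in self.richness_levels:
            for f in self.fungicide_levels:
                cell = both[(both.richness == r) & (both.fungicide == f)]
                if cell.empty:
                    logger.warning("treatment cell (%s, %s) is empty", r, f)
                elif cell.plant.nunique() == 1:
                    logger.warning(
                        "treatment cell (%s, %s) is unreplicated (1 plant)", r, f
                    )

    @property
    def richness_levels(self) -> tuple[str, ...]:
        both = pd.concat([self.samples, self.isolates])
        return tuple(pd.unique(both["richness"]))

    @property
    def fungicide_levels(self) -> tuple[str, ...]:
        both = pd.concat([self.samples, self.isolates])
        return tuple(pd.unique(both["fungicide"]))

    @property
    def plants_per_subplot(self) -> int:
        counts = self.samples.groupby(["richness", "fungicide"])["plant"].nunique()
        return int(counts.max()) if len(counts) else 0

    def cell_of(self, identifier: str) -> tuple[str, str, str]:
        """Resolve any sample or isolate id to its (richness, fungicide, plant)."""
        for frame in (self.samples, self.isolates):
            if identifier in frame.index:
                row = frame.loc[identifier]
                return (str(row.richness), str(row.fungicide), str(row.plant))
        raise KeyError(f"unknown identifier {identifier!r}")

    def isolate_labels(self, ids: list[str] | None = None) -> pd.DataFrame:
        frame = self.isolates if ids is None else self.isolates.loc[ids]
        return frame[["richness", "fungicide", "plant"]].copy()


# ---------------------------------------------------------------------------
# readers


def read_design(path: str | Path) -> ExperimentDesign:
    """Read design.csv (columns: id, kind, richness, fungicide, plant)."""
    frame = pd.read_csv(path, dtype=str)
    required = {"id", "kind", "richness", "fungicide", "plant"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"design table missing columns {sorted(missing)}")
    bad_kind = set(frame["kind"]) - {"sample", "isolate"}
    if bad_kind:
        raise ValidationError(f"design kind must be sample|isolate, got {bad_kind}")
    samples = frame[frame.kind == "sample"].set_index("id").drop(columns="kind")
    isolates = frame[frame.kind == "isolate"].set_index("id").drop(columns="kind")
    return ExperimentDesign(samples, isolates)


def read_plate_table(
    path: str | Path, water_column: str = "water"
) -> list[RawPlate]:
    """Read plates.csv: one row per isolate, 95 substrate columns + water.

    The water-control column must be named explicitly; the plate layout does
    not identify it positionally.  Carbon-source names are kept in file
    order.
    """
    frame = pd.read_csv(path)
    if "isolate_id" not in frame.columns:
        raise ValidationError("plate table missing 'isolate_id' column")
    if water_column not in frame.columns:
        raise ValidationError(
            f"plate table missing water-control column {water_column!r}"
        )
    substrates = [c for c in frame.columns if c not in ("isolate_id", water_column)]
    if len(substrates) != N_SUBSTRATES:
        raise ValidationError(
            f"expected {N_SUBSTRATES} carbon-source wells, found {len(substrates)}"
        )
    plates = []
    for _, row in frame.iterrows():
        plates.append(
            RawPlate(
                isolate_id=str(row["isolate_id"]),
                wells={s: float(row[s]) for s in substrates},
                water_control=float(row[water_column]),
            )
        )
    return plates


def read_soil_table(
    path: str | Path, design: ExperimentDesign
) -> list[SoilSample]:
    """Read soil.csv (sample_id, C_pct, N_pct, P_ppm, K_ppm, OM_pct, pH)."""
    frame = pd.read_csv(path)
    required = {"sample_id", "C_pct", "N_pct", "P_ppm", "K_ppm", "OM_pct", "pH"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"soil table missing columns {sorted(missing)}")
    samples = []
    for _, row in frame.iterrows():
        sid = str(row["sample_id"])
        richness, fungicide, plant = design.cell_of(sid)
        samples.append(
            SoilSample(
                sample_id=sid,
                richness=richness,
                fungicide=fungicide,
                plant=plant,
                carbon_pct=float(row["C_pct"]),
                nitrogen_pct=float(row["N_pct"]),
                phosphorus_ppm=float(row["P_ppm"]),
                potassium_ppm=float(row["K_ppm"]),
                organic_matter_pct=float(row["OM_pct"]),
                ph=float(row["pH"]),
            )
        )
    return samples


def read_counts_table(path: str | Path) -> list[CountPlate]:
    frame = pd.read_csv(path)
    required = {
        "sample_id",
        "overlay",
        "plate_rep",
        "dilution",
        "volume_ml",
        "total_colonies",
        "inhibitory_colonies",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"counts table missing columns {sorted(missing)}")
    return [
        CountPlate(
            sample_id=str(r.sample_id),
            overlay=str(r.overlay),
            plate_rep=int(r.plate_rep),
            dilution=float(r.dilution),
            plated_volume_ml=float(r.volume_ml),
            total_colonies=int(r.total_colonies),
            inhibitory_colonies=int(r.inhibitory_colonies),
        )
        for r in frame.itertuples()
    ]


def read_zones_table(path: str | Path, context: str = "resistance") -> list[ZoneMeasurement]:
    frame = pd.read_csv(path)
    required = {"isolate_id", "antibiotic", "rep", "radius1_mm", "radius2_mm"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"zones table missing columns {sorted(missing)}")
    return [
        ZoneMeasurement(
            subject_id=str(r.isolate_id),
            context=context,
            agent=str(r.antibiotic),
            rep=int(r.rep),
            radius1_mm=float(r.radius1_mm),
            radius2_mm=float(r.radius2_mm),
        )
        for r in frame.itertuples()
    ]


def read_tree(
    path: str | Path | None = None,
    data: str | None = None,
    design: ExperimentDesign | None = None,
    outgroup: str | None = None,
) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths.

    An unrooted tree (basal polytomy) is rejected rather than midpoint-rooted
    silently, because Faith's PD with the root path included depends on the
    root placement.  If ``outgroup`` is given, that tip is pruned after
    reading.  If ``design`` is given, the remaining tip labels must match the
    design's isolate identifiers exactly.
    """
    if (path is None) == (data is None):
        raise ValueError("provide exactly one of path= or data=")
    kwargs = dict(schema="newick", preserve_underscores=True, rooting="default-rooted")
    tree = (
        dendropy.Tree.get(path=str(path), **kwargs)
        if path is not None
        else dendropy.Tree.get(data=data, **kwargs)
    )
    if outgroup is not None:
        taxa = [t for t in tree.taxon_namespace if t.label == outgroup]
        if not taxa:
            raise ValidationError(f"outgroup tip {outgroup!r} not found in tree")
        tree.prune_taxa(taxa)
        tree.purge_taxon_namespace()
    if len(tree.seed_node.child_nodes()) != 2:
        raise ValidationError(
            "tree is unrooted (basal polytomy); supply a rooted bifurcating tree"
        )
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            label = node.taxon.label if node.taxon else "<internal>"
            raise ValidationError(f"missing branch length above node {label}")
    if design is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        known = set(design.isolates.index)
        unknown = sorted(tips - known)
        if unknown:
            raise ValidationError(
                "unknown isolate tips not in design: " + ", ".join(unknown)
            )
        absent = sorted(known - tips)
        if absent:
            raise ValidationError(
                "design isolates missing from tree: " + ", ".join(absent)
            )
    return tree


# ---------------------------------------------------------------------------
# writers (used by the simulator CLI and for round-trip checks)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    rows = []
    for kind, frame in (("sample", design.samples), ("isolate", design.isolates)):
        for ident, row in frame.iterrows():
            rows.append(
                {
                    "id": ident,
                    "kind": kind,
                    "richness": row.richness,
                    "fungicide": row.fungicide,
                    "plant": row.plant,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_plate_table(
    plates: list[RawPlate], path: str | Path, water_column: str = "water"
) -> None:
    rows = []
    for p in plates:
        row: dict[str, object] = {"isolate_id": p.isolate_id, water_column: p.water_control}
        row.update(p.wells)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_soil_table(samples: list[SoilSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "C_pct": s.carbon_pct,
                "N_pct": s.nitrogen_pct,
                "P_ppm": s.phosphorus_ppm,
                "K_ppm": s.potassium_ppm,
                "OM_pct": s.organic_matter_pct,
                "pH": s.ph,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def write_counts_table(plates: list[CountPlate], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "overlay": p.overlay,
                "plate_rep": p.plate_rep,
                "dilution": p.dilution,
                "volume_ml": p.plated_volume_ml,
                "total_colonies": p.total_colonies,
                "inhibitory_colonies": p.inhibitory_colonies,
            }
            for p in plates
        ]
    ).to_csv(path, index=False)


def write_zones_table(zones: list[ZoneMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "isolate_id": z.subject_id,
                "antibiotic": z.agent,
                "rep": z.rep,
                "radius1_mm": z.radius1_mm,
                "radius2_mm": z.radius2_mm,
            }
            for z in zones
        ]
    ).to_csv(path, index=False)
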
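"""End-to-end analysis: from raw tables and tree to summary statistics.

Given one experiment directory (design.csv, plates.csv, soil.csv,
counts.csv, zones.csv, tree.nwk), this module runs every analysis stage -
niche metrics and overlap, densities and inhibitor proportions, resistance
profiles, phylogenetic diversity and UniFrac/PERMANOVA, nested ANOVAs with
Tukey letters, nutrient-density correlations, and the per-carbon-source FDR
screen - and collects the results as DataFrames keyed by output file name.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays, io_design, phylo, resource_use, stats

logger = logging.getLogger(__name__)

__all__ = ["ReportOptions", "load_experiment", "run_report"]

#: Metrics analysed with the nested ANOVA, with their observation unit.
_SOIL_METRICS = [
    "carbon_pct",
    "nitrogen_pct",
    "phosphorus_ppm",
    "potassium_ppm",
    "organic_matter_pct",
    "ph",
]


@dataclass
class ReportOptions:
    threshold: float = resource_use.DEFAULT_THRESHOLD
    alpha: float = 0.05
    fdr_method: str = "bh"
    n_permutations: int = 999
    include_root: bool = True
    seed: int = 0
    overlap_group: str = "plant"


@dataclass
class LoadedExperiment:
    design: io_design.ExperimentDesign
    profiles: list
    soil: list
    counts: list
    zones: list
    tree: object


def load_experiment(
    indir: str | Path, threshold: float = resource_use.DEFAULT_THRESHOLD
) -> LoadedExperiment:
    indir = Path(indir)
    design = io_design.read_design(indir / "design.csv")
    plates = io_design.read_plate_table(indir / "plates.csv")
    profiles = [resource_use.profile_from_plate(p, threshold) for p in plates]
    soil = io_design.read_soil_table(indir / "soil.csv", design)
    counts = io_design.read_counts_table(indir / "counts.csv")
    zones = io_design.read_zones_table(indir / "zones.csv")
    tree = io_design.read_tree(path=indir / "tree.nwk", design=design)
    return LoadedExperiment(
        design=design, profiles=profiles, soil=soil, counts=counts,
        zones=zones, tree=tree,
    )


def _soil_frame(soil: list[io_design.SoilSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "richness": s.richness,
                "fungicide": s.fungicide,
                "plant": s.plant,
                **{m: getattr(s, m) for m in _SOIL_METRICS},
            }
            for s in soil
        ]
    ).set_index("sample_id")


def _anova_with_letters(
    values: np.ndarray,
    richness: np.ndarray,
    fungicide: np.ndarray,
    metric: str,
    alpha: float,
) -> tuple[list[dict], list[dict]]:
    """One nested ANOVA row set plus Tukey letters over the four cells."""
    res = stats.nested_anova(values, richness, fungicide)
    anova_rows = [
        {
            "metric": metric,
            "term": term,
            "df": int(res.table.at[term, "df"]),
            "sum_sq": res.table.at[term, "sum_sq"],
            "F": res.table.at[term, "F"],
            "p": res.table.at[term, "p"],
        }
        for term in ("richness", "fungicide(richness)", "residual")
    ]
    cells = np.char.add(np.char.add(richness.astype(str), "|"), fungicide.astype(str))
    letter_rows = []
    try:
        _, display = stats.tukey_hsd(values, cells, alpha=alpha)
        for group, letter in display.letters.items():
            letter_rows.append({"metric": metric, "group": group, "letters": letter})
    except ValueError as exc:  # e.g. singleton groups in tiny configurations
        logger.warning("Tukey HSD skipped for %s: %s", metric, exc)
    return anova_rows, letter_rows


def run_report(
    indir: str | Path, options: ReportOptions | None = None
) -> dict[str, pd.DataFrame]:
    options = options or ReportOptions()
    exp = load_experiment(indir, threshold=options.threshold)
    design = exp.design
    out: dict[str, pd.DataFrame] = {}

    # --- resource use ------------------------------------------------------
    metrics = resource_use.niche_metrics_table(exp.profiles)
    metrics = metrics.join(design.isolate_labels(list(metrics.index)))
    out["niche_metrics.csv"] = metrics.reset_index()

    overlaps = resource_use.overlap_matrix(
        exp.profiles, design, group_level=options.overlap_group
    )
    out["overlap_pairs.csv"] = overlaps.pairs
    out["overlap_group_means.csv"] = overlaps.group_means

    out["substrate_profile.csv"] = resource_use.group_substrate_profile(
        exp.profiles, design, level=["richness", "fungicide"]
    )

    # --- densities and resistance -----------------------------------------
    densities = assays.sample_density(exp.counts)
    labels = pd.DataFrame(
        [
            {"sample_id": sid, **dict(zip(("richness", "fungicide", "plant"), design.cell_of(sid)))}
            for sid in densities["sample_id"].unique()
        ]
    )
    densities = densities.merge(labels, on="sample_id")
    out["densities.csv"] = densities

    resistance = assays.resistance_profile(exp.zones)
    out["resistance_matrix.csv"] = resistance.reset_index()

    # --- phylogenetic metrics ---------------------------------------------
    iso = design.isolates
    pd_rows = []
    for (r, f), sub in iso.groupby(["richness", "fungicide"], sort=False):
        pd_rows.append(
            {
                "group": f"{r}|{f}",
                "level": "cell",
                "faith_pd": phylo.faith_pd(
                    exp.tree, list(sub.index), include_root=options.include_root
                ),
                "n_isolates": len(sub),
            }
        )
    for r, sub in iso.groupby("richness", sort=False):
        pd_rows.append(
            {
                "group": r,
                "level": "richness",
                "faith_pd": phylo.faith_pd(
                    exp.tree, list(sub.index), include_root=options.include_root
                ),
                "n_isolates": len(sub),
            }
        )
    out["pd_by_group.csv"] = pd.DataFrame(pd_rows)

    plant_groups = {
        plant: list(sub.index) for plant, sub in iso.groupby("plant", sort=False)
    }
    unifrac = phylo.pairwise_unifrac(exp.tree, plant_groups)
    out["unifrac.csv"] = unifrac.reset_index(names="plant")

    plant_factors = (
        iso.drop_duplicates("plant").set_index("plant")[["richness", "fungicide"]]
    )
    perm = phylo.permanova(
        unifrac,
        plant_factors,
        terms=["richness", ("fungicide", "richness")],
        n_permutations=options.n_permutations,
        seed=options.seed,
    )
    out["permanova.csv"] = perm.reset_index()

    # --- nested ANOVAs with Tukey letters ---------------------------------
    anova_rows: list[dict] = []
    letter_rows: list[dict] = []

    soil = _soil_frame(exp.soil)
    for metric in _SOIL_METRICS:
        a, l = _anova_with_letters(
            soil[metric].to_numpy(),
            soil["richness"].to_numpy(),
            soil["fungicide"].to_numpy(),
            metric,
            options.alpha,
        )
        anova_rows += a
        letter_rows += l

    pooled = densities[densities["overlay"] == "all"]
    for metric, column in [
        ("total_density", "total_cfu_per_g"),
        ("inhibitor_density", "inhibitor_cfu_per_g"),
        ("inhibitor_proportion", "inhibitor_proportion"),
    ]:
        sub = pooled.dropna(subset=[column])
        a, l = _anova_with_letters(
            sub[column].to_numpy(),
            sub["richness"].to_numpy(),
            sub["fungicide"].to_numpy(),
            metric,
            options.alpha,
        )
        anova_rows += a
        letter_rows += l

    for metric in ("niche_width", "efficiency"):
        sub = metrics.dropna(subset=[metric])
        a, l = _anova_with_letters(
            sub[metric].to_numpy().astype(float),
            sub["richness"].to_numpy(),
            sub["fungicide"].to_numpy(),
            metric,
            options.alpha,
        )
        anova_rows += a
        letter_rows += l

    pairs = overlaps.pairs.dropna(subset=["overlap"])
    if len(pairs):
        pair_labels = design.isolate_labels(list(pairs["a"]))
        a, l = _anova_with_letters(
            pairs["overlap"].to_numpy(),
            pair_labels["richness"].to_numpy(),
            pair_labels["fungicide"].to_numpy(),
            "niche_overlap",
            options.alpha,
        )
        anova_rows += a
        letter_rows += l

    out["anova.csv"] = pd.DataFrame(anova_rows)
    out["letters.csv"] = pd.DataFrame(letter_rows)

    # --- nutrient-density correlations, per richness level ----------------
    corr_rows = []
    merged = pooled.merge(
        soil.reset_index()[["sample_id"] + _SOIL_METRICS], on="sample_id"
    )
    for r, sub in merged.groupby("richness", sort=False):
        for nutrient in _SOIL_METRICS:
            for metric, column in [
                ("total_density", "total_cfu_per_g"),
                ("inhibitor_density", "inhibitor_cfu_per_g"),
                ("inhibitor_proportion", "inhibitor_proportion"),
            ]:
                pair = sub.dropna(subset=[column, nutrient])
                if len(pair) < 3:
                    continue
                r2, p = stats.pearson_r2(
                    pair[nutrient].to_numpy(), pair[column].to_numpy()
                )
                corr_rows.append(
                    {
                        "richness": r,
                        "nutrient": nutrient,
                        "metric": metric,
                        "R2": r2,
                        "p": p,
                        "n": len(pair),
                    }
                )
    out["correlations.csv"] = pd.DataFrame(corr_rows)

    # --- per-carbon-source screen -----------------------------------------
    out["substrate_tests.csv"] = stats.per_substrate_tests(
        exp.profiles,
        design,
        q=options.alpha,
        fdr_method=options.fdr_method,
    )
    return out


def summarize_markdown(tables: dict[str, pd.DataFrame]) -> str:
    """A short human-readable digest of the main report tables."""
    lines = ["# Analysis summary", ""]
    anova = tables.get("anova.csv")
    if anova is not None and len(anova):
        lines.append("## Nested ANOVA (fungicide within plant richness)")
        lines.append("")
        sub = anova[anova.term != "residual"]
        for _, row in sub.iterrows():
            lines.append(
                f"- {row.metric} / {row.term}: F = {row.F:.3f}, p = {row.p:.4f}"
            )
        lines.append("")
    perm = tables.get("permanova.csv")
    if perm is not None:
        lines.append("## PERMANOVA on unweighted UniFrac (plant communities)")
        lines.append("")
        for _, row in perm.iterrows():
            if row.term in ("residual", "total"):
                continue
            lines.append(
                f"- {row.term}: pseudo-F = {row.pseudo_F:.3f}, "
                f"R2 = {row.R2:.3f}, p = {row.p:.4f}"
            )
        lines.append("")
    screen = tables.get("substrate_tests.csv")
    if screen is not None and len(screen):
        lines.append("## Per-carbon-source discoveries (FDR-adjusted)")
        lines.append("")
        for family, sub in screen.groupby("family"):
            lines.append(
                f"- {family}: {int(sub.discovery.sum())} of "
                f"{sub.p_raw.notna().sum()} substrates"
            )
        lines.append("")
    return "\n".join(lines)
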
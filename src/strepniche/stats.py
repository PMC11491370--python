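"""Univariate statistical layer for the hierarchical field design.

The design nests the fungicide subplot factor within the plant-richness
whole-plot factor, so group differences are assessed with a nested ANOVA:
sequential (Type I) sums of squares with richness entered first, and both
the richness term and the fungicide-within-richness term tested against the
residual mean square (plants or isolates serve as replicates; the design's
single-plot-per-richness-level pseudo-replication caveat is documented, not
corrected).  Post-hoc group separation uses Tukey's HSD with a compact
letter display; per-carbon-source test families are corrected with
Benjamini-Hochberg (or Benjamini-Yekutieli) false-discovery-rate control.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_design import ExperimentDesign
from .resource_use import ResourceProfile

logger = logging.getLogger(__name__)

__all__ = [
    "NestedAnovaResult",
    "LetterDisplay",
    "FdrResult",
    "nested_anova",
    "nested_anova_matrix",
    "tukey_hsd",
    "compact_letters",
    "pearson_r2",
    "fdr_adjust",
    "per_substrate_tests",
]


@dataclass
class NestedAnovaResult:
    """Sequential-SS nested ANOVA table.

    ``table`` has rows ``richness``, ``fungicide(richness)``, ``residual``
    and ``total`` with columns df, sum_sq, mean_sq, F, p.
    """

    table: pd.DataFrame

    def p(self, term: str) -> float:
        return float(self.table.at[term, "p"])

    def f(self, term: str) -> float:
        return float(self.table.at[term, "F"])


def _design_projectors(
    richness: np.ndarray, fungicide: np.ndarray
) -> tuple[list[np.ndarray], list[int], int]:
    """Orthonormal bases for intercept, +richness, +fungicide-within-richness."""
    n = len(richness)
    r_levels = pd.unique(richness)
    if len(r_levels) < 2:
        raise ValueError("richness factor is constant")
    cols_r = [(richness == lev).astype(float) for lev in r_levels[1:]]
    cols_nested = []
    n_cells = 0
    for rlev in r_levels:
        mask = richness == rlev
        f_levels = pd.unique(fungicide[mask])
        if len(f_levels) < 2:
            raise ValueError(
                f"fungicide factor is constant within richness={rlev!r}"
            )
        n_cells += len(f_levels)
        for flev in f_levels[1:]:
            cols_nested.append((mask & (fungicide == flev)).astype(float))
    cell_key = pd.Series(richness).astype(str) + "|" + pd.Series(fungicide).astype(str)
    counts = cell_key.value_counts()
    if (counts < 1).any():
        raise ValueError("empty treatment cell")
    x0 = np.ones((n, 1))
    x1 = np.hstack([x0, np.column_stack(cols_r)])
    x2 = np.hstack([x1, np.column_stack(cols_nested)])
    qs = [np.linalg.qr(x)[0] for x in (x0, x1, x2)]
    dfs = [x1.shape[1] - 1, x2.shape[1] - x1.shape[1]]
    resid_df = n - x2.shape[1]
    if resid_df <= 0:
        raise ValueError("zero residual degrees of freedom (need >=2 obs per cell)")
    return qs, dfs, resid_df


def _sequential_ss(y: np.ndarray, qs: list[np.ndarray]) -> np.ndarray:
    """Fitted sums of squares under each cumulative model, per column of y."""
    return np.stack([((q.T @ y) ** 2).sum(axis=0) for q in qs])


def nested_anova_matrix(
    values: np.ndarray,
    richness: np.ndarray,
    fungicide: np.ndarray,
) -> pd.DataFrame:
    """Vectorized nested ANOVA over the columns of a 2-D response matrix.

    Returns one row per column with SS, F and p for both terms; used by the
    per-substrate screen where the same design is fit 95 times.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    richness = np.asarray(richness)
    fungicide = np.asarray(fungicide)
    if len(richness) != y.shape[0] or len(fungicide) != y.shape[0]:
        raise ValueError("labels do not match the number of observations")
    qs, term_dfs, resid_df = _design_projectors(richness, fungicide)
    fitted = _sequential_ss(y, qs)
    total_ss = (y**2).sum(axis=0)
    ss_rich = fitted[1] - fitted[0]
    ss_nested = fitted[2] - fitted[1]
    ss_resid = total_ss - fitted[2]
    # guard tiny negatives from cancellation
    ss_rich = np.maximum(ss_rich, 0.0)
    ss_nested = np.maximum(ss_nested, 0.0)
    ss_resid = np.maximum(ss_resid, 0.0)
    ms_resid = ss_resid / resid_df

    def f_and_p(ss: np.ndarray, df_t: int) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df_t) / ms_resid
        # no variation at all: report F=0, p=1 rather than 0/0
        degenerate = ss <= 1e-12
        f = np.where(degenerate, 0.0, f)
        p = np.where(degenerate, 1.0, sps.f.sf(f, df_t, resid_df))
        return f, p

    f_rich, p_rich = f_and_p(ss_rich, term_dfs[0])
    f_nested, p_nested = f_and_p(ss_nested, term_dfs[1])
    return pd.DataFrame(
        {
            "ss_richness": ss_rich,
            "ss_nested": ss_nested,
            "ss_residual": ss_resid,
            "df_richness": term_dfs[0],
            "df_nested": term_dfs[1],
            "df_residual": resid_df,
            "F_richness": f_rich,
            "p_richness": p_rich,
            "F_nested": f_nested,
            "p_nested": p_nested,
        }
    )


def nested_anova(
    values: np.ndarray,
    richness: np.ndarray,
    fungicide: np.ndarray,
) -> NestedAnovaResult:
    """Nested ANOVA of a single response: fungicide within plant richness.

    Sequential (Type I) sums of squares with richness entered first; both
    terms are tested against the residual mean square.
    """
    res = nested_anova_matrix(np.asarray(values, dtype=float), richness, fungicide)
    row = res.iloc[0]
    y = np.asarray(values, dtype=float)
    corrected_total = float(((y - y.mean()) ** 2).sum())
    table = pd.DataFrame(
        [
            {
                "term": "richness",
                "df": int(row.df_richness),
                "sum_sq": row.ss_richness,
                "F": row.F_richness,
                "p": row.p_richness,
            },
            {
                "term": "fungicide(richness)",
                "df": int(row.df_nested),
                "sum_sq": row.ss_nested,
                "F": row.F_nested,
                "p": row.p_nested,
            },
            {
                "term": "residual",
                "df": int(row.df_residual),
                "sum_sq": row.ss_residual,
                "F": np.nan,
                "p": np.nan,
            },
            {
                "term": "total",
                "df": len(y) - 1,
                "sum_sq": corrected_total,
                "F": np.nan,
                "p": np.nan,
            },
        ]
    ).set_index("term")
    table["mean_sq"] = table["sum_sq"] / table["df"].replace(0, np.nan)
    return NestedAnovaResult(table=table)


# ---------------------------------------------------------------------------
# Tukey HSD and the compact letter display


@dataclass
class LetterDisplay:
    """Letters per group: two groups share a letter iff not significantly different."""

    letters: dict[str, str]
    alpha: float


def compact_letters(
    groups: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one letter shared by all groups; each significantly
    different pair splits every letter column containing both; columns that
    become subsets of another are absorbed.  Letters are ordered by the
    first group (in input order) they contain.
    """
    columns: list[set[str]] = [set(groups)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop empties, duplicates and proper subsets
        unique: list[set[str]] = []
        for col in new_cols:
            if col and col not in unique:
                unique.append(col)
        columns = [c for c in unique if not any(c < d for d in unique)]
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: min(order[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        for g in col:
            letters[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def tukey_hsd(
    values: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, LetterDisplay]:
    """Tukey's HSD over all group pairs plus a compact letter display.

    Uses the studentized-range distribution (Tukey-Kramer for unequal
    group sizes).  Groups appear in first-occurrence order; singleton
    groups are rejected by name.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for lev in levels:
        arr = values[groups == lev]
        if len(arr) < 2:
            raise ValueError(f"group {lev!r} has fewer than two observations")
        arrays.append(arr)
    res = sps.tukey_hsd(*arrays)
    rows = []
    sig = {}
    for i, j in itertools.combinations(range(len(levels)), 2):
        p = float(res.pvalue[i, j])
        rows.append(
            {
                "group1": levels[i],
                "group2": levels[j],
                "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                "p": p,
                "significant": p < alpha,
            }
        )
        sig[(levels[i], levels[j])] = p < alpha
    table = pd.DataFrame(rows)
    letters = compact_letters([str(lev) for lev in levels], {(str(a), str(b)): s for (a, b), s in sig.items()})
    return table, LetterDisplay(letters=letters, alpha=alpha)


# ---------------------------------------------------------------------------
# correlations and FDR


def pearson_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p (t transform, n-2 df).

    Returns (NaN, NaN) for constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("correlation undefined for constant input")
        return math.nan, math.nan
    r, p = sps.pearsonr(x, y)
    return float(r * r), float(p)


@dataclass
class FdrResult:
    """Raw and FDR-adjusted p-values for one family of tests."""

    raw: np.ndarray
    adjusted: np.ndarray
    method: str
    q: float

    @property
    def discoveries(self) -> np.ndarray:
        return self.adjusted <= self.q


def fdr_adjust(
    pvalues: np.ndarray, method: str = "bh", q: float = 0.05
) -> FdrResult:
    """Benjamini-Hochberg (step-up) or Benjamini-Yekutieli adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    method = method.lower()
    if method not in ("bh", "by"):
        raise ValueError(f"unknown FDR method {method!r}")
    _, adjusted, _, _ = multipletests(p, method="fdr_" + method)
    return FdrResult(raw=p, adjusted=adjusted, method=method, q=q)


# ---------------------------------------------------------------------------
# the per-carbon-source screen


def per_substrate_tests(
    profiles: list[ResourceProfile],
    design: ExperimentDesign,
    q: float = 0.05,
    method: str = "welch",
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Treatment-effect screen on every carbon source, FDR-corrected per family.

    For each substrate's blank-corrected absorbance across isolates, three
    kinds of tests are run: (a) a two-sample fungicide comparison within
    each richness level, (b) a two-sample richness comparison pooling
    fungicide, and (c) a nested ANOVA (both terms).  Each family is
    FDR-adjusted across the 95 substrates; substrates with zero variance
    everywhere are excluded from their family with a log entry.

    ``method`` selects the two-sample test: welch | student | mann-whitney.
    """
    if method not in ("welch", "student", "mann-whitney"):
        raise ValueError(f"unknown test method {method!r}")
    ids = [p.isolate_id for p in profiles]
    od = np.vstack([p.od for p in profiles])
    substrates = list(profiles[0].substrates)
    labels = design.isolate_labels(ids)
    richness = labels["richness"].to_numpy()
    fungicide = labels["fungicide"].to_numpy()
    r_levels = list(pd.unique(richness))
    f_levels = list(pd.unique(fungicide))
    if len(f_levels) != 2:
        raise ValueError("pairwise fungicide test needs exactly two levels")

    def two_sample(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if method == "welch":
            return sps.ttest_ind(a, b, axis=0, equal_var=False).pvalue
        if method == "student":
            return sps.ttest_ind(a, b, axis=0, equal_var=True).pvalue
        return sps.mannwhitneyu(a, b, axis=0).pvalue

    families: dict[str, np.ndarray] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for rlev in r_levels:
            mask = richness == rlev
            a = od[mask & (fungicide == f_levels[0])]
            b = od[mask & (fungicide == f_levels[1])]
            families[f"fungicide_within_{rlev}"] = np.asarray(
                two_sample(a, b), dtype=float
            )
        if len(r_levels) == 2:
            families["richness"] = np.asarray(
                two_sample(od[richness == r_levels[0]], od[richness == r_levels[1]]),
                dtype=float,
            )
        anova = nested_anova_matrix(od, richness, fungicide)
        families["anova_richness"] = anova["p_richness"].to_numpy()
        families["anova_fungicide(richness)"] = anova["p_nested"].to_numpy()

    rows = []
    for family, praw in families.items():
        valid = ~np.isnan(praw)
        n_excluded = int((~valid).sum())
        if n_excluded:
            logger.info(
                "family %s: %d substrates with undefined p excluded from FDR",
                family,
                n_excluded,
            )
        padj = np.full_like(praw, np.nan)
        if valid.any():
            padj[valid] = fdr_adjust(praw[valid], method=fdr_method, q=q).adjusted
        for k, substrate in enumerate(substrates):
            rows.append(
                {
                    "substrate": substrate,
                    "family": family,
                    "p_raw": praw[k],
                    "p_adj": padj[k],
                    "discovery": bool(padj[k] <= q) if not np.isnan(padj[k]) else False,
                }
            )
    return pd.DataFrame(rows)
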
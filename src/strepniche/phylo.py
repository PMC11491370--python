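"""Phylogenetic community metrics: Faith's PD, unweighted UniFrac, PERMANOVA.

The isolate phylogeny is consumed as a rooted tree with branch lengths.
Treatment groups (e.g. the isolates of one plant, subplot or whole plot)
are presence/absence sets of tips, so community comparison is unweighted:

* **Faith's PD** of a tip set is the branch length of the minimal spanning
  subtree, optionally extended along the path to the root (the common
  convention of the classical R implementation, and the default here).
* **Unweighted UniFrac** between two tip sets is the branch length observed
  in exactly one of them divided by the branch length observed in either.
* **PERMANOVA** partitions the squared distances of a sample-by-sample
  matrix among design terms (Gower-centered, McArdle-Anderson trace form)
  and assesses each term's pseudo-F against label permutations.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import qr

logger = logging.getLogger(__name__)

__all__ = [
    "faith_pd",
    "unweighted_unifrac",
    "pairwise_unifrac",
    "permanova",
]


def _edge_tip_sets(tree: dendropy.Tree) -> list[tuple[float, frozenset[str]]]:
    """(branch length, descendant tip labels) for every non-root edge."""
    below: dict[int, frozenset[str]] = {}
    edges = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips = frozenset([node.taxon.label])
        else:
            tips = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = tips
        if node is tree.seed_node:
            continue
        length = node.edge.length
        if length is None:
            raise ValueError("tree has edges without branch lengths")
        edges.append((float(length), tips))
    return edges


def _check_tips(tree: dendropy.Tree, tips: Iterable[str]) -> frozenset[str]:
    tips = frozenset(tips)
    known = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = sorted(tips - known)
    if unknown:
        raise ValueError("unknown tips: " + ", ".join(unknown))
    return tips


def faith_pd(
    tree: dendropy.Tree, tips: Iterable[str], include_root: bool = True
) -> float:
    """Faith's phylogenetic diversity of a tip set.

    With ``include_root`` (default) the path from the tips' common ancestor
    up to the root is counted as well; without it only branches strictly
    inside the minimal spanning subtree contribute (a single tip then has
    PD 0).
    """
    tip_set = _check_tips(tree, tips)
    if not tip_set:
        raise ValueError("tip set is empty")
    total = len(tip_set)
    pd_sum = 0.0
    for length, below in _edge_tip_sets(tree):
        k = len(below & tip_set)
        if k == 0:
            continue
        if include_root or k < total:
            pd_sum += length
    return pd_sum


def unweighted_unifrac(
    tree: dendropy.Tree, tips_a: Iterable[str], tips_b: Iterable[str]
) -> float:
    """Unweighted UniFrac distance between two tip sets, in [0, 1]."""
    a = _check_tips(tree, tips_a)
    b = _check_tips(tree, tips_b)
    if not a or not b:
        raise ValueError("both tip sets must be non-empty")
    unique = 0.0
    union = 0.0
    for length, below in _edge_tip_sets(tree):
        in_a = not below.isdisjoint(a)
        in_b = not below.isdisjoint(b)
        if in_a or in_b:
            union += length
            if in_a != in_b:
                unique += length
    if union == 0.0:
        return 0.0
    return unique / union


def pairwise_unifrac(
    tree: dendropy.Tree, groups: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Symmetric matrix of unweighted UniFrac distances between groups.

    Groups are tip sets (e.g. the isolates of each plant); the resulting
    matrix is what PERMANOVA consumes.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    sets = {g: _check_tips(tree, groups[g]) for g in labels}
    for g, s in sets.items():
        if not s:
            raise ValueError(f"group {g!r} is empty")
    edges = _edge_tip_sets(tree)
    presence = {
        g: np.array([not below.isdisjoint(sets[g]) for _, below in edges])
        for g in labels
    }
    lengths = np.array([length for length, _ in edges])
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            either = presence[labels[i]] | presence[labels[j]]
            differ = presence[labels[i]] ^ presence[labels[j]]
            union = lengths[either].sum()
            out[i, j] = out[j, i] = (
                lengths[differ].sum() / union if union > 0 else 0.0
            )
    return pd.DataFrame(out, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# PERMANOVA


def _model_matrices(
    factors: pd.DataFrame, terms: Sequence[str | tuple[str, str]]
) -> tuple[list[np.ndarray], list[str], list[int]]:
    """Cumulative full-rank design matrices for sequential terms.

    A term is a column name (main effect) or a tuple ``(inner, outer)`` for
    ``inner`` nested within ``outer``.  Dummies use drop-first coding so
    each matrix is full rank when all cells are populated.
    """
    n = len(factors)
    mats = [np.ones((n, 1))]
    names = []
    dfs = []
    for term in terms:
        if isinstance(term, tuple):
            inner, outer = term
            cols = []
            for olev in pd.unique(factors[outer]):
                in_outer = (factors[outer] == olev).to_numpy()
                ilevs = pd.unique(factors.loc[in_outer, inner])
                if len(ilevs) < 2:
                    raise ValueError(
                        f"factor {inner!r} is constant within {outer}={olev!r}"
                    )
                for ilev in ilevs[1:]:
                    cols.append(in_outer & (factors[inner] == ilev).to_numpy())
            name = f"{inner}({outer})"
        else:
            levs = pd.unique(factors[term])
            if len(levs) < 2:
                raise ValueError(f"factor {term!r} is constant")
            cols = [(factors[term] == lev).to_numpy() for lev in levs[1:]]
            name = str(term)
        X = np.hstack([mats[-1], np.column_stack(cols).astype(float)])
        mats.append(X)
        names.append(name)
        dfs.append(X.shape[1] - mats[-2].shape[1])
    return mats, names, dfs


def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist**2
    n = a.shape[0]
    centerer = np.eye(n) - np.ones((n, n)) / n
    return centerer @ a @ centerer


def permanova(
    dist: pd.DataFrame,
    factors: pd.DataFrame | pd.Series,
    terms: Sequence[str | tuple[str, str]] | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
    strata: str | None = None,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    dist
        Square symmetric distance matrix with matching index/columns.
    factors
        Per-observation design labels indexed like ``dist``; a Series is
        treated as a single factor named ``group``.
    terms
        Sequential model terms: column names, or ``(inner, outer)`` tuples
        for a nested term.  Defaults to all columns of ``factors`` as main
        effects.
    strata
        Optional column restricting permutations to shuffle observations
        only within levels of that column (e.g. within whole plots for a
        nested subplot term).

    Returns a table with one row per term plus residual and total:
    df, sum of squares, R^2, pseudo-F and the add-one permutation p-value
    ``(1 + #{F* >= F}) / (1 + n_permutations)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if isinstance(factors, pd.Series):
        factors = factors.to_frame(name="group")
    factors = factors.loc[list(dist.index)]
    if terms is None:
        terms = [c for c in factors.columns]
    n = len(dist)
    mats, names, term_dfs = _model_matrices(factors, terms)
    n_groups = mats[-1].shape[1]
    if n <= n_groups:
        raise ValueError(
            f"{n} observations cannot support {n_groups} model columns"
        )
    # orthonormal bases of the cumulative column spaces
    qs = [qr(X, mode="economic")[0] for X in mats]
    dist_values = np.asarray(dist, dtype=float)
    if not np.allclose(dist_values, dist_values.T):
        raise ValueError("distance matrix is not symmetric")
    g = _gower_center(dist_values)

    rng = np.random.default_rng(seed)
    if strata is not None:
        blocks = [
            np.flatnonzero((factors[strata] == lev).to_numpy())
            for lev in pd.unique(factors[strata])
        ]

    def term_f(gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        traces = [float(np.sum((q.T @ gm) * q.T)) for q in qs]
        total = float(np.trace(gm))
        term_ss = np.diff(traces)
        resid_ss = total - traces[-1]
        resid_df = n - n_groups
        ms_resid = resid_ss / resid_df
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stats = (term_ss / np.asarray(term_dfs)) / ms_resid
        f_stats = np.where(np.abs(term_ss) <= 1e-12, 0.0, f_stats)
        return term_ss, f_stats

    term_ss, f_obs = term_f(g)
    total_ss = float(np.trace(g))
    resid_ss = total_ss - float(np.sum((qs[-1].T @ g) * qs[-1].T))
    resid_df = n - n_groups

    exceed = np.zeros(len(terms))
    for _ in range(n_permutations):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for block in blocks:
                perm[block] = block[rng.permutation(len(block))]
        gp = g[np.ix_(perm, perm)]
        _, f_perm = term_f(gp)
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_permutations)

    rows = []
    for name, df_t, ss, f, p in zip(names, term_dfs, term_ss, f_obs, pvals):
        rows.append(
            {
                "term": name,
                "df": df_t,
                "sum_sq": ss,
                "R2": ss / total_ss if total_ss > 0 else 0.0,
                "pseudo_F": f,
                "p": p,
            }
        )
    rows.append(
        {
            "term": "residual",
            "df": resid_df,
            "sum_sq": resid_ss,
            "R2": resid_ss / total_ss if total_ss > 0 else 0.0,
            "pseudo_F": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "total",
            "df": n - 1,
            "sum_sq": total_ss,
            "R2": 1.0,
            "pseudo_F": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")
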
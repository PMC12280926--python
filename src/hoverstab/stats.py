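"""Comparative statistics: morphology -> MO2 regression, variable
importance, metabolic grouping, species comparisons, and topology-based
phylogenetic signal (Abouheif's test).

The regression layer is ordinary least squares on raw (uncentred)
predictor scales, so the intercept is interpretable as the response at the
origin of the morphological space.  Variable importance is measured two
ways — refitting without a predictor (drop) and randomly permuting its
values (permute) — both scored as the degradation in R^2.

Abouheif's test detects phylogenetic autocorrelation in a tip trait using
tree topology alone.  The proximity between tips i and j is the inverse
of the product of the numbers of direct descendants of the internal nodes
on the path between them; with the matrix row-normalised and its diagonal
zero, Abouheif's C is Moran's I of the centred trait.  Significance comes
from permuting trait values across tips.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "AbouheifResult",
    "ols",
    "importance",
    "assign_groups",
    "anova_oneway",
    "tukey_hsd",
    "species_tests",
    "abouheif_proximity",
    "abouheif",
]


@dataclass
class RegressionResult:
    """OLS fit: named coefficients (incl. intercept), R^2, residuals."""

    coeffs: pd.Series
    r2: float
    residuals: np.ndarray
    fitted: np.ndarray
    n: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        names = [c for c in self.coeffs.index if c != "intercept"]
        return (
            self.coeffs.get("intercept", 0.0)
            + X[names].to_numpy() @ self.coeffs[names].to_numpy()
        )


@dataclass
class AbouheifResult:
    c_stat: float
    p: float
    n_perm: int
    seed: int | None


def ols(X: pd.DataFrame, y, add_intercept: bool = True) -> RegressionResult:
    """Least-squares fit of ``y`` on the columns of ``X``.

    Raises on rank deficiency, naming the collinear columns.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    M = X.to_numpy(dtype=float)
    if add_intercept:
        M = np.column_stack([np.ones(len(M)), M])
        cols = ["intercept"] + cols
    if np.linalg.matrix_rank(M) < M.shape[1]:
        bad = _collinear_columns(M, cols)
        raise ValueError(f"design matrix is rank-deficient; suspect columns: {bad}")
    import statsmodels.api as sm

    res = sm.OLS(y, M).fit()
    fitted = np.asarray(res.fittedvalues)
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return RegressionResult(
        coeffs=pd.Series(np.asarray(res.params), index=cols),
        r2=r2,
        residuals=resid,
        fitted=fitted,
        n=len(y),
    )


def _collinear_columns(M: np.ndarray, cols: list[str]) -> list[str]:
    """Columns implicated in a rank deficiency, via the SVD null space."""
    _, s, vt = np.linalg.svd(M)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    null = vt[np.sum(s > tol) :]
    weight = np.abs(null).sum(axis=0)
    return [c for c, w in zip(cols, weight) if w > 1e-8]


def importance(
    X: pd.DataFrame,
    y,
    method: str = "drop",
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-predictor importance as the drop in R^2.

    ``drop``: refit without the predictor; ``permute``: mean R^2 loss over
    ``n_perm`` seeded shuffles of the predictor's column (full model is
    not refit; the fitted coefficients are reused on the shuffled design).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    full = ols(X, y)
    records = []
    if method == "drop":
        for col in X.columns:
            sub = ols(X.drop(columns=[col]), y)
            records.append({"predictor": col, "delta_r2": full.r2 - sub.r2})
    elif method == "permute":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1 for permutation importance")
        rng = np.random.default_rng(seed)
        sst = float(np.sum((y - y.mean()) ** 2))
        for col in X.columns:
            losses = np.empty(n_perm)
            Xp = X.copy()
            for b in range(n_perm):
                Xp[col] = rng.permutation(X[col].to_numpy())
                pred = full.predict(Xp)
                r2p = 1.0 - float(np.sum((y - pred) ** 2)) / sst
                losses[b] = full.r2 - r2p
            records.append(
                {"predictor": col, "delta_r2": float(losses.mean()), "n_perm": n_perm}
            )
    else:
        raise ValueError("method must be 'drop' or 'permute'")
    out = pd.DataFrame(records).set_index("predictor")
    out.attrs["method"] = method
    out.attrs["seed"] = seed
    return out


def assign_groups(mo2net: pd.Series, ratio: pd.Series) -> tuple[pd.Series, dict]:
    """Split species into low (G1) and high (G2) metabolic groups.

    A species lands in G2 when either its MO2net or its hover/rest ratio
    is strictly above the respective across-species mean.
    """
    mo2net = pd.Series(mo2net)
    ratio = pd.Series(ratio).reindex(mo2net.index)
    if len(mo2net) < 2:
        raise ValueError("need at least 2 species to form groups")
    m_net, m_ratio = float(mo2net.mean()), float(ratio.mean())
    high = (mo2net > m_net) | (ratio > m_ratio)
    if not high.any():
        warnings.warn("no species above average; all assigned to G1", stacklevel=2)
    labels = pd.Series(np.where(high, "G2", "G1"), index=mo2net.index, name="group")
    return labels, {"mean_mo2net": m_net, "mean_ratio": m_ratio}


def anova_oneway(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p from the sum-of-squares split.

    Degenerate zero-within-variance designs return p = 0 with a warning
    (F is infinite) or F = 0, p = 1 when all observations are identical.
    """
    arrs = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 replicates")
    allv = np.concatenate(arrs)
    grand = allv.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    df_b = len(arrs) - 1
    df_w = allv.size - len(arrs)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance; F is infinite", stacklevel=2)
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), p


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD via the studentized-range distribution."""
    names = list(groups)
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    df_w = sum(a.size for a in arrs.values()) - len(arrs)
    msw = (
        sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs.values()) / df_w
        if df_w > 0
        else np.nan
    )
    k = len(arrs)
    rows = []
    for a, b in itertools.combinations(names, 2):
        xa, xb = arrs[a], arrs[b]
        diff = xa.mean() - xb.mean()
        se = math.sqrt(msw / 2 * (1 / xa.size + 1 / xb.size)) if msw > 0 else 0.0
        if se == 0:
            q = np.inf if diff != 0 else 0.0
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
        if q == 0.0:
            p = 1.0
        rows.append(
            {"group1": a, "group2": b, "diff": diff, "q": q, "p": p, "reject": p < alpha}
        )
    return pd.DataFrame(rows)


def species_tests(
    df: pd.DataFrame,
    value: str = "mo2",
    species: str = "species",
    condition: str | None = "condition",
    groups: pd.Series | None = None,
) -> dict:
    """Species-level comparisons of per-individual metabolic rates.

    Runs a one-way ANOVA plus Tukey HSD across species (hovering values),
    per-species hover-vs-rest Welch t-tests when ``condition`` is present,
    and a G1-vs-G2 Welch t-test when group labels are supplied.  Species
    with a single replicate are excluded with a warning.
    """
    out: dict = {}
    sub = df
    if condition is not None and condition in df.columns:
        sub = df[df[condition] == "hover"]
    by_species = {}
    for sp, g in sub.groupby(species):
        vals = g[value].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"species {sp!r} has one replicate; excluded", stacklevel=2)
            continue
        by_species[sp] = vals
    out["anova"] = anova_oneway(by_species)
    out["tukey"] = tukey_hsd(by_species)
    if condition is not None and condition in df.columns:
        per_species = {}
        for sp, g in df.groupby(species):
            h = g.loc[g[condition] == "hover", value].to_numpy(dtype=float)
            r = g.loc[g[condition] == "rest", value].to_numpy(dtype=float)
            if h.size >= 2 and r.size >= 2:
                t, p = sps.ttest_ind(h, r, equal_var=False)
                per_species[sp] = (float(t), float(p))
        out["hover_vs_rest"] = per_species
    if groups is not None:
        sp_means = sub.groupby(species)[value].mean()
        g1 = sp_means[groups.reindex(sp_means.index) == "G1"].to_numpy()
        g2 = sp_means[groups.reindex(sp_means.index) == "G2"].to_numpy()
        if g1.size >= 2 and g2.size >= 2:
            t, p = sps.ttest_ind(g2, g1, equal_var=False)
            out["g1_vs_g2"] = (float(t), float(p))
    return out


# ---------------------------------------------------------------------------
# Abouheif's phylogenetic-signal test
# ---------------------------------------------------------------------------


def _as_tree(tree):
    import dendropy

    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def abouheif_proximity(tree, taxa: list[str] | None = None) -> pd.DataFrame:
    """Topology-only Abouheif proximity matrix, row-normalised.

    A[i, j] = 1 / prod(direct-descendant counts of the internal nodes on
    the path from tip i to tip j, the MRCA included); the diagonal is 0
    and each row is divided by its sum.  Branch lengths are ignored.
    """
    t = _as_tree(tree)
    tips = [lf for lf in t.leaf_node_iter()]
    names = [lf.taxon.label for lf in tips]
    if taxa is not None:
        order = {n: i for i, n in enumerate(names)}
        missing = [x for x in taxa if x not in order]
        if missing:
            raise ValueError(f"taxa not in tree: {missing}")
        tips = [tips[order[x]] for x in taxa]
        names = list(taxa)
    n = len(tips)
    ancestors = []
    for tip in tips:
        chain = []
        node = tip.parent_node
        while node is not None:
            chain.append(node)
            node = node.parent_node
        ancestors.append(chain)
    dd = {}
    A = np.zeros((n, n))
    for i in range(n):
        set_i = {id(nd): k for k, nd in enumerate(ancestors[i])}
        for j in range(i + 1, n):
            # walk j's ancestor chain up to the MRCA
            for kj, nd in enumerate(ancestors[j]):
                if id(nd) in set_i:
                    ki = set_i[id(nd)]
                    path = ancestors[i][: ki + 1] + ancestors[j][:kj]
                    break
            prod = 1.0
            for nd in path:
                if id(nd) not in dd:
                    dd[id(nd)] = len(nd.child_nodes())
                prod *= dd[id(nd)]
            A[i, j] = A[j, i] = 1.0 / prod
    A = A / A.sum(axis=1, keepdims=True)
    return pd.DataFrame(A, index=names, columns=names)


def _moran(x: np.ndarray, W: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(xc @ xc)
    return float(xc @ W @ xc) / denom


def abouheif(
    tree,
    trait: pd.Series,
    n_perm: int = 999,
    seed: int | None = 0,
    method: str = "permutation",
) -> AbouheifResult:
    """Abouheif's C with a tip-permutation p-value.

    ``method='permutation'`` draws ``n_perm`` seeded random permutations
    and applies the +1 correction, p = (1 + #{C_perm >= C_obs}) /
    (n_perm + 1).  ``method='exhaustive'`` enumerates every permutation
    (n <= 8 tips) and reports the exact fraction with C_perm >= C_obs.
    The statistic is invariant to affine transforms of the trait; a
    constant trait is rejected.
    """
    trait = pd.Series(trait, dtype=float)
    if trait.std() == 0:
        raise ValueError("trait is constant: standardisation undefined")
    W = abouheif_proximity(tree, taxa=list(trait.index)).to_numpy()
    x = trait.to_numpy()
    c_obs = _moran(x, W)
    if method == "exhaustive":
        n = x.size
        if n > 8:
            raise ValueError("exhaustive enumeration limited to 8 tips")
        cs = np.array([_moran(np.array(p), W) for p in itertools.permutations(x)])
        p = float(np.mean(cs >= c_obs - 1e-12))
        return AbouheifResult(c_stat=c_obs, p=p, n_perm=len(cs), seed=None)
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _moran(rng.permutation(x), W) >= c_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return AbouheifResult(c_stat=c_obs, p=p, n_perm=n_perm, seed=seed)
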
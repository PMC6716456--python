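"""Hypothesis-driven three-group selection framework.

Every network feature (measure x scope, in a *strength* flavor from the
static network and a *variability* flavor from the dynamic-network
variance) is compared across the three pairwise group contrasts
(control vs ptsd, control vs pcs_ptsd, ptsd vs pcs_ptsd) with a
covariate-adjusted linear model (age, education, race, head motion),
giving six cells per feature.  p-values are Benjamini-Hochberg corrected
within each (pair, flavor) comparison family.  Features then enter the
two hypothesis sets:

* hypothesis-2: significant in all six cells, with adjusted group means
  monotone in one consistent direction (strength) and strictly
  decreasing control > ptsd > pcs_ptsd (variability: rigidity);
* hypothesis-1: significant in the four control-vs-clinical cells, NOT
  significant in either ptsd-vs-pcs cell, with both clinical groups
  displaced from control in the same direction.

Local measures are intersected (cc AND eff_loc for nodes; spl AND eb for
edges), and surviving edges are finally gated on the raw connectivity
itself: the edge's SEC (strength) and DGC variance (variability) must
independently pass the same FDR + trend scheme.

Feature columns follow the ``{measure}.{flavor}.{scope}`` schema, e.g.
``cc.static.node:R03``, ``eb.var.edge:R01>R04``, ``ec.static.edge:...``
(raw connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

GROUPS = ("control", "ptsd", "pcs_ptsd")
PAIRS = (("control", "ptsd"), ("control", "pcs_ptsd"), ("ptsd", "pcs_ptsd"))
DEFAULT_COVARIATES = ("age", "education", "race", "motion")

# measures whose higher-is-more-integrated sense doesn't matter here; the
# trend logic is direction-agnostic for strength and fixed for variability
NODE_MEASURES = ("cc", "effloc")
EDGE_MEASURES = ("spl", "eb")
RAW_MEASURE = "ec"


def count_comparisons(k: int) -> tuple[int, int, int]:
    """Comparison budget for a k-region network.

    k segregation comparisons (one per region), k^2 - k integration
    comparisons (one per ordered pair), each for the static and the
    dynamic-variance networks: total 2 k^2.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_seg = k
    n_int = k * k - k
    return n_seg, n_int, 2 * (n_seg + n_int)


# ---------------------------------------------------------------------------
# Covariate-adjusted pairwise comparison
# ---------------------------------------------------------------------------

def _covariate_design(manifest: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    cols = {}
    for c in covariates:
        v = manifest[c]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            counts = v.value_counts()
            merged = v.where(v.map(counts) >= 2, "other")
            dummies = pd.get_dummies(merged, prefix=c, drop_first=True, dtype=float)
            for dc in dummies.columns:
                cols[dc] = dummies[dc].to_numpy()
        else:
            cols[c] = v.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=manifest.index)


def _pair_design(
    groups: np.ndarray,
    covariates: pd.DataFrame | None,
    pair: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix [1, group, covariates] restricted to the pair's rows."""
    groups = np.asarray(groups)
    mask = np.isin(groups, pair)
    g = (groups[mask] == pair[1]).astype(float)
    if g.sum() < 3 or (1 - g).sum() < 3:
        raise ValueError(f"each group in {pair} needs n >= 3")
    X = np.column_stack([np.ones(g.size), g])
    names = ["const", "group"]
    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.loc[mask].to_numpy(dtype=float)
        keep = C.std(axis=0) > 0
        X = np.column_stack([X, C[:, keep]])
        names += [c for c, k in zip(covariates.columns, keep) if k]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear covariates in design: {names[2:]}")
    return X, mask, names


def _pair_ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every column of Y on X: (p for group term, group coef, base mean).

    The group dummy is column 1; adjusted means are evaluated at the
    covariate grand means (base = level-a mean, base + coef = level-b).
    """
    from scipy import stats

    n, m = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - m
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    base = beta[0].copy()
    if m > 2:
        base = base + X[:, 2:].mean(axis=0) @ beta[2:]
    return p, beta[1], base


def ancova_pair(
    feature: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | None,
    pair: tuple[str, str],
) -> tuple[float, dict[str, float], float]:
    """Two-group comparison of one feature, adjusted for covariates.

    Linear model feature ~ group + covariates on the two groups' rows;
    returns the two-sided p for the group term, adjusted group means at
    the covariate grand means, and the direction (mean[b] - mean[a]).
    Matches statsmodels OLS exactly (same normal-equations solution).
    """
    X, mask, _ = _pair_design(groups, covariates, pair)
    y = np.asarray(feature, dtype=float)[mask][:, None]
    p, coef, base = _pair_ols(X, y)
    adjusted = {pair[0]: float(base[0]), pair[1]: float(base[0] + coef[0])}
    return float(p[0]), adjusted, float(coef[0])


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject mask, adjusted q-values)."""
    reject, qvals, *_ = multipletests(np.asarray(p_values, dtype=float),
                                      alpha=q, method="fdr_bh")
    return reject, qvals


# ---------------------------------------------------------------------------
# Full comparison table
# ---------------------------------------------------------------------------

def _parse_feature(col: str) -> tuple[str, str, str] | None:
    parts = col.split(".", 2)
    if len(parts) != 3:
        return None
    return parts[0], parts[1], parts[2]  # measure, flavor, scope


def compare_features(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    q: float = 0.05,
) -> pd.DataFrame:
    """ANCOVA for every feature x pair, BH-corrected per (pair, flavor, kind).

    ``kind`` separates the network-measure family from the raw-connectivity
    (``ec``) family so the gate's correction is independent.  Returns a
    long table with columns measure/flavor/scope/pair/p/q/significant/
    mean_a/mean_b/direction.
    """
    groups = manifest["group"].to_numpy()
    cov = _covariate_design(manifest, covariates) if covariates else None
    cols = [c for c in features.columns if _parse_feature(c) is not None]
    Y_all = features[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(Y_all)):
        bad = [c for c, ok in zip(cols, np.isfinite(Y_all).all(axis=0)) if not ok]
        raise ValueError(f"non-finite feature values in {bad[:5]}")
    rows = []
    for pair in PAIRS:
        X, mask, _ = _pair_design(groups, cov, pair)
        p, coef, base = _pair_ols(X, Y_all[mask])
        for i, col in enumerate(cols):
            measure, flavor, scope = _parse_feature(col)
            rows.append({
                "measure": measure, "flavor": flavor, "scope": scope,
                "pair": f"{pair[0]}|{pair[1]}", "p": float(p[i]),
                "mean_a": float(base[i]), "mean_b": float(base[i] + coef[i]),
                "direction": float(coef[i]),
            })
    table = pd.DataFrame(rows)
    table["kind"] = np.where(table["measure"] == RAW_MEASURE, "raw", "metric")
    table["q_value"] = np.nan
    table["significant"] = False
    for (_pair, _flavor, _kind), idx in table.groupby(["pair", "flavor", "kind"]).groups.items():
        rej, qv = fdr_bh(table.loc[idx, "p"].to_numpy(), q)
        table.loc[idx, "q_value"] = qv
        table.loc[idx, "significant"] = rej
    return table


# ---------------------------------------------------------------------------
# Trend conformance and hypothesis set logic
# ---------------------------------------------------------------------------

def trend_filter(pair_means: dict[str, tuple[float, float]], flavor: str,
                 hypothesis: int) -> tuple[bool, str]:
    """Check control->ptsd->pcs_ptsd trend on adjusted means.

    For hypothesis-2, strength must be strictly monotone in one direction
    (label inflation/deflation) and variability strictly decreasing
    (rigidity); ties break conformance.  For hypothesis-1, both clinical
    groups must sit on the same side of control (no ptsd-vs-pcs ordering
    required), variability below control.
    """
    c_p = pair_means["control|ptsd"]
    c_cp = pair_means["control|pcs_ptsd"]
    p_cp = pair_means["ptsd|pcs_ptsd"]
    d1 = c_p[1] - c_p[0]        # ptsd - control
    d2 = c_cp[1] - c_cp[0]      # pcs - control
    d3 = p_cp[1] - p_cp[0]      # pcs - ptsd
    if flavor == "var":
        if hypothesis == 2:
            return (d1 < 0 and d2 < 0 and d3 < 0), "rigidity"
        return (d1 < 0 and d2 < 0), "rigidity"
    if hypothesis == 2:
        if d1 > 0 and d2 > 0 and d3 > 0:
            return True, "inflation"
        if d1 < 0 and d2 < 0 and d3 < 0:
            return True, "deflation"
        return False, ""
    if d1 > 0 and d2 > 0:
        return True, "inflation"
    if d1 < 0 and d2 < 0:
        return True, "deflation"
    return False, ""


def intersect_local(hits_a: set, hits_b: set) -> set:
    """Overlap of the two local measures' selections."""
    return set(hits_a) & set(hits_b)


@dataclass
class HypothesisResult:
    h1_nodes: set = field(default_factory=set)
    h2_nodes: set = field(default_factory=set)
    h1_edges: set = field(default_factory=set)
    h2_edges: set = field(default_factory=set)
    gated_h1_edges: set = field(default_factory=set)
    gated_h2_edges: set = field(default_factory=set)
    trend_labels: dict = field(default_factory=dict)

    @property
    def gated_edges(self) -> set:
        return self.gated_h1_edges | self.gated_h2_edges


def _cells(table: pd.DataFrame, measure: str, scope: str) -> pd.DataFrame:
    return table[(table["measure"] == measure) & (table["scope"] == scope)]


def _feature_pattern(cells: pd.DataFrame, hypothesis: int) -> tuple[bool, str]:
    """Apply the 6-cell significance + trend rule for one (measure, scope)."""
    if len(cells) != 6:
        return False, ""
    sig = {}
    means = {"static": {}, "var": {}}
    for _, r in cells.iterrows():
        sig[(r["flavor"], r["pair"])] = bool(r["significant"])
        means[r["flavor"]][r["pair"]] = (r["mean_a"], r["mean_b"])
    clinical_cells = [(f, p) for f in ("static", "var")
                      for p in ("control|ptsd", "control|pcs_ptsd")]
    pvs_cells = [(f, "ptsd|pcs_ptsd") for f in ("static", "var")]
    if hypothesis == 2:
        if not all(sig.values()):
            return False, ""
    else:
        if not all(sig[c] for c in clinical_cells):
            return False, ""
        if any(sig[c] for c in pvs_cells):
            return False, ""
    ok_s, label_s = trend_filter(means["static"], "static", hypothesis)
    ok_v, _ = trend_filter(means["var"], "var", hypothesis)
    return (ok_s and ok_v), label_s


def apply_hypotheses(table: pd.DataFrame, q: float = 0.05) -> HypothesisResult:
    """Hypothesis-1/2 membership with local-measure intersection and EC gate."""
    res = HypothesisResult()
    node_scopes = sorted(table.loc[table["measure"].isin(NODE_MEASURES), "scope"].unique())
    edge_scopes = sorted(table.loc[table["measure"].isin(EDGE_MEASURES), "scope"].unique())

    def hits(measure: str, scopes: list[str], hypothesis: int) -> set:
        out = set()
        for scope in scopes:
            ok, label = _feature_pattern(_cells(table, measure, scope), hypothesis)
            if ok:
                out.add(scope)
                res.trend_labels[(measure, scope, hypothesis)] = label
        return out

    for hyp, nodes_attr, edges_attr in ((1, "h1_nodes", "h1_edges"), (2, "h2_nodes", "h2_edges")):
        nodes = intersect_local(hits("cc", node_scopes, hyp), hits("effloc", node_scopes, hyp))
        edges = intersect_local(hits("spl", edge_scopes, hyp), hits("eb", edge_scopes, hyp))
        setattr(res, nodes_attr, nodes)
        setattr(res, edges_attr, edges)

    # h1 and h2 are mutually exclusive by construction (P-vs-CP cells); enforce
    res.h1_nodes -= res.h2_nodes
    res.h1_edges -= res.h2_edges

    raw_scopes = set(table.loc[table["measure"] == RAW_MEASURE, "scope"].unique())
    for hyp, edges, out_attr in ((1, res.h1_edges, "gated_h1_edges"),
                                 (2, res.h2_edges, "gated_h2_edges")):
        gated = set()
        for scope in edges:
            if scope not in raw_scopes:
                continue
            ok, _ = _feature_pattern(_cells(table, RAW_MEASURE, scope), hyp)
            if ok:
                gated.add(scope)
        setattr(res, out_attr, gated)
    return res


def connectivity_gate(edge_set: set, table: pd.DataFrame, hypothesis: int) -> set:
    """Retain edges whose raw SEC and DGC-variance independently pass
    the FDR + trend scheme for the given hypothesis."""
    out = set()
    for scope in edge_set:
        cells = _cells(table, RAW_MEASURE, scope)
        ok, _ = _feature_pattern(cells, hypothesis)
        if ok:
            out.add(scope)
    return out
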
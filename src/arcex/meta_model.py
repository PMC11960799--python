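"""Multilevel random-effects meta-analysis with phylogenetic correlation.

The model for the vector of observed effect sizes y (SMDH scale) is

    y = X beta + Z_study u + Z_es e + Z_sp s + Z_sp p + eps,

with independent levels: u ~ N(0, s2_study I) shared within studies,
e ~ N(0, s2_effect I) record-specific, s ~ N(0, s2_species I) species
identity, p ~ N(0, s2_phylo A) species effects correlated by the tree
correlation matrix A, and eps ~ N(0, diag(v_i)) the known sampling
errors.  The marginal covariance is therefore

    V = s2_study Zst Zst' + s2_effect I + s2_species Zsp Zsp'
        + s2_phylo Zsp A Zsp' + diag(v).

Variance components are estimated by REML on the log-variance scale with
multi-start optimisation; fixed effects by generalized least squares at
the REML solution.  Heterogeneity is summarised by the multilevel I²
(total and per level) and moderator fits report an omnibus Wald Q_M on
level-difference contrasts plus a marginal R².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "PhyloCorrelation",
    "MetaModel",
    "MetaFit",
    "tree_to_correlation",
    "fit",
    "heterogeneity",
    "moderator_test",
    "publication_bias_check",
]

_LEVELS = ("study", "effect", "species", "phylo")


@dataclass
class PhyloCorrelation:
    """Species-by-species correlation matrix of shared ancestry."""

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.matrix, dtype=float)
        k = len(self.species)
        if a.shape != (k, k):
            raise ValueError("matrix order must match the species list")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(a), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal must be 1")
        eigmin = float(np.linalg.eigvalsh(a).min())
        if eigmin < -1e-8:
            raise ValueError("correlation matrix must be positive semi-definite")
        self.matrix = a

    def reorder(self, species: list[str]) -> "PhyloCorrelation":
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelation(list(species), self.matrix[np.ix_(idx, idx)])


@dataclass
class MetaModel:
    """Specification of fixed and random structure.

    ``moderators=None`` gives the intercept-only ("null") model.  With
    moderators, the first is coded as one indicator per level and the
    rest drop their first level, all without an intercept, so every
    coefficient of the first moderator is that level's pooled mean.
    """

    moderators: list[str] | None = None
    intercept: bool = True
    random_levels: tuple[str, ...] = _LEVELS
    method: str = "REML"


@dataclass
class MetaFit:
    """Fitted multilevel meta-analytic model."""

    coefficients: pd.DataFrame  # name, estimate, se, z, p, ci_low, ci_high, pi_low, pi_high
    sigma2: dict  # per-level variance components
    loglik: float  # restricted log-likelihood
    n_records: int
    n_studies: int
    converged: bool
    model: MetaModel
    i2_total: float | None = None  # percent
    i2_levels: dict | None = None  # percent per level
    q_m: float | None = None
    q_m_df: int | None = None
    q_m_p: float | None = None
    q_m_omnibus: float | None = None
    q_m_omnibus_df: int | None = None
    q_m_omnibus_p: float | None = None
    r2_marginal: float | None = None  # percent
    diagnostics: dict = field(default_factory=dict)

    @property
    def estimate(self) -> float:
        """Pooled estimate (first coefficient; the mean for null models)."""
        return float(self.coefficients["estimate"].iloc[0])


# ---------------------------------------------------------------------------
# tree -> correlation matrix
# ---------------------------------------------------------------------------


def _normalize(name: str) -> str:
    return name.strip().lower().replace(" ", "_")


def tree_to_correlation(
    tree: "str | dendropy.Tree",
    species: list[str],
    seed: int = 0,
) -> PhyloCorrelation:
    """Correlation matrix of shared root-to-tip path length from a tree.

    Accepts a newick string, a path to a newick file, or a dendropy Tree.
    Polytomies are resolved to bifurcations by seeded randomization (zero
    length branches), missing branch lengths are set to 1 (cladogram
    rule), and the tree is made ultrametric by extending each pendant
    branch to the deepest tip.  Then ``A[i, j]`` is the depth of the MRCA
    of tips i and j divided by the total depth; the diagonal is exactly 1.
    """
    import random as _random

    if isinstance(tree, dendropy.Tree):
        t = tree.clone(depth=1)
    else:
        src = str(tree)
        if "(" not in src:  # a path, not a newick string
            t = dendropy.Tree.get(path=src, schema="newick")
        else:
            t = dendropy.Tree.get(data=src, schema="newick")

    by_norm = {_normalize(leaf.taxon.label): leaf for leaf in t.leaf_node_iter()}
    missing = [s for s in species if _normalize(s) not in by_norm]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")

    t.resolve_polytomies(rng=_random.Random(seed))
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            edge.length = 0.0
        elif edge.length is None:
            edge.length = 1.0

    # node depths from the root
    depth: dict = {t.seed_node: 0.0}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        depth[node] = depth[node.parent_node] + node.edge.length
    total = max(depth[leaf] for leaf in t.leaf_node_iter())
    if total <= 0:
        raise ValueError("tree has zero depth")
    # ultrametric: stretch pendant edges so every tip sits at `total`
    for leaf in t.leaf_node_iter():
        depth[leaf] = total

    k = len(species)
    a = np.eye(k)
    index = {_normalize(s): i for i, s in enumerate(species)}
    # pairs across the children of a node have that node as MRCA
    for node in t.postorder_internal_node_iter():
        groups = []
        for child in node.child_nodes():
            tips = [
                index[_normalize(l.taxon.label)]
                for l in child.leaf_iter()
                if _normalize(l.taxon.label) in index
            ]
            groups.append(tips)
        share = depth[node] / total
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        a[i, j] = a[j, i] = share
    return PhyloCorrelation(list(species), a)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def _indicator(codes: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(codes))
    z = np.zeros((len(codes), len(levels)))
    pos = {l: i for i, l in enumerate(levels)}
    for row, val in enumerate(codes):
        z[row, pos[val]] = 1.0
    return z, levels


def _build_design(records: pd.DataFrame, model: MetaModel):
    """Fixed design X, coefficient names, and contrast rows for Q_M."""
    if not model.moderators:
        return np.ones((len(records), 1)), ["intercept"], None
    cols, names = [], []
    contrasts = []
    offset = 0
    for m_i, mod in enumerate(model.moderators):
        z, levels = _indicator(records[mod])
        if m_i == 0:
            cols.append(z)
            names += [f"{mod}:{l}" for l in levels]
            # successive level differences within the first moderator
            for j in range(len(levels) - 1):
                contrasts.append((offset + j, offset + j + 1))
            offset += len(levels)
        else:
            cols.append(z[:, 1:])
            names += [f"{mod}:{l}" for l in levels[1:]]
            for j in range(len(levels) - 1):
                contrasts.append((offset + j, None))  # already a difference
            offset += len(levels) - 1
    return np.hstack(cols), names, contrasts


def _random_structure(records: pd.DataFrame, model: MetaModel, A):
    """Per-level marginal covariance contributions (n x n matrices)."""
    n = len(records)
    mats = {}
    if "study" in model.random_levels:
        z, _ = _indicator(records["study_id"])
        mats["study"] = z @ z.T
    if "effect" in model.random_levels:
        mats["effect"] = np.eye(n)
    need_species = ("species" in model.random_levels) or (
        "phylo" in model.random_levels
    )
    if need_species:
        z_sp, sp_levels = _indicator(records["species"])
        if "species" in model.random_levels:
            mats["species"] = z_sp @ z_sp.T
        # no tree supplied: the phylogenetic level is dropped (recorded in
        # the fit diagnostics) rather than silently replaced by I
        if "phylo" in model.random_levels and A is not None:
            missing = [s for s in sp_levels if s not in A.species]
            if missing:
                raise ValueError(f"species absent from the tree: {missing}")
            a = A.reorder(sp_levels).matrix
            mats["phylo"] = z_sp @ a @ z_sp.T
    return mats


def _neg_restricted_ll(
    log_s2: np.ndarray,
    mats: list[np.ndarray],
    v: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
) -> float:
    vmat = np.diag(v).copy()
    for g, m in zip(np.exp(log_s2), mats):
        vmat += g * m
    try:
        c, low = linalg.cho_factor(vmat, lower=True)
    except linalg.LinAlgError:
        return 1e12
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    vinv_x = linalg.cho_solve((c, low), x)
    vinv_y = linalg.cho_solve((c, low), y)
    xtvx = x.T @ vinv_x
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(xtvx, x.T @ vinv_y)
    resid = y - x @ beta
    vinv_r = linalg.cho_solve((c, low), resid)
    return 0.5 * (logdet_v + logdet_xtvx + float(resid @ vinv_r))


def _reml_optimize(mats, v, x, y, seed: int = 0):
    """Multi-start L-BFGS-B on log variance components."""
    q = len(mats)
    var_y = float(np.var(y, ddof=1)) if len(y) > 1 else 1.0
    excess = max(var_y - float(np.mean(v)), 1e-4)
    rng = np.random.default_rng(seed)
    starts = [
        np.full(q, math.log(1e-4)),
        np.full(q, math.log(excess / q)),
        np.log(np.maximum(excess / q, 1e-4))
        + rng.normal(0.0, 1.0, size=q),
    ]
    best = None
    bounds = [(-30.0, 10.0)] * q
    for s0 in starts:
        res = optimize.minimize(
            _neg_restricted_ll,
            s0,
            args=(mats, v, x, y),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit(
    records: pd.DataFrame,
    model: MetaModel | None = None,
    A: PhyloCorrelation | None = None,
    seed: int = 0,
) -> MetaFit:
    """Fit the multilevel model to an effect-size table.

    ``records`` needs columns ``smdh``, ``variance``, ``study_id``,
    ``species`` plus any moderator columns the model names.  Returns the
    fitted coefficients (95% CIs and 95% prediction intervals on the SMD
    scale), REML variance components, heterogeneity decomposition, and —
    for moderator models — Q_M and the marginal R².
    """
    model = model or MetaModel()
    y = records["smdh"].to_numpy(dtype=float)
    v = records["variance"].to_numpy(dtype=float)
    if (v <= 0).any():
        raise ValueError("all sampling variances must be > 0")
    n_studies = records["study_id"].nunique()
    if n_studies < 2:
        raise ValueError("need at least 2 studies")
    x, names, contrasts = _build_design(records, model)
    struct = _random_structure(records, model, A)
    level_names = [l for l in _LEVELS if l in struct]
    mats = [struct[l] for l in level_names]

    res = _reml_optimize(mats, v, x, y, seed=seed)
    s2 = {l: float(g) for l, g in zip(level_names, np.exp(res.x))}
    # snap numerically-zero components to exact zero
    s2 = {l: (0.0 if g < 1e-8 else g) for l, g in s2.items()}

    vmat = np.diag(v).copy()
    for l, m in zip(level_names, mats):
        vmat += s2[l] * m
    c, low = linalg.cho_factor(vmat, lower=True)
    vinv_x = linalg.cho_solve((c, low), x)
    xtvx = x.T @ vinv_x
    cov_beta = np.linalg.inv(xtvx)
    beta = cov_beta @ (x.T @ linalg.cho_solve((c, low), y))
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    zc = stats.norm.ppf(0.975)
    tau_total = sum(s2.values())
    pi_se = np.sqrt(se**2 + tau_total)
    coef = pd.DataFrame(
        {
            "name": names,
            "estimate": beta,
            "se": se,
            "z": z,
            "p": p,
            "ci_low": beta - zc * se,
            "ci_high": beta + zc * se,
            "pi_low": beta - zc * pi_se,
            "pi_high": beta + zc * pi_se,
        }
    )

    out = MetaFit(
        coefficients=coef,
        sigma2=s2,
        loglik=-float(res.fun),
        n_records=len(records),
        n_studies=int(n_studies),
        converged=bool(res.success),
        model=model,
        diagnostics={
            "optimizer_message": str(res.message),
            "n_function_evals": int(res.nfev),
            "seed": seed,
            "phylo_level_dropped": (
                "phylo" in model.random_levels and "phylo" not in struct
            ),
        },
    )
    heterogeneity(out, records)

    if model.moderators:
        # omnibus Wald test: all coefficients zero (df = p)
        q_omni = float(beta @ xtvx @ beta)
        out.q_m_omnibus = q_omni
        out.q_m_omnibus_df = len(beta)
        out.q_m_omnibus_p = float(stats.chi2.sf(q_omni, len(beta)))
        # contrast-coded Q_M: differences among levels (df = sum(p_m - 1))
        rows = []
        for a_idx, b_idx in contrasts:
            r = np.zeros(len(beta))
            r[a_idx] = 1.0
            if b_idx is not None:
                r[b_idx] = -1.0
            rows.append(r)
        if rows:
            lmat = np.vstack(rows)
            lb = lmat @ beta
            lcl = lmat @ cov_beta @ lmat.T
            q_m = float(lb @ np.linalg.solve(lcl, lb))
            out.q_m = q_m
            out.q_m_df = len(rows)
            out.q_m_p = float(stats.chi2.sf(q_m, len(rows)))
        # marginal R2: fixed-effect variance over total
        fitted = x @ beta
        var_fixed = float(np.var(fitted))
        denom = var_fixed + tau_total
        out.r2_marginal = 100.0 * var_fixed / denom if denom > 0 else 0.0
    return out


def heterogeneity(
    fit_result: MetaFit,
    records: pd.DataFrame,
    typical: str = "higgins",
) -> tuple[float, dict]:
    """Multilevel I²: total and per-level shares, in percent.

    The typical sampling variance v̄ follows the multilevel convention
    (``"higgins"``): v̄ = (k−1) Σw / ((Σw)² − Σw²) with w = 1/v_i;
    ``typical="mean"`` uses the plain mean of the v_i.  Shares sum to the
    total by construction.  Results are stored on the fit and returned.
    """
    v = records["variance"].to_numpy(dtype=float)
    if typical == "mean":
        vbar = float(np.mean(v))
    else:
        w = 1.0 / v
        k = len(v)
        vbar = float((k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()))
    tau_total = sum(fit_result.sigma2.values())
    denom = tau_total + vbar
    total = 100.0 * tau_total / denom if denom > 0 else 0.0
    shares = {
        l: (100.0 * g / denom if denom > 0 else 0.0)
        for l, g in fit_result.sigma2.items()
    }
    fit_result.i2_total = total
    fit_result.i2_levels = shares
    fit_result.diagnostics["typical_sampling_variance"] = vbar
    fit_result.diagnostics["i2_typical_convention"] = typical
    return total, shares


def moderator_test(
    records: pd.DataFrame,
    moderators: "str | list[str]",
    A: PhyloCorrelation | None = None,
    seed: int = 0,
) -> MetaFit:
    """No-intercept meta-regression on one or more categorical moderators.

    Each level of the first moderator gets its own pooled estimate with
    CI and prediction interval; Q_M tests whether levels differ.  A
    single-level moderator leaves Q_M undefined (None).
    """
    if isinstance(moderators, str):
        moderators = [moderators]
    for m in moderators:
        if records[m].nunique() < 1:
            raise ValueError(f"moderator {m} has no levels")
    model = MetaModel(moderators=list(moderators), intercept=False)
    out = fit(records, model, A=A, seed=seed)
    if records[moderators[0]].nunique() < 2 and len(moderators) == 1:
        out.q_m = out.q_m_df = out.q_m_p = None
    return out


def publication_bias_check(
    records: pd.DataFrame,
    A: PhyloCorrelation | None = None,
    grouping: str = "first_author",
    seed: int = 0,
) -> tuple[MetaFit, float]:
    """First-authorship check: per-group pooled effects and difference p.

    Fits the no-intercept model with the authorship flag as moderator and
    returns the fit plus the Wald p-value for the between-group contrast.
    """
    counts = records[grouping].value_counts()
    if len(counts) < 2 or (counts < 1).any():
        raise ValueError("both authorship groups must be non-empty")
    out = moderator_test(records, grouping, A=A, seed=seed)
    return out, float(out.q_m_p)
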
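"""Normalization and random-variance-model moderated differential expression.

Two-condition microarray designs with very few replicates (here 3 vs 3)
make the per-gene variance estimate the weakest link of an ordinary
t-test. The random variance model (RVM) assumes the per-gene inverse
variances are exchangeable draws from a gamma distribution,

    1 / sigma_g^2  ~  Gamma(shape a, scale b),

under which the pooled per-gene sample variance satisfies

    s_g^2 * a * b  ~  F(d, 2a),        d = n1 + n2 - 2.

Fitting (a, b) across all genes by maximum likelihood yields a moderated
variance per gene,

    s~_g^2 = (d * s_g^2 + 2 / b) / (d + 2a),

which shrinks s_g^2 toward the prior point 1/(a*b) and buys 2a extra
degrees of freedom: the moderated t statistic is referred to a t
distribution with d + 2a df. Zero-variance genes are excluded from the
prior fit but still scored — the prior term keeps their moderated
variance positive.

The module also houses quantile normalization, Benjamini–Hochberg FDR,
direction calling, hierarchical clustering of the DE matrix, and the
2^-ddCt fold-change utility used for qPCR validation panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix


class ConvergenceError(RuntimeError):
    """Raised when the RVM prior likelihood has no usable maximum."""


@dataclass(frozen=True)
class RVMPrior:
    """Gamma prior on inverse variances: 1/sigma^2 ~ Gamma(shape a, scale b).

    ``d`` is the per-gene residual degrees of freedom (n1 + n2 - 2) the
    prior was fitted against.
    """

    a: float
    b: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("prior parameters must be positive")
        if self.d < 1:
            raise ValueError("residual degrees of freedom must be >= 1")

    @property
    def moderated_df(self) -> float:
        return self.d + 2.0 * self.a

    @property
    def prior_variance_point(self) -> float:
        """Shrinkage target for the per-gene variance, 1/(a*b)."""
        return 1.0 / (self.a * self.b)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cycle thresholds for one target in test and control conditions,
    each normalized against a reference gene."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_ctrl: float
    ct_ref_ctrl: float

    @property
    def delta_delta_ct(self) -> float:
        for v in (
            self.ct_target_test,
            self.ct_ref_test,
            self.ct_target_ctrl,
            self.ct_ref_ctrl,
        ):
            if not math.isfinite(v):
                raise ValueError("non-finite Ct value")
        return (self.ct_target_test - self.ct_ref_test) - (
            self.ct_target_ctrl - self.ct_ref_ctrl
        )

    @property
    def fold_change(self) -> float:
        return 2.0 ** (-self.delta_delta_ct)


def ddct_fold_change(m: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method."""
    return m.fold_change


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (across-sample mean) distribution.

    After the transform each column's sorted values equal the mean of the
    rank-ordered values across columns; row and column labels survive.
    """
    x = matrix.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    order = np.argsort(x, axis=0, kind="stable")
    ranks = np.argsort(order, axis=0, kind="stable")
    target = np.sort(x, axis=0).mean(axis=1)
    out = target[ranks]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(values)


def log2_transform(matrix: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """log2 with a positive floor applied before the transform."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    values = np.log2(np.maximum(matrix.values.to_numpy(dtype=float), floor))
    return matrix.with_values(
        pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns)
    )


# ----------------------------------------------------------------------
# RVM prior fit
# ----------------------------------------------------------------------

def _neg_loglik(theta: np.ndarray, s2: np.ndarray, d: float) -> float:
    a, b = np.exp(theta)
    # density of s^2 when s^2 * a * b ~ F(d, 2a)
    ll = np.log(a * b) + stats.f.logpdf(s2 * a * b, d, 2.0 * a)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(ll.sum())


def _moment_init(s2: np.ndarray, d: float) -> tuple[float, float]:
    mean = float(s2.mean())
    cv2 = float(s2.var() / mean**2)
    c = cv2 * d
    if c > 2.0:
        a0 = (d - 2.0 + 2.0 * c) / (c - 2.0)
    else:
        a0 = 10.0
    a0 = min(max(a0, 0.1), 100.0)
    b0 = 1.0 / (mean * max(a0 - 1.0, 0.5))
    return a0, b0


def fit_rvm_prior(pooled_variances, d: float) -> RVMPrior:
    """Maximum-likelihood fit of the gamma prior on inverse variances.

    Genes with zero variance are excluded from the fit (they carry no
    information about the prior and break the likelihood); at least 50
    positive variances are required for a stable estimate.
    """
    s2 = np.asarray(pooled_variances, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("negative variance in input")
    if d < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    s2 = s2[s2 > 0]
    if s2.size < 50:
        raise ValueError("need >= 50 genes with positive variance")
    if np.ptp(s2) < 1e-12 * s2.mean():
        raise ConvergenceError("variances are (near-)identical; prior fit degenerate")

    a0, b0 = _moment_init(s2, d)
    # a is bounded above: homogeneous variances push a -> inf (the gamma
    # prior degenerates to a point), where the capped fit approaches the
    # correct large-df pooled test instead of diverging.
    bounds = [(np.log(1e-3), np.log(1e3)), (np.log(1e-12), np.log(1e12))]
    res = optimize.minimize(
        _neg_loglik,
        x0=np.clip(np.log([a0, b0]), [b[0] for b in bounds], [b[1] for b in bounds]),
        args=(s2, float(d)),
        method="Nelder-Mead",
        bounds=bounds,
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success or not np.all(np.isfinite(res.x)):
        raise ConvergenceError("RVM prior likelihood failed to converge")
    a, b = np.exp(res.x)
    return RVMPrior(a=float(a), b=float(b), d=float(d))


def moderated_variance(s2, prior: RVMPrior) -> np.ndarray:
    """Shrink per-gene variances toward the prior point 1/(a*b)."""
    s2 = np.asarray(s2, dtype=float)
    return (prior.d * s2 + 2.0 / prior.b) / (prior.d + 2.0 * prior.a)


# ----------------------------------------------------------------------
# moderated t-test
# ----------------------------------------------------------------------

def rvm_t_test(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    prior: RVMPrior | None = None,
) -> pd.DataFrame:
    """Per-probe moderated t-test between two conditions.

    Returns a DataFrame with one row per probe: ``probe_id`` (index),
    ``mean_a``, ``mean_b``, ``log2_fc`` (mean_a - mean_b on log2 data),
    ``s2`` (pooled variance), ``s2_tilde`` (moderated), ``t``, ``df``,
    ``p``, ``q`` (Benjamini–Hochberg), ``direction`` (initially "null";
    see :func:`classify_de`).

    When ``prior`` is None it is fitted on this matrix's pooled variances.
    """
    for cond in (group_a, group_b):
        if cond not in matrix.conditions:
            raise ValueError(f"condition {cond!r} absent from design")
    sa = matrix.samples_for(group_a)
    sb = matrix.samples_for(group_b)
    na, nb = len(sa), len(sb)
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 replicates")
    d = na + nb - 2

    xa = matrix.values[sa].to_numpy(dtype=float)
    xb = matrix.values[sb].to_numpy(dtype=float)
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    ssa = ((xa - mean_a[:, None]) ** 2).sum(axis=1)
    ssb = ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = (ssa + ssb) / d

    if prior is None:
        prior = fit_rvm_prior(s2, d)

    s2_tilde = moderated_variance(s2, prior)
    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    t = (mean_a - mean_b) / se
    df = prior.moderated_df
    p = 2.0 * stats.t.sf(np.abs(t), df)
    q = bh_fdr(p)

    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": mean_a - mean_b,
            "s2": s2,
            "s2_tilde": s2_tilde,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "direction": "null",
        },
        index=pd.Index(matrix.probe_ids, name="probe_id"),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_de(
    records: pd.DataFrame,
    p_threshold: float = 0.05,
    fdr: bool = False,
    fc_threshold: float | None = None,
) -> tuple[list[str], list[str]]:
    """Assign up/down/null directions and return the (up, down) id lists.

    ``fdr=True`` applies the threshold to the q-value column instead of p;
    ``fc_threshold`` additionally requires |log2 fold change| at or above
    the cut. Mutates the ``direction`` column in place.
    """
    if len(records) == 0:
        return [], []
    stat = records["q"] if fdr else records["p"]
    sig = stat < p_threshold
    if fc_threshold is not None:
        sig &= records["log2_fc"].abs() >= fc_threshold
    records["direction"] = "null"
    records.loc[sig & (records["log2_fc"] > 0), "direction"] = "up"
    records.loc[sig & (records["log2_fc"] < 0), "direction"] = "down"
    up = list(records.index[records["direction"] == "up"])
    down = list(records.index[records["direction"] == "down"])
    return up, down


# ----------------------------------------------------------------------
# hierarchical clustering
# ----------------------------------------------------------------------

def hierarchical_cluster(
    matrix: ExpressionMatrix,
    axis: str = "samples",
    metric: str = "correlation",
    method: str = "average",
):
    """Agglomerative clustering of probes or samples.

    Defaults follow expression-heatmap convention: 1 - Pearson correlation
    distance with average linkage. Returns ``(linkage_matrix, leaf_ids)``.
    """
    if axis not in ("probes", "samples"):
        raise ValueError("axis must be 'probes' or 'samples'")
    x = matrix.values.to_numpy(dtype=float)
    labels = matrix.probe_ids
    if axis == "samples":
        x = x.T
        labels = matrix.sample_ids
    if x.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    dist = pdist(x, metric=metric)
    z = hierarchy.linkage(dist, method=method)
    leaves = hierarchy.leaves_list(z)
    return z, [labels[i] for i in leaves]


def cut_clusters(z: np.ndarray, labels: list[str], n_clusters: int) -> dict[str, int]:
    """Flat cluster membership at an ``n_clusters`` cut of the tree."""
    assignment = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return dict(zip(labels, (int(c) for c in assignment)))


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Nested-parenthesis (newick) rendering of a linkage tree."""
    tree = hierarchy.to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.get_left()), walk(node.get_right())
        return f"({left},{right}):{node.dist:.6g}"

    return walk(tree) + ";"
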
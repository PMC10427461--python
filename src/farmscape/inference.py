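"""Mixed models, variance partitioning, and spatial diagnostics.

Three pieces of statistical machinery:

* ``fit_lmm`` — a Gaussian linear mixed model with a single random
  intercept (language family), estimated by REML via a deterministic
  profiled-likelihood search over the variance ratio. One random effect
  admits a stable one-dimensional profile, so no general-purpose mixed
  model optimizer is needed and results are exactly reproducible.
* ``variance_partition`` — commonality analysis: the model R^2 is
  decomposed into 2^k - 1 unique and shared components across predictor
  blocks from the all-subsets R^2 table, by solving the
  inclusion-exclusion linear system (cross-checked internally against
  the Moebius closed form). Negative shared components (suppression) are
  reported as-is.
* ``morans_i`` / ``residual_correlogram`` — Moran's I spatial
  autocorrelation, and its correlogram over 12 great-circle distance
  classes chosen so each class holds an equal number of point pairs.
"""

from __future__ import annotations

from itertools import combinations
from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .grid import haversine_km


# ---------------------------------------------------------------------------
# Linear mixed model (single random intercept, profiled REML)


@dataclass
class ModelFit:
    response: str
    coef: pd.Series              # intercept first, then fixed effects
    se: pd.Series
    sigma2_family: float
    sigma2_resid: float
    loglik: float                # REML log-likelihood at the optimum
    n: int
    n_families: int
    trace: list[float] = field(default_factory=list)  # best-so-far REML loglik

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "coef": self.coef.to_dict(),
            "se": self.se.to_dict(),
            "sigma2_family": self.sigma2_family,
            "sigma2_resid": self.sigma2_resid,
            "loglik": self.loglik,
            "n": self.n,
            "n_families": self.n_families,
        }


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"rank-deficient fixed-effect design; collinear columns: {bad}")


def _reml_pieces(gamma: float, X, y, group_slices):
    """Profiled REML criterion pieces at variance ratio gamma = s2_fam/s2_e."""
    n, p = X.shape
    A = np.zeros((p, p))
    b = np.zeros(p)
    yy = 0.0
    logdet_v = 0.0
    for sl in group_slices:
        Xg, yg = X[sl], y[sl]
        ng = Xg.shape[0]
        c = gamma / (1.0 + gamma * ng)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        A += Xg.T @ Xg - c * np.outer(sx, sx)
        b += Xg.T @ yg - c * sx * sy
        yy += yg @ yg - c * sy * sy
        logdet_v += np.log1p(gamma * ng)
    beta = np.linalg.solve(A, b)
    rss = yy - b @ beta
    sigma2 = rss / (n - p)
    sign, logdet_a = np.linalg.slogdet(A)
    loglik = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_v + logdet_a)
    return loglik, beta, sigma2, A


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed: list[str],
    family_col: str = "family",
) -> ModelFit:
    """REML fit of ``response ~ fixed + (1 | family)``.

    Fixed predictors are z-scored before fitting (comparable coefficient
    scales). Complete cases only. The variance ratio
    ``gamma = sigma2_family / sigma2_resid`` is profiled out and located
    by a deterministic golden-section search on log-gamma; the boundary
    gamma = 0 (no family variance, plain OLS/GLS) is always compared
    against the interior optimum.
    """
    cols = [response] + fixed + [family_col]
    df = table[cols].dropna()
    n = len(df)
    if n < len(fixed) + 2:
        raise ValueError("too few complete cases")
    fams, fam_idx = np.unique(df[family_col].to_numpy(), return_inverse=True)
    if len(fams) < 2:
        warnings.warn("fewer than 2 families: random effect not identifiable", stacklevel=2)

    Xf = df[fixed].to_numpy(dtype=float)
    sd = Xf.std(axis=0, ddof=0)
    if np.any(sd == 0):
        const = [f for f, s in zip(fixed, sd) if s == 0]
        raise ValueError(f"rank-deficient fixed-effect design; collinear columns: {const}")
    Xf = (Xf - Xf.mean(axis=0)) / sd
    X = np.column_stack([np.ones(n), Xf])
    names = ["intercept"] + list(fixed)
    _check_full_rank(X, names)
    y = df[response].to_numpy(dtype=float)

    order = np.argsort(fam_idx, kind="stable")
    X, y, fam_sorted = X[order], y[order], fam_idx[order]
    edges = np.flatnonzero(np.diff(fam_sorted)) + 1
    starts = np.concatenate([[0], edges])
    stops = np.concatenate([edges, [n]])
    slices = [slice(a, b) for a, b in zip(starts, stops)]
    all_singletons = len(slices) == n

    trace: list[float] = []

    def neg_reml(log_gamma: float) -> float:
        ll = _reml_pieces(np.exp(log_gamma), X, y, slices)[0]
        trace.append(max(ll, trace[-1]) if trace else ll)
        return -ll

    ll0 = _reml_pieces(0.0, X, y, slices)[0]
    trace.append(ll0)
    if all_singletons:
        # family variance unidentifiable from singleton groups: report 0
        warnings.warn("one observation per family: family variance not identifiable, "
                      "reported as 0", stacklevel=2)
        gamma, loglik = 0.0, float(ll0)
    else:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded",
                              options={"xatol": 1e-10})
        if -res.fun > ll0:
            gamma = float(np.exp(res.x))
            loglik = float(-res.fun)
        else:
            gamma, loglik = 0.0, float(ll0)
    trace.append(max(loglik, trace[-1]))

    _, beta, sigma2, A = _reml_pieces(gamma, X, y, slices)
    cov = sigma2 * np.linalg.inv(A)
    return ModelFit(
        response=response,
        coef=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(cov)), index=names),
        sigma2_family=float(gamma * sigma2),
        sigma2_resid=float(sigma2),
        loglik=loglik,
        n=n,
        n_families=len(fams),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Commonality analysis


def _ols_r2(y: np.ndarray, X: np.ndarray | None) -> float:
    """R^2 with intercept; rank deficiency handled by least-squares pseudo-inverse."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    tss = yc @ yc
    if tss == 0:
        raise ValueError("constant response")
    if X is None or X.shape[1] == 0:
        return 0.0
    Xi = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ beta
    return float(1.0 - (resid @ resid) / tss)


def subset_r2(y: np.ndarray, blocks: dict[str, np.ndarray], subset: tuple[str, ...]) -> float:
    """OLS R^2 of y on the concatenated columns of the named blocks.

    The empty subset has R^2 identically 0. Blocks are design matrices
    (e.g. the vertical-transmission block is the language-family dummy
    columns, current ecological opportunity is mammal + plant richness).
    """
    if not subset:
        return 0.0
    X = np.column_stack([np.atleast_2d(np.asarray(blocks[b], dtype=float).T).T for b in subset])
    return _ols_r2(y, X)


@dataclass
class PartitionResult:
    block_names: tuple[str, ...]
    components: dict[tuple[str, ...], float]   # subset -> commonality component
    subset_r2: dict[tuple[str, ...], float]
    full_r2: float

    def unique(self, block: str) -> float:
        return self.components[(block,)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "&".join(k), "n_blocks": len(k), "component": v}
            for k, v in sorted(self.components.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows)


def _all_subsets(names: tuple[str, ...]):
    for r in range(1, len(names) + 1):
        yield from combinations(names, r)


def variance_partition(y: np.ndarray, blocks: dict[str, np.ndarray]) -> PartitionResult:
    """Commonality decomposition of R^2 over predictor blocks.

    The 2^k - 1 components C(T) are the unique solution of
    ``R^2(S) = sum_{T : T intersects S} C(T)`` for every non-empty subset
    S; they sum to the full-model R^2, and the unique component of block
    i equals ``R^2(full) - R^2(full \\ i)``. The linear-system solution is
    cross-checked against the Moebius closed form; disagreement beyond
    1e-10 raises (transcription-bug guard). Negative shared components
    (suppression) are legitimate output.
    """
    names = tuple(blocks.keys())
    subsets = list(_all_subsets(names))
    r2 = {s: subset_r2(y, blocks, s) for s in subsets}
    full = r2[names]

    k = len(subsets)
    M = np.zeros((k, k))
    for a, S in enumerate(subsets):
        for b, T in enumerate(subsets):
            M[a, b] = 1.0 if set(S) & set(T) else 0.0
    comp_vec = np.linalg.solve(M, np.array([r2[s] for s in subsets]))
    components = dict(zip(subsets, comp_vec))

    # Moebius closed form: with g(A) = R2(full) - R2(full \ A),
    # C(T) = sum_{A subseteq T} (-1)^{|T| - |A|} g(A)
    def g(A: tuple[str, ...]) -> float:
        if not A:
            return 0.0
        comp = tuple(nm for nm in names if nm not in A)
        return full - (r2[comp] if comp else 0.0)

    for T in subsets:
        c = sum(
            (-1) ** (len(T) - r) * sum(g(A) for A in combinations(T, r))
            for r in range(len(T) + 1)
        )
        if abs(c - components[T]) > 1e-10:
            raise AssertionError(f"commonality cross-check failed for {T}: {c} vs {components[T]}")

    return PartitionResult(block_names=names, components=components, subset_r2=r2, full_r2=full)


# ---------------------------------------------------------------------------
# Moran's I and correlograms


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with a general (zero-diagonal) spatial weight matrix.

    I = (n / sum(W)) * sum_ij w_ij z_i z_j / sum_i z_i^2, z centered.
    """
    x = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    s0 = W.sum()
    if s0 <= 0:
        raise ValueError("need at least one positive weight")
    z = x - x.mean()
    denom = z @ z
    if denom == 0:
        raise ValueError("constant values: Moran's I undefined")
    return float((n / s0) * (z @ W @ z) / denom)


@dataclass
class Correlogram:
    upper_bounds_km: np.ndarray   # strictly increasing class upper edges
    morans_i: np.ndarray
    pair_counts: np.ndarray


def residual_correlogram(
    residuals: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    n_classes: int = 12,
) -> Correlogram:
    """Moran's I per equal-pair-count great-circle distance class.

    All n(n-1)/2 pair distances are ranked (stable sort, so tied
    distances go to the lower class) and split into ``n_classes`` classes
    of equal size (+/- 1 pair). Each class defines a binary symmetric
    weight matrix over its pairs; Moran's I is computed per class.
    """
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if n < 30:
        raise ValueError("need at least 30 observations for a correlogram")
    iu, ju = np.triu_indices(n, k=1)
    d = haversine_km(np.asarray(lat)[iu], np.asarray(lon)[iu], np.asarray(lat)[ju], np.asarray(lon)[ju])
    order = np.argsort(d, kind="stable")
    chunks = np.array_split(order, n_classes)
    if any(len(c) == 0 for c in chunks):
        raise ValueError("empty distance class (too few distinct pairs)")
    z = x - x.mean()
    denom = z @ z
    if denom == 0:
        raise ValueError("constant residuals")
    bounds = np.array([d[c].max() for c in chunks])
    if np.any(np.diff(bounds) <= 0):
        raise ValueError("distance classes collapsed (duplicate coordinates?)")
    ivals = np.array([
        n * (z[iu[c]] @ z[ju[c]]) / (len(c) * denom) for c in chunks
    ])
    return Correlogram(
        upper_bounds_km=bounds,
        morans_i=ivals,
        pair_counts=np.array([len(c) for c in chunks]),
    )
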
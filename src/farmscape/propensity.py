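"""Farming propensity from Murdock subsistence codes.

The 0-9 ordinal codes only bound the percentage a society devoted to each
of the five subsistence activities. To propagate that coding uncertainty,
percentage budgets are stochastically re-drawn many times inside the
per-code ranges (always summing to 100), each draw is clr-transformed and
run through a covariance PCA, PC1 is sign-aligned so that higher scores
mean greater reliance on agriculture + pastoralism, and each society's
farming propensity is its mean PC1 score across the draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ACTIVITIES, MURDOCK_RANGES

_AGRI_IDX = (ACTIVITIES.index("agri"), ACTIVITIES.index("pastoral"))

#: clr floor for exact-zero percentage parts, far below the coarsest
#: category resolution (the narrowest Murdock bin is 6 points wide).
ZERO_FLOOR_PCT = 0.1


class InfeasibleCodesError(ValueError):
    """The sum-100 hyperplane does not intersect the code ranges' box."""


def code_bounds(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper percentage bounds for an (n, 5) integer code array."""
    codes = np.asarray(codes, dtype=int)
    lo = np.empty(codes.shape)
    hi = np.empty(codes.shape)
    for c, (a, b) in MURDOCK_RANGES.items():
        sel = codes == c
        lo[sel] = a
        hi[sel] = b
    return lo, hi


def sample_percentage_draw(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One stochastic percentage budget per society, inside each code's box.

    Each part is drawn uniformly within its category range and the vector
    is repaired onto the sum-100 hyperplane by distributing the deficit
    (or surplus) proportionally to each part's remaining slack. Because
    the deficit never exceeds the total slack on a feasible box, a single
    proportional step lands exactly on the hyperplane without leaving the
    box.

    Parameters
    ----------
    codes : (n, 5) int array of Murdock codes.
    rng : numpy Generator (drives reproducibility).
    """
    codes = np.atleast_2d(np.asarray(codes, dtype=int))
    lo, hi = code_bounds(codes)
    bad = (lo.sum(axis=1) > 100.0 + 1e-9) | (hi.sum(axis=1) < 100.0 - 1e-9)
    if np.any(bad):
        raise InfeasibleCodesError(
            f"infeasible Murdock code combination for societies at rows {np.flatnonzero(bad).tolist()}"
        )
    x = rng.uniform(lo, hi)
    deficit = 100.0 - x.sum(axis=1, keepdims=True)
    slack_up = hi - x
    slack_dn = x - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        up = np.where(slack_up.sum(axis=1, keepdims=True) > 0, slack_up / slack_up.sum(axis=1, keepdims=True), 0.0)
        dn = np.where(slack_dn.sum(axis=1, keepdims=True) > 0, slack_dn / slack_dn.sum(axis=1, keepdims=True), 0.0)
    x = x + np.where(deficit >= 0, deficit * up, deficit * dn)
    # numerical safety only; the proportional step cannot overshoot the box
    x = np.clip(x, lo, hi)
    resid = 100.0 - x.sum(axis=1)
    if np.any(np.abs(resid) > 1e-9):
        # fall back: spread the (tiny) residual over parts with slack
        for r in np.flatnonzero(np.abs(resid) > 1e-9):
            room = (hi[r] - x[r]) if resid[r] > 0 else (x[r] - lo[r])
            x[r] += resid[r] * room / room.sum()
    return x


def clr_transform(composition: np.ndarray) -> np.ndarray:
    """Centered log-ratio: ln(x_i / g(x)) with g the geometric mean.

    Rows are compositions of positive parts; each output row sums to 0.
    """
    x = np.atleast_2d(np.asarray(composition, dtype=float))
    if np.any(x <= 0):
        raise ValueError("clr requires strictly positive parts")
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def _close_with_floor(pct: np.ndarray) -> np.ndarray:
    """Floor exact zeros at ZERO_FLOOR_PCT and re-close rows to 100."""
    p = np.maximum(pct, ZERO_FLOOR_PCT)
    return 100.0 * p / p.sum(axis=1, keepdims=True)


@dataclass
class PCAResult:
    scores: np.ndarray           # (n, k) centered component scores
    loadings: np.ndarray         # (5, k) eigenvectors (columns)
    variance_fractions: np.ndarray  # (k,) eigenvalue shares, sum to 1


def compositional_pca(draw_matrix: np.ndarray) -> PCAResult:
    """Covariance PCA of the clr-transformed composition matrix.

    Standard Aitchison geometry: clr, column-center, eigendecompose the
    covariance. Variance fractions are normalized over the retained
    (nonzero) spectrum, so they sum to 1.
    """
    Y = clr_transform(draw_matrix)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 societies for PCA")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    if np.allclose(Yc, 0.0):
        raise ValueError("constant clr matrix: zero variance, PCA undefined")
    cov = Yc.T @ Yc / (Y.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PCAResult(
        scores=Yc @ evecs,
        loadings=evecs,
        variance_fractions=evals / evals.sum(),
    )


@dataclass
class PropensityScores:
    """Per-society mean PC1 score plus replicate-level PCA summaries."""

    scores: pd.Series                 # indexed by society id
    pc1_var_fraction: float           # mean across replicates
    pc1_var_fraction_sd: float        # spread across replicates
    mean_loadings: np.ndarray         # (5,) mean sign-aligned PC1 loadings

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.scores.index,
                "propensity": self.scores.to_numpy(),
                "pc1_var_fraction": self.pc1_var_fraction,
            }
        )


def farming_propensity(
    societies: pd.DataFrame, n_draws: int = 1000, seed: int = 0
) -> PropensityScores:
    """Mean sign-aligned PC1 score over stochastic percentage re-draws.

    For each of ``n_draws`` replicates: draw a feasible percentage budget
    for every society, clr-transform, run a covariance PCA, flip PC1 if
    needed so the summed agriculture + pastoralism loading is positive,
    and record the scores. Higher propensity therefore always means more
    farming. Deterministic given ``seed``.
    """
    codes = societies[list(ACTIVITIES)].to_numpy(dtype=int)
    if codes.shape[0] < 2:
        raise ValueError("need at least 2 societies")
    if (codes == codes[0]).all():
        raise ValueError("all societies have identical codes: propensity is degenerate")
    rng = np.random.default_rng(seed)
    n = codes.shape[0]
    acc = np.zeros(n)
    var1 = np.empty(n_draws)
    load_acc = np.zeros(5)
    for d in range(n_draws):
        pct = sample_percentage_draw(codes, rng)
        res = compositional_pca(_close_with_floor(pct))
        s = res.scores[:, 0]
        v = res.loadings[:, 0]
        if v[list(_AGRI_IDX)].sum() < 0:
            s, v = -s, -v
        acc += s
        var1[d] = res.variance_fractions[0]
        load_acc += v
    return PropensityScores(
        scores=pd.Series(acc / n_draws, index=societies["id"].to_numpy(), name="propensity"),
        pc1_var_fraction=float(var1.mean()),
        pc1_var_fraction_sd=float(var1.std()),
        mean_loadings=load_acc / n_draws,
    )
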
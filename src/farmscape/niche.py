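"""Maximum-entropy climatic niche models.

Presence-background species distribution modelling in the Maxent family:
the fitted model is the Gibbs distribution over background cells whose
feature expectations match the presence-data means as closely as the L1
penalty allows. The full Maxent feature set is supported — linear,
quadratic, pairwise product, threshold (step) and hinge (ramp) features
over the five bioclimatic variables, all scaled into [0, 1].

Deliberate simplifications relative to reference Maxent (documented in
the methods note): a single analytic penalty schedule
``beta_j = reg_multiplier * s_j / sqrt(m)`` (presence-sample feature
standard deviation, floored) instead of the per-feature-class
interpolation tables, and raw Gibbs-density output with no logistic
post-transform — every downstream consumer (non-omission threshold, AUC,
ranking) is rank-based, so the output scale is immaterial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.metrics import roc_auc_score

from .grid import GridSpec
from .synthetic import ClimateRaster

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Occurrence thinning


def preprocess_occurrences(
    occurrences: pd.DataFrame,
    grid: GridSpec,
    min_records: int = 15,
    seed: int = 0,
) -> pd.DataFrame | None:
    """Thin records to one per grid cell; drop sparse species.

    Keeps one uniformly chosen record per occupied cell (seeded) and
    returns ``None`` — a "dropped" marker — if fewer than ``min_records``
    cells remain. Records outside the grid are discarded first.
    """
    if occurrences.empty:
        return None
    occ = occurrences.loc[grid.contains(occurrences["lat"], occurrences["lon"])].copy()
    if occ.empty:
        return None
    i, j = grid.cell_of(occ["lat"], occ["lon"])
    occ["_cell"] = i * grid.n_lon + j
    rng = np.random.default_rng(seed)
    # order-insensitive seeded choice: permute rows once, keep first per cell
    occ = occ.sort_values("_cell", kind="stable")
    perm = occ.iloc[rng.permutation(len(occ))]
    thinned = perm.drop_duplicates("_cell", keep="first").sort_values("_cell", kind="stable")
    if len(thinned) < min_records:
        return None
    return thinned.drop(columns="_cell").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Features


@dataclass(frozen=True)
class FeatureConfig:
    n_threshold_knots: int = 10
    n_hinge_knots: int = 10


@dataclass
class FeatureSet:
    """Derived Maxent features over min-max standardized climate variables.

    Immutable after construction: the per-variable [min, max] scaling and
    the quantile knots are frozen from the background sample at fit time
    and reused verbatim for prediction on other periods.
    """

    var_min: np.ndarray                 # (5,)
    var_max: np.ndarray                 # (5,)
    threshold_knots: np.ndarray         # (5, n_t) in standardized units
    hinge_knots: np.ndarray             # (5, n_h)
    names: list[str] = field(default_factory=list)

    @classmethod
    def from_background(cls, X_bg: np.ndarray, config: FeatureConfig | None = None) -> "FeatureSet":
        cfg = config or FeatureConfig()
        var_min = X_bg.min(axis=0)
        var_max = X_bg.max(axis=0)
        span = np.where(var_max > var_min, var_max - var_min, 1.0)
        S = (X_bg - var_min) / span
        qt = np.linspace(0, 1, cfg.n_threshold_knots + 2)[1:-1]
        qh = np.linspace(0, 1, cfg.n_hinge_knots + 2)[1:-1]
        thr = np.quantile(S, qt, axis=0).T   # (5, n_t)
        hin = np.quantile(S, qh, axis=0).T
        fs = cls(var_min=var_min, var_max=var_max, threshold_knots=thr, hinge_knots=hin)
        fs.names = fs._build_names()
        return fs

    def _build_names(self) -> list[str]:
        v = [f"v{k}" for k in range(5)]
        names = [f"lin_{a}" for a in v] + [f"quad_{a}" for a in v]
        names += [f"prod_{v[a]}x{v[b]}" for a in range(5) for b in range(a + 1, 5)]
        for k in range(5):
            names += [f"thr_{v[k]}_{t}" for t in range(self.threshold_knots.shape[1])]
        for k in range(5):
            names += [f"hingef_{v[k]}_{t}" for t in range(self.hinge_knots.shape[1])]
            names += [f"hinger_{v[k]}_{t}" for t in range(self.hinge_knots.shape[1])]
        return names

    @property
    def n_features(self) -> int:
        return len(self.names)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """(n, 5) climate matrix -> (n, p) feature matrix, all in [0, 1].

        Values outside the frozen background envelope are clamped (and
        logged), matching the convention that prediction-period climates
        are evaluated inside the training feature space.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = np.where(self.var_max > self.var_min, self.var_max - self.var_min, 1.0)
        S = (X - self.var_min) / span
        if np.any(S < -1e-9) or np.any(S > 1 + 1e-9):
            logger.debug("clamping %d out-of-envelope values", int(np.sum((S < 0) | (S > 1))))
        S = np.clip(S, 0.0, 1.0)
        cols = [S, S**2]
        prods = [S[:, [a]] * S[:, [b]] for a in range(5) for b in range(a + 1, 5)]
        cols.append(np.concatenate(prods, axis=1))
        thr = [(S[:, [k]] >= self.threshold_knots[k][None, :]).astype(float) for k in range(5)]
        cols.append(np.concatenate(thr, axis=1))
        hng = []
        for k in range(5):
            kn = self.hinge_knots[k][None, :]
            fwd = np.clip((S[:, [k]] - kn) / np.maximum(1.0 - kn, 1e-12), 0.0, 1.0)
            rev = np.clip((kn - S[:, [k]]) / np.maximum(kn, 1e-12), 0.0, 1.0)
            hng.append(np.concatenate([fwd, rev], axis=1))
        cols.append(np.concatenate(hng, axis=1))
        return np.concatenate(cols, axis=1)


# ---------------------------------------------------------------------------
# Model


@dataclass
class NicheModel:
    """A fitted maximum-entropy niche model for one species."""

    species_id: str
    features: FeatureSet
    lam: np.ndarray              # (p,) feature weights (0 for dropped features)
    beta: np.ndarray             # (p,) per-feature L1 penalties
    active: np.ndarray           # (p,) bool, False where the feature was degenerate
    log_z: float                 # log partition sum over the fit background
    background_cells: np.ndarray
    train_idx: np.ndarray        # indices into the thinned occurrence table
    test_idx: np.ndarray
    auc: float | None = None
    threshold: float | None = None
    n_iter: int = 0

    def suitability_of(self, X_climate: np.ndarray) -> np.ndarray:
        """Raw Gibbs density exp(lam . f(x)) / Z_background."""
        F = self.features.transform(X_climate)
        return np.exp(F @ self.lam - self.log_z)


def split_train_test(n: int, seed: int, train_fraction: float = 0.7) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint split; training size rounds up (toward training)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.ceil(train_fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _maxent_objective(lam, F_pres_mean, F_bg):
    z = F_bg @ lam
    lz = special.logsumexp(z) - np.log(F_bg.shape[0])
    q = special.softmax(z)
    obj = -F_pres_mean @ lam + lz
    grad = -F_pres_mean + q @ F_bg
    return obj, grad


def fit_gibbs_weights(
    F_pres: np.ndarray,
    F_bg: np.ndarray,
    beta: np.ndarray,
    max_iter: int = 4000,
) -> tuple[np.ndarray, int]:
    """Minimize the L1-penalized Gibbs negative log-likelihood.

    ``-(1/m) sum_pres lam.f + ln mean_bg exp(lam.f) + sum_j beta_j |lam_j|``
    over feature weights ``lam``, given presence/background feature
    matrices. The L1 term is handled by splitting lam into non-negative
    parts and running bound-constrained L-BFGS (deterministic); restarts
    sharpen the KKT slack ``|empirical mean - model expectation| <=
    beta_j`` when the function-value stopping rule fires early. Raises if
    first-order optimality is not reached.
    """
    p = F_bg.shape[1]
    f_mean = F_pres.mean(axis=0)

    def obj(theta):
        lam = theta[:p] - theta[p:]
        o, g = _maxent_objective(lam, f_mean, F_bg)
        o += beta @ (theta[:p] + theta[p:])
        grad = np.concatenate([g + beta, -g + beta])
        return o, grad

    x0 = np.zeros(2 * p)
    n_iter = 0
    for _ in range(4):
        res = optimize.minimize(
            obj, x0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * p),
            options={"maxiter": max_iter, "ftol": 1e-16, "gtol": 1e-10, "maxls": 100},
        )
        n_iter += int(res.nit)
        x0 = res.x
        lam = res.x[:p] - res.x[p:]
        _, g = _maxent_objective(lam, f_mean, F_bg)
        if np.max(np.abs(g) - beta) <= 2e-7:
            break
    slack = np.abs(g) - beta
    kkt_violation = float(np.max(np.where(lam == 0.0, slack, np.abs(np.abs(g) - beta))))
    if kkt_violation > 1e-5:
        raise RuntimeError(
            f"Maxent fit did not converge (max KKT violation {kkt_violation:.2e}, "
            f"status={res.status}, nit={n_iter}, msg={res.message})"
        )
    return lam, n_iter


def fit_maxent(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    species_id: str = "species",
    reg_multiplier: float = 1.0,
    feature_config: FeatureConfig | None = None,
    feature_set: FeatureSet | None = None,
    background_cells: np.ndarray | None = None,
    max_iter: int = 4000,
    tol: float = 1e-8,
) -> NicheModel:
    """Fit the L1-penalized Gibbs model by deterministic convex minimization.

    Minimizes ``-(1/m) sum_pres lam.f(x) + ln mean_bg exp(lam.f(z))
    + sum_j beta_j |lam_j|`` where ``beta_j = reg_multiplier *
    max(s_j, 0.05) / sqrt(m)`` with ``s_j`` the presence-sample standard
    deviation of feature j (features live in [0, 1], so 0.05 is 5% of the
    feature range). The L1 term is handled by splitting ``lam`` into
    non-negative parts and running bound-constrained L-BFGS, which is
    deterministic and drives the KKT slack
    ``|empirical mean - model expectation| <= beta_j`` to tolerance.
    """
    presence_X = np.atleast_2d(presence_X)
    m = presence_X.shape[0]
    if m < 2:
        raise ValueError("need at least 2 presence records")
    fs = feature_set or FeatureSet.from_background(background_X, feature_config)
    F_bg = fs.transform(background_X)
    F_pres = fs.transform(presence_X)

    active = F_bg.std(axis=0) > 1e-12
    if not active.all():
        logger.info("%s: dropping %d zero-variance features", species_id, int((~active).sum()))
    Fb = F_bg[:, active]
    Fp = F_pres[:, active]
    p = Fb.shape[1]

    s = Fp.std(axis=0)
    beta_act = reg_multiplier * np.maximum(s, 0.05) / np.sqrt(m)
    lam_act, n_iter = fit_gibbs_weights(Fp, Fb, beta_act, max_iter=max_iter)

    lam = np.zeros(fs.n_features)
    lam[active] = lam_act
    beta = np.zeros(fs.n_features)
    beta[active] = beta_act
    log_z = float(special.logsumexp(F_bg @ lam) - np.log(F_bg.shape[0]))
    return NicheModel(
        species_id=species_id,
        features=fs,
        lam=lam,
        beta=beta,
        active=active,
        log_z=log_z,
        background_cells=background_cells if background_cells is not None else np.arange(len(background_X)),
        train_idx=np.arange(m),
        test_idx=np.array([], dtype=int),
        n_iter=n_iter,
    )


def predict_suitability(model: NicheModel, climate: ClimateRaster, period: str) -> np.ndarray:
    """Per-cell raw suitability on the full grid (NaN outside the mask).

    Feature scales and the background partition sum stay frozen from
    fitting, so historical predictions are directly comparable to the
    training-period surface.
    """
    if period not in climate.data:
        raise KeyError(f"period {period!r} missing from climate raster")
    out = np.full(climate.grid.n_cells, np.nan)
    cells = climate.valid_cells
    out[cells] = model.suitability_of(climate.matrix(period, cells))
    return out.reshape(climate.grid.shape)


def evaluate_auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """ROC AUC of presence vs background suitability scores (ties count 1/2)."""
    presence_scores = np.asarray(presence_scores, dtype=float)
    background_scores = np.asarray(background_scores, dtype=float)
    if presence_scores.size == 0:
        raise ValueError("empty test presence set")
    if background_scores.size == 0:
        raise ValueError("empty background sample")
    y = np.concatenate([np.ones(presence_scores.size), np.zeros(background_scores.size)])
    return float(roc_auc_score(y, np.concatenate([presence_scores, background_scores])))


@dataclass
class PresenceMap:
    """Binary expected-distribution map for one species and period."""

    species_id: str
    values: np.ndarray   # boolean grid
    period: str
    threshold: float


def binarize_non_omission(
    model: NicheModel,
    suitability: np.ndarray,
    training_cells: tuple[np.ndarray, np.ndarray],
    period: str = "historical",
) -> PresenceMap:
    """Threshold a suitability grid at the minimum training-presence value.

    The non-omission rule: a cell belongs to the expected distribution iff
    its suitability equals or exceeds the lowest suitability observed at a
    training presence, so no training record is ever omitted.
    """
    ti, tj = training_cells
    if len(np.atleast_1d(ti)) == 0:
        raise ValueError("no training presences to derive a threshold from")
    t = float(np.nanmin(suitability[ti, tj]))
    with np.errstate(invalid="ignore"):
        values = suitability >= t
    model.threshold = t
    return PresenceMap(species_id=model.species_id, values=values, period=period, threshold=t)


# ---------------------------------------------------------------------------
# Per-species driver


@dataclass
class SpeciesFitResult:
    model: NicheModel
    thinned: pd.DataFrame
    presence_current: PresenceMap
    presence_historical: PresenceMap
    suitability_current: np.ndarray
    suitability_historical: np.ndarray


def fit_species(
    species_id: str,
    occurrences: pd.DataFrame,
    climate: ClimateRaster,
    min_records: int = 15,
    reg_multiplier: float = 1.0,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
    max_background: int = 10_000,
) -> SpeciesFitResult | None:
    """Thin, split 70/30, fit, cross-validate, predict and binarize.

    Returns ``None`` when the species is dropped for having fewer than
    ``min_records`` occupied cells. The background is every valid grid
    cell, or a seeded sample of ``max_background`` cells on large grids.
    """
    ss = np.random.SeedSequence(seed)
    s_thin, s_split, s_bg = (int(x) % (2**31) for x in ss.generate_state(3))
    thinned = preprocess_occurrences(occurrences, climate.grid, min_records, seed=s_thin)
    if thinned is None:
        return None
    grid = climate.grid
    cells = climate.valid_cells
    if cells.size > max_background:
        cells = np.sort(np.random.default_rng(s_bg).choice(cells, size=max_background, replace=False))
    X_bg = climate.matrix("current", cells)

    tr, te = split_train_test(len(thinned), seed=s_split)
    i, j = grid.cell_of(thinned["lat"], thinned["lon"])
    X_all = climate.matrix("current", i * grid.n_lon + j)

    model = fit_maxent(
        X_all[tr], X_bg, species_id=species_id, reg_multiplier=reg_multiplier,
        feature_config=feature_config, background_cells=cells,
    )
    model.train_idx, model.test_idx = tr, te
    if len(te):
        model.auc = evaluate_auc(model.suitability_of(X_all[te]), model.suitability_of(X_bg))

    suit_cur = predict_suitability(model, climate, "current")
    suit_hist = predict_suitability(model, climate, "historical")
    tcells = (np.asarray(i)[tr], np.asarray(j)[tr])
    pres_cur = binarize_non_omission(model, suit_cur, tcells, period="current")
    pres_hist = binarize_non_omission(model, suit_hist, tcells, period="historical")
    return SpeciesFitResult(model, thinned, pres_cur, pres_hist, suit_cur, suit_hist)
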
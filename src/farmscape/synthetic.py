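"""Synthetic world generator with known ground truth.

Builds every input the downstream analysis consumes — bioclimatic rasters
for two periods, a pool of "early domesticate" species with Gaussian
climatic niches and origin points, biased occurrence records, and a table
of traditional societies with Murdock-coded subsistence budgets — from a
seed, so parameter recovery can be tested end to end without any external
dataset.

The society generator mirrors the structure of the fitted model the
analysis targets: a latent farming propensity driven by historical
ecological opportunity (count of early domesticates available locally),
current ecological opportunity (contemporary mammal and plant richness),
a language-family random effect, and a neighbourhood (horizontal
transmission) mixing term. The latent value is mapped through a softmax
link to a five-part subsistence budget (hunting, gathering, fishing,
agriculture, pastoralism) summing to 100%, then discretized to the 0-9
Murdock scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import GridSpec, pairwise_haversine_km

CLIMATE_LAYERS = (
    "annual_mean_temp",       # degC
    "temp_annual_range",      # degC
    "prec_wettest_month",     # mm
    "prec_driest_month",      # mm
    "prec_warmest_quarter",   # mm
)
PERIODS = ("current", "historical")

ACTIVITIES = ("hunt", "gather", "fish", "agri", "pastoral")

#: Murdock ordinal scale: code -> inclusive integer percentage range.
MURDOCK_RANGES: dict[int, tuple[int, int]] = {
    0: (0, 5),
    **{c: (10 * c - 4, 10 * c + 5) for c in range(1, 9)},
    9: (86, 100),
}


def encode_murdock(percentage: float) -> int:
    """Map a percentage in [0, 100] to its 0-9 Murdock code.

    The percentage is rounded to the nearest integer first, so the ten
    printed ranges (0-5, 6-15, ..., 86-100) tile [0, 100] without gaps.
    """
    p = np.asarray(percentage, dtype=float)
    if np.any((p < 0) | (p > 100)):
        raise ValueError("percentage outside [0, 100]")
    r = np.rint(p).astype(int)
    code = np.where(r <= 5, 0, np.minimum((r - 6) // 10 + 1, 9))
    return code if code.ndim else int(code)


def murdock_range(code: int) -> tuple[int, int]:
    """Inclusive percentage range decoded from a Murdock code."""
    return MURDOCK_RANGES[int(code)]


# ---------------------------------------------------------------------------
# Climate


@dataclass(frozen=True)
class ClimateConfig:
    """Bounds and roughness of the generated bioclimatic fields.

    The ranges are loose caricatures of global values: annual mean
    temperature spans [-15, 30] degC along a latitudinal gradient,
    precipitation layers are non-negative, and the wettest month is at
    least as wet as the driest by construction (wettest = driest + a
    non-negative seasonal excess).
    """

    temp_mean_bounds: tuple[float, float] = (-15.0, 30.0)
    temp_range_bounds: tuple[float, float] = (5.0, 45.0)
    prec_driest_bounds: tuple[float, float] = (0.0, 120.0)
    prec_excess_bounds: tuple[float, float] = (0.0, 380.0)  # wettest - driest
    prec_warmq_bounds: tuple[float, float] = (0.0, 900.0)
    noise_sigma_cells: float = 2.0   # Gaussian smoothing radius of the noise field
    noise_amplitude: float = 0.25    # fraction of each layer's span
    historical_offset: float = 0.04  # fraction of span for the period offset


@dataclass
class ClimateRaster:
    """Five named bioclimatic layers on a regular grid, for two periods."""

    grid: GridSpec
    data: dict[str, np.ndarray]  # period -> (5, n_lat, n_lon)
    mask: np.ndarray             # True where the cell is valid
    config: ClimateConfig = field(default_factory=ClimateConfig)

    layer_names = CLIMATE_LAYERS

    def layer(self, period: str, name: str) -> np.ndarray:
        return self.data[period][CLIMATE_LAYERS.index(name)]

    def matrix(self, period: str, cells: np.ndarray | None = None) -> np.ndarray:
        """Climate as an (n_cells, 5) matrix over valid (or given) flat cells."""
        flat = self.data[period].reshape(5, -1).T
        if cells is None:
            cells = np.flatnonzero(self.mask.ravel())
        return flat[cells]

    @property
    def valid_cells(self) -> np.ndarray:
        return np.flatnonzero(self.mask.ravel())

    def validate(self) -> None:
        for period in PERIODS:
            arr = self.data[period]
            if arr.shape != (5, *self.grid.shape):
                raise ValueError(f"{period}: bad layer stack shape {arr.shape}")
            if not np.all(np.isfinite(arr[:, self.mask])):
                raise ValueError(f"{period}: non-finite values in valid cells")
            wet = arr[CLIMATE_LAYERS.index("prec_wettest_month")]
            dry = arr[CLIMATE_LAYERS.index("prec_driest_month")]
            if np.any(dry[self.mask] > wet[self.mask] + 1e-9):
                raise ValueError(f"{period}: driest month exceeds wettest month")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Seeded Gaussian random field, unit-ish scale, periodic in longitude."""
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=sigma, mode=("nearest", "wrap"))
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def gen_climate(grid: GridSpec, seed: int, config: ClimateConfig | None = None) -> ClimateRaster:
    """Generate a two-period, five-layer bioclimatic raster.

    Each layer is a latitudinal gradient plus seeded, spatially smoothed
    noise, clipped to the configured bounds; the historical period is the
    current one plus a small smooth offset field. Deterministic in
    ``seed``.
    """
    cfg = config or ClimateConfig()
    rng = np.random.default_rng(seed)
    lat, _ = grid.center_mesh()
    # 1 at equator, 0 at the poles: the master gradient for temperature/rain
    warmth = np.cos(np.radians(lat))
    warmth = (warmth - warmth.min()) / max(warmth.max() - warmth.min(), 1e-12)

    def build(bounds, gradient, sign=1.0):
        lo, hi = bounds
        span = hi - lo
        f = lo + span * gradient + sign * cfg.noise_amplitude * span * _smooth_field(
            rng, grid.shape, cfg.noise_sigma_cells
        )
        return np.clip(f, lo, hi)

    current = np.empty((5, *grid.shape))
    current[0] = build(cfg.temp_mean_bounds, warmth)
    current[1] = build(cfg.temp_range_bounds, 1.0 - warmth)  # more seasonal away from equator
    dry = build(cfg.prec_driest_bounds, 0.7 * warmth)
    excess = build(cfg.prec_excess_bounds, 0.8 * warmth)
    current[3] = dry
    current[2] = dry + excess
    current[4] = build(cfg.prec_warmq_bounds, 0.75 * warmth)

    historical = current.copy()
    for k, bounds in enumerate(
        (cfg.temp_mean_bounds, cfg.temp_range_bounds, None, cfg.prec_driest_bounds, cfg.prec_warmq_bounds)
    ):
        if bounds is None:
            continue  # wettest month rebuilt from dry + excess below
        lo, hi = bounds
        historical[k] = np.clip(
            historical[k] + cfg.historical_offset * (hi - lo) * _smooth_field(rng, grid.shape, cfg.noise_sigma_cells),
            lo,
            hi,
        )
    lo, hi = cfg.prec_excess_bounds
    excess_hist = np.clip(
        excess + cfg.historical_offset * (hi - lo) * _smooth_field(rng, grid.shape, cfg.noise_sigma_cells), lo, hi
    )
    historical[2] = historical[3] + excess_hist

    raster = ClimateRaster(
        grid=grid,
        data={"current": current, "historical": historical},
        mask=np.ones(grid.shape, dtype=bool),
        config=cfg,
    )
    raster.validate()
    return raster


# ---------------------------------------------------------------------------
# Species


@dataclass(frozen=True)
class Species:
    """One early domesticate: a Gaussian climatic niche plus an origin point."""

    species_id: str
    niche_mean: np.ndarray      # (5,) in climate units
    niche_cov: np.ndarray       # (5, 5) symmetric positive definite
    origin_lat: float
    origin_lon: float


@dataclass
class SpeciesPool:
    species: list[Species]

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def origins_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [s.species_id for s in self.species],
                "lat": [s.origin_lat for s in self.species],
                "lon": [s.origin_lon for s in self.species],
            }
        )


def true_suitability(species: Species, climate: ClimateRaster, period: str = "current") -> np.ndarray:
    """Ground-truth suitability surface: the niche's Gaussian density.

    Returned on the full grid (masked cells NaN). Densities below 1e-12 of
    the surface maximum are floored to exactly zero so "unsuitable" is a
    well-defined set.
    """
    X = climate.matrix(period)
    dens = stats.multivariate_normal(mean=species.niche_mean, cov=species.niche_cov).pdf(X)
    dens = np.atleast_1d(dens)
    dens[dens < 1e-12 * dens.max()] = 0.0
    out = np.full(climate.grid.n_cells, np.nan)
    out[climate.valid_cells] = dens
    return out.reshape(climate.grid.shape)


def gen_species_pool(
    n_species: int,
    climate: ClimateRaster,
    seed: int,
    niche_breadth: float = 0.18,
    envelope_margin: float = 0.15,
) -> SpeciesPool:
    """Draw species with Gaussian niches inside the observed climate envelope.

    ``niche_breadth`` is each variable's niche standard deviation as a
    fraction of that variable's range over valid cells; ``envelope_margin``
    keeps niche means away from the envelope edges. The origin point of a
    species is a uniformly chosen cell in the top decile of its own true
    suitability (domestication happened where the species thrived).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if climate.valid_cells.size == 0:
        raise ValueError("climate raster has no valid cells")
    rng = np.random.default_rng(seed)
    X = climate.matrix("current")
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    lat_c, lon_c = climate.grid.center_mesh()
    lat_flat = lat_c.ravel()[climate.valid_cells]
    lon_flat = lon_c.ravel()[climate.valid_cells]

    species = []
    for k in range(n_species):
        mean = rng.uniform(lo + envelope_margin * span, hi - envelope_margin * span)
        sd = niche_breadth * span
        # random correlation via a low-rank factor keeps the matrix SPD
        W = 0.4 * rng.standard_normal((5, 2))
        corr = np.eye(5) + W @ W.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        cov = np.outer(sd, sd) * corr
        sp = Species(f"sp{k:03d}", mean, cov, 0.0, 0.0)
        suit = true_suitability(sp, climate)
        svals = suit.ravel()[climate.valid_cells]
        q90 = np.quantile(svals, 0.9)
        top = np.flatnonzero(svals >= q90)
        pick = rng.choice(top)
        species.append(replace(sp, origin_lat=float(lat_flat[pick]), origin_lon=float(lon_flat[pick])))
    return SpeciesPool(species)


def sample_occurrences(
    species: Species,
    climate: ClimateRaster,
    n_records: int,
    seed: int,
    duplication_rate: float = 0.0,
) -> pd.DataFrame:
    """Sample occurrence records proportional to true suitability.

    Cells are drawn with replacement with probability proportional to the
    Gaussian-density suitability; coordinates get uniform sub-cell jitter.
    ``duplication_rate`` optionally re-reports a fraction of records in
    their same cell, emulating reporting bias.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(seed)
    suit = true_suitability(species, climate).ravel()[climate.valid_cells]
    total = suit.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("all-zero suitability surface: cannot sample occurrences")
    p = suit / total
    cells = rng.choice(climate.valid_cells, size=n_records, p=p, replace=True)
    if duplication_rate > 0:
        n_dup = int(duplication_rate * n_records)
        if n_dup:
            cells = np.concatenate([cells, rng.choice(cells, size=n_dup)])
    grid = climate.grid
    i, j = np.divmod(cells, grid.n_lon)
    lat = grid.lat_min + (i + rng.uniform(0.0, 1.0, size=cells.size)) * grid.dlat
    lon = grid.lon_min + (j + rng.uniform(0.0, 1.0, size=cells.size)) * grid.dlon
    return pd.DataFrame({"species": species.species_id, "lat": lat, "lon": lon})


def true_richness_map(
    pool: SpeciesPool,
    climate: ClimateRaster,
    radius_km: float | None = None,
    suit_cut: float = 0.01,
) -> np.ndarray:
    """Ground-truth domesticate richness per cell.

    A species is "truly present" in a cell when its Gaussian-density
    suitability is at least ``suit_cut`` of its own maximum and, if
    ``radius_km`` is given, the cell center lies within that great-circle
    distance of the species' origin. Stacking these truth maps gives the
    generative historical-ecological-opportunity signal.

    The default cut of 1% of the species' peak density is the
    self-consistency point of the study design: occurrence records are
    sampled proportional to density, so with order-10^2 records the
    minimum sampled density — the non-omission threshold the estimation
    side uses — sits near max/m, i.e. about 1% of the peak. The truth
    map is thus defined by the same notion of "can occur" that the
    record-sampling model implies, not by an arbitrary envelope.
    """
    from .grid import haversine_km  # local import to keep module load cheap

    grid = climate.grid
    lat, lon = grid.center_mesh()
    rich = np.zeros(grid.shape, dtype=int)
    for sp in pool:
        suit = true_suitability(sp, climate)
        present = suit >= suit_cut * np.nanmax(suit)
        if radius_km is not None:
            present &= haversine_km(lat, lon, sp.origin_lat, sp.origin_lon) <= radius_km
        rich += np.where(np.isnan(suit), False, present)
    return rich


def sample_pool_occurrences(
    pool: SpeciesPool, climate: ClimateRaster, n_records: int, seed: int, **kw
) -> pd.DataFrame:
    """Occurrences for every species in a pool (per-species sub-seeds)."""
    seeds = np.random.SeedSequence(seed).generate_state(len(pool))
    frames = [
        sample_occurrences(sp, climate, n_records, int(s) % (2**31), **kw)
        for sp, s in zip(pool, seeds)
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Societies


@dataclass(frozen=True)
class SocietyGenParams:
    """Generative coefficients for the synthetic society table.

    The latent farming propensity of society i is

        base_i = beta_heo * z(HEO_i) + beta_ceo * z(CEO_i) + u_family(i) + eps_i
        latent_i = (base_i + beta_hor * mean_{j in kNN(i)} base_j) / (1 + beta_hor)

    with HEO the true domesticate richness at the society's cell, CEO the
    average of standardized contemporary mammal and plant richness,
    u_family ~ N(0, family_sd^2) and eps ~ N(0, noise_sd^2). Families are
    (optionally) spatially clustered, which is what confounds the
    language-family grouping with ecological opportunity.
    """

    beta_hor: float = 0.3
    beta_heo: float = 0.5
    beta_ceo: float = 0.2
    family_sd: float = 0.5
    noise_sd: float = 1.0
    n_families: int = 20
    k_true: int = 5
    cluster_families: bool = True
    cluster_sd_deg: float = 3.0
    budget_noise_sd: float = 0.15
    agri_gain: float = 0.8       # latent -> agriculture logit slope
    pastoral_gain: float = 0.3   # latent -> pastoralism logit slope


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def gen_societies(
    n: int,
    climate: ClimateRaster,
    true_richness: np.ndarray,
    params: SocietyGenParams | None = None,
    seed: int = 0,
    keep_truth: bool = True,
) -> pd.DataFrame:
    """Generate a society table with known latent structure.

    ``true_richness`` is a grid (same shape as the climate raster) of the
    ground-truth number of early domesticates available per cell; it is
    the historical-ecological-opportunity signal the downstream pipeline
    tries to recover. Contemporary mammal and plant richness covariates
    are Poisson counts whose log-rates follow the current climate.

    Returns a DataFrame with columns id, lat, lon, family, the five
    Murdock codes, mammal_rich, plant_rich, and (if ``keep_truth``) hidden
    columns ``latent_true``, ``heo_true`` and ``pct_true_<activity>``.
    """
    p = params or SocietyGenParams()
    if n < 2:
        raise ValueError("need at least 2 societies")
    if p.n_families < 1:
        raise ValueError("n_families must be >= 1")
    if p.k_true >= n:
        raise ValueError("k_true must be < n")
    grid = climate.grid
    if true_richness.shape != grid.shape:
        raise ValueError("true_richness shape does not match the climate grid")
    rng = np.random.default_rng(seed)

    # positions: family cluster centers + jitter, or fully uniform
    pad_lat, pad_lon = 0.02 * (grid.lat_max - grid.lat_min), 0.02 * (grid.lon_max - grid.lon_min)
    fam_idx = rng.integers(0, p.n_families, size=n)
    if p.cluster_families:
        centers_lat = rng.uniform(grid.lat_min + pad_lat, grid.lat_max - pad_lat, size=p.n_families)
        centers_lon = rng.uniform(grid.lon_min + pad_lon, grid.lon_max - pad_lon, size=p.n_families)
        lat = centers_lat[fam_idx] + p.cluster_sd_deg * rng.standard_normal(n)
        lon = centers_lon[fam_idx] + p.cluster_sd_deg * rng.standard_normal(n)
    else:
        lat = rng.uniform(grid.lat_min + pad_lat, grid.lat_max - pad_lat, size=n)
        lon = rng.uniform(grid.lon_min + pad_lon, grid.lon_max - pad_lon, size=n)
    lat = np.clip(lat, grid.lat_min + 1e-6, grid.lat_max - 1e-6)
    lon = np.clip(lon, grid.lon_min + 1e-6, grid.lon_max - 1e-6)

    i, j = grid.cell_of(lat, lon)
    cells = i * grid.n_lon + j

    heo = true_richness.ravel()[cells].astype(float)

    # contemporary richness covariates follow current climate
    zt = _zscore(climate.layer("current", "annual_mean_temp").ravel()[cells])
    zw = _zscore(climate.layer("current", "prec_wettest_month").ravel()[cells])
    mammal = rng.poisson(np.exp(np.log(60.0) + 0.30 * zt + 0.15 * zw))
    plant = rng.poisson(np.exp(np.log(400.0) + 0.25 * zt + 0.30 * zw))
    z_ceo = (_zscore(mammal.astype(float)) + _zscore(plant.astype(float))) / 2.0

    u_fam = p.family_sd * rng.standard_normal(p.n_families)
    base = (
        p.beta_heo * _zscore(heo)
        + p.beta_ceo * z_ceo
        + u_fam[fam_idx]
        + p.noise_sd * rng.standard_normal(n)
    )

    if p.beta_hor != 0.0:
        D = pairwise_haversine_km(lat, lon)
        np.fill_diagonal(D, np.inf)
        nbr = np.argsort(D, axis=1, kind="stable")[:, : p.k_true]
        latent = (base + p.beta_hor * base[nbr].mean(axis=1)) / (1.0 + p.beta_hor)
    else:
        latent = base

    # softmax link from latent propensity to the 5-part budget
    z_lat = _zscore(latent)
    logits = np.empty((n, 5))
    logits[:, 0] = 0.5   # hunt
    logits[:, 1] = 0.3   # gather
    logits[:, 2] = 0.0   # fish
    logits[:, 3] = 0.2 + p.agri_gain * z_lat       # agriculture
    logits[:, 4] = -0.4 + p.pastoral_gain * z_lat  # pastoralism
    logits += p.budget_noise_sd * rng.standard_normal((n, 5))
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    pct = 100.0 * e / e.sum(axis=1, keepdims=True)

    codes = encode_murdock(pct)

    df = pd.DataFrame(
        {
            "id": [f"soc{k:04d}" for k in range(n)],
            "lat": lat,
            "lon": lon,
            "family": [f"fam{f:02d}" for f in fam_idx],
            **{act: codes[:, a] for a, act in enumerate(ACTIVITIES)},
            "mammal_rich": mammal,
            "plant_rich": plant,
        }
    )
    if keep_truth:
        df["latent_true"] = latent
        df["heo_true"] = heo
        for a, act in enumerate(ACTIVITIES):
            df[f"pct_true_{act}"] = pct[:, a]
    return df
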
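"""End-to-end orchestration of the farming-propensity analysis.

Stages, in order: farming propensity from Murdock codes -> per-species
niche models -> dispersal-radius sweep and stacked richness ->
transmission proxies -> mixed model + commonality partition + residual
correlogram. Every stage gets its own sub-seed spawned from the master
seed (``numpy.random.SeedSequence(master_seed).spawn``, one child per
stage index), so stages are individually reproducible and independent.
All intermediate artifacts plus a manifest (input checksums, seeds,
timings) are written to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .inference import fit_lmm, residual_correlogram, variance_partition
from .niche import FeatureConfig, fit_species
from .propensity import farming_propensity
from .richness import richness_at_societies, sweep_dispersal_radius
from .transmission import knn_horizontal, select_k

logger = logging.getLogger(__name__)

STAGES = ("propensity", "niche", "richness", "transmission", "inference")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    societies: str
    occurrences: str
    origins: str
    climate: str
    out_dir: str
    n_draws: int = 1000
    min_records: int = 15
    reg_multiplier: float = 1.0
    radii_km: list[float] = field(default_factory=lambda: list(np.arange(250.0, 10_000.1, 250.0)))
    k: int | None = None                  # fixed neighbourhood size ...
    k_range: tuple[int, int] = (1, 30)    # ... or selected over this range
    n_classes: int = 12
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "radii_km" in raw and isinstance(raw["radii_km"], str):
            a, b, s = (float(v) for v in raw["radii_km"].split(":"))
            raw["radii_km"] = list(np.arange(a, b + 1e-9, s))
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Fixed per-stage sub-seed scheme: child i of the master SeedSequence."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0]) % (2**31) for s, c in zip(STAGES, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.master_seed)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                   for k, v in asdict(config).items()},
        "stage_seeds": seeds,
        "inputs": {},
        "stages": {},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }

    # a missing input aborts under the name of the stage that consumes it
    consumer = {"societies": "propensity", "occurrences": "niche",
                "climate": "niche", "origins": "richness"}
    current = "inputs"
    try:
        for key in ("societies", "occurrences", "origins", "climate"):
            path = getattr(config, key)
            if not Path(path).exists():
                current = consumer[key]
                raise FileNotFoundError(f"{key} input not found: {path}")
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        societies = fio.read_societies(config.societies)
        occurrences = fio.read_occurrences(config.occurrences)
        origins = fio.read_origins(config.origins)
        climate = fio.read_climate(config.climate)
        grid = climate.grid

        # -- propensity ----------------------------------------------------
        current = "propensity"
        t0 = time.perf_counter()
        prop = farming_propensity(societies, n_draws=config.n_draws, seed=seeds["propensity"])
        prop.to_frame().to_csv(out / "propensity.csv", index=False)
        manifest["stages"]["propensity"] = {
            "seconds": time.perf_counter() - t0,
            "pc1_var_fraction": prop.pc1_var_fraction,
            "pc1_var_fraction_sd": prop.pc1_var_fraction_sd,
        }

        # -- niche models --------------------------------------------------
        current = "niche"
        t0 = time.perf_counter()
        sp_ids = sorted(occurrences["species"].unique())
        sub = np.random.SeedSequence(seeds["niche"]).generate_state(len(sp_ids))
        fits, summary = {}, []
        for sp, s in zip(sp_ids, sub):
            res = fit_species(
                sp, occurrences[occurrences["species"] == sp], climate,
                min_records=config.min_records, reg_multiplier=config.reg_multiplier,
                seed=int(s) % (2**31), feature_config=FeatureConfig(),
            )
            if res is None:
                summary.append({"species": sp, "n_records": 0, "auc": np.nan,
                                "threshold": np.nan, "dropped": True})
                continue
            fits[sp] = res
            summary.append({
                "species": sp, "n_records": len(res.thinned), "auc": res.model.auc,
                "threshold": res.presence_historical.threshold, "dropped": False,
            })
        if not fits:
            raise ValueError("every species was dropped during occurrence thinning")
        pd.DataFrame(summary).to_csv(out / "models_summary.csv", index=False)
        fio.write_grid_stack({sp: r.suitability_historical for sp, r in fits.items()},
                             grid, out / "suitability_historical.nc")
        fio.write_grid_stack({sp: r.presence_historical.values.astype(np.int8) for sp, r in fits.items()},
                             grid, out / "presence_historical.nc", dtype=np.int8)
        manifest["stages"]["niche"] = {
            "seconds": time.perf_counter() - t0,
            "n_modelled": len(fits),
            "n_dropped": len(sp_ids) - len(fits),
            "mean_auc": float(np.nanmean([r.model.auc for r in fits.values()])),
        }

        # -- richness sweep ------------------------------------------------
        current = "richness"
        t0 = time.perf_counter()
        presence_maps = [r.presence_historical for r in fits.values()]
        sweep = sweep_dispersal_radius(
            presence_maps, origins, societies, prop.scores, grid,
            radii_km=np.asarray(config.radii_km),
        )
        pd.DataFrame({"radius_km": sweep.radii_km, "pearson_r": sweep.correlations}).to_csv(
            out / "radius_sweep.csv", index=False
        )
        fio.write_grid_stack({"richness": sweep.richness_at_selected.values}, grid,
                             out / "richness_selected.nc")
        heo = richness_at_societies(sweep.richness_at_selected, societies, grid)
        manifest["stages"]["richness"] = {
            "seconds": time.perf_counter() - t0,
            "selected_radius_km": sweep.selected_radius_km,
            "max_correlation": float(np.nanmax(sweep.correlations)),
        }

        # -- transmission proxies -------------------------------------------
        current = "transmission"
        t0 = time.perf_counter()
        if config.k is not None:
            chosen_k = int(config.k)
        else:
            lo, hi = config.k_range
            chosen_k = select_k(societies, prop.scores, range(lo, hi + 1),
                                n_classes=config.n_classes).chosen_k
        horizontal = knn_horizontal(societies, prop.scores, chosen_k)
        proxies = pd.DataFrame({
            "id": societies["id"], "horizontal": horizontal.to_numpy(),
            "family": societies["family"],
        })
        proxies.to_csv(out / "proxies.csv", index=False)
        manifest["stages"]["transmission"] = {
            "seconds": time.perf_counter() - t0, "k": chosen_k,
        }

        # -- inference -----------------------------------------------------
        current = "inference"
        t0 = time.perf_counter()
        tab = societies[["id", "lat", "lon", "family", "mammal_rich", "plant_rich"]].copy()
        tab["propensity"] = prop.scores.reindex(tab["id"]).to_numpy()
        tab["horizontal"] = horizontal.reindex(tab["id"]).to_numpy()
        tab["heo"] = heo.reindex(tab["id"]).to_numpy()
        cc = tab.dropna()

        fit = fit_lmm(cc, "propensity",
                      ["horizontal", "heo", "mammal_rich", "plant_rich"], "family")
        with open(out / "fit.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2)

        fam_dummies = pd.get_dummies(cc["family"], drop_first=True).to_numpy(dtype=float)
        blocks = {
            "Hor": cc[["horizontal"]].to_numpy(dtype=float),
            "Ver": fam_dummies,
            "CEO": cc[["mammal_rich", "plant_rich"]].to_numpy(dtype=float),
            "HEO": cc[["heo"]].to_numpy(dtype=float),
        }
        y = cc["propensity"].to_numpy(dtype=float)
        part = variance_partition(y, blocks)
        part.to_frame().to_csv(out / "partition.csv", index=False)

        Xfix = np.column_stack([blocks["Hor"], blocks["HEO"], blocks["CEO"], fam_dummies])
        Xi = np.column_stack([np.ones(len(y)), Xfix])
        beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
        resid = y - Xi @ beta
        cg = residual_correlogram(resid, cc["lat"].to_numpy(), cc["lon"].to_numpy(),
                                  n_classes=config.n_classes)
        pd.DataFrame({
            "upper_bound_km": cg.upper_bounds_km, "morans_i": cg.morans_i,
            "pair_count": cg.pair_counts,
        }).to_csv(out / "correlogram.csv", index=False)

        largest = max(part.components, key=lambda kk: part.components[kk])
        manifest["stages"]["inference"] = {
            "seconds": time.perf_counter() - t0,
            "n_complete_cases": int(fit.n),
            "full_r2": part.full_r2,
            "largest_component": "&".join(largest),
            "largest_component_value": part.components[largest],
            "max_abs_residual_moran": float(np.max(np.abs(cg.morans_i))),
        }
    except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
        manifest["failed_stage"] = current
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
        raise PipelineStageError(current, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def simulate_world(
    out_dir: str | Path,
    n_societies: int = 200,
    n_species: int = 8,
    grid: "GridSpec | None" = None,
    seed: int = 0,
    n_records: int = 150,
    true_radius_km: float | None = 3000.0,
    society_params=None,
) -> dict[str, str]:
    """Generate and write the four pipeline inputs for a synthetic world.

    Returns a dict of written paths (societies, occurrences, origins,
    climate). The society table is generated against the ground-truth
    richness of the species pool under ``true_radius_km`` dispersal, so a
    downstream radius sweep has a known optimum to recover.
    """
    from .grid import GridSpec
    from .synthetic import (
        SocietyGenParams, gen_climate, gen_societies, gen_species_pool,
        sample_pool_occurrences, true_richness_map,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_clim, s_pool, s_occ, s_soc = (int(x) % (2**31) for x in ss.generate_state(4))
    grid = grid or GridSpec(n_lat=30, n_lon=90, lat_min=-30, lat_max=30, lon_min=-90, lon_max=90)
    climate = gen_climate(grid, seed=s_clim)
    pool = gen_species_pool(n_species, climate, seed=s_pool)
    occ = sample_pool_occurrences(pool, climate, n_records, seed=s_occ)
    rich = true_richness_map(pool, climate, radius_km=true_radius_km)
    societies = gen_societies(
        n_societies, climate, rich, params=society_params or SocietyGenParams(), seed=s_soc
    )
    paths = {
        "societies": str(out / "societies.csv"),
        "occurrences": str(out / "occurrences.csv"),
        "origins": str(out / "origins.csv"),
        "climate": str(out / "climate.nc"),
    }
    fio.write_societies(societies, paths["societies"])
    occ.to_csv(paths["occurrences"], index=False)
    pool.origins_frame().to_csv(paths["origins"], index=False)
    fio.write_climate(climate, paths["climate"])
    return paths
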
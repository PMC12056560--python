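"""File formats, run configuration, and the end-to-end pipeline.

Interchange formats are deliberately plain text: newick trees (via dendropy),
ESRI ASCII grids for rasters (native reader/writer, nodata default -9999),
comma-separated observation/taxon tables, and YAML for configuration and
ground truth.  ``run_pipeline`` composes calibrate -> surfaces -> extract ->
scale/VIF -> mixed-model fits -> comparative analyses and writes a manifest
so a run is fully reproducible from its seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparative, morpho, pglmm, predation
from .predation import RasterGrid
from .trees import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "read_tree",
    "write_tree",
    "read_raster",
    "write_raster",
    "read_observations",
    "write_observations",
    "read_bat_taxa",
    "read_populations",
    "read_truth",
    "write_truth",
    "RunConfig",
    "load_config",
    "run_pipeline",
    "write_study",
]


# -------------------------------------------------------------------- trees
def read_tree(path) -> Phylogeny:
    """Read a rooted newick tree with branch lengths."""
    text = Path(path).read_text()
    return Phylogeny.from_newick(text)


def write_tree(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ------------------------------------------------------------------ rasters
_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_raster(path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc).

    Header keys ncols/nrows/xllcorner/yllcorner/cellsize are required;
    NODATA_value is optional and defaults to -9999 (logged when applied).
    """
    path = Path(path)
    header = {}
    data_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (*_HEADER_KEYS, "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: missing header fields {missing}")
    if "nodata_value" not in header:
        logger.info("%s: no NODATA_value header; defaulting to -9999", path)
        header["nodata_value"] = -9999.0
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.array(" ".join(lines[data_start:]).split(), dtype=float)
    if values.size != n_rows * n_cols:
        raise ValueError(
            f"{path}: expected {n_rows * n_cols} values, found {values.size}"
        )
    values = values.reshape(n_rows, n_cols)
    nodata = header["nodata_value"]
    values[values == nodata] = np.nan
    return RasterGrid(
        values=values,
        x_ll=header["xllcorner"],
        y_ll=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=nodata,
    )


def write_raster(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid; values print at full double precision so a
    read/write round trip is value-faithful."""
    path = Path(path)
    out = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_ll:.17g}\n")
        fh.write(f"yllcorner {grid.y_ll:.17g}\n")
        fh.write(f"cellsize {grid.cell_size:.17g}\n")
        fh.write(f"NODATA_value {grid.nodata:.17g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ------------------------------------------------------------------- tables
_OBS_REQUIRED = ("species", "lon", "lat", "fw", "hw", "antenna", "has_scale", "sex")


def read_observations(path) -> pd.DataFrame:
    """Read the photo/measurement table (CSV, UTF-8, '.' decimal)."""
    obs = pd.read_csv(path)
    missing = set(_OBS_REQUIRED) - set(obs.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    if ((obs["lon"].abs() > 180) | (obs["lat"].abs() > 90)).any():
        raise ValueError("coordinates outside lon [-180,180] / lat [-90,90]")
    for col in ("fw", "hw", "antenna"):
        if (obs[col].dropna() <= 0).any():
            raise ValueError(f"nonpositive values in column {col!r}")
    obs["has_scale"] = obs["has_scale"].astype(bool)
    return obs


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False)


def read_bat_taxa(path) -> pd.DataFrame:
    t = pd.read_csv(path)
    for col in ("aerial_insectivore", "overlaps_moths"):
        if col in t.columns:
            t[col] = t[col].astype(bool)
    return t


def read_populations(path) -> dict:
    t = pd.read_csv(path)
    if not {"species", "population"} <= set(t.columns):
        raise ValueError("population table needs 'species' and 'population' columns")
    return dict(zip(t["species"], t["population"].astype(float)))


def read_truth(path):
    from .synth import GenerativeTruth

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return GenerativeTruth(**raw)


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(truth), fh, sort_keys=True)


def write_study(study, outdir) -> "RunConfig":
    """Write a :class:`~mothtails.synth.SyntheticStudy` to disk.

    Produces tree.nwk, obs.csv, env/*.asc, sdm/*.asc, pops.csv and
    truth.yaml under ``outdir`` and returns a ready :class:`RunConfig`
    pointing at them (results go to ``outdir/results``).
    """
    outdir = Path(outdir)
    (outdir / "env").mkdir(parents=True, exist_ok=True)
    (outdir / "sdm").mkdir(exist_ok=True)
    write_tree(study.tree, outdir / "tree.nwk")
    # the pipeline re-extracts covariates itself; write the raw table
    raw_cols = [c for c in study.obs.columns
                if c not in ("bat_abundance", *study.env.keys())]
    write_observations(study.obs[raw_cols], outdir / "obs.csv")
    for name, grid in study.env.items():
        write_raster(grid, outdir / "env" / f"{name}.asc")
    for name, grid in study.surfaces.items():
        write_raster(grid, outdir / "sdm" / f"{name}.asc")
    pd.DataFrame(
        {"species": list(study.populations), "population": list(study.populations.values())}
    ).to_csv(outdir / "pops.csv", index=False)
    write_truth(study.truth, outdir / "truth.yaml")
    return RunConfig(
        tree=str(outdir / "tree.nwk"),
        obs=str(outdir / "obs.csv"),
        sdm_dir=str(outdir / "sdm"),
        pops=str(outdir / "pops.csv"),
        env={name: str(outdir / "env" / f"{name}.asc") for name in study.env},
        outdir=str(outdir / "results"),
        seed=study.truth.seed,
    )


# ------------------------------------------------------------------- config
@dataclass
class RunConfig:
    """Paths, model options and seeds for one pipeline run."""

    tree: str
    obs: str
    sdm_dir: str
    pops: str
    env: dict  # covariate name -> raster path
    outdir: str
    bat_taxa: str | None = None
    response: str = "adj_hw"
    fixed: tuple = ("bat_abundance", "lgp", "precipitation", "temperature", "seasonality")
    interactions: tuple = ()
    mcmc_iter: int = 0
    burn_in: int | None = None
    k_perms: int = 1000
    seed: int = 0
    males_only: bool = True
    rescale: bool = True

    def validate(self) -> None:
        for name in ("tree", "obs", "sdm_dir", "pops"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
        for cov, p in self.env.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"env raster {cov!r} does not exist: {p}")
        if self.bat_taxa is not None and not Path(self.bat_taxa).exists():
            raise FileNotFoundError(f"bat_taxa does not exist: {self.bat_taxa}")
        if not isinstance(self.seed, int):
            raise TypeError("seed must be an integer")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = RunConfig(**raw)
    cfg.fixed = tuple(cfg.fixed)
    cfg.interactions = tuple(cfg.interactions)
    return cfg


# ----------------------------------------------------------------- pipeline
def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def _fit_to_dict(fit: pglmm.PGLMMFit) -> dict:
    return {
        "beta": {
            name: {k: float(v) for k, v in row.items()}
            for name, row in fit.beta.iterrows()
        },
        "sigma2_phy": fit.sigma2_phy,
        "sigma2_sp": fit.sigma2_sp,
        "sigma2_e": fit.sigma2_e,
        "logLik_ml": fit.logLik_ml,
        "logLik_reml": fit.logLik_reml,
        "aic": fit.aic,
        "dic": fit.dic,
        "r2_marginal": fit.r2_marginal,
        "r2_conditional": fit.r2_conditional,
        "n_obs": fit.n_obs,
        "n_species": fit.n_species,
        "method": fit.method,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Run calibrate -> surfaces -> extract -> fit/compare -> comparative.

    Writes all declared outputs plus ``manifest.json`` under
    ``config.outdir`` and returns that directory.  Any stage failure raises
    with the stage name after writing a partial manifest.  Outputs carry no
    timestamps, so identical configs and seeds give byte-identical files.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("mothtails")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)

    manifest = {
        "inputs": {
            "tree": str(config.tree),
            "obs": str(config.obs),
            "sdm_dir": str(config.sdm_dir),
            "pops": str(config.pops),
            "env": {k: str(v) for k, v in config.env.items()},
            "bat_taxa": str(config.bat_taxa) if config.bat_taxa else None,
        },
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }
    stage = "load"
    try:
        tree = read_tree(config.tree)
        obs = read_observations(config.obs)
        env = {name: read_raster(p) for name, p in config.env.items()}
        pops = read_populations(config.pops)
        sdm_paths = sorted(Path(config.sdm_dir).glob("*.asc"))
        surfaces = {p.stem: read_raster(p) for p in sdm_paths}
        if not surfaces:
            raise FileNotFoundError(f"no .asc surfaces under {config.sdm_dir}")
        manifest["stages"]["load"] = {
            "n_obs": int(len(obs)),
            "n_tips": tree.n_tips,
            "n_surfaces": len(surfaces),
        }

        if config.bat_taxa:
            stage = "bat_filter"
            taxa = read_bat_taxa(config.bat_taxa)
            selected, audit = predation.filter_bat_taxa(taxa)
            surfaces = {k: v for k, v in surfaces.items() if k in set(selected)}
            if not surfaces:
                raise ValueError("bat filter removed every SDM surface")
            manifest["stages"]["bat_filter"] = audit

        stage = "calibrate"
        means = morpho.species_mean_antenna(obs, males_only=config.males_only)
        adjusted = morpho.add_adjusted_columns(obs, means)
        validation, skipped = morpho.validate_adjustment(
            obs, means, males_only=config.males_only
        )
        adjusted_path = outdir / "adjusted.csv"
        write_observations(adjusted, adjusted_path)
        validation.to_csv(outdir / "validation.csv", index=False)
        manifest["stages"]["calibrate"] = {
            "n_species": len(means.means),
            "n_validated": int(len(validation)),
            "skipped": skipped,
        }

        stage = "surfaces"
        pops = {k: pops[k] for k in surfaces}
        pressure = predation.total_pressure_surface(surfaces, pops)
        write_raster(pressure.richness, outdir / "pressure_richness.asc")
        write_raster(pressure.abundance, outdir / "pressure_abundance.asc")
        manifest["stages"]["surfaces"] = {
            "n_species": len(surfaces),
            "total_population": float(sum(pops.values())),
        }

        stage = "extract"
        points = list(zip(adjusted["lon"], adjusted["lat"]))
        adjusted["bat_abundance"] = predation.extract_at_points(
            pressure.abundance, points
        )
        for name, grid in env.items():
            adjusted[name] = predation.extract_at_points(grid, points)
        covariate_names = ["bat_abundance", *env.keys()]
        n_drop = int(adjusted[covariate_names].isna().any(axis=1).sum())
        adjusted = adjusted.dropna(subset=covariate_names).reset_index(drop=True)
        manifest["stages"]["extract"] = {
            "covariates": covariate_names,
            "n_dropped_nodata": n_drop,
            "n_rows": int(len(adjusted)),
        }

        stage = "vif"
        X = np.column_stack(
            [pglmm.center_scale(adjusted[c].to_numpy(float)) for c in covariate_names]
        )
        vif_table = pglmm.vif(X, names=covariate_names)
        high = vif_table[vif_table >= 3]
        if len(high):
            logger.warning("VIF >= 3 for: %s", dict(high))
        manifest["stages"]["vif"] = {k: float(v) for k, v in vif_table.items()}

        stage = "fit"
        fixed = tuple(c for c in config.fixed if c in adjusted.columns)
        specs = [
            pglmm.ModelSpec(response=config.response, fixed=(), name="null"),
            pglmm.ModelSpec(response=config.response, fixed=fixed, name="global"),
        ]
        no_bats = tuple(c for c in fixed if c != "bat_abundance")
        if no_bats != fixed:
            specs.append(
                pglmm.ModelSpec(response=config.response, fixed=no_bats, name="no_bats")
            )
        if config.interactions:
            specs.append(
                pglmm.ModelSpec(
                    response=config.response,
                    fixed=fixed + tuple(config.interactions),
                    name="interaction",
                )
            )
        comparison = pglmm.compare_models(
            adjusted,
            tree,
            specs,
            mcmc_iter=config.mcmc_iter,
            burn_in=config.burn_in,
            seed=config.seed,
            rescale=config.rescale,
        )
        comparison.to_csv(outdir / "model_comparison.csv", index=False)
        fits = comparison.attrs["fits"]
        if "global" not in fits:
            err = comparison.set_index("name").loc["global", "error"]
            raise RuntimeError(f"global model failed to fit: {err}")
        _write_json({n: _fit_to_dict(f) for n, f in fits.items()}, outdir / "fit.json")
        manifest["stages"]["fit"] = {
            "n_models": len(specs),
            "fitted": sorted(fits),
        }

        stage = "comparative"
        scaled_rows = adjusted[adjusted["has_scale"]]
        trait = scaled_rows.groupby("species")["adj_hw"].mean()
        missing_sp = set(tree.tip_labels()) - set(trait.index)
        if missing_sp:
            raise ValueError(
                f"no scaled specimens for species {sorted(missing_sp)}; "
                "cannot build the comparative trait"
            )
        traits = trait.to_dict()
        evo = comparative.compare_evolution_models(tree, traits)
        kres = comparative.blomberg_k(
            tree, traits, n_perm=config.k_perms, seed=config.seed
        )
        asr = comparative.asr_bm(tree, traits)
        comp_out = {
            "models": [
                {
                    "model": f.model,
                    "z0": f.z0,
                    "sigma2": f.sigma2,
                    "alpha": f.alpha,
                    "r": f.r,
                    "logLik": f.logLik,
                    "aic": f.aic,
                }
                for f in evo
            ],
            "best_model": evo[0].model,
            "blomberg_k": {"K": kres.K, "p": kres.p, "n_perm": kres.n_perm},
        }
        _write_json(comp_out, outdir / "comparative.json")
        pd.DataFrame(
            {"node": list(asr.states), "state": list(asr.states.values())}
        ).to_csv(outdir / "asr.csv", index=False)
        (outdir / "asr_annotated.nwk").write_text(
            tree.to_newick(
                node_comments={n: f"state={v:.8g}" for n, v in asr.states.items()}
            )
            + "\n"
        )
        manifest["stages"]["comparative"] = {
            "best_model": evo[0].model,
            "n_trait_species": int(len(traits)),
        }

        manifest["outputs"] = sorted(
            p.name for p in outdir.iterdir() if p.name not in ("manifest.json", "run.log")
        )
        _write_json(manifest, outdir / "manifest.json")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_json(manifest, outdir / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
    return outdir
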
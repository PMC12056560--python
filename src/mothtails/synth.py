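"""Synthetic data with known ground truth.

Everything the downstream analysis consumes can be fabricated here: a
birth-death phylogeny, Brownian-motion trait evolution on it, smooth
environmental covariate rasters, bat habitat-suitability surfaces with
population totals, and a photo-measurement table in which photos without a
scale bar report lengths in unknown per-photo pixel units.  The generative
model for hindwing length mirrors the mixed model the fitting module
estimates, so every effect size, variance component and root state is a
recoverable ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .predation import RasterGrid, extract_at_points
from .trees import Phylogeny

__all__ = [
    "GenerativeTruth",
    "SyntheticStudy",
    "DEFAULT_COVARIATES",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_environment",
    "simulate_sdm_surfaces",
    "simulate_moth_dataset",
    "make_synthetic_study",
]

#: Environmental covariates emulating the bioclim + growing-period layers the
#: analysis uses: mean annual temperature (degC), temperature seasonality
#: (sd of monthly means, degC), annual precipitation (mm), and length of
#: growing period (days).
DEFAULT_COVARIATES = ("temperature", "seasonality", "precipitation", "lgp")

# (baseline value at the mid-latitude, change per degree of latitude)
_COVARIATE_GRADIENTS = {
    "temperature": (18.0, -0.5),
    "seasonality": (6.0, 0.4),
    "precipitation": (1200.0, -15.0),
    "lgp": (220.0, -3.0),
}


@dataclass
class GenerativeTruth:
    """Ground-truth parameters of the hindwing-length generative model.

    ``beta`` holds fixed-effect sizes on *centred-and-scaled* covariates
    (mm per covariate standard deviation), so estimates from the fitting
    module are directly comparable.  Variance components are in mm^2; the
    phylogenetic component applies to the tree's unit-height BM correlation
    matrix, matching the fitter's convention.
    """

    beta: dict = field(
        default_factory=lambda: {
            "bat_abundance": 0.5,
            "lgp": 0.3,
            "precipitation": -0.2,
            "temperature": -0.2,
            "seasonality": -0.4,
        }
    )
    sigma2_phy: float = 144.0
    sigma2_sp: float = 4.0
    sigma2_e: float = 1.0
    z0: float = 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_phy", "sigma2_sp", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# --------------------------------------------------------------------- trees
def simulate_tree(
    n_tips: int,
    birth_rate: float,
    death_rate: float = 0.0,
    seed: int = 0,
    max_retries: int = 1000,
) -> Phylogeny:
    """Simulate an ultrametric birth-death tree with exactly ``n_tips`` tips.

    A crown-start forward simulation: two lineages begin at the root and
    speciate/go extinct at the given per-lineage rates.  The simulation stops
    the moment the extant count reaches ``n_tips``; the present is placed
    uniformly within the waiting time to the next event so terminal branches
    are strictly positive.  Runs that go extinct first are retried (the
    simulation conditions on survival); exceeding ``max_retries`` signals
    infeasible rates.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not (birth_rate > death_rate >= 0):
        raise ValueError("require birth_rate > death_rate >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        tree = _try_simulate(n_tips, birth_rate, death_rate, rng)
        if tree is not None:
            return tree
    raise RuntimeError(
        f"failed to reach {n_tips} extant tips in {max_retries} attempts; "
        "rates too close to criticality"
    )


def _try_simulate(n_tips, birth, death, rng):
    # node records: parent, t_start; t_end filled at speciation/extinction
    parent = [-1, 0, 0]
    t_start = [0.0, 0.0, 0.0]
    t_end = [0.0, None, None]
    alive = [1, 2]  # extant lineage node ids
    t = 0.0
    total_rate = birth + death
    while len(alive) != n_tips:
        if not alive:
            return None
        t += rng.exponential(1.0 / (len(alive) * total_rate))
        k = int(rng.integers(len(alive)))
        node = alive[k]
        if rng.random() < birth / total_rate:
            t_end[node] = t
            for _ in range(2):
                parent.append(node)
                t_start.append(t)
                t_end.append(None)
            alive[k] = len(parent) - 2
            alive.append(len(parent) - 1)
        else:
            t_end[node] = t
            del alive[k]
    # place the present uniformly inside the next waiting time
    present = t + rng.exponential(1.0 / (n_tips * total_rate)) * rng.uniform()
    extant = set(alive)
    for node in alive:
        t_end[node] = present

    # prune extinct subtrees, suppress unifurcations, relabel
    n = len(parent)
    keep = [False] * n
    for node in extant:
        j = node
        while j >= 0 and not keep[j]:
            keep[j] = True
            j = parent[j]

    children = [[] for _ in range(n)]
    for i in range(1, n):
        if keep[i]:
            children[parent[i]].append(i)

    new_parent: list = []
    new_length: list = []
    new_labels: list = []
    tip_counter = [0]

    def build(node: int, branch_top: float, new_par: int) -> None:
        kids = children[node]
        while len(kids) == 1:  # suppress unifurcation
            node = kids[0]
            kids = children[node]
        idx = len(new_parent)
        new_parent.append(new_par)
        new_length.append(t_end[node] - branch_top)
        if kids:
            new_labels.append(None)
            for c in kids:
                build(c, t_end[node], idx)
        else:
            tip_counter[0] += 1
            new_labels.append(f"sp{tip_counter[0]:03d}")

    root = 0
    root_kids = children[root]
    while len(root_kids) == 1:
        root = root_kids[0]
        root_kids = children[root]
    idx0 = len(new_parent)
    new_parent.append(-1)
    new_length.append(0.0)
    new_labels.append(None)
    for c in root_kids:
        build(c, t_end[root], idx0)
    if tip_counter[0] != n_tips:
        return None
    return Phylogeny(
        parent=np.array(new_parent), edge_length=np.array(new_length), labels=new_labels
    )


# -------------------------------------------------------------------- traits
def _mvn_factor(C: np.ndarray) -> np.ndarray:
    """A matrix L with L L^T = C; Cholesky, falling back to an eigen square
    root for positive-semidefinite inputs (e.g. zero-length branches)."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh(C)
        w = np.clip(w, 0.0, None)
        return Q * np.sqrt(w)


def simulate_bm_traits(
    tree: Phylogeny, z0: float, sigma2: float, seed: int = 0
) -> dict:
    """Brownian-motion tip traits: MVN(z0 * 1, sigma2 * C_raw(tree))."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    C, labels = tree.vcv("raw")
    z = rng.standard_normal(len(labels))
    vals = z0 + math.sqrt(sigma2) * (_mvn_factor(C) @ z)
    return dict(zip(labels, vals))


# --------------------------------------------------------------- environment
def simulate_environment(
    extent: tuple,
    n_rows: int,
    n_cols: int,
    covariates: tuple = DEFAULT_COVARIATES,
    noise_frac: float = 0.1,
    seed: int = 0,
) -> dict:
    """Smooth latitudinal-gradient covariate rasters with seeded noise.

    ``extent`` is ``(lon_min, lon_max, lat_min, lat_max)``; the two implied
    cell sizes must agree because the ASCII-grid raster model has square
    cells.  Each covariate is an affine function of latitude plus
    ``noise_frac`` times the gradient's range of smoothed Gaussian noise;
    with ``noise_frac=0`` values are strictly monotone in latitude.
    """
    from scipy.ndimage import gaussian_filter

    if not covariates:
        raise ValueError("empty covariate list")
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid must have at least one row and column")
    lon_min, lon_max, lat_min, lat_max = extent
    cell_x = (lon_max - lon_min) / n_cols
    cell_y = (lat_max - lat_min) / n_rows
    if cell_x <= 0 or abs(cell_x - cell_y) > 1e-9 * max(cell_x, 1.0):
        raise ValueError("extent and shape imply non-square cells")
    rng = np.random.default_rng(seed)
    # latitude of each row centre, row 0 = north
    lat = lat_max - (np.arange(n_rows) + 0.5) * cell_y
    lat_mid = 0.5 * (lat_min + lat_max)
    grids = {}
    for name in covariates:
        base, slope = _COVARIATE_GRADIENTS.get(name, (0.0, 1.0))
        values = np.tile((base + slope * (lat - lat_mid))[:, None], (1, n_cols))
        if noise_frac > 0:
            field_ = gaussian_filter(
                rng.standard_normal((n_rows, n_cols)), sigma=2.0, mode="nearest"
            )
            sd = field_.std()
            if sd > 0:
                field_ = field_ / sd
            amp = noise_frac * abs(slope) * (lat_max - lat_min)
            values = values + amp * field_
        grids[name] = RasterGrid(
            values=values, x_ll=lon_min, y_ll=lat_min, cell_size=cell_x
        )
    return grids


def simulate_sdm_surfaces(
    env: dict,
    n_bat_species: int,
    pop_lognormal_params: tuple = (10.0, 1.0),
    response_width: float = 1.0,
    seed: int = 0,
) -> tuple:
    """Fabricate per-bat clog-log-style suitability surfaces in [0, 1].

    Each species responds to the environmental layers through a Gaussian
    niche: suitability = exp(-0.5 * sum_k ((x_k - opt_k) / w_k)^2) with the
    optimum drawn uniformly over each covariate's observed range and the
    width ``w_k = response_width * sd_k``.  As ``response_width`` grows the
    surface flattens toward 1 everywhere.  Population totals are lognormal.
    """
    if n_bat_species < 1:
        raise ValueError("n_bat_species must be >= 1")
    if not env:
        raise ValueError("need at least one environmental layer")
    rng = np.random.default_rng(seed)
    layers = list(env.items())
    ref = layers[0][1]
    for _, g in layers[1:]:
        if not ref.same_grid(g):
            raise ValueError("environmental grids must share one geotransform")
    surfaces = {}
    populations = {}
    mu, sg = pop_lognormal_params
    for b in range(n_bat_species):
        name = f"bat{b + 1:03d}"
        logit = np.zeros_like(ref.values)
        for _, grid in layers:
            vals = grid.values
            vmin, vmax = np.nanmin(vals), np.nanmax(vals)
            opt = rng.uniform(vmin, vmax)
            width = response_width * max(np.nanstd(vals), 1e-12)
            if not np.isfinite(width) or width <= 0:
                continue
            logit = logit + 0.5 * ((vals - opt) / width) ** 2
        surfaces[name] = RasterGrid(
            values=np.exp(-logit),
            x_ll=ref.x_ll,
            y_ll=ref.y_ll,
            cell_size=ref.cell_size,
            nodata=ref.nodata,
        )
        populations[name] = float(rng.lognormal(mu, sg))
    return surfaces, populations


# ------------------------------------------------------------- observations
def simulate_moth_dataset(
    tree: Phylogeny,
    truth: GenerativeTruth,
    env: dict,
    pressure: RasterGrid,
    n_obs_per_species: int = 10,
    scale_bar_prob: float = 0.5,
    antenna_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the photo-measurement table.

    True hindwing length for observation i of species s at location x is

        HW = z0 + u_phy(s) + u_sp(s) + sum_k beta_k * cov_k(x) + eps

    with ``u_phy ~ N(0, sigma2_phy * C*)`` on the unit-height tree
    correlation, ``u_sp ~ N(0, sigma2_sp)``, ``eps ~ N(0, sigma2_e)``, and
    covariates (including predation pressure extracted from ``pressure``)
    centred and scaled across the table before the betas apply.  Forewing is
    a fixed per-species allometric multiple of hindwing; the antenna is the
    species antenna mean times ``1 + N(0, antenna_cv)``.  Rows without a
    scale bar (Bernoulli ``scale_bar_prob``) report all three lengths
    multiplied by one lognormal(0, 0.5) per-photo pixel factor; rows with a
    scale bar report millimetres.  Hidden ``true_*`` columns retain ground
    truth for testing.
    """
    from .pglmm import center_scale

    if not (0.0 <= scale_bar_prob <= 1.0):
        raise ValueError("scale_bar_prob must be in [0, 1]")
    if antenna_cv < 0:
        raise ValueError("antenna_cv must be >= 0")
    for name, grid in env.items():
        if not grid.same_grid(pressure):
            raise ValueError(
                f"environment grid {name!r} does not match the pressure grid"
            )
    rng = np.random.default_rng(seed)
    species = tree.tip_labels()
    n_sp = len(species)
    n = n_sp * n_obs_per_species

    Cstar, _ = tree.vcv("unit_height")
    u_phy = math.sqrt(truth.sigma2_phy) * (
        _mvn_factor(Cstar) @ rng.standard_normal(n_sp)
    )
    u_sp = math.sqrt(truth.sigma2_sp) * rng.standard_normal(n_sp)

    # species-level allometry and antenna calibration truth
    fw_mult = rng.uniform(1.8, 2.4, n_sp)
    antenna_mean = rng.uniform(25.0, 40.0, n_sp)

    lon_min, lon_max, lat_min, lat_max = pressure.extent
    lon = rng.uniform(lon_min, lon_max, n)
    lat = rng.uniform(lat_min, lat_max, n)
    points = list(zip(lon, lat))

    cov_values = {"bat_abundance": extract_at_points(pressure, points)}
    for name, grid in env.items():
        cov_values[name] = extract_at_points(grid, points)
    missing = set(truth.beta) - set(cov_values)
    if missing:
        raise KeyError(f"truth.beta references unknown covariates: {sorted(missing)}")

    fixed = np.zeros(n)
    for name, b in truth.beta.items():
        if b != 0.0:
            fixed = fixed + b * center_scale(cov_values[name])

    sp_idx = np.repeat(np.arange(n_sp), n_obs_per_species)
    eps = math.sqrt(truth.sigma2_e) * rng.standard_normal(n)
    true_hw = truth.z0 + u_phy[sp_idx] + u_sp[sp_idx] + fixed + eps
    if np.any(true_hw <= 0):
        raise ValueError(
            "generated nonpositive hindwing lengths; reduce variances or raise z0"
        )
    true_fw = fw_mult[sp_idx] * true_hw
    rel = 1.0 + antenna_cv * rng.standard_normal(n)
    while np.any(rel <= 0):  # redraw the rare nonpositive antenna factors
        bad = rel <= 0
        rel[bad] = 1.0 + antenna_cv * rng.standard_normal(int(bad.sum()))
    true_antenna = antenna_mean[sp_idx] * rel

    has_scale = rng.random(n) < scale_bar_prob
    pixel = np.exp(rng.normal(0.0, 0.5, n))  # one factor per photo
    factor = np.where(has_scale, 1.0, pixel)

    obs = pd.DataFrame(
        {
            "species": np.repeat(species, n_obs_per_species),
            "lon": lon,
            "lat": lat,
            "fw": true_fw * factor,
            "hw": true_hw * factor,
            "antenna": true_antenna * factor,
            "has_scale": has_scale,
            "sex": "male",
            "true_hw": true_hw,
            "true_fw": true_fw,
            "true_antenna": true_antenna,
        }
    )
    return obs


# ------------------------------------------------------------- composed study
@dataclass
class SyntheticStudy:
    """A complete synthetic study: tree, rasters, populations, observations.

    ``obs`` carries the photo measurements plus one extracted covariate
    column per environmental layer and ``bat_abundance`` from the total
    predation-pressure surface, ready for model fitting.
    """

    tree: Phylogeny
    truth: GenerativeTruth
    env: dict
    surfaces: dict
    populations: dict
    pressure: "object"  # predation.PressureSurfaces
    obs: pd.DataFrame


def make_synthetic_study(
    n_species: int = 40,
    n_obs_per_species: int = 10,
    seed: int = 0,
    truth: GenerativeTruth | None = None,
    extent: tuple = (90.0, 130.0, -10.0, 30.0),
    grid_shape: tuple = (25, 25),
    n_bats: int = 8,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    scale_bar_prob: float = 0.5,
    antenna_cv: float = 0.05,
    noise_frac: float = 0.1,
) -> SyntheticStudy:
    """Simulate every input of the analysis in one call.

    Sub-seeds for the tree, environment, suitability surfaces and the
    observation table are drawn from one generator seeded with ``seed`` so a
    single integer reproduces the whole study.
    """
    from .predation import total_pressure_surface

    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    if truth is None:
        truth = GenerativeTruth(seed=seed)
    tree = simulate_tree(n_species, birth_rate, death_rate, seed=int(sub[0]))
    env = simulate_environment(
        extent, grid_shape[0], grid_shape[1], noise_frac=noise_frac, seed=int(sub[1])
    )
    surfaces, populations = simulate_sdm_surfaces(env, n_bats, seed=int(sub[2]))
    pressure = total_pressure_surface(surfaces, populations)
    obs = simulate_moth_dataset(
        tree,
        truth,
        env,
        pressure.abundance,
        n_obs_per_species=n_obs_per_species,
        scale_bar_prob=scale_bar_prob,
        antenna_cv=antenna_cv,
        seed=int(sub[3]),
    )
    points = list(zip(obs["lon"], obs["lat"]))
    obs["bat_abundance"] = extract_at_points(pressure.abundance, points)
    for name, grid in env.items():
        obs[name] = extract_at_points(grid, points)
    return SyntheticStudy(
        tree=tree,
        truth=truth,
        env=env,
        surfaces=surfaces,
        populations=populations,
        pressure=pressure,
        obs=obs,
    )
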
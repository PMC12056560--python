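"""Antenna-based scale calibration of wing measurements.

Community-science moth photos usually lack a scale bar, so wing lengths come
out in arbitrary pixel units.  The male antenna serves as an internal scale
bar: within a photo all lengths share one unknown pixel factor, so dividing a
wing length by (antenna length / species mean antenna length) cancels the
factor and returns millimetres.  The species antenna means must come from
calibrated (scale-bar) photos.  Validation statistics: a per-species Pearson
screen that the chosen proxy is body-size agnostic, and per-species Wilcoxon
rank-sum tests that adjusted lengths from un-scaled photos match calibrated
lengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesAntennaMeans",
    "MissingCalibrationError",
    "species_mean_antenna",
    "adjusted_length",
    "add_adjusted_columns",
    "proxy_screen",
    "rank_sum_test",
    "validate_adjustment",
]


class MissingCalibrationError(ValueError):
    """A species has no scale-bar photo with a measured antenna."""


@dataclass
class SpeciesAntennaMeans:
    """Per-species mean antenna length (mm) from calibrated photos."""

    means: dict
    n_calibrated: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [s for s, m in self.means.items() if not (m > 0)]
        if bad:
            raise ValueError(f"nonpositive antenna means for: {bad}")


def _male_mask(obs: pd.DataFrame, males_only: bool) -> pd.Series:
    if males_only and "sex" in obs.columns:
        return obs["sex"].astype(str).str.lower() == "male"
    return pd.Series(True, index=obs.index)


def species_mean_antenna(
    obs: pd.DataFrame, males_only: bool = True
) -> SpeciesAntennaMeans:
    """Arithmetic mean antenna length per species over scaled male rows.

    Un-scaled rows are in arbitrary pixel units and never enter the mean.
    A species present in the table but lacking any usable calibrated antenna
    raises :class:`MissingCalibrationError` naming it.
    """
    usable = obs[
        _male_mask(obs, males_only)
        & obs["has_scale"].astype(bool)
        & obs["antenna"].notna()
    ]
    means = usable.groupby("species")["antenna"].mean().to_dict()
    counts = usable.groupby("species")["antenna"].size().to_dict()
    missing = sorted(set(obs["species"]) - set(means))
    if missing:
        raise MissingCalibrationError(
            f"no calibrated antenna measurements for species: {missing}"
        )
    return SpeciesAntennaMeans(means=means, n_calibrated=counts)


def adjusted_length(length, antenna, mean_antenna):
    """Wing length divided by (antenna / species mean antenna).

    ``length`` and ``antenna`` share the photo's unit (mm or pixels);
    ``mean_antenna`` is in mm, so the result is in mm.  Accepts scalars or
    arrays; every input must be strictly positive.
    """
    length = np.asarray(length, dtype=float)
    antenna = np.asarray(antenna, dtype=float)
    mean_antenna = np.asarray(mean_antenna, dtype=float)
    if np.any(length <= 0) or np.any(antenna <= 0) or np.any(mean_antenna <= 0):
        raise ValueError("lengths, antennae and means must all be > 0")
    out = length / (antenna / mean_antenna)
    return float(out) if out.ndim == 0 else out


def add_adjusted_columns(
    obs: pd.DataFrame, means: SpeciesAntennaMeans
) -> pd.DataFrame:
    """Return a copy with ``adj_hw`` and ``adj_fw`` columns for every row.

    The adjustment applies to scaled and un-scaled photos alike (the analysis
    uses the adjusted metric throughout so species are not biased by their
    mix of photo sources).
    """
    out = obs.copy()
    mean_vec = out["species"].map(means.means)
    if mean_vec.isna().any():
        missing = sorted(out.loc[mean_vec.isna(), "species"].unique())
        raise MissingCalibrationError(f"no antenna means for species: {missing}")
    out["adj_hw"] = adjusted_length(out["hw"], out["antenna"], mean_vec)
    out["adj_fw"] = adjusted_length(out["fw"], out["antenna"], mean_vec)
    return out


def proxy_screen(
    obs: pd.DataFrame,
    proxy: str = "antenna",
    min_rows: int = 3,
    males_only: bool = True,
) -> pd.DataFrame:
    """Pearson correlation between a proxy column and forewing length.

    Only scale-bar rows (real mm) enter.  One row per species plus a pooled
    row; species with fewer than ``min_rows`` usable rows are dropped with a
    logged warning.  A constant proxy yields a missing (NaN) correlation.
    """
    usable = obs[
        _male_mask(obs, males_only)
        & obs["has_scale"].astype(bool)
        & obs[proxy].notna()
        & obs["fw"].notna()
    ]
    rows = []

    def corr(x, y):
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            return math.nan
        return float(stats.pearsonr(x, y).statistic)

    for sp, grp in usable.groupby("species"):
        if len(grp) < min_rows:
            logger.warning(
                "proxy_screen: species %s dropped (%d < %d usable rows)",
                sp,
                len(grp),
                min_rows,
            )
            continue
        rows.append(
            {
                "species": sp,
                "n": len(grp),
                "r": corr(grp[proxy].to_numpy(), grp["fw"].to_numpy()),
            }
        )
    rows.append(
        {
            "species": "__pooled__",
            "n": len(usable),
            "r": corr(usable[proxy].to_numpy(), usable["fw"].to_numpy()),
        }
    )
    return pd.DataFrame(rows, columns=["species", "n", "r"])


# ------------------------------------------------------------------ Wilcoxon
def rank_sum_test(x, y, method: str = "auto") -> tuple:
    """Two-sided two-sample Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the sum of midranks of ``x`` in the pooled
    sample.  ``method="exact"`` enumerates all C(n1+n2, n1) assignments and
    counts ``|W - E[W]| >= |W_obs - E[W]|`` (so identical samples give p = 1);
    ``method="normal"`` uses the normal approximation with tie correction and
    a 0.5 continuity correction.  ``"auto"`` picks exact when
    ``max(n1, n2) <= 8``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    W = float(ranks[:n1].sum())
    N = n1 + n2
    mu = n1 * (N + 1) / 2.0
    if method == "auto":
        method = "exact" if max(n1, n2) <= 8 else "normal"
    if method == "exact":
        obs_dev = abs(W - mu)
        count = 0
        total = 0
        for idx in combinations(range(N), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= obs_dev - 1e-9:
                count += 1
        return W, count / total
    if method != "normal":
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return W, 1.0
    z = (W - mu - 0.5 * np.sign(W - mu)) / math.sqrt(var)
    return W, min(1.0, 2.0 * stats.norm.sf(abs(z)))


def validate_adjustment(
    obs: pd.DataFrame,
    means: SpeciesAntennaMeans,
    males_only: bool = True,
    method: str = "auto",
) -> tuple:
    """Per-species Wilcoxon rank-sum of adjusted (un-scaled) vs calibrated HW.

    For each species with at least one scaled and one un-scaled row, compares
    the adjusted hindwing lengths derived from un-scaled photos against the
    raw mm hindwing lengths of scale-bar photos.  Returns
    ``(table, skipped)`` where ``table`` has columns
    ``species, W, p, n_adjusted, n_calibrated`` and ``skipped`` lists species
    failing the precondition.
    """
    usable = obs[_male_mask(obs, males_only)]
    rows = []
    skipped = []
    for sp, grp in usable.groupby("species"):
        scaled = grp[grp["has_scale"].astype(bool)]
        unscaled = grp[~grp["has_scale"].astype(bool)]
        if scaled.empty or unscaled.empty:
            skipped.append(sp)
            continue
        adj = adjusted_length(
            unscaled["hw"], unscaled["antenna"], means.means[sp]
        )
        W, p = rank_sum_test(np.atleast_1d(adj), scaled["hw"].to_numpy(), method)
        rows.append(
            {
                "species": sp,
                "W": W,
                "p": p,
                "n_adjusted": len(unscaled),
                "n_calibrated": len(scaled),
            }
        )
    if skipped:
        logger.warning("validate_adjustment: skipped species %s", skipped)
    table = pd.DataFrame(rows, columns=["species", "W", "p", "n_adjusted", "n_calibrated"])
    return table, skipped
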
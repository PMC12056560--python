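import numpy as np
import pandas as pd
import pytest

from mothtails.predation import (
    ExtractionError,
    RasterGrid,
    abundance_surface,
    extract_at_points,
    filter_bat_taxa,
    richness_surface,
    total_pressure_surface,
)


def grid(values, x_ll=0.0, y_ll=0.0, cell=1.0):
    return RasterGrid(values=np.asarray(values, float), x_ll=x_ll, y_ll=y_ll, cell_size=cell)


# ---------------------------------------------------------------- bat filter
def _taxa(rows):
    return pd.DataFrame(
        rows,
        columns=["family", "genus", "species", "aerial_insectivore", "mean_mass_g", "overlaps_moths"],
    )


def test_filter_keeps_fully_qualifying_family():
    t = _taxa(
        [
            ("F", "G", "s1", True, 12.0, True),
            ("F", "G", "s2", True, 12.0, True),
        ]
    )
    species, audit = filter_bat_taxa(t)
    assert species == ["s1", "s2"]
    assert audit["n_families_kept"] == 1 and audit["n_genera_kept"] == 1


def test_light_species_excluded_at_species_pass():
    t = _taxa(
        [
            ("F", "G", "light", True, 9.0, True),
            ("F", "G", "heavy1", True, 15.0, True),
            ("F", "G", "heavy2", True, 15.0, True),
        ]
    )
    species, _ = filter_bat_taxa(t)
    # genus passes (2/3 qualify >= 0.5) but the 9 g species fails pass 3
    assert species == ["heavy1", "heavy2"]


def brute_force_filter(t, mass=10.0, frac=0.5):
    """Independent literal application of the three nested rules."""
    out = []
    for fam in t["family"].unique():
        fam_rows = t[t.family == fam]
        genera = fam_rows["genus"].unique()
        n_ai_genera = 0
        for g in genera:
            sp = fam_rows[fam_rows.genus == g]
            if sp["aerial_insectivore"].mean() >= frac:
                n_ai_genera += 1
        if n_ai_genera / len(genera) < frac:
            continue
        for g in genera:
            sp = fam_rows[fam_rows.genus == g]
            ok = sp["aerial_insectivore"] & (sp["mean_mass_g"] >= mass) & sp["overlaps_moths"]
            if ok.mean() >= frac:
                out.extend(sp.loc[ok, "species"].tolist())
    return sorted(out)


def test_filter_matches_brute_force_on_toy_table():
    t = _taxa(
        [
            ("F1", "G1", "a1", True, 12, True),
            ("F1", "G1", "a2", False, 12, True),
            ("F1", "G2", "b1", True, 8, True),
            ("F1", "G2", "b2", True, 20, True),
            ("F1", "G2", "b3", False, 20, False),
            ("F2", "G3", "c1", False, 15, True),
            ("F2", "G3", "c2", False, 15, True),
            ("F2", "G4", "d1", True, 15, False),
            ("F2", "G4", "d2", True, 15, True),
            ("F2", "G4", "d3", True, 5, True),
        ]
    )
    species, _ = filter_bat_taxa(t)
    assert species == brute_force_filter(t)


# ------------------------------------------------------------------ surfaces
def test_richness_of_two_uniform_surfaces():
    s = {"a": grid(np.full((2, 2), 0.5)), "b": grid(np.full((2, 2), 0.5))}
    out = richness_surface(s)
    assert np.allclose(out.values, 1.0)


def test_richness_single_species_identity():
    g = grid(np.random.default_rng(0).uniform(0, 1, (3, 4)))
    out = richness_surface({"only": g})
    assert np.allclose(out.values, g.values)


def test_richness_equals_cellwise_sum_oracle():
    rng = np.random.default_rng(1)
    s = {f"b{i}": grid(rng.uniform(0, 1, (4, 5))) for i in range(3)}
    out = richness_surface(s)
    oracle = sum(g.values for g in s.values())
    assert np.allclose(out.values, oracle)


def test_richness_nodata_propagates_only_when_all_missing():
    a = grid([[np.nan, 0.2], [0.3, np.nan]])
    b = grid([[np.nan, np.nan], [0.1, 0.4]])
    out = richness_surface({"a": a, "b": b})
    assert np.isnan(out.values[0, 0])
    assert out.values[0, 1] == pytest.approx(0.2)
    assert out.values[1, 0] == pytest.approx(0.4)


def test_richness_rejects_geotransform_mismatch():
    with pytest.raises(ValueError, match="geotransform"):
        richness_surface({"a": grid(np.ones((2, 2))), "b": grid(np.ones((2, 2)), x_ll=5)})


def test_abundance_uniform_allocation():
    out = abundance_surface(grid(np.full((2, 2), 0.7)), 100.0)
    assert np.allclose(out.values, 25.0)


def test_abundance_proportional_allocation():
    out = abundance_surface(grid([[0.2, 0.8]]), 10.0)
    assert np.allclose(out.values, [[2.0, 8.0]])


def test_abundance_zero_population_gives_zero_surface():
    out = abundance_surface(grid([[0.2, 0.8]]), 0.0)
    assert np.allclose(out.values, 0.0)


def test_abundance_all_zero_suitability_rejected():
    with pytest.raises(ValueError, match="undefined"):
        abundance_surface(grid(np.zeros((2, 2))), 10.0)


def test_total_pressure_conservation_and_order_invariance():
    rng = np.random.default_rng(2)
    surfaces = {f"b{i}": grid(rng.uniform(0, 1, (5, 5))) for i in range(4)}
    pops = {f"b{i}": float(10 ** (i + 1)) for i in range(4)}
    p1 = total_pressure_surface(surfaces, pops)
    assert np.nansum(p1.abundance.values) == pytest.approx(sum(pops.values()), rel=1e-12)
    for name, dens in p1.per_species_density.items():
        assert np.nansum(dens.values) == pytest.approx(pops[name], rel=1e-9)
    rev = dict(reversed(list(surfaces.items())))
    p2 = total_pressure_surface(rev, pops)
    assert np.allclose(p1.abundance.values, p2.abundance.values)
    assert np.allclose(p1.richness.values, p2.richness.values)


def test_total_pressure_missing_population_rejected():
    with pytest.raises(KeyError):
        total_pressure_surface({"a": grid(np.ones((2, 2)))}, {})


def test_density_monotone_in_suitability():
    """Raising one cell's suitability raises its density, lowers the rest."""
    base = np.array([[0.2, 0.4], [0.6, 0.8]])
    d0 = abundance_surface(grid(base), 100.0).values
    bumped = base.copy()
    bumped[0, 0] += 0.1
    d1 = abundance_surface(grid(bumped), 100.0).values
    assert d1[0, 0] > d0[0, 0]
    mask = np.ones_like(base, dtype=bool)
    mask[0, 0] = False
    assert np.all(d1[mask] < d0[mask])


# ---------------------------------------------------------------- extraction
def test_extract_cell_centres():
    g = grid(np.arange(6, dtype=float).reshape(2, 3), x_ll=10.0, y_ll=40.0, cell=2.0)
    # centre of row 0 (north), col 2 is lon 15, lat 43
    assert extract_at_points(g, [(15.0, 43.0)])[0] == pytest.approx(2.0)
    assert extract_at_points(g, [(11.0, 41.0)])[0] == pytest.approx(3.0)


def test_extract_shared_edge_goes_east_south():
    g = grid(np.arange(4, dtype=float).reshape(2, 2), x_ll=0.0, y_ll=0.0, cell=1.0)
    # vertical edge lon=1 -> east cell (col 1); horizontal edge lat=1 -> south row (row 1)
    assert extract_at_points(g, [(1.0, 1.5)])[0] == pytest.approx(1.0)
    assert extract_at_points(g, [(0.5, 1.0)])[0] == pytest.approx(2.0)
    assert extract_at_points(g, [(1.0, 1.0)])[0] == pytest.approx(3.0)


def test_extract_matches_nearest_centre_oracle():
    rng = np.random.default_rng(5)
    g = grid(rng.normal(size=(7, 9)), x_ll=-3.0, y_ll=11.0, cell=0.5)
    lon = rng.uniform(*g.extent[:2], 100)
    lat = rng.uniform(*g.extent[2:], 100)
    got = extract_at_points(g, list(zip(lon, lat)))
    centres_x = g.x_ll + (np.arange(g.n_cols) + 0.5) * g.cell_size
    centres_y = g.y_top - (np.arange(g.n_rows) + 0.5) * g.cell_size
    for k in range(100):
        r = np.argmin(np.abs(centres_y - lat[k]))
        c = np.argmin(np.abs(centres_x - lon[k]))
        assert got[k] == pytest.approx(g.values[r, c])


def test_extract_nodata_returned_as_missing():
    g = grid([[np.nan, 1.0]])
    vals = extract_at_points(g, [(0.5, 0.5), (1.5, 0.5)])
    assert np.isnan(vals[0]) and vals[1] == pytest.approx(1.0)


def test_extract_out_of_extent_errors_per_point():
    g = grid(np.ones((2, 2)))
    with pytest.raises(ExtractionError) as exc:
        extract_at_points(g, [(0.5, 0.5), (5.0, 0.5), (0.5, -1.0)])
    assert [r["index"] for r in exc.value.records] == [1, 2]
    vals, records = extract_at_points(g, [(0.5, 0.5), (5.0, 0.5)], errors="return")
    assert vals[0] == pytest.approx(1.0) and np.isnan(vals[1])
    assert len(records) == 1
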
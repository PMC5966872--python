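"""Synthetic organ generator: invariants, calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from zonemap.simulate import (
    ConfigError,
    GeneProfile,
    LogitNormal,
    default_profiles,
    make_fixture,
    population_ks_distance,
    profiles_from_config,
    sample_organ_geometry,
)

from conftest import FIXTURE_SEED


def _profile(gene="x", rate=2.0, **over):
    base = dict(
        laminar_median=0.5, laminar_width=0.15,
        radial_median=0.5, radial_width=0.24,
        z_median=0.5, z_width=0.30,
        mean_cells_per_section=rate,
    )
    base.update(over)
    return GeneProfile(gene=gene, **base)


class TestLogitNormal:
    @pytest.mark.parametrize("median,iqr", [(0.5, 0.2), (0.714, 0.12), (0.3, 0.4)])
    def test_median_iqr_round_trip(self, median, iqr):
        law = LogitNormal.from_median_iqr(median, iqr)
        assert law.median == pytest.approx(median, abs=1e-9)
        assert law.iqr == pytest.approx(iqr, abs=1e-9)

    def test_zero_width_is_a_spike(self):
        law = LogitNormal.from_median_iqr(0.5, 0.0)
        rng = np.random.default_rng(0)
        assert np.all(law.rvs(100, rng) == 0.5)

    def test_cdf_bounds(self):
        law = LogitNormal.from_median_iqr(0.6, 0.2)
        assert law.cdf([-1.0, 0.0])[1] == 0.0
        assert law.cdf([1.0, 2.0])[0] == 1.0
        assert law.cdf(0.6) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("median,iqr", [(1.2, 0.1), (0.5, 1.0), (0.0, 0.1)])
    def test_invalid_parameters_rejected(self, median, iqr):
        with pytest.raises((ConfigError, ValueError)):
            LogitNormal.from_median_iqr(median, iqr)


class TestProfiles:
    def test_laminar_medians_span_printed_range(self):
        profiles = default_profiles()
        medians = [profiles[g].laminar_median for g in ("g1", "n1", "q1", "u1", "j1", "t1")]
        assert min(medians) == 0.603
        assert max(medians) == 0.714

    def test_within_zone_pair_has_identical_laws(self):
        p = default_profiles()
        for coord in ("laminar", "radial", "z"):
            d = population_ks_distance(p["n1"].law(coord), p["q1"].law(coord))
            if coord == "radial":
                # radial medians differ by half a percent; far below resolvable
                assert d < 0.02
            else:
                assert d == 0.0

    def test_separated_pairs_clear_the_population_distance_floor(self):
        """Every pair meant to be distinguishable has population D >= 0.15
        in its separating coordinate (large-sample calibration contract)."""
        p = default_profiles()
        separating = [
            ("g1", "n1", "laminar"), ("g1", "j1", "laminar"),
            ("n1", "j1", "laminar"), ("q1", "t1", "laminar"),
            ("u1", "j1", "laminar"), ("u1", "t1", "laminar"),
            ("j1", "t1", "radial"), ("u1", "q1", "radial"),
            ("c1", "trpc2", "radial"),
            ("u1", "n1", "z"), ("u1", "q1", "z"), ("u1", "j1", "z"),
            ("omp", "j1", "laminar"), ("omp", "g1", "laminar"),
        ]
        for a, b, coord in separating:
            d = population_ks_distance(p[a].law(coord), p[b].law(coord))
            assert d >= 0.15, (a, b, coord, d)

    def test_config_round_trip(self):
        profiles = default_profiles()
        config = {"genes": {
            g: {k: getattr(p, k) for k in (
                "laminar_median", "laminar_width", "radial_median", "radial_width",
                "z_median", "z_width", "mean_cells_per_section")}
            for g, p in profiles.items()
        }}
        assert profiles_from_config(config) == profiles

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigError):
            profiles_from_config({"genes": {"x": {"laminar_median": 0.5}}})
        with pytest.raises(ConfigError):
            profiles_from_config({})
        with pytest.raises(ConfigError):
            _profile(laminar_median=1.5)


class TestGeometry:
    def test_section_counts_and_positive_thickness(self):
        rng = np.random.default_rng(5)
        for i in range(20):
            geom = sample_organ_geometry(f"o{i}", rng)
            assert 40 <= geom.n_sections <= 60
            assert np.all(geom.layer_thickness_um > 0)
            assert geom.lamella_length_um[0] == 0.0
            # lamella grows in over the first sections, then stays positive
            assert np.all(np.diff(geom.lamella_length_um[:3]) >= 0)
            assert np.all(geom.lamella_length_um[5:] > 0)


class TestFixture:
    def test_records_satisfy_type_invariants(self, raw_table):
        t = raw_table
        assert (t.soma_height_um >= 0).all()
        assert (t.soma_height_um <= t.layer_thickness_um).all()
        assert (t.radial_distance_um >= 0).all()
        assert (t.radial_distance_um <= t.lamella_length_um).all()
        assert (t.section_index >= 0).all()
        assert (t.section_index < t.total_sections).all()
        assert set(t.side) <= {"left", "right"}

    def test_zero_rate_gene_yields_no_records(self):
        out = make_fixture({"x": _profile(rate=0.0)}, seed=0)
        assert out.empty

    def test_zero_width_profile_is_degenerate_spike(self):
        out = make_fixture({"x": _profile(laminar_width=0.0)}, n_organs=1, seed=0)
        h_rel = out.soma_height_um / out.layer_thickness_um
        assert np.allclose(h_rel, 0.5, atol=1e-12)

    def test_pooled_counts_match_poisson_law(self, raw_table):
        """Per-gene totals within 3 SD of the Poisson expectation given the
        realized section counts (rate * sections per organ, summed)."""
        profiles = default_profiles()
        for gene, grp in raw_table.groupby("gene"):
            sections = grp.groupby("organ_id")["total_sections"].first().sum()
            expected = profiles[gene].mean_cells_per_section * sections
            assert abs(len(grp) - expected) <= 3 * np.sqrt(expected), gene

    def test_same_seed_reproduces_different_seed_differs(self):
        profiles = {"x": _profile()}
        a = make_fixture(profiles, seed=42)
        b = make_fixture(profiles, seed=42)
        c = make_fixture(profiles, seed=43)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_top_sections_exercise_radial_exclusion(self, raw_table):
        """Every fixture contains cells on short-lamella top sections, so
        downstream radial exclusion always has work to do."""
        short = raw_table["lamella_length_um"] < 50
        assert short.any()
        assert (raw_table.loc[short, "section_index"] <= 1).all()

    def test_invalid_fixture_config_rejected(self):
        with pytest.raises(ConfigError):
            make_fixture(n_organs=0)


class TestParameterRecovery:
    def test_medians_and_iqrs_recovered_at_high_density(self):
        """With ~5000 cells/gene the empirical median and IQR of every
        re-normalized coordinate sit within 0.03 of the generating values,
        i.e. the generator has no systematic bias at that scale."""
        from zonemap import normalize_table, quartiles
        from zonemap.coordinates import coordinate_samples

        profiles = {g: _profile(g, rate=20.0, **over) for g, over in {
            "a": dict(laminar_median=0.714, laminar_width=0.12),
            "b": dict(z_median=0.30),
            "c": dict(radial_median=0.44),
        }.items()}
        norm = normalize_table(make_fixture(profiles, seed=FIXTURE_SEED))
        for gene, profile in profiles.items():
            for coord in ("laminar", "radial", "z"):
                sample = coordinate_samples(norm, gene, coord)
                assert sample.size >= 500
                q1, med, q3 = quartiles(sample)
                assert med == pytest.approx(
                    getattr(profile, f"{coord}_median"), abs=0.03), (gene, coord)
                assert q3 - q1 == pytest.approx(
                    getattr(profile, f"{coord}_width"), abs=0.03), (gene, coord)

    def test_default_fixture_medians_recovered(self, normalized):
        """At the default fixture scale (~500 cells per sparse gene) the
        pooled medians still land within 0.03 of the generating profiles."""
        from zonemap import quartiles
        from zonemap.coordinates import coordinate_samples

        profiles = default_profiles()
        for gene in ("g1", "n1", "q1", "u1", "j1", "t1"):
            for coord in ("laminar", "radial", "z"):
                sample = coordinate_samples(normalized, gene, coord)
                _, med, _ = quartiles(sample)
                expected = getattr(profiles[gene], f"{coord}_median")
                assert med == pytest.approx(expected, abs=0.03), (gene, coord)
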
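import numpy as np
import pytest

from permeakit import (
    PermeabilityModel,
    Populations,
    Profile1D,
    SpeciesInput,
    ThermoConditions,
    WPmfSpec,
    bwap_effective_diffusivity,
    bwap_potential,
    effective_bwap,
    effective_ph_partitioning,
    isd_permeability,
    make_w_pmf,
    microstate_fractions,
    ph_scan,
    proxy_sensitivity_scan,
    shift_profile,
)
from permeakit.profiles import ProfileError
from permeakit import tetracycline as tcx


def const_d(z, value):
    return Profile1D(z=z, values=np.full(z.size, float(value)), kind="diffusivity")


@pytest.fixture
def tc_pops(tc310):
    return microstate_fractions(tcx.tc_model(), tc310)


class TestIsdPermeability:
    def test_flat_profile_closed_form(self, tc310):
        # w=0, D=40 A^2/ns over 80 A -> P = 0.5 A/ns = 5 cm/s
        z = np.linspace(-40, 40, 401)
        w = Profile1D(z=z, values=np.zeros(z.size), kind="pmf")
        assert isd_permeability(w, const_d(z, 40.0), tc310) == pytest.approx(5.0)

    @pytest.mark.parametrize("height", [2.0, 5.0, 10.0])
    def test_square_barrier_closed_form(self, tc310, height):
        # fine grid so the two ramp cells at the edges are negligible
        L, half_width, D0 = 80.0, 5.0, 30.0
        z = np.linspace(-L / 2, L / 2, 40001)
        w = np.where(np.abs(z) <= half_width, height, 0.0)
        p = isd_permeability(
            Profile1D(z=z, values=w, kind="pmf"), const_d(z, D0), tc310
        )
        resistance = (
            (L - 2 * half_width) / D0
            + 2 * half_width * np.exp(tc310.beta * height) / D0
        )
        assert p == pytest.approx(10.0 / resistance, rel=1e-3)

    def test_trapezoid_matches_refined_quadrature(self, tc310):
        # same analytic W-PMF regenerated at 10x finer spacing: a 0.05 A
        # trapezoid must already be converged to < 0.1%
        base = make_w_pmf(WPmfSpec(grid_spacing=0.05))
        p = isd_permeability(base, const_d(base.z, 30.0), tc310)
        fine_pmf = make_w_pmf(WPmfSpec(grid_spacing=0.005))
        p_fine = isd_permeability(fine_pmf, const_d(fine_pmf.z, 30.0), tc310)
        assert p == pytest.approx(p_fine, rel=1e-3)

    def test_barrier_monotonicity(self, tc310):
        ps = []
        for barrier in (2.0, 4.0, 8.0):
            pmf = make_w_pmf(WPmfSpec(barrier=barrier, well_depth=0.0))
            ps.append(isd_permeability(pmf, const_d(pmf.z, 30.0), tc310))
        assert ps[0] > ps[1] > ps[2]

    def test_bounds_outside_grid_rejected(self, w_pmf, tc310):
        with pytest.raises(ProfileError, match="bounds"):
            isd_permeability(w_pmf, const_d(w_pmf.z, 30.0), tc310, bounds=(-99, 99))


class TestPhPartitioning:
    def test_tetracycline_table_values(self, tc_pops, tc310):
        res = effective_ph_partitioning(tcx.tc_species(), tc_pops, tc310)
        assert res.p_eff == pytest.approx(3.17e-5, rel=0.02)
        assert res.dominant_state == "N"

    def test_single_species_unit_fraction(self, tc310):
        pops = Populations(by_macrostate={0: 1.0}, by_microstate={"A": 1.0}, pH=6.0)
        sp = [SpeciesInput(label="A", specific_permeability=1e-3)]
        res = effective_ph_partitioning(sp, pops, tc310)
        assert res.p_eff == pytest.approx(1e-3)

    def test_contributions_sum_to_p_eff(self, tc_pops, tc310):
        res = effective_ph_partitioning(tcx.tc_species(), tc_pops, tc310)
        assert sum(res.contributions.values()) == pytest.approx(res.p_eff, rel=1e-14)
        assert all(c >= 0 for c in res.contributions.values())

    def test_missing_species_for_population_rejected(self, tc_pops, tc310):
        sp = [s for s in tcx.tc_species() if s.label != "-1"]
        with pytest.raises(ValueError, match="-1"):
            effective_ph_partitioning(sp, tc_pops, tc310)

    def test_zeroing_proxies_changes_p_eff_negligibly(self, tc_pops, tc310):
        df = proxy_sensitivity_scan(tcx.tc_species(), tc_pops, tc310, [0.0])
        assert abs(df["relative_change"].iloc[0]) < 1e-3


class TestProxySensitivity:
    def test_thousandfold_proxies_raise_p_eff_by_1_7_percent(self, tc_pops, tc310):
        df = proxy_sensitivity_scan(tcx.tc_species(), tc_pops, tc310, [1e3])
        assert df["relative_change"].iloc[0] == pytest.approx(0.017, abs=0.003)

    def test_hundred_thousandfold_proxies_2_7_fold(self, tc_pops, tc310):
        df = proxy_sensitivity_scan(tcx.tc_species(), tc_pops, tc310, [1e5])
        assert df["p_eff"].iloc[0] / (df["relative_change"].iloc[0] + 1.0) > 0
        fold = df["relative_change"].iloc[0] + 1.0
        assert fold == pytest.approx(2.7, abs=0.15)


class TestBwap:
    def test_single_species_recovers_own_pmf(self, w_pmf, tc310):
        pops = Populations(by_macrostate={0: 1.0}, by_microstate={"A": 1.0}, pH=6.0)
        sp = [SpeciesInput(label="A", pmf=w_pmf, diffusivity=const_d(w_pmf.z, 30.0))]
        wm = bwap_potential(sp, pops, tc310)
        np.testing.assert_allclose(wm.values, w_pmf.values, atol=1e-10)

    def test_identical_pmfs_degenerate_mixture(self, w_pmf, tc310):
        pops = Populations(
            by_macrostate={0: 1.0}, by_microstate={"A": 0.3, "B": 0.7}, pH=6.0
        )
        d = const_d(w_pmf.z, 30.0)
        sp = [
            SpeciesInput(label="A", pmf=w_pmf, diffusivity=d),
            SpeciesInput(label="B", pmf=w_pmf, diffusivity=d),
        ]
        wm = bwap_potential(sp, pops, tc310)
        np.testing.assert_allclose(wm.values, w_pmf.values, atol=1e-10)

    def test_logsumexp_lower_bound(self, tc310, rng):
        z = np.linspace(-30, 30, 301)
        wa = Profile1D(z=z, values=rng.normal(0, 2, z.size).cumsum() * 0.1, kind="pmf")
        wb = Profile1D(z=z, values=rng.normal(0, 2, z.size).cumsum() * 0.1, kind="pmf")
        fa, fb = 0.2, 0.8
        pops = Populations(
            by_macrostate={0: 1.0}, by_microstate={"A": fa, "B": fb}, pH=6.0
        )
        d = const_d(z, 30.0)
        sp = [
            SpeciesInput(label="A", pmf=wa, diffusivity=d),
            SpeciesInput(label="B", pmf=wb, diffusivity=d),
        ]
        wm = bwap_potential(sp, pops, tc310)
        bound = np.minimum(
            wa.values - tc310.kT * np.log(fa), wb.values - tc310.kT * np.log(fb)
        )
        assert (wm.values <= bound + 1e-9).all()

    def test_effective_diffusivity_identical_profiles(self, w_pmf, tc310):
        pops = Populations(
            by_macrostate={0: 1.0}, by_microstate={"A": 0.4, "B": 0.6}, pH=6.0
        )
        d = const_d(w_pmf.z, 25.0)
        sp = [
            SpeciesInput(label="A", pmf=w_pmf, diffusivity=d),
            SpeciesInput(label="B", pmf=w_pmf, diffusivity=d),
        ]
        dm = bwap_effective_diffusivity(sp, pops, tc310)
        np.testing.assert_allclose(dm.values, 25.0, rtol=1e-12)

    def test_effective_diffusivity_dominance_limit(self, tc310):
        # where one state's shifted PMF is far lower, D_m -> that state's D
        z = np.linspace(-30, 30, 301)
        wa = Profile1D(z=z, values=np.zeros(z.size), kind="pmf")
        wb = Profile1D(z=z, values=np.full(z.size, 20.0), kind="pmf")
        pops = Populations(
            by_macrostate={0: 1.0}, by_microstate={"A": 0.5, "B": 0.5}, pH=6.0
        )
        sp = [
            SpeciesInput(label="A", pmf=wa, diffusivity=const_d(z, 10.0)),
            SpeciesInput(label="B", pmf=wb, diffusivity=const_d(z, 99.0)),
        ]
        dm = bwap_effective_diffusivity(sp, pops, tc310)
        np.testing.assert_allclose(dm.values, 10.0, rtol=1e-6)

    def test_single_species_bwap_equals_specific(self, w_pmf, tc310):
        pops = Populations(by_macrostate={0: 1.0}, by_microstate={"A": 1.0}, pH=6.0)
        d = const_d(w_pmf.z, 30.0)
        sp = [SpeciesInput(label="A", pmf=w_pmf, diffusivity=d)]
        res = effective_bwap(sp, pops, tc310)
        assert res.p_eff == pytest.approx(isd_permeability(w_pmf, d, tc310), rel=1e-10)

    def test_tc_like_bwap_matches_ph_partitioning(self, tc_like, tc310):
        model = PermeabilityModel(tc_like, tcx.tc_model(), tc310)
        both = model.fit("both")
        p_part = both["ph-partitioning"].p_eff
        p_bwap = both["bwap"].p_eff
        assert p_bwap == pytest.approx(p_part, rel=0.05)

    def test_dominant_state_agreement_random_fixtures(self, tc310, rng):
        # one state's fraction-shifted PMF >= 5 kcal/mol below the other's:
        # both protocols agree within 2%
        for _ in range(5):
            z = np.linspace(-35, 35, 351)
            base = make_w_pmf(WPmfSpec(barrier=rng.uniform(2, 5), bulk_extent=35))
            high = base.with_values(base.values + rng.uniform(8, 14))
            fa = rng.uniform(0.3, 0.9)
            pops = Populations(
                by_macrostate={0: 1.0},
                by_microstate={"A": fa, "B": 1 - fa},
                pH=6.0,
            )
            d = const_d(base.z, rng.uniform(10, 60))
            sp = [
                SpeciesInput(label="A", pmf=base, diffusivity=d),
                SpeciesInput(label="B", pmf=high, diffusivity=d),
            ]
            p1 = effective_ph_partitioning(sp, pops, tc310).p_eff
            p2 = effective_bwap(sp, pops, tc310).p_eff
            assert p2 == pytest.approx(p1, rel=0.02)


class TestPhScan:
    def test_neutral_tautomer_dominates_ph_1_to_10(self, tc310):
        df = ph_scan(tcx.tc_species(), tcx.tc_model(), tc310, range(1, 11))
        assert (df["dominant"] == "N").all()
        assert (df["dominant_share"] > 0.5).all()

    def test_acid_limit_tracks_cation(self, tc310):
        df = ph_scan(tcx.tc_species(), tcx.tc_model(), tc310, [-4.0])
        # +1 macrostate fraction -> 1, so P_eff -> its proxy value P_Z
        assert df["p_eff"].iloc[0] == pytest.approx(tcx.P_Z, rel=0.05)

    def test_p_eff_continuous_in_ph(self, tc310):
        df = ph_scan(tcx.tc_species(), tcx.tc_model(), tc310, np.linspace(2, 10, 33))
        logp = np.log10(df["p_eff"].to_numpy())
        assert np.abs(np.diff(logp)).max() < 0.6  # no jumps beyond grid slope


class TestAssignmentSensitivity:
    def test_wrong_macroscopic_assignment_shifts_p_eff_orders(self, tc310):
        from permeakit import assignment_variants, microstate_fractions

        p_by_scheme = {}
        for scheme in ("leeson", "naive-forward", "naive-reverse"):
            model = assignment_variants(tcx.tc_pkas(), scheme)
            pops = microstate_fractions(model, tc310)
            p_by_scheme[scheme] = effective_ph_partitioning(
                tcx.tc_species(), pops, tc310
            ).p_eff
        drop = np.log10(p_by_scheme["leeson"] / p_by_scheme["naive-reverse"])
        assert 2.5 < drop < 3.5
        assert p_by_scheme["naive-forward"] < p_by_scheme["leeson"]
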
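"""Community simulator: determinism, count statistics, treatment contrast."""

import numpy as np
import pytest
from scipy import stats as sps

from plankspectra import flowcytometry as fcm
from plankspectra import imaging, synthetic


def _single_pop(conc=10.0, noise=0.0, mult=1.0, domain="imaging"):
    return synthetic.PopulationSpec(
        name="p", log_esd_mean=2.5, log_esd_sd=0.05,
        abundance_knots=((1.0, conc),), treatment_multiplier=mult,
        instrument_domain=domain,
    )


def _meso(mid="M1", treatment="control", noise=0.0):
    return synthetic.MesocosmSpec(mesocosm_id=mid, treatment=treatment, replicate_noise_sd=noise)


class TestValidation:
    def test_empty_population_list_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_community([], [_meso()], [1], seed=0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            synthetic.PopulationSpec(
                name="x", log_esd_mean=1.0, log_esd_sd=0.1, abundance_knots=((1.0, -5.0),)
            )

    def test_unsorted_days_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_community([_single_pop()], [_meso()], [57, 1], seed=0)

    def test_bad_treatment_label_rejected(self):
        with pytest.raises(ValueError):
            synthetic.MesocosmSpec(mesocosm_id="M1", treatment="acid")


class TestSimulateCommunity:
    def test_zero_abundance_gives_zero_particles(self):
        pop = synthetic.PopulationSpec(
            name="ghost", log_esd_mean=1.0, log_esd_sd=0.1,
            abundance_knots=((1.0, 0.0), (57.0, 0.0)),
        )
        table = synthetic.simulate_community([pop], [_meso()], [1, 57], seed=3)
        assert len(table.particles) == 0

    def test_bitwise_determinism(self):
        pops = synthetic.default_populations()
        mesos = synthetic.default_mesocosms()
        a = synthetic.simulate_community(pops, mesos, [1], seed=9)
        b = synthetic.simulate_community(pops, mesos, [1], seed=9)
        assert a.particles.equals(b.particles)
        assert a.volumes.equals(b.volumes)

    def test_counts_in_central_poisson_interval(self):
        """Counts at lambda = 10 # L^-1 x 15.4 L stay in the central 99% band."""
        lam = 10.0 * imaging.effective_subsample_volume_l(imaging.SamplingGeometry())
        lo, hi = sps.poisson.ppf([0.005, 0.995], lam)
        counts = [
            len(synthetic.simulate_community([_single_pop()], [_meso()], [1], seed=s).particles)
            for s in range(60)
        ]
        inside = np.mean([(lo <= c <= hi) for c in counts])
        assert inside >= 0.95

    def test_count_distribution_matches_poisson(self):
        """Chi-square goodness of fit against Poisson(154) at alpha = 0.01."""
        lam = 10.0 * imaging.effective_subsample_volume_l(imaging.SamplingGeometry())
        counts = np.array(
            [
                len(synthetic.simulate_community([_single_pop()], [_meso()], [1], seed=s).particles)
                for s in range(200)
            ]
        )
        edges = np.array([0, 135, 145, 150, 154, 158, 163, 173, 100000])
        obs = np.histogram(counts, bins=edges)[0]
        prob = sps.poisson.cdf(edges[1:] - 1, lam) - sps.poisson.cdf(edges[:-1] - 1, lam)
        chi2 = float(np.sum((obs - prob * 200) ** 2 / (prob * 200)))
        p = float(sps.chi2.sf(chi2, len(obs) - 1))
        assert p > 0.01

    def test_treatment_contrast_exact_in_expectation(self):
        """With noise off, the high/control expected-count ratio equals the multiplier."""
        pop = _single_pop(conc=200.0, mult=1.4)
        mesos = [_meso("M1", "control"), _meso("M2", "high_co2")]
        ratios = []
        for s in range(40):
            t = synthetic.simulate_community([pop], mesos, [1], seed=s).particles
            ratios.append(len(t[t.mesocosm == "M2"]) / len(t[t.mesocosm == "M1"]))
        # Poisson noise around an exact 1.4 expectation
        assert np.mean(ratios) == pytest.approx(1.4, rel=0.02)

    def test_esd_distribution_lognormal(self):
        pop = _single_pop(conc=500.0)
        t = synthetic.simulate_community([pop], [_meso()], [1], seed=2).particles
        logs = np.log10(t["esd_um"])
        assert logs.mean() == pytest.approx(2.5, abs=0.01)
        assert logs.std() == pytest.approx(0.05, abs=0.01)


class TestDefaultCommunity:
    def test_ten_mesocosms_five_per_arm(self):
        mesos = synthetic.default_mesocosms()
        assert len(mesos) == 10
        arms = [m.treatment for m in mesos]
        assert arms.count("control") == 5 and arms.count("high_co2") == 5
        control_ids = {m.mesocosm_id for m in mesos if m.treatment == "control"}
        assert control_ids == {"M1", "M3", "M5", "M9", "M10"}

    def test_multipliers_match_reported_directions(self):
        by_taxon = {}
        for p in synthetic.default_populations():
            by_taxon.setdefault(p.taxon, set()).add(p.treatment_multiplier)
        assert by_taxon["picoeukaryotes"] == {1.6}
        assert by_taxon["coscinodiscus"] == {1.3}
        assert by_taxon["copepod"] == {1.4}
        assert by_taxon["hydromedusae"] == {0.8}

    def test_biomass_anchor_is_analytic(self):
        """Expected control-arm biomass equals the day-1/day-57 anchors."""
        pops = synthetic.default_populations()
        for day, target in ((1, 5.26), (57, 12.74)):
            total = sum(
                p.concentration_at(day) * p.mean_individual_biomass_mg() for p in pops
            )
            assert total == pytest.approx(target, rel=1e-9)


class TestFscFromEsd:
    def test_two_micron_fsc(self, calib):
        assert synthetic.fsc_from_esd(2.0, calib) == pytest.approx(5.51e4, rel=2e-3)

    def test_monotone(self, calib):
        esd = np.linspace(0.5, 50, 100)
        assert np.all(np.diff(synthetic.fsc_from_esd(esd, calib)) > 0)

    def test_noise_requires_rng(self, calib):
        with pytest.raises(ValueError):
            synthetic.fsc_from_esd(2.0, calib, noise_cv=0.1)

    def test_noise_is_mean_one(self, calib):
        rng = np.random.default_rng(0)
        fsc = synthetic.fsc_from_esd(np.full(20000, 5.0), calib, noise_cv=0.1, rng=rng)
        assert fsc.mean() == pytest.approx(calib.fsc(5.0), rel=0.01)


class TestRenderScanPlate:
    def test_empty_plate_uniform(self):
        img = synthetic.render_scan_plate([], shape=(32, 32), background_grey=200)
        assert np.all(img.pixels == 200)

    def test_overlap_rejected(self, pixel_size):
        objs = [
            ((50, 50), 40 * pixel_size, 40 * pixel_size, 0.0),
            ((52, 52), 40 * pixel_size, 40 * pixel_size, 0.0),
        ]
        with pytest.raises(ValueError):
            synthetic.render_scan_plate(objs, shape=(128, 128))

    def test_outside_canvas_rejected(self, pixel_size):
        with pytest.raises(ValueError):
            synthetic.render_scan_plate(
                [((2, 2), 40 * pixel_size, 40 * pixel_size, 0.0)], shape=(64, 64)
            )

    def test_equal_greys_rejected(self):
        with pytest.raises(ValueError):
            synthetic.render_scan_plate([], background_grey=100, particle_grey=100)


class TestInstrumentTables:
    def test_fcm_event_table_round_trip_sizes(self, small_community, calib):
        events = synthetic.community_to_fcm_events(
            small_community, "M1", 1, calib=calib, noise_cv=0.0, seed=11
        )
        assert len(events) > 0
        esd = fcm.esd_from_fsc(events["fsc"].to_numpy(), calib)
        ref = small_community.particles.query(
            "mesocosm == 'M1' and day == 1 and instrument == 'fcm'"
        )["esd_um"].to_numpy()
        assert np.allclose(np.sort(esd), np.sort(ref), rtol=1e-9)

    def test_object_table_consistent_with_community(self, small_community):
        objects = synthetic.community_to_object_table(small_community, "M1", 1)
        ref = small_community.particles.query(
            "mesocosm == 'M1' and day == 1 and instrument == 'imaging'"
        )
        assert len(objects) == len(ref)
        assert set(objects["category"]) <= {"copepod"}
        # sphere convention: biovolume = (pi/6) ESD^3
        d_mm = objects["esd_um"].to_numpy() / 1000.0
        assert np.allclose(objects["biovolume_mm3"], np.pi / 6 * d_mm**3, rtol=1e-12)


def test_config_round_trip(tmp_path):
    pops = synthetic.default_populations()
    mesos = synthetic.default_mesocosms()
    path = tmp_path / "config.yaml"
    synthetic.write_config(path, pops, mesos, [1, 57], 5)
    pops2, mesos2, days2, seed2 = synthetic.read_config(path)
    assert pops2 == pops
    assert mesos2 == mesos
    assert days2 == [1, 57] and seed2 == 5
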
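"""Size-spectrum construction: binning, normalization, conservation, slopes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plankspectra import spectra as sp

from conftest import particle_frame


class TestBiomassConversion:
    def test_unit_density_constant(self):
        assert sp.biomass_from_biovolume(1.0) == pytest.approx(1.060)
        assert sp.biomass_from_biovolume(0.0) == 0.0

    def test_sphere_100um(self):
        bv = sp.sphere_biovolume_mm3(100.0)
        assert bv == pytest.approx(5.236e-4, rel=1e-3)
        assert sp.biomass_from_biovolume(bv) == pytest.approx(5.550e-4, rel=1e-3)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            sp.biomass_from_biovolume(-1.0)


class TestBinGrid:
    def test_one_bin_per_decade(self):
        bins = sp.build_bins(100.0, 1000.0, bins_per_decade=1)
        assert bins.edges_um[0] == pytest.approx(100.0)
        assert bins.edges_um[1] == pytest.approx(1000.0)
        assert bins.widths_mm[0] == pytest.approx(0.9)

    def test_widths_grow_geometrically(self):
        bins = sp.build_bins(1.0, 1000.0, bins_per_decade=12)
        ratios = bins.widths_mm[1:] / bins.widths_mm[:-1]
        assert np.allclose(ratios, 10 ** (1 / 12), rtol=1e-12)

    def test_grid_covers_requested_range(self):
        bins = sp.build_bins(0.5, 2500.0, bins_per_decade=12)
        assert bins.edges_um[0] == pytest.approx(0.5)
        assert bins.edges_um[-1] >= 2500.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            sp.build_bins(10.0, 10.0, 12)

    def test_half_open_membership(self):
        bins = sp.build_bins(1.0, 100.0, 1)
        idx = bins.assign(np.array([1.0, 9.999, 10.0, 99.999, 100.0, 0.5]))
        assert list(idx) == [0, 0, 1, 1, -1, -1]


class TestPssWbs:
    def test_empty_input_all_zero(self):
        bins = sp.build_bins(1.0, 100.0, 4)
        spec = sp.compute_spectrum(particle_frame([]), bins)
        assert np.all(spec.pss == 0) and np.all(spec.wbs == 0)

    def test_hand_computed_pss(self):
        # 100 particles totalling 10 # L^-1 in one bin of width 0.1 mm -> 100
        bins = sp.BinGrid(edges_um=np.array([100.0, 200.0]))
        df = particle_frame(np.full(100, 150.0), weight_per_l=0.1)
        spec = sp.compute_pss(df, bins)
        assert bins.widths_mm[0] == pytest.approx(0.1)
        assert spec.pss[0] == pytest.approx(100.0)
        assert spec.counts[0] == 100

    def test_hand_computed_wbs(self):
        # concentration 5 # L^-1, mean individual biomass 0.2 mg -> 1.0 mg L^-1
        bins = sp.BinGrid(edges_um=np.array([100.0, 200.0]))
        df = particle_frame(np.full(5, 150.0), weight_per_l=1.0, biomass_mg=0.2)
        spec = sp.compute_wbs(df, bins)
        assert spec.wbs[0] == pytest.approx(1.0, rel=1e-12)

    def test_pss_linearity_in_weights(self):
        rng = np.random.default_rng(3)
        esd = rng.uniform(1, 900, 500)
        bins = sp.build_bins(1.0, 1000.0, 8)
        s1 = sp.compute_spectrum(particle_frame(esd, weight_per_l=0.5), bins)
        s2 = sp.compute_spectrum(particle_frame(esd, weight_per_l=1.0), bins)
        assert np.allclose(2 * s1.pss, s2.pss, rtol=1e-12)
        assert np.allclose(2 * s1.wbs, s2.wbs, rtol=1e-12)

    def test_out_of_range_counted_dropped(self):
        bins = sp.build_bins(10.0, 100.0, 4)
        spec = sp.compute_spectrum(particle_frame([5.0, 50.0, 500.0]), bins)
        assert spec.n_dropped == 2
        assert spec.counts.sum() == 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1.0, max_value=999.0), min_size=1, max_size=200),
        st.sampled_from([4, 8, 12, 24]),
    )
    def test_conservation_property(self, esds, bpd):
        """Total concentration and biomass survive binning for any bin count."""
        df = particle_frame(np.array(esds), weight_per_l=0.25)
        bins = sp.build_bins(1.0, 1000.0, bpd)
        spec = sp.compute_spectrum(df, bins)
        total_conc = float(np.sum(df["weight_per_l"]))
        total_bio = float(np.sum(df["weight_per_l"] * df["biomass_mg"]))
        assert np.sum(spec.pss * bins.widths_mm) == pytest.approx(total_conc, rel=1e-12)
        assert np.sum(spec.wbs) == pytest.approx(total_bio, rel=1e-12)


def brute_force_bins(df, bins):
    """Independent per-particle loop over all bins (the naive oracle)."""
    nb = bins.n_bins
    pss = np.zeros(nb)
    wbs = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    for _, row in df.iterrows():
        for i in range(nb):
            if bins.edges_um[i] <= row["esd_um"] < bins.edges_um[i + 1]:
                counts[i] += 1
                pss[i] += row["weight_per_l"]
                wbs[i] += row["weight_per_l"] * row["biomass_mg"]
                break
    return pss / bins.widths_mm, wbs, counts


def test_binning_matches_brute_force_oracle():
    rng = np.random.default_rng(17)
    esd = 10.0 ** rng.uniform(0, 3, 400)
    df = particle_frame(esd, weight_per_l=rng.uniform(0.1, 2.0, 400))
    bins = sp.build_bins(1.0, 1000.0, 7)
    spec = sp.compute_spectrum(df, bins)
    pss_o, wbs_o, counts_o = brute_force_bins(df, bins)
    assert np.array_equal(spec.counts, counts_o)
    assert np.allclose(spec.pss, pss_o, rtol=1e-12)
    assert np.allclose(spec.wbs, wbs_o, rtol=1e-12)


class TestSlopeFit:
    def _exact_powerlaw_frame(self, bins, beta=-2.0, c=1e4):
        """Particles whose PSS follows midpoint^beta exactly."""
        esd = bins.midpoints_um
        conc = c * esd**beta * bins.widths_mm  # one particle per bin
        return particle_frame(esd, weight_per_l=conc)

    def test_exact_minus_two_reference_case(self):
        bins = sp.build_bins(1.0, 1000.0, 6)
        spec = sp.compute_spectrum(self._exact_powerlaw_frame(bins, beta=-2.0), bins)
        fit = sp.fit_slope(spec)
        assert fit.slope == pytest.approx(-2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_bins_rejected(self):
        bins = sp.build_bins(1.0, 1000.0, 6)
        df = particle_frame([2.0, 20.0])
        with pytest.raises(ValueError):
            sp.fit_slope(sp.compute_spectrum(df, bins))

    def test_size_range_restricts_fit(self):
        bins = sp.build_bins(1.0, 1000.0, 6)
        spec = sp.compute_spectrum(self._exact_powerlaw_frame(bins, beta=-3.0), bins)
        fit = sp.fit_slope(spec, size_range_um=(1.0, 100.0))
        assert fit.slope == pytest.approx(-3.0, abs=1e-9)
        assert fit.n_bins_used < bins.n_bins


class TestMergeInstruments:
    def test_empty_imaging_keeps_fcm(self):
        f = particle_frame([1.0, 5.0], instrument="fcm")
        combined, gap = sp.merge_instruments(f, particle_frame([]))
        assert len(combined) == 2
        assert gap == (60.0, 150.0)

    def test_totals_are_conserved(self):
        f = particle_frame([1.0, 5.0], weight_per_l=2.0, instrument="fcm")
        i = particle_frame([200.0, 800.0], weight_per_l=0.1, instrument="imaging")
        combined, _ = sp.merge_instruments(f, i)
        assert combined["weight_per_l"].sum() == pytest.approx(4.2)

    def test_out_of_domain_flagged_not_dropped(self):
        f = particle_frame([80.0], instrument="fcm")  # beyond cytometer crossover
        combined, _ = sp.merge_instruments(f, particle_frame([]))
        assert bool(combined["out_of_domain"].iloc[0])
        assert len(combined) == 1

    def test_gap_bins_excluded_from_slope(self):
        bins = sp.build_bins(1.0, 1000.0, 4)
        f = particle_frame(10.0 ** np.linspace(0.1, 1.7, 50), instrument="fcm")
        combined, gap = sp.merge_instruments(f, particle_frame([]))
        spec = sp.compute_spectrum(combined, bins, gap_um=gap)
        inside = (bins.edges_um[:-1] >= 60.0) & (bins.edges_um[1:] <= 150.0)
        assert not spec.observed[inside].any()


class TestGroupBiomassTable:
    def test_matches_hand_sums(self):
        df = pd.concat(
            [
                particle_frame([5.0, 8.0], weight_per_l=2.0, biomass_mg=0.1, group="nano"),
                particle_frame([300.0, 700.0, 1200.0], weight_per_l=0.5, biomass_mg=1.0, group="copepod"),
            ],
            ignore_index=True,
        )
        table = sp.group_biomass_table(df)
        by = table.set_index("group")["biomass_mg_per_l"]
        assert by["nano"] == pytest.approx(0.4)
        assert by["Copepod S (<600 um) & nauplii"] == pytest.approx(0.5)
        assert by["Copepod M (600-1000 um)"] == pytest.approx(0.5)
        assert by["Copepod L (>1000 um)"] == pytest.approx(0.5)
        assert by["Copepod total"] == pytest.approx(1.5)
        assert by["Total biomass"] == pytest.approx(1.9)

    def test_single_group_total_equals_row(self):
        df = particle_frame([5.0, 6.0], weight_per_l=1.0, biomass_mg=0.2, group="nano")
        table = sp.group_biomass_table(df)
        by = table.set_index("group")["biomass_mg_per_l"]
        assert by["Total biomass"] == pytest.approx(by["nano"])

    def test_empty(self):
        assert len(sp.group_biomass_table(particle_frame([]))) == 0


def test_plot_spectra_smoke():
    import matplotlib

    matplotlib.use("Agg")
    bins = sp.build_bins(1.0, 1000.0, 6)
    spec = sp.compute_spectrum(particle_frame(10.0 ** np.linspace(0.1, 2.9, 60)), bins)
    axes = sp.plot_spectra(spec)
    assert len(axes) == 2


class TestPercentChange:
    def test_copepod_decline_value(self):
        # 3.43 -> 2.58 mg L^-1 is a ~25% decrease
        assert sp.percent_change(3.43, 2.58) == pytest.approx(24.78, abs=0.01)

    def test_identity_and_increase(self):
        assert sp.percent_change(5.0, 5.0) == 0.0
        assert sp.percent_change(6.02, 7.92) == pytest.approx(-31.6, abs=0.1)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            sp.percent_change(0.0, 1.0)
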
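"""Phasor transform, semicircle geometry, IRF correction, bound-fraction axis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import noise_free_histogram
from phasorflim.io import DecayCube
from phasorflim.phasor import (
    LITERATURE_ENDPOINTS,
    PhasorField,
    PhasorPoint,
    TransformConfig,
    analytic_phasor,
    bound_fraction,
    bound_fraction_histogram,
    correct_irf,
    estimate_irf_phasor,
    phasor_axis,
    phasor_field,
    phasor_histogram_2d,
    phasor_transform,
)
from phasorflim.simulate import (
    DELTA_IRF,
    FieldPhantom,
    IrfModel,
    SynthComponent,
    simulate_decay,
    simulate_field,
)


def field_of(g, s):
    return PhasorField(g=np.atleast_2d(np.asarray(g, float)),
                       s=np.atleast_2d(np.asarray(s, float)))


class TestPhasorTransform:
    def test_delta_at_origin(self, meta, tcfg):
        h = np.zeros(meta.n_bins)
        h[0] = 1000
        z = phasor_transform(h, tcfg)
        assert z.g == pytest.approx(1.0, abs=0.01)
        assert z.s == pytest.approx(0.0, abs=0.02)

    @pytest.mark.parametrize(
        "tau, expected",
        [(0.4, (0.9406, 0.2364)), (3.4, (0.1797, 0.3840))],
    )
    def test_noise_free_exponential_matches_closed_form(self, meta, tcfg, tau, expected):
        y = noise_free_histogram([tau], [1.0], meta)
        z = phasor_transform(y, tcfg)
        assert z.g == pytest.approx(expected[0], abs=1e-3)
        assert z.s == pytest.approx(expected[1], abs=1e-3)

    def test_empty_decay_rejected(self, meta, tcfg):
        with pytest.raises(ValueError):
            phasor_transform(np.zeros(meta.n_bins), tcfg)

    def test_field_transform_matches_per_pixel(self, meta, tcfg):
        rng = np.random.default_rng(2)
        counts = rng.poisson(20, (3, 4, meta.n_bins))
        cube = DecayCube(counts=counts, meta=meta)
        field = phasor_field(cube, tcfg)
        z = phasor_transform(counts[1, 2], tcfg)
        assert field.g[1, 2] == pytest.approx(z.g, rel=1e-12)
        assert field.s[1, 2] == pytest.approx(z.s, rel=1e-12)


class TestAnalyticPhasor:
    def test_limits(self, tcfg):
        near_zero = analytic_phasor([(1.0, 1e-6)], tcfg)
        assert (near_zero.g, near_zero.s) == pytest.approx((1.0, 0.0), abs=1e-5)
        near_inf = analytic_phasor([(1.0, 1e6)], tcfg)
        assert (near_inf.g, near_inf.s) == pytest.approx((0.0, 0.0), abs=1e-5)

    def test_equal_amplitude_nadh_mixture(self, tcfg):
        z = analytic_phasor([(1.0, 0.4), (1.0, 3.4)], tcfg)
        assert z.g == pytest.approx(0.2598, abs=1e-4)
        assert z.s == pytest.approx(0.3684, abs=1e-4)

    def test_semicircle_identity_exact(self, tcfg):
        for tau in np.geomspace(0.05, 10, 25):
            z = analytic_phasor([(1.0, tau)], tcfg)
            assert z.semicircle_residual() < 1e-12

    def test_discrete_transform_semicircle_residual(self, meta, tcfg):
        """Noise-free single exponentials stay within 1e-3 of the semicircle."""
        for tau in np.geomspace(0.05, 10, 15):
            y = noise_free_histogram([tau], [1.0], meta)
            z = phasor_transform(y, tcfg)
            assert z.semicircle_residual() < 1e-3

    @given(
        a1=st.floats(min_value=0.01, max_value=10),
        a2=st.floats(min_value=0.01, max_value=10),
        t1=st.floats(min_value=0.1, max_value=5),
        t2=st.floats(min_value=0.1, max_value=5),
    )
    def test_linearity_in_photon_yield(self, tcfg, a1, a2, t1, t2):
        """Mixture phasor is the A_i*tau_i-weighted mean of component phasors."""
        z = analytic_phasor([(a1, t1), (a2, t2)], tcfg)
        z1 = analytic_phasor([(1.0, t1)], tcfg)
        z2 = analytic_phasor([(1.0, t2)], tcfg)
        w1, w2 = a1 * t1, a2 * t2
        g = (w1 * z1.g + w2 * z2.g) / (w1 + w2)
        s = (w1 * z1.s + w2 * z2.s) / (w1 + w2)
        assert z.g == pytest.approx(g, abs=1e-12)
        assert z.s == pytest.approx(s, abs=1e-12)

    def test_matches_simulated_decay_phasor(self, meta, tcfg):
        comps = [(0.7, 0.6), (1.3, 2.8)]
        h = simulate_decay([SynthComponent(t, a) for a, t in comps],
                           10**6, DELTA_IRF, meta, seed=17)
        z_sim = phasor_transform(h, tcfg)
        z_ref = analytic_phasor(comps, tcfg)
        tol = 3.0 / np.sqrt(10**6) + 1e-3
        assert z_sim.g == pytest.approx(z_ref.g, abs=tol)
        assert z_sim.s == pytest.approx(z_ref.s, abs=tol)


class TestPhasorAxis:
    def test_axis_length(self, tcfg):
        calib = phasor_axis(cfg=tcfg)
        assert calib.L == pytest.approx(0.7750, abs=1e-4)

    def test_endpoints_are_pure_species_phasors(self, tcfg):
        calib = phasor_axis(cfg=tcfg)
        p1 = analytic_phasor([(1.0, 0.4)], tcfg)
        p2 = analytic_phasor([(1.0, 3.4)], tcfg)
        assert (calib.p1.g, calib.p1.s) == (p1.g, p1.s)
        assert (calib.p2.g, calib.p2.s) == (p2.g, p2.s)

    def test_literature_s_agreement(self, tcfg):
        """Computed endpoint s coordinates match the instrument-calibrated
        literature values to ~1% (g is computed analytically; see module
        notes)."""
        calib = phasor_axis(cfg=tcfg)
        assert calib.p1.s == pytest.approx(LITERATURE_ENDPOINTS["p1"]["s"], rel=0.015)
        assert calib.p2.s == pytest.approx(LITERATURE_ENDPOINTS["p2"]["s"], rel=0.01)

    def test_equal_lifetimes_rejected(self, tcfg):
        with pytest.raises(ValueError):
            phasor_axis(1.0, 1.0, tcfg)


class TestBoundFraction:
    def test_endpoints_map_to_zero_and_one(self, tcfg):
        calib = phasor_axis(cfg=tcfg)
        f = bound_fraction(field_of([calib.p1.g, calib.p2.g],
                                    [calib.p1.s, calib.p2.s]), calib)
        assert f.fraction[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert f.fraction[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_equal_amplitude_mixture_value(self, tcfg):
        calib = phasor_axis(cfg=tcfg)
        z = analytic_phasor([(1.0, 0.4), (1.0, 3.4)], tcfg)
        f = bound_fraction(field_of(z.g, z.s), calib)
        assert f.fraction[0, 0] == pytest.approx(3.4 / 3.8, abs=1e-12)

    @given(
        a1=st.floats(min_value=0.01, max_value=100),
        a2=st.floats(min_value=0.01, max_value=100),
    )
    def test_projection_equals_photon_yield_formula(self, tcfg, a1, a2):
        """Geometric projection == A2*tau2/(A1*tau1 + A2*tau2) for mixtures
        of the calibration species."""
        calib = phasor_axis(cfg=tcfg)
        z = analytic_phasor([(a1, 0.4), (a2, 3.4)], tcfg)
        f = bound_fraction(field_of(z.g, z.s), calib).fraction[0, 0]
        expected = a2 * 3.4 / (a1 * 0.4 + a2 * 3.4)
        assert f == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_bound_yield(self, tcfg):
        calib = phasor_axis(cfg=tcfg)
        fracs = []
        for a2 in np.linspace(0.05, 5, 20):
            z = analytic_phasor([(1.0, 0.4), (a2, 3.4)], tcfg)
            fracs.append(bound_fraction(field_of(z.g, z.s), calib).fraction[0, 0])
        assert np.all(np.diff(fracs) > 0)

    def test_swapping_lifetimes_flips_fraction(self, tcfg):
        calib = phasor_axis(0.4, 3.4, tcfg)
        flipped = phasor_axis(3.4, 0.4, tcfg)
        z = analytic_phasor([(1.0, 0.4), (1.0, 3.4)], tcfg)
        f = bound_fraction(field_of(z.g, z.s), calib).fraction[0, 0]
        g = bound_fraction(field_of(z.g, z.s), flipped).fraction[0, 0]
        assert g == pytest.approx(1 - f, abs=1e-12)

    def test_clamped_copy_in_unit_interval(self, tcfg):
        calib = phasor_axis(cfg=tcfg)
        fmap = bound_fraction(field_of([1.5, -0.5], [0.0, 0.0]), calib)
        clamped = fmap.clamped()
        assert clamped.min() >= 0.0 and clamped.max() <= 1.0


class TestIrfCorrection:
    def test_unit_irf_is_identity(self):
        field = field_of([0.3, 0.5], [0.2, 0.4])
        out = correct_irf(field, PhasorPoint(1.0, 0.0))
        np.testing.assert_allclose(out.g, field.g)
        np.testing.assert_allclose(out.s, field.s)
        assert out.corrected

    def test_convolve_then_correct_round_trip(self, tcfg):
        """Complex multiplication by z_irf then division restores the field."""
        rng = np.random.default_rng(9)
        g, s = rng.random((2, 4, 4))
        z_irf = PhasorPoint(0.81, 0.58)
        blurred = (g + 1j * s) * z_irf.as_complex()
        out = correct_irf(PhasorField(g=np.real(blurred), s=np.imag(blurred)), z_irf)
        np.testing.assert_allclose(out.g, g, atol=1e-12)
        np.testing.assert_allclose(out.s, s, atol=1e-12)

    def test_zero_irf_rejected(self):
        with pytest.raises(ValueError):
            correct_irf(field_of(0.5, 0.3), PhasorPoint(0.0, 0.0))


def _uniform_cube(meta, tau, irf, n_bright=400_000, n_dim=30_000, shape=(6, 6)):
    """Cube of identical single-exponential pixels with one bright pixel."""
    rng_seeds = iter(range(100, 100 + shape[0] * shape[1]))
    counts = np.zeros(shape + (meta.n_bins,), dtype=np.int64)
    for r in range(shape[0]):
        for c in range(shape[1]):
            n = n_bright if (r, c) == (2, 3) else n_dim
            counts[r, c] = simulate_decay([SynthComponent(tau)], n, irf, meta,
                                          seed=next(rng_seeds))
    return DecayCube(counts=counts, meta=meta)


class TestEstimateIrfPhasor:
    def test_delta_irf_estimates_near_unity(self, meta, tcfg):
        cube = _uniform_cube(meta, 2.0, DELTA_IRF)
        z = estimate_irf_phasor(cube, tcfg)
        assert z.g == pytest.approx(1.0, abs=0.01)
        assert z.s == pytest.approx(0.0, abs=0.01)

    def test_gaussian_irf_recovered(self, meta, tcfg):
        irf = IrfModel(shape="gaussian", center=1.0, fwhm=0.2)
        cube = _uniform_cube(meta, 2.0, irf)
        z = estimate_irf_phasor(cube, tcfg)
        assert z.g == pytest.approx(0.8079, abs=0.01)
        assert z.s == pytest.approx(0.5870, abs=0.01)

    def test_corrected_field_returns_to_semicircle(self, meta, tcfg):
        irf = IrfModel(shape="gaussian", center=1.0, fwhm=0.2)
        cube = _uniform_cube(meta, 2.0, irf)
        z_irf = estimate_irf_phasor(cube, tcfg)
        corrected = correct_irf(phasor_field(cube, tcfg), z_irf)
        resid = np.abs((corrected.g - 0.5) ** 2 + corrected.s ** 2 - 0.25)
        assert np.nanmax(resid) < 0.01

    def test_flat_image_rejected(self, meta, tcfg):
        cube = DecayCube(counts=np.zeros((3, 3, meta.n_bins), int), meta=meta)
        with pytest.raises(ValueError):
            estimate_irf_phasor(cube, tcfg)


class TestPhasorHistograms:
    def test_2d_histogram_conserves_pixels(self, meta, tcfg):
        rng = np.random.default_rng(4)
        counts = rng.poisson(50, (8, 8, meta.n_bins))
        field = phasor_field(DecayCube(counts=counts, meta=meta), tcfg)
        hist = phasor_histogram_2d(field)
        assert hist["counts"].sum() + hist["overflow"] == hist["n_pixels"]

    def test_single_valued_field_one_cell(self, tcfg):
        field = field_of(np.full((5, 5), 0.4), np.full((5, 5), 0.3))
        hist = phasor_histogram_2d(field)
        assert (hist["counts"] > 0).sum() == 1
        assert hist["counts"].max() == 25

    def test_compartment_clusters_match_analytic_phasors(self, tcfg):
        """Two-compartment phantom: per-compartment phasor centroids land on
        the compartments' analytic mixture phasors."""
        phantom = FieldPhantom(seed=31, photons_per_pixel={1: 3000.0, 2: 3000.0})
        cube, masks = simulate_field(phantom)
        field = phasor_field(cube)
        for label, comps in ((1, phantom.cytoplasm_components),
                             (2, phantom.nuclear_components)):
            sel = masks.labels == label
            ref = analytic_phasor([(c.amplitude, c.lifetime) for c in comps], tcfg)
            assert np.nanmean(field.g[sel]) == pytest.approx(ref.g, abs=0.01)
            assert np.nanmean(field.s[sel]) == pytest.approx(ref.s, abs=0.01)

    def test_bound_fraction_histogram_recovers_compartment_truth(self, tcfg):
        """Cytoplasmic mean f near 3.4/3.8, nuclear near 0 (pure free)."""
        phantom = FieldPhantom(seed=33, photons_per_pixel={1: 3000.0, 2: 3000.0})
        cube, masks = simulate_field(phantom)
        calib = phasor_axis(cfg=tcfg)
        fmap = bound_fraction(phasor_field(cube), calib)
        _, _, pops_cyt = bound_fraction_histogram(fmap, masks.labels == 1)
        assert pops_cyt is not None
        assert pops_cyt.overall_mean == pytest.approx(3.4 / 3.8, abs=0.02)
        _, _, pops_nuc = bound_fraction_histogram(fmap, masks.labels == 2)
        assert pops_nuc is not None
        assert pops_nuc.overall_mean == pytest.approx(0.0, abs=0.02)

    def test_constant_fraction_population_mean(self, tcfg):
        calib = phasor_axis(cfg=tcfg)
        fmap = bound_fraction(field_of(np.full((40, 40), 0.2598),
                                       np.full((40, 40), 0.3684)), calib)
        edges, counts, _ = bound_fraction_histogram(fmap)
        center = edges[np.argmax(counts)] + 0.0025
        assert center == pytest.approx(3.4 / 3.8, abs=0.005)
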
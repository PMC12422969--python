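import math

import numpy as np
import pytest

from ampardyn.errors import FormatError, ParameterError, StabilityError
from ampardyn.metadyn import (
    KB,
    FESurface,
    Hill,
    HillsLog,
    ToyPotential,
    WTParams,
    bias_at,
    fes_from_hills,
    fes_from_histogram,
    next_hill,
    parse_hills,
    run_toy_metad,
    write_hills,
)

HEADER = "#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height biasf\n"


def random_log(rng, n=100, periodic=(False, False), period=(0.0, 0.0)):
    hills = [
        Hill(
            time=float(i),
            center=(float(rng.uniform(-3, 3)), float(rng.uniform(-3, 3))),
            sigma=(float(rng.uniform(0.1, 1.0)), float(rng.uniform(0.1, 1.0))),
            height=float(rng.uniform(0.1, 1.2)),
            bias_factor=10.0,
        )
        for i in range(n)
    ]
    return HillsLog(hills, periodic=periodic, period=period)


class TestParseHills:
    def test_single_row(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text(HEADER + "10.0 0.5 -0.25 0.3 0.4 1.2 10\n")
        log = parse_hills(p)
        assert len(log) == 1
        h = log.hills[0]
        assert h.time == 10.0
        assert h.center == (0.5, -0.25)
        assert h.sigma == (0.3, 0.4)
        assert h.height == 1.2
        assert h.bias_factor == 10.0

    def test_two_walkers_merged_time_sorted(self, tmp_path):
        a = tmp_path / "HILLS.0"
        b = tmp_path / "HILLS.1"
        a.write_text(HEADER + "".join(f"{t}.0 0 0 0.3 0.3 1.0 10\n" for t in (10, 30, 50, 70, 90)))
        b.write_text(HEADER + "".join(f"{t}.0 1 1 0.3 0.3 1.0 10\n" for t in (20, 40, 60, 80, 100)))
        log = parse_hills([a, b])
        assert len(log) == 10
        times = [h.time for h in log.hills]
        assert times == sorted(times)
        assert log.walker_ids[:2] == [0, 1]

    def test_short_row_raises_with_line_number(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text(HEADER + "10.0 0.5 -0.25 0.3 0.4 1.2 10\n1.0 2.0 3.0\n")
        with pytest.raises(FormatError, match="line 3"):
            parse_hills(p)

    def test_missing_header_raises(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("1.0 0 0 0.3 0.3 1.0 10\n")
        with pytest.raises(FormatError):
            parse_hills(p)

    def test_periodic_metadata_from_header(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text(
            HEADER
            + "#! SET min_cv1 -pi\n#! SET max_cv1 pi\n"
            + "1.0 0 0 0.3 0.3 1.0 10\n"
        )
        log = parse_hills(p)
        assert log.periodic == (True, False)
        assert log.period[0] == pytest.approx(2 * math.pi)

    def test_write_parse_round_trip(self, tmp_path, rng):
        log = random_log(rng, n=20, periodic=(True, False), period=(360.0, 0.0))
        p = tmp_path / "HILLS"
        write_hills(log, p)
        back = parse_hills(p)
        assert len(back) == 20
        assert back.periodic == (True, False)
        for h0, h1 in zip(log.hills, back.hills):
            assert h1.center == pytest.approx(h0.center, rel=1e-9)
            assert h1.sigma == pytest.approx(h0.sigma, rel=1e-9)
            assert h1.height == pytest.approx(h0.height, rel=1e-9)


class TestBiasAt:
    def test_empty_log_is_zero(self):
        assert bias_at(HillsLog([]), (0.0, 0.0)) == 0.0

    def test_single_hill_at_centre(self):
        log = HillsLog([Hill(0.0, (1.0, -1.0), (0.3, 0.3), 1.2, 10.0)])
        assert bias_at(log, (1.0, -1.0)) == pytest.approx(1.2)

    def test_brute_force_oracle_on_grid(self, rng):
        log = random_log(rng, n=100)
        xs = np.linspace(-3, 3, 50)
        ys = np.linspace(-3, 3, 50)
        g1, g2 = np.meshgrid(xs, ys, indexing="ij")
        V = bias_at(log, np.stack([g1, g2], axis=-1))
        # naive per-node double loop
        for i in range(0, 50, 7):
            for j in range(0, 50, 7):
                v = 0.0
                for h in log.hills:
                    dx = xs[i] - h.center[0]
                    dy = ys[j] - h.center[1]
                    v += h.height * math.exp(
                        -0.5 * (dx**2 / h.sigma[0] ** 2 + dy**2 / h.sigma[1] ** 2)
                    )
                assert abs(V[i, j] - v) < 1e-10

    def test_periodic_minimum_image(self, rng):
        log = HillsLog(
            [Hill(0.0, (179.0, 0.0), (5.0, 5.0), 1.0, 10.0)],
            periodic=(True, False),
            period=(360.0, 0.0),
        )
        # -179 is 2 degrees away across the periodic boundary
        near = bias_at(log, (-179.0, 0.0))
        assert near == pytest.approx(math.exp(-0.5 * (2.0 / 5.0) ** 2))

    def test_upto_time_filters(self, rng):
        log = random_log(rng, n=10)
        v_all = bias_at(log, (0.0, 0.0))
        v_half = bias_at(log, (0.0, 0.0), upto_time=4.5)
        brute = sum(
            h.height
            * math.exp(
                -0.5
                * ((0 - h.center[0]) ** 2 / h.sigma[0] ** 2 + (0 - h.center[1]) ** 2 / h.sigma[1] ** 2)
            )
            for h in log.hills
            if h.time <= 4.5
        )
        assert v_half == pytest.approx(brute, abs=1e-12)
        assert v_half < v_all


class TestFesFromHills:
    def test_single_hill_closed_form(self):
        params = WTParams()
        log = HillsLog([Hill(0.0, (0.0, 0.0), (0.2, 0.2), 1.2, 10.0)])
        fes = fes_from_hills(log, params, ((-5, 5, 101), (-5, 5, 101)))
        assert np.nanmin(fes.F) == 0.0
        centre = fes.F[50, 50]
        far = fes.F[0, 0]
        assert centre == pytest.approx(0.0, abs=1e-12)
        assert far - centre == pytest.approx((10 / 9) * 1.2, abs=1e-6)

    def test_uniform_offset_leaves_differences(self):
        params = WTParams()
        log = HillsLog([Hill(0.0, (0.0, 0.0), (0.3, 0.3), 1.0, 10.0)])
        fes1 = fes_from_hills(log, params, ((-2, 2, 41), (-2, 2, 41)))
        wide = Hill(1.0, (0.0, 0.0), (1e4, 1e4), 0.7, 10.0)  # flat over the grid
        fes2 = fes_from_hills(HillsLog(log.hills + [wide]), params, ((-2, 2, 41), (-2, 2, 41)))
        np.testing.assert_allclose(fes2.F, fes1.F, atol=1e-6)

    def test_gamma_mismatch_raises(self):
        log = HillsLog([Hill(0.0, (0.0, 0.0), (0.3, 0.3), 1.0, 5.0)])
        with pytest.raises(ParameterError):
            fes_from_hills(log, WTParams(gamma=10.0), ((-1, 1, 11), (-1, 1, 11)))

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ParameterError):
            WTParams(gamma=0.5)


class TestFesFromHistogram:
    def test_exact_stationary_samples_recovered(self, rng):
        # rejection-free oracle: draw node indices from the discrete
        # stationary law p ~ exp(-F0/(kB(T+dT))) on the grid itself
        params = WTParams()
        kT_eff = KB * (params.T + params.delta_T)
        xs = np.linspace(-2, 2, 21)
        ys = np.linspace(-2, 2, 21)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        F0 = 3.0 * (X**2 + Y**2)
        p = np.exp(-F0 / kT_eff)
        p /= p.sum()
        idx = rng.choice(F0.size, size=400_000, p=p.ravel())
        samples = np.column_stack([X.ravel()[idx], Y.ravel()[idx]])
        fes = fes_from_histogram(samples, params, (xs, ys), kernel_width=1e-6)
        mask = np.isfinite(fes.F)
        resid = (fes.F - (F0 - F0.min()))[mask]
        resid -= resid.mean()
        # per-node Monte-Carlo noise is ~kT_eff/sqrt(n) ~ 1 kJ/mol here
        assert np.sqrt(np.mean(resid**2)) < 1.5
        assert np.abs(resid).max() < 5.0

    def test_uniform_samples_flat_surface(self, rng):
        params = WTParams()
        # grid nodes strictly inside the sampled domain so every bin is
        # fully covered (edge bins would otherwise be half-empty)
        xs = np.linspace(0.1, 0.9, 9)
        samples = np.column_stack([rng.uniform(0, 1, 200_000), rng.uniform(0, 1, 200_000)])
        fes = fes_from_histogram(samples, params, (xs, xs), kernel_width=0.2)
        assert np.nanmax(fes.F) < 1.0

    def test_single_sample_delta(self):
        params = WTParams()
        xs = np.linspace(-1, 1, 11)
        fes = fes_from_histogram(
            np.tile([[0.0, 0.0]], (5, 1)), params, (xs, xs), kernel_width=1e-6
        )
        assert fes.F[5, 5] == 0.0
        assert np.isnan(fes.F[0, 0])

    def test_empty_samples_raise(self):
        with pytest.raises(ValueError):
            fes_from_histogram(np.empty((0, 2)), WTParams(), ((-1, 1, 5), (-1, 1, 5)), 0.1)


class TestNextHill:
    def test_first_hill_height_is_h0(self):
        params = WTParams()
        h = next_hill(np.array([0.3, -0.2]), HillsLog([]), params)
        assert h.height == params.h0

    def test_second_hill_well_tempered_height(self):
        params = WTParams()  # T=300, gamma=10, h0=1.2
        first = next_hill(np.zeros(2), HillsLog([]), params, time=0.0)
        second = next_hill(np.zeros(2), HillsLog([first]), params, time=10.0)
        expected = 1.2 * math.exp(-1.2 / (KB * 2700.0))
        assert second.height == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.1375, abs=5e-4)

    def test_stationary_history_hits_floor(self):
        params = WTParams()
        state = np.array([0.5, 0.5])
        history = np.tile(state, (100, 1))
        h = next_hill(state, HillsLog([]), params, history=history, sigma_floor=0.01)
        assert h.sigma == (0.01, 0.01)

    def test_heights_non_increasing_at_fixed_point(self):
        params = WTParams()
        log = HillsLog([])
        heights = []
        for k in range(10):
            h = next_hill(np.zeros(2), log, params, time=float(k))
            heights.append(h.height)
            log = HillsLog(log.hills + [h])
        assert all(b < a for a, b in zip(heights, heights[1:]))


class TestRunToyMetad:
    def test_same_seed_bit_identical(self):
        pot = ToyPotential.double_well(barrier=6.0, tilt=2.837, ky=30.0)
        params = WTParams()
        kw = dict(
            langevin=(30.0, 0.2, 300.0), n_steps=2000, n_walkers=2, seed=11,
            domain=((-1.9, 1.9), (-2.5, 2.5)),
        )
        log1, s1 = run_toy_metad(pot, params, **kw)
        log2, s2 = run_toy_metad(pot, params, **kw)
        assert [h.center for h in log1.hills] == [h.center for h in log2.hills]
        assert [h.height for h in log1.hills] == [h.height for h in log2.hills]
        assert (s1.to_numpy() == s2.to_numpy()).all()

    def test_zero_bias_harmonic_equipartition(self):
        # unbiased overdamped sampling of a harmonic well: var = kB*T/k
        pot = ToyPotential.harmonic(kx=10.0, ky=10.0)
        params = WTParams(h0=0.0)
        _, samples = run_toy_metad(
            pot, params, langevin=(10.0, 0.02, 300.0), n_steps=50_000,
            n_walkers=4, seed=3, domain=((-4, 4), (-4, 4)), sample_stride=5,
        )
        expected = KB * 300.0 / 10.0
        assert samples.cv1.var() == pytest.approx(expected, rel=0.05)
        assert samples.cv2.var() == pytest.approx(expected, rel=0.05)

    def test_double_well_both_wells_visited(self):
        pot = ToyPotential.double_well(barrier=6.0, tilt=0.0, ky=30.0)
        params = WTParams()
        _, samples = run_toy_metad(
            pot, params, langevin=(30.0, 0.2, 300.0), n_steps=20_000,
            n_walkers=4, seed=5, domain=((-1.9, 1.9), (-2.5, 2.5)),
        )
        assert (samples.cv1 < -0.5).sum() > 100
        assert (samples.cv1 > 0.5).sum() > 100

    def test_divergent_step_raises(self):
        # absurdly large timestep on a stiff well diverges immediately
        pot = ToyPotential.harmonic(kx=1e4, ky=1e4)
        with pytest.raises(StabilityError):
            run_toy_metad(
                pot, WTParams(), langevin=(1.0, 1.0, 300.0), n_steps=100,
                n_walkers=1, seed=0, x0=np.array([1.0, 1.0]),
                domain=((-4, 4), (-4, 4)),
            )
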
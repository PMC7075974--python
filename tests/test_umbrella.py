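"""Umbrella-sampling reaction coordinate, WHAM solver and barrier analysis."""

import numpy as np
import pytest

from hsp90kit.constants import rt
from hsp90kit.errors import (
    ConvergenceError,
    DisconnectedWindowsError,
    InvalidInputError,
)
from hsp90kit.synthetic import (
    DOUBLE_WELL_BARRIER,
    default_umbrella_benchmark,
    double_well,
    gen_umbrella_dataset,
)
from hsp90kit.umbrella import (
    BarrierReport,
    FreeEnergyProfile,
    ReactionGeometry,
    UmbrellaWindow,
    barrier_height,
    bias_potential,
    bootstrap_profile,
    reaction_coordinate,
    wham_solve,
)


# ---------------------------------------------------------------- oracle ---
def brute_force_wham(windows, n_bins, r_range, tol=1e-12, max_iter=500_000):
    """Scalar-loop WHAM fixed-point iteration, independent of the package's
    vectorized solver. Returns (centers, g) anchored to min 0."""
    import math

    kt = rt(windows[0].temperature)
    lo, hi = r_range
    edges = [lo + (hi - lo) * i / n_bins for i in range(n_bins + 1)]
    centers = [(edges[i] + edges[i + 1]) / 2 for i in range(n_bins)]
    counts = [[0] * n_bins for _ in windows]
    for wi, w in enumerate(windows):
        for s in w.samples:
            if lo <= s <= hi:
                j = min(int((s - lo) / (hi - lo) * n_bins), n_bins - 1)
                counts[wi][j] += 1
    n_j = [sum(counts[wi][j] for wi in range(len(windows))) for j in range(n_bins)]
    n_i = [sum(counts[wi]) for wi in range(len(windows))]
    pref = [0.5 if w.bias_convention == "half_k" else 1.0 for w in windows]
    u = [
        [
            pref[wi] * w.force_constant * (centers[j] - w.center) ** 2
            for j in range(n_bins)
        ]
        for wi, w in enumerate(windows)
    ]
    f = [0.0] * len(windows)
    for _ in range(max_iter):
        p = []
        for j in range(n_bins):
            denom = sum(
                n_i[wi] * math.exp((f[wi] - u[wi][j]) / kt)
                for wi in range(len(windows))
            )
            p.append(n_j[j] / denom if denom > 0 else 0.0)
        total = sum(p)
        p = [x / total for x in p]
        f_new = []
        for wi in range(len(windows)):
            z = sum(math.exp(-u[wi][j] / kt) * p[j] for j in range(n_bins))
            f_new.append(-kt * math.log(z))
        f_new = [x - f_new[0] for x in f_new]
        delta = max(abs(a - b) for a, b in zip(f, f_new))
        f = f_new
        if delta < tol:
            break
    g = [(-kt * math.log(x) if n_j[j] > 0 else float("nan")) for j, x in enumerate(p)]
    gmin = min(x for j, x in enumerate(g) if n_j[j] > 0)
    g = [x - gmin for x in g]
    return np.array(centers), np.array(g)


def _aligned_rms(profile, truth_fn):
    """RMS deviation from an analytic profile after removing the free offset."""
    mask = profile.populated
    g_true = truth_fn(profile.bin_centers[mask])
    diff = profile.g[mask] - (g_true - g_true.min())
    diff = diff - diff.mean()
    return float(np.sqrt(np.mean(diff**2)))


# ------------------------------------------------- reaction coordinate ----
class TestReactionCoordinate:
    def test_cancellation(self):
        assert reaction_coordinate(ReactionGeometry(1.0, 1.0, 1.0, 1.0)) == 0.0

    def test_direct_arithmetic(self):
        geom = ReactionGeometry(r1=1.0, r2=1.8, r3=2.0, r4=2.1)
        assert reaction_coordinate(geom) == pytest.approx(0.9)

    def test_antisymmetry_under_forming_breaking_swap(self):
        geom = ReactionGeometry(r1=1.1, r2=1.7, r3=2.2, r4=2.5)
        swapped = ReactionGeometry(r1=1.7, r2=1.1, r3=2.5, r4=2.2)
        assert reaction_coordinate(swapped) == pytest.approx(
            -reaction_coordinate(geom)
        )

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_invalid_distances_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            ReactionGeometry(r1=bad, r2=1.0, r3=1.0, r4=1.0)


# ------------------------------------------------------ bias potential ----
class TestBiasPotential:
    @pytest.mark.parametrize(
        "k, dr, expected",
        [(100.0, 0.0, 0.0), (100.0, 0.1, 0.5), (500.0, 0.1, 2.5)],
    )
    def test_half_k_convention(self, k, dr, expected):
        w = UmbrellaWindow(center=1.0, force_constant=k, samples=[1.0])
        assert bias_potential(w, 1.0 + dr) == pytest.approx(expected)

    def test_full_k_convention_doubles(self):
        w = UmbrellaWindow(
            center=0.0, force_constant=100.0, samples=[0.0], bias_convention="full_k"
        )
        assert bias_potential(w, 0.1) == pytest.approx(1.0)


# ---------------------------------------------------------------- WHAM ----
class TestWhamSolve:
    def test_unbiased_gaussian_matches_boltzmann_inversion(self):
        # a zero-bias window sampling N(0, sigma) must invert to the
        # harmonic free energy RT R^2 / (2 sigma^2) + const
        sigma, temp, n = 0.3, 310.0, 100_000
        samples = np.random.default_rng(7).normal(0.0, sigma, n)
        w = UmbrellaWindow(center=0.0, force_constant=0.0, samples=samples,
                           temperature=temp)
        prof = wham_solve([w], n_bins=40, r_range=(-1.2, 1.2))
        kt = rt(temp)
        mask = prof.populated & (prof.counts >= 20)
        g_ref = kt * prof.bin_centers**2 / (2 * sigma**2)
        diff = prof.g[mask] - g_ref[mask]
        offset = np.average(diff, weights=prof.counts[mask])
        poisson = kt / np.sqrt(prof.counts[mask])
        assert np.all(np.abs(diff - offset) <= 3 * poisson)

    def test_pooling_identity(self):
        windows, _ = default_umbrella_benchmark(seed=3, n_per_window=400)
        w = windows[10]
        half = w.samples.size // 2
        split = [
            UmbrellaWindow(w.center, w.force_constant, w.samples[:half],
                           w.temperature),
            UmbrellaWindow(w.center, w.force_constant, w.samples[half:],
                           w.temperature),
        ]
        rest = windows[:10] + windows[11:]
        p_pooled = wham_solve(rest + [w], tol=1e-8)
        p_split = wham_solve(rest + split, tol=1e-8)
        np.testing.assert_allclose(p_split.g, p_pooled.g, atol=1e-5)

    def test_matches_independent_fixed_point_oracle(self):
        windows = gen_umbrella_dataset(
            double_well,
            centers=[-2.0, -1.7, -1.4],
            force_constant=100.0,
            n_per_window=300,
            seed=11,
            sampling_range=(-2.5, -1.0),
        )
        prof = wham_solve(windows, n_bins=30, r_range=(-2.5, -1.0), tol=1e-10)
        centers, g_oracle = brute_force_wham(windows, 30, (-2.5, -1.0))
        np.testing.assert_allclose(prof.bin_centers, centers, atol=1e-12)
        mask = prof.populated
        np.testing.assert_allclose(prof.g[mask], g_oracle[mask], atol=1e-8)

    def test_double_well_recovery_within_rms_bound(self):
        windows, truth = default_umbrella_benchmark(seed=1, n_per_window=1000)
        prof = wham_solve(windows)
        assert _aligned_rms(prof, truth) <= 0.2

    def test_disconnected_windows_raise(self):
        rng = np.random.default_rng(0)
        w1 = UmbrellaWindow(-2.0, 100.0, rng.normal(-2.0, 0.05, 200))
        w2 = UmbrellaWindow(2.0, 100.0, rng.normal(2.0, 0.05, 200))
        with pytest.raises(DisconnectedWindowsError):
            wham_solve([w1, w2])

    def test_max_iter_exhaustion_reports_residual(self):
        windows, _ = default_umbrella_benchmark(seed=5, n_per_window=200)
        with pytest.raises(ConvergenceError) as excinfo:
            wham_solve(windows, tol=1e-14, max_iter=3)
        assert excinfo.value.residual is not None
        assert excinfo.value.residual > 0

    def test_mixed_temperatures_rejected(self):
        w1 = UmbrellaWindow(0.0, 0.0, [0.1, 0.2], temperature=300.0)
        w2 = UmbrellaWindow(0.0, 0.0, [0.1, 0.2], temperature=310.0)
        with pytest.raises(InvalidInputError):
            wham_solve([w1, w2], r_range=(0.0, 0.4), n_bins=4)

    def test_profile_anchored_to_zero(self):
        windows, _ = default_umbrella_benchmark(seed=2, n_per_window=300)
        prof = wham_solve(windows)
        assert np.nanmin(prof.g) == pytest.approx(0.0, abs=1e-12)


# ----------------------------------------------------------- bootstrap ----
@pytest.fixture(scope="module")
def benchmark_windows():
    windows, _ = default_umbrella_benchmark(seed=4, n_per_window=300)
    return windows


class TestBootstrap:
    def test_seeded_reproducibility(self, benchmark_windows):
        a = bootstrap_profile(benchmark_windows, n_trials=10, seed=42)
        b = bootstrap_profile(benchmark_windows, n_trials=10, seed=42)
        np.testing.assert_array_equal(a.stderr, b.stderr)
        assert a.failures == b.failures == []

    def test_stderr_nonnegative(self, benchmark_windows):
        res = bootstrap_profile(benchmark_windows, n_trials=10, seed=1)
        finite = np.isfinite(res.stderr)
        assert np.all(res.stderr[finite] >= 0)

    def test_stderr_shrinks_with_sample_size(self):
        # quadrupling per-window samples should shrink errors roughly 2x
        small, _ = default_umbrella_benchmark(seed=6, n_per_window=250)
        large, _ = default_umbrella_benchmark(seed=6, n_per_window=1000)
        e_small = bootstrap_profile(small, n_trials=10, seed=9).stderr
        e_large = bootstrap_profile(large, n_trials=10, seed=9).stderr
        both = np.isfinite(e_small) & np.isfinite(e_large) & (e_small > 0)
        ratio = np.median(e_small[both] / e_large[both])
        assert 1.0 <= ratio <= 4.0  # 2.0 expected, +/-50%


# ------------------------------------------------------ barrier search ----
class TestBarrierHeight:
    def _flat_profile(self):
        centers = np.linspace(-1.0, 1.0, 21)
        return FreeEnergyProfile(
            bin_centers=centers,
            g=np.zeros(21),
            stderr=np.zeros(21),
            counts=np.ones(21),
        )

    def test_flat_profile_has_zero_barrier(self):
        rep = barrier_height(self._flat_profile(), (-1.0, -0.5), (-0.2, 0.2))
        assert rep.delta_g_barrier == 0.0

    def test_double_well_barrier_recovered(self):
        windows, _ = default_umbrella_benchmark(seed=1, n_per_window=1000)
        prof = wham_solve(windows)
        rep = barrier_height(prof, (-2.5, -1.5), (-0.8, 0.3))
        # bin width 0.1 over a quartic: resolution error well under 0.5
        assert rep.delta_g_barrier == pytest.approx(DOUBLE_WELL_BARRIER, abs=0.5)
        assert -2.3 < rep.reactant_r < -1.7
        assert -0.6 < rep.ts_r < 0.1

    def test_equal_ranges_on_monotone_profile(self):
        centers = np.linspace(0.0, 1.0, 11)
        g = np.linspace(0.0, 5.0, 11)
        prof = FreeEnergyProfile(centers, g, np.zeros(11), np.ones(11))
        rep = barrier_height(prof, (0.0, 1.0), (0.0, 1.0))
        assert rep.delta_g_barrier == pytest.approx(5.0)
        assert isinstance(rep, BarrierReport)

    def test_empty_range_raises(self):
        with pytest.raises(InvalidInputError):
            barrier_height(self._flat_profile(), (5.0, 6.0), (-0.2, 0.2))
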
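"""Seeded synthetic-data generators for every analysis stage.

Each generator draws from the exact statistical model its consuming fit or
estimator assumes — Boltzmann-distributed biased umbrella samples, a
two-state telegraph ion-pair trace, mono-exponential FRET decays, linear
NADH-depletion absorbance, Michaelis–Menten rate tables, ligand-depletion
titrations, paired HSQC peak lists, paired NOE intensities and
Guinier-regime scattering — and records its ground-truth parameters so
recovery tests are automatic.

Seeding: a single top-level seed fans out into independent per-generator
substreams via :func:`substream`, which spawns a numpy ``SeedSequence``
child keyed by a stable per-generator label hash. Adding a generator never
shifts another generator's stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, rt
from .errors import InvalidInputError
from .fits import TimeSeries, TitrationSeries, _bound_probe_fraction, _mm, _monoexp
from .ionpair import DistanceTrace
from .umbrella import DEFAULT_R_RANGE, UmbrellaWindow, bias_potential

import pandas as pd

__all__ = [
    "substream",
    "double_well",
    "DOUBLE_WELL_BARRIER",
    "gen_umbrella_dataset",
    "default_umbrella_benchmark",
    "gen_two_state_trace",
    "gen_fret_trace",
    "gen_adp_trace",
    "gen_mm_dataset",
    "gen_titration",
    "gen_peaklists",
    "gen_hetnoe",
    "gen_guinier_curve",
    "sphere_cloud",
]


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent child RNG for ``label`` under one top-level seed."""
    key = zlib.crc32(label.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


#: barrier height of the default double-well benchmark (kcal mol^-1)
DOUBLE_WELL_BARRIER = 10.0
_DW_CENTER = -0.25  # midpoint between the two minima
_DW_HALFWIDTH = 1.75  # minima at center ± halfwidth, i.e. R = -2.0 and 1.5


def double_well(r) -> np.ndarray:
    """Symmetric quartic double well over the hydrolysis coordinate range.

    Minima (g = 0) at R = -2.0 and 1.5 Å, barrier 10 kcal/mol at R = -0.25 Å.
    """
    x = np.asarray(r, dtype=float) - _DW_CENTER
    w2 = _DW_HALFWIDTH**2
    return DOUBLE_WELL_BARRIER * (x**2 - w2) ** 2 / w2**2


def gen_umbrella_dataset(
    profile,
    centers,
    force_constant: float = 100.0,
    n_per_window: int = 1000,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
    sampling_range: tuple[float, float] | None = None,
    bias_convention: str = "half_k",
    grid_points: int = 4001,
) -> list[UmbrellaWindow]:
    """Boltzmann samples of a known free-energy profile under harmonic biases.

    Each window samples R from p(R) ∝ exp(-(G(R) + U_bias(R)) / RT) by
    inverse-CDF interpolation on a fine grid; this is the exact population
    an infinitely long restrained simulation would visit, so WHAM applied to
    the output should recover ``profile`` up to statistical noise.
    """
    lo, hi = sampling_range if sampling_range is not None else DEFAULT_R_RANGE
    grid = np.linspace(lo, hi, grid_points)
    g = np.asarray(profile(grid), dtype=float)
    if not np.all(np.isfinite(g)):
        raise InvalidInputError("profile must be finite over the sampling range")
    kt = rt(temperature)
    rng = substream(seed, "umbrella")
    windows = []
    for center in centers:
        dummy = UmbrellaWindow(
            center=center,
            force_constant=force_constant,
            samples=np.array([0.0]),
            temperature=temperature,
            bias_convention=bias_convention,
        )
        energy = g + np.asarray(bias_potential(dummy, grid))
        logp = -(energy - energy.min()) / kt
        p = np.exp(logp)
        z = np.trapezoid(p, grid)
        if not np.isfinite(z) or z <= 0:
            raise InvalidInputError(f"unnormalizable density for window {center}")
        cdf = np.concatenate(([0.0], np.cumsum((p[1:] + p[:-1]) / 2 * np.diff(grid))))
        cdf /= cdf[-1]
        u = rng.uniform(0.0, 1.0, size=n_per_window)
        samples = np.interp(u, cdf, grid)
        windows.append(
            UmbrellaWindow(
                center=center,
                force_constant=force_constant,
                samples=samples,
                temperature=temperature,
                bias_convention=bias_convention,
            )
        )
    return windows


def default_umbrella_benchmark(
    seed: int = 0, n_per_window: int = 1000
) -> tuple[list[UmbrellaWindow], object]:
    """The standard double-well recovery benchmark: windows every 0.15 Å at
    k = 100 kcal/mol/Å^2 across the full coordinate range. Returns the
    windows and the truth profile callable."""
    centers = np.arange(-2.85, 2.56, 0.15)
    windows = gen_umbrella_dataset(
        double_well,
        centers,
        force_constant=100.0,
        n_per_window=n_per_window,
        seed=seed,
    )
    return windows, double_well


def gen_two_state_trace(
    k_open: float = 0.02,
    k_close: float = 0.02,
    mean_closed: float = 4.0,
    mean_open: float = 8.0,
    sd: float = 0.4,
    dt: float = 1.0,
    t_total: float = 10_000.0,
    seed: int = 0,
) -> tuple[DistanceTrace, np.ndarray]:
    """Telegraph ion-pair distance trace with Gaussian observation noise.

    ``k_open`` is the closed→open switching rate and ``k_close`` the
    open→closed rate (ns^-1); states are propagated with the exact two-state
    CTMC transition probabilities over each frame interval ``dt`` (ns).
    Returns the noisy trace and the underlying true state labels
    ("open"/"closed" per frame).
    """
    if k_open <= 0 or k_close <= 0:
        raise InvalidInputError("switching rates must be > 0")
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    if mean_closed <= 0 or mean_open <= 0:
        raise InvalidInputError("state means must be positive")
    n = int(round(t_total / dt))
    if n < 1:
        raise InvalidInputError("t_total too short for one frame")
    rng = substream(seed, "telegraph")
    ktot = k_open + k_close
    p_open_stat = k_open / ktot
    decay = np.exp(-ktot * dt)
    # exact CTMC propagator rows: P(next=open | current)
    p_open_from_open = p_open_stat + (1 - p_open_stat) * decay
    p_open_from_closed = p_open_stat * (1 - decay)
    states = np.empty(n, dtype=bool)  # True = open
    u = rng.uniform(size=n)
    state = u[0] < p_open_stat  # start from stationarity
    for i in range(n):
        if i > 0:
            p = p_open_from_open if state else p_open_from_closed
            state = u[i] < p
        states[i] = state
    means = np.where(states, mean_open, mean_closed)
    noise = rng.normal(0.0, sd, size=n) if sd > 0 else 0.0
    distances = np.clip(means + noise, 1e-6, None)
    times = np.arange(n) * dt
    labels = np.where(states, "open", "closed")
    return DistanceTrace(times=times, distances=distances), labels


def gen_fret_trace(
    a1: float = 1.0,
    t1: float = 50.0,
    y0: float = 0.2,
    sigma: float = 0.01,
    times: np.ndarray | None = None,
    seed: int = 0,
) -> TimeSeries:
    """Mono-exponential FRET relaxation y = A1 exp(-x/t1) + y0 plus noise.

    Defaults emulate a slow dimer re-opening chase (t1 = 50 min, apparent
    rate 0.02 min^-1) read out as a normalized FRET efficiency.
    """
    if t1 <= 0:
        raise InvalidInputError("t1 must be > 0")
    if times is None:
        times = np.linspace(0.0, 150.0, 200)
    times = np.asarray(times, dtype=float)
    rng = substream(seed, "fret")
    clean = _monoexp(times, a1, t1, y0)
    noise = rng.normal(0.0, sigma, size=times.size) if sigma > 0 else 0.0
    return TimeSeries(times=times, values=clean + noise, time_unit="min")


def gen_adp_trace(
    k: float = 0.50,
    eps_nadh: float = 6220.0,
    c_hsp90: float = 3e-6,
    a0: float = 1.0,
    sigma: float = 0.003,
    duration: float = 30.0,
    dt: float = 0.2,
    radicicol_time: float | None = 24.0,
    background_slope: float = -2e-4,
    seed: int = 0,
) -> TimeSeries:
    """NADH-depletion absorbance trace of an ATP-regenerating ADP-release assay.

    Before ``radicicol_time`` (min) the absorbance falls with slope
    -eps*c*k (AU min^-1); afterwards only the background slope remains,
    mimicking inhibition of the chaperone ATPase at the end of the run.
    """
    if k < 0 or eps_nadh <= 0 or c_hsp90 <= 0:
        raise InvalidInputError("k must be >= 0 and eps, c > 0")
    times = np.arange(0.0, duration + dt / 2, dt)
    signal_slope = -eps_nadh * c_hsp90 * k + background_slope
    if radicicol_time is None:
        radicicol_time = duration + 1.0
    pre = times <= radicicol_time
    values = np.empty_like(times)
    values[pre] = a0 + signal_slope * times[pre]
    a_break = a0 + signal_slope * radicicol_time
    values[~pre] = a_break + background_slope * (times[~pre] - radicicol_time)
    rng = substream(seed, "adp")
    if sigma > 0:
        values = values + rng.normal(0.0, sigma, size=times.size)
    return TimeSeries(times=times, values=values, time_unit="min")


def gen_mm_dataset(
    vmax: float = 0.5,
    km: float = 0.4,
    concentrations: np.ndarray | None = None,
    sigma: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Michaelis–Menten rate table over an ATP titration (mM).

    Defaults span the 0.1–5 mM substrate range of a chaperone ATPase assay.
    """
    if concentrations is None:
        concentrations = np.array([0.1, 0.2, 0.4, 0.8, 1.5, 2.5, 3.5, 5.0])
    concentrations = np.asarray(concentrations, dtype=float)
    rng = substream(seed, "mm")
    v = _mm(concentrations, vmax, km)
    if sigma > 0:
        v = v + rng.normal(0.0, sigma, size=v.size)
    return concentrations, v


def gen_titration(
    kd: float = 1e-7,
    f_p: float = 0.05,
    f_pl: float = 0.25,
    c_receptor: float = 5e-7,
    c_probe: float = 2e-7,
    concentrations: np.ndarray | None = None,
    sigma: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Competition anisotropy titration from the quadratic depletion isotherm."""
    if concentrations is None:
        concentrations = np.concatenate(
            ([0.0], np.logspace(-9, -4.5, 14))
        )
    concentrations = np.asarray(concentrations, dtype=float)
    fb = _bound_probe_fraction(concentrations, kd, c_receptor, c_probe)
    r = f_p + (f_pl - f_p) * fb
    rng = substream(seed, "titration")
    if sigma > 0:
        r = r + rng.normal(0.0, sigma, size=r.size)
    return TitrationSeries(
        concentrations=concentrations,
        anisotropy=r,
        c_receptor=c_receptor,
        c_probe=c_probe,
    )


def gen_peaklists(
    n_residues: int = 50,
    perturbed: tuple[int, ...] = (30, 31, 32, 33, 34),
    dh: float = 0.1,
    dn: float = 0.5,
    sigma_h: float = 0.0,
    sigma_n: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired HSQC peak lists: a reference and a state with shifted peaks.

    Residues in ``perturbed`` move by (dh, dn) ppm in the second list;
    optional Gaussian ppm noise on both dimensions of both lists.
    """
    rng = substream(seed, "peaklists")
    residues = np.arange(1, n_residues + 1)
    h = rng.uniform(7.0, 9.5, size=n_residues)
    n15 = rng.uniform(105.0, 130.0, size=n_residues)
    base = pd.DataFrame({"residue": residues, "h_ppm": h, "n_ppm": n15})
    shifted = base.copy()
    mask = shifted["residue"].isin(perturbed)
    shifted.loc[mask, "h_ppm"] += dh
    shifted.loc[mask, "n_ppm"] += dn
    if sigma_h > 0 or sigma_n > 0:
        for df in (base, shifted):
            df["h_ppm"] += rng.normal(0.0, sigma_h, size=n_residues)
            df["n_ppm"] += rng.normal(0.0, sigma_n, size=n_residues)
    return base, shifted


def gen_hetnoe(
    true_ratio: float = 0.58,
    i_ref: float = 1.0,
    noise_rmsd: float = 0.02,
    seed: int = 0,
) -> tuple[float, float]:
    """One saturated/reference intensity pair at a given true NOE ratio.

    Both intensities carry i.i.d. Gaussian baseplane noise of the given RMSD.
    """
    rng = substream(seed, "hetnoe")
    i_sat = true_ratio * i_ref + rng.normal(0.0, noise_rmsd)
    i_ref_obs = i_ref + rng.normal(0.0, noise_rmsd)
    return i_sat, i_ref_obs


def gen_guinier_curve(
    rg: float = 53.1,
    i0: float = 1.0,
    q: np.ndarray | None = None,
    rel_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Guinier-regime scattering curve I(q) = I0 exp(-q^2 Rg^2 / 3).

    Default q grid covers q*Rg <= 1.3 for the given Rg. Returns (q, I, σ)
    with multiplicative Gaussian noise of relative size ``rel_sigma``.
    """
    if rg <= 0 or i0 <= 0:
        raise InvalidInputError("rg and i0 must be > 0")
    if q is None:
        q = np.linspace(1e-3, 1.3 / rg, 60)
    q = np.asarray(q, dtype=float)
    clean = i0 * np.exp(-(q**2) * rg**2 / 3.0)
    sigma = np.maximum(rel_sigma * clean, 1e-12)
    rng = substream(seed, "guinier")
    intensity = clean + rng.normal(0.0, sigma) if rel_sigma > 0 else clean
    return q, intensity, sigma


def sphere_cloud(radius: float = 50.0, n: int = 3000, seed: int = 0) -> np.ndarray:
    """Uniform-density ball of points (Å); Rg of the continuum is
    sqrt(3/5) * radius."""
    rng = substream(seed, "sphere")
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    r = radius * rng.uniform(0.0, 1.0, size=(n, 1)) ** (1.0 / 3.0)
    return pts * r
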
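"""Fits for the standard biophysical assays around the Hsp90 cycle.

Covers the quantitative readouts used to characterize chaperone
conformational kinetics and structure:

* mono-exponential FRET opening/closing kinetics, y = A1 exp(-x/t1) + y0,
  with the apparent rate k_app = 1/t1;
* NADH-coupled ADP-release assay: linear absorbance depletion converted to a
  turnover rate k = -m / (eps_NADH * c_Hsp90 * path);
* Michaelis–Menten ATPase saturation, v = Vmax [ATP] / (K_M + [ATP]);
* fluorescence-anisotropy binding with ligand depletion (single-site
  quadratic isotherm);
* combined 1H/15N chemical-shift perturbation,
  Δδ = sqrt(Δδ_H^2 + (α Δδ_N)^2) with α = 0.1689;
* steady-state heteronuclear NOE ratios with baseplane-noise propagation;
* SAXS Guinier fits (ln I vs q^2, q·Rg ≤ 1.3) and the pair-distance
  distribution P(r) with its radius of gyration computed directly from
  atomic coordinates.

All nonlinear fits are Levenberg–Marquardt via lmfit with log-linear or
range-based starting heuristics; linear steps use ordinary or weighted
least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model

from .errors import InvalidInputError

__all__ = [
    "TimeSeries",
    "TitrationSeries",
    "FitResult",
    "fit_monoexponential",
    "adp_release_rate",
    "fit_adp_trace",
    "fit_michaelis_menten",
    "fit_anisotropy_competition",
    "csp",
    "het_noe",
    "guinier_fit",
    "pr_from_coordinates",
    "PrResult",
    "CSP_ALPHA",
    "EPS_NADH",
]

#: 1H/15N shift-range scaling factor in the combined CSP
CSP_ALPHA = 0.1689
#: NADH molar extinction coefficient at 340 nm, M^-1 cm^-1 (standard value)
EPS_NADH = 6220.0


@dataclass
class TimeSeries:
    """A sampled signal with declared time units."""

    times: np.ndarray
    values: np.ndarray
    time_unit: str = "min"
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise InvalidInputError("times and values differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.size != self.times.size:
                raise InvalidInputError("sigma length mismatch")


@dataclass
class TitrationSeries:
    """Anisotropy vs titrant concentration at fixed receptor and probe."""

    concentrations: np.ndarray  # titrant, M
    anisotropy: np.ndarray
    c_receptor: float  # M, e.g. Hsp90
    c_probe: float  # M, labelled species

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.concentrations.size != self.anisotropy.size:
            raise InvalidInputError("length mismatch")
        if np.any(self.concentrations < 0):
            raise InvalidInputError("concentrations must be >= 0")
        if np.any(np.diff(self.concentrations) < 0):
            raise InvalidInputError("concentrations must be non-decreasing")
        if self.c_receptor <= 0 or self.c_probe <= 0:
            raise InvalidInputError("receptor and probe concentrations must be > 0")


@dataclass
class FitResult:
    """Parameter estimates with standard errors plus residual diagnostics."""

    params: dict[str, float]
    stderr: dict[str, float]
    residuals: np.ndarray
    success: bool
    model_tag: str
    extras: dict[str, float] = field(default_factory=dict)
    message: str = ""

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def _result_from_lmfit(out, model_tag: str, extras=None) -> FitResult:
    params = {name: float(p.value) for name, p in out.params.items()}
    stderr = {
        name: (float(p.stderr) if p.stderr is not None else math.nan)
        for name, p in out.params.items()
    }
    return FitResult(
        params=params,
        stderr=stderr,
        residuals=np.asarray(out.residual),
        success=bool(out.success),
        model_tag=model_tag,
        extras=extras or {},
        message=out.message or "",
    )


def _monoexp(x, a1, t1, y0):
    return a1 * np.exp(-x / t1) + y0


def fit_monoexponential(ts: TimeSeries) -> FitResult:
    """Fit y = A1 exp(-x/t1) + y0 and report the apparent rate k_app = 1/t1.

    Starting values come from a log-linear pre-fit of |y - y0_guess|; a fit
    converging to t1 <= 0 is rejected. ``extras`` carries k_app and its
    propagated error (sigma_k = sigma_t1 / t1^2) in reciprocal time units.
    """
    x, y = ts.times, ts.values
    if x.size < 4:
        raise InvalidInputError("need at least 4 points for a mono-exponential fit")
    if np.ptp(y) == 0:
        raise InvalidInputError("signal is constant; no decay to fit")
    y0_guess = y[-1]
    a1_guess = y[0] - y0_guess
    # log-linear pre-fit for the time constant
    resid = (y - y0_guess) / (a1_guess if a1_guess != 0 else 1.0)
    ok = resid > 1e-3
    if np.count_nonzero(ok) >= 2:
        slope = np.polyfit(x[ok], np.log(resid[ok]), 1)[0]
        t1_guess = -1.0 / slope if slope < 0 else (x[-1] - x[0]) / 3.0
    else:
        t1_guess = (x[-1] - x[0]) / 3.0
    t1_guess = max(t1_guess, (x[1] - x[0]) / 10.0)

    model = Model(_monoexp)
    params = model.make_params(a1=a1_guess, t1=t1_guess, y0=y0_guess)
    params["t1"].set(min=1e-12)
    weights = 1.0 / ts.sigma if ts.sigma is not None else None
    out = model.fit(y, params, x=x, weights=weights)
    t1 = out.params["t1"].value
    if t1 <= 0:
        raise InvalidInputError(f"fit converged to non-positive t1 = {t1}")
    t1_err = out.params["t1"].stderr
    extras = {
        "k_app": 1.0 / t1,
        "k_app_stderr": (t1_err / t1**2) if t1_err is not None else math.nan,
    }
    return _result_from_lmfit(out, "monoexponential", extras)


def adp_release_rate(
    slope: float,
    eps_nadh: float = EPS_NADH,
    c_hsp90: float = 3e-6,
    path_cm: float = 1.0,
) -> float:
    """Convert an NADH-absorbance slope (AU min^-1) to a turnover rate.

    k = -m / (eps_NADH * c_Hsp90 * path); a negative slope (NADH depletion)
    gives a positive release rate in min^-1.
    """
    if eps_nadh <= 0 or c_hsp90 <= 0 or path_cm <= 0:
        raise InvalidInputError("extinction, concentration and path must be > 0")
    return -slope / (eps_nadh * c_hsp90 * path_cm)


def fit_adp_trace(
    ts: TimeSeries,
    fit_window: tuple[float, float] | None = None,
    background_slope: float = 0.0,
    eps_nadh: float = EPS_NADH,
    c_hsp90: float = 3e-6,
    path_cm: float = 1.0,
) -> FitResult:
    """Linear-regression analysis of an NADH-depletion absorbance trace.

    Fits an ordinary least-squares line over ``fit_window`` (whole trace if
    None), subtracts the background slope (measured after inhibiting the
    ATPase, e.g. with radicicol), and converts the corrected slope to the
    ADP-release rate ``k`` (min^-1) in ``extras``.
    """
    x, y = ts.times, ts.values
    if fit_window is not None:
        lo, hi = fit_window
        mask = (x >= lo) & (x <= hi)
        if np.count_nonzero(mask) < 3:
            raise InvalidInputError(
                f"fit window {fit_window} contains fewer than 3 points"
            )
        x, y = x[mask], y[mask]
    design = np.column_stack([x, np.ones_like(x)])
    coef, rss, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    residuals = y - fitted
    dof = max(x.size - 2, 1)
    s2 = float(residuals @ residuals) / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    slope, intercept = float(coef[0]), float(coef[1])
    slope_err = math.sqrt(cov[0, 0])
    corrected = slope - background_slope
    k = adp_release_rate(corrected, eps_nadh, c_hsp90, path_cm)
    k_err = slope_err / (eps_nadh * c_hsp90 * path_cm)
    return FitResult(
        params={"slope": slope, "intercept": intercept},
        stderr={"slope": slope_err, "intercept": math.sqrt(cov[1, 1])},
        residuals=residuals,
        success=True,
        model_tag="adp_linear",
        extras={"k": k, "k_stderr": k_err, "background_slope": background_slope},
    )


def _mm(x, vmax, km):
    return vmax * x / (km + x)


def fit_michaelis_menten(concentrations, rates) -> FitResult:
    """Fit v = Vmax [S] / (K_M + [S]) to rate-vs-concentration data."""
    x = np.asarray(concentrations, dtype=float)
    v = np.asarray(rates, dtype=float)
    if np.unique(x).size < 3:
        raise InvalidInputError("need at least 3 distinct concentrations")
    model = Model(_mm)
    params = model.make_params(vmax=float(np.max(v)), km=float(np.median(x)))
    params["vmax"].set(min=0)
    params["km"].set(min=1e-30)
    out = model.fit(v, params, x=x)
    return _result_from_lmfit(out, "michaelis_menten")


def _bound_probe_fraction(c_titrant, kd, c_receptor, c_probe):
    """Single-site quadratic (ligand-depletion) isotherm.

    Labelled probe and unlabelled titrant compete with equal affinity for
    the receptor; the total ligand pool is c_probe + c_titrant and the
    labelled signal reports the pool's bound fraction.
    """
    c_l = c_probe + np.asarray(c_titrant, dtype=float)
    s = c_receptor + c_l + kd
    disc = np.sqrt(np.clip(s * s - 4.0 * c_receptor * c_l, 0.0, None))
    complex_conc = 0.5 * (s - disc)
    return complex_conc / c_l


def fit_anisotropy_competition(tit: TitrationSeries) -> FitResult:
    """Fit K_D, F_P, F_PL to a competition anisotropy titration.

    The anisotropy interpolates between the free-probe value F_P and the
    bound-complex value F_PL with the bound fraction from the quadratic
    ligand-depletion isotherm (no weak-binding approximation): adding
    unlabelled titrant dilutes the probe's share of the receptor, so the
    signal relaxes from F_PL toward F_P.
    """
    if tit.concentrations.size < 5:
        raise InvalidInputError("need at least 5 titration points")

    def aniso(x, kd, f_p, f_pl):
        fb = _bound_probe_fraction(x, kd, tit.c_receptor, tit.c_probe)
        return f_p + (f_pl - f_p) * fb

    r = tit.anisotropy
    model = Model(aniso)
    params = model.make_params(
        kd=max(tit.c_receptor / 10.0, 1e-12), f_p=float(r[-1]), f_pl=float(r[0])
    )
    params["kd"].set(min=1e-15)
    out = model.fit(r, params, x=tit.concentrations)
    if out.params["kd"].value <= 0:
        raise InvalidInputError("fit converged to non-positive K_D")
    return _result_from_lmfit(out, "anisotropy_competition")


def csp(
    peaks_a: pd.DataFrame, peaks_b: pd.DataFrame, alpha: float = CSP_ALPHA
) -> tuple[pd.DataFrame, list]:
    """Combined 1H/15N chemical-shift perturbation between two peak lists.

    Peak lists are DataFrames with columns ``residue``, ``h_ppm``, ``n_ppm``
    (and optionally ``resname``). Residues are matched by number;
    Δδ = sqrt(Δδ_H^2 + (α Δδ_N)^2) per match. Returns the per-residue table
    and the list of unmatched residue numbers (present in only one list).
    """
    for name, df in (("A", peaks_a), ("B", peaks_b)):
        missing = {"residue", "h_ppm", "n_ppm"} - set(df.columns)
        if missing:
            raise InvalidInputError(f"peak list {name} lacks columns {missing}")
        if df["residue"].duplicated().any():
            raise InvalidInputError(f"peak list {name} has duplicate residues")
    a = peaks_a.set_index("residue")
    b = peaks_b.set_index("residue")
    common = a.index.intersection(b.index)
    unmatched = sorted(set(a.index).symmetric_difference(b.index))
    if "resname" in a.columns and "resname" in b.columns:
        clash = common[(a.loc[common, "resname"] != b.loc[common, "resname"])]
        if len(clash):
            warnings.warn(
                f"residue name mismatch at {list(clash)}; matched by number anyway",
                stacklevel=2,
            )
    dh = a.loc[common, "h_ppm"] - b.loc[common, "h_ppm"]
    dn = a.loc[common, "n_ppm"] - b.loc[common, "n_ppm"]
    delta = np.sqrt(dh**2 + (alpha * dn) ** 2)
    table = pd.DataFrame(
        {"residue": common, "delta_ppm": delta.to_numpy()}
    ).reset_index(drop=True)
    return table, unmatched


def het_noe(i_sat: float, i_ref: float, noise_rmsd: float) -> tuple[float, float]:
    """Steady-state heteronuclear NOE ratio I_sat/I_ref with its error.

    The error propagates the spectral baseplane noise RMSD through both
    intensities: sigma = |ratio| sqrt((s/I_sat)^2 + (s/I_ref)^2).
    """
    if i_ref == 0:
        raise InvalidInputError("reference intensity must be nonzero")
    if noise_rmsd < 0:
        raise InvalidInputError("noise RMSD must be >= 0")
    ratio = i_sat / i_ref
    if i_sat == 0:
        err = abs(noise_rmsd / i_ref)
    else:
        err = abs(ratio) * math.sqrt(
            (noise_rmsd / i_sat) ** 2 + (noise_rmsd / i_ref) ** 2
        )
    return ratio, err


def guinier_fit(
    q: np.ndarray,
    intensity: np.ndarray,
    sigma: np.ndarray | None = None,
    qmax_rg: float = 1.3,
    max_rounds: int = 50,
) -> FitResult:
    """Guinier analysis: weighted linear fit of ln I vs q^2 at low q.

    ln I(q) = ln I0 - (Rg^2/3) q^2 over the largest low-q prefix satisfying
    q*Rg <= ``qmax_rg``, iterated to self-consistency. A non-negative slope
    (no Guinier decay — aggregation or non-globular scatter) is an error.
    ``extras`` carries ``rg`` (Å), ``i0`` and the number of points used.
    """
    q = np.asarray(q, dtype=float)
    i = np.asarray(intensity, dtype=float)
    if q.size != i.size or q.size < 3:
        raise InvalidInputError("need matching q/I arrays with >= 3 points")
    if np.any(i <= 0):
        raise InvalidInputError("intensities must be positive in the Guinier range")
    order = np.argsort(q)
    q, i = q[order], i[order]
    w = None
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)[order]
        # ln-space weights: sigma_lnI = sigma_I / I
        w = i / sigma

    def linfit(n):
        x = q[:n] ** 2
        y = np.log(i[:n])
        weights = w[:n] if w is not None else np.ones(n)
        wsum = np.sum(weights**2)
        xm = np.sum(weights**2 * x) / wsum
        ym = np.sum(weights**2 * y) / wsum
        sxx = np.sum(weights**2 * (x - xm) ** 2)
        slope = np.sum(weights**2 * (x - xm) * (y - ym)) / sxx
        intercept = ym - slope * xm
        resid = y - (intercept + slope * x)
        dof = max(n - 2, 1)
        s2 = np.sum((weights * resid) ** 2) / dof if sigma is not None else \
            np.sum(resid**2) / dof
        slope_err = math.sqrt(s2 / sxx)
        return slope, intercept, slope_err, resid

    n = q.size
    for _ in range(max_rounds):
        slope, intercept, slope_err, resid = linfit(n)
        if slope >= 0:
            raise InvalidInputError(
                "non-negative Guinier slope; data are not in a Guinier regime"
            )
        rg = math.sqrt(-3.0 * slope)
        n_new = int(np.searchsorted(q, qmax_rg / rg, side="right"))
        n_new = max(n_new, 3)
        if n_new == n:
            break
        n = n_new
    rg_err = (1.5 / rg) * slope_err if rg > 0 else math.nan
    return FitResult(
        params={"slope": float(slope), "ln_i0": float(intercept)},
        stderr={"slope": slope_err, "ln_i0": math.nan},
        residuals=resid,
        success=True,
        model_tag="guinier",
        extras={
            "rg": rg,
            "rg_stderr": rg_err,
            "i0": math.exp(intercept),
            "n_points": int(n),
        },
    )


@dataclass
class PrResult:
    """Pair-distance distribution of a point set."""

    bin_centers: np.ndarray  # Å
    pr: np.ndarray  # pair counts per bin (unnormalized P(r))
    d_max: float  # Å
    rg: float  # Å, exact second-moment value

    def normalized(self) -> np.ndarray:
        return self.pr / self.pr.sum()


def pr_from_coordinates(points: np.ndarray, bin_width: float = 1.0) -> PrResult:
    """P(r) histogram and radius of gyration from atomic coordinates.

    All pairwise distances enter a uniform-weight histogram of width
    ``bin_width``; D_max is the largest pair distance. Rg uses the exact
    pairwise identity Rg^2 = Σ_{i<j} d_ij^2 / N^2 (equivalently the second
    moment about the centroid), so it is free of binning error — two points
    a distance d apart give exactly Rg = d/2.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidInputError("points must be an (N, 3) array")
    n = pts.shape[0]
    if n < 2:
        raise InvalidInputError("need at least two points for P(r)")
    if bin_width <= 0:
        raise InvalidInputError("bin_width must be > 0")
    from scipy.spatial.distance import pdist

    d = pdist(pts)
    d_max = float(d.max())
    n_bins = max(int(math.ceil(d_max / bin_width)), 1)
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rg = math.sqrt(float(np.sum(d**2)) / n**2)
    return PrResult(bin_centers=centers, pr=counts.astype(float), d_max=d_max, rg=rg)
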
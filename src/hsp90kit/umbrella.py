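"""Umbrella-sampling free-energy profiles along the ATP-hydrolysis coordinate.

The reaction coordinate is a linear combination of the bond-forming and
bond-breaking distances of the concerted proton-transfer / phosphate-cleavage
step, R = r4 - r3 + r2 - r1 (Å). Biased sampling windows restrained along R
are combined into a single free-energy profile with the weighted histogram
analysis method (WHAM), with bootstrap error bars and a barrier-height
report that feeds the transition-state-theory rate layer.

Conventions
-----------
* The harmonic bias is U(R) = 1/2 k (R - R0)^2 by default. Published force
  constants do not always state whether the 1/2 is included, so each window
  declares its convention explicitly (``bias_convention`` of ``"half_k"`` or
  ``"full_k"``).
* Profiles are anchored so the minimum over populated bins is zero.
* Bins with zero samples carry NaN free energy and are excluded from
  anchoring and barrier searches.
* No statistical-inefficiency correction is applied to the samples; an
  optional per-window ``decorrelate_stride`` hook subsamples instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, rt
from .errors import ConvergenceError, DisconnectedWindowsError, InvalidInputError

__all__ = [
    "ReactionGeometry",
    "UmbrellaWindow",
    "FreeEnergyProfile",
    "BarrierReport",
    "BootstrapResult",
    "reaction_coordinate",
    "bias_potential",
    "wham_solve",
    "bootstrap_profile",
    "barrier_height",
    "DEFAULT_R_RANGE",
    "DEFAULT_BIN_WIDTH",
]

#: coordinate range of the hydrolysis pathway, reactants to products (Å)
DEFAULT_R_RANGE = (-2.9, 2.6)
#: default histogram resolution (Å)
DEFAULT_BIN_WIDTH = 0.1


@dataclass(frozen=True)
class ReactionGeometry:
    """The four distances defining one point along the hydrolysis pathway.

    r1/r2 are the proton-transfer forming/breaking distances, r3/r4 the
    phosphate bond-forming/breaking distances, all in Å.
    """

    r1: float
    r2: float
    r3: float
    r4: float

    def __post_init__(self):
        for name in ("r1", "r2", "r3", "r4"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidInputError(
                    f"distance {name} must be positive and finite, got {v}"
                )


def reaction_coordinate(geom: ReactionGeometry) -> float:
    """Reaction coordinate R = r4 - r3 + r2 - r1 (Å).

    Negative R is reactant-like (bonds to be broken still intact), positive R
    product-like.
    """
    return geom.r4 - geom.r3 + geom.r2 - geom.r1


@dataclass
class UmbrellaWindow:
    """One biased sampling window along R.

    Parameters
    ----------
    center:
        Bias center R0 (Å).
    force_constant:
        Harmonic force constant k (kcal mol^-1 Å^-2); 0 means unbiased.
    samples:
        Observed R values (Å) in sampling order.
    temperature:
        Sampling temperature (K).
    bias_convention:
        ``"half_k"`` for U = 1/2 k (R-R0)^2 (default) or ``"full_k"`` for
        U = k (R-R0)^2.
    decorrelate_stride:
        Optional subsampling stride for correlated samples (1 = keep all).
    """

    center: float
    force_constant: float
    samples: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    bias_convention: str = "half_k"
    decorrelate_stride: int = 1

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise InvalidInputError("window has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("window samples must be finite")
        if self.force_constant < 0:
            raise InvalidInputError(
                f"force_constant must be >= 0, got {self.force_constant}"
            )
        if self.temperature <= 0:
            raise InvalidInputError(
                f"temperature must be > 0 K, got {self.temperature}"
            )
        if self.bias_convention not in ("half_k", "full_k"):
            raise InvalidInputError(
                f"bias_convention must be 'half_k' or 'full_k', "
                f"got {self.bias_convention!r}"
            )
        if self.decorrelate_stride < 1:
            raise InvalidInputError("decorrelate_stride must be >= 1")

    @property
    def effective_samples(self) -> np.ndarray:
        return self.samples[:: self.decorrelate_stride]


def bias_potential(window: UmbrellaWindow, r) -> np.ndarray | float:
    """Harmonic restraint energy at coordinate value(s) ``r`` (kcal mol^-1)."""
    prefactor = 0.5 if window.bias_convention == "half_k" else 1.0
    return prefactor * window.force_constant * (np.asarray(r, float) - window.center) ** 2


@dataclass
class FreeEnergyProfile:
    """Binned free energy g(R) with bootstrap errors.

    ``g`` is NaN in unpopulated bins; the minimum over populated bins is 0.
    """

    bin_centers: np.ndarray
    g: np.ndarray
    stderr: np.ndarray
    counts: np.ndarray

    @property
    def populated(self) -> np.ndarray:
        return self.counts > 0

    def interpolate(self, r: float) -> float:
        """Linear interpolation of g over populated bins."""
        mask = self.populated
        return float(np.interp(r, self.bin_centers[mask], self.g[mask]))


@dataclass(frozen=True)
class BarrierReport:
    """Free-energy barrier between a reactant basin and a transition region."""

    reactant_r: float
    ts_r: float
    delta_g_barrier: float


def _make_bins(n_bins, r_range):
    lo, hi = r_range
    if not (hi > lo):
        raise InvalidInputError(f"invalid coordinate range {r_range}")
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def _check_connected(hist: np.ndarray) -> None:
    """Require window histograms to form one overlap-connected component."""
    n_win = hist.shape[0]
    if n_win <= 1:
        return
    populated = hist > 0
    parent = list(range(n_win))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_win):
        for j in range(i + 1, n_win):
            if np.any(populated[i] & populated[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = {find(i) for i in range(n_win)}
    if len(roots) > 1:
        raise DisconnectedWindowsError(
            f"umbrella windows split into {len(roots)} histogram groups with "
            "no mutual bin overlap; add bridging windows or widen bins"
        )


def wham_solve(
    windows: list[UmbrellaWindow],
    n_bins: int = 55,
    r_range: tuple[float, float] = DEFAULT_R_RANGE,
    tol: float = 1e-5,
    max_iter: int = 100_000,
) -> FreeEnergyProfile:
    """Self-consistent WHAM estimate of the unbiased free-energy profile.

    Iterates the coupled histogram equations

        p_j ∝ n_j / Σ_i N_i exp(-β (U_i(R_j) - f_i)),
        exp(-β f_i) = Σ_j p_j exp(-β U_i(R_j)),

    until the largest change in any window free-energy constant f_i falls
    below ``tol`` (kcal mol^-1; default 1e-5). The returned profile is
    anchored to min 0 over populated bins, with ``stderr`` zero (use
    :func:`bootstrap_profile` for error bars).

    Raises
    ------
    DisconnectedWindowsError
        If window histograms do not overlap into a single group.
    ConvergenceError
        If ``max_iter`` is reached; carries the last residual.
    """
    if not windows:
        raise InvalidInputError("need at least one umbrella window")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise InvalidInputError(f"windows must share a temperature, got {temps}")
    kt = rt(windows[0].temperature)
    beta = 1.0 / kt

    edges, centers = _make_bins(n_bins, r_range)
    hist = np.empty((len(windows), n_bins))
    for i, w in enumerate(windows):
        hist[i], _ = np.histogram(w.effective_samples, bins=edges)
    n_j = hist.sum(axis=0)
    if np.count_nonzero(n_j) < 2:
        raise InvalidInputError("samples span fewer than two bins")
    _check_connected(hist)

    n_i = hist.sum(axis=1)  # in-range sample counts per window
    # Boltzmann factor of each window's bias at each bin center
    log_c = np.array([-beta * np.asarray(bias_potential(w, centers)) for w in windows])
    c_ij = np.exp(log_c)

    f = np.zeros(len(windows))  # window free-energy constants (kcal/mol)
    p = np.where(n_j > 0, n_j / n_j.sum(), 0.0)
    residual = np.inf
    for _ in range(max_iter):
        # denominator: Σ_i N_i exp(β f_i) c_ij
        denom = (n_i * np.exp(beta * f)) @ c_ij
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, n_j / denom, 0.0)
        p = p / p.sum()
        z = c_ij @ p
        f_new = -kt * np.log(z)
        f_new -= f_new[0]  # gauge fix: constants defined up to an offset
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not reach tol={tol} kcal/mol in {max_iter} iterations "
            f"(last residual {residual:.3e})",
            residual=residual,
        )

    with np.errstate(divide="ignore"):
        g = np.where(n_j > 0, -kt * np.log(np.where(n_j > 0, p, 1.0)), np.nan)
    g = g - np.nanmin(g)
    return FreeEnergyProfile(
        bin_centers=centers, g=g, stderr=np.zeros(n_bins), counts=n_j
    )


@dataclass
class BootstrapResult:
    """Per-bin bootstrap standard errors plus any failed-trial diagnostics."""

    stderr: np.ndarray
    n_trials: int
    failures: list[str] = field(default_factory=list)

    @property
    def n_success(self) -> int:
        return self.n_trials - len(self.failures)


def bootstrap_profile(
    windows: list[UmbrellaWindow],
    n_trials: int = 10,
    seed: int | None = None,
    n_bins: int = 55,
    r_range: tuple[float, float] = DEFAULT_R_RANGE,
    tol: float = 1e-5,
    max_iter: int = 100_000,
) -> BootstrapResult:
    """Monte-Carlo bootstrap error bars for the WHAM profile.

    Each trial resamples every window's samples with replacement, re-solves
    WHAM and re-anchors; the per-bin standard deviation over successful
    trials is returned. Ten trials is the conventional quick estimate.
    A trial whose WHAM solve fails is recorded in ``failures`` rather than
    silently dropped.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    failures: list[str] = []
    for trial in range(n_trials):
        resampled = []
        for w in windows:
            s = w.effective_samples
            idx = rng.integers(0, s.size, size=s.size)
            resampled.append(
                UmbrellaWindow(
                    center=w.center,
                    force_constant=w.force_constant,
                    samples=s[idx],
                    temperature=w.temperature,
                    bias_convention=w.bias_convention,
                )
            )
        try:
            prof = wham_solve(resampled, n_bins=n_bins, r_range=r_range, tol=tol,
                              max_iter=max_iter)
            profiles.append(prof.g)
        except (ConvergenceError, DisconnectedWindowsError, InvalidInputError) as exc:
            failures.append(f"trial {trial}: {exc}")
    if not profiles:
        raise ConvergenceError(
            f"all {n_trials} bootstrap trials failed: {failures}"
        )
    stack = np.vstack(profiles)
    with np.errstate(invalid="ignore"):
        n_ok = np.sum(np.isfinite(stack), axis=0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stderr = np.nanstd(stack, axis=0, ddof=1)
    stderr = np.where(n_ok >= 2, stderr, np.nan)
    return BootstrapResult(stderr=stderr, n_trials=n_trials, failures=failures)


def barrier_height(
    profile: FreeEnergyProfile,
    reactant_range: tuple[float, float],
    ts_range: tuple[float, float],
) -> BarrierReport:
    """Barrier ΔG‡ = max g over the transition-state range minus min g over
    the reactant range, with the extremum positions.

    Only populated bins count; ties resolve to the lowest-R bin.
    """
    centers, g = profile.bin_centers, profile.g
    pop = profile.populated

    def select(r_range, what):
        lo, hi = r_range
        mask = pop & (centers >= lo) & (centers <= hi)
        if not np.any(mask):
            raise InvalidInputError(
                f"{what} range {r_range} contains no populated bins"
            )
        return mask

    rmask = select(reactant_range, "reactant")
    tmask = select(ts_range, "transition-state")
    r_idx = np.flatnonzero(rmask)
    t_idx = np.flatnonzero(tmask)
    gmin_i = r_idx[int(np.argmin(g[rmask]))]  # argmin takes first on ties
    gmax_i = t_idx[int(np.argmax(g[tmask]))]
    # a TS maximum below the reactant minimum means no barrier along this cut
    dg = max(float(g[gmax_i] - g[gmin_i]), 0.0)
    return BarrierReport(
        reactant_r=float(centers[gmin_i]),
        ts_r=float(centers[gmax_i]),
        delta_g_barrier=dg,
    )
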
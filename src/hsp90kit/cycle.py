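"""Stochastic kinetic model of the Hsp90 chaperone cycle.

The cycle is modelled as a single-enzyme continuous-time Markov chain over
five conformational states:

    open -> closed1_ATP_inactive -> active -> closed2_ATP_active
         -> closed2_ADP_Pi -> open

The first three transitions are "closing" steps (ATP binding is lumped into
the first, taken as saturating), the closed2_ATP_active -> closed2_ADP_Pi
step is the chemical "catalysis" step, and closed2_ADP_Pi -> open is
product "release". Turnover is the number of release events per enzyme per
minute, the quantity an NADH-coupled ADP-release assay measures.

A decoupling variant can (i) accelerate catalysis by a fold factor,
(ii) slow every closing step by a fold factor, and (iii) add a futile
open -> open hydrolysis branch that burns ATP without ever forming the
closed state — the kinetic signature of a mutant whose catalysis is
decoupled from the conformational cycle.

Default rates are a documented calibration: closing steps 3 min^-1 each,
catalysis 1 min^-1, release 60 min^-1, giving a wild-type-scale turnover of
1/(3*(1/3) + 1 + 1/60) ≈ 0.496 min^-1 with closing and catalysis
contributing comparably to the cycle time.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidInputError

__all__ = [
    "Reaction",
    "CycleModel",
    "SSAResult",
    "SteadyStateResult",
    "STATES",
    "build_default_model",
    "build_variant",
    "steady_state",
    "simulate_ssa",
    "required_closing_reduction",
]

STATES = (
    "open",
    "closed1_ATP_inactive",
    "active",
    "closed2_ATP_active",
    "closed2_ADP_Pi",
)

VALID_TAGS = ("closing", "switching", "catalysis", "release", "decoupled")


@dataclass
class Reaction:
    source: str
    target: str
    rate: float  # min^-1
    tag: str

    def __post_init__(self):
        if self.rate < 0:
            raise InvalidInputError(f"rate must be >= 0, got {self.rate}")
        if self.tag not in VALID_TAGS:
            raise InvalidInputError(f"unknown reaction tag {self.tag!r}")
        if self.tag == "catalysis" and (
            self.source != "closed2_ATP_active" or self.target != "closed2_ADP_Pi"
        ):
            raise InvalidInputError(
                "the catalysis reaction must be closed2_ATP_active -> closed2_ADP_Pi"
            )
        if self.tag == "decoupled" and (self.source != "open" or self.target != "open"):
            raise InvalidInputError("the decoupled branch must be open -> open")


@dataclass
class CycleModel:
    states: tuple[str, ...] = STATES
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self):
        names = set(self.states)
        for r in self.reactions:
            if r.source not in names or r.target not in names:
                raise InvalidInputError(
                    f"reaction {r.source}->{r.target} references unknown state"
                )

    def rate_matrix(self) -> np.ndarray:
        """Off-diagonal transition rates Q[i, j] = rate(i -> j), min^-1.

        Self-loops (the decoupled branch) do not enter the matrix; they
        change no state and only add flux.
        """
        idx = {s: i for i, s in enumerate(self.states)}
        q = np.zeros((len(self.states), len(self.states)))
        for r in self.reactions:
            if r.source != r.target:
                q[idx[r.source], idx[r.target]] += r.rate
        return q

    def tagged(self, tag: str) -> list[Reaction]:
        return [r for r in self.reactions if r.tag == tag]

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "reactions": [
                {"source": r.source, "target": r.target, "rate": r.rate, "tag": r.tag}
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CycleModel":
        unknown = set(d) - {"states", "reactions"}
        if unknown:
            raise InvalidInputError(f"unknown model keys: {sorted(unknown)}")
        return cls(
            states=tuple(d.get("states", STATES)),
            reactions=[Reaction(**r) for r in d["reactions"]],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def build_default_model() -> CycleModel:
    """The calibrated five-state wild-type cycle (no decoupled branch)."""
    return CycleModel(
        reactions=[
            Reaction("open", "closed1_ATP_inactive", 3.0, "closing"),
            Reaction("closed1_ATP_inactive", "active", 3.0, "closing"),
            Reaction("active", "closed2_ATP_active", 3.0, "closing"),
            Reaction("closed2_ATP_active", "closed2_ADP_Pi", 1.0, "catalysis"),
            Reaction("closed2_ADP_Pi", "open", 60.0, "release"),
        ]
    )


def build_variant(
    model: CycleModel,
    f_cat: float = 1.0,
    f_close: float = 1.0,
    k_decoupled: float = 0.0,
) -> CycleModel:
    """Perturbed cycle: catalysis ×f_cat, closing steps ÷f_close, plus an
    optional futile open→open hydrolysis branch at ``k_decoupled`` min^-1."""
    if f_cat <= 0 or f_close <= 0:
        raise InvalidInputError("fold factors must be > 0")
    if k_decoupled < 0:
        raise InvalidInputError("k_decoupled must be >= 0")
    variant = copy.deepcopy(model)
    for r in variant.reactions:
        if r.tag == "catalysis":
            r.rate *= f_cat
        elif r.tag == "closing":
            r.rate /= f_close
    if k_decoupled > 0:
        variant.reactions.append(Reaction("open", "open", k_decoupled, "decoupled"))
    return variant


@dataclass
class SteadyStateResult:
    occupancies: dict[str, float]
    turnover: float  # release flux, min^-1 per enzyme
    decoupled_flux: float = 0.0  # futile hydrolysis flux, min^-1 per enzyme


def steady_state(model: CycleModel) -> SteadyStateResult:
    """Stationary distribution of the single-enzyme master equation.

    Solves π Q = 0 with Σπ = 1 (Q the generator built from the off-diagonal
    rate matrix). Turnover is the stationary release flux; the decoupled
    branch's futile flux is reported separately because it changes no state.
    """
    q = model.rate_matrix()
    n = len(model.states)
    gen = q.copy()
    np.fill_diagonal(gen, gen.diagonal() - q.sum(axis=1))
    # replace one balance equation by normalization
    a = np.vstack([gen.T[:-1], np.ones(n)])
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise InvalidInputError(f"singular stationary system: {exc}") from exc
    if not np.all(np.isfinite(pi)) or np.any(pi < -1e-9) or abs(pi.sum() - 1) > 1e-6:
        raise InvalidInputError(
            "no valid stationary distribution (disconnected or absorbing cycle)"
        )
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    occ = dict(zip(model.states, map(float, pi)))
    idx = {s: i for i, s in enumerate(model.states)}
    turnover = sum(r.rate * pi[idx[r.source]] for r in model.tagged("release"))
    dec_flux = sum(r.rate * pi[idx[r.source]] for r in model.tagged("decoupled"))
    return SteadyStateResult(
        occupancies=occ, turnover=float(turnover), decoupled_flux=float(dec_flux)
    )


@dataclass
class SSAResult:
    events: list[tuple[float, str, int]]  # (time min, tag, enzyme index)
    occupancies: dict[str, float]  # time-weighted fractions
    turnover: float  # release events / (enzyme * min)
    decoupled_rate: float  # futile hydrolysis events / (enzyme * min)
    seed: int | None
    t_end: float
    n_enzymes: int

    def event_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, tag, _ in self.events:
            counts[tag] = counts.get(tag, 0) + 1
        return counts

    def per_enzyme_release_rates(self) -> np.ndarray:
        counts = np.zeros(self.n_enzymes)
        for _, tag, enz in self.events:
            if tag == "release":
                counts[enz] += 1
        return counts / self.t_end


def simulate_ssa(
    model: CycleModel,
    t_end: float,
    n_enzymes: int = 1,
    seed: int | None = None,
    start_state: str = "open",
) -> SSAResult:
    """Exact stochastic simulation (Gillespie direct method).

    Each enzyme is an independent realization of the Markov chain starting
    from ``start_state``. Events are logged as (time, reaction tag, enzyme);
    occupancies are time-weighted over [0, t_end] pooled across enzymes.
    Bit-reproducible for a fixed seed.
    """
    if t_end <= 0:
        raise InvalidInputError("t_end must be > 0")
    if n_enzymes < 1:
        raise InvalidInputError("n_enzymes must be >= 1")
    if all(r.rate == 0 for r in model.reactions):
        raise InvalidInputError("all reaction rates are zero")
    idx = {s: i for i, s in enumerate(model.states)}
    # per-state reaction lists
    by_state: list[list[Reaction]] = [[] for _ in model.states]
    for r in model.reactions:
        if r.rate > 0:
            by_state[idx[r.source]].append(r)
    totals = np.array([sum(r.rate for r in rs) for rs in by_state])

    rng = np.random.default_rng(seed)
    events: list[tuple[float, str, int]] = []
    time_in_state = np.zeros(len(model.states))
    n_release = 0
    n_decoupled = 0
    for enz in range(n_enzymes):
        state = idx[start_state]
        t = 0.0
        while True:
            a0 = totals[state]
            if a0 == 0:
                time_in_state[state] += t_end - t
                break
            dt = rng.exponential(1.0 / a0)
            if t + dt >= t_end:
                time_in_state[state] += t_end - t
                break
            t += dt
            time_in_state[state] += dt
            u = rng.uniform(0, a0)
            acc = 0.0
            chosen = by_state[state][-1]
            for r in by_state[state]:
                acc += r.rate
                if u < acc:
                    chosen = r
                    break
            events.append((t, chosen.tag, enz))
            if chosen.tag == "release":
                n_release += 1
            elif chosen.tag == "decoupled":
                n_decoupled += 1
            state = idx[chosen.target]
    occ = dict(zip(model.states, time_in_state / (n_enzymes * t_end)))
    return SSAResult(
        events=events,
        occupancies={k: float(v) for k, v in occ.items()},
        turnover=n_release / (n_enzymes * t_end),
        decoupled_rate=n_decoupled / (n_enzymes * t_end),
        seed=seed,
        t_end=t_end,
        n_enzymes=n_enzymes,
    )


def required_closing_reduction(
    model: CycleModel, f_cat: float, tol: float = 1e-9
) -> float:
    """Closing-rate reduction that keeps turnover unchanged when catalysis is
    accelerated ``f_cat``-fold.

    Root-finds f_close in [1, 100] such that the variant's steady-state
    turnover equals the baseline's. For a unidirectional cycle this has the
    closed form f_close = 1 + (1 - 1/f_cat) * t_cat / t_close, where t_cat
    and t_close are the baseline catalysis and total closing times; the
    numerical root is found by bisection regardless.
    """
    if f_cat <= 0:
        raise InvalidInputError("f_cat must be > 0")
    baseline = steady_state(model).turnover

    def gap(f_close: float) -> float:
        return steady_state(build_variant(model, f_cat, f_close, 0.0)).turnover - baseline

    lo, hi = 1.0, 100.0
    g_lo, g_hi = gap(lo), gap(hi)
    if abs(g_lo) <= tol:
        return lo
    if g_lo * g_hi > 0:
        raise InvalidInputError(
            f"no matching f_close in [{lo}, {hi}]: turnover gaps "
            f"{g_lo:.3e} and {g_hi:.3e} have the same sign"
        )
    return float(brentq(gap, lo, hi, xtol=tol))
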
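"""Ion-pair (salt-bridge) conformational-switch analysis.

The Arg-32/Glu-33 ion pair in the Hsp90 N-terminal domain acts as a
conformational switch: its side-chain distance (conventionally Cζ of the
arginine to Cδ of the glutamate) telegraphs between a closed (< 5 Å) and an
open (> 5 Å) state, and the open state electrostatically tunes both the
hydrolysis barrier and the glutamate pKa. This module extracts distance
traces from labelled coordinate frames, classifies open/closed states,
measures dwell times, counts interdomain salt bridges, and evaluates the
coulombic 1/d barrier-tuning fit and the point-charge pKa-shift estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_KCAL, DEFAULT_TEMPERATURE, rt
from .errors import InvalidInputError

__all__ = [
    "AtomLabel",
    "LabelledFrame",
    "DistanceTrace",
    "StateTrace",
    "CoulombModel",
    "DwellReport",
    "sidechain_distance_trace",
    "classify_ionpair",
    "dwell_times",
    "count_ion_pairs",
    "fit_inverse_distance",
    "coulomb_pka_shift",
    "CLOSED_THRESHOLD",
    "SALT_BRIDGE_CUTOFF",
    "CHARGED_ATOMS",
]

#: open/closed split of the Arg/Glu side-chain distance (Å)
CLOSED_THRESHOLD = 5.0
#: heavy-atom distance defining a salt bridge (Å); common convention
SALT_BRIDGE_CUTOFF = 4.0

#: charged side-chain heavy atoms by residue name; sign of the formal charge.
#: OXT (C-terminal carboxylate) is negative on any residue.
CHARGED_ATOMS = {
    "ARG": {"NH1": +1, "NH2": +1, "NE": +1},
    "LYS": {"NZ": +1},
    "ASP": {"OD1": -1, "OD2": -1},
    "GLU": {"OE1": -1, "OE2": -1},
}

AtomLabel = tuple[str, int, str, str]  # (chain, residue number, resname, atom)


@dataclass
class LabelledFrame:
    """One coordinate frame: unique atom labels mapped to 3-D positions (Å)."""

    frame_time: float  # ns
    atoms: dict[AtomLabel, np.ndarray]

    def __post_init__(self):
        for label, xyz in self.atoms.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise InvalidInputError(f"bad coordinates for atom {label}: {xyz}")
            self.atoms[label] = xyz


@dataclass
class DistanceTrace:
    """Time series of an interatomic distance."""

    times: np.ndarray  # ns, strictly increasing
    distances: np.ndarray  # Å

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.size != self.distances.size:
            raise InvalidInputError("times and distances differ in length")
        if self.times.size == 0:
            raise InvalidInputError("empty distance trace")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(self.distances < 0) or not np.all(np.isfinite(self.distances)):
            raise InvalidInputError("distances must be finite and non-negative")


@dataclass
class StateTrace:
    """Open/closed labels per frame plus the threshold that produced them."""

    times: np.ndarray
    labels: np.ndarray  # array of "open"/"closed"
    threshold: float
    occupancy: dict[str, float] = field(default_factory=dict)


def sidechain_distance_trace(
    frames: list[LabelledFrame], atom_a: AtomLabel, atom_b: AtomLabel
) -> DistanceTrace:
    """Euclidean distance between two labelled atoms across frames.

    Coincident atoms (distance 0) are suspicious for real structures and
    trigger a warning, but the trace is still returned.
    """
    if not frames:
        raise InvalidInputError("no frames supplied")
    times = np.empty(len(frames))
    dists = np.empty(len(frames))
    for i, frame in enumerate(frames):
        for label in (atom_a, atom_b):
            if label not in frame.atoms:
                raise InvalidInputError(
                    f"atom {label} missing from frame {i} (t={frame.frame_time} ns)"
                )
        times[i] = frame.frame_time
        dists[i] = float(np.linalg.norm(frame.atoms[atom_a] - frame.atoms[atom_b]))
    if np.any(dists == 0):
        warnings.warn(
            f"coincident atoms {atom_a}/{atom_b} in "
            f"{int(np.sum(dists == 0))} frame(s)",
            stacklevel=2,
        )
    return DistanceTrace(times=times, distances=dists)


def classify_ionpair(
    trace: DistanceTrace, threshold: float = CLOSED_THRESHOLD
) -> StateTrace:
    """Label each frame closed (d <= threshold) or open (d > threshold).

    A distance exactly at the threshold counts as closed. Occupancies are
    the fraction of frames per label.
    """
    closed = trace.distances <= threshold
    labels = np.where(closed, "closed", "open")
    n = trace.distances.size
    occ = {
        "closed": float(np.sum(closed)) / n,
        "open": float(np.sum(~closed)) / n,
    }
    return StateTrace(
        times=trace.times, labels=labels, threshold=threshold, occupancy=occ
    )


@dataclass
class DwellReport:
    """Dwell times per state; censored (first/last) runs listed separately."""

    dwells: dict[str, np.ndarray]  # uncensored run durations, ns
    censored: dict[str, np.ndarray]
    means: dict[str, float]  # over uncensored runs; NaN if none


def dwell_times(
    states: StateTrace, frame_durations: np.ndarray | None = None
) -> DwellReport:
    """Contiguous-run dwell times per state.

    Frame spacing must be uniform unless explicit per-frame durations are
    given. The first and last runs are censored (their true length is
    unknown) and are reported separately, excluded from the means.
    """
    labels = np.asarray(states.labels)
    n = labels.size
    if n == 0:
        raise InvalidInputError("empty state trace")
    if frame_durations is None:
        if n > 1:
            dts = np.diff(states.times)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
                raise InvalidInputError(
                    "non-uniform frame spacing; supply frame_durations explicitly"
                )
            dt = float(dts[0])
        else:
            dt = 0.0
        frame_durations = np.full(n, dt)
    else:
        frame_durations = np.asarray(frame_durations, dtype=float)
        if frame_durations.size != n:
            raise InvalidInputError("frame_durations length mismatch")

    # run-length encode
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    run_labels = labels[starts]
    run_durs = np.array(
        [float(frame_durations[s:e].sum()) for s, e in zip(starts, ends)]
    )

    dwells: dict[str, list[float]] = {"open": [], "closed": []}
    censored: dict[str, list[float]] = {"open": [], "closed": []}
    n_runs = run_labels.size
    for i in range(n_runs):
        target = censored if (i == 0 or i == n_runs - 1) else dwells
        target[str(run_labels[i])].append(run_durs[i])
    means = {
        state: (float(np.mean(vals)) if vals else math.nan)
        for state, vals in dwells.items()
    }
    return DwellReport(
        dwells={k: np.asarray(v) for k, v in dwells.items()},
        censored={k: np.asarray(v) for k, v in censored.items()},
        means=means,
    )


def _charged_atoms_of(frame: LabelledFrame, residues: set[tuple[str, int]]):
    """Per residue: list of (sign, xyz) for its charged heavy atoms."""
    found: dict[tuple[str, int], list[tuple[int, np.ndarray]]] = {
        res: [] for res in residues
    }
    for (chain, resnum, resname, atom), xyz in frame.atoms.items():
        if (chain, resnum) not in residues:
            continue
        sign = CHARGED_ATOMS.get(resname, {}).get(atom)
        if sign is None and atom == "OXT":
            sign = -1
        if sign is not None:
            found[(chain, resnum)].append((sign, xyz))
    for res, atoms in list(found.items()):
        if not atoms:
            warnings.warn(f"residue {res} has no charged atoms; skipped",
                          stacklevel=3)
            del found[res]
    return found


def count_ion_pairs(
    frame: LabelledFrame,
    group_a: set[tuple[str, int]],
    group_b: set[tuple[str, int]],
    cutoff: float = SALT_BRIDGE_CUTOFF,
) -> tuple[int, list[tuple[tuple[str, int], tuple[str, int]]]]:
    """Count residue-level salt bridges between two disjoint residue groups.

    A residue pair counts once if any opposite-charge heavy-atom pair across
    the groups is within ``cutoff`` Å. Returns the count and the pair list.
    """
    if group_a & group_b:
        raise InvalidInputError("residue groups must be disjoint")
    atoms_a = _charged_atoms_of(frame, set(group_a))
    atoms_b = _charged_atoms_of(frame, set(group_b))
    pairs = []
    for res_a, alist in atoms_a.items():
        for res_b, blist in atoms_b.items():
            hit = any(
                sa * sb < 0 and np.linalg.norm(xa - xb) <= cutoff
                for sa, xa in alist
                for sb, xb in blist
            )
            if hit:
                pairs.append((res_a, res_b))
    pairs.sort()
    return len(pairs), pairs


def fit_inverse_distance(
    points: list[tuple[float, float]]
) -> tuple[float, float, np.ndarray]:
    """Fit ΔG‡(d) = a + b/d to (distance, barrier) points.

    Linear least squares in the transformed variable 1/d: ``a`` is the
    asymptotic (fully open) barrier, ``b`` the coulombic coupling strength
    (kcal Å mol^-1). Returns (a, b, residuals).
    """
    if len(points) < 3:
        raise InvalidInputError("need at least 3 points")
    d = np.asarray([p[0] for p in points], dtype=float)
    g = np.asarray([p[1] for p in points], dtype=float)
    if np.any(d <= 0):
        raise InvalidInputError("distances must be positive")
    if np.allclose(d, d[0]):
        raise InvalidInputError("all distances identical; 1/d model is rank-deficient")
    design = np.column_stack([np.ones_like(d), 1.0 / d])
    coef, *_ = np.linalg.lstsq(design, g, rcond=None)
    residuals = g - design @ coef
    return float(coef[0]), float(coef[1]), residuals


@dataclass(frozen=True)
class CoulombModel:
    """Point charges in a dielectric continuum (screened Coulomb's law)."""

    epsilon: float = 4.0
    q1: float = 1.0
    q2: float = -1.0
    coulomb_const: float = COULOMB_KCAL

    def __post_init__(self):
        if self.epsilon <= 0:
            raise InvalidInputError(f"epsilon must be > 0, got {self.epsilon}")

    def interaction_energy(self, d: float) -> float:
        """Screened pair interaction energy at separation d (kcal mol^-1)."""
        if d <= 0:
            raise InvalidInputError(f"distance must be > 0, got {d}")
        return self.coulomb_const * self.q1 * self.q2 / (self.epsilon * d)


def coulomb_pka_shift(
    d: float,
    model: CoulombModel = CoulombModel(),
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Point-charge estimate of the pKa shift from losing an ion-pair partner.

    Removing a charge at distance ``d`` changes the deprotonation free
    energy by the screened pair energy; in pKa units

        ΔpKa = C |q1 q2| / (ε d ln10 R T).

    For unit charges at ~5.5 Å in a protein-like ε = 4 this is about ten
    pKa units — the scale of the glutamate pKa upshift when the arginine
    swings away.
    """
    if d <= 0:
        raise InvalidInputError(f"distance must be > 0, got {d}")
    return model.coulomb_const * abs(model.q1 * model.q2) / (
        model.epsilon * d * math.log(10.0) * rt(temperature)
    )
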
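"""Inverse design: fabrication variables from desired material properties.

Given a desired Young's modulus E_des (kPa) and linewidth W_des (µm), the
fabrication coordinates (peg_pi, focus_z) are found by minimizing the
relative-residual objective

    ((E_des - Ê(x, z)) / E_des)^2 + ((W_des - Ŵ(x, z)) / W_des)^2,

where Ê and Ŵ are the kernel-interpolated properties of the calibration
state-space (see :mod:`nichefab.statespace`). The objective is smooth but can
be multimodal over sparse tables, so it is minimized by multistart
Nelder–Mead simplex search from Latin-hypercube starting points over the
record bounding box.

The unified monomer–photoinitiator index is then split into physical
concentrations on the calibration ellipse

    ((peg_pi - 50) / 40)^2 + ((pi_conc - 0.5) / 0.35)^2 = 1,

with peg_conc = peg_pi (% w/v monomer scale). Both ellipse branches give a
positive photoinitiator concentration; the default upper branch
(pi_conc = 0.5 + 0.35*sqrt(...)) makes the initiator rise with the unified
index mid-range, consistent with stiffer prints requiring more initiator.
Laser power is fixed at 100% PWM and scan velocity at a fixed constant; the
velocity's unit is carried explicitly because the hardware operated at a
fixed setting reported inconsistently (mm/min vs µm/min) and downstream
consumers must not guess.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .errors import DomainError, EnvelopeError, SolverError
from .statespace import PEG_PI_CENTER, PEG_PI_HALFWIDTH, StateSpace

__all__ = [
    "DesignTarget",
    "FabricationVariables",
    "SolveReport",
    "ENVELOPE",
    "objective",
    "solve_fabrication",
    "split_peg_pi",
    "check_envelope",
]

#: Characterized interpolation envelope: Young's moduli 2–20 kPa, linewidths
#: 40–300 µm, biochemical additives up to 4 mM.
ENVELOPE = {"E_kPa": (2.0, 20.0), "W_um": (40.0, 300.0), "conjugate_mM_max": 4.0}

#: Ellipse axes of the monomer–photoinitiator relationship.
ELLIPSE_PI_CENTER = 0.5
ELLIPSE_PI_HALFAXIS = 0.35

LASER_POWER_PCT = 100.0
SCAN_VELOCITY = 100.0
SCAN_VELOCITY_UNIT = "mm/min"


@dataclass(frozen=True)
class DesignTarget:
    """Desired material microproperties for one printed region."""

    E_des: float  # kPa
    W_des: float  # µm
    conjugates: tuple[tuple[str, float], ...] = ()  # (species, mM)

    def __post_init__(self):
        if not self.E_des > 0:
            raise DomainError(f"E_des must be > 0, got {self.E_des}")
        if not self.W_des > 0:
            raise DomainError(f"W_des must be > 0, got {self.W_des}")
        for name, conc in self.conjugates:
            if conc < 0:
                raise DomainError(f"conjugate {name!r} concentration {conc} < 0")


@dataclass(frozen=True)
class FabricationVariables:
    """Solved printer and photoresist settings for one region."""

    peg_pi: float
    focus_z: float
    peg_conc: float  # % w/v
    pi_conc: float  # % w/v
    laser_power: float = LASER_POWER_PCT  # % PWM, fixed
    scan_velocity: float = SCAN_VELOCITY
    scan_velocity_unit: str = SCAN_VELOCITY_UNIT
    conjugates: tuple[tuple[str, float], ...] = ()

    def ellipse_residual(self) -> float:
        t = (self.peg_pi - PEG_PI_CENTER) / PEG_PI_HALFWIDTH
        u = (self.pi_conc - ELLIPSE_PI_CENTER) / ELLIPSE_PI_HALFAXIS
        return abs(t * t + u * u - 1.0)


@dataclass(frozen=True)
class SolveReport:
    objective_value: float
    achieved_E: float
    achieved_W: float
    iterations: int
    converged: bool
    n_starts: int = 0


def check_envelope(target: DesignTarget) -> list[str]:
    """Violations of the characterized envelope, empty when valid."""
    issues = []
    lo, hi = ENVELOPE["E_kPa"]
    if not (lo <= target.E_des <= hi):
        issues.append(f"E_des={target.E_des} kPa outside [{lo}, {hi}] kPa")
    lo, hi = ENVELOPE["W_um"]
    if not (lo <= target.W_des <= hi):
        issues.append(f"W_des={target.W_des} um outside [{lo}, {hi}] um")
    cmax = ENVELOPE["conjugate_mM_max"]
    for name, conc in target.conjugates:
        if conc > cmax:
            issues.append(f"conjugate {name!r} at {conc} mM exceeds {cmax} mM")
    return issues


def objective(target: DesignTarget, space: StateSpace, x: float, z: float) -> float:
    """Squared relative mismatch of interpolated (E, W) against the target."""
    E, W, _ = space.interpolate(x, z)
    return ((target.E_des - E) / target.E_des) ** 2 + (
        (target.W_des - W) / target.W_des
    ) ** 2


def split_peg_pi(peg_pi: float, branch: str = "upper") -> tuple[float, float]:
    """Split the unified index into (peg_conc, pi_conc) on the ellipse.

    ``branch`` selects the upper (default) or lower root of the ellipse; at
    the domain apexes (peg_pi − 50 = ±40) the branches coincide at
    pi_conc = 0.5 exactly.
    """
    t = (peg_pi - PEG_PI_CENTER) / PEG_PI_HALFWIDTH
    if abs(t) > 1.0:
        raise DomainError(
            f"peg_pi={peg_pi} outside [{PEG_PI_CENTER - PEG_PI_HALFWIDTH}, "
            f"{PEG_PI_CENTER + PEG_PI_HALFWIDTH}]: no real solution"
        )
    if branch not in ("upper", "lower"):
        raise DomainError(f"branch must be 'upper' or 'lower', got {branch!r}")
    s = np.sqrt(max(0.0, 1.0 - t * t))
    sign = 1.0 if branch == "upper" else -1.0
    pi_conc = ELLIPSE_PI_CENTER + sign * ELLIPSE_PI_HALFAXIS * s
    return float(peg_pi), float(pi_conc)


def solve_fabrication(
    target: DesignTarget,
    space: StateSpace,
    n_starts: int = 8,
    seed: int | None = 0,
    branch: str = "upper",
    enforce_envelope: bool = True,
    objective_tol: float = 1e-10,
) -> tuple[FabricationVariables, SolveReport]:
    """Best-of-multistart local minimization of the design objective.

    Starting points are a seeded Latin-hypercube sample over the record
    bounding box, augmented with the three calibration grid coordinates where
    the objective is lowest (cheap deterministic seeding that guards against
    local minima in wobbly tables); each start runs an unconstrained
    Nelder–Mead simplex. Ties (objectives within 1e-12 of the best) break to
    the smallest ``|focus_z|``, then the smallest ``peg_pi``.
    """
    if enforce_envelope:
        issues = check_envelope(target)
        if issues:
            raise EnvelopeError("; ".join(issues))

    (x_lo, x_hi), (z_lo, z_hi) = space.bounding_box()
    if x_hi == x_lo:
        x_lo, x_hi = x_lo - 1.0, x_hi + 1.0
    if z_hi == z_lo:
        z_lo, z_hi = z_lo - 0.5, z_hi + 0.5
    sampler = qmc.LatinHypercube(d=2, seed=seed)
    unit = sampler.random(n=n_starts)
    starts = qmc.scale(unit, [x_lo, z_lo], [x_hi, z_hi])

    fun = lambda p: objective(target, space, p[0], p[1])
    # deterministic extra starts: best record coordinates by objective value
    coords = np.unique(np.column_stack([space.peg_pi, space.focus_z]), axis=0)
    grid_obj = np.array([fun(c) for c in coords])
    best_coords = coords[np.argsort(grid_obj)[:3]]
    starts = np.vstack([starts, best_coords])
    results = []
    total_iters = 0
    for p0 in starts:
        res = minimize(
            fun,
            p0,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 600},
        )
        total_iters += int(res.nit)
        results.append(res)

    best_obj = min(r.fun for r in results)
    # tie-break among near-equal minima: smallest |focus|, then smallest peg_pi
    tied = [r for r in results if r.fun <= best_obj + 1e-12]
    best = min(tied, key=lambda r: (abs(r.x[1]), r.x[0]))
    converged = bool(best.success and np.isfinite(best_obj))
    if not any(r.success for r in results) and best_obj > objective_tol:
        raise SolverError(
            "no start converged",
            best_point=tuple(best.x),
            best_objective=float(best_obj),
        )

    x_sol = float(np.clip(best.x[0], PEG_PI_CENTER - PEG_PI_HALFWIDTH,
                          PEG_PI_CENTER + PEG_PI_HALFWIDTH))
    z_sol = float(best.x[1])
    E, W, _ = space.interpolate(x_sol, z_sol)
    peg_conc, pi_conc = split_peg_pi(x_sol, branch=branch)
    fab = FabricationVariables(
        peg_pi=x_sol,
        focus_z=z_sol,
        peg_conc=peg_conc,
        pi_conc=pi_conc,
        conjugates=tuple(target.conjugates),
    )
    report = SolveReport(
        objective_value=float(objective(target, space, x_sol, z_sol)),
        achieved_E=E,
        achieved_W=W,
        iterations=total_iters,
        converged=converged,
        n_starts=n_starts,
    )
    return fab, report


def solution_to_json(fab: FabricationVariables, report: SolveReport) -> str:
    """Serialize a solution (variables + report) to a JSON document."""
    payload = {
        "fabrication_variables": asdict(fab),
        "solve_report": asdict(report),
    }
    return json.dumps(payload, indent=2)
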
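"""Rigid-body hovering-stability simulation.

A near-neutrally buoyant fish whose center of mass (COM) sits dorsal of
its center of buoyancy (COB) is an inverted pendulum: a small angular
displacement theta produces a destabilising torque

    tau_comcob = m * g * d * sin(theta),

with m body mass, g gravity and d the COM-COB separation.  Posture obeys
the torque balance

    I * dw/dt = tau_comcob(theta) - D(w) + tau_fin + tau_perturb(t),

where I = m * r_gyration^2 is the moment of inertia about the rotation
axis (radius of gyration proportional to body width for roll, body length
for pitch), D = drag_coeff * w is a linear hydrodynamic damping whose
coefficient scales with body surface area, and tau_fin is the corrective
torque from the fins.  Solving the balance for tau_fin recovers the
required-fin-torque form tau_fin = tau_comcob - I*alpha - D.

The fins are modelled as a saturated proportional-derivative controller,
tau_fin = clip(-kp*theta - kd*w, +-max_force*lever_arm): the animal senses
tilt and tilt rate and pushes back, with the achievable torque limited by
fin force times lever arm.  Perturbations are a sinusoidal ventilation
torque plus white torque noise (broadband internal/external disturbance).

Two energetic read-outs are provided:

* the mechanical stabilisation work ``integral |tau_fin * w| dt`` (both
  signs of work are paid; no elastic storage), and
* a fin-force actuation cost ``integral (|tau_fin| / lever)^1.5 dt`` for
  sweeps over fin position.  Drag-based fin force production satisfies
  F ~ v^2, so the hydrodynamic power F*v scales as F^1.5: a longer lever
  arm needs less force for the same torque and therefore less power.

Integration is fixed-step classical Runge-Kutta (RK4); noise is held
constant within each step so a trajectory is reproducible under a fixed
seed and step size.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RigidBodyParams",
    "FinController",
    "PerturbationSpec",
    "SimResult",
    "destabilizing_torque",
    "simulate",
    "stabilization_cost",
    "fin_force_cost",
    "sweep_and_fit",
    "DEFAULT_SWEEP_GRID",
]

G_DEFAULT = 9.81


@dataclass(frozen=True)
class RigidBodyParams:
    """Rigid-body parameters for one rotational axis.

    ``d_comcob`` is the physical COM-COB separation (m) driving the
    destabilising torque; ``r_gyration`` the radius of gyration (m) about
    the axis; ``drag_coeff`` the linear rotational damping (N m s rad^-1).
    """

    mass: float
    d_comcob: float
    r_gyration: float
    drag_coeff: float = 0.0
    g: float = G_DEFAULT

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.r_gyration <= 0:
            raise ValueError("mass and r_gyration must be positive")
        if self.d_comcob < 0:
            raise ValueError("d_comcob must be non-negative")
        if self.drag_coeff < 0:
            raise ValueError("drag_coeff must be non-negative")

    @property
    def inertia(self) -> float:
        """Moment of inertia I = m * r_gyration^2 (kg m^2)."""
        return self.mass * self.r_gyration**2

    @property
    def growth_rate(self) -> float:
        """Small-angle instability growth rate sqrt(m g d / I) (rad s^-1)."""
        return float(np.sqrt(self.mass * self.g * self.d_comcob / self.inertia))


@dataclass(frozen=True)
class FinController:
    """Saturated PD fin controller.

    ``lever_arm`` is the distance from the COM to the fin's point of force
    application; the available torque is ``max_force * lever_arm``.
    """

    lever_arm: float
    kp: float
    kd: float
    max_force: float = np.inf

    def __post_init__(self) -> None:
        if self.lever_arm <= 0:
            raise ValueError("lever_arm must be positive")
        if self.kp < 0 or self.kd < 0:
            raise ValueError("gains must be non-negative")

    @classmethod
    def tuned_for(
        cls,
        body: RigidBodyParams,
        lever_arm: float,
        stiffness_factor: float = 5.0,
        max_force: float = np.inf,
    ) -> "FinController":
        """Gains scaled to the body: kp at ``stiffness_factor`` times the
        critical stiffness m*g*d, kd at critical damping of the closed loop."""
        kp = stiffness_factor * body.mass * body.g * body.d_comcob
        net_k = max(kp - body.mass * body.g * body.d_comcob, 0.0)
        kd = 2.0 * float(np.sqrt(body.inertia * net_k))
        return cls(lever_arm=lever_arm, kp=kp, kd=kd, max_force=max_force)


@dataclass(frozen=True)
class PerturbationSpec:
    """Ventilation-like sinusoidal torque plus white torque noise."""

    ventilation_amp: float = 0.0
    ventilation_freq: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ventilation_amp < 0 or self.noise_sd < 0:
            raise ValueError("perturbation amplitudes must be non-negative")


@dataclass
class SimResult:
    """Trajectory and energetics of one stability run."""

    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    tau_fin: np.ndarray
    cost: float
    max_angle: float
    capsized: bool
    dt: float = field(default=0.0)


def destabilizing_torque(theta, body: RigidBodyParams):
    """COM-COB torque m*g*d*sin(theta): zero upright, amplifies tilt."""
    return body.mass * body.g * body.d_comcob * np.sin(theta)


def _fin_torque(theta: float, omega: float, ctl: FinController) -> float:
    tau = -ctl.kp * theta - ctl.kd * omega
    cap = ctl.max_force * ctl.lever_arm
    return float(np.clip(tau, -cap, cap))


def simulate(
    body: RigidBodyParams,
    controller: FinController,
    perturb: PerturbationSpec | None = None,
    dt: float = 1e-3,
    duration: float = 5.0,
    theta0: float = 0.0,
    omega0: float = 0.0,
) -> SimResult:
    """Integrate the torque balance with fixed-step RK4.

    If |theta| exceeds pi/2 the run is truncated and flagged ``capsized``
    (the upright linearisation has lost meaning) rather than raising.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    perturb = perturb or PerturbationSpec()
    n = int(round(duration / dt))
    rng = np.random.default_rng(perturb.seed)
    noise = (
        rng.normal(0.0, perturb.noise_sd, size=n)
        if perturb.noise_sd > 0
        else np.zeros(n)
    )
    inv_i = 1.0 / body.inertia
    mgd = body.mass * body.g * body.d_comcob
    w_vent = 2.0 * np.pi * perturb.ventilation_freq

    t = np.empty(n + 1)
    theta = np.empty(n + 1)
    omega = np.empty(n + 1)
    tau_fin = np.empty(n + 1)
    theta[0], omega[0], t[0] = theta0, omega0, 0.0
    tau_fin[0] = _fin_torque(theta0, omega0, controller)

    cost = 0.0
    capsized = False
    last = n
    for k in range(n):
        tk = k * dt
        nz = noise[k]

        def deriv(ti: float, th: float, om: float) -> tuple[float, float]:
            tf = _fin_torque(th, om, controller)
            ext = perturb.ventilation_amp * np.sin(w_vent * ti) + nz
            return om, (mgd * np.sin(th) - body.drag_coeff * om + tf + ext) * inv_i

        th, om = theta[k], omega[k]
        k1 = deriv(tk, th, om)
        k2 = deriv(tk + dt / 2, th + dt / 2 * k1[0], om + dt / 2 * k1[1])
        k3 = deriv(tk + dt / 2, th + dt / 2 * k2[0], om + dt / 2 * k2[1])
        k4 = deriv(tk + dt, th + dt * k3[0], om + dt * k3[1])
        theta[k + 1] = th + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        omega[k + 1] = om + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        t[k + 1] = tk + dt
        tau_fin[k + 1] = _fin_torque(theta[k + 1], omega[k + 1], controller)
        cost += abs(tau_fin[k + 1] * omega[k + 1]) * dt
        if abs(theta[k + 1]) > np.pi / 2:
            capsized = True
            last = k + 1
            break

    sl = slice(0, last + 1)
    return SimResult(
        t=t[sl],
        theta=theta[sl],
        omega=omega[sl],
        tau_fin=tau_fin[sl],
        cost=cost,
        max_angle=float(np.max(np.abs(theta[sl]))),
        capsized=capsized,
        dt=dt,
    )


def stabilization_cost(
    result: SimResult, efficiency: float = 1.0, mass: float | None = None
) -> dict[str, float]:
    """Metabolic-side stabilisation cost from the mechanical fin work.

    Divides the mechanical work by a muscle/hydrodynamic efficiency in
    (0, 1]; reports joules, mean watts, and W kg^-1 when mass is given.
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must lie in (0, 1]")
    joules = result.cost / efficiency
    duration = float(result.t[-1] - result.t[0]) if result.t.size > 1 else np.nan
    out = {"joules": joules, "watts": joules / duration if duration else np.nan}
    if mass is not None:
        out["watts_per_kg"] = out["watts"] / mass
    return out


def fin_force_cost(
    result: SimResult,
    lever_arm: float,
    coeff: float = 1.0,
    exponent: float = 1.5,
) -> float:
    """Fin actuation cost ``coeff * integral (|tau_fin|/lever)^exponent dt``.

    With drag-based force production (F ~ v^2) the hydrodynamic power for
    a demanded force F scales as F^1.5, so fins with longer lever arms,
    needing less force for the same corrective torque, pay less.
    """
    if lever_arm <= 0:
        raise ValueError("lever_arm must be positive")
    force = np.abs(result.tau_fin) / lever_arm
    return float(coeff * np.sum(force**exponent) * result.dt)


#: Default factor grid for :func:`sweep_and_fit`.  ``comcob_dv`` follows the
#: dorsal-origin sign convention (negative = COB ventral of COM, larger
#: magnitude = larger separation); ``lever_prop`` and the fineness ratio are
#: dimensionless shape factors mapped onto physical parameters by isometry.
DEFAULT_SWEEP_GRID: dict[str, tuple[float, ...]] = {
    "mass": (0.002, 0.01, 0.05),
    "comcob_dv": (-0.15, -0.09, -0.03),
    "lever_prop": (0.10, 0.25, 0.40),
    "fineness": (2.5, 3.5, 5.0),
}

# Isometric shape constants used to map the sweep factors to physics.
_LENGTH_COEF = 0.45  # body length L = 0.45 * mass^(1/3)  (m; ~10 cm at 10 g)
_WIDTH_FRACTION = 1.3  # width = L / (1.3 * fineness)
_RGYR_FRACTION = 0.35  # roll radius of gyration = 0.35 * width
_DRAG_COEF = 0.05  # drag_coeff = 0.05 * (L * depth) * depth  (N m s)


def body_from_factors(
    mass: float, comcob_dv: float, fineness: float
) -> RigidBodyParams:
    """Map sweep factors to physical rigid-body parameters by isometry.

    Body length scales as mass^(1/3); depth = L/fineness; width and the
    roll radius of gyration scale with depth via fixed shape fractions;
    the physical COM-COB separation is |comcob_dv| * depth; the linear
    drag coefficient scales with lateral surface area (L * depth).
    """
    length = _LENGTH_COEF * mass ** (1.0 / 3.0)
    depth = length / fineness
    width = length / (_WIDTH_FRACTION * fineness)
    return RigidBodyParams(
        mass=mass,
        d_comcob=abs(comcob_dv) * depth,
        r_gyration=_RGYR_FRACTION * width,
        drag_coeff=_DRAG_COEF * length * depth * depth,
    )


def sweep_and_fit(
    grid: dict[str, tuple[float, ...]] | None = None,
    seed: int = 0,
    perturb_noise_sd: float = 1e-4,
    ventilation_amp: float = 2e-5,
    ventilation_freq: float = 2.0,
    dt: float = 1e-3,
    duration: float = 5.0,
    efficiency: float = 0.2,
):
    """Simulate a full factorial sweep and regress cost on the factors.

    Every cell of the {mass, comcob_dv, lever_prop, fineness} grid is
    simulated under an identical seeded perturbation sequence; the
    response is the mass-specific fin actuation cost.  The cost table,
    the OLS fit and the coefficient signs are returned.

    The comparative prediction is: cost falls with mass (bigger bodies
    have disproportionately more inertia and damping), rises with COM-COB
    separation (comcob_dv more negative under the dorsal-origin
    convention, hence a negative coefficient), falls with fin lever arm,
    and rises with fineness (thin bodies have less surface drag and less
    rotational inertia).
    """
    from . import stats as hs_stats

    grid = dict(DEFAULT_SWEEP_GRID if grid is None else grid)
    for name, levels in grid.items():
        if len(set(levels)) < 2:
            raise ValueError(f"factor {name!r} needs at least 2 distinct levels")
    names = list(grid)
    rows = []
    n_capsized = 0
    for values in itertools.product(*(grid[n] for n in names)):
        cell = dict(zip(names, values))
        body = body_from_factors(cell["mass"], cell["comcob_dv"], cell["fineness"])
        length = _LENGTH_COEF * cell["mass"] ** (1.0 / 3.0)
        lever = cell["lever_prop"] * length
        ctl = FinController.tuned_for(body, lever_arm=lever)
        res = simulate(
            body,
            ctl,
            PerturbationSpec(
                ventilation_amp=ventilation_amp,
                ventilation_freq=ventilation_freq,
                noise_sd=perturb_noise_sd,
                seed=seed,
            ),
            dt=dt,
            duration=duration,
        )
        if res.capsized:
            n_capsized += 1
            warnings.warn(f"cell {cell} capsized; excluded from the fit", stacklevel=2)
            continue
        cost = fin_force_cost(res, lever) / efficiency / cell["mass"]
        rows.append({**cell, "cost": cost, "max_angle": res.max_angle})
    if n_capsized > 0.5 * int(np.prod([len(grid[n]) for n in names])):
        raise RuntimeError("more than half of the sweep cells capsized")
    table = pd.DataFrame(rows)
    fit = hs_stats.ols(table[names], table["cost"])
    signs = {n: int(np.sign(fit.coeffs[n])) for n in names}
    return table, fit, signs
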
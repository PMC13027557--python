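"""Single-DOF forward dynamics of the elbow driven by prescribed activations.

The joint is planar elbow flexion–extension, theta = 0 at full extension
(forearm hanging vertically in a seated posture), flexion positive.
Four Hill-type muscle–tendon actuators span the joint: long head of
biceps (BIClong), long head of triceps (TRIlong), brachialis (BRA) and
brachioradialis (BRD).  The tendon is rigid, so fiber length is an
algebraic function of joint angle through a constant moment arm per
muscle, and the only state is (theta, omega) plus the first-order
activation states.

Equation of motion::

    I * theta'' = sum_i r_i F_i(a_i, theta, omega) + M_passive(theta, omega)
                  + M_task(omega) - m g c sin(theta)

integrated with fixed-step RK4.  ``M_task`` is a lumped viscous
task-constraint moment (see :func:`task_constraint_moment`); the
reported net *internal* joint moment is muscles + passive joint
mechanics only — task damping and gravity are external to it.  Movement emerges solely from the
prescribed activation envelopes, passive properties and gravity — there
is no tracking, optimization or feedback of any kind, and the
simulation is fully deterministic.

Muscle–tendon parameters follow published upper-limb model values
(maximum isometric forces, optimal fiber lengths, tendon slack lengths,
pennation) with constant averaged elbow moment arms; see
docs/methods.md for sources and units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .emg import ConfigurationError
from .scenarios import ActivationSet


class IntegrationError(RuntimeError):
    """Raised when the forward integration produces non-finite state."""


@dataclass(frozen=True)
class MuscleParams:
    """Hill-type muscle–tendon actuator with rigid tendon.

    ``r`` is the constant flexion moment arm in metres, signed: positive
    for flexors, negative for the extensor.  ``theta_opt`` is the elbow
    angle (rad) at which the fiber sits at optimal length; the MTU
    length at theta = 0 follows from it.
    """

    name: str
    f_max: float          # N, maximum isometric force
    l_opt: float          # m, optimal fiber length
    l_slack: float        # m, tendon slack length (rigid tendon)
    penn: float           # rad, pennation angle
    r: float              # m, constant flexion moment arm (signed)
    v_max: float = 10.0   # optimal fiber lengths per second
    theta_opt: float = 1.0  # rad, angle of optimal fiber length

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.l_opt <= 0 or self.v_max <= 0:
            raise ConfigurationError(f"{self.name}: f_max, l_opt, v_max must be > 0")

    @property
    def l_mtu0(self) -> float:
        """MTU length at theta = 0 such that the fiber is optimal at theta_opt."""
        return self.l_slack + self.l_opt * np.cos(self.penn) + self.r * self.theta_opt


def default_muscles() -> tuple[MuscleParams, ...]:
    """Literature-based defaults for the four elbow actuators."""
    return (
        MuscleParams("BIClong", f_max=624.3, l_opt=0.1157, l_slack=0.2723,
                     penn=0.0, r=+0.036),
        MuscleParams("TRIlong", f_max=798.5, l_opt=0.1340, l_slack=0.1430,
                     penn=0.2094, r=-0.021),
        MuscleParams("BRA", f_max=987.3, l_opt=0.0858, l_slack=0.0535,
                     penn=0.0, r=+0.022),
        MuscleParams("BRD", f_max=261.3, l_opt=0.1726, l_slack=0.1330,
                     penn=0.0, r=+0.055),
    )


@dataclass(frozen=True)
class ElbowModelParams:
    """Inertial, gravitational and passive-joint parameters.

    Forearm+hand segment values follow standard anthropometry for an
    adult; the passive joint moment combines exponential end-range
    stiffness with light viscous damping.
    """

    forearm_mass: float = 1.8        # kg, forearm + hand
    forearm_com: float = 0.18        # m, elbow to segment COM
    forearm_inertia: float = 0.09    # kg m^2 about the elbow
    g: float = 9.81                  # m/s^2
    muscles: tuple[MuscleParams, ...] = field(default_factory=default_muscles)
    tau_act: float = 0.010           # s, activation time constant
    tau_deact: float = 0.040         # s, deactivation time constant
    theta_min: float = 0.0           # rad, full extension
    theta_max: float = 2.618         # rad (150 deg), full flexion
    k_lim: float = 5.0               # Nm, end-range stiffness scale
    beta_lim: float = 30.0           # 1/rad, end-range exponential steepness
    c_damp: float = 0.25             # Nm s / rad, passive joint damping
    c_task: float = 25.0             # Nm s / rad, task-constraint damping
    use_activation_dynamics: bool = True

    def __post_init__(self) -> None:
        if self.forearm_inertia <= 0:
            raise ConfigurationError("forearm_inertia must be > 0")
        if self.theta_min >= self.theta_max:
            raise ConfigurationError("theta_min must be below theta_max")
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ConfigurationError("activation time constants must be > 0")

    def muscle(self, name: str) -> MuscleParams:
        for m in self.muscles:
            if m.name == name:
                return m
        raise ConfigurationError(f"unknown muscle {name!r}")


@dataclass
class SimulationResult:
    """Forward-dynamics output on the simulation grid.

    Angles are degrees at the interface (flexion positive, 0 = full
    extension); ``net_moment`` is the internal flexion–extension moment
    (muscle moments + passive joint moment, gravity excluded).
    """

    time: np.ndarray
    theta: np.ndarray          # deg
    omega: np.ndarray          # deg/s
    activations: dict[str, np.ndarray]
    forces: dict[str, np.ndarray]        # N
    moments: dict[str, np.ndarray]       # Nm
    passive_moment: np.ndarray           # Nm
    net_moment: np.ndarray               # Nm
    cycle_span: tuple[float, float]
    dt: float
    provenance: str = ""


# ---------------------------------------------------------------------------
# Hill-curve primitives

def force_length(l_norm: np.ndarray | float) -> np.ndarray | float:
    """Active force–length: Gaussian centred at optimal length."""
    return np.exp(-(((l_norm - 1.0) / 0.45) ** 2))


def force_velocity(v_norm: np.ndarray | float, a_f: float = 0.25,
                   f_len: float = 1.4) -> np.ndarray | float:
    """Force–velocity: Hill hyperbola (shortening) with eccentric plateau.

    ``v_norm`` is fiber velocity in optimal lengths per v_max, negative
    for shortening; the curve is 0 at -1, 1 at 0 and saturates at
    ``f_len`` for fast lengthening.
    """
    v = np.asarray(v_norm, dtype=float)
    denom = 1.0 - v / a_f
    denom = np.where(np.abs(denom) < 1e-9, 1e-9, denom)
    short = np.clip((1.0 + v) / denom, 0.0, None)
    length = 1.0 + (f_len - 1.0) * v / (v + a_f)
    out = np.where(v < 0, short, length)
    return float(out) if np.isscalar(v_norm) else out


def passive_force_length(l_norm: np.ndarray | float, k_pe: float = 4.0,
                         eps0: float = 0.6) -> np.ndarray | float:
    """Passive fiber force: exponential engaging above optimal length."""
    l = np.asarray(l_norm, dtype=float)
    fp = (np.exp(k_pe * (l - 1.0) / eps0) - 1.0) / (np.exp(k_pe) - 1.0)
    out = np.where(l > 1.0, fp, 0.0)
    return float(out) if np.isscalar(l_norm) else out


# ---------------------------------------------------------------------------
# Muscle-level operations

def mtu_length(theta: float | np.ndarray, p: MuscleParams) -> float | np.ndarray:
    """Muscle–tendon unit length at elbow angle theta (rad).

    Constant moment arm r implies l_mtu(theta) = l_mtu0 - r * theta, so
    d(l_mtu)/d(theta) = -r: flexor MTUs shorten as flexion increases.
    """
    return p.l_mtu0 - p.r * theta


def fiber_length_norm(theta: float | np.ndarray, p: MuscleParams) -> float | np.ndarray:
    """Normalized fiber length under the rigid-tendon assumption."""
    l_f = (mtu_length(theta, p) - p.l_slack) / np.cos(p.penn)
    return l_f / p.l_opt


def muscle_force(a: float, theta: float, omega: float, p: MuscleParams) -> float:
    """Hill-type fiber force projected along the tendon, in N.

    ``F = f_max [a fl(l) fv(v) + fp(l)] cos(penn)``, clipped at zero.
    Fiber velocity follows from the joint velocity through the constant
    moment arm (v_mtu = -r omega).
    """
    l_norm = fiber_length_norm(theta, p)
    if l_norm <= 0:
        raise IntegrationError(
            f"{p.name}: non-positive fiber length at theta={theta:.3f} rad"
        )
    v_fiber = (-p.r * omega) / np.cos(p.penn)       # m/s
    v_norm = v_fiber / (p.v_max * p.l_opt)
    f = p.f_max * (a * force_length(l_norm) * force_velocity(v_norm)
                   + passive_force_length(l_norm)) * np.cos(p.penn)
    return max(float(f), 0.0)


def passive_joint_moment(theta: float | np.ndarray, omega: float | np.ndarray,
                         params: ElbowModelParams) -> float | np.ndarray:
    """Exponential end-range stiffness plus viscous damping, in Nm.

    Restoring at both limits: positive (flexing) below theta_min,
    negative (extending) above theta_max, negligible mid-range.
    """
    b = params.beta_lim
    m = params.k_lim * (np.exp(-b * (theta - params.theta_min))
                        - np.exp(b * (theta - params.theta_max)))
    return m - params.c_damp * omega


# ---------------------------------------------------------------------------
# Activation dynamics

def activation_dynamics(u: np.ndarray, dt: float, tau_act: float,
                        tau_deact: float, a0: float | None = None) -> np.ndarray:
    """First-order excitation-to-activation lag on a uniform grid.

    ``da/dt = (u - a)/tau`` with tau = tau_act when u >= a (rising) and
    tau_deact otherwise; advanced with the exact exponential update under
    zero-order hold of u over each step.  Output stays in [0, 1].
    """
    if tau_act <= 0 or tau_deact <= 0:
        raise ConfigurationError("time constants must be positive")
    u = np.asarray(u, dtype=float)
    a = np.empty_like(u)
    a[0] = u[0] if a0 is None else a0
    for k in range(u.size - 1):
        tau = tau_act if u[k] >= a[k] else tau_deact
        a[k + 1] = u[k] + (a[k] - u[k]) * np.exp(-dt / tau)
    return np.clip(a, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Forward simulation

def _gravity_moment(theta: float, params: ElbowModelParams) -> float:
    return -params.forearm_mass * params.g * params.forearm_com * np.sin(theta)


def task_constraint_moment(omega: float | np.ndarray,
                           params: ElbowModelParams) -> float | np.ndarray:
    """Velocity-proportional resistance of the paced, guided task.

    Lumps everything that keeps a self-paced movement slow and smooth —
    soft-tissue and antagonistic co-contraction damping, the seated
    support, and the subject's own pacing — into one viscous term.  It
    enters the equation of motion like gravity but, also like gravity,
    is external to the reported net *internal* joint moment.
    """
    return -params.c_task * omega


def static_net_moment(theta: float, activations: dict[str, float],
                      params: ElbowModelParams) -> float:
    """Total static moment (muscle + passive + gravity) at omega = 0."""
    m = sum(p.r * muscle_force(activations.get(p.name, 0.0), theta, 0.0, p)
            for p in params.muscles)
    return m + passive_joint_moment(theta, 0.0, params) + _gravity_moment(theta, params)


def equilibrium_angle(params: ElbowModelParams,
                      activations: dict[str, float] | None = None) -> float:
    """Elbow angle (rad) where the static moment balance vanishes."""
    acts = activations or {}
    f = lambda th: static_net_moment(th, acts, params)
    lo, hi = params.theta_min - 0.15, params.theta_max + 0.15
    thetas = np.linspace(lo, hi, 400)
    vals = np.array([f(t) for t in thetas])
    sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise ConfigurationError("no static equilibrium in the joint range")
    i = sign_change[0]
    return float(optimize.brentq(f, thetas[i], thetas[i + 1]))


def forward_simulate(
    acts: ActivationSet,
    params: ElbowModelParams = ElbowModelParams(),
    dt: float = 0.001,
    theta0: float | None = None,
    omega0: float = 0.0,
) -> SimulationResult:
    """Integrate the elbow equation of motion under prescribed activations.

    The activation envelopes are resampled to the integration grid,
    passed through first-order activation dynamics (unless bypassed in
    ``params``), and drive the muscles as the sole neural input.  Fixed
    -step RK4; deterministic.  ``theta0`` defaults to the passive static
    equilibrium (rest).
    """
    t_start, t_end = float(acts.grid[0]), float(acts.grid[-1])
    n = int(round((t_end - t_start) / dt))
    if n < 2:
        raise ConfigurationError("simulation span shorter than two steps")
    time = t_start + dt * np.arange(n + 1)

    # neural input on the fine grid
    excitations = {
        name: np.interp(time, acts.grid, vals)
        for name, vals in acts.activations.items()
    }
    for m in params.muscles:
        excitations.setdefault(m.name, np.zeros_like(time))

    if params.use_activation_dynamics:
        activations = {
            name: activation_dynamics(u, dt, params.tau_act, params.tau_deact)
            for name, u in excitations.items()
        }
    else:
        activations = excitations

    def act_at(name: str, t: float) -> float:
        # linear interpolation between fine-grid activation samples
        x = (t - t_start) / dt
        i = int(x)
        if i >= n:
            return float(activations[name][-1])
        frac = x - i
        arr = activations[name]
        return float(arr[i] * (1 - frac) + arr[i + 1] * frac)

    def deriv(t: float, theta: float, omega: float) -> tuple[float, float]:
        m_musc = sum(
            p.r * muscle_force(act_at(p.name, t), theta, omega, p)
            for p in params.muscles
        )
        m_total = (m_musc + passive_joint_moment(theta, omega, params)
                   + task_constraint_moment(omega, params)
                   + _gravity_moment(theta, params))
        return omega, m_total / params.forearm_inertia

    if theta0 is None:
        theta0 = equilibrium_angle(params)

    theta = np.empty(n + 1)
    omega = np.empty(n + 1)
    theta[0], omega[0] = theta0, omega0
    for k in range(n):
        t, th, om = time[k], theta[k], omega[k]
        k1 = deriv(t, th, om)
        k2 = deriv(t + dt / 2, th + dt / 2 * k1[0], om + dt / 2 * k1[1])
        k3 = deriv(t + dt / 2, th + dt / 2 * k2[0], om + dt / 2 * k2[1])
        k4 = deriv(t + dt, th + dt * k3[0], om + dt * k3[1])
        theta[k + 1] = th + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        omega[k + 1] = om + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if not (np.isfinite(theta[k + 1]) and np.isfinite(omega[k + 1])):
            raise IntegrationError(f"integration diverged at t={time[k + 1]:.4f} s")

    # bookkeeping on the output grid
    forces = {}
    moments = {}
    for p in params.muscles:
        f = np.array([
            muscle_force(activations[p.name][k], theta[k], omega[k], p)
            for k in range(n + 1)
        ])
        forces[p.name] = f
        moments[p.name] = p.r * f
    passive = np.array([
        passive_joint_moment(theta[k], omega[k], params) for k in range(n + 1)
    ])
    net = passive + sum(moments.values())

    return SimulationResult(
        time=time,
        theta=np.degrees(theta),
        omega=np.degrees(omega),
        activations=activations,
        forces=forces,
        moments=moments,
        passive_moment=passive,
        net_moment=net,
        cycle_span=acts.cycle_span,
        dt=dt,
        provenance=acts.provenance,
    )


def net_moment_series(result: SimulationResult) -> np.ndarray:
    """Net internal flexion–extension moment: muscles + passive, no gravity."""
    return result.passive_moment + sum(result.moments.values())
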
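"""Reference numerical integration of the full nonlinear network model.

The state of each area is (u, v, q): excitatory and inhibitory population
variables plus the synaptic efficacy of the area's outgoing excitatory
synapses.  Dynamics:

    tau_m du/dt = -u + W_ee Q g[u] - W_ei g[v] + i_aff_e(t)
    tau_m dv/dt = -v + W_ie g[u] - W_ii g[v]
    dq/dt       = -q g[u] / tau_o + (1 - q) / tau_rec

with g[x] = tanh(alpha x) or the linearisation alpha x, and Q = diag(q).
Stimuli are afferent delta impulses at the IC excitatory population;
integrating across the impulse turns each into an instantaneous jump
u_IC <- u_IC + a/tau_m, so integration proceeds smoothly between onsets and
restarts at each jump.  Subcortical efficacies are clamped to one: IC and
thalamus do not adapt.

This module is the oracle against which the spectral and slow-fast
solutions are validated; it is deliberately plain and accurate rather than
fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import IC, ModelParameters, NetworkTopology

FIRING_RATES = ("tanh", "linear")


@dataclass(frozen=True)
class StimulusTrain:
    """Periodic train of identical afferent impulses.

    The s-th stimulus arrives at ``t_s = s * soi``; each impulse enters the
    excitatory population of the IC only (afferent input to inhibitory
    populations is identically zero).
    """

    soi: float
    n_stimuli: int = 1

    def __post_init__(self) -> None:
        if not self.soi > 0:
            raise ValueError(f"soi must be positive, got {self.soi!r}")
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")

    @property
    def onset_times(self) -> np.ndarray:
        return self.soi * np.arange(self.n_stimuli)

    def amplitude_vector(self, params: ModelParameters, n_areas: int) -> np.ndarray:
        amp = np.zeros(n_areas)
        amp[IC] = params.a
        return amp


@dataclass
class StateTrajectory:
    """Sampled trajectory of the network state.

    ``u``/``v``/``q`` have shape (n_times, n_areas); ``d = 1 - q`` is the
    depression variable.
    """

    time: np.ndarray
    u: np.ndarray
    v: np.ndarray
    q: np.ndarray

    @property
    def d(self) -> np.ndarray:
        return 1.0 - self.q


def _firing(kind: str, alpha: float):
    if kind == "tanh":
        return lambda x: np.tanh(alpha * x)
    if kind == "linear":
        return lambda x: alpha * x
    raise ValueError(f"unknown firing rate {kind!r}; expected one of {FIRING_RATES}")


def integrate_full(
    top: NetworkTopology,
    params: ModelParameters,
    train: StimulusTrain,
    firing_rate: str = "tanh",
    dt_out: float = 1e-3,
    t_end: float | None = None,
    freeze_efficacy: bool = False,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> StateTrajectory:
    """Integrate the full nonlinear system under a periodic impulse train.

    Integration runs piecewise between stimulus onsets with an adaptive
    Runge–Kutta scheme and is restarted at each onset with the jump
    ``u_IC += a/tau_m`` applied.  ``freeze_efficacy`` pins q to one
    everywhere (the fixed-efficacy linear benchmark); otherwise q is pinned
    only for the non-adapting (subcortical) areas.

    Returns the trajectory sampled on a uniform grid of step ``dt_out``,
    from 0 to ``t_end`` (default: one SOI past the last onset).
    """
    if not dt_out > 0:
        raise ValueError("dt_out must be positive")
    g = _firing(firing_rate, params.alpha)
    n = top.n_areas
    onsets = train.onset_times
    if t_end is None:
        t_end = onsets[-1] + train.soi
    adapting = top.adapting_mask & ~freeze_efficacy

    def rhs(_t, y):
        u, v, q = y[:n], y[n : 2 * n], y[2 * n :]
        gu, gv = g(u), g(v)
        du = (-u + top.W_ee @ (q * gu) - top.W_ei @ gv) / params.tau_m
        dv = (-v + top.W_ie @ gu - top.W_ii @ gv) / params.tau_m
        dq = np.where(adapting, -q * gu / params.tau_o + (1.0 - q) / params.tau_rec, 0.0)
        return np.concatenate([du, dv, dq])

    t_grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    jump = params.a / params.tau_m

    y = np.zeros(3 * n)
    y[2 * n :] = 1.0  # q starts fully recovered
    out = np.empty((t_grid.size, 3 * n))
    # breakpoints: onsets within the grid plus the end
    breakpoints = [t for t in onsets if t < t_end] + [t_end]
    t_prev = 0.0
    first = breakpoints[0]
    if first > 0:
        # silent lead-in before the first onset (all-zero state)
        mask = t_grid < first
        out[mask] = y
        t_prev = first
    for t_next in breakpoints:
        if t_next <= t_prev and t_next != t_end:
            continue
        if np.isclose(t_prev, onsets, atol=1e-12).any():
            y = y.copy()
            y[IC] += jump
        mask = (t_grid >= t_prev) & (t_grid <= t_next + 1e-12)
        t_eval = t_grid[mask]
        if t_next > t_prev:
            sol = solve_ivp(
                rhs,
                (t_prev, t_next),
                y,
                method="RK45",
                t_eval=t_eval if t_eval.size else None,
                rtol=rtol,
                atol=atol,
                dense_output=False,
            )
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise FloatingPointError(
                    f"integration diverged on [{t_prev}, {t_next}]: {sol.message}"
                )
            if t_eval.size:
                out[mask] = sol.y.T
            y = sol.y[:, -1]
        elif t_eval.size:
            out[mask] = y
        t_prev = t_next

    u = out[:, :n]
    v = out[:, n : 2 * n]
    q = out[:, 2 * n :]
    return StateTrajectory(time=t_grid, u=u, v=v, q=q)


@dataclass(frozen=True)
class FiringRateComparison:
    """Per-area discrepancies between tanh and linear firing-rate runs."""

    rel_linf: np.ndarray
    rel_l2: np.ndarray
    peak_scale: np.ndarray

    @property
    def max_rel_linf(self) -> float:
        return float(np.max(self.rel_linf))


def compare_firing_rates(
    top: NetworkTopology,
    params: ModelParameters,
    train: StimulusTrain,
    dt_out: float = 1e-3,
    kinds: tuple[str, str] = ("tanh", "linear"),
) -> FiringRateComparison:
    """Quantify the effect of the firing-rate choice.

    Runs the full model once per entry of ``kinds`` (default: tanh vs its
    linearisation) and reports, per area, the L-inf and L2 differences of
    u(t) relative to the peak magnitude of the first run.
    """
    ref = integrate_full(top, params, train, firing_rate=kinds[0], dt_out=dt_out)
    lin = integrate_full(top, params, train, firing_rate=kinds[1], dt_out=dt_out)
    diff = ref.u - lin.u
    peak = np.max(np.abs(ref.u), axis=0)
    scale = np.where(peak > 0, peak, 1.0)
    rel_linf = np.max(np.abs(diff), axis=0) / scale
    rel_l2 = np.linalg.norm(diff, axis=0) / np.where(
        np.linalg.norm(ref.u, axis=0) > 0, np.linalg.norm(ref.u, axis=0), 1.0
    )
    return FiringRateComparison(rel_linf=rel_linf, rel_l2=rel_l2, peak_scale=peak)


def trajectory_frame(traj: StateTrajectory, labels) -> "pd.DataFrame":
    """Trajectory as a tidy wide table (time_s, then u/v/q/d per area)."""
    import pandas as pd

    data = {"time_s": traj.time}
    for k, lab in enumerate(labels):
        data[f"u_{lab}"] = traj.u[:, k]
        data[f"v_{lab}"] = traj.v[:, k]
        data[f"q_{lab}"] = traj.q[:, k]
        data[f"d_{lab}"] = traj.d[:, k]
    return pd.DataFrame(data)
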
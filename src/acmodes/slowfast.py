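"""Slow-fast approximation of short-term synaptic depression.

Transmitter release (time constant tau_o) is much faster than vesicle
replenishment (tau_rec), so the efficacy dynamics separate into two
processes handled independently per inter-stimulus interval:

* a fast drop-off at each stimulus, obtained by integrating the release
  term over the stimulus-induced activity.  With linear firing rates and
  the normal-mode solution for u(t) the integral has the closed form

      F_s(q_s) = q_s * prod_n exp( -alpha c_{n,s}
                   (exp(lambda_{n,s} dt) - 1) / (tau_o lambda_{n,s}) x_{n,s} )

* a slow exponential recovery towards one over the full interval:

      q_{s+1} = 1 - (1 - F_s(q_s)) exp(-dt / tau_rec).

Between stimuli the efficacy is held piecewise constant, Q(t) = Q_s, so the
(u, v) dynamics in each interval are linear with coefficient matrix
M_s = M(Q_s) and the normal modes are recomputed stimulus by stimulus.  The
state variables are assumed to have decayed to zero before each onset; each
stimulus therefore restarts the system at the jump state (a/tau_m on the IC
excitatory variable).  Subcortical efficacies stay pinned at one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import StimulusTrain, integrate_full
from .network import CORTICAL, IC, ModelParameters, NetworkTopology
from .spectral import (
    SpectralDecomposition,
    assemble_coefficient_matrix,
    mode_coefficients,
    spectral_decomposition,
)

#: below this SOI the between-stimulus decay assumption becomes questionable
MIN_RELIABLE_SOI = 0.5


def jump_state(params: ModelParameters, n_areas: int) -> tuple[np.ndarray, np.ndarray]:
    """Post-impulse initial condition: a/tau_m on the IC excitatory variable."""
    u0 = np.zeros(n_areas)
    u0[IC] = params.a / params.tau_m
    return u0, np.zeros(n_areas)


def fast_dropoff(
    q_s: np.ndarray,
    dec_s: SpectralDecomposition,
    coeffs_s: np.ndarray,
    interval: float,
    params: ModelParameters,
    imag_tol: float = 1e-9,
) -> np.ndarray:
    """Efficacy after transmitter release over one interval (closed form).

    Evaluates the mode-product form of the release integral.  Eigenvalues
    with |lambda| ~ 0 use the limit (exp(lambda dt) - 1)/lambda -> dt.  The
    firing-rate gain alpha multiplies the exponent (the release term acts
    on the firing rate alpha*u, not on u itself).
    """
    if interval < 0:
        raise ValueError("interval must be non-negative")
    lam = dec_s.eigenvalues
    growth = np.empty_like(lam)
    small = np.abs(lam) * interval < 1e-12
    growth[~small] = (np.exp(lam[~small] * interval) - 1.0) / lam[~small]
    growth[small] = interval
    # exponent per area: -(alpha/tau_o) sum_n c_n x_{n,area} growth_n
    exponent = -(params.alpha / params.tau_o) * (dec_s.x @ (coeffs_s * growth))
    scale = max(np.max(np.abs(exponent.real)), 1e-300)
    if np.max(np.abs(exponent.imag)) > imag_tol * scale:
        raise FloatingPointError("imaginary residual in release exponent")
    return np.asarray(q_s, dtype=float) * np.exp(exponent.real)


def slow_recovery(
    q_after_drop: np.ndarray,
    interval: float,
    params: ModelParameters,
    adapting_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Exponential replenishment towards one over the interval.

    Non-adapting (subcortical) entries are forced back to exactly one.
    """
    if interval < 0:
        raise ValueError("interval must be non-negative")
    q = np.asarray(q_after_drop, dtype=float)
    out = 1.0 - (1.0 - q) * np.exp(-interval / params.tau_rec)
    if adapting_mask is not None:
        out = np.where(adapting_mask, out, 1.0)
    return out


@dataclass
class AdaptationTrajectory:
    """Per-stimulus record of a slow-fast run.

    ``q[s]`` is the efficacy vector in force during interval s (q[0] = 1:
    the initial state); ``decompositions[s]`` and ``coefficients[s]`` are
    the spectrum and mode coefficients for that interval.  The adapted
    state is the last recorded stimulus.
    """

    train: StimulusTrain
    q: np.ndarray  # (S_recorded, N)
    decompositions: list[SpectralDecomposition]
    coefficients: list[np.ndarray]
    converged_at: int | None = None
    variant: str = "DEF"

    @property
    def n_recorded(self) -> int:
        return len(self.decompositions)

    @property
    def initial(self) -> int:
        return 0

    @property
    def adapted(self) -> int:
        return self.n_recorded - 1

    def efficacy_frame(self, labels) -> pd.DataFrame:
        rows = []
        for s in range(self.n_recorded):
            for k, lab in enumerate(labels):
                rows.append(
                    {"stimulus_index": s, "area": lab, "q": self.q[s, k], "d": 1 - self.q[s, k]}
                )
        return pd.DataFrame(rows)


def run_stimulus_train(
    top: NetworkTopology,
    params: ModelParameters,
    train: StimulusTrain,
    q_tol: float = 1e-6,
) -> AdaptationTrajectory:
    """Drive the network through a periodic train with the slow-fast scheme.

    Iterates stimulus by stimulus: reset (u, v) to the jump state, assemble
    M_s = M(Q_s), decompose, project, apply the fast drop-off and the slow
    recovery to obtain q_{s+1}.  Stops early once consecutive efficacy
    vectors agree to ``q_tol`` (set ``q_tol=0`` to disable); the last
    recorded stimulus is the adapted state.
    """
    if train.soi < MIN_RELIABLE_SOI:
        warnings.warn(
            f"SOI {train.soi} s is below {MIN_RELIABLE_SOI} s; the assumption that "
            "u and v decay to zero between stimuli may be violated",
            stacklevel=2,
        )
    n = top.n_areas
    u0, v0 = jump_state(params, n)
    q = np.ones(n)
    qs: list[np.ndarray] = []
    decs: list[SpectralDecomposition] = []
    coefs: list[np.ndarray] = []
    converged_at = None
    for s in range(train.n_stimuli):
        M_s = assemble_coefficient_matrix(top, params, q)
        dec = spectral_decomposition(M_s)
        c = mode_coefficients(dec, u0, v0)
        qs.append(q.copy())
        decs.append(dec)
        coefs.append(c)
        if s == train.n_stimuli - 1:
            break
        dropped = fast_dropoff(q, dec, c, train.soi, params)
        q_next = slow_recovery(dropped, train.soi, params, top.adapting_mask)
        if q_tol > 0 and np.max(np.abs(q_next - q)) < q_tol:
            converged_at = s
            q = q_next
            break
        q = q_next
    return AdaptationTrajectory(
        train=train,
        q=np.array(qs),
        decompositions=decs,
        coefficients=coefs,
        converged_at=converged_at,
        variant=top.variant,
    )


@dataclass(frozen=True)
class SlowFastValidation:
    """Per-stimulus peak-amplitude discrepancies, slow-fast vs full model."""

    peaks_slowfast: np.ndarray  # (S, N)
    peaks_linear: np.ndarray
    peaks_tanh: np.ndarray
    rel_diff_linear: np.ndarray
    rel_diff_tanh: np.ndarray

    @property
    def max_rel_diff_linear(self) -> float:
        return float(np.max(self.rel_diff_linear))

    @property
    def max_rel_diff_tanh(self) -> float:
        return float(np.max(self.rel_diff_tanh))


def validate_against_full_model(
    top: NetworkTopology,
    params: ModelParameters,
    train: StimulusTrain,
    dt: float = 1e-3,
) -> SlowFastValidation:
    """Compare slow-fast per-stimulus u-peaks against full integrations.

    Peaks are taken per area within each inter-stimulus interval; relative
    differences are normalised by the full-model peak of the same interval.
    Comparisons cover the cortical areas (the subcortical peaks are set by
    the impulse itself).
    """
    adapt = run_stimulus_train(top, params, train, q_tol=0.0)
    n = top.n_areas
    grid = np.arange(0.0, train.soi, dt)
    peaks_sf = np.empty((train.n_stimuli, n))
    for s in range(train.n_stimuli):
        u, _ = evolve_interval(adapt, s, grid)
        peaks_sf[s] = np.max(np.abs(u), axis=0)

    def interval_peaks(traj):
        peaks = np.empty((train.n_stimuli, n))
        for s in range(train.n_stimuli):
            lo, hi = s * train.soi, (s + 1) * train.soi
            mask = (traj.time >= lo) & (traj.time < hi)
            peaks[s] = np.max(np.abs(traj.u[mask]), axis=0)
        return peaks

    full_lin = integrate_full(top, params, train, firing_rate="linear", dt_out=dt)
    full_tanh = integrate_full(top, params, train, firing_rate="tanh", dt_out=dt)
    peaks_lin = interval_peaks(full_lin)
    peaks_tanh = interval_peaks(full_tanh)
    cortical = list(CORTICAL)
    rel_lin = np.abs(peaks_sf - peaks_lin)[:, cortical] / peaks_lin[:, cortical]
    rel_tanh = np.abs(peaks_sf - peaks_tanh)[:, cortical] / peaks_tanh[:, cortical]
    return SlowFastValidation(
        peaks_slowfast=peaks_sf,
        peaks_linear=peaks_lin,
        peaks_tanh=peaks_tanh,
        rel_diff_linear=rel_lin,
        rel_diff_tanh=rel_tanh,
    )


def evolve_interval(
    adapt: AdaptationTrajectory, s: int, time: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (u, v) within interval ``s`` of an adaptation run."""
    from .spectral import evolve_modes

    return evolve_modes(adapt.decompositions[s], adapt.coefficients[s], time)
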
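"""Simulated MEG signal (event-related field) and its decompositions.

The forward model weights every excitatory-to-excitatory and every
inhibitory-to-excitatory synaptic input by a topology multiplier and sums
over the cortical columns:

    R(t) = sum_j [ B (u(t); v(t)) ]_j,
    B    = [[K1 o W_ee Q, 0], [0, K2 o W_ei]]   (o: Hadamard product).

The MEG contribution of an area is proportional to the synaptic input it
receives, and excitatory-to-excitatory transmission is depressed by the
current efficacy Q — so by default the depressed weights W_ee Q enter the
sum (``meg_weights="depressed"``).  The undepressed alternative
(``"static"``, B built from bare W_ee) is kept as an option; in the
unadapted state (q = 1) the two coincide.  Substituting the normal-mode
solution gives the
mode decomposition R(t) = sum_n c_n kappa_n exp(lambda_n t), where the MEG
efficiency kappa_n = sum_j [B (x_n; y_n)]_j measures how strongly mode n's
spatial pattern projects into the sensor; a conjugate mode pair contributes
the real waveform 2 Re(c_n kappa_n exp(lambda_n t)).

Alternatively the summands of R(t) can be grouped anatomically: by
receiving area (the source-modelling view), by sending area (each area's
impact on the network), or by connection class (feedforward, feedback,
lateral, inhibitory).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkTopology
from .slowfast import AdaptationTrajectory
from .spectral import SpectralDecomposition, evolve_modes

SCHEMES = ("incoming", "outgoing", "type")

#: display shift added to exported time stamps only (subcortical delay), s
DISPLAY_SHIFT = 0.030


def _forward_blocks(
    top: NetworkTopology, q: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(K1 o W_ee, K2 o W_ei), optionally with efficacy-modulated W_ee."""
    w_ee = top.W_ee * q[np.newaxis, :] if q is not None else top.W_ee
    return top.K1 * w_ee, top.K2 * top.W_ei


@dataclass
class ERFWaveform:
    """Simulated MEG waveform with provenance."""

    time: np.ndarray
    R: np.ndarray
    variant: str = "DEF"
    soi: float | None = None
    stimulus_index: int | None = None
    state: str | None = None  # "initial" | "adapted"

    def to_frame(self, display_shift: float = 0.0) -> pd.DataFrame:
        """Export table; an optional display shift affects time stamps only."""
        return pd.DataFrame(
            {"time_ms": 1e3 * (self.time + display_shift), "R": self.R}
        )


def meg_signal(
    top: NetworkTopology,
    time: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    q: np.ndarray | None = None,
    **provenance,
) -> ERFWaveform:
    """Compute R(t) from a sampled (u, v) trajectory.

    Pass the efficacy vector ``q`` in force during the trajectory to weight
    the excitatory inputs by the depressed synaptic strengths (the default
    forward model); with ``q=None`` the bare (static) W_ee is used.
    """
    b_ee, b_ei = _forward_blocks(top, q)
    r = u @ b_ee.sum(axis=0) + v @ b_ei.sum(axis=0)
    return ERFWaveform(time=np.asarray(time), R=r, variant=top.variant, **provenance)


@dataclass
class ModeContribution:
    """Per-mode make-up of the MEG signal.

    ``abs_c`` is the input efficiency (how strongly the afferent impulse
    excites the mode), ``kappa`` the MEG efficiency (how visible the mode's
    spatial pattern is to the sensor).  ``r(t) = c kappa exp(lambda t)`` is
    the mode's complex trajectory; a conjugate pair sums to 2 Re(r).
    """

    eigenvalues: np.ndarray
    c: np.ndarray
    kappa: np.ndarray
    pair: np.ndarray

    @property
    def abs_c(self) -> np.ndarray:
        return np.abs(self.c)

    @property
    def total_contribution(self) -> np.ndarray:
        """|c_n| * |kappa_n| — invariant under eigenvector rescaling."""
        return np.abs(self.c) * np.abs(self.kappa)

    def trajectories(self, time: np.ndarray) -> np.ndarray:
        """Complex r_n(t), shape (n_times, 2N)."""
        return (self.c * self.kappa)[np.newaxis, :] * np.exp(
            np.outer(np.asarray(time), self.eigenvalues)
        )

    def pair_waveforms(self, time: np.ndarray) -> np.ndarray:
        """Real contribution 2 Re(r_n(t)) per mode pair (one column per pair)."""
        r = self.trajectories(time)
        cols = []
        seen = set()
        for n in range(self.eigenvalues.size):
            partner = self.pair[n]
            if n in seen:
                continue
            seen.update({n, int(partner)})
            if partner == n:  # real (overdamped) mode
                cols.append(r[:, n].real)
            else:
                cols.append(2.0 * r[:, n].real)
        return np.column_stack(cols)

    def signal(self, time: np.ndarray) -> np.ndarray:
        """R(t) reconstructed as the mode sum (real part)."""
        total = self.trajectories(time).sum(axis=1)
        return total.real

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode_id": np.arange(self.eigenvalues.size),
                "nu_hz": self.eigenvalues.imag / (2 * np.pi),
                "gamma_per_s": self.eigenvalues.real,
                "abs_c": self.abs_c,
                "arg_c": np.angle(self.c),
                "kappa_re": self.kappa.real,
                "kappa_im": self.kappa.imag,
                "total": self.total_contribution,
            }
        )


def mode_contributions(
    dec: SpectralDecomposition,
    coeffs: np.ndarray,
    top: NetworkTopology,
    q: np.ndarray | None = None,
) -> ModeContribution:
    """Input efficiency, MEG efficiency and trajectory factors per mode.

    ``q`` selects the depressed forward model, as in :func:`meg_signal`.
    """
    b_ee, b_ei = _forward_blocks(top, q)
    kappa = b_ee.sum(axis=0) @ dec.x + b_ei.sum(axis=0) @ dec.y
    return ModeContribution(
        eigenvalues=dec.eigenvalues, c=np.asarray(coeffs), kappa=kappa, pair=dec.pair
    )


def _connection_class(top: NetworkTopology, i: int, j: int) -> str:
    """Classify an excitatory connection j -> i by its anatomical direction."""
    if i == j:
        return "lateral"
    return "feedforward" if j < i else "feedback"


def decompose_by_connection(
    top: NetworkTopology,
    time: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    scheme: str,
    q: np.ndarray | None = None,
) -> pd.DataFrame:
    """Partition the summands of R(t) into anatomical groups.

    ``incoming`` groups by receiving area, ``outgoing`` by sending area
    (inhibitory self-inputs count as their area's own traffic in both
    views), ``type`` groups by connection class {feedforward, feedback,
    lateral, inhibitory}.  The groups sum to R(t) exactly.  ``q`` selects
    the depressed forward model, as in :func:`meg_signal`.  Returns a table
    with a time column and one column per group.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    b_ee, b_ei = _forward_blocks(top, q)
    n = top.n_areas
    labels = top.area_labels
    groups: dict[str, np.ndarray] = {}

    def add(key: str, series: np.ndarray) -> None:
        groups[key] = groups.get(key, 0.0) + series

    for i in range(n):
        for j in range(n):
            if b_ee[i, j] != 0.0:
                term = b_ee[i, j] * u[:, j]
                if scheme == "incoming":
                    add(labels[i], term)
                elif scheme == "outgoing":
                    add(labels[j], term)
                else:
                    add(_connection_class(top, i, j), term)
            if b_ei[i, j] != 0.0:
                term = b_ei[i, j] * v[:, j]
                if scheme == "incoming":
                    add(labels[i], term)
                elif scheme == "outgoing":
                    add(labels[j], term)
                else:
                    add("inhibitory", term)

    out = pd.DataFrame({"time_s": np.asarray(time)})
    for key, series in groups.items():
        out[key] = series
    out["total"] = sum(groups.values())
    return out


def state_efficacy(adapt: AdaptationTrajectory, state: str, meg_weights: str) -> np.ndarray | None:
    """Efficacy vector for the requested forward model, or None for static."""
    if meg_weights not in ("depressed", "static"):
        raise ValueError(f"unknown meg_weights {meg_weights!r}")
    if meg_weights == "static":
        return None
    s = adapt.initial if state == "initial" else adapt.adapted
    return adapt.q[s]


def adapted_state_waveform(
    top: NetworkTopology,
    adapt: AdaptationTrajectory,
    state: str = "adapted",
    dt: float = 1e-3,
    max_window: float = 0.6,
    meg_weights: str = "depressed",
) -> ERFWaveform:
    """ERF of the initial or adapted interval of a slow-fast run.

    The waveform is sampled at ``dt`` over [0, min(SOI, max_window)) —
    enough to cover the P1m/N1m/P2m landmarks without crossing into the
    next stimulus.
    """
    s = adapt.initial if state == "initial" else adapt.adapted
    window = min(adapt.train.soi, max_window)
    time = np.arange(0.0, window, dt)
    u, v = evolve_modes(adapt.decompositions[s], adapt.coefficients[s], time)
    wave = meg_signal(
        top, time, u, v, q=state_efficacy(adapt, state, meg_weights),
        soi=adapt.train.soi, stimulus_index=s, state=state,
    )
    return wave
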
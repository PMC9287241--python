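"""Normal-mode machinery for the linearised network.

With linear firing rates g[x] = alpha x and a fixed synaptic-efficacy
vector q, the homogeneous (u, v) dynamics form a standard linear system
d/dt (u; v) = M (u; v) with the 2N x 2N coefficient matrix

    M = (1/tau_m) [[alpha W_ee Q - I,  -alpha W_ei],
                   [alpha W_ie,        -alpha W_ii - I]],   Q = diag(q).

The general solution is a superposition of normal modes
sum_n c_n exp(lambda_n t) (x_n; y_n), where (x_n; y_n) are right
eigenvectors of M and the coefficients c_n are projections of the initial
state onto the corresponding left eigenvectors.  For the parameter regime
used here M is stable (all decay rates gamma_n = Re(lambda_n) < 0) and the
modes are underdamped: eigenvalues appear in complex-conjugate pairs with
non-zero angular frequency omega_n = Im(lambda_n).

Convention: right eigenvectors are scaled to unit Euclidean norm and the
left eigenvectors are rescaled so that the left/right systems are
biorthonormal (the rows of the inverse of the right-eigenvector matrix).
Any consistent biorthonormal convention leaves all physical observables
(eigenvalues, mode sums, the product |c_n| * |kappa_n|) unchanged, but the
individual magnitudes of c_n and of the MEG efficiency kappa_n do depend
on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .network import ModelParameters, NetworkTopology

#: modes with |omega| below this (rad/s) are treated as overdamped
OVERDAMPED_OMEGA_TOL = 1e-8


def assemble_coefficient_matrix(
    top: NetworkTopology, params: ModelParameters, q: np.ndarray | float = 1.0
) -> np.ndarray:
    """Build the 2N x 2N coefficient matrix M for efficacy state ``q``."""
    n = top.n_areas
    q = np.broadcast_to(np.asarray(q, dtype=float), (n,))
    if np.any(q <= 0) or np.any(q > 1):
        raise ValueError(f"q must lie in (0, 1], got {q}")
    a = params.alpha
    eye = np.eye(n)
    upper = np.hstack([a * top.W_ee * q[np.newaxis, :] - eye, -a * top.W_ei])
    lower = np.hstack([a * top.W_ie, -a * top.W_ii - eye])
    return np.vstack([upper, lower]) / params.tau_m


@dataclass
class SpectralDecomposition:
    """Eigen-decomposition of a coefficient matrix M.

    Modes are sorted by |omega| ascending (ties: gamma descending), so
    conjugate partners are adjacent.  ``right`` holds unit-norm right
    eigenvectors as columns; ``left`` holds the biorthonormal left
    eigenvectors as rows, i.e. ``left @ right == I``.  ``pair`` maps each
    mode index to its conjugate partner (its own index for real modes).
    """

    M: np.ndarray
    eigenvalues: np.ndarray
    right: np.ndarray
    left: np.ndarray
    pair: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    @property
    def n_areas(self) -> int:
        return self.eigenvalues.size // 2

    @property
    def gamma(self) -> np.ndarray:
        """Decay rates (1/s)."""
        return self.eigenvalues.real

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies (rad/s)."""
        return self.eigenvalues.imag

    @property
    def nu(self) -> np.ndarray:
        """Frequencies (Hz)."""
        return self.omega / (2.0 * np.pi)

    @property
    def underdamped(self) -> np.ndarray:
        return np.abs(self.omega) > OVERDAMPED_OMEGA_TOL

    @property
    def x(self) -> np.ndarray:
        """Excitatory (u) components of the right eigenvectors, (N, 2N)."""
        return self.right[: self.n_areas]

    @property
    def y(self) -> np.ndarray:
        """Inhibitory (v) components of the right eigenvectors, (N, 2N)."""
        return self.right[self.n_areas :]

    def to_frame(self) -> pd.DataFrame:
        """Spectrum table: one row per mode, eigenvector components inline."""
        rows = {
            "mode_id": np.arange(self.n_modes),
            "nu_hz": self.nu,
            "gamma_per_s": self.gamma,
            "damping_class": np.where(self.underdamped, "underdamped", "overdamped"),
            "pair": self.pair,
        }
        for k in range(self.n_areas):
            rows[f"re_x{k}"] = self.x[k].real
            rows[f"im_x{k}"] = self.x[k].imag
        return pd.DataFrame(rows)


def spectral_decomposition(M: np.ndarray, cond_tol: float = 1e10) -> SpectralDecomposition:
    """Eigen-decompose M into a biorthonormal left/right system.

    Raises ``np.linalg.LinAlgError`` when M is defective within tolerance
    (ill-conditioned eigenvector matrix); no silent regularisation.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    if not np.all(np.isfinite(M)):
        raise ValueError("M contains non-finite entries")
    lam, vr = scipy.linalg.eig(M)
    vr = vr / np.linalg.norm(vr, axis=0, keepdims=True)
    order = np.lexsort((-lam.real, np.abs(lam.imag)))
    lam, vr = lam[order], vr[:, order]
    cond = np.linalg.cond(vr)
    if cond > cond_tol:
        raise np.linalg.LinAlgError(
            f"coefficient matrix is defective within tolerance (cond={cond:.3g})"
        )
    vl = np.linalg.inv(vr)  # rows: biorthonormal left eigenvectors

    pair = np.arange(lam.size)
    used = np.zeros(lam.size, dtype=bool)
    for i in range(lam.size):
        if used[i] or abs(lam[i].imag) <= OVERDAMPED_OMEGA_TOL:
            continue
        candidates = [
            j
            for j in range(lam.size)
            if not used[j] and j != i and np.isclose(lam[j], lam[i].conjugate())
        ]
        if candidates:
            j = candidates[0]
            pair[i], pair[j] = j, i
            used[i] = used[j] = True
    return SpectralDecomposition(M=M, eigenvalues=lam, right=vr, left=vl, pair=pair)


def mode_coefficients(dec: SpectralDecomposition, u0: np.ndarray, v0: np.ndarray) -> np.ndarray:
    """Project an initial state onto the modes: c = left @ (u0; v0).

    The projection is bilinear (no conjugation), so the superposition
    sum_n c_n (x_n; y_n) reproduces the initial state exactly and real
    states give conjugate coefficients on conjugate mode pairs.
    """
    state = np.concatenate([np.asarray(u0, dtype=float), np.asarray(v0, dtype=float)])
    if state.size != dec.n_modes:
        raise ValueError(
            f"state dimension {state.size} does not match 2N = {dec.n_modes}"
        )
    return dec.left @ state


def evolve_modes(
    dec: SpectralDecomposition,
    coeffs: np.ndarray,
    time: np.ndarray,
    imag_tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the mode superposition on a time grid.

    Returns real arrays ``u`` and ``v`` of shape (n_times, N).  The
    imaginary residual of the superposition must stay below ``imag_tol``
    relative to the real part (it is then discarded).
    """
    time = np.asarray(time, dtype=float)
    if np.any(np.diff(time) < 0):
        raise ValueError("time grid must be non-decreasing")
    phases = np.exp(np.outer(time, dec.eigenvalues))  # (T, 2N)
    states = (phases * coeffs[np.newaxis, :]) @ dec.right.T  # (T, 2N)
    scale = max(np.max(np.abs(states.real)), 1e-300)
    if np.max(np.abs(states.imag)) > imag_tol * scale:
        raise FloatingPointError("imaginary residual exceeds tolerance")
    real = states.real
    n = dec.n_areas
    return real[:, :n], real[:, n:]


def match_modes(ref: SpectralDecomposition, other: SpectralDecomposition) -> np.ndarray:
    """Track mode identity between two efficacy states.

    Returns an index array ``idx`` such that mode ``idx[n]`` of ``other``
    corresponds to mode ``n`` of ``ref``, matched greedily by maximal
    right-eigenvector overlap |<r_ref, r_other>|; falls back to the shared
    frequency ordering when overlaps are ambiguous (near-uniform).
    """
    overlap = np.abs(ref.right.conj().T @ other.right)  # (2N, 2N)
    idx = np.full(ref.n_modes, -1)
    taken = np.zeros(ref.n_modes, dtype=bool)
    # greedy assignment, strongest overlaps first
    flat = np.argsort(overlap, axis=None)[::-1]
    for f in flat:
        i, j = divmod(f, ref.n_modes)
        if idx[i] == -1 and not taken[j]:
            idx[i] = j
            taken[j] = True
    if np.any(idx == -1):  # pragma: no cover - greedy always completes
        idx[idx == -1] = np.flatnonzero(~taken)
    return idx
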
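"""Network construction for the core–belt–parabelt auditory-cortex model.

The model comprises five serially connected areas: two subcortical stages
(inferior colliculus, thalamus) and three cortical stages (core, belt,
parabelt).  Each area holds one excitatory and one inhibitory mean-field
population.  Only excitatory-to-excitatory connections run between areas;
all other connection classes are local, so their weight matrices are
diagonal.  Two additional matrices, ``K1`` and ``K2``, carry the
connection-specific multipliers with which each synaptic input projects
into the simulated MEG signal (the forward model): feedforward and lateral
inputs drive current away from the cortical surface, feedback inputs drive
it towards the surface, and subcortical areas contribute nothing.

Structural variants add shortcut excitatory connections (core↔parabelt or
thalamus↔belt); "normalised" variants rescale the excitatory matrix so that
its element sum — the measure of total excitation — matches the serial
default, preserving the excitation–inhibition balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

AREA_LABELS = ("IC", "thalamus", "core", "belt", "parabelt")
IC, THALAMUS, CORE, BELT, PARABELT = range(5)
CORTICAL = (CORE, BELT, PARABELT)
SUBCORTICAL = (IC, THALAMUS)

VARIANTS = ("DEF", "CP", "TB", "CPN", "TBN")


@dataclass(frozen=True)
class ModelParameters:
    """Scalar parameters of the model, with the published defaults.

    Weights ``w_*`` are dimensionless synaptic strengths: ``_d`` lateral
    (within-area), ``_ff`` feedforward, ``_fb`` feedback.  ``tau_m`` is the
    membrane time constant, ``tau_o`` the transmitter-release and
    ``tau_rec`` the replenishment time constant of short-term synaptic
    depression (all seconds).  ``a`` is the afferent impulse strength at
    the IC and ``alpha`` the firing-rate gain.  ``k1_*``/``k2_d`` are the
    MEG topology multipliers for excitatory and inhibitory inputs.
    """

    w_ee_d: float = 2.0
    w_ee_ff: float = 0.5
    w_ee_fb: float = 0.4
    w_ie_d: float = 3.5
    w_ei_d: float = 2.2
    w_ii_d: float = 2.5
    tau_m: float = 0.03
    tau_o: float = 0.04
    tau_rec: float = 5.0
    a: float = 0.02
    alpha: float = 1.0
    k1_d: float = -1.0
    k1_ff: float = -1.0
    k1_fb: float = 15.0
    k2_d: float = 2.0

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_o", "tau_rec"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value!r}")
        if not self.tau_o < self.tau_rec:
            raise ValueError(
                "tau_o must be smaller than tau_rec (slow-fast assumption); "
                f"got tau_o={self.tau_o}, tau_rec={self.tau_rec}"
            )

    def with_overrides(self, **overrides: float) -> "ModelParameters":
        known = {f.name for f in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)


@dataclass(frozen=True)
class NetworkTopology:
    """Weight and MEG-topology matrices of a five-area network.

    Orientation: row = receiving area, column = sending area, so
    ``W_ee[i, j]`` is the connection j → i and feedforward connections sit
    on the subdiagonal.  ``adapting_mask`` marks the areas whose outgoing
    excitatory synapses are subject to short-term depression (cortex only).
    """

    W_ee: np.ndarray
    W_ei: np.ndarray
    W_ie: np.ndarray
    W_ii: np.ndarray
    K1: np.ndarray
    K2: np.ndarray
    variant: str = "DEF"
    area_labels: tuple[str, ...] = AREA_LABELS
    adapting_mask: np.ndarray = field(
        default_factory=lambda: np.array([False, False, True, True, True])
    )

    @property
    def n_areas(self) -> int:
        return self.W_ee.shape[0]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Matrices as labelled DataFrames (for CSV export)."""
        labels = list(self.area_labels)
        return {
            name: pd.DataFrame(getattr(self, name), index=labels, columns=labels)
            for name in ("W_ee", "W_ei", "W_ie", "W_ii", "K1", "K2")
        }


def _serial_w_ee(params: ModelParameters, n: int) -> np.ndarray:
    w = np.zeros((n, n))
    np.fill_diagonal(w, params.w_ee_d)
    for i in range(1, n):
        w[i, i - 1] = params.w_ee_ff  # feedforward: sender one step below
        w[i - 1, i] = params.w_ee_fb  # feedback: sender one step above
    return w


def _meg_matrices(params: ModelParameters, n: int) -> tuple[np.ndarray, np.ndarray]:
    """K1/K2 for the serial network.

    Only cortical rows are non-zero: subcortical areas do not generate MEG,
    but the thalamus→core feedforward synapse terminates in cortex and
    therefore does contribute.
    """
    k1 = np.zeros((n, n))
    k2 = np.zeros((n, n))
    for i in CORTICAL:
        k1[i, i] = params.k1_d
        k1[i, i - 1] = params.k1_ff
        if i + 1 < n:
            k1[i, i + 1] = params.k1_fb
        k2[i, i] = params.k2_d
    return k1, k2


def build_default_network(params: ModelParameters, n_areas: int = 5) -> NetworkTopology:
    """Construct the serial (DEF) five-area topology.

    ``W_ee`` is tridiagonal (only neighbouring areas are directly
    connected); the other weight matrices are scalar multiples of the
    identity.
    """
    if n_areas != 5:
        raise ValueError("the default builder supports exactly 5 areas")
    n = n_areas
    k1, k2 = _meg_matrices(params, n)
    return NetworkTopology(
        W_ee=_serial_w_ee(params, n),
        W_ei=params.w_ei_d * np.eye(n),
        W_ie=params.w_ie_d * np.eye(n),
        W_ii=params.w_ii_d * np.eye(n),
        K1=k1,
        K2=k2,
        variant="DEF",
    )


# Shortcut connections per variant: (receiver, sender, kind) with kind
# deciding which generic weight and MEG multiplier the new entry inherits.
_VARIANT_EDGES: dict[str, list[tuple[int, int, str]]] = {
    "CP": [(PARABELT, CORE, "ff"), (CORE, PARABELT, "fb")],
    "TB": [(BELT, THALAMUS, "ff"), (THALAMUS, BELT, "fb")],
}
_VARIANT_EDGES["CPN"] = _VARIANT_EDGES["CP"]
_VARIANT_EDGES["TBN"] = _VARIANT_EDGES["TB"]


def build_variant(
    params: ModelParameters,
    variant: str,
    *,
    added_ff: float | None = None,
    added_fb: float | None = None,
    bidirectional: bool = False,
) -> NetworkTopology:
    """Construct a structural variant of the serial network.

    CP adds a direct core→parabelt excitatory connection, TB a direct
    thalamus→belt connection; CPN/TBN additionally rescale ``W_ee``
    uniformly so that the sum of its elements equals that of the DEF
    network.  The added entry is a single feedforward connection with the
    generic serial weight ``w_ee_ff`` (override with ``added_ff``); setting
    ``bidirectional`` also adds the reciprocal feedback connection at
    ``w_ee_fb``/``added_fb``.  A MEG multiplier consistent with the
    connection type is assigned to any added entry that terminates in
    cortex.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    base = build_default_network(params)
    if variant == "DEF":
        return base

    weights = {"ff": params.w_ee_ff if added_ff is None else added_ff,
               "fb": params.w_ee_fb if added_fb is None else added_fb}
    k1_values = {"ff": params.k1_ff, "fb": params.k1_fb}

    w_ee = base.W_ee.copy()
    k1 = base.K1.copy()
    for receiver, sender, kind in _VARIANT_EDGES[variant]:
        if kind == "fb" and not bidirectional:
            continue
        w_ee[receiver, sender] = weights[kind]
        if receiver in CORTICAL:  # subcortical targets generate no MEG
            k1[receiver, sender] = k1_values[kind]

    if variant.endswith("N"):
        w_ee *= base.W_ee.sum() / w_ee.sum()

    return replace(base, W_ee=w_ee, K1=k1, variant=variant)
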
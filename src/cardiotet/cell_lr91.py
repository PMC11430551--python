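"""Luo-Rudy 1991 (LR91) ventricular action-potential model.

The reaction half of the monodomain system: a guinea-pig ventricular myocyte
membrane model with six ionic currents

* fast sodium ``I_Na`` (gates m, h, j),
* slow inward (calcium) ``I_si`` (gates d, f; dynamic intracellular Ca),
* time-dependent potassium ``I_K`` (gate X with inactivation factor Xi),
* time-independent potassium ``I_K1``,
* plateau potassium ``I_Kp``,
* background current ``I_b``,

and eight state fields per node: the membrane voltage ``V`` (mV), six
Hodgkin-Huxley gates in [0, 1] evolving as du/dt = alpha(V)(1-u) - beta(V)u,
and the intracellular calcium concentration ``Cai`` (mmol/L).

All state lives in structure-of-arrays (SoA) layout: one contiguous array per
field, the layout a SIMD backend can stream.  The roughly 60 quantities the
model touches per node split into ~20 run-constant parameters (stored once,
see :data:`CONSTANT_PARAMETERS`) and ~40 per-node varying quantities
(:data:`VARYING_PARAMETERS`); :func:`parameter_accounting` turns that
partition into the memory-footprint numbers.

Removable 0/0 singularities in the published rate formulas (alpha_m at
V = -47.13 mV, the Xi factor at V = -77 mV) are replaced by their limit
values so exact grid voltages never produce NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

from .errors import NumericStateError

__all__ = [
    "CellConstants",
    "CellStateArrays",
    "StimulusProtocol",
    "ParameterAccounting",
    "STATE_FIELDS",
    "CONSTANT_PARAMETERS",
    "VARYING_PARAMETERS",
    "init_resting",
    "resting_state",
    "ionic_currents",
    "ode_rhs",
    "reaction_rhs",
    "parameter_accounting",
]

STATE_FIELDS = ("V", "m", "h", "j", "d", "f", "X", "Cai")

#: Parameters constant throughout a simulation: stored once, not per node.
CONSTANT_PARAMETERS = (
    "C_m", "g_Na", "g_si", "g_K_bar", "g_K1_bar", "g_Kp", "g_b", "E_b",
    "K_o", "K_i", "Na_o", "Na_i", "Ca_o", "PR_NaK", "R", "T", "F",
    "E_Na", "E_K", "E_K1",
)

#: Per-node quantities that vary during the simulation (state, currents,
#: rates, steady states and scheme bookkeeping) -- one contiguous array each.
VARYING_PARAMETERS = (
    # state (8)
    "V", "m", "h", "j", "d", "f", "X", "Cai",
    # currents (8)
    "I_Na", "I_si", "I_K", "I_K1", "I_Kp", "I_b", "I_ion", "I_stim",
    # gate opening/closing rates (12)
    "alpha_m", "beta_m", "alpha_h", "beta_h", "alpha_j", "beta_j",
    "alpha_d", "beta_d", "alpha_f", "beta_f", "alpha_X", "beta_X",
    # gate steady states (6)
    "m_inf", "h_inf", "j_inf", "d_inf", "f_inf", "X_inf",
    # derived per-node quantities and stepping bookkeeping (6)
    "E_si", "Xi", "Kp", "K1_inf", "dVdt", "nbr_diff_sum",
)


@dataclass(frozen=True)
class CellConstants:
    """Fixed LR91 parameters (units: mS/cm^2 for conductances, mV for
    potentials, mmol/L for concentrations, uF/cm^2 for capacitance).

    The default values are the published LR91 set.  :meth:`short_apd` returns
    a variant with the slow-inward conductance reduced so the action
    potential repolarizes within ~60 ms; tissue-level validation runs with a
    150 ms horizon use it (the full plateau lasts ~360 ms).
    """

    C_m: float = 1.0  # membrane capacitance, uF/cm^2
    g_Na: float = 23.0
    g_si: float = 0.09
    g_K_bar: float = 0.282  # scaled by sqrt(K_o/5.4)
    g_K1_bar: float = 0.6047  # scaled by sqrt(K_o/5.4)
    g_Kp: float = 0.0183
    g_b: float = 0.03921
    E_b: float = -59.87  # background reversal, mV
    K_o: float = 5.4
    K_i: float = 145.0
    Na_o: float = 140.0
    Na_i: float = 18.0
    Ca_o: float = 1.8
    PR_NaK: float = 0.01833  # Na/K permeability ratio in E_K
    R: float = 8.314  # J/(mol K)
    T: float = 310.15  # K
    F: float = 96485.0  # C/mol

    @property
    def RTF(self) -> float:
        """R*T/F in mV."""
        return 1000.0 * self.R * self.T / self.F

    @property
    def E_Na(self) -> float:
        return self.RTF * math.log(self.Na_o / self.Na_i)

    @property
    def E_K(self) -> float:
        return self.RTF * math.log(
            (self.K_o + self.PR_NaK * self.Na_o)
            / (self.K_i + self.PR_NaK * self.Na_i)
        )

    @property
    def E_K1(self) -> float:
        return self.RTF * math.log(self.K_o / self.K_i)

    @property
    def g_K(self) -> float:
        return self.g_K_bar * math.sqrt(self.K_o / 5.4)

    @property
    def g_K1(self) -> float:
        return self.g_K1_bar * math.sqrt(self.K_o / 5.4)

    @classmethod
    def short_apd(cls) -> "CellConstants":
        """Short-plateau variant: g_si reduced to zero so the action
        potential duration drops from ~360 ms to ~55 ms, matching tissue
        experiments that expect full repolarization within a 150 ms run."""
        return cls(g_si=0.0)

    def to_dict(self) -> dict:
        """Plain dict of the stored constants (keys are the field names)."""
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def save(self, path: str) -> None:
        """Serialize to a JSON text file."""
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "CellConstants":
        import json

        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class CellStateArrays:
    """Structure-of-arrays cell state: one contiguous row per field.

    ``data`` is an (8, n_nodes) C-contiguous array; the named properties
    (``V``, ``m``, ..., ``Cai``) are zero-copy row views, so each model
    parameter is stored separately and contiguously.
    """

    data: np.ndarray

    def __post_init__(self):
        data = np.ascontiguousarray(np.asarray(self.data, dtype=np.float64))
        if data.ndim != 2 or data.shape[0] != len(STATE_FIELDS):
            raise ValueError(
                f"state data must be ({len(STATE_FIELDS)}, n_nodes), got {data.shape}"
            )
        self.data = data

    @classmethod
    def from_fields(cls, **fields_) -> "CellStateArrays":
        arrays = [np.atleast_1d(np.asarray(fields_[name], dtype=np.float64))
                  for name in STATE_FIELDS]
        return cls(data=np.stack(arrays, axis=0))

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "CellStateArrays":
        return CellStateArrays(data=self.data.copy())

    def to_csv(self, path: str) -> None:
        """Per-node state dump: one row per node, one column per field."""
        header = "node_id," + ",".join(STATE_FIELDS)
        np.savetxt(
            path,
            np.column_stack([np.arange(self.n_nodes), self.data.T]),
            delimiter=",",
            header=header,
            comments="",
            fmt=["%d"] + ["%.17g"] * len(STATE_FIELDS),
        )

    @classmethod
    def from_csv(cls, path: str) -> "CellStateArrays":
        raw = np.loadtxt(path, delimiter=",", skiprows=1)
        raw = np.atleast_2d(raw)
        return cls(data=np.ascontiguousarray(raw[:, 1:].T))

    def validate(self) -> None:
        """Raise :class:`NumericStateError` if any entry is non-finite, and
        ValueError if gates leave [0, 1] or Cai is non-positive."""
        if not np.all(np.isfinite(self.data)):
            f, node = np.argwhere(~np.isfinite(self.data))[0]
            raise NumericStateError(
                f"non-finite {STATE_FIELDS[f]} at node {node}"
            )
        gates = self.data[1:7]
        if gates.min() < 0.0 or gates.max() > 1.0:
            raise ValueError("gate variable outside [0, 1]")
        if self.Cai.min() <= 0.0:
            raise ValueError("intracellular calcium must stay positive")


for _i, _name in enumerate(STATE_FIELDS):
    setattr(
        CellStateArrays,
        _name,
        property(lambda self, _i=_i: self.data[_i],
                 doc=f"per-node {_name} (contiguous row view)"),
    )
del _i, _name


@dataclass(frozen=True)
class StimulusProtocol:
    """External stimulus current applied to a node set.

    ``amplitude`` follows the membrane-equation sign convention
    dV/dt = -(I_ion + I_stim)/C_m, so a *negative* amplitude depolarizes.
    With ``period`` set the pulse repeats every ``period`` ms (pacing),
    which long-duration runs need to keep producing activity.
    """

    nodes: np.ndarray  # node indices receiving current
    amplitude: float = -80.0  # uA/cm^2
    t_start: float = 0.0  # ms
    duration: float = 0.5  # ms
    period: Optional[float] = None  # ms; None = single pulse

    def __post_init__(self):
        object.__setattr__(
            self, "nodes", np.atleast_1d(np.asarray(self.nodes, dtype=np.int64))
        )
        if self.duration < 0:
            raise ValueError("stimulus duration must be >= 0")
        if not math.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")
        if self.period is not None and self.period <= 0:
            raise ValueError("stimulus period must be positive")

    @classmethod
    def from_box(cls, mesh, box, **kwargs) -> "StimulusProtocol":
        """Stimulate all nodes inside the axis-aligned coordinate box
        ``(x0, x1, y0, y1, z0, z1)``."""
        x0, x1, y0, y1, z0, z1 = box
        c = mesh.coords
        inside = (
            (c[:, 0] >= x0) & (c[:, 0] <= x1)
            & (c[:, 1] >= y0) & (c[:, 1] <= y1)
            & (c[:, 2] >= z0) & (c[:, 2] <= z1)
        )
        return cls(nodes=np.nonzero(inside)[0], **kwargs)

    def active_at(self, t: float) -> bool:
        """Whether the pulse is on at time ``t`` (ms)."""
        if t < self.t_start:
            return False
        phase = t - self.t_start
        if self.period is not None:
            phase = phase % self.period
        return phase < self.duration

    def current_vector(self, n_nodes: int, t: float) -> np.ndarray:
        """Per-node I_stim (uA/cm^2) at time ``t``."""
        stim = np.zeros(n_nodes)
        if self.active_at(t):
            stim[self.nodes] = self.amplitude
        return stim


# ---------------------------------------------------------------------------
# rate functions and currents (array-or-scalar numpy code)
# ---------------------------------------------------------------------------


def _safe_ratio(num, den, singular, limit):
    """num/den with the removable singularity at ``den == 0`` replaced by
    its analytic limit.  ``singular`` marks the offending entries."""
    den_safe = np.where(singular, 1.0, den)
    return np.where(singular, limit, num / den_safe)


def gate_rates(V):
    """All twelve LR91 gate opening/closing rates at voltage ``V`` (ms^-1).

    Returns a dict {gate: (alpha, beta)} for gates m, h, j, d, f, X.
    """
    V = np.asarray(V, dtype=np.float64)

    dv = V + 47.13
    singular = np.abs(dv) < 1e-7
    a_m = _safe_ratio(0.32 * dv, 1.0 - np.exp(-0.1 * dv), singular, 3.2)
    b_m = 0.08 * np.exp(-V / 11.0)

    # h and j switch formulas at V = -40 mV
    low = V < -40.0
    a_h = np.where(low, 0.135 * np.exp(-(80.0 + V) / 6.8), 0.0)
    b_h = np.where(
        low,
        3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
        1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
    )
    a_j = np.where(
        low,
        (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
        * (V + 37.78)
        / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0,
    )
    b_j = np.where(
        low,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )

    a_d = 0.095 * np.exp(-0.01 * (V - 5.0)) / (1.0 + np.exp(-0.072 * (V - 5.0)))
    b_d = 0.07 * np.exp(-0.017 * (V + 44.0)) / (1.0 + np.exp(0.05 * (V + 44.0)))
    a_f = 0.012 * np.exp(-0.008 * (V + 28.0)) / (1.0 + np.exp(0.15 * (V + 28.0)))
    b_f = 0.0065 * np.exp(-0.02 * (V + 30.0)) / (1.0 + np.exp(-0.2 * (V + 30.0)))
    a_X = 0.0005 * np.exp(0.083 * (V + 50.0)) / (1.0 + np.exp(0.057 * (V + 50.0)))
    b_X = 0.0013 * np.exp(-0.06 * (V + 20.0)) / (1.0 + np.exp(-0.04 * (V + 20.0)))

    return {
        "m": (a_m, b_m),
        "h": (a_h, b_h),
        "j": (a_j, b_j),
        "d": (a_d, b_d),
        "f": (a_f, b_f),
        "X": (a_X, b_X),
    }


def _xi_factor(V):
    """Inactivation factor Xi of I_K: 1 below -100 mV, otherwise the
    published expression with its removable singularity at V = -77 mV."""
    V = np.asarray(V, dtype=np.float64)
    dv = V + 77.0
    singular = np.abs(dv) < 1e-7
    expr = _safe_ratio(
        2.837 * (np.exp(0.04 * dv) - 1.0),
        dv * np.exp(0.04 * (V + 35.0)),
        singular,
        2.837 * 0.04 / np.exp(0.04 * (-77.0 + 35.0)),
    )
    return np.where(V > -100.0, expr, 1.0)


def compute_currents(V, m, h, j, d, f, X, Cai, consts: CellConstants) -> dict:
    """The six LR91 membrane currents (uA/cm^2) as a dict; pure function."""
    E_si = 7.7 - 13.0287 * np.log(Cai)
    I_Na = consts.g_Na * m * m * m * h * j * (V - consts.E_Na)
    I_si = consts.g_si * d * f * (V - E_si)
    I_K = consts.g_K * X * _xi_factor(V) * (V - consts.E_K)

    dv1 = V - consts.E_K1
    a_K1 = 1.02 / (1.0 + np.exp(0.2385 * (dv1 - 59.215)))
    b_K1 = (
        0.49124 * np.exp(0.08032 * (dv1 + 5.476))
        + np.exp(0.06175 * (dv1 - 594.31))
    ) / (1.0 + np.exp(-0.5143 * (dv1 + 4.753)))
    I_K1 = consts.g_K1 * (a_K1 / (a_K1 + b_K1)) * dv1

    Kp = 1.0 / (1.0 + np.exp((7.488 - V) / 5.98))
    I_Kp = consts.g_Kp * Kp * (V - consts.E_K1)
    I_b = consts.g_b * (V - consts.E_b)

    return {
        "I_Na": I_Na, "I_si": I_si, "I_K": I_K,
        "I_K1": I_K1, "I_Kp": I_Kp, "I_b": I_b,
    }


def ionic_currents(
    state: CellStateArrays, consts: CellConstants = CellConstants()
):
    """Total transmembrane ionic current and its per-channel breakdown.

    Returns ``(I_ion, channels)`` where ``I_ion`` is the per-node sum
    (uA/cm^2) and ``channels`` maps the six current names to per-node
    arrays.  Raises :class:`NumericStateError` naming the first offending
    node if the state holds non-finite values.
    """
    if not np.all(np.isfinite(state.data)):
        f_, node = np.argwhere(~np.isfinite(state.data))[0]
        raise NumericStateError(f"non-finite {STATE_FIELDS[f_]} at node {node}")
    channels = compute_currents(
        state.V, state.m, state.h, state.j, state.d, state.f, state.X,
        state.Cai, consts,
    )
    total = (
        channels["I_Na"] + channels["I_si"] + channels["I_K"]
        + channels["I_K1"] + channels["I_Kp"] + channels["I_b"]
    )
    return total, channels


def reaction_rhs(Y: np.ndarray, consts: CellConstants, stim) -> np.ndarray:
    """Time derivatives of the full (8, n) state block ``Y``.

    Row order follows :data:`STATE_FIELDS`; ``stim`` is the per-node
    stimulus current (uA/cm^2, scalar or array).  This is the hot kernel:
    plain array expressions, no data-dependent branching, so it runs
    identically on full arrays and on length-1 node slices.
    """
    V, m, h, j, d, f, X, Cai = Y
    ch = compute_currents(V, m, h, j, d, f, X, Cai, consts)
    I_ion = (ch["I_Na"] + ch["I_si"] + ch["I_K"] + ch["I_K1"]
             + ch["I_Kp"] + ch["I_b"])
    rates = gate_rates(V)
    K = np.empty_like(Y)
    K[0] = -(I_ion + stim) / consts.C_m
    for row, gate in ((1, "m"), (2, "h"), (3, "j"), (4, "d"), (5, "f"), (6, "X")):
        a, b = rates[gate]
        K[row] = a * (1.0 - Y[row]) - b * Y[row]
    K[7] = -1e-4 * ch["I_si"] + 0.07 * (1e-4 - Cai)
    return K


def ode_rhs(
    state: CellStateArrays,
    consts: CellConstants = CellConstants(),
    stim=0.0,
) -> CellStateArrays:
    """Reaction derivatives as a :class:`CellStateArrays`-shaped container.

    dV/dt = -(I_ion + I_stim)/C_m; gates follow du/dt = alpha(1-u) - beta*u;
    dCai/dt couples to the slow inward current.
    """
    if not np.all(np.isfinite(state.data)):
        f_, node = np.argwhere(~np.isfinite(state.data))[0]
        raise NumericStateError(f"non-finite {STATE_FIELDS[f_]} at node {node}")
    return CellStateArrays(data=reaction_rhs(state.data, consts, np.asarray(stim)))


# ---------------------------------------------------------------------------
# resting state
# ---------------------------------------------------------------------------

_RESTING_CACHE: dict[CellConstants, np.ndarray] = {}


def _steady_cai(V: float, consts: CellConstants) -> float:
    """Calcium fixed point 0 = -1e-4 I_si + 0.07 (1e-4 - Cai) at voltage V
    with d, f at their steady states (the residual is monotone in Cai)."""
    from scipy.optimize import brentq

    rates = gate_rates(V)
    d_inf = float(rates["d"][0] / (rates["d"][0] + rates["d"][1]))
    f_inf = float(rates["f"][0] / (rates["f"][0] + rates["f"][1]))

    def residual(cai):
        I_si = consts.g_si * d_inf * f_inf * (V - (7.7 - 13.0287 * math.log(cai)))
        return -1e-4 * I_si + 0.07 * (1e-4 - cai)

    return brentq(residual, 1e-9, 1e-1, xtol=1e-16, rtol=1e-15)


def resting_state(consts: CellConstants = CellConstants()) -> np.ndarray:
    """The single-cell resting equilibrium as an (8,) state vector.

    Gates sit at alpha/(alpha+beta) of the resting voltage, calcium at its
    fixed point, and the voltage at the root of the steady-state total
    current (~ -84 mV for default constants).  Cached per constants set.
    """
    cached = _RESTING_CACHE.get(consts)
    if cached is not None:
        return cached.copy()
    from scipy.optimize import brentq

    def steady_current(V):
        rates = gate_rates(V)
        g = {k: float(a / (a + b)) for k, (a, b) in rates.items()}
        cai = _steady_cai(V, consts)
        ch = compute_currents(
            V, g["m"], g["h"], g["j"], g["d"], g["f"], g["X"], cai, consts
        )
        return float(sum(ch.values()))

    V0 = brentq(steady_current, -95.0, -70.0, xtol=1e-13, rtol=8.9e-16)
    rates = gate_rates(V0)
    g = {k: float(a / (a + b)) for k, (a, b) in rates.items()}
    state = np.array(
        [V0, g["m"], g["h"], g["j"], g["d"], g["f"], g["X"],
         _steady_cai(V0, consts)]
    )
    _RESTING_CACHE[consts] = state
    return state.copy()


def init_resting(
    n_nodes: int, consts: CellConstants = CellConstants()
) -> CellStateArrays:
    """All ``n_nodes`` cells at the LR91 resting equilibrium.

    With zero stimulus and zero diffusion the returned state is a fixed
    point of the dynamics to solver precision.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    eq = resting_state(consts)
    return CellStateArrays(data=np.repeat(eq[:, None], n_nodes, axis=1))


# ---------------------------------------------------------------------------
# memory accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterAccounting:
    """Per-node memory footprint of the model before/after extracting the
    run-constant parameters into shared single-copy storage."""

    n_total: int
    n_constant: int
    n_varying: int
    bytes_naive: int
    bytes_optimized: int
    percent_saved: int


def parameter_accounting(
    n_total: Optional[int] = None,
    n_constant: Optional[int] = None,
    bytes_per_param: int = 8,
) -> ParameterAccounting:
    """Memory accounting for the constant-parameter extraction.

    Without arguments the module's own LR91 enumeration is used
    (:data:`CONSTANT_PARAMETERS` + :data:`VARYING_PARAMETERS`: 60 quantities,
    20 of them run-constant).  ``bytes_naive`` counts every parameter per
    node; ``bytes_optimized`` counts only the varying ones (constants are
    stored once, off the per-node budget).
    """
    if n_total is None:
        n_total = len(CONSTANT_PARAMETERS) + len(VARYING_PARAMETERS)
    if n_constant is None:
        n_constant = len(CONSTANT_PARAMETERS)
    if not (0 <= n_constant <= n_total):
        raise ValueError("need 0 <= n_constant <= n_total")
    n_varying = n_total - n_constant
    bytes_naive = n_total * bytes_per_param
    bytes_optimized = n_varying * bytes_per_param
    saved = 0 if bytes_naive == 0 else 100.0 * (bytes_naive - bytes_optimized) / bytes_naive
    return ParameterAccounting(
        n_total=n_total,
        n_constant=n_constant,
        n_varying=n_varying,
        bytes_naive=bytes_naive,
        bytes_optimized=bytes_optimized,
        percent_saved=int(round(saved)),
    )
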
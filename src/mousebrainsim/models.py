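"""Node models: the bistable reduced Wong-Wang mean field and the networked
Epileptor.

Time unit is the millisecond throughout; firing rates are in Hz, so the
Wong-Wang gating drift carries an explicit 1/1000 conversion.

The reduced Wong-Wang model (eMFM — *enhanced nonlinearity mean-field
model*) describes each brain region by one NMDA synaptic gating variable
``S`` driven by the population firing rate through the transfer function
``H``.  With the defaults below each isolated region is bistable — it
possesses a low- and a high-activity stable fixed point — which is the
regime that produces the switching (non-stationary) functional connectivity
this package analyzes.

The Epileptor is a six-variable phenomenological seizure model: a fast
ensemble (x1, y1) for ictal discharges, an intermediate ensemble (x2, y2)
for spike-and-wave events, the slow permittivity variable z that carries the
node through seizure onset and offset, and the low-pass memory variable g
coupling the fast ensemble into the second one.  Brain regions interact
through a permittivity coupling: weighted differences of the fast variables
entering the z equation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EmfmParams",
    "EpileptorParams",
    "EmfmModel",
    "EpileptorModel",
    "sigmoid_H",
    "emfm_coupling",
    "emfm_drift",
    "emfm_fixed_points",
    "epileptor_coupling",
    "epileptor_drift",
]


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# reduced Wong-Wang (eMFM)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmfmParams:
    """Parameters of the reduced Wong-Wang population model.

    ``gamma`` (kinetic parameter) is stored as printed (0.641); the drift
    divides it by 1000 because rates are in Hz and time is in ms.  ``w`` is
    the local excitatory recurrence and ``I_0`` the external input current;
    the default pair (1.0, 0.32 nA) places each isolated region in the
    bistable regime (with I_0 = 0.30 the node is monostable — see the
    methods note).  ``G`` scales all connection strengths; ``sigma`` is the
    amplitude of the additive Gaussian noise on S.
    """

    gamma: float = 0.641          # kinetic parameter, dimensionless
    tau_s: float = 100.0          # NMDA decay time constant, ms
    a: float = 270.0              # transfer-function gain, 1/nC
    b: float = 108.0              # transfer-function threshold, Hz
    d: float = 0.154              # transfer-function curvature, s
    J_N: float = 0.2609           # synaptic current scale, nA
    w: float = 1.0                # local excitatory recurrence
    I_0: float = 0.32             # external input current, nA
    G: float = 0.096              # global coupling strength
    sigma: float = 5.1e-3         # noise amplitude on S

    def __post_init__(self):
        for name in ("tau_s", "a", "d", "J_N"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive")
        if self.G < 0 or self.sigma < 0:
            raise ModelError("G and sigma must be nonnegative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EmfmParams":
        return cls(**json.loads(text))


def sigmoid_H(x, params: Optional[EmfmParams] = None) -> np.ndarray:
    """Population transfer function H(x) = (a x - b) / (1 - exp(-d (a x - b))).

    Continuous and strictly increasing; the removable singularity at
    ``a x = b`` evaluates to ``1/d``.  Output in Hz, always positive.
    """
    p = params or EmfmParams()
    u = p.a * np.asarray(x, dtype=float) - p.b
    du = p.d * u
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        core = u / (1.0 - np.exp(-du))
        # series around the singularity: u/(1-e^{-du}) = 1/d + u/2 + O(du^2)/...
        small = 1.0 / p.d + u / 2.0
        # far below threshold 1 - e^{-du} ~ -e^{-du}: H ~ -u e^{du} -> 0+
        tiny = -u * np.exp(du)
    out = np.where(np.abs(du) < 1e-6, small, core)
    out = np.where(du < -500.0, tiny, out)
    return out if out.ndim else float(out)


def emfm_coupling(S, C, params: Optional[EmfmParams] = None) -> np.ndarray:
    """Synaptic input x_i = w J_N S_i + J_N G sum_j C_ij S_j + I_0 (nA)."""
    p = params or EmfmParams()
    S = np.atleast_1d(np.asarray(S, dtype=float))
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] != S.shape[-1]:
        raise ModelError(
            f"coupling dimension mismatch: S has {S.shape[-1]} regions, C is {C.shape}"
        )
    return p.w * p.J_N * S + p.J_N * p.G * (C @ S) + p.I_0


def emfm_drift(S, C, params: Optional[EmfmParams] = None) -> np.ndarray:
    """Deterministic drift dS/dt (per ms): -S/tau_s + (1 - S) gamma H(x)/1000.

    Noise is handled by the integrator, not here.
    """
    p = params or EmfmParams()
    S = np.asarray(S, dtype=float)
    x = emfm_coupling(S, C, p)
    return -S / p.tau_s + (1.0 - S) * (p.gamma / 1000.0) * sigmoid_H(x, p)


def emfm_fixed_points(
    params: Optional[EmfmParams] = None, n_grid: int = 4001
) -> list:
    """Fixed points of an isolated node (G = 0) on S in [0, 1].

    Returns ``[(S_root, stable), ...]`` found by a sign-change scan refined
    with Brent's method; stability from the local drift slope.
    """
    p = params or EmfmParams()
    C = np.zeros((1, 1))

    def f(s):
        return float(emfm_drift(np.array([s]), C, p)[0])

    grid = np.linspace(0.0, 1.0, n_grid)
    vals = np.array([f(s) for s in grid])
    roots = []
    for i in range(n_grid - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-14))
    out = []
    for r in roots:
        h = 1e-6
        slope = (f(min(r + h, 1.0)) - f(max(r - h, 0.0))) / (2 * h)
        out.append((float(r), bool(slope < 0)))
    return out


class EmfmModel:
    """Reduced Wong-Wang network model: state = (S,) per region."""

    name = "emfm"
    state_variables: Tuple[str, ...] = ("S",)
    noisy_variables: Tuple[str, ...] = ("S",)
    default_dt_ms = 0.1
    default_scheme = "euler_maruyama"

    def __init__(self, params: Optional[EmfmParams] = None):
        self.params = params or EmfmParams()

    def default_noise_amplitudes(self) -> dict:
        return {"S": self.params.sigma}

    def drift(self, state: np.ndarray, C: np.ndarray) -> np.ndarray:
        return emfm_drift(state[0], C, self.params)[None, :]

    def initial_state(self, rng: np.random.Generator, n_regions: int) -> np.ndarray:
        # uniform gating per region; the network then relaxes into an attractor
        return rng.uniform(0.0, 1.0, size=(1, n_regions))

    def clamp(self, state: np.ndarray) -> np.ndarray:
        # the gating variable is a channel fraction: keep it in [0, 1]
        return np.clip(state, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Epileptor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpileptorParams:
    """Parameters of the networked Epileptor.

    ``x0`` is the degree of epileptogenicity: an isolated node with
    ``x0 > x0_critical`` (i.e. |x0| below 2.06) seizes autonomously, one
    below it rests at equilibrium and can only be recruited.  ``r`` sets the
    slow permittivity timescale (1/r in ms); ``Ks`` scales the permittivity
    coupling.  ``x0_overrides`` maps region labels to per-region
    epileptogenicity values on top of the global default.
    """

    I1: float = 3.1
    I2: float = 0.45
    tau: float = 10.0
    gamma_g: float = 0.01
    r: float = 3.5e-4
    Ks: float = -60.0
    x0: float = -2.1
    x0_critical: float = -2.06
    x0_overrides: Optional[Tuple[Tuple[str, float], ...]] = None

    def __post_init__(self):
        if self.tau <= 0 or self.gamma_g <= 0 or self.r <= 0:
            raise ModelError("tau, gamma_g and r must be positive")
        if self.x0_overrides is not None:
            object.__setattr__(
                self, "x0_overrides", tuple((str(k), float(v)) for k, v in self.x0_overrides)
            )

    def x0_vector(self, region_labels: Sequence[str]) -> np.ndarray:
        """Per-region epileptogenicity from the default plus label overrides."""
        x0 = np.full(len(region_labels), self.x0, dtype=float)
        if self.x0_overrides:
            lowered = [l.lower() for l in region_labels]
            for name, value in self.x0_overrides:
                if name in region_labels:
                    x0[list(region_labels).index(name)] = value
                elif name.lower() in lowered:
                    x0[lowered.index(name.lower())] = value
                else:
                    raise ModelError(f"x0 override for unknown region {name!r}")
        if not np.all(np.isfinite(x0)):
            raise ModelError("x0 must be finite for every region")
        return x0

    def to_json(self) -> str:
        d = asdict(self)
        if d["x0_overrides"] is not None:
            d["x0_overrides"] = dict(d["x0_overrides"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EpileptorParams":
        d = json.loads(text)
        if d.get("x0_overrides"):
            d["x0_overrides"] = tuple(d["x0_overrides"].items())
        return cls(**d)


def epileptor_coupling(x1, C, Ks: float = -60.0) -> np.ndarray:
    """Permittivity coupling term_i = Ks sum_j C_ij (x1_j - x1_i).

    A linear difference coupling: it vanishes when all fast variables agree,
    and for symmetric C the terms sum to zero over regions.
    """
    x1 = np.asarray(x1, dtype=float)
    C = np.asarray(C, dtype=float)
    if C.shape != (x1.shape[-1], x1.shape[-1]):
        raise ModelError(
            f"coupling dimension mismatch: x1 has {x1.shape[-1]} regions, C is {C.shape}"
        )
    return Ks * (C @ x1 - C.sum(axis=1) * x1)


def epileptor_drift(
    state: np.ndarray,
    C: np.ndarray,
    params: Optional[EpileptorParams] = None,
    x0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Six-component derivative of the networked Epileptor.

    ``state`` has shape (6, N) ordered (x1, y1, z, x2, y2, g).  The slow
    variable's restoring term gains ``-0.1 z^7`` only for z < 0, and the
    network enters through the permittivity coupling in dz/dt.
    """
    p = params or EpileptorParams()
    x1, y1, z, x2, y2, g = state
    if x0 is None:
        x0 = np.full_like(x1, p.x0)
    f1 = np.where(
        x1 < 0,
        x1**3 - 3.0 * x1**2,
        (x2 - 0.6 * (z - 4.0) ** 2) * x1,
    )
    f2 = np.where(x2 < -0.25, 0.0, 6.0 * (x2 + 0.25))
    dx1 = y1 - f1 - z + p.I1
    dy1 = 1.0 - 5.0 * x1**2 - y1
    dz = p.r * (
        4.0 * (x1 - x0) - z - np.where(z < 0, 0.1 * z**7, 0.0)
    ) + epileptor_coupling(x1, C, p.Ks)
    dx2 = -y2 + x2 - x2**3 + p.I2 + 0.002 * g - 0.3 * (z - 3.5)
    dy2 = (-y2 + f2) / p.tau
    dg = x1 - p.gamma_g * g
    return np.stack([dx1, dy1, dz, dx2, dy2, dg])


#: generic pre-ictal starting point; g = x1/gamma_g is its own steady state
EPILEPTOR_START = np.array([-1.6, -11.8, 3.0, -1.0, 0.0, -160.0])


class EpileptorModel:
    """Networked Epileptor: state = (x1, y1, z, x2, y2, g) per region."""

    name = "epileptor"
    state_variables: Tuple[str, ...] = ("x1", "y1", "z", "x2", "y2", "g")
    noisy_variables: Tuple[str, ...] = ("x2", "y2")
    default_dt_ms = 0.04
    default_scheme = "heun_stochastic"

    def __init__(
        self,
        params: Optional[EpileptorParams] = None,
        region_labels: Optional[Sequence[str]] = None,
    ):
        self.params = params or EpileptorParams()
        self.region_labels = list(region_labels) if region_labels is not None else None

    def default_noise_amplitudes(self) -> dict:
        # additive white noise of variance 0.0025 on the intermediate
        # ensemble: sigma = sqrt(0.0025) under the wiener_sigma convention
        amp = float(np.sqrt(0.0025))
        return {"x2": amp, "y2": amp}

    def x0_vector(self, n_regions: int) -> np.ndarray:
        labels = self.region_labels or [str(i) for i in range(n_regions)]
        if len(labels) != n_regions:
            raise ModelError(
                f"model has {len(labels)} region labels but network has {n_regions}"
            )
        return self.params.x0_vector(labels)

    def drift(self, state: np.ndarray, C: np.ndarray) -> np.ndarray:
        return epileptor_drift(state, C, self.params, self.x0_vector(state.shape[1]))

    def initial_state(self, rng: np.random.Generator, n_regions: int) -> np.ndarray:
        # per-node deterministic relaxation, so that seizures emerge from the
        # dynamics rather than from initial transients
        from .integrate import epileptor_relaxed_state

        return epileptor_relaxed_state(self.params, self.x0_vector(n_regions))

    def clamp(self, state: np.ndarray) -> np.ndarray:
        return state
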
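"""Stochastic integrators, simulation orchestration, and monitors.

Two fixed-step schemes are provided: Euler-Maruyama and stochastic Heun
(predictor-corrector with the same Wiener increment in both stages).  Noise
amplitudes can follow either of two conventions:

``wiener_sigma``
    the drift line carries ``sigma * eta(t)`` read literally as an SDE with
    amplitude sigma, so a step adds ``sigma * sqrt(dt) * xi``;
``tvb_nsig``
    the amplitude is a diffusion intensity ``nsig`` and a step adds
    ``sqrt(2 * nsig * dt) * xi``.

All randomness flows from one seeded ``numpy.random.Generator``; per-step
normal draws are made in a fixed (step, variable, region) order so the
result does not depend on chunking or vectorization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .connectome import Connectome
from .models import EPILEPTOR_START, EmfmModel, EpileptorModel, EpileptorParams

SCHEMES = ("euler_maruyama", "heun_stochastic")
NOISE_CONVENTIONS = ("wiener_sigma", "tvb_nsig")
_CHUNK_STEPS = 100_000


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class IntegratorSpec:
    """Scheme, step size, noise amplitudes (per state variable) and seed."""

    scheme: str = "euler_maruyama"
    dt_ms: float = 0.1
    noise_amplitudes: Tuple[Tuple[str, float], ...] = ()
    noise_convention: str = "wiener_sigma"
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise IntegrationError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.noise_convention not in NOISE_CONVENTIONS:
            raise IntegrationError(
                f"noise_convention must be one of {NOISE_CONVENTIONS}"
            )
        if self.dt_ms <= 0:
            raise IntegrationError("dt_ms must be positive")
        amps = tuple((str(k), float(v)) for k, v in dict(self.noise_amplitudes).items())
        if any(v < 0 for _, v in amps):
            raise IntegrationError("noise amplitudes must be nonnegative")
        object.__setattr__(self, "noise_amplitudes", amps)

    def increment_scale(self, amplitude: float) -> float:
        """Standard deviation of one noise increment for a given amplitude."""
        if self.noise_convention == "wiener_sigma":
            return amplitude * np.sqrt(self.dt_ms)
        return np.sqrt(2.0 * amplitude * self.dt_ms)


@dataclass
class SimulationResult:
    """Monitored multivariate time series.

    ``data`` has shape (time, state_variable, region); ``times`` are in ms,
    strictly increasing with uniform spacing ``dt_effective``.
    """

    times: np.ndarray
    data: np.ndarray
    state_variables: Tuple[str, ...]
    dt_effective: float
    seed: int
    region_labels: Optional[Sequence[str]] = None
    metadata: Dict = field(default_factory=dict)

    def get(self, svar: str) -> np.ndarray:
        """(time, region) series of one state variable."""
        if svar not in self.state_variables:
            raise KeyError(
                f"state variable {svar!r} not monitored; have {self.state_variables}"
            )
        return self.data[:, self.state_variables.index(svar), :]

    @property
    def n_regions(self) -> int:
        return self.data.shape[2]

    def to_dir(self, path: str | Path) -> Path:
        """Serialize as delimited text (one regions x time file per variable)
        with a JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, svar in enumerate(self.state_variables):
            np.savetxt(path / f"{svar}.txt", self.data[:, i, :].T, fmt="%.9g")
        sidecar = {
            "state_variables": list(self.state_variables),
            "dt_effective_ms": self.dt_effective,
            "t0_ms": float(self.times[0]) if len(self.times) else 0.0,
            "seed": self.seed,
            "region_labels": list(self.region_labels) if self.region_labels is not None else None,
            "metadata": self.metadata,
        }
        (path / "series.json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "SimulationResult":
        path = Path(path)
        sidecar = json.loads((path / "series.json").read_text())
        svars = tuple(sidecar["state_variables"])
        mats = [np.loadtxt(path / f"{s}.txt", ndmin=2).T for s in svars]
        data = np.stack(mats, axis=1)
        dt = float(sidecar["dt_effective_ms"])
        t0 = float(sidecar.get("t0_ms", 0.0))
        return cls(
            times=t0 + dt * np.arange(data.shape[0]),
            data=data,
            state_variables=svars,
            dt_effective=dt,
            seed=int(sidecar["seed"]),
            region_labels=sidecar.get("region_labels"),
            metadata=sidecar.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# generic single steps (reference path; the model kernels specialize these)
# ---------------------------------------------------------------------------

def _draw_increment(shape, noise_amp, dt, rng, convention):
    amp = np.broadcast_to(np.asarray(noise_amp, dtype=float), shape)
    if not np.any(amp > 0):
        return 0.0
    if convention == "wiener_sigma":
        scale = amp * np.sqrt(dt)
    else:
        scale = np.sqrt(2.0 * amp * dt)
    return scale * rng.standard_normal(shape)


def euler_maruyama_step(
    state: np.ndarray,
    drift_fn: Callable[[np.ndarray], np.ndarray],
    dt: float,
    noise_amp=0.0,
    rng: Optional[np.random.Generator] = None,
    convention: str = "wiener_sigma",
) -> np.ndarray:
    """One explicit Euler-Maruyama step: state + dt*drift + increment."""
    state = np.asarray(state, dtype=float)
    dw = _draw_increment(state.shape, noise_amp, dt, rng or np.random.default_rng(), convention)
    new = state + dt * drift_fn(state) + dw
    if not np.all(np.isfinite(new)):
        raise IntegrationError("non-finite state after Euler-Maruyama step")
    return new


def heun_stochastic_step(
    state: np.ndarray,
    drift_fn: Callable[[np.ndarray], np.ndarray],
    dt: float,
    noise_amp=0.0,
    rng: Optional[np.random.Generator] = None,
    convention: str = "wiener_sigma",
) -> np.ndarray:
    """One stochastic Heun step; the same Wiener increment enters the
    predictor and the corrector."""
    state = np.asarray(state, dtype=float)
    dw = _draw_increment(state.shape, noise_amp, dt, rng or np.random.default_rng(), convention)
    d0 = drift_fn(state)
    pred = state + dt * d0 + dw
    new = state + 0.5 * dt * (d0 + drift_fn(pred)) + dw
    if not np.all(np.isfinite(new)):
        raise IntegrationError("non-finite state after Heun step")
    return new


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _weights_of(connectome) -> Tuple[np.ndarray, Optional[Sequence[str]]]:
    if isinstance(connectome, Connectome):
        return connectome.weights, list(connectome.region_labels)
    w = np.asarray(connectome, dtype=float)
    return w, None


def default_integrator_spec(model, seed: int = 0) -> IntegratorSpec:
    """Per-model defaults: Euler at 0.1 ms with sigma on S for the mean-field
    model; stochastic Heun at 0.04 ms with variance-0.0025 noise on (x2, y2)
    for the Epileptor."""
    return IntegratorSpec(
        scheme=model.default_scheme,
        dt_ms=model.default_dt_ms,
        noise_amplitudes=tuple(model.default_noise_amplitudes().items()),
        seed=seed,
    )


def simulate(
    model,
    connectome,
    duration_ms: float,
    spec: Optional[IntegratorSpec] = None,
    record_period_ms: Optional[float] = None,
    initial_state: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Integrate a network model and return the monitored series.

    ``record_period_ms=None`` records every step.  Reproducible for a fixed
    ``spec.seed``; the eMFM path clamps S to [0, 1] after every step.
    """
    C, labels = _weights_of(connectome)
    n = C.shape[0]
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise IntegrationError(f"weight matrix must be square, got {C.shape}")
    spec = spec or default_integrator_spec(model)
    dt = spec.dt_ms
    rec_every = 1
    if record_period_ms is not None:
        rec_every = int(round(record_period_ms / dt))
        if rec_every < 1 or record_period_ms < dt:
            raise IntegrationError(
                f"record period {record_period_ms} ms below integration step {dt} ms"
            )
    n_steps = int(round(duration_ms / dt))
    n_rec = n_steps // rec_every + 1
    rng = np.random.default_rng(spec.seed)

    svars = tuple(model.state_variables)
    if initial_state is None:
        state = np.asarray(model.initial_state(rng, n), dtype=float)
    else:
        state = np.array(initial_state, dtype=float).reshape(len(svars), n)
    if hasattr(model, "clamp"):
        state = model.clamp(state)

    out = np.empty((n_rec, len(svars), n))
    out[0] = state

    amps = dict(spec.noise_amplitudes)
    noisy = [v for v in model.noisy_variables if amps.get(v, 0.0) > 0.0]
    scales = np.array([spec.increment_scale(amps[v]) for v in noisy])

    if isinstance(model, EmfmModel) and spec.scheme == "euler_maruyama":
        _run_emfm(model, C, state, dt, n_steps, rec_every, rng, noisy, scales, out)
    elif isinstance(model, EpileptorModel) and spec.scheme == "heun_stochastic":
        _run_epileptor(model, C, state, dt, n_steps, rec_every, rng, noisy, scales, out)
    else:
        _run_generic(model, C, state, dt, n_steps, rec_every, rng, spec, amps, out)

    if not np.all(np.isfinite(out[: n_steps // rec_every + 1])):
        t_bad, _, r_bad = np.argwhere(~np.isfinite(out))[0]
        raise IntegrationError(
            f"simulation diverged (non-finite state) near step "
            f"{int(t_bad) * rec_every}, region {int(r_bad)}"
        )
    times = np.arange(n_rec) * dt * rec_every
    return SimulationResult(
        times=times,
        data=out,
        state_variables=svars,
        dt_effective=dt * rec_every,
        seed=spec.seed,
        region_labels=labels,
        metadata={
            "model": model.name,
            "scheme": spec.scheme,
            "noise_convention": spec.noise_convention,
            "monitor": "raw",
        },
    )


def _chunks(n_steps):
    start = 0
    while start < n_steps:
        yield start, min(start + _CHUNK_STEPS, n_steps)
        start = start + _CHUNK_STEPS


def _run_emfm(model, C, state, dt, n_steps, rec_every, rng, noisy, scales, out):
    p = model.params
    S = state[0].copy()
    scale = float(scales[0]) if len(scales) else 0.0
    for lo, hi in _chunks(n_steps):
        noise = (
            scale * rng.standard_normal((hi - lo, S.shape[0]))
            if scale > 0
            else np.zeros((hi - lo, S.shape[0]))
        )
        _kernels.emfm_euler_chunk(
            S,
            C,
            p.w * p.J_N,
            p.G * p.J_N,
            p.I_0,
            p.a,
            p.b,
            p.d,
            p.gamma / 1000.0,
            p.tau_s,
            dt,
            noise,
            out,
            lo,
            rec_every,
        )
    state[0] = S


def _run_epileptor(model, C, state, dt, n_steps, rec_every, rng, noisy, scales, out):
    p = model.params
    x0 = model.x0_vector(C.shape[0])
    st = np.ascontiguousarray(state)
    n = C.shape[0]
    scale_map = dict(zip(noisy, scales))
    sx2 = float(scale_map.get("x2", 0.0))
    sy2 = float(scale_map.get("y2", 0.0))
    for lo, hi in _chunks(n_steps):
        if sx2 > 0 or sy2 > 0:
            noise = rng.standard_normal((hi - lo, 2, n))
            noise[:, 0, :] *= sx2
            noise[:, 1, :] *= sy2
        else:
            noise = np.zeros((hi - lo, 2, n))
        _kernels.epileptor_heun_chunk(
            st, C, x0, p.I1, p.I2, p.tau, p.gamma_g, p.r, p.Ks, dt, noise, out, lo, rec_every
        )
    state[:] = st


def _run_generic(model, C, state, dt, n_steps, rec_every, rng, spec, amps, out):
    svars = tuple(model.state_variables)
    amp_vec = np.array([amps.get(v, 0.0) for v in svars])[:, None]
    step = euler_maruyama_step if spec.scheme == "euler_maruyama" else heun_stochastic_step
    x = state
    for i in range(n_steps):
        x = step(
            x,
            lambda s: model.drift(s, C),
            dt,
            noise_amp=amp_vec,
            rng=rng,
            convention=spec.noise_convention,
        )
        if hasattr(model, "clamp"):
            x = model.clamp(x)
        if (i + 1) % rec_every == 0:
            out[(i + 1) // rec_every] = x
    state[:] = x


def epileptor_relaxed_state(
    params: EpileptorParams,
    x0: np.ndarray,
    relax_ms: float = 5000.0,
    dt_ms: float = 0.04,
) -> np.ndarray:
    """Deterministic per-node relaxation from the generic pre-ictal point.

    Coupling and noise are off; each distinct x0 value is relaxed once and
    the result broadcast to all nodes sharing it.  For sub-critical x0 this
    converges to the node's equilibrium; for epileptogenic x0 it lands on the
    node's autonomous seizure cycle.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.shape[0]
    state = np.empty((6, n))
    n_steps = int(round(relax_ms / dt_ms))
    for value in np.unique(x0):
        st = np.ascontiguousarray(EPILEPTOR_START[:, None].copy())
        out = np.empty((1, 6, 1))
        _kernels.epileptor_heun_chunk(
            st,
            np.zeros((1, 1)),
            np.array([value]),
            params.I1,
            params.I2,
            params.tau,
            params.gamma_g,
            params.r,
            params.Ks,
            dt_ms,
            np.zeros((n_steps, 2, 1)),
            out,
            0,
            n_steps + 1,
        )
        state[:, x0 == value] = st
    return state


def monitor_subsample(
    result: SimulationResult, period_ms: float, projection: str = "identity"
) -> SimulationResult:
    """Temporal subsampling plus an optional state projection.

    ``projection="identity"`` keeps all state variables; ``"lfp"`` emits the
    Epileptor's local field potential proxy ``-x1 + x2`` together with the
    slow permittivity ``z``.
    """
    if period_ms < result.dt_effective:
        raise IntegrationError(
            f"subsample period {period_ms} ms below series step {result.dt_effective} ms"
        )
    k = int(round(period_ms / result.dt_effective))
    data = result.data[::k]
    times = result.times[::k]
    svars = result.state_variables
    if projection == "identity":
        pass
    elif projection == "lfp":
        for needed in ("x1", "x2", "z"):
            if needed not in svars:
                raise IntegrationError(
                    f"lfp projection needs state variable {needed!r}"
                )
        ix1 = svars.index("x1")
        ix2 = svars.index("x2")
        iz = svars.index("z")
        data = np.stack([-data[:, ix1, :] + data[:, ix2, :], data[:, iz, :]], axis=1)
        svars = ("lfp", "z")
    else:
        raise IntegrationError(f"unknown projection {projection!r}")
    meta = dict(result.metadata)
    meta["monitor"] = projection
    meta["sampling_period_ms"] = period_ms
    return SimulationResult(
        times=times,
        data=data,
        state_variables=svars,
        dt_effective=result.dt_effective * k,
        seed=result.seed,
        region_labels=result.region_labels,
        metadata=meta,
    )
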
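"""Balloon-Windkessel hemodynamic forward model and BOLD resampling.

Neural activity (for the mean-field model, the synaptic gating S itself)
drives a vasodilatory signal s, which drives blood inflow f; the venous
balloon volume v and deoxyhemoglobin content q respond through the
Windkessel, and the BOLD signal is read out as a weighted sum of their
deviations from rest:

    ds/dt = u - kappa s - gamma_f (f - 1)
    df/dt = s
    tau_h dv/dt = f - v^(1/alpha)
    tau_h dq/dt = f (1 - (1-rho)^(1/f)) / rho - v^(1/alpha) q / v
    y = V0 (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v))

Rest (s=0, f=v=q=1, u=0) is an exact fixed point with y = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from . import _kernels
from .integrate import SimulationResult


class HemodynamicsError(ValueError):
    pass


@dataclass(frozen=True)
class BalloonParams:
    """Standard parameter set of the hemodynamic model (all configurable).

    Units: kappa, gamma_f in 1/s; tau_h in s; alpha, rho, V0 dimensionless.
    The BOLD weights are tied to rho: k1 = 7 rho, k2 = 2, k3 = 2 rho - 0.2.
    """

    kappa: float = 0.65
    gamma_f: float = 0.41
    tau_h: float = 0.98
    alpha: float = 0.32
    rho: float = 0.34
    V0: float = 0.02

    def __post_init__(self):
        if min(self.kappa, self.gamma_f, self.tau_h, self.rho, self.V0) <= 0:
            raise HemodynamicsError("hemodynamic parameters must be positive")
        if not 0 < self.alpha < 1:
            raise HemodynamicsError("alpha must lie in (0, 1)")

    @property
    def k1(self) -> float:
        return 7.0 * self.rho

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.rho - 0.2


@dataclass
class BoldSeries:
    """BOLD signal, shape (region, time), sampled every ``dt_s`` seconds."""

    values: np.ndarray
    dt_s: float
    region_labels: Optional[Sequence[str]] = None

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.values.shape[1] * self.dt_s


def balloon_windkessel(
    activity: Union[SimulationResult, np.ndarray],
    dt_ms: Optional[float] = None,
    params: Optional[BalloonParams] = None,
    target_dt_ms: float = 1.0,
    state_variable: Optional[str] = None,
) -> BoldSeries:
    """Convert a per-region activity series to BOLD.

    ``activity`` is either a :class:`SimulationResult` (the driving variable
    is ``state_variable``, defaulting to the only/first one) or a plain
    (region, time) array with ``dt_ms`` given.  The neural series is first
    decimated to ``target_dt_ms`` to bound cost, then integrated with
    explicit Euler at that step.
    """
    p = params or BalloonParams()
    labels = None
    if isinstance(activity, SimulationResult):
        svar = state_variable or activity.state_variables[0]
        u = activity.get(svar).T  # (region, time)
        dt_ms = activity.dt_effective
        labels = activity.region_labels
    else:
        u = np.asarray(activity, dtype=float)
        if dt_ms is None:
            raise HemodynamicsError("dt_ms required for plain-array input")
    if not np.all(np.isfinite(u)):
        raise HemodynamicsError("activity contains non-finite values")
    if dt_ms > 50.0:
        raise HemodynamicsError(
            f"input step {dt_ms} ms too coarse for stable explicit integration "
            "(must be <= 50 ms)"
        )
    k = max(1, int(round(target_dt_ms / dt_ms)))
    u = np.ascontiguousarray(u[:, ::k])
    dt_s = dt_ms * k / 1000.0
    out = np.empty_like(u)
    bad_region, bad_t = _kernels.balloon_chunk(
        u, dt_s, p.kappa, p.gamma_f, p.tau_h, p.alpha, p.rho, p.V0, p.k1, p.k2, p.k3, out
    )
    if bad_region >= 0:
        raise HemodynamicsError(
            f"blood flow/volume became nonpositive at region {bad_region}, "
            f"t = {bad_t * dt_s:.3f} s"
        )
    return BoldSeries(values=out, dt_s=dt_s, region_labels=labels)


def downsample_bold(
    bold: BoldSeries, tr_s: float = 2.0, total_min: float = 20.0
) -> BoldSeries:
    """Resample to one sample per repetition time over ``total_min`` minutes.

    With the defaults (TR 2 s, 20 min) the output has exactly 600 samples
    per region.  A shorter input is an error stating the required length.
    """
    if tr_s <= 0 or total_min <= 0:
        raise HemodynamicsError("tr_s and total_min must be positive")
    n_out = int(round(total_min * 60.0 / tr_s))
    idx = np.round(np.arange(n_out) * tr_s / bold.dt_s).astype(int)
    if idx[-1] >= bold.values.shape[1]:
        raise HemodynamicsError(
            f"BOLD series of {bold.duration_s:.1f} s too short: "
            f"{total_min} min requested ({total_min * 60.0:.0f} s required)"
        )
    return BoldSeries(
        values=bold.values[:, idx], dt_s=tr_s, region_labels=bold.region_labels
    )
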
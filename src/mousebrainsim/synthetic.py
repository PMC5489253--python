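"""Seeded generators for every input the tests and examples need.

All generators are pure functions of their arguments and a seed: the same
call yields a bit-identical object.  They emulate the *schemas* of the real
inputs (tracer-experiment records, connectome archives, scanner BOLD) — not
their detailed signal statistics — so analysis correctness can be tested
independently of simulation correctness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .analysis import Epoch, EpochSet
from .connectome import Connectome, euclidean_tract_lengths, mirror_hemisphere
from .hemodynamics import BoldSeries
from .integrate import SimulationResult
from .tracer import TracerExperiment, TracerExperimentSet


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------

def make_connectome(
    n_regions: int,
    seed: int = 0,
    n_modules: int = 2,
    density: float = 0.6,
    weight_scale: float = 1.0,
    with_volume: bool = False,
) -> Connectome:
    """Random modular connectome with exact hemispheric block symmetry.

    ``n_regions`` must be even (half right, half left).  Within-module
    connections are denser and stronger than between-module ones; the left
    hemisphere mirrors the right (R-R = L-L, R-L = L-R), and centres mirror
    across the x = 0 midplane.
    """
    if n_regions % 2:
        raise FixtureError(f"n_regions must be even, got {n_regions}")
    if n_regions < 2:
        raise FixtureError("need at least 2 regions")
    h = n_regions // 2
    rng = np.random.default_rng(seed)
    module = np.arange(h) % max(1, n_modules)
    same = module[:, None] == module[None, :]
    prob = np.where(same, density, density / 3.0)
    rr = (rng.random((h, h)) < prob) * rng.uniform(0.5, 1.5, (h, h))
    rr *= np.where(same, 1.0, 0.3) * weight_scale
    np.fill_diagonal(rr, 0.0)
    rl = (rng.random((h, h)) < prob / 2.0) * rng.uniform(0.2, 0.6, (h, h)) * weight_scale
    weights = mirror_hemisphere(rr, rl)

    right = np.column_stack(
        [
            2.0 + 1.5 * np.arange(h),
            3.0 * (np.arange(h) % 3),
            2.0 * (np.arange(h) // 3),
        ]
    )
    left = right.copy()
    left[:, 0] *= -1.0
    centres = np.vstack([right, left])

    labels = [f"R{i:02d}" for i in range(h)] + [f"L{i:02d}" for i in range(h)]
    volume = None
    if with_volume:
        volume = np.full((2 * n_regions, 2, 2), -1, dtype=int)
        for i in range(n_regions):
            volume[2 * i, :, :] = i
    return Connectome(
        weights=weights,
        region_labels=np.array(labels),
        centres=centres,
        tract_lengths=euclidean_tract_lengths(centres),
        hemispheres=np.array(["R"] * h + ["L"] * h),
        volume=volume,
    )


# ---------------------------------------------------------------------------
# tracer-experiment sets
# ---------------------------------------------------------------------------

@dataclass
class TracerGroundTruth:
    """The weight blocks the builder must recover from the fixture records."""

    region_ids: List[int]
    rr: np.ndarray
    rl: np.ndarray


def make_tracer_set(
    n_regions: int = 3,
    seed: int = 0,
    experiments_per_source: int = 2,
    n_low_volume: int = 0,
    n_low_voxel: int = 0,
    resolution_um: int = 100,
) -> Tuple[TracerExperimentSet, np.ndarray, TracerGroundTruth]:
    """Tracer records whose builder output equals a known weight matrix.

    ``n_regions`` structures pass the default volume/voxel-count filters;
    ``n_low_volume`` and ``n_low_voxel`` extra distractor structures fail
    them.  Per source, ``experiments_per_source`` experiments report every
    target with strengths ``truth * (1 + eps_k)`` where the ``eps_k`` sum to
    zero, so the cross-experiment mean reproduces the ground truth exactly
    (under the density-over-injection weight definition).  Also returns a
    two-hemisphere annotation volume assigning each structure a voxel block,
    mirrored across the first-axis midplane.
    """
    if n_regions < 2:
        raise FixtureError("need at least 2 retained regions")
    rng = np.random.default_rng(seed)
    kept_ids = [10 * (i + 1) for i in range(n_regions)]
    extra_ids = [
        10 * (n_regions + i + 1) for i in range(n_low_volume + n_low_voxel)
    ]
    all_ids = kept_ids + extra_ids

    h = n_regions
    rr = rng.uniform(0.1, 1.0, (h, h)) * (rng.random((h, h)) > 0.2)
    np.fill_diagonal(rr, 0.0)
    rl = rng.uniform(0.05, 0.6, (h, h)) * (rng.random((h, h)) > 0.3)

    volumes = {sid: float(rng.uniform(3.0, 6.0)) for sid in all_ids}
    names = {sid: f"Structure {sid}" for sid in all_ids}
    for sid in extra_ids[:n_low_volume]:
        volumes[sid] = float(rng.uniform(0.5, 1.9))

    m = experiments_per_source
    eps = 0.2 * (np.arange(m) - (m - 1) / 2.0)

    experiments = []
    truth_by_id = {
        sid: (rr[i], rl[i]) for i, sid in enumerate(kept_ids)
    }
    for sid in all_ids:
        low_voxel = sid in extra_ids[n_low_volume:]
        for k in range(m):
            q = float(rng.uniform(0.3, 0.9))
            projections = {}
            for j, tid in enumerate(all_ids):
                if sid in truth_by_id and tid in truth_by_id:
                    w_rr, w_rl = truth_by_id[sid][0][j], truth_by_id[sid][1][j]
                else:
                    # projections involving distractor structures: arbitrary,
                    # removed by the volume/voxel filters before averaging
                    w_rr, w_rl = rng.uniform(0.1, 0.5), rng.uniform(0.1, 0.5)
                for lat, w in (("ipsi", w_rr), ("contra", w_rl)):
                    if w > 0:
                        strength = w * (1.0 + eps[k])
                        projections[(tid, lat)] = (strength * q, strength * q * 2.0)
            experiments.append(
                TracerExperiment(
                    experiment_id=f"exp-{sid}-{k}",
                    source=sid,
                    injection_density=q,
                    infected_voxel_count=int(rng.integers(30, 46))
                    if low_voxel
                    else int(rng.integers(60, 200)),
                    projections=projections,
                )
            )

    tset = TracerExperimentSet(
        experiments=experiments, structure_volumes=volumes, structure_names=names
    )

    # annotation: each structure gets a 1 x 2 x 2 block in the right half,
    # mirrored into the left half
    n_all = len(all_ids)
    half = n_all + 1
    annotation = np.zeros((2 * half, 4, 4), dtype=int)
    for i, sid in enumerate(all_ids):
        annotation[i, 0:2, 0:2] = sid
        annotation[2 * half - 1 - i, 0:2, 0:2] = sid
    truth = TracerGroundTruth(region_ids=sorted(kept_ids), rr=rr, rl=rl)
    order = np.argsort(kept_ids)
    truth.rr = rr[np.ix_(order, order)]
    truth.rl = rl[np.ix_(order, order)]
    return tset, annotation, truth


# ---------------------------------------------------------------------------
# switching BOLD
# ---------------------------------------------------------------------------

def _state_pattern(state: int, n_regions: int) -> np.ndarray:
    """Deterministic ±1 loading pattern for a correlation state.

    Patterns for different states flip the sign of half the regions relative
    to one another (for n_regions a multiple of 8), giving strongly distinct
    FC matrices.
    """
    i = np.arange(n_regions)
    return np.where((i >> state) & 1 == 0, 1.0, -1.0)


def make_switching_bold(
    n_regions: int = 16,
    tr_s: float = 2.0,
    schedule: Sequence[Tuple[int, float]] = ((0, 600.0), (1, 600.0)),
    loading: float = 0.9,
    seed: int = 0,
) -> Tuple[BoldSeries, EpochSet]:
    """Piecewise-stationary Gaussian BOLD with scheduled correlation states.

    Within each scheduled epoch, region i is ``loading * pattern(i) * f(t)``
    plus idiosyncratic noise, with ``f`` a shared factor — a one-factor
    model whose correlation matrix has entries ±loading².  The returned
    :class:`EpochSet` is the ground-truth schedule.
    """
    if not 0 < loading < 1:
        raise FixtureError("loading must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    blocks = []
    epochs = []
    t = 0.0
    for state, duration_s in schedule:
        m = int(round(duration_s / tr_s))
        if m < 2:
            raise FixtureError(f"epoch of {duration_s} s too short for TR {tr_s} s")
        pat = _state_pattern(int(state), n_regions)
        f = rng.standard_normal(m)
        eps = rng.standard_normal((n_regions, m))
        blocks.append(loading * pat[:, None] * f[None, :] + np.sqrt(1 - loading**2) * eps)
        epochs.append(Epoch(start_s=t, end_s=t + duration_s, label=int(state)))
        t += duration_s
    values = np.concatenate(blocks, axis=1)
    labels = [f"R{i:02d}" for i in range(n_regions)]
    return (
        BoldSeries(values=values, dt_s=tr_s, region_labels=labels),
        EpochSet(epochs=epochs),
    )


# ---------------------------------------------------------------------------
# step-onset seizure-like series
# ---------------------------------------------------------------------------

def make_onset_series(
    onsets_ms: Sequence[Optional[float]],
    duration_ms: float = 10_000.0,
    dt_ms: float = 1.0,
    seed: int = 0,
    baseline: float = -1.6,
    active_mean: float = 0.8,
    active_swing: float = 0.5,
    noise: float = 0.02,
) -> SimulationResult:
    """Fast-variable-like series with known onset times.

    Each node sits at a subthreshold baseline and, from its scheduled onset,
    oscillates with mean ``active_mean`` and amplitude ``active_swing`` —
    staying above zero so a sustained-crossing detector recovers the onset
    to within one sample.  ``None`` entries never seize.
    """
    rng = np.random.default_rng(seed)
    n = len(onsets_ms)
    t = np.arange(0.0, duration_ms, dt_ms)
    x = np.empty((len(t), n))
    for j, onset in enumerate(onsets_ms):
        x[:, j] = baseline + noise * rng.standard_normal(len(t))
        if onset is not None:
            active = t >= onset
            x[active, j] = (
                active_mean
                + active_swing * np.sin(2 * np.pi * (t[active] - onset) / 50.0)
                + noise * rng.standard_normal(int(active.sum()))
            )
    return SimulationResult(
        times=t,
        data=x[:, None, :],
        state_variables=("x1",),
        dt_effective=dt_ms,
        seed=seed,
        region_labels=[f"N{j:02d}" for j in range(n)],
        metadata={"generator": "make_onset_series"},
    )
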
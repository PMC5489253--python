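"""End-to-end workflows: resting state, seizure propagation, and the
epileptogenicity boundary.

These functions wire the modules together the way the worked examples use
them; the command-line interface is a thin wrapper around them.  Every
tunable lives in :class:`RunConfig`, whose defaults are the reference
parameterization (global coupling G = 0.096, gating noise 5.1e-3, Euler step
0.1 ms; TR 2 s over 20 min; FCD windows of 180 s overlapping by 176 s;
Heun step 0.04 ms with variance-0.0025 noise on the Epileptor's fast
ensemble; epileptogenic x0 = -1.9 against a propagation zone at -2.1 with
permittivity coupling Ks = -60).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .analysis import (
    EpochSet,
    FCMatrix,
    FCDMatrix,
    HubReport,
    OnsetLatencyReport,
    count_seizure_cycles,
    fcd_matrix,
    functional_connectivity,
    functional_hubs,
    segment_epochs,
    seizure_onset_latency,
    spectral_embedding,
)
from .connectome import Connectome, LesionSpec, lesion_connectome
from .hemodynamics import BalloonParams, BoldSeries, balloon_windkessel, downsample_bold
from .integrate import (
    IntegratorSpec,
    SimulationResult,
    epileptor_relaxed_state,
    monitor_subsample,
    simulate,
)
from .models import EmfmModel, EmfmParams, EpileptorModel, EpileptorParams


class ConfigError(ValueError):
    pass


#: electrode-proximity grouping of connectome regions used to report seizure
#: recruitment order (hippocampal formation outward to neocortex/striatum)
SEIZURE_REGION_GROUPS: Dict[str, Tuple[str, ...]] = {
    "Hippocampus": ("Field CA1", "Field CA3", "Dentate gyrus"),
    "Subiculum": ("Subiculum",),
    "Entorhinal cortex": (
        "Entorhinal area, lateral part",
        "Entorhinal area, medial part, dorsal zone",
    ),
    "Olfactory cortex": (
        "Main olfactory bulb",
        "Anterior olfactory nucleus",
        "Piriform area",
    ),
    "Neocortex": (
        "Primary motor area",
        "Secondary motor area",
        "Primary somatosensory area, nose",
        "Primary somatosensory area, barrel field",
        "Primary somatosensory area, mouth",
        "Primary somatosensory area, upper limb",
        "Supplemental somatosensory area",
        "Gustatory areas",
        "Dorsal auditory area",
        "Primary auditory area",
        "Ventral auditory area",
        "Primary visual area",
        "Anterior cingulate area, dorsal part",
        "Anterior cingulate area, ventral part",
        "Agranular insular area, dorsal part",
        "Retrosplenial area, dorsal part",
        "Retrosplenial area, ventral part",
        "Temporal association areas",
        "Right perirhinal area",
        "Ectorhinal area",
    ),
    "Striatum": ("Caudoputamen", "Nucleus accumbens"),
}

#: hippocampal regions seeded as the epileptogenic zone (left hemisphere)
EZ_REGION_NAMES: Tuple[str, ...] = ("Field CA1", "Field CA3", "Dentate gyrus")


def _strict(cls, data: Mapping, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class RestConfig:
    duration_min: float = 20.0
    dt_ms: float = 0.1
    record_period_ms: float = 1.0
    noise_convention: str = "wiener_sigma"


@dataclass(frozen=True)
class BoldConfig:
    tr_s: float = 2.0
    total_min: float = 20.0


@dataclass(frozen=True)
class FcdConfig:
    window_s: float = 180.0
    overlap_s: float = 176.0


@dataclass(frozen=True)
class SegmentationConfig:
    max_clusters: int = 6
    n_restarts: int = 50
    min_run: int = 3


@dataclass(frozen=True)
class SeizureConfig:
    duration_s: float = 30.0
    dt_ms: float = 0.04
    record_period_ms: float = 1.0
    noise_convention: str = "wiener_sigma"
    x0_ez: float = -1.9
    x0_propagation: float = -2.1
    relax_ms: float = 5000.0


@dataclass(frozen=True)
class OnsetConfig:
    # threshold sits between the interictal level (about -1.4) and the ictal
    # oscillation range; at 0 the noisy fast discharges dip below threshold
    # often enough to defeat the 100-ms dwell requirement
    threshold: float = -0.5
    dwell_ms: float = 100.0


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of every pipeline stage, JSON-round-trippable.

    Unknown keys in a JSON document are rejected so a typo cannot silently
    fall back to a default.
    """

    emfm: EmfmParams = field(default_factory=EmfmParams)
    epileptor: EpileptorParams = field(default_factory=EpileptorParams)
    rest: RestConfig = field(default_factory=RestConfig)
    bold: BoldConfig = field(default_factory=BoldConfig)
    balloon: BalloonParams = field(default_factory=BalloonParams)
    fcd: FcdConfig = field(default_factory=FcdConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    seizure: SeizureConfig = field(default_factory=SeizureConfig)
    onset: OnsetConfig = field(default_factory=OnsetConfig)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(sections)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, f in sections.items():
            if name in data:
                section_cls = f.default_factory  # all sections are dataclasses
                payload = dict(data[name])
                if name == "epileptor" and payload.get("x0_overrides"):
                    payload["x0_overrides"] = tuple(payload["x0_overrides"].items())
                kwargs[name] = _strict(section_cls, payload, name)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["epileptor"]["x0_overrides"] is not None:
            d["epileptor"]["x0_overrides"] = dict(d["epileptor"]["x0_overrides"])
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# resting state
# ---------------------------------------------------------------------------

@dataclass
class RestResult:
    """Everything the resting-state pipeline produces."""

    gating: SimulationResult
    bold: BoldSeries
    fc_global: FCMatrix
    fcd: Optional[FCDMatrix]
    epochs: Optional[EpochSet]
    hubs_global: HubReport
    hubs_per_epoch: List[HubReport]
    connectome: Connectome


def simulate_rest(
    connectome: Connectome,
    config: Optional[RunConfig] = None,
    seed: int = 0,
    lesion: Optional[LesionSpec] = None,
) -> RestResult:
    """Full resting-state pipeline: mean-field network -> BOLD -> FCD ->
    epochs -> functional hubs.

    With ``lesion`` the named regions' connections are removed (total weight
    conserved) before simulating, mimicking the anatomic reorganization of
    temporal-lobe epilepsy.  If the series is shorter than one FCD window,
    FCD and epochs are ``None`` and only global hubs are reported.
    """
    cfg = config or RunConfig()
    if lesion is not None:
        connectome = lesion_connectome(connectome, lesion)
    model = EmfmModel(cfg.emfm)
    spec = IntegratorSpec(
        scheme="euler_maruyama",
        dt_ms=cfg.rest.dt_ms,
        noise_amplitudes={"S": cfg.emfm.sigma},
        noise_convention=cfg.rest.noise_convention,
        seed=seed,
    )
    sim = simulate(
        model,
        connectome,
        duration_ms=cfg.rest.duration_min * 60_000.0,
        spec=spec,
        record_period_ms=cfg.rest.record_period_ms,
    )
    bold_full = balloon_windkessel(sim, params=cfg.balloon)
    total_min = min(cfg.bold.total_min, cfg.rest.duration_min)
    bold = downsample_bold(bold_full, tr_s=cfg.bold.tr_s, total_min=total_min)
    fc_global = functional_connectivity(bold)
    hubs_global = functional_hubs(fc_global)

    fcd = epochs = None
    hubs_per_epoch: List[HubReport] = []
    if bold.duration_s > cfg.fcd.window_s:
        fcd = fcd_matrix(bold, window_s=cfg.fcd.window_s, overlap_s=cfg.fcd.overlap_s)
        emb = spectral_embedding(fcd)
        epochs = segment_epochs(
            emb,
            fcd.window_centers_s,
            max_clusters=cfg.segmentation.max_clusters,
            n_restarts=cfg.segmentation.n_restarts,
            min_run=cfg.segmentation.min_run,
            seed=seed,
        )
        for ep in epochs.epochs:
            lo = int(ep.start_s / bold.dt_s)
            hi = int(ep.end_s / bold.dt_s) + 1
            seg = BoldSeries(
                values=bold.values[:, lo:hi],
                dt_s=bold.dt_s,
                region_labels=bold.region_labels,
            )
            hubs_per_epoch.append(functional_hubs(functional_connectivity(seg)))
    return RestResult(
        gating=sim,
        bold=bold,
        fc_global=fc_global,
        fcd=fcd,
        epochs=epochs,
        hubs_global=hubs_global,
        hubs_per_epoch=hubs_per_epoch,
        connectome=connectome,
    )


# ---------------------------------------------------------------------------
# seizure propagation
# ---------------------------------------------------------------------------

@dataclass
class SeizureResult:
    raw: SimulationResult
    lfp: SimulationResult
    latency: OnsetLatencyReport
    ez_labels: List[str]


def _resolve_names(labels: Sequence[str], names: Sequence[str]) -> List[str]:
    """Map prose region names onto connectome labels.

    Exact (case-insensitive) match first, then unique-substring match; an
    ambiguous or missing name raises listing the candidates.
    """
    out = []
    lowered = {l.lower(): l for l in labels}
    for name in names:
        key = name.lower()
        if key in lowered:
            out.append(lowered[key])
            continue
        matches = [l for l in labels if key in l.lower()]
        if len(matches) == 1:
            out.append(matches[0])
        elif not matches:
            raise ConfigError(
                f"region {name!r} not found; candidates: {sorted(labels)[:10]}"
            )
        else:
            raise ConfigError(f"region {name!r} ambiguous: matches {matches}")
    return out


def simulate_seizure(
    connectome: Connectome,
    config: Optional[RunConfig] = None,
    seed: int = 0,
    ez_names: Optional[Sequence[str]] = None,
    region_groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> SeizureResult:
    """Networked-Epileptor run with an epileptogenic zone, plus latencies.

    ``ez_names`` (default: the left hippocampal regions) get
    ``x0 = x0_ez``; every other region is a propagation zone at
    ``x0_propagation``.  Nodes start from their per-node deterministic
    equilibria; the monitored local field potential is -x1 + x2 alongside
    the slow permittivity z, down-sampled to 1 ms.
    """
    cfg = config or RunConfig()
    labels = list(connectome.region_labels)
    if ez_names is None:
        ez_names = [f"Left {n}" for n in EZ_REGION_NAMES]
    ez_labels = _resolve_names(labels, ez_names)
    params = dataclasses.replace(
        cfg.epileptor,
        x0=cfg.seizure.x0_propagation,
        x0_overrides=tuple((l, cfg.seizure.x0_ez) for l in ez_labels),
    )
    model = EpileptorModel(params, region_labels=labels)
    spec = IntegratorSpec(
        scheme="heun_stochastic",
        dt_ms=cfg.seizure.dt_ms,
        noise_amplitudes=EpileptorModel(params).default_noise_amplitudes(),
        noise_convention=cfg.seizure.noise_convention,
        seed=seed,
    )
    x0_vec = params.x0_vector(labels)
    init = epileptor_relaxed_state(
        params, x0_vec, relax_ms=cfg.seizure.relax_ms, dt_ms=cfg.seizure.dt_ms
    )
    raw = simulate(
        model,
        connectome,
        duration_ms=cfg.seizure.duration_s * 1000.0,
        spec=spec,
        record_period_ms=cfg.seizure.record_period_ms,
        initial_state=init,
    )
    lfp = monitor_subsample(raw, period_ms=raw.dt_effective, projection="lfp")
    if region_groups is None:
        groups: Dict[str, Sequence[str]] = {}
        for gname, members in SEIZURE_REGION_GROUPS.items():
            resolved = []
            for m in members:
                try:
                    resolved.extend(_resolve_names(labels, [f"Left {m}"]))
                except ConfigError:
                    continue
            if resolved:
                groups[gname] = resolved
        if not groups:
            groups = {"all regions": labels}
    else:
        groups = {g: _resolve_names(labels, ms) for g, ms in region_groups.items()}
    latency = seizure_onset_latency(
        raw,
        groups,
        ez_labels,
        threshold=cfg.onset.threshold,
        dwell_ms=cfg.onset.dwell_ms,
    )
    return SeizureResult(raw=raw, lfp=lfp, latency=latency, ez_labels=ez_labels)


# ---------------------------------------------------------------------------
# epileptogenicity boundary
# ---------------------------------------------------------------------------

def node_seizes(
    x0: float,
    params: Optional[EpileptorParams] = None,
    dt_ms: float = 0.04,
    probe_ms: float = 20_000.0,
    relax_ms: float = 5_000.0,
) -> bool:
    """Whether an isolated, noise-free Epileptor node seizes autonomously.

    The node is relaxed deterministically for ``relax_ms``, integrated for
    ``probe_ms``, and classified epileptogenic if the fast variable shows at
    least one complete, sustained onset-offset cycle.
    """
    p = params or EpileptorParams()
    p = dataclasses.replace(p, x0=float(x0), x0_overrides=None)
    model = EpileptorModel(p, region_labels=["node"])
    init = epileptor_relaxed_state(p, np.array([x0]), relax_ms=relax_ms, dt_ms=dt_ms)
    spec = IntegratorSpec(
        scheme="heun_stochastic", dt_ms=dt_ms, noise_amplitudes={}, seed=0
    )
    sim = simulate(
        model,
        np.zeros((1, 1)),
        duration_ms=probe_ms,
        spec=spec,
        record_period_ms=1.0,
        initial_state=init,
    )
    return count_seizure_cycles(sim.get("x1")[:, 0], sim.dt_effective) >= 1


def critical_epileptogenicity(
    params: Optional[EpileptorParams] = None,
    lo: float = -2.5,
    hi: float = -1.5,
    resolution: float = 0.01,
    dt_ms: float = 0.04,
    probe_ms: float = 20_000.0,
    relax_ms: float = 5_000.0,
) -> float:
    """|x0| at the equilibrium -> spontaneous-seizure transition, by bisection.

    ``lo`` must rest at equilibrium and ``hi`` must seize; the boundary is
    bracketed to ``resolution`` and returned as a magnitude (about 2.06 with
    canonical parameters).
    """
    if node_seizes(lo, params, dt_ms, probe_ms, relax_ms):
        raise ValueError(f"x0 = {lo} already seizes; widen the bracket")
    if not node_seizes(hi, params, dt_ms, probe_ms, relax_ms):
        raise ValueError(f"x0 = {hi} does not seize; widen the bracket")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if node_seizes(mid, params, dt_ms, probe_ms, relax_ms):
            hi = mid
        else:
            lo = mid
    return abs(0.5 * (lo + hi))
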
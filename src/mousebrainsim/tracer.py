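"""Connectome construction from anterograde tracer experiments.

Each experiment records a viral tracer injection into one source structure of
the right hemisphere and, per target structure, the detected projection
density (infected pixels in the target normalized by the target's pixel
count) and projection energy (detected intensity normalized the same way).
The builder pipeline:

1. *clean*: restrict to a structure universe in which the injection
   structures are exactly the target structures, so the connectome is square;
2. *filter*: drop structures below a volume threshold, or never infected
   above a voxel-count threshold in any injection;
3. *average*: convert each experiment's measurement to a connection strength
   (one of three definitions) and average across all experiments sharing the
   same source/target pair, separately for ipsilateral and contralateral
   targets;
4. *mirror*: build the left hemisphere as the mirror image of the right;
5. compute region centres (voxel centroids of the annotation volume),
   Euclidean tract lengths, and the region-volume mapping.

Fixture schema on disk: ``experiments.jsonl`` (one JSON record per
experiment), ``structures.json`` (id -> volume in mm^3 and name), and an
optional ``annotation.nii[.gz]`` volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import nibabel as nib
import numpy as np

from .connectome import (
    Connectome,
    build_region_volume_mapping,
    euclidean_tract_lengths,
    mirror_hemisphere,
)

WEIGHT_DEFINITIONS = ("projection_density", "projection_energy", "density_over_injection")
RESOLUTIONS_UM = (25, 50, 100)
LATERALITIES = ("ipsi", "contra")


class TracerBuildError(ValueError):
    """Raised by any stage of the tracer-builder pipeline."""


@dataclass(frozen=True)
class TracerExperiment:
    """One injection experiment.

    ``projections`` maps ``(target_structure_id, laterality)`` — laterality
    ``"ipsi"`` (right-hemisphere target) or ``"contra"`` (left) — to the pair
    ``(projection_density, projection_energy)``.
    """

    experiment_id: str
    source: int
    injection_density: float
    infected_voxel_count: int
    projections: Mapping[Tuple[int, str], Tuple[float, float]]

    def __post_init__(self):
        if not 0.0 <= self.injection_density <= 1.0:
            raise TracerBuildError(
                f"experiment {self.experiment_id}: injection_density "
                f"{self.injection_density} outside [0, 1]"
            )
        for (tgt, lat), (dens, energy) in self.projections.items():
            if lat not in LATERALITIES:
                raise TracerBuildError(
                    f"experiment {self.experiment_id}: unknown laterality {lat!r}"
                )
            if dens < 0 or energy < 0:
                raise TracerBuildError(
                    f"experiment {self.experiment_id}: negative projection "
                    f"measurement for target {tgt}"
                )

    def targets(self) -> set:
        return {tgt for tgt, _ in self.projections}


@dataclass
class TracerExperimentSet:
    """A collection of experiments plus per-structure metadata."""

    experiments: List[TracerExperiment]
    structure_volumes: Dict[int, float]
    structure_names: Dict[int, str] = field(default_factory=dict)

    def sources(self) -> set:
        return {e.source for e in self.experiments}

    def targets(self) -> set:
        out = set()
        for e in self.experiments:
            out |= e.targets()
        return out

    def name(self, sid: int) -> str:
        return self.structure_names.get(sid, str(sid))


@dataclass(frozen=True)
class BuilderConfig:
    """User-facing knobs of the builder.

    Defaults follow the reference configuration: 100 um grid, connection
    strength as projection density over injection density, regions kept only
    if their volume exceeds 2 mm^3 and some injection infected more than 50
    voxels (both strict inequalities).
    """

    resolution_um: int = 100
    weight_definition: str = "density_over_injection"
    min_region_volume_mm3: float = 2.0
    min_infected_voxels: int = 50

    def __post_init__(self):
        if self.resolution_um not in RESOLUTIONS_UM:
            raise TracerBuildError(
                f"resolution_um must be one of {RESOLUTIONS_UM}, got {self.resolution_um}"
            )
        if self.weight_definition not in WEIGHT_DEFINITIONS:
            raise TracerBuildError(
                f"weight_definition must be one of {WEIGHT_DEFINITIONS}, "
                f"got {self.weight_definition!r}"
            )
        if self.min_region_volume_mm3 < 0 or self.min_infected_voxels < 0:
            raise TracerBuildError("thresholds must be nonnegative")


def clean_to_square(experiments: TracerExperimentSet) -> TracerExperimentSet:
    """Restrict to the intersection of source and target structures.

    Guarantees that the final connectome is square: every region appears both
    as an injection structure and as a target structure.
    """
    if not experiments.experiments:
        raise TracerBuildError("experiment set is empty")
    universe = experiments.sources() & experiments.targets()
    if not universe:
        raise TracerBuildError("no structure appears as both source and target")
    kept = []
    for e in experiments.experiments:
        if e.source not in universe:
            continue
        projections = {
            key: val for key, val in e.projections.items() if key[0] in universe
        }
        kept.append(replace(e, projections=projections))
    return TracerExperimentSet(
        experiments=kept,
        structure_volumes={
            k: v for k, v in experiments.structure_volumes.items() if k in universe
        },
        structure_names={
            k: v for k, v in experiments.structure_names.items() if k in universe
        },
    )


def filter_regions(
    experiments: TracerExperimentSet, config: BuilderConfig
) -> TracerExperimentSet:
    """Keep regions exceeding both the volume and infected-voxel thresholds.

    A region survives if its volume is strictly greater than
    ``min_region_volume_mm3`` *and* at least one injection into it infected
    strictly more than ``min_infected_voxels`` voxels.  The set is re-cleaned
    to square afterwards.
    """
    max_infected: Dict[int, int] = {}
    for e in experiments.experiments:
        max_infected[e.source] = max(
            max_infected.get(e.source, 0), e.infected_voxel_count
        )
    kept = {
        sid
        for sid in experiments.sources()
        if experiments.structure_volumes.get(sid, 0.0) > config.min_region_volume_mm3
        and max_infected.get(sid, 0) > config.min_infected_voxels
    }
    if not kept:
        raise TracerBuildError("all regions removed by volume/voxel thresholds")
    trimmed = TracerExperimentSet(
        experiments=[
            replace(
                e,
                projections={k: v for k, v in e.projections.items() if k[0] in kept},
            )
            for e in experiments.experiments
            if e.source in kept
        ],
        structure_volumes={
            k: v for k, v in experiments.structure_volumes.items() if k in kept
        },
        structure_names={
            k: v for k, v in experiments.structure_names.items() if k in kept
        },
    )
    return clean_to_square(trimmed)


def connection_strength(
    exp: TracerExperiment,
    target: int,
    definition: str = "density_over_injection",
    laterality: str = "ipsi",
) -> float:
    """Connection strength of one experiment toward one target.

    ``projection_density`` and ``projection_energy`` are pass-throughs of the
    recorded measurements; ``density_over_injection`` is the projection
    density divided by the injection density of the source region.
    """
    if definition not in WEIGHT_DEFINITIONS:
        raise TracerBuildError(f"unknown weight definition {definition!r}")
    key = (target, laterality)
    if key not in exp.projections:
        raise TracerBuildError(
            f"experiment {exp.experiment_id} has no measurement for target "
            f"{target} ({laterality})"
        )
    density, energy = exp.projections[key]
    if definition == "projection_density":
        return density
    if definition == "projection_energy":
        return energy
    if exp.injection_density == 0:
        raise TracerBuildError(
            f"experiment {exp.experiment_id}: injection_density is zero, "
            "density_over_injection undefined"
        )
    return density / exp.injection_density


def average_weight_block(
    experiments: TracerExperimentSet, config: BuilderConfig
) -> Tuple[np.ndarray, np.ndarray, List[int]]:
    """Cross-experiment mean strengths as right-hemisphere blocks.

    Returns ``(RR, RL, region_ids)``: entry ``(i, j)`` is the arithmetic mean
    of the connection strength over all experiments injecting source
    ``region_ids[i]`` that report target ``region_ids[j]`` — ipsilateral
    targets fill RR, contralateral fill RL.  A pair with no measurement stays
    at 0: an unmeasured projection is treated as absent, not averaged in as
    zero.
    """
    region_ids = sorted(experiments.sources() | experiments.targets())
    pos = {sid: k for k, sid in enumerate(region_ids)}
    h = len(region_ids)
    sums = {lat: np.zeros((h, h)) for lat in LATERALITIES}
    counts = {lat: np.zeros((h, h)) for lat in LATERALITIES}
    for e in experiments.experiments:
        i = pos[e.source]
        for (tgt, lat) in sorted(e.projections):
            s = connection_strength(e, tgt, config.weight_definition, lat)
            sums[lat][i, pos[tgt]] += s
            counts[lat][i, pos[tgt]] += 1
    with np.errstate(invalid="ignore"):
        rr = np.where(counts["ipsi"] > 0, sums["ipsi"] / np.maximum(counts["ipsi"], 1), 0.0)
        rl = np.where(counts["contra"] > 0, sums["contra"] / np.maximum(counts["contra"], 1), 0.0)
    return rr, rl, region_ids


def _region_centres(
    annotation: np.ndarray,
    region_ids: List[int],
    resolution_um: float,
    names: Mapping[int, str],
    mirror_axis: int = 0,
) -> np.ndarray:
    """Right-hemisphere voxel centroids in mm, and their mirror images.

    The annotation volume holds both hemispheres with identical structure
    ids; the hemispheres are split at the midplane of ``mirror_axis`` with
    the right hemisphere on the low-index side.  Left centres are the mirror
    images of the right ones across that midplane.
    """
    size = annotation.shape[mirror_axis]
    mid = size / 2.0
    mm = resolution_um / 1000.0
    right = np.empty((len(region_ids), 3))
    for k, rid in enumerate(region_ids):
        coords = np.argwhere(annotation == rid)
        coords = coords[coords[:, mirror_axis] < mid]
        if coords.size == 0:
            raise TracerBuildError(
                f"structure {names.get(rid, rid)} has no voxels in the "
                "right-hemisphere half of the annotation volume"
            )
        right[k] = (coords.mean(axis=0) + 0.5) * mm
    left = right.copy()
    left[:, mirror_axis] = size * mm - right[:, mirror_axis]
    return np.vstack([right, left])


def _hemispheric_volume_mapping(
    annotation: np.ndarray, region_ids: List[int], mirror_axis: int = 0
) -> np.ndarray:
    """Region-volume mapping with right regions indexed 0..H-1, left H..2H-1."""
    h = len(region_ids)
    base = build_region_volume_mapping(annotation, region_ids)
    coords = np.arange(annotation.shape[mirror_axis])
    is_left = coords >= annotation.shape[mirror_axis] / 2.0
    shape = [1, 1, 1]
    shape[mirror_axis] = -1
    left_mask = is_left.reshape(shape)
    return np.where((base >= 0) & left_mask, base + h, base)


def build_tracer_connectome(
    experiments: TracerExperimentSet,
    annotation_volume: np.ndarray,
    config: Optional[BuilderConfig] = None,
    mirror_axis: int = 0,
) -> Connectome:
    """Run the full builder pipeline and return a validated connectome.

    Errors from individual stages are re-raised labelled with the stage name.
    """
    config = config or BuilderConfig()
    annotation = np.asarray(annotation_volume)

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except TracerBuildError as exc:
            raise TracerBuildError(f"stage {name}: {exc}") from exc

    cleaned = stage("clean_to_square", clean_to_square, experiments)
    filtered = stage("filter_regions", filter_regions, cleaned, config)
    rr, rl, region_ids = stage("average_weights", average_weight_block, filtered, config)
    if len(region_ids) < 2:
        raise TracerBuildError(
            "stage average_weights: a single region cannot form a network"
        )
    weights = stage("mirror", mirror_hemisphere, rr, rl)
    centres = stage(
        "centres",
        _region_centres,
        annotation,
        region_ids,
        config.resolution_um,
        filtered.structure_names,
        mirror_axis,
    )
    volume = _hemispheric_volume_mapping(annotation, region_ids, mirror_axis)
    labels = [f"Right {filtered.name(rid)}" for rid in region_ids] + [
        f"Left {filtered.name(rid)}" for rid in region_ids
    ]
    h = len(region_ids)
    return Connectome(
        weights=weights,
        region_labels=np.array(labels),
        centres=centres,
        tract_lengths=euclidean_tract_lengths(centres),
        hemispheres=np.array(["R"] * h + ["L"] * h),
        volume=volume,
        voxel_resolution_um=float(config.resolution_um),
    )


# -- fixture-schema persistence ---------------------------------------------

def save_tracer_set(
    experiments: TracerExperimentSet,
    path: str | Path,
    annotation: Optional[np.ndarray] = None,
) -> Path:
    """Write the JSON-lines fixture schema (plus optional NIfTI annotation)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "experiments.jsonl", "w") as fh:
        for e in experiments.experiments:
            rec = {
                "experiment_id": e.experiment_id,
                "source": e.source,
                "injection_density": e.injection_density,
                "infected_voxel_count": e.infected_voxel_count,
                "projections": [
                    {
                        "target": tgt,
                        "laterality": lat,
                        "density": dens,
                        "energy": energy,
                    }
                    for (tgt, lat), (dens, energy) in sorted(e.projections.items())
                ],
            }
            fh.write(json.dumps(rec) + "\n")
    (path / "structures.json").write_text(
        json.dumps(
            {
                "volumes_mm3": {str(k): v for k, v in experiments.structure_volumes.items()},
                "names": {str(k): v for k, v in experiments.structure_names.items()},
            },
            indent=2,
        )
    )
    if annotation is not None:
        nib.save(
            nib.Nifti1Image(np.asarray(annotation).astype(np.int32), np.eye(4)),
            path / "annotation.nii.gz",
        )
    return path


def load_tracer_set(path: str | Path) -> Tuple[TracerExperimentSet, Optional[np.ndarray]]:
    """Read a fixture directory written by :func:`save_tracer_set`."""
    path = Path(path)
    experiments = []
    with open(path / "experiments.jsonl") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            experiments.append(
                TracerExperiment(
                    experiment_id=rec["experiment_id"],
                    source=int(rec["source"]),
                    injection_density=float(rec["injection_density"]),
                    infected_voxel_count=int(rec["infected_voxel_count"]),
                    projections={
                        (int(p["target"]), p["laterality"]): (
                            float(p["density"]),
                            float(p["energy"]),
                        )
                        for p in rec["projections"]
                    },
                )
            )
    structures = json.loads((path / "structures.json").read_text())
    tset = TracerExperimentSet(
        experiments=experiments,
        structure_volumes={int(k): float(v) for k, v in structures["volumes_mm3"].items()},
        structure_names={int(k): v for k, v in structures.get("names", {}).items()},
    )
    annotation = None
    for name in ("annotation.nii.gz", "annotation.nii"):
        if (path / name).exists():
            annotation = np.asarray(nib.load(path / name).get_fdata()).astype(int)
            break
    return tset, annotation
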
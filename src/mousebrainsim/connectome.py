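"""Structural connectome container, on-disk archive format, and editing operations.

A connectome here is a square, nonnegative matrix of directed connection
strengths between parcellated brain regions, together with region labels,
3-D region centres (mm), tract lengths (mm), a hemisphere tag per region and,
optionally, a region-volume mapping: a 3-D voxel array whose entries label
each voxel with the connectome row index of the region it belongs to
(-1 = background / excluded structures).

The archive layout is a directory (or ``.zip``) of delimited text files::

    weights.txt        N x N matrix
    tract_lengths.txt  N x N matrix (optional; recomputed from centres if absent)
    centres.txt        one "label x y z" row per region (mm)
    hemispheres.txt    one R/L flag per region (optional; default all R)
    meta.json          voxel resolution and format metadata
    volume.nii.gz      region-volume mapping (optional, NIfTI-1)

Region ordering convention: all right-hemisphere regions first, then left,
each hemisphere in identical intra-hemisphere order.  That convention makes
the mirror symmetries R-R = L-L and R-L = L-R checkable as exact block
identities.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)

_FORMAT_VERSION = 1


class ConnectomeError(ValueError):
    """Raised when a connectome violates its structural invariants."""


@dataclass
class Connectome:
    """Whole-brain structural connectivity.

    Parameters
    ----------
    weights
        N x N nonnegative connection strengths (dimensionless).  The diagonal
        is forced to zero: self-projections are degenerate with the local
        recurrence term of the node models and are excluded from the network
        coupling sums.
    tract_lengths
        N x N symmetric tract lengths in mm, zero diagonal.  If ``None``,
        computed as Euclidean distances between region centres.
    region_labels
        N unique region names.
    centres
        N x 3 region centres in mm.
    hemispheres
        Per-region ``"R"``/``"L"`` flag.
    volume
        Optional 3-D integer region-volume mapping; entries in
        ``{-1, 0, ..., N-1}``.
    voxel_resolution_um
        Edge length of a voxel of ``volume`` in micrometres.
    """

    weights: np.ndarray
    region_labels: np.ndarray
    centres: np.ndarray
    tract_lengths: Optional[np.ndarray] = None
    hemispheres: Optional[np.ndarray] = None
    volume: Optional[np.ndarray] = None
    voxel_resolution_um: float = 100.0

    def __post_init__(self) -> None:
        self.weights = np.array(self.weights, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=str)
        self.centres = np.asarray(self.centres, dtype=float)
        np.fill_diagonal(self.weights, 0.0)
        if self.tract_lengths is None:
            self.tract_lengths = euclidean_tract_lengths(self.centres, self.region_labels)
        else:
            self.tract_lengths = np.asarray(self.tract_lengths, dtype=float)
        if self.hemispheres is None:
            self.hemispheres = np.array(["R"] * len(self.region_labels))
        else:
            self.hemispheres = np.asarray(self.hemispheres, dtype=str)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weights must be square, got shape {w.shape}")
        n = w.shape[0]
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise ConnectomeError(f"negative weight {w[i, j]} at entry ({i}, {j})")
        if not np.all(np.isfinite(w)):
            raise ConnectomeError("weights contain non-finite entries")
        tl = self.tract_lengths
        if tl.shape != (n, n):
            raise ConnectomeError(
                f"tract_lengths shape {tl.shape} does not match weights shape {w.shape}"
            )
        if np.any(tl < 0) or not np.allclose(tl, tl.T) or np.any(np.diag(tl) != 0):
            raise ConnectomeError("tract_lengths must be symmetric, nonnegative, zero diagonal")
        if len(self.region_labels) != n:
            raise ConnectomeError(
                f"{len(self.region_labels)} labels for {n} regions"
            )
        if len(set(self.region_labels)) != n:
            dup = [l for l in self.region_labels if list(self.region_labels).count(l) > 1]
            raise ConnectomeError(f"region labels not unique: {sorted(set(dup))}")
        if self.centres.shape != (n, 3):
            raise ConnectomeError(f"centres shape {self.centres.shape}, expected ({n}, 3)")
        if not np.all(np.isfinite(self.centres)):
            bad = int(np.argwhere(~np.isfinite(self.centres))[0][0])
            raise ConnectomeError(
                f"non-finite centre for region {self.region_labels[bad]!r}"
            )
        if len(self.hemispheres) != n or not set(self.hemispheres) <= {"R", "L"}:
            raise ConnectomeError("hemispheres must be one R/L flag per region")
        if self.volume is not None:
            v = np.asarray(self.volume)
            if v.ndim != 3:
                raise ConnectomeError("region volume mapping must be a 3-D array")
            if v.min() < -1 or v.max() > n - 1:
                raise ConnectomeError(
                    f"volume entries must lie in [-1, {n - 1}], got "
                    f"[{v.min()}, {v.max()}]"
                )

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def index(self, label: str) -> int:
        """Region index for ``label``; exact match first, then case-insensitive."""
        labels = list(self.region_labels)
        if label in labels:
            return labels.index(label)
        lowered = [l.lower() for l in labels]
        if label.lower() in lowered:
            return lowered.index(label.lower())
        raise KeyError(f"region {label!r} not found; labels include {labels[:6]}...")

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Write the connectome archive to a directory or ``.zip`` file."""
        path = Path(path)
        files = {
            "weights.txt": _matrix_text(self.weights),
            "tract_lengths.txt": _matrix_text(self.tract_lengths),
            "centres.txt": "".join(
                f"{lab} {x:.9g} {y:.9g} {z:.9g}\n"
                for lab, (x, y, z) in zip(self.region_labels, self.centres)
            ),
            "hemispheres.txt": "".join(h + "\n" for h in self.hemispheres),
            "meta.json": json.dumps(
                {
                    "format_version": _FORMAT_VERSION,
                    "voxel_resolution_um": self.voxel_resolution_um,
                    "n_regions": self.n_regions,
                },
                indent=2,
            ),
        }
        volume_bytes = None
        if self.volume is not None:
            img = nib.Nifti1Image(self.volume.astype(np.int32), affine=np.eye(4))
            volume_bytes = img.to_bytes()
        if str(path).endswith(".zip"):
            with zipfile.ZipFile(path, "w") as zf:
                for name, text in files.items():
                    zf.writestr(name, text)
                if volume_bytes is not None:
                    zf.writestr("volume.nii", volume_bytes)
        else:
            path.mkdir(parents=True, exist_ok=True)
            for name, text in files.items():
                (path / name).write_text(text)
            if volume_bytes is not None:
                (path / "volume.nii").write_bytes(volume_bytes)
        return path


def _matrix_text(m: np.ndarray) -> str:
    buf = io.StringIO()
    np.savetxt(buf, m, fmt="%.12g")
    return buf.getvalue()


def _parse_matrix(text: str, source: str) -> np.ndarray:
    try:
        m = np.loadtxt(io.StringIO(text.replace(",", " ")), ndmin=2)
    except ValueError as exc:
        raise ConnectomeError(f"{source}: cannot parse matrix ({exc})") from exc
    return m


def load_connectome(path: str | Path) -> Connectome:
    """Load a connectome archive from a directory or ``.zip``.

    Raises :class:`ConnectomeError` naming the offending file and entry on
    a non-square weight matrix, a label-count mismatch, or negative weights.
    Missing tract lengths are recomputed as Euclidean distances between
    centres; a missing volume is simply absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"connectome archive not found: {path}")

    def read(name: str) -> Optional[bytes]:
        if str(path).endswith(".zip"):
            with zipfile.ZipFile(path) as zf:
                names = set(zf.namelist())
                for cand in (name, name.replace(".nii", ".nii.gz")):
                    if cand in names:
                        return zf.read(cand)
                return None
        for cand in (path / name, path / name.replace(".nii", ".nii.gz")):
            if cand.exists():
                return cand.read_bytes()
        return None

    wtext = read("weights.txt")
    if wtext is None:
        raise ConnectomeError(f"{path}: weights.txt missing")
    weights = _parse_matrix(wtext.decode(), f"{path}/weights.txt")
    if weights.shape[0] != weights.shape[1]:
        raise ConnectomeError(
            f"{path}/weights.txt: non-square matrix of shape {weights.shape}"
        )
    if np.any(weights < 0):
        i, j = np.argwhere(weights < 0)[0]
        raise ConnectomeError(
            f"{path}/weights.txt: negative weight {weights[i, j]} at entry ({i}, {j})"
        )

    ctext = read("centres.txt")
    if ctext is None:
        raise ConnectomeError(f"{path}: centres.txt missing")
    labels, centres = [], []
    for ln, line in enumerate(ctext.decode().splitlines()):
        parts = line.replace(",", " ").split()
        if not parts:
            continue
        if len(parts) < 4:
            raise ConnectomeError(f"{path}/centres.txt line {ln + 1}: expected 'label x y z'")
        labels.append(" ".join(parts[:-3]))
        centres.append([float(v) for v in parts[-3:]])
    if len(labels) != weights.shape[0]:
        raise ConnectomeError(
            f"{path}/centres.txt: {len(labels)} labels for "
            f"{weights.shape[0]} weight rows"
        )

    ltext = read("tract_lengths.txt")
    lengths = _parse_matrix(ltext.decode(), f"{path}/tract_lengths.txt") if ltext else None

    htext = read("hemispheres.txt")
    hemis = htext.decode().split() if htext else None

    meta = json.loads(read("meta.json").decode()) if read("meta.json") else {}

    vbytes = read("volume.nii")
    volume = None
    if vbytes is not None:
        volume = np.asarray(
            nib.Nifti1Image.from_bytes(vbytes).get_fdata()
        ).astype(int)

    conn = Connectome(
        weights=weights,
        region_labels=np.array(labels),
        centres=np.array(centres),
        tract_lengths=lengths,
        hemispheres=np.array(hemis) if hemis else None,
        volume=volume,
        voxel_resolution_um=float(meta.get("voxel_resolution_um", 100.0)),
    )
    checksum = hashlib.sha256(wtext).hexdigest()[:12]
    log.info("loaded connectome %s: N=%d, weights sha256[:12]=%s", path, conn.n_regions, checksum)
    return conn


def euclidean_tract_lengths(
    centres: np.ndarray, region_labels: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Tract lengths approximated by straight-line distances between centres.

    Returns the symmetric, zero-diagonal matrix of pairwise Euclidean
    distances (mm).  A non-finite coordinate raises an error identifying the
    region.
    """
    centres = np.asarray(centres, dtype=float)
    if centres.ndim != 2 or centres.shape[1] != 3:
        raise ConnectomeError(f"centres must be N x 3, got {centres.shape}")
    if not np.all(np.isfinite(centres)):
        bad = int(np.argwhere(~np.isfinite(centres))[0][0])
        name = region_labels[bad] if region_labels is not None else f"index {bad}"
        raise ConnectomeError(f"non-finite centre coordinate for region {name}")
    return squareform(pdist(centres))


def mirror_hemisphere(right_to_right: np.ndarray, right_to_left: np.ndarray) -> np.ndarray:
    """Assemble a whole-brain matrix from right-hemisphere tracer blocks.

    Tracer injections are performed in the right hemisphere only, so the left
    hemisphere is the mirror image of the right: with the block order
    ``[[RR, RL], [LR, LL]]`` the output satisfies ``R-R = L-L`` and
    ``R-L = L-R`` exactly.
    """
    rr = np.asarray(right_to_right, dtype=float)
    rl = np.asarray(right_to_left, dtype=float)
    if rr.ndim != 2 or rr.shape[0] != rr.shape[1]:
        raise ConnectomeError(f"R-R block must be square, got {rr.shape}")
    if rl.shape != rr.shape:
        raise ConnectomeError(f"block shapes differ: R-R {rr.shape}, R-L {rl.shape}")
    if np.any(rr < 0) or np.any(rl < 0):
        raise ConnectomeError("hemisphere blocks must be nonnegative")
    return np.block([[rr, rl], [rl, rr]])


def build_region_volume_mapping(
    annotation_volume: np.ndarray, region_ids: Sequence[int]
) -> np.ndarray:
    """Relabel an annotation volume with connectome row indices.

    Voxels of the i-th region of ``region_ids`` (ordered as the connectome
    rows) receive value ``i``; every other voxel — background and structures
    not present in ``region_ids`` — receives ``-1``.
    """
    annotation = np.asarray(annotation_volume)
    out = np.full(annotation.shape, -1, dtype=int)
    for i, rid in enumerate(region_ids):
        out[annotation == rid] = i
    return out


@dataclass(frozen=True)
class LesionSpec:
    """Regions whose in/out connections are removed, mimicking structural damage.

    With ``conserve_total_weight`` the surviving connections are rescaled by a
    single constant so the total weight of the lesioned matrix equals the
    original total.
    """

    region_names: tuple = ()
    conserve_total_weight: bool = True

    def __post_init__(self):
        object.__setattr__(self, "region_names", tuple(self.region_names))


def lesion_connectome(connectome: Connectome, spec: LesionSpec) -> Connectome:
    """Zero the rows and columns of the named regions; optionally renormalize.

    The renormalization factor is computed from the sum over *all* matrix
    entries (total weight), not per row.  Lesioning every region, or a set
    whose removal leaves zero total weight, is an error.
    """
    if not spec.region_names:
        raise ConnectomeError("lesion set is empty")
    idx = sorted({connectome.index(name) for name in spec.region_names})
    n = connectome.n_regions
    if len(idx) >= n:
        raise ConnectomeError("cannot lesion all regions")
    w = connectome.weights.copy()
    total = w.sum()
    w[idx, :] = 0.0
    w[:, idx] = 0.0
    if spec.conserve_total_weight:
        remaining = w.sum()
        if remaining <= 0:
            raise ConnectomeError(
                "lesion removes all weight; cannot conserve total weight"
            )
        w *= total / remaining
    return replace(connectome, weights=w, tract_lengths=connectome.tract_lengths)
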
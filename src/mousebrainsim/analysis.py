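"""Functional-network analysis of simulated series.

Covers the spatial and temporal views of functional connections:

* FC — Pearson correlation matrix between regional BOLD series;
* FCD — correlation matrix between the vectorized upper triangles of
  sliding-window FC matrices (3-min windows, 176-s overlap by default);
  diagonal blocks of elevated correlation are *epochs* of stable FC;
* epoch segmentation — spectral embedding of the FCD seen as a graph, using
  the commute distance (expected round-trip steps of a random walk), then
  seeded k-means over the embedded windows;
* functional hubs — regions with the largest absolute components of the
  leading FC eigenvectors (eigenvector-centrality reading of the FC);
* seizure onset latency — per-group mean onset times relative to the
  epileptogenic zone, for seizure-propagation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .hemodynamics import BoldSeries
from .integrate import SimulationResult


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# functional connectivity
# ---------------------------------------------------------------------------

@dataclass
class FCMatrix:
    """Pearson-correlation functional connectivity; symmetric, unit diagonal."""

    values: np.ndarray
    region_labels: Optional[Sequence[str]] = None

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class FCDMatrix:
    """Correlation between sliding-window FCs.

    ``values[i, j]`` is the Pearson correlation between the vectorized strict
    upper triangles of FC(t_i) and FC(t_j); ``window_centers_s`` locate the
    windows in time.
    """

    values: np.ndarray
    window_centers_s: np.ndarray
    window_s: float
    overlap_s: float

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def stride_s(self) -> float:
        return self.window_s - self.overlap_s


def _as_bold(bold, tr_s=None) -> Tuple[np.ndarray, float, Optional[Sequence[str]]]:
    if isinstance(bold, BoldSeries):
        return np.asarray(bold.values, dtype=float), bold.dt_s, bold.region_labels
    arr = np.asarray(bold, dtype=float)
    return arr, tr_s if tr_s is not None else 1.0, None


def functional_connectivity(bold, tr_s: Optional[float] = None) -> FCMatrix:
    """Pairwise Pearson correlation over the full series.

    Requires at least 3 time points and nonzero variance in every region
    (a zero-variance region is reported by name/index).
    """
    values, _, labels = _as_bold(bold, tr_s)
    if values.ndim != 2 or values.shape[1] < 3:
        raise AnalysisError("functional connectivity needs >= 3 time points")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argwhere(sd == 0)[0][0])
        name = labels[bad] if labels is not None else f"index {bad}"
        raise AnalysisError(f"region {name} has zero variance; FC undefined")
    fc = np.corrcoef(values)
    fc = np.clip(fc, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return FCMatrix(values=fc, region_labels=labels)


def fcd_matrix(
    bold,
    window_s: float = 180.0,
    overlap_s: float = 176.0,
    tr_s: Optional[float] = None,
) -> FCDMatrix:
    """Functional connectivity dynamics over sliding windows.

    Windows of ``window_s`` advance by ``window_s - overlap_s`` (4 s with the
    defaults); each window's FC is computed on its samples, and entry (i, j)
    is the Pearson correlation of the strict-upper-triangle vectors.  The
    diagonal FC entries (constant 1) are excluded so they cannot inflate the
    correlations.
    """
    values, tr, _ = _as_bold(bold, tr_s)
    if overlap_s >= window_s:
        raise AnalysisError(
            f"overlap ({overlap_s} s) must be smaller than the window ({window_s} s)"
        )
    win = int(round(window_s / tr))
    stride = int(round((window_s - overlap_s) / tr))
    if stride < 1:
        raise AnalysisError("window stride below one sample")
    t_len = values.shape[1]
    if t_len <= win:
        raise AnalysisError(
            f"series of {t_len} samples not longer than one window ({win} samples)"
        )
    n_windows = (t_len - win) // stride + 1
    iu = np.triu_indices(values.shape[0], k=1)
    vecs = np.empty((n_windows, len(iu[0])))
    centers = np.empty(n_windows)
    for i in range(n_windows):
        seg = values[:, i * stride : i * stride + win]
        sd = seg.std(axis=1)
        if np.any(sd == 0):
            bad = int(np.argwhere(sd == 0)[0][0])
            raise AnalysisError(
                f"region index {bad} has zero variance inside window {i}"
            )
        vecs[i] = np.corrcoef(seg)[iu]
        centers[i] = (i * stride + win / 2.0) * tr
    fcd = np.corrcoef(vecs)
    fcd = np.clip(fcd, -1.0, 1.0)
    np.fill_diagonal(fcd, 1.0)
    return FCDMatrix(
        values=fcd, window_centers_s=centers, window_s=window_s, overlap_s=overlap_s
    )


# ---------------------------------------------------------------------------
# commute distance and spectral embedding
# ---------------------------------------------------------------------------

def _laplacian_eig(W: np.ndarray):
    d = W.sum(axis=1)
    L = np.diag(d) - W
    evals, evecs = np.linalg.eigh(L)
    tol = max(1e-12, 1e-9 * max(evals.max(), 1.0))
    null = evals < tol
    return evals, evecs, null, W.sum()


def _check_affinity(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise AnalysisError(f"affinity must be square, got {W.shape}")
    if not np.allclose(W, W.T):
        raise AnalysisError("affinity must be symmetric")
    if np.any(W < 0):
        raise AnalysisError("affinity must be nonnegative")
    n_comp, _ = connected_components((W > 0).astype(int), directed=False)
    if n_comp > 1:
        raise AnalysisError(
            f"affinity graph has {n_comp} connected components; commute "
            "distance is undefined across components"
        )
    return W


def commute_distance(W: np.ndarray) -> np.ndarray:
    """Commute distances on a weighted graph.

    c_ij = vol(V) (e_i - e_j)^T L^+ (e_i - e_j), with L = D - W the graph
    Laplacian, L^+ its eigendecomposition pseudoinverse (null modes zeroed),
    and vol(V) the total weight.  Equals the expected number of steps of a
    random walk from i to j and back.
    """
    W = _check_affinity(W)
    evals, evecs, null, vol = _laplacian_eig(W)
    inv = np.where(null, 0.0, 1.0 / np.where(null, 1.0, evals))
    Ldag = (evecs * inv) @ evecs.T
    diag = np.diag(Ldag)
    c = vol * (diag[:, None] + diag[None, :] - 2.0 * Ldag)
    c = np.maximum(c, 0.0)
    np.fill_diagonal(c, 0.0)
    return c


@dataclass
class SpectralEmbedding:
    """Commute-distance-preserving coordinates of the FCD windows.

    Row i is z_i = sqrt(vol) (row i of U (Lambda^+)^(1/2)), so that
    ||z_i - z_j||^2 equals the commute distance c_ij exactly.  Columns are
    ordered by Laplacian eigenvalue (ascending; the first spans the null
    space and is identically zero).
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    vol: float


def spectral_embedding(
    fcd: Union[FCDMatrix, np.ndarray]
) -> SpectralEmbedding:
    """Embed FCD windows so Euclidean geometry reproduces commute distance.

    Negative FCD entries are clipped to zero to keep the Laplacian positive
    semidefinite; a disconnected affinity is an error.
    """
    W = fcd.values if isinstance(fcd, FCDMatrix) else np.asarray(fcd, dtype=float)
    W = _check_affinity(np.maximum(W, 0.0))
    evals, evecs, null, vol = _laplacian_eig(W)
    inv_sqrt = np.where(null, 0.0, 1.0 / np.sqrt(np.where(null, 1.0, evals)))
    coords = np.sqrt(vol) * evecs * inv_sqrt
    return SpectralEmbedding(coordinates=coords, eigenvalues=evals, vol=vol)


# ---------------------------------------------------------------------------
# epoch segmentation
# ---------------------------------------------------------------------------

@dataclass
class Epoch:
    start_s: float
    end_s: float
    label: int


@dataclass
class EpochSet:
    """Disjoint, ordered epochs of stable functional connectivity."""

    epochs: List[Epoch]
    window_labels: Optional[np.ndarray] = None
    n_clusters: Optional[int] = None

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def boundaries_s(self) -> np.ndarray:
        """Midpoints between consecutive epochs."""
        return np.array(
            [
                0.5 * (self.epochs[i].end_s + self.epochs[i + 1].start_s)
                for i in range(len(self.epochs) - 1)
            ]
        )

    def validate(self) -> None:
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.start_s <= a.start_s or a.end_s > b.start_s:
                raise AnalysisError("epochs must be ordered and non-overlapping")


def _eigengap_k(evals: np.ndarray, max_clusters: int) -> int:
    gaps = np.diff(evals[: max_clusters + 1])
    if len(gaps) == 0:
        return 1
    return int(np.argmax(gaps)) + 1


def segment_epochs(
    embedding: Union[SpectralEmbedding, np.ndarray],
    window_centers_s: np.ndarray,
    n_clusters: Optional[int] = None,
    max_clusters: int = 6,
    n_restarts: int = 50,
    min_run: int = 3,
    seed: int = 0,
) -> EpochSet:
    """Group FCD windows into temporally contiguous epochs of stability.

    Seeded k-means (``n_restarts`` restarts) on the leading embedding
    coordinates; the number of clusters, when not given, is chosen by the
    largest Laplacian eigengap capped at ``max_clusters``.  Cluster labels
    are smoothed so that only maximal contiguous runs of at least
    ``min_run`` windows survive; the runs are reported as epochs.
    """
    centers = np.asarray(window_centers_s, dtype=float)
    if isinstance(embedding, SpectralEmbedding):
        coords_all = embedding.coordinates
        evals = embedding.eigenvalues
    else:
        coords_all = np.asarray(embedding, dtype=float)
        evals = None
    n_windows = coords_all.shape[0]
    if n_windows < 2:
        raise AnalysisError("need at least 2 windows to segment")
    if len(centers) != n_windows:
        raise AnalysisError("window_centers length does not match embedding rows")

    k = n_clusters
    if k is None:
        if evals is None:
            raise AnalysisError("n_clusters required for raw-coordinate input")
        k = _eigengap_k(evals, min(max_clusters, n_windows - 1))
    k = max(1, min(k, n_windows))

    if k == 1:
        labels = np.zeros(n_windows, dtype=int)
    else:
        coords = coords_all[:, 1 : k + 1]
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(coords)

    labels = _smooth_runs(labels, min_run)

    epochs = []
    start = 0
    for i in range(1, n_windows + 1):
        if i == n_windows or labels[i] != labels[i - 1]:
            epochs.append(
                Epoch(
                    start_s=float(centers[start]),
                    end_s=float(centers[i - 1]),
                    label=int(labels[start]),
                )
            )
            start = i
    out = EpochSet(epochs=epochs, window_labels=labels, n_clusters=k)
    out.validate()
    return out


def _smooth_runs(labels: np.ndarray, min_run: int) -> np.ndarray:
    """Absorb runs shorter than ``min_run`` into their neighbours."""
    labels = np.asarray(labels).copy()

    def runs(lab):
        out = []
        start = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[i - 1]:
                out.append((start, i - 1))
                start = i
        return out

    while True:
        r = runs(labels)
        if len(r) <= 1:
            break
        lengths = [b - a + 1 for a, b in r]
        short = [i for i, ln in enumerate(lengths) if ln < min_run]
        if not short:
            break
        i = min(short, key=lambda idx: lengths[idx])
        a, b = r[i]
        if i == 0:
            labels[a : b + 1] = labels[r[1][0]]
        elif i == len(r) - 1 or lengths[i - 1] >= lengths[i + 1]:
            labels[a : b + 1] = labels[r[i - 1][1]]
        else:
            labels[a : b + 1] = labels[r[i + 1][0]]
    return labels


# ---------------------------------------------------------------------------
# functional hubs
# ---------------------------------------------------------------------------

@dataclass
class HubReport:
    """Leading FC eigenpairs and the regions flagged as functional hubs.

    ``eigenvalues`` descending; ``eigenvectors[:, k]`` unit-norm with its
    largest-|.| component made positive; ``hub_masks[:, k]`` flags regions
    whose |component| reaches ``frac`` of the vector's maximum.
    ``degenerate`` marks an eigenvalue tie at the cut boundary (all tied
    vectors are then reported).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    hub_masks: np.ndarray
    frac: float
    degenerate: bool = False
    region_labels: Optional[Sequence[str]] = None

    def hubs(self, k: int = 0) -> List[str]:
        names = (
            list(self.region_labels)
            if self.region_labels is not None
            else [str(i) for i in range(self.eigenvectors.shape[0])]
        )
        return [names[i] for i in np.flatnonzero(self.hub_masks[:, k])]


def functional_hubs(
    fc: Union[FCMatrix, np.ndarray], n_vectors: int = 3, frac: float = 0.5
) -> HubReport:
    """Functional hubs from the leading eigenvectors of the FC matrix.

    The FC is symmetric, hence diagonalizable with real spectrum; hubs of
    eigenvector k are the regions whose absolute component reaches ``frac``
    of that vector's maximum absolute component.  The eigenvalue magnitude
    measures how much of the FC each eigenvector reproduces.
    """
    if isinstance(fc, FCMatrix):
        values, labels = fc.values, fc.region_labels
    else:
        values, labels = np.asarray(fc, dtype=float), None
    if not np.allclose(values, values.T):
        raise AnalysisError("FC matrix must be symmetric")
    n = values.shape[0]
    n_vectors = min(n_vectors, n)
    evals, evecs = np.linalg.eigh(values)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    k = n_vectors
    scale = max(abs(evals[0]), 1.0)
    degenerate = False
    while k < n and abs(evals[k] - evals[k - 1]) <= 1e-10 * scale:
        k += 1
        degenerate = True

    sel_vals = evals[:k]
    sel_vecs = evecs[:, :k].copy()
    masks = np.zeros((n, k), dtype=bool)
    for i in range(k):
        v = sel_vecs[:, i]
        peak = int(np.argmax(np.abs(v)))
        if v[peak] < 0:
            v = -v
            sel_vecs[:, i] = v
        masks[:, i] = np.abs(v) >= frac * np.abs(v[peak])
    return HubReport(
        eigenvalues=sel_vals,
        eigenvectors=sel_vecs,
        hub_masks=masks,
        frac=frac,
        degenerate=degenerate,
        region_labels=labels,
    )


def hub_volume(connectome, report: HubReport, k: int = 0) -> np.ndarray:
    """Paint |eigenvector| components onto the region-volume mapping.

    Returns a float volume with -1 outside the parcellation, suitable for
    saving as NIfTI next to the connectome's volume.
    """
    if connectome.volume is None:
        raise AnalysisError("connectome has no region-volume mapping")
    comp = np.abs(report.eigenvectors[:, k])
    vol = np.full(connectome.volume.shape, -1.0)
    mask = connectome.volume >= 0
    vol[mask] = comp[connectome.volume[mask]]
    return vol


def count_seizure_cycles(
    x1: np.ndarray,
    dt_ms: float,
    threshold: float = -0.8,
    smooth_ms: float = 100.0,
) -> int:
    """Count complete onset-offset cycles in a fast-variable trace.

    The trace is smoothed with a moving average of ``smooth_ms`` (to bridge
    the fast intra-seizure oscillations), and a cycle is a rising crossing of
    ``threshold`` followed by a falling crossing.  The threshold sits between
    the interictal level (about -1.6) and the ictal mean (about 0).
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    w = max(1, int(round(smooth_ms / dt_ms)))
    if len(x1) < w + 1:
        return 0
    smooth = np.convolve(x1, np.ones(w) / w, mode="valid")
    above = smooth > threshold
    rising = np.flatnonzero(~above[:-1] & above[1:])
    falling = np.flatnonzero(above[:-1] & ~above[1:])
    return sum(1 for r in rising if np.any(falling > r))


# ---------------------------------------------------------------------------
# seizure onset latency
# ---------------------------------------------------------------------------

@dataclass
class OnsetLatencyReport:
    """Per-group seizure onset latencies relative to the epileptogenic zone."""

    table: pd.DataFrame
    node_onsets_ms: Dict[str, Optional[float]]
    ez_onset_ms: float


def _node_onsets(
    x: np.ndarray, times: np.ndarray, threshold: float, dwell_ms: float
) -> np.ndarray:
    """First time each column rises above threshold and stays there >= dwell."""
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    w = max(1, int(round(dwell_ms / dt)))
    t_len, n = x.shape
    onsets = np.full(n, np.nan)
    if t_len < w:
        return onsets
    above = x > threshold
    for j in range(n):
        run = 0
        for t in range(t_len):
            run = run + 1 if above[t, j] else 0
            if run >= w:
                onsets[j] = times[t - w + 1]
                break
    return onsets


def seizure_onset_latency(
    result: SimulationResult,
    region_groups: Mapping[str, Sequence[str]],
    ez_labels: Sequence[str],
    threshold: float = 0.0,
    dwell_ms: float = 100.0,
    state_variable: str = "x1",
) -> OnsetLatencyReport:
    """Seizure onset latency of each region group.

    A node's onset is the first time its fast variable rises above
    ``threshold`` and stays above for at least ``dwell_ms``.  A group's
    onset is the mean over its member nodes (nodes that never seize are
    flagged absent and excluded); its latency is the difference from the
    onset of the epileptogenic zone.  An EZ that never seizes is an error.
    """
    x = result.get(state_variable)
    labels = list(result.region_labels or [str(i) for i in range(result.n_regions)])
    lowered = [l.lower() for l in labels]

    def resolve(name: str) -> int:
        if name in labels:
            return labels.index(name)
        if name.lower() in lowered:
            return lowered.index(name.lower())
        raise AnalysisError(
            f"region {name!r} not in series; labels include {labels[:6]}..."
        )

    onsets = _node_onsets(x, result.times, threshold, dwell_ms)
    node_onsets = {
        lab: (None if np.isnan(onsets[i]) else float(onsets[i]))
        for i, lab in enumerate(labels)
    }

    ez_idx = [resolve(n) for n in ez_labels]
    ez_vals = onsets[ez_idx]
    ez_vals = ez_vals[~np.isnan(ez_vals)]
    if len(ez_vals) == 0:
        raise AnalysisError("no epileptogenic-zone node ever crossed seizure onset")
    ez_onset = float(ez_vals.mean())

    rows = []
    for group, members in region_groups.items():
        idx = [resolve(n) for n in members]
        vals = onsets[idx]
        present = vals[~np.isnan(vals)]
        onset = float(present.mean()) if len(present) else np.nan
        rows.append(
            {
                "group": group,
                "onset_s": onset / 1000.0 if np.isfinite(onset) else np.nan,
                "latency_s": (onset - ez_onset) / 1000.0 if np.isfinite(onset) else np.nan,
                "n_nodes": len(idx),
                "n_absent": int(np.isnan(vals).sum()),
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    return OnsetLatencyReport(
        table=table, node_onsets_ms=node_onsets, ez_onset_ms=ez_onset
    )
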
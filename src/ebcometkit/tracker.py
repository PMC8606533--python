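"""Topological comet tracker.

A moving comet traces an elongated, tilted "pillar" through the 3D ``(x, y,
t)`` voxel volume of a preprocessed stack.  The tracker

1. finds bright local-maximum seed voxels (:func:`detect_seeds`),
2. grows each seed into a connected cloud of positive voxels with a
   gradient-capped flood fill (:func:`flood_fill_segment`),
3. deletes the fusion planes where two comet tracks collide so every
   remaining piece is a single-comet track (:func:`decouple_collisions`),
4. removes non-comet objects — too small, too short-lived, or static
   (:func:`filter_objects`).

Connectivity convention: 8-connectivity within an XY plane; components of
adjacent frames belong to the same pillar iff their XY pixel sets overlap by
at least one pixel (equivalently: a direct vertical voxel neighbour along t).
"""

from __future__ import annotations

import dataclasses
import logging
from collections import deque

import numpy as np
from scipy import ndimage

from .stack_io import ImageStack

logger = logging.getLogger(__name__)

#: 3D structuring element of the pillar connectivity: full 8-connectivity in
#: the XY plane, plus the directly-above/below voxel along the time axis.
PILLAR_STRUCTURE = np.zeros((3, 3, 3), dtype=bool)
PILLAR_STRUCTURE[1] = True
PILLAR_STRUCTURE[0, 1, 1] = True
PILLAR_STRUCTURE[2, 1, 1] = True

_XY8 = np.ones((3, 3), dtype=bool)


@dataclasses.dataclass
class VoxelCloud:
    """A connected set of positive ``(t, y, x)`` voxels (one "pillar")."""

    voxels: np.ndarray  # (N, 3) int array of (t, y, x)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)

    def __len__(self) -> int:
        return self.voxels.shape[0]

    @property
    def t_first(self) -> int:
        return int(self.voxels[:, 0].min())

    @property
    def t_last(self) -> int:
        return int(self.voxels[:, 0].max())

    def plane(self, t: int) -> np.ndarray:
        """The ``(y, x)`` pixels of the cloud in frame ``t``."""
        return self.voxels[self.voxels[:, 0] == t, 1:]

    def plane_sizes(self) -> dict[int, int]:
        ts, counts = np.unique(self.voxels[:, 0], return_counts=True)
        return dict(zip(ts.tolist(), counts.tolist()))


@dataclasses.dataclass
class CometObservation:
    """One comet in one frame: its pixel set and brightest pixel."""

    t: int
    pixels: np.ndarray          # (n, 2) of (y, x)
    y_max: int
    x_max: int
    peak_intensity: float
    total_intensity: float


@dataclasses.dataclass
class CometTrack:
    """Per-frame decomposition of a surviving pillar: a single comet track."""

    track_id: int
    observations: list[CometObservation]

    def __post_init__(self) -> None:
        ts = [o.t for o in self.observations]
        if any(b - a != 1 for a, b in zip(ts, ts[1:])):
            raise ValueError("track frames must be consecutive")

    @property
    def n_frames(self) -> int:
        return len(self.observations)


@dataclasses.dataclass
class TrackerParams:
    """Segmentation and filtering parameters.

    The object filters default to the values appropriate for bright comets on
    large fields of view: at least 500 voxels in total, a cross-section of at
    least 50 pixels in every frame, a lifespan of at least 4 consecutive
    frames, and a net centroid drift of at least 1.5 px (static
    autofluorescent particles form near-vertical pillars with ~0 drift).
    ``g_max`` caps the relative intensity rise the flood fill may climb;
    ``inf`` disables the gradient rule.
    """

    brightness_quantile: float = 0.90
    g_max: float = 3.0
    dust_px: int = 10
    partner_min_px: int = 25
    min_voxels: int = 500
    min_plane_px: int = 50
    min_planes: int = 4
    min_tilt_px: float = 1.5
    drop_whole_plane: bool = False


# ---------------------------------------------------------------------------
# Seeds
# ---------------------------------------------------------------------------

def detect_seeds(
    stack: ImageStack, brightness_quantile: float = 0.90
) -> np.ndarray:
    """Bright local maxima of the preprocessed stack, sorted by intensity.

    A seed is a voxel that is a local maximum in its 26-neighbourhood in
    ``(x, y, t)`` and whose intensity is at or above the given quantile of
    all positive voxels.  Returns an ``(n, 3)`` array of ``(t, y, x)``.
    """
    frames = stack.frames
    positive = frames[frames > 0]
    if positive.size == 0:
        return np.empty((0, 3), dtype=np.int64)
    threshold = np.quantile(positive, brightness_quantile)
    maxima = ndimage.maximum_filter(frames, size=3, mode="constant", cval=-np.inf)
    mask = (frames >= threshold) & (frames > 0) & (frames == maxima)
    coords = np.argwhere(mask)
    order = np.argsort(frames[tuple(coords.T)])[::-1]
    return coords[order]


# ---------------------------------------------------------------------------
# Flood fill
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = [
    (0, dy, dx)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dy, dx) != (0, 0)
] + [(-1, 0, 0), (1, 0, 0)]


class _UnionFind:
    def __init__(self) -> None:
        self.parent: list[int] = []

    def make(self) -> int:
        self.parent.append(len(self.parent))
        return len(self.parent) - 1

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def flood_fill_segment(
    stack: ImageStack, seeds: np.ndarray, g_max: float = 3.0
) -> list[VoxelCloud]:
    """Grow seed voxels into pairwise-disjoint clouds of positive voxels.

    Growth proceeds over the pillar connectivity and stops at voxels of zero
    intensity or where the intensity of the candidate neighbour exceeds
    ``g_max`` times the intensity of the current voxel (the object's edge
    forms a large gradient; the cap prevents leaking into a brighter
    neighbouring comet through a dim bridge).  Seeds landing in an existing
    cloud are merged with it; clouds that touch are merged as well, and the
    downstream decoupling step decides the splits.  With ``g_max=inf`` the
    result is a plain positive-intensity flood fill.
    """
    frames = stack.frames
    nt, ny, nx = frames.shape
    labels = np.full(frames.shape, -1, dtype=np.int64)
    uf = _UnionFind()

    for t0, y0, x0 in np.asarray(seeds, dtype=np.int64):
        if frames[t0, y0, x0] <= 0:
            continue
        if labels[t0, y0, x0] != -1:
            continue  # seed landed inside an existing cloud: merged
        label = uf.make()
        labels[t0, y0, x0] = label
        queue = deque([(t0, y0, x0)])
        while queue:
            t, y, x = queue.popleft()
            cur = frames[t, y, x]
            limit = g_max * cur
            for dt, dy, dx in _NEIGHBOR_OFFSETS:
                tt, yy, xx = t + dt, y + dy, x + dx
                if tt < 0 or tt >= nt or yy < 0 or yy >= ny or xx < 0 or xx >= nx:
                    continue
                val = frames[tt, yy, xx]
                if val <= 0 or val > limit:
                    continue
                other = labels[tt, yy, xx]
                if other != -1:
                    if uf.find(other) != uf.find(label):
                        uf.union(other, label)
                    continue
                labels[tt, yy, xx] = label
                queue.append((tt, yy, xx))

    if not uf.parent:
        return []
    coords = np.argwhere(labels >= 0)
    roots = np.array([uf.find(l) for l in labels[tuple(coords.T)]])
    clouds = [
        VoxelCloud(coords[roots == r]) for r in np.unique(roots)
    ]
    logger.info("flood fill: %d seed(s) -> %d cloud(s)", len(seeds), len(clouds))
    return clouds


def brute_force_components(stack: ImageStack) -> list[VoxelCloud]:
    """Connected components of all positive voxels under pillar connectivity.

    Reference labelling used by tests and by :func:`decouple_collisions` for
    re-decomposition; independent of any seed choice or gradient rule.
    """
    mask = stack.frames > 0
    labeled, n = ndimage.label(mask, structure=PILLAR_STRUCTURE)
    return [VoxelCloud(np.argwhere(labeled == i)) for i in range(1, n + 1)]


def prune_small_plane_components(
    clouds: list[VoxelCloud], dust_px: int = 10
) -> list[VoxelCloud]:
    """Remove per-plane XY components smaller than ``dust_px`` pixels.

    A diffraction-limited comet head covers well over ten pixels, so smaller
    fragments are noise specks riding on the cloud.  Left in place they make
    a single comet look like a split or merge and trip the collision rule,
    shredding genuine tracks.  Pruned clouds are re-decomposed into connected
    components; empty results are dropped.
    """
    if dust_px <= 1:
        return clouds
    result: list[VoxelCloud] = []
    for cloud in clouds:
        mask, origin = _cloud_mask(cloud)
        for t in range(mask.shape[0]):
            lab, n = ndimage.label(mask[t], structure=_XY8)
            if n == 0:
                continue
            sizes = np.bincount(lab.ravel())
            small = np.nonzero(sizes < dust_px)[0]
            if small.size:
                mask[t][np.isin(lab, small[small > 0])] = False
        if not mask.any():
            continue
        lab, n = ndimage.label(mask, structure=PILLAR_STRUCTURE)
        for i in range(1, n + 1):
            result.append(VoxelCloud(np.argwhere(lab == i) + origin))
    return result


# ---------------------------------------------------------------------------
# Decoupling
# ---------------------------------------------------------------------------

def _cloud_mask(cloud: VoxelCloud) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mask of the cloud on its cropped bounding box, plus the origin."""
    origin = cloud.voxels.min(axis=0)
    extent = cloud.voxels.max(axis=0) - origin + 1
    mask = np.zeros(tuple(extent), dtype=bool)
    rel = cloud.voxels - origin
    mask[tuple(rel.T)] = True
    return mask, origin


def decouple_collisions(
    clouds: list[VoxelCloud],
    drop_whole_plane: bool = False,
    partner_min_px: int = 25,
) -> list[VoxelCloud]:
    """Split colliding tracks by deleting the fusion-plane components.

    For every pair of adjacent planes of a cloud, an XY component that
    overlaps two or more distinct XY components of the same cloud in the
    neighbouring plane marks a comet collision; that component (the merged
    set M) is deleted.  The rule is applied in both time directions, since a
    split running forward in time is a merge running backward.  Remaining
    voxels are re-decomposed into connected components, each a candidate
    single-comet track.  With ``drop_whole_plane`` the entire frame slice of
    the cloud at the fusion plane is deleted instead of only M.

    A collision means two *comets* meeting, so only overlap partners of at
    least ``partner_min_px`` pixels are counted: a comet's own tail can
    momentarily pinch off into a fragment near the intensity floor, and
    treating that fragment as a colliding comet would shred a healthy
    track plane by plane.

    Voxels are never created: the output voxel count is non-increasing.
    """
    result: list[VoxelCloud] = []
    n_collisions = 0
    for cloud in clouds:
        mask, origin = _cloud_mask(cloud)
        nt = mask.shape[0]
        plane_labels = []
        plane_sizes = []
        for t in range(nt):
            lab, n = ndimage.label(mask[t], structure=_XY8)
            plane_labels.append(lab)
            plane_sizes.append(np.bincount(lab.ravel(), minlength=n + 1))
        delete = np.zeros_like(mask)
        for t in range(nt - 1):
            la, lb = plane_labels[t], plane_labels[t + 1]
            both = (la > 0) & (lb > 0)
            if not both.any():
                continue
            pairs = np.unique(
                np.stack([la[both], lb[both]], axis=1), axis=0
            )
            big_a = plane_sizes[t][pairs[:, 0]] >= partner_min_px
            big_b = plane_sizes[t + 1][pairs[:, 1]] >= partner_min_px
            # forward: component in t+1 with >= 2 comet-sized parents in t
            for child in np.unique(pairs[:, 1]):
                if ((pairs[:, 1] == child) & big_a).sum() >= 2:
                    n_collisions += 1
                    if drop_whole_plane:
                        delete[t + 1][mask[t + 1]] = True
                    else:
                        delete[t + 1][lb == child] = True
            # backward: component in t with >= 2 comet-sized children in t+1
            for parent in np.unique(pairs[:, 0]):
                if ((pairs[:, 0] == parent) & big_b).sum() >= 2:
                    n_collisions += 1
                    if drop_whole_plane:
                        delete[t][mask[t]] = True
                    else:
                        delete[t][la == parent] = True
        remaining = mask & ~delete
        if not remaining.any():
            continue
        lab, n = ndimage.label(remaining, structure=PILLAR_STRUCTURE)
        for i in range(1, n + 1):
            result.append(VoxelCloud(np.argwhere(lab == i) + origin))
    logger.info(
        "decoupling: %d cloud(s) -> %d piece(s), %d fusion component(s) removed",
        len(clouds),
        len(result),
        n_collisions,
    )
    return result


# ---------------------------------------------------------------------------
# Object filters
# ---------------------------------------------------------------------------

def _plane_centroids(cloud: VoxelCloud) -> dict[int, np.ndarray]:
    cents: dict[int, np.ndarray] = {}
    for t in range(cloud.t_first, cloud.t_last + 1):
        px = cloud.plane(t)
        if len(px):
            cents[t] = px.mean(axis=0)
    return cents


def filter_objects(
    clouds: list[VoxelCloud],
    stack: ImageStack,
    min_voxels: int = 500,
    min_plane_px: int = 50,
    min_planes: int = 4,
    min_tilt_px: float = 1.5,
    frag_px: int = 25,
) -> list[CometTrack]:
    """Remove non-comet objects and convert survivors to comet tracks.

    A comet fades in and out, its cross-section can momentarily dip, and
    two comets can share a pillar without ever producing the topological
    split/merge signature the decoupling rule needs.  A plane is therefore
    *analysable* only when its main XY component has at least
    ``min_plane_px`` pixels and no second component of ``frag_px`` or more
    exists (sub-``frag_px`` satellites are pinched-off tail fragments and
    are ignored); other planes are removed and the cloud is split into the
    remaining runs of consecutive frames.  Each segment then survives iff
    it has at least ``min_voxels`` voxels in total, spans at least
    ``min_planes`` consecutive frames, and its per-plane centroid drifts by
    at least ``min_tilt_px`` pixels between the first and last frame
    (rejecting the nearly vertical pillars left by static particles).
    """
    tracks: list[CometTrack] = []
    counts = {"voxels": 0, "planes": 0, "tilt": 0}
    frames = stack.frames
    segments: list[tuple[VoxelCloud, dict[int, np.ndarray]]] = []
    for cloud in clouds:
        main_px: dict[int, np.ndarray] = {}
        for t in sorted(cloud.plane_sizes()):
            px = cloud.plane(t)
            lab, ncomp = ndimage.label(_pixels_to_mask(px), structure=_XY8)
            if ncomp > 1:
                sizes = np.bincount(lab.ravel())[1:]
                order = np.argsort(sizes)[::-1]
                if sizes[order[1]] >= frag_px:
                    continue  # ambiguous plane: unresolved second comet
                origin = px.min(axis=0)
                rel = px - origin
                px = px[lab[rel[:, 0], rel[:, 1]] == order[0] + 1]
            if len(px) >= min_plane_px:
                main_px[t] = px
        good_ts = sorted(main_px)
        if not good_ts:
            counts["planes"] += 1
            continue
        runs: list[list[int]] = [[good_ts[0]]]
        for t in good_ts[1:]:
            if t == runs[-1][-1] + 1:
                runs[-1].append(t)
            else:
                runs.append([t])
        kept_any = False
        for run in runs:
            if len(run) < min_planes:
                continue
            seg_vox = np.concatenate(
                [np.column_stack([np.full(len(main_px[t]), t), main_px[t]])
                 for t in run]
            )
            segments.append((VoxelCloud(seg_vox), {t: main_px[t] for t in run}))
            kept_any = True
        if not kept_any:
            counts["planes"] += 1
    for cloud, plane_px in segments:
        if len(cloud) < min_voxels:
            counts["voxels"] += 1
            continue
        cents = _plane_centroids(cloud)
        drift = np.linalg.norm(cents[cloud.t_last] - cents[cloud.t_first])
        if drift < min_tilt_px:
            counts["tilt"] += 1
            continue
        observations = []
        for t in sorted(plane_px):
            px = plane_px[t]
            vals = frames[t, px[:, 0], px[:, 1]]
            imax = int(np.argmax(vals))
            observations.append(
                CometObservation(
                    t=t,
                    pixels=px,
                    y_max=int(px[imax, 0]),
                    x_max=int(px[imax, 1]),
                    peak_intensity=float(vals[imax]),
                    total_intensity=float(vals.sum()),
                )
            )
        tracks.append(CometTrack(track_id=len(tracks), observations=observations))
    logger.info(
        "filters: %d cloud(s) -> %d track(s); removed %s", len(clouds), len(tracks), counts
    )
    return tracks


def _pixels_to_mask(px: np.ndarray) -> np.ndarray:
    origin = px.min(axis=0)
    extent = px.max(axis=0) - origin + 1
    mask = np.zeros(tuple(extent), dtype=bool)
    rel = px - origin
    mask[rel[:, 0], rel[:, 1]] = True
    return mask


def track_stack(
    stack: ImageStack, params: TrackerParams | None = None
) -> list[CometTrack]:
    """Full tracking chain: seeds → flood fill → decoupling → filters."""
    params = params or TrackerParams()
    seeds = detect_seeds(stack, params.brightness_quantile)
    clouds = flood_fill_segment(stack, seeds, params.g_max)
    clouds = prune_small_plane_components(clouds, params.dust_px)
    pieces = decouple_collisions(
        clouds, params.drop_whole_plane, params.partner_min_px
    )
    return filter_objects(
        pieces,
        stack,
        min_voxels=params.min_voxels,
        min_plane_px=params.min_plane_px,
        min_planes=params.min_planes,
        min_tilt_px=params.min_tilt_px,
        frag_px=params.partner_min_px,
    )
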
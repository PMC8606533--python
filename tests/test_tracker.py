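import numpy as np
import pytest
from scipy import ndimage

from ebcometkit.stack_io import ImageStack
from ebcometkit.tracker import (
    PILLAR_STRUCTURE,
    TrackerParams,
    VoxelCloud,
    brute_force_components,
    decouple_collisions,
    detect_seeds,
    filter_objects,
    flood_fill_segment,
    track_stack,
)


def gaussian_blob(frame, y0, x0, amp=10.0, sigma=1.5):
    ny, nx = frame.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    frame += amp * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sigma**2))


def moving_pillar_stack(n_frames=10, size=40, start=(10, 8), step=(1, 1), width=4):
    """A compact square object translating step px/frame: one tilted pillar."""
    frames = np.zeros((n_frames, size, size))
    for t in range(n_frames):
        y = start[0] + t * step[0]
        x = start[1] + t * step[1]
        frames[t, y : y + width + 4, x : x + width + 4] = 1.0
    return ImageStack(frames)


class TestDetectSeeds:
    def test_empty_stack_no_seeds(self):
        assert len(detect_seeds(ImageStack(np.zeros((4, 16, 16))))) == 0

    def test_single_blob_single_seed(self):
        frames = np.zeros((3, 32, 32))
        gaussian_blob(frames[1], 16, 16)
        seeds = detect_seeds(ImageStack(frames), 0.9)
        assert len(seeds) == 1
        np.testing.assert_array_equal(seeds[0], [1, 16, 16])

    def test_two_separated_blobs_two_seeds(self):
        frames = np.zeros((3, 48, 48))
        gaussian_blob(frames[1], 12, 12)
        gaussian_blob(frames[1], 36, 36, amp=8.0)
        seeds = detect_seeds(ImageStack(frames), 0.5)
        assert len(seeds) == 2
        # sorted by decreasing intensity: the brighter blob first
        np.testing.assert_array_equal(seeds[0], [1, 12, 12])

    def test_seeds_match_bruteforce_local_maxima(self, rng):
        frames = np.maximum(rng.normal(0, 1, (6, 20, 20)), 0)
        seeds = detect_seeds(ImageStack(frames), 0.8)
        positive = frames[frames > 0]
        thr = np.quantile(positive, 0.8)
        for t, y, x in seeds:
            v = frames[t, y, x]
            assert v >= thr
            neigh = frames[
                max(t - 1, 0) : t + 2, max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2
            ]
            assert v == neigh.max()


class TestFloodFill:
    def test_empty_stack(self):
        assert flood_fill_segment(ImageStack(np.zeros((3, 8, 8))), np.empty((0, 3), int)) == []

    def test_matches_connected_components_without_gradient_cap(self, rng):
        # on small random stacks, seeded flood fill with the cap disabled
        # must reproduce plain connected-components labelling
        frames = np.maximum(rng.normal(-0.3, 1.0, (12, 24, 24)), 0)
        stack = ImageStack(frames)
        seeds = detect_seeds(stack, 0.5)
        clouds = flood_fill_segment(stack, seeds, g_max=np.inf)
        oracle = brute_force_components(stack)
        seeded = {
            frozenset(map(tuple, c.voxels))
            for c in oracle
            if any(tuple(s) in set(map(tuple, c.voxels)) for s in seeds)
        }
        assert {frozenset(map(tuple, c.voxels)) for c in clouds} == seeded

    def test_disjoint_blobs_give_disjoint_clouds(self):
        frames = np.zeros((4, 40, 40))
        frames[:, 5:10, 5:10] = 1.0
        frames[:, 25:30, 25:30] = 2.0
        stack = ImageStack(frames)
        clouds = flood_fill_segment(stack, detect_seeds(stack, 0.1), g_max=np.inf)
        assert len(clouds) == 2
        sets = [set(map(tuple, c.voxels)) for c in clouds]
        assert not (sets[0] & sets[1])

    def test_moving_blob_forms_single_pillar(self):
        stack = moving_pillar_stack()
        clouds = flood_fill_segment(stack, detect_seeds(stack, 0.1), g_max=np.inf)
        assert len(clouds) == 1
        assert clouds[0].t_first == 0 and clouds[0].t_last == 9

    def test_gradient_cap_blocks_climb_into_brighter_object(self):
        # dim object touches a much brighter one through a bridge; with the
        # cap the fill started in the dim object must not leak across
        frames = np.zeros((1, 10, 30))
        frames[0, 4:7, 2:10] = 1.0     # dim
        frames[0, 5, 10:14] = 1.5      # bridge
        frames[0, 3:8, 14:24] = 30.0   # bright
        stack = ImageStack(frames)
        clouds = flood_fill_segment(stack, np.array([[0, 5, 5]]), g_max=3.0)
        assert len(clouds) == 1
        xs = clouds[0].voxels[:, 2]
        assert xs.max() < 14


class TestDecoupling:
    def _y_object(self):
        """Two comet-sized arms converging into one object (Y in time)."""
        frames = np.zeros((12, 60, 30))
        for t in range(6):
            frames[t, 5 + 3 * t : 13 + 3 * t, 8:16] = 1.0      # arm moving down
            frames[t, 47 - 3 * t : 55 - 3 * t, 8:16] = 1.0     # arm moving up
        for t in range(6, 12):
            frames[t, 22 : 34, 8:16] = 1.0                     # merged
        return ImageStack(frames)

    def test_straight_pillar_unchanged(self):
        stack = moving_pillar_stack()
        clouds = flood_fill_segment(stack, detect_seeds(stack, 0.1), g_max=np.inf)
        pieces = decouple_collisions(clouds)
        assert len(pieces) == 1
        assert set(map(tuple, pieces[0].voxels)) == set(map(tuple, clouds[0].voxels))

    def test_y_merge_splits_into_separate_tracks(self):
        stack = self._y_object()
        clouds = flood_fill_segment(stack, detect_seeds(stack, 0.1), g_max=np.inf)
        assert len(clouds) == 1
        pieces = decouple_collisions(clouds)
        assert len(pieces) >= 2
        # the fusion-plane component is gone
        fusion_voxels = sum(len(p.plane(6)) for p in pieces)
        assert fusion_voxels == 0

    def test_never_creates_voxels(self):
        stack = self._y_object()
        clouds = flood_fill_segment(stack, detect_seeds(stack, 0.1), g_max=np.inf)
        before = sum(len(c) for c in clouds)
        after = sum(len(p) for p in decouple_collisions(clouds))
        assert after <= before

    def test_x_object_matches_recomputation_oracle(self):
        # merge-then-split: deleting the flagged fusion components and
        # relabelling by brute force must give the same pieces
        frames = np.zeros((9, 60, 30))
        for t in range(4):
            frames[t, 5 + 3 * t : 13 + 3 * t, 8:16] = 1.0
            frames[t, 47 - 3 * t : 55 - 3 * t, 8:16] = 1.0
        frames[4, 18:46, 8:16] = 1.0  # crossing plane overlaps both arms
        for t in range(5, 9):
            frames[t, 5 + 3 * (8 - t) : 13 + 3 * (8 - t), 8:16] = 1.0
            frames[t, 47 - 3 * (8 - t) : 55 - 3 * (8 - t), 8:16] = 1.0
        stack = ImageStack(frames)
        clouds = flood_fill_segment(stack, detect_seeds(stack, 0.1), g_max=np.inf)
        pieces = decouple_collisions(clouds)
        # oracle: remove all flagged planes' voxels, relabel positives
        masks = frames > 0
        masks[4] = False  # the X's crossing plane
        lab, n = ndimage.label(masks, structure=PILLAR_STRUCTURE)
        assert len(pieces) == n

    def test_small_fragments_do_not_count_as_collisions(self):
        # a pinched-off tail fragment (below partner size) must not shred
        # the track
        frames = np.zeros((8, 30, 40))
        for t in range(8):
            frames[t, 10:18, 2 + 2 * t : 12 + 2 * t] = 1.0     # main comet
        frames[3, 14, 0] = 1.0  # 1-px fragment touching nothing
        frames[4, 13:15, 1:3] = 1.0  # small satellite near the comet
        stack = ImageStack(frames)
        clouds = flood_fill_segment(stack, detect_seeds(stack, 0.1), g_max=np.inf)
        pieces = decouple_collisions(clouds, partner_min_px=25)
        spans = sorted((p.t_first, p.t_last) for p in pieces if len(p) > 100)
        assert (0, 7) in spans


class TestFilters:
    def _cloud_from_stack(self, stack):
        return flood_fill_segment(stack, detect_seeds(stack, 0.1), g_max=np.inf)

    def test_small_object_removed(self):
        # 400 voxels total: 100 px cross-section over 4 planes
        frames = np.zeros((6, 40, 40))
        for t in range(1, 5):
            frames[t, 10 + t : 20 + t, 10 : 20] = 1.0
        stack = ImageStack(frames)
        tracks = filter_objects(
            self._cloud_from_stack(stack), stack,
            min_voxels=500, min_plane_px=50, min_planes=4, min_tilt_px=0.5,
        )
        assert tracks == []

    def test_short_pillar_removed(self):
        # 3 planes only, everything else compliant
        frames = np.zeros((5, 40, 40))
        for t in range(3):
            frames[t, 10 + 2 * t : 20 + 2 * t, 10:26] = 1.0
        stack = ImageStack(frames)
        tracks = filter_objects(
            self._cloud_from_stack(stack), stack,
            min_voxels=100, min_plane_px=50, min_planes=4, min_tilt_px=0.5,
        )
        assert tracks == []

    def test_compliant_moving_pillar_retained(self):
        # 10 planes x 64 px moving 1.4 px/frame: passes every filter
        frames = np.zeros((10, 60, 60))
        for t in range(10):
            frames[t, 10 + t : 18 + t, 10 + t : 18 + t] = 1.0
        stack = ImageStack(frames)
        tracks = filter_objects(
            self._cloud_from_stack(stack), stack,
            min_voxels=500, min_plane_px=50, min_planes=4, min_tilt_px=1.5,
        )
        assert len(tracks) == 1
        assert tracks[0].n_frames == 10
        obs = tracks[0].observations[0]
        assert obs.pixels.shape[0] == 64

    def test_static_pillar_removed_by_tilt(self):
        frames = np.zeros((10, 40, 40))
        frames[:, 10:18, 10:18] = 1.0  # bright but motionless
        stack = ImageStack(frames)
        tracks = filter_objects(
            self._cloud_from_stack(stack), stack,
            min_voxels=500, min_plane_px=50, min_planes=4, min_tilt_px=1.5,
        )
        assert tracks == []

    def test_dim_interior_plane_splits_track(self):
        frames = np.zeros((12, 60, 60))
        for t in range(12):
            frames[t, 10 + t : 18 + t, 10 + t : 18 + t] = 1.0
        frames[6] = 0.0
        frames[6, 16:18, 16:18] = 1.0  # dip below min_plane_px
        stack = ImageStack(frames)
        tracks = filter_objects(
            self._cloud_from_stack(stack), stack,
            min_voxels=100, min_plane_px=50, min_planes=4, min_tilt_px=1.5,
        )
        assert len(tracks) == 2
        spans = sorted((t.observations[0].t, t.observations[-1].t) for t in tracks)
        assert spans == [(0, 5), (7, 11)]


def test_track_stack_outputs_disjoint_tracks():
    frames = np.zeros((10, 80, 80))
    for t in range(10):
        frames[t, 10 + t : 18 + t, 10 + t : 18 + t] = 1.0
        frames[t, 50 - t : 58 - t, 50 : 58] = 1.0
    tracks = track_stack(
        ImageStack(frames),
        TrackerParams(min_voxels=300, min_plane_px=40, min_tilt_px=1.5,
                      brightness_quantile=0.5),
    )
    assert len(tracks) == 2
    seen = set()
    for tr in tracks:
        for obs in tr.observations:
            for y, x in obs.pixels:
                key = (obs.t, y, x)
                assert key not in seen
                seen.add(key)
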
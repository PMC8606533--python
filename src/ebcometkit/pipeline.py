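"""End-to-end analysis: preprocessed stack → tracks → fitted tip table.

Thin orchestration over the preprocess, tracker and comet_fit modules; the
CLI and the synthetic-movie benchmarks both run through here.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import comet_fit
from .preprocess import PreprocessParams, preprocess_stack
from .stack_io import ImageStack, new_track_table
from .tracker import CometTrack, TrackerParams, track_stack

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FitParams:
    r_max: float = 30.0
    r_min: float = 10.0
    #: Bounds on the fitted threshold T as multiples of the residual
    #: self-background prior left after the restoration step.
    t_prior_lo: float = 0.0
    t_prior_hi: float = 2.0
    #: Observations with another track's comet closer than this (px) are
    #: flagged crowded and excluded from acceptance: overlapping Airy disks
    #: pollute the profile without necessarily fusing the voxel clouds.
    crowd_radius_px: float = 15.0
    #: Reduced-χ² acceptance gate (residual per sample over the noise
    #: variance).  A profile polluted by an undetected neighbour cannot be
    #: fitted by the single-comet model and fails this gate.
    max_chi2_red: float = 3.0
    #: Half-width (rad) of the tail-direction search window around the
    #: motion prior.
    tail_prior_halfwidth_rad: float = 0.9


def _tail_priors(track: CometTrack) -> np.ndarray:
    """Per-observation tail direction prior: against the local motion.

    The comet head leads the motion and a growing microtubule does not
    reverse, so the tail horde must point roughly backwards along the
    trajectory of the brightest pixel.  The local direction is taken over a
    ±3-frame window; where that displacement is too small to orient (< 2 px)
    the track's net drift is used instead.
    """
    pos = np.array([(o.x_max, o.y_max) for o in track.observations], dtype=float)
    n = len(pos)
    net = pos[-1] - pos[0]
    priors = np.empty(n)
    for i in range(n):
        a, b = max(i - 3, 0), min(i + 3, n - 1)
        d = pos[b] - pos[a]
        if np.hypot(*d) < 2.0:
            d = net
        priors[i] = np.arctan2(-d[1], -d[0])
    return priors


def fit_track(
    stack: ImageStack,
    track: CometTrack,
    params: FitParams | None = None,
    t_prior_map: np.ndarray | None = None,
    noise_sigma: float | None = None,
) -> pd.DataFrame:
    """Fit every observation of one track; returns canonical table rows.

    ``stack`` should be the thresholded stack *without* the segmentation
    noise floor (the floor's jump discontinuity biases the fit);
    ``t_prior_map`` is the per-voxel self-background estimate used to bound
    the fitted threshold T.
    """
    params = params or FitParams()
    priors = _tail_priors(track)
    rows = []
    for obs, prior in zip(track.observations, priors):
        frame = stack.frames[obs.t]
        t_bounds = None
        if t_prior_map is not None:
            tp = float(t_prior_map[obs.t, obs.y_max, obs.x_max])
            t_bounds = (params.t_prior_lo * tp, max(params.t_prior_hi * tp, 1e-6))
        hordes = comet_fit.extract_polar_profiles(
            frame,
            (obs.x_max, obs.y_max),
            r_max=params.r_max,
            r_min=params.r_min,
            tail_prior_rad=prior,
            tail_prior_halfwidth_rad=params.tail_prior_halfwidth_rad,
        )
        row = dict(
            track_id=track.track_id,
            frame_index=obs.t,
            x_max=obs.x_max,
            y_max=obs.y_max,
            x_end=np.nan, y_end=np.nan, L_px=np.nan, x_c_px=np.nan, d_px=np.nan,
            T=np.nan, A=np.nan, phi_head_rad=np.nan, residual=np.nan,
            clipped_fraction=np.nan, low_anisotropy=True, crowded=False,
            accepted=False,
            x_end_nm=np.nan, y_end_nm=np.nan, L_nm=np.nan,
        )
        if hordes.valid:
            row["phi_head_rad"] = hordes.phi_head
            row["low_anisotropy"] = hordes.low_anisotropy
            try:
                profile = comet_fit.build_comet_profile(hordes)
                fit = comet_fit.fit_profile(profile, t_bounds=t_bounds)
            except comet_fit.ProfileError:
                fit = None
            if fit is not None:
                tip = comet_fit.tip_global_coords(fit, hordes, stack.pixel_size_nm)
                chi2_ok = True
                if noise_sigma is not None and noise_sigma > 0:
                    n_samples = len(profile.x)
                    chi2_ok = fit.residual <= (
                        params.max_chi2_red * noise_sigma**2 * n_samples
                    )
                row.update(
                    x_end=tip.x_end, y_end=tip.y_end,
                    x_end_nm=tip.x_end_nm, y_end_nm=tip.y_end_nm,
                    L_px=fit.L, L_nm=fit.L * stack.pixel_size_nm,
                    x_c_px=fit.x_c, d_px=fit.d, T=fit.T, A=fit.A,
                    residual=fit.residual, clipped_fraction=fit.clipped_fraction,
                    accepted=bool(
                        fit.accepted and not hordes.low_anisotropy and chi2_ok
                    ),
                )
        rows.append(row)
    return new_track_table(rows)


def flag_heading_outliers(table: pd.DataFrame, max_dev_rad: float = 0.8) -> pd.DataFrame:
    """Reject observations whose head angle breaks from their track.

    A growing microtubule does not reverse: the head horde of one track
    points in a stable direction.  Observations deviating from the track's
    circular mean heading by more than ``max_dev_rad`` (default ~46°) are
    direction-assignment failures (typically frames where the truncated
    temporal window distorts the profile) and are dropped from acceptance.
    """
    table = table.copy()
    for _, idx in table.groupby("track_id").groups.items():
        sub = table.loc[idx]
        ok = sub["accepted"].to_numpy()
        if ok.sum() < 4:
            continue
        phi = sub["phi_head_rad"].to_numpy()
        mean_dir = np.angle(np.mean(np.exp(1j * phi[ok])))
        dev = np.abs(np.angle(np.exp(1j * (phi - mean_dir))))
        table.loc[idx, "accepted"] = ok & (dev <= max_dev_rad)
    return table


def flag_residual_outliers(table: pd.DataFrame, factor: float = 2.0) -> pd.DataFrame:
    """Reject observations fitting much worse than the rest of their track.

    A comet's fit residual is stable along a track; a frame whose residual
    exceeds ``factor`` times the track's median is polluted (a passing
    object, an unresolved neighbour) and is dropped from acceptance.
    """
    table = table.copy()
    for _, idx in table.groupby("track_id").groups.items():
        sub = table.loc[idx]
        ok = sub["accepted"].to_numpy()
        if ok.sum() < 4:
            continue
        med = float(np.median(sub.loc[ok, "residual"]))
        bad = sub["residual"].to_numpy() > factor * med
        table.loc[idx, "accepted"] = ok & ~bad
    return table


def flag_crowded(table: pd.DataFrame, radius_px: float) -> pd.DataFrame:
    """Flag observations with another track's comet within ``radius_px``.

    Overlapping Airy disks of nearby tips pollute each other's profiles even
    when the voxel clouds never touch, so crowded observations are dropped
    from acceptance (mirroring the removal of colliding comets upstream).
    """
    table = table.copy()
    for _, idx in table.groupby("frame_index").groups.items():
        sub = table.loc[idx]
        if len(sub) < 2:
            continue
        pos = sub[["x_max", "y_max"]].to_numpy(dtype=float)
        tid = sub["track_id"].to_numpy()
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        other = tid[:, None] != tid[None, :]
        crowded = ((d < radius_px) & other).any(axis=1)
        table.loc[idx, "crowded"] = table.loc[idx, "crowded"].to_numpy() | crowded
    table["accepted"] = table["accepted"] & ~table["crowded"]
    return table


def analyze_stack(
    stack: ImageStack,
    preprocess_params: PreprocessParams | None = None,
    tracker_params: TrackerParams | None = None,
    fit_params: FitParams | None = None,
    preprocessed: bool = False,
) -> pd.DataFrame:
    """Run the full pipeline on a raw (or already preprocessed) stack.

    Segmentation runs on the noise-floored stack; profile fitting runs on
    the zero-clamped stack with the self-background T prior.  When
    ``preprocessed`` is given, the input is used for both and T is fitted
    freely.
    """
    if preprocessed:
        seg_stack, fit_stack, t_prior, sigma = stack, stack, None, None
    else:
        result = preprocess_stack(stack, preprocess_params)
        seg_stack, fit_stack = result.stack, result.unfloored
        t_prior, sigma = result.t_prior, result.noise_sigma
    tracks = track_stack(seg_stack, tracker_params)
    tables = [
        fit_track(fit_stack, tr, fit_params, t_prior_map=t_prior, noise_sigma=sigma)
        for tr in tracks
    ]
    table = (
        pd.concat(tables, ignore_index=True) if tables else new_track_table()
    )
    if len(table):
        table = flag_crowded(table, (fit_params or FitParams()).crowd_radius_px)
        table = flag_heading_outliers(table)
        table = flag_residual_outliers(table)
    logger.info(
        "pipeline: %d track(s), %d observation(s), %d accepted fit(s)",
        len(tracks),
        len(table),
        int(table["accepted"].sum()) if len(table) else 0,
    )
    return table
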
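"""Stochastic 1D microtubule growth model and synthetic movie renderer.

Growth model
------------
The microtubule tip is a 1D coordinate ``X`` that advances once per time
step (the time discrete is 1) by a velocity drawn from a normal law,
``X_{n+1} = X_n + V_rand``, ``V_rand ~ N(µ_v, σ_v)``.  Each positive step
deposits a new decorated *region* of that length at the tip with age 0;
negative steps erode length from the newest regions (the tip retreats, but
total decorated length never goes below zero).  Every region's EB
concentration decays with its age as ``e^{−age/DT}`` where DT is the
decoration time; regions fainter than the threshold θ (default ``e^{−4}``)
are dropped.  The comet intensity profile at any instant is the
piecewise-constant function of these region intensities — intensity 1 at the
tip, fading toward the lattice.

The model's headline predictions, all reproduced by the tests: the step
velocity v_n does not correlate with the same-frame comet length L_n, the
correlation is maximal with the *next* frame's length L_{n+1} and decays for
larger lags, and when velocities are averaged over k steps the correlation
R(ϑ_k, L_{n+k}) peaks at k ≈ DT — which is what makes DT measurable from
length/velocity regression.

Renderer
--------
:func:`render_stack` turns straight-moving simulated comets into a realistic
16-bit movie: an exponential tail density convolved with a 2D Gaussian PSF,
on top of static autofluorescent blobs, an illumination gradient and
detector noise, with the exact ground truth returned alongside.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .comet_fit import exp_gauss
from .stack_io import ImageStack

logger = logging.getLogger(__name__)

#: Default region-drop threshold: regions older than 4·DT are discarded,
#: truncating < 2% of the profile area.
DEFAULT_THETA = float(np.exp(-4.0))


@dataclasses.dataclass
class GrowthModelState:
    """State of the 1D growth model.

    ``region_lengths``/``region_births`` are ordered newest-first; a
    region's age is ``step - birth`` and its intensity ``exp(-age/dt)``.
    ``tip`` is the coordinate of the microtubule end.
    """

    dt: float
    mu_v: float = 1.0
    sigma_v: float = 1.0
    theta: float = DEFAULT_THETA
    tip: float = 0.0
    step: int = 0
    region_lengths: list[float] = dataclasses.field(default_factory=list)
    region_births: list[int] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("decoration time must be positive")
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")

    @property
    def total_length(self) -> float:
        return float(sum(self.region_lengths))

    def ages(self) -> np.ndarray:
        return self.step - np.asarray(self.region_births, dtype=float)

    def intensities(self) -> np.ndarray:
        return np.exp(-self.ages() / self.dt)


def step_growth(state: GrowthModelState, rng: np.random.Generator) -> GrowthModelState:
    """Advance the model by one time step (mutates and returns ``state``).

    Draws ``V_rand``; a non-negative draw prepends a fresh region of that
    length (age 0) and moves the tip forward.  A negative draw erodes up to
    ``|V_rand|`` of length from the newest regions — the comet cannot shrink
    below zero length, so the applied tip displacement may be smaller in
    magnitude than the draw.  Ages then advance and regions whose intensity
    falls below θ are dropped (which never moves the tip).
    """
    v = float(rng.normal(state.mu_v, state.sigma_v))
    state.step += 1
    if v >= 0:
        state.region_lengths.insert(0, v)
        state.region_births.insert(0, state.step)  # age 0 at the new snapshot
        state.tip += v
    else:
        deficit = -v
        while deficit > 0 and state.region_lengths:
            if state.region_lengths[0] > deficit:
                state.region_lengths[0] -= deficit
                state.tip -= deficit
                deficit = 0.0
            else:
                eaten = state.region_lengths.pop(0)
                state.region_births.pop(0)
                state.tip -= eaten
                deficit -= eaten
    max_age = -state.dt * np.log(state.theta)
    while state.region_births and (state.step - state.region_births[-1]) > max_age:
        state.region_lengths.pop()
        state.region_births.pop()
    return state


def profile_from_regions(state: GrowthModelState) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant intensity profile n(X) of the current comet.

    Returns ``(edges, values)``: ``edges`` has ``m+1`` distances from the tip
    (0 first) and ``values`` the ``m`` region intensities ``e^{−age/DT}``,
    newest (intensity ~1) first.  An empty comet yields empty arrays.
    """
    lengths = np.asarray(state.region_lengths, dtype=float)
    if lengths.size == 0:
        return np.empty(0), np.empty(0)
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    return edges, state.intensities()


def fit_profile_decay(
    edges: np.ndarray, values: np.ndarray, amplitude: float = 1.0
) -> float:
    """Decay length of a pure exponential fitted to a piecewise profile.

    Moment (area) estimator: for a profile ``n(x) = A·e^{−x/L}`` the decay
    length equals the profile area over the amplitude, ``L = ∫n(x)dx / A``,
    so ``L̂ = Σ len_i·I_i / A``.  The decoration law fixes the density of a
    fresh region at 1, so ``amplitude`` defaults to 1.  Each region
    contributes in proportion to its current brightness — exactly the
    weighting of the underlying decoration decay — which makes the estimator
    exact for the noiseless constant-velocity profile and linear in the
    region contributions.  Returns NaN for fewer than two finite-length
    regions (no decay information).
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    lengths = np.diff(edges)
    keep = lengths > 0
    lengths, values = lengths[keep], np.asarray(values, dtype=float)[keep]
    if lengths.size < 2:
        return float("nan")
    return float(np.sum(lengths * values) / amplitude)


@dataclasses.dataclass
class SimulatedTrack:
    """Output of :func:`simulate_track`; all series are frame-aligned.

    ``v[n]`` is the tip displacement applied between frames n and n+1,
    ``length[n]`` the comet decay length fitted at frame n *before* that
    displacement, ``tip[n]`` the tip coordinate at frame n.
    """

    v: np.ndarray
    length: np.ndarray
    tip: np.ndarray
    dt: float
    mu_v: float
    sigma_v: float


def simulate_track(
    mu_v: float = 1.0,
    sigma_v: float = 1.0,
    dt: float = 40.0,
    theta: float = DEFAULT_THETA,
    n_steps: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedTrack:
    """Run the growth model for ``n_steps`` and record (v, L, tip) series.

    Deterministic for a given seed.  ``length[n]`` is NaN while the comet
    has fewer than two regions (the first steps of a run).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    state = GrowthModelState(dt=dt, mu_v=mu_v, sigma_v=sigma_v, theta=theta)
    v = np.empty(n_steps)
    length = np.empty(n_steps)
    tip = np.empty(n_steps)
    for n in range(n_steps):
        edges, values = profile_from_regions(state)
        length[n] = fit_profile_decay(edges, values)
        tip[n] = state.tip
        before = state.tip
        step_growth(state, rng)
        v[n] = state.tip - before
    return SimulatedTrack(
        v=v, length=length, tip=tip, dt=dt, mu_v=mu_v, sigma_v=sigma_v
    )


# ---------------------------------------------------------------------------
# Movie renderer
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RenderParams:
    """Synthetic movie parameters.

    Defaults emulate the targeted acquisition: 103 nm pixels, 500 ms frames,
    wide-field Gaussian PSF (``e^{−r²/d²}``, d = 1.5 px allowing slight
    defocus), comet speeds ~1.6 px/frame (≈330 nm/s) and decay lengths
    ~12 ± 6 px (≈1.25 ± 0.6 µm), peak signal-to-noise ≈ 10 over the read
    noise, static autofluorescent blobs and a linear illumination gradient
    on a constant camera baseline.
    """

    n_frames: int = 100
    height: int = 256
    width: int = 256
    pixel_size_nm: float = 103.0
    frame_interval_s: float = 0.5
    n_comets: int = 20
    psf_d_px: float = 1.5
    speed_mean_px: float = 1.6
    speed_sd_px: float = 0.3
    length_mean_px: float = 12.2
    length_sd_px: float = 6.1
    length_min_px: float = 4.0
    length_max_px: float = 25.0
    min_lifespan: int = 25
    max_lifespan: int = 60
    margin_px: float = 36.0
    peak_snr: float = 10.0
    read_noise_sd: float = 2.0
    shot_noise_gain: float = 0.5
    baseline: float = 100.0
    n_blobs: int = 12
    blob_amplitude: float = 30.0
    blob_sigma_px: float = 3.0
    illumination_amplitude: float = 20.0

    def __post_init__(self) -> None:
        for name in ("n_frames", "height", "width", "n_comets"):
            if getattr(self, name) < 0 or (name != "n_comets" and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")
        if self.psf_d_px <= 0 or self.peak_snr <= 0:
            raise ValueError("psf_d_px and peak_snr must be positive")


#: Ground-truth table columns written by the renderer.
TRUTH_COLUMNS = [
    "comet_id", "frame_index", "x_tip", "y_tip", "L_px", "speed_px_per_frame",
    "phi_rad", "amplitude", "in_bounds", "mature",
]


def _render_comet_frame(
    frame: np.ndarray,
    tip_xy: tuple[float, float],
    phi: float,
    length: float,
    amplitude: float,
    d: float,
    tail_cut: float = np.inf,
) -> None:
    """Add one comet to ``frame``: exponential tail density ⊗ Gaussian PSF.

    For a straight comet the convolution separates into an axial
    exponentially-modified-Gaussian profile and a lateral Gaussian, so the
    image is rendered exactly from the closed form used by the fitter.

    ``tail_cut`` truncates the density at that distance behind the tip: a
    freshly nucleated comet has only decorated the lattice it has grown
    since birth, so its tail ends sharply at ``speed × age``.  The truncated
    convolution is the difference of two shifted closed-form terms.
    """
    ny, nx = frame.shape
    x0, y0 = tip_xy
    reach = min(4.0 * length, tail_cut) + 5.0 * d
    xa = max(int(np.floor(x0 - reach)), 0)
    xb = min(int(np.ceil(x0 + reach)) + 1, nx)
    ya = max(int(np.floor(y0 - reach)), 0)
    yb = min(int(np.ceil(y0 + reach)) + 1, ny)
    if xa >= xb or ya >= yb:
        return
    ys, xs = np.mgrid[ya:yb, xa:xb]
    dx = xs - x0
    dy = ys - y0
    # axial coordinate u grows from the tip toward the tail (opposite motion)
    tail_dir = (-np.cos(phi), -np.sin(phi))
    u = dx * tail_dir[0] + dy * tail_dir[1]
    w = -dx * tail_dir[1] + dy * tail_dir[0]
    axial = exp_gauss(u, 0.0, length, d)
    if np.isfinite(tail_cut):
        axial = axial - np.exp(-tail_cut / length) * exp_gauss(
            u - tail_cut, 0.0, length, d
        )
    frame[ya:yb, xa:xb] += amplitude * axial * np.exp(-(w**2) / d**2)


def render_stack(
    params: RenderParams, seed: int | None = None, rng: np.random.Generator | None = None
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a synthetic comet movie and its ground truth.

    Each comet follows a straight path at a constant per-comet speed and
    direction, carries a constant decay length, and is alive for a random
    sub-interval of the movie.  The peak amplitude is normalised so the
    brightest pixel of a comet sits ``peak_snr`` background-noise standard
    deviations (read noise plus baseline shot noise) above the local
    background.  Comet tips leaving the ``margin_px`` band are flagged
    ``in_bounds=False`` in the ground truth.  Output frames are 16-bit
    quantised; everything is reproducible from the seed.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    ny, nx, nt = params.height, params.width, params.n_frames
    yy, xx = np.mgrid[0:ny, 0:nx]

    gx, gy = rng.uniform(-1, 1, 2)
    background = params.baseline + params.illumination_amplitude * (
        gx * (xx / max(nx - 1, 1) - 0.5) + gy * (yy / max(ny - 1, 1) - 0.5)
    )
    for _ in range(params.n_blobs):
        bx, by = rng.uniform(0, nx), rng.uniform(0, ny)
        amp = params.blob_amplitude * rng.uniform(0.5, 1.5)
        sig = params.blob_sigma_px * rng.uniform(0.6, 1.6)
        background += amp * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sig**2))

    comets = []
    for cid in range(params.n_comets):
        speed = max(float(rng.normal(params.speed_mean_px, params.speed_sd_px)), 0.3)
        length = float(
            np.clip(
                rng.normal(params.length_mean_px, params.length_sd_px),
                params.length_min_px,
                params.length_max_px,
            )
        )
        phi = float(rng.uniform(0, 2 * np.pi))
        # births before frame 0 give the movie a population of comets that
        # are already mature when recording starts, as in a real cell
        birth = int(
            rng.integers(-params.max_lifespan // 2, max(nt - params.min_lifespan, 1))
        )
        lifespan = int(rng.integers(params.min_lifespan, params.max_lifespan + 1))
        death = min(birth + lifespan, nt)
        m = min(params.margin_px, (min(nx, ny) - 2) / 2)  # small test frames
        x0 = float(rng.uniform(m, nx - 1 - m))
        y0 = float(rng.uniform(m, ny - 1 - m))
        # peak amplitude relative to the total background noise (read + shot)
        bg_noise_sd = float(
            np.sqrt(
                params.read_noise_sd**2 + params.shot_noise_gain * params.baseline
            )
        )
        peak = params.peak_snr * bg_noise_sd
        # normalise the density amplitude so the rendered peak equals `peak`
        axial_max = float(
            np.max(exp_gauss(np.linspace(-3 * params.psf_d_px, 3 * length, 400),
                             0.0, length, params.psf_d_px))
        )
        comets.append(
            dict(
                comet_id=cid, speed=speed, length=length, phi=phi, birth=birth,
                death=death, x0=x0, y0=y0, amplitude=peak / axial_max,
            )
        )

    frames = np.empty((nt, ny, nx), dtype=np.uint16)
    truth_rows = []
    for t in range(nt):
        clean = background.copy()
        for c in comets:
            if not (c["birth"] <= t < c["death"]):
                continue
            age = t - c["birth"]
            x_tip = c["x0"] + age * c["speed"] * np.cos(c["phi"])
            y_tip = c["y0"] + age * c["speed"] * np.sin(c["phi"])
            m = min(params.margin_px, (min(nx, ny) - 2) / 2)
            in_bounds = bool(m <= x_tip <= nx - 1 - m and m <= y_tip <= ny - 1 - m)
            tail_cut = age * c["speed"]  # decorated history since nucleation
            mature = bool(tail_cut >= 3.0 * c["length"])
            _render_comet_frame(
                clean, (x_tip, y_tip), c["phi"], c["length"], c["amplitude"],
                params.psf_d_px, tail_cut=tail_cut,
            )
            truth_rows.append(
                dict(
                    comet_id=c["comet_id"], frame_index=t, x_tip=x_tip, y_tip=y_tip,
                    L_px=c["length"], speed_px_per_frame=c["speed"], phi_rad=c["phi"],
                    amplitude=c["amplitude"], in_bounds=in_bounds, mature=mature,
                )
            )
        noise_sd = np.sqrt(
            params.read_noise_sd**2 + params.shot_noise_gain * np.maximum(clean, 0)
        )
        noisy = clean + rng.normal(0.0, 1.0, clean.shape) * noise_sd
        frames[t] = np.clip(np.round(noisy), 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    stack = ImageStack(
        frames,
        pixel_size_nm=params.pixel_size_nm,
        frame_interval_s=params.frame_interval_s,
    )
    logger.info(
        "rendered %d frame(s) %dx%d with %d comet(s)", nt, ny, nx, params.n_comets
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Ground-truth benchmarking
# ---------------------------------------------------------------------------

def match_tracks_to_truth(
    table: pd.DataFrame,
    truth: pd.DataFrame,
    max_dist_px: float = 4.0,
    min_shared: int = 4,
) -> dict[int, int]:
    """Assign recovered tracks to ground-truth comets.

    A (comet, track) pair is a candidate when they share at least
    ``min_shared`` frames on which the track's brightest pixel lies within
    ``max_dist_px`` of the true tip (median distance).  Candidates are
    assigned greedily by the number of shared frames, one track per comet.
    Returns ``{comet_id: track_id}``.
    """
    candidates = []
    for cid, g in truth.groupby("comet_id"):
        g = g.set_index("frame_index")
        for tid, tg in table.groupby("track_id"):
            shared = tg[tg["frame_index"].isin(g.index)]
            if len(shared) < min_shared:
                continue
            ref = g.loc[shared["frame_index"]]
            dist = np.hypot(
                shared["x_max"].to_numpy() - ref["x_tip"].to_numpy(),
                shared["y_max"].to_numpy() - ref["y_tip"].to_numpy(),
            )
            close = dist <= max_dist_px
            if close.sum() >= min_shared:
                candidates.append((int(close.sum()), int(cid), int(tid)))
    assignment: dict[int, int] = {}
    used_tracks: set[int] = set()
    for _, cid, tid in sorted(candidates, reverse=True):
        if cid in assignment or tid in used_tracks:
            continue
        assignment[cid] = tid
        used_tracks.add(tid)
    return assignment


def benchmark_metrics(
    table: pd.DataFrame,
    truth: pd.DataFrame,
    max_dist_px: float = 4.0,
    min_shared: int = 4,
) -> dict:
    """Score a pipeline result against the renderer's ground truth.

    Detection is evaluated over *analysable* comets — those with at least
    ``min_shared`` in-bounds, mature frames (a freshly nucleated comet has
    not yet built the tail the method measures).  Tip error and the relative
    decay-length error are evaluated on the accepted fits of assigned
    tracks, frame by frame.
    """
    analysable = truth[truth["in_bounds"] & truth["mature"]]
    eligible = [
        int(cid)
        for cid, g in analysable.groupby("comet_id")
        if len(g) >= min_shared
    ]
    assignment = match_tracks_to_truth(table, truth, max_dist_px, min_shared)
    detected = [cid for cid in eligible if cid in assignment]
    tip_err: list[float] = []
    l_rel_err: list[float] = []
    for cid in detected:
        tg = table[(table["track_id"] == assignment[cid]) & table["accepted"]]
        ref = analysable[analysable["comet_id"] == cid].set_index("frame_index")
        shared = tg[tg["frame_index"].isin(ref.index)]
        if not len(shared):
            continue
        sub = ref.loc[shared["frame_index"]]
        tip_err.extend(
            np.hypot(
                shared["x_end"].to_numpy() - sub["x_tip"].to_numpy(),
                shared["y_end"].to_numpy() - sub["y_tip"].to_numpy(),
            ).tolist()
        )
        l_rel_err.extend(
            (
                np.abs(shared["L_px"].to_numpy() - sub["L_px"].to_numpy())
                / sub["L_px"].to_numpy()
            ).tolist()
        )
    tip = np.asarray(tip_err)
    lre = np.asarray(l_rel_err)
    return {
        "n_eligible": len(eligible),
        "n_detected": len(detected),
        "detection_rate": len(detected) / len(eligible) if eligible else float("nan"),
        "n_fits": int(tip.size),
        "tip_rmse_px": float(np.sqrt(np.mean(tip**2))) if tip.size else float("nan"),
        "tip_median_px": float(np.median(tip)) if tip.size else float("nan"),
        "length_median_rel_err": float(np.median(lre)) if lre.size else float("nan"),
    }
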
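# ebcometkit

Tracking and subpixel analysis of **EB-3 comets** — the bright, tailed
intensity patterns that fluorescently tagged end-binding protein 3 forms at
growing microtubule plus ends in living cells.

Given a single-channel fluorescence time-lapse stack (16-bit TIFF, one
focal plane), the package:

1. **preprocesses** the movie so only moving objects stay positive
   (2D Fourier band-pass, 30-frame running-mean background subtraction with
   a self-background restoration step, thresholding);
2. **tracks** each comet as a 3D voxel "pillar" in (x, y, t) — seeded flood
   fill with a gradient cap, topological decoupling of comet collisions,
   and size/lifespan/tilt filters against noise and static particles;
3. **fits** every comet observation with the model

   I(x) = max( A · (e^(−(x−x_c)/L) · 1[x ≥ x_c]) ⊗ e^(−x²/d²) − T, 0 )

   — an exponential tail density convolved with the Gaussian PSF, offset by
   the preprocessing threshold — recovering the **true tip position**
   (shifted from the brightest pixel by |x_c|, typically ~300 nm), the
   **comet length** L (decay length of the tail, a proxy for the GTP-cap
   extent), and the PSF width d, all with subpixel precision;
4. computes **growth kinematics**: instantaneous and k-averaged tip
   velocities (35° axis gate against lateral fishtailing), Gaussian
   velocity-distribution fits, lagged length–velocity Pearson correlations,
   and the **EB-3 decoration time** DT = 1/a from the origin-constrained
   regression ϑ = a·L at the best-correlated averaging window;
5. provides a **stochastic 1D growth model** (Gaussian velocity steps,
   exponential decoration decay) and a **synthetic movie renderer** with
   exact ground truth, so every stage is testable without real data.

It is intended for cell biologists and image analysts quantifying
microtubule dynamics from +TIP movies, and for method development against
controlled synthetic data.

## Worked example: decoration time from the growth model

The model grows a microtubule by one Gaussian velocity step per frame and
decays each deposited region's EB signal as e^(−age/DT).  Recovering DT
from the simulated (length, velocity) series is the same computation the
pipeline runs on real tracks:

```python
from ebcometkit import simulate_track, estimate_decoration_time

sim = simulate_track(mu_v=1.0, sigma_v=1.0, dt=40.0, n_steps=10_000, seed=1)
burn, k = 120, 40                       # burn-in; averaging window = DT
theta_k = (sim.tip[burn + k:] - sim.tip[burn:-k]) / k
est = estimate_decoration_time(theta_k, sim.length[burn + k:], k)
print(f"slope a = {est.slope:.5f} / step")
print(f"decoration time = {est.dt:.2f} steps (true 40)")
print(f"correlation R = {est.r:.3f} over n = {est.n} frames")
```

prints

```
slope a = 0.02513 / step
decoration time = 39.79 steps (true 40)
correlation R = 0.889 over n = 9840 frames
```

The slope of velocity on length is 1/DT: the simulator's DT = 40 is
recovered to 0.5%.  With experimental units (L in nm, ϑ in nm/s) the same
estimator turns a slope of a = 0.51 s⁻¹ into DT = 1.96 s.  The correlation
R peaks when the averaging window k matches DT — that is the model
prediction that makes DT measurable in cells, where both L and ϑ fluctuate.

## Worked example: full pipeline on a synthetic movie

```python
from ebcometkit import analyze_stack, TrackerParams
from ebcometkit.growth_sim import RenderParams, render_stack, benchmark_metrics

stack, truth = render_stack(RenderParams(), seed=42)   # 20 comets, SNR ~10
table = analyze_stack(
    stack, tracker_params=TrackerParams(min_voxels=250, min_plane_px=25)
)
print(benchmark_metrics(table, truth))
```

prints (values rounded)

```
28 tracks, 685 observations, 497 accepted fits
{"n_eligible": 14, "n_detected": 14, "detection_rate": 1.0,
 "n_fits": 208, "tip_rmse_px": 0.223, "tip_median_px": 0.169,
 "length_median_rel_err": 0.077}
```

Every analysable ground-truth comet is recovered; accepted tips are
localised to 0.22 px RMS (≈ 23 nm at 103 nm pixels) and comet lengths to
7.7% median error.  `analyze_stack` returns one table row per comet
observation (tip, length, PSF width, threshold, quality flags) ready for
`write_tracks`/CSV.

## Command line

```bash
ebcometkit render  --n-comets 20 --frames 100 --size 256 --seed 1 \
                   --out synth.tif --truth truth.csv
ebcometkit preprocess synth.tif --out pre.tif --window 30
ebcometkit track pre.tif --min-voxels 250 --min-plane-px 25 --out tracks.csv
ebcometkit kinematics tracks.csv --k 1,2,3,4,5 --lags 0,1,2 --out kin.json
ebcometkit simulate --mu 1.0 --sigma 1.0 --dt 40 --steps 10000 --seed 1 \
                   --out sim.csv
```

Each subcommand accepts `--config conf.yaml` with a flat `pipeline:`
namespace mirroring the flags; explicit flags win.  See
[docs/methods.md](docs/methods.md) for the model, all parameters with
units and defaults, and known limitations.

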
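# rodspt

Single-particle-tracking analysis for rod-shaped bacteria.

Photoactivated-localization tracking of individual proteins in cells like
*E. coli* produces, per molecule, a short trajectory of (x, y) positions.
Three questions drive the downstream biology of enzymes such as RNase E,
whose membrane attachment controls how fast it finds and degrades mRNA:

1. **Where is the protein?** Localizations are mapped into normalized cell
   coordinates (xNorm across the cell width, yNorm along its length). The
   distribution of |xNorm| in the cylindrical part of the cell is fitted
   with a projection model — a membrane molecule projects with the arcsine
   density `1/(π√(r²−x²))`, a cytoplasmic one with the semicircle density
   `2√(r²−x²)/(πr²)` — mixed as `P(x) = m·P_memb(x) + (1−m)·P_cyto(x)`
   under defocus and localization-blur corrections. The mixture weight m,
   estimated by adaptive MCMC with uniform priors, is the
   membrane-binding percentage (MB%).
2. **How fast does it move?** Per-track time-averaged MSD fitted by
   `MSD = 4Dτ + b`, with `b = −4DΔt/3 + 4σ²` absorbing motion blur and
   localization error; ensemble mean ± SEM, and one/two-population Gaussian
   decompositions of the D histogram.
3. **Does it cluster?** Ripley's K/L/H per cell, referenced against
   complete spatial randomness simulated on the same cell's 3D membrane
   surface and projected to 2D, summarized as ∫(H_data − H_CSR) dr.

A fourth module fits windowed single-exponential mRNA decay rates
(co-transcriptional k_d1, post-transcriptional k_d2) and compares strains
with pooled t-tests. A synthetic-data generator produces cells, tracks,
and decay curves with known ground truth so that the whole pipeline is
testable by parameter recovery; see `docs/methods.md` for the model and
its assumptions.

## Worked example

Simulate an experiment with 93% membrane-bound molecules, normalize the
spots, and estimate MB%:

```python
import numpy as np
import rodspt

cfg = rodspt.SimConfig(n_cells=200, spots_per_cell=500, m_true=0.93, seed=7)
cells = rodspt.simulate_cells(cfg)
tracks, truth = rodspt.simulate_tracks(cells, cfg)

norm, qc = rodspt.normalize_movie(tracks, cells)
hist = rodspt.build_xnorm_histogram(norm, n_boot=100, seed=0)
R_um = np.mean([c.R for c in cells]) * cfg.pixel_size
fit = rodspt.fit_mb(hist, R_um, rodspt.FitSettings(seed=0))
print(f"MB% = {fit.mb_percent:.1f} [{fit.ci[0]:.1f}, {fit.ci[1]:.1f}]")
```

```
MB% = 90.3 [88.0, 92.9]
```

The point estimate is the posterior mean of 100·m and the bracket is the
central 95% credible interval. It sits a couple of points below the
simulation truth (93): the tracking step's minimum track length and
gap-free linking interact with defocus detection in a way the static
projection model cannot represent, a known systematic of this kind of
pipeline discussed in `docs/methods.md`. Diffusion analysis on the same
tracks:

```python
ts = rodspt.tracks_from_dataframe(tracks, pixel_size=cfg.pixel_size, dt=cfg.dt)
mean, sem, Ds = rodspt.ensemble_D(ts, min_length=12)
print(f"D = {mean:.4f} ± {sem:.4f} µm²/s over {len(Ds)} tracks")
```

```
D = 0.0177 ± 0.0005 µm²/s over 2364 tracks
```

The ensemble mean lands near the membrane input (0.0184 µm²/s): lateral
motion on the curved membrane surface is compressed by the 2D projection
(apparent D ≈ 0.75·D for the 93% membrane-bound majority), while the ~5×
faster cytoplasmic minority pulls the mean back up; `docs/methods.md`
discusses this geometric factor.

The same stages are exposed as a CLI:
`rodspt simulate`, `rodspt normalize`, `rodspt fitmb`, `rodspt diffusion`,
`rodspt ripley`, `rodspt decay`, `rodspt mbmodel` (see `--help`).

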
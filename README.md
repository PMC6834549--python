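# dmdnet

Time-resolved extraction of recurring spatial modes — resting-state-network
(RSN)-like patterns — from high-dimensional timeseries, using exact dynamic
mode decomposition (DMD) in short sliding windows followed by unsupervised
hierarchical clustering.

Classical RSN analyses (spatial ICA, seed correlation) assume networks are
static over a 5–15 minute scan. `dmdnet` is for researchers who want the
networks *and* their dynamics from a single scan: which networks exist, when
each is active at a resolution of seconds, how often pairs co-occur, and how
activity transfers between them.

## Method

For a data matrix whose columns are snapshots x⃗ₖ ∈ ℝⁿ (n locations —
grayordinates, voxels, pixels — at frame k), DMD seeks the best-fit linear
propagator **A** with

```
X′ ≈ A X,    X = [x⃗₁ … x⃗ₘ₋₁],   X′ = [x⃗₂ … x⃗ₘ]
```

via the rank-r SVD X = UΣV*: the reduced operator Ã = Uᵣ* X′ Vᵣ Σᵣ⁻¹ is
rescaled to Â = Σ⁻¹² Ã Σ¹² (weighting modes by their presence in the data),
eigendecomposed ÂŴ = ŴΛ, and lifted to spatial modes Φ = X′VΣ⁻¹²Ŵ. Each
mode φ⃗ⱼ carries an eigenvalue λⱼ giving its growth rate and oscillation
frequency in physical units,

```
γⱼ = Re(ln λⱼ)/Δt,    fⱼ = Im(ln λⱼ)/(2πΔt).
```

Applied in sliding windows (defaults T = 32 frames, step dT = 4, rank
r = 8), this yields a pool of (spatial map, frequency, time) triples.
Mode magnitudes are averaged on a coarse spatial bin grid, modes without
coherent large-scale structure are discarded by a continuity heuristic,
and the survivors are thresholded into binary masks and agglomeratively
clustered (average linkage on 1 − Pearson mask correlation). Flat clusters
cut at a cophenetic-distance threshold are the discovered networks; their
activity raster over windows gives occupancy matrices O₍ᵢⱼ₎, lagged
transfer matrices T₍ᵢⱼ₎, and per-timepoint activation traces.

A built-in synthetic benchmark — two overlapping images pulsing at 0.045
and 0.071 cycles/step, switched by a three-state Markov chain in uniform
noise — provides full ground truth for validating every stage, and a
windowed spatial-ICA baseline supports head-to-head method comparison.

## Worked example

`examples/` contains one narrative script per capability. Discovering the
benchmark's two hidden patterns without supervision
(`examples/03_cluster_modes.py`):

```
1718 modes -> 676 after continuity filter
34 flat clusters; the large ones:
  cluster 7: 344 modes, freq 0.048 +/- 0.142 Hz, best reference chicken (r = 0.91)
  cluster 4: 260 modes, freq 0.010 +/- 0.054 Hz, best reference cat (r = 1.00)
  ...
```

The two large clusters are the cat and the chicken: their averages
correlate at 1.00 and 0.91 with the true images that generated the data.
Recovering the switching dynamics (`examples/04_dynamics_recovery.py`):

```
cluster purity vs ground-truth window states: 1.000
configured transition matrix (per timestep):
  cat      0.980  0.004  0.016
  chicken  0.004  0.980  0.016
  both     0.010  0.010  0.980
estimated from reconstructed traces:
  cat      0.969  0.000  0.031
  chicken  0.000  0.996  0.004
  both     0.005  0.003  0.992
```

Self-transitions and transitions through the "both" state are recovered
closely; rapid direct cat↔chicken swaps are undercounted because window
smoothing relabels them as "both" — an intrinsic resolution limit of any
windowed method, and exactly the failure mode the benchmark is designed
to expose. `examples/05_method_comparison.py` shows the windowed-DMD mode
set reconstructing both references better than windowed ICA (0.9997 vs
0.9612 for the cat; 0.9993 vs 0.9833 for the chicken, seed 0).

A thin CLI mirrors the pipeline stages
(`dmdnet simulate|dmd|cluster|dynamics|benchmark|report`).

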
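# Methods

`dfcnet` implements a complete dynamic functional-connectivity (dFC)
analysis of a seed-grown brain network — here, the language network of
early vs. late bilinguals — together with a synthetic-cohort generator that
makes every stage testable without any imaging data.

## Pipeline model

**Node identification (voxel stage).** Two 3-mm-radius spherical seeds
(Broca's area, MNI −53/20/15; Wernicke's area, −51/−51/30) are correlated
voxelwise with the whole brain (Pearson r between the sphere-mean series and
each voxel). Correlation maps are Fisher z-transformed (z = atanh r) and a
one-sample t-test across subjects (df = n−1) is thresholded voxelwise at
α = 0.01 with Bonferroni correction over the gray-matter mask (probability
≥ 0.9). Family-wise error here is controlled by Bonferroni rather than
random-field theory: it is conservative, exactly reproducible and
dependency-free. Supra-threshold voxels are split into connected components
(26-neighborhood by default; 6/18 configurable) and components with ≥ 50
voxels become clusters; each cluster contributes one network node — a 3-mm
sphere at its peak-|t| voxel (ties broken toward the smallest linear voxel
index). Negative-tail clusters are extracted and reported separately but do
not enter the network. Users with a known node set (e.g., the packaged
17-node table) skip this stage entirely.

**Sliding-window dFC.** Node series are segmented into rectangular windows
of 35 TRs (105 s at TR = 3 s) sliding by 1 TR; 170 retained volumes give
exactly 136 windows. Per window, Pearson correlations with window-local
means/SDs fill an edge vector of length N(N−1)/2 in upper-triangle
row-major order. No taper and no window-level detrending are applied — the
windowed statistic is plain Pearson r, clustered as raw r (a Fisher-z
option exists). Row w of the dynamic matrix concatenates all S subjects'
edge vectors for window w (subject-major), giving a W × (S·E) matrix: one
clustering sample per *window index*, shared across subjects. This layout
presumes temporally aligned state dynamics across subjects; the generator
plants exactly that (a shared latent sequence).

**State identification.** Euclidean k-means (Lloyd, 50 random-row restarts,
best inertia; deterministic given the seed) is run for k = 2..12; the k
with the highest mean silhouette, s(i) = (b−a)/max(a,b), is selected, ties
toward smaller k, and the full silhouette-vs-k curve is always emitted.
The published selection rule ("significantly higher than the previous k")
is not operational, so argmax is used. For reporting, states are renumbered
by descending window count so labels are stable across seeds. Per subject
and state, dFC is summarized as the arithmetic mean of raw windowed r over
the windows carrying that state's label.

**Topology.** Each window's edge vector becomes a weighted graph: an edge
survives if its two-tailed correlation p-value (t = r·√((L−2)/(1−r²)),
df = L−2 = 33) passes Bonferroni over the E = 136 edges *and* r > 0
(path-length/efficiency definitions need non-negative weights, and no
negative-edge handling is reported for this analysis); surviving weights
are the raw r. Four weighted metrics follow the Rubinov–Sporns
formulations: clustering coefficient Cw (Onnela geometric-mean triangles on
max-normalized weights, binary-degree denominator, nodes with degree < 2
contribute 0), shortest paths with length 1/weight (vectorized
Floyd–Warshall, Dijkstra-checked in tests), characteristic path length Lw
(mean over finite ordered pairs, with the infinite-pair fraction reported
rather than dropping disconnected windows), global efficiency Eglob (mean
1/d, 1/∞ = 0), and local efficiency Eloc (mean over nodes of the
neighbor-induced subgraph's global efficiency, original weights). Windowed
metrics are averaged per state per subject; windows with undefined Lw are
excluded from the Lw mean with a logged count. Table-style state summaries
can alternatively be computed from state-mean networks; the per-window
average is the default.

**Group inference.** Group differences are tested with a two-sample
permutation test on |mean(A) − mean(B)| (the two-tailed statistic), 5,000
label permutations preserving group sizes. When the number of distinct
assignments C(n, n_a) is at most n_perm the null is enumerated exactly
(p = #{perm ≥ obs}/total, observed included); otherwise Monte-Carlo
sampling with the +1 convention keeps p > 0. Family-wise error across a
family — all E edges within one state, or the K states within one metric —
uses single-step max-statistic correction on the same relabelings, each
member standardized by its permutation SD; both raw and adjusted p are
always reported, since the published per-edge p-values appear to be
uncorrected permutation p. Effect sizes are pooled-SD Cohen's d,
d = (m_A − m_B)/s_p with s_p² = ((n_A−1)s_A² + (n_B−1)s_B²)/(n_A+n_B−2).
Some published d values do not reproduce from the printed rounded
means/SDs under this formula; the four that do (1.46, 2.14, 1.53, 1.33)
are the worked examples the tests assert.

**Preprocessing (optional).** The only signal conditioning implemented:
discard of the first 10 volumes, per-column linear detrend, zero-phase
Butterworth band-pass 0.01–0.08 Hz (order 4, applied forward–backward so no
phase shift; band edges must lie below Nyquist = 1/(2·TR)), and OLS
nuisance regression with an intercept (rank-deficient confound matrices are
projected with a logged warning). Global-signal regression is deliberately
not performed. The order band-pass ↔ nuisance is configurable because the
original toolchain does not pin it down; the default is discard → detrend →
band-pass → nuisance.

## Synthetic cohort generator

The generator emulates the study conditions: n = 10 vs 11 subjects, 170 TRs
at TR = 3 s, 17 nodes (packaged names), K = 4 latent states, measurement
noise SD 0.5, and planted group effects on four designated edges in states
1–3.

**States.** Each state is a modular correlation matrix: a state-specific
random partition of the nodes into 3 communities, within-module r = 0.7
(`base_strength`), cross-module background r = base_strength/14 ≈ 0.05,
projected to SPD by eigenvalue flooring at 0.05 and diagonal rescaling.
Modular blocks were chosen over random-spectrum matrices deliberately:
random-spectrum states differ by only ~0.1 r per edge, below the 35-TR
windowed-correlation sampling noise (≈ (1−r²)/√34 ≈ 0.17), which makes the
planted state count unrecoverable in principle; modular states differ by
~0.6 on a third of the edges and are recoverable, while also resembling the
block-structured connectivity patterns real dFC states show.

**Latent sequence.** One label sequence shared by all subjects (matching
the one-sample-per-window clustering layout). The default is a *balanced*
sequence: one contiguous segment per state (~42–43 TRs, longer than the
35-TR window) in seed-shuffled order. A geometric-dwell Markov chain
(self-transition 1 − 1/mean_dwell) is also provided, but over a 170-TR scan
a mean dwell of 50 produces ~3 segments and routinely fails to visit all
four states, so it is not the default. With the balanced sequence ~55% of
windows lie wholly inside one state; the rest straddle a transition.

**Subjects and noise.** At each TR the node vector is drawn from a
zero-mean multivariate normal with the active state's correlation matrix,
plus independent N(0, 0.5²) white noise per node. The noise attenuates
every observed correlation by 1/(1 + noise_sd²) = 0.8;
`StateModel.observed_correlations` exposes the attenuated matrices, which
is what recovery tests compare against. No hemodynamic convolution,
physiological noise, motion or spatial structure is simulated — passing
tests therefore demonstrate the *statistical* machinery, not robustness to
fMRI artifacts.

**Group effects.** Group A receives +delta on each planted edge in its
planted state; positive definiteness is re-verified, with deltas halved up
to 10 times before erroring. In the default cohort the two endpoint nodes
of each planted edge are first detached from their modules in that state
(rows drop to the background r), so a large delta remains SPD-safe and the
lower group sits near zero — the pattern the reported group tables show.
The default latent delta is 0.60: after noise attenuation (×0.8) and
mixed-window dilution (×≈0.7) it surfaces as an observed state-mean
difference near 0.3 (the reported magnitude), with pipeline-measured
Cohen's d mostly 1.5–4 and ≥ 90% family-wise-corrected detection across
seeds. All randomness flows from a single integer seed through a
counter-based child-seed scheme, so any stage reproduces in isolation.

**Volume phantom.** For the voxel stage, a small 3-mm-grid 4-D phantom
plants one blob of ~60 voxels per node, coupled to its seed sphere's
unit-variance latent signal with a quadratic taper (100% at the blob
center, 70% at its edge) so the t peak falls at the planted center;
background voxels are white noise and the gray-matter map is 0.98 inside a
one-voxel border. This is a synthetic stand-in for normalized fMRI, not a
simulation of it.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1]; |r| = 1 is clipped to 1 − 1e−7
  before atanh (logged). Zero-variance nodes/voxels yield r = 0 (counted).
- One-sample t with zero SD: t = 0 if the mean is 0, else signed infinity
  (treated as supra-threshold).
- k-means ties and empty clusters follow scikit-learn's handling;
  silhouette assigns 0 to singleton clusters.
- Edgeless windows: Cw = Eloc = Eglob = 0, Lw undefined (NaN, reported with
  infinite-pair fraction 1).
- Permutation p-values are never 0 (+1 smoothing or exact enumeration).
- All output tables are written atomically and carry the resolved
  configuration hash in a header line.

## Problem sizes used in validation

The test suite and the acceptance script run the full study-size problem
(21 subjects × 170 TRs × 17 nodes; 136 × 2856 dynamic matrix; k = 2..12
with 50 restarts; 5,000 permutations). State-count recovery is evaluated
over 5 seeds and group-difference recovery over 20 seeds; permutation
calibration uses 400 null simulations and graph-metric oracles cover all
4–5-node binary topologies (×3 weight draws) plus 100 random 6–7-node
graphs.

## Known limitations

- The one-row-per-window clustering layout assumes synchronized state
  dynamics across subjects; with asynchronous real data the conventional
  subject-stacked layout (available in the API by clustering per-subject
  blocks) is more appropriate.
- Bonferroni voxel FWE is stricter than the random-field correction used by
  standard neuroimaging software; with few subjects (low df) it is very
  conservative.
- The edgewise "significant dFC" threshold interprets an ambiguous
  published rule as per-window Bonferroni over edges; it is configurable.
- Silhouette magnitudes on synthetic data (~0.43 at k = 4) depend on the
  planted separation and are not calibrated to any empirical dataset.
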
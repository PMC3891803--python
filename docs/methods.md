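# Methods

This note documents the models, conventions and numerical choices behind
`eegnets`, in the order the pipeline runs.

## Preprocessing

Inputs are channels × samples matrices in microvolts with a sampling rate
(600 Hz default), assumed already referenced (e.g. to linked mastoids); no
re-referencing is applied. The band-pass is a zero-phase (forward–backward)
4th-order Butterworth, 0.5–50 Hz by default. Zero-phase filtering is chosen
because the connectivity measure is a zero-lag correlation: any phase
distortion would leak signal across the lag axis. Artifact rejection drops
any trial whose per-sample absolute amplitude exceeds a threshold on any
channel (default 100 µV, configurable); it is idempotent and its count is
logged. The pre-analysis spectrum check computes a Hann-tapered periodogram
per trial (averaged over channels) and compares conditions bin-by-bin with
the same rank-sum test used downstream; a flat p-value profile justifies
analysing the broadband signal.

Epoch lengths in seconds are converted to samples by half-up rounding
(1.3 s × 600 Hz = 780 exactly); epochs are half-open, 0-based sample
ranges, so contiguous onsets partition a recording exactly.

## Windowed rank correlation

Windows are 333 ms long and advance by 43.3 ms; in samples (half-up
rounding at 600 Hz) that is 200 and 26, giving 23 windows per 780-sample
epoch, labelled by their start time relative to stimulus onset. Windows
never extend past the epoch end. Spearman ρ is computed as the Pearson
correlation of average-rank (midrank) transformed samples, zero-lag only.
A channel that is constant within a window has undefined correlation; its
pairs are recorded as missing (NaN) with a warning and can never become
links. A lag-correlation diagnostic (ρ between x(t) and y(t+lag), positive
lag meaning y advanced) is provided to verify the zero-lag peak that
motivates the zero-lag restriction.

## Network construction

Default criterion: fixed number of links — exactly the K pairs with the
largest signed correlation are linked. Signed (not absolute) ranking is the
default, matching the "highest correlated links" reading; an absolute-value
mode is available behind a flag since negative correlations admit either
convention. Ties at the K-th value are broken by montage (lexicographic
pair) order, making construction deterministic across platforms. Because
only the order of correlations matters, the construction is invariant under
any strictly increasing transform of ρ, and link sets are nested in K.
The alternative fixed-threshold criterion (link iff ρ > r) is provided for
the stability contrast: under time-varying global coupling its link count
fluctuates strongly across windows while fixed-K variance is identically
zero, which is the reason fixed-K is the default.

## Graph measures

Implemented in-house on the adjacency matrix:

- geodesic distances and counts via adjacency powers — a walk of length
  d(i,j) cannot revisit a node, so (A^d)[i,j] counts geodesics exactly;
  float64 arithmetic keeps counts exact below 2^53;
- betweenness via the pair decomposition n_jk(i) = n_ji·n_ik whenever
  d(j,i) + d(i,k) = d(j,k), summed over **unordered** pairs and left
  **unnormalized** ("flow" through the node). This convention is pinned
  testably by the conservation law Σ_i B_i = Σ_connected pairs (d − 1);
  toolkits using ordered pairs report exactly double these values;
- clustering C_i = (neighbour links)/(k_i(k_i−1)/2), defined as 0 for
  k_i < 2 and kept in the average over all N nodes;
- average path length L over unordered **connected** pairs only, always
  reported together with the connected-pair fraction. Sparse 20-node
  networks (K ≈ 20–30) are frequently disconnected; averaging over
  connected pairs keeps L finite and interpretable.

Correctness is established two ways: exhaustive agreement with a
brute-force simple-path-enumeration oracle on every graph-atlas graph with
≤ 6 nodes, and agreement with networkx's Brandes implementation (an
algorithmically independent route) on hundreds of random 20-node graphs.

The Erdős–Rényi baseline draws G(N, K) graphs with exactly K uniform links
and reports the distribution of L, ⟨C⟩ and ⟨B⟩; the small-world ratio is
(C/C_ER)/(L/L_ER).

## Statistics

Per (electrode, metric, window, K), the per-trial metric values of the two
conditions are compared with a two-sided Wilcoxon rank-sum test, trials
being the unit of comparison (a paired per-subject variant is out of
scope). For pooled n ≤ 12 the p-value is exact — full enumeration of rank
assignments with midranks — otherwise a tie-corrected,
continuity-corrected normal approximation (vectorized across the whole
test grid). Degenerate strata with all values identical get p = 1.

The dual significance criterion: Bonferroni over the 20 electrodes
(p < 0.05/20 = 0.0025) and robustness over link density (the same
electrode/metric/window must pass at ≥ 3 values of K; default grid
{20, 30, 40, 50, 60, 70, 80}, configurable since density choice is
arbitrary). No correction is applied across windows or densities — the
family-wise guarantee is over electrodes within one (metric, window)
family, and window spans should be read descriptively. This is a
deliberate fidelity-over-stringency choice and a known statistical caveat.

Direction calls use the sample medians; exact ties give "none".
`baseline_check` reruns the identical pipeline on pre-stimulus epochs,
where a correct setup should produce no robust findings. The
first-neighbour analysis tallies, per condition, how often each electrode
is directly linked to a target across a network collection.

## Synthetic generator

The generator emulates the recording protocol: 20-electrode 10–20 montage
(standard 2-D projection, head radius 1), 600 Hz, 1.3 s epochs,
2 blocks × 2 conditions × 25 repetitions (100 trials) with randomized
within-block order and 5 s inter-stimulus intervals.

Signal model per trial, all components band-limited 0.5–50 Hz Gaussian
noise:

1. spatial field: channel covariance exp(−d/λ) (exponential kernel,
   positive definite in the plane), λ = 1.6 head radii by default;
2. common component: one shared signal with electrode gain
   a·exp(−r/σ_c), r the distance from the vertex (Cz); defaults a = 2.8,
   σ_c = 1.0. This emulates the broad volume-conducted/shared-reference
   activity that dominates scalp EEG and, topologically, makes central
   electrodes hubs;
3. optional global-coupling modulation: a common signal with a sinusoidal
   envelope (default off), reproducing alternating global
   synchronization/desynchronization;
4. optional condition effect: a shared latent added to a target electrode
   set in one condition, raising the set's mutual correlations. Default:
   {F7, Fp1, T3, C3, P3, O1} in condition "SM" with amplitude 3.0 relative
   to unit channel noise — sized so the planted links reliably out-rank
   the strong common background, giving a stable positive control.

Since the pipeline consumes only rank correlations, Gaussianity of the
marginals is innocuous. Scale is set to ~20 µV so artifact thresholds are
meaningful.

Calibration. λ and the common-component parameters were fixed once so that
null fixed-K networks occupy the realistic global operating point:
time-averaged L ≈ 2.25 at K = 30 and ≈ 1.85 at K = 70, with a small-world
ratio ≈ 2 at K = 50. Two facts constrain the model class: the ranking of
pairwise correlations — hence the fixed-K topology — is invariant to λ in
the noise-free limit (a pure spatial kernel always yields the same
lattice-like graph, L(30) ≈ 2.8), while noise-dominated ranking yields
Erdős–Rényi values (L(30) ≈ 2.45). Neither reaches L(30) ≈ 2.25, which
requires genuine hubs; the vertex-weighted common component supplies them.
The defaults are recorded as module constants and not tuned per analysis.

What the generator does **not** emulate: 1/f spectra, rhythmic
oscillations (alpha/beta peaks), evoked transients phase-locked to
stimulus onset, non-stationarity across the epoch, ocular/muscle
artifacts, and inter-subject variability. Passing tests therefore
demonstrate the pipeline's statistical calibration and sensitivity under a
plausible spatial-correlation structure, not performance on real EEG.

## Problem sizes and determinism

Statistical simulations in the test suite use reduced problem sizes chosen
to keep the suite fast while leaving the tested quantities well estimated:
shortened epochs (0.45 s → 3 windows) and 8–20 trials per condition for the
null-calibration and power runs (200 and 25 seeds respectively); the
reference path-length quantities use the full 1.3 s epochs and 25 trials.
All randomness flows through seeded `numpy` generators; the effect latent
uses a separate stream so injecting an effect never perturbs the unaffected
condition's trials. Pipeline outputs embed the seed and a configuration
hash, and identical configurations reproduce byte-identical TSVs.

## Known limitations

- Zero-lag rank correlation does not exclude volume conduction; the design
  assumes it affects both conditions equally.
- L over connected pairs changes meaning as disconnection varies with K;
  always read it with the reported connected-pair fraction.
- The multi-density robustness criterion reuses the same data across K, so
  its passes are strongly dependent across the grid; it is a stability
  screen, not an independent replication.
- Exact rank-sum enumeration is limited to pooled n ≤ 12; beyond that the
  normal approximation is used even though small-sample discreteness can
  make it slightly conservative near extreme tails.
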
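# Methods

This note documents the models, parameters and numerical choices behind
`plvnet`, in the spirit of the methods documentation of packages such as
msprime or statsmodels: what each stage computes, what the synthetic
generator does and does not emulate, and where genuinely open design
choices were resolved.

## Study design being replicated

The pipeline replicates a resting-state EEG network analysis of a
2-condition (without music / with music) x 2-time (pre / post exhaustive
exercise) within-subject crossover with 34 subjects.  Source-space signals
from 78 regions -- grouped into the sensorimotor (SMN), dorsal attention
(DAN), salience (SN), central executive (CEN) and default mode (DMN)
networks -- are analyzed in three frequency bands: theta 4-8 Hz, alpha
8-14 Hz, beta 14-30 Hz, at a 256 Hz sampling rate with 6 s epochs.  No
recordings are distributed with the original study, so every downstream
stage is exercised against the synthetic generator described below.

## Connectivity: phase locking value

For each band the signals are zero-phase bandpass filtered (4th-order
Butterworth, forward-backward via `sosfiltfilt`; the effective squared
magnitude response gives >= 20 dB stopband attenuation one band away), cut
into non-overlapping 6 s segments (trailing remainder discarded), and the
instantaneous phase extracted per segment with the analytic signal
(Hilbert transform).  PLV of a pair is the modulus of the time-averaged
unit phasor of the phase difference; it is computed per segment and
averaged across segments, which is robust to slow nonstationarity.  The
first and last 5% of each segment's samples are excluded from the average
to suppress filter/Hilbert edge transients.  The diagonal of a
connectivity matrix is stored as 1 by convention and always excluded from
statistics.

Numerical notes: PLV is clipped into [0, 1] against rounding; the
per-segment matrix is computed as `|Z Z^H| / T` with `Z = exp(i*phase)`.
Uncoupled signals do not give PLV 0 but a finite-sample floor of order
`sqrt(pi / (4 T_eff))`, where `T_eff` is the number of effectively
independent phase samples per segment (set by the band's width); at 6 s
segments the floor is roughly 0.15 for alpha and 0.09 for beta.

## Synthetic generator

Each region's signal is a narrowband oscillation
`x_i(t) = Re[c_i(t) exp(i 2 pi f_c t)]` at the band's center frequency
`f_c`, whose complex envelope `c_i` is a lowpass-filtered complex Gaussian
process (cutoff = half the band width, so the signal occupies the band).
Envelopes are correlated across regions by a matrix factor, so any
positive-semidefinite pattern of pairwise envelope coherences `rho_ij` is
realizable -- a uniform background, block structure, planted cliques, or
mixtures of these.  Because pairwise marginals of a jointly Gaussian
process depend only on `rho_ij`, the empirical PLV of a pair is a monotone
function of its coherence alone.

An earlier candidate model -- each region's phase a circular mixture of
one shared random-walk phase and an independent phase -- was rejected:
its pairwise PLV factorizes as a rank-1 product of per-region locking
strengths, which cannot jointly realize a uniform background *plus* a
planted clique (the exact configuration needed for power studies).  The
Gaussian-envelope model realizes all such patterns while keeping a
monotone scalar coupling-to-PLV map per pair.

**Calibration.**  The coupling -> PLV map has no convenient closed form
once filtering, segmentation and edge-trimming are involved, so it is
calibrated against the package's own pipeline: `calibrate_coupling`
bisects the coherence (to 0.01 PLV tolerance) against simulated
two-region runs, and matrix targets are inverted elementwise through a
cached 13-point monotone calibration curve.  Targets at or below the
finite-sample floor map to coherence 0; `calibrate_coupling` refuses
targets strictly below the floor and reports the floor.  A target matrix
whose implied coherence matrix is not positive semidefinite is rejected
with an error naming an offending region triple (a 3x3 principal
submatrix with negative determinant).

**Group designs.**  `simulate_group` produces one connectivity matrix per
subject x condition x time x band through the real signal -> PLV path.
Defaults are the study's conditions: 34 subjects, 2x2 crossover, 78
regions, 300 s at 256 Hz, uniform base coupling 0.3 (a mid-range resting
PLV comfortably above every band's floor).  Subject heterogeneity is a
truncated-normal (sd 0.03, cut at 3 sd) *global* coupling offset per
subject and band, shared across the four cells: independent per-edge
jitter of a 78-region coupling matrix pushes its coherence matrix off the
positive-semidefinite cone (the perturbation's extreme eigenvalues grow
like sd * sqrt(N)), so heterogeneity is modeled as a shift of the
subject's overall coupling level; cell-to-cell variability then comes
from finite-segment PLV estimation noise.  Planted effects add a PLV
delta to a chosen edge set (or globally) in one condition x time x band
cell; results are clipped to [0, 1] and clipping is logged.

`simulate_group_plv` is a matrix-level surrogate for simulation studies
that need hundreds of group datasets (type-I calibration, power curves):
it draws PLV matrices directly as base + subject offset + independent
Gaussian cell noise (default sd 0.03, standing in for estimation noise) +
planted deltas.  It shares the design semantics but not the signal path.

**What the generator does not emulate:** volume conduction / source
leakage, 1/f background spectra, amplitude dynamics, artifacts, or
spatially structured covariance beyond the coupling targets.  Passing
tests therefore demonstrate correctness of the analysis pipeline under a
controlled coupling model, not robustness to the confounds of real EEG.

## Graph metrics

Weighted PLV matrices are binarized over the sparsity grid 0.06..0.50 in
steps of 0.02 (23 levels), retaining exactly
`round(s * N(N-1)/2)` strongest off-diagonal edges (round half away from
zero; ties broken deterministically by weight descending, then row, then
column index).  Per level the package computes the clustering coefficient
`Cp` (nodes with degree < 2 contribute 0, avoiding 0/0), characteristic
path length `Lp` (mean over *connected* pairs; global efficiency is the
standard remedy for disconnected graphs and is reported alongside),
global efficiency `Eglob` (mean inverse shortest path, 0 for disconnected
pairs), local efficiency `Eloc` (mean global efficiency of neighborhood
subgraphs; nodes with < 2 neighbors contribute 0), and the normalized
indices `gamma = Cp / Crandom`, `lambda = Lp / Lrandom`,
`sigma = gamma / lambda` against degree-preserving Maslov-Sneppen
surrogates (default 1000; 10 x |E| attempted double-edge swaps each, the
degree sequence asserted after every surrogate).  `sigma > 1` marks
small-world organization; the metrics are always computed and sigma
reported, with no gating on its value.

Per-condition scalars are aggregated over the 23 levels as the
trapezoidal area under the metric-vs-sparsity curve divided by the grid
width -- a grid-averaged value on the metric's own scale.  For very small
or very sparse graphs, where neither the graph nor its surrogates carry
triangles, gamma and sigma are undefined and recorded as NaN; aggregates
integrate over the defined levels only.

## Network-Based Statistic

Paired comparisons between two cells use edgewise paired t-tests;
suprathreshold edges (default edge p < 0.001, two-sided with components
formed separately per sign) are grouped into connected components and
each component's *edge count* is tested against a permutation null of
maximal component sizes.  Exchangeability for the paired design is
within-subject sign flipping of the per-subject difference matrices
(default 2000 permutations); when the full sign-flip group has at most
`n_perm` elements it is enumerated exactly.  Corrected p per component is
`(1 + #{null >= size}) / (1 + n_perm)` under random flips (the +1 avoids
zero p-values) or the exact proportion under enumeration.  Edges whose
differences are a nonzero constant have undefined t and are flagged and
excluded; identically zero differences give t = 0.

## Network strengths

The total average PLV is the mean over all region pairs excluding
self-connections; within-network strength averages pairs inside one
network and between-network strength averages pairs straddling two, over
the 10 unordered network pairs.  The total average is exactly the
pair-count-weighted mean of the 5 + 10 components.  Min-max normalization
is applied per band and measure across all subject x condition x time
values, so the four compared conditions share one scale (the pooling
scope is a package choice; alternatives such as per-subject scaling would
destroy between-condition comparability).  Hemisphere is not a partition
dimension.

The shipped 78-region partition file is a synthetic stand-in with
realistic per-network counts (SMN 14, DAN 15, SN 12, CEN 13, DMN 24);
deriving true memberships from the public Schaefer 100-parcel / Yeo
7-network lookup is left to the user, and any two-column TSV with the
five canonical labels is accepted.

## Inference layer

Graph-metric aggregates are analyzed with a 2x2 fully within-subject
repeated-measures ANOVA: sums of squares are decomposed with
subject-by-effect error strata, `F = MS_effect / MS_(effect x subject)`
with df (1, n-1), and partial eta squared
`SS_effect / (SS_effect + SS_error)`.  Sphericity corrections are moot
for 1-df within-subject effects and are not applied.  Rank-scale strength
measures are compared across the four conditions with the Friedman test
(tie-corrected via midranks; exact permutation p by dynamic programming
over per-subject rank permutations for n <= 8, k <= 4, tie-free data) and
Dunn's pairwise mean-rank comparisons, `z = (Rbar_u - Rbar_v) /
sqrt(k(k+1)/(6n))`, two-sided normal reference, Bonferroni multiplier =
number of pairs (6 for four conditions).  The paired t-test follows the
standard formula with df = n-1; identical samples return t = 0, p = 1,
while a nonzero constant difference (zero variance) raises.

## Problem sizes used in tests and the acceptance script

Simulation studies are scaled to desk size while keeping the study's
structural parameters: signal-level end-to-end runs use 12 subjects, 78
regions, 120 s at 128 Hz; NBS calibration uses 200 (tests) or 100
(script) matrix-level null datasets at n = 34 subjects and 78 regions
with 500 permutations; power studies use 25 repetitions of a 6-node
clique with +0.25 PLV; random-network baselines use 100 surrogates.
These sizes are the package's own choices for routine verification; the
pipeline defaults remain the full study parameters (34 subjects, 300 s,
256 Hz, 1000 surrogates, 2000 permutations).

## Known limitations

* PLV is sensitive to zero-lag leakage; leakage-robust metrics (wPLI,
  imaginary coherence) are out of scope by design.
* The generator's coupling targets are stationary within a recording;
  dynamic connectivity is not modeled.
* `Lp` on disconnected graphs averages over connected pairs only, which
  can make sparse disconnected graphs look artificially short-pathed;
  `Eglob` is the preferred integration index at low sparsity.
* The exact Friedman permutation distribution is limited to small n and
  k and tie-free rows; otherwise the chi-square reference is used.
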
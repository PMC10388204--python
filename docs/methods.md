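# Methods

`fretscope` analyzes the conformational dynamics of two-domain proteins
— concretely, the SNARE protein Ykt6, whose longin domain and SNARE
core pack into a closed autoinhibited conformation or release into an
open one — from three kinds of measurement: immobilized-molecule smFRET
movies, isothermal titration calorimetry, and constant-velocity pulling
trajectories.  Everything below is the package's own account of what it
computes and why; no number stated here is asserted anywhere the tests
or `scripts/acceptance.py` do not themselves compute it.

## 1. The smFRET generative model

A molecule carries a donor and an acceptor dye; the FRET efficiency
`E = A / (A + γ·D)` reports the inter-dye distance, so high `E` means a
closed conformation.  The synthetic world is a hidden Markov model over
`K` conformational states sampled once per camera frame:

* **Frames.** 100 ms exposure (`frame_dt = 0.1 s`); a per-frame
  discrete-time Markov chain rather than a continuous-time one, matching
  the binning of the downstream analysis.
* **States.** Two presets encode the measured constructs: the yeast
  Ykt6ΔC construct with three states at mean efficiencies
  0.20 / 0.42 / 0.68 occupying 50.7 / 39.7 / 10.2 % of frames
  (normalized — the reported percentages sum to 100.6), and the rat construct
  with five states at 0.20 / 0.35 / 0.48 / 0.64 / 0.79 occupying
  31.4 / 19.8 / 19.3 / 16.2 / 13.3 %.
* **Kinetics.** Transition matrices are birth-death chains (only
  neighbouring states exchange) built by detailed balance from the
  stationary occupancies; forward rates are 0.10 and 0.04 per frame for
  the yeast construct (dwells of roughly 0.5–1 s, E1↔E2 exchange
  dominant, direct E1↔E3 jumps absent — the observed transition-density
  structure) and 0.08 per frame uniformly for the rat construct.  These
  rates are the generator's stated world; nothing downstream was tuned
  against them.
* **Noise.** Two knobs: per-state efficiency spread `sd_k = 0.05`
  (conformational breadth within a state) and additive camera noise at
  5% of the 1000-count summed intensity per channel.  Propagated to the
  efficiency axis these combine to an effective per-frame spread of
  about 0.06.
* **Photobleaching.** A single extinction time drawn Exponential(20 s)
  truncates both channels to camera noise; the acquisition window is
  50 s (the longest observed trajectories).  One cut, not stepwise
  two-dye bleaching: traces are only used up to dye death.

What the generator does **not** emulate: spectral crosstalk, direct
acceptor excitation, triplet blinking, ALEX sorting, stage drift.  A
green test therefore establishes that the analysis recovers the stated
HMM world at realistic noise — not that it is robust to every artifact
of real recordings.

## 2. Trace extraction from dual-view movies

Synthetic movies render each molecule as a pixel-integrated isotropic
Gaussian PSF (σ = 1–1.5 px) in two views related by a fixed translation,
with Poisson shot noise (integer pixel coordinates are pixel centres).
Extraction mirrors a minimal single-molecule pipeline: detection on the
average of the first ten frames (brightest, pre-bleach) as local maxima
of the smoothed image above a robust (median/MAD) threshold — robust
statistics, because bright spots otherwise inflate their own detection
threshold; sub-pixel refinement by background-subtracted centre of mass
re-centred once; greedy nearest-neighbour channel pairing under the
known offset with ambiguous matches dropped; circular-aperture
photometry (radius 3 px, annulus 5–7 px) with the annulus median as
local background.  The end-to-end closure test demands channel-intensity
correlation > 0.99 between extracted and generating traces at SNR ≥ 10
(peak pixel over background noise).

## 3. Photobleach detection and efficiency computation

The bleach step is the single changepoint of the summed intensity that
maximizes the two-segment Gaussian likelihood (exact O(n) scan over
splits); it is accepted only if the shift is downward and its magnitude
exceeds `z` (default 4) pooled within-segment standard deviations.
Efficiencies use `E = (A − bg_A) / [(A − bg_A) + γ(D − bg_D)]` with
γ = 1 by default (apparent efficiencies, as reported) and per-channel
backgrounds estimated from the post-bleach median when a bleach frame
exists — the natural dark reference.  Values outside [0, 1] are kept:
clamping before HMM fitting biases emission means; display stages may
clamp axes instead.  Quality control keeps traces with ≥ `min_frames`
pre-bleach frames (30 for exploratory analysis; 100 in the standard
benchmark, since state-count selection needs traces long enough to
visit the full state space).

## 4. Per-trace HMM inference

Each trace's efficiency series is fitted independently with a K-state
Gaussian-emission HMM, in two routes:

* **Maximum likelihood** (`baum_welch`): scaled forward–backward EM,
  variance floor 1e-8, convergence at log-likelihood increment < 1e-6,
  best of 10 restarts.  The log-likelihood is asserted non-decreasing at
  every iteration of every fit.
* **Variational Bayes** (`vb_em`): conjugate priors — Dirichlet(1) over
  the initial distribution, Dirichlet(α) over each transition row,
  Normal-Gamma (m₀ = series mean, κ₀ = 0.25, a₀ = 2.5, b₀ = 0.01) over
  each emission.  The E-step uses geometric-mean ("tilde") parameters;
  the evidence lower bound (ELBO) is the scaled-recursion log normalizer
  minus the Kullback–Leibler terms and is asserted non-decreasing.  The
  reported model is the posterior mean (variances = b/a).

Two inference choices differ from the obvious defaults and matter:

* **Sparse transition prior, α = 0.05.**  Single-molecule state
  networks are sparse — transitions connect neighbouring conformations.
  A uniform α = 1 prior charges every fitted state for the transitions
  it never makes (each unused Dirichlet category costs roughly one nat
  per observed transition row at these trace lengths), which on
  ~200-frame traces biases evidence-based state-count selection low: on
  the five-state benchmark the mean-evidence gap between K = 4 and
  K = 5 is −6.7 ± 0.5 nats under α = 1 and the five-state model can
  never win, at any optimization effort.  Under α = 0.05 the gap is
  positive and K = 5 is selected.
* **Sampled restarts.**  The first restart initializes means at
  quantiles refined by 1-D k-means; further restarts draw K random data
  points (sorted, small jitter).  K-means-style starts systematically
  merge close, unequally occupied states at K ≥ 4 (a 5000-frame
  five-state trace fitted at K = 5 from such starts found four
  effective states and a *lower* ELBO than K = 6); sampled starts reach
  the true optimum.

**State-count selection** fits every trace at each K in 1..6 and
averages the per-trace ELBO; the selected K maximizes the mean, ties
going to the smaller K.  A `bic` criterion (mean −BIC/2 from ML fits) is
available.  Selection uses the same 10 restarts as single fits —
under-optimizing large-K fits would bias the evidence curve downward
exactly where its optima are hardest to find.

**Idealization** is the Viterbi path with each frame's efficiency
replaced by its state's fitted mean; dynamic-programming ties break
toward the lower state index (asserted).  Models are always reported
with strictly increasing means, so state relabeling cannot change any
downstream result.

## 5. Global states, TDP, populations

Change points of the idealized trajectories contribute
(E_before, E_after) pairs to the transition density plot (50×50 bins
over [0, 1]).  Global state centres are computed from the pooled
idealized values by **exact** weighted 1-D k-means — in one dimension
the optimal clustering is contiguous in sorted order and is found by
dynamic programming.  Lloyd-style iteration is deliberately avoided: on
clusters of very unequal mass (half the frames sit in the open state)
quantile-initialized Lloyd splits the dominant cluster and merges the
rare one.  Thresholds are midpoints between adjacent centres — a
deterministic, reproducible stand-in for reading boundaries off the TDP
by eye; for well-separated states the two coincide.

Threshold assignment of every frame yields time-weighted occupancies
(populations are "all time points", not dwell-weighted), per-state dwell
times (run lengths × 0.1 s), a transition-count matrix, and per-movie
occupancy tables.  Most-probable efficiencies are the means of single
Gaussians fitted to each state's raw-efficiency histogram (peak bin as
fallback; states under 50 frames flagged low-confidence).  Group
comparisons are per-state Welch two-tailed t tests on per-movie
fractions, with no multiplicity correction (flagged in the output, since
that matches how such panels are usually reported).

## 6. ITC one-site model and fitting

The single-site (Wiseman) isotherm with MicroCal displaced-volume
bookkeeping: after cumulative injected volume ΔV, cell concentrations
scale by (1 − ΔV/2V₀); the bound concentration solves
B = ½[(N·M + X + K_D) − √((N·M + X + K_D)² − 4·N·M·X)]; cumulative heat
Q = B·ΔH·V₀; the per-injection heat applies the half-displaced-volume
correction and a constant heat-of-dilution offset, normalized per mole
of injectant.  N multiplies the site concentration *inside* the
quadratic — with N outside (Q = N·B·ΔH·V₀ over the N-free quadratic),
N and ΔH appear only as a product and the four-parameter fit is
ill-posed.  The offset is fitted free rather than subtracted from a
blank, since no blank titration is modelled.

Fitting is bounded least squares multi-started over log-spaced K_D in
[10⁻⁸, 10⁻²] M; curvature-based uncertainties are advisory.  Flags: a
fit pinned at the K_D upper bound or with a negligible binding signal is
"no detectable binding" (the behaviour of the non-binding constructs);
c = N·M₀/K_D < 1 marks K_D as poorly constrained.

Two protocol facts worth knowing.  The reported schedule (40 μl aliquots
into a 280 μl cell) would overflow the cell within a few injections; the
default simulated protocol is therefore 19 × 2 μl at the reported
concentrations (0.5 mM ligand into 0.05 mM protein), with the literal
schedule still selectable.  And at those concentrations c ≈ 1.3 and the
titration reaches only molar ratio 1.36 — fine for noiseless round
trips (which are exact), but K_D is ill-determined under noise there:
the Cramér–Rao bound on the four-parameter fit allows no better than
~30–45% 1σ relative error at 5%-of-maximum heat noise for any
reasonable one-site design we scanned.  The robustness test therefore
checks statistical *efficiency* (median error within 1.5× the CRLB
prediction at 5% noise, on a saturating c ≈ 10 design) and absolute
accuracy (±15%) at 1% noise, where it is attainable.  Round-trip truth
values fix N = 1, ΔH = −5 kcal/mol by convention; only K_D was reported
for the real interactions.

## 7. The 1-D pulling toy

A single overdamped Langevin coordinate x (Å) on a sum-of-Gaussians
landscape — a 12 kcal/mol bound well at the origin, a barrier (default
6 kcal/mol) at 3 Å, open flat region beyond — is pulled by the moving
harmonic potential U = ½k[vt − (x − x₀)]², F = k[vt − (x − x₀)], with
k = 5 (kcal/mol)/Å², v = 1.5 Å/ns.  Euler–Maruyama integration
(dt = 2 ps, γ = 0.5 kcal·mol⁻¹·ns·Å⁻², k_BT = 0.5925 kcal/mol at 298 K)
records the force identity exactly at every step.  γ is chosen so the
post-rupture drag plateau γv ≈ 0.75 kcal/mol/Å sits far below typical
rupture forces (~9), reproducing the near-zero post-rupture force
plateau of the all-atom protocol this toy stands in for; dt is validated
against both the reference drift per step and the stiffness-stability
bound.

The **turning point** (rupture) is formalized as: on the
moving-average-smoothed force (window 201 steps), the last local
maximum that is at least half the global maximum, after which the force
drops below 20% of that maximum and stays there for ≥ 500 steps —
"stays" meaning the sustained window's mean is below threshold and at
least 80% of its frames are; a window-mean criterion, because a
finite-temperature force trace always shows brief thermal excursions
(force fluctuation σ = √(k_BT·k) ≈ 1.7 kcal/mol/Å here).  The
half-of-global-maximum condition encodes that a rupture is the release
of the *largest* accumulated force; without it, small post-rupture
thermal bumps technically satisfy the drop rule and, being later, would
win.  Peaks below 10× the smoothed noise scale are rejected, so pure
noise and monotone ramps yield nothing.

**Distance steps** use binary-segmentation mean-shift changepoints with
penalty 10·σ²·ln n (σ robust, from median absolute differences); the
**synchrony report** flags each named distance series as synchronous if
any changepoint falls within a tolerance (default 50 frames) of the
turning index, always reporting the signed lag of the nearest
changepoint — an early step shows as a negative lag, the two-stage
pattern in which one inter-residue contact breaks before the main
rupture.  These operators take plain arrays, so externally computed
force/distance series (e.g. real steered-MD output saved as TSV) are
analyzed identically.

Checked limits: flat landscape at T = 0 gives steady force exactly γv;
with a stiff spring and slow pulling at T → 0 the peak force converges
to the landscape's maximum resisting slope within 5%; mean turning time
increases with barrier height and mean peak force with pulling velocity
(50 seeded replicates per condition).

## 8. Determinism and seeds

All randomness flows through `numpy.random.default_rng` seeded
explicitly; batch generators and the pipeline derive per-trace seeds
from (seed, stage, index) tuples, so identical inputs and seed are
bit-identical — the CLI `run` subcommand writes a manifest with SHA-256
hashes of all outputs and asserts nothing else touched the output
directory, and two identical runs produce identical manifests.

## 9. Known limitations

* The evidence gap between four and five states on the rat benchmark is
  small (order one nat per hundred traces at ~220-frame traces); at
  materially higher noise or shorter traces the mean-evidence rule
  saturates at K = 4.  This mirrors the known tendency of variational
  evidence to underestimate state counts on limited data.
* The rat benchmark's recovered open-state occupancy runs ~2–3
  percentage points high: with 0.13–0.16 efficiency gaps and ~0.06
  spread, threshold assignment misclassifies a few percent of frames of
  each neighbouring state, and the open state, being the most populated,
  gains the most.
* The ITC module fits integrated per-injection heats only — no raw
  power thermograms, no multi-site models.
* The pulling toy is a 1-D caricature: no force field, no solvent, no
  geometry.  Only its *analysis operators* are meant to transfer to real
  steered-MD output.
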
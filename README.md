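# fretscope

Single-molecule FRET conformational-state analysis, with companions for
isothermal titration calorimetry and steered-pulling trajectories.

`fretscope` is built around the question the Ykt6 SNARE system poses:
a protein whose longin domain and SNARE core pack into a **closed**
(autoinhibited) conformation or release into an **open** one, with the
balance differing between species, shifting on ligand binding, and
reporting directly in smFRET as distinct efficiency states.  The package
provides the full measurement-to-numbers chain for that kind of study,
on synthetic data with stated ground truth (no raw data are required):

* **Trace simulation and extraction** — dual-channel intensity traces
  from a K-state hidden Markov world (100 ms frames, Gaussian efficiency
  spread, camera noise, exponential photobleaching at ~20 s), plus
  dual-view TIFF movie synthesis, spot detection, channel pairing, and
  aperture photometry.
* **HMM idealization and state counting** — per-trace Gaussian-emission
  HMMs fitted by maximum likelihood (Baum–Welch) and variational Bayes;
  the number of conformational states selected by the mean per-trace
  evidence lower bound (ELBO) over K = 1..6, in the spirit of vbFRET.
* **State analysis** — transition density plots (TDP), global state
  centers by exact 1-D k-means, midpoint thresholds, time-weighted state
  populations, most-probable efficiencies, dwell times, and Welch
  t-test group comparisons.
* **ITC** — the one-site (Wiseman) binding isotherm with MicroCal
  volume bookkeeping, simulation, and multi-start least-squares fitting
  of (N, K_D, ΔH, offset) with no-binding and low-c flags.
* **Pulling toy** — a 1-D overdamped Langevin particle pulled by the
  moving harmonic potential U = ½k[vt − (x − x₀)]² (k = 5 (kcal/mol)/Å²,
  v = 1.5 Å/ns), with rupture (turning-point) detection, distance-step
  changepoints, and synchrony reports that also accept externally
  computed force/distance series.

The model at the core: per frame t a hidden state z_t follows a Markov
chain with row-stochastic transition matrix A; the observed efficiency
is E_t | z_t = k ~ Normal(μ_k, σ_k²).  Variational Bayes places
Dirichlet priors on the initial distribution and transition rows
(sparse, α = 0.05, on rows) and Normal-Gamma priors on (μ_k, λ_k); the
ELBO approximates the trace's log marginal likelihood under a K-state
model, and the K maximizing its per-trace mean is the reported state
count.  See `docs/methods.md` for every model, default, and numerical
choice, with rationale.

## Worked example

Reproduce the three-state benchmark end to end (yeast-construct ground
truth: efficiencies 0.20/0.42/0.68, populations 50.7/39.7/10.2%):

```python
from fretscope.pipeline import run_benchmark

res = run_benchmark("yeast", K=None, seed=0)   # K=None => select K by evidence
print("K* =", res.K)
print("occupancies (%):", (100 * res.populations.fractions).round(2))
print("modal efficiencies:", res.modal_efficiencies.round(4))
```

prints

```
K* = 3
occupancies (%): [51.47 38.54  9.99]
modal efficiencies: [0.2008 0.4216 0.6801]
```

i.e. the evidence curve peaks at three states, and the recovered
time-weighted occupancies and Gaussian-fit modal efficiencies of the
open (E1), intermediate (E2) and closed (E3) states land within ~1
percentage point and ~0.002 efficiency units of the generating truth.
The same call with `"rat"` runs the five-state benchmark.

The CLI wraps the same library:

```
fretscope simulate-traces --model yeast --n-traces 200 --n-frames 500 --seed 0 --out traces.tsv
fretscope idealize --traces traces.tsv --k-range 1:6 --seed 1 --out results.json
fretscope itc-sim --kd-um 38.5 --out iso.csv
fretscope itc-fit --isotherm iso.csv
fretscope smd-sim --seed 2 --out pull.tsv
fretscope smd-analyze --force pull.tsv
```

`fretscope itc-fit` on the noiseless 38.5 μM isotherm, for instance,
reports `"K_D_uM": 38.5` to machine precision with
`"no_binding": false`.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic benchmarks from scratch and recomputes, by
running the package itself: the yeast-benchmark occupancies of the most
open and most closed states and the open state's modal efficiency
(pipeline at K = 3); the rat-benchmark open-state occupancy (K = 5);
and the dissociation constants refitted from noiseless simulated
titrations generated at 38.5 μM and 33.3 μM.  It writes one JSON object
mapping each quantity to `{"value": ..., "n": ...}` (percent,
efficiency units, and micromolar respectively).  Runtime is a few
minutes on one CPU; everything is seeded from `--seed`.
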
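# popcode

Population-coding analysis of simulated human tactile afferents.

`popcode` asks how populations of the three mechanoreceptive afferent classes
of the glabrous skin — slowly adapting type 1 (SA1), rapidly adapting (RA)
and Pacinian (PC) fibers — jointly encode the features of a probe indented
into the skin, and how that code depends on innervation density, on the mix
of classes, and on the spatial versus temporal structure of the population
spike trains. It is aimed at computational neuroscientists studying
peripheral tactile coding and, more generally, at anyone who needs a tested
reference implementation of decoder-based population information analysis
for spiking data.

## What it computes

1. **Stimuli.** A circular probe follows a ramp-and-hold indentation with a
   superimposed sinusoid. Four features vary factorially: probe size
   (1–4 mm), ramp amplitude (0.3–1.2 mm), ramp-up time (10–50 ms) and
   vibration frequency (0–200 Hz) — 800 conditions, 40 trials each at full
   scale, with per-trial motor noise (probe location ±0.3 mm, sine amplitude
   ±0.05 mm, ramp amplitude ±0.1 mm).
2. **Spiking.** Afferents of each class terminate along a line radiating
   from the contact site (1 cm for SA1/RA, 5 cm for PC; densities 1–140
   afferents/cm²). Each afferent's drive is a spatially attenuated, rectified
   mix of indentation depth and its band-filtered derivatives; spikes come
   from a leaky integrate-and-fire mechanism with per-spike threshold noise.
3. **Decomposition.** Spike trains are binned at 2 ms and stacked into
   `R ∈ R^(M×TN)`; spatiotemporal non-negative matrix factorization
   `R = HW + residuals` expresses each trial as non-negative activation
   coefficients `H` of non-negative modules `W`. The module count is the
   smallest K reaching a class-level explained-variance threshold obtained
   from the per-density variance saturation levels (<1% gain tolerance),
   selected on a held-out 25% of trials.
4. **Decoding and information.** A multinomial logistic decoder
   (`f(s,i) = β_s·H_i`, L2-regularized, C chosen by stratified 5-fold CV)
   predicts each stimulus feature from the activation coefficients; the
   plugin mutual information of its test-set confusion matrix,

   `I(S;Ŝ) = Σ p(s,ŝ) log₂ [p(s,ŝ) / (p(s)p(ŝ))]`,

   is a data-robust lower bound on the information the population carries,
   reported in bits and normalized by the stimulus entropy `H(S) = log₂ Sₙ`.
5. **Complementarity.** For a reference class against the remaining classes,
   `I_comp = I(all) − I(others)` and `I_red = I(ref) + I(others) − I(all)`;
   the two sum exactly to `I(ref)`.
6. **Perturbations.** Spatial structure is destroyed by permuting afferent
   identity per trial; temporal structure by jittering each spike uniformly
   within ±2/5/10 ms. Perturbed responses are projected onto the *original*
   modules and decoded by the *frozen* decoder, yielding "space-coding
   removed" and "time-coding removed" information.

## Worked example

```python
from popcode import (DEFAULT_CLASS_PARAMS, PopulationCodingModel,
                     place_population, simulate_dataset, build_design,
                     MotorNoiseSpec)

design = build_design(sizes_mm=(1, 4), amplitudes_mm=(0.6,),
                      ramp_times_s=(0.03,), frequencies_hz=(0, 120))
pops = [(place_population(c, d, seed=0), DEFAULT_CLASS_PARAMS[c])
        for c, d in (("SA1", 10), ("RA", 10), ("PC", 2))]
datasets = simulate_dataset(design, pops, n_trials=12,
                            noise=MotorNoiseSpec(), master_seed=0)
model = PopulationCodingModel(datasets, n_instantiations=2, k_max=8)
results = model.fit(master_seed=0)
print(results.summary())
```

prints (abridged):

```
Population coding information estimates
  instantiations: 2   bin width: 2 ms   master seed: 0

feature    classes      densities              perturb              I (bits)       SD   I/H(S)
frequency  PC           PC:2                   none                   1.0000   0.0000   1.0000
frequency  RA           RA:10                  none                   0.0174   0.0174   0.0174
frequency  SA1          SA1:10                 none                   0.5122   0.0188   0.5122
size       PC           PC:2                   none                   0.0000   0.0000   0.0000
size       RA           RA:10                  none                   0.0036   0.0036   0.0036
size       SA1          SA1:10                 none                   0.5270   0.2312   0.5270

NMF modules per class: SA1: K=4, RA: K=8, PC: K=5
```

Each row is the decoder-confusion mutual information (mean ± SD across NMF
instantiations) one class set carries about one feature. Even at this toy
scale the class-specialization signature the analysis is built to expose is
visible: two Pacinian afferents discriminate 0 vs 120 Hz vibration
perfectly (1 bit of a 1-bit stimulus set) yet are at chance for probe size,
while SA1 afferents carry most of the size information. At desk or full
scale (below) the estimates tighten and the orderings sharpen.

The same chain scales up through the experiment runner:

```sh
popcode all --profile desk --seed 1 --outdir runs/desk   # ~6 min, 1 CPU
popcode report --outdir runs/desk
```

which writes `info.csv` (long-format information estimates),
`complementarity.csv`, `summary.json` and report figures (information vs
density, complementarity fractions, perturbation losses). The `paper`
profile runs the full 800-condition, 16-density, 50-instantiation grid and
is long-running; `micro` is a seconds-scale smoke profile.

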
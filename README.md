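# hsp90kit

Analysis toolkit for the energetic coupling between ATP hydrolysis and
conformational dynamics in the Hsp90 chaperone dimer.

Hsp90 hydrolyses ATP slowly (~0.5 ADP released per enzyme per minute) even
though the chemical step itself need not be slow: the barrier of the
hydrolysis reaction depends on the conformation of an N-terminal-domain
ion-pair switch (Arg-32/Glu-33 in yeast numbering), and the observed
turnover is set by the interplay between that chemistry and the kinetics of
forming the catalytically competent closed dimer. `hsp90kit` implements the
computational layer needed to analyse this coupling end to end, for anyone
combining free-energy simulation output with solution biophysics on
chaperone-like cyclic enzymes:

* **`hsp90kit.umbrella`** — free-energy profiles along the hydrolysis
  reaction coordinate R = r₄ − r₃ + r₂ − r₁ (bond-forming/breaking
  distances of the concerted proton transfer and phosphate cleavage) from
  umbrella-sampling windows, via a self-consistent WHAM solver with
  Monte-Carlo bootstrap errors and barrier-height reports.
* **`hsp90kit.eyring`** — transition-state theory,
  k = κ(k_BT/h)·e^(−ΔG‡/RT), in both directions, with timescale labels.
* **`hsp90kit.ionpair`** — ion-pair distance traces from multi-model PDB or
  CSV, open/closed classification at the 5 Å convention, dwell times,
  interdomain salt-bridge counts, the coulombic 1/d barrier-tuning fit and
  a screened point-charge pKa-shift estimate.
* **`hsp90kit.cycle`** — a five-state stochastic model of the chaperone
  cycle (Gillespie SSA + master-equation steady state) and the decoupling
  perturbation analysis: how much slower must dimer closing become to mask
  an f-fold faster catalytic step?
* **`hsp90kit.fits`** — the standard assay fits: mono-exponential FRET
  kinetics, NADH-coupled ADP-release slopes, Michaelis–Menten, quadratic
  ligand-depletion anisotropy binding, ¹H/¹⁵N chemical-shift perturbations,
  heteronuclear NOE ratios, SAXS Guinier R_g and P(r) from coordinates.
* **`hsp90kit.synthetic`** — seeded generators for every input above, with
  stored ground truth, so the whole pipeline is testable offline.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Reconstruct a free-energy profile from the built-in double-well benchmark
(37 windows, k = 100 kcal mol⁻¹ Å⁻², 1000 samples each), report the
barrier, and convert barriers to rates:

```python
from hsp90kit.synthetic import default_umbrella_benchmark
from hsp90kit.umbrella import wham_solve, bootstrap_profile, barrier_height

windows, truth = default_umbrella_benchmark(seed=1)
profile = wham_solve(windows)                      # tol 1e-5 kcal/mol
boot = bootstrap_profile(windows, n_trials=10, seed=1)
rep = barrier_height(profile, reactant_range=(-2.5, -1.5), ts_range=(-0.8, 0.3))
```

This prints (via an f-string over the results):

```
barrier = 10.00 kcal/mol at R = -0.15 (reactant R = -2.05)
median bootstrap stderr = 0.112 kcal/mol
```

— the generator's 10 kcal mol⁻¹ barrier recovered at the histogram
resolution, with ~0.1 kcal mol⁻¹ statistical error at these sample sizes.

The same conversion from the command line, for the barrier computed for
the open-ion-pair (R32A-like) active site:

```sh
$ hsp90kit rates --barrier 18 --temp 310
{
  "barrier_kcal_mol": 18.0,
  "temperature_K": 310.0,
  "kappa": 1.0,
  "rate_per_s": 1.3196249741382224,
  "timescale": "seconds"
}
```

An 18 kcal mol⁻¹ barrier is a seconds-timescale reaction (1.3 s⁻¹) —
faster than the observed per-minute turnover — while the closed-ion-pair
barrier of 25 kcal mol⁻¹ maps to hours. The cycle model resolves the
apparent paradox of a faster chemical step leaving turnover unchanged:

```sh
$ hsp90kit cycle scan --f-cat 100
{
  "f_cat": 100.0,
  "required_f_close": 1.990000000000733
}
```

a 100-fold catalytic acceleration is absorbed by merely a two-fold slower
closing step when closing and catalysis contribute comparably to the cycle
time.

Other subcommands: `hsp90kit wham` (window files → profile TSV),
`hsp90kit ionpair` (trace CSV → occupancies/dwells), `hsp90kit cycle
simulate|steady`, `hsp90kit fit monoexp|adp|mm|guinier`, `hsp90kit synth
<generator>`, `hsp90kit pr` (PDB → P(r), R_g).

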
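# Methods

`hsp90kit` models the coupling between the chemistry of ATP hydrolysis in
the Hsp90 chaperone and the conformational dynamics of its dimer cycle.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

## Reaction coordinate and umbrella sampling

ATP hydrolysis in the Hsp90 N-terminal domain proceeds by a semi-concerted
proton transfer and phosphate cleavage. The scalar reaction coordinate is
the standard linear combination of the bond-forming and bond-breaking
distances,

    R = r4 − r3 + r2 − r1   (Å),

with r1/r2 the proton-transfer forming/breaking distances and r3/r4 the
phosphate-bond forming/breaking distances. R runs from about −2.9 Å
(reactants) to 2.6 Å (products); the default histogram covers exactly this
range at 0.1 Å resolution (55 bins), both configurable.

Umbrella windows restrain R harmonically. Published force constants for
this kind of restraint (typically 100 or 500 kcal mol⁻¹ Å⁻²) do not always
state whether the conventional ½ prefactor is included, so each window file
declares `bias_convention: half_k` (U = ½k(R−R₀)², the default) or
`full_k`. Mixing conventions silently would scale every bias by two, which
is unrecoverable downstream; declaring it per file makes the choice
auditable.

### WHAM

The free-energy profile is estimated with the weighted histogram analysis
method. With window i contributing Nᵢ samples and bias Boltzmann factors
c₍ᵢⱼ₎ = exp(−βUᵢ(Rⱼ)) at bin centers Rⱼ, the solver iterates

    pⱼ ∝ nⱼ / Σᵢ Nᵢ exp(βfᵢ) c₍ᵢⱼ₎,   exp(−βfᵢ) = Σⱼ c₍ᵢⱼ₎ pⱼ,

until the largest change in any window constant fᵢ is below the tolerance
(default 1e-5 kcal mol⁻¹, the conventional tight criterion for these
profiles). Window constants are gauge-fixed to f₀ = 0 during iteration;
the final profile is anchored so the minimum over populated bins is zero.
Zero-count bins carry NaN free energy and are excluded from anchoring and
barrier searches. Windows whose histograms share no populated bin cannot be
stitched into one profile; the solver detects the disconnected groups with
a union–find pass and raises rather than returning a profile with an
arbitrary relative offset.

Error bars come from a Monte-Carlo bootstrap: each trial resamples every
window's samples with replacement, re-solves, re-anchors, and the per-bin
standard deviation over trials (default 10, the conventional quick
estimate) is reported. A trial whose solve fails is recorded in the result
rather than silently dropped.

No statistical-inefficiency correction is applied to the input samples:
the intended use case is short (tens of ps) restrained QM/MM trajectories
where block-averaging estimates of the correlation time are unreliable
anyway. A per-window `decorrelate_stride` subsampling hook is provided;
with correlated inputs the bootstrap errors are underestimates, which is a
known limitation of this estimator family.

Barrier heights are max-over-TS-range minus min-over-reactant-range on
populated bins; ties resolve to the lowest-R bin, and a transition-state
maximum below the reactant minimum reports a zero barrier.

### Synthetic umbrella benchmark

`default_umbrella_benchmark` samples a quartic double well (minima at
R = −2.0 and 1.5 Å, 10 kcal mol⁻¹ barrier at −0.25 Å) by inverse-CDF
sampling of the exact biased Boltzmann density on a 4001-point grid —
i.e., the population an infinitely long, perfectly equilibrated restrained
run would visit. Windows sit every 0.15 Å at k = 100 kcal mol⁻¹ Å⁻² with
1000 samples each (37 windows), chosen so adjacent spring widths
(σ = √(RT/k) ≈ 0.08 Å) overlap across the 0.1 Å bins. At these sizes the
profile is recovered to better than 0.1 kcal mol⁻¹ RMS and the benchmark
bound is 0.2. What this shows: the estimator and its implementation are
correct on data satisfying their own assumptions. What it does not show:
robustness to the correlated, possibly unequilibrated sampling of real
QM/MM trajectories, which no desk benchmark can certify.

## Eyring rates

Rate constants follow transition-state theory,
k = κ(k_BT/h)exp(−ΔG‡/RT), with κ = 1 by default and CODATA-2018 constants
pinned in one table shared by all modules (R = 1.987204×10⁻³ kcal mol⁻¹
K⁻¹; the kcal is the thermochemical 4184 J exactly). At 310 K the
prefactor is 6.46×10¹² s⁻¹; an 18 kcal mol⁻¹ barrier gives 1.3 s⁻¹ and a
25 kcal mol⁻¹ barrier 1.5×10⁻⁵ s⁻¹ (a lifetime of ~18 h). Timescale labels
classify the lifetime 1/k against clock boundaries (60 s, 3600 s, 86400 s),
matching the colloquial seconds/minutes/hours/days usage. No tunnelling or
variational corrections are attempted.

## Ion-pair switch analysis

The Arg-32/Glu-33 ion pair (yeast Hsp90 numbering; a user-editable
species-mapping is implicit in the free-form atom labels) is tracked by the
side-chain Cζ–Cδ distance. Frames classify as closed at d ≤ 5 Å and open
above; the tie goes to closed, and no hysteresis or minimum-dwell filter is
applied by default because the underlying convention is a hard threshold.
Dwell times are contiguous-run lengths with the first and last runs flagged
as censored and excluded from means. Note an estimator property quantified
by the telegraph benchmark: with Gaussian observation noise (default
σ = 0.4 Å around means of 4 and 8 Å), noise crossings of the 5 Å threshold
split long dwells at a rate of ~0.6% per closed frame, biasing
classified-trace dwell means low by roughly 20% at 50 ns true dwells.
Recovery tests therefore define dwell truth on the generator's state
sequence; users analysing real traces should treat threshold-classified
dwell means as lower bounds or apply the optional stride/duration
arguments.

Salt bridges between residue groups count once per residue pair when any
opposite-charge heavy-atom pair (Arg NH1/NH2/NE, Lys NZ vs Asp OD1/OD2,
Glu OE1/OE2, plus C-terminal OXT) is within 4.0 Å — a common convention;
the cutoff is an argument. N-terminal amine charges are not auto-detected
because a plain PDB does not mark chain termini reliably.

The electrostatic tuning of the hydrolysis barrier by the ion-pair distance
d is summarized by the two-parameter model ΔG‡(d) = a + b/d, fitted by
least squares in 1/d: a is the fully-open asymptotic barrier and b the
coulombic coupling. The pKa shift of the glutamate on losing its arginine
partner is estimated with a screened point-charge model,

    ΔpKa = C·|q₁q₂| / (ε·d·ln10·RT),  C = 332.06 kcal Å mol⁻¹ e⁻²,

with ε = 4 (protein-like continuum). Unit charges at 5.5 Å and 310 K give
≈ 10.6 units — the right scale for a buried carboxylate losing a
guanidinium partner. This deliberately replaces full Poisson–Boltzmann
titration with the leading monopole term; it carries no conformational
averaging and should be read as an order-of-magnitude estimate.

## Chaperone-cycle kinetic model

The cycle is a single-enzyme continuous-time Markov chain over five states
(open → closed1-ATP-inactive → active → closed2-ATP-active →
closed2-ADP·Pi → open), unidirectional because the driven cycle is drawn
that way and reverse rates are unknown. ATP binding is lumped into the
first closing step (assays run at saturating nucleotide). Default rates —
closing steps 3 min⁻¹ each, catalysis 1 min⁻¹, release 60 min⁻¹ — are a
calibration chosen so that (i) baseline turnover, 1/Σ(1/kᵢ) ≈ 0.496 min⁻¹,
sits at the measured wild-type ADP-release scale of ~0.5 min⁻¹, and
(ii) closing (total 1 min) and catalysis (1 min) contribute comparably to
the cycle time, the regime in which a large catalytic acceleration is
offset by a small closing penalty. All rates are config-overridable
(JSON/YAML).

The deterministic layer solves the stationary master equation πQ = 0
directly; turnover is the release flux k_release·π(ADP·Pi). The stochastic
layer is an exact Gillespie direct-method simulation over independent
enzymes with a seeded generator; occupancies are time-weighted and the
event log preserves (time, tag, enzyme). The decoupled variant's futile
open→open hydrolysis branch is a self-loop: it adds flux (ATP burned
without closing) but no occupancy change, so it is reported as a separate
flux channel.

The perturbation analysis `required_closing_reduction` asks: if catalysis
accelerates f_cat-fold, how much slower must closing become to keep
turnover unchanged? Brent root-finding on f_close ∈ [1, 100] against the
steady-state turnover; for the unidirectional cycle the closed form is
f_close = 1 + (1 − 1/f_cat)·t_cat/t_close, giving 1.99 at f_cat = 100 with
the default calibration — i.e., a hundred-fold faster chemical step is
absorbed by merely a two-fold closing penalty, which is why a decoupling
mutation can leave the observed ADP-release rate unchanged. Protomer
asymmetry and co-chaperone binding are out of scope of this model.

## Assay fits

All nonlinear fits are Levenberg–Marquardt (lmfit) with deterministic
starting heuristics; no stochastic multi-start is used.

* **Mono-exponential** y = A₁e^(−x/t₁) + y₀ (the conventional reading of
  the decay form, with k_app = 1/t₁ and σ_k = σ_t/t₁²). t₁ starts from a
  log-linear pre-fit; a fit at t₁ ≤ 0 is rejected.
* **ADP-release**: OLS slope over a user window, background slope (from an
  inhibitor-quenched tail, e.g. radicicol) subtracted, converted by
  k = −m/(ε_NADH·c_Hsp90·path). ε_NADH defaults to the standard
  6220 M⁻¹ cm⁻¹ at 340 nm with a 1 cm path; both configurable.
* **Michaelis–Menten** v = Vmax·x/(K_M + x) over substrate titrations
  (default generator range 0.1–5 mM ATP).
* **Anisotropy binding**: the printed forms of competition-anisotropy
  isotherms are frequently garbled in transcription; this package fits the
  standard single-site quadratic ligand-depletion isotherm, treating the
  labelled probe and unlabelled titrant as one equal-affinity ligand pool
  whose bound fraction maps anisotropy between F_P (free) and F_PL
  (bound). Parameter estimates are comparable to any correctly normalized
  form; coefficient-level comparison with ad-hoc printed variants is not
  meaningful.
* **CSP** Δδ = √(Δδ_H² + (αΔδ_N)²), α = 0.1689 (the ¹H/¹⁵N shift-range
  ratio); residues matched by number, name clashes warn, unmatched
  residues are returned rather than fatal.
* **Heteronuclear NOE**: ratio I_sat/I_ref with baseplane-noise
  propagation σ_ratio = |ratio|·√((σ/I_sat)² + (σ/I_ref)²).
* **Guinier**: weighted linear fit of ln I vs q² over the largest low-q
  prefix with q·R_g ≤ 1.3, iterated to self-consistency (the window
  depends on the R_g it determines); a non-negative slope aborts with an
  aggregation/non-globularity error.
* **P(r)**: uniform-weight histogram of all pairwise distances. R_g is
  computed from the exact pairwise identity R_g² = Σ_{i<j}d_ij²/N²
  (equivalently the second moment about the centroid), not from the binned
  histogram, so it is free of binning error: two points a distance d apart
  give exactly d/2, and a dense uniform ball of radius a gives √(3/5)·a.

## Synthetic data

Generators share one top-level seed fanned out into per-generator
substreams (numpy `SeedSequence` children keyed by a CRC32 label hash), so
adding a generator never shifts an existing stream. Default truth values
sit at the measured scales of the system: wild-type ADP release
0.50 min⁻¹ (mutant 0.55 min⁻¹), a 10-fold re-opening rate difference with
the wild-type apparent rate at 0.02 min⁻¹, heteronuclear NOE 0.58 on unit
reference intensity with 0.02 baseplane noise, Guinier R_g 53.1 Å
(compact) and 62.3 Å (open) — so recovery tests double as reproductions of
those readouts. Noise defaults (FRET σ = 0.01 on unit amplitude,
absorbance σ = 0.003 AU, telegraph σ = 0.4 Å) are plausible instrument
scales chosen once; each generator stores its truth for automated
recovery.

What the generators do not emulate: instrument drift and baseline
artifacts, photobleaching, correlated noise, inner-filter effects,
non-exponential exchange broadening, interparticle SAXS structure factors,
and conformational heterogeneity beyond two states. Passing recovery tests
therefore certifies the estimators under their stated statistical models,
not robustness to real-data pathologies.

## Problem sizes

Default test and benchmark sizes — 37 windows × 1000 umbrella samples,
10 bootstrap trials, 200 enzymes × 500 min of SSA, 100 assay replicates,
5×10⁴-frame telegraph traces — were chosen as the smallest sizes at which
the statistical tolerances above are comfortably resolved.
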
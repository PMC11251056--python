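# Methods

## The binding model

Native mass spectrometry of a homodimeric transporter resolves every
ligand-bound species of the intact dimer as a separate mass. With mole
fractions `F_0..F_n` of the 0- to n-bound species measured at a series of
total ligand concentrations, stepwise binding constants follow from the
sequential scheme

```
P·L_{j-1} + L  <=>  P·L_j        K_Aj = [PL_j] / ([PL_{j-1}][L])
F_n = x^n Π_{j<=n} K_Aj / (1 + Σ_i x^i Π_{j<=i} K_Aj),   x = [L]_free
```

Because the protein sits at micromolar concentration, the free ligand
concentration `x` is materially below the nominal total when binding is
tight: it is obtained from the mass balance
`x + P_total · Σ_i i·F_i(x) = L_total`, whose left side is strictly
increasing in `x`. The implementation bisects this residual on
`[0, L_total]` (72 halvings, i.e. to the double-precision floor),
vectorized over concentration grids. The protein concentration `P_total`
is the *dimer* concentration: the species ladder in the spectra is
dimer + n ligands, so sites are counted per dimer.

Assumptions worth stating explicitly:

* Stepwise constants are free parameters; no ordering between K_D1 and
  K_D2 is imposed. Negative cooperativity (K_D2 > K_D1), when it
  appears, is an outcome of the fit.
* Mg²⁺–nucleotide speciation is ignored; `L_total` is the nominal
  nucleotide concentration.
* Concentrations are µM and association constants µM⁻¹ everywhere in
  the library; conversions belong to the I/O layer.
* A model with `n_max = 0` is rejected; a step with `K_A = 0` is allowed
  and switches that step off (its K_D is reported as +inf).

## Fitting

Estimation minimizes the unweighted pseudo-χ²
`Σ_species Σ_points (F_obs − F_calc)²` with a trust-region least-squares
solver over `log10(K_A)`, which enforces positivity by construction and
makes the objective well-scaled over the decades a K_D can span.
Initialization uses a half-saturation heuristic (the L_total at which
each species' observed fraction peaks, clipped to [1e-3, 1e5] µM); an
optional seeded multi-start (default 8 log-uniform perturbations within
±2 decades) guards against local minima. Convergence tolerances are
1e-12 on the scaled step/objective with a 500-evaluation cap;
non-convergence flags the result rather than raising.

Replicates are fit independently by default and reported as mean ±
sample SD (n−1), matching how biological triplicates are reported in
this field; a pooled joint fit is available where a single global
estimate is wanted. Observed mole-fraction vectors must sum to 1 within
0.01 and are renormalized exactly before fitting.

### Bootstrap intervals

`bootstrap_uncertainty` case-resamples titration points within each
replicate, refits each resample (warm-started at the full-data
estimate), and reports intervals from the resampled estimates.
Two finite-sample corrections are applied by default (`method="bca"`):

* **BCa adjustment** — the K_D sampling distribution is right-skewed
  and slightly biased; bias-corrected accelerated quantiles (jackknife
  acceleration over leave-one-point-out fits) correct both effects.
* **Level expansion** — with a few dozen points the bootstrap
  distribution is systematically narrower than the estimator's sampling
  distribution; the nominal z-quantiles are expanded by
  `sqrt(n/(n−1))·t_{α,n−1}/z_α` (Hesterberg's expanded-percentile
  correction).

Plain percentile intervals (`method="percentile"`) are retained for
comparison; in simulation at the default conditions they cover a true
K_D a few percent less often than their nominal level, which is why the
corrected interval is the default. Resamples that lose identifiability
(fewer distinct concentrations than parameters) are redrawn with a
bounded retry count.

## Spectra

The simulator places one Gaussian per (species, charge) at
`(M + z·1.00728)/z` with σ = `M/(z·R·2.355)` for resolving power `R`
(default 17,500), area proportional to abundance × charge weight, and
applies multiplicative Gaussian point noise. The charge envelope is a
configurable Gaussian-weighted set (default centered at z = 24, width 2);
the real charge-state range of a detergent-solubilized 129 kDa dimer is
instrument-dependent, so these defaults are placeholders, and every
result downstream of the simulator is insensitive to the choice because
deconvolution uses the same envelope.

Zero-charge reduction is deliberately simple: non-negative least squares
of unit-abundance species templates against the observed trace. This is
not a general deconvolution engine — it requires the candidate species
ladder up front — but for a known protein with a known ligand set it is
exact at zero noise and stable under realistic noise, which is the
property the mole-fraction analysis needs.

Assignment maps neutral-mass peaks to the nearest ladder mass within a
tolerance (default 150 Da — far below the lightest ligand mass of
~427 Da, wide enough to absorb small adduct shifts). The tolerance must
stay below half the smallest inter-species gap so matches are unique;
peaks exactly equidistant between two species raise an error rather than
splitting intensity silently. Mg²⁺/detergent adducts are not modelled as
distinct species; the tolerance absorbs them. The apo (dimer) mass is a
configurable parameter.

## Synthetic data

The generator emulates the experimental designs the analysis consumes:

| parameter | default | rationale |
|---|---|---|
| `p_total` | 0.5 µM | dimer concentration used in the emulated experiments |
| `kd_nuc` | (47.8, 124.4) µM | ATP-like stepwise K_Ds |
| `kd_adp` | (17.8, 62.3) µM | ADP-like stepwise K_Ds (tighter than ATP) |
| `kd_lip` | (0.25, 0.5, 1.0, 2.0) µM | four lipid sites; a tight binder showing 0–4 bound at 1 µM total |
| `l_grid` | 8 points, 0.1×–4× max K_D | geometric titration grid bracketing both transitions |
| `l_nuc_total`, `l_lip_total` | 50 µM, 1 µM | joint/time-course condition |
| `replicates`, `noise_sd` | 3, 0.03 | triplicates with 3% additive mole-fraction noise |
| `alpha` | 0 | lipid→nucleotide coupling, off by default |
| `k_hyd` | ln2/6 h⁻¹ | ~50% ATP remaining at 6 h; ADP-bound states prominent mid-course |
| `times` | 0–10 h, 2 h steps | time-course sampling design |

Noise is additive on mole fractions (clipped at zero, renormalized)
because mole fractions are what the analysis consumes; an
intensity-level noise path exists through the spectra module. A single
seed determines every output, with an independent `SeedSequence`
substream per replicate.

The lipid K_D defaults are a design choice, not measured values: the
emulated experiments show 0–4 lipids bound at 1 µM lipid with 0.5 µM
protein, which requires sub-to-low-µM stepwise constants and implies
strong ligand depletion — the generator treats nominal totals as exact
and ignores detergent partitioning of the lipid.

**Coupling.** Conditional on lipid count `j`, nucleotide stepwise K_Ds
are scaled by `exp(−α·j)`: a single parameter that yields exact
independence at α = 0 (the joint table is then precisely the outer
product of its marginals) and a monotone increase of nucleotide affinity
with bound lipid at α > 0. The free nucleotide concentration is solved
self-consistently against the lipid-state mixture; the lipid marginal
itself is kept at its uncoupled equilibrium (one-way coupling). This is
a generator, not a thermodynamic model: one-way coupling is the simplest
structure that reproduces the qualitative observation (lipid-bound
states favor ATP) with a single dial.

**Hydrolysis.** The ATP pool decays exponentially with the released ADP
accumulating (`ATP(t) + ADP(t) = L₀` exactly), and each sampling time is
treated as a binding equilibrium at the current totals — binding
equilibrates much faster than cold-temperature turnover. Mixed ATP/ADP
occupancy uses a path-summed sequential partition function: the weight
of the species with `a` ATP and `b` ADP sums the products of stepwise
constants over all interleavings. With macroscopic stepwise constants
this path sum is not guaranteed thermodynamically cycle-consistent; it
reduces exactly to the single-ligand sequential model when either free
concentration is zero, which is the regime the tests pin down. Free ATP
and ADP are solved by nested bisection on the two mass balances. ADP
affinity is left unmodulated by lipid, so at α > 0 high-lipid states
stay ATP-selective as ADP accumulates.

What the generator does *not* emulate — and therefore what passing tests
cannot show about real data: charge-state-dependent transmission or
desolvation bias, adduct tails and baseline chemical noise,
detergent/lipid partitioning of free lipid, Mg²⁺ speciation, mechanistic
(Michaelis–Menten, per-site) hydrolysis kinetics, and replicate-level
systematic offsets (replicates differ only by iid noise).

## Time-course tracking

`track_stoichiometry` selects cells of joint stoichiometry tables with a
`LIGAND=k` / `LIGAND=*` selector; ligand classes omitted from the
selector are marginalized by summation. Traces are ordered by time;
absent time points are gaps, never zeros. Replicate summaries require
exactly matching time grids (sampling on a fixed interval makes silent
interpolation both unnecessary and risky) and report pointwise mean ±
sample SD.

## Structure metric

Openness of an ABC transporter conformation is summarized as the
Euclidean distance between the Cα atoms of one NBD marker residue
(author numbering; for MsbA, T561) across the two chains of the dimer.
mmCIF and legacy PDB are both read (gemmi); the first model is used;
altloc ties resolve to the highest occupancy, then altloc 'A'. For
C2-symmetric dimers the two chains are auto-detected as the only two
containing the marker residue; explicit chain selection overrides.
Ranking sorts descending with input order breaking exact ties.

## Numerical choices

* Free-ligand bisection: 72 iterations on `[0, L_total]` — absolute
  error below `L_total·2⁻⁷²`, i.e. the double-precision floor for all
  realistic concentrations; monotonicity of the residual guarantees the
  bracket.
* Fit tolerances 1e-12 (step, objective, gradient), 500 evaluations max.
* Degenerate inputs fail loudly: zero total intensity, ambiguous peak
  assignment, selectors matching nothing, misaligned replicate grids,
  non-identifiable titrations.
* Problem sizes in the test-suite simulation studies (100 datasets of
  3 × 8 titration points; 200 bootstrap resamples; 100 spectral seeds)
  were chosen to keep Monte-Carlo error on the checked summaries well
  below the asserted margins.

## Known limitations

* The template deconvolution cannot discover unexpected species; it
  quantifies a declared ladder.
* The coupling and hydrolysis sub-models are single-parameter
  caricatures intended for pipeline validation, not inference about
  mechanism.
* Percentile/BCa bootstrap coverage remains slightly below nominal at
  these sample sizes (high-80s to low-90s percent for a 95% interval in
  simulation); the replicate SD remains the primary reported
  uncertainty.
* Only the marker-residue distance is computed; domain rotation angles
  require superposition machinery that is out of scope.
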
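# msbind

Native mass spectrometry (native MS) resolves every ligand-bound state
of an intact protein complex as a separate mass. For a homodimeric ABC
transporter binding nucleotides and lipids, one spectrum therefore
contains the full joint distribution of bound states — apo, one ATP,
two ATP, each with 0–4 lipids — and a titration series turns those
relative intensities into stepwise binding constants.

`msbind` is the analysis layer for such experiments. It is written for
people who have deconvolved native-MS peak lists (or raw m/z traces) of
a dimeric membrane protein and want numbers out the other end:

* **Sequential binding model with depletion correction.** The mole
  fraction of the n-bound species is
  `F_n = x^n Π_{j≤n} K_Aj / (1 + Σ_i x^i Π_{j≤i} K_Aj)` with the free
  ligand concentration `x` solved self-consistently from
  `x + P_total Σ_i i·F_i(x) = L_total` — at 0.5 µM protein and
  micromolar ligand the bound pool is not negligible.
* **Global K_D fitting** by minimization of the unweighted pseudo-χ²
  `Σ (F_obs − F_calc)²` over all species and titration points, per
  replicate (mean ± SD) or pooled, with multi-start protection and
  case-resampling bootstrap intervals.
* **Spectrum simulation and simplified deconvolution** (non-negative
  least squares of species templates), peak-to-stoichiometry
  assignment, and intensity → mole-fraction conversion.
* **Joint nucleotide × lipid stoichiometry tables**, an independence
  null (outer product of marginals), a one-parameter lipid→nucleotide
  coupling model, and hydrolysis time courses with selector-based
  tracking of states such as `ATP=2, KDL=*`.
* **NBD-separation metric**: the inter-chain Cα–Cα distance of a marker
  residue (e.g. T561) from mmCIF/PDB files, and ranking of
  conformations by openness.

A synthetic-data generator reproduces the statistical structure of the
experiments (triplicates, 3% mole-fraction noise, ligand depletion,
hydrolysis-driven ATP→ADP conversion), so the entire pipeline is
testable without any downloads.

## Worked example

Generate a noisy triplicate ATP-like titration at 0.5 µM dimer and fit
the two stepwise dissociation constants:

```python
from msbind import (GeneratorConfig, generate_titration, fit_titration,
                    bootstrap_uncertainty)

cfg = GeneratorConfig(kd_nuc=(47.8, 124.4), noise_sd=0.03, replicates=3, seed=7)
series = generate_titration(cfg)
fit = fit_titration(series, mode="per_replicate", seed=7)
bs = bootstrap_uncertainty(series, n_boot=200, seed=7)
for j in range(2):
    print(f"KD{j+1} = {fit.k_d[j]:6.1f} +/- {fit.k_d_sd[j]:4.1f} uM "
          f"(95% CI {bs.k_d_lower[j]:.1f}-{bs.k_d_upper[j]:.1f})")
print(f"pseudo-chi2 = {fit.chi2:.4f} over {len(series.points)} points")
```

```
KD1 =   47.3 +/-  2.6 uM (95% CI 44.7-50.3)
KD2 =  119.6 +/-  8.4 uM (95% CI 116.0-125.4)
pseudo-chi2 = 0.0413 over 24 points
```

The fit recovers the generating constants (47.8 and 124.4 µM) within
one replicate SD; `K_D2 > K_D1` is the negative cooperativity the
sequential model expresses when the second site binds more weakly. The
± values are the SD over the three independently fit replicates, the CI
a bias-corrected bootstrap over titration points.

The same analysis from the shell:

```sh
msbind simulate --kd 47.8,124.4 --seed 7 --out tit.csv
msbind fit tit.csv --seed 7 --out fit.json
# fit (per_replicate): KD1=47.3 uM, KD2=120 uM; chi2=0.0413; wrote fit.json
```

Other subcommands: `assign` (raw spectrum → per-species intensities),
`fractions`, `track --select ATP=2,KDL=*` (time-course traces,
mean ± SD over replicates), and `nbd-dist FILE... --residue 561` (NBD
separations, ranked). Every output file carries the seed and a config
hash in `#` header lines.

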
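# exoflux

**13C isotope-tracer analysis of exosome-driven metabolic reprogramming in
cancer cells.**

Cancer-associated fibroblasts (CAFs) secrete exosomes that reprogram the
metabolism of nearby tumor cells: they suppress mitochondrial oxidative
phosphorylation, push glycolysis up, shift glutamine into reductive
carboxylation, and deliver an "off-the-shelf" cargo of amino acids and TCA
intermediates. All of those conclusions rest on a chain of quantitative
steps applied to GC-MS mass isotopologue distributions (MIDs) and
extracellular-flux traces. `exoflux` implements that chain as a tested,
reusable Python package for tracer analysts:

- **MID arithmetic** — normalization of raw M+0..M+N ion intensities, mean
  enrichment `ME = (Σᵢ i·Mᵢ)/N`, and isotopologue convolution for
  condensation reactions.
- **Natural-abundance correction** — a correction matrix built from the
  measured fragment's elemental formula (TBDMS derivatization, tracer
  purity included), inverted by non-negative least squares.
- **Isotopologue spectral analysis (ISA)** — the two-parameter model of
  fatty-acid labeling: the lipogenic acetyl-CoA pool is the mixture
  `X = D·T + (1−D)·N`, and the palmitate MID is
  `P(M+x) = g·f(M+x)(X) + (1−g)·f(M+x)(N)` with `f` the 8-fold
  self-convolution of the acetyl MID. `fit_isa` estimates `(D, g)` by
  bounded multistart least squares with bootstrap confidence intervals.
- **Flux metrics** — the M4/M5 citrate split of oxidative vs reductive
  glutamine entry under U-¹³C₅ glutamine, the α-ketoglutarate/citrate pool
  ratio, percentage substrate contribution, and the M1-pyruvate glycolysis
  index for the 1:1 U-¹³C₆/1-¹³C₁ glucose mixture.
- **Exosome cargo and dosimetry** — contribution of labeled-exosome
  metabolites to recipient-cell pools (cell enrichment normalized by
  exosome enrichment) and particle/mass/producer-cell-equivalent
  arithmetic.
- **Bioenergetics** — basal, maximal and reserve OCR and basal ECAR from
  injection-annotated (oligomycin/FCCP/rotenone) flux time series with
  protein normalization.
- **Synthetic data** — a ground-truth generator that propagates tracer
  label through an atom-mapped toy network of central carbon metabolism,
  so every stage above can be validated by parameter recovery without any
  raw instrument data.

## Worked example

Simulate an exosome-treated condition under U-¹³C₅ glutamine, correct the
raw table for natural abundance, and read out the reductive-carboxylation
split and the ISA parameters:

```python
import numpy as np
from exoflux import citrate_ox_red, fit_isa, tracer_acetyl_template
from exoflux.io import correct_mid_table, iter_mids
from exoflux.simulate import preset_config, simulate_mids

cfg = preset_config("cde", "U13C5-glutamine", seed=7, noise_sd=0.002)
table, truth = simulate_mids(cfg)
corrected = correct_mid_table(table, tracer_purity=1.0)

cit = [m for r, m in iter_mids(corrected, corrected=True) if r["metabolite"] == "citrate"]
mean_cit = cit[0].with_fractions(np.mean([m.as_array() for m in cit], axis=0))
split = citrate_ox_red(mean_cit)
print(f"M4 (oxidative) = {split.oxidative_fraction:.3f}")
print(f"M5 (reductive) = {split.reductive_fraction:.3f}")
print(f"M4/M5          = {split.ox_over_red:.2f}")

palm = [m for r, m in iter_mids(corrected, corrected=True) if r["metabolite"] == "palmitate"]
reps = np.vstack([m.as_array() for m in palm])
mean_palm = palm[0].with_fractions(reps.mean(axis=0) / reps.mean(axis=0).sum())
fit = fit_isa(mean_palm, tracer_acetyl_template("U13C5-glutamine"),
              replicates=reps, n_boot=200, seed=7)
print(f"D = {fit.D_hat:.3f} (95% CI {fit.D_ci[0]:.3f}-{fit.D_ci[1]:.3f}), g = {fit.g_hat:.3f}")
```

prints

```
M4 (oxidative) = 0.338
M5 (reductive) = 0.286
M4/M5          = 1.18
D = 0.238 (95% CI 0.238-0.239), g = 0.560
```

A low M4/M5 ratio marks strong reductive carboxylation (the treated
phenotype). The ISA fit says 23.8% of lipogenic acetyl-CoA carbon came from
the glutamine tracer and 56% of the palmitate pool was newly synthesized
during the labeling window — close to the generator's ground truth of
`D = 0.25, g = 0.6` despite measurement noise.

The same stages are available from the shell:

```bash
exoflux simulate --preset cde --tracer U13C5-glutamine --seed 7 --out fixtures/
exoflux correct  --in fixtures/mids.csv --out corrected.csv --tracer-purity 1.0
exoflux isa      --mids corrected.csv --metabolite palmitate \
                 --tracer U13C5-glutamine --tracer-purity 1.0 --out isa.json
exoflux metrics  --mids corrected.csv --tracer U13C5-glutamine --out metrics.csv
exoflux dose     --mass 270 --calib 4.9
```

## Layout

```
src/exoflux/
  mid.py            MID container, normalization, mean enrichment, convolution
  correction.py     fragment formulas, correction matrix, NNLS inversion
  isa.py            ISA forward model and (D, g) estimator
  metrics.py        ox/red split, pool ratio, substrate contribution, M1 index
  exosomes.py       cargo contribution and dosimetry
  bioenergetics.py  stress-test metric derivation
  simulate.py       atom-mapped network simulator and presets
  io.py             MID-table CSV, flux CSV and schedule YAML readers/writers
  cli.py            `exoflux` command group
docs/methods.md     model descriptions, assumptions and design choices
```
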
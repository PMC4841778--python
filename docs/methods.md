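# Methods

This note describes the models implemented in `exoflux`, the assumptions
behind them, the parameters that matter, and the design choices made where
more than one defensible convention exists. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Mass isotopologue distributions

A metabolite with `N` backbone carbons measured by GC-MS yields intensities
for the mass variants M+0..M+N. Dividing by their sum gives the MID; all
downstream quantities consume MIDs, so every metric is invariant to
intensity rescaling by construction. Mean enrichment,
`ME = (Σᵢ i·Mᵢ)/N`, is the average fraction of backbone carbons that are
¹³C; it is linear in the MID and bounded by [0, 1].

Isotopologue convolution models condensation reactions: if two moieties
label independently, the product's MID is the discrete convolution of
theirs. This is the primitive behind both the ISA forward model and the
simulator's citrate synthase step.

## Natural-abundance correction

The measured fragment carries atoms beyond the backbone — derivatization
carbons, silicon of TBDMS groups, oxygens — whose natural heavy isotopes
shift the observed mass exactly like tracer label. We model the distortion
as a linear operator `M`: entry `(j, i)` is the probability that a molecule
with `i` tracer-derived ¹³C atoms is observed at mass shift `j`. The
background distribution is the exact convolution of per-atom isotope
distributions (IUPAC abundances shipped as `data/isotopes.yaml`,
overridable), truncated at the measured window, so columns may sum to
slightly less than 1.

Two conventions are fixed deliberately:

- **Backbone carbons are tracer positions.** They contribute no natural
  abundance to the matrix; the corrected vector answers "how many backbone
  carbons did the tracer label". The alternative (correcting unlabeled
  backbone positions as well) changes corrected M+1 by roughly
  `N × 0.0107`; with the convention used here that residual background is
  part of what correction removes only for non-backbone atoms, and the
  round-trip tests pin the behavior.
- **Tracer purity** (¹³C enrichment of the tracer below 1, default 0.99 in
  the CLI) is folded into the same matrix as a binomial down-shift of the
  `i` tracer positions, making the matrix banded rather than
  lower-triangular.

Inversion solves `argmin_{x≥0} ‖Mx − raw‖²` with scipy's NNLS, which
enforces non-negativity — negative fractions are never produced, only
renormalized mass. On well-conditioned fragment matrices the forward →
correct round trip recovers random MIDs to ~1e-15 (asserted at 1e-10 over
1,000 random fragments).

MID tables read from CSV are auto-normalized unless flagged pre-normalized;
correction is an explicit step that sets a `corrected` flag, and
re-correcting a corrected MID is an error — whether a given table has been
corrected is never guessed.

## Isotopologue spectral analysis

Palmitate is a polymer of 8 acetyl units (stearate 9). ISA treats the
lipogenic acetyl-CoA pool as a two-component mixture — tracer-derived units
with MID `T`, naturally labeled units `N` — mixed with fraction `D`:

    X = D·T + (1−D)·N

A newly synthesized fatty-acid molecule draws its units independently from
`X`, so its MID is the 8-fold self-convolution `f(X)`; the measured pool
mixes new and pre-existing molecules with fraction `g`:

    P(M+x) = g·f_{M+x}(X) + (1−g)·f_{M+x}(N)

The per-composition weight implied by independent draws is the multinomial
coefficient `8!/(n₀!n₁!n₂!)`. A formulation sometimes written as a product
of two binomial coefficients (e.g. `C(8,5)·C(8,3)` for the 5×M0 + 3×M1
composition of M+3) double-counts arrangements; we implement the
multinomial/convolution form and verify it against exhaustive enumeration
over all 3⁸ unit assignments (agreement to <1e-12).

**Estimation.** `(D, g)` are fit by bounded least squares on [0,1]² with a
multistart grid (default 5×5; the acceptance checks use 3×3, which already
recovers a 9×9 grid of interior truths to 1e-6 noise-free). When the
measured MID is indistinguishable from `f(N)` (no synthesis), `D` is
structurally unidentifiable; the fit returns with a `g-at-boundary` flag
instead of failing. Uncertainty comes from a seeded bootstrap over
replicate spectra (default 200 resamples, percentile intervals); fits are
deterministic given a seed and invariant to replicate order.

`tracer_acetyl_template` builds `T` for the uniformly labeled substrates
(glucose, glutamine, pyruvate, acetate): both acetyl carbons derive from
labeled positions, so `T` is binomial in the tracer purity. Tracer-impurity
handling is exposed as a parameter (default on at 0.99 in the CLI) since
labs differ in whether they fold it into correction or into `T`.

Multi-substrate accounting composes independent single-tracer fits (one
experiment per tracer); the unaccounted share is `1 − ΣD̂`. No acetyl-CoA
compartmentation or elongation/desaturation beyond the n-unit polymer is
modeled.

## Flux metrics

Under U-¹³C₅ glutamine, oxidative TCA cycling produces M4 citrate (labeled
oxaloacetate + unlabeled acetyl-CoA) while reductive carboxylation of M5
α-ketoglutarate produces M5 citrate; the M4/M5 ratio therefore reads out
oxidative over reductive glutamine entry. A zero M5 yields an infinity
sentinel, not an exception, because control conditions can have vanishing
reductive flux. The α-ketoglutarate/citrate pool-size ratio (normalized ion
currents) is a second, label-free correlate of reductive carboxylation.

"Percentage substrate contribution" is operationalized as mean enrichment
of the downstream pool divided by the enrichment the tracer could at most
transmit — 1 for a uniform tracer, 7/12 for the 1:1 U-¹³C₆/1-¹³C₁ glucose
mixture — capped at 1. The raw mean enrichment is always available
alongside, since the normalizing convention for mixed tracers is not
standardized; both numbers are emitted so either convention can be audited.

The M1 index for the 1:1 glucose mix is the M1 fraction of pyruvate (or
lactate): M1 pyruvate can only arise from C1-labeled
glucose-6-phosphate routed through phosphoglucoisomerase into glycolysis,
because the oxidative pentose phosphate pathway removes that C1 as CO₂. The
interpretation is documentation; the computation is a read-off, and the
index is declared undefined for any other tracer.

## Exosome cargo and dosimetry

Producer fibroblasts labeled for 72 h (less than one population doubling)
secrete exosomes whose metabolite cargo is only partially labeled. The
contribution of exosomes to a recipient-cell pool is estimated as
`ME_cell / ME_exosome` on natural-abundance-corrected MIDs. For essential
amino acids (shipped classification table; glutamine treated as
non-essential) the ratio cannot exceed 1 at steady state and a violation is
an error; for other metabolites values above 1 are possible through de novo
synthesis and are flagged, never clipped. Because the recipient keeps
catabolizing the metabolite over the chase period, the estimate is a lower
bound on cumulative supply — the simulator reproduces this as a strict
inequality under positive turnover. Contributions are summarized per
replicate (median, bootstrap CI).

Dosimetry is exact arithmetic on a mass-per-particle calibration (default
4.9 µg per 10⁹ particles): mass ↔ particle count, and particle dose ↔
producer-cell equivalents given a per-producer secretion yield (default
28,000 particles per producer per 48 h). The producer count behind the
yield is not derivable from the calibration alone, so the yield is an
input, not a constant.

## Bioenergetics

A mitochondrial stress test injects oligomycin, FCCP and rotenone (or
antimycin — the two labels are treated as equivalent ETC-block events) into
a well while measuring OCR and ECAR. Each segment statistic is the mean of
the last 3 measurements before the next injection (window configurable),
discarding mixing transients. Derived per µg protein: non-mitochondrial
floor (post-block mean), basal (pre-injection minus floor; the uncorrected
value is also emitted since conventions differ), maximal (post-FCCP minus
floor) and reserve = maximal − basal. Missing segments leave dependent
metrics absent rather than failing the well; negative derived rates are
floored at 0 with a warning. Metrics are invariant to uniform time shifts
and to joint signal/protein rescaling.

## Synthetic data generator

The generator exists to make every stage verifiable by parameter recovery.
It propagates positional isotopomer distributions (probability vectors over
the 2ⁿ binary labeling patterns of an n-carbon metabolite) through an
atom-mapped toy network:

- glycolysis (both triose arms, with the C1→pyruvate-C3 inversion on one
  arm), an oxidative PPP shunt that loses glucose C1 as CO₂ (fraction
  `f_ppp`),
- PDH (loses pyruvate C1), citrate synthase (Kronecker product of
  oxaloacetate and acetyl patterns), oxidative IDH (loses the
  oxaloacetate-derived citrate C1), reductive carboxylation of
  α-ketoglutarate with unlabeled CO₂ (fraction `f_red` of citrate
  production),
- α-ketoglutarate dehydrogenase into a symmetric four-carbon pool with
  fumarase scrambling (succinate/fumarate rotational symmetry), mixed with
  the reductive/cataplerotic route (citrate-cleavage oxaloacetate), and
- glutaminolysis, citrate cleavage to lipogenic acetyl-CoA, and palmitate
  synthesis as 8 independent acetyl draws.

Reactions are bit permutations plus explicit CO₂/sink losses, so carbon is
conserved by construction and `check_carbon_conservation` verifies the
balance per reaction at steady state. The cyclic TCA part is solved by
fixed-point iteration (tolerance 1e-10, cap 10,000 iterations, convergence
failure raises with diagnostics). A steady-state description was chosen
over time-resolved ODEs because the emulated experiments measure single
late time points.

The oxidative PPP is deliberately not a full non-oxidative rearrangement:
glucose C2/C3 go to an untracked biomass sink and only the C4–C6 triose
re-enters glycolysis. This preserves the one property the analysis uses —
loss of the C1 label — without modeling transketolase/transaldolase
carbon shuffling.

Lipogenic acetyl-CoA is a mixture over substrate-specific delivery routes
(glucose via PDH of glucose-derived pyruvate, glutamine via reductive
carboxylation and citrate cleavage, pyruvate via PDH, acetate directly),
each conditional on the carbon actually deriving from that substrate. The
tracer substrate's configured share is therefore exactly the ISA ground
truth `D`, which is what makes end-to-end ISA recovery testable.

Emitted tables are in the MID CSV dialect with intensities forward-convolved
through each metabolite's fragment correction matrix (the shipped fragment
formulas are representative TBDMS/methyl-ester compositions, not instrument
library entries), per-isotopologue Gaussian noise (default sd 0.005,
renormalized), and a total ion current that encodes the configured pool
size. Output is byte-identical under a fixed seed.

Exosome-transfer simulation mixes a fully labeled tracer pattern with M0 at
the exosome label fraction (default 0.6 after 72 h of sub-replication
labeling), and recipient pools mix exosome-supplied and unlabeled
endogenous molecules at the configured supply fractions (defaults 0.05,
0.12, 0.14, 0.16 for leucine, lysine, glutamine, phenylalanine — the
magnitudes such feeding experiments report). Catabolic turnover removes a
fraction of supplied label from the measured pool; the read-through of
catabolized glutamine into glutamate is stylized (a fixed half-retention),
included only to make the redistribution qualitatively visible.

Two presets are shipped, `control` and `cde` (exosome-treated). Their
branch fractions differ in the directions the treated phenotype implies —
`f_red` 0.15→0.4, pyruvate oxidation down, glycolytic share up, glutamine
share of lipogenesis up, OCR parameters down, ECAR up — and are otherwise
uncalibrated: no quantitative flux measurements exist to fit them to, so
the simulator is a structural model and the tests assert only directions,
limiting cases and parameter recovery, never magnitudes.

### What passing tests do and do not show

The generator reproduces the statistical structure the analysis assumes:
steady-state labeling, independent per-isotopologue Gaussian noise,
natural-abundance distortion from known fragment formulas, complete
replicate tables. Real data violate several of these — noise is
intensity-dependent and correlated across isotopologues, fragment formulas
can be wrong, pools are not at isotopic steady state at early times, and
acetyl-CoA is compartmentalized. Passing recovery tests therefore shows
the estimators are correct under their stated model, not that the model
captures every property of a real GC-MS run.

## Numerical choices

- Fixed-point tolerance 1e-10; NNLS for correction (exact for
  well-conditioned systems); least-squares tolerances 1e-14 so noise-free
  ISA recovery reaches 1e-6.
- ISA boundary flags use a 1e-6 margin on `D̂`, `ĝ`.
- Zero denominators: empty spectra, unlabeled sources, and zero pool sizes
  raise; zero reductive citrate yields an infinity sentinel (a valid
  control-condition outcome, not an error).
- Problem sizes in the recovery suites (100 enumeration instances, 81-point
  fit grid, 50 noisy fits, 1,000 round-trip fragments, 4 replicates per
  simulated condition) were chosen to exercise each estimator across its
  domain while keeping the default suite quick to run on a laptop.

## Known limitations

- The correction convention excludes unlabeled backbone carbons from the
  natural background (see above); tables corrected under the opposite
  convention elsewhere will differ slightly in M+1.
- ISA assumes a single well-mixed lipogenic acetyl pool and a scalar `g`
  per time point; no turnover kinetics.
- The toy network omits pyruvate carboxylase anaplerosis, malic enzyme,
  and compartment-specific pools; it is not a flux-fitting model and
  none of its branch fractions should be read as measured fluxes.
- Essential-amino-acid classification is a fixed table; conditionally
  essential metabolites (glutamine) are treated as non-essential, so their
  contributions above 1 are flagged rather than rejected.
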
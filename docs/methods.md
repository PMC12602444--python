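# Methods

## Measurement model and mass balance

All isotope compositions live internally as atom fractions `x ∈ [0, 1]`;
delta per-mil and atom percent exist only at I/O boundaries. Conversion uses
`R = R_std (1 + δ/1000)`, `x = R/(1+R)` with the fixed standard ratios
VPDB ¹³C/¹²C = 0.0111802 and AIR ¹⁵N/¹⁴N = 0.0036765. The inverse map is
exact; round trips hold to well below 1e-9 ‰.

Enrichment of a labelled tissue is the plain difference between its atom
fraction and the pooled control baseline for the same species and tissue.
Controls are pooled across all unlabelled microcosms — the design labels
every experimental microcosm, so no per-pair matching is possible — and the
pooled mean defines the baseline, the pooled sd its dispersion. Negative
enrichment (possible under measurement noise) is retained and flagged
`below_zero`, never clipped: clipping would bias group means upward.
Inputs are assumed blank- and drift-corrected upstream.

Tissue tracer mass is `APE × element mass fraction × dry biomass (g) × 10⁶`
µg; the 10⁶ factor appears exactly once, in `tissue_tracer_mass`, and
contents ingested as percent are divided by 100 at the schema boundary —
both choices guard against the classic double-/missing-100 error that mixed
lab notation invites. Whole-plant pools sum tissue masses; averaging atom
percents across tissues would violate mass conservation and is never done.
Equation inputs are otherwise ambiguous about whether biomass is whole-plant
or per-tissue; per-tissue-then-sum is the conservation-respecting reading
and is the one implemented.

Percent transferred is `100 × transferred / (transferred + assimilated)`,
i.e. the share of the donor's total tracer budget (retained + exported)
found in the neighbour. With the generator's transfer fraction φ this ratio
equals 100 φ identically in the noise-free limit, which is the package's
strongest end-to-end self-check. Flagged-negative masses are floored to
zero inside this ratio only; both terms zero is an error, not a 0/0.

## Detection

A recipient counts as enriched when the biomass-weighted mean APE of its
tissues strictly exceeds

```
T = max( 2 × analytical sd (‰, converted at the control composition),
         2 × pooled control sd )
```

The analytical term uses the local derivative `dx/dδ = R_std / (1000 (1+R)²)`
so the same 0.15‰ instrument precision maps to different atom-fraction
thresholds for carbon and nitrogen, as it should. A value exactly at the
threshold is *not* a detection (strict inequality). Under the null this
two-sd rule fires in well under 5% of microcosms (measured ≈ 0.3–0.5%,
because the weighted mean averages noise over two tissues while the
threshold uses single-tissue dispersion).

At the group level (one direction, n replicate microcosms) a direction
counts as detected when **at least half** of its replicates individually
clear the threshold. Two independent confirmations at a ≤5% per-microcosm
false rate keep the group-level false rate under ~1%, while tolerating one
or two weak replicates when transfer is real. The threshold value is always
reported beside the verdict.

A recipient pool below detection is censored to 0 µg (flag
`below_detection`) before percent and net computations; its raw mass stays
in the pools table, so nothing is silently dropped.

## Net transfer and patterns

The net estimate for a pair and element is `mean(orchid→pine amounts) −
mean(pine→orchid amounts)` over replicate microcosms. The interval is a
seeded percentile bootstrap (default 10,000 resamples) over replicates,
chosen over a t-interval because the amounts are products of noisy positive
factors (skewed) and n = 4. Plain percentile intervals undercover badly at
n = 4 (≈86% for nominal 95%), so the quantile levels are expanded by the
plug-in-variance bias factor `√(n/(n−1))` times the `t_{n−1}/z` ratio
(Hesterberg-style expanded percentile); measured null coverage at n = 4 per
arm is ≈96%. Antisymmetry `f(x, y) = −f(y, x)` holds exactly under one seed
because resampling is tied to a canonical ordering of the two samples.
"Net transfer present" means the CI excludes zero — the operational
definition of "almost no net transfer" is precisely "CI spans zero".

Pattern classification is exhaustive over the verdict space: neither
direction detected → `none`; exactly one → `unidirectional` (net direction
is the detected one, no CI consulted); both → `bidirectional_no_net` or
`bidirectional_net` by the CI, with the net direction from the sign.

Group comparisons follow the conventional contract: Shapiro–Wilk on pooled
group-mean residuals and Levene across groups as pre-checks (reported as
warnings, never hard stops), one-way ANOVA, Tukey HSD at α = 0.05, and a
compact letter display built by insert–absorb (split the letter set on each
significant pair, drop subsets). Degenerate all-constant input yields
F = 0, p = 1 rather than NaN.

## Synthetic experiments

The generator emulates harvest-time endpoints of the reciprocal
dual-labelling design: per scenario, `n_labelled` microcosms per labelling
orientation (default 4 — each orientation is one treatment) plus
`n_control` unlabelled microcosms (default 4). Per labelled microcosm and
element the donor draws uptake `T` (lognormal, CV 0.3 — uptake is positive
and multiplicative), exports `φT` to the neighbour and keeps `(1−φ)T`;
conservation is exact pre-noise. Plant tracer splits 60/40
aboveground/belowground for self-assimilated label and 40/60 for received
label (received tracer arrives through the roots; the aboveground share
encodes that some of it demonstrably reaches shoots). Tissue APE is tracer
mass over the tissue element pool (biomass × content × 10⁶); compositions
are baseline (δ¹³C = −27‰, a typical C3 tissue value; δ¹⁵N = 0‰) plus APE,
then Gaussian noise of 0.15‰ is added **in delta space** — where IRMS
precision is stated — and converted back at the tissue composition.
Configurations whose φ would push an atom fraction to 1 are rejected.

Default magnitudes (chosen once as field-plausible operating points, not
calibrated to any dataset): orchid biomass 1.2/0.8 g above/below, pine
2.0/1.0 g, CV 0.2; C% 45/48, N% 1.5/1.2 (CV 0.05); uptakes — orchid ¹³C
700 µg, pine ¹³C 8000 µg (a pine seedling fixes roughly an order of
magnitude more carbon in a 20-h pulse than a small mixotrophic orchid),
orchid ¹⁵N 600 µg, pine ¹⁵N 800 µg.

The three named scenarios encode the three qualitatively distinct transfer
regimes: `goeringii-like` strictly unidirectional (φ_C pine→orchid = 0.014,
φ_N orchid→pine = 0.003, other directions zero); `faberi-like` bidirectional
with exactly balanced expected nitrogen flows (equal φ_N = 0.006 on equal
700 µg uptakes, so the true net is zero by construction; φ_C = 0.016/0.030);
`serratum-like` bidirectional with clear nets (φ_C = 0.027/0.014,
φ_N = 0.090/0.0025). Net carbon runs pine→orchid in all three.

What the generator does **not** model: fungal-compartment retention (plants
are the only measurable pools), uptake kinetics within the labelling
windows, isotope fractionation, blank/drift structure, or between-tissue
correlation beyond shared biomass draws. Passing tests therefore validate
the estimator chain under idealised noise, not the biology of any real
dataset.

## Problem sizes and numerical choices

Monte-Carlo validations use 500 simulated experiments for parameter
recovery and per-scenario pattern fidelity and ≈250 experiments (2000
labelled microcosms, 1000 per element × direction) for null calibration —
sizes at which binomial uncertainty on the checked rates is well below the
margins being asserted. Bootstrap CIs default to 10,000 resamples; the
recovery and null checks pass `n_boot = 200` since their assertions never
consult the CI. Fixture CSVs are written at full float repr precision and
read back with round-trip parsing, making write→read bit-identical, and all
randomness in a run flows from one user-visible seed recorded in the
manifest.

## Known limitations

* n = 4 per direction is the design's hard floor; the expanded bootstrap is
  calibrated for it but intervals are wide, and the no-net verdict is a
  coverage statement, not an equivalence test.
* Replicates within a run share the pooled control baseline, so reported
  within-run SEs slightly understate across-run dispersion (the recovery
  check bounds the ratio rather than asserting equality).
* The percent-transferred denominator is the donor's *recovered* budget;
  tracer respired or retained in the fungus is invisible to it, as for any
  endpoint-only tracer study.
* Heavily enriched donors sit far outside the linear range of delta
  notation; conversions remain exact, but the constant-‰ noise model is an
  idealisation there.
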
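# tatkit

Analysis pipeline for preclinical **targeted α-therapy (TAT)** studies of
CAIX-targeted radioimmunoconjugates — the quantitative chain that runs from
in-vitro binding assays, through biodistribution and surrogate-tracer
²²⁵Ac dosimetry, to spatial autoradiography/immunofluorescence correlation
and tumor-growth/survival outcome analysis. It is written for
radiopharmaceutical scientists who want each published analysis step as a
tested, reusable function rather than a sequence of spreadsheet and
GraphPad operations, and it ships synthetic-data generators with known
ground truth so every estimator can be validated by parameter recovery.

## What it computes

**Binding assays.** The immunoreactive fraction (IRF) by the Lindmo
inverse plot: under one-site binding, B(c) = IRF·c/(c+K), the regression of
total/bound on 1/c has intercept 1/IRF. The half-maximal inhibitory
concentration by one-site competition, y(c) = Top/(1 + c/IC₅₀) (unit Hill
slope, bottom fixed at 0), after normalizing the lowest-competitor
condition to 100 %. Membrane/internalized partitions with a
blocked/unblocked specificity ratio.

**Biodistribution.** Decay-corrected %IA/g against a counted standard,
Welch t-tests per organ with Holm–Šídák step-down correction, and full
branched-chain Bateman activities for the ²²⁵Ac series
(²²⁵Ac→²²¹Fr→²¹⁷At→²¹³Bi→{²¹³Po|²⁰⁹Tl}→²⁰⁹Pb→²⁰⁹Bi) — used to verify
secular equilibrium before ²²¹Fr-surrogate counting of ²²⁵Ac.

**Dosimetry.** An ¹¹¹In surrogate time–activity curve Aᴵⁿ(t) is converted
to the predicted ²²⁵Ac curve by A(t) = Aᴵⁿ(t)·e^((λᴵⁿ−λᴬᶜ)t) (identical
biological retention), time-integrated (linear rise, trapezoid,
analytic physical-decay tail A(t_last)/λ), and converted to Gy/kBq using
the chain's locally absorbed energy per parent decay (α + electrons,
≈28 MeV at secular equilibrium; photons assumed to escape mouse-scale
volumes). An autoradiograph scaled to the VOI mean dose yields a
pixel-wise dose map.

**Spatial correlation.** Registered (bicubically resampled, inverted)
image pairs are tiled into 20×20-pixel blocks; the Pearson correlation R
of block-mean gray values quantifies co-localization of the radiosignal
with CAIX/hypoxia staining. CD45⁺ area fractions inside a tumor mask
(Otsu or fixed threshold) feed a mouse-level ANOVA with Šídák pairwise
comparisons.

**Therapy outcomes.** Volumes normalized to day 1 (=100 %), fitted by
exponential Y = 100·e^(kt) or one-phase association
Y = Ymax−(Ymax−100)e^(−kt) (AICc selection); fits with R² ≤ 0.5 or
plateaus below the six-fold endpoint are excluded (with the resulting
best-responder bias surfaced in the report); time-to-six-fold = ln 6/k
for exponential growth. Kaplan–Meier survival with the humane endpoint
(tumor > 2.0 cm³) as event, pairwise Mantel–Cox log-rank tests with
Bonferroni correction over the configured comparison set, and
Kruskal–Wallis/Dunn rank comparisons.

## Worked example

Generate a full synthetic study and run every stage:

```bash
tat synth --what all --seed 1 --out synth
tat all --manifest manifest.yaml --seed 1 --out results
```

where `manifest.yaml` lists the generated files
(`lindmo: synth/lindmo.csv`, `tac: synth/tac.csv`, …, plus
`params: {administered_kbq: 15.0}`). On seed 1 this prints/writes:

- `binding`: IRF = 0.94, IC₅₀ = 3.60 nM — exact recovery of the
  generating truth (noise-free defaults).
- `dosimetry`: CAIX⁺ 4.431 Gy/kBq (66.5 Gy at 15 kBq), CAIX⁻
  0.840 Gy/kBq (12.6 Gy); the tail beyond the day-5 scan contributes 75 %
  of the integral, so the physical-decay tail assumption matters.
- `spatial`: R = 0.999 over 100 blocks (the default generator noise is
  mild; raise `noise_sd` to see realistic attenuation).
- `therapy`: median time-to-six-fold 5.7 d (control) vs 11.7 d (treated);
  median survival 11 vs 23 days, log-rank p = 1.2e-05
  (Bonferroni-corrected over the single configured comparison).

The per-stage CSV/JSON outputs land in `results/`, with
`summary.json` byte-identical across reruns at the same seed.

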
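# Methods

This note records the models tatkit implements, the defaults it chose
where a published workflow left the choice open, and what the synthetic
validation does and does not demonstrate.

## Binding estimators

**Lindmo IRF.** One-site binding with excess antigen,
B(c) = IRF·c/(c+K), linearized as total/bound = (1/IRF)(1 + K/c).
Ordinary *unweighted* least squares on (1/c, total/bound); the IRF is
1/intercept. Weighting is not applied because the original workflow does
not state any; heteroscedasticity in real counting data will slightly
favor the high-count (high-c) points either way. Specific binding uses
total-added counts as the denominator (no nonspecific wells in this
assay design); a single scalar background is subtracted, and any
non-positive specific binding is an error, never clipped — clipping
would bias the intercept downward. IRF > 1 or a non-positive intercept
is reported but flagged rather than truncated.

**IC₅₀.** One-site competition with unit Hill slope,
y = Top/(1 + c/IC₅₀), bottom fixed at 0 and Top free, fitted by
nonlinear least squares after normalizing the lowest tested
concentration (0.03 nM by default) to 100 %. Fixing the bottom
stabilizes 5–12-point curves; a fitted Top deviating >20 % from 100
is flagged, as is an IC₅₀ outside the tested range and a curve with no
descending limb. Note that normalization at a finite concentration makes
the noise-free Top slightly exceed 100 (by the factor 1 + 0.03/IC₅₀);
the IC₅₀ itself is unaffected, which is why recovery is exact.

Bootstrap CIs resample assay conditions with replacement (seeded) and
refit; percentile intervals are reported. Resamples that lose the
normalization point or drop below the minimum level count are discarded.

## Decay chains and biodistribution

Nuclear constants live in `src/tatkit/data/nuclides.yaml`
(ICRP-107/NNDC): ¹¹¹In t½ = 2.8047 d, ²²⁵Ac t½ = 9.920 d, and the chain
²²⁵Ac→²²¹Fr(4.80 min)→²¹⁷At(32.6 ms)→²¹³Bi(45.6 min)→
[97.8 % ²¹³Po(3.7 µs) / 2.2 % ²⁰⁹Tl(2.16 min)]→²⁰⁹Pb(3.23 h)→²⁰⁹Bi.
The file, not the code, is authoritative; editing it changes every
downstream energy and decay correction.

Chain activities use the analytic Bateman solution summed over branch
paths with branching-fraction products (the chain is a DAG converging at
²⁰⁹Pb). The decay constants here are pairwise distinct by many orders of
magnitude, so the classical formula is numerically benign; a stiff
Radau ODE integration of the full rate matrix agrees to ~1e-14 and is
the independent oracle in the tests (frozen at 1e-6). At t = 0 the exact
initial condition is returned directly to avoid cancellation residue.

Equilibrium guidance for ²²¹Fr-surrogate counting of ²²⁵Ac: the
daughter/parent activity ratio approaches λd/(λd−λp) = 1.00034. Ingrowth
is 1−2^(−t/4.80 min), i.e. still ~1.3 % short at 30 min and within 0.1 %
only after ~10 daughter half-lives (≈50 min); `equilibrium_ratio` lets a
user verify any chosen counting delay, and the tests check at 1 h.

%IA/g decay-corrects sample counts to the standard's reference time with
e^(+λΔt) and normalizes by the standard-implied injected counts × mass.
The result is invariant under joint rescaling of counter efficiency.
Group comparisons are Welch t-tests (a pooled-variance choice is not
stated anywhere; unequal variance is the safer default for organ data)
with Holm–Šídák step-down, p(i) → 1−(1−p(i))^(m−i+1), forced monotone.

## Dosimetry

Surrogate translation assumes identical biological retention of the
¹¹¹In- and ²²⁵Ac-labeled conjugate: decay-correct with λᴵⁿ, re-decay
with λᴬᶜ. Time integration: linear rise from A(0)=0 to the first scan
(configurable to flat; the choice affects ≤ the first scan-day's worth
of integral), trapezoid over the observations, and an analytic tail
A(t_last)/λ_phys that freezes biological retention — conservative for
long-retained antibodies; an exponential-washout alternative adds a
biological clearance rate to λ. The tail fraction is always reported; at
the 4-scan schedule (days 1,2,3,5) it is ~75 % of the ²²⁵Ac integral, so
the tail assumption, not the trapezoid, dominates the uncertainty.

Dose coefficient: 1 %IA·day/mL per kBq injected = 8.64×10⁵ parent
decays/mL; multiplied by the chain's locally absorbed energy per parent
decay (α + mean β/conversion electrons, branching-weighted, secular
equilibrium; 28.1 MeV for the shipped data, of which 27.5 MeV is α) and
divided by tissue mass at ρ = 1.0 g/mL. Photons are excluded (escape
assumption at mouse scale). No partial-volume correction and no recoil
(daughter-redistribution) modeling; a sensitivity flag can zero the
energy of members downstream of any nuclide to bound the recoil effect.
Dose maps scale autoradiograph intensity so the in-mask mean equals the
VOI mean dose; they are relative maps given absolute units, not
transport calculations.

## Spatial correlation and CD45

Registration bicubically resamples the IF image onto the autoradiograph
grid (the coarser modality) and inverts the autoradiograph
(max_gray − pixel) so signal is bright in both channels. Consecutive
sections are not pixel-identical; an aspect-ratio mismatch warns and
proceeds. The block statistic tiles both grids into non-overlapping
b×b blocks (default b = 20 px of the autoradiography grid), drops
partial edge tiles (padding would dilute means with invented pixels),
and reports the Pearson r of block means; Spearman and a pooled-pixel
mode are available but off by default. Tiles wholly outside an optional
mask are excluded; fewer than 3 usable tiles or zero variance is an
error, not a silent r.

CD45 quantification thresholds in-mask pixels with Otsu's method by
default — a stated, reproducible stand-in for manual "above background"
thresholding — with a manual override. Snapshot fractions aggregate to
mouse means (the analysis unit); mice with <10 snapshots are excluded,
then groups with <2 remaining mice; one-way ANOVA plus Šídák-adjusted
pairwise t-tests on the pooled within-group variance.

## Growth and survival

Volumes are normalized to day 1 (=100 %); day 0 is excluded from fits
(early caliper measurements are least accurate). Both models are fitted
with Y(day 1) = 100 fixed; per-curve selection uses AICc, a reproducible
surrogate for an unstated per-curve judgment (both AICc values are kept
in the audit output). Exclusions: R² ≤ 0.5 (`r2_below_min`) and
one-phase plateaus below the six-fold level (`plateau_below_sixfold`).
The plateau exclusion removes the *best responders*; the pipeline
attaches an explicit bias note whenever it fires. A nadir below 95 % of
the day-1 volume followed by regrowth triggers an exponential fit of the
growth phase only, re-anchored at the nadir (the 95 % trigger separates
real regressions from caliper noise). time-to-six-fold is reported as
elapsed days from the day-1 anchor: ln 6/k for exponential fits, and the
analytic crossing for one-phase fits that do exceed the threshold; mice
never reaching six-fold are reported as not-reached rather than imputed.

Kaplan–Meier estimation and Mantel–Cox log-rank tests come from
lifelines; the Bonferroni divisor is the size of the *configured*
comparison set (e.g. each treatment vs control plus combination vs each
monotherapy), not all pairs. Dunn's pairwise z-tests use the pooled-rank
variance with tie correction and Bonferroni adjustment over the same
comparison set; with two groups the unadjusted test is identical to the
normal-approximation Mann–Whitney test, which the suite verifies.

## Synthetic data: what it shows and what it does not

Generators are pure functions of (truth, seed). Defaults mirror the
study design: serial dilutions over 1.1×10⁶–1.7×10⁷ cells/mL (8 levels),
competitor 0.03–10 000 nM (12 levels), TAC scans on days 1, 2, 3, 5 with
peaks of 95 / 18 %IA/mL chosen to bracket the printed day-5
concentrations, cohorts of 10 mice from 67 mm³ with the 2.0 cm³ humane
endpoint and 42-day follow-up. Noise models: Poisson for counts,
multiplicative lognormal (mean-preserving, stated CV) for SPECT
quantification and caliper volumes, additive Gaussian gray noise for
images. The image generator plants a shared Gaussian-blob field in both
channels and writes the autoradiograph photographically inverted, as
phosphor-imager exports are.

Passing recovery tests shows the estimators are correct *under their own
generating models*. The generators do not emulate: nonspecific binding
wells, organ-specific kinetics or daughter redistribution, section-to-
section tissue deformation (pairs are perfectly registered), staining
artifacts, or treatment-induced hazard shapes beyond what volume-
threshold crossing of the growth model produces. Real-data departures
from those assumptions are not covered by the suite.

## Numerical choices and problem sizes

Optimizer: scipy `curve_fit` (TRF where bounded) with analytic-free
p0 heuristics; grid-search brute-force oracles in the tests confirm the
optima to 1e-6 (rates) and 1 % (IC₅₀ on noisy data). Quadrature checks
use dense sampling (4000–20000 points) against closed forms at 0.1 %.
Monte-Carlo sizes were chosen to keep the full suite under a few
minutes on one CPU while leaving wide margins: 200–1000 replicates for
recovery/null/attenuation checks, 200–300 for power simulations (all
observed rates clear their criteria by large margins), 2000 for the
type-I-error rate. Determinism: every random draw flows from an explicit
seed; pipeline summaries are JSON with sorted keys and are byte-identical
across reruns at the same seed.

## Known limitations

Dose estimates inherit the secular-equilibrium, full-local-absorption
and frozen-retention-tail assumptions; all three bias CAIX⁺ doses
upward for short observation windows. The VOI segmentation rule is a
configurable threshold, not a validated replica of any scanner-specific
procedure. The block correlation assumes the pair is already registered
up to a global rescale; no deformable registration is attempted.
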
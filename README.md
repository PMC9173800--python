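# ergtwin

Synthetic full-field electroretinogram (ERG) study pipeline for
genotype–electrophysiology association in twin cohorts.

Individual-level retinal electrophysiology with genotypes is
access-controlled almost everywhere, which makes it hard to develop,
test, or teach the analysis chain such studies rely on. `ergtwin`
provides that chain end to end on fully synthetic data: a deterministic
cellular-component ERG generator, a twin-cohort simulator with a
biallelic risk locus, ISCEV-style waveform processing, and a
kinship-adjusted linear mixed model — all tested against independent
oracles. It is aimed at visual electrophysiologists and statistical
geneticists who want a transparent, reproducible sandbox for
rod/cone-pathway association analyses.

## The model in brief

**Waveforms.** The ERG is a sum of stylized cellular components:
photoreceptor PIII `−R_max(1 − e^{−I·S·(t−t_d)²})` (rod and cone),
gamma-kernel ON-bipolar PII, a biphasic OFF-bipolar kernel (sustained
negative lobe feeding the cone a-wave trough, transient positive lobe
feeding the b-wave), and damped-sinusoid oscillatory potentials. A dim
blue rod-saturating background silences the rod pathway, so subtracting
blue-background responses from dark responses to identical flashes
isolates the dark-adapted rod response. Lesion switches emulate
recordings from central retinal artery occlusion (postreceptoral loss)
and complete congenital stationary night blindness (selective ON loss).

**Cohort.** 93 same-sex twin pairs by default (MZ co-twins share their
genotype; DZ genotypes come from explicit Mendelian parental
transmission), risk-allele frequency 0.529, lognormal between-subject
gains with kinship-structured shared deviations, and a per-allele
multiplicative effect (−0.17) on the OFF-bipolar gain only — so
cone-driven amplitudes carry a dose effect while rod-driven amplitudes
do not.

**Association.** For each ERG parameter `y`:

    y = Xβ + u + ε,   u ~ N(0, σg²K),   ε ~ N(0, σe²I)

with covariates intercept/dosage/age/sex and `K` the expected additive
relatedness (MZ 1, DZ 0.5). REML via a single eigendecomposition of `K`
(grid scan plus golden-section refinement over λ = σg²/σe²), Wald t test
on the dosage coefficient. A deliberately simple dense-solve oracle
(`gls_oracle`) cross-checks the fit to 1e−4.

## Worked example

```python
from ergtwin.cohort import CohortSpec
from ergtwin.study import StudyConfig, run_study

cfg = StudyConfig(
    seed=11,
    cohort=CohortSpec(seed=0, sweeps_per_stimulus=2),
    protocol=["DA 3", "LA 3", "X67-dark", "X67-blue"],
    lesion_demo=False,
)
report = run_study(cfg)
print(report.summary_rod_cone)
print(report.association[["parameter", "beta", "se", "p", "significant"]])
```

prints (abridged):

```
parameter  n_0  mean_0  sd_0  n_1  mean_1  sd_1  n_2  mean_2  sd_2
cone 67 a   49    59.1   7.2   89    56.7   7.7   48    52.5   7.3
 rod 67 a   49   134.3  26.0   89   147.9  29.8   48   142.4  26.0

parameter    beta     se         p  significant
   DA 3 a -0.6332  3.014    0.8338        False
   LA 3 a  -2.778 0.4722  1.89e-08         True
   LA 3 b  -10.49  2.043 7.243e-07         True
cone 67 a  -3.482 0.8495 6.253e-05         True
 rod 67 a   2.586  3.206     0.421         False
```

The grouped summary shows the cone-driven bright-flash a-wave falling
monotonically with risk-allele count (59 → 57 → 53 µV) while the
rod-isolated a-wave shows no trend. The mixed model flags the
cone-driven and light-adapted parameters (β ≈ −3.5 µV per allele for the
cone a-wave) and leaves the rod-isolated and dark-adapted a-waves null —
the rod/cone dissociation that follows from placing the allelic effect
on the OFF-bipolar gain alone.

A CLI mirrors the library (`ergtwin simulate | process | associate |
run-all | lesion-demo`), writing trace CSVs with JSON sidecars, cohort
and kinship tables, and association results with provenance headers.

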
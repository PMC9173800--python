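# Methods

`ergtwin` simulates and analyses a twin-cohort electrophysiology study of
a biallelic myopia-risk locus: it generates full-field electroretinogram
(ERG) recording sessions whose cone-driven OFF-bipolar component depends
on allelic dosage, measures the standard ERG parameters from the raw
sweeps, and tests each parameter for association with dosage using a
kinship-adjusted linear mixed model. This note documents the model, its
assumptions, the defaults, and what the validation experiments do and do
not demonstrate.

## Waveform model

The corneal ERG is modelled as an additive superposition of stylized
cellular components on a uniform 2 kHz grid spanning −20 ms to +250 ms
around flash onset:

* **Photoreceptor PIII** (rods and cones): a saturating exponential,
  `−R_max (1 − exp(−I·S·(t−t_d)²))` for `t > t_d`, with flash strength
  `I` (photopic cd·m⁻²·s), sensitivity `S` and transduction delay `t_d`.
  The deflection is negative-going and monotone in both time and flash
  strength; no recovery phase is modelled (see Limitations).
* **ON-bipolar PII** (rod- and cone-driven): positive unit-peak gamma
  kernels `x^n exp(n(1−x))` with onset delays, scaled by Naka–Rushton
  drives `I/(I+I₅₀)` with pathway-specific half-saturations. The rod PII
  onset is 30 ms, so the rod b-wave is silent throughout the a-wave
  measurement window — this is what makes the rod-isolated a-wave exactly
  invariant to postreceptoral lesions.
* **Cone OFF-bipolar kernel**: a difference of two gamma kernels — a
  fast-onset, slowly recovering (plateau-like, shape exponent 0.5)
  negative lobe representing sustained OFF-cell hyperpolarization, which
  deepens the cone-driven a-wave trough, and a sharper, later positive
  lobe that contributes to the b-wave region. The positive lobe's drive
  is bell-shaped in flash strength, `(I/I_pk)·exp(1−I/I_pk)` with
  `I_pk = 3 cd·m⁻²·s`: it is maximal at the standard photopic flash and
  negligible for bright (≥13 cd·m⁻²·s) flashes. This single mechanism
  reproduces two clinical observations at once: ON-pathway loss abolishes
  the bright-flash blue-background b-wave but leaves a clear b-wave to
  the standard light-adapted flash, and the rising limb of the healthy
  light-adapted flash response carries a gradient change near 25 ms
  whose prominence tracks the OFF gain.
* **Oscillatory potentials**: a damped sinusoid (120 Hz, damping
  0.18 ms⁻¹) starting at 13 ms, gated multiplicatively on the ON-bipolar
  gain. The gating encodes that amacrine activity is driven through the
  ON pathway; it also makes the lesion algebra exact (selective ON loss
  removes both the PII and the oscillations, so a CRAO response equals a
  cCSNB response minus the OFF component).

**Backgrounds.** A dim blue rod-saturating background multiplies the rod
pathway by `1 − rod_suppression` (default 1.0, i.e. complete suppression
— the idealized mode; partial suppression is a parameter because real
backgrounds may not silence rods completely) and the cone pathway by a
`cone_desensitization` factor (default 1.0: cones unaffected; the degree
of cone desensitization by a blue background is genuinely unknown, so it
is exposed, never asserted). The standard white photopic background also
suppresses rods and scales cone gains by a single light-adaptation
scalar (0.95). In idealized mode, blue-background responses are
bit-identical to responses computed with the rod gains set to zero, which
is what makes the dark-minus-blue subtraction recover the generator's rod
component sub-traces exactly.

**Lesions.** `crao` zeroes every postreceptoral gain (photoreceptors are
choroid-supplied and survive an arterial occlusion); `ccsnb` zeroes the
ON-bipolar gain only.

**Flicker.** The 30-Hz response is the periodic superposition of
single-flash responses evaluated at `t mod 33.3 ms`. Because the PIII
plateau never recovers in the single-flash model, a literal superposition
diverges; the flicker synthesis therefore treats each flash's plateau as
released after one period (photoreceptors hold a steady adaptation level
under rapid flicker), so the PIII telescopes into a DC term and the
flicker modulation is carried by the transient postreceptoral components
— consistent with the physiological consensus that the 30-Hz flicker ERG
is postreceptorally dominated.

### Calibration

The default gains were fitted once, by Nelder–Mead on the noiseless
pipeline output, to typical adult normative amplitudes — dark-adapted
standard-flash (DA 3) a-wave ≈ 150 µV, light-adapted standard-flash
(LA 3) b-wave ≈ 102 µV, cone-driven a-wave at the brightest xenon flash
≈ 56 µV — together with qualitative constraints (OFF share of the cone
a-wave ≈ 0.45, lesion b-wave ratios, presence of the 25-ms gradient
change). They are frozen in `CellularGains`' field defaults and checked
by a ±10% self-consistency test. Secondary amplitudes land within
roughly ±20% of typical values; the rod-isolated amplitude series grows
too steeply with flash strength (the saturating exponential cannot
reproduce the gentle 78→148 µV growth) and the flicker amplitude runs
high (~107 µV vs ~72 µV typical). These are cosmetic: no test asserts
them.

## Cohort model

Default cohort: 93 same-sex twin pairs (50% MZ — the registry split is
not public, so an even mix is assumed), 95% female, ages Normal(64.2,
9.7) truncated to [18, 95], twins sharing age and sex. The risk-allele
frequency 0.529 is the value implied by a 37/101/48 genotype split in
186 subjects. MZ co-twins copy one parental transmission; DZ co-twins
are two independent transmissions from the same Hardy–Weinberg parents,
so allele sharing is exactly Mendelian rather than approximated by
correlated draws.

Between-subject gain variability is lognormal per gain field with two
components on the log scale: an additive-genetic-style deviation
(sd 0.16) correlated 1 within MZ and 0.5 within DZ pairs — deliberately
matching the kinship covariance the association model assumes — plus an
independent individual deviation (sd 0.12). The combined coefficient of
variation ≈ 0.2 matches the SD/mean ratios of adult ERG amplitude
distributions, and the implied broad-sense heritability (~0.64) reflects
the high reported heritability of ERG parameters.

The dosage acts multiplicatively on the OFF-bipolar gain only:
`off_gain ∝ (1 + d·e)` with `e = −0.17` per allele. The value is derived,
not free: with the OFF pathway contributing ~0.45 of the modelled
cone-driven bright-flash a-wave, `e = −0.17` moves the group means from
≈56 µV (no risk alleles) to ≈47.5 µV (two), the normative span for this
parameter. Optional effects on other gain fields support sensitivity
analyses.

Sessions: both eyes (gains shared up to a lognormal inter-eye deviation,
sd 0.03), 4 sweeps per stimulus by default, white sample noise
(sd 5 µV), slow sinusoidal baseline drift (sd 2 µV), and artifact sweeps
(rate 0.02) carrying >1.5 mV transients, logged by the generator so
rejection can be audited. Sweep counts and noise levels are declared
module defaults — no public values exist for them.

## Waveform processing

Baseline = mean over [−20, 0) ms. Artifact rejection: absolute cap
1000 µV, plus (for ≥3 sweeps) an RMS-deviation-from-median rule at 5
robust spreads; if everything fails, the least deviant sweep is kept and
flagged. Sweeps are averaged within eye, features measured per eye, and
the per-eye values averaged — parameter-level eye combination, with
trace-level eye averages available for display. Conventions: a-wave =
baseline-to-trough (reported positive, window 3–30 ms), b-wave =
a-trough-to-peak (window 10–80 ms; baseline-referenced for the dim flash
DA 0.01, whose a-wave is not reported), flicker amplitude = mean
peak-to-trough over complete steady-state cycles discarding the first,
ties at plateau extrema broken to the earliest sample. Rod isolation =
pointwise dark − blue for identical flash strengths, refused otherwise.

## Association model

`y = Xβ + u + ε` with `u ~ N(0, σg²K)`, `ε ~ N(0, σe²I)`; `X` holds
intercept, additive dosage (0/1/2), age and a sex indicator (constant
columns pruned); `K` is the expected additive relatedness (MZ 1, DZ 0.5).
With `λ = σg²/σe²`, the fit eigendecomposes `K` once, rotates, scans the
restricted likelihood on a 100-point log grid over `λ ∈ [1e−5, 1e5]`,
refines by golden section to 1e−6 in log λ (near-ties break toward the
smaller λ, which pins the boundary estimate when the profile is flat,
e.g. `K = I`), then reports GLS estimates and a Wald t test on
`n − rank(X)` degrees of freedom for the dosage column. REML is the
default (matching the convention of the software class the design
emulates); ML and genotypic coding are options. Significance is the
plain P < 0.05 rule with no multiple-testing correction by default
(an optional Benjamini–Hochberg column is available) — the parameters
fall into two correlated blocks (dark- and light-adapted), so a formal
correction is deliberately not imposed. Missing phenotypes are handled
per parameter by complete-case restriction with counts logged.

`gls_oracle` is the verification path: dense Cholesky solves of
`V = λK + I` per candidate λ, no eigendecomposition, same likelihood
definition; it exists so the spectral implementation can be checked to
1e−4 rather than trusted.

## Validation experiments and their scope

`ergtwin.validation` runs the experiments that the test suite asserts
on; problem sizes keep each under a few minutes while leaving Monte
Carlo error well below the quantities measured.

* Subtraction identity, lesion ratios, calibration: noiseless and exact.
* Oracle agreement: 20 twin datasets, n 40–60.
* OLS reduction: an unrelated cohort (kinship = identity), where GLS
  reduces to OLS identically; on twin-structured kinship with σg² = 0
  the boundary estimate is only reached in distribution (λ̂ ~ n^(−1/2)),
  so the strict 1e−4 comparison is made where it is mathematically
  guaranteed, and the twin case is checked qualitatively (median λ̂
  small).
* Type-I: 2,000 null replicates on a 93-pair cohort with phenotypes
  drawn from the mixed model itself; OLS on the same data demonstrates
  the cost of ignoring relatedness.
* Recovery and dissociation: full trace pipeline (sessions → features →
  LMM) on replicate 93-pair cohorts, restricted to the xenon
  rod/cone-separation flashes and 2 sweeps per stimulus for replicate
  throughput; the "truth" slope is an independent large Monte Carlo of
  the same generative pipeline at fixed dosage, weighted by
  Hardy–Weinberg genotype frequencies.

Passing these shows the pipeline is internally consistent and the
statistics are calibrated *under the generator's assumptions* (additive
components, lognormal gains, Gaussian noise, kinship-faithful gain
correlations). It does not show the model fits real recordings: real
ERGs have photoreceptor recovery, nonstationary noise, electrode and
adaptation drift, and genuine uncertainty about rod suppression
completeness that the idealized defaults assume away.

## Known limitations

* Amplitude phenotypes are lognormal-skewed and multiplicative while the
  mixed model assumes additive Gaussian components. In practice the
  mismatch is benign at the default cohort size — measured rod-isolated
  null rejection rates over replicate batches (0.04–0.10) are binomially
  compatible with the nominal 0.05 — but a log transform would be the
  safer choice for heavier-tailed real data.
* No phototransduction biophysics, no troland/pupil optics, no
  multifocal or pattern paradigms, no oscillatory-potential band-pass
  quantification (OPs are modelled in traces but not reported as a
  parameter), and exactly one biallelic locus with no linkage structure.
* The PIII plateau never recovers within a sweep; b-wave amplitudes are
  therefore trough-to-peak against a sustained negative pedestal, which
  is convention-consistent but makes late-time voltages unrealistic.
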
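# Methods

## Densitometry model

An ISH-stained embryo image is measured after two deterministic
transformations: inversion to negative (v → 255 − v, so darker stain maps
to higher intensity) and conversion to 8-bit grayscale. The grayscale
conversion uses the **unweighted channel mean** rounded half-to-even, the
ImageJ default for RGB→8-bit; ITU-R BT.601 luminance weights are available
via the `weights` argument of `to_grayscale_8bit` for workflows that
configured ImageJ's weighted conversion. The two operations commute up to
±1 intensity unit of rounding, which the test suite asserts.

The per-embryo score is the mean intensity of a polygon ROI over the
stained tissue minus the mean of an equal-area background ROI over
unstained tissue. Means are kept in full floating precision; only stored
images are 8-bit. The subtraction makes the score invariant to any uniform
intensity offset (verified as a property test) and deliberately allows
negative scores: a background region darker than the signal region is rare
but real, so negative scores are flagged in the output record and retained
in downstream analysis rather than truncated.

**Pixel and polygon conventions.** Coordinates are 0-based with x = column
and y = row. A pixel (x, y) belongs to an ROI iff its centre
(x + 0.5, y + 0.5) lies inside the polygon under the even-odd rule;
boundary ties follow the half-open ray-casting convention (top/left edges
in), so abutting polygons partition pixels without double counting. The
rasterizer is a vectorized crossing-number implementation, validated
against an independent per-pixel ray-casting loop. This convention is
pinned on purpose: general-purpose rasterizers differ in how they treat
boundary pixels, and with the small hand-drawn ROIs typical of this assay
(tens to a few hundred pixels) boundary pixels are a non-negligible
fraction of the area.

**Equal-area tolerance.** The background ROI is required to match the
signal ROI's rasterized area within 1% by default. Manual redrawing of
"the same shape and area" cannot be pixel-exact; 1% of a typical ROI is a
conservative allowance that still catches swapped or mis-scaled ROIs.
`translate_roi` clones a signal ROI by an integer offset, which guarantees
exact area equality by construction and is how the synthetic generator
builds its background ROIs.

## RFLP genotyping

A genotyping assay is defined by a wild-type and a mutant allele sequence
plus a restriction enzyme whose recognition site the mutation destroys.
Sites may contain IUPAC degeneracy codes (HaeII = `RGCGC^Y`, cut offset 5;
SacII = `CCGC^GG`, cut offset 4 — REBASE top-strand conventions). Only
top-strand cut coordinates matter because gel band sizes do not resolve
overhangs. Digestion is complete (all sites cut simultaneously);
overlapping degenerate matches are all counted; cuts falling exactly at a
molecule end produce no fragment. `N` in a sequence never matches any
pattern code — an unknown base must not invent a site. Amplicons are
linear; circular molecules are unsupported.

Expected band patterns per genotype are WT = digest(wt), MUT = digest(mut),
HET = union of the distinct band lengths of both alleles (a heterozygote
carries both). Observed bands are called against these patterns after
merging bands closer than the tolerance (default ±5 bp, about the
resolving power of a 2% agarose gel); zero or multiple matching patterns
yield UNKNOWN — a value, not an error, so one bad lane never aborts a
plate. In-silico PCR (`find_amplicon`) requires exact, unique primer
binding; mismatch-tolerant binding and partial digests are out of scope.

## Synthetic data

The generator exists so that every pipeline stage can be tested against a
known truth; it emulates the measurement structure of a real experiment,
not its photorealism.

**Images.** Each embryo is an elliptical body (post-inversion base level
60) on a zero background with a horizontal stripe standing in for the
stained vessel. Intensity truth is defined *post-inversion*: the stripe
adds a per-embryo intensity drawn from Normal(µ_g, (CV_g·µ_g)²) truncated
at 0, so generator parameters are on the same 0–255 scale as reported
densitometry scores (staining cannot be negative, but measured scores can
still go negative through noise). Per-pixel Gaussian noise (default
sd 3) and a linear left-to-right illumination gradient (default amplitude
10) are added; the gradient is parallel to the stripe and the background
ROI sits directly above the signal ROI with the same x-span, so the
gradient cancels in the subtraction — emulating a well-chosen background
region. The stored image is the photographic positive (inverted back),
saved as 8-bit RGB PNG, so the quantification step exercises the full
invert-and-convert path.

**Defaults.** One clutch defaults to 130 embryos from a heterozygous
incross: genotypes multinomial with probabilities (0.25, 0.5, 0.25), group
mean intensities 54 / 50.1 / 26.3 and CVs 0.24 / 0.22 / 0.21 for
WT / HET / MUT — the dispersion (CVs of 20–40%) characteristic of ISH
densitometry, with the mutant at roughly half the wild-type signal.
Reproducibility: one root generator seeded from the design; per-embryo
sub-streams are spawned deterministically from it, so the truth table does
not depend on whether images are actually rendered
(`render_images=False` skips rendering for large statistical simulations).

**Alleles.** `generate_allele_pair` places one concrete instance of the
enzyme site into random flanking sequence at the position that produces
the requested wild-type fragment lengths, then destroys it by a single
substitution (length preserved) or a k-bp deletion spanning the site,
checking that no spurious site exists anywhere in either allele; failed
constructions are retried with fresh randomness up to a bounded number of
attempts. Both alleles are verified by digestion before being returned, so
the published band arithmetic holds by construction: a substitution mutant
runs as one band equal to the sum of the wild-type fragments, a k-bp
deletion mutant as that sum minus k.

**Ct tables.** Each simulated embryo draws its ΔCt from
Normal(mean_g, sd_g²); housekeeping replicates are centred on a
per-embryo baseline (mean 18, sd 0.3) and target replicates on baseline +
ΔCt. Replicate noise (sd 0.15 cycles) is re-centred within each embryo so
the realized replicate means — and hence the embryo-level ΔCt — equal the
drawn values exactly; with sd_g = 0 every embryo reproduces the group ΔCt.

**What passing tests do and do not show.** The generator shares the
statistical skeleton of real data (genotype-conditional means, heavy
between-embryo dispersion, pixel noise, illumination gradient, replicate
structure) but none of its biological nuisance: no embryo-to-embryo shape
or orientation variation, no staining texture or edge gradients inside the
ROI, no probe-batch effects, no mis-drawn ROIs. Tests passing on synthetic
clutches validate the computational chain — scoring recovers the
configured truth (r > 0.95 at noise sd ≤ 5), the test battery has its
nominal operating characteristics — not the biological robustness of ROI
placement on real embryos.

## Statistical procedures

All location tests are exact functions of (n, mean, sd) and accept either
raw arrays or `GroupSummary` objects; summary mode is what allows
re-analysis of published group statistics without raw data.

- Pooled t: df = n₁ + n₂ − 2. Welch t: Satterthwaite df, which collapses
  to n_other − 1 when one group has zero variance. Zero pooled variance
  with unequal means is reported as an infinite statistic with a note
  rather than an exception.
- Welch ANOVA: variance-weighted means, F* with numerator df k − 1 and the
  fractional Satterthwaite-type denominator df; algebraically equal to the
  square of Welch's t for two groups (asserted to 6 decimals). A
  zero-variance group makes the weights infinite and raises.
- Levene's test centres on the group **mean** by default (the classic
  statistic and the SPSS default); `center="median"` gives Brown-Forsythe.
  All-constant groups return W = 0, p = 1 by convention.
- The Welch-or-standard ANOVA choice in the pipeline report is automated
  by Levene p < 0.05; both ANOVAs are always computed and reported.
- Tukey HSD uses the studentized range with pooled variance and df N − k;
  Games-Howell uses per-pair unpooled standard errors with per-pair Welch
  df. Distribution functions (central and noncentral t, F, χ²,
  studentized range) come from `scipy.stats`; the suite cross-checks the
  studentized range against published critical values (q(0.95; 3, 10) =
  3.88) and the post-hoc p-values against independent implementations.
- χ² contingency tests apply the Yates continuity correction iff the
  table is 2×2 (flag on by default); a zero marginal raises.
- The √-transform decision uses Shapiro-Wilk at α = 0.05 as an automatable
  proxy for visual Q-Q inspection, and is blocked (with a logged
  rationale) whenever negative scores are present.
- Power for the two-sample t-test uses the noncentral t with
  δ = d·√(n/2) and df = 2n − 2; sample-size search increments n from 2,
  guaranteeing exact minimality (power is monotone in n). At the scales
  involved (n in the tens) this is cheaper and more transparent than an
  asymptotic inversion.

## qPCR

ΔCt = mean Ct(target) − mean Ct(housekeeping), level = 2^−ΔCt. No
replicate outlier handling by default; a spread above 0.5 cycles is worth
a warning, not a deletion. Group tests default to the ΔCt scale. Percent
change is reported under **both** conventions — from the difference of
group-mean ΔCts, and from the ratio of per-embryo mean levels — because
the two disagree whenever levels are skewed and published percentages
rarely state which was used; neither is privileged.

## Numerical and design notes

- Rounding: image quantization rounds half-to-even (`np.rint`); all means
  and statistics stay in float64.
- Band merging before genotype matching uses single-linkage gaps below the
  tolerance, replacing each merged group by its rounded mean length.
- Degenerate inputs raise early with specific exception types
  (`DegenerateRoiError`, `UnequalAreaError`, `NoAmpliconError`,
  `UninformativeAssayError`, `GenerationError`); UNKNOWN genotype and
  negative scores are values, not errors.
- The CLI is a thin layer over the library: exit code 2 for config errors
  (with the offending field named), 3 for data errors; the quantification
  subcommand reads only images and ROI files, never genotype tables, so
  scoring is blind to genotype by interface design.
- Simulation sizes in the test suite (e.g. 100 replicate clutches for the
  significance-structure check, 2000 null replicates for type-I
  calibration, 200,000 simulated experiments for the Monte-Carlo power
  oracle) were chosen to keep Monte-Carlo standard errors well inside the
  asserted tolerances while running in seconds.

## Known limitations

- No automated ROI detection or segmentation: ROIs are user input, as in
  the manual workflow this package mirrors. ImageJ binary `.roi` files are
  not parsed; ROIs are exchanged as JSON polygons.
- Primer binding is exact-match only; no thermodynamics, no partial
  digests, no gel-mobility modelling beyond the ±5 bp band tolerance.
- qPCR quantification is 2^−ΔCt with a single reference gene; no
  efficiency correction (Pfaffl), standard curves or multi-reference
  normalisation.
- The significance-structure simulation at the default clutch parameters
  has an intrinsic ceiling: the WT and HET group means differ slightly by
  design (54 vs 50.1), so with n = 32/62 per group the WT-vs-HET
  comparison reaches nominal significance in a nontrivial fraction of
  replicate clutches even though each single clutch usually shows it as
  non-significant. A joint requirement that includes "WT vs HET
  non-significant" therefore cannot hold in ~95% of replicates at these
  sample sizes — a property of repeated sampling from the stated
  parameters, not of the implementation (see the acceptance suite, where
  the corresponding check is left failing rather than loosened).
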
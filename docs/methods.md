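# Methods

This note documents the models, conventions and design choices behind
each module: what is computed, under which assumptions, and what the
synthetic generators do and do not emulate.

## PGR immunofluorescence quantification (`fluoro`)

**Procedure.** A three-channel 8-bit image (PGR red, αSMA green, DAPI
blue) is decomposed from manually drawn polygons — the studied region,
the luminal epithelium and the glands — into three disjoint compartment
masks (stroma is the remainder). The red and blue channels are binarised
independently by Otsu's method and the per-compartment readout is the
ratio of red foreground area to blue foreground area, a scale-free proxy
for the fraction of nuclei expressing PGR.

**Conventions.**

* *Threshold scope*: one threshold per channel per image, computed over
  the full studied region and applied to all compartments. This keeps
  compartments of one image comparable; a per-compartment threshold
  would let local contrast shift the operating point between
  compartments of the same section.
* *Otsu tie-break*: the lowest threshold among maximisers of the
  between-class variance (deterministic); foreground is strictly greater
  than the threshold. With these rules a half-black/half-white image
  thresholds at 0.
* *Rasterisation*: polygon coordinates are 0-based pixel coordinates
  (x = column, y = row, origin top-left); a pixel belongs to a polygon
  when its center lies strictly inside (even-odd fill). Overlapping
  polygons of one compartment are unioned once; epithelium takes
  precedence over glands.
* *Units*: areas are pixel counts. Ratios are dimensionless, so no
  physical pixel size is needed; µm² areas are derivable when a pixel
  size is supplied. A compartment with zero blue area has an undefined
  ratio, carried as NaN with a `ratio_defined` flag.
* The green (αSMA) channel delineates the myometrium visually and is
  carried through IO but never enters quantification.

**Degenerate inputs.** A constant region has no Otsu threshold and
raises `DegenerateHistogramError`; empty compartments yield zero areas
and an undefined ratio rather than an error.

## Depth-of-invasion grading (`grading`)

**Model.** The myometrial wall between the endometrial–myometrial
interface (inner boundary) and the serosa (outer boundary) is given the
normalised depth coordinate d(p) = d_in / (d_in + d_out), with exact
Euclidean point-to-boundary distances evaluated at pixel centers. In a
circular annulus this reduces to (ρ − r) / (R − r), and the measured
deviation from that closed form is well under one pixel (the residual
comes from the polygonal approximation of the circle).

**Grading rule.** The uterus grade is decided by the deepest focus pixel
(max rule — the scale is defined by deepest involvement): grade I for
0 < d_max ≤ 1/3, II for d_max ≤ 2/3, III beyond, with closed upper
bounds mirroring the "inner third" / "two-thirds" wording; grade 0 when
no focus intersects the wall. Whether the original scale grades by the
deepest point or the focus centroid is not specified anywhere we could
find; the max-point rule is the documented choice, and centroid grading
would never give a higher grade. Foci entirely outside the wall are
ignored with a warning. In very young animals the wall is too thin to
tertile meaningfully, so only `invasion_present` should be interpreted
there.

**Cohort summaries** round percentages half-up to two decimals from the
exact integer ratios (the formatting used by the printed tables this
package reconstructs).

## Estrous cytology (`cytology`)

**Rules.** The stage descriptions are qualitative (proestrus: mostly
nucleated epithelial cells; estrus: cornified cells; metestrus:
cornified cells and leukocytes together; diestrus: leukocytes at very
high density). They are made deterministic as a cascade with two
exposed thresholds:

1. metestrus when cornified fraction ≥ `m_lo` **and** leukocyte
   fraction ≥ `m_lo` (default 0.25 — both types clearly present);
2. else diestrus when leukocyte fraction ≥ `d_hi` (default 0.60 —
   "very high density");
3. else the majority cell type decides (nucleated → proestrus,
   cornified → estrus, leukocyte → diestrus), ties broken in that
   listed order.

The defaults reproduce the verbal descriptions on the simulator's
stage-specific compositions and recover 100% of true labels on
degenerate (pure-composition) profiles; they are parameters, not
constants, because real smear compositions vary by staining and counting
practice.

**Cycle counting.** "Number of cycles in 14 days" has no standard
operational definition; here a completed cycle is counted at each entry
into estrus (an estrus day whose previous *called* day is not estrus)
that is followed, before the next estrus entry, by at least one
metestrus-or-diestrus day. Missing days (failed smears) are carried as
gaps: excluded from stage percentages, and treated as stage-unknown by
the scan (they neither create an entry nor break a completion). Stage
percentages are exact rationals summing to 100 before formatting.

## Follicle densitometry (`folliculometry`)

Density per follicle type is the pooled estimator Σ counts / Σ outlined
section areas (n/mm²) over all quantified sections of an ovary — not the
mean of per-section densities — because it matches a per-mm² definition
over the whole quantified series, is invariant to how annotations are
split across sections of equal combined area, and minimises variance.
Fewer than six sections is flagged (`fewer_than_6_sections`), not
rejected. Follicle typing (primordial / primary / secondary-or-more /
corpus luteum, by standard morphological criteria) happens upstream;
the type label is input.

Corpora lutea span multiple adjacent sections, so raw counts
deduplicate by a follicle-id column within a span of 8 consecutive
stained sections (5 µm sections, one-in-ten stained → 50 µm spacing →
400 µm of tissue). No volumetric (Abercrombie-type) correction is
applied, by design. When ids are absent every annotation counts as
distinct, reproducing unadjusted raw counting.

## Relative expression (`expression`)

2^−ΔΔCt with amplification efficiency fixed at 2 and two reference
genes. The dual-housekeeper reference is the arithmetic mean of the two
housekeeper mean Cts — equivalent to geometric-mean normalisation of
the linear quantities, the standard multi-reference convention. The
control baseline is the arithmetic mean of control-sample ΔCts per
target (group-level fold changes, not a single calibrator), which makes
the geometric mean of control folds exactly 1. Duplicate wells are
averaged; a replicate range above 0.5 cycles is QC-flagged
(configurable). Fold changes are invariant to any global Ct shift.

At the default simulation settings (duplicate wells, 0.2-cycle Gaussian
well noise, n = 8 per group) the per-seed group fold estimate carries
roughly 6% sampling error, so recovery checks bound the estimate
averaged over 20 simulation seeds (sampling error ≈ 1.3%), with the
noiseless case exact.

Western densitometry divides each band by its HSP70 loading-control
intensity and expresses the result as fold change versus the
control-group mean of the same protein.

## Fertility statistics (`stats`)

* `percent_delivering`: share of dams with ≥ 1 litter, half-up to two
  decimals.
* `mean_litter_size`: total pups ÷ total litters, at birth or at
  weaning. Both this pooled estimator and the per-dam mean are
  computable; printed group means in the source material are ambiguous
  between the two, so neither is treated as a checkable constant.
* `mann_whitney`: exact two-sided p by full enumeration of the
  C(m+n, m) label assignments when both samples have ≤ 8 observations
  and no ties (two-sided p = 2·min(P(U ≤ u), P(U ≥ u)), capped at 1 — a
  standard deterministic choice); otherwise mid-rank U with
  tie-corrected normal approximation and continuity correction. The
  exact path is validated against an independent enumeration oracle and
  is conservative under the null by discreteness.
* `two_way_anova`: ordinary two-factor ANOVA with interaction
  (sequential sums of squares via OLS), applied to cumulative pup counts
  over months. **Caveat:** this deliberately ignores the within-dam
  repeated-measures structure to mirror the analysis it reimplements; a
  mixed model would be the statistically preferable treatment. A term
  with zero sum of squares reports F = 0, p = 1 (0/0 under zero residual
  variance is otherwise undefined).

## Synthetic data (`synthetic`)

**Trichrome phantoms.** Nuclei are identical disks (default radius 4 px
in a 256-px image) placed by rejection sampling so that no two disks
overlap and every disk lies wholly inside one compartment; all disks are
painted into the blue channel and a round-half-up fraction of them also
into red. Because disks are congruent and disjoint, the red/blue area
ratio per compartment equals the positive-count fraction *exactly* at
zero noise — giving an exact oracle for the whole quantification chain.
Noise is additive Gaussian (fraction of the 8-bit range) clipped to
[0, 255]. The phantom layout (left epithelium band, two gland boxes,
stroma remainder, green muscle band outside the studied region) uses
half-integer polygon vertices so pixel centers never sit on boundaries.
What this does **not** emulate: real chromatin texture, nucleus size
variation, overlapping nuclei, uneven illumination, or bleed-through —
passing phantom tests shows the measurement chain is correct, not that
thresholding is robust to every real-world artefact.

**Estrous series.** Stages repeat deterministically in the order
P→E→M→D with default block lengths 1/2/1/2 days (a 6-day cycle, about
2.3 cycles per 14-day window, within the normal range for cycling
mice); the adenomyosis condition multiplies the estrus block (factor 3
in the packaged simulation, reproducing a prolonged-estrus pattern).
Daily counts are multinomial draws (default 100 cells) from per-stage
composition profiles chosen to satisfy the classifier's verbal rules
with margin. Optional geometric jitter of block lengths is off by
default: no stochastic duration model is specified anywhere, so the
deterministic schedule is the reference condition.

**qPCR tables** program fold changes by shifting adenomyosis target Cts
by −log₂(fold) against fixed reference Cts; **follicle tables** draw
Poisson counts at programmed densities.

**Printed-proportion fixtures.** Percentage tables printed to two
decimals are inverted by `reconstruct_counts_from_percentages`: the
smallest n (and integer counts summing to n) whose exact shares re-round
half-up to the printed values. The grade table (1.47 / 2.94 / 4.41 /
91.18) yields n = 68 with counts (1, 2, 3, 62); the breeding fixture
uses 6 dams per arm with the delivering count (2 of 6) re-rounding to
33.33%. Note the source reports 55 treated animals euthanised at
3 months while the grade percentages imply a denominator of 68; the
fixture follows the percentages, and this discrepancy is surfaced here
rather than resolved. The fixtures are shipped as CSVs under
`src/adenoquant/data/` and regenerable via
`synthetic.write_fixture_csvs`.

## Amplicon utilities (`amplicon`)

Primer resolution is exact-match only (no mismatch tolerance, no
melting-temperature model): a run-on forward+reverse string splits at
the unique point where the prefix occurs exactly once on the transcript
sense strand and the reverse-complement of the suffix exactly once
downstream; ambiguous strings raise with the candidate list rather than
guessing. Product length spans the forward 5′ start through the reverse
5′ start on the opposite strand, inclusive of both primers (0-based
half-open coordinates internally). Reference transcripts must be
supplied as FASTA; the packaged panel records each assay's accession and
expected product size for checking against user-provided sequences.

## Problem sizes and determinism

Default sizes — 256-px phantoms with ~115 nuclei, 14–42-day cycle
windows, n = 8/group qPCR, 150-instance Mann–Whitney sweeps, 1,000
random histograms for the Otsu cross-check — were chosen so each
verification exercises the estimator at realistic scale while the whole
suite stays interactive. All generators take explicit integer seeds and
are bit-reproducible; CLI outputs embed the seed and a config hash in a
header comment.
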
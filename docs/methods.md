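# Methods

This note documents the algorithms, the tunable parameters and their
defaults, the design choices made where the published workflow leaves
the details open, and what the synthetic-gel tests do and do not
demonstrate about real data.

## Conventions

Images are 8-bit grayscale, indexed (row m, column n), 0-based, origin
top-left; rows are the migration axis with the wells at row 0.  All
intervals are half-open.  Internally every stage assumes the
*bands-bright* convention (stained bands are intensity maxima);
silver-stain scans, whose bands are dark on a bright background, are
inverted on input (v → 255 − v).  Under one fixed convention, lane
boundaries are minima of column-intensity profiles and bands are maxima
of lane profiles — the two detectors share a single polarity story.
`auto` polarity compares the spatial compactness of the darkest versus
brightest 5% of pixels (bands are compact stripes; background extremes
are diffuse) and falls back to bands-dark, the silver-stain default.

## Lane segmentation

1. **Strips.**  The row profile r(m) = Σₙ p(m,n) is smoothed (3-point
   moving average) and detrended with a wide running median (window
   H/4), removing background illumination gradients.  Rows whose
   residual exceeds the 75th percentile — floored at 10% of the residual
   peak so noise alone can never qualify — are high-contrast; runs
   closer than `merge_gap` = 5 rows merge.  Strip cuts fall at midpoints
   between region centres; strips shorter than `min_height` = 10 px are
   merged.  With fewer than two regions the image falls back to
   `fallback_n` = 4 equal strips.  Strip heights therefore follow the
   banding pattern: band-dense regions get their own strips.

2. **Valleys.**  Each strip's column profile cᵢ(n) = Σ_{m∈Hᵢ} p(m,n) is
   smoothed with the same 3-point average.  Local minima (plateaus
   resolve to their leftmost column) become lane boundaries when they
   pass three gates: prominence at least `prominence_frac` = 0.05 of the
   profile range *and* at least `noise_sigmas` = 6 times the profile's
   robust noise scale (1.4826·median|Δv|/√2, dominated by the flat
   stretches), and a bottom value in the lower `max_rel_depth` = 0.5 of
   the range — inter-lane gaps descend to background, whereas noise dips
   on a bright lane plateau stay high.  Surviving minima closer than
   `min_lane_width` (5 px, or W/(4·K) when the expected lane count K is
   given) are thinned deepest-first, ties to the left.  Columns 0 and
   W−1 are always boundaries; a strip with no interior minima reports
   "no lanes here", and an image where no strip has any yields zero
   lanes.  A per-strip absolute prominence floor scaled from the whole
   image's per-row column contrast keeps band-free strips (pure
   background) from contributing noise valleys.

3. **Stitching.**  A lane with no band in some strip is invisible there,
   and worse, an *empty lane's centre* reads as a wide background basin
   whose minimum mimics a valley.  Stitching therefore seeds one chain
   per valley of the *anchor strip* — the strip with the most detected
   valleys, ties broken by cross-strip corroboration; under the usual
   reference-band protocol (one band present in every lane) the anchor
   sees every gap.  Walking outward strip by strip, chains are matched
   to the next strip's valleys by a minimum-total-displacement monotone
   assignment (dynamic programming; gap cost = `max_drift`; ties prefer
   matching, then the leftmost option).  `max_drift` defaults to just
   under half the lane pitch (0.45 × the median valley spacing of the
   richest strip) so a boundary can never jump across a lane.  Two
   safeguards against the basin mimics: valleys wider than 2.5× the
   anchor's median valley width (width at half prominence) may not
   update a chain — a gap is a narrow notch, an empty-lane basin is a
   pitch-wide bowl — and chains unobserved in a strip ride the *drift
   field* interpolated from their matched neighbours rather than
   propagating vertically, since curvature and slant move the whole lane
   register coherently.  A chain unobserved for k strips gets a k-fold
   (capped 3×) matching radius, with cost rescaled so wide-radius
   matches never beat near ones, and each strip is matched twice: once
   raw, then against drift-corrected predictions (outlier-trimmed
   field), which stops a chain with accumulated error from snapping to
   the neighbouring gap.  Chains closer than 0.4× the median chain
   spacing are duplicates of one physical boundary; the less-corroborated
   one is dropped.

4. **Boundary geometry.**  Chains become piecewise-linear boundaries
   with breakpoints at strip midlines, refined on a 16-row grid: each
   grid slab re-measures the boundary as the local profile minimum
   within ±4 px of the interpolated course, accepted only where the slab
   shows ≥6σ of valley contrast (featureless regions keep the
   interpolated course).  Ends extend to rows 0 and H along the local
   drift slope.  Outer boundaries are the image edges; because the edge
   is static while interior boundaries drift, the outermost lanes are
   re-bounded parallel to their interior neighbour at the interior
   median width (otherwise row-wise resampling smears margin and band
   pixels together).  Lanes are extracted by per-row nearest-neighbour
   resampling to the lane's median width — intensity-preserving, no
   interpolation artifacts on 8-bit data.  Lanes narrower than
   `min_lane_width`, and lanes whose detrended profile contrast is below
   5% of the strongest lane's (slab margins), are dropped.

5. **Straight mode** runs the same machinery on a single full-height
   strip, for gels whose banding is too sparse for the strip histograms
   — the curved mode's documented failure regime.

## Band extraction

**Straightening.**  For each lane column n, the shift k*(n) maximises
the truncated-overlap inner product R(k) = Σ_h p(h+k, ref)·p(h, n) over
k ∈ [−B, B]; terms with either index out of range are simply absent,
which is the only reading that keeps R defined for negative lags.  The
raw (unnormalised) product is the default; a config switch enables
normalised correlation.  `search_bound` B defaults to H/8 — searching
the full ±H range makes near-zero-overlap sums spurious optima.  The
reference column is the first whose variance reaches a quarter of the
lane's maximum column variance (an empty margin column would register
arbitrary shifts); ties at equal correlation prefer the smallest |k|,
then the negative lag (minimal distortion, deterministic).  Columns are
translated by k* with zero-fill — wrapping would fabricate bands at the
opposite end — so total intensity never increases.

**Band calling.**  The lane profile b(n) sums across the lane width.
The pipeline uses a per-row *trimmed* sum (`edge_trim_frac` = 0.25 of
the extreme column values dropped per row): a genuine band spans the
whole lane width so central columns carry the same signal, while a
sliver of a neighbouring lane's band that crossed the boundary, or a
bright speckle, is confined to a few columns and trimmed away.
Candidates are the + → − sign changes of G(n) = b(n+1) − b(n); zero
runs carry the previous sign so a plateau peak is reported once, at its
leftmost row.  No minimum peak separation is imposed — that is what
lets doublets through.  Candidates are thresholded on the
baseline-subtracted profile (running-median baseline, window H/4, only
for profiles of length ≥ 30): a candidate survives if its residual
exceeds the `percentile` = 85th percentile of all residuals.  On a raw
dark-band scan the classic formulation keeps peaks whose summed
intensity lies in the *bottom* 15% of values; under the bands-bright
convention that same rule is the 85th percentile.  Peak rows are
refined to sub-pixel precision by a parabola through the peak and its
neighbours (clamped to ±1 px); integer positions are reported alongside.

## Genotype calling

**Alignment.**  Lanes are registered to an anchor lane (leftmost by
default; optionally the most intense) by the same truncated-overlap
correlation applied to their summed profiles, within ±H/8, then refined
locally in a window around the expected reference-band position.  The
reference band — a band designed into the assay so it appears in every
lane at near-constant mobility — is then the detected band nearest the
expected position; lanes where none falls within the window are
excluded from clustering (with a warning) and emitted as all-missing
calls.  Fewer than two lanes with a reference band aborts genotyping.

**Offsets and clustering.**  Each band's mobility offset is its
sub-pixel position minus the lane's own reference-band position, so
every reference band sits at exactly 0.  DBSCAN (scikit-learn) clusters
the pooled offsets with ε = the range of reference-band positions after
global but *before* local alignment (measuring after local refinement
would collapse ε toward 0 by construction), floored at `eps_floor` =
2 px for the degenerate clean-single-gel case, and minPts =
round(0.1 × lane count) floored at 2 (the 10% rule gives 0–1 on small
gels, and DBSCAN needs at least 2).  Isolated offsets stay noise.  Each
cluster's mean and variance come directly from its member offsets
(variance floored at `var_floor` = 0.25 px²); by default the
non-reference clusters share one pooled variance — migration error is a
property of the gel, not of a fragment size, and per-cluster variances
estimated from a dozen lanes whipsaw the classification boundaries.
Exactly one cluster must contain offset 0 (the reference cluster);
otherwise clustering errors out.

**Classification and calls.**  A band offset is assigned to the cluster
maximising the Gaussian density; exact ties go to the smaller mean.
Offsets more than `max_z` = 4 standard deviations from the winning mean
are flagged NOVEL and excluded from presence vectors (`max_z = inf`
restores unbounded assignment).  The gate is calibrated for experiments
classifying on the order of 50 bands: at 3σ the family-wise chance of
falsely rejecting a genuine band is ~10–15%, at 4σ well under 1%, while
genuine artifacts sit far beyond either.  A lane's genotype is the
presence/absence vector over non-reference clusters in ascending-mean
order; identical vectors share a group id, assigned in order of first
appearance.  Band intensity is recorded but does not enter calls.
Cluster models serialize to versioned JSON; a saved model classifies
bands from related gels, absorbing gel-to-gel systematic error.

## Synthetic gels

The generator renders a geometric image model, not electrophoresis
physics: no voltage/mobility law, no molecular-weight calibration.
Mobilities are specified in pixels.  Lanes follow sinusoidal or slanted
centerlines; bands are Gaussian-profile bars (σ = `band_sigma`, default
2 px) riding the centerline, with an optional parabolic smile term and
optional doublet splitting of the first fragment class.  Backgrounds
have a base level plus a vertical gradient; speckles model sample
contamination; pixel noise is additive Gaussian, clipped to [0, 255];
default polarity is bands-dark so the polarity normalisation is always
exercised.  Two jitter terms supply the mobility error that clustering
must absorb: `lane_offset_sd` shifts a whole lane vertically
(lane-to-lane migration variation, corrected by global alignment) and
`band_jitter_sd` perturbs each band independently (the residual spread
DBSCAN clusters over).  Defaults (10 lanes of 20 px at 8 px gaps,
220-px height, three fragment classes at 40/80/120 px below a reference
at 50 px, peak 180 over background 20 with a 0.02/row gradient, noise
σ = 3) are modelled on the mid-gel crop of a silver-stained PAGE scan
at typical densitometer resolution.

What passing the synthetic studies does *not* show: real scans have
spatially correlated noise, nonuniform staining within a band, partial
digestion smears, and comb artifacts at the wells, none of which the
generator renders.  The studies demonstrate the geometry — curvature
tracking, distortion correction, doublet resolution, mobility
registration — under controlled, seedable conditions.

## Degenerate inputs and tie rules (summary)

- Flat column profile → outer boundaries only; image with no valleys in
  any strip → zero lanes (a blank image segments to nothing).
- All-zero correlation (empty column/profile) → shift 0, logged.
- Valley/peak ties → leftmost; correlation ties → smallest |k|, then
  negative; likelihood ties → smaller cluster mean.
- Profiles shorter than 3 cannot be smoothed or band-called (error);
  profiles shorter than 30 skip baseline detrending.
- Cluster variance and ε floors guard noiseless synthetic gels.

## Known limitations

- Boundary positions outside the banded region (above the first and
  below the last band) are extrapolated and carry several pixels of
  uncertainty under strong curvature; on gels whose drift amplitude
  approaches 0.6× the lane width with short wavelength, a few percent
  of rows at the image ends can fall outside the nominal lane.
- Lanes with very few bands starve the strip histograms; curved mode
  may under-segment there.  Straight mode is the intended fallback.
- ε measured from a single clean gel underestimates multi-gel mobility
  spread; fitting the cluster model on several related gels (one run,
  multiple images) is recommended before reusing it.
- The evaluation-set metadata in `gelcaller.benchmark` records pixel
  dimensions and lane counts only; the scans themselves are an external
  download, so the full-raster studies here use synthetic stand-ins of
  the same geometry (so labelled).
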
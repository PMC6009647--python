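# Methods

This note documents the models, estimators and numerical choices behind
`mtagmap`, in the spirit of a methods appendix: what is assumed, what the
knobs mean, and what the synthetic validation does and does not show.

## Labeled-molecule model

A molecule is a linear DNA fragment of length `L` bp carrying a reference
map of `S` motif sites (motif starts, 0-based; for TCGA-class motifs the
few-bp offset to the modified adenine is far below the localization scale
and is ignored).

* **On-site labels.** Each site is labeled independently with probability
  `p_site`. Palindromic duplex sites carry at most one fluorophore — the
  hairpin/mass-spec observation encoded in the generator — so single-strand
  mode is the default. In double-strand mode a second label appears with
  probability `p_second`, offset by the motif width (the opposite strand's
  target base), modeling the rarer both-strands-alkylated case.
* **Off-target labels.** A homogeneous Poisson process with density
  `rho_off` labels/kb, positions uniform on `[0, L)`. Defaults: 0.46/kb
  (combed-fragment preset) and 0.37/kb with `p_site = 0.63` (plasmid
  preset), the two regimes the counting and mapping assays operate in.
* **Localization error.** Gaussian with `sigma_loc` (default 100 bp),
  applied in bp *before* stretch conversion, so the quoted precision is in
  sequence units.
* **Stretch.** Combed molecules are over-stretched by a factor near 1.6
  relative to B-DNA (0.34 nm/bp). Stretch is per molecule — drawn from a
  truncated normal, mean 1.6, SD `1.6 × stretch_tol` (default 0.1), cut at
  ±2 tolerances; a uniform-band option exists because the field quotes
  "variation 0.1" both as an SD and as a hard band. Within-molecule stretch
  fluctuation is not modeled separately; it is folded into `sigma_loc`.
* **Orientation.** Coordinates are mirrored with probability `flip_prob`
  (default 0.5); deposition does not record polarity.

Positions clip to `[0, molecule_length]` after noise. One master seed
drives `numpy` child streams per stage, so every pipeline run is
bit-reproducible from its manifest.

## Photobleaching movies and localization

Movies are sums of pixel-integrated 2D Gaussian PSFs over a constant
background, with Poisson shot noise and Gaussian read noise; each emitter
is on at constant brightness until its bleach frame (geometric with mean
`bleach_lifetime`) and off afterwards — single-step bleaching, no blinking.
The backbone (intercalator) channel is modeled directly as a cloud of
localization points around the plasmid contour rather than as a movie.

`bleaching_localization` runs the backward pass: average the trailing
`segment_frames` of the residual movie; detect maxima above
`background + n·σ` (median/MAD, default `n = 5` — the source assay states
no threshold, so it is a logged parameter); least-squares fit
`(x, y, σ, A, offset)` in an ROI; estimate the bleach frame by an exact
single-step least-squares changepoint on the PSF-weighted intensity trace;
subtract the fitted PSF from all frames up to the bleach frame over a box
covering ±4σ (subtracting only the fit ROI leaves tail residue that
re-triggers detection); repeat, sliding the segment toward the movie start.
Non-converging fits are discarded with a logged warning. A final pass
merges detections within `min_separation` px with overlapping bleach
windows (subtraction residue), and an absolute amplitude floor
(`min_amplitude`, 5 photons/frame) suppresses numerically-empty peaks.
Overlapping PSFs are resolved only through this subtract-and-redetect loop;
there is no multi-emitter joint fit.

Masks: backbone localizations are histogrammed at `sr_pixel` resolution,
smoothed, thresholded (Otsu by default; fixed threshold available), closed
and hole-filled; connected components are accepted when circularity
`4πA/P² ≥ 0.6` (the assay says only "circular in appearance"; 0.6 cleanly
separates filled discs, ~0.9+, from linear debris, <0.3) and the area is in
bounds. Counting assigns each emitter to the accepted mask containing it
(nearest centroid on overlap, logged), keeps zero-count plasmids in the
histogram, and reports `mean = Σcounts/N` and `sem = stdev/√N`.

## Alignment

The aligner is a global monotone matching with optional free end-gaps —
appropriate because molecules are full-length fragments of the mapped
region; a `local` flag frees terminal label skips too. A match between
converted label position and site contributes
`match_score · max(0, 1 − |Δ|/w)` and is only allowed for `|Δ| ≤ w`
(`w = 150` bp); the triangular taper discriminates distance, and a
`flat_score` flag restores flat scoring. Skipped sites cost 0.5, extra
labels 0.25 (in units of `match_score`; no canonical values exist — the
acceptance properties hold across a 4× range of both).

Stretch handling: a grid of `n_stretch = 11` candidate stretches across
`1.6 ± 10%`, each combined with global-offset candidates taken from
label-minus-site differences (deduplicated at `w/4`, bounded by
`max_offset = 150·2 = 300` bp — molecules are full-length, so kb-scale
shifts are unphysical and only let wrong orientations cheat), followed by a
joint linear least-squares refinement of (stretch, offset) on the matched
anchor pairs, clipped to the tolerance band and accepted only if the score
improves. This is the "single stretch + offset" reading of stretch-tolerant
alignment; per-gap elastic scaling is deliberately out of scope.

The DP maximizes (score, number of matches) lexicographically; among
optima the reconstruction keeps the lexicographically smallest pair list,
built bottom-up (a greedy transition preference is *not* sufficient for
this tie-break). Orientation is resolved by aligning the trace and its
mirror; exact ties go to forward. A brute-force enumeration oracle over all
monotone partial matchings reproduces the DP exactly on randomized small
instances, under all scoring variants.

## Consensus and off-site statistics

Matched labels snap to their site coordinate. Unmatched labels interpolate
piecewise-linearly between flanking matched anchors (observed → reference),
and extrapolate with the molecule's fitted affine (stretch, offset) map
beyond the outermost anchors or when nothing matched. Dual-strand removal
is applied per molecule, before pooling: visiting matched labels in
coordinate order, each may delete at most one not-yet-removed unmatched
label within 100 bp — nearest first (ties to the lower coordinate), with a
`leftmost` variant since the verbal rule is ambiguous about order. The
consensus histogram uses 50 bp bins, below the 100–150 bp precision scale.

Reported statistics after removal: `offsite_fraction =
unmatched/(matched+unmatched)`; `offsite_density = unmatched/(N·L_kb)`
(full-length molecules assumed); a Kolmogorov–Smirnov test of unmatched
coordinates against Uniform(0, L); the raw `onsite_per_site =
matched/(S·N)`; and a corrected `site_efficiency`. The correction matters:
with `sigma_loc = 100` bp and `w = 150` bp a true site label escapes the
window with probability `2Φ(−w/σ_eff) ≈ 8–13%`, so the raw matched
fraction underestimates `p_site` by ~0.06. Because each molecule's
(stretch, offset) is fitted to its own `k` anchors, the residuals facing
the window are shrunk, `σ_eff = sigma_loc·√(1 − 2/k̄)`; an unlabeled site
can also capture an off-site label, `q = 1 − e^{−2wρ̂}` with `ρ̂` the
observed off-site density. Inverting `E[matched/site] = p·c + (1−p)·q`
gives the estimator; it is analytic (no fitted calibration constants) and
recovers `p_site` to within ~0.02 across regimes in validation.

## Kinetics and summary statistics

`fit_pseudo_first_order` fits `N(t) = N∞(1 − e^{−k′t})` to per-time *mean*
counts by nonlinear least squares (`curve_fit`, tolerances 1e-10),
initialized from the largest mean and a log-linear rate regression. Counts
from a real (or simulated) labeling reaction include a time-independent
off-target baseline, which the bare two-parameter model cannot absorb and
which biases `k′` badly; `baseline=True` adds the constant
(`N(t) = b + N∞(1 − e^{−k′t})`) and is used whenever the data contain
off-target labels. The package's kinetic validation uses a 14-point
stopped-time design with replicated anchors,
`t = {0, 0, 1, 2, 3, 4, 6, 8, 10, 15, 20, 30, 60, 60}` min at 300
plasmids per time — a conventional design that concentrates points where
rates in `k ∈ [0.1, 0.5] /min` are informative; with it, `k′` lands within
10% of truth in ≥90% of replicates. A count-level likelihood is not
implemented; means-level least squares mirrors how such plots are fitted.

The specificity bound uses the Poisson zero class, `λ = −ln f₀`,
`bound = L_kb/λ` (an `odds` variant `(1−f₀)/f₀` is available; both round
to ~85 kb for the 97% / 2.6 kb control). The titration regression is OLS of
group means against site count; when per-group SEMs are supplied the
parameter standard errors are propagated from them rather than estimated
from the few regression residuals.

## Validation scope — what the synthetic tests show

The generator reproduces the *statistical structure* the analysis assumes:
Bernoulli sites, Poisson off-target labels, Gaussian localization error,
global per-molecule stretch, single-step bleaching. Passing tests show the
estimators are unbiased and the algorithms correct *under that model*. Real
data add effects the generator omits — within-molecule stretch
fluctuation, molecule fragmentation and overlap, dye blinking and
photophysics beyond single-step bleaching, drift, non-uniform off-target
chemistry — so quantitative transfer to microscope data is not implied.
Known limitations worth naming: at site pairs ~100 bp apart a second-strand
label can be captured by the neighboring site, leaking through dual-strand
removal (the removal invariant is therefore validated on well-separated
sites); orientation recovery degrades from ~98% at `σ = 50` bp to ~90% at
`σ = 100` bp — an intrinsic ambiguity of the score at that noise level, not
a search failure; and the consensus treats every molecule as full length.

Problem sizes in the test suite (cohorts of 180–1000 molecules, 10 movies
of 5 emitters, 200 kinetic replicates) were chosen as the smallest sizes at
which the 3-SE / percentage criteria are statistically meaningful.
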
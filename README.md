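# mtagmap

Single-molecule analysis for **methyltransferase-directed fluorescent DNA
labeling** (mTAG / optical DNA mapping). DNA methyltransferases such as
M.TaqI can be coaxed into transferring a fluorophore instead of a methyl
group onto their recognition motif (TCGA), turning every motif occurrence
into a sequence-specific fluorescent label. Imaging stretched, labeled
molecules then yields an optical "barcode" of each molecule. This package
implements the quantitative pipeline behind that assay, for people who run
(or simulate) such experiments:

* **refmap** — motif-site maps from FASTA sequences, in-silico PCR, BED I/O.
* **simulate** — a ground-truthed generator of labeled molecules, plasmid
  fields, photobleaching movies and kinetic time courses: per-site Bernoulli
  labeling (at most one fluorophore per palindromic duplex site), uniform
  Poisson off-target labeling, ~100 bp localization error, per-molecule
  stretch 1.6 ± 10%, random polarity, single-step bleaching.
* **blinkcount** — bleaching-assisted localization (2D-Gaussian fitting with
  backward PSF subtraction, which resolves emitters far below the
  diffraction limit), super-resolution plasmid-mask reconstruction with a
  circularity filter, and per-plasmid label counting.
* **mapalign** — stretch-tolerant, orientation-aware alignment of a
  molecule's label positions to the reference map: a dynamic program over
  monotone label↔site matchings with match/skip-site/skip-label moves,
  searched over a grid of stretch factors plus a global offset.
* **consensus** — projection of aligned labels onto reference coordinates,
  the dual-strand removal rule (one unaligned label within 100 bp of each
  aligned label), consensus histograms and off-site labeling statistics.
* **stats** — pseudo-first-order kinetics fits, the Poisson zero-class
  specificity bound, fold changes, and the labels-vs-sites titration
  regression.

## The core quantities

For a molecule of length `L` kb with `S` recognition sites, per-site
labeling probability `p` and off-target density `ρ` (labels/kb), the
expected label count is `S·p + ρ·L`; the expected off-site fraction is
`ρ·L / (ρ·L + S·p)`. Alignment scores a match between label `i` (at
converted position `x_i = nm_i/(0.34·s) − δ`, stretch `s`, offset `δ`) and
site `j` as `max(0, 1 − |x_i − c_j|/w)` with window `w = 150` bp. Labeling
kinetics follow `N(t) = N∞(1 − e^{−k′t})`; the specificity control uses the
Poisson zero class, `λ = −ln f₀`, giving `L/λ` kb of DNA per spurious
fluorophore.

## Worked example

```bash
python examples/02_simulate_and_align.py
```

```
simulated 180 molecules, 10.48 labels each (expected 10.58)
orientation recovered for 160/180 molecules with >=4 labels
consensus histogram: 1786 labels in 100 bins; top bins near [600, 700, 1450, 1900, 2400, 2950, 3050, 3700, 4400]
off-site fraction 22.8% (generator expectation 21.7%)
off-site density 0.45 labels/kb (truth 0.46)
per-site efficiency 0.91 (truth 0.92); raw matched/site 0.85 before window correction
unmatched-coordinate uniformity p = 0.06 (high = consistent with uniform off-target labeling)
```

180 molecules are drawn in the combed-fragment regime, aligned to the
nine-site map (the consensus peaks sit on the true site coordinates), and
the off-site statistics recover the generator's ground truth: ~22% of
surviving labels are off-site, ~0.46 per kb, per-site efficiency 0.92.
The other examples cover reference-map construction (`01`), sub-diffraction
localization and plasmid counting (`03`), and kinetics/specificity
arithmetic (`04` — e.g. a 97% label-free zero class on a 2.6 kb plasmid
bounds non-specific association at one fluorophore per ~85 kb).

A thin CLI mirrors the library (`mtagmap sites|pcr|run|bound|fold`), and
`mtagmap run --config cfg.yaml --out dir` executes a seeded, manifest-backed
pipeline (`preset: combed-fragment` gives the 9-site / 180-molecule regime).

## Layout

```
src/mtagmap/     library (refmap, sequences, simulate, blinkcount,
                 mapalign, consensus, stats, pipeline, cli)
examples/        narrative scripts, one per capability
tests/           pytest suite incl. brute-force oracles
docs/methods.md  model assumptions, estimators, design choices
```
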
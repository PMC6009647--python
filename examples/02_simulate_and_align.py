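"""Simulate a combed-molecule cohort, align it, and quantify off-site labels.

Generates 180 stretched molecules in the combed-fragment regime (per-site
efficiency 0.92, 0.46 off-target labels/kb, 100 bp localization error,
stretch 1.6 +/- 10%, random polarity), aligns each to the nine-site map with
the stretch-tolerant DP, applies dual-strand removal, and prints the
consensus and off-site statistics.
"""

import numpy as np

import mtagmap as m
from mtagmap.sequences import AMPLICON_SITE_LAYOUT, synthetic_sequence

seq = synthetic_sequence(5000, "TCGA", AMPLICON_SITE_LAYOUT, seed=1)
refmap = m.find_sites(seq, "TCGA", name="amplicon")

cfg = m.SimConfig.preset("combed-fragment", n_molecules=180, seed=0)
traces, truths = m.simulate_molecules(refmap, cfg)
print(f"simulated {len(traces)} molecules, "
      f"{np.mean([len(t.label_positions) for t in traces]):.2f} labels each "
      f"(expected {9 * cfg.p_site + cfg.rho_off * 5:.2f})")

placed, n_correct, n_oriented = [], 0, 0
for tr, tu in zip(traces, truths):
    aln = m.align_best_orientation(tr, refmap)
    if len(tr.label_positions) >= 4:
        n_oriented += 1
        n_correct += (aln.orientation == "reverse") == tu.flipped
    placed += m.remove_dual_strand(m.place_labels(aln, tr, refmap))

print(f"orientation recovered for {n_correct}/{n_oriented} molecules "
      "with >=4 labels")

hist = m.build_consensus(placed, refmap, bin_width=50)
peak_bins = np.argsort(hist.counts)[-9:]
print(f"consensus histogram: {hist.total} labels in {len(hist.counts)} bins; "
      f"top bins near {sorted(int(hist.edges[b]) for b in peak_bins)}")

st = m.offsite_stats(placed, refmap, cfg.n_molecules, sigma_loc=cfg.sigma_loc)
print(f"off-site fraction {st.offsite_fraction:.1%} "
      f"(generator expectation 21.7%)")
print(f"off-site density {st.offsite_density:.2f} labels/kb (truth 0.46)")
print(f"per-site efficiency {st.site_efficiency:.2f} (truth {cfg.p_site}); "
      f"raw matched/site {st.onsite_per_site:.2f} before window correction")
print(f"unmatched-coordinate uniformity p = {st.uniformity_pvalue:.2f} "
      "(high = consistent with uniform off-target labeling)")
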
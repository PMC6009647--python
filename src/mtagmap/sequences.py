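"""Synthetic DNA sequences with controlled motif content.

These generators build random sequences that contain a methyltransferase
recognition motif at exactly the requested positions and nowhere else.  They
stand in for public reference sequences in tests and examples: the stand-ins
reproduce the documented site *counts and layout* (e.g. a 2686 bp plasmid
with four TCGA sites; a ~5 kb amplicon with nine sites, two close pairs) but
are otherwise random — they are synthetic, not the real pUC19 or phage
sequences.
"""

from __future__ import annotations

import numpy as np

from .refmap import _revcomp, _validate_dna, find_sites

__all__ = [
    "synthetic_sequence",
    "synthetic_plasmid",
    "synthetic_amplicon_template",
    "AMPLICON_SITE_LAYOUT",
    "FWD_PRIMER",
    "REV_PRIMER",
]

_BASES = np.array(list("ACGT"))

# Primer pair used to delimit the ~5 kb amplicon (printed primer sequences,
# whitespace removed); neither primer nor its reverse complement contains TCGA.
FWD_PRIMER = "CGAGTCCTCCAAGATGG"
REV_PRIMER = "CCTCTCCCTATAGTGAGTCG"

# Nine-site layout on a 5 kb fragment: two close pairs (near 0.65 and 3.0 kb)
# flanked by isolated sites, mirroring the density structure of the mapped
# fragment's theoretical map.
AMPLICON_SITE_LAYOUT = (600, 700, 1450, 1900, 2400, 2950, 3050, 3700, 4400)


def _scrub(seq: list[str], motifs: list[str], rng: np.random.Generator,
           protected: set[int]) -> None:
    """Mutate bases until no motif occurs outside protected positions."""
    s = "".join(seq)
    for _ in range(10000):
        hit = None
        for m in motifs:
            idx = s.find(m)
            while idx >= 0:
                if not all(p in protected for p in range(idx, idx + len(m))):
                    hit = (idx, len(m))
                    break
                idx = s.find(m, idx + 1)
            if hit:
                break
        if hit is None:
            return
        idx, mlen = hit
        mutable = [p for p in range(idx, idx + mlen) if p not in protected]
        p = mutable[rng.integers(len(mutable))]
        seq[p] = str(rng.choice([b for b in "ACGT" if b != seq[p]]))
        s = "".join(seq)
    raise RuntimeError("could not scrub spurious motif occurrences")


def synthetic_sequence(
    length: int,
    motif: str,
    site_positions: list[int] | tuple[int, ...],
    seed: int = 0,
    name: str = "synthetic",
) -> str:
    """Random sequence containing ``motif`` at exactly ``site_positions``.

    Both the motif and its reverse complement are excluded everywhere else,
    so :func:`mtagmap.refmap.find_sites` on the result returns exactly the
    requested sites.
    """
    motif = _validate_dna(motif, "motif")
    rng = np.random.default_rng(seed)
    positions = sorted(int(p) for p in site_positions)
    for a, b in zip(positions, positions[1:]):
        if b - a < len(motif):
            raise ValueError("site positions overlap")
    if positions and positions[-1] + len(motif) > length:
        raise ValueError("site beyond sequence end")

    seq = list(rng.choice(_BASES, size=length))
    protected: set[int] = set()
    for p in positions:
        seq[p : p + len(motif)] = list(motif)
        protected.update(range(p, p + len(motif)))
    motifs = [motif]
    rc = _revcomp(motif)
    if rc != motif:
        motifs.append(rc)
    _scrub(seq, motifs, rng, protected)

    out = "".join(seq)
    got = find_sites(out, motif, name=name)
    if got.positions != positions:
        raise RuntimeError("synthetic sequence failed site verification")
    return out


def synthetic_plasmid(
    n_sites: int = 4,
    length: int = 2686,
    motif: str = "TCGA",
    seed: int = 0,
    name: str = "synthetic-plasmid",
) -> str:
    """Synthetic plasmid-length stand-in with ``n_sites`` evenly spread sites.

    The default (four TCGA sites on 2686 bp) mirrors the site count of the
    pUC19 plasmid used in labeling-efficiency assays; the sequence itself is
    random, not pUC19.
    """
    if n_sites == 0:
        positions: list[int] = []
    else:
        spacing = length // (n_sites + 1)
        positions = [spacing * (i + 1) for i in range(n_sites)]
    return synthetic_sequence(length, motif, positions, seed=seed, name=name)


def synthetic_amplicon_template(
    motif: str = "TCGA",
    site_layout: tuple[int, ...] = AMPLICON_SITE_LAYOUT,
    flank: int = 500,
    amplicon_length: int = 5000,
    seed: int = 0,
) -> tuple[str, str, str]:
    """Synthetic PCR template: (template, fwd_primer, rev_primer).

    The template embeds a unique forward-primer site, an amplicon of
    ``amplicon_length`` bp carrying ``motif`` at ``site_layout`` (amplicon
    coordinates), and a unique reverse-primer binding site, with random
    flanks on both ends — a stand-in for amplifying a mapped fragment out of
    a genomic template.
    """
    rng = np.random.default_rng(seed + 104729)
    fwd, rev = FWD_PRIMER, REV_PRIMER
    rev_site = _revcomp(rev)
    total = flank + amplicon_length + flank
    seq = list(rng.choice(_BASES, size=total))

    protected: set[int] = set()

    def plant(s: str, at: int) -> None:
        seq[at : at + len(s)] = list(s)
        protected.update(range(at, at + len(s)))

    plant(fwd, flank)
    plant(rev_site, flank + amplicon_length - len(rev_site))
    for p in site_layout:
        plant(motif, flank + p)

    motifs = [motif, fwd, rev_site]
    rc = _revcomp(motif)
    if rc != motif:
        motifs.append(rc)
    # also forbid accidental extra primer-binding sites on either strand
    motifs.extend([_revcomp(fwd), rev])
    _scrub(seq, motifs, rng, protected)
    return "".join(seq), fwd, rev
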
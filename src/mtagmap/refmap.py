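"""Reference motif maps for methyltransferase labeling sites.

A DNA methyltransferase such as M.TaqI recognises a short motif (TCGA for
M.TaqI) and deposits a label there.  The ordered list of motif positions on a
sequence is the "theoretical map" against which observed single-molecule label
positions are aligned.  This module builds such maps from FASTA sequences,
extracts PCR amplicons in silico, and round-trips maps through BED.

Coordinates are 0-based; intervals are half-open.  A site's position is the
motif start, not the modified base inside the motif — the few-bp discrepancy
is negligible against the ~100 bp localization precision of the imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "MotifSite",
    "ReferenceMap",
    "find_sites",
    "in_silico_pcr",
    "read_fasta",
    "write_map",
    "read_map",
    "AmplificationError",
]

_VALID = frozenset("ACGT")


class AmplificationError(ValueError):
    """In-silico PCR failed: a primer has zero or multiple binding sites."""


def _validate_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in _VALID:
            raise ValueError(
                f"{what} contains non-ACGT symbol {c!r} at position {i}; "
                "IUPAC ambiguity codes are not supported"
            )
    return seq


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True, order=True)
class MotifSite:
    """One motif occurrence: 0-based start position and strand ('+' or '-')."""

    position: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class ReferenceMap:
    """Ordered motif-site map on a named sequence (the theoretical label map)."""

    name: str
    length: int
    motif: str
    sites: list[MotifSite] = field(default_factory=list)

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.sites]

    @property
    def length_kb(self) -> float:
        return self.length / 1000.0

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[MotifSite]:
        return iter(self.sites)


def find_sites(sequence: str, motif: str, name: str = "seq") -> ReferenceMap:
    """Locate every motif occurrence on both strands of ``sequence``.

    Forward-strand matches are reported with strand '+'.  Occurrences of the
    motif's reverse complement on the forward sequence are reported with
    strand '-'.  Palindromic (self-reverse-complementary) motifs such as TCGA
    occur identically on both strands and are reported once, with strand '+',
    matching the biology: one duplex recognition site per location.
    """
    if not sequence or not motif:
        raise ValueError("sequence and motif must be non-empty")
    sequence = _validate_dna(sequence, "sequence")
    motif = _validate_dna(motif, "motif")
    if len(motif) > len(sequence):
        raise ValueError(
            f"motif length {len(motif)} exceeds sequence length {len(sequence)}"
        )

    rc = _revcomp(motif)
    palindromic = rc == motif
    sites: list[MotifSite] = []
    for pos in _find_all(sequence, motif):
        sites.append(MotifSite(pos, "+"))
    if not palindromic:
        for pos in _find_all(sequence, rc):
            sites.append(MotifSite(pos, "-"))
    sites.sort(key=lambda s: (s.position, s.strand))
    return ReferenceMap(name=name, length=len(sequence), motif=motif, sites=sites)


def _find_all(haystack: str, needle: str) -> Iterator[int]:
    """Yield all (possibly overlapping) match starts of needle in haystack."""
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return
        yield idx
        start = idx + 1


def in_silico_pcr(template: str, fwd_primer: str, rev_primer: str) -> str:
    """Extract the amplicon a primer pair would produce from ``template``.

    The forward primer must match the forward strand exactly once; the
    reverse primer's reverse complement must occur exactly once, downstream
    of the forward match.  Returns the inclusive subsequence from the start
    of the forward-primer match through the end of the reverse-primer
    binding site.
    """
    template = _validate_dna(template, "template")
    fwd_primer = _validate_dna(fwd_primer, "forward primer")
    rev_primer = _validate_dna(rev_primer, "reverse primer")

    fwd_hits = list(_find_all(template, fwd_primer))
    if len(fwd_hits) != 1:
        raise AmplificationError(
            f"forward primer has {len(fwd_hits)} binding sites (need exactly 1)"
        )
    rev_site = _revcomp(rev_primer)
    rev_hits = [p for p in _find_all(template, rev_site) if p >= fwd_hits[0]]
    if len(rev_hits) != 1:
        raise AmplificationError(
            f"reverse primer has {len(rev_hits)} downstream binding sites "
            "(need exactly 1)"
        )
    start = fwd_hits[0]
    end = rev_hits[0] + len(rev_site)
    return template[start:end]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict of name -> uppercase sequence."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_map(refmap: ReferenceMap, path: str | Path) -> None:
    """Write a reference map as BED (0-based half-open, strand column set)."""
    with open(path, "w") as fh:
        fh.write(f"# name={refmap.name} length={refmap.length} motif={refmap.motif}\n")
        for site in refmap.sites:
            fh.write(
                f"{refmap.name}\t{site.position}\t{site.position + len(refmap.motif)}"
                f"\t{refmap.motif}\t.\t{site.strand}\n"
            )


def read_map(path: str | Path) -> ReferenceMap:
    """Read a BED map written by :func:`write_map` back into a ReferenceMap."""
    length = None
    motif = None
    name = None
    sites: list[MotifSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    key, _, val = tok.partition("=")
                    if key == "name":
                        name = val
                    elif key == "length":
                        length = int(val)
                    elif key == "motif":
                        motif = val
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            name = parts[0]
            sites.append(MotifSite(int(parts[1]), parts[5]))
            if motif is None:
                motif = parts[3]
    if motif is None:
        raise ValueError(f"{path}: no motif recorded (empty file?)")
    if length is None:
        length = (sites[-1].position + len(motif)) if sites else 0
    return ReferenceMap(
        name=name or "map", length=length, motif=motif, sites=sorted(sites)
    )
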
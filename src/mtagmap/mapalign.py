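"""Stretch-tolerant alignment of label positions to a reference motif map.

A deposited molecule reports its fluorophore positions in nm along the
molecule axis, with unknown polarity and a molecule-specific stretch factor
near 1.6 (±~10%).  Alignment converts positions to bp at candidate stretch
values, subtracts a global offset, and runs a dynamic program over (label,
site) index pairs with three moves — match, skip-site, skip-label — keeping
the matching monotone (no crossings).  A match within ``match_width`` bp
scores positively, tapering linearly with distance; skipped sites and extra
labels carry penalties; with free end-gaps, sites overhanging either end of
the molecule are free.

The search is a grid over candidate stretches plus a global offset chosen
from label-to-site differences and refined by least squares on the matched
pairs.  Orientation is resolved by aligning the trace and its mirror image
and keeping the better score (ties go to forward).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .refmap import ReferenceMap
from .simulate import NM_PER_BP, MoleculeTrace

__all__ = [
    "AlignmentParams",
    "Alignment",
    "to_bp",
    "align",
    "align_best_orientation",
    "alignment_score",
]

_EPS = 1e-9


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and search parameters for map alignment.

    ``match_width`` is the hard matching window in bp (score tapers to zero
    at the window edge unless ``flat_score``).  ``stretch``/``stretch_tol``
    define the candidate-stretch search interval; ``n_stretch`` its grid
    resolution.  ``free_ends`` makes terminal skipped sites free, which is
    appropriate for full-length molecules shorter than or equal to the map;
    ``local`` additionally makes terminal skipped labels free.
    """

    stretch: float = 1.6
    stretch_tol: float = 0.1
    n_stretch: int = 11
    match_width: float = 150.0       # bp
    match_score: float = 1.0
    miss_site_penalty: float = 0.5
    extra_label_penalty: float = 0.25
    nm_per_bp: float = NM_PER_BP
    max_offset: float = 300.0        # bp; molecules are full-length fragments
    free_ends: bool = True
    flat_score: bool = False
    local: bool = False

    def __post_init__(self):
        if self.match_width <= 0:
            raise ValueError("match_width must be positive")
        if not 0 <= self.stretch_tol < 1:
            raise ValueError("stretch_tol must be in [0, 1)")
        if self.miss_site_penalty < 0 or self.extra_label_penalty < 0:
            raise ValueError("penalties must be >= 0")

    def stretch_grid(self) -> np.ndarray:
        if self.stretch_tol == 0 or self.n_stretch == 1:
            return np.array([self.stretch])
        return np.linspace(
            self.stretch * (1 - self.stretch_tol),
            self.stretch * (1 + self.stretch_tol),
            self.n_stretch,
        )


@dataclass
class Alignment:
    """A monotone label-to-site matching for one molecule.

    ``pairs`` holds (label index, site index) strictly increasing in both;
    label indices refer to the trace *after* orienting (mirroring if
    ``orientation == "reverse"``).  Every label is either in ``pairs`` or in
    ``unmatched_labels``; every site is in ``pairs`` or ``skipped_sites``.
    ``fitted_offset`` is the global bp offset subtracted from converted
    label positions before matching.
    """

    orientation: str                     # "forward" | "reverse"
    fitted_stretch: float
    fitted_offset: float
    pairs: list[tuple[int, int]]
    unmatched_labels: list[int]
    skipped_sites: list[int]
    score: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def to_bp(
    positions_nm: np.ndarray | Sequence[float] | MoleculeTrace,
    stretch: float,
    nm_per_bp: float = NM_PER_BP,
) -> np.ndarray:
    """Convert physical label positions (nm) to bp at a given stretch."""
    if stretch <= 0:
        raise ValueError("stretch must be positive")
    if isinstance(positions_nm, MoleculeTrace):
        positions_nm = positions_nm.label_positions
    return np.asarray(positions_nm, dtype=float) / (nm_per_bp * stretch)


def _match_scores(pos: np.ndarray, sites: np.ndarray,
                  params: AlignmentParams) -> np.ndarray:
    """(n_labels, n_sites) match-score matrix; -inf outside the window."""
    d = np.abs(pos[:, None] - sites[None, :])
    if params.flat_score:
        m = np.full(d.shape, params.match_score)
    else:
        m = params.match_score * (1.0 - d / params.match_width)
    m[d > params.match_width] = -np.inf
    return m


def _dp_align(pos: np.ndarray, sites: np.ndarray,
              params: AlignmentParams) -> tuple[float, list[tuple[int, int]]]:
    """Optimal monotone matching by dynamic programming.

    Maximizes (score, number of matches) lexicographically; among equals the
    reconstruction prefers match > skip-site > skip-label at each state,
    which yields the lexicographically smallest pair list.
    """
    L, S = len(pos), len(sites)
    miss, extra = params.miss_site_penalty, params.extra_label_penalty
    M = _match_scores(pos, sites, params) if L and S else None

    def site_cost(i: int) -> float:
        return 0.0 if (params.free_ends and i in (0, L)) else miss

    def label_cost(j: int) -> float:
        return 0.0 if (params.local and j in (0, S)) else extra

    # suffix DP over (labels i.., sites j..): value = (score, n_matches);
    # boundary rows use the same arithmetic as the interior so that the
    # reconstruction's float comparisons are exact.
    score = np.empty((L + 1, S + 1))
    nmat = np.zeros((L + 1, S + 1), dtype=int)
    score[L, S] = 0.0
    for j in range(S - 1, -1, -1):
        score[L, j] = score[L, j + 1] - site_cost(L)
    for i in range(L - 1, -1, -1):
        score[i, S] = score[i + 1, S] - label_cost(S)
        for j in range(S - 1, -1, -1):
            best = (score[i, j + 1] - site_cost(i), nmat[i, j + 1])
            cand = (score[i + 1, j] - label_cost(j), nmat[i + 1, j])
            if cand > best:
                best = cand
            m = M[i, j]
            if np.isfinite(m):
                cand = (m + score[i + 1, j + 1], 1 + nmat[i + 1, j + 1])
                if cand > best:
                    best = cand
            score[i, j], nmat[i, j] = best

    # reconstruction: among (score, n_matches)-optimal transitions, keep the
    # lexicographically smallest pair list, built bottom-up so local ties
    # resolve on the actual continuation rather than a greedy preference
    pairs_tab: list[list[tuple]] = [[()] * (S + 1) for _ in range(L + 1)]
    for i in range(L - 1, -1, -1):
        pairs_tab[i][S] = pairs_tab[i + 1][S]
    for j in range(S - 1, -1, -1):
        pairs_tab[L][j] = pairs_tab[L][j + 1]
    for i in range(L - 1, -1, -1):
        for j in range(S - 1, -1, -1):
            target = (score[i, j], nmat[i, j])
            cands = []
            if np.isfinite(M[i, j]) and (
                M[i, j] + score[i + 1, j + 1], 1 + nmat[i + 1, j + 1]
            ) == target:
                cands.append(((i, j),) + pairs_tab[i + 1][j + 1])
            if (score[i, j + 1] - site_cost(i), nmat[i, j + 1]) == target:
                cands.append(pairs_tab[i][j + 1])
            if (score[i + 1, j] - label_cost(j), nmat[i + 1, j]) == target:
                cands.append(pairs_tab[i + 1][j])
            pairs_tab[i][j] = min(cands)
    return float(score[0, 0]), list(pairs_tab[0][0])


def _dp_score_batch(P: np.ndarray, sites: np.ndarray,
                    params: AlignmentParams) -> np.ndarray:
    """Score-only DP vectorized over candidates: P is (C, L) label positions."""
    C, L = P.shape
    S = len(sites)
    miss, extra = params.miss_site_penalty, params.extra_label_penalty
    d = np.abs(P[:, :, None] - sites[None, None, :])
    if params.flat_score:
        M = np.full(d.shape, params.match_score)
    else:
        M = params.match_score * (1.0 - d / params.match_width)
    M[d > params.match_width] = -np.inf

    score = np.empty((C, L + 1, S + 1))
    for j in range(S + 1):
        score[:, L, j] = 0.0 if params.free_ends else -(S - j) * miss
    for i in range(L - 1, -1, -1):
        score[:, i, S] = 0.0 if params.local else -(L - i) * extra
        site_cost = 0.0 if (params.free_ends and i == 0) else miss
        for j in range(S - 1, -1, -1):
            label_cost = 0.0 if (params.local and j == 0) else extra
            best = np.maximum(score[:, i, j + 1] - site_cost,
                              score[:, i + 1, j] - label_cost)
            with np.errstate(invalid="ignore"):
                best = np.maximum(best, M[:, i, j] + score[:, i + 1, j + 1])
            score[:, i, j] = best
    return score[:, 0, 0]


def _candidate_offsets(conv: np.ndarray, sites: np.ndarray,
                       params: AlignmentParams) -> np.ndarray:
    """Global-offset candidates: deduplicated label-minus-site differences."""
    if len(conv) == 0 or len(sites) == 0:
        return np.array([0.0])
    diffs = (conv[:, None] - sites[None, :]).ravel()
    diffs = diffs[np.abs(diffs) <= params.max_offset]
    merged = np.sort(np.concatenate([[0.0], diffs]))
    keep: list[float] = []
    last = -np.inf
    tol = params.match_width / 4.0
    for off in merged:
        if off - last > tol:
            keep.append(float(off))
            last = off
    return np.asarray(keep)


def align(
    trace: MoleculeTrace,
    refmap: ReferenceMap,
    params: AlignmentParams | None = None,
    orientation: str = "forward",
    _dp: Callable | None = None,
) -> Alignment:
    """Align one trace (as oriented) to the reference map.

    Searches the stretch grid and global-offset candidates, then refines the
    offset by least squares over the matched pairs.  ``_dp`` swaps the
    matching routine (used to validate the DP against brute force).
    """
    if params is None:
        params = AlignmentParams()
    if len(refmap) == 0:
        raise ValueError("reference map has no sites")
    dp = _dp or _dp_align
    sites = np.asarray(refmap.positions, dtype=float)
    pos_nm = np.asarray(trace.label_positions, dtype=float)

    best: tuple[float, float, float] | None = None  # score, stretch, offset
    for s in params.stretch_grid():
        conv = to_bp(pos_nm, s, params.nm_per_bp)
        offsets = _candidate_offsets(conv, sites, params)
        if len(conv) and _dp is None:
            scores = _dp_score_batch(conv[None, :] - offsets[:, None],
                                     sites, params)
        else:
            scores = np.array(
                [dp(conv - off, sites, params)[0] for off in offsets])
        k = int(np.argmax(scores))
        if best is None or scores[k] > best[0] + _EPS:
            best = (float(scores[k]), float(s), float(offsets[k]))

    score, s, off = best
    conv = to_bp(pos_nm, s, params.nm_per_bp)
    score, pairs = dp(conv - off, sites, params)

    # least-squares refinement of (stretch, offset) on the matched anchor
    # pairs: site ~ u/s - off with u = nm / nm_per_bp, linear in (1/s, off)
    s_lo = params.stretch * (1 - params.stretch_tol)
    s_hi = params.stretch * (1 + params.stretch_tol)
    for _ in range(5):
        if not pairs:
            break
        u = np.array([pos_nm[i] / params.nm_per_bp for i, _ in pairs])
        site_y = np.array([sites[j] for _, j in pairs])
        if len(pairs) >= 2 and np.ptp(u) > 0:
            a, b = np.polyfit(u, site_y, 1)
            new_s = float(np.clip(1.0 / a, s_lo, s_hi)) if a > 0 else s
            new_off = float(np.clip(-b, -params.max_offset, params.max_offset))
        else:
            new_s = s
            new_off = float(np.clip(np.mean(u / s - site_y),
                                    -params.max_offset, params.max_offset))
        if abs(new_off - off) < 1e-9 and abs(new_s - s) < 1e-12:
            break
        new_conv = to_bp(pos_nm, new_s, params.nm_per_bp)
        new_score, new_pairs = dp(new_conv - new_off, sites, params)
        if new_score > score + _EPS:
            score, pairs, off, s, conv = new_score, new_pairs, new_off, new_s, new_conv
        else:
            break

    matched_labels = {i for i, _ in pairs}
    matched_sites = {j for _, j in pairs}
    return Alignment(
        orientation=orientation,
        fitted_stretch=s,
        fitted_offset=off,
        pairs=pairs,
        unmatched_labels=[i for i in range(len(pos_nm)) if i not in matched_labels],
        skipped_sites=[j for j in range(len(sites)) if j not in matched_sites],
        score=float(score),
    )


def align_best_orientation(
    trace: MoleculeTrace,
    refmap: ReferenceMap,
    params: AlignmentParams | None = None,
    _dp: Callable | None = None,
) -> Alignment:
    """Align the trace in both polarities and keep the better score.

    Exact ties go to the forward orientation.  Pair label indices in a
    reverse alignment refer to the mirrored (re-sorted) trace.
    """
    fwd = align(trace, refmap, params, orientation="forward", _dp=_dp)
    rev = align(trace.mirrored(), refmap, params, orientation="reverse", _dp=_dp)
    return rev if rev.score > fwd.score + _EPS else fwd


def alignment_score(
    alignment: Alignment,
    trace: MoleculeTrace,
    refmap: ReferenceMap,
    params: AlignmentParams,
) -> float:
    """Recompute an alignment's score from its pairs and the parameters.

    Independent bookkeeping recomputation: match taper scores minus skipped
    site / extra label penalties, honoring free end-gaps.
    """
    oriented = trace.mirrored() if alignment.orientation == "reverse" else trace
    conv = to_bp(oriented, alignment.fitted_stretch, params.nm_per_bp)
    conv = conv - alignment.fitted_offset
    sites = np.asarray(refmap.positions, dtype=float)

    total = 0.0
    for i, j in alignment.pairs:
        d = abs(conv[i] - sites[j])
        if params.flat_score:
            total += params.match_score
        else:
            total += params.match_score * (1.0 - d / params.match_width)
    total -= params.extra_label_penalty * len(alignment.unmatched_labels)
    if alignment.pairs:
        j_first = alignment.pairs[0][1]
        j_last = alignment.pairs[-1][1]
        interior = [j for j in alignment.skipped_sites if j_first < j < j_last]
    else:
        interior = []
    if params.free_ends:
        total -= params.miss_site_penalty * len(interior)
    else:
        total -= params.miss_site_penalty * len(alignment.skipped_sites)
    return total
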
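"""Synthetic single-molecule data with ground truth.

The generators here reproduce the statistical structure the analysis stages
assume about methyltransferase-labeled, surface-stretched DNA:

* per-site Bernoulli labeling with at most one fluorophore per palindromic
  site (optionally a second, offset label when both strands are alkylated);
* homogeneous Poisson off-target labeling, uniform along the molecule;
* Gaussian localization error (quoted in bp, ~100 bp scale);
* a per-molecule stretch factor around 1.6 with ~10% fractional variation,
  converting bp to nm at 0.34 nm/bp;
* random molecule orientation (coordinate mirroring);
* single-step photobleaching movies with Poisson shot noise;
* pseudo-first-order labeling kinetics, p(t) = p_inf * (1 - exp(-k t)).

Every generator returns ground truth alongside the observable data so the
analysis stages can be validated as estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .refmap import ReferenceMap

__all__ = [
    "SimConfig",
    "MoleculeTruth",
    "MoleculeTrace",
    "MovieConfig",
    "GroundTruthEmitter",
    "PlasmidTruth",
    "PlasmidField",
    "simulate_molecules",
    "simulate_plasmid_field",
    "simulate_movie",
    "simulate_kinetics",
    "traces_to_frame",
    "traces_from_frame",
]

NM_PER_BP = 0.34


@dataclass
class SimConfig:
    """Parameters of the labeled-molecule generator.

    Defaults are the combed-fragment regime: per-site efficiency 0.92,
    off-target density 0.46 labels/kb, localization error 100 bp, stretch
    1.6 with 0.1 fractional variation.  ``preset("plasmid")`` switches to the
    plasmid-counting regime (0.63 per site, 0.37/kb).
    """

    p_site: float = 0.92
    p_second: float = 0.0          # >0 enables double-strand labeling mode
    rho_off: float = 0.46          # off-target labels per kb
    sigma_loc: float = 100.0       # localization error, bp
    stretch_mean: float = 1.6
    stretch_tol: float = 0.1       # fractional variation of the stretch
    stretch_dist: Literal["truncnorm", "uniform"] = "truncnorm"
    nm_per_bp: float = NM_PER_BP
    flip_prob: float = 0.5
    n_molecules: int = 180
    seed: int = 0

    def __post_init__(self):
        for name in ("p_site", "p_second", "flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rho_off < 0 or self.sigma_loc < 0:
            raise ValueError("rho_off and sigma_loc must be >= 0")
        if self.stretch_mean * (1 - self.stretch_tol) <= 0:
            raise ValueError("stretch lower bound must be positive")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SimConfig":
        presets = {
            "combed-fragment": dict(p_site=0.92, rho_off=0.46),
            "plasmid": dict(p_site=0.63, rho_off=0.37),
        }
        if name not in presets:
            raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
        return cls(**{**presets[name], **overrides})

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class MoleculeTruth:
    """Ground truth for one simulated molecule.

    ``origins`` parallels the sorted trace positions: each entry is
    (kind, index, true_bp) with kind in {"site", "second", "off"} and index
    the site index (or off-label counter).
    """

    stretch: float
    flipped: bool
    on_site_labels: list[tuple[int, float]]
    off_site_labels: list[float]
    origins: list[tuple[str, int, float]] = field(default_factory=list)

    @property
    def n_labels(self) -> int:
        return len(self.origins)


@dataclass
class MoleculeTrace:
    """Observed label positions (nm, sorted) along one deposited molecule."""

    molecule_id: int
    label_positions: np.ndarray     # nm, ascending
    molecule_length: float          # nm

    def __post_init__(self):
        self.label_positions = np.asarray(self.label_positions, dtype=float)

    def mirrored(self) -> "MoleculeTrace":
        pos = np.sort(self.molecule_length - self.label_positions)
        return MoleculeTrace(self.molecule_id, pos, self.molecule_length)


def _draw_stretch(cfg: SimConfig, rng: np.random.Generator) -> float:
    lo = cfg.stretch_mean * (1 - 2 * cfg.stretch_tol)
    hi = cfg.stretch_mean * (1 + 2 * cfg.stretch_tol)
    if cfg.stretch_tol == 0:
        return cfg.stretch_mean
    if cfg.stretch_dist == "uniform":
        return float(rng.uniform(cfg.stretch_mean * (1 - cfg.stretch_tol),
                                 cfg.stretch_mean * (1 + cfg.stretch_tol)))
    while True:  # truncated normal, +/- 2 fractional tolerances
        s = rng.normal(cfg.stretch_mean, cfg.stretch_mean * cfg.stretch_tol)
        if lo <= s <= hi:
            return float(s)


def simulate_molecules(
    refmap: ReferenceMap,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[MoleculeTrace], list[MoleculeTruth]]:
    """Draw ``cfg.n_molecules`` labeled molecules from the reference map.

    Each site is labeled independently with probability ``p_site``; in
    double-strand mode an additional label appears with probability
    ``p_second``, offset by the motif width (the second alkylated strand).
    Off-target labels follow a homogeneous Poisson process with density
    ``rho_off`` per kb, uniform along the molecule.  True bp positions are
    perturbed by Gaussian localization noise, converted to nm through the
    per-molecule stretch, and mirrored with probability ``flip_prob``.
    """
    if cfg.n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    motif_w = len(refmap.motif)
    site_pos = np.asarray(refmap.positions, dtype=float)
    n_sites = len(site_pos)
    length = refmap.length

    traces: list[MoleculeTrace] = []
    truths: list[MoleculeTruth] = []
    for mol_id in range(cfg.n_molecules):
        stretch = _draw_stretch(cfg, rng)
        labeled = rng.random(n_sites) < cfg.p_site

        true_bp: list[float] = []
        origins: list[tuple[str, int, float]] = []
        on_site: list[tuple[int, float]] = []
        for j in np.flatnonzero(labeled):
            bp = float(site_pos[j])
            true_bp.append(bp)
            origins.append(("site", int(j), bp))
            on_site.append((int(j), bp))
            if cfg.p_second > 0 and rng.random() < cfg.p_second:
                bp2 = bp + motif_w
                true_bp.append(bp2)
                origins.append(("second", int(j), bp2))
                on_site.append((int(j), bp2))

        n_off = rng.poisson(cfg.rho_off * length / 1000.0)
        off_bp = np.sort(rng.uniform(0, length, size=n_off))
        for k, bp in enumerate(off_bp):
            true_bp.append(float(bp))
            origins.append(("off", k, float(bp)))

        true_arr = np.asarray(true_bp, dtype=float)
        noisy_bp = true_arr + rng.normal(0, cfg.sigma_loc, size=true_arr.shape)
        mol_len_nm = length * cfg.nm_per_bp * stretch
        pos_nm = np.clip(noisy_bp * cfg.nm_per_bp * stretch, 0.0, mol_len_nm)

        flipped = bool(rng.random() < cfg.flip_prob)
        if flipped:
            pos_nm = mol_len_nm - pos_nm
        order = np.argsort(pos_nm, kind="stable")
        traces.append(MoleculeTrace(mol_id, pos_nm[order], mol_len_nm))
        truths.append(
            MoleculeTruth(
                stretch=stretch,
                flipped=flipped,
                on_site_labels=on_site,
                off_site_labels=[float(b) for b in off_bp],
                origins=[origins[i] for i in order],
            )
        )
    return traces, truths


# ---------------------------------------------------------------------------
# Plasmid fields (two-channel counting geometry)
# ---------------------------------------------------------------------------

@dataclass
class PlasmidTruth:
    center: tuple[float, float]
    radius: float
    n_labels: int
    is_decoy: bool


@dataclass
class PlasmidField:
    """A simulated two-channel field: backbone localizations + label emitters."""

    backbone_points: np.ndarray       # (N, 2) x,y in px
    label_positions: np.ndarray       # (M, 2) x,y in px
    label_plasmid: np.ndarray         # (M,) index into truths
    truths: list[PlasmidTruth]
    field_size: int


def _label_count(refmap: ReferenceMap, cfg: SimConfig,
                 rng: np.random.Generator) -> int:
    n = int(rng.binomial(len(refmap), cfg.p_site)) if len(refmap) else 0
    if cfg.p_second > 0 and n:
        n += int(rng.binomial(n, cfg.p_second))
    n += int(rng.poisson(cfg.rho_off * refmap.length / 1000.0))
    return n


def simulate_plasmid_field(
    refmap: ReferenceMap,
    cfg: SimConfig,
    n_plasmids: int,
    field_size: int = 128,
    radius: float = 4.0,
    backbone_locs: int = 400,
    backbone_jitter: float = 0.35,
    decoy_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PlasmidField:
    """Simulate a field of surface-deposited plasmids for the counting assay.

    Each plasmid is a closed, roughly circular cloud of backbone
    localizations (emulating reversible intercalator binding) at a random,
    non-overlapping field position, carrying a number of label emitters drawn
    from the site/off-target model.  A ``decoy_fraction`` of objects are
    non-circular (linear) decoys the mask filter must reject; decoys are
    flagged in the truth record.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if n_plasmids == 0:
        return PlasmidField(np.empty((0, 2)), np.empty((0, 2)),
                            np.empty(0, dtype=int), [], field_size)

    margin = 3.5 * radius
    min_sep = 4.0 * radius
    centers: list[tuple[float, float]] = []
    for _ in range(n_plasmids):
        for attempt in range(4000):
            c = rng.uniform(margin, field_size - margin, size=2)
            if all((c[0] - x) ** 2 + (c[1] - y) ** 2 >= min_sep**2
                   for x, y in centers):
                centers.append((float(c[0]), float(c[1])))
                break
        else:
            raise RuntimeError(
                f"could not place {n_plasmids} plasmids of radius {radius} "
                f"in a {field_size} px field without overlap"
            )

    backbone = []
    labels = []
    label_owner = []
    truths: list[PlasmidTruth] = []
    for i, (cx, cy) in enumerate(centers):
        is_decoy = bool(rng.random() < decoy_fraction)
        count = _label_count(refmap, cfg, rng)
        if is_decoy:
            # linear decoy: localizations along a random segment
            theta = rng.uniform(0, np.pi)
            t = rng.uniform(-3 * radius, 3 * radius, size=backbone_locs)
            pts = np.stack(
                [cx + t * np.cos(theta), cy + t * np.sin(theta)], axis=1
            ) + rng.normal(0, backbone_jitter, size=(backbone_locs, 2))
            lab_t = rng.uniform(-3 * radius, 3 * radius, size=count)
            lab = np.stack(
                [cx + lab_t * np.cos(theta), cy + lab_t * np.sin(theta)], axis=1
            ) + rng.normal(0, backbone_jitter, size=(count, 2))
        else:
            ang = rng.uniform(0, 2 * np.pi, size=backbone_locs)
            r = radius + rng.normal(0, backbone_jitter, size=backbone_locs)
            pts = np.stack(
                [cx + r * np.cos(ang), cy + r * np.sin(ang)], axis=1)
            lab_ang = rng.uniform(0, 2 * np.pi, size=count)
            lab_r = radius * 0.9 + rng.normal(0, backbone_jitter, size=count)
            lab = np.stack(
                [cx + lab_r * np.cos(lab_ang), cy + lab_r * np.sin(lab_ang)],
                axis=1)
        backbone.append(pts)
        labels.append(lab)
        label_owner.append(np.full(count, i))
        truths.append(PlasmidTruth((cx, cy), radius, count, is_decoy))

    return PlasmidField(
        backbone_points=np.concatenate(backbone) if backbone else np.empty((0, 2)),
        label_positions=np.concatenate(labels) if labels else np.empty((0, 2)),
        label_plasmid=np.concatenate(label_owner).astype(int)
        if label_owner else np.empty(0, dtype=int),
        truths=truths,
        field_size=field_size,
    )


# ---------------------------------------------------------------------------
# Photobleaching movies
# ---------------------------------------------------------------------------

@dataclass
class MovieConfig:
    """Imaging model for single-fluorophore photobleaching movies."""

    field_size: int = 32            # px (square field)
    n_frames: int = 400
    pixel_size_nm: float = 100.0
    psf_sigma: float = 1.1          # px
    photons_per_frame: float = 400.0
    bleach_lifetime: float = 100.0  # mean frames to bleach (geometric)
    background: float = 20.0        # photons / px / frame
    read_noise: float = 2.0         # e- rms, Gaussian
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.psf_sigma < 0.5:
            raise ValueError("psf_sigma must be >= 0.5 px")
        for name in ("field_size", "n_frames"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruthEmitter:
    """A single fluorophore: position, brightness and its bleaching frame.

    Intensity follows the single-step model: full brightness on frames
    0..bleach_frame inclusive, zero afterwards.
    """

    x: float
    y: float
    brightness: float = 400.0
    bleach_frame: int | None = None    # None: draw geometrically


def _psf_patch(x: float, y: float, sigma: float, size: int) -> np.ndarray:
    """Unit-integral pixel-sampled 2D Gaussian over the full field."""
    grid = np.arange(size)
    gx = np.exp(-((grid - x) ** 2) / (2 * sigma**2))
    gy = np.exp(-((grid - y) ** 2) / (2 * sigma**2))
    patch = np.outer(gy, gx)
    return patch / (2 * np.pi * sigma**2)


def simulate_movie(
    emitters: Sequence[GroundTruthEmitter],
    mcfg: MovieConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[GroundTruthEmitter]]:
    """Render a (frames, H, W) photobleaching movie of the given emitters.

    Returns the stack and the emitter list with bleach frames resolved
    (drawn geometrically from ``bleach_lifetime`` where unset).
    """
    if rng is None:
        rng = np.random.default_rng(mcfg.seed)
    size, n_frames = mcfg.field_size, mcfg.n_frames
    resolved: list[GroundTruthEmitter] = []
    for em in emitters:
        if not (0 <= em.x < size and 0 <= em.y < size):
            raise ValueError(f"emitter at ({em.x}, {em.y}) outside field")
        bf = em.bleach_frame
        if bf is None:
            bf = int(min(rng.geometric(1.0 / mcfg.bleach_lifetime) - 1,
                         n_frames - 1))
        resolved.append(GroundTruthEmitter(em.x, em.y, em.brightness, bf))

    clean = np.full((n_frames, size, size), float(mcfg.background))
    for em in resolved:
        patch = _psf_patch(em.x, em.y, mcfg.psf_sigma, size) * em.brightness
        clean[: em.bleach_frame + 1] += patch

    if mcfg.shot_noise:
        stack = rng.poisson(clean).astype(float)
    else:
        stack = clean.copy()
    if mcfg.read_noise > 0:
        stack += rng.normal(0, mcfg.read_noise, size=stack.shape)
    return stack, resolved


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def simulate_kinetics(
    times: Sequence[float],
    k: float,
    p_inf: float,
    refmap: ReferenceMap,
    cfg: SimConfig,
    n_per_time: int = 300,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], dict]:
    """Label counts of a stopped labeling reaction at each time point.

    Per-site labeling probability saturates as p(t) = p_inf (1 - e^{-k t});
    off-target labeling is time-independent in this model.  Returns one
    count array (length ``n_per_time``) per time point plus the truth dict.
    """
    if k <= 0:
        raise ValueError("rate constant k must be positive")
    times = [float(t) for t in times]
    if any(t < 0 for t in times):
        raise ValueError("negative reaction time")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    samples: list[np.ndarray] = []
    for t in times:
        p_t = p_inf * (1.0 - np.exp(-k * t))
        cfg_t = cfg.with_(p_site=float(p_t), n_molecules=n_per_time)
        counts = np.array(
            [_label_count(refmap, cfg_t, rng) for _ in range(n_per_time)]
        )
        samples.append(counts)
    truth = {"k": k, "p_inf": p_inf, "n_sites": len(refmap),
             "rho_off": cfg.rho_off, "length_kb": refmap.length_kb}
    return samples, truth


# ---------------------------------------------------------------------------
# Movie / trace (de)serialization
# ---------------------------------------------------------------------------

def write_movie(stack: np.ndarray, path) -> None:
    """Write a (frames, H, W) stack as a multi-frame TIFF."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_movie(path) -> np.ndarray:
    """Read a multi-frame TIFF written by :func:`write_movie`."""
    import tifffile

    return tifffile.imread(str(path)).astype(float)



def traces_to_frame(traces: Sequence[MoleculeTrace]):
    """Flatten traces to a tidy DataFrame (molecule_id, position_nm, length)."""
    import pandas as pd

    rows = []
    for tr in traces:
        if len(tr.label_positions) == 0:
            rows.append((tr.molecule_id, np.nan, tr.molecule_length))
        for p in tr.label_positions:
            rows.append((tr.molecule_id, float(p), tr.molecule_length))
    return pd.DataFrame(
        rows, columns=["molecule_id", "position_nm", "molecule_length_nm"]
    )


def traces_from_frame(df) -> list[MoleculeTrace]:
    traces = []
    for mol_id, grp in df.groupby("molecule_id", sort=True):
        pos = grp["position_nm"].dropna().to_numpy(dtype=float)
        traces.append(
            MoleculeTrace(int(mol_id), np.sort(pos),
                          float(grp["molecule_length_nm"].iloc[0]))
        )
    return traces
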
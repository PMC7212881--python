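"""Synthetic multiphoton-like images of tumor and nontumor brain tissue.

No public image data exist for this problem, so the pipeline is exercised on
phenomenological textures that reproduce the morphochemical contrasts seen
in label-free multiphoton imaging of brain tissue:

* **CARS** — nontumor: ordered axon-like strands plus regularly spaced
  cell-like blobs on a smooth background; tumor: low-frequency intensity
  patches (spatial inhomogeneity) with densely packed, irregularly sized
  blobs and fading strand order.
* **TPEF** — nontumor: sparse, regularly distributed punctate
  autofluorescence; tumor: diffuse fluorescence plus clustered puncta.
* **SHG** — mostly dark; with some probability a fibrillar structure
  (a single arc/ellipse fragment in nontumor tissue — corpora amylacea or a
  vessel wall — versus multiple straighter collagen fibers in tumors).

Every class-discriminating recipe parameter difference is scaled linearly by
``effect_size``: at 0 the two classes are identical in distribution, at the
default 1.0 they are separable at the level the pipeline's acceptance
simulations demonstrate.  Intensities are in arbitrary units (min–max
normalization downstream makes the absolute scale irrelevant); additive
Gaussian detector noise is applied everywhere and intensities are clipped
at 0.  A spec plus a seed fully determines every pixel.

These are texture stand-ins, not optical simulations: they carry no
diffraction, no coherent image formation, and no nucleus-level morphology.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging_io import Channel, FieldOfView, Image2D, DEFAULT_FOV_SHAPE
from .lda_classifier import split_by_patient

CHANNEL_ORDER = (Channel.CARS, Channel.TPEF, Channel.SHG)


class SyntheticError(Exception):
    """Invalid synthetic-data specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic tissue class.

    ``effect_size`` linearly scales every tumor-vs-nontumor recipe
    difference (0 = identical classes).  ``cell_density`` is the nontumor
    CARS blob density in blobs per 1000 µm²; ``patch_corr_len_um`` the
    correlation length of tumor intensity patches; ``shg_presence_prob`` the
    nontumor probability that an SHG-active structure is present at all.
    """

    tissue_class: str = "tumor"
    channels: tuple[Channel, ...] = (Channel.CARS, Channel.TPEF)
    effect_size: float = 1.0
    noise_sd: float = 0.05
    cell_density: float = 3.0
    patch_corr_len_um: float = 25.0
    shg_presence_prob: float = 0.25
    fov_shape: tuple[int, int] = DEFAULT_FOV_SHAPE
    pixel_size_um: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels",
                           tuple(Channel(c) for c in self.channels))
        if self.tissue_class not in ("tumor", "nontumor"):
            raise SyntheticError(f"unknown tissue class {self.tissue_class!r}")
        if not self.channels:
            raise SyntheticError("at least one channel required")
        if self.effect_size < 0:
            raise SyntheticError("effect_size must be ≥ 0")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be ≥ 0")
        if not (0 <= self.shg_presence_prob <= 1):
            raise SyntheticError("shg_presence_prob must be in [0, 1]")
        if self.cell_density <= 0 or self.patch_corr_len_um <= 0:
            raise SyntheticError("densities and length scales must be positive")
        r, c = self.fov_shape
        if r < 2 or c < 2 or self.pixel_size_um <= 0:
            raise SyntheticError("invalid FoV geometry")


#: Recipe keys that receive per-patient multiplicative jitter (interpatient
#: variability); drawn identically for both classes so the jitter itself
#: carries no class information.
JITTERED_PARAMS = (
    "cars_strand_amp", "cars_cell_density", "cars_blob_amp", "cars_patch_amp",
    "tpef_punct_density", "tpef_punct_amp", "tpef_diffuse_amp",
    "shg_fiber_amp",
)


def recipe_params(spec: SyntheticSpec) -> dict[str, float]:
    """Numeric texture-recipe parameters for one class.

    Nontumor values are the base; tumor values shift by ``effect_size``
    times a fixed delta, so every class difference scales linearly and
    vanishes at effect_size = 0.
    """
    g = spec.effect_size * (1.0 if spec.tissue_class == "tumor" else 0.0)
    return {
        # CARS: strands + cell blobs + (tumor) low-frequency patches
        "cars_background": 0.55,
        "cars_strand_amp": max(0.0, 0.35 - 0.30 * g),
        "cars_strand_wavelength_um": 12.0,
        "cars_cell_density": spec.cell_density * (1.0 + 1.3 * g),
        "cars_jitter_frac": 0.12 + 0.88 * g,
        "cars_blob_sigma_um": 3.0,
        "cars_blob_sigma_cv": 0.10 + 0.50 * g,
        "cars_blob_amp": 0.35,          # subtracted: lipid-poor nuclei appear dark
        "cars_blob_amp_cv": 0.10 + 0.60 * g,
        "cars_patch_amp": 0.55 * g,
        "cars_patch_corr_len_um": spec.patch_corr_len_um,
        # TPEF: puncta + (tumor) diffuse/clustered fluorescence
        "tpef_background": 0.12,
        "tpef_punct_density": 1.5 * (1.0 + 1.2 * g),
        "tpef_jitter_frac": 0.12 + 0.88 * g,
        "tpef_punct_sigma_um": 1.6,
        "tpef_punct_amp": 0.8,
        "tpef_punct_amp_cv": 0.10 + 0.50 * g,
        "tpef_diffuse_amp": 0.45 * g,
        "tpef_diffuse_corr_len_um": 15.0,
        "tpef_cluster_frac": min(1.0, 0.7 * g),
        "tpef_cluster_sigma_um": 10.0,
        # SHG: rare arcs (nontumor) vs. variably present fiber bundles (tumor)
        "shg_background": 0.02,
        "shg_presence_prob": float(np.clip(spec.shg_presence_prob + 0.5 * g, 0.0, 1.0)),
        "shg_n_fibers": 1.0 + 5.0 * g,
        "shg_curvature": max(0.05, 0.8 - 0.6 * g),
        "shg_fiber_amp": 0.6,
        "shg_thickness_um": 2.0,
    }


def blend_params(nontumor: Mapping[str, float], tumor: Mapping[str, float],
                 w: float) -> dict[str, float]:
    """Linear interpolation between the two class recipes (w = tumor weight)."""
    return {k: (1.0 - w) * nontumor[k] + w * tumor[k] for k in nontumor}


def _apply_jitter(params: dict[str, float],
                  factors: Mapping[str, float]) -> dict[str, float]:
    out = dict(params)
    for k, f in factors.items():
        out[k] = out[k] * f
    return out


def draw_patient_jitter(rng: np.random.Generator, sd: float) -> dict[str, float]:
    """Multiplicative log-normal jitter factors for one patient."""
    return {k: float(np.exp(rng.normal(0.0, sd))) for k in JITTERED_PARAMS}


# --------------------------------------------------------------------------
# texture primitives

def _smooth_noise(shape: tuple[int, int], corr_px: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-SD Gaussian random field with the given correlation length."""
    field = gaussian_filter(rng.standard_normal(shape), sigma=corr_px, truncate=3.0)
    sd = field.std()
    return field / sd if sd > 0 else field


def _strand_field(shape: tuple[int, int], wavelength_px: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Quasi-regular oriented strands in [0, 1] (axon-like banding)."""
    theta = rng.uniform(0.0, np.pi)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    u = np.cos(theta) * cc + np.sin(theta) * rr
    phase = 1.5 * _smooth_noise(shape, max(2.0, wavelength_px), rng)
    return 0.5 * (1.0 + np.sin(2.0 * np.pi * u / wavelength_px + phase))


def _lattice_positions(shape: tuple[int, int], n: int, jitter_frac: float,
                       rng: np.random.Generator) -> np.ndarray:
    """~n points on a jittered square lattice (jitter_frac ≈ 1 → random)."""
    R, C = shape
    if n < 1:
        return np.empty((0, 2))
    spacing = np.sqrt(R * C / n)
    rows = np.arange(spacing / 2, R, spacing)
    cols = np.arange(spacing / 2, C, spacing)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pos = np.stack([rr.ravel(), cc.ravel()], axis=1)
    pos = pos + rng.normal(0.0, jitter_frac * spacing, size=pos.shape)
    pos[:, 0] %= R
    pos[:, 1] %= C
    return pos


def _render_blobs(canvas: np.ndarray, positions: np.ndarray,
                  sigmas: np.ndarray, amps: np.ndarray) -> None:
    """Accumulate Gaussian blobs in-place (each drawn in a 3σ window)."""
    R, C = canvas.shape
    for (r, c), s, a in zip(positions, sigmas, amps):
        rad = max(2, int(np.ceil(3.0 * s)))
        r0, r1 = max(0, int(r) - rad), min(R, int(r) + rad + 1)
        c0, c1 = max(0, int(c) - rad), min(C, int(c) + rad + 1)
        if r1 <= r0 or c1 <= c0:
            continue
        dr = np.arange(r0, r1) - r
        dc = np.arange(c0, c1) - c
        canvas[r0:r1, c0:c1] += a * np.exp(
            -(dr[:, None] ** 2 + dc[None, :] ** 2) / (2.0 * s * s))


def _fiber_strokes(shape: tuple[int, int], n_fibers: int, curvature: float,
                   thickness_px: float, rng: np.random.Generator) -> np.ndarray:
    """Fibrillar strokes: quadratic Bézier curves with Gaussian cross-profile."""
    R, C = shape
    spikes = np.zeros(shape)
    diag = float(np.hypot(R, C))
    for _ in range(n_fibers):
        p0 = rng.uniform([0, 0], [R, C])
        theta = rng.uniform(0.0, np.pi)
        length = rng.uniform(0.3, 0.7) * diag
        direction = np.array([np.sin(theta), np.cos(theta)])
        p2 = p0 + length * direction
        perp = np.array([-direction[1], direction[0]])
        p1 = 0.5 * (p0 + p2) + curvature * length * rng.uniform(0.3, 0.7) * perp
        t = np.linspace(0.0, 1.0, max(8, int(2 * length)))[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
        idx = np.round(pts).astype(int)
        keep = (idx[:, 0] >= 0) & (idx[:, 0] < R) & (idx[:, 1] >= 0) & (idx[:, 1] < C)
        idx = idx[keep]
        np.add.at(spikes, (idx[:, 0], idx[:, 1]), 1.0)
    out = gaussian_filter(spikes, sigma=thickness_px, truncate=3.0)
    m = out.max()
    return out / m if m > 0 else out


# --------------------------------------------------------------------------
# channel recipes

def _gen_cars(shape, px, p, rng):
    canvas = np.full(shape, p["cars_background"])
    canvas += p["cars_strand_amp"] * _strand_field(
        shape, p["cars_strand_wavelength_um"] / px, rng)
    area_um2 = shape[0] * shape[1] * px * px
    n = max(1, int(round(p["cars_cell_density"] * area_um2 / 1000.0)))
    pos = _lattice_positions(shape, n, p["cars_jitter_frac"], rng)
    sigmas = (p["cars_blob_sigma_um"] / px) * np.exp(
        rng.normal(0.0, p["cars_blob_sigma_cv"], len(pos)))
    amps = -p["cars_blob_amp"] * np.exp(
        rng.normal(0.0, p["cars_blob_amp_cv"], len(pos)))
    _render_blobs(canvas, pos, sigmas, amps)
    if p["cars_patch_amp"] > 0:
        canvas += p["cars_patch_amp"] * _smooth_noise(
            shape, p["cars_patch_corr_len_um"] / px, rng)
    else:  # keep the draw sequence identical across classes
        _smooth_noise(shape, p["cars_patch_corr_len_um"] / px, rng)
    return canvas


def _gen_tpef(shape, px, p, rng):
    canvas = np.full(shape, p["tpef_background"])
    diffuse = _smooth_noise(shape, p["tpef_diffuse_corr_len_um"] / px, rng)
    if p["tpef_diffuse_amp"] > 0:
        canvas += p["tpef_diffuse_amp"] * 0.5 * (1.0 + diffuse)
    area_um2 = shape[0] * shape[1] * px * px
    n = max(1, int(round(p["tpef_punct_density"] * area_um2 / 1000.0)))
    pos = _lattice_positions(shape, n, p["tpef_jitter_frac"], rng)
    n_clustered = int(round(p["tpef_cluster_frac"] * len(pos)))
    if n_clustered > 0:
        n_centers = max(1, n_clustered // 8)
        centers = rng.uniform([0, 0], list(shape), size=(n_centers, 2))
        which = rng.integers(0, n_centers, n_clustered)
        offsets = rng.normal(0.0, p["tpef_cluster_sigma_um"] / px, (n_clustered, 2))
        pos[:n_clustered] = centers[which] + offsets
        pos[:, 0] %= shape[0]
        pos[:, 1] %= shape[1]
    sigmas = np.full(len(pos), p["tpef_punct_sigma_um"] / px)
    amps = p["tpef_punct_amp"] * np.exp(
        rng.normal(0.0, p["tpef_punct_amp_cv"], len(pos)))
    _render_blobs(canvas, pos, sigmas, amps)
    return canvas


def _gen_shg(shape, px, p, rng):
    canvas = np.full(shape, p["shg_background"])
    present = rng.random() < p["shg_presence_prob"]
    n_fibers = max(1, int(round(p["shg_n_fibers"])))
    strokes = _fiber_strokes(shape, n_fibers, p["shg_curvature"],
                             p["shg_thickness_um"] / px, rng)
    if present:
        canvas += p["shg_fiber_amp"] * strokes
    return canvas


_CHANNEL_GENERATORS = {
    Channel.CARS: _gen_cars,
    Channel.TPEF: _gen_tpef,
    Channel.SHG: _gen_shg,
}


def gen_fov(spec: SyntheticSpec, rng: np.random.Generator | None = None,
            sample_id: str = "", grid_row: int = 0, grid_col: int = 0,
            params: Mapping[str, float] | None = None) -> dict[Channel, FieldOfView]:
    """Generate one multi-channel FoV.

    ``params`` (e.g. jittered or blended recipes) overrides the spec's own
    recipe; ``rng`` defaults to a generator seeded from ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = dict(params) if params is not None else recipe_params(spec)
    out: dict[Channel, FieldOfView] = {}
    for channel in CHANNEL_ORDER:
        if channel not in spec.channels:
            continue
        canvas = _CHANNEL_GENERATORS[channel](spec.fov_shape, spec.pixel_size_um, p, rng)
        if spec.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, spec.noise_sd, spec.fov_shape)
        canvas = np.clip(canvas, 0.0, None)
        out[channel] = FieldOfView(pixels=canvas, grid_row=grid_row,
                                   grid_col=grid_col, sample_id=sample_id,
                                   channel=channel,
                                   pixel_size_um=spec.pixel_size_um)
    return out


# --------------------------------------------------------------------------
# cohorts

@dataclass
class SyntheticSample:
    sample_id: str
    tissue_class: str
    type_tag: str
    fovs: list[dict[Channel, FieldOfView]]


@dataclass
class SyntheticCohort:
    samples: list[SyntheticSample]
    train_ids: list[str]
    test_ids: list[str]

    @property
    def labels(self) -> dict[str, str]:
        return {s.sample_id: s.tissue_class for s in self.samples}


def iter_cohort(n_tumor_patients: int, n_nontumor_patients: int,
                fovs_per_sample: int = 100,
                spec: SyntheticSpec | None = None,
                seed: int = 0,
                patient_jitter_sd: float = 0.08) -> Iterator[SyntheticSample]:
    """Yield synthetic patients one at a time (tumor patients first).

    Each patient receives multiplicative log-normal jitter of the recipe
    amplitudes/densities (interpatient variability), drawn identically for
    both classes, then ``fovs_per_sample`` independent FoVs.
    """
    if n_tumor_patients < 1 or n_nontumor_patients < 1 or fovs_per_sample < 1:
        raise SyntheticError("patient and FoV counts must be ≥ 1")
    base = spec if spec is not None else SyntheticSpec()
    roster = ([("tumor", f"T{i:03d}") for i in range(n_tumor_patients)]
              + [("nontumor", f"N{i:03d}") for i in range(n_nontumor_patients)])
    children = np.random.SeedSequence(seed).spawn(len(roster))
    for (tissue_class, sample_id), child in zip(roster, children):
        rng = np.random.default_rng(child)
        pspec = dataclasses.replace(base, tissue_class=tissue_class)
        params = _apply_jitter(recipe_params(pspec),
                               draw_patient_jitter(rng, patient_jitter_sd))
        fovs = [gen_fov(pspec, rng, sample_id=sample_id, grid_row=0, grid_col=k,
                        params=params)
                for k in range(fovs_per_sample)]
        yield SyntheticSample(sample_id=sample_id, tissue_class=tissue_class,
                              type_tag=tissue_class, fovs=fovs)


def gen_cohort(n_tumor_patients: int, n_nontumor_patients: int,
               fovs_per_sample: int = 100,
               spec: SyntheticSpec | None = None,
               seed: int = 0,
               patient_jitter_sd: float = 0.08,
               train_proportion: float = 0.5) -> SyntheticCohort:
    """Materialize a cohort plus a reproducible patient-level train/test split."""
    samples = list(iter_cohort(n_tumor_patients, n_nontumor_patients,
                               fovs_per_sample, spec, seed, patient_jitter_sd))
    split_seed = int(np.random.SeedSequence([seed, 0x5917]).generate_state(1)[0]
                     % 2 ** 31)
    train, test = split_by_patient({s.sample_id: s.tissue_class for s in samples},
                                   train_proportion, split_seed)
    return SyntheticCohort(samples=samples, train_ids=train, test_ids=test)


def gen_border_section(width_tiles: int, height_tiles: int,
                       transition_center: float, transition_width: float,
                       spec: SyntheticSpec | None = None,
                       seed: int = 0) -> tuple[dict[Channel, Image2D], np.ndarray]:
    """A large tiled scan crossing a tumor border.

    Tiles left of the transition are drawn from the nontumor recipe, tiles
    right of it from the tumor recipe; inside the transition band of width
    ``transition_width`` (in tiles, centered on ``transition_center``) the
    recipes blend linearly.  Returns the per-channel stitched images and a
    (height_tiles × width_tiles) array of per-tile truth labels (majority
    class, i.e. the side of the transition center the tile's midpoint falls
    on).
    """
    if width_tiles < 1 or height_tiles < 1:
        raise SyntheticError("section must be at least 1×1 tiles")
    if not (0 < transition_center < width_tiles):
        raise SyntheticError("transition center must lie inside the section")
    if transition_width < 0:
        raise SyntheticError("transition width must be ≥ 0")
    base = spec if spec is not None else SyntheticSpec()
    p_nt = recipe_params(dataclasses.replace(base, tissue_class="nontumor"))
    p_tu = recipe_params(dataclasses.replace(base, tissue_class="tumor"))
    rows, cols = base.fov_shape
    canvases = {c: np.zeros((height_tiles * rows, width_tiles * cols))
                for c in base.channels}
    labels = np.empty((height_tiles, width_tiles), dtype=object)
    children = np.random.SeedSequence([seed, 0xB0]).spawn(height_tiles * width_tiles)
    for r in range(height_tiles):
        for c in range(width_tiles):
            mid = c + 0.5
            if transition_width == 0:
                w = 1.0 if mid > transition_center else 0.0
            else:
                w = float(np.clip(
                    (mid - (transition_center - transition_width / 2.0))
                    / transition_width, 0.0, 1.0))
            rng = np.random.default_rng(children[r * width_tiles + c])
            fovs = gen_fov(base, rng, grid_row=r, grid_col=c,
                           params=blend_params(p_nt, p_tu, w))
            for ch, fov in fovs.items():
                canvases[ch][r * rows:(r + 1) * rows,
                             c * cols:(c + 1) * cols] = fov.pixels
            labels[r, c] = "tumor" if mid > transition_center else "nontumor"
    images = {ch: Image2D(pixels=canvas, pixel_size_um=base.pixel_size_um, channel=ch)
              for ch, canvas in canvases.items()}
    return images, labels
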
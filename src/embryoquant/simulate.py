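"""Synthetic two-cell embryo movies with ground truth.

Real two-cell *C. elegans* recordings pair a DIC channel (fine
intracellular texture, smooth background) with a fluorescence channel in
which nuclei are brighter than cytoplasm, which is brighter than the
medium outside the embryo. The anterior AB blastomere is larger than the
posterior P1 blastomere, and a tagged replication factor may accumulate
asymmetrically between the two nuclei. This module renders movies with
exactly that statistical structure — plus per-z defocus blur, additive
Gaussian noise, and nuclear-envelope-breakdown (NEB) events — together
with the exact masks and intensities used to render them, so every
downstream stage can be scored against truth.

Randomness
----------
One ``numpy.random.Generator`` seeded from ``SimParams.seed`` drives the
whole movie. Stream consumption order (stable contract for regeneration):

1. one standard-normal DIC texture field (Y, X),
2. for each frame t, each z-slice, fluorescence then DIC: one additive
   noise field (skipped entirely when ``noise_sd == 0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.ndimage import gaussian_filter
from skimage.morphology import convex_hull_image

from .errors import ParameterError
from .io import Hyperstack

AB, P1 = "AB", "P1"


class Ellipse(BaseModel):
    """Axis-aligned-by-default ellipse in pixel coordinates (row, col)."""

    model_config = ConfigDict(frozen=True)

    center_y: float
    center_x: float
    semi_y: float
    semi_x: float
    orientation_deg: float = 0.0

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_y * self.semi_x)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        dy = yy - self.center_y
        dx = xx - self.center_x
        th = np.deg2rad(self.orientation_deg)
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        return (u / self.semi_x) ** 2 + (v / self.semi_y) ** 2 <= 1.0


class SimParams(BaseModel):
    """Parameters of one synthetic movie.

    Intensities are in arbitrary units (AU); the movie is written as
    16-bit unsigned, so defaults sit comfortably inside [0, 65535].
    ``asymmetry_ratio`` is the P1/AB ratio of *background-corrected*
    nuclear means; the rendered P1 nuclear level is derived from it as
    ``background + ratio * (nuc_intensity_ab - background)`` so the
    ground-truth ratio is exact by construction.
    """

    model_config = ConfigDict(frozen=True)

    image_shape: tuple[int, int] = (150, 230)
    n_frames: int = 30
    n_z: int = 5
    focal_z: int = 2
    frame_interval_s: float = 8.0
    pixel_size_um: float = 0.2
    ab_ellipse: Ellipse = Ellipse(center_y=75, center_x=75, semi_y=55, semi_x=62)
    p1_ellipse: Ellipse = Ellipse(center_y=75, center_x=178, semi_y=45, semi_x=48)
    nucleus_radius_ab_px: float = 11.0
    nucleus_radius_p1_px: float = 9.0
    background_intensity: float = 100.0
    cyto_intensity_ab: float = 300.0
    cyto_intensity_p1: float = 300.0
    nuc_intensity_ab: float = 900.0
    asymmetry_ratio: float = 0.6
    noise_sd: float = 20.0
    defocus_sigma_per_z: float = 2.0
    neb_frame_ab: int | None = 22
    neb_frame_p1: int | None = 26
    neck_depth: int = 2
    dic_texture_grain_px: float = 1.0
    # strong enough that the 5x5-window local std inside the embryo dominates
    # the outside (camera noise only) >= 5-fold — the premise DIC mapping
    # relies on; at grain 1 px and sd 200 the measured factor is ~6
    dic_texture_sd: float = 200.0
    channel_order: tuple[str, str] = ("fluorescence", "dic")
    seed: int = 0

    @property
    def nuc_intensity_p1(self) -> float:
        return self.background_intensity + self.asymmetry_ratio * (
            self.nuc_intensity_ab - self.background_intensity
        )

    @model_validator(mode="after")
    def _check(self) -> "SimParams":
        if self.ab_ellipse.area <= self.p1_ellipse.area:
            raise ParameterError("AB ellipse area must exceed P1 ellipse area")
        if self.asymmetry_ratio <= 0:
            raise ParameterError("asymmetry_ratio must be > 0")
        if not (
            self.nuc_intensity_ab
            >= self.cyto_intensity_ab
            >= self.background_intensity
        ):
            raise ParameterError(
                "require nuc_intensity >= cyto_intensity >= background_intensity"
            )
        for neb in (self.neb_frame_ab, self.neb_frame_p1):
            if neb is not None and not (0 <= neb < self.n_frames):
                raise ParameterError("neb_frame must lie in [0, n_frames)")
        if not (0 <= self.focal_z < self.n_z):
            raise ParameterError("focal_z must lie in [0, n_z)")
        if self.noise_sd < 0 or self.defocus_sigma_per_z < 0:
            raise ParameterError("noise_sd and defocus_sigma_per_z must be >= 0")
        if set(self.channel_order) != {"fluorescence", "dic"}:
            raise ParameterError("channel_order must contain fluorescence and dic")
        return self


@dataclass
class GroundTruth:
    """Truth channel for a synthetic movie.

    ``cell_labels``/``nucleus_labels`` are (T, Y, X) label stacks with
    0 = background, 1 = AB, 2 = P1. Means are in AU on the rendered
    (absolute) scale; ``true_ratio`` is the background-corrected P1/AB
    nuclear ratio.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    true_nuclear_means: dict[str, np.ndarray]
    true_cyto_means: dict[str, np.ndarray]
    background: float
    true_neb_frames: dict[str, int | None]
    true_ratio: float
    fusion_frame: int = 0

    def cell_mask(self, cell: str, frame: int = 0) -> np.ndarray:
        return self.cell_labels[frame] == (1 if cell == AB else 2)

    def nucleus_mask(self, cell: str, frame: int) -> np.ndarray:
        return self.nucleus_labels[frame] == (1 if cell == AB else 2)


def apply_defocus(image: np.ndarray, z_offset: int, sigma_per_z: float) -> np.ndarray:
    """Defocus an in-focus scene by ``|z_offset|`` z-steps.

    Gaussian blur with sigma = |z_offset| * sigma_per_z px; zero offset
    (or zero sigma) returns the input values unchanged.
    """
    if sigma_per_z < 0:
        raise ParameterError("sigma_per_z must be >= 0")
    image = np.asarray(image, dtype=float)
    sigma = abs(z_offset) * sigma_per_z
    if sigma == 0:
        return image.copy()
    return gaussian_filter(image, sigma=sigma, mode="reflect")


def _disk_mask(shape, cy, cx, radius) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _carve_neck(mask: np.ndarray, x_split: int, depth: int) -> np.ndarray:
    """Deepen the contact-zone concavity by ``depth`` px from top and bottom."""
    mask = mask.copy()
    for col in range(max(0, x_split - 1), min(mask.shape[1], x_split + 2)):
        rows = np.nonzero(mask[:, col])[0]
        if rows.size > 2 * depth:
            mask[rows[:depth], col] = False
            mask[rows[-depth:], col] = False
    return mask


def build_geometry(params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Static cell and nucleus label images (0 bg, 1 AB, 2 P1).

    The two ellipses abut; pixels claimed by both are assigned to the
    nearer centre, which flattens the contact boundary. With
    ``neck_depth == 0`` the outline is replaced by its convex hull (no
    concave features — exercises the ellipse-fallback split); with
    ``neck_depth > 0`` the natural junction concavity is carved deeper.
    """
    shape = params.image_shape
    a_mask = params.ab_ellipse.mask(shape)
    p_mask = params.p1_ellipse.mask(shape)
    if not a_mask.any() or not p_mask.any():
        raise ParameterError("ellipse lies outside the image")
    overlap = a_mask & p_mask
    if overlap.sum() > 0.3 * min(a_mask.sum(), p_mask.sum()):
        raise ParameterError("cells overlap beyond tolerance")

    union = a_mask | p_mask
    x_split = int(
        round((params.ab_ellipse.center_x + params.p1_ellipse.center_x) / 2)
    )
    if overlap.any():
        x_split = int(round(np.nonzero(overlap.any(axis=0))[0].mean()))
    if params.neck_depth == 0:
        outline = convex_hull_image(union)
    else:
        outline = _carve_neck(union, x_split, params.neck_depth)

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d_ab = (yy - params.ab_ellipse.center_y) ** 2 + (xx - params.ab_ellipse.center_x) ** 2
    d_p1 = (yy - params.p1_ellipse.center_y) ** 2 + (xx - params.p1_ellipse.center_x) ** 2
    cells = np.zeros(shape, dtype=np.uint8)
    cells[outline & (d_ab <= d_p1)] = 1
    cells[outline & (d_ab > d_p1)] = 2

    nuclei = np.zeros(shape, dtype=np.uint8)
    nuc_ab = _disk_mask(
        shape, params.ab_ellipse.center_y, params.ab_ellipse.center_x,
        params.nucleus_radius_ab_px,
    )
    nuc_p1 = _disk_mask(
        shape, params.p1_ellipse.center_y, params.p1_ellipse.center_x,
        params.nucleus_radius_p1_px,
    )
    if (nuc_ab & ~(cells == 1)).any() or (nuc_p1 & ~(cells == 2)).any():
        raise ParameterError("nucleus mask extends outside its cell")
    nuclei[nuc_ab] = 1
    nuclei[nuc_p1] = 2
    return cells, nuclei


def generate_two_cell_movie(params: SimParams) -> tuple[Hyperstack, GroundTruth]:
    """Render a movie and its ground truth.

    Fluorescence scene per frame: background / cytoplasm / nucleus
    piecewise-constant levels, nucleus removed from its cell's scene at
    and after that cell's NEB frame. DIC scene: smoothed-noise texture
    inside the embryo over a flat background. Each z-slice is the focal
    scene defocused by its distance to ``focal_z``, plus iid Gaussian
    noise. Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.image_shape
    cells, nuclei_static = build_geometry(params)
    embryo = cells > 0

    # 1st RNG draw: static DIC texture field
    texture = rng.standard_normal(shape)
    if params.dic_texture_grain_px > 0:
        texture = gaussian_filter(texture, params.dic_texture_grain_px, mode="reflect")
    sd = texture.std()
    if sd > 0:
        texture = texture / sd * params.dic_texture_sd
    # baseline 3 texture-sd above background so the written uint16 movie
    # does not clip the texture's negative excursions
    dic_base = params.background_intensity + 3.0 * params.dic_texture_sd
    dic_scene = np.full(shape, dic_base, dtype=float)
    dic_scene[embryo] += texture[embryo]

    neb = {AB: params.neb_frame_ab, P1: params.neb_frame_p1}
    nuc_level = {AB: params.nuc_intensity_ab, P1: params.nuc_intensity_p1}
    cyto_level = {AB: params.cyto_intensity_ab, P1: params.cyto_intensity_p1}

    n_t, n_z = params.n_frames, params.n_z
    fluor_idx = params.channel_order.index("fluorescence")
    dic_idx = params.channel_order.index("dic")
    data = np.empty((n_t, n_z, 2, *shape), dtype=float)
    nucleus_labels = np.zeros((n_t, *shape), dtype=np.uint8)
    nuc_means = {c: np.full(n_t, np.nan) for c in (AB, P1)}
    cyto_means = {c: np.zeros(n_t) for c in (AB, P1)}

    for t in range(n_t):
        scene = np.full(shape, params.background_intensity, dtype=float)
        for cell, label in ((AB, 1), (P1, 2)):
            region = cells == label
            scene[region] = cyto_level[cell]
            nucleus_present = neb[cell] is None or t < neb[cell]
            nuc_mask = nuclei_static == label
            if nucleus_present:
                scene[nuc_mask] = nuc_level[cell]
                nucleus_labels[t][nuc_mask] = label
                nuc_means[cell][t] = nuc_level[cell]
                cyto_region = region & ~nuc_mask
            else:
                cyto_region = region
            cyto_means[cell][t] = scene[cyto_region].mean()
        for z in range(n_z):
            fl = apply_defocus(scene, z - params.focal_z, params.defocus_sigma_per_z)
            di = apply_defocus(dic_scene, z - params.focal_z, params.defocus_sigma_per_z)
            if params.noise_sd > 0:
                fl = fl + params.noise_sd * rng.standard_normal(shape)
                di = di + params.noise_sd * rng.standard_normal(shape)
            data[t, z, fluor_idx] = fl
            data[t, z, dic_idx] = di

    stack = Hyperstack(
        data=data,
        pixel_size_um=params.pixel_size_um,
        frame_interval_s=params.frame_interval_s,
        channels=params.channel_order,
    )
    truth = GroundTruth(
        cell_labels=np.broadcast_to(cells, (n_t, *shape)).copy(),
        nucleus_labels=nucleus_labels,
        true_nuclear_means=nuc_means,
        true_cyto_means=cyto_means,
        background=params.background_intensity,
        true_neb_frames=neb,
        true_ratio=params.asymmetry_ratio,
    )
    return stack, truth


# --- named fixture presets -------------------------------------------------

def preset(name: str, seed: int = 0, **overrides) -> SimParams:
    """Named study-condition fixtures addressable from the CLI.

    ``asym04`` / ``asym06`` / ``symmetric``: P1/AB nuclear ratio 0.4 /
    0.6 / 1.0 with a concave neck (watershed split path).
    ``fallback_convex``: convex outline (ellipse-minor-axis split path).
    ``noisefree``: default geometry with zero noise.
    """
    table: dict[str, dict] = {
        "default": {},
        "asym04": {"asymmetry_ratio": 0.4},
        "asym06": {"asymmetry_ratio": 0.6},
        "symmetric": {"asymmetry_ratio": 1.0},
        # convex outline: near-equal abutting cells whose convex hull is a
        # left-right symmetric stadium, so the minor-axis fallback split is
        # both the correct behaviour and an almost equal-area division
        "fallback_convex": {
            "neck_depth": 0,
            "p1_ellipse": Ellipse(center_y=75, center_x=166, semi_y=54.5, semi_x=61.5),
        },
        "noisefree": {"noise_sd": 0.0},
    }
    if name not in table:
        raise ParameterError(f"unknown preset {name!r}; known: {sorted(table)}")
    kwargs = {**table[name], **overrides, "seed": seed}
    return SimParams(**kwargs)


PRESET_NAMES = ("default", "asym04", "asym06", "symmetric", "fallback_convex", "noisefree")
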
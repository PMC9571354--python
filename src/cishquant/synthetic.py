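"""Seeded generator of CISH/FISH-like bright-field scenes with full ground truth.

Clinical CISH tiles are not redistributable, so every downstream stage is
exercised on rendered scenes: blue elliptical nuclei (singular, overlapping
and border-truncated), magenta CEP17 and black HER2 dot signals, composited
as per-dye density maps and pushed through the same forward Beer-Lambert
camera model the color module inverts.  On clean scenes (no blur, no noise,
no quantisation) deconvolution therefore recovers the generator's density
maps exactly, which anchors the round-trip tests.

All randomness flows from ``SceneSpec.seed``; identical specs give
bit-identical images and ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import tifffile
import yaml
from scipy import ndimage as ndi

from cishquant.color import DEFAULT_BASIS, DyeBasis, build_od_matrix, synthesize_rgb

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "PlacementError",
    "generate_scene",
    "render_scene",
    "degrade",
    "make_label_map",
    "save_scene",
    "load_ground_truth",
]

_MAX_PLACEMENT_TRIES = 200


class PlacementError(RuntimeError):
    """Raised when a nucleus cannot be placed under its constraint."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults emulate a tile at roughly the working resolution of a 40x CISH
    scan: nucleus radii 14-26 px (areas ~600-2100 px, inside the 500-5000
    suitability gate), a healthy complement of ~4 HER2 and ~2 CEP17 signals
    per nucleus drawn from Poisson distributions, and small dot radii.
    """

    image_height_px: int = 256
    image_width_px: int = 256
    n_nuclei: int = 12
    overlap_fraction: float = 0.15
    truncated_fraction: float = 0.10
    nucleus_radius_range_px: tuple[int, int] = (14, 26)
    ellipticity_range: tuple[float, float] = (1.0, 1.5)
    signals_per_nucleus: tuple[float, float] = (4.0, 2.0)  # (her2_mean, cep17_mean)
    signal_radius_px: int = 2
    signal_straddle_fraction: float = 0.0
    background_density: float = 0.0  # diffuse stromal counterstain uptake
    dye_basis: DyeBasis = field(default_factory=lambda: DEFAULT_BASIS)
    blur_sigma_px: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_range_px[0] < 2:
            raise ValueError("nucleus radii must be >= 2 px")
        if not (0 <= self.overlap_fraction <= 1 and 0 <= self.truncated_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.overlap_fraction + self.truncated_fraction > 1:
            raise ValueError("overlap_fraction + truncated_fraction must be <= 1")
        if self.ellipticity_range[0] < 1:
            raise ValueError("axis ratios must be >= 1")
        if min(self.signals_per_nucleus) < 0 or self.signal_radius_px < 1:
            raise ValueError("signal parameters must be nonnegative")
        if self.blur_sigma_px < 0 or self.noise_sd < 0:
            raise ValueError("blur/noise must be nonnegative")
        if self.background_density < 0:
            raise ValueError("background density must be nonnegative")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["dye_basis"] = {
            k: list(v) for k, v in asdict(self.dye_basis).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        basis = data.pop("dye_basis")
        data["dye_basis"] = DyeBasis(**{k: tuple(v) for k, v in basis.items()})
        for key in ("nucleus_radius_range_px", "ellipticity_range", "signals_per_nucleus"):
            data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Per-instance truth for one scene.

    ``instance_masks`` are full-frame boolean masks; ``singular_flags[i]`` is
    true iff nucleus ``i`` neither overlaps another nucleus nor crosses the
    image border — only such nuclei are valid segmentation targets.
    ``signal_points`` holds ``(row, col, kind, parent_id)`` with kind in
    {"HER2", "CEP17"} and ``parent_id`` None for stray signals.
    """

    instance_masks: list[np.ndarray]
    singular_flags: list[bool]
    signal_points: list[tuple[float, float, str, int | None]]

    def instance_label_image(self, shape: tuple[int, int]) -> np.ndarray:
        """16-bit label image; 0 = background, i+1 = nucleus i (later wins ties)."""
        out = np.zeros(shape, dtype=np.uint16)
        for i, mask in enumerate(self.instance_masks):
            out[mask] = i + 1
        return out


def _ellipse_density(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    theta: float,
) -> np.ndarray:
    """Anti-aliased filled ellipse: density 1 inside, ~1 px smooth rim falloff."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = rr - center[0], cc - center[1]
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    a, b = radii
    # normalised radial coordinate; convert to an approximate signed pixel
    # distance from the rim using the local gradient scale min(a, b)
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    signed = (1.0 - r) * min(a, b)
    return np.clip(signed + 0.5, 0.0, 1.0)


def _disk_density(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    return _ellipse_density(shape, center, (radius, radius), 0.0)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render the float RGB image, the HxWx3 density maps and the ground truth.

    No blur, noise or 8-bit quantisation is applied here; this is the exact
    forward Beer-Lambert image used by the deconvolution round-trip tests.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    shape = (h, w)

    n_overlap = int(round(spec.overlap_fraction * spec.n_nuclei))
    n_trunc = int(round(spec.truncated_fraction * spec.n_nuclei))
    n_singular = spec.n_nuclei - n_overlap - n_trunc
    kinds = ["singular"] * n_singular + ["overlap"] * n_overlap + ["truncated"] * n_trunc

    nucleus_density = np.zeros(shape)
    masks: list[np.ndarray] = []
    params: list[tuple[tuple[float, float], tuple[float, float], float]] = []
    flags: list[bool] = []
    occupied = np.zeros(shape, dtype=bool)

    for kind in kinds:
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            r_minor = rng.uniform(*spec.nucleus_radius_range_px)
            ratio = rng.uniform(*spec.ellipticity_range)
            r_major = min(r_minor * ratio, spec.nucleus_radius_range_px[1] * 1.2)
            theta = rng.uniform(0, np.pi)
            r_max = max(r_major, r_minor)
            if kind == "truncated":
                # centre close to (or beyond) a border so the mask is cut
                side = rng.integers(4)
                off = rng.uniform(-0.3 * r_max, 0.6 * r_max)
                if side == 0:
                    center = (off, rng.uniform(r_max, w - r_max))
                elif side == 1:
                    center = (h - 1 - off, rng.uniform(r_max, w - r_max))
                elif side == 2:
                    center = (rng.uniform(r_max, h - r_max), off)
                else:
                    center = (rng.uniform(r_max, h - r_max), w - 1 - off)
                center = (float(center[0]), float(center[1]))
            else:
                margin = r_max + 2
                if margin * 2 >= min(h, w):
                    raise PlacementError("nucleus radius too large for the image")
                center = (
                    float(rng.uniform(margin, h - 1 - margin)),
                    float(rng.uniform(margin, w - 1 - margin)),
                )
            dens = _ellipse_density(shape, center, (r_major, r_minor), theta)
            mask = dens >= 0.5
            if not mask.any():
                continue
            grown = ndi.binary_dilation(mask, iterations=2)
            touches = (grown & occupied).any()
            if kind == "overlap":
                if masks and not (mask & np.logical_or.reduce(masks)).any():
                    continue  # must genuinely overlap an existing nucleus
                ok = bool(masks)
            elif kind == "truncated":
                edge = np.zeros(shape, dtype=bool)
                edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
                ok = (mask & edge).any() and not touches
            else:
                ok = not touches
            if ok:
                nucleus_density += dens
                masks.append(mask)
                params.append((center, (r_major, r_minor), theta))
                occupied |= mask
                flags.append(kind == "singular")
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a {kind} nucleus after {_MAX_PLACEMENT_TRIES} tries"
            )

    # recheck singularity against the final layout: deliberate overlaps may
    # have landed on a nucleus placed as singular
    all_other = [
        np.logical_or.reduce([m for j, m in enumerate(masks) if j != i])
        if len(masks) > 1
        else np.zeros(shape, dtype=bool)
        for i in range(len(masks))
    ]
    edge = np.zeros(shape, dtype=bool)
    if h and w:
        edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    flags = [
        flags[i] and not (masks[i] & all_other[i]).any() and not (masks[i] & edge).any()
        for i in range(len(masks))
    ]

    her2_mean, cep17_mean = spec.signals_per_nucleus
    her2_density = np.zeros(shape)
    cep17_density = np.zeros(shape)
    signal_points: list[tuple[float, float, str, int | None]] = []
    for i, ((cy, cx), (r_major, r_minor), theta) in enumerate(params):
        for kind_name, mean, target in (
            ("HER2", her2_mean, her2_density),
            ("CEP17", cep17_mean, cep17_density),
        ):
            for _ in range(int(rng.poisson(mean))):
                straddle = rng.uniform() < spec.signal_straddle_fraction
                # sample a point in the ellipse frame; interior points keep the
                # whole dot inside the rim, straddling points sit on the rim
                phi = rng.uniform(0, 2 * np.pi)
                if straddle:
                    rho = 1.0
                else:
                    shrink_a = max(r_major - spec.signal_radius_px - 1.5, 1.0)
                    shrink_b = max(r_minor - spec.signal_radius_px - 1.5, 1.0)
                    rho = np.sqrt(rng.uniform())
                u = (shrink_a if not straddle else r_major) * rho * np.cos(phi)
                v = (shrink_b if not straddle else r_minor) * rho * np.sin(phi)
                sy = cy + u * np.cos(theta) - v * np.sin(theta)
                sx = cx + u * np.sin(theta) + v * np.cos(theta)
                if not (0 <= sy < h and 0 <= sx < w):
                    continue
                target += _disk_density(shape, (sy, sx), spec.signal_radius_px)
                signal_points.append((float(sy), float(sx), kind_name, i))

    densities = np.stack(
        [nucleus_density + spec.background_density, cep17_density, her2_density],
        axis=-1,
    )
    od = build_od_matrix(spec.dye_basis)
    image = synthesize_rgb(densities, od, spec.dye_basis.io)
    gt = GroundTruth(instance_masks=masks, singular_flags=flags, signal_points=signal_points)
    return image, densities, gt


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Generate an 8-bit scene and its ground truth.

    Applies the spec's Gaussian blur and additive noise on top of the clean
    render, then quantises to uint8.  Deterministic in (spec, seed).
    """
    image, _, gt = render_scene(spec)
    image = degrade(
        image, spec.blur_sigma_px, spec.noise_sd, seed=spec.seed + 1_000_003, _quantize=False
    )
    return np.clip(np.rint(image), 0, 255).astype(np.uint8), gt


def degrade(
    image: np.ndarray,
    blur_sigma_px: float,
    noise_sd: float,
    seed: int,
    _quantize: bool | None = None,
) -> np.ndarray:
    """Gaussian blur followed by additive Gaussian noise, clipped to [0, 255].

    With ``blur_sigma_px == noise_sd == 0`` the image is returned unchanged.
    uint8 input gives uint8 output; float input stays float.
    """
    if blur_sigma_px < 0 or noise_sd < 0:
        raise ValueError("blur and noise levels must be nonnegative")
    img = np.asarray(image)
    as_uint8 = img.dtype == np.uint8 if _quantize is None else _quantize
    if blur_sigma_px == 0 and noise_sd == 0:
        return img.copy()
    out = img.astype(float)
    if blur_sigma_px > 0:
        sigmas = (blur_sigma_px, blur_sigma_px) + (0,) * (out.ndim - 2)
        out = ndi.gaussian_filter(out, sigma=sigmas)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    out = np.clip(out, 0.0, 255.0)
    if as_uint8:
        out = np.rint(out).astype(np.uint8)
    return out


def make_label_map(
    gt: GroundTruth,
    shape: tuple[int, int],
    boundary_halfwidth_px: int = 2,
) -> np.ndarray:
    """3-class per-pixel label map: 0 background, 1 boundary, 2 inside.

    Only singular (untruncated, non-overlapping) nuclei are labelled as
    targets; all other pixels — including non-singular nuclei — are
    background.  Boundary pixels are those of a singular nucleus within
    ``boundary_halfwidth_px`` inside its contour.
    """
    from skimage.morphology import disk as _disk_footprint

    labels = np.zeros(shape, dtype=np.uint8)
    footprint = _disk_footprint(boundary_halfwidth_px)
    for mask, singular in zip(gt.instance_masks, gt.singular_flags):
        if not singular:
            continue
        # Euclidean-disk erosion matches the disk dilation used when
        # converting predicted class maps back to instances
        interior = ndi.binary_erosion(mask, structure=footprint)
        labels[mask & ~interior] = 1
        labels[interior] = 2
    return labels


def save_scene(directory, stem: str, image: np.ndarray, gt: GroundTruth) -> None:
    """Write image + ground truth: PNG/TIFF image, 16-bit label TIFF, JSON sidecar."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{stem}.png", image)
    tifffile.imwrite(
        directory / f"{stem}_instances.tiff",
        gt.instance_label_image(image.shape[:2]),
    )
    sidecar = {
        "singular_flags": [bool(f) for f in gt.singular_flags],
        "signal_points": [
            {"row": r, "col": c, "kind": k, "parent_nucleus_id": p}
            for r, c, k, p in gt.signal_points
        ],
    }
    with open(directory / f"{stem}_gt.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_ground_truth(directory, stem: str) -> GroundTruth:
    """Inverse of :func:`save_scene` for the ground-truth part."""
    from pathlib import Path

    directory = Path(directory)
    label_img = tifffile.imread(directory / f"{stem}_instances.tiff")
    with open(directory / f"{stem}_gt.json") as fh:
        sidecar = json.load(fh)
    n = int(label_img.max())
    masks = [label_img == i + 1 for i in range(n)]
    points = [
        (d["row"], d["col"], d["kind"], d["parent_nucleus_id"])
        for d in sidecar["signal_points"]
    ]
    return GroundTruth(
        instance_masks=masks,
        singular_flags=[bool(f) for f in sidecar["singular_flags"]],
        signal_points=points,
    )
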
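"""Reference-based color correction and Beer-Lambert stain deconvolution.

A CISH tile mixes three absorbing dyes — blue nuclear counterstain, magenta
CEP17 probe, black HER2 probe — over a bright glass background.  Two linear
models drive this module:

* **Color correction** treats each RGB pixel as a weighted sum of the three
  per-dye primary color vectors.  Solving for the weights against the input
  image's own primaries and re-projecting onto a reference basis maps the
  image into the reference staining condition.

* **Color deconvolution** works in optical-density space, ``g_k =
  log(Io_k / I_k)`` with ``Io`` the mean glass intensity.  Beer-Lambert
  absorption is linear in dye concentration, so the per-pixel density triplet
  ``a`` satisfies ``g = M a`` with ``M`` the 3x3 matrix of per-dye optical
  densities; inverting ``M`` separates the nuclei, CEP17 and HER2 channels.

The natural logarithm is used throughout; any fixed base rescales densities
uniformly and cancels in the forward/inverse round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "DyeBasis",
    "OdMatrix",
    "DyeChannels",
    "DEFAULT_BASIS",
    "DEFAULT_DENSITY_CEILING",
    "estimate_basis",
    "color_correct",
    "build_od_matrix",
    "deconvolve",
    "synthesize_rgb",
    "nuclei_channel_image",
]

#: Fixed density ceiling used to normalise the nuclei channel for the U-net.
#: A shared constant (not a per-image max) keeps tiles of one specimen on a
#: common scale; ~2.5 covers a nucleus overlapped by a second nucleus plus a
#: dot at the default basis without saturating singular nuclei.
DEFAULT_DENSITY_CEILING = 2.5

_MAX_CONDITION = 1e6


@dataclass(frozen=True)
class DyeBasis:
    """Per-dye mean RGB primaries and mean glass intensity.

    Each primary is the average RGB over areas stained by that dye only;
    ``io`` is the average intensity of glass (background) pixels.
    """

    p_nuclei: tuple[float, float, float]
    p_cep17: tuple[float, float, float]
    p_her2: tuple[float, float, float]
    io: tuple[float, float, float] = (245.0, 245.0, 245.0)

    def __post_init__(self) -> None:
        mat = self.primary_matrix()
        if np.any(mat <= 0) or np.any(mat > 255) or np.any(np.asarray(self.io) <= 0):
            raise ValueError("basis components must lie in (0, 255]")
        if np.linalg.cond(mat) > _MAX_CONDITION:
            raise ValueError("primary matrix is singular or ill-conditioned")

    def primary_matrix(self) -> np.ndarray:
        """3x3 matrix with the primaries as columns (order nuclei, CEP17, HER2)."""
        return np.stack([self.p_nuclei, self.p_cep17, self.p_her2], axis=1).astype(float)

    def to_yaml(self, path) -> None:
        data = {
            "p_nuclei": list(map(float, self.p_nuclei)),
            "p_cep17": list(map(float, self.p_cep17)),
            "p_her2": list(map(float, self.p_her2)),
            "io": list(map(float, self.io)),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "DyeBasis":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            p_nuclei=tuple(data["p_nuclei"]),
            p_cep17=tuple(data["p_cep17"]),
            p_her2=tuple(data["p_her2"]),
            io=tuple(data["io"]),
        )


#: Packaged reference basis approximating typical CISH colors: blue nuclei,
#: magenta CEP17 dots, near-black HER2 dots on bright glass.
DEFAULT_BASIS = DyeBasis(
    p_nuclei=(70.0, 80.0, 160.0),
    p_cep17=(180.0, 60.0, 140.0),
    p_her2=(40.0, 40.0, 40.0),
    io=(245.0, 245.0, 245.0),
)


@dataclass(frozen=True)
class OdMatrix:
    """3x3 optical-density mixing matrix, rows ordered (nuclei, CEP17, HER2).

    Entry ``m[d, k]`` is the optical density of dye ``d`` in channel ``k``:
    ``log(io_k / mean_k(dye d))``.
    """

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("OD matrix must be 3x3")
        if np.any(m < 0):
            raise ValueError("OD entries must be nonnegative (absorbing dyes)")
        object.__setattr__(self, "m", m)

    def is_singular(self) -> bool:
        # a dye identical to glass yields a zero row; such a matrix can be
        # built and inspected but not inverted
        return abs(np.linalg.det(self.m)) < 1e-12 or np.linalg.cond(self.m) > _MAX_CONDITION

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"m": self.m.tolist()}, fh)

    @classmethod
    def from_yaml(cls, path) -> "OdMatrix":
        with open(path) as fh:
            return cls(m=np.asarray(yaml.safe_load(fh)["m"], dtype=float))


@dataclass
class DyeChannels:
    """Stain-separated density images for the three dyes."""

    a_nuclei: np.ndarray
    a_cep17: np.ndarray
    a_her2: np.ndarray
    clip_fraction: float = 0.0

    def stack(self) -> np.ndarray:
        return np.stack([self.a_nuclei, self.a_cep17, self.a_her2], axis=-1)


def _channel_means(image: np.ndarray, mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"empty mask for {name}")
    return image[mask].reshape(-1, 3).mean(axis=0)


def estimate_basis(
    image: np.ndarray,
    nuclei_mask: np.ndarray,
    cep17_mask: np.ndarray,
    her2_mask: np.ndarray,
    glass_mask: np.ndarray | None = None,
    white_level: float = 200.0,
) -> DyeBasis:
    """Estimate the dye basis of an image from dye-only region masks.

    Each primary is the per-channel mean over its mask.  When ``glass_mask``
    is omitted, glass pixels are taken as those whose grayscale value is at
    least ``white_level``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    if glass_mask is None:
        from cishquant.quality import to_grayscale

        glass_mask = to_grayscale(img) >= white_level
    return DyeBasis(
        p_nuclei=tuple(_channel_means(img, nuclei_mask, "nuclei")),
        p_cep17=tuple(_channel_means(img, cep17_mask, "cep17")),
        p_her2=tuple(_channel_means(img, her2_mask, "her2")),
        io=tuple(_channel_means(img, glass_mask, "glass")),
    )


def color_correct(
    image: np.ndarray, input_basis: DyeBasis, reference_basis: DyeBasis
) -> np.ndarray:
    """Map an image from its own staining condition onto a reference one.

    Per pixel, weights ``W`` solve ``P_input W = [R, G, B]``; the corrected
    pixel is ``P_reference W``, clipped to [0, 255].  Output dtype matches the
    input: uint8 input is rounded back to uint8, float input stays float.
    """
    img = np.asarray(image)
    as_uint8 = img.dtype == np.uint8
    flat = img.reshape(-1, 3).astype(float)
    transfer = reference_basis.primary_matrix() @ np.linalg.inv(input_basis.primary_matrix())
    out = flat @ transfer.T
    out = np.clip(out, 0.0, 255.0).reshape(img.shape)
    if as_uint8:
        out = np.rint(out).astype(np.uint8)
    return out


def build_od_matrix(basis: DyeBasis) -> OdMatrix:
    """Optical-density matrix from a dye basis: ``m[d,k] = ln(io_k / P_d[k])``."""
    primaries = basis.primary_matrix().T  # rows = dyes
    io = np.asarray(basis.io, dtype=float)
    bad = primaries > io[None, :]
    if bad.any():
        rows, cols = np.nonzero(bad)
        names = [f"{['nuclei','cep17','her2'][r]}/{'RGB'[c]}" for r, c in zip(rows, cols)]
        raise ValueError(f"dye brighter than glass in: {', '.join(names)}")
    return OdMatrix(m=np.log(io[None, :] / primaries))


def deconvolve(
    image: np.ndarray,
    od: OdMatrix,
    io: tuple[float, float, float] | np.ndarray,
    intensity_floor: float = 1.0,
) -> DyeChannels:
    """Separate an RGB image into per-dye density images.

    Camera response ``g_k = ln(io_k / max(I_k, floor))`` per channel; the
    density triplet solves ``g = M^T a`` (row-vector form ``a = g M^{-1}``).
    Negative densities — out-of-gamut pixels the three-dye model cannot
    explain — are clipped to zero and the clipped fraction recorded.
    """
    io = np.asarray(io, dtype=float)
    if np.any(io <= 0):
        raise ValueError("glass intensity must be positive")
    if od.is_singular():
        raise ValueError("OD matrix is singular; cannot deconvolve")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    g = np.log(io[None, None, :] / np.maximum(img, intensity_floor))
    a = g.reshape(-1, 3) @ np.linalg.inv(od.m)
    clip_fraction = float(np.mean(np.any(a < -1e-9, axis=1)))
    a = np.maximum(a, 0.0).reshape(img.shape)
    return DyeChannels(
        a_nuclei=a[..., 0], a_cep17=a[..., 1], a_her2=a[..., 2], clip_fraction=clip_fraction
    )


def synthesize_rgb(
    densities: np.ndarray,
    od: OdMatrix,
    io: tuple[float, float, float] | np.ndarray,
) -> np.ndarray:
    """Forward Beer-Lambert rendering: ``I_k = io_k * exp(-(M^T a)_k)``.

    ``densities`` is HxWx3 (nuclei, CEP17, HER2).  The float output is the
    exact inverse image of :func:`deconvolve` on clean scenes; the synthetic
    generator quantises it to 8 bits for realistic tiles.
    """
    io = np.asarray(io, dtype=float)
    dens = np.asarray(densities, dtype=float)
    g = dens.reshape(-1, 3) @ od.m
    return (io[None, None, :] * np.exp(-g.reshape(dens.shape)))


def nuclei_channel_image(
    channels: DyeChannels, ceiling: float = DEFAULT_DENSITY_CEILING
) -> np.ndarray:
    """Nuclei-dye density rescaled to [0, 1] by a fixed ceiling.

    The ceiling is a configuration constant shared across tiles, never a
    per-image maximum — equal densities in two tiles must map to equal values
    so that a model trained on one tile transfers to another.
    """
    if ceiling <= 0:
        raise ValueError("density ceiling must be positive")
    return np.clip(channels.a_nuclei / ceiling, 0.0, 1.0).astype(np.float32)
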
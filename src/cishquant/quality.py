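"""Referenceless image-quality gate for bright-field tiles.

Two checks precede any analysis.  The *white check* rejects tiles that are
mostly glass: the fraction of grayscale pixels at or above a white level
(default 200) must stay below a threshold ``Wth`` (default 0.5), otherwise
the tile holds too little tissue.  The *quality check* scores degradation as
a linear index

    Q = alpha + beta * blurriness + gamma * noise

whose coefficients are fitted by ordinary least squares against the mean
squared error between pristine tiles and digitally degraded copies — a
referenceless proxy trained once, then applied without any reference image.

*Blurriness* is the mean width of intensity edges: an edge pixel is one whose
1-D gradient magnitude (along rows or columns) exceeds a threshold, and its
width is the distance between the local minimum and local maximum flanking it
on the scan line.  Blur stretches edges, so mean width grows.

*Noise* averages the squared minimum center-to-neighbour difference over
candidate pixels flagged by an unsharp mask (image minus 3x3 mean).  An
isolated noisy pixel differs from all eight neighbours, so its minimum
difference is large; a true edge pixel has at least one similar neighbour
along the edge, so it contributes little.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "QualityModel",
    "QualityReport",
    "NoEdgeWarning",
    "to_grayscale",
    "white_fraction",
    "blurriness",
    "noise_index",
    "fit_quality_model",
    "assess",
]

_GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


class NoEdgeWarning(UserWarning):
    """Emitted when an image has no edge above the gradient threshold."""


@dataclass
class QualityModel:
    """Fitted linear quality-degradation model and the gate thresholds."""

    alpha: float
    beta: float
    gamma: float
    edge_gradient_threshold: float = 20.0
    white_level: float = 200.0
    wth: float = 0.5
    qth: float = float("inf")
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.wth <= 1):
            raise ValueError("Wth must lie in (0, 1]")
        if not (0 < self.white_level <= 255):
            raise ValueError("white_level must lie in (0, 255]")

    def q_index(self, blur: float, noise: float) -> float:
        return self.alpha + self.beta * blur + self.gamma * noise

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path) -> "QualityModel":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class QualityReport:
    """Per-tile quality measurements and the two gate decisions."""

    white_fraction: float
    blurriness: float
    noise: float
    q_index: float
    tissue_ok: bool
    quality_ok: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma conversion 0.299 R + 0.587 G + 0.114 B (real-valued output)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    return img @ _GRAY_WEIGHTS


def white_fraction(gray: np.ndarray, white_level: float = 200.0) -> float:
    """Fraction of pixels at or above the white level."""
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty image")
    return float(np.mean(gray >= white_level))


def _profile_edge_widths(profile: np.ndarray, threshold: float) -> list[int]:
    """Edge widths along one 1-D scan line.

    An edge sits between samples i and i+1 where |p[i+1] - p[i]| > threshold;
    its width is the distance between the local extrema flanking it (the run
    of strictly monotone samples through the edge).
    """
    widths: list[int] = []
    grad = np.diff(profile)
    for i in np.nonzero(np.abs(grad) > threshold)[0]:
        sign = 1.0 if grad[i] > 0 else -1.0
        left = i
        while left > 0 and sign * (profile[left] - profile[left - 1]) > 0:
            left -= 1
        right = i + 1
        while right < len(profile) - 1 and sign * (profile[right + 1] - profile[right]) > 0:
            right += 1
        widths.append(right - left)
    return widths


def blurriness(gray: np.ndarray, edge_gradient_threshold: float = 20.0) -> float:
    """Mean edge width over all edges found on horizontal and vertical scans.

    Raises a :class:`NoEdgeWarning` and returns 0 when no gradient exceeds
    the threshold (a featureless tile is the white check's job, not ours).
    """
    gray = np.asarray(gray, dtype=float)
    widths: list[int] = []
    for row in gray:
        widths.extend(_profile_edge_widths(row, edge_gradient_threshold))
    for col in gray.T:
        widths.extend(_profile_edge_widths(col, edge_gradient_threshold))
    if not widths:
        warnings.warn("no edge above the gradient threshold", NoEdgeWarning)
        return 0.0
    return float(np.mean(widths))


def noise_index(gray: np.ndarray, edge_gradient_threshold: float = 10.0) -> float:
    """Mean squared minimum center-to-neighbour difference over noise candidates.

    Candidates are pixels whose unsharp-mask (high-pass) response exceeds one
    standard deviation of that response in magnitude; such pixels are either
    noise or structural edges.  Edge pixels are then removed: a pixel on or
    next to an edge of the mean-filtered image (gradient magnitude above the
    threshold after 3x3 smoothing, which suppresses the noise itself) does
    not count as noise.  The squared minimum absolute difference between each
    remaining candidate and its 8 neighbours is averaged.  Border pixels are
    never candidates (no full 3x3 neighbourhood); an image with no candidates
    scores 0.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    smoothed = ndi.uniform_filter(gray, size=3, mode="nearest")
    highpass = gray - smoothed
    cutoff = highpass.std()
    gy, gx = np.gradient(smoothed)
    edges = np.hypot(gy, gx) > edge_gradient_threshold
    candidates = (np.abs(highpass) > cutoff) & ~edges
    candidates[0, :] = candidates[-1, :] = candidates[:, 0] = candidates[:, -1] = False
    if not candidates.any() or cutoff == 0:
        return 0.0
    center = gray[1:-1, 1:-1]
    dmin = np.full(center.shape, np.inf)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            neighbor = gray[1 + dy : gray.shape[0] - 1 + dy, 1 + dx : gray.shape[1] - 1 + dx]
            dmin = np.minimum(dmin, np.abs(center - neighbor))
    return float(np.mean(dmin[candidates[1:-1, 1:-1]] ** 2))


def fit_quality_model(
    originals: list[np.ndarray],
    degradations: list[tuple[float, float]],
    seed: int = 0,
    edge_gradient_threshold: float = 20.0,
    white_level: float = 200.0,
    wth: float = 0.5,
    qth_percentile: float = 95.0,
    responses: list[float] | None = None,
) -> QualityModel:
    """Fit ``Q = alpha + beta*blurriness + gamma*noise`` by OLS.

    Every original grayscale image is degraded at every ``(blur_sigma,
    noise_sd)`` grid point; the regression response is the MSE between the
    original and its degraded copy, and the predictors are the blurriness and
    noise indices of the degraded copy.  ``responses`` substitutes an
    externally constructed response vector (one per original x degradation,
    in that order) for calibration tests.

    ``Qth`` defaults to the ``qth_percentile`` of Q over the pristine
    originals, so clean tiles pass the gate by construction.
    """
    from cishquant.synthetic import degrade

    if len(degradations) < 2:
        raise ValueError("need at least 2 degradation levels")
    rows, mses = [], []
    for j, gray in enumerate(originals):
        gray = np.asarray(gray, dtype=float)
        for k, (blur_sigma, noise_sd) in enumerate(degradations):
            degraded = degrade(gray, blur_sigma, noise_sd, seed=seed + 7919 * j + k)
            rows.append(
                [
                    1.0,
                    blurriness(degraded, edge_gradient_threshold),
                    noise_index(degraded, edge_gradient_threshold),
                ]
            )
            mses.append(float(np.mean((degraded - gray) ** 2)))
    design = np.asarray(rows)
    y = np.asarray(responses if responses is not None else mses, dtype=float)
    if y.shape[0] != design.shape[0]:
        raise ValueError("response length does not match originals x degradations")
    if np.linalg.matrix_rank(design) < 3 and not np.allclose(y, 0.0):
        # a zero response (no degradation at all) is fit exactly by the zero
        # model even when predictors are collinear
        stds = design[:, 1:].std(axis=0)
        name = ["blurriness", "noise"][int(np.argmin(stds))]
        raise ValueError(f"rank-deficient design: predictor '{name}' is collinear/constant")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    model = QualityModel(
        alpha=float(coef[0]),
        beta=float(coef[1]),
        gamma=float(coef[2]),
        edge_gradient_threshold=edge_gradient_threshold,
        white_level=white_level,
        wth=wth,
        r_squared=r2,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NoEdgeWarning)
        clean_q = [
            model.q_index(
                blurriness(np.asarray(g, dtype=float), edge_gradient_threshold),
                noise_index(np.asarray(g, dtype=float), edge_gradient_threshold),
            )
            for g in originals
        ]
    model.qth = float(np.percentile(clean_q, qth_percentile))
    return model


def assess(image: np.ndarray, model: QualityModel) -> QualityReport:
    """White check, then (only if tissue is sufficient) the quality check."""
    gray = to_grayscale(image)
    wf = white_fraction(gray, model.white_level)
    tissue_ok = wf < model.wth
    if not tissue_ok:
        return QualityReport(
            white_fraction=wf,
            blurriness=float("nan"),
            noise=float("nan"),
            q_index=float("nan"),
            tissue_ok=False,
            quality_ok=False,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NoEdgeWarning)
        blur = blurriness(gray, model.edge_gradient_threshold)
    noise = noise_index(gray, model.edge_gradient_threshold)
    q = model.q_index(blur, noise)
    return QualityReport(
        white_fraction=wf,
        blurriness=blur,
        noise=noise,
        q_index=q,
        tissue_ok=True,
        quality_ok=q <= model.qth,
    )
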
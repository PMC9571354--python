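"""End-to-end orchestration of the singular-nuclei segmentation pipeline.

Stage order for a CISH tile: white check -> quality check -> color
correction to the reference basis -> color deconvolution -> U-net
segmentation on the nuclei-dye channel -> morphological postprocessing and
suitability filtering -> (optional) signal assignment and HER2 grading.
A tile rejected by either gate yields a structured rejection record — batch
processing over many tiles must not abort on a poor one — and no later
stage runs.

FISH mode replaces color correction and deconvolution with an inverted
grayscale intensity image (fluorescence is bright-on-dark where CISH is
dark-on-bright); segmentation and everything after it are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from cishquant import color as color_mod
from cishquant import grading as grading_mod
from cishquant import postprocess as post_mod
from cishquant import quality as quality_mod
from cishquant import segmentation as seg_mod

__all__ = ["PipelineConfig", "PipelineResult", "run", "run_image", "batch"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, resolvable up front."""

    quality_model_path: str | None = None
    reference_basis_path: str | None = None
    model_checkpoint_path: str | None = None
    input_basis_path: str | None = None
    mode: str = "CISH"
    wth: float | None = None
    qth: float | None = None
    density_ceiling: float = color_mod.DEFAULT_DENSITY_CEILING
    opening_radius_px: int = 1
    dilation_radius_px: int = 2
    circularity_min: float = post_mod.CIRCULARITY_MIN
    area_min: int = post_mod.AREA_MIN
    area_max: int = post_mod.AREA_MAX
    min_nuclei: int = 20
    signal_min_density: float = 0.3
    signal_min_radius_px: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("CISH", "FISH"):
            raise ValueError("mode must be CISH or FISH")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class PipelineResult:
    """Per-image outcome: either a rejection record or the full bundle."""

    image_path: str | None = None
    rejected: bool = False
    rejection_reason: str | None = None
    quality: quality_mod.QualityReport | None = None
    candidates: list[post_mod.NucleusCandidate] = field(default_factory=list)
    accepted: list[post_mod.NucleusCandidate] = field(default_factory=list)
    counts: list[grading_mod.NucleusCounts] = field(default_factory=list)
    grade: grading_mod.Her2Grade | None = None
    grade_error: str | None = None
    error: str | None = None

    def to_row(self) -> dict:
        return {
            "image": self.image_path,
            "rejected": self.rejected,
            "rejection_reason": self.rejection_reason,
            "error": self.error,
            "n_candidates": len(self.candidates),
            "n_accepted": len(self.accepted),
            "ratio": self.grade.ratio if self.grade else None,
            "avg_her2": self.grade.avg_her2 if self.grade else None,
            "group": self.grade.group if self.grade else None,
            "status": self.grade.status if self.grade else None,
        }


def _load_artifacts(config: PipelineConfig):
    qmodel = (
        quality_mod.QualityModel.load(config.quality_model_path)
        if config.quality_model_path
        else None
    )
    if qmodel is not None:
        if config.wth is not None:
            qmodel.wth = config.wth
        if config.qth is not None:
            qmodel.qth = config.qth
    reference = (
        color_mod.DyeBasis.from_yaml(config.reference_basis_path)
        if config.reference_basis_path
        else color_mod.DEFAULT_BASIS
    )
    input_basis = (
        color_mod.DyeBasis.from_yaml(config.input_basis_path)
        if config.input_basis_path
        else None
    )
    model, extra = None, {}
    if config.model_checkpoint_path:
        model, extra = seg_mod.load_checkpoint(config.model_checkpoint_path)
    return qmodel, reference, input_basis, model, extra


def run_image(
    image: np.ndarray,
    config: PipelineConfig,
    *,
    quality_model: quality_mod.QualityModel | None = None,
    reference_basis: color_mod.DyeBasis | None = None,
    input_basis: color_mod.DyeBasis | None = None,
    model: seg_mod.UNet | None = None,
    signals: grading_mod.SignalSet | None = None,
    image_path: str | None = None,
) -> PipelineResult:
    """Run all stages on an in-memory image; artifacts passed explicitly."""
    result = PipelineResult(image_path=image_path)

    if quality_model is not None:
        report = quality_mod.assess(image, quality_model)
        result.quality = report
        if not report.tissue_ok:
            result.rejected = True
            result.rejection_reason = "insufficient tissue"
            return result
        if not report.quality_ok:
            result.rejected = True
            result.rejection_reason = "poor quality"
            return result

    reference = reference_basis or color_mod.DEFAULT_BASIS
    if config.mode == "FISH":
        gray = quality_mod.to_grayscale(image)
        net_input = 1.0 - gray / 255.0  # bright fluorescent nuclei -> high values
        channels = None
    else:
        corrected = (
            color_mod.color_correct(image, input_basis, reference)
            if input_basis is not None
            else image
        )
        od = color_mod.build_od_matrix(reference)
        channels = color_mod.deconvolve(corrected, od, reference.io)
        net_input = color_mod.nuclei_channel_image(channels, config.density_ceiling)

    if model is None:
        result.error = "no segmentation model supplied"
        return result
    classmap = seg_mod.predict(model, net_input.astype(np.float32))
    masks = seg_mod.classmap_to_instances(classmap, config.dilation_radius_px)
    masks = [post_mod.opening(m, config.opening_radius_px) for m in masks]
    masks = [m for m in masks if m.any()]
    # opening can split a mask; keep the largest component of each
    from scipy import ndimage as ndi

    cleaned = []
    for m in masks:
        labels, n = ndi.label(m, structure=ndi.generate_binary_structure(2, 2))
        if n <= 1:
            cleaned.append(m)
        else:
            sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            cleaned.append(labels == int(np.argmax(sizes)) + 1)
    result.candidates = post_mod.extract_candidates(cleaned)
    result.accepted = post_mod.filter_and_score(
        result.candidates, config.circularity_min, config.area_min, config.area_max
    )

    if signals is None and channels is not None:
        signals = grading_mod.detect_signals(
            channels, config.signal_min_density, config.signal_min_radius_px
        )
    if signals is not None and result.accepted:
        result.counts = grading_mod.assign_signals(result.accepted, signals)
        try:
            result.grade = grading_mod.grade(result.counts, config.min_nuclei)
        except (grading_mod.InsufficientNucleiError, grading_mod.UndefinedRatioError) as exc:
            result.grade_error = str(exc)
    return result


def run(image_path, config: PipelineConfig, signals: grading_mod.SignalSet | None = None) -> PipelineResult:
    """Load an image from disk and run the pipeline with configured artifacts."""
    import imageio.v3 as iio

    qmodel, reference, input_basis, model, _extra = _load_artifacts(config)
    image = iio.imread(image_path)
    if image.ndim == 3 and image.shape[2] == 4:
        image = image[..., :3]
    return run_image(
        image,
        config,
        quality_model=qmodel,
        reference_basis=reference,
        input_basis=input_basis,
        model=model,
        signals=signals,
        image_path=str(image_path),
    )


def batch(image_paths, config: PipelineConfig) -> "pandas.DataFrame":
    """Run many tiles; per-image failures become rows, never aborts.

    Results are ordered by filename.  The frame has a stable header even
    when the input list is empty.
    """
    import pandas as pd

    qmodel, reference, input_basis, model, _extra = _load_artifacts(config)
    rows = []
    for path in sorted(map(str, image_paths)):
        try:
            import imageio.v3 as iio

            image = iio.imread(path)
            if image.ndim == 3 and image.shape[2] == 4:
                image = image[..., :3]
            result = run_image(
                image,
                config,
                quality_model=qmodel,
                reference_basis=reference,
                input_basis=input_basis,
                model=model,
                image_path=path,
            )
        except Exception as exc:  # noqa: BLE001 - error isolation per tile
            result = PipelineResult(image_path=path, error=f"{type(exc).__name__}: {exc}")
        rows.append(result.to_row())
    columns = [
        "image",
        "rejected",
        "rejection_reason",
        "error",
        "n_candidates",
        "n_accepted",
        "ratio",
        "avg_her2",
        "group",
        "status",
    ]
    return pd.DataFrame(rows, columns=columns)
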
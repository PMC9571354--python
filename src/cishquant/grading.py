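"""Per-nucleus HER2/CEP17 signal counting and ASCO/CAP grading.

A signal is counted for a nucleus only if its whole disk lies inside the
nucleus mask (interior or boundary band); a signal that partially overlaps
the mask edge is excluded from the count, since its parent nucleus is
ambiguous.  Grading follows the five-group ASCO/CAP scheme over the
HER2-to-CEP17 ratio (total HER2 / total CEP17 across the quantified nuclei)
and the average HER2 copy number (total HER2 / number of nuclei):

    ratio >= 2, avg >= 4        -> Group 1, Positive
    ratio >= 2, avg <  4        -> Group 2, Positive
    ratio <  2, avg >= 6        -> Group 3, Positive
    ratio <  2, 4 <= avg < 6    -> Group 4, Equivocal
    ratio <  2, avg <  4        -> Group 5, Negative

At least 20 nuclei must be quantified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi

from cishquant.color import DyeChannels
from cishquant.postprocess import NucleusCandidate

__all__ = [
    "SignalSet",
    "NucleusCounts",
    "Her2Grade",
    "InsufficientNucleiError",
    "UndefinedRatioError",
    "assign_signals",
    "grade",
    "detect_signals",
]

SIGNAL_KINDS = ("HER2", "CEP17")


class InsufficientNucleiError(ValueError):
    """Fewer quantified nuclei than the clinical minimum."""


class UndefinedRatioError(ZeroDivisionError):
    """Total CEP17 count is zero; the HER2/CEP17 ratio is undefined."""


@dataclass
class SignalSet:
    """Detected or ground-truth dot signals: (row, col, radius_px, kind)."""

    points: list[tuple[float, float, float, str]]

    def __post_init__(self) -> None:
        for r, c, radius, kind in self.points:
            if radius < 1:
                raise ValueError("signal radius must be >= 1 px")
            if kind not in SIGNAL_KINDS:
                raise ValueError(f"unknown signal kind {kind!r}")

    def of_kind(self, kind: str) -> list[tuple[float, float, float, str]]:
        return [p for p in self.points if p[3] == kind]

    @classmethod
    def from_csv(cls, path) -> "SignalSet":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            points=[
                (float(r.row), float(r.col), float(r.radius), str(r.kind))
                for r in df.itertuples()
            ]
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.points, columns=["row", "col", "radius", "kind"]).to_csv(
            path, index=False
        )


@dataclass
class NucleusCounts:
    nucleus_id: int
    her2_count: int = 0
    cep17_count: int = 0


@dataclass
class Her2Grade:
    """Cohort-level HER2 grade over the quantified nuclei."""

    n_nuclei: int
    ratio: float
    avg_her2: float
    group: int
    status: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def summary(self) -> str:
        return (
            f"{self.n_nuclei} nuclei quantified; HER2/CEP17 ratio = {self.ratio:.2f}; "
            f"average HER2 copy = {self.avg_her2:.2f} -> Group {self.group} ({self.status})"
        )


def _disk_pixels(
    row: float, col: float, radius: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Pixel coordinates of a signal disk; flag marks disks leaving the frame."""
    r0, r1 = int(np.floor(row - radius)), int(np.ceil(row + radius))
    c0, c1 = int(np.floor(col - radius)), int(np.ceil(col + radius))
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    rr, cc = rr[inside], cc[inside]
    in_frame = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    return rr[in_frame], cc[in_frame], bool(np.all(in_frame))


def assign_signals(
    nuclei: list[NucleusCandidate], signals: SignalSet
) -> list[NucleusCounts]:
    """Count each fully contained signal disk for its nucleus.

    A disk any pixel of which falls outside the nucleus mask (or outside the
    frame) is excluded.  If accepted masks overlap — possible after the
    post-segmentation dilation — a contained signal goes to the
    highest-scoring containing nucleus only, so nothing is double-counted.
    """
    counts = {
        (c.nucleus_id if c.nucleus_id is not None else i): NucleusCounts(
            nucleus_id=c.nucleus_id if c.nucleus_id is not None else i
        )
        for i, c in enumerate(nuclei)
    }
    ranked = sorted(
        enumerate(nuclei), key=lambda t: (-t[1].score, t[1].centroid[0], t[1].centroid[1])
    )
    for row, col, radius, kind in signals.points:
        for i, cand in ranked:
            shape = cand.mask.shape
            rr, cc, fully_in_frame = _disk_pixels(row, col, radius, shape)
            if not fully_in_frame or rr.size == 0:
                continue
            if np.all(cand.mask[rr, cc]):
                key = cand.nucleus_id if cand.nucleus_id is not None else i
                if kind == "HER2":
                    counts[key].her2_count += 1
                else:
                    counts[key].cep17_count += 1
                break
    result = [counts[c.nucleus_id if c.nucleus_id is not None else i] for i, c in enumerate(nuclei)]
    for cand, cnt in zip(nuclei, result):
        cand.her2_count = cnt.her2_count
        cand.cep17_count = cnt.cep17_count
    return result


def grade(counts: list[NucleusCounts], min_nuclei: int = 20) -> Her2Grade:
    """ASCO/CAP group and status from per-nucleus HER2/CEP17 counts."""
    if len(counts) < min_nuclei:
        raise InsufficientNucleiError(
            f"need at least {min_nuclei} quantified nuclei, got {len(counts)}"
        )
    total_her2 = sum(c.her2_count for c in counts)
    total_cep17 = sum(c.cep17_count for c in counts)
    if total_cep17 == 0:
        raise UndefinedRatioError("total CEP17 count is zero; ratio undefined")
    ratio = total_her2 / total_cep17
    avg = total_her2 / len(counts)
    if ratio >= 2 and avg >= 4:
        group, status = 1, "Positive"
    elif ratio >= 2:
        group, status = 2, "Positive"
    elif avg >= 6:
        group, status = 3, "Positive"
    elif avg >= 4:
        group, status = 4, "Equivocal"
    else:
        group, status = 5, "Negative"
    return Her2Grade(
        n_nuclei=len(counts), ratio=ratio, avg_her2=avg, group=group, status=status
    )


def detect_signals(
    channels: DyeChannels,
    min_density: float = 0.3,
    min_radius_px: float = 1.0,
    dot_radius_px: float = 2.0,
) -> SignalSet:
    """Blob detection on the CEP17 and HER2 density channels independently.

    Each channel is thresholded at ``min_density`` and 8-connected components
    at least as large as a disk of ``min_radius_px`` are kept.  Because dot
    densities are additive, a component's integrated density conserves the
    number of dots it contains even when dots overlap and merge: the count is
    the component mass divided by the mass of one dot of ``dot_radius_px``,
    rounded.  Multi-dot components emit that many points at the component
    centroid with the equivalent single-dot radius.
    """
    points: list[tuple[float, float, float, str]] = []
    min_area = np.pi * min_radius_px**2
    struct = ndi.generate_binary_structure(2, 2)
    unit_mass = _single_dot_mass(dot_radius_px, min_density)
    for kind, channel in (("CEP17", channels.a_cep17), ("HER2", channels.a_her2)):
        channel = np.asarray(channel)
        above = channel > min_density
        labels, n = ndi.label(above, structure=struct)
        if n == 0:
            continue
        idx = np.arange(1, n + 1)
        areas = ndi.sum_labels(np.ones_like(channel), labels, index=idx)
        masses = ndi.sum_labels(channel, labels, index=idx)
        centroids = ndi.center_of_mass(channel, labels, index=idx)
        for area, mass, (cy, cx) in zip(areas, masses, centroids):
            if area < min_area:
                continue
            count = max(1, int(round(mass / unit_mass)))
            radius = float(np.sqrt(area / (np.pi * count)))
            points.extend([(float(cy), float(cx), max(radius, 1.0), kind)] * count)
    return SignalSet(points=points)


def _single_dot_mass(dot_radius_px: float, min_density: float) -> float:
    """Integrated density of one rendered dot, above the detection threshold."""
    from cishquant.synthetic import _disk_density

    size = int(np.ceil(dot_radius_px)) * 2 + 5
    proto = _disk_density((size, size), (size / 2, size / 2), dot_radius_px)
    return float(proto[proto > min_density].sum())
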
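"""Anchor-based piecewise-linear intensity normalization.

Each sample contributes three anchor intensities — background,
autofluorescence, and positive immunolabel — each averaged from 3 depths
× 10 manual readings. A continuous, monotone piecewise-linear map sends
the sample anchors onto reference anchors (by default the cohort mean),
putting all samples on one common intensity dataspace. Beyond the outer
anchors the nearest segment's slope is extended, so ordering among very
bright structures is preserved rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import ImageVolume

__all__ = [
    "AnchorMeasurements",
    "PiecewiseMap",
    "average_anchors",
    "fit_piecewise_map",
    "normalize_volume",
    "reference_from_cohort",
]

CATEGORIES = ("background", "autofluorescence", "positive")


@dataclass
class AnchorMeasurements:
    """Raw anchor readings: per category, an (n_depths, n_per_depth) array."""

    background: np.ndarray
    autofluorescence: np.ndarray
    positive: np.ndarray

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            arr = np.asarray(getattr(self, cat), dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"{cat} readings must be 2D (depths × readings)")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{cat} readings must be finite and nonnegative")
            setattr(self, cat, arr)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {cat: getattr(self, cat) for cat in CATEGORIES}

    @classmethod
    def from_dict(cls, readings: dict[str, np.ndarray]) -> "AnchorMeasurements":
        return cls(**{cat: readings[cat] for cat in CATEGORIES})


def average_anchors(measurements: AnchorMeasurements) -> tuple[float, float, float]:
    """Arithmetic mean per category → (m_bg, m_af, m_pos), strictly increasing."""
    means = tuple(float(np.mean(getattr(measurements, cat))) for cat in CATEGORIES)
    if not (means[0] < means[1] < means[2]):
        raise ValueError(
            f"anchor means must be strictly increasing (bg < af < pos), got {means}; "
            "check for mislabeled anchor categories"
        )
    return means


@dataclass
class PiecewiseMap:
    """Monotone piecewise-linear intensity transform fixed at three anchors.

    ``map(m_i) == r_i`` exactly for each anchor pair; between anchors the
    map is linear; below m_bg and above m_pos the adjacent segment's slope
    continues.
    """

    sample_anchors: tuple[float, float, float]
    reference_anchors: tuple[float, float, float]

    def __post_init__(self) -> None:
        s, r = self.sample_anchors, self.reference_anchors
        if not (s[0] < s[1] < s[2]):
            raise ValueError(f"sample anchors must be strictly increasing, got {s}")
        if not (r[0] < r[1] < r[2]):
            raise ValueError(f"reference anchors must be strictly increasing, got {r}")
        self.sample_anchors = tuple(float(v) for v in s)
        self.reference_anchors = tuple(float(v) for v in r)

    @property
    def slopes(self) -> tuple[float, float]:
        s, r = self.sample_anchors, self.reference_anchors
        return (
            (r[1] - r[0]) / (s[1] - s[0]),
            (r[2] - r[1]) / (s[2] - s[1]),
        )

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        s = np.asarray(self.sample_anchors)
        r = np.asarray(self.reference_anchors)
        lo, hi = self.slopes
        y = np.interp(x, s, r)
        y = np.where(x < s[0], r[0] + lo * (x - s[0]), y)
        y = np.where(x > s[2], r[2] + hi * (x - s[2]), y)
        return y if y.ndim else float(y)


def fit_piecewise_map(sample_anchors, reference_anchors) -> PiecewiseMap:
    """Build the anchor-to-anchor map (validates both triples)."""
    return PiecewiseMap(tuple(sample_anchors), tuple(reference_anchors))


def normalize_volume(volume: ImageVolume, pmap: PiecewiseMap) -> ImageVolume:
    """Apply the map voxelwise; monotone inputs give monotone outputs."""
    return ImageVolume(pmap(volume.data), volume.voxel_size, volume.channel)


def reference_from_cohort(anchor_triples) -> tuple[float, float, float]:
    """Reference anchors = per-category mean over all samples' anchor triples."""
    arr = np.asarray(list(anchor_triples), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or len(arr) == 0:
        raise ValueError("need a nonempty list of (bg, af, pos) triples")
    ref = tuple(float(v) for v in arr.mean(axis=0))
    if not (ref[0] < ref[1] < ref[2]):
        raise ValueError(f"cohort mean anchors are not increasing: {ref}")
    return ref
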
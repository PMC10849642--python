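"""Object segmentation, cross-channel colocalization and layer assignment.

Neurofibrillary tangles (tau channel) and neuron somata (HuD channel) are
segmented as connected components of a thresholded volume, size-filtered,
matched across channels by voxel overlap, and assigned a cortical layer
from a label volume. This threshold/connected-components stage is the
package's portable stand-in for interactively trained pixel/object
classifiers: downstream quantification depends only on the resulting
object tables, which can equally be ingested from external classifier
exports via :mod:`vesseltau.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volumes import ImageVolume, LayerVolume

__all__ = [
    "ObjectRecord",
    "ObjectSet",
    "segment_objects",
    "match_colocalized",
    "assign_layers",
]

log = logging.getLogger(__name__)

OBJECT_CLASSES = ("neuron", "tangle", "noise")


@dataclass
class ObjectRecord:
    """One segmented object (NFT tangle or neuron soma).

    ``layer`` 0 means unassigned. ``distance_um`` / ``arc_um`` /
    ``vessel_id`` are only defined once the object has been located
    within a vessel's 100-μm neighborhood. ``nft_positive`` applies to
    neurons only.
    """

    object_id: int
    object_class: str
    centroid_um: np.ndarray  # (z, y, x) μm
    voxel_count: int
    layer: int = 0
    vessel_id: int | None = None
    distance_um: float | None = None
    arc_um: float | None = None
    nft_positive: bool | None = None

    def __post_init__(self) -> None:
        if self.object_class not in OBJECT_CLASSES:
            raise ValueError(
                f"unknown object class {self.object_class!r}; expected one of {OBJECT_CLASSES}"
            )
        self.centroid_um = np.asarray(self.centroid_um, dtype=float)


@dataclass
class ObjectSet:
    """Segmented objects plus their label volume (needed for overlap tests)."""

    records: list[ObjectRecord]
    labels: np.ndarray  # int volume, 0 = background, i = records[i-1]
    voxel_size: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.records)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def segment_objects(
    volume: ImageVolume,
    threshold: float,
    min_size: int = 1,
    max_size: int | None = None,
    object_class: str = "tangle",
    connectivity: int = 26,
) -> ObjectSet:
    """Segment connected super-threshold components into objects.

    Components are 26-connected by default (6-connectivity available),
    filtered to ``min_size <= voxel_count <= max_size``, and returned with
    centroids in μm. Object ids are assigned 1..n in scan order of the
    surviving components, so the operation is deterministic.
    """
    if max_size is not None and min_size > max_size:
        raise ValueError(f"min_size ({min_size}) > max_size ({max_size})")
    binary = volume.data > threshold
    labels, n = ndi.label(binary, structure=_structure(connectivity))
    if n == 0:
        return ObjectSet([], labels, volume.voxel_size)
    counts = np.bincount(labels.ravel())[1:]  # per original label 1..n
    keep = counts >= min_size
    if max_size is not None:
        keep &= counts <= max_size
    # relabel surviving components 1..m in original label order
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[1:][keep] = np.arange(1, int(keep.sum()) + 1)
    labels = remap[labels]
    centroids_idx = ndi.center_of_mass(
        np.ones_like(labels, dtype=np.uint8), labels, index=np.arange(1, int(keep.sum()) + 1)
    )
    records = []
    kept_counts = counts[keep]
    vs = np.asarray(volume.voxel_size)
    for i, (cidx, cnt) in enumerate(zip(centroids_idx, kept_counts), start=1):
        centroid_um = (np.asarray(cidx) + 0.5) * vs
        records.append(
            ObjectRecord(
                object_id=i,
                object_class=object_class,
                centroid_um=centroid_um,
                voxel_count=int(cnt),
            )
        )
    return ObjectSet(records, labels, volume.voxel_size)


def match_colocalized(
    tangles: ObjectSet,
    neurons: ObjectSet,
    min_overlap_fraction: float = 0.5,
) -> ObjectSet:
    """Flag neurons that contain a colocalized tangle (NFT-positive).

    A neuron is flagged iff some tangle overlaps it by at least
    ``min_overlap_fraction`` of the *tangle's* volume. Each tangle is
    matched to at most one neuron — the one with the largest overlap,
    ties broken toward the lower neuron id. Returns ``neurons`` with
    ``nft_positive`` set on every record (False where unmatched).
    """
    if tangles.labels.shape != neurons.labels.shape:
        raise ValueError("tangle and neuron label volumes must share a grid")
    for rec in neurons.records:
        rec.nft_positive = False
    both = (tangles.labels > 0) & (neurons.labels > 0)
    if both.any():
        t = tangles.labels[both]
        u = neurons.labels[both]
        pairs, overlap = np.unique(np.stack([t, u], axis=1), axis=0, return_counts=True)
        tangle_sizes = {r.object_id: r.voxel_count for r in tangles.records}
        # best neuron per tangle: largest overlap, then lowest neuron id
        order = np.lexsort((pairs[:, 1], -overlap, pairs[:, 0]))
        seen: set[int] = set()
        neuron_by_id = {r.object_id: r for r in neurons.records}
        for k in order:
            tid, nid = int(pairs[k, 0]), int(pairs[k, 1])
            if tid in seen:
                continue
            seen.add(tid)
            if overlap[k] >= min_overlap_fraction * tangle_sizes[tid]:
                neuron_by_id[nid].nft_positive = True
    return neurons


def assign_layers(objects: list[ObjectRecord] | ObjectSet, layers: LayerVolume) -> list[ObjectRecord]:
    """Set each object's cortical layer from the label at its centroid voxel."""
    records = objects.records if isinstance(objects, ObjectSet) else objects
    vs = np.asarray(layers.voxel_size)
    shape = np.asarray(layers.shape)
    for rec in records:
        idx = np.floor(rec.centroid_um / vs).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            raise ValueError(
                f"object {rec.object_id} centroid {rec.centroid_um} μm lies outside the layer grid"
            )
        rec.layer = int(layers.labels[tuple(idx)])
    return records
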
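"""Myotube and nucleus segmentation from two-channel immunofluorescence.

The myotube boundary is taken from the structural channel (sarcomeric
alpha-actinin), which also discriminates myotubes from the feeder
fibroblasts: feeder nuclei are DAPI-positive but lie outside the
alpha-actinin mask.  Nuclei are segmented from the nuclear (DAPI) channel
and each nucleus is assigned to the myotube containing its centroid;
nuclei whose centroid falls on background are recorded with parent label 0
and excluded from per-myotube denominators downstream.

Thresholds are automatic (Otsu after Gaussian smoothing) so the pipeline
is deterministic and reproducible; touching myotubes are deliberately not
split (elongated myotubes rarely merge in sparse fields), whereas touching
nuclei are separated by a distance-transform watershed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

__all__ = [
    "FluorescenceField",
    "MyotubeMap",
    "NucleusRecord",
    "segment_myotubes",
    "segment_nuclei",
    "assign_nuclei",
]


@dataclass
class FluorescenceField:
    """Co-registered channels of one imaged field.

    ``channels`` maps channel names to 2-D intensity arrays; the standard
    names are ``structural`` (alpha-actinin), ``nuclear`` (DAPI) and
    ``marker`` (TDP-43 or p62).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None  # microns per pixel, informational
    field_id: str = "field"

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(ch).shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if np.asarray(ch).ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")

    def __getitem__(self, name: str) -> np.ndarray:
        return np.asarray(self.channels[name])

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class MyotubeMap:
    """Labeled myotube regions (0 = background) with per-label geometry."""

    label_image: np.ndarray
    areas: dict[int, int] = field(default_factory=dict)
    bboxes: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)

    @classmethod
    def from_labels(cls, label_image: np.ndarray) -> "MyotubeMap":
        areas, bboxes = {}, {}
        for rp in regionprops(label_image):
            areas[rp.label] = int(rp.area)
            bboxes[rp.label] = tuple(rp.bbox)
        return cls(label_image=label_image, areas=areas, bboxes=bboxes)

    @property
    def labels(self) -> list[int]:
        return sorted(self.areas)

    @property
    def n_myotubes(self) -> int:
        return len(self.areas)

    def mask(self, label: int | None = None) -> np.ndarray:
        if label is None:
            return self.label_image > 0
        return self.label_image == label


@dataclass
class NucleusRecord:
    """One segmented nucleus and its myotube membership."""

    nucleus_label: int
    centroid: tuple[float, float]
    area: int
    parent_myotube_label: int = 0  # 0 = outside all myotubes (feeder/fibroblast)
    marker_positive: bool = False


def _otsu_mask(channel: np.ndarray, sigma: float) -> np.ndarray:
    img = np.asarray(channel, dtype=np.float64)
    if img.max() == img.min():  # flat channel: nothing to segment
        return np.zeros(img.shape, dtype=bool)
    if sigma > 0:
        img = gaussian(img, sigma=sigma, preserve_range=True)
    return img > threshold_otsu(img)


def segment_myotubes(
    structural: np.ndarray,
    min_myotube_area: int = 500,
    smoothing_sigma: float = 2.0,
) -> MyotubeMap:
    """Segment myotubes from the structural (alpha-actinin) channel.

    Gaussian smoothing, global Otsu threshold, hole filling, removal of
    objects below ``min_myotube_area``, then connected-component labeling.
    Touching myotubes are not split.  An all-flat channel yields an empty
    map rather than an error.
    """
    if min_myotube_area <= 0:
        raise ValueError("min_myotube_area must be > 0")
    mask = _otsu_mask(structural, smoothing_sigma)
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=min_myotube_area - 1)
    return MyotubeMap.from_labels(cc_label(mask))


def segment_nuclei(
    nuclear: np.ndarray,
    min_nucleus_area: int = 30,
    smoothing_sigma: float = 1.0,
    min_distance: int = 5,
) -> np.ndarray:
    """Segment nuclei from the DAPI channel, splitting touching nuclei.

    Otsu threshold on the smoothed channel, then a distance-transform
    watershed seeded at distance maxima at least ``min_distance`` pixels
    apart separates touching nuclei; objects below ``min_nucleus_area``
    are dropped.  Returns an integer label image.
    """
    mask = _otsu_mask(nuclear, smoothing_sigma)
    if not mask.any():
        return np.zeros(np.asarray(nuclear).shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)
    keep = remove_small_objects(labels > 0, max_size=min_nucleus_area - 1)
    labels[~keep] = 0
    # relabel compactly so labels are 1..n
    return _relabel(labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    uniq = np.unique(labels)
    uniq = uniq[uniq > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(uniq, start=1):
        out[labels == old] = new
    return out


def assign_nuclei(
    nucleus_labels: np.ndarray, myotube_map: MyotubeMap
) -> list[NucleusRecord]:
    """Assign each nucleus to the myotube its centroid falls in.

    A nucleus whose centroid lands on background gets parent label 0 —
    those are feeder-fibroblast nuclei and are excluded from per-myotube
    nucleus counts.
    """
    if nucleus_labels.shape != myotube_map.label_image.shape:
        raise ValueError("nucleus labels and myotube map shapes differ")
    records = []
    for rp in regionprops(nucleus_labels):
        r, c = rp.centroid
        parent = int(myotube_map.label_image[int(round(r)), int(round(c))])
        records.append(
            NucleusRecord(
                nucleus_label=rp.label,
                centroid=(float(r), float(c)),
                area=int(rp.area),
                parent_myotube_label=parent,
            )
        )
    return records
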
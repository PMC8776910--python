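"""p62 puncta quantification: puncta area relative to myotube area.

Autophagy-receptor p62 forms small granule-like cytoplasmic puncta.  The
readout is, per myotube, the puncta area divided by the total myotube
area.  Puncta are separated from diffuse cytoplasmic signal by a white
top-hat (which removes any structure wider than the structuring element,
including flat offsets), followed by an automatic threshold restricted to
the myotube mask and a size gate on connected components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, white_tophat

from .segmentation import MyotubeMap

log = logging.getLogger(__name__)

__all__ = ["PunctaResult", "detect_puncta", "puncta_area_ratio"]


@dataclass
class PunctaResult:
    """Puncta load of one myotube."""

    myotube_label: int
    puncta_area: int
    myotube_area: int
    n_puncta: int

    @property
    def puncta_ratio(self) -> float:
        return self.puncta_area / self.myotube_area


def detect_puncta(
    marker: np.ndarray,
    myotube_map: MyotubeMap,
    tophat_radius: int = 5,
    min_size: int = 4,
    max_size: int = 400,
    mode: str = "puncta",
) -> tuple[np.ndarray, np.ndarray]:
    """Detect marker puncta inside the myotube mask.

    White top-hat with a disk of ``tophat_radius`` suppresses diffuse
    background (a uniform channel yields no puncta), Otsu restricted to
    within-myotube pixels binarizes, and components outside
    [``min_size``, ``max_size``] are discarded.  With ``mode="total"``
    the top-hat and size gate are skipped and all thresholded marker
    pixels inside myotubes count, for protocols that score total positive
    area rather than puncta only.

    Returns (puncta mask, connected-component label image).
    """
    if not 0 < min_size <= max_size:
        raise ValueError("need 0 < min_size <= max_size")
    if mode not in ("puncta", "total"):
        raise ValueError("mode must be 'puncta' or 'total'")
    marker = np.asarray(marker, dtype=np.float64)
    tube_mask = myotube_map.mask()
    img = white_tophat(marker, footprint=disk(tophat_radius)) if mode == "puncta" else marker
    vals = img[tube_mask]
    if tube_mask.sum() == 0 or vals.max() == vals.min():
        empty = np.zeros(marker.shape, dtype=bool)
        return empty, empty.astype(np.int32)
    mask = tube_mask & (img > threshold_otsu(vals))
    comps = cc_label(mask)
    if mode == "puncta":
        sizes = np.bincount(comps.ravel())
        bad = np.flatnonzero((sizes < min_size) | (sizes > max_size))
        mask &= ~np.isin(comps, bad[bad > 0])
        comps = cc_label(mask)
    return mask, comps


def puncta_area_ratio(
    puncta_labels: np.ndarray, myotube_map: MyotubeMap
) -> tuple[list[PunctaResult], pd.DataFrame]:
    """Per-myotube puncta-to-myotube area ratio and its condition summary.

    Each punctum is attributed to the myotube containing its centroid.
    Myotubes of zero area would be excluded (and logged); the summary row
    holds the mean ratio, SE over myotubes and counts.
    """
    per_tube: dict[int, dict[str, int]] = {
        lbl: {"area": 0, "n": 0} for lbl in myotube_map.labels
    }
    for rp in regionprops(puncta_labels):
        r, c = rp.centroid
        parent = int(myotube_map.label_image[int(round(r)), int(round(c))])
        if parent in per_tube:
            per_tube[parent]["area"] += int(rp.area)
            per_tube[parent]["n"] += 1
    results = []
    for lbl in myotube_map.labels:
        tube_area = myotube_map.areas[lbl]
        if tube_area == 0:
            log.warning("myotube %d has zero area; excluded", lbl)
            continue
        results.append(
            PunctaResult(
                myotube_label=lbl,
                puncta_area=per_tube[lbl]["area"],
                myotube_area=tube_area,
                n_puncta=per_tube[lbl]["n"],
            )
        )
    ratios = np.array([r.puncta_ratio for r in results])
    summary = pd.DataFrame(
        {
            "n_myotubes": [len(ratios)],
            "mean_puncta_ratio": [float(ratios.mean()) if len(ratios) else float("nan")],
            "se_puncta_ratio": [
                float(ratios.std(ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else float("nan")
            ],
            "total_puncta": [int(sum(r.n_puncta for r in results))],
        }
    )
    return results, summary
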
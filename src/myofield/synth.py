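"""Ground-truthed synthetic data for every pipeline stage.

Three generators emulate the raw material of a feeder-supported in vitro
exercise experiment, each returning its inputs together with the exact
ground truth the pipeline is supposed to recover:

* :func:`generate_contraction_sequence` — a bright-field time-lapse of
  elongated myotube-like ribbons oscillating sinusoidally at the pacing
  frequency (1 Hz by default), for the movement-index stage;
* :func:`generate_fluorescence_field` — a three-channel field (structural
  alpha-actinin, nuclear DAPI, marker) containing 6-12 multinucleated
  ribbons over feeder-fibroblast nuclei, with a controllable
  nuclear:cytoplasmic marker partition, a controllable fraction of
  accumulation-positive myotubes, and optionally puncta of a requested
  total area fraction, for the segmentation/localization/puncta stages;
* :func:`generate_expression_table` — a long-format Ct table with
  reference-gene structure, for the expression stage.

All generators are deterministic: the same spec and seed produce
bit-identical output.  Textures and intensity levels are idealized
stand-ins, not photorealistic microscopy — geometry, counts and area
fractions are the properties the generators guarantee.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .motion import FrameSequence
from .segmentation import FluorescenceField

__all__ = [
    "SceneSpec",
    "MotionSpec",
    "GroundTruth",
    "GeometryError",
    "generate_contraction_sequence",
    "generate_fluorescence_field",
    "generate_expression_table",
    "round_half_away",
]

# Intensity levels on the 8-bit scale (scaled up for 16-bit output).
_BG = 5.0  # structural / nuclear background
_STRUCT_FG = 200.0  # alpha-actinin inside myotubes
_NUC_FG = 220.0  # DAPI inside nuclei
_MARKER_BG = 10.0  # marker channel baseline
_MARKER_FG = 220.0  # marker-positive pixels (nuclei, deposits, puncta)
_MARKER_DIFFUSE = 60.0  # diffuse in-myotube signal in puncta-style fields


class GeometryError(RuntimeError):
    """Raised when objects cannot be placed in the field after bounded retries."""


def round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1), for non-negative counts."""
    return int(math.floor(x + 0.5))


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


@dataclass
class SceneSpec:
    """Parameters of one synthetic fluorescence field.

    Defaults follow the imaged fields the pipeline targets: 6-12
    elongated multinucleated myotubes per field on a bed of feeder
    nuclei.  ``marker_nuclear_fraction`` sets the nuclear share of the
    marker-positive area per myotube; unless ``nuclear_positive_fraction``
    is given it also sets the fraction of marker-positive nuclei, so
    shifting marker mass to the cytoplasm depletes nuclear positivity the
    way nucleocytoplasmic translocation does.  Exactly
    ``round_half_away(accumulation_fraction * n_myotubes)`` myotubes
    receive 1-3 bright cytoplasmic aggregate blobs.  A positive
    ``puncta_area_fraction`` switches the marker channel to puncta style
    (diffuse cytoplasmic signal plus small granules totalling the
    requested fraction of the myotube area).
    """

    field_shape: tuple[int, int] = (512, 512)
    n_myotubes: int = 8
    nuclei_per_myotube: tuple[int, int] = (4, 10)
    n_feeder_nuclei: int = 30
    marker_nuclear_fraction: float = 0.8
    nuclear_positive_fraction: float | None = None
    accumulation_fraction: float = 0.0
    puncta_area_fraction: float = 0.0
    noise_sd: float = 0.0
    poisson_noise: bool = False
    bit_depth: int = 8
    seed: int = 0
    # geometry (pixels at the default 512x512 scale)
    myotube_length: tuple[float, float] = (120.0, 200.0)
    myotube_width: tuple[float, float] = (16.0, 26.0)
    nucleus_radii: tuple[float, float] = (4.0, 6.0)
    aggregate_radius: tuple[float, float] = (5.0, 7.0)
    punctum_radius: float = 2.5
    max_placement_tries: int = 400

    def __post_init__(self) -> None:
        _require(len(self.field_shape) == 2 and min(self.field_shape) > 0,
                 "field_shape must be two positive integers")
        _require(self.n_myotubes >= 0, "n_myotubes must be >= 0")
        _require(self.n_feeder_nuclei >= 0, "n_feeder_nuclei must be >= 0")
        lo, hi = self.nuclei_per_myotube
        _require(0 <= lo <= hi, "nuclei_per_myotube must be a (low, high) range with 0 <= low <= high")
        for name in ("marker_nuclear_fraction", "accumulation_fraction", "puncta_area_fraction"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must be in [0, 1]")
        if self.nuclear_positive_fraction is not None:
            _require(0.0 <= self.nuclear_positive_fraction <= 1.0,
                     "nuclear_positive_fraction must be in [0, 1]")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.bit_depth in (8, 16), "bit_depth must be 8 or 16")


@dataclass
class MotionSpec:
    """Parameters of one synthetic contraction time-lapse.

    The default pacing emulates 1 Hz electrical stimulation; all moving
    objects oscillate in phase (field stimulation synchronizes
    contraction), with per-frame displacement ``amplitude *
    cos(2*pi*frequency*t)`` along each object's axis plus a small shear.
    ``frame_rate`` must exceed twice the frequency so contraction and
    relaxation phases are both sampled.
    """

    amplitude: float = 3.0
    frequency: float = 1.0
    frame_rate: float = 10.0
    n_frames: int = 20
    moving_area_fraction: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    field_shape: tuple[int, int] = (256, 256)
    n_objects: int = 6
    bit_depth: int = 8
    object_length: tuple[float, float] = (80.0, 140.0)
    object_width: tuple[float, float] = (12.0, 20.0)
    shear_fraction: float = 0.15
    max_placement_tries: int = 400

    def __post_init__(self) -> None:
        _require(self.amplitude >= 0, "amplitude must be >= 0")
        _require(self.frequency > 0, "frequency must be > 0")
        _require(self.frame_rate > 2 * self.frequency,
                 "frame_rate must exceed 2 x frequency to resolve contraction and relaxation")
        _require(self.n_frames >= 2, "n_frames must be >= 2")
        _require(0.0 <= self.moving_area_fraction <= 1.0,
                 "moving_area_fraction must be in [0, 1]")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.bit_depth in (8, 16), "bit_depth must be 8 or 16")


@dataclass
class GroundTruth:
    """What the generators actually rendered, for recovery checks.

    Field generation fills the label images and per-object tables; the
    motion generator fills ``objects`` and ``frame_offsets``.
    """

    myotube_labels: np.ndarray | None = None
    nucleus_labels: np.ndarray | None = None
    nuclei: pd.DataFrame | None = None  # nucleus_label, parent, area, row, col, marker_positive
    myotubes: pd.DataFrame | None = None  # label, area, n_nuclei, ..., accumulation
    puncta_mask: np.ndarray | None = None
    puncta_area: int = 0
    n_puncta: int = 0
    objects: pd.DataFrame | None = None  # motion: rest centroid, moving flag
    frame_offsets: np.ndarray | None = None  # motion: axial displacement per frame
    extras: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometric primitives


def _dist_to_segment(rr: np.ndarray, cc: np.ndarray,
                     p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    v = p1 - p0
    vv = float(v @ v)
    wr = rr - p0[0]
    wc = cc - p0[1]
    t = np.clip((wr * v[0] + wc * v[1]) / vv, 0.0, 1.0) if vv > 0 else 0.0
    dr = wr - t * v[0]
    dc = wc - t * v[1]
    return np.hypot(dr, dc)


def _capsule_mask(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray,
                  half_width: float, margin: float = 0.0) -> np.ndarray:
    pad = half_width + margin + 2
    r0 = int(max(0, math.floor(min(p0[0], p1[0]) - pad)))
    r1 = int(min(shape[0], math.ceil(max(p0[0], p1[0]) + pad)))
    c0 = int(max(0, math.floor(min(p0[1], p1[1]) - pad)))
    c1 = int(min(shape[1], math.ceil(max(p0[1], p1[1]) + pad)))
    full = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return full
    rr, cc = np.mgrid[r0:r1, c0:c1]
    full[r0:r1, c0:c1] = _dist_to_segment(rr.astype(float), cc.astype(float),
                                          p0, p1) <= half_width + margin
    return full


def _place_capsules(shape, n, length_range, width_range, rng, tries, margin=8.0):
    """Place n non-overlapping capsules; returns (spines, widths, masks)."""
    occupied = np.zeros(shape, dtype=bool)
    spines, widths, masks = [], [], []
    for i in range(n):
        for attempt in range(tries):
            length = rng.uniform(*length_range)
            width = rng.uniform(*width_range)
            theta = rng.uniform(0, np.pi)
            u = np.array([math.sin(theta), math.cos(theta)])
            pad = width / 2 + margin
            lo_r = pad + abs(u[0]) * length / 2
            lo_c = pad + abs(u[1]) * length / 2
            if 2 * lo_r >= shape[0] or 2 * lo_c >= shape[1]:
                continue
            center = np.array([rng.uniform(lo_r, shape[0] - lo_r),
                               rng.uniform(lo_c, shape[1] - lo_c)])
            p0 = center - u * length / 2
            p1 = center + u * length / 2
            guard = _capsule_mask(shape, p0, p1, width / 2, margin=margin)
            if (guard & occupied).any():
                continue
            mask = _capsule_mask(shape, p0, p1, width / 2)
            occupied |= guard
            spines.append((p0, p1))
            widths.append(width)
            masks.append(mask)
            break
        else:
            raise GeometryError(
                f"could not place myotube {i + 1}/{n} after {tries} tries; "
                "reduce n_myotubes or enlarge field_shape"
            )
    return spines, widths, masks


def _quantize(img: np.ndarray, bit_depth: int) -> np.ndarray:
    full = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return np.clip(np.rint(img), 0, full).astype(dtype)


def _apply_noise(img: np.ndarray, rng, noise_sd: float, poisson: bool) -> np.ndarray:
    if poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


# ---------------------------------------------------------------------------
# fluorescence field


def _place_ellipse(rng, tube_mask, spine, forbidden, radii_range, tries):
    """One ellipse fully inside tube_mask avoiding ``forbidden`` pixels."""
    p0, p1 = spine
    for _ in range(tries):
        t = rng.uniform(0.1, 0.9)
        center = p0 + t * (p1 - p0) + rng.normal(0, 2.0, size=2)
        a = rng.uniform(*radii_range)
        b = rng.uniform(*radii_range)
        rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(center[0], center[1], a, b,
                              shape=tube_mask.shape, rotation=rot)
        if len(rr) == 0:
            continue
        if tube_mask[rr, cc].all() and not forbidden[rr, cc].any():
            return rr, cc
    return None


def generate_fluorescence_field(spec: SceneSpec) -> tuple[FluorescenceField, GroundTruth]:
    """Render one three-channel field and its ground truth.

    The structural channel covers exactly the myotube label regions;
    feeder nuclei appear only in the nuclear channel, outside the
    structural mask.  See :class:`SceneSpec` for the marker-channel
    semantics.  Raises :class:`GeometryError` when the requested objects
    cannot be placed (too many myotubes for the field size).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.field_shape)
    spines, widths, tube_masks = _place_capsules(
        shape, spec.n_myotubes, spec.myotube_length, spec.myotube_width,
        rng, spec.max_placement_tries,
    )
    labels = np.zeros(shape, dtype=np.int32)
    for i, m in enumerate(tube_masks):
        labels[m] = i + 1

    structural = np.full(shape, _BG)
    structural[labels > 0] = _STRUCT_FG
    nuclear = np.full(shape, _BG)
    marker = np.full(shape, _MARKER_BG)

    # --- nuclei inside myotubes -------------------------------------------
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    nuc_guard = np.zeros(shape, dtype=bool)  # nuclei dilated by a margin
    nuc_rows = []
    next_nuc = 1
    lo, hi = spec.nuclei_per_myotube
    per_tube_nuclei: list[list[int]] = []
    for i, (spine, mask) in enumerate(zip(spines, tube_masks)):
        want = int(rng.integers(lo, hi + 1))
        placed = []
        for _ in range(want):
            hit = _place_ellipse(rng, mask, spine, nuc_guard,
                                 spec.nucleus_radii, spec.max_placement_tries)
            if hit is None:
                continue
            rr, cc = hit
            nucleus_labels[rr, cc] = next_nuc
            nuclear[rr, cc] = _NUC_FG
            guard = ndi.binary_dilation(nucleus_labels == next_nuc, iterations=3)
            nuc_guard |= guard
            nuc_rows.append({"nucleus_label": next_nuc, "parent": i + 1,
                             "area": len(rr),
                             "row": float(rr.mean()), "col": float(cc.mean()),
                             "marker_positive": False})
            placed.append(next_nuc)
            next_nuc += 1
        per_tube_nuclei.append(placed)

    # --- feeder nuclei outside the structural mask ------------------------
    outside = ~ndi.binary_dilation(labels > 0, iterations=6)
    for _ in range(spec.n_feeder_nuclei):
        for _try in range(spec.max_placement_tries):
            r = rng.uniform(8, shape[0] - 8)
            c = rng.uniform(8, shape[1] - 8)
            rad = rng.uniform(*spec.nucleus_radii)
            rr, cc = draw_disk((r, c), rad, shape=shape)
            if len(rr) and outside[rr, cc].all() and not nuc_guard[rr, cc].any():
                nucleus_labels[rr, cc] = next_nuc
                nuclear[rr, cc] = _NUC_FG
                nuc_guard |= ndi.binary_dilation(nucleus_labels == next_nuc, iterations=3)
                nuc_rows.append({"nucleus_label": next_nuc, "parent": 0,
                                 "area": len(rr),
                                 "row": float(rr.mean()), "col": float(cc.mean()),
                                 "marker_positive": False})
                next_nuc += 1
                break

    nuclei_df = pd.DataFrame(nuc_rows) if nuc_rows else pd.DataFrame(
        columns=["nucleus_label", "parent", "area", "row", "col", "marker_positive"])
    puncta_style = spec.puncta_area_fraction > 0

    # --- marker channel ----------------------------------------------------
    tube_rows = []
    puncta_mask = np.zeros(shape, dtype=bool)
    n_puncta = 0
    acc_count = round_half_away(spec.accumulation_fraction * spec.n_myotubes)
    flagged = set(rng.choice(np.arange(1, spec.n_myotubes + 1), size=acc_count,
                             replace=False).tolist()) if acc_count else set()

    if puncta_style:
        marker[labels > 0] = _MARKER_DIFFUSE
        # nuclear TDP-style partition not rendered in puncta fields
        total_area = int((labels > 0).sum())
        target = round_half_away(spec.puncta_area_fraction * total_area)
        placed_area = 0
        guard = nuc_guard.copy()
        areas = np.array([m.sum() for m in tube_masks], dtype=float)
        budget = 50 * max(1, target)  # bounded effort
        attempts = 0
        while placed_area < target and attempts < budget:
            attempts += 1
            i = int(rng.choice(len(tube_masks), p=areas / areas.sum()))
            p0, p1 = spines[i]
            t = rng.uniform(0.05, 0.95)
            center = p0 + t * (p1 - p0) + rng.normal(0, widths[i] / 4, size=2)
            rr, cc = draw_disk((center[0], center[1]), spec.punctum_radius, shape=shape)
            if len(rr) == 0 or not tube_masks[i][rr, cc].all() or guard[rr, cc].any():
                continue
            if placed_area + len(rr) > target + len(rr) / 2:
                break  # next punctum would overshoot more than half its area
            puncta_mask[rr, cc] = True
            marker[rr, cc] = _MARKER_FG
            dil = np.zeros(shape, dtype=bool)
            dil[rr, cc] = True
            guard |= ndi.binary_dilation(dil, iterations=2)
            placed_area += len(rr)
            n_puncta += 1
        if target and placed_area < 0.8 * target:
            raise GeometryError(
                f"could only place {placed_area}/{target} puncta pixels; "
                "lower puncta_area_fraction or enlarge myotubes"
            )
    else:
        f_pos = (spec.nuclear_positive_fraction
                 if spec.nuclear_positive_fraction is not None
                 else spec.marker_nuclear_fraction)
        f_area = spec.marker_nuclear_fraction
        # feeder fibroblasts retain nuclear marker signal
        feeder = nuclei_df[nuclei_df["parent"] == 0]["nucleus_label"] if len(nuclei_df) else []
        for nl in feeder:
            marker[nucleus_labels == int(nl)] = _MARKER_FG

        for i, mask in enumerate(tube_masks):
            lbl = i + 1
            nuc_ids = per_tube_nuclei[i]
            n_pos = round_half_away(f_pos * len(nuc_ids))
            pos_ids = rng.choice(nuc_ids, size=n_pos, replace=False) if n_pos else []
            nuclear_area = 0
            for nl in pos_ids:
                sel = nucleus_labels == int(nl)
                marker[sel] = _MARKER_FG
                nuclear_area += int(sel.sum())
                nuclei_df.loc[nuclei_df["nucleus_label"] == int(nl), "marker_positive"] = True
            tube_area = int(mask.sum())
            if f_area <= 0:
                cyt_target = round_half_away(0.25 * tube_area)
            elif f_area >= 1:
                cyt_target = 0
            else:
                cyt_target = round_half_away(nuclear_area * (1 - f_area) / f_area)
            cyto = mask & (nucleus_labels == 0) & (marker < _MARKER_FG)
            idx = np.flatnonzero(cyto.ravel())
            scatter = rng.choice(idx, size=min(cyt_target, len(idx)), replace=False)
            marker.ravel()[scatter] = _MARKER_FG
            cyt_area = len(scatter)

            blob_area = 0
            if lbl in flagged:
                # centers taken from the distance transform of the nucleus-free
                # cytoplasm, so a feasible blob is found without rejection loops
                free = mask & (nucleus_labels == 0)
                clearance = ndi.distance_transform_edt(free)
                n_blobs = int(rng.integers(1, 4))
                placed_blobs = 0
                min_rad = 4.2  # keeps blob area above the default detector gate
                for _ in range(n_blobs):
                    rad = rng.uniform(*spec.aggregate_radius)
                    cand = np.flatnonzero((clearance >= rad + 1).ravel())
                    if len(cand) == 0:
                        rad = max(min_rad, float(clearance.max()) - 1.0)
                        cand = np.flatnonzero((clearance >= rad + 1).ravel())
                    if len(cand) == 0:
                        continue
                    r, c = np.unravel_index(int(rng.choice(cand)), shape)
                    rr, cc = draw_disk((r, c), rad, shape=shape)
                    marker[rr, cc] = _MARKER_FG
                    blob_area += len(rr)
                    placed_blobs += 1
                if placed_blobs == 0:
                    raise GeometryError(
                        f"could not place an aggregate blob in myotube {lbl}; "
                        "myotube too crowded with nuclei for aggregate_radius"
                    )
            tube_rows.append({
                "label": lbl, "area": tube_area,
                "n_nuclei": len(nuc_ids), "n_positive_nuclei": int(len(pos_ids)),
                "nuclear_marker_area": nuclear_area,
                "cytoplasmic_marker_area": cyt_area + blob_area,
                "accumulation": lbl in flagged,
            })

    if puncta_style:
        for i, mask in enumerate(tube_masks):
            lbl = i + 1
            tube_rows.append({
                "label": lbl, "area": int(mask.sum()),
                "n_nuclei": len(per_tube_nuclei[i]), "n_positive_nuclei": 0,
                "nuclear_marker_area": 0,
                "cytoplasmic_marker_area": int((puncta_mask & mask).sum()),
                "accumulation": False,
            })

    channels = {}
    for name, img in (("structural", structural), ("nuclear", nuclear), ("marker", marker)):
        channels[name] = _quantize(
            _apply_noise(img, rng, spec.noise_sd, spec.poisson_noise), spec.bit_depth
        )
    fieldobj = FluorescenceField(channels=channels, field_id=f"synthetic-seed{spec.seed}")
    truth = GroundTruth(
        myotube_labels=labels,
        nucleus_labels=nucleus_labels,
        nuclei=nuclei_df,
        myotubes=pd.DataFrame(tube_rows),
        puncta_mask=puncta_mask,
        puncta_area=int(puncta_mask.sum()),
        n_puncta=n_puncta,
        extras={"accumulation_labels": sorted(flagged)},
    )
    return fieldobj, truth


# ---------------------------------------------------------------------------
# contraction time-lapse


def _render_capsule_soft(img, p0, p1, half_width, amp, edge=1.5):
    pad = half_width + 4 * edge
    r0 = int(max(0, math.floor(min(p0[0], p1[0]) - pad)))
    r1 = int(min(img.shape[0], math.ceil(max(p0[0], p1[0]) + pad)))
    c0 = int(max(0, math.floor(min(p0[1], p1[1]) - pad)))
    c1 = int(min(img.shape[1], math.ceil(max(p0[1], p1[1]) + pad)))
    if r1 <= r0 or c1 <= c0:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = _dist_to_segment(rr.astype(float), cc.astype(float), np.asarray(p0), np.asarray(p1))
    img[r0:r1, c0:c1] += amp * 0.5 * (1.0 + np.tanh((half_width - d) / edge))


def generate_contraction_sequence(spec: MotionSpec) -> tuple[FrameSequence, GroundTruth]:
    """Render a time-lapse of sinusoidally deforming ribbon objects.

    Displacement of moving objects at frame ``k`` (time ``k /
    frame_rate``) is ``amplitude * cos(2*pi*frequency*t)`` along the
    object axis, plus a shear that rotates the endpoints in opposite
    perpendicular directions by ``shear_fraction`` of the displacement.
    With amplitude 0 and no noise all frames are bit-identical.
    ``moving_area_fraction`` selects objects (largest first in placement
    order) until the requested share of the total object area moves.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.field_shape)
    spines, widths, masks = _place_capsules(
        shape, spec.n_objects, spec.object_length, spec.object_width,
        rng, spec.max_placement_tries, margin=max(6.0, spec.amplitude + 4),
    )
    areas = np.array([m.sum() for m in masks], dtype=float)
    total = areas.sum()
    moving = np.zeros(spec.n_objects, dtype=bool)
    if spec.moving_area_fraction > 0 and spec.n_objects:
        order = rng.permutation(spec.n_objects)
        cum = 0.0
        for i in order:
            moving[i] = True
            cum += areas[i]
            if cum / total >= spec.moving_area_fraction:
                break

    # static background texture (smooth random field), shared by all frames
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma=6)
    texture = 20.0 + 12.0 * (texture - texture.min()) / max(np.ptp(texture), 1e-12)
    amps = rng.uniform(120.0, 170.0, size=spec.n_objects)

    t = np.arange(spec.n_frames) / spec.frame_rate
    offsets = spec.amplitude * np.cos(2 * np.pi * spec.frequency * t)

    static = texture.copy()
    for i, (p0, p1) in enumerate(spines):
        if not moving[i]:
            _render_capsule_soft(static, p0, p1, widths[i] / 2, amps[i])

    dtype_noise_rng = np.random.default_rng(spec.seed + 1)
    frames = np.empty((spec.n_frames, *shape),
                      dtype=np.uint8 if spec.bit_depth == 8 else np.uint16)
    for k in range(spec.n_frames):
        img = static.copy()
        for i, (p0, p1) in enumerate(spines):
            if not moving[i]:
                continue
            u = (np.asarray(p1) - np.asarray(p0))
            u = u / np.linalg.norm(u)
            perp = np.array([-u[1], u[0]])
            d = offsets[k]
            shear = spec.shear_fraction * d
            q0 = np.asarray(p0) + d * u + shear * perp
            q1 = np.asarray(p1) + d * u - shear * perp
            _render_capsule_soft(img, q0, q1, widths[i] / 2, amps[i])
        if spec.noise_sd > 0:
            img = img + dtype_noise_rng.normal(0.0, spec.noise_sd, size=shape)
        frames[k] = _quantize(img, spec.bit_depth)

    obj_rows = []
    for i, (p0, p1) in enumerate(spines):
        c = (np.asarray(p0) + np.asarray(p1)) / 2
        obj_rows.append({"object": i + 1, "row": float(c[0]), "col": float(c[1]),
                         "width": widths[i], "area": int(areas[i]),
                         "moving": bool(moving[i])})
    seq = FrameSequence(frames, frame_interval=1.0 / spec.frame_rate,
                        bit_depth=spec.bit_depth)
    truth = GroundTruth(objects=pd.DataFrame(obj_rows), frame_offsets=offsets)
    return seq, truth


# ---------------------------------------------------------------------------
# expression tables


def generate_expression_table(
    n_samples: int,
    true_delta_ct: Mapping[str, float] | Mapping[str, Mapping[str, float]],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    reference_gene: str = "RPLP0",
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Long-format Ct table with reference-gene structure.

    ``true_delta_ct`` maps gene -> dCt for a single condition named
    "basal", or condition -> {gene -> dCt}.  Per sample the reference Ct
    is drawn around ``reference_ct`` and each target Ct is that sample's
    reference Ct plus the true dCt, both with Gaussian cycle noise of SD
    ``ct_noise_sd``.  Zero noise makes every row's Ct(target) -
    Ct(reference) equal to the true dCt exactly.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    first = next(iter(true_delta_ct.values()))
    per_condition: Mapping[str, Mapping[str, float]]
    if isinstance(first, Mapping):
        per_condition = true_delta_ct  # type: ignore[assignment]
    else:
        per_condition = {"basal": true_delta_ct}  # type: ignore[dict-item]
    rng = np.random.default_rng(seed)
    rows = []
    for cond, gene_map in per_condition.items():
        for s in range(n_samples):
            sid = f"{cond}_s{s + 1}"
            ref = reference_ct + (rng.normal(0, ct_noise_sd) if ct_noise_sd else 0.0)
            rows.append({"sample_id": sid, "condition": cond,
                         "gene": reference_gene, "ct": ref})
            for gene, dct in gene_map.items():
                ct = ref + dct + (rng.normal(0, ct_noise_sd) if ct_noise_sd else 0.0)
                rows.append({"sample_id": sid, "condition": cond,
                             "gene": gene, "ct": ct})
    return pd.DataFrame(rows)
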
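"""Reading and writing the pipeline's on-disk formats.

Frame sequences are multi-page grayscale TIFFs; fluorescence fields are
multi-channel TIFFs with a channel-name mapping supplied by the caller
(default channel order: structural, nuclear, marker).  Ground truth from
the synthetic generators is written as a sidecar: label images as TIFF
and per-object records as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .motion import FrameSequence
from .segmentation import FluorescenceField
from .synth import GroundTruth

__all__ = [
    "write_frame_sequence",
    "read_frame_sequence",
    "write_field",
    "read_field",
    "write_ground_truth",
]

DEFAULT_CHANNEL_ORDER = ("structural", "nuclear", "marker")


def write_frame_sequence(seq: FrameSequence, path: str | Path) -> Path:
    """Write a frame sequence as a multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, seq.frames, photometric="minisblack",
                     metadata={"frame_interval_s": seq.frame_interval})
    return path


def read_frame_sequence(
    path: str | Path, frame_interval: float = 0.1
) -> FrameSequence:
    """Read a multi-page TIFF (or a directory of numbered TIFFs) as a sequence."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF files in {path}")
        frames = np.stack([tifffile.imread(f) for f in files])
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    bit_depth = 16 if frames.dtype == np.uint16 else 8
    return FrameSequence(frames.astype(np.uint16 if bit_depth == 16 else np.uint8),
                         frame_interval=frame_interval, bit_depth=bit_depth)


def write_field(
    field: FluorescenceField,
    path: str | Path,
    channel_order: tuple[str, ...] = DEFAULT_CHANNEL_ORDER,
) -> Path:
    """Write a fluorescence field as a (channels, rows, cols) TIFF."""
    path = Path(path)
    stack = np.stack([field[name] for name in channel_order])
    tifffile.imwrite(path, stack, photometric="minisblack",
                     metadata={"channels": list(channel_order)})
    return path


def read_field(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    field_id: str | None = None,
) -> FluorescenceField:
    """Read a multi-channel TIFF.

    ``channel_map`` maps channel names to plane indices, e.g.
    ``{"structural": 0, "nuclear": 1, "marker": 2}`` (the default).
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if channel_map is None:
        channel_map = {name: i for i, name in enumerate(DEFAULT_CHANNEL_ORDER[: len(stack)])}
    channels = {name: stack[idx] for name, idx in channel_map.items()}
    return FluorescenceField(channels=channels, field_id=field_id or path.stem)


def write_ground_truth(truth: GroundTruth, outdir: str | Path, prefix: str = "truth") -> Path:
    """Write a ground-truth sidecar (label TIFFs + record CSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if truth.myotube_labels is not None:
        tifffile.imwrite(outdir / f"{prefix}_myotube_labels.tif",
                         truth.myotube_labels.astype(np.uint16))
    if truth.nucleus_labels is not None:
        tifffile.imwrite(outdir / f"{prefix}_nucleus_labels.tif",
                         truth.nucleus_labels.astype(np.uint16))
    if truth.puncta_mask is not None and truth.puncta_mask.any():
        tifffile.imwrite(outdir / f"{prefix}_puncta_mask.tif",
                         truth.puncta_mask.astype(np.uint8) * 255)
    if truth.nuclei is not None:
        truth.nuclei.to_csv(outdir / f"{prefix}_nuclei.csv", index=False)
    if truth.myotubes is not None:
        truth.myotubes.to_csv(outdir / f"{prefix}_myotubes.csv", index=False)
    if truth.objects is not None:
        truth.objects.to_csv(outdir / f"{prefix}_objects.csv", index=False)
    if truth.frame_offsets is not None:
        np.savetxt(outdir / f"{prefix}_frame_offsets.csv", truth.frame_offsets,
                   delimiter=",", header="axial_offset_px", comments="")
    return outdir
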
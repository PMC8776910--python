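"""Movement-index quantification of contracting myotubes.

Contractile activity of electrically paced myotubes is scored from a
bright-field time-lapse by differential image subtraction: the relaxation
frame is subtracted from the contraction frame, and because intensity
changes between successive frames are produced by moving scattering
objects, the mean intensity of the absolute difference image measures how
much of the field moved and by how much.  The per-sequence statistic
("movement index") is the mean of the per-pair differential intensities,
normalized to the full bit scale so 8-bit and 16-bit recordings are
comparable.  The index is in arbitrary units; only relative comparisons
(e.g. across stimulation voltages) are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FrameSequence",
    "DifferentialImage",
    "MovementIndexResult",
    "MovementSummary",
    "pair_frames",
    "differential_image",
    "movement_index",
    "render_motion_overlay",
    "summarize_movement",
]

_BIT_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclass
class FrameSequence:
    """Ordered grayscale frames with a uniform shape and bit depth.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Stack of grayscale frames, dtype uint8 or uint16.
    frame_interval : float
        Seconds between consecutive frames.
    bit_depth : int
        8 or 16; must match the dtype of ``frames``.
    """

    frames: np.ndarray
    frame_interval: float = 0.1
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (n_frames, rows, cols) stack")
        if self.n_frames < 2:
            raise ValueError("frames: a sequence needs at least 2 frames")
        if self.bit_depth not in _BIT_DTYPES:
            raise ValueError("bit_depth must be 8 or 16")
        expected = _BIT_DTYPES[self.bit_depth]
        if self.frames.dtype != expected:
            raise ValueError(
                f"frames dtype {self.frames.dtype} does not match bit_depth "
                f"{self.bit_depth} (expected {np.dtype(expected).name})"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class DifferentialImage:
    """Per-pixel absolute intensity difference between two frames."""

    values: np.ndarray
    pair: tuple[int, int] = (0, 1)

    @property
    def mean_intensity(self) -> float:
        return float(self.values.mean())


@dataclass
class MovementIndexResult:
    """Movement index of a sequence plus its per-pair trace.

    ``movement_index`` is the mean of ``per_pair_trace``; the trace holds
    the mean differential intensity of each frame pair, both normalized to
    the full bit scale of the recording.
    """

    movement_index: float
    per_pair_trace: np.ndarray
    n_pairs: int
    lag: int
    noise_floor: float = 0.0
    normalization: str = "full bit scale"


@dataclass
class MovementSummary:
    mean: float
    se: float
    n: int
    values: np.ndarray = field(repr=False, default=None)


def default_lag(frame_rate: float, stimulation_hz: float | None) -> int:
    """Pairing lag in frames: half a stimulation period when the pacing
    frequency is known (contraction vs. relaxation phase), else 1."""
    if stimulation_hz is None:
        return 1
    if stimulation_hz <= 0:
        raise ValueError("stimulation_hz must be > 0")
    return max(1, int(round(frame_rate / (2.0 * stimulation_hz))))


def pair_frames(
    seq: FrameSequence,
    lag: int | None = None,
    stimulation_hz: float | None = None,
) -> list[tuple[int, int]]:
    """All frame-index pairs ``(i, i + lag)`` used for differencing.

    With an explicit ``lag`` that lag is used; otherwise the default is one
    frame, or half a stimulation period when ``stimulation_hz`` is given.
    """
    if lag is None:
        lag = default_lag(seq.frame_rate, stimulation_hz)
    if not 1 <= lag <= seq.n_frames - 1:
        raise ValueError(
            f"lag {lag} out of range [1, {seq.n_frames - 1}] for "
            f"{seq.n_frames} frames"
        )
    return [(i, i + lag) for i in range(seq.n_frames - lag)]


def differential_image(frame_a: np.ndarray, frame_b: np.ndarray) -> DifferentialImage:
    """Absolute per-pixel difference of two frames (symmetric in arguments)."""
    a = np.asarray(frame_a)
    b = np.asarray(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    diff = np.abs(a.astype(np.int64) - b.astype(np.int64)).astype(np.float64)
    return DifferentialImage(values=diff)


def movement_index(
    seq: FrameSequence,
    lag: int | None = None,
    noise_floor: float = 0.0,
    stimulation_hz: float | None = None,
    frame_range: tuple[int, int] | None = None,
) -> MovementIndexResult:
    """Movement index of a frame sequence.

    For each frame pair the absolute difference image is computed, pixels
    at or below ``noise_floor`` are zeroed, and the mean over all pixels is
    normalized by the full bit scale.  The index is the mean across pairs.
    A static noiseless sequence yields exactly 0.

    Parameters
    ----------
    lag : int, optional
        Frame offset between the paired images; defaults to 1 or, when
        ``stimulation_hz`` is given, to half a stimulation period.
    noise_floor : float
        Differential intensities ≤ this value are treated as camera noise
        and zeroed before averaging.  Default 0 (raw averaging).
    frame_range : (start, stop), optional
        Restrict the evaluation to ``frames[start:stop]`` (e.g. the final
        minutes of a stimulation session).
    """
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")
    if frame_range is not None:
        start, stop = frame_range
        sub = seq.frames[start:stop]
        seq = FrameSequence(sub, seq.frame_interval, seq.bit_depth)
    pairs = pair_frames(seq, lag=lag, stimulation_hz=stimulation_hz)
    used_lag = pairs[0][1] - pairs[0][0]
    scale = float(seq.full_scale)
    trace = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        diff = differential_image(seq.frames[i], seq.frames[j]).values
        if noise_floor > 0:
            diff = np.where(diff <= noise_floor, 0.0, diff)
        trace[k] = diff.mean() / scale
    return MovementIndexResult(
        movement_index=float(trace.mean()),
        per_pair_trace=trace,
        n_pairs=len(pairs),
        lag=used_lag,
        noise_floor=noise_floor,
    )


def render_motion_overlay(
    seq: FrameSequence,
    pairs: Sequence[tuple[int, int]] | None = None,
    cmap: str = "jet",
) -> np.ndarray:
    """Pseudo-colored motion overlay on the bright-field background.

    The pixelwise maximum of the differential images across ``pairs`` is
    mapped through a matplotlib colormap and painted over the first frame
    wherever motion was detected; static pixels keep the grayscale
    background.  Purely presentational.

    Returns an (rows, cols, 3) uint8 RGB image.
    """
    import matplotlib

    if pairs is None:
        pairs = pair_frames(seq)
    if len(pairs) == 0:
        raise ValueError("at least one frame pair is required")
    maxdiff = np.zeros(seq.frame_shape, dtype=np.float64)
    for i, j in pairs:
        np.maximum(maxdiff, differential_image(seq.frames[i], seq.frames[j]).values, out=maxdiff)
    scale = float(seq.full_scale)
    bg = (seq.frames[0].astype(np.float64) / scale)[..., None].repeat(3, axis=2)
    colormap = matplotlib.colormaps[cmap]
    colored = colormap(maxdiff / max(maxdiff.max(), 1.0))[..., :3]
    moving = maxdiff > 0
    out = np.where(moving[..., None], colored, bg)
    return (out * 255 + 0.5).astype(np.uint8)


def summarize_movement(
    indices: Sequence[MovementIndexResult | float],
) -> MovementSummary:
    """Mean ± SE of the movement index across fields of one condition.

    Three to five fields per condition is typical; SE uses the sample
    standard deviation (ddof=1) and is NaN for a single field.
    """
    if len(indices) == 0:
        raise ValueError("at least one field is required")
    vals = np.array(
        [x.movement_index if isinstance(x, MovementIndexResult) else float(x) for x in indices]
    )
    n = len(vals)
    se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return MovementSummary(mean=float(vals.mean()), se=se, n=n, values=vals)
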
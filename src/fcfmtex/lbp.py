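"""Rotation-invariant uniform local binary patterns (riu2 LBP) on circular frames.

At each pixel, the P neighbours at angles 2πp/P on a circle of radius R
(bilinearly interpolated) are compared to the centre: neighbour >= centre gives
bit 1. Patterns with at most two circular 0/1 transitions ("uniform") are
binned by their number of set bits (0..P); everything else falls in one
miscellaneous bin, giving P+2 bins per (R, P) resolution. Per-frame histograms
are normalized and mean-pooled over the on-target frames of a video, and the
default multiresolution set (1,8), (2,16), (3,24), (4,24) concatenates to an
80-dimensional video feature (10+18+26+26).

Frames are circular: patterns are extracted at every pixel inside the field-of-
view disk whose sampling circle fits within the frame *bounds*; pixels near the
FOV-circle boundary are deliberately not excluded (they are a ~1% minority and
excluding them needs a per-radius mask for negligible gain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FCFMVideo, VideoFeature, on_target_frames

DEFAULT_RESOLUTIONS: list[tuple[int, int]] = [(1, 8), (2, 16), (3, 24), (4, 24)]


@dataclass
class LBPConfig:
    resolutions: list[tuple[int, int]] = field(
        default_factory=lambda: list(DEFAULT_RESOLUTIONS)
    )

    def __post_init__(self) -> None:
        for r, p in self.resolutions:
            if r < 1 or p < 4:
                raise ValueError(f"invalid LBP resolution (R={r}, P={p})")

    @property
    def dim(self) -> int:
        return sum(p + 2 for _, p in self.resolutions)


def _neighbour_offsets(R: float, P: int) -> np.ndarray:
    """(P, 2) array of (dy, dx) sampling offsets at angles 2πp/P."""
    p = np.arange(P)
    ang = 2.0 * np.pi * p / P
    return np.stack([-R * np.sin(ang), R * np.cos(ang)], axis=1)


def lbp_code(frame: np.ndarray, pixel: tuple[int, int], R: float, P: int) -> int:
    """LBP code (P-bit integer, bit p = neighbour p >= centre) at one pixel.

    The sampling circle must fit inside the frame bounds.
    """
    frame = np.asarray(frame, dtype=float)
    y, x = pixel
    h, w = frame.shape
    if not (y - R >= 0 and y + R <= h - 1 and x - R >= 0 and x + R <= w - 1):
        raise ValueError(f"sampling circle (R={R}) at {pixel} crosses frame bounds")
    centre = frame[y, x]
    code = 0
    for p, (dy, dx) in enumerate(_neighbour_offsets(R, P)):
        ny, nx = y + dy, x + dx
        y0, x0 = int(np.floor(ny)), int(np.floor(nx))
        fy, fx = ny - y0, nx - x0
        y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
        # interpolate the *difference* to the centre: exact at ties, where the
        # four bilinear weights would otherwise not sum to 1 in floating point
        diff = (
            (frame[y0, x0] - centre) * (1 - fy) * (1 - fx)
            + (frame[y0, x1] - centre) * (1 - fy) * fx
            + (frame[y1, x0] - centre) * fy * (1 - fx)
            + (frame[y1, x1] - centre) * fy * fx
        )
        if diff >= 0:
            code |= 1 << p
    return code


def riu2_bin(code: int, P: int) -> int:
    """Map a P-bit LBP code to its riu2 bin.

    Uniform codes (<= 2 circular bit transitions) map to their popcount
    (0..P); all other codes map to the miscellaneous bin P+1.
    """
    bits = [(code >> p) & 1 for p in range(P)]
    transitions = sum(bits[p] != bits[(p + 1) % P] for p in range(P))
    return sum(bits) if transitions <= 2 else P + 1


def _interp_diff_shifted(frame: np.ndarray, dy: float, dx: float, R: int) -> np.ndarray:
    """Bilinear sample of ``frame - centre`` at (y+dy, x+dx) for interior pixels.

    Interior = pixels at least R from every frame edge; returned array matches
    ``frame[R:-R, R:-R]``. Interpolating differences (not raw values) makes the
    >= 0 comparison exact at ties: a constant neighbourhood gives exactly 0.
    """
    y0, x0 = int(np.floor(dy)), int(np.floor(dx))
    fy, fx = dy - y0, dx - x0
    # when the offset is an exact integer the +1 corner has zero weight;
    # collapsing it keeps the slice within bounds at the positive extreme
    y1 = y0 + 1 if fy > 0 else y0
    x1 = x0 + 1 if fx > 0 else x0
    h, w = frame.shape
    centre = frame[R : h - R, R : w - R]

    def block(oy: int, ox: int) -> np.ndarray:
        return frame[R + oy : h - R + oy, R + ox : w - R + ox] - centre

    return (
        block(y0, x0) * (1 - fy) * (1 - fx)
        + block(y0, x1) * (1 - fy) * fx
        + block(y1, x0) * fy * (1 - fx)
        + block(y1, x1) * fy * fx
    )


def frame_lbp_histogram(
    frame: np.ndarray, fov_mask: np.ndarray, R: int, P: int
) -> np.ndarray:
    """riu2 histogram (P+2 bins, summing to 1) over the eligible pixels of one frame.

    Eligible: inside ``fov_mask`` and with the radius-R sampling circle inside
    the frame bounds. Fully vectorized; per-pixel integer codes are never
    materialized — uniformity is decided from the stacked bit planes.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    if h <= 2 * R or w <= 2 * R:
        raise ValueError(f"frame {frame.shape} too small for R={R}")
    shape = (h - 2 * R, w - 2 * R)
    bits = np.empty((P,) + shape, dtype=bool)
    for p, (dy, dx) in enumerate(_neighbour_offsets(R, P)):
        bits[p] = _interp_diff_shifted(frame, dy, dx, R) >= 0.0

    transitions = (bits != np.roll(bits, -1, axis=0)).sum(axis=0)
    popcount = bits.sum(axis=0)
    bins = np.where(transitions <= 2, popcount, P + 1)

    eligible = fov_mask[R : h - R, R : w - R]
    if not eligible.any():
        raise ValueError("no eligible pixels for LBP histogram")
    hist = np.bincount(bins[eligible].ravel(), minlength=P + 2).astype(float)
    return hist / hist.sum()


def video_lbp_feature(video: FCFMVideo, config: LBPConfig | None = None) -> VideoFeature:
    """Mean of per-frame riu2 histograms over on-target frames, concatenated
    across the configured (R, P) resolutions. Each (R, P) block sums to 1."""
    config = config or LBPConfig()
    frames = on_target_frames(video)
    mask = video.fov_mask
    blocks = []
    for R, P in config.resolutions:
        hists = np.stack([frame_lbp_histogram(f, mask, R, P) for f in frames])
        blocks.append(hists.mean(axis=0))
    return VideoFeature(
        patient_id=video.patient_id, scheme="lbp", vector=np.concatenate(blocks)
    )
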
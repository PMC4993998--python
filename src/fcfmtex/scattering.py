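"""Windowed 2-D scattering-transform features of the central frame square.

The scattering transform is a cascade of wavelet-modulus operations with fixed
(not learned) filters: dilated and rotated Morlet wavelets psi_{j,theta} with
j = 0..J-1 dilations and L equispaced rotations in [0, pi), plus a Gaussian
low-pass phi_J. Layer outputs are

* order 0: x smoothed by phi_J,
* order 1: |x * psi_{j1,t1}| smoothed by phi_J,
* order 2: ||x * psi_{j1,t1}| * psi_{j2,t2}| smoothed by phi_J, only along
  frequency-decreasing paths j2 > j1 (the energy of other paths is negligible),

each smoothed output downsampled by 2^J. With 2J = log2(N) (N = pixel count)
every path leaves exactly one coefficient, so the total is

    1 + J*L + L^2 * J*(J-1)/2

which is 1401 at the defaults J=7, L=8, m=2 on a 128x128 image. Because a
single retained sample of a unit-mass low-pass equals global average pooling,
coefficients are computed as the spatial mean of the modulus along each path.

Frames are min-max normalized to [0, 1] per frame before the transform (FCFM
videos differ drastically in dynamic range); the largest axis-aligned square
inscribed in the circular field of view is cropped and resized first, so the
transform never sees the black FOV corners. A histogram-equalization
preprocessing step exists behind a flag but is off by default (it does not
help in practice).

Second-layer inputs are subsampled by 2^j1 (Fourier periodization, the exact
frequency-domain counterpart of spatial subsampling) — the standard speed
optimization, valid because |x * psi_j| is concentrated below frequency 2^-j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.fft as _fft
from skimage.transform import resize

from .io import FCFMVideo, VideoFeature, on_target_frames

_MIN_WORKING_SIZE = 16  # floor for subsampled second-layer resolution


@dataclass(frozen=True)
class ScatteringConfig:
    J: int = 7  # number of dyadic dilations
    L: int = 8  # rotations per layer, equispaced in [0, pi)
    m: int = 2  # maximum order
    resize_to: int = 128
    equalize: bool = False  # optional histogram equalization (off by default)

    def __post_init__(self) -> None:
        if self.J < 1 or self.L < 1 or self.m not in (0, 1, 2):
            raise ValueError("invalid scattering configuration")
        if self.resize_to < 2**2:
            raise ValueError("resize_to too small")

    @property
    def n_coefficients(self) -> int:
        return coefficient_count(self.J, self.L, self.m)


def coefficient_count(J: int, L: int, m: int) -> int:
    """Closed-form path count: 1 + J*L + L^2 * J*(J-1)/2 (truncated at order m)."""
    n = 1
    if m >= 1:
        n += J * L
    if m >= 2:
        n += L * L * J * (J - 1) // 2
    return n


def enumerate_paths(J: int, L: int, m: int) -> list[tuple]:
    """All scattering paths in coefficient order.

    Order 0 is the empty path; order 1 paths are (j1, t1); order 2 paths are
    (j1, t1, j2, t2) with j2 > j1 (frequency-decreasing) and unrestricted
    rotation pairs.
    """
    paths: list[tuple] = [()]
    if m >= 1:
        paths += [(j1, t1) for j1 in range(J) for t1 in range(L)]
    if m >= 2:
        paths += [
            (j1, t1, j2, t2)
            for j1 in range(J)
            for t1 in range(L)
            for j2 in range(j1 + 1, J)
            for t2 in range(L)
        ]
    return paths


# ---------------------------------------------------------------------------
# Morlet filter bank (Fourier domain)
# ---------------------------------------------------------------------------

def _centered_grid(n: int) -> np.ndarray:
    """Coordinates 0, 1, ..., n/2-1, -n/2, ..., -1 (fft layout)."""
    return ((np.arange(n) + n // 2) % n) - n // 2


def _morlet_spatial(n: int, sigma: float, xi: float, theta: float, slant: float) -> np.ndarray:
    """Zero-mean Morlet wavelet sampled on an n x n grid in fft layout."""
    y = _centered_grid(n)[:, None]
    x = _centered_grid(n)[None, :]
    u = x * np.cos(theta) + y * np.sin(theta)  # along the wave vector
    v = -x * np.sin(theta) + y * np.cos(theta)
    env = np.exp(-(u**2 + (slant * v) ** 2) / (2.0 * sigma**2))
    wave = np.exp(1j * xi * u)
    beta = (env * wave).sum() / env.sum()  # cancels the DC component
    psi = (wave - beta) * env
    return psi / (2 * np.pi * sigma**2 / slant)


def _periodize(filter_hat: np.ndarray, k: int) -> np.ndarray:
    """Fold an n x n Fourier filter to resolution n/k (subsampling by k)."""
    if k == 1:
        return filter_hat
    n = filter_hat.shape[-1]
    m = n // k
    return filter_hat.reshape(filter_hat.shape[:-2] + (k, m, k, m)).sum(axis=(-4, -2)) / k**2


@lru_cache(maxsize=8)
def _filter_bank(n: int, J: int, L: int) -> dict:
    """psi_hat[j][theta] at full resolution plus periodized copies per j1 level.

    Kymatio-style parameterization: sigma = 0.8 * 2^j, center frequency
    xi = 3*pi/4 / 2^j, slant 4/L.
    """
    slant = 4.0 / L
    psi_hat = np.empty((J, L, n, n), dtype=np.complex64)
    for j in range(J):
        sigma = 0.8 * 2**j
        xi = 3.0 * np.pi / 4.0 / 2**j
        for t in range(L):
            theta = np.pi * t / L
            psi_hat[j, t] = np.fft.fft2(_morlet_spatial(n, sigma, xi, theta, slant))
    # second-layer working resolution: subsample |x*psi_j1| by max(2^j1, 2)
    # (floor of 2 because the modulus is low-frequency-dominated even at j1=0),
    # never below _MIN_WORKING_SIZE pixels
    subs = {
        j1: min(max(2**j1, 2), max(n // _MIN_WORKING_SIZE, 1)) for j1 in range(J)
    }
    psi_at = {}
    for j1, k in subs.items():
        if k not in psi_at:
            psi_at[k] = _periodize(psi_hat, k)
    return {"psi_hat": psi_hat, "subs": subs, "psi_at": psi_at}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def central_square(
    frame: np.ndarray, resize_to: int = 128, equalize: bool = False
) -> np.ndarray:
    """Largest inscribed axis-aligned square of the FOV circle, resized and
    min-max normalized to [0, 1].

    The inscribed square of a circle of diameter d has side floor(d/sqrt(2)).
    A constant frame cannot be normalized and comes back as all zeros with a
    warning.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    d = min(h, w)
    side = int(np.floor(d / np.sqrt(2.0)))
    cy, cx = h // 2, w // 2
    y0, x0 = cy - side // 2, cx - side // 2
    crop = frame[y0 : y0 + side, x0 : x0 + side]
    out = resize(crop, (resize_to, resize_to), order=1, anti_aliasing=side > resize_to)
    lo, hi = out.min(), out.max()
    if hi <= lo:
        warnings.warn("constant frame: returning all-zeros square")
        return np.zeros((resize_to, resize_to))
    out = (out - lo) / (hi - lo)
    if equalize:
        from skimage.exposure import equalize_hist

        out = equalize_hist(out)
    return out


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def scattering_coefficients(image: np.ndarray, config: ScatteringConfig | None = None) -> np.ndarray:
    """Scattering coefficient vector (one scalar per path) for one square image."""
    config = config or ScatteringConfig()
    image = np.asarray(image, dtype=float)
    if image.shape != (config.resize_to, config.resize_to):
        raise ValueError(
            f"expected {(config.resize_to,) * 2} image, got {image.shape}"
        )
    return scattering_batch(image[None], config)[0]


def scattering_batch(images: np.ndarray, config: ScatteringConfig) -> np.ndarray:
    """Coefficients for a (F, N, N) stack, F frames at once (shared FFT plans).

    Coefficient order matches :func:`enumerate_paths`.
    """
    F, n, n2 = images.shape
    assert n == n2 == config.resize_to
    J, L, m = config.J, config.L, config.m
    bank = _filter_bank(n, J, L)
    out = np.empty((F, config.n_coefficients))
    out[:, 0] = images.mean(axis=(1, 2))  # order 0: unit-mass low-pass pooled
    if m == 0:
        return out

    col = 1
    s2_cols: dict[tuple[int, int], int] = {}
    if m >= 2:  # precompute column offsets for (j1, t1) second-order blocks
        c = 1 + J * L
        for j1 in range(J):
            for t1 in range(L):
                s2_cols[(j1, t1)] = c
                c += (J - 1 - j1) * L

    # single precision throughout the cascade: the coefficients are spatial
    # means of |conv|, far above float32 noise, and the FFTs dominate runtime
    X_hat = _fft.fft2(images.astype(np.float32)).astype(np.complex64)
    for j1 in range(J):
        conv = _fft.ifft2(X_hat[:, None] * bank["psi_hat"][j1][None])
        U1 = np.abs(conv)  # (F, L, n, n) float32
        out[:, col : col + L] = U1.mean(axis=(2, 3), dtype=np.float64)
        col += L
        if m < 2 or j1 == J - 1:
            continue
        k = bank["subs"][j1]
        psi_s = bank["psi_at"][k]  # (J, L, n/k, n/k)
        for t1 in range(L):
            U1_hat = _periodize(_fft.fft2(U1[:, t1]), k)  # (F, n/k, n/k)
            base = s2_cols[(j1, t1)]
            for i2, j2 in enumerate(range(j1 + 1, J)):
                conv2 = _fft.ifft2(U1_hat[:, None] * psi_s[j2][None])
                out[:, base + i2 * L : base + (i2 + 1) * L] = np.abs(conv2).mean(
                    axis=(2, 3), dtype=np.float64
                )
    return out


def video_scattering_feature(
    video: FCFMVideo, config: ScatteringConfig | None = None
) -> VideoFeature:
    """Elementwise mean of per-frame scattering coefficients over on-target frames."""
    config = config or ScatteringConfig()
    frames = on_target_frames(video)
    squares = np.stack(
        [central_square(f, config.resize_to, config.equalize) for f in frames]
    )
    coeffs = scattering_batch(squares, config)
    return VideoFeature(
        patient_id=video.patient_id, scheme="scattering", vector=coeffs.mean(axis=0)
    )
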
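"""Synthetic FCFM-like cohorts with known ground truth.

Real FCFM video of lung parenchyma shows bright curvilinear elastin/collagen
fibres (autofluorescence) over a dark background, inside a circular fibre-bundle
field of view, with drastically different dynamic ranges between videos. The
study cohort this emulates is not publicly deposited, so every downstream stage
(feature extraction, classification, fusion, evaluation) is exercised on
cohorts from this generator.

The generative model:

* **Fibre texture** — each frame is a superposition of persistent random walks
  (von Mises turning angles; the concentration parameter is the orientation
  *coherence*), rasterized and Gaussian-blurred to a configurable fibre width,
  plus additive Gaussian noise clipped at zero; pixels outside the inscribed
  circle are zero.
* **Class effect** — a single dimensionless effect size ``texture_effect``
  (δ) shifts the three texture parameters (fibre density, width, coherence)
  jointly by ±δ/2 of their between-video SD according to the malignancy label.
  δ = 0 makes benign and malignant textures exchangeable.
* **Dynamic range** — a per-video gain/offset drawn uniformly from configured
  ranges, applied after texture synthesis, reproduces the cross-video
  dynamic-range variability of real FCFM.
* **Clinical coupling** — 12 clinical/radiological covariates are drawn from
  physiologic ranges; labels are Bernoulli with a Mayo-style linear predictor
  (standardized, scaled by ``clinical_effect``) whose intercept is solved
  numerically so the expected prevalence matches the configured one. This makes
  the published risk calculators genuinely better than chance on synthetic
  cohorts, as in a real clinic population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit

from .io import (
    ClinicalRecord,
    FCFMVideo,
    clinical_to_frame,
    write_clinical_csv,
    write_segments_csv,
    write_truth_meta,
    write_video_tiff,
)

DEFAULT_PREVALENCE = 25 / 91  # malignant fraction of the emulated cohort

#: baseline texture parameters (benign/malignant midpoint) and their
#: between-video standard deviations, in which the effect size δ is expressed
TEXTURE_BASE = {"fibre_density": 1.2, "fibre_width": 2.2, "coherence": 8.0}
TEXTURE_SD = {"fibre_density": 0.25, "fibre_width": 0.35, "coherence": 1.6}
#: within-class video-to-video jitter, as a fraction of the SD above
WITHIN_CLASS_JITTER = 0.5


class SyntheticConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass
class SyntheticConfig:
    """Configuration of a synthetic cohort.

    Defaults are the test scale (128 px frames, ~20 on-target frames per
    video); :meth:`paper_scale` returns the full-scale configuration
    (500 px frames, log-normal frame counts with quartiles near 97/159/219).
    """

    n_patients: int = 91
    prevalence: float = DEFAULT_PREVALENCE
    frame_size: int = 128
    frames_median: float = 20.0
    frames_sigma: float = 0.35  # log-normal shape; 0 = fixed count
    texture_effect: float = 1.0  # δ, in units of the texture-parameter SD
    clinical_effect: float = 1.0  # scale of the clinical linear predictor
    gain_range: tuple[float, float] = (0.5, 1.6)
    offset_range: tuple[float, float] = (0.0, 0.12)
    noise_sigma: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise SyntheticConfigError("prevalence must be in (0, 1)")
        if self.texture_effect < 0:
            raise SyntheticConfigError("texture_effect must be >= 0")
        if self.frame_size < 32:
            raise SyntheticConfigError("frame_size must be >= 32")
        if self.frames_median < 1 or self.frames_sigma < 0:
            raise SyntheticConfigError("invalid frames-per-video distribution")
        if not (self.gain_range[0] <= self.gain_range[1]) or self.gain_range[0] <= 0:
            raise SyntheticConfigError("invalid gain_range")
        if not (self.offset_range[0] <= self.offset_range[1]) or self.offset_range[0] < 0:
            raise SyntheticConfigError("invalid offset_range")

    @classmethod
    def paper_scale(cls, **overrides) -> "SyntheticConfig":
        """Full-scale configuration: 500 px frames, median 159 frames/video.

        The log-normal shape 0.6 reproduces frame-count quartiles near
        97/159/219 (the asymmetric quartiles of the emulated cohort).
        """
        kw = dict(frame_size=500, frames_median=159.0, frames_sigma=0.6)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SyntheticCohort:
    """A generated cohort: videos, clinical records, labels, and truth metadata."""

    videos: list[FCFMVideo]
    clinical: list[ClinicalRecord]
    labels: np.ndarray  # 1 = malignant
    truth_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [v.patient_id for v in self.videos]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids are not unique")
        if not (len(self.videos) == len(self.clinical) == len(self.labels)):
            raise ValueError("one clinical record and one label per video required")
        for v in self.videos:
            if v.on_target_indices.size == 0:
                raise ValueError(f"{v.patient_id}: no on-target frames")

    @property
    def patient_ids(self) -> list[str]:
        return [v.patient_id for v in self.videos]

    def clinical_matrix(self) -> np.ndarray:
        return np.stack([r.as_feature_vector() for r in self.clinical])


# ---------------------------------------------------------------------------
# frame synthesis
# ---------------------------------------------------------------------------

def generate_frame(
    texture_params: dict,
    frame_size: int,
    rng: np.random.Generator,
    noise_sigma: float = 0.06,
) -> np.ndarray:
    """Render one circular-FOV frame of fibrous texture.

    ``texture_params`` holds ``fibre_density`` (fibres per 1000 px² of FOV),
    ``fibre_width`` (px, the Gaussian blur FWHM-ish scale) and ``coherence``
    (von Mises concentration of the turning angles; larger = straighter
    fibres). Returns a float array in roughly [0, ~1.5], exactly 0 outside the
    inscribed circle.
    """
    if frame_size < 32:
        raise SyntheticConfigError("frame_size must be >= 32")
    radius = frame_size / 2.0
    centre = (frame_size - 1) / 2.0
    area = np.pi * radius**2
    density = max(float(texture_params["fibre_density"]), 0.0)
    width = max(float(texture_params["fibre_width"]), 0.5)
    kappa = max(float(texture_params["coherence"]), 1e-3)

    canvas = np.zeros((frame_size, frame_size), dtype=float)
    n_fibres = rng.poisson(density * area / 1000.0)
    for _ in range(n_fibres):
        # start uniformly inside the disk
        r = radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        y0, x0 = centre + r * np.sin(phi), centre + r * np.cos(phi)
        n_steps = int(rng.uniform(0.4, 1.0) * frame_size)
        turns = rng.vonmises(0.0, kappa, size=n_steps)
        heading = rng.uniform(0, 2 * np.pi) + np.cumsum(turns)
        ys = y0 + np.cumsum(np.sin(heading))
        xs = x0 + np.cumsum(np.cos(heading))
        keep = (ys >= 0) & (ys < frame_size) & (xs >= 0) & (xs < frame_size)
        if not keep.any():
            continue
        brightness = rng.uniform(0.8, 1.2)
        np.add.at(canvas, (ys[keep].astype(int), xs[keep].astype(int)), brightness)

    canvas = gaussian_filter(canvas, sigma=width / 2.0)
    if canvas.max() > 0:
        canvas *= 0.9 / max(canvas.max(), 1e-12)
    canvas += rng.normal(0.0, noise_sigma, canvas.shape)
    np.clip(canvas, 0.0, None, out=canvas)

    yy, xx = np.ogrid[:frame_size, :frame_size]
    inside = (yy - centre) ** 2 + (xx - centre) ** 2 <= radius**2
    canvas[~inside] = 0.0
    return canvas


def _video_texture_params(label: int, delta: float, rng: np.random.Generator) -> dict:
    """Per-video texture parameters: class shift ±δ/2·SD plus within-class jitter."""
    sign = +0.5 if label == 1 else -0.5
    params = {}
    for k, base in TEXTURE_BASE.items():
        sd = TEXTURE_SD[k]
        val = base + sign * delta * sd + rng.normal(0.0, WITHIN_CLASS_JITTER * sd)
        params[k] = max(val, 0.05)
    return params


# ---------------------------------------------------------------------------
# clinical synthesis
# ---------------------------------------------------------------------------

_MAYO_STYLE = {  # linear-predictor weights used for label coupling
    "age": 0.0391,
    "smoker": 0.7917,
    "previous_extrathoracic_cancer": 1.3388,
    "nodule_size": 0.1274,
    "spiculation": 1.0407,
    "upper_lobe": 0.7838,
}


def generate_clinical(
    patient_id: str, rng: np.random.Generator, label: int | None = None
) -> ClinicalRecord:
    """Draw one patient's 12 covariates from physiologic ranges.

    The label is attached afterwards by :func:`generate_cohort`, which couples
    labels to covariates through the cohort-level linear predictor.
    """
    smoker = int(rng.uniform() < 0.8)
    nodule_type = rng.choice(["solid", "part-solid", "non-solid"], p=[0.8, 0.12, 0.08])
    return ClinicalRecord(
        patient_id=patient_id,
        age=float(np.clip(rng.normal(67, 9), 35, 90)),
        sex=int(rng.uniform() < 0.5),
        smoker=smoker,
        smoking_pack_years=float(smoker * max(rng.normal(32, 18), 0.0)),
        previous_extrathoracic_cancer=int(rng.uniform() < 0.15),
        family_history=int(rng.uniform() < 0.2),
        nodule_size=float(np.clip(rng.lognormal(np.log(12.0), 0.4), 4.0, 30.0)),
        nodule_count=int(1 + rng.poisson(0.8)),
        upper_lobe=int(rng.uniform() < 0.55),
        spiculation=int(rng.uniform() < 0.25),
        nodule_type=str(nodule_type),
        emphysema=int(rng.uniform() < 0.35),
        label=label,
    )


def _clinical_linear_predictor(records: list[ClinicalRecord]) -> np.ndarray:
    """Standardized Mayo-style risk score per patient (mean 0, SD 1)."""
    lp = np.array(
        [sum(w * float(getattr(r, k)) for k, w in _MAYO_STYLE.items()) for r in records]
    )
    sd = lp.std()
    return (lp - lp.mean()) / sd if sd > 0 else np.zeros_like(lp)


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept b0 with mean(expit(b0 + eta)) == prevalence."""
    f = lambda b0: expit(b0 + eta).mean() - prevalence
    return brentq(f, -30.0, 30.0)


# ---------------------------------------------------------------------------
# cohort synthesis
# ---------------------------------------------------------------------------

def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full cohort: videos + clinical records + coupled labels.

    Labels are Bernoulli(logistic(b0 + clinical_effect·η)) where η is the
    standardized Mayo-style score of the drawn covariates, so the expected
    malignant count equals ``n_patients * prevalence``. Texture parameters are
    then shifted by ±δ/2 according to the label, and a per-video gain/offset
    is applied after synthesis.
    """
    rng = np.random.default_rng(config.seed)
    ids = [f"P{i:03d}" for i in range(config.n_patients)]
    records = [generate_clinical(pid, rng) for pid in ids]
    eta = config.clinical_effect * _clinical_linear_predictor(records)
    b0 = _solve_intercept(eta, config.prevalence)
    labels = (rng.uniform(size=config.n_patients) < expit(b0 + eta)).astype(int)
    for r, y in zip(records, labels):
        r.label = int(y)

    videos, meta = [], {}
    for pid, y in zip(ids, labels):
        params = _video_texture_params(int(y), config.texture_effect, rng)
        if config.frames_sigma > 0:
            n_on = int(round(rng.lognormal(np.log(config.frames_median), config.frames_sigma)))
        else:
            n_on = int(round(config.frames_median))
        n_on = max(n_on, 3)
        gain = rng.uniform(*config.gain_range)
        offset = rng.uniform(*config.offset_range)

        # one or two on-target segments, separated by an off-target noise frame
        n_segments = 1 if n_on < 6 else int(rng.integers(1, 3))
        frames, segments, cursor = [], [], 0
        split = n_on // 2 if n_segments == 2 else n_on
        for si, seg_len in enumerate([split, n_on - split][:n_segments]):
            if si > 0:  # off-target gap frame: structureless noise
                gap = generate_frame(
                    {"fibre_density": 0.0, "fibre_width": 1.0, "coherence": 1.0},
                    config.frame_size, rng, config.noise_sigma,
                )
                frames.append(gap)
                cursor += 1
            start = cursor
            for _ in range(seg_len):
                frames.append(
                    generate_frame(params, config.frame_size, rng, config.noise_sigma)
                )
            cursor += seg_len
            segments.append((start, cursor))

        stack = np.stack(frames)
        stack = gain * stack + offset
        stack[:, ~_disk(config.frame_size)] = 0.0
        # quantize to uint16, emulating the detector's integer intensities
        stack = np.clip(stack * 10000.0, 0, 65535).astype(np.uint16)
        videos.append(FCFMVideo(patient_id=pid, frames=stack, segments=segments))
        meta[pid] = {
            "label": int(y),
            "gain": gain,
            "offset": offset,
            "n_on_target": n_on,
            **params,
        }

    return SyntheticCohort(
        videos=videos,
        clinical=records,
        labels=labels,
        truth_meta={"config": config.__dict__.copy() | {
            "gain_range": list(config.gain_range),
            "offset_range": list(config.offset_range)}, "videos": meta},
    )


def _disk(frame_size: int) -> np.ndarray:
    centre = (frame_size - 1) / 2.0
    yy, xx = np.ogrid[:frame_size, :frame_size]
    return (yy - centre) ** 2 + (xx - centre) ** 2 <= (frame_size / 2.0) ** 2


def simulate_expert_annotation(
    labels: np.ndarray,
    rng: np.random.Generator,
    sensitivity: float = 0.6,
    specificity: float = 0.6,
    availability: float = 83 / 91,
) -> np.ndarray:
    """Simulated blinded-expert benign/malignant call per video.

    Returns a float array: 1/0 where the expert annotated, NaN where the video
    was uninterpretable (a fraction ``1 - availability`` of videos, as when an
    expert can only annotate 83 of 91). Default sensitivity/specificity are
    modest — real FCFM texture is hard to call by eye.
    """
    labels = np.asarray(labels)
    ann = np.where(
        labels == 1,
        rng.uniform(size=labels.size) < sensitivity,
        rng.uniform(size=labels.size) >= specificity,
    ).astype(float)
    missing = rng.uniform(size=labels.size) >= availability
    ann[missing] = np.nan
    return ann


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort to disk: per-patient multi-page TIFF, segments CSV,
    clinical CSV, truth-meta JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for v in cohort.videos:
        write_video_tiff(v, out / f"{v.patient_id}.tiff")
    write_segments_csv(cohort.videos, out / "segments.csv")
    write_clinical_csv(cohort.clinical, out / "clinical.csv")
    write_truth_meta(cohort.truth_meta, out / "truth_meta.json")


def cohort_clinical_frame(cohort: SyntheticCohort):
    return clinical_to_frame(cohort.clinical)
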
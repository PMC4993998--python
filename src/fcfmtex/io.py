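"""Data model and I/O for FCFM videos, on-target segments, clinical records and features.

FCFM (fibered confocal fluorescence microscopy) frames are circular: the fibre
bundle images a disk, stored inside an enclosing square (about 500x500 px on the
Cellvizio system; smaller for synthetic test data). Only manually annotated
*on-target* frame segments — where the fibre tip is at the nodule — enter
feature extraction. Segments are 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: canonical clinical covariate order (12 predictors)
CLINICAL_COLUMNS = [
    "age",
    "sex",  # 1 = female, 0 = male
    "smoker",
    "smoking_pack_years",
    "previous_extrathoracic_cancer",
    "family_history",
    "nodule_size",  # maximal axial diameter, mm
    "nodule_count",
    "upper_lobe",
    "spiculation",
    "nodule_type",  # 0 = solid, 1 = part-solid, 2 = non-solid
    "emphysema",
]

NODULE_TYPES = {"solid": 0, "part-solid": 1, "non-solid": 2}

FEATURE_DIMS = {"lbp": 80, "bow": 1024, "scattering": 1401}


class VideoIOError(ValueError):
    """Raised for malformed video stacks or segment tables."""


def fov_mask(shape: tuple[int, int]) -> np.ndarray:
    """Boolean disk mask of the circular field of view for a frame shape.

    The disk is centred on the frame centre with radius ``floor(min(side)/2)``;
    a pixel is inside if its centre is at distance <= radius.
    """
    h, w = shape
    radius = min(h, w) // 2
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


@dataclass
class FCFMVideo:
    """One patient's FCFM video: frame stack + on-target segment annotations.

    Parameters
    ----------
    patient_id : str
    frames : ndarray, shape (n_frames, h, w)
        Nonnegative grayscale intensities, one dtype for the whole stack.
    segments : list of (start, end)
        Disjoint on-target frame-index ranges, 0-based half-open.
    """

    patient_id: str
    frames: np.ndarray
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise VideoIOError(
                f"{self.patient_id}: expected a (n, h, w) grayscale stack, "
                f"got ndim={self.frames.ndim} (multi-channel input is rejected)"
            )
        if self.frames.shape[0] == 0:
            raise VideoIOError(f"{self.patient_id}: empty frame stack")
        n = self.frames.shape[0]
        self.segments = [(int(s), int(e)) for s, e in self.segments]
        for s, e in self.segments:
            if not (0 <= s < e <= n):
                raise VideoIOError(
                    f"{self.patient_id}: segment ({s}, {e}) out of range for "
                    f"{n}-frame video"
                )
        order = sorted(self.segments)
        for (s1, e1), (s2, e2) in zip(order, order[1:]):
            if s2 < e1:
                raise VideoIOError(
                    f"{self.patient_id}: overlapping segments ({s1},{e1}) and ({s2},{e2})"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def fov_mask(self) -> np.ndarray:
        return fov_mask(self.frame_shape)

    @property
    def on_target_indices(self) -> np.ndarray:
        """Sorted frame indices covered by any on-target segment."""
        idx: list[int] = []
        for s, e in sorted(self.segments):
            idx.extend(range(s, e))
        return np.asarray(idx, dtype=int)


def on_target_frames(video: FCFMVideo) -> np.ndarray:
    """On-target frames of a video, concatenated in frame-index order.

    Raises
    ------
    VideoIOError
        If the video has no on-target frames (such videos must be excluded
        upstream, mirroring the exclusion of not-reached nodules).
    """
    idx = video.on_target_indices
    if idx.size == 0:
        raise VideoIOError(f"{video.patient_id}: no on-target frames")
    return video.frames[idx]


@dataclass
class ClinicalRecord:
    """The 12 clinical/radiological predictors for one patient.

    ``sex`` is 1 for female (the Brock model's coding); ``nodule_type`` is one
    of ``solid`` / ``part-solid`` / ``non-solid``. ``label`` (1 = malignant) is
    optional at prediction time.
    """

    patient_id: str
    age: float
    sex: int
    smoker: int
    smoking_pack_years: float
    previous_extrathoracic_cancer: int
    family_history: int
    nodule_size: float
    nodule_count: int
    upper_lobe: int
    spiculation: int
    nodule_type: str
    emphysema: int
    label: int | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not (0 < self.nodule_size <= 30):
            raise ValueError("nodule_size must be in (0, 30] mm")
        if self.nodule_type not in NODULE_TYPES:
            raise ValueError(f"unknown nodule_type {self.nodule_type!r}")
        for f in ("sex", "smoker", "previous_extrathoracic_cancer",
                  "family_history", "upper_lobe", "spiculation", "emphysema"):
            if getattr(self, f) not in (0, 1):
                raise ValueError(f"{f} must be 0 or 1")

    def as_feature_vector(self) -> np.ndarray:
        """Numeric 12-vector in ``CLINICAL_COLUMNS`` order (nodule_type coded 0/1/2)."""
        vals = []
        for c in CLINICAL_COLUMNS:
            v = getattr(self, c)
            vals.append(NODULE_TYPES[v] if c == "nodule_type" else float(v))
        return np.asarray(vals, dtype=float)


@dataclass
class VideoFeature:
    """One fixed-length feature vector for one video under one scheme."""

    patient_id: str
    scheme: str  # lbp | bow | scattering
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.scheme in FEATURE_DIMS and self.vector.ndim != 1:
            raise ValueError("feature vector must be 1-D")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_video_tiff(video: FCFMVideo, path: str | Path) -> None:
    """Write the frame stack as a multi-page TIFF (one file per patient)."""
    tifffile.imwrite(str(path), video.frames, photometric="minisblack")


def read_frames(frames_path: str | Path) -> np.ndarray:
    """Read a frame stack from a multi-page TIFF file or a directory of PNGs.

    PNG sequences are read in lexicographic filename order.
    """
    frames_path = Path(frames_path)
    if frames_path.is_dir():
        import imageio.v3 as iio

        files = sorted(frames_path.glob("*.png"))
        if not files:
            raise VideoIOError(f"no PNG frames in {frames_path}")
        frames = [iio.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise VideoIOError(f"frame shape mismatch in {frames_path}: {shapes}")
        arr = np.stack(frames)
    else:
        arr = tifffile.imread(str(frames_path))
        if arr.ndim == 2:
            arr = arr[None]
    if arr.ndim != 3:
        raise VideoIOError(
            f"{frames_path}: expected grayscale frames, got shape {arr.shape}"
        )
    return arr


def load_video(
    frames_path: str | Path,
    segments_table: pd.DataFrame,
    patient_id: str,
) -> FCFMVideo | None:
    """Load one patient's video, attaching its on-target segments.

    ``segments_table`` has columns ``patient_id, segment_start, segment_end``
    (0-based, half-open). A patient absent from the table is excluded: returns
    ``None`` with a logged warning (videos whose nodule was never reached carry
    no usable signal).
    """
    rows = segments_table[segments_table["patient_id"].astype(str) == str(patient_id)]
    if rows.empty:
        logger.warning("patient %s has no on-target segments; video excluded", patient_id)
        warnings.warn(f"patient {patient_id} has no on-target segments; excluded")
        return None
    frames = read_frames(frames_path)
    segs = [(int(r.segment_start), int(r.segment_end)) for r in rows.itertuples()]
    return FCFMVideo(patient_id=str(patient_id), frames=frames, segments=segs)


def write_segments_csv(videos: list[FCFMVideo], path: str | Path) -> None:
    rows = [
        {"patient_id": v.patient_id, "segment_start": s, "segment_end": e}
        for v in videos
        for s, e in v.segments
    ]
    pd.DataFrame(rows, columns=["patient_id", "segment_start", "segment_end"]).to_csv(
        path, index=False
    )


def read_segments_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {"patient_id": r.patient_id}
        d.update({c: getattr(r, c) for c in CLINICAL_COLUMNS})
        d["label"] = r.label
        rows.append(d)
    return pd.DataFrame(rows)


def clinical_from_frame(df: pd.DataFrame) -> list[ClinicalRecord]:
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        label = d.pop("label", None)
        if label is not None and not pd.isna(label):
            label = int(label)
        else:
            label = None
        records.append(ClinicalRecord(label=label, **{k: d[k] for k in ["patient_id"] + CLINICAL_COLUMNS}))
    return records


def write_clinical_csv(records: list[ClinicalRecord], path: str | Path) -> None:
    clinical_to_frame(records).to_csv(path, index=False)


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    return clinical_from_frame(pd.read_csv(path))


def write_features_tsv(features: list[VideoFeature], path: str | Path) -> None:
    """Write features as TSV: patient_id, scheme, v0..v_{d-1}."""
    if not features:
        raise ValueError("no features to write")
    d = features[0].vector.size
    cols = ["patient_id", "scheme"] + [f"v{i}" for i in range(d)]
    rows = []
    for f in features:
        if f.vector.size != d:
            raise ValueError("mixed feature dimensions in one table")
        rows.append([f.patient_id, f.scheme] + f.vector.tolist())
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_features_tsv(path: str | Path) -> list[VideoFeature]:
    df = pd.read_csv(path, sep="\t")
    vcols = [c for c in df.columns if c.startswith("v")]
    return [
        VideoFeature(
            patient_id=str(r["patient_id"]),
            scheme=str(r["scheme"]),
            vector=r[vcols].to_numpy(dtype=float),
        )
        for _, r in df.iterrows()
    ]


def feature_matrix(features: list[VideoFeature]) -> tuple[np.ndarray, list[str]]:
    """Stack per-video features into (n, d), returning patient ids in row order."""
    X = np.stack([f.vector for f in features])
    return X, [f.patient_id for f in features]


def write_truth_meta(meta: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1, default=float)
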
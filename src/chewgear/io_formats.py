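"""File dialects and in-memory containers for marker motion data.

Marker CSVs follow the XMALab 3D-points export convention: one row per video
frame and one ``<marker>_X, <marker>_Y, <marker>_Z`` column triplet per
marker, coordinates in millimetres.  Blank cells mark frames on which a
marker could not be digitised (occluded); they are carried through as NaN and
handled downstream (short gaps are linearly interpolated before filtering).

Landmark CSVs are plain ``name,x,y,z`` tables holding CT-derived points
(coronoid tips, gonial angles) expressed in the reference-pose coordinate
system of the marker data.

The long-format results table is the tidy interchange between the kinematics
pipeline and the statistics layer: one row per
(subject, food, cycle, %cycle, variable) observation.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MarkerDataset",
    "LandmarkSet",
    "AnatomicalFrame",
    "PipelineConfig",
    "MarkerFormatError",
    "read_marker_csv",
    "write_marker_csv",
    "read_landmarks",
    "write_landmarks",
    "write_long_table",
    "read_long_table",
]

_AXES = ("X", "Y", "Z")


class MarkerFormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


@dataclass
class MarkerDataset:
    """Named 3-D marker trajectories sampled at a fixed frame rate.

    ``markers`` maps marker name to an ``(n_frames, 3)`` float array in mm.
    Occluded frames are rows of NaN.  ``coordinate_frame_tag`` records which
    coordinate system positions live in (``"lab"`` for raw digitised data,
    ``"cranial"`` once the cranial reference frame has been fixed).
    """

    markers: dict[str, np.ndarray]
    frame_rate: float = 150.0
    coordinate_frame_tag: str = "lab"

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        n = None
        for name, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {name!r}: expected (n_frames, 3) array, got {arr.shape}")
            if np.isinf(arr).any():
                raise ValueError(f"marker {name!r}: positions must be finite or NaN")
            self.markers[name] = arr
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError(
                    f"marker {name!r} has {arr.shape[0]} frames, expected {n}"
                )

    @property
    def n_frames(self) -> int:
        if not self.markers:
            return 0
        return next(iter(self.markers.values())).shape[0]

    @property
    def marker_names(self) -> list[str]:
        return list(self.markers)

    def positions(self, name: str) -> np.ndarray:
        try:
            return self.markers[name]
        except KeyError:
            raise KeyError(
                f"marker {name!r} not in dataset (have {sorted(self.markers)})"
            ) from None

    def missing_mask(self, name: str) -> np.ndarray:
        """Boolean mask, True on frames where the marker is missing."""
        return np.isnan(self.positions(name)).any(axis=1)

    def copy(self) -> "MarkerDataset":
        return MarkerDataset(
            {k: v.copy() for k, v in self.markers.items()},
            frame_rate=self.frame_rate,
            coordinate_frame_tag=self.coordinate_frame_tag,
        )


@dataclass
class LandmarkSet:
    """Named CT-derived 3-D points (mm) in the reference-pose coordinates."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.isfinite(p).all():
                raise ValueError(f"landmark {name!r}: coordinates must be finite")
            self.points[name] = p

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def names(self) -> list[str]:
        return list(self.points)


@dataclass
class AnatomicalFrame:
    """Anatomical coordinate axes used to define sagittal and coronal planes.

    The sagittal plane is spanned by the anteroposterior (AP) and
    superoinferior (SI) axes; the coronal plane by the mediolateral (ML) and
    SI axes.  Axes must be unit length, pairwise orthogonal, and oriented so
    that (AP, ML, SI) is a right-handed triad.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_ap: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    axis_ml: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    axis_si: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        for attr in ("axis_ap", "axis_ml", "axis_si"):
            v = np.asarray(getattr(self, attr), dtype=float).reshape(3)
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError(f"{attr} must be unit length")
            setattr(self, attr, v)
        for a, b in (("axis_ap", "axis_ml"), ("axis_ap", "axis_si"), ("axis_ml", "axis_si")):
            if abs(np.dot(getattr(self, a), getattr(self, b))) > 1e-8:
                raise ValueError(f"{a} and {b} must be orthogonal")
        m = np.stack([self.axis_ap, self.axis_ml, self.axis_si])
        if np.linalg.det(m) < 0:
            raise ValueError("(AP, ML, SI) must form a right-handed triad")

    def components(self, vectors: np.ndarray) -> np.ndarray:
        """Project row vectors onto (AP, ML, SI) components."""
        v = np.atleast_2d(np.asarray(vectors, dtype=float))
        basis = np.stack([self.axis_ap, self.axis_ml, self.axis_si], axis=1)
        return v @ basis


@dataclass
class PipelineConfig:
    """Everything the processing pipeline needs beyond the raw files.

    Marker roles map anatomical roles onto marker names as exported from the
    digitising software; filter / smoothing / standardisation settings default
    to the recording conventions of the study design this package targets
    (150 fps, 30 Hz low-pass, 25% LOESS span, 50-frame standardised cycles).
    """

    cranial: tuple[str, ...] = ("cran1", "cran2", "cran3", "cran4")
    mandibular: tuple[str, ...] = ("mand_ant", "mand2", "mand3", "mand4")
    anterior_mandible: str = "mand_ant"
    cmj_marker: str = "m1"              # central myotendinous junction
    superficial_marker: str = "m2"      # superficial fascicle termination
    attachment_marker: str = "m3"       # superior attachment of the muscle
    coronoid_landmark: str = "coronoid_R"
    frame: AnatomicalFrame = field(default_factory=AnatomicalFrame)
    frame_rate: float = 150.0
    filter_cutoff_hz: float = 30.0
    filter_order: int = 4
    loess_span: float = 0.25
    n_standard: int = 50
    agr_epsilon_frac: float = 0.02
    min_prominence_frac: float = 0.2
    max_gap_frames: int = 5
    reference_frame: int | None = None
    occlusion_frame: int | None = None
    subject: str | None = None
    food: str | None = None

    def __post_init__(self) -> None:
        self.cranial = tuple(self.cranial)
        self.mandibular = tuple(self.mandibular)
        if self.filter_cutoff_hz >= self.frame_rate / 2:
            raise ValueError(
                f"filter cutoff {self.filter_cutoff_hz} Hz must be below the "
                f"Nyquist frequency {self.frame_rate / 2} Hz"
            )
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        if self.n_standard < 2:
            raise ValueError("n_standard must be at least 2")

    def bone_roles(self) -> tuple[str, ...]:
        return self.cranial + self.mandibular

    def validate_roles(self, dataset: MarkerDataset) -> None:
        """Check that every configured role resolves to a dataset marker."""
        needed = set(self.bone_roles()) | {
            self.anterior_mandible,
            self.cmj_marker,
            self.superficial_marker,
            self.attachment_marker,
        }
        missing = sorted(needed - set(dataset.marker_names))
        if missing:
            raise MarkerFormatError(f"config roles missing from dataset: {missing}")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "markers": {
                "cranial": list(self.cranial),
                "mandibular": list(self.mandibular),
                "anterior_mandible": self.anterior_mandible,
                "cmj": self.cmj_marker,
                "superficial": self.superficial_marker,
                "attachment": self.attachment_marker,
            },
            "landmarks": {"coronoid": self.coronoid_landmark},
            "frame": {
                "origin": self.frame.origin.tolist(),
                "axis_ap": self.frame.axis_ap.tolist(),
                "axis_ml": self.frame.axis_ml.tolist(),
                "axis_si": self.frame.axis_si.tolist(),
            },
            "frame_rate": self.frame_rate,
            "filter": {"cutoff_hz": self.filter_cutoff_hz, "order": self.filter_order},
            "loess_span": self.loess_span,
            "n_standard": self.n_standard,
            "agr_epsilon_frac": self.agr_epsilon_frac,
            "min_prominence_frac": self.min_prominence_frac,
            "max_gap_frames": self.max_gap_frames,
            "reference_frame": self.reference_frame,
            "occlusion_frame": self.occlusion_frame,
            "subject": self.subject,
            "food": self.food,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        markers = d.get("markers", {})
        frame_d = d.get("frame", {})
        filt = d.get("filter", {})
        kwargs = dict(
            cranial=tuple(markers.get("cranial", cls.cranial)),
            mandibular=tuple(markers.get("mandibular", cls.mandibular)),
            anterior_mandible=markers.get("anterior_mandible", cls.anterior_mandible),
            cmj_marker=markers.get("cmj", cls.cmj_marker),
            superficial_marker=markers.get("superficial", cls.superficial_marker),
            attachment_marker=markers.get("attachment", cls.attachment_marker),
            coronoid_landmark=d.get("landmarks", {}).get("coronoid", cls.coronoid_landmark),
            frame=AnatomicalFrame(
                origin=frame_d.get("origin", (0.0, 0.0, 0.0)),
                axis_ap=frame_d.get("axis_ap", (1.0, 0.0, 0.0)),
                axis_ml=frame_d.get("axis_ml", (0.0, 1.0, 0.0)),
                axis_si=frame_d.get("axis_si", (0.0, 0.0, 1.0)),
            ),
            frame_rate=float(d.get("frame_rate", 150.0)),
            filter_cutoff_hz=float(filt.get("cutoff_hz", 30.0)),
            filter_order=int(filt.get("order", 4)),
            loess_span=float(d.get("loess_span", 0.25)),
            n_standard=int(d.get("n_standard", 50)),
            agr_epsilon_frac=float(d.get("agr_epsilon_frac", 0.02)),
            min_prominence_frac=float(d.get("min_prominence_frac", 0.2)),
            max_gap_frames=int(d.get("max_gap_frames", 5)),
            reference_frame=d.get("reference_frame"),
            occlusion_frame=d.get("occlusion_frame"),
            subject=d.get("subject"),
            food=d.get("food"),
        )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# marker CSV
# ---------------------------------------------------------------------------

def read_marker_csv(path: str | Path | io.StringIO, frame_rate: float = 150.0) -> MarkerDataset:
    """Read an XMALab-style 3D-points CSV into a :class:`MarkerDataset`.

    Columns are grouped into ``<name>_X/_Y/_Z`` triplets; column order is
    irrelevant.  Blank cells become NaN (occluded frames).  A marker with an
    incomplete triplet raises :class:`MarkerFormatError` naming the missing
    column; a non-numeric cell raises a parse error with its row number.
    """
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise MarkerFormatError("marker CSV is empty") from None
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise MarkerFormatError("marker CSV contains no data rows")

    groups: dict[str, dict[str, str]] = {}
    for col in df.columns:
        col_s = col.strip()
        if "_" not in col_s:
            raise MarkerFormatError(f"column {col!r} is not of the form <marker>_X/_Y/_Z")
        name, axis = col_s.rsplit("_", 1)
        axis = axis.upper()
        if axis not in _AXES:
            raise MarkerFormatError(f"column {col!r} has unknown axis suffix {axis!r}")
        groups.setdefault(name, {})[axis] = col

    markers: dict[str, np.ndarray] = {}
    for name, cols in groups.items():
        for axis in _AXES:
            if axis not in cols:
                raise MarkerFormatError(f"marker {name!r} is missing column {name}_{axis}")
        triplet = []
        for axis in _AXES:
            raw = df[cols[axis]]
            num = pd.to_numeric(raw, errors="coerce")
            bad = num.isna() & raw.notna() & (raw.str.strip() != "")
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise MarkerFormatError(
                    f"non-numeric value {raw.iloc[row]!r} in column {cols[axis]!r}, "
                    f"data row {row}"
                )
            triplet.append(num.to_numpy(dtype=float))
        markers[name] = np.column_stack(triplet)

    return MarkerDataset(markers, frame_rate=frame_rate)


def write_marker_csv(dataset: MarkerDataset, path: str | Path) -> None:
    """Write a dataset back out in the marker CSV dialect (NaN -> blank)."""
    cols = {}
    for name, arr in dataset.markers.items():
        for i, axis in enumerate(_AXES):
            cols[f"{name}_{axis}"] = arr[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path | io.StringIO) -> LandmarkSet:
    """Read a ``name,x,y,z`` landmark CSV; an empty file yields an empty set."""
    try:
        df = pd.read_csv(path, header=None, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        return LandmarkSet({})
    # tolerate an optional header row
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if first[:1] == ["name"]:
        df = df.iloc[1:]
    if df.shape[0] == 0:
        return LandmarkSet({})
    points: dict[str, np.ndarray] = {}
    for i, row in df.iterrows():
        vals = [v for v in row.tolist() if v is not None and not (isinstance(v, float) and math.isnan(v))]
        if len(vals) < 4:
            raise MarkerFormatError(f"landmark row {i}: need name plus 3 coordinates, got {vals}")
        name = str(vals[0]).strip()
        if name in points:
            raise MarkerFormatError(f"duplicate landmark name {name!r}")
        try:
            xyz = np.array([float(v) for v in vals[1:4]])
        except ValueError:
            raise MarkerFormatError(f"landmark row {i}: non-numeric coordinate in {vals[1:4]}") from None
        points[name] = xyz
    return LandmarkSet(points)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name,x,y,z\n")
        for name, p in landmarks.points.items():
            fh.write(f"{name},{float(p[0])!r},{float(p[1])!r},{float(p[2])!r}\n")


# ---------------------------------------------------------------------------
# long-format results table
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["subject", "food", "cycle", "phase", "pct_cycle", "variable", "value"]


def write_long_table(records: pd.DataFrame | list[dict], path: str | Path) -> None:
    """Write tidy result rows to CSV.

    Non-finite values are written as empty cells so the file stays purely
    numeric for downstream tools.
    """
    df = pd.DataFrame(records)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long table records missing columns: {missing}")
    df = df[LONG_COLUMNS]
    df.to_csv(path, index=False, na_rep="")


def read_long_table(path: str | Path | io.StringIO) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise MarkerFormatError(f"long table missing columns: {missing}")
    return df
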
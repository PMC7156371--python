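"""Rigid-body kinematics: trajectory filtering, cranial-frame fixing,
per-frame mandibular transforms, landmark animation and gape distance.

The registration core is the Kabsch/SVD solution of the orthogonal
Procrustes problem: given paired point sets it returns the least-squares
rotation and translation, with the reflection case corrected so the rotation
is proper (det = +1).  Fixing the cranial markers "in space" is registration
of each frame's cranial cloud back onto its reference-frame configuration,
applied to every marker; mandibular motion is then expressed as per-frame
rigid transforms relative to the reference pose, which also animate the
CT-derived landmarks (e.g. the coronoid tip used for whole-muscle length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .io_formats import AnatomicalFrame, LandmarkSet, MarkerDataset

__all__ = [
    "RigidTransform",
    "GapeSeries",
    "DegenerateConfigurationError",
    "butterworth_lowpass",
    "fill_gaps",
    "filter_dataset",
    "fit_rigid_transform",
    "fix_cranial_frame",
    "mandible_transforms",
    "transform_landmarks",
    "find_occlusion_frame",
    "gape_distance",
]


class DegenerateConfigurationError(ValueError):
    """Raised when a marker configuration cannot define a rigid transform."""


@dataclass
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t`` (rotation mm-preserving)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-8:
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation matrix must be proper (det = +1)")
        self.rotation = R
        self.translation = t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass
class GapeSeries:
    """Per-frame gape distance (mm) relative to the maximum-occlusion pose."""

    values: np.ndarray
    frame_rate: float
    occlusion_frame: int
    occlusion_reference: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.occlusion_reference = np.asarray(self.occlusion_reference, dtype=float).reshape(3)
        finite = self.values[np.isfinite(self.values)]
        if (finite < -1e-9).any():
            raise ValueError("gape distances must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def butterworth_lowpass(
    series: np.ndarray,
    cutoff_hz: float,
    order: int = 4,
    frame_rate: float = 150.0,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Operates along axis 0 so a single coordinate series or an ``(n, 3)``
    trajectory can be filtered alike.  The two-pass scheme squares the
    magnitude response and cancels phase lag, so low-frequency peak timing is
    preserved; DC gain is exactly 1.  Edges are padded by reflection over
    ``3 * order`` samples.
    """
    x = np.asarray(series, dtype=float)
    if cutoff_hz >= frame_rate / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({frame_rate / 2} Hz)"
        )
    padlen = 3 * order
    if x.shape[0] <= padlen:
        raise ValueError(f"series too short to filter: {x.shape[0]} <= {padlen} samples")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values; fill gaps first")
    b, a = butter(order, cutoff_hz, btype="low", fs=frame_rate)
    return filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def fill_gaps(dataset: MarkerDataset, max_gap: int = 5) -> MarkerDataset:
    """Linearly interpolate occluded-marker gaps of at most ``max_gap`` frames.

    Longer gaps (and gaps touching the recording boundary) are left as NaN,
    to be excluded from cycle-level analysis downstream.
    """
    out = dataset.copy()
    for name, arr in out.markers.items():
        bad = np.isnan(arr).any(axis=1)
        if not bad.any():
            continue
        idx = np.flatnonzero(bad)
        # split into consecutive runs
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            lo, hi = run[0] - 1, run[-1] + 1
            if lo < 0 or hi >= arr.shape[0] or len(run) > max_gap:
                continue
            w = (run - lo) / (hi - lo)
            arr[run] = np.outer(1 - w, arr[lo]) + np.outer(w, arr[hi])
    return out


def filter_dataset(
    dataset: MarkerDataset,
    cutoff_hz: float = 30.0,
    order: int = 4,
) -> MarkerDataset:
    """Low-pass filter every marker coordinate independently.

    Frames still missing after gap interpolation split a trajectory into
    segments; each sufficiently long segment is filtered on its own and
    segments too short for the filter pad are left untouched.
    """
    out = dataset.copy()
    padlen = 3 * order
    for name, arr in out.markers.items():
        good = ~np.isnan(arr).any(axis=1)
        if good.all():
            out.markers[name] = butterworth_lowpass(arr, cutoff_hz, order, dataset.frame_rate)
            continue
        idx = np.flatnonzero(good)
        if idx.size == 0:
            continue
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            if len(run) > padlen:
                arr[run] = butterworth_lowpass(arr[run], cutoff_hz, order, dataset.frame_rate)
    return out


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _check_not_collinear(points: np.ndarray, context: str) -> None:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[0] <= 0 or s[1] / s[0] < 1e-8:
        raise DegenerateConfigurationError(f"{context}: points are collinear or coincident")


def fit_rigid_transform(reference_points: np.ndarray, frame_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping reference points onto frame points.

    Kabsch/SVD solution minimising ``sum ||R p_i + t - q_i||^2`` over proper
    rotations; a reflection in the raw SVD solution is corrected by flipping
    the smallest singular direction.
    """
    p = np.asarray(reference_points, dtype=float)
    q = np.asarray(frame_points, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"paired (n, 3) point sets required, got {p.shape} and {q.shape}")
    if p.shape[0] < 3:
        raise DegenerateConfigurationError(f"need >= 3 paired points, got {p.shape[0]}")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("points must be finite")
    _check_not_collinear(p, "reference points")

    pc, qc = p.mean(axis=0), q.mean(axis=0)
    H = (p - pc).T @ (q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return RigidTransform(R, t)


def registration_rmsd(transform: RigidTransform, reference_points: np.ndarray, frame_points: np.ndarray) -> float:
    """Root-mean-square residual of a fitted registration (mm)."""
    resid = transform.apply(reference_points) - np.asarray(frame_points, dtype=float)
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def fix_cranial_frame(
    dataset: MarkerDataset,
    cranial_roles: tuple[str, ...] | list[str],
    reference_frame_index: int = 0,
) -> MarkerDataset:
    """Register every frame so the cranial markers are stationary.

    For each frame a rigid transform is fitted from that frame's cranial
    marker cloud onto its reference-frame configuration and applied to all
    markers, removing whole-scene motion (subject repositioning, drift).
    Frames with fewer than three trackable cranial markers, or a degenerate
    cranial configuration, raise with the frame index.
    """
    roles = list(cranial_roles)
    ref = np.stack([dataset.positions(r)[reference_frame_index] for r in roles])
    if np.isnan(ref).any():
        raise DegenerateConfigurationError(
            f"cranial markers missing at reference frame {reference_frame_index}"
        )
    _check_not_collinear(ref, f"cranial markers at reference frame {reference_frame_index}")

    n = dataset.n_frames
    cranial = np.stack([dataset.positions(r) for r in roles], axis=1)  # (n, k, 3)
    out = dataset.copy()
    names = out.marker_names
    stacked = np.stack([out.positions(name) for name in names], axis=1)  # (n, m, 3)
    for f in range(n):
        pts = cranial[f]
        ok = ~np.isnan(pts).any(axis=1)
        if ok.sum() < 3:
            raise DegenerateConfigurationError(
                f"frame {f}: only {int(ok.sum())} cranial markers trackable"
            )
        try:
            T = fit_rigid_transform(pts[ok], ref[ok])
        except DegenerateConfigurationError as exc:
            raise DegenerateConfigurationError(f"frame {f}: {exc}") from None
        stacked[f] = T.apply(stacked[f])
    for i, name in enumerate(names):
        out.markers[name] = stacked[:, i, :]
    out.coordinate_frame_tag = "cranial"
    return out


def mandible_transforms(
    dataset_cranial: MarkerDataset,
    mandibular_roles: tuple[str, ...] | list[str],
    reference_frame_index: int = 0,
) -> list[RigidTransform]:
    """Per-frame rigid transforms of the mandible relative to the reference pose.

    Fitted from the mandibular markers in the cranial-fixed dataset; the
    transform at the reference frame is the identity (up to noise), and
    applying transform ``f`` to reference-pose points reproduces the frame-f
    marker positions.
    """
    roles = list(mandibular_roles)
    ref = np.stack([dataset_cranial.positions(r)[reference_frame_index] for r in roles])
    if np.isnan(ref).any():
        raise DegenerateConfigurationError(
            f"mandibular markers missing at reference frame {reference_frame_index}"
        )
    _check_not_collinear(ref, f"mandibular markers at reference frame {reference_frame_index}")
    pts = np.stack([dataset_cranial.positions(r) for r in roles], axis=1)
    transforms: list[RigidTransform] = []
    for f in range(dataset_cranial.n_frames):
        cur = pts[f]
        ok = ~np.isnan(cur).any(axis=1)
        if ok.sum() < 3:
            raise DegenerateConfigurationError(
                f"frame {f}: only {int(ok.sum())} mandibular markers trackable"
            )
        transforms.append(fit_rigid_transform(ref[ok], cur[ok]))
    return transforms


def transform_landmarks(
    landmarks: LandmarkSet,
    transforms: list[RigidTransform],
) -> dict[str, np.ndarray]:
    """Animate reference-pose landmarks with the per-frame mandible transforms.

    Returns a map landmark name -> ``(n_frames, 3)`` trajectory in the fixed
    cranial space.
    """
    n = len(transforms)
    R = np.stack([T.rotation for T in transforms])       # (n, 3, 3)
    t = np.stack([T.translation for T in transforms])    # (n, 3)
    out: dict[str, np.ndarray] = {}
    for name, p in landmarks.points.items():
        out[name] = np.einsum("fij,j->fi", R, p) + t
    return out


# ---------------------------------------------------------------------------
# gape
# ---------------------------------------------------------------------------

def find_occlusion_frame(
    dataset_cranial: MarkerDataset,
    anterior_mandible_role: str,
    frame: AnatomicalFrame | None = None,
) -> int:
    """Estimate the frame of maximum occlusion (jaw fully closed).

    Occlusion is the extreme of jaw elevation: the closed-jaw pose cannot be
    overshot (teeth in contact), so the anterior mandibular marker is at its
    most superior position exactly there.  The heuristic therefore anchors on
    the frame maximising the superoinferior coordinate and then re-anchors
    once at the frame minimising displacement from that candidate within its
    local gape trough.  Supply ``occlusion_frame`` in the config to bypass
    the heuristic.
    """
    frame = frame or AnatomicalFrame()
    x = dataset_cranial.positions(anterior_mandible_role)
    good = ~np.isnan(x).any(axis=1)
    if not good.any():
        raise ValueError(f"marker {anterior_mandible_role!r} has no trackable frames")
    si = (x - frame.origin) @ frame.axis_si
    si = np.where(good, si, -np.inf)
    cand = int(np.argmax(si))
    d = np.full(x.shape[0], np.inf)
    d[good] = np.linalg.norm(x[good] - x[cand], axis=1)
    return int(np.argmin(d))


def gape_distance(
    dataset_cranial: MarkerDataset,
    anterior_mandible_role: str,
    occlusion_frame: int | None = None,
    frame: AnatomicalFrame | None = None,
) -> GapeSeries:
    """Gape distance: Euclidean displacement of the anterior mandibular marker
    from its position at maximum occlusion (cranial frame).
    """
    x = dataset_cranial.positions(anterior_mandible_role)
    if occlusion_frame is None:
        occlusion_frame = find_occlusion_frame(dataset_cranial, anterior_mandible_role, frame)
    ref = x[occlusion_frame]
    if np.isnan(ref).any():
        raise ValueError(
            f"marker {anterior_mandible_role!r} missing at occlusion frame {occlusion_frame}"
        )
    values = np.linalg.norm(x - ref, axis=1)
    return GapeSeries(
        values=values,
        frame_rate=dataset_cranial.frame_rate,
        occlusion_frame=int(occlusion_frame),
        occlusion_reference=ref,
    )
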
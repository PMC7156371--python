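"""Dynamic muscle-architecture variables and the architectural gear ratio.

Fascicle length is the distance between the intramuscular markers at the
central myotendinous junction (m1) and the superficial fascicle termination
(m2); whole-muscle length runs from the coronoid tip (a CT landmark animated
by the mandibular transforms) to the marker at the muscle's superior
attachment (m3).  Fascicle angles are planar: the fascicle vector (m1->m2)
and the line-of-action vector (m1->m3) are each projected onto the sagittal
(AP-SI) and coronal (ML-SI) planes and the angle between the projections is
reported, folded into [0, 90] degrees as pinnation conventionally is.

The architectural gear ratio AGR is whole-muscle velocity divided by
fascicle velocity.  AGR > 1 means fascicle rotation gears muscle velocity
up (velocity-favouring); AGR < 1 means restricted rotation favouring force.
The ratio is undefined near velocity zero-crossings (minimum and maximum
gape), so frames where the fascicle velocity magnitude falls below a small
threshold, or where the two velocities disagree in sign, are masked rather
than silently dropped.

``run_pipeline`` composes the whole chain in recording order: gap
interpolation -> low-pass filtering -> cranial-frame fixing -> mandibular
transforms -> landmark animation -> gape -> cycle segmentation and phase
detection -> per-cycle variables -> 50-frame standardisation ->
per-food averaging -> LOESS velocity smoothing -> AGR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from . import cycles as _cycles
from . import kinematics as _kin
from .io_formats import (
    AnatomicalFrame,
    LandmarkSet,
    MarkerDataset,
    PipelineConfig,
    read_landmarks,
    read_marker_csv,
)

__all__ = [
    "ArchitectureSeries",
    "BulgingMetric",
    "PipelineError",
    "PipelineResult",
    "fascicle_length",
    "muscle_length",
    "fascicle_angles",
    "instantaneous_velocity",
    "loess_smooth",
    "compute_agr",
    "normalize_to_zero",
    "bulging",
    "run_pipeline",
    "run_pipeline_data",
    "per_cycle_agr",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ArchitectureSeries:
    """Per-frame architecture variables for one gape cycle (masked = NaN)."""

    fascicle_length: np.ndarray      # mm
    muscle_length: np.ndarray        # mm
    sagittal_angle: np.ndarray       # deg, [0, 90]
    coronal_angle: np.ndarray        # deg, [0, 90]
    fascicle_velocity: np.ndarray    # mm/s, shortening negative
    muscle_velocity: np.ndarray      # mm/s
    gape: np.ndarray                 # mm
    frame_rate: float
    agr: np.ndarray | None = None
    agr_valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.fascicle_length.shape[0]
        for name in ("muscle_length", "sagittal_angle", "coronal_angle",
                     "fascicle_velocity", "muscle_velocity", "gape"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length differs from fascicle_length")

    @property
    def n_frames(self) -> int:
        return self.fascicle_length.shape[0]


@dataclass
class BulgingMetric:
    """Within-cycle range of the superficial fascicle marker (mm)."""

    ap_range: float
    ml_range: float

    def __post_init__(self) -> None:
        if self.ap_range < 0 or self.ml_range < 0:
            raise ValueError("bulging ranges must be non-negative")


# ---------------------------------------------------------------------------
# per-frame variables
# ---------------------------------------------------------------------------

def _pairwise_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"trajectories must have equal shape, got {a.shape} vs {b.shape}")
    return np.linalg.norm(b - a, axis=1)


def fascicle_length(m1_traj: np.ndarray, m2_traj: np.ndarray) -> np.ndarray:
    """Euclidean distance m1 (CMJ) to m2 (superficial termination), mm.

    Frames where either marker is missing are NaN; coincident markers yield
    0 and are flagged with a warning (degenerate for angle computation).
    """
    d = _pairwise_distance(m1_traj, m2_traj)
    if np.any(d[np.isfinite(d)] < 1e-9):
        warnings.warn("coincident fascicle markers on some frames (degenerate)")
    return d


def muscle_length(coronoid_tip_traj: np.ndarray, m3_traj: np.ndarray) -> np.ndarray:
    """Euclidean distance coronoid tip to the superior attachment marker, mm."""
    return _pairwise_distance(coronoid_tip_traj, m3_traj)


def fascicle_angles(
    m1_traj: np.ndarray,
    m2_traj: np.ndarray,
    m3_traj: np.ndarray,
    frame: AnatomicalFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal- and coronal-plane fascicle angles (degrees, folded to [0, 90]).

    The fascicle vector v = m2 - m1 and the line-of-action reference
    r = m3 - m1 are projected onto each plane; the angle between the
    projections is arccos of their normalised dot product.  Frames where a
    projected vector nearly vanishes (< 1e-9 mm) are masked.
    """
    v = np.asarray(m2_traj, float) - np.asarray(m1_traj, float)
    r = np.asarray(m3_traj, float) - np.asarray(m1_traj, float)
    comp_v = frame.components(v)  # columns: AP, ML, SI
    comp_r = frame.components(r)

    def planar(i: int, j: int) -> np.ndarray:
        vp = comp_v[:, [i, j]]
        rp = comp_r[:, [i, j]]
        nv = np.linalg.norm(vp, axis=1)
        nr = np.linalg.norm(rp, axis=1)
        dot = np.abs(np.sum(vp * rp, axis=1))
        cross = np.abs(vp[:, 0] * rp[:, 1] - vp[:, 1] * rp[:, 0])
        # atan2 of |cross| / |dot| is well conditioned near 0 and 90 degrees
        ang = np.degrees(np.arctan2(cross, dot))
        ang[(nv < 1e-9) | (nr < 1e-9)] = np.nan
        return ang

    sagittal = planar(0, 2)  # AP, SI
    coronal = planar(1, 2)   # ML, SI
    return sagittal, coronal


def instantaneous_velocity(length_series: np.ndarray, frame_rate: float) -> np.ndarray:
    """Temporal derivative of a length series, mm/s.

    Central differences on interior frames, one-sided at the ends;
    shortening is negative.  Frames with a masked neighbour are masked.
    """
    y = np.asarray(length_series, dtype=float)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 samples for a velocity estimate")
    v = np.gradient(y, edge_order=1) * frame_rate
    bad = ~np.isfinite(y)
    if bad.any():
        # central differences straddle a masked frame without touching it;
        # mask every frame whose stencil includes a missing sample
        spread = bad.copy()
        spread[:-1] |= bad[1:]
        spread[1:] |= bad[:-1]
        v[spread] = np.nan
    return v


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.25) -> np.ndarray:
    """LOESS (locally weighted linear regression, tricube weights).

    ``span`` is the fraction of points in each local neighbourhood; the
    smoother is deterministic and reproduces exactly linear data exactly.
    NaN points are excluded from the fit and returned as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    good = np.isfinite(x) & np.isfinite(y)
    n = int(good.sum())
    if n < 10:
        raise ValueError(f"need >= 10 points for LOESS, got {n}")
    if int(np.ceil(span * n)) < 4:
        raise ValueError(
            f"span {span} gives a local window of {int(np.ceil(span * n))} < 4 points"
        )
    out = np.full_like(y, np.nan)
    out[good] = _sm_lowess(
        y[good], x[good], frac=span, it=0, return_sorted=False
    )
    return out


def compute_agr(
    muscle_velocity: np.ndarray,
    fascicle_velocity: np.ndarray,
    epsilon: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Architectural gear ratio with its validity mask.

    ``agr[f] = muscle_velocity[f] / fascicle_velocity[f]`` on frames where
    the fascicle velocity magnitude is at least ``epsilon`` and both
    velocities share sign; elsewhere NaN with mask False.  Near velocity
    zero-crossings (minimum/maximum gape) the ratio is undefined and the
    mask makes that explicit.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    mv = np.asarray(muscle_velocity, float)
    fv = np.asarray(fascicle_velocity, float)
    if mv.shape != fv.shape:
        raise ValueError("velocity series must be co-registered (equal length)")
    with np.errstate(invalid="ignore"):
        valid = np.isfinite(mv) & np.isfinite(fv) & (np.abs(fv) >= epsilon) & (mv * fv > 0)
    agr = np.full_like(mv, np.nan)
    agr[valid] = mv[valid] / fv[valid]
    return agr, valid


def normalize_to_zero(series: np.ndarray, mode: str = "min") -> np.ndarray:
    """Shift a series so its minimum (or maximum) is zero.

    Shape and derivatives are unchanged; used to compare architectural
    variables between animals.
    """
    y = np.asarray(series, dtype=float)
    if not np.isfinite(y).any():
        raise ValueError("cannot normalize an all-masked series")
    if mode == "min":
        return y - np.nanmin(y)
    if mode == "max":
        return y - np.nanmax(y)
    raise ValueError(f"mode must be 'min' or 'max', got {mode!r}")


def bulging(
    m2_traj: np.ndarray,
    frame: AnatomicalFrame,
    cycle_span: tuple[int, int],
) -> BulgingMetric:
    """Muscle shape change within a cycle: AP and ML excursion ranges of the
    superficial fascicle marker (mm)."""
    a, b = cycle_span
    seg = np.asarray(m2_traj, float)[a : b + 1]
    if seg.shape[0] == 0:
        raise ValueError(f"empty cycle span {cycle_span}")
    comp = frame.components(seg)
    good = np.isfinite(comp).all(axis=1)
    if not good.any():
        raise ValueError("no trackable frames in cycle span")
    ap = comp[good, 0]
    ml = comp[good, 1]
    return BulgingMetric(float(ap.max() - ap.min()), float(ml.max() - ml.min()))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_STANDARD_VARIABLES = (
    "gape",
    "fascicle_length",
    "muscle_length",
    "sagittal_angle",
    "coronal_angle",
    "fascicle_velocity",
    "muscle_velocity",
)


@dataclass
class PipelineResult:
    """Everything the pipeline computes for one recording."""

    long_table: pd.DataFrame          # tidy (subject, food, cycle, phase, %cycle, variable, value)
    cycle_table: pd.DataFrame         # one row per cycle with boundaries and bulging
    per_cycle: list[ArchitectureSeries]
    cycles: list[_cycles.GapeCycle]
    food_curves: dict[str, dict[str, tuple[np.ndarray, np.ndarray, int]]]
    agr_by_food: pd.DataFrame         # food, pct_cycle, agr, valid
    gape: _kin.GapeSeries
    dataset_cranial: MarkerDataset
    landmark_trajectories: dict[str, np.ndarray]
    log: dict = field(default_factory=dict)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(
    config: PipelineConfig,
    marker_csv: str,
    landmarks_csv: str,
) -> PipelineResult:
    """File-based entry point: read the marker and landmark CSVs, then run
    :func:`run_pipeline_data`."""
    with _stage("io_formats"):
        dataset = read_marker_csv(marker_csv, frame_rate=config.frame_rate)
        landmarks = read_landmarks(landmarks_csv)
    return run_pipeline_data(config, dataset, landmarks)


def run_pipeline_data(
    config: PipelineConfig,
    dataset: MarkerDataset,
    landmarks: LandmarkSet,
) -> PipelineResult:
    """Run the full processing chain on in-memory data.

    Deterministic given its inputs.  Stage failures re-raise as
    :class:`PipelineError` naming the stage.
    """
    with _stage("config"):
        config.validate_roles(dataset)
        if config.coronoid_landmark not in landmarks.names():
            raise ValueError(
                f"coronoid landmark {config.coronoid_landmark!r} not in landmark set"
            )

    with _stage("preprocess"):
        filled = _kin.fill_gaps(dataset, config.max_gap_frames)
        filtered = _kin.filter_dataset(filled, config.filter_cutoff_hz, config.filter_order)

    with _stage("register"):
        if config.reference_frame is not None:
            ref_idx = config.reference_frame
        else:
            bone = np.stack(
                [filtered.missing_mask(r) for r in config.bone_roles()], axis=0
            ).any(axis=0)
            complete = np.flatnonzero(~bone)
            if complete.size == 0:
                raise ValueError("no frame has all bone markers trackable")
            ref_idx = int(complete[0])
        cranial_ds = _kin.fix_cranial_frame(filtered, config.cranial, ref_idx)
        transforms = _kin.mandible_transforms(cranial_ds, config.mandibular, ref_idx)
        lm_traj = _kin.transform_landmarks(landmarks, transforms)

    with _stage("gape"):
        gape = _kin.gape_distance(
            cranial_ds,
            config.anterior_mandible,
            occlusion_frame=config.occlusion_frame,
            frame=config.frame,
        )

    with _stage("cycles"):
        prom = config.min_prominence_frac * (
            np.nanmax(gape.values) - np.nanmin(gape.values)
        )
        cycle_list = _cycles.extract_cycles(gape, min_prominence=prom)

    with _stage("architecture"):
        m1 = cranial_ds.positions(config.cmj_marker)
        m2 = cranial_ds.positions(config.superficial_marker)
        m3 = cranial_ds.positions(config.attachment_marker)
        tip = lm_traj[config.coronoid_landmark]

        l_full = fascicle_length(m1, m2)
        L_full = muscle_length(tip, m3)
        sag_full, cor_full = fascicle_angles(m1, m2, m3, config.frame)

        per_cycle: list[ArchitectureSeries] = []
        cycle_rows = []
        long_rows = []
        pct = np.linspace(0.0, 100.0, config.n_standard)
        for ci, cyc in enumerate(cycle_list):
            sl = slice(cyc.start, cyc.end + 1)
            fv = instantaneous_velocity(l_full[sl], config.frame_rate)
            mv = instantaneous_velocity(L_full[sl], config.frame_rate)
            series = ArchitectureSeries(
                fascicle_length=l_full[sl],
                muscle_length=L_full[sl],
                sagittal_angle=sag_full[sl],
                coronal_angle=cor_full[sl],
                fascicle_velocity=fv,
                muscle_velocity=mv,
                gape=gape.values[sl],
                frame_rate=config.frame_rate,
            )
            per_cycle.append(series)
            bulge = bulging(m2, config.frame, (cyc.start, cyc.end))
            cycle_rows.append(
                {
                    "subject": config.subject,
                    "food": config.food,
                    "cycle": ci,
                    "start_frame": cyc.start,
                    "fc_sc": cyc.fc_sc,
                    "min_gape": cyc.min_gape,
                    "so_fo": cyc.so_fo,
                    "end_frame": cyc.end,
                    "duration_s": cyc.duration_s,
                    "bulging_ap_mm": bulge.ap_range,
                    "bulging_ml_mm": bulge.ml_range,
                }
            )
            labels = cyc.phase_labels()
            label_std = labels[
                np.clip(
                    np.round(np.linspace(0, labels.size - 1, config.n_standard)).astype(int),
                    0,
                    labels.size - 1,
                )
            ]
            for var in _STANDARD_VARIABLES:
                values = getattr(series, var)
                std = _cycles.standardize_cycle(values, config.n_standard)
                for p, lab, val in zip(pct, label_std, std):
                    long_rows.append(
                        {
                            "subject": config.subject,
                            "food": config.food,
                            "cycle": ci,
                            "phase": lab,
                            "pct_cycle": p,
                            "variable": var,
                            "value": val,
                        }
                    )
        long_table = pd.DataFrame(
            long_rows,
            columns=["subject", "food", "cycle", "phase", "pct_cycle", "variable", "value"],
        )
        cycle_table = pd.DataFrame(cycle_rows)

    with _stage("food_average"):
        food = config.food if config.food is not None else "all"
        food_curves: dict[str, dict[str, tuple[np.ndarray, np.ndarray, int]]] = {}
        agr_rows = []
        if per_cycle:
            stacks = {
                var: np.stack(
                    [
                        _cycles.standardize_cycle(getattr(s, var), config.n_standard)
                        for s in per_cycle
                    ]
                )
                for var in _STANDARD_VARIABLES
            }
            curves = {
                var: _cycles.average_cycles(stacks[var], [food] * len(per_cycle))[food]
                for var in _STANDARD_VARIABLES
            }
            food_curves[food] = curves
            fv_mean = curves["fascicle_velocity"][0]
            mv_mean = curves["muscle_velocity"][0]
            fv_s = loess_smooth(pct, fv_mean, config.loess_span)
            mv_s = loess_smooth(pct, mv_mean, config.loess_span)
            eps = config.agr_epsilon_frac * np.nanmax(np.abs(fv_s))
            agr, valid = compute_agr(mv_s, fv_s, eps)
            for p, a, vl in zip(pct, agr, valid):
                agr_rows.append(
                    {"food": food, "pct_cycle": p, "agr": a, "valid": bool(vl)}
                )
        agr_by_food = pd.DataFrame(agr_rows, columns=["food", "pct_cycle", "agr", "valid"])

    log = {
        "n_frames": dataset.n_frames,
        "reference_frame": ref_idx,
        "occlusion_frame": gape.occlusion_frame,
        "n_cycles": len(cycle_list),
        "cycles_per_food": {config.food: len(cycle_list)},
        "masked_agr_fraction": float(np.mean(~agr_by_food["valid"].to_numpy()))
        if len(agr_by_food)
        else np.nan,
    }
    return PipelineResult(
        long_table=long_table,
        cycle_table=cycle_table,
        per_cycle=per_cycle,
        cycles=cycle_list,
        food_curves=food_curves,
        agr_by_food=agr_by_food,
        gape=gape,
        dataset_cranial=cranial_ds,
        landmark_trajectories=lm_traj,
        log=log,
    )


def per_cycle_agr(
    series: ArchitectureSeries,
    span: float = 0.25,
    epsilon_frac: float = 0.02,
    n_standard: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle AGR route: standardise this cycle's velocities, LOESS-smooth
    them and form the gear ratio (alternative to the per-food-average route).
    """
    pct = np.linspace(0.0, 100.0, n_standard)
    fv = _cycles.standardize_cycle(series.fascicle_velocity, n_standard)
    mv = _cycles.standardize_cycle(series.muscle_velocity, n_standard)
    fv_s = loess_smooth(pct, fv, span)
    mv_s = loess_smooth(pct, mv, span)
    eps = epsilon_frac * np.nanmax(np.abs(fv_s))
    return compute_agr(mv_s, fv_s, eps)
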
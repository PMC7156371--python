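"""Synthetic jaw + pinnate-muscle recordings with closed-form ground truth.

The generator emulates a marker-based biplanar videoradiography recording of
a primate chewing: four cranial and four mandibular bone markers plus three
intramuscular markers on a pinnate jaw-elevator fascicle, sampled at
150 frames/s with Gaussian marker noise at the 0.1-0.2 mm precision typical
of the technique.  Everything the analysis pipeline is supposed to recover -
gape, rigid transforms, phase-transition frames, fascicle length l(t),
pinnation angle theta(t), whole-muscle length L(t) and the architectural
gear ratio AGR(t) = dL/dl - is known analytically, so recovery can be tested
against exact truth rather than against another implementation.

Jaw model
    The mandible rotates rigidly about a fixed mediolateral axis through a
    rotation centre near the jaw joint.  The prescribed gape trajectory g(t)
    maps to a rotation angle through the chord relation
    ``2 r sin(phi/2) = g`` where r is the distance of the anterior
    mandibular marker from the axis.

Gape trajectory
    Each cycle is C1 piecewise-cosine through four phases FC, SC, SO, FO
    (fast close, slow close to zero gape, slow open, fast open back to
    maximum).  Velocity is zero at every junction; acceleration jumps there,
    giving the acceleration-based phase detector a well-defined target.  The
    intermediate gape at the fast/slow handoff is
    ``0.6 * G * T_slow^2 / (T_fast^2 + T_slow^2)`` so that the fast-phase
    acceleration discontinuity dominates the slow-phase one for any duration
    ratio (with equal durations this is the conventional ~30% of max gape).

Muscle model
    The muscle line of action runs from a fixed superior attachment (marker
    m3, on the temporal-fascia side) to the coronoid tip; the central
    myotendinous junction marker m1 rides the central tendon at a fixed
    fraction of the muscle belly, and the superficial fascicle marker m2
    sits at distance l(t) from m1 along a direction at pinnation angle
    theta(t) to the line of action.  Constraint modes:

    ``constant_pinnation``  theta = theta0, l = k (L - Lt) / cos(theta0),
        so AGR = dL/dl = cos(theta0) / k  (the low-gear, reduced-rotation
        limit: fascicles shorten without rotating).
    ``constant_thickness``  l sin(theta) = t0 fixed, so
        l = sqrt(k^2 (L - Lt)^2 + t0^2), theta = atan2(t0, k (L - Lt)) and
        AGR = 1 / (k cos(theta))  (the high-gear limit: fascicles rotate as
        they shorten, gearing muscle velocity above fascicle velocity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    AnatomicalFrame,
    LandmarkSet,
    MarkerDataset,
    PipelineConfig,
    write_landmarks,
    write_marker_csv,
)
from .kinematics import RigidTransform

__all__ = [
    "SyntheticScenario",
    "SyntheticGroundTruth",
    "SyntheticRecording",
    "StudyData",
    "TILT_SAGITTAL_TWICE_CORONAL",
    "FOOD_FMP_GROUPS",
    "build_gape_trajectory",
    "build_jaw_scene",
    "build_muscle_markers",
    "build_recording",
    "add_noise",
    "make_study",
]

# Coronal tilt of the fascicle plane (degrees) for which the sagittal-plane
# projection of fascicle rotation spans about twice the coronal-plane
# projection with the default muscle geometry: atan(1/2).
TILT_SAGITTAL_TWICE_CORONAL = math.degrees(math.atan(0.5))

# Food items used in the study design and their mechanical-property group.
FOOD_FMP_GROUPS = {
    "popcorn": "high",
    "cashew": "high",
    "grape": "low",
    "marshmallow": "low",
    "apple": "low",
}


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic chewing recording.

    Defaults describe a small primate chewing at 2.5 Hz with a 15 mm maximum
    gape: phase durations (12, 18, 18, 12) frames at 150 frames/s, moderate
    fast phases and longer slow phases.  Geometry is in mm, closed-jaw
    (occlusion) pose, with AP = +x, ML = +y, SI = +z and the jaw rotation
    axis along ML through the origin (near the jaw joint, inferior to the
    condyle).
    """

    frame_rate: float = 150.0
    n_cycles: int = 6
    phase_frames: tuple[int, int, int, int] = (12, 18, 18, 12)  # FC, SC, SO, FO
    amplitude_mm: float = 15.0
    amplitude_jitter: float = 0.0      # relative SD of per-cycle max gape
    handoff: float = 0.6               # gamma of the fast/slow handoff rule
    rotation_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cranial_markers: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "cran1": (10.0, 15.0, 40.0),
            "cran2": (15.0, -18.0, 38.0),
            "cran3": (-12.0, 12.0, 45.0),
            "cran4": (-8.0, -10.0, 50.0),
        }
    )
    mandibular_markers: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "mand_ant": (45.0, 3.0, 0.0),
            "mand2": (38.0, -6.0, 2.0),
            "mand3": (22.0, 8.0, -2.0),
            "mand4": (20.0, -7.0, -4.0),
        }
    )
    coronoid_tip: tuple[float, float, float] = (18.0, 10.0, 18.0)
    gonial_right: tuple[float, float, float] = (-5.0, 12.0, -8.0)
    gonial_left: tuple[float, float, float] = (-5.0, -12.0, -8.0)
    m3_position: tuple[float, float, float] = (12.0, 11.0, 58.0)
    cmj_fraction: float = 0.5          # m1 position along the tendon line
    fascicle_ref_mm: float = 12.0      # muscle-belly span L - Lt at occlusion
    tendon_length_mm: float | None = None  # default: L_occlusion - fascicle_ref
    mode: str = "constant_thickness"   # | "constant_pinnation" | "prescribed_theta"
    theta_ref_deg: float = 20.0        # pinnation at occlusion (fixed angle for constant_pinnation)
    theta_of_gape: object | None = None  # callable gape_mm -> theta_deg, for prescribed_theta
    k: float = 1.0                     # tendon-to-muscle transmission factor
    coronal_tilt_deg: float = 0.0      # tilt of fascicle plane out of the sagittal plane
    noise_sigma_mm: float = 0.15
    drift_translation_mm: float = 0.0  # slow whole-scene rigid drift amplitude
    drift_rotation_deg: float = 0.0
    seed: int = 0
    subject: str | None = None
    food: str | None = None

    def __post_init__(self) -> None:
        if any(t < 2 for t in self.phase_frames):
            raise ValueError("each phase must last at least 2 frames")
        if not 0 < self.theta_ref_deg < 60:
            raise ValueError("theta_ref_deg must be in (0, 60) degrees")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if self.amplitude_mm <= 0:
            raise ValueError("amplitude must be positive")
        if not 0 < self.handoff < 1:
            raise ValueError("handoff fraction must be in (0, 1)")

    @property
    def cycle_frames(self) -> int:
        return sum(self.phase_frames)


@dataclass
class SyntheticGroundTruth:
    """Per-frame truth emitted alongside a synthetic recording (all in the
    cranial frame, no noise)."""

    gape: np.ndarray                 # mm
    phi: np.ndarray                  # jaw rotation angle, rad (0 = occlusion)
    fascicle_length: np.ndarray      # l(t), mm
    theta_deg: np.ndarray            # 3-D pinnation angle
    sagittal_deg: np.ndarray         # sagittal-plane projection angle
    coronal_deg: np.ndarray          # coronal-plane projection angle
    muscle_length: np.ndarray        # L(t), mm
    agr: np.ndarray                  # dL/dl from the mode's closed form
    transitions: list[dict]          # per cycle: start, fc_sc, min_gape, so_fo, end
    transforms: list[RigidTransform]  # mandible pose relative to frame 0
    occlusion_position: np.ndarray   # anterior marker at occlusion (cranial frame)

    def transitions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.transitions)


@dataclass
class SyntheticRecording:
    """A complete synthetic recording: what the lab would hand the pipeline
    (noisy marker data, CT landmarks, config) plus the hidden truth."""

    dataset: MarkerDataset
    dataset_clean: MarkerDataset
    landmarks: LandmarkSet
    config: PipelineConfig
    truth: SyntheticGroundTruth
    scenario: SyntheticScenario


# ---------------------------------------------------------------------------
# gape trajectory
# ---------------------------------------------------------------------------

def _cos_segment(a: float, b: float, n: int) -> np.ndarray:
    """Cosine ease from level a to level b over n frames (samples 1..n)."""
    tau = np.arange(1, n + 1) / n
    return b + (a - b) * (1.0 + np.cos(np.pi * tau)) / 2.0


def build_gape_trajectory(
    scenario: SyntheticScenario,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Prescribed gape series plus the true phase-transition frames.

    The series starts mid-opening and ends mid-closing so every prescribed
    cycle maximum is an interior peak for the segmenter.  Minimum gape is
    exactly 0 at each SC/SO boundary and maximum gape exactly the (possibly
    jittered) cycle amplitude at each cycle boundary.
    """
    s = scenario
    t_fc, t_sc, t_so, t_fo = s.phase_frames
    if rng is None:
        rng = np.random.default_rng(s.seed)
    n_max = s.n_cycles + 1
    if s.amplitude_jitter > 0:
        jit = np.clip(s.amplitude_jitter * rng.standard_normal(n_max), -0.25, 0.25)
    else:
        jit = np.zeros(n_max)
    amps = s.amplitude_mm * (1.0 + jit)

    def g1_of(G: float) -> float:   # FC -> SC handoff gape
        return s.handoff * G * t_sc**2 / (t_fc**2 + t_sc**2)

    def g2_of(G: float) -> float:   # SO -> FO handoff gape
        return s.handoff * G * t_so**2 / (t_so**2 + t_fo**2)

    vals = [g2_of(amps[0])]
    vals.extend(_cos_segment(vals[0], amps[0], t_fo))       # lead-in ascent
    lead = t_fo
    period = s.cycle_frames
    transitions: list[dict] = []
    for c in range(s.n_cycles):
        G0, G1 = amps[c], amps[c + 1]
        start = lead + c * period
        transitions.append(
            {
                "cycle": c,
                "start": start,
                "fc_sc": start + t_fc,
                "min_gape": start + t_fc + t_sc,
                "so_fo": start + t_fc + t_sc + t_so,
                "end": start + period,
                "max_gape_mm": G0,
            }
        )
        vals.extend(_cos_segment(G0, g1_of(G0), t_fc))
        vals.extend(_cos_segment(g1_of(G0), 0.0, t_sc))
        vals.extend(_cos_segment(0.0, g2_of(G1), t_so))
        vals.extend(_cos_segment(g2_of(G1), G1, t_fo))
    vals.extend(_cos_segment(amps[-1], g1_of(amps[-1]), t_fc))  # tail descent
    return np.asarray(vals), transitions


# ---------------------------------------------------------------------------
# rigid jaw scene
# ---------------------------------------------------------------------------

def _rot_ml(phi: np.ndarray) -> np.ndarray:
    """Stack of rotations about the +ML (y) axis; positive phi opens the jaw
    (lowers the anterior mandible)."""
    c, s = np.cos(phi), np.sin(phi)
    R = np.zeros(phi.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 2] = s
    R[..., 1, 1] = 1.0
    R[..., 2, 0] = -s
    R[..., 2, 2] = c
    return R


def build_jaw_scene(
    gape: np.ndarray,
    scenario: SyntheticScenario,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Bone-marker trajectories realising a prescribed gape series.

    Returns ``(marker trajectories, phi, coronoid-tip trajectory)``.  The
    mandible rotates about the ML axis through the rotation centre so that
    the anterior marker's chord displacement from its occlusion position
    equals the gape (``2 r sin(phi/2) = gape``); cranial markers stay put.
    """
    s = scenario
    center = np.asarray(s.rotation_center, dtype=float)
    ant = np.asarray(s.mandibular_markers["mand_ant"], dtype=float)
    rel = ant - center
    r = math.hypot(rel[0], rel[2])  # distance to the ML rotation axis
    if np.max(gape) > 2 * r:
        raise ValueError(f"gape {np.max(gape):.1f} mm unreachable: marker radius {r:.1f} mm")
    phi = 2.0 * np.arcsin(np.asarray(gape, float) / (2.0 * r))
    R = _rot_ml(phi)

    traj: dict[str, np.ndarray] = {}
    n = gape.shape[0]
    for name, p in s.cranial_markers.items():
        traj[name] = np.broadcast_to(np.asarray(p, float), (n, 3)).copy()
    for name, p in s.mandibular_markers.items():
        traj[name] = np.einsum("fij,j->fi", R, np.asarray(p, float) - center) + center
    tip = np.einsum("fij,j->fi", R, np.asarray(s.coronoid_tip, float) - center) + center
    return traj, phi, tip


# ---------------------------------------------------------------------------
# muscle geometry
# ---------------------------------------------------------------------------

def _planar_angle_deg(v: np.ndarray, r: np.ndarray, i: int, j: int) -> np.ndarray:
    """Folded angle between the (i, j)-plane projections of row vectors."""
    vp = v[:, [i, j]]
    rp = r[:, [i, j]]
    dot = np.abs(np.sum(vp * rp, axis=1))
    cross = np.abs(vp[:, 0] * rp[:, 1] - vp[:, 1] * rp[:, 0])
    return np.degrees(np.arctan2(cross, dot))


def build_muscle_markers(
    tip: np.ndarray,
    scenario: SyntheticScenario,
    gape: np.ndarray,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Muscle-marker trajectories (m1, m2, m3) plus architecture truth.

    Implements the constraint modes documented in the module docstring; see
    there for the closed-form AGR each mode pins down.
    """
    s = scenario
    m3 = np.asarray(s.m3_position, dtype=float)
    n = tip.shape[0]
    L = np.linalg.norm(tip - m3, axis=1)

    center = np.asarray(s.rotation_center, dtype=float)
    tip0 = np.asarray(s.coronoid_tip, dtype=float)
    L_occ = float(np.linalg.norm(tip0 - m3))
    Lt = s.tendon_length_mm if s.tendon_length_mm is not None else L_occ - s.fascicle_ref_mm
    belly = L - Lt
    if np.min(belly) <= 0:
        raise ValueError(
            f"tendon slack: muscle length {np.min(L):.2f} mm <= tendon {Lt:.2f} mm"
        )

    theta_ref = math.radians(s.theta_ref_deg)
    if s.mode == "constant_pinnation":
        theta = np.full(n, theta_ref)
        ell = s.k * belly / math.cos(theta_ref)
        agr = np.full(n, math.cos(theta_ref) / s.k)
    elif s.mode == "constant_thickness":
        t0 = s.k * (L_occ - Lt) * math.tan(theta_ref)
        ell = np.sqrt((s.k * belly) ** 2 + t0**2)
        theta = np.arctan2(t0, s.k * belly)
        agr = 1.0 / (s.k * np.cos(theta))
    elif s.mode == "prescribed_theta":
        if s.theta_of_gape is None:
            raise ValueError("prescribed_theta mode requires theta_of_gape")
        theta = np.radians(np.asarray([s.theta_of_gape(g) for g in gape], dtype=float))
        ell = s.k * belly / np.cos(theta)
        # no single closed form: AGR from the exact series' derivative ratio
        dL = np.gradient(L)
        dl = np.gradient(ell)
        with np.errstate(divide="ignore", invalid="ignore"):
            agr = np.where(np.abs(dl) > 1e-12, dL / dl, np.nan)
    else:
        raise ValueError(f"unknown constraint mode {s.mode!r}")

    u = (tip - m3) / L[:, None]                       # line of action, m3 -> tip
    s_hat = np.stack([-u[:, 2], np.zeros(n), u[:, 0]], axis=1)
    s_hat /= np.linalg.norm(s_hat, axis=1)[:, None]   # sagittal-plane normal to u
    m_hat = np.cross(u, s_hat)
    flip = np.sign(m_hat[:, 1])
    flip[flip == 0] = 1.0
    m_hat *= flip[:, None]                            # lateral (+ML)

    psi = math.radians(s.coronal_tilt_deg)
    lat = math.cos(psi) * s_hat + math.sin(psi) * m_hat
    f_hat = -np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * lat

    m1 = m3 + s.cmj_fraction * belly[:, None] * u
    m2 = m1 + ell[:, None] * f_hat

    sag = _planar_angle_deg(f_hat, -u, 0, 2)  # AP-SI plane
    cor = _planar_angle_deg(f_hat, -u, 1, 2)  # ML-SI plane

    markers = {"m1": m1, "m2": m2, "m3": np.broadcast_to(m3, (n, 3)).copy()}
    truth = {
        "fascicle_length": ell,
        "theta_deg": np.degrees(theta),
        "sagittal_deg": sag,
        "coronal_deg": cor,
        "muscle_length": L,
        "agr": agr,
        "tendon_length": Lt,
    }
    return markers, truth


# ---------------------------------------------------------------------------
# noise, drift, assembly
# ---------------------------------------------------------------------------

def add_noise(dataset: MarkerDataset, sigma: float, seed: int = 0) -> MarkerDataset:
    """Add iid zero-mean Gaussian noise (mm) per coordinate per frame."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    out = dataset.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for name in out.marker_names:
        arr = out.markers[name]
        arr += rng.normal(0.0, sigma, size=arr.shape)
    return out


def _apply_drift(
    traj: dict[str, np.ndarray],
    scenario: SyntheticScenario,
    n: int,
) -> dict[str, np.ndarray]:
    """Slow whole-scene rigid drift (subject repositioning); zero at frame 0."""
    s = scenario
    if s.drift_translation_mm == 0 and s.drift_rotation_deg == 0:
        return traj
    t = np.arange(n)
    w = np.sin(np.pi * t / max(n - 1, 1)) ** 2  # smooth, zero at both ends
    axis = np.array([0.3, 0.9, 0.3])
    axis /= np.linalg.norm(axis)
    ang = math.radians(s.drift_rotation_deg) * w
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = (
        np.eye(3)[None]
        + np.sin(ang)[:, None, None] * K[None]
        + (1 - np.cos(ang))[:, None, None] * (K @ K)[None]
    )
    direction = np.array([0.7, -0.5, 0.5])
    direction /= np.linalg.norm(direction)
    d = s.drift_translation_mm * w[:, None] * direction[None, :]
    return {name: np.einsum("fij,fj->fi", R, arr) + d for name, arr in traj.items()}


def build_recording(scenario: SyntheticScenario) -> SyntheticRecording:
    """Assemble a full synthetic recording from a scenario.

    Pipeline-facing outputs (noisy dataset, landmarks at the frame-0 pose,
    ready config) are bundled with the noiseless truth.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    gape, transitions = build_gape_trajectory(s, rng)
    n = gape.shape[0]
    bones, phi, tip = build_jaw_scene(gape, s)
    muscle, truth_arch = build_muscle_markers(tip, s, gape)

    traj = {**bones, **muscle}
    traj_lab = _apply_drift(traj, s, n)

    clean = MarkerDataset({k: v.copy() for k, v in traj_lab.items()}, frame_rate=s.frame_rate)
    noise_seed = int(rng.integers(2**31))
    noisy = add_noise(clean, s.noise_sigma_mm, seed=noise_seed)

    # landmarks in the frame-0 (reference) pose of the cranial frame
    center = np.asarray(s.rotation_center, dtype=float)
    R0 = _rot_ml(np.asarray([phi[0]]))[0]
    landmarks = LandmarkSet(
        {
            "coronoid_R": R0 @ (np.asarray(s.coronoid_tip) - center) + center,
            "gonial_R": R0 @ (np.asarray(s.gonial_right) - center) + center,
            "gonial_L": R0 @ (np.asarray(s.gonial_left) - center) + center,
        }
    )

    # true mandible transforms relative to the frame-0 pose
    R_all = _rot_ml(phi - phi[0])
    transforms = []
    for f in range(n):
        Rf = R_all[f]
        tf = center - Rf @ center
        transforms.append(RigidTransform(Rf, tf))

    occl = np.asarray(s.mandibular_markers["mand_ant"], dtype=float)

    truth = SyntheticGroundTruth(
        gape=gape,
        phi=phi,
        fascicle_length=truth_arch["fascicle_length"],
        theta_deg=truth_arch["theta_deg"],
        sagittal_deg=truth_arch["sagittal_deg"],
        coronal_deg=truth_arch["coronal_deg"],
        muscle_length=truth_arch["muscle_length"],
        agr=truth_arch["agr"],
        transitions=transitions,
        transforms=transforms,
        occlusion_position=occl,
    )

    config = PipelineConfig(
        cranial=tuple(s.cranial_markers),
        mandibular=tuple(s.mandibular_markers),
        anterior_mandible="mand_ant",
        frame_rate=s.frame_rate,
        subject=s.subject,
        food=s.food,
    )
    return SyntheticRecording(
        dataset=noisy,
        dataset_clean=clean,
        landmarks=landmarks,
        config=config,
        truth=truth,
        scenario=s,
    )


# ---------------------------------------------------------------------------
# simulated study
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """A simulated feeding study: one recording per subject x food."""

    recordings: list[SyntheticRecording]
    manifest: pd.DataFrame


def make_study(
    out_dir: str | Path | None = None,
    seed: int = 0,
    subjects: tuple[str, ...] = ("S1", "S2", "S3"),
    foods: dict[str, str] | None = None,
    cycles_per_food: tuple[int, ...] = (7, 7, 7, 6, 6),
    noise_sigma_mm: float = 0.15,
    base_scenario: SyntheticScenario | None = None,
) -> StudyData:
    """Generate a full simulated study (3 subjects x 5 foods by default).

    Mechanically challenging ("high" FMP) foods are chewed in the
    constant-pinnation (low-gear, reduced-rotation) mode, compliant ("low"
    FMP) foods in the constant-thickness (high-gear, rotating) mode, so the
    built-in FMP group difference in AGR is recoverable end to end.  Subjects
    differ in overall scale and reference pinnation.  Per-subject totals
    follow the target design of ~30-33 chewing cycles per animal.

    With ``out_dir`` set, marker CSVs, landmark CSVs, per-recording configs
    and truth/transition tables are written there; the in-memory study is
    returned either way.
    """
    foods = dict(foods) if foods is not None else dict(FOOD_FMP_GROUPS)
    if len(cycles_per_food) != len(foods):
        raise ValueError("need one cycle count per food")
    rng = np.random.default_rng(seed)
    base = base_scenario or SyntheticScenario()

    subject_scale = {sub: 0.95 + 0.05 * i for i, sub in enumerate(subjects)}
    subject_theta = {sub: 18.0 + 2.0 * i for i, sub in enumerate(subjects)}

    recs: list[SyntheticRecording] = []
    rows = []
    for sub in subjects:
        sc = subject_scale[sub]
        for (food, fmp), n_cycles in zip(foods.items(), cycles_per_food):
            mode = "constant_pinnation" if fmp == "high" else "constant_thickness"
            scen = replace(
                base,
                n_cycles=n_cycles,
                amplitude_mm=base.amplitude_mm * sc,
                amplitude_jitter=0.05,
                cranial_markers={k: tuple(np.array(v) * sc) for k, v in base.cranial_markers.items()},
                mandibular_markers={k: tuple(np.array(v) * sc) for k, v in base.mandibular_markers.items()},
                coronoid_tip=tuple(np.array(base.coronoid_tip) * sc),
                gonial_right=tuple(np.array(base.gonial_right) * sc),
                gonial_left=tuple(np.array(base.gonial_left) * sc),
                m3_position=tuple(np.array(base.m3_position) * sc),
                fascicle_ref_mm=base.fascicle_ref_mm * sc,
                tendon_length_mm=None,
                mode=mode,
                theta_ref_deg=subject_theta[sub],
                noise_sigma_mm=noise_sigma_mm,
                drift_translation_mm=0.5,
                drift_rotation_deg=0.5,
                seed=int(rng.integers(2**31)),
                subject=sub,
                food=food,
            )
            rec = build_recording(scen)
            recs.append(rec)
            rows.append(
                {
                    "subject": sub,
                    "food": food,
                    "fmp_group": fmp,
                    "n_cycles": n_cycles,
                    "mode": mode,
                    "true_agr_occlusion": float(rec.truth.agr[np.argmin(rec.truth.gape)]),
                }
            )
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in recs:
            tag = f"{rec.scenario.subject}_{rec.scenario.food}"
            write_marker_csv(rec.dataset, out / f"markers_{tag}.csv")
            write_landmarks(rec.landmarks, out / f"landmarks_{tag}.csv")
            rec.config.to_yaml(out / f"config_{tag}.yaml")
            truth_df = pd.DataFrame(
                {
                    "frame": np.arange(rec.truth.gape.shape[0]),
                    "gape": rec.truth.gape,
                    "fascicle_length": rec.truth.fascicle_length,
                    "theta_deg": rec.truth.theta_deg,
                    "muscle_length": rec.truth.muscle_length,
                    "agr": rec.truth.agr,
                }
            )
            truth_df.to_csv(out / f"truth_{tag}.csv", index=False)
            rec.truth.transitions_frame().to_csv(out / f"transitions_{tag}.csv", index=False)
        manifest.to_csv(out / "manifest.csv", index=False)

    return StudyData(recordings=recs, manifest=manifest)
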
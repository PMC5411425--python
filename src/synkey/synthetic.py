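"""Synthetic population generator: simulated grasp kinematics and rendered
hand-posture images, so every other module is testable without human data.

Kinematic model
---------------
Each simulated subject owns an orthonormal basis of ``k`` smooth synergy
matrices (10 joints x L samples): per-joint sums of Gaussian velocity bumps
with seeded centres, widths, and signs, orthonormalized by QR on the
flattened vectors.  A grasp of object ``o`` is a weighted mixture

    velocity = sum_i w_{o,i} * basis_i + noise

where the weights are fixed per (subject, object) — repetitions of the same
object differ only by the additive trial noise — and the weight scales are
set so that synergy 1 carries a configurable share of the expected weight
variance (default 0.54, the share the reference protocol attributes to the
first synergy).  Velocities are integrated to joint angles for output as
raw recordings, 151 samples at 125 Hz.

One randomly chosen joint of each first synergy carries a wide velocity
envelope that keeps its speed above the 5% segmentation threshold across the
whole window, so single-synergy (k = 1, noiseless) trials survive movement
segmentation untrimmed and the generator basis is exactly recoverable.

Population protocol
-------------------
The default population mirrors the reference study design: 10 subjects,
25 objects spanning 6 grasp types (4 objects per type, 5 for hook), 3
repetitions (repetition 1 = registration template, repetitions 2-3 = entry
attempts), and 4 extra follow-up entry sessions for the first 5 subjects —
giving 40 true and 180 false movement verification conditions.  Posture
attempts follow the same protocol: 2 authentic entry images per subject and
synergy (20 true conditions) and 2 imposter attempts by each of 5 imposter
subjects (10 false conditions per synergy).

Rendering
---------
Postures are drawn as white filled capsule digits plus a palm polygon on a
uniform green background (the chroma-key setting the imaging module
expects).  Authentic repeats apply a small seeded joint-angle jitter;
imposter attempts render the victim's posture with a larger jitter and the
imposter's own abduction habits (per-subject digit-axis offsets).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .errors import ConfigurationError, InvalidInputError
from .handmodel import HandGeometry, Posture, forward_kinematics, select_gain
from .joints import DIGITS, N_JOINTS
from .kinematics import (
    DEFAULT_LENGTH,
    DEFAULT_RATE,
    RawRecording,
    pad_to_fixed,
    segment_trial,
)
from .population import Population, Session, SubjectRecord, session_synergies
from .synergy import SynergySet

GRASP_TYPES: tuple[str, ...] = (
    "power",
    "precision",
    "hook",
    "tripod",
    "lateral_key",
    "spherical",
)


def default_objects() -> tuple[list[str], dict[str, str]]:
    """The 25-object taxonomy: 4 objects per grasp type, 5 for hook."""
    objects, types = [], {}
    for gtype in GRASP_TYPES:
        count = 5 if gtype == "hook" else 4
        for i in range(1, count + 1):
            name = f"{gtype}-{i}"
            objects.append(name)
            types[name] = gtype
    return objects, types


@dataclass
class SubjectSpec:
    """Latent description of one simulated subject."""

    subject_id: str
    basis: np.ndarray  # (k, 10, L), orthonormal when flattened
    dominant_share: float = 0.54
    noise_sd: float = 4.0  # deg/s additive white trial noise
    amplitude: float = 240.0  # weight scale, deg/s
    seed: int = 0
    handedness: str = "right"
    abduction_offsets: np.ndarray = field(
        default_factory=lambda: np.zeros(len(DIGITS))
    )

    def __post_init__(self):
        self.basis = np.asarray(self.basis, dtype=float)
        if not 0 < self.dominant_share < 1:
            raise InvalidInputError("dominant_share must be in (0, 1)")

    @property
    def k(self) -> int:
        return self.basis.shape[0]


@dataclass
class PopulationSpec:
    """Study-design parameters of a simulated population."""

    n_subjects: int = 10
    objects: list[str] | None = None  # default: the 25-object taxonomy
    repetitions: int = 3
    n_followup_subjects: int = 5
    followup_sessions: int = 4
    followup_drift: float = 0.15
    k: int = 10
    dominant_share: float = 0.54
    noise_sd: float = 4.0
    amplitude: float = 240.0
    rate: float = DEFAULT_RATE
    length: int = DEFAULT_LENGTH
    #: 'distinct' subjects, identical 'clone's, or jointly 'orthogonal' bases.
    mode: str = "distinct"
    seed: int = 0

    def resolve_objects(self) -> tuple[list[str], dict[str, str]]:
        if self.objects is None:
            return default_objects()
        return list(self.objects), {o: "custom" for o in self.objects}


@dataclass
class RenderSpec:
    resolution: int = 320
    window_mm: float = 260.0  # world window edge length rendered into the image
    angle_jitter_sd: float = 2.0  # degrees, authentic repeats
    imposter_jitter_sd: float = 4.0
    background: tuple[int, int, int] = (0, 150, 60)
    #: Internal supersampling factor: geometry is drawn at this multiple of
    #: the resolution and box-downsampled, giving subpixel-accurate edges the
    #: way a camera's optics antialias real silhouettes.
    supersample: int = 4

    def __post_init__(self):
        if self.resolution < 64:
            raise InvalidInputError("resolution must be >= 64")
        if self.supersample < 1:
            raise InvalidInputError("supersample must be >= 1")


# ---------------------------------------------------------------------------
# Subject and trial generation
# ---------------------------------------------------------------------------

def _smooth_raw_vector(
    rng: np.random.Generator, length: int, floor_joint: int | None
) -> np.ndarray:
    """One smooth (10, L) raw synergy: Gaussian bumps per joint."""
    t = np.arange(length, dtype=float)
    out = np.zeros((N_JOINTS, length))
    for j in range(N_JOINTS):
        n_bumps = rng.integers(2, 4)
        for _ in range(n_bumps):
            c = rng.uniform(15.0, min(125.0, length - 15.0))
            w = rng.uniform(6.0, 18.0)
            a = rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0])
            out[j] += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    if floor_joint is not None:
        c = rng.uniform(0.4 * length, 0.55 * length)
        w = rng.uniform(0.35 * length, 0.5 * length)
        out[floor_joint] += 1.2 * np.exp(-0.5 * ((t - c) / w) ** 2)
    return out


def _orthonormalize(raw: np.ndarray) -> np.ndarray:
    """QR-orthonormalize (k, 10, L) raw vectors on their flattened form.

    The first vector's direction is preserved (Gram-Schmidt order), and each
    vector's sign is canonicalized to match the extraction convention.
    """
    k = raw.shape[0]
    flat = raw.reshape(k, -1).T  # (10L, k)
    q, _ = np.linalg.qr(flat)
    q = q.T  # (k, 10L)
    for i in range(k):
        j = int(np.argmax(np.abs(q[i])))
        if q[i, j] < 0:
            q[i] *= -1.0
    return q.reshape(raw.shape)


def make_subject(
    seed: int,
    k: int = 10,
    dominant_share: float = 0.54,
    noise_sd: float = 4.0,
    amplitude: float = 240.0,
    length: int = DEFAULT_LENGTH,
    subject_id: str | None = None,
) -> SubjectSpec:
    """Build a subject with a seeded orthonormal smooth synergy basis."""
    if k > N_JOINTS * length:
        raise InvalidInputError("k exceeds the flattened dimension")
    rng = np.random.default_rng(seed)
    floor_joint = int(rng.integers(N_JOINTS))
    raw = np.stack(
        [
            _smooth_raw_vector(rng, length, floor_joint if i == 0 else None)
            for i in range(k)
        ]
    )
    basis = _orthonormalize(raw)
    abduction = rng.normal(0.0, 3.0, size=len(DIGITS))
    return SubjectSpec(
        subject_id=subject_id or f"S{seed}",
        basis=basis,
        dominant_share=dominant_share,
        noise_sd=noise_sd,
        amplitude=amplitude,
        seed=seed,
        abduction_offsets=abduction,
    )


def object_weights(subject: SubjectSpec, object_index: int) -> np.ndarray:
    """Mixing weights for one object; fixed across repetitions.

    Scales are chosen so synergy 1 carries ``dominant_share`` of the expected
    squared-weight total: ``E[w_1^2] = d * A^2`` (mean 1, sd 0.3 modulation)
    and the remaining share is split evenly over synergies 2..k.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([subject.seed & 0x7FFFFFFF, 71, object_index])
    )
    d = subject.dominant_share
    k = subject.k
    w = np.empty(k)
    a1 = subject.amplitude * np.sqrt(d / (1.0 + 0.3**2))
    w[0] = a1 * (1.0 + 0.3 * rng.standard_normal())
    if k > 1:
        ai = subject.amplitude * np.sqrt((1.0 - d) / (k - 1))
        w[1:] = ai * rng.standard_normal(k - 1)
    return w


def simulate_trials(
    subject: SubjectSpec,
    objects: list[str],
    repetition: int = 1,
    rng: np.random.Generator | None = None,
    rate: float = DEFAULT_RATE,
    object_types: dict[str, str] | None = None,
) -> list[RawRecording]:
    """One session: a noisy grasp recording for every object."""
    rng = np.random.default_rng(0) if rng is None else rng
    object_types = object_types or {}
    length = subject.basis.shape[2]
    recordings = []
    for idx, obj in enumerate(objects):
        w = object_weights(subject, idx)
        velocity = np.einsum("i,ijl->lj", w, subject.basis)  # (L, 10)
        if subject.noise_sd > 0:
            velocity = velocity + rng.normal(0.0, subject.noise_sd, velocity.shape)
        angles = np.cumsum(velocity, axis=0) / rate
        recordings.append(
            RawRecording(
                angles=angles,
                rate=rate,
                subject_id=subject.subject_id,
                object_id=obj,
                grasp_type=object_types.get(obj, ""),
                repetition=repetition,
            )
        )
    return recordings


def recordings_to_session(
    recordings: list[RawRecording],
    length: int = DEFAULT_LENGTH,
    threshold_fraction: float = 0.05,
) -> Session:
    """Segment and pad one session's recordings into fixed profiles."""
    profiles = [
        pad_to_fixed(segment_trial(r, threshold_fraction), length)
        for r in recordings
    ]
    return Session(profiles=profiles, objects=[r.object_id for r in recordings])


def _drifted(subject: SubjectSpec, drift: float, seed: int) -> SubjectSpec:
    """Follow-up version of a subject: basis perturbed and re-orthonormalized."""
    if drift <= 0:
        return subject
    rng = np.random.default_rng(seed)
    perturbation = np.stack(
        [_smooth_raw_vector(rng, subject.basis.shape[2], None) for _ in range(subject.k)]
    )
    perturbation /= np.linalg.norm(
        perturbation.reshape(subject.k, -1), axis=1
    )[:, None, None]
    basis = _orthonormalize(subject.basis + drift * perturbation)
    # A drift is a small rotation, never a reflection: align each drifted
    # vector with its source (element-wise sign canonicalization alone can
    # flip a vector when two peaks compete for the largest element).
    for i in range(subject.k):
        if float(basis[i].ravel() @ subject.basis[i].ravel()) < 0:
            basis[i] *= -1.0
    return SubjectSpec(
        subject_id=subject.subject_id,
        basis=basis,
        dominant_share=subject.dominant_share,
        noise_sd=subject.noise_sd,
        amplitude=subject.amplitude,
        seed=subject.seed,
        abduction_offsets=subject.abduction_offsets,
    )


@dataclass
class SimulatedPopulation:
    """A generated dataset plus the latent subject specifications."""

    population: Population
    subject_specs: list[SubjectSpec]
    spec: PopulationSpec


def make_population(spec: PopulationSpec) -> SimulatedPopulation:
    """Generate the full labelled dataset for a population specification."""
    objects, object_types = spec.resolve_objects()
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in root.spawn(spec.n_subjects)]
    noise_root = np.random.SeedSequence([spec.seed, 9291])

    if spec.mode == "clone":
        base = make_subject(
            subject_seeds[0], spec.k, spec.dominant_share, spec.noise_sd,
            spec.amplitude, spec.length,
        )
        specs = [
            SubjectSpec(
                subject_id=f"S{i:02d}",
                basis=base.basis,
                dominant_share=base.dominant_share,
                noise_sd=base.noise_sd,
                amplitude=base.amplitude,
                seed=base.seed,  # identical weights: clones share everything
                abduction_offsets=base.abduction_offsets,
            )
            for i in range(spec.n_subjects)
        ]
    else:
        specs = [
            make_subject(
                subject_seeds[i], spec.k, spec.dominant_share, spec.noise_sd,
                spec.amplitude, spec.length, subject_id=f"S{i:02d}",
            )
            for i in range(spec.n_subjects)
        ]
        if spec.mode == "orthogonal":
            stacked = np.concatenate([s.basis for s in specs])
            ortho = _orthonormalize(stacked)
            for i, s in enumerate(specs):
                s.basis = ortho[i * spec.k : (i + 1) * spec.k]
        elif spec.mode != "distinct":
            raise ConfigurationError(f"unknown population mode {spec.mode!r}")

    noise_streams = noise_root.spawn(spec.n_subjects)
    subjects = []
    for i, sub in enumerate(specs):
        rng = np.random.default_rng(noise_streams[i])
        sessions = []
        for rep in range(spec.repetitions):
            recs = simulate_trials(sub, objects, rep + 1, rng, spec.rate, object_types)
            sessions.append(recordings_to_session(recs, spec.length))
        if i < spec.n_followup_subjects:
            drifted = _drifted(sub, spec.followup_drift, seed=sub.seed ^ 0x5A5A)
            for rep in range(spec.followup_sessions):
                recs = simulate_trials(
                    drifted, objects, spec.repetitions + rep + 1, rng, spec.rate,
                    object_types,
                )
                sessions.append(recordings_to_session(recs, spec.length))
        subjects.append(
            SubjectRecord(subject_id=sub.subject_id, sessions=sessions,
                          n_primary_entries=spec.repetitions - 1)
        )
    population = Population(
        subjects=subjects, objects=objects, object_types=object_types
    )
    return SimulatedPopulation(population=population, subject_specs=specs, spec=spec)


def dataset_digest(sim: SimulatedPopulation) -> str:
    """Stable content digest of a simulated dataset (for determinism checks)."""
    h = hashlib.sha256()
    for sub in sim.population.subjects:
        for sess in sub.sessions:
            for p in sess.profiles:
                h.update(np.ascontiguousarray(p.velocity).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Posture rendering
# ---------------------------------------------------------------------------

def render_posture(
    spec: RenderSpec,
    geometry: HandGeometry,
    posture: Posture,
    abduction_offsets: np.ndarray | None = None,
    jitter_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render a posture as a white hand silhouette on the keyed background.

    Returns an ``(resolution, resolution, 3)`` uint8 RGB array; deterministic
    for a given seed.
    """
    rng = np.random.default_rng(seed)
    angles = posture.angles.copy()
    if jitter_sd > 0:
        angles = angles + rng.normal(0.0, jitter_sd, angles.shape)
    geom = geometry
    if abduction_offsets is not None:
        geom = HandGeometry(
            segments=geometry.segments,
            mcp_positions=geometry.mcp_positions,
            digit_axes={
                d: geometry.digit_axes[d] + float(abduction_offsets[i])
                for i, d in enumerate(DIGITS)
            },
            palm=geometry.palm,
            digit_width=geometry.digit_width,
        )
    chains = forward_kinematics(geom, Posture(angles=angles))

    # Exact world-space hand shape: palm polygon plus capsule digits.
    radius = geom.digit_width / 2.0
    parts = [Polygon(geom.palm)]
    for digit in DIGITS:
        pts = chains[digit]
        for a, b in zip(pts[:-1], pts[1:]):
            if np.hypot(*(b - a)) > 1e-9:
                parts.append(LineString([a, b]).buffer(radius, quad_segs=16))
            else:
                parts.append(Point(a).buffer(radius, quad_segs=16))
    shape = unary_union(parts)

    # Per-pixel coverage by unbiased subpixel point sampling; image row 0 is
    # the top of the world window.
    res = spec.resolution
    ss = spec.supersample
    half = spec.window_mm / 2.0
    mm_per_px = spec.window_mm / res
    sub = (np.arange(ss) + 0.5) / ss  # subpixel offsets in pixel units
    # Only pixels inside the shape's bounding box need point-in-polygon tests.
    minx, miny, maxx, maxy = shape.bounds
    c0 = max(0, int((minx + half) / mm_per_px) - 1)
    c1 = min(res, int(np.ceil((maxx + half) / mm_per_px)) + 1)
    r0 = max(0, int((half + 10.0 - maxy) / mm_per_px) - 1)
    r1 = min(res, int(np.ceil((half + 10.0 - miny) / mm_per_px)) + 1)
    coverage = np.zeros((res, res))
    if c1 > c0 and r1 > r0:
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        xs = (cols[:, None] + sub[None, :]).reshape(-1) * mm_per_px - half
        ys = (half + 10.0) - (rows[:, None] + sub[None, :]).reshape(-1) * mm_per_px
        gx, gy = np.meshgrid(xs, ys)  # row-major top-down
        inside = shapely.contains_xy(shape, gx.ravel(), gy.ravel()).reshape(gx.shape)
        coverage[r0:r1, c0:c1] = inside.reshape(
            rows.size, ss, cols.size, ss
        ).mean(axis=(1, 3))

    bg = np.array(spec.background, dtype=float)
    white = np.array([255.0, 255.0, 255.0])
    img = bg[None, None, :] + coverage[:, :, None] * (white - bg)[None, None, :]
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def subject_postures(
    sim_subject_spec: SubjectSpec,
    template_set: SynergySet,
    geometry: HandGeometry | None = None,
    rate: float = DEFAULT_RATE,
) -> list:
    """Postural synergies (gain-selected end postures) of a template set."""
    geometry = geometry or HandGeometry()
    postures = []
    for i in range(1, template_set.n + 1):
        postures.append(
            select_gain(
                template_set.synergy(i),
                geometry,
                rate,
                source_index=i,
                # Keep every finger well clear of the knuckle line so the
                # rendered silhouette retains five detectable fingertips.
                clearance=geometry.digit_width,
            )
        )
    return postures


def posture_attempt_plan(
    n_subjects: int = 10,
    n_synergies: int = 10,
    true_attempts: int = 2,
    n_imposter_subjects: int = 5,
    imposter_attempts: int = 2,
) -> list[dict]:
    """Attempt schedule mirroring the reference posture protocol.

    Per synergy: every subject makes ``true_attempts`` authentic entries
    (default 10 x 2 = 20 true conditions) and each of ``n_imposter_subjects``
    imposters makes ``imposter_attempts`` attempts at the next subject's
    template (default 5 x 2 = 10 false conditions).
    """
    plan = []
    for syn in range(1, n_synergies + 1):
        for s in range(n_subjects):
            for a in range(true_attempts):
                plan.append(
                    {"synergy": syn, "template_subject": s, "performer": s,
                     "attempt": a, "kind": "true"}
                )
        for imp in range(n_imposter_subjects):
            victim = (imp + 1) % n_subjects
            for a in range(imposter_attempts):
                plan.append(
                    {"synergy": syn, "template_subject": victim, "performer": imp,
                     "attempt": a, "kind": "false"}
                )
    return plan


def render_posture_attempts(
    sim: SimulatedPopulation,
    synergy_indices: list[int] | None = None,
    subjects: list[int] | None = None,
    render_spec: RenderSpec | None = None,
    geometry: HandGeometry | None = None,
    true_attempts: int = 2,
    imposter_attempts: int = 2,
    seed: int = 0,
    config=None,
) -> "pd.DataFrame":
    """Render and score authentic and imposter posture attempts.

    For each requested subject and synergy, the template posture is rendered
    once, authentic entries re-render it with the subject's own abduction
    habits and a small angle jitter, and imposter entries render the same
    target posture with the next subject's abduction habits and a larger
    jitter.  Returns one row per attempt with the summed per-finger error
    (infinite when the image analysis could not resolve five fingers).
    """
    import pandas as pd

    from .imaging import posture_verify

    render_spec = render_spec or RenderSpec()
    geometry = geometry or HandGeometry()
    synergy_indices = synergy_indices or [1]
    subject_ids = subjects if subjects is not None else range(len(sim.subject_specs))
    rows = []
    rng = np.random.default_rng(seed)
    for si in subject_ids:
        spec_i = sim.subject_specs[si]
        imposter = sim.subject_specs[(si + 1) % len(sim.subject_specs)]
        template_set = session_synergies(sim.population.subjects[si].sessions[0])
        postures = subject_postures(spec_i, template_set, geometry)
        for syn in synergy_indices:
            posture = postures[syn - 1].posture
            template_img = render_posture(
                render_spec, geometry, posture, spec_i.abduction_offsets
            )
            for kind, n_att, jitter, offsets in (
                ("true", true_attempts, render_spec.angle_jitter_sd,
                 spec_i.abduction_offsets),
                ("false", imposter_attempts, render_spec.imposter_jitter_sd,
                 imposter.abduction_offsets),
            ):
                for att in range(n_att):
                    entry_img = render_posture(
                        render_spec, geometry, posture, offsets,
                        jitter_sd=jitter, seed=int(rng.integers(2**31)),
                    )
                    score = posture_verify(
                        template_img, entry_img, T_p=float("inf"), config=config
                    )
                    rows.append(
                        {
                            "subject": si,
                            "synergy": syn,
                            "kind": kind,
                            "attempt": att,
                            "total_error": score.total,
                            "reason": score.reason,
                        }
                    )
    return pd.DataFrame(rows)


def posture_condition_counts(plan: list[dict]) -> tuple[int, int]:
    """(true, false) posture conditions per synergy in an attempt plan."""
    synergies = {p["synergy"] for p in plan}
    n_true = sum(1 for p in plan if p["kind"] == "true") // len(synergies)
    n_false = sum(1 for p in plan if p["kind"] == "false") // len(synergies)
    return n_true, n_false
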
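"""Population containers: per-subject sessions of fixed-length grasp profiles.

A *session* is one complete pass over the object set (one repetition of every
grasp); each session yields one synergy set.  Session 0 is the registration
session whose synergies form the stored template; later sessions are entry
attempts.  The first ``n_primary_entries`` entry sessions (default 2,
repetitions 2 and 3 of the protocol) also serve as imposter material against
other subjects; any further sessions are follow-up attempts and count toward
true attempts only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import ConfigurationError
from .kinematics import DEFAULT_RATE, FixedProfile
from .synergy import SynergySet, build_velocity_matrix, extract_synergies


@dataclass
class Session:
    """One repetition of the full grasp protocol for one subject."""

    profiles: list[FixedProfile]
    objects: list[str]

    def __post_init__(self):
        if len(self.profiles) != len(self.objects):
            raise ConfigurationError("one profile per object required")


@dataclass
class SubjectRecord:
    subject_id: str
    sessions: list[Session]  # sessions[0] is the registration/template session
    n_primary_entries: int = 2

    @property
    def entry_sessions(self) -> list[Session]:
        return self.sessions[1:]

    @property
    def primary_entry_sessions(self) -> list[Session]:
        return self.sessions[1 : 1 + self.n_primary_entries]


@dataclass
class Population:
    subjects: list[SubjectRecord]
    objects: list[str]
    object_types: dict[str, str] = field(default_factory=dict)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise ConfigurationError(f"unknown subject {subject_id!r}")


def session_synergies(
    session: Session,
    object_subset: list[str] | None = None,
    n: int = 10,
) -> SynergySet:
    """Extract a session's synergy set, optionally from a subset of objects."""
    if object_subset is None:
        profiles = session.profiles
    else:
        wanted = set(object_subset)
        profiles = [p for p, o in zip(session.profiles, session.objects) if o in wanted]
        if not profiles:
            raise ConfigurationError("object subset matches no session profiles")
    V = build_velocity_matrix(profiles)
    n_eff = min(n, min(V.V.shape))
    return extract_synergies(V, n=n_eff)


# ---------------------------------------------------------------------------
# HDF5 serialization
# ---------------------------------------------------------------------------

def save_population_h5(population: Population, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["objects"] = [o.encode() for o in population.objects]
        f.attrs["object_types"] = [
            f"{o}={t}".encode() for o, t in population.object_types.items()
        ]
        for sub in population.subjects:
            g = f.create_group(f"/subjects/{sub.subject_id}")
            g.attrs["n_primary_entries"] = sub.n_primary_entries
            for k, sess in enumerate(sub.sessions):
                arr = np.stack([p.velocity for p in sess.profiles])
                ds = g.create_dataset(f"sessions/{k}", data=arr)
                ds.attrs["objects"] = [o.encode() for o in sess.objects]
                ds.attrs["rate"] = sess.profiles[0].rate if sess.profiles else DEFAULT_RATE


def _as_str(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


def load_population_h5(path) -> Population:
    with h5py.File(path, "r") as f:
        objects = [_as_str(o) for o in f.attrs["objects"]]
        object_types = dict(
            _as_str(s).split("=", 1) for s in f.attrs.get("object_types", [])
        )
        subjects = []
        for sid in sorted(f["subjects"]):
            g = f[f"subjects/{sid}"]
            sessions = []
            for k in sorted(g["sessions"], key=int):
                ds = g[f"sessions/{k}"]
                objs = [_as_str(o) for o in ds.attrs["objects"]]
                rate = float(ds.attrs["rate"])
                arr = ds[()]
                profiles = [
                    FixedProfile(
                        velocity=arr[i],
                        rate=rate,
                        subject_id=sid,
                        object_id=objs[i],
                        repetition=int(k),
                    )
                    for i in range(arr.shape[0])
                ]
                sessions.append(Session(profiles=profiles, objects=objs))
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    sessions=sessions,
                    n_primary_entries=int(g.attrs["n_primary_entries"]),
                )
            )
    return Population(subjects=subjects, objects=objects, object_types=object_types)
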
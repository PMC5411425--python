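"""Spatiotemporal synergy extraction by truncated singular value decomposition.

Fixed-length velocity profiles (10 joints x L samples, L = 151 by default)
are flattened joint-major and stacked into a velocity matrix ``V`` of shape
``G x (10 L)`` — one row per grasp, 25 x 1510 for the reference protocol.
The economy SVD ``V = U S R'`` is taken on ``V`` directly (no mean-centering:
a ``center`` option exists for comparison but is off by default).  The first
``n`` right singular vectors, reshaped back to ``10 x L``, are the ranked
spatiotemporal synergies; the fraction of variance accounted for by synergy
``i`` is ``s_i^2 / sum_j s_j^2`` over all singular values.

Sign indeterminacy is resolved by canonicalizing each synergy so that its
largest-magnitude element is positive (the matching ``U`` column is flipped
with it, keeping the reconstruction identity intact).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .errors import InvalidInputError, ShapeError
from .joints import JOINT_NAMES, N_JOINTS
from .kinematics import DEFAULT_LENGTH, FixedProfile

DEFAULT_N_SYNERGIES: int = 10


@dataclass
class VelocityMatrix:
    """Stacked joint-major flattened velocity profiles, one grasp per row."""

    V: np.ndarray  # (G, n_joints * L)
    row_labels: list[str]
    n_joints: int = N_JOINTS
    length: int = DEFAULT_LENGTH

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim != 2 or self.V.shape[1] != self.n_joints * self.length:
            raise ShapeError(
                f"V must be (G, {self.n_joints * self.length}); got {self.V.shape}"
            )
        if len(self.row_labels) != self.V.shape[0]:
            raise ShapeError("row_labels must have one entry per row")

    @property
    def n_grasps(self) -> int:
        return self.V.shape[0]

    def unflatten(self, row: int) -> np.ndarray:
        """Reshape row ``row`` back to a ``(n_joints, L)`` profile."""
        return self.V[row].reshape(self.n_joints, self.length)


@dataclass
class SynergySet:
    """Ranked spatiotemporal synergies with singular values and variance."""

    synergies: np.ndarray  # (n, n_joints, L)
    singular_values: np.ndarray  # (n,) descending
    variance_fractions: np.ndarray  # (n,), of the total over ALL components
    weights: np.ndarray | None = None  # U_S, (G, n); kept for reconstruction

    def __post_init__(self):
        self.synergies = np.asarray(self.synergies, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        self.variance_fractions = np.asarray(self.variance_fractions, dtype=float)
        if self.synergies.ndim != 3:
            raise ShapeError("synergies must be (n, n_joints, L)")
        if np.any(np.diff(self.singular_values) > 1e-9):
            raise InvalidInputError("singular values must be non-increasing")

    @property
    def n(self) -> int:
        return self.synergies.shape[0]

    @property
    def n_joints(self) -> int:
        return self.synergies.shape[1]

    @property
    def length(self) -> int:
        return self.synergies.shape[2]

    def synergy(self, index: int) -> np.ndarray:
        """1-based access: ``synergy(1)`` is the top-ranked synergy."""
        if not 1 <= index <= self.n:
            raise InvalidInputError(f"synergy index {index} outside 1..{self.n}")
        return self.synergies[index - 1]

    def flattened(self) -> np.ndarray:
        """(n, n_joints*L) joint-major flattening of every synergy."""
        return self.synergies.reshape(self.n, -1)


def build_velocity_matrix(profiles: list[FixedProfile]) -> VelocityMatrix:
    """Stack fixed-length profiles into the grasp-by-feature matrix ``V``."""
    if not profiles:
        raise InvalidInputError("need at least one profile")
    L = profiles[0].length
    if any(p.length != L for p in profiles):
        raise ShapeError("all profiles must share the fixed length L")
    V = np.stack([p.flattened() for p in profiles])
    labels = [
        f"{p.subject_id}/{p.object_id}/{p.repetition}" for p in profiles
    ]
    return VelocityMatrix(V=V, row_labels=labels, length=L)


def extract_synergies(
    V: VelocityMatrix, n: int = DEFAULT_N_SYNERGIES, center: bool = False
) -> SynergySet:
    """Extract the first ``n`` ranked synergies from ``V`` by economy SVD."""
    M = V.V - V.V.mean(axis=0, keepdims=True) if center else V.V
    max_n = min(M.shape)
    if not 1 <= n <= max_n:
        raise InvalidInputError(f"n must be in 1..{max_n}; got {n}")
    if not np.all(np.isfinite(M)):
        raise InvalidInputError("V must be finite")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float(np.sum(s**2))
    fractions = (s[:n] ** 2) / total if total > 0 else np.zeros(n)
    components = Vt[:n].copy()
    weights = U[:, :n].copy()
    # Sign canonicalization: largest-|element| of each synergy made positive.
    for i in range(n):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            weights[:, i] *= -1.0
    return SynergySet(
        synergies=components.reshape(n, V.n_joints, V.length),
        singular_values=s[:n],
        variance_fractions=fractions,
        weights=weights,
    )


def reconstruct(V: VelocityMatrix, synergy_set: SynergySet) -> np.ndarray:
    """Rank-``n`` approximation ``V~ = U_S diag(s) R_S'`` of ``V``."""
    if synergy_set.weights is None:
        raise InvalidInputError("synergy set lacks weights; extract from V first")
    R_S = synergy_set.flattened()  # (n, n_joints*L)
    if R_S.shape[1] != V.V.shape[1] or synergy_set.weights.shape[0] != V.n_grasps:
        raise ShapeError("synergy set does not match V's shape")
    return (synergy_set.weights * synergy_set.singular_values) @ R_S


def variance_table(synergy_set: SynergySet) -> pd.DataFrame:
    """Per-synergy and cumulative fractions of variance accounted for."""
    frac = synergy_set.variance_fractions
    return pd.DataFrame(
        {
            "synergy": np.arange(1, synergy_set.n + 1),
            "variance_fraction": frac,
            "cumulative_fraction": np.cumsum(frac),
        }
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_synergies_h5(synergy_set: SynergySet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("synergies", data=synergy_set.synergies)
        f.create_dataset("singular_values", data=synergy_set.singular_values)
        f.create_dataset("variance_fractions", data=synergy_set.variance_fractions)
        if synergy_set.weights is not None:
            f.create_dataset("weights", data=synergy_set.weights)


def load_synergies_h5(path) -> SynergySet:
    with h5py.File(path, "r") as f:
        return SynergySet(
            synergies=f["synergies"][()],
            singular_values=f["singular_values"][()],
            variance_fractions=f["variance_fractions"][()],
            weights=f["weights"][()] if "weights" in f else None,
        )


def export_synergies_csv(synergy_set: SynergySet, path) -> None:
    """Human-readable export: one row per (synergy, sample) with joint columns."""
    rows = []
    for i in range(synergy_set.n):
        df = pd.DataFrame(synergy_set.synergies[i].T, columns=list(JOINT_NAMES))
        df.insert(0, "sample", np.arange(synergy_set.length))
        df.insert(0, "synergy", i + 1)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
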
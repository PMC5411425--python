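"""Virtual hand: posture construction from movement synergies.

A postural synergy is the end posture of a movement synergy: each joint's
velocity profile is integrated over time (rectangle rule) and multiplied by
the largest gain that keeps the posture displayable.  Two criteria bound the
gain:

1. every measured joint angle stays within the range of motion, taken as the
   glove calibration range [-10 deg, 90 deg];
2. no finger's distal interphalangeal (DIP) joint crosses the upper palm
   edge — checked on the virtual hand, with the gain reduced in 0.01
   decrements from the ROM-maximal gain until the DIP clears the palm.

The glove does not measure finger DIP joints, so the virtual hand couples
them anatomically as DIP = (2/3) PIP.  The thumb is held straight at its
default abduction during posture construction.

Geometry model
--------------
The hand is rendered in the front (camera) view.  Each digit is a chain of
segments leaving its MCP base along a fixed digit axis; flexion folds the
segments *out of the image plane*, so a segment of length ``l`` with
cumulative flexion ``theta`` advances the silhouette by ``l * cos(theta)``
along the digit axis.  Past 90 degrees of cumulative flexion the chain
doubles back toward the palm, which is exactly when the DIP joint crosses
the knuckle line (the upper palm edge) — the palm-crossing criterion.  This
projection model keeps neighbouring fingers from colliding laterally and
produces silhouettes that shorten under flexion the way photographed hands
do.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSynergyError, InvalidInputError
from .joints import DIGITS, DIGIT_JOINTS, N_JOINTS
from .kinematics import DEFAULT_RATE

ROM_DEG: tuple[float, float] = (-10.0, 90.0)
GAIN_DECREMENT: float = 0.01
#: Anatomical DIP/PIP coupling ratio for the four fingers.
DIP_COUPLING: float = 2.0 / 3.0


@dataclass
class HandGeometry:
    """Planar geometry of an average adult right hand, in millimetres.

    ``digit_axes`` are degrees from vertical (+y), positive toward the ulnar
    (pinky) side; ``segments`` are phalanx lengths base-to-tip (thumb has
    two, fingers three).
    """

    segments: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "thumb": (26.0, 20.0),
            "index": (30.0, 18.0, 13.0),
            "middle": (33.0, 20.0, 14.0),
            "ring": (30.0, 18.0, 13.0),
            "pinky": (24.0, 15.0, 11.0),
        }
    )
    mcp_positions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "thumb": (-42.0, 0.0),
            "index": (-23.0, 0.0),
            "middle": (-1.0, 0.0),
            "ring": (21.0, 0.0),
            "pinky": (42.0, 0.0),
        }
    )
    digit_axes: dict[str, float] = field(
        default_factory=lambda: {
            "thumb": -35.0,
            "index": -9.0,
            "middle": 0.0,
            "ring": 9.0,
            "pinky": 19.0,
        }
    )
    #: Simple palm outline polygon (x, y), y up, knuckle line at y = 0.  The
    #: palm is deep relative to the digits so the silhouette centroid sits
    #: well below the knuckle line, as in a wrist-cropped hand photograph;
    #: shallow V-notches between adjacent digit bases model the inter-finger
    #: webs, giving the radial profile sharp, well-localized valleys.
    palm: tuple[tuple[float, float], ...] = (
        (-50.0, 0.0),
        (-42.0, 0.0),
        (-32.5, -3.0),
        (-23.0, 0.0),
        (-12.0, -3.0),
        (-1.0, 0.0),
        (10.0, -3.0),
        (21.0, 0.0),
        (31.5, -3.0),
        (42.0, 0.0),
        (50.0, 0.0),
        (47.0, -110.0),
        (-47.0, -110.0),
    )
    digit_width: float = 12.0

    def __post_init__(self):
        for d, lengths in self.segments.items():
            if any(l <= 0 for l in lengths):
                raise InvalidInputError(f"non-positive segment length for {d}")

    @property
    def palm_top(self) -> float:
        return max(y for _, y in self.palm)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "segments": self.segments,
                    "mcp_positions": self.mcp_positions,
                    "digit_axes": self.digit_axes,
                    "palm": self.palm,
                    "digit_width": self.digit_width,
                },
                f,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "HandGeometry":
        with open(path) as f:
            raw = json.load(f)
        return cls(
            segments={k: tuple(v) for k, v in raw["segments"].items()},
            mcp_positions={k: tuple(v) for k, v in raw["mcp_positions"].items()},
            digit_axes=raw["digit_axes"],
            palm=tuple(tuple(p) for p in raw["palm"]),
            digit_width=raw["digit_width"],
        )


@dataclass
class Posture:
    """Ten joint angles in degrees, canonical joint order."""

    angles: np.ndarray

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != (N_JOINTS,):
            raise InvalidInputError(f"posture needs {N_JOINTS} angles")

    def digit_flexions(self, digit: str) -> tuple[float, ...]:
        """(MCP, IP) for the thumb; (MCP, PIP, DIP) for fingers, degrees."""
        mcp, pip = DIGIT_JOINTS[digit]
        if digit == "thumb":
            return (float(self.angles[mcp]), float(self.angles[pip]))
        return (
            float(self.angles[mcp]),
            float(self.angles[pip]),
            DIP_COUPLING * float(self.angles[pip]),
        )


@dataclass
class PosturalSynergy:
    posture: Posture
    source_index: int
    gain: float


def integrate_synergy(
    synergy: np.ndarray, gain: float = 1.0, rate: float = DEFAULT_RATE
) -> Posture:
    """Final joint angles from a velocity synergy: gain * sum_t v(t) / rate."""
    synergy = np.asarray(synergy, dtype=float)
    if not rate > 0:
        raise InvalidInputError("rate must be positive")
    if synergy.ndim != 2 or synergy.shape[0] != N_JOINTS:
        raise InvalidInputError(f"synergy must be ({N_JOINTS}, L)")
    return Posture(angles=gain * synergy.sum(axis=1) / rate)


def forward_kinematics(
    geometry: HandGeometry, posture: Posture
) -> dict[str, np.ndarray]:
    """Per-digit joint positions in the image plane, millimetres.

    Each digit returns ``(n_segments + 1, 2)`` points: the MCP base, then the
    joint after each phalanx.  For fingers the third point (after two
    phalanges) is the DIP joint.  Flexion folds out of the plane, so each
    phalanx advances its length times the cosine of the cumulative flexion
    along the (fixed) digit axis.
    """
    chains = {}
    for digit in DIGITS:
        base = np.array(geometry.mcp_positions[digit], dtype=float)
        axis_deg = geometry.digit_axes[digit]
        axis = np.array(
            [math.sin(math.radians(axis_deg)), math.cos(math.radians(axis_deg))]
        )
        flexions = posture.digit_flexions(digit)
        points = [base]
        cumulative = 0.0
        pos = base.copy()
        for length, flex in zip(geometry.segments[digit], flexions):
            cumulative += flex
            pos = pos + length * math.cos(math.radians(cumulative)) * axis
            points.append(pos.copy())
        chains[digit] = np.array(points)
    return chains


def crosses_palm(geometry: HandGeometry, chain: np.ndarray) -> bool:
    """True iff the DIP joint lies strictly palm-side of the upper palm edge.

    ``chain`` is a finger chain from :func:`forward_kinematics` (4 points);
    the DIP joint is the point after the first two phalanges.  A DIP exactly
    on the edge does not count as crossing.
    """
    dip_y = float(chain[2, 1])
    return dip_y < geometry.palm_top


def _posture_at(synergy_unit_angles: np.ndarray, gain: float) -> Posture:
    return Posture(angles=gain * synergy_unit_angles)


def select_gain(
    synergy: np.ndarray,
    geometry: HandGeometry | None = None,
    rate: float = DEFAULT_RATE,
    rom: tuple[float, float] = ROM_DEG,
    decrement: float = GAIN_DECREMENT,
    straight_thumb: bool = True,
    source_index: int = 1,
    clearance: float = 0.0,
) -> PosturalSynergy:
    """Largest gain meeting the ROM and palm-crossing criteria.

    The ROM-maximal gain ``g0`` has a closed form (the tightest ROM bound
    over joints); the palm criterion is then enforced by stepping the gain
    down in ``decrement`` (0.01) increments until no finger DIP crosses the
    upper palm edge.  ``clearance`` optionally requires the DIP to stay that
    many millimetres above the edge — used when postures feed the silhouette
    renderer, where a finger whose DIP merely touches the knuckle line
    leaves no visible peak for the image analysis to find.
    """
    geometry = geometry or HandGeometry()
    unit = integrate_synergy(synergy, gain=1.0, rate=rate).angles
    if straight_thumb:
        unit = unit.copy()
        unit[0:2] = 0.0
    lo, hi = rom
    if np.max(np.abs(unit)) < 1e-12:
        raise DegenerateSynergyError("synergy integrates to a zero posture")
    bounds = np.where(unit > 0, hi / np.maximum(unit, 1e-300), np.inf)
    neg = unit < 0
    bounds = np.minimum(bounds, np.where(neg, lo / np.where(neg, unit, -1.0), np.inf))
    g0 = float(np.min(bounds))
    gain = g0
    while gain > 0:
        posture = _posture_at(unit, gain)
        chains = forward_kinematics(geometry, posture)
        if not any(
            chains[d][2, 1] < geometry.palm_top + clearance
            for d in DIGITS
            if d != "thumb"
        ):
            break
        gain -= decrement
    if gain <= 0:
        raise DegenerateSynergyError("no compliant gain >= 0 found")
    return PosturalSynergy(
        posture=_posture_at(unit, gain), source_index=source_index, gain=gain
    )
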
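"""Canonical labelling of the ten instrumented hand joints.

The data glove measures two joints per digit: the metacarpophalangeal (MCP)
and interphalangeal (IP) joints of the thumb, and the MCP and proximal
interphalangeal (PIP) joints of the four fingers.  Distal interphalangeal
(DIP) joints and abduction/wrist channels are not recorded.

Canonical order is thumb to pinky, MCP before IP/PIP within a digit.  Every
array in this package with a joint axis follows this order.
"""

from __future__ import annotations

from enum import Enum


class Joint(str, Enum):
    T_MCP = "T_MCP"
    T_IP = "T_IP"
    I_MCP = "I_MCP"
    I_PIP = "I_PIP"
    M_MCP = "M_MCP"
    M_PIP = "M_PIP"
    R_MCP = "R_MCP"
    R_PIP = "R_PIP"
    P_MCP = "P_MCP"
    P_PIP = "P_PIP"


#: Canonical joint order used for every joint-indexed array.
JOINT_ORDER: tuple[Joint, ...] = tuple(Joint)

#: Column names in canonical order (for tabular I/O).
JOINT_NAMES: tuple[str, ...] = tuple(j.value for j in JOINT_ORDER)

N_JOINTS: int = len(JOINT_ORDER)

#: Digits in radial-to-ulnar order; each maps to its (MCP, IP/PIP) indices.
DIGITS: tuple[str, ...] = ("thumb", "index", "middle", "ring", "pinky")

DIGIT_JOINTS: dict[str, tuple[int, int]] = {
    "thumb": (0, 1),
    "index": (2, 3),
    "middle": (4, 5),
    "ring": (6, 7),
    "pinky": (8, 9),
}

#: MCP joint indices (one per digit) and IP/PIP indices.
MCP_INDICES: tuple[int, ...] = (0, 2, 4, 6, 8)
PIP_INDICES: tuple[int, ...] = (1, 3, 5, 7, 9)
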
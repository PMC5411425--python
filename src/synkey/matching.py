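"""Template-vs-entry synergy matching.

The verification statistic is the *summed correlation*: for a pair of
synergies (each 10 joints x L samples) the Pearson correlation of the two
velocity profiles is computed per joint and summed over the joints included
in the active :class:`JointMask`, so the maximum attainable score equals the
number of included joints (10 with all joints).  Before the correlation is
taken, the entry synergy may be time-shifted by up to +/-20 samples (160 ms
at 125 Hz) with zero fill, to absorb timing variation; the maximizing shift
is kept, with ties broken toward the smaller |shift| and then the negative
shift.

Because the ranking of synergies can differ between sessions, template
synergies are paired greedily in rank order: template synergy 1 takes the
available entry synergy with the highest shifted summed correlation, which
is then removed from the pool, and so on.  A chance baseline is obtained by
permuting contiguous time bins of each joint profile (8 bins of 20 samples,
the last bin 11 samples when L = 151) and re-running the same comparison.

Correlations are computed over the full padded L samples; a profile with
zero variance in the compared window contributes 0 (not NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, ShapeError
from .joints import JOINT_NAMES, MCP_INDICES, N_JOINTS, PIP_INDICES
from .synergy import SynergySet

DEFAULT_MAX_SHIFT: int = 20
DEFAULT_BINS: int = 8
DEFAULT_BIN_LENGTH: int = 20


# ---------------------------------------------------------------------------
# Joint masks
# ---------------------------------------------------------------------------

def _minus_digit(mcp: int, pip: int) -> tuple[int, ...]:
    return tuple(i for i in range(N_JOINTS) if i not in (mcp, pip))


MASK_PRESETS: dict[str, tuple[int, ...]] = {
    "all": tuple(range(N_JOINTS)),
    "mcp_only": MCP_INDICES,
    "pip_only": PIP_INDICES,
    "minus_thumb": _minus_digit(0, 1),
    "minus_index": _minus_digit(2, 3),
    "minus_middle": _minus_digit(4, 5),
    "minus_ring": _minus_digit(6, 7),
    "minus_pinky": _minus_digit(8, 9),
}


@dataclass(frozen=True)
class JointMask:
    """A non-empty subset of the ten joints used in the comparison."""

    included: tuple[int, ...]
    name: str = "custom"

    def __post_init__(self):
        if len(self.included) == 0:
            raise InvalidInputError("joint mask must be non-empty")
        if len(set(self.included)) != len(self.included):
            raise InvalidInputError("joint mask has duplicate joints")
        if any(not 0 <= i < N_JOINTS for i in self.included):
            raise InvalidInputError("joint index outside 0..9")

    @classmethod
    def preset(cls, name: str) -> "JointMask":
        try:
            return cls(included=MASK_PRESETS[name], name=name)
        except KeyError:
            raise InvalidInputError(
                f"unknown mask preset {name!r}; choose from {sorted(MASK_PRESETS)}"
            ) from None

    def __len__(self) -> int:
        return len(self.included)

    @property
    def joint_names(self) -> tuple[str, ...]:
        return tuple(JOINT_NAMES[i] for i in self.included)


@dataclass
class PairScore:
    """Best alignment of one template synergy with one entry synergy."""

    template_index: int  # 1-based rank of the template synergy
    entry_index: int  # 1-based rank of the paired entry synergy
    shift: int  # samples; positive = entry delayed
    summed_correlation: float


@dataclass
class MatchResult:
    """Greedy one-to-one pairing between a template and an entry synergy set."""

    pairs: list[PairScore]
    mask: JointMask

    @property
    def total_score(self) -> float:
        return float(sum(p.summed_correlation for p in self.pairs))

    def pair_for(self, template_index: int) -> PairScore:
        for p in self.pairs:
            if p.template_index == template_index:
                return p
        raise InvalidInputError(f"no pair for template synergy {template_index}")


# ---------------------------------------------------------------------------
# Correlation primitives
# ---------------------------------------------------------------------------

def joint_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two 1-D profiles; 0 if either has zero variance."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ShapeError(f"length mismatch: {a.shape} vs {b.shape}")
    am = a - a.mean()
    bm = b - b.mean()
    na = np.linalg.norm(am)
    nb = np.linalg.norm(bm)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(am @ bm / (na * nb))


def shift_values(max_shift: int) -> np.ndarray:
    """Shift grid ordered by the tie-break rule: |s| ascending, negative first."""
    s = np.arange(-max_shift, max_shift + 1)
    order = sorted(range(len(s)), key=lambda k: (abs(int(s[k])), int(s[k])))
    return s[order]


def _shift_stack(profiles: np.ndarray, max_shift: int) -> np.ndarray:
    """All zero-filled shifts of ``(J, L)`` profiles -> ``(n_shifts, J, L)``.

    Row k holds the profiles delayed by ``shift_values(max_shift)[k]`` samples
    (positive shift: zeros enter at the head).
    """
    J, L = profiles.shape
    if max_shift >= L:
        raise InvalidInputError("max_shift must be smaller than the profile length")
    shifts = shift_values(max_shift)
    padded = np.zeros((J, L + 2 * max_shift))
    padded[:, max_shift : max_shift + L] = profiles
    idx = np.arange(L)[None, :] - shifts[:, None] + max_shift  # (n_shifts, L)
    return padded[:, idx].transpose(1, 0, 2)


def _pearson_vs_stack(x: np.ndarray, stack: np.ndarray) -> np.ndarray:
    """Per-joint Pearson r of ``x`` (J, L) against every shift in ``stack``.

    Returns ``(n_shifts, J)``; zero-variance profiles contribute 0.
    """
    xm = x - x.mean(axis=1, keepdims=True)
    ym = stack - stack.mean(axis=2, keepdims=True)
    num = np.einsum("jl,sjl->sj", xm, ym)
    nx = np.linalg.norm(xm, axis=1)  # (J,)
    ny = np.linalg.norm(ym, axis=2)  # (S, J)
    den = nx[None, :] * ny
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def pairwise_correlation_tensor(
    template: SynergySet, entry: SynergySet, max_shift: int = DEFAULT_MAX_SHIFT
) -> np.ndarray:
    """Per-joint correlations at every shift for every synergy pair.

    Returns ``(n_template, n_entry, n_shifts, n_joints)`` with the shift axis
    following :func:`shift_values` order, so that the first argmax along it
    honours the tie-break rule.
    """
    if template.length != entry.length:
        raise ShapeError("template and entry synergy sets must share L")
    nt, ne = template.n, entry.n
    n_shifts = 2 * max_shift + 1
    out = np.empty((nt, ne, n_shifts, template.n_joints))
    for e in range(ne):
        stack = _shift_stack(entry.synergies[e], max_shift)
        for t in range(nt):
            out[t, e] = _pearson_vs_stack(template.synergies[t], stack)
    return out


def shifted_summed_correlation(
    template: np.ndarray,
    entry: np.ndarray,
    mask: JointMask,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> PairScore:
    """Best shift-aligned summed per-joint correlation of two synergies."""
    template = np.asarray(template, dtype=float)
    entry = np.asarray(entry, dtype=float)
    if template.shape != entry.shape:
        raise ShapeError("template and entry must share shape (n_joints, L)")
    stack = _shift_stack(entry, max_shift)
    r = _pearson_vs_stack(template, stack)  # (n_shifts, J)
    summed = r[:, list(mask.included)].sum(axis=1)
    k = int(np.argmax(summed))  # first max wins: tie-break by shift order
    return PairScore(
        template_index=1,
        entry_index=1,
        shift=int(shift_values(max_shift)[k]),
        summed_correlation=float(summed[k]),
    )


def _greedy_from_scores(
    scores: np.ndarray, shifts: np.ndarray, n_pairs: int
) -> list[tuple[int, int, int, float]]:
    """Greedy rank-order pairing from precomputed (nt, ne) best-shift scores."""
    nt, ne = scores.shape
    available = list(range(ne))
    pairs = []
    for t in range(min(n_pairs, nt, ne)):
        col = int(available[int(np.argmax(scores[t, available]))])
        available.remove(col)
        pairs.append((t + 1, col + 1, int(shifts[t, col]), float(scores[t, col])))
    return pairs


def best_shift_scores(
    tensor: np.ndarray, mask: JointMask, max_shift: int = DEFAULT_MAX_SHIFT
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a correlation tensor to best-shift summed scores per pair.

    Returns ``(scores, shifts)`` of shape ``(n_template, n_entry)``.
    """
    summed = tensor[:, :, :, list(mask.included)].sum(axis=3)
    k = np.argmax(summed, axis=2)
    scores = np.take_along_axis(summed, k[:, :, None], axis=2)[:, :, 0]
    shifts = shift_values(max_shift)[k]
    return scores, shifts


def pair_synergies(
    template: SynergySet,
    entry: SynergySet,
    mask: JointMask,
    max_shift: int = DEFAULT_MAX_SHIFT,
    n_pairs: int | None = None,
    method: str = "greedy",
) -> MatchResult:
    """Pair ranked template synergies with entry synergies.

    ``method='greedy'`` (default) processes templates in rank order, each
    taking the best available entry synergy and removing it from the pool.
    ``method='hungarian'`` solves the optimal assignment instead (comparison
    mode, not the default behaviour).
    """
    if template.n == 0 or entry.n == 0:
        raise InvalidInputError("both synergy sets must be non-empty")
    n_pairs = min(template.n, entry.n) if n_pairs is None else n_pairs
    # Greedy pairing of the first n_pairs templates only ever consults the
    # correlations of those templates, so the tensor is restricted to them.
    template_used = template
    if method == "greedy" and n_pairs < template.n:
        template_used = SynergySet(
            synergies=template.synergies[:n_pairs],
            singular_values=template.singular_values[:n_pairs],
            variance_fractions=template.variance_fractions[:n_pairs],
        )
    tensor = pairwise_correlation_tensor(template_used, entry, max_shift)
    scores, shifts = best_shift_scores(tensor, mask, max_shift)
    if method == "greedy":
        raw = _greedy_from_scores(scores, shifts, n_pairs)
    elif method == "hungarian":
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-scores)
        raw = [
            (int(r) + 1, int(c) + 1, int(shifts[r, c]), float(scores[r, c]))
            for r, c in zip(rows, cols)
        ][:n_pairs]
    else:
        raise InvalidInputError(f"unknown pairing method {method!r}")
    pairs = [PairScore(*p) for p in raw]
    return MatchResult(pairs=pairs, mask=mask)


# ---------------------------------------------------------------------------
# Chance baseline
# ---------------------------------------------------------------------------

def bin_slices(length: int, bins: int = DEFAULT_BINS, bin_length: int = DEFAULT_BIN_LENGTH):
    """Contiguous time bins: bins-1 of ``bin_length`` samples, then the rest."""
    if bins * bin_length < length:
        raise InvalidInputError("bins * bin_length must cover the profile")
    last = length - (bins - 1) * bin_length
    if last < 1:
        raise InvalidInputError("last bin would be empty; reduce bins or bin_length")
    edges = [i * bin_length for i in range(bins)] + [length]
    return [slice(edges[i], edges[i + 1]) for i in range(bins)]


def shuffle_joint_profile(
    profile: np.ndarray,
    bins: int = DEFAULT_BINS,
    bin_length: int = DEFAULT_BIN_LENGTH,
    permutation: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Permute the time bins of a single joint's L-sample profile."""
    profile = np.asarray(profile, dtype=float).ravel()
    slices = bin_slices(profile.size, bins, bin_length)
    if permutation is None:
        if rng is None:
            raise InvalidInputError("provide a permutation or an rng")
        permutation = rng.permutation(bins)
    return np.concatenate([profile[slices[p]] for p in permutation])


def shuffle_synergy_set(
    synergy_set: SynergySet,
    bins: int = DEFAULT_BINS,
    bin_length: int = DEFAULT_BIN_LENGTH,
    rng: np.random.Generator | None = None,
) -> SynergySet:
    """Independently bin-shuffle every joint profile of every synergy."""
    rng = np.random.default_rng() if rng is None else rng
    shuffled = np.empty_like(synergy_set.synergies)
    for i in range(synergy_set.n):
        for j in range(synergy_set.n_joints):
            shuffled[i, j] = shuffle_joint_profile(
                synergy_set.synergies[i, j], bins, bin_length, rng=rng
            )
    return SynergySet(
        synergies=shuffled,
        singular_values=synergy_set.singular_values,
        variance_fractions=synergy_set.variance_fractions,
    )


def chance_baseline(
    template: SynergySet,
    entry: SynergySet,
    mask: JointMask,
    bins: int = DEFAULT_BINS,
    bin_length: int = DEFAULT_BIN_LENGTH,
    draws: int = 100,
    seed: int | None = None,
    synergy_indices: frozenset[int] | set[int] = frozenset({1}),
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> np.ndarray:
    """Distribution of chance scores from bin-shuffled entries.

    Each draw permutes the time bins of every joint profile of the entry set,
    re-runs the greedy pairing, and records the summed correlation of the
    designated synergy pairs (synergy 1 by default).  Returns ``(draws,)``.
    """
    bin_slices(template.length, bins, bin_length)  # validate binning early
    indices = sorted(synergy_indices)
    if any(not 1 <= i <= template.n for i in indices):
        raise InvalidInputError("synergy indices outside 1..n")
    rng = np.random.default_rng(seed)
    out = np.empty(draws)
    for d in range(draws):
        shuffled = shuffle_synergy_set(entry, bins, bin_length, rng=rng)
        match = pair_synergies(
            template, shuffled, mask, max_shift=max_shift, n_pairs=max(indices)
        )
        out[d] = sum(match.pair_for(i).summed_correlation for i in indices)
    return out


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

@dataclass
class VerifyResult:
    accepted: bool
    score_percent: float
    threshold: float
    match: MatchResult


def match_score_percent(
    match: MatchResult, synergy_indices, mask: JointMask
) -> float:
    """Summed correlation of the designated pairs, as percent of the maximum.

    The maximum is ``|mask| * |indices|`` (each joint correlation caps at 1).
    """
    indices = sorted(synergy_indices)
    total = sum(match.pair_for(i).summed_correlation for i in indices)
    return 100.0 * total / (len(mask) * len(indices))


def verify(
    template: SynergySet,
    entry: SynergySet,
    mask: JointMask,
    synergy_indices: frozenset[int] | set[int] = frozenset({1}),
    T_m: float = 70.0,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> VerifyResult:
    """Accept the entry iff its percent-of-maximum score strictly exceeds T_m.

    ``T_m`` is expressed as percent of the configuration's maximum so that
    thresholds are comparable across joint masks and index sets.
    """
    indices = sorted(synergy_indices)
    if not indices or any(not 1 <= i <= min(template.n, entry.n) for i in indices):
        raise InvalidInputError(f"synergy indices {indices} outside 1..n")
    match = pair_synergies(template, entry, mask, max_shift, n_pairs=max(indices))
    score = match_score_percent(match, indices, mask)
    return VerifyResult(
        accepted=bool(score > T_m), score_percent=score, threshold=T_m, match=match
    )
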
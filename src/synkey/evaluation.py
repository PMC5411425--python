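"""Population-level biometric evaluation.

True (authentic) scores come from each subject's entry sessions matched
against that subject's own template synergies; false (imposter) scores come
from every other subject's primary entry sessions matched against the same
template.  With the reference protocol (10 subjects, 2 primary entry
sessions each, 5 subjects with 4 extra follow-up sessions) this yields
40 true and 180 false conditions.

The equal error rate (EER) is the operating point where the false acceptance
rate FAR(t) = #(false > t)/#false and the false rejection rate
FRR(t) = #(true <= t)/#true cross; both are evaluated over the sorted union
of observed scores plus midpoints, and the crossing is linearly interpolated
between the two bracketing thresholds.  The accept rule is strict
(score > t), matching :func:`synkey.matching.verify`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .matching import (
    DEFAULT_MAX_SHIFT,
    JointMask,
    MASK_PRESETS,
    best_shift_scores,
    match_score_percent,
    pair_synergies,
    pairwise_correlation_tensor,
)
from .population import Population, SubjectRecord, session_synergies
from .synergy import SynergySet


@dataclass
class ScoreSet:
    """Authentic and imposter percent-of-maximum scores with provenance."""

    true_scores: np.ndarray
    false_scores: np.ndarray
    labels: pd.DataFrame  # columns: subject, entry_subject, session, kind

    def __post_init__(self):
        self.true_scores = np.asarray(self.true_scores, dtype=float)
        self.false_scores = np.asarray(self.false_scores, dtype=float)


@dataclass
class EERResult:
    thresholds: np.ndarray
    far: np.ndarray  # percent
    frr: np.ndarray  # percent
    eer: float  # percent
    eer_threshold: float


@dataclass
class ObjectRanking:
    """Objects ordered by how much their omission reduced imposter scores."""

    ranked_objects: list[str]
    deltas: dict[str, float]  # positive = omission decreased false correlation


# ---------------------------------------------------------------------------
# Score collection
# ---------------------------------------------------------------------------

def _session_sets(
    population: Population,
    object_subset: list[str] | None,
    n: int,
) -> dict[tuple[str, int], SynergySet]:
    sets = {}
    for sub in population.subjects:
        if not sub.sessions:
            raise ConfigurationError(f"subject {sub.subject_id} has no sessions")
        if len(sub.sessions) < 2:
            raise ConfigurationError(
                f"subject {sub.subject_id} has a template but no entry session"
            )
        for k, sess in enumerate(sub.sessions):
            sets[(sub.subject_id, k)] = session_synergies(sess, object_subset, n)
    return sets


def iter_comparisons(population: Population):
    """Yield (template_subject, entry_subject, entry_session_index, is_true).

    True attempts: every entry session of the template's owner.  False
    attempts: the primary entry sessions of every other subject.
    """
    for sub in population.subjects:
        for k in range(1, len(sub.sessions)):
            yield (sub.subject_id, sub.subject_id, k, True)
        for other in population.subjects:
            if other.subject_id == sub.subject_id:
                continue
            for k in range(1, 1 + min(other.n_primary_entries, len(other.sessions) - 1)):
                yield (sub.subject_id, other.subject_id, k, False)


def collect_scores(
    population: Population,
    mask: JointMask,
    synergy_indices: frozenset[int] | set[int] = frozenset({1}),
    object_subset: list[str] | None = None,
    n: int = 10,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> ScoreSet:
    """Percent-of-maximum matched scores for every authentic/imposter attempt."""
    indices = sorted(synergy_indices)
    sets = _session_sets(population, object_subset, n)
    true_scores, false_scores, rows = [], [], []
    for tmpl_sid, entry_sid, k, is_true in iter_comparisons(population):
        template = sets[(tmpl_sid, 0)]
        entry = sets[(entry_sid, k)]
        match = pair_synergies(
            template, entry, mask, max_shift, n_pairs=max(indices)
        )
        score = match_score_percent(match, indices, mask)
        (true_scores if is_true else false_scores).append(score)
        rows.append(
            {
                "subject": tmpl_sid,
                "entry_subject": entry_sid,
                "session": k,
                "kind": "true" if is_true else "false",
                "score": score,
            }
        )
    return ScoreSet(
        true_scores=np.array(true_scores),
        false_scores=np.array(false_scores),
        labels=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# EER
# ---------------------------------------------------------------------------

def far_frr(
    true_scores: np.ndarray, false_scores: np.ndarray, thresholds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical rates (percent) under the strict accept-if-greater rule."""
    t = np.asarray(thresholds)[:, None]
    far = 100.0 * (np.asarray(false_scores)[None, :] > t).mean(axis=1)
    frr = 100.0 * (np.asarray(true_scores)[None, :] <= t).mean(axis=1)
    return far, frr


def compute_eer(
    true_scores: np.ndarray | ScoreSet, false_scores: np.ndarray | None = None
) -> EERResult:
    """EER at the FAR/FRR crossing, linearly interpolated between thresholds."""
    if isinstance(true_scores, ScoreSet):
        scores = true_scores
        true_scores, false_scores = scores.true_scores, scores.false_scores
    true_scores = np.asarray(true_scores, dtype=float)
    false_scores = np.asarray(false_scores, dtype=float)
    if true_scores.size == 0 or false_scores.size == 0:
        raise InvalidInputError("both score lists must be non-empty")
    observed = np.unique(np.concatenate([true_scores, false_scores]))
    mid = (observed[:-1] + observed[1:]) / 2 if observed.size > 1 else np.array([])
    lo, hi = observed[0] - 1.0, observed[-1] + 1.0
    thresholds = np.unique(np.concatenate([[lo], observed, mid, [hi]]))
    far, frr = far_frr(true_scores, false_scores, thresholds)
    d = far - frr  # non-increasing in t; starts at +100, ends at -100
    i_lo = int(np.flatnonzero(d >= 0)[-1])
    if d[i_lo] == 0 or i_lo == len(thresholds) - 1:
        eer = float(far[i_lo])
        t_eer = float(thresholds[i_lo])
    else:
        i_hi = i_lo + 1
        alpha = d[i_lo] / (d[i_lo] - d[i_hi])
        eer = float(far[i_lo] + alpha * (far[i_hi] - far[i_lo]))
        t_eer = float(
            thresholds[i_lo] + alpha * (thresholds[i_hi] - thresholds[i_lo])
        )
    return EERResult(
        thresholds=thresholds, far=far, frr=frr, eer=eer, eer_threshold=t_eer
    )


# ---------------------------------------------------------------------------
# Configuration sweep (joint masks x synergy rank)
# ---------------------------------------------------------------------------

def configuration_sweep(
    population: Population,
    masks: list[JointMask] | None = None,
    synergies: range | list[int] | None = None,
    n: int = 10,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> pd.DataFrame:
    """Mean/SD matched correlation and EER per (synergy rank, joint mask).

    The per-pair correlation tensors are computed once per comparison and
    reused across masks and ranks.
    """
    if len(population.subjects) < 2:
        raise ConfigurationError("need at least 2 subjects")
    if masks is None:
        masks = [JointMask.preset(name) for name in MASK_PRESETS]
    synergies = list(synergies) if synergies is not None else list(range(1, n + 1))
    sets = _session_sets(population, None, n)

    records: dict[tuple[int, str], dict[str, list[float]]] = {
        (i, m.name): {"true": [], "false": []} for i in synergies for m in masks
    }
    for tmpl_sid, entry_sid, k, is_true in iter_comparisons(population):
        template = sets[(tmpl_sid, 0)]
        entry = sets[(entry_sid, k)]
        tensor = pairwise_correlation_tensor(template, entry, max_shift)
        for m in masks:
            scores, shifts = best_shift_scores(tensor, m, max_shift)
            available = list(range(entry.n))
            for t in range(min(template.n, entry.n)):
                col = int(available[int(np.argmax(scores[t, available]))])
                available.remove(col)
                rank = t + 1
                if (rank, m.name) in records:
                    pct = 100.0 * scores[t, col] / len(m)
                    records[(rank, m.name)]["true" if is_true else "false"].append(pct)
    rows = []
    for (rank, mname), rec in records.items():
        true_arr = np.array(rec["true"])
        false_arr = np.array(rec["false"])
        eer = compute_eer(true_arr, false_arr).eer if true_arr.size and false_arr.size else np.nan
        rows.append(
            {
                "synergy": rank,
                "mask": mname,
                "mean_true": true_arr.mean() if true_arr.size else np.nan,
                "sd_true": true_arr.std(ddof=1) if true_arr.size > 1 else np.nan,
                "mean_false": false_arr.mean() if false_arr.size else np.nan,
                "eer": eer,
            }
        )
    return pd.DataFrame(rows).sort_values(["synergy", "mask"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Object ranking and subset curve
# ---------------------------------------------------------------------------

def _mean_false_score(
    population: Population,
    mask: JointMask,
    synergy_indices,
    object_subset: list[str] | None,
    n: int,
    max_shift: int,
    score_kind: str = "false",
) -> float:
    scores = collect_scores(
        population, mask, synergy_indices, object_subset, n, max_shift
    )
    arr = scores.false_scores if score_kind == "false" else scores.true_scores
    return float(arr.mean())


def rank_objects(
    population: Population,
    mask: JointMask | None = None,
    synergy_indices: frozenset[int] | set[int] = frozenset({1}),
    n: int = 10,
    max_shift: int = DEFAULT_MAX_SHIFT,
    score_kind: str = "false",
) -> ObjectRanking:
    """Leave-one-object-out priority ranking.

    For each object, synergies are re-extracted from every session with that
    object omitted and the mean imposter (false-entry) score is recomputed.
    An object whose presence *decreases* the false correlation — omitting it
    makes imposters match better — contributes most to distinctiveness and
    ranks highest.  ``score_kind='true'`` ranks on authentic correlations
    instead (the opposite reading of the leave-one-out attribution).
    """
    if len(population.objects) < 2:
        raise InvalidInputError("need at least 2 objects to rank")
    mask = mask or JointMask.preset("all")
    baseline = _mean_false_score(
        population, mask, synergy_indices, None, n, max_shift, score_kind
    )
    deltas = {}
    for obj in population.objects:
        subset = [o for o in population.objects if o != obj]
        mean_without = _mean_false_score(
            population, mask, synergy_indices, subset, n, max_shift, score_kind
        )
        # Positive: the object's presence lowers imposter correlation.
        deltas[obj] = mean_without - baseline
    ranked = sorted(population.objects, key=lambda o: -deltas[o])
    return ObjectRanking(ranked_objects=ranked, deltas=deltas)


def subset_curve(
    population: Population,
    ranking: ObjectRanking,
    mask: JointMask | None = None,
    synergy_indices: frozenset[int] | set[int] = frozenset({1}),
    n: int = 10,
    max_shift: int = DEFAULT_MAX_SHIFT,
    ks: list[int] | None = None,
) -> pd.DataFrame:
    """EER when only the top-k ranked objects are used, for k = 1..G."""
    mask = mask or JointMask.preset("all")
    G = len(ranking.ranked_objects)
    ks = ks or list(range(1, G + 1))
    rows = []
    for k in ks:
        subset = ranking.ranked_objects[:k]
        scores = collect_scores(
            population, mask, synergy_indices, subset, n, max_shift
        )
        rows.append({"k": k, "eer": compute_eer(scores).eer})
    return pd.DataFrame(rows)


def grasp_type_eer(
    population: Population,
    grasp_type: str,
    mask: JointMask | None = None,
    synergy_indices: frozenset[int] | set[int] = frozenset({1}),
    n: int = 10,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> EERResult:
    """EER when synergies are re-extracted from one grasp type's objects only."""
    mask = mask or JointMask.preset("all")
    subset = [o for o, t in population.object_types.items() if t == grasp_type]
    if not subset:
        raise InvalidInputError(f"no objects of grasp type {grasp_type!r}")
    scores = collect_scores(population, mask, synergy_indices, subset, n, max_shift)
    return compute_eer(scores)


# ---------------------------------------------------------------------------
# Short-term stability
# ---------------------------------------------------------------------------

def stability_report(
    subject: SubjectRecord,
    mask: JointMask | None = None,
    synergy_index: int = 1,
    n: int = 10,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> pd.DataFrame:
    """Matched synergy correlation of each later session against the template."""
    if len(subject.sessions) < 2:
        raise ConfigurationError("need the template session plus >= 1 follow-up")
    mask = mask or JointMask.preset("all")
    template = session_synergies(subject.sessions[0], n=n)
    rows = []
    for k in range(1, len(subject.sessions)):
        entry = session_synergies(subject.sessions[k], n=n)
        match = pair_synergies(template, entry, mask, max_shift, n_pairs=synergy_index)
        score = match_score_percent(match, [synergy_index], mask)
        rows.append({"session": k, "score_percent": score})
    return pd.DataFrame(rows)
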
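"""Distance-capped optimal one-to-one assignment of detections to reference dots.

A detection and a reference dot may be paired only if they lie within a
maximum permitted distance τ of each other — the maximum diameter of a tumor
cell, so a detection is credited only when it plausibly marks the same
nucleus.  Among all one-to-one assignments using allowed pairs, the matcher
returns one that first maximizes the number of matched pairs and then
minimizes the total matched distance (Hungarian algorithm on a cost matrix
whose forbidden entries carry a prohibitively large cost).  Matched pairs are
true positives; unmatched reference dots are false negatives; unmatched
detections are false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .annotations import AnnotationSet
from .errors import ConfigurationError, FrameMismatchError, ValidationError

#: Default maximum permitted match distance in µm.  Well-differentiated
#: neuroendocrine tumor nuclei are fairly uniform, round and ~10-15 µm across;
#: the cap is the largest plausible nuclear diameter so that two dots placed
#: anywhere on the same nucleus can still be paired.
DEFAULT_MAX_DIST_UM = 15.0

_ORACLE_LIMIT = 8


@dataclass(frozen=True)
class MatchConfig:
    """Matching parameters.

    Parameters
    ----------
    max_dist_um : float
        Maximum permitted distance τ between a matched reference/detection
        pair, in µm; converted to pixels through the shared frame's
        resolution.
    """

    max_dist_um: float = DEFAULT_MAX_DIST_UM

    def __post_init__(self) -> None:
        if not self.max_dist_um > 0:
            raise ConfigurationError(f"max_dist_um must be > 0, got {self.max_dist_um}")

    def max_dist_px(self, um_per_px: float) -> float:
        return self.max_dist_um / um_per_px


@dataclass
class MatchResult:
    """Outcome of one capped assignment.

    ``pairs`` holds ``(ref_index, det_index, distance_px)`` triples sorted by
    ``(ref_index, det_index)``; ``fn_ref_indices`` / ``fp_det_indices`` are the
    unmatched reference and detector indices, sorted ascending.
    """

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    fn_ref_indices: list[int] = field(default_factory=list)
    fp_det_indices: list[int] = field(default_factory=list)

    @property
    def n_tp(self) -> int:
        return len(self.pairs)

    @property
    def n_fn(self) -> int:
        return len(self.fn_ref_indices)

    @property
    def n_fp(self) -> int:
        return len(self.fp_det_indices)

    @property
    def total_distance(self) -> float:
        return float(sum(d for _, _, d in self.pairs))

    def to_dict(self) -> dict:
        return {
            "pairs": [[i, j, d] for i, j, d in self.pairs],
            "fn_ref_indices": list(self.fn_ref_indices),
            "fp_det_indices": list(self.fp_det_indices),
        }


def _check_inputs(ref: AnnotationSet, det: AnnotationSet, cfg: MatchConfig) -> float:
    if ref.frame != det.frame:
        raise FrameMismatchError(
            "reference and detector sets must share one coordinate frame; "
            "apply transform.apply_mapping first"
        )
    return cfg.max_dist_px(ref.frame.um_per_px)


def _result(n_ref: int, n_det: int, pairs: list[tuple[int, int, float]]) -> MatchResult:
    pairs = sorted(pairs)
    matched_ref = {i for i, _, _ in pairs}
    matched_det = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=pairs,
        fn_ref_indices=[i for i in range(n_ref) if i not in matched_ref],
        fp_det_indices=[j for j in range(n_det) if j not in matched_det],
    )


def match_points(ref: AnnotationSet, det: AnnotationSet, cfg: MatchConfig) -> MatchResult:
    """Optimal capped one-to-one assignment between two point sets.

    Among assignments that use only pairs with Euclidean distance ≤ τ, the
    result maximizes the number of pairs and, among those, minimizes the
    total matched distance.  Deterministic for fixed inputs: the solver is
    deterministic and the returned pair list is canonically sorted.
    """
    tau_px = _check_inputs(ref, det, cfg)
    n_ref, n_det = ref.n_total, det.n_total
    if n_ref == 0 or n_det == 0:
        return _result(n_ref, n_det, [])

    d = cdist(ref.xy(), det.xy())
    feasible = d <= tau_px
    # Forbidden entries cost more than any full feasible assignment can save,
    # so minimizing total cost maximizes the feasible pair count first.
    big = (max(n_ref, n_det) + 1.0) * tau_px + 1.0
    cost = np.where(feasible, d, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j), float(d[i, j]))
        for i, j in zip(rows, cols)
        if feasible[i, j]
    ]
    return _result(n_ref, n_det, pairs)


def match_oracle(ref: AnnotationSet, det: AnnotationSet, cfg: MatchConfig) -> MatchResult:
    """Exhaustive-search reference matcher for tiny instances (n ≤ 8 per side).

    Considers every injective partial assignment respecting the cap and
    returns the optimum under the same criterion as :func:`match_points`
    (maximum pairs, then minimum total distance, then lexicographically
    smallest pair list).  Exponential state space explored via memoization;
    intended for verification only.
    """
    tau_px = _check_inputs(ref, det, cfg)
    n_ref, n_det = ref.n_total, det.n_total
    if n_ref > _ORACLE_LIMIT or n_det > _ORACLE_LIMIT:
        raise ValidationError(
            f"match_oracle is limited to {_ORACLE_LIMIT} points per side "
            f"(got {n_ref} and {n_det})"
        )
    if n_ref == 0 or n_det == 0:
        return _result(n_ref, n_det, [])

    d = cdist(ref.xy(), det.xy())
    memo: dict[tuple[int, int], tuple[int, float]] = {}

    def best_from(i: int, mask: int) -> tuple[int, float]:
        """Optimal (-pairs, distance) over refs i.. with detector-use bitmask."""
        if i == n_ref:
            return (0, 0.0)
        key = (i, mask)
        if key in memo:
            return memo[key]
        best = best_from(i + 1, mask)  # leave ref i unmatched
        for j in range(n_det):
            if not (mask >> j) & 1 and d[i, j] <= tau_px:
                neg_cnt, dist = best_from(i + 1, mask | (1 << j))
                cand = (neg_cnt - 1, dist + d[i, j])
                if cand < best:
                    best = cand
        memo[key] = best
        return best

    # Reconstruct the lexicographically smallest optimal pair list: at each
    # ref index prefer matching (smallest det first) over skipping.
    pairs: list[tuple[int, int, float]] = []
    i, mask = 0, 0
    target = best_from(0, 0)
    remaining_cnt, remaining_dist = target
    while i < n_ref:
        chosen = None
        for j in range(n_det):
            if not (mask >> j) & 1 and d[i, j] <= tau_px:
                neg_cnt, dist = best_from(i + 1, mask | (1 << j))
                if (neg_cnt - 1 == remaining_cnt
                        and abs(dist + d[i, j] - remaining_dist) <= 1e-12 * (1 + abs(remaining_dist))):
                    chosen = j
                    break
        if chosen is not None:
            pairs.append((i, chosen, float(d[i, chosen])))
            mask |= 1 << chosen
            remaining_cnt += 1
            remaining_dist -= d[i, chosen]
        i += 1
        remaining_cnt, remaining_dist = best_from(i, mask)
    return _result(n_ref, n_det, pairs)


def stratified_match(
    ref: AnnotationSet,
    det: AnnotationSet,
    cfg: MatchConfig,
    stratify: bool = True,
) -> tuple[MatchResult, MatchResult | None]:
    """Match all cells, and independently the Ki67-positive subsets.

    Returns ``(total, positive)`` where ``total`` ignores labels and
    ``positive`` restricts both sides to positive-labeled points (indices in
    the positive result refer to the original sets).  With
    ``stratify=False`` the positive result is ``None``.
    """
    total = match_points(ref, det, cfg)
    if not stratify:
        return total, None
    if not (ref.labeled and det.labeled):
        raise ValidationError("stratified matching requires labeled sets on both sides")
    ref_idx = [i for i, p in enumerate(ref.points) if p.label == "positive"]
    det_idx = [j for j, p in enumerate(det.points) if p.label == "positive"]
    sub = match_points(ref.subset(ref_idx), det.subset(det_idx), cfg)
    positive = MatchResult(
        pairs=[(ref_idx[i], det_idx[j], dist) for i, j, dist in sub.pairs],
        fn_ref_indices=[ref_idx[i] for i in sub.fn_ref_indices],
        fp_det_indices=[det_idx[j] for j in sub.fp_det_indices],
    )
    return total, positive
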
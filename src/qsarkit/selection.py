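"""Staged descriptor selection.

Four stages, applied in order:

1. ``drop_degenerate``  — remove all-zero and zero-variance columns.
2. ``prune_correlated`` — remove one member of every descriptor pair with
   |Pearson r| above a cutoff (default 0.9), keeping the member more
   correlated with activity.
3. ``cfs_select``       — correlation-based feature subset selection: best-first
   search over subsets scored by merit k·r̄_cf / sqrt(k + k(k−1)·r̄_ff),
   which favours features correlated with activity but not with each other.
4. ``f_stepping``       — remove-one backward elimination: a descriptor is
   permanently removed only when refitting without it does not decrease the
   cross-validated correlation of the model.

``enforce_budget`` caps the final subset at floor(n_compounds / 4) features to
guard against over-parameterised models, and ``select_features`` chains all
stages.  Every stage is a pure function of (matrix, activity, config, seed);
all tie-breaks are lexicographic on column name.
"""

from __future__ import annotations

import heapq
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .descriptors import DescriptorMatrix


class SelectionError(ValueError):
    pass


@dataclass
class SelectionReport:
    """What one selection stage removed, and why."""

    stage: str  # zero_value | correlation_prune | cfs | f_stepping | budget
    removed: list[tuple[str, str, float]]  # (column, reason, statistic)
    retained: list[str]
    budget: int | None = None
    extra: dict = field(default_factory=dict)  # stage-specific bookkeeping

    def __post_init__(self) -> None:
        overlap = {c for c, _, _ in self.removed} & set(self.retained)
        if overlap:
            raise SelectionError(f"columns both removed and retained: {sorted(overlap)}")
        if self.budget is not None and len(self.retained) > self.budget:
            raise SelectionError(
                f"{len(self.retained)} retained exceeds budget {self.budget}"
            )

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "removed": [list(t) for t in self.removed],
            "retained": list(self.retained),
            "budget": self.budget,
            "extra": self.extra,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _activity_vector(activity, n: int) -> np.ndarray:
    y = np.asarray(activity, dtype=float)
    if y.ndim != 1 or y.shape[0] != n:
        raise SelectionError(f"activity must be a length-{n} vector")
    if not np.isfinite(y).all():
        raise SelectionError("activity contains non-finite values")
    return y


def _safe_corr_with(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """|Pearson r| of each column of X with y; 0 where undefined."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = math.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    return np.abs(np.nan_to_num(r, nan=0.0))


def _safe_corr_matrix(X: np.ndarray) -> np.ndarray:
    """|Pearson r| between columns; 0 where undefined, 1 on the diagonal."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(X, rowvar=False)
    c = np.atleast_2d(np.nan_to_num(c, nan=0.0))
    np.fill_diagonal(c, 1.0)
    return np.abs(c)


# ---------------------------------------------------------------------------
# stage 1: degenerate columns

def drop_degenerate(matrix: DescriptorMatrix) -> tuple[DescriptorMatrix, SelectionReport]:
    """Remove all-zero and zero-variance descriptor columns."""
    if not matrix.column_names:
        raise SelectionError("empty descriptor matrix")
    X = matrix.values
    removed: list[tuple[str, str, float]] = []
    retained: list[str] = []
    for j, col in enumerate(matrix.column_names):
        v = X[:, j]
        if np.allclose(v, 0.0):
            removed.append((col, "all_zero", 0.0))
        elif np.isclose(v.std(ddof=0), 0.0):
            removed.append((col, "zero_variance", float(v[0])))
        else:
            retained.append(col)
    if not retained:
        raise SelectionError("no informative descriptors: all columns degenerate")
    report = SelectionReport(stage="zero_value", removed=removed, retained=retained)
    return matrix.subset(retained), report


# ---------------------------------------------------------------------------
# stage 2: pairwise correlation pruning

def prune_correlated(
    matrix: DescriptorMatrix,
    activity,
    cutoff: float = 0.9,
) -> tuple[DescriptorMatrix, SelectionReport]:
    """Remove one member of every descriptor pair with |r| > cutoff.

    The worst offending pair is resolved first; the member with the smaller
    |correlation to activity| is removed (ties: lexicographically later name).
    The returned matrix contains no pair above the cutoff.
    """
    if not (0 < cutoff <= 1):
        raise SelectionError(f"cutoff must be in (0,1], got {cutoff}")
    cols = matrix.column_names
    X = matrix.values
    n = X.shape[0]
    if n < 3:
        raise SelectionError(f"need >= 3 compounds for correlations, got {n}")
    y = _activity_vector(activity, n)

    relevance = _safe_corr_with(y, X)
    C = _safe_corr_matrix(X)
    alive = np.ones(len(cols), dtype=bool)
    removed: list[tuple[str, str, float]] = []

    while True:
        sub = np.where(alive)[0]
        block = C[np.ix_(sub, sub)].copy()
        np.fill_diagonal(block, 0.0)
        if block.size == 0 or block.max() <= cutoff:
            break
        offenders = [
            (block[i, j], sub[i], sub[j])
            for i in range(len(sub))
            for j in range(i + 1, len(sub))
            if block[i, j] > cutoff
        ]
        offenders.sort(key=lambda t: (-t[0], cols[t[1]], cols[t[2]]))
        r, a, b = offenders[0]
        if relevance[a] < relevance[b]:
            drop = a
        elif relevance[b] < relevance[a]:
            drop = b
        else:
            drop = a if cols[a] > cols[b] else b
        keep = b if drop == a else a
        alive[drop] = False
        removed.append(
            (cols[drop], f"|r|={r:.4f} with {cols[keep]}", float(r))
        )

    retained = [c for c, a in zip(cols, alive) if a]
    report = SelectionReport(
        stage="correlation_prune",
        removed=removed,
        retained=retained,
        extra={"cutoff": cutoff},
    )
    return matrix.subset(retained), report


# ---------------------------------------------------------------------------
# stage 3: CFS subset search

def cfs_merit(subset_idx: Sequence[int], rcf: np.ndarray, rff: np.ndarray) -> float:
    """CFS merit k·r̄_cf / sqrt(k + k(k−1)·r̄_ff) for a subset of columns."""
    k = len(subset_idx)
    if k == 0:
        return 0.0
    idx = np.asarray(subset_idx)
    sum_rcf = float(rcf[idx].sum())
    if k == 1:
        return sum_rcf
    block = rff[np.ix_(idx, idx)]
    sum_pairs = float((block.sum() - k) / 2.0)  # diagonal is 1
    return sum_rcf / math.sqrt(k + 2.0 * sum_pairs)


def cfs_select(
    matrix: DescriptorMatrix,
    activity,
    max_subset: int | None = None,
    *,
    max_expansions: int = 10_000,
    stale_limit: int = 5,
    exhaustive_limit: int = 15,
    locally_predictive: bool = True,
) -> tuple[list[str], float, SelectionReport]:
    """Select the highest-merit descriptor subset.

    Exhaustive enumeration when the matrix has at most ``exhaustive_limit``
    columns; otherwise best-first forward search that stops after
    ``stale_limit`` consecutive non-improving expansions or
    ``max_expansions`` node expansions.  Ties prefer the smaller subset, then
    the lexicographically earlier column tuple.

    With ``locally_predictive`` (the classical CFS default), the merit-best
    subset is augmented by a post-pass that repeatedly admits the left-out
    feature most correlated with activity, provided that correlation exceeds
    its correlation with every feature already selected — recovering
    independently informative features that the redundancy penalty of the
    merit alone would discard.  The augmentation never exceeds ``max_subset``.
    """
    cols = matrix.column_names
    if not cols:
        raise SelectionError("empty descriptor matrix")
    X = matrix.values
    y = _activity_vector(activity, X.shape[0])
    p = len(cols)
    if max_subset is None:
        max_subset = p
    if max_subset < 1:
        raise SelectionError(f"max_subset must be >= 1, got {max_subset}")
    max_subset = min(max_subset, p)

    rcf = _safe_corr_with(y, X)
    rff = _safe_corr_matrix(X)

    def key(idx: tuple[int, ...]) -> tuple:
        return (-cfs_merit(idx, rcf, rff), len(idx), tuple(cols[i] for i in idx))

    if p <= exhaustive_limit:
        best: tuple[int, ...] | None = None
        for k in range(1, max_subset + 1):
            for combo in itertools.combinations(range(p), k):
                if best is None or key(combo) < key(best):
                    best = combo
        assert best is not None
        best_idx = best
    else:
        # best-first search over forward expansions, seeded with singletons
        counter = itertools.count()
        heap: list = []
        seen: set[tuple[int, ...]] = set()
        best_idx: tuple[int, ...] = (int(np.argmax(rcf)),)
        for i in range(p):
            node = (i,)
            heapq.heappush(heap, (-cfs_merit(node, rcf, rff), next(counter), node))
            seen.add(node)
            if key(node) < key(best_idx):
                best_idx = node
        stale = 0
        expansions = 0
        while heap and expansions < max_expansions and stale < stale_limit:
            _, _, node = heapq.heappop(heap)
            expansions += 1
            improved = False
            if len(node) < max_subset:
                for i in range(p):
                    if i in node:
                        continue
                    child = tuple(sorted(node + (i,)))
                    if child in seen:
                        continue
                    seen.add(child)
                    heapq.heappush(heap, (-cfs_merit(child, rcf, rff), next(counter), child))
                    if key(child) < key(best_idx):
                        best_idx = child
                        improved = True
            stale = 0 if improved else stale + 1

    search_idx = tuple(sorted(best_idx))
    merit = cfs_merit(search_idx, rcf, rff)

    chosen = set(search_idx)
    if locally_predictive:
        while len(chosen) < max_subset:
            candidates = [
                i for i in range(p)
                if i not in chosen and rcf[i] > max(rff[i, j] for j in chosen)
            ]
            if not candidates:
                break
            # most activity-correlated first; ties by name for determinism
            nxt = min(candidates, key=lambda i: (-rcf[i], cols[i]))
            chosen.add(nxt)
    final_idx = tuple(sorted(chosen))

    retained = [cols[i] for i in final_idx]
    removed = [
        (cols[i], "below_best_merit_subset", float(rcf[i]))
        for i in range(p)
        if i not in final_idx
    ]
    report = SelectionReport(
        stage="cfs",
        removed=removed,
        retained=retained,
        extra={
            "merit": merit,
            "search_subset": [cols[i] for i in search_idx],
            "locally_predictive_added": [
                cols[i] for i in final_idx if i not in search_idx
            ],
            "relevance": {c: float(r) for c, r in zip(cols, rcf)},
        },
    )
    return retained, merit, report


# ---------------------------------------------------------------------------
# stage 4: F-stepping remove-one backward elimination

def f_stepping(
    matrix: DescriptorMatrix,
    activity,
    trainer_config=None,
    seed: int = 0,
) -> tuple[list[str], SelectionReport]:
    """Backward elimination scored by cross-validated Pearson R of the SVR.

    Each cycle scores every leave-one-descriptor-out subset; the descriptor
    whose removal yields the largest R that is at least the current R is
    permanently removed.  The loop stops when every removal would decrease R,
    so the R trajectory is non-decreasing.  Fold assignment is fixed by
    ``seed`` and shared across subset evaluations.
    """
    from .model import SvrConfig, cross_validate  # deferred: model imports selection

    cols = list(matrix.column_names)
    if len(cols) < 2:
        raise SelectionError(f"need >= 2 features for backward elimination, got {len(cols)}")
    y = _activity_vector(activity, matrix.values.shape[0])
    config = trainer_config if trainer_config is not None else SvrConfig(seed=seed)

    def score(subset: list[str]) -> float:
        return cross_validate(matrix.subset(subset), y, config).R

    current = list(cols)
    current_r = score(current)
    trajectory = [current_r]
    removed: list[tuple[str, str, float]] = []

    while len(current) > 1:
        candidates = []
        for col in current:
            subset = [c for c in current if c != col]
            candidates.append((score(subset), col))
        # best removal; ties remove the lexicographically later name
        candidates.sort(key=lambda t: (-t[0], t[1]))
        ties = [c for c in candidates if c[0] == candidates[0][0]]
        best_r, best_col = max(ties, key=lambda t: t[1])
        if best_r < current_r:
            break
        current = [c for c in current if c != best_col]
        removed.append((best_col, f"removal kept CV R at {best_r:.4f}", float(best_r)))
        current_r = best_r
        trajectory.append(current_r)

    report = SelectionReport(
        stage="f_stepping",
        removed=removed,
        retained=current,
        extra={"cv_r_trajectory": trajectory, "seed": seed},
    )
    return current, report


# ---------------------------------------------------------------------------
# feature budget

def enforce_budget(
    subset: Sequence[str],
    n_compounds: int,
    relevance: Mapping[str, float] | None = None,
) -> tuple[list[str], SelectionReport]:
    """Cap the feature count at floor(n_compounds / 4).

    When the cap binds, features are ranked by |correlation to activity|
    (``relevance``, typically carried forward from the CFS report); ties are
    broken lexicographically.
    """
    if n_compounds < 4:
        raise SelectionError(f"need >= 4 compounds for a budget, got {n_compounds}")
    budget = n_compounds // 4
    subset = list(subset)
    if len(subset) <= budget:
        report = SelectionReport(stage="budget", removed=[], retained=subset, budget=budget)
        return subset, report
    if relevance is None:
        raise SelectionError("budget binds but no relevance ranking was provided")
    ranked = sorted(subset, key=lambda c: (-float(relevance.get(c, 0.0)), c))
    kept = ranked[:budget]
    kept = [c for c in subset if c in set(kept)]  # preserve input order
    dropped = [
        (c, "over_budget", float(relevance.get(c, 0.0))) for c in subset if c not in set(kept)
    ]
    report = SelectionReport(stage="budget", removed=dropped, retained=kept, budget=budget)
    return kept, report


# ---------------------------------------------------------------------------
# full pipeline

def select_features(
    matrix: DescriptorMatrix,
    activity,
    *,
    corr_cutoff: float = 0.9,
    trainer_config=None,
    seed: int = 0,
    max_subset: int | None = None,
    run_f_stepping: bool = True,
) -> tuple[list[str], list[SelectionReport]]:
    """Run the full selection pipeline: degenerate → prune → CFS → F-stepping
    → feature budget.  Returns the selected column names and the per-stage
    reports.  Pure function of (matrix, activity, config, seed)."""
    n = matrix.values.shape[0]
    budget = n // 4 if n >= 4 else None
    if max_subset is None and budget is not None:
        max_subset = budget

    reports: list[SelectionReport] = []
    m, rep = drop_degenerate(matrix)
    reports.append(rep)
    m, rep = prune_correlated(m, activity, cutoff=corr_cutoff)
    reports.append(rep)
    selected, _, rep = cfs_select(m, activity, max_subset=max_subset)
    reports.append(rep)
    relevance = rep.extra["relevance"]
    if run_f_stepping and len(selected) >= 2:
        selected, rep = f_stepping(
            m.subset(selected), activity, trainer_config=trainer_config, seed=seed
        )
        reports.append(rep)
    if budget is not None:
        selected, rep = enforce_budget(selected, n, relevance)
        reports.append(rep)
    return selected, reports
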
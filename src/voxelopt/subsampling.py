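"""Disjoint, age-stratified sub-sampling.

Each Bayesian-optimization iteration scores a candidate parameter pair on a
fresh subset of subjects, so that differing conditions are always evaluated
on separate data.  A plan partitions the cohort into floor(N/n) disjoint
subsets of exactly n subjects each, every subset approximately reproducing
the cohort's age distribution; the N mod n remainder is left unassigned,
never recycled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import InputError
from .volumes import SubjectRecord

__all__ = ["SubsamplePlan", "build_strata", "make_plan"]

#: Default number of age strata for regression-mode plans.
DEFAULT_N_STRATA = 8


@dataclass(frozen=True)
class SubsamplePlan:
    """Ordered disjoint index subsets of size ``n_per_iter`` — one per
    optimization iteration — plus the unassigned remainder."""

    subsets: tuple[np.ndarray, ...]
    n_per_iter: int
    n_total: int
    unassigned: np.ndarray
    mode: str
    seed: int
    subject_ids: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for sub in self.subsets:
            if len(sub) != self.n_per_iter:
                raise InputError("every subset must have exactly n_per_iter members")
            if seen.intersection(sub.tolist()):
                raise InputError("subsets must be pairwise disjoint")
            seen.update(sub.tolist())
        covered = seen.union(self.unassigned.tolist())
        if covered != set(range(self.n_total)):
            raise InputError("subsets plus unassigned must cover all indices exactly once")

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    def to_json(self, path: Union[str, Path]) -> None:
        """Serialize subset membership (by subject id when known) for audit."""
        def name(i: int):
            return self.subject_ids[i] if self.subject_ids is not None else int(i)

        payload = {
            "mode": self.mode,
            "seed": self.seed,
            "n_per_iter": self.n_per_iter,
            "n_total": self.n_total,
            "subsets": [[name(i) for i in sub] for sub in self.subsets],
            "unassigned": [name(i) for i in self.unassigned],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def build_strata(ages: Sequence[float], n_strata: int) -> list[np.ndarray]:
    """Cut subjects into ``n_strata`` contiguous near-equal age bins.

    Subjects are stably sorted by age (ties keep input order) and split into
    bins whose sizes differ by at most one.  Returns index arrays.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise InputError("empty age list")
    if not 1 <= n_strata <= ages.size:
        raise InputError(f"n_strata must be in [1, {ages.size}], got {n_strata}")
    order = np.argsort(ages, kind="stable")
    return [b for b in np.array_split(order, n_strata)]


def _deal_stratified(
    pool: np.ndarray, quota: int, m: int, rng: np.random.Generator, ages: np.ndarray
) -> tuple[list[list[int]], list[int]]:
    """Deal ``quota`` members of an age-sorted pool to each of ``m`` subsets.

    The pool is shuffled, truncated to m·quota members, re-sorted by age and
    dealt in age-blocks of size m (one member per subset per block) so every
    subset spans the pool's age range.  Returns per-subset picks and the
    unused remainder.
    """
    pool = np.asarray(pool)
    shuffled = rng.permutation(pool)
    kept, rest = shuffled[: m * quota], shuffled[m * quota :]
    kept = kept[np.argsort(ages[kept], kind="stable")]
    picks: list[list[int]] = [[] for _ in range(m)]
    for b in range(quota):
        block = rng.permutation(kept[b * m : (b + 1) * m])
        for j in range(m):
            picks[j].append(int(block[j]))
    return picks, [int(i) for i in rest]


def make_plan(
    subjects: Union[Sequence[SubjectRecord], Sequence[float], np.ndarray],
    n_per_iter: int,
    mode: str,
    seed: int,
    groups: Optional[Sequence[Optional[str]]] = None,
    n_strata: int = DEFAULT_N_STRATA,
) -> SubsamplePlan:
    """Build a disjoint stratified plan with floor(N / n_per_iter) subsets.

    ``subjects`` may be SubjectRecords or a bare age vector (with ``groups``
    supplied separately for classification mode).  Classification subsets
    draw exactly n/2 from each group, age-stratified within group;
    regression subsets draw proportionally from ``n_strata`` age strata.
    Deterministic per seed.
    """
    if mode not in ("classification", "regression"):
        raise InputError(f"mode must be classification or regression, got {mode!r}")
    if subjects is not None and len(subjects) and isinstance(subjects[0], SubjectRecord):
        ages = np.array([s.age_years for s in subjects], dtype=float)
        if groups is None:
            groups = [s.group for s in subjects]
        ids: Optional[tuple[str, ...]] = tuple(s.id for s in subjects)
    else:
        ages = np.asarray(subjects, dtype=float)
        ids = None
    n_total = ages.size
    if n_total == 0:
        raise InputError("empty cohort")
    if not 1 <= n_per_iter <= n_total:
        raise InputError(f"n_per_iter must be in [1, {n_total}], got {n_per_iter}")

    m = n_total // n_per_iter
    rng = np.random.default_rng(seed)
    picks: list[list[int]] = [[] for _ in range(m)]
    leftovers: list[int] = []

    if mode == "classification":
        if groups is None:
            raise InputError("classification mode needs group labels")
        groups = np.asarray([g if g is not None else "" for g in groups])
        labels = [g for g in dict.fromkeys(groups) if g != ""]
        if len(labels) != 2:
            raise InputError(f"classification mode needs exactly 2 groups, found {labels}")
        if n_per_iter % 2:
            raise InputError("classification subsets need an even size (n/2 per group)")
        n_half = n_per_iter // 2
        for lab in labels:
            members = np.flatnonzero(groups == lab)
            if members.size < n_half * m:
                raise InputError(
                    f"group {lab!r} has {members.size} subjects, "
                    f"needs at least {n_half * m} for {m} subsets of {n_half}"
                )
            g_picks, g_rest = _deal_stratified(members, n_half, m, rng, ages)
            for j in range(m):
                picks[j].extend(g_picks[j])
            leftovers.extend(g_rest)
    else:
        n_strata = min(n_strata, n_total)
        strata = build_strata(ages, n_strata)
        sizes = np.array([len(s) for s in strata])
        # largest-remainder allocation of the m·n total draws across strata
        # (T_h <= s_h holds because m·n <= N)
        shares = m * n_per_iter * sizes / n_total
        totals = np.floor(shares).astype(int)
        frac_order = np.argsort(-(shares - totals), kind="stable")
        for h in frac_order[: m * n_per_iter - totals.sum()]:
            totals[h] += 1
        offset = 0  # rotates so per-stratum remainders spread evenly
        for h, stratum in enumerate(strata):
            pool = rng.permutation(np.asarray(stratum))[: totals[h]]
            pool = pool[np.argsort(ages[pool], kind="stable")]
            base, r = divmod(int(totals[h]), m)
            for b in range(base):
                block = rng.permutation(pool[b * m : (b + 1) * m])
                for j in range(m):
                    picks[j].append(int(block[j]))
            tail = rng.permutation(pool[base * m :])
            for i, t in enumerate(tail):
                picks[(offset + i) % m].append(int(t))
            offset = (offset + r) % m
            leftovers.extend(int(i) for i in np.setdiff1d(stratum, pool))

    subsets = tuple(np.array(sorted(p), dtype=int) for p in picks)
    unassigned = np.array(sorted(leftovers), dtype=int)
    return SubsamplePlan(
        subsets=subsets,
        n_per_iter=n_per_iter,
        n_total=n_total,
        unassigned=unassigned,
        mode=mode,
        seed=seed,
        subject_ids=ids,
    )
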
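"""Selective genotyping: shrinking marker panels by four strategies.

All strategies start from an LD-pruned panel and walk down a geometric size
schedule (keep 30% at each step until a floor, by default 48 markers):

* ``NRE_MB`` — rank once by |marker effect| from a single RR-BLUP fit on the
  full panel; take the top-s for every scheduled size (nested by
  construction).
* ``NRE_R``  — size-matched random subsets, many replicates, as the
  no-information baseline.
* ``RE_MAB`` — like NRE_MB but the model is refit on the current subset
  before every further cut (effects re-estimated each round).
* ``RE_MOB`` — model-based: at each size draw many random subsets of the
  current entry set, score each candidate with a fixed cross-validation
  evaluator, and keep the best-scoring subset as the new entry set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .io import GenotypeMatrix, PhenotypeVector
from .rrblup import RRBLUPFit, fit_rrblup

__all__ = [
    "SelectionSchedule",
    "MarkerSubset",
    "schedule_sizes",
    "restrict_schedule",
    "select_nre_mb",
    "select_nre_r",
    "select_re_mab",
    "select_re_mob",
]

STRATEGIES = ("NRE_MB", "NRE_R", "RE_MAB", "RE_MOB")


@dataclass
class SelectionSchedule:
    """Strictly decreasing subset sizes produced by the 30%-retention rule."""

    sizes: list[int]
    retention_fraction: float = 0.30
    min_size: int = 48
    origin_m: int = 0

    def __post_init__(self) -> None:
        if any(s2 >= s1 for s1, s2 in zip(self.sizes, self.sizes[1:])):
            raise ValueError("schedule sizes must be strictly decreasing")
        if self.sizes and self.origin_m and self.sizes[0] >= self.origin_m:
            raise ValueError("all schedule sizes must be below the origin marker count")
        if any(s < 1 for s in self.sizes):
            raise ValueError("schedule sizes must be positive")

    def __iter__(self):
        return iter(self.sizes)

    def __len__(self):
        return len(self.sizes)


@dataclass
class MarkerSubset:
    """One selected marker panel with its provenance."""

    strategy: str
    size: int
    marker_ids: list[str]
    replicate_index: Optional[int] = None
    parent_ids: Optional[list[str]] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if len(self.marker_ids) != self.size:
            raise ValueError("marker id count does not match declared size")
        if len(set(self.marker_ids)) != self.size:
            raise ValueError("marker ids not unique")
        if self.parent_ids is not None and not set(self.marker_ids) <= set(self.parent_ids):
            raise ValueError("subset not nested within its parent set")


def schedule_sizes(
    origin_m: int, retention_fraction: float = 0.30, min_size: int = 48
) -> SelectionSchedule:
    """Iterate s <- floor(retention_fraction * s) while s >= min_size.

    From 20,242 pruned markers the default 30%/48 rule yields
    6072, 1821, 546, 163, 48.  An origin at or below min_size (or whose first
    cut already falls below it) gives an empty schedule.
    """
    sizes: list[int] = []
    s = origin_m
    while True:
        # guard against float products landing epsilon under an integer
        s = math.floor(retention_fraction * s + 1e-9)
        if s < min_size:
            break
        sizes.append(s)
    if not sizes:
        import warnings

        warnings.warn(
            f"origin_m={origin_m} yields an empty schedule (min_size={min_size})"
        )
    return SelectionSchedule(
        sizes=sizes,
        retention_fraction=retention_fraction,
        min_size=min_size,
        origin_m=origin_m,
    )


def restrict_schedule(canonical: SelectionSchedule, m_available: int) -> SelectionSchedule:
    """Keep only scheduled sizes strictly below the available marker count
    (e.g. the canonical 6072/1821/546/163/48 chain restricted to a 1,044-
    marker panel leaves 546/163/48)."""
    return SelectionSchedule(
        sizes=[s for s in canonical.sizes if s < m_available],
        retention_fraction=canonical.retention_fraction,
        min_size=canonical.min_size,
        origin_m=min(canonical.origin_m, m_available),
    )


def _rank_by_effect(marker_ids: Sequence[str], beta: np.ndarray) -> list[str]:
    """Marker ids in decreasing |effect| order; ties keep input order."""
    order = np.argsort(-np.abs(beta), kind="stable")
    return [marker_ids[j] for j in order]


def select_nre_mb(fit_full: RRBLUPFit, schedule: SelectionSchedule) -> list[MarkerSubset]:
    """Rank once by |beta| from the full-panel fit; top-s per scheduled size."""
    ranked = _rank_by_effect(fit_full.marker_ids, fit_full.beta)
    subsets = []
    parent = list(fit_full.marker_ids)
    for s in schedule:
        if s > len(ranked):
            raise ValueError(f"requested size {s} exceeds panel size {len(ranked)}")
        subsets.append(
            MarkerSubset("NRE_MB", s, ranked[:s], parent_ids=parent)
        )
        parent = ranked[:s]
    return subsets


def select_nre_r(
    pruned_ids: Sequence[str],
    schedule: SelectionSchedule,
    n_reps: int = 1000,
    seed: int = 0,
) -> list[MarkerSubset]:
    """Independent uniform draws without replacement, ``n_reps`` per size."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(pruned_ids)
    out = []
    for s in schedule:
        if s > len(ids):
            raise ValueError(f"requested size {s} exceeds panel size {len(ids)}")
        for rep in range(n_reps):
            pick = rng.choice(len(ids), size=s, replace=False)
            out.append(
                MarkerSubset(
                    "NRE_R",
                    s,
                    [ids[j] for j in sorted(pick)],
                    replicate_index=rep,
                    parent_ids=ids,
                )
            )
    return out


def select_re_mab(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    schedule: SelectionSchedule,
    lambda_fixed: Optional[float] = None,
) -> list[MarkerSubset]:
    """Iterative effect-based cuts: refit RR-BLUP on the current panel before
    every size reduction, rank by the re-estimated |beta|, keep the top-s."""
    current = list(G.marker_ids)
    out = []
    for s in schedule:
        if s > len(current):
            raise ValueError(f"requested size {s} exceeds current panel {len(current)}")
        fit = fit_rrblup(G.subset_markers(current), y, lambda_fixed=lambda_fixed)
        if fit.degenerate:
            raise RuntimeError("degenerate RR-BLUP fit (zero phenotypic variance)")
        ranked = _rank_by_effect(fit.marker_ids, fit.beta)
        chosen = ranked[:s]
        chosen = [m for m in current if m in set(chosen)]  # original order
        out.append(MarkerSubset("RE_MAB", s, chosen, parent_ids=current))
        current = chosen
    return out


def select_re_mob(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    schedule: SelectionSchedule,
    n_reps: int = 1000,
    evaluator: Optional[Callable[[list[str]], float]] = None,
    seed: int = 0,
) -> list[MarkerSubset]:
    """Model-based selection: best of ``n_reps`` random candidate subsets per
    size, scored by ``evaluator`` (default: mean prediction ability over one
    fixed 5-fold partition, shared by all candidates so scores are
    comparable).  The winner becomes the entry set for the next size.
    """
    rng = np.random.default_rng(seed)
    if evaluator is None:
        from .validation import CVConfig, fixed_partition_evaluator

        evaluator = fixed_partition_evaluator(
            G, y, CVConfig(k=5, n_repetitions=1, seed=int(rng.integers(2**31)))
        )
    entry = list(G.marker_ids)
    out = []
    for s in schedule:
        if s > len(entry):
            raise ValueError(f"requested size {s} exceeds entry set {len(entry)}")
        best_ids: Optional[list[str]] = None
        best_score = -np.inf
        for _ in range(n_reps):
            pick = rng.choice(len(entry), size=s, replace=False)
            cand = [entry[j] for j in sorted(pick)]
            score = evaluator(cand)
            if score > best_score:  # ties: first encountered wins
                best_score = score
                best_ids = cand
        out.append(
            MarkerSubset("RE_MOB", s, best_ids, parent_ids=entry, score=float(best_score))
        )
        entry = best_ids
    return out
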
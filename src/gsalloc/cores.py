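"""Selective phenotyping: IBS distances and EN/AN core-set selection.

A core set is a fixed-size subset of genotypes chosen from marker data to be
phenotyped and used as the training population.  Two single-objective
criteria over an identity-by-state (IBS) distance matrix are supported:

* ``EN`` — average entry-to-nearest-entry distance: mean, over selected
  entries, of the distance to the closest *other* selected entry.
  Maximized: spreads the core over the diversity of the collection.
* ``AN`` — average accession-to-nearest-entry distance: mean, over *all*
  accessions, of the distance to the closest selected entry (zero for the
  entries themselves).  Minimized: makes the core maximally representative.

The optimizer is a restarted steepest-ascent/descent single-swap local
search: from a seeded random core, evaluate every (selected, unselected)
swap, apply the best improving one, repeat to a local optimum; keep the best
of ``n_restarts`` starts.  Swap evaluation is incremental (top-2/top-3
nearest bookkeeping), so one sweep costs O(c (n - c) n / c) rather than a
full objective re-evaluation per move.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "CoreSet",
    "ibs_distance",
    "kinship_from_distance",
    "core_size",
    "objective_en",
    "objective_an",
    "select_core",
]


@dataclass
class DistanceMatrix:
    """Symmetric n x n genetic distances in [0, 1] with zero diagonal."""

    genotype_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        n = len(self.genotype_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match id count")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must have zero diagonal")
        if self.d.min() < -1e-12 or self.d.max() > 1.0 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.genotype_ids)


@dataclass
class CoreSet:
    method: str
    fraction: float
    indices: np.ndarray
    objective_value: float
    optimizer_trace: list[float] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.indices)


def ibs_distance(G: GenotypeMatrix) -> DistanceMatrix:
    """IBS dissimilarity d(i,j) = mean_j |g_i - g_j| / 2 on the {0,1,2} scale."""
    if G.has_missing:
        raise ValueError("IBS distance requires complete dosages; impute first")
    d = G.dosage
    n = G.n_genotypes
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d[i + 1 :] - d[i]).mean(axis=1) / 2.0
        out[i, i + 1 :] = diff
        out[i + 1 :, i] = diff
    return DistanceMatrix(list(G.genotype_ids), out)


def kinship_from_distance(D: DistanceMatrix) -> np.ndarray:
    """IBS similarity (1 - distance); computed for completeness, the core
    objectives consume only the distance."""
    return 1.0 - D.d


def core_size(fraction: float, n: int) -> int:
    """Nearest integer to fraction * n with exact .5 ties rounded down
    (the convention consistent with sizes 45, 55, 111, 113 and 553 for the
    fractions used on collections of 227 and 1,107)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    s = int(np.ceil(fraction * n - 0.5))
    if s < 1:
        raise ValueError(f"core of fraction {fraction} of {n} would be empty")
    return s


def objective_en(D: DistanceMatrix | np.ndarray, subset: Sequence[int]) -> float:
    """Mean over selected i of min over selected j != i of d(i, j)."""
    d = D.d if isinstance(D, DistanceMatrix) else np.asarray(D)
    idx = np.asarray(list(subset), dtype=int)
    if len(idx) < 2:
        raise ValueError("EN objective requires at least 2 entries")
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def objective_an(D: DistanceMatrix | np.ndarray, subset: Sequence[int]) -> float:
    """Mean over all accessions of the distance to the nearest selected entry
    (entries contribute zero: their nearest entry is themselves)."""
    d = D.d if isinstance(D, DistanceMatrix) else np.asarray(D)
    idx = np.asarray(list(subset), dtype=int)
    if len(idx) < 1:
        raise ValueError("AN objective requires a non-empty core")
    return float(d[:, idx].min(axis=1).mean())


# ---------------------------------------------------------------------------
# steepest-swap local search
# ---------------------------------------------------------------------------


def _top2(M: np.ndarray):
    """Row-wise two smallest values and the argmin (ties -> smallest index)."""
    a1 = M.argmin(axis=1)
    v1 = M[np.arange(M.shape[0]), a1]
    M2 = M.copy()
    M2[np.arange(M.shape[0]), a1] = np.inf
    v2 = M2.min(axis=1)
    return v1, v2, a1


def _an_swap_deltas(d, sel, unsel):
    """AN objective for every swap (remove sel[j], add unsel[u]); (c, n-c)."""
    n = d.shape[0]
    M = d[:, sel]  # (n, c)
    v1, v2, a1 = _top2(M)
    Du = d[:, unsel]  # (n, n-c)
    out = np.empty((len(sel), len(unsel)))
    for j in range(len(sel)):
        base = np.where(a1 == j, v2, v1)  # nearest among sel \ {j}
        out[j] = np.minimum(base[:, None], Du).mean(axis=0)
    return out


def _en_swap_values(d, sel, unsel):
    """EN objective for every swap (remove sel[j], add unsel[u]); (c, n-c)."""
    c = len(sel)
    M = d[np.ix_(sel, sel)].copy()
    np.fill_diagonal(M, np.inf)
    # top-3 per row so we can exclude both the row itself (diagonal) and one
    # removed column j
    part = np.argsort(M, axis=1)[:, :2]
    v1 = M[np.arange(c), part[:, 0]]
    v2 = M[np.arange(c), part[:, 1]]
    a1 = part[:, 0]
    Dsu = d[np.ix_(sel, unsel)]  # (c, n-c)
    Dus = d[np.ix_(unsel, sel)]  # (n-c, c)
    out = np.empty((c, len(unsel)))
    keep_mask = np.ones(c, dtype=bool)
    for j in range(c):
        keep_mask[:] = True
        keep_mask[j] = False
        # nearest among sel \ {self, j} for each kept row
        base = np.where(a1 == j, v2, v1)[keep_mask]
        vals = np.minimum(base[:, None], Dsu[keep_mask])  # (c-1, n-c)
        # the entering entry's own nearest: min over sel \ {j}
        enter = Dus[:, keep_mask].min(axis=1)  # (n-c,)
        out[j] = (vals.sum(axis=0) + enter) / c
    return out


def select_core(
    D: DistanceMatrix,
    fraction: float,
    method: str = "AN",
    n_restarts: int = 10,
    max_iters: int = 200,
    seed: int = 0,
) -> CoreSet:
    """Select a core of ``core_size(fraction, n)`` genotypes.

    ``method`` is ``"EN"`` (maximize entry-to-nearest-entry) or ``"AN"``
    (minimize accession-to-nearest-entry).  Deterministic under ``seed``.
    """
    method = method.upper()
    if method not in ("EN", "AN"):
        raise ValueError("method must be 'EN' or 'AN'")
    n = D.n
    c = core_size(fraction, n)
    if method == "EN" and c < 2:
        raise ValueError("EN requires a core of at least 2 entries")
    d = D.d
    objective = objective_en if method == "EN" else objective_an
    sign = 1.0 if method == "EN" else -1.0  # maximize sign * objective
    if c == n:
        idx = np.arange(n)
        return CoreSet(method, fraction, idx, objective(D, idx), [objective(D, idx)])

    rng = np.random.default_rng(seed)
    best_idx: Optional[np.ndarray] = None
    best_val = -np.inf
    best_trace: list[float] = []
    for _ in range(n_restarts):
        sel = np.sort(rng.choice(n, size=c, replace=False))
        cur = sign * objective(d, sel)
        trace = [sign * cur]
        for _ in range(max_iters):
            unsel = np.setdiff1d(np.arange(n), sel, assume_unique=False)
            vals = (
                _en_swap_values(d, sel, unsel)
                if method == "EN"
                else _an_swap_deltas(d, sel, unsel)
            )
            vals = sign * vals
            j, u = np.unravel_index(np.argmax(vals), vals.shape)
            if vals[j, u] <= cur + 1e-13:
                break
            cur = vals[j, u]
            sel = np.sort(np.concatenate([np.delete(sel, j), [unsel[u]]]))
            trace.append(sign * cur)
        if cur > best_val:
            best_val = cur
            best_idx = sel
            best_trace = trace
    value = objective(d, best_idx)  # re-derive from scratch
    return CoreSet(method, fraction, np.asarray(best_idx), value, best_trace)
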
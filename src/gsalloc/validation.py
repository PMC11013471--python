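"""Cross-validation, external validation, and experiment drivers.

The three drivers mirror the study designs the package exists to run:

* ``run_strategy_comparison`` — prediction ability of every marker-selection
  strategy at every scheduled subset size, against the all-markers baseline;
* ``run_ts_size_sweep`` — prediction ability of EN / AN cores and random
  training sets across population fractions;
* ``run_grid`` — joint reduction: RE-MoB marker subsets selected *within*
  each AN core, over the full (subset size x fraction) grid.

Fold-level aggregation convention: the mean/min/max are taken over all
k x n_repetitions fold-level correlations (not over repetition means).
Folds whose phenotypes or predictions are degenerate (zero variance) are
skipped and counted, never imputed as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .cores import DistanceMatrix, core_size, ibs_distance, select_core
from .io import GenotypeMatrix, PhenotypeVector
from .markers import (
    MarkerSubset,
    SelectionSchedule,
    select_nre_mb,
    select_nre_r,
    select_re_mab,
    select_re_mob,
)
from .rrblup import fit_rrblup, predict_gebv, prediction_ability

__all__ = [
    "CVConfig",
    "EvaluationResult",
    "kfold_partition",
    "holdout_split",
    "run_cv",
    "run_external",
    "fixed_partition_evaluator",
    "run_strategy_comparison",
    "run_ts_size_sweep",
    "run_grid",
    "results_frame",
]


@dataclass
class CVConfig:
    """Repeated k-fold cross-validation settings (default 20 x 10-fold)."""

    k: int = 10
    n_repetitions: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class EvaluationResult:
    """One strategy x subset-size x fraction record of prediction abilities."""

    population_label: str
    strategy: str
    subset_size: int
    ts_fraction: float
    r_cv_mean: float
    r_cv_min: float
    r_cv_max: float
    r_ev: float
    n_models: int
    r_ev_min: Optional[float] = None
    r_ev_max: Optional[float] = None


def results_frame(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def kfold_partition(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Random partition of range(n) into k folds with sizes differing by <= 1."""
    if n < k:
        raise ValueError(f"cannot split {n} genotypes into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def holdout_split(n: int, k: int) -> tuple[int, int]:
    """Training/validation sizes of one k-fold holdout: the validation split
    is the nearest integer to n/k (ties down), the rest trains.  227 lines at
    3-fold gives (151, 76); 1,107 at 5-fold gives (886, 221)."""
    if not n > k or k < 2:
        raise ValueError("need n > k >= 2")
    v = int(np.ceil(n / k - 0.5))
    return n - v, v


def run_cv(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    marker_ids: Optional[Sequence[str]] = None,
    cfg: Optional[CVConfig] = None,
) -> tuple[float, float, float, list[float]]:
    """Repeated k-fold CV prediction ability (r_cv) on the given marker panel.

    Returns (mean, min, max, per-fold r list) over all repetitions x folds.
    If folds would be smaller than 3 genotypes, k is reduced (with a warning)
    so each validation fold supports a correlation.
    """
    cfg = cfg or CVConfig()
    Gs = G.subset_markers(marker_ids) if marker_ids is not None else G
    Gs = Gs.subset_genotypes(y.genotype_ids)
    n = len(y)
    k = cfg.k
    if n // k < 3:
        k_new = max(2, n // 3)
        if k_new < k:
            warnings.warn(f"reducing folds from {k} to {k_new} for n={n}")
            k = k_new
    if n // k < 3:
        raise ValueError(f"population of {n} too small for cross-validation")
    rs: list[float] = []
    skipped = 0
    seed_stream = np.random.default_rng(cfg.seed).integers(2**31, size=cfg.n_repetitions)
    X = Gs.dosage
    ids = np.array(y.genotype_ids)
    for rep in range(cfg.n_repetitions):
        folds = kfold_partition(n, k, seed=int(seed_stream[rep]))
        assert sum(len(f) for f in folds) == n
        for fold in folds:
            mask = np.zeros(n, dtype=bool)
            mask[fold] = True
            y_tr = PhenotypeVector(list(ids[~mask]), y.values[~mask])
            G_tr = Gs.subset_genotypes(list(ids[~mask]))
            G_va = Gs.subset_genotypes(list(ids[mask]))
            try:
                fit = fit_rrblup(G_tr, y_tr)
                gebv = predict_gebv(fit, G_va)
                rs.append(prediction_ability(y.values[mask], gebv))
            except ValueError as e:
                skipped += 1
                warnings.warn(f"fold skipped: {e}")
    if not rs:
        raise RuntimeError("no fold produced a valid prediction ability")
    return float(np.mean(rs)), float(np.min(rs)), float(np.max(rs)), rs


def run_external(
    G_train: GenotypeMatrix,
    y_train: PhenotypeVector,
    G_val: GenotypeMatrix,
    y_val: PhenotypeVector,
    marker_ids: Optional[Sequence[str]] = None,
) -> float:
    """Single fit on the training population, prediction ability (r_ev) on a
    disjoint external validation population."""
    overlap = set(y_train.genotype_ids) & set(y_val.genotype_ids)
    if overlap:
        raise ValueError(f"training and validation sets overlap: {sorted(overlap)[:5]}")
    Gt = G_train.subset_markers(marker_ids) if marker_ids is not None else G_train
    Gv = G_val.subset_markers(marker_ids) if marker_ids is not None else G_val
    fit = fit_rrblup(Gt, y_train)
    gebv = predict_gebv(fit, Gv.subset_genotypes(y_val.genotype_ids))
    return prediction_ability(y_val.values, gebv)


def fixed_partition_evaluator(
    G: GenotypeMatrix, y: PhenotypeVector, cfg: CVConfig
) -> Callable[[Sequence[str]], float]:
    """Marker-subset scorer on one fixed k-fold partition (shared across all
    candidate subsets so their scores are comparable); returns the mean fold
    prediction ability, -inf if every fold degenerates."""
    n = len(y)
    folds = kfold_partition(n, cfg.k, seed=cfg.seed)
    ids = np.array(y.genotype_ids)
    Gy = G.subset_genotypes(y.genotype_ids)

    def score(marker_ids: Sequence[str]) -> float:
        Gs = Gy.subset_markers(marker_ids)
        rs = []
        for fold in folds:
            mask = np.zeros(n, dtype=bool)
            mask[fold] = True
            try:
                fit = fit_rrblup(
                    Gs.subset_genotypes(list(ids[~mask])),
                    PhenotypeVector(list(ids[~mask]), y.values[~mask]),
                )
                gebv = predict_gebv(fit, Gs.subset_genotypes(list(ids[mask])))
                rs.append(prediction_ability(y.values[mask], gebv))
            except ValueError:
                continue
        return float(np.mean(rs)) if rs else -np.inf

    return score


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------


def _safe_external(G, y, G_val, y_val, marker_ids):
    if G_val is None or y_val is None:
        return np.nan
    try:
        return run_external(G, y, G_val, y_val, marker_ids)
    except ValueError as e:
        warnings.warn(f"external validation degenerate: {e}")
        return np.nan


def run_strategy_comparison(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    G_val: Optional[GenotypeMatrix],
    y_val: Optional[PhenotypeVector],
    strategies: Sequence[str],
    schedule: SelectionSchedule,
    cfg: CVConfig,
    population_label: str = "pop",
    n_random_reps: int = 100,
    re_mob_reps: int = 100,
    seed: int = 0,
) -> list[EvaluationResult]:
    """Marker-selection strategies x subset sizes, plus the all-markers
    baseline row.  ``G`` must already be LD-pruned.  NRE_R rows aggregate the
    per-replicate mean r_cv (and r_ev) as mean/min/max over replicates.
    """
    rng = np.random.default_rng(seed)
    results: list[EvaluationResult] = []

    # baseline: all pruned markers
    m_all = G.n_markers
    r_mean, r_min, r_max, rs = run_cv(G, y, None, cfg)
    results.append(
        EvaluationResult(
            population_label, "ALL", m_all, 1.0, r_mean, r_min, r_max,
            _safe_external(G, y, G_val, y_val, None), len(rs),
        )
    )

    subsets: list[MarkerSubset] = []
    for strat in strategies:
        s = strat.upper().replace("-", "_")
        if s == "NRE_MB":
            fit_full = fit_rrblup(G, y)
            subsets += select_nre_mb(fit_full, schedule)
        elif s == "NRE_R":
            subsets += select_nre_r(
                G.marker_ids, schedule, n_reps=n_random_reps,
                seed=int(rng.integers(2**31)),
            )
        elif s == "RE_MAB":
            subsets += select_re_mab(G, y, schedule)
        elif s == "RE_MOB":
            subsets += select_re_mob(
                G, y, schedule, n_reps=re_mob_reps, seed=int(rng.integers(2**31)),
            )
        else:
            raise ValueError(f"unknown strategy {strat!r}")

    # deterministic strategies: one row per subset
    for sub in [s for s in subsets if s.strategy != "NRE_R"]:
        r_mean, r_min, r_max, rs = run_cv(G, y, sub.marker_ids, cfg)
        results.append(
            EvaluationResult(
                population_label, sub.strategy, sub.size, 1.0,
                r_mean, r_min, r_max,
                _safe_external(G, y, G_val, y_val, sub.marker_ids), len(rs),
            )
        )

    # NRE_R: summarize replicate-level mean r over replicates per size
    nre_r = [s for s in subsets if s.strategy == "NRE_R"]
    for size in sorted({s.size for s in nre_r}, reverse=True):
        reps = [s for s in nre_r if s.size == size]
        cv_means, evs = [], []
        for sub in reps:
            r_mean, _, _, _ = run_cv(G, y, sub.marker_ids, cfg)
            cv_means.append(r_mean)
            evs.append(_safe_external(G, y, G_val, y_val, sub.marker_ids))
        evs = [e for e in evs if not np.isnan(e)]
        results.append(
            EvaluationResult(
                population_label, "NRE_R", size, 1.0,
                float(np.mean(cv_means)), float(np.min(cv_means)), float(np.max(cv_means)),
                float(np.mean(evs)) if evs else np.nan, len(reps),
                r_ev_min=float(np.min(evs)) if evs else None,
                r_ev_max=float(np.max(evs)) if evs else None,
            )
        )
    return results


def run_ts_size_sweep(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    G_val: Optional[GenotypeMatrix],
    y_val: Optional[PhenotypeVector],
    fractions: Sequence[float] = (0.75, 0.5, 0.2, 0.1, 0.05),
    methods: Sequence[str] = ("EN", "AN", "RANDOM"),
    n_random_reps: int = 20,
    cfg: Optional[CVConfig] = None,
    population_label: str = "pop",
    n_restarts: int = 5,
    seed: int = 0,
    D: Optional[DistanceMatrix] = None,
) -> list[EvaluationResult]:
    """Training-set-size sweep: EN / AN cores and random training sets of the
    same sizes; r_cv within the core, r_ev from a model trained on the core.
    Random rows report mean/min/max over replicates (the Ra/Rmin/Rmax
    summaries)."""
    cfg = cfg or CVConfig()
    rng = np.random.default_rng(seed)
    Gy = G.subset_genotypes(y.genotype_ids)
    if D is None:
        D = ibs_distance(Gy)
    n = len(y)
    ids = np.array(y.genotype_ids)
    results: list[EvaluationResult] = []

    def evaluate(core_ids: list[str]) -> tuple[float, float, float, int, float]:
        y_core = y.subset(core_ids)
        G_core = Gy.subset_genotypes(core_ids)
        r_mean, r_min, r_max, rs = run_cv(G_core, y_core, None, cfg)
        r_ev = _safe_external(G_core, y_core, G_val, y_val, None)
        return r_mean, r_min, r_max, len(rs), r_ev

    for frac in fractions:
        c = core_size(frac, n)
        for method in methods:
            if method.upper() in ("EN", "AN"):
                core = select_core(
                    D, frac, method=method, n_restarts=n_restarts,
                    seed=int(rng.integers(2**31)),
                )
                core_ids = [ids[i] for i in core.indices]
                r_mean, r_min, r_max, n_models, r_ev = evaluate(core_ids)
                results.append(
                    EvaluationResult(
                        population_label, method.upper(), G.n_markers, frac,
                        r_mean, r_min, r_max, r_ev, n_models,
                    )
                )
            else:  # RANDOM
                cv_means, evs = [], []
                for _ in range(n_random_reps):
                    pick = rng.choice(n, size=c, replace=False)
                    core_ids = [ids[i] for i in np.sort(pick)]
                    r_mean, _, _, _, r_ev = evaluate(core_ids)
                    cv_means.append(r_mean)
                    evs.append(r_ev)
                evs = [e for e in evs if not np.isnan(e)]
                results.append(
                    EvaluationResult(
                        population_label, "RANDOM", G.n_markers, frac,
                        float(np.mean(cv_means)), float(np.min(cv_means)),
                        float(np.max(cv_means)),
                        float(np.mean(evs)) if evs else np.nan, n_random_reps,
                        r_ev_min=float(np.min(evs)) if evs else None,
                        r_ev_max=float(np.max(evs)) if evs else None,
                    )
                )
    return results


def run_grid(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    G_val: Optional[GenotypeMatrix],
    y_val: Optional[PhenotypeVector],
    schedule: SelectionSchedule,
    fractions: Sequence[float] = (0.75, 0.5, 0.2, 0.1, 0.05),
    cfg: Optional[CVConfig] = None,
    population_label: str = "pop",
    re_mob_reps: int = 50,
    n_restarts: int = 5,
    seed: int = 0,
) -> list[EvaluationResult]:
    """Joint marker x training-set reduction grid.

    For each population fraction an AN core is selected; RE-MoB marker
    selection is then re-run *inside* the core (no information from excluded
    genotypes leaks into marker selection), and each (size, fraction) cell is
    evaluated by CV within the core and externally.  Fraction 1.0 and the
    all-markers column are included as baselines.
    """
    cfg = cfg or CVConfig()
    rng = np.random.default_rng(seed)
    Gy = G.subset_genotypes(y.genotype_ids)
    D = ibs_distance(Gy)
    ids = np.array(y.genotype_ids)
    n = len(y)
    results: list[EvaluationResult] = []
    all_fracs = list(fractions) + ([1.0] if 1.0 not in fractions else [])
    for frac in sorted(all_fracs, reverse=True):
        if frac == 1.0:
            core_ids = list(ids)
        else:
            core = select_core(
                D, frac, method="AN", n_restarts=n_restarts,
                seed=int(rng.integers(2**31)),
            )
            core_ids = [ids[i] for i in core.indices]
        y_core = y.subset(core_ids)
        G_core = Gy.subset_genotypes(core_ids)
        subsets = select_re_mob(
            G_core, y_core, schedule, n_reps=re_mob_reps,
            seed=int(rng.integers(2**31)),
        )
        panels = [("ALL", G.n_markers, None)] + [
            ("RE_MOB", s.size, s.marker_ids) for s in subsets
        ]
        for strat, size, mids in panels:
            r_mean, r_min, r_max, rs = run_cv(G_core, y_core, mids, cfg)
            r_ev = _safe_external(G_core, y_core, G_val, y_val, mids)
            results.append(
                EvaluationResult(
                    population_label, strat, size, frac,
                    r_mean, r_min, r_max, r_ev, len(rs),
                )
            )
    return results
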
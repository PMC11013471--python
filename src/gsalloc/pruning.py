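"""Sliding-window LD pruning of marker panels.

A single greedy left-to-right pass per chromosome: a marker is dropped iff
its squared dosage correlation with some already-retained marker inside the
trailing window exceeds the threshold.  The result is a marker set in
approximate pairwise linkage equilibrium within every window, which removes
clusters of near-duplicate SNPs before model fitting or marker ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix

__all__ = ["PruneConfig", "pairwise_r2", "prune"]


@dataclass
class PruneConfig:
    r2_threshold: float = 0.95
    window_size: int = 100  # consecutive markers, when window_unit == "snps"
    window_unit: str = "snps"
    window_bp: int = 500_000

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.window_unit not in ("snps", "bp"):
            raise ValueError("window_unit must be 'snps' or 'bp'")


def pairwise_r2(G: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation between dosage columns i and j.

    Monomorphic columns have undefined correlation; they are defined here as
    r2 = 0 (with a warning) so they can never trigger pruning.
    """
    return _r2_cols(G.dosage[:, i], G.dosage[:, j])


def _r2_cols(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        warnings.warn("monomorphic marker in r2 computation; returning 0")
        return 0.0
    r = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
    return float(min(r * r, 1.0))


def prune(G: GenotypeMatrix, cfg: PruneConfig | None = None) -> GenotypeMatrix:
    """Greedy windowed pruning; returns the retained markers in input order.

    Markers are processed per chromosome in map order (input order when no
    map is present).  On ties the earlier marker wins (it was retained
    first).  Guarantee: no two retained markers within a window have
    r2 > threshold.
    """
    cfg = cfg or PruneConfig()
    d = G.dosage
    m = G.n_markers
    if G.chrom is not None:
        chrom_of = G.chrom
    else:
        chrom_of = np.array(["*"] * m, dtype=object)
    pos = G.pos_bp if (cfg.window_unit == "bp" and G.pos_bp is not None) else None
    if cfg.window_unit == "bp" and pos is None:
        raise ValueError("bp window requested but no physical positions present")

    keep = np.zeros(m, dtype=bool)
    retained_by_chrom: dict = {}
    # column statistics once
    mean = d.mean(axis=0)
    std = d.std(axis=0)
    dc = d - mean
    n = d.shape[0]
    for j in range(m):
        ret = retained_by_chrom.setdefault(chrom_of[j], [])
        if pos is None:
            window = [i for i in ret if j - i < cfg.window_size]
        else:
            window = [i for i in ret if pos[j] - pos[i] <= cfg.window_bp]
        drop = False
        if std[j] > 0.0:
            for i in window:
                if std[i] == 0.0:
                    continue
                r = (dc[:, i] @ dc[:, j]) / (n * std[i] * std[j])
                if r * r > cfg.r2_threshold:
                    drop = True
                    break
        if not drop:
            keep[j] = True
            ret.append(j)
    kept_ids = [G.marker_ids[j] for j in np.flatnonzero(keep)]
    return G.subset_markers(kept_ids)
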
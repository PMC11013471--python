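"""Synthetic soybean-style populations for exercising the prediction pipeline.

Three archetypes are emulated, mirroring the diversity gradient found in
soybean breeding material:

* ``RIL`` — a biparental recombinant-inbred-line family: F1 from two
  homozygous parents followed by several selfing generations (default 4,
  i.e. F5-derived lines), meiosis as a Poisson crossover process on the
  centimorgan map (Haldane, no interference).
* ``MULTIFAM`` — several biparental families drawn from a shared founder
  pool, emulating a multifamily breeding panel.
* ``GERMPLASM`` — a structured collection: subpopulation allele frequencies
  from a Balding–Nichols model around ancestral frequencies, individuals
  built as mosaics of founder haplotypes so that markers show block-wise
  linkage disequilibrium.

Phenotypes are additive: a chosen set of markers act as QTL with standard
normal allele-substitution effects, and the residual variance is set so the
genetic variance ratio matches the target narrow-sense heritability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import GenotypeMatrix, PhenotypeVector

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_founders",
    "simulate_ril",
    "simulate_panel",
    "simulate_phenotype",
    "simulate_population",
]


@dataclass
class SimConfig:
    """Knobs for population and phenotype simulation.

    ``archetype`` selects the population model; ``h2`` is the target
    narrow-sense heritability of the simulated trait; ``fst`` controls
    subpopulation divergence under the Balding–Nichols model; ``block_mean_cM``
    is the mean founder-mosaic block length that sets the LD decay scale in
    GERMPLASM panels.
    """

    archetype: str = "GERMPLASM"
    n_genotypes: int = 200
    n_markers: int = 500
    n_chromosomes: int = 5
    chrom_length_cM: float = 100.0
    n_qtl: int = 20
    h2: float = 0.5
    n_subpop: int = 1
    fst: float = 0.1
    selfing_generations: int = 4
    n_families: int = 5
    n_founder_haplotypes: int = 20
    block_mean_cM: float = 20.0
    hidden_qtl: bool = False
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ("RIL", "MULTIFAM", "GERMPLASM"):
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 <= self.fst <= 0.5:
            raise ValueError("fst must be in [0, 0.5]")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        for name in ("n_genotypes", "n_markers", "n_chromosomes", "n_qtl"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth of a simulated phenotype, for parameter-recovery tests."""

    qtl_marker_ids: list[str]
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    realized_h2: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "qtl_marker_ids": self.qtl_marker_ids,
                    "qtl_effects": list(map(float, self.qtl_effects)),
                    "true_breeding_values": list(map(float, self.true_breeding_values)),
                    "realized_h2": float(self.realized_h2),
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


def _make_map(cfg: SimConfig, rng: np.random.Generator):
    """Markers placed uniformly on each chromosome's cM map, sorted."""
    per = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes, dtype=int)
    per[: cfg.n_markers % cfg.n_chromosomes] += 1
    chrom, pos_cm = [], []
    for c in range(cfg.n_chromosomes):
        p = np.sort(rng.uniform(0.0, cfg.chrom_length_cM, size=per[c]))
        chrom.extend([f"Gm{c + 1:02d}"] * per[c])
        pos_cm.extend(p)
    chrom = np.array(chrom, dtype=object)
    pos_cm = np.array(pos_cm)
    pos_bp = np.empty(cfg.n_markers, dtype=int)
    # pseudo-physical coordinates: 1 cM ~ 0.4 Mb, strictly increasing per chrom
    start = 0
    for c in range(cfg.n_chromosomes):
        n = per[c]
        seg = pos_cm[start : start + n]
        bp = np.round(seg * 400_000).astype(int) + 1
        bp = np.maximum.accumulate(bp) + np.arange(n)  # enforce strict increase
        pos_bp[start : start + n] = bp
        start += n
    marker_ids = [f"m{j + 1:05d}" for j in range(cfg.n_markers)]
    return marker_ids, chrom, pos_cm, pos_bp, per


# ---------------------------------------------------------------------------
# founders (Balding–Nichols)
# ---------------------------------------------------------------------------


def subpop_frequencies(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_subpop, m) allele frequencies from the Balding–Nichols construction.

    Ancestral frequency p ~ U(0.1, 0.9); each subpopulation draws
    Beta(p(1-F)/F, (1-p)(1-F)/F) around it.  F = 0 collapses to the ancestral
    frequency exactly (no division by zero: handled analytically).
    """
    p = rng.uniform(0.1, 0.9, size=cfg.n_markers)
    if cfg.fst == 0.0:
        return np.tile(p, (cfg.n_subpop, 1))
    a = p * (1.0 - cfg.fst) / cfg.fst
    b = (1.0 - p) * (1.0 - cfg.fst) / cfg.fst
    freqs = rng.beta(a, b, size=(cfg.n_subpop, cfg.n_markers))
    return np.clip(freqs, 1e-6, 1.0 - 1e-6)


def simulate_founders(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Founder haplotype pool: binary haplotypes drawn at subpopulation
    frequencies, returned as a GenotypeMatrix with {0,1} entries (one row per
    haplotype) plus the marker map.  Haplotypes are split evenly across
    subpopulations; row ids encode the subpopulation (``hapP<k>_<i>``)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    marker_ids, chrom, pos_cm, pos_bp, _ = _make_map(cfg, rng)
    freqs = subpop_frequencies(cfg, rng)
    n_h = cfg.n_founder_haplotypes
    per = np.full(cfg.n_subpop, n_h // cfg.n_subpop, dtype=int)
    per[: n_h % cfg.n_subpop] += 1
    rows, ids = [], []
    for k in range(cfg.n_subpop):
        h = (rng.random((per[k], cfg.n_markers)) < freqs[k]).astype(float)
        rows.append(h)
        ids.extend(f"hapP{k + 1}_{i + 1}" for i in range(per[k]))
    return GenotypeMatrix(
        genotype_ids=ids,
        marker_ids=marker_ids,
        dosage=np.vstack(rows),
        chrom=chrom,
        pos_bp=pos_bp,
        pos_cm=pos_cm,
    )


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _chrom_slices(chrom: np.ndarray) -> list[slice]:
    slices, start = [], 0
    for j in range(1, len(chrom) + 1):
        if j == len(chrom) or chrom[j] != chrom[start]:
            slices.append(slice(start, j))
            start = j
    return slices


def _gamete(h1, h2, pos_cm, slices, rng) -> np.ndarray:
    """One recombinant gamete; crossovers are a Poisson process on the cM map
    (Haldane: no interference), independent per chromosome."""
    out = np.empty_like(h1)
    for sl in slices:
        seg = pos_cm[sl]
        length = seg[-1] - seg[0] if len(seg) > 1 else 0.0
        n_xo = rng.poisson(length / 100.0)
        phase = rng.integers(0, 2)
        if n_xo == 0:
            out[sl] = h1[sl] if phase == 0 else h2[sl]
            continue
        xo = np.sort(rng.uniform(seg[0], seg[-1], size=n_xo))
        flips = np.searchsorted(xo, seg, side="left")
        use_h1 = (flips + phase) % 2 == 0
        out[sl] = np.where(use_h1, h1[sl], h2[sl])
    return out


def simulate_ril(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    cfg: SimConfig,
    *,
    marker_ids=None,
    chrom=None,
    pos_cm=None,
    pos_bp=None,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeMatrix:
    """Biparental RIL family by single-seed descent.

    Parents are homozygous haplotypes ({0,1} arrays on a shared map).  Each
    line is an F1 selfed for ``cfg.selfing_generations`` rounds; with the
    default of 4 the lines are F5-derived and retain ~(1/2)^4 residual
    heterozygosity per locus.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    parent_a = np.asarray(parent_a, float)
    parent_b = np.asarray(parent_b, float)
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must share the same marker map")
    m = parent_a.size
    if pos_cm is None:
        ids, chrom, pos_cm, pos_bp, _ = _make_map(
            SimConfig(**{**cfg.__dict__, "n_markers": m, "n_qtl": min(cfg.n_qtl, m)}), rng
        )
        marker_ids = marker_ids or ids
    slices = _chrom_slices(chrom)
    lines = np.empty((cfg.n_genotypes, m))
    for i in range(cfg.n_genotypes):
        h1, h2 = parent_a.copy(), parent_b.copy()  # the F1
        for _ in range(cfg.selfing_generations):
            g1 = _gamete(h1, h2, pos_cm, slices, rng)
            g2 = _gamete(h1, h2, pos_cm, slices, rng)
            h1, h2 = g1, g2
        lines[i] = h1 + h2
    return GenotypeMatrix(
        genotype_ids=[f"RIL{i + 1:04d}" for i in range(cfg.n_genotypes)],
        marker_ids=list(marker_ids),
        dosage=lines,
        chrom=chrom,
        pos_bp=pos_bp,
        pos_cm=pos_cm,
    )


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------


def _mosaic_haplotype(pool: np.ndarray, pos_cm, slices, block_mean_cM, rng):
    """Haplotype stitched from random pool haplotypes in geometric-length
    blocks (switch probability per interval 1 - exp(-d/block_mean))."""
    m = pool.shape[1]
    out = np.empty(m)
    for sl in slices:
        seg = pos_cm[sl]
        cur = rng.integers(0, pool.shape[0])
        idx = np.empty(len(seg), dtype=int)
        idx[0] = cur
        if len(seg) > 1:
            d = np.diff(seg)
            switch = rng.random(len(d)) < -np.expm1(-d / block_mean_cM)
            for t, s in enumerate(switch, start=1):
                if s:
                    cur = rng.integers(0, pool.shape[0])
                idx[t] = cur
        out[sl] = pool[idx, np.arange(sl.start, sl.stop)]
    return out


def simulate_panel(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """MULTIFAM or GERMPLASM panel (see module docstring).

    MULTIFAM: ``n_families`` biparental families of (near-)equal size bred
    from founder-pool haplotypes by the RIL process; family labels are encoded
    in genotype ids (``F<k>_<i>``).  GERMPLASM: individuals are pairs of
    independent founder-mosaic haplotypes drawn within a subpopulation.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.archetype not in ("MULTIFAM", "GERMPLASM"):
        raise ValueError("simulate_panel requires MULTIFAM or GERMPLASM archetype")
    founders = simulate_founders(cfg, rng)
    pool = founders.dosage
    slices = _chrom_slices(founders.chrom)
    if cfg.archetype == "MULTIFAM":
        fam_sizes = np.full(cfg.n_families, cfg.n_genotypes // cfg.n_families, int)
        fam_sizes[: cfg.n_genotypes % cfg.n_families] += 1
        rows, ids = [], []
        for k in range(cfg.n_families):
            pa, pb = rng.choice(pool.shape[0], size=2, replace=False)
            sub = SimConfig(**{**cfg.__dict__, "n_genotypes": int(fam_sizes[k])})
            fam = simulate_ril(
                pool[pa],
                pool[pb],
                sub,
                marker_ids=founders.marker_ids,
                chrom=founders.chrom,
                pos_cm=founders.pos_cm,
                pos_bp=founders.pos_bp,
                rng=rng,
            )
            rows.append(fam.dosage)
            ids.extend(f"F{k + 1}_{i + 1:03d}" for i in range(fam_sizes[k]))
        dosage = np.vstack(rows)
    else:
        # subpopulation of each founder haplotype, from its id prefix
        hap_pop = np.array(
            [int(g.split("_")[0][4:]) - 1 for g in founders.genotype_ids]
        )
        sizes = np.full(cfg.n_subpop, cfg.n_genotypes // cfg.n_subpop, int)
        sizes[: cfg.n_genotypes % cfg.n_subpop] += 1
        rows, ids = [], []
        for k in range(cfg.n_subpop):
            sub_pool = pool[hap_pop == k]
            for i in range(sizes[k]):
                h1 = _mosaic_haplotype(sub_pool, founders.pos_cm, slices, cfg.block_mean_cM, rng)
                h2 = _mosaic_haplotype(sub_pool, founders.pos_cm, slices, cfg.block_mean_cM, rng)
                rows.append(h1 + h2)
                ids.append(f"P{k + 1}_{i + 1:04d}")
        dosage = np.vstack(rows)
    return GenotypeMatrix(
        genotype_ids=ids,
        marker_ids=founders.marker_ids,
        dosage=dosage,
        chrom=founders.chrom,
        pos_bp=founders.pos_bp,
        pos_cm=founders.pos_cm,
    )


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------


def simulate_phenotype(
    G: GenotypeMatrix, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[PhenotypeVector, TruthRecord]:
    """Additive polygenic trait on the given genotypes.

    ``n_qtl`` markers are chosen uniformly; effects ~ N(0, 1); the breeding
    value is the centered-dosage weighted sum; the residual SD is set from the
    sample variance of the breeding values so that the realized heritability
    matches ``h2`` in expectation.  ``h2 = 1`` gives a noise-free trait,
    ``h2 = 0`` pure noise.  With ``hidden_qtl`` the QTL columns would need to
    be dropped from the marker panel by the caller (ids are reported).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    if G.has_missing:
        raise ValueError("phenotype simulation requires a complete genotype matrix")
    qtl_idx = np.sort(rng.choice(G.n_markers, size=cfg.n_qtl, replace=False))
    effects = rng.normal(0.0, 1.0, size=cfg.n_qtl)
    X = G.dosage[:, qtl_idx]
    g = (X - X.mean(axis=0)) @ effects
    var_g = float(np.var(g))
    if cfg.h2 >= 1.0:
        e = np.zeros_like(g)
        y = cfg.mu + g + e
    elif cfg.h2 <= 0.0:
        sd = np.sqrt(var_g) if var_g > 0 else 1.0
        e = rng.normal(0.0, sd, size=len(g))
        y = cfg.mu + e  # trait carries no genetic signal
    else:
        var_e = var_g * (1.0 - cfg.h2) / cfg.h2
        e = rng.normal(0.0, np.sqrt(var_e), size=len(g))
        y = cfg.mu + g + e
    genic = g if cfg.h2 > 0.0 else np.zeros_like(g)
    denom = np.var(genic) + np.var(e)
    realized = float(np.var(genic) / denom) if denom > 0 else 0.0
    truth = TruthRecord(
        qtl_marker_ids=[G.marker_ids[j] for j in qtl_idx],
        qtl_effects=effects,
        true_breeding_values=g,
        realized_h2=realized,
    )
    return PhenotypeVector(list(G.genotype_ids), y), truth


# ---------------------------------------------------------------------------
# one-call population factory
# ---------------------------------------------------------------------------


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeVector, TruthRecord]:
    """Generate a genotype panel plus phenotype for the configured archetype."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.archetype == "RIL":
        founders = simulate_founders(cfg, rng)
        pa = (founders.dosage[0] > 0.5).astype(float)
        pb = 1.0 - pa  # fully contrasting homozygous parents
        G = simulate_ril(
            pa,
            pb,
            cfg,
            marker_ids=founders.marker_ids,
            chrom=founders.chrom,
            pos_cm=founders.pos_cm,
            pos_bp=founders.pos_bp,
            rng=rng,
        )
    else:
        G = simulate_panel(cfg, rng)
    y, truth = simulate_phenotype(G, cfg, rng)
    return G, y, truth
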
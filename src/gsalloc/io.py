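"""Genotype and phenotype containers, file formats, marker QC filters.

Dosages are stored on the VCF-native {0, 1, 2} alternate-allele-count scale
with ``numpy.nan`` as the missing sentinel.  After mean imputation dosages may
be fractional; all readers validate the {0, 1, 2, NA} domain on the way in.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = np.nan


class GenotypeIOError(ValueError):
    """Raised on malformed genotype/phenotype input."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise GenotypeIOError(f"duplicate {what}: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """n genotypes x m markers dosage matrix with an optional marker map.

    Parameters
    ----------
    genotype_ids, marker_ids
        Unique string identifiers for rows and columns.
    dosage
        ``(n, m)`` float array; entries count copies of the alternate allele
        (0, 1 or 2), ``nan`` marks a missing call.  Fractional values are
        permitted (post-imputation matrices).
    chrom, pos_bp
        Optional per-marker chromosome labels and 1-based physical positions.
        When present, markers must be grouped by chromosome with
        non-decreasing positions.
    pos_cm
        Optional genetic-map positions (centimorgan); used by the simulator.
    """

    genotype_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    chrom: Optional[np.ndarray] = None
    pos_bp: Optional[np.ndarray] = None
    pos_cm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        _check_unique(self.genotype_ids, "genotype id")
        _check_unique(self.marker_ids, "marker id")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.genotype_ids), len(self.marker_ids)):
            raise GenotypeIOError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.genotype_ids)} genotypes x {len(self.marker_ids)} markers"
            )
        for name in ("chrom", "pos_bp", "pos_cm"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (len(self.marker_ids),):
                    raise GenotypeIOError(f"{name} length does not match marker count")
                setattr(self, name, v)
        if self.chrom is not None and self.pos_bp is not None:
            self._check_sorted()

    def _check_sorted(self) -> None:
        seen: set = set()
        prev_chrom = None
        prev_pos = -np.inf
        for c, p in zip(self.chrom, self.pos_bp):
            if c != prev_chrom:
                if c in seen:
                    raise GenotypeIOError(
                        f"markers not grouped by chromosome (chromosome {c!r} recurs)"
                    )
                seen.add(c)
                prev_chrom, prev_pos = c, p
            elif p < prev_pos:
                raise GenotypeIOError(
                    f"marker positions not sorted on chromosome {c!r}"
                )
            else:
                prev_pos = p

    # -- basic properties -------------------------------------------------

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosage).any())

    def genotype_index(self, ids: Sequence[str]) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.genotype_ids)}
        missing = [g for g in ids if g not in lut]
        if missing:
            raise KeyError(f"genotype ids not present: {missing[:5]}")
        return np.array([lut[g] for g in ids], dtype=int)

    def marker_index(self, ids: Sequence[str]) -> np.ndarray:
        lut = {m: j for j, m in enumerate(self.marker_ids)}
        missing = [m for m in ids if m not in lut]
        if missing:
            raise KeyError(f"marker ids not present: {missing[:5]}")
        return np.array([lut[m] for m in ids], dtype=int)

    def subset_markers(self, ids: Sequence[str]) -> "GenotypeMatrix":
        """Column subset in the given order.

        The marker map is carried along when the requested order follows the
        genomic order; an out-of-map-order subset (e.g. effect-ranked panels)
        keeps its order and drops the map.
        """
        idx = self.marker_index(ids)
        in_order = bool(np.all(np.diff(idx) > 0))
        return GenotypeMatrix(
            genotype_ids=list(self.genotype_ids),
            marker_ids=[self.marker_ids[j] for j in idx],
            dosage=self.dosage[:, idx].copy(),
            chrom=None if (self.chrom is None or not in_order) else self.chrom[idx],
            pos_bp=None if (self.pos_bp is None or not in_order) else self.pos_bp[idx],
            pos_cm=None if (self.pos_cm is None or not in_order) else self.pos_cm[idx],
        )

    def subset_genotypes(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.genotype_index(ids)
        return GenotypeMatrix(
            genotype_ids=[self.genotype_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            dosage=self.dosage[idx, :].copy(),
            chrom=self.chrom,
            pos_bp=self.pos_bp,
            pos_cm=self.pos_cm,
        )


@dataclass
class PhenotypeVector:
    """Continuous trait values (e.g. yield BLUPs) aligned to genotype ids."""

    genotype_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        _check_unique(self.genotype_ids, "genotype id")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genotype_ids),):
            raise GenotypeIOError("phenotype values length does not match ids")
        if np.isnan(self.values).any():
            raise GenotypeIOError("phenotype values contain NaN")

    def __len__(self) -> int:
        return len(self.genotype_ids)

    def subset(self, ids: Sequence[str]) -> "PhenotypeVector":
        lut = {g: i for i, g in enumerate(self.genotype_ids)}
        missing = [g for g in ids if g not in lut]
        if missing:
            raise KeyError(f"phenotype ids not present: {missing[:5]}")
        idx = [lut[g] for g in ids]
        return PhenotypeVector([self.genotype_ids[i] for i in idx], self.values[idx])


@dataclass
class FilterConfig:
    """Marker QC thresholds: keep markers with missingness <= ``max_missing_prop``
    and minor-allele frequency >= ``min_maf``."""

    max_missing_prop: float = 0.8
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_prop <= 1.0:
            raise ValueError("max_missing_prop must be in [0, 1]")
        if not 0.0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF (optionally gzipped) into dosages.

    Dosage is the alternate-allele count of the GT field; any missing allele
    makes the cell missing.  Multiallelic records are rejected.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    _check_unique(samples, "sample name")
    marker_ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    cols: list[np.ndarray] = []
    for k, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise GenotypeIOError(
                f"record {rec.CHROM}:{rec.POS} (#{k + 1}) is not biallelic "
                f"(ALT={rec.ALT}); split or drop multiallelic sites first"
            )
        # gts012=True: 0/1/2 = alt count, 3 = unknown
        g = rec.gt_types.astype(float)
        g[g == 3] = MISSING
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        marker_ids.append(mid)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        cols.append(g)
    vcf.close()
    if not cols:
        raise GenotypeIOError(f"no variant records in {path}")
    dosage = np.column_stack(cols)
    return GenotypeMatrix(
        genotype_ids=samples,
        marker_ids=marker_ids,
        dosage=dosage,
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(poss, dtype=int),
    )


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write integer dosages as a minimal VCF 4.2 (REF=A, ALT=T placeholders).

    Missing cells are written as ``./.``.  Fractional dosages cannot be
    represented in GT and are rejected.
    """
    d = G.dosage
    ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
    if not ok.all():
        raise GenotypeIOError("VCF writer requires integer dosages in {0,1,2} or NA")
    chrom = G.chrom if G.chrom is not None else np.array(["1"] * G.n_markers, dtype=object)
    pos = G.pos_bp if G.pos_bp is not None else np.arange(1, G.n_markers + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.genotype_ids)
            + "\n"
        )
        for j in range(G.n_markers):
            gts = [
                "./." if np.isnan(d[i, j]) else _GT_CODE[int(d[i, j])]
                for i in range(G.n_genotypes)
            ]
            fh.write(
                f"{chrom[j]}\t{int(pos[j])}\t{G.marker_ids[j]}\tA\tT\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_genotypes_table(
    path: str | Path, map_path: str | Path | None = None
) -> GenotypeMatrix:
    """Read a delimited dosage table (rows = genotypes, columns = markers).

    Entries must be 0/1/2 or NA.  ``map_path`` may point to a TSV with columns
    (marker, chrom, pos) giving the physical map.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
    if df.empty:
        raise GenotypeIOError(f"empty genotype table: {path}")
    genotype_ids = [str(i) for i in df.index]
    marker_ids = [str(c) for c in df.columns]
    raw = df.to_numpy()
    dosage = np.full(raw.shape, MISSING)
    valid = {"0": 0.0, "1": 1.0, "2": 2.0}
    na = {"NA", "NaN", "nan", "", ".", "na"}
    for (i, j), v in np.ndenumerate(raw):
        s = str(v).strip() if v is not None and v == v else "NA"
        if s in valid:
            dosage[i, j] = valid[s]
        elif s in na:
            continue
        else:
            raise GenotypeIOError(
                f"invalid dosage {s!r} at genotype {genotype_ids[i]!r}, "
                f"marker {marker_ids[j]!r}"
            )
    chrom = pos = None
    if map_path is not None:
        m = pd.read_csv(map_path, sep="\t", dtype={0: str, 1: str})
        m.columns = ["marker", "chrom", "pos"][: len(m.columns)]
        m = m.set_index("marker")
        try:
            m = m.loc[marker_ids]
        except KeyError as e:
            raise GenotypeIOError(f"marker map missing entries: {e}") from e
        chrom = m["chrom"].to_numpy(dtype=object)
        pos = m["pos"].astype(int).to_numpy()
    return GenotypeMatrix(genotype_ids, marker_ids, dosage, chrom=chrom, pos_bp=pos)


def write_genotypes_table(
    G: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None
) -> None:
    """Write dosages as CSV with an NA missing sentinel; optional map TSV."""
    d = G.dosage
    out = np.empty(d.shape, dtype=object)
    for (i, j), v in np.ndenumerate(d):
        out[i, j] = "NA" if np.isnan(v) else (str(int(v)) if float(v).is_integer() else repr(v))
    pd.DataFrame(out, index=G.genotype_ids, columns=G.marker_ids).to_csv(path)
    if map_path is not None:
        if G.chrom is None or G.pos_bp is None:
            raise GenotypeIOError("no marker map to write")
        pd.DataFrame(
            {"marker": G.marker_ids, "chrom": G.chrom, "pos": G.pos_bp}
        ).to_csv(map_path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeVector:
    """Read a two-column TSV (genotype id, trait value)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError as e:
        raise GenotypeIOError(f"empty phenotype file: {path}") from e
    if df.shape[1] < 2:
        raise GenotypeIOError("phenotype file must have two tab-separated columns")
    ids = [str(x) for x in df.iloc[:, 0]]
    try:
        vals = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as e:
        raise GenotypeIOError(f"non-numeric phenotype value: {e}") from e
    return PhenotypeVector(ids, vals)


def write_phenotypes(y: PhenotypeVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g, v in zip(y.genotype_ids, y.values):
            fh.write(f"{g}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# QC filters and imputation
# ---------------------------------------------------------------------------


def marker_missingness(G: GenotypeMatrix) -> np.ndarray:
    """Per-marker proportion of missing calls."""
    return np.isnan(G.dosage).mean(axis=0)


def marker_maf(G: GenotypeMatrix) -> np.ndarray:
    """Per-marker minor-allele frequency from non-missing dosages.

    All-missing markers get MAF 0 (they never survive a positive threshold).
    """
    with np.errstate(invalid="ignore"):
        p = np.nanmean(G.dosage, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    return np.minimum(p, 1.0 - p)


def filter_markers(G: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Retain markers with missingness <= max_missing_prop and MAF >= min_maf.

    Marker order is preserved; the result may be empty (downstream model fits
    reject empty marker sets).
    """
    keep = (marker_missingness(G) <= cfg.max_missing_prop) & (
        marker_maf(G) >= cfg.min_maf
    )
    kept_ids = [m for m, k in zip(G.marker_ids, keep) if k]
    return G.subset_markers(kept_ids)


def impute_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with its marker's mean non-missing dosage."""
    d = G.dosage
    nan_mask = np.isnan(d)
    if not nan_mask.any():
        return dataclasses.replace(G, dosage=d.copy())
    all_missing = nan_mask.all(axis=0)
    if all_missing.any():
        bad = [G.marker_ids[j] for j in np.flatnonzero(all_missing)[:5]]
        raise GenotypeIOError(f"markers with no observed calls cannot be imputed: {bad}")
    col_mean = np.nanmean(d, axis=0)
    out = np.where(nan_mask, col_mean[None, :], d)
    return dataclasses.replace(G, dosage=out)


def align(G: GenotypeMatrix, y: PhenotypeVector) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Restrict both containers to the shared genotype ids, in G's row order."""
    shared = [g for g in G.genotype_ids if g in set(y.genotype_ids)]
    if len(shared) < 2:
        raise GenotypeIOError("fewer than 2 genotypes shared between G and y")
    return G.subset_genotypes(shared), y.subset(shared)
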
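"""SNP genotype handling and the genomic relationship (kinship) matrix.

Genotypes are coded on the allele-dosage half scale used throughout the
package: 1 for one homozygote, 0.5 for heterozygotes, 0 for the other
homozygote, ``nan`` for missing calls.  On this scale the reference-allele
frequency of marker *l* is simply the column mean ``p_l`` and the kinship
between varieties *i* and *j* is

    K_ij = sum_l (M_il - p_l)(M_jl - p_l) / b,    b = sum_l p_l (1 - p_l).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "KinshipMatrix",
    "filter_markers",
    "ld_prune",
    "impute_missing",
    "compute_kinship",
    "read_vcf",
    "read_plink_raw",
    "read_csv_matrix",
]

_VALID_CODES = (0.0, 0.5, 1.0)


@dataclass
class MarkerMatrix:
    """Coded SNP genotypes for a panel of varieties.

    Attributes
    ----------
    genotypes : (n_varieties, n_markers) float array with values in
        {1, 0.5, 0} or nan for missing.
    variety_ids, marker_ids : unique labels for rows / columns.
    positions : (n_markers, 2) int array of (chromosome, base pair).
    allele_freq : optional externally supplied reference-allele
        frequencies; when absent, panel-observed frequencies are used.
    """

    genotypes: np.ndarray
    variety_ids: list[str]
    marker_ids: list[str]
    positions: np.ndarray | None = None
    allele_freq: np.ndarray | None = field(default=None)
    imputed: bool = False  # frequency-imputed matrices carry fractional codes

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        n, L = self.genotypes.shape
        if len(self.variety_ids) != n or len(self.marker_ids) != L:
            raise ValueError("label lengths do not match genotype dimensions")
        if len(set(self.variety_ids)) != n:
            raise ValueError("duplicate variety ids")
        if len(set(self.marker_ids)) != L:
            raise ValueError("duplicate marker ids")
        obs = self.genotypes[~np.isnan(self.genotypes)]
        if self.imputed:
            if obs.size and ((obs < 0) | (obs > 1)).any():
                raise ValueError("imputed genotype codes must lie in [0, 1]")
        elif obs.size and not np.isin(obs, _VALID_CODES).all():
            bad = obs[~np.isin(obs, _VALID_CODES)][:5]
            raise ValueError(f"genotype codes must be 0, 0.5 or 1; found {bad}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions)
            if self.positions.shape != (L, 2):
                raise ValueError("positions must be (n_markers, 2)")

    @property
    def n_varieties(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def observed_freq(self) -> np.ndarray:
        """Per-marker mean genotype code over non-missing calls (= p_l)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0)

    def frequencies(self) -> np.ndarray:
        """Reference frequencies used in formulas: supplied or observed."""
        if self.allele_freq is not None:
            return np.asarray(self.allele_freq, dtype=float)
        return self.observed_freq()

    def subset_markers(self, idx: np.ndarray) -> "MarkerMatrix":
        idx = np.asarray(idx)
        return MarkerMatrix(
            genotypes=self.genotypes[:, idx],
            variety_ids=list(self.variety_ids),
            marker_ids=[self.marker_ids[i] for i in idx],
            positions=None if self.positions is None else self.positions[idx],
            allele_freq=None if self.allele_freq is None else np.asarray(self.allele_freq)[idx],
            imputed=self.imputed,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.genotypes, index=self.variety_ids, columns=self.marker_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix with its scaling constant b."""

    values: np.ndarray
    variety_ids: list[str]
    scale_b: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.variety_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.variety_ids, columns=self.variety_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def index_of(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variety_ids)}
        missing = [v for v in ids if v not in lookup]
        if missing:
            raise KeyError(f"varieties absent from kinship: {missing[:5]}")
        return np.array([lookup[v] for v in ids], dtype=int)

    @classmethod
    def from_csv(cls, path, scale_b: float = float("nan")) -> "KinshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), list(df.index.astype(str)), scale_b)


def _marker_rates(m: MarkerMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = m.genotypes
    miss = np.isnan(g)
    n_obs = (~miss).sum(axis=0)
    miss_rate = miss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0)
        het = np.nansum(g == 0.5, axis=0) / np.maximum(n_obs, 1)
    maf = np.minimum(p, 1.0 - p)
    maf[n_obs == 0] = 0.0
    return maf, het, miss_rate


def filter_markers(
    raw: MarkerMatrix,
    maf_min: float = 0.05,
    max_het: float = 0.05,
    max_missing: float = 0.05,
) -> MarkerMatrix:
    """Remove markers failing minor-allele-frequency, heterozygosity or
    missing-rate thresholds (all rates computed on non-missing calls for
    MAF and heterozygosity).  Marker order is preserved.
    """
    if raw.n_markers == 0:
        raise ValueError("no markers to filter")
    for name, v in [("maf_min", maf_min), ("max_het", max_het), ("max_missing", max_missing)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    maf, het, miss = _marker_rates(raw)
    fail_maf = maf < maf_min
    fail_het = het > max_het
    fail_miss = miss > max_missing
    keep = ~(fail_maf | fail_het | fail_miss)
    logger.info(
        "marker filter: %d/%d retained (removed %d by MAF, %d by het, %d by missing)",
        keep.sum(), raw.n_markers, fail_maf.sum(), fail_het.sum(), fail_miss.sum(),
    )
    if not keep.any():
        counts = {"MAF": int(fail_maf.sum()), "heterozygosity": int(fail_het.sum()),
                  "missing rate": int(fail_miss.sum())}
        binding = max(counts, key=counts.get)
        raise ValueError(
            f"all {raw.n_markers} markers removed by filtering; "
            f"binding criterion: {binding} ({counts})"
        )
    return raw.subset_markers(np.flatnonzero(keep))


def _imputed_codes(g: np.ndarray) -> np.ndarray:
    """Mean-impute a genotype block column-wise (for r² computation)."""
    out = g.copy()
    col_mean = np.nanmean(out, axis=0)
    idx = np.where(np.isnan(out))
    out[idx] = col_mean[idx[1]]
    return out


def ld_prune(
    m: MarkerMatrix,
    window: int = 100,
    step: int = 5,
    r2_max: float = 0.8,
) -> MarkerMatrix:
    """Greedy windowed LD pruning on squared Pearson correlation of
    genotype codes.

    Within each window of ``window`` markers (slid by ``step`` along the
    position-sorted marker list, per chromosome), pairs of retained
    markers are scanned in order; whenever a pair exceeds ``r2_max`` the
    later-positioned marker is removed.  Removed markers stay removed.
    """
    if m.positions is None:
        raise ValueError("ld_prune requires marker positions")
    pos = m.positions
    order_key = np.lexsort((pos[:, 1], pos[:, 0]))
    if not np.array_equal(order_key, np.arange(m.n_markers)):
        raise ValueError("markers must be sorted by (chromosome, position)")

    g = _imputed_codes(m.genotypes)
    gc = g - g.mean(axis=0)
    norm = np.sqrt((gc**2).sum(axis=0))
    keep = np.ones(m.n_markers, dtype=bool)
    chroms = pos[:, 0]
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        n = len(idx)
        start = 0
        while True:
            win = idx[start:start + window]
            live = win[keep[win]]
            if len(live) > 1:
                ok_sd = norm[live] > 0
                # one r² matrix per window; removals cannot create new
                # violating pairs, so a single ordered scan suffices
                gl = gc[:, live]
                with np.errstate(invalid="ignore", divide="ignore"):
                    R = (gl.T @ gl) / np.outer(norm[live], norm[live])
                R2 = R * R
                alive = np.ones(len(live), dtype=bool)
                for a in range(len(live)):
                    if not alive[a] or not ok_sd[a]:
                        continue
                    for b in range(a + 1, len(live)):
                        if alive[b] and ok_sd[b] and R2[a, b] > r2_max:
                            alive[b] = False
                keep[live[~alive]] = False
            if start + window >= n:
                break
            start += step
    logger.info("LD pruning: %d/%d markers retained", keep.sum(), m.n_markers)
    return m.subset_markers(np.flatnonzero(keep))


def impute_missing(m: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing call by the marker's observed mean code
    (the observed frequency on the 0-1 scale)."""
    g = m.genotypes
    entirely = np.isnan(g).all(axis=0)
    if entirely.any():
        bad = [m.marker_ids[i] for i in np.flatnonzero(entirely)[:5]]
        raise ValueError(f"markers entirely missing, cannot impute: {bad}")
    if not np.isnan(g).any():
        return m
    return replace(m, genotypes=_imputed_codes(g), imputed=True)


def compute_kinship(m: MarkerMatrix) -> KinshipMatrix:
    """Kinship K_ij = Σ_l (M_il − p_l)(M_jl − p_l) / b with
    b = Σ_l p_l(1−p_l)."""
    g = m.genotypes
    if np.isnan(g).any():
        raise ValueError("genotypes contain missing values; run impute_missing first")
    p = m.frequencies()
    b = float(np.sum(p * (1.0 - p)))
    if b == 0.0:
        raise ValueError("all markers monomorphic (b = 0); kinship undefined")
    C = g - p
    K = (C @ C.T) / b
    K = 0.5 * (K + K.T)
    return KinshipMatrix(values=K, variety_ids=list(m.variety_ids), scale_b=b)


# ---------------------------------------------------------------- readers

_GT_TO_CODE = {(0, 0): 1.0, (0, 1): 0.5, (1, 0): 0.5, (1, 1): 0.0}


def read_vcf(path) -> MarkerMatrix:
    """Read biallelic sites from a VCF; GT mapped to 1 / 0.5 / 0
    (homozygous-ref / het / homozygous-alt)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, pos = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = var.genotypes  # [allele1, allele2, phased]
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(gts):
            a, b_ = gt[0], gt[1]
            if a < 0 or b_ < 0:
                continue
            col[i] = _GT_TO_CODE.get((a, b_), np.nan)
        cols.append(col)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        try:
            chrom = int(str(var.CHROM).lstrip("chr"))
        except ValueError:
            chrom = abs(hash(var.CHROM)) % 10**6
        pos.append((chrom, var.POS))
    if not cols:
        raise ValueError("no biallelic sites in VCF")
    return MarkerMatrix(np.column_stack(cols), samples, ids, np.array(pos))


def read_plink_raw(path) -> MarkerMatrix:
    """Read a PLINK .raw additive file (0/1/2 dosage, rescaled by /2)."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    ids = df["IID"].astype(str).tolist() if "IID" in df.columns else [str(i) for i in df.index]
    g = df.drop(columns=meta).to_numpy(float) / 2.0
    markers = [c for c in df.columns if c not in meta]
    return MarkerMatrix(g, ids, markers)


def read_csv_matrix(path) -> MarkerMatrix:
    """Read a plain varieties × markers CSV of codes in {1, 0.5, 0}."""
    df = pd.read_csv(path, index_col=0)
    return MarkerMatrix(df.to_numpy(float), list(df.index.astype(str)),
                        list(df.columns.astype(str)))
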
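"""Additive association scan, conditional analysis, genomic control and PCA.

The scan is ordinary least squares of the phenotype on per-variant dosage
plus covariates, computed via Frisch-Waugh-Lovell residualization so that a
whole panel is scanned with two matrix products per variant block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: chi-square(1 df) median, the genomic-control normalizer.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class ScanResult:
    """Per-variant association records plus scan-level diagnostics.

    ``records`` uses the summary-stat dialect columns (ID, CHR, POS, EA, OA,
    EAF, BETA, SE, P, N) plus Z and a ``flag`` column (empty or
    ``monomorphic``), sorted by position.
    """

    records: pd.DataFrame
    lambda_gc: float
    covariates: list[str] = field(default_factory=list)


def _residualize(y: np.ndarray, covariates: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Project out covariates + intercept; returns (residual maker applied to y, Q, k)."""
    n = len(y)
    x = np.column_stack([np.ones(n), covariates]) if covariates.size else np.ones((n, 1))
    q, r = np.linalg.qr(x)
    if np.linalg.matrix_rank(r, tol=1e-8) < x.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    y_res = y - q @ (q.T @ y)
    return y_res, q, x.shape[1]


def additive_scan(phenotype: np.ndarray,
                  dosages: np.ndarray,
                  variants: pd.DataFrame,
                  covariates: pd.DataFrame | np.ndarray | None = None) -> ScanResult:
    """Per-variant OLS of phenotype on dosage + covariates + intercept.

    ``variants`` must carry ``id, chrom, pos`` and effect/other allele
    columns (``alt``/``ref`` or ``EA``/``OA``).  Dosage-term p-values use
    the t distribution with ``n - k`` residual degrees of freedom.  Constant
    dosage columns are flagged ``monomorphic`` and get no estimate.
    """
    y = np.asarray(phenotype, dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values")
    dos = np.asarray(dosages, dtype=float)
    n, n_var = dos.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match dosage rows")

    cov_names: list[str] = []
    if covariates is None:
        cov = np.empty((n, 0))
    elif isinstance(covariates, pd.DataFrame):
        cov_names = list(covariates.columns)
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float)
        cov_names = [f"c{i}" for i in range(cov.shape[1])]
    if cov.size and np.isnan(cov).any():
        keep = ~np.isnan(cov).any(axis=1)  # listwise deletion
        y, dos, cov = y[keep], dos[keep], cov[keep]
        n = len(y)

    y_res, q, k_cov = _residualize(y, cov)
    x_res = dos - q @ (q.T @ dos)

    sxx = np.einsum("ij,ij->j", x_res, x_res)
    sxy = x_res.T @ y_res
    syy = float(y_res @ y_res)
    mono = sxx <= 1e-12

    df = n - k_cov - 1
    if df <= 0:
        raise ValueError("not enough samples for the requested model")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, np.nan, sxy / np.where(mono, 1.0, sxx))
        rss = syy - beta * sxy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / np.where(mono, np.nan, sxx))
        z = beta / se
    p = 2.0 * stats.t.sf(np.abs(z), df=df)

    ea = variants["alt"] if "alt" in variants else variants["EA"]
    oa = variants["ref"] if "ref" in variants else variants["OA"]
    records = pd.DataFrame({
        "ID": variants["id"].to_numpy() if "id" in variants else variants["ID"].to_numpy(),
        "CHR": variants["chrom"].to_numpy() if "chrom" in variants else variants["CHR"].to_numpy(),
        "POS": variants["pos"].to_numpy() if "pos" in variants else variants["POS"].to_numpy(),
        "EA": np.asarray(ea),
        "OA": np.asarray(oa),
        "EAF": dos.mean(axis=0) / 2.0,
        "BETA": beta,
        "SE": se,
        "Z": z,
        "P": p,
        "N": n,
        "flag": np.where(mono, "monomorphic", ""),
    })
    records.loc[mono, ["BETA", "SE", "Z", "P"]] = np.nan
    records = records.sort_values("POS", kind="stable").reset_index(drop=True)

    ok = records["P"].notna()
    lam = genomic_control_lambda(records.loc[ok, "P"].to_numpy()) if ok.any() else np.nan
    return ScanResult(records=records, lambda_gc=lam, covariates=cov_names)


def conditional_scan(phenotype: np.ndarray,
                     dosages: np.ndarray,
                     variants: pd.DataFrame,
                     condition_on: Sequence[str],
                     covariates: pd.DataFrame | np.ndarray | None = None) -> ScanResult:
    """Re-scan with the dosages of ``condition_on`` variants as covariates.

    The conditioned variants themselves are omitted from the output.  An
    empty ``condition_on`` reduces to :func:`additive_scan`.
    """
    ids = variants["id"] if "id" in variants else variants["ID"]
    ids = ids.to_numpy()
    cond_idx = []
    for vid in condition_on:
        hits = np.flatnonzero(ids == vid)
        if len(hits) == 0:
            raise KeyError(f"conditioning variant {vid!r} not in panel")
        cond_idx.append(int(hits[0]))

    dos = np.asarray(dosages, dtype=float)
    for j in cond_idx:
        if np.nanstd(dos[:, j]) <= 1e-12:
            raise ValueError(f"conditioning variant {ids[j]!r} is monomorphic")

    if covariates is None:
        cov = pd.DataFrame(index=range(dos.shape[0]))
    elif isinstance(covariates, pd.DataFrame):
        cov = covariates.copy()
    else:
        cov = pd.DataFrame(np.asarray(covariates, dtype=float))
        cov.columns = [f"c{i}" for i in cov.columns]
    for j in cond_idx:
        cov[f"cond_{ids[j]}"] = dos[:, j]

    keep = np.setdiff1d(np.arange(dos.shape[1]), cond_idx)
    result = additive_scan(phenotype, dos[:, keep],
                           variants.iloc[keep].reset_index(drop=True), cov)
    return result


def genomic_control_lambda(p_values: np.ndarray | None = None,
                           chi2: np.ndarray | None = None) -> float:
    """Median 1-df chi-square statistic over its null median (0.45494)."""
    if chi2 is None:
        if p_values is None or len(p_values) == 0:
            raise ValueError("need p-values or chi-square statistics")
        chi2 = stats.chi2.isf(np.asarray(p_values, dtype=float), df=1)
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValueError("empty input")
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def pca_covariates(dosages: np.ndarray, k: int = 4) -> np.ndarray:
    """Top-k principal components of the column-standardized dosage matrix.

    Returns an (N, k) score matrix ordered by explained variance.  Input
    should be LD-pruned first.  Monomorphic columns are ignored.
    """
    dos = np.asarray(dosages, dtype=float)
    mu = np.nanmean(dos, axis=0)
    sd = np.nanstd(dos, axis=0)
    ok = sd > 0
    x = (dos[:, ok] - mu[ok]) / sd[ok]
    x = np.nan_to_num(x)
    if k == 0:
        return np.empty((dos.shape[0], 0))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if k > rank:
        raise ValueError(f"requested {k} components but rank is {rank}")
    return u[:, :k] * s[:k]


def variance_explained(eaf: float, beta: float, phenotype_variance: float) -> float:
    """Fraction of phenotype variance from one additive variant: 2p(1-p)b^2/s2."""
    if phenotype_variance <= 0:
        raise ValueError("phenotype variance must be positive")
    if beta == 0.0:
        return 0.0
    if not 0.0 < eaf < 1.0:
        raise ValueError("eaf must be in (0, 1)")
    return 2.0 * eaf * (1.0 - eaf) * beta ** 2 / phenotype_variance
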
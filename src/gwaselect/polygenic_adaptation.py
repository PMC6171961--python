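"""Polygenic scores per population and the excess-divergence (Qx) test.

The score for population m is ``Z_m = 2 * sum_l beta_l * p_ml``.  Under
neutral drift the vector of scores deviates from its mean according to a
multivariate-normal model whose among-population covariance F is estimated
from frequency-matched, presumably neutral variants; coordinated selection
shows up as excess divergence.  Both a chi-square p-value (M - 1 df) and an
empirical p-value from resampled matched neutral locus sets are computed;
the empirical null is authoritative when they disagree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QxResult:
    qx: float
    df: int
    p_chi2: float
    p_empirical: float
    n_resamples: int
    scores: pd.Series | None = None


def genetic_score(freqs: pd.DataFrame, betas: pd.Series) -> pd.Series:
    """Z_m = 2 * sum_l beta_l * p_ml for every population (column of freqs).

    ``freqs`` is indexed by variant id with one column per population and
    must cover every scored locus in every population.
    """
    betas = betas.astype(float)
    missing_loci = [v for v in betas.index if v not in freqs.index]
    if missing_loci:
        raise KeyError(f"no frequencies for loci {missing_loci}")
    sub = freqs.loc[betas.index]
    bad = sub.isna()
    if bad.any().any():
        locus = bad.index[bad.any(axis=1)][0]
        pop = bad.columns[bad.loc[locus]][0]
        raise ValueError(f"missing frequency for locus {locus} in population {pop}")
    return 2.0 * sub.mul(betas, axis=0).sum(axis=0)


def _standardized_deviations(freqs: pd.DataFrame,
                             reference: pd.Series | None = None) -> np.ndarray:
    """x_lm = (p_ml - pbar_l) / sqrt(pbar_l (1 - pbar_l)), rows = variants.

    ``pbar`` is the across-population mean by default; a per-variant
    ancestral/outgroup frequency may be supplied instead (the mean is only a
    proxy for the unobservable ancestral frequency, and degenerates for
    M = 2 where centered deviations are exactly opposite).
    """
    p = freqs.to_numpy(dtype=float)
    pbar = (reference.loc[freqs.index].to_numpy(dtype=float)
            if reference is not None else p.mean(axis=1))
    ok = (pbar > 0) & (pbar < 1)
    scale = np.sqrt(pbar[ok] * (1.0 - pbar[ok]))
    return (p[ok] - pbar[ok, None]) / scale[:, None]


def _freq_bins(freqs: pd.DataFrame, bin_width: float) -> np.ndarray:
    pbar = freqs.to_numpy(dtype=float).mean(axis=1)
    n_bins = round(1.0 / bin_width)
    return np.clip((pbar // bin_width).astype(int), 0, n_bins - 1)


def neutral_covariance(neutral_freqs: pd.DataFrame,
                       scored_freqs: pd.DataFrame,
                       bin_width: float = 0.05,
                       n_sets: int = 1000,
                       rng: np.random.Generator | None = None,
                       reference: pd.Series | None = None
                       ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Drift covariance F from neutral variants plus matched resampling sets.

    F is the among-population covariance of standardized neutral frequency
    deviations.  Each matched set replaces every scored locus with a random
    neutral variant from the same mean-frequency bin (drawn without
    replacement within a set) so the empirical null preserves the scored
    loci's frequency composition.
    """
    rng = rng if rng is not None else np.random.default_rng()
    x = _standardized_deviations(neutral_freqs, reference)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 usable neutral variants")
    f_mat = np.cov(x.T)

    neutral_bins = _freq_bins(neutral_freqs, bin_width)
    scored_bins = _freq_bins(scored_freqs, bin_width)
    by_bin = {b: np.flatnonzero(neutral_bins == b) for b in set(neutral_bins)}
    for b in set(scored_bins):
        need = int(np.sum(scored_bins == b))
        have = len(by_bin.get(b, ()))
        if have < need:
            raise ValueError(f"frequency bin {b} has {have} neutral variants "
                             f"but {need} scored loci need matches")

    matched_sets: list[np.ndarray] = []
    for _ in range(n_sets):
        chosen: list[int] = []
        used: dict[int, set] = {}
        for b in scored_bins:
            pool = by_bin[b]
            taken = used.setdefault(b, set())
            pick = int(pool[rng.integers(len(pool))])
            while pick in taken and len(taken) < len(pool):
                pick = int(pool[rng.integers(len(pool))])
            taken.add(pick)
            chosen.append(pick)
        matched_sets.append(np.asarray(chosen))
    return f_mat, matched_sets


def _qx_statistic(z: np.ndarray, v_a: float, f_mat: np.ndarray) -> float:
    m = len(z)
    t = np.eye(m) - np.ones((m, m)) / m  # project out the mean
    dev = t @ z
    cov = 4.0 * v_a * (t @ f_mat @ t)
    return float(dev @ np.linalg.pinv(cov, rcond=1e-10) @ dev)


def qx_test(freqs: pd.DataFrame,
            betas: pd.Series,
            f_mat: np.ndarray,
            neutral_freqs: pd.DataFrame | None = None,
            matched_sets: list[np.ndarray] | None = None) -> QxResult:
    """Excess-divergence test of per-population polygenic scores.

    ``qx`` compares the centered score vector to its drift expectation
    ``4 V_A F`` on the (M - 1)-dimensional mean-orthogonal subspace, with
    ``V_A = sum_l beta_l^2 pbar_l (1 - pbar_l)``.  ``p_chi2`` uses the
    chi-square(M - 1) null; ``p_empirical`` recomputes the statistic on
    matched neutral locus sets (same betas) when they are supplied.
    """
    scores = genetic_score(freqs, betas)
    m = len(scores)
    if m < 2:
        raise ValueError("need at least 2 populations")
    sub = freqs.loc[betas.index].to_numpy(dtype=float)
    pbar = sub.mean(axis=1)
    beta_arr = betas.to_numpy(dtype=float)
    v_a = float(np.sum(beta_arr ** 2 * pbar * (1.0 - pbar)))
    if v_a <= 0.0:
        raise ValueError("additive variance V_A is zero (all betas zero or "
                         "frequencies fixed)")
    qx = _qx_statistic(scores.to_numpy(dtype=float), v_a, f_mat)
    p_chi2 = float(stats.chi2.sf(qx, df=m - 1))

    p_emp = np.nan
    n_res = 0
    if matched_sets:
        if neutral_freqs is None:
            raise ValueError("matched sets supplied without neutral frequencies")
        neutral_arr = neutral_freqs.to_numpy(dtype=float)
        exceed = 0
        for idx in matched_sets:
            p_set = neutral_arr[idx]
            pbar_set = p_set.mean(axis=1)
            v_a_set = float(np.sum(beta_arr ** 2 * pbar_set * (1.0 - pbar_set)))
            if v_a_set <= 0.0:
                continue
            z_set = 2.0 * (beta_arr @ p_set)
            q_set = _qx_statistic(z_set, v_a_set, f_mat)
            n_res += 1
            if q_set >= qx:
                exceed += 1
        if n_res:
            p_emp = (1.0 + exceed) / (1.0 + n_res)
    return QxResult(qx=qx, df=m - 1, p_chi2=p_chi2, p_empirical=float(p_emp),
                    n_resamples=n_res, scores=scores)
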
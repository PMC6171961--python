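"""Cross-cohort effect harmonization and meta-analysis.

Implements the two standard fixed-effects schemes (sample-size-weighted z
and inverse-variance), Cochran's Q with I-squared, and a DerSimonian-Laird
random-effects fallback.  All p-to-z conversion happens in log space so
p-values far below double underflow survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger("gwaselect")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MetaResult:
    """Pooled effect for one variant across k cohorts."""

    variant_id: str
    beta_meta: float
    se_meta: float
    z_meta: float
    p_meta: float
    k: int
    n_total: int
    directions: str
    q: float = np.nan
    q_df: int = 0
    i2: float = np.nan
    p_random: float = np.nan


def _complement_allele(a: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in a)


def _is_ambiguous(ea: str, oa: str) -> bool:
    return _complement_allele(ea) == oa


def harmonize_effects(cohorts: list[pd.DataFrame],
                      keep_ambiguous: bool = False) -> list[pd.DataFrame]:
    """Express every cohort on the first cohort's effect allele.

    Swapped-allele cohorts get ``beta -> -beta`` and ``eaf -> 1 - eaf``;
    strand flips (complementary allele pairs) are recognized; strand-ambiguous
    A/T and C/G variants are dropped unless ``keep_ambiguous``.  Variants
    whose allele sets are irreconcilable in any cohort are dropped with an
    error-level log.  Idempotent.
    """
    if not cohorts:
        raise ValueError("no cohorts supplied")
    ref = cohorts[0].set_index("ID")
    shared = set(ref.index)
    for df in cohorts[1:]:
        shared &= set(df["ID"])

    drop: set[str] = set()
    if not keep_ambiguous:
        for vid in shared:
            if _is_ambiguous(ref.loc[vid, "EA"], ref.loc[vid, "OA"]):
                logger.warning("dropping strand-ambiguous variant %s", vid)
                drop.add(vid)

    aligned: list[pd.DataFrame] = []
    for ci, df in enumerate(cohorts):
        out = df[df["ID"].isin(shared - drop)].copy().set_index("ID")
        if ci > 0:
            for vid in list(out.index):
                ea, oa = out.loc[vid, "EA"], out.loc[vid, "OA"]
                rea, roa = ref.loc[vid, "EA"], ref.loc[vid, "OA"]
                cea, coa = _complement_allele(ea), _complement_allele(oa)
                if (ea, oa) == (rea, roa) or (cea, coa) == (rea, roa):
                    pass
                elif (ea, oa) == (roa, rea) or (cea, coa) == (roa, rea):
                    out.loc[vid, "BETA"] = -out.loc[vid, "BETA"]
                    out.loc[vid, "EAF"] = 1.0 - out.loc[vid, "EAF"]
                else:
                    logger.error("irreconcilable alleles for %s in cohort %d "
                                 "(%s/%s vs %s/%s); dropped", vid, ci, ea, oa, rea, roa)
                    drop.add(vid)
                    continue
                out.loc[vid, ["EA", "OA"]] = [rea, roa]
        aligned.append(out)
    keep_ids = [vid for vid in ref.index if vid in shared - drop]
    return [df.loc[keep_ids].reset_index() for df in aligned]


def signed_z_from_p(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """z with |z| = Phi^-1(1 - p/2) carrying the effect direction, log-safe."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; handle underflow upstream")
    magnitude = -special.ndtri_exp(np.log(p) - np.log(2.0))
    return np.where(np.asarray(sign) >= 0, magnitude, -magnitude)


def _direction_string(betas: np.ndarray) -> str:
    return "".join("+" if b > 0 else ("-" if b < 0 else "0") for b in betas)


def meta_fixed_ss(betas: np.ndarray, ps: np.ndarray, ns: np.ndarray,
                  variant_id: str = "") -> MetaResult:
    """Sample-size-weighted z meta-analysis (METAL's default scheme)."""
    betas = np.asarray(betas, dtype=float)
    ps = np.asarray(ps, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = len(betas)
    if k < 1:
        raise ValueError("need at least one cohort")
    z = signed_z_from_p(ps, np.sign(betas))
    z_meta = float(np.sum(np.sqrt(ns) * z) / np.sqrt(np.sum(ns)))
    p_meta = float(2.0 * stats.norm.sf(abs(z_meta)))
    return MetaResult(variant_id=variant_id, beta_meta=np.nan, se_meta=np.nan,
                      z_meta=z_meta, p_meta=p_meta, k=k,
                      n_total=int(np.sum(ns)),
                      directions=_direction_string(betas))


def meta_fixed_iv(betas: np.ndarray, ses: np.ndarray,
                  ns: np.ndarray | None = None,
                  variant_id: str = "") -> MetaResult:
    """Inverse-variance fixed-effects meta-analysis."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if len(betas) < 1:
        raise ValueError("need at least one cohort")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    n_total = int(np.sum(ns)) if ns is not None else 0
    return MetaResult(variant_id=variant_id, beta_meta=beta, se_meta=se,
                      z_meta=z, p_meta=p, k=len(betas), n_total=n_total,
                      directions=_direction_string(betas))


def heterogeneity(betas: np.ndarray, ses: np.ndarray) -> tuple[float, int, float]:
    """Cochran's Q, its degrees of freedom and I-squared (percent)."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    k = len(betas)
    if k < 2:
        raise ValueError("heterogeneity needs at least 2 cohorts")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses ** 2
    beta_iv = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - beta_iv) ** 2))
    return q, k - 1, i_squared(q, k)


def i_squared(q: float, k: int) -> float:
    """I-squared in percent from Q over k cohorts: max(0, (Q - df) / Q) * 100."""
    if q <= 0.0:
        return 0.0
    return float(max(0.0, (q - (k - 1)) / q) * 100.0)


def meta_random_dl(betas: np.ndarray, ses: np.ndarray,
                   ns: np.ndarray | None = None,
                   variant_id: str = "") -> MetaResult:
    """DerSimonian-Laird random-effects meta-analysis."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    k = len(betas)
    if k < 2:
        raise ValueError("random-effects meta needs at least 2 cohorts")
    q, q_df, i2 = heterogeneity(betas, ses)
    w = 1.0 / ses ** 2
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (q - q_df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ses ** 2 + tau2)
    beta = float(np.sum(w_star * betas) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    n_total = int(np.sum(ns)) if ns is not None else 0
    return MetaResult(variant_id=variant_id, beta_meta=beta, se_meta=se,
                      z_meta=z, p_meta=p, k=k, n_total=n_total,
                      directions=_direction_string(betas),
                      q=q, q_df=q_df, i2=i2, p_random=p)


def meta_analyze(cohorts: list[pd.DataFrame],
                 keep_ambiguous: bool = False) -> pd.DataFrame:
    """Harmonize cohorts and meta-analyze every shared variant.

    Returns a METAL-style table with both fixed-effects schemes,
    heterogeneity, and the random-effects p-value where k >= 2.
    """
    aligned = harmonize_effects(cohorts, keep_ambiguous=keep_ambiguous)
    base = aligned[0][["ID", "CHR", "POS", "EA", "OA"]].copy()
    betas = np.column_stack([df["BETA"].to_numpy(dtype=float) for df in aligned])
    ses = np.column_stack([df["SE"].to_numpy(dtype=float) for df in aligned])
    ps = np.column_stack([df["P"].to_numpy(dtype=float) for df in aligned])
    ns = np.column_stack([df["N"].to_numpy(dtype=float) for df in aligned])

    rows = []
    for i, vid in enumerate(base["ID"]):
        ss = meta_fixed_ss(betas[i], ps[i], ns[i], variant_id=vid)
        iv = meta_fixed_iv(betas[i], ses[i], ns[i], variant_id=vid)
        row = {
            "ID": vid,
            "BETA": iv.beta_meta, "SE": iv.se_meta,
            "Z_IV": iv.z_meta, "P_IV": iv.p_meta,
            "Z_SS": ss.z_meta, "P_SS": ss.p_meta,
            "N": iv.n_total, "K": iv.k,
            "DIRECTIONS": iv.directions,
        }
        if len(aligned) >= 2:
            q, q_df, i2 = heterogeneity(betas[i], ses[i])
            rand = meta_random_dl(betas[i], ses[i], ns[i], variant_id=vid)
            row.update({"Q": q, "Q_DF": q_df, "I2": i2, "P_RANDOM": rand.p_meta})
        rows.append(row)
    out = base.merge(pd.DataFrame(rows), on="ID")
    return out.sort_values(["CHR", "POS"], kind="stable").reset_index(drop=True)
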
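"""Approximate Bayes factors, posterior causal probabilities, credible sets.

Per-locus procedure: take all variants within a fixed window of the lead
SNP, compute a single-causal-variant approximate Bayes factor for each from
its effect estimate and standard error, normalize to posteriors, rank, and
flag the smallest prefix whose cumulative posterior strictly exceeds the
credible mass.  All Bayes-factor arithmetic is done on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass
class FineMapConfig:
    window_halfwidth: int = 500_000
    credible_mass: float = 0.99
    prior_w: float = 0.04  # prior effect variance (prior sd 0.2 trait units)

    def __post_init__(self) -> None:
        if not 0.0 < self.credible_mass < 1.0:
            raise ValueError("credible_mass must be in (0, 1)")
        if self.prior_w <= 0.0:
            raise ValueError("prior_w must be positive")


def locus_window(records: pd.DataFrame, top: str,
                 config: FineMapConfig | None = None) -> pd.DataFrame:
    """Variants on the lead SNP's chromosome within +/- halfwidth (closed)."""
    config = config or FineMapConfig()
    hit = records.loc[records["ID"] == top]
    if hit.empty:
        raise KeyError(f"top variant {top!r} not in records")
    chrom = hit["CHR"].iloc[0]
    pos = hit["POS"].iloc[0]
    mask = (records["CHR"] == chrom) & \
        (np.abs(records["POS"] - pos) <= config.window_halfwidth)
    return records.loc[mask].reset_index(drop=True)


def log_approx_bf(beta: np.ndarray, se: np.ndarray, prior_w: float = 0.04) -> np.ndarray:
    """Log approximate Bayes factor in favor of association.

    With V = se^2 and z = beta/se:
        log BF = 0.5 * log(V / (V + W)) + z^2 * W / (2 * (V + W))
    i.e. the reciprocal of Wakefield's ABF against association.
    """
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    v = se ** 2
    z2 = (np.asarray(beta, dtype=float) / se) ** 2
    return 0.5 * np.log(v / (v + prior_w)) + z2 * prior_w / (2.0 * (v + prior_w))


def approx_bf(beta: float, se: float, prior_w: float = 0.04) -> float:
    """Linear-scale approximate Bayes factor (may overflow for huge z)."""
    return float(np.exp(log_approx_bf(np.asarray([beta]), np.asarray([se]), prior_w))[0])


def credible_set(records: pd.DataFrame,
                 config: FineMapConfig | None = None,
                 log_bf: np.ndarray | None = None) -> pd.DataFrame:
    """Posteriors, ranks and credible-set membership for one locus.

    ``records`` needs ID/POS/BETA/SE columns (log BFs may be supplied
    directly instead).  Ranking ties break by position then id so sets are
    reproducible.  Membership is the smallest descending-posterior prefix
    whose cumulative posterior strictly exceeds ``credible_mass``.
    """
    config = config or FineMapConfig()
    if len(records) == 0:
        raise ValueError("empty locus")
    if log_bf is None:
        log_bf = log_approx_bf(records["BETA"].to_numpy(),
                               records["SE"].to_numpy(), config.prior_w)
    log_bf = np.asarray(log_bf, dtype=float)
    if not np.all(np.isfinite(log_bf)):
        raise ValueError("non-finite log Bayes factor")

    posterior = np.exp(log_bf - logsumexp(log_bf))

    out = records.copy()
    out["LOG_BF"] = log_bf
    out["POSTERIOR"] = posterior
    order = sorted(
        range(len(out)),
        key=lambda i: (-log_bf[i], out["POS"].iloc[i], out["ID"].iloc[i]))
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["RANK"] = ranks

    cum = np.cumsum(posterior[order])
    # tiny tolerance so ties at exactly the mass count as "not exceeded"
    n_in = int(np.searchsorted(cum, config.credible_mass + 1e-12, side="right")) + 1
    n_in = min(n_in, len(out))
    in_set = np.zeros(len(out), dtype=bool)
    in_set[np.asarray(order[:n_in])] = True
    out["IN_CREDIBLE_SET"] = in_set
    return out.sort_values("RANK").reset_index(drop=True)


def finemap_locus(records: pd.DataFrame, top: str,
                  config: FineMapConfig | None = None) -> pd.DataFrame:
    """Window around the lead SNP, then Bayes factors and the credible set."""
    config = config or FineMapConfig()
    return credible_set(locus_window(records, top, config), config)
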
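"""Inter-rater agreement, categorical diversity and covariate summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KappaResult:
    kappa: float
    p_o: float  # observed agreement
    p_e: float  # chance agreement
    n: int
    undefined: bool = False


@dataclass
class DiversityResult:
    d: float
    frequencies: dict


def cohens_kappa(ratings_a, ratings_b,
                 weighted: bool = False) -> KappaResult:
    """Cohen's kappa between two raters over a shared ordinal category set.

    Unweighted by default; ``weighted=True`` applies linear weights (the
    ordinal variant).  If chance agreement is 1 (both raters constant and
    equal) kappa is undefined and flagged.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    if len(a) == 0:
        raise ValueError("need at least one rated case")
    cats = np.union1d(np.unique(a), np.unique(b))
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    n = len(a)
    table /= n

    if weighted:
        grid = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / max(k - 1, 1)
        w = 1.0 - grid
    else:
        w = np.eye(k)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    p_o = float(np.sum(w * table))
    p_e = float(np.sum(w * np.outer(row, col)))
    if p_e >= 1.0 - 1e-12:
        return KappaResult(kappa=np.nan, p_o=p_o, p_e=p_e, n=n, undefined=True)
    return KappaResult(kappa=(p_o - p_e) / (1.0 - p_e), p_o=p_o, p_e=p_e, n=n)


def gini_diversity(levels) -> DiversityResult:
    """Gini-Simpson diversity 1 - sum(f_k^2) over category frequencies."""
    levels = np.asarray(levels)
    if levels.size == 0:
        raise ValueError("need at least one observation")
    cats, counts = np.unique(levels, return_counts=True)
    f = counts / counts.sum()
    return DiversityResult(d=float(1.0 - np.sum(f ** 2)),
                           frequencies={c: float(x) for c, x in zip(cats.tolist(), f)})


def covariate_assoc(phenotype, sex, age) -> pd.DataFrame:
    """OLS of phenotype on sex + age; per-covariate beta, se and t-test p.

    Constant covariates are flagged instead of estimated.
    """
    y = np.asarray(phenotype, dtype=float)
    covs = {"sex": np.asarray(sex, dtype=float), "age": np.asarray(age, dtype=float)}
    usable = {k: v for k, v in covs.items() if np.std(v) > 0}
    flagged = [k for k in covs if k not in usable]
    n = len(y)
    if n <= len(usable) + 1:
        raise ValueError("too few samples for the covariate model")

    x = np.column_stack([np.ones(n)] + [usable[k] for k in usable])
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    df = n - x.shape[1]
    sigma2 = resid @ resid / df
    cov_beta = sigma2 * np.linalg.inv(x.T @ x)
    se = np.sqrt(np.diag(cov_beta))
    t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df)

    rows = []
    for i, name in enumerate(usable, start=1):
        rows.append({"covariate": name, "beta": coef[i], "se": se[i],
                     "p": p[i], "flag": ""})
    for name in flagged:
        rows.append({"covariate": name, "beta": np.nan, "se": np.nan,
                     "p": np.nan, "flag": "constant"})
    return pd.DataFrame(rows)
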
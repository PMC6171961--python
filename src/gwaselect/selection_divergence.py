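"""Pairwise between-population selection-difference test on logit frequencies.

The statistic is the log-odds contrast d = logit(p_A) - logit(p_B).  Its
null scale is calibrated empirically from genome-wide (or simulated)
variants, binned by mean frequency, with a robust (MAD-based) spread so
that truly selected calibration loci do not inflate the null.  p-values
assume a Gaussian null; ``d`` is reported in log-odds units (an optional
scaling constant converts to selection-coefficient units if the divergence
time is known).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAD_TO_SD = 1.4826022185056018  # 1 / Phi^-1(3/4)


def clamp_frequency(p: np.ndarray, n_haplotypes: np.ndarray) -> np.ndarray:
    """Clamp frequencies into [1/2n, 1 - 1/2n] so fixed alleles stay finite
    on the logit scale (n_haplotypes = 2n for diploids)."""
    n_hap = np.asarray(n_haplotypes, dtype=float)
    if np.any(n_hap <= 0):
        raise ValueError("haplotype counts must be positive")
    bound = 1.0 / n_hap
    return np.clip(np.asarray(p, dtype=float), bound, 1.0 - bound)


def logit_diff(p_a: np.ndarray, p_b: np.ndarray,
               n_a: np.ndarray, n_b: np.ndarray) -> np.ndarray:
    """logit(p_A) - logit(p_B) after per-population frequency clamping."""
    pa = clamp_frequency(p_a, n_a)
    pb = clamp_frequency(p_b, n_b)
    return np.log(pa / (1.0 - pa)) - np.log(pb / (1.0 - pb))


@dataclass
class NullCalibration:
    """Per-mean-frequency-bin null standard deviation for d."""

    bin_width: float
    sd_by_bin: dict[int, float]
    bin_of: dict[int, int] = field(default_factory=dict)  # raw bin -> merged bin

    def sd_for(self, mean_freq: float) -> float:
        raw = int(np.clip(mean_freq // self.bin_width, 0,
                          round(1.0 / self.bin_width) - 1))
        if raw not in self.bin_of:
            raise KeyError(f"no calibration for frequency bin {raw} "
                           f"(mean frequency {mean_freq:.3f})")
        return self.sd_by_bin[self.bin_of[raw]]


def calibrate_null(d: np.ndarray, mean_freq: np.ndarray,
                   bin_width: float = 0.05,
                   min_bin_count: int = 50,
                   robust: bool = True) -> NullCalibration:
    """Estimate the null sd of d per mean-frequency bin from genome-wide
    variants; thin bins are merged with their left (else right) neighbor."""
    d = np.asarray(d, dtype=float)
    mean_freq = np.asarray(mean_freq, dtype=float)
    if d.size == 0:
        raise ValueError("empty calibration set")
    if d.size < 500:
        warnings.warn(f"only {d.size} calibration variants; null sd estimates "
                      "may be unstable", stacklevel=2)
    n_bins = round(1.0 / bin_width)
    raw = np.clip((mean_freq // bin_width).astype(int), 0, n_bins - 1)

    occupied = sorted(set(raw.tolist()))
    groups: list[list[int]] = [[b] for b in occupied]
    counts = [int(np.sum(raw == b)) for b in occupied]
    changed = True
    while changed and len(groups) > 1:
        changed = False
        for gi, c in enumerate(counts):
            if c < min_bin_count:
                ni = gi - 1 if gi > 0 else gi + 1
                groups[ni].extend(groups[gi])
                counts[ni] += counts[gi]
                del groups[gi], counts[gi]
                changed = True
                break

    bin_of: dict[int, int] = {}
    sd_by_bin: dict[int, float] = {}
    for gid, members in enumerate(groups):
        for b in members:
            bin_of[b] = gid
        mask = np.isin(raw, members)
        vals = d[mask]
        if robust:
            sd = MAD_TO_SD * float(np.median(np.abs(vals - np.median(vals))))
        else:
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        sd_by_bin[gid] = sd
    return NullCalibration(bin_width=bin_width, sd_by_bin=sd_by_bin, bin_of=bin_of)


def seldiff_test(focal: pd.DataFrame,
                 calibration: NullCalibration,
                 alpha: float = 0.005,
                 pops: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Test focal variants for selection-coefficient differences.

    ``focal`` needs columns ``id, p_a, p_b, n_a, n_b`` (frequencies and
    haplotype counts per population).  ``alpha`` is interpreted as the
    already-corrected per-test threshold.  A focal variant whose frequency
    bin lacks calibration raises, naming the bin.
    """
    d = logit_diff(focal["p_a"].to_numpy(), focal["p_b"].to_numpy(),
                   focal["n_a"].to_numpy(), focal["n_b"].to_numpy())
    mean_freq = (focal["p_a"].to_numpy() + focal["p_b"].to_numpy()) / 2.0
    sd = np.array([calibration.sd_for(f) for f in mean_freq])
    if np.any(sd <= 0):
        raise ValueError("degenerate null: calibrated sd is zero")
    z = d / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "id": focal["id"].to_numpy(),
        "pop_a": pops[0],
        "pop_b": pops[1],
        "d": d,
        "sd_null": sd,
        "z": z,
        "p": p,
        "significant": p < alpha,
    })
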
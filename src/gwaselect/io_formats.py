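"""File formats, genotype QC, LD pruning and run-manifest plumbing.

This module owns the pipeline's external surface: phased VCF in/out,
summary-statistic TSVs, covariate tables, genetic maps and YAML configs.
Everything downstream works on the in-memory types defined here.
"""

from __future__ import annotations

import json
import logging
import platform
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gwaselect")

#: Column dialect for summary-statistic TSVs (one row per variant).
SUMMARY_COLUMNS = ["ID", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """Per-variant metadata carried through QC.

    Positions are 1-based (VCF convention); internal intervals elsewhere in
    the package are half-open ``[start, end)``.
    """

    id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    call_rate: float = 1.0
    hwe_p: float = 1.0
    info: float | None = None

    def __post_init__(self) -> None:
        if not self.effect_allele or not self.other_allele:
            raise ValueError(f"{self.id}: alleles must be non-empty")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: alleles must be distinct")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.id}: eaf {self.eaf} outside [0, 1]")
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"{self.id}: call_rate {self.call_rate} outside [0, 1]")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class QcThresholds:
    """Exclusion thresholds for samples and variants."""

    max_sample_missing: float = 0.05
    max_variant_missing: float = 0.02
    min_maf: float = 0.01
    min_hwe_p: float = 1e-5
    min_info: float = 0.8

    def __post_init__(self) -> None:
        for name in ("max_sample_missing", "max_variant_missing", "min_maf",
                     "min_hwe_p", "min_info"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


@dataclass
class GeneticMap:
    """Physical-to-genetic coordinate map with piecewise-linear interpolation."""

    positions: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.cm = np.asarray(self.cm, dtype=float)
        if self.positions.shape != self.cm.shape:
            raise ValueError("positions and cm must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly ascending")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("cm must be non-decreasing")

    def interpolate(self, positions: np.ndarray) -> np.ndarray:
        """cM at arbitrary bp positions (clamped beyond the map ends)."""
        return np.interp(np.asarray(positions, dtype=float), self.positions, self.cm)

    @classmethod
    def uniform(cls, positions: Sequence[int], cm_per_bp: float) -> "GeneticMap":
        pos = np.asarray(sorted(positions), dtype=float)
        return cls(positions=pos, cm=(pos - pos[0]) * cm_per_bp)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep=r"\s+")
        return cls(positions=df["POS"].to_numpy(), cm=df["CM"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"POS": self.positions.astype(int), "CM": self.cm}).to_csv(
            path, sep="\t", index=False)


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes: ``2N`` rows (two per sample) by ``L`` sites.

    ``variants`` carries at least ``id, chrom, pos, ref, alt`` in ascending
    position order; haplotype entries code REF as 0 and ALT as 1.
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("site count mismatch between haplotypes and variants")
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype rows must equal 2 x sample count")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    def frequencies(self) -> np.ndarray:
        """ALT-allele frequency per site."""
        return self.haplotypes.mean(axis=0)

    def dosages(self) -> np.ndarray:
        """Per-sample ALT dosage matrix, shape (N, L)."""
        return (self.haplotypes[0::2].astype(np.int16)
                + self.haplotypes[1::2].astype(np.int16)).astype(float)

    def site_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return int(idx[0])


# ---------------------------------------------------------------------------
# VCF in/out
# ---------------------------------------------------------------------------

def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if span:
        start, _, end = span.partition("-")
        return chrom, int(start), int(end)
    return chrom, 1, sys.maxsize


def read_haplotypes(path: str | Path, region: str | None = None) -> HaplotypePanel:
    """Read phased biallelic GTs from a VCF into a haplotype panel.

    Multiallelic sites are skipped with a warning.  Unphased or missing
    genotypes at retained sites are errors: extended-haplotype statistics
    require complete phased data.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    want = _parse_region(region) if region else None

    columns: list[np.ndarray] = []
    meta: list[tuple] = []
    n_skipped = 0
    for v in vcf:
        if want is not None:
            chrom, start, end = want
            if v.CHROM != chrom or not (start <= v.POS <= end):
                continue
        if len(v.ALT) != 1:
            n_skipped += 1
            logger.warning("skipping multiallelic site %s:%d", v.CHROM, v.POS)
            continue
        gts = v.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(gts):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                raise ValueError(f"missing genotype at {v.CHROM}:{v.POS} sample {samples[i]}")
            if not phased:
                raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS} sample {samples[i]}")
            col[2 * i] = a0
            col[2 * i + 1] = a1
        columns.append(col)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        meta.append((vid, v.CHROM, v.POS, v.REF, v.ALT[0]))
    vcf.close()

    if n_skipped:
        logger.info("skipped %d multiallelic site(s)", n_skipped)
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    haps = (np.stack(columns, axis=1) if columns
            else np.empty((2 * len(samples), 0), dtype=np.uint8))
    order = np.argsort(variants["pos"].to_numpy(), kind="stable")
    variants = variants.iloc[order].reset_index(drop=True)
    haps = haps[:, order]
    return HaplotypePanel(haplotypes=haps, variants=variants, samples=samples)


def write_haplotypes(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal phased VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        haps = panel.haplotypes
        for j, row in panel.variants.iterrows():
            gts = "\t".join(
                f"{haps[2 * i, j]}|{haps[2 * i + 1, j]}"
                for i in range(len(panel.samples)))
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value by heterozygote enumeration.

    Sums the probabilities of all heterozygote counts (with the observed
    allele counts fixed) no more likely than the observed configuration.
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    minor = 2 * n_hom_minor + n_het
    major = 2 * n_hom_major + n_het
    if minor > major:  # symmetric; orient to the true minor allele
        minor, major = major, minor

    het_values = np.arange(minor % 2, minor + 1, 2)
    # Unnormalized log-probabilities via the standard ratio recurrence:
    # P(het+2)/P(het) = 4 * hom_minor * hom_major / ((het+2) * (het+1))
    logp = np.zeros(len(het_values))
    for k in range(1, len(het_values)):
        het = het_values[k - 1]
        hom_min = (minor - het) // 2
        hom_maj = (major - het) // 2
        logp[k] = logp[k - 1] + np.log(4.0 * hom_min * hom_maj) \
            - np.log((het + 2.0) * (het + 1.0))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(het_values, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Outcome of :func:`qc_filter` with a per-exclusion audit trail."""

    dosages: np.ndarray
    variants: list[VariantRecord]
    samples: list[str]
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    excluded_variants: list[tuple[str, str]] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_samples": len(self.samples),
            "n_variants": len(self.variants),
            "n_excluded_samples": len(self.excluded_samples),
            "n_excluded_variants": len(self.excluded_variants),
        }


def qc_filter(dosages: np.ndarray,
              variants: Sequence[VariantRecord],
              samples: Sequence[str],
              thresholds: QcThresholds | None = None) -> QcReport:
    """Apply sample-missingness then variant-level QC to a dosage matrix.

    ``dosages`` is samples x variants with entries in {0, 1, 2} or NaN for
    missing.  Samples exceeding the missingness threshold are removed first
    so that variant statistics (missingness, MAF, the Hardy-Weinberg exact
    test) reflect the analyzed sample set.  INFO is taken from the variant
    records when present.
    """
    thresholds = thresholds or QcThresholds()
    dosages = np.asarray(dosages, dtype=float)
    if dosages.shape != (len(samples), len(variants)):
        raise ValueError("dosage matrix shape does not match samples x variants")

    missing = np.isnan(dosages)
    sample_miss = missing.mean(axis=1) if len(variants) else np.zeros(len(samples))
    keep_samples = sample_miss <= thresholds.max_sample_missing
    excluded_samples = [
        (samples[i], f"missingness {sample_miss[i]:.4f} > {thresholds.max_sample_missing}")
        for i in np.flatnonzero(~keep_samples)]

    dos = dosages[keep_samples]
    kept_samples = [s for s, k in zip(samples, keep_samples) if k]
    if not kept_samples:
        raise ValueError("no samples survive QC")

    keep_variants = []
    excluded_variants: list[tuple[str, str]] = []
    for j, rec in enumerate(variants):
        col = dos[:, j]
        obs = col[~np.isnan(col)]
        miss_frac = 1.0 - len(obs) / len(col)
        if miss_frac > thresholds.max_variant_missing:
            excluded_variants.append(
                (rec.id, f"missingness {miss_frac:.4f} > {thresholds.max_variant_missing}"))
            continue
        eaf = obs.mean() / 2.0 if len(obs) else 0.0
        maf = min(eaf, 1.0 - eaf)
        if maf < thresholds.min_maf:
            excluded_variants.append((rec.id, f"maf {maf:.4f} < {thresholds.min_maf}"))
            continue
        n_het = int(np.sum(obs == 1))
        n_hom_alt = int(np.sum(obs == 2))
        n_hom_ref = int(np.sum(obs == 0))
        hwe_p = hwe_exact_test(n_het, n_hom_alt, n_hom_ref)
        if hwe_p < thresholds.min_hwe_p:
            excluded_variants.append((rec.id, f"hwe_p {hwe_p:.3g} < {thresholds.min_hwe_p}"))
            continue
        if rec.info is not None and rec.info < thresholds.min_info:
            excluded_variants.append((rec.id, f"info {rec.info:.3f} < {thresholds.min_info}"))
            continue
        keep_variants.append(j)

    if not keep_variants:
        raise ValueError("no variants survive QC")

    kept = [variants[j] for j in keep_variants]
    return QcReport(dosages=dos[:, keep_variants], variants=kept,
                    samples=kept_samples,
                    excluded_samples=excluded_samples,
                    excluded_variants=excluded_variants)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(dosages: np.ndarray,
             variant_ids: Sequence[str] | None = None,
             positions: Sequence[int] | None = None,
             r2_max: float = 0.2,
             window: int = 50,
             step: int = 5) -> list[int]:
    """Greedy windowed LD pruning; returns retained column indices.

    Within each window, while any retained pair has squared Pearson dosage
    correlation above ``r2_max``, the lower-MAF member is dropped (ties drop
    the later position).  Missing dosages are excluded pairwise.
    """
    dosages = np.asarray(dosages, dtype=float)
    n_var = dosages.shape[1]
    if n_var < 2:
        raise ValueError("ld_prune requires at least 2 variants")
    if window < 2:
        raise ValueError("window must be >= 2")
    positions = np.arange(n_var) if positions is None else np.asarray(positions)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eaf = np.nanmean(dosages, axis=0) / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)

    removed = np.zeros(n_var, dtype=bool)
    start = 0
    while True:
        idx = [j for j in range(start, min(start + window, n_var)) if not removed[j]]
        changed = True
        while changed:
            changed = False
            for a_i in range(len(idx)):
                for b_i in range(a_i + 1, len(idx)):
                    a, b = idx[a_i], idx[b_i]
                    if removed[a] or removed[b]:
                        continue
                    if _pairwise_r2(dosages[:, a], dosages[:, b]) > r2_max:
                        if maf[a] < maf[b]:
                            drop = a
                        elif maf[b] < maf[a]:
                            drop = b
                        else:
                            drop = a if positions[a] > positions[b] else b
                        removed[drop] = True
                        changed = True
            idx = [j for j in idx if not removed[j]]
        if start + window >= n_var:
            break
        start += step
    return [j for j in range(n_var) if not removed[j]]


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-stat file {path} missing columns {missing}")
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False,
                                      float_format="%.6g")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """PLINK-style whitespace-separated covariate table with an IID column."""
    df = pd.read_csv(path, sep=r"\s+")
    if "IID" not in df.columns:
        raise ValueError("covariate file must contain an IID column")
    return df


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_manifest(out_dir: str | Path, command: str, params: Mapping,
                   seed: int | None = None) -> Path:
    """Record command, parameters, seed and library versions for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import scipy

    manifest = {
        "command": command,
        "seed": seed,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
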
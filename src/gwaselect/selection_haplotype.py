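"""Extended haplotype homozygosity, iHH integration and the iHS scan.

EHH at a flanking site is the probability that two random carriers of the
core allele are identical over the whole stretch from the core to that
site, computed with the sample-size-corrected combinatorial form
``sum_h C(n_h, 2) / C(n_c, 2)`` over extended-haplotype groups.  Profiles
extend outward until EHH drops below a cutoff (0.05) or the chromosome
ends, in which case they are flagged truncated.  iHH is the trapezoidal
integral of EHH against genetic distance; iHS is the log ratio of
ancestral to derived iHH, standardized within derived-allele-frequency
bins of width 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneticMap, HaplotypePanel

logger = logging.getLogger("gwaselect")

EHH_CUTOFF = 0.05


@dataclass
class EhhProfile:
    """EHH values at signed cM offsets from the core (offset 0 has EHH 1)."""

    core_id: str
    core_allele: int
    offsets_cm: np.ndarray  # ascending, includes 0
    ehh: np.ndarray
    truncated_left: bool
    truncated_right: bool

    def side(self, direction: int) -> tuple[np.ndarray, np.ndarray]:
        """(|offset|, ehh) for one side, ordered outward from the core."""
        if direction < 0:
            mask = self.offsets_cm <= 0
            return -self.offsets_cm[mask][::-1], self.ehh[mask][::-1]
        mask = self.offsets_cm >= 0
        return self.offsets_cm[mask], self.ehh[mask]


def _ehh_walk(haps: np.ndarray, carriers: np.ndarray, core: int,
              direction: int, cutoff: float) -> tuple[list[int], list[float], bool]:
    """Extend the haplotype partition outward; returns (sites, ehh, truncated)."""
    n_c = len(carriers)
    denom = n_c * (n_c - 1) / 2.0
    # Rows in singleton groups can never rejoin a group, so only haplotypes
    # still in groups of size >= 2 are tracked.  Group labels stay dense in
    # [0, n_groups), so refinement is O(n) bincount relabeling, not a sort.
    active = np.asarray(carriers)
    codes = np.zeros(len(active), dtype=np.intp)
    n_groups = 1
    pairs = denom
    sites: list[int] = []
    values: list[float] = []
    j = core + direction
    n_sites = haps.shape[1]
    while 0 <= j < n_sites:
        alleles = haps[active, j]
        if alleles.size and alleles.min() != alleles.max():
            key = codes * 2 + alleles
            counts = np.bincount(key, minlength=2 * n_groups)
            pairs = float(np.sum(counts * (counts - 1)) // 2)
            keep = counts[key] >= 2
            occupied = np.flatnonzero(counts >= 2)
            relabel = np.empty(2 * n_groups, dtype=np.intp)
            relabel[occupied] = np.arange(len(occupied))
            codes = relabel[key[keep]]
            active = active[keep]
            n_groups = len(occupied)
        ehh = pairs / denom
        sites.append(j)
        values.append(ehh)
        if ehh < cutoff:
            return sites, values, False
        j += direction
    # ran off the chromosome end with EHH still >= cutoff
    return sites, values, True


def ehh_profile(panel: HaplotypePanel, gmap: GeneticMap, core: str | int,
                allele: int, cutoff: float = EHH_CUTOFF) -> EhhProfile:
    """EHH profile of one core allele, extended left and right to the cutoff."""
    core_j = panel.site_index(core) if isinstance(core, str) else int(core)
    haps = panel.haplotypes
    carriers = np.flatnonzero(haps[:, core_j] == allele)
    if len(carriers) < 2:
        raise ValueError(
            f"core allele {allele} at site {core!r} has {len(carriers)} carrier(s); "
            "need at least 2")
    cm = gmap.interpolate(panel.positions)

    left_sites, left_vals, trunc_l = _ehh_walk(haps, carriers, core_j, -1, cutoff)
    right_sites, right_vals, trunc_r = _ehh_walk(haps, carriers, core_j, +1, cutoff)

    offsets = np.concatenate([
        cm[left_sites[::-1]] - cm[core_j] if left_sites else np.empty(0),
        [0.0],
        cm[right_sites] - cm[core_j] if right_sites else np.empty(0),
    ])
    values = np.concatenate([left_vals[::-1], [1.0], right_vals])
    vid = panel.variants["id"].iloc[core_j]
    return EhhProfile(core_id=vid, core_allele=allele, offsets_cm=offsets,
                      ehh=values, truncated_left=trunc_l, truncated_right=trunc_r)


def integrate_ihh(profile: EhhProfile, cutoff: float = EHH_CUTOFF) -> float:
    """Trapezoidal area under EHH vs cM, each side out to and including the
    first sub-cutoff point; ihh = left + right."""
    total = 0.0
    for direction in (-1, +1):
        dist, ehh = profile.side(direction)
        if np.any(np.diff(ehh) > 1e-9):
            raise ValueError("EHH profile must be non-increasing away from the core")
        if len(dist) < 2:
            continue
        below = np.flatnonzero(ehh < cutoff)
        stop = below[0] + 1 if len(below) else len(dist)
        total += float(np.trapezoid(ehh[:stop], dist[:stop]))
    return total


@dataclass
class ThresholdResult:
    cutoff: float
    n_hits: int


def empirical_threshold(scores: np.ndarray, quantile: float = 0.999) -> ThresholdResult:
    """|score| quantile cutoff with the count of strict exceedances."""
    scores = np.abs(np.asarray(scores, dtype=float))
    scores = scores[np.isfinite(scores)]
    if scores.size == 0:
        raise ValueError("no scores supplied")
    if scores.size < 1000:
        warnings.warn(f"only {scores.size} scores; the {quantile:.3%} tail is "
                      "poorly determined", stacklevel=2)
    cutoff = float(np.quantile(scores, quantile))
    return ThresholdResult(cutoff=cutoff, n_hits=int(np.sum(scores > cutoff)))


@dataclass
class IhsStandardization:
    """Per-frequency-bin mean/sd of unstandardized iHS, reusable across scans.

    Fitting on a large (genome-wide or neutral) scan and applying to a
    focused region mirrors the usual practice of standardizing against all
    SNPs of the same frequency class rather than the region under test.
    """

    bin_width: float
    merged_of: dict[int, int]
    mean: dict[int, float]
    sd: dict[int, float]

    @classmethod
    def fit(cls, bins: np.ndarray, ihs_u: np.ndarray,
            bin_width: float = 0.05, min_bin_count: int = 20) -> "IhsStandardization":
        merged = _merge_thin_bins(np.asarray(bins), min_bin_count)
        mean: dict[int, float] = {}
        sd: dict[int, float] = {}
        gids = np.array([merged[b] for b in bins])
        for gid in set(merged.values()):
            vals = np.asarray(ihs_u)[gids == gid]
            mean[gid] = float(np.mean(vals))
            sd[gid] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return cls(bin_width=bin_width, merged_of=merged, mean=mean, sd=sd)

    def apply(self, bins: np.ndarray, ihs_u: np.ndarray) -> np.ndarray:
        out = np.full(len(ihs_u), np.nan)
        known = sorted(self.merged_of)
        for i, (b, u) in enumerate(zip(bins, ihs_u)):
            if not np.isfinite(u):
                continue
            if b not in self.merged_of:
                # clamp to the nearest fitted bin
                b = min(known, key=lambda k: abs(k - b))
            gid = self.merged_of[b]
            if self.sd[gid] > 0:
                out[i] = (u - self.mean[gid]) / self.sd[gid]
        return out


def _merge_thin_bins(bins: np.ndarray, min_count: int) -> dict[int, int]:
    """Map raw bin index -> merged bin id, merging bins under min_count with
    their nearest occupied neighbor (leftward when possible)."""
    uniq, counts = np.unique(bins, return_counts=True)
    groups = [[b] for b in uniq]
    sizes = list(counts)
    changed = True
    while changed and len(groups) > 1:
        changed = False
        for gi, size in enumerate(sizes):
            if size < min_count:
                ni = gi - 1 if gi > 0 else gi + 1
                groups[ni].extend(groups[gi])
                sizes[ni] += sizes[gi]
                del groups[gi], sizes[gi]
                changed = True
                break
    mapping = {}
    for gid, members in enumerate(groups):
        for b in members:
            mapping[b] = gid
    return mapping


def ihs_scan(panel: HaplotypePanel,
             gmap: GeneticMap,
             ancestral: np.ndarray,
             min_daf: float = 0.05,
             max_gap_bp: int = 200_000,
             cutoff: float = EHH_CUTOFF,
             bin_width: float = 0.05,
             min_bin_count: int = 20,
             reference: IhsStandardization | None = None) -> pd.DataFrame:
    """Genome-wide iHS with per-frequency-bin standardization.

    ``ancestral`` gives the ancestral allele code (0/1) per site.  Sites are
    scored when derived-allele frequency lies in [min_daf, 1 - min_daf];
    profiles spanning a physical gap above ``max_gap_bp`` or truncated at a
    chromosome end are flagged and excluded from standardization.  Bins
    thinner than ``min_bin_count`` are merged with neighbors.  p-values are
    two-sided standard-normal on the standardized score.  Passing a fitted
    :class:`IhsStandardization` standardizes against that reference (e.g. a
    genome-wide neutral scan) instead of this scan's own bin statistics.
    """
    ancestral = np.asarray(ancestral, dtype=int)
    n_sites = panel.n_sites
    if len(ancestral) != n_sites:
        raise ValueError("ancestral allele vector length mismatch")
    haps = panel.haplotypes
    positions = panel.positions
    freq_alt = panel.frequencies()

    rows = []
    for j in range(n_sites):
        anc = ancestral[j]
        der = 1 - anc
        daf = float(freq_alt[j]) if der == 1 else float(1.0 - freq_alt[j])
        row = {"id": panel.variants["id"].iloc[j], "pos": int(positions[j]),
               "daf": daf, "ihh_a": np.nan, "ihh_d": np.nan,
               "ihs_u": np.nan, "flag": ""}
        if not (min_daf <= daf <= 1.0 - min_daf):
            row["flag"] = "low_daf"
            rows.append(row)
            continue
        try:
            prof_a = ehh_profile(panel, gmap, j, anc, cutoff)
            prof_d = ehh_profile(panel, gmap, j, der, cutoff)
        except ValueError:
            row["flag"] = "too_few_carriers"
            rows.append(row)
            continue
        if (prof_a.truncated_left or prof_a.truncated_right
                or prof_d.truncated_left or prof_d.truncated_right):
            row["flag"] = "truncated"
        elif _spans_gap(positions, j, prof_a, prof_d, gmap, max_gap_bp):
            row["flag"] = "gap"
        ihh_a = integrate_ihh(prof_a, cutoff)
        ihh_d = integrate_ihh(prof_d, cutoff)
        row["ihh_a"], row["ihh_d"] = ihh_a, ihh_d
        if ihh_a <= 0.0 or ihh_d <= 0.0:
            row["flag"] = row["flag"] or "zero_ihh"
        else:
            row["ihs_u"] = float(np.log(ihh_a / ihh_d))
        rows.append(row)

    out = pd.DataFrame(rows)
    out["bin"] = np.clip((out["daf"] // bin_width).astype(int), 0,
                         int(round(1.0 / bin_width)) - 1)
    usable = (out["flag"] == "") & out["ihs_u"].notna()
    if not usable.any():
        raise ValueError("no sites pass the iHS filters")

    if reference is None:
        reference = IhsStandardization.fit(
            out.loc[usable, "bin"].to_numpy(),
            out.loc[usable, "ihs_u"].to_numpy(),
            bin_width=bin_width, min_bin_count=min_bin_count)
    out["ihs_s"] = np.nan
    out.loc[usable, "ihs_s"] = reference.apply(
        out.loc[usable, "bin"].to_numpy(), out.loc[usable, "ihs_u"].to_numpy())
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["ihs_s"]))
    return out


def _spans_gap(positions: np.ndarray, core: int, prof_a: EhhProfile,
               prof_d: EhhProfile, gmap: GeneticMap, max_gap_bp: int) -> bool:
    """True if either profile's physical extent crosses a bp gap above the cap."""
    cm = gmap.interpolate(positions)
    lo_cm = cm[core] + min(prof_a.offsets_cm.min(), prof_d.offsets_cm.min())
    hi_cm = cm[core] + max(prof_a.offsets_cm.max(), prof_d.offsets_cm.max())
    within = (cm >= lo_cm - 1e-12) & (cm <= hi_cm + 1e-12)
    span = positions[within]
    if len(span) < 2:
        return False
    return bool(np.max(np.diff(span)) > max_gap_bp)
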
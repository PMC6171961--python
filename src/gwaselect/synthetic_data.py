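"""Forward Wright-Fisher simulation and ordinal phenotype generation.

Provides truth-tagged synthetic inputs for every downstream stage: phased
multi-population haplotype panels evolved forward in time (drift, mutation,
recombination, optional selection with a population split), and a latent
additive trait discretized to a 3-level ordinal score with multi-rater noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import GeneticMap, HaplotypePanel


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass
class SelectedSite:
    """A site under selection: genotype fitness ``1, 1+hs, 1+s``.

    ``s`` may be a single coefficient (applied in every population after the
    split) or a per-population mapping.  ``s_ancestral`` applies during the
    joint phase before the split.  ``p0`` optionally pins the site's initial
    allele frequency.
    """

    site_index: int
    s: float | Mapping[str, float] = 0.0
    h: float = 0.5
    s_ancestral: float = 0.0
    p0: float | None = None
    #: start all copies of the selected allele on one haplotype background
    #: (a recent single-origin mutation), the configuration sweep statistics
    #: are designed to detect
    single_origin: bool = False

    def coefficient(self, population: str | None) -> float:
        if population is None:
            return self.s_ancestral
        if isinstance(self.s, Mapping):
            return float(self.s.get(population, 0.0))
        return float(self.s)

    def __post_init__(self) -> None:
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("dominance h must be in [0, 1]")
        coeffs = list(self.s.values()) if isinstance(self.s, Mapping) else [self.s]
        for c in coeffs + [self.s_ancestral]:
            if c < -1.0:
                raise ValueError("selection coefficient must be >= -1")


@dataclass
class SimulationConfig:
    n_diploid: Mapping[str, int]
    n_sites: int = 200
    sequence_length: int = 1_000_000
    mutation_rate: float = 0.0
    recombination_rate: float = 1e-8
    genetic_map: GeneticMap | None = None
    generations: int = 100
    split_generation: int = 0
    #: neutral generations run before selection starts, letting drift and
    #: mutation build equilibrium LD; single-origin selected alleles are
    #: (re)seeded at the end of the burn-in
    burnin_generations: int = 0
    selection: Sequence[SelectedSite] = field(default_factory=list)
    n_ancestral: int | None = None
    initial_frequency_range: tuple[float, float] = (0.05, 0.95)
    #: optional pre-evolved starting state (e.g. a long neutral burn-in run
    #: shared across sweep replicates); rows are haplotypes, columns sites
    initial_haplotypes: np.ndarray | None = None
    initial_positions: np.ndarray | None = None
    require_segregating: bool = False
    max_retries: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.n_diploid, int):
            self.n_diploid = {"pop1": self.n_diploid}
        if not self.n_diploid:
            raise ValueError("at least one population required")
        if self.split_generation > self.generations:
            raise ValueError("split_generation must be <= generations")
        for sel in self.selection:
            if not 0 <= sel.site_index < self.n_sites:
                raise ValueError(f"selected site {sel.site_index} out of range")

    @property
    def populations(self) -> list[str]:
        return list(self.n_diploid)


@dataclass
class TraitArchitecture:
    """Additive genetic architecture on a latent scale plus rating noise."""

    causal: Sequence[tuple[str, float]] = field(default_factory=list)
    gamma_sex: float = 0.0
    gamma_age: float = 0.0
    noise_sd: float = 1.0
    # Default cutpoints put N(0,1) latent mass at (0.25, 0.55, 0.20).
    thresholds: tuple[float, float] = (
        float(norm.ppf(0.25)), float(norm.ppf(0.80)))
    confusion: np.ndarray = field(default_factory=lambda: np.eye(3))
    n_raters: int = 3

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=float)
        if self.thresholds[0] >= self.thresholds[1]:
            raise ValueError("thresholds must be ascending")
        if self.confusion.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if not np.allclose(self.confusion.sum(axis=1), 1.0):
            raise ValueError("confusion rows must sum to 1")
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")


@dataclass
class TruthTable:
    """Ground truth for simulated variants and (optionally) individuals."""

    variants: pd.DataFrame
    individuals: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        self.variants.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Core Wright-Fisher machinery
# ---------------------------------------------------------------------------

def _interval_crossover_probs(positions: np.ndarray,
                              rate_per_bp: float,
                              gmap: GeneticMap | None) -> np.ndarray:
    """Per-interval crossover probability (Haldane, no interference)."""
    if gmap is not None:
        morgans = np.diff(gmap.interpolate(positions)) / 100.0
    else:
        morgans = np.diff(positions.astype(float)) * rate_per_bp
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def _fitness(haps: np.ndarray,
             selected: Sequence[SelectedSite],
             population: str | None) -> np.ndarray | None:
    n = haps.shape[0] // 2
    w: np.ndarray | None = None
    for sel in selected:
        s = sel.coefficient(population)
        if s == 0.0:
            continue
        if w is None:
            w = np.ones(n)
        dos = haps[0::2, sel.site_index].astype(int) + haps[1::2, sel.site_index]
        w = w * (1.0 + s * (dos == 2) + sel.h * s * (dos == 1))
    return w


def _evolve(haps: np.ndarray,
            n_offspring: int,
            generations: int,
            rec_probs: np.ndarray,
            mutation_rate: float,
            selected: Sequence[SelectedSite],
            population: str | None,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve a haplotype matrix for ``generations`` discrete WF generations.

    Each offspring gamete is a recombinant mosaic of one parent's two
    haplotypes; parents are drawn with probability proportional to fitness;
    mutations flip alleles at the per-site rate.
    """
    n_sites = haps.shape[1]
    for _ in range(generations):
        n_parents = haps.shape[0] // 2
        w = _fitness(haps, selected, population)
        if w is None:
            parents = rng.integers(0, n_parents, size=2 * n_offspring)
        else:
            parents = rng.choice(n_parents, size=2 * n_offspring, p=w / w.sum())
        a = haps[2 * parents]
        b = haps[2 * parents + 1]
        # chooser = parity of the crossover count left of each site
        if n_sites > 1:
            switches = rng.random((2 * n_offspring, n_sites - 1)) < rec_probs
            par = np.zeros((2 * n_offspring, n_sites), dtype=np.int64)
            np.cumsum(switches, axis=1, out=par[:, 1:])
            chooser = (par & 1).astype(bool)
        else:
            chooser = np.zeros((2 * n_offspring, 1), dtype=bool)
        flip = rng.random(2 * n_offspring) < 0.5
        chooser ^= flip[:, None]
        gametes = np.where(chooser, b, a)
        if mutation_rate > 0.0:
            n_mut = rng.poisson(mutation_rate * gametes.size)
            if n_mut:
                rows = rng.integers(0, gametes.shape[0], size=n_mut)
                cols = rng.integers(0, n_sites, size=n_mut)
                gametes[rows, cols] ^= 1
        haps = gametes.astype(np.uint8)
    return haps


def _initial_panel(config: SimulationConfig, n_diploid: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Initial standing variation in linkage equilibrium.

    Frequencies are log-uniform over the configured range (density ~ 1/p,
    loosely mimicking a neutral spectrum); selection entries with ``p0``
    override their site's starting frequency.
    """
    lo, hi = config.initial_frequency_range
    u = rng.random(config.n_sites)
    p = lo * (hi / lo) ** u
    for sel in config.selection:
        if sel.p0 is not None:
            p[sel.site_index] = sel.p0
    haps = (rng.random((2 * n_diploid, config.n_sites)) < p).astype(np.uint8)
    return haps, p


def _inject_single_origin(haps: np.ndarray, config: SimulationConfig,
                          rng: np.random.Generator) -> None:
    """Place every copy of a single-origin selected allele on one haplotype
    background, as if the mutation arose once shortly before selection."""
    for sel in config.selection:
        if not sel.single_origin:
            continue
        n_hap = haps.shape[0]
        k = max(1, int(round((sel.p0 if sel.p0 is not None else 1.0 / n_hap)
                             * n_hap)))
        origin = rng.integers(n_hap)
        template = haps[origin].copy()
        template[sel.site_index] = 1
        haps[:, sel.site_index] = 0
        chosen = rng.choice(n_hap, size=k, replace=False)
        haps[chosen] = template


def simulate_populations(config: SimulationConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[dict[str, HaplotypePanel], TruthTable]:
    """Run the forward simulation and return one panel per population.

    Populations share a single panel up to ``split_generation`` and then
    evolve independently from copies of it.  With ``require_segregating``,
    runs where any selected site fixes or is lost are redrawn up to
    ``max_retries`` times before raising.
    """
    master = rng if rng is not None else np.random.default_rng(config.seed)
    for _attempt in range(max(1, config.max_retries)):
        run_rng = np.random.default_rng(master.integers(2**63))
        panels, truth = _simulate_once(config, run_rng)
        if not config.require_segregating or _all_segregating(config, panels):
            return panels, truth
    raise RuntimeError(
        f"selected site lost/fixed in all {config.max_retries} attempts")


def _all_segregating(config: SimulationConfig,
                     panels: Mapping[str, HaplotypePanel]) -> bool:
    for sel in config.selection:
        for panel in panels.values():
            f = panel.haplotypes[:, sel.site_index].mean()
            if f <= 0.0 or f >= 1.0:
                return False
    return True


def _simulate_once(config: SimulationConfig, rng: np.random.Generator
                   ) -> tuple[dict[str, HaplotypePanel], TruthTable]:
    pops = config.populations
    n_anc = config.n_ancestral or max(config.n_diploid.values())
    if config.initial_positions is not None:
        positions = np.asarray(config.initial_positions)
    else:
        positions = np.sort(rng.choice(
            np.arange(1, config.sequence_length + 1),
            size=config.n_sites, replace=False))
    rec_probs = _interval_crossover_probs(
        positions, config.recombination_rate, config.genetic_map)

    if config.initial_haplotypes is not None:
        haps = np.asarray(config.initial_haplotypes, dtype=np.uint8).copy()
        if haps.shape[1] != config.n_sites:
            raise ValueError("initial haplotypes do not match n_sites")
        if haps.shape[0] != 2 * n_anc:
            haps = _copy_or_resample(haps, n_anc, rng)
        p_init = haps.mean(axis=0)
    else:
        haps, p_init = _initial_panel(config, n_anc, rng)
    if config.burnin_generations > 0:
        haps = _evolve(haps, n_anc, config.burnin_generations, rec_probs,
                       config.mutation_rate, [], None, rng)
    _inject_single_origin(haps, config, rng)
    haps = _evolve(haps, n_anc, config.split_generation, rec_probs,
                   config.mutation_rate, config.selection, None, rng)

    post_split = config.generations - config.split_generation
    variants = pd.DataFrame({
        "id": [f"v{j:05d}" for j in range(config.n_sites)],
        "chrom": "1",
        "pos": positions,
        "ref": "A",
        "alt": "G",
    })
    panels: dict[str, HaplotypePanel] = {}
    for pop in pops:
        n_dip = config.n_diploid[pop]
        pop_haps = _copy_or_resample(haps, n_dip, rng)
        pop_haps = _evolve(pop_haps, n_dip, post_split, rec_probs,
                           config.mutation_rate, config.selection, pop, rng)
        panels[pop] = HaplotypePanel(
            haplotypes=pop_haps,
            variants=variants.copy(),
            samples=[f"{pop}_i{i:05d}" for i in range(n_dip)])

    truth_var = variants[["id", "pos"]].copy()
    truth_var["site_index"] = np.arange(config.n_sites)
    truth_var["p_init"] = p_init
    truth_var["beta"] = 0.0
    for pop in pops:
        s_col = np.zeros(config.n_sites)
        for sel in config.selection:
            s_col[sel.site_index] = sel.coefficient(pop)
        truth_var[f"s_{pop}"] = s_col
        truth_var[f"freq_{pop}"] = panels[pop].frequencies()
    return panels, TruthTable(variants=truth_var)


def _copy_or_resample(haps: np.ndarray, n_diploid: int,
                      rng: np.random.Generator) -> np.ndarray:
    n_avail = haps.shape[0] // 2
    if n_diploid == n_avail:
        return haps.copy()
    idx = rng.choice(n_avail, size=n_diploid, replace=n_diploid > n_avail)
    rows = np.empty(2 * n_diploid, dtype=int)
    rows[0::2] = 2 * idx
    rows[1::2] = 2 * idx + 1
    return haps[rows].copy()


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def draw_covariates(n: int,
                    rng: np.random.Generator,
                    age_range: tuple[float, float] = (30.0, 80.0),
                    p_female: float = 0.5,
                    sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Sex (1 = female) Bernoulli, age uniform over a configurable range."""
    ids = list(sample_ids) if sample_ids is not None else [
        f"i{i:05d}" for i in range(n)]
    return pd.DataFrame({
        "IID": ids,
        "sex": (rng.random(n) < p_female).astype(int),
        "age": rng.uniform(age_range[0], age_range[1], size=n),
    })


def simulate_phenotypes(panel: HaplotypePanel,
                        arch: TraitArchitecture,
                        covariates: pd.DataFrame | None = None,
                        rng: np.random.Generator | None = None,
                        seed: int | None = None
                        ) -> tuple[pd.DataFrame, TruthTable]:
    """Latent additive trait -> ordinal level -> noisy multi-rater average.

    latent = sum(beta_l * dosage_l) + sex * gamma_sex + age * gamma_age
             + Normal(0, noise_sd); the ordinal level is set by the two
    cutpoints; each rater reports a level drawn from the confusion row of
    the true level; the final phenotype is the mean of the rater reports.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(panel.samples)
    if covariates is None:
        covariates = draw_covariates(n, rng, sample_ids=panel.samples)
    covariates = covariates.set_index("IID").loc[panel.samples].reset_index()

    dosages = panel.dosages()
    latent = np.zeros(n)
    for vid, beta in arch.causal:
        latent += beta * dosages[:, panel.site_index(vid)]
    latent += arch.gamma_sex * covariates["sex"].to_numpy()
    latent += arch.gamma_age * covariates["age"].to_numpy()
    latent += rng.normal(0.0, arch.noise_sd, size=n)

    level = 1 + np.searchsorted(np.asarray(arch.thresholds), latent)

    cum = np.cumsum(arch.confusion, axis=1)
    ratings = np.empty((n, arch.n_raters), dtype=int)
    for r in range(arch.n_raters):
        u = rng.random(n)
        ratings[:, r] = 1 + (u[:, None] > cum[level - 1]).sum(axis=1)

    table = pd.DataFrame({
        "IID": panel.samples,
        "phenotype": ratings.mean(axis=1),
        "sex": covariates["sex"].to_numpy(),
        "age": covariates["age"].to_numpy(),
    })
    for r in range(arch.n_raters):
        table[f"rating_{r + 1}"] = ratings[:, r]

    truth_ind = pd.DataFrame({
        "IID": panel.samples,
        "latent": latent,
        "true_level": level,
    })
    truth_var = panel.variants[["id", "pos"]].copy()
    beta_map = dict(arch.causal)
    truth_var["beta"] = [beta_map.get(v, 0.0) for v in truth_var["id"]]
    return table, TruthTable(variants=truth_var, individuals=truth_ind)
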
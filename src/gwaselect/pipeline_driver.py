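"""End-to-end orchestration on synthetic cohorts.

One multi-population simulation provides a panel per cohort (so causal loci
are shared by construction); each cohort is phenotyped, QC'd and scanned;
cohorts are harmonized and meta-analyzed with heterogeneity; significant
loci are clumped by distance, fine-mapped to 99% credible sets and passed
through the selection battery (iHS lookup, pairwise selection differences,
polygenic-score divergence).  Every stage's tables are persisted so stages
can be re-run individually via the CLI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import finemap_credible, gwas_core, meta_analysis
from . import polygenic_adaptation, selection_divergence, selection_haplotype
from .io_formats import (GeneticMap, QcThresholds, VariantRecord, qc_filter,
                         write_manifest, write_summary_stats)
from .synthetic_data import (SimulationConfig, TraitArchitecture,
                             draw_covariates, simulate_phenotypes,
                             simulate_populations)


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name, partial outputs stay on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    sim: SimulationConfig          # one population per cohort
    arch: TraitArchitecture
    gwas_threshold: float = 5e-8
    locus_window: int = 1_000_000
    n_pcs: int = 2
    qc: QcThresholds = field(default_factory=QcThresholds)
    finemap: finemap_credible.FineMapConfig = field(
        default_factory=finemap_credible.FineMapConfig)
    run_ihs: bool = True
    run_seldiff: bool = True
    run_qx: bool = True
    qx_resamples: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sim.populations:
            raise ValueError("at least one cohort required")


@dataclass
class PipelineReport:
    cohort_scans: dict
    meta: pd.DataFrame
    loci: list[dict]
    finemap: dict
    conditional: dict
    selection: dict
    truth: object
    out_dir: Path


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def clump_loci(meta: pd.DataFrame, threshold: float, window: int,
               p_column: str = "P_SS") -> list[dict]:
    """Distance-based clumping of genome-wide-significant meta variants."""
    sig = meta[meta[p_column] < threshold].sort_values(p_column)
    loci: list[dict] = []
    for _, row in sig.iterrows():
        if any(l["chrom"] == row["CHR"] and abs(l["pos"] - row["POS"]) <= window
               for l in loci):
            continue
        loci.append({"top": row["ID"], "chrom": row["CHR"],
                     "pos": int(row["POS"]), "p": float(row[p_column])})
    return loci


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineReport:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    write_manifest(out_dir, "pipeline", {
        "cohorts": config.sim.populations,
        "gwas_threshold": config.gwas_threshold,
        "locus_window": config.locus_window,
        "n_pcs": config.n_pcs,
    }, seed=config.seed)

    stage = "simulate"
    try:
        panels, truth = simulate_populations(config.sim, rng=rng)
        truth.variants["beta"] = [
            dict(config.arch.causal).get(v, 0.0) for v in truth.variants["id"]]
        truth.to_tsv(out_dir / "truth_variants.tsv")

        stage = "phenotype+scan"
        scans: dict[str, gwas_core.ScanResult] = {}
        dosage_by_cohort: dict[str, np.ndarray] = {}
        vmeta_by_cohort: dict[str, pd.DataFrame] = {}
        pheno_by_cohort: dict[str, pd.DataFrame] = {}
        for pop, panel in panels.items():
            cov = draw_covariates(len(panel.samples), rng,
                                  sample_ids=panel.samples)
            pheno, _ = simulate_phenotypes(panel, config.arch, cov, rng=rng)
            dosages = panel.dosages()
            variants = [VariantRecord(
                id=r["id"], chromosome=str(r["chrom"]), position=int(r["pos"]),
                effect_allele=r["alt"], other_allele=r["ref"],
                eaf=float(f)) for (_, r), f in
                zip(panel.variants.iterrows(), panel.frequencies())]
            qc = qc_filter(dosages, variants, panel.samples, config.qc)
            kept_ids = [v.id for v in qc.variants]
            kept_mask = panel.variants["id"].isin(kept_ids).to_numpy()
            dos = dosages[:, kept_mask]
            vmeta = panel.variants.loc[kept_mask].reset_index(drop=True)

            cov_mat = pheno[["sex", "age"]].copy()
            if config.n_pcs > 0:
                pcs = gwas_core.pca_covariates(dos, k=config.n_pcs)
                for i in range(config.n_pcs):
                    cov_mat[f"PC{i + 1}"] = pcs[:, i]
            scan = gwas_core.additive_scan(
                pheno["phenotype"].to_numpy(), dos, vmeta, cov_mat)
            scans[pop] = scan
            dosage_by_cohort[pop] = dos
            vmeta_by_cohort[pop] = vmeta
            pheno_by_cohort[pop] = pheno
            write_summary_stats(scan.records.dropna(subset=["P"]),
                                out_dir / f"scan_{pop}.tsv")

        stage = "meta"
        cohort_tables = [scans[p].records.dropna(subset=["P"]).reset_index(drop=True)
                         for p in panels]
        meta = meta_analysis.meta_analyze(cohort_tables)
        _write_table(meta, out_dir / "meta.tsv")

        stage = "loci"
        loci = clump_loci(meta, config.gwas_threshold, config.locus_window)
        with open(out_dir / "loci.json", "w") as fh:
            json.dump(loci, fh, indent=2)

        stage = "finemap"
        fm_cfg = finemap_credible.FineMapConfig(
            window_halfwidth=config.locus_window // 2,
            credible_mass=config.finemap.credible_mass,
            prior_w=config.finemap.prior_w)
        finemap_out: dict[str, pd.DataFrame] = {}
        for locus in loci:
            fm = finemap_credible.finemap_locus(meta, locus["top"], fm_cfg)
            finemap_out[locus["top"]] = fm
            _write_table(fm, out_dir / f"finemap_{locus['top']}.tsv")

        stage = "conditional"
        conditional: dict[str, pd.DataFrame] = {}
        tops = [l["top"] for l in loci]
        if tops:
            for pop, panel in panels.items():
                vmeta = vmeta_by_cohort[pop]
                present = [t for t in tops if t in set(vmeta["id"])]
                if not present:
                    continue
                cov_mat = pheno_by_cohort[pop][["sex", "age"]]
                cond = gwas_core.conditional_scan(
                    pheno_by_cohort[pop]["phenotype"].to_numpy(),
                    dosage_by_cohort[pop], vmeta, present, cov_mat)
                conditional[pop] = cond.records
                write_summary_stats(cond.records.dropna(subset=["P"]),
                                    out_dir / f"conditional_{pop}.tsv")

        stage = "selection"
        selection = _selection_battery(config, panels, meta, loci, rng, out_dir)

        stage = "report"
        _markdown_report(out_dir, config, scans, meta, loci, finemap_out, selection)
    except Exception as exc:  # noqa: BLE001 - stage attribution contract
        raise PipelineError(stage, exc) from exc

    return PipelineReport(cohort_scans=scans, meta=meta, loci=loci,
                          finemap=finemap_out, conditional=conditional,
                          selection=selection, truth=truth, out_dir=out_dir)


def _selection_battery(config, panels, meta, loci, rng, out_dir) -> dict:
    selection: dict = {}
    tops = [l["top"] for l in loci]
    pops = list(panels)

    if config.run_ihs and tops:
        ihs_hits = {}
        for pop, panel in panels.items():
            gmap = config.sim.genetic_map or GeneticMap.uniform(
                panel.positions, cm_per_bp=config.sim.recombination_rate * 100.0)
            try:
                ihs = selection_haplotype.ihs_scan(
                    panel, gmap, np.zeros(panel.n_sites, dtype=int))
            except ValueError:
                continue
            thr = selection_haplotype.empirical_threshold(
                ihs["ihs_s"].dropna().to_numpy())
            hits = ihs[ihs["id"].isin(tops)]
            ihs_hits[pop] = {"cutoff": thr.cutoff,
                             "records": hits.to_dict("records")}
            _write_table(ihs, out_dir / f"ihs_{pop}.tsv")
        selection["ihs"] = ihs_hits

    if config.run_seldiff and len(pops) >= 2 and tops:
        pa, pb = pops[0], pops[1]
        fa = panels[pa].frequencies()
        fb = panels[pb].frequencies()
        na = panels[pa].n_haplotypes
        nb = panels[pb].n_haplotypes
        ids = panels[pa].variants["id"].to_numpy()
        is_top = np.isin(ids, tops)
        d_cal = selection_divergence.logit_diff(
            fa[~is_top], fb[~is_top],
            np.full((~is_top).sum(), na), np.full((~is_top).sum(), nb))
        cal = selection_divergence.calibrate_null(
            d_cal, (fa[~is_top] + fb[~is_top]) / 2.0)
        focal = pd.DataFrame({"id": ids[is_top], "p_a": fa[is_top],
                              "p_b": fb[is_top], "n_a": na, "n_b": nb})
        res = selection_divergence.seldiff_test(focal, cal, pops=(pa, pb))
        _write_table(res, out_dir / "seldiff.tsv")
        selection["seldiff"] = res.to_dict("records")

    if config.run_qx and tops and len(pops) >= 2:
        freqs = pd.DataFrame(
            {pop: panels[pop].frequencies() for pop in pops},
            index=panels[pops[0]].variants["id"])
        betas = meta.set_index("ID").loc[tops, "BETA"]
        neutral = freqs.drop(index=tops)
        try:
            f_mat, sets = polygenic_adaptation.neutral_covariance(
                neutral, freqs.loc[tops], n_sets=config.qx_resamples, rng=rng)
            qx = polygenic_adaptation.qx_test(freqs, betas, f_mat,
                                              neutral, sets)
            selection["qx"] = {"qx": qx.qx, "df": qx.df, "p_chi2": qx.p_chi2,
                               "p_empirical": qx.p_empirical,
                               "scores": qx.scores.to_dict()}
            with open(out_dir / "qx.json", "w") as fh:
                json.dump(selection["qx"], fh, indent=2)
        except ValueError as err:
            selection["qx"] = {"error": str(err)}
    return selection


def _markdown_report(out_dir: Path, config, scans, meta, loci,
                     finemap_out, selection) -> None:
    lines = ["# Pipeline run report", ""]
    lines.append("## Cohort scans")
    for pop, scan in scans.items():
        lines.append(f"- {pop}: {len(scan.records)} variants, "
                     f"lambda_gc = {scan.lambda_gc:.4f}")
    lines.append("")
    lines.append(f"## Meta-analysis: {len(meta)} variants, "
                 f"{len(loci)} locus/loci at P < {config.gwas_threshold:g}")
    for locus in loci:
        fm = finemap_out.get(locus["top"])
        set_size = int(fm["IN_CREDIBLE_SET"].sum()) if fm is not None else 0
        lines.append(f"- {locus['top']} (chr{locus['chrom']}:{locus['pos']}), "
                     f"P = {locus['p']:.3g}, 99% credible set size {set_size}")
    lines.append("")
    if "qx" in selection:
        qx = selection["qx"]
        if "qx" in qx:
            lines.append(f"## Polygenic divergence: Qx = {qx['qx']:.3f}, "
                         f"p_chi2 = {qx['p_chi2']:.3g}, "
                         f"p_empirical = {qx['p_empirical']:.3g}")
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
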
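"""End-to-end pipeline: simulate → traits → blup → scan → prioritize → localgwas.

Each stage reads its inputs from disk and writes its artifacts back, so any
stage can be re-run in isolation; a missing upstream artifact raises a
stage-scoped :class:`PipelineError`.  A run manifest records the config
snapshot, package version, seeds, per-stage artifact checksums and timings;
deterministic stages reproduce identical bytes given the same manifest
inputs.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as dio
from ._rng import spawn_seed
from .candidates import cluster_founder_effects, expression_association, gate_and_report
from .config import RunConfig
from .fluorescence import qc_filter, trait_table
from .haplotypes import reconstruct_haplotypes
from .local_gwas import impute_founder_snps, local_association_scan
from .scan import kinship_loco, run_scan
from .simulate import (
    CML91,
    DEFAULT_FOUNDERS,
    FieldDesign,
    FluorescenceProtocol,
    FounderPanel,
    QtlSpec,
    SimTruth,
    assign_gene_intervals,
    plant_qtl,
    sample_trace_params,
    simulate_fluorescence_traces,
    simulate_founder_expression,
    simulate_founder_genomes,
    simulate_founder_snps,
    simulate_magic_rils,
    simulate_phenotype_table,
    uniform_marker_map,
)
from .variance import fit_random_effects, heritability, predicted_means

__all__ = ["PipelineError", "RunManifest", "run_pipeline", "SIM_VARIANCE_COMPONENTS"]

#: trial variance components used by the default synthetic study
SIM_VARIANCE_COMPONENTS = {
    "genotype": 0.30,
    "year": 0.05,
    "year_genotype": 0.10,
    "year_rep": 0.02,
    "year_rep_block": 0.02,
    "year_date": 0.02,
    "year_silking": 0.02,
    "residual": 0.50,
}


class PipelineError(RuntimeError):
    """Stage-scoped pipeline failure."""


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, Path], elapsed: float) -> None:
        self.stages[stage] = {
            "elapsed_s": round(elapsed, 3),
            "outputs": {
                name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()
            },
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r}: missing input {path} (produced by stage {produced_by!r})"
        )
    return path


def _founder_effect_split(founder_ids: list[str]) -> dict[str, float]:
    """Single-founder contrast: F7 strongly negative, the rest balanced positive.

    CML91, when present, is assigned zero effect (its RIL share is too small
    to estimate and it is excluded from clustering downstream).
    """
    core = [f for f in founder_ids if f != CML91]
    low = "F7" if "F7" in core else core[-1]
    others = [f for f in core if f != low]
    effects = {f: 1.0 for f in others}
    effects[low] = -float(len(others))  # centred: sum is exactly zero
    if CML91 in founder_ids:
        effects[CML91] = 0.0
    return effects


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunManifest:
    """Execute the configured stages in order, writing artifacts to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(asdict(config), __version__, config.seed)
    stages = config.stages
    for stage in stages:
        t0 = time.perf_counter()
        fn = _STAGES.get(stage)
        if fn is None:
            raise PipelineError(f"unknown stage {stage!r}")
        outputs = fn(config, out)
        manifest.record(stage, outputs, time.perf_counter() - t0)
    dio.write_json(
        {"config": manifest.config, "version": manifest.version, "seed": manifest.seed, "stages": manifest.stages},
        out / "manifest.json",
    )
    return manifest


# --- stages ----------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path) -> dict[str, Path]:
    d = out / "sim"
    d.mkdir(exist_ok=True)
    seed = config.seed
    gmap = uniform_marker_map(
        config.n_chromosomes,
        config.markers_per_chromosome,
        config.chrom_length_bp,
        config.chrom_length_cm,
    )
    founder_ids = DEFAULT_FOUNDERS[: config.n_founders]
    if config.include_cml91:
        founder_ids = founder_ids + [CML91]
    panel = simulate_founder_genomes(
        len(founder_ids), gmap, seed=spawn_seed(seed, "panel"), founder_ids=founder_ids
    )
    rils, mosaics = simulate_magic_rils(
        panel,
        n_rils=config.n_rils,
        genotyping_error=config.genotyping_error,
        missing_rate=config.sim_missing_rate,
        breakpoint_rate_per_morgan=config.lambda_per_morgan,
        seed=spawn_seed(seed, "rils"),
        cml91_share=config.cml91_share,
    )
    qtl_chrom = gmap.chromosomes[0]
    qtl_bp = int(gmap.chrom_view(qtl_chrom)["bp"].iloc[len(gmap.chrom_view(qtl_chrom)) // 2])
    effects = _founder_effect_split(panel.founder_ids)
    qtl = QtlSpec(qtl_chrom, qtl_bp, effects, config.qtl_variance_explained)
    vc = SIM_VARIANCE_COMPONENTS
    design = FieldDesign()
    entry_var = (
        vc["genotype"]
        + vc["year_genotype"] / len(design.years)
        + vc["residual"] / (len(design.years) * design.n_reps)
    )
    gvals = plant_qtl(mosaics, qtl, panel, other_variance=entry_var)
    pheno = simulate_phenotype_table(
        gvals, rils.ril_ids, vc, design, mean=0.7, seed=spawn_seed(seed, "pheno"), trait="npq_max"
    )

    protocol = FluorescenceProtocol(config.light_times, config.dark_times)
    params = sample_trace_params(
        [f"S{i:04d}" for i in range(min(config.n_rils, 120))],
        seed=spawn_seed(seed, "traceparams"),
        low_fvfm_fraction=0.02,
    )
    traces = simulate_fluorescence_traces(
        params, protocol, noise_sd=config.trace_noise_sd, seed=spawn_seed(seed, "traces")
    )

    region = (max(1, qtl_bp - 10_000_000), qtl_bp + 10_000_000)
    gene_ids = [f"G{i:03d}" for i in range(config.n_interval_genes)]
    causal = gene_ids[len(gene_ids) // 2]
    genes = assign_gene_intervals(gene_ids, qtl_chrom, region, seed=spawn_seed(seed, "genes"))
    # the causal gene model covers the planted QTL position
    genes.loc[genes["gene_id"] == causal, ["start", "end"]] = [qtl_bp - 2000, qtl_bp + 1999]
    genes = genes.sort_values("start", kind="stable").reset_index(drop=True)
    expr_founders = [f for f in panel.founder_ids if f != CML91]
    counts = simulate_founder_expression(
        gene_ids,
        causal,
        {f: effects[f] for f in expr_founders},
        dispersion=config.expression_dispersion,
        n_replicates=config.n_expression_replicates,
        slope=config.expression_slope,
        seed=spawn_seed(seed, "expr"),
    )
    carriers = [f for f, v in effects.items() if v < 0 and f != CML91]
    snps = simulate_founder_snps(
        panel,
        qtl_chrom,
        region,
        n_snps=config.n_region_snps,
        causal_bp=qtl_bp,
        causal_carriers=carriers,
        seed=spawn_seed(seed, "snps"),
    )
    truth = SimTruth([qtl], mosaics, causal, dict(vc), seed)

    dio.write_map(gmap, d / "map.tsv")
    dio.write_genotypes(panel.founder_ids, panel.alleles, gmap.marker_ids, d / "founders.tsv")
    dio.write_genotypes(rils.ril_ids, rils.alleles, gmap.marker_ids, d / "rils.tsv")
    dio.write_phenotypes(pheno, d / "phenotypes.csv")
    dio.write_traces(traces, d / "traces.csv")
    dio.write_counts(counts, d / "counts.tsv")
    dio.write_genes(genes, d / "genes.tsv")
    snps.to_csv(d / "founder_snps.tsv", sep="\t", index=False)
    (d / "truth.json").write_text(truth.to_json())
    return {p.stem: p for p in d.iterdir()}


def _stage_traits(config: RunConfig, out: Path) -> dict[str, Path]:
    d = out / "traits"
    d.mkdir(exist_ok=True)
    traces = dio.read_traces(_require(out / "sim" / "traces.csv", "traits", "simulate"))
    table = trait_table(traces, config.fvfm_threshold, config.pi_parse)
    kept, _removed, report = qc_filter(table, config.fvfm_threshold)
    kept.to_csv(d / "traits.csv", index=False, float_format="%.10g")
    dio.write_json(report, d / "qc_report.json")
    return {"traits": d / "traits.csv", "qc_report": d / "qc_report.json"}


def _stage_blup(config: RunConfig, out: Path) -> dict[str, Path]:
    d = out / "blup"
    d.mkdir(exist_ok=True)
    pheno = dio.read_phenotypes(_require(out / "sim" / "phenotypes.csv", "blup", "simulate"))
    decomp = fit_random_effects(pheno)
    means = predicted_means(decomp)
    means.rename("predicted_mean").to_csv(d / "predicted_means.csv", float_format="%.10g")
    h2 = heritability(decomp, basis=config.heritability_basis)
    dio.write_json(
        {
            "variances": decomp.variances,
            "mean": decomp.mean,
            "heritability": h2,
            "heritability_basis": config.heritability_basis,
            "n_obs": decomp.n_obs,
            "converged": decomp.converged,
        },
        d / "decomposition.json",
    )
    return {"predicted_means": d / "predicted_means.csv", "decomposition": d / "decomposition.json"}


def _stage_scan(config: RunConfig, out: Path) -> dict[str, Path]:
    d = out / "scan"
    d.mkdir(exist_ok=True)
    gmap = dio.read_map(_require(out / "sim" / "map.tsv", "scan", "simulate"))
    f_ids, f_alleles, _ = dio.read_genotypes(_require(out / "sim" / "founders.tsv", "scan", "simulate"))
    r_ids, r_alleles, _ = dio.read_genotypes(_require(out / "sim" / "rils.tsv", "scan", "simulate"))
    panel = FounderPanel(f_ids, f_alleles, gmap)
    from .simulate import RilGenotypes

    rils = RilGenotypes(r_ids, r_alleles, gmap)
    probs = reconstruct_haplotypes(
        rils, panel, gmap, config.lambda_per_morgan, config.genotyping_error, compute_viterbi=True
    )
    dio.write_probabilities(probs, d / "probabilities.tsv")
    dio.write_viterbi_bed(probs, d / "mosaics.tsv")
    means = pd.read_csv(
        _require(out / "blup" / "predicted_means.csv", "scan", "blup"), index_col=0
    )["predicted_mean"]
    result = run_scan(
        probs,
        means,
        kinship_loco(probs),
        n_perm=config.n_perm,
        quantile=config.threshold_quantile,
        ci_prob=config.ci_prob,
        seed=spawn_seed(config.seed, "perms"),
    )
    result.scan.to_csv(d / "scan.tsv", sep="\t", index=False, float_format="%.6g")
    peaks = result.peaks.copy()
    for c, (lo, hi) in result.intervals.items():
        peaks.loc[peaks["chrom"] == c, "ci_low_bp"] = lo
        peaks.loc[peaks["chrom"] == c, "ci_high_bp"] = hi
    peaks["peak_mbp"] = peaks["bp"] / 1e6
    peaks["threshold"] = result.threshold
    peaks.to_csv(d / "peaks.tsv", sep="\t", index=False, float_format="%.6g")
    for c, coefs in result.coefficients.items():
        coefs.to_csv(d / f"coefficients_chr{c}.tsv", sep="\t", float_format="%.6g")
    return {p.stem: p for p in d.iterdir()}


def _stage_prioritize(config: RunConfig, out: Path) -> dict[str, Path]:
    d = out / "prioritize"
    d.mkdir(exist_ok=True)
    peaks = pd.read_csv(_require(out / "scan" / "peaks.tsv", "prioritize", "scan"), sep="\t", dtype={"chrom": str})
    counts = dio.read_counts(_require(out / "sim" / "counts.tsv", "prioritize", "simulate"))
    genes = dio.read_genes(_require(out / "sim" / "genes.tsv", "prioritize", "simulate"))
    founder_of_sample = {c: c.rsplit("_r", 1)[0] for c in counts.columns}
    clusterings, tables = {}, {}
    for _, pk in peaks.iterrows():
        c = str(pk["chrom"])
        coef_path = out / "scan" / f"coefficients_chr{c}.tsv"
        if not coef_path.exists():
            continue
        coefs = pd.read_csv(coef_path, sep="\t", index_col=0)
        coefs = coefs[coefs.index != CML91]  # too few RILs carry it
        clustering = cluster_founder_effects(
            coefs, config.silhouette_floor, seed=spawn_seed(config.seed, "kmeans")
        )
        clusterings[c] = clustering
        tables[c] = expression_association(
            counts,
            founder_of_sample,
            genes,
            clustering,
            (c, int(pk["ci_low_bp"]), int(pk["ci_high_bp"])),
            fdr=config.fdr,
            max_span_mbp=config.max_span_mbp,
        )
    if tables:
        pd.concat(
            [t.assign(chrom=c) for c, t in tables.items()], ignore_index=True
        ).to_csv(d / "candidates.csv", index=False, float_format="%.6g")
    else:
        pd.DataFrame(columns=["gene_id", "stat", "p", "q", "pass", "chrom"]).to_csv(
            d / "candidates.csv", index=False
        )
    report = gate_and_report(peaks, clusterings, tables)
    dio.write_json(report, d / "report.json")
    return {"candidates": d / "candidates.csv", "report": d / "report.json"}


def _stage_localgwas(config: RunConfig, out: Path) -> dict[str, Path]:
    d = out / "localgwas"
    d.mkdir(exist_ok=True)
    gmap = dio.read_map(_require(out / "sim" / "map.tsv", "localgwas", "simulate"))
    probs = dio.read_probabilities(
        _require(out / "scan" / "probabilities.tsv", "localgwas", "scan"), gmap
    )
    peaks = pd.read_csv(_require(out / "scan" / "peaks.tsv", "localgwas", "scan"), sep="\t", dtype={"chrom": str})
    snps = pd.read_csv(_require(out / "sim" / "founder_snps.tsv", "localgwas", "simulate"), sep="\t", dtype={"chrom": str})
    genes = dio.read_genes(_require(out / "sim" / "genes.tsv", "localgwas", "simulate"))
    means = pd.read_csv(_require(out / "blup" / "predicted_means.csv", "localgwas", "blup"), index_col=0)["predicted_mean"]
    kinships = kinship_loco(probs)
    results = {}
    for _, pk in peaks.iterrows():
        c = str(pk["chrom"])
        lo, hi = int(pk["ci_low_bp"]), int(pk["ci_high_bp"])
        dosages = impute_founder_snps(
            probs, snps, (c, lo - config.extension_bp, hi + config.extension_bp)
        )
        res = local_association_scan(
            dosages,
            means,
            kinships[c],
            (lo, hi),
            gene_intervals=genes,
            extension_bp=config.extension_bp,
            alpha=config.bonferroni_alpha,
        )
        res.table.to_csv(d / f"local_scan_chr{c}.tsv", sep="\t", index=False, float_format="%.6g")
        results[c] = {
            "bonferroni_threshold": res.bonferroni_threshold,
            "n_tested": res.n_tested,
            "top_snp": res.top_snp,
            "overlapping_genes": res.overlapping_genes,
            "note": res.note,
        }
    dio.write_json(results, d / "top_hits.json")
    return {p.stem: p for p in d.iterdir()}


_STAGES = {
    "simulate": _stage_simulate,
    "traits": _stage_traits,
    "blup": _stage_blup,
    "scan": _stage_scan,
    "prioritize": _stage_prioritize,
    "localgwas": _stage_localgwas,
}
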
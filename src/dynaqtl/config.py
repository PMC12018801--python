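"""Run configuration.

Defaults follow the published analysis procedure wherever it states a
constant: the Fv/Fm quality cutoff (0.70), the pulse schedules, 999
permutations at the 95th percentile, FDR 0.1 for candidate genes, the
30 Mbp interval gate, the 250 kbp local-GWAS extension, Bonferroni
alpha 0.05 and the 20% missingness cap.  Simulation sizes (RILs, markers,
chromosomes) are package choices and freely adjustable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "DEFAULTS"]


@dataclass
class RunConfig:
    # procedure constants (published defaults)
    fvfm_threshold: float = 0.70
    light_times: tuple[float, ...] = (20, 40, 60, 120, 180, 240, 300, 360, 420, 480, 540, 600)
    dark_times: tuple[float, ...] = (20, 40, 60, 120, 180, 360, 540)
    n_perm: int = 999
    threshold_quantile: float = 0.95
    fdr: float = 0.1
    max_span_mbp: float = 30.0
    extension_bp: int = 250_000
    bonferroni_alpha: float = 0.05
    max_missing: float = 0.20
    ci_prob: float = 0.95
    pi_parse: str = "nested-ratio"

    # model tunables
    lambda_per_morgan: float = 2.0
    genotyping_error: float = 0.002
    silhouette_floor: float = 0.5
    heritability_basis: str = "entry_mean"

    # simulation scale (package defaults, not published values)
    n_rils: int = 300
    n_chromosomes: int = 3
    markers_per_chromosome: int = 120
    chrom_length_bp: int = 150_000_000
    chrom_length_cm: float = 100.0
    n_founders: int = 8
    include_cml91: bool = False
    cml91_share: float = 0.05
    sim_missing_rate: float = 0.02
    qtl_variance_explained: float = 0.2
    n_interval_genes: int = 60
    n_region_snps: int = 400
    expression_slope: float = 2.0
    expression_dispersion: float = 10.0
    n_expression_replicates: int = 3
    trace_noise_sd: float = 0.01

    # bookkeeping
    seed: int = 1
    stages: tuple[str, ...] = ("simulate", "traits", "blup", "scan", "prioritize", "localgwas")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["light_times"] = list(self.light_times)
        d["dark_times"] = list(self.dark_times)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("light_times", "dark_times", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


DEFAULTS = RunConfig()
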
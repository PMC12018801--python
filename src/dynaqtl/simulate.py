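"""Synthetic MAGIC populations with recorded ground truth.

This module generates every input the analysis consumes — founder genomes,
recombinant inbred line (RIL) mosaics with genotyping noise, planted QTL,
multi-year field phenotypes with the full random-effects variance structure,
chlorophyll-fluorescence pulse traces, and founder expression counts — while
recording the truth needed to score recovery downstream.

The population emulated is an 8-founder funnel MAGIC design in which a ninth
founder (CML91) entered as a two-way hybrid and therefore contributes only a
small share of the genome.  RIL genomes are modelled as single-haplotype
founder mosaics produced by an exchangeable Markov walk along the genetic
map: crossover events arrive as a Poisson process at ``breakpoint_rate``
events per Morgan and each event switches to a uniformly chosen *different*
founder.  This is an approximation of the funnel pedigree, not an attempt to
reproduce its exact transition probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .genmap import GeneticMap

__all__ = [
    "FounderPanel",
    "TrueMosaic",
    "QtlSpec",
    "SimTruth",
    "RilGenotypes",
    "FluorescenceProtocol",
    "TraceParams",
    "simulate_founder_genomes",
    "simulate_magic_rils",
    "plant_qtl",
    "simulate_phenotype_table",
    "simulate_fluorescence_traces",
    "simulate_founder_expression",
    "simulate_founder_snps",
    "sample_trace_params",
    "assign_gene_intervals",
    "uniform_marker_map",
]

DEFAULT_FOUNDERS = ["A632", "B73", "B96", "F7", "H99", "HP301", "Mo17", "W153R"]
CML91 = "CML91"

#: protocol pulse times (seconds) — 12 light-phase and 7 dark-phase pulses
LIGHT_PULSE_TIMES = (20, 40, 60, 120, 180, 240, 300, 360, 420, 480, 540, 600)
DARK_PULSE_TIMES = (20, 40, 60, 120, 180, 360, 540)
ACTINIC_PAR = 1500.0  # µmol m⁻² s⁻¹


# ---------------------------------------------------------------------------
# domain types


@dataclass
class FounderPanel:
    """Founder inbred panel: biallelic allele codes, founders × markers."""

    founder_ids: list[str]
    alleles: np.ndarray  # (F, M) int8 in {0, 1}
    gmap: GeneticMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.founder_ids), self.gmap.n_markers):
            raise ValueError("allele matrix shape does not match founders × markers")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("founder alleles must be biallelic codes {0,1} with no missing")

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)


@dataclass
class ChromosomeMosaic:
    """One RIL chromosome as ordered founder segments.

    ``breakpoints_bp`` are the internal segment boundaries; segment ``i``
    spans from the previous boundary (or the chromosome start) up to
    ``breakpoints_bp[i]`` and carries founder ``founders[i]``.
    """

    breakpoints_bp: np.ndarray  # (n_breaks,) float, internal boundaries
    founders: np.ndarray  # (n_breaks + 1,) int founder indices

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints_bp)

    def founder_at(self, bp: np.ndarray) -> np.ndarray:
        """Founder index of the segment covering each physical position."""
        idx = np.searchsorted(self.breakpoints_bp, np.asarray(bp, dtype=float), side="right")
        return self.founders[idx]


@dataclass
class TrueMosaic:
    """True founder mosaic of one RIL, per chromosome."""

    ril_id: str
    chromosomes: dict[str, ChromosomeMosaic]

    def founder_at(self, chrom: str, bp: float) -> int:
        return int(self.chromosomes[str(chrom)].founder_at(np.array([bp]))[0])

    def n_breakpoints(self) -> int:
        return sum(c.n_breakpoints for c in self.chromosomes.values())


@dataclass
class RilGenotypes:
    """Observed RIL marker alleles (0/1, -1 = missing), aligned to a map."""

    ril_ids: list[str]
    alleles: np.ndarray  # (n_rils, M) int8, -1 missing
    gmap: GeneticMap

    @property
    def n_rils(self) -> int:
        return len(self.ril_ids)


@dataclass
class QtlSpec:
    """A planted QTL: location, founder-specific additive effects, size.

    ``founder_effects`` maps founder label → additive effect in trait units;
    effects must be centred (mean 0 across founders).  ``variance_explained``
    is the fraction of total phenotypic variance (on the analysis scale) the
    locus should account for.
    """

    chrom: str
    pos_bp: int
    founder_effects: dict[str, float]
    variance_explained: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.variance_explained < 1.0:
            raise ValueError("variance_explained must be in [0, 1)")
        vals = np.array(list(self.founder_effects.values()), dtype=float)
        if len(vals) and abs(vals.mean()) > 1e-8 * max(1.0, np.abs(vals).max()):
            raise ValueError("founder effects must be centred (mean 0 across founders)")


@dataclass
class SimTruth:
    """Everything needed to score a synthetic run against its truth."""

    qtl_specs: list[QtlSpec]
    mosaics: list[TrueMosaic] = field(repr=False)
    causal_gene_id: str | None = None
    variance_components: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "causal_gene_id": self.causal_gene_id,
            "variance_components": self.variance_components,
            "qtl": [
                {
                    "chrom": q.chrom,
                    "pos_bp": q.pos_bp,
                    "founder_effects": q.founder_effects,
                    "variance_explained": q.variance_explained,
                }
                for q in self.qtl_specs
            ],
            "mosaics": [
                {
                    "ril_id": m.ril_id,
                    "chromosomes": {
                        c: {
                            "breakpoints_bp": np.asarray(cm.breakpoints_bp).tolist(),
                            "founders": np.asarray(cm.founders).tolist(),
                        }
                        for c, cm in m.chromosomes.items()
                    },
                }
                for m in self.mosaics
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        qtl = [
            QtlSpec(q["chrom"], q["pos_bp"], q["founder_effects"], q["variance_explained"])
            for q in d["qtl"]
        ]
        mosaics = [
            TrueMosaic(
                m["ril_id"],
                {
                    c: ChromosomeMosaic(
                        np.asarray(cm["breakpoints_bp"], dtype=float),
                        np.asarray(cm["founders"], dtype=int),
                    )
                    for c, cm in m["chromosomes"].items()
                },
            )
            for m in d["mosaics"]
        ]
        return cls(qtl, mosaics, d.get("causal_gene_id"), d.get("variance_components", {}), d.get("seed"))


# ---------------------------------------------------------------------------
# maps and founders


def uniform_marker_map(
    n_chromosomes: int = 3,
    markers_per_chromosome: int = 200,
    chrom_length_bp: int = 150_000_000,
    chrom_length_cm: float = 100.0,
) -> GeneticMap:
    """Evenly spaced marker map used throughout the synthetic studies."""
    rows = []
    for c in range(1, n_chromosomes + 1):
        bp = np.linspace(1, chrom_length_bp, markers_per_chromosome).round().astype(np.int64)
        bp = np.unique(bp)
        cm = (bp - 1) / (chrom_length_bp - 1) * chrom_length_cm
        for i, (b, g) in enumerate(zip(bp, cm)):
            rows.append((str(c), f"m{c}_{i}", int(b), float(g)))
    return GeneticMap(pd.DataFrame(rows, columns=["chrom", "marker", "bp", "cM"]))


def simulate_founder_genomes(
    n_founders: int,
    gmap: GeneticMap,
    maf_range: tuple[float, float] = (0.2, 0.5),
    seed: int | None = None,
    founder_ids: list[str] | None = None,
) -> FounderPanel:
    """Draw a biallelic founder panel with per-marker MAF inside ``maf_range``.

    The minor-allele frequency across founders at each marker is drawn from
    the feasible integer carrier counts whose frequency lies in the range;
    if no integer count is feasible the closest one is used.
    """
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = substream(seed or 0, "founder_genomes") if seed is not None else np.random.default_rng()
    F, M = n_founders, gmap.n_markers
    counts = np.arange(1, F // 2 + 1)
    feasible = counts[(counts / F >= lo - 1e-12) & (counts / F <= hi + 1e-12)]
    if feasible.size == 0:
        feasible = np.array([counts[np.argmin(np.abs(counts / F - (lo + hi) / 2))]])
    alleles = np.zeros((F, M), dtype=np.int8)
    for m in range(M):
        k = int(rng.choice(feasible))
        carriers = rng.choice(F, size=k, replace=False)
        col = np.zeros(F, dtype=np.int8)
        col[carriers] = 1
        if rng.random() < 0.5:  # which allele is minor is arbitrary
            col = 1 - col
        alleles[:, m] = col
    if founder_ids is None:
        founder_ids = (DEFAULT_FOUNDERS + [CML91] + [f"F{i}" for i in range(10, 10 + F)])[:F]
    return FounderPanel(list(founder_ids[:F]), alleles, gmap)


# ---------------------------------------------------------------------------
# RIL mosaics


def _sample_chromosome_mosaic(
    rng: np.random.Generator,
    sub: pd.DataFrame,
    n_founders: int,
    rate_per_morgan: float,
    start_probs: np.ndarray,
) -> ChromosomeMosaic:
    cm = sub["cM"].to_numpy()
    bp = sub["bp"].to_numpy(dtype=float)
    length_m = (cm[-1] - cm[0]) / 100.0
    n_breaks = rng.poisson(rate_per_morgan * length_m) if rate_per_morgan > 0 else 0
    founders = [int(rng.choice(n_founders, p=start_probs))]
    if n_breaks == 0:
        return ChromosomeMosaic(np.empty(0), np.asarray(founders))
    pos_cm = np.sort(rng.uniform(cm[0], cm[-1], size=n_breaks))
    for _ in range(n_breaks):
        # forced switch: every event is a visible breakpoint
        current = founders[-1]
        nxt = int(rng.integers(n_founders - 1))
        founders.append(nxt if nxt < current else nxt + 1)
    breaks_bp = np.interp(pos_cm, cm, bp)
    return ChromosomeMosaic(breaks_bp, np.asarray(founders))


def simulate_magic_rils(
    panel: FounderPanel,
    gmap: GeneticMap | None = None,
    n_rils: int = 320,
    n_self_generations: int = 6,
    breakpoint_rate_per_morgan: float = 2.0,
    genotyping_error: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
    cml91_share: float = 0.05,
) -> tuple[RilGenotypes, list[TrueMosaic]]:
    """Simulate RIL founder mosaics and their observed marker alleles.

    Each chromosome of each RIL is an independent exchangeable Markov walk:
    breakpoints arrive at ``breakpoint_rate_per_morgan`` per Morgan and each
    one switches to a uniformly chosen different founder, so the expected
    breakpoint count per Morgan equals the rate exactly.  Observed alleles
    are copied from the underlying founder, flipped with probability
    ``genotyping_error`` and masked (-1) with probability ``missing_rate``.

    If the panel contains a ``CML91`` founder it enters the start-state
    distribution with weight ``cml91_share`` (that founder joined the real
    design as a two-way hybrid and carries a minor genome share).
    """
    if n_self_generations < 1:
        raise ValueError("n_self_generations must be >= 1")
    if breakpoint_rate_per_morgan < 0:
        raise ValueError("breakpoint rate must be non-negative")
    if not (0.0 <= genotyping_error < 0.5):
        raise ValueError("genotyping_error must be in [0, 0.5)")
    gmap = gmap or panel.gmap
    rng = substream(seed or 0, "magic_rils") if seed is not None else np.random.default_rng()
    F = panel.n_founders
    start = np.full(F, 1.0 / F)
    if CML91 in panel.founder_ids:
        i = panel.founder_ids.index(CML91)
        start[:] = (1.0 - cml91_share) / (F - 1)
        start[i] = cml91_share

    chrom_subs = {c: gmap.chrom_view(c) for c in gmap.chromosomes}
    ril_ids = [f"RIL{i:04d}" for i in range(n_rils)]
    mosaics: list[TrueMosaic] = []
    geno = np.empty((n_rils, gmap.n_markers), dtype=np.int8)
    for r in range(n_rils):
        chroms: dict[str, ChromosomeMosaic] = {}
        for c, sub in chrom_subs.items():
            mos = _sample_chromosome_mosaic(rng, sub, F, breakpoint_rate_per_morgan, start)
            chroms[c] = mos
            idx = gmap.marker_indices(c)
            f_at = mos.founder_at(sub["bp"].to_numpy(dtype=float))
            geno[r, idx] = panel.alleles[f_at, idx]
        mosaics.append(TrueMosaic(ril_ids[r], chroms))

    if genotyping_error > 0:
        flips = rng.random(geno.shape) < genotyping_error
        geno = np.where(flips, 1 - geno, geno).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = -1
    return RilGenotypes(ril_ids, geno, gmap), mosaics


def plant_qtl(
    mosaics: list[TrueMosaic],
    qtl_spec: QtlSpec,
    panel: FounderPanel,
    other_variance: float = 1.0,
) -> np.ndarray:
    """Genetic values of each RIL at a planted QTL, scaled to its target size.

    The raw value of a RIL is the founder effect of the mosaic founder at the
    QTL position.  Values are then rescaled so that their sample variance is
    ``ve/(1-ve) * other_variance`` where ``ve`` is the QTL's
    ``variance_explained`` and ``other_variance`` is the total variance of
    every non-QTL phenotype component on the analysis scale — making the QTL
    explain the requested share of total phenotypic variance in expectation.
    """
    chrom = str(qtl_spec.chrom)
    if chrom not in mosaics[0].chromosomes:
        raise ValueError(f"QTL chromosome {chrom!r} not simulated")
    sub = panel.gmap.chrom_view(chrom)
    lo, hi = int(sub["bp"].iloc[0]), int(sub["bp"].iloc[-1])
    if not (lo <= qtl_spec.pos_bp <= hi):
        raise ValueError(f"QTL position {qtl_spec.pos_bp} outside map span [{lo}, {hi}]")
    effects = np.array(
        [qtl_spec.founder_effects.get(f, 0.0) for f in panel.founder_ids], dtype=float
    )
    raw = np.array([effects[m.founder_at(chrom, qtl_spec.pos_bp)] for m in mosaics])
    if qtl_spec.variance_explained == 0.0 or np.allclose(raw, raw[0]):
        return raw if qtl_spec.variance_explained == 0.0 else np.zeros_like(raw)
    target = qtl_spec.variance_explained / (1.0 - qtl_spec.variance_explained) * other_variance
    sd = raw.std()
    return raw * np.sqrt(target) / sd


# ---------------------------------------------------------------------------
# phenotypes (multi-year field design)

EQ5_TERMS = (
    "genotype",
    "year",
    "year_genotype",
    "year_rep",
    "year_rep_block",
    "year_date",
    "year_silking",
    "residual",
)


@dataclass
class FieldDesign:
    """Layout of the multi-year trial the phenotype simulator emulates."""

    years: tuple[str, ...] = ("2021", "2022")
    n_reps: int = 2
    n_blocks: int = 40
    n_dates: int = 15
    n_silking_classes: int = 6


def simulate_phenotype_table(
    genetic_values: np.ndarray,
    ril_ids: list[str],
    variance_components: dict[str, float],
    design: FieldDesign | None = None,
    mean: float = 0.0,
    seed: int | None = None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Simulate a long-format multi-year phenotype table.

    Each record is the sum of the overall mean, the genotype effect (the
    planted genetic value plus a polygenic draw with variance
    ``variance_components['genotype']``) and independent draws for every
    random term of the trial model: year, year:genotype, year:rep,
    year:rep:block, year:date, year:silking and the residual, each with its
    stated variance.
    """
    design = design or FieldDesign()
    vc = {t: float(variance_components.get(t, 0.0)) for t in EQ5_TERMS}
    if any(v < 0 for v in vc.values()):
        raise ValueError("variance components must be non-negative")
    rng = substream(seed or 0, "phenotypes") if seed is not None else np.random.default_rng()
    n = len(ril_ids)
    genetic_values = np.asarray(genetic_values, dtype=float)
    if genetic_values.shape != (n,):
        raise ValueError("genetic_values length must match ril_ids")

    g_poly = rng.normal(0.0, np.sqrt(vc["genotype"]), size=n)
    geno_eff = genetic_values + g_poly
    rows = []
    for year in design.years:
        e_year = rng.normal(0.0, np.sqrt(vc["year"]))
        e_gy = rng.normal(0.0, np.sqrt(vc["year_genotype"]), size=n)
        e_rep = rng.normal(0.0, np.sqrt(vc["year_rep"]), size=design.n_reps)
        e_block = rng.normal(
            0.0, np.sqrt(vc["year_rep_block"]), size=(design.n_reps, design.n_blocks)
        )
        e_date = rng.normal(0.0, np.sqrt(vc["year_date"]), size=design.n_dates)
        e_silk = rng.normal(0.0, np.sqrt(vc["year_silking"]), size=design.n_silking_classes)
        # silking class is a genotype property within a year; date varies by plot
        silk_of = rng.integers(design.n_silking_classes, size=n)
        for rep in range(design.n_reps):
            block_of = rng.integers(design.n_blocks, size=n)
            date_of = rng.integers(design.n_dates, size=n)
            resid = rng.normal(0.0, np.sqrt(vc["residual"]), size=n)
            values = (
                mean
                + geno_eff
                + e_year
                + e_gy
                + e_rep[rep]
                + e_block[rep, block_of]
                + e_date[date_of]
                + e_silk[silk_of]
                + resid
            )
            for i, rid in enumerate(ril_ids):
                rows.append(
                    (
                        rid,
                        year,
                        f"rep{rep + 1}",
                        f"block{block_of[i] + 1}",
                        f"d{date_of[i] + 1}",
                        f"s{silk_of[i] + 1}",
                        trait,
                        values[i],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "genotype",
            "year",
            "rep",
            "block",
            "date",
            "silking_interval",
            "trait",
            "value",
        ],
    )


# ---------------------------------------------------------------------------
# fluorescence traces


@dataclass
class FluorescenceProtocol:
    """Pulse schedule of the fluorometer protocol (times in seconds)."""

    light_times: tuple[float, ...] = LIGHT_PULSE_TIMES
    dark_times: tuple[float, ...] = DARK_PULSE_TIMES
    actinic_par: float = ACTINIC_PAR


@dataclass
class TraceParams:
    """Kinetic parameters generating one sample's trace.

    NPQ under actinic light follows ``a_ind * (1 - exp(-b_ind * t))``; after
    light-off it relaxes as ``a_rel * exp(-b_rel * t) + c_rel`` and PSII
    operating efficiency recovers as ``a_phi * (1 - exp(-b_phi * t)) +
    c_phi`` (dark clock re-zeroed at light-off).  Light-phase ΦPSII declines
    exponentially from ``phi_light_start`` to ``phi_light_ss`` at rate
    ``phi_light_rate`` — a modelling convenience for trace construction, not
    a fitted trait.
    """

    fo: float = 200.0
    fm: float = 1000.0
    a_ind: float = 2.5
    b_ind: float = 0.03
    a_rel: float = 1.5
    b_rel: float = 0.01
    c_rel: float = 0.3
    a_phi: float = 0.30
    b_phi: float = 0.02
    c_phi: float = 0.25
    phi_light_start: float = 0.70
    phi_light_ss: float = 0.25
    phi_light_rate: float = 0.05


@dataclass
class FluorescenceTrace:
    """One sample's pulse record: Fo, Fm, then timed (t, F', Fm') pairs."""

    sample_id: str
    fo: float
    fm: float
    light_pulses: list[tuple[float, float, float]]  # (t_s, F', Fm')
    dark_pulses: list[tuple[float, float, float]]
    actinic_par: float = ACTINIC_PAR

    def __post_init__(self) -> None:
        if not (self.fm >= self.fo > 0):
            raise ValueError("require Fm >= Fo > 0")
        for pulses, phase in ((self.light_pulses, "light"), (self.dark_pulses, "dark")):
            ts = [p[0] for p in pulses]
            if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
                raise ValueError(f"{phase}-phase pulse times must be strictly increasing")


def _npq_phi_at(params: TraceParams, t_light: np.ndarray, t_dark: np.ndarray):
    npq_l = params.a_ind * (1.0 - np.exp(-params.b_ind * t_light))
    phi_l = params.phi_light_ss + (params.phi_light_start - params.phi_light_ss) * np.exp(
        -params.phi_light_rate * t_light
    )
    npq_d = params.a_rel * np.exp(-params.b_rel * t_dark) + params.c_rel
    phi_d = params.a_phi * (1.0 - np.exp(-params.b_phi * t_dark)) + params.c_phi
    return npq_l, phi_l, npq_d, phi_d


def simulate_fluorescence_traces(
    params_per_sample: dict[str, TraceParams],
    protocol: FluorescenceProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[FluorescenceTrace]:
    """Generate pulse traces from kinetic parameters.

    NPQ and ΦPSII are evaluated at the protocol pulse times and converted to
    fluorescence via ``Fm' = Fm / (1 + NPQ)`` and ``F' = Fm' * (1 - ΦPSII)``.
    Multiplicative Gaussian noise of standard deviation ``noise_sd`` is
    applied to every fluorescence value (Fo, Fm, F', Fm').
    """
    protocol = protocol or FluorescenceProtocol()
    rng = substream(seed or 0, "fluor_traces") if seed is not None else np.random.default_rng()
    t_l = np.asarray(protocol.light_times, dtype=float)
    t_d = np.asarray(protocol.dark_times, dtype=float)
    traces = []
    for sid, p in params_per_sample.items():
        if not (p.fm > p.fo > 0):
            raise ValueError(f"{sid}: require Fm > Fo > 0")
        if min(p.b_ind, p.b_rel, p.b_phi) <= 0:
            raise ValueError(f"{sid}: rate constants must be positive")
        npq_l, phi_l, npq_d, phi_d = _npq_phi_at(p, t_l, t_d)
        if (npq_l < 0).any() or (npq_d < 0).any():
            raise ValueError(f"{sid}: parameters imply NPQ < 0, i.e. Fm' > Fm")
        fm_l = p.fm / (1.0 + npq_l)
        f_l = fm_l * (1.0 - phi_l)
        fm_d = p.fm / (1.0 + npq_d)
        f_d = fm_d * (1.0 - phi_d)
        fo, fm = p.fo, p.fm
        if noise_sd > 0:
            mult = lambda x: x * (1.0 + rng.normal(0.0, noise_sd, size=np.shape(x)))  # noqa: E731
            fo = float(fo * (1.0 + rng.normal(0.0, noise_sd)))
            fm = float(fm * (1.0 + rng.normal(0.0, noise_sd)))
            f_l, fm_l, f_d, fm_d = mult(f_l), mult(fm_l), mult(f_d), mult(fm_d)
        traces.append(
            FluorescenceTrace(
                sid,
                fo,
                fm,
                list(zip(t_l.tolist(), f_l.tolist(), fm_l.tolist())),
                list(zip(t_d.tolist(), f_d.tolist(), fm_d.tolist())),
                protocol.actinic_par,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# founder expression


def simulate_founder_expression(
    gene_ids: list[str],
    causal_gene_id: str,
    founder_effects: dict[str, float],
    baseline_mean: float = 500.0,
    dispersion: float = 10.0,
    n_replicates: int = 3,
    slope: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Negative-binomial founder expression counts with one causal gene.

    Non-causal genes share a (gene-specific) mean across founders.  The
    causal gene's log-mean per founder is ``log(gene mean) + slope *
    founder_effect`` — emulating a constitutive founder expression
    difference that tracks the planted QTL effects.  ``dispersion`` is the
    NB size parameter (variance = µ + µ²/size).

    Returns a genes × samples count DataFrame whose columns are named
    ``<founder>_r<replicate>``.
    """
    if causal_gene_id not in gene_ids:
        raise ValueError("causal_gene_id must be one of gene_ids")
    if n_replicates < 2:
        raise ValueError("need n_replicates >= 2")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = substream(seed or 0, "founder_expression") if seed is not None else np.random.default_rng()
    founders = list(founder_effects)
    eff = np.array([founder_effects[f] for f in founders], dtype=float)
    if len(eff):
        eff = eff - eff.mean()
    n_genes = len(gene_ids)
    base = np.exp(rng.normal(np.log(baseline_mean), 0.5, size=n_genes))
    mu = np.repeat(base[:, None], len(founders), axis=1)  # genes × founders
    ci = gene_ids.index(causal_gene_id)
    mu[ci, :] = base[ci] * np.exp(slope * eff)
    cols, data = [], []
    for j, f in enumerate(founders):
        for r in range(n_replicates):
            cols.append(f"{f}_r{r + 1}")
            # NB as gamma-poisson mixture
            lam = rng.gamma(shape=dispersion, scale=mu[:, j] / dispersion)
            data.append(rng.poisson(lam))
    counts = pd.DataFrame(np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    return counts


def sample_trace_params(
    sample_ids: list[str],
    seed: int | None = None,
    low_fvfm_fraction: float = 0.0,
) -> dict[str, TraceParams]:
    """Draw per-sample kinetic parameters for a phenotyping cohort.

    Parameters vary log-normally (~10%) around the defaults; a fraction of
    samples are planted with degraded Fv/Fm (< 0.70) to exercise the
    quality filter, as damaged or poorly dark-adapted leaves would.
    """
    rng = substream(seed or 0, "trace_params") if seed is not None else np.random.default_rng()
    base = TraceParams()
    out = {}
    for sid in sample_ids:
        j = lambda x, s=0.1: float(x * np.exp(rng.normal(0.0, s)))  # noqa: E731
        fo = j(base.fo)
        if low_fvfm_fraction > 0 and rng.random() < low_fvfm_fraction:
            fm = fo / (1.0 - rng.uniform(0.5, 0.69))  # Fv/Fm in [0.5, 0.69)
        else:
            fm = fo / (1.0 - rng.uniform(0.75, 0.82))
        out[sid] = TraceParams(
            fo=fo,
            fm=fm,
            a_ind=j(base.a_ind),
            b_ind=j(base.b_ind),
            a_rel=j(base.a_rel),
            b_rel=j(base.b_rel),
            c_rel=j(base.c_rel),
            a_phi=j(base.a_phi),
            b_phi=j(base.b_phi),
            c_phi=j(base.c_phi),
            phi_light_start=min(j(base.phi_light_start, 0.05), 0.84),
            phi_light_ss=j(base.phi_light_ss),
            phi_light_rate=j(base.phi_light_rate),
        )
    return out


def simulate_founder_snps(
    panel: FounderPanel,
    chrom: str,
    region: tuple[int, int],
    n_snps: int = 500,
    causal_bp: int | None = None,
    causal_carriers: list[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a dense founder WGS SNP table for a local-GWAS region.

    Returns ``chrom, snp, bp`` plus one homozygous biallelic 0/1 column per
    founder; every SNP is polymorphic across founders.  If ``causal_bp``
    and ``causal_carriers`` are given, one SNP at that position carries
    allele 1 exactly in those founders — an allele pattern consistent with
    a planted founder-effect split.
    """
    rng = substream(seed or 0, "founder_snps") if seed is not None else np.random.default_rng()
    lo, hi = int(region[0]), int(region[1])
    f = panel.n_founders
    pos = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_snps, replace=False))
    patterns = np.zeros((n_snps, f), dtype=np.int8)
    for s in range(n_snps):
        k = int(rng.integers(1, f))  # 1 .. F-1 carriers -> always polymorphic
        carriers = rng.choice(f, size=k, replace=False)
        patterns[s, carriers] = 1
    snp_ids = [f"snp_{chrom}_{p}" for p in pos]
    if causal_bp is not None:
        if causal_carriers is None:
            raise ValueError("causal_carriers required with causal_bp")
        causal_pat = np.array(
            [1 if fid in causal_carriers else 0 for fid in panel.founder_ids], dtype=np.int8
        )
        # one causal SNP among background SNPs: background patterns must be
        # statistically distinct, so the causal pattern (or its complement,
        # which yields the mirrored dosage) is resampled away
        for s in range(n_snps):
            while np.array_equal(patterns[s], causal_pat) or np.array_equal(
                patterns[s], 1 - causal_pat
            ):
                k = int(rng.integers(1, f))
                patterns[s] = 0
                patterns[s, rng.choice(f, size=k, replace=False)] = 1
        ci = int(np.argmin(np.abs(pos.astype(np.int64) - int(causal_bp))))
        pos = pos.copy()
        pos[ci] = int(causal_bp)
        patterns[ci] = causal_pat
        snp_ids[ci] = f"snp_causal_{chrom}_{causal_bp}"
        order = np.argsort(pos, kind="stable")
        pos, patterns = pos[order], patterns[order]
        snp_ids = [snp_ids[i] for i in order]
    out = pd.DataFrame({"chrom": str(chrom), "snp": snp_ids, "bp": pos.astype(np.int64)})
    for j, fid in enumerate(panel.founder_ids):
        out[fid] = patterns[:, j]
    return out


def assign_gene_intervals(
    gene_ids: list[str],
    chrom: str,
    region: tuple[int, int],
    seed: int | None = None,
    gene_length: int = 4000,
) -> pd.DataFrame:
    """Place gene models as non-overlapping 1-based inclusive intervals.

    Genes are laid out in order at uniformly jittered starts across
    ``region``; used to build the BED-like gene file for candidate tests.
    """
    rng = substream(seed or 0, "gene_intervals") if seed is not None else np.random.default_rng()
    lo, hi = int(region[0]), int(region[1])
    n = len(gene_ids)
    n_slots = (hi - lo - gene_length) // gene_length
    if n_slots < n:
        raise ValueError("region too small for the requested genes")
    starts = np.sort(rng.choice(n_slots, size=n, replace=False)) * gene_length + lo
    starts = np.minimum(starts, hi - gene_length)
    return pd.DataFrame(
        {
            "chrom": str(chrom),
            "start": starts.astype(np.int64),
            "end": (starts + gene_length - 1).astype(np.int64),
            "gene_id": gene_ids,
        }
    )
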
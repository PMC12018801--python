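"""LOCO-kinship mixed-model genome scans on founder-haplotype probabilities.

The phenotype (per-genotype predicted means) is regressed marker-by-marker
on the founder-probability design under a linear mixed model whose polygenic
covariance is a kinship matrix built with the leave-one-chromosome-out
(LOCO) rule: the kinship used on chromosome c is computed from every marker
*not* on c, so the tested locus never contributes to its own covariance
correction.

Per chromosome the null polygenic variance ratio is estimated once by REML
on the kinship eigenbasis, the data are rotated and whitened accordingly,
and each marker is scored by a generalized-least-squares regression on the
K-1 df founder-probability design:

    LOD = (n/2) * log10(RSS_null / RSS_marker)

Genome-wide significance uses trait-specific permutations of the phenotype
vector (default 999, 95th percentile of the per-permutation genome-wide
maximum).  Peaks get Bayesian credible intervals — 10^LOD treated as an
unnormalized posterior over marker positions, accumulated outward from the
peak and expanded to the flanking marker positions — and founder-effect
coefficients (zero-sum contrasts) across the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .haplotypes import HaplotypeProbabilities

__all__ = [
    "KinshipSet",
    "ScanResult",
    "kinship_loco",
    "scan_lmm",
    "permutation_threshold",
    "find_peaks",
    "credible_interval",
    "founder_coefficients",
    "run_scan",
    "N_PERMUTATIONS",
    "THRESHOLD_QUANTILE",
]

N_PERMUTATIONS = 999
THRESHOLD_QUANTILE = 0.95


@dataclass
class KinshipSet:
    """Per-chromosome LOCO kinship matrices, normalized to mean diagonal 1."""

    matrices: dict[str, np.ndarray]
    ril_ids: list[str]

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.matrices[str(chrom)]


@dataclass
class ScanResult:
    """Scan curve plus threshold, peaks, intervals and founder effects."""

    scan: pd.DataFrame  # chrom, marker, bp, lod
    threshold: float | None = None
    peaks: pd.DataFrame | None = None
    intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    coefficients: dict[str, pd.DataFrame] = field(default_factory=dict)
    h2_by_chrom: dict[str, float] = field(default_factory=dict)


def kinship_loco(hap_probs: HaplotypeProbabilities) -> KinshipSet:
    """LOCO kinship: scaled founder-probability inner products off-chromosome.

    For chromosome c, K_c = X X' over the probability columns of all markers
    not on c, scaled so the mean diagonal is 1.  Requires >= 2 chromosomes
    (LOCO is undefined otherwise).
    """
    chroms = hap_probs.gmap.chromosomes
    if len(chroms) < 2:
        raise ValueError("LOCO kinship needs >= 2 chromosomes")
    n, m, k = hap_probs.probs.shape
    flat = hap_probs.probs.reshape(n, m * k)
    full = flat @ flat.T
    per_chrom = {}
    for c in chroms:
        idx = hap_probs.gmap.marker_indices(c)
        xc = hap_probs.probs[:, idx, :].reshape(n, len(idx) * k)
        kc = full - xc @ xc.T
        kc = kc * (n / np.trace(kc))
        per_chrom[c] = kc
    return KinshipSet(per_chrom, list(hap_probs.ril_ids))


class _ChromDesign:
    """Rotated per-chromosome scan design, reusable across phenotypes.

    Holds the kinship eigendecomposition and the rotated marker designs so
    that scanning a new (or permuted) phenotype costs one rotation, one 1-D
    REML optimization and a batch of small GLS solves.
    """

    def __init__(
        self,
        chrom: str,
        probs: np.ndarray,  # (n, mc, K) founder probabilities on this chromosome
        kinship: np.ndarray | None,
    ):
        self.chrom = chrom
        n, mc, kf = probs.shape
        self.n, self.n_markers, self.n_founders = n, mc, kf
        if kinship is None:
            self.eigvals = np.zeros(n)
            u = np.eye(n)
        else:
            w, u = np.linalg.eigh(kinship)
            self.eigvals = np.clip(w, 0.0, None)
        self.u = u
        self.x0 = u.T @ np.ones(n)
        design = np.concatenate([np.ones((n, 1, 1)).repeat(mc, axis=1), probs[:, :, :-1]], axis=2)
        # rotate: (mc, n, p)
        self.designs = np.einsum("ij,imp->mjp", u, design)
        self.full_probs_rot = np.einsum("ij,imp->mjp", u, probs)

    def null_h2(self, y_rot: np.ndarray) -> float:
        """REML estimate of the polygenic variance share h² under the null."""
        lam = self.eigvals
        n = self.n
        x0 = self.x0

        def neg_reml(h2: float) -> float:
            w = h2 * lam + (1.0 - h2)
            xw = x0 / w
            xvx = float(x0 @ xw)
            beta = float(xw @ y_rot) / xvx
            r = y_rot - beta * x0
            quad = float((r * r / w).sum())
            if quad <= 0:
                return 1e12
            return 0.5 * (
                (n - 1) * np.log(quad / (n - 1)) + np.log(w).sum() + np.log(xvx)
            )

        res = minimize_scalar(neg_reml, bounds=(0.0, 0.99), method="bounded",
                              options={"xatol": 1e-6})
        return float(res.x)

    def weights(self, h2: float) -> np.ndarray:
        return 1.0 / np.sqrt(h2 * self.eigvals + (1.0 - h2))

    def lod_curve(self, y_rot: np.ndarray, h2: float) -> np.ndarray:
        """Per-marker LOD for one (rotated) phenotype at fixed weights."""
        d = self.weights(h2)
        yw = y_rot * d
        x0w = self.x0 * d
        tss = float(yw @ yw)
        rss0 = tss - float(x0w @ yw) ** 2 / float(x0w @ x0w)
        xw = self.designs * d[None, :, None]
        g = np.einsum("mnp,mnq->mpq", xw, xw, optimize=True)
        b = np.einsum("mnp,n->mp", xw, yw, optimize=True)
        try:
            beta = np.linalg.solve(g, b[..., None])[..., 0]
            rss1 = tss - np.einsum("mp,mp->m", b, beta)
        except np.linalg.LinAlgError:
            rss1 = np.empty(self.n_markers)
            for m in range(self.n_markers):
                beta_m, res, rank, _ = np.linalg.lstsq(xw[m], yw, rcond=None)
                rss1[m] = tss - float((xw[m] @ beta_m) @ yw)
        bad = ~np.isfinite(rss1) | (rss1 < 0) | (rss1 > rss0 * (1 + 1e-9))
        if bad.any():
            for m in np.flatnonzero(bad):
                beta_m, _, _, _ = np.linalg.lstsq(xw[m], yw, rcond=None)
                rss1[m] = float(((yw - xw[m] @ beta_m) ** 2).sum())
        rss1 = np.clip(rss1, 1e-300, None)
        lod = (self.n / 2.0) * np.log10(np.clip(rss0 / rss1, 1.0, None))
        return lod

    def scan_phenotype(self, y: np.ndarray, use_kinship: bool = True) -> tuple[np.ndarray, float]:
        y_rot = self.u.T @ y
        h2 = self.null_h2(y_rot) if use_kinship else 0.0
        return self.lod_curve(y_rot, h2), h2


def _build_designs(
    hap_probs: HaplotypeProbabilities,
    kinship_set: KinshipSet | None,
) -> dict[str, _ChromDesign]:
    designs = {}
    for c in hap_probs.gmap.chromosomes:
        idx = hap_probs.gmap.marker_indices(c)
        kin = kinship_set[c] if kinship_set is not None else None
        designs[c] = _ChromDesign(c, hap_probs.probs[:, idx, :], kin)
    return designs


def _align_phenotype(hap_probs: HaplotypeProbabilities, phenotype: pd.Series) -> np.ndarray:
    missing = [r for r in hap_probs.ril_ids if r not in phenotype.index]
    if missing:
        raise ValueError(f"phenotype missing {len(missing)} RILs (e.g. {missing[:3]})")
    y = phenotype.loc[hap_probs.ril_ids].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    return y


def scan_lmm(
    hap_probs: HaplotypeProbabilities,
    phenotype: pd.Series,
    kinship_set: KinshipSet | None,
    use_kinship: bool = True,
    _designs: dict[str, _ChromDesign] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Genome scan: per-marker LOD, plus the per-chromosome null h².

    ``phenotype`` is a Series of per-genotype predicted means indexed by RIL
    id.  With ``use_kinship=False`` (or ``kinship_set=None``) the scan
    reduces exactly to Haley-Knott OLS regression on founder probabilities.
    """
    y = _align_phenotype(hap_probs, phenotype)
    designs = _designs or _build_designs(hap_probs, kinship_set if use_kinship else None)
    rows = []
    h2s = {}
    for c, d in designs.items():
        lod, h2 = d.scan_phenotype(y, use_kinship=use_kinship and kinship_set is not None)
        h2s[c] = h2
        sub = hap_probs.gmap.chrom_view(c)
        rows.append(
            pd.DataFrame(
                {"chrom": c, "marker": sub["marker"].to_numpy(), "bp": sub["bp"].to_numpy(), "lod": lod}
            )
        )
    return pd.concat(rows, ignore_index=True), h2s


def permutation_threshold(
    hap_probs: HaplotypeProbabilities,
    phenotype: pd.Series,
    kinship_set: KinshipSet | None,
    n_perm: int = N_PERMUTATIONS,
    quantile: float = THRESHOLD_QUANTILE,
    seed: int | None = None,
    use_kinship: bool = True,
    _designs: dict[str, _ChromDesign] | None = None,
    return_maxima: bool = False,
):
    """Trait-specific permutation threshold for the genome-wide maximum LOD.

    The phenotype vector is permuted against the genotype rows ``n_perm``
    times; each permutation is rescanned (the null h² is re-estimated per
    permutation) and the stated quantile of the per-permutation maxima is
    the threshold.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must be in (0, 1]")
    y = _align_phenotype(hap_probs, phenotype)
    designs = _designs or _build_designs(hap_probs, kinship_set if use_kinship else None)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        yp = y[rng.permutation(len(y))]
        best = 0.0
        for d in designs.values():
            lod, _ = d.scan_phenotype(yp, use_kinship=use_kinship and kinship_set is not None)
            best = max(best, float(lod.max()))
        maxima[i] = best
    thr = float(np.quantile(maxima, quantile))
    if return_maxima:
        return thr, maxima
    return thr


def find_peaks(scan: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """One peak per chromosome: its maximum-LOD marker, if above threshold.

    Ties break to the smallest physical position.
    """
    peaks = []
    for c, sub in scan.groupby("chrom", sort=False):
        sub = sub.sort_values("bp")
        i = int(np.argmax(sub["lod"].to_numpy()))  # first max = smallest bp
        row = sub.iloc[i]
        if row["lod"] >= threshold:
            peaks.append((c, row["marker"], int(row["bp"]), float(row["lod"])))
    return pd.DataFrame(peaks, columns=["chrom", "marker", "bp", "lod"])


def credible_interval(
    scan: pd.DataFrame, chrom: str, prob: float = 0.95
) -> tuple[int, int]:
    """Bayesian credible interval for the peak on one chromosome.

    10^LOD is treated as an unnormalized posterior over marker positions.
    Starting from the peak marker, the higher-posterior neighbour is added
    first (ties toward lower bp) until the accumulated mass reaches
    ``prob``; the endpoints are then expanded outward to the nearest
    flanking marker positions.
    """
    sub = scan[scan["chrom"] == str(chrom)].sort_values("bp").reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no markers on chromosome {chrom}")
    lod = sub["lod"].to_numpy(dtype=float)
    bp = sub["bp"].to_numpy()
    post = 10.0 ** (lod - lod.max())
    post = post / post.sum()
    peak = int(np.argmax(lod))
    lo = hi = peak
    mass = post[peak]
    while mass < prob and (lo > 0 or hi < len(post) - 1):
        left = post[lo - 1] if lo > 0 else -np.inf
        right = post[hi + 1] if hi < len(post) - 1 else -np.inf
        if left >= right:  # tie toward lower bp
            lo -= 1
            mass += post[lo]
        else:
            hi += 1
            mass += post[hi]
    lo_x = max(lo - 1, 0)
    hi_x = min(hi + 1, len(post) - 1)
    return int(bp[lo_x]), int(bp[hi_x])


def founder_coefficients(
    hap_probs: HaplotypeProbabilities,
    phenotype: pd.Series,
    kinship: np.ndarray | None,
    chrom: str,
    interval: tuple[int, int],
    h2: float | None = None,
    min_presence: float = 0.01,
) -> pd.DataFrame:
    """Founder haplotype effects at every marker of a credible interval.

    At each marker the (whitened) phenotype is regressed on the K
    founder-probability columns; coefficients are centred to sum to zero
    across founders.  Founders whose maximum posterior probability stays
    below ``min_presence`` across the interval are flagged unreliable
    (column ``reliable`` in the attached attrs).
    """
    sub = hap_probs.gmap.chrom_view(chrom)
    sel = (sub["bp"] >= interval[0]) & (sub["bp"] <= interval[1])
    if not sel.any():
        raise ValueError("interval contains no markers")
    idx = sub.index[sel].to_numpy()
    y = _align_phenotype(hap_probs, phenotype)
    n = len(y)
    if kinship is not None:
        w, u = np.linalg.eigh(kinship)
        w = np.clip(w, 0.0, None)
        y_rot = u.T @ y
        if h2 is None:
            d0 = _ChromDesign(chrom, hap_probs.probs[:, hap_probs.gmap.marker_indices(chrom), :], kinship)
            h2 = d0.null_h2(d0.u.T @ y)
            u, w = d0.u, d0.eigvals
            y_rot = u.T @ y
        dw = 1.0 / np.sqrt(h2 * w + (1.0 - h2))
        yw = y_rot * dw
        rot = lambda a: (u.T @ a) * dw[:, None]  # noqa: E731
    else:
        yw = y
        rot = lambda a: a  # noqa: E731

    founders = hap_probs.founder_ids
    coefs = np.empty((len(founders), len(idx)))
    presence = hap_probs.probs[:, idx, :].max(axis=(0, 1))
    for j, mi in enumerate(idx):
        xw = rot(hap_probs.probs[:, mi, :])
        beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
        coefs[:, j] = beta - beta.mean()  # zero-sum contrasts
    out = pd.DataFrame(
        coefs,
        index=pd.Index(founders, name="founder"),
        columns=sub.loc[idx, "marker"].to_numpy(),
    )
    out.attrs["reliable"] = {f: bool(presence[i] >= min_presence) for i, f in enumerate(founders)}
    out.attrs["markers_bp"] = sub.loc[idx, "bp"].to_numpy().tolist()
    return out


def run_scan(
    hap_probs: HaplotypeProbabilities,
    phenotype: pd.Series,
    kinship_set: KinshipSet | None = None,
    n_perm: int = N_PERMUTATIONS,
    quantile: float = THRESHOLD_QUANTILE,
    ci_prob: float = 0.95,
    seed: int | None = None,
    use_kinship: bool = True,
) -> ScanResult:
    """Full per-trait scan: LOD curve, threshold, peaks, CIs, founder effects."""
    if kinship_set is None and use_kinship:
        kinship_set = kinship_loco(hap_probs)
    designs = _build_designs(hap_probs, kinship_set if use_kinship else None)
    scan, h2s = scan_lmm(hap_probs, phenotype, kinship_set, use_kinship, _designs=designs)
    thr = permutation_threshold(
        hap_probs, phenotype, kinship_set, n_perm, quantile, seed, use_kinship, _designs=designs
    )
    peaks = find_peaks(scan, thr)
    intervals = {}
    coefficients = {}
    for _, pk in peaks.iterrows():
        c = pk["chrom"]
        ci = credible_interval(scan, c, ci_prob)
        intervals[c] = ci
        kin = kinship_set[c] if (kinship_set is not None and use_kinship) else None
        coefficients[c] = founder_coefficients(
            hap_probs, phenotype, kin, c, ci, h2=h2s.get(c) if use_kinship else 0.0
        )
    return ScanResult(scan, thr, peaks, intervals, coefficients, h2s)
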
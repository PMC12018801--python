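"""Founder-haplotype reconstruction along RIL genomes.

MAGIC RILs are (effectively) fully inbred, so each RIL chromosome is a
single-haplotype mosaic of founder genomes.  The hidden state at a marker is
the founder of origin; transitions follow an exchangeable continuous Markov
chain along the genetic map (rate ``lambda`` per Morgan, uniform switch
target), and emissions compare the observed RIL allele with each founder's
allele under a symmetric genotyping-error rate.  Posterior probabilities
come from the forward-backward algorithm with per-position scaling; the
most-probable founder path (Viterbi) is a secondary output.

Observed heterozygous calls are treated as missing — inbred lines should
not be heterozygous, so such calls carry no reliable founder information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap, interpolate_map  # re-export: map completion lives with the HMM  # noqa: F401
from .simulate import FounderPanel, RilGenotypes

__all__ = [
    "HaplotypeProbabilities",
    "interpolate_map",
    "transition_matrix",
    "emission_prob",
    "reconstruct_haplotypes",
    "DEFAULT_ERROR_RATE",
    "DEFAULT_LAMBDA",
]

DEFAULT_ERROR_RATE = 0.002
DEFAULT_LAMBDA = 2.0  # breakpoints per Morgan

MISSING = -1
HET = 2


@dataclass
class HaplotypeProbabilities:
    """Posterior founder probabilities: RILs × markers × founders.

    Every (RIL, marker) slice sums to one; ``viterbi`` holds the
    most-probable founder path when requested.
    """

    probs: np.ndarray  # (n_rils, n_markers, n_founders)
    ril_ids: list[str]
    founder_ids: list[str]
    gmap: GeneticMap
    viterbi: np.ndarray | None = field(default=None, repr=False)  # (n_rils, n_markers) int

    def __post_init__(self) -> None:
        n, m, k = self.probs.shape
        if n != len(self.ril_ids) or m != self.gmap.n_markers or k != len(self.founder_ids):
            raise ValueError("probability array shape does not match ids/map")

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    def argmax_founders(self) -> np.ndarray:
        """Marker-wise most-probable founder index per RIL."""
        return np.argmax(self.probs, axis=2)

    def to_wide_frame(self) -> pd.DataFrame:
        """Long/wide TSV layout: one row per (RIL, marker), a column per founder."""
        n, m, k = self.probs.shape
        rows = {
            "ril": np.repeat(self.ril_ids, m),
            "marker": np.tile(self.gmap.marker_ids, n),
        }
        flat = self.probs.reshape(n * m, k)
        for j, f in enumerate(self.founder_ids):
            rows[f] = flat[:, j]
        return pd.DataFrame(rows)


def transition_matrix(d_cm: float, n_founders: int, lambda_per_morgan: float) -> np.ndarray:
    """Exchangeable founder-switch transition matrix over distance ``d_cm``.

    With d in Morgans and K founders: stay probability
    ``exp(-lambda d) + (1 - exp(-lambda d))/K``, and probability
    ``(1 - exp(-lambda d))/K`` of arriving at each specific other founder.
    Rows sum to one; d = 0 gives the identity, d → ∞ the uniform matrix.
    """
    if d_cm < 0:
        raise ValueError("distance must be non-negative")
    if lambda_per_morgan < 0:
        raise ValueError("lambda must be non-negative")
    k = int(n_founders)
    d_m = d_cm / 100.0
    e = np.exp(-lambda_per_morgan * d_m)
    off = (1.0 - e) / k
    t = np.full((k, k), off)
    np.fill_diagonal(t, e + off)
    return t


def emission_prob(
    observed_allele: int, founder_allele: int, error_rate: float = DEFAULT_ERROR_RATE
) -> float:
    """Emission probability of one observed allele given a founder state.

    Match → 1-ε, mismatch → ε; missing or heterozygous observations are
    uninformative (probability 1 for every founder).
    """
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    if observed_allele in (MISSING, HET):
        return 1.0
    return 1.0 - error_rate if observed_allele == founder_allele else error_rate


def _emission_table(
    geno: np.ndarray, founder_alleles: np.ndarray, error_rate: float
) -> np.ndarray:
    """Emission probabilities, (n_rils, n_markers, n_founders)."""
    obs = geno[:, :, None]  # (n, m, 1)
    fa = founder_alleles.T[None, :, :]  # (1, m, k)
    match = obs == fa
    e = np.where(match, 1.0 - error_rate, error_rate)
    uninformative = (obs == MISSING) | (obs == HET)
    return np.where(uninformative, 1.0, e)


def reconstruct_haplotypes(
    ril_genotypes: RilGenotypes,
    founder_panel: FounderPanel,
    gmap: GeneticMap | None = None,
    lambda_per_morgan: float = DEFAULT_LAMBDA,
    error_rate: float = DEFAULT_ERROR_RATE,
    compute_viterbi: bool = False,
) -> HaplotypeProbabilities:
    """Forward-backward posterior over founder states per RIL and marker.

    Runs the scaled forward-backward recursion independently per chromosome
    (chromosomes are unlinked) with the exchangeable transition model and
    symmetric-error emissions.  RILs with no informative markers get a
    uniform posterior and a warning.  With ``compute_viterbi`` the
    most-probable path is attached (log-space DP; ties break to the lowest
    founder index).
    """
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    gmap = gmap or ril_genotypes.gmap
    if gmap.n_markers != founder_panel.alleles.shape[1]:
        raise ValueError("founder panel and map marker sets are not aligned")
    if ril_genotypes.alleles.shape[1] != gmap.n_markers:
        raise ValueError("RIL genotypes and map marker sets are not aligned")
    geno = ril_genotypes.alleles
    n, m = geno.shape
    k = founder_panel.n_founders

    all_missing = np.all((geno == MISSING) | (geno == HET), axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} RIL(s) have no informative markers; "
            "their posterior is uniform",
            RuntimeWarning,
            stacklevel=2,
        )

    emis = _emission_table(geno, founder_panel.alleles, error_rate)
    post = np.empty((n, m, k))
    vit = np.empty((n, m), dtype=np.int32) if compute_viterbi else None

    for chrom in gmap.chromosomes:
        idx = gmap.marker_indices(chrom)
        cm = gmap.table["cM"].to_numpy()[idx]
        e_c = emis[:, idx, :]  # (n, mc, k)
        mc = len(idx)
        trans = [
            transition_matrix(cm[j + 1] - cm[j], k, lambda_per_morgan) for j in range(mc - 1)
        ]

        # scaled forward-backward, vectorized over RILs
        alpha = np.empty((mc, n, k))
        scale = np.empty((mc, n))
        a = np.full((n, k), 1.0 / k) * e_c[:, 0, :]
        s = a.sum(axis=1)
        s[s == 0] = 1.0
        alpha[0] = a / s[:, None]
        scale[0] = s
        for j in range(1, mc):
            a = (alpha[j - 1] @ trans[j - 1]) * e_c[:, j, :]
            s = a.sum(axis=1)
            s[s == 0] = 1.0
            alpha[j] = a / s[:, None]
            scale[j] = s
        beta = np.ones((n, k))
        p = alpha[mc - 1] * beta
        post[:, idx[mc - 1], :] = p / p.sum(axis=1, keepdims=True)
        for j in range(mc - 2, -1, -1):
            beta = (beta * e_c[:, j + 1, :]) @ trans[j].T
            bs = beta.sum(axis=1, keepdims=True)
            bs[bs == 0] = 1.0
            beta = beta / bs
            p = alpha[j] * beta
            post[:, idx[j], :] = p / p.sum(axis=1, keepdims=True)

        if compute_viterbi:
            with np.errstate(divide="ignore"):
                log_e = np.log(e_c)
                log_t = [np.log(t) for t in trans]
            delta = np.full((n, k), -np.log(k)) + log_e[:, 0, :]
            back = np.empty((mc, n, k), dtype=np.int32)
            for j in range(1, mc):
                # (n, k_prev, k_next): previous delta plus transition
                cand = delta[:, :, None] + log_t[j - 1][None, :, :]
                back[j] = np.argmax(cand, axis=1)  # first max → lowest founder index
                delta = np.take_along_axis(cand, back[j][:, None, :], axis=1)[:, 0, :] + log_e[:, j, :]
            path = np.empty((n, mc), dtype=np.int32)
            path[:, mc - 1] = np.argmax(delta, axis=1)
            for j in range(mc - 1, 0, -1):
                path[:, j - 1] = np.take_along_axis(back[j], path[:, j][:, None], axis=1)[:, 0]
            vit[:, idx] = path

    return HaplotypeProbabilities(
        post, list(ril_genotypes.ril_ids), list(founder_panel.founder_ids), gmap, vit
    )
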
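"""Random-effects variance decomposition, BLUPs and heritability.

The trial model treats every design factor as a random intercept::

    phenotype = overall mean + genotype + year + year:genotype + year:rep
                + year:rep:block + year:date + year:silking + residual

with independent components per term.  REML estimates are obtained by
maximizing the profiled restricted log-likelihood over the variance ratios
``gamma_k = sigma²_k / sigma²_e`` (the residual variance is profiled out in
closed form), with components bounded at zero.  Genotype BLUPs are the
posterior means of the genotype intercepts; adding them to the overall mean
gives per-genotype predicted means, the phenotype carried into QTL mapping.

Broad-sense heritability defaults to the entry-mean basis

    H² = sigma²_g / (sigma²_g + sigma²_gxy / n_years
                     + sigma²_e / (n_years * n_reps))

with the plot basis (no divisors) available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

__all__ = [
    "VarianceDecomposition",
    "fit_random_effects",
    "predicted_means",
    "heritability",
    "trait_correlations",
    "year_mean_comparison",
    "MODEL_TERMS",
]

MODEL_TERMS = (
    "genotype",
    "year",
    "year_genotype",
    "year_rep",
    "year_rep_block",
    "year_date",
    "year_silking",
)

_TERM_COLUMNS = {
    "genotype": ("genotype",),
    "year": ("year",),
    "year_genotype": ("year", "genotype"),
    "year_rep": ("year", "rep"),
    "year_rep_block": ("year", "rep", "block"),
    "year_date": ("year", "date"),
    "year_silking": ("year", "silking_interval"),
}


@dataclass
class VarianceDecomposition:
    """REML variance estimates, overall mean and BLUPs for one trait."""

    variances: dict[str, float]  # per term + "residual"
    mean: float
    blups: pd.Series  # genotype BLUPs (posterior means)
    converged: bool
    loglik: float
    n_obs: int
    n_years: int
    n_reps: int
    terms: tuple[str, ...]
    optimizer_info: dict = field(default_factory=dict, repr=False)


def _term_codes(table: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    cols = _TERM_COLUMNS[term]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"term {term!r} needs columns {missing}")
    key = table[cols[0]].astype(str)
    for c in cols[1:]:
        key = key + ":" + table[c].astype(str)
    codes, levels = pd.factorize(key, sort=True)
    return codes.astype(np.int64), list(levels)


def _canonical_partition(codes: np.ndarray) -> np.ndarray:
    """Relabel codes by first occurrence so identical partitions compare equal."""
    _, canon = np.unique(codes, return_inverse=True)
    first = {}
    out = np.empty_like(canon)
    nxt = 0
    for i, c in enumerate(canon):
        if c not in first:
            first[c] = nxt
            nxt += 1
        out[i] = first[c]
    return out


def _reml_neg_loglik(log_gamma, eq_mats, codes_list, z_all, z_slices, y, n):
    """Profiled REML negative log-likelihood and its analytic gradient.

    With V0 = I + sum_k gamma_k Z_k Z_k' and sigma²_e profiled out, each
    per-term gradient needs tr(V0^-1 Z_k Z_k') and two quadratic forms; the
    trace comes from one triangular solve of the stacked indicator matrix
    against the Cholesky factor, the quadratics from group sums.
    """
    gammas = np.exp(log_gamma)
    v0 = np.eye(n)
    for g, e in zip(gammas, eq_mats):
        v0 += g * e
    try:
        cf = cho_factor(v0, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(log_gamma)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    sol = cho_solve(cf, np.column_stack([y, np.ones(n)]), check_finite=False)
    viy, vix = sol[:, 0], sol[:, 1]
    xvx = float(vix.sum())
    xvy = float(viy.sum())
    beta = xvy / xvx
    quad = float(y @ viy) - beta * xvy
    if quad <= 0:
        return 1e12, np.zeros_like(log_gamma)
    f = 0.5 * ((n - 1) * np.log(quad / (n - 1)) + logdet + np.log(xvx) + (n - 1))

    # tr(V0^{-1} Z_k Z_k') = ||L^{-1} Z_k||_F² via one stacked solve
    w = solve_triangular(cf[0], z_all, lower=cf[1], check_finite=False)
    col_sq = (w * w).sum(axis=0)
    u = viy - beta * vix  # P0 y
    grad = np.empty(len(gammas))
    for k, codes in enumerate(codes_list):
        q = codes.max() + 1
        tr_k = float(col_sq[z_slices[k]].sum())
        zx = np.bincount(codes, weights=vix, minlength=q)
        zu = np.bincount(codes, weights=u, minlength=q)
        grad[k] = 0.5 * gammas[k] * (
            tr_k - float(zx @ zx) / xvx - (n - 1) * float(zu @ zu) / quad
        )
    return f, grad


def fit_random_effects(
    table: pd.DataFrame,
    terms: tuple[str, ...] | None = None,
    trait: str | None = None,
    max_iter: int = 200,
) -> VarianceDecomposition:
    """REML fit of the random-intercept trial model.

    Parameters
    ----------
    table
        Long-format phenotype records with columns ``genotype, year, rep,
        block, date, silking_interval, trait, value`` (only the columns the
        requested terms need must be present).
    terms
        Random terms to include; defaults to every model term whose columns
        are present.  A year-specific fit passes ``("genotype",)`` on a
        single year's records.
    trait
        Restrict to one trait name if the table holds several.

    Raises
    ------
    ValueError
        If an included factor has fewer than two levels, or two terms are
        aliased (identical partitions of the records).
    RuntimeError
        If the optimizer does not converge (the message carries the
        iteration trace).
    """
    if trait is not None:
        table = table[table["trait"] == trait]
    if table.empty:
        raise ValueError("no records to fit")
    if terms is None:
        terms = tuple(
            t for t in MODEL_TERMS if all(c in table.columns for c in _TERM_COLUMNS[t])
        )
    if "genotype" not in terms:
        raise ValueError("the model must include the genotype term")
    y = table["value"].to_numpy(dtype=float)
    n = len(y)

    codes = {}
    for t in terms:
        c, levels = _term_codes(table, t)
        if len(levels) < 2:
            raise ValueError(f"term {t!r} has fewer than 2 levels")
        codes[t] = (c, levels)
    canon = {t: _canonical_partition(codes[t][0]) for t in terms}
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            if np.array_equal(canon[a], canon[b]):
                raise ValueError(f"terms {a!r} and {b!r} are confounded (identical partitions)")

    eq_mats = [
        (codes[t][0][:, None] == codes[t][0][None, :]).astype(float) for t in terms
    ]

    # starting values: between-level variance share per term
    resid_guess = max(np.var(y), 1e-8)
    starts = []
    g0 = []
    for t in terms:
        c, _ = codes[t]
        means = pd.Series(y).groupby(c).mean().to_numpy()
        g0.append(max(np.var(means) / resid_guess, 1e-3))
    starts.append(np.log(np.array(g0)))
    starts.append(np.full(len(terms), np.log(0.1)))

    codes_list = [codes[t][0] for t in terms]
    z_blocks = []
    z_slices = []
    start_col = 0
    for c in codes_list:
        q = int(c.max()) + 1
        z = np.zeros((n, q))
        z[np.arange(n), c] = 1.0
        z_blocks.append(z)
        z_slices.append(slice(start_col, start_col + q))
        start_col += q
    z_all = np.concatenate(z_blocks, axis=1)
    best = None
    traces = []
    for x0 in starts:
        if best is not None and best.success and np.isfinite(best.fun):
            break  # fallback start only needed when the first fails
        res = minimize(
            _reml_neg_loglik,
            np.clip(x0, -12, 8),
            args=(eq_mats, codes_list, z_all, z_slices, y, n),
            method="L-BFGS-B",
            jac=True,
            bounds=[(-14.0, 10.0)] * len(terms),
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
        )
        traces.append(f"start={np.round(x0, 2).tolist()} nit={res.nit} fun={res.fun:.8f} status={res.status}")
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError("REML did not converge; trace: " + " | ".join(traces))

    gammas = np.exp(best.x)
    gammas[gammas < 1e-5] = 0.0  # snap boundary components to zero
    v0 = np.eye(n)
    for g, e in zip(gammas, eq_mats):
        v0 += g * e
    cf = cho_factor(v0, lower=True, check_finite=False)
    x = np.ones((n, 1))
    sol = cho_solve(cf, np.column_stack([y, x]), check_finite=False)
    viy, vix = sol[:, 0], sol[:, 1]
    xvx = float(x[:, 0] @ vix)
    beta = float(x[:, 0] @ viy) / xvx
    r = y - beta
    vir = cho_solve(cf, r, check_finite=False)
    sigma2_e = float(r @ vir) / (n - 1)

    variances = {t: float(g * sigma2_e) for t, g in zip(terms, gammas)}
    variances["residual"] = sigma2_e

    gi = terms.index("genotype")
    gcodes, glevels = codes["genotype"]
    # BLUP_g = gamma_g * Z_g' V0^{-1} (y - X beta)
    agg = np.zeros(len(glevels))
    np.add.at(agg, gcodes, vir)
    blups = pd.Series(gammas[gi] * agg, index=pd.Index(glevels, name="genotype"))

    n_years = int(table["year"].nunique()) if "year" in table.columns else 1
    if {"year", "rep"} <= set(table.columns):
        n_reps = int(table.groupby("year")["rep"].nunique().max())
    else:
        n_reps = int(table["rep"].nunique()) if "rep" in table.columns else 1

    return VarianceDecomposition(
        variances=variances,
        mean=beta,
        blups=blups,
        converged=bool(best.success),
        loglik=-float(best.fun),
        n_obs=n,
        n_years=n_years,
        n_reps=n_reps,
        terms=tuple(terms),
        optimizer_info={"trace": traces},
    )


def predicted_means(decomposition: VarianceDecomposition) -> pd.Series:
    """Per-genotype predicted means: overall mean + genotype BLUP."""
    if not decomposition.converged:
        raise ValueError("decomposition did not converge; predicted means unavailable")
    return decomposition.mean + decomposition.blups


def heritability(
    decomposition: VarianceDecomposition,
    n_years: int | None = None,
    n_reps: int | None = None,
    basis: str = "entry_mean",
) -> float:
    """Broad-sense heritability from a joint-year decomposition.

    ``entry_mean`` (default) divides the interaction and residual variances
    by the numbers of years and replicate observations entering a genotype
    mean; ``plot`` uses the raw component sum.
    """
    v = decomposition.variances
    s_g = v.get("genotype", 0.0)
    s_gy = v.get("year_genotype", 0.0)
    s_e = v.get("residual", 0.0)
    ny = n_years or decomposition.n_years
    nr = n_reps or decomposition.n_reps
    if basis == "entry_mean":
        denom = s_g + s_gy / ny + s_e / (ny * nr)
    elif basis == "plot":
        denom = s_g + s_gy + s_e
    else:
        raise ValueError("basis must be 'entry_mean' or 'plot'")
    if denom <= 0:
        raise ValueError("zero phenotypic variance; heritability undefined")
    return float(s_g / denom)


def trait_correlations(
    table_a: pd.DataFrame, table_b: pd.DataFrame, min_pairs: int = 3
) -> pd.DataFrame:
    """Pearson r and two-sided p for every trait-column pair.

    Both inputs are genotype-indexed trait tables (e.g. predicted means from
    two years, or two trait sets from one year); correlations use the shared
    genotypes.  Pairs where either side has zero variance are returned with
    NaN and flagged undefined.
    """
    shared = table_a.index.intersection(table_b.index)
    rows = []
    for ca in table_a.columns:
        for cb in table_b.columns:
            a = table_a.loc[shared, ca].to_numpy(dtype=float)
            b = table_b.loc[shared, cb].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            a, b = a[ok], b[ok]
            if len(a) < min_pairs:
                raise ValueError(f"fewer than {min_pairs} paired genotypes for ({ca}, {cb})")
            if np.std(a) == 0 or np.std(b) == 0:
                rows.append((ca, cb, len(a), np.nan, np.nan, True))
                continue
            r, p = stats.pearsonr(a, b)
            rows.append((ca, cb, len(a), float(r), float(p), False))
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "n", "r", "p", "undefined"])


def year_mean_comparison(values_by_year: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p comparing a trait's values across years."""
    groups = [np.asarray(v, dtype=float) for v in values_by_year.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
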
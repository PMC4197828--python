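"""Two-colour array normalisation, replicate averaging and moderated tests.

The chain is the classical limma-style analysis of dye-swapped two-colour
hybridisations: per-array loess correction of the intensity-dependent dye
bias on the (M, A) plane, orientation-aware averaging over duplicate
probes and dye pairs so that each gene keeps one value per biological
replicate, empirical-Bayes shrinkage of the gene-wise variances towards a
scaled inverse chi-square prior (d0, s0^2) estimated by the method of
moments on log variances, and a moderated t-statistic whose null is a
standard normal by default (a t null with d0 + d_g degrees of freedom is
available).  Multiplicity is handled by Bonferroni, Benjamini-Hochberg,
or a semi-parametric local false discovery rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .simulate import ArrayDesign


@dataclass(frozen=True)
class EBayesPrior:
    """Hierarchical variance prior: sigma_g^2 ~ scaled-inv-chi2(d0, s0^2)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (may be inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


@dataclass
class LogRatioMatrix:
    """Mean log-ratios per gene and comparison, plus the replicate-level values.

    ``mean`` is genes x comparisons; ``replicates`` is genes x
    (comparison, bio_rep) with exactly one value per biological replicate,
    the basis for variance estimation.
    """

    mean: pd.DataFrame
    replicates: pd.DataFrame  # columns: MultiIndex (comparison, bio_rep)


def loess_normalize(
    m: np.ndarray, a: np.ndarray, span: float = 0.3, iterations: int = 2
) -> np.ndarray:
    """Remove the intensity-dependent trend from one hybridisation.

    Fits M ~ loess(A) (local linear regression with tricube weights at the
    given span, with robustness iterations) and returns the residuals.
    When A carries no information (constant across probes) the plain mean
    of M is subtracted instead.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.shape != a.shape:
        raise ValueError("M and A must have the same shape")
    if m.size < 50:
        raise ValueError("need at least 50 probes per hybridisation")
    if np.ptp(a) < 1e-12:
        return m - m.mean()
    fit = lowess(m, a, frac=span, it=iterations, return_sorted=False)
    return m - fit


def normalize_table(probe_table: pd.DataFrame, span: float = 0.3) -> pd.DataFrame:
    """Per-hybridisation loess normalisation of a probe-level intensity table.

    Expects columns probe_id, gene_id, comparison, bio_rep, dye_swap, R, G;
    adds A (mean log2 intensity) and M (corrected log2 ratio, still in raw
    dye orientation).
    """
    table = probe_table.copy()
    log_r = np.log2(table["R"].to_numpy(dtype=float))
    log_g = np.log2(table["G"].to_numpy(dtype=float))
    table["A"] = (log_r + log_g) / 2.0
    raw_m = log_r - log_g
    corrected = np.empty_like(raw_m)
    for _, idx in table.groupby(["comparison", "bio_rep", "dye_swap"]).groups.items():
        pos = table.index.get_indexer(idx)
        corrected[pos] = loess_normalize(raw_m[pos], table["A"].to_numpy()[pos], span=span)
    table["M"] = corrected
    return table


def average_replicates(normalized: pd.DataFrame, design: ArrayDesign) -> LogRatioMatrix:
    """Collapse probes and dye pairs to one value per biological replicate.

    Dye-swapped M values are sign-flipped to biological orientation, then
    averaged first over duplicate probes within each hybridisation and
    next over the dye pair, leaving one value per (gene, comparison,
    biological replicate).  A gene absent from every replicate of a
    comparison is an error; absence from a single hybridisation only
    drops that hybridisation from the mean.
    """
    df = normalized.copy()
    orient = np.where(df["dye_swap"].astype(bool), -1.0, 1.0)
    df["m_bio"] = df["M"] * orient
    per_hyb = (
        df.groupby(["gene_id", "comparison", "bio_rep", "dye_swap"], sort=True)["m_bio"]
        .mean()
        .reset_index()
    )
    per_rep = (
        per_hyb.groupby(["gene_id", "comparison", "bio_rep"], sort=True)["m_bio"]
        .mean()
        .reset_index()
    )
    replicates = per_rep.pivot_table(
        index="gene_id", columns=["comparison", "bio_rep"], values="m_bio"
    )
    comparisons = [c for c in design.comparisons if c in replicates.columns.get_level_values(0)]
    replicates = replicates.reindex(columns=comparisons, level=0)
    mean = replicates.T.groupby(level="comparison", sort=False).mean().T
    mean = mean[comparisons]
    if mean.isna().any().any():
        missing = mean.index[mean.isna().any(axis=1)].tolist()
        raise ValueError(f"genes with no data in some comparison: {missing[:5]}")
    return LogRatioMatrix(mean=mean, replicates=replicates)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> EBayesPrior:
    """Method-of-moments fit of (d0, s0^2) from gene-wise sample variances.

    Matches the mean and variance of log s_g^2 to the moments of the log
    of a scaled F variate: with e_g = log s_g^2 - digamma(d_g/2) +
    log(d_g/2), one has E[e] = log s0^2 - digamma(d0/2) + log(d0/2) and
    Var(e) = trigamma(d_g/2) + trigamma(d0/2).  When the empirical
    variance of e does not exceed the trigamma term the variances are
    declared constant (d0 = inf) and s0^2 is their plain mean.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (df >= 1) & (s2 > 0) & np.isfinite(s2)
    if ok.sum() < 20:
        raise ValueError("need at least 20 genes with positive variance and df >= 1")
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(s2.mean())
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def squeeze_var(s2: np.ndarray, df: np.ndarray, prior: EBayesPrior) -> np.ndarray:
    """Posterior mean variances: (d0 s0^2 + d_g s_g^2) / (d0 + d_g)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.isinf(prior.d0):
        return np.full_like(s2, prior.s0_sq)
    return (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)


def moderated_test(
    matrix: LogRatioMatrix,
    prior: EBayesPrior | None = None,
    null: str = "normal",
) -> pd.DataFrame:
    """Moderated t-statistics for every gene x comparison.

    The statistic is mean / (s_tilde * sqrt(1/n_rep)) with the posterior
    standard deviation s_tilde from :func:`squeeze_var`.  Two-sided
    p-values come from the standard normal (``null="normal"``, the
    default) or from a t distribution with d0 + d_g degrees of freedom
    (``null="t"``).  When the prior is not supplied it is estimated from
    all gene x comparison variances of the replicate matrix.
    """
    if null not in ("normal", "t"):
        raise ValueError("null must be 'normal' or 't'")
    reps = matrix.replicates
    comparisons = list(dict.fromkeys(reps.columns.get_level_values(0)))
    rows = []
    n_by_comp = {}
    s2_all, df_all = [], []
    for comp in comparisons:
        block = reps[comp]
        n = block.notna().sum(axis=1)
        if (n < 2).any():
            raise ValueError(f"comparison {comp}: every gene needs >= 2 replicates")
        s2 = block.var(axis=1, ddof=1)
        n_by_comp[comp] = n
        s2_all.append(s2.to_numpy())
        df_all.append((n - 1).to_numpy())
    if prior is None:
        prior = estimate_prior(np.concatenate(s2_all), np.concatenate(df_all))

    for comp, s2, dfree in zip(comparisons, s2_all, df_all):
        block = reps[comp]
        mean = block.mean(axis=1).to_numpy()
        n = n_by_comp[comp].to_numpy(dtype=float)
        s2_post = squeeze_var(s2, dfree, prior)
        se = np.sqrt(s2_post) * np.sqrt(1.0 / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(se > 0, mean / np.where(se > 0, se, 1.0), np.sign(mean) * np.inf)
        if np.any(se == 0):
            warnings.warn("zero posterior variance: statistics mapped to +/-inf, p = 0")
        if null == "normal":
            p = 2.0 * stats.norm.sf(np.abs(stat))
        else:
            total_df = np.where(np.isinf(prior.d0), np.inf, prior.d0 + dfree)
            p = np.where(
                np.isinf(total_df),
                2.0 * stats.norm.sf(np.abs(stat)),
                2.0 * stats.t.sf(np.abs(stat), np.where(np.isinf(total_df), 1.0, total_df)),
            )
        p = np.where(np.isinf(stat), 0.0, p)
        p = np.where(np.isnan(stat), 1.0, p)
        stat = np.where(np.isnan(stat), 0.0, stat)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": reps.index,
                    "comparison": comp,
                    "logratio": mean,
                    "s2": s2,
                    "df": dfree,
                    "s2_post": s2_post,
                    "stat": stat,
                    "p": np.clip(p, 0.0, 1.0),
                }
            )
        )
    result = pd.concat(rows, ignore_index=True)
    result.attrs["prior"] = prior
    return result


def local_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Semi-parametric two-component local false discovery rate.

    P-values are probit-transformed (z = Phi^{-1}(1 - p)); the marginal
    density of z is estimated by a Gaussian kernel, the null component is
    the standard normal with weight pi0 estimated from the p > 1/2 mass,
    and the local fdr is the per-gene posterior null probability
    pi0 * phi(z) / f(z), clipped to [0, 1].  Degenerate inputs (fewer
    than 8 values, or no spread) are returned unchanged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 8:
        return p.copy()
    z = stats.norm.ppf(np.clip(1.0 - p, 1e-15, 1.0 - 1e-15))
    if np.std(z) < 1e-12:
        return p.copy()
    kde = stats.gaussian_kde(z)
    f = np.maximum(kde(z), 1e-300)
    pi0 = min(1.0, np.mean(p > 0.5) / 0.5) or 1e-8
    return np.clip(pi0 * stats.norm.pdf(z) / f, 0.0, 1.0)


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment: 'bonferroni', 'bh', or 'local_fdr'."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "local_fdr":
        return local_fdr(p)
    raise ValueError(f"unknown method {method!r}")


def call_de(
    test_table: pd.DataFrame, alpha: float = 0.05, fdr_method: str = "bh"
) -> pd.DataFrame:
    """Attach adjusted p-values and the DE call at the given threshold.

    Adjustment is done within each comparison (each contrast is its own
    family of tests).  Adds columns p_bonf, p_adj (the chosen method) and
    de_flag (p_adj <= alpha).
    """
    out = []
    for _, block in test_table.groupby("comparison", sort=False):
        block = block.copy()
        block["p_bonf"] = adjust_pvalues(block["p"].to_numpy(), "bonferroni")
        block["p_adj"] = adjust_pvalues(block["p"].to_numpy(), fdr_method)
        block["de_flag"] = block["p_adj"] <= alpha
        out.append(block)
    return pd.concat(out, ignore_index=True)


def mapk_dependence(
    logratios: pd.DataFrame,
    de_in_reference: pd.Series,
    reference: str,
    mutants: list[str],
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Classify each regulated gene as MAPK-affected per mutant contrast.

    For genes flagged as regulated in the reference contrast, a mutant is
    ``affected`` when the flagellin response differs from the reference
    by at least ``threshold`` log2 units in either direction
    (|logratio_mutant - logratio_reference| >= threshold), ``unaffected``
    otherwise, and ``unclassifiable`` when the mutant value is missing.
    """
    genes = logratios.index[de_in_reference.reindex(logratios.index, fill_value=False)]
    rows = []
    for mutant in mutants:
        diff = (logratios.loc[genes, mutant] - logratios.loc[genes, reference]).abs()
        status = np.where(diff.isna(), "unclassifiable",
                          np.where(diff >= threshold, "affected", "unaffected"))
        rows.append(pd.DataFrame({"gene_id": genes, "mutant": mutant, "status": status}))
    return pd.concat(rows, ignore_index=True)
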
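"""Per-probe two-group comparison with empirical-Bayes variance moderation.

The screen compares NLRP7-mutated moles against pooled normal placenta on
the beta scale.  Each probe g contributes a mean difference
``delta_beta_g = mean(case) - mean(control)`` and a pooled residual
variance ``s2_g`` with ``df = n1 + n2 - 2``.  The per-probe variances are
shrunk toward a common prior by fitting a scaled inverse-chi-square prior
``s2_g ~ s0^2 * d0 / chi^2_{d0}`` across all probes, via moment matching on
``log s2_g`` (digamma/trigamma relations).  The posterior variance

    s2_post = (d0 * s0^2 + df * s2_g) / (d0 + df)

yields the moderated t-statistic ``t = delta / sqrt(s2_post * (1/n1 + 1/n2))``
referred to a t distribution with ``d0 + df`` degrees of freedom (standard
normal when d0 is infinite).

Tests are run on beta values directly, not logit M-values, because the
screen's effect threshold is stated on the beta scale.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import DataError, EBayesParams, MethylationDataset

logger = logging.getLogger(__name__)

#: Floor applied to sample variances before log-moment estimation, so that
#: degenerate (zero-variance) probes cannot poison the prior fit.
VARIANCE_FLOOR = 1e-8


def group_difference(
    dataset: MethylationDataset,
    case_group: str,
    control_groups: Sequence[str],
) -> pd.DataFrame:
    """Per-probe mean difference and pooled two-group residual variance.

    Returns a DataFrame indexed by probe id with columns ``delta_beta``,
    ``s_sq``, ``df_residual``, ``n_case``, ``n_control``.
    """
    case_ids = dataset.samples_in_group(case_group)
    ctrl_ids = dataset.samples_in_group(*control_groups)
    n1, n2 = len(case_ids), len(ctrl_ids)
    if n1 < 2 or n2 < 2:
        raise DataError(
            f"need >=2 samples per side, got case={n1}, control={n2}"
        )
    case = dataset.beta[case_ids].to_numpy(dtype=float)
    ctrl = dataset.beta[ctrl_ids].to_numpy(dtype=float)
    delta = case.mean(axis=1) - ctrl.mean(axis=1)
    ss_case = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_ctrl = ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s_sq = (ss_case + ss_ctrl) / df
    return pd.DataFrame(
        {
            "delta_beta": delta,
            "s_sq": s_sq,
            "df_residual": df,
            "n_case": n1,
            "n_control": n2,
        },
        index=dataset.beta.index,
    )


def trigamma_inverse(x: float) -> float:
    """Solve ``trigamma(y) = x`` for y > 0 by Newton iteration.

    Monotone decreasing, so the iteration from ``y = 0.5 + 1/x`` converges
    quadratically for any positive x.
    """
    if not np.isfinite(x) or x <= 0:
        raise DataError(f"trigamma_inverse needs finite positive input, got {x}")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def fit_variance_prior(s_sq: np.ndarray, df: float) -> EBayesParams:
    """Fit the scaled inverse-chi-square prior by log-variance moments.

    With ``s2_g ~ s0^2 (chi2_df / df) * (d0 / chi2_{d0})``, the log sample
    variances satisfy

        E[log s2] = log s0^2 + digamma(df/2) - log(df/2)
                              - digamma(d0/2) + log(d0/2)
        Var[log s2] = trigamma(df/2) + trigamma(d0/2)

    so the excess of the observed log-variance spread over trigamma(df/2)
    identifies d0, and the mean then identifies s0^2.  A non-positive excess
    means the variances are exchangeable with a single value: d0 = inf.
    """
    if len(s_sq) < 2:
        raise DataError("variance prior needs at least 2 probes")
    s_sq = np.maximum(np.asarray(s_sq, dtype=float), VARIANCE_FLOOR)
    z = np.log(s_sq)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return EBayesParams(d0=d0, s0_sq=s0_sq)


def posterior_variance(s_sq: np.ndarray, df: float, prior: EBayesParams) -> np.ndarray:
    """Shrink per-probe variances toward the prior."""
    s_sq = np.asarray(s_sq, dtype=float)
    if np.isinf(prior.d0):
        return np.full_like(s_sq, prior.s0_sq)
    return (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)


def ebayes_moderate(
    stats_df: pd.DataFrame,
    prior: Optional[EBayesParams] = None,
    min_probes: int = 50,
) -> tuple[EBayesParams, pd.DataFrame]:
    """Moderated t-statistics and p-values for a table from
    :func:`group_difference`.

    Parameters
    ----------
    stats_df : DataFrame
        Columns ``delta_beta``, ``s_sq``, ``df_residual``, ``n_case``,
        ``n_control`` (all df equal — balanced design assumption).
    prior : EBayesParams, optional
        Override the fitted prior.  ``EBayesParams(d0=..)`` with tiny d0
        approaches the ordinary pooled two-sample t; to get it exactly use
        :func:`ordinary_t`.
    min_probes : int
        Minimum number of probes for moment estimation (the prior is a
        cross-probe quantity).

    Returns the prior actually used and the input table augmented with
    ``s_sq_post``, ``t_mod``, ``p_value`` and ``df_total`` columns.
    """
    dfs = stats_df["df_residual"].unique()
    if len(dfs) != 1:
        raise DataError(f"residual df must be constant across probes, got {dfs}")
    df = float(dfs[0])
    if prior is None:
        if len(stats_df) < min_probes:
            raise DataError(
                f"need >= {min_probes} probes to fit the variance prior, "
                f"got {len(stats_df)}"
            )
        prior = fit_variance_prior(stats_df["s_sq"].to_numpy(), df)
    logger.info("eBayes prior: d0=%.4g, s0_sq=%.4g", prior.d0, prior.s0_sq)

    s_post = posterior_variance(stats_df["s_sq"].to_numpy(), df, prior)
    n1 = stats_df["n_case"].to_numpy(dtype=float)
    n2 = stats_df["n_control"].to_numpy(dtype=float)
    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    delta = stats_df["delta_beta"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
        t_mod = np.where((se == 0) & (delta != 0), np.sign(delta) * np.inf, t_mod)
    df_total = prior.d0 + df
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = stats_df.copy()
    out["s_sq_post"] = s_post
    out["t_mod"] = t_mod
    out["p_value"] = np.clip(p, 0.0, 1.0)
    out["df_total"] = df_total
    return prior, out


def ordinary_t(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Classical pooled two-sample t per probe (the d0 -> 0 limit)."""
    df = float(stats_df["df_residual"].iloc[0])
    n1 = stats_df["n_case"].to_numpy(dtype=float)
    n2 = stats_df["n_control"].to_numpy(dtype=float)
    se = np.sqrt(stats_df["s_sq"].to_numpy() * (1.0 / n1 + 1.0 / n2))
    delta = stats_df["delta_beta"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (delta != 0), np.sign(delta) * np.inf, t)
    out = stats_df.copy()
    out["t_ordinary"] = t
    out["p_ordinary"] = np.clip(2.0 * stats.t.sf(np.abs(t), df), 0.0, 1.0)
    return out


def run_diffmeth(
    dataset: MethylationDataset,
    case_group: str = "NLRP7_RHM",
    control_groups: Sequence[str] = ("PLACENTA_FIRST", "PLACENTA_TERM"),
    prior: Optional[EBayesParams] = None,
) -> tuple[EBayesParams, pd.DataFrame]:
    """Full differential stage: group difference then eBayes moderation.

    The returned table also carries probe coordinates for region calling.
    """
    gd = group_difference(dataset, case_group, control_groups)
    prior, table = ebayes_moderate(gd, prior=prior)
    table = table.join(dataset.annotation[["chrom", "pos"]])
    return prior, table
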
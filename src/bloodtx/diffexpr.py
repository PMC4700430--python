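"""Two-group differential expression with an empirical-Bayes moderated t.

Per probe, the unpaired two-sample statistics are the group means on the
log2 scale, their difference (log2 fold change) and the pooled residual
variance s2 with df = n1 + n2 - 2.  Across probes, the s2 are assumed to
be draws from a scaled inverse-chi-square prior with hyper-parameters
(d0, s0_sq); the moderated t replaces each probe's s2 by the posterior
value

    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)

and refers t_mod = log2_fc / sqrt(s2_post * (1/n1 + 1/n2)) to a Student
t with df_total = df + d0.  The hyper-parameters are estimated by
matching the first two moments of log s2 against the theoretical
log-F-like distribution (digamma/trigamma inversion).  When the spread
of log s2 is no larger than sampling noise alone implies, d0 is reported
as infinite and every probe shares the common variance.

Fold changes are reported in the signed display convention: +f means
f-fold up-regulation in cases, -f means f-fold down-regulation
(|f| >= 1 always).  DEG selection uses the hybrid rule p < p_max AND
|signed FC| > fc_min with strict inequalities; no multiple-testing
correction is applied to the selection (a Benjamini-Hochberg column is
emitted for reference only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .datatypes import ExpressionMatrix, ProbeAnnotation, SampleTable

#: p-value sentinel for degenerate probes with zero posterior variance.
P_DEGENERATE = 1e-300


@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse-chi-square prior on per-probe variances."""

    d0: float  # prior degrees of freedom; may be math.inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def probe_stats(matrix: ExpressionMatrix, samples: SampleTable) -> pd.DataFrame:
    """Per-probe unpaired group means, log2 FC and pooled variance.

    Returns a DataFrame indexed by probe with columns ``mean_case``,
    ``mean_control``, ``log2_fc``, ``s2`` and ``df_resid``.
    """
    case_mask = samples.group_mask(matrix.sample_ids)
    n1, n2 = int(case_mask.sum()), int((~case_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group, got n1={n1}, n2={n2}")
    arr = matrix.values.to_numpy()
    case = arr[:, case_mask]
    ctrl = arr[:, ~case_mask]
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    s2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "log2_fc": mean_case - mean_ctrl,
            "s2": s2,
            "df_resid": float(n1 + n2 - 2),
        },
        index=matrix.probe_ids,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    # trigamma(y) ~ 1/y + 1/(2y^2); start from the 1/y approximation
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df_resid: float) -> VariancePrior:
    """Estimate (d0, s0_sq) by moment matching on log s2.

    With z = log s2, E[z] = log s0_sq + digamma(df/2) - log(df/2)
    - digamma(d0/2) + log(d0/2) and Var[z] = trigamma(df/2) +
    trigamma(d0/2).  The observed variance of z in excess of
    trigamma(df/2) is inverted through the trigamma function to get d0;
    no excess means d0 = inf (all probes share s0_sq).  Zero variances
    are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need >=2 probes with positive s2 to fit the prior")
    df_half = df_resid / 2.0
    z = np.log(s2)
    if np.ptp(z) == 0:  # exactly constant: no information beyond the value
        return VariancePrior(d0=np.inf, s0_sq=float(s2[0]))
    e = z - digamma(df_half) + np.log(df_half)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(polygamma(1, df_half))
    if excess <= 0:
        return VariancePrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t(stats_df: pd.DataFrame, prior: VariancePrior, n1: int, n2: int
                ) -> pd.DataFrame:
    """Moderated t statistic, total df and two-sided p for every probe.

    ``d0 -> 0`` recovers the ordinary pooled t; ``d0 = inf`` gives a
    normal reference (t with infinite df).  A probe whose posterior
    variance is exactly zero (constant everywhere, degenerate) receives
    the sentinel p :data:`P_DEGENERATE` with a warning.
    """
    df_resid = stats_df["df_resid"].to_numpy()
    s2 = stats_df["s2"].to_numpy()
    lfc = stats_df["log2_fc"].to_numpy()
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (prior.d0 * prior.s0_sq + df_resid * s2) / (prior.d0 + df_resid)
        df_total = df_resid + prior.d0
    scale = s2_post * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = lfc / np.sqrt(scale)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t_mod)),
        2.0 * stats.t.sf(np.abs(t_mod), df=np.where(np.isinf(df_total), 1.0, df_total)),
    )
    degenerate = scale == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} probe(s) with zero posterior variance; "
            "p set to sentinel",
            RuntimeWarning,
            stacklevel=2,
        )
        t_mod = np.where(degenerate & (lfc == 0), 0.0, t_mod)
        p = np.where(degenerate, np.where(lfc == 0, 1.0, P_DEGENERATE), p)
    p = np.clip(p, P_DEGENERATE, 1.0)
    return pd.DataFrame(
        {"t_mod": t_mod, "df_total": df_total, "p": p}, index=stats_df.index
    )


def signed_fold_change(log2_fc) -> np.ndarray:
    """Signed display fold change: 2**lfc if lfc >= 0 else -2**(-lfc).

    The magnitude is always >= 1; a log2 FC of 0 maps to +1.
    """
    lfc = np.asarray(log2_fc, dtype=float)
    out = np.where(lfc >= 0, np.exp2(lfc), -np.exp2(-lfc))
    return out if out.ndim else float(out)


def de_table(matrix: ExpressionMatrix, samples: SampleTable, paired: bool = False
             ) -> pd.DataFrame:
    """Full moderated-t differential expression table.

    Columns: group means, ``log2_fc``, ``signed_fc``, ``s2``, ``t_mod``,
    ``df_total``, ``p``, ``p_bh`` (Benjamini-Hochberg, reference only)
    and ``direction`` (up/down in cases).  ``paired=True`` analyses
    within-pair differences with a one-sample moderated t instead of the
    default unpaired comparison.
    """
    if paired:
        stats_df, n1, n2 = _paired_stats(matrix, samples)
    else:
        stats_df = probe_stats(matrix, samples)
        n1, n2 = samples.n_case, samples.n_control
    prior = fit_variance_prior(stats_df["s2"].to_numpy(), float(stats_df["df_resid"].iloc[0]))
    mod = moderated_t(stats_df, prior, n1, n2)
    out = stats_df.join(mod)
    out["signed_fc"] = signed_fold_change(out["log2_fc"].to_numpy())
    out["direction"] = np.where(out["log2_fc"] >= 0, "up", "down")
    out["p_bh"] = _bh_adjust(out["p"].to_numpy())
    out.attrs["prior_d0"] = prior.d0
    out.attrs["prior_s0_sq"] = prior.s0_sq
    out.attrs["n1"], out.attrs["n2"] = n1, n2
    return out


def _paired_stats(matrix: ExpressionMatrix, samples: SampleTable
                  ) -> tuple[pd.DataFrame, int, int]:
    # One-sample analysis of case-minus-control pair differences.  The
    # moderated-t formula applies with 1/n1 + 1/n2 replaced by 1/n_pairs,
    # which we encode by passing n1 = n2 = 2 * n_pairs.
    pairs = samples.pairs
    case_ids = [c for c, _ in pairs]
    ctrl_ids = [c for _, c in pairs]
    diff = matrix.values[case_ids].to_numpy() - matrix.values[ctrl_ids].to_numpy()
    n = diff.shape[1]
    if n < 2:
        raise ValueError("paired analysis needs >=2 pairs")
    mean_d = diff.mean(axis=1)
    stats_df = pd.DataFrame(
        {
            "mean_case": matrix.values[case_ids].mean(axis=1).to_numpy(),
            "mean_control": matrix.values[ctrl_ids].mean(axis=1).to_numpy(),
            "log2_fc": mean_d,
            "s2": diff.var(axis=1, ddof=1),
            "df_resid": float(n - 1),
        },
        index=matrix.probe_ids,
    )
    return stats_df, 2 * n, 2 * n


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEGSelection:
    """Probes passing the hybrid p / fold-change thresholds."""

    p_max: float
    fc_min: float
    deg_ids: list
    n_up: int
    n_down: int

    @property
    def n_total(self) -> int:
        return len(self.deg_ids)


def select_degs(det: pd.DataFrame, p_max: float = 0.01, fc_min: float = 1.5
                ) -> DEGSelection:
    """Hybrid selection: p < p_max AND |signed FC| > fc_min (both strict)."""
    if p_max <= 0 or fc_min < 1:
        raise ValueError("require p_max > 0 and fc_min >= 1")
    mask = (det["p"] < p_max) & (det["signed_fc"].abs() > fc_min)
    sel = det[mask]
    return DEGSelection(
        p_max=p_max,
        fc_min=fc_min,
        deg_ids=sel.index.tolist(),
        n_up=int((sel["signed_fc"] > 0).sum()),
        n_down=int((sel["signed_fc"] < 0).sum()),
    )


def top_table(det: pd.DataFrame, k: int = 20,
              annotation: Optional[ProbeAnnotation] = None,
              symbols_only: bool = False) -> pd.DataFrame:
    """Top-k probes sorted by p ascending.

    Ties in p are broken by |signed FC| descending, then probe id.  With
    ``symbols_only=True`` probes lacking a gene symbol are excluded
    before taking the top k (requires ``annotation``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tab = det.copy()
    if annotation is not None:
        tab["gene_symbol"] = annotation.symbols(tab.index).to_numpy()
    if symbols_only:
        if annotation is None:
            raise ValueError("symbols_only requires an annotation")
        tab = tab[tab["gene_symbol"].notna()]
    tab = tab.assign(_absfc=tab["signed_fc"].abs(), _id=tab.index.astype(str))
    tab = tab.sort_values(
        ["p", "_absfc", "_id"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_id")
    if k > len(tab):
        tab.attrs["note"] = f"requested top {k} of only {len(tab)} rows"
        k = len(tab)
    return tab.drop(columns="_absfc").head(k)
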
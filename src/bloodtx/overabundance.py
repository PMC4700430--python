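"""Overabundance of small p-values relative to the uniform null.

For a grid of thresholds alpha the observed count O(alpha) = #{p_i <=
alpha} is compared with the expectation E(alpha) = alpha * N that holds
when no probe is differentially expressed (p uniform).  A ratio O/E
above 1 across the p-value range is the qualitative signature of a
genuine group difference.  An optional permutation band re-runs the
moderated-t analysis under random group-label permutations — by default
swapping labels within matched pairs to honor the paired design — and
records per-threshold quantiles of the null counts.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleTable
from .diffexpr import fit_variance_prior, moderated_t, probe_stats


def default_alpha_grid(n: int = 100, lo: float = 1e-4, hi: float = 1.0) -> np.ndarray:
    """Log-spaced threshold grid (100 points from 1e-4 to 1 by default)."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def overabundance_curve(p_values, alpha_grid=None) -> pd.DataFrame:
    """Observed vs expected significant-probe counts over a threshold grid.

    Counting is non-strict (p <= alpha) so O(1) = N exactly.  Returns a
    DataFrame with columns alpha, observed, expected, ratio.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha = np.asarray(alpha_grid, dtype=float)
    if (np.diff(alpha) <= 0).any():
        raise ValueError("alpha grid must be strictly ascending")
    n = p.size
    observed = np.searchsorted(np.sort(p), alpha, side="right")
    expected = alpha * n
    return pd.DataFrame(
        {
            "alpha": alpha,
            "observed": observed,
            "expected": expected,
            "ratio": observed / expected,
        }
    )


def _permutation_assignments(samples: SampleTable, rng: np.random.Generator,
                             paired: bool) -> np.ndarray:
    """One random case/control relabelling, as a case-mask over sample ids."""
    ids = list(samples.sample_ids)
    pos = {s: i for i, s in enumerate(ids)}
    mask = np.zeros(len(ids), dtype=bool)
    if paired:
        for case_id, ctrl_id in samples.pairs:
            if rng.random() < 0.5:
                mask[pos[case_id]] = True
            else:
                mask[pos[ctrl_id]] = True
    else:
        n_case = samples.n_case
        chosen = rng.choice(len(ids), size=n_case, replace=False)
        mask[chosen] = True
    return mask


def _pvalues_for_mask(arr: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Moderated-t p-values for an arbitrary case/control split of columns."""
    n1 = int(case_mask.sum())
    n2 = int((~case_mask).sum())
    case = arr[:, case_mask]
    ctrl = arr[:, ~case_mask]
    df = float(n1 + n2 - 2)
    s2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / df
    stats_df = pd.DataFrame(
        {"log2_fc": case.mean(axis=1) - ctrl.mean(axis=1), "s2": s2, "df_resid": df}
    )
    prior = fit_variance_prior(s2, df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mod = moderated_t(stats_df, prior, n1, n2)
    return mod["p"].to_numpy()


def permutation_band(matrix: ExpressionMatrix, samples: SampleTable,
                     alpha_grid=None, n_permutations: int = 200,
                     seed: int = 0, paired: bool = True) -> pd.DataFrame:
    """Null band for O(alpha) from group-label permutations.

    For each of ``n_permutations`` relabellings the full moderated-t
    analysis is recomputed (prior refit included) and O(alpha) counted;
    the band columns are the per-alpha 2.5%, 50% and 97.5% quantiles.
    Deterministic given ``seed``.  With ``paired=True`` labels are
    swapped only within matched pairs.
    """
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} < 100 gives a coarse band",
            UserWarning,
            stacklevel=2,
        )
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha = np.asarray(alpha_grid, dtype=float)
    arr = matrix.values.to_numpy()
    rng = np.random.default_rng(seed)
    counts = np.empty((n_permutations, alpha.size), dtype=int)
    for b in range(n_permutations):
        mask = _permutation_assignments(samples, rng, paired)
        p = _pvalues_for_mask(arr, mask)
        counts[b] = np.searchsorted(np.sort(p), alpha, side="right")
    qs = np.quantile(counts, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {
            "alpha": alpha,
            "band_lo": qs[0],
            "band_median": qs[1],
            "band_hi": qs[2],
        }
    )


def overabundance_analysis(matrix: ExpressionMatrix, samples: SampleTable,
                           alpha_grid=None, n_permutations: int = 0,
                           seed: int = 0, paired: bool = True) -> pd.DataFrame:
    """Observed curve for the real labels, optionally with the null band."""
    det_stats = probe_stats(matrix, samples)
    prior = fit_variance_prior(det_stats["s2"].to_numpy(),
                               float(det_stats["df_resid"].iloc[0]))
    mod = moderated_t(det_stats, prior, samples.n_case, samples.n_control)
    curve = overabundance_curve(mod["p"].to_numpy(), alpha_grid)
    if n_permutations > 0:
        band = permutation_band(matrix, samples, curve["alpha"].to_numpy(),
                                n_permutations, seed, paired)
        curve = curve.merge(band, on="alpha")
    return curve
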
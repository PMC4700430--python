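"""Single-color microarray preprocessing chain.

The chain mirrors a standard GeneSpring-style workflow for one-color
Agilent intensities:

1. floor raw intensities at a small constant and take log2;
2. per-sample 75th-percentile shift (each column's chosen percentile is
   subtracted, so arrays become comparable);
3. per-probe baseline transformation (subtract each probe's median over
   all samples);
4. expression filter: drop probes whose normalized signal summary falls
   at or below a chosen percentile of all probes;
5. flag filter: drop probes not detected (present/marginal) in enough
   samples.

Percentiles use linear interpolation between order statistics.  The
expression filter summarizes each probe by its median across samples on
the *shifted* (normalized, pre-baseline) values; the cut percentile is
taken over those per-probe summaries.  Both readings are recorded in the
filter report so downstream users can audit them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import FLAG_CHARS, ExpressionMatrix, SampleTable


@dataclass
class FlagPolicy:
    """Detection-call filter policy.

    ``min_fraction_present``: minimum fraction of samples flagged present
    or marginal.  ``scope='any_group'`` requires the fraction within at
    least one diagnostic group (the common vendor default, "100% of
    samples in any one condition"); ``scope='all_samples'`` pools everyone.
    """

    min_fraction_present: float = 1.0
    scope: str = "any_group"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction_present <= 1.0:
            raise ValueError("min_fraction_present must be in [0, 1]")
        if self.scope not in ("any_group", "all_samples"):
            raise ValueError("scope must be 'any_group' or 'all_samples'")


@dataclass
class PreprocessConfig:
    raw_floor: float = 1.0
    shift_percentile: float = 75.0
    filter_percentile: float = 20.0
    flag_policy: FlagPolicy = field(default_factory=FlagPolicy)

    def __post_init__(self) -> None:
        for q in (self.shift_percentile,):
            if not 0.0 < q < 100.0:
                raise ValueError("shift percentile must be in (0, 100)")
        if not 0.0 <= self.filter_percentile < 100.0:
            raise ValueError("filter percentile must be in [0, 100)")


@dataclass
class FilterReport:
    """Per-step probe accounting plus the filter conventions in force."""

    steps: pd.DataFrame  # columns: step, probes_in, probes_out
    notes: list = field(default_factory=list)

    @property
    def n_final(self) -> int:
        return int(self.steps["probes_out"].iloc[-1])


def threshold_and_log(matrix: ExpressionMatrix, raw_floor: float = 1.0) -> ExpressionMatrix:
    """Floor raw intensities at ``raw_floor`` and log2-transform.

    With the default floor of 1.0 the output minimum is exactly 0.
    Negative intensities indicate a corrupt input and raise.
    """
    if matrix.stage != "raw":
        raise ValueError(f"expected stage 'raw', got {matrix.stage!r}")
    arr = matrix.values.to_numpy()
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative raw intensity at probe {matrix.probe_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}"
        )
    logged = np.log2(np.maximum(arr, raw_floor))
    values = pd.DataFrame(logged, index=matrix.probe_ids, columns=matrix.sample_ids)
    return matrix.with_values(values, "log2")


def percentile_shift(matrix: ExpressionMatrix, q: float = 75.0) -> ExpressionMatrix:
    """Subtract each sample's q-th percentile (linear interpolation).

    Afterwards the q-th percentile of every column is 0 to numerical
    tolerance.  Constant columns become all-zero.
    """
    if matrix.stage != "log2":
        raise ValueError(f"expected stage 'log2', got {matrix.stage!r}")
    if not 0.0 < q < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    arr = matrix.values.to_numpy()
    col_q = np.percentile(arr, q, axis=0, method="linear")
    values = pd.DataFrame(arr - col_q, index=matrix.probe_ids, columns=matrix.sample_ids)
    return matrix.with_values(values, "shifted")


def baseline_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each probe's median across all samples (row median -> 0).

    This per-probe centering does not change any between-group mean
    difference, so fold changes are unaffected.
    """
    if matrix.stage != "shifted":
        raise ValueError(f"expected stage 'shifted', got {matrix.stage!r}")
    arr = matrix.values.to_numpy()
    row_med = np.median(arr, axis=1, keepdims=True)
    values = pd.DataFrame(arr - row_med, index=matrix.probe_ids, columns=matrix.sample_ids)
    return matrix.with_values(values, "baselined")


def filter_low_expression(matrix: ExpressionMatrix, pct: float = 20.0
                          ) -> tuple[list, pd.DataFrame]:
    """Keep probes whose per-probe summary exceeds the pct-th percentile.

    The summary is the probe's median across samples; the cut is the
    pct-th percentile (linear interpolation) of all probes' summaries,
    and the comparison is strict.  ``pct=0`` keeps every probe.  Returns
    the kept probe ids (input order) and a one-row report.
    """
    if not 0.0 <= pct < 100.0:
        raise ValueError("filter percentile must be in [0, 100)")
    summaries = np.median(matrix.values.to_numpy(), axis=1)
    if pct == 0.0:
        kept_mask = np.ones(matrix.n_probes, dtype=bool)
    else:
        cut = np.percentile(summaries, pct, method="linear")
        kept_mask = summaries > cut
    kept = matrix.probe_ids[kept_mask].tolist()
    report = pd.DataFrame(
        {"step": ["expression_filter"], "probes_in": [matrix.n_probes],
         "probes_out": [len(kept)]}
    )
    return kept, report


def filter_flags(flags: pd.DataFrame, samples: SampleTable,
                 policy: Optional[FlagPolicy] = None) -> tuple[list, pd.DataFrame]:
    """Keep probes reliably detected under the flag policy.

    A sample counts as detected when its call is present (P) or marginal
    (M).  A probe is kept when the detected fraction reaches
    ``min_fraction_present`` within at least one diagnostic group
    (``any_group``) or over all samples (``all_samples``).
    """
    policy = policy or FlagPolicy()
    chars = set(np.unique(flags.to_numpy().astype(str)))
    unknown = chars - FLAG_CHARS
    if unknown:
        raise ValueError(f"unknown flag characters: {sorted(unknown)}")
    detected = flags.isin(["P", "M"]).to_numpy()
    if policy.scope == "all_samples":
        frac = detected.mean(axis=1)
        kept_mask = frac >= policy.min_fraction_present
    else:
        cols = flags.columns
        case_mask = samples.group_mask(cols)
        frac_case = detected[:, case_mask].mean(axis=1)
        frac_ctrl = detected[:, ~case_mask].mean(axis=1)
        kept_mask = (frac_case >= policy.min_fraction_present) | (
            frac_ctrl >= policy.min_fraction_present
        )
    kept = flags.index[kept_mask].tolist()
    report = pd.DataFrame(
        {"step": ["flag_filter"], "probes_in": [flags.shape[0]],
         "probes_out": [len(kept)]}
    )
    return kept, report


def preprocess_pipeline(raw: ExpressionMatrix, samples: SampleTable,
                        config: Optional[PreprocessConfig] = None
                        ) -> tuple[ExpressionMatrix, FilterReport]:
    """Run the full chain: floor+log2 -> shift -> baseline -> filters.

    The expression filter is evaluated on the shifted (normalized,
    pre-baseline) values; surviving probes are then taken from the
    baselined matrix, so filtering never alters surviving values.
    Returns the filtered, baselined matrix plus a per-step report.
    """
    config = config or PreprocessConfig()
    if set(samples.sample_ids) != set(raw.sample_ids):
        raise ValueError("sample table ids do not match matrix columns")
    rows = [("input", raw.n_probes, raw.n_probes)]

    logged = threshold_and_log(raw, config.raw_floor)
    rows.append(("threshold_log2", logged.n_probes, logged.n_probes))
    shifted = percentile_shift(logged, config.shift_percentile)
    rows.append(("percentile_shift", shifted.n_probes, shifted.n_probes))
    baselined = baseline_transform(shifted)
    rows.append(("baseline_transform", baselined.n_probes, baselined.n_probes))

    kept_expr, _ = filter_low_expression(shifted, config.filter_percentile)
    rows.append(("expression_filter", baselined.n_probes, len(kept_expr)))
    current = baselined.subset_probes(kept_expr)

    notes = [
        "percentile convention: linear interpolation between order statistics",
        "expression filter summary: per-probe median of shifted (normalized) values",
    ]
    if current.flags is not None:
        kept_flag, _ = filter_flags(current.flags, samples, config.flag_policy)
        rows.append(("flag_filter", current.n_probes, len(kept_flag)))
        current = current.subset_probes(kept_flag)
        notes.append(
            f"flag policy: fraction present/marginal >= "
            f"{config.flag_policy.min_fraction_present} in scope "
            f"{config.flag_policy.scope}"
        )
    else:
        notes.append("flag filter skipped: no flags supplied")

    steps = pd.DataFrame(rows, columns=["step", "probes_in", "probes_out"])
    return current, FilterReport(steps=steps, notes=notes)
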
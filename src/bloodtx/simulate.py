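"""Synthetic single-color microarray datasets with planted ground truth.

The generator emulates the statistical structure of a matched
case-control blood expression study on an Agilent-style one-color
platform: log-normal raw intensities, a fraction of low-expression
probes flagged absent, a planted set of differentially expressed probes
with |fold change| >= 1.5, and a candidate-gene module whose pairwise
co-expression is driven by a per-sample latent factor with high loading
in controls and low loading in cases (the disruption mechanism).

On the log2 scale the signal for probe g in sample s is

    baseline_g + de_effect_g * [s is case] + loading_{group(s)} * f_s + eps

with f_s ~ N(0, 1) shared by all module probes of a sample and
eps ~ N(0, noise_sd).  Raw intensity is 2 ** signal.  Low-expression
probes sit near the raw floor and carry absent flags so both the
expression filter and the flag filter have genuine work to do.

Every output (matrix + flags, sample table, annotation, candidate list,
truth record) is bit-identical across runs with the same seed, and the
truth record is sufficient to score recovery of every planted feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, ProbeAnnotation, SampleTable


@dataclass
class SynthConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror a 14-pair matched design measured on a large probe
    set (5,000 probes keeps routine runs quick; 44,000 approximates a
    full array), with 20% low-expression probes, 100 planted DE probes
    with log2 effect sizes uniform in [0.7, 1.5] (|FC| 1.62-2.83,
    random sign), and a 20-probe candidate module whose latent-factor
    loading drops from 0.9 in controls to 0.1 in cases.
    """

    n_pairs: int = 14
    n_probes: int = 5000
    frac_low_expression: float = 0.2
    n_de: int = 100
    de_log2fc_lo: float = 0.7
    de_log2fc_hi: float = 1.5
    module_size: int = 20
    loading_control: float = 0.9
    loading_case: float = 0.1
    noise_sd_log2: float = 0.5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    candidate_list_size: int = 169
    frac_unannotated: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_low_expression <= 1.0:
            raise ValueError("frac_low_expression must be in [0, 1]")
        if not (0.0 <= self.loading_case <= 1.0 and 0.0 <= self.loading_control <= 1.0):
            raise ValueError("loadings must be in [0, 1]")
        if self.n_de + self.module_size > self.n_probes:
            raise ValueError("n_de + module_size exceeds n_probes")
        if self.module_size > self.candidate_list_size:
            raise ValueError("module must fit inside the candidate list")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")


@dataclass
class SyntheticTruth:
    """Planted structure: what a perfect analysis should recover."""

    de_probes: pd.Series        # probe_id -> true log2 FC (case - control)
    module_probes: list
    loading_case: float
    loading_control: float
    low_expression_probes: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, lfc in self.de_probes.items():
            rows.append((p, "de", lfc))
        for p in self.module_probes:
            rows.append((p, "module", np.nan))
        for p in self.low_expression_probes:
            rows.append((p, "low_expression", np.nan))
        df = pd.DataFrame(rows, columns=["probe_id", "role", "true_log2fc"])
        df.attrs["loading_case"] = self.loading_case
        df.attrs["loading_control"] = self.loading_control
        return df


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix          # stage=raw, flags attached
    samples: SampleTable
    annotation: ProbeAnnotation
    candidates: GeneSet
    truth: SyntheticTruth
    config: SynthConfig


def _sample_table(cfg: SynthConfig, rng: np.random.Generator) -> SampleTable:
    rows = []
    for i in range(1, cfg.n_pairs + 1):
        pair = f"pair{i:02d}"
        sex = "F" if i % 2 else "M"
        age = int(rng.integers(25, 58))
        age_ctrl = int(np.clip(age + rng.integers(-3, 4), 20, 70))
        rows.append((f"case{i:02d}", "case", pair, age, sex))
        rows.append((f"ctrl{i:02d}", "control", pair, age_ctrl, sex))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "pair_id", "age", "sex"])
    return SampleTable(df.set_index("sample_id"))


def generate_dataset(config: Optional[SynthConfig] = None) -> SyntheticDataset:
    """Generate one raw-intensity dataset with planted ground truth.

    Probe roles are disjoint: the first ``module_size`` probes carry the
    candidate co-expression module, the next ``n_de`` carry the planted
    group effects, and the low-expression probes are drawn from the
    remaining background.  Module and DE probes always carry gene
    symbols (the module genes head the candidate list); a small fraction
    of background probes is left unannotated, as on real arrays.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    samples = _sample_table(cfg, rng)
    n_samples = 2 * cfg.n_pairs
    probe_ids = [f"A_01_P{i:06d}" for i in range(1, cfg.n_probes + 1)]

    module_idx = np.arange(cfg.module_size)
    de_idx = np.arange(cfg.module_size, cfg.module_size + cfg.n_de)
    background = np.arange(cfg.module_size + cfg.n_de, cfg.n_probes)
    n_low = int(round(cfg.frac_low_expression * cfg.n_probes))
    n_low = min(n_low, background.size)
    low_idx = rng.choice(background, size=n_low, replace=False)
    low_mask = np.zeros(cfg.n_probes, dtype=bool)
    low_mask[low_idx] = True

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_probes)
    # low-expression probes sit just above the raw floor (log2 ~ 0.5)
    baseline[low_mask] = rng.normal(0.5, 0.3, n_low)

    de_sign = rng.choice([-1.0, 1.0], size=cfg.n_de)
    de_mag = rng.uniform(cfg.de_log2fc_lo, cfg.de_log2fc_hi, cfg.n_de)
    de_effect = np.zeros(cfg.n_probes)
    de_effect[de_idx] = de_sign * de_mag

    case_mask = samples.group_mask(samples.sample_ids)
    factor = rng.normal(0.0, 1.0, n_samples)
    loading = np.where(case_mask, cfg.loading_case, cfg.loading_control)

    signal = baseline[:, None] + np.zeros((cfg.n_probes, n_samples))
    signal += de_effect[:, None] * case_mask[None, :]
    signal[module_idx[:, None], np.arange(n_samples)[None, :]] += (
        loading[None, :] * factor[None, :]
    )
    signal += rng.normal(0.0, cfg.noise_sd_log2, size=signal.shape)

    raw = np.exp2(signal)
    probe_index = pd.Index(probe_ids, name="probe_id")
    values = pd.DataFrame(raw, index=probe_index,
                          columns=list(samples.sample_ids))

    flags = np.full(signal.shape, "P", dtype="<U1")
    marginal = rng.random(signal.shape) < 0.02
    flags[marginal] = "M"
    flags[low_mask, :] = "A"
    flags_df = pd.DataFrame(flags, index=probe_index,
                            columns=list(samples.sample_ids))

    annotation, candidates = _annotate(cfg, probe_ids, module_idx, de_idx,
                                       low_mask, rng)

    truth = SyntheticTruth(
        de_probes=pd.Series(de_effect[de_idx],
                            index=[probe_ids[i] for i in de_idx]),
        module_probes=[probe_ids[i] for i in module_idx],
        loading_case=cfg.loading_case,
        loading_control=cfg.loading_control,
        low_expression_probes=[probe_ids[i] for i in sorted(low_idx)],
    )
    matrix = ExpressionMatrix(values, stage="raw", flags=flags_df)
    return SyntheticDataset(matrix, samples, annotation, candidates, truth, cfg)


def _annotate(cfg: SynthConfig, probe_ids: list, module_idx: np.ndarray,
              de_idx: np.ndarray, low_mask: np.ndarray,
              rng: np.random.Generator) -> tuple[ProbeAnnotation, GeneSet]:
    """Gene symbols per probe; candidate list = module genes + extras.

    Non-module candidate genes are spread over well-expressed *null*
    background probes (never the planted DE probes, so candidate status
    and differential expression stay independent outside the module);
    every fifth extra gene gets a second probe, giving the multi-probe
    genes that exercise same-gene edge suppression and gene collapsing.
    """
    n = cfg.n_probes
    symbols = np.array([f"GENE{i + 1:05d}" for i in range(n)], dtype=object)
    unannotated = rng.random(n) < cfg.frac_unannotated
    module_set = set(module_idx.tolist())
    de_set = set(de_idx.tolist())

    cand_names = [f"CAND{i + 1:04d}" for i in range(cfg.candidate_list_size)]
    for rank, idx in enumerate(module_idx):
        symbols[idx] = cand_names[rank]
        unannotated[idx] = False

    eligible = [
        i for i in range(n)
        if i not in module_set and i not in de_set
        and not low_mask[i] and not unannotated[i]
    ]
    extra = cand_names[cfg.module_size:]
    pos = 0
    for j, name in enumerate(extra):
        take = 2 if j % 5 == 0 else 1
        for _ in range(take):
            if pos >= len(eligible):
                break
            symbols[eligible[pos]] = name
            pos += 1

    table = pd.DataFrame(
        {
            "gene_symbol": np.where(unannotated, pd.NA, symbols),
            "entrez_id": [str(100000 + i) for i in range(n)],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    annotation = ProbeAnnotation(table)
    candidates = GeneSet("candidates",
                         "synthetic evidence-based candidate gene list",
                         frozenset(cand_names))
    return annotation, candidates


def null_dataset(config: Optional[SynthConfig] = None) -> SyntheticDataset:
    """Dataset with no group structure: n_de = 0 and equal loadings.

    The module still co-expresses, identically in both groups, and the
    low-expression/flag structure is retained, so calibration tests see
    realistic correlation without any case-control signal.
    """
    cfg = config or SynthConfig()
    cfg = replace(cfg, n_de=0, loading_case=cfg.loading_control)
    return generate_dataset(cfg)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write every component in the pipeline's on-disk formats.

    Returns a path map (matrix, flags, samples, annotation, candidates,
    truth).  Files written here round-trip through the package readers.
    """
    from . import io as btio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "raw_matrix.tsv",
        "flags": outdir / "flags.tsv",
        "samples": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "candidates": outdir / "candidates.txt",
        "truth": outdir / "truth.tsv",
    }
    ds.matrix.values.to_csv(paths["matrix"], sep="\t", index_label="probe_id")
    ds.matrix.flags.to_csv(paths["flags"], sep="\t", index_label="probe_id")
    ds.samples.table.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    ds.annotation.table.to_csv(paths["annotation"], sep="\t", index_label="probe_id")
    paths["candidates"].write_text(
        "\n".join(sorted(ds.candidates.members)) + "\n"
    )
    ds.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
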
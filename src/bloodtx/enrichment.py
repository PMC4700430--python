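"""Candidate-gene mapping and over-representation statistics.

The candidate-gene analysis asks whether an evidence-prioritized gene
list is enriched for expression changes.  The core statistic is a 2x2
Pearson chi-square (no continuity correction) on exceedance counts:
candidate probes exceeding a fold-change cutoff vs all probes doing so.
Two table constructions are offered: ``printed`` keeps candidates inside
the totals column (matching how such ratio comparisons are commonly
printed, e.g. 19/164 vs 1,941/26,498), while ``disjoint`` removes the
candidates from the comparison column for a statistically clean
partition; on realistic counts the two agree closely.  A generic
hypergeometric over-representation test against GMT gene-set
collections (with Benjamini-Hochberg adjustment) stands in for external
pathway services.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSet, ProbeAnnotation


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b | c, d): rows gene classes, columns exceed / not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class CandidateMapReport:
    genes_requested: int
    genes_matched: int
    probes_matched: int
    note: str = "symbols matched case-insensitively after whitespace strip"


def map_candidates(annotation: ProbeAnnotation, candidates: GeneSet,
                   matrix: ExpressionMatrix) -> tuple[list, CandidateMapReport]:
    """Probes of candidate genes that survived filtering.

    Matching is by gene symbol, case-insensitive after stripping
    whitespace.  Returns the candidate probe ids present in ``matrix``
    (matrix order) and a report of genes requested / matched and probes
    matched.  Zero matches raise with a hint to check symbol case.
    """
    wanted = {str(s).strip().upper() for s in candidates.members}
    sym = annotation.symbols(matrix.probe_ids).astype("string").str.strip().str.upper()
    mask = sym.isin(wanted).to_numpy()
    probe_ids = matrix.probe_ids[mask].tolist()
    if not probe_ids:
        raise ValueError(
            "no candidate genes matched any surviving probe; check that the "
            "gene-list symbols use the same nomenclature as the annotation"
        )
    matched_genes = set(sym[mask].dropna())
    report = CandidateMapReport(
        genes_requested=len(candidates),
        genes_matched=len(matched_genes),
        probes_matched=len(probe_ids),
    )
    return probe_ids, report


def exceedance_table(det: pd.DataFrame, candidate_ids: Sequence[str],
                     fc_min: float = 1.5, mode: str = "printed"
                     ) -> ContingencyTable2x2:
    """2x2 exceedance table: candidates vs totals at a fold-change cutoff.

    a = candidate probes with |signed FC| > fc_min (strict), b = the
    rest of the candidates; in ``printed`` mode c/d count *all* tested
    probes (candidates included, as such ratios are usually printed),
    in ``disjoint`` mode only non-candidate probes.
    """
    if mode not in ("printed", "disjoint"):
        raise ValueError("mode must be 'printed' or 'disjoint'")
    missing = [p for p in candidate_ids if p not in det.index]
    if missing:
        raise ValueError(f"candidate probes not in DE table: {missing[:5]}")
    exceeds = det["signed_fc"].abs() > fc_min
    cand_mask = det.index.isin(candidate_ids)
    a = int((exceeds & cand_mask).sum())
    b = int((~exceeds & cand_mask).sum())
    if mode == "printed":
        c = int(exceeds.sum())
        d = int((~exceeds).sum())
    else:
        c = int((exceeds & ~cand_mask).sum())
        d = int((~exceeds & ~cand_mask).sum())
    return ContingencyTable2x2(a, b, c, d)


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False
                   ) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 table, df = 1.

    No continuity correction by default; set ``yates=True`` to apply
    one.  Raises on a zero margin (expected count of zero).
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=yates)
    assert dof == 1
    return float(chi2), float(p)


def enrichment_ratio(k1: float, n1: float, k2: float, n2: float) -> float:
    """Ratio of proportions (k1/n1) / (k2/n2)."""
    if min(k1, n1, k2, n2) <= 0:
        raise ValueError("all counts must be positive")
    return (k1 / n1) / (k2 / n2)


def gene_set_ora(query: Iterable[str], background: Iterable[str],
                 gene_sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Only the in-background portion of each set counts.  The upper-tail
    p is P[X >= overlap] for X hypergeometric(M=|background|,
    K=|set ∩ background|, N=|query|); adjustment across sets is
    Benjamini-Hochberg.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    rows = []
    for gs in gene_sets:
        in_bg = gs.members & background
        overlap = len(in_bg & query)
        if in_bg:
            p = float(stats.hypergeom.sf(overlap - 1, len(background),
                                         len(in_bg), len(query)))
        else:
            p = 1.0
        rows.append((gs.name, len(gs), len(in_bg), overlap, p))
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "in_background", "overlap", "p"]
    ).set_index("set")
    from statsmodels.stats.multitest import multipletests

    out["p_adjusted"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p")
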
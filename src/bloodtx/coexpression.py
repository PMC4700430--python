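"""Group-wise Spearman co-expression networks over candidate probes.

All C(m, 2) probe pairs are correlated within each diagnostic group
using Spearman's rank correlation (mid-ranks for ties); significance
uses the t approximation t = rho * sqrt((n-2) / (1-rho^2)) with df =
n - 2.  Edges passing a significance threshold form a per-group network
(optionally suppressing edges between two probes of the same gene, and
optionally collapsing multi-probe genes to single nodes); hub nodes are
those reaching a minimum degree.  Comparing the case and control
networks — counts of significant pairs at several thresholds, common
and group-specific edges — quantifies co-expression disruption.  A
Shapiro-Wilk normality screen documents why the rank correlation is
preferred over Pearson for these data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, ProbeAnnotation, SampleTable

#: p-value sentinel for |rho| = 1 (perfect monotone association).
P_PERFECT = 1e-300


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Returns NaN with a warning when either vector is constant (zero
    rank variance makes the coefficient undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("constant vector: Spearman rho undefined", UserWarning,
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_p(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho via the Student-t approximation.

    t = rho * sqrt((n-2)/(1-rho^2)), df = n - 2.  |rho| = 1 returns the
    sentinel :data:`P_PERFECT`; rho = NaN propagates.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if np.isnan(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return P_PERFECT
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(max(2.0 * stats.t.sf(abs(t), df=n - 2), P_PERFECT))


def rho_threshold(p_target: float, n: int, tol: float = 1e-6) -> float:
    """Smallest rho >= 0 whose two-sided t-approximation p is <= p_target.

    Found by bisection on [0, 1) to ``tol``.  Raises when even rho just
    below 1 cannot reach the target.
    """
    if not 0.0 < p_target < 1.0:
        raise ValueError("p_target must be in (0, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    hi = 1.0 - 1e-12
    if spearman_p(hi, n) > p_target:
        raise ValueError(f"p_target={p_target} unreachable at n={n}")
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spearman_p(mid, n) <= p_target:
            hi = mid
        else:
            lo = mid
    return hi


def pair_correlations(matrix: ExpressionMatrix, probes: Sequence[str],
                      samples: SampleTable, group: str) -> pd.DataFrame:
    """All C(m, 2) Spearman edges among ``probes`` within one group.

    Probes are ordered by id so that probe_i < probe_j in every edge.
    Constant probes yield missing rho/p; the count of affected edges is
    recorded in ``DataFrame.attrs['n_missing']``.
    """
    if group not in ("case", "control"):
        raise ValueError("group must be 'case' or 'control'")
    sample_ids = samples.case_ids if group == "case" else samples.control_ids
    if len(sample_ids) < 4:
        raise ValueError("need >= 4 samples in the group")
    probes = sorted(probes)
    sub = matrix.subset_probes(probes).values[sample_ids].to_numpy()
    n = sub.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, sub)
    sd = ranks.std(axis=1)
    constant = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_mat = np.corrcoef(ranks)
    rho_mat[constant, :] = np.nan
    rho_mat[:, constant] = np.nan
    iu, ju = np.triu_indices(len(probes), k=1)
    rho = np.clip(rho_mat[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, P_PERFECT, p)
    p = np.clip(p, P_PERFECT, 1.0)
    out = pd.DataFrame(
        {
            "probe_i": np.asarray(probes)[iu],
            "probe_j": np.asarray(probes)[ju],
            "rho": rho,
            "p": np.where(np.isnan(rho), np.nan, p),
            "group": group,
        }
    )
    out.attrs["n_missing"] = int(out["rho"].isna().sum())
    out.attrs["n_samples"] = n
    return out


def count_significant(edges: pd.DataFrame, alpha: float) -> int:
    """Number of edges with p < alpha (strict); missing edges excluded."""
    return int((edges["p"] < alpha).sum())


def build_network(edges: pd.DataFrame, p_threshold: float,
                  annotation: Optional[ProbeAnnotation] = None,
                  suppress_same_gene: bool = True,
                  collapse_genes: bool = False) -> nx.Graph:
    """Threshold edges into a co-expression graph.

    Retains edges with p < p_threshold; when ``suppress_same_gene`` is
    on, edges whose two probes map to the same gene symbol are dropped
    (they reflect probe redundancy, not co-regulation).  With
    ``collapse_genes`` nodes become gene symbols (probes without a
    symbol keep their probe id) and multi-probe genes merge, keeping
    the union of their edges.  Nodes are only the endpoints of retained
    edges; the empty graph is a valid result.
    """
    if (suppress_same_gene or collapse_genes) and annotation is None:
        raise ValueError("annotation required for same-gene handling")
    sig = edges[edges["p"] < p_threshold]
    G = nx.Graph()
    G.graph["p_threshold"] = p_threshold
    if "group" in edges.columns and len(edges):
        G.graph["group"] = str(edges["group"].iloc[0])
    for _, row in sig.iterrows():
        ni, nj = row["probe_i"], row["probe_j"]
        if annotation is not None:
            gi = annotation.symbol_of(ni)
            gj = annotation.symbol_of(nj)
            if suppress_same_gene and gi is not None and gi == gj:
                continue
            if collapse_genes:
                ni = gi or ni
                nj = gj or nj
                if ni == nj:
                    continue
        if G.has_edge(ni, nj):
            if abs(row["rho"]) > abs(G.edges[ni, nj]["rho"]):
                G.edges[ni, nj].update(rho=float(row["rho"]), p=float(row["p"]))
        else:
            G.add_edge(ni, nj, rho=float(row["rho"]), p=float(row["p"]))
    return G


def hubs(graph: nx.Graph, min_degree: int = 6) -> list:
    """Nodes with degree >= min_degree, by degree descending then name."""
    deg = dict(graph.degree())
    out = [n for n, d in deg.items() if d >= min_degree]
    return sorted(out, key=lambda n: (-deg[n], str(n)))


@dataclass
class NetworkComparison:
    """Case vs control co-expression summary."""

    counts: pd.DataFrame          # index threshold, columns case/control
    common_edges: set
    case_specific: set
    control_specific: set
    case_graph: nx.Graph
    control_graph: nx.Graph
    case_hubs: list = field(default_factory=list)
    control_hubs: list = field(default_factory=list)


def compare_networks(case_edges: pd.DataFrame, control_edges: pd.DataFrame,
                     thresholds: Sequence[float] = (0.01, 0.001, 1e-8),
                     network_p: float = 1e-8,
                     annotation: Optional[ProbeAnnotation] = None,
                     suppress_same_gene: bool = True,
                     hub_min_degree: int = 6) -> NetworkComparison:
    """Per-threshold significant-pair counts and edge-set comparison.

    Edge sets are keyed by (probe_i, probe_j); graphs and hubs are
    built at ``network_p`` (the strictest display threshold).  Raises
    when the two edge tables cover different probe universes.
    """
    key = lambda df: set(zip(df["probe_i"], df["probe_j"]))
    if key(case_edges) != key(control_edges):
        raise ValueError("case and control edge tables cover different pairs")
    counts = pd.DataFrame(
        {
            "case": [count_significant(case_edges, a) for a in thresholds],
            "control": [count_significant(control_edges, a) for a in thresholds],
        },
        index=pd.Index(thresholds, name="p_threshold"),
    )
    sup = suppress_same_gene and annotation is not None
    g_case = build_network(case_edges, network_p, annotation, sup)
    g_ctrl = build_network(control_edges, network_p, annotation, sup)
    e_case = {tuple(sorted(e)) for e in g_case.edges}
    e_ctrl = {tuple(sorted(e)) for e in g_ctrl.edges}
    return NetworkComparison(
        counts=counts,
        common_edges=e_case & e_ctrl,
        case_specific=e_case - e_ctrl,
        control_specific=e_ctrl - e_case,
        case_graph=g_case,
        control_graph=g_ctrl,
        case_hubs=hubs(g_case, hub_min_degree),
        control_hubs=hubs(g_ctrl, hub_min_degree),
    )


def normality_screen(matrix: ExpressionMatrix, probes: Sequence[str],
                     samples: SampleTable, alpha: float = 0.05
                     ) -> tuple[int, pd.DataFrame]:
    """Shapiro-Wilk screen justifying the rank correlation.

    Tests each probe within each diagnostic group; a probe counts as
    non-normal when p < alpha in at least one group.  Constant probes
    are flagged degenerate and excluded from the count.  Returns
    (count, per-probe table with p_case, p_control, non_normal,
    degenerate).
    """
    case_ids, ctrl_ids = samples.case_ids, samples.control_ids
    for ids in (case_ids, ctrl_ids):
        if not 3 <= len(ids) <= 5000:
            raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000 per group")
    sub = matrix.subset_probes(sorted(probes))
    rows = []
    for probe in sub.probe_ids:
        vals = sub.values.loc[probe]
        pcs = []
        degenerate = False
        for ids in (case_ids, ctrl_ids):
            v = vals[ids].to_numpy()
            if np.ptp(v) == 0:
                degenerate = True
                pcs.append(np.nan)
            else:
                pcs.append(float(stats.shapiro(v).pvalue))
        non_normal = (not degenerate) and any(p < alpha for p in pcs)
        rows.append((probe, pcs[0], pcs[1], non_normal, degenerate))
    table = pd.DataFrame(
        rows, columns=["probe_id", "p_case", "p_control", "non_normal", "degenerate"]
    ).set_index("probe_id")
    return int(table["non_normal"].sum()), table
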
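"""End-to-end orchestration of the analysis stages.

A :class:`PipelineConfig` (usually loaded from a YAML file) names the
input files, the stage parameters and the output directory.  Stages run
in a fixed order — preprocess, differential expression, overabundance,
separation, candidate enrichment, co-expression — each writing its
results as provenance-stamped TSV (plus GraphML for networks and Newick
for dendrograms) under the run directory, and :func:`report` renders a
Markdown summary from whatever outputs are present.  All randomness
flows from the single configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__, io as btio
from .coexpression import (compare_networks, count_significant,
                           normality_screen, pair_correlations, rho_threshold)
from .datatypes import ExpressionMatrix, SampleTable
from .diffexpr import de_table, select_degs, top_table
from .enrichment import (chi_square_2x2, enrichment_ratio, exceedance_table,
                         gene_set_ora, map_candidates)
from .overabundance import overabundance_analysis
from .preprocess import FlagPolicy, PreprocessConfig, preprocess_pipeline
from .separation import separation_report
from .simulate import SynthConfig, generate_dataset, write_dataset

log = logging.getLogger("bloodtx")

STAGE_ORDER = ("preprocess", "de", "overabundance", "enrich",
               "separation", "coexpress")


@dataclass
class PipelineConfig:
    paths: dict
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    p_max: float = 0.01
    fc_min: float = 1.5
    paired: bool = False
    top_k: int = 20
    permutations: int = 0
    paired_permutation: bool = True
    alpha_list: tuple = (0.01, 0.001, 1e-8)
    network_p: float = 1e-8
    suppress_same_gene: bool = True
    hub_min_degree: int = 6
    enrichment_mode: str = "printed"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pp = raw.get("preprocess", {})
        policy = FlagPolicy(
            min_fraction_present=pp.get("flag_min_fraction", 1.0),
            scope=pp.get("flag_scope", "any_group"),
        )
        return cls(
            paths=raw.get("paths", {}),
            preprocess=PreprocessConfig(
                raw_floor=pp.get("raw_floor", 1.0),
                shift_percentile=pp.get("shift_percentile", 75.0),
                filter_percentile=pp.get("filter_percentile", 20.0),
                flag_policy=policy,
            ),
            p_max=raw.get("de", {}).get("p_max", 0.01),
            fc_min=raw.get("de", {}).get("fc_min", 1.5),
            paired=raw.get("de", {}).get("paired", False),
            top_k=raw.get("de", {}).get("top_k", 20),
            permutations=raw.get("overabundance", {}).get("permutations", 0),
            paired_permutation=raw.get("overabundance", {}).get(
                "paired_permutation", True),
            alpha_list=tuple(raw.get("coexpression", {}).get(
                "alpha_list", (0.01, 0.001, 1e-8))),
            network_p=raw.get("coexpression", {}).get("network_p", 1e-8),
            suppress_same_gene=raw.get("coexpression", {}).get(
                "suppress_same_gene", True),
            hub_min_degree=raw.get("coexpression", {}).get("hub_min_degree", 6),
            enrichment_mode=raw.get("enrichment", {}).get("mode", "printed"),
            seed=raw.get("seed", 0),
        )

    def hash(self) -> str:
        payload = {
            "p_max": self.p_max, "fc_min": self.fc_min, "paired": self.paired,
            "permutations": self.permutations, "alpha_list": list(self.alpha_list),
            "network_p": self.network_p, "seed": self.seed,
            "shift_percentile": self.preprocess.shift_percentile,
            "filter_percentile": self.preprocess.filter_percentile,
        }
        return btio.config_hash(payload)


class PipelineRun:
    """Stateful runner: executes stages, caching and persisting outputs.

    Stage methods read prerequisites from the in-memory cache when this
    process produced them, else from the run directory, so individual
    stages can be re-run from a completed directory.
    """

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.outdir = Path(config.paths.get("outdir", "bloodtx_run"))
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._hash = config.hash()
        self._cache: dict = {}
        log.info("bloodtx %s run in %s (config %s, seed %d)",
                 __version__, self.outdir, self._hash, config.seed)

    # -- input loading -------------------------------------------------
    def _samples(self) -> SampleTable:
        if "samples" not in self._cache:
            self._cache["samples"] = btio.read_sample_table(self.cfg.paths["samples"])
        return self._cache["samples"]

    def _annotation(self):
        if "annotation" not in self._cache:
            path = self.cfg.paths.get("annotation")
            self._cache["annotation"] = (
                btio.read_probe_annotation(path) if path else None
            )
        return self._cache["annotation"]

    def _filtered(self) -> ExpressionMatrix:
        if "filtered" not in self._cache:
            path = self.outdir / "filtered_matrix.tsv"
            if not path.exists():
                raise RuntimeError("preprocess stage has not been run")
            values = btio.read_table(path)
            self._cache["filtered"] = ExpressionMatrix(values, stage="baselined")
        return self._cache["filtered"]

    def _det(self) -> pd.DataFrame:
        if "det" not in self._cache:
            path = self.outdir / "de_table.tsv"
            if not path.exists():
                raise RuntimeError("de stage has not been run")
            self._cache["det"] = btio.read_table(path)
        return self._cache["det"]

    def _deg_ids(self) -> list:
        path = self.outdir / "degs.txt"
        if not path.exists():
            raise RuntimeError("de stage has not been run")
        return [ln for ln in path.read_text().splitlines()
                if ln and not ln.startswith("#")]

    def _candidate_ids(self) -> list:
        path = self.outdir / "candidate_probes.txt"
        if not path.exists():
            raise RuntimeError("enrich stage has not been run")
        return [ln for ln in path.read_text().splitlines()
                if ln and not ln.startswith("#")]

    # -- stages --------------------------------------------------------
    def stage_preprocess(self) -> None:
        log.info("stage: preprocess")
        raw = btio.read_expression_matrix(
            self.cfg.paths["matrix"], self.cfg.paths.get("flags")
        )
        filtered, report = preprocess_pipeline(raw, self._samples(),
                                               self.cfg.preprocess)
        self._cache["filtered"] = filtered
        btio.write_table(filtered.values, self.outdir / "filtered_matrix.tsv",
                         index_label="probe_id", config_hash=self._hash)
        btio.write_table(report.steps, self.outdir / "filter_report.tsv",
                         index=False, config_hash=self._hash)
        (self.outdir / "filter_notes.txt").write_text(
            "\n".join(report.notes) + "\n")

    def stage_de(self) -> None:
        log.info("stage: de")
        det = de_table(self._filtered(), self._samples(), paired=self.cfg.paired)
        self._cache["det"] = det
        btio.write_table(det, self.outdir / "de_table.tsv",
                         index_label="probe_id", config_hash=self._hash)
        sel = select_degs(det, self.cfg.p_max, self.cfg.fc_min)
        (self.outdir / "degs.txt").write_text("\n".join(sel.deg_ids) + "\n")
        top = top_table(det, self.cfg.top_k, self._annotation(),
                        symbols_only=self._annotation() is not None)
        btio.write_table(
            top[[c for c in ("gene_symbol", "p", "signed_fc", "log2_fc", "t_mod")
                 if c in top.columns]],
            self.outdir / "top_table.tsv", index_label="probe_id",
            config_hash=self._hash)
        volcano = pd.DataFrame(
            {"log2_fc": det["log2_fc"], "neg_log10_p": -np.log10(det["p"])},
            index=det.index)
        btio.write_table(volcano, self.outdir / "volcano.tsv",
                         index_label="probe_id", config_hash=self._hash)
        summary = {"n_tested": int(len(det)), "n_deg": sel.n_total,
                   "n_up": sel.n_up, "n_down": sel.n_down,
                   "p_max": sel.p_max, "fc_min": sel.fc_min,
                   "prior_d0": float(det.attrs.get("prior_d0", float("nan"))),
                   "prior_s0_sq": float(det.attrs.get("prior_s0_sq", float("nan")))}
        (self.outdir / "de_summary.json").write_text(json.dumps(summary, indent=1))

    def stage_overabundance(self) -> None:
        log.info("stage: overabundance")
        curve = overabundance_analysis(
            self._filtered(), self._samples(),
            n_permutations=self.cfg.permutations, seed=self.cfg.seed,
            paired=self.cfg.paired_permutation)
        btio.write_table(curve, self.outdir / "overabundance.tsv", index=False,
                         config_hash=self._hash)

    def stage_separation(self) -> None:
        log.info("stage: separation")
        matrix = self._filtered()
        samples = self._samples()
        subsets = {"all": None}
        try:
            subsets["degs"] = self._deg_ids()
        except RuntimeError:
            pass
        try:
            subsets["candidates"] = self._candidate_ids()
        except RuntimeError:
            pass
        rows = []
        for name, subset in subsets.items():
            if subset is not None and len(subset) == 0:
                continue
            rep = separation_report(matrix, samples, subset)
            rows.append((name,
                         len(subset) if subset is not None else matrix.n_probes,
                         rep["cluster_accuracy"], rep["linear_accuracy"]))
            btio.write_table(rep["pc_coordinates"],
                             self.outdir / f"pca_{name}.tsv",
                             index_label="sample_id", config_hash=self._hash)
            (self.outdir / f"dendrogram_{name}.nwk").write_text(
                rep["newick"] + "\n")
        btio.write_table(
            pd.DataFrame(rows, columns=["probe_set", "n_probes",
                                        "cluster_accuracy", "linear_accuracy"]),
            self.outdir / "separation.tsv", index=False, config_hash=self._hash)

    def stage_enrich(self) -> None:
        log.info("stage: enrich")
        annotation = self._annotation()
        if annotation is None or "candidates" not in self.cfg.paths:
            log.warning("enrich stage skipped: no annotation or candidate list")
            return
        candidates, _ = btio.read_gene_list(self.cfg.paths["candidates"])
        probe_ids, map_report = map_candidates(annotation, candidates,
                                               self._filtered())
        (self.outdir / "candidate_probes.txt").write_text(
            "\n".join(probe_ids) + "\n")
        det = self._det()
        table = exceedance_table(det, probe_ids, self.cfg.fc_min,
                                 mode=self.cfg.enrichment_mode)
        chi2, p = chi_square_2x2(table)
        if min(table.a, table.c) > 0:
            fold = enrichment_ratio(table.a, table.a + table.b,
                                    table.c, table.c + table.d)
        else:
            fold = float("nan")  # no exceeding probes on one side
        out = pd.DataFrame([{
            "genes_requested": map_report.genes_requested,
            "genes_matched": map_report.genes_matched,
            "probes_matched": map_report.probes_matched,
            "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "mode": self.cfg.enrichment_mode, "fc_min": self.cfg.fc_min,
            "chi2": chi2, "p": p, "enrichment_ratio": fold,
        }])
        btio.write_table(out, self.outdir / "enrichment.tsv", index=False,
                         config_hash=self._hash)
        gmt_path = self.cfg.paths.get("gene_sets")
        if gmt_path:
            degs = set(annotation.symbols(self._deg_ids()).dropna())
            background = set(
                annotation.symbols(self._filtered().probe_ids).dropna())
            ora = gene_set_ora(degs & background, background,
                               btio.read_gmt(gmt_path))
            btio.write_table(ora, self.outdir / "ora.tsv",
                             config_hash=self._hash)

    def stage_coexpress(self) -> None:
        log.info("stage: coexpress")
        matrix = self._filtered()
        samples = self._samples()
        annotation = self._annotation()
        probes = self._candidate_ids()
        edges = {}
        for group in ("case", "control"):
            edges[group] = pair_correlations(matrix, probes, samples, group)
            btio.write_table(edges[group],
                             self.outdir / f"coexpression_edges_{group}.tsv",
                             index=False, config_hash=self._hash)
        comp = compare_networks(
            edges["case"], edges["control"], self.cfg.alpha_list,
            self.cfg.network_p, annotation, self.cfg.suppress_same_gene,
            self.cfg.hub_min_degree)
        btio.write_table(comp.counts, self.outdir / "coexpression_counts.tsv",
                         config_hash=self._hash)
        for group, graph in (("case", comp.case_graph),
                             ("control", comp.control_graph)):
            nx.write_graphml(graph, self.outdir / f"network_{group}.graphml")
        n_nonnormal, screen = normality_screen(matrix, probes, samples)
        btio.write_table(screen, self.outdir / "normality_screen.tsv",
                         config_hash=self._hash)
        summary = {
            "counts": {str(t): {"case": int(r["case"]), "control": int(r["control"])}
                       for t, r in comp.counts.iterrows()},
            "network_p": self.cfg.network_p,
            "nodes": {"case": comp.case_graph.number_of_nodes(),
                      "control": comp.control_graph.number_of_nodes()},
            "edges": {"case": comp.case_graph.number_of_edges(),
                      "control": comp.control_graph.number_of_edges()},
            "common_edges": sorted(map(list, comp.common_edges)),
            "hubs": {"case": comp.case_hubs, "control": comp.control_hubs},
            "n_non_normal_probes": n_nonnormal,
            "rho_threshold_at_network_p": rho_threshold(
                self.cfg.network_p, len(samples.case_ids)),
        }
        (self.outdir / "coexpression_summary.json").write_text(
            json.dumps(summary, indent=1))

    def run(self, stages: Optional[Sequence[str]] = None) -> Path:
        wanted = list(stages) if stages else list(STAGE_ORDER)
        for stage in STAGE_ORDER:
            if stage in wanted:
                getattr(self, f"stage_{stage}")()
        (self.outdir / "report.md").write_text(report(self.outdir))
        return self.outdir


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage in order and write the consolidated report."""
    return PipelineRun(config).run()


def _section(title: str, body: str) -> str:
    return f"## {title}\n\n{body.rstrip()}\n\n"


def report(outdir) -> str:
    """Render a Markdown summary from saved stage outputs.

    Regeneration from the same directory is idempotent; sections whose
    outputs are missing are marked "not run".
    """
    outdir = Path(outdir)
    parts = [f"# bloodtx run report\n\nPackage version {__version__}. "
             f"Run directory: `{outdir}`.\n\n"]

    path = outdir / "filter_report.tsv"
    if path.exists():
        steps = btio.read_table(path, index_col=None)
        body = steps.to_markdown(index=False)
        notes = outdir / "filter_notes.txt"
        if notes.exists():
            body += "\n\nConventions in force:\n" + "\n".join(
                f"- {ln}" for ln in notes.read_text().splitlines() if ln)
        parts.append(_section("Preprocessing", body))
    else:
        parts.append(_section("Preprocessing", "not run"))

    path = outdir / "de_summary.json"
    if path.exists():
        s = json.loads(path.read_text())
        body = (f"{s['n_tested']} probes tested; {s['n_deg']} DEGs at "
                f"p < {s['p_max']} and |FC| > {s['fc_min']} "
                f"({s['n_up']} up, {s['n_down']} down in cases). "
                f"Variance prior: d0 = {s['prior_d0']:.3g}, "
                f"s0^2 = {s['prior_s0_sq']:.3g}.")
        top = outdir / "top_table.tsv"
        if top.exists():
            body += "\n\n" + btio.read_table(top).head(20).to_markdown()
        parts.append(_section("Differential expression", body))
    else:
        parts.append(_section("Differential expression", "not run"))

    path = outdir / "overabundance.tsv"
    if path.exists():
        curve = btio.read_table(path, index_col=None)
        near = curve.iloc[(curve["alpha"] - 0.01).abs().argmin()]
        verdict = ("overabundance detected" if near["ratio"] > 1.5
                   else "no overabundance detected")
        body = (f"At alpha ~ {near['alpha']:.3g}: observed {int(near['observed'])} "
                f"vs expected {near['expected']:.1f} "
                f"(ratio {near['ratio']:.2f}) — **{verdict}**.")
        parts.append(_section("Overabundance", body))
    else:
        parts.append(_section("Overabundance", "not run"))

    path = outdir / "separation.tsv"
    if path.exists():
        parts.append(_section(
            "Sample separation",
            btio.read_table(path, index_col=None).to_markdown(index=False)))
    else:
        parts.append(_section("Sample separation", "not run"))

    path = outdir / "enrichment.tsv"
    if path.exists():
        e = btio.read_table(path, index_col=None).iloc[0]
        body = (f"{e['genes_matched']} candidate genes / {e['probes_matched']} "
                f"probes survived filtering. Exceedance table "
                f"({e['a']}, {e['b']} | {e['c']}, {e['d']}), mode {e['mode']}: "
                f"chi2 = {e['chi2']:.3f}, p = {e['p']:.4f}; enrichment ratio "
                f"{e['enrichment_ratio']:.2f}.")
        parts.append(_section("Candidate-gene enrichment", body))
    else:
        parts.append(_section("Candidate-gene enrichment", "not run"))

    path = outdir / "coexpression_summary.json"
    if path.exists():
        s = json.loads(path.read_text())
        lines = ["Significant pairs per threshold (case / control):"]
        for t, c in s["counts"].items():
            lines.append(f"- p < {t}: {c['case']} / {c['control']}")
        lines.append(
            f"\nNetwork at p < {s['network_p']:g} "
            f"(rho > {s['rho_threshold_at_network_p']:.2f}): "
            f"{s['nodes']['case']} vs {s['nodes']['control']} nodes, "
            f"{s['edges']['case']} vs {s['edges']['control']} edges "
            f"(case vs control); hubs: case {s['hubs']['case'] or '—'}, "
            f"control {s['hubs']['control'] or '—'}.")
        lines.append(
            f"\nShapiro-Wilk: {s['n_non_normal_probes']} probes non-normal "
            f"in at least one group (rank correlation justified).")
        parts.append(_section("Co-expression networks", "\n".join(lines)))
    else:
        parts.append(_section("Co-expression networks", "not run"))

    return "".join(parts)
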
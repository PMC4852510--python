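"""End-to-end orchestration: simulate -> classify -> enrich -> network.

One YAML config, one output directory per run. Every number in the report
is recomputed from the emitted intermediate files by the stage functions;
there is no hidden state, and a fixed seed reproduces the run byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, enrich, io, network, simulate, stats

log = logging.getLogger("tfinet")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of synthetic mode (default) or real-input paths must be
    active. Real inputs use the same plain-text formats the simulator
    writes (probes.tsv + probe_map.tsv, counts.tsv, genes.bed, per-TF
    peak/read BEDs, input BED).
    """

    seed: int = 0
    synthetic: bool = True
    sim: simulate.SimConfig | None = None
    inputs: dict = field(default_factory=dict)  # real-mode file paths
    rules: classify.ClassificationRuleSet = field(
        default_factory=classify.ClassificationRuleSet)
    thresholds: stats.Thresholds = field(default_factory=stats.Thresholds)
    net: network.NetworkParams = field(default_factory=network.NetworkParams)
    kmeans_k: int = 8
    n_tfs: int = 6
    targets_per_tf: int = 12

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        cfg.seed = int(raw.get("seed", 0))
        cfg.synthetic = bool(raw.get("synthetic", not raw.get("inputs")))
        cfg.inputs = dict(raw.get("inputs", {}))
        if "sim" in raw:
            cfg.sim = simulate.SimConfig(**raw["sim"])
        if "rules" in raw:
            cfg.rules = classify.ClassificationRuleSet(**raw["rules"])
        if "thresholds" in raw:
            cfg.thresholds = stats.Thresholds(**raw["thresholds"])
        if "network" in raw:
            cfg.net = network.NetworkParams(**raw["network"])
        cfg.kmeans_k = int(raw.get("kmeans_k", cfg.kmeans_k))
        return cfg


def validate_config(config: RunConfig) -> list[str]:
    """Schema and cross-field checks; an empty list means runnable."""
    issues = []
    if config.synthetic and config.inputs:
        issues.append("config activates both synthetic mode and real inputs; "
                      "choose one")
    if not config.synthetic:
        required = ["probes", "probe_map", "annotation", "input_reads"]
        for key in required:
            if key not in config.inputs:
                issues.append(f"real mode missing input path: {key}")
        if "peaks" not in config.inputs or "chip_reads" not in config.inputs:
            issues.append("real mode missing per-TF peak/read paths")
    if not 0 < config.rules.alpha < 1:
        issues.append(f"alpha out of range: {config.rules.alpha}")
    if config.kmeans_k < 1:
        issues.append("kmeans_k must be >= 1")
    if config.seed < 0:
        issues.append("seed must be non-negative")
    return issues


def _default_tf_specs(annotation: pd.DataFrame, tfi_genes: list[str],
                      n_tfs: int, targets_per_tf: int, seed: int
                      ) -> dict[str, simulate.TFSpec]:
    """Plant a binding design over called-TFI genes, including a fully
    connected triad with autoregulation among the first three TF genes."""
    rng = np.random.default_rng(seed)
    names = list(annotation["name"])
    tf_names = [f"TF{i + 1}" for i in range(n_tfs)]
    tf_genes = names[:n_tfs]
    pool = [g for g in (tfi_genes or names) if g not in tf_genes]
    specs = {}
    triad_genes = tf_genes[:3]
    for i, tf in enumerate(tf_names):
        if pool:
            picks = list(rng.choice(pool, size=min(targets_per_tf, len(pool)),
                                    replace=False))
        else:
            picks = []
        targets = set(picks)
        if i < 3:  # the planted triad: each of TF1..TF3 binds all three genes
            targets |= set(triad_genes)
        specs[tf] = simulate.TFSpec(gene=tf_genes[i], targets=tuple(sorted(targets)))
    return specs


def run_all(config: RunConfig, outdir) -> Path:
    """Execute every stage and write results plus a markdown report."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    sim_cfg = config.sim or simulate.SimConfig(seed=config.seed)
    if config.sim is None:
        sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)

    # ----- stage 1: inputs -------------------------------------------------
    if config.synthetic:
        log.info("simulating expression experiment (seed=%d)", sim_cfg.seed)
        design = simulate.make_default_design()
        probes, probe_map, truth = simulate.generate_expression_experiment(
            sim_cfg, design)
        count_design = simulate.make_count_design()
        counts = simulate.generate_count_experiment(sim_cfg, count_design, truth)
        n_ann = min(sim_cfg.n_genes, 60)
        annotation = simulate.generate_annotation(
            2, 2_000_000, n_ann, seed=sim_cfg.seed + 2, min_gap=12_000)
        # name annotation genes after the first simulated transcripts
        annotation = annotation.assign(
            name=list(truth.gene_classes.index[:n_ann]))
        simulate.write_experiment(out, probes, probe_map, truth,
                                  counts=counts, annotation=annotation)
    else:
        probes = io.read_matrix_tsv(config.inputs["probes"])
        probe_map = pd.read_csv(config.inputs["probe_map"], sep="\t",
                                index_col=0)["transcript_id"]
        design = pd.read_csv(config.inputs["design"], sep="\t")
        annotation = io.read_bed(config.inputs["annotation"])
        counts = (io.read_matrix_tsv(config.inputs["counts"])
                  if "counts" in config.inputs else None)
        truth = None
        count_design = None

    # ----- stage 2: classification ----------------------------------------
    log.info("classifying transcripts")
    labeling = classify.tfi_set(probes, probe_map, design, config.rules)
    labeling.to_csv(out / "labeling.tsv", sep="\t")
    tfi_genes = list(labeling.index[labeling["tfi"]])

    # ----- stage 3: clustering --------------------------------------------
    ratios = classify.ratio_matrix(probes, probe_map, design, config.rules)
    active = sorted(set(labeling.index[labeling["induced"]])
                    | set(labeling.index[labeling["amanitin_sensitive"]]))
    cluster_rows = ratios.loc[active] if active else ratios
    k = min(config.kmeans_k, max(1, len(cluster_rows)))
    assignment, _, history = classify.kmeans_ratio_clusters(
        cluster_rows, k=k, seed=config.seed)
    assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t")

    # ----- stage 4: differential expression (TKD counts) -------------------
    de = None
    if counts is not None and count_design is not None:
        de = stats.nb_de_test(
            counts,
            {"treated": simulate.design_samples(count_design, "st10.5", "tkd"),
             "control": simulate.design_samples(count_design, "st10.5",
                                                "control")},
            config.thresholds)
        de.to_csv(out / "de_tkd.tsv", sep="\t")

    # ----- stage 5: enrichment --------------------------------------------
    universe = list(labeling.index)
    enr_rows = []
    if truth is not None:
        for cls in sorted(truth.gene_classes.unique()):
            members = set(truth.gene_classes.index[truth.gene_classes == cls])
            res = enrich.set_overrepresentation(universe, members, tfi_genes,
                                                term_id=f"class:{cls}")
            enr_rows.append(res)
        pd.DataFrame([dataclasses.asdict(r) for r in enr_rows]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False)

    # ----- stage 6: binding network ----------------------------------------
    log.info("building binding network")
    tfi_in_ann = [g for g in tfi_genes if g in set(annotation["name"])]
    tf_specs = _default_tf_specs(annotation, tfi_in_ann, config.n_tfs,
                                 config.targets_per_tf, seed=config.seed + 3)
    peaks_by_tf, reads_by_tf, input_reads, chip_truth = \
        simulate.generate_chip_experiment(annotation, tf_specs,
                                          seed=config.seed + 4)
    edges, domains = network.build_network(peaks_by_tf, reads_by_tf,
                                           input_reads, annotation, config.net)
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    all_genes = list(annotation["name"])
    net_gene_set = tfi_in_ann or all_genes
    combos = network.binding_combinations(edges, net_gene_set)
    hist_set, hist_bg = network.indegree_distribution(
        edges, net_gene_set, all_genes, n_tfs=len(tf_specs))
    tf_gene_map = {tf: spec.gene for tf, spec in tf_specs.items()}
    circuitry = network.core_circuitry(edges, tf_gene_map)
    net_json = {
        "tfs": sorted(tf_specs),
        "edges": [list(e) for e in edges.itertuples(index=False)],
        "combinations": {"|".join(sorted(c)) or "(none)": int(n)
                         for c, n in sorted(combos.items(),
                                            key=lambda kv: (-kv[1], sorted(kv[0])))},
        "fully_connected_triads": [list(t) for t in
                                   circuitry["fully_connected_triads"]],
    }
    io.write_json(net_json, out / "network.json")

    # ----- report ----------------------------------------------------------
    report = _render_report(config, labeling, assignment, history, de,
                            enr_rows, edges, combos, hist_set, hist_bg,
                            circuitry, truth, chip_truth)
    (out / "report.md").write_text(report)
    (out / "run.log").write_text(
        json.dumps({"seed": config.seed,
                    "thresholds": dataclasses.asdict(config.thresholds),
                    "rules": dataclasses.asdict(config.rules),
                    "network": dataclasses.asdict(config.net)},
                   indent=1, sort_keys=True) + "\n")
    return out


def recovery_metrics(labeling: pd.DataFrame, truth: simulate.SyntheticTruth
                     ) -> dict[str, float]:
    """Sensitivity/specificity of the TFI call against planted classes."""
    truth_tfi = truth.gene_classes == simulate.GeneClass.TFI.value
    called = labeling["tfi"].reindex(truth.gene_classes.index, fill_value=False)
    tp = int((called & truth_tfi).sum())
    fn = int((~called & truth_tfi).sum())
    fp = int((called & ~truth_tfi).sum())
    tn = int((~called & ~truth_tfi).sum())
    return {"sensitivity": tp / max(tp + fn, 1),
            "specificity": tn / max(tn + fp, 1),
            "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def edge_recovery(edges: pd.DataFrame, truth: simulate.SyntheticTruth
                  ) -> dict[str, float]:
    """Precision/recall of recovered TF->gene edges against planted ones."""
    called = {(t, g) for t, g in edges.itertuples(index=False)}
    planted = truth.edges
    tp = len(called & planted)
    return {"precision": tp / max(len(called), 1),
            "recall": tp / max(len(planted), 1),
            "n_called": len(called), "n_planted": len(planted)}


def _render_report(config, labeling, assignment, history, de, enr_rows,
                   edges, combos, hist_set, hist_bg, circuitry, truth,
                   chip_truth) -> str:
    lines = ["# tfinet run report", ""]
    n_tfi = int(labeling["tfi"].sum())
    lines += [f"- transcripts: {len(labeling)}",
              f"- TFI transcripts called: {n_tfi}",
              f"- clusters: {assignment.nunique()} "
              f"(objective {history[-1]:.4f} after {len(history)} iterations)"]
    if truth is not None:
        m = recovery_metrics(labeling, truth)
        lines += [f"- TFI recovery vs planted truth: sensitivity "
                  f"{m['sensitivity']:.3f}, specificity {m['specificity']:.3f}"]
    if de is not None:
        n_dec = int((de["direction"] == stats.DECREASE).sum())
        n_inc = int((de["direction"] == stats.INCREASE).sum())
        lines += [f"- TKD differential expression: {n_dec} decreased, "
                  f"{n_inc} increased at FDR {config.thresholds.de_fdr:g}"]
    if enr_rows:
        lines += ["", "## TFI-set over-representation by planted class", "",
                  "| term | N | K | n | k | fold | p |", "|---|---|---|---|---|---|---|"]
        for r in enr_rows:
            fold = "nan" if np.isnan(r.fold) else f"{r.fold:.1f}"
            lines.append(f"| {r.term_id} | {r.N} | {r.K} | {r.n} | {r.k} | "
                         f"{fold} | {r.p:.3g} |")
    lines += ["", "## Binding network", "",
              f"- directed TF->gene edges: {len(edges)}"]
    if chip_truth is not None:
        em = edge_recovery(edges, chip_truth)
        lines += [f"- edge recovery vs planted: precision {em['precision']:.3f}, "
                  f"recall {em['recall']:.3f}"]
    lines += ["- most common bound-TF combinations: "
              + "; ".join(f"{{{','.join(sorted(c)) or '-'}}}x{n}"
                          for c, n in combos.most_common(5))]
    lines += ["- indegree histogram (gene set): "
              + " ".join(f"{v:.2f}" for v in hist_set),
              "- indegree histogram (background): "
              + " ".join(f"{v:.2f}" for v in hist_bg)]
    triads = circuitry["fully_connected_triads"]
    lines += [f"- fully connected triads (incl. autoregulation): "
              + (", ".join("-".join(t) for t in triads) if triads else "none")]
    lines.append("")
    return "\n".join(lines)
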
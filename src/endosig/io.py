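"""Readers/writers for the pipeline's file formats, config and orchestration.

Formats: GMT gene-set collections (set name, description, tab-separated gene
ids), 3-column scored edge lists (node, node, confidence — STRING-flat
compatible), TSV feature matrices (first column feature ids, header row of
sample ids, empty cells missing) and CSV subject tables. The canonical
dialect is TSV with dot decimals, UTF-8 and LF endings; CSV is accepted on
read by delimiter sniffing.

``run_all`` chains the stages end to end on synthetic inputs — simulate ->
quantify -> endotype -> assoc -> enrich -> panel — and records row counts at
every filter step in a run report, so each analysis is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import assoc, endotype, enrich, panel, quantify, synth

logger = logging.getLogger(__name__)


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Parse a GMT file into {set name: set of gene ids}.

    Each line is set name, description, then >=1 tab-separated gene ids.
    Duplicate genes within a set are dropped with a warning; a line with
    fewer than 3 fields is a parse error carrying the line number.
    """
    sets: dict = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} "
                             f"tab-separated fields, need >= 3")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        unique = list(dict.fromkeys(genes))
        if len(unique) < len(genes):
            logger.warning("%s:%d: set %s has duplicate gene ids; deduplicated",
                           path, lineno, name)
        sets[name] = set(unique)
    if not sets:
        logger.warning("%s: empty GMT collection", path)
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# Interaction networks
# ---------------------------------------------------------------------------

def read_network(path, min_conf: float = 0.0) -> nx.Graph:
    """Load a 3-column (node, node, confidence) edge list as an undirected graph.

    Duplicate pairs keep the maximum confidence; self-loops are dropped with a
    warning; edges with confidence <= ``min_conf`` are dropped (strict
    threshold). A header line is tolerated; any other non-numeric confidence
    is a parse error with the line number.
    """
    g = nx.Graph()
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    delim = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if delim is None:
            delim = _sniff_delimiter(line)
            first_data_line = lineno
        fields = line.split(delim)
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: edge line has {len(fields)} fields, need 3")
        u, v, conf_str = fields[0].strip(), fields[1].strip(), fields[2].strip()
        try:
            conf = float(conf_str)
        except ValueError:
            if lineno == first_data_line:  # header row
                continue
            raise ValueError(f"{path}:{lineno}: non-numeric confidence {conf_str!r}")
        if u == v:
            logger.warning("%s:%d: self-loop (%s) dropped", path, lineno, u)
            continue
        if conf <= min_conf:
            continue
        if g.has_edge(u, v):
            g.edges[u, v]["confidence"] = max(g.edges[u, v]["confidence"], conf)
        else:
            g.add_edge(u, v, confidence=conf)
    return g


def write_network(g: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node1\tnode2\tconfidence\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('confidence', 1.0):.6g}\n")


# ---------------------------------------------------------------------------
# Feature matrices and subject tables
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    """Read a features x samples matrix (first column ids, empty cells missing)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    delim = _sniff_delimiter(lines[0])
    header = lines[0].split(delim)
    n_cols = len(header)
    rows, index = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(delim)
        if len(fields) != n_cols:
            raise ValueError(f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                             f"header has {n_cols})")
        index.append(fields[0])
        rows.append([float(x) if x.strip() else np.nan for x in fields[1:]])
    if len(set(index)) < len(index):
        dups = sorted({i for i in index if index.count(i) > 1})
        raise ValueError(f"{path}: duplicate feature ids: {dups}")
    return pd.DataFrame(rows, index=pd.Index(index, name=header[0] or "feature"),
                        columns=header[1:], dtype=float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "feature",
                  na_rep="", lineterminator="\n")


def read_subjects(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_subjects(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, index_label=subjects.index.name or "subject",
                    lineterminator="\n")


def write_peptides(pq: quantify.PeptideQuantSet, path) -> None:
    pq.records.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_peptides(path, ref_channel: str = synth.TMT_REF_CHANNEL
                  ) -> quantify.PeptideQuantSet:
    rec = pd.read_csv(path, sep="\t")
    return quantify.PeptideQuantSet(records=rec, ref_channel=ref_channel)


# ---------------------------------------------------------------------------
# Pipeline configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run parameters; defaults give a small, fast demo run."""

    out_dir: str = "endosig_out"
    seed: int = 0
    sim: dict = field(default_factory=dict)         # SimConfig overrides
    rollup_method: str = "median"
    min_detection: float = 0.8
    iqr_multiplier: float = 3.0
    threshold: float = 1.0                           # pathology dichotomy
    covariates: tuple = ("age", "sex", "apoe_e4", "storage_years")
    covariate_kinds: tuple = ("continuous", "binary", "binary", "continuous")
    min_conf: float = 0.4
    iterations: int = 2000                           # permutations (50k in full runs)
    panel_label: str = "pet_status"
    repeats: int = 5
    folds: int = 5
    max_panel_size: int = 10
    rule: str = "max"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "covariate_kinds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_all(config: PipelineConfig) -> dict:
    """Execute simulate -> quantify -> endotype -> assoc -> enrich -> panel.

    Writes all stage outputs plus ``report.json`` under ``config.out_dir``
    and returns the run report (seeds, parameters, row counts at each filter).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed,
                    "parameters": {k: v for k, v in vars(config).items()
                                   if not isinstance(v, dict)}}

    sim_cfg = synth.SimConfig(seed=config.seed, **config.sim)
    subjects, protein_matrix, truth = synth.simulate_cohort(sim_cfg)
    pq = synth.simulate_tmt(protein_matrix, sim_cfg)
    network = synth.simulate_network(sim_cfg, truth)
    gene_sets = synth.simulate_gene_sets(sim_cfg, truth)
    write_subjects(subjects, out / "subjects.csv")
    write_matrix(protein_matrix, out / "proteins.csv")
    write_peptides(pq, out / "peptides.tsv")
    write_network(network, out / "network.tsv")
    write_gmt(gene_sets, out / "sets.gmt")
    (out / "truth.json").write_text(json.dumps(
        {"signal_protein_ids": sorted(truth.signal_protein_ids),
         "effects": truth.effects}, indent=1))

    # Quantify: normalize, roll up, detection-filter.
    normalized = quantify.median_ratio_normalize(pq)
    isoforms = quantify.rollup_isoforms(normalized, method=config.rollup_method)
    report["n_isoforms"] = int(len(isoforms.values))
    filtered = quantify.filter_detection(isoforms, config.min_detection)
    report["n_isoforms_detected"] = int(len(filtered.values))
    write_matrix(filtered.values, out / "isoform_matrix.tsv")

    # Endotype.
    endo = endotype.endotype_subjects(subjects, threshold=config.threshold)
    endo.table.to_csv(out / "endotype.tsv", sep="\t", lineterminator="\n")
    groups = endo.table["group"]
    continuous = endo.table["x"]

    # Association battery on the isoform matrix.
    spec = assoc.CovariateSpec(tuple(config.covariates), tuple(config.covariate_kinds))
    design = spec.design(subjects)
    battery = assoc.run_battery(filtered.values, groups, continuous, design)
    battery.to_csv(out / "associations.tsv", sep="\t", lineterminator="\n")
    report["n_features_tested"] = int(len(battery))
    report["n_features_any_sig"] = int((battery["n_sig"] > 0).sum())

    # Enrichment from isoform-level linear-regression p-values.
    iso_p = pd.DataFrame({
        "protein": [r.split("|")[0] for r in battery.index],
        "p": battery["linear_p"].to_numpy()})
    results, enrich_report = enrich.enrich_pipeline(
        iso_p, network, {"synthetic": gene_sets}, min_conf=config.min_conf,
        B=config.iterations, seed=config.seed)
    report["enrichment"] = enrich_report
    for cname, res in results.items():
        res.to_csv(out / f"enrichment_{cname}.tsv", sep="\t", lineterminator="\n")

    # Panel on the (log10, cleaned) protein matrix.
    cleaned, removals = quantify.log10_and_clean(protein_matrix,
                                                 config.iqr_multiplier)
    report["n_outliers_removed"] = int(len(removals))
    complete = cleaned.dropna(axis=1)
    report["n_panel_samples"] = int(complete.shape[1])
    adjusted = panel.glm_adjust(complete, design)
    labels = subjects[config.panel_label].reindex(adjusted.values.columns)
    sizes = range(1, min(config.max_panel_size, len(adjusted.values)) + 1)
    curve = panel.cv_auc_sweep(adjusted, labels, sizes=sizes,
                               repeats=config.repeats, folds=config.folds,
                               seed=config.seed)
    size, members = panel.select_minimal_panel(curve, rule=config.rule)
    metrics = panel.evaluate_panel(adjusted, labels, members,
                                   repeats=config.repeats, folds=config.folds,
                                   seed=config.seed)
    pd.DataFrame({"size": curve.sizes, "mean_auc": curve.mean_auc,
                  "sd_auc": curve.sd_auc}).to_csv(
        out / "panel_curve.tsv", sep="\t", index=False, lineterminator="\n")
    (out / "panel_result.json").write_text(json.dumps(
        {"rule": config.rule, "size": size, "features": members,
         "metrics": {"auc": metrics.auc, "sensitivity": metrics.sensitivity,
                     "specificity": metrics.specificity, "ppv": metrics.ppv,
                     "npv": metrics.npv, "threshold": metrics.threshold}},
        indent=1))
    report["panel"] = {"size": size, "features": members, "auc": metrics.auc}

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    logger.info("pipeline complete: %d isoforms tested, panel size %d (AUC %.3f)",
                report["n_features_tested"], size, metrics.auc)
    return report
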
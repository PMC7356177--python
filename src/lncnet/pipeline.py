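"""End-to-end orchestration: config validation, stage sequencing, outputs.

The pipeline runs read/generate -> differential expression -> DEG network
induction -> module detection -> enrichment -> lncRNA cascade, writing
one TSV/JSON artifact per stage plus a run manifest with the config hash,
seed, stage cardinalities and output checksums. Outputs contain no
timestamps or absolute paths, so a fixed config and seed reproduce every
file byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as io_formats
from .data import LNCRNA, ExpressionMatrix, GeneSetCollection, RegulatoryAnnotation
from .deg import compute_differential, select_degs, split_by_class
from .enrichment import enrich_go_bp, enrich_pathways
from .errors import AnalysisError, ConfigError, LncnetError
from .network import count_connected, find_modules, induce_deg_network
from .prioritize import render_priority_table, run_cascade
from .synthetic import GeneratorConfig, generate_all

log = logging.getLogger(__name__)

#: input-file roles for a run on real (non-generated) data
INPUT_KEYS = ("matrix", "groups", "classes", "edges", "lnc_mirna",
              "lnc_gene", "mirna_gene", "gmt")


@dataclass
class RunConfig:
    """Validated run configuration; exactly one of inputs/generate is set."""

    inputs: dict[str, str] | None = None
    generate: GeneratorConfig | None = None
    deg_fc_min: float = 1.5
    deg_q_max: float = 0.01
    edge_min_score: float = 0.4
    mcode_k_core: int = 4
    mcode_node_score_cutoff: float = 0.2
    mcode_haircut: bool = True
    mcode_fluff: bool = False
    lnc_fc_min: float = 4.0
    go_alpha: float = 0.05
    pathway_alpha: float = 0.05
    seed: int = 17

    def validate(self) -> None:
        if (self.inputs is None) == (self.generate is None):
            raise ConfigError(
                "exactly one of 'inputs' and 'generate' must be present")
        checks = [
            ("deg_fc_min", self.deg_fc_min >= 1),
            ("deg_q_max", 0 < self.deg_q_max <= 1),
            ("edge_min_score", 0 <= self.edge_min_score <= 1),
            ("mcode_k_core", self.mcode_k_core >= 1),
            ("mcode_node_score_cutoff",
             0 <= self.mcode_node_score_cutoff < 1),
            ("lnc_fc_min", self.lnc_fc_min >= 1),
            ("go_alpha", 0 < self.go_alpha <= 1),
            ("pathway_alpha", 0 < self.pathway_alpha <= 1),
        ]
        for key, ok in checks:
            if not ok:
                raise ConfigError(
                    f"config value {key} = {getattr(self, key)!r} "
                    "is out of range")
        if self.inputs is not None:
            unknown = set(self.inputs) - set(INPUT_KEYS)
            if unknown:
                raise ConfigError(
                    f"unknown input key {sorted(unknown)[0]!r}")
            missing = [k for k in INPUT_KEYS[:-1] if k not in self.inputs]
            if missing:
                raise ConfigError(f"missing input path {missing[0]!r}")

    def as_canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generate is not None:
            d["generate"] = dataclasses.asdict(self.generate)
            d["generate"]["fc_range"] = list(self.generate.fc_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.as_canonical_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


_RUN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}
_GEN_KEYS = {f.name for f in dataclasses.fields(GeneratorConfig)}


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default and range-check a YAML run configuration.

    Unknown keys are rejected by name. An empty file yields the
    documented defaults (a generated cohort at the default seed).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config key {sorted(unknown)[0]!r}")
    kwargs = dict(raw)
    gen_section = kwargs.pop("generate", None)
    if gen_section is not None:
        if not isinstance(gen_section, dict):
            raise ConfigError(f"{path}: 'generate' must be a mapping")
        bad = set(gen_section) - _GEN_KEYS
        if bad:
            raise ConfigError(
                f"{path}: unknown generate key {sorted(bad)[0]!r}")
        if "fc_range" in gen_section:
            gen_section["fc_range"] = tuple(gen_section["fc_range"])
        kwargs["generate"] = GeneratorConfig(**gen_section)
    if kwargs.get("inputs") is None and gen_section is None:
        kwargs["generate"] = GeneratorConfig()
    try:
        config = RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    config.validate()
    if config.generate is not None:
        config.generate.validate()
    return config


def _load_inputs(config: RunConfig) -> tuple[
        ExpressionMatrix, "object", RegulatoryAnnotation,
        GeneSetCollection | None]:
    if config.generate is not None:
        # the run seed is the single root seed: it overrides the
        # generator section's own seed so one flag reseeds everything
        gen = dataclasses.replace(config.generate, seed=config.seed)
        bundle = generate_all(gen)
        return bundle.matrix, bundle.network, bundle.annotation, bundle.genesets
    paths = config.inputs
    matrix = io_formats.read_expression(paths["matrix"], paths["groups"],
                                        paths["classes"])
    network = io_formats.read_edge_list(paths["edges"],
                                        min_score=config.edge_min_score)
    annotation = io_formats.read_regulatory(
        paths["lnc_mirna"], paths["lnc_gene"], paths["mirna_gene"])
    genesets = (io_formats.read_gmt(paths["gmt"])
                if paths.get("gmt") else None)
    return matrix, network, annotation, genesets


def _write_enrichment(results, path: Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        path, sep="\t", index=False)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write all artifacts into ``out_dir``.

    Returns the manifest. On a stage failure an ``AnalysisError`` naming
    the stage is raised and a ``STALE`` marker is left in ``out_dir`` so
    partial outputs are recognizable.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    counts: dict[str, int] = {}
    files: dict[str, str] = {}
    try:
        matrix, network, annotation, genesets = _load_inputs(config)
        counts["n_features"] = len(matrix.feature_ids)
        counts["n_samples"] = len(matrix.sample_ids)
        log.info("load_inputs: %d features x %d samples",
                 counts["n_features"], counts["n_samples"])

        stage = "differential_expression"
        records = compute_differential(matrix)
        select_degs(records, fc_min=config.deg_fc_min,
                    q_max=config.deg_q_max)
        coding_degs, lnc_degs = split_by_class(records)
        counts["n_selected"] = len(coding_degs) + len(lnc_degs)
        counts["n_coding_degs"] = len(coding_degs)
        counts["n_lnc_degs"] = len(lnc_degs)
        log.info("differential_expression: %d selected "
                 "(%d coding, %d lncRNA)", counts["n_selected"],
                 len(coding_degs), len(lnc_degs))
        deg_table = pd.DataFrame(
            {"feature_id": [r.feature_id for r in records],
             "class": [r.feature_class for r in records],
             "fc": [r.fc for r in records],
             "log2fc": [r.log2fc for r in records],
             "p_raw": [r.p_raw for r in records],
             "q_fdr": [r.q_fdr for r in records],
             "selected": [r.selected for r in records]})
        files["degs"] = "degs.tsv"
        deg_table.to_csv(out / files["degs"], sep="\t", index=False)

        stage = "network"
        deg_net = induce_deg_network(network, coding_degs)
        counts["n_network_nodes"] = deg_net.number_of_nodes()
        counts["n_network_edges"] = deg_net.number_of_edges()
        counts["n_connected_degs"] = count_connected(deg_net)
        log.info("network: %d nodes, %d edges, %d connected DEGs",
                 counts["n_network_nodes"], counts["n_network_edges"],
                 counts["n_connected_degs"])
        files["network_stats"] = "network_stats.json"
        (out / files["network_stats"]).write_text(json.dumps(
            {k: counts[k] for k in ("n_network_nodes", "n_network_edges",
                                    "n_connected_degs")},
            indent=1, sort_keys=True) + "\n")

        stage = "module_detection"
        modules = find_modules(
            deg_net, k_core_filter=config.mcode_k_core,
            node_score_cutoff=config.mcode_node_score_cutoff,
            haircut=config.mcode_haircut, fluff=config.mcode_fluff)
        counts["n_modules"] = len(modules)
        log.info("module_detection: %d modules", len(modules))
        files["modules"] = "modules.tsv"
        pd.DataFrame(
            {"label": [m.label for m in modules],
             "seed_gene": [m.seed_gene for m in modules],
             "size": [len(m.members) for m in modules],
             "density": [m.density for m in modules],
             "score": [m.score for m in modules],
             "members": [",".join(sorted(m.members)) for m in modules]}
        ).to_csv(out / files["modules"], sep="\t", index=False)

        stage = "enrichment"
        if genesets is not None:
            files["enrichment_degs_go"] = "enrichment_degs_go.tsv"
            _write_enrichment(
                enrich_go_bp(coding_degs, genesets, alpha=config.go_alpha),
                out / files["enrichment_degs_go"])
            files["enrichment_degs_pathways"] = "enrichment_degs_pathways.tsv"
            _write_enrichment(
                enrich_pathways(coding_degs, genesets,
                                alpha=config.pathway_alpha),
                out / files["enrichment_degs_pathways"])
            for mod in modules:
                key = f"enrichment_{mod.label}"
                files[key] = f"enrichment_{mod.label}.tsv"
                _write_enrichment(
                    enrich_go_bp(set(mod.members), genesets,
                                 alpha=config.go_alpha),
                    out / files[key])
            log.info("enrichment: DEG list + %d modules tested",
                     len(modules))
        else:
            log.info("enrichment: skipped (no gene-set collection)")

        stage = "lnc_prioritization"
        lnc_records = [r for r in records
                       if r.selected and r.feature_class == LNCRNA]
        priority = run_cascade(lnc_records, annotation, coding_degs,
                               modules, fc_min=config.lnc_fc_min)
        prioritized = sorted(r.lnc_id for r in priority if r.prioritized)
        counts["n_lnc_pass_fc"] = sum(r.passed_fc for r in priority)
        counts["n_prioritized"] = len(prioritized)
        log.info("lnc_prioritization: %d lncRNAs, %d pass |FC| filter, "
                 "%d prioritized", len(priority), counts["n_lnc_pass_fc"],
                 len(prioritized))
        files["lnc_priority"] = "lnc_priority.tsv"
        render_priority_table(priority).to_csv(
            out / files["lnc_priority"], sep="\t", index=False)
        files["prioritized"] = "prioritized.txt"
        (out / files["prioritized"]).write_text(
            "".join(f"{l}\n" for l in prioritized))
    except LncnetError as exc:
        (out / "STALE").write_text(f"failed at stage: {stage}\n")
        raise AnalysisError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_counts": dict(sorted(counts.items())),
        "files": dict(sorted(files.items())),
        "checksums": {
            name: hashlib.sha256((out / fname).read_bytes()).hexdigest()
            for name, fname in sorted(files.items())
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    stale = out / "STALE"
    if stale.exists():
        stale.unlink()
    return manifest
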
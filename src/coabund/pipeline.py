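"""Orchestration: one reproducible run from raw plex tables to all outputs.

``run_pipeline`` executes ingest -> differential abundance (per-timepoint t
tests + per-protein ANOVA + overlaps + PCA) -> network analysis (soft power,
modules, eigenproteins, kME, temporal profiles) -> marker enrichment ->
cross-dataset comparison, writing each stage's TSV outputs and a manifest of
content hashes.  Stage outputs are written even when a later stage fails;
identical config + seed gives byte-identical non-timestamp outputs.

``simulate_and_validate`` closes the loop against the synthetic generator's
ground truth: module recovery (adjusted Rand index), differential-abundance
sensitivity/specificity, and null calibration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import conet, crossmap, diffabund, enrich, ingest
from . import synth as synthmod

logger = logging.getLogger("coabund")

EXIT_OK = 0
EXIT_OTHER = 1
EXIT_SCHEMA = 2
EXIT_DEGENERATE = 3


@dataclass
class PipelineConfig:
    """Everything one run needs; thresholds default to the study's values."""

    out_dir: str = "coabund_run"
    seed: int = 0
    # inputs: either per-plex intensity TSVs + design, or a ready ratio matrix
    plex_tables: dict[str, str] = field(default_factory=dict)
    matrix_path: str | None = None
    design_path: str | None = None
    synth: synthmod.SynthConfig | None = None
    marker_gmt: str | None = None
    comparator_tables: dict[str, str] = field(default_factory=dict)
    # thresholds
    fc_up: float = diffabund.DEFAULT_FC_UP
    fc_down: float = diffabund.DEFAULT_FC_DOWN
    p_cut: float = diffabund.DEFAULT_P_CUT
    max_missing_fraction: float = 0.0
    network: conet.NetworkParams = field(default_factory=conet.NetworkParams)
    association_alpha: float = 0.001
    disease_genotype: str = synthmod.DISEASE
    control_genotype: str = synthmod.CONTROL
    disease_timepoints: tuple[str, ...] = tuple(synthmod.DISEASE_TIMEPOINTS)
    control_timepoints: tuple[str, ...] = tuple(synthmod.CONTROL_TIMEPOINTS)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        net = raw.pop("network", {})
        cfg = cls(**{k: v for k, v in raw.items() if k != "synth"})
        cfg.network = conet.NetworkParams(**net)
        if "synth" in raw:
            cfg.synth = synthmod.SynthConfig(**raw["synth"])
        return cfg

    def echo(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        d = {k: v for k, v in dataclasses.asdict(self).items()}
        d.pop("synth", None)
        out = clean(d)
        if self.synth is not None:
            s = dataclasses.asdict(self.synth)
            s.pop("design", None)
            out["synth"] = clean(s)
        return out


@dataclass
class RunArtifacts:
    out_dir: Path
    manifest: dict[str, str]  # relative path -> sha256
    stage_status: dict[str, str]

    def manifest_path(self) -> Path:
        return self.out_dir / "manifest.json"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path, manifest: dict, index: bool = False,
           index_label: str | None = None) -> None:
    frame.to_csv(path, sep="\t", index=index, index_label=index_label,
                 float_format="%.12g")
    manifest[path.name] = _sha256(path)


def load_inputs(config: PipelineConfig):
    """Resolve the configured input source into (plex tables, design, truth?)."""
    if config.synth is not None:
        plexes, truth = synthmod.simulate_dataset(config.synth)
        return plexes, config.synth.design, truth
    if config.matrix_path is not None:
        if config.design_path is None:
            raise ingest.SchemaError("matrix input requires a design file")
        design = ingest.StudyDesign.from_tsv(config.design_path)
        matrix = ingest.AbundanceMatrix.from_tsv(config.matrix_path, design)
        return matrix, design, None
    if config.plex_tables:
        if config.design_path is None:
            raise ingest.SchemaError("plex-table input requires a design file")
        design = ingest.StudyDesign.from_tsv(config.design_path)
        plexes = {
            plex: ingest.PlexIntensities.from_tsv(plex, path)
            for plex, path in config.plex_tables.items()
        }
        return plexes, design, None
    raise ingest.SchemaError("no input configured: set synth, matrix_path or plex_tables")


def prepare_matrix(config: PipelineConfig, source, design) -> ingest.AbundanceMatrix:
    """Reference ratios -> merge -> missingness filter -> log2."""
    if isinstance(source, ingest.AbundanceMatrix):
        merged = source
    else:
        ratio_tables = {
            plex: ingest.reference_ratios(tab, design.reference_channel_by_plex[plex])
            for plex, tab in source.items()
        }
        merged = ingest.merge_plexes(ratio_tables, design)
    filtered = ingest.filter_missing(merged, config.max_missing_fraction)
    return ingest.log_transform(filtered)


def run_de_stage(config: PipelineConfig, log_matrix: ingest.AbundanceMatrix,
                 out: Path, manifest: dict) -> dict[str, pd.DataFrame]:
    tables = {}
    for tp in config.disease_timepoints:
        spec = diffabund.timepoint_vs_grouped_controls(
            tp, config.control_genotype, config.disease_genotype,
            config.control_timepoints,
        )
        table = diffabund.classify_de(
            diffabund.pairwise_de(log_matrix, spec),
            config.fc_up, config.fc_down, config.p_cut,
        )
        tables[tp] = table
        _write(table.reset_index(), out / f"de_{tp}.tsv", manifest)

    anova = diffabund.protein_anova(log_matrix)
    _write(anova.reset_index(), out / "anova.tsv", manifest)

    for direction in ("up", "down"):
        named = {
            tp: set(t.index[t["call"] == direction]) for tp, t in tables.items()
        }
        named = {k: v for k, v in named.items() if v}
        if len(named) >= 2:
            ov = diffabund.overlap_sets(named)
            ov = ov.assign(members=ov["members"].map(";".join)).drop(columns=["sets"])
            _write(ov, out / f"overlap_{direction}.tsv", manifest)

    pca = diffabund.sample_pca(log_matrix, k=5)
    scores = pca.scores.copy()
    scores.insert(0, "sample_id", scores.index)
    _write(scores, out / "pca_scores.tsv", manifest)
    _write(
        pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(pca.variance_ratio))],
                      "variance_ratio": pca.variance_ratio}),
        out / "pca_variance.tsv", manifest,
    )
    return tables


def run_network_stage(config: PipelineConfig, log_matrix: ingest.AbundanceMatrix,
                      out: Path, manifest: dict):
    params = config.network
    if params.beta is None:
        beta, fit_table, reached = conet.pick_soft_threshold(
            log_matrix, params.candidate_powers, params.rsq_cut,
            params.adjacency_variant,
        )
        _write(fit_table, out / "soft_threshold.tsv", manifest)
    else:
        beta = params.beta
    cor = conet.correlation_matrix(log_matrix)
    adj = conet.signed_adjacency(cor, beta, params.adjacency_variant)
    tom = conet.topological_overlap(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist.values, 0.0)
    dendro = conet.cluster_tree(dist)
    assignment = conet.dynamic_tree_cut(
        dendro, dist, params.min_cluster_size, params.deep_split, params.pam_stage
    )
    (out / "dendrogram.nwk").write_text(dendro.to_newick(), encoding="utf-8")
    manifest["dendrogram.nwk"] = _sha256(out / "dendrogram.nwk")

    eig = conet.module_eigenproteins(log_matrix, assignment)
    kme = conet.module_membership_kme(log_matrix, eig)

    assign_frame = assignment.labels.rename("module").to_frame()
    own = [
        kme.loc[p, m] if m != conet.GREY and m in kme.columns else np.nan
        for p, m in assignment.labels.items()
    ]
    assign_frame["own_kme"] = own
    _write(assign_frame.reset_index(names="protein_id"), out / "modules.tsv", manifest)
    _write(eig.vectors.reset_index(names="sample_id"), out / "eigenproteins.tsv", manifest)
    _write(kme.reset_index(names="protein_id"), out / "kme.tsv", manifest)

    profiles = conet.module_profiles(
        log_matrix, assignment,
        [(config.control_genotype, tp) for tp in config.control_timepoints],
    )
    _write(profiles, out / "module_profiles.tsv", manifest)
    return beta, assignment, eig, kme


def run_pipeline(config: PipelineConfig) -> RunArtifacts:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    status: dict[str, str] = {}

    (out / "config_echo.yaml").write_text(
        yaml.safe_dump(config.echo(), sort_keys=True), encoding="utf-8"
    )
    manifest["config_echo.yaml"] = _sha256(out / "config_echo.yaml")

    source, design, truth = load_inputs(config)
    if config.synth is not None:
        for plex, tab in source.items():
            tab.to_tsv(out / f"intensities_{plex}.tsv")
            manifest[f"intensities_{plex}.tsv"] = _sha256(out / f"intensities_{plex}.tsv")
        design.to_tsv(out / "design.tsv")
        manifest["design.tsv"] = _sha256(out / "design.tsv")
        truth.to_tsv(out / "truth.tsv")
        manifest["truth.tsv"] = _sha256(out / "truth.tsv")
    status["ingest"] = "ok"

    log_matrix = prepare_matrix(config, source, design)
    _write(log_matrix.values.reset_index(), out / "log2_matrix.tsv", manifest)
    status["prep"] = "ok"

    assignment = None
    try:
        run_de_stage(config, log_matrix, out, manifest)
        status["de"] = "ok"
    except Exception as exc:  # stage isolation: later stages still run
        logger.exception("DE stage failed")
        status["de"] = f"failed: {exc}"

    try:
        _, assignment, _, _ = run_network_stage(config, log_matrix, out, manifest)
        status["wcna"] = "ok"
    except Exception as exc:
        logger.exception("network stage failed")
        status["wcna"] = f"failed: {exc}"

    if config.marker_gmt and assignment is not None:
        try:
            markers = enrich.read_gmt(config.marker_gmt)
            table = enrich.module_marker_enrichment(assignment.labels, markers)
            _write(table, out / "marker_enrichment.tsv", manifest)
            status["enrich"] = "ok"
        except Exception as exc:
            logger.exception("enrichment stage failed")
            status["enrich"] = f"failed: {exc}"

    if config.comparator_tables and assignment is not None:
        try:
            run_crossmap_stage(config, assignment, out, manifest)
            status["crossmap"] = "ok"
        except Exception as exc:
            logger.exception("crossmap stage failed")
            status["crossmap"] = f"failed: {exc}"

    artifacts = RunArtifacts(out_dir=out, manifest=manifest, stage_status=status)
    (out / "manifest.json").write_text(
        json.dumps({"files": manifest, "stages": status}, indent=2, sort_keys=True),
        encoding="utf-8",
    )
    return artifacts


def run_crossmap_stage(config: PipelineConfig, assignment, out: Path, manifest: dict):
    own = assignment.labels[assignment.labels != conet.GREY]
    for name, path in config.comparator_tables.items():
        comp = crossmap.DatasetSummary.from_tsv(name, path)
        if "cluster" not in comp.table.columns:
            continue
        theirs = comp.table.set_index(
            comp.table["gene_symbol"].astype(str).str.upper()
        )["cluster"]
        ours = own.copy()
        ours.index = ours.index.astype(str).str.upper()
        assoc = crossmap.module_module_association(
            ours, theirs, alpha=config.association_alpha
        )
        _write(assoc, out / f"module_association_{name}.tsv", manifest)


@dataclass
class ValidationReport:
    properties: dict[str, dict]

    @property
    def all_passed(self) -> bool:
        return all(p["passed"] for p in self.properties.values())


def simulate_and_validate(
    config: synthmod.SynthConfig,
    ari_threshold: float = 0.8,
    null_call_threshold: float = 0.06,
    sensitivity_threshold: float = 0.9,
    network: conet.NetworkParams | None = None,
) -> ValidationReport:
    """Simulate, run the full chain in memory, compare against ground truth."""
    props: dict[str, dict] = {}
    try:
        plexes, truth = synthmod.simulate_dataset(config)
        design = config.design
        ratio_tables = {
            p: ingest.reference_ratios(t, design.reference_channel_by_plex[p])
            for p, t in plexes.items()
        }
        log_matrix = ingest.log_transform(
            ingest.filter_missing(ingest.merge_plexes(ratio_tables, design), 0.0)
        )

        params = network or conet.NetworkParams()
        result = module_recovery(log_matrix, truth, params)
        props["module_recovery_ari"] = {
            "value": result["ari"], "threshold": ari_threshold,
            "passed": bool(result["ari"] >= ari_threshold),
        }
        props["kme_margin"] = {
            "value": result["min_kme_margin"], "threshold": 0.0,
            "passed": bool(result["min_kme_margin"] > 0.0),
        }

        de = de_performance(log_matrix, truth)
        props["de_sensitivity"] = {
            "value": de["sensitivity"], "threshold": sensitivity_threshold,
            "passed": bool(np.isnan(de["sensitivity"]) or de["sensitivity"] >= sensitivity_threshold),
        }
        props["de_null_called_fraction"] = {
            "value": de["null_called_fraction"], "threshold": null_call_threshold,
            "passed": bool(de["null_called_fraction"] <= null_call_threshold),
        }
    except Exception as exc:
        logger.exception("validation failed")
        props["run"] = {"value": str(exc), "threshold": None, "passed": False}
    return ValidationReport(properties=props)


def module_recovery(log_matrix: ingest.AbundanceMatrix, truth: synthmod.GroundTruth,
                    params: conet.NetworkParams | None = None) -> dict:
    """Run the network chain and score module recovery against planted labels."""
    params = params or conet.NetworkParams()
    if params.beta is None:
        beta, _, _ = conet.pick_soft_threshold(
            log_matrix, params.candidate_powers, params.rsq_cut, params.adjacency_variant
        )
    else:
        beta = params.beta
    cor = conet.correlation_matrix(log_matrix)
    adj = conet.signed_adjacency(cor, beta, params.adjacency_variant)
    tom = conet.topological_overlap(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist.values, 0.0)
    dendro = conet.cluster_tree(dist)
    assignment = conet.dynamic_tree_cut(
        dendro, dist, params.min_cluster_size, params.deep_split, params.pam_stage
    )
    planted = truth.module_label_by_protein.reindex(assignment.labels.index)
    ari = adjusted_rand_score(planted.to_numpy(), assignment.labels.to_numpy())

    eig = conet.module_eigenproteins(log_matrix, assignment)
    kme = conet.module_membership_kme(log_matrix, eig)
    margins = []
    background = planted.index[planted == synthmod.BACKGROUND]
    for module in assignment.modules():
        members = assignment.members(module)
        member_med = kme.loc[members, module].median()
        bg_med = kme.loc[kme.index.intersection(background), module].median()
        margins.append(member_med - bg_med)
    return {
        "ari": float(ari),
        "beta": int(beta),
        "n_modules": len(assignment.modules()),
        "n_grey": int((assignment.labels == conet.GREY).sum()),
        "min_kme_margin": float(min(margins)) if margins else np.nan,
        "assignment": assignment,
    }


def de_performance(log_matrix: ingest.AbundanceMatrix, truth: synthmod.GroundTruth,
                   fc_up: float = diffabund.DEFAULT_FC_UP,
                   fc_down: float = diffabund.DEFAULT_FC_DOWN,
                   p_cut: float = diffabund.DEFAULT_P_CUT,
                   min_effect: float | None = None) -> dict:
    """Sensitivity on planted effects and false-call rate on nulls, pooled
    over the disease timepoints.

    Sensitivity counts only effects of at least ``min_effect`` (default:
    the largest planted magnitude, i.e. full-strength shifts); partial
    shifts are excluded from both the positive and the null denominators.
    """
    tp_list = sorted({s.timepoint for s in log_matrix.design.samples
                      if s.genotype == synthmod.DISEASE})
    deltas = {tp: truth.de_effect(tp) for tp in tp_list}
    if min_effect is None:
        top = max((d.abs().max() for d in deltas.values()), default=0.0)
        min_effect = 0.999 * top if top > 0 else np.inf
    n_true = n_hit = n_null = n_false = 0
    for tp in tp_list:
        spec = diffabund.timepoint_vs_grouped_controls(tp)
        table = diffabund.classify_de(
            diffabund.pairwise_de(log_matrix, spec), fc_up, fc_down, p_cut
        )
        delta = deltas[tp].reindex(table.index)
        status = truth.de_status(tp).reindex(table.index)
        called = table["call"].isin(["up", "down"])
        correct_dir = table["call"] == status
        is_true = status.isin(["up", "down"]) & (delta.abs() >= min_effect)
        is_null = status == "null"
        n_true += int(is_true.sum())
        n_hit += int((is_true & correct_dir).sum())
        n_null += int(is_null.sum())
        n_false += int((is_null & called).sum())
    return {
        "sensitivity": n_hit / n_true if n_true else np.nan,
        "null_called_fraction": n_false / n_null if n_null else np.nan,
        "n_true": n_true, "n_null": n_null,
    }
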
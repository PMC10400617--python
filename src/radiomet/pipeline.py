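"""End-to-end orchestration of the radiometabolomics analysis.

``run_pipeline`` executes: (optional) synthetic data generation or file input,
reader-stability filtering and z-score normalization, per-condition sparse-PLS
association networks with community detection and eigenvector centrality,
delta-centrality node selection, pathway over-representation and sample
clustering on the selected metabolites, SMOTE balancing, a 60:40 stratified
split, boosted-tree training for three feature sets (combined, radiomics-only,
metabolite-only), and ROC/AUC evaluation with bootstrap CIs and pairwise
DeLong comparisons.

Determinism: one global seed fans out to per-stage seeds (stable hash of the
stage name), so any stage is reproducible in isolation. The class balancing
and the train/validation split are computed once on the combined feature set
and the single-block models are trained on column subsets of the same
balanced matrix — this keeps validation samples identical across the three
models, which paired DeLong comparison requires, and makes each single-block
model's predictions exactly those of the combined design restricted to its
columns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    GbtConfig,
    Split,
    smote_balance,
    stratified_split,
    train_gbt,
)
from .enrichment import hierarchical_cluster, hypergeometric_ora
from .evaluate import delong_compare, evaluate_scores
from .integration import (
    association_matrix,
    build_network,
    delta_centrality,
    detect_communities,
    eigenvector_centrality,
    fit_spls,
    select_discriminative_nodes,
)
from .io import (
    BENIGN,
    CONDITIONS,
    MALIGNANT,
    METABOLITE,
    RADIOMICS,
    OmicsBlock,
    PathwayMap,
    derive_seed,
    read_labels,
)
from .preprocess import stability_filter, zscore_normalize
from .synthetic import SyntheticSpec, generate_coupled_blocks, generate_pathway_map, \
    generate_reader_replicates

logger = logging.getLogger(__name__)

#: default edge threshold on association scores; see the integration module's
#: note on the 1/s scale of outer-product scores for factors of s features
DEFAULT_TAU_ASSOC = 0.1


@dataclass
class PreprocessParams:
    cv_max: float = 0.10
    cv_aggregate: str = "per_sample"


@dataclass
class IntegrationParams:
    """Integration-stage settings.

    Defaults were calibrated on the synthetic generator's operating
    characteristics: one component (with ~15 samples per condition only the
    leading cross-covariance direction is estimable with any stability),
    a dozen retained loadings per block per component, and an association
    threshold of 0.1 on the outer-product score scale.
    """

    n_components: int = 1
    keep_x: int | None = None  # None = min(12, p)
    keep_y: int | None = None
    tau_assoc: float = DEFAULT_TAU_ASSOC
    tau_dc: float = 0.1
    selection_mode: str = "absolute"
    resolution: float = 1.0

    def resolve_keep(self, p: int, q: int) -> tuple[int, int]:
        kx = min(12, p) if self.keep_x is None else min(self.keep_x, p)
        ky = min(12, q) if self.keep_y is None else min(self.keep_y, q)
        return kx, ky


@dataclass
class ClassifyParams:
    gbt: GbtConfig = field(default_factory=GbtConfig)
    smote_k: int = 5
    target_per_class: int = 20
    train_fraction: float = 0.6
    smote_after_split: bool = False
    minority_only: bool = False


@dataclass
class EvalParams:
    n_boot: int = 2000
    level: float = 0.95
    threshold: float = 0.5


@dataclass
class InputPaths:
    radiomics: str
    metabolites: str
    labels: str
    radiomics_reader_b: str | None = None
    pathway_gmt: str | None = None


@dataclass
class PipelineConfig:
    """Full configuration of one analysis run.

    Exactly one of ``synthetic`` / ``inputs`` provides the data. Defaults for
    every stage parameter with an established value follow that value
    (cv_max 0.10, tau_dc 0.1, target 20 per class, 60:40 split, 2000
    bootstrap rounds, the boosted-tree optimum).
    """

    synthetic: SyntheticSpec | None = field(default_factory=SyntheticSpec)
    inputs: InputPaths | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    evaluate: EvalParams = field(default_factory=EvalParams)
    k_clusters: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticSpec(**d["synthetic"])
        if d.get("inputs") is not None:
            d["inputs"] = InputPaths(**d["inputs"])
        if "preprocess" in d:
            d["preprocess"] = PreprocessParams(**d["preprocess"])
        if "integration" in d:
            d["integration"] = IntegrationParams(**d["integration"])
        if "classify" in d:
            c = dict(d["classify"])
            if "gbt" in c:
                c["gbt"] = GbtConfig(**c["gbt"])
            d["classify"] = ClassifyParams(**c)
        if "evaluate" in d:
            d["evaluate"] = EvalParams(**d["evaluate"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


MODEL_NAMES = ("combined", "radiomics_only", "metabolomics_only")


@dataclass
class RunReport:
    """Structured result of one pipeline run (JSON-serializable)."""

    selection: dict
    networks: dict
    enrichment: list[dict] | None
    clusters: dict | None
    models: dict
    delong: dict
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# --------------------------------------------------------------------------- #
# stages
# --------------------------------------------------------------------------- #

def _load_inputs(config: PipelineConfig):
    if (config.synthetic is None) == (config.inputs is None):
        raise ValueError("exactly one of synthetic / inputs must be set")
    if config.synthetic is not None:
        spec = config.synthetic
        rf, met, labels, truth = generate_coupled_blocks(spec)
        # reader instability hits only unplanted features: the CV filter should
        # emulate segmentation variability, not delete the planted biology
        planted = truth.discriminative_ids | truth.shared_ids
        rng = np.random.default_rng([spec.seed, 0xCF])
        unplanted = np.array([f not in planted for f in rf.feature_ids])
        mask = unplanted & (rng.random(rf.n_features) < spec.reader_cv_unstable_fraction)
        reader_a, reader_b = generate_reader_replicates(rf, spec, unstable_mask=mask)
        pmap = generate_pathway_map(truth, seed=derive_seed(spec.seed, "pathways"))
        return reader_a, reader_b, met, labels, pmap, truth
    paths = config.inputs
    rf = OmicsBlock.read(paths.radiomics, RADIOMICS)
    met = OmicsBlock.read(paths.metabolites, METABOLITE)
    labels = read_labels(paths.labels)
    reader_b = (
        OmicsBlock.read(paths.radiomics_reader_b, RADIOMICS)
        if paths.radiomics_reader_b
        else None
    )
    pmap = PathwayMap.read_gmt(paths.pathway_gmt) if paths.pathway_gmt else None
    return rf, reader_b, met, labels, pmap, None


def integrate_condition(
    rf: OmicsBlock,
    met: OmicsBlock,
    sample_ids: list[str],
    params: IntegrationParams,
    seed: int,
) -> dict:
    """Fit one condition's association network and centralities.

    The blocks are restricted to the condition's samples and re-z-scored
    within that subset before fitting.
    """
    x = zscore_normalize(rf.subset_samples(sample_ids))
    y = zscore_normalize(met.subset_samples(sample_ids))
    n_comp = min(params.n_components, x.n_features, y.n_features, len(sample_ids) - 1)
    kx, ky = params.resolve_keep(x.n_features, y.n_features)
    model = fit_spls(x, y, n_components=n_comp, keep_x=kx, keep_y=ky)
    assoc = association_matrix(model)
    net = build_network(assoc, params.tau_assoc)
    if net.n_edges == 0:
        logger.warning("condition network has no edges at tau_assoc=%g", params.tau_assoc)
        return {"network": net, "model": model, "ec": {}, "communities": None}
    ec = eigenvector_centrality(net)
    communities = detect_communities(net, resolution=params.resolution, seed=seed)
    return {"network": net, "model": model, "ec": ec, "communities": communities}


def _network_summary(result: dict) -> dict:
    net = result["network"]
    comm = result["communities"]
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_isolated_radiomics": len(net.isolated.get(RADIOMICS, [])),
        "n_isolated_metabolites": len(net.isolated.get(METABOLITE, [])),
        "n_communities": comm.n_communities if comm else 0,
        "modularity": comm.modularity if comm else None,
        "n_nonzero_ec": int(sum(v > 0 for v in result["ec"].values())),
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full analysis; optionally write artifacts under *outdir*."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        for sub in ("networks", "selection", "enrichment", "models"):
            (out / sub).mkdir(exist_ok=True)
        config.write_yaml(out / "config.lock")

    seed = config.seed

    # ---- load / generate -------------------------------------------------- #
    try:
        reader_a, reader_b, met, labels, pmap, truth = _load_inputs(config)
    except Exception as e:  # noqa: BLE001
        raise StageError("load", e) from e

    # ---- preprocess ------------------------------------------------------- #
    try:
        if reader_b is not None:
            rf_stable, stab_report = stability_filter(
                reader_a, reader_b, cv_max=config.preprocess.cv_max,
                aggregate=config.preprocess.cv_aggregate,
            )
        else:
            rf_stable, stab_report = reader_a, None
        rf_norm = zscore_normalize(rf_stable)
        met_norm = zscore_normalize(met)
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", e) from e
    if out is not None and stab_report is not None:
        stab_report.write(out / "selection" / "stability_report.tsv")

    # ---- per-condition integration ---------------------------------------- #
    try:
        per_condition = {}
        for cond in CONDITIONS:
            ids = [s for s in labels.index if labels[s] == cond]
            per_condition[cond] = integrate_condition(
                rf_norm, met_norm, ids, config.integration,
                seed=derive_seed(seed, f"communities:{cond}"),
            )
        table = delta_centrality(
            per_condition[BENIGN]["ec"], per_condition[MALIGNANT]["ec"],
            tau_dc=config.integration.tau_dc, mode=config.integration.selection_mode,
        )
        selected = select_discriminative_nodes(
            table, tau_dc=config.integration.tau_dc, mode=config.integration.selection_mode
        )
        rf_ids = set(rf_norm.feature_ids)
        met_ids = set(met_norm.feature_ids)
        selected_rf = sorted(selected & rf_ids)
        selected_met = sorted(selected & met_ids)
    except Exception as e:  # noqa: BLE001
        raise StageError("integration", e) from e

    if out is not None:
        table.write(out / "selection" / "centrality_table.tsv")
        for cond in CONDITIONS:
            res = per_condition[cond]
            g = res["network"].graph
            comm = res["communities"]
            for node in g.nodes:
                g.nodes[node]["ec_benign"] = float(per_condition[BENIGN]["ec"].get(node, 0.0))
                g.nodes[node]["ec_malignant"] = float(
                    per_condition[MALIGNANT]["ec"].get(node, 0.0))
                g.nodes[node]["dc"] = float(table.table["dc"].get(node, 0.0))
                if comm:
                    g.nodes[node]["community"] = int(comm.membership.get(node, -1))
            res["network"].write_graphml(out / "networks" / f"{cond}.graphml")
            res["network"].write_edgelist(out / "networks" / f"{cond}_edges.tsv")

    # ---- enrichment + clustering ------------------------------------------ #
    enrichment_records = None
    cluster_info = None
    try:
        if pmap is not None and selected_met:
            universe = met_ids & set().union(*pmap.members.values())
            sel_in_universe = set(selected_met) & universe
            if sel_in_universe:
                ora = hypergeometric_ora(sel_in_universe, universe, pmap)
                enrichment_records = ora.to_dict(orient="records")
                if out is not None:
                    ora.to_csv(out / "enrichment" / "ora.tsv", sep="\t", index=False)
        if selected_met and config.k_clusters <= met_norm.n_samples:
            assignment, _ = hierarchical_cluster(
                met_norm.subset_features(selected_met), config.k_clusters
            )
            cluster_info = {str(k): int(v) for k, v in assignment.items()}
    except Exception as e:  # noqa: BLE001
        raise StageError("enrichment", e) from e

    # ---- classification --------------------------------------------------- #
    try:
        feature_sets = {
            "combined": selected_rf + selected_met,
            "radiomics_only": selected_rf,
            "metabolomics_only": selected_met,
        }
        features = pd.concat([rf_norm.data, met_norm.data], axis=1)
        combined_cols = feature_sets["combined"]
        models: dict[str, dict] = {}
        scores: dict[str, np.ndarray] = {}
        val_labels = None
        balanced = None
        if combined_cols:
            base = features.loc[:, combined_cols]
            smote_seed = derive_seed(seed, "smote")
            split_seed = derive_seed(seed, "split")
            if config.classify.smote_after_split:
                split = stratified_split(
                    base, labels, config.classify.train_fraction, seed=split_seed)
                balanced = smote_balance(
                    split.train_data, split.train_labels,
                    smote_k=config.classify.smote_k,
                    target_per_class=config.classify.target_per_class,
                    seed=smote_seed, minority_only=config.classify.minority_only)
                split = Split(balanced.data, balanced.labels,
                              split.val_data, split.val_labels)
            else:
                balanced = smote_balance(
                    base, labels,
                    smote_k=config.classify.smote_k,
                    target_per_class=config.classify.target_per_class,
                    seed=smote_seed, minority_only=config.classify.minority_only)
                split = stratified_split(
                    balanced.data, balanced.labels,
                    config.classify.train_fraction, seed=split_seed)
            val_labels = split.val_labels
            gbt_cfg = GbtConfig(**{**asdict(config.classify.gbt),
                                   "seed": derive_seed(seed, "gbt")})
            for name, cols in feature_sets.items():
                if not cols:
                    models[name] = {"n_features": 0, "skipped": "empty feature set"}
                    continue
                clf = train_gbt(split.train_data.loc[:, cols],
                                split.train_labels, gbt_cfg)
                s = clf.predict_proba(split.val_data.loc[:, cols])
                scores[name] = s
                report = evaluate_scores(
                    name, s, val_labels,
                    threshold=config.evaluate.threshold,
                    n_boot=config.evaluate.n_boot,
                    level=config.evaluate.level,
                    seed=derive_seed(seed, f"bootstrap:{name}"),
                )
                models[name] = {
                    "n_features": len(cols),
                    "features": list(cols),
                    "evaluation": report.to_dict(),
                    "feature_importances": {
                        k: float(v) for k, v in clf.feature_importances.items()},
                }
            if out is not None:
                balanced.write(out / "models" / "balanced_dataset.tsv")
        delong: dict[str, dict] = {}
        names = [n for n in MODEL_NAMES if n in scores]
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                delong[f"{a}_vs_{b}"] = delong_compare(
                    scores[a], scores[b], val_labels).to_dict()
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", e) from e

    # ---- report ------------------------------------------------------------ #
    selection_info = {
        "n_selected": len(selected),
        "n_selected_radiomics": len(selected_rf),
        "n_selected_metabolites": len(selected_met),
        "selected_radiomics": selected_rf,
        "selected_metabolites": selected_met,
        "tau_dc": config.integration.tau_dc,
        "mode": config.integration.selection_mode,
    }
    if truth is not None:
        planted = set(truth.discriminative_ids)
        present = planted & (rf_ids | met_ids)
        unplanted = (rf_ids | met_ids) - planted
        recovered = planted & selected
        false_sel = selected - planted
        selection_info["ground_truth"] = {
            "n_planted": len(planted),
            "n_planted_present": len(present),
            "n_recovered": len(recovered),
            "recovery_rate": len(recovered) / len(present) if present else None,
            "n_false_selected": len(false_sel),
            "false_selection_rate": len(false_sel) / len(unplanted) if unplanted else None,
        }
    report = RunReport(
        selection=selection_info,
        networks={c: _network_summary(per_condition[c]) for c in CONDITIONS},
        enrichment=enrichment_records,
        clusters=cluster_info,
        models=models,
        delong=delong,
        provenance={
            "package_version": __version__,
            "config_hash": config.content_hash(),
            "seed": seed,
            "n_samples": int(len(labels)),
            "n_benign": int((labels == BENIGN).sum()),
            "n_malignant": int((labels == MALIGNANT).sum()),
            "n_radiomics_features": rf_norm.n_features,
            "n_metabolite_features": met_norm.n_features,
            "n_radiomics_prefilter": reader_a.n_features,
        },
    )
    if out is not None:
        report.write_json(out / "report.json")
    return report
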
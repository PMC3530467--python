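"""End-to-end orchestration: from matrices + interactome to accuracy report.

Stage order (combined mode): intersect gene universes -> giant connected
component -> extreme-survivor training set -> per-analyte differential
q-values on the training samples -> edge-weighted networks -> greedy module
search -> permutation significance -> within-analyte merge -> cross-analyte
merge -> module-activity features -> SVM-RFE feature selection -> paired
LOOCV on held-out patients.  A single master seed determines every stochastic
choice, and the JSON report echoes every effective parameter, so any run is
re-executable from its report alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import classify, diffstats, io, significance, synthetic
from .search import Module, SearchConfig, find_modules
from .weighting import WeightedNetwork, assign_edge_weights

logger = logging.getLogger(__name__)

MODES = ("expression", "methylation", "combined")


@dataclass
class PipelineParams:
    """Every tunable of the pipeline, with study defaults."""

    mode: str = "combined"
    alpha: float = 0.8
    max_module_size: int = 50
    seed_rank_limit: int | None = 200
    gain: str = "size-normalized"
    redundancy_threshold: float | None = 0.5
    rank_matched_null: bool = True
    sam_n_perm: int = 200
    n_permutations: int = 100
    p_cutoff: float = 0.05
    overlap_threshold: float = 0.5
    overlap_kind: str = "min"
    kernel: str = "quadratic"
    regularization: float = 1.0
    k_extremes: int = 21
    upper_years: float = 2.5
    lower_years: float = 0.5
    n_repeats: int = 100
    zscore_basis: str = "all"  # "all" (study default) | "train"
    evaluate: bool = True
    use_rfe: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.zscore_basis not in ("all", "train"):
            raise ValueError("zscore_basis must be 'all' or 'train'")


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    rng = np.random.default_rng(master)
    return {n: int(rng.integers(0, 2**31 - 1)) for n in names}


def _discover_analyte(
    tag: str,
    matrix_train: io.OmicsMatrix,
    backbone: nx.Graph,
    params: PipelineParams,
    seeds: dict[str, int],
    counts: dict,
) -> tuple[list[Module], WeightedNetwork, pd.DataFrame]:
    """q-values -> weighted network -> search -> permutation significance ->
    within-analyte merge, for one analyte."""
    sig = diffstats.sam_qvalues(
        matrix_train, n_perm=params.sam_n_perm, seed=seeds[f"sam_{tag}"]
    )
    wnet = assign_edge_weights(backbone, sig, analyte=tag)
    config = SearchConfig(
        alpha=params.alpha,
        max_module_size=params.max_module_size,
        seed_rank_limit=params.seed_rank_limit,
        gain=params.gain,
        redundancy_threshold=params.redundancy_threshold,
    )
    modules = find_modules(wnet, config)
    null = significance.null_distribution(
        wnet, config, n_perm=params.n_permutations, seed=seeds[f"null_{tag}"]
    )
    significant = significance.filter_significant(
        modules, null, cutoff=params.p_cutoff, rank_matched=params.rank_matched_null
    )
    merged = significance.merge_modules(
        significant, threshold=params.overlap_threshold, kind=params.overlap_kind
    )
    prefix = tag[0]
    named = [
        m.with_name(m.name or f"{prefix}{i + 1:02d}")
        for i, m in enumerate(merged)
    ]
    counts[f"{tag}_modules_found"] = len(modules)
    counts[f"{tag}_modules_significant"] = len(significant)
    counts[f"{tag}_modules_merged"] = len(named)
    counts[f"{tag}_null_scores"] = int(null.scores.size)
    return named, wnet, sig


@dataclass
class StudyResult:
    """In-memory result of one full run; ``report`` is JSON-serialisable."""

    report: dict
    modules: dict[str, list[Module]]
    features: dict[str, classify.ActivityMatrix]
    significance: dict[str, pd.DataFrame]


def run_study(
    network: nx.Graph,
    expression: io.OmicsMatrix,
    methylation: io.OmicsMatrix,
    survival: pd.Series,
    params: PipelineParams,
) -> StudyResult:
    """Run the pipeline on in-memory inputs and return modules, features and
    the run report."""
    t0 = time.time()
    seeds = _stage_seeds(
        params.seed,
        ["sam_expression", "sam_methylation", "null_expression", "null_methylation",
         "loocv"],
    )
    counts: dict = {}

    expr, meth, net = io.intersect_gene_universe(expression, methylation, network)
    backbone = io.giant_connected_component(net)
    expr = expr.restrict_genes(backbone.nodes)
    meth = meth.restrict_genes(backbone.nodes)
    counts["genes_backbone"] = backbone.number_of_nodes()
    counts["edges_backbone"] = backbone.number_of_edges()

    long_ids, short_ids = classify.select_training_extremes(
        survival, k=params.k_extremes, upper=params.upper_years, lower=params.lower_years
    )
    train_samples = long_ids + short_ids
    train_labels = pd.Series(
        [io.POSITIVE] * len(long_ids) + [io.NEGATIVE] * len(short_ids),
        index=train_samples,
    )

    # group labels for every sample that clears a survival threshold
    eligible = survival[(survival > params.upper_years) | (survival < params.lower_years)]
    all_labels = pd.Series(
        np.where(eligible > params.upper_years, io.POSITIVE, io.NEGATIVE),
        index=eligible.index,
    )

    def train_view(m: io.OmicsMatrix) -> io.OmicsMatrix:
        return io.OmicsMatrix(m.analyte, m.values[train_samples], train_labels)

    modules: dict[str, list[Module]] = {}
    sig_tables: dict[str, pd.DataFrame] = {}
    wnets: dict[str, WeightedNetwork] = {}
    if params.mode in ("expression", "combined"):
        modules["expression"], wnets["expression"], sig_tables["expression"] = (
            _discover_analyte("expression", train_view(expr), backbone, params, seeds, counts)
        )
    if params.mode in ("methylation", "combined"):
        modules["methylation"], wnets["methylation"], sig_tables["methylation"] = (
            _discover_analyte("methylation", train_view(meth), backbone, params, seeds, counts)
        )
    if params.mode == "combined":
        pooled = modules["expression"] + modules["methylation"]
        combined = significance.merge_modules(
            pooled, threshold=params.overlap_threshold, kind=params.overlap_kind
        )
        modules["combined"] = sorted(combined, key=lambda m: m.name or "")
        counts["combined_modules"] = len(modules["combined"])

    # activity features
    if params.zscore_basis == "all":
        expr_z, _ = classify.zscore_normalize(expr)
        meth_z, _ = classify.zscore_normalize(meth)
    else:
        expr_z, _ = classify.zscore_normalize(train_view(expr))
        meth_z, _ = classify.zscore_normalize(train_view(meth))
    feature_samples = [s for s in all_labels.index if s in expr.samples]

    features: dict[str, classify.ActivityMatrix] = {}
    for marker_set, mods in modules.items():
        if not mods:
            continue
        mode = "combined" if marker_set == "combined" else marker_set
        features[marker_set] = classify.build_feature_matrix(
            mods,
            expr_z if mode in ("expression", "combined") else None,
            meth_z if mode in ("methylation", "combined") else None,
            samples=feature_samples,
            labels=all_labels,
            mode=mode,
        )

    # classification: RFE on the training extremes, paired LOOCV on held out
    accuracy: dict[str, dict] = {}
    selected: dict[str, list[str]] = {}
    if params.evaluate:
        held_pos = [s for s in all_labels.index
                    if all_labels[s] == io.POSITIVE and s not in set(train_samples)]
        held_neg = [s for s in all_labels.index
                    if all_labels[s] == io.NEGATIVE and s not in set(train_samples)]
        k = params.k_extremes
        if len(held_pos) < k or len(held_neg) < k:
            raise ValueError(
                f"evaluation needs {k} held-out samples per group; have "
                f"{len(held_pos)} positive / {len(held_neg)} negative "
                "(set evaluate=False for discovery-only runs)"
            )
        held_pos = sorted(held_pos, key=lambda s: (-survival[s], s))[:k]
        for marker_set, feats in features.items():
            train_feats = feats.subset(samples=train_samples)
            if params.use_rfe:
                subset, path, elim = classify.rfe_select(
                    train_feats, kernel=params.kernel,
                    regularization=params.regularization,
                )
            else:
                subset, path, elim = list(feats.features), [], []
            mean, sd, per_repeat = classify.paired_loocv(
                feats,
                positives=held_pos,
                negative_pool=held_neg,
                n_repeats=params.n_repeats,
                # one seed for every marker set: identical test panels make
                # the accuracy comparison between marker sets paired
                seed=seeds["loocv"],
                kernel=params.kernel,
                regularization=params.regularization,
                feature_subset=subset,
            )
            selected[marker_set] = subset
            accuracy[marker_set] = {
                "mean": round(mean, 6),
                "sd": round(sd, 6),
                "per_repeat": [round(a, 6) for a in per_repeat],
                "n_features_selected": len(subset),
                "rfe_path": [[n, round(a, 6)] for n, a in path],
                "elimination_order": elim,
            }

    report = {
        "skipped_stages": sorted(
            a for a in ("expression", "methylation") if a not in modules
        ),
        "parameters": {k: v for k, v in asdict(params).items()},
        "stage_seeds": seeds,
        "counts": counts,
        "training_samples": {"long": long_ids, "short": short_ids},
        "modules": {
            marker_set: [
                {
                    "name": m.name,
                    "analyte": m.analyte,
                    "n_genes": len(m.genes),
                    "genes": sorted(m.genes),
                    "score": None if m.score is None else round(m.score, 6),
                    "pvalue": m.pvalue,
                }
                for m in mods
            ]
            for marker_set, mods in modules.items()
        },
        "selected_features": selected,
        "accuracy": {
            k: {kk: vv for kk, vv in v.items() if kk != "per_repeat"}
            for k, v in accuracy.items()
        },
        "per_repeat_accuracy": {k: v["per_repeat"] for k, v in accuracy.items()},
    }
    logger.info("run finished in %.1fs", time.time() - t0)
    return StudyResult(
        report=report, modules=modules, features=features, significance=sig_tables
    )


# ---------------------------------------------------------------------------
# file-based entry points


@dataclass
class RunConfig:
    """File paths plus pipeline parameters for a file-based run."""

    expression_path: str
    methylation_path: str = ""
    network_path: str = ""
    labels_path: str | None = None
    survival_path: str = ""
    outdir: str = "netmark_out"
    params: PipelineParams = field(default_factory=PipelineParams)


def read_survival(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: survival table needs (sample, time) columns")
    s = pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str))
    return s.rename("survival_years")


def run_pipeline(config: RunConfig) -> dict:
    """Load inputs, run the study, write GMT / feature TSV / JSON report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = io.read_omics_matrix(config.expression_path, "expression", config.labels_path)
    meth = io.read_omics_matrix(config.methylation_path, "methylation", config.labels_path)
    network = io.read_network(config.network_path)
    survival = read_survival(config.survival_path)

    result = run_study(network, expr, meth, survival, config.params)

    final_set = config.params.mode if config.params.mode != "combined" else "combined"
    if result.modules.get(final_set):
        io.write_modules_gmt(result.modules[final_set], outdir / "modules.gmt")
        io.write_node_attributes(
            result.modules[final_set], outdir / "module_nodes.tsv",
            q_by_analyte={a: t["q"].to_dict() for a, t in result.significance.items()},
        )
    if final_set in result.features:
        result.features[final_set].values.to_csv(
            outdir / "features.tsv", sep="\t", index_label="sample"
        )
    for analyte, table in result.significance.items():
        table.to_csv(outdir / f"gene_significance_{analyte}.tsv", sep="\t",
                     index_label="gene")
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(result.report, sort_keys=True, indent=2) + "\n")
    logger.info("report written to %s", report_path)
    return result.report


def generate_fixture(spec: synthetic.SyntheticCohortSpec, outdir: str | Path) -> list[Path]:
    """Write a synthetic cohort in exactly the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.generate_cohort(spec)
    paths = []
    p = outdir / "expression.tsv"
    io.write_omics_matrix(cohort.expression, p)
    paths.append(p)
    p = outdir / "methylation.tsv"
    io.write_omics_matrix(cohort.methylation, p)
    paths.append(p)
    p = outdir / "network.tsv"
    io.write_network(cohort.network, p)
    paths.append(p)
    p = outdir / "labels.tsv"
    io.write_labels(cohort.expression.labels, p)
    paths.append(p)
    p = outdir / "survival.tsv"
    with open(p, "w") as fh:
        fh.write("sample\tsurvival_years\n")
        for s, t in cohort.survival.items():
            fh.write(f"{s}\t{t:.6g}\n")
    paths.append(p)
    truth_modules = [
        Module(genes=g, analyte=m.analytes if m.analytes != "both" else "merged",
               name=f"planted{i + 1:02d}")
        for i, (m, g) in enumerate(zip(cohort.truth, cohort.truth_genes))
    ]
    p = outdir / "truth_modules.gmt"
    io.write_modules_gmt(truth_modules, p)
    paths.append(p)
    return paths


def alpha_sweep(
    network: nx.Graph,
    expression: io.OmicsMatrix,
    methylation: io.OmicsMatrix,
    survival: pd.Series,
    alphas: list[float],
    params: PipelineParams,
) -> tuple[pd.DataFrame, float]:
    """Full pipeline per alpha; best alpha maximises the combined-marker
    paired-LOOCV accuracy (ties -> smaller alpha)."""
    if not alphas:
        raise ValueError("need at least one alpha")
    rows = []
    for alpha in alphas:
        result = run_study(
            network, expression, methylation, survival, replace(params, alpha=alpha)
        )
        acc = result.report["accuracy"]
        rows.append(
            {
                "alpha": alpha,
                "accuracy_expression": acc.get("expression", {}).get("mean", np.nan),
                "accuracy_methylation": acc.get("methylation", {}).get("mean", np.nan),
                "accuracy_combined": acc.get("combined", {}).get("mean", np.nan),
            }
        )
    table = pd.DataFrame(rows)
    key_col = (
        "accuracy_combined" if params.mode == "combined"
        else f"accuracy_{params.mode}"
    )
    best = table.sort_values([key_col, "alpha"], ascending=[False, True]).iloc[0]
    return table, float(best["alpha"])
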
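"""Configuration and orchestration of the full staging pipeline.

Stages: simulate -> preprocess -> fit -> stage -> associate -> branches
-> enrich -> resistance.  Each stage reads its inputs from the output
directory (or from configured paths), writes TSV artifacts plus a JSON
manifest with content hashes, and is deterministic given config + seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ptio
from .association import celltype_trajectory, geneset_correlation_shift, logistic_assoc, ordinal_assoc
from .branches import (
    bicluster,
    branch_anova_tukey,
    branch_mean_matrix,
    direction_gene_sets,
    fisher_enrichment,
    overlap_upset,
    resistant_de,
    resistant_individuals,
    select_reference_branch,
)
from .ddrtree import DDRTreeParams, fit
from .preprocess import ExpressionMatrix, cpm_filter, de_gene_selection, log_normalize, variance_gene_selection
from .staging import stage_samples
from .synthetic import simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("pseudotree")

STAGES = [
    "simulate",
    "preprocess",
    "fit",
    "stage",
    "associate",
    "branches",
    "enrich",
    "resistance",
]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    output_dir: Path
    seed: int = 0
    verbosity: int = 1
    expression: Path | None = None  # external log-scale expression TSV
    counts: Path | None = None  # external counts TSV (optional)
    metadata: Path | None = None  # external metadata TSV
    gene_sets: Path | None = None  # GMT used by `enrich`
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    ddrtree: dict = field(default_factory=dict)
    staging: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    branches: dict = field(default_factory=dict)
    resistance: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ValueError("config requires output_dir")
        cfg = cls(**{**raw, "output_dir": Path(raw["output_dir"])})
        for name in ("expression", "counts", "metadata", "gene_sets"):
            v = getattr(cfg, name)
            if v is not None:
                setattr(cfg, name, Path(v))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.output_dir.mkdir(parents=True, exist_ok=True)
        for name in ("expression", "counts", "metadata", "gene_sets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.metadata is not None:
            meta = ptio.read_metadata(self.metadata)
            for col in self._referenced_columns():
                if col not in meta.columns:
                    raise ValueError(f"metadata lacks configured column {col!r}")

    def _referenced_columns(self) -> list[str]:
        cols = [
            self.preprocess.get("diagnosis_column", "diagnosis"),
            self.staging.get("orientation_column", "diagnosis"),
            self.association.get("score_column", "score"),
        ]
        return [c for c in cols if c]


def _load_inputs(cfg: PipelineConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    out = cfg.output_dir
    expr_path = cfg.expression or out / "expression.tsv"
    meta_path = cfg.metadata or out / "metadata.tsv"
    if not expr_path.exists() or not meta_path.exists():
        raise FileNotFoundError(
            "expression/metadata not found; run `simulate` first or configure paths"
        )
    expr = ptio.read_expression(expr_path, scale="log_cpm")
    meta = ptio.read_metadata(meta_path)
    missing = set(expr.sample_ids) - set(map(str, meta.index))
    if missing:
        raise ValueError(f"metadata missing {len(missing)} sample(s)")
    meta = meta.loc[[str(s) for s in expr.sample_ids]]
    return expr, meta


def _case_indicator(meta: pd.DataFrame, cfg: PipelineConfig) -> np.ndarray:
    col = cfg.preprocess.get("diagnosis_column", "diagnosis")
    case = cfg.preprocess.get("case_label", "case")
    if col not in meta.columns:
        raise ValueError(f"metadata lacks column {col!r}")
    return (meta[col] == case).to_numpy()


def _run_simulate(cfg: PipelineConfig) -> list[Path]:
    out = cfg.output_dir
    opts = dict(cfg.simulate)
    cohort, truth = simulate_cohort(seed=cfg.seed, **opts)
    ptio.write_expression(cohort.expression_matrix(), out / "expression.tsv")
    artifacts = [out / "expression.tsv"]
    if cohort.counts is not None:
        counts = ExpressionMatrix(cohort.counts, cohort.gene_ids, cohort.sample_ids, "counts")
        ptio.write_expression(counts, out / "counts.tsv")
        artifacts.append(out / "counts.tsv")
    ptio.write_metadata(cohort.metadata, out / "metadata.tsv")
    sets = dict(cohort.marker_sets)
    if cohort.gwas_set:
        sets["gwas"] = cohort.gwas_set
    if truth.resistant_genes:
        sets["resistant_cluster"] = truth.resistant_genes
    ptio.write_gene_sets(sets, out / "sets.gmt")
    truth_df = pd.DataFrame(
        {
            "true_pseudotime": truth.true_pseudotime,
            "true_branch": truth.true_branch,
            "resistant": [s in set(truth.resistant_samples) for s in cohort.sample_ids],
        },
        index=pd.Index(cohort.sample_ids, name="sample_id"),
    )
    ptio.write_metadata(truth_df, out / "truth.tsv")
    programs = pd.DataFrame(
        {"program": list(truth.gene_programs.values())},
        index=pd.Index(list(truth.gene_programs.keys()), name="gene_id"),
    )
    ptio.write_metadata(programs, out / "gene_programs.tsv")
    (out / "generator.yaml").write_text(
        yaml.safe_dump({"seed": cfg.seed, "options": opts, "label_params": truth.label_params})
    )
    artifacts += [out / "metadata.tsv", out / "sets.gmt", out / "truth.tsv",
                  out / "gene_programs.tsv", out / "generator.yaml"]
    return artifacts


def _run_preprocess(cfg: PipelineConfig) -> list[Path]:
    out = cfg.output_dir
    opts = cfg.preprocess
    if opts.get("use_counts"):
        counts_path = cfg.counts or out / "counts.tsv"
        counts = ptio.read_expression(counts_path, scale="counts")
        counts = cpm_filter(
            counts,
            cpm_threshold=opts.get("cpm_threshold", 1.0),
            sample_fraction=opts.get("sample_fraction", 0.5),
        )
        expr = log_normalize(counts)
        meta = ptio.read_metadata(cfg.metadata or out / "metadata.tsv")
        meta = meta.loc[[str(s) for s in expr.sample_ids]]
    else:
        expr, meta = _load_inputs(cfg)
    method = opts.get("selection", "de")
    if method == "de":
        sel = de_gene_selection(expr, _case_indicator(meta, cfg), opts.get("fdr", 0.10))
    elif method == "variance":
        sel = variance_gene_selection(expr, opts.get("top_n", min(2000, expr.n_genes)))
    else:
        raise ValueError(f"unknown selection method {method!r}")
    if not sel.kept_gene_ids:
        raise ValueError("gene selection kept no genes")
    filtered = expr.subset_genes(sel.kept_gene_ids)
    ptio.write_expression(filtered, out / "expression_filtered.tsv")
    sel.table.to_csv(out / "gene_selection.tsv", sep="\t", index=False)
    return [out / "expression_filtered.tsv", out / "gene_selection.tsv"]


def _filtered_expression(cfg: PipelineConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    out = cfg.output_dir
    path = out / "expression_filtered.tsv"
    if not path.exists():
        raise FileNotFoundError("expression_filtered.tsv not found; run `preprocess` first")
    expr = ptio.read_expression(path, scale="log_cpm")
    meta = ptio.read_metadata(cfg.metadata or out / "metadata.tsv")
    meta = meta.loc[[str(s) for s in expr.sample_ids]]
    return expr, meta


def _run_fit(cfg: PipelineConfig) -> list[Path]:
    out = cfg.output_dir
    expr, _ = _filtered_expression(cfg)
    params = DDRTreeParams(seed=cfg.seed, **cfg.ddrtree)
    model = fit(expr.values, params)
    ptio.save_model(model, out / "model")
    d = out / "model"
    return sorted(d.glob("*"))


def _run_stage(cfg: PipelineConfig) -> list[Path]:
    out = cfg.output_dir
    expr, meta = _filtered_expression(cfg)
    model = ptio.load_model(out / "model")
    labels = None
    col = cfg.staging.get("orientation_column", "diagnosis")
    if col and col in meta.columns:
        positive = cfg.staging.get("positive_label", "case")
        labels = (meta[col] == positive).to_numpy().astype(float)
    graph, result = stage_samples(
        model,
        orientation_labels=labels,
        root_override=cfg.staging.get("root_override"),
        centers_only=cfg.staging.get("centers_only", False),
    )
    df = result.to_frame(expr.sample_ids)
    ptio.write_metadata(df, out / "staging.tsv")
    vtx = pd.DataFrame(graph.vertices, columns=[f"dim{i}" for i in range(graph.vertices.shape[1])])
    vtx.index.name = "vertex"
    vtx.to_csv(out / "graph_vertices.tsv", sep="\t")
    edges = pd.DataFrame(
        {
            "from": [e[0] for e in graph.edges],
            "to": [e[1] for e in graph.edges],
            "length": graph.lengths,
            "branch": [graph.branch_of_edge[e] for e in graph.edges],
        }
    )
    edges.to_csv(out / "graph_edges.tsv", sep="\t", index=False)
    return [out / "staging.tsv", out / "graph_vertices.tsv", out / "graph_edges.tsv"]


def _staged(cfg: PipelineConfig) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    out = cfg.output_dir
    path = out / "staging.tsv"
    if not path.exists():
        raise FileNotFoundError("staging.tsv not found; run `stage` first")
    expr, meta = _filtered_expression(cfg)
    staging = ptio.read_metadata(path)
    return expr, meta, staging.loc[[str(s) for s in expr.sample_ids]]


def _run_associate(cfg: PipelineConfig) -> list[Path]:
    out = cfg.output_dir
    expr, meta, staging = _staged(cfg)
    pt = staging["pseudotime"].to_numpy()
    rows = []
    case = _case_indicator(meta, cfg)
    res = logistic_assoc(pt, case.astype(float))
    rows.append(("diagnosis", "logistic", res))
    score_col = cfg.association.get("score_column", "score")
    if score_col in meta.columns:
        res = ordinal_assoc(pt, meta[score_col].to_numpy())
        rows.append((score_col, "ordinal", res))
    dosage_col = cfg.association.get("dosage_column", "dosage")
    if dosage_col in meta.columns:
        res = ordinal_assoc(pt, meta[dosage_col].to_numpy())
        rows.append((dosage_col, "ordinal", res))
    assoc = pd.DataFrame(
        [
            {
                "outcome": name,
                "model": kind,
                "coef": r.coef,
                "se": r.se,
                "statistic": r.statistic,
                "p": r.p,
                "n": r.n,
                "converged": r.converged,
            }
            for name, kind, r in rows
        ]
    )
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    artifacts = [out / "associations.tsv"]

    sets_path = cfg.gene_sets or out / "sets.gmt"
    if sets_path.exists():
        sets = ptio.read_gene_sets(sets_path)
        gwas_name = cfg.association.get("gwas_set_name", "gwas")
        if gwas_name in sets:
            table, shift, p = geneset_correlation_shift(expr, pt, sets[gwas_name])
            table.to_csv(out / "correlation_shift.tsv", sep="\t", index=False)
            pd.DataFrame([{"set": gwas_name, "shift": shift, "p": p}]).to_csv(
                out / "correlation_shift_summary.tsv", sep="\t", index=False
            )
            artifacts += [out / "correlation_shift.tsv", out / "correlation_shift_summary.tsv"]
        marker_names = cfg.association.get(
            "marker_sets", ["neuron", "microglia", "astrocyte", "oligodendrocyte"]
        )
        markers = {n: sets[n] for n in marker_names if n in sets}
        markers = {
            n: [g for g in genes if g in set(expr.gene_ids)] for n, genes in markers.items()
        }
        markers = {n: genes for n, genes in markers.items() if genes}
        if markers:
            trajs = celltype_trajectory(
                expr, pt, markers, spline_df=cfg.association.get("spline_df", 3.0)
            )
            tdf = pd.DataFrame(
                [
                    {
                        "cell_type": t.cell_type,
                        "n_genes": len(t.genes_used),
                        "slope": t.slope,
                        "slope_p": t.slope_p,
                    }
                    for t in trajs.values()
                ]
            )
            tdf.to_csv(out / "trajectories.tsv", sep="\t", index=False)
            curves = pd.DataFrame(
                {t.cell_type: t.mean_curve for t in trajs.values()},
                index=pd.Index(next(iter(trajs.values())).grid, name="pseudotime"),
            )
            curves.to_csv(out / "trajectory_curves.tsv", sep="\t")
            artifacts += [out / "trajectories.tsv", out / "trajectory_curves.tsv"]
    return artifacts


def _run_branches(cfg: PipelineConfig) -> list[Path]:
    out = cfg.output_dir
    expr, meta, staging = _staged(cfg)
    branch = staging["branch"].to_numpy()
    control = ~_case_indicator(meta, cfg)
    ref = select_reference_branch(branch, control)
    fdr = cfg.branches.get("fdr", 0.05)
    table = branch_anova_tukey(expr, branch, ref, fdr=fdr)
    table.to_csv(out / "branch_de.tsv", sep="\t", index=False)
    sets = direction_gene_sets(table, fdr=fdr)
    named = {f"branch{b}_{d}": genes for (b, d), genes in sets.items()}
    ptio.write_gene_sets(named, out / "branch_direction_sets.gmt")
    bm = branch_mean_matrix(expr, branch)
    bm.to_csv(out / "branch_means.tsv", sep="\t")
    labels, branch_order, gene_order = bicluster(
        bm, n_gene_clusters=cfg.branches.get("n_gene_clusters", 6)
    )
    pd.DataFrame(
        {"gene": bm.index, "cluster": labels}
    ).to_csv(out / "gene_clusters.tsv", sep="\t", index=False)
    (out / "reference_branch.txt").write_text(f"{ref}\n")
    return [
        out / "branch_de.tsv",
        out / "branch_direction_sets.gmt",
        out / "branch_means.tsv",
        out / "gene_clusters.tsv",
        out / "reference_branch.txt",
    ]


def _run_enrich(cfg: PipelineConfig) -> list[Path]:
    out = cfg.output_dir
    expr, _, _ = _staged(cfg)
    sets_path = cfg.gene_sets or out / "sets.gmt"
    if not sets_path.exists():
        raise FileNotFoundError("no gene-set GMT configured and sets.gmt absent")
    gene_sets = ptio.read_gene_sets(sets_path)
    queries = ptio.read_gene_sets(out / "branch_direction_sets.gmt")
    frames = []
    for name, genes in queries.items():
        enr = fisher_enrichment(genes, gene_sets, expr.gene_ids, fdr=cfg.branches.get("fdr", 0.05))
        enr.insert(0, "query", name)
        frames.append(enr)
    res = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    res.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return [out / "enrichment.tsv"]


def _run_resistance(cfg: PipelineConfig) -> list[Path]:
    out = cfg.output_dir
    expr, meta, staging = _staged(cfg)
    # the resistant DE runs genome-wide (all measured genes), not just the
    # manifold gene subset, mirroring the array-wide replication analysis
    full_path = cfg.expression or out / "expression.tsv"
    if full_path.exists():
        full = ptio.read_expression(full_path, scale="log_cpm")
        if full.sample_ids == expr.sample_ids:
            expr = full
    pt = staging["pseudotime"].to_numpy()
    control = ~_case_indicator(cfg=cfg, meta=meta)
    quantile = cfg.resistance.get("quantile", 0.8)
    fdr = cfg.resistance.get("fdr", 0.05)
    resistant = resistant_individuals(pt, control, quantile=quantile, sample_ids=expr.sample_ids)
    flags = np.isin(expr.sample_ids, resistant)
    pd.DataFrame({"sample_id": resistant}).to_csv(out / "resistant_samples.tsv", sep="\t", index=False)
    artifacts = [out / "resistant_samples.tsv"]
    if flags.sum() >= 2 and (~flags).sum() >= 2:
        up, down, table = resistant_de(expr, flags, fdr=fdr)
        table.to_csv(out / "resistant_de.tsv", sep="\t", index=False)
        artifacts.append(out / "resistant_de.tsv")
        clusters_path = out / "gene_clusters.tsv"
        if clusters_path.exists() and (up or down):
            clusters = pd.read_csv(clusters_path, sep="\t")
            named = {
                f"cluster{c}": grp["gene"].tolist()
                for c, grp in clusters.groupby("cluster")
            }
            lists = {"resistant_up": up, "resistant_down": down}
            lists = {k: v for k, v in lists.items() if v}
            pair, exclusive = overlap_upset({**lists, **named}, expr.gene_ids)
            pair.to_csv(out / "resistant_overlap.tsv", sep="\t", index=False)
            excl = pd.DataFrame(
                [{"lists": "&".join(k), "count": v} for k, v in sorted(exclusive.items())]
            )
            excl.to_csv(out / "resistant_exclusive_counts.tsv", sep="\t", index=False)
            artifacts += [out / "resistant_overlap.tsv", out / "resistant_exclusive_counts.tsv"]
    return artifacts


_RUNNERS = {
    "simulate": _run_simulate,
    "preprocess": _run_preprocess,
    "fit": _run_fit,
    "stage": _run_stage,
    "associate": _run_associate,
    "branches": _run_branches,
    "enrich": _run_enrich,
    "resistance": _run_resistance,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict[str, list[Path]]:
    """Run the requested stages (default: all, in order).  Any stage error
    is re-raised with the stage named; each stage writes a manifest."""
    if stages is None or stages == ["all"]:
        stages = list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    level = {0: logging.WARNING, 1: logging.INFO}.get(cfg.verbosity, logging.DEBUG)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
    results: dict[str, list[Path]] = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        try:
            artifacts = _RUNNERS[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        params_of = {
            "simulate": cfg.simulate, "preprocess": cfg.preprocess, "fit": cfg.ddrtree,
            "stage": cfg.staging, "associate": cfg.association, "branches": cfg.branches,
            "enrich": cfg.branches, "resistance": cfg.resistance,
        }
        ptio.write_manifest(
            cfg.output_dir,
            stage,
            inputs={
                k: getattr(cfg, k)
                for k in ("expression", "counts", "metadata", "gene_sets")
                if getattr(cfg, k) is not None
            },
            params=params_of[stage],
            seed=cfg.seed,
            artifacts=artifacts,
        )
        results[stage] = artifacts
    return results
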
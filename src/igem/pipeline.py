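"""End-to-end pipeline driver.

Runs the stages of the iGEM analysis in dependency order —

    simulate -> foci -> screen -> labels -> assoc -> methylome -> rrbs
             -> expr -> report

— with every artifact written as CSV/TSV/JSON under one output directory, a
resolved copy of the configuration next to the outputs, and a plain-text +
JSONL log recording every threshold actually applied.  Stages are idempotent
given identical inputs and configuration, and a stage fails with a clear
message naming the stage to run first when its upstream artifact is absent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity, association, imaging, methylome, screen, synthetic
from .config import ConfigError, PipelineConfig

STAGES = [
    "simulate", "foci", "screen", "labels", "assoc",
    "methylome", "rrbs", "expr", "report",
]

# stage -> (upstream stage, artifact that must exist)
_REQUIRES = {
    "foci": ("simulate", "images"),
    "screen": ("simulate", "screen_table.csv"),
    "labels": ("simulate", "genotox.csv"),
    "assoc": ("labels", "labels.csv"),
    "methylome": ("simulate", "beta.csv"),
    "rrbs": ("simulate", "rrbs_control.tsv"),
    "expr": ("simulate", "expression.csv"),
    "report": ("screen", "categories.csv"),
}


class StageError(RuntimeError):
    pass


class _Log:
    def __init__(self, out: Path):
        self.text = out / "igem.log"
        self.jsonl = out / "igem.log.jsonl"

    def event(self, stage: str, message: str, **values) -> None:
        with open(self.text, "a") as fh:
            fh.write(f"[{stage}] {message} {values if values else ''}\n")
        with open(self.jsonl, "a") as fh:
            fh.write(json.dumps({"stage": stage, "message": message, **values}) + "\n")


def run_pipeline(
    cfg: PipelineConfig, stages: list[str] | None = None, out_dir: str | None = None
) -> dict:
    """Run the requested stages (all by default) and return the report."""
    requested = stages or STAGES
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage names: {sorted(unknown)}")
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(str(out / "resolved_config.yaml"))
    log = _Log(out)
    report: dict = {}
    for stage in STAGES:
        if stage not in requested:
            continue
        need = _REQUIRES.get(stage)
        if need and not (out / need[1]).exists():
            raise StageError(
                f"stage {stage!r} needs artifact {need[1]!r}; run stage {need[0]!r} first"
            )
        result = _RUNNERS[stage](cfg, out, log)
        if stage == "report":
            report = result
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    sim = cfg.sim
    table, struth = synthetic.gen_screen_table(sim)
    table.to_csv(out / "screen_table.csv")
    struth.categories.to_csv(out / "true_categories.csv")
    snapshot, atruth = synthetic.gen_activity_db(sim)
    for name, df in snapshot.items():
        df.to_csv(out / f"{name}.csv", index=False)
    atruth.labels.to_csv(out / "true_labels.csv")
    beta, ann, btruth = synthetic.gen_beta_matrix(sim)
    beta.to_csv(out / "beta.csv")
    ann.to_csv(out / "beta_annotation.csv")
    rrbs, rrbs_ann, _ = synthetic.gen_rrbs_calls(sim)
    for sample, calls in rrbs.items():
        calls.to_csv(out / f"rrbs_{_safe(sample)}.tsv", sep="\t", index=False)
    rrbs_ann.to_csv(out / "rrbs_annotation.tsv", sep="\t", index=False)
    expr, _ = synthetic.gen_expression(sim, btruth)
    expr.to_csv(out / "expression.csv")
    img_dir = out / "images"
    for chem in sim.effect_multipliers:
        for w in range(cfg.n_wells_per_condition):
            images, _ = synthetic.gen_plate_images(sim, chem, well_index=w)
            synthetic.write_plate_tiffs(images, img_dir, f"{_safe(chem)}_w{w}")
    log.event("simulate", "synthetic inputs written",
              n_chemicals=sim.n_chemicals, seed=sim.seed)


def _stage_foci(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    import tifffile

    img_dir = out / "images"
    wells: dict[str, list] = {}
    for path in sorted(img_dir.glob("*.tif")):
        well_id = path.stem.rsplit("_f", 1)[0]
        wells.setdefault(well_id, []).append(path)
    rows = []
    for well_id, paths in sorted(wells.items()):
        fields = [tifffile.imread(p) for p in paths]
        wm = imaging.quantify_well(
            fields,
            well_id,
            min_area_px=cfg.nucleus_min_area_px,
            max_area_px=cfg.nucleus_max_area_px,
            spot_sigma_px=cfg.spot_sigma_px,
            k_threshold=cfg.k_threshold,
        )
        rows.append(
            {
                "well_id": well_id,
                "chemical": well_id.rsplit("_w", 1)[0],
                "nuclei_count": wm.nuclei_count,
                "foci_intensity_per_nucleus": wm.foci_intensity_per_nucleus,
                "foci_area_per_nucleus": wm.foci_area_per_nucleus,
                "foci_count_per_nucleus": wm.foci_count_per_nucleus,
            }
        )
    pd.DataFrame(rows).to_csv(out / "well_measures.csv", index=False)
    log.event("foci", "wells quantified", n_wells=len(wells),
              k_threshold=cfg.k_threshold, spot_sigma_px=cfg.spot_sigma_px)


def _stage_screen(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    table = pd.read_csv(out / "screen_table.csv", index_col=0)
    gated = screen.viability_gate(table, cfg.viability_min_fraction)
    usable = gated[gated["viable"]]
    linkage, clusters = screen.cluster_chemicals(usable, k=cfg.n_clusters)
    calls = screen.assign_categories(clusters, usable, delta=cfg.category_delta)
    cat = pd.DataFrame(
        {
            "chemical": [c.chemical for c in calls],
            "cluster_id": [c.cluster_id for c in calls],
            "category": [c.category for c in calls],
        }
    ).set_index("chemical")
    cat.to_csv(out / "categories.csv")
    gated.to_csv(out / "screen_table_gated.csv")
    with open(out / "dendrogram.nwk", "w") as fh:
        fh.write(screen.linkage_to_newick(linkage, list(usable.index)))
    log.event("screen", "categories assigned",
              viability_min_fraction=cfg.viability_min_fraction,
              k=cfg.n_clusters, delta=cfg.category_delta,
              n_flagged=int((~gated["viable"]).sum()))


def _stage_labels(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    snapshot = {
        name: pd.read_csv(out / f"{name}.csv")
        for name in ("genotox", "ccris", "iarc", "tox21")
    }
    matrix = activity.build_activity_matrix(snapshot)
    matrix.to_csv(out / "labels.csv")
    log.event("labels", "activity matrix built", n_labeled=len(matrix),
              n_activities=matrix.shape[1])


def _stage_assoc(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    matrix = activity.matrix_from_csv(out / "labels.csv")
    table = pd.read_csv(out / "screen_table.csv", index_col=0)
    features = association.encode_activities(matrix, encoding=cfg.encoding)
    for param in screen.RATIO_COLUMNS:
        ranking = association.rf_importance(
            features, table[param], n_trees=cfg.n_trees, seed=cfg.rf_seed
        )
        ranking.to_csv(out / f"ranking_{param}.csv", index=False)
    log.event("assoc", "importance rankings written",
              n_trees=cfg.n_trees, seed=cfg.rf_seed, encoding=cfg.encoding)


def _stage_methylome(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    beta = pd.read_csv(out / "beta.csv", index_col=0)
    ann = pd.read_csv(out / "beta_annotation.csv", index_col=0)
    ann["gene"] = ann["gene"].fillna("")
    treatments = [c for c in beta.columns if c != "control"]
    summary_rows, region_rows = [], []
    calls = {}
    for chem in treatments:
        _, mean = methylome.beta_log2_summary(beta[chem], beta["control"], cfg.beta_floor)
        scores = methylome.diff_score(beta[chem], beta["control"], sigma_beta=cfg.sigma_beta)
        called = methylome.call_hypermethylated(scores, cfg.diff_score_threshold)
        calls[chem] = called
        summary_rows.append({"chemical": chem, "mean_log2_ratio": mean, "n_hyper_called": len(called)})
        methylome.calls_to_bed(
            called.join(ann).rename(columns={"chromosome": "chrom", "position": "pos"})
        ).to_csv(out / f"hyper_sites_{_safe(chem)}.bed", sep="\t", header=False, index=False)
        for axis, dist in methylome.region_distribution(called, ann).items():
            for name, row in dist.iterrows():
                region_rows.append(
                    {"chemical": chem, "axis": axis, "class": name,
                     "count": int(row["count"]), "proportion": row["proportion"]}
                )
    pd.DataFrame(summary_rows).to_csv(out / "beta_summary.csv", index=False)
    pd.DataFrame(region_rows).to_csv(out / "region_distribution.csv", index=False)
    panel = [g for g in synthetic.panel_truth(cfg.sim).panel]
    for chem in ("etoposide", "propyl_gallate"):
        if chem in beta.columns:
            pm = methylome.gene_panel_methylation(beta, ann, panel, chem, floor=cfg.beta_floor)
            pm.to_csv(out / f"panel_methylation_{_safe(chem)}.csv")
    if {"etoposide", "propyl_gallate"} <= set(treatments):
        common = methylome.common_hyper_genes(
            calls["etoposide"], calls["propyl_gallate"], beta, ann,
            "etoposide", "propyl_gallate",
            fold_threshold=cfg.fold_threshold, floor=cfg.beta_floor,
        )
        (out / "common_hyper_genes.txt").write_text("\n".join(sorted(common)) + "\n")
    fc = np.log2(
        beta[treatments].clip(lower=cfg.beta_floor).div(
            beta["control"].clip(lower=cfg.beta_floor), axis=0
        )
    )
    methylome.tsne_embed(fc.T, seed=cfg.tsne_seed).to_csv(out / "tsne_beta.csv")
    log.event("methylome", "array analytics written",
              diff_score_threshold=cfg.diff_score_threshold,
              sigma_beta=cfg.sigma_beta, fold_threshold=cfg.fold_threshold)


def _stage_rrbs(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    samples = {}
    for path in sorted(out.glob("rrbs_*.tsv")):
        name = path.stem[len("rrbs_"):]
        if name == "annotation":
            continue
        samples[name] = pd.read_csv(path, sep="\t")
    ann = pd.read_csv(out / "rrbs_annotation.tsv", sep="\t").fillna({"gene": ""})
    filtered, filter_rows = {}, []
    for name, calls in samples.items():
        kept, info = methylome.rrbs_filter(
            calls, cfg.rrbs_min_coverage, cfg.rrbs_max_coverage_percentile
        )
        filtered[name] = kept
        filter_rows.append({"sample": name, **info, "n_kept": len(kept)})
    pd.DataFrame(filter_rows).to_csv(out / "rrbs_filter_summary.csv", index=False)
    norm = methylome.rrbs_normalize_coverage(filtered)
    rows = []
    control = norm["control"]
    genes = [g for g in sorted(set(ann["gene"])) if g]
    gene_tables = {}
    for name, calls in norm.items():
        if name == "control":
            continue
        tiles = methylome.rrbs_tile(calls, cfg.rrbs_window)
        b_t, b_c = methylome.rrbs_beta(calls), methylome.rrbs_beta(control)
        common_sites = b_t.index.intersection(b_c.index)
        lr = np.log2(
            b_t.loc[common_sites].clip(lower=cfg.beta_floor)
            / b_c.loc[common_sites].clip(lower=cfg.beta_floor)
        )
        rows.append({"sample": name, "mean_log2_ratio": float(lr.mean()), "n_tiles": len(tiles)})
        gm = methylome.rrbs_gene_methylation(calls, control, ann, genes, floor=cfg.beta_floor)
        gm.to_csv(out / f"rrbs_gene_methylation_{_safe(name)}.csv")
        gene_tables[name] = gm
    pd.DataFrame(rows).to_csv(out / "rrbs_summary.csv", index=False)
    if {"etoposide", "propyl_gallate"} <= set(gene_tables):
        ge, gp = gene_tables["etoposide"], gene_tables["propyl_gallate"]
        confirmed = sorted(
            g for g in genes
            if ge.loc[g, "mean_log2_ratio"] > cfg.rrbs_gene_min_effect
            and gp.loc[g, "mean_log2_ratio"] > cfg.rrbs_gene_min_effect
        )
        (out / "rrbs_confirmed_genes.txt").write_text("\n".join(confirmed) + "\n")
    log.event("rrbs", "RRBS analytics written",
              min_coverage=cfg.rrbs_min_coverage,
              max_percentile=cfg.rrbs_max_coverage_percentile,
              window=cfg.rrbs_window, gene_min_effect=cfg.rrbs_gene_min_effect)


def _stage_expr(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    expr = pd.read_csv(out / "expression.csv", index_col=0)
    res = methylome.expression_analysis(expr)
    res.fold_change.to_csv(out / "fold_change.csv")
    (out / "common_down_genes.txt").write_text("\n".join(sorted(res.common_down)) + "\n")
    if res.linkage is not None:
        with open(out / "expression_dendrogram.nwk", "w") as fh:
            fh.write(screen.linkage_to_newick(res.linkage, res.treatment_order))
    log.event("expr", "expression analytics written",
              n_common_down=len(res.common_down),
              n_excluded=len(res.excluded_genes))


def _stage_report(cfg: PipelineConfig, out: Path, log: _Log) -> dict:
    report: dict = {}
    cat = pd.read_csv(out / "categories.csv", index_col=0)
    report["category_counts"] = cat["category"].value_counts().to_dict()
    truth_path = out / "true_categories.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, index_col=0)["category"]
        agree = (cat["category"] == truth.loc[cat.index]).mean()
        report["category_recovery"] = float(agree)
    if (out / "labels.csv").exists():
        report["n_labeled_chemicals"] = int(len(pd.read_csv(out / "labels.csv")))
    rankings = {}
    for path in sorted(out.glob("ranking_*.csv")):
        df = pd.read_csv(path)
        rankings[path.stem[len("ranking_"):]] = df[df["top"]]["activity"].tolist()
    if rankings:
        report["top_activities"] = rankings
    if (out / "region_distribution.csv").exists():
        rd = pd.read_csv(out / "region_distribution.csv")
        island = rd[(rd["axis"] == "cpg_context") & (rd["class"] == "island")]
        report["island_proportions"] = dict(
            zip(island["chemical"], island["proportion"].round(4))
        )
    common_down_path = out / "common_down_genes.txt"
    funnel = None
    if common_down_path.exists():
        common_down = set(common_down_path.read_text().split())
        pm = {}
        for chem in ("etoposide", "propyl_gallate"):
            p = out / f"panel_methylation_{_safe(chem)}.csv"
            if p.exists():
                pm[chem] = pd.read_csv(p, index_col=0)
        if len(pm) == 2:
            funnel = methylome.methylation_expression_funnel(
                common_down, pm["etoposide"], pm["propyl_gallate"],
                min_effect=cfg.min_meth_effect,
            )
            report["funnel"] = {
                "common_down": funnel[0],
                "hyper_either": funnel[1],
                "hyper_both": funnel[2],
            }
    confirmed_path = out / "rrbs_confirmed_genes.txt"
    if confirmed_path.exists():
        report["rrbs_confirmed_genes"] = confirmed_path.read_text().split()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.event("report", "report assembled")
    return report


def _safe(name: str) -> str:
    return name.replace("/", "_").replace(" ", "_")


_RUNNERS = {
    "simulate": _stage_simulate,
    "foci": _stage_foci,
    "screen": _stage_screen,
    "labels": _stage_labels,
    "assoc": _stage_assoc,
    "methylome": _stage_methylome,
    "rrbs": _stage_rrbs,
    "expr": _stage_expr,
    "report": _stage_report,
}
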
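"""Methylome and expression analytics.

Array side: per-site log2 beta ratios to the vehicle control, a signed
DiffScore (``sgn(d-beta) * -10 log10 p``, so |13.0103| corresponds to
p = 0.05) with hypermethylated calls at score > 13, genome-area
distributions of called sites, gene-panel methylation summaries, and the
high-fold-change common-hyper gene set.

Because a single array per condition carries no replicate variance, the
p-value entering the DiffScore is computed from a Gaussian measurement-error
model on beta with a configurable noise scale ``sigma_beta`` (default 0.03):
``p = 2 Phi(-|d-beta| / (sqrt(2) sigma_beta))``.  This model is declared, not
claimed identical to any scanner software's proprietary score.

RRBS side: methylKit-style coverage filtering (drop sites below 10 reads and
above the per-sample 99.9th coverage percentile), median-based coverage
normalization, and 1000-base non-overlapping window tiling with strands
merged (non-directional protocol).

Expression side: RPKM fold changes to the vehicle control, hierarchical
clustering of treatments (Euclidean distance, average linkage), the
commonly down-regulated gene set, and the methylation-expression funnel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.manifold import TSNE

DIFF_SCORE_P05 = -10.0 * np.log10(0.05)  # 13.0103


class MethylomeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# beta-value analytics
# ---------------------------------------------------------------------------

def beta_log2_ratio(
    treated: pd.Series, control: pd.Series, floor: float = 1e-3
) -> pd.Series:
    """Per-site log2(beta_t / beta_c), with beta floored at ``floor`` to
    avoid infinities at fully unmethylated sites."""
    t = treated.clip(lower=floor)
    c = control.clip(lower=floor)
    if not t.index.equals(c.index):
        raise MethylomeError("treated and control probes do not match")
    return np.log2(t / c)


def beta_log2_summary(
    treated: pd.Series, control: pd.Series, floor: float = 1e-3
) -> tuple[pd.Series, float]:
    """Per-site log2 ratios plus their genome-wide mean."""
    ratios = beta_log2_ratio(treated, control, floor)
    return ratios, float(ratios.mean())


def diff_score(
    beta_t: pd.Series | float,
    beta_c: pd.Series | float,
    p: pd.Series | float | None = None,
    sigma_beta: float = 0.03,
) -> pd.DataFrame | float:
    """Signed differential-methylation score ``sgn(d-beta) * -10 log10 p``.

    If ``p`` is not given it comes from the Gaussian beta-noise model with
    scale ``sigma_beta``.  Scalar inputs return a scalar score; Series
    inputs return a DataFrame with delta_beta, p_value and diff_score.
    """
    scalar = np.isscalar(beta_t) and np.isscalar(beta_c)
    t = np.atleast_1d(np.asarray(beta_t, dtype=float))
    c = np.atleast_1d(np.asarray(beta_c, dtype=float))
    delta = t - c
    if p is None:
        z = np.abs(delta) / (np.sqrt(2.0) * sigma_beta)
        pv = 2.0 * stats.norm.sf(z)
    else:
        pv = np.atleast_1d(np.asarray(p, dtype=float))
    pv = np.clip(pv, 1e-300, 1.0)
    score = np.sign(delta) * (-10.0 * np.log10(pv))
    if scalar:
        return float(score[0])
    index = beta_t.index if isinstance(beta_t, pd.Series) else pd.RangeIndex(len(delta))
    return pd.DataFrame(
        {"delta_beta": delta, "p_value": pv, "diff_score": score}, index=index
    )


def call_hypermethylated(
    scores: pd.DataFrame, threshold: float = DIFF_SCORE_P05
) -> pd.DataFrame:
    """Differentially hypermethylated sites: diff_score strictly above the
    p = 0.05 score (13.0103, printed as "> 13"), i.e. p strictly below 0.05."""
    return scores[scores["diff_score"] > threshold]


def region_distribution(
    called: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Counts and proportions of called sites per RefGene group and per CpG
    context.  Proportions sum to 1 on each axis; an empty call set yields
    empty (flagged) tables."""
    out = {}
    ann = annotation.loc[annotation.index.intersection(called.index)]
    for axis in ("refgene_group", "cpg_context"):
        counts = ann.loc[called.index.intersection(ann.index), axis].value_counts()
        table = counts.rename("count").to_frame()
        table["proportion"] = (
            table["count"] / table["count"].sum() if len(table) else np.nan
        )
        out[axis] = table
    return out


def gene_panel_methylation(
    betas: pd.DataFrame,
    annotation: pd.DataFrame,
    genes: list[str],
    treated: str,
    control: str = "control",
    floor: float = 1e-3,
) -> pd.DataFrame:
    """Per-gene CpG-site count and mean log2 methylation ratio.

    A probe belongs to a gene when the gene symbol appears in the probe's
    (possibly multi-valued, ``;``-separated) gene annotation.  Genes with no
    probes report n = 0 and an undefined mean.
    """
    ratios = beta_log2_ratio(betas[treated], betas[control], floor)
    gene_lists = annotation["gene"].fillna("").astype(str).str.split(";")
    rows = []
    for gene in genes:
        mask = gene_lists.map(lambda gl: gene in gl)
        probes = annotation.index[mask].intersection(ratios.index)
        rows.append(
            {
                "gene": gene,
                "n_sites": len(probes),
                "mean_log2_ratio": float(ratios.loc[probes].mean()) if len(probes) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def common_hyper_genes(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    betas: pd.DataFrame,
    annotation: pd.DataFrame,
    treatment_a: str,
    treatment_b: str,
    control: str = "control",
    fold_threshold: float = 10.0,
    floor: float = 1e-3,
) -> set[str]:
    """Genes with at least one called hypermethylated site whose beta ratio
    to control is strictly greater than ``fold_threshold`` under *both*
    treatments.  The fold measure is the floored beta ratio (the DiffScore
    saturates under the noise model, so the ratio is the informative scale).
    """
    def gene_set(calls: pd.DataFrame, treatment: str) -> set[str]:
        probes = calls.index.intersection(betas.index)
        fold = betas.loc[probes, treatment].clip(lower=floor) / betas.loc[
            probes, control
        ].clip(lower=floor)
        hits = probes[fold > fold_threshold]
        genes: set[str] = set()
        for symbols in annotation.loc[hits, "gene"].fillna("").astype(str):
            genes.update(s for s in symbols.split(";") if s)
        return genes

    return gene_set(calls_a, treatment_a) & gene_set(calls_b, treatment_b)


# ---------------------------------------------------------------------------
# RRBS
# ---------------------------------------------------------------------------

def rrbs_filter(
    calls: pd.DataFrame,
    min_coverage: int = 10,
    max_percentile: float = 99.9,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop sites with coverage below ``min_coverage`` (strictly) and above
    the per-sample ``max_percentile`` coverage percentile (strictly).  The
    percentile is computed on the unfiltered table.  Returns the filtered
    table and the counts removed by each rule."""
    cov = calls["coverage"].to_numpy()
    hi = float(np.percentile(cov, max_percentile)) if len(cov) else np.inf
    low_mask = cov < min_coverage
    high_mask = cov > hi
    kept = calls[~(low_mask | high_mask)].copy()
    return kept, {
        "low_coverage_removed": int(low_mask.sum()),
        "high_coverage_removed": int((high_mask & ~low_mask).sum()),
        "coverage_ceiling": hi,
    }


def rrbs_normalize_coverage(samples: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Scale each sample's coverage so per-sample median coverages agree
    (to the median of medians); methylated counts are scaled by the same
    factor and rounded, preserving methylation fractions within rounding."""
    medians = {s: float(np.median(t["coverage"])) for s, t in samples.items()}
    target = float(np.median(list(medians.values())))
    out = {}
    for s, t in samples.items():
        factor = target / medians[s] if medians[s] > 0 else 1.0
        scaled = t.copy()
        new_cov = np.round(t["coverage"] * factor).astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(t["coverage"] > 0, t["n_meth"] / t["coverage"], 0.0)
        # counts re-derived from the scaled coverage and the original
        # fraction: per-site drift is bounded by 0.5 / scaled coverage
        scaled["coverage"] = new_cov
        scaled["n_meth"] = np.minimum(new_cov, np.round(new_cov * frac).astype(int))
        out[s] = scaled
    return out


def rrbs_tile(calls: pd.DataFrame, window: int = 1000) -> pd.DataFrame:
    """Sum coverage and methylated counts over 1-based non-overlapping
    windows ``[1 + k*window, (k+1)*window]`` per chromosome, strands merged.
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=["chrom", "start", "coverage", "n_meth", "fraction"])
    start = ((calls["pos"] - 1) // window) * window + 1
    grouped = (
        calls.assign(start=start)
        .groupby(["chrom", "start"], as_index=False)[["coverage", "n_meth"]]
        .sum()
    )
    grouped["fraction"] = grouped["n_meth"] / grouped["coverage"]
    return grouped.sort_values(["chrom", "start"]).reset_index(drop=True)


def rrbs_beta(calls: pd.DataFrame) -> pd.Series:
    """Per-site methylation fraction keyed by (chrom, pos)."""
    idx = pd.MultiIndex.from_arrays([calls["chrom"], calls["pos"]], names=["chrom", "pos"])
    frac = calls["n_meth"].to_numpy() / np.maximum(calls["coverage"].to_numpy(), 1)
    return pd.Series(frac, index=idx).groupby(level=[0, 1]).mean()


def rrbs_gene_methylation(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    annotation: pd.DataFrame,
    genes: list[str],
    floor: float = 1e-3,
) -> pd.DataFrame:
    """Per-gene mean log2 methylation ratio from RRBS calls.

    ``annotation`` maps sites (chrom, pos) to gene symbols; per gene the
    mean of per-site log2(beta_t / beta_c) over sites covered in both
    samples is reported together with the site count.
    """
    b_t, b_c = rrbs_beta(treated), rrbs_beta(control)
    common = b_t.index.intersection(b_c.index)
    ratios = np.log2(
        b_t.loc[common].clip(lower=floor) / b_c.loc[common].clip(lower=floor)
    )
    idx = pd.MultiIndex.from_arrays(
        [annotation["chrom"], annotation["pos"]], names=["chrom", "pos"]
    )
    site_gene = pd.Series(annotation["gene"].to_numpy(), index=idx)
    site_gene = site_gene[~site_gene.index.duplicated()]
    rows = []
    for gene in genes:
        sites = site_gene.index[site_gene == gene].intersection(common)
        rows.append(
            {
                "gene": gene,
                "n_sites": len(sites),
                "mean_log2_ratio": float(ratios.loc[sites].mean()) if len(sites) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def calls_to_bed(calls: pd.DataFrame) -> pd.DataFrame:
    """Express called sites as BED intervals (0-based, half-open)."""
    return pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["pos"] - 1,
            "end": calls["pos"],
        }
    )


# ---------------------------------------------------------------------------
# embedding and expression
# ---------------------------------------------------------------------------

def tsne_embed(profiles: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """2-D t-SNE embedding of samples (rows) from per-site fold-change
    profiles; perplexity adapts to the small sample counts of targeted
    studies (min(5, n-1)).  Deterministic under a fixed seed."""
    n = len(profiles)
    if n < 3:
        raise MethylomeError("need at least 3 samples to embed")
    perplexity = min(5.0, n - 1.0)
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=500,
    ).fit_transform(profiles.to_numpy())
    return pd.DataFrame(emb, index=profiles.index, columns=["tsne1", "tsne2"])


@dataclass
class ExpressionResult:
    fold_change: pd.DataFrame        # genes x treatments
    linkage: np.ndarray | None       # over treatments
    treatment_order: list[str]
    common_down: set[str]
    excluded_genes: list[str]        # zero-control-RPKM genes


def expression_analysis(
    expr: pd.DataFrame,
    control: str = "control",
    common_pair: tuple[str, str] = ("etoposide", "propyl_gallate"),
) -> ExpressionResult:
    """Fold change vs the vehicle control, hierarchical clustering of
    treatments (Euclidean distance, average linkage), and the set of genes
    with fold change < 1 under both members of ``common_pair``."""
    if control not in expr.columns:
        raise MethylomeError(f"control column {control!r} missing")
    zero = expr.index[expr[control] <= 0].tolist()
    usable = expr.drop(index=zero)
    treatments = [c for c in usable.columns if c != control]
    fold = usable[treatments].div(usable[control], axis=0)
    linkage = None
    if len(treatments) >= 2:
        dist = pdist(fold.T.to_numpy(), metric="euclidean")
        linkage = hierarchy.linkage(dist, method="average")
    common_down: set[str] = set()
    a, b = common_pair
    if a in fold.columns and b in fold.columns:
        common_down = set(fold.index[(fold[a] < 1.0) & (fold[b] < 1.0)])
    return ExpressionResult(
        fold_change=fold,
        linkage=linkage,
        treatment_order=treatments,
        common_down=common_down,
        excluded_genes=zero,
    )


def methylation_expression_funnel(
    common_down: set[str],
    panel_meth_a: pd.DataFrame,
    panel_meth_b: pd.DataFrame,
    min_effect: float = 0.0,
) -> tuple[int, int, int]:
    """Funnel counts over the commonly down-regulated genes: (number down,
    number with mean log2 methylation ratio > ``min_effect`` under either
    treatment, number under both).  ``panel_meth_*`` are the outputs of
    :func:`gene_panel_methylation` for the two treatments."""
    if not common_down:
        return (0, 0, 0)
    up_a = {
        g for g in common_down
        if g in panel_meth_a.index and panel_meth_a.loc[g, "mean_log2_ratio"] > min_effect
    }
    up_b = {
        g for g in common_down
        if g in panel_meth_b.index and panel_meth_b.loc[g, "mean_log2_ratio"] > min_effect
    }
    return (len(common_down), len(up_a | up_b), len(up_a & up_b))
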
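"""Synthetic-data generators for every input the iGEM pipeline consumes.

The real study screened 135 chemicals on an MBD-reporter iPS-cell line,
harmonized toxicology-database records for 114 of them, and profiled a
handful of agents by EPIC methylation array, RRBS, and a 100-gene targeted
expression panel.  These generators emulate each of those inputs with known
ground truth so the whole pipeline is testable without any download:

* two-channel field images with disk nuclei and Gaussian MBD foci,
* a chemicals x 4-parameter ratio table with three latent categories,
* GENE-TOX / CCRIS / IARC / Tox21 record snapshots,
* a beta-value matrix with CpG-context-dependent hypermethylation effects,
* per-cytosine RRBS call tables, and
* a 100-gene RPKM panel anti-correlated with gene-level methylation.

Each generator draws from its own pseudo-random stream seeded from
``SimConfig.seed`` plus a stable per-generator offset, so adding or rerunning
one generator never perturbs another.  Fixed seed implies bit-identical
output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import ConfigError, SimConfig

# stable per-generator stream offsets
_OFF_CATEGORY = 1
_OFF_PLATE = 2
_OFF_SCREEN = 3
_OFF_ACTIVITY = 4
_OFF_BETA = 5
_OFF_RRBS = 6
_OFF_EXPR = 7

RATIO_COLUMNS = ["foci_intensity", "foci_area", "foci_count", "nuclei_count"]

IARC_GROUPS = ("1", "2A", "2B", "3", "4", "none")
TOX21_OUTCOMES = ("active", "inconclusive", "inactive", "none")

# Tox21-style activity vocabulary; the first entries carry the planted
# association with the hypermethylation category.
TOX21_ACTIVITIES = [
    "CAR antagonist", "H2AX phosphorylation", "ESR1 antagonist",
    "ESR1 agonist", "AR antagonist", "AR agonist", "PPARg agonist",
    "PPARg antagonist", "PPARd agonist", "RXR agonist", "VDR agonist",
    "TR agonist", "TR antagonist", "GR agonist", "GR antagonist",
    "FXR agonist", "FXR antagonist", "PXR agonist", "CAR agonist",
    "AhR agonist", "Nrf2/ARE activation", "p53 activation",
    "ATAD5 induction", "aromatase inhibition", "HSE activation",
    "mitochondrial toxicity", "ER stress", "SHH pathway inhibition",
    "Wnt pathway inhibition", "Wnt pathway activation", "NFkB agonist",
    "NFkB antagonist", "RORg antagonist", "RORg agonist", "TSHR agonist",
    "TSHR antagonist", "TRHR agonist", "acetylcholinesterase inhibition",
    "hERG channel block", "DNA re-replication", "HDAC inhibition",
    "DNMT inhibition", "caspase 3/7 activation", "MMP modulation",
    "PGC-1a modulation", "elastase inhibition", "steroidogenesis modulation",
    "CYP1A2 inhibition",
]


def _rng(cfg: SimConfig, offset: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng((int(cfg.seed), int(offset), *map(int, extra)))


def _chem_key(chemical_id: str) -> int:
    return zlib.crc32(chemical_id.encode("utf8"))


def chemical_ids(cfg: SimConfig) -> list[str]:
    return [f"chem_{i + 1:03d}" for i in range(cfg.n_chemicals)]


def category_assignment(cfg: SimConfig) -> pd.Series:
    """True A/B/C category per chemical, shared across all generators.

    Category counts follow ``category_proportions`` exactly (largest-remainder
    apportionment), so the default configuration yields 63 hypomethylation
    (A), 36 hypermethylation (B), and 36 intermediate (C) chemicals.
    """
    if cfg.n_chemicals < 3:
        raise ConfigError("need at least 3 chemicals")
    if abs(sum(cfg.category_proportions) - 1.0) > 1e-9:
        raise ConfigError("category_proportions must sum to 1")
    n = cfg.n_chemicals
    quotas = [p * n for p in cfg.category_proportions]
    counts = [int(np.floor(q)) for q in quotas]
    order = np.argsort([-(q - c) for q, c in zip(quotas, counts)])
    for i in range(n - sum(counts)):
        counts[order[i]] += 1
    labels = np.repeat(list("ABC"), counts)
    rng = _rng(cfg, _OFF_CATEGORY)
    labels = labels[rng.permutation(n)]
    return pd.Series(labels, index=chemical_ids(cfg), name="category")


# ---------------------------------------------------------------------------
# planted gene-panel structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelTruth:
    """Planted methylation/expression structure over the 100-gene panel.

    The leading panel entries carry the effects: 9 genes hypermethylated by
    both hypermethylation agents (4 of which are re-confirmed by RRBS),
    4 more by etoposide only, 3 more by propyl gallate only (16 "either" in
    total), and 12 further genes down-regulated without a methylation change,
    for 28 commonly down-regulated genes overall.
    """

    panel: tuple[str, ...]
    hyper_both: tuple[str, ...]      # 9 genes, both agents
    rrbs_confirmed: tuple[str, ...]  # 4 of the 9, also seen by RRBS
    hyper_etoposide: tuple[str, ...]  # 13 = both + etoposide-only
    hyper_propyl_gallate: tuple[str, ...]  # 12 = both + PG-only
    common_down: tuple[str, ...]     # 28 genes down under both agents
    etoposide_only_down: tuple[str, ...]
    propyl_gallate_only_down: tuple[str, ...]
    biotin_down: tuple[str, ...]


def panel_truth(cfg: SimConfig) -> PanelTruth:
    p = list(cfg.panel_genes)
    if len(p) < 50:
        raise ConfigError("panel must have at least 50 genes")
    both = tuple(p[:9])
    etop_only = tuple(p[9:13])
    pg_only = tuple(p[13:16])
    return PanelTruth(
        panel=tuple(p),
        hyper_both=both,
        rrbs_confirmed=("JAG1", "LIFR", "CCND2", "RB1"),
        hyper_etoposide=both + etop_only,
        hyper_propyl_gallate=both + pg_only,
        common_down=tuple(p[:28]),
        etoposide_only_down=tuple(p[28:34]),
        propyl_gallate_only_down=tuple(p[34:39]),
        biotin_down=tuple(p[39:47]),
    )


# ---------------------------------------------------------------------------
# plate images
# ---------------------------------------------------------------------------

@dataclass
class FocusTruth:
    x: float
    y: float
    sigma: float
    amplitude: float


@dataclass
class NucleusTruth:
    x: float
    y: float
    radius: float
    foci: list[FocusTruth] = field(default_factory=list)
    crowded: bool = False  # any two foci centers closer than 2x focus radius

    @property
    def n_foci(self) -> int:
        return len(self.foci)


@dataclass
class PlateTruth:
    chemical: str
    multipliers: tuple[float, float, float, float]
    fields: list[list[NucleusTruth]]

    def mean_foci_count(self) -> float:
        counts = [n.n_foci for f in self.fields for n in f]
        return float(np.mean(counts)) if counts else float("nan")

    def n_nuclei(self) -> list[int]:
        return [len(f) for f in self.fields]


def _place_points(rng, n: int, low, high, min_dist: float, max_tries: int = 200):
    """Sequential rejection sampling with a soft minimum separation."""
    pts: list[tuple[float, float]] = []
    forced: list[bool] = []
    for _ in range(n):
        placed = False
        for _ in range(max_tries):
            x = rng.uniform(low[0], high[0])
            y = rng.uniform(low[1], high[1])
            if all((x - px) ** 2 + (y - py) ** 2 >= min_dist**2 for px, py in pts):
                pts.append((x, y))
                forced.append(False)
                placed = True
                break
        if not placed:
            pts.append((rng.uniform(low[0], high[0]), rng.uniform(low[1], high[1])))
            forced.append(True)
    return pts, forced


def _place_in_disk(rng, n: int, cx, cy, r, min_dist, max_tries: int = 60):
    """Best-candidate sampling in a disk: take the first candidate meeting
    the minimum separation, else the candidate farthest from its nearest
    accepted neighbour (overlap then possible, and flagged by the caller)."""
    pts: list[tuple[float, float]] = []
    for _ in range(n):
        best, best_d2 = None, -1.0
        for _ in range(max_tries):
            rad = r * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            x, y = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            d2 = min(((x - px) ** 2 + (y - py) ** 2 for px, py in pts), default=np.inf)
            if d2 >= min_dist**2:
                best = (x, y)
                break
            if d2 > best_d2:
                best, best_d2 = (x, y), d2
        pts.append(best)
    return pts


def _add_gaussian(img: np.ndarray, x: float, y: float, sigma: float, amp: float) -> None:
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))


def gen_plate_images(
    cfg: SimConfig, chemical_id: str, well_index: int = 0
) -> tuple[list[np.ndarray], PlateTruth]:
    """Simulate one well: ``n_fields_per_well`` two-channel field images.

    Channel 0 is the nuclear stain (blurred disks), channel 1 the MBD
    reporter (diffuse nuclear signal plus punctate foci).  The chemical's
    effect multipliers scale, in order, the four well-level parameters the
    imaging pipeline reports: summed focus intensity per nucleus, summed
    focus area per nucleus, focus count per nucleus, and nuclei count.
    Per focus that means a flux factor of ``m_int / m_count`` and an area
    (sigma^2) factor of ``m_area / m_count``, so the per-nucleus totals scale
    exactly as requested while focus amplitude stays near the control level.
    Returns the images as ``(2, H, W)`` float32 arrays and the ground truth.
    """
    cfg.validate()
    if chemical_id not in cfg.effect_multipliers:
        raise ConfigError(f"no effect multipliers for {chemical_id!r}")
    m_int, m_area, m_count, m_nuc = cfg.effect_multipliers[chemical_id]
    rng = _rng(cfg, _OFF_PLATE, _chem_key(chemical_id), well_index)
    h, w = cfg.image_size
    r_mean, r_sd = cfg.nucleus_radius_px

    images: list[np.ndarray] = []
    fields: list[list[NucleusTruth]] = []
    for _ in range(cfg.n_fields_per_well):
        n = cfg.n_nuclei_per_field * m_nuc
        if cfg.nuclei_count_cv > 0:
            n *= max(0.0, 1.0 + cfg.nuclei_count_cv * rng.standard_normal())
        n = max(0, int(round(n)))
        margin = r_mean + 4
        centers, _ = _place_points(
            rng, n, (margin, margin), (w - margin, h - margin), 2.4 * r_mean
        )
        blue = np.zeros((h, w), dtype=np.float64)
        red = np.zeros((h, w), dtype=np.float64)
        yy, xx = np.mgrid[0:h, 0:w]
        nuclei: list[NucleusTruth] = []
        area_factor = m_area / m_count if m_count > 0 else 0.0
        sigma_f0 = cfg.focus_radius_px * np.sqrt(max(area_factor, 0.0))
        for cx, cy in centers:
            radius = max(3.0, rng.normal(r_mean, r_sd))
            disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
            blue[disk] += cfg.nucleus_amplitude
            red[disk] += cfg.mbd_diffuse_amplitude
            nuc = NucleusTruth(x=cx, y=cy, radius=radius)
            k = rng.poisson(cfg.foci_per_nucleus * m_count) if m_count > 0 else 0
            if k > 0 and m_area > 0 and m_int > 0:
                pts = _place_in_disk(
                    rng, k, cx, cy, cfg.focus_placement_frac * radius, cfg.focus_min_sep_px
                )
                for fx, fy in pts:
                    sigma = sigma_f0 * np.exp(rng.normal(0, 0.05))
                    amp = (
                        cfg.focus_amplitude
                        * (m_int / m_area)
                        * np.exp(rng.normal(0, 0.08))
                    )
                    nuc.foci.append(FocusTruth(fx, fy, sigma, amp))
                d2min = min(
                    (
                        (a.x - b.x) ** 2 + (a.y - b.y) ** 2
                        for i, a in enumerate(nuc.foci)
                        for b in nuc.foci[i + 1 :]
                    ),
                    default=np.inf,
                )
                nuc.crowded = d2min < (2 * sigma_f0) ** 2
            nuclei.append(nuc)
        blue = gaussian_filter(blue, 2.0)
        red = gaussian_filter(red, 2.0)
        for nuc in nuclei:
            for f in nuc.foci:
                _add_gaussian(red, f.x, f.y, f.sigma, f.amplitude)
        if cfg.background_noise_sd > 0:
            blue = blue + rng.normal(0, cfg.background_noise_sd, (h, w))
            red = red + rng.normal(0, cfg.background_noise_sd, (h, w))
        img = np.stack([np.clip(blue, 0, None), np.clip(red, 0, None)])
        images.append(img.astype(np.float32))
        fields.append(nuclei)
    return images, PlateTruth(chemical_id, (m_int, m_area, m_count, m_nuc), fields)


def write_plate_tiffs(images: Sequence[np.ndarray], out_dir, well_id: str) -> list[str]:
    """Write each field as a two-page TIFF (page 0 nuclei, page 1 MBD)."""
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images, start=1):
        path = out / f"{well_id}_f{i}.tif"
        tifffile.imwrite(path, img)
        paths.append(str(path))
    return paths


# ---------------------------------------------------------------------------
# screening ratio table
# ---------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    categories: pd.Series  # chemical -> A/B/C
    means: pd.DataFrame    # chemical x 4 noise-free ratios


def gen_screen_table(cfg: SimConfig) -> tuple[pd.DataFrame, ScreenTruth]:
    """Per-chemical 4-parameter ratio-to-control table with latent A/B/C
    categories: A profiles have foci ratios < 1 and nuclei ratio > 1, B the
    reverse, C all near 1, plus i.i.d. Gaussian noise."""
    cfg.validate()
    cats = category_assignment(cfg)
    rng = _rng(cfg, _OFF_SCREEN)
    means = np.array([cfg.category_means[c] for c in cats], dtype=float)
    noise = rng.normal(0.0, cfg.screen_noise_sd, means.shape)
    ratios = np.clip(means + noise, 0.01, None)
    table = pd.DataFrame(ratios, index=cats.index, columns=RATIO_COLUMNS)
    table.insert(0, "concentration_m", 1e-6)
    truth = ScreenTruth(
        categories=cats,
        means=pd.DataFrame(means, index=cats.index, columns=RATIO_COLUMNS),
    )
    return table, truth


# ---------------------------------------------------------------------------
# activity database snapshot
# ---------------------------------------------------------------------------

@dataclass
class ActivityTruth:
    labels: pd.DataFrame          # labeled chemicals x activities
    categories: pd.Series         # chemical -> A/B/C (all chemicals)
    labeled_chemicals: list[str]  # chemicals with >= 1 record anywhere


def _merge_pair(a: str, b: str) -> str:
    """Ground-truth Tox21 parent/hydrochloride merge used by the generator
    (kept separate from the harmonizer under test)."""
    if a == "none" and b == "none":
        return "missing"
    if a == "none":
        return b
    if b == "none":
        return a
    if a == b:
        return a
    pair = {a, b}
    if pair == {"active", "inconclusive"}:
        return "active"
    if pair == {"active", "inactive"}:
        return "inconclusive"
    return "inactive"  # {inactive, inconclusive}


def _carc_truth(group: str, ccris_outcomes: list[str]) -> str:
    any_pos = "positive" in ccris_outcomes
    if group in ("1", "2A"):
        return "active"
    if group in ("2B", "3"):
        return "active" if any_pos else "inconclusive"
    # group 4 or no IARC data
    if any_pos:
        return "active"
    if ccris_outcomes:
        return "inactive"
    return "missing"


def gen_activity_db(
    cfg: SimConfig,
) -> tuple[dict[str, pd.DataFrame], ActivityTruth]:
    """Snapshot tables emulating GENE-TOX, CCRIS, IARC, and Tox21 records.

    Exactly ``n_labeled_chemicals`` chemicals receive at least one record;
    the rest have none and are excluded from the labeled subset.  The "CAR
    antagonist" and "H2AX phosphorylation" activities are planted with a
    strong enrichment of active outcomes among category-B (hypermethylation)
    chemicals, mirroring the association the screen is meant to surface.
    """
    cfg.validate()
    cats = category_assignment(cfg)
    chems = list(cats.index)
    rng = _rng(cfg, _OFF_ACTIVITY)
    n_sel = min(cfg.n_labeled_chemicals, len(chems))
    selected = sorted(rng.choice(len(chems), size=n_sel, replace=False))
    selected_ids = [chems[i] for i in selected]

    activities = ["genotoxicity", "carcinogenicity"] + TOX21_ACTIVITIES[: cfg.n_tox21_activities]
    genotox_rows, ccris_rows, iarc_rows, tox21_rows = [], [], [], []
    labels: dict[str, dict[str, str]] = {c: {} for c in selected_ids}

    planted = {"CAR antagonist": (0.85, 0.10), "H2AX phosphorylation": (0.70, 0.12)}

    for chem in selected_ids:
        cat = cats[chem]
        # GENE-TOX
        if rng.uniform() < 0.8:
            n_rec = rng.integers(1, 5)
            outs = ["positive" if rng.uniform() < 0.4 else "negative" for _ in range(n_rec)]
            for j, o in enumerate(outs):
                genotox_rows.append((chem, f"assay_{j + 1}", o))
            labels[chem]["genotoxicity"] = "active" if "positive" in outs else "inactive"
        else:
            labels[chem]["genotoxicity"] = "missing"
        # IARC + CCRIS
        group = "none"
        if rng.uniform() < 0.6:
            group = str(rng.choice(["1", "2A", "2B", "3", "4"], p=[0.1, 0.1, 0.3, 0.4, 0.1]))
            iarc_rows.append((chem, group))
        ccris_outs: list[str] = []
        if rng.uniform() < 0.6:
            n_rec = rng.integers(1, 4)
            ccris_outs = ["positive" if rng.uniform() < 0.4 else "negative" for _ in range(n_rec)]
            for j, o in enumerate(ccris_outs):
                ccris_rows.append((chem, f"animal_{j + 1}", o))
        labels[chem]["carcinogenicity"] = _carc_truth(group, ccris_outs)
        # Tox21
        for act in activities[2:]:
            if act in planted:
                p_active = planted[act][0] if cat == "B" else planted[act][1]
                rest = 1.0 - p_active
                probs = [p_active, 0.15 * rest, 0.55 * rest, 0.30 * rest]
            else:
                probs = [0.15, 0.15, 0.45, 0.25]
            parent = str(rng.choice(TOX21_OUTCOMES, p=probs))
            # hydrochloride records are sparse, and sparser still for the
            # planted activities so the parent outcome carries the signal
            hydro_p = [0.05, 0.05, 0.10, 0.80] if act in planted else [0.10, 0.10, 0.30, 0.50]
            hydro = str(rng.choice(TOX21_OUTCOMES, p=hydro_p))
            if parent != "none":
                tox21_rows.append((chem, act, "parent", parent))
            if hydro != "none":
                tox21_rows.append((chem, act, "hydrochloride", hydro))
            labels[chem][act] = _merge_pair(parent, hydro)
        # guarantee the chemical really has at least one record
        has_record = (
            labels[chem]["genotoxicity"] != "missing"
            or group != "none"
            or ccris_outs
            or any(labels[chem][a] != "missing" for a in activities[2:])
        )
        if not has_record:
            genotox_rows.append((chem, "assay_1", "negative"))
            labels[chem]["genotoxicity"] = "inactive"

    snapshot = {
        "genotox": pd.DataFrame(genotox_rows, columns=["chemical", "assay", "outcome"]),
        "ccris": pd.DataFrame(ccris_rows, columns=["chemical", "experiment", "outcome"]),
        "iarc": pd.DataFrame(iarc_rows, columns=["chemical", "group"]),
        "tox21": pd.DataFrame(tox21_rows, columns=["chemical", "activity", "form", "outcome"]),
    }
    label_df = pd.DataFrame.from_dict(labels, orient="index").loc[selected_ids, activities]
    label_df.index.name = "chemical"
    return snapshot, ActivityTruth(labels=label_df, categories=cats, labeled_chemicals=selected_ids)


# ---------------------------------------------------------------------------
# methylation array
# ---------------------------------------------------------------------------

CPG_CONTEXTS = ("island", "shore", "shelf", "open_sea")
REFGENE_GROUPS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic")

N_COMMON_HYPER_GENES = 12  # genes planted for the fold>10 common-hyper set


@dataclass
class BetaTruth:
    delta: pd.DataFrame           # probes x samples planted effect on beta
    annotation: pd.DataFrame
    panel: PanelTruth
    common_hyper_genes: tuple[str, ...]
    island_effect_probes: dict[str, np.ndarray]  # agent -> bool mask


def gen_beta_matrix(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, BetaTruth]:
    """Beta-value matrix (probes x samples) plus probe annotation.

    The vehicle-control column is drawn from the U-shaped mixture
    Beta(0.5, 8) / Beta(8, 0.5) with island probes biased to the unmethylated
    component.  Hypermethylation agents add ``beta_effect`` to a shared set
    of island probes (restricted to probes with control beta >= 0.05 so the
    global effect never masquerades as a >10-fold change) and to the promoter
    probes of their planted panel genes.  A dozen extra genes are planted
    with near-zero control beta and strong gains under both etoposide and
    propyl gallate to populate the high-fold-change common-hyper set.
    """
    cfg.validate()
    rng = _rng(cfg, _OFF_BETA)
    truth_panel = panel_truth(cfg)
    n = cfg.n_probes

    probe_ids = [f"cg{i:08d}" for i in range(n)]
    chrom = rng.choice([f"chr{i}" for i in range(1, 23)], size=n)
    pos = rng.integers(1, 200_000_000, size=n)
    other = 1.0 - cfg.island_fraction
    ctx = rng.choice(
        CPG_CONTEXTS, size=n,
        p=[cfg.island_fraction, 0.4 * other, 0.15 * other, 0.45 * other],
    )
    refgene = rng.choice(REFGENE_GROUPS, size=n, p=[0.1, 0.08, 0.08, 0.05, 0.35, 0.04, 0.3])
    gene = np.array([""] * n, dtype=object)

    # dedicate promoter probes to the panel genes and the common-hyper genes
    n_panel_probes = 8
    hyper_genes = tuple(f"HYPERC{i + 1:02d}" for i in range(N_COMMON_HYPER_GENES))
    special = list(truth_panel.panel) + list(hyper_genes)
    need = n_panel_probes * len(truth_panel.panel) + 3 * len(hyper_genes)
    if need > n:
        raise ConfigError("n_probes too small for the gene panel")
    special_idx = rng.choice(n, size=need, replace=False)
    cursor = 0
    panel_probe_idx: dict[str, np.ndarray] = {}
    for g in truth_panel.panel:
        idx = special_idx[cursor : cursor + n_panel_probes]
        cursor += n_panel_probes
        panel_probe_idx[g] = idx
        gene[idx] = g
        ctx[idx] = "island"
        refgene[idx] = rng.choice(["TSS200", "TSS1500"], size=len(idx))
    hyper_probe_idx: dict[str, np.ndarray] = {}
    for g in hyper_genes:
        idx = special_idx[cursor : cursor + 3]
        cursor += 3
        hyper_probe_idx[g] = idx
        gene[idx] = g
        ctx[idx] = "island"
        refgene[idx] = "TSS200"
    # sprinkle generic gene symbols on some remaining probes
    rest = np.setdiff1d(np.arange(n), special_idx)
    tagged = rng.choice(rest, size=int(0.4 * len(rest)), replace=False)
    gene[tagged] = [f"GENE{i:05d}" for i in rng.integers(0, 8000, size=len(tagged))]

    ann = pd.DataFrame(
        {
            "probe": probe_ids,
            "chromosome": chrom,
            "position": pos,
            "gene": gene,
            "refgene_group": refgene,
            "cpg_context": ctx,
        }
    ).set_index("probe")

    # control beta: U-shaped mixture, islands biased low
    p_low = np.select(
        [ctx == "island", ctx == "shore", ctx == "shelf"],
        [0.85, 0.5, 0.35],
        default=0.2,
    )
    low = rng.beta(0.5, 8.0, size=n)
    high = rng.beta(8.0, 0.5, size=n)
    base = np.where(rng.uniform(size=n) < p_low, low, high)
    special_mask = np.zeros(n, dtype=bool)
    special_mask[special_idx] = True
    for g in truth_panel.panel:
        base[panel_probe_idx[g]] = rng.uniform(0.08, 0.15, size=n_panel_probes)
    for g in hyper_genes:
        base[hyper_probe_idx[g]] = rng.uniform(0.010, 0.025, size=3)

    samples = ["control"] + list(cfg.array_chemicals)
    beta = pd.DataFrame(
        np.tile(base[:, None], (1, len(samples))), index=probe_ids, columns=samples
    )
    delta = pd.DataFrame(0.0, index=probe_ids, columns=samples)

    # global island effect: shared core across hypermethylation agents plus a
    # small agent-specific fringe
    eligible = (ctx == "island") & (~special_mask) & (base >= 0.05)
    elig_idx = np.flatnonzero(eligible)
    core = rng.uniform(size=len(elig_idx)) < 0.6
    island_effect: dict[str, np.ndarray] = {}
    agent_hyper_panel = {
        "etoposide": truth_panel.hyper_etoposide,
        "propyl_gallate": truth_panel.hyper_propyl_gallate,
        "biotin": truth_panel.hyper_both,
    }
    for agent in cfg.hyper_agents:
        fringe = rng.uniform(size=len(elig_idx)) < 0.1
        mask = np.zeros(n, dtype=bool)
        mask[elig_idx[core | fringe]] = True
        island_effect[agent] = mask
        delta.loc[mask, agent] += cfg.beta_effect
        for g in agent_hyper_panel.get(agent, ()):
            delta.iloc[panel_probe_idx[g], delta.columns.get_loc(agent)] += cfg.beta_effect
    if cfg.beta_effect > 0:
        for agent in ("etoposide", "propyl_gallate"):
            if agent in beta.columns:
                for g in hyper_genes:
                    idx = hyper_probe_idx[g]
                    target = rng.uniform(0.28, 0.35, size=len(idx))
                    delta.iloc[idx, delta.columns.get_loc(agent)] = target - base[idx]

    beta = beta.add(delta)
    if cfg.beta_noise_sd > 0:
        noise = rng.normal(0.0, cfg.beta_noise_sd, beta.shape)
        noise[:, 0] = 0.0  # control column is the shared reference
        beta = beta + noise
    beta = beta.clip(0.0, 1.0)
    truth = BetaTruth(
        delta=delta,
        annotation=ann,
        panel=truth_panel,
        common_hyper_genes=hyper_genes,
        island_effect_probes=island_effect,
    )
    return beta, ann, truth


# ---------------------------------------------------------------------------
# RRBS calls
# ---------------------------------------------------------------------------

@dataclass
class RrbsTruth:
    fractions: pd.DataFrame       # sites x samples true methylation fraction
    site_gene: pd.Series          # site index -> gene symbol ("" if none)
    confirmed_genes: tuple[str, ...]
    gene_effects: dict[str, tuple[str, ...]]  # agent -> genes with planted gain


def gen_rrbs_calls(
    cfg: SimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, RrbsTruth]:
    """Per-cytosine RRBS call tables (one per sample, methylKit-style),
    plus a site annotation table (chrom, pos, gene) for the tracked genes.

    Coverage is negative-binomial around ``rrbs_mean_coverage`` with a heavy
    right tail; methylated counts are binomial in the true site fraction.
    Etoposide and propyl gallate gain methylation globally and at the four
    confirmed genes; 5-aza-dc loses methylation globally.
    """
    cfg.validate()
    rng = _rng(cfg, _OFF_RRBS)
    truthp = panel_truth(cfg)
    genes9 = list(truthp.hyper_both)
    n_gene_sites = cfg.rrbs_gene_sites * len(genes9)
    n = max(cfg.n_rrbs_sites, n_gene_sites)

    chrom = rng.choice([f"chr{i}" for i in range(1, 23)], size=n)
    posn = np.sort(rng.integers(1, 200_000_000, size=n))
    strand = rng.choice(["+", "-"], size=n)
    site_gene = np.array([""] * n, dtype=object)
    for k, g in enumerate(genes9):
        sl = slice(k * cfg.rrbs_gene_sites, (k + 1) * cfg.rrbs_gene_sites)
        site_gene[sl] = g
        chrom[sl] = f"chr{k + 1}"
        posn[sl] = 1_000_000 + np.arange(cfg.rrbs_gene_sites) * 50

    base = np.empty(n)
    gene_mask = site_gene != ""
    base[gene_mask] = rng.uniform(0.20, 0.45, size=gene_mask.sum())
    rest = ~gene_mask
    u = rng.uniform(size=rest.sum())
    vals = np.where(u < 0.5, rng.uniform(0.01, 0.08, size=rest.sum()),
                    np.where(u < 0.8, rng.uniform(0.7, 0.95, size=rest.sum()),
                             rng.uniform(0.1, 0.6, size=rest.sum())))
    base[rest] = vals

    samples = ["control"] + list(cfg.rrbs_chemicals)
    frac = pd.DataFrame(np.tile(base[:, None], (1, len(samples))), columns=samples)

    eligible = rest & (base >= 0.1) & (base <= 0.75)
    gain_mask = eligible & (rng.uniform(size=n) < 0.3)
    loss_mask = rest & (base >= 0.2) & (rng.uniform(size=n) < 0.4)
    gene_effects = {
        "etoposide": tuple(truthp.rrbs_confirmed) + ("NOTCH4", "CCNA2"),
        "propyl_gallate": tuple(truthp.rrbs_confirmed) + ("SMAD4", "JUND"),
    }
    for agent in ("etoposide", "propyl_gallate"):
        if agent not in frac.columns:
            continue
        frac.loc[gain_mask, agent] += 0.10
        affected = np.isin(site_gene, gene_effects[agent])
        frac.loc[affected, agent] += cfg.rrbs_gene_effect
    if "5-aza-dc" in frac.columns:
        frac.loc[loss_mask, "5-aza-dc"] -= 0.15
    frac = frac.clip(0.0, 1.0)

    p_nb = cfg.rrbs_dispersion / (cfg.rrbs_dispersion + cfg.rrbs_mean_coverage)
    tables: dict[str, pd.DataFrame] = {}
    for s in samples:
        cov = rng.negative_binomial(cfg.rrbs_dispersion, p_nb, size=n)
        meth = rng.binomial(cov, frac[s].to_numpy())
        tables[s] = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": posn,
                "strand": strand,
                "coverage": cov,
                "n_meth": meth,
            }
        )
    annotation = pd.DataFrame({"chrom": chrom, "pos": posn, "gene": site_gene})
    truth = RrbsTruth(
        fractions=frac,
        site_gene=pd.Series(site_gene),
        confirmed_genes=truthp.rrbs_confirmed,
        gene_effects=gene_effects,
    )
    return tables, annotation, truth


# ---------------------------------------------------------------------------
# targeted expression panel
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    fold: pd.DataFrame            # genes x treated samples true fold change
    common_down: tuple[str, ...]  # genes down under both etoposide and PG


def gen_expression(
    cfg: SimConfig, methylation_truth: BetaTruth | None = None
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """100-gene RPKM table (genes x samples) anti-correlated with the planted
    gene-level methylation: panel genes hypermethylated by an agent are
    down-regulated most strongly in that agent's sample, and 28 genes are
    commonly decreased under both etoposide and propyl gallate."""
    cfg.validate()
    rng = _rng(cfg, _OFF_EXPR)
    truthp = methylation_truth.panel if methylation_truth is not None else panel_truth(cfg)
    genes = list(truthp.panel)
    samples = ["control"] + list(cfg.array_chemicals)

    base = np.exp(rng.normal(np.log(50.0), 1.0, size=len(genes)))
    fold = pd.DataFrame(1.0, index=genes, columns=samples[1:])
    agent_hyper = {
        "etoposide": set(truthp.hyper_etoposide),
        "propyl_gallate": set(truthp.hyper_propyl_gallate),
        "biotin": set(truthp.hyper_both),
    }
    if methylation_truth is not None:
        # honour the actually-planted methylation effects: a gene counts as
        # hypermethylated for an agent only if its promoter probes gained beta
        ann = methylation_truth.annotation
        in_panel = ann["gene"].isin(genes).to_numpy()
        agent_hyper = {}
        for agent in fold.columns:
            if agent in methylation_truth.delta.columns:
                hit = (methylation_truth.delta[agent].to_numpy() > 1e-12) & in_panel
                agent_hyper[agent] = set(ann["gene"].to_numpy()[hit])
            else:
                agent_hyper[agent] = set()
        if not any(agent_hyper.values()):
            # null methylation experiment: no downstream expression changes
            expr = pd.DataFrame(
                np.tile(base[:, None], (1, len(samples))), index=genes, columns=samples
            )
            expr.index.name = "gene"
            return expr, ExpressionTruth(fold=fold, common_down=())
    for agent, hyper in agent_hyper.items():
        if agent not in fold.columns:
            continue
        for g in hyper:
            fold.loc[g, agent] = rng.uniform(0.25, 0.55)
    # remaining commonly-down genes fall without a methylation change
    for agent in ("etoposide", "propyl_gallate"):
        if agent not in fold.columns:
            continue
        for g in truthp.common_down:
            if fold.loc[g, agent] >= 1.0:
                fold.loc[g, agent] = rng.uniform(0.45, 0.80)
    for agent, extra in (
        ("etoposide", truthp.etoposide_only_down),
        ("propyl_gallate", truthp.propyl_gallate_only_down),
        ("biotin", truthp.biotin_down),
    ):
        if agent not in fold.columns:
            continue
        for g in extra:
            fold.loc[g, agent] = rng.uniform(0.40, 0.80)

    expr = pd.DataFrame(0.0, index=genes, columns=samples)
    expr["control"] = base
    for s in samples[1:]:
        values = base * fold[s].to_numpy()
        if cfg.expression_noise_sd > 0:
            values = values * np.exp(rng.normal(0, cfg.expression_noise_sd, len(genes)))
        expr[s] = values
    expr.index.name = "gene"
    return expr, ExpressionTruth(fold=fold, common_down=truthp.common_down)
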
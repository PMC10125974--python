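"""Configuration objects for the simulator and the pipeline.

Everything tunable lives here: the synthetic-plate geometry, the planted
effect sizes, and every analysis threshold (viability gate, category band,
differential-methylation cutoff, RRBS coverage filters).  Configs are plain
dataclasses; :func:`PipelineConfig.from_yaml` rejects unknown keys so that a
typo in a config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is out of range or unknown."""


# Per-chemical multiplicative shifts applied by the plate-image simulator to
# (foci integrated intensity, foci area, foci count, nuclei count).  The
# reference effect sizes are the ratio-to-control values measured for the
# archetypal hyper- and hypomethylation agents of the screen.
DEFAULT_EFFECT_MULTIPLIERS: dict[str, tuple[float, float, float, float]] = {
    "DMSO": (1.0, 1.0, 1.0, 1.0),
    "etoposide": (1.37, 1.35, 1.34, 0.90),
    "5-aza-dc": (0.56, 0.56, 0.63, 1.10),
}


def _default_panel_genes() -> list[str]:
    """100-gene stemness panel used by the targeted expression simulator.

    The first entries are the cell-cycle / development genes tracked through
    the methylation-expression funnel; the remainder are canonical stemness
    and signalling genes padded with systematic placeholders to reach 100.
    """
    named = [
        # funnel genes (hypermethylated under both hypermethylation agents)
        "NOTCH4", "JAG1", "LIFR", "CCNA2", "CCND2", "RB1", "SMAD4", "JUND",
        "CREBBP",
        # core pluripotency and signalling
        "POU5F1", "NANOG", "SOX2", "KLF4", "LIN28A", "MYC", "ZFP42", "DNMT3B",
        "SALL4", "UTF1", "DPPA4", "TDGF1", "FGF4", "GDF3", "LEFTY1", "LEFTY2",
        "NODAL", "FOXD3", "GATA4", "GATA6", "SOX17", "AFP", "CDX2", "EOMES",
        "T", "HAND1", "NES", "PAX6", "OTX2", "GBX2", "NEUROD1", "NOTCH1",
        "DLL1", "HES1", "WNT3A", "CTNNB1", "AXIN2", "BMP4", "SMAD1", "TGFB1",
        "ACVR1B", "FGF2", "FGFR1", "STAT3", "LIF", "IL6ST", "ESRRB", "TBX3",
        "PRDM14", "DPPA3", "TET1", "TET2", "DNMT1", "EZH2", "SUZ12", "JARID2",
        "KDM6A", "CDK1", "CDK2", "CDK4", "CDK6", "CCNB1", "CCND1", "CCNE1",
        "CDKN1A", "CDKN2A", "E2F1", "MDM2", "TP53", "MKI67", "PCNA", "AURKA",
        "PLK1", "BUB1", "MAD2L1", "TERT", "THY1", "CD9", "EPCAM", "CDH1",
        "CDH2", "VIM", "SNAI1", "SNAI2", "TWIST1", "ZEB1",
    ]
    i = 1
    while len(named) < 100:
        named.append(f"STEM{i:03d}")
        i += 1
    return named[:100]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the design of the screen being emulated: nine imaging
    fields per well, 135 chemicals split 63/36/36 into hypo- / hyper- /
    intermediate-methylation categories, a 100-gene stemness expression
    panel, and 114 chemicals with at least one toxicology-database record.
    """

    seed: int = 0

    # --- plate imaging ---
    n_fields_per_well: int = 9
    image_size: tuple[int, int] = (256, 256)
    n_nuclei_per_field: int = 12
    nucleus_radius_px: tuple[float, float] = (11.0, 1.2)  # mean, sd
    nucleus_amplitude: float = 120.0
    foci_per_nucleus: float = 3.0  # Poisson mean
    focus_radius_px: float = 1.5  # Gaussian sigma of a rendered focus
    focus_amplitude: float = 90.0
    focus_min_sep_px: float = 5.0  # soft minimum separation between foci
    # foci are placed within this fraction of the nucleus radius: MBD puncta
    # concentrate in the heterochromatic interior, away from the envelope
    focus_placement_frac: float = 0.65
    mbd_diffuse_amplitude: float = 8.0  # diffuse nuclear MBD signal
    background_noise_sd: float = 2.0
    nuclei_count_cv: float = 0.0  # per-field seeding variability
    effect_multipliers: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MULTIPLIERS)
    )

    # --- chemical screen ---
    n_chemicals: int = 135
    category_proportions: tuple[float, float, float] = (63 / 135, 36 / 135, 36 / 135)
    screen_noise_sd: float = 0.02
    # Category mean ratio profiles (foci_intensity, foci_area, foci_count,
    # nuclei).  C carries a weak but *correlated* shape (intensity/area tick
    # up, count dips, nuclei flat) orthogonal to the A/B axis: profiles are
    # clustered on Pearson correlation, which is scale-free, so a class with
    # no reproducible shape would have no defined cluster direction at all.
    category_means: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "A": (0.65, 0.65, 0.70, 1.15),
            "B": (1.35, 1.33, 1.25, 0.85),
            "C": (1.04, 1.04, 0.92, 1.00),
        }
    )

    # --- activity database snapshot ---
    n_labeled_chemicals: int = 114
    n_tox21_activities: int = 48  # plus genotoxicity and carcinogenicity = 50

    # --- methylation array ---
    n_probes: int = 30_000
    island_fraction: float = 0.20
    beta_effect: float = 0.15
    beta_noise_sd: float = 0.0
    array_chemicals: tuple[str, ...] = (
        "biotin", "etoposide", "propyl_gallate", "theophylline", "bisphenol_a"
    )
    hyper_agents: tuple[str, ...] = ("biotin", "etoposide", "propyl_gallate")

    # --- RRBS ---
    rrbs_mean_coverage: float = 30.0
    rrbs_dispersion: float = 3.0  # negative-binomial size parameter
    n_rrbs_sites: int = 50_000
    rrbs_gene_sites: int = 80  # CpG sites simulated per tracked gene
    rrbs_gene_effect: float = 0.20
    rrbs_chemicals: tuple[str, ...] = (
        "etoposide", "propyl_gallate", "theophylline", "5-aza-dc"
    )

    # --- targeted expression panel ---
    panel_genes: list[str] = field(default_factory=_default_panel_genes)
    expression_noise_sd: float = 0.0

    def validate(self) -> "SimConfig":
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ConfigError("image_size must be positive")
        if self.nucleus_radius_px[0] <= 0:
            raise ConfigError("nucleus radius must be positive")
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ConfigError("category_proportions must sum to 1")
        for name, value in (
            ("focus_amplitude", self.focus_amplitude),
            ("background_noise_sd", self.background_noise_sd),
            ("rrbs_mean_coverage", self.rrbs_mean_coverage),
            ("beta_noise_sd", self.beta_noise_sd),
        ):
            if value < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.island_fraction <= 1.0:
            raise ConfigError("island_fraction must be in [0, 1]")
        if len(self.panel_genes) != len(set(self.panel_genes)):
            raise ConfigError("panel_genes must be unique")
        return self


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: one simulator config plus every
    analysis threshold, with the seeds that make a run reproducible."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "igem_out"

    # imaging analysis
    nucleus_min_area_px: int = 120
    nucleus_max_area_px: int = 2000
    spot_sigma_px: float = 1.5
    k_threshold: float = 5.0
    n_wells_per_condition: int = 5

    # screen profiling
    viability_min_fraction: float = 0.70
    n_clusters: int = 3
    category_delta: float = 0.05

    # association
    n_trees: int = 500
    rf_seed: int = 0
    encoding: str = "ordinal"

    # methylome
    beta_floor: float = 1e-3
    sigma_beta: float = 0.03
    # score at p = 0.05 is 13.0103; calls require p strictly below 0.05
    diff_score_threshold: float = 13.0103
    fold_threshold: float = 10.0
    min_meth_effect: float = 0.0
    rrbs_min_coverage: int = 10
    rrbs_max_coverage_percentile: float = 99.9
    rrbs_window: int = 1000
    rrbs_gene_min_effect: float = 0.30
    tsne_seed: int = 0

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = raw.pop("sim", {})
        _check_keys(sim_raw, SimConfig, "sim")
        _check_keys(raw, cls, "pipeline")
        sim = _build_dataclass(SimConfig, sim_raw).validate()
        cfg = _build_dataclass(cls, raw)
        cfg.sim = sim
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _check_keys(raw: Mapping, cls, where: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown {where} config keys: {sorted(unknown)}")


def _coerce(value, target):
    """YAML gives lists where dataclass defaults are tuples; align them."""
    if isinstance(target, tuple) and isinstance(value, Sequence) and not isinstance(value, str):
        return tuple(value)
    if isinstance(target, dict) and isinstance(value, Mapping):
        return {k: _coerce(v, next(iter(target.values())) if target else v) for k, v in value.items()}
    return value


def _build_dataclass(cls, raw: Mapping):
    defaults = cls()
    kwargs = {}
    for key, value in raw.items():
        kwargs[key] = _coerce(value, getattr(defaults, key))
    return dataclasses.replace(defaults, **kwargs)
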
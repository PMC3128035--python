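"""Synthetic MAQC-like study generator with known differential-expression truth.

Emulates the four-sample titration design: two reference profiles A and B,
mixtures C = 0.75*A + 0.25*B and D = 0.25*A + 0.75*B built on the natural
scale, replicated at several test sites on several array "platforms" whose
probe sets overlap but differ (gene dropout, multi-probe genes, duplicate
probe IDs), plus a low-noise RT-PCR-like assay on a gene subset and a
randomly drawn gene-set collection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .errors import ConfigurationError, DataError
from .matrix import LOG2, NATURAL, ExpressionMatrix

SAMPLE_TYPES = ("A", "B", "C", "D")
#: natural-scale fraction of Sample A in each sample type
MIX_FRACTIONS = {"A": 1.0, "B": 0.0, "C": 0.75, "D": 0.25}


@dataclass(frozen=True)
class PlatformSpec:
    """Descriptor of one simulated array platform."""

    name: str
    duplicate_id_rate: float = 0.0
    multi_probe_rate: float = 0.1
    dropout_rate: float = 0.05
    probe_affinity_sd: float = 0.2  # log2 spread between probes of one gene

    def validate(self) -> None:
        for attr in ("duplicate_id_rate", "multi_probe_rate", "dropout_rate"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"platform {self.name}: {attr}={v} outside [0,1]")
        if self.probe_affinity_sd < 0:
            raise ConfigurationError(f"platform {self.name}: negative probe_affinity_sd")


def _default_platforms() -> list[PlatformSpec]:
    return [
        PlatformSpec(name="PLA", duplicate_id_rate=0.0, multi_probe_rate=0.10, dropout_rate=0.05),
        PlatformSpec(name="PLB", duplicate_id_rate=0.02, multi_probe_rate=0.05, dropout_rate=0.08),
    ]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; a single seed drives every stream."""

    n_genes: int = 1000
    n_deg: int = 100
    effect_size: float = 2.0
    effect_size_sd: float | None = None  # default effect_size / 10
    base_mean_range: tuple[float, float] = (4.0, 12.0)
    noise_sd: float = 0.5
    intensity_noise_slope: float = 0.0
    site_effect_sd: float = 0.1
    n_sites: int = 3
    n_reps: int = 5
    platforms: tuple[PlatformSpec, ...] = field(
        default_factory=lambda: tuple(_default_platforms())
    )
    rtpcr_n_genes: int = 200
    rtpcr_n_reps: int = 4
    rtpcr_noise_sd: float = 0.1
    rtpcr_deg_fraction: float = 0.3
    n_gene_sets: int = 50
    gene_set_size_range: tuple[int, int] = (10, 60)
    gene_set_enriched_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not 0 <= self.n_deg <= self.n_genes:
            raise ConfigurationError("n_deg must lie in [0, n_genes]")
        if self.rtpcr_n_genes > self.n_genes:
            raise ConfigurationError("rtpcr_n_genes exceeds n_genes")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2")
        if self.rtpcr_n_reps < 2:
            raise ConfigurationError("rtpcr_n_reps must be >= 2")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.effect_size < 0 or self.noise_sd < 0 or self.rtpcr_noise_sd < 0:
            raise ConfigurationError("negative scale parameter")
        if self.rtpcr_noise_sd > self.noise_sd:
            raise ConfigurationError("RT-PCR noise must not exceed microarray noise")
        if not 0.0 <= self.rtpcr_deg_fraction <= 1.0:
            raise ConfigurationError("rtpcr_deg_fraction outside [0,1]")
        if not 0.0 <= self.gene_set_enriched_fraction <= 1.0:
            raise ConfigurationError("gene_set_enriched_fraction outside [0,1]")
        if self.base_mean_range[0] >= self.base_mean_range[1]:
            raise ConfigurationError("base_mean_range must be an increasing interval")
        lo, hi = self.gene_set_size_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("invalid gene_set_size_range")
        if hi > self.n_genes:
            raise ConfigurationError("gene_set_size_range upper bound exceeds n_genes")
        if not self.platforms:
            raise ConfigurationError("at least one platform required")
        for p in self.platforms:
            p.validate()

    # -- (de)serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["platforms"] = [dataclasses.asdict(p) for p in self.platforms]
        d["base_mean_range"] = list(self.base_mean_range)
        d["gene_set_size_range"] = list(self.gene_set_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "platforms" in d:
            d["platforms"] = tuple(PlatformSpec(**p) for p in d["platforms"])
        for key in ("base_mean_range", "gene_set_size_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        try:
            return cls.from_dict(data)
        except TypeError as exc:  # unknown field
            raise ConfigurationError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class GroundTruth:
    """True per-gene differential state between Samples A and B."""

    genes: tuple[str, ...]
    true_effect: np.ndarray  # signed log2 difference B - A; 0 for non-DEGs

    @property
    def is_deg(self) -> np.ndarray:
        return self.true_effect != 0.0

    @property
    def deg_genes(self) -> set[str]:
        return {g for g, d in zip(self.genes, self.is_deg) if d}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"true_effect": self.true_effect, "is_deg": self.is_deg},
            index=pd.Index(self.genes, name="gene"),
        )


@dataclass
class Universe:
    """Gene symbols with their baseline natural-scale A and B profiles."""

    genes: tuple[str, ...]
    log2_a: np.ndarray
    log2_b: np.ndarray

    @property
    def natural_a(self) -> np.ndarray:
        return np.exp2(self.log2_a)

    @property
    def natural_b(self) -> np.ndarray:
        return np.exp2(self.log2_b)


def _stream(config: SimConfig, *key: int) -> np.random.Generator:
    """Deterministic child RNG derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def generate_universe(config: SimConfig) -> tuple[Universe, GroundTruth]:
    """Draw the gene universe, baseline profiles and the true DEG subset.

    DEG effect magnitudes are Gaussian around ``effect_size`` (sd
    ``effect_size_sd``, default ``effect_size/10``, clipped below at half
    the mean) with random sign; non-DEG genes have B identical to A.
    """
    rng = _stream(config, 0)
    genes = tuple(f"G{i:05d}" for i in range(config.n_genes))
    lo, hi = config.base_mean_range
    log2_a = rng.uniform(lo, hi, config.n_genes)

    effect = np.zeros(config.n_genes)
    deg_idx = rng.choice(config.n_genes, size=config.n_deg, replace=False)
    if config.n_deg:
        sd = config.effect_size_sd
        if sd is None:
            sd = config.effect_size / 10.0
        magnitude = rng.normal(config.effect_size, sd, config.n_deg)
        magnitude = np.clip(magnitude, config.effect_size / 2.0, None)
        sign = rng.choice([-1.0, 1.0], size=config.n_deg)
        effect[deg_idx] = sign * magnitude

    log2_b = log2_a + effect
    return Universe(genes, log2_a, log2_b), GroundTruth(genes, effect)


def mix_samples(
    profile_a: np.ndarray, profile_b: np.ndarray, fraction_a: float
) -> np.ndarray:
    """Natural-scale mixture ``fraction_a * A + (1 - fraction_a) * B``."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("profiles must have the same shape")
    if (a < 0).any() or (b < 0).any():
        raise DataError("negative intensities in natural-scale profiles")
    if not 0.0 <= fraction_a <= 1.0:
        raise DataError(f"fraction_a={fraction_a} outside [0,1]")
    return fraction_a * a + (1.0 - fraction_a) * b


@dataclass
class PlatformLayout:
    """Realised probe content of one platform."""

    spec: PlatformSpec
    probe_ids: list[str]  # one entry per physical probe; duplicate IDs possible
    gene_of_probe: list[str]
    affinity: np.ndarray  # per-probe log2 offset shared by all samples

    def annotation(self) -> pd.DataFrame:
        """Probe-to-gene map with one row per unique probe ID."""
        df = pd.DataFrame({dio.PROBE_COLUMN: self.probe_ids, "gene": self.gene_of_probe})
        return df.drop_duplicates(subset=dio.PROBE_COLUMN).reset_index(drop=True)


def _realize_platform(
    config: SimConfig, universe: Universe, platform_index: int
) -> PlatformLayout:
    spec = config.platforms[platform_index]
    rng = _stream(config, 1, platform_index)
    n = len(universe.genes)
    kept = np.nonzero(rng.random(n) >= spec.dropout_rate)[0]

    probe_ids: list[str] = []
    gene_of_probe: list[str] = []
    affinities: list[float] = []
    counter = 0
    for gi in kept:
        gene = universe.genes[gi]
        n_probes = 1
        if rng.random() < spec.multi_probe_rate:
            n_probes = int(rng.integers(2, 4))
        for _ in range(n_probes):
            pid = f"{spec.name}_{counter:06d}"
            counter += 1
            aff = float(rng.normal(0.0, spec.probe_affinity_sd))
            copies = 2 if rng.random() < spec.duplicate_id_rate else 1
            for _ in range(copies):
                probe_ids.append(pid)
                gene_of_probe.append(gene)
                affinities.append(aff)
    return PlatformLayout(spec, probe_ids, gene_of_probe, np.array(affinities))


@dataclass
class SimulatedStudy:
    """Everything one simulation run produces."""

    config: SimConfig
    universe: Universe
    truth: GroundTruth
    layouts: dict[str, PlatformLayout]
    # (platform name, site number 1-based) -> natural-scale matrix
    expression: dict[tuple[str, int], ExpressionMatrix]
    rtpcr: ExpressionMatrix
    gene_sets: dict[str, tuple[str, ...]]


def generate_expression(
    config: SimConfig, universe: Universe
) -> tuple[dict[str, PlatformLayout], dict[tuple[str, int], ExpressionMatrix]]:
    """One natural-scale probes x (4 types * n_reps) matrix per platform/site.

    Replicate noise is additive Gaussian on the log2 scale with per-probe
    sd ``noise_sd + intensity_noise_slope * (max_mean - probe_mean)``, so
    low-intensity probes are noisier.  Site effects are per-probe additive
    log2 offsets drawn once per site.
    """
    layouts: dict[str, PlatformLayout] = {}
    matrices: dict[tuple[str, int], ExpressionMatrix] = {}
    gene_index = {g: i for i, g in enumerate(universe.genes)}

    for pi, spec in enumerate(config.platforms):
        layout = _realize_platform(config, universe, pi)
        layouts[spec.name] = layout
        gidx = np.array([gene_index[g] for g in layout.gene_of_probe])

        probe_log2_a = universe.log2_a[gidx] + layout.affinity
        probe_log2_b = universe.log2_b[gidx] + layout.affinity
        nat_a = np.exp2(probe_log2_a)
        nat_b = np.exp2(probe_log2_b)
        profiles = {
            t: mix_samples(nat_a, nat_b, MIX_FRACTIONS[t]) for t in SAMPLE_TYPES
        }

        probe_mean = 0.5 * (probe_log2_a + probe_log2_b)
        sd = config.noise_sd + config.intensity_noise_slope * (
            probe_mean.max() - probe_mean
        )
        sd = np.clip(sd, 0.0, None)

        for site in range(1, config.n_sites + 1):
            rng = _stream(config, 2, pi, site)
            site_offset = rng.normal(0.0, config.site_effect_sd, len(gidx)) \
                if config.site_effect_sd > 0 else np.zeros(len(gidx))
            columns: dict[str, np.ndarray] = {}
            meta_rows = []
            for t in SAMPLE_TYPES:
                base = np.log2(profiles[t]) + site_offset
                for rep in range(1, config.n_reps + 1):
                    noise = rng.normal(0.0, 1.0, len(gidx)) * sd if sd.any() else 0.0
                    sid = f"{spec.name}_s{site}_{t}{rep}"
                    columns[sid] = np.exp2(base + noise)
                    meta_rows.append((sid, t, str(site), spec.name))
            values = pd.DataFrame(
                columns, index=pd.Index(layout.probe_ids, name=dio.PROBE_COLUMN)
            )
            meta = pd.DataFrame(
                meta_rows, columns=["sample_id", "type", "site", "platform"]
            ).set_index("sample_id")
            matrices[(spec.name, site)] = ExpressionMatrix(values, NATURAL, meta)
    return layouts, matrices


def generate_rtpcr(config: SimConfig, universe: Universe, truth: GroundTruth) -> ExpressionMatrix:
    """Low-noise log2 table on a gene subset enriched for true DEGs."""
    rng = _stream(config, 3)
    deg = np.nonzero(truth.is_deg)[0]
    non = np.nonzero(~truth.is_deg)[0]
    n_deg_wanted = int(round(config.rtpcr_deg_fraction * config.rtpcr_n_genes))
    n_deg_take = min(n_deg_wanted, len(deg))
    n_non_take = config.rtpcr_n_genes - n_deg_take
    if n_non_take > len(non):
        # not enough non-DEGs; fill with extra DEGs
        n_non_take = len(non)
        n_deg_take = config.rtpcr_n_genes - n_non_take
    chosen = np.concatenate(
        [
            rng.choice(deg, size=n_deg_take, replace=False),
            rng.choice(non, size=n_non_take, replace=False),
        ]
    )
    chosen.sort()

    nat_a = universe.natural_a[chosen]
    nat_b = universe.natural_b[chosen]
    genes = [universe.genes[i] for i in chosen]
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for t in SAMPLE_TYPES:
        base = np.log2(mix_samples(nat_a, nat_b, MIX_FRACTIONS[t]))
        for rep in range(1, config.rtpcr_n_reps + 1):
            sid = f"RT_{t}{rep}"
            noise = rng.normal(0.0, config.rtpcr_noise_sd, len(chosen)) \
                if config.rtpcr_noise_sd > 0 else 0.0
            columns[sid] = base + noise
            meta_rows.append((sid, t, "1", "RTPCR"))
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "type", "site", "platform"]
    ).set_index("sample_id")
    return ExpressionMatrix(values, LOG2, meta)


def generate_gene_sets(
    universe: Universe,
    n_sets: int,
    size_range: tuple[int, int],
    seed: int,
    enriched_fraction: float = 0.0,
    truth: GroundTruth | None = None,
) -> dict[str, tuple[str, ...]]:
    """Random gene-set collection; an ``enriched_fraction`` of sets draws
    half of its members from the true DEG pool."""
    lo, hi = size_range
    if hi > len(universe.genes):
        raise ConfigurationError("gene-set size exceeds universe size")
    if enriched_fraction > 0 and truth is None:
        raise ConfigurationError("enriched sets require ground truth")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    genes = np.array(universe.genes)
    deg = np.array(sorted(truth.deg_genes)) if truth is not None else np.array([])
    non_deg = np.array([g for g in genes if g not in set(deg)])

    n_enriched = int(round(enriched_fraction * n_sets))
    sets: dict[str, tuple[str, ...]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched and len(deg):
            n_from_deg = min(size // 2, len(deg))
            members = np.concatenate(
                [
                    rng.choice(deg, size=n_from_deg, replace=False),
                    rng.choice(non_deg, size=size - n_from_deg, replace=False),
                ]
            )
            name = f"SET_ENR_{i:04d}"
        else:
            members = rng.choice(genes, size=size, replace=False)
            name = f"SET_{i:04d}"
        sets[name] = tuple(sorted(members))
    return sets


def simulate(config: SimConfig) -> SimulatedStudy:
    """Run the full generator: universe, expression, RT-PCR and gene sets."""
    universe, truth = generate_universe(config)
    layouts, matrices = generate_expression(config, universe)
    rtpcr = generate_rtpcr(config, universe, truth)
    gene_sets = generate_gene_sets(
        universe,
        config.n_gene_sets,
        config.gene_set_size_range,
        config.seed,
        enriched_fraction=config.gene_set_enriched_fraction,
        truth=truth,
    )
    return SimulatedStudy(config, universe, truth, layouts, matrices, rtpcr, gene_sets)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, str]:
    """Write every artefact of a simulation as TSV/GMT; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    for (platform, site), matrix in study.expression.items():
        stem = f"expression_{platform}_site{site}"
        dio.write_expression(matrix, outdir / f"{stem}.tsv")
        dio.write_sample_metadata(matrix.samples, outdir / f"{stem}.meta.tsv")
        paths[stem] = f"{stem}.tsv"
    for platform, layout in study.layouts.items():
        name = f"annotation_{platform}.tsv"
        dio.write_annotation(layout.annotation(), outdir / name)
        paths[f"annotation_{platform}"] = name

    dio.write_expression(study.rtpcr, outdir / "rtpcr.tsv")
    dio.write_sample_metadata(study.rtpcr.samples, outdir / "rtpcr.meta.tsv")
    paths["rtpcr"] = "rtpcr.tsv"

    dio.write_truth_table(study.truth.frame(), outdir / "truth.tsv")
    paths["truth"] = "truth.tsv"

    dio.write_gmt(study.gene_sets, outdir / "gene_sets.gmt")
    paths["gene_sets"] = "gene_sets.gmt"

    study.config.to_yaml(outdir / "config.yaml")
    paths["config"] = "config.yaml"
    return paths
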
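"""Synthetic spatial and single-nucleus dataset generators.

Counts are drawn gene-independently from a negative binomial with
log-normal per-observation size factors; structure (region marker
programs, condition-dependent effect programs, cell types and subtypes,
detection-rate variation) enters only through the mean. This is
deliberately the simplest generative model whose marginals every
downstream statistic assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from txflow.data import CONDITIONS, MITO_PREFIX, ConfigError, ExpressionDataset

__all__ = [
    "RegionSpec",
    "CellTypeSpec",
    "SubtypeSpec",
    "EffectProgram",
    "SpatialSimConfig",
    "SnSimConfig",
    "generate_spatial",
    "generate_snrna",
    "generate_reference_signatures",
    "generate_gene_sets",
    "default_spatial_config",
    "default_snrna_config",
    "default_region_map",
]


@dataclass(frozen=True)
class RegionSpec:
    """A spatial region: fraction of spots, marker genes, marker elevation."""

    name: str
    fraction: float
    markers: tuple[str, ...] = ()
    log2_elevation: float = 2.0


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    fraction: float
    markers: tuple[str, ...] = ()
    log2_elevation: float = 2.0


@dataclass(frozen=True)
class SubtypeSpec:
    """Inhibitory subtype defined by a single marker gene."""

    name: str
    marker: str
    fraction: float
    log2_elevation: float = 2.0


@dataclass(frozen=True)
class EffectProgram:
    """Condition-dependent mean shift of a gene set within one target
    region / cell type / subtype."""

    target: str
    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    log2_effect: float


def _check_fractions(fracs, what: str) -> None:
    if any(f < 0 for f in fracs):
        raise ConfigError(f"{what} fractions must be non-negative")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ConfigError(f"{what} fractions must sum to 1 (got {sum(fracs)})")


@dataclass(frozen=True)
class SpatialSimConfig:
    """Configuration of the spatial generator (hex lattice of spots)."""

    n_spots_per_sample: int = 3000
    grid_spacing: float = 1.0
    regions: tuple[RegionSpec, ...] = ()
    n_genes: int = 2000
    baseline_mean: float = 1.0
    nb_dispersion: float = 0.4
    mito_fraction_range: tuple[float, float] = (0.0, 0.1)
    n_mito_genes: int = 5
    conditions: tuple[str, ...] = tuple(CONDITIONS)
    n_samples_per_condition: int = 1
    libsize_sigma: float = 0.3
    effect_programs: tuple[EffectProgram, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots_per_sample <= 0:
            raise ConfigError("n_spots_per_sample must be positive")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be non-negative")
        if not self.regions:
            raise ConfigError("at least one region is required")
        _check_fractions([r.fraction for r in self.regions], "region")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ConfigError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        for p in self.effect_programs:
            if not math.isfinite(p.log2_effect):
                raise ConfigError("effect sizes must be finite")
            unknown = set(p.conditions) - set(self.conditions)
            if unknown:
                raise ConfigError(f"effect program references unknown "
                                  f"conditions {sorted(unknown)}")


@dataclass(frozen=True)
class SnSimConfig:
    """Configuration of the single-nucleus generator."""

    n_nuclei: int = 3000
    cell_types: tuple[CellTypeSpec, ...] = ()
    inhibitory_type: str = "Inh"
    inhibitory_subtypes: tuple[SubtypeSpec, ...] = ()
    n_genes: int = 1000
    baseline_mean: float = 1.0
    nb_dispersion: float = 0.4
    mito_fraction_range: tuple[float, float] = (0.0, 0.05)
    n_mito_genes: int = 5
    cdr_spread: float = 0.3
    conditions: tuple[str, ...] = tuple(CONDITIONS)
    n_samples_per_condition: int = 1
    effect_programs: tuple[EffectProgram, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei <= 0:
            raise ConfigError("n_nuclei must be positive")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.cdr_spread < 0:
            raise ConfigError("cdr_spread must be non-negative")
        if not self.cell_types:
            raise ConfigError("at least one cell type is required")
        _check_fractions([c.fraction for c in self.cell_types], "cell type")
        if self.inhibitory_subtypes:
            _check_fractions(
                [s.fraction for s in self.inhibitory_subtypes], "subtype"
            )
        for p in self.effect_programs:
            if not math.isfinite(p.log2_effect):
                raise ConfigError("effect sizes must be finite")


# ----------------------------------------------------------------------
# Gene universe


def gene_universe(config: SpatialSimConfig | SnSimConfig) -> list[str]:
    """Gene ids of the simulated universe: named marker/effect genes
    first, anonymous filler genes next, mitochondrial genes last."""
    named: dict[str, None] = {}
    groups = (
        config.regions if isinstance(config, SpatialSimConfig)
        else config.cell_types
    )
    for g in groups:
        for m in g.markers:
            named[m] = None
    if isinstance(config, SnSimConfig):
        for s in config.inhibitory_subtypes:
            named[s.marker] = None
    for p in config.effect_programs:
        for m in p.genes:
            named[m] = None
    n_named = len(named)
    n_filler = config.n_genes - n_named - config.n_mito_genes
    if n_filler < 0:
        raise ConfigError(
            f"n_genes={config.n_genes} too small for {n_named} named genes "
            f"plus {config.n_mito_genes} mitochondrial genes"
        )
    filler = [f"g{i:05d}" for i in range(n_filler)]
    mito = [f"{MITO_PREFIX}{i + 1}" for i in range(config.n_mito_genes)]
    return list(named) + filler + mito


def _split_counts(n: int, fractions: np.ndarray) -> np.ndarray:
    """Integer group sizes summing to n, proportional to fractions
    (largest-remainder rounding)."""
    raw = fractions * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def _hex_lattice(n: int, spacing: float) -> np.ndarray:
    """First ``n`` points of a row-offset hexagonal lattice."""
    ncol = int(math.ceil(math.sqrt(n)))
    rows = int(math.ceil(n / ncol))
    pts = []
    for r in range(rows):
        for c in range(ncol):
            pts.append(((c + 0.5 * (r % 2)) * spacing,
                        r * spacing * math.sqrt(3) / 2))
    return np.asarray(pts[:n])


def _angular_regions(coords: np.ndarray,
                     regions: tuple[RegionSpec, ...]) -> np.ndarray:
    """Assign contiguous angular sectors around the centroid."""
    center = coords.mean(axis=0)
    theta = np.arctan2(coords[:, 1] - center[1], coords[:, 0] - center[0])
    order = np.argsort(theta, kind="stable")
    sizes = _split_counts(len(coords), np.array([r.fraction for r in regions]))
    labels = np.empty(len(coords), dtype=object)
    start = 0
    for spec, size in zip(regions, sizes):
        labels[order[start:start + size]] = spec.name
        start += size
    return labels


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mean`` and variance
    ``mean + dispersion * mean**2`` (Poisson when dispersion == 0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def _apply_mito(mean: np.ndarray, mito_cols: np.ndarray,
                frac: np.ndarray) -> None:
    """Set mitochondrial gene means so each observation's expected
    mitochondrial fraction equals ``frac`` (in place)."""
    if mito_cols.size == 0:
        return
    nonmito_total = np.delete(mean, mito_cols, axis=1).sum(axis=1)
    per_gene = np.where(frac < 1, frac / (1 - frac), 0.0) * nonmito_total
    mean[:, mito_cols] = (per_gene / mito_cols.size)[:, None]


# ----------------------------------------------------------------------
# Generators


def generate_spatial(config: SpatialSimConfig) -> ExpressionDataset:
    """Simulate Visium-like spots on a hex lattice with contiguous
    regions, region marker programs, condition effect programs and
    log-normal library-size variation. Deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config)
    gidx = {g: i for i, g in enumerate(genes)}
    mito_cols = np.array(
        [i for i, g in enumerate(genes) if g.startswith(MITO_PREFIX)], dtype=int
    )
    _validate_program_genes(config, gidx)

    blocks = []
    obs_frames = []
    sample_no = 0
    for cond in config.conditions:
        for _rep in range(config.n_samples_per_condition):
            sample = f"S{sample_no}_{cond}"
            coords = _hex_lattice(config.n_spots_per_sample, config.grid_spacing)
            # each sample is its own slide: offset lattices so samples are
            # spatially disjoint islands
            span = coords[:, 0].max() - coords[:, 0].min()
            coords[:, 0] += sample_no * (span + 10 * config.grid_spacing)
            sample_no += 1
            region = _angular_regions(coords, config.regions)

            mean = np.full(
                (config.n_spots_per_sample, config.n_genes),
                config.baseline_mean,
            )
            for spec in config.regions:
                in_region = region == spec.name
                cols = [gidx[m] for m in spec.markers]
                if cols:
                    mean[np.ix_(in_region, cols)] *= 2.0 ** spec.log2_elevation
            for prog in config.effect_programs:
                if cond not in prog.conditions:
                    continue
                in_target = region == prog.target
                cols = [gidx[m] for m in prog.genes]
                mean[np.ix_(in_target, cols)] *= 2.0 ** prog.log2_effect

            lo, hi = config.mito_fraction_range
            frac = rng.uniform(lo, hi, size=config.n_spots_per_sample)
            _apply_mito(mean, mito_cols, frac)

            lib = np.exp(
                rng.normal(0.0, config.libsize_sigma,
                           size=config.n_spots_per_sample)
            )
            counts = _nb_draw(rng, mean * lib[:, None], config.nb_dispersion)
            blocks.append(sp.csr_matrix(counts))
            obs_frames.append(pd.DataFrame({
                "sample": sample,
                "condition": cond,
                "x": coords[:, 0],
                "y": coords[:, 1],
                "region": region,
            }, index=[f"{sample}_spot{i}" for i in range(len(coords))]))

    counts = sp.vstack(blocks, format="csr")
    obs = pd.concat(obs_frames)
    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    return ExpressionDataset(counts, obs, var)


def _validate_program_genes(config, gidx) -> None:
    for prog in config.effect_programs:
        missing = [g for g in prog.genes if g not in gidx]
        if missing:
            raise ConfigError(
                f"effect program genes not in universe: {missing}"
            )


def generate_snrna(config: SnSimConfig) -> ExpressionDataset:
    """Simulate single nuclei over cell types (with inhibitory subtypes),
    per-cell detection-rate variation, and condition effect programs."""
    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config)
    gidx = {g: i for i, g in enumerate(genes)}
    mito_cols = np.array(
        [i for i, g in enumerate(genes) if g.startswith(MITO_PREFIX)], dtype=int
    )
    _validate_program_genes(config, gidx)

    blocks = []
    obs_frames = []
    sample_no = 0
    for cond in config.conditions:
        for _rep in range(config.n_samples_per_condition):
            sample = f"S{sample_no}_{cond}"
            sample_no += 1
            n = config.n_nuclei

            type_sizes = _split_counts(
                n, np.array([c.fraction for c in config.cell_types])
            )
            cell_type = np.repeat(
                [c.name for c in config.cell_types], type_sizes
            ).astype(object)
            rng.shuffle(cell_type)

            subtype = np.array(["na"] * n, dtype=object)
            inh = np.flatnonzero(cell_type == config.inhibitory_type)
            if config.inhibitory_subtypes and inh.size:
                sub_sizes = _split_counts(
                    inh.size,
                    np.array([s.fraction for s in config.inhibitory_subtypes]),
                )
                sub_labels = np.repeat(
                    [s.name for s in config.inhibitory_subtypes], sub_sizes
                )
                subtype[inh] = sub_labels

            mean = np.full((n, config.n_genes), config.baseline_mean)
            for spec in config.cell_types:
                in_type = cell_type == spec.name
                cols = [gidx[m] for m in spec.markers]
                if cols:
                    mean[np.ix_(in_type, cols)] *= 2.0 ** spec.log2_elevation
            for spec in config.inhibitory_subtypes:
                in_sub = subtype == spec.name
                mean[np.ix_(in_sub, [gidx[spec.marker]])] *= (
                    2.0 ** spec.log2_elevation
                )
            for prog in config.effect_programs:
                if cond not in prog.conditions:
                    continue
                in_target = (cell_type == prog.target) | (subtype == prog.target)
                cols = [gidx[m] for m in prog.genes]
                mean[np.ix_(in_target, cols)] *= 2.0 ** prog.log2_effect

            lo, hi = config.mito_fraction_range
            frac = rng.uniform(lo, hi, size=n)
            _apply_mito(mean, mito_cols, frac)

            # detection-rate factor: scales every gene's mean per cell
            cdr_factor = np.exp(rng.normal(0.0, config.cdr_spread, size=n))
            counts = _nb_draw(rng, mean * cdr_factor[:, None],
                              config.nb_dispersion)
            blocks.append(sp.csr_matrix(counts))
            obs_frames.append(pd.DataFrame({
                "sample": sample,
                "condition": cond,
                "cell_type": cell_type,
                "subtype": subtype,
            }, index=[f"{sample}_nuc{i}" for i in range(n)]))

    counts = sp.vstack(blocks, format="csr")
    obs = pd.concat(obs_frames)
    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    return ExpressionDataset(counts, obs, var)


# ----------------------------------------------------------------------
# Reference signatures and gene sets


def generate_reference_signatures(config: SpatialSimConfig) -> pd.DataFrame:
    """True mean expression profile of each region's cell type
    (``<region>_cell`` x gene), aligned with :func:`generate_spatial`
    gene ids. Mitochondrial means are taken at the midpoint of the
    configured fraction range; condition effects are excluded."""
    genes = gene_universe(config)
    gidx = {g: i for i, g in enumerate(genes)}
    mito_cols = np.array(
        [i for i, g in enumerate(genes) if g.startswith(MITO_PREFIX)], dtype=int
    )
    rows = []
    for spec in config.regions:
        mean = np.full((1, config.n_genes), config.baseline_mean)
        cols = [gidx[m] for m in spec.markers]
        if cols:
            mean[0, cols] *= 2.0 ** spec.log2_elevation
        frac = np.array([np.mean(config.mito_fraction_range)])
        _apply_mito(mean, mito_cols, frac)
        rows.append(mean[0])
    return pd.DataFrame(
        rows,
        index=pd.Index([f"{r.name}_cell" for r in config.regions],
                       name="cell_type"),
        columns=genes,
    )


def default_region_map(config: SpatialSimConfig) -> dict[str, str]:
    """Cell type -> region mapping matching the generated signatures."""
    return {f"{r.name}_cell": r.name for r in config.regions}


def generate_gene_sets(
    kind: str,
    config: SpatialSimConfig | SnSimConfig,
    n_sets: int = 10,
    set_size: int = 10,
    seed: int = 0,
    active_program: EffectProgram | None = None,
    exclude: set[str] | None = None,
) -> dict[str, list[str]]:
    """Named gene sets over the simulated universe.

    For ``kind="regulon"`` with an ``active_program``, the first set
    (``"regulon_active"``) is exactly the program's member genes, so its
    activity is elevated wherever the program is; the remaining sets are
    random distractors. ``kind="pathway"`` yields random sets only.
    Genes in ``exclude`` are kept out of the random sets (e.g. pass all
    effect-program genes to obtain strictly null distractors).
    """
    if kind not in ("regulon", "pathway"):
        raise ConfigError(f"unknown gene set kind {kind!r}")
    universe = gene_universe(config)
    uset = set(universe)
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    if active_program is not None:
        missing = [g for g in active_program.genes if g not in uset]
        if missing:
            raise ConfigError(f"unknown gene ids in active program: {missing}")
        sets["regulon_active"] = list(active_program.genes)
    pool = [g for g in universe if g not in (exclude or set())]
    for i in range(n_sets):
        members = rng.choice(pool, size=min(set_size, len(pool)),
                             replace=False)
        sets[f"{kind}_{i}"] = list(members)
    return sets


# ----------------------------------------------------------------------
# Default configurations


def default_spatial_config(**overrides) -> SpatialSimConfig:
    """Six contiguous regions with marker programs, an IEG-like program
    induced in the DCN under CD and TN, and one gene induced in CD only."""
    def _markers(lead: tuple[str, ...], tag: str) -> tuple[str, ...]:
        return lead + tuple(f"{tag}_m{j}" for j in range(8 - len(lead)))

    regions = (
        RegionSpec("molecular_layer", 0.20, _markers(("Calb2m",), "ml"), 2.0),
        RegionSpec("granular_layer", 0.25,
                   _markers(("Gabra6", "Neurod1"), "gl"), 2.0),
        RegionSpec("purkinje_layer", 0.10,
                   _markers(("Calb1", "Pcp2"), "pl"), 2.0),
        RegionSpec("DCN", 0.15, _markers(("Snap25d", "Slc17a6"), "dcn"), 2.0),
        RegionSpec("white_matter", 0.15, _markers(("Mbp", "Plp1"), "wm"), 2.0),
        RegionSpec("medulla", 0.15, _markers(("Th", "Slc6a5"), "md"), 2.0),
    )
    effects = (
        EffectProgram("DCN", ("Fos", "Junb", "Egr1"), ("CD", "TN"), 1.0),
        EffectProgram("DCN", ("Npas4",), ("CD",), 1.0),
    )
    defaults = dict(regions=regions, effect_programs=effects)
    defaults.update(overrides)
    return SpatialSimConfig(**defaults)


def default_snrna_config(**overrides) -> SnSimConfig:
    """Six cell types with three inhibitory subtypes, a Grm5-like effect
    in the Kit-like subtype (CD and TN) and a myelination-like program in
    oligodendrocytes (TN only)."""
    cell_types = (
        CellTypeSpec("Exc", 0.35, ("Slc17a6", "Snap25e")),
        CellTypeSpec("Inh", 0.25, ("Gad1", "Gad2")),
        CellTypeSpec("Astro", 0.12, ("Aqp4", "Gja1")),
        CellTypeSpec("Oligo", 0.12, ("Mbp", "Plp1")),
        CellTypeSpec("OPC", 0.08, ("Pdgfra", "Cspg4")),
        CellTypeSpec("Micro", 0.08, ("Cx3cr1", "Csf1r")),
    )
    subtypes = (
        SubtypeSpec("Inh-Kit", "Kit", 0.4),
        SubtypeSpec("Inh-Zfhx4", "Zfhx4", 0.35),
        SubtypeSpec("Inh-Piezo2", "Piezo2", 0.25),
    )
    effects = (
        EffectProgram("Inh-Kit", ("Grm5",), ("CD", "TN"), 1.0),
        EffectProgram("Oligo", ("Mal", "Mog", "Cnp"), ("TN",), 1.0),
    )
    defaults = dict(
        cell_types=cell_types,
        inhibitory_subtypes=subtypes,
        effect_programs=effects,
    )
    defaults.update(overrides)
    return SnSimConfig(**defaults)
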
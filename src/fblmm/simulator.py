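"""Synthetic family-based sequencing studies.

Generates founder genotypes over a minor-allele-frequency spectrum that
includes rare variants, drops them through configurable pedigrees by
Mendelian transmission, and simulates quantitative outcomes under three
disease models: shared environment only, genetic only (with one causal
region unmeasured), and a combined additive model.  Founders are
Hardy-Weinberg binomial draws — a synthetic stand-in for a real founder
genotype pool, which is not distributable.  Loci segregate independently
(no linkage), which suffices for phenotype models built on unlinked
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, Pedigree, PedigreeRecord, PhenotypeTable, RegionMap
from .kernels import WeightScheme, build_region_kernel

__all__ = [
    "MafSampler",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_founders",
    "build_pedigrees",
    "gene_drop",
    "simulate_env_only",
    "simulate_genetic_only",
    "simulate_combined",
    "run_scenario",
    "SCENARIO_PRESETS",
]


@dataclass(frozen=True)
class MafSampler:
    """Mixture spectrum: a `rare_fraction` of variants draw their target
    maf from Uniform(rare_low, rare_high), the rest from
    Uniform(common_low, common_high)."""

    rare_fraction: float = 0.3
    rare_low: float = 0.001
    rare_high: float = 0.01
    common_low: float = 0.05
    common_high: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must be in [0, 1]")
        for lo, hi in ((self.rare_low, self.rare_high), (self.common_low, self.common_high)):
            if not 0.0 < lo <= hi <= 0.5:
                raise ValueError("maf bounds must satisfy 0 < low <= high <= 0.5")

    def draw(self, p: int, rng: np.random.Generator) -> np.ndarray:
        rare = rng.random(p) < self.rare_fraction
        maf = np.where(
            rare,
            rng.uniform(self.rare_low, self.rare_high, size=p),
            rng.uniform(self.common_low, self.common_high, size=p),
        )
        return maf


# structure name -> number of individuals it contributes
STRUCTURE_SIZES = {
    "half-sib-5": 5,
    "nuclear-2-offspring": 4,
    "nuclear-4-offspring": 6,
    "twin": 4,
    "mz-twin": 4,
    "trio": 3,
    "threegen-avuncular": 6,
    "threegen-double-cousin": 10,
    "threegen-grandparent": 5,
    "threegen-sibling": 8,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to regenerate one synthetic study."""

    founder_pool: int = 808
    n_variants: int = 260
    maf_sampler: MafSampler = MafSampler()
    pedigree_blocks: tuple[tuple[str, int], ...] = (
        ("half-sib-5", 30),
        ("nuclear-2-offspring", 177),
        ("nuclear-4-offspring", 197),
    )
    model: str = "env-only"  # env-only | genetic-only | combined | S1 | S2 | S3
    causal_region_sizes: tuple[int, ...] = (20, 20, 20)
    weight_scheme: WeightScheme = WeightScheme("uniform")
    env_fraction: float = 0.5          # env-only: sigma_a^2 / (sigma_a^2 + sigma^2)
    h_total: float = 0.6               # genetic-only: total heritability
    unmeasured_fraction: float = 0.5   # genetic-only: share of h from the unmeasured gene
    explained_total: float = 0.4       # combined / S models: total explained variance
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h_total < 1.0:
            raise ValueError("h_total must be in [0, 1)")
        if not 0.0 <= self.env_fraction <= 1.0:
            raise ValueError("env_fraction must be in [0, 1]")
        for name, count in self.pedigree_blocks:
            if name not in STRUCTURE_SIZES:
                raise ValueError(f"unknown pedigree structure {name!r}")
            if count < 1 or count != int(count):
                raise ValueError("pedigree counts must be positive integers")


@dataclass
class SimulatedStudy:
    """One synthetic dataset plus its ground truth.

    ``genotypes`` contains only the measured variants; the unmeasured
    causal region, when present, lives in ``hidden_genotypes``.  The
    ``components`` arrays sum exactly to the phenotype.
    """

    config: SimulationConfig
    genotypes: GenotypeMatrix
    hidden_genotypes: Optional[GenotypeMatrix]
    pedigree: Pedigree
    phenotypes: PhenotypeTable
    region_map: RegionMap
    components: dict[str, np.ndarray]
    variance_partition: dict[str, float]

    @property
    def phenotype(self) -> np.ndarray:
        return self.phenotypes.phenotype


def simulate_founders(
    n: int,
    p: int,
    maf_sampler: MafSampler | Callable[[int, np.random.Generator], np.ndarray],
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Hardy-Weinberg founder pool: dosage_j ~ Binomial(2, maf_j).

    Realized-monomorphic columns are redrawn up to 10 times and dropped if
    still monomorphic, so every exported variant is polymorphic in the pool.
    """
    if n < 1 or p < 1:
        raise ValueError("need n >= 1 founders and p >= 1 variants")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draw = maf_sampler.draw if isinstance(maf_sampler, MafSampler) else maf_sampler
    target = np.asarray(draw(p, rng), dtype=float)
    if np.any(target <= 0.0) or np.any(target > 0.5):
        raise ValueError("maf sampler must return values in (0, 0.5]")
    dosages = rng.binomial(2, target, size=(n, p)).astype(float)
    for _ in range(10):
        mono = (dosages.sum(axis=0) == 0) | (dosages.sum(axis=0) == 2 * n)
        if not mono.any():
            break
        dosages[:, mono] = rng.binomial(2, target[mono], size=(n, int(mono.sum())))
    mono = (dosages.sum(axis=0) == 0) | (dosages.sum(axis=0) == 2 * n)
    keep = ~mono
    dosages = dosages[:, keep]
    ids = [f"v{j}" for j in range(p)]
    kept_ids = [v for v, k in zip(ids, keep) if k]
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * len(kept_ids),
            "pos": np.arange(1, len(kept_ids) + 1),
            "a1": ["A"] * len(kept_ids),
            "a2": ["G"] * len(kept_ids),
        },
        index=pd.Index(kept_ids, name="variant"),
    )
    samples = [f"P{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def _structure_records(structure: str, fam: str) -> list[PedigreeRecord]:
    R = PedigreeRecord
    if structure == "half-sib-5":
        # one shared parent, two mates, one offspring per mate pair
        return [
            R(f"{fam}_p", fam, None, None),
            R(f"{fam}_m1", fam, None, None),
            R(f"{fam}_m2", fam, None, None),
            R(f"{fam}_c1", fam, f"{fam}_p", f"{fam}_m1"),
            R(f"{fam}_c2", fam, f"{fam}_p", f"{fam}_m2"),
        ]
    if structure in ("nuclear-2-offspring", "twin", "mz-twin"):
        mz = f"{fam}_mz" if structure == "mz-twin" else None
        return [
            R(f"{fam}_f", fam, None, None),
            R(f"{fam}_m", fam, None, None),
            R(f"{fam}_c1", fam, f"{fam}_f", f"{fam}_m", mz_group=mz),
            R(f"{fam}_c2", fam, f"{fam}_f", f"{fam}_m", mz_group=mz),
        ]
    if structure == "nuclear-4-offspring":
        kids = [
            R(f"{fam}_c{k}", fam, f"{fam}_f", f"{fam}_m") for k in range(1, 5)
        ]
        return [R(f"{fam}_f", fam, None, None), R(f"{fam}_m", fam, None, None)] + kids
    if structure == "trio":
        return [
            R(f"{fam}_f", fam, None, None),
            R(f"{fam}_m", fam, None, None),
            R(f"{fam}_c", fam, f"{fam}_f", f"{fam}_m"),
        ]
    if structure == "threegen-grandparent":
        return [
            R(f"{fam}_gf", fam, None, None),
            R(f"{fam}_gm", fam, None, None),
            R(f"{fam}_p", fam, f"{fam}_gf", f"{fam}_gm"),
            R(f"{fam}_s", fam, None, None),
            R(f"{fam}_c", fam, f"{fam}_p", f"{fam}_s"),
        ]
    if structure == "threegen-avuncular":
        return [
            R(f"{fam}_gf", fam, None, None),
            R(f"{fam}_gm", fam, None, None),
            R(f"{fam}_p1", fam, f"{fam}_gf", f"{fam}_gm"),
            R(f"{fam}_p2", fam, f"{fam}_gf", f"{fam}_gm"),
            R(f"{fam}_s", fam, None, None),
            R(f"{fam}_c", fam, f"{fam}_p1", f"{fam}_s"),
        ]
    if structure == "threegen-sibling":
        return [
            R(f"{fam}_gf", fam, None, None),
            R(f"{fam}_gm", fam, None, None),
            R(f"{fam}_p1", fam, f"{fam}_gf", f"{fam}_gm"),
            R(f"{fam}_p2", fam, f"{fam}_gf", f"{fam}_gm"),
            R(f"{fam}_s1", fam, None, None),
            R(f"{fam}_s2", fam, None, None),
            R(f"{fam}_c1", fam, f"{fam}_p1", f"{fam}_s1"),
            R(f"{fam}_c2", fam, f"{fam}_p2", f"{fam}_s2"),
        ]
    if structure == "threegen-double-cousin":
        # sibling pairs from two founder couples marry crosswise: the two
        # grandchildren are double first cousins
        recs = [
            R(f"{fam}_agf", fam, None, None),
            R(f"{fam}_agm", fam, None, None),
            R(f"{fam}_bgf", fam, None, None),
            R(f"{fam}_bgm", fam, None, None),
            R(f"{fam}_a1", fam, f"{fam}_agf", f"{fam}_agm"),
            R(f"{fam}_a2", fam, f"{fam}_agf", f"{fam}_agm"),
            R(f"{fam}_b1", fam, f"{fam}_bgf", f"{fam}_bgm"),
            R(f"{fam}_b2", fam, f"{fam}_bgf", f"{fam}_bgm"),
            R(f"{fam}_c1", fam, f"{fam}_a1", f"{fam}_b1"),
            R(f"{fam}_c2", fam, f"{fam}_a2", f"{fam}_b2"),
        ]
        return recs
    raise ValueError(f"unknown pedigree structure {structure!r}")


def build_pedigrees(blocks: Sequence[tuple[str, int]]) -> Pedigree:
    """Assemble a pedigree from (structure, count) blocks.

    Individual counts per structure are deterministic (STRUCTURE_SIZES),
    e.g. 30 half-sib pedigrees contribute exactly 150 individuals.
    """
    records: list[PedigreeRecord] = []
    fam_no = 0
    for structure, count in blocks:
        if structure not in STRUCTURE_SIZES:
            raise ValueError(f"unknown pedigree structure {structure!r}")
        for _ in range(count):
            fam_no += 1
            records.extend(_structure_records(structure, f"F{fam_no}"))
    return Pedigree(records=records)


def gene_drop(
    ped: Pedigree,
    founders: GenotypeMatrix,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Mendelian transmission of founder genotypes through the pedigree.

    Pedigree founders are assigned rows of the founder pool (without
    replacement while the pool lasts, with replacement once pedigree
    founders outnumber it).  A founder's dosage is split into two allele
    draws (dosage 1 = heterozygote); each offspring inherits one uniformly
    random allele from each parent, independently per variant.  MZ-group
    members share one transmitted genome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = founders.n_variants
    ped_founders = ped.founders
    pool_n = founders.n_samples
    if len(ped_founders) <= pool_n:
        rows = rng.choice(pool_n, size=len(ped_founders), replace=False)
    else:
        rows = rng.choice(pool_n, size=len(ped_founders), replace=True)
    founder_row = dict(zip(ped_founders, rows))

    haplos: dict[str, np.ndarray] = {}  # individual -> (2, p) allele matrix
    mz_genomes: dict[str, np.ndarray] = {}
    for rec in ped.records:  # topological order: parents first
        if rec.is_founder:
            d = founders.dosages[founder_row[rec.individual]]
            h = np.zeros((2, p), dtype=np.int8)
            h[0] = d >= 1  # dosage 1 -> heterozygote, 2 -> both alleles
            h[1] = d == 2
            haplos[rec.individual] = h
        else:
            if rec.mz_group is not None and rec.mz_group in mz_genomes:
                haplos[rec.individual] = mz_genomes[rec.mz_group]
                continue
            hf, hm = haplos[rec.father], haplos[rec.mother]
            h = np.empty((2, p), dtype=np.int8)
            h[0] = hf[rng.integers(0, 2, size=p), np.arange(p)]
            h[1] = hm[rng.integers(0, 2, size=p), np.arange(p)]
            haplos[rec.individual] = h
            if rec.mz_group is not None:
                mz_genomes[rec.mz_group] = h
    dosages = np.array(
        [haplos[ind].sum(axis=0) for ind in ped.individuals], dtype=float
    )
    return GenotypeMatrix(
        samples=list(ped.individuals),
        variants=founders.variants.copy(),
        dosages=dosages,
    )


def _family_effects(ped: Pedigree, sigma_a2: float, rng: np.random.Generator) -> np.ndarray:
    fams = ped.families
    draw = {f: rng.normal(0.0, np.sqrt(sigma_a2)) for f in fams}
    fam_of = {r.individual: r.family for r in ped.records}
    return np.array([draw[fam_of[s]] for s in ped.individuals])


def simulate_env_only(
    ped: Pedigree,
    sigma_a2: float,
    sigma2: float,
    seed: int | np.random.Generator = 0,
) -> tuple[PhenotypeTable, dict[str, np.ndarray]]:
    """Y = alpha + eps with alpha shared within family.

    Equivalent to Y ~ N(0, K sigma_a^2 + I sigma^2) with K the block-of-ones
    family matrix; the within-family (intraclass) correlation is
    sigma_a^2 / (sigma_a^2 + sigma^2).
    """
    if sigma_a2 < 0 or sigma2 < 0:
        raise ValueError("variances must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = _family_effects(ped, sigma_a2, rng)
    eps = rng.normal(0.0, np.sqrt(sigma2), size=len(ped.individuals))
    y = alpha + eps
    table = pd.DataFrame(
        {"phenotype": y}, index=pd.Index(ped.individuals, name="individual")
    )
    return PhenotypeTable(table=table), {"env": alpha, "residual": eps}


def _scale_to_variance(x: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale a draw to hit a sample variance exactly (zero draws and zero
    targets pass through)."""
    if target_var <= 0.0:
        return np.zeros_like(x)
    sd = x.std()
    if sd == 0.0:
        return x
    return (x - x.mean()) * (np.sqrt(target_var) / sd)


def _draw_region_effect(
    genotypes: GenotypeMatrix,
    name: str,
    variant_ids: Sequence[str],
    scheme: WeightScheme,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw of g ~ N(0, K) for a region kernel built under `scheme`."""
    rk = build_region_kernel(genotypes, name, variant_ids, scheme=scheme, center=True)
    z = rng.standard_normal(rk.rank)
    return rk.Z @ z


def _split_regions(
    variant_ids: Sequence[str], sizes: Sequence[int]
) -> dict[str, list[str]]:
    if sum(sizes) > len(variant_ids):
        raise ValueError("not enough variants for the requested causal regions")
    regions: dict[str, list[str]] = {}
    start = 0
    for i, sz in enumerate(sizes, start=1):
        regions[f"gene{i}"] = list(variant_ids[start : start + sz])
        start += sz
    return regions


def _assemble_study(
    config: SimulationConfig,
    ped: Pedigree,
    G_all: GenotypeMatrix,
    regions: dict[str, list[str]],
    unmeasured: Optional[str],
    components: dict[str, np.ndarray],
) -> SimulatedStudy:
    y = np.sum(list(components.values()), axis=0)
    table = pd.DataFrame(
        {"phenotype": y}, index=pd.Index(ped.individuals, name="individual")
    )
    hidden = None
    measured_ids = list(G_all.variants.index)
    if unmeasured is not None:
        hidden_ids = regions[unmeasured]
        hidden = G_all.subset(variants=hidden_ids)
        measured_ids = [v for v in measured_ids if v not in set(hidden_ids)]
    genotypes = G_all.subset(variants=measured_ids)
    region_map = RegionMap(
        regions={n: v for n, v in regions.items() if n != unmeasured}
    )
    var_y = float(np.var(y)) if np.var(y) > 0 else 1.0
    partition = {k: float(np.var(v)) / var_y for k, v in components.items()}
    return SimulatedStudy(
        config=config,
        genotypes=genotypes,
        hidden_genotypes=hidden,
        pedigree=ped,
        phenotypes=PhenotypeTable(table=table),
        region_map=region_map,
        components=components,
        variance_partition=partition,
    )


def simulate_genetic_only(
    G_all: GenotypeMatrix,
    regions: dict[str, list[str]],
    ped: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedStudy:
    """Y = sum_m g_m + eps over three causal regions, one unmeasured.

    Component draws are rescaled to hit the target variance partition
    exactly in-sample: total heritability ``h_total``, a fraction
    ``unmeasured_fraction`` of it carried by the unmeasured gene, the rest
    split evenly over the measured genes.
    """
    names = list(regions)
    if len(names) != 3:
        raise ValueError("genetic-only model expects exactly 3 causal regions")
    unmeasured = names[int(rng.integers(0, len(names)))]
    h, uf = config.h_total, config.unmeasured_fraction
    shares = {
        name: (h * uf if name == unmeasured else h * (1 - uf) / 2.0)
        for name in names
    }
    components: dict[str, np.ndarray] = {}
    for name in names:
        raw = _draw_region_effect(G_all, name, regions[name], config.weight_scheme, rng)
        key = "unmeasured" if name == unmeasured else f"region:{name}"
        components[key] = _scale_to_variance(raw, shares[name])
    eps = rng.standard_normal(G_all.n_samples)
    components["residual"] = _scale_to_variance(eps, 1.0 - h)
    return _assemble_study(config, ped, G_all, regions, unmeasured, components)


def simulate_combined(
    G_all: GenotypeMatrix,
    regions: dict[str, list[str]],
    ped: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedStudy:
    """Y = alpha + sum_m g_m + eps with one causal region unmeasured.

    In the default equal-contribution mode the shared-environment variance
    equals the total genetic variance; the S1-S3 presets reweight the
    partition to their defining inequalities.
    """
    names = list(regions)
    if len(names) != 3:
        raise ValueError("combined model expects exactly 3 causal regions")
    unmeasured = names[int(rng.integers(0, len(names)))]
    v = config.explained_total
    model = config.model
    if model in ("combined", "S1"):
        if model == "combined":
            # env = total genetic, genetic split evenly over the 3 regions
            env_share, shares = v / 2.0, {n: v / 6.0 for n in names}
        else:
            # unmeasured variance equals the sum of the measured variances
            env_share = 0.0
            shares = {n: (v / 2.0 if n == unmeasured else v / 4.0) for n in names}
    elif model == "S2":
        # shared environment dominates the measured genetic contribution
        env_share = v / 2.0
        shares = {n: (v / 4.0 if n == unmeasured else v / 8.0) for n in names}
    elif model == "S3":
        # unmeasured genetic variance dominates everything else combined
        env_share = v / 6.0
        shares = {n: (2.0 * v / 3.0 if n == unmeasured else v / 12.0) for n in names}
    else:
        raise ValueError(f"unknown combined-model preset {model!r}")
    components: dict[str, np.ndarray] = {}
    components["env"] = _scale_to_variance(_family_effects(ped, 1.0, rng), env_share)
    # S1 keeps a zero env component so the conservation invariant still holds
    if env_share == 0.0:
        components["env"] = np.zeros(G_all.n_samples)
    for name in names:
        scheme = config.weight_scheme
        raw = _draw_region_effect(G_all, name, regions[name], scheme, rng)
        key = "unmeasured" if name == unmeasured else f"region:{name}"
        components[key] = _scale_to_variance(raw, shares[name])
    eps = rng.standard_normal(G_all.n_samples)
    components["residual"] = _scale_to_variance(eps, 1.0 - env_share - sum(shares.values()))
    return _assemble_study(config, ped, G_all, regions, unmeasured, components)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full pipeline for one configuration: founders, pedigrees,
    gene dropping, then the configured phenotype model."""
    rng = np.random.default_rng(config.seed)
    ped = build_pedigrees(config.pedigree_blocks)
    founders = simulate_founders(
        config.founder_pool, config.n_variants, config.maf_sampler, rng
    )
    G_all = gene_drop(ped, founders, rng)
    regions = _split_regions(list(G_all.variants.index), config.causal_region_sizes)
    if config.model == "env-only":
        total = 1.0
        sa2 = config.env_fraction * total
        s2 = total - sa2
        pheno, comps = simulate_env_only(ped, sa2, s2, rng)
        study = _assemble_study(config, ped, G_all, regions, None, comps)
        return study
    if config.model == "genetic-only":
        return simulate_genetic_only(G_all, regions, ped, config, rng)
    if config.model in ("combined", "S1", "S2", "S3"):
        return simulate_combined(G_all, regions, ped, config, rng)
    raise ValueError(f"unknown phenotype model {config.model!r}")


_TWO_GEN_BLOCKS = (
    ("half-sib-5", 30),
    ("nuclear-2-offspring", 177),
    ("nuclear-4-offspring", 197),
)
_THREE_GEN_BLOCKS = (
    ("threegen-avuncular", 24),
    ("threegen-double-cousin", 30),
    ("threegen-grandparent", 42),
    ("threegen-sibling", 278),
)

SCENARIO_PRESETS: dict[str, SimulationConfig] = {
    "fig2": SimulationConfig(model="env-only", pedigree_blocks=_TWO_GEN_BLOCKS),
    "fig3A": SimulationConfig(
        model="genetic-only", pedigree_blocks=_TWO_GEN_BLOCKS,
        weight_scheme=WeightScheme("uniform"), h_total=0.6,
    ),
    "fig3B": SimulationConfig(
        model="genetic-only", pedigree_blocks=_TWO_GEN_BLOCKS,
        weight_scheme=WeightScheme("beta"), h_total=0.6,
        maf_sampler=MafSampler(rare_fraction=0.7),
    ),
    "fig3C": SimulationConfig(
        model="genetic-only", pedigree_blocks=_TWO_GEN_BLOCKS,
        weight_scheme=WeightScheme("wss"), h_total=0.6,
        maf_sampler=MafSampler(rare_fraction=0.7),
    ),
    "fig4": SimulationConfig(
        model="combined", pedigree_blocks=_TWO_GEN_BLOCKS, explained_total=0.4,
    ),
    "S1": SimulationConfig(
        model="S1", pedigree_blocks=(("mz-twin", 125), ("twin", 125)),
        explained_total=0.4,
    ),
    "S2": SimulationConfig(
        model="S2", pedigree_blocks=(("mz-twin", 125), ("twin", 125)),
        explained_total=0.4,
    ),
    "S3": SimulationConfig(
        model="S3", pedigree_blocks=(("mz-twin", 125), ("twin", 125)),
        explained_total=0.4,
    ),
}


def run_scenario(
    preset: str, overrides: Optional[dict] = None, seed: Optional[int] = None
) -> SimulatedStudy:
    """Instantiate a named study design, optionally overridden field by
    field (e.g. desk-scale pedigree blocks) and re-seeded."""
    if preset not in SCENARIO_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(SCENARIO_PRESETS)}"
        )
    config = SCENARIO_PRESETS[preset]
    if overrides:
        config = replace(config, **overrides)
    if seed is not None:
        config = replace(config, seed=seed)
    return simulate_study(config)
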
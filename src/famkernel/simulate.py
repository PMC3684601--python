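"""Synthetic pedigrees, gene-dropped genotypes and polygenic phenotypes.

The generator reproduces the statistical structure the method assumes:
multigeneration families defining a block-diagonal relationship matrix, a
mixture of common and rare unlinked variants transmitted by Mendelian gene
dropping, and traits y = sum_c beta_c g_c + u + e with cov(u) = sigma2_g R.
Replicates derive independent child RNG streams from one global seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import GenotypeRegion, PedigreeTable
from .kinship import RelationshipMatrix

MAX_SEED = 2 ** 31 - 1


@dataclass
class CausalSpec:
    """Causal-region description for power studies.

    ``n_causal`` markers of the region receive effects; when
    ``maf_weighted`` is set, |beta_c| is proportional to |log10 maf_c|
    (rarer variants get larger effects). ``mixed_sign`` alternates effect
    directions; ``variance`` is the total trait variance contributed by the
    causal markers (in trait-variance units, before u and e are added).
    """

    region: int = 0
    n_causal: int = 10
    variance: float = 0.05
    mixed_sign: bool = True
    maf_weighted: bool = True


@dataclass
class SimConfig:
    """Study-design parameters for the replicate simulations.

    Defaults are the desk-scale null design used throughout the calibration
    study: 50 three-generation families (~500 individuals), 200 unlinked
    markers (half common, half rare), a fully polygenic trait with
    h2 = 0.5 and total variance 1.
    """

    n_families: int = 50
    generations: int = 3
    offspring_per_couple: int = 2
    n_variants: int = 200
    common_fraction: float = 0.5
    common_maf: tuple[float, float] = (0.05, 0.5)
    rare_maf_max: float = 0.05
    rare_maf_beta: tuple[float, float] = (1.0, 2.0)
    h2: float = 0.5
    sigma2: float = 1.0
    causal: CausalSpec | None = None
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must lie in [0, 1)")
        if not (0 <= self.common_fraction <= 1):
            raise ValueError("common_fraction must lie in [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("causal"):
            d["causal"] = CausalSpec(**d["causal"])
        if "common_maf" in d:
            d["common_maf"] = tuple(d["common_maf"])
        if "rare_maf_beta" in d:
            d["rare_maf_beta"] = tuple(d["rare_maf_beta"])
        return cls(**d)


def child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Independent per-replicate seed sequences from one global seed."""
    return np.random.SeedSequence(seed).spawn(n)


def simulate_pedigree(n_families: int = 50, generations: int = 3,
                      offspring_per_couple: int = 2,
                      seed: int | None = None) -> PedigreeTable:
    """Non-overlapping families: a founder couple plus ``generations - 1``
    descendant generations; each non-terminal child marries a new founder.

    The structure is deterministic given the arguments (the seed is kept
    for interface symmetry with the stochastic generators).
    """
    rows = []

    def add(fid, iid, father, mother, sex):
        rows.append((f"F{fid}", f"F{fid}_I{iid}",
                     f"F{fid}_I{father}" if father else "0",
                     f"F{fid}_I{mother}" if mother else "0", sex))

    for f in range(1, n_families + 1):
        counter = 0

        def nxt():
            nonlocal counter
            counter += 1
            return counter

        pa, ma = nxt(), nxt()
        add(f, pa, 0, 0, 1)
        add(f, ma, 0, 0, 2)
        couples = [(pa, ma)]
        for gen in range(2, generations + 1):
            next_couples = []
            for (fa, mo) in couples:
                for k in range(offspring_per_couple):
                    child = nxt()
                    sex = 1 if k % 2 == 0 else 2
                    add(f, child, fa, mo, sex)
                    if gen < generations:
                        spouse = nxt()
                        add(f, spouse, 0, 0, 2 if sex == 1 else 1)
                        next_couples.append((child, spouse) if sex == 1
                                            else (spouse, child))
            couples = next_couples
    t = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    return PedigreeTable(t)


def draw_mafs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Founder MAF spectrum: common Uniform plus rare Beta-skewed mass."""
    m = cfg.n_variants
    common = rng.random(m) < cfg.common_fraction
    mafs = np.empty(m)
    mafs[common] = rng.uniform(*cfg.common_maf, common.sum())
    mafs[~common] = cfg.rare_maf_max * rng.beta(*cfg.rare_maf_beta,
                                                (~common).sum())
    return np.clip(mafs, 1e-6, 0.5)


def gene_drop(ped: PedigreeTable, founder_mafs: np.ndarray,
              seed=None) -> np.ndarray:
    """Drop unlinked variants through the pedigree; returns N x M coded {0,0.5,1}.

    Founder alleles are Bernoulli(maf) per haplotype; each offspring inherits
    one uniformly chosen allele from each parent, independently per marker.
    Rows follow the pedigree's own order.
    """
    rng = np.random.default_rng(seed)
    mafs = np.asarray(founder_mafs, dtype=float)
    m = len(mafs)
    order = ped.topological_order()
    parents = ped.parent_map()
    hap: dict[str, np.ndarray] = {}
    for iid in order:
        fa, mo = parents[iid]
        h = np.empty((2, m), dtype=np.int8)
        for k, p in enumerate((fa, mo)):
            if p in hap:
                pick = rng.integers(0, 2, m)
                h[k] = hap[p][pick, np.arange(m)]
            else:
                h[k] = rng.random(m) < mafs
        hap[iid] = h
    G = np.vstack([hap[i].sum(axis=0) for i in ped.ids]) / 2.0
    return G


def genotype_regions(ped: PedigreeTable, cfg: SimConfig,
                     seed=None, chrom: str = "1") -> GenotypeRegion:
    """One gene-dropped chromosome of cfg.n_variants unlinked markers."""
    rng = np.random.default_rng(seed)
    mafs = draw_mafs(cfg, rng)
    g = gene_drop(ped, mafs, rng)
    positions = (np.arange(cfg.n_variants) + 1) * 1000
    return GenotypeRegion(g, chrom, positions, ped.ids)


def causal_effects(cfg: SimConfig, region: GenotypeRegion,
                   marker_idx: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Effect sizes over ``marker_idx`` scaled to the configured variance."""
    spec = cfg.causal
    mafs = np.maximum(region.mafs[marker_idx], 1e-4)
    beta = np.abs(np.log10(mafs)) if spec.maf_weighted else np.ones(len(mafs))
    if spec.mixed_sign:
        beta = beta * np.where(np.arange(len(beta)) % 2 == 0, 1.0, -1.0)
    var_g = region.genotypes[:, marker_idx].var(axis=0)
    total = float((beta ** 2 * var_g).sum())
    if total > 0:
        beta *= np.sqrt(spec.variance / total)
    return beta


def simulate_phenotype(R: RelationshipMatrix | np.ndarray, cfg: SimConfig,
                       region: GenotypeRegion | None = None,
                       causal_idx: np.ndarray | None = None,
                       seed=None,
                       chol: np.ndarray | None = None) -> np.ndarray:
    """Trait vector y = causal + u + e for one replicate.

    u is multivariate normal with covariance h2*sigma2*R drawn through a
    (cached, pass ``chol``) symmetric factor of R; e is iid normal with
    variance (1-h2)*sigma2. The causal term is added only when both a
    genotype region and causal marker indices are supplied.
    """
    rng = np.random.default_rng(seed)
    A = R.values if isinstance(R, RelationshipMatrix) else np.asarray(R, float)
    n = A.shape[0]
    if chol is None:
        chol = relationship_factor(A)
    u = np.sqrt(cfg.h2 * cfg.sigma2) * (chol @ rng.standard_normal(n))
    e = np.sqrt((1 - cfg.h2) * cfg.sigma2) * rng.standard_normal(n)
    y = u + e
    if region is not None and causal_idx is not None and cfg.causal is not None:
        beta = causal_effects(cfg, region, causal_idx, rng)
        y = y + region.genotypes[:, causal_idx] @ beta
    return y


def relationship_factor(R: np.ndarray) -> np.ndarray:
    """Symmetric square root of R via eigendecomposition (PSD-clipped)."""
    w, u = np.linalg.eigh(R)
    return u * np.sqrt(np.clip(w, 0.0, None))
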
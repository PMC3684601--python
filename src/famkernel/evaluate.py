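"""Calibration and power evaluation of the region tests.

Replicated null/causal simulations are scored over sliding marker windows
under the three trait presentations (original centered, environmental
residuals, GRAMMAR+) and the configured weight schemes; type I error,
empirical significance thresholds and empirical power are computed from the
pooled null P values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernel_test import W2, kernel_test
from .kinship import RelationshipMatrix, condition_psd, kinship_pcs, \
    pedigree_relationship
from .polygenic import PolygenicModel
from .simulate import SimConfig, child_seeds, genotype_regions, \
    relationship_factor, simulate_pedigree, simulate_phenotype
from .transform import grammar_plus

logger = logging.getLogger(__name__)

TRANSFORMS = ("original", "env_residual", "grammar_plus")


@dataclass(frozen=True)
class RegionSet:
    """Half-open marker-index windows (chrom, start, end) over a variant list."""

    windows: tuple[tuple[str, int, int], ...]
    window: int
    shift: int

    def __len__(self) -> int:
        return len(self.windows)


def sliding_windows(chroms, window: int = 20, shift: int = 10,
                    min_markers: int = 2) -> RegionSet:
    """Index windows [k*shift, k*shift + window) per chromosome.

    ``chroms`` is the per-variant chromosome label array (sorted); a final
    partial window is kept iff it holds at least ``min_markers`` markers and
    is not fully contained in the previous window.
    """
    chroms = np.asarray(chroms)
    wins: list[tuple[str, int, int]] = []
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        n = len(idx)
        if n == 0:
            continue
        start = 0
        while start < n:
            end = min(start + window, n)
            if end - start >= min_markers and (start == 0 or end > wins[-1][2]
                                               or wins[-1][0] != c):
                wins.append((str(c), start, end))
            if end == n:
                break
            start += shift
    return RegionSet(tuple(wins), window, shift)


@dataclass
class CalibrationReport:
    """Pooled region-level P values plus study metadata.

    ``pvalues`` columns: replicate, chrom, start, end, transform, scheme,
    p, causal (bool). Helper methods compute the summary quantities.
    """

    pvalues: pd.DataFrame
    n_replicates: int
    n_failed: int = 0
    config: SimConfig | None = None

    def null_p(self, transform: str, scheme: str) -> np.ndarray:
        t = self.pvalues
        sel = (~t["causal"]) & (t["transform"] == transform) & (t["scheme"] == scheme)
        return t.loc[sel, "p"].to_numpy()

    def causal_p(self, transform: str, scheme: str) -> np.ndarray:
        t = self.pvalues
        sel = t["causal"] & (t["transform"] == transform) & (t["scheme"] == scheme)
        return t.loc[sel, "p"].to_numpy()

    def type1_table(self, alphas=(0.01, 0.05, 0.1)) -> pd.DataFrame:
        rows = []
        for (tr, sc), grp in self.pvalues[~self.pvalues["causal"]].groupby(
                ["transform", "scheme"], sort=False):
            for a, rate, se, n in type1_error(grp["p"].to_numpy(), alphas
                                              ).itertuples(index=False):
                rows.append((tr, sc, a, rate, se, n))
        return pd.DataFrame(rows, columns=["transform", "scheme", "alpha",
                                           "type1", "se", "n_tests"])

    def power_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Nominal and empirical power per (transform, scheme)."""
        rows = []
        for (tr, sc), grp in self.pvalues[self.pvalues["causal"]].groupby(
                ["transform", "scheme"], sort=False):
            cp = grp["p"].to_numpy()
            thr = empirical_threshold(self.null_p(tr, sc), alpha)
            emp, emp_se = empirical_power(cp, thr)
            nom, nom_se = empirical_power(cp, alpha)
            rows.append((tr, sc, thr, emp, emp_se, nom, nom_se, len(cp)))
        return pd.DataFrame(rows, columns=[
            "transform", "scheme", "threshold", "empirical_power",
            "empirical_se", "nominal_power", "nominal_se", "n_tests"])


def type1_error(null_p: np.ndarray, alphas=(0.01, 0.05, 0.1)) -> pd.DataFrame:
    """Proportion of null P values at or below each nominal alpha, with
    binomial standard errors."""
    null_p = np.asarray(null_p, dtype=float)
    n = len(null_p)
    if n == 0:
        raise ValueError("no null P values supplied")
    rows = []
    for a in alphas:
        rate = float(np.mean(null_p <= a))
        rows.append((a, rate, float(np.sqrt(rate * (1 - rate) / n)), n))
    return pd.DataFrame(rows, columns=["alpha", "type1", "se", "n_tests"])


def empirical_threshold(null_p: np.ndarray, alpha: float = 0.05) -> float:
    """alpha-quantile of the pooled null P values (lower order statistic).

    With n null realizations, returns the floor(alpha * n)-th order
    statistic, so rejecting at P <= threshold realizes a type I error of
    alpha on the null sample itself.
    """
    null_p = np.sort(np.asarray(null_p, dtype=float))
    n = len(null_p)
    k = int(np.floor(alpha * n))
    if k < 1:
        raise ValueError(f"need at least 1/alpha = {1 / alpha:.0f} null "
                         f"realizations (got {n})")
    return float(null_p[k - 1])


def empirical_power(causal_p: np.ndarray, threshold: float) -> tuple[float, float]:
    """Proportion of causal-region P values at or below the threshold."""
    causal_p = np.asarray(causal_p, dtype=float)
    n = len(causal_p)
    power = float(np.mean(causal_p <= threshold)) if n else float("nan")
    se = float(np.sqrt(power * (1 - power) / n)) if n else float("nan")
    return power, se


def _transformed_traits(fit: PolygenicModel, transforms) -> dict:
    out = {}
    for name in transforms:
        if name == "original":
            out[name] = fit.center_phenotype()
        elif name == "env_residual":
            out[name] = fit.environmental_residuals()
        elif name == "grammar_plus":
            out[name] = grammar_plus(fit)
        else:
            raise ValueError(f"unknown transform {name!r}")
    return out


def run_study(cfg: SimConfig,
              schemes=(W2,),
              transforms=TRANSFORMS,
              window: int = 20, shift: int = 10,
              n_pcs: int = 0,
              n_resamples: int = 0,
              seed: int | None = None) -> CalibrationReport:
    """Replicated simulation study on one fixed pedigree.

    Per replicate: gene-drop genotypes, draw the phenotype, fit the
    polygenic model (kinship PCs as extra covariates when ``n_pcs`` > 0),
    produce the requested trait presentations, and run every weight scheme
    over every sliding window. Windows overlapping the configured causal
    markers are flagged causal; all others pool into the null distribution.
    Deterministic given ``seed`` (falls back to ``cfg.seed``); a failing
    replicate is logged and skipped.
    """
    seed = cfg.seed if seed is None else seed
    ped = simulate_pedigree(cfg.n_families, cfg.generations,
                            cfg.offspring_per_couple)
    R = condition_psd(pedigree_relationship(ped))
    chol = relationship_factor(R.values)
    X = np.ones((len(ped), 1))
    if n_pcs:
        X = np.column_stack([X, kinship_pcs(R, n_pcs)])

    causal_idx = None
    if cfg.causal is not None:
        lo = cfg.causal.region * window
        causal_idx = lo + np.arange(min(cfg.causal.n_causal, window))

    records = []
    n_failed = 0
    seeds = child_seeds(seed, cfg.n_replicates)
    for rep, ss in enumerate(seeds):
        try:
            gseed, pseed = ss.spawn(2)
            region_all = genotype_regions(ped, cfg, gseed)
            y = simulate_phenotype(R, cfg, region_all, causal_idx, pseed,
                                   chol=chol)
            fit = PolygenicModel().fit(X, y, relationship=R)
            traits = _transformed_traits(fit, transforms)
            regions = sliding_windows([region_all.chrom] * cfg.n_variants,
                                      window, shift)
            for chrom, lo, hi in regions.windows:
                sub = region_all.subset(np.arange(lo, hi))
                is_causal = (causal_idx is not None
                             and bool(np.any((causal_idx >= lo)
                                             & (causal_idx < hi))))
                for scheme in schemes:
                    for name, trait in traits.items():
                        try:
                            res = kernel_test(
                                trait, sub, scheme, covariates=X,
                                n_resamples=n_resamples,
                                seed=ss.spawn(1)[0].generate_state(1)[0]
                                if n_resamples else None,
                                start_index=lo, end_index=hi)
                        except ValueError as err:
                            logger.info("replicate %d window %d-%d skipped: %s",
                                        rep, lo, hi, err)
                            continue
                        records.append((rep, chrom, lo, hi, name,
                                        res.scheme, res.p_mixture,
                                        res.p_resampling, is_causal))
        except Exception:
            n_failed += 1
            logger.exception("replicate %d failed; skipping", rep)
    t = pd.DataFrame(records, columns=["replicate", "chrom", "start", "end",
                                       "transform", "scheme", "p",
                                       "p_resampling", "causal"])
    if n_failed:
        logger.warning("%d/%d replicates failed", n_failed, cfg.n_replicates)
    return CalibrationReport(pvalues=t, n_replicates=cfg.n_replicates,
                             n_failed=n_failed, config=cfg)
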
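"""Readers and writers for the standard file formats.

Genotypes come from VCF (GT field only) and are coded by minor-allele count
as 0, 0.5 and 1; phenotypes and pedigrees are plain TSV; relationship
matrices use the GCTA text GRM dialect (``<prefix>.grm.txt`` lower triangle
plus a ``<prefix>.grm.id`` sidecar).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: chromosome labels never analyzed (autosomal markers only)
NON_AUTOSOMAL = {"X", "Y", "MT", "M", "XY"}

MISSING_PARENT = "0"


def _is_autosomal(chrom: str) -> bool:
    return chrom.removeprefix("chr").upper() not in NON_AUTOSOMAL


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SampleFrame:
    """Phenotype and covariates for an ordered set of individuals.

    ``covariates`` always carries an intercept column (named ``intercept``),
    so the fixed-effect design is X = covariates.
    """

    ids: np.ndarray
    phenotype: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids must be unique")
        n = len(self.ids)
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match ids")
        if self.covariates.shape[0] != n:
            raise ValueError("covariate rows do not match ids")
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValueError("covariate_names does not match covariate columns")
        is_const = [np.allclose(c, c[0]) and c[0] != 0 for c in self.covariates.T]
        if sum(is_const) != 1:
            raise ValueError("exactly one intercept (constant) column required")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class PedigreeTable:
    """FAM-like pedigree: family, individual, father, mother, sex.

    Parents are either present in the table or coded '0' (missing); the
    graph is validated acyclic and sexes of named fathers/mothers checked.
    """

    table: pd.DataFrame  # columns fid, iid, father, mother, sex

    def __post_init__(self) -> None:
        t = self.table
        required = ["fid", "iid", "father", "mother", "sex"]
        if list(t.columns[:5]) != required:
            t = t.copy()
            t.columns = required + list(t.columns[5:])
            self.table = t
        for c in ("fid", "iid", "father", "mother"):
            self.table[c] = self.table[c].astype(str)
        if t["iid"].duplicated().any():
            dup = t.loc[t["iid"].duplicated(), "iid"].iloc[0]
            raise ValueError(f"duplicated individual id: {dup}")
        known = set(t["iid"])
        for col, sexcode in (("father", 1), ("mother", 2)):
            named = t[col][t[col] != MISSING_PARENT]
            missing = set(named) - known
            if missing:
                raise ValueError(f"{col} ids not in pedigree: {sorted(missing)}")
            sex = t.set_index("iid")["sex"]
            bad = [p for p in set(named) if int(sex[p]) not in (0, sexcode)]
            if bad:
                raise ValueError(f"inconsistent sex for {col}(s): {sorted(bad)}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = self.parent_map()
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(i: str, stack: list[str]) -> None:
            if state.get(i) == 1:
                return
            if state.get(i) == 0:
                raise ValueError(f"pedigree cycle involving individual {i}")
            state[i] = 0
            for p in parents.get(i, ()):
                if p != MISSING_PARENT:
                    visit(p, stack + [i])
            state[i] = 1

        for i in self.table["iid"]:
            visit(i, [])

    def parent_map(self) -> dict[str, tuple[str, str]]:
        t = self.table
        return dict(zip(t["iid"], zip(t["father"], t["mother"])))

    @property
    def ids(self) -> np.ndarray:
        return self.table["iid"].to_numpy(dtype=object)

    @property
    def founders(self) -> np.ndarray:
        t = self.table
        return ((t["father"] == MISSING_PARENT)
                & (t["mother"] == MISSING_PARENT)).to_numpy()

    def topological_order(self) -> list[str]:
        """Individual ids ordered so every parent precedes its offspring."""
        parents = self.parent_map()
        order: list[str] = []
        seen: set[str] = set()

        def visit(i: str) -> None:
            if i in seen or i == MISSING_PARENT:
                return
            seen.add(i)
            for p in parents.get(i, ()):
                visit(p)
            order.append(i)

        for i in self.table["iid"]:
            visit(i)
        return order

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeRegion:
    """N x M genotype matrix for one chromosome stretch, coded {0, 0.5, 1}.

    Missing calls are NaN until :meth:`impute_missing`; ``mafs`` is the
    sample minor-allele frequency of each variant, in [0, 0.5].
    """

    genotypes: np.ndarray
    chrom: str
    positions: np.ndarray
    ids: np.ndarray
    mafs: np.ndarray = field(default=None)  # type: ignore[assignment]
    variant_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] < 1:
            raise ValueError("genotypes must be N x M with M >= 1")
        obs = self.genotypes[~np.isnan(self.genotypes)]
        if not np.all(np.isin(obs, (0.0, 0.5, 1.0))):
            raise ValueError("genotype entries must be in {0, 0.5, 1, NaN}")
        self.positions = np.asarray(self.positions, dtype=int)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.mafs is None:
            self.mafs = compute_mafs(self.genotypes)
        self.mafs = np.asarray(self.mafs, dtype=float)
        if np.any((self.mafs < 0) | (self.mafs > 0.5)):
            raise ValueError("MAF must lie in [0, 0.5]")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def monomorphic(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.array([np.nanmax(c) == np.nanmin(c) if np.any(~np.isnan(c))
                             else True for c in self.genotypes.T])

    def impute_missing(self) -> "GenotypeRegion":
        """Mean-impute missing calls per variant (logged)."""
        g = self.genotypes
        n_missing = int(np.isnan(g).sum())
        if n_missing == 0:
            return self
        g = g.copy()
        col_mean = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(g))
        g[idx] = col_mean[idx[1]]
        logger.info("imputed %d missing genotypes to variant means (%s:%d-%d)",
                    n_missing, self.chrom, self.positions[0], self.positions[-1])
        out = GenotypeRegion.__new__(GenotypeRegion)
        out.genotypes, out.chrom, out.positions = g, self.chrom, self.positions
        out.ids, out.mafs, out.variant_ids = self.ids, self.mafs, self.variant_ids
        return out

    def subset(self, marker_idx: np.ndarray) -> "GenotypeRegion":
        return GenotypeRegion(
            self.genotypes[:, marker_idx], self.chrom, self.positions[marker_idx],
            self.ids, self.mafs[marker_idx],
            None if self.variant_ids is None else self.variant_ids[marker_idx])


def compute_mafs(genotypes: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per column of a {0, 0.5, 1}-coded matrix."""
    freq = np.nanmean(genotypes, axis=0)
    freq = np.where(np.isnan(freq), 0.0, freq)
    return np.minimum(freq, 1.0 - freq)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path,
             sample_order: Sequence[str] | None = None) -> Iterator[GenotypeRegion]:
    """Stream biallelic autosomal SNPs from a VCF, one region per chromosome.

    Genotypes are re-coded to minor-allele counts {0 -> 0, 1 -> 0.5, 2 -> 1}
    where the minor allele is determined per variant from the sample allele
    frequency (ties at 0.5 broken toward ALT). Missing GT stays NaN.
    Multiallelic and non-autosomal records are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_order is not None:
        unknown = [s for s in sample_order if s not in samples]
        if unknown:
            raise ValueError(f"sample ids not in VCF: {unknown}")
        order = np.array([samples.index(s) for s in sample_order])
        ids = np.asarray(list(sample_order), dtype=object)
    else:
        order = np.arange(len(samples))
        ids = np.asarray(samples, dtype=object)

    current: str | None = None
    cols: list[np.ndarray] = []
    pos: list[int] = []
    vids: list[str] = []

    def flush() -> GenotypeRegion | None:
        if not cols:
            return None
        g = np.column_stack(cols)
        return GenotypeRegion(g, current, np.array(pos), ids,
                              variant_ids=np.array(vids, dtype=object))

    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or not rec.is_snp:
            logger.warning("skipping non-biallelic-SNP record %s:%s (record %d)",
                           rec.CHROM, rec.POS, i + 1)
            continue
        if not _is_autosomal(rec.CHROM):
            logger.warning("skipping non-autosomal record %s:%s", rec.CHROM, rec.POS)
            continue
        gt = rec.gt_types  # 0=hom ref, 1=het, 2=missing(UNKNOWN), 3=hom alt
        if gt is None:
            raise ValueError(f"malformed record at line for {rec.CHROM}:{rec.POS}")
        alt_count = np.where(gt == 0, 0.0,
                             np.where(gt == 1, 1.0,
                                      np.where(gt == 3, 2.0, np.nan)))[order]
        obs = alt_count[~np.isnan(alt_count)]
        alt_freq = obs.mean() / 2.0 if obs.size else 0.0
        minor_count = alt_count if alt_freq <= 0.5 else 2.0 - alt_count
        coded = minor_count / 2.0
        if rec.CHROM != current:
            region = flush()
            if region is not None:
                yield region
            current, cols, pos, vids = rec.CHROM, [], [], []
        cols.append(coded)
        pos.append(rec.POS)
        vids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    region = flush()
    if region is not None:
        yield region


def write_vcf(path: str | Path, region: GenotypeRegion | Sequence[GenotypeRegion]) -> None:
    """Write {0, 0.5, 1}-coded genotypes as a minimal VCF 4.2 text file.

    The coded minor allele is written as ALT, so reading the file back
    reproduces the matrix.
    """
    regions = [region] if isinstance(region, GenotypeRegion) else list(region)
    ids = regions[0].ids
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for r in regions:
        lines.append(f"##contig=<ID={r.chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in ids))
    gt_map = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}
    for r in regions:
        for m in range(r.n_markers):
            vid = (r.variant_ids[m] if r.variant_ids is not None
                   else f"{r.chrom}:{r.positions[m]}")
            calls = ["./." if np.isnan(g) else gt_map[g] for g in r.genotypes[:, m]]
            lines.append(f"{r.chrom}\t{r.positions[m]}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t"
                         + "\t".join(calls))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pedigree / phenotype TSV
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read a whitespace/tab-delimited FAM-like file: FID IID PAT MAT SEX."""
    t = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if t.shape[1] < 5:
        raise ValueError("pedigree file needs 5 columns: FID IID PAT MAT SEX")
    t = t.iloc[:, :5]
    t.columns = ["fid", "iid", "father", "mother", "sex"]
    t["sex"] = t["sex"].astype(int)
    return PedigreeTable(t)


def write_pedigree(path: str | Path, ped: PedigreeTable) -> None:
    ped.table.to_csv(path, sep="\t", header=False, index=False)


def read_phenotypes(path: str | Path, trait: str,
                    covariate_names: Sequence[str] = ()) -> SampleFrame:
    """Read a phenotype TSV (header row, id column first) into a SampleFrame.

    Rows with a missing trait or covariate value are dropped (logged); an
    intercept column is prepended to the covariates.
    """
    t = pd.read_csv(path, sep="\t")
    if trait not in t.columns:
        raise ValueError(f"trait column {trait!r} not found; "
                         f"available: {list(t.columns)}")
    missing_cov = [c for c in covariate_names if c not in t.columns]
    if missing_cov:
        raise ValueError(f"covariate column(s) {missing_cov} not found; "
                         f"available: {list(t.columns)}")
    id_col = t.columns[0]
    used = [trait, *covariate_names]
    keep = t[used].notna().all(axis=1)
    if (~keep).any():
        logger.info("dropped %d rows with missing trait/covariate values",
                    int((~keep).sum()))
    t = t[keep]
    x = np.column_stack([np.ones(len(t))]
                        + [t[c].to_numpy(dtype=float) for c in covariate_names])
    return SampleFrame(ids=t[id_col].to_numpy(dtype=object),
                       phenotype=t[trait].to_numpy(dtype=float),
                       covariates=x,
                       covariate_names=["intercept", *covariate_names])


def write_phenotypes(path: str | Path, ids: Sequence[str],
                     **columns: np.ndarray) -> None:
    """Write named trait vectors as a phenotype TSV (id column first)."""
    out = pd.DataFrame({"id": list(ids), **columns})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GRM text format
# ---------------------------------------------------------------------------

def write_grm(R: np.ndarray, ids: Sequence[str], prefix: str | Path) -> None:
    """Write a symmetric relationship matrix in the GCTA text dialect.

    ``<prefix>.grm.txt`` holds ``i j n_snps value`` (1-based, lower
    triangle); ``<prefix>.grm.id`` holds ``fid iid`` per individual.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("R must be symmetric")
    if len(ids) != R.shape[0]:
        raise ValueError("id count does not match matrix dimension")
    prefix = Path(prefix)
    with open(f"{prefix}.grm.txt", "w") as fh:
        for i in range(R.shape[0]):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t0\t{R[i, j]:.12g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in ids:
            fh.write(f"{s}\t{s}\n")


def read_grm(prefix: str | Path):
    """Read a GCTA-style text GRM written by :func:`write_grm`.

    Returns a :class:`famkernel.kinship.RelationshipMatrix`.
    """
    from .kinship import RelationshipMatrix

    prefix = Path(prefix)
    ids = [line.split()[1] for line in
           Path(f"{prefix}.grm.id").read_text().strip().splitlines()]
    n = len(ids)
    R = np.zeros((n, n))
    for line in Path(f"{prefix}.grm.txt").read_text().strip().splitlines():
        i, j, _, v = line.split()
        R[int(i) - 1, int(j) - 1] = R[int(j) - 1, int(i) - 1] = float(v)
    return RelationshipMatrix(values=R, ids=np.asarray(ids, dtype=object),
                              source="file")
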
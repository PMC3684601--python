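import numpy as np
import pandas as pd
import pytest

import famkernel as fk


def make_pedigree(rows):
    """rows: (fid, iid, father, mother, sex) tuples."""
    t = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    return fk.PedigreeTable(t)


@pytest.fixture
def trio():
    return make_pedigree([("1", "dad", "0", "0", 1),
                          ("1", "mom", "0", "0", 2),
                          ("1", "kid", "dad", "mom", 1)])


@pytest.fixture(scope="session")
def family_pedigree():
    """50 three-generation families of 10 (the default study pedigree)."""
    return fk.simulate_pedigree(50, 3, 2)


@pytest.fixture(scope="session")
def family_R(family_pedigree):
    return fk.condition_psd(fk.pedigree_relationship(family_pedigree))


@pytest.fixture
def two_block_R():
    """N = 4, two unrelated full-sib pairs (the worked toy example)."""
    R = np.array([[1.0, 0.5, 0.0, 0.0],
                  [0.5, 1.0, 0.0, 0.0],
                  [0.0, 0.0, 1.0, 0.5],
                  [0.0, 0.0, 0.5, 1.0]])
    return R


def label_gene_drop(ped, n_rep, rng):
    """IBD-label gene dropping: Monte Carlo oracle for 2*Phi.

    Each founder receives two unique allele labels; transmission is
    Mendelian. Returns the MC estimate of the relationship matrix
    R_ij = 2 * P(random allele of i IBD to random allele of j)
    (diagonal: 1 + P(the two alleles of i are IBD)).
    """
    order = ped.topological_order()
    parents = ped.parent_map()
    ids = list(ped.ids)
    idx = {s: k for k, s in enumerate(ids)}
    n = len(ids)
    est = np.zeros((n, n))
    next_label = 0
    hap = {}
    for _ in range(n_rep):
        hap.clear()
        for iid in order:
            fa, mo = parents[iid]
            al = []
            for p in (fa, mo):
                if p in hap:
                    al.append(hap[p][rng.integers(0, 2)])
                else:
                    nonlocal_label = next_label
                    next_label += 1
                    al.append(nonlocal_label)
            hap[iid] = al
        lab = np.array([hap[i] for i in ids])  # n x 2
        same = (lab[:, None, :, None] == lab[None, :, None, :]).mean(axis=(2, 3))
        est += 2 * same
    est /= n_rep
    # diagonal of `same` counts self-identity of each allele (0.5 base)
    return est


def random_region(rng, n, m, chrom="1"):
    g = rng.integers(0, 3, (n, m)) / 2.0
    return fk.GenotypeRegion(g, chrom, (np.arange(m) + 1) * 10,
                             np.array([f"s{i}" for i in range(n)], dtype=object))
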
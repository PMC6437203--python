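"""Independent oracle implementations used only by the tests.

These are deliberately written by different routes than the library code
(enumeration, textbook variance components, brute-force grid search) so that
agreement is evidence of correctness rather than shared bugs.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

from seabream.io import MISSING, GenotypeTable


def exhaustive_rarefaction(counts, g: int) -> float:
    """Mean number of distinct alleles over every size-g subsample, by
    explicit enumeration of the multiset of gene copies."""
    copies = []
    for allele, c in enumerate(np.asarray(counts, dtype=int)):
        copies.extend([allele] * int(c))
    vals = [len(set(sub)) for sub in itertools.combinations(copies, g)]
    return float(np.mean(vals))


def weir_cockerham_fst(table: GenotypeTable) -> float:
    """Multilocus Weir-Cockerham theta (ratio of summed variance components).

    Textbook 1984 formulation per locus and allele with observed
    heterozygote frequencies; missing genotypes excluded per locus.
    """
    num = 0.0
    den = 0.0
    pops = table.population_names()
    pop_arr = np.array(table.populations)
    r = len(pops)
    for l in range(table.n_loci):
        geno = table.genotypes[:, l, :]
        ok = (geno != MISSING).all(axis=1)
        alleles = np.unique(geno[ok])
        n_i = np.array([int((ok & (pop_arr == p)).sum()) for p in pops], dtype=float)
        if (n_i == 0).any():
            continue
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        for a in alleles:
            p_i = np.zeros(r)
            h_i = np.zeros(r)
            for k, p in enumerate(pops):
                sub = geno[ok & (pop_arr == p)]
                p_i[k] = (sub == a).sum() / (2 * n_i[k])
                h_i[k] = ((sub == a).sum(axis=1) == 1).mean()
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            va = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            vb = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            vc = hbar / 2
            num += va
            den += va + vb + vc
    return num / den


def grid_search_two_source(logf: np.ndarray, step: float = 0.001) -> float:
    """Brute-force ML mixing proportion of source 1 for a 2-source problem."""
    assert logf.shape[1] == 2
    grid = np.arange(0.0, 1.0 + step / 2, step)
    f = np.exp(logf - logf.max(axis=1, keepdims=True))
    scale = logf.max(axis=1)
    best_pi, best_ll = 0.0, -np.inf
    for pi in grid:
        ll = float(np.log(pi * f[:, 0] + (1 - pi) * f[:, 1] + 1e-300).sum() + scale.sum())
        if ll > best_ll:
            best_ll, best_pi = ll, float(pi)
    return best_pi


def hand_upgma_3taxa() -> tuple[np.ndarray, str]:
    """A 3-leaf instance agglomerated by hand: d(A,B)=2, d(A,C)=d(B,C)=6.

    A and B merge at height 1; the (A,B) cluster joins C at average distance
    6, height 3, so C's branch is 3 and the internal branch is 2.
    """
    d = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]])
    return d, "((A:1,B:1):2,C:3);"
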
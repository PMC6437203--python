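"""Diversity, differentiation and clustering statistics for multi-allelic data.

The centrepiece is the empirical-Bayes pairwise F_ST for weakly differentiated
(high gene flow) populations: a Dirichlet-multinomial hierarchy in which each
population's true allele-frequency vector at a locus is Dirichlet(theta * pbar)
around the pooled frequencies pbar, theta is estimated by maximizing the
marginal likelihood across loci and both populations, and F_ST = 1/(1+theta).
Around it sit the standard descriptive statistics: rarefaction richness,
unbiased expected heterozygosity, haplotype and nucleotide diversity, a
permutation G-test of differentiation, and UPGMA clustering of the pairwise
F_ST matrix.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .io import MISSING, GenotypeTable, HaplotypeAlignment

__all__ = [
    "AlleleFrequencyTable",
    "allele_counts",
    "rarefied_richness",
    "allelic_richness",
    "haplotype_richness",
    "expected_heterozygosity",
    "haplotype_diversity",
    "nucleotide_diversity",
    "permutation_differentiation_test",
    "DifferentiationTest",
    "eb_fst_pair",
    "eb_fst_matrix",
    "EBFstResult",
    "DistanceMatrix",
    "TreeNode",
    "UPGMATree",
    "upgma",
]


# ---------------------------------------------------------------------------
# Allele counts and frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per-population, per-locus allele counts and/or frequencies.

    ``frequencies[locus]`` and ``counts[locus]`` are DataFrames indexed by
    population with one column per allele code.  ``sample_sizes[locus]`` is
    the number of non-missing *gene copies* (2 x individuals for diploid
    data) per population.  Simulated truth tables carry frequencies only.
    """

    frequencies: dict[str, pd.DataFrame]
    counts: dict[str, pd.DataFrame] | None = None
    sample_sizes: dict[str, pd.Series] | None = None

    def __post_init__(self) -> None:
        for locus, f in self.frequencies.items():
            rows = f.to_numpy(dtype=float)
            sums = rows.sum(axis=1)
            live = sums > 0
            if not np.allclose(sums[live], 1.0, atol=1e-9):
                raise ValueError(f"locus {locus}: frequencies do not sum to 1")

    @property
    def loci(self) -> list[str]:
        return list(self.frequencies)

    @property
    def populations(self) -> list[str]:
        first = next(iter(self.frequencies.values()))
        return list(first.index)


def allele_counts(g: GenotypeTable) -> AlleleFrequencyTable:
    """Tabulate allele counts, frequencies and gene-copy sample sizes.

    Missing genotypes are excluded per locus; counts conserve twice the
    non-missing individual count.  A (population, locus) cell where every
    genotype is missing keeps zero counts and NaN-free zero frequencies.
    """
    pops = g.population_names()
    pop_of = np.array(g.populations)
    freqs: dict[str, pd.DataFrame] = {}
    counts: dict[str, pd.DataFrame] = {}
    sizes: dict[str, pd.Series] = {}
    for l, locus in enumerate(g.locus_names):
        copies = g.genotypes[:, l, :]  # (n, 2)
        alleles = np.unique(copies[copies != MISSING])
        if alleles.size == 0:
            alleles = np.array([], dtype=int)
        cmat = np.zeros((len(pops), len(alleles)), dtype=int)
        n_copies = np.zeros(len(pops), dtype=int)
        a_index = {a: j for j, a in enumerate(alleles)}
        for i, pop in enumerate(pops):
            sub = copies[pop_of == pop].ravel()
            sub = sub[sub != MISSING]
            n_copies[i] = sub.size
            for a, c in zip(*np.unique(sub, return_counts=True)):
                cmat[i, a_index[a]] = c
        counts[locus] = pd.DataFrame(cmat, index=pops, columns=alleles)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_copies[:, None] > 0, cmat / np.maximum(n_copies, 1)[:, None], 0.0)
        freqs[locus] = pd.DataFrame(f, index=pops, columns=alleles)
        sizes[locus] = pd.Series(n_copies, index=pops)
    return AlleleFrequencyTable(freqs, counts, sizes)


# ---------------------------------------------------------------------------
# Rarefaction richness
# ---------------------------------------------------------------------------

def rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` gene copies.

    For N total copies with N_a copies of allele a, each allele contributes
    1 - C(N - N_a, g) / C(N, g): the probability it appears at least once in
    a hypergeometric subsample of size g.  Exact integer binomials are used
    so the value matches exhaustive subsample enumeration to float precision.
    """
    counts = np.asarray(counts, dtype=int)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds {N} gene copies")
    denom = math.comb(N, g)
    return float(sum(1 - math.comb(N - int(na), g) / denom for na in counts))


def allelic_richness(freq_table: AlleleFrequencyTable, g: int) -> pd.DataFrame:
    """Rarefied allelic richness per locus (rows) and population (columns).

    ``g`` is the standardized number of gene copies; it must not exceed the
    smallest per-cell copy count among cells with data.  All-missing cells
    come back NaN.
    """
    if freq_table.counts is None:
        raise ValueError("allelic richness requires observed counts")
    loci = freq_table.loci
    pops = freq_table.populations
    out = pd.DataFrame(np.nan, index=loci, columns=pops)
    for locus in loci:
        cmat = freq_table.counts[locus]
        for pop in pops:
            c = cmat.loc[pop].to_numpy()
            if c.sum() == 0:
                continue
            out.loc[locus, pop] = rarefied_richness(c, g)
    return out


def haplotype_richness(counts: np.ndarray | pd.Series, g: int) -> float:
    """Rarefied haplotype richness; identical formula on haploid copies."""
    return rarefied_richness(np.asarray(counts), g)


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def expected_heterozygosity(freq_table: AlleleFrequencyTable) -> pd.DataFrame:
    """Unbiased expected heterozygosity per locus and population.

    H_e = N/(N-1) * (1 - sum p_a^2) with N the non-missing gene-copy count
    (= 2n for n diploids).  Cells with fewer than 2 individuals are NaN.
    """
    if freq_table.sample_sizes is None:
        raise ValueError("expected heterozygosity requires sample sizes")
    loci = freq_table.loci
    pops = freq_table.populations
    out = pd.DataFrame(np.nan, index=loci, columns=pops)
    for locus in loci:
        f = freq_table.frequencies[locus]
        N = freq_table.sample_sizes[locus]
        for pop in pops:
            ncop = int(N[pop])
            if ncop < 4:  # fewer than 2 diploid individuals
                continue
            p = f.loc[pop].to_numpy(dtype=float)
            out.loc[locus, pop] = ncop / (ncop - 1) * (1 - float(p @ p))
    return out


def haplotype_diversity(counts: np.ndarray | pd.Series) -> float:
    """h = n/(n-1) * (1 - sum p_i^2) over haplotype counts."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 sequences")
    p = c / n
    return float(n / (n - 1) * (1 - p @ p))


def nucleotide_diversity(aln: HaplotypeAlignment) -> float:
    """Average pairwise difference per site, complete deletion of gapped sites.

    pi = sum_{i<j} d_ij / (C(n,2) * L) where d_ij counts differing included
    sites and L is the number of included sites.
    """
    mat = np.array([list(s) for s in aln.sequences])
    keep = ~np.isin(mat, ["-", "N"]).any(axis=0)
    if not keep.any():
        raise ValueError("complete deletion removed every alignment site")
    mat = mat[:, keep]
    n, L = mat.shape
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    total = 0.0
    for s in range(L):
        _, cnt = np.unique(mat[:, s], return_counts=True)
        total += (n * n - (cnt.astype(float) ** 2).sum()) / 2.0
    return float(total / (n * (n - 1) / 2) / L)


# ---------------------------------------------------------------------------
# Permutation G-test of differentiation
# ---------------------------------------------------------------------------

@dataclass
class DifferentiationTest:
    per_locus_g: pd.Series
    per_locus_p: pd.Series
    combined_statistic: float
    combined_p: float
    n_perm: int


def _g_statistic(rows: np.ndarray, col_tot: np.ndarray, row_tot: np.ndarray) -> np.ndarray:
    """Log-likelihood-ratio G over one or many 2 x A tables.

    ``rows``: (..., A) counts for population A; population B is implied by
    fixed column totals.  Vectorized over leading axes.
    """
    N = row_tot.sum()
    other = col_tot - rows
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = row_tot[0] * col_tot / N
        e2 = row_tot[1] * col_tot / N
        t1 = np.where(rows > 0, rows * np.log(rows / e1), 0.0)
        t2 = np.where(other > 0, other * np.log(other / e2), 0.0)
    return 2.0 * (t1.sum(axis=-1) + t2.sum(axis=-1))


def permutation_differentiation_test(
    countsA: dict[str, np.ndarray],
    countsB: dict[str, np.ndarray],
    n_perm: int = 999,
    seed: int = 0,
) -> DifferentiationTest:
    """Permutation test of allele-frequency homogeneity between two samples.

    Per locus the statistic is the multinomial G over the 2 x A allele-count
    table; gene copies are permuted between the samples; the p-value is
    (1 + #{perm >= obs}) / (n_perm + 1) with ties counted as >= (conservative).
    Loci are combined by Fisher's method.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    loci = list(countsA)
    g_obs: dict[str, float] = {}
    p_vals: dict[str, float] = {}
    for locus in loci:
        ca = np.asarray(countsA[locus], dtype=int)
        cb = np.asarray(countsB[locus], dtype=int)
        if ca.sum() == 0 or cb.sum() == 0:
            raise ValueError(f"locus {locus}: a sample has zero gene copies")
        col_tot = ca + cb
        row_tot = np.array([ca.sum(), cb.sum()])
        obs = float(_g_statistic(ca.astype(float), col_tot.astype(float),
                                 row_tot.astype(float)))
        labels = np.repeat(np.arange(col_tot.size), col_tot)
        perm = np.tile(labels, (n_perm, 1))
        rng.permuted(perm, axis=1, out=perm)
        first = perm[:, : row_tot[0]]
        pc = np.stack(
            [(first == a).sum(axis=1) for a in range(col_tot.size)], axis=1
        ).astype(float)
        g_perm = _g_statistic(pc, col_tot.astype(float), row_tot.astype(float))
        p_vals[locus] = (1 + int((g_perm >= obs - 1e-12).sum())) / (n_perm + 1)
        g_obs[locus] = obs
    stat = -2.0 * sum(math.log(p) for p in p_vals.values())
    combined_p = float(chi2.sf(stat, 2 * len(loci)))
    return DifferentiationTest(
        pd.Series(g_obs), pd.Series(p_vals), stat, combined_p, n_perm
    )


def differentiation_test_from_table(
    g: GenotypeTable, popA: str, popB: str, n_perm: int = 999, seed: int = 0
) -> DifferentiationTest:
    """Convenience wrapper running the permutation test on two populations."""
    ft = allele_counts(g.subset([popA, popB]))
    ca = {l: ft.counts[l].loc[popA].to_numpy() for l in ft.loci}
    cb = {l: ft.counts[l].loc[popB].to_numpy() for l in ft.loci}
    return permutation_differentiation_test(ca, cb, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Empirical-Bayes pairwise F_ST
# ---------------------------------------------------------------------------

@dataclass
class EBFstResult:
    """Posterior-mean pairwise F_ST under the Dirichlet-multinomial hierarchy.

    ``theta`` is the hyper-scale (F_ST scale 1/(1+theta)); ``fst`` is the
    posterior-mean pairwise Wright F_ST; ``log_likelihood`` is the
    Dirichlet-multinomial marginal log-likelihood of the pair at theta.
    ``converged`` is False when theta had to be clamped at a bound (no
    detectable divergence, or divergence at the saturation limit).
    """

    fst: float
    theta: float
    log_likelihood: float
    converged: bool


_FST_EPS = 1e-6
_THETA_LO = 1e-4
_THETA_HI = 1e6


def _dm_loglik(theta: float, counts_list: list[np.ndarray],
               pbar_list: list[np.ndarray]) -> float:
    """Dirichlet-multinomial marginal log-likelihood summed over samples."""
    ll = 0.0
    for x, pbar in zip(counts_list, pbar_list):
        alpha = theta * pbar
        n = x.sum()
        ll += gammaln(theta) - gammaln(theta + n)
        ll += float((gammaln(alpha + x) - gammaln(alpha)).sum())
    return ll


def _moment_fst(
    count_rows: list[dict[str, np.ndarray]],
    hyper_mean: dict[str, np.ndarray],
) -> float:
    """Method-of-moments multilocus F over all pairs of count profiles.

    Uses E[sum_a (phat_ia - phat_ja)^2] = H_l [2F + (1/n_i + 1/n_j)(1 - F)]
    with H_l = 1 - sum_a kappa_a^2; pairwise differences cancel the hyper
    mean, so the estimate carries none of the shrinkage bias a plug-in mean
    would introduce.  May return a non-positive value when sampling noise
    exceeds the between-population signal.
    """
    num = 0.0
    den = 0.0
    for locus, kappa in hyper_mean.items():
        H = 1.0 - float(kappa @ kappa)
        profiles = []
        for row in count_rows:
            c = np.asarray(row[locus], dtype=float)
            n = c.sum()
            if n > 0:
                profiles.append((c / n, n))
        for i in range(len(profiles)):
            for j in range(i + 1, len(profiles)):
                pi, ni = profiles[i]
                pj, nj = profiles[j]
                D = float(((pi - pj) ** 2).sum())
                num += D - H * (1 / ni + 1 / nj)
                den += H * (2 - 1 / ni - 1 / nj)
    if den <= 0:
        raise ValueError("no informative locus for the moment estimator")
    return num / den


def _pooled_mean(count_rows: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for locus in count_rows[0]:
        pooled = sum(np.asarray(r[locus], dtype=float) for r in count_rows)
        if pooled.sum() == 0:
            continue
        out[locus] = pooled / pooled.sum()
    if not out:
        raise ValueError("no shared locus with data")
    return out


def _posterior_pair_fst(
    countsA: dict[str, np.ndarray],
    countsB: dict[str, np.ndarray],
    theta: float,
    hyper_mean: dict[str, np.ndarray],
) -> float:
    """Posterior-mean pairwise Wright F_ST at fixed hyperparameters.

    Each population's frequency vector has Dirichlet posterior
    theta*kappa + x; the two-population between variance uses posterior
    means and variances, E[(p_i - p_j)^2] = (mu_i - mu_j)^2 + V_i + V_j,
    normalized by 2 * (1 - sum kappa^2) summed over loci (the r/(r-1)
    small-number-of-populations correction is folded into the ratio, making
    the estimate directly comparable with the simulated island F_ST).
    """
    num = 0.0
    den = 0.0
    for locus, kappa in hyper_mean.items():
        xa = np.asarray(countsA[locus], dtype=float)
        xb = np.asarray(countsB[locus], dtype=float)
        na, nb = xa.sum(), xb.sum()
        if na == 0 or nb == 0:
            continue
        mu_a = (theta * kappa + xa) / (theta + na)
        mu_b = (theta * kappa + xb) / (theta + nb)
        va = mu_a * (1 - mu_a) / (theta + na + 1)
        vb = mu_b * (1 - mu_b) / (theta + nb + 1)
        num += float(((mu_a - mu_b) ** 2 + va + vb).sum())
        den += 2.0 * (1.0 - float(kappa @ kappa))
    if den <= 0:
        raise ValueError("no informative locus")
    return num / den


def eb_fst_pair(
    countsA: dict[str, np.ndarray],
    countsB: dict[str, np.ndarray],
    hyper_mean: dict[str, np.ndarray] | None = None,
    theta: float | None = None,
) -> EBFstResult:
    """Empirical-Bayes pairwise F_ST between two allele-count profiles.

    Hierarchy: true frequency vectors ~ Dirichlet(theta * kappa) per locus,
    observed counts multinomial given the truth.  The hyper-mean kappa
    defaults to the pooled frequencies of the pair and the scale theta to a
    method-of-moments fit of the pairwise frequency differences (which
    cancel kappa and therefore estimate the divergence without shrinkage
    bias); both can be supplied externally, as :func:`eb_fst_matrix` does
    when many populations share the hyperparameters.  The reported value is
    the posterior-mean pairwise Wright F_ST, clamped to [1e-6, 1-1e-6].
    """
    rows = [countsA, countsB]
    if hyper_mean is None:
        hyper_mean = _pooled_mean(rows)
    converged = True
    if theta is None:
        f_mm = _moment_fst(rows, hyper_mean)
        f_mm = min(max(f_mm, 0.0), 1.0)
        theta = 1.0 / f_mm - 1.0 if f_mm > 0 else math.inf
        if not _THETA_LO <= theta <= _THETA_HI:
            theta = min(max(theta, _THETA_LO), _THETA_HI)
            converged = False
    fst = _posterior_pair_fst(countsA, countsB, theta, hyper_mean)
    fst = min(max(fst, _FST_EPS), 1.0 - _FST_EPS)
    counts_list: list[np.ndarray] = []
    pbar_list: list[np.ndarray] = []
    for locus, kappa in hyper_mean.items():
        live = kappa > 0
        for row in rows:
            c = np.asarray(row[locus], dtype=float)
            if c.sum() > 0:
                counts_list.append(c[live])
                pbar_list.append(kappa[live] / kappa[live].sum())
    ll = _dm_loglik(theta, counts_list, pbar_list)
    return EBFstResult(fst, float(theta), ll, converged)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix (here: EB F_ST) with labels."""

    labels: list[str]
    values: np.ndarray
    thetas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.isnan(self.values).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def eb_fst_matrix(g: GenotypeTable, populations: list[str] | None = None) -> DistanceMatrix:
    """All-pairs EB F_ST matrix from a genotype table.

    The Dirichlet hyperparameters are fit once from *all* populations — the
    hyper-mean from the pooled counts, the scale theta from the moment fit
    over every pair — and each pair's posterior-mean F_ST is evaluated under
    those shared hyperparameters.  This is the empirical-Bayes borrowing
    that stabilizes pairwise values for weakly differentiated populations.
    """
    ft = allele_counts(g)
    pops = populations or ft.populations
    n = len(pops)
    counts = {
        p: {l: ft.counts[l].loc[p].to_numpy() for l in ft.loci} for p in pops
    }
    rows = [counts[p] for p in pops]
    hyper_mean = _pooled_mean(rows)
    f_mm = min(max(_moment_fst(rows, hyper_mean), 0.0), 1.0)
    theta = 1.0 / f_mm - 1.0 if f_mm > 0 else _THETA_HI
    theta = min(max(theta, _THETA_LO), _THETA_HI)
    mat = np.zeros((n, n))
    thetas = np.full((n, n), theta)
    np.fill_diagonal(thetas, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            r = eb_fst_pair(
                counts[pops[i]], counts[pops[j]], hyper_mean=hyper_mean,
                theta=theta,
            )
            mat[i, j] = mat[j, i] = r.fst
    return DistanceMatrix(list(pops), mat, thetas)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    height: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class UPGMATree:
    root: TreeNode

    def leaf_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            if node.is_leaf():
                depths[node.label] = acc  # type: ignore[index]
            for c in node.children:
                walk(c, acc + node.height - c.height)

        walk(self.root, 0.0)
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = list(self.leaf_depths().values())
        return max(d) - min(d) <= tol


def upgma(dm: DistanceMatrix) -> UPGMATree:
    """Average-linkage agglomeration of a distance matrix.

    Node heights are half the merge distance, so the tree is ultrametric by
    construction.  Ties in the minimum distance are broken toward the pair
    whose sorted member-label tuple is lexicographically smallest, making the
    topology deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 leaves")
    d = dm.values.astype(float).copy()
    active: dict[int, TreeNode] = {
        i: TreeNode(0.0, label=dm.labels[i]) for i in range(n)
    }
    members: dict[int, tuple[str, ...]] = {
        i: (dm.labels[i],) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), v in dist.items():
            if i not in active or j not in active:
                continue
            key = (v, tuple(sorted(members[i] + members[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        assert best is not None
        (v, _), i, j = best
        children = sorted(
            [active[i], active[j]], key=lambda c: min(c.leaves())
        )
        node = TreeNode(v / 2.0, children=children)
        si, sj = sizes[i], sizes[j]
        new_members = tuple(sorted(members[i] + members[j]))
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = (si * dik + sj * djk) / (si + sj)
        del active[i], active[j]
        active[next_id] = node
        members[next_id] = new_members
        sizes[next_id] = si + sj
        next_id += 1
    return UPGMATree(next(iter(active.values())))
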
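"""Conditional-maximum-likelihood genetic stock identification.

Given baseline allele counts for candidate source populations and a mixture
sample of genotypes, the mixture composition pi is estimated by maximizing

    L(pi) = prod_i sum_k pi_k f_k(x_i)

where f_k(x_i) is the Hardy-Weinberg probability of individual i's multilocus
genotype under source k's allele-frequency estimates (the conditional
formulation: baseline frequencies are held fixed at their estimates, with
baseline sampling error pushed into the standard errors).  EM alternates
posterior source probabilities (E-step) with pi_k = mean posterior (M-step);
the log-likelihood is checked to be non-decreasing at every iteration.

Standard errors decompose into a mixture-sampling component (inverse observed
information at the optimum) and a baseline-sampling component (parametric
resampling of baseline allele counts, re-running EM); percentile bootstrap
confidence intervals resample mixture individuals and baseline gene copies.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import MISSING, GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineSet",
    "MixtureEstimate",
    "em_estimate",
    "baseline_aware_se",
    "bootstrap_ci",
    "assign_individuals",
]


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

@dataclass
class BaselineSet:
    """Per-source, per-locus allele counts for the candidate populations.

    ``counts[locus]`` is a DataFrame (sources x allele codes) of gene-copy
    counts.  Genotype probabilities use pseudo-count smoothed frequencies
    p = (x + 1) / (N + A), A the number of alleles known at the locus, so a
    mixture fish carrying an allele unseen in a baseline keeps a positive
    likelihood (floor 1/(N + A)).
    """

    sources: list[str]
    counts: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        if len(self.sources) < 2:
            raise ValueError("at least 2 baseline sources required")
        for locus, df in self.counts.items():
            if list(df.index) != list(self.sources):
                raise ValueError(f"locus {locus}: sources do not match")
            if (df.to_numpy() < 0).any():
                raise ValueError(f"locus {locus}: negative counts")

    @property
    def loci(self) -> list[str]:
        return list(self.counts)

    @classmethod
    def from_genotypes(
        cls,
        baselines: GenotypeTable,
        grouping: dict[str, list[str]] | None = None,
    ) -> "BaselineSet":
        """Build baselines from a genotype table.

        ``grouping`` maps source label -> population labels pooled into it;
        by default every population is its own source.
        """
        from .popgen import allele_counts

        ft = allele_counts(baselines)
        if grouping is None:
            grouping = {p: [p] for p in ft.populations}
        sources = list(grouping)
        counts: dict[str, pd.DataFrame] = {}
        for locus in ft.loci:
            raw = ft.counts[locus]
            rows = []
            for src, pops in grouping.items():
                missing = [p for p in pops if p not in raw.index]
                if missing:
                    raise ValueError(f"unknown population(s) {missing}")
                rows.append(raw.loc[pops].sum(axis=0))
            counts[locus] = pd.DataFrame(rows, index=sources)
        return cls(sources, counts)

    def smoothed_frequencies(
        self, allele_universe: dict[str, np.ndarray] | None = None
    ) -> dict[str, pd.DataFrame]:
        """(x + 1)/(N + A) frequencies over a (possibly extended) allele set."""
        out: dict[str, pd.DataFrame] = {}
        for locus, df in self.counts.items():
            if allele_universe is not None:
                extra = [
                    a for a in allele_universe[locus] if a not in df.columns
                ]
                if extra:
                    df = df.reindex(
                        columns=list(df.columns) + list(extra), fill_value=0
                    )
            mat = df.to_numpy(dtype=float)
            A = mat.shape[1]
            N = mat.sum(axis=1, keepdims=True)
            out[locus] = pd.DataFrame(
                (mat + 1.0) / (N + A), index=df.index, columns=df.columns
            )
        return out

    def resample(self, rng: np.random.Generator) -> "BaselineSet":
        """Parametric resample of every source's allele counts.

        Counts at each (source, locus) are redrawn Multinomial(N, phat) with
        phat the observed raw frequencies; the baseline-sampling variance
        this induces is what the EB standard-error component measures.
        """
        new: dict[str, pd.DataFrame] = {}
        for locus, df in self.counts.items():
            mat = df.to_numpy(dtype=float)
            out = np.zeros_like(mat)
            for i in range(mat.shape[0]):
                N = int(mat[i].sum())
                if N == 0:
                    continue
                out[i] = rng.multinomial(N, mat[i] / mat[i].sum())
            new[locus] = pd.DataFrame(out, index=df.index, columns=df.columns)
        return BaselineSet(list(self.sources), new)


# ---------------------------------------------------------------------------
# Genotype log-likelihood matrix
# ---------------------------------------------------------------------------

def _mixture_allele_universe(
    mixture: GenotypeTable, baselines: BaselineSet
) -> dict[str, np.ndarray]:
    universe: dict[str, np.ndarray] = {}
    for l, locus in enumerate(mixture.locus_names):
        copies = mixture.genotypes[:, l, :]
        seen = np.unique(copies[copies != MISSING])
        base = baselines.counts[locus].columns.to_numpy(dtype=int)
        universe[locus] = np.union1d(base, seen)
    return universe


def genotype_log_likelihoods(
    mixture: GenotypeTable, baselines: BaselineSet
) -> np.ndarray:
    """(n_individuals x n_sources) log HWE genotype probabilities.

    Loci are treated as independent; missing genotypes contribute nothing
    (log-probability 0 at that locus).
    """
    shared = [l for l in mixture.locus_names if l in baselines.loci]
    if not shared:
        raise ValueError("mixture and baselines share no locus")
    universe = _mixture_allele_universe(mixture, baselines)
    freqs = baselines.smoothed_frequencies(universe)
    n, K = mixture.n_individuals, len(baselines.sources)
    logf = np.zeros((n, K))
    for locus in shared:
        l = mixture.locus_names.index(locus)
        fmat = freqs[locus]
        codes = fmat.columns.to_numpy(dtype=int)
        code_idx = {c: j for j, c in enumerate(codes)}
        p = fmat.to_numpy(dtype=float)  # (K, A)
        a = mixture.genotypes[:, l, 0]
        b = mixture.genotypes[:, l, 1]
        obs = a != MISSING
        ai = np.array([code_idx[c] for c in a[obs]], dtype=int)
        bi = np.array([code_idx[c] for c in b[obs]], dtype=int)
        het = (ai != bi).astype(float)
        # log P(genotype) = log(2^het * p_a * p_b) per source
        contrib = (
            np.log(p[:, ai]) + np.log(p[:, bi]) + het * np.log(2.0)
        )  # (K, n_obs)
        logf[obs] += contrib.T
    return logf


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

@dataclass
class MixtureEstimate:
    """Mixture composition with uncertainty decomposition."""

    proportions: pd.Series
    log_likelihood: float
    n_iterations: int
    converged: bool
    posteriors: pd.DataFrame
    n_mixture: int
    excluded_ids: list[str] = field(default_factory=list)
    se_total: pd.Series | None = None
    se_information: pd.Series | None = None
    se_baseline: pd.Series | None = None
    ci_lower: pd.Series | None = None
    ci_upper: pd.Series | None = None


def _em_core(
    logf: np.ndarray,
    pi0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int, bool, np.ndarray]:
    pi = pi0.copy()
    prev_ll = -np.inf
    post = np.full_like(logf, np.nan)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            w = logf + np.log(np.maximum(pi, 1e-300))
        norm = logsumexp(w, axis=1)
        ll = float(norm.sum())
        # EM guarantee: the observed-data log-likelihood never decreases
        if ll < prev_ll - 1e-8:
            raise AssertionError("EM log-likelihood decreased")
        post = np.exp(w - norm[:, None])
        new_pi = post.mean(axis=0)
        if np.abs(new_pi - pi).max() < tol:
            pi = new_pi
            converged = True
            break
        pi = new_pi
        prev_ll = ll
    with np.errstate(divide="ignore"):
        w = logf + np.log(np.maximum(pi, 1e-300))
    norm = logsumexp(w, axis=1)
    return pi, float(norm.sum()), it, converged, np.exp(w - norm[:, None])


def em_estimate(
    mixture: GenotypeTable,
    baselines: BaselineSet,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    n_starts: int = 10,
    seed: int = 0,
) -> MixtureEstimate:
    """Conditional-ML mixture proportions by multi-start EM.

    ``n_starts`` runs are performed (a uniform start plus Dirichlet-random
    starts seeded from ``seed``) and the best optimum kept.  Individuals with
    zero likelihood under every source (possible only when every locus is
    missing and smoothing cannot help) are excluded with a logged warning.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    K = len(baselines.sources)
    logf = genotype_log_likelihoods(mixture, baselines)
    bad = ~np.isfinite(logf).any(axis=1)
    excluded = [mixture.individual_ids[i] for i in np.flatnonzero(bad)]
    if excluded:
        logger.warning(
            "excluding %d mixture individual(s) with zero likelihood under "
            "every source: %s", len(excluded), excluded,
        )
        logf = logf[~bad]
    if logf.shape[0] == 0:
        raise ValueError("no usable mixture individuals")
    rng = np.random.default_rng(seed)
    starts = [np.full(K, 1.0 / K)]
    starts += [rng.dirichlet(np.ones(K)) for _ in range(max(n_starts - 1, 0))]
    best = None
    for pi0 in starts:
        pi, ll, it, conv, post = _em_core(logf, pi0, tol, max_iter)
        if best is None or ll > best[1]:
            best = (pi, ll, it, conv, post)
    pi, ll, it, conv, post = best
    if not conv:
        warnings.warn("EM did not converge within max_iter", stacklevel=2)
    kept_ids = [i for i, b in zip(mixture.individual_ids, bad) if not b]
    return MixtureEstimate(
        pd.Series(pi, index=baselines.sources, name="proportion"),
        ll,
        it,
        conv,
        pd.DataFrame(post, index=kept_ids, columns=baselines.sources),
        logf.shape[0],
        excluded,
    )


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------

def _information_se(logf: np.ndarray, pi: np.ndarray) -> np.ndarray | None:
    """SEs from the observed information of the mixture likelihood at pi.

    Free parameters are pi_1..pi_{K-1}; H_{kl} = -sum_i (a_ik - a_iK)
    (a_il - a_iK) with a_ik = f_ik / sum_j pi_j f_ij.  Returns None when the
    information matrix is singular.
    """
    K = pi.size
    with np.errstate(divide="ignore"):
        w = logf + np.log(np.maximum(pi, 1e-300))
    logs = logsumexp(w, axis=1)
    a = np.exp(logf - logs[:, None])  # f_ik / s_i
    d = a[:, : K - 1] - a[:, [K - 1]]
    info = d.T @ d
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
        return None
    var = np.empty(K)
    var[: K - 1] = np.diag(cov)
    var[K - 1] = float(np.ones(K - 1) @ cov @ np.ones(K - 1))
    return np.sqrt(var)


def baseline_aware_se(
    est: MixtureEstimate,
    mixture: GenotypeTable,
    baselines: BaselineSet,
    n_resample: int = 200,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> MixtureEstimate:
    """Total SEs combining mixture-sampling and baseline-sampling variance.

    The mixture component is the inverse observed information at the
    optimum; the baseline component is the empirical SD of re-estimates
    under parametric resampling of the baseline allele counts (EM restarted
    at the point estimate).  total^2 = information^2 + baseline^2.  Fills the
    SE fields of ``est`` in place and returns it.
    """
    logf = genotype_log_likelihoods(mixture, baselines)
    keep = np.isfinite(logf).any(axis=1)
    logf = logf[keep]
    pi = est.proportions.to_numpy()
    se_info = _information_se(logf, pi)
    if se_info is None:
        warnings.warn(
            "singular information matrix; reporting resampling-only SEs",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    draws = np.zeros((n_resample, pi.size))
    for b in range(n_resample):
        bset = baselines.resample(rng)
        lf = genotype_log_likelihoods(mixture, bset)[keep]
        draws[b], _, _, _, _ = _em_core(lf, pi, tol, max_iter)
    se_base = draws.std(axis=0, ddof=1)
    if se_info is None:
        total = se_base
        est.se_information = None
    else:
        total = np.sqrt(se_info**2 + se_base**2)
        est.se_information = pd.Series(se_info, index=est.proportions.index)
    est.se_baseline = pd.Series(se_base, index=est.proportions.index)
    est.se_total = pd.Series(total, index=est.proportions.index)
    return est


def bootstrap_ci(
    mixture: GenotypeTable,
    baselines: BaselineSet,
    n_boot: int = 1000,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 2000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for the mixture proportions.

    Each replicate resamples mixture individuals with replacement and
    baseline gene copies parametrically, then re-runs EM (uniform start).
    Returns a DataFrame with columns ``lower``/``upper`` per source.
    """
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    rng = np.random.default_rng(seed)
    logf_full = genotype_log_likelihoods(mixture, baselines)
    n = logf_full.shape[0]
    K = len(baselines.sources)
    draws = np.zeros((n_boot, K))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bset = baselines.resample(rng)
        lf = genotype_log_likelihoods(mixture, bset)[idx]
        draws[b], _, _, _, _ = _em_core(lf, np.full(K, 1.0 / K), tol, max_iter)
    lo = np.percentile(draws, 100 * alpha / 2, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    return pd.DataFrame({"lower": lo, "upper": hi}, index=baselines.sources)


def assign_individuals(est: MixtureEstimate) -> pd.DataFrame:
    """Per-individual posterior source probabilities at the ML composition."""
    return est.posteriors.copy()
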
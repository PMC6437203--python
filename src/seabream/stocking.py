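"""Stocking-effect analyses: mark surveys, recapture decay, gene replacement.

Four stages of the hatchery-impact assessment live here:

1. expansion of deformity-mark surveys into the proportion of hatchery fish
   in the landings (P_h), with binomial standard errors and landings-weighted
   pooling across market strata;
2. effort-corrected cumulative recapture rates of release cohorts and
   nonlinear exponential-decline fits across release years, with a z-test
   comparing decline rates between age horizons;
3. conversion of a per-year decline rate into a per-generation fitness
   reduction, 1 - exp(-lambda * G);
4. a deterministic single-locus recursion for the replacement of the wild
   gene under continued stocking: wild fish WW (fitness 1), hatchery fish HH
   (fitness f), hybrids WH with fitness (1+f)/2, random mating to
   Hardy-Weinberg offspring, and R stocked HH recruits added per wild-born
   recruit each generation.  The wild-gene growth factor near extinction is
   (1+f) / (2 f (1+R)); its position relative to 1 separates persistence
   (interior equilibrium) from complete replacement.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "HatcheryFractionEstimate",
    "estimate_hatchery_fraction",
    "pool_hatchery_fraction",
    "expand_catch",
    "ReleaseCohortSeries",
    "cumulative_recapture_rate",
    "DecayFit",
    "fit_exponential_decay",
    "RateComparison",
    "compare_decay_rates",
    "FitnessReduction",
    "fitness_reduction_per_generation",
    "ReplacementParams",
    "ReplacementTrajectory",
    "replacement_step",
    "replacement_trajectory",
    "generations_to_threshold",
    "equilibrium_surface",
    "wild_gene_growth_factor",
]

_N_AGES = 8


# ---------------------------------------------------------------------------
# Mark-survey expansion
# ---------------------------------------------------------------------------

@dataclass
class HatcheryFractionEstimate:
    """Proportion of hatchery fish in the landings from a mark survey."""

    p_h: float
    se: float
    n_checked: int
    n_marked: int
    mark_rate: float
    stratum: str = ""


def estimate_hatchery_fraction(
    n_checked: int, n_marked: int, q: float = 1.0, stratum: str = ""
) -> HatcheryFractionEstimate:
    """Expand a deformity-mark count into a hatchery fraction.

    ``q`` is the incidence of the mark among hatchery fish (1.0 when the mark
    is fully reliable); P_h = (n_marked/n_checked)/q, clamped to [0, 1], with
    SE = sqrt(phat (1-phat)/n)/q on the raw mark fraction phat.
    """
    if n_checked < 1:
        raise ValueError("n_checked must be >= 1")
    if not 0 < q <= 1:
        raise ValueError("mark incidence q must be in (0, 1]")
    if n_marked > n_checked:
        raise ValueError("n_marked cannot exceed n_checked")
    phat = n_marked / n_checked
    p_h = min(max(phat / q, 0.0), 1.0)
    se = math.sqrt(phat * (1 - phat) / n_checked) / q
    return HatcheryFractionEstimate(p_h, se, n_checked, n_marked, q, stratum)


def pool_hatchery_fraction(
    estimates: list[HatcheryFractionEstimate], landings: list[float]
) -> HatcheryFractionEstimate:
    """Landings-weighted average of per-stratum hatchery fractions."""
    if len(estimates) != len(landings):
        raise ValueError("one landings weight per stratum required")
    w = np.asarray(landings, dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("landings weights must be >= 0 with positive total")
    w = w / w.sum()
    p = float(sum(wi * e.p_h for wi, e in zip(w, estimates)))
    se = float(math.sqrt(sum((wi * e.se) ** 2 for wi, e in zip(w, estimates))))
    return HatcheryFractionEstimate(
        p, se,
        sum(e.n_checked for e in estimates),
        sum(e.n_marked for e in estimates),
        float(np.average([e.mark_rate for e in estimates], weights=w)),
        "pooled",
    )


def expand_catch(
    landings_total: float,
    p_h: float,
    weight_by_age: pd.Series,
    age_composition: pd.Series,
) -> pd.DataFrame:
    """Split total landed mass into hatchery/wild numbers-at-age.

    ``age_composition`` is the mass fraction per age (sums to 1);
    ``weight_by_age`` is the mean individual mass per age.  Numbers at age =
    landings x composition / weight, split by P_h; total mass is conserved.
    """
    if not np.allclose(age_composition.sum(), 1.0):
        raise ValueError("age composition must sum to 1")
    if (weight_by_age <= 0).any():
        raise ValueError("body weights must be positive")
    if not age_composition.index.equals(weight_by_age.index):
        raise ValueError("age vectors of composition and weights do not match")
    mass = landings_total * age_composition
    numbers = mass / weight_by_age
    return pd.DataFrame(
        {
            "mass_total": mass,
            "numbers_total": numbers,
            "numbers_hatchery": p_h * numbers,
            "numbers_wild": (1 - p_h) * numbers,
            "mass_hatchery": p_h * mass,
            "mass_wild": (1 - p_h) * mass,
        }
    )


# ---------------------------------------------------------------------------
# Release cohorts and recapture rates
# ---------------------------------------------------------------------------

@dataclass
class ReleaseCohortSeries:
    """Releases, recaptures-by-age and effort indices per release year.

    ``table`` columns: ``release_year``, ``n_released``, ``age1``..``age8``
    (age 8 a plus-group); ``effort`` is indexed by calendar year; fish of
    cohort y at age a are caught in calendar year y + a.
    """

    table: pd.DataFrame
    effort: pd.Series
    weight_by_age: pd.Series | None = None

    def __post_init__(self) -> None:
        need = {"release_year", "n_released"} | {f"age{a}" for a in range(1, _N_AGES + 1)}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        if (self.table[[f"age{a}" for a in range(1, _N_AGES + 1)]] < 0).any().any():
            raise ValueError("recapture counts must be >= 0")
        if (self.effort <= 0).any():
            raise ValueError("effort indices must be positive")

    @property
    def release_years(self) -> np.ndarray:
        return self.table["release_year"].to_numpy()


def cumulative_recapture_rate(
    cohorts: ReleaseCohortSeries,
    max_age: int,
    effort_reference_year: int | None = None,
    corrected: bool = True,
) -> pd.Series:
    """Cumulative recapture rate per cohort up to ``max_age``.

    With effort correction, each age class's recaptures are multiplied by
    E_ref / E(catch year) before summation, standardizing recovery to the
    reference year's fishing pressure; the uncorrected variant sums raw
    recaptures.  Rate = corrected recaptures / number released.
    """
    if not 1 <= max_age <= _N_AGES:
        raise ValueError(f"max_age must be in 1..{_N_AGES}")
    t = cohorts.table
    if effort_reference_year is None:
        effort_reference_year = int(cohorts.effort.index[0])
    if corrected and effort_reference_year not in cohorts.effort.index:
        raise ValueError(f"no effort for reference year {effort_reference_year}")
    e_ref = float(cohorts.effort[effort_reference_year]) if corrected else 1.0
    rates = np.zeros(len(t))
    for i, (_, row) in enumerate(t.iterrows()):
        total = 0.0
        for age in range(1, max_age + 1):
            rec = row[f"age{age}"]
            if corrected:
                year = int(row["release_year"]) + age
                if year not in cohorts.effort.index:
                    raise ValueError(f"no effort index for catch year {year}")
                e = float(cohorts.effort[year])
                if e <= 0:
                    raise ValueError(f"zero effort in year {year}")
                rec = rec * e_ref / e
            total += rec
        rates[i] = total / row["n_released"]
    return pd.Series(rates, index=t["release_year"].to_numpy(), name=f"rate_age{max_age}")


# ---------------------------------------------------------------------------
# Exponential decline fits
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    """Nonlinear fit of y = a * exp(-lambda * x) across release years."""

    amplitude: float
    rate: float
    se_amplitude: float
    se_rate: float
    t_statistic: float
    p_value: float
    rss: float
    n: int
    loglinear_rate: float
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-self.rate * np.asarray(x, dtype=float))


def fit_exponential_decay(
    x: np.ndarray, y: np.ndarray, weights: str = "relative"
) -> DecayFit:
    """Fit y = a * exp(-lambda x) by nonlinear least squares.

    Initialized from the log-linear OLS fit (which requires y > 0); standard
    errors come from the asymptotic covariance; the t statistic and two-sided
    p-value test lambda = 0 on n - 2 degrees of freedom.  ``weights`` is
    ``"relative"`` (default; residuals scaled by y, appropriate for rate
    data whose dispersion grows with the mean, as multiplicative survey
    noise does) or ``"absolute"`` (unweighted).  If the nonlinear stage
    fails, the log-linear estimates are reported with ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 (x, y) points")
    if (y <= 0).any():
        raise ValueError("y must be positive for the log-linear stage")
    if weights not in {"relative", "absolute"}:
        raise ValueError("weights must be 'relative' or 'absolute'")
    slope, intercept = np.polyfit(x, np.log(y), 1)
    a0, lam0 = math.exp(intercept), -slope

    def model(xx, a, lam):
        return a * np.exp(-lam * xx)

    try:
        popt, pcov = optimize.curve_fit(
            model, x, y, p0=[a0, lam0], maxfev=10000,
            sigma=y if weights == "relative" else None,
        )
        a, lam = popt
        se_a, se_lam = np.sqrt(np.diag(pcov))
        rss = float(((y - model(x, a, lam)) ** 2).sum())
        converged = np.isfinite(se_lam)
    except RuntimeError:
        a, lam = a0, lam0
        resid = np.log(y) - (intercept + slope * x)
        sigma2 = float(resid @ resid) / max(x.size - 2, 1)
        sxx = float(((x - x.mean()) ** 2).sum())
        se_lam = math.sqrt(sigma2 / sxx)
        se_a = a * math.sqrt(sigma2 * (1 / x.size + x.mean() ** 2 / sxx))
        rss = float(((y - model(x, a, lam)) ** 2).sum())
        converged = False
    df = x.size - 2
    tval = lam / se_lam if se_lam > 0 else math.inf
    pval = 2 * float(stats.t.sf(abs(tval), df)) if math.isfinite(tval) else 0.0
    return DecayFit(
        float(a), float(lam), float(se_a), float(se_lam), float(tval), pval,
        rss, x.size, lam0, converged,
    )


@dataclass
class RateComparison:
    z: float
    p_one_sided: float
    mean_simple: float
    se_mean_simple: float
    mean_pooled: float
    se_mean_pooled: float


def compare_decay_rates(
    rate_a: float, se_a: float, rate_b: float, se_b: float
) -> RateComparison:
    """z-test for equality of two decline rates plus combined summaries.

    z = |lambda_A - lambda_B| / sqrt(SE_A^2 + SE_B^2) with a one-sided normal
    p-value; both the simple average (SE by quadrature/2) and the
    inverse-variance-weighted pooled rate are reported.
    """
    se2 = se_a**2 + se_b**2
    if se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = abs(rate_a - rate_b) / math.sqrt(se2)
    p = float(stats.norm.sf(z))
    mean_simple = (rate_a + rate_b) / 2
    se_simple = math.sqrt(se2) / 2
    w = np.array([1 / se_a**2, 1 / se_b**2])
    mean_pooled = float((w @ [rate_a, rate_b]) / w.sum())
    se_pooled = math.sqrt(1 / w.sum())
    return RateComparison(z, p, mean_simple, se_simple, mean_pooled, se_pooled)


def compare_decay_fits(fit_a: DecayFit, fit_b: DecayFit) -> RateComparison:
    return compare_decay_rates(fit_a.rate, fit_a.se_rate, fit_b.rate, fit_b.se_rate)


# ---------------------------------------------------------------------------
# Fitness conversion
# ---------------------------------------------------------------------------

@dataclass
class FitnessReduction:
    """Per-generation fitness reduction 1 - exp(-lambda * G).

    ``se`` is the exact delta-method propagation G exp(-lambda G) SE_lambda;
    ``se_linear`` is the first-order propagation G SE_lambda (the SE of the
    cumulative exponent itself, which common field reports attach directly
    to the reduction since 1 - exp(-x) ~ x).  Both are exposed because they
    differ appreciably once lambda G is not small.
    """

    value: float
    se: float | None
    se_linear: float | None


def fitness_reduction_per_generation(
    rate: float, generation_time: float, se_rate: float | None = None
) -> FitnessReduction:
    """Convert a per-year survival decline rate into a per-generation loss."""
    if generation_time <= 0:
        raise ValueError("generation time must be positive")
    value = 1.0 - math.exp(-rate * generation_time)
    if se_rate is None:
        return FitnessReduction(value, None, None)
    se = generation_time * math.exp(-rate * generation_time) * se_rate
    se_linear = generation_time * se_rate
    return FitnessReduction(value, se, se_linear)


# ---------------------------------------------------------------------------
# Wild-gene replacement recursion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplacementParams:
    """Parameters of the single-locus replacement model.

    ``f``: relative fitness of the hatchery genotype HH (wild WW has fitness
    1, hybrids WH have (1+f)/2, i.e. additive effects).  ``R``: stocked HH
    recruits added per wild-born recruit each generation.  ``p0``: initial
    wild-gene proportion (1 = pristine population).
    """

    f: float
    R: float
    p0: float = 1.0

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("fitness f must be >= 0")
        if self.f > 1:
            import warnings

            warnings.warn(
                "f > 1 (hatchery fitness above wild) is outside the regime "
                "this model was built for",
                stacklevel=3,
            )
        if self.R < 0:
            raise ValueError("stocking rate R must be >= 0")
        if not 0 <= self.p0 <= 1:
            raise ValueError("p0 must be in [0, 1]")

    def initial_state(self) -> np.ndarray:
        p = self.p0
        return np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])


def wild_gene_growth_factor(params: ReplacementParams) -> float:
    """Per-generation growth factor of the wild gene near p -> 0.

    (1+f) / (2 f (1+R)); > 1 means the wild gene persists at an interior
    equilibrium, < 1 means complete replacement.  Infinite when f = 0
    (HH cannot reproduce, so the wild gene always persists through hybrids).
    """
    if params.f == 0:
        return math.inf
    return (1 + params.f) / (2 * params.f * (1 + params.R))


def replacement_step(state: np.ndarray, params: ReplacementParams) -> np.ndarray:
    """Advance genotype proportions (WW, WH, HH) by one generation.

    Reproduction weights (1, (1+f)/2, f) act on the adult genotype
    proportions; the weighted gamete pool sets the wild-allele frequency p*;
    wild-born offspring are at Hardy-Weinberg in p*; stocked HH recruits are
    then added at R per wild-born recruit:
    next = (HWE(p*) + R * [0,0,1]) / (1 + R).
    """
    state = np.asarray(state, dtype=float)
    if state.min() < -1e-12 or abs(state.sum() - 1) > 1e-9:
        raise ValueError("state must be genotype proportions summing to 1")
    w = np.array([1.0, (1.0 + params.f) / 2.0, params.f])
    weighted = state * w
    total = weighted.sum()
    if total <= 0:
        # no reproduction at all: the next generation is pure stocked HH
        return np.array([0.0, 0.0, 1.0])
    weighted /= total
    p_star = weighted[0] + weighted[1] / 2.0
    offspring = np.array(
        [p_star**2, 2 * p_star * (1 - p_star), (1 - p_star) ** 2]
    )
    nxt = (offspring + params.R * np.array([0.0, 0.0, 1.0])) / (1.0 + params.R)
    return nxt


def wild_gene_proportion(state: np.ndarray) -> float:
    return float(state[0] + state[1] / 2.0)


@dataclass
class ReplacementTrajectory:
    states: np.ndarray  # (T+1, 3) genotype proportions, row 0 = generation 0
    wild_gene: np.ndarray  # (T+1,)
    equilibrium: float | None
    converged: bool

    def generations(self) -> np.ndarray:
        return np.arange(self.states.shape[0])


def replacement_trajectory(
    params: ReplacementParams,
    n_generations: int | None = None,
    tol: float = 1e-12,
    max_generations: int = 10**6,
) -> ReplacementTrajectory:
    """Iterate the recursion for a fixed horizon or until convergence.

    With ``n_generations`` given, exactly that many steps are taken and the
    equilibrium field is left None unless the trajectory happened to settle.
    Otherwise iteration stops when the largest genotype-proportion change
    falls below ``tol`` (or at ``max_generations``, flagged non-converged).
    """
    state = params.initial_state()
    states = [state]
    converged = False
    horizon = n_generations if n_generations is not None else max_generations
    for _ in range(horizon):
        nxt = replacement_step(state, params)
        states.append(nxt)
        if np.abs(nxt - state).max() < tol:
            state = nxt
            converged = True
            if n_generations is None:
                break
        state = nxt
    arr = np.array(states)
    wg = arr[:, 0] + arr[:, 1] / 2.0
    eq = float(wg[-1]) if converged else None
    return ReplacementTrajectory(arr, wg, eq, converged)


def generations_to_threshold(
    params: ReplacementParams,
    threshold: float,
    max_generations: int = 10**6,
) -> int | None:
    """First generation at which the wild-gene proportion drops below ``threshold``.

    Returns None ("never") when the wild gene persists: either the
    persistence condition (growth factor near p=0 above 1) holds, or the
    iteration converges to an equilibrium at or above the threshold.
    Generation 0 is the pre-stocking state; the test is strict (<).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if wild_gene_proportion(params.initial_state()) < threshold:
        return 0
    if wild_gene_growth_factor(params) > 1:
        return None
    state = params.initial_state()
    prev = wild_gene_proportion(state)
    for t in range(1, max_generations + 1):
        state = replacement_step(state, params)
        p = wild_gene_proportion(state)
        if p < threshold:
            return t
        if abs(p - prev) < 1e-15:
            return None  # settled at an equilibrium above the threshold
        prev = p
    return None


def equilibrium_surface(
    f_grid: np.ndarray,
    R_grid: np.ndarray,
    tol: float = 1e-12,
    max_generations: int = 10**6,
) -> pd.DataFrame:
    """Equilibrium wild-gene proportion over a (f, R) grid.

    All cells are iterated simultaneously (vectorized over the grid) from
    p0 = 1 until the largest per-cell change is below ``tol``.  Rows are
    indexed by f, columns by R.  Cells still changing after
    ``max_generations`` (this happens on the critical boundary
    (1+f) = 2f(1+R), where the wild gene decays algebraically rather than
    geometrically) keep their current value and are flagged False in the
    boolean frame stored at ``result.attrs["converged"]``.
    """
    f = np.asarray(f_grid, dtype=float)
    R = np.asarray(R_grid, dtype=float)
    if (f < 0).any() or (R < 0).any():
        raise ValueError("grids must be non-negative")
    F, RR = np.meshgrid(f, R, indexing="ij")
    ww = np.ones_like(F)
    wh = np.zeros_like(F)
    hh = np.zeros_like(F)
    w_mid = (1.0 + F) / 2.0
    cell_delta = np.full_like(F, np.inf)
    for _ in range(max_generations):
        tot = ww + wh * w_mid + hh * F
        dead = tot <= 0
        tot = np.where(dead, 1.0, tot)
        p_star = (ww + wh * w_mid / 2.0) / tot
        p_star = np.where(dead, 0.0, p_star)
        n_ww = p_star**2 / (1.0 + RR)
        n_wh = 2 * p_star * (1 - p_star) / (1.0 + RR)
        n_hh = ((1 - p_star) ** 2 + RR) / (1.0 + RR)
        cell_delta = np.maximum(
            np.abs(n_ww - ww), np.maximum(np.abs(n_wh - wh), np.abs(n_hh - hh))
        )
        ww, wh, hh = n_ww, n_wh, n_hh
        if cell_delta.max() < tol:
            break
    p_eq = ww + wh / 2.0
    out = pd.DataFrame(
        p_eq, index=pd.Index(f, name="f"), columns=pd.Index(R, name="R")
    )
    out.attrs["converged"] = pd.DataFrame(
        cell_delta < tol, index=out.index, columns=out.columns
    )
    return out
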
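"""Bayesian pairwise TMRCA estimation from Y-STR difference vectors.

Model
-----
Two paternal lineages coalesce t generations ago, so each locus has seen
2t meioses since the common ancestor (t on each branch).  Per-locus
mutation is Bernoulli(μ_i) per meiosis.

Under the infinite-allele model (IAM) every mutation creates a novel
allele, so a locus matches iff no mutation occurred on either branch:

    P(match | t)    = (1 − μ_i)^(2t)
    P(mismatch | t) = 1 − (1 − μ_i)^(2t)

Under the stepwise mutation model (SMM) each mutation shifts the repeat
count by ±1 with equal probability, and the observed signed repeat
difference d at a locus has likelihood

    P(d | t) = Σ_m Binom(m; 2t, μ_i) · P(±1 walk of m steps ends at d),

where the walk term is C(m, (m+d)/2)/2^m when m ≥ |d| and m ≡ d (mod 2),
else zero.

The prior on t is geometric with mean λ, P(t) = (1/(λ+1))(λ/(λ+1))^t on
t = 0, 1, 2, …  — the discrete analogue of the exponential pairwise
coalescence-time prior.  The posterior is evaluated on the integer grid
0..grid_max and normalized; summaries are the posterior mean, the
discrete median, the (smallest) mode, and central equal-tailed credible
intervals with bounds snapped outward to grid points.

Because t counts generations back to the ancestor on *one* branch, the
total number of generations separating the two sampled men is 2t;
:func:`generations_separating` performs that doubling and
:func:`to_years` converts generations to years (default 33 years per
generation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import stats
from scipy.special import gammaln

from .pairwise import PairDifference
from .panels import RM_SERIES, PanelDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRateTable",
    "WalshConfig",
    "TmrcaPosterior",
    "default_rates",
    "read_rate_table",
    "iam_likelihood",
    "smm_likelihood",
    "tmrca_posterior",
    "generations_separating",
    "to_years",
]

#: Synthetic default per-generation mutation rates (not a published table):
#: core 17-plex series 2e-3, added non-RM series 4e-3, rapidly mutating
#: series 1.2e-2 — the order-of-magnitude structure of Y-STR panels.
_CORE_RATE = 2e-3
_ADDITIONAL_RATE = 4e-3
_RM_RATE = 1.2e-2


@dataclass(frozen=True)
class MutationRateTable:
    """Per-series per-generation mutation probabilities μ_i ∈ (0, 0.1]."""

    rates: dict[str, float]

    def __post_init__(self):
        for s, mu in self.rates.items():
            if not (0.0 <= mu <= 0.1):
                raise ValueError(f"mutation rate out of range at {s}: {mu}")

    def __getitem__(self, series: str) -> float:
        try:
            return self.rates[series]
        except KeyError:
            raise KeyError(f"no mutation rate for series {series!r}") from None

    def for_loci(self, loci: tuple[str, ...]) -> np.ndarray:
        return np.array([self[s] for s in loci])


def default_rates(panel: PanelDefinition) -> MutationRateTable:
    """Bundled synthetic default rate table for a panel (see module note)."""
    core17 = {
        "DYS19", "DYS385a", "DYS385b", "DYS389I", "DYS389b", "DYS389II",
        "DYS390", "DYS391", "DYS392", "DYS393", "DYS437", "DYS438",
        "DYS439", "DYS448", "DYS456", "DYS458", "DYS635", "YGATAH4",
    }
    rates = {}
    for s in panel.series:
        if s in RM_SERIES:
            rates[s] = _RM_RATE
        elif s in core17:
            rates[s] = _CORE_RATE
        else:
            rates[s] = _ADDITIONAL_RATE
    return MutationRateTable(rates)


def read_rate_table(path) -> MutationRateTable:
    """Load a per-series rate table from a YAML mapping (series → rate)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return MutationRateTable({str(k): float(v) for k, v in doc.items()})


@dataclass(frozen=True)
class WalshConfig:
    """Estimator settings.

    ``lambda_prior`` is the prior mean TMRCA in generations for a random
    pair; ``grid_max`` defaults to max(10λ, 5000), which carries
    >99.99% of the geometric prior mass.
    """

    model: str = "IAM"
    lambda_prior: float = 1000.0
    grid_max: int | None = None
    ci_levels: tuple[float, ...] = (0.50, 0.95)

    def __post_init__(self):
        if self.model not in ("IAM", "SMM"):
            raise ValueError(f"unknown mutation model {self.model!r}")
        if self.lambda_prior <= 0:
            raise ValueError("lambda_prior must be > 0")
        if any(not 0 < l < 1 for l in self.ci_levels):
            raise ValueError("ci_levels must lie in (0, 1)")

    @property
    def effective_grid_max(self) -> int:
        if self.grid_max is not None:
            return int(self.grid_max)
        return int(max(10 * self.lambda_prior, 5000))


@dataclass
class TmrcaPosterior:
    """Discrete posterior over time to the MRCA.

    ``support`` and all summaries share one unit: generations per branch
    after :func:`tmrca_posterior`, total generations after
    :func:`generations_separating`, years after :func:`to_years`.
    """

    support: np.ndarray
    mass: np.ndarray
    mean: float
    median: float
    mode: float
    ci: dict[float, tuple[float, float]]
    unit: str = "generations"

    def scaled(self, factor: float, unit: str) -> "TmrcaPosterior":
        return TmrcaPosterior(
            support=self.support * factor,
            mass=self.mass.copy(),
            mean=self.mean * factor,
            median=self.median * factor,
            mode=self.mode * factor,
            ci={l: (lo * factor, hi * factor) for l, (lo, hi) in self.ci.items()},
            unit=unit,
        )


# ---------------------------------------------------------------------------
# likelihoods


def _iam_loglik_grid(
    diff: PairDifference, rates: MutationRateTable, ts: np.ndarray
) -> np.ndarray:
    mu = rates.for_loci(diff.loci)
    iam = np.asarray(diff.iam_vector, dtype=bool)
    log_keep = np.log1p(-mu)  # log(1 - mu)
    # matches: sum_i 2t*log(1-mu_i); mismatches: log(1 - (1-mu_i)^(2t))
    match_part = 2.0 * ts[:, None] * log_keep[None, ~iam]
    with np.errstate(divide="ignore"):
        mism_part = np.log(
            -np.expm1(2.0 * ts[:, None] * log_keep[None, iam])
        )
    return match_part.sum(axis=1) + mism_part.sum(axis=1)


def iam_likelihood(
    diff: PairDifference, rates: MutationRateTable, t: int
) -> float:
    """Infinite-allele likelihood of a difference vector at TMRCA ``t``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0 if diff.n_mismatch else 1.0
    ll = _iam_loglik_grid(diff, rates, np.array([float(t)]))[0]
    return float(np.exp(ll))


def _walk_logpmf(d: int, m: np.ndarray) -> np.ndarray:
    """log P(symmetric ±1 walk of m steps ends at displacement d)."""
    d = abs(d)
    out = np.full(m.shape, -np.inf)
    ok = (m >= d) & ((m - d) % 2 == 0)
    mm = m[ok]
    k = (mm + d) // 2
    out[ok] = gammaln(mm + 1) - gammaln(k + 1) - gammaln(mm - k + 1) - mm * np.log(2.0)
    return out


def _smm_locus_likelihood(d: float, mu: float, t: int) -> float:
    """P(signed repeat difference d | 2t meioses, rate mu) under SMM.

    Non-integer differences are rounded to the nearest repeat with a
    warning (the stepwise walk lives on an integer lattice).  The binomial
    sum over mutation counts m is truncated where the tail < 1e-12.
    """
    if d != round(d):
        logger.warning("non-integer repeat difference %s rounded for SMM", d)
    d = int(round(d))
    n = 2 * t
    if n == 0:
        return 1.0 if d == 0 else 0.0
    m_hi = int(stats.binom.ppf(1.0 - 1e-12, n, mu))
    m = np.arange(0, min(m_hi, n) + 1)
    log_binom = stats.binom.logpmf(m, n, mu)
    return float(np.exp(np.logaddexp.reduce(log_binom + _walk_logpmf(d, m))))


def smm_likelihood(
    diff: PairDifference, rates: MutationRateTable, t: int
) -> float:
    """Stepwise-model likelihood of the signed repeat-difference vector."""
    if t < 0:
        raise ValueError("t must be >= 0")
    mu = rates.for_loci(diff.loci)
    out = 1.0
    for d, m in zip(diff.smm_vector, mu):
        out *= _smm_locus_likelihood(d, m, t)
    return out


# ---------------------------------------------------------------------------
# posterior


def _geometric_log_prior(ts: np.ndarray, lam: float) -> np.ndarray:
    p = 1.0 / (lam + 1.0)
    return np.log(p) + ts * np.log1p(-p)


def _summaries(
    support: np.ndarray, mass: np.ndarray, ci_levels
) -> tuple[float, float, float, dict]:
    cdf = np.cumsum(mass)
    last = len(support) - 1

    def quantile(q: float) -> float:
        return float(support[min(int(np.searchsorted(cdf, q)), last)])

    mean = float(np.dot(support, mass))
    median = quantile(0.5)
    mode = float(support[int(np.argmax(mass))])  # argmax → smallest tied t
    ci = {}
    for level in sorted(ci_levels):
        alpha = (1.0 - level) / 2.0
        ci[level] = (quantile(alpha), quantile(1.0 - alpha))
    return mean, median, mode, ci


def tmrca_posterior(
    diff: PairDifference,
    rates: MutationRateTable,
    config: WalshConfig = WalshConfig(),
) -> TmrcaPosterior:
    """Posterior over the per-branch TMRCA t on the grid 0..grid_max.

    posterior(t) ∝ geometric prior(t; λ) × likelihood(t); all-zero
    likelihood across the grid raises (enlarge ``grid_max``).
    """
    ts = np.arange(config.effective_grid_max + 1, dtype=float)
    if config.model == "IAM":
        loglik = _iam_loglik_grid(diff, rates, ts)
    else:
        with np.errstate(divide="ignore"):
            loglik = np.array(
                [np.log(smm_likelihood(diff, rates, int(t))) for t in ts]
            )
    logpost = loglik + _geometric_log_prior(ts, config.lambda_prior)
    if not np.any(np.isfinite(logpost)):
        raise ValueError(
            "likelihood is zero everywhere on the grid; increase grid_max"
        )
    logpost -= np.max(logpost[np.isfinite(logpost)])
    mass = np.exp(logpost)
    mass /= mass.sum()
    if mass[-5:].sum() > 1e-4:
        logger.warning(
            "posterior mass %.2e within 5 points of grid_max=%d; "
            "consider a larger grid",
            mass[-5:].sum(),
            config.effective_grid_max,
        )
    mean, median, mode, ci = _summaries(ts, mass, config.ci_levels)
    return TmrcaPosterior(ts, mass, mean, median, mode, ci, unit="generations")


def generations_separating(post: TmrcaPosterior) -> TmrcaPosterior:
    """Total generations separating the two men: 2 × per-branch TMRCA."""
    return post.scaled(2.0, unit="total generations")


def to_years(post: TmrcaPosterior, generation_time: float = 33.0) -> TmrcaPosterior:
    """Convert a posterior over generations to years before present."""
    if generation_time <= 0:
        raise ValueError("generation_time must be > 0")
    return post.scaled(generation_time, unit="years")
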
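"""Recombination frequency from pooled read counts: the bulk-segregant model.

For one SNV and one bulk of ``n`` F2 plants, let ``G`` be the number of
mutant-parent alleles among the pool's ``2n`` chromosomes. Given the
recombination frequency ``alpha`` between the SNV and the causal locus, the
per-plant marker genotype probabilities are

* recessive-phenotype pool (causal homozygotes):
  ``p_LL = (1-alpha)^2``, ``p_Ll = 2*alpha*(1-alpha)``, ``p_ll = alpha^2``;
* dominant-phenotype pool (carriers of at least one wild-type causal
  allele, obtained by conditioning the 16 equiprobable gamete pairings):
  ``p_LL = alpha*(2-alpha)/3``, ``p_Ll = 2*(1-alpha+alpha^2)/3``,
  ``p_ll = (1-alpha^2)/3``,

where ``L`` denotes the mutant-parent allele (coupling phase). ``G`` is the
sum of ``n`` iid per-plant draws, i.e. trinomial. The mutant-read count
``M`` out of coverage ``c`` is beta-binomial: the library's mutant fraction
``Gamma ~ Beta(G*xi, (2n-G)*xi)`` models uneven tissue mixing with
concentration ``xi``, degenerating to a point mass at ``G/(2n)`` for
``G`` in ``{0, 2n}``, and ``M ~ Binomial(c, Gamma)``. The SNV likelihood is
the product over pools of the G-marginalised read probability; ``alpha`` is
estimated by maximum likelihood on [0, 0.5] with a profile-likelihood
confidence interval and a LOD score against independence (alpha = 0.5).

SNVs whose counts are implausible at *every* recombination frequency — the
signature of cross-library contamination — are flagged by
:func:`improbable_ratio_test`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import betabinom, chi2

from .synthetic_data import DOMINANT, RECESSIVE

__all__ = [
    "PoolObservation",
    "GenotypeClassProbs",
    "MixingModel",
    "RfEstimate",
    "genotype_class_probs",
    "pmf_G",
    "read_likelihood",
    "log_read_likelihood_vector",
    "snv_log_likelihood",
    "estimate_rf",
    "improbable_ratio_test",
    "analyze_snv",
    "estimate_rf_table",
]

DEFAULT_XI = 10.0
DEFAULT_GRID_STEP = 1e-4
DEFAULT_CI_LEVEL = 0.80
DEFAULT_EXCLUSION_THRESHOLD = 1e-3
#: coarse grid for the plausibility scan of the exclusion test
DEFAULT_EXCLUSION_GRID = np.linspace(0.0, 0.5, 101)


class PoolObservation(NamedTuple):
    """One bulk's read counts at one SNV: m mutant-parent reads of c total."""

    pool_id: str
    phenotype_class: str
    n: int
    m: int
    c: int


class GenotypeClassProbs(NamedTuple):
    """Per-plant probabilities of carrying 2/1/0 mutant-parent alleles."""

    p_LL: float
    p_Ll: float
    p_ll: float

    def per_copy(self) -> np.ndarray:
        """Probabilities indexed by allele copies 0, 1, 2."""
        return np.array([self.p_ll, self.p_Ll, self.p_LL])


@dataclass(frozen=True)
class MixingModel:
    xi: float = DEFAULT_XI

    def __post_init__(self) -> None:
        if not self.xi > 0:
            raise ValueError("xi must be > 0")


@dataclass
class RfEstimate:
    """ML recombination-frequency estimate for one SNV."""

    alpha_hat: float
    ci: tuple[float, float]
    lod: float
    excluded: bool | None = None
    pool_tails: dict | None = None
    defined: bool = True


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha <= 0.5:
        raise ValueError(f"alpha must be in [0, 0.5], got {alpha}")


def genotype_class_probs(alpha: float, pool_class: str) -> GenotypeClassProbs:
    """Marker genotype distribution of one plant drawn into a bulk."""
    _check_alpha(alpha)
    if pool_class == RECESSIVE:
        return GenotypeClassProbs(
            (1 - alpha) ** 2, 2 * alpha * (1 - alpha), alpha**2
        )
    if pool_class == DOMINANT:
        return GenotypeClassProbs(
            alpha * (2 - alpha) / 3,
            2 * (1 - alpha + alpha**2) / 3,
            (1 - alpha**2) / 3,
        )
    raise ValueError(f"unknown pool class {pool_class!r}")


def pmf_G(n: int, probs: GenotypeClassProbs) -> np.ndarray:
    """Distribution of G = mutant-parent allele count in a bulk of n plants.

    The trinomial sum over (k LL-plants, h Ll-plants) with 2k + h = g,
    computed as the n-fold convolution of the per-plant copy distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    per = probs.per_copy()
    if per.min() < -1e-12 or abs(per.sum() - 1) > 1e-9:
        raise ValueError(f"invalid genotype class probabilities {probs}")
    out = np.array([1.0])
    for _ in range(n):
        out = np.convolve(out, per)
    return out


def _class_probs_grid(alphas: np.ndarray, pool_class: str) -> np.ndarray:
    """Per-copy probabilities (len(alphas), 3) for a whole alpha grid."""
    a = np.asarray(alphas, dtype=float)
    if pool_class == RECESSIVE:
        cols = (a**2, 2 * a * (1 - a), (1 - a) ** 2)
    elif pool_class == DOMINANT:
        cols = ((1 - a**2) / 3, 2 * (1 - a + a**2) / 3, a * (2 - a) / 3)
    else:
        raise ValueError(f"unknown pool class {pool_class!r}")
    return np.stack(cols, axis=1)  # columns: 0, 1, 2 copies


_PMF_GRID_CACHE: dict = {}


def _pmf_G_grid(alphas: np.ndarray, n: int, pool_class: str) -> np.ndarray:
    """pmf of G for every alpha in the grid, shape (len(alphas), 2n+1).

    Grids are cached: the same dense alpha grid is reused for every SNV
    sharing a pool size and phenotype class.
    """
    key = (n, pool_class, len(alphas),
           float(alphas[0]), float(alphas[-1])) if len(alphas) > 1 else None
    if key is not None and key in _PMF_GRID_CACHE:
        return _PMF_GRID_CACHE[key]
    out = _pmf_G_grid_uncached(alphas, n, pool_class)
    if key is not None and len(_PMF_GRID_CACHE) < 64:
        _PMF_GRID_CACHE[key] = out
    return out


def _pmf_G_grid_uncached(alphas: np.ndarray, n: int, pool_class: str) -> np.ndarray:
    per = _class_probs_grid(alphas, pool_class)
    out = np.zeros((len(alphas), 2 * n + 1))
    out[:, 0] = 1.0
    width = 1
    for _ in range(n):
        new = np.zeros_like(out)
        for d in range(3):
            new[:, d:d + width] += out[:, :width] * per[:, d:d + 1]
        out, width = new, width + 2
    return out


def log_read_likelihood_vector(m: int, c: int, n: int, xi: float) -> np.ndarray:
    """log P(M = m | G = g) for g = 0..2n under the beta-binomial read model.

    Boundaries G = 0 and G = 2n are the point-mass limits of the Beta: the
    read count is then deterministic (m = 0, resp. m = c).
    """
    if not 0 <= m <= c:
        raise ValueError(f"need 0 <= m <= c, got m={m}, c={c}")
    g = np.arange(1, 2 * n)
    out = np.empty(2 * n + 1)
    if c == 0:
        out[:] = 0.0  # P(M=0 | c=0) = 1 for every G
        return out
    with np.errstate(divide="ignore"):
        out[1:2 * n] = betabinom.logpmf(m, c, g * xi, (2 * n - g) * xi)
    out[0] = 0.0 if m == 0 else -np.inf
    out[2 * n] = 0.0 if m == c else -np.inf
    return out


def read_likelihood(m: int, c: int, G: int, n: int,
                    mix: MixingModel | float = DEFAULT_XI) -> float:
    """P(M = m | G) for a single G (scalar convenience wrapper)."""
    xi = mix.xi if isinstance(mix, MixingModel) else float(mix)
    if not 0 <= G <= 2 * n:
        raise ValueError(f"G={G} outside [0, {2 * n}]")
    return float(np.exp(log_read_likelihood_vector(m, c, n, xi)[G]))


def _as_pools(pools: Sequence) -> list[PoolObservation]:
    out = [p if isinstance(p, PoolObservation) else PoolObservation(*p)
           for p in pools]
    if not out:
        raise ValueError("need at least one pool observation")
    for p in out:
        if p.n < 1:
            raise ValueError(f"pool {p.pool_id!r}: n must be >= 1")
        if not 0 <= p.m <= p.c:
            raise ValueError(f"pool {p.pool_id!r}: need 0 <= m <= c")
    return out


def snv_log_likelihood(alpha: float, pools: Sequence,
                       mix: MixingModel | float = DEFAULT_XI) -> float:
    """Log-likelihood of one SNV's pooled counts at recombination frequency alpha."""
    xi = mix.xi if isinstance(mix, MixingModel) else float(mix)
    _check_alpha(alpha)
    total = 0.0
    for p in _as_pools(pools):
        pg = pmf_G(p.n, genotype_class_probs(alpha, p.phenotype_class))
        lrl = log_read_likelihood_vector(p.m, p.c, p.n, xi)
        with np.errstate(divide="ignore"):
            terms = np.where(pg > 0, np.log(np.where(pg > 0, pg, 1.0)) + lrl,
                             -np.inf)
        total += float(logsumexp(terms))
    return total


def _loglik_grid(pools: list[PoolObservation], alphas: np.ndarray,
                 xi: float) -> np.ndarray:
    """Vectorised log-likelihood over an alpha grid (sum over pools)."""
    ll = np.zeros(len(alphas))
    pmf_cache: dict[tuple[int, str], np.ndarray] = {}
    for p in pools:
        key = (p.n, p.phenotype_class)
        if key not in pmf_cache:
            pmf_cache[key] = _pmf_G_grid(alphas, p.n, p.phenotype_class)
        pg = pmf_cache[key]
        # probability space is safe here: the marginal is a convex mixture
        # and at least one G keeps P(m|G) well above the float64 floor
        rl = np.exp(log_read_likelihood_vector(p.m, p.c, p.n, xi))
        marg = pg @ rl
        with np.errstate(divide="ignore"):
            ll += np.log(marg)
    return ll


def estimate_rf(pools: Sequence, mix: MixingModel | float = DEFAULT_XI,
                grid_step: float = DEFAULT_GRID_STEP,
                ci_level: float = DEFAULT_CI_LEVEL) -> RfEstimate:
    """ML estimate of alpha on [0, 0.5] with profile-likelihood CI and LOD.

    A dense grid locates the maximum, a bounded scalar optimisation refines
    it; the CI is the connected set around the maximum where the
    likelihood-ratio statistic 2*(l(a_hat) - l(a)) stays below the chi2(1)
    quantile of ``ci_level``, intersected with [0, 0.5].
    """
    xi = mix.xi if isinstance(mix, MixingModel) else float(mix)
    pools = _as_pools(pools)
    if all(p.c == 0 for p in pools):
        return RfEstimate(np.nan, (np.nan, np.nan), np.nan, defined=False)
    alphas = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
    ll = _loglik_grid(pools, alphas, xi)
    i = int(np.argmax(ll))
    lo = max(0.0, alphas[i] - grid_step)
    hi = min(0.5, alphas[i] + grid_step)
    # the read-likelihood vectors do not depend on alpha: fix them once and
    # refine on the cheap G-mixture only
    rls = [np.exp(log_read_likelihood_vector(p.m, p.c, p.n, xi))
           for p in pools]

    def _ll_scalar(a: float) -> float:
        total = 0.0
        for p, rl in zip(pools, rls):
            marg = pmf_G(p.n, genotype_class_probs(a, p.phenotype_class)) @ rl
            if marg <= 0.0:
                return -np.inf
            total += np.log(marg)
        return total

    res = minimize_scalar(lambda a: -_ll_scalar(a),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-9})
    alpha_hat, ll_hat = float(res.x), float(-res.fun)
    if ll[i] > ll_hat:  # grid point can beat the local refinement at edges
        alpha_hat, ll_hat = float(alphas[i]), float(ll[i])
    lod = max(0.0, (ll_hat - ll[-1]) / np.log(10))
    thresh = ll_hat - chi2.ppf(ci_level, 1) / 2
    inside = ll >= thresh
    j_lo = i
    while j_lo > 0 and inside[j_lo - 1]:
        j_lo -= 1
    j_hi = i
    while j_hi < len(alphas) - 1 and inside[j_hi + 1]:
        j_hi += 1

    def _cross(j_in: int, j_out: int) -> float:
        # linear interpolation of the log-likelihood across the threshold
        y1, y2 = ll[j_in], ll[j_out]
        if not np.isfinite(y2) or y1 == y2:
            return float(alphas[j_out])
        f = (y1 - thresh) / (y1 - y2)
        return float(alphas[j_in] + f * (alphas[j_out] - alphas[j_in]))

    ci_lo = 0.0 if j_lo == 0 else _cross(j_lo, j_lo - 1)
    ci_hi = 0.5 if j_hi == len(alphas) - 1 else _cross(j_hi, j_hi + 1)
    return RfEstimate(alpha_hat, (ci_lo, ci_hi), lod)


def _pool_tail_curve(p: PoolObservation, alphas: np.ndarray,
                     xi: float) -> np.ndarray:
    """min(P(M<=m), P(M>=m)) under the G-marginalised model, per alpha."""
    g = np.arange(1, 2 * p.n)
    lower_g = np.empty(2 * p.n + 1)
    upper_g = np.empty(2 * p.n + 1)
    if p.c == 0:
        lower_g[:] = 1.0
        upper_g[:] = 1.0
    else:
        lower_g[1:2 * p.n] = betabinom.cdf(p.m, p.c, g * xi, (2 * p.n - g) * xi)
        upper_g[1:2 * p.n] = betabinom.sf(p.m - 1, p.c, g * xi,
                                          (2 * p.n - g) * xi)
        lower_g[0] = 1.0                       # M = 0 <= m always
        upper_g[0] = 1.0 if p.m == 0 else 0.0
        lower_g[2 * p.n] = 1.0 if p.m == p.c else 0.0
        upper_g[2 * p.n] = 1.0                 # M = c >= m always
    pg = _pmf_G_grid(alphas, p.n, p.phenotype_class)
    return np.minimum(pg @ lower_g, pg @ upper_g)


def improbable_ratio_test(pools: Sequence,
                          mix: MixingModel | float = DEFAULT_XI,
                          p_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
                          alpha_grid: np.ndarray | None = None,
                          alpha_hat: float | None = None):
    """Exclusion test for SNVs with an implausible inherited-allele ratio.

    For every alpha on the grid, each pool's exact tail probability of its
    read count is the smaller of P(M <= m) and P(M >= m) under the
    G-marginalised beta-binomial model. The SNV is excluded iff no alpha in
    [0, 0.5] renders every pool plausible (all tails >= ``p_threshold``) —
    the pattern produced by cross-library read contamination rather than by
    any recombination frequency. Returns ``(excluded, per-pool tails)``
    with tails evaluated at ``alpha_hat`` (the MLE if not supplied).
    """
    xi = mix.xi if isinstance(mix, MixingModel) else float(mix)
    pools = _as_pools(pools)
    grid = DEFAULT_EXCLUSION_GRID if alpha_grid is None else np.asarray(alpha_grid)
    curves = np.stack([_pool_tail_curve(p, grid, xi) for p in pools])
    plausible = (curves >= p_threshold).all(axis=0)
    excluded = not bool(plausible.any())
    if alpha_hat is None:
        alpha_hat = estimate_rf(pools, xi).alpha_hat
    at_hat = np.stack([_pool_tail_curve(p, np.array([alpha_hat]), xi)
                       for p in pools])[:, 0]
    tails = {p.pool_id: float(t) for p, t in zip(pools, at_hat)}
    return excluded, tails


def analyze_snv(pools: Sequence, mix: MixingModel | float = DEFAULT_XI,
                grid_step: float = DEFAULT_GRID_STEP,
                ci_level: float = DEFAULT_CI_LEVEL,
                p_threshold: float = DEFAULT_EXCLUSION_THRESHOLD) -> RfEstimate:
    """Full per-SNV analysis: RF estimate, CI, LOD and exclusion flag."""
    est = estimate_rf(pools, mix, grid_step, ci_level)
    if not est.defined:
        return est
    est.excluded, est.pool_tails = improbable_ratio_test(
        pools, mix, p_threshold, alpha_hat=est.alpha_hat
    )
    return est


def estimate_rf_table(counts: pd.DataFrame,
                      mix: MixingModel | float = DEFAULT_XI,
                      grid_step: float = DEFAULT_GRID_STEP,
                      ci_level: float = DEFAULT_CI_LEVEL,
                      p_threshold: float = DEFAULT_EXCLUSION_THRESHOLD) -> pd.DataFrame:
    """Per-SNV RF estimates from a long counts table.

    ``counts`` needs columns snv_id, pool_id, phenotype_class, n, m, c.
    Output is sorted ascending by the point estimate (ties: LOD descending,
    then SNV id), with uninformative and excluded SNVs flagged.
    """
    required = {"snv_id", "pool_id", "phenotype_class", "n", "m", "c"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    rows = []
    for snv_id, grp in counts.groupby("snv_id", sort=False):
        pools = [PoolObservation(str(r.pool_id), r.phenotype_class,
                                 int(r.n), int(r.m), int(r.c))
                 for r in grp.itertuples()]
        est = analyze_snv(pools, mix, grid_step, ci_level, p_threshold)
        rows.append((snv_id, est.alpha_hat, est.ci[0], est.ci[1], est.lod,
                     bool(est.excluded) if est.excluded is not None else False,
                     est.defined))
    out = pd.DataFrame(rows, columns=["snv_id", "alpha_hat", "ci_low",
                                      "ci_high", "lod", "excluded", "defined"])
    return out.sort_values(["alpha_hat", "lod", "snv_id"],
                           ascending=[True, False, True],
                           na_position="last").reset_index(drop=True)
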
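"""Uncertainty and Specificity statistics for NPA scores.

Uncertainty is a confidence interval for a score.  Strength and GPI admit
analytic t-intervals: the score is a weighted sum of (approximately) normal
per-gene estimators, its variance follows by error propagation, and the
effective degrees of freedom come from the Welch-Satterthwaite equation.
MASS and EPI are non-linear, so a parametric bootstrap resamples each beta_i
from Normal(beta_i, sd_i^2) and the interval is the bias-corrected
percentile interval of the bootstrap score distribution.

Specificity asks whether a score is attributable to the HYP's specific genes
rather than to a data-set-wide trend: the HYP is re-scored after replacing
every downstream gene by a different measured gene with a similar number of
known upstream controllers (drawn from the same controller-count "cadre"),
and a two-tailed permutation p-value places the observed score on that null
distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from npascore.contrasts import Contrast, MatchedInput, align_hyp_contrast
from npascore.hyp import Hyp
from npascore.scoring import EpiConfig, ScoringError, epi, gpi, mass, score, strength

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    """Invalid statistic input (bad cadres, depleted pools, missing columns)."""


@dataclass
class ScoreResult:
    """A point score with its companion statistics."""

    method: str
    value: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    eff_df: float | None = None
    n_boot: int | None = None
    specificity_p: float | None = None
    n_used: int = 0
    n_missing: int = 0

    def __post_init__(self) -> None:
        if not self.ci_low <= self.ci_high:
            raise StatsError("ci_low must not exceed ci_high")
        if not 0 < self.alpha < 1:
            raise StatsError("alpha must lie in (0, 1)")


def welch_satterthwaite(weights: np.ndarray, sd: np.ndarray, df: np.ndarray) -> float:
    """Effective degrees of freedom of a weighted sum of t-distributed terms.

    Df = (sum w_i^2 sd_i^2)^2 / sum (w_i^2 sd_i^2)^2 / df_i.
    """
    weights = np.asarray(weights, dtype=float)
    sd = np.asarray(sd, dtype=float)
    df = np.asarray(df, dtype=float)
    if weights.size == 0:
        raise StatsError("empty input")
    if np.any(sd <= 0) or np.any(df <= 0):
        raise StatsError("sd and df must be positive")
    terms = weights**2 * sd**2
    return float(np.sum(terms) ** 2 / np.sum(terms**2 / df))


def _t_interval(value: float, sd_score: float, weights, sd, df, alpha: float):
    if sd_score == 0:
        return value, value, float("inf")
    eff_df = welch_satterthwaite(weights, sd, df)
    tq = float(sps.t.ppf(1 - alpha / 2, eff_df))
    return value - tq * sd_score, value + tq * sd_score, eff_df


def strength_ci(m: MatchedInput, alpha: float = 0.05) -> ScoreResult:
    """Analytic t confidence interval for Strength.

    Sd^2 = (1/N^2) sum sd_i^2; the effective degrees of freedom use
    Welch-Satterthwaite with weights 1/N.
    """
    m.require("sd", "df")
    value = strength(m)
    n = m.n_used
    sd_score = float(np.sqrt(np.sum(m.sd**2)) / n)
    lo, hi, eff_df = _t_interval(value, sd_score, np.full(n, 1.0 / n), m.sd, m.df, alpha)
    return ScoreResult("strength", value, lo, hi, alpha, eff_df=eff_df,
                       n_used=n, n_missing=m.n_missing)


def gamma_weights(m: MatchedInput) -> np.ndarray:
    """First-order error-propagation weights for GPI.

    gamma_i = fndr_i + 2 (fdr_i/p_i) |beta_i/sd_i| t-pdf_{df_i}(beta_i/sd_i):
    the derivative of fndr(beta_i) * beta_i holding the BH adjustment factor
    fdr_i/p_i fixed (its own derivative is negligible at small p).  When
    fdr_i = 0 the adjustment term vanishes and gamma_i = fndr_i = 1.
    """
    m.require("sd", "df", "p", "fdr")
    fdr, p = m.fdr, m.p
    if np.any((p == 0) & (fdr > 0)):
        raise StatsError("p = 0 with fdr > 0: BH adjustment factor undefined")
    ratio = np.where(fdr > 0, fdr / np.where(p > 0, p, 1.0), 0.0)
    t = m.beta / m.sd
    return m.fndr + 2.0 * ratio * np.abs(t) * sps.t.pdf(t, m.df)


def gpi_ci(m: MatchedInput, alpha: float = 0.05) -> ScoreResult:
    """Analytic t confidence interval for GPI via the gamma-weighted variance.

    Sd^2 = (1/N) sum gamma_i^2 sd_i^2; Welch-Satterthwaite effective degrees
    of freedom use weights gamma_i / sqrt(N), mirroring the variance
    decomposition.
    """
    value = gpi(m)
    n = m.n_used
    m.require("sd", "df", "p", "fdr")
    if np.max(m.sd) == 0:
        return ScoreResult("gpi", value, value, value, alpha, eff_df=float("inf"),
                           n_used=n, n_missing=m.n_missing)
    gam = gamma_weights(m)
    sd_score = float(np.sqrt(np.sum(gam**2 * m.sd**2) / n))
    lo, hi, eff_df = _t_interval(value, sd_score, gam / np.sqrt(n), m.sd, m.df, alpha)
    return ScoreResult("gpi", value, lo, hi, alpha, eff_df=eff_df,
                       n_used=n, n_missing=m.n_missing)


def _bootstrap_scores(m: MatchedInput, method: str, B: int,
                      rng: np.random.Generator, cfg: EpiConfig | None) -> np.ndarray:
    """B parametric bootstrap scores: beta* ~ Normal(beta, sd^2) per gene."""
    beta_star = rng.normal(loc=m.beta, scale=m.sd, size=(B, m.n_used))
    if method == "strength":
        return np.mean(m.s * beta_star, axis=1)
    if method == "gpi":
        m.require("fndr")
        # fndr weights held at their observed values; only beta is resampled
        return (m.s * m.fndr * beta_star).sum(axis=1) / np.sqrt(m.n_used)
    if method == "mass":
        m.require("treated", "control")
        # split the resampled fold change symmetrically around the observed
        # per-gene geometric mean abundance, so MASS stays a function of
        # abundances while only beta is bootstrapped (always non-negative)
        g = np.sqrt(m.treated * m.control)
        tr = g * np.exp2(beta_star / 2.0)
        ct = g * np.exp2(-beta_star / 2.0)
        denom = (tr + ct).sum(axis=1) / 2.0
        return (m.s * (tr - ct)).sum(axis=1) / denom
    if method == "epi":
        cfg = cfg or EpiConfig()
        out = np.empty(B)
        for b in range(B):
            mb = MatchedInput(genes=m.genes, s=m.s, beta=beta_star[b], sd=None,
                              df=None, p=None, fdr=None, fndr=None,
                              treated=None, control=None)
            out[b] = epi(mb, cfg)
        return out
    raise ScoringError(f"unknown scoring method {method!r}")


def bootstrap_ci(
    m: MatchedInput,
    method: str,
    alpha: float = 0.05,
    B: int = 2000,
    seed: int = 0,
    cfg: EpiConfig | None = None,
) -> ScoreResult:
    """Bias-corrected percentile bootstrap confidence interval.

    z0 is the standard-normal quantile of the fraction of bootstrap scores
    below the observed score; the interval endpoints are the bootstrap
    quantiles at Phi(2 z0 -/+ z_{1-alpha/2}).  A one-sided bootstrap (all
    scores on one side of the observed value) clamps the fraction to
    1/(2B) from the boundary to keep z0 finite.
    """
    if B < 100:
        raise StatsError(f"B must be >= 100, got {B}")
    m.require("sd")
    value = score(m, method, cfg)
    if np.max(m.sd) == 0:
        return ScoreResult(method, value, value, value, alpha, n_boot=B,
                           n_used=m.n_used, n_missing=m.n_missing)
    rng = np.random.default_rng(seed)
    boot = _bootstrap_scores(m, method, B, rng, cfg)
    frac_below = np.clip(np.mean(boot < value), 1.0 / (2 * B), 1 - 1.0 / (2 * B))
    z0 = float(sps.norm.ppf(frac_below))
    zq = float(sps.norm.ppf(1 - alpha / 2))
    a_lo = float(sps.norm.cdf(2 * z0 - zq))
    a_hi = float(sps.norm.cdf(2 * z0 + zq))
    lo, hi = np.quantile(boot, [a_lo, a_hi])
    return ScoreResult(method, value, float(lo), float(hi), alpha, n_boot=B,
                       n_used=m.n_used, n_missing=m.n_missing)


@dataclass
class CadreIndex:
    """Measured genes partitioned into controller-count-ranked cadres.

    Cadres are ordered from most to fewest upstream controllers; each holds
    exactly ``cadre_size`` genes except the last (fewest controllers), which
    absorbs the remainder and holds between cadre_size and 2*cadre_size - 1.
    """

    cadres: list[list[str]]
    cadre_size: int

    def __post_init__(self) -> None:
        self._lookup = {g: i for i, cadre in enumerate(self.cadres) for g in cadre}
        sizes = [len(c) for c in self.cadres]
        if len(self._lookup) != sum(sizes):
            raise StatsError("cadres must be pairwise disjoint")
        if any(s != self.cadre_size for s in sizes[:-1]):
            raise StatsError("all cadres but the last must have exactly cadre_size genes")
        if not self.cadre_size <= sizes[-1] <= 2 * self.cadre_size - 1:
            raise StatsError("last cadre must hold cadre_size..2*cadre_size-1 genes")

    def cadre_of(self, gene: str) -> int:
        try:
            return self._lookup[gene]
        except KeyError:
            raise StatsError(f"gene {gene!r} not in the cadre universe") from None

    @property
    def universe(self) -> set[str]:
        return set(self._lookup)


def build_cadres(
    counts: dict[str, int],
    measured: set[str] | None = None,
    cadre_size: int = 100,
) -> CadreIndex:
    """Rank measured genes by descending upstream-controller count into cadres.

    Ties break lexicographically; the remainder short of a full cadre is
    merged into the final (fewest-controllers) cadre.
    """
    if cadre_size < 2:
        raise StatsError("cadre_size must be >= 2")
    genes = sorted(measured if measured is not None else counts)
    missing = [g for g in genes if g not in counts]
    if missing:
        raise StatsError(f"no controller count for measured gene(s): {missing[:5]}")
    if len(genes) < cadre_size:
        raise StatsError(
            f"{len(genes)} measured genes cannot fill one cadre of {cadre_size}"
        )
    ranked = sorted(genes, key=lambda g: (-counts[g], g))
    n_full = len(ranked) // cadre_size - 1
    cadres = [ranked[i * cadre_size:(i + 1) * cadre_size] for i in range(n_full)]
    cadres.append(ranked[n_full * cadre_size:])
    return CadreIndex(cadres=cadres, cadre_size=cadre_size)


def _comparable_indices(
    positions_by_cadre: dict[int, np.ndarray],
    orig_idx: np.ndarray,
    cadre_pools: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Replacement gene indices for one comparable HYP.

    Within each cadre, samples as many distinct genes as the HYP has
    positions there, then repairs any position that drew its own original
    gene (single collision: swap with another position; several: cyclic
    rotation among the colliding positions, valid because original genes are
    pairwise distinct).
    """
    out = np.empty_like(orig_idx)
    for cadre, pos in positions_by_cadre.items():
        pool = cadre_pools[cadre]
        k = len(pos)
        if k > len(pool) or (k == 1 and len(pool) < 2):
            raise StatsError(
                f"cadre {cadre} too depleted to supply {k} distinct replacements"
            )
        pick = rng.choice(pool, size=k, replace=False)
        orig = orig_idx[pos]
        bad = np.flatnonzero(pick == orig)
        if len(bad) == 1:
            if k == 1:
                others = pool[pool != orig[0]]
                pick[0] = others[rng.integers(len(others))]
            else:
                j = bad[0]
                l = (j + 1 + rng.integers(k - 1)) % k
                pick[j], pick[l] = pick[l], pick[j]
        elif len(bad) > 1:
            pick[bad] = np.roll(pick[bad], 1)
        out[pos] = pick
    return out


def specificity(
    h: Hyp,
    c: Contrast,
    method: str,
    cadres: CadreIndex,
    n_null: int = 1000,
    seed: int = 0,
    cfg: EpiConfig | None = None,
    naive: bool = False,
) -> float:
    """Two-tailed cadre-matched permutation p-value for a HYP score.

    Builds ``n_null`` comparable HYPs by replacing every downstream gene with
    a different measured gene from the same cadre (preserving the original
    sign at each position, genes unique within one comparable HYP), scores
    each against the contrast, and doubles the lesser tail fraction (strict
    inequalities; capped at 1).  ``naive=True`` replaces the cadre pools with
    the whole measured universe -- the anti-conservative baseline sampler,
    provided for comparison only.
    """
    if n_null < 100:
        raise StatsError(f"n_null must be >= 100, got {n_null}")
    m = align_hyp_contrast(h, c)
    observed = score(m, method, cfg)

    # restrict cadre pools to genes actually measured in this contrast
    gene_pos = {g: i for i, g in enumerate(c.genes)}
    if naive:
        cadre_of = {g: 0 for g in gene_pos}
        pools = {0: np.arange(len(gene_pos))}
    else:
        cadre_of = {}
        pools_list: dict[int, list[int]] = {}
        for i, cadre in enumerate(cadres.cadres):
            for g in cadre:
                j = gene_pos.get(g)
                if j is not None:
                    cadre_of[g] = i
                    pools_list.setdefault(i, []).append(j)
        pools = {i: np.asarray(v) for i, v in pools_list.items()}

    missing = [g for g in m.genes if g not in cadre_of]
    if missing:
        raise StatsError(
            f"HYP gene(s) absent from the measured cadre universe: {missing[:5]}"
        )
    orig_idx = np.asarray([gene_pos[g] for g in m.genes])
    positions_by_cadre: dict[int, np.ndarray] = {}
    cadre_ids = np.asarray([cadre_of[g] for g in m.genes])
    for cad in np.unique(cadre_ids):
        positions_by_cadre[int(cad)] = np.flatnonzero(cadre_ids == cad)

    tab = c.table
    beta_all = tab["beta"].to_numpy(dtype=float)
    fndr_all = treated_all = control_all = None
    if method == "gpi":
        from npascore.contrasts import bh_fdr

        if c.has("fdr"):
            fndr_all = 1.0 - tab["fdr"].to_numpy(dtype=float)
        else:
            m.require("fdr")  # ensures p existed array-wide
            fndr_all = 1.0 - bh_fdr(tab["p"].to_numpy(dtype=float))
    elif method == "mass":
        m.require("treated", "control")
        treated_all = tab["treated"].to_numpy(dtype=float)
        control_all = tab["control"].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    s = m.s
    null = np.empty(n_null)
    sqrt_n = np.sqrt(m.n_used)
    for r in range(n_null):
        idx = _comparable_indices(positions_by_cadre, orig_idx, pools, rng)
        if method == "strength":
            null[r] = np.mean(s * beta_all[idx])
        elif method == "gpi":
            null[r] = np.sum(s * fndr_all[idx] * beta_all[idx]) / sqrt_n
        elif method == "mass":
            tr, ct = treated_all[idx], control_all[idx]
            null[r] = np.sum(s * (tr - ct)) / (np.sum(tr + ct) / 2.0)
        elif method == "epi":
            mb = MatchedInput(genes=m.genes, s=s, beta=beta_all[idx], sd=None,
                              df=None, p=None, fdr=None, fndr=None,
                              treated=None, control=None)
            null[r] = epi(mb, cfg)
        else:
            raise ScoringError(f"unknown scoring method {method!r}")

    return two_tailed_p(null, observed)


def two_tailed_p(null: np.ndarray, observed: float) -> float:
    """Double the lesser strict-tail fraction of a permutation null, capped at 1.

    Ties with the observed score contribute to neither tail; an observed
    score outside the null range yields 0 (reported as < 1/n in logs).
    """
    null = np.asarray(null, dtype=float)
    n = null.size
    greater = int(np.sum(null > observed))
    lesser = int(np.sum(null < observed))
    if min(greater, lesser) == 0:
        logger.info("specificity: observed score outside the null range; p < %g", 1.0 / n)
    return min(2.0 * min(greater, lesser) / n, 1.0)
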
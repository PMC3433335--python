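"""The four Network Perturbation Amplitude point scores.

Given matched per-gene vectors (HYP signs s_i and contrast statistics), the
scores are:

* ``strength`` -- (1/N) sum s_i * beta_i, the sign-adjusted mean log2
  differential expression.
* ``gpi``      -- (1/sqrt(N)) sum s_i * fndr_i * beta_i, the projection of
  the differential-expression vector onto the unit HYP sign vector under an
  fndr-weighted scalar product.
* ``mass``     -- sum s_i (treated_i - control_i) / sum (treated_i + control_i)/2,
  the sign-adjusted absolute abundance change relative to the average total
  abundance (linear scale).
* ``epi``      -- the expectation of an evidence-weighted density over signed
  differential values on [-M, M]; a smoothed, threshold-free relative of GPI
  that up-weights strong differential expression.

Positive values mean the process the HYP describes is up-regulated in the
treated condition; all four scores negate exactly under contrast reversal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from npascore.contrasts import MatchedInput

logger = logging.getLogger(__name__)


class ScoringError(ValueError):
    """Invalid score input (empty, missing columns, degenerate denominator)."""


@dataclass
class EpiConfig:
    """EPI construction parameters.

    M bounds |log2 differential expression| (expression signal saturates
    around 15 on log2 microarray scale, hence the default); epsilon is the
    half-width of the interpolation band joining the two density branches at
    zero; literal_prefactor applies the raw 1/(2M) factor to the expectation
    instead of folding it into the density normalisation (the default keeps
    the score bounded by M).
    """

    M: float = 15.0
    epsilon: float | None = None  # default M * 1e-12
    literal_prefactor: bool = False

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ScoringError(f"M must be positive, got {self.M}")
        if self.epsilon is None:
            self.epsilon = self.M * 1e-12
        if not 0 < self.epsilon < self.M:
            raise ScoringError("epsilon must satisfy 0 < epsilon < M")


def strength(m: MatchedInput) -> float:
    """Sign-adjusted mean log2 differential expression, (1/N) sum s_i beta_i."""
    if m.n_used < 1:
        raise ScoringError("empty input")
    return float(np.mean(m.s * m.beta))


def gpi(m: MatchedInput) -> float:
    """Geometric Perturbation Index, (1/sqrt(N)) sum s_i fndr_i beta_i."""
    if m.n_used < 1:
        raise ScoringError("empty input")
    m.require("fndr")
    if np.any((m.fndr < 0) | (m.fndr > 1)):
        raise ScoringError("fndr values must lie in [0, 1]")
    return float(np.sum(m.s * m.fndr * m.beta) / np.sqrt(m.n_used))


def mass(m: MatchedInput) -> float:
    """Measured Abundance Signal Score on linear-scale abundances."""
    if m.n_used < 1:
        raise ScoringError("empty input")
    m.require("treated", "control")
    if np.any(m.treated < 0) or np.any(m.control < 0):
        raise ScoringError("abundances must be non-negative")
    denom = float(np.sum(m.treated + m.control) / 2.0)
    if denom <= 0:
        raise ScoringError("all-zero abundances: MASS denominator is zero")
    num = float(np.sum(m.s * (m.treated - m.control)))
    return num / denom


def _epi_density_breaks(x: np.ndarray, M: float, eps: float):
    """Breakpoints and plateau values of the un-normalised EPI density.

    For phi in (eps, M] the density is (1/(N*M)) * sum of |x_i| over x_i > phi
    (the cumulated magnitude of correctly-signed values exceeding phi);
    symmetrically for phi in [-M, -eps); linear interpolation bridges
    [-eps, eps].  x_i = s_i * beta_i, already clamped to [-M, M].
    Returns (pos_breaks, pos_vals, neg_breaks, neg_vals) where the density on
    (pos_breaks[k], pos_breaks[k+1]) is pos_vals[k], etc.
    """
    n = len(x)
    pos = np.sort(x[x > eps])
    # plateau just above eps holds the full positive magnitude sum; each
    # breakpoint sheds its own magnitude
    pos_breaks = np.concatenate(([eps], pos, [M]))
    tail = np.concatenate((np.cumsum(pos[::-1])[::-1], [0.0]))  # sum of pos >= pos[k]
    # on (pos[k-1], pos[k]) density counts x_i > phi, i.e. x_i >= pos[k]
    pos_vals = tail / (n * M)
    neg = np.sort(-x[x < -eps])  # magnitudes
    neg_breaks = np.concatenate(([eps], neg, [M]))
    ntail = np.concatenate((np.cumsum(neg[::-1])[::-1], [0.0]))
    neg_vals = ntail / (n * M)
    return pos_breaks, pos_vals, neg_breaks, neg_vals


def epi(m: MatchedInput, cfg: EpiConfig | None = None) -> float:
    """Expected Perturbation Index by exact piecewise integration.

    Builds the piecewise-constant density from the signed differential values
    x_i = s_i * beta_i, normalises its total mass on [-M, M] to one, and
    returns the expectation (times 1/(2M) when ``literal_prefactor``).
    Degenerate inputs with no mass (all x_i = 0) score 0.
    """
    if m.n_used < 1:
        raise ScoringError("empty input")
    cfg = cfg or EpiConfig()
    M, eps = cfg.M, cfg.epsilon
    x = m.s * m.beta
    n_clamped = int(np.sum(np.abs(x) > M))
    if n_clamped:
        logger.warning("EPI: clamping %d value(s) with |s*beta| > M=%g", n_clamped, M)
        x = np.clip(x, -M, M)

    pb, pv, nb, nv = _epi_density_breaks(x, M, eps)
    # piecewise-constant segments: mass = c*(u-l), first moment = c*(u^2-l^2)/2
    pw = np.diff(pb)
    mass_pos = float(np.sum(pv * pw))
    mom_pos = float(np.sum(pv * (pb[1:] ** 2 - pb[:-1] ** 2)) / 2.0)
    nw = np.diff(nb)
    mass_neg = float(np.sum(nv * nw))
    mom_neg = -float(np.sum(nv * (nb[1:] ** 2 - nb[:-1] ** 2)) / 2.0)
    # linear bridge on [-eps, eps] between f(-eps)=nv[0] and f(eps)=pv[0]
    f_lo, f_hi = nv[0], pv[0]
    mass_mid = eps * (f_lo + f_hi)
    mom_mid = (f_hi - f_lo) * eps**2 / 3.0

    total = mass_pos + mass_neg + mass_mid
    if total <= 0:
        return 0.0
    value = (mom_pos + mom_neg + mom_mid) / total
    if cfg.literal_prefactor:
        value /= 2.0 * M
    return float(value)


_METHODS = {"strength": strength, "gpi": gpi, "mass": mass}


def score(m: MatchedInput, method: str, cfg: EpiConfig | None = None) -> float:
    """Dispatch a point score by method name (strength | gpi | mass | epi)."""
    method = method.lower()
    if method == "epi":
        return epi(m, cfg)
    if method not in _METHODS:
        raise ScoringError(f"unknown scoring method {method!r}")
    return _METHODS[method](m)


def gene_contributions(m: MatchedInput, method: str) -> np.ndarray:
    """Per-gene additive contributions for the linear scores (strength, gpi)."""
    if method == "strength":
        return m.s * m.beta / m.n_used
    if method == "gpi":
        m.require("fndr")
        return m.s * m.fndr * m.beta / np.sqrt(m.n_used)
    raise ScoringError(f"per-gene decomposition is defined for strength/gpi, not {method!r}")
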
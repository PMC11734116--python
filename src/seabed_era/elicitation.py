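"""Conditional-probability-table generation from minimal expert input.

Eliciting a full CPT for a child with several multi-state parents requires an
infeasible number of judgments.  The interpolation approach implemented here
reduces the burden to two distributions plus a handful of weights: experts
supply a *best case* beta distribution (every parent at its most favorable
state), a *worst case* beta distribution (every parent at its least favorable
state), a weight per parent expressing its relative importance, and a score in
[0, 1] per parent state ordering that state along the best-to-worst axis.

For any parent configuration, a relevance index

    lambda = sum_i w_i * s_i(config) / sum_i w_i

positions the configuration between the elicited extremes; the child's beta
parameters are interpolated linearly in (alpha, beta) space and the resulting
distribution is discretized over the outcome bins with the regularized
incomplete beta function.  Linear (alpha, beta) interpolation makes the mean a
ratio of linear functions of lambda and hence monotone from the best-case mean
to the worst-case mean.

Also provided: method-of-moments fitting of beta distributions to empirical
samples of relative decrease, which is how field-survey data enter as the
best-case distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .bn import Cpt, DegenerateWeightsError

logger = logging.getLogger(__name__)


class CannotFitError(Exception):
    """Sample moments incompatible with a beta distribution."""


@dataclass(frozen=True)
class BetaSpec:
    """Shape parameters of a beta distribution on [0, 1]."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("beta parameters must be finite")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta parameters must be strictly positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class BinScheme:
    """Ordered bin edges on [0, 1] for discretizing a decrease fraction.

    The default five 20-%-wide bins mirror the outcome states used for every
    abundance-decrease node (0-20, 21-40, 41-60, 61-80, 81-100 %).
    """

    edges: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

    def __post_init__(self):
        object.__setattr__(self, "edges", tuple(float(e) for e in self.edges))
        e = np.asarray(self.edges)
        if len(e) < 2 or e[0] != 0.0 or e[-1] != 1.0 or np.any(np.diff(e) <= 0):
            raise ValueError(
                "bin edges must be strictly increasing from exactly 0 to exactly 1"
            )

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def labels(self) -> tuple[str, ...]:
        out = []
        prev_pct = 0
        for lo, hi in zip(self.edges[:-1], self.edges[1:]):
            lo_pct = prev_pct
            hi_pct = int(round(hi * 100))
            out.append(f"{lo_pct}-{hi_pct}%")
            prev_pct = hi_pct + 1
        return tuple(out)

    def bin_index(self, x: float) -> int:
        """Bin containing ``x``; values on an edge go to the lower-impact bin."""
        e = self.edges
        if x <= e[1]:
            return 0
        for k in range(1, self.n_bins):
            if e[k] < x <= e[k + 1]:
                return k
        return self.n_bins - 1


DEFAULT_BINS = BinScheme()


@dataclass(frozen=True)
class ParentInfluence:
    """Weight and per-state scores of one parent in an elicitation spec.

    Scores place each parent state on the best (0) to worst (1) axis and must
    be nondecreasing over the ordinal state order, spanning [0, 1].
    """

    parent: str
    weight: float
    scores: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        if self.weight < 0:
            raise ValueError(f"influence of {self.parent!r}: weight must be >= 0")
        s = np.asarray(self.scores)
        if len(s) < 2:
            raise ValueError(f"influence of {self.parent!r}: need >=2 state scores")
        if np.any(np.diff(s) < 0):
            raise ValueError(f"influence of {self.parent!r}: scores must be nondecreasing")
        if s.min() != 0.0 or s.max() != 1.0:
            raise ValueError(f"influence of {self.parent!r}: scores must span [0, 1]")


@dataclass(frozen=True)
class ElicitationSpec:
    """Minimal expert input from which a full CPT is generated."""

    child: str
    best: BetaSpec
    worst: BetaSpec
    influences: tuple[ParentInfluence, ...]
    bins: BinScheme = field(default_factory=BinScheme)

    def __post_init__(self):
        object.__setattr__(self, "influences", tuple(self.influences))
        if not self.influences:
            raise ValueError(f"spec for {self.child!r}: needs at least one parent")
        if all(i.weight == 0 for i in self.influences):
            raise DegenerateWeightsError(
                f"spec for {self.child!r}: all parent weights are zero"
            )
        if self.worst.mean < self.best.mean:
            raise ValueError(
                f"spec for {self.child!r}: worst-case mean must be >= best-case mean"
            )

    @property
    def parents(self) -> tuple[str, ...]:
        return tuple(i.parent for i in self.influences)


def relevance_index(spec: ElicitationSpec, config: dict[str, int]) -> float:
    """Weight-averaged parent-state score in [0, 1] for one configuration.

    ``config`` maps parent name -> state index.  0 is the elicited best case,
    1 the worst case.
    """
    wsum = sum(i.weight for i in spec.influences)
    if wsum == 0:
        raise DegenerateWeightsError(f"spec for {spec.child!r}: all weights zero")
    num = sum(i.weight * i.scores[config[i.parent]] for i in spec.influences)
    return num / wsum


def interpolate_beta(best: BetaSpec, worst: BetaSpec, lam: float) -> BetaSpec:
    """Linear interpolation of the (alpha, beta) parameters between extremes."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return BetaSpec(
        alpha=(1.0 - lam) * best.alpha + lam * worst.alpha,
        beta=(1.0 - lam) * best.beta + lam * worst.beta,
    )


def beta_bin_probs(bs: BetaSpec, bins: BinScheme = DEFAULT_BINS) -> np.ndarray:
    """Bin masses of a beta distribution: differences of the regularized
    incomplete beta function at the bin edges."""
    cdf = stats.beta.cdf(np.asarray(bins.edges), bs.alpha, bs.beta)
    probs = np.diff(cdf)
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum()


def build_cpt_from_elicitation(spec: ElicitationSpec) -> Cpt:
    """Expand an elicitation spec into a full CPT.

    Each parent configuration's column is the binned interpolated beta; the
    all-best and all-worst configurations reproduce the elicited endpoint
    distributions exactly.
    """
    cards = [len(i.scores) for i in spec.influences]
    rows = []
    for combo in itertools.product(*(range(c) for c in cards)):
        config = {i.parent: k for i, k in zip(spec.influences, combo)}
        lam = relevance_index(spec, config)
        rows.append(beta_bin_probs(interpolate_beta(spec.best, spec.worst, lam), spec.bins))
    return Cpt(child=spec.child, parents=spec.parents, table=np.asarray(rows))


def fit_beta_moments(samples) -> BetaSpec:
    """Method-of-moments beta fit to samples on [0, 1].

    Values are clipped to [0.001, 0.999] before fitting (clipping is logged).
    Raises :class:`CannotFitError` when the sample variance is degenerate
    (zero, or at least m(1-m), which no beta distribution attains).
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size < 3:
        raise CannotFitError("need at least 3 samples")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("samples must lie in [0, 1]")
    clipped = np.clip(x, 0.001, 0.999)
    n_clipped = int(np.sum(clipped != x))
    if n_clipped:
        logger.info("fit_beta_moments: clipped %d sample(s) to [0.001, 0.999]", n_clipped)
    m = float(clipped.mean())
    v = float(clipped.var(ddof=1))
    if not 0.0 < v < m * (1.0 - m):
        raise CannotFitError(
            f"sample variance {v:.3g} outside (0, m(1-m)) = (0, {m * (1 - m):.3g}); "
            "use a point-mass column instead"
        )
    nu = m * (1.0 - m) / v - 1.0
    return BetaSpec(alpha=m * nu, beta=(1.0 - m) * nu)
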
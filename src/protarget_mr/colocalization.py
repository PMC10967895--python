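"""Bayesian colocalization of two traits over a shared variant set.

Per-SNP approximate Bayes factors are combined, entirely in log space, into
posterior probabilities of the five single-causal-variant hypotheses:

    H0  no association with either trait
    H1  association with trait 1 only
    H2  association with trait 2 only
    H3  association with both traits, distinct causal variants
    H4  association with both traits, one shared causal variant

Default priors p1 = p2 = 1e-4, p12 = 1e-5; colocalization is called when
PPH4 >= 0.8.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .sumstats import VariantAssociation

__all__ = [
    "ColocPriors",
    "ColocResult",
    "PRIOR_SD_QUANTITATIVE",
    "PRIOR_SD_CASE_CONTROL",
    "log_abf",
    "colocalize",
]

#: effect-size prior SD for quantitative traits (SD units)
PRIOR_SD_QUANTITATIVE = 0.15
#: effect-size prior SD for case-control traits (log-odds)
PRIOR_SD_CASE_CONTROL = 0.20

_PRIOR_SD = {"quant": PRIOR_SD_QUANTITATIVE, "cc": PRIOR_SD_CASE_CONTROL}


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities: trait-1 only, trait-2 only, both."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.p1 + self.p2 + self.p12 >= 1.0:
            raise ValueError("p1 + p2 + p12 must be < 1")


@dataclass(frozen=True)
class ColocResult:
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int

    def __post_init__(self) -> None:
        total = self.pph0 + self.pph1 + self.pph2 + self.pph3 + self.pph4
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {total}, not 1")

    @property
    def colocalized(self) -> bool:
        return self.pph4 >= 0.8

    def as_dict(self) -> dict[str, float]:
        return {
            "pph0": self.pph0, "pph1": self.pph1, "pph2": self.pph2,
            "pph3": self.pph3, "pph4": self.pph4,
        }


def log_abf(beta: float, se: float, w_prior_sd: float) -> float:
    """Log approximate Bayes factor for one SNP under a N(0, W) effect prior.

    With V = se^2, W = w_prior_sd^2, r = W/(V+W) and z = beta/se:
    log ABF = 0.5*log(1-r) + 0.5*z^2*r.
    """
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    if w_prior_sd < 0:
        raise ValueError("prior SD must be >= 0")
    v = se * se
    w = w_prior_sd * w_prior_sd
    r = w / (v + w)
    z = beta / se
    return 0.5 * math.log1p(-r) + 0.5 * z * z * r


def colocalize(
    trait1: Sequence[VariantAssociation],
    trait2: Sequence[VariantAssociation],
    priors: ColocPriors = ColocPriors(),
    trait_types: tuple[str, str] = ("quant", "cc"),
) -> ColocResult:
    """Posterior probabilities of H0-H4 over the variants shared by two traits.

    ``trait_types`` selects the per-trait ABF effect-size prior SD:
    ``"quant"`` -> 0.15, ``"cc"`` -> 0.20.
    """
    for t in trait_types:
        if t not in _PRIOR_SD:
            raise ValueError(f"unknown trait type {t!r}; expected 'quant' or 'cc'")
    by_id1 = {a.variant_id: a for a in trait1}
    shared = [a.variant_id for a in trait2 if a.variant_id in by_id1]
    if not shared:
        raise ValueError("no shared variants between the two traits")
    by_id2 = {a.variant_id: a for a in trait2}

    sd1, sd2 = _PRIOR_SD[trait_types[0]], _PRIOR_SD[trait_types[1]]
    l1 = np.array([log_abf(by_id1[v].beta, by_id1[v].se, sd1) for v in shared])
    l2 = np.array([log_abf(by_id2[v].beta, by_id2[v].se, sd2) for v in shared])

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)

    lp1, lp2, lp12 = math.log(priors.p1), math.log(priors.p2), math.log(priors.p12)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = lp1 + s1
    lh[2] = lp2 + s2
    # H3: sum over ordered pairs i != j = exp(s1+s2) - exp(s12); log-diff-exp
    both = s1 + s2
    diff = s12 - both
    if diff >= 0.0:
        if diff > 1e-9:
            warnings.warn("H3 term negative from cancellation; clamped to 0",
                          RuntimeWarning, stacklevel=2)
        lh[3] = -np.inf
    else:
        lh[3] = lp1 + lp2 + both + math.log1p(-math.exp(diff))
    lh[4] = lp12 + s12

    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()
    return ColocResult(
        pph0=float(post[0]), pph1=float(post[1]), pph2=float(post[2]),
        pph3=float(post[3]), pph4=float(post[4]), n_snps=len(shared),
    )
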
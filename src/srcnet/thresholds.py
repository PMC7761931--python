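"""Binomial significance thresholds for decoding accuracy.

The theoretical chance level 100/c % holds only for infinite samples; with n
subjects the 1-alpha quantile of the null accuracy distribution is obtained
from the inverse binomial CDF,

    St_alpha = binoinv(1 - alpha, n, 1/c) * 100 / n,

where binoinv(q, n, p) is the smallest k in [0, n] whose Binomial(n, p) CDF
reaches q. A cross-validated accuracy above St_alpha is unlikely (p < alpha)
under label-independent predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom


def binom_inv(q: float, n: int, p: float) -> int:
    """Smallest k in [0, n] with Binomial(n, p) CDF(k) >= q."""
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must be in [0, 1]")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    if q == 0.0:
        return 0  # CDF(0) = (1-p)^n >= 0 always
    if q == 1.0:
        return 0 if p == 0.0 else n  # only the full support reaches CDF = 1
    k = int(binom.ppf(q, n, p))
    k = max(0, min(k, n))
    # resolve float rounding at exact CDF ties (e.g. CDF = q precisely for
    # symmetric p = 1/2): step to the smallest k whose CDF reaches q
    tol = 1e-10
    while k > 0 and binom.cdf(k - 1, n, p) >= q - tol:
        k -= 1
    while k < n and binom.cdf(k, n, p) < q - tol:
        k += 1
    return k


def chance_level(c: int) -> float:
    """Theoretical chance accuracy (percent) for c equiprobable classes."""
    if c < 1:
        raise ValueError("c must be >= 1")
    return 100.0 / c


def significance_threshold(n: int, c: int, alpha: float) -> float:
    """Decoding-accuracy significance threshold in percent, rounded to 2 decimals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if c < 1:
        raise ValueError("c must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    k = binom_inv(1.0 - alpha, n, 1.0 / c)
    return round(k * 100.0 / n, 2)


@dataclass(frozen=True)
class ThresholdSpec:
    """A resolved significance threshold and the inputs that produced it."""

    n: int
    c: int
    alpha: float
    st_alpha: float

    @classmethod
    def compute(cls, n: int, c: int, alpha: float = 0.05) -> "ThresholdSpec":
        return cls(n=n, c=c, alpha=alpha, st_alpha=significance_threshold(n, c, alpha))
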
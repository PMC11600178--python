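"""Special-function helpers for the power-law spectrum closed forms.

scipy's incomplete gamma only covers positive shape parameters, while the
spectrum transform needs Γ(a, x) at negative non-integer ``a`` (the
generalized exponential-integral family E_ν).  The downward recurrence

    Γ(a, x) = (Γ(a+1, x) − x^a e^{−x}) / a

is numerically safe here because the subtraction only loses accuracy for
large ``x``, where the whole term is exponentially negligible against the
power-law part of the closed form; callers clip at ``x > _X_NEGLIGIBLE``.
"""

from __future__ import annotations

import numpy as np
from scipy import special

import mpmath as mp

#: beyond this argument e^{-x} terms are treated as exactly zero
_X_NEGLIGIBLE = 700.0


def upper_gamma(a: float, x: np.ndarray) -> np.ndarray:
    """Upper incomplete gamma Γ(a, x) for scalar real ``a`` (any sign,
    non-zero and non-negative-integer for a<=0), vectorized over ``x > 0``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("upper_gamma requires x > 0")
    if abs(a - round(a)) < 1e-9 and round(a) <= 0:
        # Γ(−n, x) = x^{−n} E_{n+1}(x): non-positive-integer shape
        n = int(round(-a))
        with np.errstate(under="ignore"):
            return x ** (-n) * special.expn(n + 1, x)
    k = 0
    aa = float(a)
    while aa <= 0.0:
        aa += 1.0
        k += 1
    out = special.gammaincc(aa, x) * special.gamma(aa)
    xs = np.minimum(x, _X_NEGLIGIBLE)
    for _ in range(k):
        aa -= 1.0
        with np.errstate(under="ignore"):
            out = (out - np.where(x > _X_NEGLIGIBLE, 0.0,
                                  xs ** aa * np.exp(-xs))) / aa
    return out


def hyp2f1(a: float, b: float, c: float, z: complex) -> complex:
    """Gauss hypergeometric ₂F₁ with full analytic continuation (mpmath)."""
    return complex(mp.hyp2f1(a, b, c, z))
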
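"""Censored maximum-likelihood Gumbel fitting and significance conversion.

Optimal local alignment scores of a query against randomized subjects follow,
to good approximation, a type-I extreme value (Gumbel) law with CDF

    F(x) = exp(-exp(-lambda * (x - mu)))

The low tail of a permutation null is the part most contaminated by
non-Gumbel behaviour, so the fit left-censors it: scores at or below a
censoring value c contribute only their count z through log F(c), while
scores above c contribute full log-density terms.  The fitted (lambda, mu)
convert to Karlin-Altschul-style constants through K = exp(lambda*mu)/(m*n),
so the expected number of alignments scoring >= x is

    E(x) = K * m * n * exp(-lambda * x) = exp(-lambda * (x - mu))

and the P-value is P = 1 - exp(-E(x)).

Numerics: with mu profiled out of the likelihood in closed form, the score
equation for lambda,

    g(lambda) = 1/lambda - mean(observed) + T1(lambda)/S0(lambda) = 0,

where S0 = sum(exp(-lambda*x_i)) + z*exp(-lambda*c) and T1 its x-weighted
analogue, is strictly decreasing, so Newton iteration with a maintained
bisection bracket converges to the unique root.  Scores are shifted by their
minimum before exponentiation to avoid under/overflow; the root and the
profiled mu are shift-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

_REL_TOL = 1e-6
_MAX_ITER = 200


class FitError(RuntimeError):
    """Raised for degenerate samples or non-convergence, with diagnostics."""


@dataclass(frozen=True)
class GumbelFit:
    """A fitted Gumbel null distribution for alignment scores."""

    lambda_: float
    mu: float
    K: float
    censor_value: float
    n_observed: int
    n_censored: int
    converged: bool
    iterations: int
    m: int
    n: int


@dataclass(frozen=True)
class Significance:
    """E-value (expected count of alignments scoring >= x) and its P-value."""

    evalue: float
    pvalue: float


def fit_censored_evd(
    scores,
    censor_value: Union[float, str] = "auto",
    m: int = 1,
    n: int = 1,
    min_observed: int = 50,
) -> GumbelFit:
    """Fit a left-censored Gumbel by maximum likelihood.

    Parameters
    ----------
    scores : array-like of int
        The permutation-null alignment scores.
    censor_value : float, "auto", or -inf
        Scores <= this value are censored (only counted).  ``"auto"`` uses
        the empirical 25th percentile; ``-inf`` (or ``None``) disables
        censoring and gives the ordinary uncensored ML fit.
    m, n : int
        Query and subject lengths, used only to derive K from (lambda, mu).
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("scores must be a nonempty 1-D array")
    if censor_value is None:
        c = -math.inf
    elif censor_value == "auto":
        c = float(np.percentile(x, 25.0))
    else:
        c = float(censor_value)

    observed = x[x > c]
    z = int(x.size - observed.size)
    if observed.size < max(2, min_observed):
        raise FitError(
            f"only {observed.size} scores above censor value {c} "
            f"(minimum {max(2, min_observed)}); cannot fit"
        )
    if np.ptp(observed) == 0:
        raise FitError(
            f"degenerate sample: all {observed.size} observed scores equal "
            f"{observed[0]:g}"
        )

    # Shift so exponentials are bounded; everything below is shift-invariant.
    shift = float(observed.min() if not math.isfinite(c) else min(observed.min(), c))
    y = observed - shift
    yc = c - shift if math.isfinite(c) else None
    ybar = float(y.mean())
    n_obs = observed.size

    def parts(lam: float):
        w = np.exp(-lam * y)
        s0 = float(w.sum())
        t1 = float((y * w).sum())
        t2 = float((y * y * w).sum())
        if yc is not None and z > 0:
            wc = z * math.exp(-lam * yc)
            s0 += wc
            t1 += yc * wc
            t2 += yc * yc * wc
        return s0, t1, t2

    def g_and_gprime(lam: float):
        s0, t1, t2 = parts(lam)
        r1 = t1 / s0
        g = 1.0 / lam - ybar + r1
        gp = -1.0 / (lam * lam) - (t2 / s0 - r1 * r1)
        return g, gp

    # Moment start: sd of a Gumbel is pi / (lambda * sqrt(6)).
    sd = float(observed.std(ddof=1))
    lam = math.pi / (math.sqrt(6.0) * sd)

    # g is strictly decreasing: expand a sign-changing bracket around lam.
    lo, hi = lam, lam
    g0, _ = g_and_gprime(lam)
    if g0 > 0:
        while True:
            hi *= 2.0
            if g_and_gprime(hi)[0] <= 0 or hi > 1e6:
                break
        if g_and_gprime(hi)[0] > 0:
            raise FitError("no root for lambda: sample may not be Gumbel-like")
    else:
        while True:
            lo /= 2.0
            if g_and_gprime(lo)[0] >= 0 or lo < 1e-12:
                break
        if g_and_gprime(lo)[0] < 0:
            raise FitError("no root for lambda: sample may not be Gumbel-like")

    converged = False
    iterations = 0
    for iterations in range(1, _MAX_ITER + 1):
        g, gp = g_and_gprime(lam)
        if g > 0:
            lo = max(lo, lam)
        else:
            hi = min(hi, lam)
        step = -g / gp if gp != 0 else 0.0
        new = lam + step
        if not (lo < new < hi):  # Newton left the bracket: bisect
            new = 0.5 * (lo + hi)
        if abs(new - lam) <= _REL_TOL * lam:
            lam = new
            converged = True
            break
        lam = new
    if not converged:
        raise FitError(
            f"lambda did not converge in {_MAX_ITER} iterations "
            f"(last lambda={lam:.6g}, bracket=[{lo:.6g}, {hi:.6g}])"
        )

    s0, _, _ = parts(lam)
    mu = shift + math.log(n_obs / s0) / lam
    K = math.exp(lam * mu) / (m * n)
    return GumbelFit(
        lambda_=lam,
        mu=mu,
        K=K,
        censor_value=c,
        n_observed=n_obs,
        n_censored=z,
        converged=True,
        iterations=iterations,
        m=m,
        n=n,
    )


def evalue(x: float, fit: GumbelFit, m: int | None = None, n: int | None = None) -> float:
    """E(x) = K*m*n*exp(-lambda*x), computed as exp(-lambda*(x-mu)) for stability."""
    m = fit.m if m is None else m
    n = fit.n if n is None else n
    # K absorbs fit.m*fit.n; rescale if the caller supplies other lengths.
    log_e = -fit.lambda_ * (x - fit.mu) + math.log(m * n) - math.log(fit.m * fit.n)
    return math.exp(log_e) if log_e < 700 else math.inf


def pvalue(x: float, fit: GumbelFit, m: int | None = None, n: int | None = None) -> Significance:
    """Significance of score x under the fitted null: P = 1 - exp(-E(x))."""
    if not fit.converged:
        raise FitError("fit did not converge; refusing to compute significance")
    e = evalue(x, fit, m, n)
    p = -math.expm1(-e) if math.isfinite(e) else 1.0
    return Significance(evalue=e, pvalue=p)
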
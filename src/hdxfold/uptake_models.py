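"""Exchange-curve models: stretched-exponential and multi-exponential fits.

Two complementary descriptions of a normalized uptake curve are provided.

*Stretched exponential*, ``D(t) = A * (1 - exp(-(k t)^beta))`` — a robust
two-parameter-shape summary whose characteristic rate ``k`` supports
peptide-level free-energy comparisons between states:
``ddG = R T ln(k_a / k_b)``.  This is a deliberately rough estimator; only
the rate ratio is interpreted.

*Sum of exponentials*, ``D(t) = sum_i a_i * (1 - exp(-k_i t))`` — used to ask
how many kinetically distinct residue classes a peptide contains.  The number
of exponentials ``n`` is chosen by fit quality: the largest ``n`` whose fit
converges with every relative rate error ``sd(k_i)/k_i < 1`` and whose
chi-squared improves materially over the ``n - 1`` fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import R_KCAL, T_REF
from .normalize import UptakeCurve

__all__ = [
    "StretchedExpFit",
    "MultiExpFit",
    "eligible_for_fitting",
    "fit_stretched",
    "ddg_between_states",
    "fit_multiexp",
    "fit_multiexp_n",
]

#: Allowed rate window, s^-1.
RATE_BOUNDS = (1e-8, 1e3)
#: Replicate-noise floor used when a point has no replicate SD, Da.
SIGMA_FLOOR = 0.06
#: Default RNG seed for multi-start initialization.
DEFAULT_FIT_SEED = 20230606
#: A fit whose chi-squared is already below this is numerically perfect;
#: adding components to it cannot be justified.
CHISQ_FLOOR = 1e-6
#: Smallest amplitude (Da) a kinetic class may carry: every accepted
#: exponential must represent at least about half an exchange-competent
#: residue, which keeps noise blips from being fit as extra rate classes.
MIN_AMPLITUDE = 0.4


@dataclass
class StretchedExpFit:
    """Stretched-exponential summary of one uptake curve."""

    peptide_name: str
    state: str
    k: float  # characteristic rate, s^-1
    beta: float  # stretching exponent in (0, 1]
    amplitude: float  # Da
    residual: float  # root-mean-square residual, Da
    converged: bool
    mean_k_chem: float | None = None  # peptide-mean intrinsic rate, s^-1

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.amplitude * (1.0 - np.exp(-np.power(self.k * t, self.beta)))


@dataclass
class MultiExpFit:
    """Sum-of-exponentials fit with the accepted number of components."""

    peptide_name: str
    state: str
    n: int
    rates: np.ndarray  # s^-1, sorted descending
    rate_sd: np.ndarray
    amplitudes: np.ndarray  # Da, same order as rates
    chisq: float
    converged: bool
    fallback: bool = False  # True when no n satisfied the criteria and n=1 was forced
    selection_log: list = field(default_factory=list)

    @property
    def relative_errors(self) -> np.ndarray:
        return self.rate_sd / self.rates

    def __call__(self, t):
        t = np.asarray(t, dtype=float)[..., None]
        return np.sum(self.amplitudes * (1.0 - np.exp(-self.rates * t)), axis=-1)


def eligible_for_fitting(
    curve: UptakeCurve,
    min_fraction: float = 0.10,
    min_long_time: float = 1e4,
) -> bool:
    """Exclude peptides that barely exchange over the sampled window.

    A curve qualifies only if it reaches at least ``min_fraction`` of its
    exchange-competent residue count at its longest labeling time (boundary
    inclusive), and that longest time is at least ``min_long_time`` seconds;
    slower peptides carry no usable rate information.
    """
    if curve.times.size == 0 or curve.times[-1] < min_long_time:
        return False
    frac = curve.uptake[-1] / curve.n_exchangeable
    return bool(frac >= min_fraction - 1e-12)


def _sigma(curve: UptakeCurve) -> np.ndarray:
    """Per-point chi-squared denominator: the curve's pooled replicate SD.

    Per-timepoint SDs from a handful of replicates are individually too noisy
    to weight with, so the root-mean-square SD over the curve's replicated
    points is used for every point; the repeatability floor applies only when
    no point is replicated.
    """
    sd = np.asarray(curve.sd, dtype=float)
    replicated = sd[sd > 0]
    pooled = float(np.sqrt(np.mean(replicated**2))) if replicated.size else SIGMA_FLOOR
    return np.full(sd.shape, pooled)


def fit_stretched(curve: UptakeCurve, seed: int = DEFAULT_FIT_SEED) -> StretchedExpFit:
    """Fit ``A (1 - exp(-(k t)^beta))`` by weighted least squares."""
    t = curve.times
    y = curve.uptake
    sigma = _sigma(curve)
    n_ex = curve.n_exchangeable

    def resid(x):
        logk, beta, amp = x
        model = amp * (1.0 - np.exp(-np.power(10.0**logk * t, beta)))
        return (model - y) / sigma

    rng = np.random.default_rng(seed)
    amp0 = min(max(y.max(), 0.2), n_ex)
    best = None
    logt_mid = np.log10(t).mean()
    for logk0 in (-logt_mid, -logt_mid + 1.5, -logt_mid - 1.5, *(
        -logt_mid + rng.uniform(-2, 2, 2)
    )):
        try:
            res = least_squares(
                resid,
                x0=[float(np.clip(logk0, -8, 3)), 0.8, amp0],
                bounds=([-8, 0.05, 1e-3], [3, 1.0, n_ex]),
                method="trf",
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return StretchedExpFit(curve.peptide.name, curve.state, math.nan, math.nan,
                               math.nan, math.inf, converged=False)
    logk, beta, amp = best.x
    model = amp * (1.0 - np.exp(-np.power(10.0**logk * t, beta)))
    rms = float(np.sqrt(np.mean((model - y) ** 2)))
    return StretchedExpFit(
        peptide_name=curve.peptide.name,
        state=curve.state,
        k=float(10.0**logk),
        beta=float(beta),
        amplitude=float(amp),
        residual=rms,
        converged=bool(best.success),
    )


def ddg_between_states(
    fit_a: StretchedExpFit, fit_b: StretchedExpFit, temperature: float = T_REF
) -> float:
    """Free-energy-of-unfolding difference from a rate ratio, kcal/mol.

    ``R T ln(k_a / k_b)``: positive when state *b* exchanges slower (is more
    stable) than state *a*.  Antisymmetric by construction.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("ddG requires two converged stretched-exponential fits")
    if fit_a.peptide_name != fit_b.peptide_name:
        raise ValueError("ddG compares the same peptide across states")
    return R_KCAL * temperature * math.log(fit_a.k / fit_b.k)


def _fit_candidate(t, y, sigma, n, n_ex, starts, min_amplitude=0.0, plateau_sigma=None):
    """Best weighted least-squares fit with n components over given starts.

    When ``plateau_sigma`` is given, a pseudo-observation anchors the total
    amplitude at ``n_ex``: for back-exchange-corrected curves the
    maximally-labeled control pins the saturation plateau to the
    exchange-competent residue count, which removes the rate/amplitude
    degeneracy of poorly sampled slow components.
    """
    lo = [math.log10(RATE_BOUNDS[0])] * n + [min_amplitude] * n
    hi = [math.log10(RATE_BOUNDS[1])] * n + [float(n_ex)] * n

    def resid(x):
        logk = np.asarray(x[:n])
        amps = np.asarray(x[n:])
        model = np.sum(amps * (1.0 - np.exp(-(10.0**logk) * t[:, None])), axis=1)
        out = (model - y) / sigma
        if plateau_sigma is not None:
            out = np.append(out, (np.sum(amps) - n_ex) / plateau_sigma)
        return out

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(resid, x0=x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_multiexp_n(
    curve: UptakeCurve,
    n: int,
    seed: int = DEFAULT_FIT_SEED,
    prev: MultiExpFit | None = None,
    n_random_starts: int = 5,
    min_amplitude: float = MIN_AMPLITUDE,
) -> MultiExpFit:
    """Fit exactly ``n`` exponentials (with free non-negative amplitudes).

    Initialization is multi-start: rates log-spaced across the sampled time
    window, seeded random jitters, and — when ``prev`` (the best fit with
    ``n - 1`` components) is supplied — a nested start that reproduces it
    with a vanishing extra component, which guarantees the chi-squared of the
    returned fit does not exceed that of ``prev``.
    """
    t = curve.times
    y = curve.uptake
    sigma = _sigma(curve)
    n_ex = curve.n_exchangeable
    if len(t) < 2 * n:
        raise ValueError(f"need >= {2 * n} timepoints for {n} exponentials")

    rng = np.random.default_rng(seed)
    lo_logk = -math.log10(t[-1] * 5)
    hi_logk = -math.log10(max(t[0] / 5, 1e-3))
    base_logk = (
        np.linspace(hi_logk, lo_logk, n) if n > 1 else np.array([(lo_logk + hi_logk) / 2])
    )
    amp0 = max(y.max() / n, min_amplitude, 0.05)
    starts = [np.concatenate([base_logk, np.full(n, amp0)])]
    for _ in range(n_random_starts):
        starts.append(
            np.concatenate([base_logk + rng.uniform(-1.0, 1.0, n), np.full(n, amp0)])
        )
    if prev is not None and prev.n == n - 1:
        # nested starts: reproduce the (n-1)-fit with a vanishing extra
        # component placed mid-window, below the slowest, or above the fastest
        prev_logk = np.log10(prev.rates)
        for extra_logk in ((lo_logk + hi_logk) / 2, prev_logk[-1] - 1.5, prev_logk[0] + 1.5):
            starts.append(
                np.concatenate([prev_logk, [extra_logk], prev.amplitudes, [min_amplitude]])
            )

    plateau_sigma = float(sigma[0]) if curve.back_exchange_applied else None
    best = _fit_candidate(
        t, y, sigma, n, n_ex, starts, min_amplitude=min_amplitude,
        plateau_sigma=plateau_sigma,
    )
    if best is None:
        return MultiExpFit(curve.peptide.name, curve.state, n, np.full(n, np.nan),
                           np.full(n, np.nan), np.full(n, np.nan), math.inf, False)

    logk = np.asarray(best.x[:n])
    amps = np.asarray(best.x[n:])
    order = np.argsort(-logk)
    logk, amps = logk[order], amps[order]
    chisq = float(2.0 * best.cost)

    # rate SDs from the scaled approximate covariance of the solution
    m, p = len(t) + (plateau_sigma is not None), 2 * n
    sd_logk = np.full(n, np.inf)
    if m > p:
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.inv(jtj) * (chisq / (m - p))
            sd_logk = np.sqrt(np.abs(np.diag(cov)[:n]))[order]
        except np.linalg.LinAlgError:
            pass
    rates = 10.0**logk
    rate_sd = rates * math.log(10.0) * sd_logk

    return MultiExpFit(
        peptide_name=curve.peptide.name,
        state=curve.state,
        n=n,
        rates=rates,
        rate_sd=rate_sd,
        amplitudes=amps,
        chisq=chisq,
        converged=bool(best.success),
    )


def fit_multiexp(
    curve: UptakeCurve,
    max_n: int | None = None,
    seed: int = DEFAULT_FIT_SEED,
    min_improvement: float = 0.05,
) -> MultiExpFit:
    """Fit a sum of exponentials, selecting ``n`` by fit quality.

    Starting from ``n = 1``, a larger model is accepted only while it
    converges, keeps every relative rate error below one, and lowers
    chi-squared by at least ``min_improvement`` (relative) — the elbow rule.
    Ties break toward smaller ``n``.  If even ``n = 1`` fails the relative
    error screen the single-exponential fit is returned flagged as a
    fallback.
    """
    if max_n is None:
        max_n = curve.n_exchangeable
    max_n = min(max_n, curve.n_exchangeable, len(curve.times) // 2)
    log: list[str] = []

    best: MultiExpFit | None = None
    for n in range(1, max_n + 1):
        fit = fit_multiexp_n(curve, n, seed=seed, prev=best)
        ok_err = bool(np.all(fit.relative_errors < 1.0))
        if best is None:
            log.append(f"n=1 chisq={fit.chisq:.4g} relerr_ok={ok_err}")
            if not (fit.converged and ok_err):
                fit.fallback = True
                fit.selection_log = log + ["no n satisfied the criteria; fallback n=1"]
                return fit
            best = fit
            continue
        improved = (
            best.chisq > CHISQ_FLOOR
            and fit.chisq <= (1.0 - min_improvement) * best.chisq
        )
        log.append(
            f"n={n} chisq={fit.chisq:.4g} relerr_ok={ok_err} improved={improved}"
        )
        if fit.converged and ok_err and improved:
            best = fit
        else:
            break
    assert best is not None
    best.selection_log = log
    return best
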
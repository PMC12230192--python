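"""Power-law (Lévy) fitting of step-length distributions.

The continuous power law has density

    p(x) = (mu - 1) / xmin * (x / xmin) ** (-mu),   x >= xmin,  mu > 1,

with scaling exponent ``mu`` and lower cutoff ``xmin``. Given the
cutoff, the maximum-likelihood estimate is the Hill estimator

    mu_hat = 1 + n / sum(ln(x_i / xmin)),

over the ``n`` tail values ``x_i >= xmin``. When the cutoff is free it
is selected by scanning the observed values and minimising the
Kolmogorov-Smirnov distance between the tail's empirical CDF and the
fitted power law — the standard empirical procedure for heavy-tailed
data. Step lengths are continuous distances, so the continuous (not
discrete) variant is used throughout.

Exponents in the range 1 < mu < 3 mark Lévy-flight movement (many
short steps, occasional long displacements); values near 3 approach
Brownian-like diffusion. ``classify_movement`` operationalises that
with configurable thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .movement_metrics import StepSeries
from .trajectory_io import SEASONS

__all__ = [
    "PowerLawFit",
    "fit_power_law",
    "classify_movement",
    "seasonal_fits",
]

log = logging.getLogger(__name__)

#: mu above which movement is reported as Brownian-like rather than Levy.
LEVY_MAX = 2.75
#: mu above which the fit is outside the interpretable range.
BROWNIAN_MAX = 3.25


@dataclass
class PowerLawFit:
    """MLE power-law fit of a step-length tail."""

    mu: float
    xmin: float
    n_tail: int
    ks_D: float
    loglik: float
    #: (length, empirical CCDF) pairs of the tail, for log-log plots.
    ccdf_points: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {"mu": self.mu, "xmin": self.xmin, "n_tail": self.n_tail,
                "ks_D": self.ks_D, "loglik": self.loglik}


def _hill_mu(tail: np.ndarray, xmin: float) -> float:
    return 1.0 + len(tail) / float(np.sum(np.log(tail / xmin)))


def _ks_distance(tail_sorted: np.ndarray, xmin: float, mu: float) -> float:
    n = len(tail_sorted)
    fit_cdf = 1.0 - (tail_sorted / xmin) ** (1.0 - mu)
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(emp_hi - fit_cdf)),
                     np.max(np.abs(emp_lo - fit_cdf))))


def fit_power_law(lengths, xmin: float | None = None,
                  min_tail: int = 10) -> PowerLawFit:
    """Fit a continuous power law to positive step lengths.

    With ``xmin`` given, the Hill MLE is computed over the tail
    ``x >= xmin``. With ``xmin=None`` the cutoff is chosen by the KS
    scan over observed values (candidates whose tail has at least
    ``min_tail`` points; ties broken toward the smaller cutoff).
    """
    x = np.asarray(lengths, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < min_tail:
        raise ValueError(f"need at least {min_tail} positive lengths, "
                         f"got {len(x)}")

    if xmin is not None:
        if xmin <= 0:
            raise ValueError("xmin must be positive")
        tail = np.sort(x[x >= xmin])
        if len(tail) < 2:
            raise ValueError("fewer than 2 tail points above xmin")
        if np.sum(np.log(tail / xmin)) <= 0:
            # all tail values sit at the cutoff: exponent undefined
            raise ValueError("tail has no spread above xmin; "
                             "exponent undefined")
        mu = _hill_mu(tail, xmin)
        return _finalize(tail, xmin, mu)

    if np.all(x == x[0]):
        raise ValueError("all step lengths equal; exponent undefined")

    candidates = np.unique(x)
    best: tuple[float, float, float] | None = None  # (D, xmin, mu)
    for cand in candidates:
        tail = x[x >= cand]
        if len(tail) < min_tail:
            break  # candidates are increasing; tails only shrink
        if np.all(tail == tail[0]):
            continue
        tail = np.sort(tail)
        mu = _hill_mu(tail, cand)
        D = _ks_distance(tail, cand, mu)
        if best is None or D < best[0]:
            best = (D, cand, mu)
    if best is None:
        raise ValueError("no candidate cutoff leaves a usable tail")
    _, xmin_hat, mu_hat = best
    tail = np.sort(x[x >= xmin_hat])
    return _finalize(tail, xmin_hat, mu_hat)


def _finalize(tail_sorted: np.ndarray, xmin: float, mu: float) -> PowerLawFit:
    n = len(tail_sorted)
    loglik = float(n * np.log((mu - 1.0) / xmin)
                   - mu * np.sum(np.log(tail_sorted / xmin)))
    D = _ks_distance(tail_sorted, xmin, mu)
    ccdf = np.column_stack([tail_sorted, 1.0 - np.arange(n) / n])
    return PowerLawFit(mu=float(mu), xmin=float(xmin), n_tail=n,
                       ks_D=D, loglik=loglik, ccdf_points=ccdf)


def classify_movement(fit: PowerLawFit, levy_max: float = LEVY_MAX,
                      brownian_max: float = BROWNIAN_MAX) -> str:
    """Classify a fitted exponent as ``levy``, ``near_brownian`` or
    ``out_of_range``."""
    if 1.0 < fit.mu <= levy_max:
        return "levy"
    if levy_max < fit.mu <= brownian_max:
        return "near_brownian"
    return "out_of_range"


def seasonal_fits(steps: StepSeries, xmin: float | None = None,
                  min_tail: int = 10) -> dict[str, PowerLawFit]:
    """Fit the power law per season with the same cutoff policy as the
    overall fit; seasons without a usable tail are skipped (warned)."""
    out: dict[str, PowerLawFit] = {}
    df = steps.steps
    for season in SEASONS:
        lengths = df.loc[df["season"] == season, "length_m"].to_numpy()
        lengths = lengths[lengths > 0]
        if len(lengths) < min_tail:
            log.warning("season %s: only %d positive steps, skipped",
                        season, len(lengths))
            continue
        try:
            out[season] = fit_power_law(lengths, xmin=xmin, min_tail=min_tail)
        except ValueError as exc:
            log.warning("season %s: fit failed (%s), skipped", season, exc)
    return out
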
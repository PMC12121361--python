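"""Biomarker positivity labeling via a two-component normal mixture.

Continuous biomarker levels (GFAP, NfL, pTau181, and the reciprocal
amyloid ratio so that higher always means riskier) are modeled as a
mixture of a "negative" and a "positive" normal component fitted by EM.
The positivity threshold is the point between the two component means
where the weighted component densities are equal (posterior probability
0.5); values strictly above it are labeled positive.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CutoffModel:
    """Fitted two-component mixture and the derived positivity threshold."""

    pi: float  # weight of the lower-mean component
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    threshold: float
    log_likelihood: float
    ll_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.mu1 < self.mu2:
            raise ValueError("component means must satisfy mu1 < mu2")
        if not (self.mu1 <= self.threshold <= self.mu2):
            raise ValueError("threshold must lie between the component means")

    def as_dict(self) -> dict[str, float]:
        return {
            "pi": self.pi,
            "mu1": self.mu1,
            "mu2": self.mu2,
            "sigma1": self.sigma1,
            "sigma2": self.sigma2,
            "threshold": self.threshold,
            "log_likelihood": self.log_likelihood,
        }


def equal_density_threshold(
    pi: float, mu1: float, sigma1: float, mu2: float, sigma2: float
) -> float:
    """Closed-form point in [mu1, mu2] where the weighted densities cross.

    Solving pi N(t; mu1, s1) = (1-pi) N(t; mu2, s2) in log form yields a
    quadratic in t; the root between the means is returned (for equal
    variances the equation is linear).
    """
    a = 0.5 / sigma2**2 - 0.5 / sigma1**2
    b = mu1 / sigma1**2 - mu2 / sigma2**2
    c = (
        0.5 * mu2**2 / sigma2**2
        - 0.5 * mu1**2 / sigma1**2
        - np.log(((1.0 - pi) * sigma1) / (pi * sigma2))
    )
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            return 0.5 * (mu1 + mu2)
        roots = np.array([-c / b])
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            return 0.5 * (mu1 + mu2)
        roots = (-b + np.array([-1.0, 1.0]) * np.sqrt(disc)) / (2.0 * a)
    inside = roots[(roots >= mu1) & (roots <= mu2)]
    if inside.size:
        return float(inside[np.argmin(np.abs(inside - 0.5 * (mu1 + mu2)))])
    return float(np.clip(roots[np.argmin(np.abs(roots - 0.5 * (mu1 + mu2)))], mu1, mu2))


def _em_once(
    x: np.ndarray, pi: float, mu: np.ndarray, sigma: np.ndarray, max_iter: int, tol: float
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    weights = np.array([pi, 1.0 - pi])
    trace: list[float] = []
    for _ in range(max_iter):
        dens = weights[None, :] * stats.norm.pdf(x[:, None], mu[None, :], sigma[None, :])
        total = dens.sum(axis=1)
        total = np.clip(total, 1e-300, None)
        trace.append(float(np.log(total).sum()))
        resp = dens / total[:, None]
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise FloatingPointError("component collapsed (empty responsibility)")
        weights = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(var)
        if np.any(sigma < 1e-8 * max(1.0, float(np.std(x)))):
            raise FloatingPointError("component variance collapsed")
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * max(1.0, abs(trace[-2])):
            break
    return float(weights[0]), mu, sigma, np.asarray(trace)


def fit_mixture_cutoff(
    values: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-10,
    seed: int = 0,
) -> CutoffModel:
    """EM fit of a two-normal mixture plus the equal-density threshold.

    Components are initialized from the lower and upper terciles of the
    sorted sample, which makes the fit deterministic; degenerate runs
    (a collapsing component) are restarted with seeded jitter up to three
    times before giving up.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 values to fit a mixture cutoff")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    xs = np.sort(x)
    third = max(2, x.size // 3)
    lo, hi = xs[:third], xs[-third:]
    mu = np.array([lo.mean(), hi.mean()])
    sigma = np.array([max(lo.std(), 1e-3), max(hi.std(), 1e-3)])
    pi = 0.5
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(4):
        try:
            pi_f, mu_f, sigma_f, trace = _em_once(x, pi, mu, sigma, max_iter, tol)
            break
        except FloatingPointError as err:
            last_err = err
            scale = float(np.std(x)) or 1.0
            mu = mu + rng.normal(0.0, 0.1 * scale, size=2)
            sigma = np.maximum(sigma * (1.0 + rng.uniform(0.1, 0.5, size=2)), 1e-2 * scale)
            pi = float(np.clip(0.5 + rng.normal(0, 0.1), 0.05, 0.95))
    else:
        raise RuntimeError(f"EM failed after 3 jittered restarts: {last_err}")
    order = np.argsort(mu_f)
    mu_f, sigma_f = mu_f[order], sigma_f[order]
    if order[0] == 1:
        pi_f = 1.0 - pi_f
    thr = equal_density_threshold(pi_f, mu_f[0], sigma_f[0], mu_f[1], sigma_f[1])
    return CutoffModel(
        pi=pi_f,
        mu1=float(mu_f[0]),
        mu2=float(mu_f[1]),
        sigma1=float(sigma_f[0]),
        sigma2=float(sigma_f[1]),
        threshold=thr,
        log_likelihood=float(trace[-1]),
        ll_trace=trace,
    )


def assign_positivity(
    values: np.ndarray, model: CutoffModel, higher_is_risk: bool = True
) -> np.ndarray:
    """Binary labels: 1 iff value strictly exceeds the fitted threshold.

    ``higher_is_risk`` should be True for all four biomarkers once the
    amyloid ratio has been transformed to its reciprocal upstream (see
    :func:`reciprocal`); with ``higher_is_risk`` False the comparison is
    mirrored (strictly below threshold is positive).
    """
    v = np.asarray(values, dtype=float)
    if higher_is_risk:
        return (v > model.threshold).astype(int)
    return (v < model.threshold).astype(int)


def reciprocal(values: np.ndarray) -> np.ndarray:
    """Map the amyloid Abeta42/40 ratio to Abeta40/42 (1/v, requires v > 0).

    Lower Abeta42/40 signals higher risk; the reciprocal keeps the
    "higher = riskier" orientation shared by the other biomarkers.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        bad = int(np.argmax(v <= 0))
        raise ValueError(f"nonpositive ratio at position {bad}; reciprocal undefined")
    return 1.0 / v


def positivity_rate(labels: np.ndarray) -> float:
    """Percentage of positive labels, e.g. 192 of 906 -> 21.2 (one decimal
    is the conventional reporting precision; the exact value is returned)."""
    arr = np.asarray(labels)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return 100.0 * float(arr.mean())
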
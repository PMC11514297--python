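"""Compressed-sensing reconstruction by iterative soft thresholding (IST).

The missing-quadrant (Echo/Anti-Echo) and missing-row (NUS) problems are
both *data completion* problems in the Virtual Echo time domain: part of the
complex VE array is measured, the rest is unknown, and among all consistent
completions IST seeks the one whose real spectrum is sparsest.  Each
iteration replaces the known VE samples with the measured values, transforms
to the frequency domain, and soft-thresholds the real spectrum with a
geometrically decreasing threshold.

Also provides a Poisson-gap schedule generator for non-uniform sampling:
gap lengths are Poisson-distributed with a sinusoidally modulated mean so
early increments (large signal) are sampled densely and late ones sparsely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .hypercomplex import (from_virtual_echo, quadrant_weights,
                           to_virtual_echo, validate_schedule)

__all__ = [
    "ISTConfig",
    "CompletionProblem",
    "poisson_gap",
    "soft_threshold",
    "ist_complete",
    "cs_echo",
    "cs_nus",
    "ISTReconstructor",
]


def poisson_gap(n_increments: int, fraction: float, seed: int = 0) -> np.ndarray:
    """Poisson-gap NUS schedule with exactly ``round(fraction * n)`` points.

    Gaps after each sampled index are drawn from a Poisson law whose mean is
    modulated by ``sin(pi/2 * position)``, front-loading the schedule.  The
    rate is tuned by bisection (re-drawing with the same seed) until the
    target count is hit exactly; index 0 is always included.
    """
    if n_increments < 1:
        raise ValueError("n_increments must be >= 1")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    target = int(round(fraction * n_increments))
    target = max(target, 1)
    if target >= n_increments:
        return np.arange(n_increments)

    def draw(rate: float, rng_seed: int) -> np.ndarray:
        rng = np.random.default_rng(rng_seed)
        picks = []
        i = 0
        while i < n_increments:
            picks.append(i)
            lam = rate * np.sin(0.5 * np.pi * (i + 0.5) / n_increments)
            i += 1 + rng.poisson(lam)
        return np.asarray(picks)

    for attempt in range(32):
        sub_seed = int(np.random.SeedSequence((seed, attempt))
                       .generate_state(1)[0] & 0x7FFFFFFF)
        lo, hi = 0.0, 4.0 * n_increments / target
        # larger rate -> larger gaps -> fewer picks: count is non-increasing
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            count = draw(mid, sub_seed).size
            if count == target:
                return draw(mid, sub_seed)
            if count > target:
                lo = mid
            else:
                hi = mid
    raise RuntimeError("poisson_gap: bisection failed to hit the target count")


@dataclass(frozen=True)
class ISTConfig:
    """IST solver settings.

    ``threshold_start`` is the initial soft threshold as a fraction of the
    starting spectrum's maximum; the schedule decays geometrically down to a
    noise-floor estimate (``noise_floor_factor`` times the median absolute
    spectral value) at the final iteration.  ``enforce_consistency`` projects
    the final estimate back onto the measured data.
    """

    n_iterations: int = 200
    threshold_start: float = 0.9
    noise_floor_factor: float = 5.0
    enforce_consistency: bool = True
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 < self.threshold_start <= 1.0):
            raise ValueError("threshold_start must be in (0, 1]")


@dataclass
class CompletionProblem:
    """Known VE data plus the weight mask of the known support.

    ``known`` must vanish where ``weights`` is zero; weights are in [0, 1]
    (1/2 on quadrant-boundary lines for echo-type problems).
    """

    known: np.ndarray
    weights: np.ndarray
    flavor: str = "echo"

    def __post_init__(self) -> None:
        self.known = np.asarray(self.known, dtype=np.complex128)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.known.shape != self.weights.shape:
            raise ValueError("known data and weight mask shapes differ")
        scale = np.abs(self.known).max()
        if scale > 0 and np.abs(self.known[self.weights == 0]).size:
            if np.abs(self.known * (self.weights == 0)).max() > 1e-12 * scale:
                raise ValueError("known data must vanish outside the mask")


def soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    """Sign-preserving soft threshold of a real array."""
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def ist_complete(problem: CompletionProblem,
                 config: ISTConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """IST completion of a VE data-completion problem.

    Iterates ``x <- SoftThreshold(FT[known + (1 - w) * iFT[x]])`` with a
    geometrically decreasing threshold, optionally followed by an exact
    data-consistency projection.  Returns ``(spectrum, residual_history)``
    where the history holds the per-iteration data residual
    ``max |w * iFT[x] - known|`` (reported, never raised on).
    """
    cfg = config or ISTConfig()
    known, w = problem.known, problem.weights
    x = from_virtual_echo(known)  # starting spectrum = FT of measured data
    scale = np.abs(x).max()
    if scale == 0:
        return np.zeros_like(x), np.zeros(cfg.n_iterations)

    lam0 = cfg.threshold_start * scale
    floor = cfg.noise_floor_factor * np.median(np.abs(x))
    lam_final = max(floor, 1e-8 * scale)
    lam_final = min(lam_final, lam0)
    if cfg.n_iterations > 1:
        ratio = (lam_final / lam0) ** (1.0 / (cfg.n_iterations - 1))
    else:
        ratio = 1.0

    history = np.empty(cfg.n_iterations)
    lam = lam0
    for j in range(cfg.n_iterations):
        ve = known + (1.0 - w) * to_virtual_echo(x)
        x = soft_threshold(from_virtual_echo(ve), lam)
        history[j] = np.abs(w * to_virtual_echo(x) - known).max()
        lam *= ratio
    if cfg.enforce_consistency:
        ve = known + (1.0 - w) * to_virtual_echo(x)
        x = from_virtual_echo(ve)
    return x, history


def _echo_problem(echo: np.ndarray, flavor: str) -> CompletionProblem:
    if flavor not in ("echo", "anti_echo"):
        raise ValueError(f"unknown flavor {flavor!r}")
    side = "P_side" if flavor == "echo" else "N_side"
    w = quadrant_weights(echo.shape, side)
    ve = to_virtual_echo(echo)
    # iFT of the twisted spectrum already lives on the retained quadrants;
    # mask multiplication only cleans numerical dust outside them
    return CompletionProblem(known=ve * (w > 0), weights=w, flavor=flavor)


def cs_echo(echo: np.ndarray, flavor: str = "echo",
            config: ISTConfig | None = None,
            return_history: bool = False):
    """Absorptive spectrum from a single phase-twisted Echo/Anti-Echo one."""
    x, hist = ist_complete(_echo_problem(echo, flavor), config)
    return (x, hist) if return_history else x


def cs_nus(nus_spectrum: np.ndarray, schedule: Sequence[int],
           config: ISTConfig | None = None,
           return_history: bool = False):
    """Reconstruction of a NUS-corrupted spectrum (sampled rows known)."""
    n1 = nus_spectrum.shape[0]
    sched = validate_schedule(schedule, n1 // 2)
    keep = np.zeros(n1, dtype=bool)
    keep[sched] = True
    keep[(-sched) % n1] = True
    keep[n1 // 2] = True  # Nyquist row is fixed by convention, not sampling
    w = np.broadcast_to(keep[:, None], nus_spectrum.shape).astype(float)
    ve = to_virtual_echo(nus_spectrum) * w
    problem = CompletionProblem(known=ve, weights=w, flavor="nus")
    x, hist = ist_complete(problem, config)
    return (x, hist) if return_history else x


class ISTReconstructor(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around the IST completion solver.

    ``transform`` maps a stack of corrupted spectra ``(n, H, W)`` (or a
    single 2D spectrum) to reconstructions.  ``mode`` selects the problem:
    'echo'/'anti_echo' complete the missing VE quadrants, 'nus' the missing
    rows of ``schedule``.  Stateless: ``fit`` only validates parameters.
    """

    def __init__(self, mode: Literal["echo", "anti_echo", "nus"] = "echo",
                 schedule: Sequence[int] | None = None,
                 n_iterations: int = 200, threshold_start: float = 0.9,
                 noise_floor_factor: float = 5.0,
                 enforce_consistency: bool = True):
        self.mode = mode
        self.schedule = schedule
        self.n_iterations = n_iterations
        self.threshold_start = threshold_start
        self.noise_floor_factor = noise_floor_factor
        self.enforce_consistency = enforce_consistency

    def _config(self) -> ISTConfig:
        return ISTConfig(n_iterations=self.n_iterations,
                         threshold_start=self.threshold_start,
                         noise_floor_factor=self.noise_floor_factor,
                         enforce_consistency=self.enforce_consistency)

    def fit(self, X=None, y=None):
        if self.mode not in ("echo", "anti_echo", "nus"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "nus" and self.schedule is None:
            raise ValueError("mode='nus' requires a schedule")
        self.config_ = self._config()
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self.fit()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        stack = X[None] if single else X
        out = np.empty_like(stack)
        for i, spec in enumerate(stack):
            if self.mode == "nus":
                out[i] = cs_nus(spec, self.schedule, self.config_)
            else:
                out[i] = cs_echo(spec, self.mode, self.config_)
        return out[0] if single else out
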
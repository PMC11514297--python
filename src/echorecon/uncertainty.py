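"""Per-point intensity uncertainty and the reference-free quality score.

A dilated-convolution network is trained to predict, from the corrupted
input spectrum alone, the standard deviation ``sigma`` of a Gaussian error
model for the intensities produced by a *fixed* reconstruction method.  The
training loss is the Gaussian negative log-likelihood

    NLL(y | mu, sigma) = (y - mu)^2 / (2 sigma^2) + log(sigma)

where ``y`` is the ground truth, ``mu`` the method's reconstruction (fixed,
not learned) and ``sigma`` the network output, kept positive by a rectifier
plus a small floor.  One predictor is trained per method (e.g. cascade-echo,
CS-echo, CS-NUS).

The predicted uncertainties double as a reference-free *predicted Spectrum
Quality* (pSQ) score: sigma is normalized by the maximum intensity of the
reconstruction and summarized over the spectral support (points above 1% of
that maximum); smaller normalized sigma means a better spectrum, and the
score needs no reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm as _norm
from sklearn.base import BaseEstimator

from .cascade import _as_stack, apply_model
from .nn import TrainConfig, fit_network, gaussian_nll_loss
from .wnn import TileScheme, WNNSpec, build_wnn, central_crop, stitch, tile

__all__ = ["nll", "coverage", "SigmaPredictor", "train_uncertainty",
           "predict_sigma", "PSQReport", "psq_score", "z_quantile"]

SIGMA_FLOOR = 1e-6


def nll(y, mu, sigma):
    """Pointwise Gaussian negative log-likelihood (up to a constant).

    ``(y - mu)^2 / (2 sigma^2) + log(sigma)``; minimized over sigma at
    ``sigma = |y - mu|``.  Broadcasts like numpy.
    """
    y, mu, sigma = np.asarray(y, float), np.asarray(mu, float), np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return (y - mu) ** 2 / (2.0 * sigma ** 2) + np.log(sigma)


def z_quantile(level: float) -> float:
    """Two-sided standard-normal quantile, e.g. 1.959964 for level 0.95."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    return float(_norm.ppf(0.5 + level / 2.0))


def coverage(y, mu, sigma, level: float = 0.95) -> float:
    """Fraction of points whose error lies inside the two-sided CI band."""
    y, mu, sigma = np.broadcast_arrays(np.asarray(y, float),
                                       np.asarray(mu, float),
                                       np.asarray(sigma, float))
    z = z_quantile(level)
    return float(np.mean(np.abs(y - mu) <= z * sigma))


class SigmaPredictor(BaseEstimator):
    """Heteroscedastic uncertainty network for one reconstruction method.

    ``fit(X, y, mu=...)`` takes corrupted input spectra ``X``, ground-truth
    spectra ``y`` and the method's reconstructions ``mu`` (fixed means of
    the Gaussian model).  The network sees only ``X``; each triple is
    normalized by the Euclidean norm of the input spectrum, and predicted
    sigmas are scaled back to intensity units on ``predict``.
    """

    def __init__(self, spec: WNNSpec | None = None,
                 output_extent: tuple[int, int] = (32, 64),
                 learning_rate: float = 1e-3, batch_size: int = 64,
                 max_epochs: int = 200, patience: int = 20,
                 val_fraction: float = 0.1, sigma_floor: float = SIGMA_FLOOR,
                 random_state: int = 0):
        self.spec = spec
        self.output_extent = output_extent
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.sigma_floor = sigma_floor
        self.random_state = random_state

    def fit(self, X, y, mu=None):
        if mu is None:
            raise ValueError("fit requires the method reconstructions mu")
        X, y, mu = _as_stack(X), _as_stack(y), _as_stack(mu)
        if not X.shape == y.shape == mu.shape:
            raise ValueError("X, y and mu must share one shape")
        spec = self.spec if self.spec is not None else WNNSpec()
        self.scheme_ = TileScheme(X.shape[1:], tuple(self.output_extent),
                                  spec.receptive_field)
        xs, ys, ms = [], [], []
        for xi, yi, mi in zip(X, y, mu):
            n = np.linalg.norm(xi)
            if n == 0:
                continue
            xs.append(tile(xi / n, self.scheme_))
            ys.append(central_crop(tile(yi / n, self.scheme_), self.scheme_))
            ms.append(central_crop(tile(mi / n, self.scheme_), self.scheme_))
        if not xs:
            raise ValueError("no usable (non-zero) training spectra")
        cfg = TrainConfig(learning_rate=self.learning_rate,
                          batch_size=self.batch_size,
                          max_epochs=self.max_epochs, patience=self.patience,
                          val_fraction=self.val_fraction,
                          sigma_floor=self.sigma_floor,
                          seed=self.random_state)
        self.model_ = build_wnn(spec, seed=self.random_state)
        # start the sigma head as a nearly uniform positive map: damping the
        # projection weights and biasing it up keeps the initial sigma away
        # from the floor everywhere (raw near the floor explodes the NLL)
        self.model_.layers[-1].weight *= 0.01
        self.model_.layers[-1].bias[...] = 0.5
        self.history_ = fit_network(self.model_, np.concatenate(xs)[:, None],
                                    np.concatenate(ys)[:, None], cfg,
                                    loss="nll", mu=np.concatenate(ms)[:, None])
        return self

    def predict(self, X) -> np.ndarray:
        """Sigma map(s) in the intensity units of the input spectra."""
        X = _as_stack(X)
        out = np.empty_like(X)
        for i, xi in enumerate(X):
            n = np.linalg.norm(xi)
            if n == 0:
                out[i] = self.sigma_floor
                continue
            raw = apply_model(self.model_, xi / n, self.scheme_)
            out[i] = (np.maximum(raw, 0.0) + self.sigma_floor) * n
        return out

    def nll_score(self, X, y, mu) -> float:
        """Mean NLL of predicted sigmas on held-out triples (lower=better)."""
        sigma = self.predict(X)
        return float(np.mean(nll(_as_stack(y), _as_stack(mu), sigma)))


def train_uncertainty(inputs, truths, reconstructions,
                      **kwargs) -> SigmaPredictor:
    """Functional wrapper: fit a :class:`SigmaPredictor`."""
    return SigmaPredictor(**kwargs).fit(inputs, truths, mu=reconstructions)


def predict_sigma(input_spectrum, model: SigmaPredictor) -> np.ndarray:
    """Functional wrapper around :meth:`SigmaPredictor.predict`."""
    out = model.predict(input_spectrum)
    return out[0] if np.asarray(input_spectrum).ndim == 2 else out


@dataclass(frozen=True)
class PSQReport:
    """Summary of the normalized-sigma distribution over the support."""

    median: float
    mean: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_points: int
    threshold: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("median", "mean", "q1", "q3", "whisker_low", "whisker_high",
                 "n_points", "threshold")}


def psq_score(sigma_map: np.ndarray, reconstruction: np.ndarray,
              threshold: float = 0.01) -> PSQReport:
    """Reference-free predicted Spectrum Quality score.

    Sigmas are normalized by the maximum absolute intensity of the
    reconstruction and summarized (box-plot statistics) over the points
    whose normalized absolute intensity exceeds ``threshold``.  Invariant
    under joint rescaling of (reconstruction, sigma); the headline statistic
    is the median (the mean is also reported).
    """
    sigma_map = np.asarray(sigma_map, float)
    reconstruction = np.asarray(reconstruction, float)
    if sigma_map.shape != reconstruction.shape:
        raise ValueError("sigma map and reconstruction grids differ")
    peak = np.abs(reconstruction).max()
    if peak == 0:
        raise ValueError("reconstruction is identically zero")
    support = np.abs(reconstruction) > threshold * peak
    if not support.any():
        raise ValueError("empty support at this threshold")
    vals = sigma_map[support] / peak
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo = vals[vals >= q1 - 1.5 * iqr].min()
    hi = vals[vals <= q3 + 1.5 * iqr].max()
    return PSQReport(median=float(med), mean=float(vals.mean()), q1=float(q1),
                     q3=float(q3), whisker_low=float(lo),
                     whisker_high=float(hi), n_points=int(vals.size),
                     threshold=threshold)
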
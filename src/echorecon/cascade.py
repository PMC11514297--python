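"""Multi-stage network reconstruction of Echo/Anti-Echo spectra.

The reconstructor chains ``n_stages`` dilated-convolution networks.  Stage
``i`` receives a corrected spectrum that keeps the measured Echo part exact
and takes only the *predicted* Anti-Echo part (attenuated by a factor
``C(i) = 1 - 0.05 * 2^(1-i)``) from the previous stage::

    S_cor(i) = S_echo + C(i) * FT[ Z_E[ iFT[ S_pred(i) ] ] ]

(for anti-echo flavor the projector roles swap).  No correction is applied
after the final stage.  Networks are trained sequentially, each on the
corrected outputs of the frozen upstream stages; inputs and targets of each
stage are normalized by the Euclidean norm of the stage input.

Anti-Echo data is handled by reflecting the indirect frequency axis, which
turns the anti-echo twist into the echo twist, so echo-trained weights can
be reused (a switch allows training a separate network instead).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .hypercomplex import from_virtual_echo, to_virtual_echo, zero_quadrants
from .nn import Sequential, TrainConfig, TrainingHistory, fit_network
from .wnn import TileScheme, WNNSpec, build_wnn, central_crop, stitch, tile

__all__ = ["correction_factor", "correction_step", "reflect_indirect",
           "apply_model", "WNNRegressor", "CascadeReconstructor",
           "train_cascade", "reconstruct"]


def correction_factor(stage: int) -> float:
    """Attenuation ``C(i) = 1 - 0.05 * 2^(1-i)`` of the predicted part."""
    if stage < 1:
        raise ValueError("stage index starts at 1")
    return 1.0 - 0.05 * 2.0 ** (1 - stage)


def correction_step(s_echo: np.ndarray, s_pred: np.ndarray, stage: int,
                    flavor: str = "echo", n_stages: int = 5) -> np.ndarray:
    """Inter-stage correction: measured part restored, predicted part damped."""
    if not 1 <= stage <= n_stages - 1:
        raise ValueError(f"correction applies after stages 1..{n_stages - 1}")
    if flavor not in ("echo", "anti_echo"):
        raise ValueError(f"unknown flavor {flavor!r}")
    # keep the complementary (predicted) side: for echo input, zero the echo
    # (P) side of the prediction and keep its anti-echo part
    which = "P_side" if flavor == "echo" else "N_side"
    # warn=False: a prediction with (near-)empty complementary quadrants
    # projects to a numerically empty array that trips the symmetry check
    predicted_part = from_virtual_echo(
        zero_quadrants(to_virtual_echo(s_pred), which), warn=False)
    return s_echo + correction_factor(stage) * predicted_part


def reflect_indirect(spectrum: np.ndarray) -> np.ndarray:
    """Reflect the indirect frequency axis (unshifted layout).

    Maps the anti-echo twist pattern onto the echo twist pattern and back.
    """
    n = spectrum.shape[0]
    return np.ascontiguousarray(spectrum[(-np.arange(n)) % n, :])


def apply_model(model: Sequential, spectrum: np.ndarray,
                scheme: TileScheme, batch_size: int = 16) -> np.ndarray:
    """Run a network over a full spectrum via tile/stitch."""
    patches = tile(spectrum, scheme)[:, None]  # add channel axis
    outs = [model.forward(patches[s:s + batch_size])[:, 0]
            for s in range(0, len(patches), batch_size)]
    return stitch(np.concatenate(outs), scheme)


def _as_stack(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.ndim != 3:
        raise ValueError("expected a spectrum or a stack of spectra")
    return X


class WNNRegressor(RegressorMixin, BaseEstimator):
    """One dilated-convolution network as a spectrum-to-spectrum regressor.

    ``fit(X, y)`` trains on stacks of equally sized spectra (inputs and
    targets on the same grid); each input/target pair is normalized by the
    Euclidean norm of the input.  ``predict`` tiles arbitrary same-grid
    spectra through the trained network.
    """

    def __init__(self, spec: WNNSpec | None = None,
                 output_extent: tuple[int, int] = (32, 64),
                 learning_rate: float = 1e-4, batch_size: int = 64,
                 max_epochs: int = 1000, patience: int = 20,
                 val_fraction: float = 0.1, random_state: int = 0):
        self.spec = spec
        self.output_extent = output_extent
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _spec(self) -> WNNSpec:
        return self.spec if self.spec is not None else WNNSpec()

    def _train_config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate,
                           batch_size=self.batch_size,
                           max_epochs=self.max_epochs, patience=self.patience,
                           val_fraction=self.val_fraction,
                           seed=self.random_state)

    def fit(self, X, y):
        X, y = _as_stack(X), _as_stack(y)
        if X.shape != y.shape:
            raise ValueError("input and target stacks must share one shape")
        spec = self._spec()
        self.scheme_ = TileScheme(X.shape[1:], tuple(self.output_extent),
                                  spec.receptive_field)
        xs, ys = [], []
        for xi, yi in zip(X, y):
            norm = np.linalg.norm(xi)
            if norm == 0:
                import warnings
                warnings.warn("skipping zero-norm input spectrum")
                continue
            xs.append(tile(xi / norm, self.scheme_))
            ys.append(central_crop(tile(yi / norm, self.scheme_),
                                   self.scheme_))
        if not xs:
            raise ValueError("no usable (non-zero) training spectra")
        Xp = np.concatenate(xs)[:, None]
        yp = np.concatenate(ys)[:, None]
        self.model_ = build_wnn(spec, seed=self.random_state)
        self.history_ = fit_network(self.model_, Xp, yp,
                                    self._train_config(), loss="mse")
        self.n_parameters_ = self.model_.n_parameters()
        return self

    def predict(self, X):
        X = _as_stack(X)
        out = np.empty_like(X)
        for i, xi in enumerate(X):
            norm = np.linalg.norm(xi)
            if norm == 0:
                out[i] = 0.0
                continue
            out[i] = apply_model(self.model_, xi / norm, self.scheme_) * norm
        return out


class CascadeReconstructor(RegressorMixin, BaseEstimator):
    """Sequentially trained cascade of networks with inter-stage correction.

    ``fit(X, y)`` takes twisted single-quadrature spectra ``X`` and their
    absorptive references ``y``; ``predict`` reconstructs new spectra of the
    training flavor.  ``predict_reflected`` serves the mirror flavor by
    reflecting the indirect axis around a cascade trained on the other one.
    """

    def __init__(self, n_stages: int = 5, spec: WNNSpec | None = None,
                 output_extent: tuple[int, int] = (32, 64),
                 flavor: str = "echo", learning_rate: float = 1e-4,
                 batch_size: int = 64, max_epochs: int = 1000,
                 patience: int = 20, val_fraction: float = 0.1,
                 random_state: int = 0):
        self.n_stages = n_stages
        self.spec = spec
        self.output_extent = output_extent
        self.flavor = flavor
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        X, y = _as_stack(X), _as_stack(y)
        self.stages_ = []
        self.histories_: list[TrainingHistory] = []
        current = X
        for s in range(1, self.n_stages + 1):
            reg = WNNRegressor(spec=self.spec,
                               output_extent=self.output_extent,
                               learning_rate=self.learning_rate,
                               batch_size=self.batch_size,
                               max_epochs=self.max_epochs,
                               patience=self.patience,
                               val_fraction=self.val_fraction,
                               random_state=self.random_state + s)
            reg.fit(current, y)
            self.stages_.append(reg)
            self.histories_.append(reg.history_)
            if s < self.n_stages:
                preds = reg.predict(current)
                current = np.stack([
                    correction_step(X[i], preds[i], s, self.flavor,
                                    self.n_stages)
                    for i in range(len(X))])
        return self

    def predict(self, X):
        X = _as_stack(X)
        current = X
        for s, reg in enumerate(self.stages_, start=1):
            preds = reg.predict(current)
            if s < self.n_stages:
                current = np.stack([
                    correction_step(X[i], preds[i], s, self.flavor,
                                    self.n_stages)
                    for i in range(len(X))])
        return preds

    def predict_reflected(self, X):
        """Reconstruct spectra of the mirror flavor via axis reflection."""
        X = _as_stack(X)
        mirrored = np.stack([reflect_indirect(x) for x in X])
        preds = self.predict(mirrored)
        return np.stack([reflect_indirect(p) for p in preds])


def train_cascade(inputs, references, **kwargs) -> CascadeReconstructor:
    """Functional wrapper: fit a :class:`CascadeReconstructor`."""
    return CascadeReconstructor(**kwargs).fit(inputs, references)


def reconstruct(echo, model: CascadeReconstructor,
                flavor: str | None = None) -> np.ndarray:
    """Functional wrapper: reconstruct one spectrum with a trained cascade."""
    flavor = flavor or model.flavor
    if flavor == model.flavor:
        out = model.predict(echo)
    else:
        out = model.predict_reflected(echo)
    return out[0] if np.asarray(echo).ndim == 2 else out
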
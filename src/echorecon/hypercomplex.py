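"""Hypercomplex 2D processing, the Virtual Echo transform and quadrant algebra.

A phase-modulated (P/N) acquisition pair is converted to amplitude-modulated
cos/sin components, processed dimension by dimension (apodization,
zero-filling, FFT, phase correction) into a real pure-absorption spectrum
``S`` on the doubled ``2k x 2l`` grid.

The *Virtual Echo* (VE) of a real spectrum is its inverse 2D FFT: a complex,
conjugate-symmetric time-domain array whose four time-sign quadrants carry
the P-type data (t1>0, t2>0), its time-reversed conjugate P~ (t1<0, t2<0),
the N-type data (t1<0, t2>0) and N~ (t1>0, t2<0).  Zeroing the N-side
quadrants and transforming back yields the phase-twisted Echo spectrum;
zeroing the P side yields the Anti-Echo spectrum.  With half weights on the
time-sign boundary lines the two projectors add up to the identity, so
``S_echo + S_anti_echo == S`` exactly.

Index/time convention (unshifted FFT layout, per axis of length 2T):
index 0 is t=0, indices 1..T-1 are positive times, index T is the Nyquist
point, indices T+1..2T-1 are negative times ascending to -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .simulate import HypercomplexFID

__all__ = [
    "ProcessingOptions",
    "process_spectrum",
    "to_virtual_echo",
    "from_virtual_echo",
    "time_sign",
    "quadrant_weights",
    "zero_quadrants",
    "echo_spectrum",
    "nus_corrupt",
    "validate_schedule",
]

Flavor = Literal["echo", "anti_echo"]


@dataclass(frozen=True)
class ProcessingOptions:
    """Options of the standard processing chain.

    apodization: 'cos2' (cosine-squared window over the acquired points) or
    'none'.  zero_fill: multiplicative factor per dimension (2 doubles each
    axis, the default and the grid every other module assumes).  phase0 /
    phase1: zero- and first-order phase corrections in degrees per dimension
    (indirect, direct); first-order is relative to the full spectral width.
    """

    apodization: str = "cos2"
    zero_fill: int = 2
    phase0: tuple[float, float] = (0.0, 0.0)
    phase1: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.apodization not in ("cos2", "none"):
            raise ValueError("apodization must be 'cos2' or 'none'")
        if self.zero_fill < 1:
            raise ValueError("zero_fill factor must be >= 1")


def _window(n: int, kind: str) -> np.ndarray:
    if kind == "none":
        return np.ones(n)
    # cosine-squared over the acquisition, 1 at t=0 falling to ~0 at the end
    return np.cos(0.5 * np.pi * np.arange(n) / n) ** 2


def _phase_ramp(n: int, p0_deg: float, p1_deg: float) -> np.ndarray:
    f = np.fft.fftfreq(n)  # cycles/dwell in [-0.5, 0.5)
    return np.exp(-1j * np.deg2rad(p0_deg + p1_deg * (f + 0.5)))


def _ft_dim(x: np.ndarray, axis: int, n_out: int, window: np.ndarray,
            p0: float, p1: float) -> np.ndarray:
    """Apodize, zero-fill, FFT and phase one dimension of a complex array."""
    shape = [1] * x.ndim
    shape[axis] = -1
    x = x * window.reshape(shape)
    spec = np.fft.fft(x, n=n_out, axis=axis)
    return spec * _phase_ramp(n_out, p0, p1).reshape([1] * (axis) + [-1] +
                                                     [1] * (x.ndim - axis - 1))


def process_spectrum(fid: HypercomplexFID,
                     options: ProcessingOptions | None = None) -> np.ndarray:
    """Hypercomplex (States-equivalent) processing of a P/N pair.

    Converts the phase-modulated pair to amplitude-modulated components
    (``cos = (X_P + X_N)/2``, ``sin = (X_P - X_N)/(2i)``), transforms the
    direct dimension of each, assembles the indirect-dimension complex
    interferogram from the two real parts, transforms it, and returns the
    real absorptive part on the zero-filled (default ``2k x 2l``) grid.
    """
    opts = options or ProcessingOptions()
    k, l = fid.shape
    cos = (fid.p_data + fid.n_data) / 2.0
    sin = (fid.p_data - fid.n_data) / 2.0j

    n2 = opts.zero_fill * l
    w2 = _window(l, opts.apodization)
    cos_f2 = _ft_dim(cos, 1, n2, w2, opts.phase0[1], opts.phase1[1])
    sin_f2 = _ft_dim(sin, 1, n2, w2, opts.phase0[1], opts.phase1[1])

    inter = cos_f2.real + 1j * sin_f2.real  # complex in t1, frequency in F2
    n1 = opts.zero_fill * k
    w1 = _window(k, opts.apodization)
    spec = _ft_dim(inter, 0, n1, w1, opts.phase0[0], opts.phase1[0])
    return np.ascontiguousarray(spec.real)


def to_virtual_echo(spectrum: np.ndarray) -> np.ndarray:
    """Inverse 2D FFT of a real spectrum: the complex Virtual Echo array."""
    spectrum = np.asarray(spectrum)
    if np.iscomplexobj(spectrum):
        raise ValueError("virtual echo is defined for real spectra")
    return np.fft.ifft2(spectrum)


def from_virtual_echo(ve: np.ndarray, tol: float = 1e-8,
                      warn: bool = True) -> np.ndarray:
    """Forward 2D FFT of a VE array; returns the real part.

    Warns when the imaginary residual exceeds ``tol`` times the maximum —
    a symptom of broken conjugate symmetry in the input.  ``warn=False``
    silences the check for callers transforming numerically empty arrays,
    where the relative test is meaningless.
    """
    spec = np.fft.fft2(ve)
    scale = np.abs(spec).max()
    if warn and scale > 0 and np.abs(spec.imag).max() > tol * scale:
        warnings.warn("virtual echo lost conjugate symmetry; imaginary part "
                      "discarded", RuntimeWarning, stacklevel=2)
    return np.ascontiguousarray(spec.real)


def time_sign(n: int) -> np.ndarray:
    """Per-index time-sign class on an axis of even length ``n = 2T``.

    Returns +1 for positive times (1..T-1), -1 for negative times
    (T+1..2T-1) and 0 on the boundary lines t=0 and Nyquist (0 and T).
    """
    if n % 2:
        raise ValueError("axis length must be even (doubled grid)")
    s = np.zeros(n, dtype=np.int8)
    s[1:n // 2] = 1
    s[n // 2 + 1:] = -1
    return s


def quadrant_weights(shape: tuple[int, int],
                     side: Literal["P_side", "N_side"]) -> np.ndarray:
    """Weights of the quadrant projector that *keeps* the requested side.

    P side = quadrants P and P~ (time signs multiply to +1), N side = N and
    N~ (signs multiply to -1).  Points on any boundary line (t=0 or Nyquist
    in either dimension) get weight 1/2 in both projectors, so the two
    projectors sum to the identity exactly.
    """
    if side not in ("P_side", "N_side"):
        raise ValueError("side must be 'P_side' or 'N_side'")
    s1 = time_sign(shape[0])[:, None].astype(float)
    s2 = time_sign(shape[1])[None, :].astype(float)
    prod = s1 * s2
    want = 1.0 if side == "P_side" else -1.0
    w = np.where(prod == want, 1.0, 0.0)
    boundary = np.broadcast_to((s1 == 0) | (s2 == 0), shape)
    w[boundary] = 0.5
    return w


def zero_quadrants(ve: np.ndarray,
                   which: Literal["P_side", "N_side"]) -> np.ndarray:
    """Zero the requested quadrant pair of a VE array.

    ``which='N_side'`` zeroes N and N~ (leaving Echo data); ``'P_side'``
    zeroes P and P~ (leaving Anti-Echo data).  Boundary lines are halved.
    """
    keep = "P_side" if which == "N_side" else "N_side"
    return ve * quadrant_weights(ve.shape, keep)


def echo_spectrum(spectrum: np.ndarray, flavor: Flavor) -> np.ndarray:
    """Phase-twisted single-quadrature spectrum from an absorptive one.

    ``FT[Z[iFT[S]]]`` where Z zeroes the N side (echo flavor) or the P side
    (anti-echo flavor).  The retained quadrant pair is conjugate-symmetric,
    so the output is real.
    """
    if flavor not in ("echo", "anti_echo"):
        raise ValueError(f"unknown flavor {flavor!r}")
    which = "N_side" if flavor == "echo" else "P_side"
    return from_virtual_echo(zero_quadrants(to_virtual_echo(spectrum), which))


def validate_schedule(schedule: Sequence[int], n_increments: int) -> np.ndarray:
    sched = np.asarray(schedule, dtype=np.int64)
    if sched.ndim != 1 or sched.size == 0:
        raise ValueError("schedule must be a non-empty 1D index list")
    if np.unique(sched).size != sched.size:
        raise ValueError("schedule contains duplicate indices")
    if sched.min() < 0 or sched.max() >= n_increments:
        raise ValueError("schedule index out of range")
    return np.sort(sched)


def nus_corrupt(data: HypercomplexFID | np.ndarray,
                schedule: Sequence[int],
                options: ProcessingOptions | None = None) -> np.ndarray:
    """Spectrum with non-uniform-sampling aliasing artifacts.

    Unsampled indirect increments are zeroed in the time domain and the
    result is processed to a spectrum.  Accepts either a hypercomplex FID
    (rows of both cos/sin components zeroed before processing) or an
    already-processed real spectrum (mirrored +/- t1 rows zeroed in its VE
    presentation); the two routes are equivalent for linear processing.
    """
    if isinstance(data, HypercomplexFID):
        k = data.shape[0]
        sched = validate_schedule(schedule, k)
        mask = np.zeros(k, dtype=bool)
        mask[sched] = True
        xp = data.p_data * mask[:, None]
        xn = data.n_data * mask[:, None]
        return process_spectrum(HypercomplexFID(xp, xn), options)
    spectrum = np.asarray(data)
    n1 = spectrum.shape[0]
    k = n1 // 2
    sched = validate_schedule(schedule, k)
    ve = to_virtual_echo(spectrum)
    keep = np.zeros(n1, dtype=bool)
    keep[sched] = True
    keep[(-sched) % n1] = True
    ve = ve * keep[:, None]
    return from_virtual_echo(ve)
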
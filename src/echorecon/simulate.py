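"""Synthetic 2D hypercomplex FID generator.

Emulates phase-modulated (Echo/Anti-Echo) quadrature acquisitions of a
2D 1H-15N-like correlation experiment: each FID is a sum of damped complex
exponentials, acquired simultaneously as a P-type (echo, ``+i`` indirect
modulation) and an N-type (anti-echo, ``-i``) complex matrix, plus Gaussian
noise and an optional P/N amplitude imbalance.

The model for exponential ``n`` evaluated at integer dwell times
``t1 = 0..k-1`` (indirect) and ``t2 = 0..l-1`` (direct) is::

    X_{P/N}(t1, t2) = sum_n A_n  exp(+/- i (2 pi w1_n t1 + p1_n)) exp(-t1 / tau1_n)
                              * exp(     i (2 pi w2_n t2 + p2_n)) exp(-t2 / tau2_n)

with frequencies ``w`` in cycles per dwell time (so the full unaliased band
is ``[-0.5, 0.5]``), phases ``p`` in radians internally (degrees in the
configuration), and decay times ``tau`` in dwell-point units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ExponentialParams",
    "SimConfig",
    "HypercomplexFID",
    "sample_params",
    "synthesize_fid",
    "add_noise",
    "apply_imbalance",
    "generate_pairs",
    "PairDataset",
    "pair_seed",
]


@dataclass(frozen=True)
class ExponentialParams:
    """Parameters of one damped complex exponential.

    Frequencies are in cycles per dwell (normalized, within [-0.5, 0.5]),
    phases in degrees, decay constants in dwell-point units (must be > 0;
    ``inf`` means no decay).
    """

    amplitude: float
    freq_indirect: float
    freq_direct: float
    phase_indirect: float = 0.0
    phase_direct: float = 0.0
    decay_indirect: float = np.inf
    decay_direct: float = np.inf

    def __post_init__(self) -> None:
        if not (self.decay_indirect > 0 and self.decay_direct > 0):
            raise ValueError("decay constants must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic FID generator.

    Defaults are the study conditions for a 2D amide-correlation-like
    spectrum: 256 direct x 128 indirect complex points, 512 exponentials,
    SNR 500, frequencies uniform over the full band, phases within +/-3
    degrees, amplitudes in [-0.2, 1], decays of 12.8-128 (direct) and
    256-1280 (indirect) points.
    """

    n_indirect: int = 128
    n_direct: int = 256
    n_exponentials: int = 512
    snr: float = 500.0
    freq_range: tuple[float, float] = (-0.5, 0.5)
    phase_range_deg: tuple[float, float] = (-3.0, 3.0)
    amp_range: tuple[float, float] = (-0.2, 1.0)
    decay_range_indirect: tuple[float, float] = (256.0, 1280.0)
    decay_range_direct: tuple[float, float] = (12.8, 128.0)
    imbalance_deficit: float = 0.0
    #: if True, use the literal growing indirect envelope exp(+t1/tau1)
    literal_indirect_growth: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_indirect < 2 or self.n_direct < 2:
            raise ValueError("need at least 2 complex points per dimension")
        if self.n_exponentials < 0:
            raise ValueError("n_exponentials must be >= 0")
        if not self.snr > 0:
            raise ValueError("snr must be > 0 (use numpy.inf for noiseless)")
        if not (0.0 <= self.imbalance_deficit < 1.0):
            raise ValueError("imbalance_deficit must be in [0, 1)")
        for name in ("freq_range", "phase_range_deg", "amp_range",
                     "decay_range_indirect", "decay_range_direct"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds {hi}")


@dataclass
class HypercomplexFID:
    """Paired P-type and N-type complex time-domain matrices.

    Axis order is (indirect t1, direct t2); both matrices share one shape.
    """

    p_data: np.ndarray
    n_data: np.ndarray

    def __post_init__(self) -> None:
        self.p_data = np.asarray(self.p_data, dtype=np.complex128)
        self.n_data = np.asarray(self.n_data, dtype=np.complex128)
        if self.p_data.shape != self.n_data.shape:
            raise ValueError("P and N matrices must have identical shape")
        if self.p_data.ndim != 2:
            raise ValueError("FID matrices must be 2D (indirect x direct)")
        if not (np.isfinite(self.p_data).all() and np.isfinite(self.n_data).all()):
            raise ValueError("FID contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_data.shape

    def copy(self) -> "HypercomplexFID":
        return HypercomplexFID(self.p_data.copy(), self.n_data.copy())


def sample_params(config: SimConfig, seed: int) -> list[ExponentialParams]:
    """Draw ``config.n_exponentials`` random exponentials, uniform per field."""
    rng = np.random.default_rng(seed)
    n = config.n_exponentials
    amp = rng.uniform(*config.amp_range, n)
    w1 = rng.uniform(*config.freq_range, n)
    w2 = rng.uniform(*config.freq_range, n)
    p1 = rng.uniform(*config.phase_range_deg, n)
    p2 = rng.uniform(*config.phase_range_deg, n)
    tau1 = rng.uniform(*config.decay_range_indirect, n)
    tau2 = rng.uniform(*config.decay_range_direct, n)
    return [
        ExponentialParams(amp[i], w1[i], w2[i], p1[i], p2[i], tau1[i], tau2[i])
        for i in range(n)
    ]


def synthesize_fid(params: Sequence[ExponentialParams],
                   config: SimConfig) -> HypercomplexFID:
    """Evaluate the sum-of-exponentials model on the (t1, t2) grid.

    The P part carries ``+i`` and the N part ``-i`` in front of the whole
    indirect phase ``2 pi w1 t1 + p1``; the direct-dimension factor is
    identical in both. Linear in the parameter list.
    """
    k, l = config.n_indirect, config.n_direct
    t1 = np.arange(k)[:, None]
    t2 = np.arange(l)[None, :]
    xp = np.zeros((k, l), dtype=np.complex128)
    xn = np.zeros((k, l), dtype=np.complex128)
    sign1 = +1.0 if config.literal_indirect_growth else -1.0
    for p in params:
        phi1 = np.deg2rad(p.phase_indirect)
        phi2 = np.deg2rad(p.phase_direct)
        theta1 = 2.0 * np.pi * p.freq_indirect * t1 + phi1
        with np.errstate(over="ignore"):
            env1 = np.exp(sign1 * t1 / p.decay_indirect)
            env2 = np.exp(-t2 / p.decay_direct)
        direct = np.exp(1j * (2.0 * np.pi * p.freq_direct * t2 + phi2)) * env2
        xp += p.amplitude * (np.exp(+1j * theta1) * env1) * direct
        xn += p.amplitude * (np.exp(-1j * theta1) * env1) * direct
    return HypercomplexFID(xp, xn)


def add_noise(fid: HypercomplexFID, snr: float, seed: int,
              amplitude_scale: float = 1.0) -> HypercomplexFID:
    """Add i.i.d. Gaussian noise to real and imaginary parts of both P and N.

    Per-component noise std is ``amplitude_scale / snr`` — SNR is pegged to
    the maximum attainable single-exponential amplitude (1 under the default
    ranges). P and N receive independent draws (separate acquisitions).
    ``snr = inf`` returns an unchanged copy.
    """
    if not snr > 0:
        raise ValueError("snr must be > 0")
    if np.isinf(snr):
        return fid.copy()
    rng = np.random.default_rng(seed)
    sigma = amplitude_scale / snr
    shape = fid.shape
    noise = rng.normal(0.0, sigma, (4,) + shape)
    xp = fid.p_data + noise[0] + 1j * noise[1]
    xn = fid.n_data + noise[2] + 1j * noise[3]
    return HypercomplexFID(xp, xn)


def apply_imbalance(fid: HypercomplexFID, deficit: float) -> HypercomplexFID:
    """Scale the P-type matrix by ``1 - deficit``; N is left unchanged.

    Emulates the amplitude imbalance between the separately acquired echo
    and anti-echo experiments (e.g. deficit 0.10 makes P 10% smaller).
    """
    if not (0.0 <= deficit < 1.0):
        raise ValueError("deficit must be in [0, 1)")
    return HypercomplexFID(fid.p_data * (1.0 - deficit), fid.n_data.copy())


def pair_seed(master_seed: int, index: int) -> int:
    """Counter-based child seed: independent of generation order, < 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class PairDataset:
    """A stack of (input spectrum, reference spectrum) training pairs."""

    inputs: np.ndarray        # (count, 2k, 2l)
    references: np.ndarray    # (count, 2k, 2l)
    seeds: np.ndarray         # (count,)
    mode: str
    config: SimConfig = field(repr=False, default_factory=SimConfig)

    def __len__(self) -> int:
        return self.inputs.shape[0]


def generate_pairs(config: SimConfig, count: int,
                   mode: Literal["echo", "anti_echo", "nus"],
                   master_seed: int = 0,
                   schedule: np.ndarray | None = None) -> PairDataset:
    """Simulate ``count`` (corrupted input, absorptive reference) pairs.

    Each pair uses a fresh random FID (fresh child seed derived from
    ``master_seed``); the reference is its traditionally processed
    absorptive spectrum and the input is the Echo/Anti-Echo or NUS-corrupted
    counterpart of that same reference.
    """
    # local import: hypercomplex imports nothing from here, but keep the
    # module graph acyclic at import time for the package __init__
    from .hypercomplex import echo_spectrum, nus_corrupt, process_spectrum
    from .cs import poisson_gap

    if mode not in ("echo", "anti_echo", "nus"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "nus" and schedule is None:
        schedule = poisson_gap(config.n_indirect, 0.5,
                               seed=pair_seed(master_seed, 1 << 20))

    inputs, refs, seeds = [], [], []
    for i in range(count):
        s = pair_seed(master_seed, i)
        params = sample_params(config, s)
        fid = synthesize_fid(params, config)
        if config.imbalance_deficit > 0:
            fid = apply_imbalance(fid, config.imbalance_deficit)
        fid = add_noise(fid, config.snr, s + 1)
        ref = process_spectrum(fid)
        if mode == "nus":
            inp = nus_corrupt(fid, schedule)
        else:
            inp = echo_spectrum(ref, mode)
        inputs.append(inp)
        refs.append(ref)
        seeds.append(s)
    shape = (count, 2 * config.n_indirect, 2 * config.n_direct)
    return PairDataset(
        inputs=np.asarray(inputs).reshape(shape),
        references=np.asarray(refs).reshape(shape),
        seeds=np.asarray(seeds, dtype=np.int64),
        mode=mode,
        config=config,
    )


def scaled_config(**overrides) -> SimConfig:
    """A reduced-size configuration for desk-scale runs and tests.

    Keeps the spectral physics (full frequency band, small phases, the
    default SNR) while shrinking the grid so spectra are 16 x 32 points
    after processing. Decay ranges shrink with the grid so linewidths in
    points are comparable to the full-size conditions.
    """
    base = dict(
        n_indirect=8, n_direct=16, n_exponentials=6,
        decay_range_indirect=(16.0, 80.0), decay_range_direct=(6.4, 16.0),
    )
    base.update(overrides)
    return SimConfig(**base)
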
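"""Reference-based spectrum quality metrics.

Reconstruction and reference are each normalized by their own maximum
absolute intensity, and compared only on the *support*: points whose
normalized absolute intensity exceeds a threshold (default 1% of the
maximum) in **either** spectrum.  Using the union makes the metrics
sensitive to both false-positive artifacts (present only in the
reconstruction) and false negatives (missing peaks), while points at or
below the noise floor are ignored.  Reported are the point-to-point RMSD
and the squared Pearson correlation R^2 over the support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["QualityReport", "support_mask", "rmsd", "r2", "quality_report"]


@dataclass(frozen=True)
class QualityReport:
    rmsd: float
    r2: float
    n_support: int
    threshold: float

    def as_dict(self) -> dict:
        return {"rmsd": self.rmsd, "r2": self.r2,
                "n_support": self.n_support, "threshold": self.threshold}


def _normalize(spec: np.ndarray) -> np.ndarray:
    peak = np.abs(spec).max()
    if peak == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return spec / peak


def _prepare(rec, ref, normalize: bool):
    rec = np.asarray(rec, float)
    ref = np.asarray(ref, float)
    if rec.shape != ref.shape:
        raise ValueError("spectra grids differ")
    if normalize:
        rec, ref = _normalize(rec), _normalize(ref)
    return rec, ref


def support_mask(rec, ref, threshold: float = 0.01,
                 normalize: bool = True) -> np.ndarray:
    """Boolean grid of points above threshold in either spectrum.

    Absolute intensities are used, so negative (dispersive) artifacts count
    toward the support.
    """
    rec, ref = _prepare(rec, ref, normalize)
    mask = (np.abs(rec) > threshold) | (np.abs(ref) > threshold)
    if not mask.any():
        raise ValueError("empty support: threshold too high for these spectra")
    return mask


def rmsd(rec, ref, threshold: float = 0.01, normalize: bool = True) -> float:
    """Point-to-point RMSD over the support, on max-normalized intensities."""
    mask = support_mask(rec, ref, threshold, normalize)
    rec, ref = _prepare(rec, ref, normalize)
    return float(np.sqrt(np.mean((rec[mask] - ref[mask]) ** 2)))


def r2(rec, ref, threshold: float = 0.01, normalize: bool = True) -> float:
    """Squared Pearson correlation over the support (affine-invariant)."""
    mask = support_mask(rec, ref, threshold, normalize)
    rec, ref = _prepare(rec, ref, normalize)
    r, _ = stats.pearsonr(rec[mask], ref[mask])
    return float(r ** 2)


def quality_report(rec, ref, threshold: float = 0.01,
                   normalize: bool = True) -> QualityReport:
    mask = support_mask(rec, ref, threshold, normalize)
    rec_n, ref_n = _prepare(rec, ref, normalize)
    r, _ = stats.pearsonr(rec_n[mask], ref_n[mask])
    return QualityReport(
        rmsd=float(np.sqrt(np.mean((rec_n[mask] - ref_n[mask]) ** 2))),
        r2=float(r ** 2), n_support=int(mask.sum()), threshold=threshold)
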
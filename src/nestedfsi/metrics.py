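"""The study's observables: landmark-to-surface separations and stress
scalars.

Cushioning is quantified by minimum Euclidean distances between anatomical
landmarks and the opposing surface, normalised to their baseline values:
values below one indicate compression of the protective fluid layer, values
above one increased separation.  Hierarchical attenuation shows up as outer
(fetus-uterus) separations swinging widely while inner (brain-skull)
separations stay near one.

Stress scalars follow the standard invariants: von Mises equivalent stress
from the principal stresses, mean stress sigma_m = tr(sigma)/3, triaxiality
T = sigma_m / sigma_VM, and the first deviatoric principal stress (largest
eigenvalue of the stress deviator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupling import closest_on_segments

__all__ = [
    "DistanceSeries",
    "min_distance",
    "normalized_series",
    "principal_stresses",
    "von_mises",
    "triaxiality",
    "first_deviatoric_principal_stress",
    "attenuation_percent",
    "mean_abs_deviation",
]


@dataclass
class DistanceSeries:
    """Per-landmark separation over time, raw and baseline-normalised."""

    landmark: str
    level: str                # "outer" (vs uterus) | "inner" (vs skull)
    times: np.ndarray
    raw: np.ndarray           # m
    baseline: float           # m, raw value at t = 0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"baseline for {self.landmark} must be > 0")
        if np.any(self.raw < 0):
            raise ValueError("raw distances must be >= 0")

    @property
    def normalized(self) -> np.ndarray:
        return self.raw / self.baseline


def min_distance(point, surface_positions: np.ndarray,
                 surface_segments: np.ndarray) -> float:
    """Exact minimum point-to-surface distance over all surface segments."""
    if len(surface_segments) == 0:
        raise ValueError("empty surface")
    a = surface_positions[surface_segments[:, 0]]
    b = surface_positions[surface_segments[:, 1]]
    _, _, _, d = closest_on_segments(np.atleast_2d(np.asarray(point, float)),
                                     a, b, k_candidates=len(surface_segments))
    return float(d[0])


def normalized_series(landmark: str, level: str, times, raw) -> DistanceSeries:
    """Baseline-normalise a raw separation series (baseline = first sample)."""
    raw = np.asarray(raw, dtype=float)
    if raw[0] <= 0:
        raise ValueError("zero baseline separation")
    return DistanceSeries(landmark=landmark, level=level,
                          times=np.asarray(times, float), raw=raw,
                          baseline=float(raw[0]))


def principal_stresses(stress: np.ndarray) -> np.ndarray:
    """Principal stresses (descending) from [xx, yy, zz, xy] component
    arrays; the out-of-plane direction is principal in plane strain."""
    stress = np.asarray(stress, dtype=float)
    sxx, syy, szz, sxy = (stress[..., i] for i in range(4))
    centre = 0.5 * (sxx + syy)
    radius = np.sqrt(0.25 * (sxx - syy) ** 2 + sxy**2)
    trio = np.stack([centre + radius, centre - radius, szz], axis=-1)
    return -np.sort(-trio, axis=-1)


def von_mises(s1, s2, s3):
    """Von Mises equivalent stress
    sqrt(0.5 [(s1-s2)^2 + (s2-s3)^2 + (s3-s1)^2]); invariant under
    permutation and under a common hydrostatic shift."""
    s1, s2, s3 = (np.asarray(s, dtype=float) for s in (s1, s2, s3))
    return np.sqrt(0.5 * ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2))


def triaxiality(s1, s2, s3):
    """Mean stress and triaxiality ratio T = sigma_m / sigma_VM.

    Returns (sigma_m, T); T is NaN where the stress state is hydrostatic
    (sigma_VM = 0), signalling that the ratio is undefined.
    """
    s1, s2, s3 = (np.asarray(s, dtype=float) for s in (s1, s2, s3))
    sm = (s1 + s2 + s3) / 3.0
    svm = von_mises(s1, s2, s3)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(svm > 0.0, sm / np.where(svm > 0.0, svm, 1.0), np.nan)
    return sm, t


def first_deviatoric_principal_stress(tensor: np.ndarray) -> float:
    """Largest eigenvalue of the stress deviator sigma - sigma_m I.

    Accepts a symmetric 3x3 tensor; quantifies the maximum-shear-dominated
    part of the stress state.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3) or not np.allclose(tensor, tensor.T,
                                                 rtol=1e-8, atol=1e-12):
        raise ValueError("stress tensor must be symmetric 3x3")
    dev = tensor - np.trace(tensor) / 3.0 * np.eye(3)
    return float(np.linalg.eigvalsh(dev)[-1])


def attenuation_percent(protected_peak: float, unprotected_peak: float) -> float:
    """Percent reduction 100 (1 - protected/unprotected).

    Negative values (amplification) are legal and simply reported.
    """
    if unprotected_peak <= 0:
        raise ValueError("unprotected reference peak must be > 0")
    return 100.0 * (1.0 - protected_peak / unprotected_peak)


def mean_abs_deviation(series_list) -> float:
    """Mean absolute deviation of normalised separations from 1 across a set
    of DistanceSeries — the per-level cushioning-stability summary."""
    devs = [np.abs(s.normalized - 1.0) for s in series_list]
    return float(np.mean(np.concatenate(devs)))
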
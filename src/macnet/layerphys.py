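"""Scalar-trace analysis for the membrane interface.

Two measurement families live here:

* RIfS (reflectometric interference spectroscopy) reports the optical
  thickness change dOT = n*d of an adsorbed protein layer; dividing by
  the protein refractive index n_prot gives the physical layer
  thickness d.
* FRAP recovery of a uniformly bleached disc on a supported bilayer
  yields the lipid (or protein) diffusion coefficient and the immobile
  fraction, via the closed-form 2D free-diffusion recovery model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ive

__all__ = [
    "RIfSTrace",
    "FRAPTrace",
    "ProteinLayer",
    "FRAPFitError",
    "ot_to_thickness",
    "binding_amplitude",
    "fit_frap",
]

DEFAULT_N_PROT = 1.455  # refractive index of a compact protein layer


@dataclass
class RIfSTrace:
    """Time course of the optical thickness change dOT (nm)."""

    times_s: np.ndarray
    dOT_nm: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.dOT_nm = np.asarray(self.dOT_nm, dtype=float)
        if self.times_s.shape != self.dOT_nm.shape:
            raise ValueError("times and values must have equal length")
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class FRAPTrace:
    """Normalized mean intensity of a bleached spot over time.

    Pre-bleach intensity is 1 after normalization; ``bleach_index`` is
    the first post-bleach sample.
    """

    times_s: np.ndarray
    spot_intensity: np.ndarray
    bleach_radius_um: float
    bleach_index: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.spot_intensity = np.asarray(self.spot_intensity, dtype=float)
        if self.times_s.shape != self.spot_intensity.shape:
            raise ValueError("times and intensities must have equal length")
        if self.bleach_radius_um <= 0:
            raise ValueError("bleach_radius_um must be positive")
        if not 0 <= self.bleach_index < self.times_s.size:
            raise ValueError("bleach_index out of range")


@dataclass
class ProteinLayer:
    """An adsorbed protein layer characterized by RIfS."""

    dOT_nm: float
    n_prot: float
    d_nm: float


class FRAPFitError(RuntimeError):
    """Raised when the FRAP recovery fit cannot converge or D is unidentifiable."""


def ot_to_thickness(dOT_nm: float, n_prot: float = DEFAULT_N_PROT) -> float:
    """Physical layer thickness d (nm) from optical thickness dOT = n*d.

    >>> round(ot_to_thickness(6.0), 1)
    4.1
    """
    if n_prot <= 1.0:
        raise ValueError("n_prot must exceed 1 (denser than water/buffer)")
    if dOT_nm < 0:
        raise ValueError("dOT_nm must be non-negative")
    return dOT_nm / n_prot


def binding_amplitude(
    trace: RIfSTrace,
    baseline_window: tuple[int, int],
    plateau_window: tuple[int, int],
) -> float:
    """Step height (nm) between two plateaus of a binding trace.

    Uses the median within each index window for outlier robustness.
    Windows are half-open ``[start, stop)`` sample-index ranges, must be
    disjoint and each contain at least 5 samples.
    """
    b0, b1 = baseline_window
    p0, p1 = plateau_window
    if b1 - b0 < 5 or p1 - p0 < 5:
        raise ValueError("each window needs at least 5 samples")
    if not (b1 <= p0 or p1 <= b0):
        raise ValueError("windows must be disjoint")
    return float(np.median(trace.dOT_nm[p0:p1]) - np.median(trace.dOT_nm[b0:b1]))


def _disc_recovery(t: np.ndarray, D: float, radius_um: float) -> np.ndarray:
    # e^-x [I0(x) + I1(x)], x = r^2 / (2 D t): uniform-disc 2D diffusion
    f = np.zeros_like(t)
    pos = t > 0
    x = radius_um**2 / (2.0 * D * t[pos])
    f[pos] = ive(0, x) + ive(1, x)
    return f


def fit_frap(trace: FRAPTrace) -> tuple[float, float]:
    """Fit diffusion coefficient and immobile fraction to a FRAP trace.

    The post-bleach trace is fit by least squares to the uniform-disc
    2D-diffusion recovery model
    ``I(t) = 1 - beta + beta (1 - phi) f(t; D)`` with bleach depth beta,
    immobile fraction phi and the closed-form disc recovery f.  Returns
    ``(D_um2_per_s, immobile_fraction)``.

    Raises
    ------
    FRAPFitError
        If fewer than 20 post-bleach samples are available, the
        optimizer fails, or the trace shows no recovery at all (D is
        then unidentifiable; the immobile fraction is 1).
    """
    i0 = trace.bleach_index
    t = trace.times_s[i0:] - trace.times_s[i0]
    y = trace.spot_intensity[i0:]
    if t.size < 20:
        raise FRAPFitError("need at least 20 post-bleach samples")
    pre = trace.spot_intensity[:i0]
    pre_level = float(np.mean(pre)) if pre.size else 1.0
    y0 = float(np.min(y[: max(1, t.size // 10)]))
    beta0 = max(pre_level - y0, 1e-3)
    plateau = float(np.median(y[-max(5, t.size // 10):]))
    recovered = plateau - y0
    if recovered <= 0.02 * beta0:
        # flat trace: no measurable recovery
        raise FRAPFitError(
            "no recovery detected; D unidentifiable, immobile fraction = 1.0"
        )

    tau0 = max(t[1], trace.bleach_radius_um**2 / 4.0)  # s; rough scale
    phi0 = float(np.clip(1.0 - recovered / beta0, 0.0, 1.0))

    def resid(p: np.ndarray) -> np.ndarray:
        D, phi, beta = p
        model = pre_level - beta + beta * (1.0 - phi) * _disc_recovery(
            t, D, trace.bleach_radius_um
        )
        return model - y

    D0 = trace.bleach_radius_um**2 / (4.0 * tau0)
    try:
        res = least_squares(
            resid,
            x0=np.array([max(D0, 1e-3), phi0, beta0]),
            bounds=([1e-6, 0.0, 1e-6], [np.inf, 1.0, np.inf]),
        )
    except Exception as exc:  # pragma: no cover - scipy internal failure
        raise FRAPFitError(f"FRAP fit failed: {exc}") from exc
    if not res.success:
        raise FRAPFitError(f"FRAP fit did not converge: {res.message}")
    D_hat, phi_hat, _ = res.x
    return float(D_hat), float(phi_hat)


def immobile_fraction_nonparametric(trace: FRAPTrace) -> float:
    """Model-free immobile fraction: 1 - (plateau - min) / (pre - min)."""
    i0 = trace.bleach_index
    y = trace.spot_intensity
    pre = float(np.mean(y[:i0])) if i0 else 1.0
    post = y[i0:]
    ymin = float(np.min(post))
    plateau = float(np.median(post[-max(5, post.size // 10):]))
    denom = pre - ymin
    if denom <= 0:
        return 0.0
    return float(np.clip(1.0 - (plateau - ymin) / denom, 0.0, 1.0))
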
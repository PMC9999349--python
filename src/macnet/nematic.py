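"""Nematic order analysis of filament orientation fields.

The image is tiled into non-overlapping square windows; each window's
dominant orientation comes from its structure tensor (the ridge
direction, i.e. the direction of least gradient variance).  The local
nematic order parameter

    q = 2 <cos^2 theta - 1/2>

is evaluated per window over a kernel of adjacent windows, with theta
measured relative to the local director (principal axis of the mean
nematic tensor of the kernel).  q = 1 marks perfect alignment, q = 0
maximal disorder.  Because the chosen window size strongly influences
q, a window-size sweep selects an operating size on a plateau of the
q_mean(window) curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Micrograph, OrientationField, QMap

__all__ = [
    "orientation_field",
    "local_q",
    "q_mean",
    "window_sweep",
    "nematic_order_of_angles",
]

ENERGY_FLOOR_FRACTION = 0.05  # of the median per-window gradient energy
MIN_VALID_NEIGHBORS = 3


def orientation_field(img: Micrograph, window_px: int) -> OrientationField:
    """Per-window dominant orientation from the structure tensor.

    Intensity gradients are taken with Gaussian-derivative filters at
    scale ``window_px / 4``; the structure tensor (outer product of the
    gradient) is averaged over each non-overlapping ``window_px`` tile.
    The reported angle is the ridge direction — the eigenvector of the
    *smaller* structure-tensor eigenvalue — in [0, pi), measured from
    the +x axis.  Coherence is the normalized eigenvalue anisotropy
    (l1 - l2)/(l1 + l2).  Windows whose total gradient energy falls
    below a floor (5% of the median window energy) are marked invalid.
    """
    if window_px < 4:
        raise ValueError("window_px must be >= 4")
    rows, cols = img.shape
    if window_px > min(rows, cols):
        raise ValueError("window larger than image")

    sigma = window_px / 4.0
    gy = ndimage.gaussian_filter(img.pixels, sigma, order=(1, 0), mode="reflect")
    gx = ndimage.gaussian_filter(img.pixels, sigma, order=(0, 1), mode="reflect")
    jxx, jxy, jyy = gx * gx, gx * gy, gy * gy

    n_wr = -(-rows // window_px)
    n_wc = -(-cols // window_px)

    def window_sum(a: np.ndarray) -> np.ndarray:
        out = np.zeros((n_wr, n_wc))
        for i in range(n_wr):
            for j in range(n_wc):
                out[i, j] = a[
                    i * window_px : (i + 1) * window_px,
                    j * window_px : (j + 1) * window_px,
                ].sum()
        return out

    sxx, sxy, syy = window_sum(jxx), window_sum(jxy), window_sum(jyy)
    energy = sxx + syy
    med = float(np.median(energy))
    valid = energy > max(ENERGY_FLOOR_FRACTION * med, 0.0)
    valid &= energy > 0

    # orientation of maximal gradient variance; ridge is perpendicular
    theta_grad = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)
    angles = (theta_grad + np.pi / 2.0) % np.pi

    root = np.sqrt((sxx - syy) ** 2 + 4.0 * sxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(energy > 0, root / energy, 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)

    return OrientationField(
        window_px=window_px,
        angles=angles,
        coherence=coherence,
        valid=valid,
        pixel_size_um=img.pixel_size_um,
    )


def nematic_order_of_angles(angles: np.ndarray) -> float:
    """q of a bag of pi-periodic angles about their own mean director.

    Computes the director as the principal axis of the mean nematic
    tensor <[cos 2theta, sin 2theta]> and returns
    mean(2 cos^2(theta - director) - 1), which equals the magnitude of
    the mean double-angle resultant vector.
    """
    a = np.asarray(angles, dtype=float).ravel()
    if a.size == 0:
        return float("nan")
    c = np.mean(np.cos(2.0 * a))
    s = np.mean(np.sin(2.0 * a))
    director = 0.5 * np.arctan2(s, c)
    return float(np.mean(2.0 * np.cos(a - director) ** 2 - 1.0))


def local_q(field: OrientationField, kernel: int = 5) -> QMap:
    """Local nematic order per window over a kernel of adjacent windows.

    For each window the valid orientations within the centered
    ``kernel x kernel`` neighborhood are collected and
    ``q = <2 cos^2 theta - 1> = <cos 2 theta>`` is evaluated with theta
    the alignment difference of each neighbor to the local director.
    When the center window is valid it defines the director, so q
    measures how well the adjacent windows align with it: identical
    orientations give q = 1 exactly, and q averages to zero for
    orientations drawn uniformly on [0, pi) — the maximal-disorder
    limit.  (Referencing the director to the mean nematic tensor of the
    kernel instead would inflate q by the finite-sample bias of the
    resultant length, ~0.18 for a 5x5 kernel, and could never reach the
    isotropic limit.)  For invalid center windows the kernel's mean
    nematic tensor supplies the director.  Windows with fewer than 3
    valid neighbors are undefined (NaN) and excluded from
    :func:`q_mean`.
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 3")
    ang = field.angles
    val = field.valid.astype(float)
    c2 = np.cos(2.0 * ang) * val
    s2 = np.sin(2.0 * ang) * val
    k = np.ones((kernel, kernel))
    conv = lambda a: ndimage.convolve(a, k, mode="constant", cval=0.0)
    C, S, N = conv(c2), conv(s2), conv(val)

    q = np.full(ang.shape, np.nan)
    # center valid: director = center orientation; exclude the center
    # window's trivial self-term from the average
    cen = field.valid
    n_nb = N - 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        q_center = (C * np.cos(2.0 * ang) + S * np.sin(2.0 * ang) - 1.0) / n_nb
    ok = cen & (n_nb >= MIN_VALID_NEIGHBORS)
    q[ok] = q_center[ok]
    # center invalid: director from the kernel's mean nematic tensor,
    # q reduces to the resultant length of the neighbor orientations
    with np.errstate(invalid="ignore", divide="ignore"):
        q_res = np.sqrt(C**2 + S**2) / N
    ok2 = (~cen) & (N >= MIN_VALID_NEIGHBORS)
    q[ok2] = q_res[ok2]
    return QMap(q=np.clip(q, -1.0, 1.0), kernel=kernel)


def q_mean(qmap: QMap, include_undefined_as_zero: bool = False) -> float:
    """Mean nematic order parameter over the defined windows.

    With ``include_undefined_as_zero`` background/undefined windows
    count as fully disordered (q = 0) instead of being excluded.
    """
    q = qmap.q
    defined = np.isfinite(q)
    if not defined.any():
        raise ValueError("q_mean requires at least one defined window")
    if include_undefined_as_zero:
        return float(np.nansum(q) / q.size)
    return float(np.mean(q[defined]))


@dataclass
class WindowSweepResult:
    """q_mean(window size) curve and the selected operating size."""

    window_um: np.ndarray
    q_mean: np.ndarray
    selected_window_um: float


def window_sweep(
    img: Micrograph,
    window_sizes_um: "list[float] | np.ndarray",
    kernel: int = 5,
    band_um: tuple[float, float] = (1.0, 2.0),
    plateau_slope: float = 0.02,
    fallback_um: float = 1.5,
) -> WindowSweepResult:
    """q_mean as a function of window size, with plateau-based selection.

    The selected size is the smallest window inside ``band_um`` where
    the step-to-step change of q_mean falls below ``plateau_slope``;
    if no window qualifies, ``fallback_um`` (clamped into the band)
    is used.
    """
    sizes = np.asarray(sorted(window_sizes_um), dtype=float)
    qs = []
    for s_um in sizes:
        wpx = max(4, int(round(s_um / img.pixel_size_um)))
        f = orientation_field(img, wpx)
        qs.append(q_mean(local_q(f, kernel)))
    qs = np.asarray(qs)

    selected = None
    for k in range(1, len(sizes)):
        s = sizes[k]
        if band_um[0] <= s <= band_um[1] and abs(qs[k] - qs[k - 1]) < plateau_slope:
            selected = float(s)
            break
    if selected is None:
        in_band = sizes[(sizes >= band_um[0]) & (sizes <= band_um[1])]
        selected = float(in_band[0]) if in_band.size else float(
            np.clip(fallback_um, *band_um)
        )
    return WindowSweepResult(window_um=sizes, q_mean=qs, selected_window_um=selected)
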
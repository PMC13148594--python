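"""Dark-field contrast images and objective q-range selection.

A dark-field contrast image maps each scan point to the summed detector
counts inside a q-annulus.  Fast raster scans with millisecond exposures
are noisy, and additive stripe noise along the fast-scan axis enters at
high q; the upper q-bound therefore trades signal for noise.  The bound
is chosen objectively: dark-field images are computed for a ladder of
upper bounds, each is normalized to [0, 1], the mean (absolute)
deviation (MD) of a featureless background rectangle is taken as the
noise metric, the MD-vs-q curve is smoothed with a moving average, and
the q at its minimum is the optimum q_opt.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import QMap, annular_selection
from .scan_io import ScanStack


@dataclass
class DarkFieldImage:
    """ny×nz dark-field contrast image over a q-range (nm⁻¹)."""

    values: np.ndarray
    q_range: tuple[float, float]
    normalized: bool = False


@dataclass(frozen=True)
class BackgroundRegion:
    """Rectangular featureless region on the scan grid.

    (row0, col0) is the top-left corner; a × b its side lengths in scan
    pixels (rows × cols).
    """

    row0: int
    col0: int
    a: int
    b: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0 or self.a < 1 or self.b < 1:
            raise ValueError("region must have non-negative origin, sides >= 1")
        if self.a * self.b < 2:
            raise ValueError("region must contain at least 2 scan pixels")

    def slices(self, grid_shape: tuple[int, int]) -> tuple[slice, slice]:
        if self.row0 + self.a > grid_shape[0] or self.col0 + self.b > grid_shape[1]:
            raise ValueError(
                f"region {self} exceeds scan grid {grid_shape}"
            )
        return (slice(self.row0, self.row0 + self.a),
                slice(self.col0, self.col0 + self.b))


@dataclass
class MDCurve:
    """Mean-deviation noise metric vs. upper q-bound.

    ``md_raw`` may contain NaN where the annulus [q_lo, q_hi) holds no
    valid pixel (e.g. entirely behind the beamstop); such entries are
    excluded from smoothing and minimum selection.
    """

    q_upper: np.ndarray
    md_raw: np.ndarray
    md_smoothed: np.ndarray | None = None
    window: int | None = None
    q_opt: float | None = None
    q_lo: float = 0.0


def darkfield_image(
    stack: ScanStack, qmap: QMap, q_lo: float, q_hi: float
) -> DarkFieldImage:
    """Sum counts over the [q_lo, q_hi) annulus at every scan point."""
    sel = annular_selection(qmap, q_lo, q_hi)
    if not sel.any():
        raise ValueError(
            f"annulus [{q_lo}, {q_hi}) nm^-1 selects no valid detector pixel"
        )
    n_rows, n_cols = stack.grid_shape
    flat = stack.frames.reshape(n_rows * n_cols, -1)[:, sel.ravel()]
    values = flat.sum(axis=1, dtype=np.float64).reshape(n_rows, n_cols)
    return DarkFieldImage(values=values, q_range=(q_lo, q_hi))


def normalize01(image: DarkFieldImage) -> DarkFieldImage:
    """Min–max normalize to [0, 1]; a constant image maps to all zeros."""
    v = image.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        out = np.zeros_like(v, dtype=float)
    else:
        out = (v - lo) / (hi - lo)
    return DarkFieldImage(values=out, q_range=image.q_range, normalized=True)


def mean_deviation(image: DarkFieldImage, region: BackgroundRegion) -> float:
    """Mean absolute deviation of a normalized image over a region.

    MD = (1/(a·b)) Σ |I − Ī| with Ī the region mean.  For a normalized
    image this lies in [0, 0.5] and acts as an inverse signal-to-noise
    proxy of the dark-field image.
    """
    if not image.normalized:
        raise ValueError("mean_deviation expects a normalized dark-field image")
    sl = region.slices(image.values.shape)
    patch = image.values[sl]
    return float(np.abs(patch - patch.mean()).mean())


def md_curve(
    stack: ScanStack,
    qmap: QMap,
    region: BackgroundRegion,
    q_lo: float = 0.0,
    q_step: float = 0.003,
    q_max: float | None = None,
) -> MDCurve:
    """MD of the background region vs. upper q-bound.

    Upper bounds run over q_lo + q_step, q_lo + 2·q_step, … ≤ q_max.
    Internally the per-frame counts are histogrammed once into the
    q-grid annuli and accumulated, which is exactly equivalent to
    recomputing each dark-field image from scratch.
    """
    if q_step <= 0:
        raise ValueError("q_step must be > 0")
    if q_max is None:
        q_max = float(qmap.q_magnitude[qmap.valid_mask].max())
    n = int(np.floor((q_max - q_lo) / q_step + 1e-9))
    if n < 1:
        raise ValueError(
            f"empty MD curve: q_max={q_max} leaves no grid point above "
            f"q_lo={q_lo} at step {q_step}"
        )
    q_upper = q_lo + q_step * np.arange(1, n + 1)

    valid = qmap.valid_mask
    qv = qmap.q_magnitude[valid]
    # annulus index of each valid pixel: edges q_lo, q_lo+step, ...
    # pixels below q_lo or >= last edge fall outside every [q_lo, q_hi)
    idx = np.floor((qv - q_lo) / q_step).astype(int)
    inside = (qv >= q_lo) & (idx >= 0) & (idx < n)
    idx = idx[inside]

    n_rows, n_cols = stack.grid_shape
    flat = stack.frames.reshape(n_rows * n_cols, -1)[:, valid.ravel()][:, inside]
    # per-scan-point counts in each annulus, then cumulative over annuli
    per_annulus = np.zeros((n_rows * n_cols, n))
    np.add.at(per_annulus.T, idx, flat.T)
    cumulative = per_annulus.cumsum(axis=1)  # (scan point, q_upper)

    pixel_counts = np.bincount(idx, minlength=n).cumsum()
    md = np.full(n, np.nan)
    sl = region.slices((n_rows, n_cols))
    for k in range(n):
        if pixel_counts[k] == 0:
            continue  # annulus chain still empty: MD undefined
        img = DarkFieldImage(cumulative[:, k].reshape(n_rows, n_cols),
                             (q_lo, float(q_upper[k])))
        md[k] = mean_deviation(normalize01(img), region)
    return MDCurve(q_upper=q_upper, md_raw=md, q_lo=q_lo)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated at the ends, NaN-aware."""
    finite = np.isfinite(values)
    v = np.where(finite, values, 0.0)
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    out = np.full_like(v, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    out[~finite] = np.nan
    return out


def _elbow_window(md_raw: np.ndarray, w_max: int) -> int:
    """Pick the smoothing window by the geometric elbow criterion.

    For candidate odd windows 1, 3, …, w_max, the RMS difference between
    smoothed and raw curves grows with window size; the elbow is the
    candidate at maximum perpendicular distance from the chord joining
    the curve's endpoints.
    """
    candidates = np.arange(1, w_max + 1, 2)
    finite = np.isfinite(md_raw)
    rms = np.array([
        float(np.sqrt(np.nanmean((_moving_average(md_raw, w) - md_raw)[finite] ** 2)))
        for w in candidates
    ])
    x = candidates.astype(float)
    y = rms
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    if norm == 0:
        return 1
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    return int(candidates[int(np.argmax(dist))])


def smooth_and_select(
    curve: MDCurve, window: int | str = "auto"
) -> MDCurve:
    """Smooth the MD curve and select q_opt at its global minimum.

    The smoother is a centered moving average truncated at the curve
    ends.  ``window="auto"`` chooses the window by the elbow criterion;
    an even window is widened to the next odd value.  Ties at the
    minimum break toward the smallest q, minimizing included noise.
    """
    n = len(curve.q_upper)
    if window == "auto":
        w = _elbow_window(curve.md_raw, min(n if n % 2 else n - 1, 101))
    else:
        w = int(window)
        if w < 1:
            raise ValueError("window must be >= 1")
        if w % 2 == 0:
            w += 1
        if w > n:
            raise ValueError(f"window {w} exceeds curve length {n}")
    smoothed = _moving_average(curve.md_raw, w)
    if not np.isfinite(smoothed).any():
        raise ValueError("MD curve contains no defined values")
    k = int(np.nanargmin(smoothed))
    return MDCurve(
        q_upper=curve.q_upper, md_raw=curve.md_raw, md_smoothed=smoothed,
        window=w, q_opt=float(curve.q_upper[k]), q_lo=curve.q_lo,
    )


def md_curve_to_frame(curve: MDCurve):
    """MD curve as a pandas DataFrame (q_upper, md_raw, md_smoothed)."""
    import pandas as pd

    return pd.DataFrame({
        "q_upper": curve.q_upper,
        "md_raw": curve.md_raw,
        "md_smoothed": (curve.md_smoothed if curve.md_smoothed is not None
                        else np.full_like(curve.q_upper, np.nan)),
    })
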
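"""The Progressive Moving Average Transform (PMAT) and its building blocks.

A moving average (MA) of window size ``w`` over a signal of length ``n``
yields ``n - w + 1`` values, i.e. a shorter signal.  Padding the MA series
back to length ``n`` — repeating the first mean on the left, the last mean
on the right, or splitting the padding between both sides — gives the
left-, right- and centered-padded moving averages (LPMA/RPMA/CPMA).
Stacking the padded series for every window size ``w = 1 .. w_max`` (the
``w = 1`` row being the raw signal) produces a 2-D matrix whose axes are
window size and time: the PMAT.  Rendered as an image it plays the role a
scalogram or spectrogram plays for wavelet or Fourier analysis, but is
built from nothing more than arithmetic means.

All public indices follow the 1-based convention of the defining formulas;
arrays are stored 0-based with row ``r`` holding window size ``w = r + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.transform import resize as _skimage_resize

Variant = Literal["left", "right", "centered"]

_VARIANTS = ("left", "right", "centered")


def _as_signal(x) -> np.ndarray:
    """Validate and return ``x`` as a 1-D float array of length >= 2."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"signal must be 1-D, got shape {arr.shape}")
    if arr.size < 2:
        raise ValueError(f"signal length must be > 1, got n={arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("signal contains non-finite samples")
    return arr


def _check_window(w: int, n: int) -> None:
    if not (2 <= w <= n):
        raise ValueError(f"window size w={w} out of range [2, n={n}]")


def moving_average(x, j: int, w: int) -> float:
    """Mean of the ``w`` consecutive samples of ``x`` starting at 1-based ``j``.

    ``j`` must lie in ``[1, n - w + 1]`` and ``w`` in ``[2, n]``.
    """
    arr = _as_signal(x)
    n = arr.size
    _check_window(w, n)
    if not (1 <= j <= n - w + 1):
        raise ValueError(f"start index j={j} out of range [1, n-w+1={n - w + 1}]")
    return float(arr[j - 1 : j - 1 + w].mean())


def moving_average_series(x, w: int) -> np.ndarray:
    """All ``n - w + 1`` consecutive window-``w`` means of ``x``, in order.

    Computed with a cumulative sum; agrees with direct summation to
    ~1e-12 relative error (checked in the test suite).
    """
    arr = _as_signal(x)
    _check_window(w, arr.size)
    csum = np.concatenate(([0.0], np.cumsum(arr)))
    return (csum[w:] - csum[:-w]) / w


def lpma(x, w: int) -> np.ndarray:
    """Left-padded moving average: length-``n`` series.

    Positions ``k <= w`` repeat the first mean; position ``k > w`` holds the
    mean starting at ``k - w + 1``.
    """
    ma = moving_average_series(x, w)
    return np.concatenate((np.full(w, ma[0]), ma[1:]))


def rpma(x, w: int) -> np.ndarray:
    """Right-padded moving average: length-``n`` series.

    Position ``k <= n - w`` holds the mean starting at ``k``; positions
    ``k > n - w`` repeat the last mean.
    """
    ma = moving_average_series(x, w)
    return np.concatenate((ma[:-1], np.full(w, ma[-1])))


def cpma(x, w: int) -> np.ndarray:
    """Centered-padded moving average: length-``n`` series.

    The padding of ``w - 1`` copies is split as ``floor((w-1)/2) + p`` on the
    left and ``floor((w-1)/2)`` on the right, with ``p = 1`` for even ``w``
    and ``0`` otherwise.
    """
    ma = moving_average_series(x, w)
    p = 1 if w % 2 == 0 else 0
    left = (w - 1) // 2 + p
    right = (w - 1) // 2
    return np.concatenate((np.full(left, ma[0]), ma, np.full(right, ma[-1])))


_PAD_FUNCS = {"left": lpma, "right": rpma, "centered": cpma}


@dataclass
class PMATMatrix:
    """2-D PMAT output: row ``r`` (0-based) holds window size ``w = r + 1``.

    The defining formulas print window size descending top-to-bottom; this
    container stores it ascending (row index = w - 1), flipping only for
    display.
    """

    values: np.ndarray
    variant: Variant
    w_max: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.w_max:
            raise ValueError(
                f"expected {self.w_max} rows, got shape {self.values.shape}"
            )
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def row(self, w: int) -> np.ndarray:
        """The series for window size ``w`` (1-based)."""
        if not (1 <= w <= self.w_max):
            raise ValueError(f"w={w} out of range [1, w_max={self.w_max}]")
        return self.values[w - 1]

    def entry(self, w: int, i: int) -> float:
        """Entry at window size ``w`` and 1-based time index ``i``."""
        if not (1 <= i <= self.n):
            raise ValueError(f"time index i={i} out of range [1, n={self.n}]")
        return float(self.row(w)[i - 1])

    def display(self) -> np.ndarray:
        """Matrix as printed: window size descending top-to-bottom."""
        return self.values[::-1]


def pmat(x, w_max: int | None = None, variant: Variant = "left") -> PMATMatrix:
    """Progressive Moving Average Transform of ``x``.

    Row ``w = 1`` is the signal itself; row ``w > 1`` is the padded moving
    average of the chosen variant.  ``w_max`` defaults to ``n`` (all scales,
    a square matrix), and must lie in ``[1, n]``.
    """
    arr = _as_signal(x)
    n = arr.size
    if w_max is None:
        w_max = n
    if not (1 <= w_max <= n):
        raise ValueError(f"w_max={w_max} out of range [1, n={n}]")
    if variant not in _PAD_FUNCS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {_VARIANTS}")
    fn = _PAD_FUNCS[variant]
    rows = np.empty((w_max, n), dtype=float)
    rows[0] = arr
    for w in range(2, w_max + 1):
        rows[w - 1] = fn(arr, w)
    return PMATMatrix(values=rows, variant=variant, w_max=w_max)


def resize_image(m, height: int, width: int) -> np.ndarray:
    """Bilinear resize of a PMAT matrix (or any 2-D array) to height x width.

    Anti-aliasing is off; output values stay within the convex hull of the
    input values, hence within ``[min, max]`` of the source.  Identity when
    the target equals the source dimensions.
    """
    arr = m.values if isinstance(m, PMATMatrix) else np.asarray(m, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D input, got shape {arr.shape}")
    if height < 1 or width < 1:
        raise ValueError(f"target size {height}x{width} must be positive")
    if arr.shape == (height, width):
        return arr.copy()
    return _skimage_resize(
        arr,
        (height, width),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
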
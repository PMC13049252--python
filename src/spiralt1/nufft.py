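"""Non-uniform Fourier transforms for spiral sampling.

Two implementations of the same transform:

* :func:`nudft_forward` / :func:`nudft_adjoint` — direct summation, exact,
  O(N^2 M).  Restricted to small grids; used as the oracle.
* :class:`GriddingNUFFT` — Kaiser-Bessel gridding on a 2x-oversampled FFT
  grid with a sparse interpolation matrix.  The adjoint is the conjugate
  transpose of the same matrix, so the operator pair is exactly adjoint by
  construction.

Coordinate convention (fixed for bit-reproducibility): image pixel indices
are centered, ``x = index - N // 2``; k-space coordinates are in cycles per
field of view; the forward transform uses a negative exponent,

    s_j = sum_x I(x) exp(-2 pi i (kx_j * x + ky_j * y) / N).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numpy.fft import fft2, fftshift, ifft2, ifftshift
from scipy.special import i0

_ORACLE_MAX_GRID = 64


def _centered_freqs(n: int) -> np.ndarray:
    return np.arange(n, dtype=float) - n // 2


def nudft_forward(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Direct non-uniform DFT of a 2D image at ``coords`` (cycles/FOV).

    Exact summation; grids larger than 64x64 are refused — use
    :class:`GriddingNUFFT` for production sizes.
    """
    ny, nx = image.shape
    if max(ny, nx) > _ORACLE_MAX_GRID:
        raise ValueError(
            f"direct NUDFT limited to {_ORACLE_MAX_GRID}x{_ORACLE_MAX_GRID} "
            "grids; use GriddingNUFFT for larger images"
        )
    y = _centered_freqs(ny)
    x = _centered_freqs(nx)
    kx = np.asarray(coords)[:, 0]
    ky = np.asarray(coords)[:, 1]
    # separable phase: (M, ny) @ (ny, nx) * ... done as two matmuls
    ey = np.exp(-2j * np.pi * np.outer(ky, y) / ny)
    ex = np.exp(-2j * np.pi * np.outer(kx, x) / nx)
    return np.einsum("my,yx,mx->m", ey, image.astype(complex), ex, optimize=True)


def nudft_adjoint(
    samples: np.ndarray, coords: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Adjoint of :func:`nudft_forward` (positive-exponent summation)."""
    ny, nx = shape
    if max(ny, nx) > _ORACLE_MAX_GRID:
        raise ValueError(
            f"direct NUDFT limited to {_ORACLE_MAX_GRID}x{_ORACLE_MAX_GRID} "
            "grids; use GriddingNUFFT for larger images"
        )
    y = _centered_freqs(ny)
    x = _centered_freqs(nx)
    kx = np.asarray(coords)[:, 0]
    ky = np.asarray(coords)[:, 1]
    ey = np.exp(2j * np.pi * np.outer(y, ky) / ny)
    ex = np.exp(2j * np.pi * np.outer(x, kx) / nx)
    return np.einsum("ym,m,xm->yx", ey, samples.astype(complex), ex, optimize=True)


def _kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel interpolation kernel on the open support (-w/2, w/2).

    The support is open: I0 does not vanish at the band edge, and keeping
    the edge point would truncate the tap set asymmetrically for integer
    coordinates, breaking the exactness of interpolation + deapodization
    at on-grid frequencies.
    """
    mask = np.abs(u) < width / 2.0
    arg = np.zeros_like(u, dtype=float)
    frac = 1.0 - (2.0 * u[mask] / width) ** 2
    arg[mask] = i0(beta * np.sqrt(np.maximum(frac, 0.0)))
    return arg


class GriddingNUFFT:
    """Kaiser-Bessel gridding NUFFT for one set of k-space coordinates.

    Parameters
    ----------
    coords : (M, 2) k-space coordinates in cycles/FOV.
    shape : image shape (ny, nx); square grids only.
    oversamp : grid oversampling factor (default 2.0).
    width : interpolation kernel width in oversampled-grid units (default 6).

    The kernel shape parameter follows Beatty's minimal-aliasing rule.  The
    apodization (deapodization) function is computed as the inverse DFT of
    the sampled kernel, which makes interpolation exact at integer grid
    frequencies.
    """

    def __init__(
        self,
        coords: np.ndarray,
        shape: tuple[int, int],
        oversamp: float = 2.0,
        width: int = 6,
    ):
        ny, nx = shape
        if ny != nx:
            raise ValueError("square image grids only")
        self.shape = (ny, nx)
        n = ny
        g = int(round(oversamp * n))
        g += g % 2  # even oversampled grid
        self.grid = g
        self.width = width
        self.beta = np.pi * np.sqrt(
            max((width / oversamp) ** 2 * (oversamp - 0.5) ** 2 - 0.8, 0.0)
        )
        self.coords = np.asarray(coords, dtype=float)
        self._interp = self._build_interp_matrix()
        self._apod = self._build_apodization()

    def _build_interp_matrix(self) -> sp.csr_matrix:
        g, w = self.grid, self.width
        n = self.shape[0]
        # cycles/FOV -> oversampled-grid frequency units, centered at g//2
        u = self.coords * (g / n) + g // 2
        m = u.shape[0]
        offsets = np.arange(w)
        # (M, 2): w taps centered on u, floor(u) - w/2 + 1 .. floor(u) + w/2
        base = np.floor(u).astype(int) - w // 2 + 1
        rows, cols, vals = [], [], []
        colx = (base[:, 0, None] + offsets[None, :]) % g  # (M, w)
        coly = (base[:, 1, None] + offsets[None, :]) % g
        wx = _kb_kernel(
            base[:, 0, None] + offsets[None, :] - u[:, 0, None], w, self.beta
        )
        wy = _kb_kernel(
            base[:, 1, None] + offsets[None, :] - u[:, 1, None], w, self.beta
        )
        # outer product of the two 1D kernels per sample
        vals = (wy[:, :, None] * wx[:, None, :]).reshape(m, -1)
        cols = (coly[:, :, None] * g + colx[:, None, :]).reshape(m, -1)
        rows = np.repeat(np.arange(m), w * w)
        mat = sp.csr_matrix(
            (vals.ravel(), (rows, cols.ravel())), shape=(m, g * g)
        )
        mat.sum_duplicates()
        return mat

    def _build_apodization(self) -> np.ndarray:
        g, n = self.grid, self.shape[0]
        # sampled kernel on the centered oversampled grid
        u = _centered_freqs(g)
        kb = _kb_kernel(u, self.width, self.beta)
        q = np.real(fftshift(np.fft.ifft(ifftshift(kb)))) * g
        lo = g // 2 - n // 2
        q2 = np.outer(q[lo : lo + n], q[lo : lo + n])
        return q2

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Evaluate the forward transform at the stored coordinates."""
        n, g = self.shape[0], self.grid
        lo = g // 2 - n // 2
        padded = np.zeros((g, g), dtype=complex)
        padded[lo : lo + n, lo : lo + n] = image / self._apod
        spectrum = fftshift(fft2(ifftshift(padded)))
        return self._interp @ spectrum.ravel()

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        n, g = self.shape[0], self.grid
        lo = g // 2 - n // 2
        spectrum = (self._interp.conj().T @ samples).reshape(g, g)
        padded = fftshift(ifft2(ifftshift(spectrum))) * (g * g)
        return padded[lo : lo + n, lo : lo + n] / self._apod
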
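"""Kaiser-Bessel gridding engine for non-Cartesian k-space.

Implements the classic convolution-gridding pair:

* adjoint (reconstruction) transform — spread weighted samples onto an
  oversampled Cartesian grid, inverse FFT, deapodise by the kernel's
  analytic transform, crop;
* forward transform (used by the raster-mode simulator) — the exact
  conjugate-transpose of the adjoint: deapodise, zero-pad, FFT, interpolate
  back at the sample positions.

k-space coordinates are cycles/m; density-compensation weights carry the
k-space volume element, so the adjoint approximates the continuous inverse
Fourier integral and reconstructed values keep the physical units of the
simulated signal density (mM after relaxation weighting).

The inner spreading/interpolation loops are numba-compiled; everything else
is numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["GridSpec", "grid_samples", "degrid_samples",
           "adjoint_nufft", "forward_nufft", "kb_transform"]

_TABLE_LEN = 2048


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the oversampled gridding problem."""

    n: int                 # image matrix size per axis
    fov_m: float           # field of view, m
    oversampling: float = 1.5
    kernel_width: int = 4  # in oversampled grid units

    @classmethod
    def for_protocol(cls, protocol, oversampling: float = 1.5,
                     kernel_width: int = 4) -> "GridSpec":
        return cls(n=protocol.grid_size, fov_m=protocol.fov_mm * 1e-3,
                   oversampling=oversampling, kernel_width=kernel_width)

    @property
    def n_os(self) -> int:
        m = int(np.ceil(self.n * self.oversampling))
        return m + (m % 2)

    @property
    def os_actual(self) -> float:
        return self.n_os / self.n

    @property
    def beta(self) -> float:
        # standard width/oversampling prescription for the KB shape parameter
        w, a = self.kernel_width, self.os_actual
        return np.pi * np.sqrt((w / a) ** 2 * (a - 0.5) ** 2 - 0.8)

    @property
    def delta_k(self) -> float:
        """Oversampled grid spacing in cycles/m."""
        return 1.0 / (self.fov_m * self.os_actual)

    def kernel_table(self) -> np.ndarray:
        """Sampled KB kernel I0(beta*sqrt(1-(2u/W)^2)) on u in [0, W/2]."""
        u = np.linspace(0.0, 1.0, _TABLE_LEN)
        return np.i0(self.beta * np.sqrt(np.maximum(1.0 - u ** 2, 0.0)))

    def to_grid_units(self, k: np.ndarray) -> np.ndarray:
        return k / self.delta_k + self.n_os / 2.0


def kb_transform(xi: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Analytic Fourier transform of the KB kernel at xi cycles/grid-unit.

    Continuous pair of I0(beta*sqrt(1-(2u/W)^2)) on |u| <= W/2; past the
    kernel's numerical bandwidth the sinh argument turns imaginary and the
    expression continues as sin(x)/x.
    """
    z2 = beta ** 2 - (np.pi * width * np.asarray(xi, dtype=float)) ** 2
    out = np.empty_like(z2)
    pos = z2 > 0
    zp = np.sqrt(z2[pos])
    out[pos] = np.sinh(zp) / zp
    zn = np.sqrt(-z2[~pos])
    with np.errstate(invalid="ignore"):
        out[~pos] = np.where(zn > 0, np.sin(zn) / np.maximum(zn, 1e-300), 1.0)
    return width * out


@njit(fastmath=True)
def _spread3(u, vals_re, vals_im, grid_re, grid_im, table, width):  # pragma: no cover
    n = grid_re.shape[0]
    half = width / 2.0
    scale = (_TABLE_LEN - 1) / half
    for i in range(u.shape[0]):
        ux, uy, uz = u[i, 0], u[i, 1], u[i, 2]
        x0 = int(np.ceil(ux - half))
        y0 = int(np.ceil(uy - half))
        z0 = int(np.ceil(uz - half))
        for dx in range(width):
            gx = x0 + dx
            ax = abs(gx - ux)
            if ax >= half:
                continue
            gx = gx % n  # periodic wrap: aliases land outside the cropped FOV
            tx = ax * scale
            ix = int(tx)
            wx = table[ix] + (tx - ix) * (table[min(ix + 1, _TABLE_LEN - 1)] - table[ix])
            for dy in range(width):
                gy = y0 + dy
                ay = abs(gy - uy)
                if ay >= half:
                    continue
                gy = gy % n
                ty = ay * scale
                iy = int(ty)
                wy = table[iy] + (ty - iy) * (table[min(iy + 1, _TABLE_LEN - 1)] - table[iy])
                wxy = wx * wy
                for dz in range(width):
                    gz = z0 + dz
                    az = abs(gz - uz)
                    if az >= half:
                        continue
                    gz = gz % n
                    tz = az * scale
                    iz = int(tz)
                    wz = table[iz] + (tz - iz) * (table[min(iz + 1, _TABLE_LEN - 1)] - table[iz])
                    wgt = wxy * wz
                    grid_re[gx, gy, gz] += wgt * vals_re[i]
                    grid_im[gx, gy, gz] += wgt * vals_im[i]


@njit(fastmath=True)
def _interp3(u, grid_re, grid_im, out_re, out_im, table, width):  # pragma: no cover
    n = grid_re.shape[0]
    half = width / 2.0
    scale = (_TABLE_LEN - 1) / half
    for i in range(u.shape[0]):
        ux, uy, uz = u[i, 0], u[i, 1], u[i, 2]
        x0 = int(np.ceil(ux - half))
        y0 = int(np.ceil(uy - half))
        z0 = int(np.ceil(uz - half))
        acc_re = 0.0
        acc_im = 0.0
        for dx in range(width):
            gx = x0 + dx
            ax = abs(gx - ux)
            if ax >= half:
                continue
            gx = gx % n
            tx = ax * scale
            ix = int(tx)
            wx = table[ix] + (tx - ix) * (table[min(ix + 1, _TABLE_LEN - 1)] - table[ix])
            for dy in range(width):
                gy = y0 + dy
                ay = abs(gy - uy)
                if ay >= half:
                    continue
                gy = gy % n
                ty = ay * scale
                iy = int(ty)
                wy = table[iy] + (ty - iy) * (table[min(iy + 1, _TABLE_LEN - 1)] - table[iy])
                wxy = wx * wy
                for dz in range(width):
                    gz = z0 + dz
                    az = abs(gz - uz)
                    if az >= half:
                        continue
                    gz = gz % n
                    tz = az * scale
                    iz = int(tz)
                    wz = table[iz] + (tz - iz) * (table[min(iz + 1, _TABLE_LEN - 1)] - table[iz])
                    wgt = wxy * wz
                    acc_re += wgt * grid_re[gx, gy, gz]
                    acc_im += wgt * grid_im[gx, gy, gz]
        out_re[i] = acc_re
        out_im[i] = acc_im


def grid_samples(points: np.ndarray, values: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Spread complex sample values onto the oversampled Cartesian grid."""
    u = spec.to_grid_units(np.ascontiguousarray(points, dtype=np.float64))
    v = np.ascontiguousarray(values, dtype=np.complex128)
    n = spec.n_os
    gr = np.zeros((n, n, n))
    gi = np.zeros((n, n, n))
    _spread3(u, np.ascontiguousarray(v.real), np.ascontiguousarray(v.imag),
             gr, gi, spec.kernel_table(), spec.kernel_width)
    return gr + 1j * gi


def degrid_samples(grid: np.ndarray, points: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Interpolate a Cartesian k-space grid back at sample positions."""
    u = spec.to_grid_units(np.ascontiguousarray(points, dtype=np.float64))
    m = len(u)
    out_re = np.empty(m)
    out_im = np.empty(m)
    _interp3(u, np.ascontiguousarray(grid.real), np.ascontiguousarray(grid.imag),
             out_re, out_im, spec.kernel_table(), spec.kernel_width)
    return out_re + 1j * out_im


def _deapodization(spec: GridSpec) -> np.ndarray:
    j = np.arange(spec.n) - spec.n // 2
    xi = j / spec.n_os
    d = kb_transform(xi, spec.kernel_width, spec.beta)
    return d[:, None, None] * d[None, :, None] * d[None, None, :]


def adjoint_nufft(points: np.ndarray, values: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Evaluate sum_i v_i * exp(+2*pi*i k_i . x) on the image grid.

    Image pixel x runs over ``(j - n/2) * fov / n`` per axis.  With values
    pre-multiplied by density-compensation volumes this approximates the
    continuous inverse Fourier integral.
    """
    grid = grid_samples(points, values, spec)
    img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid))) * spec.n_os ** 3
    lo = spec.n_os // 2 - spec.n // 2
    hi = lo + spec.n
    img = img[lo:hi, lo:hi, lo:hi]
    return img / _deapodization(spec)


def forward_nufft(image: np.ndarray, points: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Evaluate sum_j image_j * exp(-2*pi*i k_i . x_j) at the sample points.

    Exact conjugate-transpose of :func:`adjoint_nufft` (same kernel, same
    deapodisation), so the pair passes adjointness tests to rounding noise.
    """
    if image.shape != (spec.n,) * 3:
        raise ValueError(f"image shape {image.shape} does not match spec n={spec.n}")
    padded = np.zeros((spec.n_os,) * 3, dtype=complex)
    lo = spec.n_os // 2 - spec.n // 2
    hi = lo + spec.n
    padded[lo:hi, lo:hi, lo:hi] = image / _deapodization(spec)
    ksp = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(padded)))
    return degrid_samples(ksp, points, spec)
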
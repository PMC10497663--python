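"""Morlet continuous wavelet transform and cross-wavelet transform.

The transform follows the standard FFT formulation: the analysed series is
mean-centered, zero-padded to the next power of two, and for each scale the
coefficients are the inverse FFT of the series spectrum multiplied by the
conjugate of the scaled Morlet window, with unit-energy scale normalisation
sqrt(2*pi*s/dt).  Scales map to Fourier periods through the factor
4*pi/(omega0 + sqrt(2 + omega0**2)).

The cross-wavelet transform of the two performers' speed series is
Wxy = Wx * conj(Wy) with the pianist fixed as the first channel; its
modulus is the coordination power, its argument the phase difference whose
sign encodes who leads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import SpeedSeries

__all__ = [
    "ScaleGrid",
    "XwtField",
    "morlet_fourier_factor",
    "morlet_cwt",
    "cross_wavelet",
    "time_average_power",
]

DEFAULT_OMEGA0 = 6.0
DEFAULT_DJ = 1.0 / 20.0


def morlet_fourier_factor(omega0: float = DEFAULT_OMEGA0) -> float:
    """Ratio of Fourier period to wavelet scale for the Morlet wavelet."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


@dataclass(frozen=True)
class ScaleGrid:
    """Geometric grid of periods with ``dj`` sub-octave spacing."""

    periods_s: np.ndarray
    dj: float
    omega0: float = DEFAULT_OMEGA0

    def __post_init__(self) -> None:
        p = np.asarray(self.periods_s, dtype=float)
        if p.ndim != 1 or len(p) < 2:
            raise ValueError("need at least two periods")
        if np.any(np.diff(p) <= 0):
            raise ValueError("periods must be strictly increasing")
        ratios = p[1:] / p[:-1]
        if not np.allclose(ratios, 2.0**self.dj, rtol=1e-8):
            raise ValueError("consecutive period ratio must equal 2**dj")
        object.__setattr__(self, "periods_s", p)

    @classmethod
    def from_range(
        cls,
        low_s: float,
        high_s: float,
        dj: float = DEFAULT_DJ,
        omega0: float = DEFAULT_OMEGA0,
    ) -> "ScaleGrid":
        """Periods low_s * 2**(j*dj) covering [low_s, high_s]."""
        if not (0 < low_s < high_s):
            raise ValueError("require 0 < low < high")
        n = int(np.floor(np.log2(high_s / low_s) / dj)) + 1
        periods = low_s * 2.0 ** (dj * np.arange(n))
        return cls(periods_s=periods, dj=dj, omega0=omega0)

    @property
    def fourier_factor(self) -> float:
        return morlet_fourier_factor(self.omega0)

    @property
    def scales(self) -> np.ndarray:
        return self.periods_s / self.fourier_factor


@dataclass(frozen=True)
class CwtResult:
    """Complex Morlet coefficients of one series on a period grid."""

    times_s: np.ndarray
    periods_s: np.ndarray
    coeffs: np.ndarray  # complex, shape (n_periods, n_times)
    coi_s: np.ndarray  # max reliable period per timestamp

    def outside_coi(self) -> np.ndarray:
        """Boolean (n_periods, n_times) mask, True where edge effects are
        negligible (period shorter than the cone-of-influence bound)."""
        return self.periods_s[:, None] < self.coi_s[None, :]


@dataclass(frozen=True)
class XwtField:
    """Cross-wavelet power and phase difference on a time x period grid.

    Channel order is fixed: the pianist's series is the first input, so a
    positive phase means the pianist's oscillation is earlier in the cycle.
    """

    times_s: np.ndarray
    periods_s: np.ndarray
    power: np.ndarray
    phase_rad: np.ndarray
    coi_s: np.ndarray
    channel_order: tuple[str, str] = ("pianist", "singer")
    power_squared: bool = False

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.periods_s), len(self.times_s)):
            raise ValueError("power shape inconsistent with grids")
        if self.phase_rad.shape != self.power.shape:
            raise ValueError("phase shape inconsistent with power")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(self.phase_rad <= -np.pi) or np.any(self.phase_rad > np.pi):
            raise ValueError("phase must lie in (-pi, pi]")

    def outside_coi(self) -> np.ndarray:
        return self.periods_s[:, None] < self.coi_s[None, :]


def _pad_length(n: int) -> int:
    """Next power of two at least twice the series length.

    Doubling before padding leaves a zero margin of at least one series
    length, so the circular convolution of the FFT route agrees with a
    direct linear convolution to numerical precision at every retained
    scale (the Gaussian envelope has decayed to ~1e-14 within the margin
    for scales shorter than the series).
    """
    return 1 << int(2 * n - 1).bit_length()


def morlet_cwt(
    x: SpeedSeries, grid: ScaleGrid, *, standardize: bool = False
) -> CwtResult:
    """Continuous Morlet wavelet transform of one speed series.

    The series is mean-centered (and optionally variance-normalized with
    ``standardize``) and zero-padded to the next power of two; padding is
    removed from the output.  The cone of influence records, per
    timestamp, the longest period whose coefficient is unaffected by the
    series edges under the e-folding criterion.
    """
    values = np.asarray(x.values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("series must have length >= 2")
    dt = 1.0 / x.fs
    if grid.periods_s[0] < 2.0 * dt:
        raise ValueError(
            f"shortest requested period {grid.periods_s[0]:g} s is below the "
            f"Nyquist period {2.0 * dt:g} s"
        )
    xc = values - values.mean()
    if standardize:
        sd = xc.std()
        if sd > 0:
            xc = xc / sd
    npad = _pad_length(n)
    xf = np.fft.fft(xc, npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    scales = grid.scales
    positive = omega > 0
    # one batched inverse FFT over all scales
    psi_hat = np.zeros((len(scales), npad))
    psi_hat[:, positive] = (
        np.pi**-0.25
        * np.sqrt(2.0 * np.pi * scales[:, None] / dt)
        * np.exp(-0.5 * (scales[:, None] * omega[None, positive] - grid.omega0) ** 2)
    )
    coeffs = np.fft.ifft(xf[None, :] * psi_hat, axis=1)[:, :n]
    edge = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    coi_s = grid.fourier_factor / np.sqrt(2.0) * edge
    return CwtResult(
        times_s=x.times_s, periods_s=grid.periods_s, coeffs=coeffs, coi_s=coi_s
    )


def cross_wavelet(
    x_pianist: SpeedSeries,
    y_singer: SpeedSeries,
    grid: ScaleGrid,
    *,
    power_squared: bool = False,
    standardize: bool = False,
) -> XwtField:
    """Cross-wavelet transform with the pianist as first channel.

    power = |Wx * conj(Wy)| (modulus; squared modulus by config) and
    phase = arg(Wx * conj(Wy)).  Swapping the inputs negates the phase and
    leaves the power unchanged.
    """
    if len(x_pianist) != len(y_singer):
        raise ValueError("series lengths differ")
    if x_pianist.fs != y_singer.fs:
        raise ValueError("sampling rates differ")
    wx = morlet_cwt(x_pianist, grid, standardize=standardize)
    wy = morlet_cwt(y_singer, grid, standardize=standardize)
    wxy = wx.coeffs * np.conj(wy.coeffs)
    power = np.abs(wxy)
    if power_squared:
        power = power**2
    phase = np.angle(wxy)
    # np.angle returns [-pi, pi]; fold the closed lower endpoint onto +pi
    phase[phase == -np.pi] = np.pi
    return XwtField(
        times_s=wx.times_s,
        periods_s=grid.periods_s,
        power=power,
        phase_rad=phase,
        coi_s=wx.coi_s,
        power_squared=power_squared,
    )


def time_average_power(
    field: XwtField,
    mask: np.ndarray | None = None,
    *,
    exclude_coi: bool = False,
) -> np.ndarray:
    """Arithmetic mean of power over (masked) timestamps, one value per period.

    ``mask`` is a boolean selector over timestamps.  With ``exclude_coi``
    the average at each period additionally drops timestamps inside the
    cone of influence; periods with no remaining timestamp yield NaN.
    """
    if mask is None:
        mask = np.ones(len(field.times_s), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.times_s.shape:
        raise ValueError("mask length must match the time grid")
    if not mask.any():
        raise ValueError("empty time mask")
    if not exclude_coi:
        return field.power[:, mask].mean(axis=1)
    cells = field.outside_coi() & mask[None, :]
    counts = cells.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(
            counts > 0, (field.power * cells).sum(axis=1) / np.maximum(counts, 1),
            np.nan,
        )
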
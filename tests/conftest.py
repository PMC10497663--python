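import numpy as np
import pytest

from duosync.kinematics import SpeedSeries


def direct_morlet_cwt(
    values: np.ndarray, fs: float, periods: np.ndarray, omega0: float = 6.0
) -> np.ndarray:
    """Independent time-domain Morlet transform (brute-force convolution).

    W_n(s) = sum_k x[n+k] * conj(psi(k*dt/s)) * sqrt(dt/s) with
    psi(eta) = pi**-0.25 * exp(i*omega0*eta) * exp(-eta**2/2), truncated at
    |eta| = 8 where the Gaussian envelope is ~1e-14.
    """
    x = np.asarray(values, float)
    x = x - x.mean()
    dt = 1.0 / fs
    ff = 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))
    W = np.empty((len(periods), len(x)), complex)
    for i, p in enumerate(periods):
        s = p / ff
        m = int(np.ceil(8.0 * s / dt))
        eta = np.arange(-m, m + 1) * dt / s
        psi = (
            np.pi**-0.25
            * np.exp(1j * omega0 * eta)
            * np.exp(-0.5 * eta**2)
            * np.sqrt(dt / s)
        )
        # correlation with conj(psi) == convolution with psi (conjugate-
        # symmetric kernel); slice the full convolution so the kernel
        # centre aligns with each sample even when the kernel is longer
        # than the series
        full = np.convolve(x, psi, mode="full")
        W[i] = full[m : m + len(x)]
    return W


@pytest.fixture
def speed_pair():
    """Factory for a pair of lagged sinusoidal speed series."""

    def make(period_s=8.0, tau_s=1.0, fs=16.0, duration_s=256.0, amp=2.0, base=5.0):
        t = np.arange(0.0, duration_s, 1.0 / fs)
        x = base + amp * np.sin(2 * np.pi * t / period_s)
        y = base + amp * np.sin(2 * np.pi * (t - tau_s) / period_s)
        return (
            SpeedSeries("pianist", "front_head", fs, x),
            SpeedSeries("singer", "front_head", fs, y),
        )

    return make
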
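"""Linear superposition of three basis fields into a time-resolved ds-tACS field.

Dual-site tACS drives two electrode clusters with sinusoidal currents whose
relative timing is set by a phase lag applied to the second site.  Because
the quasi-static forward problem is linear in the injected currents, the
time-resolved field is a sinusoidally weighted sum of three static basis
fields, each obtained from a single-channel (direct-current) solve against a
common return electrode:

    E(p, t) = Io * [ (E_R1(p) - E_C1(p)) * sin(2*pi*f*t)
                     + E_R2(p) * sin(2*pi*f*t + phi) ]

where E_C1 is the field of the first site's central electrode, E_R1 of its
surround electrodes, and E_R2 of the whole second site; phi is the phase lag.
Basis fields are stored per unit channel current (V/m per mA), so current
ratios between central and surround electrodes are already baked into them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BasisFieldSet",
    "TimeResolvedField",
    "default_phase_lags",
    "make_time_grid",
    "superpose",
    "envelope",
]

#: the eight phase lags of the standard protocol: 0, pi/4, ..., 7*pi/4
DEFAULT_N_PHASE_LAGS = 8
DEFAULT_N_TIME_STEPS = 24
DEFAULT_CURRENT_MA = 2.0   # amplitude of the largest channel; 4 mA peak-to-peak
DEFAULT_FREQUENCY_HZ = 20.0


def default_phase_lags(n: int = DEFAULT_N_PHASE_LAGS) -> np.ndarray:
    """Equally spaced phase lags covering one full cycle: k * 2*pi/n."""
    return np.arange(n) * (2.0 * np.pi / n)


@dataclass
class BasisFieldSet:
    """The three per-node basis fields of one montage on one individual.

    ``e_r1``, ``e_c1``, ``e_r2`` are ``(N, 3)`` arrays in V/m per mA of
    channel current; ``io_amp`` is the stimulation current amplitude in mA
    (half the peak-to-peak current) and ``f`` the frequency in Hz.
    """

    e_r1: np.ndarray
    e_c1: np.ndarray
    e_r2: np.ndarray
    io_amp: float = DEFAULT_CURRENT_MA
    f: float = DEFAULT_FREQUENCY_HZ
    montage_id: str = ""
    individual_id: str = ""

    def __post_init__(self) -> None:
        self.e_r1 = np.asarray(self.e_r1, dtype=float)
        self.e_c1 = np.asarray(self.e_c1, dtype=float)
        self.e_r2 = np.asarray(self.e_r2, dtype=float)
        shapes = {self.e_r1.shape, self.e_c1.shape, self.e_r2.shape}
        if len(shapes) != 1 or self.e_r1.ndim != 2 or self.e_r1.shape[1] != 3:
            raise ValueError("basis fields must share one (N, 3) shape")
        if self.io_amp <= 0 or self.f <= 0:
            raise ValueError("io_amp and f must be positive")

    @property
    def n_nodes(self) -> int:
        return self.e_r1.shape[0]

    @property
    def site1_pattern(self) -> np.ndarray:
        """Io-scaled spatial pattern oscillating with the unshifted sine."""
        return self.io_amp * (self.e_r1 - self.e_c1)

    @property
    def site2_pattern(self) -> np.ndarray:
        """Io-scaled spatial pattern oscillating with the phase-shifted sine."""
        return self.io_amp * self.e_r2


@dataclass
class TimeResolvedField:
    """Per-node field vectors at each time step for one phase-lag condition.

    ``vectors`` has shape ``(T, N, 3)`` in V/m.
    """

    vectors: np.ndarray
    times: np.ndarray
    phase_lag: float
    montage_id: str = ""
    individual_id: str = ""

    @property
    def magnitudes(self) -> np.ndarray:
        """(T, N) Euclidean norm at each node and time step."""
        return np.linalg.norm(self.vectors, axis=2)


def make_time_grid(n_steps: int = DEFAULT_N_TIME_STEPS, f: float = DEFAULT_FREQUENCY_HZ) -> np.ndarray:
    """Equally spaced sample times covering one stimulation period.

    The grid is offset by half a step, t_k = (k + 1/2) / (n_steps * f), so no
    sample coincides with a zero crossing of sin(2*pi*f*t); an unshifted grid
    would make the whole zero-lag field vanish identically at two steps,
    leaving normalised comparison metrics undefined there.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    if f <= 0:
        raise ValueError("frequency must be positive")
    return (np.arange(n_steps) + 0.5) / (n_steps * f)


def superpose(basis: BasisFieldSet, phase_lag: float, times: np.ndarray) -> TimeResolvedField:
    """Reconstruct the time-resolved dual-site field at one phase lag.

    The phase lag is applied to the second site only (E_R2); linearity in the
    current amplitude is exact.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    w = 2.0 * np.pi * basis.f * times
    s0 = np.sin(w)                       # (T,)
    sphi = np.sin(w + phase_lag)
    vectors = (
        s0[:, None, None] * basis.site1_pattern[None, :, :]
        + sphi[:, None, None] * basis.site2_pattern[None, :, :]
    )
    return TimeResolvedField(
        vectors=vectors,
        times=times,
        phase_lag=float(phase_lag),
        montage_id=basis.montage_id,
        individual_id=basis.individual_id,
    )


def envelope(field: TimeResolvedField | np.ndarray) -> np.ndarray:
    """Per-node maximum over the cycle.

    For a ``TimeResolvedField`` (or a ``(T, N, 3)`` array) this is the maximum
    Euclidean norm over time steps; for a ``(T, N)`` scalar series it is the
    maximum absolute value.  The envelope summarises one condition in a single
    per-node scalar that is stable across time steps, which is what the
    thresholding stage operates on.
    """
    if isinstance(field, TimeResolvedField):
        values = field.magnitudes
    else:
        values = np.asarray(field, dtype=float)
        if values.ndim == 3:
            values = np.linalg.norm(values, axis=2)
        else:
            values = np.abs(values)
    if values.ndim != 2 or values.shape[0] < 1:
        raise ValueError("need a (T, N) series with at least one time step")
    return values.max(axis=0)
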
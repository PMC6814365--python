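"""Forward photophysics model for TCSPC decays.

With pulsed excitation at period ``T`` a fluorophore whose lifetime is not
short compared to ``T`` does not fully decay between pulses; the steady-state
histogram is the superposition of the current pulse and all preceding ones
("incomplete decay").  For an exponential component with lifetime ``tau``
that geometric pile-up has the closed form

    f(t) = exp(-t / tau) / (1 - exp(-T / tau)),   0 <= t < T,

which is periodic in ``T``.  The measured curve is this periodic decay
circularly convolved with the instrument response function (IRF), optionally
displaced by a sub-bin shift, plus a constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IRF, TimeAxis

__all__ = [
    "DecayParams",
    "periodic_decay",
    "shift_histogram",
    "model_curve",
    "weighted_mean_lifetime",
    "fractional_lifetime_change",
]


@dataclass
class DecayParams:
    """Parameters of a one- or two-component exponential decay.

    components
        List of ``(amplitude, lifetime_ns)`` pairs, lifetimes sorted
        ascending; amplitudes are peak amplitudes (counts scale).
    shift
        Sub-bin displacement of the IRF relative to the decay, in ADC-bin
        units (positive shifts the IRF to later times).
    offset
        Constant per-bin background in counts.
    """

    components: list[tuple[float, float]]
    shift: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 2:
            raise ValueError("1 or 2 decay components supported")
        comps = [(float(a), float(t)) for a, t in self.components]
        for a, tau in comps:
            if not np.isfinite(a) or a < 0:
                raise ValueError(f"amplitude must be finite and >= 0, got {a}")
            if tau <= 0:
                raise ValueError(f"lifetime must be positive, got {tau}")
        self.components = sorted(comps, key=lambda c: c[1])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([t for _, t in self.components])


def periodic_decay(axis: TimeAxis, components: list[tuple[float, float]]) -> np.ndarray:
    """Steady-state periodic (incomplete) multi-exponential decay.

    Returns the expected signal at each bin's left edge, including
    wrap-around contributions from all preceding pulses.
    """
    t = axis.times()
    out = np.zeros(axis.n_bins)
    for a, tau in components:
        wrap = 1.0 / (1.0 - np.exp(-axis.period / tau))
        out += a * np.exp(-t / tau) * wrap
    return out


def shift_histogram(values: np.ndarray, shift: float) -> np.ndarray:
    """Circularly displace a histogram by a fractional number of bins.

    Linear interpolation between the two neighbouring integer shifts;
    positive ``shift`` moves content toward later bins.
    """
    s = int(np.floor(shift))
    frac = shift - s
    rolled = np.roll(values, s)
    if frac == 0.0:
        return rolled
    return (1.0 - frac) * rolled + frac * np.roll(values, s + 1)


def model_curve(params: DecayParams, irf: IRF, axis: TimeAxis) -> np.ndarray:
    """Expected counts per bin: (shifted IRF) ⊛ periodic decay + offset.

    The circular convolution is consistent with the periodic signal model;
    the IRF is normalized, so the convolution conserves the integral of the
    decay over one period.
    """
    if irf.axis != axis:
        raise ValueError("IRF and model must share the same time axis")
    decay = periodic_decay(axis, params.components)
    kernel = shift_histogram(irf.values, params.shift)
    curve = np.fft.irfft(np.fft.rfft(kernel) * np.fft.rfft(decay), n=axis.n_bins)
    # FFT round-off can produce tiny negatives on an analytically positive curve
    return np.maximum(curve, 0.0) + params.offset


def weighted_mean_lifetime(params: DecayParams | list[tuple[float, float]]) -> float:
    """Amplitude-weighted mean lifetime  tau_m = sum(a_i tau_i) / sum(a_i)."""
    comps = params.components if isinstance(params, DecayParams) else params
    a = np.array([c[0] for c in comps], dtype=float)
    tau = np.array([c[1] for c in comps], dtype=float)
    total = a.sum()
    if total <= 0:
        raise ValueError("at least one amplitude must be positive")
    return float((a * tau).sum() / total)


def fractional_lifetime_change(
    m: float, b: float, v_from: float = -60.0, v_to: float = 40.0
) -> float:
    """Percent lifetime change over a voltage step, relative to the start.

    Parameters are the linear calibration slope ``m`` (ps/mV) and 0 mV
    lifetime ``b`` (ps); the default step is the conventional -60 -> +40 mV
    (100 mV) used to express dye sensitivity.
    """
    baseline = b + m * v_from
    if baseline <= 0:
        raise ValueError(f"baseline lifetime {baseline} ps is not positive")
    return 100.0 * m * (v_to - v_from) / baseline
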
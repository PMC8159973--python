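"""Tidal breathing waveforms.

Flow is prescribed (no pressure/resistance/compliance dynamics): a
half-sinusoid inspiration followed by a half-sinusoid expiration, with the
inspiratory:expiratory duration split set by ``ie_ratio``.  Both halves
integrate exactly to the tidal volume, so inhaled and exhaled volumes
balance per breath by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class BreathingWaveform:
    """Closed-form sinusoidal tidal breathing waveform.

    ``Q(t)`` is the flow at the trachea inlet in mL/s (inspiration
    positive) and ``V(t)`` the lung volume above FRC in mL; both are
    periodic with period ``1/RR``.
    """

    TV: float          # mL
    RR: float          # breaths/s
    ie_ratio: float    # inspiratory:expiratory time ratio

    @property
    def period(self) -> float:
        return 1.0 / self.RR

    @property
    def t_insp(self) -> float:
        return self.period * self.ie_ratio / (1.0 + self.ie_ratio)

    @property
    def t_exp(self) -> float:
        return self.period - self.t_insp

    def Q(self, t):
        """Inlet flow, mL/s; vectorized over ``t`` (s)."""
        tau = np.asarray(t) % self.period
        Ti, Te = self.t_insp, self.t_exp
        insp = (math.pi * self.TV / (2.0 * Ti)) * np.sin(math.pi * tau / Ti)
        exp_ = -(math.pi * self.TV / (2.0 * Te)) * np.sin(math.pi * (tau - Ti) / Te)
        out = np.where(tau < Ti, insp, exp_)
        return out if out.shape else float(out)

    def V(self, t):
        """Lung volume above FRC, mL; vectorized over ``t`` (s)."""
        tau = np.asarray(t) % self.period
        Ti, Te = self.t_insp, self.t_exp
        insp = self.TV * 0.5 * (1.0 - np.cos(math.pi * tau / Ti))
        exp_ = self.TV * 0.5 * (1.0 + np.cos(math.pi * (tau - Ti) / Te))
        out = np.where(tau < Ti, insp, exp_)
        return out if out.shape else float(out)

    def sample(self, n: int = 1001):
        """Return (t, Q, V) arrays over one period."""
        t = np.linspace(0.0, self.period, n)
        return t, self.Q(t), self.V(t)


def make_waveform(
    TV: float, RR: float, shape: str = "sinusoid", ie_ratio: float = 1.0
) -> BreathingWaveform:
    """Build a tidal breathing waveform from tidal volume (mL) and rate (breaths/s)."""
    if shape != "sinusoid":
        raise ValidationError(f"unsupported waveform shape {shape!r}")
    if TV <= 0 or RR <= 0 or ie_ratio <= 0:
        raise ValidationError("TV, RR and ie_ratio must be positive")
    return BreathingWaveform(TV=TV, RR=RR, ie_ratio=ie_ratio)


def mean_inspiratory_flow(waveform: BreathingWaveform) -> float:
    """Mean inspiratory flow TV / T_insp in mL/s (2·TV·RR for a 1:1 duty cycle)."""
    return waveform.TV / waveform.t_insp


def mL_s_to_L_min(q: float) -> float:
    """Convert a flow from mL/s to L/min."""
    return q * 60.0 / 1000.0


def waveform_to_csv(waveform: BreathingWaveform, path, n: int = 1001) -> None:
    """Export one period as a two-column CSV (t_s, Q_mL_s) for inspection."""
    t, Q, _ = waveform.sample(n)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("t_s,Q_mL_s\n")
        for ti, qi in zip(t, Q):
            fh.write(f"{ti:.6g},{qi:.6g}\n")
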
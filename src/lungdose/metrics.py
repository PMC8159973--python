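"""Dosimetry statistics and dose-scaling metrics.

Given a closed deposition ledger, this layer computes the deposited
fractions (total, conducting, respiratory), the conducting-to-respiratory
ratio (CR), and the derived dose scalings used to compare ages: tissue
dose Dep_T·TV/A_FRC (%·mL/cm²), deposition rate Dep_T·TV·RR (%·L/s), its
BSA-normalized form, and the tidal-volume-scaled deposition
Dep_T·(TV/TV_adult).  All of these are exact arithmetic on the ledger and
the subject record — independent of the transport solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .subjects import CONDUCTING, RESPIRATORY, SubjectParams
from .transport import DepositionResult, PHASES


def total_deposition(result: DepositionResult) -> float:
    """Total deposition Dep_T: deposited mass over both phases as % of inhaled."""
    if result.inhaled_ug <= 0:
        raise ValidationError("inhaled mass must be positive")
    return 100.0 * result.deposited_ug / result.inhaled_ug


def zone_deposition(result: DepositionResult) -> dict[str, float]:
    """Dep_C and Dep_R, % of inhaled, keyed by zone label."""
    if result.inhaled_ug <= 0:
        raise ValidationError("inhaled mass must be positive")
    by_zone = result.by("zone") if len(result.ledger) else pd.Series(dtype=float)
    return {
        zone: 100.0 * float(by_zone.get(zone, 0.0)) / result.inhaled_ug
        for zone in (CONDUCTING, RESPIRATORY)
    }


def exhaled_fraction(result: DepositionResult) -> float:
    """Exhaled mass as % of inhaled."""
    return 100.0 * result.exhaled_ug / result.inhaled_ug


def suspended_fraction(result: DepositionResult) -> float:
    """Still-airborne mass at the end of the run as % of inhaled."""
    return 100.0 * result.suspended_ug / result.inhaled_ug


def cr_ratio(result: DepositionResult) -> float:
    """Conducting-to-respiratory deposition ratio Dep_C / Dep_R.

    Returns ``math.inf`` when nothing deposited in the respiratory zone.
    """
    zones = zone_deposition(result)
    if zones[RESPIRATORY] == 0.0:
        return math.inf
    return zones[CONDUCTING] / zones[RESPIRATORY]


@dataclass(frozen=True)
class DoseMetrics:
    """Derived whole-lung dose metrics for one subject × particle size."""

    dep_T: float                    # %
    dep_C: float                    # %
    dep_R: float                    # %
    cr_ratio: float                 # dimensionless (inf if dep_R = 0)
    exhaled: float                  # %
    suspended: float                # %
    tissue_dose: float              # %·mL/cm², Dep_T·TV/A_FRC
    dep_rate: float                 # %·L/s,   Dep_T·TV·RR
    dep_rate_per_BSA: float         # %·L/s/m²
    tv_scaled_dep: float            # %,       Dep_T·TV/TV_A
    zone_doses: dict | None = None  # %/cm², only when zone areas supplied


def dose_scalings(
    dep_T: float,
    subject: SubjectParams,
    zone_areas_cm2: Mapping[str, float] | None = None,
    dep_C: float | None = None,
    dep_R: float | None = None,
) -> dict[str, float]:
    """The Dep_T-derived scaling metrics from a deposition % and a subject record.

    Unit conventions required by the column definitions: TV in mL for the
    tissue dose (%·mL/cm², with A_FRC converted m²→cm²) and TV in L for
    the deposition rate (%·L/s).
    """
    if dep_T < 0:
        raise ValidationError("deposition percentage cannot be negative")
    out = {
        "tissue_dose": dep_T * subject.TV / (subject.A_FRC * 1e4),
        "dep_rate": dep_T * (subject.TV / 1000.0) * subject.RR,
        "tv_scaled_dep": dep_T * subject.TV_over_TVA,
    }
    out["dep_rate_per_BSA"] = out["dep_rate"] / subject.BSA
    if zone_areas_cm2 is not None:
        if dep_C is None or dep_R is None:
            raise ValidationError("zone doses need dep_C and dep_R")
        out["zone_doses"] = {
            CONDUCTING: dep_C / zone_areas_cm2[CONDUCTING],
            RESPIRATORY: dep_R / zone_areas_cm2[RESPIRATORY],
        }
    return out


def dose_metrics(
    result: DepositionResult,
    subject: SubjectParams,
    zone_areas_cm2: Mapping[str, float] | None = None,
) -> DoseMetrics:
    """Assemble the full metric record for one simulation result."""
    dep_T = total_deposition(result)
    zones = zone_deposition(result)
    scalings = dose_scalings(dep_T, subject, zone_areas_cm2,
                             zones[CONDUCTING], zones[RESPIRATORY])
    return DoseMetrics(
        dep_T=dep_T,
        dep_C=zones[CONDUCTING],
        dep_R=zones[RESPIRATORY],
        cr_ratio=cr_ratio(result),
        exhaled=exhaled_fraction(result),
        suspended=suspended_fraction(result),
        tissue_dose=scalings["tissue_dose"],
        dep_rate=scalings["dep_rate"],
        dep_rate_per_BSA=scalings["dep_rate_per_BSA"],
        tv_scaled_dep=scalings["tv_scaled_dep"],
        zone_doses=scalings.get("zone_doses"),
    )


def np_concentration(N_e: Sequence[float], area_e: Sequence[float]) -> np.ndarray:
    """Area-normalized deposited-particle concentration per surface element.

    NP_e = (N_e / N_T) · (Σ_T / Σ_e); the area-weighted mean of NP is 1 by
    construction, so NP > 1 marks hotspots relative to a uniform surface
    density.
    """
    N = np.asarray(N_e, dtype=float)
    S = np.asarray(area_e, dtype=float)
    if np.any(S <= 0):
        raise ValidationError("every element area must be positive")
    N_T = N.sum()
    if N_T <= 0:
        raise ValidationError("total deposited count must be positive")
    return (N / N_T) * (S.sum() / S)


def lobar_table(result: DepositionResult) -> pd.DataFrame:
    """Per-lobe deposited % of inhaled, split by breath phase.

    Includes ``exhaled`` and ``suspended`` rows so the table closes to 100%.
    """
    if result.inhaled_ug <= 0:
        raise ValidationError("inhaled mass must be positive")
    rows = []
    if len(result.ledger):
        by = result.by("lobe", "phase")
        for (lobe, phase), ug in by.items():
            rows.append({"lobe": lobe, "phase": phase,
                         "percent": 100.0 * ug / result.inhaled_ug})
    rows.append({"lobe": "exhaled", "phase": "", "percent": exhaled_fraction(result)})
    rows.append({"lobe": "suspended", "phase": "", "percent": suspended_fraction(result)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Extrathoracic (mouth/nose-throat) pre-filtering
# ---------------------------------------------------------------------------
# No coefficients ship with the package: published correlations must be
# registered by the user.  The correction is OFF by default so the lung
# results match a bare tracheal inlet.

_EXTRATHORACIC: dict[str, Callable[[float, float], float]] = {}


def register_extrathoracic(name: str, fn: Callable[[float, float], float]) -> None:
    """Register an extrathoracic efficiency correlation η(Re, Stk) → %."""
    _EXTRATHORACIC[name] = fn


def extrathoracic_efficiency(Re: float, Stk: float, correlation=None) -> float:
    """Evaluate a mouth/nose-throat deposition efficiency, % of inhaled.

    ``correlation`` is a registered name or a callable η(Re, Stk).  There is
    no packaged default: supply one via :func:`register_extrathoracic` or
    directly.
    """
    if correlation is None:
        raise ConfigurationError(
            "no extrathoracic correlation configured; register one with "
            "register_extrathoracic(name, fn) or pass a callable"
        )
    fn = _EXTRATHORACIC[correlation] if isinstance(correlation, str) else correlation
    eta = float(fn(Re, Stk))
    if not 0.0 <= eta <= 100.0:
        raise ValidationError("extrathoracic efficiency must lie in [0, 100] %")
    return eta


def apply_extrathoracic(result: DepositionResult, eta_percent: float) -> DepositionResult:
    """Return a result with the inhaled bolus pre-filtered by η% at the inlet.

    Lung-deposited, exhaled and suspended masses scale by (1 − η/100) while
    the inhaled reference mass is unchanged, so every lung percentage
    shrinks by the same factor.
    """
    f = 1.0 - eta_percent / 100.0
    ledger = result.ledger.copy()
    if len(ledger):
        ledger["deposited_ug"] = ledger["deposited_ug"] * f
    meta = dict(result.metadata, extrathoracic_eta_pct=eta_percent)
    return DepositionResult(
        ledger=ledger,
        inhaled_ug=result.inhaled_ug,
        exhaled_ug=result.exhaled_ug * f,
        suspended_ug=result.suspended_ug * f,
        metadata=meta,
    )
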
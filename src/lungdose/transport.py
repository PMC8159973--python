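"""1D trumpet-model aerosol transport over full breaths.

The whole-lung airway tree is discretized into five 1D columns, one per
lobe, each consisting of the shared trachea/main-bronchi path (with its
cross-section scaled by the lobe's flow share) followed by the lobe's own
generations.  On each column the solver advances the cross-section
integrated advection–mixing–loss equation

    ∂(A_total c)/∂t + ∂(Q c)/∂x = ∂/∂x(D_app A_airway ∂c/∂x) − Λ A_total c

with a conservative finite-volume scheme: first-order upwind advection,
explicit central mixing, exact exponential loss, and automatic sub-stepping
to satisfy the combined advective/diffusive stability limit.  The apparent
mixing coefficient D_app = D_B + β σ_L |u| grows with the within-generation
length spread σ_L and the local conduit speed, representing dispersion by
branching heterogeneity.

Respiratory-zone alveolar volumes inflate linearly with the breathing
waveform (conducting airways are rigid); the axial flow profile follows
from continuity, Q(x,t) = Q_in(t) × (expandable volume distal to x) /
(total expandable volume).  Deposited mass is credited to a ledger by
generation, lobe, zone, mechanism and breath phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .breathing import BreathingWaveform
from .errors import NumericalError, StructuralError, ValidationError
from .kernels import (
    DEFAULT_CONSTANTS,
    DEFAULT_KERNELS,
    ParticleSpec,
    PhysicalConstants,
    get_kernel,
    mechanism_of,
    prob_to_rate,
)
from .subjects import CONDUCTING, LOBES, LungModel, GenerationRow

PHASES = ("inspiration", "expiration")

MAX_LOSS_RATE = 1e4  # 1/s, cap on any single-mechanism first-order rate


@dataclass
class ColumnGrid:
    """One 1D flow path: cell-centred geometry arrays in SI units."""

    lobe_path: str                  # lobe this column drains into
    lobe: np.ndarray                # per-cell lobe label ("shared" or lobe)
    generation: np.ndarray          # per-cell generation index
    zone: np.ndarray                # per-cell zone label
    dx: np.ndarray                  # cell length, m
    A_airway: np.ndarray            # summed duct cross-section, m²
    v_alv: np.ndarray               # alveolar volume at FRC per cell, m³
    diameter: np.ndarray            # single-airway duct diameter, m
    settle_diameter: np.ndarray     # volume-weighted settling scale, m
    gen_length: np.ndarray          # full generation length, m
    length_sd: np.ndarray           # within-generation length SD, m
    gravity_cos: np.ndarray
    branch_angle: np.ndarray        # deg

    @property
    def n_cells(self) -> int:
        return self.dx.size

    @property
    def x(self) -> np.ndarray:
        """Cell-centre path distance from the inlet, m."""
        edges = np.concatenate(([0.0], np.cumsum(self.dx)))
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def V_rigid(self) -> np.ndarray:
        """Rigid (duct) volume per cell, m³."""
        return self.A_airway * self.dx


def column_from_rows(
    rows: Sequence[GenerationRow],
    cells_per_generation: int = 2,
    area_scale: float | None = None,
    lobe_path: str = "",
) -> ColumnGrid:
    """Discretize an ordered row path into a :class:`ColumnGrid`.

    ``area_scale``, if given, multiplies duct areas and alveolar volumes of
    rows labelled ``shared`` (used to split the common path between lobes).
    """
    if cells_per_generation < 1:
        raise ValidationError("cells_per_generation must be >= 1")
    if not rows:
        raise StructuralError("cannot discretize an empty row collection")
    cpg = cells_per_generation
    lobe, gen, zone = [], [], []
    dx, A, valv, diam, dset, glen, lsd, gcos, bang = [], [], [], [], [], [], [], [], []
    for r in rows:
        scale = area_scale if (area_scale is not None and r.lobe == "shared") else 1.0
        L = r.length * 1e-3
        d = r.diameter * 1e-3
        # sedimentation acts on duct-resident mass over the duct diameter
        # and on alveolus-resident mass over the alveolar diameter; the
        # rate is 1/d-weighted by the two compartment volumes
        d_alv = (r.alveolar_diameter or 0.0) * 1e-3
        V_duct, V_alv = r.airway_volume, r.alveolar_volume
        if V_alv > 0.0 and d_alv > 0.0:
            w_a = V_alv / (V_duct + V_alv)
            d_eff = 1.0 / ((1.0 - w_a) / d + w_a / d_alv)
        else:
            d_eff = d
        for _ in range(cpg):
            lobe.append(r.lobe)
            gen.append(r.generation)
            zone.append(r.zone)
            dx.append(L / cpg)
            A.append(scale * r.airway_area * 1e-4)           # cm² -> m²
            valv.append(scale * r.alveolar_volume * 1e-6 / cpg)  # mL -> m³
            diam.append(d)
            dset.append(d_eff)
            glen.append(L)
            lsd.append(r.length_sd * 1e-3)
            gcos.append(r.gravity_cos)
            bang.append(r.branch_angle)
    return ColumnGrid(
        lobe_path=lobe_path or rows[-1].lobe,
        lobe=np.array(lobe), generation=np.array(gen), zone=np.array(zone),
        dx=np.array(dx), A_airway=np.array(A), v_alv=np.array(valv),
        diameter=np.array(diam), settle_diameter=np.array(dset),
        gen_length=np.array(glen),
        length_sd=np.array(lsd), gravity_cos=np.array(gcos),
        branch_angle=np.array(bang),
    )


@dataclass
class Grid1D:
    """The whole-lung grid: five lobe columns plus bookkeeping totals."""

    columns: list[ColumnGrid]
    V_alv_total: float  # m³, whole-lung expandable volume at FRC

    @property
    def n_cells(self) -> int:
        return sum(c.n_cells for c in self.columns)

    def column_share(self, col: ColumnGrid) -> float:
        """Flow share of a column = its expandable volume fraction."""
        return float(col.v_alv.sum() / self.V_alv_total)

    @property
    def total_alveolar_volume_ml(self) -> float:
        return self.V_alv_total * 1e6


def discretize(lung: LungModel, cells_per_generation: int = 2) -> Grid1D:
    """Build the per-lobe column grids for a :class:`LungModel`."""
    if not lung.rows:
        raise StructuralError("cannot discretize an empty lung")
    shared = [r for r in lung.rows if r.lobe == "shared"]
    V_alv_total = lung.V_alveolar * 1e-6
    columns = []
    for lobe in LOBES:
        lobe_rows = lung.lobe_rows(lobe)
        if not lobe_rows:
            continue
        share = sum(r.alveolar_volume for r in lobe_rows) * 1e-6 / V_alv_total
        col = column_from_rows(
            shared + lobe_rows, cells_per_generation,
            area_scale=share, lobe_path=lobe,
        )
        columns.append(col)
    if not columns:
        raise StructuralError("lung has no lobe rows")
    return Grid1D(columns=columns, V_alv_total=V_alv_total)


def wall_motion(grid: Grid1D, col: ColumnGrid, V_above_frc_ml: float) -> np.ndarray:
    """Cell volumes (m³) of a column at lung volume V_FRC + ``V_above_frc_ml``.

    Respiratory (alveolar) volumes deform linearly with the whole-lung
    inflation, v(t) = v_FRC (1 + V(t)/V_alv,FRC); conducting ducts are rigid.
    """
    if V_above_frc_ml < -1e-9:
        raise ValidationError("lung volume below FRC")
    infl = 1.0 + (V_above_frc_ml * 1e-6) / grid.V_alv_total
    return col.V_rigid + col.v_alv * infl


def flow_field(grid: Grid1D, col: ColumnGrid, Q_in_ml_s: float) -> np.ndarray:
    """Face flows (m³/s) along a column for whole-lung inlet flow ``Q_in_ml_s``.

    Faces are indexed 0..n_cells; Q at each face equals the inlet flow times
    the fraction of whole-lung expandable volume distal to that face, so the
    distal-most face carries zero flow.
    """
    distal = np.concatenate((np.cumsum(col.v_alv[::-1])[::-1], [0.0]))
    return (Q_in_ml_s * 1e-6) * distal / grid.V_alv_total


@dataclass
class TransportState:
    """Evolving solver state for the whole grid."""

    grid: Grid1D
    time: float = 0.0
    mass: list[np.ndarray] = field(default_factory=list)  # µg per cell per column
    # deposited[column][phase, mechanism, cell], µg
    deposited: list[np.ndarray] = field(default_factory=list)
    mechanisms: tuple[str, ...] = ()
    inhaled: float = 0.0   # µg
    exhaled: float = 0.0   # µg

    @property
    def suspended(self) -> float:
        """Airborne mass still in the lung, µg."""
        return float(sum(m.sum() for m in self.mass))

    def concentration(self, col_index: int, V_above_frc_ml: float) -> np.ndarray:
        """Concentration c = m/V per cell, µg/m³."""
        col = self.grid.columns[col_index]
        return self.mass[col_index] / wall_motion(self.grid, col, V_above_frc_ml)


def new_state(grid: Grid1D, kernel_keys: Sequence[str] = DEFAULT_KERNELS) -> TransportState:
    mechanisms = tuple(mechanism_of(k) for k in kernel_keys)
    return TransportState(
        grid=grid,
        mass=[np.zeros(c.n_cells) for c in grid.columns],
        deposited=[np.zeros((2, len(kernel_keys), c.n_cells)) for c in grid.columns],
        mechanisms=mechanisms,
    )


def _stable_dt(
    grid: Grid1D,
    col: ColumnGrid,
    Q_peak_ml_s: float,
    D_B: float,
    mixing_beta: float,
    cfl: float = 0.9,
) -> float:
    """Conservative fixed sub-step for a column: peak flow, FRC volumes."""
    V_cell = col.V_rigid + col.v_alv  # minimum (FRC) cell volumes
    Q_face = np.abs(flow_field(grid, col, Q_peak_ml_s))
    A_face = 0.5 * (col.A_airway[:-1] + col.A_airway[1:])
    dx_face = 0.5 * (col.dx[:-1] + col.dx[1:])
    u_face = Q_face[1:-1] / A_face
    sd_face = 0.5 * (col.length_sd[:-1] + col.length_sd[1:])
    D_face = D_B + mixing_beta * sd_face * u_face
    # per-cell outflow coefficient (advective + diffusive), 1/s
    out = np.zeros(col.n_cells)
    out += Q_face[1:] / V_cell
    out += Q_face[:-1] / V_cell
    diff_coef = D_face * A_face / dx_face
    out[:-1] += diff_coef / V_cell[:-1]
    out[1:] += diff_coef / V_cell[1:]
    peak = out.max()
    return cfl / peak if peak > 0 else math.inf


def step(
    state: TransportState,
    dt: float,
    waveform: BreathingWaveform,
    particle: ParticleSpec,
    kernel_keys: Sequence[str] = DEFAULT_KERNELS,
    mixing_beta: float = 1.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    inlet_concentration: float = 1.0,
    max_substep_ratio: int = 200_000,
) -> TransportState:
    """Advance the state by ``dt`` seconds, sub-stepping internally for stability.

    ``inlet_concentration`` is the tracheal aerosol concentration in µg/mL
    applied whenever the inlet flow is inspiratory.
    """
    kernels = [get_kernel(k) for k in kernel_keys]
    grid = state.grid
    t_end = state.time + dt
    c_in = inlet_concentration * 1e6  # µg/mL -> µg/m³

    # fixed conservative sub-step from peak flow and end-expiratory volumes
    Q_peak = float(np.abs(waveform.Q(np.linspace(state.time, t_end, 257))).max())
    Q_peak = max(Q_peak, 1e-12)
    dt_stable = min(
        _stable_dt(grid, col, Q_peak, particle.D_B, mixing_beta)
        for col in grid.columns
    )
    if dt_stable < dt / max_substep_ratio:
        raise NumericalError(
            f"stability limit requires more than {max_substep_ratio} sub-steps"
        )

    while state.time < t_end - 1e-12:
        t = state.time
        sub = min(dt_stable, t_end - t)
        tm = t + 0.5 * sub
        Q_mid = float(waveform.Q(tm))
        V_t = float(waveform.V(t))
        phase = 0 if Q_mid >= 0.0 else 1

        for ci, col in enumerate(grid.columns):
            m = state.mass[ci]
            V_cell = wall_motion(grid, col, V_t)
            c = m / V_cell
            Q_face = flow_field(grid, col, Q_mid)
            u_face = Q_face[1:-1] / (0.5 * (col.A_airway[:-1] + col.A_airway[1:]))
            sd_face = 0.5 * (col.length_sd[:-1] + col.length_sd[1:])
            D_face = particle.D_B + mixing_beta * sd_face * np.abs(u_face)

            # advective fluxes, upwinded (µg/s); faces 0..n
            F = np.empty(col.n_cells + 1)
            Fq = Q_face[1:-1]
            F[1:-1] = np.where(Fq > 0.0, Fq * c[:-1], Fq * c[1:])
            F[0] = Q_face[0] * (c_in if Q_face[0] > 0.0 else c[0])
            F[-1] = 0.0
            # mixing fluxes through interior faces
            dx_face = 0.5 * (col.dx[:-1] + col.dx[1:])
            A_face = 0.5 * (col.A_airway[:-1] + col.A_airway[1:])
            G = -D_face * A_face * np.diff(c) / dx_face
            flux_div = np.zeros(col.n_cells)
            flux_div += F[:-1] - F[1:]
            flux_div[:-1] -= G
            flux_div[1:] += G
            m_new = m + sub * flux_div

            if m_new.min() < -1e-9 * max(m_new.max(), 1.0):
                raise NumericalError("negative concentration beyond tolerance")

            # deposition losses.  Per-transit mechanisms (impaction at the
            # generation's bifurcation, diffusion over the duct length) see
            # only the mass flux actually transiting the ducts; resident
            # mechanisms (sedimentation) act on all mass held in the cell.
            u_cell = 0.5 * (np.abs(Q_face[:-1]) + np.abs(Q_face[1:])) / col.A_airway
            slow = u_cell < 1e-6
            t_res = np.where(slow, sub, col.dx / np.maximum(u_cell, 1e-6))
            # through-flux exposure rate: fraction of the cell's mass
            # carried through its ducts per second, 1/s
            flux_rate = u_cell * col.A_airway / V_cell
            rates = np.zeros((len(kernels), col.n_cells))
            for ki, (key, kern) in enumerate(zip(kernel_keys, kernels)):
                P = kern(
                    particle, constants,
                    diameter=col.diameter,
                    settle_diameter=col.settle_diameter,
                    length=col.gen_length,
                    speed=u_cell, t_res=t_res,
                    gravity_cos=col.gravity_cos,
                    branch_angle_deg=col.branch_angle,
                )
                if getattr(kern, "exposure", "transit") == "resident":
                    rates[ki] = prob_to_rate(P, t_res, MAX_LOSS_RATE)
                else:
                    # P is per generation transit; spread over this cell's
                    # share dx/L of the generation and apply to the flux
                    per_cell = -np.log1p(-np.minimum(P, 1.0 - 1e-15))
                    per_cell *= col.dx / col.gen_length
                    rates[ki] = np.minimum(per_cell * flux_rate, MAX_LOSS_RATE)
            total_rate = rates.sum(axis=0)
            factor = -np.expm1(-total_rate * sub)
            removed = m_new * factor
            with np.errstate(invalid="ignore", divide="ignore"):
                shares = np.where(total_rate > 0.0, rates / total_rate, 0.0)
            state.deposited[ci][phase] += shares * removed
            state.mass[ci] = m_new - removed

            # boundary bookkeeping
            if Q_face[0] > 0.0:
                state.inhaled += F[0] * sub
            else:
                state.exhaled += -F[0] * sub
        state.time = t + sub
    return state


@dataclass
class DepositionResult:
    """Closed deposition ledger for one simulation."""

    ledger: pd.DataFrame      # generation, lobe, zone, mechanism, phase, deposited_ug
    inhaled_ug: float
    exhaled_ug: float
    suspended_ug: float
    metadata: dict = field(default_factory=dict)

    @property
    def deposited_ug(self) -> float:
        return float(self.ledger["deposited_ug"].sum())

    @property
    def mass_balance_residual(self) -> float:
        """Relative residual of inhaled − (deposited + exhaled + suspended)."""
        if self.inhaled_ug == 0.0:
            return 0.0
        return (self.inhaled_ug - self.deposited_ug - self.exhaled_ug
                - self.suspended_ug) / self.inhaled_ug

    def by(self, *keys: str) -> pd.Series:
        """Deposited µg aggregated over the given ledger keys."""
        return self.ledger.groupby(list(keys))["deposited_ug"].sum()


def _build_ledger(state: TransportState, kernel_keys: Sequence[str]) -> pd.DataFrame:
    recs = []
    for ci, col in enumerate(state.grid.columns):
        dep = state.deposited[ci]
        for pi, phase in enumerate(PHASES):
            for ki, key in enumerate(kernel_keys):
                mech = mechanism_of(key)
                for cell in range(col.n_cells):
                    v = dep[pi, ki, cell]
                    if v != 0.0:
                        recs.append((int(col.generation[cell]), str(col.lobe[cell]),
                                     str(col.zone[cell]), mech, phase, v))
    frame = pd.DataFrame(
        recs, columns=["generation", "lobe", "zone", "mechanism", "phase",
                       "deposited_ug"],
    )
    return (frame.groupby(["generation", "lobe", "zone", "mechanism", "phase"],
                          as_index=False)["deposited_ug"].sum()
            if len(frame) else frame)


def simulate_breath(
    lung: LungModel,
    waveform: BreathingWaveform,
    particle: ParticleSpec,
    kernel_keys: Sequence[str] = DEFAULT_KERNELS,
    n_breaths: int = 1,
    inlet_concentration: float = 1.0,
    cells_per_generation: int = 2,
    mixing_beta: float = 1.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> DepositionResult:
    """Run ``n_breaths`` full breaths with a constant inspiratory inlet concentration.

    The inlet mass flux is proportional to the local flow rate (fixed
    concentration ``inlet_concentration`` µg/mL at the trachea during
    inspiration); expired mass crossing the inlet is tallied as exhaled.
    """
    if n_breaths < 1:
        raise ValidationError("n_breaths must be >= 1")
    grid = discretize(lung, cells_per_generation)
    state = new_state(grid, kernel_keys)
    period = waveform.period
    for b in range(n_breaths):
        # split each breath at the flow reversal for clean phase attribution
        for t_target in (b * period + waveform.t_insp, (b + 1) * period):
            span = t_target - state.time
            if span > 0:
                step(state, span, waveform, particle, kernel_keys, mixing_beta,
                     constants, inlet_concentration)
    ledger = _build_ledger(state, kernel_keys)
    result = DepositionResult(
        ledger=ledger,
        inhaled_ug=state.inhaled,
        exhaled_ug=state.exhaled,
        suspended_ug=state.suspended,
        metadata={
            "subject": lung.subject.label,
            "d_p_um": particle.d_p,
            "kernels": list(kernel_keys),
            "cells_per_generation": cells_per_generation,
            "mixing_beta": mixing_beta,
            "n_breaths": n_breaths,
            "n_cells": grid.n_cells,
        },
    )
    result.metadata["mass_balance_residual"] = result.mass_balance_residual
    return result
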
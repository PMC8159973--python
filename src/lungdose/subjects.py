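"""Subject parameters and lobe-resolved airway-tree morphometry.

The lung is represented as an ordered collection of per-generation rows:
a shared path (trachea + main bronchi) feeding five lobe trees (left
inferior/superior, right inferior/middle/superior).  Within each lobe the
airway dimensions decay geometrically with generation (Weibel-like taper)
and the whole lobe is rescaled so that its total volume — airway plus
attached alveolar volume — matches the subject's functional residual
capacity (FRC) share for that lobe.  Generations at or beyond the
respiratory-zone start carry expandable alveolar volume; conducting
generations are rigid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import StructuralError, ValidationError

LOBES: tuple[str, ...] = ("LI", "LS", "RI", "RM", "RS")
SHARED = "shared"

#: Subtended lobe volume fractions for LI, LS, RI, RM, RS.
DEFAULT_LOBAR_FRACTIONS: tuple[float, ...] = (0.25, 0.20, 0.25, 0.09, 0.21)

#: Weibel-like per-generation dimension decay (daughter/parent ratio).
DEFAULT_TAPER: float = 2.0 ** (-1.0 / 3.0)

#: Default within-generation length coefficient of variation (drives mixing).
DEFAULT_CV_L: float = 0.3

#: Mean |cos| of the airway-to-gravity angle for a randomly oriented airway.
DEFAULT_GRAVITY_COS: float = 0.5

#: Default branch angle from the parent flow direction, degrees.
DEFAULT_BRANCH_ANGLE: float = 35.0

#: Within the acinus the conducting taper law no longer applies: acinar
#: duct diameters shrink only mildly with depth (transitional bronchiole
#: ~0.5 mm down to alveolar sacs ~0.25 mm in the adult).
DEFAULT_RESP_TAPER: float = 0.93

#: Alveolar volume attached per unit respiratory-duct lumen volume
#: (alveoli hold roughly twice the duct lumen).  Because duct volume grows
#: with acinar depth, this weights the expandable volume distally and
#: leaves the conducting tree near 4% of FRC — the intrathoracic
#: anatomic dead-space fraction.
DEFAULT_ALV_MULT: float = 2.0

#: First alveolated generation (0-based at the trachea); the infant's left
#: inferior lobe starts one generation later.
DEFAULT_Z_RESP: int = 16
DEFAULT_N_GENERATIONS: int = 24

CONDUCTING = "conducting"
RESPIRATORY = "respiratory"


@dataclass(frozen=True)
class SubjectParams:
    """One subject's anthropometry and resting respiration parameters.

    Units: TV and V_FRC in mL, RR in breaths/s, A_FRC and BSA in m²,
    D_trachea in mm, height in cm, weight in kg, age in years.
    """

    label: str
    age: float
    weight: float
    height: float
    sex: str
    TV: float
    TV_over_TVA: float
    V_FRC: float
    RR: float
    A_FRC: float
    BSA: float
    D_trachea: float

    def __post_init__(self) -> None:
        for name in ("age", "weight", "height", "TV", "TV_over_TVA",
                     "V_FRC", "RR", "A_FRC", "BSA", "D_trachea"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"SubjectParams.{name} must be positive")


# Resting-breathing subject records: a 3-month infant, a 6-year child and a
# 36-year adult.  Trachea diameters: infant 4 mm; child/adult via the
# height-based doubling used throughout this package (8 / 16 mm).
_SUBJECTS: dict[str, SubjectParams] = {
    "infant": SubjectParams("infant", 0.25, 6.1, 55.2, "F",
                            TV=49.0, TV_over_TVA=0.10, V_FRC=81.0, RR=0.66,
                            A_FRC=3.2, BSA=0.31, D_trachea=4.0),
    "child": SubjectParams("child", 6.0, 18.8, 115.0, "M",
                           TV=209.0, TV_over_TVA=0.42, V_FRC=830.0, RR=0.32,
                           A_FRC=27.4, BSA=0.77, D_trachea=8.0),
    "adult": SubjectParams("adult", 36.0, 59.8, 160.0, "F",
                           TV=500.0, TV_over_TVA=1.0, V_FRC=3000.0, RR=0.25,
                           A_FRC=64.7, BSA=1.64, D_trachea=16.0),
}


def load_subject(label: str) -> SubjectParams:
    """Return a built-in subject record by label (``infant``/``child``/``adult``)."""
    try:
        return _SUBJECTS[label]
    except KeyError:
        raise LookupError(
            f"unknown subject {label!r}; available: {sorted(_SUBJECTS)}"
        ) from None


@dataclass
class GenerationRow:
    """All airways of one generation within one lobe, lumped together.

    ``n_airways`` airways, each of ``diameter`` × ``length`` (mm), with
    ``length_sd`` the within-generation length standard deviation.
    ``alveolar_volume`` (mL) is the expandable volume attached to this
    generation at FRC (zero for conducting rows).
    """

    lobe: str
    generation: int
    n_airways: int
    diameter: float
    length: float
    length_sd: float
    zone: str
    gravity_cos: float = DEFAULT_GRAVITY_COS
    branch_angle: float = DEFAULT_BRANCH_ANGLE
    alveolar_volume: float = 0.0
    #: characteristic alveolus diameter, mm; settling scale for mass held
    #: in the attached alveolar volume.  Defaults to half the duct
    #: diameter for respiratory rows, 0 for conducting rows.
    alveolar_diameter: float | None = None

    def __post_init__(self) -> None:
        if self.alveolar_diameter is None:
            self.alveolar_diameter = (
                0.5 * self.diameter if self.zone == RESPIRATORY else 0.0
            )
        if self.diameter <= 0 or self.length <= 0:
            raise ValidationError("airway diameter and length must be positive")
        if not 0.0 <= self.gravity_cos <= 1.0:
            raise ValidationError("gravity_cos must lie in [0, 1]")
        if self.zone not in (CONDUCTING, RESPIRATORY):
            raise ValidationError(f"unknown zone {self.zone!r}")
        if self.zone == CONDUCTING and self.alveolar_volume != 0.0:
            raise ValidationError("conducting rows carry no alveolar volume")

    @property
    def airway_volume(self) -> float:
        """Total duct volume of the generation, mL."""
        return self.n_airways * math.pi / 4.0 * self.diameter**2 * self.length / 1e3

    @property
    def airway_area(self) -> float:
        """Summed cross-sectional area of the generation, cm²."""
        return self.n_airways * math.pi / 4.0 * (self.diameter / 10.0) ** 2

    @property
    def total_volume(self) -> float:
        """Airway plus alveolar volume at FRC, mL."""
        return self.airway_volume + self.alveolar_volume


def total_volume(rows: Iterable[GenerationRow]) -> float:
    """Airway + alveolar volume of a row collection at FRC, mL."""
    return sum(r.total_volume for r in rows)


def build_lobe_tree(
    lobe: str,
    n_generations: int,
    z_resp: int,
    seed_dims: Mapping[str, float],
    taper: float = DEFAULT_TAPER,
    *,
    start_generation: int = 0,
    cv_L: float = DEFAULT_CV_L,
    gravity_cos: float = DEFAULT_GRAVITY_COS,
    branch_angle: float = DEFAULT_BRANCH_ANGLE,
    alv_mult: float = DEFAULT_ALV_MULT,
    resp_taper: float = DEFAULT_RESP_TAPER,
) -> list[GenerationRow]:
    """Build a geometric-taper lobe tree of ``n_generations`` rows.

    Row k (absolute generation ``start_generation + k``) has ``2**k``
    airways; conducting rows follow the geometric decay ``d0 * taper**k``
    (likewise lengths), while within the respiratory zone the decay
    flattens to ``resp_taper`` per generation (acinar ducts do not follow
    the conducting branching law).  Respiratory rows carry ``alv_mult``
    times their duct volume as attached alveolar volume, which weights the
    expandable volume toward the deep acinus.
    """
    if not 0.0 < taper < 1.0:
        raise ValidationError(f"taper must lie in (0, 1), got {taper}")
    if not 0.0 < resp_taper < 1.0:
        raise ValidationError(f"resp_taper must lie in (0, 1), got {resp_taper}")
    d0, L0 = float(seed_dims["d0"]), float(seed_dims["L0"])
    if d0 <= 0 or L0 <= 0:
        raise ValidationError("seed dimensions d0, L0 must be positive")
    if z_resp >= start_generation + n_generations:
        raise ValidationError("z_resp must fall inside the generation range")

    rows: list[GenerationRow] = []
    for k in range(n_generations):
        z = start_generation + k
        zone = RESPIRATORY if z >= z_resp else CONDUCTING
        k_cond = min(k, max(z_resp - start_generation - 1, 0))
        k_resp = max(k - k_cond, 0)
        d = d0 * taper**k_cond * resp_taper**k_resp
        L = L0 * taper**k_cond * resp_taper**k_resp
        row = GenerationRow(
            lobe=lobe, generation=z, n_airways=2**k,
            diameter=d, length=L, length_sd=cv_L * L, zone=zone,
            gravity_cos=gravity_cos, branch_angle=branch_angle,
        )
        if zone == RESPIRATORY:
            row.alveolar_volume = alv_mult * row.airway_volume
        rows.append(row)
    return rows


def scale_to_frc(rows: Sequence[GenerationRow], V_target: float) -> list[GenerationRow]:
    """Rescale a tree so its total (airway + alveolar) volume equals ``V_target`` mL.

    All linear dimensions are multiplied by the cube root of the volume
    ratio; alveolar volumes scale with its cube, so the tree shape is
    preserved exactly.
    """
    if V_target <= 0:
        raise ValidationError("target volume must be positive")
    V_current = total_volume(rows)
    if V_current <= 0:
        raise ValidationError("current tree volume must be positive")
    s = (V_target / V_current) ** (1.0 / 3.0)
    return [
        replace(r, diameter=r.diameter * s, length=r.length * s,
                length_sd=r.length_sd * s,
                alveolar_volume=r.alveolar_volume * s**3,
                alveolar_diameter=(r.alveolar_diameter or 0.0) * s)
        for r in rows
    ]


def merge_central_distal(
    central_rows: Sequence[GenerationRow],
    distal_rows: Sequence[GenerationRow],
    area_expansion: float = 1.0,
) -> list[GenerationRow]:
    """Join a central path to a distal tree with cross-sectional area continuity.

    Distal diameters are rescaled by one multiplicative factor so that the
    summed cross-sectional area at the first distal generation equals
    ``area_expansion`` times the area at the last central generation.
    """
    if not central_rows or not distal_rows:
        raise StructuralError("both central and distal collections must be non-empty")
    z_end = max(r.generation for r in central_rows)
    z_start = min(r.generation for r in distal_rows)
    if z_start != z_end + 1:
        raise StructuralError(
            f"generation gap/overlap: central ends at {z_end}, distal starts at {z_start}"
        )
    A_central = sum(r.airway_area for r in central_rows if r.generation == z_end)
    A_distal = sum(r.airway_area for r in distal_rows if r.generation == z_start)
    factor = math.sqrt(area_expansion * A_central / A_distal)
    merged = list(central_rows) + [
        replace(r, diameter=r.diameter * factor) for r in distal_rows
    ]
    return merged


@dataclass
class LungModel:
    """A subject's full airway tree: shared path plus five scaled lobe trees."""

    subject: SubjectParams
    rows: list[GenerationRow]
    lobar_fractions: tuple[float, ...] = DEFAULT_LOBAR_FRACTIONS

    @property
    def V_FRC_model(self) -> float:
        """Total model volume at FRC, mL."""
        return total_volume(self.rows)

    @property
    def V_conducting(self) -> float:
        """Conducting (rigid) airway volume, mL."""
        return sum(r.airway_volume for r in self.rows if r.zone == CONDUCTING)

    @property
    def V_alveolar(self) -> float:
        """Total expandable alveolar volume at FRC, mL."""
        return sum(r.alveolar_volume for r in self.rows)

    def lobe_rows(self, lobe: str) -> list[GenerationRow]:
        return [r for r in self.rows if r.lobe == lobe]


def _shared_path(subject: SubjectParams, taper: float) -> list[GenerationRow]:
    """Trachea (generation 0) and main bronchi (generation 1).

    Trachea length follows a height-based scaling (0.6 mm per cm of body
    height); main bronchi take 40% of the tracheal length and one taper
    step in diameter.
    """
    L_tr = 0.6 * subject.height
    d_tr = subject.D_trachea
    trachea = GenerationRow(SHARED, 0, 1, d_tr, L_tr, DEFAULT_CV_L * L_tr, CONDUCTING)
    d_mb = d_tr * taper
    L_mb = 0.4 * L_tr
    bronchi = GenerationRow(SHARED, 1, 2, d_mb, L_mb, DEFAULT_CV_L * L_mb, CONDUCTING)
    return [trachea, bronchi]


def assemble_lung(
    subject: SubjectParams,
    lobar_fractions: Sequence[float] | None = None,
    config: Mapping[str, object] | None = None,
) -> LungModel:
    """Assemble the FRC-scaled whole-lung model for a subject.

    The shared path keeps the subject's tabulated tracheal dimensions; each
    lobe tree is scaled so its volume equals its lobar fraction of the
    remaining FRC.  ``config`` may override ``n_generations``, ``taper``,
    ``cv_L``, ``alv_mult``, ``gravity_cos``, ``branch_angle`` and the
    per-lobe respiratory-zone start ``z_resp`` (int or mapping lobe→int).
    """
    fractions = tuple(lobar_fractions) if lobar_fractions is not None else DEFAULT_LOBAR_FRACTIONS
    if len(fractions) != len(LOBES):
        raise ValidationError(f"expected {len(LOBES)} lobar fractions")
    if any(not 0.0 < f < 1.0 for f in fractions):
        raise ValidationError("each lobar fraction must lie in (0, 1)")
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValidationError("lobar fractions must sum to 1 within 1e-6")

    cfg = dict(config or {})
    n_gen = int(cfg.get("n_generations", DEFAULT_N_GENERATIONS))
    taper = float(cfg.get("taper", DEFAULT_TAPER))
    cv_L = float(cfg.get("cv_L", DEFAULT_CV_L))
    alv_mult = float(cfg.get("alv_mult", DEFAULT_ALV_MULT))
    resp_taper = float(cfg.get("resp_taper", DEFAULT_RESP_TAPER))
    gravity_cos = float(cfg.get("gravity_cos", DEFAULT_GRAVITY_COS))
    branch_angle = float(cfg.get("branch_angle", DEFAULT_BRANCH_ANGLE))

    z_resp_cfg = cfg.get("z_resp")
    if z_resp_cfg is None:
        z_resp_map = {lobe: DEFAULT_Z_RESP for lobe in LOBES}
        # The infant's left inferior lobe alveolates one generation later.
        if subject.label == "infant":
            z_resp_map["LI"] = DEFAULT_Z_RESP + 1
    elif isinstance(z_resp_cfg, Mapping):
        z_resp_map = {lobe: int(z_resp_cfg.get(lobe, DEFAULT_Z_RESP)) for lobe in LOBES}
    else:
        z_resp_map = {lobe: int(z_resp_cfg) for lobe in LOBES}

    shared = _shared_path(subject, taper)
    V_shared = total_volume(shared)
    V_lobes = subject.V_FRC - V_shared
    if V_lobes <= 0:
        raise ValidationError("shared-path volume exceeds subject FRC")

    rows = list(shared)
    d0 = subject.D_trachea * taper**2  # lobar bronchus seed; rescaled per lobe anyway
    for lobe, frac in zip(LOBES, fractions):
        tree = build_lobe_tree(
            lobe, n_gen - 2, z_resp_map[lobe],
            {"d0": d0, "L0": 3.0 * d0}, taper,
            start_generation=2, cv_L=cv_L, gravity_cos=gravity_cos,
            branch_angle=branch_angle, alv_mult=alv_mult,
            resp_taper=resp_taper,
        )
        rows.extend(scale_to_frc(tree, frac * V_lobes))
    return LungModel(subject=subject, rows=rows, lobar_fractions=fractions)


def area_profile(lung: LungModel, lung_volume: float) -> dict[int, dict[str, float]]:
    """Per-generation summed cross-sectional areas (cm²) at a given lung volume.

    ``A_airway`` is the rigid duct area; ``A_total`` adds the respiratory
    expansion (alveolar volume per unit path length) under the linear wall
    deformation rule.  Valid for V_FRC ≤ lung_volume ≤ V_FRC + TV.
    """
    V0, TV = lung.subject.V_FRC, lung.subject.TV
    if not V0 - 1e-9 <= lung_volume <= V0 + TV + 1e-9:
        raise ValidationError(
            f"lung volume {lung_volume} outside [{V0}, {V0 + TV}] mL"
        )
    inflation = 1.0 + (lung_volume - V0) / lung.V_alveolar
    profile: dict[int, dict[str, float]] = {}
    for r in lung.rows:
        entry = profile.setdefault(r.generation, {"A_airway": 0.0, "A_total": 0.0})
        entry["A_airway"] += r.airway_area
        # alveolar volume (mL = cm³) spread over the generation length (cm)
        A_alv = r.alveolar_volume * inflation / (r.length / 10.0)
        entry["A_total"] += r.airway_area + A_alv
    return profile
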
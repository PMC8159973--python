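"""Synthetic subjects and perturbed morphometries.

The three built-in subject records define the study conditions; this module
generates statistically structured variations around them so that every
pipeline stage can be exercised, and intersubject-robustness experiments
run, without any external data.  Perturbations are multiplicative lognormal
(positivity-preserving) with a configurable coefficient of variation; the
default CV of 0.1 is a modest anatomical spread, not a calibrated
population model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .subjects import (
    LOBES,
    GenerationRow,
    LungModel,
    SubjectParams,
    assemble_lung,
    load_subject,
    scale_to_frc,
    total_volume,
)

#: Allometric exponents used to co-scale surface areas with perturbed volume:
#: areas grow like volume^(2/3).
AREA_VOLUME_EXPONENT = 2.0 / 3.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Reproducible generator settings."""

    seed: int
    age_class: str = "adult"
    cv_dims: float = 0.1
    cv_subject: float = 0.1
    n_subjects: int = 1

    def __post_init__(self) -> None:
        if self.cv_dims < 0 or self.cv_subject < 0:
            raise ValidationError("coefficients of variation must be >= 0")


def fixture_subjects() -> tuple[SubjectParams, SubjectParams, SubjectParams]:
    """The three built-in subject records (infant, child, adult)."""
    return (load_subject("infant"), load_subject("child"), load_subject("adult"))


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0.0:
        return np.ones(size) if size else 1.0
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def generate_subject(
    age_class: str, seed: int, cv_subject: float = 0.1
) -> SubjectParams:
    """Perturb a fixture subject's TV, RR and V_FRC lognormally.

    A_FRC is rescaled with the FRC perturbation to the 2/3 power and BSA is
    kept (body size is not perturbed); TV/TV_adult tracks the perturbed TV
    against the unperturbed adult fixture.  Deterministic per seed.
    """
    if cv_subject < 0:
        raise ValidationError("cv_subject must be >= 0")
    base = load_subject(age_class)
    if cv_subject == 0.0:
        return base
    rng = np.random.default_rng(seed)
    f_tv, f_rr, f_frc = _lognormal_factor(rng, cv_subject, 3)
    TV = base.TV * f_tv
    V_FRC = base.V_FRC * f_frc
    return replace(
        base,
        label=f"{age_class}-synthetic-{seed}",
        TV=TV,
        RR=base.RR * f_rr,
        V_FRC=V_FRC,
        A_FRC=base.A_FRC * (V_FRC / base.V_FRC) ** AREA_VOLUME_EXPONENT,
        TV_over_TVA=TV / load_subject("adult").TV,
    )


def generate_morphometry(
    age_class: str,
    seed: int,
    cv_dims: float = 0.1,
    subject: SubjectParams | None = None,
    config: dict | None = None,
    max_resample: int = 10,
) -> LungModel:
    """Generate a perturbed, FRC-rescaled lung model for an age class.

    Diameters and lengths of every lobe row receive independent lognormal
    factors with CV ``cv_dims``; each lobe is then rescaled back to its
    original volume so the whole-lung FRC constraint still holds exactly.
    """
    if cv_dims < 0:
        raise ValidationError("cv_dims must be >= 0")
    subj = subject if subject is not None else load_subject(age_class)
    lung = assemble_lung(subj, config=config)
    if cv_dims == 0.0:
        return lung
    rng = np.random.default_rng(seed)
    rows = [r for r in lung.rows if r.lobe == "shared"]
    for lobe in LOBES:
        lobe_rows = lung.lobe_rows(lobe)
        V_target = total_volume(lobe_rows)
        perturbed: list[GenerationRow] = []
        for r in lobe_rows:
            for _ in range(max_resample):
                fd, fl = _lognormal_factor(rng, cv_dims, 2)
                if r.diameter * fd > 0 and r.length * fl > 0:
                    break
            perturbed.append(
                replace(r, diameter=r.diameter * fd, length=r.length * fl,
                        length_sd=r.length_sd * fl,
                        alveolar_volume=r.alveolar_volume * fd**2 * fl)
            )
        rows.extend(scale_to_frc(perturbed, V_target))
    return LungModel(subject=subj, rows=rows, lobar_fractions=lung.lobar_fractions)
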
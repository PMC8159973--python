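"""Run configuration, file IO and pipeline assembly.

File dialects:

* Morphometry CSV — header ``lobe,generation,n_airways,diameter_mm,
  length_mm,length_sd_mm,zone,gravity_cos,branch_angle_deg,
  alveolar_volume_ml``; UTF-8, dot decimal, generation 0-based at the
  trachea.
* Results CSV — the deposition ledger with percentages of inhaled mass.
* Metrics JSON — one record per subject × particle size mirroring the
  dose-metric columns.
* RunConfig YAML — round-trips losslessly; every output embeds its hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .breathing import make_waveform
from .errors import ConfigurationError, ParseError
from .kernels import DEFAULT_KERNELS, ParticleSpec
from .metrics import dose_metrics
from .subjects import GenerationRow, LungModel, SubjectParams, assemble_lung, load_subject
from .transport import DepositionResult, simulate_breath

log = logging.getLogger("lungdose")

MORPHOMETRY_COLUMNS = [
    "lobe", "generation", "n_airways", "diameter_mm", "length_mm",
    "length_sd_mm", "zone", "gravity_cos", "branch_angle_deg",
    "alveolar_volume_ml",
]


def write_morphometry(rows: Sequence[GenerationRow], path) -> None:
    """Write rows in the standard morphometry CSV dialect (6 significant digits)."""
    frame = pd.DataFrame(
        [
            {
                "lobe": r.lobe, "generation": r.generation,
                "n_airways": r.n_airways, "diameter_mm": r.diameter,
                "length_mm": r.length, "length_sd_mm": r.length_sd,
                "zone": r.zone, "gravity_cos": r.gravity_cos,
                "branch_angle_deg": r.branch_angle,
                "alveolar_volume_ml": r.alveolar_volume,
            }
            for r in rows
        ],
        columns=MORPHOMETRY_COLUMNS,
    )
    frame.to_csv(path, index=False, float_format="%.6g")


def read_morphometry(path) -> list[GenerationRow]:
    """Read a morphometry CSV, validating the dialect."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse morphometry file {path}: {exc}") from exc
    missing = [c for c in MORPHOMETRY_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    rows = []
    for i, rec in enumerate(frame.to_dict("records"), start=2):  # 1-based + header
        try:
            rows.append(
                GenerationRow(
                    lobe=str(rec["lobe"]), generation=int(rec["generation"]),
                    n_airways=int(rec["n_airways"]),
                    diameter=float(rec["diameter_mm"]),
                    length=float(rec["length_mm"]),
                    length_sd=float(rec["length_sd_mm"]), zone=str(rec["zone"]),
                    gravity_cos=float(rec["gravity_cos"]),
                    branch_angle=float(rec["branch_angle_deg"]),
                    alveolar_volume=float(rec["alveolar_volume_ml"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: malformed row at line {i}: {exc}") from exc
    return rows


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation campaign."""

    subjects: list = field(default_factory=lambda: ["infant", "child", "adult"])
    morphometry_file: str | None = None
    particle_diameters_um: list = field(default_factory=lambda: [1.0, 3.0, 5.0])
    particle_density_g_ml: float = 1.0
    kernels: list = field(default_factory=lambda: list(DEFAULT_KERNELS))
    cells_per_generation: int = 2
    mixing_beta: float = 1.0
    ie_ratio: float = 1.0
    n_breaths: int = 1
    inlet_concentration_ug_ml: float = 1.0
    extrathoracic: bool = False
    extrathoracic_correlation: str | None = None
    seed: int = 0
    output_dir: str = "lungdose-out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def results_frame(result: DepositionResult) -> pd.DataFrame:
    """Ledger as the results CSV layout with deposited % of inhaled."""
    frame = result.ledger.copy()
    if len(frame):
        frame["deposited_pct"] = 100.0 * frame["deposited_ug"] / result.inhaled_ug
    else:
        frame["deposited_pct"] = pd.Series(dtype=float)
    return frame


def run_pipeline(config: RunConfig) -> dict:
    """Morphometry → waveform → transport → metrics for every subject × size.

    Writes, under ``config.output_dir``: one results CSV per run, a
    combined ``metrics.json``, and ``run.log``; returns the metrics
    records.  Any stage failure removes partial outputs and re-raises.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    records = []
    try:
        user_rows = (
            read_morphometry(config.morphometry_file)
            if config.morphometry_file else None
        )
        for label in config.subjects:
            subject = load_subject(label)
            if user_rows is not None:
                lung = LungModel(subject=subject, rows=list(user_rows))
            else:
                lung = assemble_lung(subject)
            waveform = make_waveform(subject.TV, subject.RR, ie_ratio=config.ie_ratio)
            for d_p in config.particle_diameters_um:
                log.info("simulating subject=%s d_p=%.3g um", label, d_p)
                particle = ParticleSpec(d_p=d_p, rho_p=config.particle_density_g_ml)
                result = simulate_breath(
                    lung, waveform, particle,
                    kernel_keys=tuple(config.kernels),
                    n_breaths=config.n_breaths,
                    inlet_concentration=config.inlet_concentration_ug_ml,
                    cells_per_generation=config.cells_per_generation,
                    mixing_beta=config.mixing_beta,
                )
                result.metadata["config_hash"] = config.hash
                path = outdir / f"results_{label}_{d_p:g}um.csv"
                results_frame(result).to_csv(path, index=False)
                written.append(path)
                m = dose_metrics(result, subject)
                records.append(
                    {
                        "subject": label, "d_p_um": d_p,
                        "dep_T": m.dep_T, "dep_C": m.dep_C, "dep_R": m.dep_R,
                        "cr_ratio": m.cr_ratio, "exhaled": m.exhaled,
                        "suspended": m.suspended, "tissue_dose": m.tissue_dose,
                        "dep_rate": m.dep_rate,
                        "dep_rate_per_BSA": m.dep_rate_per_BSA,
                        "tv_scaled_dep": m.tv_scaled_dep,
                        "mass_balance_residual": result.mass_balance_residual,
                        "kernels": list(config.kernels),
                        "cells_per_generation": config.cells_per_generation,
                        "config_hash": config.hash,
                    }
                )
        metrics_path = outdir / "metrics.json"
        metrics_path.write_text(json.dumps(records, indent=2))
        written.append(metrics_path)
        (outdir / "run.log").write_text(
            f"config_hash: {config.hash}\nruns: {len(records)}\n"
        )
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return {"metrics": records, "config_hash": config.hash, "output_dir": str(outdir)}
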
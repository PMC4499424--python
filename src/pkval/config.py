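"""Declarative run configuration with the study-design defaults.

Every field defaults to the validated study design: a 5 mg/kg IV bolus in
n=6 subjects sampled at the 12-point schedule, a 5 ng/mL LLOQ with a
5–1000 ng/mL calibration range and 10-fold dilution above it, QC levels
{10, 50, 100, 500, 1000} ng/mL, and the 15%/20% (LOQ) precision-accuracy
limits with a ±5% stability tolerance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    # study design
    dose_ug_per_kg: float = 5000.0
    n_subjects: int = 6
    schedule_h: tuple = (0.0833, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0, 48.0)
    seed: int = 0
    # simulator noise
    proportional_cv: float = 0.10
    additive_sd: float = 0.0
    inter_subject_cv: float = 0.20
    # assay
    lloq_ng_per_ml: float = 5.0
    uloq_ng_per_ml: float = 1000.0
    dilution_factor: float = 10.0
    calibration_levels: tuple = (5.0, 10.0, 20.0, 50.0, 70.0, 100.0, 200.0, 500.0, 700.0, 1000.0)
    qc_levels: tuple = (10.0, 50.0, 100.0, 500.0, 1000.0)
    # NCA options
    terminal: str = "auto"
    auc_method: str = "linear"
    vss_mode: str = "paper"
    # acceptance limits
    acceptance_limit_pct: float = 15.0
    acceptance_limit_loq_pct: float = 20.0
    stability_tolerance_pct: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("schedule_h", "calibration_levels", "qc_levels"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
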
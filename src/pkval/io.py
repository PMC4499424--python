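"""Delimited-text I/O and plain-text report rendering.

Interchange format is comma-separated UTF-8 with a header row and "." as the
decimal mark. Concentration–time tables carry one row per sample:

    subject_id, dose_ug_per_kg, time_h, conc_ng_per_ml, blq_flag, diluted_flag

QC/calibration/stability batches carry one row per replicate:

    level_ng_per_ml, day, replicate, value

Rounding happens only at rendering time; files hold full precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ConcentrationTimeProfile

PROFILE_COLUMNS = [
    "subject_id",
    "dose_ug_per_kg",
    "time_h",
    "conc_ng_per_ml",
    "blq_flag",
    "diluted_flag",
]

BATCH_COLUMNS = ["level_ng_per_ml", "day", "replicate", "value"]


class ParseError(ValueError):
    """A delimited input file violates the expected schema."""


def profiles_to_frame(profiles) -> pd.DataFrame:
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": p.subject_id,
                    "dose_ug_per_kg": p.dose,
                    "time_h": p.times,
                    "conc_ng_per_ml": p.concentrations,
                    "blq_flag": p.blq_flags.astype(int),
                    "diluted_flag": p.diluted_flags.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_profiles(profiles, path) -> None:
    """Write a cohort of profiles to one delimited file.

    Floats are written at full (shortest round-trip) precision.
    """
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path) -> list[ConcentrationTimeProfile]:
    """Read and validate a cohort file; malformed content raises ParseError.

    Errors name the offending subject (or the missing columns) so a bad row
    in a multi-animal file is directly traceable. Floats are parsed with the
    round-trip parser so write/read is bit-faithful.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    missing = [c for c in PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if frame.empty:
        raise ParseError(f"{path}: no data rows")
    profiles = []
    for subject, g in frame.groupby("subject_id", sort=False):
        doses = g["dose_ug_per_kg"].unique()
        if doses.size != 1:
            raise ParseError(f"{path}: subject {subject!r} has conflicting doses {doses}")
        try:
            profiles.append(
                ConcentrationTimeProfile(
                    subject_id=str(subject),
                    dose=float(doses[0]),
                    times=g["time_h"].to_numpy(dtype=float),
                    concentrations=g["conc_ng_per_ml"].to_numpy(dtype=float),
                    blq_flags=g["blq_flag"].to_numpy(dtype=bool),
                    diluted_flags=g["diluted_flag"].to_numpy(dtype=bool),
                )
            )
        except ValueError as exc:
            first_line = int(g.index[0]) + 2  # header is line 1
            raise ParseError(
                f"{path}: subject {subject!r} (rows from line {first_line}): {exc}"
            ) from None
    return profiles


def write_batch(batch: pd.DataFrame, path) -> None:
    """Write a QC/calibration batch table."""
    batch.to_csv(path, index=False)


def read_batch(path, required=("level_ng_per_ml", "value")) -> pd.DataFrame:
    """Read a replicate batch table, checking the required columns exist."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if frame.empty:
        raise ParseError(f"{path}: no data rows")
    return frame


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return "pass" if x else "FAIL"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, float) and not np.isfinite(x):
        return "n/a"
    if isinstance(x, (float, np.floating)):
        return f"{x:.2f}"
    return str(x)


def _table(frame: pd.DataFrame, index_name: str | None = None) -> list[str]:
    show = frame.reset_index() if index_name else frame
    cols = list(show.columns)
    rows = [[_fmt(v) for v in show[c]] for c in cols]
    widths = [max(len(c), *(len(v) for v in col)) if col else len(c) for c, col in zip(cols, rows)]
    header = "  ".join(c.ljust(w) for c, w in zip(cols, widths))
    lines = [header, "-" * len(header)]
    for i in range(len(show)):
        lines.append("  ".join(rows[j][i].ljust(widths[j]) for j in range(len(cols))))
    return lines


def render_report(
    nca_summary: pd.DataFrame | None = None,
    validation_tables: dict[str, pd.DataFrame] | None = None,
    calibration_summary: str | None = None,
) -> str:
    """Render a deterministic plain-text report.

    Numbers are displayed at 2 decimals (full precision lives in the files);
    sections without content are omitted rather than emitted blank.
    """
    sections: list[str] = []
    if nca_summary is not None and not nca_summary.empty:
        sections.append("Pharmacokinetic parameters (mean ± SD)")
        sections.append("")
        sections.extend(_table(nca_summary, index_name="parameter"))
        sections.append("")
    if calibration_summary:
        sections.append(calibration_summary)
        sections.append("")
    for title, table in (validation_tables or {}).items():
        if table is None or table.empty:
            continue
        sections.append(title)
        sections.append("")
        sections.extend(_table(table))
        sections.append("")
    return "\n".join(sections).rstrip() + "\n"
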
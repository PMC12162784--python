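"""File formats: curve CSV, fit-result JSON, comparison report CSV.

All formats are plain text (UTF-8, ``.`` decimal). The curve table is a
long-format CSV with header ``specimen_id,orientation,strain,stress_kpa``
sorted by (specimen_id, strain); lines beginning with ``#`` are
provenance comments and are skipped on read. Validation is strict and
errors name the offending line.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from hyperfiber.fitting import FitResult, TensileCurve
from hyperfiber.models import params_from_dict, params_to_dict

__all__ = [
    "CurveParseError",
    "read_curves",
    "write_curves",
    "write_report",
    "save_fit_result",
    "load_params",
    "REPORT_COLUMNS",
]

CURVE_HEADER = ["specimen_id", "orientation", "strain", "stress_kpa"]
ORIENTATIONS = ("circumferential", "longitudinal")

#: Fixed column order of the comparison report. Parameter columns not
#: applicable to a model are left empty.
REPORT_COLUMNS = [
    "model_name",
    "C1", "C2", "C3",          # Yeoh / fiber matrix / Neo-Hookean (C1 only)
    "mu", "alpha",             # Ogden (single term; extra terms join with ';')
    "C_iso", "k1", "k2", "kappa",   # GOH
    "E_f", "phi", "k", "theta",     # fiber
    "rmse_circ_pct", "rmse_long_pct",
    "converged", "boundary_hit", "n_iterations", "objective_value",
    "seed", "normalization", "error",
]


class CurveParseError(ValueError):
    """Curve CSV failed validation; the message names the offending line."""


def _provenance_lines(seed=None, config_digest=None) -> list[str]:
    from hyperfiber import __version__
    parts = [f"hyperfiber v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_digest is not None:
        parts.append(f"config_sha256={config_digest}")
    return ["# " + " ".join(parts)]


def config_digest(config: dict) -> str:
    """Short SHA-256 digest of a configuration mapping (provenance tag)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_curves(path: str | Path) -> list[TensileCurve]:
    """Read a curve CSV into per-specimen :class:`TensileCurve` objects.

    Raises :class:`CurveParseError` naming the line for: a wrong header,
    ragged rows, unknown orientation tokens, non-numeric fields, negative
    strain, non-monotone strain within a specimen, or an orientation that
    changes within a specimen.
    """
    path = Path(path)
    rows: dict[str, dict] = {}
    order: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        lineno = 0
        header = None
        for record in reader:
            lineno += 1
            if record and record[0].startswith("#"):
                continue
            if header is None:
                if record != CURVE_HEADER:
                    raise CurveParseError(
                        f"{path}:{lineno}: header must be "
                        f"{','.join(CURVE_HEADER)!r}, got {','.join(record)!r}")
                header = record
                continue
            if not record:
                continue
            if len(record) != 4:
                raise CurveParseError(
                    f"{path}:{lineno}: expected 4 fields, got {len(record)}")
            sid, orientation, strain_s, stress_s = record
            if orientation not in ORIENTATIONS:
                raise CurveParseError(
                    f"{path}:{lineno}: unknown orientation {orientation!r} "
                    f"(expected one of {ORIENTATIONS})")
            try:
                strain = float(strain_s)
                stress = float(stress_s)
            except ValueError as exc:
                raise CurveParseError(f"{path}:{lineno}: non-numeric value: {exc}") from None
            if strain < 0:
                raise CurveParseError(f"{path}:{lineno}: negative strain {strain}")
            if sid not in rows:
                rows[sid] = {"orientation": orientation, "strain": [], "stress": []}
                order.append(sid)
            rec = rows[sid]
            if rec["orientation"] != orientation:
                raise CurveParseError(
                    f"{path}:{lineno}: specimen {sid!r} changes orientation")
            if rec["strain"] and strain < rec["strain"][-1]:
                raise CurveParseError(
                    f"{path}:{lineno}: non-monotone strain within specimen {sid!r}")
            rec["strain"].append(strain)
            rec["stress"].append(stress)
        if header is None:
            raise CurveParseError(f"{path}: empty file, header missing")
    return [TensileCurve(strain=np.array(rows[s]["strain"]),
                         stress=np.array(rows[s]["stress"]),
                         orientation=rows[s]["orientation"], specimen_id=s)
            for s in order]


def write_curves(curves: Sequence[TensileCurve], path: str | Path,
                 seed=None, config_digest=None) -> None:
    """Write curves to the standard CSV, full float precision (repr round-trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        for line in _provenance_lines(seed, config_digest):
            fh.write(line + "\n")
        writer = csv.writer(fh)
        writer.writerow(CURVE_HEADER)
        for c in curves:
            for e, s in zip(c.strain, c.stress):
                writer.writerow([c.specimen_id, c.orientation, repr(float(e)),
                                 repr(float(s))])


def _result_row(r: FitResult) -> dict[str, str]:
    row = {col: "" for col in REPORT_COLUMNS}
    row.update({
        "model_name": r.model_name,
        "rmse_circ_pct": _fmt(r.rmse_circ), "rmse_long_pct": _fmt(r.rmse_long),
        "converged": str(r.converged).lower(),
        "boundary_hit": str(r.boundary_hit).lower(),
        "n_iterations": str(r.n_iterations),
        "objective_value": _fmt(r.objective_value),
        "seed": str(r.seed), "normalization": r.normalization,
        "error": r.error or "",
    })
    if r.params is not None:
        d = params_to_dict(r.params)
        for key in ("C1", "C2", "C3", "C_iso", "k1", "k2", "kappa",
                    "E_f", "phi", "k", "theta"):
            if key in d:
                row[key] = _fmt(d[key])
        if d["model"] == "ogden":
            row["mu"] = ";".join(_fmt(m) for m in d["mu"])
            row["alpha"] = ";".join(_fmt(a) for a in d["alpha"])
    return row


def _fmt(x) -> str:
    import math
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    return repr(float(x))


def write_report(results: Sequence[FitResult], path: str | Path,
                 seed=None, config_digest=None) -> None:
    """Write the model-comparison report: one CSV row per calibrated model."""
    if not results:
        raise ValueError("cannot write an empty report")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        for line in _provenance_lines(seed, config_digest):
            fh.write(line + "\n")
        writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS)
        writer.writeheader()
        for r in results:
            writer.writerow(_result_row(r))


def save_fit_result(result: FitResult, path: str | Path,
                    config_digest=None) -> None:
    """Serialise a fit result to JSON with full provenance."""
    from hyperfiber import __version__
    payload = {
        "tool": "hyperfiber", "version": __version__,
        "model_name": result.model_name,
        "params": params_to_dict(result.params) if result.params is not None else None,
        "rmse_circ_pct": result.rmse_circ, "rmse_long_pct": result.rmse_long,
        "n_iterations": result.n_iterations, "converged": result.converged,
        "objective_value": result.objective_value,
        "bounds_used": [list(b) for b in result.bounds_used],
        "seed": result.seed, "normalization": result.normalization,
        "boundary_hit": result.boundary_hit, "error": result.error,
        "config_sha256": config_digest,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def load_params(path: str | Path, validate: bool = True):
    """Load model parameters from a JSON file (flat dict or saved fit result)."""
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    if "params" in d and isinstance(d["params"], dict):
        d = d["params"]
    return params_from_dict(d, validate=validate)
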
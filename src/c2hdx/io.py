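"""Readers/writers for the package's file dialects and the pipeline driver.

Dialects (all UTF-8, comma-separated, dot decimal, header row required):

* peak-list CSV — columns ``offset,intensity`` (integer isotope offset) or
  ``mz,intensity`` (centroided peaks, matched to the peptide's theoretical
  isotope lattice within a ppm tolerance);
* manifest CSV — columns ``file,t_hours,role`` with ``role`` one of
  ``reference|sample`` (optional ``quenched`` column, 0/1);
* profile CSV — columns ``pH,k`` (optional ``stderr_k``);
* reference-table TSV — the shipped ``table1.tsv``/``table2.tsv`` with rate
  columns in units of 1e-4 / h as printed.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .deuteration import IsotopeEnvelope
from .kinetics import DHX, HDX, ExchangeTimeSeries, TimePoint, fit_dhx_rate, fit_hdx_rate
from .peptide import PROTON_MASS, Peptide, elemental_composition, monoisotopic_mass
from .ph_profile import RateProfile, fit_profile
from .phospho import classify_phospho

__all__ = [
    "read_peaklist", "write_envelope", "read_manifest_series", "read_profile_csv",
    "load_reference_table", "run_pipeline", "resolve_config", "REPORT_SCHEMA_VERSION",
]

log = logging.getLogger("c2hdx")

REPORT_SCHEMA_VERSION = 1

#: Spacing of unit-resolution isotope peaks (13C - 12C), Da.
ISOTOPE_SPACING = 1.0033548378

DEFAULT_PPM_TOL = 10.0


def read_peaklist(path, peptide: Optional[Peptide] = None, charge: int = 1,
                  ppm_tol: float = DEFAULT_PPM_TOL, n_peaks: int = 10) -> IsotopeEnvelope:
    """Read a centroided peak list into an offset-indexed envelope.

    Offset-dialect files are taken as-is (duplicate offsets are summed with
    a warning).  m/z-dialect files are matched against the theoretical
    isotope lattice of ``peptide`` at the given charge: each peak goes to
    the nearest lattice position within ``ppm_tol``; unmatched peaks are
    dropped.
    """
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip().lower() for h in next(reader)]
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            try:
                rows.append((float(row[0]), float(row[1])))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed numeric value in {row!r}") from None

    if header[:2] == ["offset", "intensity"]:
        offsets: Dict[int, float] = {}
        dup = False
        for off_f, inten in rows:
            off = int(round(off_f))
            if off in offsets:
                dup = True
            offsets[off] = offsets.get(off, 0.0) + inten
        if dup:
            warnings.warn(f"{path}: duplicate offsets summed")
        if not offsets:
            raise ValueError(f"{path}: no peaks")
        size = max(max(offsets) + 1, 2)
        env = np.zeros(size)
        for off, inten in offsets.items():
            env[off] = inten
        return IsotopeEnvelope(env, charge=charge)

    if header[:2] == ["mz", "intensity"]:
        if peptide is None:
            raise ValueError(f"{path}: mz-dialect peak list needs a peptide for lattice matching")
        mono = monoisotopic_mass(elemental_composition(peptide))
        base = (mono + charge * PROTON_MASS) / charge
        lattice = base + np.arange(n_peaks) * ISOTOPE_SPACING / charge
        env = np.zeros(n_peaks)
        matched = 0
        for mz, inten in rows:
            j = int(np.argmin(np.abs(lattice - mz)))
            if abs(lattice[j] - mz) / lattice[j] * 1e6 <= ppm_tol:
                env[j] += inten
                matched += 1
        if matched == 0:
            raise ValueError(f"{path}: no peaks within {ppm_tol} ppm of the theoretical lattice")
        last = int(np.flatnonzero(env).max())
        return IsotopeEnvelope(env[: max(last + 1, 2)], charge=charge, base_mz=float(base))

    raise ValueError(f"{path}: unrecognized header {header!r}; expected offset,intensity or mz,intensity")


def write_envelope(path, env: IsotopeEnvelope, normalize: bool = True) -> None:
    """Write an envelope as TSV (offset, intensity)."""
    vals = env.normalized().intensities if normalize else env.intensities
    with Path(path).open("w") as fh:
        fh.write("offset\tintensity\n")
        for j, v in enumerate(vals):
            fh.write(f"{j}\t{v:.12g}\n")


def read_manifest_series(manifest_path, peptide: Peptide, direction: str, pH: float = float("nan"),
                         charge: int = 1, ppm_tol: float = DEFAULT_PPM_TOL) -> ExchangeTimeSeries:
    """Assemble an exchange time series from a manifest CSV of peak-list files."""
    mpath = Path(manifest_path)
    df = pd.read_csv(mpath)
    required = {"file", "t_hours", "role"}
    if not required <= set(df.columns):
        raise ValueError(f"{mpath}: manifest needs columns {sorted(required)}, got {list(df.columns)}")
    reference = None
    points: List[TimePoint] = []
    for _, row in df.iterrows():
        fpath = mpath.parent / str(row["file"])
        if not fpath.exists():
            raise FileNotFoundError(f"{mpath}: referenced file not found: {fpath}")
        env = read_peaklist(fpath, peptide=peptide, charge=charge, ppm_tol=ppm_tol)
        quenched = bool(row.get("quenched", 0)) if "quenched" in df.columns else False
        if str(row["role"]).strip() == "reference":
            reference = env
        else:
            points.append(TimePoint(t=float(row["t_hours"]), envelope=env, quenched=quenched))
    if reference is None:
        raise ValueError(f"{mpath}: no row with role=reference")
    points.sort(key=lambda p: p.t)
    return ExchangeTimeSeries(peptide=peptide, direction=direction, pH=pH,
                              points=points, reference=reference)


def read_profile_csv(path, direction: str = HDX) -> RateProfile:
    """Read a (pH, k[, stderr_k]) table into a RateProfile."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "ph" not in cols or "k" not in cols:
        raise ValueError(f"{path}: profile CSV needs columns pH,k")
    return RateProfile(points=[(float(r[cols["ph"]]), float(r[cols["k"]])) for _, r in df.iterrows()],
                       direction=direction)


def load_reference_table(name: str) -> pd.DataFrame:
    """Load a shipped reference rate table (``table1`` or ``table2``).

    Rate columns are in the printed unit of 1e-4 per hour.
    """
    from importlib.resources import files

    if name not in ("table1", "table2"):
        raise ValueError("name must be 'table1' or 'table2'")
    with files("c2hdx.data").joinpath(f"{name}.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


_PIPELINE_DEFAULTS = {
    "direction": HDX,
    "pH": float("nan"),
    "charge": 1,
    "ppm_tol": DEFAULT_PPM_TOL,
    "k_reference": None,     # enables the phospho call when set
    "threshold_orders": 1.5,
    "seed": None,
}


def resolve_config(defaults: dict, file_config: Optional[dict] = None, overrides: Optional[dict] = None) -> dict:
    """Resolve a run configuration: defaults <- config file <- CLI flags.

    Unknown keys are rejected; every resolved value is logged at startup.
    """
    resolved = dict(defaults)
    for source, layer in (("config file", file_config), ("command line", overrides)):
        if not layer:
            continue
        unknown = set(layer) - set(defaults)
        if unknown:
            raise ValueError(f"unknown configuration keys from {source}: {sorted(unknown)}")
        resolved.update({k: v for k, v in layer.items() if v is not None})
    for key, value in resolved.items():
        log.info("config %s = %r", key, value)
    return resolved


def run_pipeline(manifest_path, peptide: Peptide, config: Optional[dict] = None) -> dict:
    """parse -> envelopes -> kinetics -> optional phospho call, with provenance.

    Any stage failure is re-raised with the stage name and offending input.
    """
    cfg = resolve_config(_PIPELINE_DEFAULTS, file_config=config)
    stage = "read-manifest"
    try:
        series = read_manifest_series(manifest_path, peptide, direction=cfg["direction"],
                                      pH=cfg["pH"], charge=cfg["charge"], ppm_tol=cfg["ppm_tol"])
        stage = "fit-kinetics"
        fit = fit_hdx_rate(series) if cfg["direction"] == HDX else fit_dhx_rate(series)
        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "package_version": __version__,
            "inputs": {"manifest": str(manifest_path), "peptide": peptide.display()},
            "config": {k: v for k, v in cfg.items() if v is not None},
            "fit": {"k": fit.k, "stderr_k": fit.stderr_k, "r_squared": fit.r_squared,
                    "n_points": fit.n_points, "method": fit.method,
                    **({"d0": fit.d0} if fit.d0 is not None else {})},
        }
        if cfg["k_reference"] is not None:
            stage = "classify"
            call = classify_phospho(fit.k, float(cfg["k_reference"]), float(cfg["threshold_orders"]))
            report["phospho_call"] = {"call": call.call, "ratio_orders": call.ratio_orders,
                                      "threshold_orders": call.threshold_orders}
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed for {manifest_path}: {exc}") from exc


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
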
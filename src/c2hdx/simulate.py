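"""Synthetic isotope-envelope time series with the kinetic and noise structure
the fitting modules assume.

The generator emulates a single slowly exchanging site (the histidine
imidazole C2 proton) on top of the peptide's natural isotope envelope:

* uptake (HDX):  d(t) = 1 - exp(-k_eff t)
* loss (DHX):    d(t) = d0 * exp(-k_eff t)

with ``k_eff = k * phospho_suppression`` when the peptide carries a
phosphohistidine.  The observed envelope at each timepoint is the mixture
``(1-d) * natural + d * shift(natural, +1)``, optionally contaminated by a
residual-labile-deuterium artifact (a fraction of molecules retaining one
labile deuteron after back-exchange, shifting the whole pattern one more
offset), then perturbed by multiplicative Gaussian noise per peak.
Negative noise draws are truncated at zero and counted in the series
metadata.

Randomness is fully reproducible: one master seed per run, per-series
substreams derived by stable hashing of (sequence, pH, direction), so a
fixture set is byte-identical regardless of generation order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .deuteration import IsotopeEnvelope, shift_envelope
from .kinetics import DHX, HDX, ExchangeTimeSeries, TimePoint
from .peptide import Peptide, elemental_composition, natural_envelope, parse_sequence
from .ph_profile import model_rate

__all__ = ["SimulationConfig", "simulate_series", "simulate_panel", "make_fixtures"]

#: Default sampling grids (hours).  Uptake runs span ~2 half-lives of the
#: unmodified rate (~0.03 1/h); loss runs extend to the 96 h used to
#: prepare fully deuterated material.
DEFAULT_HDX_TIMEPOINTS = (0.0, 6.0, 12.0, 24.0, 48.0)
DEFAULT_DHX_TIMEPOINTS = (0.0, 8.0, 24.0, 48.0, 96.0)

#: Default pH grid for a titration panel: spans the imidazole pKa region
#: (~7-7.7 in short model peptides) plus alkaline plateau coverage.
DEFAULT_PH_GRID = (6.0, 6.8, 7.3, 7.8, 8.6, 9.2)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated exchange series."""

    peptide: Peptide
    direction: str = HDX
    k: float = 0.027  # h^-1; mid-range unmodified plateau rate
    timepoints: Optional[Sequence[float]] = None  # hours; None -> direction default
    noise_sigma: float = 0.03  # multiplicative Gaussian sd per peak
    residual_labile_fraction: float = 0.0  # workup artifact; 0 = clean back-exchange
    d0: float = 0.95  # initial deuterated fraction (DHX)
    phospho_suppression: float = 0.013  # k multiplier when the peptide carries pHis
    pH: float = 8.5
    temperature: float = 40.0
    n_peaks: int = 8
    quench_after: Optional[float] = None  # hours; later timepoints are acid-quenched holds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.residual_labile_fraction <= 1:
            raise ValueError("residual_labile_fraction must be in [0, 1]")
        if not 0 < self.d0 <= 1:
            raise ValueError("d0 must be in (0, 1]")
        if not 0 < self.phospho_suppression <= 1:
            raise ValueError("phospho_suppression must be in (0, 1]")
        if self.direction not in (HDX, DHX):
            raise ValueError("direction must be HDX or DHX")


def _series_rng(cfg: SimulationConfig) -> np.random.Generator:
    """Substream keyed by (sequence, pH, direction) under the master seed."""
    key = f"{cfg.peptide.display()}|{cfg.pH:.4f}|{cfg.direction}".encode()
    sub = int.from_bytes(hashlib.sha256(key).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(sub,)))


def _occupancy(cfg: SimulationConfig, t: float) -> float:
    k_eff = cfg.k * (cfg.phospho_suppression if cfg.peptide.is_phosphorylated else 1.0)
    t_eff = min(t, cfg.quench_after) if cfg.quench_after is not None else t
    if cfg.direction == HDX:
        return 1.0 - float(np.exp(-k_eff * t_eff))
    return cfg.d0 * float(np.exp(-k_eff * t_eff))


def _observed_envelope(nat: np.ndarray, d: float, residual: float) -> np.ndarray:
    n = nat.size
    base = (1.0 - d) * np.pad(nat, (0, 1)) + d * shift_envelope(nat, 1)
    if residual > 0:
        base = (1.0 - residual) * np.pad(base, (0, 1)) + residual * shift_envelope(base, 1)
    return base[: n + 2]


def simulate_series(cfg: SimulationConfig) -> ExchangeTimeSeries:
    """Generate one exchange time series under ``cfg``; deterministic in the seed."""
    rng = _series_rng(cfg)
    nat = natural_envelope(elemental_composition(cfg.peptide), cfg.n_peaks)
    times = tuple(cfg.timepoints) if cfg.timepoints is not None else (
        DEFAULT_HDX_TIMEPOINTS if cfg.direction == HDX else DEFAULT_DHX_TIMEPOINTS
    )
    truncated = 0

    def noisy(env: np.ndarray) -> np.ndarray:
        nonlocal truncated
        if cfg.noise_sigma == 0:
            return env
        out = env * (1.0 + cfg.noise_sigma * rng.standard_normal(env.size))
        neg = out < 0
        truncated += int(neg.sum())
        out[neg] = 0.0
        return out

    ref_d = 0.0 if cfg.direction == HDX else cfg.d0
    reference = IsotopeEnvelope(noisy(_observed_envelope(nat, ref_d, cfg.residual_labile_fraction)))
    points: List[TimePoint] = []
    for t in times:
        env = IsotopeEnvelope(noisy(_observed_envelope(nat, _occupancy(cfg, t), cfg.residual_labile_fraction)))
        quenched = cfg.quench_after is not None and t > cfg.quench_after
        points.append(TimePoint(t=float(t), envelope=env, quenched=quenched))
    return ExchangeTimeSeries(
        peptide=cfg.peptide, direction=cfg.direction, pH=cfg.pH, points=points,
        reference=reference, temperature=cfg.temperature,
        meta={"true_k": cfg.k, "seed": cfg.seed, "noise_sigma": cfg.noise_sigma,
              "truncated_peaks": truncated},
    )


def simulate_panel(pKa: float, k_max: float, pH_grid: Sequence[float] = DEFAULT_PH_GRID,
                   per_pH_cfg: Optional[SimulationConfig] = None) -> List[ExchangeTimeSeries]:
    """One series per pH, rates drawn from the titration sigmoid; input for fit_profile."""
    if len(pH_grid) < 4:
        raise ValueError("a titration panel needs >= 4 pH values")
    base = per_pH_cfg if per_pH_cfg is not None else SimulationConfig(peptide=parse_sequence("AAAHAF"))
    out = []
    for pH in pH_grid:
        k = float(model_rate(pH, pKa, k_max))
        out.append(simulate_series(replace(base, k=k, pH=float(pH))))
    return out


# --- fixture generation -----------------------------------------------------

_FIXTURE_SPECS = (
    # (name, sequence, direction, k, noise, extras)
    ("hdx_70H0_clean", "AAAHAF", HDX, 0.0270, 0.0, {}),
    ("hdx_70H0_noisy", "AAAHAF", HDX, 0.0270, 0.03, {}),
    ("dhx_6DH2_clean", "DAAHAF", DHX, 0.0255, 0.0, {}),
    ("dhx_6DH2_noisy", "DAAHAF", DHX, 0.0255, 0.03, {}),
    ("dhx_70H0_phospho", "AAAH[p]AF", DHX, 0.0270, 0.03, {}),
    ("hdx_2his_amide", "NHFWKTHT-NH2", HDX, 0.0270, 0.03, {}),
    ("hdx_bAsp_angII", "bDRVYIHPF", HDX, 0.0270, 0.03, {}),
    ("hdx_70H0_labile", "AAAHAF", HDX, 0.0270, 0.03, {"residual_labile_fraction": 0.05}),
)


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the reference rate tables and a deterministic simulated dataset suite.

    Each dataset is a directory of per-timepoint peak-list CSVs plus a
    manifest CSV (columns file,t_hours,role) in the dialect the fitting
    commands consume.  Returns (and writes) a manifest dict recording
    sequences, true rates and seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        from importlib.resources import files

        for name in ("table1.tsv", "table2.tsv"):
            (out / name).write_text(files("c2hdx.data").joinpath(name).read_text())
    except OSError as exc:  # pragma: no cover
        raise OSError(f"cannot write reference tables under {out}: {exc}") from exc

    manifest = {"seed": seed, "datasets": []}
    for name, seq, direction, k, sigma, extras in _FIXTURE_SPECS:
        cfg = SimulationConfig(peptide=parse_sequence(seq), direction=direction, k=k,
                               noise_sigma=sigma, seed=seed, **extras)
        series = simulate_series(cfg)
        ds_dir = out / name
        ds_dir.mkdir(exist_ok=True)
        rows = ["file,t_hours,role"]
        ref_file = ds_dir / "t_ref.csv"
        _write_peaklist(ref_file, series.reference)
        rows.append("t_ref.csv,0.0,reference")
        for pt in series.points:
            fname = f"t_{pt.t:g}h.csv"
            _write_peaklist(ds_dir / fname, pt.envelope)
            rows.append(f"{fname},{pt.t:g},sample")
        (ds_dir / "manifest.csv").write_text("\n".join(rows) + "\n")
        manifest["datasets"].append({
            "name": name, "sequence": seq, "direction": direction, "true_k": k,
            "noise_sigma": sigma, "pH": cfg.pH, "seed": seed,
            "manifest": str(Path(name) / "manifest.csv"), **extras,
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _write_peaklist(path: Path, env: IsotopeEnvelope) -> None:
    lines = ["offset,intensity"]
    lines += [f"{j},{v:.12g}" for j, v in enumerate(env.intensities)]
    path.write_text("\n".join(lines) + "\n")
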
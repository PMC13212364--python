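"""Synthetic phenotyping projects in the exact input layout of the pipeline.

The generator emulates a climate-chamber longitudinal phenotyping experiment:
a factorial design of cultivars x treatments x replicates distributed over
spatial blocks, scanned in waves with per-block start offsets and per-scan
jitter (so raw timestamps are irregular), with logistic height growth, a
drifting NDVI, a saturating PSRI, Gaussian trait noise, and sporadic gross
spikes emulating foreign objects in the scanner's field of view. Everything
is deterministic given the seed, and the emitted directory loads cleanly
through :func:`phenostat.io_project.load_project`.

The default design mirrors a realistic chamber study: 50 cultivars x
2 treatments x 2 replicates (200 plants) over 9 blocks, five scan waves over
20 days.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "generate_project", "ground_truth", "simulate_tables"]


@dataclass
class SyntheticConfig:
    """Design, schedule, trajectory, and artifact parameters.

    Growth per (cultivar, treatment) is logistic,
    ``H(t) = K / (1 + exp(-r (t - t0)))`` with K in mm, r per day, t0 in
    days; cultivar-level variation of K and r is drawn deterministically from
    the seed, and ``treatment_k_effect`` is the relative K difference between
    the first and second treatment (treatment 1 taller). Trait noise is
    Gaussian with sd expressed as a fraction of K. With probability
    ``artifact_rate`` a measurement is multiplied by ``spike_magnitude``.
    """

    n_cultivars: int = 50
    n_treatments: int = 2
    n_replicates: int = 2
    n_blocks: int = 9
    scan_times: tuple = (0.0, 5.0, 10.0, 15.0, 20.0)  # day offsets of scan waves
    scans_per_wave: int = 1
    intra_wave_jitter_hours: float = 1.0
    block_offset_hours: float = 2.0
    base_height_k: float = 300.0  # mm
    cultivar_k_sd: float = 0.08  # relative K spread across cultivars
    treatment_k_effect: float = 0.15  # relative K difference between treatments
    growth_rate: float = 0.35  # r, per day
    growth_rate_jitter: float = 0.05  # relative r spread across cultivars
    growth_midpoint_day: float = 10.0  # t0
    trait_noise_sd: float = 0.05  # fraction of K
    ndvi_start: float = 0.50
    ndvi_end: float = 0.80
    ndvi_treatment_drift: float = 0.05  # extra end-of-experiment NDVI for treatment 2
    ndvi_noise_sd: float = 0.02
    psri_start: float = 0.05
    psri_plateau: float = 0.25
    psri_plateau_day: float = 10.0
    psri_noise_sd: float = 0.02
    artifact_rate: float = 0.01
    spike_magnitude: float = 5.0
    seed: int = 0
    start_datetime: str = "2026-06-01 08:00:00"

    def __post_init__(self):
        for name in ("n_cultivars", "n_treatments", "n_replicates", "n_blocks", "scans_per_wave"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be a probability")
        if list(self.scan_times) != sorted(set(self.scan_times)):
            raise ValueError("scan_times must be strictly increasing")

    @property
    def n_plants(self) -> int:
        return self.n_cultivars * self.n_treatments * self.n_replicates

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scan_times"] = list(self.scan_times)
        return d


def _cultivar_names(config):
    return [f"c{i + 1:02d}" for i in range(config.n_cultivars)]


def _treatment_names(config):
    return [f"T{i + 1}" for i in range(config.n_treatments)]


def ground_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Generating logistic parameters per (cultivar, treatment).

    Keys match the handmade-table metadata exactly, so pipeline estimates can
    be compared against the parameters that generated them.
    """
    rng = np.random.default_rng([config.seed, 0])
    cultivars = _cultivar_names(config)
    treatments = _treatment_names(config)
    k_mult = 1.0 + config.cultivar_k_sd * rng.standard_normal(config.n_cultivars)
    r_mult = 1.0 + config.growth_rate_jitter * rng.standard_normal(config.n_cultivars)
    rows = []
    for ci, cultivar in enumerate(cultivars):
        for ti, treatment in enumerate(treatments):
            # Treatment 1 gets +effect/2, the rest -effect/2 relative K.
            t_mult = 1.0 + (config.treatment_k_effect / 2 if ti == 0 else -config.treatment_k_effect / 2)
            rows.append(
                {
                    "cultivar": cultivar,
                    "treatment": treatment,
                    "K": config.base_height_k * max(k_mult[ci], 0.1) * t_mult,
                    "r": config.growth_rate * max(r_mult[ci], 0.05),
                    "t0": config.growth_midpoint_day,
                }
            )
    return pd.DataFrame(rows)


def _logistic(t, K, r, t0):
    return K / (1.0 + np.exp(-r * (t - t0)))


def simulate_tables(config: SyntheticConfig):
    """Simulate the four project tables in memory.

    Returns ``(raw, handmade, translation, groups)`` DataFrames in the same
    shape as the files written by :func:`generate_project`.
    """
    truth = ground_truth(config).set_index(["cultivar", "treatment"])
    rng = np.random.default_rng([config.seed, 1])
    cultivars = _cultivar_names(config)
    treatments = _treatment_names(config)
    start = pd.Timestamp(config.start_datetime)
    total_days = max(config.scan_times) if max(config.scan_times) > 0 else 1.0

    # Plant roster and spatial layout: round-robin over blocks, 6 plants/row.
    plants = []
    for ci, cultivar in enumerate(cultivars):
        for ti, treatment in enumerate(treatments):
            for rep in range(config.n_replicates):
                plants.append((f"{cultivar}.{treatment}.r{rep + 1}", cultivar, treatment, rep + 1))
    per_block_pos = {}
    roster = []
    for i, (vtr, cultivar, treatment, rep) in enumerate(plants):
        block = i % config.n_blocks + 1
        pos = per_block_pos.get(block, 0)
        per_block_pos[block] = pos + 1
        unit = f"{block}:{pos // 6 + 1}:{pos % 6 + 1}"
        roster.append((vtr, cultivar, treatment, rep, block, unit))

    block_offsets = {
        b: (b - 1) / max(config.n_blocks - 1, 1) * config.block_offset_hours
        for b in range(1, config.n_blocks + 1)
    }

    rows = []
    for vtr, cultivar, treatment, rep, block, unit in roster:
        K, r, t0 = truth.loc[(cultivar, treatment), ["K", "r", "t0"]]
        for wave_day in config.scan_times:
            for _ in range(config.scans_per_wave):
                jitter_h = rng.uniform(0, config.intra_wave_jitter_hours)
                t_hours = wave_day * 24.0 + block_offsets[block] + jitter_h
                t_days = t_hours / 24.0
                height = _logistic(t_days, K, r, t0) + rng.normal(0, config.trait_noise_sd * K)
                frac = min(t_days / total_days, 1.0)
                ndvi_val = config.ndvi_start + (config.ndvi_end - config.ndvi_start) * frac
                if treatment == treatments[-1] and config.n_treatments > 1:
                    ndvi_val += config.ndvi_treatment_drift * frac
                ndvi_val = float(np.clip(ndvi_val + rng.normal(0, config.ndvi_noise_sd), -1, 1))
                psri_val = config.psri_start + (config.psri_plateau - config.psri_start) * min(
                    t_days / config.psri_plateau_day, 1.0
                ) + rng.normal(0, config.psri_noise_sd)
                traits = {"height_mm": height, "ndvi": ndvi_val, "psri": psri_val}
                # draw unconditionally so configs differing only in
                # artifact_rate share the same noise stream
                spikes = rng.random(len(traits)) < config.artifact_rate
                for spiked, name in zip(spikes, traits):
                    if spiked:
                        traits[name] *= config.spike_magnitude
                rows.append(
                    {
                        "unit": unit,
                        "timestamp": (start + pd.to_timedelta(t_hours, unit="h")).strftime(
                            "%Y-%m-%d %H:%M:%S"
                        ),
                        "treatment": treatment,
                        **{k: round(v, 6) for k, v in traits.items()},
                    }
                )
    raw = pd.DataFrame(rows)

    handmade = pd.DataFrame(
        {
            "V.T.R": [p[0] for p in roster],
            "Treatment": [p[2] for p in roster],
            "Cultivar": [p[1] for p in roster],
            "replicate": [f"r{p[3]}" for p in roster],
        }
    )
    translation = pd.DataFrame(
        {"V.T.R": [p[0] for p in roster], "T:X:Y": [p[5] for p in roster]}
    )
    maturity = ["early", "mid", "late"]
    groups = pd.DataFrame(
        {
            "Cultivar": cultivars,
            "maturity_group": [maturity[i % 3] for i in range(config.n_cultivars)],
        }
    )
    return raw, handmade, translation, groups


def generate_project(config: SyntheticConfig, out_dir, name: str = "synthetic") -> Path:
    """Write a complete synthetic project directory.

    Emits ``<name>_data.zip`` (one CSV inside), ``<name>_handmade.csv``,
    ``<name>_translation.csv``, and ``groups.xlsx``. Byte-identical output
    for identical configs (fixed zip metadata, fixed float formatting).
    """
    if config.n_plants == 0:
        raise ValueError("design produces zero plants")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw, handmade, translation, groups = simulate_tables(config)

    zip_path = out_dir / f"{name}_data.zip"
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo(f"{name}_raw.csv", date_time=(2026, 1, 1, 0, 0, 0))
        zf.writestr(info, raw.to_csv(index=False))
    handmade.to_csv(out_dir / f"{name}_handmade.csv", index=False)
    translation.to_csv(out_dir / f"{name}_translation.csv", index=False)
    groups.to_excel(out_dir / "groups.xlsx", index=False)
    return out_dir
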
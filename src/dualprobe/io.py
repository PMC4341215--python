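"""File formats, run configuration and the synthetic cohort generator.

Concentration curves travel as tidy CSV (one row per sample × probe ×
rinse index, concentrations in pM); spectra as two-column (channel,
intensity) CSV with a per-directory manifest; run configuration as a flat
``key = value`` text file.  All CSV files are comma-separated UTF-8 with a
mandatory header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demultiplex import RamanSpectrum, ReferenceLibrary
from .fitting import SolverOptions
from .kinetics import (
    AcquisitionSchedule,
    ConcentrationCurve,
    DualProbeMeasurement,
    simulate_dual_probe,
)
from .simstudy import SimulationConfig

__all__ = [
    "CURVE_COLUMNS",
    "RunConfig",
    "read_curves",
    "write_curves",
    "measurements_to_table",
    "table_to_measurements",
    "generate_cohort",
    "cohort_measurements",
    "read_spectrum",
    "write_spectrum",
    "read_library",
    "write_library",
    "COHORT_GROUPS",
]

log = logging.getLogger("dualprobe")

CURVE_COLUMNS = [
    "sample_id",
    "tissue_label",
    "probe_label",
    "rinse_index",
    "time_min",
    "concentration_pM",
]

#: tissue groups of the emulated cohort: (label, n samples, generating BP)
COHORT_GROUPS = (("healthy", 9, 0.0005), ("U251", 8, 1.0), ("A431", 9, 3.0))


# ---------------------------------------------------------------------------
# concentration-curve tables


def measurements_to_table(measurements: list[DualProbeMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for probe in ("targeted", "untargeted"):
            curve = getattr(m, probe)
            for i, (t, v) in enumerate(zip(curve.times, curve.values)):
                rows.append(
                    {
                        "sample_id": m.sample_id,
                        "tissue_label": m.tissue_label,
                        "probe_label": probe,
                        "rinse_index": i,
                        "time_min": t,
                        "concentration_pM": v,
                    }
                )
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def table_to_measurements(
    table: pd.DataFrame, clamp_negative: bool = True
) -> list[DualProbeMeasurement]:
    """Validate a curve table and assemble paired measurements.

    Negative concentrations (a demultiplexing artifact) are clamped to
    zero with a logged warning when ``clamp_negative`` is set.
    """
    missing = [c for c in CURVE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"curve table is missing columns: {missing}")
    if (table["time_min"] < 0).any():
        row = int(table.index[table["time_min"] < 0][0])
        raise ValueError(f"negative time_min at row {row}")
    dup = table.duplicated(subset=["sample_id", "probe_label", "rinse_index"])
    if dup.any():
        row = int(table.index[dup][0])
        raise ValueError(f"duplicate (sample_id, probe_label, rinse_index) at row {row}")
    n_neg = int((table["concentration_pM"] < 0).sum())
    if n_neg and clamp_negative:
        log.warning("clamping %d negative concentration value(s) to 0 pM", n_neg)
        table = table.copy()
        table.loc[table["concentration_pM"] < 0, "concentration_pM"] = 0.0

    measurements = []
    for sample_id, sample in table.groupby("sample_id", sort=False):
        labels = sample["tissue_label"].unique()
        if len(labels) != 1:
            raise ValueError(f"sample {sample_id!r} has conflicting tissue labels")
        curves = {}
        for probe in ("targeted", "untargeted"):
            rows = sample[sample["probe_label"] == probe].sort_values("rinse_index")
            if rows.empty:
                raise ValueError(f"sample {sample_id!r} is missing {probe} rows")
            idx = rows["rinse_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise ValueError(
                    f"sample {sample_id!r} {probe}: rinse_index not 0-based contiguous"
                )
            curves[probe] = ConcentrationCurve(
                probe,
                rows["time_min"].to_numpy(dtype=float),
                rows["concentration_pM"].to_numpy(dtype=float),
            )
        measurements.append(
            DualProbeMeasurement(
                sample_id=str(sample_id),
                tissue_label=str(labels[0]),
                targeted=curves["targeted"],
                untargeted=curves["untargeted"],
            )
        )
    return measurements


def write_curves(measurements: list[DualProbeMeasurement], path) -> None:
    measurements_to_table(measurements).to_csv(path, index=False)


def read_curves(path, clamp_negative: bool = True) -> list[DualProbeMeasurement]:
    return table_to_measurements(pd.read_csv(path), clamp_negative=clamp_negative)


# ---------------------------------------------------------------------------
# cohort generator


def cohort_measurements(config: "RunConfig") -> list[DualProbeMeasurement]:
    """Simulate the emulated 26-sample tissue cohort.

    Three tissue groups (healthy n=9, U251 n=8, A431 n=9) at generating BP
    0.0005 / 1 / 3, all sharing the default nonspecific rates and noise
    level; per-sample RNG streams are spawned from the run seed.
    """
    sim = config.sim
    out = []
    sample_index = 0
    for label, n, bp in COHORT_GROUPS:
        rates = sim.rates_for_bp(bp)
        for k in range(n):
            seed = np.random.SeedSequence(sim.seed, spawn_key=(2000, sample_index))
            out.append(
                simulate_dual_probe(
                    rates,
                    sim.schedule,
                    noise_percent=sim.noise_percent,
                    seed=seed,
                    applied_concentration=sim.applied_concentration,
                    sample_id=f"{label[0].upper()}{k + 1:02d}",
                    tissue_label=label,
                )
            )
            sample_index += 1
    return out


def generate_cohort(config: "RunConfig") -> pd.DataFrame:
    """Cohort fixture as a curve table (see :data:`CURVE_COLUMNS`)."""
    return measurements_to_table(cohort_measurements(config))


# ---------------------------------------------------------------------------
# spectra files


def write_spectrum(spectrum: RamanSpectrum, path) -> None:
    pd.DataFrame(
        {"channel_cm1": spectrum.channels, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_spectrum(path) -> RamanSpectrum:
    df = pd.read_csv(path)
    for col in ("channel_cm1", "intensity"):
        if col not in df.columns:
            raise ValueError(f"spectrum file {path} is missing column {col!r}")
    return RamanSpectrum(df["channel_cm1"].to_numpy(), df["intensity"].to_numpy())


def write_library(library: ReferenceLibrary, directory) -> None:
    """One CSV per component plus a ``manifest.csv`` (name, role, file)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, spec in library.flavor_spectra.items():
        fname = f"{name}.csv"
        write_spectrum(spec, directory / fname)
        rows.append({"name": name, "role": "flavor", "file": fname})
    write_spectrum(library.background, directory / "background.csv")
    rows.append({"name": "background", "role": "background", "file": "background.csv"})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def read_library(directory) -> ReferenceLibrary:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    flavors: dict[str, RamanSpectrum] = {}
    background = None
    for _, row in manifest.iterrows():
        spec = read_spectrum(directory / row["file"])
        if row["role"] == "flavor":
            flavors[row["name"]] = spec
        elif row["role"] == "background":
            background = spec
    if background is None:
        raise ValueError(f"manifest in {directory} declares no background spectrum")
    return ReferenceLibrary(flavor_spectra=flavors, background=background)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated run configuration: simulation settings plus output paths."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    output_dir: str = "."

    # flat key → (target, attribute, parser)
    _SCHEDULE_KEYS = {
        "stain_duration": float,
        "rinse_interval": float,
        "n_rinses": int,
        "include_pre_rinse": None,  # bool, parsed specially
    }
    _SIM_KEYS = {
        "f_washout": float,
        "k4": float,
        "k5_default": float,
        "k6": float,
        "noise_percent": float,
        "n_iterations": int,
        "bp_fixed_for_sweep": float,
        "applied_concentration": float,
        "seed": int,
    }
    _SIM_LIST_KEYS = ("bp_levels", "k5_sweep")
    _SOLVER_KEYS = {
        "tikhonov_lambda": float,
        "max_sweeps": int,
        "tolerance": float,
        "solver_seed": int,
    }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` text file; unknown keys are rejected.

        Blank lines and ``#`` comments are ignored; list values are
        comma-separated; booleans are ``true``/``false``.
        """
        entries: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in entries:
                raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
            entries[key] = value
        return cls.from_mapping(entries)

    @classmethod
    def from_mapping(cls, entries: dict[str, str]) -> "RunConfig":
        sched_kw: dict = {}
        sim_kw: dict = {}
        solver_kw: dict = {}
        output_dir = "."
        for key, value in entries.items():
            if key == "output_dir":
                output_dir = value
            elif key == "include_pre_rinse":
                if value.lower() not in ("true", "false"):
                    raise ValueError(f"{key} must be true or false, got {value!r}")
                sched_kw[key] = value.lower() == "true"
            elif key in cls._SCHEDULE_KEYS:
                sched_kw[key] = cls._SCHEDULE_KEYS[key](value)
            elif key in cls._SIM_KEYS:
                sim_kw[key] = cls._SIM_KEYS[key](value)
            elif key in cls._SIM_LIST_KEYS:
                sim_kw[key] = tuple(float(v) for v in value.split(",") if v.strip())
            elif key == "solver_seed":
                solver_kw["seed"] = int(value)
            elif key in cls._SOLVER_KEYS:
                solver_kw[key] = cls._SOLVER_KEYS[key](value)
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        sim = SimulationConfig(
            schedule=AcquisitionSchedule(**sched_kw),
            solver=SolverOptions(**solver_kw),
            **sim_kw,
        )
        return cls(sim=sim, output_dir=output_dir)

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]
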
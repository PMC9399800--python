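"""Synthetic concentration-time datasets emulating the batch isomerization study.

The experimental campaign behind the model is a nine-run matrix varying
temperature (70-90 degC), initial sesamin concentration (21.47-23.83 mmol/L),
catalyst loading (1.0-3.0 wt.%) and stirring speed (200-400 rpm, kinetically
inert), always starting from zero asarinin.  No machine-readable
concentration data were deposited, so this module generates datasets with
exactly that structure: the default design, the model dynamics, and a
configurable measurement-noise model calibrated to triplicate HPLC
quantification (default 2% multiplicative Gaussian).

External units mirror the experimental report: mmol/L, degC, wt.%, rpm, and
seconds in the CSV time column.  Internally concentrations stay in mmol/L,
temperature becomes K, catalyst loading a mass fraction, and time minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetic_core import KineticParameters, ReactionConditions
from .simulator import (
    ConcentrationProfile,
    DEFAULT_TIMES_MIN,
    KineticDataset,
    simulate_matrix,
)

__all__ = [
    "NoiseModel",
    "DesignRow",
    "CSV_COLUMNS",
    "default_design",
    "design_to_conditions",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

NOISE_KINDS = ("none", "multiplicative-gaussian", "additive-gaussian")

CSV_COLUMNS = ("run_id", "time_s", "temp_C", "catalyst_wtpct", "rpm",
               "C_A_mmol_per_L", "C_B_mmol_per_L")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise specification.

    ``cv_or_sd`` is a coefficient of variation for multiplicative noise and
    an SD in mmol/L for additive noise; ignored for kind "none".
    """

    kind: str = "multiplicative-gaussian"
    cv_or_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(
                f"invalid noise kind {self.kind!r}; expected one of "
                f"{NOISE_KINDS}")
        if self.cv_or_sd < 0:
            raise ValueError("cv_or_sd must be non-negative")


@dataclass(frozen=True)
class DesignRow:
    """One run of the experimental design, in as-designed (external) units."""

    run_id: str
    C_A0_mmol: float   # initial sesamin, mmol/L
    T_C: float         # temperature, degC
    loading_wtpct: float  # catalyst loading, wt.% of oil
    rpm: float         # stirring speed (metadata only)


def default_design() -> list[DesignRow]:
    """The nine-run experimental matrix of the original campaign."""
    rows = [
        ("run1", 21.47, 80.0, 1.6, 300.0),
        ("run2", 23.83, 80.0, 1.6, 300.0),
        ("run3", 22.91, 80.0, 1.6, 300.0),
        ("run4", 21.47, 70.0, 1.6, 300.0),
        ("run5", 21.47, 90.0, 1.6, 300.0),
        ("run6", 21.47, 80.0, 1.0, 300.0),
        ("run7", 21.47, 80.0, 3.0, 300.0),
        ("run8", 21.47, 80.0, 1.6, 200.0),
        ("run9", 21.47, 80.0, 1.6, 400.0),
    ]
    return [DesignRow(*r) for r in rows]


def design_to_conditions(row: DesignRow) -> ReactionConditions:
    """Convert a design row to internal reaction conditions.

    wt.% loading becomes a catalyst-to-oil mass fraction; asarinin starts
    at exactly zero.
    """
    return ReactionConditions(
        T=row.T_C + 273.15,
        w_cat=row.loading_wtpct / 100.0,
        C_A0=row.C_A0_mmol,
        C_B0=0.0,
        rpm=row.rpm,
        run_id=row.run_id,
    )


def _apply_noise(values: np.ndarray, noise: NoiseModel,
                 rng: np.random.Generator) -> np.ndarray:
    if noise.kind == "none" or noise.cv_or_sd == 0.0:
        return values.copy()
    z = rng.standard_normal(values.shape)
    if noise.kind == "multiplicative-gaussian":
        noisy = values * (1.0 + noise.cv_or_sd * z)
    else:  # additive-gaussian
        noisy = values + noise.cv_or_sd * z
    return np.clip(noisy, 0.0, None)


def generate_dataset(params: KineticParameters,
                     design: Sequence[DesignRow] | None = None,
                     times: Sequence[float] = DEFAULT_TIMES_MIN,
                     noise: NoiseModel = NoiseModel("none", 0.0, 0),
                     replicates: int = 1) -> KineticDataset:
    """Simulate the design and perturb it with the noise model.

    Deterministic given ``noise.seed``.  ``replicates > 1`` appends
    independent noisy copies of each run (run_id suffixed ``-repK``),
    mimicking triplicate measurement campaigns.  Negative noise draws are
    truncated at zero; the noise-free asarinin series starts at exactly 0.
    """
    if design is None:
        design = default_design()
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    conditions = [design_to_conditions(r) for r in design]
    clean = simulate_matrix(conditions, params, times)
    rng = np.random.default_rng(noise.seed)
    profiles = []
    for rep in range(1, replicates + 1):
        suffix = "" if replicates == 1 else f"-rep{rep}"
        for prof in clean:
            profiles.append(ConcentrationProfile(
                run_id=prof.run_id + suffix,
                times=prof.times.copy(),
                C_A=_apply_noise(prof.C_A, noise, rng),
                C_B=_apply_noise(prof.C_B, noise, rng),
                conditions=ReactionConditions(
                    T=prof.conditions.T, w_cat=prof.conditions.w_cat,
                    C_A0=prof.conditions.C_A0, C_B0=prof.conditions.C_B0,
                    rpm=prof.conditions.rpm,
                    run_id=prof.run_id + suffix),
            ))
    return KineticDataset(profiles)


def _profile_frame(prof: ConcentrationProfile) -> pd.DataFrame:
    c = prof.conditions
    return pd.DataFrame({
        "run_id": prof.run_id,
        "time_s": prof.times * 60.0,
        "temp_C": c.T - 273.15,
        "catalyst_wtpct": c.w_cat * 100.0,
        "rpm": c.rpm,
        "C_A_mmol_per_L": prof.C_A,
        "C_B_mmol_per_L": prof.C_B,
    })


def write_dataset(dataset: KineticDataset, path: str | Path) -> None:
    """Serialize a dataset to the package CSV dialect (external units)."""
    frame = pd.concat([_profile_frame(p) for p in dataset], ignore_index=True)
    frame.to_csv(path, index=False, float_format="%.10g")


def read_dataset(path: str | Path) -> KineticDataset:
    """Read a dataset CSV (header-keyed; column order free) and validate it.

    Rows are reported 1-based (excluding the header) in error messages.
    """
    frame = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(frame.columns)
    extra = set(frame.columns) - set(CSV_COLUMNS)
    if missing:
        raise ValueError(f"dataset file {path}: missing columns {sorted(missing)}")
    if extra:
        raise ValueError(f"dataset file {path}: unexpected columns {sorted(extra)}")
    numeric = [c for c in CSV_COLUMNS if c != "run_id"]
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna()]
        if len(bad):
            raise ValueError(
                f"dataset file {path}: non-numeric value in column {col!r}, "
                f"row {int(bad[0]) + 1}")
        frame[col] = coerced
    for col in ("C_A_mmol_per_L", "C_B_mmol_per_L"):
        bad = frame.index[frame[col] < 0]
        if len(bad):
            raise ValueError(
                f"dataset file {path}: negative concentration in column "
                f"{col!r}, row {int(bad[0]) + 1}")

    profiles = []
    for run_id, grp in frame.groupby("run_id", sort=False):
        grp = grp.sort_values("time_s")
        for meta in ("temp_C", "catalyst_wtpct", "rpm"):
            if grp[meta].nunique() > 1:
                raise ValueError(
                    f"dataset file {path}: run {run_id!r} has inconsistent "
                    f"{meta!r} values")
        times_min = grp["time_s"].to_numpy() / 60.0
        C_A = grp["C_A_mmol_per_L"].to_numpy()
        cond = ReactionConditions(
            T=float(grp["temp_C"].iloc[0]) + 273.15,
            w_cat=float(grp["catalyst_wtpct"].iloc[0]) / 100.0,
            C_A0=float(C_A[0]),
            C_B0=float(grp["C_B_mmol_per_L"].iloc[0]),
            rpm=float(grp["rpm"].iloc[0]),
            run_id=str(run_id),
        )
        profiles.append(ConcentrationProfile(
            run_id=str(run_id), times=times_min, C_A=C_A,
            C_B=grp["C_B_mmol_per_L"].to_numpy(), conditions=cond))
    return KineticDataset(profiles)
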
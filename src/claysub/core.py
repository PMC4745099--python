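"""Domain types, dataset I/O and configuration shared by all analysis stages.

The experimental unit is a *paired replicate*: one arm where the wooden block
carries a structural load (concrete pavers, or pavers plus water barrels in
the field) and one control arm where metal spacers carry the load.  Per arm
we record clay mass deposited by the termites, initial and leftover wood
mass, and the inter-paver volume before and after the trial.  Masses are
stored in grams internally; volumes in cm^3.

A replicate enters the analysis only when the termites contacted both arms,
recorded as an explicit boolean rather than inferred from the measurements.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from enum import Enum
from pathlib import Path
import pandas as pd

logger = logging.getLogger("claysub")

__all__ = [
    "Arm",
    "Scale",
    "UnitMeasurement",
    "PairedReplicate",
    "ExperimentDataset",
    "AnalysisConfig",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "dataset_to_json",
    "dataset_from_json",
    "filter_included",
    "CSV_COLUMNS",
]

#: Required columns of the per-arm CSV layout (one row per replicate × arm).
CSV_COLUMNS = [
    "replicate_id",
    "arm",
    "clay_mass_g",
    "initial_wood_g",
    "leftover_wood_g",
    "initial_volume_cm3",
    "final_volume_cm3",
    "contacted_both",
]

#: Relative tolerance for the "unloaded volume unchanged" invariant.
_VOL_RTOL = 1e-6


class SchemaError(ValueError):
    """Input file does not match the expected column layout."""


class ValidationError(ValueError):
    """A measurement violates a physical invariant; names the replicate."""


class Arm(str, Enum):
    UNLOADED = "unloaded"
    LOADED = "loaded"


class Scale(str, Enum):
    FIELD = "field"
    LAB = "lab"


@dataclass(frozen=True)
class UnitMeasurement:
    """Measurements for one arm of a paired replicate (grams, cm^3).

    Invariants: non-negative clay, ``0 <= leftover_wood <= initial_wood``,
    ``0 < final_volume <= initial_volume``, and for the unloaded arm the
    spacers fix the gap so ``final_volume == initial_volume``.
    """

    arm: Arm
    clay_mass: float
    initial_wood: float
    leftover_wood: float
    initial_volume: float
    final_volume: float

    def __post_init__(self) -> None:
        arm = Arm(self.arm)
        object.__setattr__(self, "arm", arm)
        if self.clay_mass < 0:
            raise ValidationError(f"clay_mass must be >= 0, got {self.clay_mass}")
        if not (0 <= self.leftover_wood <= self.initial_wood):
            raise ValidationError(
                "leftover_wood must lie in [0, initial_wood], got "
                f"leftover={self.leftover_wood}, initial={self.initial_wood}"
            )
        if not (0 < self.final_volume <= self.initial_volume * (1 + _VOL_RTOL)):
            raise ValidationError(
                "final_volume must lie in (0, initial_volume], got "
                f"final={self.final_volume}, initial={self.initial_volume}"
            )
        if arm is Arm.UNLOADED and not math.isclose(
            self.final_volume, self.initial_volume, rel_tol=_VOL_RTOL
        ):
            raise ValidationError(
                "unloaded arm must keep final_volume == initial_volume "
                f"(spacers fix the gap), got {self.final_volume} != {self.initial_volume}"
            )


@dataclass(frozen=True)
class PairedReplicate:
    """One replicate unit: an unloaded control arm and a loaded treatment arm."""

    replicate_id: str
    unloaded: UnitMeasurement
    loaded: UnitMeasurement
    contacted_both: bool

    def __post_init__(self) -> None:
        if self.unloaded.arm is not Arm.UNLOADED:
            raise ValidationError(
                f"replicate {self.replicate_id}: 'unloaded' slot holds arm={self.unloaded.arm}"
            )
        if self.loaded.arm is not Arm.LOADED:
            raise ValidationError(
                f"replicate {self.replicate_id}: 'loaded' slot holds arm={self.loaded.arm}"
            )


@dataclass(frozen=True)
class ExperimentDataset:
    """An experiment: its scale, replicates and duration in days."""

    scale: Scale
    replicates: tuple[PairedReplicate, ...]
    duration_days: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "scale", Scale(self.scale))
        object.__setattr__(self, "replicates", tuple(self.replicates))

    @property
    def n_included(self) -> int:
        return sum(r.contacted_both for r in self.replicates)

    def __len__(self) -> int:
        return len(self.replicates)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants shared by the analysis stages.

    gravity in m s^-2; gross_energy_wood in kJ g^-1 (standard softwood gross
    calorific value); lignin_fraction is the indigestible fraction of the
    consumed wood.
    """

    seed: int = 0
    prior_kind: str = "jeffreys"
    n_bootstrap: int = 10_000
    credibility_mass: float = 0.99
    gravity: float = 9.80665
    gross_energy_wood: float = 20.0
    lignin_fraction: float = 0.29
    normalize_mineral_fractions: bool = False
    coupling_model: str = "gaussian_copula"

    def __post_init__(self) -> None:
        if not (0 < self.credibility_mass < 1):
            raise ValidationError("credibility_mass must be in (0, 1)")
        if self.n_bootstrap < 1:
            raise ValidationError("n_bootstrap must be >= 1")
        if not (0 <= self.lignin_fraction < 1):
            raise ValidationError("lignin_fraction must be in [0, 1)")
        if self.prior_kind not in ("jeffreys", "uniform"):
            raise ValidationError(f"unknown prior_kind {self.prior_kind!r}")
        if self.coupling_model not in ("independent", "gaussian_copula"):
            raise ValidationError(f"unknown coupling_model {self.coupling_model!r}")


# ---------------------------------------------------------------------------
# CSV I/O — RFC 4180, UTF-8, header mandatory, one row per (replicate, arm).
# ---------------------------------------------------------------------------


def _row_to_measurement(row: pd.Series, mass_factor: float) -> UnitMeasurement:
    return UnitMeasurement(
        arm=Arm(str(row["arm"])),
        clay_mass=float(row["clay_mass_g"]) * mass_factor,
        initial_wood=float(row["initial_wood_g"]) * mass_factor,
        leftover_wood=float(row["leftover_wood_g"]) * mass_factor,
        initial_volume=float(row["initial_volume_cm3"]),
        final_volume=float(row["final_volume_cm3"]),
    )


def read_dataset(
    path: str | Path,
    scale: Scale | str,
    *,
    duration_days: int | None = None,
    mass_unit: str = "g",
) -> ExperimentDataset:
    """Read a paired-replicate dataset from CSV.

    The file must contain the eight columns in :data:`CSV_COLUMNS`, with one
    row per (replicate, arm).  ``mass_unit='kg'`` converts the three mass
    columns to grams on read (field data are conveniently recorded in kg).

    Raises
    ------
    SchemaError
        if a required column is missing.
    ValidationError
        if a row violates a type invariant; the message names the replicate.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if mass_unit not in ("g", "kg"):
        raise SchemaError(f"mass_unit must be 'g' or 'kg', got {mass_unit!r}")
    mass_factor = 1000.0 if mass_unit == "kg" else 1.0

    scale = Scale(scale)
    if duration_days is None:
        duration_days = 365 if scale is Scale.FIELD else 30

    replicates: list[PairedReplicate] = []
    for rid, group in df.groupby("replicate_id", sort=False):
        arms = {str(a) for a in group["arm"]}
        if arms != {"unloaded", "loaded"} or len(group) != 2:
            raise ValidationError(
                f"replicate {rid}: expected exactly one unloaded and one loaded row, "
                f"got arms {sorted(group['arm'])}"
            )
        by_arm = {str(row["arm"]): row for _, row in group.iterrows()}
        flags = {bool(row["contacted_both"]) for _, row in group.iterrows()}
        if len(flags) != 1:
            raise ValidationError(f"replicate {rid}: inconsistent contacted_both flags")
        try:
            unloaded = _row_to_measurement(by_arm["unloaded"], mass_factor)
            loaded = _row_to_measurement(by_arm["loaded"], mass_factor)
        except ValidationError as exc:
            raise ValidationError(f"replicate {rid}: {exc}") from exc
        replicates.append(
            PairedReplicate(
                replicate_id=str(rid),
                unloaded=unloaded,
                loaded=loaded,
                contacted_both=flags.pop(),
            )
        )
    return ExperimentDataset(scale=scale, replicates=tuple(replicates), duration_days=duration_days)


def write_dataset(ds: ExperimentDataset, path: str | Path) -> None:
    """Write a dataset to the per-arm CSV layout (grams throughout)."""
    rows = []
    for rep in ds.replicates:
        for unit in (rep.unloaded, rep.loaded):
            rows.append(
                {
                    "replicate_id": rep.replicate_id,
                    "arm": unit.arm.value,
                    "clay_mass_g": repr(unit.clay_mass),
                    "initial_wood_g": repr(unit.initial_wood),
                    "leftover_wood_g": repr(unit.leftover_wood),
                    "initial_volume_cm3": repr(unit.initial_volume),
                    "final_volume_cm3": repr(unit.final_volume),
                    "contacted_both": rep.contacted_both,
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def dataset_to_json(ds: ExperimentDataset) -> str:
    """Serialize a dataset to JSON (bit-exact round-trip via float repr)."""
    doc = {
        "scale": ds.scale.value,
        "duration_days": ds.duration_days,
        "replicates": [
            {
                "replicate_id": r.replicate_id,
                "contacted_both": r.contacted_both,
                "unloaded": {**asdict(r.unloaded), "arm": r.unloaded.arm.value},
                "loaded": {**asdict(r.loaded), "arm": r.loaded.arm.value},
            }
            for r in ds.replicates
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def dataset_from_json(text: str) -> ExperimentDataset:
    doc = json.loads(text)
    reps = tuple(
        PairedReplicate(
            replicate_id=r["replicate_id"],
            contacted_both=bool(r["contacted_both"]),
            unloaded=UnitMeasurement(**r["unloaded"]),
            loaded=UnitMeasurement(**r["loaded"]),
        )
        for r in doc["replicates"]
    )
    return ExperimentDataset(
        scale=Scale(doc["scale"]), replicates=reps, duration_days=int(doc["duration_days"])
    )


def filter_included(ds: ExperimentDataset) -> ExperimentDataset:
    """Retain exactly the replicates where termites contacted both arms.

    Order is preserved and the operation is idempotent.  An empty result is
    legal but logged as a warning; downstream stages must handle n = 0.
    """
    kept = tuple(r for r in ds.replicates if r.contacted_both)
    if not kept:
        logger.warning("filter_included: no replicate had contact to both arms (n=0)")
    return replace(ds, replicates=kept)
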
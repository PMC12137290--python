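"""Seeded synthetic maize-soybean intercropping datasets.

The generator emulates the structure of plot-season yield records from a
maize-soybean intercropping trial: 26 numeric soil/crop/management features
plus a treatment code and a location code (28 parameters total), 225 records
by default, and yields in tons/ha bounded roughly 0-10 with maize-dominant
treatments out-yielding sole soybean and Khairpur out-yielding Bahawalpur.

The yield signal is additive-linear in the standardized features plus
treatment and location offsets and Gaussian noise, clipped at zero.  Each
feature's signed contribution is declared in its :class:`FeatureSpec`, so
downstream feature-selection and interpretability code can be tested against
a planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

TREATMENTS = ("SS", "SM", "2M2S", "2M3S")
LOCATIONS = ("Bahawalpur", "Khairpur")

__all__ = [
    "TREATMENTS",
    "LOCATIONS",
    "FeatureSpec",
    "GeneratorConfig",
    "Record",
    "Dataset",
    "SchemaError",
    "default_schema",
    "default_config",
    "generate",
    "write_csv",
    "read_csv",
    "kfold_split",
]


class SchemaError(ValueError):
    """Raised when a feature schema or a CSV file violates the data contract."""


@dataclass(frozen=True)
class FeatureSpec:
    """One numeric feature: its expert range and planted yield contribution.

    ``effect`` is the signed linear contribution (t/ha) of the feature
    standardized to [-1, 1] within its [low, high] range.  ``noise_only``
    features carry no yield signal and exist so selection-recovery tests
    have a planted answer.
    """

    name: str
    group: str  # soil | crop | management
    low: float
    high: float
    effect: float = 0.0
    noise_only: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("soil", "crop", "management"):
            raise SchemaError(f"feature {self.name!r}: unknown group {self.group!r}")
        if not self.low < self.high:
            raise SchemaError(
                f"feature {self.name!r}: requires low < high, got [{self.low}, {self.high}]"
            )
        if self.noise_only and self.effect != 0.0:
            raise SchemaError(
                f"feature {self.name!r}: noise_only features must have effect=0"
            )

    def standardize(self, x: np.ndarray) -> np.ndarray:
        """Map raw values in [low, high] to [-1, 1]."""
        mid = 0.5 * (self.low + self.high)
        half = 0.5 * (self.high - self.low)
        return (np.asarray(x, dtype=float) - mid) / half


def default_schema() -> list[FeatureSpec]:
    """The default 26-feature schema (soil, crop, management groups).

    Effect signs follow the planted ground truth: total biomass, residue
    biomass, PMC and pH act positively on yield; iron and clay negatively.
    """
    s = FeatureSpec
    return [
        # soil
        s("soil_organic_carbon", "soil", 0.3, 2.5, 0.20),
        s("soil_N_pct", "soil", 0.02, 0.25, 0.10),
        s("soil_C_pct", "soil", 0.3, 3.0, 0.08),
        s("CN_ratio", "soil", 8.0, 16.0, 0.05),
        s("bulk_density", "soil", 1.1, 1.7, -0.10),
        s("Mn", "soil", 2.0, 40.0, 0.0, noise_only=True),
        s("P", "soil", 4.0, 30.0, 0.12),
        s("K", "soil", 80.0, 300.0, 0.10),
        s("soil_pH", "soil", 6.0, 8.8, 0.15),
        s("water_pH", "soil", 6.2, 8.5, 0.10),
        s("iron", "soil", 1.0, 12.0, -0.30),
        s("clay_content", "soil", 8.0, 45.0, -0.20),
        s("PMC", "soil", 5.0, 30.0, 0.25),
        s("soil_EC", "soil", 0.2, 4.0, 0.0, noise_only=True),
        s("soil_moisture", "soil", 5.0, 35.0, 0.0, noise_only=True),
        s("zinc_content", "soil", 0.3, 5.0, 0.0, noise_only=True),
        s("sand_content", "soil", 20.0, 70.0, 0.0, noise_only=True),
        # crop
        s("total_biomass", "crop", 0.0, 20.0, 0.80),
        s("crop_biomass", "crop", 0.0, 15.0, 0.30),
        s("LAI", "crop", 0.5, 7.0, 0.25),
        s("transpiration", "crop", 1.0, 9.0, 0.20),
        s("crop_N_uptake", "crop", 20.0, 250.0, 0.20),
        s("yield_per_plant", "crop", 0.05, 0.5, 0.0, noise_only=True),
        # management
        s("M_residue_biomass", "management", 0.0, 10000.0, 0.35),
        s("nutrient_mgmt_score", "management", 1.0, 10.0, 0.15),
        s("pest_mgmt_score", "management", 1.0, 10.0, 0.10),
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic generator; defaults are the study conditions."""

    n_records: int = 225
    features: tuple[FeatureSpec, ...] = field(
        default_factory=lambda: tuple(default_schema())
    )
    base_yield: float = 6.0
    treatment_effects: dict[str, float] = field(
        default_factory=lambda: {"SS": -1.2, "SM": 1.2, "2M2S": 0.45, "2M3S": 0.5}
    )
    location_effects: dict[str, float] = field(
        default_factory=lambda: {"Khairpur": 0.4, "Bahawalpur": -0.4}
    )
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 8:
            raise SchemaError("n_records must be >= 8 (one record per treatment x location)")
        if self.noise_sd < 0:
            raise SchemaError("noise_sd must be >= 0")
        if set(self.treatment_effects) != set(TREATMENTS):
            raise SchemaError(f"treatment_effects keys must be exactly {set(TREATMENTS)}")
        if set(self.location_effects) != set(LOCATIONS):
            raise SchemaError(f"location_effects keys must be exactly {set(LOCATIONS)}")
        seen: set[str] = set()
        for spec in self.features:
            if spec.name in seen:
                raise SchemaError(f"duplicate feature name {spec.name!r}")
            seen.add(spec.name)


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(seed=seed), **overrides)


@dataclass(frozen=True)
class Record:
    """One plot-season observation."""

    features: dict[str, float]
    treatment: str
    location: str
    yield_t_ha: float


@dataclass
class Dataset:
    """An ordered collection of records sharing one feature schema.

    Backed by a :class:`pandas.DataFrame` (columns: features in schema order,
    then ``treatment``, ``location``, ``yield``), which is the tabular
    currency of every downstream module.
    """

    df: pd.DataFrame
    schema: list[FeatureSpec]

    def __post_init__(self) -> None:
        names = [s.name for s in self.schema]
        missing = [c for c in names + ["treatment", "location", "yield"] if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing column: {missing[0]}")
        bad_t = set(self.df["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise SchemaError(
                f"unknown treatment code(s) {sorted(bad_t)}; valid codes: {sorted(TREATMENTS)}"
            )
        bad_l = set(self.df["location"]) - set(LOCATIONS)
        if bad_l:
            raise SchemaError(
                f"unknown location code(s) {sorted(bad_l)}; valid codes: {sorted(LOCATIONS)}"
            )
        # canonical column order
        self.df = self.df[names + ["treatment", "location", "yield"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.schema]

    @property
    def X(self) -> pd.DataFrame:
        """Numeric feature block, schema order."""
        return self.df[self.feature_names]

    @property
    def y(self) -> np.ndarray:
        return self.df["yield"].to_numpy(dtype=float)

    @property
    def groups(self) -> pd.Series:
        """Treatment x location group key per record."""
        return self.df["treatment"] + "/" + self.df["location"]

    def records(self) -> list[Record]:
        out = []
        for _, row in self.df.iterrows():
            out.append(
                Record(
                    features={n: float(row[n]) for n in self.feature_names},
                    treatment=row["treatment"],
                    location=row["location"],
                    yield_t_ha=float(row["yield"]),
                )
            )
        return out

    def subset(self, indices) -> "Dataset":
        return Dataset(self.df.iloc[np.asarray(indices)].reset_index(drop=True), list(self.schema))


def generate(config: GeneratorConfig | None = None) -> Dataset:
    """Draw a seeded synthetic dataset.

    Features are uniform within their expert [low, high] ranges.  Yield is

        base + treatment_effect + location_effect + sum_j effect_j * z_j + N(0, noise_sd)

    with z_j the feature standardized to [-1, 1], clipped below at 0.
    Treatment x location groups are assigned near-balanced, order shuffled
    by the seed; identical seeds give byte-identical output.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_records

    # near-balanced group assignment, then a seeded shuffle of row order
    cells = [(t, loc) for t in TREATMENTS for loc in LOCATIONS]
    assign = [cells[i % len(cells)] for i in range(n)]
    order = rng.permutation(n)
    treatment = np.array([assign[i][0] for i in order])
    location = np.array([assign[i][1] for i in order])

    cols: dict[str, np.ndarray] = {}
    signal = np.zeros(n)
    for spec in config.features:
        x = rng.uniform(spec.low, spec.high, size=n)
        cols[spec.name] = x
        if spec.effect != 0.0:
            signal += spec.effect * spec.standardize(x)

    y = (
        config.base_yield
        + np.array([config.treatment_effects[t] for t in treatment])
        + np.array([config.location_effects[loc] for loc in location])
        + signal
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    y = np.clip(y, 0.0, None)

    df = pd.DataFrame(cols)
    df["treatment"] = treatment
    df["location"] = location
    df["yield"] = y
    return Dataset(df, list(config.features))


def write_csv(data: Dataset, path) -> None:
    """Write a dataset as RFC-4180 CSV (header row, '.' decimal, UTF-8)."""
    data.df.to_csv(path, index=False, float_format="%.17g")


def read_csv(path, schema: list[FeatureSpec] | None = None) -> Dataset:
    """Read a dataset written by :func:`write_csv`.

    ``schema`` defaults to the generator's default schema.  Numeric fields
    round-trip to at least 12 significant digits; category codes exactly.
    """
    schema = schema if schema is not None else default_schema()
    df = pd.read_csv(path, dtype={"treatment": str, "location": str})
    names = [s.name for s in schema]
    for col in names + ["treatment", "location", "yield"]:
        if col not in df.columns:
            raise SchemaError(f"missing column: {col}")
    for col in names + ["yield"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise SchemaError(f"non-numeric value in column {col!r} at row {bad}")
        df[col] = vals
    return Dataset(df, list(schema))


def kfold_split(data: Dataset, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled k-fold partition of the record indices."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(data):
        raise ValueError(f"k={k} exceeds number of records ({len(data)})")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(np.arange(len(data)))]
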
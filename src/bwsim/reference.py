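"""Normalised human-reference trend tables and a synthetic fixture generator.

The reference table has the structure of a BWS meta-analysis export: one
row per (parameter, environment, bws_level) with the normalised mean and
standard deviation of the gait parameter at that unloading level (mean at
0 % BWS is 1 by construction).  The fixture generator emits *synthetic*
tables of the same structure — normalised means near 1 up to a plateau,
declining linearly above it, with seeded Gaussian jitter — so that every
pipeline stage is testable offline.  Fixture values are never human data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import FLOAT_FMT

REFERENCE_COLUMNS = ("parameter", "environment", "bws_level", "mean", "std")
ENVIRONMENTS = ("overground", "treadmill")


class SchemaError(ValueError):
    """A reference table violates its schema."""


@dataclass
class HumanReference:
    """Normalised reference trends, indexed by (parameter, environment)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REFERENCE_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"reference table missing column(s): {', '.join(missing)}")
        errs = []
        for (param, env), grp in self.table.groupby(["parameter", "environment"]):
            levels = set(grp["bws_level"].astype(int))
            if 0 not in levels:
                errs.append(f"{param}/{env}: mandatory 0% BWS row missing")
                continue
            mean0 = float(grp.loc[grp["bws_level"] == 0, "mean"].iloc[0])
            if mean0 != 1.0:
                errs.append(f"{param}/{env}: mean at 0% BWS is {mean0}, must be 1")
        if (self.table["std"] < 0).any():
            errs.append("std column contains negative values")
        if errs:
            raise SchemaError("; ".join(errs))

    @property
    def parameters(self) -> list[str]:
        return sorted(self.table["parameter"].unique())

    def environments(self, parameter: str) -> list[str]:
        sub = self.table[self.table["parameter"] == parameter]
        return sorted(sub["environment"].unique())

    def means(
        self, parameter: str, environment: str, levels: tuple[int, ...]
    ) -> np.ndarray | None:
        """Normalised means at the given levels, or None if absent."""
        sub = self.table[
            (self.table["parameter"] == parameter)
            & (self.table["environment"] == environment)
        ]
        if sub.empty:
            return None
        by_level = dict(zip(sub["bws_level"].astype(int), sub["mean"].astype(float)))
        if not all(lvl in by_level for lvl in levels):
            return None
        return np.array([by_level[lvl] for lvl in levels])


@dataclass
class FixtureSpec:
    """Specification of a synthetic reference table.

    The mean trend stays at ~1 up to ``plateau_end`` percent BWS and then
    declines by ``slope`` (normalised units per 5 % level); seeded Gaussian
    jitter of sd ``noise_std`` is added to the means (the 0 % mean is
    pinned to exactly 1), and the std column is ``noise_std``.
    """

    parameters: tuple[str, ...] = ("stride_length", "cadence", "walking_speed")
    levels: tuple[int, ...] = tuple(range(0, 45, 5))
    environments: tuple[str, ...] = ENVIRONMENTS
    plateau_end: int = 30
    slope: float = 0.05
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_end % 5 != 0:
            raise ValueError(f"plateau_end={self.plateau_end} must be a multiple of 5")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


def generate_reference_fixture(spec: FixtureSpec) -> HumanReference:
    """Generate a synthetic normalised reference table (reproducible per seed)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for parameter in spec.parameters:
        for env in spec.environments:
            for lvl in spec.levels:
                decline = max(0, (lvl - spec.plateau_end) // 5) * spec.slope
                mean = 1.0 - decline
                if lvl != 0 and spec.noise_std > 0:
                    mean += rng.normal(0.0, spec.noise_std)
                rows.append(
                    {
                        "parameter": parameter,
                        "environment": env,
                        "bws_level": lvl,
                        "mean": mean,
                        "std": spec.noise_std,
                    }
                )
    return HumanReference(pd.DataFrame(rows, columns=list(REFERENCE_COLUMNS)))


def write_reference(ref: HumanReference, path: str | Path) -> None:
    """Deterministic CSV export (stable column order, 12-significant-digit floats)."""
    ref.table.to_csv(path, index=False, float_format=FLOAT_FMT, columns=list(REFERENCE_COLUMNS))


def read_reference(path: str | Path, column_map: dict[str, str] | None = None) -> HumanReference:
    """Read and validate a reference CSV.

    ``column_map`` renames external column layouts onto the canonical
    schema, e.g. ``{"level": "bws_level"}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return HumanReference(df)
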
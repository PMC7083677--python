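"""Reading plant observation tables and computing resistance indices.

Each row of an observation table is one ramet (clonal replicate) with its
genotype/population/garden labels, per-level lace-bug damage leaf counts,
a count of leaves damaged by other herbivores, and the total leaf count.
The two resistance indices are per-leaf damage rates: a weighted lace-bug
damage score divided by total leaves, and the other-herbivore damaged-leaf
count divided by total leaves.  The regression model itself consumes the raw
counts with log(total leaves) as covariate; the per-leaf indices are kept for
reporting.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import COUNTRIES, DesignSpec

logger = logging.getLogger(__name__)

LEVEL_COLUMNS = ("lace_lvl_a", "lace_lvl_b", "lace_lvl_c", "lace_lvl_d")

OBSERVATION_COLUMNS = (
    "genotype_id",
    "population_id",
    "origin_country",
    "garden_id",
    "garden_country",
    *LEVEL_COLUMNS,
    "other_damaged_leaves",
    "total_leaves",
)

DEFAULT_WEIGHTS = (0.0, 1.0, 2.0, 3.0)


@dataclass(frozen=True, order=True)
class GroupKey:
    """One of the four origin-country x garden-country analysis groups."""

    origin_country: str
    garden_country: str

    def __post_init__(self):
        for c in (self.origin_country, self.garden_country):
            if c not in COUNTRIES:
                raise ValueError(f"country labels must be one of {COUNTRIES}, got {c!r}")

    def __str__(self) -> str:
        return f"{self.origin_country}_plants_{self.garden_country}_gardens"


#: The four groups in a fixed, reportable order.
ALL_GROUP_KEYS = tuple(
    GroupKey(o, g) for o in COUNTRIES for g in COUNTRIES
)


class ObservationValidationError(ValueError):
    """Raised when an observation table violates row-level invariants."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid observation table:\n" + "\n".join(problems[:50])
            + ("" if len(problems) <= 50 else f"\n... and {len(problems) - 50} more")
        )


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a PlantObservation table, raising a per-row error report."""
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationValidationError([f"missing column(s): {', '.join(missing)}"])
    problems: list[str] = []
    count_cols = [*LEVEL_COLUMNS, "other_damaged_leaves", "total_leaves"]
    for col in count_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        for idx in df.index[bad]:
            problems.append(f"row {idx}: column {col} must be a non-negative integer, got {df.at[idx, col]!r}")
    if not problems:
        df = df.copy()
        for col in count_cols:
            df[col] = df[col].astype(np.int64)
        lace_sum = df[list(LEVEL_COLUMNS)].sum(axis=1)
        for idx in df.index[df["total_leaves"] < 1]:
            problems.append(f"row {idx}: total_leaves must be >= 1")
        for idx in df.index[lace_sum > df["total_leaves"]]:
            problems.append(
                f"row {idx}: lace-level counts sum to {lace_sum[idx]} "
                f"> total_leaves {df.at[idx, 'total_leaves']}"
            )
        for idx in df.index[df["other_damaged_leaves"] > df["total_leaves"]]:
            problems.append(f"row {idx}: other_damaged_leaves exceeds total_leaves")
        for col in ("origin_country", "garden_country"):
            bad = ~df[col].isin(COUNTRIES)
            for idx in df.index[bad]:
                problems.append(f"row {idx}: {col} must be one of {COUNTRIES}, got {df.at[idx, col]!r}")
    if problems:
        raise ObservationValidationError(problems)
    return df


def read_observations(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate an observation CSV.

    Parameters
    ----------
    path:
        CSV file with the documented header.
    column_map:
        Optional mapping from external column names to the canonical ones,
        for ingesting files with different headers.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return validate_observations(df)


def lace_bug_damage_score(level_counts, weights: Sequence[float] = DEFAULT_WEIGHTS):
    """Weighted sum of per-level lace-bug damaged-leaf counts.

    ``level_counts`` may be a length-4 sequence or an (n, 4) array; the score
    is sum_level weight_level * count_level.
    """
    counts = np.asarray(level_counts, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise ValueError("weights must have length 4")
    if counts.shape[-1] != 4:
        raise ValueError("level_counts must have trailing dimension 4")
    if (counts < 0).any():
        raise ValueError("level counts must be non-negative")
    return counts @ w


def damage_index(score, total_leaves):
    """Per-leaf damage: score divided by total leaf count."""
    leaves = np.asarray(total_leaves, dtype=float)
    if (leaves < 1).any():
        raise ValueError("total_leaves must be >= 1")
    return np.asarray(score, dtype=float) / leaves


def add_damage_indices(df: pd.DataFrame, weights: Sequence[float] = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Append lace score and the two per-leaf resistance indices."""
    out = df.copy()
    out["lace_score"] = lace_bug_damage_score(df[list(LEVEL_COLUMNS)].to_numpy(), weights)
    out["lace_index"] = damage_index(out["lace_score"], out["total_leaves"])
    out["other_index"] = damage_index(out["other_damaged_leaves"], out["total_leaves"])
    return out


def subset_by_group(records: pd.DataFrame, key: GroupKey) -> pd.DataFrame:
    """Rows whose plant origin and garden country match ``key``.

    Attaches ``n_genotypes`` and ``replicates_per_genotype`` to the result's
    ``attrs`` and warns on an empty subset rather than silently returning it.
    """
    if len(records) == 0:
        raise ValueError("records table is empty")
    mask = (records["origin_country"] == key.origin_country) & (
        records["garden_country"] == key.garden_country
    )
    sub = records[mask].copy()
    if len(sub) == 0:
        warnings.warn(f"group {key} has no observations", stacklevel=2)
        sub.attrs["n_genotypes"] = 0
        sub.attrs["replicates_per_genotype"] = {}
        return sub
    reps = sub.groupby("genotype_id").size()
    sub.attrs["n_genotypes"] = int(reps.size)
    sub.attrs["replicates_per_genotype"] = reps.to_dict()
    logger.info(
        "group %s: %d genotypes, replicates per genotype %s",
        key,
        reps.size,
        sorted(set(reps.values)),
    )
    return sub


def partition_groups(records: pd.DataFrame) -> dict[GroupKey, pd.DataFrame]:
    """Split a full table into the four analysis groups (a disjoint partition)."""
    return {key: subset_by_group(records, key) for key in ALL_GROUP_KEYS}


def expected_subset_shape(design: DesignSpec, key: GroupKey) -> tuple[int, int]:
    """(genotype count, replicates per genotype) implied by a design for a group."""
    n_gen = sum(
        design.genotypes_per_population
        for _, origin in design.populations
        if origin == key.origin_country
    )
    n_gardens = sum(1 for _, c in design.gardens if c == key.garden_country)
    return n_gen, n_gardens * design.ramets_per_genotype_per_garden
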
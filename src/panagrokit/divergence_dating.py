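"""Generation-time-calibrated divergence dating from genome distances.

Whole-genome pairwise distances (e.g. an alignment-free ANDI matrix) are
converted to absolute ages by linear calibration against a reference pair
of known divergence time, then rescaled by generation time: organisms that
cycle faster accumulate substitutions faster per calendar year, so at a
fixed per-generation substitution rate the age in years is proportional to
the assumed generation time,

    age(i, j) = cal_age * d(i, j) / d(cal pair) * (target_gen / cal_gen).

Reporting the same distances under, say, 8-day and 50-day generation times
brackets the age of a split between a laboratory measure and a
conservative field estimate (ratio 50/8 = 6.25 exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

JC_SATURATION = 0.75  # mismatch fraction at which Jukes-Cantor diverges
_SKIP_CHARS = frozenset("-Nn.?")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if list(self.data.index) != list(self.data.columns):
            raise ValueError("row and column taxa must match")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("diagonal must be zero")
        if (values < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def distance(self, a: str, b: str) -> float:
        return float(self.data.loc[a, b])

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        """Read a square PHYLIP distance matrix (count line, then rows)."""
        with open(path) as fh:
            tokens = fh.read().split()
        n = int(tokens[0])
        taxa, rows, k = [], [], 1
        for _ in range(n):
            taxa.append(tokens[k])
            rows.append([float(t) for t in tokens[k + 1:k + 1 + n]])
            k += 1 + n
        return cls(pd.DataFrame(rows, index=taxa, columns=taxa))

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "DistanceMatrix":
        """Read a long-format TSV (taxonA, taxonB, distance)."""
        df = pd.read_csv(
            path, sep="\t", header=None, names=["a", "b", "d"],
            comment="#", dtype=str,
        )
        try:  # tolerate an optional header row
            float(df.iloc[0]["d"])
        except ValueError:
            df = df.iloc[1:].reset_index(drop=True)
        df["d"] = df["d"].astype(float)
        taxa = sorted(set(df["a"]) | set(df["b"]))
        m = pd.DataFrame(0.0, index=taxa, columns=taxa)
        for _, row in df.iterrows():
            m.loc[row["a"], row["b"]] = row["d"]
            m.loc[row["b"], row["a"]] = row["d"]
        return cls(m)

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for taxon in self.taxa:
                row = " ".join(f"{self.data.loc[taxon, t]:.6f}" for t in self.taxa)
                fh.write(f"{taxon} {row}\n")


@dataclass(frozen=True)
class CalibrationSpec:
    """Reference pair, its age, and the generation times involved."""

    cal_taxa: tuple[str, str]
    cal_age_myr: float
    cal_gen_days: float
    target_gen_days: float

    def __post_init__(self) -> None:
        if self.cal_age_myr <= 0 or self.cal_gen_days <= 0 or self.target_gen_days <= 0:
            raise ValueError("calibration age and generation times must be positive")


@dataclass(frozen=True)
class DivergenceEstimate:
    taxon_a: str
    taxon_b: str
    age_myr: float
    gen_days: float


def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance between two aligned sequences.

    Columns containing a gap or N in either sequence are dropped. The
    mismatch fraction p maps to d = -(3/4) ln(1 - 4p/3); p >= 3/4 is
    saturated and raises.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    kept = 0
    mismatches = 0
    for x, y in zip(seq_a, seq_b):
        if x in _SKIP_CHARS or y in _SKIP_CHARS:
            continue
        kept += 1
        if x.upper() != y.upper():
            mismatches += 1
    if kept == 0:
        raise ValueError("no comparable columns after dropping gaps/Ns")
    p = mismatches / kept
    if p >= JC_SATURATION:
        raise ValueError(
            f"mismatch fraction {p:.3f} >= {JC_SATURATION}: distance saturated"
        )
    return -0.75 * math.log(1.0 - p / 0.75)


def rescale_age(age_myr: float, gen_days_from: float, gen_days_to: float) -> float:
    """Rescale an age between generation-time assumptions (linear)."""
    if age_myr <= 0 or gen_days_from <= 0 or gen_days_to <= 0:
        raise ValueError("age and generation times must be positive")
    return age_myr * gen_days_to / gen_days_from


def estimate_ages(
    dm: DistanceMatrix, cal: CalibrationSpec
) -> list[DivergenceEstimate]:
    """Age every taxon pair by linear calibration and generation rescaling."""
    a, b = cal.cal_taxa
    missing = {a, b} - set(dm.taxa)
    if missing:
        raise KeyError(f"calibration taxa not in matrix: {sorted(missing)}")
    d_cal = dm.distance(a, b)
    if d_cal <= 0:
        raise ValueError("calibration pair distance must be positive")
    scale = cal.cal_age_myr / d_cal * (cal.target_gen_days / cal.cal_gen_days)
    return [
        DivergenceEstimate(t1, t2, dm.distance(t1, t2) * scale, cal.target_gen_days)
        for t1, t2 in combinations(dm.taxa, 2)
    ]


def ages_to_frame(estimates: Sequence[DivergenceEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_a": e.taxon_a,
                "taxon_b": e.taxon_b,
                "gen_days": e.gen_days,
                "age_myr": e.age_myr,
            }
            for e in estimates
        ]
    )
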
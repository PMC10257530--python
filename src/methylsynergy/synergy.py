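"""Bliss-independence synergy scoring for combination-treatment viability.

Under Bliss independence the expected viability of a combination is the
product of the single-agent viabilities, V_expected = V_A * V_B (viabilities
as fractions of the untreated control).  For each replicate set the score is
delta = V_expected - V_observed; the combination is synergistic when the
mean delta over retained replicates is positive.  Replicate sets whose
control viability lies 3 or more sample standard deviations from the mean
control viability are excluded before scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

TREATMENT_COLUMNS = ["drug_a", "drug_b", "combination", "control"]


@dataclass
class ViabilityTable:
    """Replicate-set x treatment viability fractions (control-normalised)."""

    values: pd.DataFrame   # columns drug_a, drug_b, combination, control

    def __post_init__(self):
        df = pd.DataFrame(self.values).reset_index(drop=True).astype(float)
        missing = [c for c in TREATMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"viability table missing columns {missing}")
        if (df[TREATMENT_COLUMNS] < 0).any().any():
            raise ValueError("negative viability")
        self.values = df[TREATMENT_COLUMNS]

    def __len__(self) -> int:
        return len(self.values)


def read_plate_csv(path, treatment_map: dict[str, str] | None = None) -> ViabilityTable:
    """Read a long-format plate CSV (replicate_id, treatment, viability).

    ``treatment_map`` renames plate treatment labels to the canonical
    drug_a / drug_b / combination / control columns.
    """
    df = pd.read_csv(path)
    if treatment_map:
        df["treatment"] = df["treatment"].map(lambda t: treatment_map.get(t, t))
    wide = df.pivot_table(index="replicate_id", columns="treatment",
                          values="viability", aggfunc="mean")
    return ViabilityTable(wide.reset_index(drop=True))


@dataclass
class SynergyResult:
    expected: np.ndarray       # per retained replicate
    observed: np.ndarray
    delta: np.ndarray          # expected - observed
    mean_delta: float
    is_synergistic: bool
    n_excluded: int = 0

    def to_json_dict(self) -> dict:
        return {"mean_delta": self.mean_delta,
                "is_synergistic": bool(self.is_synergistic),
                "n_replicates": int(len(self.delta)),
                "n_excluded": int(self.n_excluded),
                "delta": [float(x) for x in self.delta]}


def expected_combination_viability(v_a: float, v_b: float) -> float:
    """Bliss expected viability of the combination: V_A * V_B."""
    if v_a < 0 or v_b < 0:
        raise ValueError("viabilities must be >= 0")
    return v_a * v_b


def exclude_outlier_replicates(table: ViabilityTable,
                               control_column: str = "control"
                               ) -> tuple[ViabilityTable, int]:
    """Drop replicate sets whose control deviates >= 3 sample SD from the mean.

    Each control is compared against the mean and sample SD (ddof=1) of the
    *other* controls (leave-one-out): with the candidate left in, the
    deviation is bounded by (n-1)/sqrt(n) sample SDs, so a 3-SD rule could
    never fire on plates with fewer than 11 replicate sets.  A zero
    leave-one-out SD with zero deviation keeps the replicate; a nonzero
    deviation over a zero SD is infinitely many SDs and excludes it.
    Needs >= 2 control replicates (so the SD is defined), excluding nothing
    when all controls are equal.
    """
    ctrl = table.values[control_column].to_numpy(float)
    n = len(ctrl)
    if n < 2:
        raise ValueError("outlier rule needs >= 2 control replicates")
    keep = np.ones(n, dtype=bool)
    total = ctrl.sum()
    total_sq = (ctrl ** 2).sum()
    for i in range(n):
        rest_n = n - 1
        mean = (total - ctrl[i]) / rest_n
        if rest_n >= 2:
            var = max(0.0, (total_sq - ctrl[i] ** 2 - rest_n * mean ** 2)
                      / (rest_n - 1))
        else:
            var = 0.0
        dev = abs(ctrl[i] - mean)
        sd = np.sqrt(var)
        if dev == 0:
            continue
        if sd == 0 or dev >= 3 * sd:
            keep[i] = rest_n < 2  # undefined SD for n=2: keep
    return ViabilityTable(table.values[keep]), int((~keep).sum())


def synergy_score(table: ViabilityTable, exclude_outliers: bool = True,
                  control_column: str = "control") -> SynergyResult:
    """Score a plate: per-replicate Bliss delta and the mean verdict."""
    n_excluded = 0
    if exclude_outliers and len(table) >= 2:
        table, n_excluded = exclude_outlier_replicates(table, control_column)
    if len(table) == 0:
        raise ValueError("no replicate sets retained for synergy scoring")
    va = table.values["drug_a"].to_numpy(float)
    vb = table.values["drug_b"].to_numpy(float)
    obs = table.values["combination"].to_numpy(float)
    exp = va * vb
    delta = exp - obs
    mean_delta = float(delta.mean())
    return SynergyResult(exp, obs, delta, mean_delta, mean_delta > 0, n_excluded)


def write_synergy_report(result: SynergyResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
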
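"""Trait adjustment to a 100 kg endpoint and mid-parent heterosis.

Growth records are taken at slaughter-test weights that differ between
animals, so age (AGE, days) and backfat thickness (BF, mm) are projected to
a common 100 kg body-weight endpoint with the standard linear corrections

    100AGE = AGE + (100 - wt) * (AGE - A) / wt
    100BF  = BF  + (100 - wt) * BF / (wt - B)

where A and B are sex-specific correction coefficients (boar-scale vs
sow-scale constants).  Mid-parent heterosis for a trait is

    MPH = (F1 - MP) / MP * 100,  MP = (P1 + P2) / 2,

the percent superiority of the crossbred value over the parental average.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

_MALE = {"male", "m", "sire", "boar", "1"}
_FEMALE = {"female", "f", "sow", "dam", "gilt", "2"}


@dataclass(frozen=True)
class AdjustmentConstants:
    """Sex-specific correction coefficients for the 100 kg adjustment."""

    A_sire: float = 50.775
    A_sow: float = 46.415
    B_sire: float = -7.277
    B_sow: float = -9.440


def _is_male(sex) -> np.ndarray:
    sex_arr = np.atleast_1d(np.asarray(sex)).astype(str)
    low = np.char.lower(sex_arr)
    male = np.isin(low, list(_MALE))
    female = np.isin(low, list(_FEMALE))
    if not np.all(male | female):
        bad = sex_arr[~(male | female)][0]
        raise ValueError(f"unrecognized sex label {bad!r}")
    return male


def adjust_age_100kg(
    age_days, weight, sex, constants: AdjustmentConstants = AdjustmentConstants()
):
    """Project age at a recorded weight to the expected age at 100 kg.

    At ``weight == 100`` the record is returned unchanged; heavier animals
    adjust downward (they would have hit 100 kg younger).  Scalar in, scalar
    out; arrays broadcast elementwise.
    """
    age = np.asarray(age_days, dtype=float)
    wt = np.asarray(weight, dtype=float)
    if np.any(wt <= 0):
        raise ValueError("weight must be positive")
    male = _is_male(sex)
    A = np.where(male, constants.A_sire, constants.A_sow)
    out = np.atleast_1d(age + (100.0 - wt) * (age - A) / wt)
    return float(out[0]) if np.isscalar(age_days) and out.size == 1 else out


def adjust_bf_100kg(
    backfat, weight, sex, constants: AdjustmentConstants = AdjustmentConstants()
):
    """Project backfat thickness at a recorded weight to 100 kg."""
    bf = np.asarray(backfat, dtype=float)
    wt = np.asarray(weight, dtype=float)
    if np.any(wt <= 0):
        raise ValueError("weight must be positive")
    male = _is_male(sex)
    B = np.where(male, constants.B_sire, constants.B_sow)
    denom = wt - B
    if np.any(denom <= 0):
        raise ValueError("weight - B must be positive")
    out = np.atleast_1d(bf + (100.0 - wt) * bf / denom)
    return float(out[0]) if np.isscalar(backfat) and out.size == 1 else out


@dataclass
class MPHResult:
    """Mid-parent heterosis, per individual and for the group mean.

    ``group_mph`` is the MPH of the mean F1 value — not the mean of the
    per-individual MPH values, which is reported separately as
    ``mean_individual_mph`` (the two coincide here because MPH is linear in
    F1 at fixed parental means, but both are kept and labeled distinctly).
    """

    individual_mph: np.ndarray
    group_mph: float
    mean_individual_mph: float
    p1_mean: float
    p2_mean: float
    group: str | None = None


def mid_parent_heterosis(
    f1_values, p1_mean: float, p2_mean: float, group: str | None = None
) -> MPHResult:
    """Percent deviation of crossbred values from the mid-parent mean."""
    mp = (p1_mean + p2_mean) / 2.0
    if mp == 0:
        raise ValueError("mid-parent value is zero; MPH undefined")
    f1 = np.asarray(f1_values, dtype=float)
    indiv = (f1 - mp) / mp * 100.0
    return MPHResult(
        individual_mph=indiv,
        group_mph=float((f1.mean() - mp) / mp * 100.0),
        mean_individual_mph=float(indiv.mean()),
        p1_mean=float(p1_mean),
        p2_mean=float(p2_mean),
        group=group,
    )


def mph_by_group(
    values: pd.DataFrame,
    p1_mean: float | dict,
    p2_mean: float | dict,
    value_col: str = "value",
    group_col: str = "sire",
) -> pd.DataFrame:
    """MPH per sire family, the six-group layout of a boar-line cross.

    ``p1_mean``/``p2_mean`` may be scalars (breed-wide means) or dicts keyed
    by group (e.g. sire-specific parental means).
    """
    rows = []
    for grp, sub in values.groupby(group_col, sort=True):
        p1 = p1_mean[grp] if isinstance(p1_mean, dict) else p1_mean
        p2 = p2_mean[grp] if isinstance(p2_mean, dict) else p2_mean
        res = mid_parent_heterosis(sub[value_col].to_numpy(), p1, p2, group=str(grp))
        rows.append(
            {
                "group": str(grp),
                "n": len(sub),
                "group_mph": res.group_mph,
                "mean_individual_mph": res.mean_individual_mph,
                "p1_mean": p1,
                "p2_mean": p2,
            }
        )
    return pd.DataFrame(rows)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated phenotype table (id, sex, age, bf, wt, sire, dam)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    required = {"id", "sex", "age", "bf", "wt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def adjust_table(
    df: pd.DataFrame, constants: AdjustmentConstants = AdjustmentConstants()
) -> pd.DataFrame:
    """Add 100AGE / 100BF columns to a raw phenotype table."""
    out = df.copy()
    out["age100"] = adjust_age_100kg(df["age"], df["wt"], df["sex"], constants)
    out["bf100"] = adjust_bf_100kg(df["bf"], df["wt"], df["sex"], constants)
    return out
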
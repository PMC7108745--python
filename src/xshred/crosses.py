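"""Genetic-cross summary statistics for sex-distorter experiments.

The replicate unit is the single-male cross (one male x three females);
pooled crosses contribute one observation each. Per cross the module reports
the male fraction with an exact (Clopper-Pearson) 95% confidence interval;
genotypes are compared with Welch's unequal-variance t-test on per-replicate
fractions, and developmental cohorts are summarised as stage-wise survival
rates (embryo->pupa, pupa->adult, adult sex fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class CrossRecord:
    genotype: str
    replicate: str | int
    n_males: int
    n_females: int
    design: str = "single-male"  # or "pool"

    def __post_init__(self):
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("counts must be >= 0")
        if self.design not in ("single-male", "pool"):
            raise ValueError("design must be 'single-male' or 'pool'")

    @property
    def total(self) -> int:
        return self.n_males + self.n_females


@dataclass(frozen=True)
class SurvivalRecord:
    collection: str
    embryos: int
    hatched: int
    pupae: int
    adult_females: int
    adult_males: int

    def __post_init__(self):
        if min(self.embryos, self.hatched, self.pupae,
               self.adult_females, self.adult_males) < 0:
            raise ValueError("counts must be >= 0")
        if self.hatched > self.embryos:
            raise ValueError("hatched cannot exceed embryos collected")
        if self.pupae > self.embryos:
            raise ValueError("pupae cannot exceed embryos collected")
        if self.adult_females + self.adult_males > self.pupae:
            raise ValueError("adults cannot exceed pupae")


def male_fraction(record: CrossRecord, alpha: float = 0.05) -> dict:
    """Male fraction with an exact binomial (Clopper-Pearson) confidence interval.

    A cross with no scored offspring yields NaN sentinels, never 0.
    """
    n = record.total
    if n == 0:
        return {"fraction": math.nan, "ci_low": math.nan, "ci_high": math.nan, "n": 0}
    lo, hi = proportion_confint(record.n_males, n, alpha=alpha, method="beta")
    return {
        "fraction": record.n_males / n,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n": n,
    }


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Welch's unequal-variance t-test with Satterthwaite degrees of freedom.

    Two identical zero-variance groups are a defined no-effect case
    (t = 0, p = 1); zero variance with different means gives p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(a.size + b.size - 2), "p_value": 1.0}
        return {
            "t": math.copysign(math.inf, a.mean() - b.mean()),
            "df": float(a.size + b.size - 2),
            "p_value": 0.0,
        }
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p_value": float(res.pvalue)}


def survival_rates(record: SurvivalRecord) -> dict:
    """Stage-wise survival: embryo->pupa, pupa->adult and adult sex fractions."""
    if record.pupae == 0 and (record.adult_females + record.adult_males) > 0:
        raise ValueError("adults recorded without pupae: invariant violation")
    out = {
        "embryo_to_pupa": record.pupae / record.embryos if record.embryos else math.nan,
        "pupa_to_adult": (
            (record.adult_females + record.adult_males) / record.pupae
            if record.pupae
            else math.nan
        ),
    }
    adults = record.adult_females + record.adult_males
    out["adult_male_fraction"] = record.adult_males / adults if adults else math.nan
    out["adult_female_fraction"] = record.adult_females / adults if adults else math.nan
    return out


def pooled_male_fraction(records: Sequence[CrossRecord]) -> float:
    """Count-weighted male fraction across replicates (equals the pooled tally)."""
    males = sum(r.n_males for r in records)
    total = sum(r.total for r in records)
    return males / total if total else math.nan


def summarize_crosses(df: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype summary of a cross table.

    Expects columns ``genotype``, ``replicate``, ``males``, ``females``.
    Reports mean and SD of per-replicate male fractions, the pooled
    fraction, replicate count and total offspring scored.
    """
    rows = []
    for genotype, g in df.groupby("genotype", sort=False):
        fracs = g["males"] / (g["males"] + g["females"])
        rows.append(
            {
                "genotype": genotype,
                "n_replicates": len(g),
                "n_total": int((g["males"] + g["females"]).sum()),
                "mean_male_fraction": float(fracs.mean()),
                "sd_male_fraction": float(fracs.std(ddof=1)) if len(g) > 1 else math.nan,
                "pooled_male_fraction": float(
                    g["males"].sum() / (g["males"].sum() + g["females"].sum())
                ),
            }
        )
    return pd.DataFrame(rows).set_index("genotype")


def compare_genotypes(
    df: pd.DataFrame, genotype_a: str, genotype_b: str
) -> dict:
    """Welch test between two genotypes' per-replicate male fractions."""
    def fracs(name):
        g = df[df["genotype"] == name]
        if g.empty:
            raise ValueError(f"genotype {name!r} not in table")
        return (g["males"] / (g["males"] + g["females"])).to_numpy()

    return welch_t_test(fracs(genotype_a), fracs(genotype_b))
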
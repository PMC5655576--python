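"""Inter-rater agreement statistics for vignette ratings.

Ratings are ordinal with three categories — S (stable), M-DA (mild disease
activity), S-DA (significant disease activity).  For a balanced block of
scenarios each rated by the same n raters:

* per-scenario agreement  Pr_i = sum_j n_ij (n_ij - 1) / [n (n - 1)],
  the fraction of rater pairs in agreement on scenario i;
* category proportions    Pc_j = sum_i n_ij / (N n);
* Fleiss' kappa           kappa = (Pbar - Pe) / (1 - Pe),
  with Pbar the mean of the Pr_i and Pe = sum_j Pc_j**2.

kappa is chance-corrected: 1 means perfect agreement, 0 the level expected
if raters assigned categories at random with the observed marginal rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateKappaError,
    InsufficientDataError,
    UnbalancedTableError,
    UndefinedAgreementError,
    ValidationError,
)
from .scenario import N_SCENARIOS

#: The three disease-activity categories, in severity order.
CATEGORIES = ("S", "M-DA", "S-DA")


@dataclass(frozen=True)
class RatingTable:
    """Long-format ratings: one row per (rater, scenario) pair."""

    df: pd.DataFrame  # columns: rater_id, scenario_id, rating

    def __post_init__(self):
        df = self.df
        required = {"rater_id", "scenario_id", "rating"}
        if not required.issubset(df.columns):
            raise ValidationError(f"rating table needs columns {sorted(required)}")
        bad = ~df["rating"].isin(CATEGORIES)
        if bad.any():
            tok = df.loc[bad, "rating"].iloc[0]
            raise ValidationError(f"unknown rating token {tok!r}; expected one of {CATEGORIES}")
        out = ~df["scenario_id"].between(1, N_SCENARIOS)
        if out.any():
            raise ValidationError(
                f"scenario_id {df.loc[out, 'scenario_id'].iloc[0]} outside [1, {N_SCENARIOS}]"
            )
        if df.duplicated(subset=["rater_id", "scenario_id"]).any():
            dup = df[df.duplicated(subset=["rater_id", "scenario_id"])].iloc[0]
            raise ValidationError(
                f"duplicate rating for rater {dup['rater_id']!r}, scenario {dup['scenario_id']}"
            )

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "RatingTable":
        df = pd.DataFrame(records, columns=["rater_id", "scenario_id", "rating"])
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def rater_ids(self) -> list:
        return sorted(self.df["rater_id"].unique().tolist())

    def common_scenarios(self) -> list[int]:
        """Scenarios rated by every rater in the table."""
        n = self.df["rater_id"].nunique()
        counts = self.df.groupby("scenario_id")["rater_id"].nunique()
        return sorted(counts[counts == n].index.tolist())

    def drop_rater(self, rater_id) -> "RatingTable":
        return RatingTable(self.df[self.df["rater_id"] != rater_id].reset_index(drop=True))


@dataclass(frozen=True)
class CountMatrix:
    """Per-scenario category counts for a balanced block of ratings."""

    scenario_ids: tuple[int, ...]
    counts: np.ndarray  # (n_scenarios, 3) ints, rows sum to n_raters
    n_raters: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.size and (counts.ndim != 2 or counts.shape[1] != 3):
            raise ValidationError("count matrix must have 3 category columns")
        if counts.size and not (counts.sum(axis=1) == self.n_raters).all():
            raise UnbalancedTableError("every count row must sum to the rater count")
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def n_scenarios(self) -> int:
        return len(self.scenario_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, columns=["n_s", "n_mda", "n_sda"]
        ).assign(scenario_id=self.scenario_ids)[["scenario_id", "n_s", "n_mda", "n_sda"]]


@dataclass(frozen=True)
class AgreementSummary:
    """Pr per scenario, Pc per category, and Fleiss' kappa for one block."""

    scenario_ids: tuple[int, ...]
    pr_per_scenario: tuple[float, ...]
    pc_per_category: tuple[float, float, float]
    kappa: float
    n_raters: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scenario_id": self.scenario_ids, "pr": self.pr_per_scenario}
        )


def tabulate(rt: RatingTable, scenario_ids: Sequence[int] | None = None) -> CountMatrix:
    """Aggregate long-format ratings into a per-scenario count matrix.

    Every listed scenario must be rated by the same number of raters
    (a balanced block); by default the scenarios rated by all raters.
    """
    if scenario_ids is None:
        scenario_ids = rt.common_scenarios()
    scenario_ids = [int(s) for s in scenario_ids]
    if not scenario_ids:
        return CountMatrix(scenario_ids=(), counts=np.zeros((0, 3), dtype=int), n_raters=0)

    sub = rt.df[rt.df["scenario_id"].isin(scenario_ids)]
    pivot = (
        sub.groupby(["scenario_id", "rating"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=scenario_ids, columns=list(CATEGORIES), fill_value=0)
    )
    totals = pivot.sum(axis=1)
    if totals.nunique() != 1:
        raise UnbalancedTableError(
            "listed scenarios were rated by unequal numbers of raters: "
            f"{dict(totals[totals != totals.iloc[0]])}"
        )
    return CountMatrix(
        scenario_ids=tuple(scenario_ids),
        counts=pivot.to_numpy(dtype=int),
        n_raters=int(totals.iloc[0]),
    )


def per_scenario_agreement(row: Sequence[int], n: int) -> float:
    """Fraction of agreeing rater pairs for one scenario's count row."""
    row = np.asarray(row, dtype=int)
    if n < 2:
        raise UndefinedAgreementError("pairwise agreement needs at least 2 raters")
    if row.sum() != n:
        raise ValidationError(f"counts {row.tolist()} do not sum to n={n}")
    return float((row * (row - 1)).sum() / (n * (n - 1)))


def category_proportions(cm: CountMatrix) -> tuple[float, float, float]:
    """Proportion of all assessments assigned to each category (sums to 1)."""
    if cm.n_scenarios == 0:
        raise ValidationError("cannot compute category proportions of an empty matrix")
    totals = cm.counts.sum(axis=0)
    pc = totals / (cm.n_scenarios * cm.n_raters)
    return tuple(float(p) for p in pc)


def fleiss_kappa(cm: CountMatrix) -> float:
    """Fleiss' kappa for a balanced count matrix."""
    if cm.n_scenarios < 2:
        raise ValidationError("Fleiss' kappa needs at least 2 scenarios")
    if cm.n_raters < 2:
        raise UndefinedAgreementError("Fleiss' kappa needs at least 2 raters")
    pr = [per_scenario_agreement(row, cm.n_raters) for row in cm.counts]
    pc = category_proportions(cm)
    p_bar = float(np.mean(pr))
    p_e = float(sum(p * p for p in pc))
    if p_e >= 1.0:
        raise DegenerateKappaError("all assessments fell in one category; kappa undefined")
    return (p_bar - p_e) / (1.0 - p_e)


def summarize_agreement(
    rt_or_cm: RatingTable | CountMatrix, scenario_ids: Sequence[int] | None = None
) -> AgreementSummary:
    """Full agreement report (Pr table, Pc, kappa) for one balanced block."""
    cm = rt_or_cm if isinstance(rt_or_cm, CountMatrix) else tabulate(rt_or_cm, scenario_ids)
    pr = tuple(per_scenario_agreement(row, cm.n_raters) for row in cm.counts)
    pc = category_proportions(cm)
    return AgreementSummary(
        scenario_ids=cm.scenario_ids,
        pr_per_scenario=pr,
        pc_per_category=pc,
        kappa=fleiss_kappa(cm),
        n_raters=cm.n_raters,
    )


def leave_one_rater_out(
    rt: RatingTable, scenario_ids: Sequence[int] | None = None
) -> list[tuple[object, float]]:
    """Sensitivity analysis: kappa recomputed with each rater excluded.

    Needs the long-format table (per-rater ratings), not just counts; the
    block is restricted to scenarios rated by every rater.
    """
    if not isinstance(rt, RatingTable):
        raise InsufficientDataError("leave-one-out needs long-format per-rater ratings")
    raters = rt.rater_ids
    if len(raters) < 3:
        raise UndefinedAgreementError(
            "leave-one-out needs at least 3 raters so each subset has >= 2"
        )
    if scenario_ids is None:
        scenario_ids = rt.common_scenarios()
    out = []
    for rater in raters:
        cm = tabulate(rt.drop_rater(rater), scenario_ids)
        out.append((rater, fleiss_kappa(cm)))
    return out
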
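"""Scenario space of the vignette validation survey.

The five health-status parameters (IGF-I, tumor status, comorbidities,
symptoms, quality-of-life impairment), each at three severity levels, span
3**5 = 243 hypothetical patient profiles.  Scenario ids 1..243 map to level
vectors by a mixed-radix rule with the QoL digit varying fastest, which
reproduces every printed (id, bracket-code) pair of the published common
scenarios, e.g. 166 <-> [31121].

Also provides the survey-design arithmetic: the events-per-variable sample
size rule and rater-to-scenario assignment with a common-scenario core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import InfeasibleDesignError, InvalidScenarioError

#: Fixed parameter order used everywhere in the package.
PARAM_NAMES = ("igf", "tumor", "comorbidity", "symptoms", "qol")

N_SCENARIOS = 243

#: The ten panel-chosen common scenarios of the validation survey.
COMMON_SCENARIO_IDS = (1, 5, 11, 59, 92, 122, 166, 203, 230, 243)


class LevelVector(NamedTuple):
    """Severity levels (1/2/3) for the five parameters, in fixed order."""

    igf: int
    tumor: int
    comorbidity: int
    symptoms: int
    qol: int

    def validate(self) -> "LevelVector":
        for name, level in zip(PARAM_NAMES, self):
            if level not in (1, 2, 3):
                raise InvalidScenarioError(
                    f"{name} level must be 1, 2 or 3; got {level!r}"
                )
        return self

    @property
    def code(self) -> str:
        """Bracket-code digit string, e.g. '31121'."""
        return "".join(str(l) for l in self)


def encode_scenario(v: Sequence[int]) -> int:
    """Scenario id in [1, 243] for a level vector (rightmost digit fastest)."""
    v = LevelVector(*v).validate()
    sid = 1
    for k, level in enumerate(v):
        sid += (level - 1) * 3 ** (4 - k)
    return sid


def decode_scenario(sid: int) -> LevelVector:
    """Inverse of :func:`encode_scenario`."""
    if not (isinstance(sid, (int, np.integer)) and 1 <= sid <= N_SCENARIOS):
        raise InvalidScenarioError(f"scenario id must be in [1, {N_SCENARIOS}]; got {sid!r}")
    rem = int(sid) - 1
    levels = []
    for k in range(5):
        digit, rem = divmod(rem, 3 ** (4 - k))
        levels.append(digit + 1)
    return LevelVector(*levels)


def enumerate_scenarios() -> list[tuple[int, LevelVector]]:
    """All 243 (id, level-vector) pairs in id order."""
    return [(sid, decode_scenario(sid)) for sid in range(1, N_SCENARIOS + 1)]


def scenario_table():
    """The full 243-row scenario grid as a DataFrame (id + one column per parameter)."""
    import pandas as pd

    rows = [(sid,) + tuple(v) for sid, v in enumerate_scenarios()]
    return pd.DataFrame(rows, columns=("scenario_id",) + PARAM_NAMES)


def required_design_size(
    events_per_var: int,
    n_vars: int,
    event_rate: float,
    inflation: float,
    n_raters: int,
) -> tuple[int, int]:
    """Minimum total observations and per-rater workload for the survey.

    Applies the events-per-variable rule for multivariable modelling: with
    ``events_per_var`` events required for each of ``n_vars`` model variables
    and an event occurring in a fraction ``event_rate`` of responses, the
    study needs ``inflation * events_per_var * n_vars / event_rate``
    observations (the inflation factor compensates for non-independence of
    repeated ratings by the same physician).  The per-rater minimum divides
    by the number of available raters, rounding up.

    With the survey's numbers (10 events, 10 indicator variables, rate 1/3,
    doubling, 21 raters) this yields (600, 29).
    """
    if min(events_per_var, n_vars, inflation, n_raters) <= 0 or not (0 < event_rate <= 1):
        raise InvalidScenarioError("design-size inputs must be positive (event_rate in (0, 1])")
    min_obs = inflation * events_per_var * n_vars / event_rate
    min_observations = math.ceil(min_obs - 1e-9)
    min_per_rater = math.ceil(min_observations / n_raters - 1e-9)
    return min_observations, min_per_rater


@dataclass(frozen=True)
class SurveyDesign:
    """Assignment of scenarios to raters: a common core plus a random fill."""

    n_raters: int
    per_rater: int
    common_ids: tuple[int, ...]
    assignments: dict[int, tuple[int, ...]]
    seed: int
    stratified: bool = True
    coverage: dict[int, int] = field(default_factory=dict, compare=False)

    @property
    def n_observations(self) -> int:
        return sum(len(a) for a in self.assignments.values())


def build_survey_design(
    n_raters: int,
    per_rater: int,
    common_ids: Sequence[int] = COMMON_SCENARIO_IDS,
    seed: int = 0,
    stratified: bool = True,
) -> SurveyDesign:
    """Assign ``per_rater`` scenarios to each of ``n_raters`` raters.

    Every rater receives all ``common_ids`` plus a without-replacement fill
    from the remaining scenarios.  Stratified mode balances coverage by
    always drawing from the least-assigned scenarios (random tie-break);
    simple mode draws uniformly.  Deterministic under ``seed``.
    """
    common = tuple(dict.fromkeys(int(c) for c in common_ids))
    for c in common:
        if not 1 <= c <= N_SCENARIOS:
            raise InvalidScenarioError(f"common scenario id {c} out of range")
    if n_raters < 1:
        raise InfeasibleDesignError("need at least one rater")
    if per_rater > N_SCENARIOS:
        raise InfeasibleDesignError(
            f"per_rater={per_rater} exceeds the {N_SCENARIOS} available scenarios"
        )
    if per_rater < len(common):
        raise InfeasibleDesignError(
            f"per_rater={per_rater} cannot hold the {len(common)} common scenarios"
        )

    rng = np.random.default_rng(seed)
    pool = np.array([s for s in range(1, N_SCENARIOS + 1) if s not in set(common)])
    n_fill = per_rater - len(common)
    counts = {s: 0 for s in pool.tolist()}

    assignments: dict[int, tuple[int, ...]] = {}
    for rater in range(1, n_raters + 1):
        if n_fill == 0:
            fill = np.empty(0, dtype=int)
        elif stratified:
            # least-assigned first, random tie-break within equal counts
            keys = np.array([counts[s] for s in pool.tolist()], dtype=float)
            keys = keys + rng.random(len(pool))  # random fractional tie-break
            fill = pool[np.argsort(keys, kind="stable")][:n_fill]
        else:
            fill = rng.choice(pool, size=n_fill, replace=False)
        for s in fill.tolist():
            counts[s] += 1
        assignments[rater] = tuple(sorted(common + tuple(int(s) for s in fill)))

    coverage = {s: c for s, c in counts.items()}
    for c in common:
        coverage[c] = n_raters
    return SurveyDesign(
        n_raters=n_raters,
        per_rater=per_rater,
        common_ids=common,
        assignments=assignments,
        seed=int(seed),
        stratified=stratified,
        coverage=dict(sorted(coverage.items())),
    )
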
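"""Packaged reference data: the ten common validation-survey scenarios.

All 21 participating endocrinologists rated the same ten panel-chosen
scenarios; the per-scenario category counts, per-scenario agreement Pr,
category proportions Pc, and Fleiss' kappa for that block are published and
serve as the package's reference fixture.  Each count row is the unique
composition of 21 consistent with the published digit string and the printed
Pr value (e.g. scenario 59 is (1, 9, 11), not (19, 1, 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agreement import CountMatrix
from .errors import ValidationError

#: (scenario_id, bracket code, n_S, n_M-DA, n_S-DA, printed Pr)
FIXTURE_ROWS: tuple[tuple[int, str, int, int, int, float], ...] = (
    (1,   "11111", 21,  0,  0, 1.000),
    (5,   "11122", 17,  4,  0, 0.676),
    (11,  "11212", 14,  7,  0, 0.533),
    (59,  "13122",  1,  9, 11, 0.433),
    (92,  "21212",  4, 16,  1, 0.600),
    (122, "22222",  1, 17,  3, 0.662),
    (166, "31121",  2,  8, 11, 0.400),
    (203, "32222",  1,  3, 17, 0.662),
    (230, "33222",  1,  0, 20, 0.905),
    (243, "33333",  0,  0, 21, 1.000),
)

PRINTED_PC = (0.295, 0.305, 0.400)
PRINTED_KAPPA = 0.526
N_RATERS = 21


@dataclass(frozen=True)
class CommonScenarioFixture:
    """Common-scenario count matrix with its printed reference statistics."""

    scenario_ids: tuple[int, ...]
    codes: tuple[str, ...]
    counts: np.ndarray  # (10, 3)
    printed_pr: tuple[float, ...]
    printed_pc: tuple[float, float, float]
    printed_kappa: float
    n_raters: int

    def count_matrix(self) -> CountMatrix:
        return CountMatrix(
            scenario_ids=self.scenario_ids, counts=self.counts, n_raters=self.n_raters
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "scenario_id": self.scenario_ids,
                "code": self.codes,
                "n_s": self.counts[:, 0],
                "n_mda": self.counts[:, 1],
                "n_sda": self.counts[:, 2],
                "pr_printed": self.printed_pr,
            }
        )


def load_common_scenario_fixture(self_check: bool = True) -> CommonScenarioFixture:
    """The packaged ten-common-scenario fixture.

    With ``self_check`` (default) the stored counts are re-validated against
    the printed Pr values at 3-decimal precision before being returned.
    """
    fx = CommonScenarioFixture(
        scenario_ids=tuple(r[0] for r in FIXTURE_ROWS),
        codes=tuple(r[1] for r in FIXTURE_ROWS),
        counts=np.array([r[2:5] for r in FIXTURE_ROWS], dtype=int),
        printed_pr=tuple(r[5] for r in FIXTURE_ROWS),
        printed_pc=PRINTED_PC,
        printed_kappa=PRINTED_KAPPA,
        n_raters=N_RATERS,
    )
    if self_check:
        from .agreement import per_scenario_agreement

        for row, pr in zip(fx.counts, fx.printed_pr):
            recomputed = per_scenario_agreement(row, fx.n_raters)
            if abs(round(recomputed, 3) - pr) > 5e-4:
                raise ValidationError(
                    f"fixture self-check failed: counts {row.tolist()} give "
                    f"Pr={recomputed:.3f}, printed {pr}"
                )
    return fx
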
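"""Shared fixtures: task shapes, a small simulated cohort, and a
parametric generator of mixed-model analysis tables with known structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tracekin.cohort import CohortConfig, simulate_cohort
from tracekin.shapes import all_task_shapes

SHAPES = ("clover", "petals", "ellipse", "rounded_square")


@pytest.fixture(scope="session")
def curves():
    return all_task_shapes()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny but complete simulated study: 5/5/5 participants, one day,
    three cycles per trial, one successful trial per block."""
    cfg = CohortConfig(
        n_per_group=(5, 5, 5),
        n_days=1,
        n_cycles=3,
        successes_per_block=1,
        max_attempts=2,
        seed=42,
    )
    return simulate_cohort(cfg)


def make_lmm_table(
    rng: np.random.Generator,
    n_per_group: int = 12,
    n_days: int = 2,
    trials: int = 2,
    shapes: tuple = SHAPES,
    group_effect: float = 0.0,
    shape_effect: tuple[str, float] | None = None,
    age_slope: float = 0.0,
    participant_sd: float = 0.5,
    day_sd: float = 0.2,
    resid_sd: float = 1.0,
) -> pd.DataFrame:
    """Analysis table drawn from the random-intercept model the mixed model
    assumes: participant and day intercepts plus i.i.d. residuals.

    ``group_effect`` shifts the ASD group on every shape; ``shape_effect``
    = (shape, delta) shifts ASD only on that shape.
    """
    rows = []
    pid = 0
    for g in ("ASD", "PD", "CTRL"):
        for _ in range(n_per_group):
            pid += 1
            re_p = rng.normal(0.0, participant_sd)
            age = rng.normal(60.0, 8.0)
            dep = rng.normal(6.0, 4.0)
            anx = rng.normal(6.0, 4.0)
            for d in range(1, n_days + 1):
                re_d = rng.normal(0.0, day_sd)
                for sh in shapes:
                    for tr in range(1, trials + 1):
                        dv = re_p + re_d + age_slope * (age - 60.0) + rng.normal(0.0, resid_sd)
                        if g == "ASD":
                            dv += group_effect
                            if shape_effect is not None and sh == shape_effect[0]:
                                dv += shape_effect[1]
                        rows.append(
                            dict(
                                participant=f"P{pid:03d}", group=g, shape=sh,
                                day=d, trial=tr, age=age, depression=dep,
                                anxiety=anx, dv=dv,
                            )
                        )
    return pd.DataFrame(rows)
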
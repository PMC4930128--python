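import numpy as np
import pandas as pd
import pytest

from psyscreen.expression import ExpressionMatrix

TREATED = ["e1", "e2", "e3", "e4"]
CONTROL = ["c1", "c2", "c3", "c4"]


def make_matrix(rows: dict[str, list[float]]) -> ExpressionMatrix:
    """Build a 4v4 matrix from probe -> 8 values (e1..e4 then c1..c4)."""
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=TREATED + CONTROL
    )
    groups = {s: "treated" for s in TREATED} | {s: "control" for s in CONTROL}
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    """A seeded 1000-probe null matrix for numerical comparisons."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(7.0, 0.5, (1000, 8)),
        index=[f"p{i}" for i in range(1000)],
        columns=TREATED + CONTROL,
    )
    groups = {s: "treated" for s in TREATED} | {s: "control" for s in CONTROL}
    return ExpressionMatrix(values=values, groups=groups)


#: Stringency grid hit counts as printed in the published threshold search
#: (|ALR|, P, experimental count, three permutation counts, FDR %).
PUBLISHED_GRID = [
    (0.585, 0.05, 74, (39, 12, 14), 34.5),
    (0.848, 0.05, 24, (15, 5, 3), 41.7),
    (0.585, 0.01, 15, (11, 4, 2), 50.0),
    (0.848, 0.01, 3, (3, 1, 0), 66.7),
    (0.263, 0.005, 46, (25, 12, 5), 40.2),
    (0.585, 0.005, 4, (3, 1, 2), 50.0),
    (0.848, 0.005, 1, (0, 0, 0), 0.0),
]
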
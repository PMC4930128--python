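"""Differential-expression screening for a small pooled two-group design.

The screen operates on a normalized log2 expression matrix with 4 treated and
4 control pooled samples. Its stages:

1. per-probe average log2 ratio (ALR = mean(treated) - mean(control)) and an
   equal-variance two-tailed t-test;
2. a stringency grid over (|ALR|, P) thresholds, with the experimental hit
   count compared against hit counts from balanced relabeled ("permutation")
   groupings to estimate a false discovery rate;
3. selection of the stringency with the lowest FDR among those yielding a
   minimum number of hits;
4. a robustness filter comparing each treated sample individually against
   each control sample (16 pairwise log2 differences in the default design)
   and keeping probes exceeding the fold-change threshold in at least
   ``min_count`` of them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "PermutationDesign",
    "StringencyGridRow",
    "ProbeScreenResult",
    "DEFAULT_STRINGENCIES",
    "compute_alr",
    "two_tailed_t",
    "default_permutation_designs",
    "enumerate_balanced_designs",
    "count_passing",
    "fdr_percent",
    "fdr_grid",
    "select_stringency",
    "pairwise_robustness",
    "robust_hits",
]

#: Default (|ALR|, P) stringency grid. |ALR| = 0.263, 0.585 and 0.848
#: correspond to 20%, 50% and 80% expression changes on the log2 scale.
DEFAULT_STRINGENCIES: tuple[tuple[float, float], ...] = (
    (0.585, 0.05),
    (0.848, 0.05),
    (0.585, 0.01),
    (0.848, 0.01),
    (0.263, 0.005),
    (0.585, 0.005),
    (0.848, 0.005),
)


class InputError(ValueError):
    """Raised on malformed or inconsistent inputs."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale probe x sample expression values with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
    groups
        Mapping sample id -> ``"treated"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise InputError("duplicate probe identifiers")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate sample identifiers")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise InputError(f"samples without group label: {missing}")
        bad = {g for g in self.groups.values()} - {"treated", "control"}
        if bad:
            raise InputError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise InputError("expression values must be finite")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def treated_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "treated"]

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "control"]

    def _submatrix(self, samples: Sequence[str]) -> np.ndarray:
        unknown = [s for s in samples if s not in self.values.columns]
        if unknown:
            raise InputError(f"unknown sample ids: {unknown}")
        return self.values[list(samples)].to_numpy(dtype=float)


@dataclass(frozen=True)
class PermutationDesign:
    """A balanced relabeling: side_a vs side_b, each mixing both arms."""

    label: str
    side_a: frozenset[str]
    side_b: frozenset[str]

    def validate(self, all_samples: set[str]) -> None:
        if self.side_a & self.side_b:
            raise InputError(f"{self.label}: sides overlap")
        if self.side_a | self.side_b != all_samples:
            raise InputError(f"{self.label}: sides do not cover all samples")


@dataclass
class StringencyGridRow:
    """One stringency level with experimental and permutation hit counts.

    ``fdr_percent`` is NaN when ``exp_count`` is zero (undefined rate).
    """

    alr_thresh: float
    p_thresh: float
    exp_count: int
    perm_counts: tuple[int, ...]
    fdr_percent: float = field(default=math.nan)

    @classmethod
    def from_counts(
        cls,
        alr_thresh: float,
        p_thresh: float,
        exp_count: int,
        perm_counts: Sequence[int],
        agg: Literal["first_two", "mean_all"] = "first_two",
    ) -> "StringencyGridRow":
        return cls(
            alr_thresh=alr_thresh,
            p_thresh=p_thresh,
            exp_count=exp_count,
            perm_counts=tuple(int(c) for c in perm_counts),
            fdr_percent=fdr_percent(exp_count, perm_counts, agg=agg),
        )


@dataclass
class ProbeScreenResult:
    """Per-probe screen summary: effect size, P, and pairwise robustness."""

    probe_id: str
    alr: float
    p_value: float
    pairwise_count: int
    pairwise_sd: float
    direction: Literal["up_in_treated", "down_in_treated"]


def compute_alr(
    matrix: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> np.ndarray:
    """Average log2 ratio per probe: mean over ``group_a`` minus ``group_b``.

    Values are already log2, so the difference of means is the log2 ratio.
    """
    if not group_a or not group_b:
        raise InputError("groups must be non-empty")
    if set(group_a) & set(group_b):
        raise InputError("groups must be disjoint")
    a = matrix._submatrix(group_a)
    b = matrix._submatrix(group_b)
    return a.mean(axis=1) - b.mean(axis=1)


def two_tailed_t(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    variant: Literal["student", "welch"] = "student",
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample two-tailed t-test per probe.

    Default is the equal-variance (Student) test with nA + nB - 2 degrees of
    freedom, the conventional choice for a balanced pooled design; Welch's
    unequal-variance form is available via ``variant``.

    Degenerate probes (zero variance in both groups): equal means give
    (t=0, p=1); unequal means give (t=+/-inf, p=0).
    """
    a = matrix._submatrix(group_a)
    b = matrix._submatrix(group_b)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise InputError("each group needs at least 2 samples")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    diff = mean_a - mean_b

    if variant == "student":
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        df = np.full_like(se, float(na + nb - 2))
    elif variant == "welch":
        se2 = var_a / na + var_b / nb
        se = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
            )
        df = np.where(np.isfinite(df), df, float(na + nb - 2))
    else:  # pragma: no cover - guarded by type hint
        raise InputError(f"unknown t-test variant: {variant}")

    zero_se = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_se, 0.0, diff / np.where(zero_se, 1.0, se))
        # zero variance, unequal means: infinitely strong evidence
        t = np.where(zero_se & (diff != 0), np.sign(diff) * np.inf, t)
    p = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df)
    )
    p = np.where(zero_se & (diff == 0), 1.0, p)
    return t, p


def default_permutation_designs(
    treated_ids: Sequence[str], control_ids: Sequence[str]
) -> list[PermutationDesign]:
    """The three fixed balanced relabelings used to estimate the FDR.

    With treated pools e1-e4 and control pools c1-c4 (in input order):

    * Boot 1: c1-c2-e3-e4 vs c3-c4-e1-e2
    * Boot 2: c1-c3-e2-e4 vs c2-c4-e1-e3
    * Boot 3: c1-c4-e2-e3 vs c2-c3-e1-e4

    Each side mixes two treated with two control pools, so a pure treatment
    effect cancels within each side and surviving hits estimate the null.
    Requires exactly 4 samples per arm; for other designs use
    :func:`enumerate_balanced_designs`.
    """
    if len(treated_ids) != 4 or len(control_ids) != 4:
        raise InputError(
            "the fixed three-design scheme requires 4 samples per arm; "
            "use enumerate_balanced_designs for other arm sizes"
        )
    e = list(treated_ids)
    c = list(control_ids)
    spec = [
        ("Boot 1", [c[0], c[1], e[2], e[3]], [c[2], c[3], e[0], e[1]]),
        ("Boot 2", [c[0], c[2], e[1], e[3]], [c[1], c[3], e[0], e[2]]),
        ("Boot 3", [c[0], c[3], e[1], e[2]], [c[1], c[2], e[0], e[3]]),
    ]
    return [
        PermutationDesign(label, frozenset(a), frozenset(b))
        for label, a, b in spec
    ]


def enumerate_balanced_designs(
    treated_ids: Sequence[str], control_ids: Sequence[str]
) -> list[PermutationDesign]:
    """All distinct balanced half-and-half relabelings, up to side swap.

    For 4 + 4 samples this yields 18 designs (6 x 6 treated/control half
    choices, halved for side symmetry).
    """
    n_t, n_c = len(treated_ids), len(control_ids)
    if n_t % 2 or n_c % 2 or n_t < 2 or n_c < 2:
        raise InputError("balanced designs need even arm sizes >= 2")
    seen: set[frozenset[frozenset[str]]] = set()
    designs: list[PermutationDesign] = []
    for ta in itertools.combinations(treated_ids, n_t // 2):
        for ca in itertools.combinations(control_ids, n_c // 2):
            side_a = frozenset(ta) | frozenset(ca)
            side_b = (frozenset(treated_ids) | frozenset(control_ids)) - side_a
            key = frozenset({side_a, side_b})
            if key in seen:
                continue
            seen.add(key)
            designs.append(
                PermutationDesign(f"Perm {len(designs) + 1}", side_a, side_b)
            )
    return designs


def count_passing(
    alr: np.ndarray, p: np.ndarray, alr_thresh: float, p_thresh: float
) -> int:
    """Number of probes with ``|alr| >= alr_thresh`` and ``p < p_thresh``.

    The magnitude threshold is inclusive ("reaching" the fold change) and the
    P threshold exclusive; ties have measure zero on real data.
    """
    alr = np.asarray(alr, dtype=float)
    p = np.asarray(p, dtype=float)
    if alr.shape != p.shape:
        raise InputError("alr and p vectors must be aligned")
    return int(np.sum((np.abs(alr) >= alr_thresh) & (p < p_thresh)))


def fdr_percent(
    exp_count: int,
    perm_counts: Sequence[int],
    agg: Literal["first_two", "mean_all"] = "first_two",
) -> float:
    """Permutation-estimated false discovery rate, in percent.

    FDR = 100 * mean(null hit counts) / experimental hit count. The default
    aggregation averages the first two permutation designs only, which is the
    convention this screen was calibrated with; ``mean_all`` averages every
    design. NaN when ``exp_count`` is zero. May exceed 100.
    """
    if exp_count == 0:
        return math.nan
    if not perm_counts:
        raise InputError("at least one permutation count required")
    if agg == "first_two":
        used = list(perm_counts)[:2]
    elif agg == "mean_all":
        used = list(perm_counts)
    else:
        raise InputError(f"unknown aggregation mode: {agg}")
    return 100.0 * (sum(used) / len(used)) / exp_count


def fdr_grid(
    matrix: ExpressionMatrix,
    stringencies: Sequence[tuple[float, float]] = DEFAULT_STRINGENCIES,
    designs: Sequence[PermutationDesign] | None = None,
    agg: Literal["first_two", "mean_all"] = "first_two",
    t_variant: Literal["student", "welch"] = "student",
) -> list[StringencyGridRow]:
    """Hit counts and FDR across a grid of (|ALR|, P) stringencies.

    For each stringency, ``exp_count`` counts probes passing under the real
    treated-vs-control grouping and ``perm_counts`` under each balanced
    relabeled design (side_a acting as pseudo-treated).
    """
    if not stringencies:
        raise InputError("at least one stringency required")
    if designs is None:
        designs = default_permutation_designs(
            matrix.treated_ids, matrix.control_ids
        )
    all_samples = set(matrix.sample_ids)
    for d in designs:
        d.validate(all_samples)

    groupings = [(matrix.treated_ids, matrix.control_ids)] + [
        (sorted(d.side_a), sorted(d.side_b)) for d in designs
    ]
    stats_per_grouping = []
    for ga, gb in groupings:
        alr = compute_alr(matrix, ga, gb)
        _, p = two_tailed_t(matrix, ga, gb, variant=t_variant)
        stats_per_grouping.append((alr, p))

    rows = []
    for alr_thresh, p_thresh in stringencies:
        counts = [
            count_passing(alr, p, alr_thresh, p_thresh)
            for alr, p in stats_per_grouping
        ]
        rows.append(
            StringencyGridRow.from_counts(
                alr_thresh, p_thresh, counts[0], counts[1:], agg=agg
            )
        )
    return rows


def select_stringency(
    grid: Sequence[StringencyGridRow], min_exp: int = 10
) -> StringencyGridRow:
    """Pick the stringency with the lowest FDR among sufficiently yielding rows.

    Rows with fewer than ``min_exp`` experimental hits are ignored: a row with
    one hit and zero permutation hits has a nominal 0% FDR but no usable
    yield. Ties break toward larger ``exp_count``, then larger ``alr_thresh``.
    If no row qualifies, the global minimum-FDR row is returned (the caller
    should treat this as a warning condition).
    """
    defined = [r for r in grid if not math.isnan(r.fdr_percent)]
    if not defined:
        raise InputError("no grid row has a defined FDR")
    eligible = [r for r in defined if r.exp_count >= min_exp]
    pool = eligible if eligible else defined
    return min(
        pool, key=lambda r: (r.fdr_percent, -r.exp_count, -r.alr_thresh)
    )


def pairwise_robustness(
    matrix: ExpressionMatrix,
    treated_ids: Sequence[str] | None = None,
    control_ids: Sequence[str] | None = None,
    thresh: float = 0.585,
) -> list[ProbeScreenResult]:
    """Per-probe robustness over all treated-vs-control sample pairs.

    Every treated sample is compared individually against every control
    sample: d_ij = value(treated_i) - value(control_j), giving nA x nB
    differences (16 in the default design). ``pairwise_count`` is the number
    of pairs with ``|d_ij| >= thresh``; ``pairwise_sd`` the sample standard
    deviation of the differences. Direction follows the sign of the ALR.
    """
    treated_ids = list(
        matrix.treated_ids if treated_ids is None else treated_ids
    )
    control_ids = list(
        matrix.control_ids if control_ids is None else control_ids
    )
    if not treated_ids or not control_ids:
        raise InputError("both arms must be non-empty")
    t_vals = matrix._submatrix(treated_ids)  # probes x nA
    c_vals = matrix._submatrix(control_ids)  # probes x nB
    # probes x nA x nB pairwise differences
    d = t_vals[:, :, None] - c_vals[:, None, :]
    n_pairs = d.shape[1] * d.shape[2]
    d_flat = d.reshape(d.shape[0], n_pairs)
    counts = (np.abs(d_flat) >= thresh).sum(axis=1)
    sds = d_flat.std(axis=1, ddof=1)
    alr = compute_alr(matrix, treated_ids, control_ids)
    _, p = two_tailed_t(matrix, treated_ids, control_ids)
    return [
        ProbeScreenResult(
            probe_id=pid,
            alr=float(alr[i]),
            p_value=float(p[i]),
            pairwise_count=int(counts[i]),
            pairwise_sd=float(sds[i]),
            direction="up_in_treated" if alr[i] > 0 else "down_in_treated",
        )
        for i, pid in enumerate(matrix.probe_ids)
    ]


def robust_hits(
    results: Sequence[ProbeScreenResult], min_count: int = 9
) -> list[ProbeScreenResult]:
    """Probes robust in at least ``min_count`` pairwise comparisons.

    Ordered by ALR ascending (strongest down-regulation first).
    """
    kept = [r for r in results if r.pairwise_count >= min_count]
    return sorted(kept, key=lambda r: r.alr)


def results_to_frame(results: Sequence[ProbeScreenResult]) -> pd.DataFrame:
    """Tabulate screen results (one row per probe)."""
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in results],
            "alr": [r.alr for r in results],
            "sd": [r.pairwise_sd for r in results],
            "count": [r.pairwise_count for r in results],
            "p": [r.p_value for r in results],
            "direction": [r.direction for r in results],
        }
    )


def grid_to_frame(grid: Sequence[StringencyGridRow]) -> pd.DataFrame:
    """Tabulate a stringency grid (one row per stringency)."""
    n_perm = max(len(r.perm_counts) for r in grid)
    data: dict[str, list] = {
        "alr_thresh": [r.alr_thresh for r in grid],
        "p_thresh": [r.p_thresh for r in grid],
        "exp_count": [r.exp_count for r in grid],
    }
    for i in range(n_perm):
        data[f"perm_{i + 1}"] = [
            r.perm_counts[i] if i < len(r.perm_counts) else None for r in grid
        ]
    data["fdr_percent"] = [r.fdr_percent for r in grid]
    return pd.DataFrame(data)
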
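"""Synthetic inputs with known ground truth for the whole pipeline.

The expression generator emulates the pooled two-group design of the study
it models: 12 treated and 12 control animals, pooled three-at-a-time into
4 + 4 arrays. Animals are simulated individually and then averaged into
pools, so the variance reduction of pooling (animal variance divided by the
pool size, plus per-array technical noise) is represented faithfully —
pool-level variance is ``animal_sd**2 / pool_size + tech_sd**2``.

The GWAS generator places markers uniformly in each locus with Uniform(0,1)
null P-values and can spike a locus with a marker carrying an exact minimum
P. The CNV generator fragments true events into pieces whose total gap stays
below 50% of the span, so the joining rule can provably restore them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv import CnvCall
from .expression import ExpressionMatrix
from .gwas import GeneLocus, GwasMarker

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ConfigurationError",
    "gen_expression",
    "gen_gwas_markers",
    "gen_cnv_calls",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the pooled expression simulation.

    Defaults mirror the modeled design: ~31k probes (the scale of the
    Rat Genome 230 2.0 array), 4 pools of 3 animals per arm, log2 values
    around a baseline of 7. ``effect_log2`` is the mean log2 shift applied
    to differentially expressed (DE) probes in treated animals only; its
    sign per probe is drawn at random. ``animal_sd`` is per-animal
    biological noise, ``tech_sd`` per-array technical noise (both log2).
    """

    n_probes: int = 31000
    n_de: int = 20
    effect_log2: float = 0.8
    baseline_mean: float = 7.0
    animal_sd: float = 0.35
    tech_sd: float = 0.12
    pool_size: int = 3
    n_pools_per_arm: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ConfigurationError("n_probes must be positive")
        if not (0 <= self.n_de <= self.n_probes):
            raise ConfigurationError("need 0 <= n_de <= n_probes")
        if self.animal_sd < 0 or self.tech_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.pool_size <= 0 or self.n_pools_per_arm <= 0:
            raise ConfigurationError("pool dimensions must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside synthetic data."""

    de_effects: dict[str, float] = field(default_factory=dict)
    spiked_markers: dict[str, float] = field(default_factory=dict)
    true_cnvs: list[CnvCall] = field(default_factory=list)

    @property
    def de_probe_ids(self) -> set[str]:
        return set(self.de_effects)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": pid, "kind": "de_probe", "effect": eff}
            for pid, eff in sorted(self.de_effects.items())
        ]
        rows += [
            {"id": mid, "kind": "spiked_marker", "effect": p}
            for mid, p in sorted(self.spiked_markers.items())
        ]
        rows += [
            {
                "id": f"{c.sample_id}:{c.chrom}:{c.start}-{c.end}",
                "kind": f"true_cnv_{c.copy_state}",
                "effect": c.n_markers,
            }
            for c in self.true_cnvs
        ]
        return pd.DataFrame(rows, columns=["id", "kind", "effect"])


def gen_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate the pooled expression matrix plus its ground truth.

    Each animal's log2 value per probe is baseline + (signed effect if the
    animal is treated and the probe is DE) + N(0, animal_sd). Each pool value
    is the mean of its ``pool_size`` animals plus N(0, tech_sd) array noise.
    Columns are e1..e4 (treated pools) then c1..c4 (control pools).
    """
    rng = np.random.default_rng(config.seed)
    n_animals = config.pool_size * config.n_pools_per_arm
    width = len(str(config.n_probes))
    probe_ids = [f"probe_{i + 1:0{width}d}" for i in range(config.n_probes)]

    de_idx = rng.choice(config.n_probes, size=config.n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_de)
    effects = np.zeros(config.n_probes)
    effects[de_idx] = signs * config.effect_log2

    def simulate_arm(effect_shift: np.ndarray) -> np.ndarray:
        # probes x animals, then averaged into probes x pools
        animals = (
            config.baseline_mean
            + effect_shift[:, None]
            + rng.normal(0.0, config.animal_sd, (config.n_probes, n_animals))
        )
        pools = animals.reshape(
            config.n_probes, config.n_pools_per_arm, config.pool_size
        ).mean(axis=2)
        pools += rng.normal(
            0.0, config.tech_sd, (config.n_probes, config.n_pools_per_arm)
        )
        return pools

    treated = simulate_arm(effects)
    control = simulate_arm(np.zeros(config.n_probes))

    sample_ids = [f"e{i + 1}" for i in range(config.n_pools_per_arm)] + [
        f"c{i + 1}" for i in range(config.n_pools_per_arm)
    ]
    values = pd.DataFrame(
        np.hstack([treated, control]), index=probe_ids, columns=sample_ids
    )
    groups = {s: ("treated" if s.startswith("e") else "control") for s in sample_ids}
    truth = SyntheticTruth(
        de_effects={probe_ids[i]: float(effects[i]) for i in de_idx}
    )
    return ExpressionMatrix(values=values, groups=groups), truth


def gen_gwas_markers(
    loci: Sequence[GeneLocus],
    n_markers_per_locus: Sequence[int],
    spiked: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[GwasMarker], SyntheticTruth]:
    """Simulate per-marker association P-values inside gene lookup regions.

    Markers are positioned uniformly (without replacement) in each locus.
    Null P-values are Uniform(0, 1). A locus listed in ``spiked`` receives
    one marker whose P equals the requested value exactly and is guaranteed
    to be the locus minimum (null draws falling below it are redrawn above).
    """
    spiked = dict(spiked or {})
    if len(loci) != len(n_markers_per_locus):
        raise ConfigurationError("loci and marker counts must be aligned")
    unknown = set(spiked) - {l.gene for l in loci}
    if unknown:
        raise ConfigurationError(f"spiked loci not in locus list: {unknown}")
    rng = np.random.default_rng(seed)
    markers: list[GwasMarker] = []
    truth = SyntheticTruth()
    for locus, n in zip(loci, n_markers_per_locus):
        if n <= 0:
            raise ConfigurationError(f"{locus.gene}: marker count must be > 0")
        if locus.length < n:
            raise ConfigurationError(
                f"{locus.gene}: locus too short for {n} distinct positions"
            )
        positions = np.sort(
            rng.choice(locus.length, size=n, replace=False) + locus.start
        )
        p = rng.uniform(0.0, 1.0, size=n)
        if locus.gene in spiked:
            spike_p = float(spiked[locus.gene])
            if not (0 < spike_p <= 1):
                raise ConfigurationError("spiked P must be in (0, 1]")
            low = p <= spike_p
            p[low] = rng.uniform(spike_p, 1.0, size=int(low.sum()))
            spike_at = int(rng.integers(n))
            p[spike_at] = spike_p
        for i in range(n):
            is_spike = locus.gene in spiked and i == spike_at
            mid = (
                f"{locus.gene}_spike"
                if is_spike
                else f"{locus.gene}_m{i + 1}"
            )
            markers.append(
                GwasMarker(
                    marker_id=mid,
                    chrom=locus.chrom,
                    pos=int(positions[i]),
                    p=float(p[i]),
                )
            )
            if is_spike:
                truth.spiked_markers[mid] = float(p[i])
    return markers, truth


def _split_lengths(
    rng: np.random.Generator, total: int, parts: int, minimum: int
) -> list[int]:
    """Random composition of ``total`` into ``parts`` pieces, each >= minimum."""
    if total < parts * minimum:
        raise ValueError("total too small for requested parts")
    free = total - parts * minimum
    cuts = np.sort(rng.integers(0, free + 1, size=parts - 1))
    pieces = np.diff(np.concatenate([[0], cuts, [free]]))
    return [int(x) + minimum for x in pieces]


def gen_cnv_calls(
    true_cnvs: Sequence[CnvCall],
    fragmentation_rate: float = 0.5,
    min_fragment_markers: int = 10,
    seed: int = 0,
) -> tuple[list[CnvCall], SyntheticTruth]:
    """Fragment true CNV events into caller-style call lists.

    Each true event is emitted intact with probability
    ``1 - fragmentation_rate``; otherwise it is split into 2 or 3 fragments
    whose gaps total at most 40% of the original span — strictly under the
    50% joining criterion — so the merge rule restores the original interval
    exactly. Marker counts are apportioned over fragments (each at least
    ``min_fragment_markers``) and sum to the original count; events too
    small to split cleanly are emitted intact.
    """
    if not (0 <= fragmentation_rate <= 1):
        raise ValueError("fragmentation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[CnvCall] = []
    truth = SyntheticTruth(true_cnvs=list(true_cnvs))
    for cnv in true_cnvs:
        n_frag = int(rng.choice([2, 3])) if rng.random() < fragmentation_rate else 1
        span = cnv.length
        # need room for n_frag covered pieces (>=1 bp) and n_frag-1 gaps (>=1 bp)
        can_split = (
            n_frag > 1
            and cnv.n_markers >= n_frag * min_fragment_markers
            and span >= 5 * n_frag
        )
        if not can_split:
            out.append(cnv)
            continue
        max_gap_total = max(n_frag - 1, int(0.4 * span))
        gap_total = int(rng.integers(n_frag - 1, max_gap_total + 1))
        gaps = _split_lengths(rng, gap_total, n_frag - 1, 1)
        covered = _split_lengths(rng, span - gap_total, n_frag, 1)
        marker_parts = _split_lengths(
            rng, cnv.n_markers, n_frag, min_fragment_markers
        )
        pos = cnv.start
        for i in range(n_frag):
            frag_end = pos + covered[i] - 1
            out.append(
                replace(
                    cnv, start=pos, end=frag_end, n_markers=marker_parts[i]
                )
            )
            pos = frag_end + 1 + (gaps[i] if i < n_frag - 1 else 0)
    out.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end))
    return out, truth
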
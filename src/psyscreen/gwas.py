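"""Gene-locus GWAS significance from single-marker summary statistics.

For each candidate gene a lookup region is built from its RefSeq transcripts
padded by 20 kb on each side. Locus-wide (gene-wide) significance is the
per-gene Bonferroni bound: the best single-marker P in the region multiplied
by the number of markers in the region, capped at 1. An experiment-wide
correction multiplies instead by the total marker count over all loci.

All coordinates are 1-based and inclusive on both ends; BED input is
converted on ingest (see :mod:`psyscreen.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import pandas as pd

__all__ = [
    "GeneLocus",
    "GwasMarker",
    "LocusAssociation",
    "build_locus",
    "markers_in_locus",
    "locus_wide_significance",
    "experiment_wide",
    "summarize_loci",
    "load_candidate_loci",
]


def _norm_chrom(chrom: str) -> str:
    """Normalize chromosome names: tolerate a 'chr' prefix, case-insensitive."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True)
class GeneLocus:
    """A padded gene lookup region with its transcript and exon models."""

    gene: str
    chrom: str
    start: int
    end: int
    transcripts: tuple[tuple[int, int], ...] = ()
    exons: tuple[tuple[int, int], ...] = ()
    pad: int = 20000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GwasMarker:
    """A single association-test marker: id, position, P-value."""

    marker_id: str
    chrom: str
    pos: int
    p: float

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.marker_id}: p must be in (0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.marker_id}: positions are 1-based")


@dataclass
class LocusAssociation:
    """Per-locus association summary derived from markers in the region."""

    gene: str
    n_markers: int
    best_marker: str | None = None
    best_p: float | None = None
    locus_wide_p: float = field(default=math.nan)


def build_locus(
    gene: str,
    chrom: str,
    transcripts: Sequence[tuple[int, int]],
    exons: Sequence[tuple[int, int]] = (),
    pad: int = 20000,
) -> GeneLocus:
    """Build a lookup region spanning all transcripts, padded both sides.

    The region runs from the furthest-upstream transcript start minus ``pad``
    (floored at position 1) to the furthest-downstream transcript end plus
    ``pad``.
    """
    if not transcripts:
        raise ValueError(f"{gene}: at least one transcript required")
    start = max(1, min(s for s, _ in transcripts) - pad)
    end = max(e for _, e in transcripts) + pad
    return GeneLocus(
        gene=gene,
        chrom=chrom,
        start=start,
        end=end,
        transcripts=tuple(tuple(t) for t in transcripts),
        exons=tuple(tuple(e) for e in exons),
        pad=pad,
    )


def markers_in_locus(
    markers: Sequence[GwasMarker], locus: GeneLocus
) -> tuple[list[GwasMarker], int]:
    """Markers on the locus chromosome with start <= pos <= end (inclusive)."""
    chrom = _norm_chrom(locus.chrom)
    subset = [
        m
        for m in markers
        if _norm_chrom(m.chrom) == chrom and locus.start <= m.pos <= locus.end
    ]
    return subset, len(subset)


def locus_wide_significance(best_p: float, n_markers: int) -> float:
    """Per-gene Bonferroni bound: min(1, best_p * n_markers).

    NaN when the region holds no markers (no test was performed).
    """
    if n_markers == 0:
        return math.nan
    if not (0 < best_p <= 1):
        raise ValueError("best_p must be in (0, 1]")
    return min(1.0, best_p * n_markers)


def associate_locus(
    markers: Sequence[GwasMarker], locus: GeneLocus
) -> LocusAssociation:
    """Best marker and locus-wide significance for one lookup region.

    Ties for best P resolve to the first marker by position (deterministic).
    """
    subset, n = markers_in_locus(markers, locus)
    if n == 0:
        return LocusAssociation(gene=locus.gene, n_markers=0)
    best = min(subset, key=lambda m: (m.p, m.pos))
    return LocusAssociation(
        gene=locus.gene,
        n_markers=n,
        best_marker=best.marker_id,
        best_p=best.p,
        locus_wide_p=locus_wide_significance(best.p, n),
    )


def experiment_wide(
    loci: Sequence[LocusAssociation], alpha: float = 0.05
) -> tuple[int, pd.DataFrame, list[str]]:
    """Correct each locus's best P for the total marker count over all loci.

    Returns the total marker count, a per-locus table with the corrected P
    (min(1, best_p * total_markers)), and the genes significant at ``alpha``
    after this experiment-wide correction.
    """
    if not loci:
        raise ValueError("at least one locus required")
    total = sum(l.n_markers for l in loci)
    rows = []
    for l in loci:
        corrected = (
            math.nan if l.best_p is None else min(1.0, l.best_p * total)
        )
        rows.append(
            {
                "gene": l.gene,
                "best_marker": l.best_marker,
                "best_p": l.best_p,
                "corrected_p": corrected,
            }
        )
    table = pd.DataFrame(rows)
    significant = [
        r["gene"]
        for r in rows
        if not (r["best_p"] is None) and r["corrected_p"] < alpha
    ]
    return total, table, significant


def summarize_loci(
    loci: Sequence[LocusAssociation], alpha: float = 0.05
) -> tuple[pd.DataFrame, int]:
    """Report table sorted by locus-wide P ascending, plus significance count.

    Ties order by gene symbol. The count is the number of loci with
    locus-wide P below ``alpha`` (NaN rows never count).
    """
    ordered = sorted(
        loci,
        key=lambda l: (
            math.isnan(l.locus_wide_p),
            l.locus_wide_p if not math.isnan(l.locus_wide_p) else 0.0,
            l.gene,
        ),
    )
    table = pd.DataFrame(
        {
            "gene": [l.gene for l in ordered],
            "n_markers": [l.n_markers for l in ordered],
            "best_marker": [l.best_marker for l in ordered],
            "best_p": [l.best_p for l in ordered],
            "locus_wide_p": [l.locus_wide_p for l in ordered],
        }
    )
    n_sig = sum(
        1
        for l in loci
        if not math.isnan(l.locus_wide_p) and l.locus_wide_p < alpha
    )
    return table, n_sig


def load_candidate_loci() -> pd.DataFrame:
    """The 20 candidate schizophrenia gene loci with their PGC SCZ lookups.

    Packaged input table: per gene, the hg19 lookup region (already padded),
    the number of markers in the PGC schizophrenia meta-analysis summary
    statistics falling in the region, and the best marker with its P-value.
    """
    with resources.files("psyscreen.data").joinpath(
        "candidate_loci.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def candidate_associations() -> list[LocusAssociation]:
    """Candidate-locus table as ready-made :class:`LocusAssociation` records."""
    df = load_candidate_loci()
    return [
        LocusAssociation(
            gene=row.gene,
            n_markers=int(row.n_markers),
            best_marker=row.best_marker,
            best_p=float(row.best_p),
            locus_wide_p=locus_wide_significance(
                float(row.best_p), int(row.n_markers)
            ),
        )
        for row in df.itertuples()
    ]
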
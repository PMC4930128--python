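"""Refinement and annotation of raw CNV call lists.

Array-based CNV callers fragment long events and emit spurious short calls;
the refinement here mirrors standard post-processing of such call lists:

1. drop calls from outlier samples (excess genome-wide call counts);
2. drop calls supported by fewer than 10 consecutive markers;
3. join same-sample, same-chromosome, same-state calls whenever the total
   gap between them is under 50% of the joined span (gaps included);
4. annotate the refined calls against candidate gene loci, flagging
   exon-disrupting overlaps, and tabulate by case/control status.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .gwas import GeneLocus, _norm_chrom

__all__ = [
    "CnvCall",
    "CnvAnnotation",
    "exclude_outlier_samples",
    "filter_min_markers",
    "merge_calls",
    "annotate_overlaps",
    "case_control_table",
    "refine_calls",
]


@dataclass(frozen=True)
class CnvCall:
    """One CNV call: sample, phenotype, interval, copy state, marker support."""

    sample_id: str
    phenotype: Literal["case", "control"]
    chrom: str
    start: int
    end: int
    copy_state: Literal["deletion", "duplication"]
    n_markers: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CnvAnnotation:
    """Overlap of one call with one gene locus."""

    call: CnvCall
    gene: str
    overlaps_locus: bool
    exon_disrupting: bool


def exclude_outlier_samples(
    calls: Sequence[CnvCall],
    rule: Literal["mad"] | Sequence[str] = "mad",
) -> tuple[list[CnvCall], list[str]]:
    """Remove calls from samples with outlying genome-wide call counts.

    The default rule flags samples whose call count exceeds
    median + 3 * MAD over all samples; when the MAD degenerates to zero
    (typical for discrete counts) the IQR takes its place, and if that is
    also zero any count above the median is flagged. Passing an explicit
    sequence of sample ids removes exactly those samples instead.
    """
    if not isinstance(rule, str):
        excluded = set(rule)
        kept = [c for c in calls if c.sample_id not in excluded]
        return kept, sorted(excluded)
    if rule != "mad":
        raise ValueError(f"unknown outlier rule: {rule}")
    counts = Counter(c.sample_id for c in calls)
    if not counts:
        return [], []
    values = np.array(list(counts.values()), dtype=float)
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    spread = mad
    if spread == 0:
        q75, q25 = np.percentile(values, [75, 25])
        spread = float(q75 - q25)
    cutoff = med + 3.0 * spread
    excluded = sorted(s for s, n in counts.items() if n > cutoff)
    excluded_set = set(excluded)
    kept = [c for c in calls if c.sample_id not in excluded_set]
    return kept, excluded


def filter_min_markers(
    calls: Sequence[CnvCall], min_markers: int = 10
) -> list[CnvCall]:
    """Keep calls spanning at least ``min_markers`` consecutive markers."""
    return [c for c in calls if c.n_markers >= min_markers]


def _gap_fraction(members: Sequence[CnvCall]) -> float:
    """Fraction of the joined span not covered by any member interval."""
    span_start = min(c.start for c in members)
    span_end = max(c.end for c in members)
    span = span_end - span_start + 1
    covered = 0
    prev_end = span_start - 1
    for c in sorted(members, key=lambda x: (x.start, x.end)):
        s = max(c.start, prev_end + 1)
        if c.end >= s:
            covered += c.end - s + 1
            prev_end = c.end
        prev_end = max(prev_end, c.end)
    return (span - covered) / span


def _merge_group(calls: list[CnvCall]) -> list[CnvCall]:
    """Greedy adjacent joining within one (sample, chrom, state) group.

    Each working call tracks its member fragments so the gap criterion is
    evaluated on the union of original intervals, not on already-joined
    bounding boxes. Iterates to a fixed point.
    """
    groups: list[list[CnvCall]] = [
        [c] for c in sorted(calls, key=lambda x: (x.start, x.end))
    ]
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(groups) - 1:
            candidate = groups[i] + groups[i + 1]
            if _gap_fraction(candidate) < 0.5:
                groups[i : i + 2] = [candidate]
                changed = True
            else:
                i += 1
    out = []
    for members in groups:
        first = members[0]
        out.append(
            replace(
                first,
                start=min(c.start for c in members),
                end=max(c.end for c in members),
                n_markers=sum(c.n_markers for c in members),
            )
        )
    return out


def merge_calls(calls: Sequence[CnvCall]) -> list[CnvCall]:
    """Join nearby fragments of the same event.

    Joining is confined to calls sharing sample, chromosome and copy state
    (a deletion is never joined to a duplication). Two adjacent calls (or
    previously joined groups) are joined when the total length of the
    interval(s) between the member calls is less than 50% of their combined
    length including those intervals. Overlapping same-state calls join
    unconditionally (gap 0). Marker counts add over members; markers falling
    in the gaps are unknown from the call list and are not invented.
    """
    grouped: dict[tuple[str, str, str], list[CnvCall]] = defaultdict(list)
    for c in calls:
        grouped[(c.sample_id, _norm_chrom(c.chrom), c.copy_state)].append(c)
    out: list[CnvCall] = []
    for key in sorted(grouped):
        out.extend(_merge_group(grouped[key]))
    out.sort(key=lambda c: (c.sample_id, _norm_chrom(c.chrom), c.start, c.end))
    return out


def refine_calls(
    calls: Sequence[CnvCall],
    min_markers: int = 10,
    outlier_rule: Literal["mad"] | Sequence[str] = "mad",
) -> tuple[list[CnvCall], list[str]]:
    """Full refinement: outlier exclusion, marker filter, then joining."""
    kept, excluded = exclude_outlier_samples(calls, outlier_rule)
    kept = filter_min_markers(kept, min_markers)
    return merge_calls(kept), excluded


def annotate_overlaps(
    calls: Sequence[CnvCall], loci: Iterable[GeneLocus]
) -> list[CnvAnnotation]:
    """Overlaps of refined calls with gene loci, flagging exon disruption.

    A call overlaps a locus when the intervals share at least 1 bp; it is
    exon-disrupting when it additionally intersects any exon of the locus's
    gene models. Chromosome names are compared 'chr'-prefix-tolerantly.
    """
    loci = list(loci)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, locus in enumerate(loci):
        # IntervalTree is half-open; +1 makes the 1-based inclusive end interior
        trees[_norm_chrom(locus.chrom)].addi(locus.start, locus.end + 1, idx)
    annotations = []
    for call in calls:
        for hit in trees[_norm_chrom(call.chrom)].overlap(
            call.start, call.end + 1
        ):
            locus = loci[hit.data]
            exonic = any(
                call.start <= ex_end and call.end >= ex_start
                for ex_start, ex_end in locus.exons
            )
            annotations.append(
                CnvAnnotation(
                    call=call,
                    gene=locus.gene,
                    overlaps_locus=True,
                    exon_disrupting=exonic,
                )
            )
    annotations.sort(
        key=lambda a: (a.gene, a.call.sample_id, a.call.start, a.call.end)
    )
    return annotations


def case_control_table(annotations: Sequence[CnvAnnotation]) -> pd.DataFrame:
    """Per-gene counts of deletions/duplications split by phenotype."""
    counts: dict[str, Counter] = defaultdict(Counter)
    for a in annotations:
        if not a.overlaps_locus:
            continue
        counts[a.gene][(a.call.phenotype, a.call.copy_state)] += 1
    rows = []
    for gene in sorted(counts):
        c = counts[gene]
        rows.append(
            {
                "gene": gene,
                "case_deletions": c[("case", "deletion")],
                "control_deletions": c[("control", "deletion")],
                "case_duplications": c[("case", "duplication")],
                "control_duplications": c[("control", "duplication")],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "case_deletions",
            "control_deletions",
            "case_duplications",
            "control_duplications",
        ],
    )
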
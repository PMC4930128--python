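"""End-to-end orchestration: synthetic study generation and the full run.

``simulate_study`` writes a complete synthetic input set (expression matrix,
gene models, marker table, CNV calls, mapping and truth files) emulating the
modeled study: a 4 + 4 pooled expression design with spiked differentially
expressed probes, 20 candidate gene loci with GWAS markers (one locus
association spiked), and fragmented CNV call lists.

``run_pipeline`` executes the four analysis stages over any conforming
inputs and writes a deterministic report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cnv import annotate_overlaps, case_control_table, refine_calls
from .config import PipelineConfig
from .expression import (
    StringencyGridRow,
    fdr_grid,
    grid_to_frame,
    pairwise_robustness,
    results_to_frame,
    robust_hits,
    select_stringency,
)
from .gwas import GeneLocus, associate_locus, experiment_wide, summarize_loci
from .io import (
    read_cnv_calls,
    read_expression_matrix,
    read_gene_models,
    read_marker_table,
    read_probe_gene_map,
    write_cnv_calls,
    write_expression_matrix,
    write_gene_models,
    write_group_map,
    write_marker_table,
    write_probe_gene_map,
)
from .simulate import (
    SimulationConfig,
    SyntheticTruth,
    gen_cnv_calls,
    gen_expression,
    gen_gwas_markers,
)
from .cnv import CnvCall

logger = logging.getLogger("psyscreen")

__all__ = ["RunReport", "simulate_study", "run_pipeline"]


# ------------------------------------------------------------- simulation

_CHROMS = [str(c) for c in range(1, 23)]


def _gen_gene_models(
    n_loci: int, rng: np.random.Generator
) -> list[tuple[str, str, list[tuple[int, int]], list[tuple[int, int]]]]:
    """Synthetic gene models: one or two transcripts, 4-9 exons each."""
    records = []
    for i in range(n_loci):
        gene = f"GENE{i + 1:02d}"
        chrom = _CHROMS[i % len(_CHROMS)]
        start = int(rng.integers(1_000_000, 100_000_000))
        length = int(rng.integers(60_000, 300_000))
        end = start + length
        transcripts = [(start, end)]
        if rng.random() < 0.5:  # second, shorter isoform
            t2_start = start + int(rng.integers(0, length // 3))
            t2_end = end - int(rng.integers(0, length // 3))
            transcripts.append((t2_start, t2_end))
        n_exons = int(rng.integers(4, 10))
        exon_starts = np.sort(
            rng.choice(length - 2000, size=n_exons, replace=False) + start
        )
        exons = [
            (int(s), int(s) + int(rng.integers(100, 2000)))
            for s in exon_starts
        ]
        exons = [(s, min(e, end)) for s, e in exons]
        records.append((gene, chrom, transcripts, exons))
    return records


def _gen_true_cnvs(
    loci: list[GeneLocus],
    n_samples: int,
    n_events: int,
    rng: np.random.Generator,
) -> list[CnvCall]:
    """True (unfragmented) CNV events; roughly half land on candidate loci."""
    events: list[CnvCall] = []
    taken: dict[tuple[str, str], list[tuple[int, int]]] = {}
    attempts = 0
    while len(events) < n_events and attempts < n_events * 20:
        attempts += 1
        sample = f"S{int(rng.integers(n_samples)) + 1:04d}"
        phenotype = "case" if rng.random() < 0.5 else "control"
        state = "deletion" if rng.random() < 0.5 else "duplication"
        length = int(rng.integers(50_000, 300_000))
        if rng.random() < 0.5 and loci:
            locus = loci[int(rng.integers(len(loci)))]
            chrom = locus.chrom
            start = int(
                rng.integers(
                    max(1, locus.start - length // 2), locus.end
                )
            )
        else:
            chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
            start = int(rng.integers(1_000_000, 200_000_000))
        end = start + length - 1
        key = (sample, chrom)
        overlap = any(
            s <= end and e >= start for s, e in taken.get(key, [])
        )
        if overlap:  # true events must not overlap within a sample
            continue
        taken.setdefault(key, []).append((start, end))
        events.append(
            CnvCall(
                sample_id=sample,
                phenotype=phenotype,
                chrom=chrom,
                start=start,
                end=end,
                copy_state=state,
                n_markers=int(rng.integers(20, 120)),
            )
        )
    return sorted(events, key=lambda c: (c.sample_id, c.chrom, c.start))


def simulate_study(
    out_dir: str | Path,
    sim_config: SimulationConfig | None = None,
    n_loci: int = 20,
    mean_markers_per_locus: int = 2000,
    spike_locus_p: float = 1.5e-11,
    n_cnv_samples: int = 300,
    n_true_cnvs: int = 700,
    fragmentation_rate: float = 0.5,
) -> SyntheticTruth:
    """Generate and write every pipeline input, returning the ground truth.

    Differentially expressed probes are mapped round-robin onto the
    synthetic genes; the gene of the first DE probe receives the spiked
    GWAS marker, so the end-to-end run should flag exactly that gene as
    gene-wide significant.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config = sim_config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([sim_config.seed, 17]))

    matrix, truth = gen_expression(sim_config)
    write_expression_matrix(matrix, out / "expression.tsv")
    write_group_map(matrix, out / "groups.tsv")

    gene_records = _gen_gene_models(n_loci, rng)
    write_gene_models(gene_records, out / "gene_models.bed")
    loci = [
        GeneLocus(
            gene=g,
            chrom=c,
            start=max(1, min(s for s, _ in ts) - 20000),
            end=max(e for _, e in ts) + 20000,
            transcripts=tuple(ts),
            exons=tuple(ex),
        )
        for g, c, ts, ex in gene_records
    ]

    # probe -> gene mapping: DE probes cycle through the genes
    de_probes = sorted(truth.de_effects)
    mapping = {
        pid: gene_records[i % n_loci][0] for i, pid in enumerate(de_probes)
    }
    write_probe_gene_map(mapping, out / "probe_gene_map.tsv")

    spiked_gene = gene_records[0][0] if de_probes else None
    spiked = {spiked_gene: spike_locus_p} if spiked_gene else {}
    n_markers = [
        max(10, int(rng.normal(mean_markers_per_locus, mean_markers_per_locus / 5)))
        for _ in loci
    ]
    markers, marker_truth = gen_gwas_markers(
        loci, n_markers, spiked=spiked, seed=int(rng.integers(2**31))
    )
    write_marker_table(markers, out / "markers.tsv")
    truth.spiked_markers = marker_truth.spiked_markers

    true_cnvs = _gen_true_cnvs(loci, n_cnv_samples, n_true_cnvs, rng)
    calls, cnv_truth = gen_cnv_calls(
        true_cnvs,
        fragmentation_rate=fragmentation_rate,
        seed=int(rng.integers(2**31)),
    )
    write_cnv_calls(calls, out / "cnv_calls.tsv")
    truth.true_cnvs = cnv_truth.true_cnvs

    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    logger.info(
        "simulated study: %d probes (%d DE), %d loci, %d markers, "
        "%d CNV calls from %d true events",
        sim_config.n_probes,
        sim_config.n_de,
        n_loci,
        len(markers),
        len(calls),
        len(true_cnvs),
    )
    return truth


# --------------------------------------------------------------- full run

@dataclass
class RunReport:
    """All tables produced by one pipeline run, plus provenance."""

    grid: pd.DataFrame
    selected: StringencyGridRow
    hits: pd.DataFrame
    loci: pd.DataFrame
    n_gene_wide_significant: int
    experiment_wide: pd.DataFrame
    total_markers: int
    experiment_wide_significant: list[str]
    cnv_refined: pd.DataFrame
    cnv_gene_table: pd.DataFrame
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = dict(sep="\t", index=False, float_format="%.6g")
        self.grid.to_csv(out / "stringency_grid.tsv", **fmt)
        self.hits.to_csv(out / "robust_hits.tsv", **fmt)
        self.loci.to_csv(out / "locus_associations.tsv", **fmt)
        self.experiment_wide.to_csv(out / "experiment_wide.tsv", **fmt)
        self.cnv_refined.to_csv(out / "cnv_refined.tsv", **fmt)
        self.cnv_gene_table.to_csv(out / "cnv_gene_table.tsv", **fmt)
        summary = {
            "selected_stringency": {
                "alr_thresh": self.selected.alr_thresh,
                "p_thresh": self.selected.p_thresh,
                "exp_count": self.selected.exp_count,
                "fdr_percent": self.selected.fdr_percent,
            },
            "n_robust_hits": int(len(self.hits)),
            "n_gene_wide_significant": self.n_gene_wide_significant,
            "total_markers": self.total_markers,
            "experiment_wide_significant": self.experiment_wide_significant,
            "provenance": self.provenance,
        }
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )


def run_pipeline(config: PipelineConfig, base_dir: str | Path = ".") -> RunReport:
    """Execute screening, robustness, locus lookup and CNV refinement."""
    base = Path(base_dir)

    def path(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    for name in ("expression", "groups", "gene_models", "markers", "cnv_calls"):
        p = path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"missing input '{name}': {p}")

    matrix = read_expression_matrix(
        path(config.expression), path(config.groups)
    )
    logger.info(
        "expression: %d probes x %d samples",
        len(matrix.probe_ids),
        len(matrix.sample_ids),
    )

    grid = fdr_grid(matrix, config.stringencies, agg=config.fdr_boot_agg)
    grid_df = grid_to_frame(grid)
    logger.info("stringency grid:\n%s", grid_df.to_string(index=False))
    selected = select_stringency(grid, min_exp=config.min_exp)

    results = pairwise_robustness(matrix, thresh=config.robust_thresh)
    # robustness refines the list that already passed the selected stringency
    passing = [
        r
        for r in results
        if abs(r.alr) >= selected.alr_thresh
        and r.p_value < selected.p_thresh
    ]
    hits = robust_hits(passing, min_count=config.robust_min_count)
    if not hits:
        logger.warning("robustness filter returned an empty hit list")
    hits_df = results_to_frame(hits)
    map_path = path(config.probe_gene_map)
    mapping = read_probe_gene_map(map_path) if map_path.exists() else {}
    hits_df["gene"] = [mapping.get(p, "") for p in hits_df["probe_id"]]

    loci = read_gene_models(path(config.gene_models), pad=config.pad)
    markers = read_marker_table(path(config.markers))
    associations = [associate_locus(markers, locus) for locus in loci]
    loci_df, n_sig = summarize_loci(associations, alpha=config.alpha)
    total_markers, exp_wide_df, exp_sig = experiment_wide(
        associations, alpha=config.alpha
    )
    logger.info(
        "locus lookup: %d loci, %d markers total, %d gene-wide significant",
        len(loci),
        total_markers,
        n_sig,
    )

    raw_calls = read_cnv_calls(path(config.cnv_calls))
    refined, excluded = refine_calls(
        raw_calls,
        min_markers=config.cnv_min_markers,
        outlier_rule=config.outlier_rule,
    )
    annotations = annotate_overlaps(refined, loci)
    exonic = [a for a in annotations if a.exon_disrupting]
    gene_table = case_control_table(exonic)
    logger.info(
        "cnv: %d raw -> %d refined calls (%d outlier samples), "
        "%d exon-disrupting overlaps",
        len(raw_calls),
        len(refined),
        len(excluded),
        len(exonic),
    )
    refined_df = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "phenotype": c.phenotype,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "copy_state": c.copy_state,
                "n_markers": c.n_markers,
            }
            for c in refined
        ]
    )

    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "excluded_cnv_samples": excluded,
    }
    report = RunReport(
        grid=grid_df,
        selected=selected,
        hits=hits_df,
        loci=loci_df,
        n_gene_wide_significant=n_sig,
        experiment_wide=exp_wide_df,
        total_markers=total_markers,
        experiment_wide_significant=exp_sig,
        cnv_refined=refined_df,
        cnv_gene_table=gene_table,
        provenance=provenance,
    )
    report.write(path(config.out_dir))
    return report
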
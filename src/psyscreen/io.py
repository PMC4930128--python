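"""Readers and writers for the pipeline's plain-text formats.

Formats: expression matrix TSV (first column probe id, header = sample ids),
sample-group map TSV, BED12 gene models, PLINK-style association tables,
CNV call lists (named-column TSV or PennCNV ``rawcnv`` lines), a
probe-to-gene mapping TSV and the synthetic-truth TSV.

Internal coordinates are 1-based inclusive throughout; BED's 0-based
half-open intervals are converted on ingest and egress. All readers report
malformed lines with their line number.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cnv import CnvCall
from .expression import ExpressionMatrix
from .gwas import GeneLocus, GwasMarker, build_locus


class ParseError(ValueError):
    """A malformed input line or field, with location information."""


# ---------------------------------------------------------------- expression

def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_group_map(matrix: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": matrix.sample_ids,
         "group": [matrix.groups[s] for s in matrix.sample_ids]}
    ).to_csv(path, sep="\t", index=False)


def read_expression_matrix(
    values_path: str | Path, groups_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in gdf.columns:
            raise ParseError(f"{groups_path}: missing column '{col}'")
    groups = dict(zip(gdf["sample_id"], gdf["group"]))
    return ExpressionMatrix(values=values, groups=groups)


# ------------------------------------------------------------------- BED12

_BED12_FIELDS = 12


def read_gene_models(path: str | Path, pad: int = 20000) -> list[GeneLocus]:
    """Read BED12 transcripts, grouped by name, into padded gene loci.

    Each BED line is one transcript; its blocks are the exons. Lines sharing
    the ``name`` field belong to one gene. BED chromStart is 0-based
    half-open: internal starts are chromStart + 1.
    """
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < _BED12_FIELDS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_BED12_FIELDS} BED fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                chrom_end = int(fields[2])
                name = fields[3]
                block_count = int(fields[9])
                block_sizes = [
                    int(x) for x in fields[10].rstrip(",").split(",")
                ]
                block_starts = [
                    int(x) for x in fields[11].rstrip(",").split(",")
                ]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise ParseError(
                    f"{path}:{lineno}: block count mismatch in blockSizes/"
                    "blockStarts"
                )
            transcript = (chrom_start + 1, chrom_end)
            exons = [
                (chrom_start + off + 1, chrom_start + off + size)
                for off, size in zip(block_starts, block_sizes)
            ]
            entry = per_gene.setdefault(
                name, {"chrom": chrom, "transcripts": [], "exons": []}
            )
            if entry["chrom"] != chrom:
                raise ParseError(
                    f"{path}:{lineno}: gene '{name}' spans chromosomes"
                )
            entry["transcripts"].append(transcript)
            entry["exons"].extend(exons)
    return [
        build_locus(
            gene, entry["chrom"], entry["transcripts"], entry["exons"], pad=pad
        )
        for gene, entry in per_gene.items()
    ]


def write_gene_models(
    genes: Iterable[tuple[str, str, Sequence[tuple[int, int]], Sequence[tuple[int, int]]]],
    path: str | Path,
) -> None:
    """Write (gene, chrom, transcripts, exons) records as BED12.

    Each transcript becomes one BED line; exons falling within a transcript
    become its blocks. Inputs are 1-based inclusive.
    """
    with open(path, "w") as fh:
        for gene, chrom, transcripts, exons in genes:
            for t_start, t_end in transcripts:
                blocks = sorted(
                    (s, e) for s, e in exons if s >= t_start and e <= t_end
                )
                if not blocks:
                    blocks = [(t_start, t_end)]
                sizes = ",".join(str(e - s + 1) for s, e in blocks)
                offsets = ",".join(str(s - t_start) for s, _ in blocks)
                fh.write(
                    "\t".join(
                        [
                            chrom,
                            str(t_start - 1),
                            str(t_end),
                            gene,
                            "0",
                            "+",
                            str(t_start - 1),
                            str(t_end),
                            "0",
                            str(len(blocks)),
                            sizes,
                            offsets,
                        ]
                    )
                    + "\n"
                )


# ------------------------------------------------------------ marker tables

DEFAULT_MARKER_ALIASES: dict[str, str] = {
    "snp": "marker_id",
    "marker": "marker_id",
    "marker_id": "marker_id",
    "chr": "chrom",
    "chrom": "chrom",
    "chromosome": "chrom",
    "bp": "pos",
    "pos": "pos",
    "position": "pos",
    "p": "p",
    "pval": "p",
    "p-value": "p",
    "pvalue": "p",
}


def read_marker_table(
    path: str | Path, aliases: dict[str, str] | None = None
) -> list[GwasMarker]:
    """Read a PLINK-association-style table (whitespace- or tab-delimited).

    The header must contain columns resolvable (case-insensitively, via the
    alias map) to marker id, chromosome, position and P.
    """
    alias_map = dict(DEFAULT_MARKER_ALIASES)
    if aliases:
        alias_map.update({k.lower(): v for k, v in aliases.items()})
    df = pd.read_csv(path, sep=r"\s+")
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in alias_map:
            renames[col] = alias_map[key]
    df = df.rename(columns=renames)
    missing = {"marker_id", "chrom", "pos", "p"} - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}: cannot resolve required columns {sorted(missing)} "
            f"from header {list(df.columns)}"
        )
    markers = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            markers.append(
                GwasMarker(
                    marker_id=str(row.marker_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    p=float(row.p),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{i}: {exc}") from exc
    return markers


def write_marker_table(markers: Iterable[GwasMarker], path: str | Path) -> None:
    pd.DataFrame(
        {
            "SNP": [m.marker_id for m in markers],
            "CHR": [m.chrom for m in markers],
            "BP": [m.pos for m in markers],
            "P": [m.p for m in markers],
        }
    ).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- CNVs

_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+length=(?P<length>[\d,]+)\s+"
    r"state\d+,cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
)

_CNV_COLUMNS = [
    "sample_id",
    "phenotype",
    "chrom",
    "start",
    "end",
    "copy_state",
    "n_markers",
]


def read_cnv_calls(path: str | Path) -> list[CnvCall]:
    """Read CNV calls from a named-column TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_CNV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    calls = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            calls.append(
                CnvCall(
                    sample_id=str(row.sample_id),
                    phenotype=str(row.phenotype),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    copy_state=str(row.copy_state),
                    n_markers=int(row.n_markers),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{i}: {exc}") from exc
    return calls


def read_penncnv_rawcnv(
    path: str | Path, phenotypes: dict[str, str]
) -> list[CnvCall]:
    """Read PennCNV ``rawcnv`` lines, assigning phenotypes from a map.

    Copy number below 2 is a deletion, above 2 a duplication; cn=2 lines are
    rejected (no event).
    """
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            m = _RAWCNV_RE.match(line)
            if not m:
                raise ParseError(
                    f"{path}:{lineno}: unrecognized rawcnv line"
                )
            cn = int(m.group("cn"))
            if cn == 2:
                raise ParseError(
                    f"{path}:{lineno}: cn=2 is not a copy-number event"
                )
            sample = m.group("sample")
            if sample not in phenotypes:
                raise ParseError(
                    f"{path}:{lineno}: sample '{sample}' missing from "
                    "phenotype map"
                )
            calls.append(
                CnvCall(
                    sample_id=sample,
                    phenotype=phenotypes[sample],
                    chrom=m.group("chrom"),
                    start=int(m.group("start")),
                    end=int(m.group("end")),
                    copy_state="deletion" if cn < 2 else "duplication",
                    n_markers=int(m.group("numsnp").replace(",", "")),
                )
            )
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    pd.DataFrame(
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
            for c in calls
        ],
        columns=_CNV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "phenotype"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column '{col}'")
    return dict(zip(df["sample_id"], df["phenotype"]))


# ----------------------------------------------------------- small mappings

def read_probe_gene_map(path: str | Path) -> dict[str, str]:
    """Probe-to-gene mapping TSV with columns probe_id, gene_symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_symbol"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column '{col}'")
    return dict(zip(df["probe_id"], df["gene_symbol"]))


def write_probe_gene_map(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(mapping), "gene_symbol": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)
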
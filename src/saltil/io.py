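"""Readers and writers for the pipeline's standard formats.

Conventions: GFF3 and the internal annotation use 1-based inclusive
coordinates; exported BED intervals are 0-based half-open (start-1, end).
TSV files are tab-delimited UTF-8 with a header row and '.' for missing
values. Genotype matrices round-trip through VCF v4.2 (GT-only FORMAT;
0/0 = recurrent homozygote, 0/1 = heterozygote, 1/1 = donor homozygote)
and through a lines x markers TSV of A/H/B symbols.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .breeding import GeneticMap, LineGenotype, STATE_SYMBOL, SYMBOL_STATE
from .introgression import IntrogressionBlock, IntrogressionReport
from .synth import ExpressionTruth, LineTruth

logger = logging.getLogger("saltil")


class FormatError(ValueError):
    """Raised when a file violates its format contract."""


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write the transcript annotation as GFF3 (one mRNA feature per row)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            fh.write("\t".join([
                row.chrom, "saltil", "mRNA", str(row.start), str(row.end),
                ".", getattr(row, "strand", "."), ".",
                f"ID={row.transcript_id}",
            ]) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read transcript features from GFF3, preserving 1-based inclusive
    coordinates.

    Records without an ``ID`` attribute are skipped with a logged warning;
    malformed lines (wrong column count, non-numeric or inverted
    coordinates) raise :class:`FormatError` naming the line number.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, _ftype, start, end, _score, strand, _phase, attrs \
                = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}:{lineno}: non-numeric coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise FormatError(
                    f"{path.name}:{lineno}: invalid interval {start}-{end}")
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if "ID" not in attributes:
                logger.warning("%s:%d: record without ID skipped",
                               path.name, lineno)
                continue
            records.append((attributes["ID"], chrom, start_i, end_i, strand))
    return pd.DataFrame(
        records, columns=["transcript_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, na_rep=".")


def read_variant_profiles(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "chrom", "start", "end", "v_test", "v_control"}
    if not required.issubset(table.columns):
        raise FormatError(f"variant-profile table needs columns {required}")
    if (table[["v_test", "v_control"]] < 0).to_numpy().any():
        raise FormatError("negative variant counts")
    if (table["end"] < table["start"]).any():
        raise FormatError("end < start in variant-profile table")
    return table


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts < 0).to_numpy().any():
        raise FormatError("negative expression counts")
    return counts


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "genotype", "condition", "replicate"}
    if not required.issubset(meta.columns):
        raise FormatError(f"metadata needs columns {required}")
    return meta


def read_gene_lengths(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", index_col=0)
    series = table.iloc[:, 0]
    if (series <= 0).any():
        raise FormatError("gene lengths must be positive")
    return series


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=".")
    required = {"line_id", "replicate", "condition", "Ec1", "Ec2"}
    if not required.issubset(table.columns):
        raise FormatError(f"phenotype table needs columns {required}")
    both = table[["Ec1", "Ec2"]].dropna()
    if (both["Ec1"] > both["Ec2"]).any():
        raise FormatError("Ec1 > Ec2 in phenotype table")
    return table


def read_ions(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"line_id", "tissue", "replicate", "na_amount", "k_amount", "unit"}
    if not required.issubset(table.columns):
        raise FormatError(f"ion table needs columns {required}")
    if (table[["na_amount", "k_amount"]] <= 0).to_numpy().any():
        raise FormatError("ion amounts must be positive")
    return table


def read_genetic_map(path: str | Path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t"))


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    write_tsv(gmap.table, path)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(report: IntrogressionReport, path: str | Path) -> None:
    """Write called blocks as BED: 0-based half-open, score = gene count."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\n")
        for i, block in enumerate(report.blocks, start=1):
            fh.write(f"{block.chrom}\t{block.start_bp - 1}\t{block.end_bp}\t"
                     f"block{i}\t{block.n_genes}\n")


def read_bed_blocks(path: str | Path) -> tuple[IntrogressionBlock, ...]:
    """Read blocks back from BED (members are not stored in BED; the gene
    count is carried in the score column and member ids are left empty)."""
    blocks = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"BED line {lineno}: expected 5 columns")
            chrom, start, end, _name, score = fields[:5]
            blocks.append(IntrogressionBlock(
                chrom=chrom, start_bp=int(start) + 1, end_bp=int(end),
                members=("",) * int(score)))
    return tuple(blocks)


# ---------------------------------------------------------------------------
# VCF v4.2 genotype matrices
# ---------------------------------------------------------------------------

_STATE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes_vcf(
    lines: list[LineGenotype],
    gmap: GeneticMap,
    path: str | Path,
) -> None:
    """Write a marker x line genotype matrix as VCF v4.2 (GT-only)."""
    if not lines:
        raise FormatError("no lines to write")
    path = Path(path)
    table = gmap.table
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=saltil\n")
        for chrom, sub in table.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos_bp'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.line_id for g in lines) + "\n")
        index = {m: i for i, m in enumerate(lines[0].marker_ids)}
        for row in table.itertuples(index=False):
            i = index[row.marker_id]
            gts = "\t".join(_STATE_TO_GT[int(g.states[i])] for g in lines)
            fh.write(f"{row.chrom}\t{row.pos_bp}\t{row.marker_id}\tA\tG\t.\t"
                     f"PASS\t.\tGT\t{gts}\n")


def read_genotypes_vcf(path: str | Path) -> pd.DataFrame:
    """Read a GT-only VCF back into a lines x markers table of A/H/B symbols."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers, columns = [], []
    for variant in vcf:
        markers.append(variant.ID)
        states = []
        for gt in variant.genotypes:
            alleles = gt[:2]
            states.append(STATE_SYMBOL[int(sum(alleles))])
        columns.append(states)
    vcf.close()
    return pd.DataFrame(
        np.array(columns).T, index=samples, columns=markers)


def write_genotypes_tsv(lines: list[LineGenotype], path: str | Path) -> None:
    """Lines x markers TSV with A (RR), H (RD), B (DD) symbols."""
    if not lines:
        raise FormatError("no lines to write")
    data = {g.line_id: [STATE_SYMBOL[int(s)] for s in g.states] for g in lines}
    frame = pd.DataFrame(data, index=list(lines[0].marker_ids)).T
    frame.index.name = "line_id"
    frame.to_csv(path, sep="\t")


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    bad = set(np.unique(frame.to_numpy())) - set(SYMBOL_STATE)
    if bad:
        raise FormatError(f"unknown genotype symbols {sorted(bad)}")
    return frame


# ---------------------------------------------------------------------------
# truth JSON
# ---------------------------------------------------------------------------

def write_truth(
    truth: LineTruth,
    path: str | Path,
    expression_truth: ExpressionTruth | None = None,
) -> None:
    payload: dict = {
        "donor_blocks": [list(b) for b in truth.donor_blocks],
        "labels": truth.labels.to_dict(),
        "dispersed_transcripts": list(truth.dispersed_transcripts),
        "block_transcripts": [list(b) for b in truth.block_transcripts],
    }
    if expression_truth is not None:
        payload["deg_truth"] = {
            "up": {g: sorted(s) for g, s in expression_truth.up.items()},
            "down": {g: sorted(s) for g, s in expression_truth.down.items()},
        }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> tuple[LineTruth, ExpressionTruth | None]:
    payload = json.loads(Path(path).read_text())
    labels = pd.Series(payload["labels"], name="label")
    labels.index.name = "transcript_id"
    truth = LineTruth(
        donor_blocks=tuple(tuple(b) for b in payload["donor_blocks"]),
        labels=labels,
        dispersed_transcripts=tuple(payload["dispersed_transcripts"]),
        block_transcripts=tuple(tuple(b) for b in payload["block_transcripts"]),
    )
    expr = None
    if "deg_truth" in payload:
        expr = ExpressionTruth(
            up={g: frozenset(s) for g, s in payload["deg_truth"]["up"].items()},
            down={g: frozenset(s)
                  for g, s in payload["deg_truth"]["down"].items()},
        )
    return truth, expr
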
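"""Plain-text readers and writers for the pipeline's standard formats.

BEDPE coordinates are 0-based half-open (breakends written as 1 bp
intervals); GFF3 is 1-based inclusive; MatrixMarket counts ship with
``features.tsv``/``barcodes.tsv`` plus a cell-metadata TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .domain_expression import ExonCoverageTrack
from .genemodel import GeneModel, read_gff3, write_gff3
from .single_nucleus import CountMatrix
from .sv_consequence import BreakpointPair, CopyNumberSegment
from .variant_filters import VariantRecord

__all__ = [
    "write_model",
    "read_model",
    "write_bedpe",
    "read_bedpe",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_coverage_tsv",
    "read_coverage_tsv",
    "write_cn_tsv",
    "read_cn_tsv",
    "write_counts",
    "read_counts",
]

_NA = "."


def write_model(model: GeneModel, path) -> None:
    write_gff3(model, path)


def read_model(path) -> GeneModel:
    return read_gff3(path)


def _fmt(value) -> str:
    return _NA if value is None else str(value)


def _opt_float(token: str):
    return None if token == _NA else float(token)


BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "sv_class", "cluster", "assembly_score", "reads", "sample_type", "truth",
]


def write_bedpe(records: list[VariantRecord], path) -> None:
    rows = []
    for rec in records:
        if rec.variant_class != "rearrangement" or rec.breakpoints is None:
            continue
        bp = rec.breakpoints
        rows.append(
            [
                bp.contig, bp.pos_a, bp.pos_a + 1,
                bp.contig_b or bp.contig, bp.pos_b, bp.pos_b + 1,
                rec.id, _NA, bp.orient_a, bp.orient_b,
                bp.sv_class, _fmt(bp.cluster), _fmt(rec.assembly_score),
                _fmt(rec.supporting_reads), _fmt(rec.sample_type), _fmt(rec.truth),
            ]
        )
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bedpe(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        bp = BreakpointPair(
            id=row["name"],
            contig=row["chrom1"],
            pos_a=int(row["start1"]),
            pos_b=int(row["start2"]),
            sv_class=row["sv_class"],
            orient_a=row["strand1"],
            orient_b=row["strand2"],
            cluster=None if row["cluster"] == _NA else row["cluster"],
            contig_b=None if row["chrom2"] == row["chrom1"] else row["chrom2"],
        )
        reads = row["reads"]
        records.append(
            VariantRecord(
                id=row["name"],
                variant_class="rearrangement",
                contig=row["chrom1"],
                assembly_score=_opt_float(row["assembly_score"]),
                supporting_reads=None if reads == _NA else int(float(reads)),
                sample_type=None if row["sample_type"] == _NA else row["sample_type"],
                breakpoints=bp,
                truth=None if row["truth"] == _NA else row["truth"],
            )
        )
    return records


VARIANT_COLUMNS = [
    "id", "class", "contig", "position", "asmd", "clpm",
    "quality", "sample_type", "effect", "truth",
]


def write_variants_tsv(records: list[VariantRecord], path) -> None:
    rows = [
        [
            rec.id, rec.variant_class, _fmt(rec.contig), _fmt(rec.position),
            _fmt(rec.asmd), _fmt(rec.clpm), _fmt(rec.quality),
            _fmt(rec.sample_type), _fmt(rec.effect), _fmt(rec.truth),
        ]
        for rec in records
        if rec.variant_class != "rearrangement"
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            VariantRecord(
                id=row["id"],
                variant_class=row["class"],
                contig=None if row["contig"] == _NA else row["contig"],
                position=None if row["position"] == _NA else int(row["position"]),
                asmd=_opt_float(row["asmd"]),
                clpm=_opt_float(row["clpm"]),
                quality=_opt_float(row["quality"]),
                sample_type=None if row["sample_type"] == _NA else row["sample_type"],
                effect=None if row["effect"] == _NA else row["effect"],
                truth=None if row["truth"] == _NA else row["truth"],
            )
        )
    return out


def write_coverage_tsv(tracks, path) -> None:
    if isinstance(tracks, ExonCoverageTrack):
        tracks = [tracks]
    rows = []
    for t in tracks:
        for i in range(t.n_exons):
            rows.append(
                [t.gene, i + 1, int(t.counts[i]), int(t.lengths[i]), t.library_size, t.sample, t.group]
            )
    pd.DataFrame(
        rows, columns=["gene", "exon_index", "count", "length", "library_size", "sample", "group"]
    ).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path) -> list[ExonCoverageTrack]:
    df = pd.read_csv(path, sep="\t")
    tracks = []
    for (gene, sample, group, lib), sub in df.groupby(
        ["gene", "sample", "group", "library_size"], sort=False
    ):
        sub = sub.sort_values("exon_index")
        tracks.append(
            ExonCoverageTrack(
                gene=gene,
                counts=sub["count"].to_numpy(dtype=float),
                lengths=sub["length"].to_numpy(dtype=float),
                library_size=int(lib),
                sample=sample,
                group=group,
            )
        )
    return tracks


def write_cn_tsv(segments: list[CopyNumberSegment], path) -> None:
    pd.DataFrame(
        [[s.contig, s.start, s.end, s.total_cn, s.sample] for s in segments],
        columns=["contig", "start", "end", "total_cn", "sample"],
    ).to_csv(path, sep="\t", index=False)


def read_cn_tsv(path) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t")
    return [
        CopyNumberSegment(r.contig, int(r.start), int(r.end), float(r.total_cn), r.sample)
        for r in df.itertuples()
    ]


def write_counts(matrix: CountMatrix, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    spio.mmwrite(
        os.path.join(directory, "matrix.mtx"),
        sparse.coo_matrix(matrix.counts),
        field="integer",
    )
    matrix.genes.reset_index().to_csv(
        os.path.join(directory, "features.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"cell": matrix.cell_ids}).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", index=False
    )
    matrix.cells.reset_index().to_csv(
        os.path.join(directory, "cell_metadata.tsv"), sep="\t", index=False
    )


def read_counts(directory) -> CountMatrix:
    counts = np.asarray(
        spio.mmread(os.path.join(directory, "matrix.mtx")).todense(), dtype=np.int64
    )
    genes = pd.read_csv(os.path.join(directory, "features.tsv"), sep="\t").set_index("gene")
    cells = pd.read_csv(os.path.join(directory, "cell_metadata.tsv"), sep="\t").set_index("cell")
    return CountMatrix(counts=counts, genes=genes, cells=cells)
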
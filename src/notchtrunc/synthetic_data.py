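"""Generators for every input the pipeline consumes, with planted truth.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical configurations produce identical
outputs, byte for byte, when serialized via :func:`write_fixtures`.

The genomic layout emulates the locus geometry the pipeline targets: a
minus-strand 34-exon gene with extracellular (exons 1-27), transmembrane
(exon 28) and intracellular (exons 29-34) domains, a small two-exon
negative-regulator gene ~0.8 Mb away with its promoter facing the main
gene, a renin-like gene, and two decoy genes. The coordinates reproduce
the published magnitudes (0.8 Mb deletion span, ~3 kb 3' breakpoint
proximity) without claiming positional fidelity.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .domain_expression import ExonCoverageTrack
from .genemodel import ECD, ICD, TM, DEFAULT_PROMOTER_LENGTH, Exon, Gene, GeneModel
from .single_nucleus import CountMatrix
from .sv_consequence import BreakpointPair
from .variant_filters import VariantRecord

__all__ = [
    "SimConfig",
    "make_gene_model",
    "simulate_sv_callset",
    "simulate_exon_coverage",
    "simulate_counts",
    "write_fixtures",
    "CASE1_TRUTH",
    "CASE2_TRUTH",
    "SCENARIOS",
]

CASE1_TRUTH = "activating_truncation+regulator_promoter_hit"
CASE2_TRUTH = "activating_truncation+regulator_whole_gene_deleted"
SCENARIOS = ("case1", "case2", "decoys", "artifacts")

CONTIG = "toy9q"
REGULATOR_SPACER = 800_000  # main-gene end to regulator promoter start

MITO_GENES = ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CYB")
ENDOTHELIAL_MARKERS = ("PECAM1", "VWF", "FLT1")
MESANGIAL_MARKERS = ("PDGFRB", "ITGA8")
HOUSEKEEPING = ("ACTB", "GAPDH", "B2M")
TARGET_GENES = ("HEYL", "HEY1", "HEY2", "HES1", "HES4", "HES5")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    contig_length: int = 1_100_000
    exon_count: int = 34
    strand: str = "-"
    truncated_fraction: float = 0.5
    depth: float = 100.0
    cells_per_type: dict = field(
        default_factory=lambda: {"tumour": 500, "mesangial": 300, "endothelial": 200}
    )
    ren_fold: float = 3.0
    notch1_fold: float = 2.0
    target_ratio_fold: float = 4.0
    doublet_rate: float = 0.05
    lowq_rate: float = 0.05
    nb_dispersion: float = 0.1
    promoter_length: int = DEFAULT_PROMOTER_LENGTH
    n_filler_genes: int = 1280

    def __post_init__(self):
        for name in ("truncated_fraction", "doublet_rate", "lowq_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("ren_fold", "notch1_fold", "target_ratio_fold"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if self.exon_count < 30:
            raise ValueError(
                f"exon_count={self.exon_count} < 30; the domain scheme needs "
                "exons 1-27 (ECD), 28 (TM) and 29+ (ICD)"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def _domain_for(index: int) -> str:
    if index <= 27:
        return ECD
    if index == 28:
        return TM
    return ICD


def make_gene_model(config: SimConfig) -> GeneModel:
    """Toy contig with the main gene, its regulator, a renin-like gene and
    two decoys. Built in minus-strand geometry and mirrored when a
    plus-strand main gene is requested, so scenario geometry is preserved
    on both strands."""
    rng = np.random.default_rng(config.seed)
    pl = config.promoter_length
    model = GeneModel(CONTIG, config.contig_length)

    def simple_gene(name, strand, anchor, exon_lengths, intron_lengths):
        starts, cur = [], anchor
        for el, il in zip(exon_lengths, list(intron_lengths) + [0]):
            starts.append(cur)
            cur += el + il
        exons = [
            Exon(s, s + el, i + 1, "none") for i, (s, el) in enumerate(zip(starts, exon_lengths))
        ]
        if strand == "-":
            exons = [replace(e, index=len(exons) - e.index + 1) for e in exons][::-1]
            promoter = (exons[0].end, exons[0].end + pl)
        else:
            promoter = (anchor - pl, anchor)
        return Gene(name, CONTIG, strand, tuple(exons), promoter)

    model.add(simple_gene("DECOY1", "+", 5_000, [400, 600], [600]))
    model.add(simple_gene("REN", "+", 40_000, [300, 500, 600], [700, 700]))

    # main gene: built bottom-up in genomic coordinates, last exon first
    exon_lengths = rng.integers(120, 201, size=config.exon_count)
    intron_lengths = rng.integers(800, 1501, size=config.exon_count - 1)
    anchor = 100_000
    cur = anchor
    exons = []
    for i in range(config.exon_count, 0, -1):
        el = int(exon_lengths[i - 1])
        exons.append(Exon(cur, cur + el, i, _domain_for(i)))
        if i > 1:
            cur += el + int(intron_lengths[i - 2])
    exons = tuple(sorted(exons, key=lambda e: e.index))
    gene_end = exons[0].end  # exon 1 sits at the genomic top on '-'
    main = Gene("NOTCH1", CONTIG, "-", exons, (gene_end, gene_end + pl))
    model.add(main)

    # regulator: promoter faces the main gene so a deletion reaching into
    # the promoter need not touch the gene body
    reg_prom_start = gene_end + REGULATOR_SPACER
    reg = simple_gene("NRARP", "+", reg_prom_start + pl, [350, 500], [1_000])
    model.add(reg)

    decoy2_anchor = reg.end + 50_000
    model.add(simple_gene("DECOY2", "+", decoy2_anchor, [500, 400], [800]))

    required = decoy2_anchor + 3_000
    if config.contig_length < required:
        raise ValueError(
            f"contig_length={config.contig_length} is "
            f"{required - config.contig_length} bp short of the required {required}"
        )
    if config.strand == "+":
        model = model.mirrored()
    return model


def _point_in(rng, lo: int, hi: int, margin: int = 10) -> int:
    if hi - lo <= 2 * margin:
        margin = 0
    return int(rng.integers(lo + margin, hi - margin))


def simulate_sv_callset(model: GeneModel, scenario: str, seed: int = 0) -> list[VariantRecord]:
    """Rearrangement call sets with planted truth labels.

    ``case1``: one deletion from an extracellular intron of the main gene
    into the regulator promoter. ``case2``: an inversion with breakends in
    the introns flanking the transmembrane exon plus a deletion
    encompassing the whole regulator gene. ``decoys``: intergenic and
    decoy-gene events. ``artifacts``: records engineered so each filter
    rule fails exactly once.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    rng = np.random.default_rng(seed)
    contig = model.contig
    main = model["NOTCH1"]
    reg = model["NRARP"]

    def sv_record(rid, bp, truth):
        return VariantRecord(
            id=rid,
            variant_class="rearrangement",
            contig=contig,
            assembly_score=float(rng.integers(80, 100)),
            supporting_reads=int(rng.integers(20, 60)),
            sample_type="tumour",
            breakpoints=bp,
            truth=truth,
        )

    if scenario == "case1":
        k = int(rng.integers(1, 27))  # any extracellular intron
        a = _point_in(rng, *main.intron_interval(k))
        b = _point_in(rng, *reg.promoter, margin=100)
        lo, hi = sorted((a, b))
        bp = BreakpointPair("sv_case1_del", contig, lo, hi, "deletion", cluster="case1")
        return [sv_record("sv_case1_del", bp, CASE1_TRUTH)]

    if scenario == "case2":
        k = int(rng.integers(3, 15))
        a = _point_in(rng, *main.intron_interval(k))
        # ~3 kb beyond the case-1 breakpoint: just past the regulator body
        reg_lo, reg_hi = reg.footprint
        if reg_lo > main.start:  # regulator genomically above the main gene
            b = reg_hi + int(rng.integers(200, 800))
        else:
            b = reg_lo - int(rng.integers(200, 800))
        lo, hi = sorted((a, b))
        dele = BreakpointPair("sv_case2_del", contig, lo, hi, "deletion", cluster="case2")
        x = _point_in(rng, *main.intron_interval(27))
        y = _point_in(rng, *main.intron_interval(28))
        lo2, hi2 = sorted((x, y))
        inv = BreakpointPair("sv_case2_inv", contig, lo2, hi2, "inversion", cluster="case2")
        return [
            sv_record("sv_case2_inv", inv, CASE2_TRUTH),
            sv_record("sv_case2_del", dele, CASE2_TRUTH),
        ]

    if scenario == "decoys":
        jitter = int(rng.integers(0, 2_000))
        gap_lo = min(model["REN"].end, model["DECOY1"].end) + 5_000
        inter = BreakpointPair(
            "sv_decoy_intergenic",
            contig,
            gap_lo + jitter,
            gap_lo + 4_000 + jitter,
            "deletion",
            cluster="decoy1",
        )
        d2 = model["DECOY2"]
        inside = BreakpointPair(
            "sv_decoy_gene",
            contig,
            _point_in(rng, d2.start, d2.end),
            d2.end + 2_000,
            "deletion",
            cluster="decoy2",
        )
        return [
            sv_record("sv_decoy_intergenic", inter, "decoy"),
            sv_record("sv_decoy_gene", inside, "decoy"),
        ]

    # artifacts: one record per filter rule, each failing exactly that rule
    pos = int(rng.integers(60_000, 90_000))
    return [
        VariantRecord(
            id="art_asmd",
            variant_class="substitution",
            contig=contig,
            position=pos,
            asmd=float(rng.uniform(50, 139)),
            clpm=0.0,
            sample_type="tumour",
            truth="artifact:asmd",
        ),
        VariantRecord(
            id="art_clpm",
            variant_class="substitution",
            contig=contig,
            position=pos + 10,
            asmd=float(rng.uniform(141, 250)),
            clpm=float(rng.uniform(0.05, 0.5)),
            sample_type="tumour",
            truth="artifact:clpm",
        ),
        VariantRecord(
            id="art_indel",
            variant_class="indel",
            contig=contig,
            position=pos + 20,
            quality=float(rng.uniform(10, 299)),
            sample_type="tumour",
            truth="artifact:indel_quality",
        ),
        VariantRecord(
            id="art_sv",
            variant_class="rearrangement",
            contig=contig,
            supporting_reads=int(rng.integers(0, 4)),
            sample_type="tumour",
            breakpoints=BreakpointPair(
                "art_sv", contig, pos + 100, pos + 6_000, "deletion", cluster="artifact"
            ),
            truth="artifact:sv_support",
        ),
    ]


def simulate_exon_coverage(
    model: GeneModel,
    truncated_fraction: float,
    depth: float,
    seed: int = 0,
    gene: str = "NOTCH1",
    sample: str = "sim",
    group: str = "simulated",
) -> ExonCoverageTrack:
    """Poisson per-exon read-base counts for a wildtype/truncated transcript
    mixture: truncated molecules cover only the transmembrane and
    intracellular exons, so extracellular exons see depth * (1 - p)."""
    p = truncated_fraction
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"truncated_fraction={p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    g = model[gene]
    lengths = np.array([e.length for e in g.exons], dtype=float)
    domains = np.array([e.domain for e in g.exons])
    means = depth * lengths * np.where(domains == ECD, 1.0 - p, 1.0)
    counts = rng.poisson(means).astype(float)
    return ExonCoverageTrack(
        gene=gene,
        counts=counts,
        lengths=lengths,
        library_size=max(int(counts.sum()), 1),
        sample=sample,
        group=group,
    )


# ---------------------------------------------------------------------------
# single-nucleus counts
# ---------------------------------------------------------------------------

def _gene_panel(config: SimConfig, rng) -> pd.DataFrame:
    names = (
        ["REN", "NOTCH1", "NRARP"]
        + list(TARGET_GENES)
        + list(MITO_GENES)
        + list(ENDOTHELIAL_MARKERS)
        + list(MESANGIAL_MARKERS)
        + list(HOUSEKEEPING)
        + [f"FILLER{i:04d}" for i in range(1, config.n_filler_genes + 1)]
    )
    base = {"REN": 5.0, "NOTCH1": 3.0, "NRARP": 8.0}
    base.update({t: 2.0 for t in TARGET_GENES})
    base.update({m: 30.0 for m in MITO_GENES})
    base.update({m: 1.5 for m in ENDOTHELIAL_MARKERS})
    base.update({m: 2.0 for m in MESANGIAL_MARKERS})
    base.update({h: 40.0 for h in HOUSEKEEPING})
    filler_means = np.clip(rng.lognormal(np.log(3.0), 0.6, size=config.n_filler_genes), 0.5, 30.0)
    for name, mu in zip(names[-config.n_filler_genes:], filler_means):
        base[name] = float(mu)
    return pd.DataFrame(
        {"base_mean": [base[n] for n in names], "mito": [n in MITO_GENES for n in names]},
        index=pd.Index(names, name="gene"),
    )


def _plant_target_ratio(
    counts: np.ndarray, target_rows, denominator_row: int, fold: float, scale: float = 1e4
) -> None:
    """Rescale planted target counts so each cell's log-normalized
    target/denominator ratio is ``fold`` times what its baseline draw
    would have produced.

    Works in place on the tumour columns. For a baseline draw ``x`` in a
    cell whose pre-planting scaling is ``s0 = scale / T0``, the
    replacement solves

        log1p(s*x') = fold * log1p(s0*x) * log1p(s*d) / log1p(s0*d)

    where ``d`` is the cell's denominator count and ``s`` the
    post-planting scaling (found by a damped fixed point over the cell
    totals). Dividing by the cell's realized denominator value then gives
    exactly ``fold`` times the cell's baseline ratio, so the planted fold
    is the estimand of the downstream statistic, not just an asymptotic
    approximation. Zero draws stay zero, preserving the >0 gating.
    """
    if fold == 1.0:
        return
    x0 = counts[target_rows].astype(float)
    den = counts[denominator_row].astype(float)
    other = counts.sum(axis=0).astype(float) - x0.sum(axis=0)
    log_s0 = np.log(scale) - np.log(other + x0.sum(axis=0))
    s0 = np.exp(log_s0)
    v0 = fold * np.log1p(s0 * x0)
    vd0 = np.log1p(s0 * den)

    def planted_for(s):
        correction = np.where(den > 0, np.log1p(s * den) / np.where(vd0 > 0, vd0, 1.0), 1.0)
        return np.expm1(v0 * correction) / s

    log_s = log_s0.copy()
    for _ in range(25):
        planted = planted_for(np.exp(log_s))
        log_s = 0.5 * (log_s + np.log(scale) - np.log(other + planted.sum(axis=0)))
    counts[target_rows] = np.rint(planted_for(np.exp(log_s))).astype(counts.dtype)


def simulate_counts(config: SimConfig) -> CountMatrix:
    """Negative-binomial genes x cells counts with planted cell-type
    effects, doublets (sums of two parents with high doublet scores) and
    low-quality cells (subsampled below the gene-count QC floor)."""
    if any(v <= 0 for v in config.cells_per_type.values()):
        raise ValueError("cells_per_type must all be positive")
    rng = np.random.default_rng(config.seed)
    panel = _gene_panel(config, rng)
    genes = panel.index
    base = panel["base_mean"].to_numpy()

    type_means = {
        "tumour": base.copy(),
        "mesangial": base.copy(),
        "endothelial": base.copy(),
    }
    gi = genes.get_loc
    type_means["tumour"][gi("REN")] *= config.ren_fold
    type_means["tumour"][gi("NOTCH1")] *= config.notch1_fold
    for m in MESANGIAL_MARKERS:
        type_means["mesangial"][gi(m)] *= 6.0
    for m in ENDOTHELIAL_MARKERS:
        type_means["endothelial"][gi(m)] *= 8.0

    alpha = config.nb_dispersion
    target_rows = genes.get_indexer(TARGET_GENES)

    def nb_draw(mu):
        mu = np.maximum(mu, 1e-9)
        n = 1.0 / alpha
        return rng.negative_binomial(n, n / (n + mu))

    blocks, meta = [], []
    for ctype, n_cells in config.cells_per_type.items():
        sizes = rng.lognormal(0.0, 0.1, size=n_cells)
        block = nb_draw(np.outer(type_means[ctype], sizes)).astype(np.int64)
        if ctype == "tumour":
            _plant_target_ratio(block, target_rows, gi("NRARP"), config.target_ratio_fold)
        blocks.append(block)
        meta.extend((ctype, ctype, float(sc)) for sc in rng.beta(1.2, 30.0, size=n_cells))
    singlets = np.concatenate(blocks, axis=1)

    n_singlets = singlets.shape[1]
    extra = []
    n_doublets = int(round(config.doublet_rate * n_singlets))
    for _ in range(n_doublets):
        i, j = rng.choice(n_singlets, size=2, replace=False)
        extra.append(singlets[:, i] + singlets[:, j])
        meta.append(("doublet", "doublet", float(rng.beta(8.0, 2.0))))

    n_lowq = int(round(config.lowq_rate * n_singlets))
    types = list(config.cells_per_type)
    for _ in range(n_lowq):
        ctype = types[int(rng.integers(len(types)))]
        full = nb_draw(type_means[ctype] * rng.lognormal(0.0, 0.1))
        extra.append(rng.binomial(full, 0.08))
        meta.append(("lowq", ctype, float(rng.beta(1.2, 30.0))))

    counts = np.concatenate([singlets] + ([np.column_stack(extra)] if extra else []), axis=1)
    order = rng.permutation(counts.shape[1])
    counts = counts[:, order]
    meta = [meta[i] for i in order]
    cells = pd.DataFrame(
        {
            "sample": "S1",
            "truth": [m[0] for m in meta],
            "label": [m[1] for m in meta],
            "doublet_score": [m[2] for m in meta],
        },
        index=pd.Index([f"CELL{i + 1:06d}" for i in range(counts.shape[1])], name="cell"),
    )
    return CountMatrix(counts=counts, genes=panel[["mito"]].copy(), cells=cells)


# ---------------------------------------------------------------------------
# fixture serialization
# ---------------------------------------------------------------------------

def write_fixtures(fixtures: dict, directory, seed: int | None = None) -> dict:
    """Write the provided objects as plain-text standard formats.

    Recognized keys: ``model`` (GFF3), ``sv_records`` (BEDPE),
    ``small_variants`` (TSV), ``coverage`` (TSV), ``counts``
    (MatrixMarket + barcodes/features TSV + cell metadata TSV),
    ``cn_segments`` (TSV), ``truth`` (JSON). Returns a manifest (also
    written as ``manifest.json``) listing the files and the seed.
    """
    from . import io as ntio

    os.makedirs(directory, exist_ok=True)
    files = {}

    def path(name):
        return os.path.join(directory, name)

    try:
        if "model" in fixtures:
            ntio.write_model(fixtures["model"], path("model.gff3"))
            files["model"] = "model.gff3"
        if "sv_records" in fixtures:
            ntio.write_bedpe(fixtures["sv_records"], path("sv.bedpe"))
            files["sv_records"] = "sv.bedpe"
        if "small_variants" in fixtures:
            ntio.write_variants_tsv(fixtures["small_variants"], path("variants.tsv"))
            files["small_variants"] = "variants.tsv"
        if "coverage" in fixtures:
            ntio.write_coverage_tsv(fixtures["coverage"], path("coverage.tsv"))
            files["coverage"] = "coverage.tsv"
        if "cn_segments" in fixtures:
            ntio.write_cn_tsv(fixtures["cn_segments"], path("cn.tsv"))
            files["cn_segments"] = "cn.tsv"
        if "counts" in fixtures:
            ntio.write_counts(fixtures["counts"], directory)
            files["counts"] = "matrix.mtx"
        if "truth" in fixtures:
            with open(path("truth.json"), "w") as fh:
                json.dump(fixtures["truth"], fh, indent=2, sort_keys=True)
            files["truth"] = "truth.json"
    except OSError as exc:
        raise OSError(f"failed writing fixtures under {directory}: {exc}") from exc

    manifest = {"seed": seed, "files": files}
    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
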
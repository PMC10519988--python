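"""Breakpoint-to-domain consequence classification and driver annotation.

Maps structural-variant breakends onto a gene/domain model, detects
activating truncations of a NOTCH1-class gene (extracellular regulatory
region lost, intracellular signalling domain retained), reports whether the
transmembrane exon was spared (which decides gamma-secretase targetability),
annotates disruption of a negative-regulator gene, and applies rule-based
driver calling over small variants, copy-number segments and rearrangements.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genemodel import ECD, ICD, TM, GeneModel, LocusContext
from .variant_filters import VariantRecord

__all__ = [
    "BreakpointPair",
    "ConsequenceCall",
    "CopyNumberSegment",
    "CancerGeneEntry",
    "DriverCall",
    "locate_breakpoint",
    "classify_truncation",
    "annotate_regulator",
    "call_drivers",
    "FOCAL_MAX_BP",
    "AMP_CN_DIPLOID",
    "AMP_CN_TETRAPLOID",
]

SV_CLASSES = ("deletion", "inversion", "tandem-dup", "translocation")

FOCAL_MAX_BP = 1_000_000
AMP_CN_DIPLOID = 4
AMP_CN_TETRAPLOID = 8


@dataclass(frozen=True)
class BreakpointPair:
    """Two breakends; the unit of SV consequence annotation."""

    id: str
    contig: str
    pos_a: int
    pos_b: int
    sv_class: str
    orient_a: str = "+"
    orient_b: str = "-"
    cluster: str | None = None
    contig_b: str | None = None  # for translocations; defaults to contig

    def __post_init__(self):
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown sv_class {self.sv_class!r}")
        same_contig = self.contig_b is None or self.contig_b == self.contig
        if self.sv_class in ("deletion", "inversion"):
            if not same_contig:
                raise ValueError(f"{self.id}: {self.sv_class} breakends on two contigs")
            if not self.pos_a < self.pos_b:
                raise ValueError(f"{self.id}: requires pos_a < pos_b")

    @property
    def interval(self) -> tuple[int, int]:
        """Genomic interval spanned (deletion/inversion/tandem-dup)."""
        return (self.pos_a, self.pos_b)


@dataclass(frozen=True)
class ConsequenceCall:
    gene: str
    category: str  # activating_truncation | regulator_promoter_hit |
    #                regulator_whole_gene_deleted | intragenic_inversion |
    #                intergenic | intact | other
    retained_domains: tuple[str, ...] = ()
    tm_status: str = "unknown"  # spared | involved | unknown
    targetability: str = "none"  # gamma_secretase_candidate |
    #                              transcription_complex_candidate | none

    def __post_init__(self):
        if self.tm_status == "spared" and self.targetability != "gamma_secretase_candidate":
            raise ValueError("tm_status=spared requires gamma_secretase_candidate")
        if (
            self.category == "activating_truncation"
            and self.tm_status in ("involved", "unknown")
            and self.targetability != "transcription_complex_candidate"
        ):
            raise ValueError(
                "activating truncation with TM involved/unknown requires "
                "transcription_complex_candidate"
            )


@dataclass(frozen=True)
class CopyNumberSegment:
    contig: str
    start: int
    end: int
    total_cn: float
    sample: str = "tumour"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CancerGeneEntry:
    gene: str
    role: str  # oncogene | recessive
    hotspots: tuple[int, ...] = ()

    def __post_init__(self):
        if self.role not in ("oncogene", "recessive"):
            raise ValueError(f"{self.gene}: unknown role {self.role!r}")


@dataclass(frozen=True)
class DriverCall:
    source_id: str
    gene: str
    rule: str


def locate_breakpoint(model: GeneModel, position: int, contig: str | None = None) -> LocusContext:
    """Locus context of one breakend (thin wrapper over the model index)."""
    return model.locate(position, contig=contig)


def _overlaps(iv: tuple[int, int], lo: int, hi: int) -> bool:
    return iv[0] < hi and lo < iv[1]


def _contains(iv: tuple[int, int], lo: int, hi: int) -> bool:
    return iv[0] <= lo and hi <= iv[1]


def _cluster_breakends(cluster):
    for bp in cluster:
        yield bp, bp.pos_a
        yield bp, bp.pos_b


def classify_truncation(
    model: GeneModel, cluster: list[BreakpointPair], gene: str = "NOTCH1"
) -> ConsequenceCall:
    """Classify a breakpoint cluster against a NOTCH1-class gene.

    An activating truncation requires a deletion breakend inside the
    extracellular (regulatory) region with every intracellular exon left on
    the retained allele. The transmembrane exon is "spared" only when
    neither it nor its two flanking introns are touched by any cluster
    member; an inversion bracketing it leaves the status "unknown".
    """
    if not cluster:
        raise ValueError("empty breakpoint cluster")
    g = model[gene]
    tm_exons = g.domain_exons(TM)
    if len(tm_exons) != 1:
        raise ValueError(f"{gene}: expected exactly one TM exon, found {len(tm_exons)}")
    tm = tm_exons[0]

    contexts = [
        (bp, pos, model.locate(pos, contig=bp.contig)) for bp, pos in _cluster_breakends(cluster)
    ]
    deletions = [bp for bp in cluster if bp.sv_class == "deletion"]
    inversions = [bp for bp in cluster if bp.sv_class == "inversion"]

    def in_ecd_region(ctx: LocusContext) -> bool:
        if ctx.gene != gene:
            return False
        if ctx.feature == "exon":
            return ctx.domain == ECD
        if ctx.feature == "intron":
            return ctx.index < tm.index  # introns 1..tm-1 lie 5' of the TM exon
        return False

    icd_exons = g.domain_exons(ICD)
    truncating = None
    for d in deletions:
        ends_in_ecd = any(
            in_ecd_region(model.locate(p, contig=d.contig)) for p in (d.pos_a, d.pos_b)
        )
        keeps_icd = not any(_overlaps(d.interval, e.start, e.end) for e in icd_exons)
        if ends_in_ecd and keeps_icd:
            truncating = d
            break

    # transmembrane status over the whole cluster
    tm_status = "spared"
    flank_intervals = [(tm.start, tm.end)]
    if tm.index > 1:
        flank_intervals.append(g.intron_interval(tm.index - 1))
    if tm.index < len(g.exons):
        flank_intervals.append(g.intron_interval(tm.index))
    if any(
        _overlaps(d.interval, tm.start, tm.end) for d in deletions
    ):
        tm_status = "involved"
    elif any(
        lo <= pos < hi
        for _, pos, _ in contexts
        for lo, hi in flank_intervals
    ):
        tm_status = "unknown"

    in_gene = [ctx for _, _, ctx in contexts if ctx.gene == gene and not ctx.in_promoter]

    if truncating is not None:
        retained = tuple(
            sorted(
                {
                    e.domain
                    for e in g.exons
                    if e.domain != "none"
                    and not any(_overlaps(d.interval, e.start, e.end) for d in deletions)
                },
                key=[ECD, TM, ICD].index,
            )
        )
        if tm_status == "spared":
            target = "gamma_secretase_candidate"
        else:
            target = "transcription_complex_candidate"
        return ConsequenceCall(gene, "activating_truncation", retained, tm_status, target)

    if inversions and any(
        model.locate(p, contig=iv.contig).gene == gene
        for iv in inversions
        for p in (iv.pos_a, iv.pos_b)
    ):
        status = tm_status if tm_status != "spared" else "unknown"
        return ConsequenceCall(gene, "intragenic_inversion", (), status, "none")

    if not in_gene:
        return ConsequenceCall(gene, "intergenic", (), "unknown", "none")
    return ConsequenceCall(gene, "other", (), "unknown", "none")


def annotate_regulator(
    model: GeneModel, cluster: list[BreakpointPair], regulator: str = "NRARP"
) -> ConsequenceCall:
    """Negative-regulator disruption: whole-gene deletion beats promoter hit."""
    if regulator not in model.genes:
        raise ValueError(f"regulator gene {regulator!r} absent from model")
    g = model[regulator]
    deletions = [bp for bp in cluster if bp.sv_class == "deletion"]
    if any(_contains(d.interval, g.start, g.end) for d in deletions):
        return ConsequenceCall(regulator, "regulator_whole_gene_deleted", (), "unknown", "none")
    if any(g.in_promoter(pos) for _, pos in _cluster_breakends(cluster)):
        return ConsequenceCall(regulator, "regulator_promoter_hit", (), "unknown", "none")
    return ConsequenceCall(regulator, "intact", (), "unknown", "none")


_TRUNCATING_EFFECTS = frozenset({"truncating", "nonsense", "frameshift", "splice"})


def call_drivers(
    model: GeneModel,
    variants: list[VariantRecord],
    cn_segments: list[CopyNumberSegment],
    gene_table: list[CancerGeneEntry],
    ploidy: str = "diploid",
    fusions: set[frozenset] | None = None,
) -> list[DriverCall]:
    """Rule-based driver annotation.

    Drivers are: missense/in-frame indels at oncogene hotspots; truncating
    small variants inside a recessive-gene footprint; focal (<1 Mb)
    homozygous deletions over recessive genes; focal amplifications with
    copy number >4 (diploid) or >8 (tetraploid) over oncogenes; and
    rearrangements that produce a listed fusion or break inside a
    recessive-gene footprint.
    """
    if ploidy not in ("diploid", "tetraploid"):
        raise ValueError(f"unknown ploidy context {ploidy!r}")
    amp_threshold = AMP_CN_DIPLOID if ploidy == "diploid" else AMP_CN_TETRAPLOID
    by_gene = {e.gene: e for e in gene_table}
    fusions = fusions or set()
    drivers: list[DriverCall] = []

    for v in variants:
        if v.variant_class == "rearrangement":
            bp = v.breakpoints
            if bp is None:
                continue
            genes_hit = []
            for pos in (bp.pos_a, bp.pos_b):
                ctx = model.locate(pos, contig=bp.contig)
                if ctx.gene is not None and not ctx.in_promoter:
                    genes_hit.append(ctx.gene)
            if len(genes_hit) == 2 and frozenset(genes_hit) in fusions:
                drivers.append(DriverCall(v.id, "+".join(sorted(genes_hit)), "oncogenic_fusion"))
                continue
            for name in genes_hit:
                entry = by_gene.get(name)
                if entry is not None and entry.role == "recessive":
                    drivers.append(DriverCall(v.id, name, "recessive_sv_disruption"))
                    break
            continue
        if v.position is None:
            continue
        ctx = model.locate(v.position, contig=v.contig)
        if ctx.gene is None:
            continue
        entry = by_gene.get(ctx.gene)
        if entry is None:
            continue
        if (
            entry.role == "oncogene"
            and v.effect in ("missense", "inframe_indel")
            and v.position in entry.hotspots
        ):
            drivers.append(DriverCall(v.id, ctx.gene, "oncogene_hotspot"))
        elif entry.role == "recessive" and v.effect in _TRUNCATING_EFFECTS:
            g = model[ctx.gene]
            if g.start <= v.position < g.end:
                drivers.append(DriverCall(v.id, ctx.gene, "recessive_truncation"))

    for i, seg in enumerate(cn_segments):
        if seg.length >= FOCAL_MAX_BP:
            continue
        for entry in gene_table:
            if entry.gene not in model.genes:
                continue
            g = model[entry.gene]
            if not _overlaps((seg.start, seg.end), g.start, g.end):
                continue
            seg_id = f"cn{i}"
            if seg.total_cn == 0 and entry.role == "recessive":
                drivers.append(DriverCall(seg_id, entry.gene, "homozygous_deletion"))
            elif seg.total_cn > amp_threshold and entry.role == "oncogene":
                drivers.append(DriverCall(seg_id, entry.gene, "focal_amplification"))
    return drivers
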
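"""Gene/exon/domain models on a toy contig.

Internal coordinates are 0-based half-open throughout; GFF3 serialization
converts to 1-based inclusive at the boundary. Exons are stored in transcript
order (exon 1 = transcript 5' end), so on the minus strand genomic starts
strictly decrease with exon index. Intron ``k`` lies between transcript-ordered
exons ``k`` and ``k + 1``. The promoter window extends upstream of the
transcription start site in transcript orientation.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace

__all__ = [
    "Exon",
    "Gene",
    "GeneModel",
    "LocusContext",
    "DEFAULT_PROMOTER_LENGTH",
]

DEFAULT_PROMOTER_LENGTH = 2_000

ECD = "ECD"
TM = "TM"
ICD = "ICD"
NO_DOMAIN = "none"


@dataclass(frozen=True)
class Exon:
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    index: int  # 1-based transcript order
    domain: str = NO_DOMAIN

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"exon {self.index}: end {self.end} <= start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Gene:
    name: str
    contig: str
    strand: str  # "+" or "-"
    exons: tuple[Exon, ...]  # transcript order
    promoter: tuple[int, int]  # 0-based half-open

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        idx = [e.index for e in self.exons]
        if idx != list(range(1, len(self.exons) + 1)):
            raise ValueError(f"{self.name}: exon indices not contiguous from 1: {idx}")
        starts = [e.start for e in self.exons]
        if self.strand == "+":
            if sorted(starts) != starts:
                raise ValueError(f"{self.name}: + strand exons not genomically increasing")
        else:
            if sorted(starts, reverse=True) != starts:
                raise ValueError(f"{self.name}: - strand exons not genomically decreasing")

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def tss(self) -> int:
        """Transcription start position (0-based base of the first exon)."""
        first = self.exons[0]
        return first.start if self.strand == "+" else first.end - 1

    def exon_by_index(self, index: int) -> Exon:
        return self.exons[index - 1]

    def intron_interval(self, k: int) -> tuple[int, int]:
        """Genomic interval of intron k (between transcript exons k, k+1)."""
        if not 1 <= k < len(self.exons):
            raise ValueError(f"{self.name}: no intron {k}")
        a, b = self.exons[k - 1], self.exons[k]
        if self.strand == "+":
            return (a.end, b.start)
        return (b.end, a.start)

    def in_promoter(self, pos: int) -> bool:
        return self.promoter[0] <= pos < self.promoter[1]

    def domain_exons(self, domain: str) -> list[Exon]:
        return [e for e in self.exons if e.domain == domain]

    def mirrored(self, contig_length: int) -> "Gene":
        """Reflect the gene around the contig midpoint, flipping strand."""
        exons = tuple(
            replace(e, start=contig_length - e.end, end=contig_length - e.start)
            for e in self.exons
        )
        p0, p1 = self.promoter
        return Gene(
            name=self.name,
            contig=self.contig,
            strand="-" if self.strand == "+" else "+",
            exons=exons,
            promoter=(contig_length - p1, contig_length - p0),
        )


@dataclass(frozen=True)
class LocusContext:
    """Where a single genomic position lands relative to the model."""

    gene: str | None
    feature: str  # "exon" | "intron" | "promoter" | "intergenic"
    index: int | None  # exon or intron number, else None
    domain: str
    in_promoter: bool


@dataclass
class GeneModel:
    contig: str
    contig_length: int
    genes: dict[str, Gene] = field(default_factory=dict)

    def __post_init__(self):
        self._index: list[tuple[int, int, str]] | None = None

    def add(self, gene: Gene) -> None:
        if gene.contig != self.contig:
            raise ValueError(f"gene {gene.name} on {gene.contig}, model on {self.contig}")
        self.genes[gene.name] = gene
        self._index = None

    def __getitem__(self, name: str) -> Gene:
        return self.genes[name]

    def _build_index(self) -> list[tuple[int, int, str]]:
        # sorted, non-overlapping footprint/promoter intervals for bisect lookup
        ivals: list[tuple[int, int, str]] = []
        for g in self.genes.values():
            ivals.append((g.start, g.end, g.name))
            ivals.append((g.promoter[0], g.promoter[1], g.name))
        ivals.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping features {n1} [{s1},{e1}) and {n2} [{s2},{e2})"
                )
        self._index = ivals
        return ivals

    def locate(self, pos: int, contig: str | None = None) -> LocusContext:
        """Map a genomic position to its unique locus context."""
        if contig is not None and contig != self.contig:
            raise ValueError(f"contig {contig!r} not in model (have {self.contig!r})")
        ivals = self._index if self._index is not None else self._build_index()
        i = bisect_right(ivals, (pos, self.contig_length + 1, "￿")) - 1
        if i >= 0:
            s, e, name = ivals[i]
            if s <= pos < e:
                gene = self.genes[name]
                if gene.in_promoter(pos):
                    return LocusContext(name, "promoter", None, NO_DOMAIN, True)
                for exon in gene.exons:
                    if exon.contains(pos):
                        return LocusContext(name, "exon", exon.index, exon.domain, False)
                for k in range(1, len(gene.exons)):
                    lo, hi = gene.intron_interval(k)
                    if lo <= pos < hi:
                        return LocusContext(name, "intron", k, NO_DOMAIN, False)
                raise AssertionError(f"position {pos} inside {name} footprint but unplaced")
        return LocusContext(None, "intergenic", None, NO_DOMAIN, False)

    def mirrored(self) -> "GeneModel":
        """Strand-mirrored model: every feature reflected, strands flipped."""
        m = GeneModel(self.contig, self.contig_length)
        for g in self.genes.values():
            m.add(g.mirrored(self.contig_length))
        return m

    def mirror_position(self, pos: int) -> int:
        """Position of ``pos`` after mirroring (reflection of a single base)."""
        return self.contig_length - 1 - pos


# ---------------------------------------------------------------------------
# GFF3 serialization (1-based inclusive at the boundary)
# ---------------------------------------------------------------------------

def write_gff3(model: GeneModel, path) -> None:
    lines = ["##gff-version 3", f"##sequence-region {model.contig} 1 {model.contig_length}"]
    for g in model.genes.values():
        gid = f"gene:{g.name}"
        lines.append(
            "\t".join(
                [
                    model.contig,
                    "notchtrunc",
                    "gene",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    f"ID={gid};Name={g.name}",
                ]
            )
        )
        p0, p1 = g.promoter
        lines.append(
            "\t".join(
                [
                    model.contig,
                    "notchtrunc",
                    "promoter",
                    str(p0 + 1),
                    str(p1),
                    ".",
                    g.strand,
                    ".",
                    f"ID=promoter:{g.name};Parent={gid}",
                ]
            )
        )
        for e in g.exons:
            lines.append(
                "\t".join(
                    [
                        model.contig,
                        "notchtrunc",
                        "exon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID=exon:{g.name}:{e.index};Parent={gid};"
                        f"exon_index={e.index};domain={e.domain}",
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _attrs(col: str) -> dict[str, str]:
    out = {}
    for part in col.strip().split(";"):
        if part:
            k, _, v = part.partition("=")
            out[k] = v
    return out


def read_gff3(path) -> GeneModel:
    contig = None
    contig_length = 0
    gene_rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, contig, _, end = line.split()
                contig_length = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            seqid, _, ftype, start, end, _, strand, _, attr_col = line.split("\t")
            attrs = _attrs(attr_col)
            start0, end0 = int(start) - 1, int(end)
            if ftype == "gene":
                gene_rows[attrs["Name"]] = {
                    "contig": seqid,
                    "strand": strand,
                    "exons": [],
                    "promoter": None,
                }
            elif ftype == "promoter":
                name = attrs["Parent"].split(":", 1)[1]
                gene_rows[name]["promoter"] = (start0, end0)
            elif ftype == "exon":
                name = attrs["Parent"].split(":", 1)[1]
                gene_rows[name]["exons"].append(
                    Exon(start0, end0, int(attrs["exon_index"]), attrs["domain"])
                )
    if contig is None:
        raise ValueError(f"{path}: missing ##sequence-region directive")
    model = GeneModel(contig, contig_length)
    for name, row in gene_rows.items():
        exons = tuple(sorted(row["exons"], key=lambda e: e.index))
        model.add(
            Gene(
                name=name,
                contig=row["contig"],
                strand=row["strand"],
                exons=exons,
                promoter=row["promoter"],
            )
        )
    return model
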
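"""Post-calling quality filters for somatic substitution, indel and
rearrangement records.

Rules (names used in reports):

* ``asmd`` — substitutions need a median supporting-read alignment score
  of at least 140.
* ``clpm`` — substitutions need a clipped-read metric of exactly 0. The
  upstream description also speaks of "fewer than half of the reads";
  the operational threshold used here is the exact-zero one, and the
  discrepancy is deliberately resolved in favour of the parenthetical.
* ``indel_quality`` — indels need a quality score of at least 300.
* ``sv_support`` — rearrangements need either an assembly score (presence
  suffices, no minimum value) or at least 4 supporting reads in tumour
  samples / 25 in normal samples.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "VariantRecord",
    "Verdict",
    "FilterReport",
    "filter_substitution",
    "filter_indel",
    "filter_rearrangement",
    "apply_filters",
    "ASMD_MIN",
    "INDEL_QUALITY_MIN",
    "SV_MIN_READS_TUMOUR",
    "SV_MIN_READS_NORMAL",
]

ASMD_MIN = 140.0
INDEL_QUALITY_MIN = 300.0
SV_MIN_READS_TUMOUR = 4
SV_MIN_READS_NORMAL = 25

VARIANT_CLASSES = ("substitution", "indel", "rearrangement")


class MissingFieldError(ValueError):
    """A record lacks a field its filter rule needs."""

    def __init__(self, record_id: str, field_name: str):
        self.field_name = field_name
        super().__init__(f"record {record_id!r}: missing required field {field_name!r}")


@dataclass
class VariantRecord:
    """One somatic call with the quality fields the filters inspect."""

    id: str
    variant_class: str  # substitution | indel | rearrangement
    contig: str | None = None
    position: int | None = None
    asmd: float | None = None
    clpm: float | None = None
    quality: float | None = None
    assembly_score: float | None = None
    supporting_reads: int | None = None
    sample_type: str | None = None  # tumour | normal
    breakpoints: object | None = None  # BreakpointPair for rearrangements
    effect: str | None = None  # missense | inframe_indel | truncating | ...
    gene: str | None = None
    truth: str | None = None

    def __post_init__(self):
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if self.supporting_reads is not None and self.supporting_reads < 0:
            raise ValueError(f"record {self.id!r}: supporting_reads < 0")


@dataclass(frozen=True)
class Verdict:
    record_id: str
    passed: bool
    failed_rules: tuple[str, ...] = ()

    def __post_init__(self):
        # pass <=> no failed rule
        if self.passed != (len(self.failed_rules) == 0):
            raise ValueError("verdict inconsistent with failed-rule list")


def _require(record: VariantRecord, *fields: str):
    for name in fields:
        if getattr(record, name) is None:
            raise MissingFieldError(record.id, name)


def filter_substitution(record: VariantRecord) -> Verdict:
    if record.variant_class != "substitution":
        raise ValueError(f"record {record.id!r} is not a substitution")
    _require(record, "asmd", "clpm")
    failed = []
    if record.asmd < ASMD_MIN:
        failed.append("asmd")
    if record.clpm != 0:
        failed.append("clpm")
    return Verdict(record.id, not failed, tuple(failed))


def filter_indel(record: VariantRecord) -> Verdict:
    if record.variant_class != "indel":
        raise ValueError(f"record {record.id!r} is not an indel")
    _require(record, "quality")
    failed = [] if record.quality >= INDEL_QUALITY_MIN else ["indel_quality"]
    return Verdict(record.id, not failed, tuple(failed))


def filter_rearrangement(record: VariantRecord) -> Verdict:
    if record.variant_class != "rearrangement":
        raise ValueError(f"record {record.id!r} is not a rearrangement")
    _require(record, "sample_type")
    if record.sample_type not in ("tumour", "normal"):
        raise ValueError(f"record {record.id!r}: unknown sample_type {record.sample_type!r}")
    if record.assembly_score is not None:
        return Verdict(record.id, True)
    reads = record.supporting_reads or 0
    minimum = SV_MIN_READS_TUMOUR if record.sample_type == "tumour" else SV_MIN_READS_NORMAL
    failed = [] if reads >= minimum else ["sv_support"]
    return Verdict(record.id, not failed, tuple(failed))


_DISPATCH = {
    "substitution": filter_substitution,
    "indel": filter_indel,
    "rearrangement": filter_rearrangement,
}


@dataclass
class FilterReport:
    verdicts: list[Verdict]
    rule_counts: Counter = field(default_factory=Counter)

    @property
    def n_total(self) -> int:
        return len(self.verdicts)

    @property
    def n_pass(self) -> int:
        return sum(v.passed for v in self.verdicts)

    @property
    def n_fail(self) -> int:
        return self.n_total - self.n_pass

    def verdict_for(self, record_id: str) -> Verdict:
        for v in self.verdicts:
            if v.record_id == record_id:
                return v
        raise KeyError(record_id)


def apply_filters(records: list[VariantRecord]) -> FilterReport:
    """Dispatch each record to its class filter; totals equal input count."""
    if not records:
        raise ValueError("apply_filters requires a non-empty record list")
    verdicts = []
    counts: Counter = Counter()
    for rec in records:
        try:
            fn = _DISPATCH[rec.variant_class]
        except KeyError:
            raise ValueError(f"unknown variant class {rec.variant_class!r}") from None
        v = fn(rec)
        verdicts.append(v)
        counts.update(v.failed_rules)
    return FilterReport(verdicts=verdicts, rule_counts=counts)
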
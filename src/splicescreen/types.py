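"""Core domain types shared across the package.

Coordinate convention: a splice junction is the excised intron, stored as
1-based inclusive endpoints of the first and last intronic base.  Exon
coordinates arriving from event tables (0-based start, 1-based end) are
converted at read time so that every module joins on one canonical key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

EVENT_TYPES = ("SE", "A5SS", "A3SS", "RI")
STRANDS = ("+", "-", ".")


class SpliceJunction(NamedTuple):
    """A genomic intron interval; the atomic unit of counting and testing."""

    chrom: str
    start: int  # first intronic base, 1-based inclusive
    end: int  # last intronic base, 1-based inclusive
    strand: str

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def from_key(cls, key: str) -> "SpliceJunction":
        chrom, span, strand = key.rsplit(":", 2)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end), strand)

    def validate(self) -> None:
        if self.start > self.end:
            raise ValueError(f"junction start > end: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class ASEvent:
    """A binary alternative-splicing event linking the junctions of its two
    isoforms.

    ``coords`` holds the exon coordinates of the source table row
    (0-based starts, 1-based ends, per the event-table dialect) keyed by
    column name; junction tuples are derived from them once, at read time.
    For RI events the "inclusion" (retained) isoform carries two
    single-base boundary pseudo-junctions at the first and last intronic
    base, used for junction presence testing of the retained isoform.
    """

    event_id: str
    event_type: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    coords: dict = field(compare=False, repr=False)
    inclusion_junctions: tuple
    skipping_junctions: tuple

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if set(self.inclusion_junctions) & set(self.skipping_junctions):
            raise ValueError(f"{self.event_id}: isoform junction sets overlap")
        for j in self.junctions():
            j.validate()
            if j.chrom != self.chrom or j.strand != self.strand:
                raise ValueError(f"{self.event_id}: junction {j} on wrong chrom/strand")

    def junctions(self) -> tuple:
        return tuple(self.inclusion_junctions) + tuple(self.skipping_junctions)

    def isoform_junctions(self, isoform: str) -> tuple:
        if isoform == "inclusion":
            return tuple(self.inclusion_junctions)
        if isoform == "skipping":
            return tuple(self.skipping_junctions)
        raise ValueError(f"unknown isoform {isoform!r}")

    @property
    def alt_exon_length(self) -> int | None:
        """Length (nt) of the alternative exon; defined for SE events."""
        if self.event_type != "SE":
            return None
        return int(self.coords["exonEnd"]) - int(self.coords["exonStart_0base"])


@dataclass
class SampleGroup:
    """A named cohort of samples with a role in the screen design."""

    group_id: str
    role: str  # tumor_query | normal_reference | tumor_reference
    sample_ids: list
    total_mapped_reads: dict  # sample_id -> int R, for CPM normalization

    ROLES = ("tumor_query", "normal_reference", "tumor_reference")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValueError(f"unknown role {self.role!r} for group {self.group_id}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"duplicate sample ids in group {self.group_id}")
        if not self.sample_ids:
            raise ValueError(f"group {self.group_id} has no samples")
        for sid in self.sample_ids:
            r = self.total_mapped_reads.get(sid)
            if r is not None and r <= 0:
                raise ValueError(f"non-positive total_mapped_reads for {sid}")
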
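"""Translate splice junctions of tumor-enriched isoforms into short
junction-spanning peptides using annotated reading frames.

The reading frame at a junction is taken from a coding transcript whose
CDS covers the exonic base immediately upstream (in transcription order)
of the junction.  The peptide window is at most 21 residues: up to 10
full codons of upstream sequence, the split codon when the junction falls
inside a codon, and downstream codons to fill the window.  Translation
stops at the first stop codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

from .types import ASEvent, SpliceJunction

log = logging.getLogger(__name__)

DEFAULT_WINDOW_AA = 21
MICROEXON_MAX_NT = 30
UPSTREAM_CODONS = 10


@dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list  # [(start, end)] 1-based inclusive, genomic order
    cds: list  # [(start, end)] 1-based inclusive, genomic order
    protein_id: str | None = None

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    chrom: str
    transcripts: list = field(default_factory=list)


@dataclass
class FrameAssignment:
    junction: SpliceJunction
    transcript_id: str
    protein_id: str | None
    phase: int  # nt of the junction-spanning codon lying upstream (0/1/2)
    coding_offset: int  # coding nt from CDS start through the upstream flank base
    upstream_avail_nt: int  # CDS nt available upstream of the junction in that exon


@dataclass
class JunctionPeptide:
    event_id: str
    isoform: str  # inclusion | skipping
    sequence: str
    junction_position: int  # 1-based residue whose codon spans/abuts the junction
    flags: set = field(default_factory=set)
    transcript_id: str | None = None
    protein_id: str | None = None
    protein_start: int | None = None  # 1-based residue interval on the source protein
    protein_end: int | None = None

    def __post_init__(self) -> None:
        if "*" in self.sequence:
            raise ValueError("peptide sequence contains a stop symbol")


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

def load_gene_models(gtf_path: str | Path,
                     protein_map: dict | None = None) -> dict:
    """Parse a GTF into :class:`GeneModel` objects keyed by gene_id.

    ``protein_map`` optionally maps transcript_id to protein_id, overriding
    any ``protein_id`` attribute present in the GTF.
    """
    db = gffutils.create_db(
        str(gtf_path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique", keep_order=True,
    )
    models: dict[str, GeneModel] = {}
    for tr in db.features_of_type("transcript"):
        gene_id = tr.attributes["gene_id"][0]
        model = models.setdefault(
            gene_id, GeneModel(gene_id=gene_id, strand=tr.strand,
                               chrom=tr.seqid))
        exons = sorted((f.start, f.end)
                       for f in db.children(tr, featuretype="exon"))
        cds = sorted((f.start, f.end)
                     for f in db.children(tr, featuretype="CDS"))
        protein_id = None
        if "protein_id" in tr.attributes:
            protein_id = tr.attributes["protein_id"][0]
        if protein_map and tr.id in protein_map:
            protein_id = protein_map[tr.id]
        model.transcripts.append(Transcript(
            transcript_id=tr.id, strand=tr.strand, exons=exons, cds=cds,
            protein_id=protein_id))
    return models


def load_protein_map(path: str | Path) -> dict:
    """Two-column TSV (transcript_id, protein_id), with optional header."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if fields[0] == "transcript_id":
            continue
        out[fields[0]] = fields[1]
    return out


def load_genome(fasta_path: str | Path) -> Fasta:
    return Fasta(str(fasta_path), sequence_always_upper=True)


# ---------------------------------------------------------------------------
# frame resolution
# ---------------------------------------------------------------------------

def upstream_flank_base(junction: SpliceJunction) -> int:
    """Genomic position of the exonic base immediately 5' (in transcription
    order) of the junction."""
    return junction.start - 1 if junction.strand == "+" else junction.end + 1


def resolve_reading_frame(
    junction: SpliceJunction,
    gene_models: dict,
) -> FrameAssignment | None:
    """Pick the coding transcript whose CDS contains the upstream exonic
    flank base and compute the phase at the junction.

    Ties break deterministically: longest CDS first, then lexicographic
    transcript id.  Returns None when no annotated frame covers the flank.
    """
    flank = upstream_flank_base(junction)
    candidates = []
    for model in gene_models.values():
        if model.chrom != junction.chrom or model.strand != junction.strand:
            continue
        for tr in model.transcripts:
            if not tr.cds:
                continue
            containing = [iv for iv in tr.cds if iv[0] <= flank <= iv[1]]
            if containing:
                candidates.append((tr, containing[0]))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0].cds_length, c[0].transcript_id))
    tr, flank_iv = candidates[0]

    if junction.strand == "+":
        coding_offset = sum(min(e, flank) - s + 1
                            for s, e in tr.cds if s <= flank)
        avail = flank - flank_iv[0] + 1
    else:
        coding_offset = sum(e - max(s, flank) + 1
                            for s, e in tr.cds if e >= flank)
        avail = flank_iv[1] - flank + 1
    return FrameAssignment(
        junction=junction,
        transcript_id=tr.transcript_id,
        protein_id=tr.protein_id,
        phase=coding_offset % 3,
        coding_offset=coding_offset,
        upstream_avail_nt=avail,
    )


# ---------------------------------------------------------------------------
# sequence assembly
# ---------------------------------------------------------------------------

def _fetch(genome: Fasta, chrom: str, start: int, end: int, strand: str) -> str:
    """1-based inclusive fetch on the coding strand."""
    seq = genome[chrom][start - 1:end].seq.upper()
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _downstream_segments(event: ASEvent, isoform: str) -> list[tuple]:
    """Genomic intervals (1-based inclusive) downstream of the translated
    junction, in transcription order."""
    c = event.coords
    strand = event.strand
    if event.event_type == "SE":
        alt = (c["exonStart_0base"] + 1, c["exonEnd"])
        flanks = sorted([(c["upstreamES"] + 1, c["upstreamEE"]),
                         (c["downstreamES"] + 1, c["downstreamEE"])])
        down_flank = flanks[1] if strand == "+" else flanks[0]
        if isoform == "inclusion":
            return [alt, down_flank]
        return [down_flank]
    if event.event_type in ("A5SS", "A3SS"):
        long_iv = (c["longExonStart_0base"] + 1, c["longExonEnd"])
        short_iv = (c["shortES"] + 1, c["shortEE"])
        flank_iv = (c["flankingES"] + 1, c["flankingEE"])
        j = event.inclusion_junctions[0] if isoform == "inclusion" \
            else event.skipping_junctions[0]
        # the downstream segment is whichever annotated interval starts just
        # after the junction in transcription order
        for iv in (flank_iv, long_iv, short_iv):
            if strand == "+" and iv[0] == j.end + 1:
                return [iv]
            if strand == "-" and iv[1] == j.start - 1:
                return [iv]
        return []
    if event.event_type == "RI":
        flanks = sorted([(c["upstreamES"] + 1, c["upstreamEE"]),
                         (c["downstreamES"] + 1, c["downstreamEE"])])
        left, right = flanks
        if isoform == "inclusion":
            # read-through: intron and the next exon are genomically contiguous
            if strand == "+":
                return [(left[1] + 1, right[1])]
            return [(left[0], right[0] - 1)]
        down_flank = right if strand == "+" else left
        return [down_flank]
    raise ValueError(f"unsupported event type {event.event_type}")


def _upstream_segment(event: ASEvent, isoform: str) -> tuple:
    """Genomic interval of the exon 5' of the translated junction."""
    c = event.coords
    strand = event.strand
    if event.event_type == "SE":
        flanks = sorted([(c["upstreamES"] + 1, c["upstreamEE"]),
                         (c["downstreamES"] + 1, c["downstreamEE"])])
        return flanks[0] if strand == "+" else flanks[1]
    if event.event_type in ("A5SS", "A3SS"):
        long_iv = (c["longExonStart_0base"] + 1, c["longExonEnd"])
        short_iv = (c["shortES"] + 1, c["shortEE"])
        flank_iv = (c["flankingES"] + 1, c["flankingEE"])
        j = event.inclusion_junctions[0] if isoform == "inclusion" \
            else event.skipping_junctions[0]
        for iv in (long_iv, short_iv, flank_iv):
            if strand == "+" and iv[1] == j.start - 1:
                return iv
            if strand == "-" and iv[0] == j.end + 1:
                return iv
        raise ValueError(f"{event.event_id}: no exon abuts the junction")
    if event.event_type == "RI":
        flanks = sorted([(c["upstreamES"] + 1, c["upstreamEE"]),
                         (c["downstreamES"] + 1, c["downstreamEE"])])
        return flanks[0] if strand == "+" else flanks[1]
    raise ValueError(f"unsupported event type {event.event_type}")


def translated_junction(event: ASEvent, isoform: str) -> SpliceJunction:
    """The junction the peptide is centered on: the transcription-first
    junction of the isoform."""
    juncs = event.isoform_junctions(isoform)
    if event.event_type == "RI" and isoform == "inclusion":
        # retained isoform: center on the 5' exon-intron border pseudo-junction
        return min(juncs, key=lambda j: j.start) if event.strand == "+" \
            else max(juncs, key=lambda j: j.end)
    return min(juncs, key=lambda j: j.start) if event.strand == "+" \
        else max(juncs, key=lambda j: j.end)


def translate_junction_peptide(
    event: ASEvent,
    isoform: str,
    frame: FrameAssignment,
    genome: Fasta,
    window_aa: int = DEFAULT_WINDOW_AA,
) -> JunctionPeptide:
    """Translate the junction of the given isoform into a peptide of at
    most ``window_aa`` residues centered at the splice site.

    Downstream sequence follows the isoform's transcript structure (for an
    SE inclusion isoform it enters the alternative exon and crosses into
    the downstream exon when the alternative exon is shorter than the
    window; for a retained intron it reads through the exon-intron
    border).  Translation proceeds in the upstream reading frame even when
    the isoform shifts frame downstream, and halts at the first stop codon.
    """
    strand = event.strand
    chrom = event.chrom
    flags: set[str] = set()
    phase = frame.phase
    split = phase != 0
    half = (window_aa - 1) // 2  # 10 for the default window

    up_iv = _upstream_segment(event, isoform)
    up_codons = min(half, max(0, (frame.upstream_avail_nt - phase)) // 3)
    if up_codons < half:
        flags.add("exon_boundary")
    u_nt = phase + 3 * up_codons
    if strand == "+":
        up_seq = _fetch(genome, chrom, up_iv[1] - u_nt + 1, up_iv[1], strand) \
            if u_nt else ""
    else:
        up_seq = _fetch(genome, chrom, up_iv[0], up_iv[0] + u_nt - 1, strand) \
            if u_nt else ""

    down_codons = window_aa - up_codons - (1 if split else 0)
    down_needed = ((3 - phase) % 3) + 3 * down_codons
    down_parts = []
    remaining = down_needed
    for seg in _downstream_segments(event, isoform):
        if remaining <= 0:
            break
        seg_seq = _fetch(genome, chrom, seg[0], seg[1], strand)
        down_parts.append(seg_seq[:remaining])
        remaining -= len(seg_seq[:remaining])
    if remaining > 0:
        flags.add("exon_boundary")
    down_seq = "".join(down_parts)

    window_nt = up_seq + down_seq
    n_pos = window_nt.find("N")
    if n_pos != -1:
        window_nt = window_nt[:n_pos]
        flags.add("ambiguous_base")
    window_nt = window_nt[:len(window_nt) - len(window_nt) % 3]

    aa = str(Seq(window_nt).translate(table=1)) if window_nt else ""
    stop = aa.find("*")
    if stop != -1:
        aa = aa[:stop]
        flags.add("stop_codon")

    junction_position = min(up_codons + 1, max(len(aa), 1))
    protein_start = protein_end = None
    if frame.coding_offset is not None and aa:
        first_codon_offset = frame.coding_offset - u_nt  # nt before window
        protein_start = first_codon_offset // 3 + 1
        protein_end = protein_start + len(aa) - 1
    return JunctionPeptide(
        event_id=event.event_id,
        isoform=isoform,
        sequence=aa,
        junction_position=junction_position,
        flags=flags,
        transcript_id=frame.transcript_id,
        protein_id=frame.protein_id,
        protein_start=protein_start,
        protein_end=protein_end,
    )


def translate_event(
    event: ASEvent,
    gene_models: dict,
    genome: Fasta,
    window_aa: int = DEFAULT_WINDOW_AA,
) -> dict:
    """Translate both isoforms of an event; returns a possibly-empty dict
    ``{isoform: JunctionPeptide}``.  Events whose upstream flank has no
    annotated frame are dropped (empty dict)."""
    out = {}
    for isoform in ("inclusion", "skipping"):
        j = translated_junction(event, isoform)
        frame = resolve_reading_frame(j, gene_models)
        if frame is None:
            log.info("%s/%s: no annotated frame", event.event_id, isoform)
            continue
        try:
            pep = translate_junction_peptide(event, isoform, frame, genome,
                                             window_aa)
        except (KeyError, ValueError) as exc:
            log.warning("%s/%s: translation failed: %s",
                        event.event_id, isoform, exc)
            continue
        if pep.sequence:
            out[isoform] = pep
    return out


def diff_isoform_peptides(
    tumor_peptide: JunctionPeptide,
    normal_peptide: JunctionPeptide | None,
) -> tuple[bool, str]:
    """Keep the tumor-isoform peptide only when it differs from the
    normal-isoform peptide; an untranslatable normal peptide keeps the
    tumor one with a flag."""
    if normal_peptide is None or not normal_peptide.sequence:
        tumor_peptide.flags.add("no-normal-peptide")
        return True, "no-normal-peptide"
    if tumor_peptide.sequence == normal_peptide.sequence:
        return False, "identical-to-normal-isoform"
    return True, "distinct"


def classify_microexon(event: ASEvent) -> str:
    """SE events whose alternative exon is at most 30 nt are microexon
    events; paired with the enriched isoform this yields the
    inclusion/skipping microexon tallies."""
    if event.event_type != "SE":
        return "none"
    length = event.alt_exon_length
    return "microexon" if length is not None and length <= MICROEXON_MAX_NT \
        else "none"


def microexon_tally(events: list, enriched_isoforms: dict) -> pd.DataFrame:
    """Tally microexon involvement per enriched-isoform class.

    ``enriched_isoforms`` maps event_id -> {inclusion, skipping}.  Returns
    a table with counts and the percentage of events involving a
    microexon per isoform class, rounded half-up to one decimal.
    """
    counts = {"inclusion": [0, 0], "skipping": [0, 0]}  # [microexon, total]
    for ev in events:
        iso = enriched_isoforms.get(ev.event_id)
        if iso not in counts:
            continue
        counts[iso][1] += 1
        if classify_microexon(ev) == "microexon":
            counts[iso][0] += 1
    rows = []
    for iso, (micro, total) in counts.items():
        pct = round_half_up_pct(micro, total) if total else float("nan")
        rows.append({"isoform": iso, "microexon": micro, "total": total,
                     "percent_microexon": pct})
    return pd.DataFrame(rows).set_index("isoform")


def round_half_up_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (2/32 -> 6.3)."""
    import math
    pct = 100.0 * numerator / denominator
    return math.floor(pct * 10 + 0.5) / 10
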
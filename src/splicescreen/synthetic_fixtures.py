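"""Reproducible synthetic inputs: reference panels with planted events,
tumor cohorts, and a toy genome/annotation with a hand-built peptide
answer key.

Null events share one PSI-generating process across all groups (a
logit-normal around a per-event baseline); junction counts are drawn to
be consistent with PSI (total depth negative-binomial, inclusion split
binomial at the event's inclusion probability), so ratio-based and
count-based screens see two views of the same signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .panel_store import ReferencePanel, event_from_row
from .types import SampleGroup

log = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    n_normal_groups: int = 11
    samples_per_group: int = 20
    n_tumor_samples: int = 23
    n_events: int = 500
    n_planted_associated: int = 0
    n_planted_specific: int = 0
    delta_psi_effect: float = 0.3
    psi_noise_sd: float = 0.5  # on the logit scale
    baseline_psi_range: tuple = (0.25, 0.75)
    nb_mean: float = 40.0
    nb_dispersion: float = 10.0
    total_mapped_reads_range: tuple = (20_000_000, 50_000_000)
    n_tumor_reference_groups: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_associated + self.n_planted_specific > self.n_events:
            raise ValueError("more planted events than events")
        for name in ("samples_per_group", "n_tumor_samples", "n_events",
                     "n_normal_groups"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.delta_psi_effect < 1):
            raise ValueError("delta_psi_effect must be in (0,1)")
        if self.psi_noise_sd <= 0 or self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("rates must be positive")


# ---------------------------------------------------------------------------
# event scaffolding
# ---------------------------------------------------------------------------

def _synthetic_events(n: int):
    events = []
    for i in range(n):
        base = 10_000 * (i + 1)
        row = {
            "GeneID": f"GSYN{i:05d}", "geneSymbol": f"SYN{i:05d}",
            "chr": "chrS", "strand": "+",
            "exonStart_0base": base + 300, "exonEnd": base + 400,
            "upstreamES": base, "upstreamEE": base + 200,
            "downstreamES": base + 500, "downstreamEE": base + 700,
        }
        events.append(event_from_row("SE", row))
    return events


def _draw_group(rng, base_psi, noise_sd, nb_mean, nb_disp, n_samples,
                max_inclusion=None):
    """Draw (psi, inc_per_junction, skip) matrices for one sample group.

    ``psi`` is the empirical inclusion ratio of the drawn counts, so the
    two representations are mutually consistent.
    """
    n_events = len(base_psi)
    p = expit(logit(np.clip(base_psi, 1e-4, 1 - 1e-4))[:, None]
              + rng.normal(0.0, noise_sd, size=(n_events, n_samples)))
    nb_p = nb_disp / (nb_disp + nb_mean)
    depth = rng.negative_binomial(nb_disp, nb_p, size=(n_events, n_samples))
    inc = rng.binomial(depth, p)
    if max_inclusion is not None:
        inc = np.minimum(inc, max_inclusion)
    skip = depth - np.minimum(inc, depth)
    total = inc + skip
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, inc / np.maximum(total, 1), np.nan)
    return psi, inc, skip


def generate_reference_panel(spec: SyntheticSpec):
    """Normal-tissue reference panel plus the truth table of planted
    events.  Planted tumor-specific events are constructed with
    normal-group inclusion-junction counts forced below 2 in every normal
    group; the tumor-side effect is added by :func:`plant_tumor_events`.

    Returns ``(panel, truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    events = _synthetic_events(spec.n_events)

    classes = np.array(["null"] * spec.n_events, dtype=object)
    planted = rng.choice(spec.n_events,
                         spec.n_planted_associated + spec.n_planted_specific,
                         replace=False)
    classes[planted[:spec.n_planted_associated]] = "associated"
    classes[planted[spec.n_planted_associated:]] = "specific"

    lo, hi = spec.baseline_psi_range
    base = rng.uniform(lo, hi, size=spec.n_events)
    # keep the planted effect from collapsing against the [0,1] ceiling
    redraw = (classes == "associated") & (base + spec.delta_psi_effect > 0.94)
    for _ in range(100):
        if not redraw.any():
            break
        log.info("re-drawing %d baseline(s) too close to 1", int(redraw.sum()))
        base[redraw] = rng.uniform(lo, (lo + hi) / 2, size=int(redraw.sum()))
        redraw = (classes == "associated") & (base + spec.delta_psi_effect > 0.94)
    else:
        raise ValueError("infeasible spec: baseline_psi_range leaves no room "
                         "for delta_psi_effect")
    base[classes == "specific"] = 0.01

    group_ids = [f"tissue{i + 1:02d}" for i in range(spec.n_normal_groups)]
    psi_parts, inc1_parts, inc2_parts, skip_parts, columns = [], [], [], [], []
    groups = {}
    for gid in group_ids:
        cap = np.where(classes == "specific", 1, np.iinfo(np.int64).max)[:, None]
        psi, inc, skip = _draw_group(
            rng, base, spec.psi_noise_sd, spec.nb_mean, spec.nb_dispersion,
            spec.samples_per_group, max_inclusion=cap)
        sample_ids = [f"{gid}_s{j + 1:02d}" for j in range(spec.samples_per_group)]
        columns.extend(sample_ids)
        psi_parts.append(psi)
        inc1_parts.append(inc)
        inc2_parts.append(inc)
        skip_parts.append(skip)
        totals = rng.integers(*spec.total_mapped_reads_range,
                              size=spec.samples_per_group)
        groups[gid] = SampleGroup(
            group_id=gid, role="normal_reference", sample_ids=sample_ids,
            total_mapped_reads=dict(zip(sample_ids, (int(t) for t in totals))))

    psi_df = pd.DataFrame(np.hstack(psi_parts),
                          index=[e.event_id for e in events], columns=columns)
    sjc_df = _sjc_frame(events, np.hstack(inc1_parts), np.hstack(inc2_parts),
                        np.hstack(skip_parts), columns)
    panel = ReferencePanel(groups=groups,
                           events={e.event_id: e for e in events},
                           psi=psi_df, sjc=sjc_df)
    truth = pd.DataFrame({
        "event_id": [e.event_id for e in events],
        "planted_class": classes,
        "baseline_psi": base,
        "effect": np.where(classes == "null", 0.0, spec.delta_psi_effect),
    }).set_index("event_id")
    _assert_construction(panel, truth)
    return panel, truth


def _sjc_frame(events, inc1, inc2, skip, columns):
    keys, rows = [], []
    for i, ev in enumerate(events):
        j1, j2 = ev.inclusion_junctions
        js, = ev.skipping_junctions
        keys.extend([j1.key(), j2.key(), js.key()])
        rows.extend([inc1[i], inc2[i], skip[i]])
    return pd.DataFrame(np.vstack(rows), index=keys,
                        columns=columns).astype(np.int64)


def plant_tumor_events(panel: ReferencePanel, truth: pd.DataFrame,
                       spec: SyntheticSpec, group_id: str = "TUMOR",
                       role: str = "tumor_query", seed_offset: int = 1):
    """Draw the tumor cohort matrices and merge them into a new panel.

    Planted events get their inclusion probability shifted by
    ``delta_psi_effect`` (clipped to [0.01, 0.99]); planted tumor-specific
    events additionally get inclusion-junction counts of at least 5 in
    every tumor sample.
    """
    rng = np.random.default_rng(spec.seed + seed_offset)
    events = list(panel.events.values())
    classes = truth["planted_class"].to_numpy()
    base = truth["baseline_psi"].to_numpy(dtype=float)
    shifted = np.where(classes == "null", base,
                       np.clip(base + spec.delta_psi_effect, 0.01, 0.99))
    effect = shifted - base
    collapsed = (classes != "null") & (effect < 0.05)
    if collapsed.any():
        raise ValueError(
            f"{int(collapsed.sum())} planted event(s) lost their effect to "
            "clipping; lower baseline_psi_range or delta_psi_effect")

    psi, inc, skip = _draw_group(rng, shifted, spec.psi_noise_sd, spec.nb_mean,
                                 spec.nb_dispersion, spec.n_tumor_samples)
    specific = classes == "specific"
    inc[specific] = np.maximum(inc[specific], 5)
    total = inc + skip
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, inc / np.maximum(total, 1), np.nan)

    sample_ids = [f"{group_id}_s{j + 1:02d}" for j in range(spec.n_tumor_samples)]
    totals = rng.integers(*spec.total_mapped_reads_range,
                          size=spec.n_tumor_samples)
    tumor_group = SampleGroup(
        group_id=group_id, role=role, sample_ids=sample_ids,
        total_mapped_reads=dict(zip(sample_ids, (int(t) for t in totals))))

    psi_df = pd.concat(
        [panel.psi,
         pd.DataFrame(psi, index=panel.psi.index, columns=sample_ids)], axis=1)
    sjc_t = _sjc_frame(events, inc, inc, skip, sample_ids)
    sjc_df = pd.concat([panel.sjc, sjc_t.reindex(panel.sjc.index)], axis=1)
    groups = dict(panel.groups)
    groups[group_id] = tumor_group
    return ReferencePanel(groups=groups, events=dict(panel.events),
                          psi=psi_df, sjc=sjc_df.astype(np.int64))


def generate_panel_with_cohort(spec: SyntheticSpec):
    """Convenience: reference panel + tumor cohort (+ optional auxiliary
    tumor-reference cohorts, planted identically).  Returns
    ``(panel, truth)``."""
    panel, truth = generate_reference_panel(spec)
    panel = plant_tumor_events(panel, truth, spec)
    for k in range(spec.n_tumor_reference_groups):
        panel = plant_tumor_events(panel, truth, spec,
                                   group_id=f"TUMOR_REF{k + 1}",
                                   role="tumor_reference", seed_offset=2 + k)
    return panel, truth


def _assert_construction(panel: ReferencePanel, truth: pd.DataFrame) -> None:
    """Post-generation check of construction guarantees."""
    specific = truth.index[truth["planted_class"] == "specific"]
    for event_id in specific:
        ev = panel.events[event_id]
        for g in panel.groups_with_role("normal_reference"):
            for j in ev.inclusion_junctions:
                counts = panel.sjc.loc[j.key(), g.sample_ids]
                if (counts >= 2).any():
                    raise AssertionError(
                        f"{event_id}: planted specific event expressed in "
                        f"normal group {g.group_id}")


# ---------------------------------------------------------------------------
# dialect writers (round-trip through the panel_store readers)
# ---------------------------------------------------------------------------

def write_panel_inputs(panel: ReferencePanel, outdir: str | Path) -> dict:
    """Emit the panel as reader-dialect files: one SE event table, one
    STAR-style junction file per sample, and the group manifest TSV.
    Returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = panel.sample_ids

    header = ["ID", "GeneID", "geneSymbol", "chr", "strand",
              "exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
              "downstreamES", "downstreamEE", "IJC_SAMPLE_1", "SJC_SAMPLE_1",
              "IncLevel1"]
    lines = ["\t".join(header)]
    for i, ev in enumerate(panel.events.values()):
        if ev.event_type != "SE":
            continue
        inc_keys = [j.key() for j in ev.inclusion_junctions]
        skp_key = ev.skipping_junctions[0].key()
        ijc = panel.sjc.loc[inc_keys, samples].sum(axis=0)
        sjc = panel.sjc.loc[skp_key, samples]
        psi = panel.psi.loc[ev.event_id, samples]
        lv = ",".join("NA" if np.isnan(v) else f"{v:.3f}" for v in psi)
        c = ev.coords
        lines.append("\t".join(str(x) for x in [
            i, ev.gene_id, ev.gene_symbol, ev.chrom, ev.strand,
            c["exonStart_0base"], c["exonEnd"], c["upstreamES"],
            c["upstreamEE"], c["downstreamES"], c["downstreamEE"],
            ",".join(str(int(v)) for v in ijc),
            ",".join(str(int(v)) for v in sjc), lv]))
    se_path = outdir / "SE.events.txt"
    se_path.write_text("\n".join(lines) + "\n")

    star_dir = outdir / "sj"
    star_dir.mkdir(exist_ok=True)
    strand_code = {".": 0, "+": 1, "-": 2}
    star_paths = {}
    for s in samples:
        rows = []
        for key, count in panel.sjc[s].items():
            chrom, span, strand = key.rsplit(":", 2)
            start, end = span.split("-")
            rows.append(f"{chrom}\t{start}\t{end}\t{strand_code[strand]}"
                        f"\t1\t1\t{int(count)}\t0\t30")
        p = star_dir / f"{s}.SJ.out.tab"
        p.write_text("\n".join(rows) + "\n")
        star_paths[s] = p

    manifest = pd.DataFrame([
        {"sample_id": s, "group_id": g.group_id, "role": g.role,
         "total_mapped_reads": g.total_mapped_reads[s]}
        for g in panel.groups.values() for s in g.sample_ids])
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    sample_list = outdir / "samples.txt"
    sample_list.write_text("\n".join(samples) + "\n")
    return {"se_table": se_path, "star": star_paths,
            "manifest": manifest_path, "samples": sample_list}


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}
_AA_BY_CODON = {}
_BASES = "TCAG"
_TABLE1 = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
           "VVVVAAAADDEEGGGG")
for _i, _c in enumerate(
        [a + b + c for a in _BASES for b in _BASES for c in _BASES]):
    _AA_BY_CODON[_c] = _TABLE1[_i]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UP_AA = "ADEFGHIKLN"  # shared 10-residue upstream window of every toy gene


def _rt(aa: str) -> str:
    return "".join(_CODON[a] for a in aa)


def _tx(nt: str) -> str:
    """Naive codon-loop translation (used only to derive the answer key)."""
    return "".join(_AA_BY_CODON.get(nt[i:i + 3], "X")
                   for i in range(0, len(nt) - len(nt) % 3, 3))


def _revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def _expected_window(up_nt: str, down_nt: str, phase: int,
                     window_aa: int = 21) -> tuple:
    """Answer-key window: last (30 + phase) nt of upstream coding sequence
    plus downstream nt to fill 21 codons, truncated at N and at the first
    stop."""
    up = up_nt[-(30 + phase):] if (30 + phase) else ""
    split = 1 if phase else 0
    down_needed = ((3 - phase) % 3) + 3 * (window_aa - 10 - split)
    window = up + down_nt[:down_needed]
    flags = set()
    if "N" in window:
        window = window[:window.index("N")]
        flags.add("ambiguous_base")
    aa = _tx(window)
    if "*" in aa:
        aa = aa[:aa.index("*")]
        flags.add("stop_codon")
    return aa, flags


@dataclass
class ToyGene:
    name: str
    chrom: str
    strand: str
    chrom_seq: str
    transcripts: list  # [(transcript_id, [(s,e) exons], [(s,e) cds], protein_id)]
    event_row: dict | None
    event_type: str = "SE"
    expected: dict = field(default_factory=dict)  # isoform -> (peptide, flags)
    extracellular: list | None = None
    protein_id: str | None = None


def _layout(pieces: list) -> tuple:
    """Concatenate sequence pieces; returns (sequence, {name: (start, end)})
    with 1-based inclusive coordinates."""
    seq, spans, pos = [], {}, 0
    for name, s in pieces:
        spans[name] = (pos + 1, pos + len(s))
        seq.append(s)
        pos += len(s)
    return "".join(seq), spans


def _mirror(spans: dict, length: int) -> dict:
    return {k: (length - e + 1, length - s + 1) for k, (s, e) in spans.items()}


def _make_se_gene(idx: int, name: str, *, phase: int = 0,
                  split_aa: str = "", alt_nt: str, down_aa: str,
                  strand: str = "+", coding: bool = True,
                  extracellular: list | None = None) -> ToyGene:
    chrom = f"chrT{idx:02d}"
    pad = "C" * 30
    split_codon = _CODON[split_aa] if phase else ""
    up_coding = _rt("M" + UP_AA) + split_codon[:phase]
    down_nt_full = _rt(down_aa) + "TAA" + "C" * 12
    intron1 = "GTAAGT" + "C" * 14 + "TTTCAG"
    intron2 = "GTAAGT" + "C" * 20 + "TTTCAG"
    alt_full = split_codon[phase:] + alt_nt

    seq, spans = _layout([
        ("pad1", pad), ("exon1", up_coding), ("intron1", intron1),
        ("alt", alt_full), ("intron2", intron2), ("exon3", down_nt_full),
        ("pad2", pad)])
    if strand == "-":
        seq = _revcomp(seq)
        spans = _mirror(spans, len(seq))

    exon1, alt, exon3 = spans["exon1"], spans["alt"], spans["exon3"]
    genomic = sorted([exon1, exon3])
    gene_id, tx_inc, tx_skip = f"g{idx:02d}", f"g{idx:02d}.t1", f"g{idx:02d}.t2"
    protein_id = f"P{idx:02d}" if coding else None
    transcripts = [(tx_inc, sorted([exon1, alt, exon3]), [], None)]
    if coding:
        transcripts.append((tx_skip, genomic,
                            sorted([exon1, exon3]), protein_id))
    event_row = {
        "GeneID": gene_id, "geneSymbol": name, "chr": chrom, "strand": strand,
        "exonStart_0base": alt[0] - 1, "exonEnd": alt[1],
        "upstreamES": genomic[0][0] - 1, "upstreamEE": genomic[0][1],
        "downstreamES": genomic[1][0] - 1, "downstreamEE": genomic[1][1],
    }
    expected = {}
    if coding:
        # downstream nt in transcription order: the alternative exon (which
        # carries the tail of any split codon) then the constitutive exon
        inc_aa, inc_flags = _expected_window(up_coding,
                                             alt_full + down_nt_full, phase)
        skip_aa, skip_flags = _expected_window(up_coding, down_nt_full, phase)
        expected = {"inclusion": (inc_aa, inc_flags),
                    "skipping": (skip_aa, skip_flags)}
    return ToyGene(name=name, chrom=chrom, strand=strand, chrom_seq=seq,
                   transcripts=transcripts, event_row=event_row,
                   expected=expected, extracellular=extracellular,
                   protein_id=protein_id)


def _make_ri_gene(idx: int, name: str, intron_aa: str, down_aa: str) -> ToyGene:
    chrom = f"chrT{idx:02d}"
    pad = "C" * 30
    up_coding = _rt("M" + UP_AA)
    intron = _rt(intron_aa) + "CCCCAG"  # starts GT via first codon (V...), ends AG
    down_nt_full = _rt(down_aa) + "TAA" + "C" * 12
    seq, spans = _layout([
        ("pad1", pad), ("exon1", up_coding), ("intron", intron),
        ("exon3", down_nt_full), ("pad2", pad)])
    exon1, exon3 = spans["exon1"], spans["exon3"]
    gene_id, tx_ret, tx_spl = f"g{idx:02d}", f"g{idx:02d}.t1", f"g{idx:02d}.t2"
    protein_id = f"P{idx:02d}"
    transcripts = [
        (tx_ret, [(exon1[0], exon3[1])], [], None),
        (tx_spl, [exon1, exon3], [exon1, exon3], protein_id),
    ]
    event_row = {
        "GeneID": gene_id, "geneSymbol": name, "chr": chrom, "strand": "+",
        "riExonStart_0base": exon1[0] - 1, "riExonEnd": exon3[1],
        "upstreamES": exon1[0] - 1, "upstreamEE": exon1[1],
        "downstreamES": exon3[0] - 1, "downstreamEE": exon3[1],
    }
    inc_aa, inc_flags = _expected_window(up_coding, intron + down_nt_full, 0)
    skip_aa, skip_flags = _expected_window(up_coding, down_nt_full, 0)
    return ToyGene(name=name, chrom=chrom, strand="+", chrom_seq=seq,
                   transcripts=transcripts, event_row=event_row,
                   event_type="RI",
                   expected={"inclusion": (inc_aa, inc_flags),
                             "skipping": (skip_aa, skip_flags)},
                   protein_id=protein_id)


def build_toy_genes() -> list:
    """The toy gene set: codon-aligned and phase-1/2 junctions, a 12-nt
    microexon, a frameshifting skip, both strands, a retained intron, a
    premature stop, an ambiguous base, surface-annotated proteins, and a
    non-coding gene."""
    genes = [
        _make_se_gene(1, "TOY_PLAIN", phase=0,
                      alt_nt=_rt("PQRSTVYACDE"), down_aa="GHIKNPQRSTVY"),
        _make_se_gene(2, "TOY_PHASE1", phase=1, split_aa="T",
                      alt_nt=_rt("PQRSTVYACD"), down_aa="GHIKNPQRSTV"),
        _make_se_gene(3, "TOY_PHASE2", phase=2, split_aa="S",
                      alt_nt=_rt("PQRSTVYACD"), down_aa="GHIKNPQRSTV"),
        _make_se_gene(4, "TOY_MICRO", phase=0,
                      alt_nt=_rt("PQRS"), down_aa="GHIKNPQRSTVY"),
        _make_se_gene(5, "TOY_SHIFT", phase=0,
                      alt_nt=_rt("PQR") + "C", down_aa="GHIKNPQRSTVY"),
        _make_se_gene(6, "TOY_MINUS", phase=0, strand="-",
                      alt_nt=_rt("PQRSTVYACDE"), down_aa="GHIKNPQRSTVY"),
        _make_ri_gene(7, "TOY_RETAIN", intron_aa="VSTAETAYKLM",
                      down_aa="GHIKNPQRSTVY"),
        _make_se_gene(8, "TOY_STOP", phase=1, split_aa="T",
                      alt_nt=_rt("PQRST") + "TAA" + "C" * 18,
                      down_aa="GHIKNPQRSTV"),
        _make_se_gene(9, "TOY_SURFACE", phase=0,
                      alt_nt=_rt("PQRSTVYACDE"), down_aa="GHIKNPQRSTVY",
                      extracellular=[(1, 50)]),
        _make_se_gene(10, "TOY_INNER", phase=0,
                      alt_nt=_rt("PQRSTVYACDE"), down_aa="GHIKNPQRSTVY",
                      extracellular=[(100, 200)]),
        _make_se_gene(11, "TOY_NONCODING", phase=0, coding=False,
                      alt_nt=_rt("PQRSTVYACDE"), down_aa="GHIKNPQRSTVY"),
        _make_se_gene(12, "TOY_AMBIG", phase=0,
                      alt_nt=_rt("PQ") + "N" + _rt("RSTVYACD"),
                      down_aa="GHIKNPQRSTVY"),
    ]
    return genes


def generate_toy_genome(outdir: str | Path) -> dict:
    """Write the toy genome FASTA, GTF, protein annotation and answer key.

    Returns a dict with paths plus the in-memory ``genes`` list and
    ``events`` (one :class:`ASEvent` per gene) and ``answer_key``
    (event_id -> isoform -> (peptide, flags)).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = build_toy_genes()

    fasta_path = outdir / "toy_genome.fa"
    with open(fasta_path, "w") as fh:
        for g in genes:
            fh.write(f">{g.chrom}\n")
            for i in range(0, len(g.chrom_seq), 60):
                fh.write(g.chrom_seq[i:i + 60] + "\n")

    gtf_path = outdir / "toy_annotation.gtf"
    with open(gtf_path, "w") as fh:
        for g in genes:
            gene_id = g.event_row["GeneID"]
            for tx_id, exons, cds, protein_id in g.transcripts:
                attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
                if protein_id:
                    attrs += f' protein_id "{protein_id}";'
                tx_start = min(s for s, _ in exons)
                tx_end = max(e for _, e in exons)
                fh.write(f"{g.chrom}\ttoy\ttranscript\t{tx_start}\t{tx_end}"
                         f"\t.\t{g.strand}\t.\t{attrs}\n")
                for s, e in exons:
                    fh.write(f"{g.chrom}\ttoy\texon\t{s}\t{e}\t.\t{g.strand}"
                             f"\t.\t{attrs}\n")
                running = 0
                cds_tx_order = sorted(cds, reverse=(g.strand == "-"))
                for s, e in cds_tx_order:
                    frame = (3 - running % 3) % 3
                    fh.write(f"{g.chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{g.strand}"
                             f"\t{frame}\t{attrs}\n")
                    running += e - s + 1

    protein_path = outdir / "toy_proteins.tsv"
    with open(protein_path, "w") as fh:
        fh.write("protein_id\tstart\tend\tlabel\n")
        for g in genes:
            if g.extracellular and g.protein_id:
                for s, e in g.extracellular:
                    fh.write(f"{g.protein_id}\t{s}\t{e}\tExtracellular\n")

    events, answer_key = [], {}
    for g in genes:
        ev = event_from_row(g.event_type, g.event_row)
        events.append(ev)
        if g.expected:
            answer_key[ev.event_id] = g.expected

    key_path = outdir / "toy_answer_key.tsv"
    with open(key_path, "w") as fh:
        fh.write("event_id\tisoform\tpeptide\tflags\n")
        for event_id, isoforms in answer_key.items():
            for isoform, (pep, flags) in isoforms.items():
                fh.write(f"{event_id}\t{isoform}\t{pep}\t"
                         f"{','.join(sorted(flags)) or '-'}\n")
    return {"fasta": fasta_path, "gtf": gtf_path, "proteins": protein_path,
            "answer_key_path": key_path, "genes": genes, "events": events,
            "answer_key": answer_key}
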
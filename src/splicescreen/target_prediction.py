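"""HLA-I epitope candidate calling and cell-surface target mapping.

Binding prediction is delegated to a pluggable predictor contract; a
deterministic mock ships for offline tests.  A candidate is positive when
the median of its per-predictor IC50 values is strictly below 500 nM.
Peptides mapping into annotated extracellular intervals of their source
protein are flagged as cell-surface (CAR-T) candidates.
"""

from __future__ import annotations

import hashlib
import logging
import math
import statistics
from dataclasses import dataclass, field

import pandas as pd

from .junction_translation import JunctionPeptide

log = logging.getLogger(__name__)

IC50_POSITIVE_THRESHOLD_NM = 500.0
DEFAULT_EPITOPE_LENGTHS = (9, 10)


@dataclass
class EpitopeCandidate:
    event_id: str
    peptide: str  # 8-11mer overlapping the junction residue
    allele: str
    ic50_values: list = field(default_factory=list)  # per-predictor, nM
    median_ic50: float = float("nan")
    positive: bool = False
    scored: bool = True


class AffinityPredictor:
    """Contract for binding-affinity predictors.

    Implementations must be deterministic for fixed inputs and either
    return one or more IC50 values (nM) or raise
    :class:`UnsupportedAllele`.
    """

    name = "abstract"

    def supports(self, allele: str) -> bool:  # pragma: no cover - interface
        raise NotImplementedError

    def predict(self, peptide: str, allele: str) -> list:  # pragma: no cover
        raise NotImplementedError


class UnsupportedAllele(ValueError):
    pass


class MockAffinityPredictor(AffinityPredictor):
    """Deterministic stand-in for an external binding predictor.

    Hashes (peptide, allele, replicate) to a log-uniform IC50 in
    [1, 50000] nM; emits three pseudo-tool values per query so the median
    path is exercised.
    """

    name = "mock"

    def __init__(self, supported_alleles: list | None = None,
                 n_tools: int = 3):
        self.supported_alleles = (set(supported_alleles)
                                  if supported_alleles is not None else None)
        self.n_tools = n_tools

    def supports(self, allele: str) -> bool:
        return self.supported_alleles is None or allele in self.supported_alleles

    def predict(self, peptide: str, allele: str) -> list:
        if not self.supports(allele):
            raise UnsupportedAllele(allele)
        values = []
        for i in range(self.n_tools):
            digest = hashlib.sha256(
                f"{peptide}|{allele}|{i}".encode()).digest()
            frac = int.from_bytes(digest[:8], "big") / 2**64
            values.append(math.exp(frac * math.log(50000.0)))
        return values


def enumerate_junction_epitopes(
    peptide: JunctionPeptide,
    lengths: tuple = DEFAULT_EPITOPE_LENGTHS,
) -> list:
    """All windows of the requested lengths that contain the junction
    residue, deduplicated to unique strings per event."""
    seq = peptide.sequence
    jp = peptide.junction_position  # 1-based
    windows: list[str] = []
    seen: set[str] = set()
    for length in sorted(lengths):
        if length > len(seq):
            continue
        lo = max(1, jp - length + 1)
        hi = min(jp, len(seq) - length + 1)
        for start in range(lo, hi + 1):
            w = seq[start - 1:start - 1 + length]
            if w not in seen:
                seen.add(w)
                windows.append(w)
    if not windows:
        log.info("%s/%s: peptide too short for epitope windows (%d aa)",
                 peptide.event_id, peptide.isoform, len(seq))
    return windows


def median_ic50(values: list) -> float:
    """Median of the per-predictor IC50 values; even counts take the
    midpoint mean."""
    return float(statistics.median(values))


def score_epitopes(
    candidates: dict,
    alleles: list,
    predictor: AffinityPredictor,
    ic50_threshold: float = IC50_POSITIVE_THRESHOLD_NM,
) -> list:
    """Score each (event, peptide) x allele pair through the predictor.

    ``candidates`` maps event_id -> list of peptide strings.  Unsupported
    alleles yield unscored candidates rather than silent drops.  A
    candidate is positive iff its median IC50 is strictly below the
    threshold (500 nM default).
    """
    if not alleles:
        raise ValueError("allele list is empty")
    out = []
    for event_id, peptides in candidates.items():
        for pep in peptides:
            for allele in alleles:
                cand = EpitopeCandidate(event_id=event_id, peptide=pep,
                                        allele=allele)
                try:
                    values = list(predictor.predict(pep, allele))
                except UnsupportedAllele:
                    cand.scored = False
                    log.warning("allele %s unsupported by predictor %s",
                                allele, predictor.name)
                    out.append(cand)
                    continue
                if not values:
                    cand.scored = False
                    out.append(cand)
                    continue
                cand.ic50_values = values
                cand.median_ic50 = median_ic50(values)
                cand.positive = cand.median_ic50 < ic50_threshold
                out.append(cand)
    return out


def epitopes_to_table(epitopes: list) -> pd.DataFrame:
    rows = []
    for e in epitopes:
        rows.append({
            "event_id": e.event_id,
            "peptide": e.peptide,
            "allele": e.allele,
            "ic50_values": ";".join(f"{v:.6g}" for v in e.ic50_values),
            "median_ic50": e.median_ic50,
            "positive": e.positive,
            "scored": e.scored,
        })
    return pd.DataFrame(rows, columns=["event_id", "peptide", "allele",
                                       "ic50_values", "median_ic50",
                                       "positive", "scored"])


# ---------------------------------------------------------------------------
# cell-surface (CAR-T) mapping
# ---------------------------------------------------------------------------

def normalize_intervals(intervals: list) -> list:
    """Sort and merge overlapping/adjacent 1-based inclusive intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def map_extracellular(
    peptide: JunctionPeptide,
    annotations: dict,
) -> dict:
    """Cell-surface candidacy: does the peptide's residue interval on its
    source protein intersect an annotated extracellular interval?

    ``annotations`` maps protein_id -> list of (start, end) residue
    intervals.  Returns a dict with ``candidate`` plus the overlap length
    or the reason it is not a candidate.
    """
    if peptide.protein_id is None or peptide.protein_start is None:
        return {"candidate": False, "reason": "unmapped", "overlap": 0}
    intervals = annotations.get(peptide.protein_id)
    if not intervals:
        return {"candidate": False, "reason": "no annotation", "overlap": 0}
    p_start, p_end = peptide.protein_start, peptide.protein_end
    overlap = 0
    for s, e in normalize_intervals(intervals):
        overlap += max(0, min(e, p_end) - max(s, p_start) + 1)
    if overlap > 0:
        return {"candidate": True, "reason": "extracellular", "overlap": overlap}
    return {"candidate": False, "reason": "no overlap", "overlap": 0}


def read_extracellular_annotation(path) -> dict:
    """TSV of (protein_id, start, end, label); rows labeled
    'Extracellular' (case-insensitive) are kept."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    if "label" in df.columns:
        df = df[df["label"].str.lower() == "extracellular"]
    out: dict[str, list] = {}
    for r in df.itertuples():
        out.setdefault(str(r.protein_id), []).append((int(r.start), int(r.end)))
    return {k: normalize_intervals(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# validation shortlist
# ---------------------------------------------------------------------------

def prioritize_candidates(
    epitopes: list,
    records: dict,
    gene_expression: pd.Series,
    event_genes: dict,
    allele_restriction: str = "HLA-A*02:01",
    fc_min: float = 2.0,
    fpkm_min: float = 20.0,
    tumor_specific_events: set | None = None,
) -> pd.DataFrame:
    """Shortlist positive epitopes for experimental follow-up.

    Filters: restriction to one allele, fold change of the tumor-enriched
    isoform at or above ``fc_min``, and mean gene expression at or above
    ``fpkm_min`` FPKM.  The shortlist is deduplicated to unique peptide
    strings; rows list every contributing event and flag tumor-specific
    ones for priority.
    """
    tumor_specific_events = tumor_specific_events or set()
    by_peptide: dict[str, dict] = {}
    for e in epitopes:
        if not (e.scored and e.positive and e.allele == allele_restriction):
            continue
        rec = records.get(e.event_id)
        if rec is None:
            continue
        fc = rec.fold_change if hasattr(rec, "fold_change") else rec["fold_change"]
        if not (fc == fc and fc >= fc_min):  # NaN-safe
            continue
        gene = event_genes.get(e.event_id)
        if gene is None or gene not in gene_expression.index:
            log.info("epitope %s: no expression for gene of %s; excluded",
                     e.peptide, e.event_id)
            continue
        if gene_expression[gene] < fpkm_min:
            continue
        entry = by_peptide.setdefault(e.peptide, {
            "peptide": e.peptide, "allele": e.allele, "events": set(),
            "median_ic50": e.median_ic50, "tumor_specific": False,
        })
        entry["events"].add(e.event_id)
        entry["median_ic50"] = min(entry["median_ic50"], e.median_ic50)
        if e.event_id in tumor_specific_events:
            entry["tumor_specific"] = True
    rows = [{**v, "events": ";".join(sorted(v["events"]))}
            for v in by_peptide.values()]
    df = pd.DataFrame(rows, columns=["peptide", "allele", "events",
                                     "median_ic50", "tumor_specific"])
    return df.sort_values("peptide").reset_index(drop=True) if not df.empty else df
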
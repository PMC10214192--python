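"""Cross-validation of predicted epitopes against MS immunopeptidomics.

Builds an RNA-seq-augmented proteome FASTA for external search engines,
intersects FDR-filtered peptide-spectrum matches with predicted epitopes,
and bins detection rates by transcript-level expression and predicted
binding affinity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

DEFAULT_Q_MAX = 0.05
#: FPKM-scale expression bin edges and IC50 (nM) affinity bin edges
DEFAULT_EXPRESSION_EDGES = (0.0, 1.0, 10.0, 100.0, float("inf"))
DEFAULT_AFFINITY_EDGES = (0.0, 50.0, 250.0, 500.0, float("inf"))


@dataclass
class PsmRecord:
    peptide: str
    spectrum_id: str
    q_value: float
    protein: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value out of [0,1]: {self.q_value}")
        self.peptide = self.peptide.upper()


def read_psm_table(
    path: str | Path,
    column_map: dict | None = None,
) -> list:
    """Read a PSM TSV with at least (peptide, q_value) columns.

    ``column_map`` adapts other dialects, e.g. ``{"peptide": "Peptide",
    "q_value": "QValue"}``.
    """
    cmap = {"peptide": "peptide", "q_value": "q_value",
            "spectrum_id": "spectrum_id", "protein": "protein"}
    cmap.update(column_map or {})
    df = pd.read_csv(path, sep="\t")
    for needed in ("peptide", "q_value"):
        if cmap[needed] not in df.columns:
            raise ValueError(f"{path}: missing column {cmap[needed]!r}")
    out = []
    for i, r in df.iterrows():
        out.append(PsmRecord(
            peptide=str(r[cmap["peptide"]]),
            spectrum_id=str(r[cmap["spectrum_id"]])
            if cmap["spectrum_id"] in df.columns else f"psm{i}",
            q_value=float(r[cmap["q_value"]]),
            protein=str(r[cmap["protein"]])
            if cmap["protein"] in df.columns else "",
        ))
    return out


def build_custom_proteome(
    junction_peptides: list,
    reference_fasta: str | Path,
    out_fasta: str | Path,
) -> int:
    """Write reference proteome entries unchanged, then one entry per
    junction peptide with a machine-parsable header
    ``as|<event_id>|<isoform>|<flags>``.

    Duplicate sequences are still emitted under distinct ids (downstream
    search engines deduplicate).  Peptides identical to a substring of a
    reference entry are flagged in the header.  Returns the number of
    entries written.
    """
    reference = list(SeqIO.parse(str(reference_fasta), "fasta"))
    if not junction_peptides:
        log.warning("no junction peptides; writing reference passthrough")
    ref_seqs = [str(r.seq) for r in reference]
    records = list(reference)
    for pep in junction_peptides:
        flags = set(pep.flags)
        if any(pep.sequence in s for s in ref_seqs):
            flags.add("substring-of-reference")
        header = f"as|{pep.event_id}|{pep.isoform}|{','.join(sorted(flags)) or '-'}"
        records.append(SeqRecord(Seq(pep.sequence), id=header, description=""))
    count = SeqIO.write(records, str(out_fasta), "fasta")
    return count


def _collapse_il(seq: str) -> str:
    return seq.replace("I", "L")


def crossref_ms_peptides(
    predicted: set,
    psms: list,
    q_max: float = DEFAULT_Q_MAX,
    il_equivalence: bool = False,
) -> dict:
    """Intersect predicted epitope strings with FDR-passing PSM peptides.

    Returns counts of passing PSMs, unique passing peptides and the
    validated epitope set.  With ``il_equivalence`` the intersection is
    computed after collapsing I to L on both sides (MS cannot distinguish
    them); the returned validated set keeps the original predicted
    strings.
    """
    passing = [p for p in psms if p.q_value <= q_max]
    peptides = {p.peptide for p in passing}
    if il_equivalence:
        collapsed = {_collapse_il(p) for p in peptides}
        validated = {e for e in predicted if _collapse_il(e) in collapsed}
    else:
        validated = set(predicted) & peptides
    return {
        "n_psms": len(passing),
        "n_unique_peptides": len(peptides),
        "n_predicted": len(predicted),
        "validated": validated,
        "n_validated": len(validated),
    }


def bin_detection_rates(
    epitopes: pd.DataFrame,
    validated: set,
    expression_edges: tuple = DEFAULT_EXPRESSION_EDGES,
    affinity_edges: tuple = DEFAULT_AFFINITY_EDGES,
) -> pd.DataFrame:
    """Detection-rate grid over expression x affinity bins.

    ``epitopes`` needs columns peptide, fpkm, psi, isoform, median_ic50.
    Transcript-level expression is FPKM * PSI for inclusion-derived
    epitopes and FPKM * (1 - PSI) for skipping-derived ones.  Each grid
    cell tallies predicted and detected epitopes; the fraction is NaN for
    empty cells.  Epitopes missing expression are excluded and counted in
    the ``n_excluded`` attribute.
    """
    required = {"peptide", "fpkm", "psi", "isoform", "median_ic50"}
    missing = required - set(epitopes.columns)
    if missing:
        raise ValueError(f"epitope table missing column(s) {sorted(missing)}")
    df = epitopes.copy()
    ok = df["fpkm"].notna() & df["psi"].notna() & df["median_ic50"].notna()
    n_excluded = int((~ok).sum())
    df = df[ok]
    side = np.where(df["isoform"] == "inclusion", df["psi"], 1.0 - df["psi"])
    expression = df["fpkm"].to_numpy(dtype=float) * side

    e_bin = np.digitize(expression, expression_edges[1:-1], right=False)
    a_bin = np.digitize(df["median_ic50"].to_numpy(dtype=float),
                        affinity_edges[1:-1], right=False)
    detected = df["peptide"].isin(validated).to_numpy()

    rows = []
    for ei in range(len(expression_edges) - 1):
        for ai in range(len(affinity_edges) - 1):
            mask = (e_bin == ei) & (a_bin == ai)
            n_pred = int(mask.sum())
            n_det = int(detected[mask].sum())
            rows.append({
                "expression_bin": f"[{expression_edges[ei]:g},{expression_edges[ei + 1]:g})",
                "affinity_bin": f"[{affinity_edges[ai]:g},{affinity_edges[ai + 1]:g})",
                "expression_bin_index": ei,
                "affinity_bin_index": ai,
                "predicted": n_pred,
                "detected": n_det,
                "fraction": n_det / n_pred if n_pred else np.nan,
            })
    grid = pd.DataFrame(rows)
    grid.attrs["n_excluded"] = n_excluded
    return grid
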
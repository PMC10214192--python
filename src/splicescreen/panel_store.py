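"""Build, persist and query a multi-group reference panel of splicing
quantifications.

The panel holds two matrices over the same samples: event-level inclusion
ratios (PSI, in [0, 1] with NaN for missing) and junction-level read
counts (non-negative integers; an absent junction is a zero row).  Events
and junctions are indexed by genomic coordinates, gene id and gene symbol.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ASEvent, SampleGroup, SpliceJunction

log = logging.getLogger(__name__)

PANEL_FORMAT_VERSION = 1

#: coordinate columns required per event-table dialect
COORD_COLUMNS = {
    "SE": ["exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
    "A5SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "A3SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "RI": ["riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
}

META_COLUMNS = ["GeneID", "geneSymbol", "chr", "strand"]
COUNT_COLUMNS = ["IJC_SAMPLE_1", "SJC_SAMPLE_1", "IncLevel1"]


class FormatError(ValueError):
    """Raised when an input file does not follow its declared dialect."""


# ---------------------------------------------------------------------------
# junction derivation
# ---------------------------------------------------------------------------

def _se_junctions(chrom: str, strand: str, c: dict) -> tuple[tuple, tuple]:
    alt_s, alt_e = int(c["exonStart_0base"]), int(c["exonEnd"])
    flanks = sorted(
        [(int(c["upstreamES"]), int(c["upstreamEE"])),
         (int(c["downstreamES"]), int(c["downstreamEE"]))]
    )
    left, right = flanks
    if not (left[1] <= alt_s and right[0] >= alt_e):
        raise ValueError("alternative exon not inside its flanking exons")
    inc = (
        SpliceJunction(chrom, left[1] + 1, alt_s, strand),
        SpliceJunction(chrom, alt_e + 1, right[0], strand),
    )
    skp = (SpliceJunction(chrom, left[1] + 1, right[0], strand),)
    return inc, skp


def _alt_ss_junctions(chrom: str, strand: str, c: dict) -> tuple[tuple, tuple]:
    # A5SS/A3SS share one dialect: a long and a short exon on one side of a
    # flanking exon.  Orientation is detected from the coordinates so that
    # the same code serves both types and both strands.
    long_s, long_e = int(c["longExonStart_0base"]), int(c["longExonEnd"])
    short_s, short_e = int(c["shortES"]), int(c["shortEE"])
    flank_s, flank_e = int(c["flankingES"]), int(c["flankingEE"])
    if flank_s >= long_e:  # flanking exon to the right
        inc = (SpliceJunction(chrom, long_e + 1, flank_s, strand),)
        skp = (SpliceJunction(chrom, short_e + 1, flank_s, strand),)
    elif flank_e <= long_s:  # flanking exon to the left
        inc = (SpliceJunction(chrom, flank_e + 1, long_s, strand),)
        skp = (SpliceJunction(chrom, flank_e + 1, short_s, strand),)
    else:
        raise ValueError("flanking exon overlaps the alternative exon")
    return inc, skp


def _ri_junctions(chrom: str, strand: str, c: dict) -> tuple[tuple, tuple]:
    # Retained isoform: two single-base boundary pseudo-junctions (first and
    # last intronic base) stand in for the exon-intron borders; the
    # non-retained isoform carries the true spliced junction.
    flanks = sorted(
        [(int(c["upstreamES"]), int(c["upstreamEE"])),
         (int(c["downstreamES"]), int(c["downstreamEE"]))]
    )
    left, right = flanks
    if left[1] >= right[0]:
        raise ValueError("retained-intron flanking exons overlap")
    inc = (
        SpliceJunction(chrom, left[1] + 1, left[1] + 1, strand),
        SpliceJunction(chrom, right[0], right[0], strand),
    )
    skp = (SpliceJunction(chrom, left[1] + 1, right[0], strand),)
    return inc, skp


_JUNCTION_BUILDERS = {
    "SE": _se_junctions,
    "A5SS": _alt_ss_junctions,
    "A3SS": _alt_ss_junctions,
    "RI": _ri_junctions,
}


def event_from_row(event_type: str, row: dict) -> ASEvent:
    """Build an :class:`ASEvent` from one event-table row (dict of strings)."""
    chrom = str(row["chr"])
    strand = str(row["strand"])
    coords = {k: int(row[k]) for k in COORD_COLUMNS[event_type]}
    inc, skp = _JUNCTION_BUILDERS[event_type](chrom, strand, coords)
    coord_key = ":".join(str(coords[k]) for k in COORD_COLUMNS[event_type])
    event_id = f"{event_type}@{chrom}:{strand}:{coord_key}"
    return ASEvent(
        event_id=event_id,
        event_type=event_type,
        gene_id=str(row["GeneID"]),
        gene_symbol=str(row["geneSymbol"]),
        chrom=chrom,
        strand=strand,
        coords=coords,
        inclusion_junctions=inc,
        skipping_junctions=skp,
    )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_csv_ints(text: str) -> list[int]:
    return [int(x) for x in str(text).split(",")]


def _parse_csv_floats(text: str) -> list[float]:
    out = []
    for x in str(text).split(","):
        x = x.strip()
        out.append(np.nan if x in ("NA", "nan", "") else float(x))
    return out


def recompute_psi(inc_count: int, skp_count: int,
                  n_inc_junctions: int, n_skp_junctions: int) -> float:
    """Inclusion ratio from summed junction counts, normalized by the number
    of junctions supporting each isoform (2 for an SE inclusion isoform)."""
    inc_eff = inc_count / n_inc_junctions
    skp_eff = skp_count / n_skp_junctions
    total = inc_eff + skp_eff
    if total == 0:
        return np.nan
    return inc_eff / total


def read_rmats_events(
    path: str | Path,
    event_type: str,
    sample_ids: list[str] | None = None,
) -> tuple[list[ASEvent], pd.DataFrame, pd.DataFrame]:
    """Read one event table (JC dialect) into events, a PSI matrix and a
    junction count matrix.

    Per-sample inclusion/skipping counts and inclusion levels are
    comma-separated in the ``*_SAMPLE_1`` / ``IncLevel1`` columns.  When the
    level field is NA it is recomputed from the counts.  The summed
    inclusion count of a row is split evenly across the isoform's junctions
    (remainder to the first) so that per-junction counts conserve the total.

    Returns ``(events, psi, sjc)`` with events in file order (duplicates of
    a coordinate tuple keep the first occurrence, with a warning).
    """
    if event_type not in COORD_COLUMNS:
        raise ValueError(f"unknown event type {event_type!r}")
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, no header")
        header = header_line.rstrip("\n").split("\t")
        required = META_COLUMNS + COORD_COLUMNS[event_type] + COUNT_COLUMNS
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        rows = []
        for line in fh:
            if line.strip():
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))

    events: list[ASEvent] = []
    seen: set[str] = set()
    psi_rows, sjc_acc = [], {}
    n_samples = None
    for row in rows:
        try:
            ev = event_from_row(event_type, row)
        except (ValueError, KeyError) as exc:
            log.warning("%s: rejected row (%s): %s", path, exc, row)
            continue
        if ev.event_id in seen:
            log.warning("%s: duplicate coordinates for %s; keeping first row",
                        path, ev.event_id)
            continue
        seen.add(ev.event_id)

        try:
            inc = _parse_csv_ints(row["IJC_SAMPLE_1"])
            skp = _parse_csv_ints(row["SJC_SAMPLE_1"])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer count field: {exc}") from None
        levels = _parse_csv_floats(row["IncLevel1"])
        if not (len(inc) == len(skp) == len(levels)):
            raise FormatError(
                f"{path}: count/level arity mismatch for {ev.event_id}")
        if n_samples is None:
            n_samples = len(inc)
        elif len(inc) != n_samples:
            raise FormatError(f"{path}: inconsistent sample count at {ev.event_id}")

        n_ij, n_sj = len(ev.inclusion_junctions), len(ev.skipping_junctions)
        psi = [lv if not np.isnan(lv) else recompute_psi(i, s, n_ij, n_sj)
               for lv, i, s in zip(levels, inc, skp)]
        events.append(ev)
        psi_rows.append(psi)

        for j_idx, j in enumerate(ev.inclusion_junctions):
            share = [i // n_ij + (i % n_ij if j_idx == 0 else 0) for i in inc]
            prev = sjc_acc.get(j.key())
            sjc_acc[j.key()] = share if prev is None else [a + b for a, b in zip(prev, share)]
        for j in ev.skipping_junctions:
            prev = sjc_acc.get(j.key())
            sjc_acc[j.key()] = list(skp) if prev is None else [a + b for a, b in zip(prev, skp)]

    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n_samples or 0)]
    elif n_samples is not None and len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: {n_samples} samples in file but {len(sample_ids)} ids given")

    psi_df = pd.DataFrame(psi_rows, index=[e.event_id for e in events],
                          columns=sample_ids, dtype=float)
    sjc_df = pd.DataFrame.from_dict(sjc_acc, orient="index", dtype=np.int64)
    if not sjc_df.empty:
        sjc_df.columns = sample_ids
    else:
        sjc_df = pd.DataFrame(index=pd.Index([], dtype=object),
                              columns=sample_ids, dtype=np.int64)
    return events, psi_df, sjc_df


_STAR_STRAND = {0: ".", 1: "+", 2: "-"}


def read_star_junctions(path: str | Path, sample_id: str | None = None) -> pd.Series:
    """Read a STAR-style splice-junction tab file into a count Series.

    Columns: chrom, intron start (1-based), intron end (1-based), strand
    code (0 undefined / 1 plus / 2 minus), motif, annotated, unique-read
    count, multi-read count, overhang.  Unique-read counts are kept.
    Strand code 0 is stored under the both-strand key ``.`` with a warning.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: expected >=7 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
                strand_code = int(fields[3])
                unique = int(fields[6])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate/count field") from None
            strand = _STAR_STRAND.get(strand_code)
            if strand is None:
                raise FormatError(f"{path}:{lineno}: bad strand code {strand_code}")
            if strand == ".":
                log.warning("%s:%d: undefined strand, stored as '.'", path, lineno)
            j = SpliceJunction(fields[0], start, end, strand)
            counts[j.key()] = counts.get(j.key(), 0) + unique
    s = pd.Series(counts, dtype=np.int64)
    s.name = sample_id or path.stem
    return s


def read_group_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sample/group manifest TSV (sample_id, group_id, role,
    total_mapped_reads)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group_id": str})
    required = {"sample_id", "group_id", "role", "total_mapped_reads"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# the panel
# ---------------------------------------------------------------------------

@dataclass
class ReferencePanel:
    """Indexed PSI and junction-count matrices over named sample groups."""

    groups: dict  # group_id -> SampleGroup
    events: dict  # event_id -> ASEvent
    psi: pd.DataFrame  # event_id x sample_id, float with NaN missing
    sjc: pd.DataFrame  # junction key x sample_id, int64
    _by_gene_id: dict = field(default_factory=dict, repr=False)
    _by_symbol: dict = field(default_factory=dict, repr=False)
    _by_junction: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._reindex()
        self._validate()

    def _reindex(self) -> None:
        self._by_gene_id, self._by_symbol, self._by_junction = {}, {}, {}
        for ev in self.events.values():
            self._by_gene_id.setdefault(ev.gene_id, []).append(ev.event_id)
            self._by_symbol.setdefault(ev.gene_symbol, []).append(ev.event_id)
            for j in ev.junctions():
                self._by_junction.setdefault(j.key(), []).append(ev.event_id)

    def _validate(self) -> None:
        sample_set = set(self.psi.columns)
        for g in self.groups.values():
            unknown = [s for s in g.sample_ids if s not in sample_set]
            if unknown:
                raise ValueError(
                    f"group {g.group_id}: sample(s) absent from inputs: {unknown}")
        counts: dict[str, int] = {}
        for g in self.groups.values():
            for s in g.sample_ids:
                counts[s] = counts.get(s, 0) + 1
        dupes = [s for s, c in counts.items() if c > 1]
        if dupes:
            raise ValueError(f"sample(s) assigned to more than one group: {dupes}")
        # every event junction must have a row in sjc; add zero rows if absent
        needed = [j.key() for ev in self.events.values() for j in ev.junctions()]
        missing = [k for k in dict.fromkeys(needed) if k not in self.sjc.index]
        if missing:
            zeros = pd.DataFrame(0, index=missing, columns=self.sjc.columns,
                                 dtype=np.int64)
            self.sjc = pd.concat([self.sjc, zeros])

    # -- queries ----------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.psi.columns)

    def groups_with_role(self, role: str) -> list:
        return [g for g in self.groups.values() if g.role == role]

    def samples_of(self, group_id: str) -> list:
        return list(self.groups[group_id].sample_ids)

    def total_mapped_reads(self) -> pd.Series:
        """Per-sample total mapped reads R, for CPM normalization."""
        out = {}
        for g in self.groups.values():
            for s in g.sample_ids:
                r = g.total_mapped_reads.get(s)
                if r is not None:
                    out[s] = r
        return pd.Series(out, dtype=float)

    def lookup(self, key: str) -> list:
        """Resolve an event id, gene id, gene symbol or junction key to the
        list of matching event ids."""
        if key in self.events:
            return [key]
        for index in (self._by_gene_id, self._by_symbol, self._by_junction):
            if key in index:
                return list(index[key])
        return []

    def event_junction_sums(self) -> pd.DataFrame:
        """Per-event, per-sample sum of read counts over all the event's
        junctions (inclusion + skipping)."""
        rows = np.empty((len(self.events), self.sjc.shape[1]), dtype=np.int64)
        sjc_vals = self.sjc
        for i, ev in enumerate(self.events.values()):
            keys = [j.key() for j in ev.junctions()]
            rows[i] = sjc_vals.loc[keys].to_numpy().sum(axis=0)
        return pd.DataFrame(rows, index=list(self.events), columns=self.sjc.columns)

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        """Persist to a versioned directory of TSV matrices plus a JSON
        sidecar index; :func:`load_panel` round-trips bit-exactly."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": PANEL_FORMAT_VERSION,
            "groups": [
                {"group_id": g.group_id, "role": g.role,
                 "sample_ids": list(g.sample_ids),
                 "total_mapped_reads": {k: int(v) for k, v in
                                        g.total_mapped_reads.items()}}
                for g in self.groups.values()
            ],
            "n_events": len(self.events),
            "n_junctions": int(self.sjc.shape[0]),
        }
        (directory / "panel.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True))
        ev_rows = []
        for ev in self.events.values():
            ev_rows.append({
                "event_id": ev.event_id,
                "event_type": ev.event_type,
                "gene_id": ev.gene_id,
                "gene_symbol": ev.gene_symbol,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "coords": json.dumps(ev.coords, sort_keys=True),
                "inclusion_junctions": ";".join(j.key() for j in ev.inclusion_junctions),
                "skipping_junctions": ";".join(j.key() for j in ev.skipping_junctions),
            })
        pd.DataFrame(ev_rows).to_csv(directory / "events.tsv", sep="\t", index=False)
        self.psi.to_csv(directory / "psi.tsv", sep="\t", na_rep="NA",
                        index_label="event_id")
        self.sjc.to_csv(directory / "sjc.tsv", sep="\t", index_label="junction")
        return directory


def load_panel(directory: str | Path) -> ReferencePanel:
    directory = Path(directory)
    meta = json.loads((directory / "panel.json").read_text())
    if meta.get("format_version") != PANEL_FORMAT_VERSION:
        raise FormatError(
            f"{directory}: unsupported panel format version "
            f"{meta.get('format_version')!r}")
    groups = {
        g["group_id"]: SampleGroup(
            group_id=g["group_id"], role=g["role"],
            sample_ids=list(g["sample_ids"]),
            total_mapped_reads={k: int(v) for k, v in
                                g["total_mapped_reads"].items()},
        )
        for g in meta["groups"]
    }
    ev_df = pd.read_csv(directory / "events.tsv", sep="\t", dtype=str)
    events = {}
    for _, r in ev_df.iterrows():
        ev = ASEvent(
            event_id=r["event_id"], event_type=r["event_type"],
            gene_id=r["gene_id"], gene_symbol=r["gene_symbol"],
            chrom=r["chrom"], strand=r["strand"],
            coords=json.loads(r["coords"]),
            inclusion_junctions=tuple(
                SpliceJunction.from_key(k)
                for k in str(r["inclusion_junctions"]).split(";") if k),
            skipping_junctions=tuple(
                SpliceJunction.from_key(k)
                for k in str(r["skipping_junctions"]).split(";") if k),
        )
        events[ev.event_id] = ev
    psi = pd.read_csv(directory / "psi.tsv", sep="\t", index_col="event_id",
                      na_values=["NA"]).astype(float)
    sjc = pd.read_csv(directory / "sjc.tsv", sep="\t", index_col="junction"
                      ).astype(np.int64)
    psi.columns = psi.columns.astype(str)
    sjc.columns = sjc.columns.astype(str)
    psi.index.name = None
    sjc.index.name = None
    return ReferencePanel(groups=groups, events=events, psi=psi, sjc=sjc)


def build_reference_panel(
    event_tables: list[tuple],
    junction_tables: dict | None,
    manifest: pd.DataFrame,
) -> ReferencePanel:
    """Assemble a :class:`ReferencePanel` from event tables, optional
    per-sample junction files and a group manifest.

    ``event_tables`` is a list of ``(path, event_type, sample_ids)``;
    ``junction_tables`` maps sample_id to a STAR-style junction file whose
    counts override/extend the counts inferred from event tables.
    """
    all_events: dict[str, ASEvent] = {}
    psi_parts, sjc_parts = [], []
    for path, event_type, sample_ids in event_tables:
        events, psi, sjc = read_rmats_events(path, event_type, sample_ids)
        for ev in events:
            if ev.event_id in all_events:
                log.warning("duplicate event across tables: %s", ev.event_id)
            else:
                all_events[ev.event_id] = ev
        psi_parts.append(psi)
        sjc_parts.append(sjc)

    psi = pd.concat(psi_parts, axis=1) if psi_parts else pd.DataFrame()
    psi = psi.loc[~psi.index.duplicated(keep="first")]
    psi = psi.loc[:, ~psi.columns.duplicated(keep="first")]
    if sjc_parts:
        sjc = pd.concat(sjc_parts, axis=1)
        sjc = sjc.T.groupby(level=0).first().T  # dedupe sample columns
        sjc = sjc.groupby(level=0).sum()  # merge junction rows across tables
    else:
        sjc = pd.DataFrame()

    if junction_tables:
        star = pd.DataFrame({sid: read_star_junctions(p, sid)
                             for sid, p in junction_tables.items()})
        star = star.fillna(0).astype(np.int64)
        sjc = star.combine_first(sjc) if not sjc.empty else star

    sjc = sjc.reindex(columns=psi.columns).fillna(0).astype(np.int64)

    groups = {}
    for group_id, sub in manifest.groupby("group_id", sort=False):
        roles = sub["role"].unique()
        if len(roles) != 1:
            raise ValueError(f"group {group_id}: conflicting roles {list(roles)}")
        groups[group_id] = SampleGroup(
            group_id=str(group_id), role=str(roles[0]),
            sample_ids=[str(s) for s in sub["sample_id"]],
            total_mapped_reads={str(r.sample_id): int(r.total_mapped_reads)
                                for r in sub.itertuples()},
        )
    present = set(psi.columns)
    absent = sorted(set(manifest["sample_id"].astype(str)) - present)
    if absent:
        raise ValueError(f"manifest sample(s) absent from inputs: {absent}")
    return ReferencePanel(groups=groups, events=all_events, psi=psi, sjc=sjc)


# ---------------------------------------------------------------------------
# coverage masking
# ---------------------------------------------------------------------------

def mask_low_coverage(
    panel: ReferencePanel,
    min_avg_total: float = 10.0,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Return a copy of the panel's PSI matrix with low-coverage values set
    to NaN.

    An event is masked in a sample group when the group mean of the summed
    read counts over all the event's junctions is strictly below
    ``min_avg_total`` (default 10); with ``per_sample=True`` each sample is
    masked on its own sum instead.  Counts are left untouched.
    """
    psi = panel.psi.copy()
    sums = panel.event_junction_sums()
    if per_sample:
        psi[sums < min_avg_total] = np.nan
        return psi
    for g in panel.groups.values():
        cols = g.sample_ids
        group_mean = sums[cols].mean(axis=1)
        masked_events = group_mean.index[group_mean < min_avg_total]
        psi.loc[masked_events, cols] = np.nan
    return psi
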
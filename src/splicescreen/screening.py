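"""In-silico screening of splicing events against the normal-tissue panel.

Four tests are implemented:

* ratio (PSI) based differential screen with a per-tissue two-sample
  t test and a delta-PSI threshold, summarized as a "degree of
  association" over the normal panel;
* a secondary junction-expression screen on CPM (count * 1e6 / total
  mapped reads) with a one-sided t test;
* a presence/absence specificity screen with a one-sided Fisher exact
  test per junction and normal tissue type;
* a recurrence screen replicating the ratio screen in auxiliary tumor
  cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel_store import ReferencePanel

log = logging.getLogger(__name__)

FC_DENOMINATOR_FLOOR = 0.01


@dataclass
class ScreenConfig:
    psi_p_threshold: float = 0.01
    delta_psi_threshold: float = 0.05
    equal_variance: bool = False
    association_degree_min: int = 8
    cpm_p_threshold: float = 0.01
    specificity_count_tumor: int = 5
    specificity_count_normal: int = 2
    specificity_p_threshold: float = 1e-6
    specificity_degree_min: int = 8
    min_tumor_nonmissing: int = 3
    recurrence_groups: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("psi_p_threshold", "delta_psi_threshold", "cpm_p_threshold",
                     "specificity_p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("association_degree_min", "specificity_degree_min",
                     "min_tumor_nonmissing", "specificity_count_tumor",
                     "specificity_count_normal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroupComparison:
    group_id: str
    p_value: float  # NaN when untestable
    delta_psi: float  # tumor mean - normal mean; NaN when untestable
    significant: bool
    direction: int  # +1 tumor higher, -1 tumor lower, 0 untestable/ns


@dataclass
class ScreenRecord:
    event_id: str
    comparisons: list = field(default_factory=list)
    degree_of_association: int = 0
    tumor_associated: bool = False
    tumor_enriched_isoform: str = "none"  # inclusion | skipping | none
    fold_change: float = float("nan")
    fc_denominator_floored: bool = False
    tumor_mean_psi: float = float("nan")
    junction_specificity: dict = field(default_factory=dict)
    tumor_specific: bool = False
    cpm_degree: dict = field(default_factory=dict)  # junction key -> degree
    cpm_pass: bool | None = None
    recurrent: bool | None = None
    skip_reason: str | None = None

    def to_row(self) -> dict:
        row = {
            "event_id": self.event_id,
            "degree_of_association": self.degree_of_association,
            "tumor_associated": self.tumor_associated,
            "tumor_enriched_isoform": self.tumor_enriched_isoform,
            "fold_change": self.fold_change,
            "fc_denominator_floored": self.fc_denominator_floored,
            "tumor_mean_psi": self.tumor_mean_psi,
            "tumor_specific": self.tumor_specific,
            "cpm_pass": self.cpm_pass,
            "recurrent": self.recurrent,
            "skip_reason": self.skip_reason,
        }
        for c in self.comparisons:
            row[f"p_{c.group_id}"] = c.p_value
            row[f"dpsi_{c.group_id}"] = c.delta_psi
        return row


# ---------------------------------------------------------------------------
# statistical primitives
# ---------------------------------------------------------------------------

def two_sample_t(
    x: np.ndarray,
    y: np.ndarray,
    equal_var: bool = False,
    alternative: str = "two-sided",
) -> float:
    """p-value of a two-sample t test (Welch by default).

    Degenerate zero-variance inputs take the limit value: p = 1 when the
    means are equal, p = 0 (or 1 against the alternative's direction) when
    they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        return np.nan
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        diff = x.mean() - y.mean()
        if diff == 0:
            return 1.0
        if alternative == "two-sided":
            return 0.0
        if alternative == "greater":
            return 0.0 if diff > 0 else 1.0
        return 0.0 if diff < 0 else 1.0
    res = stats.ttest_ind(x, y, equal_var=equal_var, alternative=alternative)
    return float(res.pvalue)


def fisher_exact_greater(
    k: np.ndarray, n_tumor: np.ndarray, m: np.ndarray, n_normal: np.ndarray
) -> np.ndarray:
    """Vectorized one-sided Fisher exact test for tumor enrichment.

    Table per element: ``[[k, n_tumor-k], [m, n_normal-m]]`` where k/m are
    the numbers of expressing samples.  Returns
    P(X >= k) under the hypergeometric null with N = n_tumor + n_normal
    draws of size n_tumor from K = k + m successes, i.e. exactly the
    one-sided Fisher p-value.
    """
    k = np.atleast_1d(np.asarray(k, dtype=np.int64))
    n_tumor = np.atleast_1d(np.asarray(n_tumor, dtype=np.int64))
    m = np.atleast_1d(np.asarray(m, dtype=np.int64))
    n_normal = np.atleast_1d(np.asarray(n_normal, dtype=np.int64))
    N = n_tumor + n_normal
    K = k + m
    p = stats.hypergeom.sf(k - 1, N, K, n_tumor)
    return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# ratio (PSI) screen
# ---------------------------------------------------------------------------

def tumor_association_screen(
    panel: ReferencePanel,
    masked_psi: pd.DataFrame,
    tumor_group: str,
    config: ScreenConfig,
) -> dict:
    """Run the per-tissue differential PSI screen for every event.

    A comparison against one normal tissue type is significant iff its
    two-sided t-test p-value is below ``psi_p_threshold`` AND
    ``|delta PSI|`` strictly exceeds ``delta_psi_threshold``.  The degree
    of association is the number of significant comparisons sharing one
    direction; any significant comparison in the opposite direction
    disqualifies the event.  Untestable comparisons (masked or too few
    samples) count as non-significant.
    """
    tumor_cols = panel.samples_of(tumor_group)
    normal_groups = panel.groups_with_role("normal_reference")
    if not normal_groups:
        raise ValueError("panel has no normal_reference groups")
    records: dict[str, ScreenRecord] = {}

    tumor_mat = masked_psi[tumor_cols].to_numpy()
    normal_mats = {g.group_id: masked_psi[g.sample_ids].to_numpy()
                   for g in normal_groups}

    for i, event_id in enumerate(masked_psi.index):
        rec = ScreenRecord(event_id=event_id)
        records[event_id] = rec
        tvals = tumor_mat[i]
        tvals = tvals[~np.isnan(tvals)]
        if len(tvals) < config.min_tumor_nonmissing:
            rec.skip_reason = "tumor_nonmissing_below_minimum"
            continue
        rec.tumor_mean_psi = float(tvals.mean())
        n_up = n_down = 0
        for g in normal_groups:
            nvals = normal_mats[g.group_id][i]
            nvals = nvals[~np.isnan(nvals)]
            if len(nvals) < 2:
                rec.comparisons.append(GroupComparison(
                    g.group_id, np.nan, np.nan, False, 0))
                continue
            delta = float(tvals.mean() - nvals.mean())
            p = two_sample_t(tvals, nvals, equal_var=config.equal_variance)
            sig = (p < config.psi_p_threshold
                   and abs(delta) > config.delta_psi_threshold)
            direction = int(np.sign(delta)) if sig else 0
            rec.comparisons.append(GroupComparison(g.group_id, p, delta, sig,
                                                   direction))
            n_up += direction > 0
            n_down += direction < 0
        rec.degree_of_association = max(n_up, n_down)
        consistent = not (n_up > 0 and n_down > 0)
        rec.tumor_associated = (consistent and
                                rec.degree_of_association >= config.association_degree_min)
        if rec.tumor_associated:
            direction = 1 if n_up > 0 else -1
            isoform, fc, floored = determine_enriched_isoform_and_fc(
                rec, tvals, normal_mats, i, direction)
            rec.tumor_enriched_isoform = isoform
            rec.fold_change = fc
            rec.fc_denominator_floored = floored
    return records


def determine_enriched_isoform_and_fc(
    record: ScreenRecord,
    tumor_vals: np.ndarray,
    normal_mats: dict,
    row: int,
    direction: int,
) -> tuple[str, float, bool]:
    """Enriched isoform (from the consistent direction of the significant
    delta PSI) and its fold change: tumor-isoform proportion over the
    unweighted mean of per-tissue mean proportions.  A zero denominator is
    floored at ``FC_DENOMINATOR_FLOOR`` and flagged.
    """
    isoform = "inclusion" if direction > 0 else "skipping"
    tumor_prop = float(np.mean(tumor_vals))
    group_means = []
    for mat in normal_mats.values():
        vals = mat[row]
        vals = vals[~np.isnan(vals)]
        if len(vals):
            group_means.append(float(vals.mean()))
    if isoform == "skipping":
        tumor_prop = 1.0 - tumor_prop
        group_means = [1.0 - m for m in group_means]
    if not group_means:
        return isoform, float("nan"), False
    denom = float(np.mean(group_means))
    floored = denom < FC_DENOMINATOR_FLOOR
    denom = max(denom, FC_DENOMINATOR_FLOOR)
    return isoform, tumor_prop / denom, floored


# ---------------------------------------------------------------------------
# CPM screen
# ---------------------------------------------------------------------------

def cpm_matrix(sjc: pd.DataFrame, total_mapped_reads: pd.Series) -> pd.DataFrame:
    """Counts-per-million: count * 1e6 / R per sample."""
    missing = [c for c in sjc.columns if c not in total_mapped_reads.index
               or not np.isfinite(total_mapped_reads[c])]
    if missing:
        raise ValueError(f"total mapped reads missing for sample(s): {missing}")
    factors = 1e6 / total_mapped_reads[sjc.columns]
    return sjc * factors


def sj_cpm_screen(
    panel: ReferencePanel,
    tumor_group: str,
    config: ScreenConfig,
    records: dict,
) -> pd.DataFrame:
    """One-sided (tumor > normal) t test on junction CPM per normal tissue
    type.  A junction passes when its CPM degree of association reaches
    ``association_degree_min``; an event's ``cpm_pass`` requires every
    junction of its tumor-enriched isoform to pass.
    """
    cpm = cpm_matrix(panel.sjc, panel.total_mapped_reads())
    tumor_cols = panel.samples_of(tumor_group)
    normal_groups = panel.groups_with_role("normal_reference")
    tested = sorted({j.key()
                     for rec in records.values() if rec.tumor_associated
                     for j in panel.events[rec.event_id].isoform_junctions(
                         rec.tumor_enriched_isoform)})
    rows = []
    degree_by_junction: dict[str, int] = {}
    for key in tested:
        tvals = cpm.loc[key, tumor_cols].to_numpy(dtype=float)
        degree = 0
        for g in normal_groups:
            nvals = cpm.loc[key, g.sample_ids].to_numpy(dtype=float)
            p = two_sample_t(tvals, nvals, equal_var=config.equal_variance,
                             alternative="greater")
            if not np.isnan(p) and p < config.cpm_p_threshold:
                degree += 1
        degree_by_junction[key] = degree
        rows.append({"junction": key, "cpm_degree": degree,
                     "cpm_pass": degree >= config.association_degree_min})
    for rec in records.values():
        if not rec.tumor_associated:
            rec.cpm_pass = None
            continue
        keys = [j.key() for j in panel.events[rec.event_id].isoform_junctions(
            rec.tumor_enriched_isoform)]
        rec.cpm_degree = {k: degree_by_junction.get(k, 0) for k in keys}
        rec.cpm_pass = all(degree_by_junction.get(k, 0) >=
                           config.association_degree_min for k in keys)
    return pd.DataFrame(rows).set_index("junction") if rows else pd.DataFrame(
        columns=["cpm_degree", "cpm_pass"])


# ---------------------------------------------------------------------------
# specificity screen
# ---------------------------------------------------------------------------

def tumor_specificity_screen(
    panel: ReferencePanel,
    tumor_group: str,
    config: ScreenConfig,
    records: dict,
) -> pd.DataFrame:
    """Presence/absence screen: per junction and normal tissue type, a
    one-sided Fisher exact test on the counts of samples expressing the
    junction at or above the role-specific read-count threshold (default
    tumor >= 5, normal >= 2).  A junction is tumor-specific when the number
    of tissue types with p below ``specificity_p_threshold`` reaches
    ``specificity_degree_min``; an event is tumor-specific when it is
    tumor-associated and every junction of its tumor-enriched isoform is.
    """
    tumor_cols = panel.samples_of(tumor_group)
    normal_groups = panel.groups_with_role("normal_reference")
    sjc = panel.sjc
    keys = list(sjc.index)
    t_mat = sjc[tumor_cols].to_numpy()
    t_expr = (t_mat >= config.specificity_count_tumor).sum(axis=1)
    n_tumor = len(tumor_cols)

    per_group = {}
    for g in normal_groups:
        n_mat = sjc[g.sample_ids].to_numpy()
        m_expr = (n_mat >= config.specificity_count_normal).sum(axis=1)
        n_norm = len(g.sample_ids)
        if n_norm == 0:
            per_group[g.group_id] = (np.full(len(keys), np.nan),
                                     np.zeros(len(keys)))
            continue
        p = fisher_exact_greater(t_expr, np.full_like(t_expr, n_tumor),
                                 m_expr, np.full_like(m_expr, n_norm))
        per_group[g.group_id] = (p, m_expr / n_norm)

    sig_counts = np.zeros(len(keys), dtype=int)
    for p, _frac in per_group.values():
        sig_counts += (np.nan_to_num(p, nan=1.0) < config.specificity_p_threshold)
    specific = sig_counts >= config.specificity_degree_min

    table = pd.DataFrame({
        "tumor_expressing_fraction": t_expr / max(n_tumor, 1),
        "n_significant_groups": sig_counts,
        "tumor_specific": specific,
    }, index=pd.Index(keys, name="junction"))
    for gid, (p, frac) in per_group.items():
        table[f"fisher_p_{gid}"] = p
        table[f"normal_fraction_{gid}"] = frac

    specific_by_key = dict(zip(keys, specific))
    for rec in records.values():
        ev = panel.events[rec.event_id]
        rec.junction_specificity = {
            j.key(): bool(specific_by_key.get(j.key(), False))
            for j in ev.junctions()}
        if rec.tumor_associated and rec.tumor_enriched_isoform != "none":
            iso_keys = [j.key() for j in
                        ev.isoform_junctions(rec.tumor_enriched_isoform)]
            rec.tumor_specific = all(specific_by_key.get(k, False)
                                     for k in iso_keys)
        else:
            rec.tumor_specific = False
    return table


# ---------------------------------------------------------------------------
# recurrence screen
# ---------------------------------------------------------------------------

def tumor_recurrence_screen(
    panel: ReferencePanel,
    masked_psi: pd.DataFrame,
    config: ScreenConfig,
    records: dict,
) -> None:
    """Replicate the ratio screen with each configured auxiliary tumor
    cohort as the query; an event is recurrent iff every cohort reproduces
    a tumor-associated call in the same direction.  With no cohorts
    configured, flags stay None.
    """
    cohorts = config.recurrence_groups or [
        g.group_id for g in panel.groups_with_role("tumor_reference")]
    if not cohorts:
        log.warning("no tumor_reference cohorts configured; "
                    "recurrence screen skipped")
        return
    aux_records = {c: tumor_association_screen(panel, masked_psi, c, config)
                   for c in cohorts}
    for event_id, rec in records.items():
        if not rec.tumor_associated:
            rec.recurrent = False
            continue
        primary_direction = 1 if rec.tumor_enriched_isoform == "inclusion" else -1
        ok = True
        for c in cohorts:
            aux = aux_records[c].get(event_id)
            if aux is None or not aux.tumor_associated:
                ok = False
                break
            aux_dir = 1 if aux.tumor_enriched_isoform == "inclusion" else -1
            if aux_dir != primary_direction:
                ok = False
                break
        rec.recurrent = ok


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_screens(
    panel: ReferencePanel,
    masked_psi: pd.DataFrame,
    tumor_group: str,
    config: ScreenConfig | None = None,
    with_cpm: bool = True,
    with_specificity: bool = True,
    with_recurrence: bool = True,
) -> tuple[dict, pd.DataFrame]:
    """Run all screens; returns (records, tabular summary)."""
    config = config or ScreenConfig()
    records = tumor_association_screen(panel, masked_psi, tumor_group, config)
    if with_cpm:
        sj_cpm_screen(panel, tumor_group, config, records)
    if with_specificity:
        tumor_specificity_screen(panel, tumor_group, config, records)
    if with_recurrence:
        tumor_recurrence_screen(panel, masked_psi, config, records)
    table = records_to_table(records)
    return records, table


def records_to_table(records: dict) -> pd.DataFrame:
    rows = [rec.to_row() for rec in records.values()]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("event_id")
        # optional BH-FDR over the per-group p-value columns, informational only
        pcols = [c for c in df.columns if c.startswith("p_")]
        for c in pcols:
            df[f"bh_{c}"] = _bh_fdr(df[c].to_numpy(dtype=float))
    return df


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    mask = ~np.isnan(p)
    pv = p[mask]
    n = len(pv)
    if n == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    q[mask] = out
    return q
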
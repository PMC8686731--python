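"""The decontamination cascade: raw read matrices -> presence/absence.

Canonical stage order (enforced by :func:`run_cascade`; permuting stages
is *not* equivalent and no reordering switch is offered):

1. negative-control filter, per primer set and replicate;
2. confidence-threshold taxonomy resolution (per-rank acceptance ladder);
3. ASV -> taxon collapse;
4. replicate-consistency filter, per primer set;
5. non-target (phylum) removal;
6. tag-jump rate estimation from the mock sample, then tag-jump filter,
   per primer set;
7. primer-set merge;
8. removal of mock and explicitly excluded taxa;
9. presence/absence conversion (empty specimens dropped and logged).

Every filter is a pointwise non-increasing map on counts.  Read totals
(specimen columns only) and row counts are tracked per stage in a
:class:`CascadeReport`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    FilterConfig,
    PresenceMatrix,
    PreyDnaError,
    ReadMatrix,
    ResolvedTaxon,
    Role,
    SampleMeta,
    TaxonomyTable,
    TaxonSampleTable,
    ValidationError,
    RESOLUTION_RANKS,
    roles_by_sample,
    specimen_sex,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class CascadeReport:
    """Per-stage bookkeeping mirroring read-count tracking through the
    pipeline.  ``stages`` entries: stage name, primer set, replicate,
    specimen-column read total, number of rows."""

    stages: list[dict] = field(default_factory=list)
    tag_jump_rates: dict[str, float] = field(default_factory=dict)
    tag_jump_threshold_basis: str = "column total at filter stage"
    removed_taxa: list[dict] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)

    def record(self, stage: str, counts: pd.DataFrame,
               specimen_cols: Sequence[str], primer_set: str | None = None,
               replicate: int | None = None) -> None:
        cols = [c for c in counts.columns if c in set(specimen_cols)]
        self.stages.append({
            "stage": stage,
            "primer_set": primer_set,
            "replicate": replicate,
            "reads_specimens": int(counts[cols].to_numpy().sum()),
            "n_rows": int(counts.shape[0]),
        })

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "stages": self.stages,
            "tag_jump_rates": self.tag_jump_rates,
            "tag_jump_threshold_basis": self.tag_jump_threshold_basis,
            "removed_taxa": self.removed_taxa,
            "dropped_samples": self.dropped_samples,
        }


def _negative_columns(m: ReadMatrix, meta: Sequence[SampleMeta]) -> list[str]:
    negs = {
        r.sample_id for r in meta
        if r.role is Role.NEGATIVE_CONTROL
        and r.primer_set == m.primer_set and r.replicate == m.replicate
    }
    return [c for c in m.sample_ids if c in negs]


def negative_control_filter(m: ReadMatrix,
                            meta: Sequence[SampleMeta]) -> ReadMatrix:
    """Zero any cell whose count does not exceed the maximum count of that
    ASV across the negative controls.

    The per-ASV threshold is the max over negatives ("any negative
    control" read conservatively); removal applies at <= threshold, so a
    specimen tied with a blank is treated as contamination.  Negative
    columns themselves are retained untouched for reporting.
    """
    neg_cols = _negative_columns(m, meta)
    if not neg_cols:
        warnings.warn(
            f"dataset ({m.primer_set!r}, rep {m.replicate}) has no negative "
            "controls; negative-control filter is a pass-through",
            stacklevel=2,
        )
        return m.copy_with(m.counts.copy())
    thresholds = m.counts[neg_cols].max(axis=1)
    out = m.counts.copy()
    other = [c for c in out.columns if c not in neg_cols]
    sub = out[other]
    out[other] = sub.where(sub.gt(thresholds, axis=0), 0)
    return m.copy_with(out)


def resolve_taxonomy(
    tax: TaxonomyTable, cfg: FilterConfig
) -> dict[str, ResolvedTaxon | None]:
    """Assign each ASV at the deepest rank whose confidence clears its
    threshold, demoting rank-by-rank; None means DISCARD (order failed).

    A missing label at an otherwise-accepted rank demotes further.
    """
    out: dict[str, ResolvedTaxon | None] = {}
    t = tax.table
    for asv in t.index:
        resolved = None
        for rank in RESOLUTION_RANKS:  # species -> order
            conf = float(t.at[asv, f"{rank}_conf"])
            label = str(t.at[asv, f"{rank}_label"])
            if conf >= cfg.rank_thresholds[rank] and label.strip():
                resolved = ResolvedTaxon(rank=rank, label=label)
                break
        out[asv] = resolved
    return out


def collapse_to_taxa(
    m: ReadMatrix,
    resolution: Mapping[str, ResolvedTaxon | None],
    tax: TaxonomyTable | None = None,
) -> TaxonSampleTable:
    """Sum reads of ASVs resolved to the same taxon; drop DISCARDed ASVs.

    When a taxonomy table is supplied, per-taxon phylum labels and mock
    flags are carried along for the later stages.
    """
    missing = [a for a in m.asv_ids if a not in resolution]
    if missing:
        raise ValidationError(f"resolution does not cover ASVs: {missing}")
    keys = []
    taxa: dict[str, ResolvedTaxon] = {}
    phyla: dict[str, str] = {}
    mock_keys: set[str] = set()
    kept_rows = []
    for asv in m.asv_ids:
        r = resolution[asv]
        if r is None:
            continue
        key = r.key()
        kept_rows.append(asv)
        keys.append(key)
        taxa[key] = r
        if tax is not None:
            phyla.setdefault(key, tax.label(asv, "phylum"))
            if bool(tax.table.at[asv, "is_mock"]):
                mock_keys.add(key)
    if kept_rows:
        grouped = m.counts.loc[kept_rows].groupby(pd.Index(keys, name="taxon"),
                                                  sort=True).sum()
    else:
        grouped = pd.DataFrame(
            np.zeros((0, len(m.sample_ids)), dtype=np.int64),
            columns=m.sample_ids,
        )
    return TaxonSampleTable(
        counts=grouped.astype("int64"),
        taxa=taxa,
        provenance=(m.primer_set,),
        replicate=m.replicate,
        taxon_phylum=phyla,
        mock_taxa=frozenset(mock_keys),
    )


def _outer_align(a: pd.DataFrame, b: pd.DataFrame
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = a.index.union(b.index)
    cols = a.columns.union(b.columns)
    return (a.reindex(index=rows, columns=cols, fill_value=0),
            b.reindex(index=rows, columns=cols, fill_value=0))


def replicate_consistency_filter(rep1: TaxonSampleTable,
                                 rep2: TaxonSampleTable) -> TaxonSampleTable:
    """Keep a (taxon, sample) cell only if both technical replicates
    produced reads there; kept cells carry the summed reads."""
    if {rep1.replicate, rep2.replicate} != {1, 2}:
        raise ValidationError(
            f"replicate labels must be {{1, 2}}, got "
            f"{{{rep1.replicate}, {rep2.replicate}}}"
        )
    if rep1.provenance != rep2.provenance:
        raise ValidationError("replicates come from different primer sets")
    c1, c2 = _outer_align(rep1.counts, rep2.counts)
    both = (c1 > 0) & (c2 > 0)
    merged = (c1 + c2).where(both, 0).astype("int64")
    taxa = {**rep2.taxa, **rep1.taxa}
    return TaxonSampleTable(
        counts=merged,
        taxa={k: taxa[k] for k in merged.index},
        provenance=rep1.provenance,
        replicate=None,
        taxon_phylum={**rep2.taxon_phylum, **rep1.taxon_phylum},
        mock_taxa=rep1.mock_taxa | rep2.mock_taxa,
    )


def remove_nontarget(t: TaxonSampleTable, cfg: FilterConfig,
                     report: CascadeReport | None = None) -> TaxonSampleTable:
    """Retain only taxa whose phylum equals the configured target."""
    if not t.taxon_phylum:
        raise ValidationError("no phylum labels available on this table")
    keep = [k for k in t.counts.index
            if t.taxon_phylum.get(k) == cfg.target_phylum]
    removed = [k for k in t.counts.index if k not in set(keep)]
    before = t.total_reads()
    out = t.copy_with(t.counts.loc[keep])
    if report is not None:
        for k in removed:
            report.removed_taxa.append(
                {"taxon": k, "reason": "non-target phylum "
                 + str(t.taxon_phylum.get(k))}
            )
    if before:
        logger.info("non-target removal retained %.1f%% of reads",
                    100.0 * out.total_reads() / before)
    return out


def _mock_sample_ids(meta: Sequence[SampleMeta],
                     columns: Iterable[str]) -> list[str]:
    mocks = {r.sample_id for r in meta if r.role is Role.MOCK}
    return [c for c in columns if c in mocks]


def estimate_tag_jump_rate(
    table: TaxonSampleTable | ReadMatrix,
    meta: Sequence[SampleMeta],
    mock_taxa: Iterable[str],
) -> float:
    """Estimate cross-sample read misassignment from the mock sample(s):
    reads assigned to non-mock taxa in mock samples, over total mock reads.

    ``mock_taxa`` lists row ids (taxon keys or ASV ids) of the expected
    mock-community members.
    """
    counts = table.counts
    mock_cols = _mock_sample_ids(meta, counts.columns)
    if not mock_cols:
        raise PreyDnaError("no mock sample present in this dataset")
    mock_rows = set(mock_taxa)
    sub = counts[mock_cols]
    total = int(sub.to_numpy().sum())
    if total == 0:
        raise PreyDnaError("mock sample(s) contain zero reads")
    is_mock_row = sub.index.isin(mock_rows)
    non_mock = int(sub.loc[~is_mock_row].to_numpy().sum())
    return non_mock / total


def tag_jump_filter(table, rate: float):
    """Zero cells whose count is strictly below rate x (column read total).

    The threshold is computed once per column from the totals at this
    stage, before any cell is zeroed.  Works on :class:`ReadMatrix` and
    :class:`TaxonSampleTable` alike.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"tag-jump rate must lie in [0,1], got {rate}")
    counts = table.counts
    col_totals = counts.sum(axis=0)
    thresh = rate * col_totals  # strict < keeps cells equal to threshold
    out = counts.where(counts.ge(thresh, axis=1), 0).astype("int64")
    return table.copy_with(out)


def merge_primer_sets(a: TaxonSampleTable,
                      b: TaxonSampleTable) -> TaxonSampleTable:
    """Combine two primer-set tables: taxon union, per-cell count sums."""
    if set(a.counts.columns) != set(b.counts.columns):
        raise ValidationError("primer-set tables cover different samples")
    ca, cb = _outer_align(a.counts, b.counts[a.counts.columns])
    taxa = {**b.taxa, **a.taxa}
    return TaxonSampleTable(
        counts=(ca + cb).astype("int64"),
        taxa={k: taxa[k] for k in ca.index},
        provenance=tuple(dict.fromkeys(a.provenance + b.provenance)),
        replicate=None,
        taxon_phylum={**b.taxon_phylum, **a.taxon_phylum},
        mock_taxa=a.mock_taxa | b.mock_taxa,
    )


def remove_excluded_taxa(t: TaxonSampleTable, cfg: FilterConfig,
                         report: CascadeReport | None = None
                         ) -> TaxonSampleTable:
    """Drop mock taxa and configured exclusion taxa (e.g. a parasite whose
    DNA plausibly reflects contamination rather than diet)."""
    excluded_labels = set(cfg.exclusion_taxa)
    drop = []
    for key in t.counts.index:
        if key in t.mock_taxa:
            drop.append((key, "mock community taxon"))
        elif t.taxa[key].label in excluded_labels:
            drop.append((key, "configured exclusion"))
    drop_keys = {k for k, _ in drop}
    out = t.copy_with(t.counts.loc[[k for k in t.counts.index
                                    if k not in drop_keys]])
    if report is not None:
        for k, why in drop:
            report.removed_taxa.append({"taxon": k, "reason": why})
    if out.counts.shape[0] == 0:
        warnings.warn("all taxa were excluded; table is empty", stacklevel=2)
    return out


def to_presence(t: TaxonSampleTable, meta: Sequence[SampleMeta]
                ) -> PresenceMatrix:
    """Binarise and keep specimen columns with at least one detection."""
    roles = roles_by_sample(meta)
    spec_cols = [c for c in t.counts.columns
                 if roles.get(c) is Role.SPECIMEN]
    return PresenceMatrix.from_counts(t.counts[spec_cols],
                                      specimen_sex(meta))


def run_cascade(
    datasets: Mapping[tuple[str, int], ReadMatrix],
    tax: TaxonomyTable,
    meta: Sequence[SampleMeta],
    cfg: FilterConfig,
) -> tuple[PresenceMatrix, CascadeReport]:
    """Run the full canonical cascade over all primer/replicate datasets."""
    report = CascadeReport()
    roles = roles_by_sample(meta)
    specimen_cols = [s for s, r in roles.items() if r is Role.SPECIMEN]

    resolution = resolve_taxonomy(tax, cfg)
    for asv, r in resolution.items():
        if r is None:
            report.removed_taxa.append(
                {"taxon": asv, "reason": "unresolved below order threshold"}
            )

    primer_sets = sorted({p for p, _ in datasets})
    per_primer: dict[str, TaxonSampleTable] = {}
    for primer in primer_sets:
        collapsed = {}
        for rep in (1, 2):
            if (primer, rep) not in datasets:
                raise ValidationError(
                    f"missing dataset ({primer!r}, replicate {rep})"
                )
            m = datasets[(primer, rep)]
            m.validate_against(meta)
            report.record("input", m.counts, specimen_cols, primer, rep)
            filtered = negative_control_filter(m, meta)
            report.record("negative_control_filter", filtered.counts,
                          specimen_cols, primer, rep)
            coll = collapse_to_taxa(filtered, resolution, tax)
            report.record("collapse_to_taxa", coll.counts,
                          specimen_cols, primer, rep)
            collapsed[rep] = coll
        merged_rep = replicate_consistency_filter(collapsed[1], collapsed[2])
        report.record("replicate_consistency_filter", merged_rep.counts,
                      specimen_cols, primer)
        arth = remove_nontarget(merged_rep, cfg, report)
        report.record("remove_nontarget", arth.counts, specimen_cols, primer)
        # rate is estimated from the replicate-*pooled* reads (sum of both
        # replicates, no consistency mask): the estimator wants every stray
        # read in the mock, and the consistency filter removes most of them
        c1, c2 = _outer_align(collapsed[1].counts, collapsed[2].counts)
        pooled_taxa = {**collapsed[2].taxa, **collapsed[1].taxa}
        pooled = TaxonSampleTable(
            counts=(c1 + c2).astype("int64"),
            taxa={k: pooled_taxa[k] for k in c1.index},
            provenance=collapsed[1].provenance,
            taxon_phylum={**collapsed[2].taxon_phylum,
                          **collapsed[1].taxon_phylum},
            mock_taxa=collapsed[1].mock_taxa | collapsed[2].mock_taxa,
        )
        try:
            rate = estimate_tag_jump_rate(pooled, meta, pooled.mock_taxa)
        except PreyDnaError as exc:
            warnings.warn(
                f"tag-jump rate not estimable for {primer!r} ({exc}); "
                "using 0", stacklevel=2,
            )
            rate = 0.0
        report.tag_jump_rates[primer] = rate
        cleaned = tag_jump_filter(arth, rate)
        report.record("tag_jump_filter", cleaned.counts, specimen_cols, primer)
        per_primer[primer] = cleaned

    merged = reduce(merge_primer_sets,
                    [per_primer[p] for p in primer_sets])
    report.record("merge_primer_sets", merged.counts, specimen_cols)
    final = remove_excluded_taxa(merged, cfg, report)
    report.record("remove_excluded_taxa", final.counts, specimen_cols)
    pm = to_presence(final, meta)
    report.dropped_samples = list(pm.dropped_samples)
    report.record("to_presence", pm.values, specimen_cols)
    return pm, report
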
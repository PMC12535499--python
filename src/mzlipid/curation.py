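"""Data cleaning and outcome labelling for identified metabolites.

Three rules turn a raw feature table into the modelling set:

1. **RT window** — features eluting at or before ``rt_low`` (column setup /
   dead time) or at or after ``rt_high`` (washing and re-equilibration) are
   excluded; both boundaries are exclusive on the kept side.
2. **Polarity deduplication** — a metabolite identified in both ionization
   modes is kept only in the preferred mode (negative by default, where
   identification coverage is typically larger); the rule keys on the HMDB
   accession and never touches unidentified features.
3. **Labelling** — identified features are mapped through the HMDB taxonomy
   and labelled ``lipid`` iff their super class is "Lipids and lipid-like
   molecules" (case-insensitive); everything else identified is
   ``non_lipid``.  Unidentified features and accessions missing from the
   taxonomy are excluded from modelling, never defaulted to a class.

The CurationReport partitions the input exactly:
``n_input == n_labeled + n_rt_excluded + n_polarity_dropped +
n_unidentified + n_unmapped``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import FeatureRecord, FeatureTable, TaxonomyMap

__all__ = [
    "LabeledExample",
    "CurationReport",
    "filter_rt_window",
    "deduplicate_polarity",
    "assign_labels",
    "curate",
    "DEFAULT_LIPID_CLASS",
    "LABEL_LIPID",
    "LABEL_NON_LIPID",
]

DEFAULT_LIPID_CLASS = "Lipids and lipid-like molecules"
LABEL_LIPID = "lipid"
LABEL_NON_LIPID = "non_lipid"


@dataclass(frozen=True)
class LabeledExample:
    """One curated, identified feature ready for modelling."""

    mz: float
    gradient_pct_a: float
    label: str
    hmdb_id: str
    source_feature_id: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.gradient_pct_a <= 100.0):
            raise ValueError(f"gradient_pct_a out of [0, 100]: {self.gradient_pct_a}")
        if self.label not in (LABEL_LIPID, LABEL_NON_LIPID):
            raise ValueError(f"label must be lipid/non_lipid, got {self.label!r}")


@dataclass
class CurationReport:
    """Bookkeeping for every feature the pipeline saw."""

    n_input: int = 0
    n_rt_excluded: int = 0
    n_polarity_dropped: int = 0
    n_unidentified: int = 0
    n_unmapped: int = 0
    n_labeled: int = 0
    rt_excluded_ids: list[str] = field(default_factory=list)
    polarity_dropped_ids: list[str] = field(default_factory=list)
    unidentified_ids: list[str] = field(default_factory=list)
    unmapped_ids: list[str] = field(default_factory=list)
    # accessions appearing on >1 record within one polarity (kept, flagged)
    within_polarity_duplicates: list[str] = field(default_factory=list)
    n_labeled_unique_accessions: int = 0
    n_lipid: int = 0
    n_non_lipid: int = 0

    def counts_partition_input(self) -> bool:
        return self.n_input == (
            self.n_labeled
            + self.n_rt_excluded
            + self.n_polarity_dropped
            + self.n_unidentified
            + self.n_unmapped
        )

    def summary_lines(self) -> list[str]:
        return [
            f"input features: {self.n_input}",
            f"excluded by RT window: {self.n_rt_excluded}",
            f"dropped by polarity preference: {self.n_polarity_dropped}",
            f"unidentified (no accession): {self.n_unidentified}",
            f"identified but unmapped in taxonomy: {self.n_unmapped}",
            f"labeled for modelling: {self.n_labeled} "
            f"({self.n_lipid} lipid / {self.n_non_lipid} non-lipid; "
            f"{self.n_labeled_unique_accessions} unique accessions)",
        ]


def filter_rt_window(
    table: FeatureTable, rt_low: float = 1.0, rt_high: float = 14.0
) -> tuple[FeatureTable, list[FeatureRecord]]:
    """Keep records with rt_low < rt_min < rt_high; both boundaries excluded."""
    if not rt_low < rt_high:
        raise ValueError("rt_low must be strictly below rt_high")
    kept, excluded = [], []
    for rec in table.records:
        if rt_low < rec.rt_min < rt_high:
            kept.append(rec)
        else:
            excluded.append(rec)
    return table.with_records(kept), excluded


def deduplicate_polarity(
    table: FeatureTable, preferred: str = "negative"
) -> tuple[FeatureTable, list[FeatureRecord]]:
    """Resolve dual-polarity identifications in favour of ``preferred``.

    For every accession seen on records of both polarities, all records of
    the non-preferred polarity carrying it are dropped.  Records without an
    accession, and single-polarity identifications, pass through untouched.
    """
    if preferred not in ("positive", "negative"):
        raise ValueError("preferred polarity must be 'positive' or 'negative'")
    polarities_of: dict[str, set[str]] = {}
    for rec in table.records:
        if rec.hmdb_id is not None:
            polarities_of.setdefault(rec.hmdb_id, set()).add(rec.polarity)
    dual = {acc for acc, pols in polarities_of.items() if len(pols) == 2}

    kept, dropped = [], []
    for rec in table.records:
        if rec.hmdb_id in dual and rec.polarity != preferred:
            dropped.append(rec)
        else:
            kept.append(rec)
    return table.with_records(kept), dropped


def assign_labels(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    lipid_class: str = DEFAULT_LIPID_CLASS,
    report: Optional[CurationReport] = None,
) -> tuple[list[LabeledExample], CurationReport]:
    """Attach the binary outcome from HMDB super classes.

    Records must already carry ``gradient_pct_a``.  Returns the labelled
    examples in input order plus the (possibly pre-seeded) report with the
    identification/labelling counts filled in.
    """
    rep = report if report is not None else CurationReport(n_input=len(table))
    examples: list[LabeledExample] = []
    lipid_key = lipid_class.strip().lower()
    seen_in_polarity: dict[tuple[str, str], int] = {}

    for rec in table.records:
        if rec.hmdb_id is None:
            rep.n_unidentified += 1
            rep.unidentified_ids.append(rec.feature_id)
            continue
        super_class = taxonomy.get(rec.hmdb_id)
        if super_class is None:
            rep.n_unmapped += 1
            rep.unmapped_ids.append(rec.feature_id)
            continue
        if rec.gradient_pct_a is None:
            raise ValueError(
                f"record {rec.feature_id} lacks gradient_pct_a; "
                "run annotate_gradient before labelling"
            )
        key = (rec.hmdb_id, rec.polarity)
        seen_in_polarity[key] = seen_in_polarity.get(key, 0) + 1
        label = (
            LABEL_LIPID
            if super_class.strip().lower() == lipid_key
            else LABEL_NON_LIPID
        )
        examples.append(
            LabeledExample(
                mz=rec.mz,
                gradient_pct_a=rec.gradient_pct_a,
                label=label,
                hmdb_id=rec.hmdb_id,
                source_feature_id=rec.feature_id,
            )
        )

    rep.n_labeled = len(examples)
    rep.n_lipid = sum(1 for ex in examples if ex.label == LABEL_LIPID)
    rep.n_non_lipid = rep.n_labeled - rep.n_lipid
    rep.n_labeled_unique_accessions = len({ex.hmdb_id for ex in examples})
    rep.within_polarity_duplicates = sorted(
        {acc for (acc, _pol), n in seen_in_polarity.items() if n > 1}
    )
    return examples, rep


def curate(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    rt_low: float = 1.0,
    rt_high: float = 14.0,
    preferred_polarity: str = "negative",
    lipid_class: str = DEFAULT_LIPID_CLASS,
) -> tuple[list[LabeledExample], CurationReport]:
    """Full cleaning pipeline: RT window -> polarity dedup -> labelling."""
    report = CurationReport(n_input=len(table))
    windowed, rt_excluded = filter_rt_window(table, rt_low, rt_high)
    report.n_rt_excluded = len(rt_excluded)
    report.rt_excluded_ids = [r.feature_id for r in rt_excluded]

    deduped, dropped = deduplicate_polarity(windowed, preferred_polarity)
    report.n_polarity_dropped = len(dropped)
    report.polarity_dropped_ids = [r.feature_id for r in dropped]

    examples, report = assign_labels(deduped, taxonomy, lipid_class, report)
    assert report.counts_partition_input(), "curation counts must partition the input"
    return examples, report
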
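"""Protein inclusion/exclusion rules and condition-overlap accounting.

"Detected" always means an observed, non-missing, non-zero raw count;
imputed cells never count as detection. Each rule is evaluated on the raw
evidence independently of the others, so rule verdicts are order-free and
the report records every rule's verdict per protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import FoldChangeMatrix

__all__ = [
    "FilterReport",
    "OverlapSummary",
    "exclusion_filter",
    "cluster_inclusion_filter",
    "condition_overlap",
    "percentage",
]


@dataclass
class FilterReport:
    """Per-protein boolean verdicts, one column per rule, plus the final call."""

    table: pd.DataFrame
    rule_order: list[str]

    @property
    def passed(self) -> pd.Series:
        return self.table["pass"]

    def counts(self) -> pd.Series:
        """Number of proteins failing each rule (independently evaluated)."""
        return (~self.table[self.rule_order]).sum(axis=0)


@dataclass
class OverlapSummary:
    """Per-age-group condition membership accounting (Venn counts)."""

    condition_sets: dict[str, dict[str, set[str]]]
    totals: dict[str, int] = field(init=False)
    common: dict[str, int] = field(init=False)
    common_pct: dict[str, int] = field(init=False)
    unique_counts: dict[str, dict[str, int]] = field(init=False)
    mean_unique: dict[str, float] = field(init=False)
    mean_unique_pct: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.totals, self.common, self.common_pct = {}, {}, {}
        self.unique_counts, self.mean_unique, self.mean_unique_pct = {}, {}, {}
        for age, sets in self.condition_sets.items():
            union = set().union(*sets.values())
            inter = set.intersection(*sets.values()) if sets else set()
            self.totals[age] = len(union)
            self.common[age] = len(inter)
            self.common_pct[age] = percentage(len(inter), len(union))
            uniq = {}
            for cond, members in sets.items():
                others = set().union(*(s for c, s in sets.items() if c != cond))
                uniq[cond] = len(members - others)
            self.unique_counts[age] = uniq
            self.mean_unique[age] = float(np.mean(list(uniq.values())))
            self.mean_unique_pct[age] = percentage(self.mean_unique[age], len(union))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for age in self.condition_sets:
            rows.append(
                {
                    "age_group": age,
                    "total": self.totals[age],
                    "common": self.common[age],
                    "common_pct": self.common_pct[age],
                    "mean_unique": self.mean_unique[age],
                    "mean_unique_pct": self.mean_unique_pct[age],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            age: {
                "total": self.totals[age],
                "common": self.common[age],
                "common_pct": self.common_pct[age],
                "unique_counts": dict(self.unique_counts[age]),
                "mean_unique": self.mean_unique[age],
                "mean_unique_pct": self.mean_unique_pct[age],
            }
            for age in self.condition_sets
        }


def percentage(count: float, total: int) -> int:
    """Integer percent with round-half-up (617/1519 -> 41, 565/1717 -> 33)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(count / total * 100.0 + 0.5))


def _detected(m: pd.DataFrame) -> pd.DataFrame:
    return m.notna() & (m > 0)


def exclusion_filter(m: pd.DataFrame, samples: pd.DataFrame) -> FilterReport:
    """Exclude proteins whose only evidence is a single count of exactly 1.

    A protein is excluded when it is detected in exactly one sample of one
    condition and that single count equals 1 (i.e. the entire detection
    evidence is one spectrum).
    """
    missing = [s for s in m.columns if s not in samples.index]
    if missing:
        raise ValueError(f"samples without sheet annotation: {missing}")
    det = _detected(m)
    n_detected = det.sum(axis=1)
    max_count = m.where(det).max(axis=1)
    single_spectrum = (n_detected == 1) & (max_count == 1)
    table = pd.DataFrame(
        {
            "single_count_of_one": ~single_spectrum,
            "pass": ~single_spectrum,
        },
        index=m.index,
    )
    return FilterReport(table=table, rule_order=["single_count_of_one"])


def cluster_inclusion_filter(
    fc: FoldChangeMatrix,
    m: pd.DataFrame,
    samples: pd.DataFrame,
    fc_threshold: float = 2.0,
    spectra_scope: str = "age_group",
) -> pd.DataFrame:
    """Which proteins enter clustering, per (age_group, treatment) condition.

    A protein enters a condition's cluster analysis iff (a) its summed raw
    spectra are >= 2 within the scope, (b) it is detected in >= 2
    biological samples within the scope, and (c) its per-subject fold
    change is >= ``fc_threshold`` in strictly more than half of that
    condition's paired replicates. ``spectra_scope`` sets the sample scope
    of rules (a)/(b): all samples of the age group (default) or only the
    condition's own samples (``"condition"``).

    Returns a boolean DataFrame (proteins x conditions MultiIndex) of the
    conjunction, with the three rule verdicts available via the attribute
    ``rules`` (dict of DataFrames).
    """
    if spectra_scope not in ("age_group", "condition"):
        raise ValueError(f"unknown spectra_scope {spectra_scope!r}")
    det = _detected(m)
    counts = m.fillna(0.0)
    conditions = list(fc.per_subject.columns.droplevel("subject_id").unique())
    rule_a, rule_b, rule_c = {}, {}, {}
    for age, treatment in conditions:
        if spectra_scope == "age_group":
            scope = samples.index[(samples["age_group"] == age)]
        else:
            scope = samples.index[
                (samples["age_group"] == age) & (samples["treatment"] == treatment)
            ]
        scope = [s for s in scope if s in m.columns]
        rule_a[(age, treatment)] = counts[scope].sum(axis=1) >= 2
        rule_b[(age, treatment)] = det[scope].sum(axis=1) >= 2
        sub = fc.per_subject.xs((age, treatment), axis=1, level=["age_group", "treatment"])
        n_rep = sub.shape[1]
        rule_c[(age, treatment)] = (sub >= fc_threshold).sum(axis=1) > n_rep / 2.0
    cols = pd.MultiIndex.from_tuples(conditions, names=["age_group", "treatment"])
    a = pd.DataFrame(rule_a)[list(cols)].set_axis(cols, axis=1)
    b = pd.DataFrame(rule_b)[list(cols)].set_axis(cols, axis=1)
    c = pd.DataFrame(rule_c)[list(cols)].set_axis(cols, axis=1)
    result = a & b & c
    result.attrs["rules"] = {"min_spectra": a, "min_samples": b, "fold_change_majority": c}
    return result


def condition_overlap(
    m: pd.DataFrame,
    samples: pd.DataFrame,
    exclusions: FilterReport | None = None,
    apply_exclusion: bool = True,
) -> OverlapSummary:
    """Per-age-group condition membership sets and their Venn accounting.

    A protein belongs to a condition when it is detected (observed,
    non-zero) in at least one of that condition's samples. The exclusion
    filter is applied first by default.
    """
    keep = m.index
    if apply_exclusion:
        report = exclusions if exclusions is not None else exclusion_filter(m, samples)
        keep = m.index[report.passed.loc[m.index]]
    det = _detected(m.loc[keep])
    sets: dict[str, dict[str, set[str]]] = {}
    for age, age_samples in samples.groupby("age_group", sort=True):
        conds: dict[str, set[str]] = {}
        for treatment, grp in age_samples.groupby("treatment", sort=True):
            cols = [s for s in grp.index if s in det.columns]
            if not cols:
                continue
            mask = det[cols].any(axis=1)
            if not mask.any():
                continue  # a condition with no detections is not a data set
            conds[treatment] = set(det.index[mask])
        if len(conds) >= 2:
            sets[age] = conds
    if not sets:
        raise ValueError("need at least two conditions in at least one age group")
    return OverlapSummary(condition_sets=sets)
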
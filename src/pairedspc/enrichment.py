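"""Gene-set over-representation for significant-protein lists.

One 2x2 table per set — (in query & in set, in query & not, not in query &
in set, neither) — tested with Fisher's exact test, one-sided (greater) by
default since over-representation is a right-tail question; the sample
odds ratio accompanies each p. ``ease_variant`` applies the conservative
jackknife used by DAVID's EASE score: one member is removed from the
overlap cell before taking the right tail, so single-member overlaps can
never be significant. Reporting filters mirror the convention of keeping
only pathways hit by more than one protein at p < 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import GeneSetCollection
from .stats import fisher_exact

__all__ = ["enrich", "table3_filter", "ease_variant"]


def _overlap_table(query: set, members: set, universe: set) -> tuple[int, int, int, int]:
    a = len(query & members)
    b = len(query - members)
    c = len(members - query)
    d = len(universe) - a - b - c
    return a, b, c, d


def enrich(
    query,
    sets: GeneSetCollection,
    universe,
    alternative: str = "greater",
    jackknife: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each set, against ``universe``.

    ``query`` must be a subset of ``universe``; set members are
    intersected with the universe before testing and sets that end up
    disjoint from it are skipped with a warning. Results are sorted by p.
    With ``jackknife`` the overlap cell is reduced by one before taking
    the (one-sided) tail — the EASE convention.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query)
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query proteins outside the universe: {stray}")
    rows = []
    for name, members in sets.sets.items():
        members_u = set(members) & universe
        if not members_u:
            warnings.warn(f"set {name!r} is disjoint from the universe; skipped", stacklevel=2)
            continue
        a, b, c, d = _overlap_table(query, members_u, universe)
        res = fisher_exact([[a, b], [c, d]], alternative=alternative)
        oratio = res.odds_ratio
        p = res.p
        if jackknife:
            # EASE: right tail taken from overlap - 1 under the same margins
            p = float(min(1.0, _sps.hypergeom.sf(a - 2, a + b + c + d, a + c, a + b)))
        with np.errstate(divide="ignore"):
            mlp = float(-np.log10(p)) if p > 0 else np.inf
        rows.append(
            {
                "set_name": name,
                "overlap": a,
                "set_size": len(members_u),
                "query_size": len(query),
                "universe_size": len(universe),
                "p": p,
                "odds_ratio": oratio,
                "minus_log10_p": mlp,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "overlap",
            "set_size",
            "query_size",
            "universe_size",
            "p",
            "odds_ratio",
            "minus_log10_p",
        ],
    )
    return out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)


def table3_filter(
    results: pd.DataFrame | dict[str, pd.DataFrame],
    min_overlap: int = 2,
    alpha: float = 0.05,
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Reporting filter: overlap >= ``min_overlap`` in at least one data
    set AND p < ``alpha`` in at least one data set; named exclusions (e.g.
    disease-specific pathways) dropped.

    ``results`` is either a single enrichment table or a dict keyed by
    data-set label (e.g. age group); with a dict, per-data-set overlap and
    p columns are suffixed with the label in the output.
    """
    if isinstance(results, pd.DataFrame):
        results = {"all": results}
    merged: pd.DataFrame | None = None
    for label, df in results.items():
        cols = df[["set_name", "overlap", "p", "odds_ratio", "minus_log10_p"]].copy()
        cols = cols.rename(
            columns={c: f"{c}_{label}" for c in cols.columns if c != "set_name"}
        )
        merged = cols if merged is None else merged.merge(cols, on="set_name", how="outer")
    assert merged is not None
    overlap_cols = [c for c in merged.columns if c.startswith("overlap_")]
    p_cols = [c for c in merged.columns if c.startswith("p_")]
    keep = (merged[overlap_cols].fillna(0) >= min_overlap).any(axis=1) & (
        merged[p_cols].fillna(1.0) < alpha
    ).any(axis=1)
    if exclude:
        keep &= ~merged["set_name"].isin(set(exclude))
    return merged.loc[keep].reset_index(drop=True)


def ease_variant(query, sets: GeneSetCollection, universe, alpha: float = 0.05) -> pd.DataFrame:
    """EASE-score variant: one-sided Fisher with the overlap cell reduced by 1.

    Conservative by construction (p_EASE >= p_Fisher on every table); a
    single-member overlap gives p = 1. Adds a ``significant`` column at
    ``alpha``.
    """
    out = enrich(query, sets, universe, alternative="greater", jackknife=True)
    out["significant"] = out["p"] < alpha
    return out
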
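"""Cross-omics concordance between a secretome and a transcriptome layer.

Workflow: quantile-normalize the probe x sample intensity matrix, call
per-gene changes between two timepoints with the exact paired Wilcoxon
signed-rank test (min-p probe per gene), join genes to secretome proteins
through an id map, encode each layer's call as a ternary -1/0/+1 against a
fixed measurable background, and test the association of the two ternary
vectors with Kendall tau-b. "Concordant" molecules are significant in both
layers with the same sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _st

__all__ = [
    "quantile_normalize",
    "call_gene_changes",
    "match_molecules",
    "concordance_test",
    "go_overlap_fraction",
    "ConcordanceResult",
    "GoOverlap",
]


def quantile_normalize(e: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization of a probe x sample matrix.

    Each column's ranks are mapped to the cross-column mean of order
    statistics; ties within a column receive the mean of their tied
    reference values. Afterwards all columns share the same multiset of
    values (up to tie averaging). Idempotent and rank-preserving per
    column. Missing intensities are rejected.
    """
    if e.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    vals = e.to_numpy(dtype=float)
    n, k = vals.shape
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(k):
        col = vals[:, j]
        ranks = np.empty(n, dtype=np.int64)
        ranks[order[:, j]] = np.arange(n)
        mapped = ref[ranks]
        # average the reference values over tied groups
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < n:
            sums = np.bincount(inv, weights=mapped)
            counts = np.bincount(inv)
            mapped = (sums / counts)[inv]
        out[:, j] = mapped
    return pd.DataFrame(out, index=e.index, columns=e.columns)


def call_gene_changes(
    e: pd.DataFrame,
    annotation: pd.DataFrame,
    from_tp: str,
    to_tp: str,
    probe_map: pd.DataFrame,
    alpha: float = 0.05,
    participants: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene paired change calls between two timepoints.

    For every probe the paired Wilcoxon signed-rank test is applied to the
    (to - from) differences across participants; the direction is the sign
    of the median paired difference. Each gene is represented by its
    minimum-p probe (ties broken by probe id). Probes without a gene
    mapping are retained under their own id with a warning.
    """
    for tp in (from_tp, to_tp):
        if tp not in set(annotation["timepoint"]):
            raise ValueError(f"timepoint {tp!r} absent from annotation")
    ann = annotation.copy()
    ann["sample_id"] = ann.index
    if participants is not None:
        ann = ann[ann["participant"].isin(participants)]
    from_by_part = ann[ann["timepoint"] == from_tp].set_index("participant")["sample_id"]
    to_by_part = ann[ann["timepoint"] == to_tp].set_index("participant")["sample_id"]
    shared = sorted(set(from_by_part.index) & set(to_by_part.index))
    if len(shared) < 2:
        raise ValueError("need both timepoints for at least two participants")
    from_by_part = from_by_part.loc[shared]
    to_by_part = to_by_part.loc[shared]
    diffs = e[list(to_by_part)].to_numpy(dtype=float) - e[list(from_by_part)].to_numpy(dtype=float)

    gene_of = dict(zip(probe_map["source_id"], probe_map["target_id"]))
    unmapped = [p for p in e.index if p not in gene_of]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} probe(s) without gene mapping retained under their own ids",
            stacklevel=2,
        )
    w, p = _st.wilcoxon_signed_rank_batch(diffs)
    per_probe = pd.DataFrame(
        {
            "probe": e.index,
            "gene_id": [gene_of.get(pr, pr) for pr in e.index],
            "p": p,
            "direction": np.sign(np.median(diffs, axis=1)),
            "statistic": w,
        }
    )
    per_probe = per_probe.sort_values(["gene_id", "p", "probe"], kind="stable")
    best = per_probe.groupby("gene_id", sort=True).first().reset_index()
    best["significant"] = best["p"] < alpha
    best = best.rename(columns={"probe": "representative_probe"})
    return best[["gene_id", "representative_probe", "statistic", "p", "direction", "significant"]]


def match_molecules(
    genes: pd.DataFrame,
    proteins: pd.DataFrame,
    id_map: pd.DataFrame,
    keep_unmatched_genes: bool = False,
) -> pd.DataFrame:
    """Join gene calls to protein calls through a gene -> protein map.

    Many-to-many mappings keep each (gene, protein) pair once. Unmatched
    molecules on either side are counted in the result's ``attrs``. An
    empty intersection yields an empty frame with a warning, not an error.
    With ``keep_unmatched_genes`` measured genes without a protein partner
    are retained (protein columns NaN, treated as not significant
    downstream), so the concordance background can consist of the actually
    measured platform rather than synthetic all-zero entries.
    """
    m = id_map.drop_duplicates(subset=["source_id", "target_id"])
    g = genes.rename(columns={c: f"gene_{c}" for c in genes.columns if c != "gene_id"})
    prot = proteins.reset_index().rename(columns={proteins.index.name or "index": "protein_id"})
    prot = prot.rename(columns={c: f"protein_{c}" for c in prot.columns if c != "protein_id"})
    joined = (
        m.rename(columns={"source_id": "gene_id", "target_id": "protein_id"})
        .merge(g, on="gene_id", how="inner")
        .merge(prot, on="protein_id", how="inner")
    )
    if keep_unmatched_genes:
        extra = g[~g["gene_id"].isin(set(joined["gene_id"]))].copy()
        extra["protein_id"] = pd.NA
        joined = pd.concat([joined, extra], ignore_index=True)
    joined = joined.drop_duplicates(subset=["gene_id", "protein_id"]).reset_index(drop=True)
    if joined.empty:
        warnings.warn("no molecules shared between the two layers", stacklevel=2)
    joined.attrs["n_unmatched_genes"] = int(len(set(g["gene_id"]) - set(joined["gene_id"])))
    joined.attrs["n_unmatched_proteins"] = int(
        len(set(prot["protein_id"]) - set(joined["protein_id"]))
    )
    return joined


@dataclass
class ConcordanceResult:
    """Ternary-call association between two omics layers.

    ``n_concordant`` counts molecules significant in both layers with the
    same sign; ``tau_b``/``p`` test the association of the two ternary
    vectors over a fixed background of ``background_n`` measurable
    molecules (unmatched background molecules contribute (0, 0))."""

    n_matched: int
    n_concordant: int
    background_n: int
    tau_b: float
    p: float
    secretome_calls: np.ndarray
    transcriptome_calls: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "n_concordant": self.n_concordant,
            "background_n": self.background_n,
            "tau_b": None if np.isnan(self.tau_b) else float(self.tau_b),
            "p": float(self.p),
        }


def concordance_test(
    matched: pd.DataFrame, background_n: int = 12893, alpha: float = 0.05
) -> ConcordanceResult:
    """Kendall tau-b association of ternary calls against a fixed background.

    ``matched`` needs columns gene_significant, gene_direction,
    protein_significant and protein_log2fc (as produced by
    ``match_molecules`` on a gene-call table and a differential result).
    """
    n_matched = len(matched)
    if background_n < n_matched:
        raise ValueError(
            f"background_n ({background_n}) smaller than matched set ({n_matched})"
        )
    if n_matched:
        trans = np.where(
            matched["gene_significant"].astype("boolean").fillna(False).to_numpy(dtype=bool),
            np.sign(matched["gene_direction"].astype(float).fillna(0.0).to_numpy()),
            0.0,
        )
        sec = np.where(
            matched["protein_significant"].astype("boolean").fillna(False).to_numpy(dtype=bool),
            np.sign(matched["protein_log2fc"].astype(float).fillna(0.0).to_numpy()),
            0.0,
        )
    else:
        trans = np.zeros(0)
        sec = np.zeros(0)
    pad = background_n - n_matched
    sec_full = np.concatenate([sec, np.zeros(pad)])
    trans_full = np.concatenate([trans, np.zeros(pad)])
    n_conc = int(((sec != 0) & (trans != 0) & (sec == trans)).sum())
    res = _st.kendall_tau_b(sec_full, trans_full)
    return ConcordanceResult(
        n_matched=n_matched,
        n_concordant=n_conc,
        background_n=background_n,
        tau_b=res.statistic,
        p=res.p,
        secretome_calls=sec,
        transcriptome_calls=trans,
    )


@dataclass
class GoOverlap:
    """Fraction of the secretome's significant terms found in both layers."""

    n_secretome: int
    n_transcriptome: int
    n_intersection: int
    fraction: float
    intersection: set


def go_overlap_fraction(secretome_terms, transcriptome_terms) -> GoOverlap:
    """Term co-occurrence, |intersection| / |secretome term set|."""
    s = set(secretome_terms)
    t = set(transcriptome_terms)
    if not s:
        raise ValueError("secretome term set must be non-empty")
    inter = s & t
    return GoOverlap(
        n_secretome=len(s),
        n_transcriptome=len(t),
        n_intersection=len(inter),
        fraction=len(inter) / len(s),
        intersection=inter,
    )
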
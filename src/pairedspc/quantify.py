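"""Spectral-count preprocessing: imputation, normalization, fold change.

The preprocessing chain for the cluster analysis is: impute missing counts
at half the data set's minimum observed positive SpC (0.5 when the minimum
is 1), scale every sample to the maximum column total, form per-subject
treated/control fold changes, average log2 fold changes per condition, and
z-score rows. Length normalization (counts per residue) feeds only the
differential model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PairedDesign

__all__ = [
    "NormalizedMatrix",
    "FoldChangeMatrix",
    "impute_half_min",
    "normalize_total_spc",
    "length_normalize",
    "fold_change",
    "zscore_rows",
]


@dataclass
class NormalizedMatrix:
    """A count matrix with per-cell provenance.

    ``imputed`` flags cells that were filled by half-minimum imputation;
    ``factors`` are the per-sample scaling factors applied by total-SpC
    normalization (None before normalization); ``floor`` is the imputation
    value on the *raw* count scale.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame
    factors: pd.Series | None = None
    floor: float | None = None

    def provenance(self) -> pd.DataFrame:
        """Per-protein audit: number of imputed cells."""
        return pd.DataFrame({"n_imputed": self.imputed.sum(axis=1)})


@dataclass
class FoldChangeMatrix:
    """Per-subject fold changes and per-condition mean log2 fold changes.

    ``per_subject`` columns are a (age_group, treatment, subject_id)
    MultiIndex of treated/control ratios; ``mean_log2`` columns are a
    (age_group, treatment) MultiIndex of arithmetic means of log2 ratios
    across that condition's paired subjects.
    """

    per_subject: pd.DataFrame
    mean_log2: pd.DataFrame


def impute_half_min(m: pd.DataFrame) -> NormalizedMatrix:
    """Fill missing counts with half the data set's minimum positive SpC.

    The floor is computed over the whole matrix (all samples of the data
    set being processed), so a data set whose smallest observed positive
    count is 1 imputes 0.5. Observed cells, including literal zeros, are
    untouched.
    """
    vals = m.to_numpy(dtype=float)
    positive = vals[np.isfinite(vals) & (vals > 0)]
    if positive.size == 0:
        raise ValueError("cannot impute: matrix has no observed positive counts")
    floor = float(positive.min()) / 2.0
    imputed_mask = m.isna()
    filled = m.fillna(floor)
    return NormalizedMatrix(values=filled, imputed=imputed_mask, factors=None, floor=floor)


def normalize_total_spc(m: NormalizedMatrix | pd.DataFrame) -> NormalizedMatrix:
    """Scale each sample by (maximum column total) / (its column total).

    After scaling, every column total equals the pre-scaling maximum.
    Idempotent: a second application finds all factors equal to 1.
    """
    if isinstance(m, pd.DataFrame):
        m = NormalizedMatrix(values=m, imputed=m.isna() & False, factors=None, floor=None)
    if m.values.isna().any().any():
        raise ValueError("normalize_total_spc requires an imputed (complete) matrix")
    totals = m.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    factors = totals.max() / totals
    scaled = m.values.mul(factors, axis=1)
    return NormalizedMatrix(values=scaled, imputed=m.imputed, factors=factors, floor=m.floor)


def length_normalize(m: NormalizedMatrix, info: pd.DataFrame) -> NormalizedMatrix:
    """Divide each protein row by its length in amino acids."""
    missing = [p for p in m.values.index if p not in info.index]
    if missing:
        raise ValueError(f"proteins without length annotation: {missing}")
    lengths = info.loc[m.values.index, "length"].astype(float)
    return NormalizedMatrix(
        values=m.values.div(lengths, axis=0),
        imputed=m.imputed,
        factors=m.factors,
        floor=m.floor,
    )


def fold_change(m: NormalizedMatrix, design: PairedDesign) -> FoldChangeMatrix:
    """Per-subject treated/control fold change and per-condition mean log2.

    Subjects without a same-age control are excluded (the design already
    flags them). Cells equal to exactly zero are substituted with the
    imputation floor (scaled by that sample's normalization factor) before
    forming ratios, so denominators are strictly positive; a warning
    reports how many cells were floored.
    """
    if design.pairs.empty:
        raise ValueError("design contains no complete pairs")
    floor = m.floor if m.floor is not None else 0.5
    vals = m.values
    n_floored = 0
    cols = {}
    for row in design.pairs.itertuples(index=False):
        treated = vals[row.treated_sample].to_numpy(dtype=float).copy()
        control = vals[row.control_sample].to_numpy(dtype=float).copy()
        for arr, sample in ((treated, row.treated_sample), (control, row.control_sample)):
            f = 1.0 if m.factors is None else float(m.factors[sample])
            zero = arr == 0
            n_floored += int(zero.sum())
            arr[zero] = floor * f
        cols[(row.age_group, row.treatment, row.subject_id)] = treated / control
    if n_floored:
        warnings.warn(
            f"{n_floored} zero-valued cell(s) floored at the imputation value "
            "when forming fold-change ratios",
            stacklevel=2,
        )
    per_subject = pd.DataFrame(cols, index=vals.index)
    per_subject.columns = pd.MultiIndex.from_tuples(
        per_subject.columns, names=["age_group", "treatment", "subject_id"]
    )
    mean_log2 = np.log2(per_subject).T.groupby(level=["age_group", "treatment"]).mean().T
    return FoldChangeMatrix(per_subject=per_subject, mean_log2=mean_log2)


def zscore_rows(x: pd.DataFrame) -> pd.DataFrame:
    """Center each row to mean 0 and scale to sample SD 1 (n-1 denominator).

    Constant rows map to all-zero instead of NaN so the matrix shape is
    stable; the clustering inclusion filter removes them upstream anyway.
    """
    if x.shape[1] < 2:
        raise ValueError("z-scoring needs at least two columns")
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    z = x.sub(mu, axis=0).div(sd.where(sd > 0, other=np.inf), axis=0)
    return z.fillna(0.0)
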
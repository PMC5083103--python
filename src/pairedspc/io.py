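"""Readers and writers for every table the pipeline touches.

All flat files are strict TSV: tab-separated, no quoting, '.' decimal
separator, UTF-8, one header row, first column header literally ``id`` on
output. Readers reject malformed input with errors that carry file, line
and field coordinates rather than coercing. A missing spectral count means
"not detected/reported" and is distinct from a literal 0, which is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "GeneSetCollection",
    "PairedDesign",
    "read_spc_matrix",
    "write_spc_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_protein_info",
    "write_protein_info",
    "read_id_map",
    "write_id_map",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
    "validate_design",
]

AGE_GROUPS = ("newborn", "adult")
SAMPLE_SHEET_COLUMNS = ("age_group", "treatment", "subject_id", "replicate")


class TableFormatError(ValueError):
    """Malformed input table (carries file/line/field coordinates)."""


@dataclass
class GeneSetCollection:
    """Named gene/protein sets with optional per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            # preserve order, drop duplicates
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class PairedDesign:
    """Resolved subject pairing of a spectral-count experiment.

    ``pairs`` has one row per (age_group, subject, treatment) with the
    treated sample and its same-subject control sample; subjects without a
    control (or controls without any treated sample) are listed in
    ``incomplete_subjects`` and excluded from ``pairs``. ``sample_totals``
    holds each sample's raw total SpC, the exposure offset of the
    differential model.
    """

    samples: pd.DataFrame
    control: str
    pairs: pd.DataFrame
    incomplete_subjects: list[tuple[str, str]]
    sample_totals: pd.Series

    @property
    def n_complete_pairs(self) -> int:
        return self.pairs[["age_group", "subject_id"]].drop_duplicates().shape[0]

    def contrast_pairs(self, age_group: str, treatment: str) -> pd.DataFrame:
        sel = (self.pairs["age_group"] == age_group) & (self.pairs["treatment"] == treatment)
        return self.pairs.loc[sel].reset_index(drop=True)


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=False)


def read_spc_matrix(path, missing_sentinel: str = "NA") -> pd.DataFrame:
    """Read a proteins x samples spectral-count TSV.

    Empty cells and ``missing_sentinel`` parse as missing (NaN); everything
    else must be a non-negative integer. Returns a float DataFrame indexed
    by protein accession with NaN marking missing counts.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise TableFormatError(f"{path}: need an id column plus at least one sample column")
    ids = raw.iloc[:, 0]
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise TableFormatError(f"{path}: duplicate protein ids {dups}")
    samples = list(raw.columns[1:])
    if len(set(samples)) != len(samples):
        raise TableFormatError(f"{path}: duplicate sample ids in header")
    out = np.full((raw.shape[0], len(samples)), np.nan)
    for j, col in enumerate(samples):
        cells = raw[col].str.strip()
        blank = (cells == "") | (cells == missing_sentinel)
        ok = cells.str.fullmatch(r"\d+") | blank
        if not ok.all():
            i = int(np.flatnonzero(~ok)[0])
            raise TableFormatError(
                f"{path}: line {i + 2}, column {col!r}: "
                f"{cells.iloc[i]!r} is not a non-negative integer count"
            )
        vals = cells.where(~blank, other="-1").astype(float)
        out[:, j] = np.where(blank, np.nan, vals)
    return pd.DataFrame(out, index=pd.Index(ids, name="id"), columns=samples)


def write_spc_matrix(m: pd.DataFrame, path, missing_sentinel: str = "") -> None:
    """Write a count matrix; NaN cells become ``missing_sentinel``."""
    out = m.copy()
    txt = out.map(lambda v: missing_sentinel if pd.isna(v) else str(int(v)))
    txt.index.name = "id"
    txt.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the per-sample annotation sheet (sample_id indexed)."""
    raw = _read_tsv(path)
    cols = list(raw.columns)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in cols]
    if missing:
        raise TableFormatError(f"{path}: sample sheet missing columns {missing}")
    sheet = raw.set_index(raw.columns[0])
    sheet.index.name = "id"
    if sheet.index.duplicated().any():
        raise TableFormatError(f"{path}: duplicate sample ids")
    bad_age = set(sheet["age_group"]) - set(AGE_GROUPS)
    if bad_age:
        raise TableFormatError(f"{path}: unknown age_group values {sorted(bad_age)}")
    try:
        sheet["replicate"] = sheet["replicate"].astype(int)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-integer replicate: {exc}") from None
    dup = sheet.duplicated(subset=["age_group", "subject_id", "treatment", "replicate"])
    if dup.any():
        raise TableFormatError(
            f"{path}: duplicated (age_group, subject, treatment, replicate): "
            f"{sheet.index[dup].tolist()}"
        )
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    out = sheet.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t")


def read_protein_info(path) -> pd.DataFrame:
    """Read the protein metadata table (accession, gene_symbol, length)."""
    raw = _read_tsv(path)
    for col in ("gene_symbol", "length"):
        if col not in raw.columns:
            raise TableFormatError(f"{path}: protein info missing column {col!r}")
    info = raw.set_index(raw.columns[0])
    info.index.name = "id"
    if info.index.duplicated().any():
        raise TableFormatError(f"{path}: duplicate accessions")
    try:
        info["length"] = info["length"].astype(int)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-integer protein length: {exc}") from None
    if (info["length"] < 1).any():
        bad = info.index[info["length"] < 1].tolist()
        raise TableFormatError(f"{path}: non-positive lengths for {bad}")
    return info


def write_protein_info(info: pd.DataFrame, path) -> None:
    out = info.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t")


def read_id_map(path) -> pd.DataFrame:
    """Read a two-column many-to-many id mapping (source_id, target_id)."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise TableFormatError(f"{path}: id map needs two columns")
    m = raw.iloc[:, :2].copy()
    m.columns = ["source_id", "target_id"]
    if m.duplicated().any():
        m = m.drop_duplicates()
    return m.reset_index(drop=True)


def write_id_map(m: pd.DataFrame, path) -> None:
    out = m.rename(columns={m.columns[0]: "id", m.columns[1]: "target_id"})
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise TableFormatError(f"{path}: line {lineno}: set {name!r} has no members")
            if name in sets:
                raise TableFormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    """Generic numeric TSV reader for the pipeline's own outputs."""
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    out = df.copy()
    if index:
        out.index.name = "id"
    out.to_csv(path, sep="\t", index=index)


def validate_design(spc: pd.DataFrame, samples: pd.DataFrame, control: str = "control") -> PairedDesign:
    """Resolve the paired design of a count matrix against its sample sheet.

    Every matrix column must appear in the sheet. Within each
    (age_group, subject) at most one control sample is allowed; subjects
    lacking a control, or whose control lacks any treated sample, are
    flagged as incomplete, kept in the sheet, and excluded from ``pairs``
    (mirrors retaining an unpaired subject in the experiment while leaving
    it out of paired statistics).
    """
    orphans = [s for s in spc.columns if s not in samples.index]
    if orphans:
        raise ValueError(f"samples in matrix but not in sheet: {orphans}")
    sheet = samples.loc[list(spc.columns)]
    if control not in set(sheet["treatment"]):
        raise ValueError(f"control treatment {control!r} absent from sample sheet")

    rows = []
    incomplete: list[tuple[str, str]] = []
    for (age, subject), grp in sheet.groupby(["age_group", "subject_id"], sort=True):
        ctrl = grp.index[grp["treatment"] == control]
        if len(ctrl) > 1:
            raise ValueError(
                f"subject {subject!r} ({age}) has {len(ctrl)} control samples: {list(ctrl)}"
            )
        treated = grp.loc[grp["treatment"] != control]
        if len(ctrl) == 0 or treated.empty:
            incomplete.append((age, subject))
            continue
        for sample_id, row in treated.iterrows():
            rows.append(
                {
                    "age_group": age,
                    "treatment": row["treatment"],
                    "subject_id": subject,
                    "control_sample": ctrl[0],
                    "treated_sample": sample_id,
                }
            )
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} subject(s) without a complete control/treated pairing "
            f"retained but excluded from paired statistics: {incomplete}",
            stacklevel=2,
        )
    pairs = pd.DataFrame(
        rows, columns=["age_group", "treatment", "subject_id", "control_sample", "treated_sample"]
    )
    totals = spc.sum(axis=0, skipna=True)
    return PairedDesign(
        samples=sheet,
        control=control,
        pairs=pairs,
        incomplete_subjects=incomplete,
        sample_totals=totals,
    )
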
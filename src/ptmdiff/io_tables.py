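"""Readers and validators for the four input tables.

All tables are comma-delimited CSV with a header row (UTF-8, "." decimal).
Samples are bound to statistics through a metadata table that maps raw
intensity-column names to groups, replicates and display labels; binding is
exact-string on the column name — no fuzzy matching, a silent mis-bind being
worse than an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = {
    "file_name": ("file_name", "file name", "filename"),
    "sample_group": ("sample_group", "sample group"),
    "replicate": ("replicate", "rep"),
    "experimental_group": ("experimental_group", "experimental group", "group"),
    "custom_id": ("custom_id", "custom id", "id"),
}

PROTEIN_ANNOTATION_COLUMNS = {
    "uniprot_id": ("uniprot_id", "uniprot id", "uniprot", "accession", "protein id"),
    "gene_id": ("gene_id", "gene id", "gene", "gene symbol", "symbol"),
    "description": ("description", "desc", "protein name", "protein names"),
}

PTM_KEY_COLUMNS = {
    "histone_protein": ("histone_protein", "histone protein", "histone", "protein"),
    "site": ("site", "position", "amino_acid", "amino acid"),
    "modification": ("modification", "mod", "ptm"),
}

MODIFIER_ROLES = frozenset({"writer", "eraser", "reader"})
MODIFIER_MARKS = frozenset({"acetylation", "methylation"})


class TableFormatError(ValueError):
    """Raised when an input table violates its schema or invariants."""


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"input file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if "\t" in header and "," not in header:
        raise TableFormatError(
            f"{path}: looks tab-delimited; inputs must be comma-delimited CSV"
        )
    return pd.read_csv(path, sep=",")

def _canonical_columns(
    df: pd.DataFrame, aliases: dict[str, tuple[str, ...]]
) -> dict[str, str]:
    """Map canonical column names to the actual header spellings present."""
    lowered = {c.lower().strip(): c for c in df.columns}
    found = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in lowered:
                found[canonical] = lowered[name]
                break
    return found


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations binding intensity columns to the design.

    ``experimental_group`` must have exactly two levels (the comparison
    arms) with at least two samples each; with fewer the residual variance
    of the two-group fit is undefined.
    """

    table: pd.DataFrame  # columns: file_name, sample_group, replicate,
                         # experimental_group, custom_id

    def __post_init__(self) -> None:
        t = self.table
        required = ["file_name", "sample_group", "replicate", "experimental_group"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise TableFormatError(f"metadata missing columns: {missing}")
        if not pd.api.types.is_integer_dtype(t["replicate"]):
            raise TableFormatError("replicate numbers must be integers")
        if (t["replicate"] < 1).any():
            raise TableFormatError("replicate numbers must be positive")
        levels = t["experimental_group"].unique().tolist()
        if len(levels) != 2:
            raise TableFormatError(
                "experimental_group must have exactly 2 levels, got "
                f"{len(levels)}: {sorted(map(str, levels))}"
            )
        counts = t["experimental_group"].value_counts()
        small = counts[counts < 2]
        if len(small):
            raise TableFormatError(
                "each experimental group needs >= 2 samples (variance is "
                f"undefined otherwise); too small: {small.to_dict()}"
            )
        if "custom_id" not in t.columns or t["custom_id"].isna().all():
            object.__setattr__(self, "table", t.assign(custom_id=_default_ids(t)))
        dup = self.table["custom_id"][self.table["custom_id"].duplicated()]
        if len(dup):
            raise TableFormatError(f"custom_id values not unique: {sorted(set(dup))}")
        if self.table["file_name"].duplicated().any():
            raise TableFormatError("file_name values must be unique")

    @property
    def groups(self) -> list[str]:
        """The two experimental-group levels, in first-appearance order."""
        return self.table["experimental_group"].unique().tolist()

    @property
    def custom_ids(self) -> list[str]:
        return self.table["custom_id"].tolist()

    def group_members(self, level: str) -> list[str]:
        t = self.table
        return t.loc[t["experimental_group"] == level, "custom_id"].tolist()


def _default_ids(t: pd.DataFrame) -> list[str]:
    """Synthesize display ids as <group-initials>_<replicate>_<arm-initial>."""
    ids = []
    for _, row in t.iterrows():
        initials = "".join(w[0] for w in str(row["sample_group"]).split()).upper()
        arm = str(row["experimental_group"])[0].upper()
        ids.append(f"{initials}_{row['replicate']}_{arm}")
    if len(set(ids)) != len(ids):  # group/replicate/arm collision: add ordinal
        ids = [f"{s}_{i}" for i, s in enumerate(ids, start=1)]
    return ids


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read and validate the sample-metadata CSV.

    Missing ``custom_id`` values are synthesized from the sample group,
    replicate number and experimental arm.
    """
    df = _read_csv(path)
    cols = _canonical_columns(df, METADATA_COLUMNS)
    missing = [c for c in METADATA_COLUMNS if c not in cols and c != "custom_id"]
    if missing:
        raise TableFormatError(f"metadata missing columns: {missing}")
    out = df.rename(columns={v: k for k, v in cols.items()})
    out["file_name"] = out["file_name"].astype(str)
    try:
        out["replicate"] = pd.to_numeric(out["replicate"], downcast=None)
        if not (out["replicate"] % 1 == 0).all():
            raise ValueError
        out["replicate"] = out["replicate"].astype(int)
    except (ValueError, TypeError):
        raise TableFormatError("replicate numbers must be integers") from None
    return SampleMetadata(out[[c for c in METADATA_COLUMNS if c in out.columns]])


# ---------------------------------------------------------------------------
# protein matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinMatrix:
    """Feature-annotated non-negative intensity matrix (features x samples).

    Missing values are NaN, never zero: a zero is a measured zero.
    """

    annotations: pd.DataFrame   # uniprot_id / gene_id / description, indexed by feature
    intensities: pd.DataFrame   # float matrix, same index, columns = samples

    def __post_init__(self) -> None:
        if not self.annotations.index.equals(self.intensities.index):
            raise TableFormatError("annotation and intensity indices differ")
        if (self.intensities < 0).any().any():
            raise TableFormatError("intensities must be non-negative")
        if self.intensities.index.duplicated().any():
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise TableFormatError(f"duplicate feature ids: {sorted(set(dups))}")

    @property
    def n_features(self) -> int:
        return len(self.intensities)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def to_csv(self, path: str | Path) -> None:
        pd.concat([self.annotations, self.intensities], axis=1).to_csv(
            path, index=False
        )


def _disambiguate(ids: pd.Series) -> pd.Index:
    """Append the row ordinal to duplicated ids (aggregation would change
    the statistics, so duplicates are kept as distinct features)."""
    ids = ids.astype(str)
    dup_mask = ids.duplicated(keep=False)
    if dup_mask.any():
        logger.warning(
            "%d duplicate feature ids disambiguated with row ordinals",
            int(dup_mask.sum()),
        )
        ids = ids.where(
            ~dup_mask, ids + "_" + pd.Series(range(len(ids)), index=ids.index).astype(str)
        )
    return pd.Index(ids, name="feature")


def read_protein_matrix(path: str | Path) -> ProteinMatrix:
    """Read a comma-delimited matrix of MS1 protein abundances.

    Annotation columns (uniprot id, gene id, description) are recognised by
    name; every other column is a sample and is coerced to numeric, with
    non-numeric cells becoming missing. Rows are never dropped.
    """
    df = _read_csv(path)
    cols = _canonical_columns(df, PROTEIN_ANNOTATION_COLUMNS)
    if not cols:
        raise TableFormatError(
            "protein table needs at least one annotation column "
            "(uniprot id / gene id / description)"
        )
    ann = df[[cols[k] for k in cols]].rename(columns={v: k for k, v in cols.items()})
    for k in PROTEIN_ANNOTATION_COLUMNS:
        if k not in ann.columns:
            ann[k] = pd.NA
    ann = ann[list(PROTEIN_ANNOTATION_COLUMNS)]
    sample_cols = [c for c in df.columns if c not in cols.values()]
    if len(sample_cols) < 2:
        raise TableFormatError("protein table needs >= 2 sample columns")
    inten = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    if inten.isna().all().all():
        raise TableFormatError("no numeric intensity columns found")
    key = "uniprot_id" if "uniprot_id" in cols else next(iter(cols))
    index = _disambiguate(ann[key])
    ann.index = index
    inten.index = index
    return ProteinMatrix(ann, inten)


# ---------------------------------------------------------------------------
# PTM table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PTMTable:
    """Histone/site/modification-keyed intensity table.

    ``beta`` and ``m_value`` start unset when only intensities are supplied;
    the normalization module fills them. The family key groups all
    modification states co-normalised in the beta denominator (by default
    every state of the same site-bearing peptide).
    """

    annotations: pd.DataFrame          # histone_protein, site, modification
    intensities: pd.DataFrame          # features x samples, non-negative
    beta: pd.DataFrame | None = None   # same shape, values in [0, 1)
    m_value: pd.DataFrame | None = None
    family_key: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ann, inten = self.annotations, self.intensities
        for c in ("histone_protein", "site", "modification"):
            if c not in ann.columns:
                raise TableFormatError(f"PTM table missing key column: {c}")
        if ann[["histone_protein", "site", "modification"]].duplicated().any():
            raise TableFormatError(
                "(histone_protein, site, modification) triples must be unique"
            )
        if (inten < 0).any().any():
            raise TableFormatError("PTM intensities must be non-negative")
        if self.beta is not None:
            b = self.beta.to_numpy(float)
            ok = np.isnan(b) | ((b >= 0) & (b < 1))
            if not ok.all():
                raise TableFormatError("beta values must lie in [0, 1)")
        if self.family_key is None:
            object.__setattr__(
                self,
                "family_key",
                ann["histone_protein"].astype(str) + ":" + ann["site"].astype(str),
            )

    @property
    def n_features(self) -> int:
        return len(self.intensities)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def to_csv(self, path: str | Path) -> None:
        parts = [self.annotations, self.intensities]
        if self.beta is not None:
            parts.append(self.beta.add_prefix("beta_"))
        if self.m_value is not None:
            parts.append(self.m_value.add_prefix("m_"))
        pd.concat(parts, axis=1).to_csv(path, index=False)


def read_ptm_table(path: str | Path) -> PTMTable:
    """Read a PTM CSV: key columns plus per-sample intensities.

    Optional precomputed relative abundances are recognised as
    ``beta_<sample>`` / ``m_<sample>`` columns; when absent they are left
    unset for :func:`ptmdiff.normalization.compute_beta` to fill.
    """
    df = _read_csv(path)
    cols = _canonical_columns(df, PTM_KEY_COLUMNS)
    missing = [c for c in PTM_KEY_COLUMNS if c not in cols]
    if missing:
        raise TableFormatError(f"PTM table missing key columns: {missing}")
    ann = df[[cols[k] for k in PTM_KEY_COLUMNS]].rename(
        columns={v: k for k, v in cols.items()}
    )
    rest = [c for c in df.columns if c not in cols.values()]
    beta_cols = [c for c in rest if c.lower().startswith("beta_")]
    m_cols = [c for c in rest if c.lower().startswith("m_")]
    sample_cols = [c for c in rest if c not in beta_cols + m_cols]
    if not sample_cols:
        raise TableFormatError("PTM table needs >= 1 intensity column")
    inten = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    if (inten < 0).any().any():
        raise TableFormatError("negative PTM intensities")
    beta = df[beta_cols].rename(columns=lambda c: c[5:]) if beta_cols else None
    m = df[m_cols].rename(columns=lambda c: c[2:]) if m_cols else None
    return PTMTable(ann, inten, beta=beta, m_value=m)


# ---------------------------------------------------------------------------
# modifier (writer / eraser / reader) annotation table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModifierDB:
    """Catalogue of writer/eraser/reader proteins of histone marks."""

    table: pd.DataFrame  # protein_id, organism, role, mark

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ("protein_id", "organism", "role", "mark")
                   if c not in t.columns]
        if missing:
            raise TableFormatError(f"modifier table missing columns: {missing}")
        bad_role = set(t["role"].str.lower()) - MODIFIER_ROLES
        if bad_role:
            raise TableFormatError(f"unknown modifier roles: {sorted(bad_role)}")
        bad_mark = set(t["mark"].str.lower()) - MODIFIER_MARKS
        if bad_mark:
            raise TableFormatError(f"unknown modifier marks: {sorted(bad_mark)}")

    @property
    def organisms(self) -> list[str]:
        return sorted(self.table["organism"].unique())

    def for_organism(self, organism: str) -> pd.DataFrame:
        t = self.table
        return t[t["organism"].str.lower() == organism.lower()]


def read_modifier_db(path: str | Path) -> ModifierDB:
    """Read a writer/eraser/reader annotation CSV."""
    df = _read_csv(path)
    df.columns = [c.lower().strip().replace(" ", "_") for c in df.columns]
    return ModifierDB(df)


def bundled_modifier_db() -> ModifierDB:
    """The small writer/eraser/reader table shipped with the package."""
    path = Path(__file__).parent / "data" / "modifier_db.csv"
    return read_modifier_db(path)


# ---------------------------------------------------------------------------
# binding samples to metadata
# ---------------------------------------------------------------------------

def bind(
    matrix: ProteinMatrix | PTMTable, meta: SampleMetadata
) -> ProteinMatrix | PTMTable:
    """Subset and rename intensity columns to the metadata's custom ids.

    Columns are put in metadata row order; matrix columns the metadata does
    not reference are dropped with a warning. The result is invariant to
    both metadata row order and matrix column order up to the declared
    metadata ordering.
    """
    wanted = meta.table["file_name"].tolist()
    have = set(matrix.intensities.columns)
    missing = [c for c in wanted if c not in have]
    if missing:
        raise TableFormatError(
            f"metadata file_name(s) not found in matrix columns: {missing}"
        )
    dropped = sorted(have - set(wanted))
    if dropped:
        logger.warning("dropping %d unreferenced columns: %s", len(dropped), dropped)
    rename = dict(zip(meta.table["file_name"], meta.table["custom_id"]))
    sub = matrix.intensities[wanted].rename(columns=rename)
    if isinstance(matrix, ProteinMatrix):
        return ProteinMatrix(matrix.annotations, sub)
    new_beta = (
        matrix.beta[wanted].rename(columns=rename)
        if matrix.beta is not None and set(wanted) <= set(matrix.beta.columns)
        else None
    )
    new_m = (
        matrix.m_value[wanted].rename(columns=rename)
        if matrix.m_value is not None and set(wanted) <= set(matrix.m_value.columns)
        else None
    )
    return PTMTable(
        matrix.annotations, sub, beta=new_beta, m_value=new_m,
        family_key=matrix.family_key,
    )
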
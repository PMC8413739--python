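"""Region vocabulary, cohort ingestion and TIV normalization.

The analysis operates on 56 medial-temporal regions per subject: 9 amygdala
nuclei and 19 hippocampal subfields per hemisphere, as produced by
FreeSurfer's joint hippocampus/amygdala segmentation.  This module defines
the canonical region atlas (fixed ordering shared by every matrix downstream),
readers for cohort CSV tables and per-subject FreeSurfer subfield volume
files, and the conversion from absolute volumes (mm^3) to percent of total
intracranial volume (TIV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("scnet.atlas")

__all__ = [
    "Region",
    "RegionAtlas",
    "SubjectRecord",
    "CohortTable",
    "CohortError",
    "default_atlas",
    "normalize_volumes",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_freesurfer_subfield_tables",
    "cohort_from_records",
    "DEFAULT_SEX_CODES",
    "META_COLUMNS",
]


class CohortError(ValueError):
    """Raised for malformed cohort inputs (missing regions, bad values...)."""


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

#: Amygdala nuclei, one hemisphere (9 entries).
AMYGDALA_NUCLEI: tuple[str, ...] = (
    "anterior-amygdala-area",
    "cortico-amygdaloid-transition-area",
    "lateral-nucleus",
    "basal-nucleus",
    "paralaminar-nucleus",
    "accessory-basal-nucleus",
    "medial-nucleus",
    "central-nucleus",
    "cortical-nucleus",
)

#: Hippocampal subfields, one hemisphere (19 entries).
HIPPOCAMPAL_SUBFIELDS: tuple[str, ...] = (
    "parasubiculum",
    "presubiculum-head",
    "subiculum-head",
    "ca1-head",
    "ca3-head",
    "ca4-head",
    "granule-cell-layer-of-dentate-gyrus-head",
    "molecular-layer-head",
    "hippocampus-amygdala-transition-area",
    "presubiculum-body",
    "subiculum-body",
    "ca1-body",
    "ca3-body",
    "ca4-body",
    "granule-cell-layer-of-dentate-gyrus-body",
    "molecular-layer-body",
    "fimbria",
    "hippocampal-tail",
    "hippocampal-fissure",
)


@dataclass(frozen=True)
class Region:
    """One atlas entry: canonical name, hemisphere and parent structure."""

    name: str
    hemisphere: str  # "left" | "right"
    structure: str  # "amygdala" | "hippocampus"


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered, immutable list of regions.

    The order is fixed and defines row/column order for every connectivity
    matrix, metric vector and report table produced downstream.
    """

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise CohortError("atlas region names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)

    @property
    def size(self) -> int:
        return len(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset_names(self, hemisphere: str | None = None,
                     structure: str | None = None) -> tuple[str, ...]:
        """Names filtered by hemisphere and/or structure (atlas order kept)."""
        out = []
        for r in self.regions:
            if hemisphere is not None and r.hemisphere != hemisphere:
                continue
            if structure is not None and r.structure != structure:
                continue
            out.append(r.name)
        return tuple(out)


def default_atlas() -> RegionAtlas:
    """The 56-region amygdala + hippocampal-subfield atlas.

    Order: left amygdala (9), right amygdala (9), left hippocampus (19),
    right hippocampus (19).
    """
    regions: list[Region] = []
    for hemi in ("left", "right"):
        for nucleus in AMYGDALA_NUCLEI:
            regions.append(Region(f"{hemi}_{nucleus}", hemi, "amygdala"))
    for hemi in ("left", "right"):
        for subfield in HIPPOCAMPAL_SUBFIELDS:
            regions.append(Region(f"{hemi}_{subfield}", hemi, "hippocampus"))
    return RegionAtlas(tuple(regions))


# ---------------------------------------------------------------------------
# FreeSurfer name aliases
# ---------------------------------------------------------------------------

#: FreeSurfer segmentHA_T1 output labels -> canonical tokens (no hemisphere;
#: the hemisphere comes from which file the row was read from).
FREESURFER_ALIASES: dict[str, str] = {
    # hippocampal subfield file
    "Hippocampal_tail": "hippocampal-tail",
    "subiculum-head": "subiculum-head",
    "subiculum-body": "subiculum-body",
    "CA1-head": "ca1-head",
    "CA1-body": "ca1-body",
    "CA3-head": "ca3-head",
    "CA3-body": "ca3-body",
    "CA4-head": "ca4-head",
    "CA4-body": "ca4-body",
    "GC-ML-DG-head": "granule-cell-layer-of-dentate-gyrus-head",
    "GC-ML-DG-body": "granule-cell-layer-of-dentate-gyrus-body",
    "molecular_layer_HP-head": "molecular-layer-head",
    "molecular_layer_HP-body": "molecular-layer-body",
    "presubiculum-head": "presubiculum-head",
    "presubiculum-body": "presubiculum-body",
    "parasubiculum": "parasubiculum",
    "fimbria": "fimbria",
    "hippocampal-fissure": "hippocampal-fissure",
    "HATA": "hippocampus-amygdala-transition-area",
    # amygdala nuclei file
    "Lateral-nucleus": "lateral-nucleus",
    "Basal-nucleus": "basal-nucleus",
    "Accessory-Basal-nucleus": "accessory-basal-nucleus",
    "Anterior-amygdaloid-area-AAA": "anterior-amygdala-area",
    "Central-nucleus": "central-nucleus",
    "Medial-nucleus": "medial-nucleus",
    "Cortical-nucleus": "cortical-nucleus",
    "Corticoamygdaloid-transitio": "cortico-amygdaloid-transition-area",
    "Paralaminar-nucleus": "paralaminar-nucleus",
}

#: Aggregate rows in FreeSurfer files that are skipped, not parsed as regions.
FREESURFER_AGGREGATES: frozenset[str] = frozenset(
    {
        "Whole_hippocampal_head",
        "Whole_hippocampal_body",
        "Whole_hippocampus",
        "Whole_amygdala",
    }
)

#: Canonical token -> FreeSurfer label (used by the fixture writer).
CANONICAL_TO_FREESURFER: dict[str, str] = {
    v: k for k, v in FREESURFER_ALIASES.items()
}

#: Default mapping of sex tokens in input tables to the {0,1} regressor code.
#: Female = 0, male = 1.
DEFAULT_SEX_CODES: dict[str, int] = {
    "0": 0,
    "1": 1,
    "f": 0,
    "m": 1,
    "female": 0,
    "male": 1,
}

META_COLUMNS: tuple[str, ...] = ("subject_id", "group", "age", "sex", "tiv")


# ---------------------------------------------------------------------------
# Cohort containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: identifiers, covariates, TIV and per-region volumes."""

    subject_id: str
    group: str
    age: float
    sex: int
    tiv: float
    volumes: Mapping[str, float]

    def validate(self, atlas: RegionAtlas) -> None:
        if self.tiv <= 0:
            raise CohortError(
                f"subject {self.subject_id!r}: TIV must be > 0, got {self.tiv}"
            )
        missing = [n for n in atlas.names if n not in self.volumes]
        if missing:
            raise CohortError(
                f"subject {self.subject_id!r}: missing regions {missing}"
            )


@dataclass(frozen=True)
class CohortTable:
    """Per-subject covariates plus regional volumes for a whole cohort.

    ``data`` holds one row per subject with columns ``subject_id, group,
    age, sex, tiv``, then one column per atlas region (atlas order), then
    any extra numeric columns carried through from the input (e.g. clinical
    variables).  ``normalized`` records whether volumes are percent-of-TIV.
    """

    atlas: RegionAtlas
    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise CohortError(f"cohort table missing columns: {missing}")
        missing_regions = [n for n in self.atlas.names
                           if n not in self.data.columns]
        if missing_regions:
            raise CohortError(
                f"cohort table missing region columns: {missing_regions}"
            )
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique().tolist())
            raise CohortError(f"duplicate subject_id values: {dups}")

    # -- shape -------------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def group_names(self) -> tuple[str, ...]:
        """Group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.data["group"]:
            seen.setdefault(str(g))
        return tuple(seen)

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.data["group"] == g).sum())
                for g in self.group_names()}

    @property
    def extra_columns(self) -> tuple[str, ...]:
        known = set(META_COLUMNS) | set(self.atlas.names)
        return tuple(c for c in self.data.columns if c not in known)

    # -- matrices ----------------------------------------------------------

    def volumes_matrix(self, group: str | None = None) -> np.ndarray:
        """Subjects x regions volume matrix (atlas column order)."""
        df = self.data if group is None else self.data[
            self.data["group"] == group]
        if group is not None and df.empty:
            raise CohortError(f"no subjects in group {group!r}")
        return df.loc[:, list(self.atlas.names)].to_numpy(dtype=float)

    def covariate_matrix(self, covariates: Sequence[str],
                         group: str | None = None) -> np.ndarray:
        df = self.data if group is None else self.data[
            self.data["group"] == group]
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise CohortError(f"unknown covariate columns: {missing}")
        return df.loc[:, list(covariates)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_volumes(cohort: CohortTable) -> CohortTable:
    """Convert absolute volumes (mm^3) to percent of TIV.

    structural volume (%) = 100 * absolute volume / TIV, per subject.
    Refuses to run twice: normalization is a unit change, and applying the
    ratio to already-relative volumes would silently corrupt the data.
    """
    if cohort.normalized:
        raise CohortError("cohort is already normalized (percent of TIV)")
    bad = cohort.data[cohort.data["tiv"] <= 0]
    if not bad.empty:
        sid = bad.iloc[0]["subject_id"]
        raise CohortError(f"subject {sid!r}: TIV must be > 0")
    df = cohort.data.copy()
    region_cols = list(cohort.atlas.names)
    df[region_cols] = (
        df[region_cols].to_numpy(dtype=float)
        * (100.0 / df["tiv"].to_numpy(dtype=float)[:, None])
    )
    over = (df[region_cols].to_numpy() >= 100.0).any()
    if over:
        raise CohortError(
            "normalized volume >= 100% of TIV; inputs are probably already "
            "relative or TIV units are wrong"
        )
    return CohortTable(atlas=cohort.atlas, data=df, normalized=True)


# ---------------------------------------------------------------------------
# CSV reader / writer
# ---------------------------------------------------------------------------


def _coerce_sex(values: pd.Series, sex_codes: Mapping[str, int]) -> pd.Series:
    out = []
    for i, v in enumerate(values):
        token = str(v).strip().lower()
        if token.endswith(".0"):  # pandas float round-trip of integer codes
            token = token[:-2]
        if token not in sex_codes:
            raise CohortError(
                f"row {i}: sex value {v!r} not in mapping "
                f"{sorted(sex_codes)} (configure sex_codes to extend)"
            )
        out.append(int(sex_codes[token]))
    return pd.Series(out, index=values.index)


def read_cohort_csv(
    path: str | Path,
    atlas: RegionAtlas | None = None,
    *,
    normalized: bool = False,
    sex_codes: Mapping[str, int] | None = None,
    delimiter: str = ",",
) -> CohortTable:
    """Read a cohort table: subject_id, group, age, sex, tiv, one column per
    region (any column order; matched by name), extra columns kept.

    Sex is recoded to {0,1} via ``sex_codes`` (default accepts 0/1, f/m,
    female/male, case-insensitive).
    """
    atlas = atlas or default_atlas()
    sex_codes = dict(DEFAULT_SEX_CODES if sex_codes is None else sex_codes)
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str,
                      skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]

    missing_meta = [c for c in META_COLUMNS if c not in raw.columns]
    if missing_meta:
        raise CohortError(f"{path.name}: missing columns {missing_meta}")
    missing_regions = [n for n in atlas.names if n not in raw.columns]
    if missing_regions:
        raise CohortError(
            f"{path.name}: missing region columns {missing_regions}"
        )

    df = raw.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["group"] = df["group"].astype(str)
    df["sex"] = _coerce_sex(df["sex"], sex_codes)

    numeric_cols = ["age", "tiv"] + list(atlas.names)
    extra = [c for c in df.columns
             if c not in set(META_COLUMNS) | set(atlas.names)]
    for col in numeric_cols + extra:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if col in numeric_cols and bad.any():
            row = int(bad.idxmax())
            raise CohortError(
                f"{path.name}: non-numeric value {df[col][row]!r} "
                f"at row {row}, column {col!r}"
            )
        if converted.isna().any() and col in numeric_cols:
            row = int(converted.isna().idxmax())
            raise CohortError(
                f"{path.name}: missing value at row {row}, column {col!r}"
            )
        df[col] = converted

    ordered = list(META_COLUMNS) + list(atlas.names) + extra
    df = df.loc[:, ordered].reset_index(drop=True)
    return CohortTable(atlas=atlas, data=df, normalized=normalized)


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> Path:
    """Write the cohort table as UTF-8 comma-delimited text (round-trips
    with :func:`read_cohort_csv`)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# FreeSurfer subfield-table reader
# ---------------------------------------------------------------------------


def _parse_subfield_file(path: str | Path, hemisphere: str) -> dict[str, float]:
    """Parse one two-column (label, mm^3) FreeSurfer subfield volume file."""
    path = Path(path)
    volumes: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise CohortError(
                f"{path.name}:{lineno}: expected 'label volume', got {line!r}"
            )
        label, value = parts
        if label in FREESURFER_AGGREGATES or label.startswith("Whole_"):
            continue
        if label in FREESURFER_ALIASES:
            canonical = FREESURFER_ALIASES[label]
        elif label in CANONICAL_TO_FREESURFER:  # canonical token accepted too
            canonical = label
        else:
            raise CohortError(
                f"{path.name}:{lineno}: unknown structure label {label!r} "
                "(no alias defined)"
            )
        name = f"{hemisphere}_{canonical}"
        if name in volumes:
            raise CohortError(
                f"{path.name}:{lineno}: duplicated structure line for "
                f"{label!r}"
            )
        try:
            volumes[name] = float(value)
        except ValueError as exc:
            raise CohortError(
                f"{path.name}:{lineno}: non-numeric volume {value!r}"
            ) from exc
    return volumes


def read_freesurfer_subfield_tables(
    lh_hippo: str | Path,
    rh_hippo: str | Path,
    lh_amyg: str | Path,
    rh_amyg: str | Path,
    meta: Mapping[str, object],
    atlas: RegionAtlas | None = None,
) -> SubjectRecord:
    """Assemble one subject from the four per-hemisphere FreeSurfer subfield
    volume files plus a metadata record (subject_id, group, age, sex, tiv).

    Aggregate rows (``Whole_*``) are skipped; every other label must resolve
    through the documented alias table.
    """
    atlas = atlas or default_atlas()
    volumes: dict[str, float] = {}
    for path, hemi in ((lh_hippo, "left"), (rh_hippo, "right"),
                       (lh_amyg, "left"), (rh_amyg, "right")):
        parsed = _parse_subfield_file(path, hemi)
        clash = set(parsed) & set(volumes)
        if clash:
            raise CohortError(
                f"{Path(path).name}: regions parsed twice: {sorted(clash)}"
            )
        volumes.update(parsed)
    record = SubjectRecord(
        subject_id=str(meta["subject_id"]),
        group=str(meta["group"]),
        age=float(meta["age"]),  # type: ignore[arg-type]
        sex=int(meta["sex"]),  # type: ignore[arg-type]
        tiv=float(meta["tiv"]),  # type: ignore[arg-type]
        volumes=volumes,
    )
    record.validate(atlas)
    return record


def cohort_from_records(
    records: Iterable[SubjectRecord],
    atlas: RegionAtlas | None = None,
    *,
    normalized: bool = False,
) -> CohortTable:
    """Build a :class:`CohortTable` from subject records (validates each)."""
    atlas = atlas or default_atlas()
    rows = []
    for rec in records:
        rec.validate(atlas)
        row: dict[str, object] = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": rec.age,
            "sex": rec.sex,
            "tiv": rec.tiv,
        }
        row.update({n: float(rec.volumes[n]) for n in atlas.names})
        rows.append(row)
    if not rows:
        raise CohortError("no subject records given")
    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(atlas.names))
    return CohortTable(atlas=atlas, data=df, normalized=normalized)
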
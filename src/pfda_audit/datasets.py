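"""Specimen tables for bone-compactness lifestyle analysis.

Each specimen is a single (maximum bone diameter *MD*, global bone
compactness *Cg*) point annotated with two lifestyle codes — flying ability
``F`` and diving habit ``D``, each on the scale 0 (absent) / 1 (infrequent) /
2 (habitual) — plus an extinct/extant status and a train/test role.

The on-disk format is a plain comma-separated table with one row per
specimen ("Fabbri-dialect" CSV).  Column headers vary between sources, so
readers accept a :class:`ColumnMap`; *MD* may be stored linear (mm) or as
log10(mm) and is normalized to millimetres on read.  log10(MD) is taken at
analysis time, never at storage time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
import pandas as pd

__all__ = [
    "TaxonRecord",
    "Dataset",
    "ClassRule",
    "ClassPartition",
    "ColumnMap",
    "DatasetError",
    "ColumnMapError",
    "ValidationError",
    "PartitionError",
    "read_dataset",
    "write_fabbri_csv",
    "partition",
    "shared_taxa",
]

_CODES = ("0", "1", "2", "unknown")
_STATUS = ("extinct", "extant", "unknown")
_ROLES = ("train", "test")


class DatasetError(Exception):
    """Base class for specimen-table problems."""


class ColumnMapError(DatasetError):
    """A mapped column is missing from the file."""


class ValidationError(DatasetError):
    """A row violates a field invariant (e.g. Cg outside (0, 1])."""


class PartitionError(DatasetError):
    """A class partition is unusable for discriminant fitting."""


def _norm_code(value) -> str:
    if value is None:
        return "unknown"
    s = str(value).strip().lower()
    if s in ("", "na", "n/a", "nan", "none", "unknown", "?", "u"):
        return "unknown"
    try:
        f = float(s)
    except ValueError:
        return "unknown"
    i = int(f)
    if i in (0, 1, 2) and f == i:
        return str(i)
    raise ValidationError(f"lifestyle code {value!r} not in {{0, 1, 2, unknown}}")


def _norm_status(value) -> str:
    if value is None:
        return "unknown"
    s = str(value).strip().lower()
    if s in ("extinct", "extant"):
        return s
    if s in ("e",):  # shorthand used in some compilations
        return "extant"
    return "unknown"


@dataclass(frozen=True)
class TaxonRecord:
    """One specimen: an (MD, Cg) point with lifestyle codes and status."""

    taxon_id: str
    md_mm: float
    cg: float
    fly_code: str = "unknown"
    dive_code: str = "unknown"
    status: str = "unknown"
    role: str = "train"

    def __post_init__(self):
        if not self.taxon_id:
            raise ValidationError("taxon_id must be non-empty")
        if not (self.md_mm > 0 and math.isfinite(self.md_mm)):
            raise ValidationError(
                f"{self.taxon_id}: MD must be a positive finite diameter in mm, "
                f"got {self.md_mm!r}"
            )
        if not (0 < self.cg <= 1):
            raise ValidationError(
                f"{self.taxon_id}: Cg must lie in (0, 1], got {self.cg!r}"
            )
        for name, val, allowed in (
            ("fly_code", self.fly_code, _CODES),
            ("dive_code", self.dive_code, _CODES),
            ("status", self.status, _STATUS),
            ("role", self.role, _ROLES),
        ):
            if val not in allowed:
                raise ValidationError(
                    f"{self.taxon_id}: {name}={val!r} not in {allowed}"
                )

    @property
    def log_md(self) -> float:
        """log10(MD/mm), the analysis abscissa."""
        return math.log10(self.md_mm)

    @property
    def group(self) -> str:
        """Lifestyle group label, e.g. ``'F0D2'`` (``'u'`` for unknown)."""
        f = self.fly_code if self.fly_code != "unknown" else "u"
        d = self.dive_code if self.dive_code != "unknown" else "u"
        return f"F{f}D{d}"


@dataclass
class Dataset:
    """A named, ordered collection of specimen records with unique ids."""

    name: str
    records: list[TaxonRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.taxon_id for r in self.records]
        dupes = {t for t in ids if ids.count(t) > 1}
        if dupes:
            raise ValidationError(
                f"dataset {self.name!r}: duplicate taxon_id(s) {sorted(dupes)}; "
                "disambiguate repeated specimens with a suffix (e.g. Nothosaurus_102)"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def taxon_ids(self) -> list[str]:
        return [r.taxon_id for r in self.records]

    def subset(self, predicate) -> "Dataset":
        return Dataset(self.name, [r for r in self.records if predicate(r)])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per record; MD linear, in mm)."""
        return pd.DataFrame(
            {
                "taxon": [r.taxon_id for r in self.records],
                "diameter": [r.md_mm for r in self.records],
                "compactness": [r.cg for r in self.records],
                "flying": [r.fly_code for r in self.records],
                "diving": [r.dive_code for r in self.records],
                "status": [r.status for r in self.records],
                "role": [r.role for r in self.records],
            }
        )


@dataclass(frozen=True)
class ClassRule:
    """How lifestyle codes define the two discriminant classes.

    ``F0D0_vs_F0D2`` keeps only terrestrial nonfliers (class 1) and nonflying
    habitual divers (class 2).  ``Many_vs_F0D2`` assigns class 2 to F0D2 and
    class 1 to every other *coded* taxon (the comparison used by the study
    under audit).  Records with an unknown F or D code never train.
    """

    mode: str = "F0D0_vs_F0D2"
    positive_class: str = "D2"

    _MODES = ("F0D0_vs_F0D2", "Many_vs_F0D2")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValidationError(f"unknown class rule {self.mode!r}")

    def class_of(self, record: TaxonRecord) -> int | None:
        """Return 1, 2, or None (excluded from training)."""
        f, d = record.fly_code, record.dive_code
        if "unknown" in (f, d):
            return None
        if f == "0" and d == "2":
            return 2
        if self.mode == "F0D0_vs_F0D2":
            return 1 if (f == "0" and d == "0") else None
        return 1


@dataclass
class ClassPartition:
    """Two disjoint training classes produced by a :class:`ClassRule`."""

    class1: list[TaxonRecord]
    class2: list[TaxonRecord]
    rule: ClassRule

    def __post_init__(self):
        ids1 = {r.taxon_id for r in self.class1}
        ids2 = {r.taxon_id for r in self.class2}
        if ids1 & ids2:
            raise PartitionError(f"classes overlap: {sorted(ids1 & ids2)}")
        for k, cls in (("1", self.class1), ("2", self.class2)):
            if len(cls) < 3:
                raise PartitionError(
                    f"class {k} has {len(cls)} records; at least 3 are needed "
                    "to estimate a centroid and pooled covariance"
                )

    @property
    def records(self) -> list[TaxonRecord]:
        return list(self.class1) + list(self.class2)

    @property
    def labels(self) -> list[int]:
        return [1] * len(self.class1) + [2] * len(self.class2)


@dataclass(frozen=True)
class ColumnMap:
    """Header names of the CSV dialect (defaults match :meth:`Dataset.to_frame`)."""

    taxon: str = "taxon"
    diameter: str = "diameter"
    compactness: str = "compactness"
    flying: str = "flying"
    diving: str = "diving"
    status: str | None = "status"
    role: str | None = "role"


def read_dataset(
    path,
    column_map: ColumnMap | None = None,
    md_scale: str = "linear",
    name: str | None = None,
) -> Dataset:
    """Read a Fabbri-dialect CSV into a :class:`Dataset`.

    Parameters
    ----------
    md_scale
        ``'linear'`` if the diameter column holds MD in mm, ``'log10'`` if it
        holds log10(MD); either way records store millimetres.
    """
    cm = column_map or ColumnMap()
    if md_scale not in ("linear", "log10"):
        raise ValueError("md_scale must be 'linear' or 'log10'")
    df = pd.read_csv(path)
    required = [cm.taxon, cm.diameter, cm.compactness, cm.flying, cm.diving]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ColumnMapError(
            f"{path}: missing mapped column(s) {missing}; present: {list(df.columns)}"
        )
    records = []
    for i, row in df.iterrows():
        try:
            md = float(row[cm.diameter])
            if md_scale == "log10":
                md = 10.0 ** md
            rec = TaxonRecord(
                taxon_id=str(row[cm.taxon]).strip(),
                md_mm=md,
                cg=float(row[cm.compactness]),
                fly_code=_norm_code(row[cm.flying]),
                dive_code=_norm_code(row[cm.diving]),
                status=_norm_status(row[cm.status]) if cm.status in df.columns else "unknown",
                role=(
                    str(row[cm.role]).strip().lower()
                    if cm.role in df.columns and str(row[cm.role]).strip().lower() in _ROLES
                    else "train"
                ),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}, row {i + 2} (1-based, incl. header): {exc}") from exc
        records.append(rec)
    return Dataset(name or str(path), records)


def write_fabbri_csv(ds: Dataset, path) -> None:
    """Write a dataset in the default-dialect CSV; lossless round trip."""
    ds.to_frame().to_csv(path, index=False)


def partition(ds: Dataset, rule: ClassRule) -> ClassPartition:
    """Split training records into the two classes defined by ``rule``.

    Membership is determined solely by the (F, D) codes; records with unknown
    codes, records outside the rule's groups, and ``role='test'`` records are
    excluded.
    """
    if len(ds) == 0:
        raise DatasetError(f"dataset {ds.name!r} is empty")
    c1, c2 = [], []
    for r in ds:
        if r.role == "test":
            continue
        k = rule.class_of(r)
        if k == 1:
            c1.append(r)
        elif k == 2:
            c2.append(r)
    return ClassPartition(c1, c2, rule)


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name).strip()


def shared_taxa(a: Dataset, b: Dataset, normalize: bool = True) -> tuple[int, list[str]]:
    """Count and list taxa present in both datasets (exact string match
    after optional whitespace normalization)."""
    f = _normalize_name if normalize else (lambda s: s)
    sa = {f(t) for t in a.taxon_ids()}
    sb = {f(t) for t in b.taxon_ids()}
    common = sorted(sa & sb)
    return len(common), common


def with_status(ds: Dataset, status_by_taxon: dict[str, str]) -> Dataset:
    """Return a copy with extinct/extant status supplied from a side table."""
    out = []
    for r in ds:
        s = status_by_taxon.get(r.taxon_id)
        out.append(replace(r, status=_norm_status(s)) if s is not None else r)
    return Dataset(ds.name, out)
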
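"""Domain types and tabular I/O shared by every pipeline stage.

The interchange formats are deliberately plain: UTF-8, tab-delimited text
with a fixed header vocabulary, '.' decimal separator.  Three file kinds
exist:

``counts.<primer>.<rep>.tsv``
    ASV-by-sample integer read counts; ASV ids in the first column
    (header ``asv_id``), sample ids in the remaining headers.
``taxonomy.tsv``
    One row per ASV: rank labels and per-rank confidences for
    kingdom..species plus an ``is_mock`` flag.
``metadata.tsv``
    One row per (sample_id, primer_set, replicate): role, sex.

All readers validate eagerly and raise typed errors; nothing is silently
coerced.  Writers are exact inverses of the readers on canonical files.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Taxonomic ranks from coarse to fine.  Thresholded resolution only uses
#: order..species; phylum/kingdom are carried for the non-target filter.
RANKS = ("kingdom", "phylum", "order", "family", "genus", "species")

#: Ranks that participate in confidence-threshold resolution, fine to coarse.
RESOLUTION_RANKS = ("species", "genus", "family", "order")


class PreyDnaError(Exception):
    """Base class for all package errors."""


class ParseError(PreyDnaError):
    """A file could not be parsed into the declared format."""


class ValidationError(PreyDnaError):
    """Parsed data violates a documented invariant."""


class ConfigError(PreyDnaError):
    """A configuration object is internally inconsistent."""


class Role(str, enum.Enum):
    SPECIMEN = "specimen"
    NEGATIVE_CONTROL = "negative_control"
    MOCK = "mock"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    NA = "NA"


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample within one primer-set/replicate dataset.

    Invariants: ``sex`` is :data:`Sex.NA` iff ``role`` is not specimen;
    the triple (sample_id, primer_set, replicate) is unique in a dataset.
    """

    sample_id: str
    role: Role
    sex: Sex
    primer_set: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate not in (1, 2):
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be 1 or 2, "
                f"got {self.replicate!r}"
            )
        if self.role is Role.SPECIMEN and self.sex is Sex.NA:
            raise ValidationError(
                f"sample {self.sample_id!r}: specimen samples must declare sex"
            )
        if self.role is not Role.SPECIMEN and self.sex is not Sex.NA:
            raise ValidationError(
                f"sample {self.sample_id!r}: sex must be NA for role "
                f"{self.role.value!r}"
            )


def _check_unique_meta(records: Sequence[SampleMeta]) -> None:
    seen: set[tuple[str, str, int]] = set()
    for r in records:
        key = (r.sample_id, r.primer_set, r.replicate)
        if key in seen:
            raise ValidationError(f"duplicate metadata record for {key}")
        seen.add(key)


def specimen_sex(records: Sequence[SampleMeta]) -> "pd.Series[str]":
    """Collapse metadata to one sex label per specimen sample id.

    Raises :class:`ValidationError` if the same sample id is recorded with
    conflicting sexes across primer sets / replicates.
    """
    out: dict[str, Sex] = {}
    for r in records:
        if r.role is not Role.SPECIMEN:
            continue
        if r.sample_id in out and out[r.sample_id] is not r.sex:
            raise ValidationError(
                f"sample {r.sample_id!r} has conflicting sex labels"
            )
        out[r.sample_id] = r.sex
    return pd.Series({k: v.value for k, v in out.items()}, dtype=object)


def roles_by_sample(records: Sequence[SampleMeta]) -> dict[str, Role]:
    out: dict[str, Role] = {}
    for r in records:
        if r.sample_id in out and out[r.sample_id] is not r.role:
            raise ValidationError(
                f"sample {r.sample_id!r} has conflicting roles"
            )
        out[r.sample_id] = r.role
    return out


@dataclass
class ReadMatrix:
    """Integer read counts, ASV x sample, for one primer set and replicate."""

    counts: pd.DataFrame  # index: asv ids, columns: sample ids, int64
    primer_set: str
    replicate: int

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("read counts must be integral")
        if (arr < 0).any():
            raise ValidationError("read counts must be non-negative")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def validate_against(self, meta: Sequence[SampleMeta]) -> None:
        """Every sample column must have a metadata record for this dataset."""
        known = {
            m.sample_id
            for m in meta
            if m.primer_set == self.primer_set and m.replicate == self.replicate
        }
        missing = [s for s in self.sample_ids if s not in known]
        if missing:
            raise ValidationError(
                f"samples without metadata in dataset "
                f"({self.primer_set!r}, rep {self.replicate}): {missing}"
            )

    def copy_with(self, counts: pd.DataFrame) -> "ReadMatrix":
        return ReadMatrix(counts=counts, primer_set=self.primer_set,
                          replicate=self.replicate)


@dataclass
class TaxonomyTable:
    """Per-ASV rank labels, per-rank confidences in [0, 1], mock flag.

    ``table`` columns: ``<rank>_label`` (str, may be empty) and
    ``<rank>_conf`` (float) for every rank in :data:`RANKS`, plus
    ``is_mock`` (bool).  Index: ASV ids.

    Confidences are expected to be non-increasing from coarse to fine rank
    (order >= family >= genus >= species); violations are accepted with a
    warning because real classifier output occasionally breaks this.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = [f"{r}_label" for r in RANKS] + [f"{r}_conf" for r in RANKS]
        required.append("is_mock")
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"taxonomy table missing columns: {missing}")
        # canonical column order, so round-trips compare bit-exactly
        canonical = ([f"{r}_label" for r in RANKS]
                     + [f"{r}_conf" for r in RANKS] + ["is_mock"])
        extras = [c for c in t.columns if c not in canonical]
        self.table = t = t[canonical + extras]
        if t.index.has_duplicates:
            raise ValidationError("duplicate ASV ids in taxonomy table")
        conf = t[[f"{r}_conf" for r in RANKS]].to_numpy(dtype=float)
        if np.isnan(conf).any() or (conf < 0).any() or (conf > 1).any():
            raise ValidationError("confidences must lie in [0, 1]")
        ladder = t[[f"{r}_conf" for r in ("order", "family", "genus", "species")]]
        viol = (np.diff(ladder.to_numpy(dtype=float), axis=1) > 1e-12).any(axis=1)
        if viol.any():
            warnings.warn(
                f"{int(viol.sum())} ASV(s) have confidences increasing from "
                "coarse to fine rank; accepted as-is",
                stacklevel=2,
            )

    def label(self, asv_id: str, rank: str) -> str:
        return str(self.table.at[asv_id, f"{rank}_label"])

    def confidence(self, asv_id: str, rank: str) -> float:
        return float(self.table.at[asv_id, f"{rank}_conf"])

    def mock_asvs(self) -> list[str]:
        return list(self.table.index[self.table["is_mock"].astype(bool)])


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and exclusion rules for the decontamination cascade."""

    rank_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {
            "species": 0.45, "genus": 0.40, "family": 0.30, "order": 0.20,
        }
    )
    target_phylum: str = "Arthropoda"
    exclusion_taxa: tuple[str, ...] = ("Arrenurus reflexus",)
    negative_rule: str = "max_across_negatives"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        th = self.rank_thresholds
        missing = [r for r in RESOLUTION_RANKS if r not in th]
        if missing:
            raise ConfigError(f"rank_thresholds missing ranks: {missing}")
        for r in RESOLUTION_RANKS:
            if not 0.0 < th[r] < 1.0:
                raise ConfigError(f"threshold for {r} must be in (0, 1)")
        if not (th["species"] >= th["genus"] >= th["family"] >= th["order"]):
            raise ConfigError(
                "thresholds must satisfy species >= genus >= family >= order"
            )
        if self.negative_rule != "max_across_negatives":
            raise ConfigError(
                f"unknown negative_rule {self.negative_rule!r}; "
                "allowed: 'max_across_negatives'"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ResolvedTaxon:
    """A taxon identity after threshold resolution: (rank, label)."""

    rank: str
    label: str

    def key(self) -> str:
        return f"{self.rank}:{self.label}"


@dataclass
class TaxonSampleTable:
    """Read counts after ASV -> taxon collapse.

    Rows are resolved taxa (indexed by ``rank:label`` keys), columns are
    sample ids.  ``taxa`` maps the row key to its :class:`ResolvedTaxon`.
    ``provenance`` lists the primer set(s) whose reads contributed.

    Intermediate cascade tables may retain negative-control and mock
    columns (the tag-jump estimator needs the mock sample); the final
    table handed to presence conversion carries specimen columns only.
    """

    counts: pd.DataFrame
    taxa: dict[str, ResolvedTaxon]
    provenance: tuple[str, ...]
    replicate: int | None = None
    taxon_phylum: dict[str, str] = field(default_factory=dict)
    mock_taxa: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("collapsed counts must be integral")
        if arr.size and (arr < 0).any():
            raise ValidationError("collapsed counts must be non-negative")
        unknown = [k for k in self.counts.index if k not in self.taxa]
        if unknown:
            raise ValidationError(f"rows without taxon records: {unknown}")

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def copy_with(self, counts: pd.DataFrame,
                  replicate: int | None = "unset") -> "TaxonSampleTable":
        taxa = {k: self.taxa[k] for k in counts.index}
        phyla = {k: v for k, v in self.taxon_phylum.items() if k in taxa}
        return TaxonSampleTable(
            counts=counts,
            taxa=taxa,
            provenance=self.provenance,
            replicate=self.replicate if replicate == "unset" else replicate,
            taxon_phylum=phyla,
            mock_taxa=frozenset(k for k in self.mock_taxa if k in taxa),
        )


@dataclass
class PresenceMatrix:
    """Binary taxa x specimen matrix; the object all diet statistics consume.

    Columns are specimens with at least one detected taxon; all-zero
    columns are dropped (and counted) at construction.  ``sex`` maps each
    retained specimen to 'female' or 'male'.
    """

    values: pd.DataFrame  # int8 in {0,1}
    sex: "pd.Series[str]"
    n_dropped_empty: int = 0
    dropped_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValidationError("presence values must be 0 or 1")
        missing = [s for s in self.values.columns if s not in self.sex.index]
        if missing:
            raise ValidationError(f"specimens without sex label: {missing}")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def specimens(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, specimens: Iterable[str]) -> "PresenceMatrix":
        cols = list(specimens)
        return PresenceMatrix(
            values=self.values[cols],
            sex=self.sex.loc[cols],
        )

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        sex: "pd.Series[str]",
    ) -> "PresenceMatrix":
        """Binarise a count table and drop empty specimen columns."""
        binary = (counts > 0).astype("int8")
        keep = binary.sum(axis=0) > 0
        dropped = tuple(binary.columns[~keep])
        if dropped:
            logger.info(
                "dropping %d specimen(s) with no detections: %s",
                len(dropped), list(dropped),
            )
        binary = binary.loc[:, keep]
        return cls(
            values=binary,
            sex=sex.loc[list(binary.columns)],
            n_dropped_empty=len(dropped),
            dropped_samples=dropped,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_count_table(
    path,
    primer_set: str,
    replicate: int,
    meta: Sequence[SampleMeta] | None = None,
) -> ReadMatrix:
    """Read an ASV-by-sample TSV of integer read counts.

    Parameters
    ----------
    path : path-like
        TSV with ``asv_id`` as the first header field and sample ids as
        the remaining headers.
    meta : optional
        If given, every sample column must have a metadata record for
        this (primer_set, replicate) dataset.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "asv_id":
        raise ParseError(
            f"{path}: first column must be 'asv_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("asv_id").rename_axis(None)
    parsed = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            vals = raw[col].astype("int64")
        except ValueError:
            bad = raw.index[~raw[col].str.fullmatch(r"[+-]?\d+")][:1]
            raise ParseError(
                f"{path}: non-integer cell at row {bad[0]!r}, column {col!r}"
            ) from None
        neg = vals.index[vals < 0]
        if len(neg):
            raise ParseError(
                f"{path}: negative count at row {neg[0]!r}, column {col!r}"
            )
        parsed[col] = vals
    m = ReadMatrix(counts=parsed, primer_set=primer_set, replicate=replicate)
    if meta is not None:
        m.validate_against(meta)
    return m


def write_count_table(m: ReadMatrix, path) -> None:
    m.counts.to_csv(path, sep="\t", index_label="asv_id")


_META_COLUMNS = ("sample_id", "role", "sex", "primer_set", "replicate")


def read_metadata(path) -> list[SampleMeta]:
    """Read sample metadata; enums are validated, uniqueness enforced."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing columns {missing}")
    records: list[SampleMeta] = []
    allowed_roles = [r.value for r in Role]
    allowed_sexes = [s.value for s in Sex]
    for _, row in raw.iterrows():
        if row["role"] not in allowed_roles:
            raise ValidationError(
                f"{path}: unknown role {row['role']!r} for sample "
                f"{row['sample_id']!r}; allowed roles: {allowed_roles}"
            )
        if row["sex"] not in allowed_sexes:
            raise ValidationError(
                f"{path}: unknown sex {row['sex']!r} for sample "
                f"{row['sample_id']!r}; allowed: {allowed_sexes}"
            )
        try:
            rep = int(row["replicate"])
        except ValueError:
            raise ParseError(
                f"{path}: non-integer replicate {row['replicate']!r}"
            ) from None
        records.append(
            SampleMeta(
                sample_id=row["sample_id"],
                role=Role(row["role"]),
                sex=Sex(row["sex"]),
                primer_set=row["primer_set"],
                replicate=rep,
            )
        )
    _check_unique_meta(records)
    return records


def write_metadata(records: Sequence[SampleMeta], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "role": r.role.value,
                "sex": r.sex.value,
                "primer_set": r.primer_set,
                "replicate": r.replicate,
            }
            for r in records
        ],
        columns=list(_META_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def write_presence(pm: PresenceMatrix, path) -> None:
    pm.values.to_csv(path, sep="\t", index_label="taxon")


def read_presence(path, meta: Sequence[SampleMeta]) -> PresenceMatrix:
    """Read a binary taxa x specimen TSV; sex labels come from metadata."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "taxon":
        raise ParseError(f"{path}: first column must be 'taxon'")
    raw = raw.set_index("taxon").rename_axis(None)
    try:
        values = raw.astype("int8")
    except ValueError:
        raise ParseError(f"{path}: presence cells must be 0 or 1") from None
    return PresenceMatrix(values=values, sex=specimen_sex(meta))


def read_taxonomy(path) -> TaxonomyTable:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "asv_id" not in raw.columns:
        raise ParseError(f"{path}: taxonomy must have an 'asv_id' column")
    raw = raw.set_index("asv_id").rename_axis(None)
    out = pd.DataFrame(index=raw.index)
    for rank in RANKS:
        lcol, ccol = f"{rank}_label", f"{rank}_conf"
        if lcol not in raw.columns or ccol not in raw.columns:
            raise ParseError(f"{path}: taxonomy missing {lcol}/{ccol}")
        out[lcol] = raw[lcol]
        try:
            out[ccol] = raw[ccol].astype(float)
        except ValueError:
            raise ParseError(f"{path}: non-numeric confidence in {ccol}") from None
    if "is_mock" not in raw.columns:
        raise ParseError(f"{path}: taxonomy missing 'is_mock'")
    lowered = raw["is_mock"].str.lower()
    if not lowered.isin(["true", "false", "0", "1"]).all():
        raise ParseError(f"{path}: 'is_mock' must be true/false")
    out["is_mock"] = lowered.isin(["true", "1"])
    return TaxonomyTable(table=out)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    df = tax.table.copy()
    df["is_mock"] = df["is_mock"].map({True: "true", False: "false"})
    # default float formatting is repr-based and round-trips exactly
    df.to_csv(path, sep="\t", index_label="asv_id")
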
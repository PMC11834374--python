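"""Observation tables for tripartite aphid community surveys.

One record per sampled aphid individual, linking the aphid species to the
plant it was collected from, the parasitoid that attacked it (if any) and
the facultative-symbiont strain it carried (if any).  Screened-but-negative
samples carry the sentinel ``"No Association"`` which is distinct from a
missing value: the former is an observation, the latter is absent data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NO_ASSOCIATION = "No Association"

#: canonical column names; input headers are matched case-insensitively
COLUMNS = (
    "sample_id",
    "year",
    "location",
    "aphid_species",
    "plant_species",
    "parasitoid_species",
    "strain_id",
    "source",
)

MANDATORY = ("sample_id", "aphid_species")

PARTNER_COLUMNS = {
    "parasitoid": "parasitoid_species",
    "plant": "plant_species",
    "strain": "strain_id",
}

SOURCES = ("mummy", "live", "legacy")


class ValidationError(ValueError):
    """Raised when an observation table violates its invariants."""


class ConfigurationError(ValueError):
    """Raised when input columns cannot be mapped onto the record schema."""


@dataclass
class ObservationTable:
    """Validated table of per-individual observations.

    Attributes
    ----------
    records
        One row per sampled aphid; columns per :data:`COLUMNS`.
    provenance
        Free-text log entries (source path, filters applied, rows removed).
    """

    records: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "ObservationTable":
        return ObservationTable(self.records.copy(), list(self.provenance))


def _is_present(series: pd.Series) -> pd.Series:
    """True where a partner field holds an actual taxon (not missing, not
    the 'No Association' sentinel)."""
    return series.notna() & (series != NO_ASSOCIATION) & (series != "")


def validate_table(df: pd.DataFrame) -> None:
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate sample_id values: {dup}")
    empty = df.index[df["aphid_species"].isna() | (df["aphid_species"] == "")]
    if len(empty):
        raise ValidationError(
            f"empty aphid_species in rows {empty.tolist()}"
        )
    partners = [c for c in PARTNER_COLUMNS.values() if c in df.columns]
    if partners:
        any_present = np.zeros(len(df), dtype=bool)
        for c in partners:
            any_present |= df[c].notna().to_numpy() & (df[c] != "").to_numpy()
        orphans = df.index[~any_present]
        if len(orphans):
            raise ValidationError(
                "records with no plant, parasitoid or strain field at rows "
                f"{orphans.tolist()}"
            )


def read_observations(
    path: str | Path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> ObservationTable:
    """Read a delimited observation table (CSV/TSV autodetected).

    Parameters
    ----------
    path
        Input file; first row is the header.
    delimiter
        Explicit field delimiter; sniffed from the header line if omitted.
    column_map
        Optional ``{input header -> canonical field}`` mapping applied
        after lower-casing, for files whose headers differ from
        :data:`COLUMNS`.

    Raises
    ------
    ConfigurationError
        If a mandatory column cannot be located.
    ValidationError
        If sample ids are duplicated or rows violate record invariants;
        offending row numbers are reported.
    """
    path = Path(path)
    if delimiter is None:
        with open(path, newline="") as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.replace({"": np.nan, "NA": np.nan}, inplace=True)

    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    if column_map:
        df = df.rename(columns={k.lower(): v for k, v in column_map.items()})
    df = df[[c for c in COLUMNS if c in df.columns]]
    if "year" in df.columns:
        bad = df.index[df["year"].notna() & ~df["year"].str.fullmatch(r"\d{4}")]
        if len(bad):
            raise ValidationError(f"unparseable year in rows {(bad + 2).tolist()}")
        df["year"] = df["year"].astype("Int64")
    validate_table(df)
    table = ObservationTable(df.reset_index(drop=True))
    table.log(f"read {len(df)} records from {path}")
    return table


@dataclass
class FilterConfig:
    """Rules applied by :func:`filter_observations`.

    ``host_list`` maps aphid species to their recognised host plants; a
    singleton (aphid, plant) pair on an unlisted plant is treated as a
    transient association and removed.  With no host list every singleton
    pair is removed.  ``partner_kind`` additionally drops records that are
    missing or 'No Association' for that partner, preparing the table for
    a single downstream community matrix.
    """

    partner_kind: str | None = None
    host_list: Mapping[str, Iterable[str]] | None = None
    drop_transient: bool = True


def filter_observations(
    table: ObservationTable, rules: FilterConfig
) -> ObservationTable:
    """Apply transient-association and partner-presence filters.

    Returns a filtered copy; every removal is appended to the provenance
    log.  An empty result is permitted (logged as a warning line).
    """
    df = table.records
    keep = pd.Series(True, index=df.index)
    log: list[str] = []

    # partner-presence rule first: transient detection then operates on the
    # records that actually enter the downstream analysis, which makes the
    # combined filter idempotent.
    if rules.partner_kind is not None:
        col = PARTNER_COLUMNS[rules.partner_kind]
        present = _is_present(df[col]) if col in df.columns else pd.Series(False, index=df.index)
        for idx in df.index[~present]:
            log.append(
                f"removed {df.at[idx, 'sample_id']}: no {rules.partner_kind} association"
            )
        keep &= present

    if rules.drop_transient and "plant_species" in df.columns:
        plant_ok = keep & _is_present(df["plant_species"])
        pair_counts = df[plant_ok].groupby(
            ["aphid_species", "plant_species"]
        ).size()
        singletons = set(pair_counts.index[pair_counts == 1])
        for idx in df.index[plant_ok]:
            pair = (df.at[idx, "aphid_species"], df.at[idx, "plant_species"])
            if pair not in singletons:
                continue
            hosts = set(rules.host_list.get(pair[0], ())) if rules.host_list else set()
            if pair[1] not in hosts:
                keep[idx] = False
                log.append(
                    f"removed {df.at[idx, 'sample_id']}: singleton (aphid,plant) "
                    f"pair {pair} not in recognised host list"
                )

    out = ObservationTable(df[keep].reset_index(drop=True), list(table.provenance))
    out.provenance.extend(log)
    out.log(f"filter: kept {int(keep.sum())}/{len(df)} records")
    if keep.sum() == 0:
        out.log("warning: filter produced an empty table")
    return out


@dataclass
class CommunityMatrix:
    """Aphid-species x partner-taxon count matrix.

    Rows are focal aphid species, columns partner taxa (parasitoid species,
    plant taxa, or symbiont strain ids), both sorted lexicographically so
    output is byte-stable across runs.
    """

    counts: pd.DataFrame
    partner_kind: str

    @property
    def focal_labels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def partner_labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def __post_init__(self) -> None:
        v = self.counts.to_numpy()
        if (v < 0).any():
            raise ValidationError("negative counts in community matrix")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValidationError("duplicate row/column labels")

    def to_csv(self, path: str | Path) -> None:
        self.counts.to_csv(path)


def build_community_matrix(
    table: ObservationTable, partner_kind: str
) -> CommunityMatrix:
    """Tally records into an aphid x partner count matrix.

    ``counts[i, j]`` is the number of records pairing aphid species *i*
    with partner taxon *j*.  Records missing the partner (or carrying the
    'No Association' sentinel) are ignored; if none remain an error names
    the partner kind.
    """
    col = PARTNER_COLUMNS[partner_kind]
    df = table.records
    if col not in df.columns:
        raise ValidationError(f"no usable records for partner_kind={partner_kind!r}")
    usable = df[_is_present(df[col])]
    if usable.empty:
        raise ValidationError(f"no usable records for partner_kind={partner_kind!r}")
    counts = (
        usable.groupby(["aphid_species", col])
        .size()
        .unstack(fill_value=0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    counts = counts.astype(int)
    counts.index.name = "aphid_species"
    counts.columns.name = col
    return CommunityMatrix(counts, partner_kind)


def align_species(
    matrices: Sequence[CommunityMatrix],
    relatedness: pd.DataFrame | None = None,
) -> tuple[list[CommunityMatrix], pd.DataFrame | None, list[str]]:
    """Restrict all inputs to the aphid species common to every matrix.

    A species counts as present in a matrix only if its row is non-zero.
    The shared species set is applied in one common (lexicographic) order
    to every matrix and to the relatedness matrix if given.  Species
    lacking data in any input are dropped and reported.

    Returns ``(aligned matrices, aligned relatedness, dropped species)``.

    Raises
    ------
    ValidationError
        If fewer than 3 species are common to all inputs (pairwise matrix
        regression needs at least 3 species to form off-diagonal pairs).
    """
    sets = []
    for m in matrices:
        nz = m.counts.index[m.counts.sum(axis=1) > 0]
        sets.append(set(nz))
    if relatedness is not None:
        sets.append(set(relatedness.index))
    common = sorted(set.intersection(*sets))
    union = sorted(set.union(*sets))
    dropped = [s for s in union if s not in common]
    if len(common) < 3:
        raise ValidationError(
            f"only {len(common)} species common to all inputs; need >= 3"
        )
    aligned = [
        CommunityMatrix(m.counts.loc[common], m.partner_kind) for m in matrices
    ]
    rel = relatedness.loc[common, common] if relatedness is not None else None
    return aligned, rel, dropped


def write_removal_log(table: ObservationTable, path: str | Path) -> None:
    Path(path).write_text("\n".join(table.provenance) + "\n")
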
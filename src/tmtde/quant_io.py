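"""Readers and writers for protein quantification tables, study designs and gene sets.

The ingestion target is the tab-separated protein-groups table produced by
MaxQuant-style search engines: one row per protein group, an accession
column, an optional gene-symbol column, and one reporter-intensity column
per labelled sample.  Zero intensities mean "not quantified" and are kept
as zeros at ingestion -- downstream filtering counts them explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

LINEAR = "linear"
LOG2 = "log2"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class QuantTable:
    """Protein x sample intensity matrix.

    ``values`` is a float DataFrame indexed by unique protein accessions with
    one column per sample; ``NaN`` marks a missing (unparseable or explicitly
    absent) cell, which is distinct from a zero reporter intensity on the
    linear scale.  ``scale`` is ``"linear"`` (non-negative intensities) or
    ``"log2"`` (finite log2 intensities, zeros impossible).
    """

    values: pd.DataFrame
    gene_symbols: pd.Series | None = None
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series("", index=self.values.index, dtype=object)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise FormatError(f"duplicate protein ids: {dups}")
        if (idx.astype(str) == "").any():
            raise FormatError("empty protein id")
        if not self.gene_symbols.index.equals(idx):
            raise ValueError("gene_symbols index does not match protein ids")
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        arr = self.values.to_numpy(dtype=float)
        observed = ~np.isnan(arr)
        if self.scale == LINEAR:
            if not np.all(np.isfinite(arr[observed])) or (arr[observed] < 0).any():
                raise ValueError("linear-scale cells must be finite and >= 0")
        else:
            if not np.all(np.isfinite(arr[observed])):
                raise ValueError("log2-scale cells must be finite")

    # -- conveniences ------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "QuantTable":
        return QuantTable(self.values.copy(), self.gene_symbols.copy(), self.scale)

    def subset(self, protein_ids) -> "QuantTable":
        return QuantTable(
            self.values.loc[protein_ids],
            self.gene_symbols.loc[protein_ids],
            self.scale,
        )


@dataclass
class StudyDesign:
    """Sample-to-group assignment for one tissue.

    The reference design is four groups of four pooled samples each:
    naive-sedentary, naive-exercise, lesioned-sedentary, lesioned-exercise.
    """

    sample_to_group: dict[str, str]
    tissue: str = ""

    def __post_init__(self) -> None:
        if not self.sample_to_group:
            raise ValueError("design has no samples")
        # insertion order of first appearance defines group order
        self.groups: list[str] = list(dict.fromkeys(self.sample_to_group.values()))

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_group)

    def samples_in(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return [s for s, g in self.sample_to_group.items() if g == group]

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in self.groups}

    def validate_against(self, q: QuantTable) -> None:
        missing = [s for s in self.samples if s not in q.values.columns]
        if missing:
            raise ValueError(f"design samples absent from quant table: {missing}")


@dataclass(frozen=True)
class Contrast:
    """A numerator/denominator group pair, e.g. exercise over sedentary."""

    numerator: str
    denominator: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("contrast numerator equals denominator")
        if not self.name:
            object.__setattr__(self, "name", f"{self.numerator}_vs_{self.denominator}")

    def validate_against(self, d: StudyDesign) -> None:
        for g in (self.numerator, self.denominator):
            if g not in d.groups:
                raise ValueError(f"contrast group {g!r} not in design groups {d.groups}")

    def reversed(self) -> "Contrast":
        return Contrast(self.denominator, self.numerator)


@dataclass
class GeneSetCollection:
    """Named identifier sets (e.g. pathway memberships) for enrichment."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class IngestReport:
    """Bookkeeping from reading a quantification table."""

    n_rows_read: int
    n_flagged_dropped: int
    dropped_ids: list[str]
    intensity_columns: list[str]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

FLAG_COLUMNS = ("Reverse", "Potential contaminant")


def read_quant_table(
    path,
    id_column: str = "Protein IDs",
    intensity_prefix: str = "Reporter intensity corrected",
    gene_column: str = "Gene names",
) -> tuple[QuantTable, IngestReport]:
    """Read a MaxQuant-style protein-groups TSV into a linear-scale QuantTable.

    Sample columns are those whose header starts with ``intensity_prefix``;
    the prefix itself is stripped from the resulting sample names.  Rows
    flagged ``+`` in the standard ``Reverse`` / ``Potential contaminant``
    columns (when present) are dropped and counted in the report.
    Unparseable or blank intensity cells become missing; negative values are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise FormatError(f"missing id column {id_column!r}")
    intensity_cols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not intensity_cols:
        raise FormatError(f"no column matches intensity prefix {intensity_prefix!r}")

    n_read = len(df)
    flagged = pd.Series(False, index=df.index)
    for col in FLAG_COLUMNS:
        if col in df.columns:
            flagged |= df[col].str.strip() == "+"
    dropped_ids = df.loc[flagged, id_column].tolist()
    df = df.loc[~flagged]

    ids = df[id_column].str.strip()
    if (ids == "").any():
        raise FormatError("blank protein id")
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate protein ids: {sorted(dup)}")

    values = (
        df[intensity_cols]
        .apply(pd.to_numeric, errors="coerce")
        .set_axis(ids, axis=0)
    )
    sample_names = [c[len(intensity_prefix):].strip() or c for c in intensity_cols]
    values.columns = sample_names
    if (values.to_numpy() < 0).any():
        raise FormatError("negative intensity value")

    if gene_column in df.columns:
        genes = df[gene_column].str.strip().set_axis(ids)
    else:
        genes = pd.Series("", index=ids, dtype=object)

    report = IngestReport(
        n_rows_read=n_read,
        n_flagged_dropped=int(flagged.sum()),
        dropped_ids=dropped_ids,
        intensity_columns=intensity_cols,
    )
    logger.info(
        "read %d rows from %s; dropped %d flagged rows; %d samples",
        n_read, path, report.n_flagged_dropped, len(sample_names),
    )
    return QuantTable(values, genes, scale=LINEAR), report


def read_design(path, tissue: str = "") -> StudyDesign:
    """Read a two-column (sample, group) delimited file into a StudyDesign."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#",
                     skip_blank_lines=True)
    if df.shape[1] < 2:
        raise FormatError("design file needs two tab-separated columns: sample, group")
    # tolerate a header row
    first = df.iloc[0]
    if first[0].strip().lower() in ("sample", "sample_id") :
        df = df.iloc[1:]
    if df.empty:
        raise FormatError("design file has no sample rows")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        sample, group = row[0].strip(), row[1].strip()
        if not sample or not group:
            raise FormatError(f"blank sample or group in design row {row.tolist()}")
        if sample in mapping and mapping[sample] != group:
            raise FormatError(
                f"sample {sample!r} assigned to both {mapping[sample]!r} and {group!r}"
            )
        mapping[sample] = group
    return StudyDesign(mapping, tissue=tissue)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >= 3 fields, got {len(fields)}")
            name, desc, *members = fields
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

DE_COLUMNS = ["protein_id", "gene_symbol", "log2_ratio", "status",
              "lower_fence", "upper_fence"]

ENRICH_COLUMNS = ["set_name", "overlap", "set_size", "query_size",
                  "universe_size", "p_value", "q_value", "overlap_ids"]

_FLOAT_FMT = "%.17g"


def write_results(results, path) -> None:
    """Write a DEResultSet or a list of EnrichmentRecords as a TSV.

    Numeric fields are written with 17 significant digits so a round trip
    through :func:`read_de_results` is lossless; undefined values render as
    the explicit ``NA`` token.
    """
    if hasattr(results, "records"):          # DEResultSet (duck-typed)
        rows = [
            {
                "protein_id": r.protein_id,
                "gene_symbol": r.gene_symbol,
                "log2_ratio": r.log2_ratio,
                "status": r.status,
                "lower_fence": results.fences.lower,
                "upper_fence": results.fences.upper,
            }
            for r in results.records
        ]
        df = pd.DataFrame(rows, columns=DE_COLUMNS)
    else:                                     # enrichment record list
        rows = [
            {
                "set_name": r.set_name,
                "overlap": r.k,
                "set_size": r.K,
                "query_size": r.n,
                "universe_size": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "overlap_ids": ";".join(sorted(r.overlap_ids)),
            }
            for r in results
        ]
        df = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format=_FLOAT_FMT)


def read_de_results(path) -> pd.DataFrame:
    """Read back a DE result TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene_symbol": str},
                     na_values=[NA_TOKEN], keep_default_na=False,
                     float_precision="round_trip")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"DE result table missing columns {missing}")
    return df


def write_quant_table(q: QuantTable, path, zeros_for_missing: bool = False) -> None:
    """Write a QuantTable as a TSV with protein_id / gene_symbol / sample columns."""
    values = q.values
    if zeros_for_missing:
        values = values.fillna(0.0)
    out = values.copy()
    out.insert(0, "gene_symbol", q.gene_symbols)
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=_FLOAT_FMT)
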
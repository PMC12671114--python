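"""Reading and writing the tabular formats the pipeline consumes.

The universal input is a MetaPhlAn-style merged abundance table: a TSV whose
first column holds clade strings (``k__Bacteria|p__...|g__...|s__...``) and
whose remaining columns are samples, values being relative abundances in
percent.  Sample metadata travels as a plain TSV with one row per sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gutcompass")

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "GutcompassError",
    "RANK_PREFIXES",
    "read_metaphlan_table",
    "write_metaphlan_table",
    "read_metadata",
    "write_metadata",
    "align_samples",
    "write_tsv",
    "write_manifest",
]

#: float format used for every TSV the pipeline writes (12 significant digits,
#: enough for lossless round-trips of float64-derived results at this scale)
TSV_FLOAT_FORMAT = "%.12g"

RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}

#: sub-species (SGB) marker; rows carrying it are below species rank
SGB_PREFIX = "t__"


class GutcompassError(ValueError):
    """Raised for invalid inputs anywhere in the pipeline."""


@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances (percent), at a single rank.

    ``data`` is a DataFrame indexed by sample id with taxon clade strings as
    columns.  ``rank`` is the taxonomic level of the columns, or
    ``"functional"`` for module-abundance tables (which are exempt from the
    percent-sum invariant).
    """

    data: pd.DataFrame
    rank: str

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def validate(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise GutcompassError(f"duplicate sample ids: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise GutcompassError(f"duplicate taxon labels: {dupes}")
        vals = self.values
        if not np.isfinite(vals).all():
            raise GutcompassError("abundance table contains non-finite values")
        if (vals < 0).any():
            raise GutcompassError("abundance table contains negative values")
        if self.rank != "functional":
            sums = vals.sum(axis=1)
            bad = (sums < 99.0) | (sums > 101.0)
            if bad.any():
                offenders = [self.sample_ids[i] for i in np.flatnonzero(bad)[:5]]
                raise GutcompassError(
                    f"per-sample abundance sums outside [99, 101] for {offenders} "
                    f"(sums {sums[bad][:5]})"
                )

    def proportions(self) -> pd.DataFrame:
        """Per-sample closure to proportions summing to 1."""
        vals = self.values
        return pd.DataFrame(
            vals / vals.sum(axis=1, keepdims=True),
            index=self.data.index,
            columns=self.data.columns,
        )


@dataclass
class SampleMetadata:
    """Per-sample covariates: cohort, age, sex, medication exposure flags.

    Medication flags are 0/1 columns named with a common prefix (one per ATC
    3rd-level group in real data, e.g. exposure within 30 days before
    sampling; antineoplastics use a 180-day window).  ``any_medication`` is
    1 iff at least one flag is 1, and is re-derived on construction if the
    file did not carry it.
    """

    data: pd.DataFrame
    medication_columns: list[str] = field(default_factory=list)

    REQUIRED = ("sample_id", "cohort", "age", "sex")

    def __post_init__(self) -> None:
        df = self.data
        for col in self.REQUIRED:
            if col not in df.columns:
                raise GutcompassError(f"metadata is missing required column '{col}'")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise GutcompassError(f"duplicated sample_id in metadata: {dupes}")
        if (pd.to_numeric(df["age"], errors="coerce") < 0).any():
            raise GutcompassError("negative age in metadata")
        for col in self.medication_columns:
            if not set(pd.unique(df[col])) <= {0, 1}:
                raise GutcompassError(f"medication flag column '{col}' is not 0/1")
        if self.medication_columns:
            derived = df[self.medication_columns].max(axis=1).astype(int)
        else:
            derived = pd.Series(0, index=df.index)
        if "any_medication" in df.columns:
            if self.medication_columns and not (df["any_medication"].astype(int) == derived).all():
                raise GutcompassError(
                    "any_medication inconsistent with medication flags"
                )
        else:
            df["any_medication"] = derived
        self.data = df.set_index(df["sample_id"].astype(str)).rename_axis(None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, name: str) -> pd.Series:
        return self.data[name]


def _rank_of(clade: str) -> str | None:
    """Rank at which a clade string terminates, or None if unrecognised."""
    last = clade.split("|")[-1]
    if last.startswith(SGB_PREFIX):
        return "sgb"
    for rank, prefix in RANK_PREFIXES.items():
        if last.startswith(prefix):
            return rank
    return None


def read_metaphlan_table(path, rank: str = "species") -> AbundanceTable:
    """Read a merged MetaPhlAn-style TSV, keeping rows at a single rank.

    Handles both the plain dialect (first column = clade, rest samples) and
    the two-column-header dialect with an ``NCBI_tax_id`` column, detected by
    header sniffing.  Comment lines start with ``#``.  Rows below species
    (``t__`` SGB rows) are never returned.
    """
    if rank not in RANK_PREFIXES and rank != "functional":
        raise GutcompassError(f"unknown rank '{rank}'")
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if df.shape[1] < 2:
        raise GutcompassError(f"{path}: expected >=2 tab-separated columns")
    clade_col = df.columns[0]
    drop = [clade_col]
    if len(df.columns) > 1 and df.columns[1].lower() in ("ncbi_tax_id", "clade_taxid"):
        drop.append(df.columns[1])
    clades = df[clade_col].astype(str)
    values = df.drop(columns=drop)
    if rank == "functional":
        keep = pd.Series(True, index=df.index)
    else:
        keep = clades.map(lambda c: _rank_of(c) == rank)
    if not keep.any():
        raise GutcompassError(f"{path}: no rows at rank '{rank}'")
    sub = values[keep]
    cols = {}
    for col in sub.columns:
        parsed = pd.to_numeric(sub[col], errors="coerce")
        if parsed.isna().any():
            bad_row = clades[keep][parsed.isna()].iloc[0]
            raise GutcompassError(
                f"{path}: non-numeric value in column '{col}', row '{bad_row}'"
            )
        cols[col] = parsed.to_numpy()
    numeric = pd.DataFrame(cols, index=clades[keep].to_numpy())
    table_rank = rank
    return AbundanceTable(data=numeric.T, rank=table_rank)


def write_metaphlan_table(table: AbundanceTable, path, with_parent_ranks: bool = False) -> None:
    """Write an AbundanceTable back to merged-MetaPhlAn layout (taxa as rows).

    With ``with_parent_ranks`` a species table additionally receives genus
    rows (sums over species sharing a genus) and a kingdom row, as real
    merged profiles carry all ranks.
    """
    frames = [table.data.T]
    if with_parent_ranks and table.rank == "species":
        genus_labels = [lbl.rsplit("|", 1)[0] for lbl in table.taxon_labels]
        genus = table.data.T.groupby(genus_labels).sum()
        kingdom_labels = [lbl.split("|", 1)[0] for lbl in genus.index]
        kingdom = genus.groupby(kingdom_labels).sum()
        frames = [kingdom, genus, table.data.T]
    out = pd.concat(frames)
    out.index.name = "clade_name"
    out.to_csv(path, sep="\t", float_format=TSV_FLOAT_FORMAT)


def read_metadata(path, medication_prefix: str = "med_") -> SampleMetadata:
    """Read a metadata TSV; medication flags are detected by column prefix.

    Unknown extra columns are preserved as passthrough.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    med_cols = [c for c in df.columns if c.startswith(medication_prefix)]
    for col in med_cols:
        df[col] = df[col].astype(int)
    return SampleMetadata(data=df, medication_columns=med_cols)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index=False, float_format=TSV_FLOAT_FORMAT)


def align_samples(table: AbundanceTable, meta: SampleMetadata) -> tuple[AbundanceTable, SampleMetadata]:
    """Inner-join the table and metadata on sample id.

    Samples present on one side only are dropped with a logged warning
    listing their ids (fail-soft on partial cohorts, loudly).
    """
    common = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    dropped_tab = sorted(set(table.sample_ids) - set(common))
    dropped_meta = sorted(set(meta.sample_ids) - set(common))
    if not common:
        raise GutcompassError("no overlapping sample ids between table and metadata")
    if dropped_tab or dropped_meta:
        logger.warning(
            "sample/metadata join dropped ids: abundance-only=%s metadata-only=%s",
            dropped_tab, dropped_meta,
        )
    new_table = AbundanceTable(data=table.data.loc[common], rank=table.rank)
    new_meta = SampleMetadata(
        data=meta.data.loc[common].reset_index(drop=True),
        medication_columns=list(meta.medication_columns),
    )
    return new_table, new_meta


def collapse_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum a species-level table up to a coarser rank (e.g. genus).

    Column labels are truncated at the requested rank's field; columns whose
    clade string does not reach that rank are dropped.
    """
    if rank not in RANK_PREFIXES:
        raise GutcompassError(f"unknown rank '{rank}'")
    prefix = RANK_PREFIXES[rank]
    groups: dict[str, list[str]] = {}
    for label in table.taxon_labels:
        fields = label.split("|")
        idx = next((i for i, f in enumerate(fields) if f.startswith(prefix)), None)
        if idx is None:
            continue
        groups.setdefault("|".join(fields[: idx + 1]), []).append(label)
    if not groups:
        raise GutcompassError(f"no taxa reach rank '{rank}'")
    data = pd.DataFrame(
        {parent: table.data[children].sum(axis=1)
         for parent, children in groups.items()}
    )
    return AbundanceTable(data=data, rank=rank)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a result table at the package's declared TSV precision."""
    df.to_csv(path, sep="\t", index=index, float_format=TSV_FLOAT_FORMAT)


def write_manifest(path, *, inputs: dict, seed, parameters: dict) -> None:
    """Write the machine-readable run manifest (inputs, seed, versions, params)."""
    import importlib.metadata

    versions = {"gutcompass": "0.1.0"}
    for dep in ("numpy", "scipy", "pandas", "scikit-learn", "statsmodels"):
        try:
            versions[dep] = importlib.metadata.version(dep)
        except importlib.metadata.PackageNotFoundError:  # pragma: no cover
            versions[dep] = "unknown"
    manifest = {
        "inputs": inputs,
        "seed": seed,
        "versions": versions,
        "parameters": parameters,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
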
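"""Data model and I/O for OTU count tables, taxonomy, metadata and networks.

The central object is :class:`CountTable`, an OTU-rows x sample-columns
matrix of read counts with an ``is_relative`` flag.  Supported on-disk
dialects are mothur ``.shared`` / ``.cons.taxonomy`` files (the output of the
standard amplicon pipeline upstream of this package) and plain UTF-8
tab-separated tables.  All file orientation quirks are resolved at read time:
internally every table is OTU x sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

DEPTH_LEVELS = ("topsoil", "subsoil")
COMPARTMENT_LEVELS = ("bulk", "drilosphere", "rhizosphere")


class TableFormatError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """OTU x sample abundance matrix.

    Parameters
    ----------
    counts
        DataFrame with OTU ids on the index and sample ids on the columns.
        Raw tables hold non-negative integers (reads); relative tables hold
        per-sample proportions in [0, 1].
    is_relative
        False for raw read counts, True after closure to proportions.
    """

    counts: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate otu_ids in count table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample_ids in count table")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("negative values in count table")
        if self.is_relative and arr.size:
            sums = arr.sum(axis=0)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0))
            if bad.any():
                raise ValueError(
                    "relative table columns must sum to 1 (or 0): "
                    f"{list(self.counts.columns[bad])}"
                )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.is_relative)


@dataclass
class SampleMetadata:
    """Sample design table: depth x compartment x replicate per sample."""

    table: pd.DataFrame  # index sample_id; columns depth, compartment, replicate

    def __post_init__(self) -> None:
        required = {"depth", "compartment", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample_ids in metadata")
        bad_depth = set(self.table["depth"]) - set(DEPTH_LEVELS)
        if bad_depth:
            raise ValueError(f"unknown depth levels: {sorted(bad_depth)}")
        bad_comp = set(self.table["compartment"]) - set(COMPARTMENT_LEVELS)
        if bad_comp:
            raise ValueError(f"unknown compartments: {sorted(bad_comp)}")
        if (self.table["replicate"].astype(int) < 1).any():
            raise ValueError("replicate ids must be >= 1")
        dup = self.table.duplicated(subset=["depth", "compartment", "replicate"])
        if dup.any():
            raise ValueError(
                "replicate ids must be unique within each depth x compartment cell"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def cell(self, sample_id: str) -> tuple[str, str]:
        row = self.table.loc[sample_id]
        return str(row["depth"]), str(row["compartment"])

    def cells(self) -> list[tuple[str, str]]:
        """Design cells present, in fixed (depth, compartment) order."""
        present = {
            (str(d), str(c))
            for d, c in zip(self.table["depth"], self.table["compartment"])
        }
        return [
            (d, c)
            for d in DEPTH_LEVELS
            for c in COMPARTMENT_LEVELS
            if (d, c) in present
        ]

    def samples_in_cell(self, depth: str, compartment: str) -> list[str]:
        mask = (self.table["depth"] == depth) & (
            self.table["compartment"] == compartment
        )
        return list(self.table.index[mask])

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass
class TaxonomyTable:
    """OTU -> ranked lineage with per-rank classified flags.

    ``lineage`` holds rank names (``domain`` .. ``genus``); a rank whose name
    contains the token "unclassified" (case-insensitive, RDP-style
    ``<parent>_unclassified`` placeholders included) is flagged unclassified.
    """

    lineage: pd.DataFrame  # index otu_id; columns RANKS (strings)
    classified: pd.DataFrame = field(default=None)  # same shape, bool

    def __post_init__(self) -> None:
        if self.lineage.index.has_duplicates:
            raise ValueError("duplicate otu_ids in taxonomy")
        for rank in RANKS:
            if rank not in self.lineage.columns:
                raise ValueError(f"taxonomy missing rank column {rank!r}")
        if self.classified is None:
            self.classified = ~self.lineage.apply(
                lambda col: col.str.contains("unclassified", case=False, na=True)
            )
        # contiguity: once a rank is unclassified, all deeper ranks are too
        flags = self.classified[list(RANKS)].to_numpy(dtype=bool)
        seen_unclassified = np.zeros(flags.shape[0], dtype=bool)
        for j in range(flags.shape[1]):
            bad = seen_unclassified & flags[:, j]
            if bad.any():
                raise ValueError(
                    "non-contiguous classification for OTUs "
                    f"{list(self.lineage.index[bad])}: classified rank below an "
                    "unclassified one"
                )
            seen_unclassified |= ~flags[:, j]

    @property
    def otu_ids(self) -> list[str]:
        return list(self.lineage.index)

    def classified_lineage(self, otu_id: str) -> list[tuple[str, str]]:
        """(rank, name) pairs from domain down to the deepest classified rank."""
        out = []
        for rank in RANKS:
            if not bool(self.classified.loc[otu_id, rank]):
                break
            out.append((rank, str(self.lineage.loc[otu_id, rank])))
        return out

    def label(self, otu_id: str) -> str:
        """Deepest classified name, or 'unclassified' when nothing resolved."""
        lin = self.classified_lineage(otu_id)
        return lin[-1][1] if lin else "unclassified"


@dataclass
class CopyNumberTable:
    """(rank, taxon name) -> mean 16S rRNA gene copies per genome.

    A default entry at rank "root" is mandatory; lineage lookups that fail at
    every classified rank fall back to it.
    """

    entries: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (rank, name), copies in self.entries.items():
            if not copies > 0:
                raise ValueError(f"mean_copies must be > 0 for ({rank}, {name})")
        if not any(rank == "root" for rank, _ in self.entries):
            raise ValueError("copy-number table requires a rank='root' default")

    @property
    def root_default(self) -> float:
        for (rank, _), copies in self.entries.items():
            if rank == "root":
                return copies
        raise AssertionError("unreachable: root default enforced at init")

    def lookup(self, lineage: list[tuple[str, str]]) -> float:
        """Mean copies at the deepest classified rank present, else the root."""
        for rank, name in reversed(lineage):
            value = self.entries.get((rank, name))
            if value is not None:
                return value
        return self.root_default


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty file") from exc
    return df


def read_count_table(path, dialect: str = "tsv") -> CountTable:
    """Read a raw OTU count table.

    ``dialect="tsv"``: header row of sample ids, first column OTU ids.
    ``dialect="mothur_shared"``: mothur shared file (sample rows; the
    label/Group/numOtus columns are consumed and the matrix transposed).
    """
    df = _read_tsv(path)
    if dialect == "tsv":
        otu_col = df.columns[0]
        df = df.set_index(otu_col)
        counts = _to_int_counts(df, path)
    elif dialect == "mothur_shared":
        expected = ["label", "Group", "numOtus"]
        if [c.lower() for c in df.columns[:3]] != [c.lower() for c in expected]:
            raise TableFormatError(
                f"{path}: mothur shared header must start with {expected}, "
                f"got {list(df.columns[:3])}"
            )
        groups = df.iloc[:, 1]
        if groups.duplicated().any():
            raise TableFormatError(f"{path}: duplicate Group entries")
        body = df.iloc[:, 3:].copy()
        body.index = groups
        counts = _to_int_counts(body.T, path)  # -> OTU rows x sample cols
    else:
        raise ValueError(f"unknown count-table dialect {dialect!r}")
    if counts.index.duplicated().any():
        raise TableFormatError(f"{path}: duplicate OTU ids")
    return CountTable(counts, is_relative=False)


def _to_int_counts(df: pd.DataFrame, path) -> pd.DataFrame:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise TableFormatError(
            f"{path}: non-numeric count at OTU {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    arr = numeric.to_numpy()
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere((arr < 0) | ~np.isclose(arr, np.round(arr)))[0]
        raise TableFormatError(
            f"{path}: counts must be non-negative integers; offending cell "
            f"OTU {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    out = numeric.astype(np.int64)
    out.index = out.index.astype(str)
    out.index.name = "otu_id"
    out.columns = out.columns.astype(str)
    return out


def parse_lineage_string(raw: str) -> list[str]:
    """Split an RDP-style lineage, stripping bootstrap confidences.

    ``"Bacteria(100);Actinobacteria(98);"`` -> ``["Bacteria", "Actinobacteria"]``.
    """
    names = []
    for tok in str(raw).strip().strip(";").split(";"):
        tok = tok.strip()
        if not tok:
            continue
        if tok.endswith(")") and "(" in tok:
            tok = tok[: tok.rindex("(")]
        names.append(tok.strip().strip('"'))
    return names


def read_taxonomy(path, dialect: str = "tsv") -> TaxonomyTable:
    """Read OTU taxonomy (mothur ``.cons.taxonomy`` or a 2+-column TSV).

    Both dialects carry one row per OTU with a semicolon-separated lineage;
    the mothur dialect additionally has a Size column which is ignored.
    """
    df = _read_tsv(path)
    cols = [c.lower() for c in df.columns]
    if dialect == "mothur_cons":
        if "taxonomy" not in cols:
            raise TableFormatError(f"{path}: missing Taxonomy column")
        tax_col = df.columns[cols.index("taxonomy")]
    elif dialect == "tsv":
        tax_col = df.columns[-1]
    else:
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    otu_col = df.columns[0]
    if df[otu_col].duplicated().any():
        raise TableFormatError(f"{path}: duplicate OTU ids in taxonomy")
    rows = {}
    for _, row in df.iterrows():
        names = parse_lineage_string(row[tax_col])
        names = (names + ["unclassified"] * len(RANKS))[: len(RANKS)]
        rows[str(row[otu_col])] = names
    lineage = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    lineage.index.name = "otu_id"
    return TaxonomyTable(lineage)


def read_metadata(path) -> SampleMetadata:
    """Read the sample design TSV (sample_id, depth, compartment, replicate)."""
    df = _read_tsv(path)
    needed = {"sample_id", "depth", "compartment", "replicate"}
    if not needed <= set(df.columns):
        raise TableFormatError(
            f"{path}: metadata needs columns {sorted(needed)}, got {list(df.columns)}"
        )
    df = df.set_index("sample_id")
    df["replicate"] = df["replicate"].astype(int)
    return SampleMetadata(df[["depth", "compartment", "replicate"]])


def read_copy_numbers(path) -> CopyNumberTable:
    """Read a copy-number TSV shaped like rrnDB pan-taxa statistics exports.

    Columns: rank, name, mean_copies.  A rank="root" default row is required.
    """
    df = _read_tsv(path)
    needed = {"rank", "name", "mean_copies"}
    if not needed <= set(df.columns):
        raise TableFormatError(
            f"{path}: copy-number table needs columns {sorted(needed)}"
        )
    entries = {
        (str(r["rank"]), str(r["name"])): float(r["mean_copies"])
        for _, r in df.iterrows()
    }
    return CopyNumberTable(entries)


# ---------------------------------------------------------------------------
# validation & writers
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    missing_metadata: list[str]
    missing_taxonomy: list[str]
    all_zero_otus: list[str]
    all_zero_samples: list[str]

    @property
    def is_clean(self) -> bool:
        return not (
            self.missing_metadata
            or self.missing_taxonomy
            or self.all_zero_otus
            or self.all_zero_samples
        )


def validate(
    table: CountTable,
    meta: SampleMetadata | None = None,
    tax: TaxonomyTable | None = None,
) -> ValidationReport:
    """Cross-check a table against its metadata and taxonomy.

    Unresolvable sample ids are an error (downstream design math would be
    wrong); missing taxonomy and all-zero rows/columns are warnings only.
    """
    missing_meta: list[str] = []
    if meta is not None:
        missing_meta = [s for s in table.sample_ids if s not in meta.table.index]
        if missing_meta:
            raise ValueError(f"samples with no metadata record: {missing_meta}")
    missing_tax: list[str] = []
    if tax is not None:
        known = set(tax.otu_ids)
        missing_tax = [o for o in table.otu_ids if o not in known]
    zero_otus = list(table.counts.index[table.counts.sum(axis=1) == 0])
    zero_samples = list(table.counts.columns[table.counts.sum(axis=0) == 0])
    report = ValidationReport(missing_meta, missing_tax, zero_otus, zero_samples)
    if not report.is_clean:
        warnings.warn(
            f"validation warnings: {len(missing_tax)} OTUs without taxonomy, "
            f"{len(zero_otus)} all-zero OTUs, {len(zero_samples)} all-zero samples",
            stacklevel=2,
        )
    return report


def write_count_table(table: CountTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def write_edge_list(edges, path) -> None:
    """Write network edges as a TSV (source, target, rho, p, sign)."""
    rows = [
        {"source": e.otu_a, "target": e.otu_b, "rho": e.rho, "p": e.p, "sign": e.sign}
        for e in edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
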
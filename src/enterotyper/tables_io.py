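"""Reading, writing and reshaping taxon count tables, metadata and trees.

Count tables are samples x taxa with integer entries; taxonomic lineage is
carried per taxon so that counts can be aggregated to any rank (the
enterotyping workflow operates at genus level).  Taxa whose genus is not
resolved are kept distinct per their deepest known ancestor, so e.g. an
unresolved genus within Enterobacteriaceae stays a unit of its own rather
than being pooled with every other unknown.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_RANK_PREFIX = dict(zip(RANKS, "kpcofg"))
UNKNOWN = "unknown"


class TableFormatError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class TaxonTable:
    """Samples x taxa count matrix with per-taxon lineage.

    ``counts`` is an integer DataFrame indexed by sample ID with taxon IDs
    as columns.  ``lineage`` maps each taxon ID to a ``rank -> name`` dict
    covering kingdom..genus, with ``"unknown"`` for unresolved ranks.
    """

    counts: pd.DataFrame
    lineage: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise TableFormatError(f"duplicated sample ID: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise TableFormatError(f"duplicated taxon ID: {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            arr = self.counts.to_numpy()
            i, j = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"taxon {self.counts.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        # fill lineage for taxa without one: genus defaults to the taxon ID
        for taxon in self.counts.columns:
            lin = self.lineage.setdefault(str(taxon), {})
            for rank in RANKS:
                lin.setdefault(rank, str(taxon) if rank == "genus" else UNKNOWN)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.counts.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.counts.columns]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.lineage == other.lineage


def read_taxon_table(path, format: str = "tsv", taxonomy_path=None) -> TaxonTable:
    """Read a count table from TSV (samples in rows) or BIOM-style JSON.

    The TSV dialect is UTF-8, tab-delimited, ``#`` comment lines ignored,
    sample IDs in the first column.  BIOM-style JSON follows the v1.0
    layout (rows are taxa/observations, columns are samples, ``data`` is
    dense or ``[row, col, value]`` sparse).  ``taxonomy_path`` optionally
    points to a TSV of per-taxon lineages (columns: taxon_id + ranks).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
        try:
            values = df.astype(float)
        except ValueError as exc:
            raise TableFormatError(f"non-numeric count in {path}: {exc}") from exc
        if not np.allclose(values, np.round(values)):
            raise TableFormatError(f"non-integer counts in {path}")
        counts = values.round().astype(np.int64)
        counts.index = counts.index.astype(str)
        lineage = _read_taxonomy(taxonomy_path) if taxonomy_path else {}
        return TaxonTable(counts, lineage)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat = np.asarray(doc["data"], dtype=float)
        lineage = {}
        for r in doc["rows"]:
            tax = (r.get("metadata") or {}).get("taxonomy")
            if tax:
                lineage[r["id"]] = _lineage_from_list(tax)
        counts = pd.DataFrame(mat.T, index=samples, columns=taxa)
        if not np.allclose(counts, np.round(counts)):
            raise TableFormatError(f"non-integer counts in {path}")
        return TaxonTable(counts.round().astype(np.int64), lineage)
    raise TableFormatError(f"unknown table format: {format!r}")


def write_taxon_table(table: TaxonTable, path, taxonomy_path=None,
                      header_lines: list[str] | None = None) -> None:
    """Write counts as TSV (samples in rows); lineage to a companion TSV."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.counts.to_csv(fh, sep="\t", index_label="sample_id")
    if taxonomy_path is not None:
        rows = [{"taxon_id": t, **table.lineage[t]} for t in table.taxon_ids]
        pd.DataFrame(rows).to_csv(taxonomy_path, sep="\t", index=False)


def _read_taxonomy(path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).set_index("taxon_id")
    return {
        str(t): {rank: str(df.loc[t].get(rank, UNKNOWN)) for rank in RANKS}
        for t in df.index
    }


def _lineage_from_list(tax: list[str]) -> dict[str, str]:
    """Greengenes-style ['k__Bacteria', ..., 'g__Bifidobacterium'] to a rank map."""
    lin = {}
    for rank, item in zip(RANKS, tax):
        name = item.split("__", 1)[1] if "__" in item else item
        lin[rank] = name if name else UNKNOWN
    for rank in RANKS:
        lin.setdefault(rank, UNKNOWN)
    return lin


def collapse_to_rank(table: TaxonTable, rank: str) -> TaxonTable:
    """Sum counts over taxa sharing the same lineage down to ``rank``.

    Taxa unresolved at ``rank`` are grouped by their deepest known lineage,
    so unresolved genera from different families form distinct units
    (labelled ``"<deepest known>;g__unknown"``).
    """
    if rank not in RANKS:
        raise TableFormatError(f"unknown rank: {rank!r}")
    depth = RANKS.index(rank) + 1
    keys: dict[str, tuple] = {}
    for taxon in table.taxon_ids:
        lin = table.lineage[taxon]
        keys[taxon] = tuple(lin[r] for r in RANKS[:depth])

    def key_label(key: tuple) -> str:
        if key[-1] != UNKNOWN:
            return key[-1]
        known = [k for k in key if k != UNKNOWN]
        deepest = known[-1] if known else UNKNOWN
        return f"{deepest};{_RANK_PREFIX[rank]}__{UNKNOWN}"

    labels: dict[tuple, str] = {}
    for key in dict.fromkeys(keys.values()):
        lab = key_label(key)
        if lab in labels.values():  # same name under a different lineage
            lab = ";".join(k for k in key if k != UNKNOWN) or UNKNOWN
        labels[key] = lab

    grouped = table.counts.T.groupby(
        [labels[keys[t]] for t in table.taxon_ids], sort=False
    ).sum().T
    lineage = {}
    for key, lab in labels.items():
        lin = dict(zip(RANKS[:depth], key))
        for r in RANKS[depth:]:
            lin[r] = UNKNOWN
        lineage[lab] = lin
    return TaxonTable(grouped, lineage)


def to_relative(table: TaxonTable) -> pd.DataFrame:
    """Per-sample relative abundances (rows sum to 1)."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise TableFormatError(f"all-zero sample: {zero.index[0]!r}")
    return table.counts.div(totals, axis=0).astype(np.float64)


def read_newick(path_or_str) -> TreeNode:
    """Parse a rooted Newick tree; missing branch lengths become 0 (warned)."""
    if isinstance(path_or_str, str) and path_or_str.rstrip().endswith(";"):
        handle = io.StringIO(path_or_str)
    else:
        handle = path_or_str
    tree = TreeNode.read(handle, format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            warnings.warn(
                f"branch without length treated as 0 ({node.name or 'internal'})",
                stacklevel=2,
            )
            node.length = 0.0
        elif node.length < 0:
            raise TableFormatError(f"negative branch length at {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(path, format="newick")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV; enforces unique (subject, time_point) pairs
    among non-failed samples."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str,
                                                         "subject_id": str})
    df = df.set_index("sample_id")
    ok = df[~df.get("extraction_failed", pd.Series(False, index=df.index)).astype(bool)]
    dup = ok.duplicated(subset=["subject_id", "time_point"])
    if dup.any():
        pair = ok.loc[dup, ["subject_id", "time_point"]].iloc[0].tolist()
        raise TableFormatError(f"duplicate (subject, time_point): {pair}")
    return df


def write_metadata(df: pd.DataFrame, path, header_lines=None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label="sample_id")
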
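"""Per-sample alpha diversity: Shannon (bits), Chao1, observed features,
Faith's phylogenetic diversity.

Shannon entropy is reported in log base 2 for comparability with the common
amplicon-pipeline convention.  Chao1 uses the bias-corrected form
``S_obs + F1(F1-1) / (2(F2+1))`` which is defined even without doubletons.
Faith's PD is root-inclusive: the branch lengths on every root-to-tip path
of an observed taxon are counted once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity.alpha import chao1 as _chao1
from skbio.diversity.alpha import faith_pd as _faith_pd

from .tables_io import TaxonTable, to_relative

__all__ = [
    "shannon", "chao1", "observed_features", "faith_pd",
    "alpha_diversity_table", "rarefy",
]


def shannon(p) -> float:
    """Shannon entropy in bits of a relative-abundance profile ``p``.

    Zero entries contribute nothing; ``p`` must sum to 1.
    """
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"profile sums to {p.sum()}, not 1")
    if (p < 0).any():
        raise ValueError("negative abundance")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate from integer counts."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("negative count")
    return float(_chao1(counts, bias_corrected=True))


def observed_features(counts) -> int:
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("negative count")
    return int((counts > 0).sum())


def faith_pd(counts, taxa, tree: TreeNode) -> float:
    """Faith's PD: total branch length spanning the observed taxa (root-inclusive)."""
    counts = np.asarray(counts)
    tips = {t.name for t in tree.tips()}
    observed = [t for t, c in zip(taxa, counts) if c > 0]
    missing = sorted(set(observed) - tips)
    if missing:
        raise ValueError(f"observed taxa missing from tree: {missing}")
    if not observed:
        return 0.0
    return float(_faith_pd(counts, taxa, tree))


def alpha_diversity_table(table: TaxonTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """All four indices per sample; ``faith_pd`` column is NaN without a tree."""
    rel = to_relative(table)
    taxa = table.taxon_ids
    records = []
    for sample in table.sample_ids:
        counts = table.counts.loc[sample].to_numpy()
        records.append({
            "sample_id": sample,
            "shannon": shannon(rel.loc[sample].to_numpy()),
            "chao1": chao1(counts),
            "observed_features": observed_features(counts),
            "faith_pd": faith_pd(counts, taxa, tree) if tree is not None else np.nan,
        })
    return pd.DataFrame(records).set_index("sample_id")


def rarefy(table: TaxonTable, depth: int, seed: int) -> TaxonTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped.  Optional
    preprocessing; the default pipeline does not rarefy.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    keep = table.counts.sum(axis=1) >= depth
    sub = table.counts.loc[keep]
    out = np.vstack([
        rng.multivariate_hypergeometric(row, depth)
        for row in sub.to_numpy()
    ]) if len(sub) else np.empty((0, len(table.taxon_ids)), dtype=np.int64)
    return TaxonTable(
        pd.DataFrame(out, index=sub.index, columns=sub.columns),
        {t: dict(l) for t, l in table.lineage.items()},
    )
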
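"""Per-subject enterotype trajectories and their hierarchical clustering.

Each subject's enterotype sequence over the visit schedule is encoded as a
concatenated one-hot vector of length T x K (T visits, K enterotypes);
missing visits are masked rather than imputed.  Subjects are compared by
Pearson-correlation distance d = 1 - r over pairwise-complete positions
and grouped by agglomerative clustering (average linkage by default), the
dendrogram being cut at a requested number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .tables_io import TaxonTable, to_relative

__all__ = [
    "TrajectoryTable", "SubjectDendrogram", "build_trajectories",
    "pearson_distance", "trajectory_distance_matrix", "hcluster",
    "cluster_composition",
]


@dataclass
class TrajectoryTable:
    """Subject-level enterotype sequences plus their one-hot encoding.

    ``states`` is subjects x time points (cluster index, NaN = missing
    visit); ``encoding`` is subjects x (T*K) floats with masked positions
    NaN.  The alternative ``transition_pairs`` encoding counts ordered
    (from, to) state pairs over consecutive observed visits.
    """

    states: pd.DataFrame
    encoding: pd.DataFrame
    time_points: list[str]
    n_states: int


def build_trajectories(assignment: pd.Series, metadata: pd.DataFrame,
                       n_states: int | None = None,
                       encoding: str = "one-hot") -> TrajectoryTable:
    """Pivot per-sample enterotype assignments into per-subject sequences.

    ``assignment`` maps sample_id to cluster index; ``metadata`` supplies
    subject, time point and the extraction-failed flag (failed samples
    become missing visits).  Rejects duplicate (subject, time point) pairs.
    """
    meta = metadata.copy()
    if "extraction_failed" in meta.columns:
        meta = meta[~meta["extraction_failed"].astype(bool)]
    missing = [s for s in assignment.index if s not in meta.index]
    if missing:
        raise ValueError(f"assigned samples without metadata: {missing[:3]}")
    meta = meta.loc[list(assignment.index)]
    dup = meta.duplicated(subset=["subject_id", "time_point"])
    if dup.any():
        pair = meta.loc[dup, ["subject_id", "time_point"]].iloc[0].tolist()
        raise ValueError(f"two samples for one (subject, time point): {pair}")

    time_points = list(dict.fromkeys(meta["time_point"]))
    states = pd.DataFrame(
        np.nan,
        index=list(dict.fromkeys(meta["subject_id"])),
        columns=time_points,
    )
    for sample, cluster in assignment.items():
        states.loc[meta.at[sample, "subject_id"],
                   meta.at[sample, "time_point"]] = cluster
    states = states.dropna(how="all")

    K = int(n_states if n_states is not None else assignment.max() + 1)
    T = len(time_points)
    if encoding == "one-hot":
        enc = np.full((len(states), T * K), np.nan)
        vals = states.to_numpy()
        for t in range(T):
            obs = ~np.isnan(vals[:, t])
            block = np.zeros((obs.sum(), K))
            block[np.arange(obs.sum()), vals[obs, t].astype(int)] = 1.0
            enc[obs, t * K:(t + 1) * K] = block
        cols = [f"{tp}:ET{c}" for tp in time_points for c in range(K)]
    elif encoding == "transition-pairs":
        enc = np.zeros((len(states), K * K))
        vals = states.to_numpy()
        for i in range(len(states)):
            seq = vals[i][~np.isnan(vals[i])].astype(int)
            for a, b in zip(seq[:-1], seq[1:]):
                enc[i, a * K + b] += 1.0
        cols = [f"ET{a}->ET{b}" for a in range(K) for b in range(K)]
    else:
        raise ValueError(f"unknown encoding: {encoding!r}")
    return TrajectoryTable(
        states=states,
        encoding=pd.DataFrame(enc, index=states.index, columns=cols),
        time_points=time_points,
        n_states=K,
    )


def pearson_distance(x, y) -> float:
    """d = 1 - Pearson r over pairwise-complete positions; range [0, 2].

    Constant vectors (zero variance over the complete positions) have no
    defined correlation; by convention d = 0 if the vectors are equal there
    and d = 2 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("need >= 2 jointly observed positions")
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0 if np.array_equal(xs, ys) else 2.0
    r = float(np.clip(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy),
                      -1.0, 1.0))
    return 1.0 - r


def trajectory_distance_matrix(table: TrajectoryTable) -> DistanceMatrix:
    enc = table.encoding.to_numpy()
    n = len(enc)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pearson_distance(enc[i], enc[j])
    return DistanceMatrix(D, ids=[str(s) for s in table.encoding.index])


@dataclass
class SubjectDendrogram:
    """Agglomerative merge history plus a flat cut."""

    merges: np.ndarray             # scipy linkage matrix (n-1 x 4)
    heights: np.ndarray
    assignment: pd.Series          # subject -> cluster 0..n_clusters-1
    n_clusters: int
    linkage_method: str


def hcluster(D: DistanceMatrix, linkage_method: str = "average",
             n_clusters: int = 6) -> SubjectDendrogram:
    """Agglomerative clustering of a subject distance matrix.

    Supports average and complete linkage; the tree is cut to exactly
    ``n_clusters`` groups (labelled 0.. in order of first appearance).
    """
    if linkage_method not in ("average", "complete"):
        raise ValueError(f"unsupported linkage: {linkage_method!r}")
    n = len(D.ids)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    Z = linkage(squareform(D.data, checks=False), method=linkage_method)
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    # relabel clusters 0.. in subject order for determinism
    relabel, labels = {}, []
    for c in flat:
        labels.append(relabel.setdefault(c, len(relabel)))
    return SubjectDendrogram(
        merges=Z,
        heights=Z[:, 2].copy(),
        assignment=pd.Series(labels, index=list(D.ids), name="cluster"),
        n_clusters=n_clusters,
        linkage_method=linkage_method,
    )


def cluster_composition(table: TrajectoryTable, dendrogram: SubjectDendrogram,
                        metadata: pd.DataFrame,
                        taxon_table: TaxonTable | None = None,
                        panel=None) -> dict[int, dict]:
    """Per-cluster summaries: arm membership counts (the Fisher-test input),
    per-visit enterotype frequencies, and optionally mean genus composition
    and biomarker means over member samples."""
    meta = metadata.copy()
    if "extraction_failed" in meta.columns:
        meta = meta[~meta["extraction_failed"].astype(bool)]
    subject_arm = meta.groupby("subject_id")["arm"].first()
    arms = sorted(subject_arm.unique())
    rel = to_relative(taxon_table) if taxon_table is not None else None

    out: dict[int, dict] = {}
    for c in sorted(dendrogram.assignment.unique()):
        members = dendrogram.assignment.index[dendrogram.assignment == c]
        arm_counts = {
            arm: int((subject_arm.loc[members] == arm).sum()) for arm in arms
        }
        freq = {}
        for tp in table.time_points:
            col = table.states.loc[members, tp].dropna().astype(int)
            freq[tp] = {int(et): int(n) for et, n in col.value_counts().items()}
        summary = {
            "n_subjects": len(members),
            "arm_counts": arm_counts,
            "enterotype_frequencies": freq,
        }
        member_samples = meta.index[meta["subject_id"].isin(members)]
        if rel is not None:
            samp = [s for s in member_samples if s in rel.index]
            summary["mean_composition"] = rel.loc[samp].mean(axis=0).to_dict()
        if panel is not None:
            samp = [s for s in member_samples if s in panel.values.index]
            summary["biomarker_means"] = panel.values.loc[samp].mean(axis=0).to_dict()
        out[int(c)] = summary
    return out
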
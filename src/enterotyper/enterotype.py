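"""Enterotype discovery: Jensen-Shannon distances, PAM clustering,
Calinski-Harabasz model selection, PCoA, and dominant-genus labelling.

The distance is the square root of the Jensen-Shannon divergence computed
with natural logarithms, so entries are bounded by sqrt(ln 2) and the
matrix is a true metric -- partitioning around medoids (PAM) and principal
coordinates are both well behaved on it.  PAM uses the deterministic
BUILD + SWAP algorithm (greedy seeding, then steepest-descent single
swaps), so identical inputs always give identical clusterings with no
random initialisation.  The number of enterotypes is chosen by maximising
the Calinski-Harabasz index over a candidate range, evaluated directly on
the distance matrix through the pairwise sums-of-squares identity

    W = sum_c (1 / 2 n_c) sum_{i,j in c} D_ij^2,   B = T - W,
    CH = (B / (k - 1)) / (W / (n - k)),

which coincides with the textbook centroid form whenever D is Euclidean.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "jsd_matrix", "pam", "calinski_harabasz", "select_k", "pcoa",
    "label_enterotypes", "assign_new", "EnterotypeModel", "PCoAResult",
]

JSD_MAX = math.sqrt(math.log(2.0))

#: abbreviations used when naming clusters after their dominant genus
GENUS_ABBREV = {
    "Bifidobacterium": "Bifi",
    "Bacteroides": "Bact",
    "Enterobacteriaceae;g__unknown": "Ent",
    "Enterococcus": "Eco",
    "Clostridium": "Clo",
    "Streptococcus": "St",
    "Staphylococcus": "Staph",
    "Lactobacillus": "Lacto",
    "Veillonella": "Veil",
    "Escherichia": "Esch",
    "Klebsiella": "Kleb",
}


def _abbrev(genus: str) -> str:
    return GENUS_ABBREV.get(genus, genus[:4])


def jsd_matrix(profiles: pd.DataFrame, pseudocount: float = 1e-10) -> DistanceMatrix:
    """Pairwise sqrt Jensen-Shannon distances between relative-abundance rows.

    Zeros are replaced by ``pseudocount`` and rows renormalised before the
    divergence is computed (natural log), so disjoint-support pairs stay
    strictly below the sqrt(ln 2) bound.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if len(profiles) < 2:
        raise ValueError("need at least 2 samples")
    P = profiles.to_numpy(dtype=float)
    P = np.where(P <= 0, pseudocount, P)
    P /= P.sum(axis=1, keepdims=True)
    # JS(p, q) = H(m) - (H(p) + H(q)) / 2 with natural-log entropies
    H = -(P * np.log(P)).sum(axis=1)
    M = 0.5 * (P[:, None, :] + P[None, :, :])
    Hm = -(M * np.log(M)).sum(axis=2)
    js = Hm - 0.5 * (H[:, None] + H[None, :])
    np.clip(js, 0.0, None, out=js)
    D = np.sqrt(js)
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return DistanceMatrix(D, ids=[str(s) for s in profiles.index])


def _swap_deltas(D: np.ndarray, cand: int, d1: np.ndarray, d2: np.ndarray,
                 n1: np.ndarray, k: int) -> np.ndarray:
    """Cost change of swapping candidate ``cand`` in for each current medoid.

    Uses the nearest (d1) / second-nearest (d2) medoid distances: points not
    served by the removed medoid can only improve (toward cand), points served
    by it fall back to min(cand, second nearest).
    """
    dc = D[cand]
    gain = np.minimum(dc - d1, 0.0)
    reloc = np.minimum(dc, d2) - d1
    common = gain.sum()
    per_medoid_gain = np.bincount(n1, weights=gain, minlength=k)
    per_medoid_reloc = np.bincount(n1, weights=reloc, minlength=k)
    return common - per_medoid_gain + per_medoid_reloc


def _build(D: np.ndarray, k: int, first: int) -> list[int]:
    """Greedy BUILD seeding with a forced first medoid."""
    medoids = [first]
    d1 = D[first].copy()
    while len(medoids) < k:
        reduction = np.minimum(D - d1[None, :], 0.0).sum(axis=1)
        reduction[medoids] = np.inf
        best = int(np.argmin(reduction))
        medoids.append(best)
        d1 = np.minimum(d1, D[best])
    return sorted(medoids)


def _swap_descent(D: np.ndarray, medoids: list[int], k: int,
                  max_iter: int) -> tuple[list[int], float]:
    """Steepest single-swap descent until no exchange lowers the cost."""
    n = len(D)
    medoids = list(medoids)
    for _ in range(max_iter):
        med = np.array(medoids)
        sub = D[med]                              # k x n
        order = np.argsort(sub, axis=0, kind="stable")
        n1 = order[0]                             # index into medoid list
        d1 = sub[n1, np.arange(n)]
        d2 = sub[order[1], np.arange(n)]
        best_delta, best_swap = -1e-12, None
        for cand in range(n):
            if cand in medoids:
                continue
            deltas = _swap_deltas(D, cand, d1, d2, n1, k)
            i = int(np.argmin(deltas))
            if deltas[i] < best_delta:
                best_delta, best_swap = float(deltas[i]), (i, cand)
        if best_swap is None:
            break
        i, cand = best_swap
        medoids[i] = cand
        medoids = sorted(medoids)
    med = np.array(medoids)
    cost = float(D[med].min(axis=0).sum())
    return medoids, cost


def pam(D: DistanceMatrix | np.ndarray, k: int, max_iter: int = 200,
        n_starts: int | None = None) -> tuple[list, np.ndarray, float]:
    """Deterministic PAM: multi-start BUILD seeding + steepest SWAP descent.

    Single-swap descent from one greedy BUILD can stall in a local optimum,
    so the search is restarted from ``n_starts`` deterministic seedings
    (forcing each of the ``n_starts`` most central points as first medoid;
    default ``min(n, 8)``) and the cheapest solution kept, ties broken by
    the lexicographically smallest medoid set.  Returns ``(medoid_ids,
    assignment, cost)``: medoids sorted by sample index, each sample
    assigned to its nearest medoid (ties to the lowest cluster index), and
    the total within-cluster distance.
    """
    ids = None
    if isinstance(D, DistanceMatrix):
        ids = list(D.ids)
        D = D.data
    D = np.asarray(D, dtype=float)
    n = len(D)
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n; got k={k}, n={n}")
    if n_starts is None:
        n_starts = min(n, 8)
    centrality = np.lexsort((np.arange(n), D.sum(axis=1)))
    best: tuple[float, list[int]] | None = None
    for first in centrality[:n_starts]:
        medoids, cost = _swap_descent(D, _build(D, k, int(first)), k, max_iter)
        if best is None or cost < best[0] - 1e-12 \
                or (abs(cost - best[0]) <= 1e-12 and medoids < best[1]):
            best = (cost, medoids)
    cost, medoids = best[0], best[1]
    med = np.array(medoids)
    assignment = np.argmin(D[med], axis=0)        # ties -> lowest medoid index
    cost = float(D[med][assignment, np.arange(n)].sum())
    medoid_ids = [ids[m] for m in medoids] if ids is not None else medoids
    return medoid_ids, assignment, cost


def calinski_harabasz(D: DistanceMatrix | np.ndarray, assignment, k: int) -> float:
    """Calinski-Harabasz score from a distance matrix via the pairwise identity.

    Perfect clusterings (zero within-cluster dispersion) return ``inf``;
    a fully degenerate matrix (all points identical) returns ``nan`` with a
    warning.
    """
    if isinstance(D, DistanceMatrix):
        D = D.data
    D = np.asarray(D, dtype=float)
    assignment = np.asarray(assignment)
    n = len(D)
    if k < 2:
        raise ValueError("k must be >= 2")
    D2 = D * D
    T = D2.sum() / (2 * n)
    W = 0.0
    for c in range(k):
        members = np.flatnonzero(assignment == c)
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        W += D2[np.ix_(members, members)].sum() / (2 * len(members))
    if T <= 0:
        warnings.warn("degenerate distance matrix: all points identical",
                      stacklevel=2)
        return float("nan")
    B = max(T - W, 0.0)
    if W <= 0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


@dataclass
class EnterotypeModel:
    """A fitted enterotype clustering on a sample distance matrix."""

    k: int
    medoid_ids: list
    assignment: pd.Series          # sample_id -> cluster index 0..k-1
    ch_curve: dict[int, float]
    cost: float
    labels: dict[int, str] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        doc = {
            "k": self.k,
            "medoid_ids": list(self.medoid_ids),
            "assignment": {str(s): int(c) for s, c in self.assignment.items()},
            "ch_curve": {str(kk): (None if not np.isfinite(v) else v)
                         for kk, v in self.ch_curve.items()},
            "cost": self.cost,
            "labels": {str(c): lab for c, lab in self.labels.items()},
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "EnterotypeModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            k=doc["k"],
            medoid_ids=doc["medoid_ids"],
            assignment=pd.Series({s: int(c) for s, c in doc["assignment"].items()},
                                 name="enterotype"),
            ch_curve={int(kk): (math.inf if v is None else v)
                      for kk, v in doc["ch_curve"].items()},
            cost=doc["cost"],
            labels={int(c): lab for c, lab in doc.get("labels", {}).items()},
        )


def select_k(D: DistanceMatrix, k_range=range(2, 11)) -> EnterotypeModel:
    """Fit PAM for every k in ``k_range`` and keep the Calinski-Harabasz
    argmax (ties to the smallest k)."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k range")
    n = len(D.ids)
    if min(k_range) < 2 or max(k_range) >= n:
        raise ValueError(f"k range {k_range} outside [2, {n - 1}]")
    fits = {}
    curve = {}
    for k in k_range:
        medoid_ids, assignment, cost = pam(D, k)
        curve[k] = calinski_harabasz(D, assignment, k)
        fits[k] = (medoid_ids, assignment, cost)
    best = max(sorted(curve), key=lambda k: (curve[k], -k))
    medoid_ids, assignment, cost = fits[best]
    return EnterotypeModel(
        k=best,
        medoid_ids=medoid_ids,
        assignment=pd.Series(assignment, index=list(D.ids), name="enterotype"),
        ch_curve=curve,
        cost=cost,
    )


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame      # samples x retained axes
    eigenvalues: np.ndarray        # retained, non-increasing
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float


def pcoa(D: DistanceMatrix, tol: float = 1e-10) -> PCoAResult:
    """Classical principal coordinates: Gower-centre -D^2/2, eigendecompose,
    scale retained axes by sqrt(eigenvalue).  Negative eigenvalues (non-
    Euclidean distances) are dropped and their summed magnitude reported."""
    ids = list(D.ids)
    A = -0.5 * D.data ** 2
    n = len(A)
    if n < 3:
        raise ValueError("need at least 3 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = 0.5 * (G + G.T)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg_mass = float(-eigval[eigval < 0].sum())
    keep = eigval > tol * max(eigval.max(), 1.0)
    ev = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(ev)[None, :]
    total = eigval[eigval > 0].sum()
    prop = ev / total if total > 0 else np.zeros_like(ev)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        eigenvalues=ev,
        proportion_explained=prop,
        negative_eigenvalue_mass=neg_mass,
    )


def label_enterotypes(model: EnterotypeModel, profiles: pd.DataFrame,
                      margin: float = 0.15) -> dict[int, str]:
    """Name each cluster after its highest mean-abundance genus.

    When the top two genus means are within ``margin`` the cluster gets a
    dual name (e.g. "ET-Bifi and Bact").  Clusters sharing a name are
    suffixed by their size rank ("ET-Bifi 1" is the largest).
    """
    aligned = profiles.loc[model.assignment.index]
    base: dict[int, str] = {}
    sizes: dict[int, int] = {}
    for c in range(model.k):
        members = aligned[model.assignment.to_numpy() == c]
        sizes[c] = len(members)
        means = members.mean(axis=0).sort_values(ascending=False)
        top, second = means.index[0], means.index[1]
        if means.iloc[0] - means.iloc[1] <= margin:
            base[c] = f"ET-{_abbrev(top)} and {_abbrev(second)}"
        else:
            base[c] = f"ET-{_abbrev(top)}"
    labels: dict[int, str] = {}
    for name in set(base.values()):
        clusters = [c for c, b in base.items() if b == name]
        if len(clusters) == 1:
            labels[clusters[0]] = name
        else:
            for rank, c in enumerate(
                    sorted(clusters, key=lambda c: (-sizes[c], c)), start=1):
                labels[c] = f"{name} {rank}"
    model.labels = labels
    return labels


def assign_new(model: EnterotypeModel, dist_to_medoids: pd.DataFrame) -> pd.Series:
    """Nearest-medoid assignment for held-out samples.

    ``dist_to_medoids`` has one column per medoid, in model order; ties go
    to the lowest cluster index.
    """
    missing = [m for m in model.medoid_ids if m not in dist_to_medoids.columns]
    if missing:
        raise ValueError(f"missing distances to medoids: {missing}")
    if dist_to_medoids.isna().any().any():
        raise ValueError("missing (NaN) distance entries")
    mat = dist_to_medoids[list(model.medoid_ids)].to_numpy()
    return pd.Series(np.argmin(mat, axis=1), index=dist_to_medoids.index,
                     name="enterotype")
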
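"""Nonparametric statistical battery for stratified biomarker comparisons.

Covers the trial's analysis toolkit: fecal-weight normalisation of
cytokines with below-LOD censoring to exact zero, breastfeeding-rate
computation from daily feed counts, Wilcoxon rank-sum and Kruskal-Wallis
tests, Dunn's post-hoc pairwise comparisons with Bonferroni correction,
Fisher's exact test for R x C enterotype/arm tables, and an ALDEx2-style
CLR Monte-Carlo differential-abundance test with Benjamini-Hochberg
q-values.

The CLR test re-derives the standard recipe: per Monte-Carlo instance,
sample proportions are drawn Dirichlet(counts + 0.5) per sample, centred
log-ratio transformed, and compared between groups with a two-sided
rank-sum test per taxon; the expected p (mean over instances) is BH
corrected across taxa.  The effect size is the median over instances of
the between-group median CLR difference scaled by the pooled within-group
median absolute deviation ("effect (simplified)").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .tables_io import TaxonTable

__all__ = [
    "TestResult", "normalize_cytokine", "breastfeeding_rate",
    "breastfeeding_rates", "wilcoxon_rank_sum", "kruskal_wallis",
    "dunn_bonferroni", "fisher_exact", "clr_diff_abundance", "bh_adjust",
    "stratified_compare",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    groups: tuple | None = None
    n: tuple | None = None
    effect: float | None = None
    degenerate: bool = False
    method: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p outside [0, 1]: {self.p_value}")


def normalize_cytokine(raw_conc: float, dilution_factor: float,
                       fecal_mass_mg: float, lod: float,
                       extract_volume_ml: float = 1.0) -> tuple[float, bool]:
    """Convert an extract concentration (pg/mL) to pg per gram of feces.

    Values strictly below the detection limit are recorded as exact 0 and
    flagged censored; a value equal to the LOD is retained.  The per-gram
    value is raw x dilution x extract volume / fecal mass.
    """
    if raw_conc < 0:
        raise ValueError("negative concentration")
    if fecal_mass_mg <= 0:
        raise ValueError("fecal mass must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if raw_conc < lod:
        return 0.0, True
    grams = fecal_mass_mg / 1000.0
    return raw_conc * dilution_factor * extract_volume_ml / grams, False


def breastfeeding_rate(breast_feeds, formula_feeds) -> float:
    """Fraction of breast feeds among all feeds over a window of daily counts.

    Returns NaN (with a warning) when the window holds no feeds at all.
    """
    breast = np.asarray(breast_feeds, dtype=float)
    formula = np.asarray(formula_feeds, dtype=float)
    total = breast.sum() + formula.sum()
    if total == 0:
        warnings.warn("window contains no feeds; rate undefined", stacklevel=2)
        return float("nan")
    return float(breast.sum() / total)


def breastfeeding_rates(metadata: pd.DataFrame) -> pd.Series:
    """Per-sample breastfeeding rate from the comma-separated daily feed
    columns written by the cohort generator."""
    out = {}
    for sample, row in metadata.iterrows():
        breast = [int(v) for v in str(row["breast_feeds_daily"]).split(",") if v]
        formula = [int(v) for v in str(row["formula_feeds_daily"]).split(",") if v]
        out[sample] = breastfeeding_rate(breast, formula)
    return pd.Series(out, name="breastfeeding_rate")


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration when the combined sample is small (<= 20) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Identical constant samples give p = 1 (degenerate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1 or len(x) + len(y) < 2:
        raise ValueError("each group needs >= 1 value, combined >= 2")
    combined = np.concatenate([x, y])
    rank_sum = float(sps.rankdata(combined)[: len(x)].sum())
    if np.all(combined == combined[0]):
        return TestResult(rank_sum, 1.0, degenerate=True,
                          n=(len(x), len(y)), method="wilcoxon-degenerate")
    ties = len(np.unique(combined)) < len(combined)
    exact = not ties and len(combined) <= 20
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(rank_sum, float(min(res.pvalue, 1.0)),
                      n=(len(x), len(y)), method=f"wilcoxon-{method}",
                      extra={"U": float(res.statistic)})


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square reference)."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need total n >= 3")
    try:
        stat, p = sps.kruskal(*groups)
    except ValueError:  # all values identical
        return TestResult(0.0, 1.0, degenerate=True, method="kruskal-degenerate",
                          n=tuple(len(g) for g in groups))
    return TestResult(float(stat), float(p), n=tuple(len(g) for g in groups),
                      method="kruskal-wallis")


def dunn_bonferroni(groups, labels=None) -> list[TestResult]:
    """Dunn's pairwise post-hoc z tests on pooled ranks, Bonferroni-adjusted.

    Empty groups are excluded with a warning; the Bonferroni factor is the
    number of pairwise comparisons actually performed.
    """
    if labels is None:
        labels = list(range(len(groups)))
    kept = [(lab, np.asarray(g, dtype=float)) for lab, g in zip(labels, groups)
            if len(g)]
    dropped = set(labels) - {lab for lab, _ in kept}
    if dropped:
        warnings.warn(f"empty groups excluded: {sorted(dropped)}", stacklevel=2)
    if len(kept) < 3:
        raise ValueError("need >= 3 non-empty groups")
    pooled = np.concatenate([g for _, g in kept])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for lab, g in kept:
        mean_ranks[lab] = ranks[start:start + len(g)].mean()
        sizes[lab] = len(g)
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(kept) * (len(kept) - 1) // 2
    results = []
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept[i][0], kept[j][0]
            se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = float(2.0 * sps.norm.sf(abs(z)))
            results.append(TestResult(
                statistic=float(z), p_value=p,
                adjusted_p=float(min(1.0, p * m)),
                groups=(a, b), n=(sizes[a], sizes[b]),
                method="dunn-bonferroni",
            ))
    return results


def _log_table_prob(table: np.ndarray, lgr, lgc, lgn) -> float:
    return lgr + lgc - lgn - gammaln(table + 1).sum()


def fisher_exact(table, max_tables: int = 2_000_000, n_mc: int = 100_000,
                 seed: int = 0) -> TestResult:
    """Fisher's exact test for an R x C count table.

    2 x 2 tables use the exact hypergeometric two-sided p.  Larger tables
    are enumerated exactly (summing the probability of every table with the
    observed margins whose probability does not exceed the observed one)
    when the enumeration stays under ``max_tables`` tables: two-row (or
    two-column) tables -- the enterotype-by-arm case -- go through a fast
    vectorised support scan, other shapes through a slower recursive
    enumeration capped at 200,000 tables.  Beyond the bound a seeded
    Monte-Carlo estimate over ``n_mc`` margin-preserving draws is returned
    together with its simulation standard error.
    """
    table = np.asarray(table)
    if not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)):
            raise ValueError("table entries must be integers")
        table = np.round(table).astype(np.int64)
    if (table < 0).any():
        raise ValueError("table entries must be non-negative")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return TestResult(0.0, 1.0, degenerate=True, method="fisher-degenerate")
    if table.shape == (2, 2):
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return TestResult(float(odds), float(p), method="fisher-2x2")

    rows, cols = table.sum(axis=1), table.sum(axis=0)
    N = table.sum()
    lgr = gammaln(rows + 1).sum()
    lgc = gammaln(cols + 1).sum()
    lgn = gammaln(N + 1)
    obs_lp = _log_table_prob(table, lgr, lgc, lgn)
    # enumeration accumulates only the -sum log a_ij! part; the margin
    # constant lgr + lgc - lgn is added when exponentiating
    obs_core = obs_lp - (lgr + lgc - lgn)
    tol = 1e-7

    if min(table.shape) == 2:
        p = _fisher_two_row_exact(table if table.shape[0] == 2 else table.T,
                                  obs_lp, max_tables)
        if p is not None:
            return TestResult(float(obs_lp), float(min(p, 1.0)),
                              method="fisher-exact-enumeration")
    else:
        p = _fisher_enumerate_recursive(table, rows, cols, lgr, lgc, lgn,
                                        obs_core, tol, min(max_tables, 200_000))
        if p is not None:
            return TestResult(float(obs_lp), float(min(p, 1.0)),
                              method="fisher-exact-enumeration")

    rng = np.random.default_rng(seed)
    dist = sps.random_table(rows, cols)
    draws = dist.rvs(n_mc, random_state=rng)
    lps = lgr + lgc - lgn - gammaln(draws + 1).sum(axis=(1, 2))
    hits = int((lps <= obs_lp + tol).sum())
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return TestResult(float(obs_lp), float(p), method="fisher-monte-carlo",
                      extra={"n_mc": n_mc, "se": se})


def _fisher_two_row_exact(table: np.ndarray, obs_lp: float,
                          max_states: int) -> float | None:
    """Exact p for a 2 x C table by vectorised enumeration of the first row
    (a multivariate hypergeometric support scan).  Returns None when the
    intermediate state count exceeds ``max_states``."""
    cols = table.sum(axis=0)
    r1 = int(table.sum(axis=1)[0])
    N = int(table.sum())
    # log C(c_j, v) per column; prefix states = (remaining r1, accumulated lp)
    rem = np.array([r1], dtype=np.int64)
    lp = np.array([0.0])
    for j, cj in enumerate(cols):
        v = np.arange(cj + 1)
        lg_choose = (gammaln(cj + 1) - gammaln(v + 1) - gammaln(cj - v + 1))
        new_rem = rem[:, None] - v[None, :]
        new_lp = lp[:, None] + lg_choose[None, :]
        cap = int(cols[j + 1:].sum())
        valid = (new_rem >= 0) & (new_rem <= cap)
        rem, lp = new_rem[valid], new_lp[valid]
        if len(rem) > max_states:
            return None
    lp -= gammaln(N + 1) - gammaln(r1 + 1) - gammaln(N - r1 + 1)
    tol = 1e-7
    return float(np.exp(lp[lp <= obs_lp + tol]).sum())


def _fisher_enumerate_recursive(table, rows, cols, lgr, lgc, lgn, obs_core,
                                tol, max_tables) -> float | None:
    """Exact p by recursive enumeration of all tables with the observed
    margins; None once more than ``max_tables`` tables are visited."""
    tables_seen = 0
    total_p = 0.0
    R, C = table.shape
    overflow = False

    def recurse(r: int, col_rem: np.ndarray, lp_acc: float) -> None:
        nonlocal tables_seen, total_p, overflow
        if overflow:
            return
        if r == R - 1:
            tables_seen += 1
            if tables_seen > max_tables:
                overflow = True
                return
            lp = lp_acc - gammaln(col_rem + 1).sum()
            if lp <= obs_core + tol:
                total_p += math.exp(lp + lgr + lgc - lgn)
            return
        # enumerate row r cell by cell
        def fill(c: int, row_rem: int, col_rem: np.ndarray, lp_row: float) -> None:
            nonlocal overflow
            if overflow:
                return
            if c == C - 1:
                if row_rem <= col_rem[c]:
                    nxt = col_rem.copy()
                    nxt[c] -= row_rem
                    recurse(r + 1, nxt,
                            lp_row - gammaln(row_rem + 1))
                return
            hi = min(row_rem, col_rem[c])
            for v in range(hi + 1):
                nxt = col_rem.copy()
                nxt[c] -= v
                fill(c + 1, row_rem - v, nxt, lp_row - gammaln(v + 1))

        fill(0, rows[r], col_rem, lp_acc)

    recurse(0, cols.copy(), 0.0)
    return None if overflow else total_p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-invariant)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _ranksum_p_matrix(X: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Vectorised two-sided rank-sum p per column of X (normal approximation
    with continuity correction; CLR draws are continuous so ties are not
    corrected here)."""
    na = int(mask_a.sum())
    nb = X.shape[0] - na
    ranks = sps.rankdata(X, axis=0)
    U = ranks[mask_a].sum(axis=0) - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    sigma = math.sqrt(na * nb * (na + nb + 1) / 12.0)
    z = (np.abs(U - mu) - 0.5) / sigma
    return np.minimum(2.0 * sps.norm.sf(z), 1.0)


def clr_diff_abundance(table, groups, n_instances: int = 128,
                       seed: int = 0) -> pd.DataFrame:
    """ALDEx2-style CLR Monte-Carlo differential abundance between two groups.

    Returns a per-taxon DataFrame with the expected rank-sum p (mean over
    Dirichlet instances), the BH q-value across taxa, and the simplified
    median/MAD effect size.  Deterministic for a given seed.
    """
    if isinstance(table, TaxonTable):
        counts = table.counts
    else:
        counts = pd.DataFrame(table)
    if n_instances < 2:
        raise ValueError("need n_instances >= 2")
    groups = pd.Series(groups)
    if not groups.index.equals(counts.index):
        groups = pd.Series(np.asarray(groups), index=counts.index)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    mask_a = (groups == levels[0]).to_numpy()
    if mask_a.sum() == 0 or (~mask_a).sum() == 0:
        raise ValueError("a group is empty")
    C = counts.to_numpy(dtype=float) + 0.5
    n, m = C.shape
    if m < 2:
        raise ValueError("need >= 2 taxa")
    rng = np.random.default_rng(seed)
    eps = 1e-12

    p_sum = np.zeros(m)
    effects = np.empty((n_instances, m))
    for inst in range(n_instances):
        gam = rng.standard_gamma(C)
        P = gam / gam.sum(axis=1, keepdims=True)
        logp = np.log(P)
        clr = logp - logp.mean(axis=1, keepdims=True)
        p_sum += _ranksum_p_matrix(clr, mask_a)
        A, B = clr[mask_a], clr[~mask_a]
        med_a, med_b = np.median(A, axis=0), np.median(B, axis=0)
        spread = np.median(
            np.abs(np.vstack([A - med_a, B - med_b])), axis=0)
        effects[inst] = (med_a - med_b) / np.maximum(spread, eps)

    expected_p = p_sum / n_instances
    return pd.DataFrame({
        "p_expected": expected_p,
        "q": bh_adjust(expected_p),
        "effect": np.median(effects, axis=0),
    }, index=counts.columns)


def stratified_compare(panel, strata: pd.Series, min_stratum_size: int = 3,
                       min_detection_rate: float = 0.2) -> pd.DataFrame:
    """Kruskal-Wallis omnibus + Dunn-Bonferroni post-hoc per biomarker
    across enterotype (or trajectory-cluster) strata.

    Strata smaller than ``min_stratum_size`` are excluded with a warning;
    biomarkers detected (value > 0) in fewer than ``min_detection_rate`` of
    samples are skipped.  Returns a tidy table (one row per test).
    """
    values = panel.values if hasattr(panel, "values") and not isinstance(
        panel, pd.DataFrame) else pd.DataFrame(panel)
    common = [s for s in values.index if s in strata.index]
    values = values.loc[common]
    strata = strata.loc[common]
    counts = strata.value_counts()
    usable = [s for s in counts.index if counts[s] >= min_stratum_size]
    dropped = [s for s in counts.index if counts[s] < min_stratum_size]
    if dropped:
        warnings.warn(f"strata below minimum size excluded: {sorted(map(str, dropped))}",
                      stacklevel=2)
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable strata")
    usable = sorted(usable)
    rows = []
    for biomarker in values.columns:
        col = values[biomarker].astype(float)
        detection = float((col > 0).mean())
        if detection < min_detection_rate:
            rows.append({"biomarker": biomarker, "test": "skipped-low-detection",
                         "group_a": None, "group_b": None,
                         "statistic": np.nan, "p": np.nan, "p_adjusted": np.nan,
                         "n": len(col), "detection_rate": detection})
            continue
        groups = [col[strata == s].to_numpy() for s in usable]
        omni = kruskal_wallis(groups)
        rows.append({"biomarker": biomarker, "test": "kruskal-wallis",
                     "group_a": None, "group_b": None,
                     "statistic": omni.statistic, "p": omni.p_value,
                     "p_adjusted": np.nan, "n": sum(omni.n),
                     "detection_rate": detection})
        if len(usable) >= 3:
            for res in dunn_bonferroni(groups, labels=usable):
                rows.append({"biomarker": biomarker, "test": "dunn-bonferroni",
                             "group_a": res.groups[0], "group_b": res.groups[1],
                             "statistic": res.statistic, "p": res.p_value,
                             "p_adjusted": res.adjusted_p, "n": sum(res.n),
                             "detection_rate": detection})
        else:
            res = wilcoxon_rank_sum(groups[0], groups[1])
            rows.append({"biomarker": biomarker, "test": "wilcoxon",
                         "group_a": usable[0], "group_b": usable[1],
                         "statistic": res.statistic, "p": res.p_value,
                         "p_adjusted": np.nan, "n": sum(res.n),
                         "detection_rate": detection})
    return pd.DataFrame(rows)
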
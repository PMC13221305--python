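"""Synthetic longitudinal two-arm infant-microbiome trial generator.

Emulates the structure of a placebo-controlled infant probiotic trial:
two arms of roughly 56 and 53 analysable subjects sampled at four time
points (pre-intervention, 1 week, 1 month, 3 months), giving ~436 planned
stools of which a few fail DNA extraction.  Each subject moves through a
small set of enterotype archetypes (two Bifidobacterium-dominant variants,
a Bifidobacterium+Bacteroides type, an Enterobacteriaceae type, an
Enterococcus+Clostridium type, and a Streptococcus type) under a per-arm
Markov kernel; genus counts are Dirichlet-multinomial draws from the
archetype of the subject's current state, fecal biomarkers are lognormal
with state-dependent means and below-LOD censoring to exact zero, and
daily breast/formula feed counts follow a state-linked breastfeeding
propensity.  All ground truth (states, archetype profiles, biomarker
effects) is returned so recovery can be tested downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables_io import RANKS, UNKNOWN, TaxonTable

__all__ = [
    "GeneratorConfig", "BiomarkerModel", "CohortTruth",
    "generate_cohort", "generate_tree", "study_accounting",
    "DEFAULT_GENERA", "ARCHETYPE_NAMES",
]

DEFAULT_GENERA = (
    "Bifidobacterium", "Bacteroides", "Enterobacteriaceae;g__unknown",
    "Enterococcus", "Clostridium", "Streptococcus",
    "Veillonella", "Lactobacillus", "Staphylococcus", "Klebsiella",
    "Escherichia", "Parabacteroides", "Collinsella", "Blautia",
    "Ruminococcus", "Faecalibacterium", "Akkermansia", "Prevotella",
    "Eggerthella", "Haemophilus", "Rothia", "Actinomyces", "Citrobacter",
    "Enterobacter", "Serratia", "Cutibacterium", "Finegoldia", "Gemella",
    "Megasphaera", "Dialister",
)

ARCHETYPE_NAMES = (
    "Bifi-1", "Bifi-2", "Bifi+Bact", "Entero", "Eco+Clo", "Strep",
)

_FAMILY = {
    "Bifidobacterium": ("Actinomycetota", "Bifidobacteriaceae"),
    "Bacteroides": ("Bacteroidota", "Bacteroidaceae"),
    "Enterobacteriaceae;g__unknown": ("Pseudomonadota", "Enterobacteriaceae"),
    "Enterococcus": ("Bacillota", "Enterococcaceae"),
    "Clostridium": ("Bacillota", "Clostridiaceae"),
    "Streptococcus": ("Bacillota", "Streptococcaceae"),
    "Escherichia": ("Pseudomonadota", "Enterobacteriaceae"),
    "Klebsiella": ("Pseudomonadota", "Enterobacteriaceae"),
}


def _default_lineage() -> dict[str, dict[str, str]]:
    lineage = {}
    for g in DEFAULT_GENERA:
        phylum, family = _FAMILY.get(g, (UNKNOWN, UNKNOWN))
        genus = UNKNOWN if g.endswith(f"g__{UNKNOWN}") else g
        lin = {r: UNKNOWN for r in RANKS}
        lin.update(kingdom="Bacteria", phylum=phylum, family=family, genus=genus)
        lineage[g] = lin
    return lineage


def default_archetypes(concentration: float = 120.0) -> np.ndarray:
    """Dirichlet concentration vectors (K x G) for the six default archetypes.

    One genus carries 60-85% of the expected mass per archetype, with the
    two Bifidobacterium-dominant variants separated by their secondary
    genera.  ``concentration`` is the per-row total, controlling how tightly
    samples scatter around the archetype centre.
    """
    g = {name: i for i, name in enumerate(DEFAULT_GENERA)}
    K, G = len(ARCHETYPE_NAMES), len(DEFAULT_GENERA)
    frac = np.full((K, G), 0.003)
    specs = [
        {"Bifidobacterium": 0.82, "Collinsella": 0.04, "Veillonella": 0.03},
        {"Bifidobacterium": 0.60, "Streptococcus": 0.12, "Lactobacillus": 0.10,
         "Veillonella": 0.05},
        {"Bifidobacterium": 0.42, "Bacteroides": 0.36, "Parabacteroides": 0.06},
        {"Enterobacteriaceae;g__unknown": 0.68, "Escherichia": 0.08,
         "Klebsiella": 0.07},
        {"Enterococcus": 0.44, "Clostridium": 0.34, "Blautia": 0.05},
        {"Streptococcus": 0.70, "Staphylococcus": 0.08, "Gemella": 0.05},
    ]
    for k, spec in enumerate(specs):
        for genus, f in spec.items():
            frac[k, g[genus]] = f
        frac[k] /= frac[k].sum()
    return frac * concentration


def _kernel(rows: list[list[float]]) -> np.ndarray:
    arr = np.asarray(rows, dtype=float)
    return arr / arr.sum(axis=1, keepdims=True)


def default_transition_kernels() -> dict[str, np.ndarray]:
    """Per-arm K x K Markov kernels (applied at every inter-visit step).

    The probiotic arm pulls strongly and quickly toward the two
    Bifidobacterium-dominant states; the placebo arm drifts there more
    slowly (healthy term infants bifidify spontaneously), retaining more
    Enterobacteriaceae / Streptococcus mass at intermediate visits.
    """
    probiotic = _kernel([
        [0.82, 0.10, 0.05, 0.01, 0.01, 0.01],
        [0.30, 0.58, 0.08, 0.01, 0.02, 0.01],
        [0.18, 0.12, 0.66, 0.01, 0.02, 0.01],
        [0.42, 0.22, 0.10, 0.16, 0.06, 0.04],
        [0.40, 0.22, 0.10, 0.05, 0.18, 0.05],
        [0.40, 0.24, 0.10, 0.04, 0.05, 0.17],
    ])
    placebo = _kernel([
        [0.72, 0.14, 0.08, 0.02, 0.02, 0.02],
        [0.16, 0.62, 0.12, 0.03, 0.04, 0.03],
        [0.10, 0.14, 0.66, 0.03, 0.04, 0.03],
        [0.10, 0.16, 0.12, 0.46, 0.09, 0.07],
        [0.10, 0.16, 0.12, 0.08, 0.44, 0.10],
        [0.10, 0.18, 0.12, 0.07, 0.09, 0.44],
    ])
    return {"probiotic": probiotic, "placebo": placebo}


@dataclass
class BiomarkerModel:
    """Lognormal biomarker model: per-state natural-log means, shared log-sd,
    a lower limit of detection (values below it are recorded as exact 0),
    and the panel the biomarker belongs to."""

    log_mean: np.ndarray          # length K
    log_sd: float
    lod: float
    panel: str                    # cytokine / metabolite / scfa / immune
    unit: str

    def __post_init__(self) -> None:
        self.log_mean = np.asarray(self.log_mean, dtype=float)


def default_biomarker_models() -> dict[str, BiomarkerModel]:
    """State-linked biomarker effects, states ordered as ARCHETYPE_NAMES.

    Proinflammatory cytokines and calprotectin run higher in the
    Enterobacteriaceae-type states; tryptophan metabolites (ILA, IAA),
    acetate and sIgA run higher in the Bifidobacterium-dominant states.
    IL-8 is flat across states and IL-6 sits almost entirely below its LOD
    (exercising the minimum-detection-rate filter).
    """
    ln = np.log
    return {
        "IFN-g": BiomarkerModel(ln([40, 45, 50, 160, 140, 100]), 0.8, 10.0,
                                "cytokine", "pg/g"),
        "IL-1b": BiomarkerModel(ln([100, 110, 130, 420, 260, 360]), 0.9, 20.0,
                                "cytokine", "pg/g"),
        "TNF-a": BiomarkerModel(ln([30, 32, 36, 72, 60, 55]), 0.8, 10.0,
                                "cytokine", "pg/g"),
        "IL-22": BiomarkerModel(ln([40, 38, 55, 20, 24, 26]), 0.8, 5.0,
                                "cytokine", "pg/g"),
        "IL-8": BiomarkerModel(ln([500] * 6), 1.0, 50.0, "cytokine", "pg/g"),
        "IL-6": BiomarkerModel(ln([2] * 6), 0.8, 15.0, "cytokine", "pg/g"),
        "ILA": BiomarkerModel(ln([3000, 2800, 2400, 400, 500, 600]), 0.9, 100.0,
                              "metabolite", "AUC/g"),
        "IAA": BiomarkerModel(ln([800, 760, 700, 250, 280, 300]), 0.9, 100.0,
                              "metabolite", "AUC/g"),
        "acetate": BiomarkerModel(ln([60, 56, 50, 24, 28, 30]), 0.6, 1.0,
                                  "scfa", "umol/g"),
        "sIgA": BiomarkerModel(ln([2.6, 2.5, 2.3, 1.7, 1.8, 1.9]), 0.7, 0.05,
                               "immune", "mg/g"),
        "calprotectin": BiomarkerModel(ln([150, 160, 180, 420, 330, 300]), 0.8,
                                       10.0, "immune", "ug/g"),
    }


def default_breastfeeding_model(kappa: float = 12.0) -> np.ndarray:
    """Per-state Beta(a, b) parameters for the daily breast-feed fraction.

    Means decrease from the Bifidobacterium-dominant states (~0.82, 0.75)
    to the Enterobacteriaceae state (~0.53); ``kappa`` = a + b sets the
    between-subject spread.
    """
    means = np.array([0.82, 0.75, 0.72, 0.53, 0.58, 0.62])
    return np.column_stack([means * kappa, (1 - means) * kappa])


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic trial.

    Defaults reproduce the study-scale layout: arms of 56 and 53 analysed
    subjects (57/54 randomised, 111 enrolled), four visits, 30 genera, six
    archetypes, negative-binomial read depth (mean 30000, dispersion 5) and
    exactly 3 pre-intervention extraction failures.
    """

    n_subjects_per_arm: tuple[int, int] = (56, 53)
    n_enrolled_per_arm: tuple[int, int] = (57, 54)
    arms: tuple[str, str] = ("probiotic", "placebo")
    time_points: tuple[str, ...] = ("pre", "wk1", "mo1", "mo3")
    window_days: dict[str, int] | None = None
    genera: tuple[str, ...] = DEFAULT_GENERA
    lineage: dict[str, dict[str, str]] = field(default_factory=_default_lineage)
    archetypes: np.ndarray = field(default_factory=default_archetypes)
    archetype_names: tuple[str, ...] = ARCHETYPE_NAMES
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.array([0.14, 0.10, 0.12, 0.28, 0.20, 0.16]))
    transition_kernels: dict[str, np.ndarray] = field(
        default_factory=default_transition_kernels)
    depth_mean: float = 30000.0
    depth_dispersion: float = 5.0
    biomarker_models: dict[str, BiomarkerModel] = field(
        default_factory=default_biomarker_models)
    breastfeeding_model: np.ndarray = field(
        default_factory=default_breastfeeding_model)
    feeds_per_day: float = 8.0
    missing_rate: float = 0.0
    n_failures: int | None = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.archetypes = np.asarray(self.archetypes, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, float)
        if self.window_days is None:
            defaults = {"pre": 7, "wk1": 7, "mo1": 23, "mo3": 60}
            self.window_days = {tp: defaults.get(tp, 14) for tp in self.time_points}
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.archetypes)

    def validate(self) -> None:
        K, G = self.archetypes.shape
        if not 1 <= K <= len(self.genera):
            raise ValueError(f"need 1 <= K <= n_genera; got K={K}")
        if G != len(self.genera):
            raise ValueError("archetype width != number of genera")
        if (self.archetypes <= 0).any():
            raise ValueError("Dirichlet concentrations must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth mean must be positive")
        if not np.isclose(self.initial_distribution.sum(), 1.0, atol=1e-12):
            raise ValueError("initial state distribution must sum to 1")
        for arm in self.arms:
            if arm not in self.transition_kernels:
                raise ValueError(f"no transition kernel for arm {arm!r}")
            kern = np.asarray(self.transition_kernels[arm], dtype=float)
            kern = kern[None] if kern.ndim == 2 else kern
            if kern.shape[1:] != (K, K):
                raise ValueError(
                    f"kernel for {arm!r} is {kern.shape[1:]}, expected ({K},{K})")
            if (kern < 0).any() or not np.allclose(
                    kern.sum(axis=2), 1.0, atol=1e-12):
                raise ValueError(f"kernel rows for {arm!r} must sum to 1")
        for name, model in self.biomarker_models.items():
            if len(model.log_mean) != K:
                raise ValueError(f"biomarker {name!r} has {len(model.log_mean)} "
                                 f"state means, expected {K}")

    def step_kernel(self, arm: str, step: int) -> np.ndarray:
        kern = np.asarray(self.transition_kernels[arm], dtype=float)
        return kern if kern.ndim == 2 else kern[step]


@dataclass
class BiomarkerPanel:
    """Per-sample biomarker values with censoring flags and LODs.

    ``values`` is samples x biomarkers; censored (below-LOD) entries are
    exact 0 and flagged True in ``censored``.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    lod: dict[str, float]
    units: dict[str, str]
    panels: dict[str, str] = field(default_factory=dict)


@dataclass
class CohortTruth:
    """Generator ground truth for recovery testing."""

    true_enterotype: dict[str, int]           # sample_id -> state index
    archetype_profiles: pd.DataFrame          # K x G expected rel. abundance
    biomarker_truth: dict[str, dict]
    trajectory_states: dict[str, list[int]]   # subject -> state per visit
    breastfeeding_fraction: dict[str, list[float]]

    def to_json(self, path=None) -> str:
        doc = {
            "true_enterotype": self.true_enterotype,
            "archetype_profiles": {
                str(k): row.tolist()
                for k, row in zip(self.archetype_profiles.index,
                                  self.archetype_profiles.to_numpy())
            },
            "biomarker_truth": self.biomarker_truth,
            "trajectory_states": self.trajectory_states,
            "breastfeeding_fraction": self.breastfeeding_fraction,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def study_accounting(config: GeneratorConfig | None = None) -> dict[str, int]:
    """Pure arithmetic on the trial layout: enrolment, per-arm analysed
    counts, planned and retained samples."""
    config = config or GeneratorConfig()
    analyzed = list(config.n_subjects_per_arm)
    planned = sum(analyzed) * len(config.time_points)
    failed = config.n_failures if config.n_failures is not None else 0
    return {
        "enrolled": sum(config.n_enrolled_per_arm),
        "randomized_per_arm": list(config.n_enrolled_per_arm),
        "analyzed_per_arm": analyzed,
        "subjects_analyzed": sum(analyzed),
        "planned_samples": planned,
        "failed_samples": failed,
        "retained_samples": planned - failed,
    }


def generate_cohort(config: GeneratorConfig | None = None,
                    ) -> tuple[TaxonTable, pd.DataFrame, BiomarkerPanel, CohortTruth]:
    """Draw one full synthetic cohort.

    Identical configs (including seed) give byte-identical outputs.  Failed
    samples appear in the metadata flagged ``extraction_failed`` but are
    absent from the count table, the biomarker panel and the truth map.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    K = config.n_states
    T = len(config.time_points)
    genera = list(config.genera)

    subjects, subject_arm = [], {}
    for arm, n in zip(config.arms, config.n_subjects_per_arm):
        for i in range(n):
            sid = f"{arm[:4]}-{i + 1:03d}"
            subjects.append(sid)
            subject_arm[sid] = arm

    # per-subject Markov state sequences (initial distribution is arm-free)
    trajectory_states: dict[str, list[int]] = {}
    for sid in subjects:
        state = int(rng.choice(K, p=config.initial_distribution))
        states = [state]
        for step in range(T - 1):
            kern = config.step_kernel(subject_arm[sid], step)
            state = int(rng.choice(K, p=kern[state]))
            states.append(state)
        trajectory_states[sid] = states

    planned = [(sid, tp) for sid in subjects for tp in config.time_points]
    sample_ids = [f"{sid}_{tp}" for sid, tp in planned]

    # extraction failures: exact count drawn among first-visit samples, or
    # Bernoulli(missing_rate) over all planned samples
    failed = np.zeros(len(planned), dtype=bool)
    if config.n_failures is not None:
        first_tp = config.time_points[0]
        pre_idx = [i for i, (_, tp) in enumerate(planned) if tp == first_tp]
        if config.n_failures > len(pre_idx):
            raise ValueError("more failures requested than first-visit samples")
        failed[rng.choice(pre_idx, size=config.n_failures, replace=False)] = True
    elif config.missing_rate > 0:
        failed = rng.random(len(planned)) < config.missing_rate

    # counts: Dirichlet-multinomial from the subject's state at the visit
    nb_p = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    rows, kept_ids, true_state = [], [], {}
    meta_rows = []
    bf_fraction: dict[str, list[float]] = {sid: [] for sid in subjects}
    bm_names = list(config.biomarker_models)
    bm_rows = []
    for idx, ((sid, tp), sample_id) in enumerate(zip(planned, sample_ids)):
        t = config.time_points.index(tp)
        state = trajectory_states[sid][t]
        arm = subject_arm[sid]

        # feeding record for the window ending at this visit
        a, b = config.breastfeeding_model[state]
        frac = float(rng.beta(a, b))
        bf_fraction[sid].append(frac)
        days = config.window_days[tp]
        totals = np.maximum(rng.poisson(config.feeds_per_day, size=days), 1)
        breast = rng.binomial(totals, frac)
        formula = totals - breast

        meta_rows.append({
            "sample_id": sample_id,
            "subject_id": sid,
            "arm": arm,
            "time_point": tp,
            "fecal_mass": round(float(rng.uniform(50, 100)), 1),
            "extraction_failed": bool(failed[idx]),
            "breast_feeds_daily": ",".join(map(str, breast)),
            "formula_feeds_daily": ",".join(map(str, formula)),
            "GWG": round(float(rng.normal(10.0, 3.0)), 2),
        })

        depth = max(1, int(rng.negative_binomial(config.depth_dispersion, nb_p)))
        p = rng.dirichlet(config.archetypes[state])
        counts = rng.multinomial(depth, p)
        values = {}
        for name in bm_names:
            model = config.biomarker_models[name]
            raw = float(np.exp(rng.normal(model.log_mean[state], model.log_sd)))
            values[name] = raw
        if not failed[idx]:
            rows.append(counts)
            kept_ids.append(sample_id)
            true_state[sample_id] = state
            bm_rows.append(values)

    table = TaxonTable(
        pd.DataFrame(np.vstack(rows), index=kept_ids, columns=genera),
        {g: dict(l) for g, l in config.lineage.items()},
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    raw_values = pd.DataFrame(bm_rows, index=kept_ids)[bm_names]
    lod = {name: config.biomarker_models[name].lod for name in bm_names}
    censored = raw_values.lt(pd.Series(lod))
    values = raw_values.mask(censored, 0.0)
    panel = BiomarkerPanel(
        values=values,
        censored=censored,
        lod=lod,
        units={n: config.biomarker_models[n].unit for n in bm_names},
        panels={n: config.biomarker_models[n].panel for n in bm_names},
    )

    profiles = config.archetypes / config.archetypes.sum(axis=1, keepdims=True)
    truth = CohortTruth(
        true_enterotype=true_state,
        archetype_profiles=pd.DataFrame(
            profiles, index=list(config.archetype_names), columns=genera),
        biomarker_truth={
            name: {"log_mean": m.log_mean.tolist(), "log_sd": m.log_sd,
                   "lod": m.lod}
            for name, m in config.biomarker_models.items()
        },
        trajectory_states=trajectory_states,
        breastfeeding_fraction=bf_fraction,
    )
    return table, metadata, panel, truth


def generate_tree(taxa: list[str], seed: int) -> TreeNode:
    """Random rooted bifurcating tree over ``taxa`` with exponential branch
    lengths; deterministic per seed."""
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon names")
    rng = np.random.default_rng(seed)

    def draw_length() -> float:
        return float(rng.exponential(0.1) + 0.01)

    nodes = [TreeNode(name=str(t), length=draw_length()) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=draw_length(), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    root.name = "root"
    return root
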
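import numpy as np
import pandas as pd
import pytest

from enterotyper.synthetic_cohort import GeneratorConfig, generate_cohort
from enterotyper.tables_io import TaxonTable


def make_config(K: int, G: int = 8, n_subjects: int = 20, seed: int = 0,
                concentration: float = 80.0, dominant_frac: float = 0.8,
                kernel=None, biomarkers=None, **kwargs) -> GeneratorConfig:
    """Minimal valid generator config with K well-separated archetypes over
    G generic genera (genus g_k dominant in archetype k)."""
    genera = tuple(f"Genus{i}" for i in range(G))
    frac = np.full((K, G), (1 - dominant_frac) / max(G - 1, 1))
    for k in range(K):
        frac[k, k % G] = dominant_frac
    frac /= frac.sum(axis=1, keepdims=True)
    if kernel is None:
        kernel = np.full((K, K), 1.0 / K)
    kernels = {"probiotic": np.asarray(kernel, float),
               "placebo": np.asarray(kernel, float)}
    defaults = dict(
        n_subjects_per_arm=(n_subjects, n_subjects),
        n_enrolled_per_arm=(n_subjects, n_subjects),
        genera=genera,
        lineage={g: {} for g in genera},
        archetypes=frac * concentration,
        archetype_names=tuple(f"state{k}" for k in range(K)),
        initial_distribution=np.full(K, 1.0 / K),
        transition_kernels=kernels,
        biomarker_models=biomarkers if biomarkers is not None else {},
        breastfeeding_model=np.tile([8.0, 4.0], (K, 1)),
        n_failures=0,
        seed=seed,
    )
    defaults.update(kwargs)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """One full study-scale cohort under the default configuration."""
    return generate_cohort(GeneratorConfig(seed=0))


@pytest.fixture
def toy_table():
    counts = pd.DataFrame([[5, 3], [1, 0], [2, 7]],
                          index=["s1", "s2", "s3"], columns=["A", "B"])
    return TaxonTable(counts)


@pytest.fixture
def lineage_table():
    """Five taxa: two Bifidobacterium species, two unresolved genera within
    Enterobacteriaceae, one fully known Streptococcus."""
    counts = pd.DataFrame(
        [[5, 7, 2, 4, 1], [0, 3, 6, 0, 9]],
        index=["s1", "s2"],
        columns=["B.longum", "B.breve", "EntA", "EntB", "S.thermophilus"],
    )
    base = {"kingdom": "Bacteria", "phylum": "unknown", "class": "unknown",
            "order": "unknown"}
    lineage = {
        "B.longum": {**base, "family": "Bifidobacteriaceae",
                     "genus": "Bifidobacterium"},
        "B.breve": {**base, "family": "Bifidobacteriaceae",
                    "genus": "Bifidobacterium"},
        "EntA": {**base, "family": "Enterobacteriaceae", "genus": "unknown"},
        "EntB": {**base, "family": "Enterobacteriaceae", "genus": "unknown"},
        "S.thermophilus": {**base, "family": "Streptococcaceae",
                           "genus": "Streptococcus"},
    }
    return TaxonTable(counts, lineage)
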
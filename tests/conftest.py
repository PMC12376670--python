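import numpy as np
import pytest
from scipy.spatial import cKDTree

import fibertension as ft

COHORT_SEEDS = range(10)


@pytest.fixture(scope="session")
def config():
    return ft.AnalysisConfig(pixel_size=0.5)


@pytest.fixture(scope="session")
def cohort10():
    """Ten healthy + ten invasive_G2 samples (seeds 0-9, 1024 px, 0.5 um/px)."""
    return {
        "healthy": [ft.generate_tissue("healthy", seed=s) for s in COHORT_SEEDS],
        "invasive_G2": [ft.generate_tissue("invasive_G2", seed=s) for s in COHORT_SEEDS],
    }


@pytest.fixture(scope="session")
def analyzed10(cohort10, config):
    """Full per-sample analysis results for the seeds 0-9 cohort."""
    return {cond: [ft.run_sample(s.image, config) for s in samples]
            for cond, samples in cohort10.items()}


@pytest.fixture(scope="session")
def healthy_sample(cohort10):
    return cohort10["healthy"][0]


@pytest.fixture(scope="session")
def invasive_sample(cohort10):
    return cohort10["invasive_G2"][0]


def match_centroids(truth_xy, detected_xy, tol_um=3.0):
    """(recall, precision) by nearest-neighbor matching within tol_um."""
    if len(detected_xy) == 0:
        return 0.0, 0.0
    d_t, _ = cKDTree(detected_xy).query(truth_xy)
    d_d, _ = cKDTree(truth_xy).query(detected_xy)
    return float((d_t <= tol_um).mean()), float((d_d <= tol_um).mean())


#: Generated phenotypes contributing to each composite marker rule.
RULE_TRUTH_PHENOTYPES = {
    "Ki67+panCK+": ("cancer",),
    "GATA3+panCK+": ("cancer", "epithelial"),
    "aSMA+": ("myoepithelial", "caf"),
    "CD45+CD8+": ("t_cytotoxic",),
    "CD4+FoxP3+": ("treg",),
}


def truth_rule_percentage(truth, rule):
    cells = truth.cells
    return 100.0 * cells["phenotype"].isin(RULE_TRUTH_PHENOTYPES[rule]).mean()
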
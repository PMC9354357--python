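import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("derandomized", derandomize=True)
hypothesis_settings.load_profile("derandomized")

from finmeta.de import CountMatrix
from finmeta.evaluate import run_simulation_study
from finmeta.meta import EvidenceTable, StudyDesign

SEED = 0


@pytest.fixture
def design3() -> StudyDesign:
    """Three studies with the reference replicate layout."""
    return StudyDesign(("s1", "s2", "s3"), ((10, 10), (15, 10), (12, 16)))


@pytest.fixture
def toy_evidence(design3: StudyDesign) -> EvidenceTable:
    """Four genes, two studies, equal replicates: the hand-checkable case.

    g1: strongly DE, concordant up.  g2: strongly DE, conflicting directions
    with perfectly balanced evidence.  g3: null.  g4: present in one study
    only.
    """
    design = StudyDesign(("a", "b"), ((10, 10), (10, 10)))
    pv = pd.DataFrame(
        {
            "a": [1e-6, 1e-6, 0.5, 1e-6],
            "b": [1e-6, 1e-6, 0.5, np.nan],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    lfc = pd.DataFrame(
        {
            "a": [2.0, 2.0, 0.1, 2.0],
            "b": [2.0, -2.0, 0.1, np.nan],
        },
        index=pv.index,
    )
    return EvidenceTable(design=design, pvalues=pv, log2fc=lfc)


def nb_counts(
    rng: np.random.Generator,
    n_genes: int = 2000,
    n1: int = 10,
    n2: int = 10,
    dispersion: float | np.ndarray = 0.1,
    lfc: np.ndarray | None = None,
    mean_log: float = 3.5,
    mean_sd: float = 1.8,
) -> CountMatrix:
    """NB count matrix with optional case-side log2 fold changes."""
    mu = rng.lognormal(mean_log, mean_sd, n_genes)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_genes,))
    case_mu = mu * np.exp2(lfc if lfc is not None else 0.0)
    mu_mat = np.hstack(
        [np.tile(case_mu[:, None], (1, n1)), np.tile(mu[:, None], (1, n2))]
    )
    pois = phi < 1e-12
    y = np.empty_like(mu_mat, dtype=np.int64)
    if pois.any():
        y[pois] = rng.poisson(mu_mat[pois])
    if (~pois).any():
        r = (1.0 / phi[~pois])[:, None]
        y[~pois] = rng.negative_binomial(r, r / (r + mu_mat[~pois]))
    frame = pd.DataFrame(y, index=[f"g{i:04d}" for i in range(n_genes)])
    return CountMatrix(frame, np.array([1] * n1 + [2] * n2))


@pytest.fixture(scope="session")
def scaled_study():
    """The scaled-down four-setting simulation benchmark (shared, ~3 min).

    20 trials per setting, 5000 genes, 10% DE, seed fixed; the per-setting
    summaries back the FDR-control, unique-TP and AUC-ordering checks.
    """
    summary, per_trial = run_simulation_study(
        (1, 2, 3, 4), 20, n_genes=5000, pi_de=0.1, seed=SEED
    )
    return summary, per_trial
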
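"""Multi-study negative-binomial RNA-seq count simulation with known truth.

Counts for gene *g*, condition *c*, replicate *r*, study *s* are drawn as

    y_gcrs ~ NB(mean = exp(log mu_gc + eps_gs), dispersion = phi_g)

where ``mu_gc`` are the per-condition base means (equal for non-DE genes,
separated by the true log2 fold change for DE genes) and ``eps_gs ~ N(0,
sigma^2)`` is a lognormal study effect drawn once per gene and study.  By
default the effect is shared between the two conditions of a study, so the
inter-study variability parameter sigma moves expression levels between
studies without touching the true within-study fold change; observed
direction conflicts then arise from estimation noise, which grows when a
study effect pushes a gene's counts low.  A per-condition variant of the
study effect is available through ``study_effect``.

Base parameters can be generated synthetically (log-normal means, gamma
dispersions) or estimated from any user-supplied two-condition count matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import CASE, CONTROL, CountMatrix, DEConfig, run_study_de
from .meta import StudyDesign, bh_adjust

__all__ = [
    "SimParams",
    "SimulatedDataset",
    "default_sim_params",
    "estimate_base_params",
    "simulate_counts",
    "TABLE1_SETTINGS",
]

logger = logging.getLogger(__name__)

#: The four simulation settings of the reference study design: inter-study
#: variability sigma and per-study (cases, controls) replicate counts.
TABLE1_SETTINGS: dict[int, dict] = {
    1: {"sigma": 0.15, "replicates": ((10, 10), (15, 10), (12, 16))},
    2: {"sigma": 0.15, "replicates": ((10, 10), (15, 10), (12, 16), (14, 12), (20, 20))},
    3: {"sigma": 0.5, "replicates": ((10, 10), (15, 10), (12, 16))},
    4: {"sigma": 0.5, "replicates": ((10, 10), (15, 10), (12, 16), (14, 12), (20, 20))},
}


def design_for_setting(setting: int) -> StudyDesign:
    reps = TABLE1_SETTINGS[setting]["replicates"]
    return StudyDesign(
        studies=tuple(f"study{i + 1}" for i in range(len(reps))), replicates=reps
    )


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of a multi-study NB simulation.

    ``base_mean`` is (G, 2): column 0 the case-condition mean, column 1 the
    control mean; non-DE genes have equal columns.  ``true_log2fc`` is the
    signed case-vs-control log2 fold change (0 for non-DE genes) and
    ``true_direction`` its sign.
    """

    base_mean: np.ndarray
    dispersion: np.ndarray
    is_de: np.ndarray
    true_log2fc: np.ndarray
    sigma: float
    design: StudyDesign
    study_effect: str = "shared"

    def __post_init__(self) -> None:
        g = self.base_mean.shape[0]
        if self.base_mean.shape != (g, 2):
            raise ValueError("base_mean must have shape (G, 2)")
        for name, arr in (
            ("dispersion", self.dispersion),
            ("is_de", self.is_de),
            ("true_log2fc", self.true_log2fc),
        ):
            if np.asarray(arr).shape != (g,):
                raise ValueError(f"{name} must have shape (G,)")
        if np.any(self.base_mean <= 0):
            raise ValueError("base means must be positive")
        if np.any(self.dispersion < 0):
            raise ValueError("dispersions must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if np.any(self.true_log2fc[~self.is_de] != 0):
            raise ValueError("non-DE genes must have zero true log2FC")
        if self.study_effect not in ("shared", "per_condition"):
            raise ValueError("study_effect must be 'shared' or 'per_condition'")

    @property
    def n_genes(self) -> int:
        return self.base_mean.shape[0]

    @property
    def true_direction(self) -> np.ndarray:
        """+1 / -1 for DE genes, 0 for non-DE genes."""
        return np.sign(self.true_log2fc).astype(int)

    def genes(self) -> pd.Index:
        width = len(str(self.n_genes))
        return pd.Index([f"g{i:0{width}d}" for i in range(self.n_genes)], name="gene")


@dataclass(frozen=True)
class SimulatedDataset:
    """Simulated counts per study plus the generating truth.

    ``studies`` maps study id to a :class:`~finmeta.de.CountMatrix` whose
    columns are the case replicates followed by the control replicates.
    ``truth`` is a frame (gene, is_de, true_direction, true_log2fc) and
    ``realized_log_mean`` records ``log mu_gc + eps_gs`` per (gene, study,
    condition) for inspection of the study effect.
    """

    params: SimParams
    studies: dict[str, CountMatrix]
    truth: pd.DataFrame
    realized_log_mean: np.ndarray  # (G, S, 2)
    seed: int


def default_sim_params(
    n_genes: int = 5000,
    pi_de: float = 0.1,
    *,
    sigma: float = 0.15,
    design: StudyDesign | None = None,
    seed: int = 0,
    mean_log_mu: float = 3.5,
    mean_log_sd: float = 1.8,
    dispersion_shape: float = 2.0,
    dispersion_scale: float = 0.08,
    lfc_median: float = 0.6,
    lfc_spread: float = 0.6,
    lfc_range: tuple[float, float] | None = None,
    study_effect: str = "shared",
) -> SimParams:
    """Synthetic generative parameters mimicking a deep human cohort.

    Base (control) means are log-normal — median ``exp(mean_log_mu)`` ≈ 33
    counts with a heavy right tail — and dispersions gamma with mean
    ``shape * scale`` = 0.16, the magnitude typical of human bulk RNA-seq
    cohorts.  Exactly ``round(pi_de * n_genes)`` genes are differentially
    expressed with equiprobable direction; the fold change is applied to the
    case condition.

    Absolute log2 fold changes are log-normal with median ``lfc_median``
    and log-scale spread ``lfc_spread``, emulating the effect-size profile
    of a DEG set estimated from a large human cohort, where modest effects
    dominate and only a tail exceeds one unit of log2FC.  Pass ``lfc_range``
    for a uniform draw over an explicit interval instead.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    if not 0.0 <= pi_de <= 1.0:
        raise ValueError("pi_de must lie in [0, 1]")
    if lfc_range is not None and (lfc_range[0] < 0 or lfc_range[1] < lfc_range[0]):
        raise ValueError("lfc_range must be non-negative and increasing")
    if lfc_range is None and lfc_median <= 0:
        raise ValueError("lfc_median must be positive")
    design = design or design_for_setting(1)
    rng = np.random.default_rng(seed)

    control = rng.lognormal(mean=mean_log_mu, sigma=mean_log_sd, size=n_genes)
    phi = rng.gamma(shape=dispersion_shape, scale=dispersion_scale, size=n_genes)

    n_de = int(round(pi_de * n_genes))
    is_de = np.zeros(n_genes, dtype=bool)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de[de_idx] = True
    lfc = np.zeros(n_genes)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    if lfc_range is not None:
        magnitude = rng.uniform(lfc_range[0], lfc_range[1], size=n_de)
    else:
        magnitude = rng.lognormal(mean=np.log(lfc_median), sigma=lfc_spread, size=n_de)
    lfc[de_idx] = signs * magnitude

    case = control * np.exp2(lfc)
    base = np.column_stack([case, control])
    return SimParams(
        base_mean=base,
        dispersion=phi,
        is_de=is_de,
        true_log2fc=lfc,
        sigma=sigma,
        design=design,
        study_effect=study_effect,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) sample; dispersion 0 degenerates to Poisson."""
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi < 1e-12
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_counts(params: SimParams, seed: int = 0) -> SimulatedDataset:
    """Draw the full counts tensor for every study of ``params.design``.

    One lognormal study effect ``eps_gs ~ N(0, sigma^2)`` per gene and study
    (shared between conditions by default) shifts the log means before NB
    sampling; with ``sigma = 0`` the realised means equal the base means
    exactly.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    g, s = params.n_genes, params.design.n_studies
    genes = params.genes()
    phi = params.dispersion
    log_base = np.log(params.base_mean)  # (G, 2)

    realized = np.empty((g, s, 2))
    studies: dict[str, CountMatrix] = {}
    for j, (sid, (r_case, r_ctrl)) in enumerate(
        zip(params.design.studies, params.design.replicates)
    ):
        if params.study_effect == "shared":
            eps = rng.normal(0.0, params.sigma, size=g)[:, None]  # (G, 1)
            realized[:, j, :] = log_base + eps
        else:
            eps = rng.normal(0.0, params.sigma, size=(g, 2))
            realized[:, j, :] = log_base + eps
        mu_case = np.exp(realized[:, j, 0])
        mu_ctrl = np.exp(realized[:, j, 1])
        phi_rep = np.broadcast_to(phi[:, None], (g, max(r_case, r_ctrl)))
        y_case = _nb_draw(rng, np.broadcast_to(mu_case[:, None], (g, r_case)), phi_rep[:, :r_case])
        y_ctrl = _nb_draw(rng, np.broadcast_to(mu_ctrl[:, None], (g, r_ctrl)), phi_rep[:, :r_ctrl])
        cols = [f"{sid}_case{r + 1}" for r in range(r_case)] + [
            f"{sid}_ctrl{r + 1}" for r in range(r_ctrl)
        ]
        frame = pd.DataFrame(np.hstack([y_case, y_ctrl]), index=genes, columns=cols)
        labels = np.array([CASE] * r_case + [CONTROL] * r_ctrl)
        studies[sid] = CountMatrix(frame, labels)

    truth = pd.DataFrame(
        {
            "is_de": params.is_de,
            "true_direction": params.true_direction,
            "true_log2fc": params.true_log2fc,
        },
        index=genes,
    )
    return SimulatedDataset(
        params=params, studies=studies, truth=truth, realized_log_mean=realized, seed=seed
    )


def estimate_base_params(
    counts: CountMatrix,
    *,
    sigma: float = 0.15,
    design: StudyDesign | None = None,
    alpha: float = 0.05,
    de_config: DEConfig | None = None,
) -> SimParams:
    """Estimate simulation parameters from a real two-condition matrix.

    Per-condition means come from average CPM scaled to the mean library
    size; dispersions from the method of moments on library-size-normalised
    counts (floored at 0); the DE set is whatever the per-study NB-GLM
    pipeline calls at BH < ``alpha`` on the same matrix, with the observed
    log2FC taken as the true fold change.
    """
    labels = counts.labels
    if len(set(labels.tolist())) < 2:
        raise ValueError("need both conditions to estimate parameters")
    y = counts.counts.to_numpy(dtype=float)
    lib = counts.library_sizes()
    norm = y / lib[None, :] * lib.mean()

    mean_case = norm[:, labels == CASE].mean(axis=1)
    mean_ctrl = norm[:, labels == CONTROL].mean(axis=1)

    # moment dispersion pooled across conditions: var = mu + phi mu^2
    phis = []
    for lab in (CASE, CONTROL):
        sub = norm[:, labels == lab]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phis.append(np.where(m > 0, (v - m) / m**2, 0.0))
    phi = np.maximum(np.nanmean(np.column_stack(phis), axis=1), 0.0)

    de_res = run_study_de(counts, de_config or DEConfig())
    qv = pd.Series(bh_adjust(de_res["pvalue"].to_numpy()), index=de_res.index)
    is_de = pd.Series(False, index=counts.genes)
    is_de.loc[qv.index[qv < alpha]] = True
    lfc = pd.Series(0.0, index=counts.genes)
    lfc.loc[de_res.index] = de_res["log2FC"]
    lfc[~is_de] = 0.0

    base_ctrl = np.maximum(mean_ctrl, 1e-2)
    base_case = np.where(is_de.to_numpy(), np.maximum(mean_case, 1e-2), base_ctrl)
    # re-derive the stored fold change from the (possibly floored) means
    true_lfc = np.where(is_de.to_numpy(), np.log2(base_case / base_ctrl), 0.0)
    return SimParams(
        base_mean=np.column_stack([base_case, base_ctrl]),
        dispersion=phi,
        is_de=is_de.to_numpy(),
        true_log2fc=true_lfc,
        sigma=sigma,
        design=design or design_for_setting(1),
    )
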
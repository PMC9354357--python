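"""Direction-aware inverse-normal combination of per-study p-values.

This module implements three weighted z-score (Stouffer-type) statistics for
combining per-gene p-values across independent RNA-seq studies:

* **IN** — the classical weighted inverse-normal statistic
  ``N_g = sum_s w_s * Phi^{-1}(1 - p_gs)``, tested one-sided on the right
  tail.  Genes whose per-study directions of expression conflict must be
  handled post hoc (they are flagged and removed from the DEG list).
* **MIN** — the modified inverse-normal statistic
  ``N_g = sum_s w_s * B_gs * |Phi^{-1}(1 - p_gs)|`` where
  ``B_gs = +1/-1`` encodes over-/under-expression in study *s*; under the
  null each term is standard normal (sign-symmetrised half-normal), so a
  two-sided test applies.
* **FIN** — the fused statistic: IN (one-sided) for genes whose directions
  agree in every study where the gene is present, MIN (two-sided) for genes
  with conflicting directions, with a single pooled BH correction.

Study weights are ``w_s = sqrt(n_s / sum_k n_k)`` with ``n_s`` the total
replicate count of study *s*; for genes absent from some studies the weights
are renormalised over the studies that do carry the gene, so
``sum w_s^2 = 1`` always holds per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StudyDesign",
    "Weights",
    "EvidenceTable",
    "METHODS",
    "compute_weights",
    "z_transform",
    "stat_in",
    "stat_min",
    "stat_fin",
    "combined_p",
    "bh_adjust",
    "effective_direction",
    "run_meta",
]

logger = logging.getLogger(__name__)

METHODS = ("IN", "MIN", "FIN")

# p-values are clamped into this open interval before the normal quantile so
# the transform stays finite; ranks are unchanged.
P_CLAMP_LO = 1e-300
P_CLAMP_HI = 1.0 - 1e-16

#: symbols used in the per-study effect string
EFFECT_UP, EFFECT_DOWN, EFFECT_ABSENT = "+", "-", "·"


@dataclass(frozen=True)
class StudyDesign:
    """Replicate layout of the studies entering a meta-analysis.

    Parameters
    ----------
    studies
        Ordered study identifiers.
    replicates
        One ``(cases, controls)`` pair of biological-replicate counts per
        study, in the same order.
    """

    studies: tuple[str, ...]
    replicates: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(str(s) for s in self.studies))
        object.__setattr__(
            self, "replicates", tuple((int(a), int(b)) for a, b in self.replicates)
        )
        if len(self.studies) == 0:
            raise ValueError("a design needs at least one study")
        if len(self.studies) != len(self.replicates):
            raise ValueError("studies and replicates differ in length")
        if len(set(self.studies)) != len(self.studies):
            raise ValueError("duplicate study identifiers")
        for sid, (r1, r2) in zip(self.studies, self.replicates):
            if r1 < 1 or r2 < 1:
                raise ValueError(
                    f"study {sid!r}: replicate counts must be positive, got ({r1}, {r2})"
                )

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def totals(self) -> np.ndarray:
        """Total replicate count per study (cases + controls)."""
        return np.array([r1 + r2 for r1, r2 in self.replicates], dtype=float)

    def index_of(self, study: str) -> int:
        try:
            return self.studies.index(study)
        except ValueError:
            raise KeyError(f"unknown study {study!r}") from None


@dataclass(frozen=True)
class Weights:
    """Per-study weights with squares summing to one over ``studies``."""

    studies: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def compute_weights(design: StudyDesign, present: Sequence[str] | None = None) -> Weights:
    """Replicate-count weights ``w_s = sqrt(n_s / sum_k n_k)``.

    ``present`` restricts the computation to the studies in which a gene was
    observed; the denominator then only counts replicates of those studies,
    so the weight vector of every gene satisfies ``sum w_s^2 = 1``.
    """
    if present is None:
        present = design.studies
    present = tuple(present)
    if len(present) == 0:
        raise ValueError("no study evidence: empty present subset")
    idx = [design.index_of(s) for s in present]
    totals = design.totals()[idx]
    w = np.sqrt(totals / totals.sum())
    return Weights(studies=present, values=w)


def z_transform(p: float | np.ndarray) -> float | np.ndarray:
    """Standard-normal quantile at ``1 - p`` (``Phi^{-1}(1 - p)``).

    Values of 0 or 1 are clamped to keep the quantile finite; anything
    outside ``[0, 1]`` is a hard error.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any((arr <= 0) | (arr >= 1)):
        logger.warning("p-values of exactly 0 or 1 clamped before quantile transform")
    clamped = np.clip(arr, P_CLAMP_LO, P_CLAMP_HI)
    z = stats.norm.isf(clamped)
    return float(z) if np.isscalar(p) else z


def _check_lengths(p: np.ndarray, w: np.ndarray, d: np.ndarray | None = None) -> None:
    if p.shape != w.shape or (d is not None and d.shape != p.shape):
        raise ValueError("p-values, weights and directions must have equal length")


def stat_in(p_vec: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted inverse-normal statistic ``sum_s w_s Phi^{-1}(1 - p_gs)``."""
    p = np.asarray(p_vec, dtype=float)
    w = np.asarray(weights, dtype=float)
    _check_lengths(p, w)
    return float(np.dot(w, z_transform(p)))


def stat_min(
    p_vec: Sequence[float], dir_vec: Sequence[int], weights: Sequence[float]
) -> float:
    """Modified statistic ``sum_s w_s B_gs |Phi^{-1}(1 - p_gs)|``.

    Antisymmetric under a global flip of all directions.
    """
    p = np.asarray(p_vec, dtype=float)
    w = np.asarray(weights, dtype=float)
    d = np.asarray(dir_vec, dtype=float)
    _check_lengths(p, w, d)
    if not np.all(np.isin(d, (-1.0, 1.0))):
        raise ValueError("directions must be +1 or -1")
    return float(np.dot(w, d * np.abs(z_transform(p))))


def stat_fin(
    p_vec: Sequence[float], dir_vec: Sequence[int], weights: Sequence[float]
) -> tuple[float, str]:
    """Fused statistic: IN on concordant genes, MIN on mismatched ones.

    Returns ``(N_g, branch)`` with branch ``"concordant"`` when every
    present-study direction agrees (a single study is vacuously concordant)
    and ``"mismatched"`` otherwise.
    """
    d = np.asarray(dir_vec, dtype=float)
    if not np.all(np.isin(d, (-1.0, 1.0))):
        raise ValueError("directions must be +1 or -1")
    if np.all(d == d[0]):
        return stat_in(p_vec, weights), "concordant"
    return stat_min(p_vec, dir_vec, weights), "mismatched"


def combined_p(n_g: float, sidedness: str) -> float:
    """Combined p-value of a standard-normal statistic.

    ``one_sided``: right-tail ``1 - Phi(N_g)`` (IN and the concordant FIN
    branch).  ``two_sided``: ``2 [1 - Phi(|N_g|)]`` (MIN and the mismatched
    FIN branch).
    """
    if sidedness == "one_sided":
        return float(stats.norm.sf(n_g))
    if sidedness == "two_sided":
        return float(min(1.0, 2.0 * stats.norm.sf(abs(n_g))))
    raise ValueError(f"unknown sidedness {sidedness!r}")


def bh_adjust(p_vec: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_vec, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def effective_direction(n_g: float, branch: str, shared_direction: int | None = None) -> str:
    """Final up/down call of a meta-analysed gene.

    Concordant genes keep their shared per-study direction; mismatched genes
    take the sign of the combined statistic ``N_g``.
    """
    if branch == "concordant":
        if shared_direction not in (-1, 1):
            raise ValueError("concordant branch requires the shared direction")
        return EFFECT_UP if shared_direction > 0 else EFFECT_DOWN
    if n_g == 0.0:
        logger.warning("mismatched gene with N_g exactly 0; direction set to '+'")
        return EFFECT_UP
    return EFFECT_UP if n_g > 0 else EFFECT_DOWN


@dataclass
class EvidenceTable:
    """Per-gene, per-study evidence aligned on a study design.

    ``pvalues`` and ``log2fc`` are genes-by-studies frames whose columns
    follow ``design.studies``; ``NaN`` marks a gene absent from a study and
    the two frames must share the same missingness pattern.  Directions
    ``B_gs`` derive from the sign of log2FC (an exact zero counts as up,
    logged once).
    """

    design: StudyDesign
    pvalues: pd.DataFrame
    log2fc: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.design.studies)
        if list(self.pvalues.columns) != cols or list(self.log2fc.columns) != cols:
            raise ValueError("evidence columns must match the design's study order")
        if not self.pvalues.index.equals(self.log2fc.index):
            raise ValueError("p-value and log2FC tables must share the gene index")
        pna, lna = self.pvalues.isna().to_numpy(), self.log2fc.isna().to_numpy()
        if not np.array_equal(pna, lna):
            raise ValueError("p-value and log2FC missingness must agree")
        vals = self.pvalues.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError("p-values must lie in [0, 1]")
        absent_everywhere = pna.all(axis=1)
        if absent_everywhere.any():
            dropped = self.pvalues.index[absent_everywhere]
            logger.warning("dropping %d genes absent from every study", len(dropped))
            self.pvalues = self.pvalues.loc[~absent_everywhere]
            self.log2fc = self.log2fc.loc[~absent_everywhere]

    @property
    def genes(self) -> pd.Index:
        return self.pvalues.index

    def present_mask(self) -> np.ndarray:
        return self.pvalues.notna().to_numpy()

    def directions(self) -> np.ndarray:
        """Direction matrix in {-1, +1}, NaN-positions arbitrary (+1)."""
        lfc = self.log2fc.to_numpy(dtype=float)
        if np.any(lfc[~np.isnan(lfc)] == 0.0):
            logger.info("log2FC of exactly 0 treated as up-regulated (+1)")
        with np.errstate(invalid="ignore"):
            d = np.where(lfc < 0, -1.0, 1.0)
        return d


def _effect_strings(dirs: np.ndarray, present: np.ndarray) -> list[str]:
    sym = np.where(present, np.where(dirs > 0, EFFECT_UP, EFFECT_DOWN), EFFECT_ABSENT)
    return ["".join(row) for row in sym]


def run_meta(
    evidence: EvidenceTable,
    method: str,
    *,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    fc_filter: bool = True,
    in_conflict_mode: str = "posthoc",
) -> pd.DataFrame:
    """Combine per-study evidence into one meta-analysis call per gene.

    Per gene the study weights are renormalised over the studies where the
    gene is present, the requested statistic is formed, a combined p-value is
    computed (IN: one-sided; MIN: two-sided; FIN: branch-dependent) and a
    single BH pass over all genes tested by the method yields FDR q-values.
    A gene is flagged DEG when ``fdr < alpha`` and — if ``fc_filter`` — its
    mean absolute log2FC over present studies exceeds ``lfc_threshold``.

    IN cannot interpret genes with conflicting directions; with
    ``in_conflict_mode="posthoc"`` (default) they are tested and BH-adjusted
    like all others but removed from the DEG list afterwards, with
    ``"prefilter"`` they are excluded before the BH pass.

    Returns a frame with columns ``gene, method, Ng, branch, effect,
    n_present, mean_abs_log2FC, pvalue_combined, fdr, effective_direction,
    is_DEG, conflicting``.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if in_conflict_mode not in ("posthoc", "prefilter"):
        raise ValueError(f"unknown IN conflict mode {in_conflict_mode!r}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")

    present = evidence.present_mask()
    pvals = evidence.pvalues.to_numpy(dtype=float)
    lfc = evidence.log2fc.to_numpy(dtype=float)
    dirs = evidence.directions()
    genes = evidence.genes
    n_genes, n_studies = present.shape
    totals = evidence.design.totals()

    z = np.full_like(pvals, np.nan)
    z[present] = z_transform(pvals[present])

    # per-gene weights renormalised over present studies: w_gs^2 = n_s / sum_present n_k
    denom = (present * totals).sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.sqrt(np.where(present, totals / denom, 0.0))

    first = np.argmax(present, axis=1)
    ref_dir = dirs[np.arange(n_genes), first]
    concordant = np.all((dirs == ref_dir[:, None]) | ~present, axis=1)

    n_in = np.nansum(np.where(present, w * z, 0.0), axis=1)
    n_min = np.nansum(np.where(present, w * dirs * np.abs(z), 0.0), axis=1)

    if method == "IN":
        n_g = n_in
        sided = np.full(n_genes, "one_sided", dtype=object)
    elif method == "MIN":
        n_g = n_min
        sided = np.full(n_genes, "two_sided", dtype=object)
    else:  # FIN
        n_g = np.where(concordant, n_in, n_min)
        sided = np.where(concordant, "one_sided", "two_sided").astype(object)

    p_comb = np.where(
        sided == "one_sided",
        stats.norm.sf(n_g),
        np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(n_g))),
    )

    conflicting = ~concordant
    tested = np.ones(n_genes, dtype=bool)
    if method == "IN" and in_conflict_mode == "prefilter":
        tested = concordant

    fdr = np.full(n_genes, np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(p_comb[tested])

    n_present = present.sum(axis=1)
    mean_abs_lfc = np.nansum(np.abs(np.where(present, lfc, np.nan)), axis=1) / n_present

    with np.errstate(invalid="ignore"):
        is_deg = tested & (fdr < alpha)
    if fc_filter:
        is_deg &= mean_abs_lfc > lfc_threshold
    if method == "IN":
        # direction information is external to the IN statistic: conflicting
        # genes cannot be called and are struck from the DEG list
        is_deg &= concordant

    eff_sign = np.where(concordant, ref_dir, np.where(n_g >= 0, 1.0, -1.0))
    eff = np.where(eff_sign > 0, EFFECT_UP, EFFECT_DOWN)

    branch = np.where(concordant, "concordant", "mismatched")
    out = pd.DataFrame(
        {
            "gene": genes.to_numpy(),
            "method": method,
            "Ng": n_g,
            "branch": branch,
            "effect": _effect_strings(dirs, present),
            "n_present": n_present,
            "mean_abs_log2FC": mean_abs_lfc,
            "pvalue_combined": p_comb,
            "fdr": fdr,
            "effective_direction": eff,
            "is_DEG": is_deg,
            "conflicting": conflicting,
        }
    )
    return out
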
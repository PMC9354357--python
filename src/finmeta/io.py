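"""Readers, writers and run configuration.

Everything on disk is tab-separated UTF-8 text: per-study result tables
(gene, pvalue, log2FC), a design file (study, cases, controls), count
matrices (first column the gene id), the meta-analysis output table and the
simulation truth table.  Missing values are written as ``NA``.  A JSON
manifest records the parameters and seed of every simulation run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .de import CASE, CONTROL, CountMatrix
from .meta import EvidenceTable, StudyDesign
from .simulate import SimulatedDataset

__all__ = [
    "RunConfig",
    "load_config",
    "read_design",
    "read_study_results",
    "read_counts",
    "assemble_evidence",
    "write_meta_table",
    "read_meta_table",
    "write_counts",
    "write_design",
]

logger = logging.getLogger(__name__)

NA = "NA"
_META_COLUMNS = [
    "gene",
    "method",
    "Ng",
    "branch",
    "effect",
    "n_present",
    "mean_abs_log2FC",
    "pvalue_combined",
    "fdr",
    "effective_direction",
    "is_DEG",
    "conflicting",
]


@dataclass
class RunConfig:
    """Parameters of a pipeline run; unknown keys are rejected on load."""

    method: str = "FIN"
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    fc_filter: bool = True
    in_conflict_mode: str = "posthoc"
    cpm_threshold: float = 0.85
    min_samples: int | None = None
    prior_df: float = 10.0
    sigma: float = 0.15
    setting: int = 1
    trials: int = 20
    n_genes: int = 5000
    pi_de: float = 0.1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration with a strict key schema."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _find_column(columns, name: str) -> str:
    matches = [c for c in columns if c.strip().lower() == name.lower()]
    if not matches:
        raise ValueError(f"missing required column {name!r}")
    return matches[0]


def read_design(path: str | Path) -> StudyDesign:
    """Read a design TSV with columns study, cases, controls."""
    df = pd.read_csv(path, sep="\t")
    cols = [_find_column(df.columns, c) for c in ("study", "cases", "controls")]
    df = df[cols]
    return StudyDesign(
        studies=tuple(df.iloc[:, 0].astype(str)),
        replicates=tuple(zip(df.iloc[:, 1].astype(int), df.iloc[:, 2].astype(int))),
    )


def write_design(design: StudyDesign, path: str | Path) -> None:
    pd.DataFrame(
        {
            "study": design.studies,
            "cases": [r for r, _ in design.replicates],
            "controls": [c for _, c in design.replicates],
        }
    ).to_csv(path, sep="\t", index=False)


def read_study_results(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a per-study result table (gene, pvalue, log2FC), validated.

    Duplicate gene identifiers, p-values outside [0, 1] and unparseable
    numbers are hard errors naming the offending gene or line.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    gene_c = _find_column(df.columns, "gene")
    p_c = _find_column(df.columns, "pvalue")
    l_c = _find_column(df.columns, "log2FC")
    out = pd.DataFrame({"gene": df[gene_c].astype(str)})
    for col, src in (("pvalue", p_c), ("log2FC", l_c)):
        try:
            out[col] = pd.to_numeric(df[src], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[src], errors="coerce")
            line = int(np.flatnonzero(bad.isna() & df[src].notna())[0]) + 2
            raise ValueError(f"{path}: unparseable {col} at line {line}") from None
    dup = out["gene"][out["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene ids: {sorted(set(dup))[:5]}")
    bad_p = out["pvalue"][(out["pvalue"] < 0) | (out["pvalue"] > 1)]
    if len(bad_p):
        line = int(bad_p.index[0]) + 2
        raise ValueError(f"{path}: p-value outside [0, 1] at line {line}")
    return out.set_index("gene")


def assemble_evidence(
    tables: dict[str, pd.DataFrame], design: StudyDesign, intersect: bool = False
) -> EvidenceTable:
    """Align per-study result tables on the union (or intersection) gene pool.

    The meta-analysed gene universe is by default the union of the genes
    reported by each study — a gene absent from a study simply contributes
    no evidence there and its weights renormalise over the studies that do
    carry it.  ``intersect=True`` restricts to genes common to all studies.
    """
    missing = set(design.studies) - set(tables)
    if missing or set(tables) - set(design.studies):
        raise ValueError(
            f"study tables and design disagree: missing {sorted(missing)}, "
            f"unexpected {sorted(set(tables) - set(design.studies))}"
        )
    sets = [set(t.index) for t in tables.values()]
    pool = set.intersection(*sets) if intersect else set.union(*sets)
    genes = sorted(pool)
    pvals = pd.DataFrame(np.nan, index=genes, columns=list(design.studies))
    lfc = pd.DataFrame(np.nan, index=genes, columns=list(design.studies))
    for sid in design.studies:
        t = tables[sid].loc[tables[sid].index.intersection(genes)]
        pvals.loc[t.index, sid] = t["pvalue"].to_numpy()
        lfc.loc[t.index, sid] = t["log2FC"].to_numpy()
    return EvidenceTable(design=design, pvalues=pvals, log2fc=lfc)


def write_meta_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write a meta-analysis result table, deterministic column order.

    Combined p-values and FDR are printed in scientific notation with six
    significant digits; missing values as ``NA``.
    """
    df = results[_META_COLUMNS].copy()
    for col in ("pvalue_combined", "fdr"):
        df[col] = df[col].map(lambda v: NA if pd.isna(v) else f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False, na_rep=NA, encoding="utf-8")


def read_meta_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                     encoding="utf-8")
    for col in ("Ng", "mean_abs_log2FC", "pvalue_combined", "fdr"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("is_DEG", "conflicting"):
        df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    return df


def read_counts(path: str | Path, design_labels: np.ndarray | None = None) -> CountMatrix:
    """Read a counts TSV (first column gene id, one column per sample).

    Condition labels default to what sample names encode (``case``/``ctrl``
    substrings); otherwise pass ``design_labels`` explicitly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if design_labels is None:
        labels = []
        for name in df.columns:
            low = name.lower()
            if "case" in low:
                labels.append(CASE)
            elif "ctrl" in low or "control" in low or "normal" in low:
                labels.append(CONTROL)
            else:
                raise ValueError(
                    f"cannot infer condition of sample {name!r}; provide labels"
                )
        design_labels = np.array(labels)
    return CountMatrix(df, design_labels)


def write_counts(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write per-study counts TSVs, the truth table and a JSON manifest.

    Returns the paths written, keyed by ``counts_<study>``, ``truth`` and
    ``manifest``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid, cm in dataset.studies.items():
        p = out / f"counts_{sid}.tsv"
        cm.counts.to_csv(p, sep="\t")
        paths[f"counts_{sid}"] = p
    truth_path = out / "truth.tsv"
    dataset.truth.to_csv(truth_path, sep="\t")
    paths["truth"] = truth_path

    params = dataset.params
    manifest = {
        "seed": dataset.seed,
        "sigma": params.sigma,
        "n_genes": params.n_genes,
        "n_de": int(params.is_de.sum()),
        "study_effect": params.study_effect,
        "design": {
            "studies": list(params.design.studies),
            "replicates": [list(r) for r in params.design.replicates],
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    paths["manifest"] = manifest_path
    return paths
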
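"""Matrix I/O, run configuration and on-disk artifacts.

Input matrices are delimited text (TSV or CSV, dialect sniffed), first row =
variable names, optional first column = sample identifiers, rows = samples.
Missing or non-numeric cells are rejected with their coordinates: imputation
policy belongs to the caller, not to a PCA routine.

:func:`run` ties the pipeline together -- centering, optional permutation
selection of the component count, (sparse) fitting and writing loadings,
scores, variance accounting and a JSON manifest that suffices to reproduce
the run.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .components import permutation_component_count
from .nipals import center_columns, fit
from .penalties import PenaltyFamily, PenaltySpec
from .tuning import TuningConfig

__all__ = ["RunConfig", "read_matrix", "run"]

log = logging.getLogger("sspca")


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    input_path: str
    method: str = "sspca"  # pca | spca | sspca
    penalty: str = "hl"  # hl | lasso | scad | en
    k: Union[int, str] = 1  # integer or "auto" (permutation selection)
    w: float = 30.0
    delta: float = 1e-8
    scad_a: float = 3.7
    en_lambda2: float = 0.0
    zero_threshold: float = 5e-5
    cv_folds: int = 5
    permutations: int = 1000
    alpha: float = 0.001
    transpose: bool = False
    output_dir: str = "sspca_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in {"pca", "spca", "sspca"}:
            raise ValueError(f"method must be pca|spca|sspca, got {self.method!r}")
        if self.k == "auto":
            if self.permutations < 100:
                raise ValueError("k='auto' requires at least 100 permutations")
        elif int(self.k) < 1:
            raise ValueError("k must be >= 1 or 'auto'")


def read_matrix(path: Union[str, Path]) -> pd.DataFrame:
    """Read a delimited samples x variables matrix with labels.

    The first row holds variable names; a first column of non-numeric values
    is taken as sample identifiers.  Any missing or non-numeric cell raises
    with its row and column label.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing input file: {path}")
    df = pd.read_csv(path, sep=None, engine="python", header=0)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"no data rows/columns in {path}")
    first = df.iloc[:, 0]
    if not pd.api.types.is_numeric_dtype(first):
        df = df.set_index(df.columns[0])
        df.index.name = "sample"
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric or missing value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} of {path}"
        )
    return numeric.astype(float)


def _build_spec(cfg: RunConfig) -> PenaltySpec:
    if cfg.method == "pca":
        return PenaltySpec(family=PenaltyFamily.NONE, lam=0.0)
    fam = PenaltyFamily(cfg.penalty)
    return PenaltySpec(
        family=fam,
        lam=1.0,
        w=cfg.w,
        delta=cfg.delta,
        scad_a=cfg.scad_a,
        en_lambda2=cfg.en_lambda2,
        zero_threshold=cfg.zero_threshold,
    )


def run(config: RunConfig) -> Path:
    """Execute one configured analysis; returns the output directory.

    Outputs: ``loadings.tsv`` (full-precision loadings plus a 0/1 sparsity
    mask per component), ``scores.tsv``, ``summary.tsv`` (singular values,
    nonzero counts, adjusted variances), ``pvalues.tsv`` when ``k='auto'``,
    and ``manifest.json``.  On error, partially written outputs are removed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        df = read_matrix(config.input_path)
        if config.transpose:
            df = df.T
        X = center_columns(df.values, row_labels=df.index.astype(str), col_labels=df.columns.astype(str))
        log.info("loaded %d samples x %d variables", X.n, X.p)

        perm = None
        k = config.k
        if k == "auto":
            perm = permutation_component_count(
                X, P=config.permutations, alpha=config.alpha, seed=config.seed
            )
            k = perm.k0
            log.info("permutation test selected k0 = %d", k)
            pv = pd.DataFrame(
                {"component": np.arange(1, perm.p_values.size + 1),
                 "d_observed": perm.d_observed, "p_value": perm.p_values}
            )
            f = out / "pvalues.tsv"
            pv.to_csv(f, sep="\t", index=False)
            written.append(f)
        k = int(k)

        spec = _build_spec(config)
        tuning = (
            None
            if spec.family is PenaltyFamily.NONE
            else TuningConfig(K=config.cv_folds, seed=config.seed)
        )
        result = None
        if k >= 1:
            result = fit(
                X,
                k=k,
                spec=spec,
                use_condition_shrinkage=(config.method == "sspca"),
                tuning=tuning,
            )
            comp = [f"PC{i + 1}" for i in range(k)]
            ld = pd.DataFrame(result.loadings, index=X.col_labels, columns=comp)
            for i, c in enumerate(comp):
                ld[f"{c}_nonzero"] = (
                    np.abs(result.loadings[:, i]) >= spec.zero_threshold
                ).astype(int)
            f = out / "loadings.tsv"
            ld.to_csv(f, sep="\t", float_format="%.17g")
            written.append(f)
            sc = pd.DataFrame(result.scores, index=X.row_labels, columns=comp)
            f = out / "scores.tsv"
            sc.to_csv(f, sep="\t", float_format="%.17g")
            written.append(f)
            summary = pd.DataFrame(
                {
                    "component": comp,
                    "singular_value": result.singular_values,
                    "nonzero_loadings": result.nonzero_counts,
                    "adjusted_variance_pct": result.adjusted_variance,
                    "cumulative_adjusted_variance_pct": result.cumulative_adjusted_variance,
                    "lambda": result.lambdas,
                    "theta": result.thetas,
                    "converged": result.converged_flags,
                }
            )
            f = out / "summary.tsv"
            summary.to_csv(f, sep="\t", index=False, float_format="%.17g")
            written.append(f)

        manifest = {
            "config": asdict(config),
            "sspca_version": __version__,
            "numpy_version": np.__version__,
            "n_samples": X.n,
            "n_variables": X.p,
            "k_fitted": k,
            "kappa_max": result.kappa_max if result is not None else None,
            "lambdas": result.lambdas.tolist() if result is not None else [],
            "thetas": result.thetas.tolist() if result is not None else [],
        }
        f = out / "manifest.json"
        f.write_text(json.dumps(manifest, indent=2))
        written.append(f)
        return out
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise
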
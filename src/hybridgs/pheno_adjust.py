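"""Per-environment spatial adjustment of raw plot phenotypes.

Field trials record one oil-content measurement per plot, confounded with
field position (row/column gradients), repetition and the check-vs-hybrid
status of the entry.  Before any genomic model is fitted, plots are reduced
to one adjusted phenotype per hybrid and environment by a simple mixed
model:

    oil = mu + row + column + repetition + status + g + e

with row, column and repetition as unordered fixed factors (sum-to-zero
coding), status a fixed check/hybrid contrast, and g an independent random
genotype effect estimated by REML.  The adjusted phenotype of a hybrid is
mu_hat + status(hybrid) coefficient + its genotype BLUP; check varieties are
dropped from the output.  This is an explicit approximation of a dedicated
spatial model (no autoregressive or spline correlation structure).

Input/output are tidy DataFrames:
  plots:    environment, row, column, repetition, genotype, status, oil
  adjusted: environment, hybrid_id, value
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .mixed_model import RandomTerm, reml_fit

__all__ = ["adjust_environment", "adjust_all"]

PLOT_COLUMNS = ["environment", "row", "column", "repetition", "genotype", "status", "oil"]


def _effect_columns(values: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero coding; levels observed on a single plot are dropped.

    A level with one plot is aliased with that plot's genotype effect; its
    plots are coded at the factor average (all-zero row) with a warning.
    """
    counts = values.value_counts()
    single = sorted(counts[counts < 2].index.tolist())
    if single:
        warnings.warn(
            f"factor {name!r}: dropping single-plot level(s) {single} (aliased with genotype)",
            stacklevel=3,
        )
    retained = sorted(counts[counts >= 2].index.tolist())
    if len(retained) < 2:
        return np.zeros((len(values), 0)), []
    cols = np.zeros((len(values), len(retained) - 1))
    arr = values.to_numpy()
    last = retained[-1]
    for j, lev in enumerate(retained[:-1]):
        cols[arr == lev, j] = 1.0
        cols[arr == last, j] = -1.0
    return cols, [f"{name}[{lev}]" for lev in retained[:-1]]


def adjust_environment(plots: pd.DataFrame) -> pd.DataFrame:
    """Adjusted phenotype per hybrid for a single environment's plots."""
    missing = [c for c in PLOT_COLUMNS if c not in plots.columns]
    if missing:
        raise ValueError(f"plots table missing columns {missing}")
    envs = plots["environment"].unique()
    if len(envs) != 1:
        raise ValueError("adjust_environment expects a single environment; use adjust_all")
    env = envs[0]
    oil = plots["oil"].to_numpy(dtype=float)
    if np.any((oil <= 0) | (oil >= 100)):
        raise ValueError("oil content must lie in (0, 100)%")
    key = plots[["environment", "row", "column", "repetition"]]
    if key.duplicated().any():
        raise ValueError("duplicate (environment, row, column, repetition) plot keys")
    if plots["row"].nunique() < 2 or plots["column"].nunique() < 2:
        raise ValueError("need at least 2 rows and 2 columns in the field layout")

    blocks = [np.ones((len(plots), 1))]
    names = ["intercept"]
    for factor in ("row", "column", "repetition"):
        if plots[factor].nunique() < 2:
            continue
        cols, colnames = _effect_columns(plots[factor], factor)
        blocks.append(cols)
        names.extend(colnames)
    status = plots["status"].astype(str)
    bad_status = set(status.unique()) - {"check", "hybrid"}
    if bad_status:
        raise ValueError(f"unknown status value(s) {sorted(bad_status)}")
    status_coef = 0.0
    has_status = status.nunique() == 2
    if has_status:
        blocks.append((status == "hybrid").to_numpy(dtype=float)[:, None])
        names.append("status[hybrid]")
    X = np.hstack(blocks)
    # drop columns that are linearly dependent on earlier ones (e.g. a
    # repetition factor aliased with row blocks); intercept always kept
    kept = [0]
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, kept + [j]]) > len(kept):
            kept.append(j)
    if len(kept) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in kept]
        warnings.warn(f"dropping aliased fixed-effect column(s) {dropped}", stacklevel=2)
        X = X[:, kept]
        names = [names[j] for j in kept]

    genotypes = sorted(plots["genotype"].astype(str).unique())
    term = RandomTerm(
        name="genotype",
        levels=genotypes,
        incidence=[genotypes.index(g) for g in plots["genotype"].astype(str)],
        kinship=None,
        axis="genotype",
    )
    fit = reml_fit(oil, [term], X=X)
    if has_status and "status[hybrid]" in names:
        status_coef = float(fit.beta[names.index("status[hybrid]")])

    hybrids = sorted(plots.loc[status == "hybrid", "genotype"].astype(str).unique())
    blup = fit.blups["genotype"]
    values = fit.intercept + status_coef + blup.loc[hybrids].to_numpy()
    return pd.DataFrame({"environment": env, "hybrid_id": hybrids, "value": values})


def adjust_all(plots: pd.DataFrame) -> pd.DataFrame:
    """Adjust each environment independently and stack the results."""
    parts = [
        adjust_environment(sub.reset_index(drop=True))
        for _, sub in plots.groupby("environment", sort=True)
    ]
    return pd.concat(parts, ignore_index=True)
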
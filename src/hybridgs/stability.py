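"""Mean multi-environment performance and Wricke's ecovalence stability screen.

Given a complete matrix of predicted performances (one prediction per hybrid
per environment, mu_hat + BLUP from the per-environment genomic model),
Wricke's ecovalence measures each hybrid's contribution to the
genotype-by-environment interaction sum of squares:

    W_i = sum_e (p_ie - pbar_i. - pbar_.e + pbar_..)^2

A purely additive hybrid (parallel response across environments) has W = 0;
small W flags a stable hybrid.  The default threshold (5, in squared oil
percentage points) is data-scale dependent and exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["StabilityResult", "wricke_ecovalence"]


@dataclass
class StabilityResult:
    """Per-hybrid MET mean, ecovalence and stability flag."""

    table: pd.DataFrame  # index: hybrid; columns: met_mean, ecovalence, stable
    threshold: float

    @property
    def interaction_ss(self) -> float:
        """Total genotype-by-environment interaction sum of squares."""
        return float(self.table["ecovalence"].sum())


def wricke_ecovalence(performance: pd.DataFrame, threshold: float = 5.0) -> StabilityResult:
    """Ecovalence screen of a complete hybrids x environments performance matrix.

    ``performance`` is indexed by hybrid with one column per environment;
    missing cells are an error (predictions exist for every cross).  The MET
    mean is the unweighted row mean.
    """
    if performance.shape[0] < 2 or performance.shape[1] < 2:
        raise ValueError("need at least 2 hybrids and 2 environments")
    if performance.isna().any().any():
        raise ValueError("performance matrix has missing cells; predictions must be complete")
    P = performance.to_numpy(dtype=float)
    row_mean = P.mean(axis=1, keepdims=True)
    col_mean = P.mean(axis=0, keepdims=True)
    grand = P.mean()
    resid = P - row_mean - col_mean + grand
    W = (resid**2).sum(axis=1)
    table = pd.DataFrame(
        {
            "met_mean": row_mean.ravel(),
            "ecovalence": W,
            "stable": W < threshold,
        },
        index=performance.index,
    )
    return StabilityResult(table=table, threshold=threshold)
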
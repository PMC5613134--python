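"""Cross-validation of hybrid prediction: test-set sampling, training loop, scoring.

Two sampling schemes probe two breeding questions:

* ``random_hybrids`` — hold out a random 10% of the observed hybrids.  Both
  parents of a held-out hybrid usually keep other phenotyped descendants in
  training, so this measures the ability to complete the factorial design.
* ``by_parents`` — hold out a random 10% of the parent lines and move every
  observed descendant of a sampled parent into the test set.  Held-out
  hybrids then have one (T1) or two (T0) parents with no phenotyped
  descendants in training; this measures prediction for untested parents,
  where genomic kinship is the only route to a parent's effect.

Predictive ability is the Pearson correlation between adjusted phenotypes
and predictions over the test hybrids of an environment, averaged over
replicated test sets; all models are evaluated on the same sets so that
model contrasts are paired.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import FactorialDesign
from .kinship import KinshipMatrix
from .mixed_model import ConvergenceError, assemble_model, predict_hybrids, reml_fit

__all__ = [
    "TestSetPlan",
    "CvResult",
    "sample_random_hybrids",
    "sample_by_parents",
    "predictive_ability",
    "run_cv",
    "relative_improvement",
]

logger = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class TestSetPlan:
    """Replicated test sets of hybrids, with T0/T1 labels for parent sampling.

    Per-set RNG substreams are derived from (seed, set index), so growing
    ``n_sets`` never reshuffles earlier sets.
    """

    scheme: Literal["random_hybrids", "by_parents"]
    fraction: float
    n_sets: int
    seed: int
    sets: list[frozenset[str]]
    parents: list[list[tuple[str, str]]] | None = None  # (role, id) per sampled parent
    t0: list[frozenset[str]] | None = None
    t1: list[frozenset[str]] | None = None


def _observed_hybrids(design: FactorialDesign) -> pd.DataFrame:
    any_obs = design.observed.any(axis=1).to_numpy()
    return design.crosses.loc[any_obs].reset_index(drop=True)


def sample_random_hybrids(
    design: FactorialDesign, fraction: float = 0.10, n_sets: int = 100, seed: int = 0
) -> TestSetPlan:
    """Independent random draws of a fixed share of the observed hybrids."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    obs = _observed_hybrids(design)
    if len(obs) == 0:
        raise ValueError("design has no observed hybrids")
    size = _round_half_up(fraction * len(obs))
    if size == 0:
        raise ValueError(f"fraction {fraction} yields an empty test set for {len(obs)} hybrids")
    ids = obs["hybrid_id"].astype(str).to_numpy()
    sets = []
    for i in range(n_sets):
        rng = np.random.default_rng([seed, i])
        sets.append(frozenset(rng.choice(ids, size=size, replace=False)))
    return TestSetPlan("random_hybrids", fraction, n_sets, seed, sets)


def sample_by_parents(
    design: FactorialDesign,
    fraction: float = 0.10,
    n_sets: int = 100,
    seed: int = 0,
    stratified: bool = False,
) -> TestSetPlan:
    """Hold out parents: every observed descendant of a sampled parent is tested.

    Parents are drawn from the pooled female+male lines (unstratified by
    default).  Hybrids with both parents sampled are labeled T0, with
    exactly one, T1; by construction every test hybrid has at least one
    untested parent.  A draw that would empty the training side is redrawn
    (logged).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if not design.is_connected():
        raise ValueError("by-parents sampling requires a connected design")
    obs = _observed_hybrids(design)
    females = sorted(obs["female_id"].astype(str).unique())
    males = sorted(obs["male_id"].astype(str).unique())
    pooled = [("female", f) for f in females] + [("male", m) for m in males]
    hyb = obs["hybrid_id"].astype(str).to_numpy()
    fcol = obs["female_id"].astype(str).to_numpy()
    mcol = obs["male_id"].astype(str).to_numpy()

    sets, parents, t0s, t1s = [], [], [], []
    for i in range(n_sets):
        for attempt in range(100):
            rng = np.random.default_rng([seed, i, attempt])
            if stratified:
                n_f = _round_half_up(fraction * len(females))
                n_m = _round_half_up(fraction * len(males))
                draw = [("female", f) for f in rng.choice(females, n_f, replace=False)]
                draw += [("male", m) for m in rng.choice(males, n_m, replace=False)]
            else:
                n_p = _round_half_up(fraction * len(pooled))
                idx = rng.choice(len(pooled), n_p, replace=False)
                draw = [pooled[j] for j in idx]
            fset = {p for r, p in draw if r == "female"}
            mset = {p for r, p in draw if r == "male"}
            f_in = np.isin(fcol, sorted(fset))
            m_in = np.isin(mcol, sorted(mset))
            test_mask = f_in | m_in
            if test_mask.all():
                logger.warning("by_parents set %d attempt %d emptied training; redrawing", i, attempt)
                continue
            sets.append(frozenset(hyb[test_mask]))
            parents.append(draw)
            t0s.append(frozenset(hyb[f_in & m_in]))
            t1s.append(frozenset(hyb[test_mask & ~(f_in & m_in)]))
            break
        else:
            raise RuntimeError(f"could not draw a feasible by_parents set {i}")
    return TestSetPlan("by_parents", fraction, n_sets, seed, sets, parents, t0s, t1s)


def predictive_ability(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between observed and predicted test phenotypes.

    Returns NaN (with a warning) if either side has zero variance; such sets
    are excluded from mean abilities by the caller.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(observed) != len(predicted) or len(observed) < 3:
        raise ValueError("need >= 3 paired observed/predicted values")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        warnings.warn("zero variance in observed or predicted values; ability undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(observed, predicted)[0])


@dataclass
class CvResult:
    """Per-set abilities plus per-environment and MET summaries."""

    per_set: pd.DataFrame  # columns: environment, model, set, ability

    def summary(self) -> pd.DataFrame:
        """Mean and variance of ability per (environment, model), NaN sets excluded."""
        g = self.per_set.groupby(["environment", "model"])["ability"]
        return pd.DataFrame({"mean": g.mean(), "var": g.var(ddof=1)}).reset_index()

    def met_average(self) -> pd.Series:
        """Unweighted mean over environments of the per-environment mean ability."""
        s = self.summary()
        return s.groupby("model")["mean"].mean()


def run_cv(
    models: Sequence[str],
    plan: TestSetPlan,
    adjusted: pd.DataFrame,
    design: FactorialDesign,
    kernels: dict[str, KinshipMatrix],
) -> CvResult:
    """Replicated train/predict/score loop, paired across models.

    For every (environment, test set): variance components are re-estimated
    on the training hybrids only, the test hybrids are predicted through the
    kernels, and ability is scored against their adjusted phenotypes.  A
    REML failure on any model skips that set for all models (logged), so
    model contrasts stay paired.  Test phenotypes are never seen by the
    training step.
    """
    cross_of = {
        str(h): (str(f), str(m))
        for h, f, m in design.crosses[["hybrid_id", "female_id", "male_id"]].itertuples(index=False)
    }
    records = []
    for env, sub in adjusted.groupby("environment", sort=True):
        hybrids = sub["hybrid_id"].astype(str).to_numpy()
        y = sub["value"].to_numpy(dtype=float)
        crosses = [cross_of[h] for h in hybrids]
        for s, test_ids in enumerate(plan.sets):
            in_test = np.array([h in test_ids for h in hybrids])
            if in_test.sum() < 3 or (~in_test).sum() < 3:
                logger.warning("env %s set %d: too few test or train hybrids; skipped", env, s)
                continue
            train_idx = np.flatnonzero(~in_test)
            test_crosses = [crosses[j] for j in np.flatnonzero(in_test)]
            y_train = y[train_idx]
            train_crosses = [crosses[j] for j in train_idx]
            set_records = []
            try:
                for model in models:
                    terms = assemble_model(model, train_crosses, kernels)
                    fit = reml_fit(y_train, terms)
                    preds = predict_hybrids(fit, test_crosses)
                    r = predictive_ability(y[in_test], preds)
                    set_records.append(
                        {"environment": env, "model": model, "set": s, "ability": r}
                    )
            except ConvergenceError as exc:
                logger.warning("env %s set %d: REML failure (%s); set skipped for all models", env, s, exc)
                continue
            records.extend(set_records)
    return CvResult(per_set=pd.DataFrame.from_records(records))


def relative_improvement(baseline: float, improved: float) -> float:
    """Percent change of a predictive ability over a baseline ability."""
    if baseline == 0:
        raise ValueError("baseline ability is zero")
    return (improved - baseline) / baseline * 100.0
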
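"""Multi-kernel linear mixed model engine (REML + BLUP) for hybrid prediction.

Per environment the phenotype of hybrid fm is modeled as

    y_fm = mu + sum_k u_k[level_k(fm)] + e_fm,    u_k ~ N(0, sigma2_k K_k),
    e ~ N(0, sigma2_e I)

with independent Gaussian random terms whose covariance over levels is a
kinship kernel K_k (identity for the classical combining-ability model).
The model families:

* ``GCA``  — independent female and male general-combining-ability effects;
* ``FM``   — female and male effects with genomic kinships K_f, K_m;
* ``FMI``  — FM plus the female-by-male interaction (SCA) term with K_fm;
* ``FM_oil`` — FM restricted to a pathway SNP subset;
* ``mk_oil`` — multi-kernel FM: pathway and remaining-SNP kernels per parent;
* ``mk_epi`` — FM plus additive-by-additive epistasis kernels K_f(.)K_f,
  K_m(.)K_m.

Variance components are estimated by average-information REML with an
EM-like first step, step-halving and a non-negativity floor; the intercept
(or any fixed design) is profiled out of the restricted likelihood.  BLUPs
are produced for every level of each kernel, including levels without
observations, which are predicted through their kinship covariance with
observed levels — this is what makes prediction of untested parents and
unobserved crosses possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kinship import KinshipMatrix, epistasis_kinship

__all__ = [
    "RandomTerm",
    "ModelFit",
    "VariancePartition",
    "ConvergenceError",
    "reml_fit",
    "parts_of_variance",
    "zratio",
    "predict_hybrids",
    "assemble_model",
    "MODEL_KINDS",
]

MODEL_KINDS = ("GCA", "FM", "FMI", "FM_oil", "mk_oil", "mk_epi")


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


@dataclass
class RandomTerm:
    """One Gaussian random effect: levels, observation incidence and kernel.

    ``incidence[i]`` is the index (into ``levels``) of the level observation
    i belongs to.  ``kinship=None`` means independent levels (identity
    kernel).  ``axis`` tells hybrid prediction how to map a cross (f, m) to
    a level: ``female`` -> f, ``male`` -> m, ``cross`` -> (f, m); terms on
    other axes (e.g. plot-level genotype effects) are not used for hybrid
    prediction.
    """

    name: str
    levels: list
    incidence: np.ndarray
    kinship: KinshipMatrix | None = None
    axis: str = "other"

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=np.intp)
        if self.incidence.min(initial=0) < 0 or self.incidence.max(initial=-1) >= len(self.levels):
            raise ValueError(f"term {self.name!r}: incidence out of level range")
        if self.kinship is not None and len(self.kinship.entities) != len(self.levels):
            raise ValueError(f"term {self.name!r}: kinship does not cover the levels")

    def gram(self) -> np.ndarray:
        """Observation-level covariance structure Z K Z'."""
        if self.kinship is None:
            return (self.incidence[:, None] == self.incidence[None, :]).astype(float)
        return self.kinship.values[np.ix_(self.incidence, self.incidence)]

    def restrict(self, rows: np.ndarray) -> "RandomTerm":
        """Same term over a subset of observations (levels unchanged)."""
        return RandomTerm(
            name=self.name,
            levels=self.levels,
            incidence=self.incidence[rows],
            kinship=self.kinship,
            axis=self.axis,
        )


@dataclass
class ModelFit:
    """REML estimates, BLUPs over all kernel levels, and diagnostics."""

    beta: np.ndarray
    var_components: dict[str, float]
    resid_variance: float
    boundary: dict[str, bool]
    blups: dict[str, pd.Series]
    loglik: float
    ai_matrix: pd.DataFrame  # over free (non-boundary) parameters, incl. residual
    converged: bool
    n_iter: int
    terms: list[RandomTerm]
    n_obs: int

    @property
    def intercept(self) -> float:
        return float(self.beta[0])


@dataclass
class VariancePartition:
    """Per-term share of total variance (residual included in the total)."""

    shares: dict[str, float]

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.shares.items()}


def _validate_kernel(K: KinshipMatrix, name: str) -> None:
    if getattr(K, "_validated", False):
        return
    asym = K.max_asymmetry()
    if asym > 1e-10 * max(1.0, float(np.abs(K.values).max())):
        raise ValueError(f"kernel for term {name!r} is not symmetric (max asymmetry {asym:.2e})")
    ev = np.linalg.eigvalsh(K.values)
    if ev[0] < -1e-8 * max(ev[-1], 1.0):
        raise ValueError(f"kernel for term {name!r} is not PSD (min eigenvalue {ev[0]:.2e})")
    K._validated = True


def _reml_state(theta: np.ndarray, grams: list[np.ndarray], X: np.ndarray, y: np.ndarray):
    """Likelihood, gradient, AI matrix and projections at a variance point."""
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], grams):
        V += t * G
    c, low = cho_factor(V, lower=True, check_finite=False)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = cho_solve((c, low), np.eye(n), check_finite=False)
    U = Vinv @ X
    XtVX = X.T @ U
    sign, logdet_x = np.linalg.slogdet(XtVX)
    XtVX_inv = np.linalg.pinv(XtVX)
    P = Vinv - U @ XtVX_inv @ U.T
    Py = P @ y
    quad = float(y @ Py)
    ll = -0.5 * (logdet_v + logdet_x + quad)
    k = len(grams)
    grad = np.empty(k + 1)
    vks = []
    for j, G in enumerate(grams):
        vk = G @ Py
        vks.append(vk)
        grad[j] = -0.5 * (float(np.sum(P * G)) - float(Py @ vk))
    vks.append(Py)  # residual: G = I
    grad[k] = -0.5 * (float(np.trace(P)) - float(Py @ Py))
    AI = np.empty((k + 1, k + 1))
    Pv = [P @ v for v in vks]
    for a in range(k + 1):
        for b in range(a, k + 1):
            AI[a, b] = AI[b, a] = 0.5 * float(vks[a] @ Pv[b])
    return ll, grad, AI, Py, XtVX_inv, U


def reml_fit(
    y: np.ndarray,
    terms: Sequence[RandomTerm],
    X: np.ndarray | None = None,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_sigma: float = 1e-6,
    validate_kernels: bool = True,
) -> ModelFit:
    """Estimate variance components by AI-REML and return BLUPs of all terms.

    ``X`` is the fixed-effect design (default: intercept only, as in the
    per-environment hybrid models).  Components driven to the non-negativity
    floor (1e-10 x phenotypic variance) are reported as exactly 0 with a
    boundary flag, and excluded from the average-information matrix.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    terms = list(terms)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.shape[0] != n:
        raise ValueError("fixed design rows must match y")
    p = np.linalg.matrix_rank(X)
    if n < p + 2:
        raise ValueError(f"too few observations (n={n}) for {p} fixed parameters")
    for t in terms:
        if len(t.incidence) != n:
            raise ValueError(f"term {t.name!r}: incidence length != n")
        if t.kinship is not None and validate_kernels:
            _validate_kernel(t.kinship, t.name)
    vary = float(np.var(y))
    if vary == 0.0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-10 * vary
    grams = [t.gram() for t in terms]
    k = len(terms)

    theta = np.full(k + 1, vary / (k + 1))
    ll, grad, AI, Py, XtVX_inv, U = _reml_state(theta, grams, X, y)
    trace: list[dict] = [{"iter": 0, "loglik": ll, "theta": theta.copy()}]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pinned = (theta <= floor * 1.0001) & (grad < 0)
        free = ~pinned

        def _try(step_dir: np.ndarray):
            """Step-halving line search along step_dir on the free coordinates."""
            step = 1.0
            for _ in range(30):
                cand = theta.copy()
                cand[free] = np.maximum(theta[free] + step * step_dir[free], floor)
                if not np.array_equal(cand, theta):
                    out = _reml_state(cand, grams, X, y)
                    if out[0] >= ll - 1e-12:
                        return cand, out
                step *= 0.5
            return None

        result = None
        if it == 1:
            # EM-like damped first step: robust far from the optimum
            em_dir = np.zeros(k + 1)
            em_dir[free] = (theta[free] ** 2) * (2.0 * grad[free]) / n
            result = _try(em_dir)
        if result is None:
            try:
                delta = np.zeros(k + 1)
                delta[free] = np.linalg.solve(AI[np.ix_(free, free)], grad[free])
                result = _try(delta)
            except np.linalg.LinAlgError:
                result = None
        if result is None:
            # gradient fallback, scaled to the phenotypic variance
            gdir = grad * (vary / max(1.0, float(np.abs(grad).max())))
            result = _try(gdir)
        if result is None:
            break  # no uphill step found: at a (possibly boundary) optimum

        new_theta, (new_ll, grad, AI, Py, XtVX_inv, U) = result
        dll = new_ll - ll
        dsig = float(np.max(np.abs(new_theta - theta) / np.maximum(theta, floor)))
        theta, ll = new_theta, new_ll
        trace.append({"iter": it, "loglik": ll, "theta": theta.copy()})
        if dll < tol_loglik and dsig < tol_sigma:
            converged = True
            break
    else:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations (last loglik {ll:.6f})", trace
        )
    if not converged:
        # line search exhausted: treat as converged at a boundary optimum
        converged = True

    beta = XtVX_inv @ (U.T @ y)
    at_floor = theta <= floor * 2.0
    names = [t.name for t in terms] + ["residual"]
    var_components = {}
    boundary = {}
    for j, t in enumerate(terms):
        boundary[t.name] = bool(at_floor[j])
        var_components[t.name] = 0.0 if at_floor[j] else float(theta[j])
    boundary["residual"] = bool(at_floor[k])
    resid = 0.0 if at_floor[k] else float(theta[k])

    blups: dict[str, pd.Series] = {}
    for j, t in enumerate(terms):
        agg = np.bincount(t.incidence, weights=Py, minlength=len(t.levels))
        if t.kinship is None:
            u = theta[j] * agg
        else:
            u = theta[j] * (t.kinship.values @ agg)
        if at_floor[j]:
            u = np.zeros_like(u)
        idx = t.levels
        try:
            series = pd.Series(u, index=pd.Index(idx))
        except TypeError:  # tuple levels
            series = pd.Series(u, index=pd.Index([tuple(x) for x in idx]))
        blups[t.name] = series

    free_names = [nm for nm, j in zip(names, range(k + 1)) if not at_floor[j]]
    free_idx = [j for j in range(k + 1) if not at_floor[j]]
    ai_df = pd.DataFrame(AI[np.ix_(free_idx, free_idx)], index=free_names, columns=free_names)

    return ModelFit(
        beta=beta,
        var_components=var_components,
        resid_variance=resid,
        boundary=boundary,
        blups=blups,
        loglik=float(ll),
        ai_matrix=ai_df,
        converged=converged,
        n_iter=it,
        terms=terms,
        n_obs=n,
    )


def parts_of_variance(fit: ModelFit | dict[str, float]) -> VariancePartition:
    """Share of each variance component in the total (residual included).

    Accepts a ``ModelFit`` or a plain mapping name -> component (useful for
    recomputing published tables); the mapping must include ``residual``.
    """
    if isinstance(fit, ModelFit):
        comps = dict(fit.var_components)
        comps["residual"] = fit.resid_variance
        if not fit.converged:
            raise ValueError("parts of variance require a converged fit")
    else:
        comps = dict(fit)
        if "residual" not in comps:
            raise ValueError("component mapping must include 'residual'")
    total = sum(comps.values())
    if total <= 0:
        raise ValueError("total variance is zero")
    return VariancePartition(shares={k: v / total for k, v in comps.items()})


def zratio(fit: ModelFit, term: str) -> float:
    """sigma2_term / SE(sigma2_term), SE from the inverse average-information matrix.

    Returns NaN (with a warning) for components estimated at the zero
    boundary, where the Wald ratio is undefined.
    """
    if term == "residual":
        est = fit.resid_variance
    else:
        est = fit.var_components[term]
    if fit.boundary[term]:
        warnings.warn(f"component {term!r} is at the zero boundary; z-ratio undefined", stacklevel=2)
        return float("nan")
    cov = np.linalg.inv(fit.ai_matrix.to_numpy())
    i = list(fit.ai_matrix.index).index(term)
    se = float(np.sqrt(cov[i, i]))
    return est / se


def predict_hybrids(fit: ModelFit, crosses: Sequence[tuple[str, str]]) -> np.ndarray:
    """Predicted genetic value mu + sum of term BLUPs for each (female, male) cross.

    Unobserved parents or crosses are predicted through their kernel
    covariance with observed levels (zero for identity kernels).  A parent
    absent from a term's kinship raises ``KeyError``.
    """
    preds = np.full(len(crosses), fit.intercept, dtype=float)
    for t in fit.terms:
        u = fit.blups[t.name]
        if t.axis == "female":
            keys = [f for f, _ in crosses]
        elif t.axis == "male":
            keys = [m for _, m in crosses]
        elif t.axis == "cross":
            keys = [(f, m) for f, m in crosses]
        else:
            continue
        try:
            preds += u.loc[keys].to_numpy()
        except KeyError as exc:
            raise KeyError(f"level missing from term {t.name!r} kinship: {exc}") from None
    return preds


def _incidence(keys: list, levels: list) -> np.ndarray:
    pos = {lv: i for i, lv in enumerate(levels)}
    try:
        return np.array([pos[k] for k in keys], dtype=np.intp)
    except KeyError as exc:
        raise KeyError(f"observation level {exc} missing from kinship entities") from None


def assemble_model(
    kind: Literal["GCA", "FM", "FMI", "FM_oil", "mk_oil", "mk_epi"],
    obs_crosses: Sequence[tuple[str, str]],
    kernels: dict[str, KinshipMatrix],
) -> list[RandomTerm]:
    """Build the random terms of one model family for a set of observations.

    ``kernels`` keys by family:
      GCA    — Kf, Km (entities only; identity covariance is used)
      FM     — Kf, Km
      FMI    — Kf, Km, Kfm (entities = design crosses incl. unobserved)
      FM_oil — Kf_oil, Km_oil
      mk_oil — Kf_oil, Km_oil, Kf_rest, Km_rest
      mk_epi — Kf, Km (epistasis squares derived here unless Kf_epi/Km_epi given)
    """
    obs_crosses = [tuple(c) for c in obs_crosses]
    fkeys = [f for f, _ in obs_crosses]
    mkeys = [m for _, m in obs_crosses]

    def parental(name: str, key: str, axis: str, identity: bool = False) -> RandomTerm:
        K = kernels[key]
        levels = list(K.entities)
        keys = fkeys if axis == "female" else mkeys
        return RandomTerm(
            name=name,
            levels=levels,
            incidence=_incidence(keys, levels),
            kinship=None if identity else K,
            axis=axis,
        )

    if kind == "GCA":
        return [
            parental("gca_female", "Kf", "female", identity=True),
            parental("gca_male", "Km", "male", identity=True),
        ]
    if kind == "FM":
        return [parental("female", "Kf", "female"), parental("male", "Km", "male")]
    if kind == "FMI":
        Kfm = kernels["Kfm"]
        levels = list(Kfm.entities)
        inter = RandomTerm(
            name="interaction",
            levels=levels,
            incidence=_incidence(obs_crosses, levels),
            kinship=Kfm,
            axis="cross",
        )
        return [parental("female", "Kf", "female"), parental("male", "Km", "male"), inter]
    if kind == "FM_oil":
        return [
            parental("female_pathway", "Kf_oil", "female"),
            parental("male_pathway", "Km_oil", "male"),
        ]
    if kind == "mk_oil":
        return [
            parental("female_pathway", "Kf_oil", "female"),
            parental("male_pathway", "Km_oil", "male"),
            parental("female_rest", "Kf_rest", "female"),
            parental("male_rest", "Km_rest", "male"),
        ]
    if kind == "mk_epi":
        kf_epi = kernels.get("Kf_epi") or epistasis_kinship(kernels["Kf"])
        km_epi = kernels.get("Km_epi") or epistasis_kinship(kernels["Km"])
        aug = dict(kernels, Kf_epi=kf_epi, Km_epi=km_epi)
        terms = [parental("female", "Kf", "female"), parental("male", "Km", "male")]
        for name, key, axis in (
            ("female_epistasis", "Kf_epi", "female"),
            ("male_epistasis", "Km_epi", "male"),
        ):
            K = aug[key]
            levels = list(K.entities)
            keys = fkeys if axis == "female" else mkeys
            terms.append(
                RandomTerm(name=name, levels=levels, incidence=_incidence(keys, levels), kinship=K, axis=axis)
            )
        return terms
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
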
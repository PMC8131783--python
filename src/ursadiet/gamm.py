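"""Generalized additive mixed models for seasonal body condition.

The response TH:HTL is strictly positive with roughly constant
coefficient of variation, so it is modelled with a gamma family and log
link. The linear predictor combines

* a thin-plate regression spline of session, optionally one smooth per
  level of a grouping factor (reproductive status or diet-year class);
* fixed effects for reproductive status, diet-year class, and their
  interaction;
* crossed random intercepts for year and bear identity, represented as
  ridge-penalized indicator blocks in the same penalized-likelihood
  framework as the smooths.

Fitting alternates penalized IRLS for the coefficients with restricted
maximum likelihood (REML) on the Gaussian working model for the
smoothing and variance parameters ("performance iteration"). Effective
degrees of freedom are traces of the corresponding blocks of the
influence matrix, and candidate models are ranked by AICc and Akaike
weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .smooth import SmoothBasis, build_tprs_basis, center_block

__all__ = [
    "ModelSpec",
    "DesignBundle",
    "GammFit",
    "ConditionGAMM",
    "build_design",
    "fit_gamm",
    "compute_aicc",
    "akaike_weights",
    "rank_models",
    "predict_curve",
    "smooth_summary",
    "candidate_models",
]

#: Dummy coding of the fixed factors. Reference levels follow the study
#: convention: solitary females, high-consumption (diet 1) years, and
#: non-low (diet 2) years are the baselines, so each estimate reads as
#: the log-scale deficit of the contrasted group.
_FACTOR_DUMMIES = {
    "status": ("status (with young)", lambda d: (d["status"] == "with_young")),
    "diet1": ("diet1 (low consumption)", lambda d: ~d["diet1"].astype(bool)),
    "diet2": ("diet2 (low consumption)", lambda d: d["diet2"].astype(bool)),
}

#: Level labelling for factor-by smooths.
_BY_LEVELS = {
    "status": ("solitary", "with_young",
               lambda d: np.where(d["status"] == "with_young", "with_young", "solitary")),
    "diet1": ("high consumption", "low consumption",
              lambda d: np.where(d["diet1"].astype(bool), "high consumption", "low consumption")),
    "diet2": ("not low", "low consumption",
              lambda d: np.where(d["diet2"].astype(bool), "low consumption", "not low")),
}


class NonPositiveResponseError(ValueError):
    pass


class AiccUndefinedError(ValueError):
    """n <= k_eff + 1: the small-sample correction is undefined."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which factor the session smooth varies by
    (None for a single common smooth) and which fixed terms enter.

    ``fixed`` uses factor names and ``a:b`` for interactions; crossed
    random intercepts for year and bear are always included.
    """

    name: str
    smooth_by: str | None = None
    fixed: tuple = ()

    def __post_init__(self):
        if self.smooth_by is not None and self.smooth_by not in _BY_LEVELS:
            raise ValueError(f"unknown by-factor {self.smooth_by!r}")
        for term in self.fixed:
            parts = term.split(":")
            for p in parts:
                if p not in _FACTOR_DUMMIES:
                    raise ValueError(f"unknown fixed term {term!r}")
        if self.smooth_by is not None and self.smooth_by not in {
            t for term in self.fixed for t in term.split(":")
        }:
            raise ValueError(
                f"by-factor {self.smooth_by!r} must also appear among fixed terms"
            )


def candidate_models() -> list:
    """The 13 candidate specifications compared in the study: every model
    keeps the session smooth and the crossed year/bear random
    intercepts; they differ in the smooth's by-factor and fixed terms."""

    def inter(a, b):
        return (a, b, f"{a}:{b}")

    return [
        ModelSpec("S(Session x Diet1) + RST x Diet1", "diet1", inter("status", "diet1")),
        ModelSpec("S(Session x RST) + RST x Diet2", "status", inter("status", "diet2")),
        ModelSpec("S(Session x RST) + RST x Diet1", "status", inter("status", "diet1")),
        ModelSpec("S(Session x RST) + RST", "status", ("status",)),
        ModelSpec("S(Session) + RST x Diet2", None, inter("status", "diet2")),
        ModelSpec("S(Session) + RST x Diet1", None, inter("status", "diet1")),
        ModelSpec("S(Session x Diet2) + RST x Diet2", "diet2", inter("status", "diet2")),
        ModelSpec("S(Session) + RST", None, ("status",)),
        ModelSpec("S(Session x Diet1) + Diet1", "diet1", ("diet1",)),
        ModelSpec("S(Session) + Diet1", None, ("diet1",)),
        ModelSpec("S(Session)", None, ()),
        ModelSpec("S(Session) + Diet2", None, ("diet2",)),
        ModelSpec("S(Session x Diet2) + Diet2", "diet2", ("diet2",)),
    ]


@dataclass
class _Block:
    name: str
    kind: str  # "fixed" | "smooth" | "random"
    start: int
    stop: int
    penalty: np.ndarray | None = None  # block-local, penalized blocks only
    rank: int = 0
    # smooth-block machinery for prediction
    basis: SmoothBasis | None = None
    Q: np.ndarray | None = None
    level: str | None = None  # by-factor level, if any

    @property
    def width(self) -> int:
        return self.stop - self.start


@dataclass
class DesignBundle:
    """Response, design matrix, and the per-block penalty structure."""

    spec: ModelSpec
    y: np.ndarray
    X: np.ndarray
    blocks: list
    fixed_names: list
    year_levels: list
    bear_levels: list
    k: int

    @property
    def n(self) -> int:
        return self.y.size

    def penalized_blocks(self) -> list:
        return [b for b in self.blocks if b.penalty is not None]

    def total_penalty(self, lambdas: np.ndarray) -> np.ndarray:
        p = self.X.shape[1]
        S = np.zeros((p, p))
        for lam, b in zip(lambdas, self.penalized_blocks()):
            S[b.start:b.stop, b.start:b.stop] += lam * b.penalty
        return S

    def build_matrix(self, data: pd.DataFrame, include_random: bool = False) -> np.ndarray:
        """Design rows for new data; random-intercept columns are zero
        unless the row's level was seen in fitting and
        ``include_random`` is set."""
        n = len(data)
        X = np.zeros((n, self.X.shape[1]))
        session = data["session"].to_numpy(float)
        for b in self.blocks:
            if b.kind == "fixed":
                X[:, b.start:b.stop] = _fixed_matrix(self.spec, data)
            elif b.kind == "smooth":
                rows = np.ones(n, dtype=bool) if b.level is None else (
                    _by_labels(self.spec.smooth_by, data) == b.level
                )
                B = b.basis.design(session[rows]) @ b.Q
                X[np.flatnonzero(rows), b.start:b.stop] = B
            elif b.kind == "random" and include_random:
                levels = self.year_levels if b.name == "year" else self.bear_levels
                index = {lv: i for i, lv in enumerate(levels)}
                col = data["year"] if b.name == "year" else data["bear_id"]
                for i, v in enumerate(col):
                    j = index.get(v)
                    if j is not None:
                        X[i, b.start + j] = 1.0
        return X


def _fixed_matrix(spec: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(data))]
    for term in spec.fixed:
        parts = term.split(":")
        col = np.ones(len(data))
        for p in parts:
            col = col * _FACTOR_DUMMIES[p][1](data).to_numpy(float)
        cols.append(col)
    return np.column_stack(cols)


def _fixed_names(spec: ModelSpec) -> list:
    names = ["intercept"]
    for term in spec.fixed:
        parts = term.split(":")
        names.append(" : ".join(_FACTOR_DUMMIES[p][0] for p in parts))
    return names


def _by_labels(by: str, data: pd.DataFrame) -> np.ndarray:
    return _BY_LEVELS[by][2](data)


def build_design(spec: ModelSpec, observations: pd.DataFrame, k: int = 5) -> DesignBundle:
    """Assemble the penalized design for one candidate model.

    ``observations`` needs columns session, th_htl, status, year,
    bear_id and — when the spec references them — boolean diet1/diet2.
    """
    obs = observations.reset_index(drop=True)
    if obs.empty:
        raise ValueError("no observations")
    y = obs["th_htl"].to_numpy(float)
    session = obs["session"].to_numpy(float)

    blocks: list = []
    parts: list = []
    pos = 0

    F = _fixed_matrix(spec, obs)
    blocks.append(_Block("fixed", "fixed", pos, pos + F.shape[1]))
    parts.append(F)
    pos += F.shape[1]

    basis = build_tprs_basis(session, k=k)
    if spec.smooth_by is None:
        B = basis.design(session)
        Bc, Sc, Q = center_block(B, basis.penalty)
        blocks.append(_Block("s(session)", "smooth", pos, pos + Bc.shape[1],
                             penalty=Sc, rank=int(np.linalg.matrix_rank(Sc)),
                             basis=basis, Q=Q))
        parts.append(Bc)
        pos += Bc.shape[1]
    else:
        labels = _by_labels(spec.smooth_by, obs)
        for level in pd.unique(labels):
            rows = labels == level
            if not rows.any():  # pragma: no cover - unique() only yields present levels
                raise ValueError(f"by-factor level {level!r} has no observations")
            B = np.zeros((len(obs), basis.k))
            B[rows] = basis.design(session[rows])
            Bc, Sc, Q = center_block(B, basis.penalty, rows=rows)
            blocks.append(_Block(f"s(session):{level}", "smooth", pos, pos + Bc.shape[1],
                                 penalty=Sc, rank=int(np.linalg.matrix_rank(Sc)),
                                 basis=basis, Q=Q, level=str(level)))
            parts.append(Bc)
            pos += Bc.shape[1]

    year_levels = sorted(pd.unique(obs["year"]).tolist())
    bear_levels = sorted(pd.unique(obs["bear_id"]).tolist())
    for name, levels, col in (("year", year_levels, obs["year"]),
                              ("bear", bear_levels, obs["bear_id"])):
        Z = np.zeros((len(obs), len(levels)))
        index = {lv: i for i, lv in enumerate(levels)}
        for i, v in enumerate(col):
            Z[i, index[v]] = 1.0
        blocks.append(_Block(name, "random", pos, pos + len(levels),
                             penalty=np.eye(len(levels)), rank=len(levels)))
        parts.append(Z)
        pos += len(levels)

    return DesignBundle(spec=spec, y=y, X=np.column_stack(parts), blocks=blocks,
                        fixed_names=_fixed_names(spec), year_levels=year_levels,
                        bear_levels=bear_levels, k=basis.k)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class GammFit:
    """A converged (or flagged) penalized fit with its accounting."""

    bundle: DesignBundle
    beta: np.ndarray
    cov: np.ndarray  # Bayesian posterior covariance of beta
    lambdas: np.ndarray
    family: str
    edf_by_block: dict
    edf_total: float
    dispersion: float
    working_scale: float
    loglik: float
    n: int
    k_eff: float
    aicc: float
    converged: bool
    n_iter: int
    keff_mode: str

    @property
    def spec(self) -> ModelSpec:
        return self.bundle.spec

    @property
    def random_sd(self) -> dict:
        """Random-intercept standard deviations on the linear-predictor
        scale (working-model variance / ridge penalty)."""
        out = {}
        for lam, b in zip(self.lambdas, self.bundle.penalized_blocks()):
            if b.kind == "random":
                out[b.name] = math.sqrt(max(self.working_scale / lam, 0.0))
        return out

    def fixed_table(self) -> pd.DataFrame:
        """Estimates, SEs, t and p for the parametric terms."""
        b = self.bundle.blocks[0]
        beta = self.beta[b.start:b.stop]
        se = np.sqrt(np.diag(self.cov)[b.start:b.stop])
        t = beta / se
        df = max(self.n - self.edf_total, 1.0)
        p = 2 * stats.t.sf(np.abs(t), df)
        return pd.DataFrame({
            "term": self.bundle.fixed_names,
            "beta": beta, "se": se, "t": t, "p": p,
        })

    def linear_predictor(self, data: pd.DataFrame, include_random: bool = False):
        X = self.bundle.build_matrix(data, include_random=include_random)
        eta = X @ self.beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        return eta, se

    def predict(self, data: pd.DataFrame, include_random: bool = False) -> np.ndarray:
        eta, _ = self.linear_predictor(data, include_random=include_random)
        return np.exp(eta) if self.family == "gamma" else eta


def _reml_score(rho, bundle, z, pdet_const):
    """-2 x restricted log likelihood of the working Gaussian model,
    with the scale profiled out. ``rho`` is log-lambda per penalized
    block."""
    lambdas = np.exp(np.clip(rho, -25.0, 25.0))
    X, n = bundle.X, z.size
    S = bundle.total_penalty(lambdas)
    A = X.T @ X + S
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return 1e10
    beta = np.linalg.solve(A, X.T @ z)
    r = z - X @ beta
    D = float(r @ r + beta @ S @ beta)
    ranks = np.array([b.rank for b in bundle.penalized_blocks()])
    Mp = X.shape[1] - int(ranks.sum())
    if D <= 0 or n - Mp <= 0:
        return 1e10
    phi = D / (n - Mp)
    logdet_A = 2.0 * float(np.log(np.diag(L)).sum())
    logdet_S = float((ranks * np.clip(rho, -25.0, 25.0)).sum()) + pdet_const
    return (n - Mp) * (math.log(2 * math.pi * phi) + 1.0) + logdet_A - logdet_S


def _solve_beta(bundle, z, lambdas):
    S = bundle.total_penalty(lambdas)
    A = bundle.X.T @ bundle.X + S
    beta = np.linalg.solve(A, bundle.X.T @ z)
    return beta, A


def fit_gamm(
    bundle: DesignBundle,
    family: str = "gamma",
    lambda_fixed=None,
    max_iter: int = 200,
    tol: float = 1e-8,
    keff_mode: str = "edf",
) -> GammFit:
    """Fit by penalized IRLS with REML selection of the smoothing and
    random-intercept variance parameters on the working model.

    ``family`` is ``"gamma"`` (log link; the analysis model) or
    ``"gaussian"`` (identity link; the degenerate configuration used for
    closed-form verification). ``lambda_fixed`` pins all penalty
    parameters (a vector over penalized blocks), bypassing REML.
    """
    y = bundle.y
    if family == "gamma":
        if np.any(y <= 0):
            raise NonPositiveResponseError("gamma family needs y > 0")
    elif family != "gaussian":
        raise ValueError(f"unknown family {family!r}")

    pen_blocks = bundle.penalized_blocks()
    pdet_const = 0.0
    for b in pen_blocks:
        w = np.linalg.eigvalsh(b.penalty)
        w = w[w > w.max(initial=1.0) * 1e-10] if b.rank else w[:0]
        pdet_const += float(np.log(w).sum())

    rho = np.zeros(len(pen_blocks))
    fixed = lambda_fixed is not None
    if fixed:
        lambdas = np.asarray(lambda_fixed, dtype=float)
        if lambdas.size != len(pen_blocks):
            raise ValueError(
                f"lambda_fixed needs {len(pen_blocks)} values, got {lambdas.size}"
            )

    if family == "gaussian":
        eta = np.full_like(y, y.mean())
        mu = eta
    else:
        mu = np.clip(y, 1e-8, None)
        eta = np.log(mu)

    converged = False
    score_prev = np.inf
    beta = np.zeros(bundle.X.shape[1])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = y if family == "gaussian" else eta + (y - mu) / mu
        if not fixed:
            res = optimize.minimize(
                _reml_score, rho, args=(bundle, z, pdet_const),
                method="Powell",
                bounds=[(-18.0, 18.0)] * len(pen_blocks),
                options={"xtol": 1e-6, "ftol": 1e-9, "maxiter": 2000},
            )
            rho = np.asarray(res.x, dtype=float)
            lambdas = np.exp(rho)
        beta_new, A = _solve_beta(bundle, z, lambdas)
        eta = bundle.X @ beta_new
        mu = np.exp(np.clip(eta, -30, 30)) if family == "gamma" else eta
        score = _reml_score(np.log(lambdas), bundle, z, pdet_const)
        delta = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta_new)))
        beta = beta_new
        if family == "gaussian" or (
            delta < tol or abs(score - score_prev) < tol * (1 + abs(score))
        ):
            converged = True
            break
        score_prev = score

    # Influence and accounting at the converged working model
    z = y if family == "gaussian" else eta + (y - mu) / mu
    S = bundle.total_penalty(lambdas)
    A = bundle.X.T @ bundle.X + S
    A_inv = np.linalg.inv(A)
    Fmat = A_inv @ (bundle.X.T @ bundle.X)
    dF = np.diag(Fmat)
    edf_by_block = {b.name: float(dF[b.start:b.stop].sum()) for b in bundle.blocks}
    edf_total = float(dF.sum())

    n = bundle.n
    resid_df = max(n - edf_total, 1.0)
    if family == "gamma":
        pearson = (y - mu) / mu
        # floor guards the degenerate constant-response case
        dispersion = max(float(pearson @ pearson) / resid_df, 1e-12)
        shape = 1.0 / dispersion
        loglik = float(stats.gamma.logpdf(y, a=shape, scale=mu / shape).sum())
    else:
        rss = float(((y - mu) ** 2).sum())
        dispersion = rss / resid_df
        sigma2_ml = rss / n
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2_ml) + 1.0)

    r = z - bundle.X @ beta
    ranks = sum(b.rank for b in pen_blocks)
    Mp = bundle.X.shape[1] - ranks
    working_scale = float(r @ r + beta @ S @ beta) / max(n - Mp, 1)
    cov = A_inv * dispersion

    n_fixed = bundle.blocks[0].width
    n_var = sum(1 for b in pen_blocks if b.kind == "random")
    if keff_mode == "edf":
        k_eff = (
            sum(edf_by_block[b.name] for b in bundle.blocks if b.kind in ("fixed", "smooth"))
            + n_var + 1.0
        )
    elif keff_mode == "params":
        k_eff = float(
            n_fixed + sum(b.width for b in bundle.blocks if b.kind == "smooth")
            + n_var + 1.0
        )
    else:
        raise ValueError(f"unknown keff_mode {keff_mode!r}")

    aicc = compute_aicc(loglik, k_eff, n)
    return GammFit(
        bundle=bundle, beta=beta, cov=cov, lambdas=np.asarray(lambdas, float),
        family=family, edf_by_block=edf_by_block, edf_total=edf_total,
        dispersion=dispersion, working_scale=working_scale, loglik=loglik,
        n=n, k_eff=float(k_eff), aicc=aicc, converged=converged, n_iter=n_iter,
        keff_mode=keff_mode,
    )


def compute_aicc(loglik: float, k_eff: float, n: int) -> float:
    """AICc = -2l + 2k + 2k(k+1)/(n - k - 1)."""
    if n <= k_eff + 1:
        raise AiccUndefinedError(f"n = {n} <= k_eff + 1 = {k_eff + 1:.1f}")
    return -2.0 * loglik + 2.0 * k_eff + 2.0 * k_eff * (k_eff + 1.0) / (n - k_eff - 1.0)


def akaike_weights(deltas) -> np.ndarray:
    """Akaike weights from Delta-AICc values: exp(-d/2), normalized."""
    d = np.asarray(deltas, dtype=float)
    w = np.exp(-d / 2.0)
    return w / w.sum()


def rank_models(fits) -> pd.DataFrame:
    """Selection table: model, AICc, Delta, weight, sorted by AICc.

    ``fits`` may be GammFit objects or (name, aicc) pairs.
    """
    rows = []
    for f in fits:
        if isinstance(f, GammFit):
            rows.append((f.spec.name, f.aicc, f.edf_total, f.converged))
        else:
            name, aicc = f
            rows.append((name, float(aicc), np.nan, True))
    if not rows:
        raise ValueError("no fits to rank")
    frame = pd.DataFrame(rows, columns=["model", "aicc", "edf", "converged"])
    frame = frame.sort_values("aicc", kind="mergesort").reset_index(drop=True)
    frame["delta"] = frame["aicc"] - frame["aicc"].iloc[0]
    frame["weight"] = akaike_weights(frame["delta"])
    return frame[["model", "aicc", "delta", "weight", "edf", "converged"]]


def predict_curve(fit: GammFit, sessions, groups: dict | None = None) -> pd.DataFrame:
    """Population-level prediction curves with pointwise 95% CIs.

    ``groups`` maps a label to the covariate values of that group, e.g.
    ``{"solitary, high": {"status": "solitary", "diet1": True, "diet2": False}}``.
    Random intercepts are set to zero. Values outside the fitted session
    range trigger an extrapolation warning, not an error.
    """
    import warnings

    sessions = np.asarray(sessions, dtype=float)
    knots = fit.bundle.blocks[1].basis.knots
    if sessions.min() < knots.min() or sessions.max() > knots.max():
        warnings.warn("prediction grid extends beyond the observed session range",
                      stacklevel=2)
    if groups is None:
        groups = {"all": {"status": "solitary", "diet1": True, "diet2": False}}
    rows = []
    for label, cov in groups.items():
        data = pd.DataFrame({"session": sessions})
        data["status"] = cov.get("status", "solitary")
        data["diet1"] = cov.get("diet1", True)
        data["diet2"] = cov.get("diet2", False)
        data["year"] = -1
        data["bear_id"] = ""
        eta, se = fit.linear_predictor(data)
        lo, hi = eta - 1.96 * se, eta + 1.96 * se
        if fit.family == "gamma":
            mean, lo, hi = np.exp(eta), np.exp(lo), np.exp(hi)
        else:
            mean = eta
        for s, m, l, h in zip(sessions, mean, lo, hi):
            rows.append({"group": label, "session": s, "mean": m, "lo95": l, "hi95": h})
    return pd.DataFrame(rows)


def smooth_summary(fit: GammFit) -> pd.DataFrame:
    """Per-smooth edf with Wald-type F and p (approximate: the reference
    distribution ignores smoothing-parameter uncertainty)."""
    rows = []
    df2 = max(fit.n - fit.edf_total, 1.0)
    for b in fit.bundle.blocks:
        if b.kind != "smooth":
            continue
        beta = fit.beta[b.start:b.stop]
        V = fit.cov[b.start:b.stop, b.start:b.stop]
        edf = fit.edf_by_block[b.name]
        stat = float(beta @ np.linalg.pinv(V, rcond=1e-10) @ beta)
        df1 = max(edf, 1e-6)
        Fval = stat / df1
        p = float(stats.f.sf(Fval, df1, df2))
        rows.append({"term": b.name, "edf": edf, "F": Fval, "p": p})
    return pd.DataFrame(rows, columns=["term", "edf", "F", "p"])


# ---------------------------------------------------------------------------
# scikit-learn style estimator


class ConditionGAMM:
    """Gamma/log-link GAMM of TH:HTL on session with crossed random
    intercepts, as a scikit-learn style estimator.

    Parameters
    ----------
    smooth_by : None or one of "status", "diet1", "diet2" — fit one
        session smooth per level of that factor.
    fixed : fixed-effect terms (factor names, ``a:b`` for interactions).
    k : basis dimension per smooth (capped at the number of distinct
        sessions).
    family : "gamma" (default) or "gaussian".
    keff_mode : effective-parameter accounting for AICc — "edf"
        (fixed + smooth edf + one per variance parameter + dispersion)
        or "params" (raw column counts).
    lambda_fixed : optional vector pinning all penalty parameters.

    After ``fit``, the fitted :class:`GammFit` is available as
    ``result_`` and its headline numbers as ``aicc_``, ``edf_``,
    ``coef_`` etc.
    """

    def __init__(self, smooth_by=None, fixed=("status",), k=5, family="gamma",
                 keff_mode="edf", max_iter=200, tol=1e-8, lambda_fixed=None):
        self.smooth_by = smooth_by
        self.fixed = fixed
        self.k = k
        self.family = family
        self.keff_mode = keff_mode
        self.max_iter = max_iter
        self.tol = tol
        self.lambda_fixed = lambda_fixed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "smooth_by": self.smooth_by, "fixed": self.fixed, "k": self.k,
            "family": self.family, "keff_mode": self.keff_mode,
            "max_iter": self.max_iter, "tol": self.tol,
            "lambda_fixed": self.lambda_fixed,
        }

    def set_params(self, **params) -> "ConditionGAMM":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "ConditionGAMM":
        """Fit to an observation table (columns session, status, year,
        bear_id, diet1/diet2 as needed). ``y`` defaults to the table's
        ``th_htl`` column."""
        X = X.copy()
        if y is not None:
            X["th_htl"] = np.asarray(y, dtype=float)
        spec = ModelSpec(name=self._spec_name(), smooth_by=self.smooth_by,
                         fixed=tuple(self.fixed))
        bundle = build_design(spec, X, k=self.k)
        self.result_ = fit_gamm(
            bundle, family=self.family, lambda_fixed=self.lambda_fixed,
            max_iter=self.max_iter, tol=self.tol, keff_mode=self.keff_mode,
        )
        self.coef_ = self.result_.beta
        self.aicc_ = self.result_.aicc
        self.edf_ = self.result_.edf_total
        self.dispersion_ = self.result_.dispersion
        self.converged_ = self.result_.converged
        return self

    def _spec_name(self) -> str:
        smooth = "S(Session)" if self.smooth_by is None else f"S(Session x {self.smooth_by})"
        terms = " + ".join([smooth, *self.fixed, "R(Year)", "R(ID)"])
        return terms

    def predict(self, X: pd.DataFrame, include_random: bool = False) -> np.ndarray:
        """Response-scale predictions (population level by default)."""
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted")
        return self.result_.predict(X, include_random=include_random)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Negative mean squared error on the response scale (so that
        larger is better, per sklearn convention)."""
        target = X["th_htl"].to_numpy(float) if y is None else np.asarray(y, float)
        return -float(np.mean((self.predict(X) - target) ** 2))
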
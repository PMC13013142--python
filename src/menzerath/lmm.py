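"""Linear mixed models for call-duration compression.

The duration model regresses log call duration on log sequence size and
ordinal position, with crossed Gaussian random intercepts for sequence,
individual, and position-as-category:

    log(d_ijk) = b0 + b1 log(n_j) + b2 pos_i + u_j + v_k + w_l + eps_ijk

A negative b1 is the Menzerath compression slope; b2 captures systematic
drift along the sequence.  Position deliberately enters twice: as a
numeric fixed effect and as a categorical random intercept absorbing
idiosyncratic position associations.

Natural logarithms are used for both the response and sequence size.

Estimation is REML by default (ML available).  Because the sequence
factor has thousands of levels and the model is refit hundreds of times
by the Monte-Carlo null models, the solver works on the sparse Henderson
mixed-model equations: the profiled (RE)ML criterion is evaluated from
one sparse LU factorization per candidate variance-ratio vector and
minimized with L-BFGS-B over the square roots of the ratios (so zero
variances sit on the search boundary, not at -inf).

Degrees of freedom for t/p use the residual approximation (n - p), and
the result records that choice; inference should key on the coefficients
and their SEs rather than exact p digits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy import optimize, stats

from .data_io import CallTable, filter_table

logger = logging.getLogger(__name__)

_DEGENERATE_RSS = 1e-12  # relative RSS below which the model is treated as noise-free


@dataclass(frozen=True)
class RandomTerm:
    """One variance component: an indicator design, optionally scaled.

    ``codes`` are 0-based level codes per observation; ``values`` (if
    given) multiply the indicator, turning the intercept into a random
    slope on that covariate.
    """

    name: str
    codes: np.ndarray
    n_levels: int
    values: np.ndarray | None = None


@dataclass(frozen=True)
class LmmSpec:
    """What to fit: estimation method and singleton handling."""

    include_singles: bool = True
    reml: bool = True

    @property
    def method(self) -> str:
        return "REML" if self.reml else "ML"


@dataclass
class FixedEffect:
    name: str
    estimate: float
    se: float
    t: float
    p: float


@dataclass
class LmmResult:
    """Fitted fixed effects, variance components and bookkeeping."""

    fixed_effects: dict[str, FixedEffect]
    variance_components: dict[str, float]
    residual_var: float
    n_obs: int
    n_sequences: int
    n_individuals: int
    method: str
    df_method: str
    df_resid: int
    loglik: float
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return self.fixed_effects[name].estimate

    def se(self, name: str) -> float:
        return self.fixed_effects[name].se

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        fe = self.fixed_effects[name]
        half = stats.t.ppf(0.5 + level / 2, self.df_resid) * fe.se
        return fe.estimate - half, fe.estimate + half

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {
                k: {"estimate": fe.estimate, "se": fe.se, "t": fe.t, "p": fe.p}
                for k, fe in self.fixed_effects.items()
            },
            "variance_components": dict(self.variance_components),
            "residual_var": self.residual_var,
            "n_obs": self.n_obs,
            "n_sequences": self.n_sequences,
            "n_individuals": self.n_individuals,
            "method": self.method,
            "df_method": self.df_method,
            "df_resid": self.df_resid,
            "loglik": self.loglik,
            "converged": self.converged,
            "warnings": list(self.warnings),
        }


# -- core solver -----------------------------------------------------------


def _build_z(terms: list[RandomTerm], n: int) -> tuple[sp.csc_matrix, list[slice]]:
    blocks, slices, start = [], [], 0
    for t in terms:
        vals = np.ones(n) if t.values is None else np.asarray(t.values, dtype=float)
        z = sp.csc_matrix((vals, (np.arange(n), t.codes)), shape=(n, t.n_levels))
        blocks.append(z)
        slices.append(slice(start, start + t.n_levels))
        start += t.n_levels
    return sp.hstack(blocks, format="csc"), slices


def _logdet_from_splu(lu) -> float:
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


class _CrossedLmm:
    """Profiled (RE)ML criterion for a crossed variance-component model."""

    def __init__(self, y: np.ndarray, X: np.ndarray, terms: list[RandomTerm], reml: bool):
        self.y, self.X, self.terms, self.reml = y, X, terms, reml
        self.n, self.p = X.shape
        self.Z, self.slices = _build_z(terms, self.n)
        self.q = self.Z.shape[1]
        self.ZtZ = (self.Z.T @ self.Z).tocsc()
        self.ZtX = np.asarray(self.Z.T @ X)
        self.Zty = np.asarray(self.Z.T @ y).ravel()
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-column scale index: which term each Z column belongs to
        self.col_term = np.empty(self.q, dtype=np.intp)
        for m, sl in enumerate(self.slices):
            self.col_term[sl] = m

    def _assemble(self, s: np.ndarray):
        d = s[self.col_term]
        D = sp.diags(d)
        A = (D @ self.ZtZ @ D + sp.eye(self.q)).tocsc()
        B = d[:, None] * self.ZtX
        M = sp.bmat([[A, sp.csc_matrix(B)], [sp.csc_matrix(B.T), sp.csc_matrix(self.XtX)]], format="csc")
        rhs = np.concatenate([d * self.Zty, self.Xty])
        return d, A, M, rhs

    def criterion(self, s: np.ndarray) -> float:
        _, A, M, rhs = self._assemble(s)
        try:
            lu = splu(M)
        except RuntimeError:
            return np.inf
        sol = lu.solve(rhs)
        r2 = max(self.yty - rhs @ sol, 1e-300)
        if self.reml:
            return _logdet_from_splu(lu) + (self.n - self.p) * np.log(r2)
        lua = splu(A)
        return _logdet_from_splu(lua) + self.n * np.log(r2)

    def solve_at(self, s: np.ndarray) -> dict:
        d, A, M, rhs = self._assemble(s)
        lu = splu(M)
        sol = lu.solve(rhs)
        r2 = max(self.yty - rhs @ sol, 0.0)
        beta = sol[self.q :]
        lua = splu(A)
        # X' V0^-1 X via the Schur complement of the MME matrix
        B = d[:, None] * self.ZtX
        xvx = self.XtX - B.T @ lua.solve(B)
        df = self.n - self.p
        sigma2 = (r2 / df) if self.reml else (r2 / self.n)
        cov_beta = sigma2 * np.linalg.inv(xvx)
        logdet_a = _logdet_from_splu(lua)
        if self.reml:
            logdet_xvx = _logdet_from_splu(lu) - logdet_a
            m2ll = logdet_a + logdet_xvx + df * (1 + np.log(2 * np.pi * max(sigma2, 1e-300)))
        else:
            m2ll = logdet_a + self.n * (1 + np.log(2 * np.pi * max(sigma2, 1e-300)))
        return {
            "beta": beta,
            "cov_beta": cov_beta,
            "sigma2": sigma2,
            "theta": s**2,
            "loglik": -0.5 * m2ll,
            "blups": d * sol[: self.q],
        }


def fit_lmm_core(
    y: np.ndarray,
    X: np.ndarray,
    fe_names: list[str],
    terms: list[RandomTerm],
    reml: bool = True,
    theta0: np.ndarray | None = None,
) -> tuple[dict, list[str], list[RandomTerm], bool]:
    """Fit y = X beta + sum_m Z_m b_m + eps by profiled (RE)ML.

    Returns (solution dict, warnings, kept terms, converged flag).
    The solution's ``theta`` are variance ratios sigma_m^2 / sigma_eps^2.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    warns: list[str] = []

    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"fixed-effect design is rank deficient (columns {fe_names})")

    kept = []
    for t in terms:
        if t.n_levels < 2:
            warns.append(f"random term {t.name!r} has a single level; dropped (variance inestimable)")
            logger.warning(warns[-1])
        else:
            kept.append(t)

    # noise-free short-circuit: exact OLS solution, all variance components zero
    beta_ols, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta_ols) ** 2).sum())
    if rss <= _DEGENERATE_RSS * max(1.0, float(y @ y)):
        sigma2 = rss / max(n - p, 1)
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        sol = {
            "beta": beta_ols,
            "cov_beta": cov,
            "sigma2": sigma2,
            "theta": np.zeros(len(kept)),
            "loglik": np.inf,
            "blups": np.zeros(sum(t.n_levels for t in kept)),
        }
        warns.append("response is an exact linear function of the fixed effects; variance components set to 0")
        return sol, warns, kept, True

    if not kept:
        # plain OLS fallback
        sigma2 = rss / (n - p)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        sol = {"beta": beta_ols, "cov_beta": cov, "sigma2": sigma2, "theta": np.zeros(0),
               "loglik": np.nan, "blups": np.zeros(0)}
        return sol, warns, kept, True

    model = _CrossedLmm(y, X, kept, reml)
    m = len(kept)
    bounds = [(0.0, 100.0)] * m
    # criterion is evaluated through a sparse LU factorization, so the
    # finite-difference step must sit well above factorization noise
    lbfgs_opts = {"maxiter": 500, "ftol": 1e-10, "gtol": 1e-6, "eps": 1e-5}

    starts = [np.full(m, 0.3)]
    if theta0 is not None:
        s0 = np.clip(np.sqrt(np.asarray(theta0, dtype=float)), 0.0, 50.0)
        if s0.shape == (m,):
            starts.insert(0, s0)
    best = None
    for s0 in starts:
        res = optimize.minimize(model.criterion, s0, method="L-BFGS-B",
                                bounds=bounds, options=lbfgs_opts)
        if best is None or res.fun < best.fun:
            best = res
    if theta0 is None or not best.success:
        # derivative-free polish: guards against the gradient path stalling
        # on the flat ridge near the boundary or aborting its line search
        res = optimize.minimize(model.criterion, best.x, method="Powell", bounds=bounds,
                                options={"maxiter": 2000, "xtol": 1e-4, "ftol": 1e-9})
        if res.fun <= best.fun:
            best = res
    converged = bool(best.success)
    if not converged:
        warns.append(f"variance-ratio optimizer did not report convergence: {best.message}")
        logger.warning(warns[-1])
    sol = model.solve_at(best.x)
    return sol, warns, kept, converged


def _result_from_solution(sol, warns, kept, converged, fe_names, reml,
                          n_obs, n_sequences, n_individuals) -> LmmResult:
    beta, cov = sol["beta"], sol["cov_beta"]
    df = n_obs - len(fe_names)
    fes = {}
    for i, name in enumerate(fe_names):
        se = float(np.sqrt(max(cov[i, i], 0.0)))
        t = float(beta[i] / se) if se > 0 else np.inf * np.sign(beta[i]) if beta[i] else 0.0
        p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        fes[name] = FixedEffect(name, float(beta[i]), se, t, p)
    vcs = {t.name: float(th * sol["sigma2"]) for t, th in zip(kept, sol["theta"])}
    return LmmResult(
        fixed_effects=fes,
        variance_components=vcs,
        residual_var=float(sol["sigma2"]),
        n_obs=n_obs,
        n_sequences=n_sequences,
        n_individuals=n_individuals,
        method="REML" if reml else "ML",
        df_method="residual",
        df_resid=df,
        loglik=float(sol["loglik"]),
        converged=converged,
        warnings=warns,
    )


# -- model-facing wrappers -------------------------------------------------


def _duration_design(df: pd.DataFrame):
    y = np.log(df["duration_s"].to_numpy())
    logn = np.log(df["seq_size"].to_numpy(dtype=float))
    pos = df["position"].to_numpy(dtype=float)
    return y, logn, pos


def _duration_terms(df: pd.DataFrame) -> list[RandomTerm]:
    seq_codes, seq_lvls = pd.factorize(df["sequence_id"], sort=False)
    ind_codes, ind_lvls = pd.factorize(df["individual_id"], sort=False)
    pos_codes, pos_lvls = pd.factorize(df["position"], sort=False)
    return [
        RandomTerm("sequence", seq_codes, len(seq_lvls)),
        RandomTerm("individual", ind_codes, len(ind_lvls)),
        RandomTerm("position_cat", pos_codes, len(pos_lvls)),
    ]


def fit_menzerath(
    table: CallTable,
    spec: LmmSpec | None = None,
    theta0: np.ndarray | None = None,
) -> LmmResult:
    """Fit the duration model on one call table.

    Reports ``log_seq_size`` (the compression slope) and ``position``
    coefficients with SE/t/p, plus variance components for the sequence,
    individual and position-category intercepts.  With
    ``spec.include_singles=False``, single-call sequences are removed
    before fitting.
    """
    spec = spec or LmmSpec()
    if not spec.include_singles:
        table = filter_table(table, exclude_singles=True)
    df = table.with_sizes()
    if df["seq_size"].nunique() < 2:
        raise ValueError("need at least 2 distinct sequence sizes to estimate the size slope")
    y, logn, pos = _duration_design(df)
    X = np.column_stack([np.ones(len(df)), logn, pos])
    fe_names = ["intercept", "log_seq_size", "position"]
    sol, warns, kept, conv = fit_lmm_core(y, X, fe_names, _duration_terms(df), spec.reml, theta0)
    return _result_from_solution(sol, warns, kept, conv, fe_names, spec.reml,
                                 len(df), df["sequence_id"].nunique(), df["individual_id"].nunique())


def fit_group_interaction(
    table_a: CallTable,
    table_b: CallTable,
    group_name: str = "group",
    spec: LmmSpec | None = None,
) -> LmmResult:
    """Pooled duration fit with a two-level group factor and interactions.

    The group labels are the tables' contexts (each table must carry a
    single context, and the two labels must differ).  ``table_a`` is coded
    0 and ``table_b`` 1, so the interaction coefficients are the b-to-a
    differences in the size and position slopes.  Sequence and individual
    identifiers are namespaced by group so the two tables never share
    random-effect levels.
    """
    spec = spec or LmmSpec()
    labels = []
    for t in (table_a, table_b):
        ctx = t.df["context"].unique()
        if len(ctx) != 1:
            raise ValueError("each table passed to fit_group_interaction must have a single context")
        labels.append(str(ctx[0]))
    if labels[0] == labels[1]:
        raise ValueError(f"group labels must be distinct, both are {labels[0]!r}")

    frames = []
    for g, t in enumerate((table_a, table_b)):
        sub = t.df.copy()
        sub["sequence_id"] = labels[g] + "::" + sub["sequence_id"]
        sub["individual_id"] = labels[g] + "::" + sub["individual_id"]
        sub["_group"] = float(g)
        frames.append(sub)
    pooled = CallTable(pd.concat(frames, ignore_index=True).drop(columns="_group"))
    if not spec.include_singles:
        pooled = filter_table(pooled, exclude_singles=True)
    df = pooled.with_sizes()
    g = np.where(df["context"] == labels[1], 1.0, 0.0)

    y, logn, pos = _duration_design(df)
    X = np.column_stack([np.ones(len(df)), g, logn, pos, g * logn, g * pos])
    fe_names = [
        "intercept", group_name, "log_seq_size", "position",
        f"{group_name}:log_seq_size", f"{group_name}:position",
    ]
    sol, warns, kept, conv = fit_lmm_core(y, X, fe_names, _duration_terms(df), spec.reml)
    return _result_from_solution(sol, warns, kept, conv, fe_names, spec.reml,
                                 len(df), df["sequence_id"].nunique(), df["individual_id"].nunique())


def fit_accuracy_model(trials: pd.DataFrame, reml: bool = True) -> LmmResult:
    """Fit the cued-number accuracy model on a trial table.

    Accuracy (proportion correct per participant per cue number, on the
    0-1 scale) is regressed on cue number with per-participant random
    intercepts and random slopes (uncorrelated).  Participants with fewer
    than two distinct cue numbers are dropped with a warning.
    """
    required = {"participant_id", "cue_number", "correct"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    acc = (
        trials.groupby(["participant_id", "cue_number"], sort=True)["correct"]
        .mean()
        .reset_index(name="accuracy")
    )
    warns_pre: list[str] = []
    n_cues = acc.groupby("participant_id")["cue_number"].nunique()
    bad = n_cues.index[n_cues < 2].tolist()
    if bad:
        warns_pre.append(f"participants with a single cue level dropped: {bad}")
        logger.warning(warns_pre[-1])
        acc = acc[~acc["participant_id"].isin(bad)]
    if acc.empty:
        raise ValueError("no participants with >= 2 cue levels")

    y = acc["accuracy"].to_numpy(dtype=float)
    cue = acc["cue_number"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(acc)), cue])
    codes, lvls = pd.factorize(acc["participant_id"], sort=False)
    terms = [
        RandomTerm("participant", codes, len(lvls)),
        RandomTerm("participant_slope", codes, len(lvls), values=cue),
    ]
    fe_names = ["intercept", "cue_number"]
    sol, warns, kept, conv = fit_lmm_core(y, X, fe_names, terms, reml)
    res = _result_from_solution(sol, warns_pre + warns, kept, conv, fe_names, reml,
                                len(acc), len(acc), len(lvls))
    return res
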
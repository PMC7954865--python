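"""Closed-population capture-recapture estimation of active clone numbers.

Longitudinal detection of an integration site across sampling timepoints is
treated as a mark-recapture experiment on a closed population of clones:
each timepoint is a capture occasion, and a clone's 0/1 detection pattern
across the t occasions is its capture history omega.  Fitting a Poisson
log-linear model to the counts of the 2^t - 1 observable histories yields
the expected count of the unobserved history (0,...,0) as exp(beta0), so
the total population estimate is

    N_hat = n_obs + exp(beta0_hat)

Four model structures are supported:

- ``M0``   : constant capture probability; log mu_omega = b0 + b1 k(omega)
- ``Mt``   : occasion-specific probabilities; log mu = b0 + sum_j b_j omega_j
- ``Mh_Chao``  : heterogeneous probabilities, Chao lower bound;
  log mu = b0 + b1 k + eta_k (k >= 3), eta_k >= 0
- ``Mth_Chao`` : time + heterogeneity; occasion effects plus the
  constrained eta_k terms

The non-negativity constraint on the eta terms is what makes the Chao
variants lower bounds on N under capture heterogeneity.  At t = 2 the Mt
model reproduces the Lincoln-Petersen estimator exactly, and at t = 3 the
unconstrained-eta Mh_Chao fit equals the analytic Chao bound
S + ((t-1)/t) * f1^2 / (2 f2).

The standard error of N_hat combines the delta-method variance of
exp(beta0) with the Poisson variance of the unseen cell:
SE^2 = exp(2 b0) Var(b0) + exp(b0).  Model selection follows a
conservative rule: among the fits with the lowest BIC, the smallest N_hat
is reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

from clonotrace.is_io import AbundanceMatrix

MODELS = ("M0", "Mt", "Mh_Chao", "Mth_Chao")


@dataclass
class IncidenceMatrix:
    """Binary IS x timepoint detection matrix M(0,1) for one compartment."""

    df: pd.DataFrame  # index is_key, columns timepoints, values 0/1

    def __post_init__(self):
        if self.df.shape[1] < 2:
            raise ValueError("incidence matrix needs >= 2 capture occasions (timepoints)")
        vals = self.df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")
        if (vals.sum(axis=1) == 0).any():
            raise ValueError("incidence rows must have at least one detection")

    @property
    def t(self) -> int:
        return self.df.shape[1]

    @property
    def n_obs(self) -> int:
        return self.df.shape[0]


def to_incidence(m: AbundanceMatrix, compartment: str, patient: str | None = None) -> IncidenceMatrix:
    """Binarise the abundance matrix over a compartment's timepoints.

    Entry 1 iff the IS has reads > 0 in that compartment at that timepoint
    (pooled over any replicate sample columns).
    """
    sub = m.select(patient=patient, compartment=compartment)
    tps = sorted(set(sub.columns.get_level_values("timepoint_months")))
    if len(tps) < 2:
        raise ValueError(
            f"compartment {compartment!r} has {len(tps)} timepoint(s); capture-recapture needs >= 2"
        )
    det = (sub > 0).T.groupby(level="timepoint_months").any().T
    det = det.loc[det.any(axis=1), tps]
    return IncidenceMatrix(det.astype(int))


@dataclass
class CaptureHistories:
    """Counts n_omega of each nonzero capture history, plus f_k frequencies."""

    t: int
    counts: dict  # history tuple -> count
    n_obs: int = field(init=False)

    def __post_init__(self):
        for omega in self.counts:
            if len(omega) != self.t or sum(omega) == 0:
                raise ValueError(f"invalid history {omega} for t={self.t}")
        self.n_obs = int(sum(self.counts.values()))

    @property
    def f(self) -> np.ndarray:
        """f[k] = number of units captured exactly k times, k = 1..t (index 0 unused)."""
        f = np.zeros(self.t + 1, dtype=int)
        for omega, n in self.counts.items():
            f[sum(omega)] += n
        return f

    def all_histories(self) -> list[tuple]:
        return [h for h in itertools.product((0, 1), repeat=self.t) if sum(h) > 0]

    def count_vector(self) -> np.ndarray:
        return np.array([self.counts.get(h, 0) for h in self.all_histories()], dtype=float)


def capture_histories(x: IncidenceMatrix) -> CaptureHistories:
    """Aggregate an incidence matrix into capture-history counts."""
    counts: dict = {}
    for row in x.df.to_numpy():
        omega = tuple(int(v) for v in row)
        counts[omega] = counts.get(omega, 0) + 1
    return CaptureHistories(t=x.t, counts=counts)


@dataclass
class ClosedPopFit:
    """A fitted closed-population log-linear model."""

    model: str
    t: int
    n_obs: int
    coefficients: np.ndarray
    coef_names: list[str]
    n_hat: float
    se: float
    deviance: float
    df: int
    aic: float
    bic: float
    converged: bool = True
    flag: str = ""

    @property
    def relative_se(self) -> float:
        return self.se / self.n_hat if self.n_hat > 0 else np.nan

    def summary_row(self) -> dict:
        return {
            "model": self.model,
            "n_obs": self.n_obs,
            "N_hat": self.n_hat,
            "SE": self.se,
            "deviance": self.deviance,
            "df": self.df,
            "AIC": self.aic,
            "BIC": self.bic,
            "converged": self.converged,
            "flag": self.flag,
        }


def _design(histories: list[tuple], model: str, t: int) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix, coefficient names, and eta-constraint mask."""
    rows, names = [], []
    k = [sum(h) for h in histories]
    if model == "M0":
        x = np.column_stack([np.ones(len(histories)), k])
        names = ["b0", "b_k"]
    elif model == "Mt":
        x = np.column_stack([np.ones(len(histories))] + [[h[j] for h in histories] for j in range(t)])
        names = ["b0"] + [f"b_t{j + 1}" for j in range(t)]
    elif model == "Mh_Chao":
        cols = [np.ones(len(histories)), k]
        names = ["b0", "b_k"]
        for kk in range(3, t + 1):
            cols.append([1.0 if ki == kk else 0.0 for ki in k])
            names.append(f"eta_{kk}")
        x = np.column_stack(cols)
    elif model == "Mth_Chao":
        cols = [np.ones(len(histories))] + [[h[j] for h in histories] for j in range(t)]
        names = ["b0"] + [f"b_t{j + 1}" for j in range(t)]
        for kk in range(3, t + 1):
            cols.append([1.0 if ki == kk else 0.0 for ki in k])
            names.append(f"eta_{kk}")
        x = np.column_stack(cols)
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    is_eta = np.array([nm.startswith("eta_") for nm in names])
    return np.asarray(x, dtype=float), names, is_eta


def _chao_analytic(t: int, f1: int, f2: int, n_obs: int, bias_corrected: bool = False) -> float:
    """Analytic Chao lower bound on population size from singleton/doubleton counts."""
    if bias_corrected or f2 == 0:
        return n_obs + ((t - 1) / t) * f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return n_obs + ((t - 1) / t) * f1**2 / (2.0 * f2)


def _newton_polish(x: np.ndarray, y: np.ndarray, beta: np.ndarray, is_eta: np.ndarray) -> np.ndarray:
    """Sharpen an L-BFGS-B solution with projected Newton steps.

    Active eta bounds (eta = 0 with outward-pointing gradient) are held
    fixed; remaining coordinates take damped Newton steps on the Poisson
    negative log-likelihood until stationarity.
    """

    def nll(b):
        lin = x @ b
        return float(np.exp(lin).sum() - y @ lin)

    beta = beta.copy()
    for _ in range(100):
        mu = np.exp(x @ beta)
        if not np.isfinite(mu).all():
            break
        g = x.T @ (mu - y)
        fixed = is_eta & (beta <= 1e-10) & (g > 0)
        free = ~fixed
        xf = x[:, free]
        info = xf.T @ (mu[:, None] * xf)
        try:
            step = np.linalg.solve(info, -g[free])
        except np.linalg.LinAlgError:
            break
        base = nll(beta)
        scale, new = 1.0, None
        for _ in range(40):
            cand = beta.copy()
            cand[free] += scale * step
            cand[is_eta] = np.maximum(cand[is_eta], 0.0)
            if np.isfinite(cand).all() and nll(cand) <= base + 1e-12:
                new = cand
                break
            scale *= 0.5
        if new is None:
            break
        delta = float(np.max(np.abs(new - beta)))
        beta = new
        if delta < 1e-13:
            break
    return beta


def fit_closedp(h: CaptureHistories, model: str) -> ClosedPopFit:
    """Fit one closed-population log-linear model to history counts.

    Poisson likelihood over the 2^t - 1 observable history cells; the eta
    heterogeneity coefficients of the Chao models are constrained >= 0 by
    bounded optimisation (active constraints return df to the fit).
    """
    t, n_obs = h.t, h.n_obs
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if model in ("Mh_Chao", "Mth_Chao") and t < 3:
        raise ValueError(f"{model} requires >= 3 capture occasions, got {t}")

    f = h.f
    if model in ("Mh_Chao", "Mth_Chao") and f[2] == 0:
        # log-linear fit diverges (no doubletons); bias-corrected analytic bound
        n_hat = _chao_analytic(t, int(f[1]), 0, n_obs, bias_corrected=True)
        return ClosedPopFit(
            model=model, t=t, n_obs=n_obs, coefficients=np.array([]), coef_names=[],
            n_hat=n_hat, se=np.nan, deviance=np.nan, df=0, aic=np.nan, bic=np.nan,
            converged=True, flag="f2_zero_bias_corrected",
        )

    histories = h.all_histories()
    y = h.count_vector()
    x, names, is_eta = _design(histories, model, t)
    n_cells, n_par = x.shape

    def nll(beta):
        lin = x @ beta
        mu = np.exp(lin)
        return float(mu.sum() - y @ lin)

    def grad(beta):
        mu = np.exp(x @ beta)
        return x.T @ (mu - y)

    beta0_init = np.zeros(n_par)
    beta0_init[0] = np.log(max(n_obs, 1) / n_cells)
    bounds = [(0.0, None) if e else (None, None) for e in is_eta]
    res = optimize.minimize(
        nll, beta0_init, jac=grad, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    beta = _newton_polish(x, y, res.x, is_eta)
    mu = np.exp(x @ beta)
    converged = bool(res.success) and np.isfinite(mu).all()

    # Degenerate saturated-overlap geometries (e.g. t=2 with m=0) push beta to
    # the boundary of the parameter space; detect via exploding estimate.
    unseen = float(np.exp(beta[0]))
    flag = "" if converged else "non_convergence"
    if not np.isfinite(unseen) or unseen > 1e12 * max(n_obs, 1):
        return ClosedPopFit(
            model=model, t=t, n_obs=n_obs, coefficients=beta, coef_names=names,
            n_hat=np.inf, se=np.inf, deviance=np.nan, df=0, aic=np.nan, bic=np.nan,
            converged=False, flag="infinite_estimate",
        )

    active = is_eta & (np.abs(beta) < 1e-9)
    free = ~active
    n_free = int(free.sum())
    # covariance from the observed information of the free parameters
    xf = x[:, free]
    info = xf.T @ (mu[:, None] * xf)
    try:
        cov = np.linalg.inv(info)
        var_b0 = float(cov[0, 0])  # b0 is always free and first
    except np.linalg.LinAlgError:
        var_b0 = np.nan
        converged = False
        flag = "singular_information"

    n_hat = n_obs + unseen
    se = float(np.sqrt(unseen**2 * var_b0 + unseen)) if np.isfinite(var_b0) else np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
    deviance = float(2.0 * dev_terms.sum())
    loglik = float((y * np.log(np.where(mu > 0, mu, 1.0)) - mu - gammaln(y + 1)).sum())
    aic = -2.0 * loglik + 2.0 * n_free
    bic = -2.0 * loglik + n_free * np.log(max(n_obs, 1))

    return ClosedPopFit(
        model=model, t=t, n_obs=n_obs, coefficients=beta, coef_names=names,
        n_hat=n_hat, se=se, deviance=deviance, df=n_cells - n_free,
        aic=aic, bic=bic, converged=converged, flag=flag,
    )


def select_model(fits: list[ClosedPopFit], bic_tol: float = 0.0) -> ClosedPopFit:
    """Pick the most conservative estimate among the lowest-BIC fits.

    Among converged fits whose BIC is within ``bic_tol`` of the minimum,
    the fit with the smallest N_hat is returned (ties in BIC resolved
    toward the lower estimate).
    """
    ok = [f for f in fits if f.converged and np.isfinite(f.n_hat) and np.isfinite(f.bic)]
    if not ok:
        raise ValueError("no converged closed-population fit to select from")
    best_bic = min(f.bic for f in ok)
    band = [f for f in ok if f.bic <= best_bic + bic_tol]
    return min(band, key=lambda f: f.n_hat)


@dataclass
class LtlpEstimate:
    """Per-patient clone-abundance estimation result (or an explicit refusal)."""

    patient: str
    fits: list[ClosedPopFit] = field(default_factory=list)
    selected: ClosedPopFit | None = None
    refused: str | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            row = {"patient": self.patient, **f.summary_row()}
            row["selected"] = f is self.selected
            rows.append(row)
        return pd.DataFrame(rows)


def estimate_ltlp(
    m: AbundanceMatrix,
    compartment: str = "TN",
    models: tuple = MODELS,
    bic_tol: float = 0.0,
) -> dict[str, LtlpEstimate]:
    """Estimate active progenitor clone numbers per patient from recapture.

    Runs the full pipeline incidence -> histories -> model fits ->
    conservative BIC selection on the chosen compartment (naive T cells by
    default).  Patients with fewer than three timepoints are refused with
    a reason rather than estimated: heterogeneity models are not
    identifiable there and two-occasion estimates are not comparable.
    """
    out: dict[str, LtlpEstimate] = {}
    for patient in m.patients():
        tps = m.timepoints(patient=patient, compartment=compartment)
        if len(tps) < 3:
            out[patient] = LtlpEstimate(
                patient=patient,
                refused=f"only {len(tps)} {compartment} timepoint(s); >= 3 required for abundance estimation",
            )
            continue
        inc = to_incidence(m, compartment, patient=patient)
        hist = capture_histories(inc)
        fits = []
        for model in models:
            try:
                fits.append(fit_closedp(hist, model))
            except ValueError:
                continue
        selected = select_model(fits, bic_tol=bic_tol)
        out[patient] = LtlpEstimate(patient=patient, fits=fits, selected=selected)
    return out


def estimates_table(estimates: dict[str, LtlpEstimate]) -> pd.DataFrame:
    """Flat TSV-ready table of all fits across patients (refusals excluded)."""
    frames = [e.summary() for e in estimates.values() if e.fits]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
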
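"""Estimation of two-weekly transition probabilities from visit panels.

The trial evidence behind the model's transition inputs is a panel of
two-weekly study visits. For each history stratum (no prior
incomplete-C5 event / prior event), consecutive visit pairs starting
from the event-free state are classified into three outcomes at the
next visit — no event, incomplete-C5 breakthrough haemolysis (BTH), or
CAC-triggered BTH — and a full-information maximum-likelihood
multinomial logit with intercept and randomized-treatment indicator is
fitted with "no event" as the reference outcome. Mean per-visit
transition probabilities per arm are the softmax-inverted linear
predictors.

Complete separation (a structural zero cell, e.g. no incomplete-C5
events ever observed under ravulizumab) is detected from the outcome
contingency table before optimisation; such fits are flagged as
boundary fits and report the empirical per-arm outcome frequencies,
which are the maximum-likelihood probabilities on the boundary of the
parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .states import Arm

OUTCOMES = ("no_event", "incc5_bth", "cac_bth")
_STATE_TO_OUTCOME = {"no_bth": 0, "incc5_bth": 1, "cac_bth": 2}

PANEL_COLUMNS = ("patient_id", "visit_index", "state_at_visit", "history_flag", "treatment")


@dataclass(frozen=True)
class VisitRecord:
    """One study visit of one patient."""

    patient_id: int
    visit_index: int
    state_at_visit: str  # no_bth | incc5_bth | cac_bth
    history_flag: bool  # prior incomplete-C5 event before this visit
    treatment: str  # eculizumab | ravulizumab


@dataclass
class MultinomialLogitFit:
    """Fitted coefficients (rows: non-reference outcomes; columns:
    intercept, treatment indicator) with fit diagnostics."""

    coef: np.ndarray
    loglik: float
    converged: bool
    boundary: bool
    n_obs: int
    stratum: bool
    #: empirical per-treatment outcome frequencies, used at the boundary
    empirical: dict = field(default_factory=dict)


def panel_to_frame(visits) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of VisitRecord."""
    if isinstance(visits, pd.DataFrame):
        missing = [c for c in PANEL_COLUMNS if c not in visits.columns]
        if missing:
            raise ValueError(f"visit panel misses columns: {missing}")
        return visits
    return pd.DataFrame([vars(v) for v in visits])


def transition_pairs(visits, stratum: bool) -> pd.DataFrame:
    """Consecutive visit pairs whose origin is the event-free state of the
    requested history stratum; returns columns treatment (1 = ravulizumab)
    and outcome (0/1/2)."""
    df = panel_to_frame(visits).sort_values(["patient_id", "visit_index"])
    nxt = df.groupby("patient_id", sort=False).shift(-1)
    ok = (
        nxt["visit_index"].notna()
        & (nxt["visit_index"] == df["visit_index"] + 1)
        & (df["state_at_visit"] == "no_bth")
        & (df["history_flag"] == stratum)
    )
    out = pd.DataFrame({
        "treatment": (df.loc[ok, "treatment"] == Arm.RAVULIZUMAB.value).astype(int),
        "outcome": nxt.loc[ok, "state_at_visit"].map(_STATE_TO_OUTCOME).astype(int),
    })
    return out.reset_index(drop=True)


def _neg_loglik_and_grad(theta: np.ndarray, X: np.ndarray, Y: np.ndarray):
    """NLL of the 3-outcome multinomial logit and its analytic gradient.

    theta is the flattened (2 outcomes x 2 params) coefficient block;
    Y is the n x 3 one-hot outcome matrix."""
    B = theta.reshape(2, 2)
    eta = np.column_stack([np.zeros(len(X)), X @ B.T])
    eta -= eta.max(axis=1, keepdims=True)
    expe = np.exp(eta)
    P = expe / expe.sum(axis=1, keepdims=True)
    nll = -float(np.sum(Y * np.log(np.clip(P, 1e-300, None))))
    G = (P - Y)[:, 1:]  # n x 2
    grad = (G.T @ X).ravel()
    return nll, grad


def fit_transition_multinomial_logit(visits, stratum: bool) -> MultinomialLogitFit:
    """Fit the per-stratum multinomial logit of next-visit outcome on
    intercept + treatment indicator."""
    pairs = transition_pairs(visits, stratum)
    if len(pairs) == 0:
        raise ValueError(f"no transition pairs in history stratum {stratum}")
    treat = pairs["treatment"].to_numpy()
    y = pairs["outcome"].to_numpy()
    X = np.column_stack([np.ones(len(y)), treat])
    Y = np.eye(3)[y]

    empirical = {}
    for t in sorted(np.unique(treat)):
        sub = y[treat == t]
        empirical[int(t)] = np.bincount(sub, minlength=3) / len(sub)

    # separation check on the outcome contingency table
    table = np.zeros((2, 3))
    for t in (0, 1):
        sel = y[treat == t]
        if len(sel):
            table[t] = np.bincount(sel, minlength=3)
    observed_groups = [t for t in (0, 1) if table[t].sum() > 0]
    boundary = any(
        table[t, j] == 0 for t in observed_groups for j in (1, 2)
    ) or len(observed_groups) < 2

    if boundary:
        # MLE lies on the boundary; probabilities are the empirical
        # frequencies, coefficients are reported at a finite pseudo-value
        loglik = 0.0
        for t in observed_groups:
            for j in range(3):
                if table[t, j] > 0:
                    loglik += table[t, j] * np.log(empirical[t][j])
        return MultinomialLogitFit(
            coef=np.full((2, 2), np.nan), loglik=float(loglik), converged=False,
            boundary=True, n_obs=len(y), stratum=stratum, empirical=empirical,
        )

    res = minimize(
        _neg_loglik_and_grad, x0=np.zeros(4), args=(X, Y),
        jac=True, method="L-BFGS-B",
    )
    return MultinomialLogitFit(
        coef=res.x.reshape(2, 2), loglik=-float(res.fun), converged=bool(res.success),
        boundary=False, n_obs=len(y), stratum=stratum, empirical=empirical,
    )


def predict_transition_probs(fit: MultinomialLogitFit, treatment: int) -> np.ndarray:
    """Outcome probability triple (no event, incomplete-C5 BTH, CAC BTH)
    for a treatment indicator (1 = ravulizumab)."""
    if fit.boundary:
        if treatment in fit.empirical:
            return np.asarray(fit.empirical[treatment], dtype=float)
        # unseen arm: fall back to the pooled stratum frequencies
        pooled = np.mean([v for v in fit.empirical.values()], axis=0)
        return np.asarray(pooled, dtype=float)
    x = np.array([1.0, float(treatment)])
    eta = np.concatenate([[0.0], fit.coef @ x])
    eta -= eta.max()
    e = np.exp(eta)
    return e / e.sum()


def fitted_probability_table(visits) -> pd.DataFrame:
    """Fit both history strata and lay the per-arm mean transition
    probabilities out as a table shaped like the model's transition
    inputs (one row per origin stratum and arm)."""
    rows = []
    for stratum in (False, True):
        fit = fit_transition_multinomial_logit(visits, stratum)
        for t, arm in ((0, Arm.ECULIZUMAB.value), (1, Arm.RAVULIZUMAB.value)):
            probs = predict_transition_probs(fit, t)
            rows.append({
                "history_stratum": stratum, "treatment": arm,
                "p_no_event": probs[0], "p_incc5_bth": probs[1],
                "p_cac_bth": probs[2], "boundary_fit": fit.boundary,
                "n_pairs": fit.n_obs,
            })
    return pd.DataFrame(rows)
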
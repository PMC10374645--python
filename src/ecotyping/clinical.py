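"""Survival association of states and ecotypes.

Log-rank is the Mantel–Cox observed-vs-expected tabulation over distinct
event times with the usual hypergeometric variance; the Cox model is a
single-covariate Newton–Raphson maximization of the Breslow partial
likelihood. Both are cross-checked against lifelines in the test suite;
they are written out here because the screening loops need tight control
over tie handling, convergence reporting and refusal conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .containers import InputError, SurvivalData

__all__ = [
    "LogRankResult",
    "CoxResult",
    "log_rank_test",
    "fit_cox",
    "state_survival_screen",
    "therapy_benefit",
    "restricted_mean_survival",
]


@dataclass
class LogRankResult:
    statistic: float
    degrees_of_freedom: int
    p: float


@dataclass
class CoxResult:
    log_hazard_ratio: float
    hazard_ratio: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool
    n_events: int


def _validate_groups(survival: SurvivalData, groups: pd.Series) -> pd.Series:
    groups = pd.Series(groups)
    missing = [s for s in survival.sample_ids if s not in groups.index]
    if missing:
        raise InputError(f"groups missing for samples {missing[:5]}")
    return groups.loc[survival.sample_ids]


def log_rank_test(survival: SurvivalData, groups: pd.Series) -> LogRankResult:
    """Mantel–Cox log-rank test across two or more groups."""
    groups = _validate_groups(survival, groups)
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) < 2:
        raise InputError("log-rank needs >= 2 non-empty groups")
    time = survival.time.to_numpy(dtype=float)
    event = survival.event.to_numpy(dtype=int)
    if event.sum() < 1:
        raise InputError("log-rank needs >= 1 event")
    g = np.array([levels.index(x) for x in groups])
    n_g = len(levels)
    O = np.zeros(n_g)
    E = np.zeros(n_g)
    V = np.zeros((n_g, n_g))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        d = int((event[(time == t)]).sum())
        if n <= 0 or d == 0:
            continue
        n_j = np.array([(at_risk & (g == j)).sum() for j in range(n_g)], dtype=float)
        d_j = np.array(
            [((time == t) & (event == 1) & (g == j)).sum() for j in range(n_g)],
            dtype=float,
        )
        frac = n_j / n
        O += d_j
        E += d * frac
        if n > 1:
            V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    df = n_g - 1
    p = 1.0 if stat == 0 else float(chi2.sf(stat, df))
    return LogRankResult(statistic=stat, degrees_of_freedom=df, p=min(max(p, 0.0), 1.0))


def fit_cox(
    survival: SurvivalData,
    covariate: pd.Series,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Single-covariate Cox proportional hazards fit (Breslow ties).

    Newton–Raphson on the partial log-likelihood; converged when the
    score magnitude drops below ``tol``. Monotone likelihoods (complete
    separation) are flagged as non-converged rather than reported as
    valid estimates.
    """
    covariate = pd.Series(covariate)
    x = covariate.loc[survival.sample_ids].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise InputError("covariate is constant")
    time = survival.time.to_numpy(dtype=float)
    event = survival.event.to_numpy(dtype=int)
    n_events = int(event.sum())
    if n_events == 0:
        raise InputError("no events; Cox model undefined")
    uniq = set(np.unique(x))
    if uniq <= {0.0, 1.0}:
        per_level = min(event[x == 0].sum(), event[x == 1].sum())
        if per_level < 5:
            warnings.warn(
                f"only {int(per_level)} events in the smaller level; "
                "estimate may be unstable",
                stacklevel=2,
            )

    order = np.argsort(-time, kind="stable")  # descending time for cumsums
    t_s, x_s, e_s = time[order], x[order], event[order]

    def score_info(beta):
        w = np.exp(beta * x_s)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x_s)
        s2 = np.cumsum(w * x_s**2)
        # risk set of an event at time t = all with time >= t; with
        # descending sort that is a prefix, located per unique event time
        ll = u = info = 0.0
        i = 0
        n = len(t_s)
        while i < n:
            j = i
            while j < n and t_s[j] == t_s[i]:
                j += 1
            d_idx = [k for k in range(i, j) if e_s[k] == 1]
            if d_idx:
                d = len(d_idx)
                S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
                xbar = S1 / S0
                ll += beta * sum(x_s[k] for k in d_idx) - d * np.log(S0)
                u += sum(x_s[k] for k in d_idx) - d * xbar
                info += d * (S2 / S0 - xbar**2)
            i = j
        return ll, u, info

    beta, converged = 0.0, False
    for _ in range(max_iter):
        _, u, info = score_info(beta)
        if abs(u) < tol:
            converged = True
            break
        if info <= 0 or not np.isfinite(info):
            break
        step = u / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > 15:  # monotone likelihood
            break
    _, u, info = score_info(beta)
    converged = converged and abs(beta) <= 15 and info > 0
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    zval = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2 * norm.sf(abs(zval)))
    ci = norm.ppf(0.975) * se
    return CoxResult(
        log_hazard_ratio=float(beta),
        hazard_ratio=float(np.exp(beta)),
        se=float(se),
        ci_low=float(np.exp(beta - ci)),
        ci_high=float(np.exp(beta + ci)),
        p=p,
        converged=bool(converged),
        n_events=n_events,
    )


def restricted_mean_survival(
    time: np.ndarray, event: np.ndarray, tau: float
) -> float:
    """Restricted mean survival time: area under the KM curve up to tau."""
    from lifelines import KaplanMeierFitter
    from lifelines.utils import restricted_mean_survival_time

    kmf = KaplanMeierFitter().fit(time, event)
    return float(restricted_mean_survival_time(kmf, t=tau))


def state_survival_screen(
    units: pd.Series,
    survival: SurvivalData,
    min_group: int = 10,
    adjust: bool = False,
) -> pd.DataFrame:
    """One-vs-rest survival screen over states or ecotypes.

    For every unit label a binary in/out Cox model and two-group log-rank
    are fit; direction is "adverse" when HR > 1 and "favorable" when
    HR < 1. Raw p < 0.05 flags significance (no multiplicity correction
    by default; Benjamini–Hochberg columns added with ``adjust=True``).
    Undersized or non-comparable units are skipped with a reason.
    """
    units = _validate_groups(survival, units)
    rows = []
    for unit in sorted(pd.unique(units.dropna())):
        ind = (units == unit).astype(float)
        n_in, n_out = int(ind.sum()), int((1 - ind).sum())
        row = {
            "unit": unit, "n_in": n_in, "n_out": n_out,
            "hazard_ratio": np.nan, "cox_p": np.nan, "log_rank_p": np.nan,
            "direction": "", "significant": False, "skipped": "",
        }
        if n_in < min_group:
            row["skipped"] = f"group size {n_in} < {min_group}"
        elif n_out == 0:
            row["skipped"] = "no comparison group"
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cox = fit_cox(survival, ind)
                    lr = log_rank_test(survival, ind)
                row.update(
                    hazard_ratio=cox.hazard_ratio,
                    cox_p=cox.p if cox.converged else np.nan,
                    log_rank_p=lr.p,
                    direction="adverse" if cox.hazard_ratio > 1 else "favorable",
                    significant=bool(cox.converged and cox.p < 0.05),
                )
                if not cox.converged:
                    row["skipped"] = "cox did not converge"
            except InputError as exc:
                row["skipped"] = str(exc)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("unit")
    if adjust and out["cox_p"].notna().any():
        from scipy.stats import false_discovery_control

        mask = out["cox_p"].notna()
        adj = np.full(len(out), np.nan)
        adj[mask.to_numpy()] = false_discovery_control(
            out.loc[mask, "cox_p"].to_numpy(), method="bh"
        )
        out["cox_p_bh"] = adj
    return out


def therapy_benefit(
    units: pd.Series,
    survival: SurvivalData,
    min_arm: int = 2,
) -> pd.DataFrame:
    """Screen units for treatment benefit (responders live longer).

    Within each unit, responders and non-responders are compared by
    log-rank; the unit is flagged as benefiting when p < 0.05 and the
    responder restricted-mean survival (up to the shorter arm maximum)
    exceeds the non-responder one — the directional half of
    "significantly longer".
    """
    if "response" not in survival.table.columns:
        raise InputError("survival data carries no response labels")
    units = _validate_groups(survival, units)
    rows = []
    for unit in sorted(pd.unique(units.dropna())):
        members = units.index[units == unit]
        sub = survival.subset(members)
        resp = sub.table["response"]
        n_r = int((resp == "responder").sum())
        n_nr = int((resp == "non_responder").sum())
        row = {
            "unit": unit, "n_responder": n_r, "n_non_responder": n_nr,
            "log_rank_p": np.nan, "rmst_responder": np.nan,
            "rmst_non_responder": np.nan, "benefit": False, "skipped": "",
        }
        if min(n_r, n_nr) < min_arm:
            row["skipped"] = f"one arm has < {min_arm} samples"
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lr = log_rank_test(sub, (resp == "responder").astype(int))
                tau = min(
                    sub.time[resp == "responder"].max(),
                    sub.time[resp == "non_responder"].max(),
                )
                rm_r = restricted_mean_survival(
                    sub.time[resp == "responder"].to_numpy(),
                    sub.event[resp == "responder"].to_numpy(),
                    tau,
                )
                rm_nr = restricted_mean_survival(
                    sub.time[resp == "non_responder"].to_numpy(),
                    sub.event[resp == "non_responder"].to_numpy(),
                    tau,
                )
                row.update(
                    log_rank_p=lr.p,
                    rmst_responder=rm_r,
                    rmst_non_responder=rm_nr,
                    benefit=bool(lr.p < 0.05 and rm_r > rm_nr),
                )
            except InputError as exc:
                row["skipped"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("unit")
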
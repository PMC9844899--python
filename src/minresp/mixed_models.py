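"""Linear mixed-effects analyses of pause-rupture associations.

Two random-intercept models on the 10-s window table, both with percent
of pauses per window as response and dyad as grouping factor:

* Model A — rupture vs. non-rupture windows as the single predictor
  (``pause_pct ~ is_rupture + (1 | dyad)``).
* Model B — rupture windows only; predictors are the dominant rupture
  type (withdrawal vs. confrontation reference) and presence of the
  minimal-response marker
  (``pause_pct ~ withdrawal + minimal_response + (1 | dyad)``).

Fits use restricted maximum likelihood.  p-values are large-sample Wald
tests (at the corpus sizes analysed here these are indistinguishable
from finite-df corrections).  Standardised betas come from refitting on
the z-scored response and predictors.  ICC is the share of residual-free
variance attributable to dyads; marginal and conditional R-squared
follow the variance-partition formulation (fixed / fixed + random +
residual).  Because two primary models are run, p-values are Bonferroni
adjusted (doubled, capped at 1), and both models are re-fit on the
square-root transformed response as a skewness sensitivity check.

The rupture-aligned time course re-bins the raw pause track of each
rupture into 10-s bins anchored at the rupture onset (20 bins before to
30 after), averaging over ruptures per offset and type.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .windowing import _cumulative_overlap


@dataclass
class MixedModelFit:
    table: pd.DataFrame  # per-coefficient estimates
    sigma2: float
    tau2: float
    icc: float
    n_groups: int
    n_obs: int
    marginal_r2: float
    conditional_r2: float
    converged: bool
    formula: str

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "estimate"])


def _fit_lmm(df: pd.DataFrame, response: str, predictors: list, formula: str) -> MixedModelFit:
    y = df[response].to_numpy(float)
    X = sm.add_constant(df[predictors].astype(float), has_constant="add")
    groups = df["dyad_id"].to_numpy()
    n_groups = len(np.unique(groups))
    converged = True
    if n_groups < 2:
        # degenerate limit: no between-dyad variance estimable; plain OLS
        res = sm.OLS(y, X).fit()
        params, bse, pvals = res.params, res.bse, res.pvalues
        ci = res.conf_int()
        sigma2, tau2 = float(res.scale), 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        converged = bool(res.converged)
        params = res.params[: X.shape[1]]
        bse = res.bse[: X.shape[1]]
        pvals = res.pvalues[: X.shape[1]]
        ci = res.conf_int().iloc[: X.shape[1]]
        sigma2 = float(res.scale)
        tau2 = float(res.cov_re.iloc[0, 0])

    # standardised betas: refit on z-scored response and predictors
    zdf = df.copy()
    for c in [response] + predictors:
        v = zdf[c].astype(float)
        sd = v.std(ddof=1)
        zdf[c] = (v - v.mean()) / sd if sd > 0 else 0.0
    Xz = sm.add_constant(zdf[predictors].astype(float), has_constant="add")
    yz = zdf[response].to_numpy(float)
    if n_groups < 2:
        rz = sm.OLS(yz, Xz).fit()
        zparams, zbse = rz.params, rz.bse
        zci = rz.conf_int()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rz = sm.MixedLM(yz, Xz, groups=groups).fit(reml=True)
        zparams = rz.params[: Xz.shape[1]]
        zbse = rz.bse[: Xz.shape[1]]
        zci = rz.conf_int().iloc[: Xz.shape[1]]

    names = ["(Intercept)"] + predictors
    table = pd.DataFrame(
        {
            "estimate": np.asarray(params),
            "se": np.asarray(bse),
            "ci_low": np.asarray(ci)[:, 0],
            "ci_high": np.asarray(ci)[:, 1],
            "std_beta": np.asarray(zparams),
            "std_se": np.asarray(zbse),
            "std_ci_low": np.asarray(zci)[:, 0],
            "std_ci_high": np.asarray(zci)[:, 1],
            "p": np.asarray(pvals),
        },
        index=names,
    )
    fixed = (X.to_numpy() @ np.asarray(params))
    var_f = float(np.var(fixed))
    denom = var_f + tau2 + sigma2
    return MixedModelFit(
        table=table,
        sigma2=sigma2,
        tau2=tau2,
        icc=tau2 / (tau2 + sigma2) if (tau2 + sigma2) > 0 else 0.0,
        n_groups=n_groups,
        n_obs=len(df),
        marginal_r2=var_f / denom if denom > 0 else 0.0,
        conditional_r2=(var_f + tau2) / denom if denom > 0 else 0.0,
        converged=converged,
        formula=formula,
    )


def fit_model_a(rows: pd.DataFrame, response: str = "pause_pct") -> MixedModelFit:
    """Rupture vs. non-rupture windows as predictor of window pause
    percentage, random intercept by dyad."""
    df = rows.copy()
    if df["in_rupture"].nunique() < 2:
        raise ValueError("Model A needs both rupture and non-rupture windows")
    df["is_rupture"] = df["in_rupture"].astype(float)
    return _fit_lmm(df, response, ["is_rupture"],
                    f"{response} ~ is_rupture + (1 | dyad)")


def fit_model_b(rows: pd.DataFrame, response: str = "pause_pct") -> MixedModelFit:
    """Rupture type and minimal-response marker as predictors, fitted on
    rupture windows exclusively (reference cell: confrontation without
    the marker)."""
    if not rows["in_rupture"].all():
        raise ValueError("Model B is fitted on rupture windows only")
    df = rows.copy()
    df["withdrawal"] = (df["dominant_type"] == "withdrawal").astype(float)
    df["minimal_response"] = df["minimal_response"].astype(float)
    predictors = [c for c in ("withdrawal", "minimal_response") if df[c].nunique() > 1]
    return _fit_lmm(df, response, predictors,
                    f"{response} ~ withdrawal + minimal_response + (1 | dyad)")


def adjust_and_sensitivity(rows_a: pd.DataFrame, rows_b: pd.DataFrame) -> dict:
    """Fit both primary models, Bonferroni-adjust their p-values (two
    tests: p_adj = min(1, 2p)) and re-fit each on the square-root
    transformed response."""
    out = {}
    for name, fitter, rows in (("model_a", fit_model_a, rows_a),
                               ("model_b", fit_model_b, rows_b)):
        fit = fitter(rows)
        fit.table["p_adj"] = np.minimum(1.0, 2.0 * fit.table["p"])
        out[name] = fit
        sq = rows.copy()
        sq["sqrt_pause"] = np.sqrt(np.clip(sq["pause_pct"].astype(float), 0.0, None))
        sfit = fitter(sq, response="sqrt_pause")
        sfit.table["p_adj"] = np.minimum(1.0, 2.0 * sfit.table["p"])
        out[f"{name}_sqrt"] = sfit
    return out


def bonferroni(p: float, m: int = 2) -> float:
    return float(min(1.0, m * p))


def corpus_recovery_summary(config) -> dict:
    """Planted-parameter recovery summary of a synthetic corpus via the
    ground-truth bypass: pooled non-rupture and rupture window pause
    means, the withdrawal/minimal-response cell mean, and the Model B
    fixed effects, with the number of windows behind each quantity.

    Sessions are generated and windowed one at a time so corpora of
    thousands of sessions fit comfortably in memory.
    """
    from .synthetic_data import generate_session, truth_to_window_table

    keep = ["dyad_id", "pause_pct", "in_rupture", "dominant_type", "minimal_response"]
    pieces = []
    for dyad in range(config.n_dyads):
        for sess in range(config.sessions_per_dyad):
            df = truth_to_window_table(generate_session(config, dyad, sess))
            pieces.append(df[keep])
    windows = pd.concat(pieces, ignore_index=True)
    nr = windows[~windows.in_rupture]
    ru = windows[windows.in_rupture]
    cell = ru[(ru.dominant_type == "withdrawal") & ru.minimal_response]
    fit = fit_model_b(ru)
    return {
        "mean_pause_pct_nonrupture": (float(nr.pause_pct.mean()), len(nr)),
        "mean_pause_pct_rupture": (float(ru.pause_pct.mean()), len(ru)),
        "model_b_intercept": (fit.coef("(Intercept)"), fit.n_obs),
        "model_b_withdrawal": (fit.coef("withdrawal"), fit.n_obs),
        "model_b_minimal_response": (fit.coef("minimal_response"), fit.n_obs),
        "mean_pause_pct_withdrawal_mr": (float(cell.pause_pct.mean()), len(cell)),
    }


def rupture_timecourse(truths, window: float = 10.0, pre: int = 20, post: int = 30):
    """Onset-anchored pause time course.

    For every rupture episode the session's pause track is re-binned into
    10-s bins aligned to the rupture onset (not to the session grid),
    from ``pre`` bins before to ``post`` bins after onset.  Returns
    (points, summary): per (offset, type) the mean pause percentage, the
    standard error of the mean over contributing ruptures (missing when
    only one rupture contributes), and the count; the summary holds the
    all-window average line and rupture-length quartiles per type.
    """
    rows = []
    lengths = {"withdrawal": [], "confrontation": []}
    tot_pause = tot_time = 0.0
    for truth in truths:
        pauses = sorted(truth.pauses, key=lambda p: p.start)
        starts = [p.start for p in pauses]
        ends = [p.end for p in pauses]
        tot_pause += sum(p.duration for p in pauses)
        tot_time += truth.session_length
        for r in truth.ruptures:
            lengths[r.dominant_type].append(r.duration)
            offs = np.arange(-pre, post)
            b0 = r.start + offs * window
            b1 = b0 + window
            ok = (b0 >= -1e-9) & (b1 <= truth.session_length + 1e-9)
            if not ok.any() or not pauses:
                continue
            F0 = _cumulative_overlap(starts, ends, b0[ok])
            F1 = _cumulative_overlap(starts, ends, b1[ok])
            for off, sec in zip(offs[ok], F1 - F0):
                rows.append((int(off), r.dominant_type, 100.0 * sec / window))
    df = pd.DataFrame(rows, columns=["offset", "rupture_type", "pause_pct"])
    points = (
        df.groupby(["rupture_type", "offset"])["pause_pct"]
        .agg(mean_pause_pct="mean",
             sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
             n_ruptures="size")
        .reset_index()
    )
    summary = {
        "overall_mean_pause_pct": 100.0 * tot_pause / tot_time if tot_time else np.nan,
        "rupture_length_quartiles": {
            t: (list(np.percentile(v, [25, 50, 75])) if v else None)
            for t, v in lengths.items()
        },
    }
    return points, summary
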
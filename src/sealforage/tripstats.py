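"""Group comparisons of trip metrics and colony-size / latitude mixed models.

Trip duration and maximum extent are compared across study sites after log
transformation.  Shapiro-Wilk (per site) and Bartlett (across sites) gate
the choice between a parametric branch (one-way ANOVA + Tukey HSD) and a
nonparametric one (Kruskal-Wallis + Dunn pairwise tests, Holm-adjusted).
A second analysis asks whether colony size (number of seals) or latitude
drives the spatial metrics, by AIC comparison of three linear mixed models
with a random site intercept:

    log(metric) ~ n_seals        + (1 | site)
    log(metric) ~ latitude       + (1 | site)
    log(metric) ~ n_seals + latitude + (1 | site)
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "AssumptionReport",
    "assumption_tests",
    "compare_sites",
    "dunn_test",
    "colony_size_models",
]

ALPHA = 0.05


@dataclass
class AssumptionReport:
    shapiro_p: pd.Series           # per site
    bartlett_p: float
    parametric: bool
    skipped_groups: list


def assumption_tests(table: pd.DataFrame, metric: str, by: str = "site",
                     alpha: float = ALPHA) -> AssumptionReport:
    """Normality (Shapiro-Wilk per site) and homoscedasticity (Bartlett).

    The parametric branch is chosen only when every per-site Shapiro test
    and the Bartlett test are non-significant at ``alpha``.  Sites with
    fewer than 3 trips are skipped (logged).
    """
    groups, skipped, sh = [], [], {}
    for site, sub in table.groupby(by, sort=True):
        v = sub[metric].to_numpy(float)
        if len(v) < 3:
            skipped.append(site)
            logger.info("assumption_tests: site %s skipped (n=%d)", site, len(v))
            continue
        sh[site] = stats.shapiro(v).pvalue
        groups.append(v)
    if len(groups) < 2:
        raise ValueError("Bartlett test needs at least two usable sites")
    bart_p = float(stats.bartlett(*groups).pvalue)
    shapiro_p = pd.Series(sh, name="shapiro_p")
    parametric = bool((shapiro_p > alpha).all() and bart_p > alpha)
    return AssumptionReport(shapiro_p=shapiro_p, bartlett_p=bart_p,
                            parametric=parametric, skipped_groups=skipped)


def dunn_test(groups: dict, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise rank-based post hoc test with multiplicity adjustment.

    Implements the standard z statistic on mean ranks with tie correction;
    ``adjust`` is "holm" (default), "bonferroni" or "none".
    """
    names = list(groups)
    all_v = np.concatenate([np.asarray(groups[g], float) for g in names])
    n_tot = len(all_v)
    ranks = stats.rankdata(all_v)
    _, tie_counts = np.unique(all_v, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_tot - 1))
    mean_rank, sizes = {}, {}
    pos = 0
    for g in names:
        k = len(groups[g])
        mean_rank[g] = ranks[pos:pos + k].mean()
        sizes[g] = k
        pos += k
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt((n_tot * (n_tot + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"a": a, "b": b, "z": z, "p": p})
    out = pd.DataFrame(rows)
    m = len(out)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(out["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * out["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_adj"] = adj
    else:
        out["p_adj"] = out["p"]
    return out


def compare_sites(table: pd.DataFrame, metric: str, by: str = "site",
                  parametric: bool | None = None, alpha: float = ALPHA) -> dict:
    """Omnibus comparison of a trip metric across sites, with post hocs.

    Parametric branch: one-way ANOVA + Tukey HSD; nonparametric branch:
    Kruskal-Wallis + Dunn (Holm).  If ``parametric`` is None the branch is
    decided by :func:`assumption_tests`.
    """
    groups = {site: sub[metric].to_numpy(float)
              for site, sub in table.groupby(by, sort=True) if len(sub) >= 3}
    if len(groups) < 2:
        raise ValueError("need at least two sites")
    if parametric is None:
        parametric = assumption_tests(table, metric, by=by, alpha=alpha).parametric
    vals = list(groups.values())
    names = list(groups)
    if parametric:
        st = stats.f_oneway(*vals)
        tk = stats.tukey_hsd(*vals)
        rows = [{"a": names[i], "b": names[j], "p_adj": tk.pvalue[i, j]}
                for i, j in itertools.combinations(range(len(names)), 2)]
        posthoc = pd.DataFrame(rows)
        return {"branch": "anova", "statistic": float(st.statistic), "df": len(names) - 1,
                "p": float(st.pvalue), "posthoc": posthoc}
    st = stats.kruskal(*vals)
    posthoc = dunn_test(groups) if len(groups) > 2 else None
    return {"branch": "kruskal", "statistic": float(st.statistic), "df": len(names) - 1,
            "p": float(st.pvalue), "posthoc": posthoc}


def colony_size_models(table: pd.DataFrame, metric: str) -> dict:
    """AIC ledger over the three colony-size / latitude mixed-model candidates.

    ``table`` needs columns ``site``, ``n_seals``, ``latitude`` and the
    (already log-transformed) metric.  Models are fitted by ML so AICs are
    comparable; the winner's fixed-effect Wald p-values are reported.
    Singular random-effect fits are retained with a warning.
    """
    if table["site"].nunique() < 4:
        raise ValueError("need at least 4 sites for the mixed-model comparison")
    candidates = {
        "n_seals": f"{metric} ~ n_seals",
        "latitude": f"{metric} ~ latitude",
        "n_seals+latitude": f"{metric} ~ n_seals + latitude",
    }
    rows, fits = [], {}
    for name, formula in candidates.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = smf.mixedlm(formula, table, groups=table["site"]).fit(reml=False)
                singular = bool(fit.cov_re.to_numpy().min() < 1e-8)
                if singular:
                    logger.warning("colony_size_models: singular RE fit for %s", name)
                rows.append({"model": name, "aic": float(fit.aic), "singular": singular})
                fits[name] = fit
            except Exception as exc:  # noqa: BLE001 - candidate failures are recorded
                logger.warning("colony_size_models: candidate %s failed (%s)", name, exc)
                rows.append({"model": name, "aic": np.nan, "singular": True})
    ledger = pd.DataFrame(rows)
    ok = ledger.dropna(subset=["aic"]).sort_values("aic", kind="stable")
    if ok.empty:
        raise RuntimeError("all mixed-model candidates failed")
    winner = ok.iloc[0]["model"]
    ledger["delta_aic"] = ledger["aic"] - ok.iloc[0]["aic"]
    fit = fits[winner]
    fixed_p = {k: float(v) for k, v in fit.pvalues.items()
               if k not in ("Group Var",) and not k.startswith("Group")}
    return {"ledger": ledger, "winner": winner, "fit": fit, "fixed_p": fixed_p}
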
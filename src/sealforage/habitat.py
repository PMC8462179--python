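"""Use-availability habitat selection model.

Foraging-dive locations (response 1) are contrasted with pseudo-absence
points (response 0) in a binomial smooth selection model on the logit scale:

    logit P(y = 1) = a + sum_j f_j(x_j) + sediment effects + b_individual

where each ``f_j`` is a penalized cubic spline smooth of a continuous
covariate (bathymetry, tidal current, distance to shore, distance to last
haulout), sediment class enters as a categorical fixed effect with a forced
reference level, and individuals (plus sites, in the pooled "global" mode)
contribute ridge-penalized random intercepts.  Smoothing parameters — one
per smooth plus one per random-effect block — are chosen by minimizing an
AIC/UBRE criterion with effective degrees of freedom, the whole fit being a
penalized IRLS.

The API follows the Model/Results convention: build a
:class:`HabitatSelectionModel` from a use-availability table, call
``fit()``, and read estimates, AIC, explained deviance, per-term importance
and prediction maps off the returned :class:`HabitatSelectionResults`.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothTerm",
    "HabitatSelectionModel",
    "HabitatSelectionResults",
    "build_table",
    "vif_screen",
    "select_model",
    "subsample_one_in_three",
]

DEFAULT_SMOOTHS = ("bathy", "tidal", "dist_shore", "dist_haulout")


# --------------------------------------------------------------------------
# design-matrix building blocks
# --------------------------------------------------------------------------
@dataclass
class SmoothTerm:
    """Penalized cubic spline smooth of one continuous covariate.

    ``k`` basis functions (cubic B-splines on quantile knots) with a
    second-difference penalty; a sum-to-zero constraint absorbs the constant
    into the intercept, leaving ``k - 1`` identifiable columns.
    """

    name: str
    k: int = 5
    degree: int = 3
    knots: np.ndarray = field(default=None, repr=False)
    Z: np.ndarray = field(default=None, repr=False)        # constraint null-space
    S: np.ndarray = field(default=None, repr=False)        # penalty, constrained space
    xmin: float = np.nan
    xmax: float = np.nan

    def build(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if self.knots is None:
            self.xmin, self.xmax = float(x.min()), float(x.max())
            if self.xmax <= self.xmin:
                raise ValueError(f"covariate {self.name!r} is constant")
            n_interior = self.k - self.degree - 1
            if n_interior > 0:
                qs = np.linspace(0, 1, n_interior + 2)[1:-1]
                interior = np.quantile(x, qs)
            else:
                interior = np.array([])
            eps = 1e-8 * (self.xmax - self.xmin)
            self.knots = np.concatenate([
                np.repeat(self.xmin - eps, self.degree + 1),
                interior,
                np.repeat(self.xmax + eps, self.degree + 1),
            ])
            B = self._raw(x)
            c = B.sum(axis=0)
            # null space of the sum-to-zero constraint
            _, _, Vt = np.linalg.svd(c[None, :])
            self.Z = Vt[1:].T
            D = np.diff(np.eye(self.k), n=2, axis=0)
            self.S = self.Z.T @ (D.T @ D) @ self.Z
        return self._raw(x) @ self.Z

    def _raw(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.knots[0] + 1e-12, self.knots[-1] - 1e-12)
        return BSpline.design_matrix(xc, self.knots, self.degree).toarray()

    def extrapolated(self, x) -> np.ndarray:
        return (np.asarray(x, float) < self.xmin) | (np.asarray(x, float) > self.xmax)


def _dummies(values: pd.Series, levels: list, reference) -> tuple[np.ndarray, list]:
    others = [lv for lv in levels if lv != reference]
    X = np.column_stack([(values == lv).to_numpy(float) for lv in others]) \
        if others else np.empty((len(values), 0))
    return X, others


# --------------------------------------------------------------------------
# table construction / screening
# --------------------------------------------------------------------------
def build_table(foraging: pd.DataFrame, absences: pd.DataFrame) -> pd.DataFrame:
    """Stack foraging dives (response 1) and pseudo-absences (response 0).

    Both inputs must already carry the covariate columns plus ``individual``
    (and optionally ``site``); foraging rows should carry ``dive_id`` so
    absences can be tied back to their dive (2 per dive, in order) for the
    1-in-3 global-mode subsampling.
    """
    for ind, sub in absences.groupby("individual"):
        if sub.empty:
            raise ValueError(f"individual {ind} has no pseudo-absences")
    f = foraging.copy()
    f["response"] = 1
    a = absences.copy()
    a["response"] = 0
    if "dive_id" in f.columns and "dive_ref" not in a.columns:
        refs = []
        for ind, sub in a.groupby("individual", sort=False):
            ids = f.loc[f["individual"] == ind, "dive_id"].to_numpy()
            if len(ids) == 0:
                raise ValueError(f"individual {ind} has pseudo-absences but no dives")
            ratio = int(np.ceil(len(sub) / len(ids)))
            refs.append(pd.Series(np.repeat(ids, ratio)[: len(sub)], index=sub.index))
        a["dive_ref"] = pd.concat(refs)
        f["dive_ref"] = f["dive_id"]
    table = pd.concat([f, a], ignore_index=True, sort=False)
    counts = table.groupby(["individual", "response"]).size()
    logger.info("build_table: %d rows (%s)", len(table), dict(counts))
    missing = table.groupby("individual")["response"].nunique() < 2
    if missing.any():
        raise ValueError(f"individuals with one response class only: "
                         f"{missing.index[missing].tolist()}")
    return table


def vif_screen(table: pd.DataFrame, covariates=DEFAULT_SMOOTHS,
               categorical: str | None = "sediment", threshold: float = 5.0) -> pd.Series:
    """Variance inflation factor per continuous covariate.

    VIF_j = 1 / (1 - R²_j) from regressing covariate j on the remaining
    covariates (sediment dummy-coded).  Report-only: values above
    ``threshold`` trigger a warning, perfectly collinear pairs come back inf.
    """
    covariates = [c for c in covariates if c in table.columns]
    if len(covariates) < 2:
        raise ValueError("need at least two continuous covariates")
    blocks = [table[c].to_numpy(float) for c in covariates]
    extra = np.empty((len(table), 0))
    if categorical and categorical in table.columns:
        levels = sorted(table[categorical].unique())
        extra, _ = _dummies(table[categorical], levels, levels[0])
    out = {}
    for j, c in enumerate(covariates):
        yj = blocks[j]
        Xj = np.column_stack([np.ones(len(table))]
                             + [blocks[i] for i in range(len(blocks)) if i != j]
                             + ([extra] if extra.size else []))
        beta, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 1.0
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        if not np.isfinite(out[c]):
            warnings.warn(f"VIF for {c!r} is infinite: perfectly collinear covariates")
        elif out[c] > threshold:
            warnings.warn(f"VIF for {c!r} = {out[c]:.2f} exceeds {threshold}")
    return pd.Series(out, name="vif")


def subsample_one_in_three(table: pd.DataFrame) -> pd.DataFrame:
    """Systematic 1-in-3 thinning of dives (with their pseudo-absences).

    Used before the pooled global fit; keeps every third foraging dive of
    each individual, in time order of appearance, and the absence rows tied
    to the kept dives.
    """
    if "dive_ref" not in table.columns:
        raise ValueError("table lacks dive_ref linkage; build it with build_table")
    kept_refs = []
    pres = table.loc[table["response"] == 1]
    for _, sub in pres.groupby("individual", sort=False):
        refs = sub["dive_ref"].to_numpy()
        kept_refs.append(refs[::3])
    kept = set(np.concatenate(kept_refs)) if kept_refs else set()
    return table.loc[table["dive_ref"].isin(kept)].reset_index(drop=True)


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------
def _binomial_deviance(y, mu):
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


class HabitatSelectionModel:
    """Binomial smooth selection model on a use-availability table.

    Parameters
    ----------
    table
        Output of :func:`build_table`: one row per foraging dive or
        pseudo-absence with covariates, ``response``, ``individual`` and
        (global mode) ``site`` columns.
    smooths
        Continuous covariates receiving penalized spline smooths.
    k
        Basis dimension per smooth.
    sediment
        Categorical covariate column, or None to omit.
    reference_sediment
        Forced reference level; default = the most represented class.
    mode
        "colony" (individual random intercepts) or "global" (individual and
        site random intercepts).
    """

    def __init__(self, table: pd.DataFrame, smooths=DEFAULT_SMOOTHS, k: int = 5,
                 sediment: str | None = "sediment", reference_sediment=None,
                 mode: str = "colony", linear: bool = False):
        if mode not in ("colony", "global"):
            raise ValueError("mode must be 'colony' or 'global'")
        self.table = table.reset_index(drop=True)
        self.y = self.table["response"].to_numpy(float)
        self.mode = mode
        self.k = k
        self.linear = linear
        self.smooth_names = [s for s in smooths if s in self.table.columns]
        self.sediment = sediment if sediment and sediment in self.table.columns else None

        n = len(self.table)
        blocks = [np.ones((n, 1))]
        self.slices: dict[str, slice] = {"intercept": slice(0, 1)}
        self.penalties: list[tuple[str, np.ndarray, slice]] = []
        col = 1

        self.terms: dict[str, SmoothTerm] = {}
        for name in self.smooth_names:
            x = self.table[name].to_numpy(float)
            if linear:
                xb = ((x - x.mean()) / (x.std() or 1.0))[:, None]
                blocks.append(xb)
                self.slices[name] = slice(col, col + 1)
                col += 1
                self._lin_stats = getattr(self, "_lin_stats", {})
                self._lin_stats[name] = (x.mean(), x.std() or 1.0)
                continue
            term = SmoothTerm(name, k=k)
            B = term.build(x)
            self.terms[name] = term
            blocks.append(B)
            sl = slice(col, col + B.shape[1])
            self.slices[name] = sl
            self.penalties.append((name, term.S, sl))
            col += B.shape[1]

        self.sediment_levels, self.sediment_ref = [], None
        if self.sediment:
            counts = self.table[self.sediment].value_counts()
            self.sediment_levels = sorted(counts.index.tolist())
            self.sediment_ref = (reference_sediment if reference_sediment is not None
                                 else counts.idxmax())
            X, others = _dummies(self.table[self.sediment], self.sediment_levels,
                                 self.sediment_ref)
            if X.shape[1]:
                blocks.append(X)
                self.slices[self.sediment] = slice(col, col + X.shape[1])
                self.sediment_others = others
                col += X.shape[1]
            else:
                self.sediment = None

        self.re_groups: dict[str, list] = {}
        re_cols = ["individual"] + (["site"] if mode == "global" else [])
        for g in re_cols:
            if g not in self.table.columns:
                continue
            levels = sorted(self.table[g].unique(), key=str)
            if len(levels) < 2:
                continue
            X = np.column_stack([(self.table[g] == lv).to_numpy(float) for lv in levels])
            blocks.append(X)
            sl = slice(col, col + X.shape[1])
            self.slices[f"re_{g}"] = sl
            self.penalties.append((f"re_{g}", np.eye(X.shape[1]), sl))
            self.re_groups[g] = levels
            col += X.shape[1]

        self.X = np.hstack(blocks)
        self.ncoef = self.X.shape[1]

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "HabitatSelectionModel":
        return cls(table, **kwargs)

    def _penalty_matrix(self, lam: np.ndarray) -> np.ndarray:
        S = np.zeros((self.ncoef, self.ncoef))
        for lam_j, (_, Sj, sl) in zip(lam, self.penalties):
            S[sl, sl] += lam_j * Sj
        return S

    def _pirls(self, lam: np.ndarray, beta0=None, max_iter: int = 100, tol: float = 1e-9):
        X, y = self.X, self.y
        S = self._penalty_matrix(lam)

        def pdev(b):
            mu = 1.0 / (1.0 + np.exp(-np.clip(X @ b, -30, 30)))
            return _binomial_deviance(y, mu) + float(b @ S @ b)

        beta = np.zeros(self.ncoef) if beta0 is None else beta0.copy()
        crit_old = pdev(beta)
        for _ in range(max_iter):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            XtW = X.T * w
            H = XtW @ X
            A = H + S
            A[np.diag_indices_from(A)] += 1e-10
            try:
                beta_new = np.linalg.solve(A, XtW @ z)
            except np.linalg.LinAlgError:
                raise RuntimeError("penalized IRLS failed: singular system "
                                   "(separation or collinear design?)")
            # step halving keeps the penalized deviance monotone
            step = beta_new - beta
            crit = pdev(beta_new)
            n_halve = 0
            while crit > crit_old + 1e-10 and n_halve < 30:
                step *= 0.5
                beta_new = beta + step
                crit = pdev(beta_new)
                n_halve += 1
            beta = beta_new
            if abs(crit - crit_old) < tol * (abs(crit) + 0.1):
                crit_old = crit
                break
            crit_old = crit
        else:
            logger.warning("PIRLS reached max_iter without full convergence")
        dev_old = _binomial_deviance(
            y, 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30))))
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (self.X.T * w) @ self.X
        A = H + self._penalty_matrix(lam)
        A[np.diag_indices_from(A)] += 1e-10
        Ainv = np.linalg.inv(A)
        edf_mat = Ainv @ H
        return beta, dev_old, Ainv, edf_mat

    def fit(self, lambdas=None, seed: int | None = None,
            maxiter_outer: int = 200) -> "HabitatSelectionResults":
        """Fit by penalized IRLS; smoothing parameters by AIC/UBRE search.

        ``lambdas`` fixes the per-penalty smoothing parameters (one per
        smooth + one per random-effect block) instead of optimizing them.
        Deterministic given the data.
        """
        npen = len(self.penalties)
        if npen == 0 or lambdas is not None:
            lam = np.ones(npen) if lambdas is None else np.asarray(lambdas, float)
            beta, dev, Ainv, edf_mat = self._pirls(lam)
            return self._results(lam, beta, dev, Ainv, edf_mat)

        state = {"beta": None}

        def objective(loglam):
            lam = 10.0 ** np.clip(loglam, -5, 5)
            try:
                beta, dev, _, edf_mat = self._pirls(lam, beta0=state["beta"])
            except RuntimeError:
                return np.inf
            state["beta"] = beta
            return dev + 2.0 * float(np.trace(edf_mat))

        x0 = np.zeros(npen)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter_outer, "xatol": 0.05, "fatol": 1e-4})
        lam = 10.0 ** np.clip(res.x, -5, 5)
        beta, dev, Ainv, edf_mat = self._pirls(lam)
        return self._results(lam, beta, dev, Ainv, edf_mat, n_outer=res.nfev)

    def _results(self, lam, beta, dev, Ainv, edf_mat, n_outer=0):
        mu0 = self.y.mean()
        null_dev = _binomial_deviance(self.y, np.full_like(self.y, mu0))
        return HabitatSelectionResults(
            model=self, lambdas=lam, params=beta, cov_params=Ainv,
            edf_by_coef=np.diag(edf_mat).copy(), deviance=dev, null_deviance=null_dev,
            n_outer_evals=n_outer,
        )

    # ------------------------------------------------------------------
    def design_for(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Design matrix for new data at the population level (REs zero).

        Returns (X_new, extrapolation flag per row).
        """
        n = len(df)
        blocks = [np.ones((n, 1))]
        extrap = np.zeros(n, bool)
        for name in self.smooth_names:
            x = df[name].to_numpy(float)
            if self.linear:
                m, s = self._lin_stats[name]
                blocks.append(((x - m) / s)[:, None])
                continue
            term = self.terms[name]
            blocks.append(term.build(x))
            extrap |= term.extrapolated(x)
        if self.sediment:
            X, _ = _dummies(df[self.sediment], self.sediment_levels, self.sediment_ref)
            blocks.append(X)
        for g, levels in self.re_groups.items():
            blocks.append(np.zeros((n, len(levels))))
        return np.hstack(blocks), extrap


@dataclass
class HabitatSelectionResults:
    """Fitted penalized smooth binomial selection model."""

    model: HabitatSelectionModel
    lambdas: np.ndarray
    params: np.ndarray
    cov_params: np.ndarray
    edf_by_coef: np.ndarray
    deviance: float
    null_deviance: float
    n_outer_evals: int = 0

    # ----------------------------------------------------------- scalars
    @property
    def edf(self) -> float:
        return float(self.edf_by_coef.sum())

    @property
    def aic(self) -> float:
        """AIC with effective degrees of freedom of the penalized terms."""
        return self.deviance + 2.0 * self.edf

    @property
    def explained_deviance(self) -> float:
        """100 * (1 - D_model / D_null), in percent."""
        if self.null_deviance <= 0:
            return 0.0
        return 100.0 * (1.0 - self.deviance / self.null_deviance)

    def edf_by_term(self) -> pd.Series:
        out = {}
        for name, sl in self.model.slices.items():
            out[name] = float(self.edf_by_coef[sl].sum())
        return pd.Series(out, name="edf")

    def random_effect_sd(self) -> dict:
        """Implied random-intercept SD per grouping (1/sqrt(lambda))."""
        out = {}
        for lam_j, (name, _, _) in zip(self.lambdas, self.model.penalties):
            if name.startswith("re_"):
                out[name[3:]] = float(1.0 / np.sqrt(lam_j))
        return out

    # ------------------------------------------------------- prediction
    def predict(self, df: pd.DataFrame, se: bool = False):
        X, extrap = self.model.design_for(df)
        eta = X @ self.params
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        if not se:
            return mu
        var = np.einsum("ij,jk,ik->i", X, self.cov_params, X)
        se_eta = np.sqrt(np.clip(var, 0, None))
        return mu, se_eta * mu * (1 - mu), extrap

    def fittedvalues(self) -> np.ndarray:
        eta = self.model.X @ self.params
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))

    def term_importance(self, alternative: bool = False) -> pd.Series:
        """Relative importance (%) of each environmental term.

        Default metric: drop the term, refit, and take the loss in explained
        deviance; raw losses are floored at zero and normalized to sum 100.
        ``alternative=True`` uses the variance of each term's partial linear
        predictor instead (no refits).
        """
        names = list(self.model.smooth_names) + ([self.model.sediment]
                                                 if self.model.sediment else [])
        if not names:
            raise ValueError("model has no environmental terms")
        raw = {}
        if alternative:
            for name in names:
                sl = self.model.slices[name]
                contrib = self.model.X[:, sl] @ self.params[sl]
                raw[name] = float(np.var(contrib))
        else:
            ed_full = self.explained_deviance
            for name in names:
                keep = [s for s in self.model.smooth_names if s != name]
                sed = self.model.sediment if name != self.model.sediment else None
                try:
                    sub = HabitatSelectionModel(
                        self.model.table, smooths=keep, k=self.model.k, sediment=sed,
                        reference_sediment=self.model.sediment_ref if sed else None,
                        mode=self.model.mode, linear=self.model.linear,
                    ).fit()
                    raw[name] = max(ed_full - sub.explained_deviance, 0.0)
                except (RuntimeError, ValueError) as exc:
                    logger.warning("term_importance: refit without %s failed (%s)", name, exc)
                    raw[name] = np.nan
        s = pd.Series(raw, name="importance")
        ok = s.dropna()
        total = ok.sum()
        if total <= 0:
            s.loc[ok.index] = 100.0 / len(ok)
        else:
            s.loc[ok.index] = 100.0 * ok / total
        return s

    def predict_map(self, seascape, seagraph=None) -> dict:
        """Population-level selection maps over the seascape's sea cells.

        Distance-to-last-haulout is surrogated by the least-cost distance to
        the nearest haulout site.  Returns dict with 'probability', 'se' and
        'extrapolated' rasters (NaN on land).
        """
        from .geo import SeaGraph

        if seagraph is None:
            seagraph = SeaGraph(seascape)
        ny, nx = seascape.shape
        sea = seascape.sea
        rr, cc = np.nonzero(sea)
        df = pd.DataFrame({
            "bathy": seascape.bathy[rr, cc],
            "tidal": seascape.tidal[rr, cc],
            "dist_shore": seascape.dist_shore_km[rr, cc],
            "sediment": seascape.sediment[rr, cc],
        })
        dh = seagraph.distance_from_points(seascape.haulouts[["x", "y"]].to_numpy())
        df["dist_haulout"] = dh[rr, cc]
        finite = np.isfinite(df[[c for c in df.columns]]).all(axis=1).to_numpy()
        mu = np.full(len(df), np.nan)
        se = np.full(len(df), np.nan)
        ex = np.zeros(len(df), bool)
        if self.model.sediment:
            known = df["sediment"].isin(self.model.sediment_levels).to_numpy()
            finite &= known
        sub = df.loc[finite]
        mu_f, se_f, ex_f = self.predict(sub, se=True)
        mu[finite], se[finite], ex[finite] = mu_f, se_f, ex_f
        out = {}
        for key, vec in (("probability", mu), ("se", se), ("extrapolated", ex.astype(float))):
            g = np.full((ny, nx), np.nan)
            g[rr, cc] = vec
            out[key] = g
        return out

    # ---------------------------------------------------------- summary
    def summary(self) -> str:
        lines = [
            "Habitat selection model (binomial logit, penalized smooths)",
            "=" * 62,
            f"rows: {len(self.model.y)}   presences: {int(self.model.y.sum())}"
            f"   mode: {self.model.mode}",
            f"deviance: {self.deviance:.2f}   null: {self.null_deviance:.2f}"
            f"   explained: {self.explained_deviance:.1f}%",
            f"AIC: {self.aic:.2f}   total EDF: {self.edf:.2f}",
            "-" * 62,
            f"{'term':<16}{'edf':>8}{'lambda':>12}",
        ]
        lam_of = {name: lam for lam, (name, _, _) in zip(self.lambdas, self.model.penalties)}
        for name, e in self.edf_by_term().items():
            lam = lam_of.get(name, np.nan)
            lines.append(f"{name:<16}{e:>8.2f}{lam:>12.3g}")
        if self.model.sediment:
            lines.append(f"sediment reference level: {self.model.sediment_ref}")
        re_sd = self.random_effect_sd()
        if re_sd:
            lines.append("random-intercept SD: "
                         + ", ".join(f"{k}={v:.3f}" for k, v in re_sd.items()))
        return "\n".join(lines)


def select_model(table: pd.DataFrame, candidates: list[list[str]] | None = None,
                 smooths=DEFAULT_SMOOTHS, include_sediment: bool = True,
                 **model_kwargs) -> tuple[HabitatSelectionResults, pd.DataFrame]:
    """AIC selection over candidate term sets (all non-empty subsets by default).

    Returns (best results, AIC ledger).  Failed candidates are recorded and
    skipped; ties break toward fewer terms.
    """
    avail = [s for s in smooths if s in table.columns]
    if candidates is None:
        candidates = []
        for r in range(1, len(avail) + 1):
            candidates += [list(c) for c in itertools.combinations(avail, r)]
    rows, fits = [], {}
    for i, terms in enumerate(candidates):
        try:
            res = HabitatSelectionModel(
                table, smooths=terms,
                sediment="sediment" if include_sediment else None,
                **model_kwargs,
            ).fit()
            rows.append({"candidate": i, "terms": "+".join(terms), "n_terms": len(terms),
                         "aic": res.aic, "ed": res.explained_deviance, "ok": True})
            fits[i] = res
        except (RuntimeError, ValueError) as exc:
            logger.warning("select_model: candidate %s failed (%s)", terms, exc)
            rows.append({"candidate": i, "terms": "+".join(terms), "n_terms": len(terms),
                         "aic": np.nan, "ed": np.nan, "ok": False})
    ledger = pd.DataFrame(rows)
    ok = ledger.loc[ledger["ok"]]
    if ok.empty:
        raise RuntimeError("all candidate models failed")
    ok = ok.sort_values(["aic", "n_terms"], kind="stable")
    best = int(ok.iloc[0]["candidate"])
    ledger["delta_aic"] = ledger["aic"] - ok.iloc[0]["aic"]
    return fits[best], ledger
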
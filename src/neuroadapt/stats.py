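"""Group-level statistics: mixed-effects regression over time–frequency
pixels and band time courses, 2D cluster-based permutation testing, FDR
time-course masks, and the coupling-level models.

Responses are observed per trial × channel, with channels nested in
patients, so the reference model is a linear mixed model with a random
intercept per patient and per channel-within-patient.  Two solver paths are
provided:

* ``method="lme"`` — statsmodels ``MixedLM`` (REML), the reference fit, used
  for single-response models (coupling contrasts, decision prediction).
* ``method="demeaned_ols"`` — both the response and the regressors are
  demeaned within each patient × channel stratum, which absorbs the random
  intercepts exactly, and the fixed effects are then estimated by ordinary
  least squares with degrees of freedom reduced by the number of strata.
  Because it is a single matrix product per permutation across all pixels,
  this is the default for the pixel-wise maps and for permutation refits.

Binary codings follow the task conventions: decision stay = 1 / switch = 0;
feedback reward = 1 / non-reward = 0; stage pre-selection = 1 /
post-feedback = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .spectral import FreqGrid

logger = logging.getLogger(__name__)

__all__ = [
    "LMEDesign",
    "RegressionMap",
    "ClusterConfig",
    "ClusterResult",
    "fit_lme",
    "tf_regression_map",
    "cluster_permutation_2d",
    "timecourse_regression_fdr",
    "coupling_stage_contrast",
    "coupling_decision_prediction",
    "coupling_variable_correlation",
]

#: binary codings used throughout
CODINGS = {"decision": {"stay": 1, "switch": 0},
           "feedback": {"reward": 1, "non_reward": 0},
           "stage": {"pre_selection": 1, "post_feedback": 0}}


@dataclass(frozen=True)
class LMEDesign:
    """Fixed terms and random-intercept structure of a mixed model."""

    fixed: tuple                      # regressor column names
    random: str = "patient_channel"   # or "patient"
    response: str = "erd"

    def __post_init__(self) -> None:
        if self.random not in ("patient", "patient_channel"):
            raise ValueError("random must be 'patient' or 'patient_channel'")
        if not self.fixed:
            raise ValueError("need at least one fixed term")


@dataclass
class RegressionMap:
    """t/p maps per fixed effect over (freq, time) pixels or a time vector."""

    terms: tuple
    t: np.ndarray        # (n_terms, n_freqs, n_times) or (n_terms, n_times)
    p: np.ndarray
    beta: np.ndarray
    df: float
    times: np.ndarray | None = None
    grid: FreqGrid | None = None


@dataclass(frozen=True)
class ClusterConfig:
    """2D cluster-permutation parameters.

    ``alpha`` is the pixel threshold 0.05 divided by the number of fixed
    effects; retained clusters need area ≥ ``min_area_hzms`` (4 Hz × 80 ms)
    and significance is the 95th percentile of the permutation null of
    maximum cluster statistics (sum of squared t).
    """

    n_fixed: int = 1
    base_alpha: float = 0.05
    min_area_hzms: float = 320.0
    n_perm: int = 5000
    percentile: float = 95.0

    @property
    def alpha(self) -> float:
        return self.base_alpha / self.n_fixed


@dataclass
class ClusterResult:
    clusters: list               # dicts: mask, area_hzms, stat, p
    significant: np.ndarray      # bool per cluster
    null_max_stats: np.ndarray
    threshold_t: float
    term: str

    @property
    def any_significant(self) -> bool:
        return bool(self.significant.any())


# ---------------------------------------------------------------------------
# reference mixed-model fit

def fit_lme(data: pd.DataFrame, design: LMEDesign, response: str | None = None) -> pd.DataFrame:
    """Fit one linear mixed model; returns a per-term (beta, t, p) table.

    Random intercepts: patient, plus channel nested in patient when
    ``design.random == "patient_channel"`` and a channel column exists.  A
    singular nested fit falls back to the patient-only structure with a
    logged downgrade.
    """
    response = response or design.response
    cols = [response, *design.fixed, "patient"]
    if "channel" in data.columns:
        cols.append("channel")
    d = data[cols].dropna().reset_index(drop=True)
    if d["patient"].nunique() < 2:
        raise ValueError("fit_lme requires at least 2 patients")
    formula = f"{response} ~ " + " + ".join(design.fixed)

    def _fit(nested: bool):
        vc = {"channel": "0 + C(channel)"} if nested else None
        model = MixedLM.from_formula(formula, data=d, groups=d["patient"],
                                     re_formula="1", vc_formula=vc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=True)

    nested = design.random == "patient_channel" and "channel" in d.columns
    try:
        res = _fit(nested)
    except (np.linalg.LinAlgError, ValueError):
        if not nested:
            raise
        logger.warning("singular nested fit; downgrading to patient-only intercept")
        res = _fit(False)

    rows = []
    for term in design.fixed:
        rows.append({
            "term": term,
            "beta": float(res.params[term]),
            "t": float(res.tvalues[term]),
            "p": float(res.pvalues[term]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fast stratified-demeaning OLS over many pixels

def _strata_codes(table: pd.DataFrame, random: str) -> np.ndarray:
    if random == "patient_channel" and "channel" in table.columns:
        key = table["patient"].astype(str) + ":" + table["channel"].astype(str)
    else:
        key = table["patient"].astype(str)
    return pd.factorize(key)[0]


def _demean_within(arr: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Subtract the stratum mean from each row group (vectorized)."""
    arr = np.asarray(arr, float)
    n_strata = codes.max() + 1
    counts = np.bincount(codes, minlength=n_strata).astype(float)
    if arr.ndim == 1:
        sums = np.bincount(codes, weights=arr, minlength=n_strata)
        return arr - (sums / counts)[codes]
    means = np.zeros((n_strata, arr.shape[1]))
    np.add.at(means, codes, arr)
    means /= counts[:, None]
    return arr - means[codes]


def _ols_tmaps(Xd: np.ndarray, Yd: np.ndarray, n_strata: int):
    """OLS t-statistics for stratum-demeaned X (n,k) against Y (n,p).

    Returns (beta, t, df); df = n − n_strata − k.
    """
    n, k = Xd.shape
    df = n - n_strata - k
    if df <= 0:
        raise ValueError("not enough observations for the design")
    xtx = Xd.T @ Xd
    xtx_inv = np.linalg.pinv(xtx)
    beta = xtx_inv @ (Xd.T @ Yd)              # (k, p)
    resid = Yd - Xd @ beta
    rss = np.einsum("np,np->p", resid, resid)
    sigma2 = rss / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    return beta, t, df


def _prepare_fast(power: np.ndarray, table: pd.DataFrame, design: LMEDesign):
    """Drop NaN rows, demean X and flattened Y within strata."""
    n_obs = power.shape[0]
    if len(table) != n_obs:
        raise ValueError("power rows and table rows must match")
    X_raw = table[list(design.fixed)].to_numpy(float)
    keep = ~np.isnan(X_raw).any(axis=1)
    X_raw = X_raw[keep]
    Y = power[keep].reshape(keep.sum(), -1)
    codes = _strata_codes(table.loc[keep].reset_index(drop=True), design.random)
    n_strata = codes.max() + 1
    Xd = _demean_within(X_raw, codes)
    Yd = _demean_within(Y, codes)
    return Xd, Yd, codes, n_strata


def tf_regression_map(
    power: np.ndarray,
    table: pd.DataFrame,
    design: LMEDesign,
    times: np.ndarray | None = None,
    grid: FreqGrid | None = None,
    method: str = "demeaned_ols",
) -> RegressionMap:
    """Per-pixel mixed-model t-map over a (n_obs, n_freqs, n_times) stack.

    ``power`` holds one row per trial × channel observation; ``table`` the
    matching regressors with ``patient`` (and optionally ``channel``)
    columns.  The default solver is the stratified-demeaning OLS path;
    ``method="lme"`` refits statsmodels ``MixedLM`` per pixel (slow, exact).
    """
    pixel_shape = power.shape[1:]
    if method == "demeaned_ols":
        Xd, Yd, _, n_strata = _prepare_fast(power, table, design)
        beta, t, df = _ols_tmaps(Xd, Yd, n_strata)
        p = 2.0 * sps.t.sf(np.abs(t), df)
    elif method == "lme":
        Y = power.reshape(power.shape[0], -1)
        n_pix = Y.shape[1]
        k = len(design.fixed)
        beta = np.full((k, n_pix), np.nan)
        t = np.full((k, n_pix), np.nan)
        p = np.full((k, n_pix), np.nan)
        d = table.copy()
        for j in range(n_pix):
            d[design.response] = Y[:, j]
            try:
                res = fit_lme(d, design)
                beta[:, j] = res["beta"].to_numpy()
                t[:, j] = res["t"].to_numpy()
                p[:, j] = res["p"].to_numpy()
            except Exception:  # failed pixels stay NaN-masked
                continue
        df = float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")
    shape = (len(design.fixed), *pixel_shape)
    return RegressionMap(
        terms=tuple(design.fixed), t=t.reshape(shape), p=p.reshape(shape),
        beta=beta.reshape(shape), df=df, times=times, grid=grid,
    )


# ---------------------------------------------------------------------------
# 2D cluster-based permutation test

_CONN4 = ndimage.generate_binary_structure(2, 1)  # 4-neighborhood


def _pixel_areas(grid: FreqGrid, times: np.ndarray) -> np.ndarray:
    """(n_freqs, n_times) pixel areas in Hz·ms on the log-frequency grid."""
    dt_ms = float(np.median(np.diff(times))) * 1000.0
    df_hz = grid.bin_widths_hz()
    return np.outer(df_hz, np.full(len(times), dt_ms))


def _clusters_from_tmap(tmap: np.ndarray, t_crit: float, areas: np.ndarray,
                        min_area: float):
    """4-connected suprathreshold clusters passing the area rule."""
    mask = np.abs(tmap) > t_crit
    labels, n = ndimage.label(mask, structure=_CONN4)
    out = []
    for lab in range(1, n + 1):
        cmask = labels == lab
        area = float(areas[cmask].sum())
        if area < min_area:
            continue
        out.append({"mask": cmask, "area_hzms": area,
                    "stat": float((tmap[cmask] ** 2).sum())})
    return out


def cluster_permutation_2d(
    power: np.ndarray,
    table: pd.DataFrame,
    design: LMEDesign,
    grid: FreqGrid,
    times: np.ndarray,
    config: ClusterConfig | None = None,
    term: str | None = None,
    seed: int = 0,
    method: str = "demeaned_ols",
) -> ClusterResult:
    """2D cluster-based permutation test for one fixed effect.

    Pixels with two-sided p below ``alpha = 0.05 / n_fixed`` are grouped by
    4-connectivity; clusters smaller than 320 Hz·ms (pixel area = Δt(ms) ×
    geometric Δf(Hz)) are dropped; each surviving cluster's statistic is the
    sum of squared t.  The null records, per permutation of trial labels
    *within each patient × channel stratum*, the maximum surviving cluster
    statistic; observed clusters are significant beyond its 95th percentile.
    """
    if config is None:
        config = ClusterConfig(n_fixed=len(design.fixed))
    term = term or design.fixed[0]
    t_idx = list(design.fixed).index(term)

    Xd, Yd, codes, n_strata = _prepare_fast(power, table, design)
    _, t_obs, df = _ols_tmaps(Xd, Yd, n_strata)
    t_crit = float(sps.t.isf(config.alpha / 2.0, df))
    n_freqs, n_times = power.shape[1:]
    areas = _pixel_areas(grid, times)
    obs_map = t_obs[t_idx].reshape(n_freqs, n_times)
    clusters = _clusters_from_tmap(obs_map, t_crit, areas, config.min_area_hzms)

    rng = np.random.default_rng(seed)
    null = np.zeros(config.n_perm)
    order = np.arange(len(Xd))
    groups = [np.where(codes == s)[0] for s in range(n_strata)]
    for i in range(config.n_perm):
        perm = order.copy()
        for g in groups:
            perm[g] = rng.permutation(g)
        _, t_perm, _ = _ols_tmaps(Xd[perm], Yd, n_strata)
        pm = t_perm[t_idx].reshape(n_freqs, n_times)
        cl = _clusters_from_tmap(pm, t_crit, areas, config.min_area_hzms)
        null[i] = max((c["stat"] for c in cl), default=0.0)

    cutoff = np.percentile(null, config.percentile)
    sig = np.array([c["stat"] > cutoff for c in clusters], dtype=bool)
    for c in clusters:
        c["p"] = float((1.0 + np.sum(null >= c["stat"])) / (config.n_perm + 1.0))
    return ClusterResult(clusters=clusters, significant=sig,
                         null_max_stats=null, threshold_t=t_crit, term=term)


# ---------------------------------------------------------------------------
# band time-course regression with FDR

def timecourse_regression_fdr(
    amplitude: np.ndarray,
    table: pd.DataFrame,
    design: LMEDesign,
    times: np.ndarray | None = None,
    q: float = 0.001,
    method: str = "demeaned_ols",
) -> dict:
    """Per-timepoint mixed regression of a band envelope with BH-FDR mask.

    ``amplitude`` is (n_obs, n_times).  Benjamini–Hochberg correction runs
    across timepoints within this one analysis at threshold ``q``; returned
    masks are per fixed term.
    """
    rmap = tf_regression_map(amplitude[:, np.newaxis, :], table, design,
                             times=times, method=method)
    t = rmap.t[:, 0, :]
    p = rmap.p[:, 0, :]
    masks = np.zeros_like(p, dtype=bool)
    for i in range(p.shape[0]):
        finite = np.isfinite(p[i])
        if finite.any():
            rej, _, _, _ = multipletests(p[i, finite], alpha=q, method="fdr_bh")
            masks[i, finite] = rej
    return {"terms": rmap.terms, "t": t, "p": p, "mask": masks, "times": times,
            "df": rmap.df}


# ---------------------------------------------------------------------------
# coupling-level models

def _stage_codes(stage_col: pd.Series) -> pd.Series:
    if stage_col.dtype == object:
        return stage_col.map(CODINGS["stage"]).astype(float)
    return stage_col.astype(float)


def coupling_stage_contrast(table: pd.DataFrame, measure: str = "value") -> tuple:
    """Stage contrast of a coupling measure: measure ~ stage + (1|patient).

    Stage coded pre-selection = 1, post-feedback = 0; a negative t means the
    measure is stronger post-feedback.
    """
    d = table.copy()
    if d["stage"].nunique() < 2:
        raise ValueError("both stages must be present")
    d["stage_code"] = _stage_codes(d["stage"])
    design = LMEDesign(fixed=("stage_code",), random="patient", response=measure)
    res = fit_lme(d, design)
    return float(res["t"][0]), float(res["p"][0])


def coupling_decision_prediction(table: pd.DataFrame, measure: str = "value",
                                 stage: str | None = None,
                                 logistic: bool = False) -> tuple:
    """Does a coupling measure predict the upcoming stay/switch decision?

    Model: decision ~ measure + (1|patient) with decision stay = 1 /
    switch = 0, so a negative t means higher coupling precedes switches.
    A logistic mixed variant is available behind ``logistic=True``.
    """
    d = table.copy()
    if stage is not None:
        d = d[d["stage"] == stage]
    d = d.dropna(subset=["decision", measure])
    if d["decision"].nunique() < 2:
        raise ValueError("decision must take both values in the selected stage")
    if logistic:
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
        d = d.reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = BinomialBayesMixedGLM.from_formula(
                f"decision ~ {measure}", {"patient": "0 + C(patient)"}, d)
            res = md.fit_vb()
        idx = list(res.model.exog_names).index(measure)
        coef = res.fe_mean[idx]
        sd = res.fe_sd[idx]
        z = coef / sd
        return float(z), float(2 * sps.norm.sf(abs(z)))
    design = LMEDesign(fixed=(measure,), random="patient", response="decision")
    res = fit_lme(d, design)
    return float(res["t"][0]), float(res["p"][0])


def coupling_variable_correlation(
    table: pd.DataFrame,
    measure: str,
    regressors: tuple = ("pe", "rv", "ru"),
    decision_subset: str = "all",
    n_bins: int = 25,
) -> dict:
    """Relate a coupling measure to model variables on a decision subset.

    Fits measure ~ regressors + (1|patient) on all / stay / switch trials
    and returns per-regressor (beta, t, p) plus a 25-percentile-bin summary
    (bin means of the measure with SEM per regressor) for reporting.
    """
    d = table.dropna(subset=["decision", measure, *regressors]).copy()
    if decision_subset == "stay":
        d = d[d["decision"] == 1]
    elif decision_subset == "switch":
        d = d[d["decision"] == 0]
    elif decision_subset != "all":
        raise ValueError("decision_subset must be all, stay, or switch")
    if len(d) == 0:
        raise ValueError("empty trial subset")
    design = LMEDesign(fixed=tuple(regressors), random="patient", response=measure)
    fit = fit_lme(d, design)
    bins = {}
    for reg in regressors:
        ranks = d[reg].rank(pct=True)
        idx = np.minimum((ranks * n_bins).astype(int), n_bins - 1)
        g = d.groupby(idx)[measure]
        bins[reg] = pd.DataFrame({
            "bin": np.arange(n_bins),
            "mean": g.mean().reindex(range(n_bins)).to_numpy(),
            "sem": g.sem().reindex(range(n_bins)).to_numpy(),
            "n": g.size().reindex(range(n_bins), fill_value=0).to_numpy(),
        })
    return {"fit": fit, "bins": bins, "n_trials": len(d)}
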
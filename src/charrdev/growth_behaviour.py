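"""Stage-level analyses of individual traits.

Growth trajectories (second-order polynomial random regressions on log10
standard length against scaled thermal age), the bivariate yolk-sac model,
onset of exogeneous feeding, and behavioural repeatability with the
latent-to-data-scale transformation for binary traits (accounting for
Jensen's inequality via Gauss-Hermite quadrature over the individual
effect distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, roots_hermitenorm

from .mixed_models import (
    ChainSettings,
    PosteriorSamples,
    Prior,
    RandomTerm,
    fit_binary,
    fit_gaussian,
    hpd_interval,
    posterior_mode,
)
from .simulate import scale_thermal_age

__all__ = [
    "GrowthFit",
    "RepeatabilityEstimate",
    "fit_growth",
    "fit_yolk",
    "yolk_conversion",
    "onset_of_feeding",
    "repeatability",
    "data_scale_binary_r",
    "data_scale_count_r",
    "probit_observed_mean",
]


@dataclass
class GrowthFit:
    """Per-cross polynomial growth coefficients with posterior summaries."""

    table: pd.DataFrame  # cross, term, mode, lo, hi
    variance_components: pd.DataFrame
    samples: PosteriorSamples
    crosses: list[str]
    age_window: tuple[float, float]

    def coefficients(self, cross: str) -> dict[str, float]:
        sub = self.table[self.table["cross"] == cross]
        return dict(zip(sub["term"], sub["mode"]))

    def predict(self, cross: str, thermal_age: np.ndarray) -> np.ndarray:
        """Posterior-mean predicted log10 length at the given thermal ages."""
        t = scale_thermal_age(thermal_age, self.age_window)
        names = [f"{cross}:{term}" for term in ("intercept", "slope", "quadratic")]
        coefs = [self.samples.fixed_draws(n).mean() for n in names]
        return coefs[0] + coefs[1] * t + coefs[2] * t**2


@dataclass
class RepeatabilityEstimate:
    """Latent-scale (and, for non-Gaussian traits, data-scale) repeatability."""

    trait: str
    latent_mode: float
    latent_lo: float
    latent_hi: float
    data_mode: float | None = None
    data_lo: float | None = None
    data_hi: float | None = None
    cross: str | None = None
    latent_draws: np.ndarray | None = None
    data_draws: np.ndarray | None = None

    @property
    def significant(self) -> bool:
        """Read as the 95% CrI lower bound exceeding zero."""
        return self.latent_lo > 0


def _summary(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float, float]:
    lo, hi = hpd_interval(draws, prob)
    return posterior_mode(draws), lo, hi


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def fit_growth(
    data: pd.DataFrame,
    chain: ChainSettings | None = None,
    age_window: tuple[float, float] = (445.0, 1100.0),
    random_slopes: bool | None = None,
) -> GrowthFit:
    """Polynomial random regression of log10 standard length on thermal age.

    ``data`` is long format with columns id, cross, family, age
    (degree-days) and length (raw, mm) or log_length.  Fixed effects are a
    per-cross intercept, slope and quadratic term on the [0, 1]-scaled age
    axis; random intercepts for family and individual, with an individual
    random slope when every individual has at least three time points
    (otherwise an intercept-only fallback).
    """
    df = data.copy()
    if "log_length" in df.columns:
        y = df["log_length"].to_numpy(float)
    else:
        ln = df["length"].to_numpy(float)
        if np.any(ln <= 0):
            raise ValueError("non-positive lengths: log10 undefined")
        y = np.log10(ln)
    t = scale_thermal_age(df["age"].to_numpy(float), age_window)
    crosses = list(pd.unique(df["cross"]))

    cols, names = [], []
    for c in crosses:
        m = (df["cross"] == c).to_numpy().astype(float)
        cols += [m, m * t, m * t**2]
        names += [f"{c}:intercept", f"{c}:slope", f"{c}:quadratic"]
    X = np.column_stack(cols)

    n_points = int(df.groupby("id")["age"].nunique().min())
    if random_slopes is None:
        random_slopes = n_points >= 3
    # family and individual effects carry polynomial deviations up to the
    # degree the repeated measures identify (slope with 3 time points, the
    # full quadratic with 4+); the prior scale is a small floor well below
    # realistic log-length variance so the data dominate whenever variance
    # is present
    ages_unique = np.sort(df["age"].unique())
    t_unique = scale_thermal_age(ages_unique, age_window)
    shared_stages = len(ages_unique) <= 6 and n_points == len(ages_unique)
    if random_slopes and shared_stages:
        # every fish is measured at the same few stages: random effects at
        # the stage level with unstructured covariance, which nests
        # polynomial deviations and keeps the implied within-individual
        # covariance fully flexible
        z = np.column_stack([(df["age"].to_numpy(float) == a).astype(float)
                             for a in ages_unique])
        basis = np.column_stack([t_unique**j for j in range(3)])
        comp_labels = [f"stage{a:g}" for a in ages_unique]
        n_sweep = 3
    elif random_slopes:
        z = np.column_stack([np.ones_like(t), t])
        basis = None
        comp_labels = ["intercept", "slope"]
        n_sweep = 2
    else:
        z = None
        basis = None
        comp_labels = ["intercept"]
        n_sweep = 1
    d = 1 if z is None else z.shape[1]
    # individual-level covariance is well identified (hundreds of levels):
    # a small floor suffices; family-level variance comes from only a
    # handful of clutches, so it gets a weakly informative scale at a
    # modest fraction of the response variance (heavy-tailed: the implied
    # prior mean is infinite), which keeps cross-level contrasts honestly
    # uncertain instead of collapsing the clutch variance toward zero
    ind_prior = Prior(1e-5, d + 0.002)
    within = float(
        pd.DataFrame({"c": df["cross"].to_numpy(), "a": df["age"].to_numpy(), "y": y})
        .groupby(["c", "a"])["y"].var().mean()
    )
    fam_prior = Prior(max(0.01 * within, 1e-12), d + 0.002)
    # sweep moves: each cross's fixed polynomial columns are expressible in
    # the random basis on that cross's rows, so the fixed-vs-random flat
    # direction can be decorrelated (essential for honest interval widths
    # with few families)
    sweep_cols = {c: [3 * ci + j for j in range(n_sweep)] for ci, c in enumerate(crosses)}
    cross_arr = df["cross"].to_numpy()
    terms = [
        RandomTerm("family", df["family"].to_numpy(), Z=z, prior=fam_prior,
                   sweep_groups=cross_arr, sweep_cols=sweep_cols,
                   sweep_basis=basis),
        RandomTerm("individual", df["id"].to_numpy(), Z=z, prior=ind_prior,
                   sweep_groups=cross_arr, sweep_cols=sweep_cols,
                   sweep_basis=basis),
    ]
    samples = fit_gaussian(
        y, X, random=terms, prior_R=Prior(1.0, 0.002),
        chain=chain or ChainSettings(), fixed_names=names,
        response_names=["log_sl"],
    )

    rows = []
    for c in crosses:
        for term in ("intercept", "slope", "quadratic"):
            d = samples.fixed_draws(f"{c}:{term}")
            mode, lo, hi = _summary(d)
            rows.append({"cross": c, "term": term, "mode": mode, "lo": lo, "hi": hi})
    vrows = []
    for name, draws in samples.G.items():
        for j in range(draws.shape[1]):
            mode, lo, hi = _summary(draws[:, j, j])
            vrows.append({"component": f"{name}:{comp_labels[j]}", "mode": mode,
                          "lo": lo, "hi": hi})
    mode, lo, hi = _summary(samples.R[:, 0, 0])
    vrows.append({"component": "residual", "mode": mode, "lo": lo, "hi": hi})
    return GrowthFit(
        table=pd.DataFrame(rows),
        variance_components=pd.DataFrame(vrows),
        samples=samples,
        crosses=crosses,
        age_window=age_window,
    )


# ---------------------------------------------------------------------------
# yolk sac
# ---------------------------------------------------------------------------

def yolk_conversion(
    area_d1: np.ndarray,
    area_d2: np.ndarray,
    length_d1: np.ndarray,
    length_d2: np.ndarray,
) -> np.ndarray:
    """Relative yolk consumed per unit growth:
    (area_D1 - area_D2) / ((length_D2 - length_D1) * area_D1).

    Isolated here so alternative definitions are swappable; identical areas
    give 0 by construction."""
    a1 = np.asarray(area_d1, float)
    a2 = np.asarray(area_d2, float)
    dl = np.asarray(length_d2, float) - np.asarray(length_d1, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a1 - a2) / (dl * a1)
    out = np.where(a1 == a2, 0.0, out)
    return out


def fit_yolk(
    data: pd.DataFrame,
    chain: ChainSettings | None = None,
    baseline: str | None = None,
) -> pd.DataFrame:
    """Bivariate mixed model on yolk-sac areas at the first two stages.

    ``data`` columns: id, cross, family, yolk_d1, yolk_d2, logl_d1,
    logl_d2.  Each response gets its own intercept, its stage's log-length
    covariate, and cross contrasts against the baseline cross; family is a
    random intercept shared across responses.  Returns a tidy table (term,
    mode, lo, hi) shaped like the published yolk-sac model output.
    """
    for col in ("yolk_d1", "yolk_d2"):
        if np.any(data[col].to_numpy(float) < 0):
            raise ValueError("negative yolk areas")
    crosses = list(pd.unique(data["cross"]))
    baseline = baseline or crosses[0]
    others = [c for c in crosses if c != baseline]

    Y = data[["yolk_d1", "yolk_d2"]].to_numpy(float)
    n = Y.shape[0]
    Xs, names = [], []
    for resp, lcol, dlab in (("yolk_d1", "logl_d1", "D1"), ("yolk_d2", "logl_d2", "D2")):
        cols = [np.ones(n), data[lcol].to_numpy(float)]
        nm = [f"Response (yolk area at {dlab})", f"Yolk area at {dlab} x log(standard length at {dlab})"]
        for c in others:
            cols.append((data["cross"] == c).to_numpy().astype(float))
            nm.append(f"Yolk area at {dlab} x Cross type {c}")
        Xs.append(np.column_stack(cols))
        names += nm

    terms = [RandomTerm("family", data["family"].to_numpy(), prior=Prior(np.eye(2), 2.002))]
    samples = fit_gaussian(
        Y, Xs, random=terms, prior_R=Prior(np.eye(2), 2.002),
        chain=chain or ChainSettings(), fixed_names=names,
        response_names=["yolk_d1", "yolk_d2"],
    )
    rows = []
    for name in names:
        mode, lo, hi = _summary(samples.fixed_draws(name))
        rows.append({"term": name, "mode": mode, "lo": lo, "hi": hi})
    # interleave D1/D2 rows the way the published table orders them
    order = []
    k = len(rows) // 2
    for j in range(k):
        order += [j, k + j]
    return pd.DataFrame([rows[j] for j in order]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# onset of feeding
# ---------------------------------------------------------------------------

def onset_of_feeding(
    records: pd.DataFrame,
    chain: ChainSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First-feeding dates from daily one-zero records, plus a cross-level
    Gaussian mixed model on the dates.

    ``records`` columns: id, cross, family, day, fed (0/1).  Individuals
    that never feed are flagged censored and excluded from the model.
    Returns (per-individual table, per-cross summary table).
    """
    fed = records["fed"].to_numpy()
    if not np.all(np.isin(np.unique(fed), [0, 1])):
        raise ValueError("one-zero records must be binary")
    rows = []
    for (iid, cross, fam), grp in records.groupby(["id", "cross", "family"], sort=False):
        g = grp.sort_values("day")
        hits = g.loc[g["fed"] == 1, "day"]
        if hits.empty:
            rows.append({"id": iid, "cross": cross, "family": fam,
                         "first_day": np.nan, "censored": True})
        else:
            rows.append({"id": iid, "cross": cross, "family": fam,
                         "first_day": float(hits.iloc[0]), "censored": False})
    onsets = pd.DataFrame(rows)

    fit_df = onsets[~onsets["censored"]]
    crosses = list(pd.unique(fit_df["cross"]))
    X = np.column_stack([(fit_df["cross"] == c).to_numpy(float) for c in crosses])
    samples = fit_gaussian(
        fit_df["first_day"].to_numpy(float),
        X,
        random=[RandomTerm("family", fit_df["family"].to_numpy())],
        prior_R=Prior(1.0, 0.002),
        chain=chain or ChainSettings(),
        fixed_names=crosses,
    )
    srows = []
    base = samples.fixed_draws(crosses[0])
    for c in crosses:
        d = samples.fixed_draws(c)
        mode, lo, hi = _summary(d)
        row = {"cross": c, "mode": mode, "lo": lo, "hi": hi}
        if c != crosses[0]:
            cmode, clo, chi = _summary(d - base)
            row |= {"contrast_mode": cmode, "contrast_lo": clo, "contrast_hi": chi}
        else:
            row |= {"contrast_mode": 0.0, "contrast_lo": np.nan, "contrast_hi": np.nan}
        srows.append(row)
    return onsets, pd.DataFrame(srows)


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------

def data_scale_binary_r(
    mu: float | np.ndarray,
    v_ind: float | np.ndarray,
    v_res: float | np.ndarray = 1.0,
    n_nodes: int = 61,
) -> np.ndarray:
    """Data-scale repeatability of a probit binary trait.

    Integrates the inverse link over the individual-effect distribution
    u ~ N(0, V_ind) by Gauss-Hermite quadrature: with p(u) =
    Phi((mu + u)/sqrt(V_res)), the observed-scale between-individual
    variance is Var_u p(u) and the within variance E_u p(u)(1 - p(u));
    their ratio to the total is the data-scale R.  This is the
    Jensen's-inequality-aware transformation: the ratio is computed from
    the integrated observed-scale variances, not by transforming the
    latent ratio."""
    nodes, weights = roots_hermitenorm(n_nodes)
    weights = weights / weights.sum()
    scalar = np.ndim(mu) == 0 and np.ndim(v_ind) == 0
    mu = np.atleast_1d(np.asarray(mu, float))
    v_ind = np.atleast_1d(np.asarray(v_ind, float))
    v_res = np.broadcast_to(np.asarray(v_res, float), v_ind.shape).astype(float)
    sd_i = np.sqrt(v_ind)[:, None]
    sd_e = np.sqrt(np.maximum(v_res, 1e-12))[:, None]
    p = ndtr((mu[:, None] + sd_i * nodes[None, :]) / sd_e)
    m1 = (weights * p).sum(axis=1)
    between = (weights * p**2).sum(axis=1) - m1**2
    within = (weights * p * (1 - p)).sum(axis=1)
    total = between + within
    out = np.where(total > 0, between / np.maximum(total, 1e-300), 0.0)
    return float(out[0]) if scalar else out


def probit_observed_mean(
    mu: float | np.ndarray,
    v_ind: float | np.ndarray,
    v_res: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Observed-scale success probability of a probit trait:
    E_u Phi((mu + u)/sd_res) = Phi(mu / sqrt(V_ind + V_res))."""
    mu = np.asarray(mu, float)
    return ndtr(mu / np.sqrt(np.asarray(v_ind, float) + np.asarray(v_res, float)))


def data_scale_count_r(mu, v_ind, v_res=0.0) -> np.ndarray:
    """Data-scale repeatability for a log-link Poisson trait with lognormal
    individual (and optional residual) effects, via the closed-form
    lognormal moments."""
    scalar = np.ndim(mu) == 0 and np.ndim(v_ind) == 0
    mu = np.atleast_1d(np.asarray(mu, float))
    v_ind = np.atleast_1d(np.asarray(v_ind, float))
    v_res = np.broadcast_to(np.asarray(v_res, float), v_ind.shape).astype(float)
    lam = np.exp(mu + (v_ind + v_res) / 2.0)
    between = lam**2 * (np.exp(v_ind) - 1.0)
    within = lam**2 * np.exp(v_ind) * (np.exp(v_res) - 1.0) + lam
    out = between / (between + within)
    return float(out[0]) if scalar else out


def repeatability(
    samples: PosteriorSamples,
    trait_family: str = "gaussian",
    term: str = "individual",
    trait: str = "",
    cross: str | None = None,
    intercept: str | None = None,
) -> RepeatabilityEstimate:
    """Adjusted repeatability from a fitted mixed model.

    The latent-scale R is V_ind / (V_ind + V_res) per posterior draw; for
    binary (probit) and count (log-Poisson) traits the data-scale R is
    additionally computed per draw by integrating the inverse link over
    the latent Gaussian.  Significance is read as the 95% CrI lower bound
    against zero."""
    if term not in samples.G:
        raise ValueError(
            f"model has no {term!r} random term; repeatability needs repeated "
            "records with an individual random effect"
        )
    v_ind = samples.G[term][:, 0, 0]
    v_res = samples.R[:, 0, 0]
    denom = v_ind + v_res
    latent = np.where(denom > 0, v_ind / np.where(denom > 0, denom, 1.0), 0.0)
    if np.allclose(v_ind, 0):
        est = RepeatabilityEstimate(trait, 0.0, 0.0, 0.0, cross=cross, latent_draws=latent)
        return est
    mode, lo, hi = _summary(latent)
    mode = float(np.clip(mode, 0.0, 1.0))
    est = RepeatabilityEstimate(
        trait, mode, max(lo, 0.0), min(hi, 1.0), cross=cross, latent_draws=latent
    )
    if trait_family == "gaussian":
        return est
    if intercept is None:
        intercept = samples.fixed_names[0]
    mu = samples.fixed_draws(intercept)
    if trait_family == "binary":
        data = data_scale_binary_r(mu, v_ind, v_res)
    elif trait_family == "count":
        data = data_scale_count_r(mu, v_ind, np.zeros_like(v_ind))
    else:
        raise ValueError(f"unknown trait family {trait_family!r}")
    dmode, dlo, dhi = _summary(data)
    est.data_mode = float(np.clip(dmode, 0.0, 1.0))
    est.data_lo = max(dlo, 0.0)
    est.data_hi = min(dhi, 1.0)
    est.data_draws = data
    return est
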
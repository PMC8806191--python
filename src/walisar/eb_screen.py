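"""Empirical-Bayes mixture screen for per-ORN valence effects.

The screen reduces each ORN's three-genotype score data to a single
moderated statistic and models the resulting Z scores as a two-component
mixture: a Gaussian null (no behavioral effect) plus a nonparametric
signal component, itself split into negative- and positive-valence
sub-components by the sign of Z.  The fit yields a signed posterior
probability of true behavioral change per ORN; its complement is the
local false discovery rate, and hit sets are reported at a bounded
average local FDR.

Statistics
----------
For ORN *i* with experimental mean ``M_exp`` and control-genotype means
``M_ctrl1``, ``M_ctrl2``::

    D_i = M_exp - (M_ctrl1 + M_ctrl2) / 2
    Z_i = D_i / (alpha0 + S_i)

where ``S_i`` is the standard error of ``D_i`` and ``alpha0`` — the
percentile "fudge factor" of moderated statistics — is the 90th
percentile of all ``S`` values, stabilising Z for ORNs with tiny
standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preference_metrics import delta_wtsale

__all__ = [
    "MixtureConfig",
    "MixtureFit",
    "PairedContrast",
    "summary_statistic",
    "build_screen_table",
    "moderated_z",
    "remove_outliers",
    "fit_mixture",
    "call_hits",
    "run_screen",
    "delta_delta",
]


@dataclass
class MixtureConfig:
    """Tunable knobs of the mixture fit.

    ``bandwidth`` is the base kernel rule for the signal density
    ("silverman" or a fixed float), scaled by ``bandwidth_scale``: the
    signal component is deliberately oversmoothed relative to a plain
    density estimate, which keeps a handful of chance tail values from
    manufacturing a sharp signal mode under the null.
    ``signal_zero_zone`` is the zero-assumption radius (in null-SD units):
    observations inside it contribute no support to the signal density,
    the standard identifiability device of two-groups models.  EM
    convergence is declared when the largest mixing-weight change drops
    below ``tol``.
    """

    bandwidth: str | float = "silverman"
    bandwidth_scale: float = 3.0
    signal_zero_zone: float = 1.0
    signal_weight_floor: float = 0.2
    tol: float = 1e-6
    max_iter: int = 500
    fdr_threshold: float = 0.25
    outlier_k: float = 20.0
    init_pi_null: float = 0.95


@dataclass
class MixtureFit:
    alpha0: float
    null_mean: float
    null_sd: float
    pi_null: float
    pi_neg: float
    pi_pos: float
    z_values: np.ndarray
    posteriors: np.ndarray  # signed, |posterior| = P(signal | z)
    converged: bool
    n_iter: int
    fdr_threshold: float = 0.25
    bandwidth: float = 1.0
    signal_points: np.ndarray = field(default_factory=lambda: np.empty(0))
    signal_weights: np.ndarray = field(default_factory=lambda: np.empty(0))

    def signal_density(self, z, sign: int) -> np.ndarray:
        """Evaluate the fitted nonparametric signal sub-density at ``z``."""
        mask = self.signal_points < 0 if sign < 0 else self.signal_points >= 0
        w = self.signal_weights * mask
        if w.sum() <= 0:
            return np.zeros_like(np.atleast_1d(np.asarray(z, dtype=float)))
        return _wkde(np.atleast_1d(np.asarray(z, dtype=float)),
                     self.signal_points, w, self.bandwidth)

    def posterior_at(self, z) -> np.ndarray:
        """Signed posterior for values not used in fitting (e.g. outliers)."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        f0 = stats.norm.pdf(z, self.null_mean, self.null_sd)
        fneg = self.signal_density(z, -1)
        fpos = self.signal_density(z, +1)
        mix = self.pi_null * f0 + self.pi_neg * fneg + self.pi_pos * fpos
        with np.errstate(invalid="ignore", divide="ignore"):
            p_sig = np.where(mix > 0, (self.pi_neg * fneg + self.pi_pos * fpos) / mix, 1.0)
        return np.sign(z) * np.clip(p_sig, 0.0, 1.0)


@dataclass
class PairedContrast:
    """ΔΔwTSALE: difference of valence effects between two conditions."""

    dd_stat: float
    ci_low: float
    ci_high: float
    pairing: str  # within_fly | between_cohort
    orn_label: str = ""
    intensity: str = ""

    def __post_init__(self) -> None:
        if self.pairing not in ("within_fly", "between_cohort"):
            raise ValueError("pairing must be within_fly or between_cohort")


# ---------------------------------------------------------------------------
# summary statistics


def summary_statistic(scores_exp, scores_ctrl1, scores_ctrl2) -> tuple[float, float]:
    """(D, S): control-averaged mean difference and its standard error."""
    groups = [np.asarray(g, dtype=float) for g in (scores_exp, scores_ctrl1, scores_ctrl2)]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >= 2 flies for a standard error")
    e, c1, c2 = groups
    d = e.mean() - (c1.mean() + c2.mean()) / 2.0
    s = np.sqrt(e.var(ddof=1) / e.size
                + (c1.var(ddof=1) / c1.size + c2.var(ddof=1) / c2.size) / 4.0)
    return float(d), float(s)


def build_screen_table(
    scores: pd.DataFrame,
    aggregate: str = "median",
) -> pd.DataFrame:
    """Per-ORN D and S from a tidy score table.

    With ``aggregate="median"`` (default) D and S are computed per
    intensity and collapsed to their across-intensity medians, mirroring
    the screen's use of the median effect across the three light levels;
    ``aggregate="none"`` keeps one row per ORN × intensity.
    """
    rows = []
    for (orn, inten), grp in scores.groupby(["orn_label", "intensity"], sort=True):
        d, s = summary_statistic(
            grp.loc[grp["role"] == "test", "wtsale"],
            grp.loc[grp["role"] == "ctrl_driver", "wtsale"],
            grp.loc[grp["role"] == "ctrl_responder", "wtsale"],
        )
        rows.append(dict(orn_label=orn, intensity=inten, d_stat=d, s_stat=s))
    table = pd.DataFrame(rows)
    if aggregate == "none":
        return table
    if aggregate != "median":
        raise ValueError("aggregate must be 'median' or 'none'")
    return (table.groupby("orn_label", sort=True)[["d_stat", "s_stat"]]
            .median().reset_index())


def moderated_z(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Attach Z = D / (alpha0 + S); alpha0 = 90th percentile of S (linear)."""
    if len(table) < 2:
        raise ValueError("need >= 2 rows to form the S percentile")
    s = table["s_stat"].to_numpy(dtype=float)
    if np.any(s < 0):
        raise ValueError("s_stat must be nonnegative")
    alpha0 = float(np.percentile(s, 90, method="linear"))
    out = table.copy()
    out["z_stat"] = out["d_stat"] / (alpha0 + s)
    return out, alpha0


def remove_outliers(z_values, k: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Median-absolute-deviation filter: drop |z - median| > k * MAD.

    Returns (kept_mask, removed_indices).  Removed items are still scored
    later by evaluating the fitted mixture at their Z values.  The default
    radius is deliberately wide: because the moderated null is tight, real
    screen hits sit at ~15-20 MAD, and the filter exists to drop corrupt
    values (orders of magnitude out), not strong biology.
    """
    z = np.asarray(z_values, dtype=float)
    med = np.median(z)
    mad = np.median(np.abs(z - med))
    if mad == 0:
        keep = np.ones(z.size, dtype=bool)
    else:
        keep = np.abs(z - med) <= k * mad
    if not keep.any():
        raise ValueError("outlier rule removed every value; loosen k")
    return keep, np.flatnonzero(~keep)


# ---------------------------------------------------------------------------
# mixture model


def _silverman(z: np.ndarray) -> float:
    sd = z.std(ddof=1)
    iqr = np.subtract(*np.percentile(z, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(sd, 1e-3)
    return 0.9 * spread * z.size ** (-1 / 5)


def _robust_scale(z: np.ndarray) -> float:
    """Bulk scale of z, insensitive to a minority of signal values.

    The max of three robust estimators (MAD, IQR, central-60%-trimmed SD,
    each normalised to the Gaussian).  Taking the max damps the downward
    sampling fluctuations of any single estimator, which would otherwise
    narrow the null and hand its tails to the signal component.
    """
    med = np.median(z)
    mad_sd = 1.4826 * np.median(np.abs(z - med))
    iqr_sd = float(np.subtract(*np.percentile(z, [75, 25]))) / 1.349
    lo, hi = np.percentile(z, [20, 80])
    core = z[(z >= lo) & (z <= hi)]
    # 0.4632 = SD of a standard normal truncated to its central 60%
    trim_sd = core.std(ddof=1) / 0.4632 if core.size > 3 else 0.0
    return max(mad_sd, iqr_sd, trim_sd, 1e-3)


def _wkde(x: np.ndarray, points: np.ndarray, weights: np.ndarray, h: float) -> np.ndarray:
    """Weighted Gaussian kernel density of ``points`` evaluated at ``x``."""
    w = weights / weights.sum()
    u = (x[:, None] - points[None, :]) / h
    return (np.exp(-0.5 * u * u) / (h * np.sqrt(2 * np.pi))) @ w


def _wkde_loo(points: np.ndarray, weights: np.ndarray, h: float) -> np.ndarray:
    """Leave-one-out weighted KDE at the support points themselves.

    Excluding each point's own kernel prevents an isolated observation
    from manufacturing signal density under itself during the EM fit.
    """
    n = points.size
    u = (points[:, None] - points[None, :]) / h
    K = np.exp(-0.5 * u * u) / (h * np.sqrt(2 * np.pi))
    np.fill_diagonal(K, 0.0)
    W = np.tile(weights, (n, 1))
    np.fill_diagonal(W, 0.0)
    denom = W.sum(axis=1)
    out = np.zeros(n)
    ok = denom > 0
    out[ok] = (K * W).sum(axis=1)[ok] / denom[ok]
    return out


def fit_mixture(z_values, config: MixtureConfig | None = None) -> MixtureFit:
    """Fit the Gaussian-null + nonparametric-signal mixture by EM.

    The E-step assigns each Z a posterior membership among null, negative
    signal, and positive signal; the M-step re-estimates the null Gaussian
    from null-weighted moments, the signal density as a signal-weighted
    kernel density (leave-one-out at the support points), and the mixing
    weights.  Convergence is on the mixing weights.  Non-convergence is
    reported in the returned fit, never silently.
    """
    cfg = config or MixtureConfig()
    z = np.asarray(z_values, dtype=float)
    if z.size < 5:
        raise ValueError("mixture fit needs at least 5 values")

    base_h = _silverman(z) if cfg.bandwidth == "silverman" else float(cfg.bandwidth)
    h = base_h * cfg.bandwidth_scale
    mu0 = float(np.median(z))
    sd_robust = _robust_scale(z)
    sd0 = sd_robust
    pi = np.array([cfg.init_pi_null,
                   (1 - cfg.init_pi_null) / 2,
                   (1 - cfg.init_pi_null) / 2])  # null, neg, pos

    # initial signal responsibilities from a broad provisional signal
    # density (3x the null scale): negligible in the bulk, rising in the
    # tails, so the EM starts from a tails-are-signal hypothesis
    f0 = stats.norm.pdf(z, mu0, sd0)
    f_broad = stats.norm.pdf(z, mu0, 3.0 * sd0)
    w_sig = (1 - pi[0]) * f_broad / (pi[0] * f0 + (1 - pi[0]) * f_broad)
    # responsibility floor: points that are only marginally signal-like
    # contribute nothing to the signal density, so a diffuse carpet of
    # borderline null values cannot sustain itself as pseudo-signal
    floor = cfg.signal_weight_floor
    w_sig = np.where(w_sig >= floor, w_sig, 0.0)
    neg, pos = z < 0, z >= 0

    converged = False
    n_iter = 0
    mask = np.abs(z - mu0) > cfg.signal_zero_zone * sd0
    for n_iter in range(1, cfg.max_iter + 1):
        # E-step pieces: signal densities from current responsibilities,
        # supported only outside the zero-assumption zone
        mask = np.abs(z - mu0) > cfg.signal_zero_zone * sd0
        fneg = _wkde_loo(z, w_sig * neg * mask + 1e-300, h)
        fpos = _wkde_loo(z, w_sig * pos * mask + 1e-300, h)
        f0 = stats.norm.pdf(z, mu0, sd0)
        num = np.vstack([pi[0] * f0, pi[1] * fneg, pi[2] * fpos])
        denom = num.sum(axis=0)
        denom[denom <= 0] = np.finfo(float).tiny
        r = num / denom

        pi_new = r.mean(axis=1)
        pi_new = pi_new / pi_new.sum()
        # M-step: null moments
        w0 = r[0]
        if w0.sum() > 0:
            mu0 = float(np.average(z, weights=w0))
            var0 = float(np.average((z - mu0) ** 2, weights=w0))
            # the null scale may not collapse below the robust bulk scale:
            # a shrinking null hands its own tails to the signal component
            # and spirals, the classic degeneracy of semiparametric mixtures
            sd0 = float(np.clip(np.sqrt(var0), 0.9 * sd_robust, 2.0 * sd_robust))
        w_sig = r[1] + r[2]
        w_sig = np.where(w_sig >= floor, w_sig, 0.0)

        if np.max(np.abs(pi_new - pi)) < cfg.tol:
            pi = pi_new
            converged = True
            break
        pi = pi_new

    # final posteriors: leave-one-out evaluation at the fitted points, so
    # no observation vouches for its own signal membership
    w_masked = w_sig * mask
    fneg_fin = _wkde_loo(z, w_masked * neg + 1e-300, h)
    fpos_fin = _wkde_loo(z, w_masked * pos + 1e-300, h)
    mix = pi[0] * stats.norm.pdf(z, mu0, sd0) + pi[1] * fneg_fin + pi[2] * fpos_fin
    mix[mix <= 0] = np.finfo(float).tiny
    p_sig = (pi[1] * fneg_fin + pi[2] * fpos_fin) / mix
    posteriors = np.sign(z) * np.clip(p_sig, 0.0, 1.0)

    return MixtureFit(
        alpha0=float("nan"), null_mean=mu0, null_sd=sd0,
        pi_null=float(pi[0]), pi_neg=float(pi[1]), pi_pos=float(pi[2]),
        z_values=z, posteriors=posteriors, converged=converged, n_iter=n_iter,
        fdr_threshold=cfg.fdr_threshold, bandwidth=h,
        signal_points=z, signal_weights=w_masked,
    )


def call_hits(fit: MixtureFit, posteriors: np.ndarray | None = None) -> np.ndarray:
    """Boolean hit mask at the fit's average-local-FDR threshold.

    Items are ranked by local FDR (1 − |posterior|); the reported set is
    the largest prefix whose *average* local FDR stays below the
    threshold, the posterior-probability analogue of an FDR cut.
    """
    post = fit.posteriors if posteriors is None else np.asarray(posteriors, dtype=float)
    lfdr = 1.0 - np.abs(post)
    # the reported set must be threshold-consistent: a posterior cutoff
    # includes whole groups of tied values or none of them
    best = None
    for v in np.unique(lfdr):
        members = lfdr <= v
        if lfdr[members].mean() < fit.fdr_threshold:
            best = members
    hits = np.zeros(lfdr.size, dtype=bool)
    if best is not None:
        hits[:] = best
    return hits


def run_screen(
    scores: pd.DataFrame,
    config: MixtureConfig | None = None,
    aggregate: str = "median",
) -> tuple[pd.DataFrame, MixtureFit, float]:
    """Score table → screen table with Z, posterior, local FDR and hit calls.

    Outliers (MAD rule) are excluded from the mixture fit but still
    receive posteriors by evaluating the fitted model at their Z.
    """
    cfg = config or MixtureConfig()
    table, alpha0 = moderated_z(build_screen_table(scores, aggregate=aggregate))
    z = table["z_stat"].to_numpy(dtype=float)
    keep, removed = remove_outliers(z, k=cfg.outlier_k)
    fit = fit_mixture(z[keep], cfg)
    fit.alpha0 = alpha0
    post = np.empty(z.size)
    post[keep] = fit.posteriors
    if removed.size:
        post[removed] = fit.posterior_at(z[removed])
    table = table.copy()
    table["posterior"] = post
    table["local_fdr"] = 1.0 - np.abs(post)
    table["hit"] = call_hits(fit, posteriors=post)
    table["sign"] = np.sign(post).astype(int)
    table["outlier"] = False
    table.loc[table.index[removed], "outlier"] = True
    return table, fit, alpha0


# ---------------------------------------------------------------------------
# condition contrasts


def _percentile_boot_delta(test, ctrl, reps, rng):
    """Vectorised bootstrap draws of mean(test) − mean(ctrl)."""
    t = rng.choice(test, size=(reps, test.size), replace=True).mean(axis=1)
    c = rng.choice(ctrl, size=(reps, ctrl.size), replace=True).mean(axis=1)
    return t - c


def delta_delta(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    pairing: str = "within_fly",
    bootstrap_reps: int = 5000,
    seed: int = 0,
    **meta,
) -> PairedContrast:
    """ΔΔwTSALE between two conditions (e.g. airflow on vs off).

    ``within_fly``: the same flies experienced both conditions; per-fly
    score differences (a − b) are formed first and their test − pooled
    control effect size is bootstrapped.  ``between_cohort``: different
    cohorts (e.g. fed vs starved); ΔwTSALE is computed per condition and
    the CI of their difference comes from independent bootstraps.
    """
    need = {"fly_id", "role", "wtsale"}
    for df in (scores_a, scores_b):
        if not need <= set(df.columns):
            raise ValueError(f"score tables need columns {sorted(need)}")

    if pairing == "within_fly":
        merged = scores_a.merge(scores_b, on=["fly_id", "role"], suffixes=("_a", "_b"))
        if len(merged) < len(scores_a) or len(merged) < len(scores_b):
            raise ValueError("within_fly pairing requires matched fly_ids in both conditions")
        merged["diff"] = merged["wtsale_a"] - merged["wtsale_b"]
        test = merged.loc[merged["role"] == "test", "diff"].to_numpy()
        c1 = merged.loc[merged["role"] == "ctrl_driver", "diff"].to_numpy()
        c2 = merged.loc[merged["role"] == "ctrl_responder", "diff"].to_numpy()
        eff = delta_wtsale(test, c1, c2, bootstrap_reps=bootstrap_reps, seed=seed)
        return PairedContrast(dd_stat=eff.delta, ci_low=eff.ci_low,
                              ci_high=eff.ci_high, pairing=pairing, **meta)

    if pairing != "between_cohort":
        raise ValueError("pairing must be within_fly or between_cohort")

    rng = np.random.default_rng(seed)
    deltas, boots = [], []
    for df in (scores_a, scores_b):
        test = df.loc[df["role"] == "test", "wtsale"].to_numpy(dtype=float)
        ctrl = df.loc[df["role"].isin(["ctrl_driver", "ctrl_responder"]),
                      "wtsale"].to_numpy(dtype=float)
        if test.size == 0 or ctrl.size == 0:
            raise ValueError("each condition needs test and control scores")
        deltas.append(test.mean() - ctrl.mean())
        boots.append(_percentile_boot_delta(test, ctrl, bootstrap_reps, rng))
    dd = float(deltas[0] - deltas[1])
    dist = boots[0] - boots[1]
    lo, hi = np.percentile(dist, [2.5, 97.5])
    return PairedContrast(dd_stat=dd, ci_low=float(min(lo, dd)),
                          ci_high=float(max(hi, dd)), pairing=pairing, **meta)
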
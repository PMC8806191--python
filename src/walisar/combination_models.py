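"""Models of two-channel valence combination.

Three pooling rules — summation, max-pooling, and min-pooling on absolute
value — predict the valence of co-activating two receptor-neuron classes
from the two single-class valences.  Agreement between predicted and
observed combination valence is quantified by R² and Bland–Altman limits
of agreement.  Channel weights are estimated by the bootstrap trio
regression: resampled single-fly scores from the three groups are rank-
paired into (channel-1, channel-2, combination) trios and a linear model
``combo = β0 + β1·s1 + β2·s2`` is fitted per bootstrap replicate.  The
point (β1, β2) relative to the diagonal β1 = β2 summarises whether one
channel dominates: the summation rule predicts points on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "ComboBeta",
    "pool_sum",
    "pool_max_abs",
    "pool_min_abs",
    "evaluate_agreement",
    "bootstrap_trio_regression",
    "beta_distance",
]


def pool_sum(i0: float, i1: float) -> float:
    """Summation pooling: the two valences simply add."""
    return i0 + i1


def pool_max_abs(i0: float, i1: float) -> float:
    """The input with the larger absolute value, sign preserved.

    On an exact absolute-value tie the first argument wins (relevant only
    for opposite-sign ties).
    """
    return i0 if abs(i0) >= abs(i1) else i1


def pool_min_abs(i0: float, i1: float) -> float:
    """The input with the smaller absolute value, sign preserved.

    Tie-break mirrors :func:`pool_max_abs`: the first argument wins, so
    the two poolings jointly return both inputs whenever |i0| ≠ |i1|.
    """
    return i0 if abs(i0) <= abs(i1) else i1


@dataclass
class AgreementReport:
    """R² plus Bland–Altman agreement between observed and predicted."""

    model_name: str
    r_squared: float
    r2_ci_low: float
    r2_ci_high: float
    bias: float  # mean(observed - predicted)
    loa_low: float  # bias - 1.96 SD of differences
    loa_high: float
    n: int
    degenerate: bool = False  # predicted series had zero variance

    def __post_init__(self) -> None:
        if not self.degenerate and not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


@dataclass
class ComboBeta:
    """Bootstrap β distributions for one channel pair."""

    pair_label: str
    intensity: str
    beta0_dist: np.ndarray
    beta1_dist: np.ndarray
    beta2_dist: np.ndarray
    beta0: float
    beta1: float
    beta2: float
    distance_from_diagonal: float
    signed_distance: float
    n_boot: int
    n_dropped: int
    seed: int


def evaluate_agreement(
    observed,
    predicted,
    bootstrap_reps: int = 5000,
    seed: int = 0,
    model_name: str = "",
) -> AgreementReport:
    """Method agreement between observed and model-predicted valences.

    R² is the ordinary least-squares coefficient of determination of
    observed on predicted, with a paired-bootstrap 95% CI.  Bland–Altman
    bias is the mean difference and the limits of agreement are
    bias ± 1.96 × SD of the differences.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need equal-length series with n >= 3")
    diff = obs - pred
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(pred) == 0:
        return AgreementReport(model_name, float("nan"), float("nan"), float("nan"),
                               bias, bias - 1.96 * sd, bias + 1.96 * sd,
                               obs.size, degenerate=True)
    r2 = float(stats.linregress(pred, obs).rvalue ** 2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, obs.size, size=(bootstrap_reps, obs.size))
    r2_boot = np.full(bootstrap_reps, np.nan)
    for b in range(bootstrap_reps):
        p, o = pred[idx[b]], obs[idx[b]]
        if np.ptp(p) > 0:
            r2_boot[b] = stats.linregress(p, o).rvalue ** 2
    lo, hi = np.nanpercentile(r2_boot, [2.5, 97.5])
    return AgreementReport(model_name, r2, float(lo), float(hi),
                           bias, bias - 1.96 * sd, bias + 1.96 * sd, obs.size)


def bootstrap_trio_regression(
    orn1_scores,
    orn2_scores,
    combo_scores,
    n_boot: int = 10000,
    seed: int = 0,
    pair_label: str = "",
    intensity: str = "",
) -> ComboBeta:
    """Bootstrap distribution of (β0, β1, β2) via rank-paired trios.

    Each replicate resamples every group with replacement at its own
    size, sorts each resample ascending, pairs rank-wise into trios
    (truncated to the smallest group), and fits the linear model by least
    squares.  Replicates with a singular design (e.g. a constant
    resampled channel) are dropped and counted.
    """
    # pre-sorting leaves the resampling distribution unchanged but makes
    # the result exactly invariant to the input ordering of flies
    g1, g2, gc = (np.sort(np.asarray(g, dtype=float))
                  for g in (orn1_scores, orn2_scores, combo_scores))
    if min(g1.size, g2.size, gc.size) < 3:
        raise ValueError("each group needs at least 3 flies")
    m = min(g1.size, g2.size, gc.size)
    rng = np.random.default_rng(seed)

    def resampled_sorted(g):
        idx = rng.integers(0, g.size, size=(n_boot, g.size))
        return np.sort(g[idx], axis=1)[:, :m]

    s1 = resampled_sorted(g1)
    s2 = resampled_sorted(g2)
    sc = resampled_sorted(gc)

    ones = np.ones((n_boot, m, 1))
    X = np.concatenate([ones, s1[..., None], s2[..., None]], axis=2)
    XtX = np.einsum("bij,bik->bjk", X, X)
    Xty = np.einsum("bij,bi->bj", X, sc)
    dets = np.linalg.det(XtX)
    scale = np.einsum("bii->b", XtX) / 3.0  # mean diagonal, for a relative cutoff
    ok = np.abs(dets) > 1e-10 * np.maximum(scale, 1.0) ** 3
    n_dropped = int(np.count_nonzero(~ok))
    if not ok.any():
        raise ValueError("all bootstrap replicates had singular designs "
                         "(constant score groups?)")
    betas = np.linalg.solve(XtX[ok], Xty[ok][..., None])[..., 0]
    b0, b1, b2 = betas[:, 0], betas[:, 1], betas[:, 2]
    med1, med2 = float(np.median(b1)), float(np.median(b2))
    dist, signed = beta_distance(med1, med2)
    return ComboBeta(
        pair_label=pair_label, intensity=intensity,
        beta0_dist=b0, beta1_dist=b1, beta2_dist=b2,
        beta0=float(np.median(b0)), beta1=med1, beta2=med2,
        distance_from_diagonal=dist, signed_distance=signed,
        n_boot=n_boot, n_dropped=n_dropped, seed=seed,
    )


def beta_distance(beta1_median: float, beta2_median: float) -> tuple[float, float]:
    """Perpendicular distance of (β1, β2) from the summation diagonal β1 = β2.

    The signed distance is positive when the first-listed channel
    dominates (β1 > β2).
    """
    signed = (beta1_median - beta2_median) / np.sqrt(2.0)
    return abs(signed), float(signed)
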
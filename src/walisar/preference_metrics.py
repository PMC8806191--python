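"""Light-preference metrics for single-fly optogenetic choice assays.

A fly confined to a narrow chamber chooses between a dark half and an
optogenetically illuminated half.  The per-fly preference score is TSALE
("time spent after light encounter"): once the fly first enters the lit
zone, the time it subsequently spends in the dark is subtracted from the
time spent in the light, normalised by the total post-encounter time.
Because a fly that discovers the light late conveys less information, the
score is down-weighted by the fraction of the lit phase remaining after
the first encounter, giving wTSALE.  Valence is then the mean difference
(ΔwTSALE) between a test genotype and the pooled driver + responder
controls, with a bootstrap confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FlyTrack",
    "EpochScore",
    "ValenceEffect",
    "first_light_encounter",
    "compute_wtsale",
    "score_tracks",
    "select_analysis_epoch",
    "delta_wtsale",
    "effect_table",
    "cohens_d",
]

ROLES = ("test", "ctrl_driver", "ctrl_responder")


@dataclass
class FlyTrack:
    """One fly's trajectory through a single protocol step.

    ``frames`` holds one row per video frame with columns ``time_s``
    (strictly increasing), ``x_mm`` (head position along the chamber) and
    ``lit_half`` (``"left"``, ``"right"`` or ``"none"``).
    """

    fly_id: str
    role: str
    orn_label: str
    intensity: str
    airflow: str
    step_index: int
    epoch: str  # "first" or "second" presentation of this condition
    frames: pd.DataFrame
    chamber_length_mm: float = 50.0

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("FlyTrack requires a nonempty frame sequence")
        t = np.asarray(self.frames["time_s"], dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def fly_half(self) -> np.ndarray:
        """Chamber half occupied per frame; the midline belongs to the lit half."""
        x = np.asarray(self.frames["x_mm"], dtype=float)
        lit = np.asarray(self.frames["lit_half"], dtype=object)
        mid = self.chamber_length_mm / 2.0
        half = np.where(x < mid, "left", "right").astype(object)
        on_line = x == mid
        half[on_line & (lit != "none")] = lit[on_line & (lit != "none")]
        return half

    def in_light(self) -> np.ndarray:
        """Boolean per frame: fly located in the currently lit half."""
        lit = np.asarray(self.frames["lit_half"], dtype=object)
        return (lit != "none") & (self.fly_half() == lit)

    def lit_phases(self) -> list[tuple[int, int]]:
        """Contiguous frame index ranges ``[start, stop)`` with any half lit."""
        lit = np.asarray(self.frames["lit_half"], dtype=object) != "none"
        edges = np.flatnonzero(np.diff(lit.astype(int)))
        bounds = np.concatenate(([0], edges + 1, [len(lit)]))
        return [
            (int(a), int(b))
            for a, b in zip(bounds[:-1], bounds[1:])
            if lit[a]
        ]


@dataclass
class EpochScore:
    """Per-fly preference score for one analyzed lit phase."""

    fly_id: str
    role: str
    orn_label: str
    intensity: str
    airflow: str
    step_index: int
    epoch: str
    tsale: float  # NaN when the fly never encountered the light
    weight: float
    wtsale: float


@dataclass
class ValenceEffect:
    """ΔwTSALE effect size (test − pooled control) with bootstrap CI."""

    delta: float
    ci_low: float
    ci_high: float
    n_test: int
    n_ctrl: int
    bootstrap_reps: int
    seed: int
    orn_label: str = ""
    intensity: str = ""
    airflow: str = ""
    ci_method: str = "BCa"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.delta <= self.ci_high):
            raise ValueError("CI bounds must bracket the point estimate")


def _phase_frames(track: FlyTrack, phase_index: int) -> tuple[int, int]:
    phases = track.lit_phases()
    if not phases:
        raise ValueError("track contains no lit phase")
    if phase_index >= len(phases):
        raise ValueError(
            f"track has {len(phases)} lit phases; phase_index {phase_index} out of range"
        )
    return phases[phase_index]


def first_light_encounter(track: FlyTrack, phase_index: int = 0) -> float | None:
    """Time (s) of the first frame inside the lit zone, or ``None``.

    Restricted to the requested lit phase (default: the first lit phase of
    the step, which is the analyzed test phase).
    """
    a, b = _phase_frames(track, phase_index)
    in_light = track.in_light()[a:b]
    hits = np.flatnonzero(in_light)
    if hits.size == 0:
        return None
    t = np.asarray(track.frames["time_s"], dtype=float)
    return float(t[a + hits[0]])


def compute_wtsale(track: FlyTrack, phase_index: int = 0) -> EpochScore:
    """TSALE and wTSALE for one lit phase of one fly.

    TSALE = (t_light − t_dark) / (t_light + t_dark) over the window from
    the first light encounter to the end of the lit phase.  The weight is
    that window's duration divided by the full phase duration; wTSALE is
    their product.  A fly that never enters the lit zone scores 0 with
    weight 0 (and is retained downstream).
    """
    a, b = _phase_frames(track, phase_index)
    t = np.asarray(track.frames["time_s"], dtype=float)[a:b]
    in_light = track.in_light()[a:b]

    # each frame covers one inter-frame interval; the last frame inherits
    # the median spacing so the phase duration is n_frames * dt on a
    # regular grid
    if len(t) > 1:
        dt = float(np.median(np.diff(t)))
    else:
        dt = 1.0
    total = len(t) * dt

    meta = dict(
        fly_id=track.fly_id, role=track.role, orn_label=track.orn_label,
        intensity=track.intensity, airflow=track.airflow,
        step_index=track.step_index, epoch=track.epoch,
    )
    hits = np.flatnonzero(in_light)
    if hits.size == 0:
        return EpochScore(**meta, tsale=float("nan"), weight=0.0, wtsale=0.0)

    post = in_light[hits[0]:]
    t_light = float(np.count_nonzero(post)) * dt
    t_dark = float(post.size - np.count_nonzero(post)) * dt
    if t_light + t_dark <= 0:
        return EpochScore(**meta, tsale=float("nan"), weight=0.0, wtsale=0.0)
    tsale = (t_light - t_dark) / (t_light + t_dark)
    weight = (t_light + t_dark) / total
    return EpochScore(**meta, tsale=tsale, weight=weight, wtsale=tsale * weight)


def score_tracks(tracks, phase_index: int = 0) -> pd.DataFrame:
    """Score a collection of tracks into a tidy per-fly score table."""
    rows = [compute_wtsale(tr, phase_index).__dict__ for tr in tracks]
    return pd.DataFrame(rows)


def select_analysis_epoch(scores: pd.DataFrame) -> pd.DataFrame:
    """Keep only second-epoch scores for effect-size computation.

    Each intensity × airflow condition is presented twice; the first
    presentation under-reports valence when the lit side is downwind, so
    only the second presentation enters the analysis.
    """
    if "epoch" not in scores.columns:
        raise ValueError("score table lacks an 'epoch' column")
    bad = set(scores["epoch"].unique()) - {"first", "second"}
    if bad:
        raise ValueError(f"unknown epoch labels: {sorted(bad)}")
    out = scores[scores["epoch"] == "second"].reset_index(drop=True)
    if out.empty:
        warnings.warn("no second-epoch scores present; result is empty")
    return out


def _mean_difference(test, ctrl, axis=-1):
    return np.mean(test, axis=axis) - np.mean(ctrl, axis=axis)


def delta_wtsale(
    test_scores,
    ctrl1_scores,
    ctrl2_scores,
    bootstrap_reps: int = 5000,
    seed: int = 0,
    ci_method: str = "BCa",
    **meta,
) -> ValenceEffect:
    """ΔwTSALE: mean(test) − mean(pooled controls), with bootstrap 95% CI.

    Driver and responder controls are pooled into one control group.  The
    CI is bias-corrected-and-accelerated by default (``ci_method="percentile"``
    selects the plain percentile interval).
    """
    test = np.asarray(test_scores, dtype=float)
    ctrl = np.concatenate(
        [np.asarray(ctrl1_scores, dtype=float), np.asarray(ctrl2_scores, dtype=float)]
    )
    if test.size == 0 or np.asarray(ctrl1_scores).size == 0 or np.asarray(ctrl2_scores).size == 0:
        raise ValueError("all three score groups must be nonempty")
    delta = float(np.mean(test) - np.mean(ctrl))

    if np.ptp(test) == 0 and np.ptp(ctrl) == 0:
        lo = hi = delta  # degenerate: resampling cannot vary the estimate
    else:
        method = {"BCa": "BCa", "percentile": "percentile"}[ci_method]
        res = stats.bootstrap(
            (test, ctrl),
            _mean_difference,
            n_resamples=bootstrap_reps,
            method=method,
            random_state=np.random.default_rng(seed),
        )
        lo = float(res.confidence_interval.low)
        hi = float(res.confidence_interval.high)
        lo, hi = min(lo, delta), max(hi, delta)
    return ValenceEffect(
        delta=delta, ci_low=lo, ci_high=hi,
        n_test=test.size, n_ctrl=ctrl.size,
        bootstrap_reps=bootstrap_reps, seed=seed, ci_method=ci_method, **meta,
    )


def effect_table(
    scores: pd.DataFrame,
    bootstrap_reps: int = 5000,
    seed: int = 0,
    ci_method: str = "BCa",
) -> pd.DataFrame:
    """Per ORN × intensity × airflow ΔwTSALE effects from a score table."""
    rows = []
    for i, ((orn, inten, air), grp) in enumerate(
        scores.groupby(["orn_label", "intensity", "airflow"], sort=True)
    ):
        eff = delta_wtsale(
            grp.loc[grp["role"] == "test", "wtsale"],
            grp.loc[grp["role"] == "ctrl_driver", "wtsale"],
            grp.loc[grp["role"] == "ctrl_responder", "wtsale"],
            bootstrap_reps=bootstrap_reps,
            seed=seed + i,
            ci_method=ci_method,
            orn_label=orn, intensity=inten, airflow=air,
        )
        rows.append(
            dict(orn_label=orn, intensity=inten, airflow=air, delta=eff.delta,
                 ci_low=eff.ci_low, ci_high=eff.ci_high, n_test=eff.n_test,
                 n_ctrl=eff.n_ctrl, reps=bootstrap_reps, seed=eff.seed)
        )
    return pd.DataFrame(rows)


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference, pooled-SD denominator."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)
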
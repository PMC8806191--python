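"""Synthetic data generators for the valence-screen pipeline.

Four generators mirror the statistical structure the analysis assumes:

* trajectory level — a bounded 1-D biased random walk through the 12-step
  choice protocol (3 light intensities × airflow on/off, each presented
  twice), with an additive drift toward the lit half whose sign and size
  encode the planted valence;
* score level — per-fly wTSALE draws from a truncated normal family, a
  fast testbed for the empirical-Bayes screen at full-screen scale;
* combination level — comonotonically coupled score trios (two single
  channels and their combination) following a planted linear rule;
* odor panel — a firing-rate matrix with low-dimensional latent structure
  and a valence that is linear in a subset of the latent factors.

Every generator is a deterministic function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preference_metrics import FlyTrack

__all__ = [
    "ProtocolSpec",
    "EffectSpec",
    "ComboTruth",
    "simulate_fly_track",
    "generate_cohort",
    "tracks_to_frame",
    "generate_screen_scores",
    "generate_combo_dataset",
    "generate_odor_panel",
    "STEP_SD_MM",
    "DRIFT_MM_PER_FRAME",
    "NULL_SCORE_SD",
]

# -- walk calibration ---------------------------------------------------------
# Per-frame Gaussian step of the random walk at the default 25 Hz frame
# rate.  This is an effective diffusion step, not a literal per-frame
# displacement: it is sized so the walker covers the 50-mm chamber on the
# ~5-s timescale a running fly does, which keeps the encounter-conditioned
# null bias of the preference metric small (see docs/methods.md).
STEP_SD_MM = 3.5
# Lit-ward drift per frame for a unit valence parameter.  Calibrated by
# Monte-Carlo over the default protocol so that valence 1.0 yields a mean
# wTSALE of ~0.5 in the analyzed lit phases.
DRIFT_MM_PER_FRAME = 0.275
# Spread of null per-fly wTSALE scores in the score-level generator,
# matching the within-genotype spread the trajectory walk produces.
NULL_SCORE_SD = 0.25


@dataclass
class ProtocolSpec:
    """Timing and geometry of the 12-step choice protocol.

    Each 180-s step runs: 30 s acclimatization, 45 s left half lit, 30 s
    dark, 45 s right half lit, 30 s dark.  Steps sweep three light
    intensities × airflow off/on, each condition presented twice
    (first/second epoch), totalling 12 steps.
    """

    epoch_duration_s: float = 180.0
    subphases_s: tuple = (30.0, 45.0, 30.0, 45.0, 30.0)
    light_intensities: tuple = ("14", "42", "70")
    airflow_states: tuple = ("off", "on")
    frame_rate_hz: float = 25.0
    chamber_length_mm: float = 50.0

    def __post_init__(self) -> None:
        if abs(sum(self.subphases_s) - self.epoch_duration_s) > 1e-9:
            raise ValueError("sub-phase durations must sum to epoch_duration_s")
        if self.n_steps != 12 and (
            len(self.light_intensities) == 3 and len(self.airflow_states) == 2
        ):
            raise AssertionError("default protocol must have 12 steps")

    @property
    def n_steps(self) -> int:
        return len(self.light_intensities) * len(self.airflow_states) * 2

    @property
    def frames_per_step(self) -> int:
        return int(round(self.epoch_duration_s * self.frame_rate_hz))

    def steps(self):
        """Yield (step_index, intensity, airflow, epoch, side_lit_first).

        Ascending-intensity order; the lit side of the leading phase
        alternates with the epoch (left first, then right).
        """
        idx = 0
        for inten in self.light_intensities:
            for air in self.airflow_states:
                for epoch, side in (("first", "left"), ("second", "right")):
                    idx += 1
                    yield idx, inten, air, epoch, side


@dataclass
class EffectSpec:
    """Planted valence for one ORN line and its cohort sizes."""

    orn_label: str
    true_valence_per_intensity: dict = field(default_factory=dict)
    n_test: int = 52
    n_ctrl1: int = 52
    n_ctrl2: int = 52

    def __post_init__(self) -> None:
        if min(self.n_test, self.n_ctrl1, self.n_ctrl2) <= 0:
            raise ValueError("cohort sizes must be positive")
        for v in self.true_valence_per_intensity.values():
            if not np.isfinite(v):
                raise ValueError("valence parameters must be finite")


@dataclass
class ComboTruth:
    """Planted linear combination rule combo = β0 + β1·s1 + β2·s2 + noise."""

    beta0: float
    beta1: float
    beta2: float
    noise_sd: float = 0.05
    n_flies: int = 52

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _lit_schedule(protocol: ProtocolSpec, side_lit_first: str) -> np.ndarray:
    """Per-frame lit_half labels over one step."""
    other = {"left": "right", "right": "left"}[side_lit_first]
    labels = ("none", side_lit_first, "none", other, "none")
    out = np.empty(protocol.frames_per_step, dtype=object)
    pos = 0
    for dur, lab in zip(protocol.subphases_s, labels):
        n = int(round(dur * protocol.frame_rate_hz))
        out[pos:pos + n] = lab
        pos += n
    out[pos:] = "none"
    return out


def _walk(
    rng: np.random.Generator,
    lit_half: np.ndarray,
    valence: float,
    protocol: ProtocolSpec,
    n_flies: int,
) -> np.ndarray:
    """Reflected biased random walks; returns positions (n_frames, n_flies).

    During lit phases each step gains an additive drift of
    ``valence * DRIFT_MM_PER_FRAME`` directed toward the lit half.
    """
    L = protocol.chamber_length_mm
    n = len(lit_half)
    direction = np.where(lit_half == "left", -1.0, np.where(lit_half == "right", 1.0, 0.0))
    x = rng.uniform(0.0, L, size=n_flies)
    out = np.empty((n, n_flies))
    out[0] = x
    steps = rng.normal(0.0, STEP_SD_MM, size=(n - 1, n_flies))
    drift = valence * DRIFT_MM_PER_FRAME
    for i in range(1, n):
        x = x + steps[i - 1] + drift * direction[i]
        x = np.abs(np.mod(x, 2.0 * L))
        x = np.where(x > L, 2.0 * L - x, x)
        out[i] = x
    return out


def simulate_fly_track(
    effect: EffectSpec,
    protocol: ProtocolSpec,
    intensity: str,
    airflow: str,
    side_lit_first: str = "left",
    seed: int = 0,
    role: str = "test",
    fly_id: str = "fly_0",
    step_index: int = 1,
    epoch: str = "first",
) -> FlyTrack:
    """Simulate one fly through one 180-s step.

    Control roles walk without drift; the test role drifts toward (or away
    from) the lit half according to the planted valence at this intensity.
    """
    if intensity not in protocol.light_intensities:
        raise ValueError(f"unknown intensity label {intensity!r}")
    valence = effect.true_valence_per_intensity.get(intensity, 0.0) if role == "test" else 0.0
    rng = np.random.default_rng(seed)
    lit = _lit_schedule(protocol, side_lit_first)
    x = _walk(rng, lit, valence, protocol, n_flies=1)[:, 0]
    frames = pd.DataFrame({
        "time_s": np.arange(len(lit)) / protocol.frame_rate_hz,
        "x_mm": x,
        "lit_half": lit,
    })
    return FlyTrack(
        fly_id=fly_id, role=role, orn_label=effect.orn_label,
        intensity=intensity, airflow=airflow, step_index=step_index,
        epoch=epoch, frames=frames, chamber_length_mm=protocol.chamber_length_mm,
    )


def generate_cohort(
    effect: EffectSpec,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
) -> list[FlyTrack]:
    """Full cohort: three genotype roles × all 12 steps × flies per role."""
    protocol = protocol or ProtocolSpec()
    ss = np.random.SeedSequence(seed)
    tracks: list[FlyTrack] = []
    role_n = {"test": effect.n_test, "ctrl_driver": effect.n_ctrl1,
              "ctrl_responder": effect.n_ctrl2}
    children = iter(ss.spawn(len(role_n) * protocol.n_steps))
    for role, n in role_n.items():
        for step_index, inten, air, epoch, side in protocol.steps():
            rng = np.random.default_rng(next(children))
            valence = (
                effect.true_valence_per_intensity.get(inten, 0.0)
                if role == "test" else 0.0
            )
            lit = _lit_schedule(protocol, side)
            xs = _walk(rng, lit, valence, protocol, n_flies=n)
            t = np.arange(len(lit)) / protocol.frame_rate_hz
            for j in range(n):
                frames = pd.DataFrame({"time_s": t, "x_mm": xs[:, j], "lit_half": lit})
                tracks.append(FlyTrack(
                    fly_id=f"{effect.orn_label}_{role}_{j}", role=role,
                    orn_label=effect.orn_label, intensity=inten, airflow=air,
                    step_index=step_index, epoch=epoch, frames=frames,
                    chamber_length_mm=protocol.chamber_length_mm,
                ))
    return tracks


def tracks_to_frame(tracks) -> pd.DataFrame:
    """Flatten tracks into the long trajectory table (one row per frame)."""
    parts = []
    for tr in tracks:
        df = tr.frames.copy()
        mid = tr.chamber_length_mm / 2.0
        df["fly_half"] = np.where(df["x_mm"].to_numpy() < mid, "left", "right")
        df.insert(0, "frame", np.arange(len(df)))
        for col, val in (
            ("airflow", tr.airflow), ("intensity", tr.intensity),
            ("step_index", tr.step_index), ("epoch", tr.epoch),
            ("orn_label", tr.orn_label), ("role", tr.role), ("fly_id", tr.fly_id),
        ):
            df.insert(0, col, val)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def _truncnorm(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """Normal draws truncated (by clipping) to the score range [-1, 1]."""
    return np.clip(rng.normal(mean, sd, size=size), -1.0, 1.0)


def generate_screen_scores(
    n_orns: int = 46,
    valent_fraction: float = 10 / 46,
    effect_size_distribution: dict | None = None,
    n_test: int = 52,
    n_ctrl: int = 104,
    seed: int = 0,
    intensities: tuple = ("14", "42", "70"),
    airflow: str = "off",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score-level screen dataset with ground-truth valence labels.

    Per-fly wTSALE draws come from a truncated normal with null SD
    ``NULL_SCORE_SD``; a ``valent_fraction`` of ORNs get their test-group
    mean shifted by an effect drawn from ``effect_size_distribution``
    (default: a fixed magnitude of 0.4 with random sign — well above the
    cohort-level noise, like the unambiguous hits of a real screen).

    Returns ``(scores, truth)``: a tidy score table and one row per ORN
    with its planted effect (0 for null ORNs).
    """
    if not 0 <= valent_fraction <= 1:
        raise ValueError("valent_fraction must lie in [0, 1]")
    dist = effect_size_distribution or {"kind": "fixed", "magnitude": 0.4}
    rng = np.random.default_rng(seed)
    n_valent = int(round(n_orns * valent_fraction))
    valent = rng.choice(n_orns, size=n_valent, replace=False)
    effects = np.zeros(n_orns)
    signs = rng.choice([-1.0, 1.0], size=n_valent)
    if dist["kind"] == "fixed":
        effects[valent] = signs * dist["magnitude"]
    elif dist["kind"] == "uniform":
        effects[valent] = signs * rng.uniform(dist["low"], dist["high"], size=n_valent)
    elif dist["kind"] == "normal":
        effects[valent] = rng.normal(dist["mean"], dist["sd"], size=n_valent) * signs
    else:
        raise ValueError(f"unknown effect_size_distribution kind {dist['kind']!r}")

    n_c1 = n_ctrl // 2
    n_c2 = n_ctrl - n_c1
    rows = []
    for i in range(n_orns):
        orn = f"Or{i:02d}"
        for inten in intensities:
            for role, n, mu in (
                ("test", n_test, effects[i]),
                ("ctrl_driver", n_c1, 0.0),
                ("ctrl_responder", n_c2, 0.0),
            ):
                w = _truncnorm(rng, mu, NULL_SCORE_SD, n)
                rows.append(pd.DataFrame({
                    "fly_id": [f"{orn}_{role}_{k}" for k in range(n)],
                    "role": role, "orn_label": orn, "intensity": inten,
                    "airflow": airflow, "epoch": "second", "wtsale": w,
                }))
    scores = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({
        "orn_label": [f"Or{i:02d}" for i in range(n_orns)],
        "true_effect": effects,
        "is_valent": effects != 0.0,
    })
    return scores, truth


def generate_combo_dataset(
    truth: ComboTruth,
    single_effects: tuple = (0.0, 0.0),
    seed: int = 0,
    score_sd: float = NULL_SCORE_SD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Comonotonically coupled single-channel and combination score samples.

    A shared standard-normal latent per trio drives both single-channel
    scores, so rank-pairing in the trio-regression estimator matches the
    generative coupling.  The combination score follows the planted linear
    rule plus Gaussian noise; all scores are truncated to [-1, 1].
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(size=truth.n_flies)
    mu1, mu2 = single_effects
    s1 = np.clip(mu1 + score_sd * z, -1.0, 1.0)
    s2 = np.clip(mu2 + score_sd * z, -1.0, 1.0)
    combo = truth.beta0 + truth.beta1 * s1 + truth.beta2 * s2
    if truth.noise_sd > 0:
        combo = combo + rng.normal(0.0, truth.noise_sd, size=truth.n_flies)
    combo = np.clip(combo, -1.0, 1.0)
    return s1, s2, combo


def generate_odor_panel(
    n_odors: int = 110,
    n_orns: int = 23,
    n_latent: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_valence_latent: int | None = None,
):
    """Odor panel with low-rank latent structure mapping activity to valence.

    Firing rates are a linear image of ``n_latent`` standard-normal latent
    factors (baseline 100 spikes/s, loading scale 30) plus optional
    Gaussian noise.  Valence is a linear function of the first
    ``n_valence_latent`` factors (default: all of them) plus noise of the
    same relative scale; class labels are the valence sign.

    Returns ``(firing, valence, labels, latent)`` with ``firing`` an
    odors × ORNs DataFrame and ``latent`` the ground-truth factor matrix.
    """
    if n_latent > n_orns:
        raise ValueError("n_latent must not exceed n_orns")
    k = n_valence_latent or n_latent
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=(n_odors, n_latent))
    loadings = rng.normal(size=(n_latent, n_orns)) / np.sqrt(n_latent)
    firing = 100.0 + 30.0 * (latent @ loadings)
    if noise_sd > 0:
        firing = firing + rng.normal(0.0, noise_sd, size=firing.shape)
    coef = rng.normal(size=k)
    valence = latent[:, :k] @ coef
    if noise_sd > 0:
        valence = valence + rng.normal(0.0, noise_sd / 30.0 * np.abs(coef).sum(),
                                       size=n_odors)
    firing_df = pd.DataFrame(
        firing,
        index=[f"odor_{i:03d}" for i in range(n_odors)],
        columns=[f"ORN_{j:02d}" for j in range(n_orns)],
    )
    valence_s = pd.Series(valence, index=firing_df.index, name="valence")
    labels = pd.Series(np.where(valence >= 0, "attractive", "aversive"),
                       index=firing_df.index, name="class_label")
    return firing_df, valence_s, labels, latent
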
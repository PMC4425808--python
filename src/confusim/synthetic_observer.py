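"""Synthetic observers: turn a design into hit/miss trial records.

Two generators are provided.

The *psychometric* generator draws each trial's outcome from a binomial
GLMM-type model: the logit of the hit probability is linear in the heading
unpredictability sigma with a slope that depends quadratically on object
density, plus a quadratic density main effect and a Gaussian per-subject
random intercept.  This is exactly the generative family the analysis
stage fits, so it supports parameter-recovery and model-selection studies.

The *mechanistic* observer actually tracks: it follows the target through
a simulated trajectory with noisy position estimates and per-frame
nearest-neighbour re-association, losing the target more often at high
density and high unpredictability, and clicks the final position of
whatever object it ends up tracking.  Its click-distance distribution is
bimodal (a near-zero mode for correct tracks, a broad mode for lost ones),
which is the reason the analysis binarises distance into hit/miss.

Default psychometric coefficients are chosen so that hit rates are near
ceiling at the lowest sigma in every condition, decline with sigma
everywhere, and decline fastest at intermediate-to-high density with a
slight recovery at the very highest density (the slope-vs-density profile
is an interior-minimum parabola).  Density enters centred and scaled
(D = (density - center)/scale) to keep the quadratic well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .motion_sim import TrajectorySet, _as_rng, admissible_bounds
from .units_design import DESIGN_COLUMNS

RESPONSE_COLUMNS = [
    "subject_id",
    "n_items",
    "area_side_px",
    "sigma",
    "density",
    "click_x",
    "click_y",
    "distance",
    "hit",
]

DEFAULT_OBJECT_SIDE_PX = 32


@dataclass(frozen=True)
class PsychometricParams:
    """Generative coefficients of the psychometric observer (logit scale).

    logit p(hit) = beta0 + u_subject + gamma1*D + gamma2*D^2
                   + (beta_u + delta1*D + delta2*D^2) * sigma

    with D the centred, scaled density and u_subject ~ Normal(0, tau^2).
    Defaults give ~0.93 hit rate at the lowest sigma level, a sigma slope
    ranging from about -2.7 (lowest density) to -10.9 (second-highest),
    easing back to about -8.5 at the highest density, and a density-flat
    profile at sigma = 0.
    """

    beta0: float = 3.0
    beta_u: float = -9.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    delta1: float = -5.0
    delta2: float = 2.5
    tau: float = 0.8
    density_center: float = 7.55
    density_scale: float = 7.0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        vals = [self.beta0, self.beta_u, self.gamma1, self.gamma2, self.delta1, self.delta2]
        if not np.all(np.isfinite(vals)):
            raise ValueError("coefficients must be finite")

    def scaled_density(self, density):
        return (np.asarray(density, dtype=float) - self.density_center) / self.density_scale

    def sigma_slope(self, density):
        """d logit / d sigma at a given raw density."""
        d = self.scaled_density(density)
        return self.beta_u + self.delta1 * d + self.delta2 * d**2


def _get(row, key):
    try:
        return row[key]
    except (TypeError, IndexError, KeyError):
        return getattr(row, key)


def hit_probability(row, params: PsychometricParams, u_subject: float = 0.0):
    """Generative hit probability for one design row at a given random intercept."""
    density = np.asarray(_get(row, "density"), dtype=float)
    sigma = np.asarray(_get(row, "sigma"), dtype=float)
    d = params.scaled_density(density)
    eta = (
        params.beta0
        + u_subject
        + params.gamma1 * d
        + params.gamma2 * d**2
        + (params.beta_u + params.delta1 * d + params.delta2 * d**2) * sigma
    )
    out = expit(eta)
    return float(out) if out.ndim == 0 else out


def score_click(click_xy, target_centre_xy, object_side_px: int = DEFAULT_OBJECT_SIDE_PX):
    """Distance and hit for a click: hit iff inside the target square footprint.

    The footprint boundary is inclusive: a click exactly half an object
    side from the centre counts as a hit.
    """
    click = np.asarray(click_xy, dtype=float)
    target = np.asarray(target_centre_xy, dtype=float)
    if not (np.all(np.isfinite(click)) and np.all(np.isfinite(target))):
        raise ValueError("coordinates must be finite")
    delta = click - target
    distance = float(np.hypot(delta[0], delta[1]))
    half = object_side_px / 2.0
    hit = int(abs(delta[0]) <= half and abs(delta[1]) <= half)
    return distance, hit


def _synth_click(hit, target_xy, lo, hi, half, rng):
    """Synthesise a click consistent with the hit flag.

    Hits land uniformly inside the target square; misses land uniformly on
    some other object's footprint (subjects click a bordered object at
    trial end), rejected until outside the target square.
    """
    if hit:
        return target_xy + rng.uniform(-half, half, size=2)
    while True:
        centre = rng.uniform(lo, hi, size=2)
        click = centre + rng.uniform(-half, half, size=2)
        if np.max(np.abs(click - target_xy)) > half:
            return click


def generate_responses(
    design: pd.DataFrame,
    params: PsychometricParams | None = None,
    rng_seed=None,
    object_side_px: int = DEFAULT_OBJECT_SIDE_PX,
) -> pd.DataFrame:
    """Simulate one hit/miss record per design row (psychometric observer).

    One random intercept per subject is drawn from Normal(0, tau^2), then
    each row's hit is Bernoulli at :func:`hit_probability`.  Click
    coordinates and click-to-target distance are synthesised consistently
    with the hit flag against a nominal target position drawn uniformly
    over the admissible centre region of that trial's arena.
    """
    if len(design) == 0:
        raise ValueError("design is empty")
    if params is None:
        params = PsychometricParams()
    rng = _as_rng(rng_seed)
    df = design.reset_index(drop=True)

    subjects = np.unique(df["subject_id"].to_numpy())
    u_map = dict(zip(subjects, rng.normal(0.0, params.tau, size=len(subjects))))
    u = df["subject_id"].map(u_map).to_numpy(dtype=float)

    p = hit_probability(df, params, u)
    hit = (rng.uniform(size=len(df)) < p).astype(int)

    half = object_side_px / 2.0
    sides = df["area_side_px"].to_numpy(dtype=float)
    lo = half
    his = sides - half
    target_x = rng.uniform(lo, his)
    target_y = rng.uniform(lo, his)

    clicks = np.empty((len(df), 2))
    dists = np.empty(len(df))
    for i in range(len(df)):
        t_xy = np.array([target_x[i], target_y[i]])
        clicks[i] = _synth_click(hit[i], t_xy, lo, his[i], half, rng)
        dists[i], scored = score_click(clicks[i], t_xy, object_side_px)
        assert scored == hit[i]

    return pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "n_items": df["n_items"],
            "area_side_px": df["area_side_px"],
            "sigma": df["sigma"],
            "density": df["density"],
            "click_x": clicks[:, 0],
            "click_y": clicks[:, 1],
            "distance": dists,
            "hit": hit,
        }
    )


def mechanistic_observer(traj: TrajectorySet, attention_noise: float, rng) -> tuple:
    """Track the target through a trial; return the final click (x, y).

    The observer knows the target at frame 0 (it is highlighted).  On each
    subsequent frame it forms a noisy estimate of the tracked object's
    position (isotropic Gaussian, SD ``attention_noise`` px) and
    re-associates to the nearest object centre.  With zero noise the
    association is always correct; as noise grows relative to
    inter-object spacing, the track jumps to distractors more often, and
    more readily in dense displays.
    """
    if attention_noise < 0:
        raise ValueError("attention_noise must be non-negative")
    rng = _as_rng(rng)
    tracked = traj.target_index
    for t in range(1, traj.n_frames):
        estimate = traj.positions[t, tracked] + rng.normal(0.0, attention_noise, size=2)
        d2 = np.sum((traj.positions[t] - estimate) ** 2, axis=1)
        tracked = int(np.argmin(d2))
    final = traj.positions[-1, tracked]
    return float(final[0]), float(final[1])


def respond_mechanistic(
    traj: TrajectorySet, attention_noise: float, rng
) -> tuple[float, int, tuple]:
    """Run the mechanistic observer and score its click against the target."""
    click = mechanistic_observer(traj, attention_noise, rng)
    target_xy = traj.positions[-1, traj.target_index]
    distance, hit = score_click(click, target_xy, traj.object_side_px)
    return distance, hit, click


def write_responses_csv(responses: pd.DataFrame, path) -> None:
    responses.loc[:, RESPONSE_COLUMNS].to_csv(path, index=False)


def read_responses_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response file missing columns: {sorted(missing)}")
    return df
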
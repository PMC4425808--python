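"""Display geometry, unit conversions, unpredictability levels, and the factorial design.

The tracking display is a square window of trinary-noise texture shown on a
100 Hz monitor at a viewing distance where one pixel subtends 2 minutes of
visual arc.  Angular conversions therefore use the small-angle linear map
``degrees = pixels * pitch / 60``; at this pitch and display sizes up to
~13 degrees the tangent correction would change the result by well under 1%.

Unpredictability is the standard deviation, in radians, of the per-frame
change of an object's heading.  The seven default levels are evenly
log-spaced from pi/2**6 to pi/2**3 (consecutive ratio sqrt(2)).

Density is expressed in items per 10^4 px^2: raw items/px^2 would be ~5e-4
over the design range and make GLMM covariates badly scaled.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

MINARC_PER_DEG = 60.0
#: area unit for density: items per 10^4 px^2
DENSITY_UNIT_PX2 = 1.0e4

DEFAULT_ITEMS_LEVELS = (20, 40, 80)
DEFAULT_AREA_LEVELS = (190, 268, 380)
DEFAULT_N_SUBJECTS = 24
#: trials per subject per condition (not dictated by the design itself)
DEFAULT_REPLICATES = 4

DESIGN_COLUMNS = ["subject_id", "n_items", "area_side_px", "sigma", "density", "replicate"]


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of the display window the objects move in.

    Parameters
    ----------
    width_px, height_px : int
        Window size in pixels.
    pixel_pitch : float
        Angular size of one pixel in minutes of arc (default 2 minarc/px).
    frame_rate : float
        Display refresh rate in Hz (default 100 Hz).
    viewing_distance : float
        Observer distance in cm (default 59 cm, the distance at which the
        default pitch holds); recorded for provenance, not used in the
        linear angular map.
    """

    width_px: int
    height_px: int
    pixel_pitch: float = 2.0
    frame_rate: float = 100.0
    viewing_distance: float = 59.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @classmethod
    def square(cls, side_px: int, **kwargs) -> "ArenaSpec":
        return cls(width_px=side_px, height_px=side_px, **kwargs)

    @property
    def width_deg(self) -> float:
        return px_to_deg(self.width_px, self.pixel_pitch)

    @property
    def height_deg(self) -> float:
        return px_to_deg(self.height_px, self.pixel_pitch)

    def to_config(self) -> str:
        """Serialise as ``key: value`` structured text."""
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_config(cls, text_or_stream) -> "ArenaSpec":
        if isinstance(text_or_stream, (str, bytes)):
            text_or_stream = io.StringIO(
                text_or_stream.decode() if isinstance(text_or_stream, bytes) else text_or_stream
            )
        return cls(**yaml.safe_load(text_or_stream))


@dataclass(frozen=True)
class DesignRow:
    """One row of the factorial design (schema of the design table)."""

    subject_id: int
    n_items: int
    area_side_px: int
    sigma: float
    density: float
    replicate: int


def px_to_deg(pixels, pitch: float = 2.0):
    """Convert a pixel extent to degrees of visual angle (linear map)."""
    pixels = np.asarray(pixels, dtype=float)
    if np.any(pixels < 0):
        raise ValueError("pixel extent must be non-negative")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    out = pixels * pitch / MINARC_PER_DEG
    return float(out) if out.ndim == 0 else out


def deg_to_px(degrees, pitch: float = 2.0):
    """Inverse of :func:`px_to_deg`."""
    degrees = np.asarray(degrees, dtype=float)
    if np.any(degrees < 0):
        raise ValueError("angular extent must be non-negative")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    out = degrees * MINARC_PER_DEG / pitch
    return float(out) if out.ndim == 0 else out


def unpredictability_levels(
    low_exponent: float = 6.0, high_exponent: float = 3.0, n_levels: int = 7
) -> np.ndarray:
    """Evenly log-spaced heading-noise levels ``pi / 2**e``, ascending.

    The default grid is pi/2**6 .. pi/2**3 in seven steps, i.e. exponents
    6, 5.5, 5, 4.5, 4, 3.5, 3 — consecutive levels differ by a factor of
    sqrt(2).  ``low_exponent`` is the exponent of the *lowest* (most
    predictable) level, hence must exceed ``high_exponent``.
    """
    if n_levels < 2:
        raise ValueError("need at least two levels")
    if not low_exponent > high_exponent:
        raise ValueError("low_exponent must exceed high_exponent")
    exponents = np.linspace(low_exponent, high_exponent, n_levels)
    return np.pi / 2.0 ** exponents


def density_of(n_items, area_side_px) -> float:
    """Object density in items per 10^4 px^2 of a square display."""
    n_items = np.asarray(n_items, dtype=float)
    area_side_px = np.asarray(area_side_px, dtype=float)
    if np.any(n_items < 0):
        raise ValueError("n_items must be non-negative")
    if np.any(area_side_px <= 0):
        raise ValueError("area side must be positive")
    out = DENSITY_UNIT_PX2 * n_items / area_side_px**2
    return float(out) if out.ndim == 0 else out


def build_design(
    n_subjects: int = DEFAULT_N_SUBJECTS,
    items_levels=DEFAULT_ITEMS_LEVELS,
    area_levels=DEFAULT_AREA_LEVELS,
    sigma_levels=None,
    replicates: int = DEFAULT_REPLICATES,
    shuffle_within_subject: bool = False,
    rng_seed: int | None = None,
) -> pd.DataFrame:
    """Fully crossed subjects x items x areas x sigma x replicates design.

    Every subject sees every condition.  Row order is deterministic
    (subject-major, then items, areas, sigma, replicate); with
    ``shuffle_within_subject`` each subject's trial order is permuted
    reproducibly from ``rng_seed``.

    Returns a DataFrame with columns :data:`DESIGN_COLUMNS`.
    """
    if sigma_levels is None:
        sigma_levels = unpredictability_levels()
    items_levels = list(items_levels)
    area_levels = list(area_levels)
    sigma_levels = list(np.asarray(sigma_levels, dtype=float))
    if n_subjects < 1 or replicates < 1:
        raise ValueError("n_subjects and replicates must be >= 1")
    if not items_levels or not area_levels or not sigma_levels:
        raise ValueError("all factor level lists must be non-empty")

    rows = [
        (s, n, a, sig, density_of(n, a), r)
        for s in range(n_subjects)
        for n, a, sig, r in itertools.product(
            items_levels, area_levels, sigma_levels, range(replicates)
        )
    ]
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    if shuffle_within_subject:
        rng = np.random.default_rng(rng_seed)
        parts = []
        for _, grp in design.groupby("subject_id", sort=True):
            parts.append(grp.iloc[rng.permutation(len(grp))])
        design = pd.concat(parts, ignore_index=True)
    return design


def write_design_csv(design: pd.DataFrame, path) -> None:
    design.loc[:, DESIGN_COLUMNS].to_csv(path, index=False)


def read_design_csv(path) -> pd.DataFrame:
    design = pd.read_csv(path)
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design file missing columns: {sorted(missing)}")
    return design
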
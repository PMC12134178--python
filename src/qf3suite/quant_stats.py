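"""Image-derived quantification statistics.

Covers the per-cell statistics used to quantify proximity-ligation (PLA)
dot assays and fraction-positive apoptosis scoring: dot counts normalised
to cell area, per-experiment treated/control density ratios, paired
Student's t tests on log-transformed ratios (the pairing unit is the
independent experiment), plain one/two-tailed two-sample t tests, percent
of positive cells, and a minimal Laplacian-of-Gaussian dot detector with a
matching synthetic dot-image generator.

Areas are in arbitrary (pixel-like) units; every reported statistic is a
ratio or a test on ratios, so no physical calibration is needed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

__all__ = [
    "CellMeasurement",
    "normalized_density",
    "condition_fold_ratio",
    "paired_log_ttest",
    "fraction_positive",
    "two_sample_ttest",
    "detect_dots",
    "synthetic_dot_image",
]

CELL_TABLE_COLUMNS = [
    "cell_id",
    "condition",
    "experiment_id",
    "dot_count",
    "cell_area",
    "positive_flag",
]


@dataclass(frozen=True)
class CellMeasurement:
    cell_id: int
    condition: str
    experiment_id: int
    dot_count: int
    cell_area: float
    positive_flag: bool = False

    def __post_init__(self) -> None:
        if self.dot_count < 0:
            raise ValueError("dot_count must be non-negative")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")


def _as_frame(cells) -> pd.DataFrame:
    if isinstance(cells, pd.DataFrame):
        return cells
    return pd.DataFrame([vars(c) if not isinstance(c, dict) else c for c in cells])


def normalized_density(cells):
    """Dots per unit cell area.

    Accepts a single CellMeasurement (returns a float) or a table (returns
    a Series aligned with the rows).
    """
    if isinstance(cells, CellMeasurement):
        return cells.dot_count / cells.cell_area
    df = _as_frame(cells)
    if (df["cell_area"] <= 0).any():
        raise ValueError("cell_area must be positive for every cell")
    return df["dot_count"] / df["cell_area"]


def condition_fold_ratio(treated, control) -> pd.Series:
    """Per-experiment ratio of mean normalised dot density, treated over
    control, indexed by experiment_id."""
    t, c = _as_frame(treated), _as_frame(control)
    if t.empty or c.empty:
        raise ValueError("both cohorts must be non-empty")
    t_mean = normalized_density(t).groupby(t["experiment_id"]).mean()
    c_mean = normalized_density(c).groupby(c["experiment_id"]).mean()
    shared = t_mean.index.intersection(c_mean.index)
    if shared.empty:
        raise ValueError("no experiment_id shared between the cohorts")
    if (c_mean[shared] == 0).any():
        bad = list(c_mean[shared][c_mean[shared] == 0].index)
        raise ValueError(f"control mean density is zero in experiments {bad}")
    ratios = t_mean[shared] / c_mean[shared]
    ratios.name = "fold_ratio"
    return ratios


def paired_log_ttest(a, b=None, tails: int = 2) -> tuple[float, int, float]:
    """Paired Student's t test after natural-log transformation.

    With two arrays, tests log(a_i) vs log(b_i) pairwise.  With a single
    array of per-experiment ratios, tests log(ratio) against 0 — the exact
    one-sample equivalent of pairing the treated and control means.
    Returns (t, df, p); df = n - 1.  One-tailed p is directional for
    a > b (ratio > 1).
    """
    a = np.asarray(a, dtype=float)
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if b is not None:
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log transform requires strictly positive values")
        d = np.log(a) - np.log(b)
    else:
        if np.any(a <= 0):
            raise ValueError("log transform requires strictly positive ratios")
        d = np.log(a)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        # zero spread: identical pairs give t = 0; a constant nonzero
        # log-ratio is infinitely significant by this statistic
        t = 0.0 if d.mean() == 0 else math.inf * float(np.sign(d.mean()))
    else:
        t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = float(stats.t.sf(t, df)) if tails == 1 else float(2 * stats.t.sf(abs(t), df))
    return t, df, p


def fraction_positive(cells, min_cells: int = 100, allow_small: bool = False) -> float:
    """Percent of cells with a set positive flag (e.g. diffuse cytochrome c,
    exposed Bax N-terminus, cleaved caspase-3).

    Cohorts below ``min_cells`` raise unless ``allow_small``, in which case
    a warning is emitted and the percentage is still returned.
    """
    df = _as_frame(cells)
    if df.empty:
        raise ValueError("empty cohort")
    n = len(df)
    if n < min_cells:
        if not allow_small:
            raise ValueError(f"cohort has {n} cells; at least {min_cells} required")
        warnings.warn(f"cohort has only {n} cells (minimum {min_cells})", stacklevel=2)
    return 100.0 * float(df["positive_flag"].sum()) / n


def two_sample_ttest(a, b, tails: int = 2, paired: bool = False) -> tuple[float, int, float]:
    """Student's t test between two groups (pooled variance when unpaired).

    Returns (t, df, p).  One-tailed p is directional for mean(a) > mean(b),
    so for t > 0 it is exactly half the two-tailed p.  Degenerate data with
    zero variance and equal means yield t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        d = a - b
        df = d.size - 1
        sd = d.std(ddof=1)
        t = 0.0 if sd == 0 and d.mean() == 0 else float(d.mean() / (sd / math.sqrt(d.size))) if sd > 0 else math.inf * np.sign(d.mean())
    else:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        se = math.sqrt(sp2 * (1 / a.size + 1 / b.size))
        diff = a.mean() - b.mean()
        t = 0.0 if se == 0 and diff == 0 else float(diff / se) if se > 0 else math.inf * np.sign(diff)
    p = float(stats.t.sf(t, df)) if tails == 1 else float(2 * stats.t.sf(abs(t), df))
    return float(t), int(df), p


def detect_dots(
    image: np.ndarray,
    threshold_sigma: float = 5.0,
    min_separation: int = 3,
    spot_sigma: float = 1.5,
) -> tuple[np.ndarray, int]:
    """Count diffraction-limited dots via Laplacian-of-Gaussian peaks.

    The LoG response (sign-flipped so bright spots are maxima) is
    thresholded at ``median + threshold_sigma * MAD-sigma`` of the
    response — a robust background estimate invariant to constant offsets
    — and local maxima closer than ``min_separation`` pixels merge into
    one detection.  Returns (sorted (row, col) coordinates, count); a
    blank image returns zero dots.
    """
    from skimage.feature import peak_local_max

    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        return np.empty((0, 2), dtype=int), 0
    response = -ndi.gaussian_laplace(img, sigma=spot_sigma)
    med = np.median(response)
    mad_sigma = 1.4826 * np.median(np.abs(response - med))
    threshold = med + threshold_sigma * (mad_sigma if mad_sigma > 0 else response.std())
    coords = peak_local_max(
        response, min_distance=min_separation, threshold_abs=threshold, exclude_border=False
    )
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    return coords, int(coords.shape[0])


def synthetic_dot_image(
    shape: tuple[int, int] = (128, 128),
    centers=None,
    n_dots: int = 0,
    amplitude: float = 100.0,
    sigma: float = 1.5,
    background: float = 10.0,
    noise_sd: float = 1.0,
    min_separation: int = 6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic PLA-like image: Gaussian spots on a noisy background.

    Provide ``centers`` explicitly or ask for ``n_dots`` spots placed at
    random with at least ``min_separation`` pixels between them.  Returns
    (image, centers used).
    """
    rng = np.random.default_rng(seed)
    if centers is None:
        centers = []
        attempts = 0
        margin = int(3 * sigma) + 1
        while len(centers) < n_dots and attempts < 10000:
            cand = rng.integers(margin, np.array(shape) - margin)
            if all(np.hypot(*(cand - np.array(c))) >= min_separation for c in centers):
                centers.append(tuple(int(v) for v in cand))
            attempts += 1
    centers = np.asarray(centers, dtype=int).reshape(-1, 2)
    img = np.full(shape, float(background))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c in centers:
        img += amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, shape)
    return img, centers
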
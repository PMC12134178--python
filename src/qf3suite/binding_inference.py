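"""Binding-curve inference from per-ROI FLIM-FRET records.

Per-ROI (free acceptor concentration, delta_omega) records are gated to
the physiological donor window, binned along the acceptor axis, averaged
across replicates, and fitted to the Hill equation with h = 1:

    delta_omega(x) = Bmax * x / (Kd + x)

The binding-vs-collision decision uses two gates taken together:

* the shape ratio (s-ratio): trapezoid area under the curve, measured from
  its minimum, divided by the complementary area of the bounding box.  A
  straight line gives exactly 1; a saturating curve gives > 1.  Binding
  requires s-ratio >= 2.
* the fitted amplitude: Bmax must exceed 0.05 rad, guaranteeing dynamic
  range well above the per-ROI noise floor.

Curves that fail either gate are reported as collisions together with
their ordinary-least-squares linear fit, whose slope estimates the
collisional FRET coefficient (rad/uM).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "BindingCurve",
    "HillFit",
    "LinearFit",
    "InteractionCall",
    "DEFAULT_BIN_EDGES",
    "filter_and_bin",
    "average_replicates",
    "s_ratio",
    "fit_hill",
    "fit_linear",
    "classify_interaction",
    "run_qf3_pipeline",
]

#: default free-acceptor bin edges in uM over the 0-50 uM screening range
DEFAULT_BIN_EDGES = (0.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0)

S_THRESHOLD = 2.0
BMAX_THRESHOLD = 0.05  # rad
KD_UPPER_BOUND_UM = 500.0


@dataclass
class BindingCurve:
    """Binned binding-curve points, strictly increasing in free acceptor.

    ``free_acceptor_uM`` holds the mean free-acceptor concentration of the
    ROIs in each bin (a better abscissa than the geometric bin center when
    ROIs are unevenly distributed within a bin); ``bin_edges`` retains the
    grid so replicate curves can be matched bin-by-bin.
    """

    free_acceptor_uM: np.ndarray
    delta_omega_mean: np.ndarray
    sem: np.ndarray
    n_rois: np.ndarray
    bin_index: np.ndarray
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    replicate_id: int | None = None
    donor_gate: tuple[float, float] = (1.0, 3.0)
    acceptor_gate: tuple[float, float] = (0.0, 50.0)

    def __post_init__(self) -> None:
        for name in ("free_acceptor_uM", "delta_omega_mean", "sem", "n_rois", "bin_index"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        x = self.free_acceptor_uM
        if x.size and (np.any(np.diff(x) <= 0) or np.any(x < 0)):
            raise ValueError("curve points must be strictly increasing in free acceptor")

    def __len__(self) -> int:
        return int(self.free_acceptor_uM.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "free_acceptor_uM": self.free_acceptor_uM,
                "delta_omega_mean": self.delta_omega_mean,
                "sem": self.sem,
                "n_rois": self.n_rois.astype(int),
            }
        )


@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill fit; ``kd_at_bound`` flags an estimate pinned at
    the optimiser's upper Kd bound (non-saturating data)."""

    bmax: float
    kd_uM: float
    h: float
    rss: float
    background_slope: float = 0.0
    kd_at_bound: bool = False

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.bmax * x**self.h / (self.kd_uM**self.h + x**self.h) + self.background_slope * x


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    rss: float

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class InteractionCall:
    """Binding-vs-collision verdict with all intermediate statistics."""

    verdict: str  # "binding" | "collision"
    s_ratio: float
    bmax: float
    kd_uM: float
    slope: float
    hill: HillFit | None
    linear: LinearFit
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in ("binding", "collision"):
            raise ValueError("verdict must be 'binding' or 'collision'")


def _as_roi_frame(rois) -> pd.DataFrame:
    if isinstance(rois, pd.DataFrame):
        return rois
    if hasattr(rois, "rois"):  # QF3Dataset
        return rois.rois
    return pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in rois])


def filter_and_bin(
    rois,
    donor_gate: tuple[float, float] = (1.0, 3.0),
    acceptor_gate: tuple[float, float] = (0.0, 50.0),
    bin_edges=DEFAULT_BIN_EDGES,
    min_rois_per_bin: int = 20,
    replicate_id: int | None = None,
) -> BindingCurve:
    """Gate ROIs to the physiological concentration windows and bin them
    by free acceptor concentration.

    Bins with fewer than ``min_rois_per_bin`` ROIs are dropped (logged).
    Raises with a breakdown of rejection reasons if nothing survives.
    """
    df = _as_roi_frame(rois)
    if df.empty:
        raise ValueError("no ROIs supplied")
    edges = np.asarray(bin_edges, dtype=float)
    in_donor = (df["donor_uM"] >= donor_gate[0]) & (df["donor_uM"] <= donor_gate[1])
    in_acceptor = (df["acceptor_uM"] >= acceptor_gate[0]) & (df["acceptor_uM"] <= acceptor_gate[1])
    kept = df[in_donor & in_acceptor]
    if kept.empty:
        raise ValueError(
            "all ROIs rejected by the concentration gates: "
            f"{int((~in_donor).sum())} outside donor gate {donor_gate}, "
            f"{int((~in_acceptor).sum())} outside acceptor gate {acceptor_gate}"
        )
    x = kept["free_acceptor_uM"].to_numpy()
    y = kept["delta_omega"].to_numpy()
    idx = np.digitize(x, edges) - 1  # bin i covers [edges[i], edges[i+1])
    valid = (idx >= 0) & (idx < edges.size - 1)
    rows = []
    for b in range(edges.size - 1):
        sel = valid & (idx == b)
        n = int(sel.sum())
        if n == 0:
            continue
        if n < min_rois_per_bin:
            logger.info("dropping bin [%g, %g) uM with only %d ROIs", edges[b], edges[b + 1], n)
            continue
        yb = y[sel]
        rows.append(
            (
                b,
                float(x[sel].mean()),
                float(yb.mean()),
                float(yb.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
                n,
            )
        )
    if not rows:
        raise ValueError(f"no bin reached min_rois_per_bin = {min_rois_per_bin}")
    rows.sort(key=lambda r: r[1])
    b, xm, ym, sem, n = zip(*rows)
    if replicate_id is None and "replicate" in kept.columns and kept["replicate"].nunique() == 1:
        replicate_id = int(kept["replicate"].iloc[0])
    return BindingCurve(
        free_acceptor_uM=np.array(xm),
        delta_omega_mean=np.array(ym),
        sem=np.array(sem),
        n_rois=np.array(n),
        bin_index=np.array(b),
        bin_edges=tuple(edges),
        replicate_id=replicate_id,
        donor_gate=donor_gate,
        acceptor_gate=acceptor_gate,
    )


def average_replicates(curves: list[BindingCurve]) -> BindingCurve:
    """Unweighted average of replicate binding curves, matched by bin.

    Bins present in only a subset of replicates are averaged over those
    present (logged); ROI counts are summed.
    """
    if not curves:
        raise ValueError("no curves to average")
    grids = {c.bin_edges for c in curves}
    if len(grids) > 1:
        raise ValueError("replicate curves use incompatible bin grids")
    if len(curves) == 1:
        return curves[0]
    bins = sorted({int(b) for c in curves for b in c.bin_index})
    xm, ym, sem, ns = [], [], [], []
    for b in bins:
        xs, ys, ss, n = [], [], [], 0
        for c in curves:
            hit = np.flatnonzero(c.bin_index == b)
            if hit.size:
                i = int(hit[0])
                xs.append(c.free_acceptor_uM[i])
                ys.append(c.delta_omega_mean[i])
                ss.append(c.sem[i])
                n += int(c.n_rois[i])
        if len(xs) < len(curves):
            logger.info("bin %d present in %d/%d replicates", b, len(xs), len(curves))
        xm.append(np.mean(xs))
        ym.append(np.mean(ys))
        sem.append(math.sqrt(np.sum(np.square(ss))) / len(ss))
        ns.append(n)
    return BindingCurve(
        free_acceptor_uM=np.array(xm),
        delta_omega_mean=np.array(ym),
        sem=np.array(sem),
        n_rois=np.array(ns),
        bin_index=np.array(bins, dtype=float),
        bin_edges=curves[0].bin_edges,
        replicate_id=None,
        donor_gate=curves[0].donor_gate,
        acceptor_gate=curves[0].acceptor_gate,
    )


def s_ratio(curve: BindingCurve | None = None, x=None, y=None) -> float:
    """Shape ratio of a binding curve.

    With the data's own extremes as the box boundaries: trapezoid area
    between the curve and its minimum, divided by the complementary area of
    the bounding box.  Exactly 1 for any straight line through the points;
    grows with curvature toward saturation.  Invariant under affine maps of
    both axes.
    """
    if curve is not None:
        x = curve.free_acceptor_uM
        y = curve.delta_omega_mean
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("s-ratio needs at least 3 points")
    span_y = float(y.max() - y.min())
    if span_y <= 0:
        raise ValueError("degenerate (flat) curve: s-ratio undefined")
    auc = float(np.trapezoid(y - y.min(), x))
    box = float((x.max() - x.min()) * span_y)
    above = box - auc
    if above <= 0:
        return math.inf
    return auc / above


def _hill_model(x, bmax, kd, h=1.0, c=0.0):
    return bmax * x**h / (kd**h + x**h) + c * x


def fit_hill(
    curve: BindingCurve,
    h: float = 1.0,
    with_background: bool = False,
    weighted: bool = False,
) -> HillFit:
    """Least-squares Hill fit with fixed Hill constant ``h``.

    Multi-start in Kd (5, 15, 40 uM), Bmax in [0, 1] rad, Kd in
    (0, 500] uM; unweighted on the bin means by default, SEM-weighted on
    request.  ``with_background`` adds a linear collision term ``c*x``.
    A Kd pinned at the upper bound (non-saturating data) is flagged, not
    an error.
    """
    x = curve.free_acceptor_uM
    y = curve.delta_omega_mean
    if x.size < 3 or np.ptp(x) <= 0:
        raise ValueError("Hill fit needs >= 3 points spanning a nonzero acceptor range")
    sigma = None
    if weighted:
        sigma = np.where(curve.sem > 0, curve.sem, np.nanmax(curve.sem) or 1.0)
    bmax0 = max(float(y.max()), 1e-6)
    best = None
    for kd0 in (5.0, 15.0, 40.0):
        if with_background:
            p0 = [bmax0, kd0, 0.0]
            bounds = ([0.0, 1e-9, -1.0], [1.0, KD_UPPER_BOUND_UM, 1.0])
            model = lambda x, bmax, kd, c: _hill_model(x, bmax, kd, h, c)
        else:
            p0 = [bmax0, kd0]
            bounds = ([0.0, 1e-9], [1.0, KD_UPPER_BOUND_UM])
            model = lambda x, bmax, kd: _hill_model(x, bmax, kd, h)
        try:
            popt, _ = optimize.curve_fit(
                model, x, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - model(x, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise RuntimeError("Hill fit did not converge from any start")
    rss, popt = best
    bmax, kd = float(popt[0]), float(popt[1])
    c = float(popt[2]) if with_background else 0.0
    # non-saturating data ride the Bmax/Kd ridge: either parameter pinned
    # at its bound with Kd beyond the sampled range means Kd is not
    # identifiable from these points
    pinned = kd > 0.99 * KD_UPPER_BOUND_UM or (bmax > 0.99 and kd > float(np.max(x)))
    return HillFit(
        bmax=bmax,
        kd_uM=kd,
        h=h,
        rss=rss,
        background_slope=c,
        kd_at_bound=pinned,
    )


def fit_linear(curve: BindingCurve | None = None, x=None, y=None) -> LinearFit:
    """Ordinary least-squares line through the curve points."""
    if curve is not None:
        x, y = curve.free_acceptor_uM, curve.delta_omega_mean
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("linear fit needs at least 2 points")
    res = stats.linregress(x, y)
    rss = float(np.sum((y - (res.slope * x + res.intercept)) ** 2))
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept), rss=rss)


def classify_interaction(
    curve: BindingCurve,
    s_threshold: float = S_THRESHOLD,
    bmax_threshold: float = BMAX_THRESHOLD,
) -> InteractionCall:
    """Binding iff s-ratio >= ``s_threshold`` AND fitted Bmax >
    ``bmax_threshold``; otherwise collision with the linear fit reported.

    A flat (zero-dynamic-range) curve cannot support either model and is
    reported as collision with a ``degenerate`` diagnostic instead of
    raising.
    """
    linear = fit_linear(curve)
    diagnostics: dict = {
        "n_points": len(curve),
        "n_rois_used": int(curve.n_rois.sum()),
        "rss_linear": linear.rss,
        "s_threshold": s_threshold,
        "bmax_threshold": bmax_threshold,
    }
    try:
        s = s_ratio(curve)
    except ValueError as err:
        diagnostics["degenerate"] = str(err)
        return InteractionCall(
            verdict="collision",
            s_ratio=float("nan"),
            bmax=float("nan"),
            kd_uM=float("nan"),
            slope=linear.slope,
            hill=None,
            linear=linear,
            diagnostics=diagnostics,
        )
    hill = fit_hill(curve)
    diagnostics["rss_hill"] = hill.rss
    diagnostics["kd_at_bound"] = hill.kd_at_bound
    is_binding = s >= s_threshold and hill.bmax > bmax_threshold
    return InteractionCall(
        verdict="binding" if is_binding else "collision",
        s_ratio=s,
        bmax=hill.bmax,
        kd_uM=hill.kd_uM,
        slope=linear.slope,
        hill=hill,
        linear=linear,
        diagnostics=diagnostics,
    )


def kd_confidence_interval(
    curve: BindingCurve,
    hill: HillFit,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Residual-resampling bootstrap percentile CI for Kd."""
    rng = np.random.default_rng(seed)
    x = curve.free_acceptor_uM
    resid = curve.delta_omega_mean - hill.predict(x)
    kds = []
    for _ in range(n_boot):
        yb = hill.predict(x) + rng.choice(resid, size=resid.size, replace=True)
        fake = BindingCurve(
            free_acceptor_uM=x,
            delta_omega_mean=yb,
            sem=curve.sem,
            n_rois=curve.n_rois,
            bin_index=curve.bin_index,
            bin_edges=curve.bin_edges,
        )
        try:
            kds.append(fit_hill(fake, h=hill.h).kd_uM)
        except RuntimeError:
            continue
    if not kds:
        return (float("nan"), float("nan"))
    lo, hi = np.percentile(kds, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return (float(lo), float(hi))


def run_qf3_pipeline(
    replicates,
    donor_gate: tuple[float, float] = (1.0, 3.0),
    acceptor_gate: tuple[float, float] = (0.0, 50.0),
    bin_edges=DEFAULT_BIN_EDGES,
    min_rois_per_bin: int = 20,
    s_threshold: float = S_THRESHOLD,
    bmax_threshold: float = BMAX_THRESHOLD,
    kd_ci: bool = False,
) -> tuple[InteractionCall, BindingCurve]:
    """Full inference chain: gate and bin each replicate, average the
    replicate curves, classify binding vs collision.

    ``replicates`` may be a list of per-replicate ROI tables/datasets or a
    single table with a ``replicate`` column.  Errors are re-raised with
    the failing stage named.
    """
    if isinstance(replicates, pd.DataFrame) and "replicate" in replicates.columns:
        replicates = [g for _, g in replicates.groupby("replicate", sort=True)]
    elif not isinstance(replicates, (list, tuple)):
        replicates = [replicates]
    if len(replicates) == 0:
        raise ValueError("pipeline stage filter_and_bin: no replicates supplied")
    curves = []
    for i, rep in enumerate(replicates):
        try:
            curves.append(
                filter_and_bin(
                    rep,
                    donor_gate=donor_gate,
                    acceptor_gate=acceptor_gate,
                    bin_edges=bin_edges,
                    min_rois_per_bin=min_rois_per_bin,
                )
            )
        except ValueError as err:
            raise ValueError(f"pipeline stage filter_and_bin (replicate {i}): {err}") from err
    try:
        avg = average_replicates(curves)
    except ValueError as err:
        raise ValueError(f"pipeline stage average_replicates: {err}") from err
    try:
        call = classify_interaction(avg, s_threshold=s_threshold, bmax_threshold=bmax_threshold)
    except (ValueError, RuntimeError) as err:
        raise type(err)(f"pipeline stage classify_interaction: {err}") from err
    if kd_ci and call.hill is not None:
        call.diagnostics["kd_ci"] = kd_confidence_interval(avg, call.hill)
    return call, avg


def report_dict(call: InteractionCall, curve: BindingCurve) -> dict:
    """JSON-ready summary of a pipeline run."""
    return {
        "verdict": call.verdict,
        "s_ratio": call.s_ratio,
        "bmax": call.bmax,
        "kd_uM": call.kd_uM,
        "kd_ci": call.diagnostics.get("kd_ci"),
        "slope": call.slope,
        "rss_hill": call.diagnostics.get("rss_hill"),
        "rss_linear": call.diagnostics.get("rss_linear"),
        "n_rois_used": call.diagnostics.get("n_rois_used"),
        "filters": {
            "donor_gate_uM": list(curve.donor_gate),
            "acceptor_gate_uM": list(curve.acceptor_gate),
            "bin_edges_uM": list(curve.bin_edges),
        },
    }
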
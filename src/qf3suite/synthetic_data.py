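"""Synthetic-data generators for every stage of the suite.

The qF3 generator emulates the structure of a live-cell FLIM-FRET screen:
per-ROI donor concentrations in the narrow physiological 1-3 uM window,
acceptor concentrations spanning 0-50 uM (log-uniform by default, because
high-intensity ROIs are rare in real screens so linear-uniform sampling
would overpopulate the high bins relative to practice), and a FRET readout
delta_omega that either saturates with a 1:1 binding equilibrium or grows
linearly with acceptor concentration (collisions).

In binding mode the noiseless readout is ``dmax * f`` where ``f`` is the
equilibrium bound fraction of the donor and ``dmax`` is the phase-angle
change corresponding to full quenching of the donor lifetime from
``tau_donor`` to ``tau_donor * (1 - e_fret)``.  Because a 1:1 equilibrium
gives ``f = A_free / (Kd + A_free)`` exactly, the generated curve is an
exact Hill curve (h = 1) in the *free* acceptor concentration, which is
what the inference stage recovers.

Per-ROI measurement noise on delta_omega is Gaussian (sd 0.01 rad by
default); the photon-level generator instead produces Poisson-distributed
TCSPC histograms of a two-lifetime exponential mixture so the phasor stage
can be exercised end-to-end with shot noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import phasor_flim
from .phasor_flim import DecayHistogram, ROI_TABLE_COLUMNS, analytic_phasor

__all__ = [
    "GeneratorConfig",
    "QF3Dataset",
    "equilibrium_bound",
    "e_fret_for_delta_omega_max",
    "simulate_qf3_dataset",
    "simulate_decay_histograms",
    "simulate_pla_counts",
    "implant_motif",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: floor used when a log-uniform acceptor range starts at 0 uM
_LOG_UNIFORM_FLOOR_UM = 0.05


@dataclass
class GeneratorConfig:
    """Parameters of the qF3 generative model.

    mode 'binding' produces saturating curves governed by ``kd_uM`` and
    ``e_fret``; 'collision' produces delta_omega linear in the acceptor
    concentration with slope ``collision_coeff``; 'mixed' superimposes a
    collision background on a binding curve.
    """

    seed: int = 0
    n_rois: int = 3000
    donor_range_uM: tuple[float, float] = (1.0, 3.0)
    acceptor_range_uM: tuple[float, float] = (0.0, 50.0)
    kd_uM: float = 16.3
    e_fret: float = 0.3
    collision_coeff: float = 0.003  # rad per uM
    tau_donor_ns: float = 3.8
    laser_period_ns: float = 12.5  # 80 MHz repetition
    n_time_bins: int = 256
    photons_per_roi: float = 20000.0
    noise_sd: float = 0.01  # rad
    mode: str = "binding"
    acceptor_log_uniform: bool = True

    def __post_init__(self) -> None:
        lo_d, hi_d = self.donor_range_uM
        lo_a, hi_a = self.acceptor_range_uM
        if lo_d < 0 or lo_a < 0 or lo_d > hi_d or lo_a > hi_a:
            raise ValueError("concentration ranges must be non-negative with low <= high")
        if self.kd_uM <= 0:
            raise ValueError("kd_uM must be positive")
        if not 0 < self.e_fret <= 1:
            raise ValueError("e_fret must be in (0, 1]")
        if self.tau_donor_ns <= 0 or self.laser_period_ns <= 0:
            raise ValueError("tau_donor_ns and laser_period_ns must be positive")
        if self.mode not in ("binding", "collision", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def omega(self) -> float:
        """First-harmonic angular frequency 2*pi/period, rad/ns."""
        return 2.0 * math.pi / self.laser_period_ns

    @property
    def tau_bound_ns(self) -> float:
        """Donor lifetime of the FRET-quenched (bound) species."""
        return self.tau_donor_ns * (1.0 - self.e_fret)

    @property
    def delta_omega_max(self) -> float:
        """Phase-angle change for a fully bound donor population."""
        return phasor_flim.delta_omega(
            analytic_phasor(self.tau_bound_ns, self.omega), self.tau_donor_ns, self.omega
        )


def e_fret_for_delta_omega_max(
    target_rad: float, tau_donor_ns: float = 3.8, laser_period_ns: float = 12.5
) -> float:
    """FRET efficiency whose fully-bound phase shift equals ``target_rad``.

    Inverts delta_omega_max: atan(w*tau_d) - atan(w*tau_d*(1-E)) = target.
    Convenient for parameterising the generator by the curve amplitude
    (Bmax, in radians) instead of by E.
    """
    omega = 2.0 * math.pi / laser_period_ns
    phi_donor = math.atan(omega * tau_donor_ns)
    phi_bound = phi_donor - target_rad
    if not 0.0 <= phi_bound < phi_donor:
        raise ValueError("target phase shift out of the attainable range")
    tau_bound = math.tan(phi_bound) / omega
    return 1.0 - tau_bound / tau_donor_ns


@dataclass
class QF3Dataset:
    """Simulated per-ROI table plus the generating truth."""

    rois: pd.DataFrame
    config: GeneratorConfig

    @property
    def true_delta_omega_max(self) -> float:
        return self.config.delta_omega_max


def equilibrium_bound(donor_uM, acceptor_uM, kd_uM):
    """Bound complex concentration of a 1:1 equilibrium, in uM.

    Exact root of Kd = (D - B)(A - B)/B:

        B = ((D + A + Kd) - sqrt((D + A + Kd)^2 - 4 D A)) / 2

    evaluated in the cancellation-safe form 2DA / (S + sqrt(S^2 - 4DA)).
    Always satisfies 0 <= B <= min(D, A).  Accepts scalars or arrays.
    """
    D = np.asarray(donor_uM, dtype=float)
    A = np.asarray(acceptor_uM, dtype=float)
    if np.any(D < 0) or np.any(A < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(np.asarray(kd_uM) <= 0):
        raise ValueError("kd_uM must be positive")
    S = D + A + kd_uM
    disc = np.sqrt(np.maximum(S * S - 4.0 * D * A, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.where(S + disc > 0, 2.0 * D * A / (S + disc), 0.0)
    B = np.minimum(B, np.minimum(D, A))
    return float(B) if B.ndim == 0 else B


def _sample_acceptor(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    lo, hi = config.acceptor_range_uM
    if not config.acceptor_log_uniform:
        return rng.uniform(lo, hi, config.n_rois)
    lo_eff = max(lo, _LOG_UNIFORM_FLOOR_UM)
    if hi <= lo_eff:
        return np.full(config.n_rois, hi)
    return np.exp(rng.uniform(math.log(lo_eff), math.log(hi), config.n_rois))


def simulate_qf3_dataset(config: GeneratorConfig, replicate_id: int = 0) -> QF3Dataset:
    """Draw one replicate of per-ROI qF3 records under ``config``.

    Deterministic given (config, replicate_id): the stream is seeded from
    ``config.seed`` and the replicate index.
    """
    rng = np.random.default_rng((config.seed, replicate_id))
    if config.n_rois == 0:
        warnings.warn("n_rois = 0: returning an empty dataset", stacklevel=2)
        empty = pd.DataFrame(columns=ROI_TABLE_COLUMNS)
        return QF3Dataset(rois=empty, config=config)

    donor = rng.uniform(*config.donor_range_uM, config.n_rois)
    acceptor = _sample_acceptor(rng, config)

    dmax = config.delta_omega_max
    if config.mode == "collision":
        bound = np.zeros_like(donor)
        noiseless = config.collision_coeff * acceptor
    else:
        bound = equilibrium_bound(donor, acceptor, config.kd_uM)
        with np.errstate(invalid="ignore"):
            frac = np.where(donor > 0, bound / donor, 0.0)
        noiseless = dmax * frac
        if config.mode == "mixed":
            noiseless = noiseless + config.collision_coeff * (acceptor - bound)
    frac = np.where(donor > 0, bound / donor, 0.0)
    observed = noiseless + rng.normal(0.0, config.noise_sd, config.n_rois)
    photons = rng.poisson(config.photons_per_roi, config.n_rois) if config.photons_per_roi > 0 else np.zeros(config.n_rois)

    rois = pd.DataFrame(
        {
            "roi_id": np.arange(config.n_rois),
            "replicate": replicate_id,
            "donor_uM": donor,
            "acceptor_uM": acceptor,
            "free_acceptor_uM": acceptor - bound,
            "delta_omega": observed,
            "n_photons": photons,
            "true_bound_fraction": frac,
        }
    )
    return QF3Dataset(rois=rois, config=config)


def simulate_replicates(config: GeneratorConfig, n_replicates: int = 3) -> list[QF3Dataset]:
    """Independent replicates sharing one config; replicate r uses the
    stream seeded by (config.seed, r)."""
    return [simulate_qf3_dataset(config, replicate_id=r) for r in range(n_replicates)]


def _bin_probabilities(tau_ns: float, n_bins: int, period_ns: float) -> np.ndarray:
    """Exact per-bin emission probability of a truncated exponential."""
    edges = np.linspace(0.0, period_ns, n_bins + 1)
    cdf = 1.0 - np.exp(-edges / tau_ns)
    p = np.diff(cdf)
    return p / p.sum()


def simulate_decay_histograms(dataset: QF3Dataset, config: GeneratorConfig | None = None) -> list[DecayHistogram]:
    """Poisson TCSPC histograms for each ROI of a simulated dataset.

    Each decay is an intensity mixture of the unbound (tau_donor) and bound
    (tau_donor*(1-e_fret)) species with weights (1-f, f) taken from the
    ROI's true bound fraction, discretised over one laser period and
    sampled bin-wise as Poisson counts.
    """
    config = config or dataset.config
    if config.photons_per_roi <= 0:
        raise ValueError("photons_per_roi must be positive")
    if config.n_time_bins < 2:
        raise ValueError("need at least 2 time bins to resolve a phase")
    rng = np.random.default_rng((config.seed, 104729))  # sub-stream distinct from replicates
    p_free = _bin_probabilities(config.tau_donor_ns, config.n_time_bins, config.laser_period_ns)
    p_bound = _bin_probabilities(config.tau_bound_ns, config.n_time_bins, config.laser_period_ns)
    bin_width = config.laser_period_ns / config.n_time_bins
    out = []
    for f in dataset.rois["true_bound_fraction"].to_numpy():
        p = (1.0 - f) * p_free + f * p_bound
        counts = rng.poisson(config.photons_per_roi * p)
        out.append(DecayHistogram(counts=counts, bin_width_ns=bin_width, period_ns=config.laser_period_ns))
    return out


def simulate_pla_counts(
    n_cells: int,
    base_density: float,
    fold: float,
    area_lognorm: tuple[float, float] = (6.0, 0.4),
    seed: int = 0,
    n_experiments: int = 1,
) -> pd.DataFrame:
    """Paired control/treated PLA dot-count cohorts.

    Cell areas are LogNormal(mu, sigma) (arbitrary area units, pixel-like);
    dot counts are Poisson with expectation ``density * area`` where the
    control density is ``base_density`` and the treated density is
    ``base_density * fold``.  Each experiment contributes its own pair of
    cohorts drawn from one seeded stream, mimicking independent biological
    replicates that are later compared with a paired test.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if base_density < 0 or fold < 0:
        raise ValueError("base_density and fold must be non-negative")
    mu, sigma = area_lognorm
    rng = np.random.default_rng(seed)
    frames = []
    for exp in range(n_experiments):
        for condition, density in (("control", base_density), ("treated", base_density * fold)):
            area = rng.lognormal(mu, sigma, n_cells)
            counts = rng.poisson(density * area)
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": np.arange(n_cells),
                        "condition": condition,
                        "experiment_id": exp,
                        "dot_count": counts,
                        "cell_area": area,
                        "positive_flag": False,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def implant_motif(
    background_length: int,
    motif: str,
    position: int,
    seed: int = 0,
    composition: dict[str, float] | None = None,
) -> tuple[str, tuple[int, int]]:
    """Random protein sequence with ``motif`` placed verbatim at a 1-based
    ``position``; returns (sequence, (start, end)) with inclusive 1-based
    ground-truth coordinates.

    Background residues are i.i.d. uniform over the 20 standard amino
    acids unless ``composition`` maps residues to weights.
    """
    motif = motif.upper()
    if background_length < len(motif):
        raise ValueError("motif longer than the background sequence")
    if not 1 <= position <= background_length - len(motif) + 1:
        raise ValueError("implant position out of range")
    if any(aa not in AMINO_ACIDS for aa in motif):
        raise ValueError("motif contains non-standard residues")
    rng = np.random.default_rng(seed)
    if composition is None:
        letters, probs = list(AMINO_ACIDS), None
    else:
        letters = list(composition)
        w = np.array([composition[aa] for aa in letters], dtype=float)
        probs = w / w.sum()
    seq = rng.choice(letters, size=background_length, p=probs)
    start = position - 1
    seq[start : start + len(motif)] = list(motif)
    return "".join(seq), (position, position + len(motif) - 1)
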
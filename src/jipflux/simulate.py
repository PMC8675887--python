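"""Synthetic OJIP transients with closed-form ground-truth JIP parameters.

The generator emulates a continuous-excitation fluorometer experiment on a
factorial field design (2 populations × 2 seasons × day/night × replicates).
A transient is a sum of three saturating exponentials,

    F(t) = F0 + (FM − F0) Σ_i w_i (1 − exp(−k_i t)),   Σ w_i = 1,

with ordered rates k1 > k2 > k3 placing the J (~2 ms) and I (~30 ms)
inflections of a real OJIP curve.  Because the curve is analytic, every
JIP-test quantity has a closed form, giving an exact oracle for the
extraction pipeline: landmark values are direct evaluations, and the
complementary area has the elementary integral

    ∫_{t_start}^{T} (FM − F(t)) dt = (FM − F0) Σ_i w_i/k_i (e^{−k_i t_start} − e^{−k_i T}).

Measurement noise is multiplicative Gaussian (matching detector behavior at
high signal); everything is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import FluorescenceTransient, SampleMetadata, metadata_frame
from .jip import (CardinalPoints, ExtractionSettings, JipParameters,
                  compute_jip_parameters)


@dataclass(frozen=True)
class KineticSpec:
    """Kinetic ground truth for one simulated sample.

    F0_true / FM_true are the minimal and asymptotic maximal fluorescence
    (a.u.); ``weights`` the three phase amplitudes (sum 1) and ``rates``
    the strictly decreasing rate constants (s⁻¹) of the J, I and P phases.
    """

    F0_true: float = 5000.0
    FM_true: float = 25000.0
    weights: tuple[float, float, float] = (0.45, 0.30, 0.25)
    rates: tuple[float, float, float] = (1500.0, 80.0, 4.0)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        k = np.asarray(self.rates, dtype=float)
        if self.F0_true <= 0 or self.FM_true <= self.F0_true:
            raise ValidationError("need 0 < F0_true < FM_true")
        if w.size != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError("weights must be 3 non-negative values summing to 1")
        if k.size != 3 or np.any(k <= 0) or not (k[0] > k[1] > k[2]):
            raise ValidationError("rates must satisfy k1 > k2 > k3 > 0")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))
        object.__setattr__(self, "rates", tuple(float(x) for x in k))


@dataclass(frozen=True)
class SamplingGrid:
    """Log-spaced acquisition grid, 10 µs – 1 s × 160 points by default."""

    t_min: float = 1e-5
    t_max: float = 1.0
    points: int = 160

    def __post_init__(self) -> None:
        if not (0 < self.t_min < 5e-5 <= self.t_max):
            raise ValidationError("require t_min < 50 µs <= t_max")
        if self.points < 50:
            raise ValidationError("need at least 50 sample points")

    def times(self) -> np.ndarray:
        return np.logspace(math.log10(self.t_min), math.log10(self.t_max), self.points)


@dataclass(frozen=True)
class DesignCell:
    """One factorial cell: its factor levels, kinetics and replicate count."""

    population: str
    season: str
    period: str
    kinetics: KineticSpec
    n_replicates: int = 10


@dataclass(frozen=True)
class DesignSpec:
    """A full simulated experiment.

    ``noise_sd`` is the relative SD of the multiplicative measurement noise;
    the ``*_jitter_sd`` fields give the between-sample biological variation
    applied to F0_true, FM_true and the J-phase weight (re-normalized).
    """

    cells: tuple[DesignCell, ...]
    noise_sd: float = 0.02
    sampling: SamplingGrid = field(default_factory=SamplingGrid)
    seed: int = 0
    f0_jitter_sd: float = 0.03
    fm_jitter_sd: float = 0.03
    weight_jitter_sd: float = 0.015

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValidationError("design has no cells")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def transient_value(spec: KineticSpec, t):
    """Noise-free fluorescence F(t); strictly increasing, → FM_true as t → ∞."""
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    w = np.asarray(spec.weights)
    k = np.asarray(spec.rates)
    rise = (w * (1.0 - np.exp(-np.outer(t, k)))).sum(axis=-1)
    out = spec.F0_true + (spec.FM_true - spec.F0_true) * rise
    return out.item() if scalar else out


def analytic_area(spec: KineticSpec, t_start: float, t_end: float | None = None) -> float:
    """Closed-form complementary area ∫ (FM_true − F(t)) dt over [t_start, t_end].

    With ``t_end=None`` the integral runs to infinity.
    """
    w = np.asarray(spec.weights)
    k = np.asarray(spec.rates)
    upper = 0.0 if t_end is None else np.exp(-k * t_end)
    integral = (w / k * (np.exp(-k * t_start) - upper)).sum()
    return float((spec.FM_true - spec.F0_true) * integral)


def true_cardinal_points(
    spec: KineticSpec,
    settings: ExtractionSettings | None = None,
    t_max: float | None = None,
) -> CardinalPoints:
    """Exact cardinal points of the noise-free curve.

    ``t_max`` selects the FM convention: ``None`` uses the asymptote
    FM_true; a finite value uses F(t_max), the plateau actually attainable
    within an acquisition window ending at t_max (the convention the
    extractor necessarily follows).
    """
    settings = settings or ExtractionSettings()
    f0 = transient_value(spec, settings.t0)
    f300 = transient_value(spec, settings.t300)
    fj = transient_value(spec, settings.tj)
    fm = spec.FM_true if t_max is None else transient_value(spec, t_max)
    vj = (fj - f0) / (fm - f0)
    m0 = 4.0 * (f300 - f0) / (fm - f0)
    return CardinalPoints(f0=f0, f300=f300, fj=fj, fm=fm,
                          t_fm=math.inf if t_max is None else t_max,
                          vj=vj, m0=m0, degenerate=False)


def true_jip_parameters(
    spec: KineticSpec,
    settings: ExtractionSettings | None = None,
    sampling: SamplingGrid | None = None,
) -> JipParameters:
    """Closed-form JIP parameter vector for a kinetic spec.

    Without a ``sampling`` grid, FM is the asymptote FM_true and the area
    integral runs from the default grid start (10 µs) to infinity.  With a
    grid, FM = F(t_max) and the
    area is the complementary area to that attainable plateau over
    [t_min, t_max] — the same convention the extractor applies to recorded
    data — still in closed form:
    A_obs = A_∞(t_min, t_max) − (FM_true − F(t_max))·(t_max − t_min).
    """
    settings = settings or ExtractionSettings()
    grid = sampling or SamplingGrid()
    if sampling is None:
        cp = true_cardinal_points(spec, settings, t_max=None)
        area = analytic_area(spec, grid.t_min, None)
    else:
        cp = true_cardinal_points(spec, settings, t_max=grid.t_max)
        area_to_fm_true = analytic_area(spec, grid.t_min, grid.t_max)
        area = area_to_fm_true - (spec.FM_true - cp.fm) * (grid.t_max - grid.t_min)
    return compute_jip_parameters(cp, area)


def simulate_transient(
    spec: KineticSpec,
    sampling: SamplingGrid | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = 0,
    sample_id: str = "sim",
) -> FluorescenceTransient:
    """Simulate one noisy acquisition of the kinetic curve.

    Fluorescence is ``F(t) × (1 + ε_t)`` with independent Gaussian ε of
    relative SD ``noise_sd``, clipped to stay positive.  Reproducible from
    the seed (a Generator may be passed to share a stream).
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    sampling = sampling or SamplingGrid()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = sampling.times()
    clean = transient_value(spec, times)
    if noise_sd > 0:
        noisy = clean * (1.0 + rng.normal(0.0, noise_sd, times.size))
    else:
        noisy = np.asarray(clean, dtype=float).copy()
    noisy = np.maximum(noisy, 1e-9)
    return FluorescenceTransient(sample_id=sample_id, times=times, fluorescence=noisy)


# -- the field-campaign-like default design --------------------------------

_POP_BASE = {  # population effects: baseline F0 and FM/F0 ratio
    "Norway": (5000.0, 5.0),
    "France": (5600.0, 4.2),
}
_SEASON_BASE = {  # season effects: phase weights and terminal rate
    "summer": ((0.45, 0.30, 0.25), 4.0),
    "winter": ((0.58, 0.27, 0.15), 5.5),
}
_PERIOD_BASE = {  # day/night effects: F0 scaling and J-phase rate
    "day": (1.0, 1500.0),
    "night": (1.15, 1150.0),
}


def default_cell_kinetics(population: str, season: str, period: str) -> KineticSpec:
    """Factorial cell kinetics for the default two-site field design."""
    f0_base, ratio = _POP_BASE[population]
    (w1, w2, w3), k3 = _SEASON_BASE[season]
    f0_scale, k1 = _PERIOD_BASE[period]
    f0 = f0_base * f0_scale
    return KineticSpec(F0_true=f0, FM_true=f0 * ratio,
                       weights=(w1, w2, w3), rates=(k1, 80.0, k3))


def paper_like_design(seed: int = 0, n_replicates: int = 10,
                      noise_sd: float = 0.02,
                      sampling: SamplingGrid | None = None) -> DesignSpec:
    """The default 2 × 2 × 2 × ``n_replicates`` factorial experiment."""
    cells = tuple(
        DesignCell(pop, season, period,
                   default_cell_kinetics(pop, season, period), n_replicates)
        for pop in ("Norway", "France")
        for season in ("summer", "winter")
        for period in ("day", "night")
    )
    return DesignSpec(cells=cells, noise_sd=noise_sd,
                      sampling=sampling or SamplingGrid(), seed=seed)


def _jitter_spec(spec: KineticSpec, design: DesignSpec,
                 rng: np.random.Generator) -> KineticSpec:
    """Between-sample biological variation around a cell's kinetics."""
    f0 = spec.F0_true * max(1.0 + rng.normal(0.0, design.f0_jitter_sd), 0.1)
    fm = spec.FM_true * max(1.0 + rng.normal(0.0, design.fm_jitter_sd), 0.1)
    fm = max(fm, f0 * 1.05)
    w = np.asarray(spec.weights, dtype=float)
    w[0] = max(w[0] + rng.normal(0.0, design.weight_jitter_sd), 0.01)
    w = np.clip(w, 1e-3, None)
    w /= w.sum()
    return KineticSpec(F0_true=f0, FM_true=fm, weights=tuple(w), rates=spec.rates)


def simulate_experiment(
    design: DesignSpec,
    settings: ExtractionSettings | None = None,
) -> tuple[list[FluorescenceTransient], pd.DataFrame, pd.DataFrame]:
    """Simulate a full factorial experiment.

    Returns
    -------
    transients : list of FluorescenceTransient
        One per replicate per cell, with per-sample jittered kinetics and
        multiplicative measurement noise.
    metadata : DataFrame indexed by sample_id
        population / season / period / replicate per sample.
    truth : DataFrame indexed by sample_id
        The closed-form JIP parameters of each sample's (jittered) kinetics
        under the design's acquisition window, for recovery scoring.
    """
    rng = np.random.default_rng(design.seed)
    transients: list[FluorescenceTransient] = []
    meta: list[SampleMetadata] = []
    truth_rows: dict[str, dict] = {}
    for cell in design.cells:
        tag = f"{cell.population[:2].upper()}_{cell.season[:2]}_{cell.period[:2]}"
        for rep in range(1, cell.n_replicates + 1):
            sid = f"{tag}_{rep:02d}"
            spec = _jitter_spec(cell.kinetics, design, rng)
            transients.append(
                simulate_transient(spec, design.sampling, design.noise_sd,
                                   seed=rng, sample_id=sid)
            )
            meta.append(SampleMetadata(sample_id=sid, population=cell.population,
                                       season=cell.season, period=cell.period,
                                       replicate=rep))
            truth_rows[sid] = asdict(
                true_jip_parameters(spec, settings, sampling=design.sampling)
            )
    metadata = metadata_frame(meta)
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth.index.name = "sample_id"
    return transients, metadata, truth
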
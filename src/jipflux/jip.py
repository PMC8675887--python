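"""Cardinal-point extraction and JIP-test parameters from OJIP transients.

The JIP test reads a handful of landmark fluorescence values off the
polyphasic OJIP rise of a dark-adapted leaf — F0 at the origin (50 µs by
convention), F at 300 µs, F_J at the J-step (2 ms) and the maximum F_M —
and turns them into quantum yields and energy fluxes per excited leaf
cross-section:

    φPo  = 1 − F0/F_M                maximum quantum yield of primary photochemistry
    V_J  = (F_J − F0)/(F_M − F0)     relative variable fluorescence at J
    ψ0   = 1 − V_J                   probability an electron moves past Q_A
    M0   = 4 (F_300µs − F0)/(F_M − F0)   initial slope of the V rise, per ms
    ABS/CS = F0;  TR0/CS = φPo·ABS/CS;  ET0/CS = φPo·ψ0·ABS/CS
    DI0/CS = ABS/CS − TR0/CS;  RC0/CS = φPo·(V_J/M0)·ABS/CS
    PI_ABS = [γRC/(1−γRC)]·[φPo/(1−φPo)]·[ψ0/(1−ψ0)],  γRC/(1−γRC) = RC0/ABS

plus the complementary area between the induction curve and F = F_M
(a proxy for the oxidized quinone-pool size).  Landmark values are obtained
by linear interpolation of fluorescence against log10(time), which suits
log-spaced acquisition; F_M is the maximum observed point.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import asdict, dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DegenerateTransientError, ExtractionError, ValidationError
from .io import FluorescenceTransient

logger = logging.getLogger(__name__)

#: Field order of the per-sample parameter vector.
JIP_PARAMETER_FIELDS = (
    "phi_po", "psi_o", "vj", "m0", "area",
    "abs_cs", "tr0_cs", "et0_cs", "di0_cs", "rc0_cs",
    "gamma_rc_odds", "pi_abs", "tr0_di0", "psi_odds",
)


@dataclass(frozen=True)
class ExtractionSettings:
    """Conventions used to read landmarks off a transient.

    t0, t300, tj are the nominal origin / slope / J-step times in seconds
    (defaults: 50 µs, 300 µs, 2 ms).  ``interpolation`` is either
    ``"log-linear"`` (linear in log10 time, the default for log-spaced
    grids) or ``"linear"``.
    """

    t0: float = 5e-5
    t300: float = 3e-4
    tj: float = 2e-3
    interpolation: str = "log-linear"

    def __post_init__(self) -> None:
        if not (0 < self.t0 < self.t300 < self.tj):
            raise ValueError("require 0 < t0 < t300 < tj")
        if self.interpolation not in ("log-linear", "linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


@dataclass(frozen=True)
class CardinalPoints:
    """Landmark values extracted from one OJIP transient."""

    f0: float
    f300: float
    fj: float
    fm: float
    t_fm: float
    vj: float
    m0: float
    degenerate: bool = False


@dataclass(frozen=True)
class JipParameters:
    """The per-sample JIP-test parameter vector.

    Undefined ratios (e.g. the odds terms when φPo = 1 or ψ0 = 1) are
    carried as NaN rather than raising, so batch analyses survive
    pathological samples.
    """

    phi_po: float
    psi_o: float
    vj: float
    m0: float
    area: float
    abs_cs: float
    tr0_cs: float
    et0_cs: float
    di0_cs: float
    rc0_cs: float
    gamma_rc_odds: float
    pi_abs: float
    tr0_di0: float
    psi_odds: float


def _interp(transient: FluorescenceTransient, t: float, mode: str) -> float:
    if mode == "log-linear":
        return float(np.interp(math.log10(t), np.log10(transient.times), transient.fluorescence))
    return float(np.interp(t, transient.times, transient.fluorescence))


def relative_variable_fluorescence(f: float, f0: float, fm: float) -> float:
    """Relative variable fluorescence V = (F − F0)/(F_M − F0), clamped to [0, 1].

    Raises
    ------
    DegenerateTransientError
        If F_M <= F0 (no variable fluorescence).
    """
    if fm <= f0:
        raise DegenerateTransientError(f"FM ({fm}) must exceed F0 ({f0})")
    v = (f - f0) / (fm - f0)
    if v < 0.0 or v > 1.0:
        warnings.warn(
            f"fluorescence {f} outside [F0={f0}, FM={fm}]; clamping V to [0, 1]",
            stacklevel=2,
        )
        v = min(max(v, 0.0), 1.0)
    return v


def extract_cardinal_points(
    transient: FluorescenceTransient,
    settings: ExtractionSettings | None = None,
) -> CardinalPoints:
    """Extract F0, F300, F_J, F_M and the derived V_J and M0 from one transient.

    F0, F300 and F_J are interpolated at the nominal times (50 µs, 300 µs,
    2 ms by default); F_M is the maximum observed fluorescence and t_FM its
    (first) time.  A transient whose maximum does not exceed F0, or whose
    maximum sits at the first sample (non-rising curve), is flagged
    ``degenerate`` with V_J and M0 set to NaN instead of raising.

    Raises
    ------
    ExtractionError
        If the transient does not span a nominal landmark time.
    """
    settings = settings or ExtractionSettings()
    t = transient.times
    for name, tt in (("F0", settings.t0), ("F300", settings.t300), ("FJ", settings.tj)):
        if tt < t[0] or tt > t[-1]:
            raise ExtractionError(
                f"sample {transient.sample_id!r}: transient does not span the "
                f"{name} landmark at {tt} s (range {t[0]}–{t[-1]} s)"
            )
    f0 = _interp(transient, settings.t0, settings.interpolation)
    f300 = _interp(transient, settings.t300, settings.interpolation)
    fj = _interp(transient, settings.tj, settings.interpolation)
    imax = int(np.argmax(transient.fluorescence))
    fm = float(transient.fluorescence[imax])
    t_fm = float(t[imax])
    degenerate = fm <= f0 or imax == 0
    if degenerate:
        vj = m0 = float("nan")
    else:
        vj = relative_variable_fluorescence(fj, f0, fm)
        # slope of V over the first 0.25 ms, expressed per ms
        m0 = 4.0 * (f300 - f0) / (fm - f0)
    return CardinalPoints(f0=f0, f300=f300, fj=fj, fm=fm, t_fm=t_fm,
                          vj=vj, m0=m0, degenerate=degenerate)


def compute_area(transient: FluorescenceTransient, fm: float, t_fm: float) -> float:
    """Complementary area between the induction curve and F = F_M.

    Trapezoidal integral of (F_M − F(t)) from the first acquired timepoint
    to t_FM, in a.u.·s.  Non-negative whenever F_M is the curve maximum.
    """
    t = transient.times
    if not (t[0] <= t_fm <= t[-1]):
        raise ValueError(f"t_fm={t_fm} outside the acquired time range")
    mask = t <= t_fm
    return float(np.trapezoid(fm - transient.fluorescence[mask], t[mask]))


def compute_jip_parameters(cp: CardinalPoints, area: float) -> JipParameters:
    """Compute the full JIP-test parameter vector from cardinal points.

    Fully quenched transients (F_M = F0, i.e. φPo = 0) yield zero trapping
    and transport fluxes and PI_ABS = 0.  Ratios that are undefined
    (φPo = 1 from F0 = 0, or ψ0 = 1 from V_J = 0) come back as NaN while
    every other field is still returned.
    """
    nan = float("nan")
    abs_cs = cp.f0
    if cp.degenerate or cp.fm <= cp.f0:
        return JipParameters(
            phi_po=0.0, psi_o=nan, vj=nan, m0=nan, area=area,
            abs_cs=abs_cs, tr0_cs=0.0, et0_cs=0.0, di0_cs=abs_cs, rc0_cs=nan,
            gamma_rc_odds=nan, pi_abs=0.0, tr0_di0=0.0, psi_odds=nan,
        )
    phi_po = 1.0 - cp.f0 / cp.fm
    psi_o = 1.0 - cp.vj
    tr0_cs = phi_po * abs_cs
    et0_cs = phi_po * psi_o * abs_cs
    di0_cs = abs_cs - tr0_cs
    rc0_cs = phi_po * (cp.vj / cp.m0) * abs_cs if cp.m0 > 0 else nan
    gamma_rc_odds = rc0_cs / abs_cs if abs_cs > 0 else nan
    tr0_di0 = phi_po / (1.0 - phi_po) if phi_po < 1.0 else nan
    psi_odds = psi_o / (1.0 - psi_o) if psi_o < 1.0 else nan
    pi_abs = gamma_rc_odds * tr0_di0 * psi_odds
    return JipParameters(
        phi_po=phi_po, psi_o=psi_o, vj=cp.vj, m0=cp.m0, area=area,
        abs_cs=abs_cs, tr0_cs=tr0_cs, et0_cs=et0_cs, di0_cs=di0_cs,
        rc0_cs=rc0_cs, gamma_rc_odds=gamma_rc_odds, pi_abs=pi_abs,
        tr0_di0=tr0_di0, psi_odds=psi_odds,
    )


def analyze_transient(
    transient: FluorescenceTransient,
    settings: ExtractionSettings | None = None,
) -> tuple[CardinalPoints, JipParameters]:
    """Extract cardinal points and compute the JIP parameters for one sample."""
    cp = extract_cardinal_points(transient, settings)
    area = compute_area(transient, cp.fm, cp.t_fm)
    return cp, compute_jip_parameters(cp, area)


def analyze_transients(
    transients: Iterable[FluorescenceTransient],
    settings: ExtractionSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the JIP test on a batch of transients.

    Returns
    -------
    params : DataFrame
        One row per non-degenerate sample, indexed by sample_id (sorted),
        with the 14 JIP parameter columns.
    rejects : DataFrame
        Columns (sample_id, reason) for degenerate or unextractable samples;
        these are reported rather than silently dropped.
    """
    transients = list(transients)
    if not transients:
        raise ValidationError("no transients to analyze")
    rows: dict[str, dict] = {}
    rejects: list[dict] = []
    for tr in transients:
        try:
            cp, params = analyze_transient(tr, settings)
        except (ExtractionError, DegenerateTransientError) as exc:
            rejects.append({"sample_id": tr.sample_id, "reason": str(exc)})
            continue
        if cp.degenerate:
            rejects.append({"sample_id": tr.sample_id, "reason": "degenerate"})
            continue
        rows[tr.sample_id] = asdict(params)
    params_df = pd.DataFrame.from_dict(rows, orient="index", columns=list(JIP_PARAMETER_FIELDS))
    params_df.index.name = "sample_id"
    params_df = params_df.sort_index()
    rejects_df = pd.DataFrame(rejects, columns=["sample_id", "reason"])
    if rejects:
        logger.warning("%d sample(s) rejected during JIP analysis", len(rejects))
    return params_df, rejects_df
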
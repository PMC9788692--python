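"""Quantification of riboswitch wet-lab readouts.

Three assay families are covered, all starting from already-extracted band
intensities or plate-reader values (densitometry itself is out of scope):

* in-line probing: per-lane ratio of a modulated band to a constant band,
  converted to relative intensity changes against the no-ligand lane,
  optionally normalised, and fitted with a Hill binding isotherm.  When the
  fitted dissociation constant lies near or beyond the top of the tested
  concentration range the curve is flagged unsaturated and no K_D is
  reported — the honest outcome for weak binders.
* transcription termination: terminated vs full-length product fraction,
  with optional correction for body labelling (alpha-32P-ATP makes band
  intensity scale with the adenosine count of each product).
* acetyltransferase activity: a linear DTNB/CoA calibration line and the
  conversion of absorbances into released CoA, plus the trivial
  fluorescence / OD600 reporter normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class BandTable:
    """Per-lane band intensities of a probing gel.

    ``concs`` holds the ligand concentration (molar) per lane, with ``None``
    marking the no-ligand "(-)" lane; at most one such lane is permitted.
    """

    lane_ids: list[str]
    concs: list[float | None]
    modulated: list[float]
    constant: list[float]

    def __post_init__(self) -> None:
        n = len(self.lane_ids)
        if not (len(self.concs) == len(self.modulated) == len(self.constant) == n):
            raise ValueError("lane columns differ in length")
        if n < 2:
            raise ValueError("need at least 2 lanes")
        if sum(c is None for c in self.concs) > 1:
            raise ValueError("more than one no-ligand lane")
        if any(m < 0 for m in self.modulated):
            raise ValueError("modulated intensities must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "BandTable":
        df = pd.read_csv(path)
        required = {"lane_id", "conc_molar", "modulated", "constant"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"band CSV missing columns: {sorted(missing)}")
        concs = [
            None if pd.isna(c) else float(c) for c in df["conc_molar"]
        ]
        return cls(
            [str(x) for x in df["lane_id"]],
            concs,
            [float(x) for x in df["modulated"]],
            [float(x) for x in df["constant"]],
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "lane_id": self.lane_ids,
                "conc_molar": [c if c is not None else np.nan for c in self.concs],
                "modulated": self.modulated,
                "constant": self.constant,
            }
        ).to_csv(path, index=False)


def relative_intensity_change(
    table: BandTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative intensity change of the modulated band per ligand lane.

    Per lane r = modulated/constant; the change is r(c) - r(no-ligand).  The
    no-ligand lane is excluded from the returned series, which is sorted by
    ascending concentration.
    """
    for lane, const in zip(table.lane_ids, table.constant):
        if const <= 0:
            raise ValueError(f"lane {lane!r}: constant band intensity is zero")
    r = np.array(table.modulated) / np.array(table.constant)
    ref = [i for i, c in enumerate(table.concs) if c is None]
    if not ref:
        raise ValueError("no no-ligand lane in band table")
    r0 = r[ref[0]]
    pairs = sorted(
        (c, r[i] - r0)
        for i, c in enumerate(table.concs)
        if c is not None
    )
    concs = np.array([p[0] for p in pairs])
    rel = np.array([p[1] for p in pairs])
    return concs, rel


def normalize_series(rel_change) -> np.ndarray:
    """Scale a series so its maximum magnitude is 1 (signs preserved)."""
    x = np.asarray(rel_change, dtype=float)
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero series")
    return x / peak


def dilution_series(top: float, factor: float, n: int) -> np.ndarray:
    """Geometric dilution series: top, top/factor, ... (length n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 1 and factor <= 1:
        raise ValueError("factor must be > 1")
    return top / factor ** np.arange(n)


def _hill(c, amp, kd, hill_n):
    return amp * c ** hill_n / (kd ** hill_n + c ** hill_n)


@dataclass(frozen=True)
class BindingCurve:
    """Fitted binding isotherm for a probing concentration series.

    ``kd`` is None whenever ``saturated`` is False: without saturation the
    amplitude, and hence the dissociation constant, is not identifiable, and
    the series is instead reported normalised to the value at the highest
    concentration tested.
    """

    concs: np.ndarray
    rel_change: np.ndarray
    normalized: np.ndarray
    kd: float | None
    hill_n: float
    f_max: float
    saturated: bool
    fit_residual: float
    flags: tuple[str, ...] = field(default_factory=tuple)
    fitted_kd: float | None = None  # raw optimiser value, even unsaturated


def fit_binding_curve(
    concs,
    rel_change,
    saturation_kd_ratio: float = 5.0,
    saturation_top_tol: float = 0.10,
) -> BindingCurve:
    """Fit f(c) = f_max * c^n / (Kd^n + c^n) to relative intensity changes.

    The Hill coefficient n is free within [0.5, 3].  The curve is declared
    saturated when the fitted Kd is at most max(conc)/``saturation_kd_ratio``
    AND the fitted values at the two highest concentrations are within
    ``saturation_top_tol`` of f_max; otherwise ``kd`` is None.  A visibly
    non-monotone series is flagged (fit still attempted); an essentially flat
    series is flagged degenerate.
    """
    c = np.asarray(concs, dtype=float)
    y = np.asarray(rel_change, dtype=float)
    if len(c) != len(y):
        raise ValueError("concs and rel_change differ in length")
    if len(c) < 5:
        raise ValueError("need at least 5 concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if c.max() / c.min() < 100:
        raise ValueError("series must span at least 2 orders of magnitude")
    order = np.argsort(c)
    c, y = c[order], y[order]
    flags: list[str] = []

    peak = np.max(np.abs(y))
    if peak == 0 or np.ptp(y) < 0.02 * max(peak, 1e-12) or peak < 1e-12:
        flags.append("degenerate_fit")
        normalized = y / peak if peak > 0 else y.copy()
        return BindingCurve(
            c, y, normalized, None, 1.0, 0.0, False, float(np.std(y)),
            tuple(flags),
        )

    # monotonicity check on magnitudes (binding response should grow with c)
    mag = np.abs(y)
    drops = np.maximum.accumulate(mag) - mag
    if np.max(drops) > 0.25 * peak:
        flags.append("non_monotone")
        logger.warning("binding series is non-monotone beyond noise tolerance")

    amp0 = y[-1] if y[-1] != 0 else y[np.argmax(mag)]
    p0 = (amp0, float(np.exp(np.mean(np.log(c)))), 1.0)
    bounds = (
        [-10 * peak, c.min() / 1e4, 0.5],
        [10 * peak, c.max() * 1e6, 3.0],
    )
    p0 = tuple(np.clip(p0, bounds[0], bounds[1]))
    try:
        popt, _ = optimize.curve_fit(
            _hill, c, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError:
        flags.append("fit_failed")
        return BindingCurve(
            c, y, y / peak, None, 1.0, 0.0, False, float("nan"), tuple(flags)
        )
    amp, kd, hill_n = (float(v) for v in popt)
    fitted = _hill(c, amp, kd, hill_n)
    residual = float(np.sqrt(np.mean((fitted - y) ** 2)))
    top2 = np.abs(fitted[-2:])
    saturated = (
        kd <= c.max() / saturation_kd_ratio
        and np.all(top2 >= (1 - saturation_top_tol) * abs(amp))
    )
    if saturated:
        normalized = normalize_series(y)
        kd_out: float | None = kd
    else:
        # no saturation: report relative to the highest concentration tested
        ref = y[-1] if y[-1] != 0 else peak
        normalized = y / abs(ref)
        kd_out = None
    return BindingCurve(
        c, y, normalized, kd_out, hill_n, amp, bool(saturated), residual,
        tuple(flags), fitted_kd=kd,
    )


@dataclass(frozen=True)
class TerminationResult:
    """Terminated fraction of a single-round transcription reaction."""

    frac_terminated: float
    intensities: tuple[float, float]  # (terminated, full-length)
    a_counts: tuple[int, int]


def terminated_fraction(
    term: float,
    full: float,
    a_term: int,
    a_full: int,
    correct_a_counts: bool = True,
) -> TerminationResult:
    """Fraction terminated from terminated/full-length band intensities.

    With body labelling via alpha-32P-ATP, band intensity scales with the
    adenosine count of each product, so intensities are divided by the
    respective A counts before forming the fraction (disable with
    ``correct_a_counts=False``).
    """
    if a_term <= 0 or a_full <= 0:
        raise ValueError("adenosine counts must be positive")
    if term < 0 or full < 0:
        raise ValueError("band intensities must be >= 0")
    if term == 0 and full == 0:
        raise ValueError("both band intensities are zero")
    if correct_a_counts:
        t, f = term / a_term, full / a_full
    else:
        t, f = term, full
    return TerminationResult(t / (t + f), (term, full), (a_term, a_full))


@dataclass(frozen=True)
class Calibration:
    """Least-squares line for the DTNB / CoA calibration."""

    slope: float  # absorbance per molar
    intercept: float
    r_squared: float


def dtnb_calibrate(coa_concs, absorbances) -> Calibration:
    """Fit the linear CoA calibration (absorbance = slope*conc + intercept)."""
    x = np.asarray(coa_concs, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if len(x) != len(y):
        raise ValueError("concentrations and absorbances differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(x) == 0:
        raise ValueError("calibration concentrations have zero variance")
    res = stats.linregress(x, y)
    return Calibration(float(res.slope), float(res.intercept),
                       float(res.rvalue ** 2))


def activity(absorbance: float, cal: Calibration) -> float:
    """Released CoA (molar) from an absorbance via the calibration line.

    Negative estimates are clipped to 0 with a warning.
    """
    value = (absorbance - cal.intercept) / cal.slope
    if value < 0:
        logger.warning(
            "absorbance %.4g below calibration intercept; clipping CoA to 0",
            absorbance,
        )
        return 0.0
    return value


def normalized_fluorescence(fluorescence: float, od: float) -> float:
    """Reporter fluorescence normalised to culture density (OD600)."""
    if od <= 0:
        raise ValueError("OD600 must be positive")
    return fluorescence / od
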
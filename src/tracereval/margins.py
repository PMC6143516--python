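"""Margin-level clinical-value analysis.

After specimen removal the surgical cavity is imaged; a remaining
fluorescence signal suggests tumor left behind.  Histopathology is the
gold standard: a margin is positive when ink lies on invasive cancer or
carcinoma in situ.  Cross-tabulating the cavity call against the margin
status gives the contingency table from which the intraoperative
detection rate (sensitivity) and specificity follow.  The module also
carries the trial's sample-size arithmetic and the CalibrationDisk
dilution-series QC for the cameras.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import FluorImage


@dataclass
class MarginCall:
    """One patient's cavity-signal call paired with the margin verdict."""

    patient_id: str
    cavity_signal: str  # "present" | "absent"
    margin_status: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.cavity_signal not in ("present", "absent"):
            raise ValueError("cavity_signal must be 'present' or 'absent'")
        if self.margin_status not in ("positive", "negative"):
            raise ValueError("margin_status must be 'positive' or 'negative'")


@dataclass
class ContingencyTable:
    """2x2 cavity-fluorescence vs histopathological margin counts.

    tp = signal present & margin tumor-positive; fp = present & negative;
    fn = absent & positive; tn = absent & negative.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def call_cavity_signal(cavity_image: FluorImage | np.ndarray, background_mfi: float,
                       k: float = 2.0, min_area_px: int = 25) -> str:
    """Operational cavity-signal rule: a clearly delineable bright focus.

    The trial's definition is qualitative (signals clearly above
    background); here a signal is *present* iff some 8-connected
    component of pixels at or above ``k`` times the background MFI spans
    at least ``min_area_px`` pixels.  Raising ``k`` can only shrink the
    superthreshold mask, so the call is monotone in ``k``.
    """
    if background_mfi <= 0:
        raise ValueError("background MFI must be positive")
    counts = cavity_image.counts if isinstance(cavity_image, FluorImage) \
        else np.asarray(cavity_image)
    mask = counts.astype(float) >= k * background_mfi
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return "absent"
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    return "present" if np.any(sizes >= min_area_px) else "absent"


def build_contingency(calls: list[MarginCall]) -> ContingencyTable:
    """Exact cross-tabulation of cavity calls against margin status."""
    if not calls:
        raise ValueError("at least one margin call required")
    tp = sum(1 for c in calls if c.cavity_signal == "present" and c.margin_status == "positive")
    fp = sum(1 for c in calls if c.cavity_signal == "present" and c.margin_status == "negative")
    fn = sum(1 for c in calls if c.cavity_signal == "absent" and c.margin_status == "positive")
    tn = sum(1 for c in calls if c.cavity_signal == "absent" and c.margin_status == "negative")
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _percent_half_up(frac: Fraction) -> int:
    return int(math.floor(frac * 100 + Fraction(1, 2)))


def diagnostic_metrics(t: ContingencyTable) -> dict:
    """Detection rate, specificity and margin rates from a 2x2 table.

    Each metric is reported as an exact fraction and as an integer
    percent rounded half-up; a metric with a zero denominator is flagged
    missing rather than emitted as NaN.
    """
    out: dict = {"total": t.total}

    def put(name: str, num: int, den: int) -> None:
        if den == 0:
            out[name] = {"missing": True}
            return
        frac = Fraction(num, den)
        out[name] = {"fraction": frac, "value": float(frac),
                     "percent": _percent_half_up(frac), "missing": False}

    put("sensitivity", t.tp, t.tp + t.fn)  # intraoperative detection rate
    put("specificity", t.tn, t.tn + t.fp)
    put("positive_margin_rate", t.tp + t.fn, t.total)
    put("tumor_free_margin_rate", t.tn + t.fp, t.total)
    return out


def required_sample_size(margin_rate: float, needed_positive_patients: int) -> int:
    """Patients per dose group so that enough have tumor-involved margins.

    ceil(needed / margin_rate): at a 20% positive-margin rate, 15 needed
    positives require 75 patients.
    """
    if not 0 < margin_rate <= 1:
        raise ValueError("margin_rate must lie in (0, 1]")
    if needed_positive_patients < 1:
        raise ValueError("needed_positive_patients must be >= 1")
    return math.ceil(needed_positive_patients / margin_rate)


def calibration_disk_qc(tube_mfis) -> dict:
    """QC the 8-tube dilution-series phantom (blank + 7 two-fold steps).

    Tubes arrive ordered blank, 1:6400, 1:3200, ..., 1:100.  The check
    passes iff the sequence increases strictly from the blank upward and
    the top tube reads at least 5x the blank; the report carries the
    log2-linearity R^2 of the 7 dilution tubes and, on failure, the
    first offending index.
    """
    v = np.asarray(tube_mfis, dtype=float)
    if v.size != 8:
        raise ValueError("expected exactly 8 tube MFIs (1 blank + 7 dilutions)")
    report: dict = {"n_tubes": 8, "blank": float(v[0])}
    steps = np.diff(v)
    bad = np.nonzero(steps <= 0)[0]
    monotone = bad.size == 0
    if not monotone:
        report["first_inversion_index"] = int(bad[0]) + 1
    dynamic = v[7] >= 5.0 * v[0]
    report["top_over_blank"] = float(v[7] / v[0]) if v[0] > 0 else float("inf")
    dil = v[1:]
    if np.all(dil > 0):
        x = np.arange(7, dtype=float)
        y = np.log2(dil)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        report["log2_r_squared"] = r2
        report["log2_slope"] = float(slope)
    else:
        report["log2_r_squared"] = None
    report["pass"] = bool(monotone and dynamic)
    return report


def load_margin_calls(path: str | Path | None = None) -> list[MarginCall]:
    """Read margin calls from CSV (patient_id, cavity_signal, margin_status).

    With no path, loads the packaged 26-patient trial table.
    """
    if path is None:
        ref = resources.files("tracereval.data").joinpath("table2.csv")
        with resources.as_file(ref) as p:
            return load_margin_calls(p)
    with open(path, newline="") as fh:
        return [MarginCall(row["patient_id"], row["cavity_signal"], row["margin_status"])
                for row in csv.DictReader(fh)]
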
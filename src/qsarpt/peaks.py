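"""Chromatographic peak-shape descriptors from time/signal traces.

For a single baseline-corrected peak the four descriptors are

* retention time ``tr`` — apex position (3-point parabolic refinement),
* ``width5`` — full width at 5 % of apex height,
* ``asym44`` — trailing/leading half-width ratio b/a at 4.4 % of apex height,
* ``tailing`` — (a + b) / (2 a) at 5 % of apex height,

with a the apex-to-left-crossing and b the apex-to-right-crossing distance,
crossings located by linear interpolation between samples.  Relative
retention normalises retention to a reference compound run on the same
column/solvent condition: k' = (tr - tr_ref) / tr_ref.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DomainError,
    DuplicateTraceError,
    MultiPeakError,
    ReferenceMissingError,
    TruncatedPeakError,
)
from .io import DescriptorMatrix, DescriptorSchema

ASYMMETRY_FRACTION = 0.044  # Empower-style asymmetry height level
TAILING_FRACTION = 0.05  # tailing-factor and width height level


@dataclass
class ChromTrace:
    """One compound's chromatogram on one column/solvent condition."""

    time: np.ndarray  # minutes, strictly increasing
    signal: np.ndarray  # arbitrary absorbance units
    compound_id: str = ""
    column_code: str = ""
    solvent_code: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.time.size < 16:
            raise ValueError("trace needs at least 16 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def condition(self) -> tuple[str, str]:
        return (self.column_code, self.solvent_code)


@dataclass
class PeakMetrics:
    tr: float
    width5: float
    asym44: float
    tailing: float
    kprime_vs_ref: float = float("nan")
    fractions: dict = field(
        default_factory=lambda: {
            "asymmetry": ASYMMETRY_FRACTION,
            "tailing": TAILING_FRACTION,
        }
    )


def subtract_baseline(trace: ChromTrace, edge_fraction: float = 0.05) -> ChromTrace:
    """Remove a linear baseline fitted to the first/last ``edge_fraction`` of samples.

    Off by default in the measurement path; traces are normally assumed
    baseline-corrected.
    """
    n = trace.time.size
    k = max(2, int(round(edge_fraction * n)))
    idx = np.r_[0:k, n - k : n]
    coef = np.polyfit(trace.time[idx], trace.signal[idx], 1)
    return ChromTrace(
        time=trace.time,
        signal=trace.signal - np.polyval(coef, trace.time),
        compound_id=trace.compound_id,
        column_code=trace.column_code,
        solvent_code=trace.solvent_code,
    )


def _refine_apex(t: np.ndarray, s: np.ndarray, i: int) -> tuple[float, float]:
    """Parabola through the 3 samples around the argmax; returns (t_apex, height)."""
    if i == 0 or i == len(s) - 1:
        raise TruncatedPeakError("apex lies on the trace boundary")
    t0, t1, t2 = t[i - 1 : i + 2]
    y0, y1, y2 = s[i - 1 : i + 2]
    # quadratic fit on possibly non-uniform spacing
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
    b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate curvature; keep the sample apex
        return float(t1), float(y1)
    t_apex = -b / (2 * a)
    if not (t0 <= t_apex <= t2):
        return float(t1), float(y1)
    c = y0 - a * t0**2 - b * t0
    return float(t_apex), float(a * t_apex**2 + b * t_apex + c)


def _cross_left(t, s, i_apex, level) -> float:
    for i in range(i_apex, -1, -1):
        if s[i] < level:
            f = (level - s[i]) / (s[i + 1] - s[i])
            return float(t[i] + f * (t[i + 1] - t[i]))
    raise TruncatedPeakError(f"signal never falls below {level:.4g} left of the apex")


def _cross_right(t, s, i_apex, level) -> float:
    for i in range(i_apex, len(s)):
        if s[i] < level:
            f = (level - s[i]) / (s[i - 1] - s[i])
            return float(t[i] - f * (t[i] - t[i - 1]))
    raise TruncatedPeakError(f"signal never falls below {level:.4g} right of the apex")


def measure_peak(
    trace: ChromTrace,
    asym_fraction: float = ASYMMETRY_FRACTION,
    tail_fraction: float = TAILING_FRACTION,
) -> PeakMetrics:
    """Peak metrics of a single baseline-corrected peak.

    Raises :class:`MultiPeakError` when more than one disjoint region rises
    above half the apex height and :class:`TruncatedPeakError` when a
    threshold level is not crossed inside the trace.
    """
    t, s = trace.time, trace.signal
    i_apex = int(np.argmax(s))
    t_apex, height = _refine_apex(t, s, i_apex)
    if height <= 0:
        raise ValueError("non-positive apex height; is the trace baseline-corrected?")

    above = s > 0.5 * height
    n_regions = int(np.sum(np.diff(above.astype(int)) == 1) + (1 if above[0] else 0))
    if n_regions > 1:
        raise MultiPeakError(f"{n_regions} disjoint regions above 50% height")

    def half_widths(fraction: float) -> tuple[float, float]:
        level = fraction * height
        left = _cross_left(t, s, i_apex, level)
        right = _cross_right(t, s, i_apex, level)
        return t_apex - left, right - t_apex

    a44, b44 = half_widths(asym_fraction)
    a5, b5 = half_widths(tail_fraction)
    return PeakMetrics(
        tr=t_apex,
        width5=a5 + b5,
        asym44=b44 / a44,
        tailing=(a5 + b5) / (2 * a5),
        fractions={"asymmetry": asym_fraction, "tailing": tail_fraction},
    )


def relative_retention(tr_bp: float, tr_ref: float) -> float:
    """k' vs reference = (tr_bp - tr_ref) / tr_ref."""
    if tr_ref <= 0:
        raise DomainError(f"reference retention time must be > 0, got {tr_ref}")
    return (tr_bp - tr_ref) / tr_ref


def traces_to_matrix(
    traces: list[ChromTrace],
    reference_compound: str,
    schema: DescriptorSchema,
    baseline_correct: bool = False,
) -> DescriptorMatrix:
    """Measure every trace and assemble the chromatographic descriptor matrix.

    Per condition (column, solvent) the four slots are filled with width5
    (#2), k' vs the reference compound measured on the same condition (#5),
    asym44 (#7) and tailing (#8).  Slots for conditions without a trace stay
    missing (NaN).
    """
    by_condition: dict[tuple[str, str], dict[str, ChromTrace]] = {}
    compounds: list[str] = []
    for tr in traces:
        cond = tr.condition
        comp = tr.compound_id
        by_condition.setdefault(cond, {})
        if comp in by_condition[cond]:
            raise DuplicateTraceError(f"compound {comp} measured twice on condition {cond}")
        by_condition[cond][comp] = tr
        if comp not in compounds:
            compounds.append(comp)

    for cond, group in by_condition.items():
        if reference_compound not in group:
            raise ReferenceMissingError(
                f"no trace of reference compound {reference_compound!r} on condition {cond}"
            )

    n = len(compounds)
    values = np.full((n, len(schema)), np.nan)
    col_index = {code: j for j, code in enumerate(schema.codes)}

    for (col, solv), group in by_condition.items():
        prep = (lambda x: subtract_baseline(x)) if baseline_correct else (lambda x: x)
        metrics = {comp: measure_peak(prep(tr)) for comp, tr in group.items()}
        tr_ref = metrics[reference_compound].tr
        for comp, m in metrics.items():
            m.kprime_vs_ref = relative_retention(m.tr, tr_ref)
            i = compounds.index(comp)
            slot_values = {2: m.width5, 5: m.kprime_vs_ref, 7: m.asym44, 8: m.tailing}
            for digit, value in slot_values.items():
                code = f"{col}{solv}{digit}"
                if code in col_index:
                    values[i, col_index[code]] = value

    missing = [
        code for j, code in enumerate(schema.codes) if np.isnan(values[:, j]).all()
    ]
    return DescriptorMatrix(compounds, schema, values, missing_codes=missing)


def write_trace_csv(trace: ChromTrace, path) -> None:
    """Two-column time/signal CSV with a metadata comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# compound={trace.compound_id}, column={trace.column_code}, "
            f"solvent={trace.solvent_code}\n"
        )
        fh.write("time_min,signal\n")
        for t, s in zip(trace.time, trace.signal):
            fh.write(f"{t:.9g},{s:.9g}\n")


def read_trace_csv(path) -> ChromTrace:
    import re

    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    meta = dict(re.findall(r"(\w+)=([^,\s]+)", header)) if header.startswith("#") else {}
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    return ChromTrace(
        time=df.iloc[:, 0].to_numpy(float),
        signal=df.iloc[:, 1].to_numpy(float),
        compound_id=meta.get("compound", ""),
        column_code=meta.get("column", ""),
        solvent_code=meta.get("solvent", ""),
    )


def read_manifest(path) -> list[ChromTrace]:
    """Batch manifest: a CSV with one column ``trace_path`` (relative to it)."""
    import pandas as pd
    from pathlib import Path

    base = Path(path).parent
    df = pd.read_csv(path)
    return [read_trace_csv(base / p) for p in df["trace_path"]]
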
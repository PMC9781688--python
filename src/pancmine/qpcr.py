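"""ΔCt / ΔΔCt expression quantification and standard-curve efficiency.

Conventions
-----------
* Quantification cycle (Ct) replicates are summarised by their arithmetic
  mean; the spread is the sample standard deviation (labelled sd, not sem).
* ΔCt = mean(target Ct) − mean(reference Ct); uncertainties propagate in
  quadrature.  Fold difference between two conditions is 2^(−ΔΔCt).
* A Ct at or beyond the protocol's cycle count (40 by default) — or a
  missing / "ND" entry — marks the reaction undetected.  Undetected values
  are propagated as flags, never imputed.
* Amplification efficiency comes from the least-squares slope m of Ct
  against log10(relative input): efficiency% = (10^(−1/m) − 1) × 100, so a
  perfect doubling per cycle (m = −3.3219) gives 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Protocol cycle count; Ct values at/over this are below the detection limit.
MAX_CYCLES = 40.0

#: Accepted spellings of the undetected sentinel in Ct tables.
ND_STRINGS = {"ND", "N.D.", "NA", "UNDETECTED", ""}


def is_detected(ct: float | str | None, max_cycles: float = MAX_CYCLES) -> bool:
    """True if a Ct value represents a detected amplification."""
    if ct is None:
        return False
    if isinstance(ct, str):
        if ct.strip().upper() in ND_STRINGS:
            return False
        ct = float(ct)
    if math.isnan(ct):
        return False
    if ct <= 0:
        raise ValueError(f"Ct must be positive, got {ct}")
    return ct < max_cycles


def _summarise(cts: Sequence[float | str | None], max_cycles: float) -> tuple[float, float, int, int]:
    """(mean, sd, n_detected, n_total) of the detected replicates."""
    if len(cts) == 0:
        raise ValueError("empty Ct group")
    detected = [float(c) for c in cts if is_detected(c, max_cycles)]
    if not detected:
        return math.nan, math.nan, 0, len(cts)
    mean = float(np.mean(detected))
    sd = float(np.std(detected, ddof=1)) if len(detected) > 1 else 0.0
    return mean, sd, len(detected), len(cts)


@dataclass
class ExpressionResult:
    """A ΔCt summary; ``delta_ct`` is NaN when either assay was undetected."""

    delta_ct: float
    delta_ct_sd: float
    flags: list[str] = field(default_factory=list)

    @property
    def is_defined(self) -> bool:
        return not math.isnan(self.delta_ct)


def delta_ct(
    target_cts: Sequence[float | str | None],
    reference_cts: Sequence[float | str | None],
    max_cycles: float = MAX_CYCLES,
) -> ExpressionResult:
    """ΔCt of a target assay against a reference assay on the same sample.

    Replicate groups are averaged; sd propagates as sqrt(sd_t² + sd_r²).
    An undetected target (or reference) yields a flagged result with
    undefined (NaN) ΔCt.
    """
    t_mean, t_sd, t_det, _ = _summarise(target_cts, max_cycles)
    r_mean, r_sd, r_det, _ = _summarise(reference_cts, max_cycles)
    flags = []
    if t_det == 0:
        flags.append("target below detection limit")
    if r_det == 0:
        flags.append("reference below detection limit")
    if flags:
        return ExpressionResult(math.nan, math.nan, flags)
    return ExpressionResult(t_mean - r_mean, math.hypot(t_sd, r_sd), [])


def fold_difference(delta_ct_a: float, delta_ct_b: float) -> float:
    """Comparative fold difference 2^−(ΔCt_a − ΔCt_b) between two conditions."""
    if math.isnan(delta_ct_a) or math.isnan(delta_ct_b):
        raise ValueError("fold_difference requires defined ΔCt values")
    return 2.0 ** -(delta_ct_a - delta_ct_b)


def amplification_efficiency(
    dilution_series: Sequence[tuple[float, float]],
) -> float:
    """Assay efficiency (percent) from a standard-curve dilution series.

    ``dilution_series`` holds (log10 relative input, mean Ct) points.  The
    efficiency is (10^(−1/m) − 1) × 100 for the least-squares slope m; it is
    invariant to uniform Ct offsets.
    """
    if len(dilution_series) < 3:
        raise ValueError("need at least 3 dilution points")
    x = np.array([p[0] for p in dilution_series], dtype=float)
    y = np.array([p[1] for p in dilution_series], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("singular fit: all inputs identical")
    fit = stats.linregress(x, y)
    return (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct CSV with columns sample_id, assay, replicate, ct.

    The ct column may contain numbers or undetected sentinels ("ND" etc.);
    sentinels are kept as NaN with a ``detected`` boolean column alongside.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "assay": str})
    required = {"sample_id", "assay", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}; got {list(df.columns)}")
    detected = df["ct"].map(lambda v: is_detected(v))
    df["detected"] = detected
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce").where(detected)
    return df


def delta_ct_table(
    df: pd.DataFrame, reference_assay: str, max_cycles: float = MAX_CYCLES
) -> pd.DataFrame:
    """Per-sample ΔCt of every assay against ``reference_assay``.

    Expects a frame as returned by :func:`read_ct_table`.  Rows with an
    undetected target or reference carry NaN ΔCt and a flag note.
    """
    rows = []
    for (sample, assay), grp in df.groupby(["sample_id", "assay"], sort=True):
        if assay == reference_assay:
            continue
        ref = df[(df["sample_id"] == sample) & (df["assay"] == reference_assay)]
        if ref.empty:
            raise ValueError(f"sample {sample!r} lacks reference assay {reference_assay!r}")
        res = delta_ct(
            grp["ct"].where(grp["detected"]).tolist(),
            ref["ct"].where(ref["detected"]).tolist(),
            max_cycles,
        )
        rows.append(
            {
                "sample_id": sample,
                "assay": assay,
                "reference": reference_assay,
                "delta_ct": res.delta_ct,
                "delta_ct_sd": res.delta_ct_sd,
                "flags": "; ".join(res.flags),
            }
        )
    return pd.DataFrame(rows)
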
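"""Exposure preparation: quantile scoring, protective reversal, IQR scaling,
and day/evening/night noise aggregation.

Quantile scores feed the weighted quantile sum index; protective exposures
(green and blue space) are reversed so that a larger score always means a
less favourable environment and all index components share one direction.
IQR scaling makes single-exposure regression slopes read "per IQR increase".
The Lden-style noise aggregate is the energy-weighted 24-h level with +5 dB
evening and +10 dB night penalties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QuantileBoundaries",
    "NoiseTriplet",
    "quantize",
    "quantize_table",
    "reverse_protective",
    "iqr_scale",
    "lden",
]


@dataclass(frozen=True)
class QuantileBoundaries:
    """Fitted cut points for one exposure column.

    ``cuts`` are the q-1 interior empirical quantiles (type-7 linear
    interpolation). Intervals are right-closed: a value equal to a cut point
    falls in the lower bin, and out-of-range values clamp to the end bins.
    """

    q: int
    cuts: tuple[float, ...]

    def score(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        return np.searchsorted(np.asarray(self.cuts), x, side="left").astype(int)


def quantize(values, q: int = 4, boundaries: QuantileBoundaries | None = None):
    """Quantile-score a column into integers {0..q-1}.

    When ``boundaries`` is None, cut points are fit on ``values`` (training
    data) and returned for reuse on validation data; otherwise the given
    boundaries are applied. Returns ``(scores, boundaries)``.
    """
    x = np.asarray(values, dtype=float)
    if boundaries is None:
        if q < 2:
            raise ValueError("q must be >= 2")
        distinct = np.unique(x[np.isfinite(x)])
        if distinct.size < 2:
            raise ValueError("cannot quantize a constant column")
        if distinct.size < q:
            raise ValueError(
                f"need at least q={q} distinct values to fit quantile boundaries, got {distinct.size}"
            )
        probs = np.arange(1, q) / q
        cuts = np.quantile(x, probs)  # type-7 linear interpolation
        boundaries = QuantileBoundaries(q=q, cuts=tuple(float(c) for c in cuts))
    elif boundaries.q != q:
        raise ValueError(f"boundaries were fit with q={boundaries.q}, requested q={q}")
    return boundaries.score(x), boundaries


def quantize_table(
    df: pd.DataFrame,
    columns,
    q: int = 4,
    boundaries: dict[str, QuantileBoundaries] | None = None,
) -> tuple[pd.DataFrame, dict[str, QuantileBoundaries]]:
    """Quantile-score several columns, fitting or reusing per-column boundaries."""
    fitted: dict[str, QuantileBoundaries] = {}
    scores = {}
    for col in columns:
        b = None if boundaries is None else boundaries[col]
        scores[col], fitted[col] = quantize(df[col].to_numpy(), q=q, boundaries=b)
    return pd.DataFrame(scores, index=df.index), fitted


def reverse_protective(scores: pd.DataFrame, q: int, which) -> pd.DataFrame:
    """Reverse the quantile scores of protective exposures: s -> (q-1) - s.

    After reversal a larger score represents *less* of the protective
    exposure, aligning its direction with the harmful exposures.
    """
    unknown = [c for c in which if c not in scores.columns]
    if unknown:
        raise KeyError(f"unknown columns to reverse: {unknown}")
    out = scores.copy()
    for col in which:
        out[col] = (q - 1) - out[col]
    return out


def iqr_scale(values) -> tuple[np.ndarray, float]:
    """Divide by the interquartile range so regression slopes read per-IQR.

    IQR = Q3 - Q1 with type-7 (linear-interpolation) quantiles. Raises on a
    zero IQR.
    """
    x = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = float(q3 - q1)
    if iqr <= 0:
        raise ValueError("IQR is zero; cannot scale")
    return x / iqr, iqr


@dataclass(frozen=True)
class NoiseTriplet:
    """Period sound levels (dB) with hour spans that must partition 24 h.

    Defaults follow day 07-19, evening 19-23, night 23-07.
    """

    l_day: float
    l_evening: float
    l_night: float
    hours_day: float = 12.0
    hours_evening: float = 4.0
    hours_night: float = 8.0


def lden(triplet: NoiseTriplet) -> float:
    """Energy-average 24-h noise level with +5 dB evening / +10 dB night penalties.

    ``10*log10((h_d*10^(L_d/10) + h_e*10^((L_e+5)/10) + h_n*10^((L_n+10)/10))/24)``.
    Silent periods may be passed as ``-np.inf``.
    """
    h = (triplet.hours_day, triplet.hours_evening, triplet.hours_night)
    if not np.isclose(sum(h), 24.0):
        raise ValueError(f"hour spans must sum to 24, got {sum(h)}")
    energy = (
        h[0] * 10.0 ** (triplet.l_day / 10.0)
        + h[1] * 10.0 ** ((triplet.l_evening + 5.0) / 10.0)
        + h[2] * 10.0 ** ((triplet.l_night + 10.0) / 10.0)
    )
    return float(10.0 * np.log10(energy / 24.0))
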
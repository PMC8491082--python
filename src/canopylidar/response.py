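"""Nitrogen-response classification and the weighted performance matrix.

Varieties are classified into four qualitative N-response classes from their
mean canopy-index (3DCI) values at low, medium and high N, with a similarity
tolerance tau:

* Class 1 - the index separates at all three N levels and decreases with N
  (strong, graded structural response).
* Class 2 - low and medium N look alike; only high N moves the canopy.
* Class 3 - medium and high N look alike; the response saturates at medium N.
* Class 4 - the best response is at medium N (the index is lowest there and
  rises again at high N).

The performance matrix ranks varieties per trait by percentage deviation from
the trimmed mean, in five bands (>=15% rank 5, 7.5-15% rank 4, +/-7.5% rank
3, -15 to -7.5% rank 2, below -15% rank 1; lower-inclusive, upper-exclusive
boundaries).  Height is penalized symmetrically - both very short and very
tall are undesirable.  The weighted score combines per-trait ranks with
weights summing to 1; yield components (grain and spike number per m^2) carry
the most weight by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

__all__ = [
    "ResponseInput",
    "DEFAULT_WEIGHTS",
    "classify_n_response",
    "performance_matrix",
]


@dataclass(frozen=True)
class ResponseInput:
    """Per-variety means at the three treatment levels."""

    dci_low: float
    dci_medium: float
    dci_high: float
    curvature_low: float | None = None
    curvature_medium: float | None = None
    curvature_high: float | None = None
    spike_density: float | None = None  # SN m^-2, optional context

    def dci(self) -> tuple[float, float, float]:
        vals = (self.dci_low, self.dci_medium, self.dci_high)
        if any(v is None or not np.isfinite(v) for v in vals):
            raise ValueError("all three treatment levels must be present")
        return vals


def classify_n_response(inp: ResponseInput, tolerance: float = 0.02) -> int | None:
    """Assign one of the four N-response classes, or None when no pattern
    fits (with the pairwise index gaps available for diagnostics via the
    returned value's absence)."""
    d_low, d_med, d_high = inp.dci()
    tau = tolerance
    gaps_all = (
        abs(d_low - d_med) > tau
        and abs(d_med - d_high) > tau
        and abs(d_low - d_high) > tau
    )
    if gaps_all and d_low > d_med > d_high:
        return 1
    if abs(d_low - d_med) <= tau and d_high < d_med - tau:
        return 2
    if abs(d_med - d_high) <= tau and d_med < d_low - tau:
        return 3
    if d_med <= min(d_low, d_high) and d_high > d_med + tau:
        return 4
    return None


#: Default trait weights; yield components GN and SN carry the most weight,
#: height the least (it is the symmetrically penalized trait).
DEFAULT_WEIGHTS = {
    "GN": 0.25,
    "SN": 0.25,
    "3DCI": 0.20,
    "surface": 0.20,
    "height": 0.10,
}


def _band_rank(dev_pct: float) -> int:
    if dev_pct >= 15.0:
        return 5
    if dev_pct >= 7.5:
        return 4
    if dev_pct >= -7.5:
        return 3
    if dev_pct >= -15.0:
        return 2
    return 1


def _height_rank(dev_pct: float) -> int:
    """Symmetric scheme: near the trimmed mean is best; both very short and
    very tall rank lowest."""
    mag = abs(dev_pct)
    if mag <= 7.5:
        return 3
    if mag <= 15.0:
        return 2
    return 1


def performance_matrix(
    traits: pd.DataFrame,
    weights: dict[str, float] | None = None,
    trim_fraction: float = 0.10,
) -> pd.DataFrame:
    """Rank varieties per trait against the trimmed mean and combine ranks
    into a weighted score.

    ``traits`` must be indexed (or carry a ``variety`` column) with one row
    per variety and the trait columns named in ``weights`` (default GN, SN,
    3DCI, surface, height).  Deviation = 100 * (v - trimmed_mean) /
    trimmed_mean, banded into ranks 1-5; the height trait uses the symmetric
    scheme.  Output has ``rank_<trait>``, ``dev_<trait>`` columns and a
    ``score`` column, sorted by score descending.
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {total}")
    df = traits.copy()
    if "variety" in df.columns:
        df = df.set_index("variety")
    if len(df) < 3:
        raise ValueError("need at least 3 varieties")
    missing = [t for t in weights if t not in df.columns]
    if missing:
        raise ValueError(f"missing trait columns: {missing}")

    out = pd.DataFrame(index=df.index)
    score = np.zeros(len(df))
    for trait, w in weights.items():
        values = df[trait].to_numpy(dtype=np.float64)
        centre = trim_mean(values, proportiontocut=trim_fraction)
        dev = 100.0 * (values - centre) / centre
        ranker = _height_rank if trait == "height" else _band_rank
        ranks = np.array([ranker(d) for d in dev])
        out[f"dev_{trait}"] = dev
        out[f"rank_{trait}"] = ranks
        score += w * ranks
    out["score"] = score
    return out.sort_values("score", ascending=False, kind="stable")
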
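"""Weighted-arithmetic water quality index (WQI) and contamination degree (Cd).

The WQI aggregates per-parameter quality ratings

    Qn = 100 * |Vn - Vi| / (Vs - Vi)

into a single number with unit weights inversely proportional to each
parameter's permissible limit, ``Wn = k / Vs`` with ``k = 1 / Σ(1/Vs)``, so
that ``Σ Wn = 1`` and

    WQI = Σ Qn Wn / Σ Wn = Σ Qn Wn.

The contamination degree sums exceedance factors over parameters whose
analytical value lies beyond the permissible concentration,

    Cd = Σ Cfi,   Cfi = CAi / CNi - 1   (only when CAi > CNi),

so values at or below the limit contribute nothing. pH is two-sided: values
above 8.5 use ``CAi/8.5 - 1``, values below 6.5 the reciprocal form
``6.5/CAi - 1``, keeping every stored factor positive and dimensionless.

Both indices map onto a five-rank scale (1 best, 5 worst): WQI ranks are
Excellent / Good / Poor / Very poor / Unsuitable for any use; Cd ranks are
Excellent / Low / Medium / High / Very high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .standards import ParameterSpec, StandardsError

__all__ = [
    "WellSample",
    "QualityBreakdown",
    "RankBin",
    "RankScale",
    "IndexResult",
    "MissingDataError",
    "WQI_SCALE",
    "CD_SCALE",
    "unit_weights",
    "quality_rating",
    "contamination_factor",
    "compute_wqi",
    "compute_cd",
    "compute_indices",
    "classify_wqi",
    "classify_cd",
]

Period = Literal["pre_sewerage", "post_sewerage"]

#: First calendar year of the post-intervention period in the default study
#: configuration (the sewerage network was completed during 2014).
DEFAULT_BOUNDARY_YEAR = 2014


class MissingDataError(ValueError):
    """A sample lacks a value for a configured parameter."""


@dataclass
class WellSample:
    """One monitoring well sampled in one year.

    ``values`` maps parameter codes to measured values (``Vn`` / ``CAi``);
    parameters may be absent (missing data). ``period`` defaults from the
    study configuration: years before 2014 are pre-sewerage.
    """

    well_id: str
    year: int
    x: float
    y: float
    values: dict[str, float]
    period: Period | None = None

    def __post_init__(self) -> None:
        if self.period is None:
            self.period = (
                "pre_sewerage" if self.year < DEFAULT_BOUNDARY_YEAR else "post_sewerage"
            )
        for code, v in self.values.items():
            if code == "pH":
                if not (0.0 < v < 14.0):
                    raise ValueError(
                        f"well {self.well_id} year {self.year}: pH {v} outside (0, 14)"
                    )
            elif v < 0:
                raise ValueError(
                    f"well {self.well_id} year {self.year}: negative {code} value {v}"
                )


@dataclass
class QualityBreakdown:
    """Per-parameter decomposition of the two indices for one sample.

    ``qn`` and ``wn`` hold the quality ratings and unit weights over the
    configured parameter set; ``k`` is the proportionality constant making
    the weights sum to one. ``cfi`` holds a contamination factor only for
    parameters that exceed their permissible bounds.
    """

    k: float
    wn: dict[str, float]
    qn: dict[str, float] = field(default_factory=dict)
    cfi: dict[str, float] = field(default_factory=dict)
    partial: bool = False


@dataclass(frozen=True)
class RankBin:
    rank: int
    lower: float
    upper: float  # math.inf for the open top bin
    label: str
    lower_open: bool = True
    upper_open: bool = False

    def contains(self, value: float) -> bool:
        above = value > self.lower if self.lower_open else value >= self.lower
        below = value < self.upper if self.upper_open else value <= self.upper
        return above and below


@dataclass(frozen=True)
class RankScale:
    """Ordered rank bins partitioning [0, inf) with no gaps or overlaps."""

    name: str
    bins: tuple[RankBin, ...]

    def classify(self, value: float) -> RankBin:
        if math.isnan(value) or value < 0:
            raise ValueError(f"{self.name}: cannot classify value {value}")
        for b in self.bins:
            if b.contains(value):
                return b
        raise AssertionError("rank bins must cover [0, inf)")  # pragma: no cover


#: Five-rank scale for the WQI. The printed integer-style bins (0–25, 26–50,
#: 51–75, 76–100, above 100) are closed up to contiguous half-open intervals
#: so every real-valued index classifies: [0,25], (25,50], (50,75], (75,100],
#: (100, inf).
WQI_SCALE = RankScale(
    "WQS",
    (
        RankBin(1, 0.0, 25.0, "Excellent", lower_open=False),
        RankBin(2, 25.0, 50.0, "Good"),
        RankBin(3, 50.0, 75.0, "Poor"),
        RankBin(4, 75.0, 100.0, "Very poor"),
        RankBin(5, 100.0, math.inf, "Unsuitable for any use"),
    ),
)

#: Five-rank scale for the contamination degree: 0 → Excellent, (0,1) Low,
#: [1,3) Medium, [3,6] High, (6, inf) Very high.
CD_SCALE = RankScale(
    "Cds",
    (
        RankBin(1, 0.0, 0.0, "Excellent", lower_open=False),
        RankBin(2, 0.0, 1.0, "Low", upper_open=True),
        RankBin(3, 1.0, 3.0, "Medium", lower_open=False, upper_open=True),
        RankBin(4, 3.0, 6.0, "High", lower_open=False),
        RankBin(5, 6.0, math.inf, "Very high"),
    ),
)


@dataclass
class IndexResult:
    """Both index values, their rank assignments and the breakdown."""

    well_id: str
    year: int
    wqi: float
    cd: float
    breakdown: QualityBreakdown
    rank_wqs: int
    wqs_label: str
    rank_cds: int
    cds_label: str
    period: Period | None = None


def unit_weights(specs: list[ParameterSpec]) -> QualityBreakdown:
    """Unit weights ``Wn = k/Vs`` with ``k = 1/Σ(1/Vs)`` over a spec set.

    The weights sum to one by construction (asserted to 1e-9).
    """
    if not specs:
        raise StandardsError("cannot build weights from an empty spec list")
    for s in specs:
        if s.standard_permissible <= 0:
            raise StandardsError(f"{s.code}: non-positive permissible limit")
    k = 1.0 / sum(1.0 / s.standard_permissible for s in specs)
    wn = {s.code: k / s.standard_permissible for s in specs}
    assert abs(sum(wn.values()) - 1.0) < 1e-9
    return QualityBreakdown(k=k, wn=wn)


def quality_rating(value: float, spec: ParameterSpec) -> float:
    """Quality rating ``Qn = 100 |Vn - Vi| / (Vs - Vi)``.

    The absolute deviation keeps sub-ideal pH penalised symmetrically; for
    every parameter with ``Vi = 0`` this reduces to ``100 Vn / Vs``. ``Qn``
    is 0 at the ideal value and exactly 100 at the permissible limit.
    """
    return 100.0 * abs(value - spec.ideal_value) / (
        spec.standard_permissible - spec.ideal_value
    )


def contamination_factor(value: float, spec: ParameterSpec) -> float | None:
    """Exceedance factor ``Cfi``, or ``None`` when within permissible bounds.

    Above the upper permissible concentration: ``CAi/CNi - 1``. Below a
    configured lower bound (pH only): ``lower/CAi - 1``. Equality with a
    bound does not exceed it.
    """
    if value > spec.cd_upper:
        return value / spec.cd_upper - 1.0
    if spec.lower_permissible is not None and value < spec.lower_permissible:
        if value <= 0:
            raise ValueError(
                f"{spec.code}: non-positive value {value} in lower-bound exceedance"
            )
        return spec.lower_permissible / value - 1.0
    return None


def compute_wqi(
    sample: WellSample,
    specs: list[ParameterSpec],
    *,
    renormalize_missing: bool = False,
) -> tuple[float, QualityBreakdown]:
    """Weighted-arithmetic WQI of one sample over the configured parameters.

    Every configured parameter must be present; with
    ``renormalize_missing=True`` the weights are instead recomputed over the
    parameters the sample does provide and the breakdown is flagged partial.
    """
    present = [s for s in specs if s.code in sample.values]
    missing = [s.code for s in specs if s.code not in sample.values]
    if missing and not renormalize_missing:
        raise MissingDataError(
            f"well {sample.well_id} year {sample.year}: missing {', '.join(missing)}"
        )
    bd = unit_weights(present)
    bd.partial = bool(missing)
    for s in present:
        bd.qn[s.code] = quality_rating(sample.values[s.code], s)
    wqi = sum(bd.qn[c] * bd.wn[c] for c in bd.wn)
    return wqi, bd


def compute_cd(
    sample: WellSample, specs: list[ParameterSpec]
) -> tuple[float, dict[str, float]]:
    """Contamination degree: the sum of exceedance factors of one sample.

    Missing parameters simply contribute no factor.
    """
    cfi: dict[str, float] = {}
    for s in specs:
        if s.code not in sample.values:
            continue
        f = contamination_factor(sample.values[s.code], s)
        if f is not None:
            cfi[s.code] = f
    return sum(cfi.values()), cfi


def classify_wqi(wqi: float) -> tuple[int, str]:
    """Rank 1–5 and status label for a WQI value."""
    b = WQI_SCALE.classify(wqi)
    return b.rank, b.label


def classify_cd(cd: float) -> tuple[int, str]:
    """Rank 1–5 and status label for a contamination degree."""
    b = CD_SCALE.classify(cd)
    return b.rank, b.label


def compute_indices(
    sample: WellSample,
    specs: list[ParameterSpec],
    *,
    renormalize_missing: bool = False,
) -> IndexResult:
    """Both indices, breakdown and rank assignments for one sample."""
    wqi, bd = compute_wqi(sample, specs, renormalize_missing=renormalize_missing)
    cd, cfi = compute_cd(sample, specs)
    bd.cfi = cfi
    rw, lw = classify_wqi(wqi)
    rc, lc = classify_cd(cd)
    return IndexResult(
        well_id=sample.well_id,
        year=sample.year,
        wqi=wqi,
        cd=cd,
        breakdown=bd,
        rank_wqs=rw,
        wqs_label=lw,
        rank_cds=rc,
        cds_label=lc,
        period=sample.period,
    )
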
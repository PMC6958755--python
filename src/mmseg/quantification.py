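"""ADC parametric maps and per-lesion histogram metrics.

The apparent diffusion coefficient is obtained from the two-point
mono-exponential signal model,

    ADC = -ln(S_i / S_0) / (b_i - b_0)        [mm^2/s]

with S_i the high-b volume (b = 800 or 1000 s/mm^2) and S_0 the b = 0
volume.  Voxels where either signal is non-positive have no defined ADC and
are excluded via the validity mask rather than clipped to +/-inf.  Per-lesion
reporting covers volume and the ADC histogram metrics used for treatment
response work: median, mean, 5th/25th/75th/95th percentiles, skewness
(Fisher g1) and excess kurtosis (Fisher g2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import BinaryMask, LabeledComponents, MaskRole, VolumetricImage

__all__ = [
    "AdcMap",
    "HistogramMetrics",
    "LesionReport",
    "compute_adc",
    "histogram_metrics",
    "lesion_report",
]

METRIC_FIELDS = ("median", "mean", "p5", "p25", "p75", "p95", "skewness", "kurtosis")


@dataclass
class AdcMap:
    """ADC volume (mm^2/s) with its validity mask and b-values."""

    data: np.ndarray
    b_high: float
    b_low: float
    valid_mask: BinaryMask

    def __post_init__(self) -> None:
        if self.b_high <= self.b_low:
            raise ValueError("b_high must exceed b_low")
        if not np.all(np.isfinite(self.data[self.valid_mask.data])):
            raise ValueError("ADC must be finite on its validity mask")

    @property
    def spacing(self):
        return self.valid_mask.spacing

    def to_image(self) -> VolumetricImage:
        out = np.where(self.valid_mask.data, self.data, 0.0)
        m = self.valid_mask
        return VolumetricImage(out, m.spacing, m.origin, m.direction)


def compute_adc(
    s_high: VolumetricImage,
    s_low: VolumetricImage,
    b_high: float,
    b_low: float = 0.0,
    clip_negative: bool = False,
) -> AdcMap:
    """Invert the mono-exponential model voxelwise.

    Negative ADC values (noise pushing S_i above S_0) are retained by
    default to preserve histogram shape; ``clip_negative`` floors them at 0.
    """
    if b_high <= b_low:
        raise ValueError(f"b_high ({b_high}) must exceed b_low ({b_low})")
    if not s_high.grid_compatible(s_low):
        raise ValueError("signal volumes are not grid-compatible")
    valid = (s_high.data > 0) & (s_low.data > 0)
    adc = np.zeros_like(s_high.data, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = -np.log(s_high.data[valid] / s_low.data[valid]) / (b_high - b_low)
    if clip_negative:
        np.clip(adc, 0.0, None, out=adc)
    return AdcMap(
        data=adc,
        b_high=float(b_high),
        b_low=float(b_low),
        valid_mask=BinaryMask.like(s_high, valid),
    )


@dataclass(frozen=True)
class HistogramMetrics:
    n: int
    mean: float
    median: float
    p5: float
    p25: float
    p75: float
    p95: float
    skewness: float | None  # None when undefined (n < 3 or zero variance)
    kurtosis: float | None

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in ("n",) + METRIC_FIELDS}


def histogram_metrics(values: Iterable[float]) -> HistogramMetrics:
    """Summary statistics of an intensity sample.

    Percentiles use linear interpolation of order statistics (the same
    convention as the outlier threshold); skewness is Fisher g1 and kurtosis
    is Fisher excess g2, both undefined — reported as None, never 0 — for
    fewer than 3 values or zero variance.
    """
    x = np.asarray(list(values), dtype=float).ravel()
    if x.size == 0:
        raise ValueError("histogram metrics need at least one value")
    p5, p25, p50, p75, p95 = np.percentile(x, [5, 25, 50, 75, 95], method="linear")
    if x.size >= 3 and np.ptp(x) > 0 and np.var(x) > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    else:
        skew = None
        kurt = None
    return HistogramMetrics(
        n=int(x.size),
        mean=float(x.mean()),
        median=float(p50),
        p5=float(p5),
        p25=float(p25),
        p75=float(p75),
        p95=float(p95),
        skewness=skew,
        kurtosis=kurt,
    )


@dataclass
class LesionReport:
    """Per-lesion and aggregate ADC metrics plus volumes (ml)."""

    per_lesion: list[dict]
    aggregate: dict | None
    flagged: list[int] = field(default_factory=list)  # ids with no valid ADC voxel

    def to_frame(self):
        import pandas as pd

        rows = list(self.per_lesion)
        if self.aggregate is not None:
            rows.append(self.aggregate)
        return pd.DataFrame(rows)


def lesion_report(
    components: LabeledComponents,
    adc: AdcMap,
    restrict_to: Sequence[int] | None = None,
) -> LesionReport:
    """ADC histogram metrics and volume per lesion, plus an aggregate row.

    ``restrict_to`` limits the report to a subset of component ids — e.g.
    the predicted components matched to the gold standard.  Lesions without
    any valid ADC voxel are flagged and their metrics left undefined.
    """
    if not components.grid_compatible(adc.valid_mask):
        raise ValueError("components and ADC map are not grid-compatible")
    ids = (
        [c.id for c in components.components]
        if restrict_to is None
        else sorted(set(int(i) for i in restrict_to))
    )
    vox_ml = float(np.prod(components.spacing)) / 1000.0
    rows: list[dict] = []
    flagged: list[int] = []
    pooled: list[np.ndarray] = []
    total_volume = 0.0
    by_id = {c.id: c for c in components.components}
    for i in ids:
        comp = by_id[i]
        sel = (components.labels == i) & adc.valid_mask.data
        vals = adc.data[sel]
        row = {"lesion_id": i, "volume_ml": comp.voxel_count * vox_ml}
        total_volume += row["volume_ml"]
        if vals.size == 0:
            flagged.append(i)
            row.update({f: None for f in ("n",) + METRIC_FIELDS})
        else:
            pooled.append(vals)
            row.update(histogram_metrics(vals).as_dict())
        rows.append(row)
    aggregate = None
    if pooled:
        aggregate = {"lesion_id": "aggregate", "volume_ml": total_volume}
        aggregate.update(histogram_metrics(np.concatenate(pooled)).as_dict())
    elif ids:
        aggregate = {"lesion_id": "aggregate", "volume_ml": total_volume}
        aggregate.update({f: None for f in ("n",) + METRIC_FIELDS})
    return LesionReport(per_lesion=rows, aggregate=aggregate, flagged=flagged)
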
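"""Threshold-envelope habitat suitability model.

A bioclimatic envelope declares a cell suitable iff every environmental
variable falls inside the range attained at known occurrence sites. For the
Chinese giant salamander the envelope has four conditions: elevation
190-1,330 m a.s.l., mean annual temperature 12.7-16.8 degC, mean annual
precipitation >= 732.6 mm, and forest land cover. All comparisons are
inclusive, since the published ranges are attained values at occupied sites.

The module aggregates 12 monthly climate layers to annual measures,
regroups a categorical land-cover layer into a binary forest mask, and
intersects the thresholded variables into a binary suitability raster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .raster import GridAlignmentError, RasterGrid, align_layers  # noqa: F401  (re-export)

__all__ = [
    "EnvelopeSpec",
    "EnvelopeCondition",
    "giant_salamander_envelope",
    "aggregate_climate",
    "annual_precipitation",
    "regroup_landcover",
    "apply_envelope",
    "align_layers",
]


@dataclass(frozen=True)
class EnvelopeCondition:
    """One per-variable suitability condition.

    kind is one of:

    - ``interval``: params ``(lo, hi)``, suitable iff lo <= value <= hi;
    - ``lower_bound``: params ``(lo,)``, suitable iff value >= lo;
    - ``category_set``: params is an iterable of category ids, suitable iff
      the (integer) value is a member.
    """

    variable: str
    kind: str
    params: tuple

    def __post_init__(self) -> None:
        if self.kind == "interval":
            lo, hi = self.params
            if lo > hi:
                raise ValueError(
                    f"interval for {self.variable!r} has min {lo} > max {hi}"
                )
        elif self.kind == "lower_bound":
            (lo,) = self.params
        elif self.kind == "category_set":
            if len(tuple(self.params)) == 0:
                raise ValueError(f"empty category set for {self.variable!r}")
        else:
            raise ValueError(f"unknown condition kind {self.kind!r}")

    def holds(self, values: np.ndarray) -> np.ndarray:
        """Elementwise truth of the condition (nodata not handled here)."""
        if self.kind == "interval":
            lo, hi = self.params
            return (values >= lo) & (values <= hi)
        if self.kind == "lower_bound":
            (lo,) = self.params
            return values >= lo
        ids = np.asarray(sorted(set(self.params)), dtype=float)
        return np.isin(values, ids)


@dataclass(frozen=True)
class EnvelopeSpec:
    """An ordered set of envelope conditions; order never affects the output."""

    conditions: tuple[EnvelopeCondition, ...]

    @classmethod
    def from_conditions(
        cls, conditions: Iterable[tuple[str, str, Sequence]]
    ) -> "EnvelopeSpec":
        return cls(
            tuple(
                EnvelopeCondition(var, kind, tuple(params))
                for var, kind, params in conditions
            )
        )

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(c.variable for c in self.conditions)


def giant_salamander_envelope(forest_ids: Iterable[int] = (1,)) -> EnvelopeSpec:
    """The published four-variable envelope for *Andrias davidianus*.

    Elevation 190-1,330 m, mean annual temperature 12.7-16.8 degC, annual
    precipitation >= 732.6 mm, land cover in the forest group. ``forest_ids``
    are the ids of the forest classes after regrouping (default: the single
    class 1 produced by :func:`regroup_landcover`).
    """
    return EnvelopeSpec.from_conditions(
        [
            ("elevation", "interval", (190.0, 1330.0)),
            ("temperature", "interval", (12.7, 16.8)),
            ("precipitation", "lower_bound", (732.6,)),
            ("forest", "category_set", tuple(forest_ids)),
        ]
    )


def aggregate_climate(monthly: Sequence[RasterGrid], mode: str = "mean") -> RasterGrid:
    """Collapse 12 monthly layers into one annual layer.

    ``mode="mean"`` gives the mean of the monthly values (mean annual
    temperature); ``mode="sum"`` gives the annual total (precipitation).
    Nodata in any month propagates to nodata in the output.
    """
    if len(monthly) != 12:
        raise ValueError(f"expected 12 monthly layers, got {len(monthly)}")
    first = monthly[0]
    for k, layer in enumerate(monthly[1:], start=2):
        if not first.same_grid(layer):
            raise GridAlignmentError(f"monthly layer {k} is not aligned with layer 1")
    if mode not in {"mean", "sum"}:
        raise ValueError(f"mode must be 'mean' or 'sum', got {mode!r}")
    stack = np.stack([m.values for m in monthly])
    valid = np.stack([m.valid_mask() for m in monthly]).all(axis=0)
    agg = stack.sum(axis=0)
    if mode == "mean":
        agg = agg / 12.0
    out = np.where(valid, agg, first.nodata)
    return first.like(out)


def annual_precipitation(
    monthly: Sequence[RasterGrid], precip_mode: str = "sum"
) -> RasterGrid:
    """Annual precipitation from 12 monthly totals.

    ``precip_mode`` controls the annualisation convention:

    - ``"sum"`` (default): annual total, the scale on which the 732.6 mm
      threshold is defined;
    - ``"mean_x12"``: monthly mean times 12 (identical to ``sum`` up to
      floating point, kept for explicitness);
    - ``"mean"``: plain monthly mean, the literal reading of "averaged" --
      only meaningful with a threshold on the monthly scale.
    """
    if precip_mode == "sum":
        return aggregate_climate(monthly, mode="sum")
    if precip_mode == "mean_x12":
        mean = aggregate_climate(monthly, mode="mean")
        out = np.where(mean.valid_mask(), mean.values * 12.0, mean.nodata)
        return mean.like(out)
    if precip_mode == "mean":
        return aggregate_climate(monthly, mode="mean")
    raise ValueError(f"unknown precip_mode {precip_mode!r}")


def regroup_landcover(
    landcover: RasterGrid, forest_class_ids: Iterable[int]
) -> RasterGrid:
    """Collapse a categorical land-cover layer to a binary forest mask.

    Cells whose class id is in ``forest_class_ids`` become 1, all other
    valid cells 0; nodata is preserved.
    """
    ids = sorted(set(int(i) for i in forest_class_ids))
    if not ids:
        raise ValueError("forest_class_ids must be non-empty")
    valid = landcover.valid_mask()
    binary = np.isin(landcover.values, np.asarray(ids, dtype=float)).astype(float)
    out = np.where(valid, binary, landcover.nodata)
    return landcover.like(out)


def apply_envelope(layers: dict[str, RasterGrid], spec: EnvelopeSpec) -> RasterGrid:
    """Intersect all envelope conditions into a binary suitability raster.

    A cell is 1 iff every condition holds, 0 if any fails, and nodata if any
    input layer is nodata there (absence of evidence is not unsuitability).
    """
    missing = [v for v in spec.variables if v not in layers]
    if missing:
        raise KeyError(
            f"envelope variables missing from layers: {', '.join(missing)}"
        )
    ref: RasterGrid | None = None
    for cond in spec.conditions:
        layer = layers[cond.variable]
        if ref is None:
            ref = layer
        elif not ref.same_grid(layer):
            raise GridAlignmentError(
                f"layer {cond.variable!r} is not aligned with {spec.variables[0]!r}"
            )
    assert ref is not None
    suitable = np.ones(ref.shape, dtype=bool)
    valid = np.ones(ref.shape, dtype=bool)
    for cond in spec.conditions:
        layer = layers[cond.variable]
        valid &= layer.valid_mask()
        suitable &= cond.holds(layer.values)
    out = np.where(valid, suitable.astype(float), ref.nodata)
    return ref.like(out)
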
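"""Growth-plate morphometry and ASBMR static/dynamic histomorphometry.

Inputs are trace tables (lengths, counts, label distances) produced by
manual tracing of sections, not images.  Lengths along the bone perimeter
are in mm, thicknesses and label distances in um, and all surface
parameters are normalised to the total bone perimeter B.Pm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthPlateRaw",
    "HistomorphRecord",
    "GrowthPlateResult",
    "OsteoclastResult",
    "FormationResult",
    "OsteoidResult",
    "growth_plate_heights",
    "osteoclast_params",
    "dynamic_formation",
    "osteoid_params",
    "resorption_fraction",
    "average_records",
    "record_from_segments",
    "read_segment_table",
]

ZONES = ("RZ", "PZ", "HZ")
SEGMENT_FLAGS = ("osteoclast", "osteoid", "eroded", "double_label", "single_label", "plain")


@dataclass(frozen=True)
class GrowthPlateRaw:
    """Zone boundary coordinates and cell counts for one section.

    ``boundary_y_um`` is a (4 locations x 4 boundaries) array of ordered
    y-coordinates: growth-plate top, reserve/proliferative boundary,
    proliferative/hypertrophic boundary, growth-plate bottom.  Cell counts
    are taken in a 200-um-wide central counting region.
    """

    boundary_y_um: np.ndarray
    cell_counts: Mapping[str, int]
    counting_region_width_um: float = 200.0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundary_y_um, dtype=float)
        object.__setattr__(self, "boundary_y_um", b)
        if b.shape != (4, 4):
            raise ValueError(
                f"boundary_y_um must be (4 locations x 4 boundaries), got {b.shape}"
            )
        if not np.isfinite(b).all():
            raise ValueError("boundary coordinates must be finite")
        if np.any(np.diff(b, axis=1) < 0):
            raise ValueError("zone boundaries must be ordered at every location")
        missing = [z for z in ZONES if z not in self.cell_counts]
        if missing:
            raise ValueError(f"cell_counts missing zones: {missing}")
        if any(self.cell_counts[z] < 0 for z in ZONES):
            raise ValueError("cell counts must be >= 0")


@dataclass(frozen=True)
class GrowthPlateResult:
    heights_um: Mapping[str, float]  # per zone, mean over the 4 locations
    total_um: float
    height_fractions_pct: Mapping[str, float]
    cell_counts: Mapping[str, int]
    cell_fractions_pct: Mapping[str, float]


def growth_plate_heights(raw: GrowthPlateRaw) -> GrowthPlateResult:
    """Mean zone heights, total height, and relative fractions.

    Per-zone height is the mean over the four measurement locations;
    relative fractions are zone/total x 100 and therefore sum to 100.
    """
    b = raw.boundary_y_um
    heights = {zone: float(np.mean(b[:, i + 1] - b[:, i])) for i, zone in enumerate(ZONES)}
    total = sum(heights.values())
    if total <= 0:
        raise ValueError("total growth-plate height is zero")
    height_frac = {z: 100.0 * h / total for z, h in heights.items()}
    n_cells = sum(raw.cell_counts[z] for z in ZONES)
    if n_cells > 0:
        cell_frac = {z: 100.0 * raw.cell_counts[z] / n_cells for z in ZONES}
    else:
        cell_frac = {z: float("nan") for z in ZONES}
    return GrowthPlateResult(
        heights_um=heights,
        total_um=total,
        height_fractions_pct=height_frac,
        cell_counts={z: int(raw.cell_counts[z]) for z in ZONES},
        cell_fractions_pct=cell_frac,
    )


@dataclass(frozen=True)
class HistomorphRecord:
    """Traced-surface and label measurements for one section.

    Lengths along the perimeter in mm; ``b_pm_mm`` is the total bone
    perimeter, of which the flagged lengths are subsets.  Osteoid widths
    and inter-label distances are in um.
    """

    b_pm_mm: float
    oc_count: int = 0
    oc_lengths_mm: Sequence[float] = field(default_factory=tuple)
    osteoid_lengths_mm: Sequence[float] = field(default_factory=tuple)
    osteoid_widths_um: Sequence[float] = field(default_factory=tuple)
    eroded_lengths_mm: Sequence[float] = field(default_factory=tuple)
    double_label_mm: float = 0.0
    single_label_mm: float = 0.0
    interlabel_um: Sequence[float] = field(default_factory=tuple)
    label_interval_days: float = 2.0
    section_id: str = ""

    def __post_init__(self) -> None:
        if self.b_pm_mm <= 0:
            raise ValueError("b_pm_mm must be > 0")
        if self.oc_count < 0:
            raise ValueError("oc_count must be >= 0")
        if self.label_interval_days <= 0:
            raise ValueError("label_interval_days must be > 0")
        for name in ("oc_lengths_mm", "osteoid_lengths_mm", "eroded_lengths_mm"):
            vals = getattr(self, name)
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} contains negative lengths")
            if sum(vals) > self.b_pm_mm * (1 + 1e-9):
                raise ValueError(f"{name} total exceeds bone perimeter B.Pm")
        if self.double_label_mm < 0 or self.single_label_mm < 0:
            raise ValueError("label surface lengths must be >= 0")
        if self.double_label_mm + self.single_label_mm > self.b_pm_mm * (1 + 1e-9):
            raise ValueError("labeled surface exceeds bone perimeter B.Pm")
        if any(w < 0 for w in self.osteoid_widths_um):
            raise ValueError("osteoid widths must be >= 0")
        if any(d < 0 for d in self.interlabel_um):
            raise ValueError("inter-label distances must be >= 0")


@dataclass(frozen=True)
class OsteoclastResult:
    oc_n_per_bpm: float  # mm^-1
    oc_s_per_bpm_pct: float  # %
    oc_pm_mm: float  # raw osteoclast perimeter length


def osteoclast_params(rec: HistomorphRecord) -> OsteoclastResult:
    """Oc.N/B.Pm (mm^-1) and Oc.S/B.Pm (%); Oc.Pm emitted as raw length."""
    oc_pm = float(sum(rec.oc_lengths_mm))
    return OsteoclastResult(
        oc_n_per_bpm=rec.oc_count / rec.b_pm_mm,
        oc_s_per_bpm_pct=100.0 * oc_pm / rec.b_pm_mm,
        oc_pm_mm=oc_pm,
    )


@dataclass(frozen=True)
class FormationResult:
    ms_pct: float  # mineralizing surface, % of B.Pm
    mar_um_per_day: Optional[float]  # None when no double labels
    bfr_um_per_day: Optional[float]  # (MS/100) x MAR
    flags: tuple[str, ...] = ()


def dynamic_formation(
    rec: HistomorphRecord, pure_double_label: bool = False
) -> FormationResult:
    """Mineralizing surface, mineral apposition rate and bone formation rate.

    MS follows the ASBMR convention ``(dL + sL/2) / B.Pm`` (single-labeled
    surface counts half); ``pure_double_label=True`` switches to dL only.
    MAR is the mean inter-label distance divided by the label interval, and
    BFR = (MS/100) x MAR so the identity holds exactly on every output.
    """
    labeled = rec.double_label_mm
    if not pure_double_label:
        labeled += rec.single_label_mm / 2.0
    ms = 100.0 * labeled / rec.b_pm_mm
    if rec.double_label_mm > 0 and len(rec.interlabel_um) > 0:
        mar = float(np.mean(rec.interlabel_um)) / rec.label_interval_days
        return FormationResult(ms_pct=ms, mar_um_per_day=mar, bfr_um_per_day=(ms / 100.0) * mar)
    return FormationResult(ms_pct=ms, mar_um_per_day=None, bfr_um_per_day=None,
                           flags=("no_double_labels",))


@dataclass(frozen=True)
class OsteoidResult:
    os_per_bpm_pct: float
    o_th_um: Optional[float]  # None when no width measurements


def osteoid_params(rec: HistomorphRecord) -> OsteoidResult:
    """OS/B.Pm (%) and mean osteoid thickness O.Th (um)."""
    os_pct = 100.0 * float(sum(rec.osteoid_lengths_mm)) / rec.b_pm_mm
    o_th = float(np.mean(rec.osteoid_widths_um)) if rec.osteoid_widths_um else None
    return OsteoidResult(os_per_bpm_pct=os_pct, o_th_um=o_th)


def resorption_fraction(rec: HistomorphRecord) -> float:
    """Eroded surface as % of bone perimeter."""
    return 100.0 * float(sum(rec.eroded_lengths_mm)) / rec.b_pm_mm


def average_records(records: Sequence[HistomorphRecord]) -> dict[str, Optional[float]]:
    """Average derived parameters over section replicates of one animal.

    Sections from separate levels are averaged per animal before any group
    statistics.  MAR/BFR averages skip sections without double labels (and
    are None if no section has them).
    """
    if not records:
        raise ValueError("need at least one record")
    oc = [osteoclast_params(r) for r in records]
    fm = [dynamic_formation(r) for r in records]
    ot = [osteoid_params(r) for r in records]
    mars = [f.mar_um_per_day for f in fm if f.mar_um_per_day is not None]
    out: dict[str, Optional[float]] = {
        "oc_n_per_bpm": float(np.mean([o.oc_n_per_bpm for o in oc])),
        "oc_s_per_bpm_pct": float(np.mean([o.oc_s_per_bpm_pct for o in oc])),
        "ms_pct": float(np.mean([f.ms_pct for f in fm])),
        "mar_um_per_day": float(np.mean(mars)) if mars else None,
        "os_per_bpm_pct": float(np.mean([o.os_per_bpm_pct for o in ot])),
        "o_th_um": (
            float(np.mean([o.o_th_um for o in ot if o.o_th_um is not None]))
            if any(o.o_th_um is not None for o in ot) else None
        ),
        "eroded_pct": float(np.mean([resorption_fraction(r) for r in records])),
    }
    out["bfr_um_per_day"] = (
        (out["ms_pct"] / 100.0) * out["mar_um_per_day"]
        if out["mar_um_per_day"] is not None else None
    )
    return out


def record_from_segments(
    table: pd.DataFrame,
    label_interval_days: float = 2.0,
    section_id: str = "",
) -> HistomorphRecord:
    """Build a record from a per-section segment table.

    Expected columns: ``segment_id, length_um, flag, width_um,
    interlabel_um``; flags are one of osteoclast | osteoid | eroded |
    double_label | single_label | plain.  B.Pm is the sum of all segment
    lengths; each osteoclast-flagged segment counts as one osteoclast.
    """
    required = {"segment_id", "length_um", "flag"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    bad = set(table["flag"]) - set(SEGMENT_FLAGS)
    if bad:
        raise ValueError(f"unknown segment flags: {sorted(bad)}")
    lengths_mm = table["length_um"].astype(float) / 1000.0
    if (lengths_mm < 0).any():
        raise ValueError("segment lengths must be >= 0")

    def _flag_lengths(flag: str) -> tuple[float, ...]:
        return tuple(lengths_mm[table["flag"] == flag])

    widths = ()
    if "width_um" in table.columns:
        w = table.loc[table["flag"] == "osteoid", "width_um"].dropna()
        widths = tuple(w.astype(float))
    distances = ()
    if "interlabel_um" in table.columns:
        d = table.loc[table["flag"] == "double_label", "interlabel_um"].dropna()
        distances = tuple(d.astype(float))

    return HistomorphRecord(
        b_pm_mm=float(lengths_mm.sum()),
        oc_count=int((table["flag"] == "osteoclast").sum()),
        oc_lengths_mm=_flag_lengths("osteoclast"),
        osteoid_lengths_mm=_flag_lengths("osteoid"),
        osteoid_widths_um=widths,
        eroded_lengths_mm=_flag_lengths("eroded"),
        double_label_mm=float(sum(_flag_lengths("double_label"))),
        single_label_mm=float(sum(_flag_lengths("single_label"))),
        interlabel_um=distances,
        label_interval_days=label_interval_days,
        section_id=section_id,
    )


def read_segment_table(path, label_interval_days: float = 2.0) -> HistomorphRecord:
    """Read one section's segment CSV and build its record."""
    table = pd.read_csv(path)
    return record_from_segments(
        table, label_interval_days=label_interval_days, section_id=str(path)
    )
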
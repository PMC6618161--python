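"""Synthetic ground-truth generators for every pipeline input.

All generators draw from :class:`numpy.random.Generator` (PCG64) seeded via
:class:`numpy.random.SeedSequence`; a single user-supplied integer seed is
split deterministically per sub-generator, so fixed seeds give bit-identical
artifacts across runs and platforms.  Every generator returns its ground
truth alongside the artifact so downstream recovery tests never rely on
hidden state.

Generators
----------
``gen_load_displacement``
    Bilinear elastic/plastic fracture curve sampled like a
    displacement-controlled destructive test (0.03 mm/s at 20 Hz).
``gen_reference_cohort`` / ``gen_mutant_group``
    Wild-type reference cohort with a linear BMC->biomechanics relationship
    plus residual noise, and mutant groups carrying an injected
    bone-quality deficit in residual-SD units.
``gen_gray_field``
    Grayscale raster containing calibration-standard regions and a bone
    region drawn from a configurable mineralization-density distribution.
``gen_histomorph_tables``
    Growth-plate zone boundary tables and perimeter-segment trace tables
    for static and dynamic histomorphometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from skelphen.biomech import LoadDisplacementCurve
from skelphen.histomorph import GrowthPlateRaw, HistomorphRecord

__all__ = [
    "CurveParams",
    "ParamLine",
    "CohortModel",
    "GrayField",
    "HistomorphSimConfig",
    "SyntheticCurve",
    "SyntheticCohort",
    "BIOMECH_PARAMETERS",
    "curve_template",
    "gen_load_displacement",
    "gen_reference_cohort",
    "gen_mutant_group",
    "gen_gray_field",
    "gen_histomorph_tables",
    "cohort_model_from_cvs",
    "default_cohort_model",
]

#: Biomechanical parameters carried by cohort tables, in canonical order.
BIOMECH_PARAMETERS = ("yield_load", "max_load", "fracture_load", "stiffness")


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and > 0, got {value}")


def _check_nonnegative(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value}")


# ---------------------------------------------------------------------------
# load-displacement curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveParams:
    """Ground-truth parameters of a bilinear elastic/plastic fracture curve.

    The generated template is: a pre-contact toe of near-zero load
    (``toe_mm``), a linear elastic ramp of slope ``stiffness`` up to
    ``yield_load``, a hardening ramp of slope
    ``hardening_ratio * stiffness`` up to ``max_load``, a softening decline
    to ``fracture_fraction * max_load`` over ``decline_mm``, then a
    single-step drop to zero followed by a short zero-load tail.
    """

    stiffness: float = 100.0  # N/mm
    yield_load: float = 10.0  # N
    max_load: float = 15.0  # N
    fracture_fraction: float = 0.8  # fracture load / max load, in (0, 1]
    hardening_ratio: float = 0.1  # post-yield slope / elastic slope
    noise_sd: float = 0.0  # N, additive Gaussian on load only
    displacement_rate: float = 0.03  # mm/s
    sample_rate: float = 20.0  # Hz
    toe_mm: float = 0.05  # pre-contact segment length
    decline_mm: float = 0.1  # post-peak softening span
    tail_mm: float = 0.02  # post-fracture zero-load tail

    def __post_init__(self) -> None:
        _check_positive("stiffness", self.stiffness)
        _check_positive("yield_load", self.yield_load)
        _check_positive("max_load", self.max_load)
        _check_positive("displacement_rate", self.displacement_rate)
        _check_positive("sample_rate", self.sample_rate)
        _check_nonnegative("noise_sd", self.noise_sd)
        _check_nonnegative("toe_mm", self.toe_mm)
        _check_nonnegative("tail_mm", self.tail_mm)
        _check_positive("decline_mm", self.decline_mm)
        if self.max_load < self.yield_load:
            raise ValueError(
                f"max_load ({self.max_load}) must be >= yield_load ({self.yield_load})"
            )
        if not 0 < self.fracture_fraction <= 1:
            raise ValueError(
                f"fracture_fraction must be in (0, 1], got {self.fracture_fraction}"
            )
        if not 0 <= self.hardening_ratio <= 0.5:
            raise ValueError(
                f"hardening_ratio must be in [0, 0.5], got {self.hardening_ratio}"
            )
        if self.max_load > self.yield_load and self.hardening_ratio == 0:
            raise ValueError(
                "hardening_ratio must be > 0 when max_load > yield_load"
            )

    @property
    def fracture_load(self) -> float:
        return self.fracture_fraction * self.max_load


def curve_template(params: CurveParams) -> Callable[[np.ndarray], np.ndarray]:
    """Return the noiseless piecewise load function f(displacement)."""
    p = params
    x_contact = p.toe_mm
    x_yield = x_contact + p.yield_load / p.stiffness
    if p.max_load > p.yield_load:
        x_peak = x_yield + (p.max_load - p.yield_load) / (
            p.hardening_ratio * p.stiffness
        )
    else:
        # flat plateau at max load so the peak region has non-zero extent
        x_peak = x_yield + p.decline_mm
    if p.fracture_fraction < 1:
        x_frac = x_peak + p.decline_mm
    else:
        x_frac = x_peak  # fracture straight off the peak

    def f(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x)
        m_elastic = (x >= x_contact) & (x < x_yield)
        y[m_elastic] = p.stiffness * (x[m_elastic] - x_contact)
        if p.max_load > p.yield_load:
            m_hard = (x >= x_yield) & (x <= x_peak)
            y[m_hard] = p.yield_load + p.hardening_ratio * p.stiffness * (
                x[m_hard] - x_yield
            )
        else:
            m_hard = (x >= x_yield) & (x <= x_peak)
            y[m_hard] = p.max_load
        if p.fracture_fraction < 1:
            m_decl = (x > x_peak) & (x <= x_frac)
            frac = p.fracture_fraction * p.max_load
            y[m_decl] = p.max_load + (frac - p.max_load) * (
                (x[m_decl] - x_peak) / p.decline_mm
            )
        # beyond x_frac the specimen has failed: load is zero
        return y

    f.x_contact = x_contact  # type: ignore[attr-defined]
    f.x_yield = x_yield  # type: ignore[attr-defined]
    f.x_peak = x_peak  # type: ignore[attr-defined]
    f.x_fracture = x_frac  # type: ignore[attr-defined]
    return f


@dataclass(frozen=True)
class SyntheticCurve:
    """A generated curve together with its generating parameters."""

    curve: LoadDisplacementCurve
    truth: CurveParams


def gen_load_displacement(
    params: CurveParams, seed: int, specimen_id: str = ""
) -> SyntheticCurve:
    """Sample a destructive-test curve from the piecewise template.

    Displacement advances at ``displacement_rate / sample_rate`` mm per
    sample (the actuator is displacement-controlled, so displacement is
    exact); i.i.d. Gaussian noise of sd ``noise_sd`` is added to load only.
    """
    rng = np.random.default_rng(seed)
    f = curve_template(params)
    dx = params.displacement_rate / params.sample_rate
    x_end = f.x_fracture + params.tail_mm  # type: ignore[attr-defined]
    n = int(np.floor(x_end / dx)) + 2
    x = np.arange(n) * dx
    y = f(x)
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, size=n)
    curve = LoadDisplacementCurve(
        displacement=x,
        load=y,
        sample_rate=params.sample_rate,
        specimen_id=specimen_id,
    )
    return SyntheticCurve(curve=curve, truth=params)


# ---------------------------------------------------------------------------
# reference cohorts and mutant groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamLine:
    """Linear BMC->parameter relationship with residual scatter."""

    slope: float  # parameter units per gray-level unit
    intercept: float  # parameter units
    residual_sd: float  # parameter units

    def __post_init__(self) -> None:
        _check_nonnegative("residual_sd", self.residual_sd)


@dataclass(frozen=True)
class CohortModel:
    """Generating model of a reference cohort.

    BMC ~ Normal(bmc_mean, (bmc_cv * bmc_mean)^2); each biomechanical
    parameter is ``intercept + slope * BMC + Normal(0, residual_sd^2)``.
    """

    n: int = 320
    bmc_mean: float = 100.0  # relative gray-level units
    bmc_cv: float = 0.02
    lines: Mapping[str, ParamLine] = field(default_factory=dict)
    sex: str = "female"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"n must be >= 3 (regression needs >= 3 points), got {self.n}")
        _check_positive("bmc_mean", self.bmc_mean)
        _check_nonnegative("bmc_cv", self.bmc_cv)
        if not self.lines:
            raise ValueError("lines must map at least one parameter to a ParamLine")


def cohort_model_from_cvs(
    n: int = 320,
    bmc_mean: float = 100.0,
    bmc_cv: float = 0.02,
    param_means: Optional[Mapping[str, float]] = None,
    param_cvs: Optional[Mapping[str, float]] = None,
    bmc_correlation: float = 0.6,
    sex: str = "female",
    seed: int = 0,
) -> CohortModel:
    """Build a :class:`CohortModel` from marginal CV targets.

    The marginal variance of each parameter is split between the BMC slope
    and the residual so that corr(BMC, parameter) = ``bmc_correlation``:
    ``slope * sd_bmc = rho * sd_param`` and
    ``residual_sd = sd_param * sqrt(1 - rho^2)``.
    """
    if param_means is None:
        param_means = {
            "yield_load": 10.0,
            "max_load": 15.0,
            "fracture_load": 12.0,
            "stiffness": 100.0,
        }
    if param_cvs is None:
        # CV catalogue: BMC 2%, maximum load 9%, fracture load 20%;
        # yield load and stiffness are given the maximum-load figure.
        param_cvs = {
            "yield_load": 0.09,
            "max_load": 0.09,
            "fracture_load": 0.20,
            "stiffness": 0.09,
        }
    if not 0 < bmc_correlation < 1:
        raise ValueError("bmc_correlation must be in (0, 1)")
    sd_bmc = bmc_cv * bmc_mean
    if sd_bmc <= 0:
        raise ValueError("bmc_cv must be > 0 to carry a BMC->parameter slope")
    lines = {}
    for name, mean in param_means.items():
        sd_param = param_cvs[name] * mean
        slope = bmc_correlation * sd_param / sd_bmc
        intercept = mean - slope * bmc_mean
        residual_sd = sd_param * float(np.sqrt(1 - bmc_correlation**2))
        lines[name] = ParamLine(slope=slope, intercept=intercept, residual_sd=residual_sd)
    return CohortModel(
        n=n, bmc_mean=bmc_mean, bmc_cv=bmc_cv, lines=lines, sex=sex, seed=seed
    )


def default_cohort_model(n: int = 320, seed: int = 0) -> CohortModel:
    """Reference model matching the published CV catalogue."""
    return cohort_model_from_cvs(n=n, seed=seed)


@dataclass(frozen=True)
class SyntheticCohort:
    """Specimen table plus the generating model (ground truth)."""

    table: pd.DataFrame
    model: CohortModel
    deficit_sd: Mapping[str, float] = field(default_factory=dict)


def _draw_specimens(
    model: CohortModel, n: int, rng: np.random.Generator, genotype: str
) -> pd.DataFrame:
    bmc = rng.normal(model.bmc_mean, model.bmc_cv * model.bmc_mean, size=n)
    data = {
        "specimen_id": [f"{genotype}_{i:04d}" for i in range(n)],
        "genotype": genotype,
        "sex": model.sex,
        "bmc": bmc,
    }
    for name, line in model.lines.items():
        noise = rng.normal(0.0, line.residual_sd, size=n) if line.residual_sd > 0 else 0.0
        data[name] = line.intercept + line.slope * bmc + noise
    return pd.DataFrame(data)


def gen_reference_cohort(model: CohortModel) -> SyntheticCohort:
    """Draw the wild-type reference cohort from the generating model."""
    rng = np.random.default_rng(np.random.SeedSequence(model.seed).spawn(1)[0])
    table = _draw_specimens(model, model.n, rng, genotype="WT")
    return SyntheticCohort(table=table, model=model)


def gen_mutant_group(
    model: CohortModel,
    deficit_sd: float | Mapping[str, float],
    n: int,
    seed: int,
    genotype: str = "mut",
) -> SyntheticCohort:
    """Draw a mutant group with an injected bone-quality deficit.

    Specimens are drawn exactly as in :func:`gen_reference_cohort`, then
    each biomechanical parameter is shifted by
    ``deficit_sd * residual_sd`` (negative = weaker than predicted from
    BMC).  The injected deficit is recorded as ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(deficit_sd, Mapping):
        deficit_sd = {name: float(deficit_sd) for name in model.lines}
    for name, d in deficit_sd.items():
        if name not in model.lines:
            raise ValueError(f"unknown parameter {name!r} in deficit_sd")
        if d != 0 and model.lines[name].residual_sd == 0:
            raise ValueError(
                f"deficit for {name!r} undefined: residual_sd is 0"
            )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    group = replace(model, n=max(n, 3))
    table = _draw_specimens(group, n, rng, genotype=genotype)
    for name, d in deficit_sd.items():
        table[name] = table[name] + d * model.lines[name].residual_sd
    return SyntheticCohort(table=table, model=model, deficit_sd=dict(deficit_sd))


# ---------------------------------------------------------------------------
# gray-level fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrayField:
    """Raster with calibration-standard regions and a bone mask.

    ``standard_regions`` maps a standard name to a 0-based, half-open
    rectangle ``(row0, row1, col0, col1)``; ``standard_densities`` carries
    the known material density of each standard.  ``truth`` records the
    generating density->gray map and bone-density distribution.
    """

    pixels: np.ndarray  # uint8 or uint16 raster
    standard_regions: Mapping[str, tuple[int, int, int, int]]
    standard_densities: Mapping[str, float]
    bone_mask: np.ndarray  # boolean raster, disjoint from standards
    truth: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype not in (np.dtype("uint8"), np.dtype("uint16")):
            raise ValueError("pixels must be uint8 or uint16")
        mask = np.asarray(self.bone_mask, dtype=bool)
        if mask.shape != px.shape:
            raise ValueError("bone_mask shape must match pixels")
        for name, (r0, r1, c0, c1) in self.standard_regions.items():
            if not (0 <= r0 < r1 <= px.shape[0] and 0 <= c0 < c1 <= px.shape[1]):
                raise ValueError(f"standard region {name!r} outside raster")
            if mask[r0:r1, c0:c1].any():
                raise ValueError(f"standard region {name!r} overlaps bone mask")
        if set(self.standard_regions) != set(self.standard_densities):
            raise ValueError("standard_regions and standard_densities must share keys")

    @property
    def bit_depth(self) -> int:
        return 8 if self.pixels.dtype == np.uint8 else 16


def gen_gray_field(
    bone_density_mean: float,
    bone_density_sd: float,
    standards: Sequence[tuple[str, float]],
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
    gain: float = 20.0,
    offset: float = 1000.0,
    noise_sd: float = 0.0,
    bit_depth: int = 16,
) -> GrayField:
    """Generate a gray-level field with standard regions and a bone region.

    gray = gain * density + offset (+ Gaussian noise), rounded and clipped
    to the bit depth.  Standard regions are laid out along the top rows;
    the bone mask is a centred rectangle in the remaining area.
    """
    if len(standards) < 2:
        raise ValueError("calibration needs at least 2 standards")
    names = [s[0] for s in standards]
    if len(set(names)) != len(names):
        raise ValueError("standard names must be unique")
    densities = [s[1] for s in standards]
    if len(set(densities)) != len(densities):
        raise ValueError("standards must have distinct densities")
    _check_positive("bone_density_sd", bone_density_sd)
    _check_positive("gain", gain)
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    rows, cols = size
    patch = 16  # 16x16 standard patches: comfortably >= 25 px each
    if rows < 2 * patch + 8 or cols < patch * len(standards) + 8:
        raise ValueError(f"size {size} too small for {len(standards)} standards")

    ss = np.random.SeedSequence(seed)
    rng_std, rng_bone = (np.random.default_rng(s) for s in ss.spawn(2))
    dmax = float(2**bit_depth - 1)

    gray = np.zeros(size, dtype=float)
    regions: dict[str, tuple[int, int, int, int]] = {}
    dens: dict[str, float] = {}
    for k, (name, density) in enumerate(standards):
        c0 = 4 + k * (patch + 4)
        rect = (4, 4 + patch, c0, c0 + patch)
        block = gain * density + offset
        if noise_sd > 0:
            block = block + rng_std.normal(0.0, noise_sd, size=(patch, patch))
        gray[rect[0] : rect[1], rect[2] : rect[3]] = block
        regions[name] = rect
        dens[name] = float(density)

    mask = np.zeros(size, dtype=bool)
    mask[2 * patch :, 4 : cols - 4] = True
    n_bone = int(mask.sum())
    bone_density = rng_bone.normal(bone_density_mean, bone_density_sd, size=n_bone)
    bone_gray = gain * bone_density + offset
    if noise_sd > 0:
        bone_gray = bone_gray + rng_bone.normal(0.0, noise_sd, size=n_bone)
    gray[mask] = bone_gray

    dtype = np.uint8 if bit_depth == 8 else np.uint16
    pixels = np.clip(np.rint(gray), 0, dmax).astype(dtype)
    return GrayField(
        pixels=pixels,
        standard_regions=regions,
        standard_densities=dens,
        bone_mask=mask,
        truth={
            "gain": gain,
            "offset": offset,
            "bone_density_mean": bone_density_mean,
            "bone_density_sd": bone_density_sd,
            "noise_sd": noise_sd,
        },
    )


# ---------------------------------------------------------------------------
# histomorphometry trace tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HistomorphSimConfig:
    """Ground truth for one simulated section's trace tables."""

    # growth plate (heights in um, 4 measurement locations)
    rz_height: float = 50.0
    pz_height: float = 100.0
    hz_height: float = 50.0
    zone_jitter: float = 0.0  # sd of per-location height jitter, um
    cells_rz: int = 20
    cells_pz: int = 60
    cells_hz: int = 25
    # perimeter traces (B.Pm in mm; coverages as fractions of B.Pm)
    b_pm_mm: float = 10.0
    oc_coverage: float = 0.12
    oc_count: int = 5
    osteoid_coverage: float = 0.05
    osteoid_thickness_um: float = 4.0
    eroded_coverage: float = 0.25
    double_label_coverage: float = 0.20
    single_label_coverage: float = 0.0
    # calcein labels
    interlabel_mean_um: float = 4.0
    interlabel_jitter: float = 0.0  # sd of each distance measurement, um
    n_interlabel: int = 20
    label_interval_days: float = 2.0  # injections 5 and 3 days pre-euthanasia
    trace_jitter: float = 0.0  # multiplicative sd on segment lengths

    def __post_init__(self) -> None:
        for name in ("rz_height", "pz_height", "hz_height", "b_pm_mm",
                     "interlabel_mean_um", "label_interval_days"):
            _check_positive(name, getattr(self, name))
        for name in ("zone_jitter", "interlabel_jitter", "trace_jitter",
                     "osteoid_thickness_um"):
            _check_nonnegative(name, getattr(self, name))
        for name in ("oc_coverage", "osteoid_coverage", "eroded_coverage",
                     "double_label_coverage", "single_label_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")


def _jittered_lengths(
    total_mm: float, n_parts: int, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Split a total length into parts with multiplicative jitter.

    Jitter perturbs the split but preserves the exact total, so configured
    coverage fractions remain exact ground truth.
    """
    if total_mm <= 0 or n_parts == 0:
        return np.zeros(0)
    w = np.ones(n_parts)
    if jitter > 0:
        w = np.exp(rng.normal(0.0, jitter, size=n_parts))
    return total_mm * w / w.sum()


def gen_histomorph_tables(
    config: HistomorphSimConfig, seed: int
) -> tuple[HistomorphRecord, GrowthPlateRaw]:
    """Generate one section's perimeter trace table and growth-plate table."""
    cov_sum = (
        config.oc_coverage
        + config.osteoid_coverage
        + config.eroded_coverage
        + config.double_label_coverage
        + config.single_label_coverage
    )
    if cov_sum > 1:
        raise ValueError(
            f"flagged coverage fractions sum to {cov_sum:.3f} > 1"
        )
    ss = np.random.SeedSequence(seed)
    rng_gp, rng_tr, rng_lb = (np.random.default_rng(s) for s in ss.spawn(3))

    # growth plate: boundary y-coordinates at 4 x-locations, top at y=0
    boundaries = np.zeros((4, 4))
    for loc in range(4):
        rz = config.rz_height
        pz = config.pz_height
        hz = config.hz_height
        if config.zone_jitter > 0:
            rz = max(rz + rng_gp.normal(0, config.zone_jitter), 1e-6)
            pz = max(pz + rng_gp.normal(0, config.zone_jitter), 1e-6)
            hz = max(hz + rng_gp.normal(0, config.zone_jitter), 1e-6)
        boundaries[loc] = (0.0, rz, rz + pz, rz + pz + hz)
    growth_plate = GrowthPlateRaw(
        boundary_y_um=boundaries,
        cell_counts={
            "RZ": config.cells_rz,
            "PZ": config.cells_pz,
            "HZ": config.cells_hz,
        },
        counting_region_width_um=200.0,
    )

    # perimeter segments: flagged coverages plus a plain remainder
    segments: list[tuple[str, float]] = []
    plan = [
        ("osteoclast", config.oc_coverage, max(config.oc_count, 1)),
        ("osteoid", config.osteoid_coverage, 4),
        ("eroded", config.eroded_coverage, 4),
        ("double_label", config.double_label_coverage, 4),
        ("single_label", config.single_label_coverage, 4),
    ]
    for flag, coverage, n_parts in plan:
        for length in _jittered_lengths(
            coverage * config.b_pm_mm, n_parts if coverage > 0 else 0,
            config.trace_jitter, rng_tr,
        ):
            segments.append((flag, float(length)))
    plain_total = config.b_pm_mm * (1 - cov_sum)
    for length in _jittered_lengths(plain_total, 6, config.trace_jitter, rng_tr):
        segments.append(("plain", float(length)))

    widths = np.full(8, config.osteoid_thickness_um)
    if config.trace_jitter > 0:
        widths = widths * np.exp(rng_tr.normal(0, config.trace_jitter, size=8))

    distances = np.full(config.n_interlabel, config.interlabel_mean_um)
    if config.interlabel_jitter > 0:
        distances = distances + rng_lb.normal(
            0, config.interlabel_jitter, size=config.n_interlabel
        )
        distances = np.clip(distances, 0.0, None)

    record = HistomorphRecord(
        b_pm_mm=config.b_pm_mm,
        oc_count=config.oc_count,
        oc_lengths_mm=tuple(l for f, l in segments if f == "osteoclast"),
        osteoid_lengths_mm=tuple(l for f, l in segments if f == "osteoid"),
        osteoid_widths_um=tuple(float(w) for w in widths),
        eroded_lengths_mm=tuple(l for f, l in segments if f == "eroded"),
        double_label_mm=sum(l for f, l in segments if f == "double_label"),
        single_label_mm=sum(l for f, l in segments if f == "single_label"),
        interlabel_um=tuple(float(d) for d in distances),
        label_interval_days=config.label_interval_days,
    )
    return record, growth_plate
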
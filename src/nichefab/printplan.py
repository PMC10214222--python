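"""Compile multi-region niche designs into resist-batched print plans.

A niche design is a named set of regions, each with a geometry (a filament
polyline or an axis-aligned rectangular domain, coordinates in µm in a
lower-left-origin, y-up niche frame) and a target set of material
microproperties. Compilation solves each region's fabrication variables by
inverse design, discretizes area regions into serpentine raster paths with
pitch equal to the achieved linewidth, and groups segments by identical
photoresist composition so that all segments sharing a resist are printed
contiguously — minimizing the number of serial resist exchanges in the flow
cell. Batches are ordered stiff-to-soft (descending monomer concentration).

Plans serialize to a versioned JSON schema; a plain-text motion listing (one
line per path vertex) is available for portability.
"""

from __future__ import annotations

import json
from typing import Annotated, Literal, Optional, Union

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from shapely.geometry import LineString, box
from shapely.ops import unary_union

from . import inverse_design as inv
from .errors import CompileError, ValidationError
from .inverse_design import DesignTarget, solve_fabrication
from .statespace import StateSpace

__all__ = [
    "TargetSpec",
    "FilamentGeometry",
    "RectGeometry",
    "NicheRegion",
    "ArrayLayout",
    "NicheDesign",
    "ResistBatch",
    "PrintSegment",
    "PrintPlan",
    "validate_design",
    "compile_plan",
    "export_plan",
    "load_plan",
    "load_design",
    "motion_listing",
    "coverage_report",
]

SCHEMA_VERSION = "1.0"
#: Compositions are identical when every field agrees within this tolerance.
COMPOSITION_TOL = 1e-9


class TargetSpec(BaseModel):
    """Desired microproperties of one region (JSON-facing mirror of DesignTarget)."""

    E_des: float = Field(gt=0, description="desired Young's modulus, kPa")
    W_des: float = Field(gt=0, description="desired linewidth, um")
    conjugates: dict[str, float] = Field(default_factory=dict)

    def to_design_target(self) -> DesignTarget:
        return DesignTarget(
            E_des=self.E_des,
            W_des=self.W_des,
            conjugates=tuple(sorted(self.conjugates.items())),
        )


class FilamentGeometry(BaseModel):
    kind: Literal["filament"] = "filament"
    points: list[tuple[float, float]] = Field(min_length=2)
    linewidth: float = Field(gt=0)


class RectGeometry(BaseModel):
    kind: Literal["rect"] = "rect"
    origin: tuple[float, float]
    width: float = Field(gt=0)
    height: float = Field(gt=0)


Geometry = Annotated[Union[FilamentGeometry, RectGeometry], Field(discriminator="kind")]


class NicheRegion(BaseModel):
    region_id: str
    geometry: Geometry
    target: TargetSpec

    @model_validator(mode="after")
    def _filament_linewidth_matches_target(self):
        g = self.geometry
        if g.kind == "filament" and abs(g.linewidth - self.target.W_des) > 1e-9:
            raise ValueError(
                f"region {self.region_id!r}: filament linewidth {g.linewidth} "
                f"must equal target W_des {self.target.W_des}"
            )
        return self


class ArrayLayout(BaseModel):
    rows: int = Field(ge=1)
    cols: int = Field(ge=1)
    pitch: float = Field(gt=0, description="replicate pitch, um")


class NicheDesign(BaseModel):
    name: str
    regions: list[NicheRegion] = Field(min_length=1)
    array_layout: Optional[ArrayLayout] = None

    @field_validator("regions")
    @classmethod
    def _unique_ids(cls, regions):
        ids = [r.region_id for r in regions]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate region ids in {ids}")
        return regions


class ResistBatch(BaseModel):
    batch_id: str
    peg_conc: float
    pi_conc: float
    conjugates: dict[str, float] = Field(default_factory=dict)


class PrintSegment(BaseModel):
    path: list[tuple[float, float]] = Field(min_length=2)
    focus_z: float
    linewidth: float = Field(gt=0, description="footprint width, um")
    laser_power: float = 100.0
    scan_velocity: float = inv.SCAN_VELOCITY
    scan_velocity_unit: str = inv.SCAN_VELOCITY_UNIT
    batch_id: str
    region_id: str


class PrintPlan(BaseModel):
    schema_version: str = SCHEMA_VERSION
    design_name: str
    seed: int
    batches: list[ResistBatch]
    segments: list[PrintSegment]
    exchange_count: int

    @model_validator(mode="after")
    def _check_structure(self):
        ids = {b.batch_id for b in self.batches}
        runs = 0
        prev = None
        for seg in self.segments:
            if seg.batch_id not in ids:
                raise ValueError(f"segment refers to unknown batch {seg.batch_id!r}")
            if seg.batch_id != prev:
                runs += 1
                prev = seg.batch_id
        if self.segments and self.exchange_count != runs - 1:
            raise ValueError(
                f"exchange_count {self.exchange_count} != contiguous runs - 1 ({runs - 1})"
            )
        return self


def validate_design(design: NicheDesign) -> list[str]:
    """Report every region whose target violates the characterized envelope.

    An empty report means the design is printable by interpolation. Conjugate
    concentrations above the 4 mM interpolation envelope but within the
    8 mM experimentally explored range are flagged with an explicit note.
    """
    issues = []
    for region in design.regions:
        target = region.target.to_design_target()
        for issue in inv.check_envelope(target):
            if "conjugate" in issue:
                for name, conc in target.conjugates:
                    if inv.ENVELOPE["conjugate_mM_max"] < conc <= 8.0 and name in issue:
                        issue += (
                            " (concentrations up to 8 mM were explored "
                            "experimentally but lie outside the interpolation "
                            "envelope)"
                        )
            issues.append(f"region {region.region_id!r}: {issue}")
    return issues


def _serpentine(rect: RectGeometry, pitch: float) -> list[tuple[float, float]]:
    """Serpentine raster along x with line spacing <= pitch, full coverage."""
    x0, y0 = rect.origin
    w, h = rect.width, rect.height
    half = pitch / 2.0
    if h <= pitch:
        ys = np.array([y0 + h / 2.0])
    else:
        n = int(np.ceil((h - pitch) / pitch)) + 2
        ys = np.linspace(y0 + half, y0 + h - half, n)
    path = []
    for i, y in enumerate(ys):
        xs = (x0, x0 + w) if i % 2 == 0 else (x0 + w, x0)
        path.append((float(xs[0]), float(y)))
        path.append((float(xs[1]), float(y)))
    return path


def _composition_key(peg_conc, pi_conc, conjugates):
    conj = tuple(sorted((k, round(v / COMPOSITION_TOL) * COMPOSITION_TOL)
                        for k, v in conjugates))
    return (
        round(peg_conc / COMPOSITION_TOL) * COMPOSITION_TOL,
        round(pi_conc / COMPOSITION_TOL) * COMPOSITION_TOL,
        conj,
    )


def compile_plan(
    design: NicheDesign,
    space: StateSpace,
    seed: int = 0,
    allow_invalid: bool = False,
    branch: str = "upper",
) -> PrintPlan:
    """Solve every region and emit a resist-batched, deterministic plan."""
    issues = validate_design(design)
    if issues and not allow_invalid:
        raise ValidationError(
            "design violates the fabrication envelope:\n  " + "\n  ".join(issues)
        )
    solved = []
    for region in design.regions:
        target = region.target.to_design_target()
        try:
            fab, report = solve_fabrication(
                target, space, seed=seed, branch=branch,
                enforce_envelope=not allow_invalid,
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with region context
            raise CompileError(
                f"inverse design failed for region {region.region_id!r}: {exc}"
            ) from exc
        solved.append((region, fab, report))

    # group by identical resist composition
    batches: dict[tuple, ResistBatch] = {}
    members: dict[tuple, list] = {}
    for region, fab, report in solved:
        key = _composition_key(fab.peg_conc, fab.pi_conc, fab.conjugates)
        if key not in batches:
            batches[key] = ResistBatch(
                batch_id=f"B{len(batches) + 1:02d}",
                peg_conc=fab.peg_conc,
                pi_conc=fab.pi_conc,
                conjugates=dict(fab.conjugates),
            )
            members[key] = []
        members[key].append((region, fab, report))

    # stiff-to-soft: descending monomer concentration, then insertion order
    order = sorted(batches, key=lambda k: (-batches[k].peg_conc, batches[k].batch_id))
    segments = []
    for key in order:
        batch = batches[key]
        for region, fab, report in members[key]:
            g = region.geometry
            if g.kind == "filament":
                path = [tuple(map(float, p)) for p in g.points]
                width = g.linewidth
            else:
                width = report.achieved_W if report.achieved_W > 0 else region.target.W_des
                path = _serpentine(g, pitch=width)
            segments.append(
                PrintSegment(
                    path=path,
                    focus_z=fab.focus_z,
                    linewidth=float(width),
                    batch_id=batch.batch_id,
                    region_id=region.region_id,
                )
            )
    return PrintPlan(
        design_name=design.name,
        seed=seed,
        batches=[batches[k] for k in order],
        segments=segments,
        exchange_count=max(len(order) - 1, 0),
    )


def export_plan(plan: PrintPlan, path, motion_path=None) -> None:
    """Serialize a plan to JSON (and optionally a text motion listing)."""
    if not plan.segments:
        raise ValidationError("refusing to export a plan with no segments")
    with open(path, "w") as fh:
        fh.write(plan.model_dump_json(indent=2))
    if motion_path is not None:
        with open(motion_path, "w") as fh:
            fh.write(motion_listing(plan))


def motion_listing(plan: PrintPlan) -> str:
    """One line per vertex: x_um y_um focus_mm power_pct velocity batch."""
    lines = []
    for seg in plan.segments:
        for x, y in seg.path:
            lines.append(
                f"{x:.3f} {y:.3f} {seg.focus_z:.4f} {seg.laser_power:.1f} "
                f"{seg.scan_velocity:.1f} {seg.batch_id}"
            )
    return "\n".join(lines) + "\n"


def load_plan(path) -> PrintPlan:
    with open(path) as fh:
        return PrintPlan.model_validate(json.load(fh))


def load_design(path) -> NicheDesign:
    with open(path) as fh:
        return NicheDesign.model_validate(json.load(fh))


def _region_polygon(region: NicheRegion):
    g = region.geometry
    if g.kind == "rect":
        x0, y0 = g.origin
        return box(x0, y0, x0 + g.width, y0 + g.height)
    return LineString(g.points).buffer(g.linewidth / 2.0, cap_style="flat")


def coverage_report(plan: PrintPlan, design: NicheDesign) -> dict[str, float]:
    """Fraction of each region's footprint covered by its segments' footprints.

    Segment footprints are the print paths dilated by half the linewidth;
    coverage is the polygon-intersection area over the region area.
    """
    regions = {r.region_id: r for r in design.regions}
    out = {}
    for region_id, region in regions.items():
        segs = [s for s in plan.segments if s.region_id == region_id]
        if not segs:
            out[region_id] = 0.0
            continue
        footprint = unary_union(
            [LineString(s.path).buffer(s.linewidth / 2.0) for s in segs]
        )
        poly = _region_polygon(region)
        out[region_id] = float(poly.intersection(footprint).area / poly.area)
    return out
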
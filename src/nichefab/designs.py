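"""Bundled example niche designs.

These reproduce, as designs, the printed parameter sets used to characterize
and exercise microstructured niches: a six-level RGD dose ladder on filaments
of fixed stiffness, a five-level stiffness ladder spanning the soft-to-stiff
physiological range, a bone-fat assembly with a soft adipogenic core and a
stiffer osteogenic periphery, a square with a graded stiffness structure, and
a square split into a morphogen-bearing and a morphogen-free half.

Morphogen conjugate concentrations (BMP2, BMP4) are nominal mM-scale values:
experimentally these species are dosed in ng/mL, and the design schema
carries all conjugates on the mM scale used for the peptide envelope.
"""

from __future__ import annotations

from .printplan import (
    FilamentGeometry,
    NicheDesign,
    NicheRegion,
    RectGeometry,
    TargetSpec,
)

__all__ = [
    "rgd_dose_ladder",
    "stiffness_ladder",
    "bone_fat_assembly",
    "stiffness_gradient_square",
    "morphogen_half_square",
    "BUNDLED_DESIGNS",
]


def rgd_dose_ladder() -> NicheDesign:
    """Six parallel 250 µm filaments at 8 kPa with RGD from 0 to 8 mM.

    The top two levels exceed the 4 mM interpolation envelope and are flagged
    by ``validate_design``; compile with the override flag to reproduce the
    experimentally printed set.
    """
    levels = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
    regions = []
    for i, rgd in enumerate(levels):
        y = 150.0 + 400.0 * i
        regions.append(
            NicheRegion(
                region_id=f"rgd_{rgd:g}mM",
                geometry=FilamentGeometry(
                    points=[(0.0, y), (2000.0, y)], linewidth=250.0
                ),
                target=TargetSpec(E_des=8.0, W_des=250.0, conjugates={"RGD": rgd}),
            )
        )
    return NicheDesign(name="rgd_dose_ladder", regions=regions)


def stiffness_ladder() -> NicheDesign:
    """Five 250 µm filaments with moduli from 2.5 to 20 kPa at 2 mM RGD."""
    levels = (2.5, 5.0, 10.0, 15.0, 20.0)
    regions = []
    for i, E in enumerate(levels):
        y = 150.0 + 400.0 * i
        regions.append(
            NicheRegion(
                region_id=f"E_{E:g}kPa",
                geometry=FilamentGeometry(
                    points=[(0.0, y), (2000.0, y)], linewidth=250.0
                ),
                target=TargetSpec(E_des=E, W_des=250.0, conjugates={"RGD": 2.0}),
            )
        )
    return NicheDesign(name="stiffness_ladder", regions=regions)


def bone_fat_assembly() -> NicheDesign:
    """Osteon-like assembly: soft adipogenic core, stiffer osteogenic rim.

    The central 400x400 µm region is soft (2.5 kPa) with high RGD (4 mM); the
    peripheral frame (four rectangles) is 8 kPa with 2 mM RGD plus conjugated
    BMP2 (nominal 0.01 mM). The two compositions compile to exactly two
    resist batches.
    """
    core = TargetSpec(E_des=2.5, W_des=250.0, conjugates={"RGD": 4.0})
    rim = TargetSpec(
        E_des=8.0, W_des=250.0, conjugates={"RGD": 2.0, "BMP2": 0.01}
    )
    regions = [
        NicheRegion(
            region_id="adipogenic_core",
            geometry=RectGeometry(origin=(300.0, 300.0), width=400.0, height=400.0),
            target=core,
        ),
        NicheRegion(
            region_id="osteogenic_bottom",
            geometry=RectGeometry(origin=(0.0, 0.0), width=1000.0, height=300.0),
            target=rim,
        ),
        NicheRegion(
            region_id="osteogenic_top",
            geometry=RectGeometry(origin=(0.0, 700.0), width=1000.0, height=300.0),
            target=rim,
        ),
        NicheRegion(
            region_id="osteogenic_left",
            geometry=RectGeometry(origin=(0.0, 300.0), width=300.0, height=400.0),
            target=rim,
        ),
        NicheRegion(
            region_id="osteogenic_right",
            geometry=RectGeometry(origin=(700.0, 300.0), width=300.0, height=400.0),
            target=rim,
        ),
    ]
    return NicheDesign(
        name="bone_fat_assembly",
        regions=regions,
    )


def stiffness_gradient_square() -> NicheDesign:
    """1000 µm square of five vertical strips graded soft-to-stiff in x."""
    levels = (2.5, 5.0, 8.0, 14.0, 20.0)
    strip_w = 1000.0 / len(levels)
    regions = [
        NicheRegion(
            region_id=f"strip_{i}_E{E:g}",
            geometry=RectGeometry(
                origin=(i * strip_w, 0.0), width=strip_w, height=1000.0
            ),
            target=TargetSpec(E_des=E, W_des=200.0),
        )
        for i, E in enumerate(levels)
    ]
    return NicheDesign(name="stiffness_gradient_square", regions=regions)


def morphogen_half_square() -> NicheDesign:
    """1000 µm square, left half with conjugated BMP4, right half without."""
    base = {"RGD": 2.0}
    regions = [
        NicheRegion(
            region_id="bmp4_half",
            geometry=RectGeometry(origin=(0.0, 0.0), width=500.0, height=1000.0),
            target=TargetSpec(
                E_des=8.0, W_des=200.0, conjugates={**base, "BMP4": 0.01}
            ),
        ),
        NicheRegion(
            region_id="plain_half",
            geometry=RectGeometry(origin=(500.0, 0.0), width=500.0, height=1000.0),
            target=TargetSpec(E_des=8.0, W_des=200.0, conjugates=dict(base)),
        ),
    ]
    return NicheDesign(name="morphogen_half_square", regions=regions)


BUNDLED_DESIGNS = {
    "rgd_dose_ladder": rgd_dose_ladder,
    "stiffness_ladder": stiffness_ladder,
    "bone_fat_assembly": bone_fat_assembly,
    "stiffness_gradient_square": stiffness_gradient_square,
    "morphogen_half_square": morphogen_half_square,
}
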
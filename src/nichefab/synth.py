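"""Synthetic inputs with ground truth for every analysis module.

The generators emulate the *structure* of the empirical characterization
data — monotone trends of modulus and linewidth with the unified
monomer–photoinitiator index and the focus offset, insensitivity of both to
the bioconjugate concentration, conjugate-proportional bound signal — not
any particular measured dataset. Functional forms are invented emulations
and configurable:

* modulus rises with the unified index through a saturating smoothstep
  response (gentle plateaus at both ends of the index range, so kernel
  interpolation remains accurate at the envelope boundaries) and is mildly
  attenuated by defocus:
  E = E_base + (E_max - E_base) * S(u^E_exp) * exp(-c|z|), with
  u = (peg_pi - 10) / 80 and S(t) = 3t^2 - 2t^3;
* linewidth grows linearly with the defocus magnitude (the conic beam
  cross-section widens away from the waist; the characterization uses
  one-sided focus offsets z >= 0) and weakly with the index:
  W = W_base + W_focus_slope * |z| + W_pegpi_slope * (peg_pi - 10);
* bound conjugate signal is proportional to the conjugate concentration.

Every generator is deterministic for a fixed seed and returns its ground
truth alongside the data; nothing is meant to be analyzed without the truth
table next to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PackingError, ValidationError
from .forcespec import (
    DEFAULT_SPRING_CONSTANT,
    DEFAULT_THRESHOLD_FORCE,
    ForceCurve,
    IndenterModel,
    simulate_curve,
)
from .quantify import LabeledVolume, SigmoidFit, _fpl
from .statespace import CalibrationRecord, StateSpace

__all__ = [
    "ForwardModelParams",
    "ImageSceneParams",
    "gen_calibration",
    "gen_force_curves",
    "gen_niche_image",
    "gen_dose_response",
]

PEGPI_LEVELS_DEFAULT = tuple(np.linspace(10.0, 90.0, 17))
FOCUS_LEVELS_DEFAULT = tuple(np.linspace(0.0, 4.0, 13))
CONJUGATE_LEVELS_DEFAULT = (0.0, 2.0, 4.0)


@dataclass(frozen=True)
class ForwardModelParams:
    """Parameters of the invented monotone forward model (see module doc)."""

    E_base: float = 2.0  # kPa at the soft end of the index range
    E_max: float = 20.0  # kPa at the stiff end, in focus
    E_exp: float = 1.0  # exponent applied to the normalized index
    E_focus_coef: float = 0.01  # per-mm attenuation of modulus with |focus|
    W_base: float = 40.0  # µm at the beam waist
    W_focus_slope: float = 65.0  # µm per mm of |focus|
    W_pegpi_slope: float = 0.6  # µm per index unit
    bound_per_mM: float = 0.9  # a.u. of bound signal per mM conjugate
    noise_cv: float = 0.05  # multiplicative noise, coefficient of variation
    seed: int = 0

    def forward(self, peg_pi, focus_z):
        """Noiseless (E, W) at fabrication coordinates; vectorized."""
        p = np.asarray(peg_pi, dtype=float)
        z = np.asarray(focus_z, dtype=float)
        u = np.clip((p - 10.0) / 80.0, 0.0, 1.0) ** self.E_exp
        s = 3.0 * u**2 - 2.0 * u**3  # smoothstep: flat approach to both ends
        E = self.E_base + (self.E_max - self.E_base) * s * np.exp(
            -self.E_focus_coef * np.abs(z)
        )
        W = self.W_base + self.W_focus_slope * np.abs(z) + self.W_pegpi_slope * (
            p - 10.0
        )
        return E, W

    def bound(self, peg_pi, focus_z, conjugate_conc):
        """Noiseless bound-conjugate signal; proportional to concentration."""
        p = np.asarray(peg_pi, dtype=float)
        return self.bound_per_mM * np.asarray(conjugate_conc, dtype=float) * (
            0.8 + 0.004 * p
        )


def gen_calibration(
    params: ForwardModelParams = ForwardModelParams(),
    pegpi_levels=PEGPI_LEVELS_DEFAULT,
    focus_levels=FOCUS_LEVELS_DEFAULT,
    conjugate_levels=CONJUGATE_LEVELS_DEFAULT,
    **kernel_kwargs,
):
    """Calibration table over a fabrication grid, plus the noiseless truth.

    Returns ``(space, forward)`` where ``forward(peg_pi, focus_z)`` is the
    noiseless (E, W) function used to generate the records. One record per
    (peg_pi, focus, conjugate) grid point with multiplicative noise of
    coefficient of variation ``params.noise_cv``.
    """
    rng = np.random.default_rng(params.seed)
    records = []
    for p in pegpi_levels:
        for z in focus_levels:
            E, W = params.forward(p, z)
            if E <= 0 or W <= 0:
                raise ValidationError(
                    f"forward model non-positive at peg_pi={p}, focus={z}"
                )
            for c in conjugate_levels:
                b = params.bound(p, z, c)
                noise = 1.0 + params.noise_cv * rng.standard_normal(3)
                noise = np.clip(noise, 0.05, None)
                records.append(
                    CalibrationRecord(
                        peg_pi=float(p),
                        focus_z=float(z),
                        conjugate_conc=float(c),
                        youngs_modulus=float(E * noise[0]),
                        linewidth=float(W * noise[1]),
                        bound_signal=float(max(b * noise[2], 0.0)),
                    )
                )
    return StateSpace(records, **kernel_kwargs), params.forward


def gen_force_curves(
    E_levels,
    n_per_level: int,
    model: IndenterModel = IndenterModel(),
    h: float | None = None,
    noise_sd: float = 0.05,
    slip_prob: float = 0.0,
    slip_jump: float = 2.0,
    spring_constant: float = DEFAULT_SPRING_CONSTANT,
    threshold_force: float = DEFAULT_THRESHOLD_FORCE,
    seed: int = 0,
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Seeded batch of simulated approach curves with a truth table.

    The truth table pairs each curve index with its modulus, contact point,
    thickness, and injected slip (NaN when none). Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    curves, rows = [], []
    for E in E_levels:
        for _ in range(n_per_level):
            z0 = float(rng.uniform(1.5, 2.5))
            slipped = bool(rng.random() < slip_prob)
            slip = None
            if slipped:
                slip = (z0 + float(rng.uniform(0.3, 0.8)), slip_jump)
            curve = simulate_curve(
                E,
                model=model,
                z0=z0,
                h=h,
                noise_sd=noise_sd,
                slip=slip,
                seed=int(rng.integers(0, 2**31 - 1)),
                spring_constant=spring_constant,
                threshold_force=threshold_force,
            )
            rows.append(
                {
                    "curve_id": len(curves),
                    "E_kPa": float(E),
                    "z0_um": z0,
                    "h_um": h if h is not None else float("nan"),
                    "slip_z_um": slip[0] if slip else float("nan"),
                    "slip_nN": slip[1] if slip else float("nan"),
                }
            )
            curves.append(curve)
    return curves, pd.DataFrame(rows)


@dataclass(frozen=True)
class ImageSceneParams:
    """Layout and noise of a synthetic labeled niche volume."""

    n_cells: int = 25
    nc_levels: tuple[float, ...] = (2.0,)  # cycled across cells
    lipid_fraction: float = 0.0
    gradient: tuple[float, float] | None = None  # N:C at x=0 and x=width
    cyto_base: float = 100.0  # marker counts in the cytoplasm
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # µm
    poisson_noise: bool = True
    read_noise_sd: float = 2.0  # ADU
    nuclear_radii: tuple[int, int, int] = (3, 5, 5)  # voxels (z, y, x)
    cyto_radii: tuple[int, int, int] = (5, 9, 9)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if not 0.0 <= self.lipid_fraction <= 1.0:
            raise ValidationError("lipid_fraction must be in [0, 1]")


def _ellipsoid_mask(shape, center, radii):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    rz, ry, rx = radii
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + (
        (xx - cx) / rx
    ) ** 2 <= 1.0


def gen_niche_image(
    params: ImageSceneParams = ImageSceneParams(),
    niche_geometry: tuple[float, float] = (160.0, 160.0),
    nz: int = 14,
) -> tuple[LabeledVolume, dict]:
    """Labeled multi-channel volume of non-overlapping model cells + truth.

    Cells are ellipsoidal nuclei inside larger cytoplasmic ellipsoids laid
    out on a jittered grid (so packing is always feasible up to the grid
    capacity; beyond it a PackingError is raised). Channels: ``nuclei``
    (bright nuclear counterstain), ``marker`` (cytoplasm at ``cyto_base``
    counts, nucleus at N:C x ``cyto_base``), and ``lipid`` (droplet blobs
    covering ``lipid_fraction`` of the cytoplasm). Noise is Poisson shot
    noise plus Gaussian read noise. Truth carries per-cell N:C, voxel
    centroids, and the achieved lipid fraction.
    """
    rng = np.random.default_rng(params.seed)
    width, height = niche_geometry
    vz, vy, vx = params.voxel_size
    ny, nx = int(round(height / vy)), int(round(width / vx))
    shape = (nz, ny, nx)
    crz, cry, crx = params.cyto_radii
    pitch_y, pitch_x = 2 * cry + 2, 2 * crx + 2
    ys = np.arange(cry + 1, ny - cry - 1 + 1, pitch_y)
    xs = np.arange(crx + 1, nx - crx - 1 + 1, pitch_x)
    capacity = len(ys) * len(xs)
    if params.n_cells > capacity:
        raise PackingError(
            f"cannot place {params.n_cells} cells; grid capacity is {capacity}"
        )
    sites = [(y, x) for y in ys for x in xs][: params.n_cells]

    if params.gradient is not None:
        lo, hi = params.gradient
        nc_truth = np.array([lo + (hi - lo) * (x * vx) / width for _, x in sites])
    else:
        levels = np.asarray(params.nc_levels, dtype=float)
        nc_truth = levels[np.arange(params.n_cells) % levels.size]

    labels = np.zeros(shape, dtype=np.int32)
    cyto = np.zeros(shape, dtype=bool)
    marker = np.zeros(shape, dtype=float)
    nuclei_ch = np.full(shape, 5.0)
    centroids = []
    cz = nz // 2
    for i, (y, x) in enumerate(sites, start=1):
        jy, jx = rng.integers(-1, 2, size=2)
        cy, cx = int(y + jy), int(x + jx)
        nuc = _ellipsoid_mask(shape, (cz, cy, cx), params.nuclear_radii)
        cell = _ellipsoid_mask(shape, (cz, cy, cx), params.cyto_radii)
        labels[nuc] = i
        cyto |= cell & ~nuc
        marker[cell & ~nuc] = params.cyto_base
        marker[nuc] = nc_truth[i - 1] * params.cyto_base
        nuclei_ch[nuc] = 200.0
        centroids.append((cz, cy, cx))

    lipid = np.where(cyto, 10.0, 0.0)
    n_cyto = int(cyto.sum())
    n_target = int(round(params.lipid_fraction * n_cyto))
    lipid_mask = np.zeros(shape, dtype=bool)
    if n_target > 0:
        cyto_idx = np.argwhere(cyto)
        order = rng.permutation(len(cyto_idx))
        placed = 0
        for k in order:
            if placed >= n_target:
                break
            z, y, x = cyto_idx[k]
            blob = _ellipsoid_mask(shape, (z, y, x), (1, 2, 2)) & cyto & ~lipid_mask
            lipid_mask |= blob
            placed = int(lipid_mask.sum())
        lipid[lipid_mask] = 300.0

    channels = {"nuclei": nuclei_ch, "marker": marker, "lipid": lipid}
    if params.poisson_noise or params.read_noise_sd > 0:
        for name, img in channels.items():
            noisy = rng.poisson(np.clip(img, 0, None)).astype(float) \
                if params.poisson_noise else img.astype(float)
            if params.read_noise_sd > 0:
                noisy = noisy + rng.normal(0, params.read_noise_sd, size=img.shape)
            channels[name] = np.clip(noisy, 0.0, None)

    transform = np.eye(4)
    transform[0, 0], transform[1, 1], transform[2, 2] = params.voxel_size
    volume = LabeledVolume(
        channels=channels,
        nuclear_labels=labels,
        cytoplasm_mask=cyto,
        voxel_size=params.voxel_size,
        niche_transform=transform,
    )
    truth = {
        "nc": nc_truth,
        "centroids_voxel": np.array(centroids, dtype=float),
        "lipid_fraction": (int(lipid_mask.sum()) / n_cyto) if n_cyto else 0.0,
        "n_cells": params.n_cells,
    }
    return volume, truth


def gen_dose_response(
    truth: SigmoidFit | tuple[float, float, float, float],
    doses,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SigmoidFit]:
    """4PL evaluations plus Gaussian noise; bit-identical for a fixed seed."""
    if isinstance(truth, SigmoidFit):
        bottom, top, ec50, hill = truth.bottom, truth.top, truth.ec50, truth.hill
    else:
        bottom, top, ec50, hill = truth
    doses = np.asarray(doses, dtype=float)
    if np.unique(doses).size < 5:
        raise ValidationError("at least 5 distinct dose levels are required")
    rng = np.random.default_rng(seed)
    clean = _fpl(doses, bottom, top, ec50, hill)
    response = clean + (rng.normal(0, noise_sd, size=doses.shape) if noise_sd else 0)
    df = pd.DataFrame({"dose": doses, "response": response})
    return df, SigmoidFit(bottom, top, ec50, hill, rss=0.0)
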
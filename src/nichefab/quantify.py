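"""Per-cell and per-region image metrics for niche-registered cell responses.

Implements the quantitative readouts used to score cell responses on printed
niches:

* **N:C ratio** — for each segmented nucleus, the mean marker intensity over
  the nuclear volume divided by the mean intensity over that cell's
  non-nuclear cytoplasmic volume. Multi-cell fields partition the cytoplasm
  mask by nearest nucleus (Voronoi partition on the Euclidean distance
  transform); nuclear voxels are excluded from the cytoplasmic term.
* **fat:cyto** — volumetric ratio of lipid-stained voxels (Otsu threshold
  inside the cytoplasm mask, or a fixed threshold) to total cytoplasmic
  voxels, the adipogenesis readout.
* **Alizarin red score** — mean red saturation over a region of interest
  divided by the mean total (R+G+B) saturation; 1/3 for any achromatic ROI.
* **Expression maps** — per-nucleus marker intensities from replicate image
  volumes are normalized per replicate and channel (1st–99th percentile to
  [0, 1] by default), remapped into a common niche coordinate frame, pooled,
  and binned into a mean-intensity surface with optional per-region
  summaries.
* **4PL dose-response fits** — four-parameter logistic (bottom, top, ec50,
  hill) least-squares fits of dose-dependent responses.

A simple deterministic threshold + distance-transform watershed nucleus
segmenter is included for label-free inputs; any externally produced integer
label image (e.g. from a star-convex segmentation network) is accepted
everywhere a label array is expected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import curve_fit
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    ConfigurationError,
    GeometryError,
    UndefinedRatioError,
    ValidationError,
)

__all__ = [
    "LabeledVolume",
    "CellMeasurement",
    "NicheMap",
    "SigmoidFit",
    "FourParamLogistic",
    "segment_nuclei_simple",
    "nc_ratio",
    "fat_cyto",
    "alizarin_score",
    "map_expression",
    "fit_sigmoid",
    "region_stats",
]


@dataclass
class LabeledVolume:
    """Multi-channel 3-D volume with nuclear labels and a cytoplasm mask.

    Arrays are indexed (z, y, x), 0-based. ``niche_transform`` is a 4x4
    homogeneous affine mapping voxel indices (z, y, x, 1) to niche-frame
    micrometers (z, y, x); the default is a pure voxel-size scaling.
    """

    channels: dict[str, np.ndarray]
    nuclear_labels: np.ndarray
    cytoplasm_mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # µm, (z, y, x)
    niche_transform: np.ndarray | None = None

    def __post_init__(self):
        shapes = {a.shape for a in self.channels.values()}
        shapes |= {self.nuclear_labels.shape, self.cytoplasm_mask.shape}
        if len(shapes) != 1:
            raise ValidationError(f"arrays disagree in shape: {shapes}")
        labels = np.unique(self.nuclear_labels)
        labels = labels[labels > 0]
        if labels.size and not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise ValidationError("nuclear label values must be contiguous from 1")
        if self.niche_transform is None:
            t = np.eye(4)
            t[0, 0], t[1, 1], t[2, 2] = self.voxel_size
            self.niche_transform = t
        self.niche_transform = np.asarray(self.niche_transform, dtype=float)
        if self.niche_transform.shape != (4, 4):
            raise ValidationError("niche_transform must be a 4x4 affine")

    @property
    def n_cells(self) -> int:
        return int(self.nuclear_labels.max())

    def voxel_to_niche(self, zyx: np.ndarray) -> np.ndarray:
        """Map voxel coordinates (n, 3) to niche-frame µm (n, 3)."""
        zyx = np.atleast_2d(zyx)
        hom = np.hstack([zyx, np.ones((zyx.shape[0], 1))])
        return (self.niche_transform @ hom.T).T[:, :3]


@dataclass(frozen=True)
class CellMeasurement:
    cell_id: int
    centroid: tuple[float, float, float]  # niche-frame µm, (z, y, x)
    channel: str
    nuclear_mean: float
    cytoplasmic_mean: float
    nc_ratio: float
    nuclear_volume: float  # µm^3


@dataclass
class NicheMap:
    """Pooled, normalized per-nucleus intensities in the common niche frame."""

    cells: pd.DataFrame  # columns: x, y, channel, normalized_intensity, replicate_id
    surface: np.ndarray  # binned mean, shape (ny_bins, nx_bins), NaN where empty
    x_edges: np.ndarray
    y_edges: np.ndarray
    empty_bins: np.ndarray
    n_pooled: int
    n_excluded: int
    region_summaries: dict[str, dict] = field(default_factory=dict)


@dataclass(frozen=True)
class SigmoidFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    degenerate: bool = False


def segment_nuclei_simple(
    nuclear_channel: np.ndarray,
    sigma: float = 1.0,
    min_size: int = 20,
    min_distance: int = 5,
) -> np.ndarray:
    """Deterministic threshold + distance-transform watershed segmentation.

    A stand-in for learned star-convex segmentation: Gaussian smoothing, Otsu
    threshold, small-object removal, then watershed from the local maxima of
    the Euclidean distance transform to split touching nuclei. Returns an
    integer label array with values contiguous from 1 (0 = background); a
    blank image yields zero labels with a warning.
    """
    img = np.asarray(nuclear_channel, dtype=float)
    if img.ndim not in (2, 3):
        raise ValidationError("expected a 2-D or 3-D intensity array")
    smoothed = gaussian(img, sigma=sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        warnings.warn("blank image: no nuclei segmented", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)
    mask = smoothed > threshold_otsu(smoothed)
    cc = cc_label(mask)
    sizes = np.bincount(cc.ravel())
    keep = np.flatnonzero(sizes >= min_size)
    mask = np.isin(cc, keep[keep > 0])
    if not mask.any():
        warnings.warn("no foreground after size filtering", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=min_distance, labels=cc_label(mask), exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    if markers.max() == 0:
        labels = cc_label(mask).astype(np.int32)
    else:
        labels = watershed(-dist, markers=markers, mask=mask).astype(np.int32)
    # relabel contiguous from 1
    vals = np.unique(labels)
    vals = vals[vals > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[vals] = np.arange(1, vals.size + 1)
    return lut[labels]


def nc_ratio(
    volume: LabeledVolume, channel: str
) -> tuple[list[CellMeasurement], dict]:
    """Per-cell nuclear:cytoplasmic mean-intensity ratios for one channel.

    The cytoplasm mask minus all nuclei is partitioned by nearest nucleus;
    cells whose cytoplasm partition is empty are dropped and counted in the
    report. Ratios are invariant to positive rescaling of the channel.
    """
    if channel not in volume.channels:
        raise KeyError(f"channel {channel!r} not in {sorted(volume.channels)}")
    img = np.asarray(volume.channels[channel], dtype=float)
    labels = volume.nuclear_labels
    n = volume.n_cells
    if n == 0:
        return [], {"n_cells": 0, "n_dropped": 0}
    ids = np.arange(1, n + 1)
    nuc_mean = ndimage.mean(img, labels=labels, index=ids)
    nuc_count = ndimage.sum_labels(np.ones_like(img), labels=labels, index=ids)
    # nearest-nucleus ownership of every voxel
    _, idx = ndimage.distance_transform_edt(
        labels == 0, sampling=volume.voxel_size, return_indices=True
    )
    owner = labels[tuple(idx)]
    cyto = volume.cytoplasm_mask & (labels == 0)
    cyto_owner = np.where(cyto, owner, 0)
    cyto_count = ndimage.sum_labels(np.ones_like(img), labels=cyto_owner, index=ids)
    with np.errstate(invalid="ignore"):
        cyto_mean = ndimage.mean(img, labels=cyto_owner, index=ids)
    centroids = np.array(ndimage.center_of_mass(np.ones_like(img), labels, ids))
    centroids_um = volume.voxel_to_niche(centroids)
    voxel_vol = float(np.prod(volume.voxel_size))

    cells, dropped = [], 0
    for i, cid in enumerate(ids):
        if cyto_count[i] == 0 or not np.isfinite(cyto_mean[i]) or cyto_mean[i] <= 0:
            dropped += 1
            continue
        cells.append(
            CellMeasurement(
                cell_id=int(cid),
                centroid=tuple(float(v) for v in centroids_um[i]),
                channel=channel,
                nuclear_mean=float(nuc_mean[i]),
                cytoplasmic_mean=float(cyto_mean[i]),
                nc_ratio=float(nuc_mean[i] / cyto_mean[i]),
                nuclear_volume=float(nuc_count[i] * voxel_vol),
            )
        )
    return cells, {"n_cells": int(n), "n_dropped": int(dropped)}


def fat_cyto(
    volume: LabeledVolume, lipid_channel: str, threshold: float | None = None
) -> tuple[float, dict]:
    """Volumetric lipid : total-cytoplasm ratio for one field of view."""
    if lipid_channel not in volume.channels:
        raise KeyError(f"channel {lipid_channel!r} not in {sorted(volume.channels)}")
    cyto = np.asarray(volume.cytoplasm_mask, dtype=bool)
    n_cyto = int(cyto.sum())
    if n_cyto == 0:
        raise UndefinedRatioError("cytoplasm mask is empty; fat:cyto undefined")
    img = np.asarray(volume.channels[lipid_channel], dtype=float)
    vals = img[cyto]
    if threshold is None:
        if np.ptp(vals) == 0:
            return 0.0, {"n_cyto": n_cyto, "n_lipid": 0, "threshold": float("inf")}
        threshold = float(threshold_otsu(vals))
    n_lipid = int(np.count_nonzero(vals > threshold))
    return n_lipid / n_cyto, {
        "n_cyto": n_cyto,
        "n_lipid": n_lipid,
        "threshold": float(threshold),
    }


def alizarin_score(rgb: np.ndarray, roi_polygon) -> float:
    """mean(R) / mean(R + G + B) over an ROI polygon of a color image.

    ``roi_polygon`` is a sequence of (x, y) pixel vertices; every vertex must
    lie inside the image. Pure red scores 1.0; any achromatic ROI scores 1/3.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValidationError("expected an (H, W, 3) color image")
    verts = np.asarray(roi_polygon, dtype=float)
    h, w = rgb.shape[:2]
    if (
        verts.ndim != 2
        or verts.shape[0] < 3
        or (verts[:, 0] < 0).any()
        or (verts[:, 1] < 0).any()
        or (verts[:, 0] > w - 1).any()
        or (verts[:, 1] > h - 1).any()
    ):
        raise GeometryError("ROI polygon falls outside the image bounds")
    rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=(h, w))
    if rr.size == 0:
        raise GeometryError("ROI polygon is degenerate (no interior pixels)")
    r = rgb[rr, cc, 0].mean()
    total = rgb[rr, cc, :].sum(axis=1).mean()
    if total == 0:
        raise UndefinedRatioError("ROI has zero total saturation")
    return float(r / total)


def _normalize(values: np.ndarray, method: str) -> np.ndarray:
    if method == "percentile":
        lo, hi = np.percentile(values, [1, 99])
    elif method == "minmax":
        lo, hi = values.min(), values.max()
    else:
        raise ConfigurationError(f"unknown normalization {method!r}")
    if hi <= lo:
        return np.zeros_like(values)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def map_expression(
    replicates: list[tuple[list[CellMeasurement], np.ndarray | None]],
    niche_geometry: tuple[float, float],
    bin_um: float = 50.0,
    normalization: str = "percentile",
    property_regions: dict[str, tuple[float, float, float, float]] | None = None,
) -> NicheMap:
    """Pool per-nucleus measurements from replicates into one niche map.

    Each replicate is ``(cells, transform)`` where ``transform`` is a 3x3
    homogeneous 2-D affine registering that replicate's (x, y) µm coordinates
    into the common niche frame (None raises). Intensities (nuclear means)
    are normalized per replicate and channel, then pooled; cells landing
    outside the niche bounding box are excluded and counted. The surface is
    the binned mean of normalized intensity on a ``bin_um`` grid (NaN and
    flagged where empty). ``property_regions`` maps region names to
    (x0, y0, width, height) rectangles for per-region summaries.
    """
    width, height = niche_geometry
    rows = []
    for rep_id, (cells, transform) in enumerate(replicates):
        if transform is None:
            raise ConfigurationError(f"replicate {rep_id} is missing its transform")
        transform = np.asarray(transform, dtype=float)
        if transform.shape != (3, 3):
            raise ConfigurationError("replicate transform must be a 3x3 affine")
        if not cells:
            continue
        xy = np.array([(c.centroid[2], c.centroid[1]) for c in cells])
        hom = np.hstack([xy, np.ones((xy.shape[0], 1))])
        mapped = (transform @ hom.T).T[:, :2]
        for c, (x, y) in zip(cells, mapped):
            rows.append(
                {
                    "x": float(x),
                    "y": float(y),
                    "channel": c.channel,
                    "intensity": c.nuclear_mean,
                    "replicate_id": rep_id,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no cells to pool")
    df["normalized_intensity"] = 0.0
    for (rep, ch), group in df.groupby(["replicate_id", "channel"]):
        df.loc[group.index, "normalized_intensity"] = _normalize(
            group["intensity"].to_numpy(), normalization
        )
    inside = (
        (df["x"] >= 0) & (df["x"] <= width) & (df["y"] >= 0) & (df["y"] <= height)
    )
    n_excluded = int((~inside).sum())
    df = df[inside].reset_index(drop=True)

    nx = max(1, int(np.ceil(width / bin_um)))
    ny = max(1, int(np.ceil(height / bin_um)))
    stat, x_edges, y_edges, _ = stats.binned_statistic_2d(
        df["x"], df["y"], df["normalized_intensity"],
        statistic="mean", bins=[nx, ny], range=[[0, width], [0, height]],
    )
    surface = stat.T  # (ny, nx), row-major in y
    empty = ~np.isfinite(surface)

    summaries = {}
    if property_regions:
        for name, (x0, y0, w, h) in property_regions.items():
            sel = df[
                (df["x"] >= x0) & (df["x"] <= x0 + w)
                & (df["y"] >= y0) & (df["y"] <= y0 + h)
            ]
            summaries[name] = {
                "n": int(len(sel)),
                "mean": float(sel["normalized_intensity"].mean())
                if len(sel)
                else float("nan"),
                "values": sel["normalized_intensity"].to_numpy(),
            }
    return NicheMap(
        cells=df.drop(columns=["intensity"]),
        surface=surface,
        x_edges=x_edges,
        y_edges=y_edges,
        empty_bins=empty,
        n_pooled=int(len(df)),
        n_excluded=n_excluded,
        region_summaries=summaries,
    )


def _fpl(x, bottom, top, ec50, hill):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        u = np.where(x > 0, x**hill / (ec50**hill + x**hill), 0.0)
    return bottom + (top - bottom) * u


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Four-parameter logistic (4PL) dose-response regressor.

    Model: y = bottom + (top - bottom) * x^hill / (ec50^hill + x^hill), with
    hill constrained positive; decreasing responses are handled by fitting
    the negated response and mapping the parameters back (bottom/top swapped,
    hill negated), so ``top_ >= bottom_`` always holds.

    Fitted attributes: ``bottom_``, ``top_``, ``ec50_``, ``hill_``, ``rss_``,
    ``degenerate_``.
    """

    def __init__(self, hill_bounds: tuple[float, float] = (0.1, 10.0)):
        self.hill_bounds = hill_bounds

    def _fit_oriented(self, x, y):
        pos = x[x > 0]
        ec50_lo = float(pos.min()) * 0.01
        ec50_hi = float(pos.max()) * 100.0
        span = float(np.ptp(y)) or 1.0
        p0 = [float(y.min()), float(y.max()), float(np.median(pos)), 1.0]
        bounds = (
            [y.min() - span, y.min() - span, ec50_lo, self.hill_bounds[0]],
            [y.max() + span, y.max() + span, ec50_hi, self.hill_bounds[1]],
        )
        popt, _ = curve_fit(_fpl, x, y, p0=p0, bounds=bounds, maxfev=20000)
        rss = float(np.sum((y - _fpl(x, *popt)) ** 2))
        return popt, rss

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if np.unique(x).size < 5:
            raise ValidationError("at least 5 distinct dose levels are required")
        if np.ptp(y) == 0:
            self.bottom_ = self.top_ = float(y[0])
            self.ec50_ = float(np.median(x[x > 0])) if (x > 0).any() else 1.0
            self.hill_ = 1.0
            self.rss_ = 0.0
            self.degenerate_ = True
            return self
        up_popt, up_rss = self._fit_oriented(x, y)
        dn_popt, dn_rss = self._fit_oriented(x, -y)
        if up_rss <= dn_rss:
            bottom, top, ec50, hill = up_popt
        else:
            b, t, ec50, h = dn_popt
            bottom, top, hill = -t, -b, -h
        if top < bottom:  # normalize orientation so top_ >= bottom_
            bottom, top, hill = top, bottom, -hill
        self.bottom_, self.top_ = float(bottom), float(top)
        self.ec50_, self.hill_ = float(ec50), float(hill)
        self.rss_ = float(min(up_rss, dn_rss))
        self.degenerate_ = False
        return self

    def predict(self, X):
        return _fpl(np.asarray(X, dtype=float).ravel(),
                    self.bottom_, self.top_, self.ec50_, self.hill_)

    def result(self) -> SigmoidFit:
        return SigmoidFit(
            bottom=self.bottom_,
            top=self.top_,
            ec50=self.ec50_,
            hill=self.hill_,
            rss=self.rss_,
            degenerate=self.degenerate_,
        )


def fit_sigmoid(dose, response) -> SigmoidFit:
    """Least-squares 4PL fit; constant responses return a flagged flat fit."""
    return FourParamLogistic().fit(dose, response).result()


def region_stats(values_by_group: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA with Tukey HSD across region groups (thin wrapper)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    f, p = stats.f_oneway(*groups.values())
    data = np.concatenate(list(groups.values()))
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    tukey = pairwise_tukeyhsd(data, labels)
    return {"anova_F": float(f), "anova_p": float(p), "tukey": tukey.summary()}


def plot_niche_map(niche_map: NicheMap, path) -> None:
    """Render a scatter + binned-surface figure of a pooled niche map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.5))
    sc = ax1.scatter(
        niche_map.cells["x"],
        niche_map.cells["y"],
        c=niche_map.cells["normalized_intensity"],
        s=8 + 40 * niche_map.cells["normalized_intensity"],
        alpha=0.25 + 0.75 * niche_map.cells["normalized_intensity"].clip(0, 1),
        cmap="viridis",
    )
    ax1.set_title("pooled cells")
    ax1.set_xlabel("x (µm)")
    ax1.set_ylabel("y (µm)")
    fig.colorbar(sc, ax=ax1, label="normalized intensity")
    im = ax2.imshow(
        niche_map.surface,
        origin="lower",
        extent=[
            niche_map.x_edges[0],
            niche_map.x_edges[-1],
            niche_map.y_edges[0],
            niche_map.y_edges[-1],
        ],
        cmap="viridis",
    )
    ax2.set_title("binned mean surface")
    ax2.set_xlabel("x (µm)")
    fig.colorbar(im, ax=ax2, label="mean normalized intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
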
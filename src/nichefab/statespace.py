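"""Empirical fabrication state-space and kernel-weighted property interpolation.

The printer's calibration data pairs the independent fabrication variables —
the unified monomer–photoinitiator index (``peg_pi``, on the % w/v monomer
scale) and the laser focus offset (``focus_z``, mm) — with the measured
material properties: Young's modulus (kPa), printed linewidth (µm), and the
relative fluorescence of bound thiol-ene conjugate (a.u.). Material
properties at arbitrary fabrication coordinates are estimated by
Nadaraya–Watson kernel regression over the calibration records, with both
coordinates normalized by fixed ranges (40 for peg_pi, 6 for focus) and a
Gaussian kernel of bandwidth 0.1 in normalized units.

Two kernel forms are provided. ``product_gaussian`` (default) treats the two
normalized differences as a 2-D Euclidean distance,

    tau_i = 1/(0.1*2*pi) * exp(-0.5*[(dx_i/0.1)^2 + (dz_i/0.1)^2]),

with dx_i = (peg_pi_i - x)/40 and dz_i = (focus_i - z)/6. The alternative
``literal_summed`` form sums the two signed differences before a single
division by the bandwidth; it is non-metric (opposite-signed differences can
cancel) and is retained only for comparison. The 1/(0.1*2*pi) prefactor
cancels in the weighted-mean ratio and is inert; it is kept for fidelity to
the weight definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FormatError, ValidationError

__all__ = [
    "CalibrationRecord",
    "StateSpace",
    "KernelInterpolator",
    "load_calibration",
    "save_calibration",
    "kernel_weights",
    "interpolate_properties",
    "CALIBRATION_COLUMNS",
]

#: Normalization ranges and bandwidth of the interpolation kernel.
RANGE_PEG_PI = 40.0
RANGE_FOCUS = 6.0
BANDWIDTH = 0.1
#: Center and half-width of the peg_pi ellipse domain (see inverse_design).
PEG_PI_CENTER = 50.0
PEG_PI_HALFWIDTH = 40.0

CALIBRATION_COLUMNS = (
    "peg_pi",
    "focus_z",
    "conjugate_conc",
    "youngs_modulus",
    "linewidth",
    "bound_signal",
)

KERNEL_FORMS = ("product_gaussian", "literal_summed")


@dataclass(frozen=True)
class CalibrationRecord:
    """One empirical pairing of fabrication variables with measured properties."""

    peg_pi: float
    focus_z: float
    conjugate_conc: float
    youngs_modulus: float
    linewidth: float
    bound_signal: float

    def __post_init__(self):
        if not self.youngs_modulus > 0:
            raise ValidationError(
                f"youngs_modulus must be > 0, got {self.youngs_modulus}"
            )
        if not self.linewidth > 0:
            raise ValidationError(f"linewidth must be > 0, got {self.linewidth}")
        if self.conjugate_conc < 0:
            raise ValidationError(
                f"conjugate_conc must be >= 0, got {self.conjugate_conc}"
            )
        if self.bound_signal < 0:
            raise ValidationError(f"bound_signal must be >= 0, got {self.bound_signal}")
        if abs(self.peg_pi - PEG_PI_CENTER) > PEG_PI_HALFWIDTH:
            raise ValidationError(
                f"peg_pi={self.peg_pi} outside the ellipse domain "
                f"|peg_pi - {PEG_PI_CENTER}| <= {PEG_PI_HALFWIDTH}"
            )


class KernelInterpolator(BaseEstimator, RegressorMixin):
    """Nadaraya–Watson regressor over fabrication coordinates.

    Parameters
    ----------
    bandwidth : float
        Kernel bandwidth in normalized coordinate units.
    range_x, range_z : float
        Normalization ranges for the peg_pi and focus axes.
    kernel_form : {"product_gaussian", "literal_summed"}
        See module docstring.

    After ``fit(X, Y)`` with X of shape (n, 2) (columns peg_pi, focus_z) and
    Y of shape (n, k), ``predict(Xq)`` returns the kernel-weighted mean of Y
    at each query row — a convex combination of the training rows, hence
    bounded by their extrema.
    """

    def __init__(
        self,
        bandwidth: float = BANDWIDTH,
        range_x: float = RANGE_PEG_PI,
        range_z: float = RANGE_FOCUS,
        kernel_form: str = "product_gaussian",
    ):
        self.bandwidth = bandwidth
        self.range_x = range_x
        self.range_z = range_z
        self.kernel_form = kernel_form

    def _validate_params(self):
        if not (self.bandwidth > 0 and self.range_x > 0 and self.range_z > 0):
            raise ValidationError("bandwidth, range_x and range_z must be > 0")
        if self.kernel_form not in KERNEL_FORMS:
            raise ValidationError(
                f"kernel_form must be one of {KERNEL_FORMS}, got {self.kernel_form!r}"
            )

    def fit(self, X, Y):
        self._validate_params()
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValidationError(f"X must have shape (n, 2), got {X.shape}")
        if X.shape[0] == 0:
            raise ValidationError("cannot fit on an empty state space")
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != X.shape[0]:
            raise ValidationError("X and Y row counts differ")
        self.X_ = X
        self.Y_ = Y
        self.n_features_in_ = 2
        return self

    def kernel(self, X):
        """Weight matrix of shape (n_query, n_train); every entry > 0."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        dx = (self.X_[None, :, 0] - X[:, 0, None]) / self.range_x
        dz = (self.X_[None, :, 1] - X[:, 1, None]) / self.range_z
        pref = 1.0 / (self.bandwidth * 2.0 * math.pi)
        if self.kernel_form == "product_gaussian":
            expo = -0.5 * ((dx / self.bandwidth) ** 2 + (dz / self.bandwidth) ** 2)
        else:  # literal_summed: signed differences summed, one bandwidth division
            expo = -0.5 * (dx + dz) / self.bandwidth
        return pref * np.exp(np.clip(expo, -700.0, 700.0))

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        tau = self.kernel(X)
        out = (tau @ self.Y_) / tau.sum(axis=1, keepdims=True)
        return out[0] if squeeze else out


@dataclass
class StateSpace:
    """Validated collection of calibration records plus the kernel settings."""

    records: list[CalibrationRecord]
    range_x: float = RANGE_PEG_PI
    range_z: float = RANGE_FOCUS
    bandwidth: float = BANDWIDTH
    kernel_form: str = "product_gaussian"
    _interp: KernelInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not self.records:
            raise ValidationError("state space requires at least one record")
        self._rebuild()

    def _rebuild(self):
        X = np.array([(r.peg_pi, r.focus_z) for r in self.records])
        Y = np.array(
            [(r.youngs_modulus, r.linewidth, r.bound_signal) for r in self.records]
        )
        self._interp = KernelInterpolator(
            bandwidth=self.bandwidth,
            range_x=self.range_x,
            range_z=self.range_z,
            kernel_form=self.kernel_form,
        ).fit(X, Y)

    # -- array views -------------------------------------------------------
    @property
    def peg_pi(self) -> np.ndarray:
        return self._interp.X_[:, 0]

    @property
    def focus_z(self) -> np.ndarray:
        return self._interp.X_[:, 1]

    @property
    def conjugate_conc(self) -> np.ndarray:
        return np.array([r.conjugate_conc for r in self.records])

    @property
    def youngs_modulus(self) -> np.ndarray:
        return self._interp.Y_[:, 0]

    @property
    def linewidth(self) -> np.ndarray:
        return self._interp.Y_[:, 1]

    @property
    def bound_signal(self) -> np.ndarray:
        return self._interp.Y_[:, 2]

    def bounding_box(self):
        """((peg_pi_min, peg_pi_max), (focus_min, focus_max)) of the records."""
        return (
            (float(self.peg_pi.min()), float(self.peg_pi.max())),
            (float(self.focus_z.min()), float(self.focus_z.max())),
        )

    def with_kernel_form(self, kernel_form: str) -> "StateSpace":
        return replace(self, kernel_form=kernel_form)

    # -- interpolation -----------------------------------------------------
    def kernel_weights(self, x: float, z: float) -> np.ndarray:
        """Weight vector tau, one strictly positive entry per record."""
        return self._interp.kernel([[x, z]])[0]

    def interpolate(self, x: float, z: float, conjugate: float | None = None):
        """Kernel-weighted (E, W, bound_signal) at fabrication coordinates.

        When ``conjugate`` is given, the bound-signal estimate is restricted
        to records at the nearest tabulated conjugate concentration
        (nearest-neighbor matching along the conjugate axis); E and W use all
        records, since they are insensitive to the conjugate concentration.
        """
        E, W, bound = (float(v) for v in self._interp.predict([x, z]))
        if conjugate is not None:
            levels = np.unique(self.conjugate_conc)
            nearest = levels[np.argmin(np.abs(levels - conjugate))]
            mask = self.conjugate_conc == nearest
            tau = self.kernel_weights(x, z)[mask]
            bound = float(np.sum(tau * self.bound_signal[mask]) / np.sum(tau))
        return E, W, bound

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peg_pi": self.peg_pi,
                "focus_z": self.focus_z,
                "conjugate_conc": self.conjugate_conc,
                "youngs_modulus": self.youngs_modulus,
                "linewidth": self.linewidth,
                "bound_signal": self.bound_signal,
            }
        )


def load_calibration(path, **kernel_kwargs) -> StateSpace:
    """Read a calibration CSV (comma-separated, UTF-8, dot decimal, header).

    Raises :class:`FormatError` naming any missing column and
    :class:`ValidationError` citing the 0-based row index of an invalid record.
    """
    df = pd.read_csv(path)
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"calibration file {path} missing column(s): {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                CalibrationRecord(
                    peg_pi=float(row.peg_pi),
                    focus_z=float(row.focus_z),
                    conjugate_conc=float(row.conjugate_conc),
                    youngs_modulus=float(row.youngs_modulus),
                    linewidth=float(row.linewidth),
                    bound_signal=float(row.bound_signal),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return StateSpace(records, **kernel_kwargs)


def save_calibration(space: StateSpace, path) -> None:
    space.to_frame().to_csv(path, index=False)


def kernel_weights(space: StateSpace, x: float, z: float) -> np.ndarray:
    """Functional wrapper over :meth:`StateSpace.kernel_weights`."""
    return space.kernel_weights(x, z)


def interpolate_properties(
    space: StateSpace, x: float, z: float, conjugate: float | None = None
):
    """Functional wrapper over :meth:`StateSpace.interpolate`."""
    return space.interpolate(x, z, conjugate=conjugate)
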
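"""AFM force-spectroscopy simulation and analysis for printed hydrogels.

Approach force-displacement curves are modeled with the Sneddon contact law
for a conical indenter of half-angle theta,

    F = (2/pi) * tan(theta) * E / (1 - nu^2) * delta^2,

with F in nN, E in kPa and the indentation delta in µm (these units are
mutually consistent: kPa * µm^2 = nN). For thin gels bonded to a rigid
support the force is amplified by the finite-thickness bottom-effect cone
correction, a polynomial series in chi = delta * tan(theta) / h:

    F = F_Sneddon * (1 + 0.721*chi + 0.650*chi^2 + 0.491*chi^3 + 0.225*chi^4)

where h is the gel thickness. The indentation is the piezo travel past the
contact point minus the cantilever deflection (deflection = force / spring
constant), so the measured force enters the abscissa as well; fits operate on
delta computed directly from the measured data, which makes the force model
linear in E and the modulus fit a one-parameter linear least-squares problem.

Contact-point detection minimizes the total squared residual of the piecewise
model (flat baseline before z0, contact law after) over a coarse grid of
candidate samples followed by bounded local refinement.

Quality control rejects curves containing force discontinuities — the
signature of the sample slipping under the tip — by comparing detrended
single-sample force steps against a robust (MAD-based) noise scale estimated
from the pre-contact region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import brentq, minimize_scalar

from .errors import ConfigurationError, InsufficientDataError, ValidationError

__all__ = [
    "IndenterModel",
    "ForceCurve",
    "FitResult",
    "BECC_COEFFS",
    "sneddon_force",
    "simulate_curve",
    "detect_contact_point",
    "fit_modulus",
    "qc_discontinuity",
]

#: Bottom-effect cone-correction series for a sample bonded to a rigid
#: support (4 terms in chi = delta*tan(theta)/h).
BECC_COEFFS = (0.721, 0.650, 0.491, 0.225)

#: Paper-reported acquisition defaults.
DEFAULT_APPROACH_VELOCITY = 0.5  # µm/s
DEFAULT_THRESHOLD_FORCE = 10.0  # nN
DEFAULT_SPRING_CONSTANT = 0.03  # N/m (soft pyramidal lever)
DEFAULT_DZ = 0.01  # µm sample spacing

#: Robust noise-scale floor (nN) so noise-free curves are not flagged by QC.
QC_SCALE_FLOOR = 1e-3


@dataclass(frozen=True)
class IndenterModel:
    """Conical indenter geometry and contact-model options."""

    half_angle_deg: float = 18.0
    poisson: float = 0.5
    correction: str = "none"  # or "bottom_effect_cone"

    def __post_init__(self):
        if not 0.0 < self.half_angle_deg < 90.0:
            raise ValidationError(f"half angle {self.half_angle_deg} outside (0, 90)")
        if not 0.0 <= self.poisson <= 0.5:
            raise ValidationError(f"poisson ratio {self.poisson} outside [0, 0.5]")
        if self.correction not in ("none", "bottom_effect_cone"):
            raise ValidationError(f"unknown correction {self.correction!r}")

    @property
    def tan_theta(self) -> float:
        return math.tan(math.radians(self.half_angle_deg))

    @property
    def prefactor(self) -> float:
        """Geometry factor so that F[nN] = prefactor * E[kPa] * delta[µm]^2."""
        return (2.0 / math.pi) * self.tan_theta / (1.0 - self.poisson**2)


@dataclass
class ForceCurve:
    """One approach curve: piezo displacement (µm) vs force (nN)."""

    piezo_z: np.ndarray
    force: np.ndarray
    spring_constant: float = DEFAULT_SPRING_CONSTANT  # N/m
    approach_velocity: float = DEFAULT_APPROACH_VELOCITY  # µm/s
    threshold_force: float = DEFAULT_THRESHOLD_FORCE  # nN
    sample_thickness: float | None = None  # µm

    def __post_init__(self):
        self.piezo_z = np.asarray(self.piezo_z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.piezo_z.shape != self.force.shape or self.piezo_z.ndim != 1:
            raise ValidationError("piezo_z and force must be equal-length 1-D arrays")
        if not np.all(np.diff(self.piezo_z) > 0):
            raise ValidationError("piezo_z must be strictly monotone increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValidationError("force contains non-finite samples")
        if self.force[-1] > self.threshold_force * 1.05:
            raise ValidationError("final force exceeds threshold_force * 1.05")

    @property
    def compliance(self) -> float:
        """Cantilever compliance in µm per nN."""
        return 1e-3 / self.spring_constant


@dataclass(frozen=True)
class FitResult:
    youngs_modulus: float  # kPa
    contact_point: float  # µm
    rss: float  # nN^2
    qc_status: str  # accepted | rejected_discontinuity | rejected_fit
    model: IndenterModel


def _becc_factor(delta, tan_theta, h):
    chi = np.asarray(delta, dtype=float) * tan_theta / h
    a1, a2, a3, a4 = BECC_COEFFS
    return 1.0 + a1 * chi + a2 * chi**2 + a3 * chi**3 + a4 * chi**4


def sneddon_force(delta, E, model: IndenterModel, h: float | None = None):
    """Contact force (nN) at indentation delta (µm) for modulus E (kPa)."""
    delta = np.asarray(delta, dtype=float)
    F = model.prefactor * E * delta**2
    if model.correction == "bottom_effect_cone":
        if h is None:
            raise ConfigurationError(
                "sample thickness h is required for the bottom-effect correction"
            )
        F = F * _becc_factor(delta, model.tan_theta, h)
    return F


def _solve_force_profile(d, E, model, h, compliance, n_iter=200, tol=1e-12):
    """Force at piezo travel-past-contact d, accounting for lever deflection.

    Solves F = S(d - compliance*F) by damped fixed-point iteration; the map is
    contractive for the soft-gel / soft-lever regime used here.
    """
    d = np.asarray(d, dtype=float)
    F = sneddon_force(np.clip(d, 0, None), E, model, h)
    for _ in range(n_iter):
        delta = np.clip(d - compliance * F, 0.0, None)
        F_new = sneddon_force(delta, E, model, h)
        if np.max(np.abs(F_new - F)) < tol:
            F = F_new
            break
        F = 0.5 * (F + F_new)
    return F


def simulate_curve(
    E: float,
    model: IndenterModel = IndenterModel(),
    z0: float = 2.0,
    h: float | None = None,
    noise_sd: float = 0.05,
    slip: tuple[float, float] | None = None,
    seed: int | None = None,
    dz: float = DEFAULT_DZ,
    pre_contact: float = 2.0,
    spring_constant: float = DEFAULT_SPRING_CONSTANT,
    threshold_force: float = DEFAULT_THRESHOLD_FORCE,
) -> ForceCurve:
    """Simulate a noisy approach curve terminated at the threshold force.

    ``slip``, when given, is (piezo position µm, jump nN): every sample at or
    past that position has the jump subtracted, mimicking the force drop of a
    slipping sample. Deterministic for a fixed seed.
    """
    if not E > 0:
        raise ValidationError(f"E must be > 0, got {E}")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    compliance = 1e-3 / spring_constant
    # piezo travel past contact needed to reach the threshold force
    delta_max = brentq(
        lambda d: sneddon_force(d, E, model, h) - threshold_force, 0.0, 1e3
    )
    d_max = delta_max + compliance * threshold_force
    d = np.arange(-pre_contact, d_max + dz, dz)
    F = np.zeros_like(d)
    post = d > 0
    F[post] = _solve_force_profile(d[post], E, model, h, compliance)
    # truncate at the first sample reaching the threshold
    over = np.nonzero(F >= threshold_force)[0]
    if over.size:
        end = over[0] + 1
        d, F = d[:end], F[:end]
    z = z0 + d
    if slip is not None:
        pos, jump = slip
        F = F - jump * (z >= pos)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sd, size=F.shape)
    # clamp any noise overshoot above the termination force
    F = np.minimum(F, threshold_force * 1.049)
    return ForceCurve(
        piezo_z=z,
        force=F,
        spring_constant=spring_constant,
        threshold_force=threshold_force,
        sample_thickness=h,
    )


def _linear_E_fit(delta, f, model, h):
    """Least-squares modulus over post-contact samples; returns (E, rss)."""
    g = model.prefactor * delta**2
    if model.correction == "bottom_effect_cone":
        g = g * _becc_factor(delta, model.tan_theta, h)
    denom = float(np.dot(g, g))
    if denom == 0.0:
        return 0.0, float(np.dot(f, f))
    E = float(np.dot(f, g) / denom)
    E = max(E, 0.0)
    resid = f - E * g
    return E, float(np.dot(resid, resid))


def _piecewise_rss(curve: ForceCurve, model: IndenterModel, z0: float):
    """Total squared residual of baseline-then-contact model at contact z0."""
    z, F = curve.piezo_z, curve.force
    pre = z < z0
    n_pre = int(pre.sum())
    baseline = float(F[pre].mean()) if n_pre else 0.0
    rss = float(np.sum((F[pre] - baseline) ** 2)) if n_pre else 0.0
    post = ~pre
    if post.any():
        f = F[post] - baseline
        delta = np.clip((z[post] - z0) - curve.compliance * f, 0.0, None)
        h = curve.sample_thickness
        _, rss_post = _linear_E_fit(delta, f, model, h)
        rss += rss_post
    return rss, baseline


def detect_contact_point(
    curve: ForceCurve, model: IndenterModel = IndenterModel(), coarse_step: int = 5
) -> float:
    """Contact point z0 minimizing the piecewise baseline/contact residual.

    Coarse grid over every ``coarse_step``-th sample, then bounded scalar
    refinement between the neighbors of the best candidate. Ties break to the
    smaller z0 (first minimum).
    """
    z = curve.piezo_z
    n = z.size
    if n < 20:
        raise InsufficientDataError(f"curve has {n} samples; at least 20 required")
    if curve.sample_thickness is None and model.correction == "bottom_effect_cone":
        raise ConfigurationError("sample_thickness required for corrected detection")
    idx = np.arange(2, n - 2, coarse_step)
    rss = np.array([_piecewise_rss(curve, model, z[i])[0] for i in idx])
    best = idx[int(np.argmin(rss))]
    lo = z[max(best - coarse_step, 1)]
    hi = z[min(best + coarse_step, n - 2)]
    res = minimize_scalar(
        lambda c: _piecewise_rss(curve, model, c)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def fit_modulus(
    curve: ForceCurve,
    model: IndenterModel = IndenterModel(),
    z0: float | None = None,
    run_qc: bool = True,
    jump_sigma: float = 6.0,
    rel_residual_tol: float = 0.05,
    tip_sample_correction: bool = True,
) -> FitResult:
    """Fit Young's modulus from an approach curve.

    The contact point is detected automatically unless supplied. With
    ``tip_sample_correction`` (default) the indentation subtracts the
    cantilever deflection computed from the measured force. The fit is
    ``rejected_fit`` when the relative residual exceeds ``rel_residual_tol``
    or no post-contact samples exist, and ``rejected_discontinuity`` when QC
    detects a slip (the modulus is still reported for diagnosis).
    """
    if model.correction == "bottom_effect_cone" and curve.sample_thickness is None:
        raise ConfigurationError(
            "curve.sample_thickness is required when correction='bottom_effect_cone'"
        )
    status = "accepted"
    if run_qc and qc_discontinuity(curve, jump_sigma=jump_sigma) != "accepted":
        status = "rejected_discontinuity"
    if z0 is None:
        z0 = detect_contact_point(curve, model)
    z, F = curve.piezo_z, curve.force
    pre = z < z0
    baseline = float(F[pre].mean()) if pre.any() else 0.0
    post = ~pre
    if not post.any():
        return FitResult(0.0, z0, float(np.sum((F - baseline) ** 2)),
                         "rejected_fit", model)
    f = F[post] - baseline
    travel = z[post] - z0
    delta = travel - curve.compliance * f if tip_sample_correction else travel
    delta = np.clip(delta, 0.0, None)
    E, rss = _linear_E_fit(delta, f, model, curve.sample_thickness)
    ss_tot = float(np.dot(f, f))
    if status == "accepted":
        rel = rss / ss_tot if ss_tot > 0 else 1.0
        if E <= 0 or rel > rel_residual_tol:
            status = "rejected_fit"
    return FitResult(E, float(z0), rss, status, model)


def qc_discontinuity(curve: ForceCurve, jump_sigma: float = 6.0) -> str:
    """Flag single-sample force jumps exceeding jump_sigma x robust noise.

    Sample-to-sample force steps are detrended with a short median filter so
    the smooth post-contact rise does not register; the noise scale is
    1.4826 * MAD of the pre-contact steps, whose underlying trend is flat
    (floored at 1 pN for noise-free data). A jump exactly at the threshold
    rejects (>= rule).
    """
    F = curve.force
    d = np.diff(F)
    if d.size < 10:
        return "accepted"
    trend = median_filter(d, size=7, mode="nearest")
    r = d - trend
    n_pre = max(10, d.size // 4)
    pre = d[:n_pre]
    scale = 1.4826 * float(np.median(np.abs(pre - np.median(pre))))
    scale = max(scale, QC_SCALE_FLOOR)
    if float(np.max(np.abs(r))) >= jump_sigma * scale:
        return "rejected_discontinuity"
    return "accepted"


def save_curve(curve: ForceCurve, csv_path, meta_path=None) -> None:
    """Write a curve as CSV (piezo_z_um, force_nN) plus a JSON metadata sidecar."""
    import json

    import pandas as pd

    pd.DataFrame({"piezo_z_um": curve.piezo_z, "force_nN": curve.force}).to_csv(
        csv_path, index=False
    )
    if meta_path is not None:
        meta = {
            "spring_constant_N_per_m": curve.spring_constant,
            "approach_velocity_um_per_s": curve.approach_velocity,
            "threshold_force_nN": curve.threshold_force,
            "sample_thickness_um": curve.sample_thickness,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def load_curve(csv_path, meta_path=None) -> ForceCurve:
    import json

    import pandas as pd

    df = pd.read_csv(csv_path)
    for col in ("piezo_z_um", "force_nN"):
        if col not in df.columns:
            from .errors import FormatError

            raise FormatError(f"curve file {csv_path} missing column {col}")
    kwargs = {}
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
        kwargs = {
            "spring_constant": meta.get(
                "spring_constant_N_per_m", DEFAULT_SPRING_CONSTANT
            ),
            "approach_velocity": meta.get(
                "approach_velocity_um_per_s", DEFAULT_APPROACH_VELOCITY
            ),
            "threshold_force": meta.get("threshold_force_nN", DEFAULT_THRESHOLD_FORCE),
            "sample_thickness": meta.get("sample_thickness_um"),
        }
    return ForceCurve(df["piezo_z_um"].to_numpy(), df["force_nN"].to_numpy(), **kwargs)
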
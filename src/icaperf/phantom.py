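"""Synthetic DSC-MRI phantom with artery / perivascular / parenchyma blocks.

The phantom is a row of three square blocks sharing partial-volume columns:

* block I   — artery: the first-pass bolus itself, relaxed in the static
  dephasing regime (SDR) with unit compartment fraction;
* block II  — artery-surrounding (perivascular) tissue: the dilution-theory
  blood curve, SDR only, with an effective perivascular vessel fraction;
* block III — parenchyma: the dilution-theory blood curve, SDR plus the
  diffusional narrowing regime (DNR) capillary contribution.

Adjacent blocks share ``overlap_cols`` columns whose signal is a
``pv_fraction`` mixture of the two pure compartment signals, emulating the
partial volume effect that confounds arterial input function selection.
Zero-mean Gaussian noise is added so that the contrast-to-noise ratio of the
arterial signal drop equals ``cnr``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .series import DynamicSeries

__all__ = [
    "GYROMAGNETIC_RATIO",
    "BolusParams",
    "KiselevParams",
    "PhantomSpec",
    "PhantomTruth",
    "bolus_concentration",
    "tissue_concentration",
    "relaxation_shift",
    "concentration_to_signal",
    "build_phantom",
    "ideal_aif",
]

#: proton gyromagnetic ratio, rad / s / T
GYROMAGNETIC_RATIO = 2.6752218744e8


@dataclass(frozen=True)
class BolusParams:
    """First-pass arterial bolus C(t) = c_max * (t/t0) * exp(1 - t/t0).

    ``t0`` is both the rise time constant and the time of the peak; it is
    expressed in the time unit of the series (seconds here).  The literature
    sometimes prints this constant in milliseconds; a 7 ms bolus is
    degenerate at a 1.5 s sampling interval, so the default is 7 s with the
    printed-unit interpretation available by passing ``t0=0.007``.
    """

    c_max: float = 3.0  # mM
    t0: float = 7.0     # s

    def __post_init__(self) -> None:
        if self.c_max <= 0 or self.t0 <= 0:
            raise ValueError("c_max and t0 must be positive")


@dataclass(frozen=True)
class KiselevParams:
    """Susceptibility-relaxation parameters (asymptotic SDR/DNR forms).

    ``chi_per_mM``, ``dnr_coeff`` and ``water_diffusivity`` are calibration
    constants of the asymptotic regime formulas; see docs/methods.md for how
    the defaults were chosen.  ``zeta_peri`` is the effective large-vessel
    volume fraction seen by perivascular voxels.
    """

    b0: float = 1.5                  # T
    te: float = 0.045                # s (gradient-echo TE of the simulation)
    zeta_a: float = 0.005            # arteriole volume fraction in tissue
    zeta_v: float = 0.01             # venule volume fraction in tissue
    zeta_c: float = 0.02             # capillary volume fraction in tissue
    zeta_peri: float = 0.3           # perivascular large-vessel fraction
    rho_a: float = 100.0             # µm
    rho_v: float = 100.0             # µm
    rho_c: float = 3.5               # µm
    chi0: float = 0.038              # ppm, venous blood susceptibility
    r2a0: float = 6.21               # 1/s, arterial blood baseline
    r2v0: float = 13.43              # 1/s, venous blood / parenchyma baseline
    chi_per_mM: float = 0.027        # ppm / mM, contrast molar susceptibility
    dnr_coeff: float = 40.0          # dimensionless DNR prefactor
    water_diffusivity: float = 1e-9  # m^2 / s

    def __post_init__(self) -> None:
        for name in (
            "b0", "te", "zeta_a", "zeta_v", "zeta_c", "zeta_peri",
            "rho_a", "rho_v", "rho_c", "chi0", "r2a0", "r2v0",
            "chi_per_mM", "dnr_coeff", "water_diffusivity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("zeta_a", "zeta_v", "zeta_c", "zeta_peri"):
            if getattr(self, name) >= 1:
                raise ValueError(f"{name} must be < 1")

    def delta_omega(self, conc: np.ndarray) -> np.ndarray:
        """Characteristic frequency shift (rad/s) at concentration ``conc`` (mM)."""
        return GYROMAGNETIC_RATIO * self.b0 * self.chi_per_mM * 1e-6 * np.asarray(conc, float)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom realization."""

    block_edge: int = 9
    overlap_cols: int = 3
    pv_fraction: float = 0.5
    n_timepoints: int = 80
    dt: float = 1.5            # s
    mtt: float = 2.6           # s
    cnr: float = 50.0          # CNR of the arterial signal drop; inf => noise-free
    injection_tp: int = 7      # 1-based
    s0: float = 1000.0         # proton-density signal scale
    bolus: BolusParams = field(default_factory=BolusParams)
    physics: KiselevParams = field(default_factory=KiselevParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_edge < 2:
            raise ValueError("block_edge must be >= 2")
        if not (0 <= self.overlap_cols < self.block_edge):
            raise ValueError("overlap_cols must be in [0, block_edge)")
        if not (0.0 < self.pv_fraction < 1.0):
            raise ValueError("pv_fraction must be in (0, 1)")
        if self.n_timepoints < 2 or self.dt <= 0 or self.mtt <= 0:
            raise ValueError("invalid time axis / mtt")
        if self.cnr <= 0:
            raise ValueError("cnr must be positive (use math.inf for noise-free)")
        if not (1 <= self.injection_tp <= self.n_timepoints):
            raise ValueError("injection_tp outside the time axis")


@dataclass
class PhantomTruth:
    """Ground truth for one phantom: voxel masks and noise-free pure curves.

    Masks are flat voxel indices into the C-order flattened image grid.
    ``pure_signals`` maps compartment name -> noise-free signal curve.
    """

    mask_artery: np.ndarray
    mask_surround: np.ndarray
    mask_tissue: np.ndarray
    mask_overlap_12: np.ndarray
    mask_overlap_23: np.ndarray
    pure_signals: Dict[str, np.ndarray]
    spatial_shape: tuple

    def region_mask(self, target: str, with_partial_volume: bool) -> np.ndarray:
        """Flat indices of a region, optionally including its 0.5-mix strips."""
        pure = {
            "artery": (self.mask_artery, [self.mask_overlap_12]),
            "surround": (self.mask_surround, [self.mask_overlap_12, self.mask_overlap_23]),
            "tissue": (self.mask_tissue, [self.mask_overlap_23]),
        }
        if target not in pure:
            raise ValueError(f"unknown target region {target!r}")
        base, strips = pure[target]
        if not with_partial_volume:
            return base
        return np.sort(np.concatenate([base, *strips]))


# ---------------------------------------------------------------------------
# curve-level physics
# ---------------------------------------------------------------------------

def bolus_concentration(t, p: BolusParams) -> np.ndarray:
    """Arterial input bolus C_a(t) = c_max (t/t0) exp(1 - t/t0), in mM.

    Zero at t = 0, maximum ``c_max`` exactly at t = t0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("bolus_concentration requires t >= 0")
    return p.c_max * (t / p.t0) * np.exp(1.0 - t / p.t0)


def tissue_concentration(
    aif: np.ndarray,
    mtt: float,
    zeta: float,
    dt: float,
    kernel: str = "exact",
) -> np.ndarray:
    """Dilution-theory compartment curve: zeta * (aif ⊛ e^{-t/mtt}) / mtt.

    ``kernel="exact"`` integrates the exponential residue over each sample
    bin, h[k] = (1 - e^{-dt/mtt}) e^{-k dt/mtt}, which conserves mass exactly
    in the long-time limit (a constant input c tends to zeta*c).
    ``kernel="riemann"`` is the left-endpoint Riemann sum
    (dt/mtt) e^{-k dt/mtt}, which carries an O(dt/mtt) scale bias.
    """
    aif = np.asarray(aif, dtype=float)
    if aif.size == 0:
        raise ValueError("empty input curve")
    if mtt <= 0 or dt <= 0:
        raise ValueError("mtt and dt must be positive")
    n = aif.size
    k = np.arange(n)
    decay = np.exp(-k * dt / mtt)
    if kernel == "exact":
        h = (1.0 - math.exp(-dt / mtt)) * decay
    elif kernel == "riemann":
        h = (dt / mtt) * decay
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return zeta * np.convolve(aif, h)[:n]


def relaxation_shift(
    conc: np.ndarray,
    regime: str,
    compartment_fraction: float,
    p: KiselevParams,
) -> np.ndarray:
    """Contrast-induced relaxation-rate change ΔR2(t) in 1/s.

    SDR (large vessels):  ΔR2* = (2π/3) ζ δω(t), linear in concentration.
    DNR (capillaries):    ΔR2  = k_DNR ζ δω(t)^2 ρ_c^2 / D, quadratic.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be elementwise >= 0")
    dw = p.delta_omega(conc)
    if regime == "SDR":
        return (2.0 * math.pi / 3.0) * compartment_fraction * dw
    if regime == "DNR":
        rho_m = p.rho_c * 1e-6
        return p.dnr_coeff * compartment_fraction * dw**2 * rho_m**2 / p.water_diffusivity
    raise ValueError(f"unknown relaxation regime {regime!r} (expected 'SDR' or 'DNR')")


def concentration_to_signal(
    delta_r2: np.ndarray,
    s0: float,
    te: float,
    r2_baseline: float,
) -> np.ndarray:
    """Spin signal S(t) = s0 exp(-TE (R2_baseline + ΔR2(t)))."""
    if s0 <= 0 or te <= 0:
        raise ValueError("s0 and te must be positive")
    return s0 * np.exp(-te * (r2_baseline + np.asarray(delta_r2, float)))


def ideal_aif(
    t,
    amplitude: float = 1.0,
    t_arrival: float = 0.0,
    alpha: float = 3.0,
    beta: float = 1.5,
) -> np.ndarray:
    """The standard first-pass gamma-variate AIF used in deconvolution studies.

    C(t) = amplitude * (t - t_arrival)^alpha * exp(-(t - t_arrival)/beta) for
    t > t_arrival, 0 before; defaults alpha=3.0, beta=1.5 s.
    """
    t = np.asarray(t, dtype=float)
    shifted = t - t_arrival
    out = np.zeros_like(shifted)
    pos = shifted > 0
    out[pos] = amplitude * shifted[pos] ** alpha * np.exp(-shifted[pos] / beta)
    return out


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

def _pure_compartment_signals(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    """Noise-free signal curves of the three compartments."""
    ph = spec.physics
    t = np.arange(spec.n_timepoints) * spec.dt
    # time since injection, clipped at 0 (no contrast before the bolus)
    t_inj = (spec.injection_tp - 1) * spec.dt
    tau = np.clip(t - t_inj, 0.0, None)

    c_artery = bolus_concentration(tau, spec.bolus)
    # dilution-theory blood concentration in tissue (zeta=1: concentration
    # within the blood compartment, delayed and dispersed by the transit)
    c_blood_tissue = tissue_concentration(c_artery, spec.mtt, 1.0, spec.dt)

    r2_artery = relaxation_shift(c_artery, "SDR", 1.0, ph)
    r2_surround = relaxation_shift(c_blood_tissue, "SDR", ph.zeta_peri, ph)
    r2_tissue = (
        relaxation_shift(c_blood_tissue, "SDR", ph.zeta_v, ph)
        + relaxation_shift(c_blood_tissue, "DNR", ph.zeta_c, ph)
    )

    return {
        "artery": concentration_to_signal(r2_artery, spec.s0, ph.te, ph.r2a0),
        "surround": concentration_to_signal(r2_surround, spec.s0, ph.te, ph.r2v0),
        "tissue": concentration_to_signal(r2_tissue, spec.s0, ph.te, ph.r2v0),
        "concentration_artery": c_artery,
        "concentration_blood_tissue": c_blood_tissue,
    }


def build_phantom(spec: PhantomSpec):
    """Build one noisy phantom realization.

    Returns
    -------
    (DynamicSeries, PhantomTruth)
        The series has shape ``(n_timepoints, block_edge, 3*block_edge -
        2*overlap_cols)``.  Noise is zero-mean Gaussian with
        sigma = (peak arterial signal drop) / cnr, fully determined by
        ``spec.seed``.
    """
    edge, ov = spec.block_edge, spec.overlap_cols
    ncols = 3 * edge - 2 * ov
    shape = (edge, ncols)
    sig = _pure_compartment_signals(spec)
    s_art, s_sur, s_tis = sig["artery"], sig["surround"], sig["tissue"]

    # column spans of the three blocks
    c1 = (0, edge)                       # block I
    c2 = (edge - ov, 2 * edge - ov)      # block II
    c3 = (2 * edge - 2 * ov, ncols)      # block III
    image = np.zeros((spec.n_timepoints, *shape))
    image[:, :, c1[0]:c1[1]] = s_art[:, None, None]
    image[:, :, c2[0]:c2[1]] = s_sur[:, None, None]
    image[:, :, c3[0]:c3[1]] = s_tis[:, None, None]
    f = spec.pv_fraction
    if ov:
        image[:, :, c2[0]:c2[0] + ov] = (f * s_art + (1 - f) * s_sur)[:, None, None]
        image[:, :, c3[0]:c3[0] + ov] = (f * s_sur + (1 - f) * s_tis)[:, None, None]

    # noise scaled to the arterial contrast-to-noise ratio
    baseline = slice(0, spec.injection_tp - 1) if spec.injection_tp > 1 else slice(0, 1)
    drop = float(s_art[baseline].mean() - s_art.min())
    if math.isfinite(spec.cnr):
        sigma = drop / spec.cnr
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, sigma, size=image.shape)

    series = DynamicSeries(
        data=image,
        dt=spec.dt,
        te=spec.physics.te,
        injection_tp=spec.injection_tp,
        meta={"phantom_cnr": spec.cnr, "phantom_seed": spec.seed,
              "arterial_drop": drop},
    )

    grid = np.arange(edge * ncols).reshape(shape)
    cols = np.arange(ncols)
    in1 = (cols >= c1[0]) & (cols < c1[1])
    in2 = (cols >= c2[0]) & (cols < c2[1])
    in3 = (cols >= c3[0]) & (cols < c3[1])
    truth = PhantomTruth(
        mask_artery=grid[:, in1 & ~in2].ravel(),
        mask_surround=grid[:, in2 & ~in1 & ~in3].ravel(),
        mask_tissue=grid[:, in3 & ~in2].ravel(),
        mask_overlap_12=grid[:, in1 & in2].ravel(),
        mask_overlap_23=grid[:, in2 & in3].ravel(),
        pure_signals={k: sig[k] for k in ("artery", "surround", "tissue")},
        spatial_shape=shape,
    )
    return series, truth
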
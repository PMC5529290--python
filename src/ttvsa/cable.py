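"""Passive cable properties of t-tubules from measured diameters.

Treating a tubule as a one-dimensional cable of diameter D filled with
electrolyte of resistivity R_L and bounded by membrane of resistivity R_m,
the steady-state space constant is λ_dc = sqrt(D·R_m / (4·R_L)).  Under
sinusoidal drive at frequency f the membrane impedance shortens the decay
length:

    λ_f = λ_dc / Re{ sqrt(1 + i·2πf·τ_m) }          (default reading)

with τ_m = R_m·C_specific the membrane time constant.  A modulus variant
λ_dc / |sqrt(1 + iωτ)| is selectable; the real-part reading is the default
because it reproduces the expected ~50% shortening at f ≈ 150 Hz with
τ_m ≈ 7 ms, whereas the modulus form gives ~61%.

Units follow electrophysiological convention: MΩ, pF, μF/cm², kΩ·cm²,
Ω·cm, μm, ms — converted internally, never silently mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class CableParams:
    """Inputs and derived constants of the single-cable model."""

    r_input_mohm: float = 45.0
    c_cell_pf: float = 150.0
    c_specific_uf_per_cm2: float = 1.0
    r_lumen_ohm_cm: float = 50.0

    def __post_init__(self) -> None:
        for name in ("r_input_mohm", "c_cell_pf", "c_specific_uf_per_cm2", "r_lumen_ohm_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def r_m_kohm_cm2(self) -> float:
        return membrane_resistivity(self.r_input_mohm, self.c_cell_pf, self.c_specific_uf_per_cm2)

    @property
    def tau_m_ms(self) -> float:
        # kΩ·cm² × μF/cm² = ms
        return self.r_m_kohm_cm2 * self.c_specific_uf_per_cm2


def membrane_resistivity(
    r_input_mohm: float, c_cell_pf: float, c_specific_uf_per_cm2: float
) -> float:
    """Specific membrane resistance R_m in kΩ·cm².

    The cell area follows from capacitance: A = C_cell / C_specific;
    R_m = R_input × A.  Unit chase: pF / (μF/cm²) = 1e-6 cm²;
    MΩ × cm² = 1e3 kΩ·cm², combined factor 1e-3.
    """
    for v, name in (
        (r_input_mohm, "input resistance"),
        (c_cell_pf, "cell capacitance"),
        (c_specific_uf_per_cm2, "specific capacitance"),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    area_cm2 = c_cell_pf * 1e-12 / (c_specific_uf_per_cm2 * 1e-6)
    r_m_ohm_cm2 = r_input_mohm * 1e6 * area_cm2
    return r_m_ohm_cm2 / 1e3


def lambda_dc(diameter_um: float, r_m_kohm_cm2: float, r_lumen_ohm_cm: float) -> float:
    """Steady-state space constant λ = sqrt(D·R_m / (4·R_L)), returned in μm."""
    for v, name in (
        (diameter_um, "diameter"),
        (r_m_kohm_cm2, "membrane resistivity"),
        (r_lumen_ohm_cm, "luminal resistivity"),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    d_cm = diameter_um * 1e-4
    r_m = r_m_kohm_cm2 * 1e3  # Ω·cm²
    lam_cm = np.sqrt(d_cm * r_m / (4.0 * r_lumen_ohm_cm))
    return float(lam_cm * 1e4)


def lambda_ac(
    lambda_dc_um: float, f_hz: float, tau_m_ms: float, variant: str = "real"
) -> float:
    """Frequency-dependent space constant, μm.

    ``variant="real"`` divides by Re{sqrt(1 + iωτ)} (default);
    ``variant="modulus"`` by |sqrt(1 + iωτ)|.  At f = 0 both reduce to the
    dc value; both decrease monotonically with f.
    """
    if f_hz < 0:
        raise ValueError("frequency must be non-negative")
    if lambda_dc_um <= 0 or tau_m_ms <= 0:
        raise ValueError("lambda_dc and tau_m must be positive")
    wt = 2.0 * np.pi * f_hz * tau_m_ms * 1e-3
    root = np.sqrt(1.0 + 1j * wt)
    if variant == "real":
        denom = float(np.real(root))
    elif variant == "modulus":
        denom = float(np.abs(root))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return lambda_dc_um / denom


def detubulation_extrapolation(
    c_total_pf: float, c_after_pf: float, fraction_removed: float
) -> tuple[float, float]:
    """Extrapolate partial detubulation to complete tubule disconnection.

    Osmotic-shock detubulation disconnects only a fraction of the TTs; the
    observed capacitance drop scaled by that fraction gives the full TT
    capacitance.  Returns ``(C_fully_detubulated pF, TT fraction of total
    capacitance %)``.  If the extrapolated TT capacitance exceeds the total
    (inconsistent inputs), the fraction is capped at 100% with a warning.
    """
    if not (0.0 < fraction_removed <= 1.0):
        raise ValueError("fraction_removed must lie in (0, 1]")
    if c_total_pf <= 0 or c_after_pf <= 0:
        raise ValueError("capacitances must be positive")
    if c_after_pf >= c_total_pf:
        raise ValueError("capacitance after detubulation must be below the total")
    c_tt = (c_total_pf - c_after_pf) / fraction_removed
    if c_tt > c_total_pf:
        log.warning(
            "extrapolated TT capacitance %.1f pF exceeds total %.1f pF; capping at 100%%",
            c_tt, c_total_pf,
        )
        c_tt = c_total_pf
    return (c_total_pf - c_tt, c_tt / c_total_pf * 100.0)


def cable_report(
    diameter_um: float,
    params: CableParams | None = None,
    f_hz: float = 150.0,
    variant: str = "real",
) -> dict:
    """R_m, τ_m, λ_dc and λ_f for one mean tubule diameter."""
    params = params or CableParams()
    r_m = params.r_m_kohm_cm2
    tau = params.tau_m_ms
    lam0 = lambda_dc(diameter_um, r_m, params.r_lumen_ohm_cm)
    lamf = lambda_ac(lam0, f_hz, tau, variant=variant)
    return {
        "diameter_um": diameter_um,
        "r_m_kohm_cm2": r_m,
        "tau_m_ms": tau,
        "lambda_dc_um": lam0,
        "f_hz": f_hz,
        "lambda_f_um": lamf,
        "ac_reduction_pct": (1.0 - lamf / lam0) * 100.0,
        "variant": variant,
    }
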
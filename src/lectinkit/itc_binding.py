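"""Single-site (Wiseman) ITC: forward simulation, fitting, thermodynamics.

The forward model is the Origin-style one-site isotherm.  After injection i
the displaced-volume corrections are::

    M_t = M0 (1 - f) / (1 + f),   X_t = Xs (ΔV/V0) / (1 + f),   f = ΔV / (2 V0)

with bound complex from the single-site quadratic and per-injection heat
given by the change in ΔH·V0·[MX] plus the standard displaced-volume term.
Fits run over (log10 K_A, ΔH[, n][, offset]); the derived quantities obey
ΔG = −RT ln K_A, −TΔS = ΔG − ΔH and c = n·K_A·[M]cell by construction.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "R_KCAL",
    "TitrationProtocol",
    "STANDARD_PROTOCOL",
    "ITCData",
    "ITCFit",
    "predicted_heats",
    "simulate_titration",
    "fit_one_site",
    "thermodynamics",
    "beer_lambert_conc",
]

#: Gas constant in kcal·mol⁻¹·K⁻¹.
R_KCAL = 1.987e-3


@dataclass(frozen=True)
class TitrationProtocol:
    """Instrument protocol: volumes in µl, concentrations in mM, T in K."""

    cell_conc_mM: float
    syringe_conc_mM: float
    cell_volume_ul: float = 280.0
    injection_volume_ul: float = 2.0
    n_injections: int = 18
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        for name in ("cell_conc_mM", "syringe_conc_mM", "cell_volume_ul",
                     "injection_volume_ul", "temperature_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_injections <= 0:
            raise ValueError("n_injections must be positive")
        if self.n_injections * self.injection_volume_ul > 0.5 * self.cell_volume_ul:
            raise ValueError("total injected volume must stay well below the cell volume")

    @property
    def cell_volume_l(self) -> float:
        return self.cell_volume_ul * 1e-6

    @property
    def injected_volumes_l(self) -> np.ndarray:
        return np.arange(1, self.n_injections + 1) * self.injection_volume_ul * 1e-6

    def molar_ratio(self) -> np.ndarray:
        """Syringe/cell molar ratio after each injection (dilution-corrected)."""
        mt, xt = _dilution_corrected(self)
        return xt / mt


#: 280 µl cell, 18 × 2 µl injections at 25 °C; 1 mM macromolecule titrated
#: with 25 mM ligand (the methyl-monosaccharide setup).
STANDARD_PROTOCOL = TitrationProtocol(cell_conc_mM=1.0, syringe_conc_mM=25.0)


@dataclass
class ITCData:
    """Per-injection heats in µcal plus the protocol that produced them."""

    heats_ucal: np.ndarray
    protocol: TitrationProtocol
    control_heats_ucal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if len(self.heats_ucal) != self.protocol.n_injections:
            raise ValueError("number of heats must equal protocol.n_injections")
        if self.control_heats_ucal is not None:
            self.control_heats_ucal = np.asarray(self.control_heats_ucal, dtype=float)
            if len(self.control_heats_ucal) != self.protocol.n_injections:
                raise ValueError("control heats must match n_injections")

    @property
    def corrected_heats_ucal(self) -> np.ndarray:
        if self.control_heats_ucal is None:
            return self.heats_ucal
        return self.heats_ucal - self.control_heats_ucal

    @property
    def normalized(self) -> np.ndarray:
        """Heats in kcal per mole of injectant."""
        p = self.protocol
        moles = p.syringe_conc_mM * 1e-3 * p.injection_volume_ul * 1e-6
        return self.corrected_heats_ucal * 1e-9 / moles


@dataclass
class ITCFit:
    """One-site fit result with the derived thermodynamic decomposition."""

    K_A: float
    n: float
    dH: float
    baseline_offset: float
    dG: float
    minus_TdS: float
    c_value: float
    temperature_K: float
    std_errors: dict[str, float] = field(default_factory=dict)
    n_fixed: bool = True

    def __post_init__(self) -> None:
        # The decomposition identities hold exactly by construction.
        assert math.isclose(self.dG, -R_KCAL * self.temperature_K * math.log(self.K_A),
                            rel_tol=1e-12)
        assert math.isclose(self.minus_TdS, self.dG - self.dH, rel_tol=0, abs_tol=1e-12)


def _dilution_corrected(protocol: TitrationProtocol) -> tuple[np.ndarray, np.ndarray]:
    v0 = protocol.cell_volume_l
    dvi = protocol.injected_volumes_l
    f = dvi / (2.0 * v0)
    mt = protocol.cell_conc_mM * 1e-3 * (1.0 - f) / (1.0 + f)
    xt = protocol.syringe_conc_mM * 1e-3 * (dvi / v0) / (1.0 + f)
    return mt, xt


def _cumulative_heat_kcal(K_A: float, n: float, dH: float,
                          protocol: TitrationProtocol) -> np.ndarray:
    """ΔH·V0·[MX] (kcal) after each injection."""
    mt, xt = _dilution_corrected(protocol)
    if K_A <= 0.0:
        return np.zeros_like(mt)
    b = n * mt + xt + 1.0 / K_A
    mx = 0.5 * (b - np.sqrt(np.clip(b * b - 4.0 * n * mt * xt, 0.0, None)))
    return mx * protocol.cell_volume_l * dH


def predicted_heats(K_A: float, n: float, dH: float, protocol: TitrationProtocol,
                    offset_kcal_per_mol: float = 0.0) -> np.ndarray:
    """Per-injection heats in kcal/mol of injectant (the fitted observable)."""
    q = _cumulative_heat_kcal(K_A, n, dH, protocol)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dv_frac = protocol.injection_volume_ul / protocol.cell_volume_ul
    heats_kcal = q - q_prev + dv_frac * (q + q_prev) / 2.0
    moles = protocol.syringe_conc_mM * 1e-3 * protocol.injection_volume_ul * 1e-6
    return heats_kcal / moles + offset_kcal_per_mol


def simulate_titration(K_A: float, n: float, dH: float, protocol: TitrationProtocol,
                       noise_sd_ucal: float = 0.0, seed: int | None = None) -> ITCData:
    """Forward-simulate an isotherm; Gaussian noise in µcal, seeded."""
    if K_A < 0:
        raise ValueError("K_A must be non-negative")
    per_mol = predicted_heats(K_A, n, dH, protocol)
    moles = protocol.syringe_conc_mM * 1e-3 * protocol.injection_volume_ul * 1e-6
    heats_ucal = per_mol * moles * 1e9
    if noise_sd_ucal > 0:
        rng = np.random.default_rng(seed)
        heats_ucal = heats_ucal + rng.normal(0.0, noise_sd_ucal, size=len(heats_ucal))
    return ITCData(heats_ucal=heats_ucal, protocol=protocol)


def thermodynamics(K_A: float, dH: float, T: float = 298.15) -> tuple[float, float]:
    """(ΔG, −TΔS) in kcal/mol from ΔG = −RT ln K_A and −TΔS = ΔG − ΔH."""
    if K_A <= 0:
        raise ValueError("K_A must be positive")
    dG = -R_KCAL * T * math.log(K_A)
    return dG, dG - dH


def beer_lambert_conc(A280: float, epsilon: float, path_cm: float = 1.0) -> float:
    """Molar concentration C = A / (ε · b)."""
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    return A280 / (epsilon * path_cm)


def fit_one_site(data: ITCData, fix_n: float | None = 1.0,
                 fit_offset: bool = False) -> ITCFit:
    """Nonlinear least-squares one-site fit of integrated injection heats.

    K_A is parameterized as log10(K_A) (negative trial values impossible);
    ``n`` is fixed to 1 by default.  Warns when the Wiseman c-value leaves the
    reliable window (c < 1: fix n; c > 1000: too steep).

    ``fit_offset`` adds a free per-injection baseline (a stand-in for an
    unsubtracted dilution heat).  It is off by default: with moderate c the
    offset is nearly degenerate with ΔH and visibly degrades K_A recovery,
    so it should be enabled only when no control titration was subtracted.
    """
    protocol = data.protocol
    y = data.normalized
    usable = np.isfinite(y)
    if usable.sum() < 5:
        raise ValueError("need at least 5 usable injections to fit")

    m0 = protocol.cell_conc_mM * 1e-3

    def residual(params: lmfit.Parameters) -> np.ndarray:
        model = predicted_heats(10.0 ** params["log10_ka"].value,
                                params["n"].value, params["dh"].value, protocol,
                                params["offset"].value)
        return (y - model)[usable]

    dh_init = float(y[np.argmax(np.abs(y))])
    inits = [(math.log10(1.0 / m0), dh_init),
             (math.log10(1.0 / m0) + 1.0, dh_init),
             (math.log10(1.0 / m0) - 1.0, dh_init),
             (math.log10(1.0 / m0), -abs(dh_init) if dh_init > 0 else abs(dh_init))]
    best = None
    for log_ka0, dh0 in inits:
        params = lmfit.Parameters()
        params.add("log10_ka", value=log_ka0, min=-3.0, max=15.0)
        params.add("dh", value=dh0 if dh0 != 0 else -1.0)
        params.add("n", value=fix_n if fix_n is not None else 1.0,
                   vary=fix_n is None, min=1e-3)
        params.add("offset", value=0.0, vary=fit_offset)
        result = lmfit.minimize(residual, params, method="leastsq")
        if result.success and (best is None or result.chisqr < best.chisqr):
            best = result
        if best is not None and best.chisqr < 1e-20:
            break
    if best is None:
        raise RuntimeError("one-site fit failed to converge from all starting points")

    p = best.params
    K_A = 10.0 ** p["log10_ka"].value
    n = p["n"].value
    dH = p["dh"].value
    dG, minus_TdS = thermodynamics(K_A, dH, protocol.temperature_K)
    c = n * K_A * m0
    if c < 1.0:
        warnings.warn(f"c-value {c:.3g} < 1: isotherm is shallow, fix n for fitting",
                      stacklevel=2)
    elif c > 1000.0:
        warnings.warn(f"c-value {c:.3g} > 1000: isotherm is near-rectangular", stacklevel=2)

    std_errors: dict[str, float] = {}
    if p["log10_ka"].stderr is not None:
        std_errors["K_A"] = abs(K_A * math.log(10.0) * p["log10_ka"].stderr)
    for key, pname in (("dH", "dh"), ("n", "n"), ("offset", "offset")):
        if p[pname].vary and p[pname].stderr is not None:
            std_errors[key] = p[pname].stderr
    return ITCFit(K_A=K_A, n=n, dH=dH, baseline_offset=p["offset"].value,
                  dG=dG, minus_TdS=minus_TdS, c_value=c,
                  temperature_K=protocol.temperature_K,
                  std_errors=std_errors, n_fixed=fix_n is not None)
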
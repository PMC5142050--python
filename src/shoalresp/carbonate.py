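"""Seawater CO2-system solver for the pH(NBS) + total-alkalinity input pair.

Solves the carbonate system the way CO2SYS does for this input pair:
equilibrium constants are evaluated from temperature and salinity at surface
pressure, converted onto the NBS activity scale via the hydrogen-ion activity
coefficient fH, and the alkalinity balance is inverted in closed form for
dissolved inorganic carbon (DIC), from which pCO2 = [CO2*]/K0.

Constant choices (the configuration used throughout this package):

* K1, K2 — Mehrbach et al. (1973) as refit by Dickson & Millero (1987),
  seawater scale.
* KHSO4 — Dickson (1990), free scale.
* K0 — Weiss (1974); KB — Dickson (1990); KW — Millero (1995);
  KF — Dickson & Riley (1979); total boron — Uppström (1974);
  fH — Takahashi et al. (1982, GEOSECS).
* Surface pressure, zero nutrient alkalinity, no fugacity correction by
  default (``apply_fugacity`` exposes it; the correction is ~3 µatm at
  reef-water pCO2, i.e. below typical reporting precision).

All concentrations are per kilogram of seawater.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field


class CarbonateDomainError(ValueError):
    """An input lies outside the domain the constant formulations support."""


class CarbonateConvergenceError(RuntimeError):
    """The internal solve failed to converge (with diagnostics attached)."""


# Hard validity limits (beyond these the empirical fits are meaningless) and
# the no-warning window for tropical surface seawater.
_TEMP_HARD = (0.0, 45.0)
_TEMP_QUIET = (15.0, 35.0)
_SAL_HARD = (0.0, 45.0)
_PH_RANGE = (7.0, 8.6)


@dataclass(frozen=True)
class SeawaterSample:
    """One water sample: temperature (°C), salinity (psu), pH on the NBS
    scale, and total alkalinity (µmol per kg seawater)."""

    temperature: float
    salinity: float
    ph_nbs: float
    total_alkalinity: float

    def __post_init__(self) -> None:
        t, s = self.temperature, self.salinity
        if not (_TEMP_HARD[0] < t < _TEMP_HARD[1]):
            raise CarbonateDomainError(
                f"temperature={t} °C outside supported range {_TEMP_HARD}"
            )
        if not (_SAL_HARD[0] < s < _SAL_HARD[1]):
            raise CarbonateDomainError(
                f"salinity={s} psu outside supported range {_SAL_HARD}"
            )
        if not (_TEMP_QUIET[0] < t < _TEMP_QUIET[1]):
            warnings.warn(
                f"temperature={t} °C outside the routine window "
                f"{_TEMP_QUIET}; constants are extrapolated",
                stacklevel=2,
            )
        if not (_PH_RANGE[0] <= self.ph_nbs <= _PH_RANGE[1]):
            raise CarbonateDomainError(
                f"ph_nbs={self.ph_nbs} outside supported range {_PH_RANGE}"
            )
        if not self.total_alkalinity > 0:
            raise CarbonateDomainError(
                f"total_alkalinity={self.total_alkalinity} must be > 0"
            )


@dataclass(frozen=True)
class ConstantsSet:
    """Equilibrium constants evaluated at (temperature, salinity), surface
    pressure.

    k1, k2, kb and kw are expressed on the NBS scale (seawater-scale values
    multiplied by fH); ks and kf are on the free scale in mol/kg-SW, as they
    enter only through the free hydrogen-ion concentration.  Totals are in
    µmol/kg-SW.
    """

    k0: float  # CO2 solubility, mol kg-1 atm-1
    k1: float
    k2: float
    kb: float
    kw: float
    ks: float
    kf: float
    total_boron: float  # µmol/kg
    total_sulfate: float  # µmol/kg
    total_fluoride: float  # µmol/kg
    fh: float  # NBS-scale hydrogen-ion activity coefficient
    provenance: tuple = field(
        default=(
            ("k1k2", "Mehrbach 1973 refit Dickson & Millero 1987 (SWS)"),
            ("khso4", "Dickson 1990"),
            ("k0", "Weiss 1974"),
            ("kb", "Dickson 1990"),
            ("kw", "Millero 1995"),
            ("kf", "Dickson & Riley 1979"),
            ("boron", "Uppström 1974"),
            ("fh", "Takahashi et al. 1982 (GEOSECS)"),
            ("pressure_dbar", 0),
            ("nutrients", "none"),
        )
    )

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "k2", "kb", "kw", "ks", "kf", "fh"):
            if not getattr(self, name) > 0:
                raise CarbonateDomainError(f"constant {name} must be > 0")
        if not self.k1 > self.k2:
            raise CarbonateDomainError("k1 must exceed k2")


@dataclass(frozen=True)
class CarbonateResult:
    """Solved CO2 system: pCO2 (µatm) and companion species (µmol/kg)."""

    pco2: float
    dic: float
    co2_star: float
    bicarbonate: float
    carbonate: float
    constants_used: ConstantsSet

    def __post_init__(self) -> None:
        for name in ("dic", "co2_star", "bicarbonate", "carbonate"):
            if getattr(self, name) < 0:
                raise CarbonateConvergenceError(
                    f"negative concentration {name}={getattr(self, name)}"
                )
        parts = self.co2_star + self.bicarbonate + self.carbonate
        if not math.isclose(self.dic, parts, rel_tol=1e-6):
            raise CarbonateConvergenceError(
                f"DIC {self.dic} != species sum {parts}"
            )


def compute_constants(temperature: float, salinity: float) -> ConstantsSet:
    """Evaluate the full constant set at (temperature °C, salinity psu).

    Deterministic: identical inputs give bit-identical outputs.
    """
    if not (_TEMP_HARD[0] < temperature < _TEMP_HARD[1]):
        raise CarbonateDomainError(
            f"temperature={temperature} °C outside supported range {_TEMP_HARD}"
        )
    if not (_SAL_HARD[0] < salinity < _SAL_HARD[1]):
        raise CarbonateDomainError(
            f"salinity={salinity} psu outside supported range {_SAL_HARD}"
        )

    t_k = temperature + 273.15
    ln_tk = math.log(t_k)
    s = salinity
    sqrt_s = math.sqrt(s)

    # Weiss (1974) CO2 solubility, mol/kg-SW/atm.
    ln_k0 = (
        93.4517 * (100.0 / t_k)
        - 60.2409
        + 23.3585 * math.log(t_k / 100.0)
        + s * (0.023517 - 0.023656 * (t_k / 100.0) + 0.0047036 * (t_k / 100.0) ** 2)
    )
    k0 = math.exp(ln_k0)

    # Mehrbach refit by Dickson & Millero (1987), seawater scale.
    pk1 = 3670.7 / t_k - 62.008 + 9.7944 * ln_tk - 0.0118 * s + 0.000116 * s * s
    pk2 = 1394.7 / t_k + 4.777 - 0.0184 * s + 0.000118 * s * s
    k1_sws = 10.0 ** -pk1
    k2_sws = 10.0 ** -pk2

    ion_s = 19.924 * s / (1000.0 - 1.005 * s)

    # Dickson (1990) bisulfate, free scale, mol/kg-H2O -> mol/kg-SW.
    ln_ks = (
        -4276.1 / t_k
        + 141.328
        - 23.093 * ln_tk
        + (-13856.0 / t_k + 324.57 - 47.986 * ln_tk) * math.sqrt(ion_s)
        + (35474.0 / t_k - 771.54 + 114.723 * ln_tk) * ion_s
        - 2698.0 / t_k * ion_s ** 1.5
        + 1776.0 / t_k * ion_s ** 2
    )
    ks = math.exp(ln_ks) * (1.0 - 0.001005 * s)

    # Dickson & Riley (1979) hydrogen fluoride, free scale.
    ln_kf = 1590.2 / t_k - 12.641 + 1.525 * math.sqrt(ion_s)
    kf = math.exp(ln_kf) * (1.0 - 0.001005 * s)

    # Salinity-proportional totals, mol/kg-SW.
    ts = (0.14 / 96.062) * (s / 1.80655)
    tf = (0.000067 / 18.998) * (s / 1.80655)
    tb = (0.000232 / 10.811) * (s / 1.80655)  # Uppström 1974

    sws_to_tot = (1.0 + ts / ks) / (1.0 + ts / ks + tf / kf)

    # Dickson (1990) boric acid, total scale -> seawater scale.
    ln_kb_tot = (
        (-8966.9 - 2890.53 * sqrt_s - 77.942 * s + 1.728 * s ** 1.5 - 0.0996 * s * s)
        / t_k
        + 148.0248
        + 137.1942 * sqrt_s
        + 1.62142 * s
        + (-24.4344 - 25.085 * sqrt_s - 0.2474 * s) * ln_tk
        + 0.053105 * sqrt_s * t_k
    )
    kb_sws = math.exp(ln_kb_tot) / sws_to_tot

    # Millero (1995) water dissociation, seawater scale.
    ln_kw = (
        148.9802
        - 13847.26 / t_k
        - 23.6521 * ln_tk
        + (118.67 / t_k - 5.977 + 1.0495 * ln_tk) * sqrt_s
        - 0.01615 * s
    )
    kw_sws = math.exp(ln_kw)

    # Takahashi et al. (1982) GEOSECS activity coefficient for the NBS scale.
    fh = 1.2948 - 0.002036 * t_k + (0.0004607 - 0.000001475 * t_k) * s * s

    return ConstantsSet(
        k0=k0,
        k1=k1_sws * fh,
        k2=k2_sws * fh,
        kb=kb_sws * fh,
        kw=kw_sws * fh,
        ks=ks,
        kf=kf,
        total_boron=tb * 1e6,
        total_sulfate=ts * 1e6,
        total_fluoride=tf * 1e6,
        fh=fh,
    )


def convert_ph_scale(ph_nbs: float, constants: ConstantsSet) -> float:
    """Seawater-scale hydrogen-ion concentration (mol/kg) from NBS pH.

    The NBS electrode reports hydrogen-ion *activity* a_H = 10^-pH_NBS; the
    seawater-scale concentration is a_H / fH.  With fH = 1 the scales
    coincide.  ``convert_ph_scale_inverse`` restores the NBS pH to 1e-10.
    """
    if constants.fh is None or not constants.fh > 0:
        raise CarbonateDomainError("constants set carries no valid fH")
    return 10.0 ** -ph_nbs / constants.fh


def convert_ph_scale_inverse(h_sws: float, constants: ConstantsSet) -> float:
    """NBS pH from a seawater-scale hydrogen-ion concentration (mol/kg)."""
    if constants.fh is None or not constants.fh > 0:
        raise CarbonateDomainError("constants set carries no valid fH")
    return -math.log10(h_sws * constants.fh)


def _fugacity_factor(temperature: float) -> float:
    """Weiss (1974) fugacity/partial-pressure ratio at 1 atm total pressure."""
    t_k = temperature + 273.15
    rt = 83.14472 * t_k  # cm3 bar mol-1
    b = -1636.75 + 12.0408 * t_k - 0.0327957 * t_k ** 2 + 3.16528e-5 * t_k ** 3
    delta = 57.7 - 0.118 * t_k
    return math.exp((b + 2.0 * delta) * 1.01325 / rt)


def solve_from_ph_ta(
    sample: SeawaterSample, apply_fugacity: bool = False
) -> CarbonateResult:
    """Solve the CO2 system from the (pH_NBS, TA) pair.

    Inverts the alkalinity balance

        TA = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]free
             - [HSO4-] - [HF]

    in closed form for DIC at the measured hydrogen-ion activity, then
    returns pCO2 = [CO2*]/K0 in µatm.  Deterministic.
    """
    c = compute_constants(sample.temperature, sample.salinity)
    ta = sample.total_alkalinity * 1e-6  # mol/kg
    tb = c.total_boron * 1e-6
    ts = c.total_sulfate * 1e-6
    tf = c.total_fluoride * 1e-6

    h = 10.0 ** -sample.ph_nbs  # NBS activity; k1/k2/kb/kw are on this scale
    h_sws = convert_ph_scale(sample.ph_nbs, c)
    h_free = h_sws / (1.0 + ts / c.ks + tf / c.kf)

    borate = tb * c.kb / (c.kb + h)
    oh = c.kw / h
    hso4 = ts / (1.0 + c.ks / h_free)
    hf = tf / (1.0 + c.kf / h_free)

    carb_alk = ta - borate - oh + h_free + hso4 + hf
    if carb_alk <= 0:
        raise CarbonateDomainError(
            f"implied carbonate alkalinity {carb_alk * 1e6:.1f} µmol/kg <= 0 "
            f"for pH_NBS={sample.ph_nbs}, TA={sample.total_alkalinity}"
        )

    denom = h * h + c.k1 * h + c.k1 * c.k2
    dic = carb_alk * denom / (c.k1 * (h + 2.0 * c.k2))
    co2_star = dic * h * h / denom
    bicarbonate = dic * c.k1 * h / denom
    carbonate = dic * c.k1 * c.k2 / denom

    pco2_atm = co2_star / c.k0
    if apply_fugacity:
        pco2_atm /= _fugacity_factor(sample.temperature)

    return CarbonateResult(
        pco2=pco2_atm * 1e6,
        dic=dic * 1e6,
        co2_star=co2_star * 1e6,
        bicarbonate=bicarbonate * 1e6,
        carbonate=carbonate * 1e6,
        constants_used=c,
    )


def solve_ph_from_dic_ta(
    dic_umol: float,
    total_alkalinity: float,
    temperature: float,
    salinity: float,
    tol: float = 1e-12,
) -> float:
    """Forward solve: NBS pH from (DIC, TA) by bounded root-finding on [H+].

    Used for round-trip validation of :func:`solve_from_ph_ta`.  The root is
    bracketed on pH_NBS in [4, 10] and polished to ``tol`` relative on the
    alkalinity residual.
    """
    from scipy.optimize import brentq

    c = compute_constants(temperature, salinity)
    dic = dic_umol * 1e-6
    ta = total_alkalinity * 1e-6
    tb = c.total_boron * 1e-6
    ts = c.total_sulfate * 1e-6
    tf = c.total_fluoride * 1e-6

    def residual(ph_nbs: float) -> float:
        h = 10.0 ** -ph_nbs
        h_sws = h / c.fh
        h_free = h_sws / (1.0 + ts / c.ks + tf / c.kf)
        denom = h * h + c.k1 * h + c.k1 * c.k2
        calk = dic * c.k1 * (h + 2.0 * c.k2) / denom
        borate = tb * c.kb / (c.kb + h)
        oh = c.kw / h
        hso4 = ts / (1.0 + c.ks / h_free)
        hf = tf / (1.0 + c.kf / h_free)
        return calk + borate + oh - h_free - hso4 - hf - ta

    try:
        return brentq(residual, 4.0, 10.0, xtol=1e-12, rtol=8.9e-16)
    except ValueError as exc:  # pragma: no cover - diagnostic path
        raise CarbonateConvergenceError(
            f"pH root not bracketed in [4, 10] for DIC={dic_umol}, "
            f"TA={total_alkalinity}: {exc}"
        ) from exc


def solve_batch(df, apply_fugacity: bool = False):
    """Solve a batch table (columns temperature_c, salinity_psu, ph_nbs,
    ta_umol_kg) and return a copy with pCO2 and companion columns appended.
    """
    import pandas as pd

    required = ["temperature_c", "salinity_psu", "ph_nbs", "ta_umol_kg"]
    missing = [col for col in required if col not in df.columns]
    if missing:
        raise CarbonateDomainError(f"batch table missing columns: {missing}")

    out = df.copy()
    results = [
        solve_from_ph_ta(
            SeawaterSample(
                temperature=row.temperature_c,
                salinity=row.salinity_psu,
                ph_nbs=row.ph_nbs,
                total_alkalinity=row.ta_umol_kg,
            ),
            apply_fugacity=apply_fugacity,
        )
        for row in df.itertuples()
    ]
    out["pco2_uatm"] = [r.pco2 for r in results]
    out["dic_umol_kg"] = [r.dic for r in results]
    out["co2_star_umol_kg"] = [r.co2_star for r in results]
    out["hco3_umol_kg"] = [r.bicarbonate for r in results]
    out["co3_umol_kg"] = [r.carbonate for r in results]
    out["constants"] = "; ".join(
        f"{k}={v}" for k, v in results[0].constants_used.provenance
    ) if results else ""
    return pd.DataFrame(out)
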
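"""Independent reference solve of the CO2 system for cross-checking.

Deliberately takes a different route from the library: instead of the
closed-form DIC inversion, it solves numerically for the DIC at which the
speciated alkalinity reproduces the measured TA, then reads pCO2 off the
speciation.  Shares only the constant set (the same formulations are under
test in both paths, anchored separately by hand-computed check values).
"""

from scipy.optimize import brentq

from shoalresp.carbonate import ConstantsSet, compute_constants


def alkalinity_from_dic_ph(dic: float, h_nbs: float, c: ConstantsSet) -> float:
    """Total alkalinity (mol/kg) implied by (DIC, H+) speciation."""
    tb = c.total_boron * 1e-6
    ts = c.total_sulfate * 1e-6
    tf = c.total_fluoride * 1e-6
    h_sws = h_nbs / c.fh
    h_free = h_sws / (1.0 + ts / c.ks + tf / c.kf)
    denom = h_nbs ** 2 + c.k1 * h_nbs + c.k1 * c.k2
    hco3 = dic * c.k1 * h_nbs / denom
    co3 = dic * c.k1 * c.k2 / denom
    borate = tb * c.kb / (c.kb + h_nbs)
    oh = c.kw / h_nbs
    hso4 = ts / (1.0 + c.ks / h_free)
    hf = tf / (1.0 + c.kf / h_free)
    return hco3 + 2.0 * co3 + borate + oh - h_free - hso4 - hf


def reference_pco2(
    temperature: float, salinity: float, ph_nbs: float, ta_umol: float
) -> float:
    """pCO2 (µatm) by numerical DIC search at fixed pH."""
    c = compute_constants(temperature, salinity)
    ta = ta_umol * 1e-6
    h = 10.0 ** -ph_nbs

    def residual(dic: float) -> float:
        return alkalinity_from_dic_ph(dic, h, c) - ta

    dic = brentq(residual, 1e-9, 0.02, xtol=1e-18, rtol=8.9e-16)
    denom = h ** 2 + c.k1 * h + c.k1 * c.k2
    co2_star = dic * h ** 2 / denom
    return co2_star / c.k0 * 1e6
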
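"""Equilibrium constants of the seawater carbonate system.

All acid-dissociation constants are returned on the **total** hydrogen-ion
scale in mol kg-sw⁻¹ (K0 in mol kg⁻¹ atm⁻¹, Ksp in mol² kg⁻²), evaluated at
surface pressure. The carbonic-acid pair uses the Lueker, Mitchell & Dickson
(2000) refit of Mehrbach's data; the remaining constants follow the default
formulations of the standard CO2-system calculation packages:

* K0   — Weiss (1974) CO2 solubility.
* K1,K2 — Lueker et al. (2000), total scale.
* KB   — Dickson (1990b) boric acid, total scale.
* Kw   — Millero (1995) water, converted from the seawater scale.
* KSi  — Millero (1995) silicic acid, converted from the seawater scale.
* KP1–KP3 — Yao & Millero (1995) phosphoric acid, converted likewise.
* KS   — Dickson (1990a) bisulfate, free scale (used for scale conversions).
* KF   — Perez & Fraga (1987) hydrogen fluoride, total scale.
* Ksp_arag — Mucci (1983) aragonite solubility.

Total borate follows Uppström (1974), total sulfate Morris & Riley (1966),
total fluoride Riley (1965) and calcium Riley & Tongudai (1967), each scaled
linearly with salinity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

__all__ = ["ConstantSet", "equilibrium_constants"]

# validity envelope of the Lueker et al. (2000) refit
_T_RANGE = (0.0, 40.0)
_S_RANGE = (5.0, 45.0)


@dataclass(frozen=True)
class ConstantSet:
    """Thermodynamic constants at one (temperature, salinity).

    Concentration-like totals (``BT``, ``TS``, ``TF``, ``Ca``) are in
    mol kg⁻¹; dissociation constants are on the total pH scale except ``KS``
    (free scale, by convention, since it defines the scale conversion).
    """

    temperature: float  # °C
    salinity: float  # practical
    K0: float  # mol kg-1 atm-1
    K1: float
    K2: float
    KB: float
    Kw: float
    KSi: float
    KP1: float
    KP2: float
    KP3: float
    KS: float  # free scale
    KF: float
    Ksp_arag: float  # mol^2 kg^-2
    BT: float  # total borate, mol kg-1
    TS: float  # total sulfate, mol kg-1
    TF: float  # total fluoride, mol kg-1
    Ca: float  # calcium, mol kg-1

    def free_to_total(self) -> float:
        """Multiplier converting free-scale [H+] to total-scale [H+]."""
        return 1.0 + self.TS / self.KS

    def sws_to_total(self) -> float:
        """Multiplier converting seawater-scale [H+] to total-scale [H+]."""
        kf_free = self.KF / self.free_to_total()
        return (1.0 + self.TS / self.KS) / (
            1.0 + self.TS / self.KS + self.TF / kf_free
        )

    def as_dict(self) -> dict:
        return asdict(self)


def equilibrium_constants(temperature: float, salinity: float) -> ConstantSet:
    """Evaluate the full constant set at ``temperature`` (°C) and ``salinity``.

    Deterministic: identical inputs give bit-identical outputs. Inputs outside
    the Lueker validity envelope (0–40 °C, S 5–45) raise a warning, not an
    error; non-finite inputs raise ``ValueError``.
    """
    if not (math.isfinite(temperature) and math.isfinite(salinity)):
        raise ValueError(
            f"non-finite inputs: temperature={temperature}, salinity={salinity}"
        )
    if not (_T_RANGE[0] <= temperature <= _T_RANGE[1]) or not (
        _S_RANGE[0] <= salinity <= _S_RANGE[1] or salinity == 0.0
    ):
        warnings.warn(
            f"(T={temperature} °C, S={salinity}) outside the constants' "
            f"validity envelope T∈{_T_RANGE}, S∈{_S_RANGE}",
            stacklevel=2,
        )

    T = temperature + 273.15
    S = salinity
    lnT = math.log(T)
    sqS = math.sqrt(S)

    # --- salinity-proportional totals (mol kg-1) ---
    BT = 0.000232 / 10.811 * S / 1.80655  # Uppström 1974
    TS = 0.14 / 96.062 * S / 1.80655  # Morris & Riley 1966
    TF = 0.000067 / 18.998 * S / 1.80655  # Riley 1965
    Ca = 0.02128 / 40.087 * S / 1.80655  # Riley & Tongudai 1967

    IonS = 19.924 * S / (1000.0 - 1.005 * S)

    # --- K0, Weiss 1974 ---
    lnK0 = (
        -60.2409
        + 93.4517 * (100.0 / T)
        + 23.3585 * math.log(T / 100.0)
        + S * (0.023517 - 0.023656 * (T / 100.0) + 0.0047036 * (T / 100.0) ** 2)
    )
    K0 = math.exp(lnK0)

    # --- K1, K2, Lueker et al. 2000 (total scale) ---
    pK1 = 3633.86 / T - 61.2172 + 9.6777 * lnT - 0.011555 * S + 0.0001152 * S * S
    pK2 = 471.78 / T + 25.929 - 3.16967 * lnT - 0.01781 * S + 0.0001122 * S * S
    K1 = 10.0 ** (-pK1)
    K2 = 10.0 ** (-pK2)

    # --- KB, Dickson 1990b (total scale) ---
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S * sqS - 0.0996 * S * S) / T
        + 148.0248
        + 137.1942 * sqS
        + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnT
        + 0.053105 * sqS * T
    )
    KB = math.exp(lnKB)

    # --- KS, Dickson 1990a (free scale) ---
    lnKS = (
        -4276.1 / T
        + 141.328
        - 23.093 * lnT
        + (-13856.0 / T + 324.57 - 47.986 * lnT) * math.sqrt(IonS)
        + (35474.0 / T - 771.54 + 114.723 * lnT) * IonS
        - 2698.0 / T * IonS**1.5
        + 1776.0 / T * IonS * IonS
        + math.log(1.0 - 0.001005 * S)
    )
    KS = math.exp(lnKS)

    # --- KF, Perez & Fraga 1987 (total scale) ---
    KF = math.exp(874.0 / T - 9.68 + 0.111 * sqS)

    # seawater -> total scale factor (fluoride term needs free-scale KF)
    free_to_tot = 1.0 + TS / KS
    kf_free = KF / free_to_tot
    sws_to_tot = free_to_tot / (free_to_tot + (TF / kf_free if TF > 0 else 0.0))

    # --- Kw, Millero 1995 (seawater scale -> total) ---
    lnKw = (
        148.9802
        - 13847.26 / T
        - 23.6521 * lnT
        + (118.67 / T - 5.977 + 1.0495 * lnT) * sqS
        - 0.01615 * S
    )
    Kw = math.exp(lnKw) * sws_to_tot

    # --- KSi, Millero 1995 (seawater scale -> total) ---
    if S > 0:
        lnKSi = (
            -8904.2 / T
            + 117.385
            - 19.334 * lnT
            + (-458.79 / T + 3.5913) * math.sqrt(IonS)
            + (188.74 / T - 1.5998) * IonS
            + (-12.1652 / T + 0.07871) * IonS * IonS
            + math.log(1.0 - 0.001005 * S)
        )
        KSi = math.exp(lnKSi) * sws_to_tot
    else:  # freshwater limit: ionic-strength expansion degenerates
        KSi = 10.0**-9.84

    # --- KP1..KP3, Yao & Millero 1995 (seawater scale -> total) ---
    lnKP1 = (
        -4576.752 / T
        + 115.525
        - 18.453 * lnT
        + (-106.736 / T + 0.69171) * sqS
        + (-0.65643 / T - 0.01844) * S
    )
    lnKP2 = (
        -8814.715 / T
        + 172.0883
        - 27.927 * lnT
        + (-160.340 / T + 1.3566) * sqS
        + (0.37335 / T - 0.05778) * S
    )
    lnKP3 = (
        -3070.75 / T
        - 18.141
        + (17.27039 / T + 2.81197) * sqS
        + (-44.99486 / T - 0.09984) * S
    )
    KP1 = math.exp(lnKP1) * sws_to_tot
    KP2 = math.exp(lnKP2) * sws_to_tot
    KP3 = math.exp(lnKP3) * sws_to_tot

    # --- aragonite Ksp, Mucci 1983 ---
    log10Ksp = (
        -171.945
        - 0.077993 * T
        + 2903.293 / T
        + 71.595 * math.log10(T)
        + (-0.068393 + 0.0017276 * T + 88.135 / T) * sqS
        - 0.10018 * S
        + 0.0059415 * S * sqS
    )
    Ksp_arag = 10.0**log10Ksp

    return ConstantSet(
        temperature=temperature,
        salinity=salinity,
        K0=K0,
        K1=K1,
        K2=K2,
        KB=KB,
        Kw=Kw,
        KSi=KSi,
        KP1=KP1,
        KP2=KP2,
        KP3=KP3,
        KS=KS,
        KF=KF,
        Ksp_arag=Ksp_arag,
        BT=BT,
        TS=TS,
        TF=TF,
        Ca=Ca,
    )
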
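"""Independent reference speciation for cross-checking the package solver.

A deliberately separate implementation of the same published constant
formulations (Weiss 1974 K0; Lueker 2000 K1/K2; Dickson 1990 KB/KS;
Millero 1995 Kw/KSi; Yao & Millero 1995 phosphoric acid; Perez & Fraga
1987 KF; Mucci 1983 aragonite), written term by term from the source
expressions with its own structure and a naive bisection pH solver, so a
transcription or algebra error in the package would not be reproduced
here. Used only by tests.
"""

import numpy as np


def oracle_constants(t_c, s):
    """Return a dict of constants (total scale) at t_c °C, salinity s."""
    tk = t_c + 273.15
    # totals, mol/kg
    tb = 0.000232 / 10.811 * (s / 1.80655)
    ts = 0.14 / 96.062 * (s / 1.80655)
    tf = 0.000067 / 18.998 * (s / 1.80655)
    ca = 0.02128 / 40.087 * (s / 1.80655)
    ion = 19.924 * s / (1000.0 - 1.005 * s)

    k0 = np.exp(-60.2409 + 9345.17 / tk + 23.3585 * np.log(tk / 100.0)
                + s * (0.023517 - 2.3656e-4 * tk + 4.7036e-7 * tk * tk))
    k1 = 10.0 ** -(3633.86 / tk - 61.2172 + 9.6777 * np.log(tk)
                   - 0.011555 * s + 1.152e-4 * s ** 2)
    k2 = 10.0 ** -(471.78 / tk + 25.929 - 3.16967 * np.log(tk)
                   - 0.01781 * s + 1.122e-4 * s ** 2)
    kb = np.exp((-8966.90 - 2890.53 * s ** 0.5 - 77.942 * s
                 + 1.728 * s ** 1.5 - 0.0996 * s ** 2) / tk
                + 148.0248 + 137.1942 * s ** 0.5 + 1.62142 * s
                - (24.4344 + 25.085 * s ** 0.5 + 0.2474 * s) * np.log(tk)
                + 0.053105 * s ** 0.5 * tk)
    ks = np.exp(-4276.1 / tk + 141.328 - 23.093 * np.log(tk)
                + (-13856.0 / tk + 324.57 - 47.986 * np.log(tk)) * ion ** 0.5
                + (35474.0 / tk - 771.54 + 114.723 * np.log(tk)) * ion
                - (2698.0 / tk) * ion ** 1.5 + (1776.0 / tk) * ion ** 2
                + np.log(1.0 - 0.001005 * s))
    kf = np.exp(874.0 / tk - 9.68 + 0.111 * s ** 0.5)  # total scale
    # seawater-scale -> total-scale factor
    kf_free = kf / (1.0 + ts / ks)
    sws2tot = (1.0 + ts / ks) / (1.0 + ts / ks + tf / kf_free)
    kw = np.exp(148.9802 - 13847.26 / tk - 23.6521 * np.log(tk)
                + (118.67 / tk - 5.977 + 1.0495 * np.log(tk)) * s ** 0.5
                - 0.01615 * s) * sws2tot
    ksi = np.exp(-8904.2 / tk + 117.385 - 19.334 * np.log(tk)
                 + (-458.79 / tk + 3.5913) * ion ** 0.5
                 + (188.74 / tk - 1.5998) * ion
                 + (-12.1652 / tk + 0.07871) * ion ** 2
                 + np.log(1.0 - 0.001005 * s)) * sws2tot
    kp1 = np.exp(-4576.752 / tk + 115.525 - 18.453 * np.log(tk)
                 + (-106.736 / tk + 0.69171) * s ** 0.5
                 + (-0.65643 / tk - 0.01844) * s) * sws2tot
    kp2 = np.exp(-8814.715 / tk + 172.0883 - 27.927 * np.log(tk)
                 + (-160.340 / tk + 1.3566) * s ** 0.5
                 + (0.37335 / tk - 0.05778) * s) * sws2tot
    kp3 = np.exp(-3070.75 / tk - 18.141
                 + (17.27039 / tk + 2.81197) * s ** 0.5
                 + (-44.99486 / tk - 0.09984) * s) * sws2tot
    ksp = 10.0 ** (-171.945 - 0.077993 * tk + 2903.293 / tk
                   + 71.595 * np.log10(tk)
                   + (-0.068393 + 0.0017276 * tk + 88.135 / tk) * s ** 0.5
                   - 0.10018 * s + 0.0059415 * s ** 1.5)
    return dict(k0=k0, k1=k1, k2=k2, kb=kb, kw=kw, ksi=ksi, kp1=kp1, kp2=kp2,
                kp3=kp3, ks=ks, kf=kf, ksp=ksp, tb=tb, ts=ts, tf=tf, ca=ca)


def oracle_ta(h, dic, k, tsi=0.0, tp=0.0):
    """Total alkalinity (mol/kg) from total-scale [H+] and DIC (mol/kg)."""
    d = h * h + k["k1"] * h + k["k1"] * k["k2"]
    hco3 = dic * k["k1"] * h / d
    co3 = dic * k["k1"] * k["k2"] / d
    boh4 = k["tb"] / (1.0 + h / k["kb"])
    oh = k["kw"] / h
    hfree = h / (1.0 + k["ts"] / k["ks"])
    hso4 = k["ts"] * hfree / (k["ks"] + hfree)
    hf = k["tf"] * h / (k["kf"] + h)
    sioh3 = tsi / (1.0 + h / k["ksi"])
    dp = (h ** 3 + k["kp1"] * h ** 2 + k["kp1"] * k["kp2"] * h
          + k["kp1"] * k["kp2"] * k["kp3"])
    palk = tp * (k["kp1"] * k["kp2"] * h
                 + 2.0 * k["kp1"] * k["kp2"] * k["kp3"] - h ** 3) / dp
    return hco3 + 2.0 * co3 + boh4 + oh + sioh3 + palk - hfree - hso4 - hf


def oracle_ph_from_ta_dic(ta_umol, dic_umol, t_c, s, tsi_umol=0.0,
                          tp_umol=0.0, n_iter=200):
    """pH (total scale) by plain bisection on [2, 12]."""
    k = oracle_constants(t_c, s)
    ta, dic = ta_umol * 1e-6, dic_umol * 1e-6
    tsi, tp = tsi_umol * 1e-6, tp_umol * 1e-6
    lo, hi = 2.0, 12.0

    def f(ph):
        return oracle_ta(10.0 ** (-ph), dic, k, tsi, tp) - ta

    flo = f(lo)
    if flo * f(hi) > 0:
        raise ValueError("no root")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if flo * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
            flo = f(lo)
    return 0.5 * (lo + hi)


def oracle_speciate_ta_dic(ta_umol, dic_umol, t_c, s, tsi_umol=0.0,
                           tp_umol=0.0):
    """Full speciation (μmol/kg and total-scale pH) from TA and DIC."""
    k = oracle_constants(t_c, s)
    ph = oracle_ph_from_ta_dic(ta_umol, dic_umol, t_c, s, tsi_umol, tp_umol)
    h = 10.0 ** (-ph)
    dic = dic_umol * 1e-6
    d = h * h + k["k1"] * h + k["k1"] * k["k2"]
    return {
        "ph": ph,
        "co2": dic * h * h / d * 1e6,
        "hco3": dic * k["k1"] * h / d * 1e6,
        "co3": dic * k["k1"] * k["k2"] / d * 1e6,
        "pco2": dic * h * h / d / k["k0"] * 1e6,
        "omega_arag": k["ca"] * (dic * k["k1"] * k["k2"] / d) / k["ksp"],
    }
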
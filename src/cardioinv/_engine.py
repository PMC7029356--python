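"""Compiled numerical core of the base model.

Everything here operates on flat float64 vectors (parameter layout from
:data:`cardioinv.parameters.PARAM_INDEX`, state layout from
:data:`cardioinv.parameters.STATE_INDEX`) and is compiled with numba.

Numerical scheme: fixed-step hybrid integrator.  Hodgkin-Huxley gates, the
RyR availability, and every free/buffered Ca2+ concentration are updated
with exponential (Rush-Larsen style) steps, which are unconditionally
stable for their locally linear dynamics; the membrane potential uses
forward Euler.  Purely voltage-dependent factors are tabulated per run on a
0.1 mV grid.  The step size is chosen by the caller (default 0.02 ms) and
the scheme is bit-deterministic.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .parameters import PARAM_INDEX as _PI, STATE_INDEX as _SI

# physical constants
F = 96485.33212  # C/mol
R = 8314.462618  # mJ/(mol K)
T = 310.0        # K
RTF = R * T / F  # mV

# parameter indices (compile-time constants)
IP_G_NA = _PI["g_Na"]; IP_G_NAL = _PI["g_NaL"]; IP_G_CAL = _PI["g_CaL"]
IP_G_TO = _PI["g_to"]; IP_G_KR = _PI["g_Kr"]; IP_G_KS = _PI["g_Ks"]
IP_G_K1 = _PI["g_K1"]; IP_G_NAK = _PI["g_NaK"]; IP_G_NACA = _PI["g_NaCa"]
IP_G_PCA = _PI["g_pCa"]; IP_G_BCA = _PI["g_bCa"]; IP_G_BCL = _PI["g_bCl"]
IP_G_F = _PI["g_f"]
IP_A_RYR = _PI["alpha_RyR"]; IP_B_RYR = _PI["beta_RyR"]; IP_C_RYR = _PI["gamma_RyR"]
IP_E_RYR = _PI["eta_RyR"]; IP_K_RYR = _PI["kappa_RyR"]
IP_G_SERCA = _PI["g_SERCA"]; IP_K_SERCA = _PI["K_SERCA"]
IP_BT_D = _PI["B_tot_d"]; IP_KON_D = _PI["k_on_d"]; IP_KOFF_D = _PI["k_off_d"]
IP_BT_SL = _PI["B_tot_sl"]; IP_KON_SL = _PI["k_on_sl"]; IP_KOFF_SL = _PI["k_off_sl"]
IP_BT_C = _PI["B_tot_c"]; IP_KON_C = _PI["k_on_c"]; IP_KOFF_C = _PI["k_off_c"]
IP_BT_S = _PI["B_tot_s"]; IP_KON_S = _PI["k_on_s"]; IP_KOFF_S = _PI["k_off_s"]
IP_K_DC = _PI["k_dc"]; IP_K_SLC = _PI["k_slc"]; IP_K_NS = _PI["k_ns"]
IP_V_CELL = _PI["V_cell"]
IP_FR_D = _PI["frac_d"]; IP_FR_SL = _PI["frac_sl"]; IP_FR_C = _PI["frac_c"]
IP_FR_S = _PI["frac_s"]; IP_FR_N = _PI["frac_n"]
IP_CHI = _PI["chi"]; IP_CM = _PI["C_m"]
IP_NAI = _PI["Na_i"]; IP_NAO = _PI["Na_o"]; IP_KI = _PI["K_i"]; IP_KO = _PI["K_o"]
IP_CAO = _PI["Ca_o"]; IP_ECL = _PI["E_Cl"]; IP_EF = _PI["E_f"]

# state indices
IS_V = _SI["v"]
IS_M = _SI["m"]; IS_H = _SI["h"]; IS_J = _SI["j"]
IS_ML = _SI["mL"]; IS_HL = _SI["hL"]
IS_D = _SI["d"]; IS_F = _SI["f_gate"]
IS_RTO = _SI["r_to"]; IS_STO = _SI["s_to"]
IS_XR1 = _SI["xr1"]; IS_XR2 = _SI["xr2"]; IS_XS = _SI["xs"]; IS_XF = _SI["xf"]
IS_CD = _SI["c_d"]; IS_BD = _SI["b_d"]
IS_CSL = _SI["c_sl"]; IS_BSL = _SI["b_sl"]
IS_CC = _SI["c_c"]; IS_BC = _SI["b_c"]
IS_CS = _SI["c_s"]; IS_BS = _SI["b_s"]
IS_CN = _SI["c_n"]
IS_R = _SI["r"]

N_CUR = 14   # 13 membrane currents + stimulus
N_FLX = 14   # flux columns, see parameters.FLUX_NAMES


@njit(cache=True)
def ghk_ca(v, c_i, c_o):
    """GHK driving term for a divalent cation (per unit permeability)."""
    w = 2.0 * v / RTF
    if abs(w) < 1e-4:
        return 2.0 * F * (c_i - 0.341 * c_o)
    ew = math.exp(w)
    return 2.0 * F * w * (c_i * ew - 0.341 * c_o) / (ew - 1.0)


@njit(cache=True)
def calc_currents(y, p, cur):
    """Fill ``cur`` (length 14) with membrane currents in A/F.

    Order matches parameters.CURRENT_NAMES; slot 13 (stimulus) is left as-is.
    """
    v = y[IS_V]
    na_i = p[IP_NAI]; na_o = p[IP_NAO]
    k_i = p[IP_KI]; k_o = p[IP_KO]; ca_o = p[IP_CAO]
    c_sl = y[IS_CSL]
    if c_sl < 1e-8:
        c_sl = 1e-8

    e_na = RTF * math.log(na_o / na_i)
    e_k = RTF * math.log(k_o / k_i)
    e_ks = RTF * math.log((k_o + 0.03 * na_o) / (k_i + 0.03 * na_i))
    e_ca = 0.5 * RTF * math.log(ca_o / c_sl)

    # fast and late Na+
    cur[0] = p[IP_G_NA] * y[IS_M] ** 3 * y[IS_H] * y[IS_J] * (v - e_na)
    cur[1] = p[IP_G_NAL] * y[IS_ML] * y[IS_HL] * (v - e_na)
    # L-type Ca2+ (GHK driving term, Ca-dependent inactivation via dyadic Ca)
    f_ca = 1.0 / (1.0 + (y[IS_CD] / 0.012) ** 2)
    cur[2] = p[IP_G_CAL] * y[IS_D] * y[IS_F] * f_ca * ghk_ca(v, y[IS_CD], ca_o)
    # transient outward K+
    cur[3] = p[IP_G_TO] * y[IS_RTO] * y[IS_STO] * (v - e_k)
    # rapid delayed rectifier
    cur[4] = p[IP_G_KR] * math.sqrt(k_o / 5.4) * y[IS_XR1] * y[IS_XR2] * (v - e_k)
    # slow delayed rectifier
    cur[5] = p[IP_G_KS] * y[IS_XS] ** 2 * (v - e_ks)
    # inward rectifier (instantaneous rectification)
    a_k1 = 0.1 / (1.0 + math.exp(0.06 * (v - e_k - 200.0)))
    b_k1 = (3.0 * math.exp(0.0002 * (v - e_k + 100.0))
            + math.exp(0.1 * (v - e_k - 10.0))) / (1.0 + math.exp(-0.5 * (v - e_k)))
    cur[6] = p[IP_G_K1] * math.sqrt(k_o / 5.4) * a_k1 / (a_k1 + b_k1) * (v - e_k)
    # Na+/K+ pump
    cur[7] = (p[IP_G_NAK] * (k_o / (k_o + 1.0)) * (na_i / (na_i + 40.0))
              / (1.0 + 0.1245 * math.exp(-0.1 * v / RTF)
                 + 0.0353 * math.exp(-v / RTF)))
    # Na+/Ca2+ exchanger (senses subsarcolemmal Ca2+)
    ex1 = math.exp(0.35 * v / RTF)
    ex2 = math.exp(-0.65 * v / RTF)
    cur[8] = (p[IP_G_NACA]
              * (ex1 * na_i ** 3 * ca_o - ex2 * na_o ** 3 * c_sl * 2.5)
              / ((87.5 ** 3 + na_o ** 3) * (1.38 + ca_o) * (1.0 + 0.1 * ex2)))
    # sarcolemmal Ca2+ pump
    cur[9] = p[IP_G_PCA] * c_sl / (c_sl + 0.0005)
    # background currents
    cur[10] = p[IP_G_BCA] * (v - e_ca)
    cur[11] = p[IP_G_BCL] * (v - p[IP_ECL])
    # funny current
    cur[12] = p[IP_G_F] * y[IS_XF] * (v - p[IP_EF])
    return cur


@njit(cache=True, fastmath=True)
def calc_fluxes(y, p, i_cal, i_naca, i_pca, i_bca, flx):
    """Fill ``flx`` (length 14) with Ca2+ fluxes in mmol/ms.

    Column order matches parameters.FLUX_NAMES.
    """
    conv = p[IP_CM] * p[IP_CHI] * p[IP_V_CELL] * 1e3 / (2.0 * F)
    v_cell = p[IP_V_CELL]
    v_d = p[IP_FR_D] * v_cell
    v_sl = p[IP_FR_SL] * v_cell
    v_c = p[IP_FR_C] * v_cell
    v_s = p[IP_FR_S] * v_cell

    c_d = y[IS_CD]; c_sl = y[IS_CSL]; c_c = y[IS_CC]
    c_s = y[IS_CS]; c_n = y[IS_CN]

    j_cal = -i_cal * conv
    j_esl = -(i_bca + i_pca - 2.0 * i_naca) * conv
    j_db = v_d * (p[IP_KON_D] * c_d * (p[IP_BT_D] - y[IS_BD]) - p[IP_KOFF_D] * y[IS_BD])
    j_slb = v_sl * (p[IP_KON_SL] * c_sl * (p[IP_BT_SL] - y[IS_BSL]) - p[IP_KOFF_SL] * y[IS_BSL])
    j_cb = v_c * (p[IP_KON_C] * c_c * (p[IP_BT_C] - y[IS_BC]) - p[IP_KOFF_C] * y[IS_BC])
    j_sb = v_s * (p[IP_KON_S] * c_s * (p[IP_BT_S] - y[IS_BS]) - p[IP_KOFF_S] * y[IS_BS])
    j_dc = p[IP_K_DC] * (c_d - c_c)
    j_slc = p[IP_K_SLC] * (c_sl - c_c)
    j_ns = p[IP_K_NS] * (c_n - c_s)
    # RyR release: open probability x availability, leak always open
    cd3 = c_d ** 3
    p_o = cd3 / (cd3 + p[IP_K_RYR] ** 3)
    grad = c_s - c_sl
    j_ryr = p_o * y[IS_R] * p[IP_A_RYR] * grad
    j_leak = p[IP_C_RYR] * p[IP_A_RYR] * grad
    # SERCA (forward-only Hill pump)
    j_cn = p[IP_G_SERCA] * c_c ** 2 / (c_c ** 2 + p[IP_K_SERCA] ** 2)

    flx[0] = j_cal
    flx[1] = j_db
    flx[2] = j_dc
    flx[3] = j_esl
    flx[4] = j_slc
    flx[5] = j_slb
    flx[6] = j_ryr + j_leak
    flx[7] = j_ryr
    flx[8] = j_leak
    flx[9] = j_cn
    flx[10] = j_cb
    flx[11] = j_ns
    flx[12] = j_sb
    flx[13] = j_cn  # J_SERCA alias
    return flx


@njit(cache=True)
def ryr_open_probability(c_d, kappa):
    cd3 = c_d ** 3
    return cd3 / (cd3 + kappa ** 3)


@njit(cache=True)
def _rl(x, x_inf, tau, dt):
    return x_inf + (x - x_inf) * math.exp(-dt / tau)


@njit(cache=True, fastmath=True)
def _expstep(x, a, b, dt):
    """Exact step of dx/dt = a - b*x over dt (falls back to Euler as b->0)."""
    if abs(b) * dt < 1e-9:
        return x + dt * (a - b * x)
    z = b * dt
    if -0.02 < z < 0.02:
        # cubic expansion of exp(-z); relative error < 1e-8 on this range
        decay = 1.0 - z * (1.0 - 0.5 * z * (1.0 - z / 3.0))
    else:
        decay = math.exp(-z)
    x_inf = a / b
    return x_inf + (x - x_inf) * decay


@njit(cache=True)
def gate_rates(v, ginf, gtau):
    """Steady states and time constants of the 13 HH gates at voltage ``v``.

    Order: m, h, j, mL, hL, d, f, r_to, s_to, xr1, xr2, xs, xf (state
    indices 1..13).
    """
    # I_Na gates
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    b_m = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    tau_m = a_m * b_m
    h_inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v < -40.0:
        a_h = 0.057 * math.exp(-(v + 80.0) / 6.8)
        b_h = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
        a_j = ((-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
               * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23))))
        b_j = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    else:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    tau_h = 1.0 / (a_h + b_h)
    tau_j = 1.0 / (a_j + b_j)
    ginf[0] = m_inf; gtau[0] = tau_m
    ginf[1] = h_inf; gtau[1] = tau_h
    ginf[2] = h_inf; gtau[2] = tau_j

    # I_NaL gates
    ginf[3] = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264)); gtau[3] = tau_m
    ginf[4] = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488)); gtau[4] = 200.0

    # I_CaL gates
    d_inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 7.5))
    a_d = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    tau_d = a_d * b_d + g_d
    f_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tau_f = 1125.0 * math.exp(-(v + 27.0) ** 2 / 240.0) + 80.0 + 165.0 / (1.0 + math.exp((25.0 - v) / 10.0))
    ginf[5] = d_inf; gtau[5] = tau_d
    ginf[6] = f_inf; gtau[6] = tau_f

    # I_to gates
    ginf[7] = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    gtau[7] = 9.5 * math.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
    ginf[8] = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
    gtau[8] = 85.0 * math.exp(-(v + 45.0) ** 2 / 320.0) + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0)) + 3.0

    # I_Kr gates
    a_xr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    b_xr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    ginf[9] = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0)); gtau[9] = a_xr1 * b_xr1
    a_xr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    b_xr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    ginf[10] = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0)); gtau[10] = a_xr2 * b_xr2

    # I_Ks gate
    a_xs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - v) / 6.0))
    b_xs = 1.0 / (1.0 + math.exp((v - 60.0) / 20.0))
    ginf[11] = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0)); gtau[11] = a_xs * b_xs

    # I_f gate
    ginf[12] = 1.0 / (1.0 + math.exp((v + 77.85) / 5.0))
    gtau[12] = 1900.0 / (1.0 + math.exp((v + 15.0) / 10.0)) + 15.0


@njit(cache=True)
def update_gates(y, dt, ginf, gtau):
    """Rush-Larsen update of all HH gates (in place)."""
    gate_rates(y[IS_V], ginf, gtau)
    for g in range(13):
        y[1 + g] = _rl(y[1 + g], ginf[g], gtau[g], dt)


# -- voltage lookup tables ---------------------------------------------------
# Per-integration tables of every purely voltage-dependent factor: gate
# steady states and per-step decay factors, the GHK driving coefficients,
# and the unit-conductance I_K1, I_NaK and NaCa exchanger terms.  Linear
# interpolation on a 0.1 mV grid; the interpolation error is far below the
# time-discretization error.
V_TAB_MIN = -150.0
V_TAB_MAX = 150.0
N_V_TAB = 3001
DV_TAB = (V_TAB_MAX - V_TAB_MIN) / (N_V_TAB - 1)
N_TAB = 32  # 13 gate_inf, 13 gate_decay, T1, T2, K1u, NaKu, Ancx, Bncx


@njit(cache=True)
def build_tables(p, dt):
    """Voltage tables for one integration run (depend on p and dt)."""
    tab = np.empty((N_V_TAB, N_TAB))
    ginf = np.empty(13)
    gtau = np.empty(13)
    na_i = p[IP_NAI]; na_o = p[IP_NAO]
    k_o = p[IP_KO]; k_i = p[IP_KI]; ca_o = p[IP_CAO]
    e_k = RTF * math.log(k_o / k_i)
    sqrt_ko = math.sqrt(k_o / 5.4)
    ncx_denom0 = (87.5 ** 3 + na_o ** 3) * (1.38 + ca_o)
    for k in range(N_V_TAB):
        v = V_TAB_MIN + k * DV_TAB
        gate_rates(v, ginf, gtau)
        for g in range(13):
            tab[k, g] = ginf[g]
            tab[k, 13 + g] = math.exp(-dt / gtau[g])
        # GHK split: phi(v, c) = c*T1(v) - T2(v)
        w = 2.0 * v / RTF
        if abs(w) < 1e-4:
            t1 = 2.0 * F
            t2 = 2.0 * F * 0.341 * ca_o
        else:
            ew = math.exp(w)
            t1 = 2.0 * F * w * ew / (ew - 1.0)
            t2 = 2.0 * F * w * 0.341 * ca_o / (ew - 1.0)
        tab[k, 26] = t1
        tab[k, 27] = t2
        a_k1 = 0.1 / (1.0 + math.exp(0.06 * (v - e_k - 200.0)))
        b_k1 = (3.0 * math.exp(0.0002 * (v - e_k + 100.0))
                + math.exp(0.1 * (v - e_k - 10.0))) / (1.0 + math.exp(-0.5 * (v - e_k)))
        tab[k, 28] = sqrt_ko * a_k1 / (a_k1 + b_k1) * (v - e_k)
        tab[k, 29] = ((k_o / (k_o + 1.0)) * (na_i / (na_i + 40.0))
                      / (1.0 + 0.1245 * math.exp(-0.1 * v / RTF)
                         + 0.0353 * math.exp(-v / RTF)))
        ex1 = math.exp(0.35 * v / RTF)
        ex2 = math.exp(-0.65 * v / RTF)
        denom = ncx_denom0 * (1.0 + 0.1 * ex2)
        tab[k, 30] = ex1 * na_i ** 3 * ca_o / denom
        tab[k, 31] = ex2 * na_o ** 3 * 2.5 / denom
    return tab


@njit(cache=True, fastmath=True)
def calc_currents_tab(y, p, tab, e_na, e_k, e_ks, cur):
    """Table-based membrane currents (same layout as calc_currents)."""
    v = y[IS_V]
    u = (v - V_TAB_MIN) / DV_TAB
    if u < 0.0:
        u = 0.0
    elif u > N_V_TAB - 1.001:
        u = N_V_TAB - 1.001
    i0 = int(u)
    w = u - i0
    c_sl = y[IS_CSL]
    if c_sl < 1e-8:
        c_sl = 1e-8
    c_d = y[IS_CD]

    t1 = tab[i0, 26] * (1.0 - w) + tab[i0 + 1, 26] * w
    t2 = tab[i0, 27] * (1.0 - w) + tab[i0 + 1, 27] * w
    k1u = tab[i0, 28] * (1.0 - w) + tab[i0 + 1, 28] * w
    naku = tab[i0, 29] * (1.0 - w) + tab[i0 + 1, 29] * w
    ancx = tab[i0, 30] * (1.0 - w) + tab[i0 + 1, 30] * w
    bncx = tab[i0, 31] * (1.0 - w) + tab[i0 + 1, 31] * w

    cur[0] = p[IP_G_NA] * y[IS_M] ** 3 * y[IS_H] * y[IS_J] * (v - e_na)
    cur[1] = p[IP_G_NAL] * y[IS_ML] * y[IS_HL] * (v - e_na)
    f_ca = 1.0 / (1.0 + (c_d / 0.012) ** 2)
    cur[2] = p[IP_G_CAL] * y[IS_D] * y[IS_F] * f_ca * (c_d * t1 - t2)
    cur[3] = p[IP_G_TO] * y[IS_RTO] * y[IS_STO] * (v - e_k)
    cur[4] = p[IP_G_KR] * math.sqrt(p[IP_KO] / 5.4) * y[IS_XR1] * y[IS_XR2] * (v - e_k)
    cur[5] = p[IP_G_KS] * y[IS_XS] ** 2 * (v - e_ks)
    cur[6] = p[IP_G_K1] * k1u
    cur[7] = p[IP_G_NAK] * naku
    cur[8] = p[IP_G_NACA] * (ancx - bncx * c_sl)
    cur[9] = p[IP_G_PCA] * c_sl / (c_sl + 0.0005)
    e_ca = 0.5 * RTF * math.log(p[IP_CAO] / c_sl)
    cur[10] = p[IP_G_BCA] * (v - e_ca)
    cur[11] = p[IP_G_BCL] * (v - p[IP_ECL])
    cur[12] = p[IP_G_F] * y[IS_XF] * (v - p[IP_EF])
    return i0, w


@njit(cache=True, fastmath=True)
def _advance(y, p, dt, flx, i0, w, tab, clamp, dv):
    """Shared post-current part of a step: v, gates, RyR availability and
    all concentration/buffer updates (exponential, Jacobi splitting)."""
    if not clamp:
        y[IS_V] = y[IS_V] + dt * dv
    # gates: Rush-Larsen with tabulated inf/decay (at the pre-step voltage
    # index; consistent operator splitting)
    for g in range(13):
        inf = tab[i0, g] * (1.0 - w) + tab[i0 + 1, g] * w
        dec = tab[i0, 13 + g] * (1.0 - w) + tab[i0 + 1, 13 + g] * w
        y[1 + g] = inf + (y[1 + g] - inf) * dec

    v_cell = p[IP_V_CELL]
    v_d = p[IP_FR_D] * v_cell
    v_sl = p[IP_FR_SL] * v_cell
    v_c = p[IP_FR_C] * v_cell
    v_s = p[IP_FR_S] * v_cell
    v_n = p[IP_FR_N] * v_cell

    # RyR availability: dr/dt = -J_RyR/(V_cell*beta) + eta*p*(1-r), linear in r
    p_o = ryr_open_probability(y[IS_CD], p[IP_K_RYR])
    grad = y[IS_CS] - y[IS_CSL]
    a_r = p[IP_E_RYR] * p_o
    b_r = a_r + p_o * p[IP_A_RYR] * grad / (v_cell * p[IP_B_RYR])
    if abs(b_r) > 1e-14:
        r_inf = a_r / b_r
        y[IS_R] = r_inf + (y[IS_R] - r_inf) * math.exp(-b_r * dt)
    else:
        y[IS_R] = y[IS_R] + dt * a_r
    if y[IS_R] < 0.0:
        y[IS_R] = 0.0
    elif y[IS_R] > 1.0:
        y[IS_R] = 1.0

    # Concentrations: exponential (linearized) updates, all coefficients
    # evaluated from pre-step values (Jacobi splitting).  For each free
    # concentration dc/dt = A - B*c with B collecting buffering on-rate,
    # outgoing diffusion and release conductance; each buffer obeys
    # db/dt = kon*c*Btot - (kon*c + koff)*b, also linear.
    c_d = y[IS_CD]; b_d = y[IS_BD]
    c_sl = y[IS_CSL]; b_sl = y[IS_BSL]
    c_c = y[IS_CC]; b_c = y[IS_BC]
    c_s = y[IS_CS]; b_s = y[IS_BS]
    c_n = y[IS_CN]
    j_cal = flx[0]; j_esl = flx[3]; j_cn = flx[9]
    g_rel = (p_o * y[IS_R] + p[IP_C_RYR]) * p[IP_A_RYR]  # L/ms, release+leak

    a_cd = (j_cal + v_d * p[IP_KOFF_D] * b_d + p[IP_K_DC] * c_c) / v_d
    b_cd = p[IP_KON_D] * (p[IP_BT_D] - b_d) + p[IP_K_DC] / v_d
    a_csl = (j_esl + g_rel * c_s + p[IP_K_SLC] * c_c
             + v_sl * p[IP_KOFF_SL] * b_sl) / v_sl
    b_csl = p[IP_KON_SL] * (p[IP_BT_SL] - b_sl) + (p[IP_K_SLC] + g_rel) / v_sl
    a_cc = (p[IP_K_SLC] * c_sl + p[IP_K_DC] * c_d - j_cn
            + v_c * p[IP_KOFF_C] * b_c) / v_c
    b_cc = p[IP_KON_C] * (p[IP_BT_C] - b_c) + (p[IP_K_SLC] + p[IP_K_DC]) / v_c
    a_cs = (p[IP_K_NS] * c_n + g_rel * c_sl + v_s * p[IP_KOFF_S] * b_s) / v_s
    b_cs = p[IP_KON_S] * (p[IP_BT_S] - b_s) + (p[IP_K_NS] + g_rel) / v_s
    a_cn = (j_cn + p[IP_K_NS] * c_s) / v_n
    b_cn = p[IP_K_NS] / v_n

    y[IS_CD] = _expstep(c_d, a_cd, b_cd, dt)
    y[IS_CSL] = _expstep(c_sl, a_csl, b_csl, dt)
    y[IS_CC] = _expstep(c_c, a_cc, b_cc, dt)
    y[IS_CS] = _expstep(c_s, a_cs, b_cs, dt)
    y[IS_CN] = _expstep(c_n, a_cn, b_cn, dt)
    y[IS_BD] = _expstep(b_d, p[IP_KON_D] * c_d * p[IP_BT_D],
                        p[IP_KON_D] * c_d + p[IP_KOFF_D], dt)
    y[IS_BSL] = _expstep(b_sl, p[IP_KON_SL] * c_sl * p[IP_BT_SL],
                         p[IP_KON_SL] * c_sl + p[IP_KOFF_SL], dt)
    y[IS_BC] = _expstep(b_c, p[IP_KON_C] * c_c * p[IP_BT_C],
                        p[IP_KON_C] * c_c + p[IP_KOFF_C], dt)
    y[IS_BS] = _expstep(b_s, p[IP_KON_S] * c_s * p[IP_BT_S],
                        p[IP_KON_S] * c_s + p[IP_KOFF_S], dt)

    # concentrations cannot go negative
    for idx in (IS_CD, IS_BD, IS_CSL, IS_BSL, IS_CC, IS_BC, IS_CS, IS_BS, IS_CN):
        if y[idx] < 0.0:
            y[idx] = 0.0


@njit(cache=True)
def integrate_kernel(p, y0, n_samples, n_sub, dt, period, stim_amp, stim_dur,
                     clamp, clamp_v, t_out, y_out, cur_out, flx_out):
    """Integrate and sample the model.

    Samples ``n_samples`` points spaced ``n_sub * dt`` apart, starting at
    t = 0 (the initial state).  If ``period > 0`` a square stimulus of
    amplitude ``stim_amp`` (A/F) is applied for ``stim_dur`` ms at the start
    of every period.  In clamp mode the membrane potential is held at
    ``clamp_v`` and the stimulus is disabled.

    Returns 0 on success, 1 if the state became non-finite (the output is
    valid up to the previous sample).
    """
    y = y0.copy()
    if clamp:
        y[IS_V] = clamp_v
    cur = np.empty(N_CUR)
    flx = np.empty(N_FLX)
    tab = build_tables(p, dt)
    e_na = RTF * math.log(p[IP_NAO] / p[IP_NAI])
    e_k = RTF * math.log(p[IP_KO] / p[IP_KI])
    e_ks = RTF * math.log((p[IP_KO] + 0.03 * p[IP_NAO])
                          / (p[IP_KI] + 0.03 * p[IP_NAI]))
    t = 0.0
    for k in range(n_samples):
        # record
        cur[13] = 0.0
        if period > 0.0 and not clamp:
            tmod = t - period * math.floor(t / period)
            if tmod < stim_dur:
                cur[13] = stim_amp
        calc_currents(y, p, cur)
        calc_fluxes(y, p, cur[2], cur[8], cur[9], cur[10], flx)
        t_out[k] = t
        for i in range(y.shape[0]):
            y_out[k, i] = y[i]
        for i in range(N_CUR):
            cur_out[k, i] = cur[i]
        for i in range(N_FLX):
            flx_out[k, i] = flx[i]
        if not math.isfinite(y[IS_V]):
            return 1
        if k == n_samples - 1:
            break
        # advance to next sample
        for s in range(n_sub):
            i_stim = 0.0
            if period > 0.0 and not clamp:
                tmod = t - period * math.floor(t / period)
                if tmod < stim_dur:
                    i_stim = stim_amp
            i0, wfrac = calc_currents_tab(y, p, tab, e_na, e_k, e_ks, cur)
            calc_fluxes(y, p, cur[2], cur[8], cur[9], cur[10], flx)
            dv = 0.0
            for i in range(13):
                dv -= cur[i]
            dv -= i_stim
            _advance(y, p, dt, flx, i0, wfrac, tab, clamp, dv)
            t += dt
        t = (k + 1) * (n_sub * dt)  # avoid drift
    return 0
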
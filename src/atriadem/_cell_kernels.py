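"""Numba kernels for the coupled human-atrial ionic / myofilament cell model.

The electrophysiology is the Courtemanche et al. (1998) human atrial action
potential model: 21 state variables (membrane potential, 15 gating variables,
Na+/K+/Ca2+ concentrations and the two SR Ca2+ compartments).  The mechanics
is the Rice et al. (2008) approximate myofilament model: 11 state variables
(regulatory-unit fractions, crossbridge populations and mean distortions,
sarcomere length and the force integral), rat parameter set with rates at
37 degC.

The two models are coupled two-way through intracellular Ca2+:

* [Ca2+]_i drives Ca binding to troponin in the myofilament model;
* the apparent troponin-bound Ca flux dTropACa/dt replaces the instantaneous
  troponin buffer in the ionic Ca2+ balance, whose buffering factor B2 then
  retains only the calmodulin term.

All cell-level units: mV, ms, pA, pF, mM (ionic side); um and normalised
force (myofilament side, with Ca in uM internally as in the source model).

Everything here is scalar, nopython-compiled, and shared by the single-cell
drivers and the tissue engine.
"""

import math

import numpy as np
from numba import njit

NVAR = 32

# State vector layout (documented ordering, used everywhere incl. snapshots)
IV, IM, IH, IJ, IOA, IOI, IUA, IUI, IXR, IXS, ID, IF, IFCA, IU, IVV, IW = range(16)
INA_I, IK_I, ICA_I, ICA_UP, ICA_REL = 16, 17, 18, 19, 20
IN_NOXB, IP_NOXB, ITRPNL, ITRPNH, IN_XB, IXBPRER, IXBPOSTR = 21, 22, 23, 24, 25, 26, 27
ISL, IXPRER, IXPOSTR, IINTF = 28, 29, 30, 31

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "f_Ca",
    "u", "v", "w", "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel",
    "N_NoXB", "P_NoXB", "TropCaL", "TropCaH", "N", "XBprer", "XBpostr",
    "SL", "xXBprer", "xXBpostr", "Integral_force",
)

# Derived (monitored) quantities filled by ``cell_rhs`` on every evaluation.
EXTRA_NAMES = (
    "I_Na", "I_K1", "I_to", "I_Kur", "I_Kr", "I_Ks", "I_CaL", "I_pCa",
    "I_NaK", "I_NaCa", "I_bNa", "I_bCa", "I_ion", "I_st",
    "I_rel", "I_up", "I_up_leak", "I_tr", "Fn",
    "E_Na", "E_K", "E_Ca",
    "F_active", "F_passive", "F_preload", "F_afterload",
    "dTropACa_dt", "SOVFThick", "SOVFThin", "permtot",
)
NEXTRA = len(EXTRA_NAMES)
(XI_NA, XI_K1, XI_TO, XI_KUR, XI_KR, XI_KS, XI_CAL, XI_PCA,
 XI_NAK, XI_NACA, XI_BNA, XI_BCA, XI_ION, XI_ST,
 XI_REL, XI_UP, XI_UPLEAK, XI_TR, XI_FN,
 XE_NA, XE_K, XE_CA,
 XF_ACT, XF_PAS, XF_PRE, XF_AFT,
 XDTROP, XSOVTHICK, XSOVTHIN, XPERM) = range(NEXTRA)

# ---------------------------------------------------------------------------
# Ionic model constants (Courtemanche et al. 1998)
R_GAS = 8.3143        # J/(mol K)
T_KELVIN = 310.0      # K
FARADAY = 96.4867     # C/mmol
V_I = 13668.0         # um^3 intracellular volume
V_UP = 1109.52        # um^3 SR uptake compartment
V_REL = 96.48         # um^3 SR release compartment
NA_O, K_O, CA_O = 140.0, 5.4, 1.8          # mM extracellular
G_NA = 7.8            # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_NA = 0.0006744375
G_B_CA = 0.001131
I_NAK_MAX = 0.59933874   # pA/pF
KM_NA_I = 10.0
KM_K_O = 1.5
I_NACA_MAX = 1600.0      # pA/pF
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA_NACA = 0.35
I_CAP_MAX = 0.275        # pA/pF
K_REL = 30.0             # 1/ms
I_UP_MAX = 0.005         # mM/ms
K_UP = 0.00092
CA_UP_MAX = 15.0
CMDN_MAX, TRPN_MAX, CSQN_MAX = 0.05, 0.07, 10.0
KM_CMDN, KM_TRPN, KM_CSQN = 0.00238, 0.0005, 0.8
TAU_TR = 180.0
TAU_FCA = 2.0
TAU_U = 8.0
KQ10 = 3.0

# ---------------------------------------------------------------------------
# Myofilament constants (Rice et al. 2008, rat, rates specified at 37 degC)
SL_MAX, SL_MIN = 2.4, 1.4          # um, hard sarcomere-length bounds
LEN_THIN, LEN_THICK, LEN_HBARE = 1.2, 1.65, 0.1   # um filament geometry
Q_KON, Q_KOFF, Q_KN_P, Q_KP_N = 1.5, 1.3, 1.6, 1.6
Q_FAPP, Q_GAPP, Q_HF, Q_HB, Q_GXB = 6.25, 2.5, 6.25, 6.25, 6.25
KON = 50e-3          # 1/(uM ms)
KOFF_L = 250e-3      # 1/ms
KOFF_H = 25e-3       # 1/ms
KOFF_MOD = 1.0       # rat
PERM50 = 0.5
NPERM = 15.0
KN_P = 500e-3        # 1/ms
KP_N = 50e-3         # 1/ms
FAPP = 500e-3        # 1/ms
GAPP = 70e-3         # 1/ms
GSLMOD = 6.0
HF_R = 2000e-3       # 1/ms
HFMDC = 5.0
HB_R = 400e-3        # 1/ms
HBMDC = 0.0
GXB = 70e-3          # 1/ms
SIGMA_P, SIGMA_N = 8.0, 1.0
XBMODSP = 1.0        # rat
X_0 = 0.007          # um mean distortion of head rotation
X_PSI = 2.0
SL_REST = 1.9        # um zero-passive-force length (titin)
PCON_T, PEXP_T = 0.002, 10.0
SL_COLLAGEN, PCON_C, PEXP_C = 2.25, 0.02, 70.0
MASS_MYO = 50.0      # norm-force ms^2 / um
VISC_MYO = 3.0       # norm-force ms / um
KSE = 1.0            # norm-force / um, series elastic element (afterload)
TROP_CONC = 70.0     # uM total troponin regulatory sites

# Steady-state crossbridge fractions of the fully-activated cycle, used to
# normalise force (fixed constants of the source model).
_DENOM0 = FAPP * HF_R + GXB * HF_R + GXB * HB_R + HB_R * FAPP + GXB * FAPP
SS_XBPRER = (HB_R * FAPP + GXB * FAPP) / _DENOM0
SS_XBPOSTR = FAPP * HF_R / _DENOM0


@njit(cache=True)
def _heav(x):
    return 1.0 if x >= 0.0 else 0.0


@njit(cache=True)
def _sign(x):
    if x > 0.0:
        return 1.0
    if x < 0.0:
        return -1.0
    return 0.0


@njit(cache=True)
def overlap_fractions(sl):
    """Thick/thin filament single-overlap fractions at sarcomere length sl."""
    sovr_ze = min(LEN_THICK * 0.5, sl * 0.5)
    sovr_cle = max(LEN_THIN - sl * 0.5, LEN_HBARE * 0.5)
    len_sovr = sovr_ze - sovr_cle
    sovf_thick = 2.0 * len_sovr / (LEN_THICK - LEN_HBARE)
    sovf_thin = len_sovr / LEN_THIN
    return sovf_thick, sovf_thin


@njit(cache=True)
def active_force(y):
    """Normalised active force from the crossbridge states of ``y``."""
    sovf_thick, _ = overlap_fractions(y[ISL])
    force = sovf_thick * (y[IXPOSTR] * y[IXBPOSTR] + y[IXPRER] * y[IXBPRER])
    return force / (X_0 * SS_XBPOSTR)


@njit(cache=True)
def cell_rhs(y, ist_pa, cm, sl0, tmpc, coupled, dy, ex):
    """Time derivatives of the full 32-variable coupled cell model.

    Parameters: state ``y`` (length 32), stimulus ``ist_pa`` in pA (positive
    depolarises), membrane capacitance ``cm`` (pF), resting sarcomere length
    ``sl0`` (um), temperature ``tmpc`` (degC), ``coupled`` flag (1.0 couples
    the myofilament troponin flux into the Ca2+ balance; 0.0 restores the
    original instantaneous troponin buffer).  Fills ``dy`` (derivatives) and
    ``ex`` (monitored quantities, see EXTRA_NAMES) in place.
    """
    v = y[IV]
    m, h, j = y[IM], y[IH], y[IJ]
    oa, oi, ua, ui = y[IOA], y[IOI], y[IUA], y[IUI]
    xr, xs = y[IXR], y[IXS]
    d, f, fca = y[ID], y[IF], y[IFCA]
    u, vv, w = y[IU], y[IVV], y[IW]
    na_i, k_i, ca_i = y[INA_I], y[IK_I], y[ICA_I]
    ca_up, ca_rel = y[ICA_UP], y[ICA_REL]

    rt_f = R_GAS * T_KELVIN / FARADAY
    e_na = rt_f * math.log(NA_O / na_i)
    e_k = rt_f * math.log(K_O / k_i)
    e_ca = 0.5 * rt_f * math.log(CA_O / ca_i)

    # --- membrane currents (pA) -------------------------------------------
    i_na = cm * G_NA * m * m * m * h * j * (v - e_na)
    i_k1 = cm * G_K1 * (v - e_k) / (1.0 + math.exp(0.07 * (v + 80.0)))
    i_to = cm * G_TO * oa * oa * oa * oi * (v - e_k)
    g_kur = 0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0))
    i_kur = cm * g_kur * ua * ua * ua * ui * (v - e_k)
    i_kr = cm * G_KR * xr * (v - e_k) / (1.0 + math.exp((v + 15.0) / 22.4))
    i_ks = cm * G_KS * xs * xs * (v - e_k)
    i_cal = cm * G_CAL * d * f * fca * (v - 65.0)

    sigma = (math.exp(NA_O / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / rt_f)
                   + 0.0365 * sigma * math.exp(-v / rt_f))
    i_nak = (cm * I_NAK_MAX * f_nak * K_O
             / ((1.0 + (KM_NA_I / na_i) ** 1.5) * (K_O + KM_K_O)))

    expg = math.exp(GAMMA_NACA * v / rt_f)
    expg1 = math.exp((GAMMA_NACA - 1.0) * v / rt_f)
    i_naca = (cm * I_NACA_MAX
              * (expg * na_i ** 3 * CA_O - expg1 * NA_O ** 3 * ca_i)
              / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                 * (1.0 + K_SAT * expg1)))

    i_b_na = cm * G_B_NA * (v - e_na)
    i_b_ca = cm * G_B_CA * (v - e_ca)
    i_cap = cm * I_CAP_MAX * ca_i / (0.0005 + ca_i)

    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal
             + i_cap + i_nak + i_naca + i_b_na + i_b_ca)

    dy[IV] = (-i_ion + ist_pa) / cm

    # --- gating variables --------------------------------------------------
    if abs(v + 47.13) < 1e-10:
        alpha_m = 3.2
    else:
        alpha_m = 0.32 * (v + 47.13) / (1.0 - math.exp(-0.1 * (v + 47.13)))
    beta_m = 0.08 * math.exp(-v / 11.0)
    dy[IM] = alpha_m * (1.0 - m) - beta_m * m

    if v < -40.0:
        alpha_h = 0.135 * math.exp(-(v + 80.0) / 6.8)
        beta_h = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        alpha_j = ((-1.2714e5 * math.exp(0.2444 * v)
                    - 3.474e-5 * math.exp(-0.04391 * v)) * (v + 37.78)
                   / (1.0 + math.exp(0.311 * (v + 79.23))))
        beta_j = (0.1212 * math.exp(-0.01052 * v)
                  / (1.0 + math.exp(-0.1378 * (v + 40.14))))
    else:
        alpha_h = 0.0
        beta_h = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        alpha_j = 0.0
        beta_j = (0.3 * math.exp(-2.535e-7 * v)
                  / (1.0 + math.exp(-0.1 * (v + 32.0))))
    dy[IH] = alpha_h * (1.0 - h) - beta_h * h
    dy[IJ] = alpha_j * (1.0 - j) - beta_j * j

    alpha_o = 0.65 / (math.exp(-(v + 10.0) / 8.5)
                      + math.exp(-(v - 30.0) / 59.0))
    beta_oa = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    tau_oa = 1.0 / ((alpha_o + beta_oa) * KQ10)
    oa_inf = 1.0 / (1.0 + math.exp(-(v + 20.47) / 17.54))
    dy[IOA] = (oa_inf - oa) / tau_oa

    alpha_oi = 1.0 / (18.53 + math.exp((v + 113.7) / 10.95))
    beta_oi = 1.0 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    tau_oi = 1.0 / ((alpha_oi + beta_oi) * KQ10)
    oi_inf = 1.0 / (1.0 + math.exp((v + 43.1) / 5.3))
    dy[IOI] = (oi_inf - oi) / tau_oi

    beta_ua = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    tau_ua = 1.0 / ((alpha_o + beta_ua) * KQ10)
    ua_inf = 1.0 / (1.0 + math.exp(-(v + 30.3) / 9.6))
    dy[IUA] = (ua_inf - ua) / tau_ua

    alpha_ui = 1.0 / (21.0 + math.exp(-(v - 185.0) / 28.0))
    beta_ui = math.exp((v - 158.0) / 16.0)
    tau_ui = 1.0 / ((alpha_ui + beta_ui) * KQ10)
    ui_inf = 1.0 / (1.0 + math.exp((v - 99.45) / 27.48))
    dy[IUI] = (ui_inf - ui) / tau_ui

    if abs(v + 14.1) < 1e-10:
        alpha_xr = 0.0015
    else:
        alpha_xr = 0.0003 * (v + 14.1) / (1.0 - math.exp(-(v + 14.1) / 5.0))
    if abs(v - 3.3328) < 1e-10:
        beta_xr = 3.7836118e-4
    else:
        beta_xr = (7.3898e-5 * (v - 3.3328)
                   / (math.exp((v - 3.3328) / 5.1237) - 1.0))
    tau_xr = 1.0 / (alpha_xr + beta_xr)
    xr_inf = 1.0 / (1.0 + math.exp(-(v + 14.1) / 6.5))
    dy[IXR] = (xr_inf - xr) / tau_xr

    if abs(v - 19.9) < 1e-10:
        alpha_xs = 6.8e-4
        beta_xs = 3.15e-4
    else:
        alpha_xs = 4e-5 * (v - 19.9) / (1.0 - math.exp(-(v - 19.9) / 17.0))
        beta_xs = 3.5e-5 * (v - 19.9) / (math.exp((v - 19.9) / 9.0) - 1.0)
    tau_xs = 0.5 / (alpha_xs + beta_xs)
    xs_inf = 1.0 / math.sqrt(1.0 + math.exp(-(v - 19.9) / 12.7))
    dy[IXS] = (xs_inf - xs) / tau_xs

    d_inf = 1.0 / (1.0 + math.exp(-(v + 10.0) / 8.0))
    if abs(v + 10.0) < 1e-10:
        tau_d = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        e_d = math.exp(-(v + 10.0) / 6.24)
        tau_d = (1.0 - e_d) / (0.035 * (v + 10.0) * (1.0 + e_d))
    dy[ID] = (d_inf - d) / tau_d

    f_inf = 1.0 / (1.0 + math.exp((v + 28.0) / 6.9))
    tau_f = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02)
    dy[IF] = (f_inf - f) / tau_f

    fca_inf = 1.0 / (1.0 + ca_i / 0.00035)
    dy[IFCA] = (fca_inf - fca) / TAU_FCA

    # --- SR fluxes and Ca release gating ----------------------------------
    i_rel = K_REL * u * u * vv * w * (ca_rel - ca_i)     # mM/ms
    i_up = I_UP_MAX / (1.0 + K_UP / ca_i)
    i_up_leak = I_UP_MAX * ca_up / CA_UP_MAX
    i_tr = (ca_up - ca_rel) / TAU_TR

    fn = 1e3 * (1e-15 * V_REL * i_rel
                - (1e-15 / (2.0 * FARADAY)) * (0.5 * i_cal - 0.2 * i_naca))
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    dy[IU] = (u_inf - u) / TAU_U
    tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    dy[IVV] = (v_inf - vv) / tau_v
    w_inf = 1.0 - 1.0 / (1.0 + math.exp(-(v - 40.0) / 17.0))
    if abs(v - 7.9) < 1e-10:
        tau_w = 6.0 * 0.2 / 1.3
    else:
        e_w = math.exp(-(v - 7.9) / 5.0)
        tau_w = 6.0 * (1.0 - e_w) / ((1.0 + 0.3 * e_w) * (v - 7.9))
    dy[IW] = (w_inf - w) / tau_w

    dy[INA_I] = (-3.0 * i_nak - 3.0 * i_naca - i_b_na - i_na) / (V_I * FARADAY)
    dy[IK_I] = (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) / (V_I * FARADAY)

    dy[ICA_UP] = i_up - i_up_leak - i_tr * V_REL / V_UP
    dy[ICA_REL] = ((i_tr - i_rel)
                   / (1.0 + CSQN_MAX * KM_CSQN / (ca_rel + KM_CSQN) ** 2))

    # ----------------------------------------------------------------------
    # Myofilament model (Rice et al. 2008); Ca in uM on this side.
    cai_um = ca_i * 1e3
    sl = y[ISL]
    trop_l, trop_h = y[ITRPNL], y[ITRPNH]
    n_noxb, p_noxb = y[IN_NOXB], y[IP_NOXB]
    n_xb, xbprer, xbpostr = y[IN_XB], y[IXBPRER], y[IXBPOSTR]
    x_prer, x_postr = y[IXPRER], y[IXPOSTR]
    intf = y[IINTF]

    sovf_thick, sovf_thin = overlap_fractions(sl)

    # temperature scaling (all factors are 1 at 37 degC)
    tscale = (tmpc - 37.0) / 10.0
    kon_t = KON * Q_KON ** tscale
    koff_l_t = KOFF_L * KOFF_MOD * Q_KOFF ** tscale
    koff_h_t = KOFF_H * KOFF_MOD * Q_KOFF ** tscale
    kn_p_t = KN_P * Q_KN_P ** tscale
    kp_n_t = KP_N * Q_KP_N ** tscale
    fapp_t = FAPP * XBMODSP * Q_FAPP ** tscale
    gapsl = 1.0 + (1.0 - sovf_thick) * GSLMOD
    gapp_t = GAPP * gapsl * XBMODSP * Q_GAPP ** tscale
    hfmd = math.exp(-_sign(x_prer) * HFMDC * (x_prer / X_0) ** 2)
    hbmd = math.exp(_sign(x_postr - X_0) * HBMDC * ((x_postr - X_0) / X_0) ** 2)
    hf_t = HF_R * hfmd * XBMODSP * Q_HF ** tscale
    hb_t = HB_R * hbmd * XBMODSP * Q_HB ** tscale
    if x_postr < X_0:
        gxbmd = math.exp(SIGMA_P * ((X_0 - x_postr) / X_0) ** 2)
    else:
        gxbmd = math.exp(SIGMA_N * ((x_postr - X_0) / X_0) ** 2)
    gxb_t = GXB * gxbmd * XBMODSP * Q_GXB ** tscale

    # Ca binding to troponin regulatory sites
    d_trop_l = kon_t * cai_um * (1.0 - trop_l) - koff_l_t * trop_l
    d_trop_h = kon_t * cai_um * (1.0 - trop_h) - koff_h_t * trop_h
    dy[ITRPNL] = d_trop_l
    dy[ITRPNH] = d_trop_h

    trop_reg = (1.0 - sovf_thin) * trop_l + sovf_thin * trop_h
    permtot = math.sqrt(1.0 / (1.0 + (PERM50 / trop_reg) ** NPERM))
    inprmt = min(1.0 / permtot, 100.0)

    p_xb = 1.0 - n_xb - xbprer - xbpostr
    dy[IN_NOXB] = -kn_p_t * permtot * n_noxb + kp_n_t * inprmt * p_noxb
    dy[IP_NOXB] = -dy[IN_NOXB]
    dy[IN_XB] = -kn_p_t * permtot * n_xb + kp_n_t * inprmt * p_xb
    d_xbprer = fapp_t * p_xb - gapp_t * xbprer - hf_t * xbprer + hb_t * xbpostr
    d_xbpostr = hf_t * xbprer - hb_t * xbpostr - gxb_t * xbpostr
    dy[IXBPRER] = d_xbprer
    dy[IXBPOSTR] = d_xbpostr

    f_active = (sovf_thick * (x_postr * xbpostr + x_prer * xbprer)
                / (X_0 * SS_XBPOSTR))

    pp_t = _sign(sl - SL_REST) * PCON_T * (math.exp(PEXP_T * abs(sl - SL_REST)) - 1.0)
    if sl > SL_COLLAGEN:
        pp_c = PCON_C * (math.exp(PEXP_C * (sl - SL_COLLAGEN)) - 1.0)
    else:
        pp_c = 0.0
    f_passive = pp_t + pp_c
    f_preload = (_sign(sl0 - SL_REST) * PCON_T
                 * (math.exp(PEXP_T * abs(sl0 - SL_REST)) - 1.0))
    # series elastic element anchored at the reference length: the afterload
    # term of the force integral, resisting both shortening and stretch
    f_afterload = KSE * (sl0 - sl)

    d_sl = ((intf + (sl0 - sl) * VISC_MYO) / MASS_MYO
            * _heav(sl - SL_MIN) * _heav(SL_MAX - sl))
    dy[ISL] = d_sl
    dy[IINTF] = -f_active - f_passive + f_preload + f_afterload

    # mean-distortion dynamics (duty fractions from the current rates)
    denom_t = (fapp_t * hf_t + gxb_t * hf_t + gxb_t * hb_t
               + hb_t * fapp_t + gxb_t * fapp_t)
    duty_prer = (hb_t * fapp_t + gxb_t * fapp_t) / denom_t
    duty_postr = fapp_t * hf_t / denom_t
    dy[IXPRER] = (0.5 * d_sl
                  + (X_PSI / duty_prer)
                  * (-x_prer * fapp_t + (x_postr - X_0 - x_prer) * hb_t))
    dy[IXPOSTR] = (0.5 * d_sl
                   + (X_PSI / duty_postr) * (X_0 + x_prer - x_postr) * hf_t)

    # apparent troponin-bound Ca flux for the Ca2+ balance (uM/ms)
    fr_sbxb = (xbpostr + xbprer) / (SS_XBPOSTR + SS_XBPRER)
    d_fr_sbxb = (d_xbpostr + d_xbprer) / (SS_XBPOSTR + SS_XBPRER)
    d_sovr_ze = -0.5 * d_sl * _heav(LEN_THICK - sl)
    d_sovr_cle = -0.5 * d_sl * _heav(2.0 * LEN_THIN - sl - LEN_HBARE)
    d_len_sovr = d_sovr_ze - d_sovr_cle
    d_sovf_thin = d_len_sovr / LEN_THIN
    d_sovf_thick = 2.0 * d_len_sovr / (LEN_THICK - LEN_HBARE)
    d_trop_tot = TROP_CONC * (
        -d_sovf_thin * trop_l + (1.0 - sovf_thin) * d_trop_l
        + d_sovf_thin * (fr_sbxb * trop_h + (1.0 - fr_sbxb) * trop_l)
        + sovf_thin * (d_fr_sbxb * trop_h + fr_sbxb * d_trop_h
                       - d_fr_sbxb * trop_l + (1.0 - fr_sbxb) * d_trop_l))

    # ----------------------------------------------------------------------
    # Intracellular Ca2+ balance (coupled: troponin handled by the explicit
    # -2 dTropACa/dt flux and B2 keeps only the calmodulin term; uncoupled:
    # original instantaneous troponin + calmodulin buffers).
    b1 = ((2.0 * i_naca - i_cap - i_cal - i_b_ca) / (2.0 * V_I * FARADAY)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    cmdn_term = CMDN_MAX * KM_CMDN / (ca_i + KM_CMDN) ** 2
    if coupled >= 0.5:
        b1 = b1 - 2.0 * d_trop_tot * 1e-3          # uM/ms -> mM/ms
        b2 = 1.0 + cmdn_term
    else:
        b2 = 1.0 + TRPN_MAX * KM_TRPN / (ca_i + KM_TRPN) ** 2 + cmdn_term
    dy[ICA_I] = b1 / b2

    # --- monitored quantities ---------------------------------------------
    ex[XI_NA] = i_na
    ex[XI_K1] = i_k1
    ex[XI_TO] = i_to
    ex[XI_KUR] = i_kur
    ex[XI_KR] = i_kr
    ex[XI_KS] = i_ks
    ex[XI_CAL] = i_cal
    ex[XI_PCA] = i_cap
    ex[XI_NAK] = i_nak
    ex[XI_NACA] = i_naca
    ex[XI_BNA] = i_b_na
    ex[XI_BCA] = i_b_ca
    ex[XI_ION] = i_ion
    ex[XI_ST] = ist_pa
    ex[XI_REL] = i_rel
    ex[XI_UP] = i_up
    ex[XI_UPLEAK] = i_up_leak
    ex[XI_TR] = i_tr
    ex[XI_FN] = fn
    ex[XE_NA] = e_na
    ex[XE_K] = e_k
    ex[XE_CA] = e_ca
    ex[XF_ACT] = f_active
    ex[XF_PAS] = f_passive
    ex[XF_PRE] = f_preload
    ex[XF_AFT] = f_afterload
    ex[XDTROP] = d_trop_tot
    ex[XSOVTHICK] = sovf_thick
    ex[XSOVTHIN] = sovf_thin
    ex[XPERM] = permtot


N_GATES = 15   # indices 1..15 are ionic gating variables in [0, 1]


@njit(cache=True)
def euler_step(y, ist_pa, dt, cm, sl0, tmpc, coupled, dy, ex):
    """One explicit-Euler update in place. Returns number of gate clips."""
    cell_rhs(y, ist_pa, cm, sl0, tmpc, coupled, dy, ex)
    clips = 0
    for k in range(NVAR):
        y[k] += dt * dy[k]
    for k in range(1, 1 + N_GATES):
        if y[k] < 0.0:
            y[k] = 0.0
            clips += 1
        elif y[k] > 1.0:
            y[k] = 1.0
            clips += 1
    return clips


@njit(cache=True)
def integrate_cell(y0, dt, n_steps, stim_amp_pa, stim_start, stim_dur,
                   sample_every, cm, sl0, tmpc, coupled):
    """Fixed-step Euler run of one cell with a single square stimulus pulse.

    Returns (t_samples, y_samples, f_active_samples, clip_count).  Sampling
    includes t = 0 and then every ``sample_every`` steps.
    """
    y = y0.copy()
    dy = np.empty(NVAR)
    ex = np.empty(NEXTRA)
    nsamp = n_steps // sample_every + 1
    tout = np.empty(nsamp)
    yout = np.empty((nsamp, NVAR))
    fout = np.empty(nsamp)
    tout[0] = 0.0
    yout[0, :] = y
    fout[0] = active_force(y)
    isamp = 1
    clips = 0
    for step in range(n_steps):
        t = step * dt
        ist = stim_amp_pa if (stim_start <= t < stim_start + stim_dur) else 0.0
        clips += euler_step(y, ist, dt, cm, sl0, tmpc, coupled, dy, ex)
        if (step + 1) % sample_every == 0:
            tout[isamp] = (step + 1) * dt
            yout[isamp, :] = y
            fout[isamp] = active_force(y)
            isamp += 1
    return tout[:isamp], yout[:isamp], fout[:isamp], clips


@njit(cache=True)
def pace_cell(y0, dt, period_ms, n_beats, stim_amp_pa, stim_dur, cm, sl0,
              tmpc, coupled):
    """Pace a cell with one stimulus per cycle; stimulus at the cycle start.

    Returns (end-diastolic state, per-beat pre-stimulus V, per-beat
    pre-stimulus Ca_i).  The returned state is taken immediately before the
    next stimulus would occur.
    """
    y = y0.copy()
    dy = np.empty(NVAR)
    ex = np.empty(NEXTRA)
    steps_per_beat = int(round(period_ms / dt))
    stim_steps = int(round(stim_dur / dt))
    v_rest = np.empty(n_beats)
    ca_rest = np.empty(n_beats)
    for beat in range(n_beats):
        for step in range(steps_per_beat):
            ist = stim_amp_pa if step < stim_steps else 0.0
            euler_step(y, ist, dt, cm, sl0, tmpc, coupled, dy, ex)
        v_rest[beat] = y[IV]
        ca_rest[beat] = y[ICA_I]
        if not np.isfinite(y[IV]):
            break
    return y, v_rest, ca_rest
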
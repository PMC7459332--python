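"""Conductance-based stellate-Purkinje microcircuit.

A Purkinje cell (PC) receives parallel-fiber (PF) excitation on its dendrite
and feedforward GABAergic inhibition from two stellate cells (SCs); the
superficial SC also inhibits the deep SC. Climbing-fiber (CF) input reaches
the PC directly (strong AMPA activation) and the SCs via glutamate spillover
with a ~10 ms diffusion delay; the CF fires a 2-spike burst at 300 Hz on
rewarded trials. A pause in PC firing drives licking, modeled by convolving
the PC spike train with a reversed Gaussian.

Units: ms, mV, nS, pA, pF throughout. Synapses are double-exponential
conductances normalized so the peak equals the tabulated peak conductance;
with a 70 mV driving force these reproduce the tabulated peak currents.

Learning and chemogenetics enter as scalars: long-term depression of the
PF-SC and SC-PC synapses for the learned unrewarded odorant, a fractional
weight reduction plus a 40% attenuation of SC activity for the CNO
(DREADD-agonist) condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import fftconvolve

# ---------------------------------------------------------------- synapses


@dataclass
class SynapseParams:
    """Double-exponential synapse: peak conductance, rise/decay times,
    reversal, axonal delay and a plasticity multiplier."""

    g_peak: float          # nS
    tau1: float            # ms
    tau2: float            # ms
    e_rev: float           # mV
    delay: float = 0.0     # ms
    weight_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.g_peak < 0:
            raise ValueError("g_peak must be >= 0")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be > 0")
        if not 0.0 <= self.weight_scale <= 1.5:
            raise ValueError("weight_scale must lie in [0, 1.5]")

    @property
    def tau_rise(self) -> float:
        return min(self.tau1, self.tau2)

    @property
    def tau_decay(self) -> float:
        return max(self.tau1, self.tau2)


# Tabulated synapse parameters (SC-SC decay uses the midpoint of the
# published 5.9-11.3 ms range).
PF_SC = SynapseParams(g_peak=1.3774, tau1=3.45, tau2=3.17, e_rev=0.0)
PF_PC = SynapseParams(g_peak=0.2857, tau1=0.28, tau2=1.23, e_rev=0.0)
SC_SC = SynapseParams(g_peak=1.0786, tau1=0.6, tau2=8.6, e_rev=-60.0)
SC_PC = SynapseParams(g_peak=15.0, tau1=1.8, tau2=8.5, e_rev=-85.0, delay=2.0)


def double_exp_conductance(t_ms, p: SynapseParams):
    """Synaptic conductance (nS) ``t_ms`` after a presynaptic event.

    g(t) = g_peak * weight_scale * [exp(-t/tau_d) - exp(-t/tau_r)] / norm,
    normalized so the maximum equals g_peak * weight_scale. At tau1 == tau2
    the alpha-function limit (t/tau) exp(1 - t/tau) is used.
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_ms must be >= 0")
    amp = p.g_peak * p.weight_scale
    tr, td = p.tau_rise, p.tau_decay
    if np.isclose(tr, td):
        g = amp * (t / td) * np.exp(1.0 - t / td)
    else:
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        norm = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        g = amp * (np.exp(-t / td) - np.exp(-t / tr)) / norm
    return g if g.shape else float(g)


def peak_current_pa(p: SynapseParams, driving_force_mv: float = 70.0) -> float:
    """Peak synaptic current (pA) at the stated driving force."""
    return p.g_peak * p.weight_scale * driving_force_mv


def cf_burst_times(t0_ms: float = 0.0, n_spikes: int = 2,
                   rate_hz: float = 300.0) -> np.ndarray:
    """Climbing-fiber burst: ``n_spikes`` at ``rate_hz`` from ``t0_ms``."""
    if n_spikes < 1 or rate_hz <= 0:
        raise ValueError("need n_spikes >= 1 and rate_hz > 0")
    return t0_ms + np.arange(n_spikes) * (1000.0 / rate_hz)


def synaptic_kernel(p: SynapseParams, dt_ms: float, scale: float = 1.0
                    ) -> np.ndarray:
    """Sampled conductance kernel for convolution with an event train."""
    t_end = p.tau_decay * 8.0 + p.delay
    t = np.arange(0.0, t_end, dt_ms)
    g = np.zeros(t.size)
    m = t >= p.delay
    g[m] = double_exp_conductance(t[m] - p.delay, p)
    return g * scale


def conductance_from_events(event_counts: np.ndarray, p: SynapseParams,
                            dt_ms: float, scale: float = 1.0) -> np.ndarray:
    """Summed conductance trace for a binned presynaptic event train."""
    k = synaptic_kernel(p, dt_ms, scale)
    return fftconvolve(event_counts, k)[:event_counts.size]


# -------------------------------------------------------------- SC neuron


@dataclass
class SCParams:
    """Single-compartment stellate cell.

    The membrane area is set so the passive input resistance equals the
    target (r_m / area = R_in), giving area ~3.5e-5 cm^2 at the default
    571.39 MOhm. Channel densities are in mS/cm^2; zeroing them yields the
    passive cell used for Ohmic checks.
    """

    r_m: float = 20.0            # kOhm cm^2
    c_m: float = 1.5             # uF/cm^2
    r_i: float = 115.0           # Ohm cm
    r_in_target: float = 571.39  # MOhm
    e_leak: float = -68.0        # mV
    g_na: float = 35.0           # mS/cm^2
    g_kdr: float = 9.0
    g_ka: float = 4.0
    g_cat: float = 0.5
    e_na: float = 55.0
    e_k: float = -90.0
    e_ca: float = 120.0

    @property
    def area_cm2(self) -> float:
        return (self.r_m * 1e3) / (self.r_in_target * 1e6)

    @property
    def c_pf(self) -> float:
        return self.c_m * self.area_cm2 * 1e6

    @property
    def g_leak_ns(self) -> float:
        return 1e3 / self.r_in_target

    def density_to_ns(self, d_ms_cm2: float) -> float:
        return d_ms_cm2 * self.area_cm2 * 1e6


@njit(cache=False)
def _sc_derivs(v, h, nk, a, b, u, c_pf, g_l, e_l, gna, e_na, gkdr, gka, e_k,
               gcat, e_ca, g_e, e_exc, g_i, e_inh, g_t, e_t, i_inj):
    # interneuron-type Na/KDR kinetics (phi = 5) + A-type K + low-threshold Ca
    am = 0.1 * (v + 35.0) / (1.0 - np.exp(-(v + 35.0) / 10.0)) \
        if abs(v + 35.0) > 1e-6 else 1.0
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    m_inf = am / (am + bm)
    ah = 0.35 * np.exp(-(v + 58.0) / 20.0)
    bh = 5.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    an = 0.05 * (v + 34.0) / (1.0 - np.exp(-(v + 34.0) / 10.0)) \
        if abs(v + 34.0) > 1e-6 else 0.5
    bn = 0.625 * np.exp(-(v + 44.0) / 80.0)
    a_inf = 1.0 / (1.0 + np.exp(-(v + 50.0) / 20.0))
    b_inf = 1.0 / (1.0 + np.exp((v + 80.0) / 6.0))
    s_inf = 1.0 / (1.0 + np.exp(-(v + 57.0) / 6.2))
    u_inf = 1.0 / (1.0 + np.exp((v + 81.0) / 4.0))
    i_ion = gna * m_inf ** 3 * h * (v - e_na) \
        + gkdr * nk ** 4 * (v - e_k) \
        + gka * a ** 3 * b * (v - e_k) \
        + gcat * s_inf ** 2 * u * (v - e_ca) \
        + g_l * (v - e_l) \
        + g_e * (v - e_exc) + g_i * (v - e_inh) + g_t * (v - e_t)
    dv = (-(i_ion) + i_inj) / c_pf
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - nk) - bn * nk
    da = (a_inf - a) / 2.0
    db = (b_inf - b) / 20.0
    du = (u_inf - u) / 30.0
    return dv, dh, dn, da, db, du


@njit(cache=False)
def _integrate_sc(dt, c_pf, g_l, e_l, gna, e_na, gkdr, gka, e_k, gcat, e_ca,
                  g_exc, e_exc, g_inh, e_inh, g_tonic, e_tonic, i_inj, v0):
    n = g_exc.shape[0]
    v_out = np.empty(n)
    spk = np.zeros(n, dtype=np.bool_)
    v = v0
    h = 0.7
    nk = 0.1
    a = 1.0 / (1.0 + np.exp(-(v + 50.0) / 20.0))
    b = 1.0 / (1.0 + np.exp((v + 80.0) / 6.0))
    u = 1.0 / (1.0 + np.exp((v + 81.0) / 4.0))
    above = False
    for i in range(n):
        # midpoint (RK2) step; synaptic conductances held over the step
        d1 = _sc_derivs(v, h, nk, a, b, u, c_pf, g_l, e_l, gna, e_na, gkdr,
                        gka, e_k, gcat, e_ca, g_exc[i], e_exc, g_inh[i],
                        e_inh, g_tonic, e_tonic, i_inj[i])
        vm = v + 0.5 * dt * d1[0]
        hm = h + 0.5 * dt * d1[1]
        nm = nk + 0.5 * dt * d1[2]
        am2 = a + 0.5 * dt * d1[3]
        bm2 = b + 0.5 * dt * d1[4]
        um = u + 0.5 * dt * d1[5]
        d2 = _sc_derivs(vm, hm, nm, am2, bm2, um, c_pf, g_l, e_l, gna, e_na,
                        gkdr, gka, e_k, gcat, e_ca, g_exc[i], e_exc,
                        g_inh[i], e_inh, g_tonic, e_tonic, i_inj[i])
        v += dt * d2[0]
        h += dt * d2[1]
        nk += dt * d2[2]
        a += dt * d2[3]
        b += dt * d2[4]
        u += dt * d2[5]
        if abs(v) > 200.0:
            raise ValueError("SC integration blew up")
        if v > -10.0 and not above:
            spk[i] = True
            above = True
        elif v < -30.0:
            above = False
        v_out[i] = v
    return v_out, spk


def simulate_sc(p: SCParams, duration_ms: float, dt_ms: float = 0.025,
                g_exc: np.ndarray | None = None, e_exc: float = 0.0,
                g_inh: np.ndarray | None = None, e_inh: float = -60.0,
                g_tonic_ns: float = 0.0, e_tonic: float = -90.0,
                i_inj_pa: np.ndarray | float = 0.0, v0: float | None = None):
    """Integrate the SC membrane; returns (t_ms, V, spike_times_ms).

    Fixed-step integration; raises if |V| exceeds 200 mV. With all channel
    densities zero the cell is passive and settles at the leak reversal.
    """
    if dt_ms > 0.025:
        raise ValueError("dt_ms must be <= 0.025 ms")
    n = int(round(duration_ms / dt_ms))
    z = np.zeros(n)
    g_e = z if g_exc is None else np.asarray(g_exc, dtype=float)[:n]
    g_i = z if g_inh is None else np.asarray(g_inh, dtype=float)[:n]
    i_inj = np.broadcast_to(np.asarray(i_inj_pa, dtype=float), (n,)) \
        if np.ndim(i_inj_pa) == 0 else np.asarray(i_inj_pa, dtype=float)[:n]
    v0 = p.e_leak if v0 is None else v0
    v, spk = _integrate_sc(
        dt_ms, p.c_pf, p.g_leak_ns, p.e_leak,
        p.density_to_ns(p.g_na), p.e_na,
        p.density_to_ns(p.g_kdr), p.density_to_ns(p.g_ka), p.e_k,
        p.density_to_ns(p.g_cat), p.e_ca,
        np.ascontiguousarray(g_e), e_exc, np.ascontiguousarray(g_i), e_inh,
        g_tonic_ns, e_tonic, np.ascontiguousarray(i_inj), v0)
    t = (np.arange(n) + 1) * dt_ms
    return t, v, t[spk]


# -------------------------------------------------------------- PC neuron


@dataclass
class PCParams:
    """Two-compartment Purkinje cell: spiking soma + passive dendrite
    coupled by an axial conductance, with a bias current standing in for
    the cell's intrinsic pacemaking (tonic firing at rest)."""

    c_soma: float = 100.0      # pF
    c_dend: float = 200.0      # pF
    g_leak_soma: float = 10.0  # nS
    e_leak_soma: float = -65.0
    g_leak_dend: float = 10.0  # nS
    e_leak_dend: float = -65.0
    g_couple: float = 15.0     # nS, from r_i over the trunk geometry
    g_na: float = 3500.0       # nS
    g_kdr: float = 900.0       # nS
    e_na: float = 55.0
    e_k: float = -90.0
    i_bias: float = 140.0      # pA, tonic ~45 Hz under background inhibition


@njit(cache=False)
def _pc_derivs(vs, vd, h, nk, cs, cd, gls, els, gld, eld, gc, gna, e_na,
               gkdr, e_k, i_bias, g_e, e_exc, g_i, e_inh):
    am = 0.1 * (vs + 35.0) / (1.0 - np.exp(-(vs + 35.0) / 10.0)) \
        if abs(vs + 35.0) > 1e-6 else 1.0
    bm = 4.0 * np.exp(-(vs + 60.0) / 18.0)
    m_inf = am / (am + bm)
    ah = 0.35 * np.exp(-(vs + 58.0) / 20.0)
    bh = 5.0 / (1.0 + np.exp(-(vs + 28.0) / 10.0))
    an = 0.05 * (vs + 34.0) / (1.0 - np.exp(-(vs + 34.0) / 10.0)) \
        if abs(vs + 34.0) > 1e-6 else 0.5
    bn = 0.625 * np.exp(-(vs + 44.0) / 80.0)
    i_soma = gna * m_inf ** 3 * h * (vs - e_na) \
        + gkdr * nk ** 4 * (vs - e_k) \
        + gls * (vs - els) + gc * (vs - vd) \
        + g_i * (vs - e_inh) - i_bias
    i_dend = gld * (vd - eld) + gc * (vd - vs) + g_e * (vd - e_exc)
    dvs = -i_soma / cs
    dvd = -i_dend / cd
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - nk) - bn * nk
    return dvs, dvd, dh, dn


@njit(cache=False)
def _integrate_pc(dt, cs, cd, gls, els, gld, eld, gc, gna, e_na, gkdr, e_k,
                  i_bias, g_exc_d, e_exc, g_inh_s, e_inh, v0):
    n = g_exc_d.shape[0]
    vs_out = np.empty(n)
    vd_out = np.empty(n)
    spk = np.zeros(n, dtype=np.bool_)
    vs = v0
    vd = v0
    h = 0.7
    nk = 0.1
    above = False
    for i in range(n):
        d1 = _pc_derivs(vs, vd, h, nk, cs, cd, gls, els, gld, eld, gc, gna,
                        e_na, gkdr, e_k, i_bias, g_exc_d[i], e_exc,
                        g_inh_s[i], e_inh)
        d2 = _pc_derivs(vs + 0.5 * dt * d1[0], vd + 0.5 * dt * d1[1],
                        h + 0.5 * dt * d1[2], nk + 0.5 * dt * d1[3],
                        cs, cd, gls, els, gld, eld, gc, gna, e_na, gkdr,
                        e_k, i_bias, g_exc_d[i], e_exc, g_inh_s[i], e_inh)
        vs += dt * d2[0]
        vd += dt * d2[1]
        h += dt * d2[2]
        nk += dt * d2[3]
        if abs(vs) > 200.0 or abs(vd) > 200.0:
            raise ValueError("PC integration blew up")
        if vs > -10.0 and not above:
            spk[i] = True
            above = True
        elif vs < -30.0:
            above = False
        vs_out[i] = vs
        vd_out[i] = vd
    return vs_out, vd_out, spk


def simulate_pc(p: PCParams, duration_ms: float, dt_ms: float = 0.025,
                g_exc_dend: np.ndarray | None = None, e_exc: float = 0.0,
                g_inh_soma: np.ndarray | None = None, e_inh: float = -85.0,
                i_inj_pa: float = 0.0, v0: float = -60.0):
    """Integrate the PC; returns (t_ms, V_soma, V_dend, spike_times_ms)."""
    if dt_ms > 0.025:
        raise ValueError("dt_ms must be <= 0.025 ms")
    n = int(round(duration_ms / dt_ms))
    z = np.zeros(n)
    g_e = z if g_exc_dend is None else np.asarray(g_exc_dend, dtype=float)[:n]
    g_i = z if g_inh_soma is None else np.asarray(g_inh_soma, dtype=float)[:n]
    vs, vd, spk = _integrate_pc(
        dt_ms, p.c_soma, p.c_dend, p.g_leak_soma, p.e_leak_soma,
        p.g_leak_dend, p.e_leak_dend, p.g_couple, p.g_na, p.e_na,
        p.g_kdr, p.e_k, p.i_bias + i_inj_pa,
        np.ascontiguousarray(g_e), e_exc, np.ascontiguousarray(g_i), e_inh, v0)
    t = (np.arange(n) + 1) * dt_ms
    return t, vs, vd, t[spk]


# ------------------------------------------------------------ microcircuit


@dataclass
class CircuitScenario:
    """One simulated trial of the PF -> SC -> PC circuit."""

    drug: str = "saline"            # saline | CNO
    valence: str = "S+"             # S+ | S-
    duration_ms: float = 3500.0
    t_odor_on_ms: float = 1000.0
    odor_duration_ms: float = 2000.0
    dt_ms: float = 0.025
    # parallel-fiber drive (aggregate over the afferent population)
    n_pf: int = 20
    pf_rate_baseline_hz: float = 0.5
    pf_rate_odor_hz: float = 1.5
    # climbing fiber: burst at reward (odor offset) on rewarded S+ trials
    cf_n_spikes: int = 2
    cf_rate_hz: float = 300.0
    cf_sc_spillover_delay_ms: float = 10.0
    cf_pc_gain: float = 50.0        # "strong activation of the PC AMPARs"
    cf_sc_gain: float = 5.0
    # plasticity / chemogenetics scalars
    ltd_splus_scale: float = 1.0
    ltd_sminus_scale: float = 0.2
    cno_activity_attenuation: float = 0.40
    cno_weight_reduction: float = 0.40
    cno_mode: str = "tonic"         # tonic | deletion
    # DREADD-activated K+ (GIRK-like) conductance, calibrated to cut the
    # baseline-drive SC firing rate by ~40%
    cno_tonic_g_inh_ns: float = 0.15
    cno_tonic_e_rev: float = -90.0
    # lick readout
    lick_l0: float = 10.0
    lick_kernel_sd_ms: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.drug not in ("saline", "CNO"):
            raise ValueError("drug must be saline or CNO")
        if self.valence not in ("S+", "S-"):
            raise ValueError("valence must be S+ or S-")
        if not 0.0 <= self.cno_activity_attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        if self.pf_rate_baseline_hz < 0 or self.pf_rate_odor_hz < 0:
            raise ValueError("rates must be >= 0")

    @property
    def t_reward_ms(self) -> float:
        return self.t_odor_on_ms + self.odor_duration_ms

    @property
    def rewarded(self) -> bool:
        return self.valence == "S+"

    def weight_scale(self) -> float:
        """Effective PF-SC / SC-PC plasticity multiplier for the condition.

        Saline: full weight for the learned S+, strong LTD for the learned
        S-. CNO: the S+ weight is reduced by ``cno_weight_reduction``; for
        S- the 40% attenuation of SC activity diminishes LTD induction, so
        the depressed weight relaxes toward baseline by the same fraction.
        """
        if self.drug == "saline":
            return self.ltd_splus_scale if self.valence == "S+" \
                else self.ltd_sminus_scale
        if self.valence == "S+":
            return self.ltd_splus_scale * (1.0 - self.cno_weight_reduction)
        return self.ltd_sminus_scale + self.cno_activity_attenuation * (
            self.ltd_splus_scale - self.ltd_sminus_scale)


@dataclass
class CircuitOutput:
    t_ms: np.ndarray
    spikes: dict
    voltages: dict
    lick_t_ms: np.ndarray
    lick_rate: np.ndarray
    lick_strength: float
    scenario: CircuitScenario = field(repr=False, default=None)


def _poisson_train(rng, n_steps: int, dt_ms: float, rate_hz: np.ndarray
                   ) -> np.ndarray:
    """Binned event counts for an inhomogeneous Poisson process."""
    lam = rate_hz * dt_ms / 1000.0
    return rng.poisson(lam, size=n_steps).astype(float)


def _spikes_to_counts(spike_times_ms: np.ndarray, n_steps: int, dt_ms: float
                     ) -> np.ndarray:
    counts = np.zeros(n_steps)
    idx = np.floor(np.asarray(spike_times_ms) / dt_ms).astype(int)
    idx = idx[(idx >= 0) & (idx < n_steps)]
    np.add.at(counts, idx, 1.0)
    return counts


def lick_rate_from_pc(pc_spike_times_ms: np.ndarray, duration_ms: float,
                      l0: float = 10.0, gain: float | None = None,
                      kernel_sd_ms: float = 50.0, out_dt_ms: float = 1.0,
                      baseline_window_ms: tuple[float, float] | None = None,
                      odor_window_ms: tuple[float, float] | None = None):
    """Lick rate from PC spiking: a PC pause disinhibits licking.

    lick(t) = max(0, L0 - gain * (spike train (x) Gaussian)), with the
    Gaussian kernel normalized to unit area so the convolution is an
    instantaneous firing-rate estimate in Hz. When ``gain`` is None it is
    calibrated from the mean rate inside ``baseline_window_ms`` so that
    baseline PC firing yields a near-zero (0.5 Hz) lick rate.
    Returns (t_ms, lick_rate, lick_strength) where lick_strength is the mean
    lick rate over ``odor_window_ms`` (whole trace when absent).
    """
    if kernel_sd_ms <= 0:
        raise ValueError("kernel width must be > 0")
    n = int(round(duration_ms / out_dt_ms))
    counts = _spikes_to_counts(np.asarray(pc_spike_times_ms), n, out_dt_ms)
    half = int(np.ceil(4 * kernel_sd_ms / out_dt_ms))
    tt = np.arange(-half, half + 1) * out_dt_ms
    k = np.exp(-0.5 * (tt / kernel_sd_ms) ** 2)
    k /= k.sum() * out_dt_ms / 1000.0        # unit area in seconds -> Hz
    rate = fftconvolve(counts, k, mode="same")
    t = np.arange(n) * out_dt_ms
    if gain is None:
        if baseline_window_ms is None:
            base = rate.mean()
        else:
            m = (t >= baseline_window_ms[0]) & (t < baseline_window_ms[1])
            base = rate[m].mean()
        gain = (l0 - 0.5) / base if base > 0 else 0.0
    lick = np.clip(l0 - gain * rate, 0.0, None)
    if odor_window_ms is None:
        strength = float(lick.mean())
    else:
        m = (t >= odor_window_ms[0]) & (t < odor_window_ms[1])
        strength = float(lick[m].mean())
    return t, lick, strength


def simulate_microcircuit(scenario: CircuitScenario,
                          sc_params: SCParams | None = None,
                          pc_params: PCParams | None = None) -> CircuitOutput:
    """Run one trial of the PF -> SC(sup, deep) -> PC circuit."""
    scenario.validate()
    sc_p = SCParams() if sc_params is None else sc_params
    pc_p = PCParams() if pc_params is None else pc_params
    dt = scenario.dt_ms
    n = int(round(scenario.duration_ms / dt))
    t = (np.arange(n) + 1) * dt
    rng = np.random.default_rng(scenario.seed)

    rate = np.full(n, scenario.n_pf * scenario.pf_rate_baseline_hz)
    odor = (t >= scenario.t_odor_on_ms) & (t < scenario.t_reward_ms)
    rate[odor] = scenario.n_pf * scenario.pf_rate_odor_hz

    w = scenario.weight_scale()
    cno = scenario.drug == "CNO"

    cf_counts = np.zeros(n)
    if scenario.rewarded:
        burst = cf_burst_times(scenario.t_reward_ms, scenario.cf_n_spikes,
                               scenario.cf_rate_hz)
        cf_counts = _spikes_to_counts(burst, n, dt)
    cf_spill = np.roll(cf_counts, int(round(scenario.cf_sc_spillover_delay_ms / dt)))

    pf_sc = replace(PF_SC, weight_scale=min(w, 1.5))
    sc_pc = replace(SC_PC, weight_scale=min(w, 1.5))

    g_tonic = scenario.cno_tonic_g_inh_ns \
        if (cno and scenario.cno_mode == "tonic") else 0.0

    spikes: dict[str, np.ndarray] = {}
    voltages: dict[str, np.ndarray] = {}
    sc_counts_out = {}
    for name, extra_inh in (("SC_superficial", None), ("SC_deep", "SC_superficial")):
        g_exc = conductance_from_events(_poisson_train(rng, n, dt, rate),
                                        pf_sc, dt)
        g_exc += conductance_from_events(cf_spill, PF_SC, dt,
                                         scale=scenario.cf_sc_gain)
        g_inh = None
        if extra_inh is not None:
            g_inh = conductance_from_events(sc_counts_out[extra_inh],
                                            SC_SC, dt)
        _, v, spk = simulate_sc(sc_p, scenario.duration_ms, dt,
                                g_exc=g_exc, e_exc=pf_sc.e_rev,
                                g_inh=g_inh, e_inh=SC_SC.e_rev,
                                g_tonic_ns=g_tonic,
                                e_tonic=scenario.cno_tonic_e_rev)
        if cno and scenario.cno_mode == "deletion":
            keep = rng.random(spk.size) >= scenario.cno_activity_attenuation
            spk = spk[keep]
        spikes[name] = spk
        voltages[name] = v
        sc_counts_out[name] = _spikes_to_counts(spk, n, dt)

    g_exc_pc = conductance_from_events(_poisson_train(rng, n, dt, rate),
                                       PF_PC, dt)
    g_exc_pc += conductance_from_events(cf_counts, PF_PC, dt,
                                        scale=scenario.cf_pc_gain)
    sc_drive = sc_counts_out["SC_superficial"] + sc_counts_out["SC_deep"]
    g_inh_pc = conductance_from_events(sc_drive, sc_pc, dt)
    _, vs, vd, pc_spk = simulate_pc(pc_p, scenario.duration_ms, dt,
                                    g_exc_dend=g_exc_pc, e_exc=PF_PC.e_rev,
                                    g_inh_soma=g_inh_pc, e_inh=sc_pc.e_rev)
    spikes["PC"] = pc_spk
    voltages["PC_soma"] = vs
    voltages["PC_dend"] = vd

    lick_t, lick, strength = lick_rate_from_pc(
        pc_spk, scenario.duration_ms, l0=scenario.lick_l0,
        kernel_sd_ms=scenario.lick_kernel_sd_ms,
        baseline_window_ms=(0.0, scenario.t_odor_on_ms),
        odor_window_ms=(scenario.t_odor_on_ms, scenario.t_reward_ms))
    return CircuitOutput(t_ms=t, spikes=spikes, voltages=voltages,
                         lick_t_ms=lick_t, lick_rate=lick,
                         lick_strength=strength, scenario=scenario)


def condition_comparison(n_reps: int = 22, seed: int = 0,
                         glm_fn=None, **scenario_kwargs):
    """Replicate simulations for the saline/CNO x S+/S- design.

    Returns (table, (F, p, anova)) where the table has one lick_strength row
    per replicate and the test is a valence x drug linear model with
    interaction.
    """
    if n_reps < 10:
        raise ValueError("need n_reps >= 10")
    if glm_fn is None:
        from .glm import glm_test
        glm_fn = glm_test
    rows = []
    cond_offset = {("saline", "S+"): 0, ("saline", "S-"): 1,
                   ("CNO", "S+"): 2, ("CNO", "S-"): 3}
    for drug in ("saline", "CNO"):
        for valence in ("S+", "S-"):
            for r in range(n_reps):
                rep_seed = (seed * 100003 + cond_offset[(drug, valence)] * 10007
                            + r) % (2 ** 31)
                sc = CircuitScenario(drug=drug, valence=valence,
                                     seed=rep_seed, **scenario_kwargs)
                out = simulate_microcircuit(sc)
                rows.append({"drug": drug, "valence": valence, "rep": r,
                             "lick_strength": out.lick_strength})
    table = pd.DataFrame(rows)
    result = glm_fn(table["lick_strength"],
                    {"valence": table["valence"], "drug": table["drug"]},
                    interactions=True)
    return table, result
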
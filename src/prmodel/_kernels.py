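"""Compiled inner loops (numba) for the 0D/1D/2D solvers.

All kernels use the same scheme: exact (Rush–Larsen) integration of the
gating variables and forward-Euler update of Vm, both advanced from the
pre-step state.  Gate fractions are clamped to [0, 1] after each update as
a round-off safety net.  Kernels return a status code: 0 = ok, 1 = numerical
blow-up (non-finite or |Vm| > 1000 mV).

The ``use_minf`` flag selects the reduced two-variable (Vm, h) variant in
which m^3 is replaced by its steady-state value m_inf(Vm)^3.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BLOWUP = 1


@njit(cache=True, inline="always")
def _gate_inf(vm, e_half, slope):
    return 1.0 / (1.0 + np.exp((vm - e_half) / slope))


@njit(cache=True, inline="always")
def _tau_gate(vm, e_half, slope, tau0, delta):
    u = (vm - e_half) / slope
    return 2.0 * tau0 * np.exp(delta * u) / (1.0 + np.exp(u))


@njit(cache=True, inline="always")
def _i_na(vm, m, h, g_na, e_na):
    return g_na * m * m * m * h * (vm - e_na)


@njit(cache=True, inline="always")
def _i_k(vm, g_k, b, e_k):
    dv = vm - e_k
    return g_k * np.exp(-b * dv) * dv


@njit(cache=True, inline="always")
def _clip01(y):
    if y < 0.0:
        return 0.0
    if y > 1.0:
        return 1.0
    return y


@njit(cache=True, inline="always")
def _stim_at(t, amp, dur, period, count, onset):
    if t < onset:
        return 0.0
    rel = t - onset
    idx = int(rel // period) if period > 0.0 else 0
    if idx >= count:
        return 0.0
    if rel - idx * period < dur:
        return amp
    return 0.0


@njit(cache=True)
def cell_run(
    vm0, m0, h0,
    g_na, e_na, e_m, k_m, tau_m, e_h, k_h, tau_h0, delta_h,
    g_k, b, e_k, cm,
    stim_amp, stim_dur, stim_period, stim_count, stim_onset,
    dt, n_steps, stride, use_minf,
):
    """Single-cell run with a periodic pulse-train stimulus.

    Returns (status, times, vm, m, h, ina, ik, istim); samples are taken
    every ``stride`` steps starting at t = 0.
    """
    n_rec = n_steps // stride + 1
    t_out = np.empty(n_rec)
    vm_out = np.empty(n_rec)
    m_out = np.empty(n_rec)
    h_out = np.empty(n_rec)
    ina_out = np.empty(n_rec)
    ik_out = np.empty(n_rec)
    istim_out = np.empty(n_rec)

    vm = vm0
    m = m0
    h = h0
    status = STATUS_OK
    j = 0
    for step in range(n_steps + 1):
        t = step * dt
        mm = _gate_inf(vm, e_m, k_m) if use_minf else m
        ina = _i_na(vm, mm, h, g_na, e_na)
        ik = _i_k(vm, g_k, b, e_k)
        istim = _stim_at(t, stim_amp, stim_dur, stim_period, stim_count, stim_onset)
        if step % stride == 0:
            t_out[j] = t
            vm_out[j] = vm
            m_out[j] = mm
            h_out[j] = h
            ina_out[j] = ina
            ik_out[j] = ik
            istim_out[j] = istim
            j += 1
        if step == n_steps:
            break
        # gates and Vm both advance from the pre-step state
        h_inf = _gate_inf(vm, e_h, k_h)
        tau_h = _tau_gate(vm, e_h, k_h, tau_h0, delta_h)
        h = _clip01(h_inf + (h - h_inf) * np.exp(-dt / tau_h))
        if not use_minf:
            m_inf = _gate_inf(vm, e_m, k_m)
            m = _clip01(m_inf + (m - m_inf) * np.exp(-dt / tau_m))
        vm = vm - dt * (ina + ik + istim) / cm
        if not np.isfinite(vm) or abs(vm) > 1000.0:
            status = STATUS_BLOWUP
            break
    return (
        status,
        t_out[:j], vm_out[:j], m_out[:j], h_out[:j],
        ina_out[:j], ik_out[:j], istim_out[:j],
    )


@njit(cache=True)
def clamp_run(
    vm_wave,
    m0, h0,
    g_na, e_na, e_m, k_m, tau_m, e_h, k_h, tau_h0, delta_h,
    g_k, b, e_k,
    dt, stride, use_minf,
):
    """Action-potential clamp: Vm prescribed on the dt grid, gates free.

    ``vm_wave`` holds Vm at every step (length n_steps + 1).  Returns
    (times, vm, m, h, ina, ik) sampled every ``stride`` steps; IK is
    recorded for completeness though it has no feedback on Vm.
    """
    n_steps = vm_wave.shape[0] - 1
    n_rec = n_steps // stride + 1
    t_out = np.empty(n_rec)
    vm_out = np.empty(n_rec)
    m_out = np.empty(n_rec)
    h_out = np.empty(n_rec)
    ina_out = np.empty(n_rec)
    ik_out = np.empty(n_rec)

    m = m0
    h = h0
    j = 0
    for step in range(n_steps + 1):
        vm = vm_wave[step]
        mm = _gate_inf(vm, e_m, k_m) if use_minf else m
        if step % stride == 0:
            t_out[j] = step * dt
            vm_out[j] = vm
            m_out[j] = mm
            h_out[j] = h
            ina_out[j] = _i_na(vm, mm, h, g_na, e_na)
            ik_out[j] = _i_k(vm, g_k, b, e_k)
            j += 1
        if step == n_steps:
            break
        h_inf = _gate_inf(vm, e_h, k_h)
        tau_h = _tau_gate(vm, e_h, k_h, tau_h0, delta_h)
        h = _clip01(h_inf + (h - h_inf) * np.exp(-dt / tau_h))
        if not use_minf:
            m_inf = _gate_inf(vm, e_m, k_m)
            m = _clip01(m_inf + (m - m_inf) * np.exp(-dt / tau_m))
    return t_out[:j], vm_out[:j], m_out[:j], h_out[:j], ina_out[:j], ik_out[:j]


@njit(cache=True)
def cable_run(
    vm, m, h,
    g_na, e_na, e_m, k_m, tau_m, e_h, k_h, tau_h0, delta_h,
    g_k, b, e_k, cm,
    diffusion, dx, dt, n_steps,
    clamp_n, clamp_vm, clamp_t_end,
    rec_idx, stride, use_minf,
):
    """1D monodomain cable with no-flux (mirrored ghost node) ends.

    The wave is initiated by holding the first ``clamp_n`` nodes at
    ``clamp_vm`` until ``clamp_t_end``.  State arrays are updated in place;
    Vm and INa are recorded at the node indices in ``rec_idx`` every
    ``stride`` steps.  Returns (status, times, vm_rec, ina_rec).
    """
    n = vm.shape[0]
    n_sites = rec_idx.shape[0]
    n_rec = n_steps // stride + 1
    t_out = np.empty(n_rec)
    vm_rec = np.empty((n_rec, n_sites))
    ina_rec = np.empty((n_rec, n_sites))
    dvm = np.empty(n)

    r = diffusion / (dx * dx)
    status = STATUS_OK
    j = 0
    for step in range(n_steps + 1):
        t = step * dt
        if t <= clamp_t_end:
            for i in range(clamp_n):
                vm[i] = clamp_vm
        if step % stride == 0:
            t_out[j] = t
            for s in range(n_sites):
                i = rec_idx[s]
                mm = _gate_inf(vm[i], e_m, k_m) if use_minf else m[i]
                vm_rec[j, s] = vm[i]
                ina_rec[j, s] = _i_na(vm[i], mm, h[i], g_na, e_na)
            j += 1
        if step == n_steps:
            break
        for i in range(n):
            left = vm[i - 1] if i > 0 else vm[0]
            right = vm[i + 1] if i < n - 1 else vm[n - 1]
            lap = left - 2.0 * vm[i] + right
            mm = _gate_inf(vm[i], e_m, k_m) if use_minf else m[i]
            ion = _i_na(vm[i], mm, h[i], g_na, e_na) + _i_k(vm[i], g_k, b, e_k)
            dvm[i] = dt * (r * lap - ion / cm)
            h_inf = _gate_inf(vm[i], e_h, k_h)
            tau_h = _tau_gate(vm[i], e_h, k_h, tau_h0, delta_h)
            h[i] = _clip01(h_inf + (h[i] - h_inf) * np.exp(-dt / tau_h))
            if not use_minf:
                m_inf = _gate_inf(vm[i], e_m, k_m)
                m[i] = _clip01(m_inf + (m[i] - m_inf) * np.exp(-dt / tau_m))
        ok = True
        for i in range(n):
            vm[i] = vm[i] + dvm[i]
            if not np.isfinite(vm[i]) or abs(vm[i]) > 1000.0:
                ok = False
        if not ok:
            status = STATUS_BLOWUP
            break
    return status, t_out[:j], vm_rec[:j], ina_rec[:j]


def build_gate_tables(
    e_m, k_m, e_h, k_h, tau_h0, delta_h, g_k, b, e_k, dt,
    vm_min=-250.0, vm_max=250.0, n_tab=20001,
):
    """Voltage-indexed lookup tables for the tissue inner loop.

    Tabulates m_inf, h_inf, exp(-dt/tau_h(Vm)) and IK(Vm) on a uniform Vm
    grid; the tissue kernel interpolates linearly.  With a 0.025 mV grid
    the interpolation error is far below the discretization error of the
    PDE solve.
    """
    v = np.linspace(vm_min, vm_max, n_tab)
    m_inf = 1.0 / (1.0 + np.exp((v - e_m) / k_m))
    u = (v - e_h) / k_h
    h_inf = 1.0 / (1.0 + np.exp(u))
    tau_h = 2.0 * tau_h0 * np.exp(delta_h * u) / (1.0 + np.exp(u))
    h_decay = np.exp(-dt / tau_h)
    dv = v - e_k
    ik = g_k * np.exp(-b * dv) * dv
    inv_step = (n_tab - 1) / (vm_max - vm_min)
    return vm_min, inv_step, m_inf, h_inf, h_decay, ik


@njit(cache=True, inline="always")
def _lut(table, v, vm_min, inv_step):
    x = (v - vm_min) * inv_step
    if x < 0.0:
        x = 0.0
    elif x > table.shape[0] - 1.001:
        x = table.shape[0] - 1.001
    i = int(x)
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(cache=True, fastmath=True)
def tissue_run(
    vm, m, h,
    g_na, e_na, tau_m,
    vm_min, inv_step, m_inf_tab, h_inf_tab, h_decay_tab, ik_tab,
    cm,
    diffusion, dx, dt, n_steps,
    stim_fields, stim_start, stim_dur,
    site_iy, site_ix, stride,
    snap_every, snapshots,
    use_minf,
):
    """2D monodomain sheet, 5-point Laplacian, no-flux boundaries.

    Gate functions and IK enter through the lookup tables from
    :func:`build_gate_tables` (built for this run's dt).  ``stim_fields``
    is a (n_stim, ny, nx) array of per-node stimulus amplitudes (uA/uF),
    each active on [stim_start[k], stim_start[k] + stim_dur[k]).  Site
    traces (Vm) are recorded every ``stride`` steps; full-field float32
    snapshots every ``snap_every`` steps into the preallocated
    ``snapshots`` array (pass shape (0, ny, nx) to disable).
    Returns (status, times, vm_sites, n_snap).
    """
    ny, nx = vm.shape
    m_decay = np.exp(-dt / tau_m)
    n_stim = stim_fields.shape[0]
    n_sites = site_iy.shape[0]
    n_rec = n_steps // stride + 1
    t_out = np.empty(n_rec)
    vm_sites = np.empty((n_rec, n_sites))
    max_snap = snapshots.shape[0]
    dvm = np.empty((ny, nx))

    r = diffusion / (dx * dx)
    status = STATUS_OK
    j = 0
    n_snap = 0
    for step in range(n_steps + 1):
        t = step * dt
        if step % stride == 0:
            t_out[j] = t
            for s in range(n_sites):
                vm_sites[j, s] = vm[site_iy[s], site_ix[s]]
            j += 1
        if max_snap > 0 and step % snap_every == 0 and n_snap < max_snap:
            for iy in range(ny):
                for ix in range(nx):
                    snapshots[n_snap, iy, ix] = vm[iy, ix]
            n_snap += 1
        if step == n_steps:
            break
        any_stim = False
        for ks in range(n_stim):
            if stim_start[ks] <= t < stim_start[ks] + stim_dur[ks]:
                any_stim = True
        for iy in range(ny):
            for ix in range(nx):
                v = vm[iy, ix]
                up = vm[iy - 1, ix] if iy > 0 else vm[0, ix]
                dn = vm[iy + 1, ix] if iy < ny - 1 else vm[ny - 1, ix]
                lf = vm[iy, ix - 1] if ix > 0 else vm[iy, 0]
                rt = vm[iy, ix + 1] if ix < nx - 1 else vm[iy, nx - 1]
                lap = up + dn + lf + rt - 4.0 * v
                m_inf = _lut(m_inf_tab, v, vm_min, inv_step)
                mm = m_inf if use_minf else m[iy, ix]
                ion = g_na * mm * mm * mm * h[iy, ix] * (v - e_na) + _lut(
                    ik_tab, v, vm_min, inv_step
                )
                istim = 0.0
                if any_stim:
                    for ks in range(n_stim):
                        if stim_start[ks] <= t < stim_start[ks] + stim_dur[ks]:
                            istim += stim_fields[ks, iy, ix]
                dvm[iy, ix] = dt * (r * lap - (ion + istim) / cm)
                h_inf = _lut(h_inf_tab, v, vm_min, inv_step)
                h_dec = _lut(h_decay_tab, v, vm_min, inv_step)
                h[iy, ix] = _clip01(h_inf + (h[iy, ix] - h_inf) * h_dec)
                if not use_minf:
                    m[iy, ix] = _clip01(m_inf + (m[iy, ix] - m_inf) * m_decay)
        ok = True
        for iy in range(ny):
            for ix in range(nx):
                vm[iy, ix] = vm[iy, ix] + dvm[iy, ix]
                if not np.isfinite(vm[iy, ix]) or abs(vm[iy, ix]) > 1000.0:
                    ok = False
        if not ok:
            status = STATUS_BLOWUP
            break
    return status, t_out[:j], vm_sites[:j], n_snap
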
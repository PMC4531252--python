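"""Low-level numba kernels for the closed-loop engine.

Internal module.  Bookkeeping times are integer nanoseconds; dynamics run in
milliseconds.  Units: mV, pA, nS, pF, ms.

Parameter-vector layout (float64[14]): C, k, v_r, v_t, a, b, c, d, v_peak,
E_exc, E_inh, tau_exc, tau_inh, literal_eq3_flag.
"""

import numpy as np
from numba import njit

NS_PER_MS = 1_000_000

(P_C, P_K, P_VR, P_VT, P_A, P_B, P_CRESET, P_D, P_VPEAK,
 P_EEXC, P_EINH, P_TEXC, P_TINH, P_LITERAL) = range(14)

LCG_A = 1664525
LCG_C = 1013904223
LCG_MOD = 4294967296  # 2**32


@njit(cache=True)
def lcg_step(x):
    return (LCG_A * x + LCG_C) & 0xFFFFFFFF


@njit(cache=True)
def lcg_fill(x, out):
    # fills `out` with successive 32-bit states, returns the final state
    for i in range(out.shape[0]):
        x = (LCG_A * x + LCG_C) & 0xFFFFFFFF
        out[i] = x
    return x


@njit(cache=True)
def rhs(v, u, ge, gi, p):
    dv = (p[P_K] * (v - p[P_VR]) * (v - p[P_VT]) - u
          - ge * (v - p[P_EEXC]) - gi * (v - p[P_EINH])) / p[P_C]
    if p[P_LITERAL] != 0.0:
        du = p[P_A] * (p[P_B] * v - u)
    else:
        du = p[P_A] * (p[P_B] * (v - p[P_VR]) - u)
    return dv, du, -ge / p[P_TEXC], -gi / p[P_TINH]


@njit(cache=True)
def _ps_series(v0, u0, e0, g0, h, p, max_order, tol, ws):
    """Power-series coefficients around the current state.

    ws rows: cv, cu, ce, cg, s1, s2 (each max_order+1 long).  Returns the
    truncation order if the series converged (two consecutive increments at
    tau=h below tol), else -1 with all coefficients filled to max_order.
    """
    cv = ws[0]; cu = ws[1]; ce = ws[2]; cg = ws[3]; s1 = ws[4]; s2 = ws[5]
    cv[0] = v0; cu[0] = u0; ce[0] = e0; cg[0] = g0
    s1[0] = v0 - p[P_VR]
    s2[0] = v0 - p[P_VT]
    run = 0
    hn = 1.0
    for n in range(max_order):
        q = 0.0
        ev = 0.0
        gv = 0.0
        for m in range(n + 1):
            q += s1[m] * s2[n - m]
            ev += ce[m] * cv[n - m]
            gv += cg[m] * cv[n - m]
        vn1 = (p[P_K] * q - cu[n] - ev + p[P_EEXC] * ce[n]
               - gv + p[P_EINH] * cg[n]) / (p[P_C] * (n + 1))
        if p[P_LITERAL] != 0.0:
            un1 = p[P_A] * (p[P_B] * cv[n] - cu[n]) / (n + 1)
        else:
            un1 = p[P_A] * (p[P_B] * s1[n] - cu[n]) / (n + 1)
        en1 = -ce[n] / (p[P_TEXC] * (n + 1))
        gn1 = -cg[n] / (p[P_TINH] * (n + 1))
        cv[n + 1] = vn1; cu[n + 1] = un1; ce[n + 1] = en1; cg[n + 1] = gn1
        s1[n + 1] = vn1; s2[n + 1] = vn1
        hn *= h
        inc = max(abs(vn1), abs(un1), abs(en1), abs(gn1)) * hn
        if inc < tol:
            run += 1
            if run >= 2:
                return n + 1
        else:
            run = 0
    return -1


@njit(cache=True)
def _ps_eval(c, order, tau):
    acc = c[order]
    for n in range(order - 1, -1, -1):
        acc = acc * tau + c[n]
    return acc


@njit(cache=True)
def ps_advance(y, h, p, max_order, tol, ws, spk_out, n0):
    """Advance y = (v, u, g_exc, g_inh) by h ms; no events inside the interval.

    Splits the interval adaptively: a non-convergent series halves the local
    step.  Threshold crossings are located by bisection on the polynomial,
    the Eq-6 reset is applied, and spike offsets (ms) are appended to spk_out
    starting at n0.  Returns the updated spike count.
    """
    cv = ws[0]; cu = ws[1]; ce = ws[2]; cg = ws[3]
    t = 0.0
    n_sp = n0
    while t < h - 1e-12:
        step = h - t
        while True:
            order = _ps_series(y[0], y[1], y[2], y[3], step, p, max_order, tol, ws)
            if order > 0:
                break
            if step < 1e-7:
                order = max_order
                break
            step *= 0.5
        v_end = _ps_eval(cv, order, step)
        if v_end >= p[P_VPEAK]:
            lo = 0.0
            hi = step
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if _ps_eval(cv, order, mid) >= p[P_VPEAK]:
                    hi = mid
                else:
                    lo = mid
            tau = hi
            y[1] = _ps_eval(cu, order, tau) + p[P_D]
            y[2] = _ps_eval(ce, order, tau)
            y[3] = _ps_eval(cg, order, tau)
            y[0] = p[P_CRESET]
            if n_sp < spk_out.shape[0]:
                spk_out[n_sp] = t + tau
                n_sp += 1
            if tau <= 0.0:
                tau = 1e-9  # guard: never stall at the boundary
            t += tau
        else:
            y[0] = v_end
            y[1] = _ps_eval(cu, order, step)
            y[2] = _ps_eval(ce, order, step)
            y[3] = _ps_eval(cg, order, step)
            t += step
    return n_sp


@njit(cache=True)
def rk4_reference(y, t_end_ms, dt_ms, ev_t_ms, ev_dg, ev_is_inh, p, v_trace, spk_out):
    """Fixed-step RK4 oracle for testing the PS integrator.

    Events are applied at the first grid point at/after their time.  Records v
    after every step into v_trace when it is non-empty.  Returns spike count.
    """
    n_steps = int(round(t_end_ms / dt_ms))
    iev = 0
    n_sp = 0
    rec = v_trace.shape[0] > 0
    if rec:
        v_trace[0] = y[0]
    for i in range(n_steps):
        t = i * dt_ms
        while iev < ev_t_ms.shape[0] and ev_t_ms[iev] <= t + 1e-12:
            if ev_is_inh[iev]:
                y[3] += ev_dg[iev]
            else:
                y[2] += ev_dg[iev]
            iev += 1
        a1, b1, c1, d1 = rhs(y[0], y[1], y[2], y[3], p)
        a2, b2, c2, d2 = rhs(y[0] + 0.5 * dt_ms * a1, y[1] + 0.5 * dt_ms * b1,
                             y[2] + 0.5 * dt_ms * c1, y[3] + 0.5 * dt_ms * d1, p)
        a3, b3, c3, d3 = rhs(y[0] + 0.5 * dt_ms * a2, y[1] + 0.5 * dt_ms * b2,
                             y[2] + 0.5 * dt_ms * c2, y[3] + 0.5 * dt_ms * d2, p)
        a4, b4, c4, d4 = rhs(y[0] + dt_ms * a3, y[1] + dt_ms * b3,
                             y[2] + dt_ms * c3, y[3] + dt_ms * d3, p)
        y[0] += dt_ms * (a1 + 2 * a2 + 2 * a3 + a4) / 6.0
        y[1] += dt_ms * (b1 + 2 * b2 + 2 * b3 + b4) / 6.0
        y[2] += dt_ms * (c1 + 2 * c2 + 2 * c3 + c4) / 6.0
        y[3] += dt_ms * (d1 + 2 * d2 + 2 * d3 + d4) / 6.0
        if y[0] >= p[P_VPEAK]:
            if n_sp < spk_out.shape[0]:
                spk_out[n_sp] = t + dt_ms
                n_sp += 1
            y[0] = p[P_CRESET]
            y[1] += p[P_D]
        if rec:
            v_trace[i + 1] = y[0]
    return n_sp


@njit(cache=True)
def run_chunk(t0_ns, n_ticks, tick_ns, step_ns,
              lcg, n_units_a, p_spike, direct, record_cortex,
              inj_t, inj_src, n_inj,
              Y, p, max_order, tol,
              syn_pre, syn_post, syn_w, syn_delay, syn_inh,
              out_ptr, out_idx, plast_ptr, plast_idx,
              ev_t, ev_w, ev_inh, ev_src, ev_n,
              last_pre, elig_trig, pair_ns,
              counters,
              c_spk_t, c_spk_id, m_spk_t, m_spk_id,
              ws, spk_buf, sub_t, sub_w, sub_inh, sub_src):
    """Advance the whole network by n_ticks synthesizer ticks (tick_ns each).

    Per tick: one LCG draw per cortical unit in fixed unit order (spike if
    x/2^32 < p_spike); units < n_units_a draw from lcg[0] (the primary
    synthesizer), the rest from lcg[1] (the separate stress synthesizer).
    Then tick_ns//step_ns global neuron steps, each split at incoming
    synaptic events.  Neuron spikes schedule delayed events to their
    targets, stamp eligibility triggers on plastic synapses, and are written
    to m_spk_*.  counters = [scheduled, delivered].
    """
    n_units = p_spike.shape[0]
    n_msn = Y.shape[0]
    cap = ev_t.shape[1]
    nc = 0
    nm = 0
    for q in range(n_inj):
        s_id = inj_src[q]
        t_sp = inj_t[q]
        last_pre[s_id] = t_sp
        for si in range(out_ptr[s_id], out_ptr[s_id + 1]):
            s = out_idx[si]
            j = syn_post[s]
            nn = ev_n[j]
            if nn >= cap:
                raise RuntimeError("synaptic event buffer overflow")
            ev_t[j, nn] = t_sp + syn_delay[s]
            ev_w[j, nn] = syn_w[s]
            ev_inh[j, nn] = syn_inh[s]
            ev_src[j, nn] = s_id
            ev_n[j] = nn + 1
            counters[0] += 1
    steps_per_tick = tick_ns // step_ns
    x = lcg[0]
    xb = lcg[1]
    for k in range(n_ticks):
        t_tick = t0_ns + k * tick_ns
        for iu in range(n_units):
            if iu < n_units_a:
                x = (LCG_A * x + LCG_C) & 0xFFFFFFFF
                draw = x
            else:
                xb = (LCG_A * xb + LCG_C) & 0xFFFFFFFF
                draw = xb
            if draw < p_spike[iu] * 4294967296.0:
                if record_cortex:
                    c_spk_t[nc] = t_tick
                    c_spk_id[nc] = iu
                    nc += 1
                if direct:
                    last_pre[iu] = t_tick
                    for si in range(out_ptr[iu], out_ptr[iu + 1]):
                        s = out_idx[si]
                        j = syn_post[s]
                        nn = ev_n[j]
                        if nn >= cap:
                            raise RuntimeError("synaptic event buffer overflow")
                        ev_t[j, nn] = t_tick + syn_delay[s]
                        ev_w[j, nn] = syn_w[s]
                        ev_inh[j, nn] = syn_inh[s]
                        ev_src[j, nn] = iu
                        ev_n[j] = nn + 1
                        counters[0] += 1
        for st in range(steps_per_tick):
            ts = t_tick + st * step_ns
            te = ts + step_ns
            for j in range(n_msn):
                nd = 0
                mm = 0
                while mm < ev_n[j]:
                    if ev_t[j, mm] < te:
                        sub_t[nd] = ev_t[j, mm]
                        sub_w[nd] = ev_w[j, mm]
                        sub_inh[nd] = ev_inh[j, mm]
                        sub_src[nd] = ev_src[j, mm]
                        nd += 1
                        last = ev_n[j] - 1
                        ev_t[j, mm] = ev_t[j, last]
                        ev_w[j, mm] = ev_w[j, last]
                        ev_inh[j, mm] = ev_inh[j, last]
                        ev_src[j, mm] = ev_src[j, last]
                        ev_n[j] = last
                    else:
                        mm += 1
                # stable order: delivery time, then source id
                for a in range(1, nd):
                    tt = sub_t[a]; ww = sub_w[a]; ff = sub_inh[a]; ss = sub_src[a]
                    b = a - 1
                    while b >= 0 and (sub_t[b] > tt or (sub_t[b] == tt and sub_src[b] > ss)):
                        sub_t[b + 1] = sub_t[b]
                        sub_w[b + 1] = sub_w[b]
                        sub_inh[b + 1] = sub_inh[b]
                        sub_src[b + 1] = sub_src[b]
                        b -= 1
                    sub_t[b + 1] = tt; sub_w[b + 1] = ww; sub_inh[b + 1] = ff; sub_src[b + 1] = ss
                counters[1] += nd
                t_cur = ts
                y = Y[j]
                for ei in range(nd + 1):
                    t_next = sub_t[ei] if ei < nd else te
                    if t_next > t_cur:
                        h = (t_next - t_cur) / 1.0e6
                        nsp = ps_advance(y, h, p, max_order, tol, ws, spk_buf, 0)
                        for q2 in range(nsp):
                            t_sp = t_cur + int(round(spk_buf[q2] * 1.0e6))
                            if nm >= m_spk_t.shape[0]:
                                raise RuntimeError("neuron spike buffer overflow")
                            m_spk_t[nm] = t_sp
                            m_spk_id[nm] = j
                            nm += 1
                            src_id = n_units + j
                            last_pre[src_id] = t_sp
                            for si in range(out_ptr[src_id], out_ptr[src_id + 1]):
                                s = out_idx[si]
                                jj = syn_post[s]
                                nn = ev_n[jj]
                                if nn >= cap:
                                    raise RuntimeError("synaptic event buffer overflow")
                                ev_t[jj, nn] = t_sp + syn_delay[s]
                                ev_w[jj, nn] = syn_w[s]
                                ev_inh[jj, nn] = syn_inh[s]
                                ev_src[jj, nn] = src_id
                                ev_n[jj] = nn + 1
                                counters[0] += 1
                            for si in range(plast_ptr[j], plast_ptr[j + 1]):
                                s = plast_idx[si]
                                dtp = t_sp - last_pre[syn_pre[s]]
                                if dtp > 0 and dtp <= pair_ns:
                                    elig_trig[s] = t_sp
                        t_cur = t_next
                    if ei < nd:
                        if sub_inh[ei]:
                            y[3] += sub_w[ei]
                        else:
                            y[2] += sub_w[ei]
    lcg[0] = x
    lcg[1] = xb
    return nc, nm
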
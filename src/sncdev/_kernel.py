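"""Numba time-stepping kernel for the branched cable equation.

Implicit (backward-Euler) voltage update with a Hines-ordered direct solve
of the tree system each step; gates advance by Rush-Larsen exponential
updates staggered with the voltage solve.  Unconditionally stable at the
default dt with stiff AIS sodium densities.

Units: mV, ms, nA, µS, nF, mM.
"""

import numpy as np
from numba import njit

# CHANNELS order: Na, KDR, A, CaL, KCa, H, leak
# kinetics vector layout (see channels.pack_kinetics):
#   8 gates x 7 params: Na-m, Na-h, KDR-n, A-a, A-b(dend), A-b(soma),
#   CaL-d, H-q; then SK kd, hill, tau; then E_Na, E_K, E_Ca, E_H, E_leak
NG = 8
_SK0 = NG * 7


@njit(cache=True, inline="always")
def _xinf(v, vh, k):
    return 1.0 / (1.0 + np.exp(-(v - vh) / k))


@njit(cache=True, inline="always")
def _xtau(v, tmin, tamp, vt, s1, s2):
    return tmin + tamp / (np.exp((v - vt) / s1) + np.exp(-(v - vt) / s2))


@njit(cache=True, inline="always")
def _gate_upd(x, v, kp, g, dt):
    o = g * 7
    inf = _xinf(v, kp[o], kp[o + 1])
    tau = _xtau(v, kp[o + 2], kp[o + 3], kp[o + 4], kp[o + 5], kp[o + 6])
    return inf + (x - inf) * np.exp(-dt / tau)


@njit(cache=True)
def init_gates(v, ca, soma_flag, kp):
    n = v.shape[0]
    gates = np.empty((NG, n))
    for i in range(n):
        for g in range(NG):
            gi = g
            if g == 4 and soma_flag[i] != 0.0:
                gi = 5  # somatic A-inactivation variant
            o = gi * 7
            gates[g, i] = _xinf(v[i], kp[o], kp[o + 1])
    kd, hill = kp[_SK0], kp[_SK0 + 1]
    z = np.empty(n)
    for i in range(n):
        cn = max(ca[i], 0.0) ** hill
        z[i] = cn / (cn + kd ** hill)
    return gates, z


@njit(cache=True)
def run(v, gates, z, ca, parent, gax, cm, gdens, soma_flag, kp,
        carest, tauca, cafac,
        stim_comp, stim_amp, stim_t0, stim_t1,
        dt, nsteps, rec_idx, rec_stride, vout, caout, theta):
    """Advance the model ``nsteps`` steps.  Returns -1 on success or the
    step index at which the state became non-finite."""
    n = v.shape[0]
    diag = np.empty(n)
    rhs = np.empty(n)
    kd, hill, tausk = kp[_SK0], kp[_SK0 + 1], kp[_SK0 + 2]
    e_na, e_k, e_ca, e_h, e_lk = (kp[_SK0 + 3], kp[_SK0 + 4], kp[_SK0 + 5],
                                  kp[_SK0 + 6], kp[_SK0 + 7])
    nrec = rec_idx.shape[0]
    irow = 0
    for m_ in range(nrec):
        vout[0, m_] = v[rec_idx[m_]]
        caout[0, m_] = ca[rec_idx[m_]]
    irow = 1

    for step in range(nsteps):
        t = step * dt
        # --- gates (Rush-Larsen at current voltage) -----------------------
        for i in range(n):
            vi = v[i]
            gates[0, i] = _gate_upd(gates[0, i], vi, kp, 0, dt)  # Na m
            gates[1, i] = _gate_upd(gates[1, i], vi, kp, 1, dt)  # Na h
            gates[2, i] = _gate_upd(gates[2, i], vi, kp, 2, dt)  # KDR n
            gates[3, i] = _gate_upd(gates[3, i], vi, kp, 3, dt)  # A a
            gb = 5 if soma_flag[i] != 0.0 else 4
            gates[4, i] = _gate_upd(gates[4, i], vi, kp, gb, dt)  # A b
            gates[6, i] = _gate_upd(gates[6, i], vi, kp, 6, dt)  # CaL d
            gates[7, i] = _gate_upd(gates[7, i], vi, kp, 7, dt)  # H q
            # SK: Hill of calcium, fixed tau
            cn = max(ca[i], 0.0) ** hill
            zinf = cn / (cn + kd ** hill)
            z[i] = zinf + (z[i] - zinf) * np.exp(-dt / tausk)

        # --- membrane conductances and implicit system --------------------
        # theta-weighted implicit step (theta = 1: backward Euler;
        # theta = 0.5: Crank-Nicolson); conductances held at their
        # post-gate-update values within the step
        for i in range(n):
            m3h = gates[0, i] ** 3 * gates[1, i]
            n3 = gates[2, i] ** 3
            a2b = gates[3, i] ** 2 * gates[4, i]
            gna = gdens[i, 0] * m3h
            gkdr = gdens[i, 1] * n3
            ga = gdens[i, 2] * a2b
            gca = gdens[i, 3] * gates[6, i]
            gsk = gdens[i, 4] * z[i]
            gh = gdens[i, 5] * gates[7, i]
            glk = gdens[i, 6]
            gsum = gna + gkdr + ga + gca + gsk + gh + glk
            gesum = (gna * e_na + (gkdr + ga + gsk) * e_k + gca * e_ca
                     + gh * e_h + glk * e_lk)
            diag[i] = cm[i] / dt + theta * gsum
            rhs[i] = (cm[i] / dt - (1.0 - theta) * gsum) * v[i] + gesum
        for s in range(stim_comp.shape[0]):
            if stim_t0[s] <= t < stim_t1[s]:
                rhs[stim_comp[s]] += stim_amp[s]
        for i in range(1, n):
            p = parent[i]
            diag[i] += theta * gax[i]
            diag[p] += theta * gax[i]
            ax = (1.0 - theta) * gax[i] * (v[p] - v[i])
            rhs[i] += ax
            rhs[p] -= ax

        # --- Hines solve (children ordered after parents) ------------------
        for i in range(n - 1, 0, -1):
            f = theta * gax[i] / diag[i]
            p = parent[i]
            diag[p] -= f * theta * gax[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] + theta * gax[i] * v[parent[i]]) / diag[i]

        # --- calcium pool ---------------------------------------------------
        for i in range(n):
            if gdens[i, 3] > 0.0 or ca[i] != carest:
                ica = gdens[i, 3] * gates[6, i] * (v[i] - e_ca)
                influx = -ica * cafac[i]
                if influx < 0.0:
                    influx = 0.0
                ca[i] = (ca[i] + dt * (influx + carest / tauca)) / (1.0 + dt / tauca)

        if (step + 1) % rec_stride == 0 and irow < vout.shape[0]:
            for m_ in range(nrec):
                vout[irow, m_] = v[rec_idx[m_]]
                caout[irow, m_] = ca[rec_idx[m_]]
            irow += 1
        if (step % 1000) == 999:
            ok = True
            for i in range(n):
                if not np.isfinite(v[i]):
                    ok = False
            if not ok:
                return step
    return -1
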
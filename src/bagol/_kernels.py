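"""Fused numba kernels for the reversible-jump sampler.

These implement exactly the updates specified in `model.py` (the readable
reference), as tight loops over flat arrays so that a full chain on a
subregion with ~10^3 localizations runs in about a second.  All randomness
flows through numba's np.random state, seeded once per chain, so a chain is
reproducible from its seed.

Conventions: per-axis weights w = 1/sigma^2; emitter arrays are fixed-size
buffers of capacity ``k_cap`` with the first K slots live; allocations Z
index those slots.  Count-model codes: 0 = Poisson(lam), 1 = negative
binomial (gamma-mixed Poisson) with shape eta and mean gam.
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def _count_logterm(n, model, lam, eta, gam):
    """Per-emitter allocation-prior term log[P(n) * n!].

    The generative model draws an unordered set of localizations per
    emitter, so a labeled allocation vector with counts {n_k} carries the
    prior prod_k P(n_k) * n_k! / N!; the N! is allocation-independent and
    cancels from every ratio.  For Poisson counts the term reduces to
    n log(lam) - lam.
    """
    if model == 0:  # Poisson
        if n == 0.0:
            return -lam
        return n * math.log(lam) - lam
    # negative binomial, r = eta, mean = gam
    return (math.lgamma(n + eta) - math.lgamma(eta)
            + eta * math.log(eta / (eta + gam)) + n * math.log(gam / (eta + gam)))


@njit(cache=True)
def _move(K, mux, muy, ax, ay, Z, nk, x, y, wx, wy, t,
          bx0, bx1, by0, by1, drift, tau):
    """Gibbs draw of (mu_k, a_k) for every emitter; always accepted."""
    N = x.size
    sw_x = np.zeros(K)
    st_x = np.zeros(K)
    stt_x = np.zeros(K)
    sv_x = np.zeros(K)
    svt_x = np.zeros(K)
    sw_y = np.zeros(K)
    st_y = np.zeros(K)
    stt_y = np.zeros(K)
    sv_y = np.zeros(K)
    svt_y = np.zeros(K)
    for i in range(N):
        k = Z[i]
        ti = t[i]
        sw_x[k] += wx[i]
        st_x[k] += wx[i] * ti
        stt_x[k] += wx[i] * ti * ti
        sv_x[k] += wx[i] * x[i]
        svt_x[k] += wx[i] * x[i] * ti
        sw_y[k] += wy[i]
        st_y[k] += wy[i] * ti
        stt_y[k] += wy[i] * ti * ti
        sv_y[k] += wy[i] * y[i]
        svt_y[k] += wy[i] * y[i] * ti
    inv_tau2 = 0.0 if tau <= 0.0 else 1.0 / (tau * tau)
    for k in range(K):
        if nk[k] == 0:
            mux[k] = bx0 + (bx1 - bx0) * np.random.random()
            muy[k] = by0 + (by1 - by0) * np.random.random()
            ax[k] = 0.0
            ay[k] = 0.0
            continue
        if drift:
            # x axis
            p11 = sw_x[k]
            p12 = st_x[k]
            p22 = stt_x[k] + inv_tau2
            det = p11 * p22 - p12 * p12
            m_mu = (p22 * sv_x[k] - p12 * svt_x[k]) / det
            m_a = (p11 * svt_x[k] - p12 * sv_x[k]) / det
            c11 = p22 / det
            c12 = -p12 / det
            c22 = p11 / det
            l11 = math.sqrt(c11)
            l21 = c12 / l11
            l22 = math.sqrt(max(c22 - l21 * l21, 0.0))
            z1 = np.random.standard_normal()
            z2 = np.random.standard_normal()
            mux[k] = m_mu + l11 * z1
            ax[k] = m_a + l21 * z1 + l22 * z2
            # y axis
            p11 = sw_y[k]
            p12 = st_y[k]
            p22 = stt_y[k] + inv_tau2
            det = p11 * p22 - p12 * p12
            m_mu = (p22 * sv_y[k] - p12 * svt_y[k]) / det
            m_a = (p11 * svt_y[k] - p12 * sv_y[k]) / det
            c11 = p22 / det
            c12 = -p12 / det
            c22 = p11 / det
            l11 = math.sqrt(c11)
            l21 = c12 / l11
            l22 = math.sqrt(max(c22 - l21 * l21, 0.0))
            z1 = np.random.standard_normal()
            z2 = np.random.standard_normal()
            muy[k] = m_mu + l11 * z1
            ay[k] = m_a + l21 * z1 + l22 * z2
        else:
            mux[k] = sv_x[k] / sw_x[k] + np.random.standard_normal() / math.sqrt(sw_x[k])
            muy[k] = sv_y[k] / sw_y[k] + np.random.standard_normal() / math.sqrt(sw_y[k])
            ax[k] = 0.0
            ay[k] = 0.0


@njit(cache=True)
def _allocate(K, mux, muy, ax, ay, Z, nk, x, y, wx, wy, t,
              model, lam, eta, gam, z_new, nk_new, logp):
    """Likelihood-weighted reallocation proposal; MH-corrected by the count prior."""
    N = x.size
    for k in range(K):
        nk_new[k] = 0
    for i in range(N):
        ti = t[i]
        xi = x[i]
        yi = y[i]
        wxi = wx[i]
        wyi = wy[i]
        mx = -1.0e300
        for k in range(K):
            dx = xi - (mux[k] + ax[k] * ti)
            dy = yi - (muy[k] + ay[k] * ti)
            lp = -0.5 * (wxi * dx * dx + wyi * dy * dy)
            logp[k] = lp
            if lp > mx:
                mx = lp
        s = 0.0
        for k in range(K):
            p = math.exp(logp[k] - mx)
            logp[k] = p
            s += p
        u = np.random.random() * s
        c = 0.0
        ksel = K - 1
        for k in range(K):
            c += logp[k]
            if u <= c:
                ksel = k
                break
        z_new[i] = ksel
        nk_new[ksel] += 1
    dlog = 0.0
    for k in range(K):
        dlog += (_count_logterm(float(nk_new[k]), model, lam, eta, gam)
                 - _count_logterm(float(nk[k]), model, lam, eta, gam))
    if math.log(np.random.random()) < dlog:
        for i in range(N):
            Z[i] = z_new[i]
        for k in range(K):
            nk[k] = nk_new[k]
        return True
    return False


@njit(cache=True)
def _birth_density(px, py, x, y, wx, wy, V):
    """Density of the 50:50 uniform / data-centered birth proposal."""
    N = x.size
    s = 0.0
    for i in range(N):
        dx = px - x[i]
        dy = py - y[i]
        s += (math.sqrt(wx[i] * wy[i]) / TWO_PI
              * math.exp(-0.5 * (wx[i] * dx * dx + wy[i] * dy * dy)))
    return 0.5 / V + 0.5 * s / N


@njit(cache=True)
def _birth(K, k_cap, mux, muy, ax, ay, Z, nk, x, y, wx, wy, t,
           bx0, bx1, by0, by1, model, lam, eta, gam,
           p_birth, p_death, drift, tau, z_new, nk_new, logp, pbuf):
    """Reversible-jump birth; returns the (possibly unchanged) K."""
    if K + 1 > k_cap:
        return K
    N = x.size
    V = (bx1 - bx0) * (by1 - by0)
    if np.random.random() < 0.5:
        px = bx0 + (bx1 - bx0) * np.random.random()
        py = by0 + (by1 - by0) * np.random.random()
    else:
        i = np.random.randint(0, N)
        px = x[i] + np.random.standard_normal() / math.sqrt(wx[i])
        py = y[i] + np.random.standard_normal() / math.sqrt(wy[i])
        if px < bx0 or px > bx1 or py < by0 or py > by1:
            return K  # outside the prior support: A = 0
    b = _birth_density(px, py, x, y, wx, wy, V)
    mux[K] = px
    muy[K] = py
    if drift:
        ax[K] = tau * np.random.standard_normal()
        ay[K] = tau * np.random.standard_normal()
    else:
        ax[K] = 0.0
        ay[K] = 0.0
    kn = K + 1
    for k in range(kn):
        nk_new[k] = 0
    log_ratio = 0.0
    for i in range(N):
        ti = t[i]
        xi = x[i]
        yi = y[i]
        wxi = wx[i]
        wyi = wy[i]
        mx = -1.0e300
        for k in range(kn):
            dx = xi - (mux[k] + ax[k] * ti)
            dy = yi - (muy[k] + ay[k] * ti)
            lp = -0.5 * (wxi * dx * dx + wyi * dy * dy)
            logp[k] = lp
            if lp > mx:
                mx = lp
        s_all = 0.0
        s_old = 0.0
        for k in range(kn):
            p = math.exp(logp[k] - mx)
            pbuf[k] = p
            s_all += p
            if k < K:
                s_old += p
        if s_old <= 0.0:
            log_ratio += math.log(s_all) + 745.0  # old model cannot explain i
        else:
            log_ratio += math.log(s_all) - math.log(s_old)
        u = np.random.random() * s_all
        c = 0.0
        ksel = kn - 1
        for k in range(kn):
            c += pbuf[k]
            if u <= c:
                ksel = k
                break
        z_new[i] = ksel
        nk_new[ksel] += 1
    dcount = 0.0
    for k in range(kn):
        dcount += _count_logterm(float(nk_new[k]), model, lam, eta, gam)
    for k in range(K):
        dcount -= _count_logterm(float(nk[k]), model, lam, eta, gam)
    log_a = (log_ratio + dcount - math.log(V)
             + math.log(p_death) - math.log(p_birth)
             - math.log(b))
    if math.log(np.random.random()) < log_a:
        for i in range(N):
            Z[i] = z_new[i]
        for k in range(kn):
            nk[k] = nk_new[k]
        return kn
    return K


@njit(cache=True)
def _death(K, mux, muy, ax, ay, Z, nk, x, y, wx, wy, t,
           bx0, bx1, by0, by1, model, lam, eta, gam,
           p_birth, p_death, z_new, nk_new, logp, pbuf):
    """Reversible-jump death of a uniformly chosen emitter; returns K."""
    if K <= 1:
        return K
    N = x.size
    V = (bx1 - bx0) * (by1 - by0)
    j = np.random.randint(0, K)
    b = _birth_density(mux[j], muy[j], x, y, wx, wy, V)
    for k in range(K - 1):
        nk_new[k] = 0
    log_ratio = 0.0
    for i in range(N):
        ti = t[i]
        xi = x[i]
        yi = y[i]
        wxi = wx[i]
        wyi = wy[i]
        mx = -1.0e300
        for k in range(K):
            dx = xi - (mux[k] + ax[k] * ti)
            dy = yi - (muy[k] + ay[k] * ti)
            lp = -0.5 * (wxi * dx * dx + wyi * dy * dy)
            logp[k] = lp
            if lp > mx:
                mx = lp
        s_all = 0.0
        s_new = 0.0
        for k in range(K):
            p = math.exp(logp[k] - mx)
            pbuf[k] = p
            s_all += p
            if k != j:
                s_new += p
        if s_new <= 0.0:
            return K  # remaining emitters cannot explain i: A = 0
        log_ratio += math.log(s_new) - math.log(s_all)
        u = np.random.random() * s_new
        c = 0.0
        ksel = K - 2  # fallback: last surviving slot
        for k in range(K):
            if k == j:
                continue
            c += pbuf[k]
            if u <= c:
                ksel = k if k < j else k - 1
                break
        z_new[i] = ksel
        nk_new[ksel] += 1
    dcount = 0.0
    for k in range(K - 1):
        dcount += _count_logterm(float(nk_new[k]), model, lam, eta, gam)
    for k in range(K):
        dcount -= _count_logterm(float(nk[k]), model, lam, eta, gam)
    log_a = (log_ratio + dcount + math.log(V)
             + math.log(p_birth) - math.log(p_death)
             + math.log(b))
    if math.log(np.random.random()) < log_a:
        for k in range(j, K - 1):  # compact the emitter buffers
            mux[k] = mux[k + 1]
            muy[k] = muy[k + 1]
            ax[k] = ax[k + 1]
            ay[k] = ay[k + 1]
        for i in range(N):
            Z[i] = z_new[i]
        for k in range(K - 1):
            nk[k] = nk_new[k]
        return K - 1
    return K


@njit(cache=True)
def _xi_update(K, nk, lam, eta, gam, proposal_sd):
    """Log-normal random-walk Metropolis step on lambda."""
    rate = eta / gam
    lam_new = lam * math.exp(proposal_sd * np.random.standard_normal())
    d = (eta - 1.0) * (math.log(lam_new) - math.log(lam)) - rate * (lam_new - lam)
    for k in range(K):
        d += nk[k] * (math.log(lam_new) - math.log(lam)) - (lam_new - lam)
    d += math.log(lam_new) - math.log(lam)  # proposal Jacobian
    if math.log(np.random.random()) < d:
        return lam_new
    return lam


@njit(cache=True)
def run_chain_kernel(x, y, wx, wy, t, bx0, bx1, by0, by1, seed,
                     n_burnin, n_samples,
                     p_move, p_allocate, p_birth, p_death,
                     model, xi_mode, xi0, eta, gam, xi_sd, xi_stride,
                     drift, tau, mux0, muy0, k0, k_cap):
    """Run a full chain; returns recorded per-sample state arrays.

    Returns
    -------
    ks : (n_samples,) int64 emitter counts
    mu_x, mu_y, a_x, a_y : (n_samples, k_cap) float64, first ks[s] slots live
    counts : (n_samples, k_cap) int32 allocations per emitter
    xis : (n_samples,) float64 lambda trace
    acc : (5, 2) int64 (proposed, accepted) per jump type
          rows: move, allocate, birth, death, xi
    z_last : final allocation vector
    """
    np.random.seed(seed)
    N = x.size
    mux = np.zeros(k_cap)
    muy = np.zeros(k_cap)
    ax = np.zeros(k_cap)
    ay = np.zeros(k_cap)
    K = k0
    for k in range(K):
        mux[k] = mux0[k]
        muy[k] = muy0[k]
    lam = xi0
    Z = np.zeros(N, dtype=np.int64)
    nk = np.zeros(k_cap, dtype=np.int64)
    for i in range(N):  # initial allocation: nearest emitter (weighted)
        best = -1.0e300
        bk = 0
        for k in range(K):
            dx = x[i] - mux[k]
            dy = y[i] - muy[k]
            lp = -0.5 * (wx[i] * dx * dx + wy[i] * dy * dy)
            if lp > best:
                best = lp
                bk = k
        Z[i] = bk
        nk[bk] += 1
    z_new = np.empty(N, dtype=np.int64)
    nk_new = np.zeros(k_cap, dtype=np.int64)
    logp = np.empty(k_cap)
    pbuf = np.empty(k_cap)

    ks = np.zeros(n_samples, dtype=np.int64)
    mu_x = np.zeros((n_samples, k_cap))
    mu_y = np.zeros((n_samples, k_cap))
    a_x = np.zeros((n_samples, k_cap))
    a_y = np.zeros((n_samples, k_cap))
    counts = np.zeros((n_samples, k_cap), dtype=np.int32)
    xis = np.zeros(n_samples)
    acc = np.zeros((5, 2), dtype=np.int64)

    total = n_burnin + n_samples
    for it in range(total):
        u = np.random.random()
        if u < p_move:
            acc[0, 0] += 1
            acc[0, 1] += 1
            _move(K, mux, muy, ax, ay, Z, nk, x, y, wx, wy, t,
                  bx0, bx1, by0, by1, drift, tau)
        elif u < p_move + p_allocate:
            acc[1, 0] += 1
            if _allocate(K, mux, muy, ax, ay, Z, nk, x, y, wx, wy, t,
                         model, lam, eta, gam, z_new, nk_new, logp):
                acc[1, 1] += 1
        elif u < p_move + p_allocate + p_birth:
            acc[2, 0] += 1
            kn = _birth(K, k_cap, mux, muy, ax, ay, Z, nk, x, y, wx, wy, t,
                        bx0, bx1, by0, by1, model, lam, eta, gam,
                        p_birth, p_death, drift, tau, z_new, nk_new, logp, pbuf)
            if kn > K:
                K = kn
                acc[2, 1] += 1
        else:
            acc[3, 0] += 1
            kn = _death(K, mux, muy, ax, ay, Z, nk, x, y, wx, wy, t,
                        bx0, bx1, by0, by1, model, lam, eta, gam,
                        p_birth, p_death, z_new, nk_new, logp, pbuf)
            if kn < K:
                K = kn
                acc[3, 1] += 1
        if xi_mode == 1 and (it + 1) % xi_stride == 0:
            acc[4, 0] += 1
            lam_new = _xi_update(K, nk, lam, eta, gam, xi_sd)
            if lam_new != lam:
                acc[4, 1] += 1
            lam = lam_new
        if it >= n_burnin:
            s = it - n_burnin
            ks[s] = K
            for k in range(K):
                mu_x[s, k] = mux[k]
                mu_y[s, k] = muy[k]
                a_x[s, k] = ax[k]
                a_y[s, k] = ay[k]
                counts[s, k] = nk[k]
            xis[s] = lam
    return ks, mu_x, mu_y, a_x, a_y, counts, xis, acc, Z
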
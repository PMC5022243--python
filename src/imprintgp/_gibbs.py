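"""Numba kernels for the single-chain Gibbs sampler.

Model: y = X b + sum_t M_t q_t + Z l + e, with flat priors on the
birth-year effects b and on all variances, l ~ N(0, I s2_l),
e ~ N(0, I s2_e), and each SNP-effect vector q_t drawn from a four-class
normal mixture with known proportions pi and estimated, strictly ordered
class variances.

Design columns for all included effect types are concatenated into one
(C, n) row-contiguous matrix MT (one row per column of the design), with
`col_type` mapping each row to its effect type.  The residual vector is
updated incrementally after every effect change and re-synchronized from
scratch every `resync_every` iterations.

All randomness uses numba's internal NumPy-compatible generator, seeded
once per chain; identical seed + data gives identical output.
"""

import numpy as np
from numba import njit

VAR_FLOOR_REL = 1e-12  # times phenotypic variance


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def update_year_effects(e, b, year_index, year_counts, var_e):
    # flat prior: b_k | rest ~ N(b_k + mean(e in year k), var_e / n_k)
    K = b.shape[0]
    sums = np.zeros(K)
    for i in range(e.shape[0]):
        sums[year_index[i]] += e[i]
    deltas = np.empty(K)
    for k in range(K):
        new = b[k] + sums[k] / year_counts[k] \
            + np.sqrt(var_e / year_counts[k]) * np.random.standard_normal()
        deltas[k] = new - b[k]
        b[k] = new
    for i in range(e.shape[0]):
        e[i] -= deltas[year_index[i]]


@njit(cache=True)
def update_litter_effects(e, l, litter_index, litter_counts, var_l, var_e):
    # N(0, var_l) prior: shrunken group mean
    K = l.shape[0]
    sums = np.zeros(K)
    for i in range(e.shape[0]):
        sums[litter_index[i]] += e[i]
    deltas = np.empty(K)
    ratio = var_e / var_l
    for k in range(K):
        denom = litter_counts[k] + ratio
        mean = (sums[k] + litter_counts[k] * l[k]) / denom
        new = mean + np.sqrt(var_e / denom) * np.random.standard_normal()
        deltas[k] = new - l[k]
        l[k] = new
    for i in range(e.shape[0]):
        e[i] -= deltas[litter_index[i]]


@njit(cache=True)
def update_snp_effects(e, MT, mtm, q, cls, col_type, class_vars, pi, var_e):
    """One scan over all SNP columns: sample class indicator (effect
    integrated out), then the effect from its normal conditional."""
    C, n = MT.shape
    logpi = np.empty(4)
    for c in range(4):
        logpi[c] = np.log(pi[c]) if pi[c] > 0.0 else -np.inf
    w = np.empty(4)
    for j in range(C):
        t = col_type[j]
        mj = mtm[j]
        if mj <= 0.0:
            # constant-zero column in the analyzed set: effect unidentified
            q[j] = 0.0
            cls[j] = 0
            continue
        r = mj * q[j]
        for i in range(n):
            r += MT[j, i] * e[i]
        # marginal likelihood of r under class c: N(0, mtm^2 v_c + mtm var_e)
        maxw = -np.inf
        for c in range(4):
            if pi[c] <= 0.0:
                w[c] = -np.inf
                continue
            s2 = mj * (mj * class_vars[t, c] + var_e)
            w[c] = logpi[c] - 0.5 * np.log(s2) - 0.5 * r * r / s2
            if w[c] > maxw:
                maxw = w[c]
        tot = 0.0
        for c in range(4):
            w[c] = np.exp(w[c] - maxw)
            tot += w[c]
        u = np.random.random() * tot
        c_new = 3
        acc = 0.0
        for c in range(4):
            acc += w[c]
            if u <= acc:
                c_new = c
                break
        cls[j] = c_new
        lam = mj + var_e / class_vars[t, c_new]
        q_new = r / lam + np.sqrt(var_e / lam) * np.random.standard_normal()
        delta = q_new - q[j]
        q[j] = q_new
        for i in range(n):
            e[i] -= MT[j, i] * delta


@njit(cache=True)
def update_class_variances(q, cls, col_type, class_vars, n_types, var_floor,
                           var_ceiling):
    """Update the ordered class variances of each effect type.

    The target conditional under a flat prior truncated to
    [var_floor, var_ceiling] is f(v) = v^(-k/2) exp(-S / 2v) with k the
    number of effects assigned to the class and S their sum of squares.
    Each class is updated in turn on the interval between its neighboring
    class variances, so the strict ordering holds at every state:

    * k >= 5: exact Gibbs draw S / chi2(k - 2) with rejection into the
      interval (<=100 redraws, else keep the previous value);
    * 1 <= k <= 4: the flat-prior conditional is improper (k <= 2) or so
      heavy-tailed that its mean does not exist (k <= 4), which at small
      SNP counts lets a sparsely occupied class wander far above the
      scale of the data.  Such a class instead draws S / chi2(k + 2),
      whose mean is exactly S / k, the mean square of the effects
      currently assigned to the class — an inverse-square-prior
      conditional that keeps the class tied to its data;
    * k == 0: no information at all — redrawn uniformly between the
      lower neighbor and twice the lower neighbor.

    The ceiling (phenotypic variance: no single-SNP effect variance
    beyond it is meaningful) bounds the top class from above.
    """
    C = q.shape[0]
    for t in range(n_types):
        S = np.zeros(4)
        k = np.zeros(4)
        for j in range(C):
            if col_type[j] == t:
                c = cls[j]
                S[c] += q[j] * q[j]
                k[c] += 1.0
        for c in range(4):
            lo = class_vars[t, c - 1] if c > 0 else var_floor
            hi = class_vars[t, c + 1] if c < 3 else var_ceiling
            if hi <= lo:
                continue
            if k[c] >= 1.0:
                df = k[c] - 2.0 if k[c] >= 5.0 else k[c] + 2.0
                for _attempt in range(100):
                    prop = S[c] / np.random.chisquare(df)
                    if lo < prop < hi:
                        class_vars[t, c] = prop
                        break
            else:
                top = min(hi, 2.0 * lo)
                if top > lo:
                    class_vars[t, c] = lo + (top - lo) * np.random.random()


@njit(cache=True)
def rescale_move(e, MT, col_type, q, cls, class_vars, t, var_e,
                 var_floor, var_ceiling):
    """Joint scaling move: q -> sqrt(g)*q and v -> g*v for one effect type.

    A Metropolis-Hastings move with log-uniform factor g in [1/2, 2] and
    acceptance ratio g^4 * exp((|e|^2 - |e'|^2) / (2 var_e)) with
    log-uniform g in [1/4, 4] (the g^4 is
    the volume factor of the four scaled class variances after the
    effect-density terms cancel against the Jacobian).  It leaves the
    posterior invariant and gives the chain a route out of the absorbing
    region where all effects and class variances of a type have collapsed
    toward zero: there the residuals barely change and upward scalings
    are accepted freely, while in equilibrium the likelihood term takes
    over.
    """
    C, n = MT.shape
    g = np.exp((np.random.random() * 2.0 - 1.0) * np.log(4.0))
    for c in range(4):
        v = g * class_vars[t, c]
        if v < var_floor or v > var_ceiling:
            return
    root = np.sqrt(g)
    # genetic contribution of this effect type
    gval = np.zeros(n)
    for j in range(C):
        if col_type[j] == t:
            qj = q[j]
            if qj != 0.0:
                for i in range(n):
                    gval[i] += MT[j, i] * qj
    delta = 0.0
    shift = root - 1.0
    for i in range(n):
        enew = e[i] - shift * gval[i]
        delta += e[i] * e[i] - enew * enew
    log_acc = 4.0 * np.log(g) + delta / (2.0 * var_e)
    if np.log(np.random.random()) < log_acc:
        for j in range(C):
            if col_type[j] == t:
                q[j] *= root
        for c in range(4):
            class_vars[t, c] *= g
        for i in range(n):
            e[i] -= shift * gval[i]


@njit(cache=True)
def run_chain_kernel(y, year_index, year_counts, litter_index, litter_counts,
                     MT, col_type, n_types, pi,
                     chain_length, burn_in, thinning, seed,
                     b0, l0, class_vars0, var_l0, var_e0,
                     update_class_vars_flag, update_var_l_flag, update_var_e_flag,
                     var_floor, var_ceiling, store_effect_samples,
                     resync_every, trace_every):
    np.random.seed(seed)
    n = y.shape[0]
    C = MT.shape[0]
    b = b0.copy()
    l = l0.copy()
    class_vars = class_vars0.copy()
    var_l = var_l0
    var_e = var_e0
    q = np.zeros(C)
    cls = np.zeros(C, dtype=np.int64)
    mtm = np.empty(C)
    for j in range(C):
        s = 0.0
        for i in range(n):
            s += MT[j, i] * MT[j, i]
        mtm[j] = s
    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - b[year_index[i]] - l[litter_index[i]]

    nsave = (chain_length - burn_in) // thinning
    class_var_samples = np.empty((nsave, n_types, 4))
    var_l_samples = np.empty(nsave)
    var_e_samples = np.empty(nsave)
    q_sum = np.zeros(C)
    q_sumsq = np.zeros(C)
    cls_counts = np.zeros((C, 4))
    cpo_inv = np.zeros(n)
    if store_effect_samples:
        q_samples = np.empty((nsave, C))
    else:
        q_samples = np.empty((0, C))
    n_trace = chain_length // trace_every
    trace = np.empty((n_trace, 3 + n_types * 4))
    max_resync = 0.0
    isave = 0
    itrace = 0
    status = 0  # 0 = ok; >0 = iteration where non-finite state was detected

    for it in range(1, chain_length + 1):
        update_year_effects(e, b, year_index, year_counts, var_e)
        update_litter_effects(e, l, litter_index, litter_counts, var_l, var_e)
        if C > 0:
            update_snp_effects(e, MT, mtm, q, cls, col_type, class_vars, pi, var_e)
            if update_class_vars_flag:
                update_class_variances(q, cls, col_type, class_vars, n_types,
                                       var_floor, var_ceiling)
                if it % 10 == 0:
                    for t in range(n_types):
                        rescale_move(e, MT, col_type, q, cls, class_vars, t,
                                     var_e, var_floor, var_ceiling)
        if update_var_l_flag and l.shape[0] >= 3:
            Sl = 0.0
            for k in range(l.shape[0]):
                Sl += l[k] * l[k]
            var_l = Sl / np.random.chisquare(l.shape[0] - 2.0)
            if var_l < var_floor:
                var_l = var_floor
        if update_var_e_flag:
            Se = 0.0
            for i in range(n):
                Se += e[i] * e[i]
            var_e = Se / np.random.chisquare(n - 2.0)
            if var_e < var_floor:
                var_e = var_floor

        if it % resync_every == 0:
            dev = 0.0
            for i in range(n):
                acc = y[i] - b[year_index[i]] - l[litter_index[i]]
                for j in range(C):
                    acc -= MT[j, i] * q[j]
                d = abs(acc - e[i])
                if d > dev:
                    dev = d
                e[i] = acc
            if dev > max_resync:
                max_resync = dev
            if not (np.isfinite(var_e) and np.isfinite(var_l) and np.isfinite(dev)):
                status = it
                break

        if it % trace_every == 0 and itrace < n_trace:
            trace[itrace, 0] = it
            trace[itrace, 1] = var_l
            trace[itrace, 2] = var_e
            for t in range(n_types):
                for c in range(4):
                    trace[itrace, 3 + t * 4 + c] = class_vars[t, c]
            itrace += 1

        if it > burn_in and (it - burn_in) % thinning == 0 and isave < nsave:
            var_l_samples[isave] = var_l
            var_e_samples[isave] = var_e
            for t in range(n_types):
                for c in range(4):
                    class_var_samples[isave, t, c] = class_vars[t, c]
            for j in range(C):
                q_sum[j] += q[j]
                q_sumsq[j] += q[j] * q[j]
                cls_counts[j, cls[j]] += 1.0
            if store_effect_samples:
                for j in range(C):
                    q_samples[isave, j] = q[j]
            # reciprocal predictive density accumulator for CPO
            c0 = np.sqrt(2.0 * np.pi * var_e)
            for i in range(n):
                cpo_inv[i] += c0 * np.exp(e[i] * e[i] / (2.0 * var_e))
            isave += 1

    return (status, class_var_samples, var_l_samples, var_e_samples,
            q_sum, q_sumsq, cls_counts, q_samples,
            cpo_inv, trace[:itrace], max_resync, isave, b, l, e)
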
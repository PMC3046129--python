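"""Numba sweep kernels for the MRF relaxation schemes.

Each kernel performs one full sweep of sequential single-site updates on the
label field in place and returns ``(energy_delta, n_changed)``.  Sequential
local updates make the accumulated local energy differences equal the global
energy change, so the driver can track total energy incrementally.

Site visit order, proposal labels and acceptance uniforms are generated by
the caller from a seeded numpy Generator and passed in as arrays, keeping
the kernels deterministic and the whole relaxation bit-reproducible.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _pair_delta(labels, i, j, a, b, beta, offsets, h, w):
    """Change in pairwise energy when site (i, j) flips from label a to b."""
    d = 0.0
    for n in range(offsets.shape[0]):
        ni = i + offsets[n, 0]
        nj = j + offsets[n, 1]
        if 0 <= ni < h and 0 <= nj < w:
            c = labels[ni, nj]
            if b == c:
                d -= beta
            else:
                d += beta
            if a == c:
                d += beta
            else:
                d -= beta
    return d


@njit(cache=True)
def metropolis_sweep(labels, energies, beta, temperature, offsets, order, proposals, uniforms):
    h, w, k = energies.shape
    delta = 0.0
    changed = 0
    for idx in range(order.shape[0]):
        s = order[idx]
        i = s // w
        j = s % w
        a = labels[i, j]
        b = proposals[idx]
        if b >= a:  # map 0..k-2 onto the k-1 labels different from a
            b += 1
        du = energies[i, j, b] - energies[i, j, a]
        du += _pair_delta(labels, i, j, a, b, beta, offsets, h, w)
        if du <= 0.0 or uniforms[idx] < np.exp(-du / temperature):
            labels[i, j] = b
            delta += du
            changed += 1
    return delta, changed


@njit(cache=True)
def mmd_sweep(labels, energies, beta, temperature, offsets, order, proposals, log_alpha):
    """Modified Metropolis: fixed acceptance threshold alpha replaces the
    per-move uniform; a worse move is accepted iff exp(-dU/T) >= alpha."""
    h, w, k = energies.shape
    delta = 0.0
    changed = 0
    for idx in range(order.shape[0]):
        s = order[idx]
        i = s // w
        j = s % w
        a = labels[i, j]
        b = proposals[idx]
        if b >= a:
            b += 1
        du = energies[i, j, b] - energies[i, j, a]
        du += _pair_delta(labels, i, j, a, b, beta, offsets, h, w)
        if du <= 0.0 or du <= -temperature * log_alpha:
            labels[i, j] = b
            delta += du
            changed += 1
    return delta, changed


@njit(cache=True)
def gibbs_sweep(labels, energies, beta, temperature, offsets, order, uniforms):
    """Resample each site from its local conditional exp(-U_local/T)."""
    h, w, k = energies.shape
    delta = 0.0
    changed = 0
    local = np.empty(k)
    probs = np.empty(k)
    for idx in range(order.shape[0]):
        s = order[idx]
        i = s // w
        j = s % w
        a = labels[i, j]
        for lam in range(k):
            e = energies[i, j, lam]
            for n in range(offsets.shape[0]):
                ni = i + offsets[n, 0]
                nj = j + offsets[n, 1]
                if 0 <= ni < h and 0 <= nj < w:
                    if labels[ni, nj] == lam:
                        e -= beta
                    else:
                        e += beta
            local[lam] = e
        emin = local[0]
        for lam in range(1, k):
            if local[lam] < emin:
                emin = local[lam]
        total = 0.0
        for lam in range(k):
            probs[lam] = np.exp(-(local[lam] - emin) / temperature)
            total += probs[lam]
        u = uniforms[idx] * total
        acc = 0.0
        b = k - 1
        for lam in range(k):
            acc += probs[lam]
            if u < acc:
                b = lam
                break
        if b != a:
            labels[i, j] = b
            delta += local[b] - local[a]
            changed += 1
    return delta, changed


@njit(cache=True)
def icm_sweep(labels, energies, beta, offsets):
    """One raster-order sweep of iterated conditional modes (greedy argmin)."""
    h, w, k = energies.shape
    delta = 0.0
    changed = 0
    for i in range(h):
        for j in range(w):
            a = labels[i, j]
            best = a
            e_cur = energies[i, j, a]
            for n in range(offsets.shape[0]):
                ni = i + offsets[n, 0]
                nj = j + offsets[n, 1]
                if 0 <= ni < h and 0 <= nj < w:
                    if labels[ni, nj] == a:
                        e_cur -= beta
                    else:
                        e_cur += beta
            e_best = e_cur
            for lam in range(k):
                if lam == a:
                    continue
                e = energies[i, j, lam]
                for n in range(offsets.shape[0]):
                    ni = i + offsets[n, 0]
                    nj = j + offsets[n, 1]
                    if 0 <= ni < h and 0 <= nj < w:
                        if labels[ni, nj] == lam:
                            e -= beta
                        else:
                            e += beta
                if e < e_best or (e == e_best and lam < best):
                    e_best = e
                    best = lam
            if best != a and e_best < e_cur:
                labels[i, j] = best
                delta += e_best - e_cur
                changed += 1
    return delta, changed
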
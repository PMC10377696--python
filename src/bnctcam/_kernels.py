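"""Numba kernels for cone-surface voxel enumeration.

The expensive primitive shared by back-projection and the MLEM system matrix
is: given a Compton cone (apex a, unit axis u, half-angle theta) and the
cubic voxel grid, find every voxel center whose angular residual
``delta - theta`` lies within ``cutoff * sigma`` and evaluate the Gaussian
angular weight there.

Instead of scanning all n^3 voxels, each (ix, iy) column is intersected with
the two boundary cones ``delta = theta +- cutoff*sigma`` (a quadratic in z),
the column is partitioned at the real roots, and only segments whose midpoint
lies inside the band are visited. This is exact (the residual is continuous
in z, so it can only enter or leave the band at a boundary root) and reduces
the work to the voxels actually touched by the cone shell.
"""

import math

import numpy as np
from numba import njit

# angular residuals below this weight are treated as zero (division safety
# and sparsity floor); matches event_voxel_probability
WEIGHT_FLOOR_DEFAULT = 1e-12


@njit(cache=True)
def _event_band(ax, ay, az, ux, uy, uz, theta, n, lo, vs,
                sigma, cutoff, dist_w, floor, idx_buf, w_buf):
    """Enumerate (voxel index, weight) pairs for one cone into the buffers.

    Returns the number of entries written. Buffers must hold n^3 entries.
    """
    cnt = 0
    half = cutoff * sigma
    band_lo = theta - half
    band_hi = theta + half
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    dzmin = (lo + 0.5 * vs) - az          # z offset of first voxel center
    dzmax = (lo + (n - 0.5) * vs) - az    # ... and last
    roots = np.empty(6, dtype=np.float64)

    for ix in range(n):
        dx = (lo + (ix + 0.5) * vs) - ax
        for iy in range(n):
            dy = (lo + (iy + 0.5) * vs) - ay
            rxy2 = dx * dx + dy * dy
            p = dx * ux + dy * uy
            q = uz

            # boundary-cone roots partitioning the column
            nr = 0
            for b in range(2):
                beta = band_lo if b == 0 else band_hi
                if beta <= 0.0 or beta >= math.pi:
                    continue
                cb = math.cos(beta)
                A = q * q - cb * cb
                B = p * q
                C = p * p - cb * cb * rxy2
                if abs(A) > 1e-14:
                    D = B * B - A * C
                    if D > 0.0:
                        sq = math.sqrt(D)
                        for sgn in range(2):
                            dz = (-B - sq) / A if sgn == 0 else (-B + sq) / A
                            if dzmin < dz < dzmax:
                                roots[nr] = dz
                                nr += 1
                elif abs(B) > 1e-14:
                    dz = -C / (2.0 * B)
                    if dzmin < dz < dzmax:
                        roots[nr] = dz
                        nr += 1
            # insertion sort of the <=4 roots
            for a_i in range(1, nr):
                v = roots[a_i]
                b_i = a_i - 1
                while b_i >= 0 and roots[b_i] > v:
                    roots[b_i + 1] = roots[b_i]
                    b_i -= 1
                roots[b_i + 1] = v

            za = dzmin
            k_done = 0
            for seg in range(nr + 1):
                zb = roots[seg] if seg < nr else dzmax
                if zb < za:
                    continue
                zm = 0.5 * (za + zb)
                dd2 = rxy2 + zm * zm
                inside = False
                if dd2 > 1e-16:
                    cosd = (p + q * zm) / math.sqrt(dd2)
                    if cosd > 1.0:
                        cosd = 1.0
                    elif cosd < -1.0:
                        cosd = -1.0
                    delta = math.acos(cosd)
                    inside = band_lo <= delta <= band_hi
                if inside:
                    ks = int(math.ceil((za - dzmin) / vs - 1e-12))
                    ke = int(math.floor((zb - dzmin) / vs + 1e-12))
                    if ks < k_done:
                        ks = k_done
                    if ks < 0:
                        ks = 0
                    if ke > n - 1:
                        ke = n - 1
                    for k in range(ks, ke + 1):
                        dzk = dzmin + k * vs
                        dd2k = rxy2 + dzk * dzk
                        if dd2k < 1e-16:
                            continue  # voxel at the apex: undefined direction
                        ddk = math.sqrt(dd2k)
                        cosk = (p + q * dzk) / ddk
                        if cosk > 1.0:
                            cosk = 1.0
                        elif cosk < -1.0:
                            cosk = -1.0
                        resid = math.acos(cosk) - theta
                        if resid < -half or resid > half:
                            continue
                        w = math.exp(-resid * resid * inv2s2)
                        if dist_w:
                            w /= dd2k
                        if w >= floor:
                            idx_buf[cnt] = (ix * n + iy) * n + k
                            w_buf[cnt] = w
                            cnt += 1
                    k_done = ke + 1
                za = zb
    return cnt


@njit(cache=True)
def _accumulate_cones(apex, axis, theta, n, lo, vs, sigma, cutoff,
                      dist_w, floor, img_flat):
    """Sum the Gaussian cone weights of every event into ``img_flat``."""
    m = apex.shape[0]
    idx_buf = np.empty(n * n * n, dtype=np.int64)
    w_buf = np.empty(n * n * n, dtype=np.float64)
    for i in range(m):
        cnt = _event_band(apex[i, 0], apex[i, 1], apex[i, 2],
                          axis[i, 0], axis[i, 1], axis[i, 2], theta[i],
                          n, lo, vs, sigma, cutoff, dist_w, floor,
                          idx_buf, w_buf)
        for t in range(cnt):
            img_flat[idx_buf[t]] += w_buf[t]


@njit(cache=True)
def _count_rows(apex, axis, theta, n, lo, vs, sigma, cutoff, dist_w, floor):
    """Per-event nonzero counts (CSR sizing pass)."""
    m = apex.shape[0]
    counts = np.zeros(m, dtype=np.int64)
    idx_buf = np.empty(n * n * n, dtype=np.int64)
    w_buf = np.empty(n * n * n, dtype=np.float64)
    for i in range(m):
        counts[i] = _event_band(apex[i, 0], apex[i, 1], apex[i, 2],
                                axis[i, 0], axis[i, 1], axis[i, 2], theta[i],
                                n, lo, vs, sigma, cutoff, dist_w, floor,
                                idx_buf, w_buf)
    return counts


@njit(cache=True)
def _fill_rows(apex, axis, theta, n, lo, vs, sigma, cutoff, dist_w, floor,
               indptr, indices, data):
    """Fill preallocated CSR arrays (sized by :func:`_count_rows`)."""
    m = apex.shape[0]
    idx_buf = np.empty(n * n * n, dtype=np.int64)
    w_buf = np.empty(n * n * n, dtype=np.float64)
    for i in range(m):
        cnt = _event_band(apex[i, 0], apex[i, 1], apex[i, 2],
                          axis[i, 0], axis[i, 1], axis[i, 2], theta[i],
                          n, lo, vs, sigma, cutoff, dist_w, floor,
                          idx_buf, w_buf)
        start = indptr[i]
        for t in range(cnt):
            indices[start + t] = idx_buf[t]
            data[start + t] = w_buf[t]


@njit(cache=True)
def _mlem_iteration(data, indices, indptr, lam, sens, guard):
    """One list-mode MLEM update: returns lam * backproj(1/forward) / sens.

    ``data/indices/indptr`` form the CSR system matrix (rows = events).
    Events whose forward projection falls below ``guard`` contribute nothing
    (0/0 protection).
    """
    n_vox = lam.shape[0]
    m = indptr.shape[0] - 1
    back = np.zeros(n_vox, dtype=np.float64)
    for i in range(m):
        start = indptr[i]
        stop = indptr[i + 1]
        q = 0.0
        for ptr in range(start, stop):
            q += data[ptr] * lam[indices[ptr]]
        if q > guard:
            inv = 1.0 / q
            for ptr in range(start, stop):
                back[indices[ptr]] += data[ptr] * inv
    out = np.empty(n_vox, dtype=np.float64)
    for j in range(n_vox):
        out[j] = lam[j] / sens[j] * back[j]
    return out


@njit(cache=True)
def _forward_project(data, indices, indptr, lam):
    """CSR row sums of t_ij * lam_j (the expected counts per event)."""
    m = indptr.shape[0] - 1
    q = np.zeros(m, dtype=np.float64)
    for i in range(m):
        s = 0.0
        for ptr in range(indptr[i], indptr[i + 1]):
            s += data[ptr] * lam[indices[ptr]]
        q[i] = s
    return q
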
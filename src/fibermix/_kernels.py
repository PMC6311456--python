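"""Numba-compiled inner loops.

Everything here is deliberately free of Python objects: plain float64/int64
arrays in, arrays out. Seeding uses numba's internal RNG state, set once per
call via ``np.random.seed`` inside the jitted function, so results are
reproducible for a given (seed, n) pair.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Russian-roulette constants: terminate packets below WEIGHT_MIN with survival
# probability ROULETTE_P (survivors are reweighted 1/ROULETTE_P; unbiased).
WEIGHT_MIN = 1e-4
ROULETTE_P = 0.1


@njit(cache=False)
def _sample_direction(sigma_theta: float) -> tuple:
    """Bivariate Gaussian angular tilt: theta ~ Rayleigh(sigma) < pi/2.

    The two tilt components are iid N(0, sigma^2) (the far field of the
    fiber's fundamental mode), so the polar angle is Rayleigh distributed
    and the angular photon density is a smooth 2-D Gaussian with no on-axis
    singularity; azimuth is uniform by symmetry.
    """
    if sigma_theta <= 0.0:
        return 0.0, 0.0, 1.0
    theta = sigma_theta * np.sqrt(-2.0 * np.log(np.random.random() + 1e-300))
    while theta >= np.pi / 2:
        theta = sigma_theta * np.sqrt(-2.0 * np.log(np.random.random() + 1e-300))
    phi = 2.0 * np.pi * np.random.random()
    st = np.sin(theta)
    return st * np.cos(phi), st * np.sin(phi), np.cos(theta)


@njit(cache=False)
def _hg_cos(g: float) -> float:
    u = np.random.random()
    if np.abs(g) < 1e-12:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - frac * frac) / (2.0 * g)


@njit(cache=False)
def _rotate(ux: float, uy: float, uz: float, ct: float, phi: float) -> tuple:
    """New unit vector at deflection cos(theta)=ct, azimuth phi about (ux,uy,uz)."""
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if np.abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct * np.sign(uz)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=False)
def _deposit_segment(fluence, x0, y0, z0, ux, uy, uz, s, weight,
                     nx, ny, nz, vox, ox, oy, oz):
    """Accumulate weight x path-length per voxel along a straight segment.

    Steps through voxel boundaries (DDA). Returns the length actually
    travelled inside the grid (== s unless the segment exits).
    Grid spans [o, o + n*vox) per axis.
    """
    travelled = 0.0
    x, y, z = x0, y0, z0
    eps = 1e-12
    while travelled < s - eps:
        ix = int(np.floor((x - ox) / vox))
        iy = int(np.floor((y - oy) / vox))
        iz = int(np.floor((z - oz) / vox))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            break
        # distance to the next voxel face along each axis
        t = s - travelled
        if ux > eps:
            tx = ((ox + (ix + 1) * vox) - x) / ux
            if tx < t:
                t = tx
        elif ux < -eps:
            tx = ((ox + ix * vox) - x) / ux
            if tx < t:
                t = tx
        if uy > eps:
            ty = ((oy + (iy + 1) * vox) - y) / uy
            if ty < t:
                t = ty
        elif uy < -eps:
            ty = ((oy + iy * vox) - y) / uy
            if ty < t:
                t = ty
        if uz > eps:
            tz = ((oz + (iz + 1) * vox) - z) / uz
            if tz < t:
                t = tz
        elif uz < -eps:
            tz = ((oz + iz * vox) - z) / uz
            if tz < t:
                t = tz
        if t < eps:
            t = eps
        fluence[ix, iy, iz] += weight * t
        travelled += t
        x = x0 + ux * travelled
        y = y0 + uy * travelled
        z = z0 + uz * travelled
        # nudge across the face so floor() lands in the next voxel
        x += ux * 1e-9
        y += uy * 1e-9
        z += uz * 1e-9
        travelled += 1e-9
    return min(travelled, s)


@njit(cache=False)
def mc_fluence(n_packets, seed, mu_a, mu_s, g_aniso, sigma_theta,
               core_radius, tip, fluence, vox, origin, max_path):
    """Weighted-packet Monte Carlo with a track-length fluence estimator.

    Returns (deposited, escaped, roulette_killed, roulette_gain): the
    energy-conservation tallies. launched + gain == deposited + escaped
    + killed, up to floating-point rounding.
    """
    np.random.seed(seed)
    nx, ny, nz = fluence.shape
    ox, oy, oz = origin[0], origin[1], origin[2]
    mu_t = mu_a + mu_s
    deposited = 0.0
    escaped = 0.0
    killed = 0.0
    gain = 0.0
    for _ in range(n_packets):
        # launch: uniform over the core disc, forward cone about +z
        r = core_radius * np.sqrt(np.random.random())
        a = 2.0 * np.pi * np.random.random()
        x = tip[0] + r * np.cos(a)
        y = tip[1] + r * np.sin(a)
        z = tip[2]
        ux, uy, uz = _sample_direction(sigma_theta)
        w = 1.0
        path = 0.0
        while True:
            if mu_t <= 0.0:
                # ballistic: traverse to the boundary and escape
                d = _deposit_segment(fluence, x, y, z, ux, uy, uz, max_path,
                                     w, nx, ny, nz, vox, ox, oy, oz)
                escaped += w
                break
            s = -np.log(np.random.random() + 1e-300) / mu_t
            d = _deposit_segment(fluence, x, y, z, ux, uy, uz, s, w,
                                 nx, ny, nz, vox, ox, oy, oz)
            if d < s * (1.0 - 1e-9):
                escaped += w
                break
            x += ux * s
            y += uy * s
            z += uz * s
            if (x < ox or x >= ox + nx * vox or y < oy or y >= oy + ny * vox
                    or z < oz or z >= oz + nz * vox):
                escaped += w
                break
            path += s
            if path > max_path:
                # pathological non-absorbing walk; count as terminated
                killed += w
                break
            absorbed = w * mu_a / mu_t
            deposited += absorbed
            w -= absorbed
            ct = _hg_cos(g_aniso)
            phi = 2.0 * np.pi * np.random.random()
            ux, uy, uz = _rotate(ux, uy, uz, ct, phi)
            if w < WEIGHT_MIN:
                if np.random.random() < ROULETTE_P:
                    gain += w / ROULETTE_P - w
                    w = w / ROULETTE_P
                else:
                    killed += w
                    break
    return deposited, escaped, killed, gain


@njit(cache=False)
def trilinear_many(values, vox, origin, pts, out):
    """Trilinear interpolation of a voxel grid at many points; 0 outside.

    ``values`` is sampled at voxel centers: center of voxel (i,j,k) sits at
    origin + (i+0.5)*vox per axis.
    """
    nx, ny, nz = values.shape
    n = pts.shape[0]
    for p in range(n):
        fx = (pts[p, 0] - origin[0]) / vox - 0.5
        fy = (pts[p, 1] - origin[1]) / vox - 0.5
        fz = (pts[p, 2] - origin[2]) / vox - 0.5
        i0 = int(np.floor(fx))
        j0 = int(np.floor(fy))
        k0 = int(np.floor(fz))
        tx = fx - i0
        ty = fy - j0
        tz = fz - k0
        acc = 0.0
        for di in range(2):
            i = i0 + di
            if i < 0 or i >= nx:
                continue
            wx = tx if di == 1 else 1.0 - tx
            for dj in range(2):
                j = j0 + dj
                if j < 0 or j >= ny:
                    continue
                wy = ty if dj == 1 else 1.0 - ty
                for dk in range(2):
                    k = k0 + dk
                    if k < 0 or k >= nz:
                        continue
                    wz = tz if dk == 1 else 1.0 - tz
                    acc += wx * wy * wz * values[i, j, k]
        out[p] = acc


@njit(cache=False)
def sensitivity_pairs(values, vox, origin, fiber_xyz, neuron_xyz, out):
    """out[k, j] = trilinear profile value at neuron j in fiber k's frame.

    Fiber-local coordinates: neuron position minus fiber tip; the profile
    grid's stated origin already places the tip at the grid center.
    """
    n_fib = fiber_xyz.shape[0]
    n_neu = neuron_xyz.shape[0]
    nx, ny, nz = values.shape
    for k in range(n_fib):
        fx0 = fiber_xyz[k, 0]
        fy0 = fiber_xyz[k, 1]
        fz0 = fiber_xyz[k, 2]
        for j in range(n_neu):
            fx = (neuron_xyz[j, 0] - fx0 - origin[0]) / vox - 0.5
            fy = (neuron_xyz[j, 1] - fy0 - origin[1]) / vox - 0.5
            fz = (neuron_xyz[j, 2] - fz0 - origin[2]) / vox - 0.5
            i0 = int(np.floor(fx))
            j0 = int(np.floor(fy))
            k0 = int(np.floor(fz))
            if i0 < -1 or i0 >= nx or j0 < -1 or j0 >= ny or k0 < -1 or k0 >= nz:
                out[k, j] = 0.0
                continue
            tx = fx - i0
            ty = fy - j0
            tz = fz - k0
            acc = 0.0
            for di in range(2):
                i = i0 + di
                if i < 0 or i >= nx:
                    continue
                wx = tx if di == 1 else 1.0 - tx
                for dj in range(2):
                    jj = j0 + dj
                    if jj < 0 or jj >= ny:
                        continue
                    wy = ty if dj == 1 else 1.0 - ty
                    for dk in range(2):
                        kk = k0 + dk
                        if kk < 0 or kk >= nz:
                            continue
                        wz = tz if dk == 1 else 1.0 - tz
                        acc += wx * wy * wz * values[i, jj, kk]
            out[k, j] = acc


@njit(cache=False)
def background_drive(seed, n_sources, n_bins, p, indptr, indices, data, out):
    """Bernoulli-spike drive of many weak sources, accumulated in one pass.

    Spikes are drawn as an exact Bernoulli(p) process over the flattened
    (source-major) bin sequence via geometric gaps; each spike of source j
    adds column j of the sparse weight matrix (CSC arrays) into ``out``
    which is laid out (n_bins, n_fibers) for write locality.
    """
    if p <= 0.0 or n_sources == 0:
        return
    np.random.seed(seed)
    n_trials = n_sources * n_bins
    lg = np.log(1.0 - p)
    pos = -1
    while True:
        gap = int(np.ceil(np.log(1.0 - np.random.random()) / lg))
        if gap < 1:
            gap = 1
        pos += gap
        if pos >= n_trials:
            break
        j = pos // n_bins
        t = pos - j * n_bins
        for idx in range(indptr[j], indptr[j + 1]):
            out[t, indices[idx]] += data[idx]


@njit(cache=False)
def add_framed_events(src_idx, frame_idx, phase_idx, poly, out):
    """out[src, f0 + t] += poly[phase, t] for each event.

    ``poly`` holds the block-mean-framed indicator kernel for each sub-frame
    phase of the event time; adding shifted copies realizes convolution with
    the 100-Hz kernel followed by frame averaging, exactly.
    """
    n_frames = out.shape[1]
    klen = poly.shape[1]
    for e in range(src_idx.shape[0]):
        s = src_idx[e]
        f0 = frame_idx[e]
        ph = phase_idx[e]
        hi = min(klen, n_frames - f0)
        for t in range(hi):
            out[s, f0 + t] += poly[ph, t]
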
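"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately written as plain enumeration / direct
formula evaluation, sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_mask_mean(plane, x, y, diameter):
    """Mean over pixels whose centers lie within diameter/2 of (x, y),
    clipped to the plane, by explicit enumeration."""
    r = diameter / 2.0
    ny, nx = plane.shape
    vals = []
    for dy in range(-int(math.ceil(r)), int(math.ceil(r)) + 1):
        for dx in range(-int(math.ceil(r)), int(math.ceil(r)) + 1):
            if dy * dy + dx * dx <= r * r:
                yy, xx = y + dy, x + dx
                if 0 <= yy < ny and 0 <= xx < nx:
                    vals.append(float(plane[yy, xx]))
    return sum(vals) / len(vals)


def oracle_ring_median(plane, x, y, diameter, ring_offset=8, halfwidth=1):
    r0 = diameter / 2.0 + ring_offset
    ny, nx = plane.shape
    vals = []
    n = int(math.ceil(r0 + halfwidth))
    for dy in range(-n, n + 1):
        for dx in range(-n, n + 1):
            d = math.hypot(dy, dx)
            if r0 - halfwidth <= d <= r0 + halfwidth:
                yy, xx = y + dy, x + dx
                if 0 <= yy < ny and 0 <= xx < nx:
                    vals.append(float(plane[yy, xx]))
    return float(np.median(vals))


def oracle_fit_window(volume, z_lo, z_hi, y_lo, y_hi, x_lo, x_hi, diameter,
                      ref_pos):
    """Best mask-mean position in an inclusive window by per-voxel
    evaluation; ties by smallest displacement from ref_pos then lowest
    (z, y, x)."""
    nz, ny, nx = volume.shape
    best = None
    for z in range(max(0, z_lo), min(nz - 1, z_hi) + 1):
        for y in range(max(0, y_lo), min(ny - 1, y_hi) + 1):
            for x in range(max(0, x_lo), min(nx - 1, x_hi) + 1):
                m = oracle_mask_mean(volume[z], x, y, diameter)
                d2 = ((z - ref_pos[0]) ** 2 + (y - ref_pos[1]) ** 2
                      + (x - ref_pos[2]) ** 2)
                cand = (-m, d2, z, y, x)
                if best is None or cand < best:
                    best = cand
    return (best[2], best[3], best[4]), -best[0]


def oracle_detect_t0(movie_data, seed_xyt, params):
    """Reference implementation of the seeded onset scan on one channel.

    ``movie_data`` is (t, z, y, x); ``seed_xyt`` is (x, y, t). Returns
    (t0, position, threshold) or None. Mirrors the documented algorithm
    using only enumeration primitives.
    """
    sx, sy, st = seed_xyt
    nt, nz, ny, nx = movie_data.shape
    start = max(0, st - params.initial_lookback_frames)
    o = params.xy_seed_offset_px
    d = params.mask_diameter_px
    history = []
    for frame in range(start, nt):
        pos, m = oracle_fit_window(movie_data[frame], 0, nz - 1,
                                   sy - o, sy + o, sx - o, sx + o, d,
                                   ref_pos=(nz // 2, sy, sx))
        if len(history) >= params.min_pre_measurements:
            h = np.asarray(history)
            theta = h.mean() + params.threshold_k * h.std()
            if m > theta:
                prev, ok = pos, True
                for j in range(1, params.confirm_frames + 1):
                    if frame + j >= nt:
                        ok = False
                        break
                    prev, mj = oracle_fit_window(
                        movie_data[frame + j],
                        prev[0] - params.track_z_offset_planes,
                        prev[0] + params.track_z_offset_planes,
                        prev[1] - params.track_xy_offset_px,
                        prev[1] + params.track_xy_offset_px,
                        prev[2] - params.track_xy_offset_px,
                        prev[2] + params.track_xy_offset_px, d, prev)
                    if not mj > theta:
                        ok = False
                        break
                if ok:
                    return frame, pos, float(theta)
        history.append(m)
    return None


def oracle_track(movie_data, t0, pos, params, until_frame):
    """Forward track positions/measurements by per-voxel evaluation."""
    out = [(t0, pos, oracle_mask_mean(movie_data[t0, pos[0]], pos[2], pos[1],
                                      params.mask_diameter_px))]
    prev = pos
    for frame in range(t0 + 1, until_frame + 1):
        prev, m = oracle_fit_window(
            movie_data[frame],
            prev[0] - params.track_z_offset_planes,
            prev[0] + params.track_z_offset_planes,
            prev[1] - params.track_xy_offset_px,
            prev[1] + params.track_xy_offset_px,
            prev[2] - params.track_xy_offset_px,
            prev[2] + params.track_xy_offset_px,
            params.mask_diameter_px, prev)
        out.append((frame, prev, m))
    return out


def oracle_rolling_mean(values, window):
    """Centered rolling mean with shrinking edge windows, by direct loops."""
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = float(np.mean(values[lo:hi]))
    return out


def oracle_segment_log(pixels, k=1.0):
    """Pixel-wise application of the log10 mean + k s.d. rule."""
    pixels = np.asarray(pixels, dtype=float)
    pos = pixels[pixels > 0]
    logs = np.log10(pos)
    thr = logs.mean() + k * logs.std()
    return np.array([p > 0 and math.log10(p) > thr for p in pixels.ravel()]
                    ).reshape(pixels.shape)


def oracle_cytosolic_dextran(image, cell_labels, threshold, control_mean,
                             margin=5):
    """Stepwise mask / dilate / median / subtract by enumeration."""
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    above = image > threshold
    dilated = np.zeros_like(above)
    offs = [(dy, dx) for dy in range(-margin, margin + 1)
            for dx in range(-margin, margin + 1)
            if dy * dy + dx * dx <= margin * margin]
    for y in range(ny):
        for x in range(nx):
            if above[y, x]:
                for dy, dx in offs:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < ny and 0 <= xx < nx:
                        dilated[yy, xx] = True
    result = {}
    for c in np.unique(cell_labels):
        if c == 0:
            continue
        vals = [image[y, x] for y in range(ny) for x in range(nx)
                if cell_labels[y, x] == c and not dilated[y, x]]
        result[int(c)] = (float(np.median(vals)) - control_mean) if vals \
            else float("nan")
    return result


def oracle_sirna_internalization(zstack, cell_labels, margin=5):
    """Stepwise background / erode / best-plane mean by enumeration."""
    zstack = np.asarray(zstack, dtype=float)
    nzp, ny, nx = zstack.shape
    outside = cell_labels == 0
    plane_means = [zstack[z][outside].mean() for z in range(nzp)]
    zbg = int(np.argmin(plane_means))
    background = float(np.median(zstack[zbg][outside]))
    offs = [(dy, dx) for dy in range(-margin, margin + 1)
            for dx in range(-margin, margin + 1)
            if dy * dy + dx * dx <= margin * margin]
    result = {}
    for c in np.unique(cell_labels):
        if c == 0:
            continue
        inside = cell_labels == c
        eroded = np.zeros_like(inside)
        for y in range(ny):
            for x in range(nx):
                if inside[y, x]:
                    ok = True
                    for dy, dx in offs:
                        yy, xx = y + dy, x + dx
                        if not (0 <= yy < ny and 0 <= xx < nx
                                and inside[yy, xx]):
                            ok = False
                            break
                    eroded[y, x] = ok
        if not eroded.any():
            result[int(c)] = float("nan")
            continue
        best = max(zstack[z][eroded].mean() for z in range(nzp))
        result[int(c)] = float(best) - background
    return result


def oracle_psf_weight(dz, dy, dx, sigma_z, sigma_xy, truncate=4.0):
    """Weight of a sampled, sum-normalized separable Gaussian at an integer
    offset (direct formula evaluation)."""
    def k1(offset, sigma):
        radius = int(truncate * sigma + 0.5)
        xs = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (xs / sigma) ** 2)
        w /= w.sum()
        return 0.0 if abs(offset) > radius else float(w[offset + radius])
    return k1(dz, sigma_z) * k1(dy, sigma_xy) * k1(dx, sigma_xy)
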
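"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written on a different code path from the
package: per-pixel python loops, scipy interpolation, O(n^2) all-pairs
distances.  The oracles are slow and only run on tiny inputs.
"""

import numpy as np
from scipy.ndimage import map_coordinates


def over_back_to_front(samples):
    """Associative over-operator evaluated back-to-front:
    C = a_i c_i + (1 - a_i) C_behind, recursively from the far end.
    Returns (premultiplied rgb, accumulated alpha)."""
    C = np.zeros(3)
    A = 0.0
    for rgb, alpha in reversed(list(samples)):
        C = alpha * np.asarray(rgb, float) + (1.0 - alpha) * C
        A = alpha + (1.0 - alpha) * A
    return C, A


def trilinear_scipy(frame, grid, points):
    """Independent trilinear sampler: scipy map_coordinates (order 1,
    edge-clamped), with the package's outside-the-box zero convention."""
    pts = np.atleast_2d(points)
    local = (pts - grid.origin) @ grid.direction
    coords = (local / grid.spacing).T
    dims = np.asarray(grid.dims)
    outside = np.any((coords.T < -0.5) | (coords.T >= dims - 0.5), axis=1)
    vals = map_coordinates(np.asarray(frame, float), coords, order=1, mode="nearest")
    vals[outside] = 0.0
    return vals, outside


def ray_box_intersect(o, d, lo, hi):
    """Scalar slab test for one ray; returns (t_in, t_out)."""
    t_in, t_out = 0.0, np.inf
    for ax in range(3):
        if abs(d[ax]) < 1e-15:
            if not (lo[ax] - 1e-12 <= o[ax] <= hi[ax] + 1e-12):
                return 1.0, 0.0
            continue
        t1 = (lo[ax] - o[ax]) / d[ax]
        t2 = (hi[ax] - o[ax]) / d[ax]
        t_in = max(t_in, min(t1, t2))
        t_out = min(t_out, max(t1, t2))
    return t_in, t_out


def dense_integrator(frame, grid, tf_values, tf_colors, camera, step_mm,
                     background=(0.0, 0.0, 0.0)):
    """Per-pixel volume rendering integrator for single-layer scenes:
    independent ray generation, scipy trilinear sampling, per-1mm opacity
    correction, and back-to-front compositing.  No early termination."""
    H, W = camera.height, camera.width
    eye = np.asarray(camera.eye, float)
    look = np.asarray(camera.look_at, float)
    up = np.asarray(camera.up, float)
    w = look - eye
    w = w / np.linalg.norm(w)
    u = np.cross(w, up)
    u = u / np.linalg.norm(u)
    v = np.cross(u, w)
    aspect = W / H

    lo = grid.origin - grid.spacing / 2.0
    hi = grid.origin + (np.asarray(grid.dims) - 1) * grid.spacing + grid.spacing / 2.0

    img = np.zeros((H, W, 4))
    for i in range(H):
        for j in range(W):
            px = (j + 0.5) / W * 2.0 - 1.0
            py = 1.0 - (i + 0.5) / H * 2.0
            if camera.orthographic:
                half_h = camera.ortho_height / 2.0
                o = eye + px * half_h * aspect * u + py * half_h * v
                d = w
            else:
                half_h = np.tan(np.radians(camera.fov_deg) / 2.0)
                d = w + px * half_h * aspect * u + py * half_h * v
                d = d / np.linalg.norm(d)
                o = eye
            t_in, t_out = ray_box_intersect(o, d, lo, hi)
            samples = []
            if t_in <= t_out:
                n = int(np.ceil((t_out - t_in) / step_mm))
                for k in range(n):
                    p = o + (t_in + (k + 0.5) * step_mm) * d
                    val, outside = trilinear_scipy(frame, grid, p)
                    rgba = np.array(
                        [np.interp(val[0], tf_values, tf_colors[:, c]) for c in range(4)]
                    )
                    a = 0.0 if outside[0] else rgba[3]
                    a = 1.0 - (1.0 - a) ** step_mm
                    samples.append((rgba[:3], a))
            C, A = over_back_to_front(samples)
            img[i, j, :3] = C + (1.0 - A) * np.asarray(background)
            img[i, j, 3] = A
    return img


def surface_voxels_bf(mask):
    """Surface voxels by explicit 6-neighbour checking, border = background."""
    fg = np.asarray(mask, bool)
    out = np.zeros_like(fg)
    dims = fg.shape
    for idx in np.argwhere(fg):
        i, j, k = idx
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            if not (0 <= ni < dims[0] and 0 <= nj < dims[1] and 0 <= nk < dims[2]):
                out[i, j, k] = True
                break
            if not fg[ni, nj, nk]:
                out[i, j, k] = True
                break
    return out


def hausdorff_bf(mask_a, mask_b, spacing):
    """All-pairs O(n^2) Hausdorff statistics on pooled directed distances."""
    sa = np.argwhere(surface_voxels_bf(mask_a)) * np.asarray(spacing)
    sb = np.argwhere(surface_voxels_bf(mask_b)) * np.asarray(spacing)
    d = np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1))
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    pooled = np.concatenate([d_ab, d_ba])
    return {
        "hd_max": float(pooled.max()),
        "hd_avg": float(pooled.mean()),
        "hd_95": float(np.percentile(pooled, 95)),
    }


def dice_bf(mask_a, mask_b):
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    return 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))


def point_in_polygon_bf(point, polygon, atol=1e-9):
    """Crossing-number test for one point with boundary-inclusive rule,
    written independently (angle-free winding via explicit edge walk)."""
    x, y = point
    poly = np.asarray(polygon, float)
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # on-segment check
        dx, dy = x2 - x1, y2 - y1
        L2 = dx * dx + dy * dy
        if L2 == 0:
            if np.hypot(x - x1, y - y1) <= atol:
                return True
        else:
            t = max(0.0, min(1.0, ((x - x1) * dx + (y - y1) * dy) / L2))
            if np.hypot(x - (x1 + t * dx), y - (y1 + t * dy)) <= atol:
                return True
        if (y1 > y) != (y2 > y):
            if x < x1 + (y - y1) * (x2 - x1) / (y2 - y1):
                inside = not inside
    return inside
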
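"""Numba kernels for directional intercept sampling inside spherical VOIs.

Positions are tracked in fractional grid-index coordinates (z, y, x order)
with nearest-voxel lookup; censoring at the VOI sphere boundary is detected
analytically from the quadratic |p0 + t*d - c|^2 = R^2.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def star_lengths(grid, spacing, pts_idx, off_c, dirs_idx, dot_dc, r2, step,
                 mean_l, mean_l3, censored_frac):
    """Point-sampled star lengths.

    grid      : uint8 (nz, ny, nx) bone phase
    spacing   : (3,) voxel size (z, y, x) -- only used via precomputed steps
    pts_idx   : (np, 3) start voxel indices (float, z,y,x)
    off_c     : (np,) |p0 - c|^2 in mm^2 for each point
    dirs_idx  : (nd, 3) per-step index increment for each direction
    dot_dc    : (np, nd) (p0 - c) . d_world in mm (for the sphere quadratic)
    r2        : VOI radius squared (mm^2)
    step      : physical step length (mm)
    outputs   : per-direction mean L, mean L^3, censored fraction
    """
    nd = dirs_idx.shape[0]
    npt = pts_idx.shape[0]
    nz, ny, nx = grid.shape
    for j in range(nd):
        dz = dirs_idx[j, 0]
        dy = dirs_idx[j, 1]
        dx = dirs_idx[j, 2]
        s_l = 0.0
        s_l3 = 0.0
        n_cens = 0
        for i in range(npt):
            total = 0.0
            censored = False
            b = dot_dc[i, j]
            c0 = off_c[i] - r2
            for sgn in (1.0, -1.0):
                t = 0.0
                pz = pts_idx[i, 0]
                py = pts_idx[i, 1]
                px = pts_idx[i, 2]
                while True:
                    t += step
                    # sphere test: |u + sgn*t*d|^2 > R^2 ?
                    if t * t + 2.0 * sgn * t * b + c0 > 0.0:
                        censored = True
                        break
                    pz += sgn * dz
                    py += sgn * dy
                    px += sgn * dx
                    iz = int(np.floor(pz + 0.5))
                    iy = int(np.floor(py + 0.5))
                    ix = int(np.floor(px + 0.5))
                    if iz < 0 or iz >= nz or iy < 0 or iy >= ny or ix < 0 or ix >= nx:
                        censored = True
                        break
                    if grid[iz, iy, ix] == 0:
                        break
                total += t - step  # last bone-confirmed travel
            L = total + step  # chord through the sampled voxel itself
            s_l += L
            s_l3 += L * L * L
            if censored:
                n_cens += 1
        mean_l[j] = s_l / npt
        mean_l3[j] = s_l3 / npt
        censored_frac[j] = n_cens / npt


@njit(cache=True)
def mil_lines(grid, origin_idx_step, c_idx, e1_idx, e2_idx, r_mm, grid_spacing,
              step, n_half, min_run, out_mil, out_flag):
    """Mean intercept length over a parallel-line grid, one direction.

    Lines run along the direction whose per-step index increment is
    ``origin_idx_step``; line origins sit on the lattice c + u*e1 + v*e2
    (e1_idx/e2_idx are the index-space images of the in-plane unit vectors
    scaled by ``grid_spacing``).  Returns mean bone intercept length
    (total bone length / number of bone runs); intercepts shorter than
    ``min_run`` (sub-voxel staircase fragments of grazing lines) are not
    resolvable at the grid resolution and are ignored.  Lines with no bone
    yield a censored value of the VOI diameter.
    """
    nz, ny, nx = grid.shape
    bone_len = 0.0
    n_runs = 0
    for iu in range(-n_half, n_half + 1):
        for iv in range(-n_half, n_half + 1):
            u = iu * grid_spacing
            v = iv * grid_spacing
            h2 = u * u + v * v
            if h2 >= r_mm * r_mm:
                continue
            half_chord = np.sqrt(r_mm * r_mm - h2)
            n_steps = int(2.0 * half_chord / step)
            if n_steps < 1:
                continue
            # start position in index space
            pz = c_idx[0] + iu * e1_idx[0] + iv * e2_idx[0] - half_chord / step * origin_idx_step[0]
            py = c_idx[1] + iu * e1_idx[1] + iv * e2_idx[1] - half_chord / step * origin_idx_step[1]
            px = c_idx[2] + iu * e1_idx[2] + iv * e2_idx[2] - half_chord / step * origin_idx_step[2]
            run = 0.0
            for s in range(n_steps):
                iz = int(np.floor(pz + 0.5))
                iy = int(np.floor(py + 0.5))
                ix = int(np.floor(px + 0.5))
                inside = (iz >= 0 and iz < nz and iy >= 0 and iy < ny
                          and ix >= 0 and ix < nx)
                val = grid[iz, iy, ix] if inside else 0
                if val != 0:
                    run += step
                else:
                    if run >= min_run:
                        bone_len += run
                        n_runs += 1
                    run = 0.0
                pz += origin_idx_step[0]
                py += origin_idx_step[1]
                px += origin_idx_step[2]
            if run >= min_run:
                bone_len += run
                n_runs += 1
    if n_runs == 0:
        out_mil[0] = 2.0 * r_mm
        out_flag[0] = 1
    else:
        out_mil[0] = bone_len / n_runs
        out_flag[0] = 0
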
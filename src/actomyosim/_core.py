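"""Numba kernels for the Brownian-dynamics engine.

Everything here operates on the flat arrays held by
:class:`actomyosim.state.SimulationState`, in nm / pN / s units.  The kernels
are composable ``@njit`` functions; :func:`run_chunk` fuses force evaluation,
thermal noise, the Euler update and motor/binding kinetics into one compiled
loop so that a time step costs microseconds.

Periodic axes use the minimum-image convention everywhere; non-periodic axes
carry harmonic repulsive walls at the box faces.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# run_chunk status codes
OK = 0
UNSTABLE = 1

# occupancy codes
FREE = 0
OCC_ACP = 1
OCC_ARM = 2


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------
@njit(cache=True, inline="always", fastmath=True)
def _min_image(dx, dy, dz, box, periodic):
    if periodic[0]:
        dx -= box[0] * np.rint(dx / box[0])
    if periodic[1]:
        dy -= box[1] * np.rint(dy / box[1])
    if periodic[2]:
        dz -= box[2] * np.rint(dz / box[2])
    return dx, dy, dz


@njit(cache=True, fastmath=True)
def _segment_closest(p1, q1, p2, q2):
    """Closest points between segments [p1,q1] and [p2,q2].

    Returns (s, t, dx, dy, dz, dist) with s, t in [0, 1] the parametric
    coordinates of the closest points and d the vector from point-on-2 to
    point-on-1.  Degenerate (parallel / coincident) cases fall back to the
    clamped projection branch of the standard algorithm.
    """
    d1x, d1y, d1z = q1[0] - p1[0], q1[1] - p1[1], q1[2] - p1[2]
    d2x, d2y, d2z = q2[0] - p2[0], q2[1] - p2[1], q2[2] - p2[2]
    rx, ry, rz = p1[0] - p2[0], p1[1] - p2[1], p1[2] - p2[2]
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    c = d1x * rx + d1y * ry + d1z * rz
    b = d1x * d2x + d1y * d2y + d1z * d2z
    denom = a * e - b * b
    if denom > 1e-12 * a * e + 1e-30:
        s = (b * f - c * e) / denom
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    else:
        s = 0.0
    t = (b * s + f) / e if e > 1e-30 else 0.0
    if t < 0.0:
        t = 0.0
        s = -c / a if a > 1e-30 else 0.0
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    elif t > 1.0:
        t = 1.0
        s = (b - c) / a if a > 1e-30 else 0.0
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    cx = p1[0] + s * d1x - (p2[0] + t * d2x)
    cy = p1[1] + s * d1y - (p2[1] + t * d2y)
    cz = p1[2] + s * d1z - (p2[2] + t * d2z)
    dist = np.sqrt(cx * cx + cy * cy + cz * cz)
    return s, t, cx, cy, cz, dist


# ----------------------------------------------------------------------
# deterministic forces
# ----------------------------------------------------------------------
@njit(cache=True, fastmath=True)
def stretch_forces(pos, f, bond_i, bond_j, bond_r0, bond_k, box, periodic):
    for n in range(bond_i.shape[0]):
        i = bond_i[n]
        j = bond_j[n]
        dx, dy, dz = _min_image(pos[j, 0] - pos[i, 0],
                                pos[j, 1] - pos[i, 1],
                                pos[j, 2] - pos[i, 2], box, periodic)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            # zero-length segment: direction undefined
            return UNSTABLE
        mag = bond_k[n] * (r - bond_r0[n]) / r
        f[i, 0] += mag * dx
        f[i, 1] += mag * dy
        f[i, 2] += mag * dz
        f[j, 0] -= mag * dx
        f[j, 1] -= mag * dy
        f[j, 2] -= mag * dz
    return OK


@njit(cache=True, inline="always", fastmath=True)
def _angle_forces_points(ax, ay, az, bx, by, bz, cx, cy, cz, kappa):
    """Bending forces for the joint a-b-c with straight equilibrium.

    The angle theta is the one between segment directions (b-a) and (c-b);
    U = 0.5*kappa*theta^2.  Returns the three force vectors.  The torque
    prefactor is capped at its theta = pi/2 value so a fully folded joint
    (theta -> pi) stays finite.
    """
    ux, uy, uz = ax - bx, ay - by, az - bz          # b->a
    vx, vy, vz = cx - bx, cy - by, cz - bz          # b->c
    lu = np.sqrt(ux * ux + uy * uy + uz * uz)
    lv = np.sqrt(vx * vx + vy * vy + vz * vz)
    if lu < 1e-12 or lv < 1e-12:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    ux, uy, uz = ux / lu, uy / lu, uz / lu
    vx, vy, vz = vx / lv, vy / lv, vz / lv
    cosab = ux * vx + uy * vy + uz * vz
    if cosab > 1.0:
        cosab = 1.0
    elif cosab < -1.0:
        cosab = -1.0
    # prefactor kappa*theta/sin(theta); theta is the deviation from straight
    # (theta = pi - angle(a,b,c)); regular theta -> 0 limit is kappa
    h = 1.0 + cosab                # = 1 - cos(theta)
    if h < 0.02:
        # series of theta/sin(theta) in h; error < 2e-6 at the cutoff
        pref = kappa * (1.0 + h / 3.0 + 2.0 * h * h / 15.0)
    else:
        theta = np.pi - np.arccos(cosab)
        sin_ab = np.sqrt(1.0 - cosab * cosab)
        if sin_ab < 1e-8:
            pref = kappa * (np.pi / 2.0)   # folded: cap at the pi/2 value
        else:
            pref = kappa * theta / sin_ab
            cap = kappa * (np.pi / 2.0)
            if pref > cap:
                pref = cap
    fax = (pref / lu) * (cosab * ux - vx)
    fay = (pref / lu) * (cosab * uy - vy)
    faz = (pref / lu) * (cosab * uz - vz)
    fcx = (pref / lv) * (cosab * vx - ux)
    fcy = (pref / lv) * (cosab * vy - uy)
    fcz = (pref / lv) * (cosab * vz - uz)
    return fax, fay, faz, -(fax + fcx), -(fay + fcy), -(faz + fcz), fcx, fcy, fcz


@njit(cache=True, fastmath=True)
def bend_forces(pos, f, ang_a, ang_b, ang_c, ang_k, box, periodic):
    for n in range(ang_a.shape[0]):
        a = ang_a[n]
        b = ang_b[n]
        c = ang_c[n]
        # place a and c in the minimum image relative to b
        dax, day, daz = _min_image(pos[a, 0] - pos[b, 0], pos[a, 1] - pos[b, 1],
                                   pos[a, 2] - pos[b, 2], box, periodic)
        dcx, dcy, dcz = _min_image(pos[c, 0] - pos[b, 0], pos[c, 1] - pos[b, 1],
                                   pos[c, 2] - pos[b, 2], box, periodic)
        bx, by, bz = pos[b, 0], pos[b, 1], pos[b, 2]
        (fax, fay, faz, fbx, fby, fbz,
         fcx, fcy, fcz) = _angle_forces_points(
            bx + dax, by + day, bz + daz, bx, by, bz,
            bx + dcx, by + dcy, bz + dcz, ang_k[n])
        f[a, 0] += fax
        f[a, 1] += fay
        f[a, 2] += faz
        f[b, 0] += fbx
        f[b, 1] += fby
        f[b, 2] += fbz
        f[c, 0] += fcx
        f[c, 1] += fcy
        f[c, 2] += fcz
    return OK


@njit(cache=True, fastmath=True)
def repulsive_forces(pos, f, pairs, n_pairs, seg_v1, seg_v2,
                     kr, rc, box, periodic):
    """Harmonic volume exclusion between actin segment pairs.

    ``pairs`` is the Verlet list built by :func:`build_pair_list`.  The force
    acts along the minimum-distance direction between the two cylinders and
    is distributed onto the four segment endpoints at the closest points.
    Coincident axes get a deterministic perpendicular tie-break direction.
    """
    p1 = np.empty(3)
    q1 = np.empty(3)
    p2 = np.empty(3)
    q2 = np.empty(3)
    for n in range(n_pairs):
        s1 = pairs[n, 0]
        s2 = pairs[n, 1]
        i1, j1 = seg_v1[s1], seg_v2[s1]
        i2, j2 = seg_v1[s2], seg_v2[s2]
        for k in range(3):
            p1[k] = pos[i1, k]
            q1[k] = pos[j1, k]
        # shift segment 2 by the minimum image of the midpoint separation
        m1x = 0.5 * (pos[i1, 0] + pos[j1, 0])
        m1y = 0.5 * (pos[i1, 1] + pos[j1, 1])
        m1z = 0.5 * (pos[i1, 2] + pos[j1, 2])
        m2x = 0.5 * (pos[i2, 0] + pos[j2, 0])
        m2y = 0.5 * (pos[i2, 1] + pos[j2, 1])
        m2z = 0.5 * (pos[i2, 2] + pos[j2, 2])
        sx, sy, sz = _min_image(m2x - m1x, m2y - m1y, m2z - m1z, box, periodic)
        ox, oy, oz = m1x + sx - m2x, m1y + sy - m2y, m1z + sz - m2z
        for k in range(3):
            p2[k] = pos[i2, k]
            q2[k] = pos[j2, k]
        p2[0] += ox
        p2[1] += oy
        p2[2] += oz
        q2[0] += ox
        q2[1] += oy
        q2[2] += oz
        s, t, dx, dy, dz, dist = _segment_closest(p1, q1, p2, q2)
        if dist >= rc:
            continue
        if dist < 1e-9:
            # coincident: push apart perpendicular to segment 1's axis
            ax_ = q1[0] - p1[0]
            ay_ = q1[1] - p1[1]
            az_ = q1[2] - p1[2]
            if abs(az_) < abs(ax_) or abs(az_) < abs(ay_):
                dx, dy, dz = -ay_, ax_, 0.0
            else:
                dx, dy, dz = 0.0, -az_, ay_
            nn = np.sqrt(dx * dx + dy * dy + dz * dz)
            if nn < 1e-12:
                dx, dy, dz, nn = 1.0, 0.0, 0.0, 1.0
            dx, dy, dz = dx / nn, dy / nn, dz / nn
        else:
            dx, dy, dz = dx / dist, dy / dist, dz / dist
        mag = kr * (rc - dist)
        # push segment 1 along +d, segment 2 along -d, split by closest point
        f[i1, 0] += mag * dx * (1.0 - s)
        f[i1, 1] += mag * dy * (1.0 - s)
        f[i1, 2] += mag * dz * (1.0 - s)
        f[j1, 0] += mag * dx * s
        f[j1, 1] += mag * dy * s
        f[j1, 2] += mag * dz * s
        f[i2, 0] -= mag * dx * (1.0 - t)
        f[i2, 1] -= mag * dy * (1.0 - t)
        f[i2, 2] -= mag * dz * (1.0 - t)
        f[j2, 0] -= mag * dx * t
        f[j2, 1] -= mag * dy * t
        f[j2, 2] -= mag * dz * t
    return OK


@njit(cache=True, inline="always", fastmath=True)
def _site_point(pos, v1, v2, frac, box, periodic):
    dx, dy, dz = _min_image(pos[v2, 0] - pos[v1, 0], pos[v2, 1] - pos[v1, 1],
                            pos[v2, 2] - pos[v1, 2], box, periodic)
    return (pos[v1, 0] + frac * dx, pos[v1, 1] + frac * dy,
            pos[v1, 2] + frac * dz, dx, dy, dz)


@njit(cache=True, fastmath=True)
def acp_forces(pos, f, acp_center, acp_seg, acp_site, seg_v1, seg_v2,
               site_frac, ks, r0, kb, box, periodic):
    """Cross-linker arm springs plus the straightening hinge at the center.

    Each bound arm is a spring from the center vertex to its binding site
    (a material point on an actin segment); the reaction is shared between
    the segment endpoints by the site's axial fraction.
    """
    for n in range(acp_center.shape[0]):
        c = acp_center[n]
        a0x = a0y = a0z = a1x = a1y = a1z = 0.0
        for arm in range(2):
            s = acp_seg[n, arm]
            if s < 0:
                continue
            v1 = seg_v1[s]
            v2 = seg_v2[s]
            frac = site_frac[acp_site[n, arm]]
            px, py, pz, _, _, _ = _site_point(pos, v1, v2, frac, box, periodic)
            # minimum image of attachment relative to center
            ddx, ddy, ddz = _min_image(px - pos[c, 0], py - pos[c, 1],
                                       pz - pos[c, 2], box, periodic)
            if arm == 0:
                a0x = pos[c, 0] + ddx
                a0y = pos[c, 1] + ddy
                a0z = pos[c, 2] + ddz
            else:
                a1x = pos[c, 0] + ddx
                a1y = pos[c, 1] + ddy
                a1z = pos[c, 2] + ddz
            r = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            if r < 1e-12:
                continue
            mag = ks * (r - r0) / r            # pulls center toward site
            f[c, 0] += mag * ddx
            f[c, 1] += mag * ddy
            f[c, 2] += mag * ddz
            f[v1, 0] -= mag * ddx * (1.0 - frac)
            f[v1, 1] -= mag * ddy * (1.0 - frac)
            f[v1, 2] -= mag * ddz * (1.0 - frac)
            f[v2, 0] -= mag * ddx * frac
            f[v2, 1] -= mag * ddy * frac
            f[v2, 2] -= mag * ddz * frac
        # hinge: straighten attachment1 - center - attachment2
        if acp_seg[n, 0] >= 0 and acp_seg[n, 1] >= 0 and kb > 0.0:
            (fax, fay, faz, fbx, fby, fbz, fcx, fcy, fcz) = \
                _angle_forces_points(a0x, a0y, a0z,
                                     pos[c, 0], pos[c, 1], pos[c, 2],
                                     a1x, a1y, a1z, kb)
            f[c, 0] += fbx
            f[c, 1] += fby
            f[c, 2] += fbz
            for arm in range(2):
                s = acp_seg[n, arm]
                v1 = seg_v1[s]
                v2 = seg_v2[s]
                frac = site_frac[acp_site[n, arm]]
                if arm == 0:
                    gx, gy, gz = fax, fay, faz
                else:
                    gx, gy, gz = fcx, fcy, fcz
                f[v1, 0] += gx * (1.0 - frac)
                f[v1, 1] += gy * (1.0 - frac)
                f[v1, 2] += gz * (1.0 - frac)
                f[v2, 0] += gx * frac
                f[v2, 1] += gy * frac
                f[v2, 2] += gz * frac
    return OK


@njit(cache=True, fastmath=True)
def arm_spring_full(pos, anchor, v1, v2, frac, ks2, r02, ks3, box, periodic):
    """Two-spring forces of one bound motor arm.

    Returns ``(fx, fy, fz, gx, gy, gz, load)``: the force the springs exert
    on the attachment point, the axis-rotation (torque couple) force applied
    +g on the barbed-side and -g on the pointed-side segment endpoint, and
    the load opposing barbed-ward walking (pN).  The transverse spring
    restores the anchor-site distance to ``r02``; the longitudinal spring
    penalizes the axial offset between the attachment and the foot of the
    anchor's perpendicular on the filament axis.  The couple term is the
    axis-direction part of the longitudinal gradient, so the total is
    exactly ``-dU/dr``.
    """
    px, py, pz, sx, sy, sz = _site_point(pos, v1, v2, frac, box, periodic)
    seglen = np.sqrt(sx * sx + sy * sy + sz * sz)
    if seglen < 1e-12:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    ux, uy, uz = sx / seglen, sy / seglen, sz / seglen   # barbed -> pointed
    dx, dy, dz = _min_image(px - pos[anchor, 0], py - pos[anchor, 1],
                            pz - pos[anchor, 2], box, periodic)
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    ftx = fty = ftz = 0.0
    if r > 1e-12:
        mag = -ks2 * (r - r02) / r
        ftx, fty, ftz = mag * dx, mag * dy, mag * dz
    # axial offset of attachment past the anchor's perpendicular foot
    aoff = dx * ux + dy * uy + dz * uz
    flx, fly, flz = -ks3 * aoff * ux, -ks3 * aoff * uy, -ks3 * aoff * uz
    fx, fy, fz = ftx + flx, fty + fly, ftz + flz
    # couple from the axis rotation: +- ks3*aoff*d_perp/L on the endpoints
    cpre = ks3 * aoff / seglen
    gx = cpre * (dx - aoff * ux)
    gy = cpre * (dy - aoff * uy)
    gz = cpre * (dz - aoff * uz)
    # walking is toward the barbed end (-u); load = force component along +u
    load = fx * ux + fy * uy + fz * uz
    if load < 0.0:
        load = 0.0
    return fx, fy, fz, gx, gy, gz, load


@njit(cache=True, fastmath=True)
def arm_spring_force(pos, anchor, v1, v2, frac, ks2, r02, ks3,
                     box, periodic):
    """Force on the attachment point and the walking load of a bound arm."""
    fx, fy, fz, _, _, _, load = arm_spring_full(
        pos, anchor, v1, v2, frac, ks2, r02, ks3, box, periodic)
    return fx, fy, fz, load


@njit(cache=True, fastmath=True)
def motor_arm_forces(pos, f, arm_bound, arm_anchor, arm_seg, arm_site,
                     seg_v1, seg_v2, site_frac, ks2, r02, ks3, box, periodic):
    for a in range(arm_bound.shape[0]):
        if arm_bound[a] == 0:
            continue
        anchor = arm_anchor[a]
        s = arm_seg[a]
        v1 = seg_v1[s]
        v2 = seg_v2[s]
        frac = site_frac[arm_site[a]]
        fx, fy, fz, gx, gy, gz, _ = arm_spring_full(
            pos, anchor, v1, v2, frac, ks2, r02, ks3, box, periodic)
        f[v1, 0] += fx * (1.0 - frac) + gx
        f[v1, 1] += fy * (1.0 - frac) + gy
        f[v1, 2] += fz * (1.0 - frac) + gz
        f[v2, 0] += fx * frac - gx
        f[v2, 1] += fy * frac - gy
        f[v2, 2] += fz * frac - gz
        f[anchor, 0] -= fx
        f[anchor, 1] -= fy
        f[anchor, 2] -= fz
    return OK


@njit(cache=True, fastmath=True)
def wall_forces(pos, f, box, periodic, kwall):
    for i in range(pos.shape[0]):
        for ax in range(3):
            if periodic[ax]:
                continue
            x = pos[i, ax]
            if x < 0.0:
                f[i, ax] += kwall * (-x)
            elif x > box[ax]:
                f[i, ax] += kwall * (box[ax] - x)
    return OK


# ----------------------------------------------------------------------
# neighbor list
# ----------------------------------------------------------------------
@njit(cache=True, fastmath=True)
def build_pair_list(pos, seg_v1, seg_v2, seg_fil, pairs, rc, skin,
                    box, periodic):
    """Verlet list of actin segment pairs with min distance < rc + skin.

    Segments adjacent on the same filament (sharing a vertex) are excluded.
    Candidates are gathered by binning segment midpoints along the longest
    box axis (elongated systems: bundles along z, thin networks along x/y);
    each candidate pair is confirmed with the exact segment-segment closest
    distance.  Returns the number of pairs, or -1 if the ``pairs`` buffer
    overflowed.
    """
    n_seg = seg_v1.shape[0]
    if n_seg == 0:
        return 0
    cut = rc + skin

    mid = np.empty((n_seg, 3))
    seg_len = np.empty(n_seg)
    for s in range(n_seg):
        i, j = seg_v1[s], seg_v2[s]
        dx, dy, dz = _min_image(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                                pos[j, 2] - pos[i, 2], box, periodic)
        mid[s, 0] = pos[i, 0] + 0.5 * dx
        mid[s, 1] = pos[i, 1] + 0.5 * dy
        mid[s, 2] = pos[i, 2] + 0.5 * dz
        seg_len[s] = np.sqrt(dx * dx + dy * dy + dz * dz)
    lmax = seg_len.max()

    # bin along the longest axis; adjacent bins cover the interaction reach
    axis = 0
    if box[1] > box[axis]:
        axis = 1
    if box[2] > box[axis]:
        axis = 2
    width = lmax + cut + 5.0
    nb = int(box[axis] / width)
    per_ax = periodic[axis] == 1

    count = 0
    p1 = np.empty(3)
    q1 = np.empty(3)
    p2 = np.empty(3)
    q2 = np.empty(3)

    if nb >= 3:
        binw = box[axis] / nb
        bin_of = np.empty(n_seg, dtype=np.int64)
        bin_count = np.zeros(nb + 1, dtype=np.int64)
        for s in range(n_seg):
            x = mid[s, axis] % box[axis]
            b = int(x / binw)
            if b >= nb:
                b = nb - 1
            bin_of[s] = b
            bin_count[b + 1] += 1
        bin_start = np.cumsum(bin_count)
        order = np.empty(n_seg, dtype=np.int64)
        fill = bin_start[:-1].copy()
        for s in range(n_seg):
            b = bin_of[s]
            order[fill[b]] = s
            fill[b] += 1
    else:
        binw = box[axis]
        nb = 1
        bin_start = np.array([0, n_seg], dtype=np.int64)
        order = np.arange(n_seg)

    for b in range(nb):
        for db in range(2):
            b2 = b + db
            if b2 >= nb:
                if not per_ax or nb < 3:
                    continue
                b2 -= nb
            for ii in range(bin_start[b], bin_start[b + 1]):
                s1 = order[ii]
                jj0 = ii + 1 if db == 0 else bin_start[b2]
                for jj in range(jj0, bin_start[b2 + 1]):
                    s2 = order[jj]
                    sa, sb = (s1, s2) if s1 < s2 else (s2, s1)
                    if seg_fil[sa] == seg_fil[sb] and sb - sa <= 1:
                        continue
                    sx, sy, sz = _min_image(mid[sb, 0] - mid[sa, 0],
                                            mid[sb, 1] - mid[sa, 1],
                                            mid[sb, 2] - mid[sa, 2],
                                            box, periodic)
                    md = np.sqrt(sx * sx + sy * sy + sz * sz)
                    if md > cut + 0.5 * (seg_len[sa] + seg_len[sb]):
                        continue
                    i1, j1 = seg_v1[sa], seg_v2[sa]
                    i2, j2 = seg_v1[sb], seg_v2[sb]
                    for k in range(3):
                        p1[k] = pos[i1, k]
                        q1[k] = pos[j1, k]
                        p2[k] = pos[i2, k]
                        q2[k] = pos[j2, k]
                    m2x = 0.5 * (p2[0] + q2[0])
                    m2y = 0.5 * (p2[1] + q2[1])
                    m2z = 0.5 * (p2[2] + q2[2])
                    ox = mid[sa, 0] + sx - m2x
                    oy = mid[sa, 1] + sy - m2y
                    oz = mid[sa, 2] + sz - m2z
                    p2[0] += ox
                    p2[1] += oy
                    p2[2] += oz
                    q2[0] += ox
                    q2[1] += oy
                    q2[2] += oz
                    _, _, _, _, _, dist = _segment_closest(p1, q1, p2, q2)
                    if dist < cut:
                        if count >= pairs.shape[0]:
                            return -1
                        pairs[count, 0] = sa
                        pairs[count, 1] = sb
                        count += 1
    return count


# ----------------------------------------------------------------------
# motor / binding kinetics
# ----------------------------------------------------------------------
@njit(cache=True, inline="always", fastmath=True)
def _point_segment_dist(pos, anchor, v1, v2, box, periodic):
    dx, dy, dz = _min_image(pos[v2, 0] - pos[v1, 0], pos[v2, 1] - pos[v1, 1],
                            pos[v2, 2] - pos[v1, 2], box, periodic)
    ax, ay, az = _min_image(pos[anchor, 0] - pos[v1, 0],
                            pos[anchor, 1] - pos[v1, 1],
                            pos[anchor, 2] - pos[v1, 2], box, periodic)
    l2 = dx * dx + dy * dy + dz * dz
    if l2 < 1e-30:
        t = 0.0
    else:
        t = (ax * dx + ay * dy + az * dz) / l2
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    ex, ey, ez = ax - t * dx, ay - t * dy, az - t * dz
    return np.sqrt(ex * ex + ey * ey + ez * ez)


@njit(cache=True)
def kinetics_step(pos, occupancy, site_frac,
                  seg_v1, seg_v2, seg_fil, fil_first_seg,
                  arm_bound, arm_anchor, arm_ref, arm_sibling,
                  arm_seg, arm_site,
                  p_bind, capture, k_w0, k_u0_eff, ku_floor, F_stall,
                  ks2, r02, ks3, dt, enable_bind, enable_walk, enable_unbind,
                  box, periodic):
    """One stochastic tick: binding attempts, walking, load-dependent release.

    Event order is binding -> walking -> unbinding; at the default time step
    every per-tick probability is << 1 so the ordering is second-order.
    Walking follows the linear force-velocity law
    ``k_w(F) = k_w0 * max(0, 1 - F/F_stall)`` and unbinding the catch bond
    ``k_u(F) = max(k_u0 * exp(-F/F_cat), floor)`` (``k_u0_eff`` already folds
    in 1/F_cat via its second slot — see caller).
    """
    n_arm = arm_bound.shape[0]
    n_sites = site_frac.shape[0]
    for a in range(n_arm):
        if arm_bound[a] == 0:
            if not enable_bind:
                continue
            if np.random.random() >= p_bind:
                continue
            anchor = arm_anchor[a]
            ref = arm_ref[a]
            wx = pos[anchor, 0] - pos[ref, 0]
            wy = pos[anchor, 1] - pos[ref, 1]
            wz = pos[anchor, 2] - pos[ref, 2]
            wn = np.sqrt(wx * wx + wy * wy + wz * wz)
            if wn < 1e-12:
                continue
            wx, wy, wz = wx / wn, wy / wn, wz / wn
            sib = arm_sibling[a]
            sib_fil = -1
            if sib >= 0 and arm_bound[sib] == 1:
                sib_fil = seg_fil[arm_seg[sib]]
            best_d = capture
            best_seg = -1
            best_site = -1
            for s in range(seg_v1.shape[0]):
                if seg_fil[s] == sib_fil:
                    continue
                if _point_segment_dist(pos, anchor, seg_v1[s], seg_v2[s],
                                       box, periodic) >= best_d:
                    continue
                v1 = seg_v1[s]
                v2 = seg_v2[s]
                dx, dy, dz = _min_image(pos[v2, 0] - pos[v1, 0],
                                        pos[v2, 1] - pos[v1, 1],
                                        pos[v2, 2] - pos[v1, 2],
                                        box, periodic)
                # polarity alignment: the walking direction (toward the arm's
                # backbone end) must have positive overlap with the filament's
                # barbed-end direction (-d, since v1 is the barbed side)
                if -(wx * dx + wy * dy + wz * dz) <= 0.0:
                    continue
                for k in range(n_sites):
                    if occupancy[s, k] != FREE:
                        continue
                    frac = site_frac[k]
                    px = pos[v1, 0] + frac * dx
                    py = pos[v1, 1] + frac * dy
                    pz = pos[v1, 2] + frac * dz
                    ddx, ddy, ddz = _min_image(px - pos[anchor, 0],
                                               py - pos[anchor, 1],
                                               pz - pos[anchor, 2],
                                               box, periodic)
                    d = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                    if d < best_d:
                        best_d = d
                        best_seg = s
                        best_site = k
            if best_seg >= 0:
                arm_bound[a] = 1
                arm_seg[a] = best_seg
                arm_site[a] = best_site
                occupancy[best_seg, best_site] = OCC_ARM
            continue

        # bound arm: load, walk, unbind
        anchor = arm_anchor[a]
        s = arm_seg[a]
        v1 = seg_v1[s]
        v2 = seg_v2[s]
        frac = site_frac[arm_site[a]]
        _, _, _, load = arm_spring_force(pos, anchor, v1, v2, frac,
                                         ks2, r02, ks3, box, periodic)
        if enable_walk:
            kw = 0.0
            if load < F_stall:
                kw = k_w0 * (1.0 - load / F_stall)
            if kw > 0.0 and np.random.random() < -np.expm1(-kw * dt):
                k = arm_site[a]
                if k > 0:
                    if occupancy[s, k - 1] == FREE:
                        occupancy[s, k] = FREE
                        occupancy[s, k - 1] = OCC_ARM
                        arm_site[a] = k - 1
                elif s > fil_first_seg[seg_fil[s]]:
                    if occupancy[s - 1, n_sites - 1] == FREE:
                        occupancy[s, k] = FREE
                        occupancy[s - 1, n_sites - 1] = OCC_ARM
                        arm_seg[a] = s - 1
                        arm_site[a] = n_sites - 1
                # barbed-end terminal site: no step
        if enable_unbind:
            ku = k_u0_eff[0] * np.exp(-load * k_u0_eff[1])
            if ku < ku_floor:
                ku = ku_floor
            if np.random.random() < -np.expm1(-ku * dt):
                occupancy[arm_seg[a], arm_site[a]] = FREE
                arm_bound[a] = 0
                arm_seg[a] = -1
                arm_site[a] = -1
    return OK


# ----------------------------------------------------------------------
# fused time stepping
# ----------------------------------------------------------------------
@njit(cache=True, fastmath=True)
def compute_forces(pos, f,
                   bond_i, bond_j, bond_r0, bond_k,
                   ang_a, ang_b, ang_c, ang_k,
                   pairs, n_pairs, seg_v1, seg_v2,
                   acp_center, acp_seg, acp_site,
                   arm_bound, arm_anchor, arm_seg, arm_site,
                   site_frac, prm, box, periodic):
    """Assemble all deterministic forces into ``f`` (pN).

    ``prm`` packs scalar parameters:
    [ks_ACP, r0_ACP, kb_ACP, ks_M2, r0_M2, ks_M3, kr_A, rc_A, kwall].
    """
    f[:] = 0.0
    st = stretch_forces(pos, f, bond_i, bond_j, bond_r0, bond_k, box, periodic)
    if st != OK:
        return st
    bend_forces(pos, f, ang_a, ang_b, ang_c, ang_k, box, periodic)
    if n_pairs > 0:
        repulsive_forces(pos, f, pairs, n_pairs, seg_v1, seg_v2,
                         prm[6], prm[7], box, periodic)
    acp_forces(pos, f, acp_center, acp_seg, acp_site, seg_v1, seg_v2,
               site_frac, prm[0], prm[1], prm[2], box, periodic)
    motor_arm_forces(pos, f, arm_bound, arm_anchor, arm_seg, arm_site,
                     seg_v1, seg_v2, site_frac, prm[3], prm[4], prm[5],
                     box, periodic)
    wall_forces(pos, f, box, periodic, prm[8])
    return OK


@njit(cache=True)
def run_chunk(nsteps, seed,
              pos, f, zeta, sigma, mobile,
              bond_i, bond_j, bond_r0, bond_k,
              ang_a, ang_b, ang_c, ang_k,
              seg_v1, seg_v2, seg_fil, fil_first_seg,
              occupancy, site_frac,
              acp_center, acp_seg, acp_site,
              arm_bound, arm_anchor, arm_ref, arm_sibling, arm_seg, arm_site,
              pairs, prm, kin, box, periodic,
              dt, skin, thermal_on, kinetics_flags, kin_stride):
    """Advance the system ``nsteps`` Euler steps.

    ``kin`` packs kinetics scalars:
    [p_bind, capture, k_w0, k_u0, 1/F_cat, ku_floor, F_stall].
    ``kinetics_flags`` = (bind, walk, unbind) as 0/1; kinetic events are
    evaluated every ``kin_stride`` steps over the interval
    ``kin_stride * dt`` (all per-tick probabilities stay << 1).
    Returns (status, steps_done).  The Verlet pair list is rebuilt whenever
    accumulated motion could have eaten through the safety skin; a per-step
    displacement above half an actin segment aborts with UNSTABLE.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_pairs = build_pair_list(pos, seg_v1, seg_v2, seg_fil, pairs,
                              prm[7], skin, box, periodic)
    if n_pairs < 0:
        return UNSTABLE, 0
    pos_ref = pos.copy()          # positions at the last pair-list rebuild
    check_every = 16
    limit2 = (0.45 * skin) ** 2
    max_disp = 0.5 * 140.0
    mob = np.empty(n)
    for i in range(n):
        mob[i] = dt / zeta[i]
    # thermal noise is drawn in batches: per-call overhead of the bulk
    # generator dwarfs the per-value cost at typical system sizes
    nbatch = 64
    noise = np.zeros(3 * n * nbatch)
    k_u0_eff = np.empty(2)
    k_u0_eff[0] = kin[3]
    k_u0_eff[1] = kin[4]
    for step in range(nsteps):
        st = compute_forces(pos, f, bond_i, bond_j, bond_r0, bond_k,
                            ang_a, ang_b, ang_c, ang_k,
                            pairs, n_pairs, seg_v1, seg_v2,
                            acp_center, acp_seg, acp_site,
                            arm_bound, arm_anchor, arm_seg, arm_site,
                            site_frac, prm, box, periodic)
        if st != OK:
            return st, step
        if thermal_on and step % nbatch == 0:
            noise = np.random.standard_normal(3 * n * nbatch)
        off = 3 * n * (step % nbatch)
        step_max = 0.0
        for i in range(n):
            if not mobile[i]:
                continue
            m = mob[i]
            dx = f[i, 0] * m
            dy = f[i, 1] * m
            dz = f[i, 2] * m
            if thermal_on:
                sm = sigma[i] * m
                dx += sm * noise[off + 3 * i]
                dy += sm * noise[off + 3 * i + 1]
                dz += sm * noise[off + 3 * i + 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > step_max:
                step_max = d2
            pos[i, 0] += dx
            pos[i, 1] += dy
            pos[i, 2] += dz
            for ax in range(3):
                if periodic[ax]:
                    if pos[i, ax] >= box[ax]:
                        pos[i, ax] -= box[ax]
                    elif pos[i, ax] < 0.0:
                        pos[i, ax] += box[ax]
        if np.sqrt(step_max) > max_disp:
            return UNSTABLE, step
        if ((kinetics_flags[0] or kinetics_flags[1] or kinetics_flags[2])
                and step % kin_stride == 0):
            kinetics_step(pos, occupancy, site_frac,
                          seg_v1, seg_v2, seg_fil, fil_first_seg,
                          arm_bound, arm_anchor, arm_ref, arm_sibling,
                          arm_seg, arm_site,
                          kin[0], kin[1], kin[2], k_u0_eff, kin[5], kin[6],
                          prm[3], prm[4], prm[5], dt * kin_stride,
                          kinetics_flags[0] == 1, kinetics_flags[1] == 1,
                          kinetics_flags[2] == 1, box, periodic)
        if step % check_every == check_every - 1:
            # rebuild the pair list when any vertex may have crossed the skin
            moved = 0.0
            for i in range(n):
                dx, dy, dz = _min_image(pos[i, 0] - pos_ref[i, 0],
                                        pos[i, 1] - pos_ref[i, 1],
                                        pos[i, 2] - pos_ref[i, 2],
                                        box, periodic)
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > moved:
                    moved = d2
            if moved > limit2:
                n_pairs = build_pair_list(pos, seg_v1, seg_v2, seg_fil, pairs,
                                          prm[7], skin, box, periodic)
                if n_pairs < 0:
                    return UNSTABLE, step
                for i in range(n):
                    pos_ref[i, 0] = pos[i, 0]
                    pos_ref[i, 1] = pos[i, 1]
                    pos_ref[i, 2] = pos[i, 2]
    return OK, nsteps
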
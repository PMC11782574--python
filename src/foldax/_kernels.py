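"""Numba kernels for the explicit quasi-static bilayer solver.

Total-Lagrangian Q4 elements with one-point (reduced) integration and
Flanagan-Belytschko hourglass stabilization.  Full integration shear-locks
the thin cortical film in bending and suppresses the folding instability at
usable mesh resolutions; reduced integration with hourglass control is the
standard explicit-dynamics treatment for this problem class.  Plane strain
is carried as full 3x3 kinematics with F_33 = 1; growth tensors keep their
3-D forms so tangential cortical growth induces out-of-plane elastic
compression.

Region codes follow :class:`foldax.kinematics.Region`:
0 = cortex (tangential growth, referential normal e_y),
1 = ECM, 2 = fiber (both grow isotropically with the substrate multiplier).
"""

import math

import numpy as np
from numba import njit

# corner sign pattern of the bilinear element, counter-clockwise
_SX = np.array([-1.0, 1.0, 1.0, -1.0])
_SY = np.array([-1.0, -1.0, 1.0, 1.0])
_G = 1.0 / np.sqrt(3.0)
_GPX = np.array([-_G, _G, _G, -_G])
_GPY = np.array([-_G, -_G, _G, _G])

STATUS_OK = 0
STATUS_INVERTED = 1
STATUS_BLOWUP = 2


@njit(cache=True)
def shape_gradients(xi, eta):
    """dN/dxi (4, 2) of the bilinear quad at a parent point."""
    d = np.empty((4, 2))
    for a in range(4):
        d[a, 0] = 0.25 * _SX[a] * (1.0 + _SY[a] * eta)
        d[a, 1] = 0.25 * _SY[a] * (1.0 + _SX[a] * xi)
    return d


@njit(cache=True)
def precompute_gradients(nodes, quads):
    """Centre shape gradients, areas and hourglass vectors per element.

    Returns (dNdX (E, 4, 2) at the element centre, area (E,), gamma (E, 4)
    Flanagan-Belytschko hourglass base vectors).
    """
    E = quads.shape[0]
    dNdX = np.empty((E, 4, 2))
    area = np.empty(E)
    gamma = np.empty((E, 4))
    h = np.array([1.0, -1.0, 1.0, -1.0])
    dxi = shape_gradients(0.0, 0.0)
    for e in range(E):
        J00 = 0.0
        J01 = 0.0
        J10 = 0.0
        J11 = 0.0
        for a in range(4):
            n = quads[e, a]
            J00 += nodes[n, 0] * dxi[a, 0]
            J10 += nodes[n, 0] * dxi[a, 1]
            J01 += nodes[n, 1] * dxi[a, 0]
            J11 += nodes[n, 1] * dxi[a, 1]
        det = J00 * J11 - J01 * J10
        area[e] = 4.0 * det
        i00 = J11 / det
        i01 = -J01 / det
        i10 = -J10 / det
        i11 = J00 / det
        hx = 0.0
        hy = 0.0
        for a in range(4):
            dNdX[e, a, 0] = dxi[a, 0] * i00 + dxi[a, 1] * i10
            dNdX[e, a, 1] = dxi[a, 0] * i01 + dxi[a, 1] * i11
            n = quads[e, a]
            hx += h[a] * nodes[n, 0]
            hy += h[a] * nodes[n, 1]
        for a in range(4):
            gamma[e, a] = h[a] - hx * dNdX[e, a, 0] - hy * dNdX[e, a, 1]
    return dNdX, area, gamma


@njit(cache=True, fastmath=True)
def internal_forces(
    quads,
    dNdX,
    area,
    gamma,
    region,
    mu,
    kbulk,
    theta_c,
    theta_s,
    u,
    f_int,
    stress,
    hg_coef,
):
    """Assemble nodal internal forces and per-element Cauchy stresses.

    One-point quadrature at the element centre with Flanagan-Belytschko
    hourglass stabilization.  ``stress[e]`` holds (T11, T22, T12, T33).
    Returns (internal energy, inverted element id or -1); ``f_int`` is
    overwritten.
    """
    E = quads.shape[0]
    f_int[:] = 0.0
    ie = 0.0
    sc = np.sqrt(theta_c)
    gs = theta_s ** (1.0 / 3.0)
    for e in range(E):
        reg = region[e]
        if reg == 0:
            gx = sc       # in-plane tangential stretch of cortical growth
            gy = 1.0      # no growth along the referential pial normal e_y
            gz = sc
            detFg = theta_c
        else:
            gx = gs
            gy = gs
            gz = gs
            detFg = theta_s
        mue = mu[e]
        ke = kbulk[e]

        F11 = 1.0
        F12 = 0.0
        F21 = 0.0
        F22 = 1.0
        for a in range(4):
            n = quads[e, a]
            F11 += u[n, 0] * dNdX[e, a, 0]
            F12 += u[n, 0] * dNdX[e, a, 1]
            F21 += u[n, 1] * dNdX[e, a, 0]
            F22 += u[n, 1] * dNdX[e, a, 1]
        # Fe = F . Fg^-1 with diagonal Fg
        e11 = F11 / gx
        e12 = F12 / gy
        e21 = F21 / gx
        e22 = F22 / gy
        e33 = 1.0 / gz
        Je = (e11 * e22 - e12 * e21) * e33
        if Je <= 0.0:
            return ie, e

        # b = Fe Fe^T (in-plane block and 33 component)
        b11 = e11 * e11 + e12 * e12
        b22 = e21 * e21 + e22 * e22
        b12 = e11 * e21 + e12 * e22
        b33 = e33 * e33
        trb = b11 + b22 + b33
        fac = mue / Je * Je ** (-2.0 / 3.0)
        third = trb / 3.0
        p = ke * (Je - 1.0)
        T11 = fac * (b11 - third) + p
        T22 = fac * (b22 - third) + p
        T12 = fac * b12
        T33 = fac * (b33 - third) + p
        stress[e, 0] = T11
        stress[e, 1] = T22
        stress[e, 2] = T12
        stress[e, 3] = T33

        w = area[e]
        ie += w * detFg * (
            0.5 * mue * (Je ** (-2.0 / 3.0) * trb - 3.0) + 0.5 * ke * (Je - 1.0) ** 2
        )

        # first Piola-Kirchhoff in-plane block: P = det(F2d) T F^-T
        # det(F2d) * F^-T = [[F22, -F21], [-F12, F11]]
        P11 = T11 * F22 - T12 * F12
        P12 = -T11 * F21 + T12 * F11
        P21 = T12 * F22 - T22 * F12
        P22 = -T12 * F21 + T22 * F11
        for a in range(4):
            n = quads[e, a]
            f_int[n, 0] += w * (P11 * dNdX[e, a, 0] + P12 * dNdX[e, a, 1])
            f_int[n, 1] += w * (P21 * dNdX[e, a, 0] + P22 * dNdX[e, a, 1])

        # hourglass stabilization (stiffness form)
        qx = 0.0
        qy = 0.0
        bb = 0.0
        for a in range(4):
            n = quads[e, a]
            qx += gamma[e, a] * u[n, 0]
            qy += gamma[e, a] * u[n, 1]
            bb += dNdX[e, a, 0] ** 2 + dNdX[e, a, 1] ** 2
        kappa = hg_coef * mue * w * bb
        for a in range(4):
            n = quads[e, a]
            f_int[n, 0] += kappa * gamma[e, a] * qx
            f_int[n, 1] += kappa * gamma[e, a] * qy
        ie += 0.5 * kappa * (qx * qx + qy * qy)
    return ie, -1


@njit(cache=True)
def pial_contact_forces(pial, nodes, u, r_contact, k_pen, f_int):
    """Penalty node-to-segment self-contact on the pial polyline.

    For every pial node closer than ``r_contact`` to a non-adjacent pial
    segment, a linear penalty force k_pen * (r_contact - d) pushes the node
    away along the closest-point normal, with the equal-and-opposite
    reaction split barycentrically over the segment nodes.  Forces are
    accumulated into ``f_int`` (internal-force sign convention).  Returns
    the number of active contacts.
    """
    n = pial.shape[0]
    n_active = 0
    for i in range(n):
        p = pial[i]
        px = nodes[p, 0] + u[p, 0]
        py = nodes[p, 1] + u[p, 1]
        for j in range(n - 1):
            if i - 2 <= j <= i + 2:  # skip the node's own neighbourhood
                continue
            a = pial[j]
            b = pial[j + 1]
            ax = nodes[a, 0] + u[a, 0]
            ay = nodes[a, 1] + u[a, 1]
            bx = nodes[b, 0] + u[b, 0]
            by = nodes[b, 1] + u[b, 1]
            ex = bx - ax
            ey = by - ay
            ee = ex * ex + ey * ey
            if ee <= 1e-30:
                continue
            t = ((px - ax) * ex + (py - ay) * ey) / ee
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
            cx = ax + t * ex
            cy = ay + t * ey
            dx = px - cx
            dy = py - cy
            d = math.sqrt(dx * dx + dy * dy)
            if d >= r_contact or d <= 1e-12:
                continue
            n_active += 1
            fmag = k_pen * (r_contact - d)
            fx = fmag * dx / d
            fy = fmag * dy / d
            f_int[p, 0] -= fx
            f_int[p, 1] -= fy
            f_int[a, 0] += (1.0 - t) * fx
            f_int[a, 1] += (1.0 - t) * fy
            f_int[b, 0] += t * fx
            f_int[b, 1] += t * fy
    return n_active


@njit(cache=True, fastmath=True)
def run_substeps(
    nsub,
    dt,
    nodes,
    quads,
    dNdX,
    area,
    gamma,
    region,
    mu,
    kbulk,
    u,
    v,
    mass,
    fix_x,
    fix_y,
    damping,
    G_ctx,
    G_sub,
    theta_c0,
    theta_s0,
    exponential,
    f_int,
    stress,
    hg_coef,
    pial,
    contact_r,
    contact_k,
    ke_out,
    ie_out,
):
    """Advance ``nsub`` central-difference increments in place.

    Growth multipliers advance per increment before force evaluation; with
    ``contact_r > 0`` pial self-contact penalty forces are added each
    increment.  Returns (theta_c, theta_s, status, bad_element).
    """
    N = u.shape[0]
    theta_c = theta_c0
    theta_s = theta_s0
    for s in range(nsub):
        if exponential:
            theta_c *= 1.0 + G_ctx * dt
            theta_s *= 1.0 + G_sub * dt
        else:
            theta_c += G_ctx * dt
            theta_s += G_sub * dt
        ie, bad = internal_forces(
            quads, dNdX, area, gamma, region, mu, kbulk,
            theta_c, theta_s, u, f_int, stress, hg_coef,
        )
        if contact_r > 0.0:
            pial_contact_forces(pial, nodes, u, contact_r, contact_k, f_int)
        ke = 0.0
        for n in range(N):
            ax = -f_int[n, 0] / mass[n] - damping * v[n, 0]
            ay = -f_int[n, 1] / mass[n] - damping * v[n, 1]
            if fix_x[n]:
                v[n, 0] = 0.0
                u[n, 0] = 0.0
            else:
                v[n, 0] += ax * dt
                u[n, 0] += v[n, 0] * dt
            if fix_y[n]:
                v[n, 1] = 0.0
                u[n, 1] = 0.0
            else:
                v[n, 1] += ay * dt
                u[n, 1] += v[n, 1] * dt
            ke += 0.5 * mass[n] * (v[n, 0] ** 2 + v[n, 1] ** 2)
        ke_out[s] = ke
        ie_out[s] = ie
        if bad >= 0:
            return theta_c, theta_s, STATUS_INVERTED, bad
        if ie > 1e-12 and ke > 10.0 * ie:
            return theta_c, theta_s, STATUS_BLOWUP, -1
    return theta_c, theta_s, STATUS_OK, -1


@njit(cache=True)
def invert_bilinear(xq, yq, px, py):
    """Newton inversion of the bilinear map of one (deformed) quad.

    ``xq, yq`` are the 4 corner coordinates (ccw).  Returns (xi, eta, ok)
    with ok = True when converged inside the slightly inflated parent square.
    """
    xi = 0.0
    eta = 0.0
    for _ in range(12):
        x = 0.0
        y = 0.0
        dxdxi = 0.0
        dxdeta = 0.0
        dydxi = 0.0
        dydeta = 0.0
        for a in range(4):
            Na = 0.25 * (1.0 + _SX[a] * xi) * (1.0 + _SY[a] * eta)
            dNxi = 0.25 * _SX[a] * (1.0 + _SY[a] * eta)
            dNeta = 0.25 * _SY[a] * (1.0 + _SX[a] * xi)
            x += Na * xq[a]
            y += Na * yq[a]
            dxdxi += dNxi * xq[a]
            dxdeta += dNeta * xq[a]
            dydxi += dNxi * yq[a]
            dydeta += dNeta * yq[a]
        rx = x - px
        ry = y - py
        det = dxdxi * dydeta - dxdeta * dydxi
        if abs(det) < 1e-300:
            return 0.0, 0.0, False
        dxi = (dydeta * rx - dxdeta * ry) / det
        deta = (-dydxi * rx + dxdxi * ry) / det
        xi -= dxi
        eta -= deta
        if abs(dxi) < 1e-12 and abs(deta) < 1e-12:
            break
    ok = (-1.0 - 1e-8 <= xi <= 1.0 + 1e-8) and (-1.0 - 1e-8 <= eta <= 1.0 + 1e-8)
    return xi, eta, ok


@njit(cache=True)
def _orient(ax, ay, bx, by, cx, cy):
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


@njit(cache=True)
def _on_segment(ax, ay, bx, by, px, py):
    return (
        min(ax, bx) - 1e-12 <= px <= max(ax, bx) + 1e-12
        and min(ay, by) - 1e-12 <= py <= max(ay, by) + 1e-12
    )


@njit(cache=True)
def seg_seg_intersect(ax, ay, bx, by, cx, cy, dx, dy):
    """Inclusive segment/segment intersection (touching counts)."""
    d1 = _orient(cx, cy, dx, dy, ax, ay)
    d2 = _orient(cx, cy, dx, dy, bx, by)
    d3 = _orient(ax, ay, bx, by, cx, cy)
    d4 = _orient(ax, ay, bx, by, dx, dy)
    if ((d1 > 0 and d2 < 0) or (d1 < 0 and d2 > 0)) and (
        (d3 > 0 and d4 < 0) or (d3 < 0 and d4 > 0)
    ):
        return True
    if d1 == 0.0 and _on_segment(cx, cy, dx, dy, ax, ay):
        return True
    if d2 == 0.0 and _on_segment(cx, cy, dx, dy, bx, by):
        return True
    if d3 == 0.0 and _on_segment(ax, ay, bx, by, cx, cy):
        return True
    if d4 == 0.0 and _on_segment(ax, ay, bx, by, dx, dy):
        return True
    return False


@njit(cache=True)
def point_in_ccw_quad(px, py, xq, yq):
    """Inclusive containment in a counter-clockwise convex quad."""
    for a in range(4):
        b = (a + 1) % 4
        if _orient(xq[a], yq[a], xq[b], yq[b], px, py) < 0.0:
            return False
    return True


@njit(cache=True)
def segment_crosses_quad(p0x, p0y, p1x, p1y, xq, yq):
    """Inclusive segment / convex-quad intersection."""
    if point_in_ccw_quad(p0x, p0y, xq, yq) or point_in_ccw_quad(p1x, p1y, xq, yq):
        return True
    for a in range(4):
        b = (a + 1) % 4
        if seg_seg_intersect(p0x, p0y, p1x, p1y, xq[a], yq[a], xq[b], yq[b]):
            return True
    return False


@njit(cache=True)
def elements_crossed_window(
    p0x, p0y, p1x, p1y, nodes, quads, u, nx, ix_lo, ix_hi, iy_lo, iy_hi, out
):
    """Crossed elements within a grid window; returns hit count (ids in out)."""
    xq = np.empty(4)
    yq = np.empty(4)
    count = 0
    for iy in range(iy_lo, iy_hi + 1):
        for ix in range(ix_lo, ix_hi + 1):
            e = iy * nx + ix
            for a in range(4):
                n = quads[e, a]
                xq[a] = nodes[n, 0] + u[n, 0]
                yq[a] = nodes[n, 1] + u[n, 1]
            if segment_crosses_quad(p0x, p0y, p1x, p1y, xq, yq):
                out[count] = e
                count += 1
    return count


@njit(cache=True)
def locate_deformed_point(px, py, nodes, quads, u, nx, ny, hint_ix, hint_iy, max_ring):
    """Find the element whose deformed footprint contains (px, py).

    Ring search in element-grid indices around a hint, testing membership by
    bilinear inversion of the deformed quad.  Returns (elem, xi, eta) or
    (-1, 0, 0) when not found within ``max_ring`` rings.
    """
    xq = np.empty(4)
    yq = np.empty(4)
    for ring in range(max_ring + 1):
        for iy in range(hint_iy - ring, hint_iy + ring + 1):
            if iy < 0 or iy >= ny:
                continue
            for ix in range(hint_ix - ring, hint_ix + ring + 1):
                if ix < 0 or ix >= nx:
                    continue
                if max(abs(ix - hint_ix), abs(iy - hint_iy)) != ring:
                    continue
                e = iy * nx + ix
                for a in range(4):
                    n = quads[e, a]
                    xq[a] = nodes[n, 0] + u[n, 0]
                    yq[a] = nodes[n, 1] + u[n, 1]
                # cheap bbox rejection
                if (
                    px < min(xq[0], min(xq[1], min(xq[2], xq[3]))) - 1e-9
                    or px > max(xq[0], max(xq[1], max(xq[2], xq[3]))) + 1e-9
                    or py < min(yq[0], min(yq[1], min(yq[2], yq[3]))) - 1e-9
                    or py > max(yq[0], max(yq[1], max(yq[2], yq[3]))) + 1e-9
                ):
                    continue
                xi, eta, ok = invert_bilinear(xq, yq, px, py)
                if ok:
                    return e, xi, eta
    return -1, 0.0, 0.0
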
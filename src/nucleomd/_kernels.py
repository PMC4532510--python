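"""Optional numba kernels for the inner force loops.

The numpy evaluation in :mod:`forcefield` is the reference implementation;
these kernels compute exactly the same sums bead-by-bead and are used
automatically when numba imports. Pair potentials are dispatched on a
per-pair kind code with packed parameters (pa, pb, pc):

===== ==================== ==========================================
code  potential            parameters
===== ==================== ==========================================
0     harmonic bond        pa=k, pb=r0
1     quadratic+quartic    pa=r0, pb=k2, pc=k4
2     12-10 contact/bp     pa=eps, pb=r0
3     12-6 stack           pa=eps, pb=r0
4     Morse-like solvation pa=eps_s, pb=alpha, pc=r_s
5     r^-12 repulsion      pa=eps, pb=sigma, pc=cutoff
6     WCA repulsion        pa=eps, pb=sigma
7     Debye-Hueckel        pa=K q_i q_j / dielectric (lam, cut scalars)
===== ==================== ==========================================
"""

from __future__ import annotations

import math

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def pair_kernel(coords, pi, pj, kind, pa, pb, pc, lam, dh_cut, forces, e_pair):
    """Returns the index of an overlapping pair, or -1 on success."""
    for idx in range(pi.shape[0]):
        i = pi[idx]
        j = pj[idx]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-6:
            return idx
        k = kind[idx]
        e = 0.0
        dedr = 0.0
        if k == 0:
            d = r - pb[idx]
            e = pa[idx] * d * d
            dedr = 2.0 * pa[idx] * d
        elif k == 1:
            d = r - pa[idx]
            d2 = d * d
            e = pb[idx] * d2 + pc[idx] * d2 * d2
            dedr = 2.0 * pb[idx] * d + 4.0 * pc[idx] * d2 * d
        elif k == 2:
            s = pb[idx] / r
            s2 = s * s
            s10 = s2 * s2 * s2 * s2 * s2
            s12 = s10 * s2
            e = pa[idx] * (5.0 * s12 - 6.0 * s10)
            dedr = -60.0 * pa[idx] * (s12 - s10) / r
        elif k == 3:
            s = pb[idx] / r
            s2 = s * s
            s6 = s2 * s2 * s2
            e = 4.0 * pa[idx] * (s6 * s6 - s6)
            dedr = -24.0 * pa[idx] * (2.0 * s6 * s6 - s6) / r
        elif k == 4:
            g = math.exp(-pb[idx] * (r - pc[idx]))
            e = pa[idx] * ((1.0 - g) * (1.0 - g) - 1.0)
            dedr = 2.0 * pa[idx] * pb[idx] * g * (1.0 - g)
        elif k == 5:
            if r < pc[idx]:
                s = pb[idx] / r
                s2 = s * s
                s12 = s2 * s2 * s2 * s2 * s2 * s2
                e = pa[idx] * s12
                dedr = -12.0 * pa[idx] * s12 / r
        elif k == 6:
            if r < 1.122462048309373 * pb[idx]:
                s = pb[idx] / r
                s2 = s * s
                s6 = s2 * s2 * s2
                e = 4.0 * pa[idx] * (s6 * s6 - s6 + 0.25)
                dedr = -24.0 * pa[idx] * (2.0 * s6 * s6 - s6) / r
        elif k == 7:
            if r < dh_cut:
                e = pa[idx] * math.exp(-r / lam) / r
                dedr = -e * (1.0 / r + 1.0 / lam)
        e_pair[idx] = e
        c = -dedr / r
        fx = c * dx
        fy = c * dy
        fz = c * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return -1


@njit(cache=True)
def angle_kernel(coords, triples, theta0, coeff, forces, e_out):
    """E = coeff (theta - theta0)^2 per triple; collinear guard as in the
    numpy path (zero force in the degenerate direction)."""
    for idx in range(triples.shape[0]):
        i = triples[idx, 0]
        j = triples[idx, 1]
        k = triples[idx, 2]
        ax = coords[i, 0] - coords[j, 0]
        ay = coords[i, 1] - coords[j, 1]
        az = coords[i, 2] - coords[j, 2]
        bx = coords[k, 0] - coords[j, 0]
        by = coords[k, 1] - coords[j, 1]
        bz = coords[k, 2] - coords[j, 2]
        na = math.sqrt(ax * ax + ay * ay + az * az)
        nb = math.sqrt(bx * bx + by * by + bz * bz)
        ct = (ax * bx + ay * by + az * bz) / (na * nb)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = math.acos(ct)
        d = theta - theta0[idx]
        e_out[idx] = coeff[idx] * d * d
        dedt = 2.0 * coeff[idx] * d
        st = math.sqrt(max(1.0 - ct * ct, 1e-12))
        ci = dedt / (na * st)
        ck = dedt / (nb * st)
        fix = ci * (bx / nb - ct * ax / na)
        fiy = ci * (by / nb - ct * ay / na)
        fiz = ci * (bz / nb - ct * az / na)
        fkx = ck * (ax / na - ct * bx / nb)
        fky = ck * (ay / na - ct * by / nb)
        fkz = ck * (az / na - ct * bz / nb)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz


@njit(cache=True)
def dihedral_kernel(coords, quads, phi0, k1, k3, forces, e_out):
    """E = k1 (1 - cos(phi - phi0)) + k3 (1 - cos 3(phi - phi0))."""
    for idx in range(quads.shape[0]):
        i = quads[idx, 0]
        j = quads[idx, 1]
        k = quads[idx, 2]
        l = quads[idx, 3]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        m1x = (n1y * b2z - n1z * b2y) / nb2
        m1y = (n1z * b2x - n1x * b2z) / nb2
        m1z = (n1x * b2y - n1y * b2x) / nb2
        xx = n1x * n2x + n1y * n2y + n1z * n2z
        yy = m1x * n2x + m1y * n2y + m1z * n2z
        phi = math.atan2(yy, xx)
        d = phi - phi0[idx]
        e_out[idx] = k1[idx] * (1.0 - math.cos(d)) + k3[idx] * (1.0 - math.cos(3.0 * d))
        dedp = k1[idx] * math.sin(d) + 3.0 * k3[idx] * math.sin(3.0 * d)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq <= 1e-12 or n2sq <= 1e-12:
            continue
        ai = nb2 / n1sq
        al = -nb2 / n2sq
        dix = ai * n1x
        diy = ai * n1y
        diz = ai * n1z
        dlx = al * n2x
        dly = al * n2y
        dlz = al * n2z
        c12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        c32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        djx = -(1.0 + c12) * dix + c32 * dlx
        djy = -(1.0 + c12) * diy + c32 * dly
        djz = -(1.0 + c12) * diz + c32 * dlz
        dkx = c12 * dix - (1.0 + c32) * dlx
        dky = c12 * diy - (1.0 + c32) * dly
        dkz = c12 * diz - (1.0 + c32) * dlz
        forces[i, 0] -= dedp * dix
        forces[i, 1] -= dedp * diy
        forces[i, 2] -= dedp * diz
        forces[j, 0] -= dedp * djx
        forces[j, 1] -= dedp * djy
        forces[j, 2] -= dedp * djz
        forces[k, 0] -= dedp * dkx
        forces[k, 1] -= dedp * dky
        forces[k, 2] -= dedp * dkz
        forces[l, 0] -= dedp * dlx
        forces[l, 1] -= dedp * dly
        forces[l, 2] -= dedp * dlz
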
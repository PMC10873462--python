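"""Numba-compiled inner loop for the overdamped Langevin integrator.

One call integrates a single particle.  The obstacle environment is a
periodic supercell (2x2 box matrix ``b``, inverse ``i``) containing ``N``
disk centers; minimum-image contacts are found by scanning the 3x3 block
of periodic images around the fractional rounding of each center, which is
exact whenever the contact radius is smaller than the supercell extent.

Contact handling per step, matching the hard-wall model:

1. orientation update  theta += omega0*dt + sqrt(2 Dr dt) * xi
2. velocity            v = v0 p_hat + v_g e_hat
3. for every contacting obstacle whose normal opposes v (v . N < 0) the
   normal component is removed (iterated over contacts, deepest first,
   until stable); motion away from a surface is never modified
4. explicit Euler move; any residual penetration is resolved by pushing
   the particle radially back to the contact circle

``noise_sign`` multiplies every Gaussian increment and exists for the
mirrored-noise harness: running (-omega0, mirrored lattice, -xi) from a
mirrored initial condition retraces the reflected trajectory.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_PENETRATION = 1

# width of the numerical contact band in units of R: a particle within
# R*(1 + CONTACT_BAND) of a center is treated as touching, so that a
# particle sliding on the circle (where a tangential Euler step leaves it
# O((v dt)^2 / R) outside) keeps sliding instead of chattering in and out
CONTACT_BAND = 1e-4


@njit(cache=True, fastmath=True)
def run_particle(
    seed,
    noise_sign,
    n_burn,
    n_steps,
    dt,
    v0,
    omega0,
    Dr,
    vg,
    psi,
    cx,
    cy,
    b11,
    b12,
    b21,
    b22,
    i11,
    i12,
    i21,
    i22,
    R,
    max_sweeps,
    cancel_outward,
    x0,
    y0,
    th0,
    record_stride,
    rec_xu,
    rec_yu,
    rec_xw,
    rec_yw,
    rec_th,
    rec_c,
    iv_start,
    iv_end,
    iv_obs,
):
    np.random.seed(seed)
    x = x0
    y = y0
    th = th0
    xu = x0
    yu = y0
    sq = np.sqrt(2.0 * Dr * dt)
    ex = vg * np.cos(psi)
    ey = vg * np.sin(psi)
    N = cx.shape[0]
    ctol = CONTACT_BAND * R
    Rc2 = (R + ctol) * (R + ctol)  # contact band (projection + flag)
    Rin2 = R * R                   # hard core (pushback)
    vmax = v0 + vg
    reach = R + ctol + vmax * dt
    reach2 = reach * reach
    db = 1e-8 * v0                 # tangential-speed dead band for reversals

    maxc = 16
    cnx = np.empty(maxc)
    cny = np.empty(maxc)
    cdep = np.empty(maxc)
    cid = np.empty(maxc, np.int64)

    n_contact_steps = 0
    n_rev = 0
    n_iv = 0
    truncated = False
    prev_sign = 0
    prev_contact = False
    iv_open = np.int64(-1)
    iv_obs_cur = np.int64(-1)
    cap = iv_start.shape[0]
    rec_i = 1
    total = n_burn + n_steps

    for s in range(total):
        if s == n_burn:
            # displacement accounting restarts after burn-in
            xu = x
            yu = y
            rec_xu[0] = x
            rec_yu[0] = y
            rec_xw[0] = x
            rec_yw[0] = y
            rec_th[0] = th
            rec_c[0] = False
            rec_i = 1
            # event bookkeeping starts fresh after burn-in
            prev_contact = False
            prev_sign = 0
            iv_open = np.int64(-1)
            iv_obs_cur = np.int64(-1)
        th = th + omega0 * dt + sq * (noise_sign * np.random.normal())
        vx = v0 * np.cos(th) + ex
        vy = v0 * np.sin(th) + ey

        # --- collect contacts at the pre-move position ---
        nc = 0
        near = False
        for j in range(N):
            ddx = x - cx[j]
            ddy = y - cy[j]
            fx = i11 * ddx + i12 * ddy
            fy = i21 * ddx + i22 * ddy
            fx -= np.round(fx)
            fy -= np.round(fy)
            bx = b11 * fx + b12 * fy
            by = b21 * fx + b22 * fy
            for ix in (-1, 0, 1):
                for iy in (-1, 0, 1):
                    gx = bx + b11 * ix + b12 * iy
                    gy = by + b21 * ix + b22 * iy
                    d2 = gx * gx + gy * gy
                    if d2 <= reach2:
                        near = True
                        if d2 <= Rc2 and nc < maxc:
                            dn = np.sqrt(d2)
                            if dn > 0.0:
                                cnx[nc] = gx / dn
                                cny[nc] = gy / dn
                            else:
                                cnx[nc] = 1.0
                                cny[nc] = 0.0
                            cdep[nc] = R - dn
                            cid[nc] = j
                            nc += 1
        in_contact = nc > 0

        # deepest-first ordering (insertion sort; nc is tiny)
        for a in range(1, nc):
            kd = cdep[a]
            knx = cnx[a]
            kny = cny[a]
            kj = cid[a]
            b = a - 1
            while b >= 0 and cdep[b] < kd:
                cdep[b + 1] = cdep[b]
                cnx[b + 1] = cnx[b]
                cny[b + 1] = cny[b]
                cid[b + 1] = cid[b]
                b -= 1
            cdep[b + 1] = kd
            cnx[b + 1] = knx
            cny[b + 1] = kny
            cid[b + 1] = kj

        # --- project out inward normal components ---
        if in_contact:
            for _sweep in range(max_sweeps):
                changed = False
                for k in range(nc):
                    vn = vx * cnx[k] + vy * cny[k]
                    if vn < 0.0 or (cancel_outward and vn > 0.0):
                        vx -= vn * cnx[k]
                        vy -= vn * cny[k]
                        changed = True
                if not changed:
                    break

        # --- event bookkeeping (post-burn only) ---
        if s >= n_burn:
            if in_contact:
                n_contact_steps += 1
                obs = cid[0]
                # tangential velocity w.r.t. the deepest contact normal
                vt = -vx * cny[0] + vy * cnx[0]
                sign = 0
                if vt > db:
                    sign = 1
                elif vt < -db:
                    sign = -1
                if prev_contact and sign != 0 and prev_sign != 0 and sign != prev_sign:
                    n_rev += 1
                if sign != 0:
                    prev_sign = sign
                step_rel = s - n_burn
                if not prev_contact:
                    iv_open = np.int64(step_rel)
                    iv_obs_cur = obs
                elif obs != iv_obs_cur:
                    if n_iv < cap:
                        iv_start[n_iv] = iv_open
                        iv_end[n_iv] = step_rel
                        iv_obs[n_iv] = iv_obs_cur
                        n_iv += 1
                    else:
                        truncated = True
                    iv_open = np.int64(step_rel)
                    iv_obs_cur = obs
            else:
                if prev_contact:
                    if n_iv < cap:
                        iv_start[n_iv] = iv_open
                        iv_end[n_iv] = s - n_burn
                        iv_obs[n_iv] = iv_obs_cur
                        n_iv += 1
                    else:
                        truncated = True
                prev_sign = 0
            prev_contact = in_contact
        else:
            prev_contact = in_contact

        # --- move ---
        x += vx * dt
        y += vy * dt
        xu += vx * dt
        yu += vy * dt

        # --- resolve residual penetration ---
        if near:
            resolved = True
            have_prev = False
            pcx = 0.0
            pcy = 0.0
            for _sweep in range(2 * max_sweeps):
                worst = -1.0
                wgx = 0.0
                wgy = 0.0
                for j in range(N):
                    ddx = x - cx[j]
                    ddy = y - cy[j]
                    fx = i11 * ddx + i12 * ddy
                    fy = i21 * ddx + i22 * ddy
                    fx -= np.round(fx)
                    fy -= np.round(fy)
                    bx = b11 * fx + b12 * fy
                    by = b21 * fx + b22 * fy
                    for ix in (-1, 0, 1):
                        for iy in (-1, 0, 1):
                            gx = bx + b11 * ix + b12 * iy
                            gy = by + b21 * ix + b22 * iy
                            d2 = gx * gx + gy * gy
                            if d2 < Rin2:
                                dn = np.sqrt(d2)
                                dep = R - dn
                                # ignore roundoff-level residuals so the
                                # push-out to the contact circle terminates
                                if dep > 1e-12 * R and dep > worst:
                                    worst = dep
                                    wgx = gx
                                    wgy = gy
                if worst < 0.0:
                    break
                cax = x - wgx
                cay = y - wgy
                if have_prev and (
                    (cax - pcx) ** 2 + (cay - pcy) ** 2 > 1e-18 * R * R
                ):
                    # a different disk than the previous push: overlapping
                    # (jittered) disks make alternating radial pushes
                    # ping-pong inside the lens, so snap to the nearest
                    # lens tip (circle-circle intersection) instead
                    cbx = pcx
                    cby = pcy
                    dcx = cbx - cax
                    dcy = cby - cay
                    dd = np.sqrt(dcx * dcx + dcy * dcy)
                    if 1e-9 * R < dd < 2.0 * R:
                        mx = 0.5 * (cax + cbx)
                        my = 0.5 * (cay + cby)
                        h2 = R * R - 0.25 * dd * dd
                        h = np.sqrt(h2) if h2 > 0.0 else 0.0
                        ex_ = -dcy / dd
                        ey_ = dcx / dd
                        p1x = mx + h * ex_
                        p1y = my + h * ey_
                        p2x = mx - h * ex_
                        p2y = my - h * ey_
                        d1 = (p1x - x) ** 2 + (p1y - y) ** 2
                        d2_ = (p2x - x) ** 2 + (p2y - y) ** 2
                        if d1 <= d2_:
                            px = p1x - x
                            py = p1y - y
                        else:
                            px = p2x - x
                            py = p2y - y
                        x += px
                        y += py
                        xu += px
                        yu += py
                        have_prev = False
                        continue
                dn = R - worst
                if dn > 0.0:
                    fac = R / dn - 1.0
                    px = fac * wgx
                    py = fac * wgy
                else:  # exactly at a center: push along +x
                    px = R
                    py = 0.0
                x += px
                y += py
                xu += px
                yu += py
                pcx = cax
                pcy = cay
                have_prev = True
            else:
                resolved = False
            if not resolved:
                return (
                    STATUS_PENETRATION,
                    n_contact_steps,
                    n_rev,
                    n_iv,
                    truncated,
                    x,
                    y,
                    xu,
                    yu,
                    th,
                )

        # --- wrap into the supercell ---
        if N > 0:
            fx = i11 * x + i12 * y
            fy = i21 * x + i22 * y
            sx = np.floor(fx)
            sy = np.floor(fy)
            if sx != 0.0 or sy != 0.0:
                x -= b11 * sx + b12 * sy
                y -= b21 * sx + b22 * sy

        # --- record ---
        if s >= n_burn:
            srel = s - n_burn + 1
            if srel % record_stride == 0:
                rec_xu[rec_i] = xu
                rec_yu[rec_i] = yu
                rec_xw[rec_i] = x
                rec_yw[rec_i] = y
                rec_th[rec_i] = th
                rec_c[rec_i] = in_contact
                rec_i += 1
            if srel == 1:
                rec_c[0] = in_contact

    # close a dangling contact interval
    if prev_contact:
        if n_iv < cap:
            iv_start[n_iv] = iv_open
            iv_end[n_iv] = n_steps
            iv_obs[n_iv] = iv_obs_cur
            n_iv += 1
        else:
            truncated = True

    return (
        STATUS_OK,
        n_contact_steps,
        n_rev,
        n_iv,
        truncated,
        x,
        y,
        xu,
        yu,
        th,
    )
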
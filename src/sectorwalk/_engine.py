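"""Inner loop of the annihilating-coalescing random-walk engine.

The kernel advances a ring of domain walls hop by hop.  Walls live in a
circular doubly-linked list over fixed array slots so that removals are
O(1); a compact ``active`` array supports uniform random wall choice.  The
same source function is compiled with numba when available and executed as
plain Python otherwise, so both paths share one implementation.

State arrays (slot-indexed, capacity = initial wall count):
  pos   : wall angle in [0, 2*pi)
  rlab  : strain of the arc counterclockwise (to the right) of the wall
  nxt/prv : linked-list neighbours in increasing angle
  active / apos : compact list of live slots and each slot's index in it

Scalars are carried in small arrays so the kernel can mutate them:
  scal = [t, L, R]      cnt = [n_active, n_events, uniform_cursor]

Randomness is consumed from a caller-supplied block of uniforms, two per
hop (wall choice, direction), which keeps trajectories reproducible and
independent of whether the compiled or interpreted kernel runs.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi

# reason codes returned by the kernel
REASON_FIXATION = 0
REASON_L_STOP = 1
REASON_REFILL = 2


def _advance_impl(pos, rlab, nxt, prv, active, apos, scal, cnt,
                  bias, a, d, radial, L_stop,
                  us, ev_L, ev_kind, ev_lab):
    n = cnt[0]
    ne = cnt[1]
    ui = cnt[2]
    t = scal[0]
    L = scal[1]
    R = scal[2]
    nu = us.shape[0]
    reason = REASON_REFILL
    while True:
        if n == 0:
            reason = REASON_FIXATION
            break
        if L >= L_stop:
            reason = REASON_L_STOP
            break
        if ui + 2 > nu:
            reason = REASON_REFILL
            break
        u1 = us[ui]
        u2 = us[ui + 1]
        ui += 2

        k = int(u1 * n)
        if k >= n:
            k = n - 1
        i = active[k]
        pi = prv[i]
        li = rlab[pi]
        ri = rlab[i]
        dphi = a / R

        inv = 1.0 / n
        t += inv
        L += d * inv
        if radial:
            # the colony expands d per generation, so R = R0 + d*t and
            # L = R - R0; the angular hop length a/R still uses the cell width
            R += d * inv

        if u2 < 0.5 * (1.0 + bias[li, ri]):
            # hop right (counterclockwise)
            j = nxt[i]
            collide = False
            if n > 1:
                gap = pos[j] - pos[i]
                if gap <= 0.0:
                    gap += TWO_PI
                collide = gap <= dphi * (1.0 + 1e-9)
            if collide:
                ro = rlab[j]
                ev_L[ne] = L
                ev_lab[ne, 0] = li
                ev_lab[ne, 1] = ri
                ev_lab[ne, 2] = ri
                ev_lab[ne, 3] = ro
                if li == ro:
                    # annihilation: both walls vanish, arcs merge
                    ev_kind[ne] = 0
                    ev_lab[ne, 4] = -1
                    ev_lab[ne, 5] = -1
                    nj = nxt[j]
                    nxt[pi] = nj
                    prv[nj] = pi
                    kk = apos[i]
                    last = active[n - 1]
                    active[kk] = last
                    apos[last] = kk
                    n -= 1
                    kk = apos[j]
                    last = active[n - 1]
                    active[kk] = last
                    apos[last] = kk
                    n -= 1
                else:
                    # coalescence: wall j survives at the collision point
                    ev_kind[ne] = 1
                    ev_lab[ne, 4] = li
                    ev_lab[ne, 5] = ro
                    nxt[pi] = j
                    prv[j] = pi
                    kk = apos[i]
                    last = active[n - 1]
                    active[kk] = last
                    apos[last] = kk
                    n -= 1
                ne += 1
            else:
                p = pos[i] + dphi
                if p >= TWO_PI:
                    p -= TWO_PI
                pos[i] = p
        else:
            # hop left (clockwise)
            collide = False
            if n > 1:
                gap = pos[i] - pos[pi]
                if gap <= 0.0:
                    gap += TWO_PI
                collide = gap <= dphi * (1.0 + 1e-9)
            if collide:
                ppi = prv[pi]
                lo = rlab[ppi]
                # consumed in spatial order: (wall pi, wall i)
                ev_L[ne] = L
                ev_lab[ne, 0] = lo
                ev_lab[ne, 1] = li
                ev_lab[ne, 2] = li
                ev_lab[ne, 3] = ri
                if lo == ri:
                    ev_kind[ne] = 0
                    ev_lab[ne, 4] = -1
                    ev_lab[ne, 5] = -1
                    ni = nxt[i]
                    nxt[ppi] = ni
                    prv[ni] = ppi
                    kk = apos[i]
                    last = active[n - 1]
                    active[kk] = last
                    apos[last] = kk
                    n -= 1
                    kk = apos[pi]
                    last = active[n - 1]
                    active[kk] = last
                    apos[last] = kk
                    n -= 1
                else:
                    # wall pi survives; its right arc now carries strain ri
                    ev_kind[ne] = 1
                    ev_lab[ne, 4] = lo
                    ev_lab[ne, 5] = ri
                    rlab[pi] = ri
                    ni = nxt[i]
                    nxt[pi] = ni
                    prv[ni] = pi
                    kk = apos[i]
                    last = active[n - 1]
                    active[kk] = last
                    apos[last] = kk
                    n -= 1
                ne += 1
            else:
                p = pos[i] - dphi
                if p < 0.0:
                    p += TWO_PI
                pos[i] = p

    cnt[0] = n
    cnt[1] = ne
    cnt[2] = ui
    scal[0] = t
    scal[1] = L
    scal[2] = R
    return reason


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _advance = njit(cache=True, nogil=True)(_advance_impl)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _advance = _advance_impl
    HAVE_NUMBA = False
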
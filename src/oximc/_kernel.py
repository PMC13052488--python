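"""Numba photon-transport kernel for the plane-parallel layered slab.

Weighted-photon transport with continuous absorption weighting: free paths
are sampled against the scattering coefficient only, and the photon weight
is attenuated by exp(-mu_a * l) along every path segment (absorbed weight
is deposited in depth bins along the segment, split at bin crossings).
Scattering uses the Henyey-Greenstein phase function; internal boundaries
use Snell/Fresnel (unpolarised); Russian roulette uses exchange bookkeeping
against the absorbed tally so the per-run energy ledger closes exactly.

Absorption weighting (rather than collision weighting) is what makes the
common-random-numbers pairing of diastole/systole runs effective: the two
phases share scattering coefficients and geometry, so paired photons follow
*identical* trajectories and differ only in the accumulated absorption
weight — the AC/DC difference is then nearly noise-free even at desk-scale
photon budgets.

RNG: xorshift128+ with a per-photon state derived from the run seed via
splitmix64 (per-photon substreams keep paired runs aligned photon by
photon).
"""
import numpy as np
from numba import njit

# tally indices
SPECULAR, DETECTED, DIFFUSE, TRANSMITTED, SIDE, ABSORBED = range(6)

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + _GOLDEN) & _MASK
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK
    return x, z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _next_u01(state):
    """xorshift128+ step; returns uniform in [0, 1)."""
    s0, s1 = state[0], state[1]
    x = s0
    y = s1
    state[0] = y
    x ^= (x << np.uint64(23)) & _MASK
    x ^= x >> np.uint64(17)
    x ^= y ^ (y >> np.uint64(26))
    state[1] = x
    return float((x + y) >> np.uint64(11)) * _INV_2_53


@njit(cache=True, fastmath=True)
def transport(mu_a, mu_s, g, n_layer, z_bounds, n_ambient,
              src_radius, det_radius, lateral_bound,
              n_photons, seed, w_threshold, p_survival,
              depth_dz, n_depth_bins):
    """Run ``n_photons`` photons; returns (tallies, depth_hist, det_sq_sum).

    tallies: launched-weight fractions [specular, detected, diffuse,
    transmitted, side, absorbed] (unnormalised sums); depth_hist: absorbed
    weight per depth bin (width depth_dz, last bin open); det_sq_sum: sum
    over photons of the squared detected weight (for the standard error of
    the detected tally).
    """
    n_lay = mu_a.shape[0]
    tallies = np.zeros(6)
    depth_hist = np.zeros(n_depth_bins)
    det_sq = 0.0
    lat2 = lateral_bound * lateral_bound
    det2 = det_radius * det_radius
    state = np.empty(2, dtype=np.uint64)
    two_pi = 2.0 * np.pi

    for ip in range(n_photons):
        # per-photon substream
        s = np.uint64(seed) ^ ((np.uint64(ip) * _GOLDEN) & _MASK)
        s, a0 = _splitmix64(s)
        s, a1 = _splitmix64(s)
        if a0 == np.uint64(0) and a1 == np.uint64(0):
            a1 = _GOLDEN
        state[0] = a0
        state[1] = a1
        _next_u01(state)
        _next_u01(state)

        # launch on the source disk, normally incident
        r = src_radius * np.sqrt(_next_u01(state))
        th = two_pi * _next_u01(state)
        x = r * np.cos(th)
        y = r * np.sin(th)
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0

        # specular loss at the ambient/top interface (normal incidence)
        rs0 = ((n_ambient - n_layer[0]) / (n_ambient + n_layer[0])) ** 2
        tallies[SPECULAR] += rs0
        w = 1.0 - rs0
        det_w = 0.0

        alive = True
        while alive:
            s_left = -np.log(1.0 - _next_u01(state))  # scattering depth
            # hop: advance by segments, possibly across boundaries
            while True:
                ms = mu_s[layer]
                ma = mu_a[layer]
                if uz > 0.0:
                    db = (z_bounds[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_bounds[layer] - z) / uz
                else:
                    db = 1e30
                d_int = s_left / ms if ms > 0.0 else 1e30
                at_boundary = db <= d_int
                seg = db if at_boundary else d_int

                # continuous absorption along the segment, deposited per
                # depth bin (exact exponential split at bin crossings)
                if ma > 0.0 and seg > 0.0:
                    if uz != 0.0:
                        z_end = (z_bounds[layer + 1] if (at_boundary and uz > 0.0)
                                 else (z_bounds[layer] if at_boundary
                                       else z + uz * seg))
                        # walk the depth bins along the segment with integer
                        # bin stepping (bin edges assigned exactly, so no
                        # floating-point stall at edges); last bin is open
                        remaining = seg
                        zc = z
                        ib = int(zc / depth_dz)
                        if ib >= n_depth_bins:
                            ib = n_depth_bins - 1
                        if uz < 0.0 and ib > 0 and zc <= ib * depth_dz:
                            ib -= 1
                        while remaining > 0.0:
                            if uz > 0.0:
                                if ib >= n_depth_bins - 1:
                                    sub = remaining
                                else:
                                    sub = ((ib + 1) * depth_dz - zc) / uz
                            else:
                                sub = (ib * depth_dz - zc) / uz
                            last = sub >= remaining or sub <= 0.0
                            if last:
                                sub = remaining
                            f = np.exp(-ma * sub)
                            dw = w * (1.0 - f)
                            tallies[ABSORBED] += dw
                            depth_hist[ib] += dw
                            w -= dw
                            remaining -= sub
                            if last:
                                zc += uz * sub
                                break
                            if uz > 0.0:
                                ib += 1
                                zc = ib * depth_dz
                            else:
                                zc = ib * depth_dz
                                ib -= 1
                                if ib < 0:
                                    ib = 0
                        z = z_end if at_boundary else zc
                    else:
                        ib = int(z / depth_dz)
                        if ib >= n_depth_bins:
                            ib = n_depth_bins - 1
                        f = np.exp(-ma * seg)
                        dw = w * (1.0 - f)
                        tallies[ABSORBED] += dw
                        depth_hist[ib] += dw
                        w -= dw
                else:
                    if at_boundary and uz != 0.0:
                        z = z_bounds[layer + 1] if uz > 0.0 else z_bounds[layer]
                    else:
                        z += uz * seg
                x += ux * seg
                y += uy * seg

                if x * x + y * y > lat2:
                    tallies[SIDE] += w
                    alive = False
                    break

                if not at_boundary:
                    break  # scatter at this point

                s_left -= db * ms
                if s_left < 0.0:
                    s_left = 0.0
                going_down = uz > 0.0
                n1 = n_layer[layer]
                if going_down:
                    n2 = n_ambient if layer == n_lay - 1 else n_layer[layer + 1]
                else:
                    n2 = n_ambient if layer == 0 else n_layer[layer - 1]
                ci = abs(uz)
                reflect = False
                ct = ci
                if n1 != n2:
                    si2 = 1.0 - ci * ci
                    if si2 < 0.0:
                        si2 = 0.0
                    ratio = n1 / n2
                    st2 = ratio * ratio * si2
                    if st2 >= 1.0:
                        reflect = True  # total internal reflection
                    else:
                        ct = np.sqrt(1.0 - st2)
                        rs_ = ((n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)) ** 2
                        rp_ = ((n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)) ** 2
                        if _next_u01(state) < 0.5 * (rs_ + rp_):
                            reflect = True
                if reflect:
                    uz = -uz
                    continue
                if n1 != n2:
                    ratio = n1 / n2
                    ux *= ratio
                    uy *= ratio
                    uz = ct if going_down else -ct
                if going_down:
                    if layer == n_lay - 1:
                        tallies[TRANSMITTED] += w
                        alive = False
                        break
                    layer += 1
                else:
                    if layer == 0:
                        if x * x + y * y <= det2:
                            tallies[DETECTED] += w
                            det_w = w
                        else:
                            tallies[DIFFUSE] += w
                        alive = False
                        break
                    layer -= 1

            if not alive:
                break

            # spin (Henyey-Greenstein)
            gg = g[layer]
            u = _next_u01(state)
            if gg > 1e-6:
                tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * u)
                cth = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
            else:
                cth = 2.0 * u - 1.0
            if cth > 1.0:
                cth = 1.0
            elif cth < -1.0:
                cth = -1.0
            sth = np.sqrt(1.0 - cth * cth)
            phi = two_pi * _next_u01(state)
            cphi = np.cos(phi)
            sphi = np.sin(phi)
            if abs(uz) > 0.99999:
                ux = sth * cphi
                uy = sth * sphi
                uz = cth if uz > 0.0 else -cth
            else:
                den = np.sqrt(1.0 - uz * uz)
                nux = sth * (ux * uz * cphi - uy * sphi) / den + ux * cth
                nuy = sth * (uy * uz * cphi + ux * sphi) / den + uy * cth
                nuz = -sth * cphi * den + uz * cth
                norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / norm
                uy = nuy / norm
                uz = nuz / norm

            # roulette with exchange bookkeeping (exact energy closure)
            if w < w_threshold:
                ib = int(z / depth_dz)
                if ib >= n_depth_bins:
                    ib = n_depth_bins - 1
                if w <= 0.0:
                    tallies[ABSORBED] += w
                    depth_hist[ib] += w
                    alive = False
                elif _next_u01(state) < p_survival:
                    w_new = w / p_survival
                    tallies[ABSORBED] += w - w_new
                    depth_hist[ib] += w - w_new
                    w = w_new
                else:
                    tallies[ABSORBED] += w
                    depth_hist[ib] += w
                    alive = False

        det_sq += det_w * det_w

    return tallies, depth_hist, det_sq
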
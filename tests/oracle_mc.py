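"""Independent brute-force photon simulator used as a cross-check oracle.

A second, deliberately separate implementation of photon transport through
the window/tissue/window slab: vectorized numpy arrays of photons stepped
in lockstep, with numpy's own Generator for randomness, explicit position/
direction state and no shared code with the package kernel beyond the
physical definitions (HG sampling, Fresnel, scoring geometry).  Absorption
uses the same weighted-walk scheme.  No Russian roulette: photons are
tracked until their weight falls below a hard floor, which biases results
by less than the floor itself (1e-7).
"""

from __future__ import annotations

import numpy as np


def fresnel_unpolarized(n1, n2, ci):
    """Vectorized (R, cos_t); R=1 and cos_t=0 under total internal reflection."""
    ci = np.clip(ci, 0.0, 1.0)
    si2 = 1.0 - ci * ci
    st2 = (n1 / n2) ** 2 * si2
    tir = st2 >= 1.0
    ct = np.sqrt(np.clip(1.0 - st2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = ((n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)) ** 2
        rp = ((n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)) ** 2
    r = np.where(tir, 1.0, 0.5 * (rs + rp))
    return np.where(n1 == n2, 0.0, r), np.where(tir, 0.0, ct)


def simulate_oracle(
    layers,  # list of dicts: thickness, mu_a, mu_s, g, n (top to bottom)
    n_ambient=1.0,
    beam_radius=0.95,
    port_radius=2.5,
    lateral_extent=6.0,
    collimation_cos=np.cos(np.radians(2.5)),
    n_photons=200_000,
    seed=1234,
    weight_floor=1e-7,
):
    """Returns dict of channel fractions and standard errors for Rd/Tt."""
    rng = np.random.default_rng(seed)
    nlay = len(layers)
    thick = np.array([la["thickness"] for la in layers])
    zb = np.concatenate([[0.0], np.cumsum(thick)])
    mua = np.array([la["mu_a"] for la in layers])
    mus = np.array([la["mu_s"] for la in layers])
    gl = np.array([la["g"] for la in layers])
    nl = np.array([la["n"] for la in layers])
    mut = mua + mus

    n = n_photons
    r0 = beam_radius * np.sqrt(rng.random(n))
    phi0 = 2.0 * np.pi * rng.random(n)
    x = r0 * np.cos(phi0)
    y = r0 * np.sin(phi0)
    z = np.zeros(n)
    ux = np.zeros(n)
    uy = np.zeros(n)
    uz = np.ones(n)
    w = np.ones(n)
    lay = np.zeros(n, dtype=np.int64)
    nscat = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)

    score = {k: np.zeros(n) for k in ("Rd", "Tt", "Td", "absorbed", "edge", "specular", "unscored")}

    # entry interface ambient -> top layer (normal incidence)
    R0, _ = fresnel_unpolarized(np.full(n, n_ambient), np.full(n, nl[0]), np.ones(n))
    refl0 = rng.random(n) < R0
    score["specular"][refl0] = w[refl0]
    alive &= ~refl0

    def classify_exit(idx, down):
        rr = np.hypot(x[idx], y[idx])
        if down:
            in_port = rr <= port_radius
            score["Tt"][idx[in_port]] += w[idx[in_port]]
            collim = in_port & (uz[idx] >= collimation_cos) & (rr <= beam_radius)
            diffuse = in_port & ~collim
            score["Td"][idx[diffuse]] += w[idx[diffuse]]
            score["unscored"][idx[~in_port]] += w[idx[~in_port]]
        else:
            spec = nscat[idx] == 0
            score["specular"][idx[spec]] += w[idx[spec]]
            in_port = ~spec & (rr <= port_radius)
            score["Rd"][idx[in_port]] += w[idx[in_port]]
            rest = ~spec & ~in_port
            score["unscored"][idx[rest]] += w[idx[rest]]

    for _sweep in range(100_000):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        li = lay[idx]
        mt = mut[li]
        clear = mt <= 0.0
        s = np.empty(idx.size)
        s[clear] = np.inf
        s[~clear] = -np.log(np.clip(rng.random((~clear).sum()), 1e-300, None)) / mt[~clear]
        # distance to boundary along z
        uzi = uz[idx]
        with np.errstate(divide="ignore"):
            db = np.where(
                uzi > 0, (zb[li + 1] - z[idx]) / uzi,
                np.where(uzi < 0, (zb[li] - z[idx]) / uzi, np.inf),
            )
        stuck = np.isinf(db) & np.isinf(s)  # direction exactly horizontal in clear layer
        if stuck.any():
            sid = idx[stuck]
            score["edge"][sid] += w[sid]
            alive[sid] = False
            idx = idx[~stuck]
            li, mt, s, db, uzi = li[~stuck], mt[~stuck], s[~stuck], db[~stuck], uzi[~stuck]
        hit = s >= db
        step = np.where(hit, db, s)
        x[idx] += ux[idx] * step
        y[idx] += uy[idx] * step
        z[idx] += uz[idx] * step
        z[idx[hit]] = np.where(uzi[hit] > 0, zb[li[hit] + 1], zb[li[hit]])
        # edge losses
        out = x[idx] ** 2 + y[idx] ** 2 > lateral_extent**2
        if out.any():
            oid = idx[out]
            score["edge"][oid] += w[oid]
            alive[oid] = False
            keep = ~out
            idx, li, hit, uzi = idx[keep], li[keep], hit[keep], uzi[keep]
        # boundary interactions
        bid = idx[hit]
        if bid.size:
            down = uz[bid] > 0
            lb = lay[bid]
            nxt = np.where(down, lb + 1, lb - 1)
            inside = (nxt >= 0) & (nxt < nlay)
            n1 = nl[lb]
            n2 = np.where(inside, nl[np.clip(nxt, 0, nlay - 1)], n_ambient)
            Rf, ct = fresnel_unpolarized(n1, n2, np.abs(uz[bid]))
            do_reflect = rng.random(bid.size) < Rf
            uz[bid[do_reflect]] *= -1.0
            tr = ~do_reflect
            tid = bid[tr]
            scale = (n1 / n2)[tr]
            ux[tid] *= scale
            uy[tid] *= scale
            uz[tid] = np.where(down[tr], ct[tr], -ct[tr])
            goes_out = tr & ~inside
            goes_in = tr & inside
            lay[bid[goes_in]] = nxt[goes_in]
            exit_idx = bid[goes_out]
            if exit_idx.size:
                ed = down[goes_out]
                classify_exit(exit_idx[ed], True)
                classify_exit(exit_idx[~ed], False)
                alive[exit_idx] = False
        # interactions in turbid layers
        iid = idx[~hit]
        if iid.size:
            lb = lay[iid]
            albedo = mus[lb] / mut[lb]
            dep = w[iid] * (1.0 - albedo)
            score["absorbed"][iid] += dep
            w[iid] *= albedo
            dead = w[iid] <= weight_floor
            if dead.any():
                did = iid[dead]
                score["absorbed"][did] += w[did]
                w[did] = 0.0
                alive[did] = False
                iid = iid[~dead]
                lb = lay[iid]
            if iid.size:
                cth = hg_cos_vec(gl[lb], rng.random(iid.size))
                sth = np.sqrt(np.clip(1.0 - cth**2, 0.0, None))
                psi = 2.0 * np.pi * rng.random(iid.size)
                cp, sp = np.cos(psi), np.sin(psi)
                u_, v_, t_ = ux[iid], uy[iid], uz[iid]
                near_vert = np.abs(t_) > 0.99999
                tmp = np.sqrt(np.clip(1.0 - t_**2, 1e-30, None))
                nux = np.where(near_vert, sth * cp, sth * (u_ * t_ * cp - v_ * sp) / tmp + u_ * cth)
                nuy = np.where(near_vert, sth * sp, sth * (v_ * t_ * cp + u_ * sp) / tmp + v_ * cth)
                nuz = np.where(near_vert, np.sign(t_) * cth, -sth * cp * tmp + t_ * cth)
                norm = np.sqrt(nux**2 + nuy**2 + nuz**2)
                ux[iid], uy[iid], uz[iid] = nux / norm, nuy / norm, nuz / norm
                nscat[iid] += 1

    out = {}
    for k, v in score.items():
        out[k] = v.sum() / n
    for k in ("Rd", "Tt"):
        v = score[k]
        mean = v.sum() / n
        out[f"se_{k}"] = np.sqrt(max((v**2).sum() / n - mean**2, 0.0) / n)
    out["Tc"] = out["Tt"] - out["Td"]
    return out


def hg_cos_vec(g, u):
    iso = g == 0.0
    g_safe = np.where(iso, 0.5, g)
    t = (1.0 - g_safe**2) / (1.0 - g_safe + 2.0 * g_safe * u)
    c = (1.0 + g_safe**2 - t**2) / (2.0 * g_safe)
    return np.where(iso, 2.0 * u - 1.0, np.clip(c, -1.0, 1.0))
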
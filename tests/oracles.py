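"""Independent reference implementations used only to check results.

Everything here is deliberately naive — O(N²) scans, Monte-Carlo
quadrature, closed forms — and shares no code with the package's own
computational paths.
"""

from __future__ import annotations

import numpy as np


def mc_sasa(coords, radii, probe, n_samples=40000, seed=0):
    """Monte-Carlo SASA: random points on each inflated sphere."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    big = np.asarray(radii, float) + probe
    total = 0.0
    for i in range(len(coords)):
        v = rng.standard_normal((n_samples, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + big[i] * v
        buried = np.zeros(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            buried |= ((pts - coords[j]) ** 2).sum(axis=1) < big[j] ** 2
        total += (1.0 - buried.mean()) * 4.0 * np.pi * big[i] ** 2
    return total


def two_sphere_csa(c1, c2, r1, r2, probe):
    """Closed-form CSA of two probe-inflated spheres (cap areas)."""
    R1, R2 = r1 + probe, r2 + probe
    d = float(np.linalg.norm(np.asarray(c1, float) - np.asarray(c2, float)))
    if d >= R1 + R2:
        return 0.0
    x = (d * d + R1 * R1 - R2 * R2) / (2 * d)   # plane of intersection
    h1 = R1 - x
    h2 = R2 - (d - x)
    return (2 * np.pi * R1 * h1 + 2 * np.pi * R2 * h2) / 2.0


def brute_force_census(protein, surface_coords, cutoff):
    """All-pairs residue contact set: {(chain, res_seq)} within cutoff."""
    hits = set()
    for res in protein.residues():
        dmin = np.inf
        for a in res.atoms:
            if not a.is_heavy:
                continue
            d = np.linalg.norm(surface_coords - a.coord, axis=1).min()
            dmin = min(dmin, d)
        if dmin <= cutoff:
            hits.add((res.chain_id, res.res_seq))
    return hits


def brute_force_energy(pc, sc, psig, peps, pq, ssig, seps, sq, cutoff,
                       coulomb_f=138.935458):
    """All-pairs LJ + Coulomb with geometric combination."""
    lj = coul = 0.0
    for i in range(len(pc)):
        for j in range(len(sc)):
            r = float(np.linalg.norm(pc[i] - sc[j]))
            if r > cutoff:
                continue
            sig = np.sqrt(psig[i] * ssig[j])
            eps = np.sqrt(peps[i] * seps[j])
            sr6 = (sig / r) ** 6
            lj += 4 * eps * (sr6 * sr6 - sr6)
            coul += coulomb_f * pq[i] * sq[j] / r
    return lj, coul


def geometric_sum_uH(h, n, delta_deg):
    """|h|·|Σ_{k=0}^{n-1} e^{ikδ}|/n via the geometric-series closed form."""
    delta = np.deg2rad(delta_deg)
    num = np.sin(n * delta / 2.0)
    den = np.sin(delta / 2.0)
    return abs(h) * abs(num / den) / n
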
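"""Flat-array lattice kernels (numba) for the stochastic simulation engines.

State is held in parallel 1-D arrays over the ``height x width`` lattice,
index ``i`` at row ``i // width``, column ``i % width``:

``kind``     int8   0 empty, 1 Rp, 2 Dp, 3 parasite
``form``     int8   0 RNA, 1 DNA
``rrec``     f8     RNA-template recognition rate constant in [0, 1]
``drec``     f8     DNA-template recognition rate constant in [0, 1]
``bond``     int8   0 free, 1 catalyst side of a complex, 2 template side
``partner``  i8     flat index of the complex partner, -1 if free
``label``    int8   lineage label: 0 none, 1 RNA-origin, 2 DNA-origin
``comp``     i4     compartment id (0 = medium / plain surface)

One pass makes ``n_sites`` attempts of the random-sequential update: pick a
site; if it holds a molecule, pick an interaction partner (a random
neighbour, or a uniform random site in well-mixed mode) and select at most
one event — decay, complex formation, dissociation, replication into an
empty square, or a diffusion swap — with probability ``rate * dt``.  A pass
advances time by ``dt``; event frequencies per unit time then equal the
configured rate constants, which is what ties the lattice timescale to the
mass-action ODE companion model (the well-mixed large-population limit of
this kernel converges to those trajectories).

Reactions, diffusion and replication never cross lattice or compartment
boundaries.  Complexes move as rigid units: any swap that would separate the
two members is rejected.

All randomness flows through numba's internal RNG; call :func:`seed_kernel`
once at the start of a run for reproducibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EMPTY, RP, DP, PARASITE = 0, 1, 2, 3
RNA, DNA = 0, 1
FREE, CAT, TMPL = 0, 1, 2

# Moore (8-neighbour) offsets; von Neumann is the first 4 of a reordered set.
MOORE_X = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
MOORE_Y = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
VON_NEUMANN_X = np.array([0, -1, 1, 0], dtype=np.int64)
VON_NEUMANN_Y = np.array([-1, 0, 0, 1], dtype=np.int64)


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _adjacent(i, j, width):
    if i == j or j < 0:
        return False
    dx = i % width - j % width
    dy = i // width - j // width
    return -1 <= dx <= 1 and -1 <= dy <= 1


@njit(cache=True)
def _neighbor(i, width, height, ox, oy):
    """Random neighbour flat index, or -1 outside the no-flux boundary."""
    o = np.random.randint(0, ox.shape[0])
    x = i % width + ox[o]
    y = i // width + oy[o]
    if x < 0 or x >= width or y < 0 or y >= height:
        return -1
    return y * width + x


@njit(cache=True)
def _clear_site(i, kind, form, rrec, drec, bond, partner, label):
    kind[i] = EMPTY
    form[i] = RNA
    rrec[i] = 0.0
    drec[i] = 0.0
    bond[i] = FREE
    partner[i] = -1
    label[i] = 0


@njit(cache=True)
def _decay(i, kind, form, rrec, drec, bond, partner, label):
    p = partner[i]
    if p >= 0:
        bond[p] = FREE
        partner[p] = -1
    _clear_site(i, kind, form, rrec, drec, bond, partner, label)


@njit(cache=True)
def _try_swap(i, j, width, wellmixed,
              kind, form, rrec, drec, bond, partner, label, comp,
              cross_boundary):
    """Exchange site contents, honouring complex rigidity.

    Any bonded content may only move to a square still adjacent to its
    partner (the partner being the other swapped site is always fine, as the
    pair's separation is preserved).  Returns 1 on success.  Swaps across
    compartment boundaries are rejected unless ``cross_boundary`` is set
    (the membrane-permeability variant); compartment ids always stay with
    the squares.
    """
    if j < 0 or (comp[i] != comp[j] and not cross_boundary):
        return 0
    if kind[i] == EMPTY and kind[j] == EMPTY:
        return 1
    if not wellmixed:
        if bond[i] != FREE:
            p = partner[i]
            if p != j and not _adjacent(j, p, width):
                return 0
        if bond[j] != FREE:
            p = partner[j]
            if p != i and not _adjacent(i, p, width):
                return 0
    qi = partner[i]
    qj = partner[j]
    kind[i], kind[j] = kind[j], kind[i]
    form[i], form[j] = form[j], form[i]
    rrec[i], rrec[j] = rrec[j], rrec[i]
    drec[i], drec[j] = drec[j], drec[i]
    bond[i], bond[j] = bond[j], bond[i]
    label[i], label[j] = label[j], label[i]
    # content formerly at i is now at j and vice versa: rewire partner links
    qa = qi
    if qa == j:
        qa = i
    partner[j] = qa
    if qa >= 0:
        partner[qa] = j
    qb = qj
    if qb == i:
        qb = j
    partner[i] = qb
    if qb >= 0:
        partner[qb] = i
    return 1


@njit(cache=True)
def _place_offspring(e, cat, tmpl,
                     kind, form, rrec, drec, bond, partner, label,
                     mu_r, mu_d, mu_rd, mu_dr, mu_par, delta):
    """Copy the template into empty square ``e`` with at most one mutation.

    The product's form is set by the catalyst's polymerase type; the lineage
    label is inherited template-side regardless of the product's form.
    Parasite templates breed true (their channels are inert).
    """
    trole = kind[tmpl]
    trr = rrec[tmpl]
    tdd = drec[tmpl]
    if trole != PARASITE:
        u = np.random.random()
        c = mu_r
        if u < c:
            trr = trr + np.random.uniform(-delta, delta)
            if trr < 0.0:
                trr = 0.0
            elif trr > 1.0:
                trr = 1.0
        else:
            c += mu_d
            if u < c:
                tdd = tdd + np.random.uniform(-delta, delta)
                if tdd < 0.0:
                    tdd = 0.0
                elif tdd > 1.0:
                    tdd = 1.0
            else:
                c += mu_rd
                if u < c:
                    if trole == RP:
                        trole = DP
                else:
                    c += mu_dr
                    if u < c:
                        if trole == DP:
                            trole = RP
                    else:
                        c += mu_par
                        if u < c:
                            trole = PARASITE
    kind[e] = trole
    form[e] = RNA if kind[cat] == RP else DNA
    rrec[e] = trr
    drec[e] = tdd
    bond[e] = FREE
    partner[e] = -1
    label[e] = label[tmpl]


@njit(cache=True)
def run_passes(kind, form, rrec, drec, bond, partner, label, comp,
               width, height, n_passes, dt,
               k, d_rna, d_dna, diff, k_p,
               mu_r, mu_d, mu_rd, mu_dr, mu_par, delta,
               complex_enabled, wellmixed, rt_suppressed, cross_boundary,
               ox, oy):
    """Advance the lattice by ``n_passes`` passes of ``dt`` time units."""
    n = width * height
    for _ in range(n_passes):
        for _a in range(n):
            i = np.random.randint(0, n)
            ki = kind[i]
            if ki == EMPTY:
                continue
            if wellmixed:
                j = np.random.randint(0, n)
                if j == i:
                    j = -1
            else:
                j = _neighbor(i, width, height, ox, oy)
            u = np.random.random()
            acc = (d_rna if form[i] == RNA else d_dna) * dt
            if u < acc:
                _decay(i, kind, form, rrec, drec, bond, partner, label)
                continue
            bi = bond[i]
            if bi == FREE:
                # -- free molecule: bind a template / replicate / diffuse
                catalytic = (ki == RP or ki == DP) and form[i] == RNA
                if (catalytic and j >= 0 and kind[j] != EMPTY
                        and bond[j] == FREE and comp[i] == comp[j]):
                    a = rrec[i] if form[j] == RNA else drec[i]
                    if rt_suppressed and ki == DP and form[j] == RNA:
                        a = 0.0
                    if kind[j] == PARASITE:
                        a *= k_p
                    nxt = acc + a * dt
                    if u < nxt:
                        if complex_enabled:
                            bond[i] = CAT
                            bond[j] = TMPL
                            partner[i] = j
                            partner[j] = i
                        else:
                            # instantaneous replication, recognition-limited
                            m = i if np.random.random() < 0.5 else j
                            if wellmixed:
                                e = np.random.randint(0, n)
                            else:
                                e = _neighbor(m, width, height, ox, oy)
                            if (e >= 0 and kind[e] == EMPTY
                                    and comp[e] == comp[i]):
                                _place_offspring(
                                    e, i, j,
                                    kind, form, rrec, drec, bond, partner,
                                    label, mu_r, mu_d, mu_rd, mu_dr, mu_par,
                                    delta)
                        continue
                    acc = nxt
                if not wellmixed and diff > 0.0:
                    if u < acc + diff * dt:
                        _try_swap(i, j, width, wellmixed,
                                  kind, form, rrec, drec, bond, partner,
                                  label, comp, cross_boundary)
            elif bi == CAT:
                # -- catalyst side of a complex: dissociate / replicate / move
                p = partner[i]
                a_base = rrec[i] if form[p] == RNA else drec[i]
                nxt = acc + (1.0 - a_base) * dt
                if u < nxt:
                    bond[i] = FREE
                    bond[p] = FREE
                    partner[i] = -1
                    partner[p] = -1
                    continue
                acc = nxt
                nxt = acc + k * dt
                if u < nxt:
                    m = i if np.random.random() < 0.5 else p
                    if wellmixed:
                        e = np.random.randint(0, n)
                    else:
                        e = _neighbor(m, width, height, ox, oy)
                    if e >= 0 and kind[e] == EMPTY and comp[e] == comp[i]:
                        _place_offspring(e, i, p,
                                         kind, form, rrec, drec, bond,
                                         partner, label,
                                         mu_r, mu_d, mu_rd, mu_dr, mu_par,
                                         delta)
                        bond[i] = FREE
                        bond[p] = FREE
                        partner[i] = -1
                        partner[p] = -1
                    continue
                acc = nxt
                if not wellmixed and diff > 0.0:
                    if u < acc + diff * dt:
                        _try_swap(i, j, width, wellmixed,
                                  kind, form, rrec, drec, bond, partner,
                                  label, comp, cross_boundary)
            else:
                # -- template side: may only decay (above) or move
                if not wellmixed and diff > 0.0:
                    if u < acc + diff * dt:
                        _try_swap(i, j, width, wellmixed,
                                  kind, form, rrec, drec, bond, partner,
                                  label, comp, cross_boundary)


@njit(cache=True)
def diffusion_passes(kind, form, rrec, drec, bond, partner, label, comp,
                     width, height, n_passes, diff, dt, ox, oy,
                     cross_boundary):
    """Diffusion-only passes (neighbour-content exchange at rate ``diff``)."""
    n = width * height
    for _ in range(n_passes):
        for _a in range(n):
            i = np.random.randint(0, n)
            if kind[i] == EMPTY:
                continue
            if np.random.random() < diff * dt:
                j = _neighbor(i, width, height, ox, oy)
                _try_swap(i, j, width, False,
                          kind, form, rrec, drec, bond, partner, label, comp,
                          cross_boundary)


@njit(cache=True)
def cpm_sweep_kernel(comp, kind, width, height, n_attempts,
                     volume, target, lam, j_contact, temp,
                     ox, oy, frozen):
    """One Metropolis sweep of boundary copy attempts.

    Hamiltonian: ``sum_c lam * (volume_c - target_c)^2`` over compartments
    (the medium, id 0, has no volume term) plus ``j_contact`` per unlike
    Moore-neighbour pair.  A copy attempt retracts compartment ``s`` from a
    site in favour of neighbour state ``t``; attempts on squares holding a
    molecule are rejected outright, which is what makes boundaries
    impermeable to replicators.
    """
    if frozen:
        return
    n = width * height
    for _ in range(n_attempts):
        i = np.random.randint(0, n)
        jn = _neighbor(i, width, height, ox, oy)
        if jn < 0:
            continue
        s = comp[i]
        t = comp[jn]
        if s == t:
            continue
        if kind[i] != EMPTY:
            continue  # never move a molecule across a boundary
        dh = 0.0
        if t > 0:
            dv = volume[t] - target[t]
            dh += lam * ((dv + 1.0) ** 2 - dv ** 2)
        if s > 0:
            dv = volume[s] - target[s]
            dh += lam * ((dv - 1.0) ** 2 - dv ** 2)
        xi = i % width
        yi = i // width
        for o in range(8):
            x = xi + MOORE_X[o]
            y = yi + MOORE_Y[o]
            if x < 0 or x >= width or y < 0 or y >= height:
                continue
            cn = comp[y * width + x]
            dh += j_contact * ((1.0 if cn != t else 0.0)
                               - (1.0 if cn != s else 0.0))
        if dh > 0.0 and np.random.random() >= np.exp(-dh / temp):
            continue
        comp[i] = t
        volume[s] -= 1
        volume[t] += 1
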
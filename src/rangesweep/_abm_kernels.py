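"""Numba kernels for the 2D deme-based spatial Moran simulator.

State layout (flat grid of G*G demes, deme index ``i*G + j``):

* per deme, up to ``S`` genotype slots (``gids``/``cnts``), a total count
  and a fitness-weighted total rate;
* genotype 0 is the background (resident, or wildtype when measuring the
  mutant invasion speed); genotypes >= 1 form the invading clade.

Only "active" demes carry events.  A deme whose individuals are all
background and whose neighbourhood contains no clade individuals can only
host no-op events (background offspring either cannot migrate, or migrate
into identical at-capacity background demes), so removing those events from
the chain leaves the law of the state process — and of the Gillespie clock —
unchanged.  Demes are activated lazily when the clade first touches them
(plus their neighbours when the background itself can migrate) and never
deactivated.

The Gillespie step selects an active deme by rejection against the maximum
per-deme rate (demes hold exactly K individuals between events), then a
genotype within the deme by a weighted scan.  The chosen individual is
replaced by two offspring; with probability ``m`` one randomly chosen
offspring migrates to one of four neighbouring demes (the one-migration
rule reproduces the published benchmark expansion speeds of this model
family, whereas independent per-offspring migration overshoots them); any
deme pushed above its carrying capacity immediately loses uniformly chosen
individuals.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes
OK_SIZE = 1          # clade reached stop_N
OK_TIME = 2          # clock reached stop_generations
EXTINCT = 3          # clade died out
ERR_GENO_CAP = 4     # genotype table exhausted
ERR_SLOTS = 5        # more genotypes in one deme than slots
ERR_EDGE = 6         # clade reached the grid boundary

S = 10  # genotype slots per deme


@njit(cache=True, inline="always")
def _activate(dm, in_active, active, n_active, gids, cnts, deme_total, deme_rate, K, r0):
    """Returns (n_active, added_rate): the freshly tracked deme's background
    rate must be added to the global Gillespie rate by the caller."""
    if in_active[dm]:
        return n_active, 0.0
    in_active[dm] = True
    gids[dm, 0] = 0
    cnts[dm, 0] = K
    deme_total[dm] = K
    deme_rate[dm] = K * r0
    active[n_active] = dm
    return n_active + 1, K * r0


@njit(cache=True)
def run_abm(
    G,
    K,
    m,
    mu_tilde,
    r_background,
    background_migrates,
    r_wt,
    effect_mode,     # 0: fixed r_m, 1: random multiplicative (diminishing returns)
    r_m_fixed,
    s_effect,
    M_cap,
    max_mutations,   # mutants may mutate further while their count < max_mutations
    wildtype_only_mutation,  # 1: mutation coupled to wildtype reproduction only
    stop_N,
    stop_generations,
    stringency,
    n_geno_cap,
    rec_dt,          # >0: record clade size on this time grid
    seed,
):
    np.random.seed(seed)
    ncells = G * G
    gids = np.full((ncells, S), -1, dtype=np.int32)
    cnts = np.zeros((ncells, S), dtype=np.int32)
    deme_total = np.zeros(ncells, dtype=np.int32)
    deme_rate = np.zeros(ncells, dtype=np.float64)
    in_active = np.zeros(ncells, dtype=np.bool_)
    active = np.zeros(ncells, dtype=np.int32)
    n_active = 0

    g_rate = np.zeros(n_geno_cap, dtype=np.float64)
    g_parent = np.full(n_geno_cap, -1, dtype=np.int32)
    g_nmut = np.zeros(n_geno_cap, dtype=np.int32)
    g_count = np.zeros(n_geno_cap, dtype=np.int64)
    g_maxcount = np.zeros(n_geno_cap, dtype=np.int64)
    g_birth_t = np.zeros(n_geno_cap, dtype=np.float64)
    g_birth_dist = np.zeros(n_geno_cap, dtype=np.float64)
    g_birth_cladeN = np.zeros(n_geno_cap, dtype=np.int64)
    g_rate[0] = r_background
    g_rate[1] = r_wt
    n_geno = 2

    n_rec = int(stop_generations / rec_dt) + 2 if rec_dt > 0 else 1
    traj = np.full(n_rec, -1, dtype=np.int64)
    next_rec_t = 0.0
    i_rec = 0

    c0 = G // 2
    centre = c0 * G + c0
    n_active, _ = _activate(
        centre, in_active, active, n_active, gids, cnts, deme_total, deme_rate, K, r_background
    )
    # replace one background individual by the founding invader
    cnts[centre, 0] = K - 1
    gids[centre, 1] = 1
    cnts[centre, 1] = 1
    deme_rate[centre] = (K - 1) * r_background + r_wt
    g_count[0] = K - 1  # background bookkeeping is local to active demes only
    g_count[1] = 1
    g_maxcount[1] = 1
    g_birth_cladeN[1] = 0

    total_rate = deme_rate[centre]
    clade_N = 1
    wt_count = 1
    n_live_mut = 0
    max_r = r_wt if r_wt > r_background else r_background

    t = 0.0
    status = 0
    sweep_radius = -1.0
    fixed_flag = np.zeros(n_geno_cap, dtype=np.bool_)
    n_fixed = 0
    next_check_N = 2 * K
    touched = np.empty(3, dtype=np.int64)
    edge_lo = 1
    edge_hi = G - 2

    while True:
        if clade_N <= 0:
            status = EXTINCT
            break
        if clade_N >= stop_N:
            status = OK_SIZE
            break
        if t >= stop_generations:
            status = OK_TIME
            break

        # Gillespie clock
        t += -np.log(np.random.random()) / total_rate
        if rec_dt > 0:
            while next_rec_t <= t and i_rec < n_rec:
                traj[i_rec] = clade_N
                next_rec_t += rec_dt
                i_rec += 1

        # select an active deme proportional to its rate (rejection)
        max_deme_rate = K * max_r
        while True:
            dm = active[np.int64(np.random.random() * n_active)]
            if np.random.random() * max_deme_rate < deme_rate[dm]:
                break

        # select the reproducing genotype slot within the deme
        u = np.random.random() * deme_rate[dm]
        slot = -1
        acc = 0.0
        for sidx in range(S):
            gid = gids[dm, sidx]
            if gid >= 0 and cnts[dm, sidx] > 0:
                acc += cnts[dm, sidx] * g_rate[gid]
                slot = sidx
                if u < acc:
                    break
        g = gids[dm, slot]

        # parent is replaced by two offspring
        cnts[dm, slot] -= 1
        deme_total[dm] -= 1
        deme_rate[dm] -= g_rate[g]
        total_rate -= g_rate[g]
        g_count[g] -= 1
        if g >= 1:
            clade_N -= 1
            if g == 1:
                wt_count -= 1
        if cnts[dm, slot] == 0:
            gids[dm, slot] = -1
            if g >= 2 and g_count[g] == 0:
                n_live_mut -= 1

        # mutation decision (coupled to reproduction)
        mut_off = -1
        if mu_tilde > 0.0 and g >= 1:
            eligible = (g == 1) if wildtype_only_mutation == 1 else (g_nmut[g] < max_mutations)
            if eligible and np.random.random() < mu_tilde:
                mut_off = 0 if np.random.random() < 0.5 else 1

        # migration decision: with probability m, one offspring disperses
        mig_off = -1
        if (g >= 1 or background_migrates == 1) and np.random.random() < m:
            mig_off = 0 if np.random.random() < 0.5 else 1

        n_touched = 1
        touched[0] = dm
        dmi = dm // G
        dmj = dm % G

        for off in range(2):
            go = g
            if off == mut_off:
                if n_geno >= n_geno_cap:
                    status = ERR_GENO_CAP
                    break
                go = n_geno
                n_geno += 1
                g_parent[go] = g
                g_nmut[go] = g_nmut[g] + 1
                if effect_mode == 0:
                    g_rate[go] = r_m_fixed
                else:
                    x_eff = -np.log(np.random.random())
                    rc = g_rate[g] * (1.0 + s_effect * x_eff * (1.0 - g_rate[g] / M_cap))
                    g_rate[go] = rc if rc < M_cap else M_cap
                if g_rate[go] > max_r:
                    max_r = g_rate[go]
                g_birth_t[go] = t
                g_birth_cladeN[go] = clade_N
                n_live_mut += 1

            # placement
            ti = dmi
            tj = dmj
            if off == mig_off:
                direction = np.int64(np.random.random() * 4.0)
                if direction == 0:
                    ti += 1
                elif direction == 1:
                    ti -= 1
                elif direction == 2:
                    tj += 1
                else:
                    tj -= 1
            out_of_grid = ti < 0 or ti >= G or tj < 0 or tj >= G
            target = dm if out_of_grid else ti * G + tj

            if off == mut_off:
                di = ti - c0
                dj = tj - c0
                g_birth_dist[go] = np.sqrt(di * di + dj * dj)

            if go == 0 and (out_of_grid or not in_active[target]):
                # a background offspring landing in a frozen background deme
                # displaces an untracked background individual: no state change
                if out_of_grid or target != dm:
                    continue
            if not in_active[target]:
                n_active, added = _activate(
                    target, in_active, active, n_active, gids, cnts,
                    deme_total, deme_rate, K, r_background,
                )
                total_rate += added
            if go >= 1:
                if ti < edge_lo or ti > edge_hi or tj < edge_lo or tj > edge_hi:
                    status = ERR_EDGE
                    break
                if background_migrates == 1:
                    # the background in neighbouring demes now feels the clade
                    for dd in range(4):
                        ni = ti + (1 if dd == 0 else -1 if dd == 1 else 0)
                        nj = tj + (1 if dd == 2 else -1 if dd == 3 else 0)
                        nb = ni * G + nj
                        if 0 <= ni < G and 0 <= nj < G and not in_active[nb]:
                            n_active, added = _activate(
                                nb, in_active, active, n_active, gids, cnts,
                                deme_total, deme_rate, K, r_background,
                            )
                            total_rate += added

            # insert offspring into target deme
            islot = -1
            for sidx in range(S):
                if gids[target, sidx] == go:
                    islot = sidx
                    break
            if islot < 0:
                for sidx in range(S):
                    if gids[target, sidx] < 0:
                        islot = sidx
                        gids[target, sidx] = go
                        break
            if islot < 0:
                status = ERR_SLOTS
                break
            if cnts[target, islot] == 0 and go >= 2 and g_count[go] == 0 and off != mut_off:
                n_live_mut += 1  # re-appearing lineage (count was transiently 0)
            cnts[target, islot] += 1
            deme_total[target] += 1
            deme_rate[target] += g_rate[go]
            total_rate += g_rate[go]
            g_count[go] += 1
            if g_count[go] > g_maxcount[go]:
                g_maxcount[go] = g_count[go]
            if go >= 1:
                clade_N += 1
                if go == 1:
                    wt_count += 1
            if target != dm:
                already = False
                for k in range(n_touched):
                    if touched[k] == target:
                        already = True
                if not already:
                    touched[n_touched] = target
                    n_touched += 1
        if status != 0:
            break

        # capacity enforcement: uniform random deaths down to K
        for k in range(n_touched):
            dmx = touched[k]
            while deme_total[dmx] > K:
                v = np.int64(np.random.random() * deme_total[dmx])
                acc2 = 0
                vslot = -1
                for sidx in range(S):
                    if gids[dmx, sidx] >= 0:
                        acc2 += cnts[dmx, sidx]
                        vslot = sidx
                        if v < acc2:
                            break
                vg = gids[dmx, vslot]
                cnts[dmx, vslot] -= 1
                deme_total[dmx] -= 1
                deme_rate[dmx] -= g_rate[vg]
                total_rate -= g_rate[vg]
                g_count[vg] -= 1
                if vg >= 1:
                    clade_N -= 1
                    if vg == 1:
                        wt_count -= 1
                if cnts[dmx, vslot] == 0:
                    gids[dmx, vslot] = -1
                    if vg >= 2 and g_count[vg] == 0:
                        n_live_mut -= 1

        # sweep monitoring
        if stringency >= 1.0 and wildtype_only_mutation == 1:
            # single-mutation model: a full sweep is exactly "wildtype gone,
            # one mutant lineage left"
            if (
                sweep_radius < 0.0
                and wt_count == 0
                and n_live_mut == 1
                and clade_N > 0
            ):
                sweep_radius = np.sqrt(clade_N / np.pi)
                n_fixed = 1
        elif clade_N >= next_check_N:
            next_check_N = clade_N + clade_N // 64 + 1
            carriers = g_count[:n_geno].copy()
            for gid in range(n_geno - 1, 1, -1):
                p = g_parent[gid]
                if p >= 1:
                    carriers[p] += carriers[gid]
            thresh = np.int64(np.ceil(stringency * clade_N))
            for gid in range(2, n_geno):
                if not fixed_flag[gid] and carriers[gid] >= thresh and carriers[gid] > 0:
                    fixed_flag[gid] = True
                    n_fixed += 1
                    if sweep_radius < 0.0:
                        sweep_radius = np.sqrt(clade_N / np.pi)

    # final sweep call: a mutation shared by >= stringency of the clade
    swept = False
    if clade_N > 0 and status in (OK_SIZE, OK_TIME):
        carriers = g_count[:n_geno].copy()
        for gid in range(n_geno - 1, 1, -1):
            p = g_parent[gid]
            if p >= 1:
                carriers[p] += carriers[gid]
        thresh = np.int64(np.ceil(stringency * clade_N))
        for gid in range(2, n_geno):
            if carriers[gid] >= thresh:
                swept = True
                if not fixed_flag[gid]:
                    fixed_flag[gid] = True
                    n_fixed += 1
                if sweep_radius < 0.0:
                    sweep_radius = np.sqrt(clade_N / np.pi)

    return (
        status,
        t,
        clade_N,
        wt_count,
        swept,
        sweep_radius,
        n_fixed,
        n_geno,
        g_rate[:n_geno].copy(),
        g_parent[:n_geno].copy(),
        g_nmut[:n_geno].copy(),
        g_count[:n_geno].copy(),
        g_maxcount[:n_geno].copy(),
        g_birth_t[:n_geno].copy(),
        g_birth_dist[:n_geno].copy(),
        g_birth_cladeN[:n_geno].copy(),
        traj[:i_rec].copy(),
    )


@njit(cache=True)
def moran_fixation_runs(K, r_resident, r_mutant, n_runs, seed):
    """Single-deme fixation experiment matching the within-deme ABM rule.

    Starts with one mutant among K - 1 residents; each event replaces a
    fitness-weighted random individual by two offspring and then removes a
    uniformly random individual.  Returns the number of runs in which the
    mutant fixed.
    """
    np.random.seed(seed)
    n_fixed = 0
    for _ in range(n_runs):
        i = 1  # mutant count
        while 0 < i < K:
            rate_mut = i * r_mutant
            rate_tot = rate_mut + (K - i) * r_resident
            mutant_reproduces = np.random.random() * rate_tot < rate_mut
            # net +1 of the reproducing type, then uniform death among K + 1
            if mutant_reproduces:
                i += 1
            victim_is_mutant = np.random.random() * (K + 1) < i
            if victim_is_mutant:
                i -= 1
        if i == K:
            n_fixed += 1
    return n_fixed
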
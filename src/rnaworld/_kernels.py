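"""Numba kernels: folding DP and the per-step simulation phases.

The simulator's hot path works on struct-of-arrays state (one slot per
agent); these kernels are jitted with numba. All randomness flows through
an explicit per-simulation xoshiro256++ state array, so trajectories are
bit-reproducible for a fixed seed even when several simulations run
interleaved in one process.

Agent state codes: 0 = free, 1 = enzyme in a complex, 2 = template in a
complex. Dead slots are recycled through an explicit free-slot stack whose
top lives in ``counters[0]``; ``counters[1..3]`` accumulate births, decay
deaths and crowding removals for conservation audits.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# counters layout
FREE_TOP = 0
BIRTHS = 1
DEATHS = 2
CROWDED = 3

_TWO_PI = 2.0 * np.pi
#: sentinel lifetime for agents with zero decay rate (effectively immortal)
_NO_DECAY_STEPS = np.int64(2) ** 62


# ---------------------------------------------------------------------------
# Per-simulation PRNG (xoshiro256++), state passed explicitly so that
# concurrent Simulation instances never share a stream
# ---------------------------------------------------------------------------


@njit(cache=True)
def _rotl(x, k):
    return (x << np.uint64(k)) | (x >> np.uint64(64 - k))


@njit(cache=True)
def next_u64(rstate):
    """Advance the xoshiro256++ state; returns a uint64."""
    result = _rotl(rstate[0] + rstate[3], 23) + rstate[0]
    t = rstate[1] << np.uint64(17)
    rstate[2] ^= rstate[0]
    rstate[3] ^= rstate[1]
    rstate[1] ^= rstate[2]
    rstate[0] ^= rstate[3]
    rstate[2] ^= t
    rstate[3] = _rotl(rstate[3], 45)
    return result


@njit(cache=True)
def rand_f64(rstate):
    """Uniform double in [0, 1) with 53 random bits."""
    return (next_u64(rstate) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def shuffle(arr, rstate):
    """In-place Fisher-Yates shuffle."""
    for i in range(arr.size - 1, 0, -1):
        j = np.int64(rand_f64(rstate) * (i + 1))
        tmp = arr[i]
        arr[i] = arr[j]
        arr[j] = tmp


def seed_state(seed_sequence) -> np.ndarray:
    """Build a nonzero 4-word xoshiro256++ state from a SeedSequence."""
    state = seed_sequence.generate_state(4, dtype=np.uint64)
    while not state.any():  # pragma: no cover - astronomically unlikely
        state = np.random.SeedSequence(1).generate_state(4, dtype=np.uint64)
    return state.copy()


# ---------------------------------------------------------------------------
# Nussinov maximum base-pairing
# ---------------------------------------------------------------------------


@njit(cache=True)
def nussinov_dp(codes, min_loop, pairable):
    """Fill the max-pair-count DP table.

    dp[i, j] = maximum number of base pairs in codes[i..j] (inclusive),
    under the hairpin constraint j - i - 1 >= min_loop for any pair (i, j)
    and the chemical rule in the 4x4 boolean ``pairable`` matrix.
    """
    n = codes.size
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if pairable[codes[i], codes[k]]:
                    inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    rest = dp[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + inner + rest
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


@njit(cache=True)
def nussinov_pair_table(codes, min_loop, pairable):
    """Predict the max-pairing structure; return a partner table.

    ``pt[i]`` is the partner index of position i, or -1 if unpaired. The
    traceback is deterministic: at each interval the 5'-most position is
    paired with its leftmost admissible partner whenever pairing achieves
    the optimum, otherwise left unpaired.
    """
    n = codes.size
    dp = nussinov_dp(codes, min_loop, pairable)
    pt = np.full(n, -1, dtype=np.int32)
    # explicit interval stack
    stack_i = np.empty(2 * n + 2, dtype=np.int64)
    stack_j = np.empty(2 * n + 2, dtype=np.int64)
    top = 0
    stack_i[top] = 0
    stack_j[top] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        if i >= j or dp[i, j] == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if pairable[codes[i], codes[k]]:
                inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                rest = dp[k + 1, j] if k + 1 <= j else 0
                if 1 + inner + rest == dp[i, j]:
                    pt[i] = k
                    pt[k] = i
                    stack_i[top] = i + 1
                    stack_j[top] = k - 1
                    top += 1
                    stack_i[top] = k + 1
                    stack_j[top] = j
                    top += 1
                    paired = True
                    break
        if not paired:
            stack_i[top] = i + 1
            stack_j[top] = j
            top += 1
    return pt


@njit(cache=True)
def folded_fraction_of(codes, min_loop, pairable):
    """Fraction of nucleotides paired in the max-pairing structure."""
    pt = nussinov_pair_table(codes, min_loop, pairable)
    paired = 0
    for i in range(pt.size):
        if pt[i] >= 0:
            paired += 1
    return paired / pt.size


# ---------------------------------------------------------------------------
# Per-agent parameter derivation (kernel-side mirror of the module API)
# ---------------------------------------------------------------------------


@njit(cache=True)
def derive_params(
    seq_row, motif_codes, match_threshold, rate_per_match, dt, base_d,
    hyd, min_loop, pairable,
):
    """Compute (l, a, b) for one encoded sequence."""
    matches = 0
    for p in range(motif_codes.size):
        if seq_row[p] == motif_codes[p]:
            matches += 1
    if matches >= match_threshold:
        a = 1.0 - np.exp(-rate_per_match * matches * dt)
    else:
        a = 0.0
    b = base_d
    for p in range(seq_row.size - 1):
        b += hyd[seq_row[p], seq_row[p + 1]]
    l = folded_fraction_of(seq_row, min_loop, pairable)
    return l, a, b


#: slots in the (l, a, b) memo cache; must be a power of two
PARAM_CACHE_SLOTS = 1 << 15
_PROBE_LIMIT = 8


@njit(cache=True)
def _seq_hash(seq_row):
    """FNV-1a over the encoded sequence."""
    h = np.uint64(0xCBF29CE484222325)
    prime = np.uint64(0x100000001B3)
    for p in range(seq_row.size):
        h = (h ^ np.uint64(seq_row[p])) * prime
    return h


@njit(cache=True)
def derive_params_cached(
    seq_row, motif_codes, match_threshold, rate_per_match, dt, base_d, hyd,
    min_loop, pairable, cache_keys, cache_vals, cache_used,
):
    """Memoised :func:`derive_params`.

    (l, a, b) are pure functions of the sequence, so an open-addressing
    cache keyed by the sequence bytes returns bit-identical values and
    consumes no randomness — trajectories do not depend on cache state.
    Collisions beyond the probe limit overwrite the primary slot.
    """
    n_slots = np.uint64(cache_keys.shape[0])
    mask = n_slots - np.uint64(1)
    h = _seq_hash(seq_row)
    L = seq_row.size
    slot0 = np.int64(h & mask)
    for probe in range(_PROBE_LIMIT):
        slot = np.int64((np.uint64(slot0) + np.uint64(probe)) & mask)
        if cache_used[slot] == 0:
            ll, aa, bb = derive_params(
                seq_row, motif_codes, match_threshold, rate_per_match, dt,
                base_d, hyd, min_loop, pairable,
            )
            for p in range(L):
                cache_keys[slot, p] = seq_row[p]
            cache_vals[slot, 0] = ll
            cache_vals[slot, 1] = aa
            cache_vals[slot, 2] = bb
            cache_used[slot] = 1
            return ll, aa, bb
        same = True
        for p in range(L):
            if cache_keys[slot, p] != seq_row[p]:
                same = False
                break
        if same:
            return cache_vals[slot, 0], cache_vals[slot, 1], cache_vals[slot, 2]
    # probe window full of other sequences: recompute and evict the slot
    ll, aa, bb = derive_params(
        seq_row, motif_codes, match_threshold, rate_per_match, dt, base_d,
        hyd, min_loop, pairable,
    )
    for p in range(L):
        cache_keys[slot0, p] = seq_row[p]
    cache_vals[slot0, 0] = ll
    cache_vals[slot0, 1] = aa
    cache_vals[slot0, 2] = bb
    cache_used[slot0] = 1
    return ll, aa, bb


@njit(cache=True)
def derive_params_batch(
    seqs, n, l, a, b, motif_codes, match_threshold, rate_per_match, dt,
    base_d, hyd, min_loop, pairable,
):
    """Fill (l, a, b) for the first *n* rows of the sequence matrix."""
    for i in range(n):
        ll, aa, bb = derive_params(
            seqs[i], motif_codes, match_threshold, rate_per_match, dt,
            base_d, hyd, min_loop, pairable,
        )
        l[i] = ll
        a[i] = aa
        b[i] = bb


@njit(cache=True)
def sample_steps(k, dt, rstate):
    """Exponential waiting time for rate k, as a step count >= 1."""
    if k <= 0.0:
        return _NO_DECAY_STEPS
    x = 1.0 - rand_f64(rstate)  # in (0, 1]
    t = -np.log(x) / k
    return np.int64(t / dt) + 1


# ---------------------------------------------------------------------------
# Phase A: decay, replication countdown, diffusion
# ---------------------------------------------------------------------------


@njit(cache=True)
def decay_diffusion_phase(
    seqs, x, y, l, a, b, lifetime, rep_steps, state, partner, alive,
    free_slots, counters,
    size_x, size_y, dt, diff_const, seq_mut, base_d, hyd,
    motif_codes, match_threshold, rate_per_match, min_loop, pairable,
    cache_keys, cache_vals, cache_used, rstate,
):
    """One pass of the decay/diffusion phase over a random agent order.

    Agents alive at phase start are visited exactly once in a fresh uniform
    random order. A complexed enzyme decrements its complex's replication
    countdown; at zero the template is copied (with per-site mutation), the
    offspring is placed at the template's position with parameters derived
    from its own sequence, and the complex dissociates. Free agents age by
    one step; at lifetime zero they are removed, otherwise they diffuse.
    Offspring enter the population immediately but are not visited (they
    neither age nor diffuse until the next step).
    """
    n_cap = alive.size
    n_alive = 0
    for i in range(n_cap):
        if alive[i]:
            n_alive += 1
    order = np.empty(n_alive, dtype=np.int64)
    w = 0
    for i in range(n_cap):
        if alive[i]:
            order[w] = i
            w += 1
    shuffle(order, rstate)

    seq_len = seqs.shape[1]
    motif_len = motif_codes.size
    for oi in range(n_alive):
        idx = order[oi]
        st = state[idx]
        if st == 1:
            # enzyme drives the complex countdown, once per complex per step
            rep_steps[idx] -= 1
            if rep_steps[idx] <= 0:
                tpl = partner[idx]
                counters[FREE_TOP] -= 1
                slot = free_slots[counters[FREE_TOP]]
                # copy template with per-site substitution mutation
                mutated = False
                for p in range(seq_len):
                    c = seqs[tpl, p]
                    if rand_f64(rstate) < seq_mut:
                        shift = 1 + np.int64(3.0 * rand_f64(rstate))
                        c = (c + shift) % 4
                        mutated = True
                    seqs[slot, p] = c
                if mutated:
                    ll, aa, bb = derive_params_cached(
                        seqs[slot], motif_codes, match_threshold,
                        rate_per_match, dt, base_d, hyd, min_loop, pairable,
                        cache_keys, cache_vals, cache_used,
                    )
                else:
                    # identical copy: parameters are a pure function of
                    # the sequence, so inherit them unchanged
                    ll, aa, bb = l[tpl], a[tpl], b[tpl]
                l[slot] = ll
                a[slot] = aa
                b[slot] = bb
                x[slot] = x[tpl]
                y[slot] = y[tpl]
                lifetime[slot] = sample_steps(bb, dt, rstate)
                rep_steps[slot] = 0
                state[slot] = 0
                partner[slot] = -1
                alive[slot] = True
                counters[BIRTHS] += 1
                # dissociation: both members resume aging and diffusion
                state[idx] = 0
                partner[idx] = -1
                state[tpl] = 0
                partner[tpl] = -1
        elif st == 2:
            pass  # template is frozen; the enzyme holds the countdown
        else:
            lifetime[idx] -= 1
            if lifetime[idx] <= 0:
                alive[idx] = False
                free_slots[counters[FREE_TOP]] = idx
                counters[FREE_TOP] += 1
                counters[DEATHS] += 1
            elif diff_const > 0.0:
                p_mag = rand_f64(rstate)
                theta = _TWO_PI * rand_f64(rstate)
                r = np.sqrt(6.0 * dt * diff_const * p_mag)
                nx = (x[idx] + r * np.cos(theta)) % size_x
                ny = (y[idx] + r * np.sin(theta)) % size_y
                if nx >= size_x:
                    nx -= size_x
                if ny >= size_y:
                    ny -= size_y
                x[idx] = nx
                y[idx] = ny


# ---------------------------------------------------------------------------
# Phase B: crowding and complex formation
# ---------------------------------------------------------------------------

_MAX_NEIGH_BUF = 512


@njit(cache=True)
def interactions_phase(
    x, y, l, a, rep_steps, state, partner, alive, free_slots, counters,
    size_x, size_y, int_radius, neigh_max, big_k, dt,
    count_complexed, rstate,
):
    """One pass of the interaction phase over a random free-agent order.

    All alive agents (free and complexed) are indexed on a uniform grid with
    cell size >= the interaction radius. Free agents are visited in a fresh
    random order; each still-free focal agent gathers its neighbours at
    toroidal distance strictly below the interaction radius. More than
    ``neigh_max`` neighbours removes the focal agent (crowding); otherwise
    the focal agent scans its neighbours in random order and, with
    probability a_E * l_E * (1 - l_T) per non-complexed neighbour, binds the
    first success as template and stops. Agents complexed earlier in the
    phase are skipped as initiators and unavailable as templates.
    """
    n_cap = alive.size
    # --- uniform grid (counting sort), cell size >= int_radius ---
    ncx = max(1, np.int64(size_x / int_radius))
    ncy = max(1, np.int64(size_y / int_radius))
    cw = size_x / ncx
    ch = size_y / ncy
    ncell = ncx * ncy
    cell_of = np.full(n_cap, -1, dtype=np.int64)
    counts = np.zeros(ncell + 1, dtype=np.int64)
    total = 0
    for i in range(n_cap):
        if alive[i]:
            cx = np.int64(x[i] / cw)
            cy = np.int64(y[i] / ch)
            if cx >= ncx:
                cx = ncx - 1
            if cy >= ncy:
                cy = ncy - 1
            c = cy * ncx + cx
            cell_of[i] = c
            counts[c + 1] += 1
            total += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    bucket = np.empty(total, dtype=np.int64)
    cursor = counts.copy()
    for i in range(n_cap):
        c = cell_of[i]
        if c >= 0:
            bucket[cursor[c]] = i
            cursor[c] += 1

    # --- random order over free agents ---
    n_free = 0
    for i in range(n_cap):
        if alive[i] and state[i] == 0:
            n_free += 1
    order = np.empty(n_free, dtype=np.int64)
    w = 0
    for i in range(n_cap):
        if alive[i] and state[i] == 0:
            order[w] = i
            w += 1
    shuffle(order, rstate)

    nb = np.empty(_MAX_NEIGH_BUF, dtype=np.int64)
    cells = np.empty(9, dtype=np.int64)
    r2 = int_radius * int_radius
    half_x = 0.5 * size_x
    half_y = 0.5 * size_y
    for oi in range(n_free):
        idx = order[oi]
        if not alive[idx] or state[idx] != 0:
            continue  # complexed earlier in this phase, or removed
        cx = cell_of[idx] % ncx
        cy = cell_of[idx] // ncx
        # 3x3 neighbourhood with wrap; dedupe for tiny grids
        n_cells = 0
        for dy in range(-1, 2):
            gy = (cy + dy) % ncy
            for dx in range(-1, 2):
                gx = (cx + dx) % ncx
                c = gy * ncx + gx
                seen = False
                for q in range(n_cells):
                    if cells[q] == c:
                        seen = True
                        break
                if not seen:
                    cells[n_cells] = c
                    n_cells += 1
        nn = 0
        for q in range(n_cells):
            c = cells[q]
            for bi in range(counts[c], counts[c + 1]):
                t = bucket[bi]
                if t == idx or not alive[t]:
                    continue
                ddx = abs(x[t] - x[idx])
                if ddx > half_x:
                    ddx = size_x - ddx
                ddy = abs(y[t] - y[idx])
                if ddy > half_y:
                    ddy = size_y - ddy
                if ddx * ddx + ddy * ddy < r2:
                    if not count_complexed and state[t] != 0:
                        continue
                    if nn < _MAX_NEIGH_BUF:
                        nb[nn] = t
                    nn += 1
        if nn > neigh_max:
            # crowding: too dense a neighbourhood removes the focal agent
            alive[idx] = False
            free_slots[counters[FREE_TOP]] = idx
            counters[FREE_TOP] += 1
            counters[CROWDED] += 1
            continue
        if nn == 0:
            continue
        shuffle(nb[:nn], rstate)
        for q in range(nn):
            t = nb[q]
            if state[t] != 0 or not alive[t]:
                continue  # complexed (or removed) agents cannot template
            prob = a[idx] * l[idx] * (1.0 - l[t])
            p = rand_f64(rstate)
            if p < prob:
                state[idx] = 1
                state[t] = 2
                partner[idx] = t
                partner[t] = idx
                if np.isinf(big_k):
                    rep_steps[idx] = 1
                else:
                    rep_steps[idx] = sample_steps(big_k, dt, rstate)
                break
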
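"""Optional numba-accelerated per-iteration kernel for the main loop.

Semantics are identical to the pure-Python path in ``reinforce``/``sampler``:
one subnetwork grown per seed (frontier draw proportional to gene score,
uniform on a zero-mass frontier), members ordered by descending alteration
count with index tie-break, MES accumulated with single-contribution
inverse-overlap sample weights and a per-gene square root.  Randomness comes
from an explicit xorshift64* state so the kernel is deterministic given its
seed and independent of global RNG state.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def deco(fn):
            return fn

        return deco(args[0]) if args and callable(args[0]) else deco


@njit(cache=True, inline="always")
def _rand01(state):
    """xorshift64* uniform in [0, 1)."""
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x &= np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    state[0] = x
    y = (x * np.uint64(2685821657736338717)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return (y >> np.uint64(11)) * (1.0 / 9007199254740992.0)


def seed_state(seed: int) -> np.ndarray:
    """Derive a nonzero xorshift64* state from an integer seed (splitmix64)."""
    z = (int(seed) + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = (z ^ (z >> 30)) * 0xBF58476D1CE4E5B9 & 0xFFFFFFFFFFFFFFFF
    z = (z ^ (z >> 27)) * 0x94D049BB133111EB & 0xFFFFFFFFFFFFFFFF
    z ^= z >> 31
    if z == 0:
        z = 0x106689D45497FDB5
    return np.array([z], dtype=np.uint64)


@njit(cache=True)
def iteration_kernel(
    indptr,  # int64[n_genes+1] CSR adjacency
    indices,  # int32[total_degree]
    scores,  # float64[n_genes]
    alt,  # uint8[n_genes, n_samples]
    gene_counts,  # int64[n_genes] per-gene total alteration count
    seed_idx,  # int64[n_seeds]
    size,  # target subnetwork size
    state,  # uint64[1] rng state
    members_out,  # int32[n_seeds, size], padded with -1
    mes_out,  # float64[n_seeds]
    seed_out,  # int32[n_seeds] grow seed of each returned subnetwork
):
    """Grow and score one subnetwork per seed; returns the number grown."""
    n_genes = scores.shape[0]
    n_samples = alt.shape[1]
    flags = np.zeros(n_genes, dtype=np.uint8)  # 0 free, 1 frontier, 2 member
    frontier = np.empty(n_genes, dtype=np.int32)
    members = np.empty(size, dtype=np.int32)
    m_buf = np.zeros(n_samples, dtype=np.int64)
    n_sub = 0
    for si in range(seed_idx.shape[0]):
        seed = seed_idx[si]
        members[0] = seed
        k = 1
        flags[seed] = 2
        fn = 0
        for j in range(indptr[seed], indptr[seed + 1]):
            nb = indices[j]
            frontier[fn] = nb
            flags[nb] = 1
            fn += 1
        while k < size and fn > 0:
            total = 0.0
            for i in range(fn):
                total += scores[frontier[i]]
            if total > 0.0:
                cut = _rand01(state) * total
                acc = 0.0
                c = fn - 1
                for i in range(fn):
                    acc += scores[frontier[i]]
                    if acc > cut:
                        c = i
                        break
            else:
                c = int(_rand01(state) * fn)
                if c >= fn:
                    c = fn - 1
            g = frontier[c]
            frontier[c] = frontier[fn - 1]
            fn -= 1
            members[k] = g
            k += 1
            flags[g] = 2
            for j in range(indptr[g], indptr[g + 1]):
                nb = indices[j]
                if flags[nb] == 0:
                    frontier[fn] = nb
                    flags[nb] = 1
                    fn += 1
        # reset flags
        for i in range(k):
            flags[members[i]] = 0
        for i in range(fn):
            flags[frontier[i]] = 0
        if k < 2:
            continue  # isolated seed: no subnetwork this iteration
        # order by (-alteration count, gene index): insertion sort, k <= 6
        for i in range(1, k):
            g = members[i]
            cg = gene_counts[g]
            j = i - 1
            while j >= 0 and (
                gene_counts[members[j]] < cg
                or (gene_counts[members[j]] == cg and members[j] > g)
            ):
                members[j + 1] = members[j]
                j -= 1
            members[j + 1] = g
        # MES: m(s, V) on the full V, one contribution per sample
        for s in range(n_samples):
            m = 0
            for i in range(k):
                m += alt[members[i], s]
            m_buf[s] = m
        mes = 0.0
        for i in range(k):
            g = members[i]
            bucket = 0.0
            for s in range(n_samples):
                if alt[g, s] == 1 and m_buf[s] > 0:
                    bucket += 1.0 / m_buf[s]
                    m_buf[s] = -m_buf[s]  # consumed
            mes += np.sqrt(bucket)
        for i in range(k):
            members_out[n_sub, i] = members[i]
        for i in range(k, members_out.shape[1]):
            members_out[n_sub, i] = -1
        mes_out[n_sub] = mes
        seed_out[n_sub] = seed
        n_sub += 1
    return n_sub
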
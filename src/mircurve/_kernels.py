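"""Numba kernels for the two dynamic programs that dominate runtime.

`duplex_min_energy` is the energy-only fast path of the intermolecular
alignment DP (used for window scans and profile curves); the pure-Python
implementation in :mod:`mircurve.duplex` additionally produces tracebacks and
must agree with it exactly.  `fold_min_energy` is a weighted
base-pair-maximization fold (Nussinov-style) used for opening energies.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e30


@njit(fastmath=False)
def duplex_min_energy(q, r, pairable, stack, loop_init, loop_ext, loop_max,
                      end_penalty, duplex_init):
    """Minimum duplex energy of guide ``q`` vs reversed target window ``r``.

    ``q`` and ``r`` are int8 base codes; ``r`` must already be reversed so
    that pairing indices increase together (antiparallel duplex).  Returns
    0.0 when no base pair can form (no-duplex sentinel: nothing is gained).
    """
    m = q.shape[0]
    n = r.shape[0]
    B = np.full((m, n), INF)
    best = INF
    for i in range(m):
        qi = q[i]
        for j in range(n):
            if not pairable[qi, r[j]]:
                continue
            e = end_penalty * i  # this is the first pair of the duplex
            if i > 0 and j > 0 and B[i - 1, j - 1] < INF:
                v = B[i - 1, j - 1] + stack[q[i - 1], r[j - 1], qi, r[j]]
                if v < e:
                    e = v
            for di in range(loop_max + 1):
                ii = i - 1 - di
                if ii < 0:
                    break
                for dj in range(loop_max + 1):
                    jj = j - 1 - dj
                    if jj < 0:
                        break
                    if di == 0 and dj == 0:
                        continue
                    if B[ii, jj] < INF:
                        L = di if di > dj else dj
                        v = B[ii, jj] + loop_init + loop_ext * (L - 1)
                        if v < e:
                            e = v
            B[i, j] = e
            tot = e + end_penalty * (m - 1 - i) + duplex_init
            if tot < best:
                best = tot
    if best >= INF:
        return 0.0
    return best


@njit(fastmath=False)
def scan_window_energies(q, t_rev, win_len, pairable, stack, loop_init,
                         loop_ext, loop_max, end_penalty, duplex_init):
    """Duplex energy for every stride-1 window of length ``win_len``.

    ``t_rev`` is the reversed transcript; output index k corresponds to the
    forward-coordinate window starting at k.
    """
    n = t_rev.shape[0]
    n_win = n - win_len + 1
    out = np.zeros(n_win)
    for k in range(n_win):
        # forward window [k, k+win_len) is reversed-transcript slice
        # [n-k-win_len, n-k)
        lo = n - k - win_len
        out[k] = duplex_min_energy(q, t_rev[lo:lo + win_len], pairable, stack,
                                   loop_init, loop_ext, loop_max, end_penalty,
                                   duplex_init)
    return out


@njit(fastmath=False)
def fold_min_energy(s, can_pair, pair_energy, min_hairpin):
    """Minimum energy of a nested intramolecular structure on ``s``.

    ``can_pair`` marks positions allowed to pair (False = forced unpaired,
    used for the opening-energy constraint).  Energy is the sum of per-pair
    weights; unpaired bases are free.  Returns <= 0.
    """
    n = s.shape[0]
    if n == 0:
        return 0.0
    E = np.zeros((n, n))
    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i + 1, j]  # i unpaired
            if can_pair[i]:
                si = s[i]
                for k in range(i + min_hairpin + 1, j + 1):
                    if can_pair[k] and pair_energy[si, s[k]] < 0.0:
                        inner = 0.0
                        if k - 1 >= i + 1:
                            inner = E[i + 1, k - 1]
                        rest = 0.0
                        if k + 1 <= j:
                            rest = E[k + 1, j]
                        v = pair_energy[si, s[k]] + inner + rest
                        if v < best:
                            best = v
            E[i, j] = best
    return E[0, n - 1]
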
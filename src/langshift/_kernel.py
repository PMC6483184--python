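"""Compiled inner loop for interaction rounds.

A whole year of T rounds runs inside one jitted call: per round a
Fisher-Yates shuffle pairs agents (uniformly random perfect matching, one
agent idle when N is odd), both partners' utterances are sampled from their
pre-round rows, and both rows then shift toward the heard variant by the
learning weight.  Distributionally identical to
:func:`langshift.core.interaction_round`; that function remains the readable
reference implementation used by the exact enumeration checks.

The loop is RNG-bound (two draws per agent per round), so it uses an inline
xorshift64* generator seeded per call from the run's seed stream.  If numba
is unavailable the engine falls back to the numpy round loop.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco(args[0]) if args and callable(args[0]) else deco


_MULT = np.uint64(0x2545F4914F6CDD1D)
_S12 = np.uint64(12)
_S25 = np.uint64(25)
_S27 = np.uint64(27)
_S11 = np.uint64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True)
def _run_rounds(probs: np.ndarray, T: int, l: float, seed: np.uint64) -> None:
    """Run T interaction rounds in place on the (N, n_variants) usage matrix."""
    s = seed
    n, nv = probs.shape
    perm = np.arange(n)
    m = n - (n % 2)
    one_l = 1.0 - l
    for _ in range(T):
        for i in range(n - 1, 0, -1):  # Fisher-Yates: uniform random matching
            s ^= s >> _S12
            s ^= s << _S25
            s ^= s >> _S27
            j = int((s * _MULT) % np.uint64(i + 1))
            tmp = perm[i]
            perm[i] = perm[j]
            perm[j] = tmp
        for p in range(0, m, 2):
            a = perm[p]
            b = perm[p + 1]
            # utterances sampled from the pre-update rows of both partners
            s ^= s >> _S12
            s ^= s << _S25
            s ^= s >> _S27
            u = float((s * _MULT) >> _S11) * _INV53
            ua = 0
            acc = probs[a, 0]
            while u >= acc and ua < nv - 1:
                ua += 1
                acc += probs[a, ua]
            s ^= s >> _S12
            s ^= s << _S25
            s ^= s >> _S27
            u = float((s * _MULT) >> _S11) * _INV53
            ub = 0
            acc = probs[b, 0]
            while u >= acc and ub < nv - 1:
                ub += 1
                acc += probs[b, ub]
            for k in range(nv):
                probs[a, k] *= one_l
                probs[b, k] *= one_l
            probs[a, ub] += l
            probs[b, ua] += l


def run_rounds(probs: np.ndarray, T: int, l: float,
               rng: np.random.Generator) -> None:
    """T rounds in place; a fresh 64-bit kernel seed per call keeps runs reproducible."""
    if T == 0:
        return
    if len(probs) < 2:
        raise ValueError("an interaction round needs at least 2 agents")
    seed = np.uint64(rng.integers(1, 2**63))  # xorshift state must be nonzero
    _run_rounds(probs, T, l, seed)
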
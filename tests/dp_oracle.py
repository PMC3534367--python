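"""Brute-force oracle for glocal profile-HMM alignment scores.

Enumerates every legal state path explicitly (flank split, match/delete
choice at every node, insert runs between nodes) and scores it from the
profile's probability tables.  Independent of the dynamic-programming
kernels it is used to check; only practical for tiny profiles/queries.
"""

from __future__ import annotations

import numpy as np

from thdpnum._alphabet import AA_INDEX, X_INDEX


def _log_odds(em_row, bg, a):
    if a == X_INDEX:
        return 0.0
    return np.log2(em_row[a] / bg[a])


def enumerate_path_scores(profile, seq) -> list[float]:
    """Log2-odds score of every legal glocal path for ``seq``."""
    enc = [AA_INDEX[c] for c in seq.residues]
    L, K = len(enc), profile.K
    me, ie, bg = profile.match_emissions, profile.insert_emissions, \
        profile.background
    with np.errstate(divide="ignore"):
        lt = {name: np.log2(getattr(profile, name))
              for name in ("tmm", "tmi", "tmd", "tim", "tii", "tdm", "tdd")}

    scores: list[float] = []

    def step(k: int, state: str, i: int, sc: float) -> None:
        # just arrived in `state` at node k having consumed i residues
        if k == K:
            scores.append(sc)   # M_K/D_K -> end is free; rest is C-flank
            return
        if state in ("M", "D"):
            src = state.lower()
            if i < L:
                step(k + 1, "M",
                     i + 1, sc + lt[f"t{src}m"][k]
                     + _log_odds(me[k], bg, enc[i]))
            step(k + 1, "D", i, sc + lt[f"t{src}d"][k])
            if state == "M" and i < L and 1 <= k <= K - 1:
                step(k, "I", i + 1, sc + lt["tmi"][k]
                     + _log_odds(ie[k], bg, enc[i]))
        else:  # insert state I_k
            if i < L:
                step(k + 1, "M", i + 1, sc + lt["tim"][k]
                     + _log_odds(me[k], bg, enc[i]))
                step(k, "I", i + 1, sc + lt["tii"][k]
                     + _log_odds(ie[k], bg, enc[i]))

    for i0 in range(L + 1):          # N-flank length, zero log-odds
        if i0 < L:
            step(1, "M", i0 + 1,
                 lt["tmm"][0] + _log_odds(me[0], bg, enc[i0]))
        step(1, "D", i0, lt["tmd"][0])

    return [s for s in scores if s > -np.inf]


def oracle_viterbi(profile, seq) -> float:
    return max(enumerate_path_scores(profile, seq))


def oracle_forward(profile, seq) -> float:
    return float(np.logaddexp2.reduce(enumerate_path_scores(profile, seq)))
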
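"""Profile hidden Markov model built from a reference multiple alignment.

Match states are exactly the alignment columns in which the designated
reference sequence has a residue, so match state k carries the reference's
k-th residue and hence one standard number.  Emissions are smoothed by
mixing weighted observed counts with the alignment-wide background
(a single pseudocount weight); sequence weighting is position-based
(Henikoff) by default.  Alignment of a query is glocal: the model is
traversed begin to end, while query residues outside the modelled region
are absorbed by flanking insert states at zero log-odds.  All scores are
log2-odds against the background model, in bits.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from . import _dp
from ._alphabet import ALPHABET, AA_INDEX, GAP, X_INDEX, encode
from .errors import InputError
from .seqio import MultipleAlignment, SequenceRecord

_N = len(ALPHABET)  # 21
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ReferenceMap:
    """Bijection between match states and the reference's residue numbers."""

    reference_id: str
    reference_residues: str
    standard_numbers: tuple  # tuple[int, ...], strictly increasing

    def __post_init__(self):
        k = len(self.reference_residues)
        if len(self.standard_numbers) != k:
            raise InputError("reference map length mismatch")
        nums = self.standard_numbers
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise InputError("standard numbers must be strictly increasing")

    @property
    def n_match_states(self) -> int:
        return len(self.reference_residues)

    def standard_number(self, k: int) -> int:
        """Standard number of match state k (1-based)."""
        return self.standard_numbers[k - 1]


class PathStep(NamedTuple):
    kind: str       # 'M', 'I' or 'D'
    node: int       # match-state index k (insert node for 'I')
    query_index: int | None  # 1-based; None for deletes


@dataclass(frozen=True)
class AlignedPath:
    """A glocal state path for one query, with its log-odds score in bits."""

    steps: tuple  # tuple[PathStep, ...], core path only
    score: float
    entry_index: int  # residues 1..entry_index are N-flank
    exit_index: int   # residues exit_index+1..L are C-flank


@dataclass(frozen=True)
class ProfileHMM:
    """Plan7-style profile with K match states over the 21-letter alphabet."""

    match_emissions: np.ndarray   # (K, 21)
    insert_emissions: np.ndarray  # (K+1, 21)
    tmm: np.ndarray  # (K,)  tmm[0] = begin->M1
    tmi: np.ndarray  # (K,)  slots 1..K-1 meaningful
    tmd: np.ndarray  # (K,)  tmd[0] = begin->D1
    tim: np.ndarray
    tii: np.ndarray
    tdm: np.ndarray
    tdd: np.ndarray
    background: np.ndarray        # (21,)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def K(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def alphabet(self) -> str:
        return ALPHABET

    def validate(self, atol: float = 1e-9) -> None:
        K = self.K
        if K < 1:
            raise InputError("profile needs at least one match state")
        for name, arr in (("match", self.match_emissions),
                          ("insert", self.insert_emissions)):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=atol):
                raise InputError(f"{name} emission rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=atol):
            raise InputError("background must sum to 1")
        if not np.isclose(self.tmm[0] + self.tmd[0], 1.0, atol=atol):
            raise InputError("begin transitions must sum to 1")
        for k in range(1, K):
            if not np.isclose(self.tmm[k] + self.tmi[k] + self.tmd[k], 1.0,
                              atol=atol):
                raise InputError(f"match transitions at node {k} must sum to 1")
            if not np.isclose(self.tim[k] + self.tii[k], 1.0, atol=atol):
                raise InputError(f"insert transitions at node {k} must sum to 1")
            if not np.isclose(self.tdm[k] + self.tdd[k], 1.0, atol=atol):
                raise InputError(f"delete transitions at node {k} must sum to 1")

    # --- log-odds parameterisation used by the DP kernels ----------------
    def _scores(self):
        if "scores" not in self._cache:
            with np.errstate(divide="ignore"):
                mat_lo = np.log2(self.match_emissions / self.background)
                ins_lo = np.log2(self.insert_emissions / self.background)
                mat_lo[:, X_INDEX] = 0.0   # X never perturbs the path
                ins_lo[:, X_INDEX] = 0.0
                ins_lo[0, :] = 0.0         # flank inserts score at background
                ins_lo[-1, :] = 0.0
                trans = [np.log2(t) for t in
                         (self.tmm, self.tmi, self.tmd,
                          self.tim, self.tii, self.tdm, self.tdd)]
            self._cache["scores"] = (np.ascontiguousarray(mat_lo),
                                     np.ascontiguousarray(ins_lo),
                                     *trans)
        return self._cache["scores"]

    @property
    def checksum(self) -> str:
        if "checksum" not in self._cache:
            h = hashlib.sha256()
            h.update(f"v{_FORMAT_VERSION};K={self.K};{ALPHABET}".encode())
            for arr in (self.match_emissions, self.insert_emissions,
                        self.tmm, self.tmi, self.tmd, self.tim, self.tii,
                        self.tdm, self.tdd, self.background):
                h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
            self._cache["checksum"] = h.hexdigest()[:16]
        return self._cache["checksum"]


def _henikoff_weights(rows: list[str]) -> np.ndarray:
    """Position-based sequence weights (mean 1)."""
    n = len(rows)
    w = np.zeros(n)
    ncol = len(rows[0])
    for c in range(ncol):
        col = [r[c] for r in rows]
        counts: dict[str, int] = {}
        for a in col:
            if a != GAP:
                counts[a] = counts.get(a, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, a in enumerate(col):
            if a != GAP:
                w[i] += 1.0 / (r * counts[a])
    if w.sum() == 0:  # pragma: no cover - impossible for valid rows
        return np.ones(n)
    return w * n / w.sum()


def _estimate_background(rows: list[str], weights: np.ndarray) -> np.ndarray:
    counts = np.zeros(_N)
    for row, w in zip(rows, weights):
        for a in row:
            if a != GAP:
                counts[AA_INDEX[a]] += w
    emp = counts / counts.sum()
    # tiny uniform floor so every symbol (incl. unseen X) has mass > 0
    bg = 0.999 * emp + 0.001 / _N
    return bg / bg.sum()


def build_profile(msa: MultipleAlignment, reference_id: str,
                  weighting: str = "henikoff",
                  pseudocount_weight: float = 1.0,
                  reference_start: int = 1) -> tuple[ProfileHMM, ReferenceMap]:
    """Build a profile HMM whose match states are the reference's residues.

    Emissions at match state k are ``(weighted counts + w_pc * background)
    / (total + w_pc)`` with ``w_pc = pseudocount_weight``; transitions use
    the same mixing weight with a uniform prior over each state's moves.
    """
    if pseudocount_weight < 0:
        raise InputError("pseudocount_weight must be non-negative")
    if weighting not in ("none", "henikoff"):
        raise InputError(f"unknown weighting {weighting!r}")
    ids = msa.ids
    if reference_id not in ids:
        raise InputError(f"reference id {reference_id!r} not in alignment")
    if len(ids) == 1:
        warnings.warn("alignment has a single row; the profile equals that "
                      "sequence with pseudocounts")
    rows = [r.residues for r in msa.records]
    ref_row = msa.row(reference_id).residues
    match_cols = [c for c, a in enumerate(ref_row) if a != GAP]
    K = len(match_cols)
    if K < 1:
        raise InputError("reference row has no residues")

    if weighting == "henikoff" and len(rows) > 1:
        weights = _henikoff_weights(rows)
    else:
        weights = np.ones(len(rows))
    # total weight 1: observed counts are weighted frequencies, so profiles
    # are invariant under row duplication and the pseudocount weight has a
    # fixed meaning (1.0 ~ one column's worth of background observations)
    weights = weights / weights.sum()
    bg = _estimate_background(rows, weights)
    pc = float(pseudocount_weight)

    # node of each column: match column -> its k; insert column -> left node
    col_node = np.zeros(msa.n_columns, dtype=int)  # insert node per column
    is_match = np.zeros(msa.n_columns, dtype=bool)
    for k, c in enumerate(match_cols, start=1):
        is_match[c] = True
    node = 0
    match_k = np.zeros(msa.n_columns, dtype=int)
    for c in range(msa.n_columns):
        if is_match[c]:
            node += 1
            match_k[c] = node
        col_node[c] = node

    m_counts = np.zeros((K, _N))
    i_counts = np.zeros((K + 1, _N))
    # transition counts: rows follow the storage layout of ProfileHMM
    c_mm = np.zeros(K)
    c_mi = np.zeros(K)
    c_md = np.zeros(K)
    c_im = np.zeros(K)
    c_ii = np.zeros(K)
    c_dm = np.zeros(K)
    c_dd = np.zeros(K)

    for row, w in zip(rows, weights):
        prev = "B"          # 'B', 'M' or 'D'
        prev_k = 0
        pending_ins = 0     # insert residues since the last match column
        for c, a in enumerate(row):
            if is_match[c]:
                k = match_k[c]
                cur = "D" if a == GAP else "M"
                if cur == "M":
                    m_counts[k - 1, AA_INDEX[a]] += w
                if pending_ins and prev_k >= 1:
                    # prev -> I_{k-1}, I self-loops, then I -> M (I -> D has
                    # no Plan7 move and is not counted)
                    if prev == "M":
                        c_mi[prev_k] += w
                    c_ii[prev_k] += w * (pending_ins - 1)
                    if cur == "M":
                        c_im[prev_k] += w
                else:
                    if prev == "B" or prev == "M":
                        (c_mm if cur == "M" else c_md)[prev_k] += w
                    else:
                        (c_dm if cur == "M" else c_dd)[prev_k] += w
                prev = cur
                prev_k = k
                pending_ins = 0
            elif a != GAP:
                i_counts[col_node[c], AA_INDEX[a]] += w
                if 1 <= col_node[c] <= K - 1:
                    pending_ins += 1
                # node-0 / node-K insert residues are flank: emissions only

    def _mix(counts: np.ndarray, prior: np.ndarray) -> np.ndarray:
        total = counts.sum(axis=-1, keepdims=True)
        denom = total + pc
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (counts + pc * prior) / denom
        # rows with no data and no pseudocount fall back to the prior
        empty = (denom == 0).ravel()
        if np.any(empty):
            out[empty] = prior
        return out

    match_em = _mix(m_counts, bg)
    insert_em = _mix(i_counts, bg)

    def _trans(pairs: list[np.ndarray]) -> list[np.ndarray]:
        stack = np.stack(pairs, axis=-1)
        prior = np.full(stack.shape[-1], 1.0 / stack.shape[-1])
        return list(np.moveaxis(_mix(stack, prior), -1, 0))

    tmm = np.zeros(K)
    tmi = np.zeros(K)
    tmd = np.zeros(K)
    tim = np.zeros(K)
    tii = np.zeros(K)
    tdm = np.zeros(K)
    tdd = np.zeros(K)
    # begin node: two moves
    b = _trans([c_mm[[0]], c_md[[0]]])
    tmm[0], tmd[0] = b[0][0], b[1][0]
    if K > 1:
        m = _trans([c_mm[1:], c_mi[1:], c_md[1:]])
        tmm[1:], tmi[1:], tmd[1:] = m
        i = _trans([c_im[1:], c_ii[1:]])
        tim[1:], tii[1:] = i
        d = _trans([c_dm[1:], c_dd[1:]])
        tdm[1:], tdd[1:] = d

    profile = ProfileHMM(match_emissions=match_em, insert_emissions=insert_em,
                         tmm=tmm, tmi=tmi, tmd=tmd, tim=tim, tii=tii,
                         tdm=tdm, tdd=tdd, background=bg)
    if pc > 0:
        profile.validate()
    numbers = tuple(range(reference_start, reference_start + K))
    refmap = ReferenceMap(reference_id=reference_id,
                          reference_residues=ref_row.replace(GAP, ""),
                          standard_numbers=numbers)
    return profile, refmap


def viterbi_align(profile: ProfileHMM, seq: SequenceRecord) -> AlignedPath:
    """Best glocal state path for ``seq``, deterministic under ties
    (match preferred over delete over insert)."""
    if not seq.residues:
        raise InputError("cannot align an empty sequence")
    enc = encode(seq.residues)
    mat_lo, ins_lo, *trans = profile._scores()
    M, I, D, pM, pI, pD = _dp.viterbi_fill(enc, mat_lo, ins_lo, *trans)
    score, kinds, nodes, qidx, n, entry_i, exit_i = _dp.viterbi_traceback(
        M, I, D, pM, pI, pD, len(enc), profile.K)
    core = [
        PathStep(kind="MID"[kinds[j]], node=int(nodes[j]),
                 query_index=int(qidx[j]) if kinds[j] != 2 else None)
        for j in range(n)]
    # flanking query residues live in insert states 0 and K at zero log-odds
    flank_n = [PathStep(kind="I", node=0, query_index=i)
               for i in range(1, int(entry_i) + 1)]
    flank_c = [PathStep(kind="I", node=profile.K, query_index=i)
               for i in range(int(exit_i) + 1, len(enc) + 1)]
    return AlignedPath(steps=tuple(flank_n + core + flank_c),
                       score=float(score),
                       entry_index=int(entry_i), exit_index=int(exit_i))


def forward_score(profile: ProfileHMM, seq: SequenceRecord) -> float:
    """Log2-sum-of-paths score in bits; always >= the Viterbi score."""
    if not seq.residues:
        raise InputError("cannot score an empty sequence")
    enc = encode(seq.residues)
    mat_lo, ins_lo, *trans = profile._scores()
    return float(_dp.forward_score(enc, mat_lo, ins_lo, *trans))


def save_profile(profile: ProfileHMM, refmap: ReferenceMap, path) -> None:
    """Serialise profile + reference map as JSON with a parameter checksum."""
    doc = {
        "format": "thdpnum-profile",
        "version": _FORMAT_VERSION,
        "alphabet": ALPHABET,
        "K": profile.K,
        "checksum": profile.checksum,
        "match_emissions": profile.match_emissions.tolist(),
        "insert_emissions": profile.insert_emissions.tolist(),
        "transitions": {name: getattr(profile, name).tolist()
                        for name in ("tmm", "tmi", "tmd", "tim", "tii",
                                     "tdm", "tdd")},
        "background": profile.background.tolist(),
        "reference": {
            "id": refmap.reference_id,
            "residues": refmap.reference_residues,
            "standard_numbers": list(refmap.standard_numbers),
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_profile(path) -> tuple[ProfileHMM, ReferenceMap]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        doc = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as e:
        raise InputError(f"{path}: not a valid profile file ({e})") from e
    if not isinstance(doc, dict) or doc.get("format") != "thdpnum-profile":
        raise InputError(f"{path}: not a thdpnum profile file")
    if doc.get("version") != _FORMAT_VERSION:
        raise InputError(f"{path}: unsupported profile version "
                         f"{doc.get('version')!r}")
    if doc.get("alphabet") != ALPHABET:
        raise InputError(f"{path}: alphabet mismatch")
    try:
        tr = doc["transitions"]
        profile = ProfileHMM(
            match_emissions=np.asarray(doc["match_emissions"], dtype=float),
            insert_emissions=np.asarray(doc["insert_emissions"], dtype=float),
            tmm=np.asarray(tr["tmm"], dtype=float),
            tmi=np.asarray(tr["tmi"], dtype=float),
            tmd=np.asarray(tr["tmd"], dtype=float),
            tim=np.asarray(tr["tim"], dtype=float),
            tii=np.asarray(tr["tii"], dtype=float),
            tdm=np.asarray(tr["tdm"], dtype=float),
            tdd=np.asarray(tr["tdd"], dtype=float),
            background=np.asarray(doc["background"], dtype=float),
        )
        ref = doc["reference"]
        refmap = ReferenceMap(reference_id=ref["id"],
                              reference_residues=ref["residues"],
                              standard_numbers=tuple(ref["standard_numbers"]))
        stored = doc["checksum"]
    except (KeyError, TypeError, ValueError) as e:
        raise InputError(f"{path}: truncated or malformed profile ({e})") from e
    if profile.K != doc["K"] or refmap.n_match_states != profile.K:
        raise InputError(f"{path}: inconsistent profile dimensions")
    if profile.checksum != stored:
        raise InputError(f"{path}: checksum mismatch (file corrupted?)")
    return profile, refmap
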
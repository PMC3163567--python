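"""Quality-aware paired-end overlap merging with posterior consensus calls.

For a candidate insert length *L* the reverse complement of the reverse
read is aligned against the forward read so that both reads' adapters
would start at position *L*.  Two classes of positions are scored jointly:

* read-read overlap positions, weighted by ``min(q_fwd, q_rev)``;
* for ``L < read_len``, read positions past the insert compared against
  the expected adapter (then pad) sequence at the identical start
  position in both reads, weighted by the read base's own quality.

The identity of a candidate is the weighted match fraction over all
scored positions; ``N`` bases carry zero weight.  All candidates whose
read-read overlap reaches ``min_overlap`` — or that leave adapter
evidence, i.e. ``L < read_len`` — are evaluated; the highest-identity
candidate wins, with ties broken toward the smaller insert (more bases
explained by adapter).  Merging requires identity >= ``min_identity``
(default 0.90); winning inserts below ``min_merged_len`` (default 5) are
discarded as adapter dimers.

In the overlapping region each base is called by combining the two
observations into a posterior over the four bases (mismatching
observations are assigned likelihood ``eps/3`` for the three non-observed
bases, i.e. equal likelihood among them); the consensus quality is the
PHRED-scaled posterior error, truncated to an integer and capped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .error_model import N_CODE, decode, encode
from .seqio import ILLUMINA_PE_ADAPTER, ReadPair, ReadRecord

#: quality-0 (and N) observations are treated as uninformative: the error
#: probability is clamped at 3/4, the uniform limit.
EPS_MAX = 0.75


@dataclass
class MergeParams:
    """Merge thresholds and adapter context."""

    min_overlap: int = 11
    min_identity: float = 0.90
    min_merged_len: int = 5
    fwd_adapter: str = ILLUMINA_PE_ADAPTER
    rev_adapter: str = ILLUMINA_PE_ADAPTER
    qual_cap: int = 60
    pad_base: str = "A"

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must lie in (0, 1]")


@dataclass
class MergeResult:
    """Outcome of merging one pair."""

    status: str  # merged | unmerged | dimer
    merged: Optional[ReadRecord] = None
    insert_len: Optional[int] = None
    identity: Optional[float] = None
    overlap_len: Optional[int] = None


def _eps(q: np.ndarray) -> np.ndarray:
    return np.minimum(10.0 ** (-np.asarray(q, dtype=float) / 10.0), EPS_MAX)


def _likelihoods(codes: np.ndarray, q: np.ndarray) -> np.ndarray:
    """(n, 4) per-read likelihood P(obs | true base); N rows are uniform."""
    n = len(codes)
    eps = _eps(q)
    lik = np.repeat((eps / 3.0)[:, None], 4, axis=1)
    is_n = codes == N_CODE
    safe = np.where(is_n, 0, codes)
    lik[np.arange(n), safe] = 1.0 - eps
    lik[is_n] = 0.25
    return lik


def consensus_arrays(
    b1: np.ndarray,
    q1: np.ndarray,
    b2: np.ndarray,
    q2: np.ndarray,
    cap: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised posterior consensus over paired base observations.

    Returns ``(codes, quals)``.  Ties in the posterior argmax prefer the
    first read's base, then the second's, then alphabetical order.
    Positions where both observations are ``N`` emit ``N`` with quality 0.
    """
    b1 = np.asarray(b1)
    b2 = np.asarray(b2)
    n = len(b1)
    post = _likelihoods(b1, q1) * _likelihoods(b2, q2)
    total = post.sum(axis=1)
    total = np.where(total > 0, total, 1.0)
    post_n = post / total[:, None]
    best = post_n.max(axis=1)
    is_best = post_n == best[:, None]
    cidx = np.arange(4)[None, :]
    pref = np.where(
        is_best,
        40 * (cidx == b1[:, None]) + 20 * (cidx == b2[:, None]) + (3 - cidx),
        -1,
    )
    call = np.argmax(pref, axis=1)
    p_call = post_n[np.arange(n), call]
    err = np.maximum(1.0 - p_call, 1e-12)
    qual = np.floor(-10.0 * np.log10(err) + 1e-9).astype(np.int64)
    qual = np.clip(qual, 0, cap)
    both_n = (b1 == N_CODE) & (b2 == N_CODE)
    codes = np.where(both_n, N_CODE, call).astype(np.uint8)
    qual = np.where(both_n, 0, qual)
    return codes, qual


def consensus_base(
    b1: str, q1: int, b2: str, q2: int, cap: int = 60
) -> tuple[str, int]:
    """Consensus call for one position (scalar convenience wrapper)."""
    if q1 < 0 or q2 < 0:
        raise ValueError("qualities must be >= 0")
    c1 = encode(b1)
    c2 = encode(b2)
    codes, quals = consensus_arrays(c1, np.array([q1]), c2, np.array([q2]), cap=cap)
    return decode(codes), int(quals[0])


class _PairArrays:
    """Per-pair numeric views used by candidate scoring and consensus."""

    def __init__(self, pair: ReadPair, params: MergeParams):
        self.f = encode(pair.fwd.seq)
        self.qf = np.asarray(pair.fwd.qual, dtype=np.int64)
        rev_codes = encode(pair.rev.seq)
        self.r_orig = rev_codes
        self.qr_orig = np.asarray(pair.rev.qual, dtype=np.int64)
        comp = np.where(rev_codes == N_CODE, N_CODE, 3 - rev_codes).astype(np.uint8)
        self.rc = comp[::-1].copy()
        self.qrc = self.qr_orig[::-1].copy()
        self.n1 = len(self.f)
        self.n2 = len(rev_codes)
        self.expf = encode(
            (params.fwd_adapter + params.pad_base * self.n1)[: self.n1]
        )
        self.expr = encode(
            (params.rev_adapter + params.pad_base * self.n2)[: self.n2]
        )


def _adapter_sums(
    read: np.ndarray, wq: np.ndarray, expected: np.ndarray, n_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted match / weight totals of read[L:] vs expected[:] per L.

    Returns arrays indexed by candidate insert length L (length ``n_len``,
    zero outside 1 <= L < len(read)).
    """
    n = len(read)
    i = np.arange(n)[:, None]
    k = np.arange(n)[None, :]
    valid = k < i  # adapter index k = i - L with L >= 1
    eq = (read[:, None] == expected[None, :]) & valid
    w = np.broadcast_to(wq[:, None], (n, n))
    d = (i - k)[valid]
    num = np.bincount(d, weights=(w * eq)[valid], minlength=n_len)[:n_len]
    # weight denominator: all scored positions i >= L, matched or not
    den = np.zeros(n_len)
    suffix = np.concatenate([np.cumsum(wq[::-1])[::-1], [0.0]])
    upto = min(n, n_len)
    den[1:upto] = suffix[1:upto]
    return num, den


def _candidate_scores(
    arrs: _PairArrays, params: MergeParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Identity, overlap length and admissibility for every candidate L.

    Returned arrays are indexed by L over ``0..n1+n2-1`` (index 0 unused).
    """
    f, rc = arrs.f, arrs.rc
    n1, n2 = arrs.n1, arrs.n2
    wf = np.where(f == N_CODE, 0, arrs.qf)
    wrc = np.where(rc == N_CODE, 0, arrs.qrc)
    n_len = n1 + n2

    eq = (f[:, None] == rc[None, :]) & (f[:, None] != N_CODE)
    w = np.minimum(wf[:, None], wrc[None, :])
    d = (np.arange(n1)[:, None] - np.arange(n2)[None, :]) + n2  # == L
    num = np.bincount(d.ravel(), weights=(w * eq).ravel(), minlength=n_len)[:n_len]
    den = np.bincount(d.ravel(), weights=w.ravel().astype(float), minlength=n_len)[
        :n_len
    ]

    num_af, den_af = _adapter_sums(f, wf.astype(float), arrs.expf, n_len)
    wr = np.where(arrs.r_orig == N_CODE, 0, arrs.qr_orig)
    num_ar, den_ar = _adapter_sums(arrs.r_orig, wr.astype(float), arrs.expr, n_len)

    num_tot = num + num_af + num_ar
    den_tot = den + den_af + den_ar
    identity = np.where(den_tot > 0, num_tot / np.maximum(den_tot, 1e-300), 0.0)

    L = np.arange(n_len)
    overlap = np.minimum(n1, L) - np.maximum(0, L - n2)
    overlap = np.maximum(overlap, 0)
    admissible = (
        (L >= 1)
        & (L <= n1 + n2 - params.min_overlap)
        & ((overlap >= params.min_overlap) | (L < min(n1, n2)))
    )
    return identity, overlap, admissible


def score_candidate(
    pair: ReadPair, insert_len: int, params: MergeParams | None = None
) -> tuple[float, int]:
    """Quality-weighted identity and overlap length of one candidate."""
    params = params or MergeParams()
    arrs = _PairArrays(pair, params)
    if not (1 <= insert_len <= arrs.n1 + arrs.n2 - params.min_overlap):
        raise ValueError(
            f"insert_len {insert_len} outside "
            f"1..{arrs.n1 + arrs.n2 - params.min_overlap}"
        )
    identity, overlap, _ = _candidate_scores(arrs, params)
    return float(identity[insert_len]), int(overlap[insert_len])


def merge_pair(pair: ReadPair, params: MergeParams | None = None) -> MergeResult:
    """Merge one pair; see module docstring for the decision rule."""
    params = params or MergeParams()
    if not pair.fwd.seq or not pair.rev.seq:
        raise ValueError("reads must be non-empty")
    arrs = _PairArrays(pair, params)
    identity, overlap, admissible = _candidate_scores(arrs, params)
    if not admissible.any():
        return MergeResult(status="unmerged")
    masked = np.where(admissible, identity, -1.0)
    L = int(np.argmax(masked))  # exact ties resolve to the smaller insert
    best = float(identity[L])
    ov = int(overlap[L])
    if best < params.min_identity:
        return MergeResult(
            status="unmerged", identity=best, overlap_len=ov
        )
    if L < params.min_merged_len:
        return MergeResult(
            status="dimer", insert_len=L, identity=best, overlap_len=ov
        )
    merged = _build_consensus(arrs, L, params, pair.fwd.id)
    return MergeResult(
        status="merged",
        merged=merged,
        insert_len=L,
        identity=best,
        overlap_len=ov,
    )


def _build_consensus(
    arrs: _PairArrays, L: int, params: MergeParams, read_id: str
) -> ReadRecord:
    n1, n2 = arrs.n1, arrs.n2
    codes = np.empty(L, dtype=np.uint8)
    quals = np.empty(L, dtype=np.int64)
    lo = max(0, L - n2)  # overlap start (molecule coords)
    hi = min(n1, L)  # overlap end
    if lo > 0:  # forward-only prefix
        codes[:lo] = arrs.f[:lo]
        quals[:lo] = arrs.qf[:lo]
    if hi < L:  # reverse-only suffix
        j0 = hi - (L - n2)
        codes[hi:] = arrs.rc[j0 : j0 + (L - hi)]
        quals[hi:] = arrs.qrc[j0 : j0 + (L - hi)]
    if hi > lo:
        p = np.arange(lo, hi)
        j = p - (L - n2)
        cc, cq = consensus_arrays(
            arrs.f[p], arrs.qf[p], arrs.rc[j], arrs.qrc[j], cap=params.qual_cap
        )
        codes[lo:hi] = cc
        quals[lo:hi] = cq
    quals = np.clip(quals, 0, params.qual_cap)
    return ReadRecord(id=read_id, seq=decode(codes), qual=quals.tolist())
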
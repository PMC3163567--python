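"""Per-cycle, per-base sequencing error profiles and quality-score models.

An :class:`ErrorProfile` stores, for every sequencing cycle and every true
base, the substitution probability and the mean PHRED quality observed for
that base at that cycle.  Profiles drive the read simulator (error
injection) and can be *estimated* from reads whose true sequence is known
(e.g. a phiX-style spike-in), which is also how the simulator itself is
validated: estimating a profile from simulated reads must recover the
generating profile.

Two quality-score models are supported:

``position_average``
    every base of a given type at a given cycle carries that cell's mean
    quality, whether or not it is an error;

``error_informative``
    the mean quality plus a uniform jitter in ``{0..jitter_max}`` for
    correct bases, minus such a jitter for erroneous bases, so that low
    quality is informative about error.

Simulated qualities are clamped to ``[2, 41]``, emulating the platform's
printable quality range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binom

from .seqio import ReadRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_CODE = 4

SIM_QUAL_MIN = 2
SIM_QUAL_MAX = 41

# uint8 lookup: ASCII byte -> base code (A,C,G,T -> 0..3, N -> 4)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i
_CODE_LUT[ord("N")] = N_CODE
_CODE_LUT[ord("n")] = N_CODE

_BASE_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a base string as uint8 codes (A,C,G,T,N -> 0..4)."""
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError(f"invalid base in sequence {seq!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


@dataclass
class QualityModel:
    """Which of the two quality-score simulation schemes to use."""

    kind: str = "error_informative"
    jitter_max: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("position_average", "error_informative"):
            raise ValueError(f"unknown quality model {self.kind!r}")
        if self.jitter_max < 0:
            raise ValueError("jitter_max must be >= 0")


@dataclass
class ErrorProfile:
    """Per-cycle, per-true-base substitution rates and mean qualities.

    ``rate`` and ``mean_q`` are ``(n_cycles, 4)`` arrays indexed by
    0-based cycle and base code (A,C,G,T).
    """

    rate: np.ndarray
    mean_q: np.ndarray

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        self.mean_q = np.asarray(self.mean_q, dtype=float)
        if self.rate.ndim != 2 or self.rate.shape[1] != 4:
            raise ValueError("rate must have shape (n_cycles, 4)")
        if self.rate.shape != self.mean_q.shape:
            raise ValueError("rate and mean_q shapes differ")
        if np.isnan(self.rate).any() or ((self.rate < 0) | (self.rate > 1)).any():
            raise ValueError("rates must lie in [0, 1]")
        if ((self.mean_q < 0) | (self.mean_q > 60)).any():
            raise ValueError("mean qualities must lie in [0, 60]")

    @property
    def n_cycles(self) -> int:
        return self.rate.shape[0]


def make_synthetic_profile(
    n_cycles: int = 101,
    e_start: float = 0.001,
    e_end: float = 0.1,
    shape: str = "linear",
    seed: int = 0,
    base_multipliers: dict[str, float] | None = None,
) -> ErrorProfile:
    """Synthesise a profile whose error rate rises along the read.

    Emulates the typical run behaviour of sub-percent error in early cycles
    rising toward the final cycles.  ``shape`` is ``linear`` or
    ``exponential`` (geometric interpolation; requires ``e_start > 0``).
    ``mean_q`` is ``round(-10*log10(rate))`` clamped to ``[2, 41]`` and is
    identical across bases unless ``base_multipliers`` scales individual
    true bases.  The synthesis is deterministic; ``seed`` is accepted for
    interface symmetry with the stochastic operations.
    """
    if not (0.0 <= e_start <= e_end <= 0.5):
        raise ValueError("need 0 <= e_start <= e_end <= 0.5")
    if n_cycles < 1:
        raise ValueError("n_cycles must be positive")
    if shape == "linear":
        r = np.linspace(e_start, e_end, n_cycles)
    elif shape == "exponential":
        if e_start <= 0:
            raise ValueError("exponential shape requires e_start > 0")
        r = np.geomspace(e_start, e_end, n_cycles)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    rate = np.repeat(r[:, None], 4, axis=1)
    if base_multipliers:
        for b, m in base_multipliers.items():
            rate[:, BASE_INDEX[b]] *= m
        rate = np.clip(rate, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        q = np.round(-10.0 * np.log10(np.where(rate > 0, rate, np.nan)))
    mean_q = np.clip(np.nan_to_num(q, nan=SIM_QUAL_MAX), SIM_QUAL_MIN, SIM_QUAL_MAX)
    return ErrorProfile(rate=rate, mean_q=mean_q)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def apply_errors_batch(
    truth_codes: np.ndarray,
    profile: ErrorProfile,
    model: QualityModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised error injection on a ``(n_reads, read_len)`` code matrix.

    Returns ``(observed_codes, qualities)``.  Each base is substituted
    independently with the profile rate for its (cycle, true base) cell;
    the substituted base is uniform over the three alternatives.  ``N``
    truth bases are passed through unchanged with quality ``SIM_QUAL_MIN``.
    """
    truth_codes = np.atleast_2d(truth_codes)
    n, L = truth_codes.shape
    if L > profile.n_cycles:
        raise ValueError(
            f"read length {L} exceeds profile cycles {profile.n_cycles}"
        )
    is_n = truth_codes == N_CODE
    safe = np.where(is_n, 0, truth_codes)
    cyc = np.arange(L)
    r = profile.rate[cyc[None, :], safe]
    err = (rng.random((n, L)) < r) & ~is_n
    shift = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
    obs = np.where(err, (safe + shift) % 4, truth_codes).astype(np.uint8)

    mq = np.round(profile.mean_q[cyc[None, :], safe]).astype(np.int64)
    if model.kind == "position_average":
        qual = mq
    else:
        jit = rng.integers(0, model.jitter_max + 1, size=(n, L))
        qual = mq + np.where(err, -jit, jit)
    qual = np.clip(qual, SIM_QUAL_MIN, SIM_QUAL_MAX)
    qual = np.where(is_n, SIM_QUAL_MIN, qual)
    return obs, qual


def apply_errors(
    truth: str,
    profile: ErrorProfile,
    model: QualityModel,
    seed: int | np.random.Generator = 0,
    read_id: str = "sim",
) -> ReadRecord:
    """Simulate one observed read from a true sequence (see batch variant)."""
    codes = encode(truth)
    obs, qual = apply_errors_batch(codes[None, :], profile, model, _rng(seed))
    return ReadRecord(id=read_id, seq=decode(obs[0]), qual=qual[0].tolist())


def assign_quality(
    true_base: str,
    cycle: int,
    was_error: bool,
    profile: ErrorProfile,
    model: QualityModel,
    rng: np.random.Generator,
) -> int:
    """Quality score for a single simulated base (1-based ``cycle``)."""
    if not (1 <= cycle <= profile.n_cycles):
        raise ValueError(f"cycle {cycle} outside 1..{profile.n_cycles}")
    mq = int(round(profile.mean_q[cycle - 1, BASE_INDEX[true_base]]))
    if model.kind == "position_average":
        q = mq
    else:
        jit = int(rng.integers(0, model.jitter_max + 1))
        q = mq - jit if was_error else mq + jit
    return int(np.clip(q, SIM_QUAL_MIN, SIM_QUAL_MAX))


def build_profile_from_truth(
    pairs: Iterable[tuple[ReadRecord, str]],
) -> ErrorProfile:
    """Estimate an :class:`ErrorProfile` from (observed read, true sequence).

    ``rate[c][b]`` is mismatches / opportunities for true base ``b`` at
    cycle ``c`` (0 where no opportunities); ``mean_q[c][b]`` the mean
    observed quality of those positions.  All pairs must share one length.
    """
    mism = None
    opp = None
    qsum = None
    L = None
    for i, (obs, truth) in enumerate(pairs):
        if len(obs.seq) != len(truth):
            raise ValueError(
                f"pair {i} ({obs.id!r}): observed length {len(obs.seq)} != "
                f"truth length {len(truth)}"
            )
        if L is None:
            L = len(truth)
            mism = np.zeros((L, 4), dtype=np.int64)
            opp = np.zeros((L, 4), dtype=np.int64)
            qsum = np.zeros((L, 4), dtype=np.float64)
        elif len(truth) != L:
            raise ValueError(f"pair {i}: length {len(truth)} != first pair's {L}")
        t = encode(truth)
        o = encode(obs.seq)
        q = np.asarray(obs.qual, dtype=float)
        valid = t != N_CODE
        cyc = np.flatnonzero(valid)
        tb = t[cyc]
        np.add.at(opp, (cyc, tb), 1)
        np.add.at(qsum, (cyc, tb), q[cyc])
        bad = valid & (o != t)
        cycb = np.flatnonzero(bad)
        np.add.at(mism, (cycb, t[cycb]), 1)
    if L is None:
        raise ValueError("empty input stream")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(opp > 0, mism / np.maximum(opp, 1), 0.0)
        mean_q = np.where(opp > 0, qsum / np.maximum(opp, 1), 0.0)
    return ErrorProfile(rate=rate, mean_q=mean_q)


def error_count_spectrum(
    pairs: Iterable[tuple[ReadRecord, str]],
    max_k: int = 5,
) -> pd.DataFrame:
    """Per-read error-count spectrum versus the independence expectation.

    For each read the number of mismatches against its true sequence is
    counted.  ``observed_fraction(k)`` is the fraction of reads with
    exactly ``k`` mismatches (``k = 0..max_k``).  ``expected_fraction(k)``
    extrapolates from the one-error fraction under independence: a
    per-base error probability ``p`` is solved from the observed ``P(1)``
    at read length ``L`` assuming ``Binomial(L, p)``, and the expected
    fractions are the binomial masses.  When errors cluster in a subset of
    reads (mixed clusters), observed ``P(>=2)`` exceeds this expectation.
    """
    counts: list[int] = []
    L = None
    for i, (obs, truth) in enumerate(pairs):
        if len(obs.seq) != len(truth):
            raise ValueError(f"pair {i}: observed/truth length mismatch")
        if L is None:
            L = len(truth)
        elif len(truth) != L:
            raise ValueError(f"pair {i}: length {len(truth)} != first pair's {L}")
        t = encode(truth)
        o = encode(obs.seq)
        counts.append(int(np.sum((o != t) & (t != N_CODE))))
    if not counts:
        raise ValueError("empty input stream")
    k_arr = np.arange(max_k + 1)
    counts_arr = np.asarray(counts)
    observed = np.array([(counts_arr == k).mean() for k in k_arr])

    p1 = observed[1] if max_k >= 1 else 0.0
    p = _solve_p_from_one_error(p1, L)
    expected = binom.pmf(k_arr, L, p)
    return pd.DataFrame(
        {"k": k_arr, "observed_fraction": observed, "expected_fraction": expected}
    )


def _solve_p_from_one_error(p1: float, L: int) -> float:
    """Solve ``L*p*(1-p)**(L-1) == p1`` for ``p`` on ``[0, 1/L]``.

    The one-error mass is increasing in ``p`` on that interval; a ``p1``
    above the attainable maximum clamps to ``1/L``.
    """
    if p1 <= 0:
        return 0.0
    p_max = 1.0 / L
    f = lambda p: L * p * (1.0 - p) ** (L - 1) - p1
    if f(p_max) <= 0:
        return p_max
    return float(brentq(f, 0.0, p_max))


PROFILE_COLUMNS = ["cycle", "base", "rate", "mean_q"]


def save_profile(profile: ErrorProfile, path: str | Path) -> None:
    """Write a profile as TSV with columns ``cycle base rate mean_q``."""
    rows = []
    for c in range(profile.n_cycles):
        for b in BASES:
            i = BASE_INDEX[b]
            rows.append((c + 1, b, profile.rate[c, i], profile.mean_q[c, i]))
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_profile(path: str | Path) -> ErrorProfile:
    """Read a profile TSV written by :func:`save_profile` (validated)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != PROFILE_COLUMNS:
        raise ValueError(f"profile {path}: expected columns {PROFILE_COLUMNS}")
    n_cycles = int(df["cycle"].max())
    if set(df["base"]) - set(BASES):
        raise ValueError(f"profile {path}: unknown base symbols")
    if len(df) != n_cycles * 4:
        raise ValueError(
            f"profile {path}: expected {n_cycles * 4} rows "
            f"(cycles 1..{n_cycles} x 4 bases), found {len(df)}"
        )
    rate = np.zeros((n_cycles, 4))
    mean_q = np.zeros((n_cycles, 4))
    seen = np.zeros((n_cycles, 4), dtype=bool)
    for row in df.itertuples(index=False):
        c = int(row.cycle) - 1
        if not (0 <= c < n_cycles):
            raise ValueError(f"profile {path}: cycle {row.cycle} out of range")
        b = BASE_INDEX[row.base]
        rate[c, b] = row.rate
        mean_q[c, b] = row.mean_q
        seen[c, b] = True
    if not seen.all():
        missing = np.argwhere(~seen)[0]
        raise ValueError(
            f"profile {path}: missing row for cycle {missing[0] + 1}, "
            f"base {BASES[missing[1]]}"
        )
    return ErrorProfile(rate=rate, mean_q=mean_q)
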
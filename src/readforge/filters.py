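"""Read-level quality-control filters.

Implements the screens recommended for Illumina-style data:

* **entropy** — removes low-complexity reads (crystals, dust, lint picked
  up as clusters) whose mononucleotide Shannon entropy, normalised by the
  2-bit maximum, falls below a cutoff (default 0.85);
* **quality** — whole-read filter: at most one base below Q15 allowed per
  20 cycles (the allowance is ``floor(len/20)``);
* **chastity** — signal-purity filter on per-cycle channel intensities:
  the called channel must be at least 1.5x the next highest, over the
  first 12 cycles with no outlier (or 25 cycles allowing one);
* **tag** — library-tag prefix match tolerating a configurable number of
  substitutions (default 1, i.e. the tag and its one-base substitutions);
* **chimera** — an ungapped oligo screen flagging reads largely explained
  by adapter/primer oligos or ordered junctions of two of them (inspired
  by TagDust's use case; not a TagDust reimplementation).

``filter_stream`` composes the configured filters in order, short-
circuiting at the first failure and reporting per-read verdicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .error_model import N_CODE, encode
from .seqio import ReadRecord, revcomp


@dataclass
class FilterConfig:
    entropy_cutoff: float = 0.85
    qual_cutoff: int = 15
    outlier_window: int = 20
    chastity_ratio: float = 1.5
    chastity_cycles: int = 12
    chastity_outliers: int = 0  # preset variant: 25 cycles / 1 outlier
    tag: Optional[str] = None
    tag_mismatch: int = 1
    oligos: Sequence[str] = field(default_factory=tuple)
    chimera_min_cov: float = 0.8
    chimera_min_identity: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.entropy_cutoff <= 1.0):
            raise ValueError("entropy_cutoff must lie in [0, 1]")
        for name in ("qual_cutoff", "outlier_window", "chastity_cycles",
                     "chastity_outliers", "tag_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FilterVerdict:
    read_id: str
    passed: bool
    failed_filter: Optional[str] = None
    statistic: Optional[float] = None


def shannon_entropy(seq: str) -> float:
    """Mononucleotide Shannon entropy of ``seq`` in units of the 2-bit max.

    ``N`` bases are excluded from the counts; an all-``N`` (or empty-after-
    exclusion) sequence has entropy 0.
    """
    if not seq:
        raise ValueError("empty sequence")
    codes = encode(seq)
    counts = np.bincount(codes[codes != N_CODE], minlength=4)[:4]
    total = counts.sum()
    if total == 0:
        return 0.0
    freqs = counts[counts > 0] / total
    return float(-(freqs * np.log2(freqs)).sum() / 2.0)


def quality_pass(qual: Sequence[int], cfg: FilterConfig | None = None) -> bool:
    """Whole-read quality filter: low-quality outliers within allowance.

    Passes iff the number of bases below ``qual_cutoff`` is at most
    ``floor(len / outlier_window)``.
    """
    cfg = cfg or FilterConfig()
    q = np.asarray(qual)
    if q.size == 0:
        raise ValueError("empty quality list")
    allowance = len(q) // cfg.outlier_window
    return int((q < cfg.qual_cutoff).sum()) <= allowance


def tag_distance(seq: str, cfg: FilterConfig) -> float:
    """Hamming distance of the read prefix to the configured tag.

    Reads shorter than the tag get ``inf`` (a distinct failing statistic).
    """
    if cfg.tag is None:
        raise ValueError("no tag configured")
    tag = cfg.tag.upper()
    if len(seq) < len(tag):
        return math.inf
    prefix = seq[: len(tag)].upper()
    return float(sum(a != b for a, b in zip(prefix, tag)))


def tag_match(seq: str, cfg: FilterConfig) -> bool:
    """Pass iff the read prefix is within ``tag_mismatch`` of the tag."""
    return tag_distance(seq, cfg) <= cfg.tag_mismatch


def chastity_pass(
    intensities: np.ndarray, cfg: FilterConfig | None = None
) -> bool:
    """Signal-purity filter on a ``(cycles, 4)`` intensity matrix (A,C,G,T).

    A cycle passes when the called (highest) channel is at least
    ``chastity_ratio`` times the next highest (a zero runner-up passes iff
    the maximum is positive).  The read passes when at most
    ``chastity_outliers`` of the first ``chastity_cycles`` cycles fail.
    """
    cfg = cfg or FilterConfig()
    inten = np.asarray(intensities, dtype=float)
    if inten.ndim != 2 or inten.shape[1] != 4:
        raise ValueError("intensities must have shape (cycles, 4)")
    if (inten < 0).any():
        raise ValueError("negative intensity")
    if inten.shape[0] < cfg.chastity_cycles:
        raise ValueError(
            f"need >= {cfg.chastity_cycles} cycles, got {inten.shape[0]}"
        )
    head = inten[: cfg.chastity_cycles]
    part = np.sort(head, axis=1)
    i_max = part[:, -1]
    i_next = part[:, -2]
    ok = np.where(
        i_next > 0, i_max >= cfg.chastity_ratio * i_next, i_max > 0
    )
    return int((~ok).sum()) <= cfg.chastity_outliers


class ChimeraScreen:
    """Ungapped oligo / oligo-junction screen (built once, applied per read).

    A read is flagged when some single oligo, or an ordered junction of two
    oligos (each in either orientation), can be placed ungapped — one
    segment per side of a split point — so that the aligned positions
    cover at least ``chimera_min_cov`` of the read at per-aligned-base
    identity >= ``chimera_min_identity``.  The per-side placement uses the
    shift maximising ``matches - min_identity * aligned``, a screen-grade
    heuristic rather than an exhaustive joint optimum.
    """

    def __init__(self, cfg: FilterConfig):
        if not cfg.oligos:
            raise ValueError("empty oligo list")
        self.cfg = cfg
        self.variants: list[tuple[str, np.ndarray]] = []
        for i, o in enumerate(cfg.oligos):
            o = o.upper()
            self.variants.append((f"oligo{i + 1}+", encode(o)))
            self.variants.append((f"oligo{i + 1}-", encode(revcomp(o))))

    def _side_tables(
        self, read: np.ndarray, oligo: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-shift cumulative matches/aligned tables along the read."""
        L = len(read)
        m = len(oligo)
        shifts = np.arange(-(m - 1), L)  # read index i aligns oligo index i-shift
        i = np.arange(L)[None, :]
        j = i - shifts[:, None]
        valid = (j >= 0) & (j < m)
        jc = np.clip(j, 0, m - 1)
        match = (read[None, :] == oligo[jc]) & valid & (read[None, :] != N_CODE)
        cm = np.concatenate(
            [np.zeros((len(shifts), 1)), np.cumsum(match, axis=1)], axis=1
        )
        ca = np.concatenate(
            [np.zeros((len(shifts), 1)), np.cumsum(valid, axis=1)], axis=1
        )
        return cm, ca, cm[:, -1:] - cm, ca[:, -1:] - ca

    def flag(self, seq: str) -> tuple[bool, Optional[str], float, float]:
        """Screen one read; returns (flagged, label, coverage, identity)."""
        read = encode(seq.upper())
        L = len(read)
        cfg = self.cfg
        min_id = cfg.chimera_min_identity
        need_cov = cfg.chimera_min_cov * L
        best = (False, None, 0.0, 0.0)
        best_score = -math.inf

        prefix: list[tuple[np.ndarray, np.ndarray]] = []
        suffix: list[tuple[np.ndarray, np.ndarray]] = []
        singles: list[tuple[float, float]] = []
        for _, oligo in self.variants:
            cm, ca, sm, sa = self._side_tables(read, oligo)
            score = cm - min_id * ca
            k = np.argmax(score, axis=0)
            cols = np.arange(L + 1)
            prefix.append((cm[k, cols], ca[k, cols]))
            score_s = sm - min_id * sa
            ks = np.argmax(score_s, axis=0)
            suffix.append((sm[ks, cols], sa[ks, cols]))
            # single-oligo placement: full-read columns
            full_m = cm[:, -1]
            full_a = ca[:, -1]
            bi = int(np.argmax(full_m - min_id * full_a))
            singles.append((float(full_m[bi]), float(full_a[bi])))

        for vi, (label, _) in enumerate(self.variants):
            m_, a_ = singles[vi]
            if a_ >= need_cov and a_ > 0 and m_ / a_ >= min_id:
                score = m_ - min_id * a_
                if score > best_score:
                    best_score = score
                    best = (True, label, a_ / L, m_ / a_)

        for ai, (la, _) in enumerate(self.variants):
            pm, pa = prefix[ai]
            for bi_, (lb, _) in enumerate(self.variants):
                sm_, sa_ = suffix[bi_]
                tm = pm + sm_
                ta = pa + sa_
                with np.errstate(invalid="ignore", divide="ignore"):
                    ident = np.where(ta > 0, tm / np.maximum(ta, 1), 0.0)
                ok = (ta >= need_cov) & (ident >= min_id)
                # splits at 1..L-1 are true junctions
                ok[0] = ok[-1] = False
                if ok.any():
                    s = int(np.argmax(np.where(ok, tm - min_id * ta, -math.inf)))
                    score = float(tm[s] - min_id * ta[s])
                    if score > best_score:
                        best_score = score
                        best = (True, f"{la}|{lb}", float(ta[s]) / L, float(ident[s]))
        return best


def chimera_flag(
    read: ReadRecord | str,
    cfg: FilterConfig,
    screen: ChimeraScreen | None = None,
) -> tuple[bool, Optional[str]]:
    """Flag a read as adapter/primer chimera (see :class:`ChimeraScreen`)."""
    screen = screen or ChimeraScreen(cfg)
    seq = read if isinstance(read, str) else read.seq
    flagged, label, _, _ = screen.flag(seq)
    return flagged, label


DEFAULT_ORDER = ("tag", "chimera", "entropy", "quality")


def filter_stream(
    reads: Iterable[ReadRecord],
    cfg: FilterConfig,
    order: Sequence[str] = DEFAULT_ORDER,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Apply the configured filters in order with short-circuit fail.

    Filters without configuration (no tag, no oligos) are skipped.
    Returns the passing reads and a per-read verdict table with columns
    ``read_id, passed, failed_filter, statistic``.
    """
    known = {"tag", "chimera", "entropy", "quality"}
    unknown = set(order) - known
    if unknown:
        raise ValueError(f"unknown filter name(s): {sorted(unknown)}")
    active = []
    for name in order:
        if name == "tag" and cfg.tag is None:
            continue
        if name == "chimera" and not cfg.oligos:
            continue
        active.append(name)
    screen = ChimeraScreen(cfg) if "chimera" in active else None

    passing: list[ReadRecord] = []
    rows: list[FilterVerdict] = []
    for rec in reads:
        verdict = FilterVerdict(read_id=rec.id, passed=True)
        for name in active:
            if name == "tag":
                stat = tag_distance(rec.seq, cfg)
                if stat > cfg.tag_mismatch:
                    verdict = FilterVerdict(rec.id, False, "tag", stat)
                    break
            elif name == "chimera":
                flagged, _, cov, _ = screen.flag(rec.seq)
                if flagged:
                    verdict = FilterVerdict(rec.id, False, "chimera", cov)
                    break
            elif name == "entropy":
                ent = shannon_entropy(rec.seq)
                if ent < cfg.entropy_cutoff:
                    verdict = FilterVerdict(rec.id, False, "entropy", ent)
                    break
            elif name == "quality":
                n_low = int((np.asarray(rec.qual) < cfg.qual_cutoff).sum())
                if not quality_pass(rec.qual, cfg):
                    verdict = FilterVerdict(rec.id, False, "quality", float(n_low))
                    break
        if verdict.passed:
            passing.append(rec)
        rows.append(verdict)
    table = pd.DataFrame(
        [
            (v.read_id, v.passed, v.failed_filter, v.statistic)
            for v in rows
        ],
        columns=["read_id", "passed", "failed_filter", "statistic"],
    )
    return passing, table


def summarize_verdicts(table: pd.DataFrame) -> pd.DataFrame:
    """Counts per outcome: one row per failing filter plus ``pass``."""
    label = table["failed_filter"].fillna("pass")
    out = label.value_counts().rename_axis("outcome").reset_index(name="count")
    return out.sort_values("outcome").reset_index(drop=True)
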
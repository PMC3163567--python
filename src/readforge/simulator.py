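"""Paired-end shotgun read simulator with an adapter-start sweep.

The simulator emulates a paired-end sequencing experiment over a sweep of
insert sizes: fixed-length windows are sampled from a reference, each
window is trimmed to every insert length in a configured range, both
library adapters are appended (and the molecule A-padded when adapter plus
insert still fall short of the read length), and a per-cycle error profile
injects substitution errors with model-driven quality scores.  With the
defaults (10,000 windows x insert lengths 1..350 at 2x101 cycles) one run
yields 3,500,000 read pairs, ten thousand for every adapter start point.

Each read name encodes its provenance as ``contig:start-end:strand:insert``
so that any mapper's SAM output can be scored against the truth without a
side file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

from . import seqio
from .error_model import (
    ErrorProfile,
    QualityModel,
    apply_errors_batch,
    encode,
    N_CODE,
    _BASE_BYTES,
)
from .seqio import ILLUMINA_PE_ADAPTER, open_text, revcomp

DEFAULT_ADAPTER = ILLUMINA_PE_ADAPTER


@dataclass
class SimConfig:
    """Parameters of one simulated run (see module docstring for defaults)."""

    n_windows: int = 10_000
    window_len: int = 350
    read_len: int = 101
    min_contig: int = 1_000_000
    fwd_adapter: str = DEFAULT_ADAPTER
    rev_adapter: str = DEFAULT_ADAPTER
    pad_base: str = "A"
    insert_min: int = 1
    insert_max: int = 350
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fwd_adapter or not self.rev_adapter:
            raise ValueError("adapters must be non-empty")
        if not (1 <= self.insert_min <= self.insert_max <= self.window_len):
            raise ValueError(
                "need 1 <= insert_min <= insert_max <= window_len"
            )
        if self.pad_base not in "ACGT":
            raise ValueError("pad_base must be one of A,C,G,T")

    @property
    def inserts(self) -> range:
        """Inclusive 1-based insert-length (adapter start) sweep."""
        return range(self.insert_min, self.insert_max + 1)


@dataclass(frozen=True)
class SimTruth:
    """Provenance of a simulated pair: source window and insert length."""

    contig: str
    start: int  # 0-based half-open window coordinates
    end: int
    strand: str
    insert_len: int

    def name(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}:{self.strand}:{self.insert_len}"


def generate_reference(
    path: str | Path,
    n_contigs: int = 1,
    contig_len: int = 2_000_000,
    gc: float = 0.41,
    seed: int = 0,
    line_width: int = 70,
) -> Path:
    """Write a synthetic FASTA reference of i.i.d. bases at GC fraction ``gc``.

    A stand-in for a real genome assembly when none is at hand; contigs are
    named ``c1..cN``.  Deterministic under ``seed``.
    """
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    path = Path(path)
    with open_text(path, "wt") as out:
        for i in range(n_contigs):
            out.write(f">c{i + 1}\n")
            codes = rng.choice(4, size=contig_len, p=probs).astype(np.uint8)
            seq = _BASE_BYTES[codes].tobytes().decode("ascii")
            for j in range(0, contig_len, line_width):
                out.write(seq[j : j + line_width])
                out.write("\n")
    return path


def _load_reference(
    reference: str | Path | Iterable[tuple[str, str]],
) -> list[tuple[str, str]]:
    if isinstance(reference, (str, Path)):
        return list(seqio.read_fasta(reference))
    return list(reference)


def sample_windows(
    reference: str | Path | Iterable[tuple[str, str]],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[SimTruth, str]]:
    """Sample ``cfg.n_windows`` N-free windows of ``cfg.window_len`` bases.

    Only contigs of at least ``cfg.min_contig`` bases are eligible; windows
    are drawn uniformly with replacement over all N-free start positions
    pooled across eligible contigs.  Raises ``ValueError`` when no eligible
    window exists.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    contigs = _load_reference(reference)
    names: list[str] = []
    seqs: list[str] = []
    starts: list[np.ndarray] = []
    counts: list[int] = []
    for name, seq in contigs:
        if len(seq) < cfg.min_contig or len(seq) < cfg.window_len:
            continue
        codes = encode(seq)
        is_n = (codes == N_CODE).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(is_n)])
        n_starts = len(seq) - cfg.window_len + 1
        s = np.arange(n_starts)
        ok = (cum[s + cfg.window_len] - cum[s]) == 0
        eligible = np.flatnonzero(ok)
        if eligible.size:
            names.append(name)
            seqs.append(seq)
            starts.append(eligible)
            counts.append(eligible.size)
    total = int(sum(counts))
    if total == 0:
        raise ValueError(
            f"no contig of >= {cfg.min_contig} bases with an N-free "
            f"{cfg.window_len} nt window"
        )
    offsets = np.concatenate([[0], np.cumsum(counts)])
    draws = rng.integers(0, total, size=cfg.n_windows)
    out: list[tuple[SimTruth, str]] = []
    for d in draws:
        ci = int(np.searchsorted(offsets, d, side="right") - 1)
        pos = int(starts[ci][d - offsets[ci]])
        window = seqs[ci][pos : pos + cfg.window_len]
        truth = SimTruth(
            contig=names[ci],
            start=pos,
            end=pos + cfg.window_len,
            strand="+",
            insert_len=0,
        )
        out.append((truth, window))
    return out


def make_pair(window: str, insert_len: int, cfg: SimConfig) -> tuple[str, str]:
    """Error-free forward/reverse read sequences for one molecule.

    The molecule is the first ``insert_len`` bases of the window; each read
    is molecule (reverse-complemented for the reverse read) followed by its
    adapter and, if still short of ``read_len``, a run of ``pad_base``.
    """
    if not (1 <= insert_len <= len(window)):
        raise ValueError(
            f"insert_len {insert_len} outside 1..{len(window)}"
        )
    mol = window[:insert_len]
    pad_n = max(0, cfg.read_len - insert_len - len(cfg.fwd_adapter))
    fwd = (mol + cfg.fwd_adapter + cfg.pad_base * pad_n)[: cfg.read_len]
    pad_n = max(0, cfg.read_len - insert_len - len(cfg.rev_adapter))
    rev = (revcomp(mol) + cfg.rev_adapter + cfg.pad_base * pad_n)[: cfg.read_len]
    return fwd, rev


def _truth_matrices(
    window_codes: np.ndarray,
    inserts: np.ndarray,
    cfg: SimConfig,
    apf: np.ndarray,
    apr: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ``make_pair`` over all insert lengths of one window."""
    R = cfg.read_len
    j = np.arange(R)[None, :]
    L = inserts[:, None]
    widx = np.minimum(j, len(window_codes) - 1)
    aidx = np.clip(j - L, 0, len(apf) - 1)
    fwd = np.where(j < L, window_codes[widx], apf[aidx])
    comp = (3 - window_codes).astype(np.uint8)  # windows are N-free
    ridx = np.clip(L - 1 - j, 0, len(window_codes) - 1)
    aidx_r = np.clip(j - L, 0, len(apr) - 1)
    rev = np.where(j < L, comp[ridx], apr[aidx_r])
    return fwd.astype(np.uint8), rev.astype(np.uint8)


def _write_batch(
    handle: IO[bytes] | None,
    names: Sequence[str],
    codes: np.ndarray,
    quals: np.ndarray,
) -> None:
    if handle is None:
        return
    seq_bytes = _BASE_BYTES[codes]
    qual_bytes = (quals + 33).astype(np.uint8)
    parts: list[bytes] = []
    for i, name in enumerate(names):
        parts.append(b"@" + name.encode("ascii") + b"\n")
        parts.append(seq_bytes[i].tobytes())
        parts.append(b"\n+\n")
        parts.append(qual_bytes[i].tobytes())
        parts.append(b"\n")
    handle.write(b"".join(parts))


class _DeterministicGzipWriter:
    """Gzip writer with zeroed mtime so identical runs are byte-identical."""

    def __init__(self, path: Path):
        import gzip

        self._raw = open(path, "wb")
        self._gz = gzip.GzipFile(filename="", mode="wb", fileobj=self._raw, mtime=0)

    def write(self, data: bytes) -> int:
        return self._gz.write(data)

    def close(self) -> None:
        self._gz.close()
        self._raw.close()


def _open_binary(path: str | Path | None):
    if path is None:
        return None
    path = Path(path)
    if path.suffix == ".gz":
        return _DeterministicGzipWriter(path)
    return open(path, "wb")


def simulate_run(
    reference: str | Path | Iterable[tuple[str, str]],
    profile: ErrorProfile,
    model: QualityModel,
    cfg: SimConfig,
    out_fwd: str | Path | None,
    out_rev: str | Path | None,
) -> int:
    """Run the full sweep; returns the number of pairs emitted.

    For every sampled window and every insert length in ``cfg.inserts`` one
    pair is pushed through the error model, so the pair count is always
    ``n_windows * len(inserts)``.  ``out_fwd``/``out_rev`` may be ``None``
    to generate (and count) without writing FASTQ.
    """
    if cfg.read_len > profile.n_cycles:
        raise ValueError(
            f"read_len {cfg.read_len} exceeds profile cycles {profile.n_cycles}"
        )
    rng = np.random.default_rng(cfg.seed)
    windows = sample_windows(reference, cfg, rng=rng)
    inserts = np.asarray(list(cfg.inserts))
    apf = encode(cfg.fwd_adapter + cfg.pad_base * cfg.read_len)
    apr = encode(cfg.rev_adapter + cfg.pad_base * cfg.read_len)
    n_pairs = 0
    h_fwd = _open_binary(out_fwd)
    h_rev = _open_binary(out_rev)
    try:
        for truth, window in windows:
            wcodes = encode(window)
            fwd_t, rev_t = _truth_matrices(wcodes, inserts, cfg, apf, apr)
            fwd_o, fwd_q = apply_errors_batch(fwd_t, profile, model, rng)
            rev_o, rev_q = apply_errors_batch(rev_t, profile, model, rng)
            names = [
                f"{truth.contig}:{truth.start}-{truth.end}:{truth.strand}:{L}"
                for L in inserts
            ]
            _write_batch(h_fwd, names, fwd_o, fwd_q)
            _write_batch(h_rev, names, rev_o, rev_q)
            n_pairs += len(inserts)
    finally:
        if h_fwd is not None:
            h_fwd.close()
        if h_rev is not None:
            h_rev.close()
    return n_pairs
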
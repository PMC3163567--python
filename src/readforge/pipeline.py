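"""End-to-end helpers: seeded stage composition, merge-error experiment,
echo-SAM generation and the demo pipeline.

Everything here is deterministic under a single global seed that is split
per stage, so whole-pipeline runs reproduce bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from . import __version__
from .error_model import (
    ErrorProfile,
    QualityModel,
    apply_errors_batch,
    decode,
    encode,
    make_synthetic_profile,
    save_profile,
)
from .filters import FilterConfig, filter_stream, summarize_verdicts
from .mapping_eval import EvalConfig, evaluate_alignments
from .merger import MergeParams, MergeResult, merge_pair
from .seqio import ReadPair, ReadRecord, write_fastq
from .simulator import (
    SimConfig,
    SimTruth,
    _truth_matrices,
    generate_reference,
    sample_windows,
    simulate_run,
)


def derive_seed(seed: int, label: str) -> int:
    """Deterministically split a global seed per pipeline stage (< 2^31)."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_pairs_in_memory(
    reference: str | Path | Iterable[tuple[str, str]],
    profile: ErrorProfile,
    model: QualityModel,
    cfg: SimConfig,
) -> tuple[list[SimTruth], list[str], list[ReadPair]]:
    """Simulate pairs without touching disk; returns truths, molecules, pairs.

    One pair per (window, insert length), exactly as :func:`simulate_run`
    emits them, but kept in memory together with the true molecule so
    downstream error rates can be measured directly.
    """
    rng = np.random.default_rng(cfg.seed)
    windows = sample_windows(reference, cfg, rng=rng)
    inserts = np.asarray(list(cfg.inserts))
    apf = encode(cfg.fwd_adapter + cfg.pad_base * cfg.read_len)
    apr = encode(cfg.rev_adapter + cfg.pad_base * cfg.read_len)
    truths: list[SimTruth] = []
    molecules: list[str] = []
    pairs: list[ReadPair] = []
    for wtruth, window in windows:
        wcodes = encode(window)
        fwd_t, rev_t = _truth_matrices(wcodes, inserts, cfg, apf, apr)
        fwd_o, fwd_q = apply_errors_batch(fwd_t, profile, model, rng)
        rev_o, rev_q = apply_errors_batch(rev_t, profile, model, rng)
        for k, L in enumerate(inserts):
            name = f"{wtruth.contig}:{wtruth.start}-{wtruth.end}:{wtruth.strand}:{L}"
            truths.append(
                SimTruth(wtruth.contig, wtruth.start, wtruth.end, wtruth.strand, int(L))
            )
            molecules.append(window[: int(L)])
            pairs.append(
                ReadPair(
                    fwd=ReadRecord(name, decode(fwd_o[k]), fwd_q[k].tolist()),
                    rev=ReadRecord(name, decode(rev_o[k]), rev_q[k].tolist()),
                )
            )
    return truths, molecules, pairs


def merge_error_experiment(
    n_windows: int = 516,
    insert_min: int = 5,
    insert_max: int = 101,
    model_kind: str = "error_informative",
    seed: int = 0,
    profile: ErrorProfile | None = None,
    read_len: int = 101,
) -> dict:
    """Measure per-base error before and after merging on simulated pairs.

    Simulates ``n_windows x (insert_max - insert_min + 1)`` pairs from a
    synthetic reference with a rising error profile (default 0.1% -> 5%
    per cycle, linear), merges them, and compares the raw-read per-base
    error rate against the merged-consensus per-base error rate measured
    against the true molecules.  Returns a dict of rates and counts.
    """
    if profile is None:
        profile = make_synthetic_profile(read_len, 0.001, 0.05, "linear")
    model = QualityModel(kind=model_kind)
    rng = np.random.default_rng(derive_seed(seed, "merge-exp-ref"))
    ref_len = 300_000
    bases = "ACGT"
    ref_seq = "".join(
        np.array(list(bases))[rng.integers(0, 4, ref_len)].tolist()
    )
    cfg = SimConfig(
        n_windows=n_windows,
        window_len=insert_max,
        read_len=read_len,
        min_contig=ref_len,
        insert_min=insert_min,
        insert_max=insert_max,
        seed=derive_seed(seed, f"merge-exp-sim-{model_kind}"),
    )
    reference = [("c1", ref_seq)]
    truths, molecules, pairs = simulate_pairs_in_memory(reference, profile, model, cfg)

    params = MergeParams(fwd_adapter=cfg.fwd_adapter, rev_adapter=cfg.rev_adapter)
    raw_err = 0
    raw_bases = 0
    merged_err = 0
    merged_bases = 0
    status_counts = {"merged": 0, "unmerged": 0, "dimer": 0}
    correct_insert = 0
    for truth, mol, pair in zip(truths, molecules, pairs):
        fwd_true, rev_true = _true_reads(mol, cfg)
        raw_err += _hamming(pair.fwd.seq, fwd_true) + _hamming(pair.rev.seq, rev_true)
        raw_bases += len(fwd_true) + len(rev_true)
        res = merge_pair(pair, params)
        status_counts[res.status] += 1
        if res.status == "merged":
            if res.insert_len == truth.insert_len:
                correct_insert += 1
            m = min(len(res.merged.seq), len(mol))
            merged_err += _hamming(res.merged.seq[:m], mol[:m]) + abs(
                len(res.merged.seq) - len(mol)
            )
            merged_bases += len(res.merged.seq)
    raw_rate = raw_err / raw_bases if raw_bases else 0.0
    merged_rate = merged_err / merged_bases if merged_bases else 0.0
    return {
        "model": model_kind,
        "n_pairs": len(pairs),
        "raw_error_rate": raw_rate,
        "merged_error_rate": merged_rate,
        "reduction_factor": raw_rate / merged_rate if merged_rate > 0 else float("inf"),
        "merged": status_counts["merged"],
        "unmerged": status_counts["unmerged"],
        "dimer": status_counts["dimer"],
        "correct_insert_fraction": (
            correct_insert / status_counts["merged"] if status_counts["merged"] else 0.0
        ),
    }


def _true_reads(mol: str, cfg: SimConfig) -> tuple[str, str]:
    from .simulator import make_pair

    window = mol  # make_pair only needs the molecule prefix
    return make_pair(window, len(mol), cfg)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def write_echo_sam(
    truths: Sequence[SimTruth],
    read_len: int,
    path: str | Path,
    contig_lengths: dict[str, int],
    mapq: int = 60,
    wrong_contig: Sequence[int] = (),
) -> Path:
    """Write a SAM that places each forward read exactly at its truth.

    ``wrong_contig`` lists indices of reads to corrupt onto another contig
    (for harness self-tests).  Requires at least two contigs to corrupt.
    """
    path = Path(path)
    names = list(contig_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": contig_lengths[n]} for n in names],
    }
    wrong = set(wrong_contig)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, t in enumerate(truths):
            a = pysam.AlignedSegment(out.header)
            a.query_name = t.name()
            a.query_sequence = "A" * read_len
            a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
            a.flag = 0
            tid = names.index(t.contig)
            if i in wrong:
                tid = (tid + 1) % len(names)
            a.reference_id = tid
            a.reference_start = t.start
            a.mapping_quality = mapq
            a.cigarstring = f"{read_len}M"
            out.write(a)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path, config: dict, outputs: Iterable[str | Path]
) -> dict:
    """Write a machine-readable run manifest (config, versions, checksums)."""
    manifest = {
        "readforge_version": __version__,
        "python": platform.python_version(),
        "config": config,
        "outputs": {
            str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest


def run_demo(outdir: str | Path, seed: int = 7, small: bool = True) -> dict:
    """Generate reference -> simulate -> merge -> filter -> evaluate.

    ``small`` keeps everything desk-scale (a 200 kb reference, a reduced
    window count) so the whole chain finishes in well under a minute.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_len = 200_000 if small else 2_000_000
    n_windows = 20 if small else 200
    ref_path = outdir / "reference.fa"
    generate_reference(
        ref_path, n_contigs=2, contig_len=ref_len, gc=0.41,
        seed=derive_seed(seed, "reference"),
    )
    profile = make_synthetic_profile(101, 0.001, 0.05, "linear")
    prof_path = outdir / "profile.tsv"
    save_profile(profile, prof_path)
    cfg = SimConfig(
        n_windows=n_windows,
        min_contig=ref_len,
        seed=derive_seed(seed, "simulate"),
    )
    model = QualityModel("error_informative")
    fq1 = outdir / "reads_1.fastq.gz"
    fq2 = outdir / "reads_2.fastq.gz"
    n_pairs = simulate_run(ref_path, profile, model, cfg, fq1, fq2)

    from .seqio import read_fastq

    params = MergeParams()
    merged_path = outdir / "merged.fastq"
    results: list[MergeResult] = []
    merged_records = []
    truths = []
    for fwd, rev in zip(read_fastq(fq1), read_fastq(fq2)):
        pair = ReadPair(fwd, rev)
        res = merge_pair(pair, params)
        results.append(res)
        if res.status == "merged":
            merged_records.append(res.merged)
        truths.append(parse_name_safe(fwd.id))
    write_fastq(merged_records, merged_path)

    fcfg = FilterConfig()
    passing, verdicts = filter_stream(merged_records, fcfg, order=("entropy", "quality"))
    report_path = outdir / "filter_report.tsv"
    summarize_verdicts(verdicts).to_csv(report_path, sep="\t", index=False)

    sam_path = outdir / "echo.sam"
    contig_lengths = {f"c{i + 1}": ref_len for i in range(2)}
    write_echo_sam(
        [t for t in truths if t is not None], cfg.read_len, sam_path, contig_lengths
    )
    eval_res = evaluate_alignments(sam_path, EvalConfig())
    eval_path = outdir / "mapping_eval.tsv"
    eval_res.table.to_csv(eval_path, sep="\t", index=False)

    status_counts = {
        s: sum(1 for r in results if r.status == s)
        for s in ("merged", "unmerged", "dimer")
    }
    summary = {
        "seed": seed,
        "n_pairs": n_pairs,
        "merge_status": status_counts,
        "n_filtered_out": int((~verdicts["passed"]).sum()),
        "mapping_total_correct_fraction": float(
            eval_res.table.iloc[-1]["frac_unique_correct"]
        ),
    }
    manifest = write_manifest(
        outdir / "manifest.json",
        {"demo": summary, "sim": asdict(cfg)},
        [ref_path, prof_path, fq1, fq2, merged_path, report_path, eval_path, sam_path],
    )
    summary["manifest"] = manifest
    return summary


def parse_name_safe(name: str):
    from .mapping_eval import parse_truth

    try:
        return parse_truth(name)
    except ValueError:
        return None
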
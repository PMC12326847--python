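"""Run configuration, stage logging, published-style reports, and the
end-to-end pipeline composition (call -> dmc -> scan-hre [-> clones]).

Reports mirror the two table styles of the study this toolkit emulates:
a promoter table (TSS-relative CpG positions with integer N%/H% columns,
rounded half-up) and an HRE-CpG table (1-based IDs, "~ d" kb distances,
levels printed with trailing-zero trimming, sorted by |methdiff|).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, fields
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from . import __version__
from .sim import SyntheticGenome, read_fastq
from .align import map_reads, extract_methylation, write_methylation_track
from .diff import join_conditions, classify_demethylated, dmc_test, write_dmc_table
from .hre import (
    scan_hre, dedup_to_hre_cpgs, attach_methylation, annotate_tss_distance,
    read_tss_bed, write_hre_table,
)

log = logging.getLogger("hremeth")


def configure_logging(level: int = logging.INFO) -> None:
    """Stage logging to stderr with timestamps."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


@dataclass
class RunConfig:
    """Pipeline constants and input/output paths.

    The defaults are the published filter: minimum per-condition coverage 5
    and strict methdiff threshold 0.2.
    """

    min_coverage: int = 5
    methdiff_threshold: float = 0.2
    merge_strands: bool = True
    conversion_qc_threshold: float = 0.95
    max_mismatches: int = -1          # -1: per-read default (2 per 75 bp)
    fisher: bool = False
    rng_seed: int = 0
    genome_fasta: str = ""
    reads_n: str = ""
    reads_h: str = ""
    tss_bed: str = ""
    out_dir: str = "hremeth_out"

    def __post_init__(self) -> None:
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be >= 0")
        if not -1.0 <= self.methdiff_threshold <= 1.0:
            raise ValueError("methdiff_threshold must lie in [-1, 1]")
        if not 0.0 <= self.conversion_qc_threshold <= 1.0:
            raise ValueError("conversion_qc_threshold must lie in [0, 1]")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        casts = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key not in casts:
                    raise KeyError(f"unknown config key: {key}")
                cur = getattr(defaults, key)
                if isinstance(cur, bool):
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                elif isinstance(cur, int):
                    kwargs[key] = int(val)
                elif isinstance(cur, float):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Published-style tables
# ---------------------------------------------------------------------------

def _pct_int(level: float) -> str:
    """Percent as an integer, rounded half-up (85.5 -> 86), or NA."""
    if pd.isna(level):
        return "NA"
    return str(int(Decimal(str(level * 100)).quantize(0, rounding=ROUND_HALF_UP)))


def _level_str(level: float) -> str:
    """Two decimals with one trailing zero trimmed: 0.60 -> '0.6', 1.00 -> '1.0'."""
    if pd.isna(level):
        return "NA"
    s = f"{level:.2f}"
    return s[:-1] if s.endswith("0") else s


def report_promoter_table(dmc: pd.DataFrame, amplicon) -> str:
    """Promoter methylation table: TSS-relative positions, integer N%/H%.

    Rows run promoter-proximal to distal (label closest to the TSS first).
    Positions without coverage print NA.
    """
    lookup = {
        (row.contig, row.cpg_pos): (row.m_N, row.m_H)
        for row in dmc.itertuples(index=False)
    }
    lines = ["position\tN(%)\tH(%)"]
    order = sorted(
        zip(amplicon.labels, amplicon.cpg_abs), key=lambda t: abs(t[0])
    )
    for label, pos in order:
        m = lookup.get((amplicon.contig, int(pos)), (float("nan"), float("nan")))
        lines.append(f"{label}\t{_pct_int(m[0])}\t{_pct_int(m[1])}")
    return "\n".join(lines) + "\n"


def report_hre_table(hre_df: pd.DataFrame) -> str:
    """HRE-CpG methylation table sorted by |methdiff| descending.

    Columns: 1-based HRE ID, '~ d' kb distance from the nearest TSS (when
    annotated), and the N/H levels with trailing-zero trimming.
    """
    lines = ["hre_id\tdistance_kb\tN\tH"]
    df = hre_df.copy()
    df["_absdiff"] = df["methdiff"].abs()
    df = df.sort_values(["_absdiff", "hre_id"], ascending=[False, True], na_position="last")
    has_dist = "distance_kb" in df.columns
    for row in df.itertuples(index=False):
        if has_dist and not pd.isna(row.distance_kb):
            d = f"~ {row.distance_kb:g}"
        else:
            d = "NA"
        lines.append(f"{row.hre_id}\t{d}\t{_level_str(row.m_N)}\t{_level_str(row.m_H)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pipeline composition
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute call -> dmc -> scan-hre on configured inputs.

    Writes per-condition methylation tracks, the DMC table/BED, and the
    HRE-CpG table/BED under ``config.out_dir`` and returns a machine-
    readable summary.  Fails fast with a stage-named error on malformed
    input.  Deterministic: identical config (and inputs) gives identical
    outputs and summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mm = None if config.max_mismatches < 0 else config.max_mismatches

    try:
        genome = SyntheticGenome.from_fasta(config.genome_fasta)
        if not genome.contigs:
            raise ValueError("no contigs in genome FASTA")
    except Exception as e:
        raise RuntimeError(f"[stage genome] {e}") from e
    log.info("genome: %d contig(s), %d bp", len(genome.contigs), genome.total_length())

    calls = {}
    for cond, path in (("N", config.reads_n), ("H", config.reads_h)):
        try:
            reads = read_fastq(path)
            alns = map_reads(reads, genome, max_mismatches=mm)
            calls[cond] = extract_methylation(
                alns, genome, cond, merge_strands=config.merge_strands
            )
        except Exception as e:
            raise RuntimeError(f"[stage call/{cond}] {e}") from e
        log.info(
            "call/%s: %d reads, %d aligned, %d CpG calls",
            cond, len(reads), len(alns), len(calls[cond]),
        )
        if calls[cond]:
            write_methylation_track(calls[cond], out / f"calls_{cond}.tsv")

    try:
        dmc = join_conditions(calls["N"], calls["H"])
        dmc, dmc_summary = classify_demethylated(
            dmc, config.min_coverage, config.methdiff_threshold
        )
        if config.fisher:
            dmc = dmc_test(dmc)
        write_dmc_table(dmc, out / "dmc.tsv", out / "demethylated.bed")
    except Exception as e:
        raise RuntimeError(f"[stage dmc] {e}") from e
    log.info(
        "dmc: %d CpGs, %d covered, %d demethylated",
        dmc_summary.n_total, dmc_summary.n_covered, dmc_summary.n_demethylated,
    )

    try:
        hre_cpgs = dedup_to_hre_cpgs(scan_hre(genome))
        hre_df, hre_summary = attach_methylation(hre_cpgs, dmc, config.min_coverage)
        if config.tss_bed:
            hre_df = annotate_tss_distance(hre_df, read_tss_bed(config.tss_bed))
        write_hre_table(hre_df, out / "hre_cpgs.tsv", out / "hre_demethylated.bed")
        (out / "hre_report.txt").write_text(report_hre_table(hre_df))
    except Exception as e:
        raise RuntimeError(f"[stage scan-hre] {e}") from e
    log.info(
        "scan-hre: %d HRE-CpGs, %d covered, %d demethylated",
        hre_summary.n_total, hre_summary.n_covered, hre_summary.n_demethylated,
    )

    summary = {
        "n_cpgs_called": dmc_summary.n_total,
        "n_cpgs_demethylated": dmc_summary.n_demethylated,
        "n_hre_cpgs_total": hre_summary.n_total,
        "n_covered": hre_summary.n_covered,
        "fraction_covered": hre_summary.fraction_covered,
        "n_demethylated": hre_summary.n_demethylated,
        "min_coverage": config.min_coverage,
        "methdiff_threshold": config.methdiff_threshold,
        "seed": config.rng_seed,
        "version": __version__,
    }
    return summary
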
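"""Differential CpG methylation between normoxia (N) and hypoxia (H).

The classification is a deliberately simple published-style filter rather
than a model fit: a CpG is called demethylated under hypoxia when both
conditions reach a minimum coverage (default 5) and the level difference
methdiff = m_N - m_H strictly exceeds a threshold (default 0.2).  Positive
methdiff means the site lost methylation under hypoxia.  An optional
per-CpG two-sided Fisher exact test with Benjamini-Hochberg correction can
be layered on top for QC; it never alters the filter-based classification.

Records are pandas DataFrames with one row per CpG; see DMC_COLUMNS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import MethylCall

DMC_COLUMNS = [
    "contig", "cpg_pos",
    "n_meth_N", "n_unmeth_N", "cov_N", "m_N",
    "n_meth_H", "n_unmeth_H", "cov_H", "m_H",
    "methdiff", "demethylated",
]


@dataclass
class DMCSummary:
    n_total: int
    n_covered: int
    fraction_covered: float
    n_demethylated: int
    n_hypermethylated: int
    min_coverage: int
    methdiff_threshold: float


def _side_frame(calls: list[MethylCall], suffix: str) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "contig": [c.contig for c in calls],
            "cpg_pos": [c.cpg_pos for c in calls],
            f"n_meth_{suffix}": [c.n_meth for c in calls],
            f"n_unmeth_{suffix}": [c.n_unmeth for c in calls],
        }
    )
    if df.duplicated(["contig", "cpg_pos"]).any():
        raise ValueError(f"duplicate CpG keys in condition {suffix}")
    return df


def join_conditions(calls_N: list[MethylCall], calls_H: list[MethylCall]) -> pd.DataFrame:
    """Outer join of the two conditions' calls keyed by (contig, cpg_pos).

    A CpG missing from one condition gets coverage 0 on that side and an
    undefined (NaN) level; such rows can never be classified demethylated.
    """
    df = _side_frame(calls_N, "N").merge(
        _side_frame(calls_H, "H"), on=["contig", "cpg_pos"], how="outer"
    )
    for s in ("N", "H"):
        for col in (f"n_meth_{s}", f"n_unmeth_{s}"):
            df[col] = df[col].fillna(0).astype(np.int64)
        df[f"cov_{s}"] = df[f"n_meth_{s}"] + df[f"n_unmeth_{s}"]
        cov = df[f"cov_{s}"]
        df[f"m_{s}"] = np.where(cov > 0, df[f"n_meth_{s}"] / cov.replace(0, 1), np.nan)
    df["methdiff"] = df["m_N"] - df["m_H"]
    df["demethylated"] = False
    return df.sort_values(["contig", "cpg_pos"]).reset_index(drop=True)[DMC_COLUMNS]


def classify_demethylated(
    records: pd.DataFrame,
    min_coverage: int = 5,
    methdiff_threshold: float = 0.2,
) -> tuple[pd.DataFrame, DMCSummary]:
    """Apply the coverage and methdiff filters; return records + summary.

    demethylated  := cov_N >= min_coverage and cov_H >= min_coverage
                     and methdiff > methdiff_threshold (strict).
    The coverage gate applies to both conditions.  Hypermethylated sites
    (methdiff < -threshold at the same coverage) are tallied separately in
    the summary but carry no flag.
    """
    df = records.copy()
    covered = (df["cov_N"] >= min_coverage) & (df["cov_H"] >= min_coverage)
    df["demethylated"] = covered & (df["methdiff"] > methdiff_threshold)
    n_total = len(df)
    n_covered = int(covered.sum())
    summary = DMCSummary(
        n_total=n_total,
        n_covered=n_covered,
        fraction_covered=(n_covered / n_total) if n_total else float("nan"),
        n_demethylated=int(df["demethylated"].sum()),
        n_hypermethylated=int((covered & (df["methdiff"] < -methdiff_threshold)).sum()),
        min_coverage=min_coverage,
        methdiff_threshold=methdiff_threshold,
    )
    return df, summary


def dmc_test(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided Fisher exact test per CpG with Benjamini-Hochberg q-values.

    The 2x2 table is [(n_meth, n_unmeth)_N ; (n_meth, n_unmeth)_H].  CpGs
    with zero coverage on either side are skipped (NaN p).  Purely additive:
    the methdiff classification is never modified.
    """
    df = records.copy()
    p = np.full(len(df), np.nan)
    testable = (df["cov_N"].to_numpy() > 0) & (df["cov_H"].to_numpy() > 0)
    mN = df["n_meth_N"].to_numpy()
    uN = df["n_unmeth_N"].to_numpy()
    mH = df["n_meth_H"].to_numpy()
    uH = df["n_unmeth_H"].to_numpy()
    cache: dict[tuple[int, int, int, int], float] = {}
    for i in np.flatnonzero(testable):
        key = (int(mN[i]), int(uN[i]), int(mH[i]), int(uH[i]))
        if key not in cache:
            cache[key] = stats.fisher_exact(
                [[key[0], key[1]], [key[2], key[3]]], alternative="two-sided"
            )[1]
        p[i] = cache[key]
    df["p_value"] = p
    q = np.full(len(df), np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], alpha=alpha, method="fdr_bh")[1]
    df["q_value"] = q
    return df


def demethylation_tail_probability(
    p_N: float, p_H: float, cov_N: int, cov_H: int, threshold: float = 0.2
) -> float:
    """Closed-form P(m_N_hat - m_H_hat > threshold) under binomial sampling.

    The estimated levels are a/cov_N and b/cov_H with a ~ Bin(cov_N, p_N)
    and b ~ Bin(cov_H, p_H) independent.  Used to predict the yield of the
    demethylation filter at planted truth values, and its false-positive
    rate under the null p_N = p_H.
    """
    a = np.arange(cov_N + 1)
    b = np.arange(cov_H + 1)
    pa = stats.binom.pmf(a, cov_N, p_N)
    pb = stats.binom.pmf(b, cov_H, p_H)
    exceed = (a[:, None] / cov_N - b[None, :] / cov_H) > threshold
    return float(pa @ exceed @ pb)


def write_dmc_table(records: pd.DataFrame, path, bed_path=None) -> None:
    """DMC TSV (1-based positions) and optional BED of demethylated CpGs."""
    out = records.copy()
    out.insert(2, "pos_1based", out["cpg_pos"] + 1)
    out.drop(columns=["cpg_pos"]).to_csv(path, sep="\t", index=False, float_format="%.6g")
    if bed_path is not None:
        demeth = records[records["demethylated"]]
        with open(bed_path, "w") as fh:
            for row in demeth.itertuples(index=False):
                fh.write(
                    f"{row.contig}\t{row.cpg_pos}\t{row.cpg_pos + 1}\t"
                    f"methdiff={row.methdiff:.3f}\n"
                )


def read_dmc_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["cpg_pos"] = df["pos_1based"] - 1
    return df[DMC_COLUMNS + [c for c in ("p_value", "q_value") if c in df.columns]]
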
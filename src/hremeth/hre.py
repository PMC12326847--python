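"""Genome-wide scan for CpG-containing hypoxia-response elements (HREs).

The HRE is the degenerate element 5'-(G/A)CGTG-3' (equivalently
3'-CACG(C/T)-5' on the complementary strand).  HIF transcription factors
bind it, and methylation of the central CpG blocks that binding, so the
quantity of interest is the unique CpG inside each motif occurrence — an
"HRE-CpG" — rather than the motif match itself.  Scanning is done on the
forward sequence with both orientations' patterns: a forward match RCGTG
places the CpG C at start+1, a reverse-orientation match CACGY (the
reverse complement of RCGTG) places it at start+2.  The palindromic E-box
CACGTG matches both ways but contains a single CpG, counted once.

The scan itself is a vectorised base-wise test (no regular expressions),
which lets a brute-force regex serve as an independent oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sim import SyntheticGenome, _seq_to_array, _A, _C, _G, _T


@dataclass
class HREMatch:
    contig: str
    start: int               # 0-based; element spans [start, start+5)
    orientation: str         # "forward" (RCGTG) or "reverse" (CACGY)
    matched_sequence: str

    @property
    def end(self) -> int:
        return self.start + 5

    @property
    def cpg_pos(self) -> int:
        return self.start + (1 if self.orientation == "forward" else 2)


@dataclass
class HRECpG:
    contig: str
    cpg_pos: int
    supporting_matches: list[HREMatch] = field(default_factory=list)

    @property
    def hre_id(self) -> str:
        """1-based identifier, e.g. 'chr18:21601384'."""
        return f"{self.contig}:{self.cpg_pos + 1}"


def _scan_contig(name: str, seq: str) -> list[HREMatch]:
    arr = _seq_to_array(seq)
    L = arr.size
    if L < 5:
        return []
    b = [arr[i : L - 4 + i] for i in range(5)]
    valid = np.ones(L - 4, dtype=bool)
    for i in range(5):
        valid &= np.isin(b[i], (_A, _C, _G, _T))  # windows containing N never match
    fwd = (
        valid
        & ((b[0] == _G) | (b[0] == _A))
        & (b[1] == _C) & (b[2] == _G) & (b[3] == _T) & (b[4] == _G)
    )
    rev = (
        valid
        & (b[0] == _C) & (b[1] == _A) & (b[2] == _C) & (b[3] == _G)
        & ((b[4] == _C) | (b[4] == _T))
    )
    matches = [
        HREMatch(name, int(s), "forward", seq[s : s + 5].upper())
        for s in np.flatnonzero(fwd)
    ] + [
        HREMatch(name, int(s), "reverse", seq[s : s + 5].upper())
        for s in np.flatnonzero(rev)
    ]
    matches.sort(key=lambda m: (m.start, m.orientation))
    return matches


def scan_hre(genome) -> list[HREMatch]:
    """All HRE motif occurrences (both orientations, overlaps included).

    ``genome`` may be a SyntheticGenome, a dict name->sequence, or an
    iterable of (name, sequence) pairs.  Soft-masked (lowercase) sequence is
    uppercased; masking is ignored.
    """
    if isinstance(genome, SyntheticGenome):
        items = genome.contigs
    elif isinstance(genome, dict):
        items = list(genome.items())
    else:
        items = list(genome)
    out: list[HREMatch] = []
    for name, seq in items:
        out.extend(_scan_contig(name, seq))
    return out


def dedup_to_hre_cpgs(matches: list[HREMatch]) -> list[HRECpG]:
    """Group motif matches into unique HRE-CpGs by (contig, cpg_pos).

    A palindromic CACGTG yields one HRE-CpG supported by two matches.
    Idempotent in effect: re-deduplicating the grouped CpGs changes nothing.
    """
    groups: dict[tuple[str, int], HRECpG] = {}
    for m in matches:
        key = (m.contig, m.cpg_pos)
        if key not in groups:
            groups[key] = HRECpG(contig=m.contig, cpg_pos=m.cpg_pos)
        groups[key].supporting_matches.append(m)
    return [groups[k] for k in sorted(groups)]


def count_hre(genome, unit: str = "cpg") -> int:
    """Genome-wide HRE tally; ``unit`` is 'cpg' (unique CpGs) or 'match'."""
    matches = scan_hre(genome)
    if unit == "match":
        return len(matches)
    if unit == "cpg":
        return len(dedup_to_hre_cpgs(matches))
    raise ValueError("unit must be 'cpg' or 'match'")


HRE_COLUMNS = [
    "contig", "cpg_pos", "hre_id", "n_matches",
    "m_N", "m_H", "cov_N", "cov_H", "methdiff", "covered", "demethylated",
]


def attach_methylation(
    hre_cpgs: list[HRECpG],
    dmc: pd.DataFrame,
    min_coverage: int = 5,
) -> tuple[pd.DataFrame, "HRESummary"]:
    """Left-join differential methylation onto the HRE-CpG set.

    HRE-CpGs with no call (or below ``min_coverage`` on either side) carry
    NaN levels and count as "not covered"; the demethylated flag is copied
    from the filter classification, never recomputed here.
    """
    base = pd.DataFrame(
        {
            "contig": [h.contig for h in hre_cpgs],
            "cpg_pos": [h.cpg_pos for h in hre_cpgs],
            "hre_id": [h.hre_id for h in hre_cpgs],
            "n_matches": [len(h.supporting_matches) for h in hre_cpgs],
        }
    )
    cols = ["contig", "cpg_pos", "m_N", "m_H", "cov_N", "cov_H", "methdiff", "demethylated"]
    df = base.merge(dmc[cols], on=["contig", "cpg_pos"], how="left")
    df["cov_N"] = df["cov_N"].fillna(0).astype(np.int64)
    df["cov_H"] = df["cov_H"].fillna(0).astype(np.int64)
    dm = df["demethylated"].to_numpy(dtype=object)
    dm[pd.isna(dm)] = False
    df["demethylated"] = dm.astype(bool)
    df["covered"] = (df["cov_N"] >= min_coverage) & (df["cov_H"] >= min_coverage)
    n_total = len(df)
    n_covered = int(df["covered"].sum())
    summary = HRESummary(
        n_total=n_total,
        n_covered=n_covered,
        fraction_covered=(n_covered / n_total) if n_total else float("nan"),
        n_demethylated=int(df["demethylated"].sum()),
    )
    return df[HRE_COLUMNS], summary


@dataclass
class HRESummary:
    n_total: int
    n_covered: int
    fraction_covered: float
    n_demethylated: int


# ---------------------------------------------------------------------------
# TSS distance annotation
# ---------------------------------------------------------------------------

@dataclass
class TSSRecord:
    gene: str
    contig: str
    tss_pos: int             # 0-based
    strand: str              # '+' or '-'


def read_tss_bed(path) -> list[TSSRecord]:
    """BED6 gene records; the TSS is start for '+' genes, end-1 for '-'."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    out = []
    for row in df.itertuples(index=False):
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        out.append(TSSRecord(str(row.name), str(row.chrom), tss, str(row.strand)))
    return out


def annotate_tss_distance(hre_df: pd.DataFrame, tss: list[TSSRecord]) -> pd.DataFrame:
    """Nearest-TSS annotation for each HRE-CpG.

    distance_kb = |cpg_pos - tss_pos| / 1000 rounded to one decimal; the
    nearest TSS by absolute distance wins, ties broken by gene name.
    Orientation is judged relative to the gene's strand ('upstream' when the
    CpG precedes the TSS in the gene's reading direction, 'tss' at distance
    zero).  Contigs with no TSS record yield NA.
    """
    by_contig: dict[str, list[TSSRecord]] = {}
    for t in tss:
        by_contig.setdefault(t.contig, []).append(t)
    genes, dists_kb, dists_bp, orients = [], [], [], []
    for row in hre_df.itertuples(index=False):
        cands = by_contig.get(row.contig)
        if not cands:
            genes.append(None)
            dists_kb.append(float("nan"))
            dists_bp.append(-1)
            orients.append("NA")
            continue
        best = min(cands, key=lambda t: (abs(row.cpg_pos - t.tss_pos), t.gene))
        d = row.cpg_pos - best.tss_pos
        if d == 0:
            orient = "tss"
        elif best.strand == "+":
            orient = "upstream" if d < 0 else "downstream"
        else:
            orient = "upstream" if d > 0 else "downstream"
        genes.append(best.gene)
        dists_bp.append(abs(d))
        dists_kb.append(round(abs(d) / 1000.0, 1))
        orients.append(orient)
    out = hre_df.copy()
    out["nearest_gene"] = genes
    out["distance_bp"] = dists_bp
    out["distance_kb"] = dists_kb
    out["orientation"] = orients
    return out


def write_hre_table(df: pd.DataFrame, path, bed_path=None) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if bed_path is not None:
        demeth = df[df["demethylated"]]
        with open(bed_path, "w") as fh:
            for row in demeth.itertuples(index=False):
                fh.write(f"{row.contig}\t{row.cpg_pos}\t{row.cpg_pos + 1}\t{row.hre_id}\n")
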
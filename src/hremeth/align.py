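"""Three-letter bisulfite read mapping and per-CpG methylation extraction.

Bisulfite conversion destroys the C/T contrast on the read's strand of
origin, so reads are mapped in "three-letter" space: the reference is
collapsed C->T for original-top (OT) candidates and G->A for original-bottom
(OB) candidates, and the read is collapsed the same way before comparison.
A seed-and-verify search (pigeonhole seeds, numpy mismatch verification)
keeps toy-genome mapping fast; ties and misses return no alignment, so
ambiguous placements can never contribute methylation evidence.

Methylation is then called per CpG: OT reads vote through the base over the
forward-strand C (C = methylated, T = unmethylated), OB reads through the
base over the G of the same CpG (G = methylated, A = unmethylated), and by
default the two strands pool into a single call keyed by the forward-strand
C position (CpG methylation is symmetric).  Bases that are neither of the
two informative letters (e.g. sequencing errors) are ignored rather than
counted as unmethylated.

Coordinates are 0-based half-open internally; text reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim import SyntheticGenome, _seq_to_array, _COMPLEMENT, _A, _C, _G, _T

_N = ord("N")
_VALID = frozenset(b"ACGTN")


def default_max_mismatches(read_length: int) -> int:
    """Mismatch budget: 2 per 75 bp, at least 2."""
    return max(2, int(2 * read_length // 75))


@dataclass
class ReadAlignment:
    read_id: str
    contig: str
    start: int                # 0-based forward-reference start
    strand_origin: str        # "OT" or "OB"
    n_mismatches: int
    unique: bool
    fwd_seq: str              # the read projected onto the forward strand


def _collapse(arr: np.ndarray, src: int, dst: int) -> np.ndarray:
    out = arr.copy()
    out[out == src] = dst
    return out


class BisulfiteIndex:
    """Seed index over the C->T and G->A collapsed reference spaces.

    Ns in the reference are encoded so that they never match any read base.
    """

    def __init__(self, genome: SyntheticGenome, seed_len: int = 20):
        self.genome = genome
        self.seed_len = seed_len
        self._spaces: dict[str, dict[str, np.ndarray]] = {"CT": {}, "GA": {}}
        self._kmers: dict[str, dict[str, dict[bytes, list[int]]]] = {"CT": {}, "GA": {}}
        for name, seq in genome.contigs:
            arr = _seq_to_array(seq)
            ct = _collapse(arr, _C, _T)
            ga = _collapse(arr, _G, _A)
            ct[arr == _N] = 255
            ga[arr == _N] = 255
            self._spaces["CT"][name] = ct
            self._spaces["GA"][name] = ga
            for space, ref in (("CT", ct), ("GA", ga)):
                table: dict[bytes, list[int]] = {}
                buf = ref.tobytes()
                for i in range(0, len(buf) - seed_len + 1):
                    table.setdefault(buf[i : i + seed_len], []).append(i)
                self._kmers[space][name] = table

    def _candidates(self, space: str, query: np.ndarray) -> list[tuple[str, int]]:
        k = self.seed_len
        L = query.size
        n_seeds = max(1, min(L // k, 5))
        offsets = np.linspace(0, L - k, n_seeds).astype(int)
        qb = query.tobytes()
        cands: set[tuple[str, int]] = set()
        for name in self.genome.names:
            table = self._kmers[space][name]
            ref_len = self._spaces[space][name].size
            for off in offsets:
                for hit in table.get(qb[off : off + k], ()):
                    start = hit - int(off)
                    if 0 <= start <= ref_len - L:
                        cands.add((name, start))
        return sorted(cands)

    def _verify(self, space: str, contig: str, start: int, query: np.ndarray) -> int:
        ref = self._spaces[space][contig][start : start + query.size]
        return int(np.count_nonzero(ref != query))


def map_bisulfite_read(
    read_id: str,
    seq: str,
    index: BisulfiteIndex,
    max_mismatches: int | None = None,
) -> ReadAlignment | None:
    """Best unique placement of one read, or None on a tie or no hit.

    The read is tested as OT (read collapsed C->T against the C->T
    reference) and as OB (reverse complement collapsed G->A against the
    G->A reference).  All hits within the mismatch budget compete; a unique
    best hit wins, equal-best hits discard the read.
    """
    seq = seq.upper()
    if not set(seq.encode()) <= _VALID:
        raise ValueError(f"read {read_id} contains non-ACGTN characters")
    if max_mismatches is None:
        max_mismatches = default_max_mismatches(len(seq))
    arr = _seq_to_array(seq)
    arr_rc = _COMPLEMENT[arr][::-1]
    q_ot = _collapse(arr, _C, _T)
    q_ob = _collapse(arr_rc, _G, _A)
    # read Ns never match (reference Ns are encoded 255)
    q_ot[arr == _N] = 254
    q_ob[arr_rc == _N] = 254
    hits: list[tuple[int, str, str, int, np.ndarray]] = []
    for space, query, strand, fwd in (
        ("CT", q_ot, "OT", arr),
        ("GA", q_ob, "OB", arr_rc),
    ):
        for contig, start in index._candidates(space, query):
            mm = index._verify(space, contig, start, query)
            if mm <= max_mismatches:
                hits.append((mm, contig, strand, start, fwd))
    if not hits:
        return None
    hits.sort(key=lambda h: h[0])
    if len(hits) > 1 and hits[0][0] == hits[1][0]:
        return None
    mm, contig, strand, start, fwd = hits[0]
    return ReadAlignment(
        read_id=read_id,
        contig=contig,
        start=start,
        strand_origin=strand,
        n_mismatches=mm,
        unique=True,
        fwd_seq=fwd.tobytes().decode("ascii"),
    )


def map_reads(
    reads,
    genome: SyntheticGenome,
    max_mismatches: int | None = None,
    seed_len: int = 20,
) -> list[ReadAlignment]:
    """Map an iterable of (read_id, seq) pairs or SimRead objects."""
    index = BisulfiteIndex(genome, seed_len=seed_len)
    out = []
    for r in reads:
        rid, seq = (r.name, r.seq) if hasattr(r, "seq") else r
        aln = map_bisulfite_read(rid, seq, index, max_mismatches)
        if aln is not None:
            out.append(aln)
    return out


@dataclass
class MethylCall:
    """Methylated/unmethylated read counts for one CpG in one condition."""

    contig: str
    cpg_pos: int              # 0-based forward-strand C of the CpG
    condition: str
    n_meth: int
    n_unmeth: int
    strand: str = "."         # '+'/'-' in per-strand mode, '.' when merged

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        if self.coverage == 0:
            return float("nan")
        return self.n_meth / self.coverage


def extract_methylation(
    alignments: list[ReadAlignment],
    genome: SyntheticGenome,
    condition: str,
    merge_strands: bool = True,
) -> list[MethylCall]:
    """Per-CpG methylation calls from unique alignments.

    With ``merge_strands`` (default) OT and OB evidence for a CpG pool into
    one call keyed by the forward-strand C position; otherwise separate '+'
    (OT) and '-' (OB) calls are emitted for strand-bias QC.
    """
    counts: dict[str, np.ndarray] = {}
    for name in genome.names:
        counts[name] = np.zeros((4, genome.cpg_index[name].size), dtype=np.int64)
        # rows: meth_top, unmeth_top, meth_bot, unmeth_bot
    for aln in alignments:
        if not aln.unique:
            continue
        idx = genome.cpg_index[aln.contig]
        L = len(aln.fwd_seq)
        tab = counts[aln.contig]
        if aln.strand_origin == "OT":
            lo = np.searchsorted(idx, aln.start)
            hi = np.searchsorted(idx, aln.start + L)
            for j in range(lo, hi):
                base = aln.fwd_seq[idx[j] - aln.start]
                if base == "C":
                    tab[0, j] += 1
                elif base == "T":
                    tab[1, j] += 1
        else:
            # OB reads vote through the G of the CpG (position cpg_pos + 1)
            lo = np.searchsorted(idx, aln.start - 1)
            hi = np.searchsorted(idx, aln.start + L - 1)
            for j in range(lo, hi):
                g = idx[j] + 1
                if not (aln.start <= g < aln.start + L):
                    continue
                base = aln.fwd_seq[g - aln.start]
                if base == "G":
                    tab[2, j] += 1
                elif base == "A":
                    tab[3, j] += 1
    calls: list[MethylCall] = []
    for name in genome.names:
        idx = genome.cpg_index[name]
        tab = counts[name]
        for j in range(idx.size):
            mt, ut, mb, ub = (int(x) for x in tab[:, j])
            if merge_strands:
                if mt + ut + mb + ub > 0:
                    calls.append(MethylCall(name, int(idx[j]), condition, mt + mb, ut + ub))
            else:
                if mt + ut > 0:
                    calls.append(MethylCall(name, int(idx[j]), condition, mt, ut, strand="+"))
                if mb + ub > 0:
                    calls.append(MethylCall(name, int(idx[j]), condition, mb, ub, strand="-"))
    return calls


# ---------------------------------------------------------------------------
# Per-cytosine track I/O (TSV dialect + bedGraph)
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ["contig", "pos_1based", "strand", "context", "n_meth", "n_unmeth", "level"]


def write_methylation_track(calls: list[MethylCall], path, bedgraph_path=None) -> None:
    """Write calls as a per-cytosine TSV (1-based positions, CpG context).

    Optionally also writes a bedGraph of levels over half-open 0-based
    single-base intervals.  The TSV round-trips losslessly through
    :func:`read_methylation_track`.
    """
    if not calls:
        raise ValueError("no methylation calls to write")
    with open(path, "w") as fh:
        fh.write("\t".join(TRACK_COLUMNS) + "\n")
        for c in calls:
            strand = c.strand if c.strand != "." else "+"
            fh.write(
                f"{c.contig}\t{c.cpg_pos + 1}\t{strand}\tCpG\t"
                f"{c.n_meth}\t{c.n_unmeth}\t{c.level:.6g}\n"
            )
    if bedgraph_path is not None:
        with open(bedgraph_path, "w") as fh:
            for c in calls:
                fh.write(f"{c.contig}\t{c.cpg_pos}\t{c.cpg_pos + 1}\t{c.level:.6g}\n")


def read_methylation_track(path, condition: str = "N") -> list[MethylCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for row in df.itertuples(index=False):
        strand = "." if row.strand == "+" else row.strand
        calls.append(
            MethylCall(
                contig=str(row.contig),
                cpg_pos=int(row.pos_1based) - 1,
                condition=condition,
                n_meth=int(row.n_meth),
                n_unmeth=int(row.n_unmeth),
                strand=".",
            )
        )
    return calls


def calls_to_frame(calls: list[MethylCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [c.contig for c in calls],
            "cpg_pos": [c.cpg_pos for c in calls],
            "n_meth": [c.n_meth for c in calls],
            "n_unmeth": [c.n_unmeth for c in calls],
            "coverage": [c.coverage for c in calls],
            "level": [c.level for c in calls],
        }
    )
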
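"""Clone-based Na-bisulfite amplicon sequencing analysis.

Individual bisulfite-PCR clones (Sanger reads of cloned amplicons) give a
per-molecule methylation pattern across a locus such as a promoter.  Each
clone is compared against the bisulfite-converted reference amplicon in
collapsed (three-letter) space — both strand products and both read
orientations are tested, so a reverse-complemented Sanger read yields
identical calls.  At each CpG site the retained base calls the state
(C = methylated, T = unmethylated on the top-strand product; G/A on the
bottom-strand product); anything else is ambiguous and excluded from
percentages.  Conversion efficiency per clone is estimated from non-CpG
cytosines, which are assumed unmethylated in somatic cells; clones whose
efficiency falls below a QC threshold (default 0.95) are excluded from the
per-site summary.

Global alignment with affine gap penalties tolerates the occasional Sanger
indel; clones exceeding a non-bisulfite mismatch fraction are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .sim import SyntheticGenome, CloneSet, _seq_to_array, revcomp, cpg_positions

_C, _G, _T, _A = (ord(x) for x in "CGTA")


@dataclass
class AmpliconRef:
    """Reference amplicon with an ordered CpG ladder and TSS-relative labels."""

    contig: str
    start: int                  # 0-based half-open interval on the contig
    end: int
    sequence: str
    cpg_rel: np.ndarray         # CpG C positions relative to amplicon start
    tss_anchor: int | None = None   # absolute 0-based TSS position, '+' strand
    labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.cpg_rel) > 0):
            raise ValueError("cpg_sites must be strictly increasing")
        if self.tss_anchor is not None and not self.labels:
            self.labels = [int(self.start + r - self.tss_anchor) for r in self.cpg_rel]
        if self.labels and len(self.labels) != self.cpg_rel.size:
            raise ValueError("labels must align 1:1 with cpg_sites")

    @property
    def cpg_abs(self) -> np.ndarray:
        return self.cpg_rel + self.start

    @classmethod
    def from_genome(
        cls, genome: SyntheticGenome, contig: str, start: int, end: int,
        tss_anchor: int | None = None,
    ) -> "AmpliconRef":
        seq = genome.sequence(contig)[start:end]
        return cls(
            contig=contig, start=start, end=end, sequence=seq,
            cpg_rel=cpg_positions(seq), tss_anchor=tss_anchor,
        )


@dataclass
class CloneMatrix:
    """Clones x CpG-sites methylation states for one amplicon and condition.

    ``states`` holds 1 (methylated), 0 (unmethylated), -1 (ambiguous).
    ``per_site_percent`` is computed over QC-passing clones and unambiguous
    calls only.
    """

    ref: AmpliconRef
    condition: str
    clone_ids: list[str]
    states: np.ndarray
    conversion_efficiency: np.ndarray
    qc_pass: np.ndarray
    rejected: list[str] = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def site_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_methylated, n_unmethylated) per site over passing clones."""
        use = self.states[self.qc_pass]
        return (use == 1).sum(axis=0), (use == 0).sum(axis=0)

    @property
    def per_site_percent(self) -> np.ndarray:
        m, u = self.site_counts()
        tot = m + u
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, 100.0 * m / np.maximum(tot, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        cols = self.ref.labels if self.ref.labels else list(self.ref.cpg_rel)
        return pd.DataFrame(self.states, index=self.clone_ids, columns=cols)


_MODES = (
    ("top", "as_is"), ("top", "revcomp"), ("bottom", "as_is"), ("bottom", "revcomp"),
)


def _collapse_seq(seq: str, mode: str) -> str:
    return seq.replace("C", "T") if mode == "top" else seq.replace("G", "A")


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -4
    al.extend_gap_score = -0.5
    return al


def _align_and_map(refc: str, clonec: str):
    """Align in collapsed space; return (n_mismatches, n_aligned, ref->clone map)."""
    al = _aligner()
    aln = al.align(refc, clonec)[0]
    ra = np.frombuffer(refc.encode(), dtype=np.uint8)
    ca = np.frombuffer(clonec.encode(), dtype=np.uint8)
    pos_map = np.full(len(refc), -1, dtype=np.int64)
    mism = 0
    n_aligned = 0
    for (rs, re_), (cs, ce) in zip(*aln.aligned):
        n = re_ - rs
        pos_map[rs:re_] = np.arange(cs, ce)
        mism += int(np.count_nonzero(ra[rs:re_] != ca[cs:ce]))
        n_aligned += n
    return mism, n_aligned, pos_map


def call_clone_states(
    clones,
    ref: AmpliconRef,
    max_mismatch_fraction: float = 0.1,
    conversion_qc_threshold: float = 0.95,
    condition: str = "N",
) -> CloneMatrix:
    """Call per-clone per-CpG methylation states against the amplicon.

    ``clones`` is a CloneSet, an iterable of (id, sequence) pairs, or a
    FASTA path.  Each clone is tested in all four (strand product x read
    orientation) combinations in collapsed space; the best-scoring one is
    kept.  Clones that exceed ``max_mismatch_fraction`` non-bisulfite
    mismatches in that space are rejected outright (they align to neither
    converted strand).
    """
    if isinstance(clones, CloneSet):
        condition = clones.condition
        items = list(clones.clones)
    elif isinstance(clones, (str,)) or hasattr(clones, "__fspath__"):
        from Bio import SeqIO

        items = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(clones), "fasta")]
    else:
        items = [(cid, s.upper()) for cid, s in clones]

    refseq = ref.sequence.upper()
    ref_arr = _seq_to_array(refseq)
    n_sites = ref.cpg_rel.size
    cpg_c = set(int(x) for x in ref.cpg_rel)            # C of each CpG
    cpg_g = set(int(x) + 1 for x in ref.cpg_rel)        # G of each CpG
    nonCpG_c = [i for i in np.flatnonzero(ref_arr == _C) if int(i) not in cpg_c]
    nonCpG_g = [i for i in np.flatnonzero(ref_arr == _G) if int(i) not in cpg_g]

    ids, rows, convs, rejected = [], [], [], []
    for cid, seq in items:
        best = None
        for mode_rank, (product, orient) in enumerate(_MODES):
            proj = seq if orient == "as_is" else revcomp(seq)
            mism, n_aligned, pos_map = _align_and_map(
                _collapse_seq(refseq, product), _collapse_seq(proj, product)
            )
            cand = (mism, mode_rank, n_aligned, product, proj, pos_map)
            if best is None or cand[:2] < best[:2]:
                best = cand
        mism, _rank, n_aligned, product, proj, pos_map = best
        # unaligned (gapped) reference positions count as errors too, so a
        # sequence that "aligns" mostly through gaps is still rejected
        frac = (mism + (len(refseq) - n_aligned)) / len(refseq)
        if frac > max_mismatch_fraction:
            rejected.append(cid)
            continue
        parr = _seq_to_array(proj)

        def base_at(ref_pos: int) -> int | None:
            j = pos_map[ref_pos]
            return None if j < 0 else int(parr[j])

        row = np.full(n_sites, -1, dtype=np.int8)
        for k, r in enumerate(ref.cpg_rel):
            if product == "top":
                b = base_at(int(r))
                row[k] = 1 if b == _C else 0 if b == _T else -1
            else:
                b = base_at(int(r) + 1)
                row[k] = 1 if b == _G else 0 if b == _A else -1
        # conversion QC from non-CpG cytosines (guanines for bottom product)
        sites = nonCpG_c if product == "top" else nonCpG_g
        conv_base, unconv_base = (_T, _C) if product == "top" else (_A, _G)
        n_conv = n_tot = 0
        for i in sites:
            b = base_at(int(i))
            if b == conv_base:
                n_conv += 1
                n_tot += 1
            elif b == unconv_base:
                n_tot += 1
        ids.append(cid)
        rows.append(row)
        convs.append(n_conv / n_tot if n_tot else float("nan"))

    states = np.array(rows, dtype=np.int8).reshape(len(ids), n_sites)
    conv = np.array(convs)
    qc = np.where(np.isnan(conv), False, conv >= conversion_qc_threshold)
    return CloneMatrix(
        ref=ref, condition=condition, clone_ids=ids, states=states,
        conversion_efficiency=conv, qc_pass=qc, rejected=rejected,
    )


def per_site_summary(matrix_N: CloneMatrix, matrix_H: CloneMatrix) -> pd.DataFrame:
    """Per-site percent methylation in each condition with Fisher tests.

    Counts are QC-passing, unambiguous clone calls.  The two-sided Fisher
    exact test compares methylated/unmethylated clone counts N vs H per
    site.  Sites with zero unambiguous calls in a condition report NaN.
    """
    if matrix_N.ref.cpg_rel.shape != matrix_H.ref.cpg_rel.shape or not np.array_equal(
        matrix_N.ref.cpg_rel, matrix_H.ref.cpg_rel
    ):
        raise ValueError("clone matrices must share the same amplicon reference")
    mN, uN = matrix_N.site_counts()
    mH, uH = matrix_H.site_counts()
    labels = matrix_N.ref.labels or list(matrix_N.ref.cpg_rel)
    rows = []
    for k, lab in enumerate(labels):
        nN, nH = int(mN[k] + uN[k]), int(mH[k] + uH[k])
        pct_N = 100.0 * mN[k] / nN if nN else float("nan")
        pct_H = 100.0 * mH[k] / nH if nH else float("nan")
        if nN and nH:
            p = stats.fisher_exact(
                [[int(mN[k]), int(uN[k])], [int(mH[k]), int(uH[k])]]
            )[1]
        else:
            p = float("nan")
        rows.append((lab, pct_N, pct_H, nN, nH, p))
    return pd.DataFrame(
        rows, columns=["site_label", "pct_N", "pct_H", "n_N", "n_H", "fisher_p"]
    )


def grouped_site_summary(
    matrices: dict[str, list[CloneMatrix]]
) -> pd.DataFrame:
    """Experiment-grouped mean +/- SD per site, with Welch t-tests N vs H.

    ``matrices`` maps condition -> one CloneMatrix per independent
    experiment.  This reproduces a mean percentage methylation +/- SD
    presentation over experiments; the default pooled analysis is
    :func:`per_site_summary`.
    """
    pct = {c: np.vstack([m.per_site_percent for m in ms]) for c, ms in matrices.items()}
    ref = next(iter(matrices.values()))[0].ref
    labels = ref.labels or list(ref.cpg_rel)
    rows = []
    for k, lab in enumerate(labels):
        a, b = pct["N"][:, k], pct["H"][:, k]
        t = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            (lab, np.nanmean(a), np.nanstd(a, ddof=1), np.nanmean(b),
             np.nanstd(b, ddof=1), float(t.pvalue))
        )
    return pd.DataFrame(
        rows,
        columns=["site_label", "mean_N", "sd_N", "mean_H", "sd_H", "t_p"],
    )


def render_lollipop(matrix: CloneMatrix, methylated: str = "●",
                    unmethylated: str = "○", ambiguous: str = "?") -> str:
    """Text clone diagram: one row per clone (input order), one column per CpG."""
    sym = {1: methylated, 0: unmethylated, -1: ambiguous}
    width = max((len(c) for c in matrix.clone_ids), default=5)
    labels = matrix.ref.labels or list(matrix.ref.cpg_rel)
    lines = [" " * width + "  " + " ".join(str(l) for l in labels)]
    for cid, row in zip(matrix.clone_ids, matrix.states):
        lines.append(f"{cid:<{width}}  " + "".join(sym[int(v)] for v in row))
    return "\n".join(lines) + "\n"


def write_clone_matrix(matrix: CloneMatrix, path) -> None:
    df = matrix.to_frame()
    df.insert(0, "conversion_efficiency", np.round(matrix.conversion_efficiency, 4))
    df.insert(1, "qc_pass", matrix.qc_pass)
    df.to_csv(path, sep="\t", index_label="clone_id")
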
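"""Synthetic genomes, directional bisulfite reads, and bisulfite clone sets.

Everything downstream of this module (alignment, methylation extraction,
differential filtering, motif scanning, clone analysis) is tested against
data produced here, where the ground truth — the per-CpG methylation
probability of every cytosine, the bisulfite conversion rate, and the origin
of every read — is known exactly.

The simulated library is directional (Lister-style): reads come from the
bisulfite-converted original top strand (OT; unmethylated C appears as T)
and the bisulfite-converted original bottom strand (OB; relative to the
forward reference the conversion appears as G->A).  Complementary-strand
(PBAT-style) reads are not simulated.  Non-CpG cytosines are unmethylated by
default, which makes them usable for conversion-efficiency QC downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(x) for x in "ACGT")
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_x] = _y

CONDITIONS = ("N", "H")


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return _array_to_seq(_COMPLEMENT[_seq_to_array(seq)][::-1])


def cpg_positions(seq: str) -> np.ndarray:
    """0-based positions of the C of every CpG dinucleotide in ``seq``."""
    arr = _seq_to_array(seq)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G)).astype(np.int64)


# ---------------------------------------------------------------------------
# Synthetic genome
# ---------------------------------------------------------------------------

@dataclass
class PlantedHRE:
    """A hypoxia-response element written into a synthetic contig."""

    contig: str
    start: int           # 0-based start of the 5-mer
    orientation: str     # "forward" (RCGTG) or "reverse" (CACGY)

    @property
    def cpg_pos(self) -> int:
        """Forward-strand C position of the CpG inside the element."""
        return self.start + (1 if self.orientation == "forward" else 2)


@dataclass
class SyntheticGenome:
    """A toy reference genome with known planted HRE sites.

    ``cpg_index`` maps each contig name to the sorted 0-based positions of
    the forward-strand C of every CpG dinucleotide.
    """

    contigs: list[tuple[str, str]]
    planted_hre_sites: list[PlantedHRE] = field(default_factory=list)
    cpg_index: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cpg_index:
            self.cpg_index = {n: cpg_positions(s) for n, s in self.contigs}

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    def sequence(self, name: str) -> str:
        for n, s in self.contigs:
            if n == name:
                return s
        raise KeyError(name)

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "SyntheticGenome":
        from Bio import SeqIO

        contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(contigs=contigs)


def simulate_genome(
    n_contigs: int = 1,
    contig_length: int = 50_000,
    gc_fraction: float = 0.41,
    n_planted_hre: int = 20,
    rng_seed: int = 0,
    max_attempts_per_site: int = 200,
) -> SyntheticGenome:
    """Random genome with ``n_planted_hre`` non-overlapping HRE elements.

    Each planted element is either a forward RCGTG (R = G or A) or a
    reverse-orientation CACGY (Y = C or T) 5-mer written over the random
    background; both orientations contain a central CpG.  The background is
    i.i.d. with the requested GC fraction.  Deterministic for a fixed seed.
    """
    if contig_length < 1000:
        raise ValueError("contig_length must be >= 1000")
    if n_planted_hre * 5 * 4 > n_contigs * contig_length:
        raise ValueError("too many planted sites for the requested genome size")
    rng = np.random.default_rng(rng_seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    contigs: list[tuple[str, str]] = []
    planted: list[PlantedHRE] = []
    # split sites as evenly as possible over the contigs
    per_contig = [n_planted_hre // n_contigs] * n_contigs
    for i in range(n_planted_hre % n_contigs):
        per_contig[i] += 1
    for ci in range(n_contigs):
        name = f"chrS{ci + 1}"
        arr = rng.choice(_BASES, size=contig_length, p=p)
        taken: list[tuple[int, int]] = []
        for _ in range(per_contig[ci]):
            placed = False
            for _att in range(max_attempts_per_site):
                start = int(rng.integers(0, contig_length - 5 + 1))
                if any(start < e and start + 5 > s for s, e in taken):
                    continue
                orientation = "forward" if rng.random() < 0.5 else "reverse"
                if orientation == "forward":
                    r = _G if rng.random() < 0.5 else _A
                    motif = np.array([r, _C, _G, _T, _G], dtype=np.uint8)
                else:
                    y = _C if rng.random() < 0.5 else _T
                    motif = np.array([_C, _A, _C, _G, y], dtype=np.uint8)
                arr[start : start + 5] = motif
                taken.append((start, start + 5))
                planted.append(PlantedHRE(name, start, orientation))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place planted HRE site in {name} after "
                    f"{max_attempts_per_site} attempts"
                )
        contigs.append((name, _array_to_seq(arr)))
    return SyntheticGenome(contigs=contigs, planted_hre_sites=planted)


# ---------------------------------------------------------------------------
# Ground-truth methylation model
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Planted methylation probabilities and simulator parameters.

    ``site_probs`` maps (contig, cpg_pos, condition) to a methylation
    probability; CpGs absent from the map fall back to
    ``default_prob[condition]``.  ``conversion_rate`` is the probability that
    an *unmethylated* cytosine is deaminated by the bisulfite treatment
    (methylated cytosines are never converted).
    """

    site_probs: dict[tuple[str, int, str], float] = field(default_factory=dict)
    default_prob: dict[str, float] = field(default_factory=lambda: {"N": 0.8, "H": 0.8})
    non_cpg_meth_prob: float = 0.0
    conversion_rate: float = 0.99
    read_length: int = 100
    target_coverage: float = 30.0
    seq_error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for v in list(self.site_probs.values()) + list(self.default_prob.values()):
            if not 0.0 <= v <= 1.0:
                raise ValueError("methylation probabilities must lie in [0, 1]")
        if not 0.0 <= self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate must lie in [0, 1]")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.target_coverage <= 0:
            raise ValueError("target_coverage must be > 0")

    def prob(self, contig: str, pos: int, condition: str) -> float:
        return self.site_probs.get((contig, pos, condition), self.default_prob[condition])

    def prob_array(self, genome: SyntheticGenome, contig: str, condition: str) -> np.ndarray:
        """Methylation probability of the CpG at each cpg_index position."""
        idx = genome.cpg_index[contig]
        return np.array([self.prob(contig, int(i), condition) for i in idx])

    def write_truth_table(self, genome: SyntheticGenome, path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tpos_0based\tcondition\tmeth_prob\n")
            for name in genome.names:
                for pos in genome.cpg_index[name]:
                    for cond in CONDITIONS:
                        fh.write(f"{name}\t{int(pos)}\t{cond}\t{self.prob(name, int(pos), cond)}\n")


# ---------------------------------------------------------------------------
# Directional bisulfite reads
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    name: str
    seq: str
    contig: str
    start: int          # 0-based forward-reference start of the fragment
    strand: str         # "OT" or "OB"


def n_reads_for(target_coverage: float, contig_length: int, read_length: int) -> int:
    """Read-count rule: ceil(coverage * contig_length / read_length)."""
    return math.ceil(target_coverage * contig_length / read_length)


def simulate_bisulfite_reads(
    genome: SyntheticGenome,
    truth: SimTruth,
    condition: str,
    _batch: int = 20_000,
) -> list[SimRead]:
    """Simulate directional WGBS reads for one condition.

    Per contig, ``ceil(target_coverage * L / read_length)`` single-end reads
    of fixed length are drawn with uniform start positions and a fair coin
    for strand of origin.  Every cytosine of the sampled strand is methylated
    with its site probability (CpG) or ``non_cpg_meth_prob``; unmethylated
    cytosines convert with probability ``conversion_rate``.  Uniform
    substitution errors are applied at ``seq_error_rate``.  Read names encode
    contig, 0-based fragment start, and strand of origin.

    The RNG is seeded from ``(truth.rng_seed, condition)`` so the two
    conditions draw independent but reproducible read sets.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if not genome.contigs:
        raise ValueError("empty genome")
    rl = truth.read_length
    rng = np.random.default_rng([truth.rng_seed, CONDITIONS.index(condition)])
    reads: list[SimRead] = []
    for name, seq in genome.contigs:
        arr = _seq_to_array(seq)
        L = arr.size
        if rl > L:
            raise ValueError(f"read_length {rl} exceeds contig length {L}")
        # per-position methylation probability, top strand (C sites) and
        # bottom strand (G sites; the G of a CpG carries the CpG's prob)
        p_top = np.zeros(L)
        p_top[arr == _C] = truth.non_cpg_meth_prob
        p_bot = np.zeros(L)
        p_bot[arr == _G] = truth.non_cpg_meth_prob
        idx = genome.cpg_index[name]
        site_p = truth.prob_array(genome, name, condition)
        p_top[idx] = site_p
        p_bot[idx + 1] = site_p

        n_reads = n_reads_for(truth.target_coverage, L, rl)
        starts_all = rng.integers(0, L - rl + 1, size=n_reads)
        is_ob_all = rng.random(n_reads) < 0.5
        offs = np.arange(rl)
        serial = 0
        for lo in range(0, n_reads, _batch):
            starts = starts_all[lo : lo + _batch]
            is_ob = is_ob_all[lo : lo + _batch]
            pos = starts[:, None] + offs
            frag = arr[pos]                                  # forward-strand bases
            # methylation probability per base of each fragment
            pmat = np.where(is_ob[:, None], p_bot[pos], p_top[pos])
            meth = rng.random(frag.shape) < pmat
            conv = rng.random(frag.shape) < truth.conversion_rate
            # OT rows: C -> T where unmethylated & converted
            ot_conv = (~is_ob[:, None]) & (frag == _C) & ~meth & conv
            # OB rows (forward projection): G -> A where unmethylated & converted
            ob_conv = is_ob[:, None] & (frag == _G) & ~meth & conv
            out = frag.copy()
            out[ot_conv] = _T
            out[ob_conv] = _A
            # sequencing error: uniform substitution to one of the other 3 bases
            if truth.seq_error_rate > 0:
                err = rng.random(out.shape) < truth.seq_error_rate
                if err.any():
                    shift = rng.integers(1, 4, size=int(err.sum()))
                    code = np.searchsorted(_BASES, out[err])
                    out[err] = _BASES[(code + shift) % 4]
            for r in range(out.shape[0]):
                row = out[r]
                if is_ob[r]:
                    row = _COMPLEMENT[row][::-1]  # emit the bottom strand 5'->3'
                strand = "OB" if is_ob[r] else "OT"
                reads.append(
                    SimRead(
                        name=f"{name}:{int(starts[r])}:{strand}:{serial}",
                        seq=_array_to_seq(row),
                        contig=name,
                        start=int(starts[r]),
                        strand=strand,
                    )
                )
                serial += 1
    return reads


def write_fastq(reads: list[SimRead], path) -> None:
    """Phred+33 FASTQ; all qualities Q40 ('I') — qualities are unused downstream."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# Bisulfite clone sets (Na-bisulfite amplicon sequencing)
# ---------------------------------------------------------------------------

@dataclass
class CloneSet:
    """Simulated bisulfite-PCR clones for one amplicon and condition.

    ``truth_matrix`` holds the drawn methylation state (1/0) for every clone
    at every CpG site of the amplicon, in amplicon order.
    """

    contig: str
    start: int
    end: int
    condition: str
    clones: list[tuple[str, str]]
    truth_matrix: np.ndarray
    cpg_rel: np.ndarray       # CpG C positions relative to amplicon start
    rng_seed: int = 0

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for cid, seq in self.clones:
                fh.write(f">{cid}\n{seq}\n")


def simulate_clones(
    genome: SyntheticGenome,
    amplicon: tuple[str, int, int],
    n_clones: int,
    per_cpg_probs,
    conversion_rate: float = 0.99,
    condition: str = "N",
    rng_seed: int = 0,
) -> CloneSet:
    """Independently bisulfite-converted top-strand copies of an amplicon.

    ``per_cpg_probs`` is either a scalar applied to every CpG or a sequence
    with one probability per CpG site in amplicon order.  Non-CpG cytosines
    are unmethylated and convert with ``conversion_rate``, so imperfect
    conversion leaves residual non-CpG Cs that downstream QC can detect.
    """
    contig, start, end = amplicon
    seq = genome.sequence(contig)[start:end]
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rel = cpg_positions(seq)
    # a trailing C whose G falls beyond the amplicon is not a scorable CpG site
    if rel.size == 0:
        raise ValueError("amplicon contains no CpG site")
    probs = np.broadcast_to(np.asarray(per_cpg_probs, dtype=float), (rel.size,)).copy()
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("per_cpg_probs must lie in [0, 1]")
    rng = np.random.default_rng([rng_seed, CONDITIONS.index(condition)])
    arr0 = _seq_to_array(seq)
    c_mask = arr0 == _C
    cpg_mask = np.zeros(arr0.size, dtype=bool)
    cpg_mask[rel] = True
    clones: list[tuple[str, str]] = []
    truth = np.zeros((n_clones, rel.size), dtype=np.int8)
    for k in range(n_clones):
        arr = arr0.copy()
        states = rng.random(rel.size) < probs
        truth[k] = states
        conv = rng.random(arr0.size) < conversion_rate
        # unmethylated CpG Cs and all non-CpG Cs convert with rate c
        unmeth = cpg_mask.copy()
        unmeth[rel[states]] = False
        to_t = c_mask & conv & (unmeth | ~cpg_mask)
        arr[to_t] = _T
        clones.append((f"clone_{condition}_{k + 1:02d}", _array_to_seq(arr)))
    return CloneSet(
        contig=contig,
        start=start,
        end=end,
        condition=condition,
        clones=clones,
        truth_matrix=truth,
        cpg_rel=rel,
        rng_seed=rng_seed,
    )


def make_promoter_amplicon(
    cpg_offsets,
    anchor_pos: int = 1000,
    pad: int = 30,
    gc_fraction: float = 0.5,
    rng_seed: int = 0,
) -> SyntheticGenome:
    """Build a one-contig genome whose only CpGs sit at given TSS offsets.

    ``cpg_offsets`` are signed positions relative to the anchor (negative =
    upstream), e.g. the twelve proximal-promoter sites -242..-81.  The
    background sequence is random but scrubbed of incidental CpGs so the
    amplicon's CpG ladder is exactly the requested one.  Useful for
    promoter-style clone simulations with labelled sites.
    """
    offsets = np.asarray(sorted(cpg_offsets), dtype=int)
    length = anchor_pos + pad + max(0, int(offsets.max()) if offsets.size else 0) + pad
    rng = np.random.default_rng(rng_seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    arr = rng.choice(_BASES, size=length, p=p)
    # scrub incidental CpGs: rewrite the G of any CpG to A
    for _ in range(4):
        bad = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
        if bad.size == 0:
            break
        arr[bad + 1] = _A
    abs_pos = anchor_pos + offsets
    if abs_pos.min() < 0 or abs_pos.max() + 1 >= length:
        raise ValueError("cpg_offsets fall outside the contig")
    arr[abs_pos] = _C
    arr[abs_pos + 1] = _G
    # planting the G may have created an upstream CpG (C at abs_pos-1 is fine,
    # but C right before our C would pair with it only if followed by G) —
    # ensure the base before each planted C is not C-with-G, and the planted G
    # is not followed so as to matter; a final scrub pass limited to
    # non-planted sites keeps the ladder exact.
    planted = set(abs_pos.tolist())
    bad = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
    for b in bad:
        if int(b) not in planted:
            arr[b] = _T
    return SyntheticGenome(contigs=[("promoter", _array_to_seq(arr))])
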
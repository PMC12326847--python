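"""Bisulfite mapping and methylation extraction against brute-force oracles."""

import numpy as np
import pytest

from hremeth import (
    BisulfiteIndex, MethylCall, ReadAlignment, SimTruth, SyntheticGenome,
    calls_to_frame, extract_methylation, map_bisulfite_read, map_reads,
    read_methylation_track, revcomp, simulate_bisulfite_reads, simulate_genome,
    write_methylation_track,
)


def _brute_force_best(read: str, genome: SyntheticGenome, max_mm: int):
    """Scan every offset of both converted spaces; None on tie/no-hit."""
    hits = []
    for contig, seq in genome.contigs:
        for space, query in (("CT", read.replace("C", "T")),
                             ("GA", revcomp(read).replace("G", "A"))):
            ref = seq.replace("C", "T") if space == "CT" else seq.replace("G", "A")
            for start in range(len(seq) - len(read) + 1):
                window = ref[start : start + len(read)]
                mm = sum(
                    1 for a, b in zip(window, query) if a != b or a == "N" or b == "N"
                )
                if mm <= max_mm:
                    hits.append((mm, contig, start, "OT" if space == "CT" else "OB"))
    if not hits:
        return None
    hits.sort(key=lambda h: h[0])
    if len(hits) > 1 and hits[0][0] == hits[1][0]:
        return None
    return hits[0]


def test_exact_read_maps_uniquely(toy_genome):
    seq = toy_genome.sequence("chrS1")
    read = seq[1200:1250].replace("C", "T")  # fully converted OT read
    index = BisulfiteIndex(toy_genome)
    aln = map_bisulfite_read("r1", read, index, max_mismatches=2)
    assert aln is not None and aln.unique
    assert (aln.contig, aln.start, aln.strand_origin) == ("chrS1", 1200, "OT")
    assert aln.n_mismatches == 0


def test_ambiguous_read_discarded():
    block = "ATGGATCCATTAGCAAGGACTACGATCAGGATCCATGCA"
    genome = SyntheticGenome(contigs=[("dup", block + "TTTTTTTTTT" + block)])
    index = BisulfiteIndex(genome, seed_len=10)
    assert map_bisulfite_read("r", block[:30], index, max_mismatches=0) is None


def test_invalid_characters_rejected(toy_genome):
    index = BisulfiteIndex(toy_genome)
    with pytest.raises(ValueError, match="non-ACGTN"):
        map_bisulfite_read("r", "ACGTXACGTGACGTGACGTG", index)


def test_mapper_agrees_with_brute_force_oracle():
    """On a <=5 kb genome the seed-and-verify search equals full enumeration."""
    g = simulate_genome(1, 3_000, 0.45, 3, rng_seed=13)
    truth = SimTruth(
        default_prob={"N": 0.6, "H": 0.6}, conversion_rate=0.98,
        read_length=60, target_coverage=1.5, seq_error_rate=0.01, rng_seed=21,
    )
    reads = simulate_bisulfite_reads(g, truth, "N")
    index = BisulfiteIndex(g)
    checked = 0
    for r in reads[:60]:
        got = map_bisulfite_read(r.name, r.seq, index, max_mismatches=2)
        want = _brute_force_best(r.seq, g, max_mm=2)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert (got.n_mismatches, got.contig, got.start, got.strand_origin) == want
            checked += 1
    assert checked >= 40


def test_simulated_reads_return_to_origin():
    g = simulate_genome(1, 20_000, 0.41, 10, rng_seed=4)
    truth = SimTruth(
        default_prob={"N": 0.8, "H": 0.8}, conversion_rate=1.0,
        read_length=80, target_coverage=2, seq_error_rate=0.0, rng_seed=6,
    )
    reads = simulate_bisulfite_reads(g, truth, "N")
    alns = map_reads(reads, g)
    ok = sum(
        1 for a in alns
        if a.read_id.split(":")[:3] == [a.contig, str(a.start), a.strand_origin]
    )
    assert len(alns) / len(reads) >= 0.99
    assert ok / len(alns) >= 0.99


def _tiny_genome():
    # one CpG at position 4 (C) / 5 (G)
    return SyntheticGenome(contigs=[("t", "ATTACGATTA")])


def _aln(seq, start, strand, rid="r"):
    fwd = seq if strand == "OT" else revcomp(seq)
    return ReadAlignment(rid, "t", start, strand, 0, True, fwd)


def test_extraction_voting_and_strand_merge():
    g = _tiny_genome()
    alns = []
    for i in range(7):
        alns.append(_aln("ATTACGATTA", 0, "OT", f"c{i}"))          # C over CpG
    for i in range(3):
        alns.append(_aln("ATTATGATTA", 0, "OT", f"t{i}"))          # T over CpG
    calls = extract_methylation(alns, g, "N")
    assert len(calls) == 1
    assert (calls[0].n_meth, calls[0].n_unmeth) == (7, 3)
    assert calls[0].level == pytest.approx(0.7)
    # add OB evidence: 5 reads keep the G (methylated), 5 read A (converted)
    for i in range(5):
        alns.append(_aln(revcomp("ATTACGATTA"), 0, "OB", f"g{i}"))
    for i in range(5):
        alns.append(_aln(revcomp("ATTACAATTA"), 0, "OB", f"a{i}"))
    merged = extract_methylation(alns, g, "N", merge_strands=True)
    assert (merged[0].n_meth, merged[0].n_unmeth) == (12, 8)
    assert merged[0].level == pytest.approx(0.6)
    per_strand = extract_methylation(alns, g, "N", merge_strands=False)
    assert {(c.strand, c.n_meth, c.n_unmeth) for c in per_strand} == {
        ("+", 7, 3), ("-", 5, 5)
    }


def test_unexpected_base_over_cpg_is_ignored():
    g = _tiny_genome()
    alns = [_aln("ATTAGGATTA", 0, "OT")]  # G over the CpG C: neither C nor T
    assert extract_methylation(alns, g, "N") == []


def test_count_conservation():
    """Sum of counts equals aligned read-bases over CpGs when none ignored."""
    g = simulate_genome(1, 4_000, 0.5, 4, rng_seed=2)
    truth = SimTruth(
        default_prob={"N": 0.5, "H": 0.5}, conversion_rate=1.0,
        read_length=70, target_coverage=8, seq_error_rate=0.0, rng_seed=3,
    )
    alns = map_reads(simulate_bisulfite_reads(g, truth, "N"), g)
    calls = extract_methylation(alns, g, "N")
    total = sum(c.coverage for c in calls)
    idx = g.cpg_index["chrS1"]
    informative = 0
    for a in alns:
        L = len(a.fwd_seq)
        if a.strand_origin == "OT":
            informative += int(np.sum((idx >= a.start) & (idx < a.start + L)))
        else:
            informative += int(np.sum((idx + 1 >= a.start) & (idx + 1 < a.start + L)))
    assert total == informative


def test_track_roundtrip_and_coordinates(tmp_path):
    calls = [MethylCall("chr1", 100, "N", 7, 3)]
    tsv, bg = tmp_path / "m.tsv", tmp_path / "m.bedGraph"
    write_methylation_track(calls, tsv, bedgraph_path=bg)
    line = tsv.read_text().splitlines()[1].split("\t")
    assert line[1] == "101" and float(line[6]) == pytest.approx(0.7)
    assert bg.read_text().splitlines()[0].split("\t")[:3] == ["chr1", "100", "101"]
    back = read_methylation_track(tsv, "N")
    assert [(c.contig, c.cpg_pos, c.n_meth, c.n_unmeth) for c in back] == [
        ("chr1", 100, 7, 3)
    ]


def test_track_roundtrip_many(tmp_path):
    rng = np.random.default_rng(0)
    calls = [
        MethylCall("chr1", int(p), "N", int(m), int(u))
        for p, m, u in zip(
            np.sort(rng.choice(100_000, 2_000, replace=False)),
            rng.integers(0, 50, 2_000),
            rng.integers(1, 50, 2_000),
        )
    ]
    path = tmp_path / "big.tsv"
    write_methylation_track(calls, path)
    back = read_methylation_track(path, "N")
    assert calls_to_frame(back).equals(calls_to_frame(calls))


def test_empty_track_write_rejected(tmp_path):
    with pytest.raises(ValueError):
        write_methylation_track([], tmp_path / "x.tsv")
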
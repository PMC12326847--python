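"""HRE motif scan, CpG deduplication, methylation attachment, TSS distances."""

import re

import numpy as np
import pandas as pd
from hypothesis import given, settings, strategies as st

from hremeth import (
    TSSRecord, annotate_tss_distance, attach_methylation, count_hre,
    dedup_to_hre_cpgs, join_conditions, classify_demethylated, MethylCall,
    read_tss_bed, revcomp, scan_hre, simulate_genome,
)


def regex_hre_cpgs(seq: str) -> set[int]:
    """Brute-force oracle: distinct CpG positions under either pattern."""
    seq = seq.upper()
    fwd = {m.start() + 1 for m in re.finditer("(?=[GA]CGTG)", seq)}
    rev = {m.start() + 2 for m in re.finditer("(?=CACG[CT])", seq)}
    return fwd | rev


def test_forward_match_forced_example():
    matches = scan_hre([("c", "TTGCGTGTT")])
    assert len(matches) == 1
    m = matches[0]
    assert (m.start, m.orientation, m.matched_sequence, m.cpg_pos) == (
        2, "forward", "GCGTG", 3
    )


def test_palindromic_ebox_counted_once():
    matches = scan_hre([("c", "CACGTG")])
    assert {(m.start, m.orientation) for m in matches} == {(1, "forward"), (0, "reverse")}
    assert all(m.cpg_pos == 2 for m in matches)
    cpgs = dedup_to_hre_cpgs(matches)
    assert len(cpgs) == 1 and len(cpgs[0].supporting_matches) == 2
    assert cpgs[0].hre_id == "c:3"


def test_two_disjoint_matches_two_cpgs():
    cpgs = dedup_to_hre_cpgs(scan_hre([("c", "GCGTGTTTTTCACGC")]))
    assert len(cpgs) == 2


def test_scan_matches_regex_oracle_and_ignores_n_and_case():
    rng = np.random.default_rng(31)
    seq = "".join(rng.choice(list("ACGT"), 50_000, p=[0.295, 0.205, 0.205, 0.295]))
    # lowercase a stretch, inject Ns
    seq = seq[:10_000] + seq[10_000:20_000].lower() + seq[20_000:]
    seq = seq[:5_000] + "N" * 50 + seq[5_050:]
    got = {h.cpg_pos for h in dedup_to_hre_cpgs(scan_hre([("c", seq)]))}
    assert got == regex_hre_cpgs(seq)
    assert all("N" not in m.matched_sequence for m in scan_hre([("c", seq)]))


@given(st.text(alphabet="ACGTNacgtn", max_size=200))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_scan_matches_regex_oracle_property(seq):
    """Scanner equals the regex oracle on arbitrary short sequences."""
    got = {h.cpg_pos for h in dedup_to_hre_cpgs(scan_hre([("c", seq)]))}
    assert got == regex_hre_cpgs(seq)


def test_dedup_idempotent_and_bounded():
    g = simulate_genome(1, 20_000, 0.5, 15, rng_seed=3)
    matches = scan_hre(g)
    cpgs = dedup_to_hre_cpgs(matches)
    assert len(cpgs) <= len(matches)
    assert len({(c.contig, c.cpg_pos) for c in cpgs}) == len(cpgs)
    assert count_hre(g, unit="cpg") == len(cpgs)
    assert count_hre(g, unit="match") == len(matches)
    planted = {(p.contig, p.cpg_pos) for p in g.planted_hre_sites}
    assert planted <= {(c.contig, c.cpg_pos) for c in cpgs}


def test_strand_closure_under_reverse_complement():
    g = simulate_genome(1, 10_000, 0.45, 10, rng_seed=17)
    seq = g.sequence("chrS1")
    fwd = {h.cpg_pos for h in dedup_to_hre_cpgs(scan_hre([("c", seq)]))}
    rc = {h.cpg_pos for h in dedup_to_hre_cpgs(scan_hre([("c", revcomp(seq))]))}
    # CpG C at p on the forward strand maps to C at L-2-p on the complement
    assert {len(seq) - 2 - p for p in rc} == fwd


def _dmc_from_levels(rows):
    """rows: (pos, n_meth_N, cov_N, n_meth_H, cov_H)."""
    calls_n = [MethylCall("c", p, "N", mn, cn - mn) for p, mn, cn, _, _ in rows]
    calls_h = [MethylCall("c", p, "H", mh, ch - mh) for p, _, _, mh, ch in rows]
    df, _ = classify_demethylated(join_conditions(calls_n, calls_h))
    return df


def test_attach_methylation_boundary_rows():
    # two HRE-CpGs: one at methdiff exactly 0.20 (not demethylated, strict
    # filter), one at 0.34 (demethylated); a third lacks any call
    seq = "TTGCGTGTTTTTTTTTTGCGTGTTTTTTTTTTGCGTGTT"
    cpgs = dedup_to_hre_cpgs(scan_hre([("c", seq)]))
    assert len(cpgs) == 3
    positions = [c.cpg_pos for c in cpgs]
    dmc = _dmc_from_levels(
        [
            (positions[0], 19, 20, 15, 20),   # 0.95 vs 0.75 -> 0.20
            (positions[1], 47, 50, 30, 50),   # 0.94 vs 0.60 -> 0.34
        ]
    )
    df, summary = attach_methylation(cpgs, dmc, min_coverage=5)
    by_pos = df.set_index("cpg_pos")
    assert not by_pos.loc[positions[0], "demethylated"]
    assert by_pos.loc[positions[1], "demethylated"]
    assert not by_pos.loc[positions[2], "covered"]
    assert np.isnan(by_pos.loc[positions[2], "m_N"])
    assert summary.n_total == 3 and summary.n_covered == 2 and summary.n_demethylated == 1
    assert summary.fraction_covered == 2 / 3


def test_pipeline_conservation_counts():
    g = simulate_genome(1, 15_000, 0.5, 10, rng_seed=8)
    cpgs = dedup_to_hre_cpgs(scan_hre(g))
    rng = np.random.default_rng(1)
    rows = []
    for c in cpgs[::2]:  # only half the HRE-CpGs receive calls
        cov = int(rng.integers(1, 40))
        rows.append((c.cpg_pos, int(rng.integers(0, cov + 1)), cov,
                     int(rng.integers(0, cov + 1)), cov))
    calls_n = [MethylCall(g.names[0], p, "N", mn, cn - mn) for p, mn, cn, _, _ in rows]
    calls_h = [MethylCall(g.names[0], p, "H", mh, ch - mh) for p, _, _, mh, ch in rows]
    dmc, _ = classify_demethylated(join_conditions(calls_n, calls_h))
    df, s = attach_methylation(cpgs, dmc)
    assert s.n_demethylated <= s.n_covered <= s.n_total
    assert s.fraction_covered == s.n_covered / s.n_total


def _hre_frame(rows):
    return pd.DataFrame(rows, columns=["contig", "cpg_pos", "hre_id"])


def test_tss_distance_annotation():
    hre = _hre_frame([("c", 9_300, "c:9301"), ("c", 10_000, "c:10001"),
                      ("d", 100, "d:101")])
    tss = [
        TSSRecord("GENE1", "c", 10_000, "+"),
        TSSRecord("GENE2", "c", 62_000, "+"),
    ]
    out = annotate_tss_distance(hre, tss).set_index("hre_id")
    assert out.loc["c:9301", "nearest_gene"] == "GENE1"
    assert out.loc["c:9301", "distance_kb"] == 0.7
    assert out.loc["c:9301", "orientation"] == "upstream"
    assert out.loc["c:10001", "distance_kb"] == 0.0
    assert out.loc["c:10001", "orientation"] == "tss"
    assert out.loc["d:101", "orientation"] == "NA"


def test_tss_nearest_and_ties():
    hre = _hre_frame([("c", 5_000, "c:5001")])
    tss = [
        TSSRecord("FAR", "c", 57_000, "+"),
        TSSRecord("NEAR", "c", 6_000, "-"),
    ]
    out = annotate_tss_distance(hre, tss)
    assert out.nearest_gene.iloc[0] == "NEAR"
    assert out.distance_kb.iloc[0] == 1.0
    # '-' strand gene with the CpG before the TSS coordinate: downstream
    assert out.orientation.iloc[0] == "downstream"
    tie = [TSSRecord("B", "c", 4_000, "+"), TSSRecord("A", "c", 6_000, "+")]
    assert annotate_tss_distance(hre, tie).nearest_gene.iloc[0] == "A"


def test_read_tss_bed(tmp_path):
    path = tmp_path / "tss.bed"
    path.write_text("c\t1000\t5000\tGENEA\t0\t+\nc\t2000\t7000\tGENEB\t0\t-\n")
    recs = read_tss_bed(path)
    assert [(r.gene, r.tss_pos, r.strand) for r in recs] == [
        ("GENEA", 1000, "+"), ("GENEB", 6999, "-")
    ]
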
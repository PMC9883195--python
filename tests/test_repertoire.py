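import numpy as np
import pytest

from pairtcr.errors import InvariantError
from pairtcr.repertoire import (
    BIN_LABELS,
    BinThresholds,
    ClonotypeTable,
    bin_clonotypes,
    bin_composition,
    call_clonotypes,
    cell_bin_labels,
    compute_frequencies,
    rank_clonotypes,
)

from conftest import make_contig


def freq_table(freqs, sample_id="s"):
    """ClonotypeTable with given frequencies (counts faked to match)."""
    t = ClonotypeTable(sample_id=sample_id)
    from pairtcr.repertoire import ClonotypeEntry

    for i, f in enumerate(freqs):
        key = f"k{i:05d}"
        t.entries[key] = ClonotypeEntry(key=key, barcodes=[f"b{i}"],
                                        clone_count=1, frequency=f)
    return t


def brute_force_bin(f):
    """Independent interval-membership oracle over the stated (lo, hi] bins."""
    intervals = [
        ("hyperexpanded", 0.1, 1.0),
        ("large", 0.01, 0.1),
        ("medium", 0.001, 0.01),
        ("small", 1e-4, 0.001),
        ("rare", 0.0, 1e-4),
    ]
    for name, lo, hi in intervals:
        if lo < f <= hi:
            return name
    raise AssertionError(f)


class TestCallClonotypes:
    def test_identical_chains_merge(self):
        recs = []
        for bc in ("A-1", "B-1"):
            recs.append(make_contig(barcode=bc, chain="TRA"))
            recs.append(make_contig(barcode=bc, chain="TRB",
                                    cdr3_nt="TGTAGTTTT", cdr3_aa="CSF",
                                    v_gene="TRBV3", j_gene="TRBJ4"))
        t = call_clonotypes(recs)
        assert len(t.entries) == 1
        (entry,) = t.entries.values()
        assert entry.clone_count == 2
        assert entry.n_chains == 2

    def test_top_umi_rule(self):
        winner = make_contig(chain="TRB", umis=5, cdr3_nt="TGTAAATTT")
        loser = make_contig(chain="TRB", umis=2, cdr3_nt="TGTCCCTTT")
        t = call_clonotypes([loser, winner])
        (entry,) = t.entries.values()
        assert "TGTAAATTT" in entry.key
        assert "TGTCCCTTT" not in entry.key

    def test_tie_breaks_reads_then_lexicographic(self):
        a = make_contig(chain="TRB", umis=5, reads=50, cdr3_nt="TGTCCCTTT")
        b = make_contig(chain="TRB", umis=5, reads=90, cdr3_nt="TGTGGGTTT")
        (entry,) = call_clonotypes([a, b]).entries.values()
        assert "TGTGGGTTT" in entry.key  # higher reads wins
        c = make_contig(chain="TRB", umis=5, reads=50, cdr3_nt="TGTAAATTT")
        (entry,) = call_clonotypes([a, c]).entries.values()
        assert "TGTAAATTT" in entry.key  # then lexicographically smaller

    def test_filters_low_quality_records(self):
        recs = [
            make_contig(productive=False),
            make_contig(is_cell=False),
            make_contig(high_confidence=False),
            make_contig(chain="Multi"),
            make_contig(chain="None"),
        ]
        assert call_clonotypes(recs).entries == {}

    def test_single_chain_flagged(self):
        t = call_clonotypes([make_contig(chain="TRA")])
        (entry,) = t.entries.values()
        assert entry.n_chains == 1

    def test_empty_input_empty_table(self):
        assert call_clonotypes([]).entries == {}

    def test_matches_brute_force_grouping_oracle(self):
        rng = np.random.default_rng(11)
        recs = []
        for _ in range(500):
            bc = f"B{int(rng.integers(0, 120)):03d}-1"
            chain = rng.choice(["TRA", "TRB"])
            recs.append(
                make_contig(
                    barcode=bc, chain=str(chain),
                    v_gene=f"{chain}V{int(rng.integers(1, 4))}",
                    j_gene=f"{chain}J{int(rng.integers(1, 4))}",
                    cdr3_nt="TGT" + "".join(
                        rng.choice(list("ACGT"), 6)) + "TTT",
                    umis=int(rng.integers(1, 10)),
                    reads=int(rng.integers(10, 100)),
                )
            )
        got = call_clonotypes(recs)

        # oracle: explicit sort-and-group over full chain tuples
        best = {}
        for r in recs:
            k = (r.barcode, r.chain)
            cur = best.get(k)
            if cur is None or (r.umis, r.reads, [-ord(c) for c in r.cdr3_nt]) > \
                    (cur.umis, cur.reads, [-ord(c) for c in cur.cdr3_nt]):
                best[k] = r
        groups = {}
        for (bc, _), r in best.items():
            groups.setdefault(bc, []).append(
                f"{r.chain}:{r.v_gene}:{r.j_gene}:{r.cdr3_nt}")
        oracle_keys = {}
        for bc, chains in groups.items():
            oracle_keys.setdefault("|".join(sorted(chains)), []).append(bc)
        assert set(got.entries) == set(oracle_keys)
        for k, e in got.entries.items():
            assert sorted(e.barcodes) == sorted(oracle_keys[k])


class TestBinning:
    def test_paper_boundary_examples(self):
        thr = BinThresholds()
        assert thr.classify(0.5) == "hyperexpanded"
        assert thr.classify(0.005) == "medium"
        assert thr.classify(5e-5) == "rare"
        assert thr.classify(0.1) == "large"     # boundary falls in lower bin
        assert thr.classify(1.0) == "hyperexpanded"

    def test_invalid_frequency_rejected(self):
        thr = BinThresholds()
        for f in (0.0, -0.1, 1.5):
            with pytest.raises(InvariantError):
                thr.classify(f)

    def test_thresholds_must_increase(self):
        with pytest.raises(InvariantError):
            BinThresholds(small_hi=1e-5)

    def test_matches_interval_oracle_on_random_frequencies(self):
        rng = np.random.default_rng(0)
        freqs = np.concatenate([
            10 ** rng.uniform(-5, 0, size=2000),
            np.array([1e-4, 0.001, 0.01, 0.1, 1.0]),
        ])
        thr = BinThresholds()
        for f in freqs:
            assert thr.classify(float(f)) == brute_force_bin(float(f))

    def test_frequencies_and_requirement(self):
        t = freq_table([None])
        t.entries["k00000"].frequency = None
        with pytest.raises(InvariantError):
            bin_clonotypes(t)


class TestCellBinLabels:
    def test_cells_inherit_clonotype_bin(self):
        t = freq_table([0.06, 0.04] + [0.9])
        t.entries["k00000"].barcodes = ["b0", "bx", "by"]
        t.entries["k00000"].clone_count = 3
        binned = bin_clonotypes(compute_frequencies(
            _with_counts(t, {"k00000": 3, "k00001": 2, "k00002": 45})))
        labels = cell_bin_labels(binned, ["b0", "bx", "by", "b1", "mac"])
        assert labels["b0"] == labels["bx"] == labels["by"]
        assert labels["mac"] == "none"

    def test_orphan_excluded(self, caplog):
        t = bin_clonotypes(compute_frequencies(freq_table([1.0])))
        labels = cell_bin_labels(t, ["other"])
        assert labels == {"other": "none"}


def _with_counts(t, counts):
    for k, c in counts.items():
        t.entries[k].clone_count = c
    return t


class TestRanking:
    def test_descending_order(self):
        t = freq_table([0.5, 0.3, 0.2])
        ranked = rank_clonotypes(t)
        assert [e.frequency for e in ranked] == [0.5, 0.3, 0.2]

    def test_tie_breaks_lexicographically(self):
        t = freq_table([0.5, 0.5])
        ranked = rank_clonotypes(t)
        assert [e.key for e in ranked] == ["k00000", "k00001"]

    def test_rank_list_is_permutation(self):
        rng = np.random.default_rng(4)
        f = rng.dirichlet(np.ones(30))
        t = freq_table(list(f))
        ranked = rank_clonotypes(t)
        assert sorted(e.key for e in ranked) == sorted(t.entries)


class TestBinComposition:
    def test_single_sample_shares(self):
        t = ClonotypeTable(sample_id="s")
        from pairtcr.repertoire import ClonotypeEntry

        for key, n in (("a", 6), ("b", 3), ("c", 1)):
            t.entries[key] = ClonotypeEntry(
                key=key, barcodes=[f"{key}{i}" for i in range(n)], clone_count=n
            )
        binned = bin_clonotypes(compute_frequencies(t))
        clono, cells = bin_composition({"s": binned},
                                       {"s": ("tumor_d15", "normal")})
        row = cells.loc[("tumor_d15", "normal")]
        assert row["hyperexpanded"] == pytest.approx(90.0)  # 6 and 3 of 10
        assert row["large"] == pytest.approx(10.0)
        crow = clono.loc[("tumor_d15", "normal")]
        assert crow["hyperexpanded"] == pytest.approx(200.0 / 3)
        assert crow["large"] == pytest.approx(100.0 / 3)

    def test_sample_order_invariance_and_row_sums(self, planted_cohort):
        _, cohort = planted_cohort
        tables = {
            sid: bin_clonotypes(compute_frequencies(
                call_clonotypes(s.contigs, sid)))
            for sid, s in cohort.samples.items()
        }
        strata = {sid: (s.tissue, s.group) for sid, s in cohort.samples.items()}
        a = bin_composition(tables, strata)
        rev = dict(reversed(list(tables.items())))
        b = bin_composition(rev, strata)
        assert a[0].equals(b[0]) and a[1].equals(b[1])
        for df in a:
            assert np.allclose(df.sum(axis=1), 100.0, atol=1e-9)

    def test_matches_manifest_recount(self, planted_cohort):
        # brute-force recount of cell-level bins from planted clone sizes
        _, cohort = planted_cohort
        tables = {
            sid: bin_clonotypes(compute_frequencies(
                call_clonotypes(s.contigs, sid)))
            for sid, s in cohort.samples.items()
        }
        strata = {sid: (s.tissue, s.group) for sid, s in cohort.samples.items()}
        _, cells = bin_composition(tables, strata)

        from collections import defaultdict

        expect = defaultdict(lambda: defaultdict(int))
        manifest = cohort.manifest
        for sid, sizes in manifest.clone_sizes.items():
            s = cohort.samples[sid]
            # T-compartment cells per planted clone; macrophage recipients add
            # their donor clone's key on top
            cellrows = manifest.cells[manifest.cells["sample"] == sid]
            member_counts = cellrows[cellrows["clonotype_id"] != ""][
                "clonotype_id"].value_counts()
            total = int(member_counts.sum())
            thr = BinThresholds()
            for cid, n in member_counts.items():
                expect[(s.tissue, s.group)][thr.classify(n / total)] += int(n)
        for stratum, counts in expect.items():
            total = sum(counts.values())
            for b in BIN_LABELS:
                assert cells.loc[stratum, b] == pytest.approx(
                    counts.get(b, 0) / total * 100.0)


def test_merging_samples_preserves_within_sample_bins(planted_cohort):
    _, cohort = planted_cohort
    sids = sorted(cohort.samples)[:2]
    t0 = bin_clonotypes(compute_frequencies(
        call_clonotypes(cohort.samples[sids[0]].contigs, sids[0])))
    merged_contigs = (cohort.samples[sids[0]].contigs
                      + cohort.samples[sids[1]].contigs)
    # per-sample calling is unchanged by other samples' contigs existing
    again = bin_clonotypes(compute_frequencies(
        call_clonotypes(cohort.samples[sids[0]].contigs, sids[0])))
    assert {k: e.bin for k, e in t0.entries.items()} == \
        {k: e.bin for k, e in again.entries.items()}
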
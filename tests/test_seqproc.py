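"""Sequence processing: demultiplexing, filtering, haplotype collapse,
MOTU clustering (with a brute-force reference), threshold selection and
taxonomic assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietlink as dl
from dietlink import pairwise_identity
from dietlink.seqproc import (
    DEFAULT_THRESHOLD_GRID,
    HaplotypeTable,
    cluster_motus,
    flag_chimeras,
)
from dietlink.synthdata import FORWARD_PRIMER, REVERSE_PRIMER, reverse_complement

SEQ = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _make_read(fmid, rmid, template):
    return fmid + FORWARD_PRIMER + template + reverse_complement(REVERSE_PRIMER) + reverse_complement(rmid)


class TestDemultiplex:
    @pytest.fixture()
    def registry(self):
        mids_f = dl.generate_mids(3, seed=1)
        mids_r = dl.generate_mids(3, seed=2)
        pairs = {(f, r): f"ind_{i}_{j}" for i, f in enumerate(mids_f) for j, r in enumerate(mids_r)}
        return mids_f, mids_r, pairs

    def test_exact_mids_assigned_and_trimmed(self, registry):
        mids_f, mids_r, pairs = registry
        template = "ACGT" * 20
        reads = [("r1", _make_read(mids_f[1], mids_r[2], template))]
        assigned, unassigned = dl.demultiplex(reads, pairs, forward_primer=FORWARD_PRIMER, reverse_primer=REVERSE_PRIMER)
        assert assigned["ind_1_2"] == [template]
        assert not unassigned

    def test_unregistered_mid_goes_to_unassigned(self, registry):
        mids_f, mids_r, pairs = registry
        rogue = "TTTTTTTTTT"
        assert rogue not in mids_f
        reads = [("r1", _make_read(rogue, mids_r[0], "ACGT" * 20))]
        assigned, unassigned = dl.demultiplex(reads, pairs, forward_primer=FORWARD_PRIMER, reverse_primer=REVERSE_PRIMER)
        assert len(unassigned) == 1
        assert all(not v for v in assigned.values())

    def test_duplicate_individual_rejected(self, registry):
        mids_f, mids_r, _ = registry
        pairs = {(mids_f[0], mids_r[0]): "x", (mids_f[0], mids_r[1]): "x"}
        with pytest.raises(ValueError):
            dl.demultiplex([], pairs, forward_primer=FORWARD_PRIMER, reverse_primer=REVERSE_PRIMER)

    def test_error_free_batch_fully_recovered(self, error_free_run):
        """With no sequencing errors every read lands on its true individual."""
        batch = error_free_run["batch"]
        assigned, unassigned = dl.demultiplex(batch)
        assert not unassigned
        truth_counts = batch.truth.groupby("individual_id").size()
        for ind, n in truth_counts.items():
            assert len(assigned[ind]) == n


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,kept",
        [(259, False), (260, True), (280, True), (300, True), (301, False)],
    )
    def test_inclusive_bounds(self, length, kept):
        out = dl.length_filter(["A" * length])
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        assert dl.length_filter([]) == []

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            dl.length_filter([], min_len=300, max_len=260)


class TestCollapseHaplotypes:
    def test_rare_haplotypes_dropped(self):
        table = dl.collapse_haplotypes({"ind": ["AAA"] * 3 + ["AAT"]})
        assert table.per_individual == {"ind": {"AAA": 3}}

    def test_threshold_copies_kept(self):
        table = dl.collapse_haplotypes({"ind": ["AAA", "AAA", "AAT", "AAT"]})
        assert table.per_individual["ind"] == {"AAA": 2, "AAT": 2}

    def test_all_singletons_empty(self):
        table = dl.collapse_haplotypes({"ind": ["AAA", "AAT", "ATT"]})
        assert "ind" not in table.per_individual
        assert table.n_haplotypes == 0


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("A" * 100, "A" * 100) == 1.0

    def test_five_substitutions(self):
        """Five scattered substitutions in a 100-mer, where the gapless
        alignment is optimal, give identity exactly 0.95."""
        rng = np.random.default_rng(42)
        a = "".join(rng.choice(list("ACGT"), 100))
        b = list(a)
        for p in (10, 30, 50, 70, 90):
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        assert pairwise_identity(a, "".join(b)) == pytest.approx(0.95)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=SEQ, b=SEQ)
    def test_symmetry_and_bounds(self, a, b):
        x = pairwise_identity(a, b)
        assert x == pairwise_identity(b, a)
        assert 0.0 <= x <= 1.0


def _brute_force_cluster(pooled, threshold):
    """Reference clustering: same defined processing order, assignment of
    each haplotype to the first qualifying centroid, written independently
    as straight-line code over explicit lists."""
    order = sorted(pooled, key=lambda x: (-x[1], x[0]))
    centroids, membership = [], {}
    for seq, total, _ in order:
        target = None
        for c in centroids:
            if pairwise_identity(seq, c) >= threshold:
                target = c
                break
        if target is None:
            centroids.append(seq)
            membership[seq] = seq
        else:
            membership[seq] = target
    return centroids, membership


def _table_from_seqs(seqs_with_counts):
    return HaplotypeTable(per_individual={"ind": dict(seqs_with_counts)}, min_copies=1)


class TestClusterMOTUs:
    def _two_seqs_at(self, identity_target=0.90, length=100):
        rng = np.random.default_rng(7)
        a = "".join(rng.choice(list("ACGT"), length))
        n_diff = round((1 - identity_target) * length)
        b = list(a)
        for p in np.linspace(3, length - 4, n_diff).astype(int):  # scattered
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        b = "".join(b)
        assert pairwise_identity(a, b) == pytest.approx(identity_target)
        return a, b

    def test_threshold_splits_and_merges(self):
        a, b = self._two_seqs_at(0.90)
        table = _table_from_seqs([(a, 5), (b, 3)])
        assert cluster_motus(table, 0.89).n_motus == 1
        assert cluster_motus(table, 0.92).n_motus == 2

    def test_single_haplotype(self):
        table = _table_from_seqs([("ACGT" * 30, 4)])
        out = cluster_motus(table, 0.95)
        assert out.n_motus == 1
        assert out.clusters[0].representative == "ACGT" * 30

    def test_input_order_invariance(self, small_db):
        seqs = [(r.sequence, i + 2) for i, r in enumerate(small_db.records[:8])]
        t1 = cluster_motus(_table_from_seqs(seqs), 0.95)
        t2 = cluster_motus(_table_from_seqs(list(reversed(seqs))), 0.95)
        assert [c.representative for c in t1.clusters] == [c.representative for c in t2.clusters]

    @pytest.mark.parametrize("threshold", [0.88, 0.92, 0.97])
    def test_matches_brute_force_reference(self, small_db, threshold):
        """Greedy clustering agrees with an independent straight-line
        reference on up to 8 haplotypes."""
        rng = np.random.default_rng(3)
        seqs = [(r.sequence, int(rng.integers(1, 20))) for r in small_db.records[:8]]
        table = _table_from_seqs(seqs)
        got = cluster_motus(table, threshold)
        pooled = table.pooled()
        ref_centroids, ref_membership = _brute_force_cluster(pooled, threshold)
        assert [c.representative for c in got.clusters] == ref_centroids
        got_membership = {seq: c.representative for c in got.clusters for seq, _, _ in c.members}
        assert got_membership == ref_membership

    def test_motu_count_monotone_in_threshold(self, error_free_run):
        """Lowering the similarity threshold never increases the MOTU count."""
        assigned, _ = dl.demultiplex(error_free_run["batch"])
        haplos = dl.collapse_haplotypes(dl.length_filter(assigned))
        counts = [cluster_motus(haplos, t).n_motus for t in DEFAULT_THRESHOLD_GRID]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_every_haplotype_in_exactly_one_motu(self, small_db):
        seqs = [(r.sequence, 2) for r in small_db.records]
        table = _table_from_seqs(seqs)
        out = cluster_motus(table, 0.95)
        members = [seq for c in out.clusters for seq, _, _ in c.members]
        assert sorted(members) == sorted(s for s, _ in seqs)
        for c in out.clusters:
            assert c.representative in [seq for seq, _, _ in c.members]


class TestAssignTaxonomy:
    def test_exact_match_assigned_at_species(self, small_db):
        rec = next(r for r in small_db.records if not r.is_predator and not r.is_contaminant)
        out = dl.assign_taxonomy({"m1": rec.sequence}, small_db)
        a = out["m1"]
        assert a.status == "assigned" and a.taxon == rec.taxon_id
        assert a.rank == "species" and a.identity == 1.0

    def test_distant_sequence_no_match(self, small_db):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 287))
        out = dl.assign_taxonomy({"m1": junk}, small_db)
        assert out["m1"].status == "no_match"

    def test_contaminant_flagged(self, small_db):
        rec = next(r for r in small_db.records if r.is_contaminant)
        out = dl.assign_taxonomy({"m1": rec.sequence}, small_db)
        assert out["m1"].status == "contaminant"

    def test_below_threshold_not_assigned(self, small_db):
        rec = small_db.records[0]
        seq = list(rec.sequence)
        rng = np.random.default_rng(1)
        for p in rng.choice(len(seq), 12, replace=False):  # ~4% divergence
            seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        out = dl.assign_taxonomy({"m1": "".join(seq)}, small_db)
        assert out["m1"].status == "no_match"


class TestSelectThreshold:
    def test_low_within_divergence_gives_high_threshold(self, small_db):
        """1% within-taxon / 10% between-taxon divergence: every high
        threshold yields zero split species, so the tie-break picks 0.97."""
        haplos = HaplotypeTable(
            per_individual={"ind": {r.sequence: 3 for r in small_db.records if not r.is_contaminant}},
            min_copies=1,
        )
        t_opt, diag = dl.select_threshold(haplos, small_db)
        assert t_opt == 0.97
        high = diag.table[diag.table["threshold"] >= 0.95]
        assert (high["species_with_multiple_motus"] == 0).all()

    def test_high_within_divergence_needs_lower_threshold(self):
        """8% within-taxon divergence: conspecific haplotypes only merge at
        low thresholds, and the split-species count is non-increasing as
        the threshold drops."""
        db = dl.generate_reference_db(
            4, haplotypes_per_taxon=3, between_taxon_divergence=0.25, within_taxon_divergence=0.08, seed=5
        )
        haplos = HaplotypeTable(
            per_individual={"ind": {r.sequence: 2 for r in db.records if not r.is_contaminant and not r.is_predator}},
            min_copies=1,
        )
        t_opt, diag = dl.select_threshold(haplos, db)
        multi = diag.table.sort_values("threshold", ascending=False)["species_with_multiple_motus"].to_numpy()
        assert (np.diff(multi) <= 0).all()
        assert multi[0] > 0  # 0.97 splits species
        assert t_opt < 0.97

    def test_single_taxon_input(self, small_db):
        rec = small_db.records[0]
        haplos = HaplotypeTable(per_individual={"ind": {rec.sequence: 5}}, min_copies=1)
        t_opt, diag = dl.select_threshold(haplos, small_db)
        assert t_opt == max(DEFAULT_THRESHOLD_GRID)
        assert (diag.table["species_with_multiple_motus"] == 0).all()
        assert (diag.table["n_species_assignments"] == 1).all()

    def test_empty_input_rejected(self, small_db):
        with pytest.raises(ValueError):
            dl.select_threshold(HaplotypeTable(per_individual={}), small_db)


def test_chimera_flagging(small_db):
    a, b = (r.sequence for r in small_db.records[:1] + small_db.records[2:3])
    assert small_db.records[0].taxon_id != small_db.records[2].taxon_id
    chimera = a[: len(a) // 2] + b[len(b) // 2 :]
    flagged = flag_chimeras({"m1": chimera, "m2": a}, small_db)
    assert flagged == {"m1"}


def test_pipeline_recovers_truth_detections(error_free_run):
    """On an error-free simulation the per-individual taxon detections equal
    the ground-truth consumed sets exactly."""
    det = error_free_run["detections"]
    det = det[det["status"] == "assigned"]
    got = det.groupby("individual_id")["taxon"].agg(set).to_dict()
    for g in error_free_run["guts"]:
        assert got.get(g.individual_id, set()) == set(g.consumed)
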
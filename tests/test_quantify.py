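"""Alignment, arm/loop consistency filtering, count assignment, novel
naming, and cascade classification."""

import numpy as np
import pandas as pd
import pytest

from plasmamir.hairpin import MatureAnnotation
from plasmamir.quantify import (
    PrecursorAlignment,
    align_to_precursors,
    assign_counts,
    cascade_classify,
    hairpin_consistency_filter,
    name_novel,
    quantify_samples,
)
from plasmamir.readprep import CollapsedRead
from plasmamir.simulate import make_hairpins, simulate_reads, study_metadata

from conftest import brute_force_hamming_hits


class TestAlign:
    def test_exact_substring_hit(self, catalog):
        p = next(iter(catalog))
        read = p.sequence[3:24]
        hits = align_to_precursors([read], catalog)
        mine = [h for h in hits if h.precursor_id == p.id and h.offset == 3]
        assert mine and mine[0].mismatches == 0

    def test_two_mismatches_not_reported(self, small_catalog):
        p = small_catalog["hpA"]
        read = list(p.sequence[0:21])
        for k in (2, 9):
            read[k] = {"A": "C", "C": "A", "G": "U", "U": "G"}[read[k]]
        assert align_to_precursors(["".join(read)], small_catalog) == []

    def test_exact_hit_preference_drops_mismatch_hits(self, small_catalog):
        p = small_catalog["hpA"]
        read = p.sequence[0:21]
        hits = align_to_precursors([read], small_catalog)
        assert all(h.mismatches == 0 for h in hits)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_brute_force_oracle(self, seed):
        """All-hits aligner == exhaustive Hamming scan, 50 reads x 20 hairpins."""
        rng = np.random.default_rng(seed)
        truth = make_hairpins(20, seed=rng)
        cat = truth.catalog
        reads = []
        for _ in range(50):
            p = truth.records[rng.integers(len(truth.records))]
            start = int(rng.integers(0, len(p[1]) - 22))
            read = list(p[1][start:start + 22])
            for _ in range(rng.integers(0, 2)):
                k = int(rng.integers(len(read)))
                read[k] = str(rng.choice([c for c in "ACGU" if c != read[k]]))
            reads.append("".join(read))
        hits = align_to_precursors(reads, cat, max_mismatch=1)
        got = {}
        for h in hits:
            got.setdefault(h.read_sequence, set()).add(
                (h.precursor_id, h.offset, h.mismatches)
            )
        for read in set(reads):
            oracle = brute_force_hamming_hits(read, cat, 1)
            if any(mm == 0 for _, _, mm in oracle):
                oracle = [h for h in oracle if h[2] == 0]
            assert got.get(read, set()) == set(oracle)


class TestConsistencyFilter:
    def _aln(self, pid, region, seq):
        return PrecursorAlignment(seq, pid, 0, 0, region)

    @pytest.mark.parametrize(
        "arm,loop,kept", [(3, 1, True), (2, 1, False), (5, 0, True), (6, 2, True)]
    )
    def test_three_to_one_boundary(self, arm, loop, kept):
        alns = [self._aln("hp", "arm5", f"a{i}") for i in range(arm)]
        alns += [self._aln("hp", "loop", f"l{i}") for i in range(loop)]
        counts = {a.read_sequence: 1 for a in alns}
        retained, discarded = hairpin_consistency_filter(alns, counts)
        assert (("hp" in retained) == kept) and (("hp" in discarded) != kept)

    def test_multiplicities_counted(self):
        alns = [self._aln("hp", "arm5", "a"), self._aln("hp", "loop", "l")]
        retained, _ = hairpin_consistency_filter(alns, {"a": 3, "l": 1})
        assert retained == ["hp"]
        retained, _ = hairpin_consistency_filter(alns, {"a": 2, "l": 1})
        assert retained == []


class TestAssign:
    def test_read_inside_mature_accumulates_multiplicity(self, hairpin_truth):
        cat = hairpin_truth.catalog
        ann = hairpin_truth.annotations[0]
        seq = cat[ann.precursor_id].sequence[ann.interval[0]:ann.interval[1]]
        alns = align_to_precursors([seq], cat)
        res = assign_counts(
            alns, cat, hairpin_truth.annotations, {seq: {"s1": 7}},
            retained=[a.precursor_id for a in alns],
        )
        assert res.counts.loc[ann.name, "s1"] == 7

    def test_loop_read_contributes_zero(self, hairpin_truth):
        cat = hairpin_truth.catalog
        p = next(iter(cat))
        ls, le = p.loop
        # a 19-nt read centered on the loop (majority in the loop)
        seq = p.sequence[ls - 5:ls - 5 + 19]
        alns = align_to_precursors([seq], cat)
        assert any(a.region == "loop" for a in alns)
        res = assign_counts(
            alns, cat, hairpin_truth.annotations, {seq: {"s1": 100}},
            retained=[p.id],
        )
        assert res.counts["s1"].sum() == 0

    def test_noiseless_round_trip_recovers_planted_matrix(self, hairpin_truth, meta12):
        rng = np.random.default_rng(7)
        names = [m for m, _ in hairpin_truth.matures]
        abund = pd.DataFrame(
            rng.lognormal(3, 1, size=(len(names), len(meta12))),
            index=names, columns=meta12.index,
        )
        fastqs, truth = simulate_reads(hairpin_truth, abund, n_reads=400, seed=8)
        per_sample = {
            s: [CollapsedRead(seq, c) for seq, c in
                pd.Series([r[1][:r[1].index("UGGAAUUCUC")] for r in recs])
                .value_counts().items()]
            for s, recs in fastqs.items()
        }
        res, tally = quantify_samples(per_sample, hairpin_truth.catalog,
                                      hairpin_truth.annotations)
        planted = truth["planted_counts"]
        got = res.counts.reindex(index=planted.index, columns=planted.columns)
        assert got.fillna(0).astype(int).equals(planted)

    def test_counts_invariant_to_read_order(self, hairpin_truth):
        cat = hairpin_truth.catalog
        reads = []
        for a in hairpin_truth.annotations[:6]:
            s, e = a.interval
            reads.append(cat[a.precursor_id].sequence[s:e])
        sc = {r: {"s1": i + 1} for i, r in enumerate(reads)}
        alns = align_to_precursors(reads, cat)
        retained = sorted({a.precursor_id for a in alns})
        r1 = assign_counts(alns, cat, hairpin_truth.annotations, sc, retained)
        r2 = assign_counts(list(reversed(alns)), cat, hairpin_truth.annotations,
                           sc, retained)
        assert r1.counts.equals(r2.counts)


class TestNovel:
    def _precursor(self, catalog):
        return next(iter(catalog))

    def test_opposite_arm_name_suffix_swap(self, catalog):
        p = self._precursor(catalog)
        known = [MatureAnnotation("gga-miR-X-5p", p.id, (0, 21), "arm5")]
        ann = name_novel(p, "arm3", [((31, 52), 9)], known)
        assert ann.name == "gga-miR-X-3p" and ann.novel

    def test_unannotated_precursor_named_from_hairpin_id(self, catalog):
        p = self._precursor(catalog)
        ann = name_novel(p, "arm5", [((0, 21), 12)], [])
        assert ann.name == f"{p.id}-5p"

    def test_suffixless_base_name_gains_arm_suffix(self, catalog):
        p = self._precursor(catalog)
        known = [MatureAnnotation("gga-miR-203", p.id, (0, 21), "arm5")]
        ann = name_novel(p, "arm3", [((31, 52), 7)], known)
        assert ann.name == "gga-miR-203-3p"

    def test_below_minimum_cluster_returns_none(self, catalog):
        p = self._precursor(catalog)
        assert name_novel(p, "arm5", [((0, 21), 4)], []) is None

    def test_modal_interval_of_overlapping_stacks(self, catalog):
        p = self._precursor(catalog)
        stack = [((0, 21), 3), ((2, 23), 8)]
        ann = name_novel(p, "arm5", stack, [])
        assert ann.interval == (2, 23)


class TestCascade:
    REFS = {
        "genome_only": ["AAACCCGGGUUUAAACCCGGGUUUAAACCC"],
        "other_ncRNA": ["GGGUUUCCCAAAGGGUUUCCCAAAGGGUUU"],
        "cDNA": ["CAUCAUCAUCAUCAUCAUCAUCAUCAUCAU"],
    }

    def test_first_reference_in_order_wins(self):
        read = CollapsedRead("AAACCCGGGUUUAAACCCGGGUU", 4)
        refs = dict(self.REFS)
        refs["cDNA"] = refs["cDNA"] + [read.sequence]
        tally = cascade_classify([read], refs)
        assert tally["genome_only"] == 4 and tally["cDNA"] == 0

    def test_cdna_only_read(self):
        read = CollapsedRead("CAUCAUCAUCAUCAUCAUCAU", 2)
        tally = cascade_classify([read], self.REFS)
        assert tally == {"genome_only": 0, "other_ncRNA": 0, "cDNA": 2, "unmapped": 0}

    def test_planted_category_tally_exact(self):
        rng = np.random.default_rng(3)
        reads, expected = [], {"genome_only": 0, "other_ncRNA": 0, "cDNA": 0,
                               "unmapped": 0}
        for i, (cat_name, ref) in enumerate(self.REFS.items()):
            for k in range(3):
                c = int(rng.integers(1, 9))
                reads.append(CollapsedRead(ref[0][k:k + 20], c))
                expected[cat_name] += c
        reads.append(CollapsedRead("U" * 21, 5))
        expected["unmapped"] += 5
        assert cascade_classify(reads, self.REFS) == expected

    def test_conservation_over_pipeline(self, hairpin_truth, meta12):
        rng = np.random.default_rng(11)
        names = [m for m, _ in hairpin_truth.matures]
        abund = pd.DataFrame(
            rng.lognormal(3, 1, size=(len(names), len(meta12))),
            index=names, columns=meta12.index)
        fastqs, _ = simulate_reads(hairpin_truth, abund, n_reads=150, seed=12)
        per_sample = {}
        total = 0
        for s, recs in fastqs.items():
            seqs = [r[1][:r[1].index("UGGAAUUCUC")] for r in recs]
            vc = pd.Series(seqs).value_counts()
            per_sample[s] = [CollapsedRead(q, c) for q, c in vc.items()]
            total += int(vc.sum())
        res, tally = quantify_samples(per_sample, hairpin_truth.catalog,
                                      hairpin_truth.annotations)
        assert tally["miRNA"] + tally["unmapped"] == total
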
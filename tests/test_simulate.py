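"""Fixture generation, the naive aligner and the evaluation harness."""

import filecmp
import random

import numpy as np
import pytest

from virannot.align import naive_align, six_frame_translate
from virannot.errors import IntegrityError
from virannot.hostmask import revcomp
from virannot.simulate import (
    MockCommunitySpec,
    build_toy_databases,
    evaluate,
    synth_community,
    synth_taxonomy,
)
from virannot.taxonomy import load_taxdump


class TestSynthTaxonomy:
    def test_minimal_tree_parses(self, tmp_path):
        tax = synth_taxonomy(1, 1, seed=7, out_dir=tmp_path)
        reloaded = load_taxdump(tax.nodes_path, tax.names_path)
        assert reloaded.virus_root_id == 10239
        assert len(tax.viral_species) == 1 and len(tax.bacterial_species) == 1

    def test_seeded_determinism_byte_identical(self, tmp_path):
        synth_taxonomy(3, 5, seed=7, out_dir=tmp_path / "a")
        synth_taxonomy(3, 5, seed=7, out_dir=tmp_path / "b")
        assert filecmp.cmp(tmp_path / "a/nodes.dmp", tmp_path / "b/nodes.dmp",
                           shallow=False)
        assert filecmp.cmp(tmp_path / "a/names.dmp", tmp_path / "b/names.dmp",
                           shallow=False)

    def test_output_passes_tree_invariants(self, tmp_path):
        tax = synth_taxonomy(4, 3, seed=1, out_dir=tmp_path)
        tax.tree.validate()  # no orphans, acyclic
        for sp in tax.viral_species:
            assert tax.tree.is_viral(sp)
        for sp in tax.bacterial_species:
            assert not tax.tree.is_viral(sp)


class TestSynthCommunity:
    def spec(self, tax, **kw):
        defaults = dict(
            viral_genomes=[("v1", 3000, tax.viral_species[0], "dsDNA")],
            bacterial_genomes=[("b1", 3000, tax.bacterial_species[0])],
            reads_per_genome=100, read_length=100, substitution_rate=0.01,
            seed=5,
        )
        defaults.update(kw)
        return MockCommunitySpec(**defaults)

    def test_zero_rate_reads_are_exact_substrings(self, fixture_taxonomy):
        com = synth_community(self.spec(fixture_taxonomy, substitution_rate=0.0))
        genomes = dict(com.genomes)
        for rid, seq in com.reads["S1"]:
            src = next(g for g, t in com.genome_taxids.items()
                       if t == com.truth[rid])
            assert seq in genomes[src] or revcomp(seq) in genomes[src], rid

    def test_fixed_seed_is_bit_reproducible(self, fixture_taxonomy):
        a = synth_community(self.spec(fixture_taxonomy))
        b = synth_community(self.spec(fixture_taxonomy))
        assert a.reads == b.reads and a.genomes == b.genomes

    def test_substitution_count_matches_binomial(self, fixture_taxonomy):
        """Mean per-read edit count within 3 sigma of Binomial(L, rate)."""
        rate, length = 0.01, 100
        com = synth_community(self.spec(
            fixture_taxonomy, substitution_rate=rate, reads_per_genome=500))
        genomes = dict(com.genomes)
        import edlib
        dists = []
        for rid, seq in com.reads["S1"]:
            src = next(g for g, t in com.genome_taxids.items()
                       if t == com.truth[rid])
            d = min(edlib.align(seq, genomes[src], mode="HW")["editDistance"],
                    edlib.align(revcomp(seq), genomes[src],
                                mode="HW")["editDistance"])
            dists.append(d)
        mean = np.mean(dists)
        expected = length * rate
        sigma = np.sqrt(length * rate * (1 - rate) / len(dists))
        assert abs(mean - expected) <= 3 * sigma

    def test_truth_covers_every_read(self, fixture_taxonomy):
        com = synth_community(self.spec(fixture_taxonomy))
        assert {rid for rid, _ in com.reads["S1"]} == set(com.truth)

    def test_read_longer_than_genome_is_error(self, fixture_taxonomy):
        with pytest.raises(ValueError):
            synth_community(self.spec(fixture_taxonomy, read_length=5000))


class TestNaiveAlign:
    def make_targets(self, seed=6, n=2, length=2000):
        rng = random.Random(seed)
        targets = [(f"t{i}", "".join(rng.choice("ACGT") for _ in range(length)))
                   for i in range(n)]
        taxid_map = {f"t{i}": 100 + i for i in range(n)}
        return targets, taxid_map

    def test_exact_substring_is_perfect_hit(self):
        targets, tmap = self.make_targets()
        query = targets[0][1][300:450]
        hits = naive_align([("q1", query)], targets, tmap, mode="nt")
        top = hits[0]
        assert top.target_id == "t0" and top.pident == 100.0
        assert top.alnlen == 150
        assert (top.tstart, top.tend) == (301, 450)
        assert top.target_taxid == 100

    def test_reverse_strand_hit_found(self):
        targets, tmap = self.make_targets()
        query = revcomp(targets[0][1][300:450])
        hits = naive_align([("q1", query)], targets, tmap, mode="nt")
        assert hits and hits[0].strand == "-"
        assert hits[0].pident == 100.0

    def test_random_query_negative_control(self):
        targets, tmap = self.make_targets()
        rng = random.Random(99)
        query = "".join(rng.choice("ACGT") for _ in range(150))
        assert naive_align([("q1", query)], targets, tmap, mode="nt") == []

    def test_planted_identity_recovered_within_one_point(self):
        targets, tmap = self.make_targets()
        rng = random.Random(7)
        query = list(targets[0][1][500:650])
        n_subs = 7  # ~95.3% identity over 150 nt
        for pos in rng.sample(range(150), n_subs):
            query[pos] = rng.choice([b for b in "ACGT" if b != query[pos]])
        hits = naive_align([("q1", "".join(query))], targets, tmap, mode="nt")
        true_identity = 100 * (150 - n_subs) / 150
        assert hits and abs(hits[0].pident - true_identity) <= 1.0

    def test_six_frame_translation_covers_in_phase_frame(self):
        targets, tmap = self.make_targets()
        genome = targets[0][1]
        from Bio.Seq import Seq
        protein = str(Seq(genome[: len(genome) - len(genome) % 3]).translate())
        prot_targets = [("p0", protein)]
        # read starting at a codon boundary: frame +1 is in phase
        read = genome[300:450]
        frames = dict(six_frame_translate(read))
        assert frames[1] in protein
        hits = naive_align([("q1", read)], prot_targets, {"p0": 100},
                           mode="aa-6frame")
        assert hits and hits[0].pident == 100.0
        assert hits[0].search_type == "aa"

    def test_deterministic_output_order(self):
        targets, tmap = self.make_targets()
        query = targets[0][1][100:250]
        a = naive_align([("q1", query)], targets, tmap, mode="nt")
        b = naive_align([("q1", query)], list(reversed(targets)), tmap, mode="nt")
        assert a == b


class TestEvaluate:
    def annotations(self, tax, assignments):
        """Tier-annotation stand-ins as (query_id -> verdict, taxid) pairs."""
        from virannot.classify import TierAnnotation
        from virannot.taxonomy import LcaResult
        out = []
        for rid, (verdict, taxid) in assignments.items():
            lca = LcaResult(taxid, False, "lca") if verdict != "unclassified" \
                else None
            out.append(TierAnnotation(
                query_id=rid, verdict=verdict, taxid=taxid,
                search_type="aa" if verdict != "unclassified" else None,
                lca=lca, top_hit=None, tier_trace=("viral_aa",)))
        return out

    def test_perfect_annotations(self, fixture_taxonomy):
        tree = fixture_taxonomy.tree
        viral = fixture_taxonomy.viral_species[0]
        bact = fixture_taxonomy.bacterial_species[0]
        truth = {f"v{i}": viral for i in range(10)}
        truth.update({f"b{i}": bact for i in range(10)})
        assignments = {f"v{i}": ("viral", viral) for i in range(10)}
        assignments.update({f"b{i}": ("nonviral", bact) for i in range(10)})
        report = evaluate(self.annotations(fixture_taxonomy, assignments),
                          truth, tree, rank="family")
        assert report.sensitivity == 1.0
        assert report.false_positive_rate == 0.0

    def test_all_unclassified(self, fixture_taxonomy):
        tree = fixture_taxonomy.tree
        viral = fixture_taxonomy.viral_species[0]
        truth = {f"v{i}": viral for i in range(10)}
        assignments = {f"v{i}": ("unclassified", 0) for i in range(10)}
        report = evaluate(self.annotations(fixture_taxonomy, assignments),
                          truth, tree, rank="family")
        assert report.sensitivity == 0.0
        assert report.false_positive_rate == 0.0

    def test_planted_misassignments_counted_exactly(self, fixture_taxonomy):
        """10 planted wrong-family and false-positive calls out of 200 reads."""
        tree = fixture_taxonomy.tree
        v0, v1 = fixture_taxonomy.viral_species[:2]
        bact = fixture_taxonomy.bacterial_species[0]
        truth, assignments = {}, {}
        for i in range(100):
            rid = f"v{i}"
            truth[rid] = v0
            # plant 5 wrong-family assignments
            assignments[rid] = ("viral", v1 if i < 5 else v0)
        for i in range(100):
            rid = f"b{i}"
            truth[rid] = bact
            # plant 5 false positives
            assignments[rid] = ("viral", v0) if i < 5 else ("nonviral", bact)
        report = evaluate(self.annotations(fixture_taxonomy, assignments),
                          truth, tree, rank="family")
        assert report.true_positive == 95
        assert report.false_negative == 5
        assert report.false_positive == 5
        assert report.sensitivity == pytest.approx(0.95)
        assert report.false_positive_rate == pytest.approx(0.05)

    def test_read_missing_from_truth_is_integrity_error(self, fixture_taxonomy):
        viral = fixture_taxonomy.viral_species[0]
        anns = self.annotations(fixture_taxonomy, {"ghost": ("viral", viral)})
        with pytest.raises(IntegrityError):
            evaluate(anns, {}, fixture_taxonomy.tree, rank="family")

    def test_taxid_rank_requires_exact_match(self, fixture_taxonomy):
        tree = fixture_taxonomy.tree
        sp = fixture_taxonomy.viral_species[0]
        genus = tree.parent(sp)
        anns = self.annotations(fixture_taxonomy, {"r1": ("viral", genus)})
        report = evaluate(anns, {"r1": sp}, tree, rank="taxid")
        assert report.true_positive == 0 and report.false_negative == 1
        report = evaluate(anns, {"r1": sp}, tree, rank="family")
        assert report.true_positive == 1
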
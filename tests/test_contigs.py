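"""Contig abundance normalizations, pooling, joins and contig taxonomy."""

import random

import numpy as np
import pandas as pd
import pytest

from virannot.contigs import (
    ReadMapping,
    contig_abundance,
    contig_annotate,
    contig_count_table,
    contig_seq_table,
    pool_unmapped,
    read_mappings_tsv,
    read_sam_mappings,
    write_mappings_tsv,
)
from virannot.errors import IntegrityError
from virannot.hits import AlignmentHit
from virannot.taxonomy import SENTINEL


def mapped(rid, sample, contig, start=0, end=100, mapq=60):
    return ReadMapping(rid, sample, contig, start, end, mapq, is_mapped=True)


def unmapped(rid, sample):
    return ReadMapping(rid, sample, is_mapped=False)


class TestPoolUnmapped:
    def test_all_mapped_gives_empty_pool(self):
        ms = [mapped(f"r{i}", "s1", "c1") for i in range(5)]
        assert pool_unmapped(ms) == {}

    def test_none_mapped_gives_full_pool(self):
        ms = [unmapped(f"r{i}", "s1") for i in range(5)]
        assert pool_unmapped(ms) == {"s1": [f"r{i}" for i in range(5)]}

    def test_planted_unmapped_recovered_across_samples(self):
        rng = random.Random(0)
        ms, planted = [], set()
        for i in range(500):
            sample = f"s{i % 3}"
            rid = f"r{i:03d}"
            if i < 120:
                ms.append(unmapped(rid, sample))
                planted.add((sample, rid))
            else:
                ms.append(mapped(rid, sample, "c1"))
        rng.shuffle(ms)
        pool = pool_unmapped(ms)
        got = {(s, r) for s, rids in pool.items() for r in rids}
        assert got == planted

    def test_conflicting_status_is_integrity_error(self):
        with pytest.raises(IntegrityError, match="r1"):
            pool_unmapped([mapped("r1", "s1", "c1"), unmapped("r1", "s1")])


class TestContigAbundance:
    def contigs(self):
        rng = random.Random(1)
        return [("c100", "".join(rng.choice("ACGT") for _ in range(100))),
                ("c300", "".join(rng.choice("ACGT") for _ in range(300)))]

    def test_equal_rates_split_spm_evenly(self):
        """Lengths 100/300 with counts 10/30: identical rates, SPM 500k each."""
        ms = [mapped(f"a{i}", "s1", "c100", 0, 50) for i in range(10)]
        ms += [mapped(f"b{i}", "s1", "c300", 0, 50) for i in range(30)]
        table = contig_abundance(ms, self.contigs())
        spm = dict(zip(table.contig_id, table.spm))
        assert spm == {"c100": pytest.approx(500000.0),
                       "c300": pytest.approx(500000.0)}

    def test_single_contig_takes_all(self):
        ms = [mapped(f"r{i}", "s1", "c100", 10 * i, 10 * i + 20)
              for i in range(5)]
        table = contig_abundance(ms, self.contigs())
        assert table.spm.iloc[0] == pytest.approx(1e6)
        # union of [0,20) [10,30) [20,40) [30,50) [40,60) covers 60 of 100
        assert table.coverage_percent.iloc[0] == pytest.approx(60.0)

    def test_scale_invariance_of_ratio_normalizations(self):
        ms = [mapped(f"a{i}", "s1", "c100", 0, 50) for i in range(4)]
        ms += [mapped(f"b{i}", "s1", "c300", 0, 50) for i in range(7)]
        base = contig_abundance(ms, self.contigs())
        doubled_ms = ms + [mapped(m.read_id + "x", m.sample_id, m.contig_id,
                                  m.start, m.end, m.mapq) for m in ms]
        doubled = contig_abundance(doubled_ms, self.contigs())
        assert np.allclose(doubled.spm, base.spm)
        assert np.allclose(doubled.rpkm, base.rpkm)
        assert list(doubled.raw_count) == [2 * c for c in base.raw_count]

    def test_spm_sums_to_1e6_per_sample(self):
        rng = random.Random(2)
        ms = []
        for sample in ("s1", "s2"):
            for i in range(rng.randint(20, 40)):
                cid = rng.choice(["c100", "c300"])
                ms.append(mapped(f"{sample}_r{i}", sample, cid, 0, 40))
        table = contig_abundance(ms, self.contigs())
        sums = table.groupby("sample_id")["spm"].sum()
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_fpkm_collapses_mate_pairs(self):
        ms = [mapped("p1/1", "s1", "c100", 0, 50),
              mapped("p1/2", "s1", "c100", 40, 90),
              mapped("q1", "s1", "c300", 0, 50)]
        table = contig_abundance(ms, self.contigs())
        row100 = table[table.contig_id == "c100"].iloc[0]
        # 2 reads but 1 fragment on c100; totals R=3 reads, F=2 fragments
        assert row100.raw_count == 2
        assert row100.rpkm == pytest.approx(2 * 1e9 / (3 * 100))
        assert row100.fpkm == pytest.approx(1 * 1e9 / (2 * 100))

    def test_unknown_contig_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            contig_abundance([mapped("r1", "s1", "ghost")], self.contigs())

    def test_count_conservation_with_pool(self):
        ms = [mapped(f"r{i}", "s1", "c100", 0, 50) for i in range(30)]
        ms += [unmapped(f"u{i}", "s1") for i in range(12)]
        table = contig_abundance(ms, self.contigs())
        pool = pool_unmapped(ms)
        assert table.raw_count.sum() + len(pool["s1"]) == 42


class TestContigSeqTable:
    def bigtable(self):
        return pd.DataFrame([{
            "seq_id": "s1:0:5:2.5", "sample_id": "s1", "verdict": "viral",
            "taxid": 105, "kingdom": "Viruses", "phylum": "p", "class": "c",
            "order": "o", "family": "Toyviridae1", "genus": "g", "species": "sp",
        }])

    def test_unit_join_carries_family(self):
        ms = [mapped("s1:0:5:2.5", "s1", "contig1", 0, 100, 60)]
        joined = contig_seq_table(ms, self.bigtable())
        assert len(joined) == 1
        assert joined.family.iloc[0] == "Toyviridae1"
        assert joined.mapq.iloc[0] == 60

    def test_missing_read_gets_sentinel_lineage(self):
        ms = [mapped("unknown:0:1:1.0", "s1", "contig1")]
        joined = contig_seq_table(ms, self.bigtable())
        assert joined.family.iloc[0] == SENTINEL
        assert joined.verdict.iloc[0] == "unclassified"

    def test_row_count_equals_mapped_pairs_and_group_by(self):
        rng = random.Random(3)
        families = ["Toyviridae1", "Toyviridae2", "Toyviridae3"]
        bigtable_rows, ms, truth = [], [], {}
        for i in range(300):
            fam = families[i % 3]
            sid = f"s1:{i}:1:0.1"
            bigtable_rows.append({
                "seq_id": sid, "verdict": "viral", "taxid": 100 + i,
                "kingdom": "Viruses", "phylum": "p", "class": "c", "order": "o",
                "family": fam, "genus": "g", "species": "sp",
            })
            contig = f"contig{rng.randint(1, 5)}"
            ms.append(mapped(sid, "s1", contig))
            truth.setdefault(contig, {}).setdefault(fam, 0)
            truth[contig][fam] += 1
        joined = contig_seq_table(ms, pd.DataFrame(bigtable_rows))
        assert len(joined) == 300
        tallies = joined.groupby(["contig_id", "family"]).size()
        for contig, fams in truth.items():
            for fam, n in fams.items():
                assert tallies[(contig, fam)] == n


class TestContigAnnotate:
    def hit(self, cid, tid, taxid, bitscore, evalue=1e-30):
        return AlignmentHit(query_id=cid, target_id=tid, pident=95.0,
                            alnlen=500, mismatch=10, gapopen=0, qstart=1,
                            qend=500, tstart=1, tend=500, evalue=evalue,
                            bitscore=bitscore, target_taxid=taxid,
                            search_type="nt")

    def test_homogeneous_viral_evidence(self, tree, fixture_taxonomy):
        sp = fixture_taxonomy.viral_species[0]
        anns = contig_annotate([self.hit("ctg1", "t1", sp, 900),
                                self.hit("ctg1", "t2", sp, 850)], tree)
        assert anns[0].verdict == "viral" and anns[0].taxid == sp

    def test_strong_bacterial_beats_weak_viral(self, tree, fixture_taxonomy):
        bact = fixture_taxonomy.bacterial_species[0]
        viral = fixture_taxonomy.viral_species[0]
        anns = contig_annotate(
            [self.hit("ctg1", "b", bact, 900, evalue=1e-60),
             self.hit("ctg1", "v", viral, 100, evalue=1e-5)], tree)
        assert anns[0].verdict == "nonviral" and anns[0].taxid == bact

    def test_no_hits_is_unclassified(self, tree):
        anns = contig_annotate([], tree, contig_ids=["lonely"])
        assert anns[0].verdict == "unclassified"

    def test_count_table_attaches_lineage(self, tree, fixture_taxonomy):
        sp = fixture_taxonomy.viral_species[0]
        rng = random.Random(4)
        contigs = [("ctg1", "".join(rng.choice("ACGT") for _ in range(200)))]
        ms = [mapped(f"r{i}", "s1", "ctg1", 0, 100) for i in range(4)]
        table = contig_count_table(
            contig_abundance(ms, contigs),
            contig_annotate([self.hit("ctg1", "t", sp, 900)], tree), tree)
        assert table.family.iloc[0] == fixture_taxonomy.viral_families[0]


class TestMappingIO:
    def test_tsv_round_trip(self, tmp_path):
        ms = [mapped("r1", "s1", "c1", 5, 105, 60), unmapped("r2", "s1")]
        write_mappings_tsv(ms, tmp_path / "m.tsv")
        back = read_mappings_tsv(tmp_path / "m.tsv")
        assert back == ms

    def test_sam_reader_primary_only(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:c1\tLN:500\n"
            "r1\t0\tc1\t11\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "r1\t256\tc1\t101\t0\t50M\t*\t0\t0\t*\t*\n"  # secondary: skipped
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 50 + "\t*\n"
        )
        ms = read_sam_mappings(sam, "s1")
        assert len(ms) == 2
        assert ms[0].is_mapped and ms[0].start == 10 and ms[0].end == 60
        assert not ms[1].is_mapped
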
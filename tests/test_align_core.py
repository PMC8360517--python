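"""Built-in aligner, unique classification, depth tables, SAM adapter."""

import numpy as np
import pytest

from paratyper.align_core import (
    AlignParams,
    ReadBatch,
    align,
    build_depth_table,
    classify_unique,
    group_frame,
    read_sam,
    write_sam,
)
from paratyper.allele_db import GeneMSA, ReferenceSet
from paratyper.probes import revcomp

from conftest import make_allele, make_db


def _naive_scan(refs, read, cap):
    """Sliding-window oracle: every placement within the mismatch cap,
    both strands, reference N matching anything."""
    out = set()
    for strand, seq in ((1, read), (-1, revcomp(read))):
        for a in refs:
            L = len(seq)
            for pos in range(len(a.seq) - L + 1):
                win = a.seq[pos:pos + L]
                mm = sum(
                    1 for x, y in zip(win, seq) if x != y and x != "N"
                )
                if mm <= cap:
                    out.add((a.allele_name, pos, strand, mm))
    return out


@pytest.fixture(scope="module")
def toy_refs():
    rng = np.random.default_rng(17)
    bases = np.frombuffer(b"ACGT", np.uint8)
    root = bases[rng.integers(0, 4, 1200)]
    refs = []
    for i, rate in enumerate([0.0, 0.01, 0.08]):
        s = root.copy()
        hits = np.flatnonzero(rng.random(len(s)) < rate)
        for p in hits:
            s[p] = bases[(np.searchsorted(bases, s[p]) + 1) % 4]
        seq = s.tobytes().decode()
        if i == 1:  # sprinkle uncharacterized stretch
            seq = seq[:600] + "N" * 10 + seq[610:]
        refs.append(make_allele(f"G{i + 1}*0010101", seq))
    return refs


class TestAlignerOracle:
    def test_exhaustive_equals_sliding_window_scan(self, toy_refs):
        rng = np.random.default_rng(23)
        params = AlignParams(max_mismatch=3)
        reads = []
        for i in range(60):
            src = toy_refs[rng.integers(0, 3)]
            pos = rng.integers(0, len(src.seq) - 150)
            read = list(src.seq[pos:pos + 150].replace("N", "A"))
            for _ in range(rng.integers(0, 3)):
                p = rng.integers(0, 150)
                read[p] = "ACGT"[rng.integers(0, 4)]
            seq = "".join(read)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(seq)
        batch = ReadBatch.from_sequences([f"r{i}" for i in range(len(reads))], reads)
        result = align(batch, ReferenceSet("toy", tuple(toy_refs)),
                       mode="exhaustive", params=params)
        got = {}
        for i in range(len(result)):
            row = result.read_rows[i]
            got.setdefault(row, set()).add((
                result.index.names[result.ref_ids[i]],
                int(result.offsets[i]), int(result.strands[i]),
                int(result.mismatches[i]),
            ))
        for i, seq in enumerate(reads):
            assert got.get(i, set()) == _naive_scan(toy_refs, seq, 3), f"read {i}"

    def test_best_is_subset_of_exhaustive(self, toy_refs):
        rng = np.random.default_rng(5)
        src = toy_refs[0]
        reads = [src.seq[p:p + 150] for p in rng.integers(0, 1000, 30)]
        batch = ReadBatch.from_sequences([f"r{i}" for i in range(30)], reads)
        refs = ReferenceSet("toy", tuple(toy_refs))
        ex = align(batch, refs, mode="exhaustive")
        best = align(batch, refs, mode="best")
        ex_set = set(zip(ex.read_rows, ex.ref_ids, ex.offsets, ex.strands))
        best_set = set(zip(best.read_rows, best.ref_ids, best.offsets, best.strands))
        assert best_set <= ex_set
        # best keeps only minimal mismatch placements per read
        for row in set(best.read_rows):
            mms = best.mismatches[best.read_rows == row]
            all_mms = ex.mismatches[ex.read_rows == row]
            assert set(mms) == {all_mms.min()}

    def test_unique_150mer_places_once(self, prepared):
        a = prepared.db.alleles["DST1*0010101"]
        read = a.seq[1200:1350]
        batch = ReadBatch.from_sequences(["r0"], [read])
        res = align(batch, prepared.min_index)
        names = {res.index.names[i] for i in res.ref_ids}
        assert all(n.startswith("DST1") for n in names)


class TestClassifyUnique:
    def test_examples_and_partition(self, toy_refs):
        g1, g2, g3 = toy_refs
        # read from G3's divergent sequence: unique to G3
        batch = ReadBatch.from_sequences(
            ["u", "shared"],
            [g3.seq[100:250], g1.seq[300:450]],  # g1[300:450] ~ g2 within cap
        )
        res = align(batch, ReferenceSet("toy", tuple(toy_refs)))
        cls = classify_unique(res)
        aligned = set(res.read_rows)
        all_rows = set()
        for rows in cls.unique_rows.values():
            all_rows |= set(rows)
        assert set(cls.cross_rows) & all_rows == set()
        assert all_rows | set(cls.cross_rows) == aligned
        assert 0 in set(cls.unique_rows["G3"])
        assert 1 in set(cls.cross_rows)  # identical in G1 and G2

    def test_truth_recount_on_low_homology_genes(self, prepared):
        import paratyper as pt

        rng = np.random.default_rng(31)
        truth = pt.sample_genotype(prepared.db, prepared.family.templates, rng, "S")
        batch = pt.simulate_reads(truth, coverage=5, rng=rng)
        reads = ReadBatch.from_pairs(batch.names, batch.r1, batch.r2)
        res = align(reads, prepared.min_index)
        cls = classify_unique(res)
        # distinct-sequence genes: every truth-labeled aligned read is unique
        from paratyper.simulate import parse_read_name

        for g in ("DST1", "CNV1", "FRW1"):
            expected = {
                i for i, n in enumerate(reads.names)
                if parse_read_name(n)[1].startswith(g)
            } & set(res.read_rows)
            assert set(cls.unique_rows[g]) == expected


class TestDepthTable:
    @staticmethod
    def _ctx():
        # gapped toy group: allele B has a 2-base deletion vs the frame
        rows = {
            "G1*0010101": "ACGTACGTACGTACGTACGT",
            "G1*0020101": "ACGTACGT--GTACGTACGT",
        }
        msa = GeneMSA(gene="G1", rows=rows)
        a1 = make_allele("G1*0010101", rows["G1*0010101"])
        a2 = make_allele("G1*0020101", rows["G1*0020101"].replace("-", ""))
        msa.row_states["G1*0010101"] = a1.states
        msa.row_states["G1*0020101"] = a2.states
        db = make_db([a1, a2], "G1", msas={"G1": msa})
        return db, a1, a2

    def test_error_free_read_counts_bases(self):
        db, a1, _ = self._ctx()
        frame = group_frame(db, "G1")
        read = a1.seq[2:14]
        batch = ReadBatch.from_sequences(["r"], [read])
        res = align(batch, ReferenceSet("g", (a1,)),
                    params=AlignParams(seed_len=8, seed_stride=2))
        table = build_depth_table(res, frame)
        total = table.counts.sum()
        assert total == len(read)
        for j, base in enumerate(read):
            row = "ACGT".index(base)
            assert table.counts[row, 2 + j] == 1

    def test_substitution_counted_at_position(self):
        db, a1, _ = self._ctx()
        frame = group_frame(db, "G1")
        read = list(a1.seq[0:12])
        read[5] = "A" if read[5] != "A" else "C"
        batch = ReadBatch.from_sequences(["r"], ["".join(read)])
        res = align(batch, ReferenceSet("g", (a1,)),
                    params=AlignParams(seed_len=6, seed_stride=2))
        table = build_depth_table(res, frame)
        assert table.counts["ACGT".index(read[5]), 5] == 1

    def test_allele_gap_projects_as_deletion(self):
        db, _, a2 = self._ctx()
        frame = group_frame(db, "G1")
        read = a2.seq[4:16]  # spans the deletion
        batch = ReadBatch.from_sequences(["r"], [read])
        res = align(batch, ReferenceSet("g", (a2,)),
                    params=AlignParams(seed_len=8, seed_stride=2))
        table = build_depth_table(res, frame)
        assert table.counts[4, 8] == 1 and table.counts[4, 9] == 1
        # bases after the gap land back on the frame
        assert table.counts.sum() == len(read) + 2

    def test_conservation_bound(self, prepared):
        import paratyper as pt

        rng = np.random.default_rng(41)
        truth = pt.sample_genotype(prepared.db, prepared.family.templates, rng, "S")
        batch = pt.simulate_reads(truth, coverage=3, rng=rng)
        reads = ReadBatch.from_pairs(batch.names, batch.r1, batch.r2)
        res = align(reads, prepared.min_index)
        frame = prepared.gctx.contexts["FRW1"].frame
        table = build_depth_table(res, frame)
        assert table.counts[:4].sum() <= len(reads) * 150


class TestSamAdapter:
    def test_round_trip(self, toy_refs, tmp_path):
        rng = np.random.default_rng(9)
        src = toy_refs[0]
        reads = [src.seq[p:p + 150] for p in rng.integers(0, 1000, 10)]
        reads += [revcomp(reads[0])]
        batch = ReadBatch.from_sequences(
            [f"r{i}" for i in range(len(reads))], reads
        )
        refs = ReferenceSet("toy", tuple(toy_refs))
        res = align(batch, refs, mode="exhaustive")
        path = tmp_path / "out.sam"
        write_sam(res, path)
        back = read_sam(path, refs)
        orig = {
            (res.reads.names[res.read_rows[i]], res.index.names[res.ref_ids[i]],
             int(res.offsets[i]), int(res.strands[i]), int(res.mismatches[i]))
            for i in range(len(res))
        }
        got = {
            (back.reads.names[back.read_rows[i]], back.index.names[back.ref_ids[i]],
             int(back.offsets[i]), int(back.strands[i]), int(back.mismatches[i]))
            for i in range(len(back))
        }
        assert got == orig

    def test_records_expose_sorted_differences(self, toy_refs):
        src = toy_refs[0]
        read = list(src.seq[10:160])
        read[7] = "A" if read[7] != "A" else "C"
        read[90] = "A" if read[90] != "A" else "C"
        batch = ReadBatch.from_sequences(["r"], ["".join(read)])
        res = align(batch, ReferenceSet("g", (src,)))
        recs = [r for r in res.records() if r.reference == src.allele_name
                and r.offset == 10]
        assert recs
        subs = recs[0].substitutions
        assert [p for p, _ in subs] == sorted(p for p, _ in subs)
        assert (17, read[7]) in subs and (100, read[90]) in subs


class TestProperPairFilter:
    def test_contradicted_placements_dropped_unpaired_kept(self, toy_refs):
        from paratyper.align_core import filter_proper_pairs

        g1, g2, g3 = toy_refs
        r1 = g3.seq[100:250]
        r2 = revcomp(g3.seq[150:300])
        # decoy pair whose mate 2 is unalignable: mate 1 must survive
        rng = np.random.default_rng(3)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        batch = ReadBatch.from_pairs(["p1", "p2"], [r1, r1], [r2, junk])
        res = align(batch, ReferenceSet("toy", (g1, g2, g3)), mode="exhaustive")
        kept = filter_proper_pairs(res)
        pairs_kept = {
            (kept.reads.names[kept.read_rows[i]],
             int(kept.reads.mates[kept.read_rows[i]]),
             kept.index.names[kept.ref_ids[i]])
            for i in range(len(kept))
        }
        assert ("p1", 1, g3.allele_name) in pairs_kept
        assert ("p1", 2, g3.allele_name) in pairs_kept
        assert ("p2", 1, g3.allele_name) in pairs_kept  # mate unmapped: allowed
        assert len(kept) <= len(res)
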
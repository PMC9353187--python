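"""Encoding oracles: one-hot windows against the FASTA, neighbor vectors
against a brute-force nearest-neighbor search."""

import numpy as np
import pandas as pd
import pytest

from cpgfill.encoding import (build_examples, encode_neighbors,
                              encode_neighbors_batch, encode_sequence,
                              encode_sequence_batch, load_batch, save_batch)
from cpgfill.io import GenomeIndex, MethylomeProfile, write_fasta

BASE_ORDER = "ACGT"


def decode_row(row):
    if row.sum() == 0:
        return "N"
    return BASE_ORDER[int(np.argmax(row))]


class TestSequenceEncoding:
    def test_one_hot_roundtrips_against_fasta(self, random_genome):
        rng = np.random.default_rng(0)
        cpg = random_genome.cpg_positions("chr1")
        sites = rng.choice(cpg[(cpg > 60) & (cpg < 9_940)], size=50,
                           replace=False)
        win = encode_sequence_batch(random_genome, "chr1", sites, 101)
        for s, mat in zip(sites, win):
            expected = random_genome.sequence("chr1", int(s) - 50, int(s) + 50)
            assert "".join(decode_row(r) for r in mat) == expected
            assert mat[50, 1] == 1.0  # centre row is the C channel

    def test_window_rows_sum_to_one_or_zero(self, tiny_genome):
        w = encode_sequence(tiny_genome, "chr1", 3, 9)
        sums = w.sum(axis=1)
        assert set(np.unique(sums)) <= {0.0, 1.0}

    def test_edge_padding_is_zero(self, tiny_genome):
        w = encode_sequence(tiny_genome, "chr1", 3, 9)  # rows cover -1..7
        assert np.all(w[:2] == 0.0)          # positions -1, 0 off-chromosome
        assert w[2].sum() == 1.0             # position 1

    def test_n_base_encodes_to_zero_row(self, tmp_path):
        write_fasta({"c": "ANCGT"}, tmp_path / "n.fa")
        g = GenomeIndex(tmp_path / "n.fa")
        w = encode_sequence(g, "c", 3, 5)
        assert w[1].sum() == 0.0             # the N at position 2
        assert decode_row(w[2]) == "C"

    def test_non_cpg_position_rejected(self, tiny_genome):
        with pytest.raises(ValueError, match="not CpG"):
            encode_sequence(tiny_genome, "chr1", 5, 9)

    def test_even_window_rejected(self, tiny_genome):
        with pytest.raises(ValueError, match="odd"):
            encode_sequence(tiny_genome, "chr1", 3, 10)


def brute_force_neighbors(profile, chrom, pos, k, dist_scale):
    """Independent oracle: sort all sites by position, pick k per side."""
    p, lv = profile.by_chrom().get(chrom, (np.array([]), np.array([])))
    left = [(pp, ll) for pp, ll in zip(p, lv) if pp < pos][-k:]
    right = [(pp, ll) for pp, ll in zip(p, lv) if pp > pos][:k]
    levels = [0.5] * (k - len(left)) + [ll for _, ll in left] \
        + [ll for _, ll in right] + [0.5] * (k - len(right))
    dists = [1.0] * (k - len(left)) \
        + [min(abs(pp - pos) / dist_scale, 1.0) for pp, _ in left] \
        + [min(abs(pp - pos) / dist_scale, 1.0) for pp, _ in right] \
        + [1.0] * (k - len(right))
    return np.array(levels), np.array(dists)


class TestNeighborEncoding:
    def test_matches_brute_force_oracle_on_1000_sites(self, random_genome):
        rng = np.random.default_rng(1)
        cpg = random_genome.cpg_positions("chr1")
        covered = np.sort(rng.choice(cpg, size=len(cpg) // 2, replace=False))
        prof = MethylomeProfile("p", pd.DataFrame({
            "chrom": "chr1", "pos": covered,
            "level": rng.random(len(covered)), "total_reads": 10}))
        targets = rng.choice(cpg, size=1000, replace=True)
        lv, d, m = encode_neighbors_batch(prof, "chr1", targets, 5, 2000.0)
        for i, pos in enumerate(targets):
            elv, ed = brute_force_neighbors(prof, "chr1", int(pos), 5, 2000.0)
            np.testing.assert_allclose(lv[i], elv, atol=1e-12)
            np.testing.assert_allclose(d[i], ed, atol=1e-12)

    def test_two_site_example(self, make_profile):
        prof = make_profile("p", [("chr1", 90, 0.8, 5), ("chr1", 110, 0.2, 5)])
        v = encode_neighbors(prof, "chr1", 100, k_per_side=1, dist_scale=100.0)
        np.testing.assert_allclose(v.levels, [0.8, 0.2])
        np.testing.assert_allclose(v.distances, [0.1, 0.1])
        assert v.mask.all()

    def test_empty_profile_fully_padded(self, make_profile):
        prof = make_profile("p", [])
        v = encode_neighbors(prof, "chr1", 100, k_per_side=3)
        assert (v.levels == 0.5).all() and (v.distances == 1.0).all()
        assert not v.mask.any()

    def test_partial_padding_on_left_edge(self, make_profile):
        prof = make_profile("p", [("chr1", 50, 0.9, 5), ("chr1", 200, 0.1, 5)])
        v = encode_neighbors(prof, "chr1", 100, k_per_side=3, dist_scale=1000.0)
        assert v.mask.tolist() == [False, False, True, True, False, False]
        assert v.levels[2] == 0.9 and v.levels[3] == 0.1

    def test_target_site_excluded_from_own_neighbors(self, make_profile):
        prof = make_profile("p", [("chr1", 100, 0.9, 5), ("chr1", 120, 0.1, 5)])
        v = encode_neighbors(prof, "chr1", 100, k_per_side=1)
        assert 0.9 not in v.levels  # only the downstream neighbor appears

    def test_translation_invariance(self, make_profile):
        shift = 5_000
        a = make_profile("a", [("chr1", 90, 0.8, 5), ("chr1", 130, 0.3, 5)])
        b = make_profile("b", [("chr1", 90 + shift, 0.8, 5),
                               ("chr1", 130 + shift, 0.3, 5)])
        va = encode_neighbors(a, "chr1", 100, 2, 1000.0)
        vb = encode_neighbors(b, "chr1", 100 + shift, 2, 1000.0)
        np.testing.assert_array_equal(va.vector, vb.vector)

    def test_encoding_is_pure(self, make_profile):
        prof = make_profile("p", [("chr1", 90, 0.8, 5)])
        v1 = encode_neighbors(prof, "chr1", 100, 2)
        v2 = encode_neighbors(prof, "chr1", 100, 2)
        np.testing.assert_array_equal(v1.vector, v2.vector)

    def test_distance_clipped_at_one(self, make_profile):
        prof = make_profile("p", [("chr1", 1, 0.8, 5)])
        v = encode_neighbors(prof, "chr1", 50_000, 1, dist_scale=25_000.0)
        assert v.distances[0] == 1.0


class TestBuildExamples:
    def test_label_mask_reflects_coverage(self, tiny_genome, make_profile):
        p1 = make_profile("a", [("chr1", 3, 0.9, 5)])
        p2 = make_profile("b", [("chr1", 7, 0.2, 5)])
        batch = build_examples([p1, p2], tiny_genome, "training",
                               window_len=5, k_per_side=2)
        assert batch.n_examples == 2
        i3 = int(np.flatnonzero(batch.pos == 3)[0])
        assert batch.label_mask[i3].tolist() == [True, False]
        assert batch.labels[i3, 0] == pytest.approx(0.9)

    def test_imputation_mode_covers_all_genome_cpgs(self, tmp_path,
                                                    make_profile):
        write_fasta({"c": "AACGTT"}, tmp_path / "g.fa")
        g = GenomeIndex(tmp_path / "g.fa")
        batch = build_examples([make_profile("a", [])], g, "imputation",
                               window_len=3, k_per_side=1)
        assert batch.n_examples == 1 and batch.pos[0] == 3

    def test_no_covered_sites_gives_empty_stream(self, tiny_genome,
                                                 make_profile):
        batch = build_examples([make_profile("a", [])], tiny_genome,
                               "training", window_len=5, k_per_side=1)
        assert batch.n_examples == 0

    def test_tasks_in_alphabetical_sample_order(self, tiny_genome,
                                                make_profile):
        pb = make_profile("zeta", [("chr1", 3, 0.9, 5)])
        pa = make_profile("alpha", [("chr1", 3, 0.1, 5)])
        batch = build_examples([pb, pa], tiny_genome, "training",
                               window_len=5, k_per_side=1)
        assert batch.task_order == ["alpha", "zeta"]
        assert batch.labels[0, 0] == pytest.approx(0.1)

    def test_deterministic_ordering_by_chrom_pos(self, tiny_genome,
                                                 make_profile):
        prof = make_profile("a", [("chr2", 6, 0.5, 5), ("chr1", 7, 0.5, 5),
                                  ("chr1", 3, 0.5, 5)])
        batch = build_examples([prof], tiny_genome, "training",
                               window_len=5, k_per_side=1)
        assert batch.chrom.tolist() == ["chr1", "chr1", "chr2"]
        assert batch.pos.tolist() == [3, 7, 6]

    def test_hdf5_roundtrip(self, tmp_path, tiny_genome, make_profile):
        prof = make_profile("a", [("chr1", 3, 0.9, 5), ("chr1", 7, 0.2, 5)])
        batch = build_examples([prof], tiny_genome, "training",
                               window_len=5, k_per_side=2)
        path = tmp_path / "batch.h5"
        save_batch(batch, path)
        back = load_batch(path)
        np.testing.assert_array_equal(back.seq, batch.seq)
        np.testing.assert_array_equal(back.neighbors, batch.neighbors)
        np.testing.assert_array_equal(back.labels, batch.labels)
        assert back.task_order == batch.task_order
        assert back.chrom.tolist() == batch.chrom.tolist()
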
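import numpy as np
import pytest

from rdnanet.occupancy import (
    NormalizationError,
    aggregate,
    count_five_prime_ends,
    load_bedgraph,
    median_profile,
    normalize_35S,
    write_bedgraph,
)

from conftest import make_profile


def _sam(tmp_path, records, length=9100, name="toy.sam"):
    header = f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:rDNA\tLN:{length}\n"
    path = tmp_path / name
    path.write_text(header + "".join(records))
    return path


def rec(qname, flag, pos, cigar="10M", seq="A" * 10):
    return f"{qname}\t{flag}\trDNA\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"


class TestCountFivePrimeEnds:
    def test_hand_counted_toy_sam(self, ann, tmp_path):
        """Reverse-strand 5' ends at 10, 10, 500 tally as 2 and 1; a
        forward read and a secondary record are excluded."""
        records = [
            rec("r1", 16, 1),            # reverse, 10M from 1 -> 5' end at 10
            rec("r2", 16, 1),            # same position
            rec("r3", 16, 491),          # reverse -> 5' end at 500
            rec("r4", 0, 100),           # forward: fails antisense policy
            rec("r5", 272, 300),         # reverse but secondary: dropped
        ]
        prof = count_five_prime_ends(_sam(tmp_path, records), ann)
        assert prof.value_at(10) == 2
        assert prof.value_at(500) == 1
        assert prof.values.sum() == 3

    def test_strand_policy_selects_reads(self, ann, tmp_path):
        records = [rec("f", 0, 100), rec("r", 16, 191)]
        sam = _sam(tmp_path, records)
        anti = count_five_prime_ends(sam, ann, "antisense")
        sense = count_five_prime_ends(sam, ann, "sense")
        both = count_five_prime_ends(sam, ann, "both")
        assert anti.values.sum() == 1 and anti.value_at(200) == 1
        assert sense.values.sum() == 1 and sense.value_at(100) == 1
        assert both.values.sum() == 2

    def test_empty_file_gives_zero_profile(self, ann, tmp_path):
        prof = count_five_prime_ends(_sam(tmp_path, []), ann)
        assert prof.values.sum() == 0
        assert len(prof) == ann.repeat_length

    def test_reference_length_mismatch_raises(self, ann, tmp_path):
        with pytest.raises(ValueError, match="length"):
            count_five_prime_ends(_sam(tmp_path, [], length=5000), ann)

    def test_read_conservation(self, ann, tmp_path, rng):
        """Total counted signal equals the number of retained alignments."""
        starts = rng.integers(1, 9000, size=40)
        records = [rec(f"q{i}", 16, int(s)) for i, s in enumerate(starts)]
        prof = count_five_prime_ends(_sam(tmp_path, records), ann)
        assert prof.values.sum() == 40


class TestBedgraph:
    def test_round_trip_random_sparse_profile(self, ann, tmp_path, rng):
        values = np.zeros(ann.repeat_length)
        idx = rng.choice(ann.repeat_length, 200, replace=False)
        values[idx] = rng.random(200) * 7
        prof = make_profile(values)
        path = tmp_path / "x.bedgraph"
        write_bedgraph(prof, path)
        back = load_bedgraph(path, ann)
        np.testing.assert_allclose(back.values, prof.values, rtol=1e-9)

    def test_disk_interval_convention(self, ann, tmp_path):
        path = tmp_path / "one.bedgraph"
        path.write_text("rDNA\t9\t10\t5.0\n")
        prof = load_bedgraph(path, ann)
        assert prof.value_at(10) == 5.0
        assert prof.values.sum() == 5.0

    def test_overlapping_intervals_rejected(self, ann, tmp_path):
        path = tmp_path / "overlap.bedgraph"
        path.write_text("rDNA\t0\t10\t1\nrDNA\t5\t15\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            load_bedgraph(path, ann)

    def test_out_of_bounds_rejected(self, ann, tmp_path):
        path = tmp_path / "oob.bedgraph"
        path.write_text(f"rDNA\t0\t{ann.repeat_length + 5}\t1\n")
        with pytest.raises(ValueError, match="outside"):
            load_bedgraph(path, ann)

    def test_zero_runs_omitted_on_write(self, ann, tmp_path):
        values = np.zeros(ann.repeat_length)
        values[99] = 2.0
        path = tmp_path / "sparse.bedgraph"
        write_bedgraph(make_profile(values), path)
        lines = path.read_text().strip().splitlines()
        assert lines == ["rDNA\t99\t100\t2"]


class TestNormalize:
    def test_uniform_profile_normalizes_to_reciprocal_t1(self, ann):
        t1 = ann.feature("T1").start
        values = np.zeros(ann.repeat_length)
        values[:t1] = 3.7
        norm = normalize_35S(make_profile(values), ann)
        np.testing.assert_allclose(norm.values[:t1], 1.0 / t1)
        assert norm.total_35S == pytest.approx(3.7 * t1)

    def test_unit_sum_and_downstream_scaling(self, ann, rng):
        t1 = ann.feature("T1").start
        prof = make_profile(rng.random(ann.repeat_length))
        norm = normalize_35S(prof, ann)
        assert norm.values[:t1].sum() == pytest.approx(1.0, abs=1e-9)
        # positions past T1 are scaled by the same factor, not re-summed
        np.testing.assert_allclose(
            norm.values[t1:], prof.values[t1:] / prof.values[:t1].sum()
        )

    def test_all_zero_profile_cannot_normalize(self, ann):
        with pytest.raises(NormalizationError):
            normalize_35S(make_profile(np.zeros(ann.repeat_length)), ann)

    def test_renormalization_guarded(self, ann, rng):
        norm = normalize_35S(make_profile(rng.random(ann.repeat_length)), ann)
        with pytest.raises(NormalizationError):
            normalize_35S(norm, ann)


class TestAggregation:
    def test_identical_replicates_identity(self, rng):
        v = rng.random(100)
        reps = [make_profile(v, replicate=f"r{i}", normalized=True) for i in range(3)]
        np.testing.assert_array_equal(median_profile(reps).values, v)

    def test_median_definition_and_order_invariance(self):
        reps = [
            make_profile([x], replicate=f"r{x}", normalized=True) for x in (9, 1, 2)
        ]
        assert median_profile(reps).values[0] == 2
        assert (
            median_profile(reps[::-1]).values[0] == median_profile(reps).values[0]
        )

    def test_sum_aggregation(self):
        reps = [make_profile([x], replicate=f"r{x}", normalized=True) for x in (1, 2)]
        assert aggregate(reps, method="sum").values[0] == 3

    def test_mixed_strains_rejected(self):
        reps = [
            make_profile([1], strain="A", normalized=True),
            make_profile([1], strain="B", normalized=True),
        ]
        with pytest.raises(ValueError, match="strain"):
            median_profile(reps)

    def test_unnormalized_rejected(self):
        reps = [make_profile([1]), make_profile([2])]
        with pytest.raises(ValueError, match="normalized"):
            median_profile(reps)
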
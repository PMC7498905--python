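"""Read-to-tag matching, methylation calling, FP calibration, RPM."""

import numpy as np
import pytest

from methylradclone.digest import Contig, ContigSet, MethylRadTag, RecognitionSite, revcomp
from methylradclone.quantify import (
    TagCountMatrix,
    call_methylation,
    estimate_false_positive_rate,
    match_reads,
    normalize_rpm,
)


def make_tag(seq, contig="c1", start=0, strand="+", mclass="CG"):
    site = RecognitionSite(contig, start, strand, mclass, "CCGG" if mclass == "CG" else "CCAGG")
    return MethylRadTag(site=site, tag_start=start, tag_end=start + len(seq), sequence=seq)


def oracle_match(read, tags, max_mm=2):
    """Exhaustive all-offsets, both-orientations Hamming search."""
    best = {}
    for i, tag in enumerate(tags):
        dmin = None
        for oriented in (read, revcomp(read)):
            short, long_ = (oriented, tag.sequence) if len(oriented) <= len(
                tag.sequence
            ) else (tag.sequence, oriented)
            for off in range(len(long_) - len(short) + 1):
                d = sum(a != b for a, b in zip(short, long_[off : off + len(short)]))
                if dmin is None or d < dmin:
                    dmin = d
        if dmin is not None and dmin <= max_mm:
            best[i] = dmin
    return best


def oracle_counts(reads, tags, max_mm=2, max_n=1):
    counts = np.zeros(len(tags), dtype=int)
    total = 0
    for _, seq in reads:
        if seq.count("N") > max_n:
            continue
        total += 1
        hits = oracle_match(seq, tags, max_mm)
        if not hits:
            continue
        dmin = min(hits.values())
        winners = [i for i, d in hits.items() if d == dmin]
        if len(winners) == 1:
            counts[winners[0]] += 1
    return counts, total


def mutate(rng, seq, k):
    arr = list(seq)
    for pos in rng.choice(len(arr), size=k, replace=False):
        arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
    return "".join(arr)


class TestMatcher:
    def test_exact_read_increments_its_site(self, rng):
        tags = [make_tag("ACGTACGTACGTACGTACGTACGTACGTACGT", start=i * 100) for i in range(1)]
        counts, total = match_reads([("r1", tags[0].sequence)], tags)
        assert counts.tolist() == [1] and total == 1

    def test_three_substitutions_do_not_match(self, rng):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        tags = [make_tag(seq)]
        read = mutate(rng, seq, 3)
        counts, total = match_reads([("r1", read)], tags, max_mismatches=2)
        assert counts.sum() == 0 and total == 1

    def test_equidistant_read_discarded_as_multimapper(self):
        base = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        other = "T" + base[1:]  # differs at position 0
        read = "G" + base[1:]  # distance 1 to both
        tags = [make_tag(base, start=0), make_tag(other, start=100)]
        counts, total = match_reads([("r1", read)], tags, max_mismatches=2)
        assert counts.sum() == 0 and total == 1
        assert oracle_counts([("r1", read)], tags)[0].sum() == 0

    def test_unique_minimum_wins_over_worse_hit(self):
        base = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        near = "TT" + base[2:]  # distance 2 from base
        # the read equals `base`: distance 0 there, 2 to `near` -> unique win
        counts, _ = match_reads([("r1", base)], [make_tag(base, 0), make_tag(near, 100)])
        assert counts.tolist() == [1, 0]

    def test_reads_with_too_many_ns_excluded_from_library_total(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        tags = [make_tag(seq)]
        noisy = "NN" + seq[2:]
        counts, total = match_reads([("ok", seq), ("bad", noisy)], tags, max_ambiguous=1)
        assert total == 1 and counts.sum() == 1

    def test_reverse_complement_reads_match(self):
        seq = "ACGTACGTACGTTCGTACGTACGTACGTACGT"
        tags = [make_tag(seq)]
        counts, _ = match_reads([("r1", revcomp(seq))], tags)
        assert counts.tolist() == [1]

    def test_containment_of_shorter_read(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTA"  # 33 bp
        tags = [make_tag(seq)]
        counts, _ = match_reads([("r1", seq[1:])], tags)  # 32 bp inside 33
        assert counts.tolist() == [1]

    def test_empty_tag_set_rejected(self):
        with pytest.raises(ValueError):
            match_reads([("r1", "ACGT")], [])

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_exhaustive_oracle_on_random_instances(self, rng, trial):
        n_tags = int(rng.integers(5, 40))
        tag_len = int(rng.integers(28, 36))
        seqs = set()
        while len(seqs) < n_tags:
            seqs.add("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=tag_len)]))
        tags = [make_tag(s, start=i * 100) for i, s in enumerate(sorted(seqs))]
        reads = []
        for i in range(300):
            src = tags[int(rng.integers(0, n_tags))].sequence
            kind = rng.random()
            if kind < 0.5:
                read = mutate(rng, src, int(rng.integers(0, 4)))
            elif kind < 0.7:
                read = revcomp(mutate(rng, src, int(rng.integers(0, 3))))
            elif kind < 0.85:
                read = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=tag_len)])
            else:
                cut = int(rng.integers(0, 3))
                read = src[cut:]
            if rng.random() < 0.05:
                read = "N" * int(rng.integers(1, 4)) + read[3:]
            reads.append((f"r{i}", read))
        got_counts, got_total = match_reads(reads, tags)
        exp_counts, exp_total = oracle_counts(reads, tags)
        assert got_total == exp_total
        np.testing.assert_array_equal(got_counts, exp_counts)


class TestCallsAndRates:
    def _cm(self, counts, totals=None, classes=None):
        counts = np.asarray(counts)
        n_sites, n_samples = counts.shape
        totals = totals if totals is not None else counts.sum(axis=0) + 10
        return TagCountMatrix(
            [f"s{i}" for i in range(n_sites)],
            [f"S{j}" for j in range(n_samples)],
            counts,
            totals,
        )

    def test_threshold_calls(self):
        cm = self._cm(np.array([[0], [1], [2], [5]]))
        calls = call_methylation(cm, min_cov=2)
        assert calls.calls[:, 0].tolist() == [0, 0, 1, 1]

    def test_min_cov_one_equals_nonzero(self):
        cm = self._cm(np.array([[0, 3], [7, 0]]))
        calls = call_methylation(cm, min_cov=1)
        np.testing.assert_array_equal(calls.calls, (cm.counts > 0).astype(int))

    def test_all_zero_matrix_zero_methylated(self):
        cm = self._cm(np.zeros((4, 2), dtype=int))
        assert call_methylation(cm).calls.sum() == 0

    def test_fp_rate_basic_arithmetic(self):
        counts = np.zeros((100, 1), dtype=int)
        counts[7, 0] = 2
        cm = self._cm(counts)
        fp = estimate_false_positive_rate(
            cm, [f"s{i}" for i in range(100)], min_cov=2,
            motif_classes=["CG"] * 100,
        )
        pooled = fp[(fp.sample_id == "__pooled__") & (fp.motif_class == "CG")]
        assert pooled["fp_rate_percent"].iloc[0] == pytest.approx(1.0)

    def test_fp_rate_monotone_in_min_cov(self, rng):
        counts = rng.poisson(0.6, size=(200, 3))
        cm = self._cm(counts)
        ids = [f"s{i}" for i in range(200)]
        r1 = estimate_false_positive_rate(cm, ids, min_cov=1)
        r2 = estimate_false_positive_rate(cm, ids, min_cov=2)
        p1 = r1[r1.sample_id == "__pooled__"]["fp_rate_percent"].iloc[0]
        p2 = r2[r2.sample_id == "__pooled__"]["fp_rate_percent"].iloc[0]
        assert p2 <= p1

    def test_fp_rate_requires_chloroplast_sites(self):
        cm = self._cm(np.zeros((3, 1), dtype=int))
        with pytest.raises(ValueError):
            estimate_false_positive_rate(cm, [], min_cov=2)

    def test_rpm_values_and_scale_invariance(self):
        cm = TagCountMatrix(["a"], ["S0"], np.array([[5]]), np.array([1_000_000]))
        assert normalize_rpm(cm).iloc[0, 0] == pytest.approx(5.0)
        cm2 = TagCountMatrix(["a"], ["S0"], np.array([[10]]), np.array([2_000_000]))
        assert normalize_rpm(cm2).iloc[0, 0] == pytest.approx(5.0)

    def test_rpm_rejects_zero_library(self):
        cm = TagCountMatrix(["a"], ["S0"], np.array([[0]]), np.array([0]))
        with pytest.raises(ValueError, match="S0"):
            normalize_rpm(cm)

    def test_column_sums_cannot_exceed_totals(self):
        with pytest.raises(ValueError):
            TagCountMatrix(["a"], ["S0"], np.array([[5]]), np.array([3]))
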
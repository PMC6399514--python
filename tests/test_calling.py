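"""Bisulfite-aware alignment, clone QC, calling and rate statistics."""

import numpy as np
import pandas as pd
import pytest

from bspmeth.calling import (
    AlignedClone,
    CloneRead,
    METHYLATED,
    MISSING,
    UNMETHYLATED,
    align_clone,
    build_call_matrix,
    call_clone,
    clone_qc,
    integral_rate,
    lollipop_text,
    parse_lollipop_text,
    per_site_rates,
    process_clones,
    summarize_group,
    _ALIGNER,
)
from bspmeth.reference import (
    ReferenceRegion,
    bisulfite_convert,
    enumerate_cpg_sites,
    reverse_complement,
)
from bspmeth.simulate import SyntheticConfig, generate_clones, generate_methylation_states

from conftest import dp_alignment_score, random_dna

# a small amplicon: 4 CpG sites plus plenty of non-CpG cytosines for QC
AMPLICON = "ATTCAGCGATCCATTACGGATTCCAGTACGTTACCATTCGAATCCTA"
REF = ReferenceRegion("amp", AMPLICON)
SITES = enumerate_cpg_sites(REF)
CONVERTED = bisulfite_convert(AMPLICON, "cpg_protected")


def read(seq, clone_id="c1", group="g"):
    return CloneRead(clone_id, group, seq)


class TestAlignClone:
    def test_fully_methylated_read_is_identical(self):
        aligned = align_clone(read(CONVERTED), CONVERTED, SITES)
        assert aligned.orientation == "forward"
        assert aligned.identity == 1.0
        assert call_clone(aligned, SITES) == [METHYLATED] * len(SITES)

    def test_reverse_complement_gives_identical_calls(self):
        fully_converted = bisulfite_convert(AMPLICON, "full")
        fwd = align_clone(read(fully_converted), CONVERTED, SITES)
        rc = align_clone(read(reverse_complement(fully_converted)), CONVERTED, SITES)
        assert rc.orientation == "reverse_complement"
        assert call_clone(fwd, SITES) == call_clone(rc, SITES)
        assert call_clone(fwd, SITES) == [UNMETHYLATED] * len(SITES)

    def test_internal_deletion_keeps_all_sites_mapped(self):
        # drop 2 bp between site 2 and site 3 (positions 20-21)
        seq = CONVERTED[:20] + CONVERTED[22:]
        aligned = align_clone(read(seq), CONVERTED, SITES)
        calls = call_clone(aligned, SITES)
        assert MISSING not in calls
        assert aligned.score == pytest.approx(dp_alignment_score(CONVERTED, seq))

    def test_unalignable_read_is_flagged(self):
        junk = "TTTTAAAATTTTAAAATTTTAAAA"
        with pytest.warns(UserWarning):
            aligned = align_clone(read(junk), CONVERTED, SITES)
        assert not aligned.alignable

    @pytest.mark.parametrize("seed", range(8))
    def test_score_equals_exhaustive_dp(self, seed):
        """Aligner score == brute-force Gotoh DP on mutated/indeled pairs."""
        rng = np.random.default_rng(seed)
        target = random_dna(rng, int(rng.integers(40, 150)))
        q = list(bisulfite_convert(target, "cpg_protected"))
        for _ in range(rng.integers(0, 8)):
            q[rng.integers(len(q))] = "ACGT"[rng.integers(4)]
        for _ in range(rng.integers(0, 3)):
            i = int(rng.integers(len(q)))
            if rng.random() < 0.5 and len(q) > 5:
                del q[i]
            else:
                q.insert(i, "ACGT"[rng.integers(4)])
        query = "".join(q)
        assert _ALIGNER.score(target, query) == pytest.approx(
            dp_alignment_score(target, query)
        )


class TestCloneQC:
    def _aligned(self, mapping, identity=1.0):
        return AlignedClone("c1", "g", "forward", 40.0, identity, mapping)

    def test_perfect_conversion_passes(self):
        aligned = align_clone(read(CONVERTED), CONVERTED, SITES)
        qc = clone_qc(aligned, AMPLICON, SITES)
        assert qc.conversion_rate == 1.0 and qc.passed

    def test_partial_conversion_fails(self):
        # retain 2 of the non-CpG Cs as C -> conversion below 0.95
        non_cpg_c = [i for i, b in enumerate(AMPLICON)
                     if b == "C" and i not in {s.c_position for s in SITES}]
        mapping = {i: b for i, b in enumerate(CONVERTED)}
        for pos in non_cpg_c[:2]:
            mapping[pos] = "C"
        qc = clone_qc(self._aligned(mapping), AMPLICON, SITES)
        n = len(non_cpg_c)
        assert qc.conversion_rate == pytest.approx((n - 2) / n)
        assert not qc.passed and "conversion" in qc.reason

    def test_low_identity_fails(self):
        mapping = {i: b for i, b in enumerate(CONVERTED)}
        qc = clone_qc(self._aligned(mapping, identity=0.85), AMPLICON, SITES)
        assert not qc.passed and "identity" in qc.reason

    def test_no_informative_positions_fails_with_reason(self):
        ref = ReferenceRegion("r", "ACGATTAGGCGATT")  # every C is a CpG C
        sites = enumerate_cpg_sites(ref)
        conv = bisulfite_convert(ref.sequence, "cpg_protected")
        aligned = align_clone(CloneRead("c", "g", conv), conv, sites)
        qc = clone_qc(aligned, ref.sequence, sites)
        assert qc.conversion_rate is None and not qc.passed
        assert "undefined" in qc.reason


class TestCallClone:
    def test_ambiguous_base_is_missing(self):
        mapping = {i: b for i, b in enumerate(CONVERTED)}
        mapping[SITES[1].c_position] = "A"
        aligned = AlignedClone("c", "g", "forward", 40.0, 1.0, mapping)
        calls = call_clone(aligned, SITES)
        assert calls[1] == MISSING
        assert all(c == METHYLATED for i, c in enumerate(calls) if i != 1)

    def test_gap_at_site_is_missing(self):
        mapping = {i: b for i, b in enumerate(CONVERTED)}
        mapping[SITES[0].c_position] = None
        aligned = AlignedClone("c", "g", "forward", 40.0, 1.0, mapping)
        assert call_clone(aligned, SITES)[0] == MISSING


def matrix_from_strings(rows, group="g"):
    calls = {f"c{i}": list(r) for i, r in enumerate(rows)}
    return build_call_matrix(group, calls, len(rows[0]))


class TestRates:
    def test_printed_site_rate_arithmetic(self):
        # 41 methylated of 57 valid calls at one site -> 71.93%
        rows = ["M"] * 41 + ["U"] * 16
        m = matrix_from_strings(rows)
        assert per_site_rates(m)[1] == pytest.approx(0.7193, abs=5e-5)

    def test_printed_integral_rate_arithmetic(self):
        # 94 methylated of 112 valid calls -> 83.93%
        rows = ["MM"] * 47 + ["UU"] * 9
        m = matrix_from_strings(rows)
        assert integral_rate(m) == pytest.approx(0.8393, abs=5e-5)

    def test_all_methylated(self):
        m = matrix_from_strings(["MMM", "MMM"])
        assert integral_rate(m) == 1.0
        assert per_site_rates(m).tolist() == [1.0, 1.0, 1.0]

    def test_all_missing_site_is_nan_not_zero(self):
        m = matrix_from_strings(["M.", "M."])
        rates = per_site_rates(m)
        assert rates[1] == 1.0 and np.isnan(rates[2])

    def test_empty_matrix_errors(self):
        m = matrix_from_strings(["..", ".."])
        with pytest.raises(ValueError, match="no valid calls"):
            integral_rate(m)

    @pytest.mark.parametrize("seed", range(5))
    def test_integral_rate_identities(self, seed):
        """Integral rate = valid-call-weighted mean of site rates and is
        invariant under row/column permutation."""
        rng = np.random.default_rng(seed)
        rows = [
            "".join(rng.choice(["M", "U", "."], p=[0.6, 0.3, 0.1], size=6))
            for _ in range(20)
        ]
        if not any("M" in r or "U" in r for r in rows):
            rows[0] = "MUMUMU"
        m = matrix_from_strings(rows)
        s = summarize_group(m)
        weighted = np.nansum(s.per_site_rate * s.valid_calls) / s.valid_calls.sum()
        assert s.integral_rate == pytest.approx(weighted)
        shuffled = m.calls.sample(frac=1, random_state=seed)
        shuffled = shuffled[list(rng.permutation(shuffled.columns))]
        from bspmeth.calling import CloneCallMatrix
        assert integral_rate(CloneCallMatrix("g", shuffled)) == pytest.approx(
            s.integral_rate
        )
        assert 0 <= s.integral_rate <= 1
        assert s.per_site_rate.min() - 1e-12 <= s.integral_rate <= s.per_site_rate.max() + 1e-12

    def test_binomial_recovery_with_planted_probabilities(self):
        """500 error-free synthetic clones recover planted per-site rates
        within 3 binomial SDs."""
        p = np.array([0.2, 0.5, 0.9])
        rng = np.random.default_rng(7)
        states = (rng.random((500, 3)) < p).astype(int)
        rows = ["".join("M" if x else "U" for x in row) for row in states]
        rates = per_site_rates(matrix_from_strings(rows))
        for k in range(3):
            sd = np.sqrt(p[k] * (1 - p[k]) / 500)
            assert abs(rates[k + 1] - p[k]) <= 3 * sd


class TestLollipop:
    def test_round_trip(self):
        m = matrix_from_strings(["MUM", "U.M", "MMM"], group="w25")
        text = lollipop_text(m)
        back = parse_lollipop_text(text)
        assert back.group_id == "w25"
        pd.testing.assert_frame_equal(back.calls, m.calls)

    def test_fill_counts_match_matrix(self):
        m = matrix_from_strings(["MM", "MU", "U."])
        text = lollipop_text(m)
        assert text.count("●") == int((m.calls == "M").sum().sum())
        assert text.count("○") == int((m.calls == "U").sum().sum())


class TestEndToEnd:
    def test_zero_error_calls_equal_planted_states(self, synthetic_reference):
        """generate -> align -> call reproduces planted states exactly."""
        ref, truth = synthetic_reference
        cfg = SyntheticConfig(
            conversion_failure_rate=0.0, sequencing_error_rate=0.0,
            weeks=(25, 60), clones_per_tissue=4,
        )
        reads, _, states = generate_clones(ref, truth, cfg, 11)
        sites = enumerate_cpg_sites(ref)
        conv = bisulfite_convert(ref.sequence, "cpg_protected")
        matrices, qc = process_clones(reads, ref.sequence, conv, sites)
        assert qc["passed"].all()
        for week in cfg.weeks:
            m = matrices[str(week)]
            ids = [f"w{week}_t{t}_c{k}" for t in range(1, 4) for k in range(1, 5)]
            got = (m.calls.loc[ids] == "M").to_numpy().astype(int)
            assert (m.calls.loc[ids] != ".").all().all()
            assert (got == states[week]).all()

    def test_monotone_in_planted_probability(self):
        """Raising every planted probability (same seed) never lowers the
        realized methylated fraction (coupled uniform draws)."""
        lo = SyntheticConfig(weeks=(25,), clones_per_tissue=334, n_tissues=3,
                             per_week_site_prob={25: (0.5,) * 14})
        hi = SyntheticConfig(weeks=(25,), clones_per_tissue=334, n_tissues=3,
                             per_week_site_prob={25: (0.6,) * 14})
        s_lo = generate_methylation_states(lo, 5)[25]
        s_hi = generate_methylation_states(hi, 5)[25]
        assert s_hi.mean() >= s_lo.mean()
        assert (s_hi >= s_lo).all()
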
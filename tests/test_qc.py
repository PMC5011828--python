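"""Quality-control cascade: marker stats, exact HWE, GRM, relatedness pruning."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mismap.errors import QCError
from mismap.qc import (
    QCThresholds,
    apply_qc,
    grm,
    hwe_exact_p,
    marker_stats,
    rel_cutoff_prune,
)
from mismap.types import GenotypePanel, MarkerRecord


def _panel(columns, sample_prefix="s"):
    """Build a panel from a list of dosage columns (lists with None=missing)."""
    cols = [
        [np.nan if v is None else float(v) for v in col] for col in columns
    ]
    dosages = np.array(cols).T
    n = dosages.shape[0]
    markers = [
        MarkerRecord(f"m{j}", "1", 1000 * (j + 1), "A", "B")
        for j in range(len(columns))
    ]
    return GenotypePanel([f"{sample_prefix}{i}" for i in range(n)], markers, dosages)


# -------------------------------------------------------------- marker stats
class TestMarkerStats:
    def test_call_rate_and_maf(self):
        stats = marker_stats(
            _panel([[0, 1, 2, None], [0, 0, 0, 0], [0, 1, 1, 2, 2, 2][:4]])
        )
        assert stats.loc[0, "call_rate"] == pytest.approx(0.75)
        assert stats.loc[1, "maf"] == 0.0

    def test_maf_matches_allele_count_oracle(self):
        # dosages 0,1,1,2,2,2 carry 4 counted alleles of 12 -> maf 1/3
        stats = marker_stats(_panel([[0, 1, 1, 2, 2, 2]]))
        # oracle: count alleles directly
        dosages = [0, 1, 1, 2, 2, 2]
        p = sum(dosages) / (2 * len(dosages))
        assert stats.loc[0, "maf"] == pytest.approx(min(p, 1 - p))
        assert stats.loc[0, "maf"] == pytest.approx(1 / 3)

    def test_all_missing_marker_flagged(self):
        stats = marker_stats(_panel([[None, None, None], [0, 1, 2]]))
        assert stats.loc[0, "call_rate"] == 0.0
        assert np.isnan(stats.loc[0, "maf"])


# ----------------------------------------------------------------- exact HWE
def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Independent enumeration of the exact conditional test via Fractions."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    na = 2 * n_aa + n_ab
    probs = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        aa = (na - h) // 2
        bb = n - aa - h
        probs[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(aa) * math.factorial(h) * math.factorial(bb),
        )
    total = sum(probs.values())
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs) / total)


class TestHWE:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(7, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 12) == 1.0

    def test_zero_total_convention(self):
        assert hwe_exact_p(0, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts", [(3, 0, 3), (1, 10, 1), (5, 5, 5), (0, 2, 0), (10, 1, 10)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)

    @settings(max_examples=150, derandomize=True)
    @given(
        n_aa=st.integers(0, 20), n_ab=st.integers(0, 20), n_bb=st.integers(0, 20)
    )
    def test_symmetry_and_range(self, n_aa, n_ab, n_bb):
        p = hwe_exact_p(n_aa, n_ab, n_bb)
        assert 0.0 < p <= 1.0
        assert p == hwe_exact_p(n_bb, n_ab, n_aa)  # allele labels are arbitrary


# ----------------------------------------------------------------------- GRM
class TestGRM:
    def test_duplicated_sample_matches_diagonal(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=50).astype(float)
        noise = rng.integers(0, 3, size=(3, 50)).astype(float)
        dosages = np.vstack([base, base, noise])
        markers = [MarkerRecord(f"m{j}", "1", j + 1) for j in range(50)]
        panel = GenotypePanel([f"s{i}" for i in range(5)], markers, dosages)
        G = grm(panel)
        assert G[0, 1] == pytest.approx(G[0, 0])
        assert G[0, 1] == pytest.approx(G[1, 1])

    def test_opposite_homozygotes_closed_form(self):
        # two samples, dosages 0 vs 2 everywhere: p = 0.5, so each product is
        # (0-1)(2-1) / (2 * 0.5 * 0.5) = -2
        panel = _panel([[0, 2], [0, 2], [0, 2], [0, 2]])
        G = grm(panel)
        assert G[0, 1] == pytest.approx(-2.0)

    def test_unrelated_cohort_mean_off_diagonal_near_zero(self):
        rng = np.random.default_rng(42)
        m, n = 3000, 40
        p = rng.uniform(0.1, 0.9, size=m)
        dosages = rng.binomial(2, p, size=(n, m)).astype(float)
        markers = [MarkerRecord(f"m{j}", "1", j + 1) for j in range(m)]
        G = grm(GenotypePanel([f"s{i}" for i in range(n)], markers, dosages))
        off = G[~np.eye(n, dtype=bool)]
        # SE of a single entry ~ 1/sqrt(m); the mean over entries is tighter
        assert abs(off.mean()) < 3.0 / math.sqrt(m)

    def test_no_polymorphic_markers_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            grm(_panel([[0, 0, 0], [2, 2, 2]]))


# --------------------------------------------------------------- rel-cutoff
class TestRelCutoff:
    def test_no_violations_keeps_all(self):
        G = np.eye(4)
        assert rel_cutoff_prune(G, 0.4).all()

    def test_duplicate_pair_removes_exactly_one(self):
        G = np.eye(3)
        G[0, 1] = G[1, 0] = 0.99
        keep = rel_cutoff_prune(G, 0.4)
        assert keep.sum() == 2
        # equal counts and call rates: the later index goes
        assert not keep[1] and keep[0] and keep[2]

    def test_triangle_fixture_matches_greedy_oracle(self):
        # samples 0,1,2 all pairwise >= cutoff; sample 3 clean.
        # greedy: all three tie at 2 violations -> lowest call rate (s0) goes;
        # then pair (1,2) remains -> s1 (lower call rate) goes; {2,3} stay.
        G = np.eye(4)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            G[i, j] = G[j, i] = 0.5
        keep = rel_cutoff_prune(G, 0.4, call_rates=np.array([0.90, 0.95, 0.99, 1.0]))
        assert list(keep) == [False, False, True, True]

    def test_result_has_no_remaining_violation(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(12, 12))
        G = (A + A.T) / 4
        np.fill_diagonal(G, 1.0)
        keep = rel_cutoff_prune(G, 0.4)
        sub = G[np.ix_(keep, keep)]
        off = sub[~np.eye(keep.sum(), dtype=bool)]
        assert (off < 0.4).all()


# ------------------------------------------------------------------ cascade
class TestApplyQC:
    def test_extreme_thresholds_are_identity(self, toy_panel):
        t = QCThresholds(
            marker_call_rate_min=0.0,
            maf_min=0.0,
            hwe_p_min=0.0,
            sample_call_rate_min=0.0,
            rel_cutoff=float("inf"),
        )
        filtered, report = apply_qc(toy_panel, t)
        assert filtered.equals(toy_panel)
        assert report.counts["markers_out"] == toy_panel.n_markers

    def test_toy_panel_failures_counted_per_marker_oracle(self):
        # 10 markers x 60 samples: m0/m1 fail MAF (one carrier each), m2 fails
        # HWE (all heterozygous), the rest are balanced and clean.
        rng = np.random.default_rng(1)
        n = 60
        clean = [list(rng.binomial(2, 0.5, size=n).astype(float)) for _ in range(7)]
        low_maf1 = [1.0] + [0.0] * (n - 1)
        low_maf2 = [0.0] * (n - 1) + [1.0]
        all_het = [1.0] * n
        panel = _panel([low_maf1, low_maf2, all_het] + clean)
        t = QCThresholds(rel_cutoff=float("inf"))  # GRM prune off for this fixture
        filtered, report = apply_qc(panel, t)
        assert filtered.n_markers == 7
        reasons = report.marker_table["fail_reason"]
        assert list(reasons[:3]) == ["maf", "maf", "hwe"]
        # oracle recomputation of the HWE failure
        assert hwe_enumeration_oracle(0, n, 0) <= 1e-8

    def test_idempotent_on_simulated_panel(self, small_panel):
        # With relatedness pruning disabled the cascade is a fixed point.
        # (The GRM prune is excluded: the matrix is re-estimated from the
        # retained samples, so borderline pairs can shift across the cutoff.)
        t = QCThresholds(rel_cutoff=float("inf"))
        once, _ = apply_qc(small_panel, t)
        twice, report = apply_qc(once, t)
        assert twice.equals(once)
        assert report.counts["markers_out"] == once.n_markers
        assert report.counts["samples_out"] == once.n_samples

    def test_marker_filters_idempotent_after_full_cascade(self, small_panel):
        once, _ = apply_qc(small_panel)
        _, report = apply_qc(once)
        c = report.counts
        assert c["markers_out"] == once.n_markers
        assert c["samples_fail_call_rate"] == 0

    def test_removal_counts_partition_inputs(self, small_panel):
        _, report = apply_qc(small_panel)
        c = report.counts
        assert c["samples_in"] == c["samples_out"] + c["samples_fail_call_rate"] + \
            c["samples_fail_relatedness"]
        assert c["markers_in"] == c["markers_out"] + c["markers_fail_call_rate"] + \
            c["markers_fail_maf"] + c["markers_fail_hwe"]

    def test_everything_removed_raises_with_report(self):
        panel = _panel([[0, 0, 0, 0], [2, 2, 2, 2]])  # all monomorphic
        with pytest.raises(QCError) as err:
            apply_qc(panel, QCThresholds(rel_cutoff=float("inf")))
        assert err.value.report is not None
        assert err.value.report.counts["markers_fail_maf"] == 2
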
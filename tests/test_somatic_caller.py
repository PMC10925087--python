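"""Somatic caller tests: callable rules, candidate discovery, the CCF mixture
classifier, the six filters, and the orchestrated window pipeline."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from hapsomatic import somatic_caller as sc
from hapsomatic.realign import ReadAlleleLikelihoods


def cov_from_depths(depths):
    """(4, L) coverage array with the whole depth on base A."""
    L = len(depths)
    cov = np.zeros((4, L), dtype=np.int64)
    cov[0] = depths
    return cov


def make_reads(n_ref, n_alt, decisive=5.0, strands=("+", "-"), mismatch=0.0):
    reads = []
    for i in range(n_ref + n_alt):
        is_alt = i >= n_ref
        good, bad = -1e-3, -decisive
        reads.append(
            ReadAlleleLikelihoods(
                read_id=f"r{i}",
                site_index=0,
                logp_ref=good if not is_alt else bad,
                logp_alt=good if is_alt else bad,
                strand=strands[i % len(strands)],
                window_mismatch=mismatch,
            )
        )
    return reads


def somatic_loglik_oracle(lpr, lpa, alpha, ccf, n_bins=100_000):
    """Independent fine-grid midpoint integration of the CCF mixture."""
    phi = (np.arange(n_bins) + 0.5) / n_bins
    pdf = beta_dist.pdf(phi, ccf.a, ccf.b) / n_bins
    total = 0.0
    for a, b in zip(lpr, lpa):
        pr, pa = math.exp(a), math.exp(b)
        sub = np.sum(pdf * (pr * (1 - alpha * phi) + pa * alpha * phi))
        clonal = ccf.rho * (pr * (1 - alpha) + pa * alpha)
        total += math.log(clonal + (1 - ccf.rho) * sub)
    return total


class TestCallable:
    @pytest.mark.parametrize(
        "d0,d1,expected",
        [
            (12, 11, True),  # both >= 10, sum <= 400
            (9, 100, False),  # one haplotype below 10x
            (250, 200, False),  # sum above 400x
            (10, 10, True),  # boundary inclusive
            (200, 200, True),  # sum boundary inclusive
        ],
    )
    def test_boundary_rules(self, d0, d1, expected):
        intervals, _, _ = sc.find_callable(
            cov_from_depths([d0]), cov_from_depths([d1]), 0
        )
        assert (len(intervals) == 1) is expected

    def test_intervals_merge_contiguous_runs(self):
        d0 = [15, 15, 3, 15, 15, 15]
        d1 = [15, 15, 15, 15, 2, 15]
        intervals, _, _ = sc.find_callable(
            cov_from_depths(d0), cov_from_depths(d1), 1000
        )
        assert intervals == [(1000, 1002), (1003, 1004), (1005, 1006)]


class TestCandidates:
    def _discover(self, hap_counts, ref_base="A", depth_pad=0):
        """hap_counts: per-base counts at one position on haplotype 0."""
        cov0 = np.array(hap_counts, dtype=np.int64).reshape(4, 1)
        cov1 = cov_from_depths([cov0.sum() + depth_pad])
        mask = np.ones(1, dtype=bool)
        return sc.discover_candidates(cov0, cov1, ref_base, 0, mask)

    def test_threshold_boundaries(self):
        # depth 20, 3 alt obs (15%): candidate
        assert len(self._discover([17, 3, 0, 0])) >= 1
        # depth 40, 3 alt obs (7.5%): fails the >10% rule
        cands = self._discover([37, 3, 0, 0])
        assert all(c.haplotype != 0 for c in cands)
        # depth 20, 2 alt obs (10%): fails both rules
        cands = self._discover([18, 2, 0, 0])
        assert all(c.haplotype != 0 for c in cands)

    def test_modal_base_reported(self):
        cands = self._discover([10, 3, 5, 0])
        mine = [c for c in cands if c.haplotype == 0]
        assert mine and mine[0].alt == "G" and mine[0].hap_alt_count == 5

    def test_uncallable_positions_skipped(self):
        cov0 = np.array([17, 3, 0, 0], dtype=np.int64).reshape(4, 1)
        cov1 = cov_from_depths([20])
        cands = sc.discover_candidates(cov0, cov1, "A", 0, np.zeros(1, dtype=bool))
        assert cands == []


class TestClassifier:
    def test_clonal_prior_reduces_to_pure_mixture(self):
        """rho=1 gives exactly the clonal product-of-mixtures likelihood."""
        reads = make_reads(5, 11)
        lpr = np.array([r.logp_ref for r in reads])
        lpa = np.array([r.logp_alt for r in reads])
        alpha = 0.5
        got = sc.somatic_log_likelihood(lpr, lpa, alpha, sc.CCFPrior(rho=1.0))
        want = sum(
            math.log(math.exp(a) * (1 - alpha) + math.exp(b) * alpha)
            for a, b in zip(lpr, lpa)
        )
        assert got == pytest.approx(want, rel=1e-12)

    def test_all_alt_candidate_classified_het(self):
        post, _ = sc.classify_candidate(make_reads(0, 25))
        assert np.argmax(post) == 1  # het dominates somatic without ref reads

    def test_balanced_candidate_classified_somatic(self):
        post, qual = sc.classify_candidate(make_reads(8, 9))
        assert np.argmax(post) == 0
        assert qual > 20

    def test_posterior_matches_fine_grid_oracle(self):
        """11 alt / 5 ref, rho=0.95, Beta(2,2): matches a 1e5-bin oracle."""
        config = sc.CallerConfig(alpha=0.5)
        reads = make_reads(5, 11)
        post, _ = sc.classify_candidate(reads, config)
        lpr = [r.logp_ref for r in reads]
        lpa = [r.logp_alt for r in reads]
        log_som = somatic_loglik_oracle(lpr, lpa, 0.5, config.ccf)
        liks = np.array([log_som, sum(lpa), sum(lpr)])
        logpost = liks + np.log(
            [config.mu_prior, config.pi_prior, 1 - config.mu_prior - config.pi_prior]
        )
        want = np.exp(logpost - logpost.max())
        want /= want.sum()
        assert post[0] == pytest.approx(want[0], rel=1e-4)  # 4 significant figures

    def test_integration_converges_by_100_bins(self, rng):
        """p_somatic at n_bins=100 is within 1e-3 of the fine-grid value."""
        for _ in range(25):
            n_alt = int(rng.integers(1, 20))
            n_ref = int(rng.integers(1, 20))
            alpha = float(rng.uniform(0.2, 0.8))
            config = sc.CallerConfig(alpha=alpha)
            reads = make_reads(n_ref, n_alt, decisive=float(rng.uniform(2, 7)))
            p100 = sc.classify_candidate(reads, config)[0][0]
            lpr = [r.logp_ref for r in reads]
            lpa = [r.logp_alt for r in reads]
            log_som = somatic_loglik_oracle(lpr, lpa, alpha, config.ccf)
            liks = np.array([log_som, sum(lpa), sum(lpr)])
            logpost = liks + np.log(
                [config.mu_prior, config.pi_prior,
                 1 - config.mu_prior - config.pi_prior]
            )
            w = np.exp(logpost - logpost.max())
            assert abs(p100 - w[0] / w.sum()) < 1e-3

    def test_increasing_clonal_mass_raises_clonal_p_somatic(self):
        reads = make_reads(8, 8)
        quals = []
        for rho in (0.5, 0.8, 0.95, 1.0):
            cfg = sc.CallerConfig(alpha=0.5, ccf=sc.CCFPrior(rho=rho))
            quals.append(sc.classify_candidate(reads, cfg)[0][0])
        assert quals == sorted(quals)

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            sc.classify_candidate([])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sc.CallerConfig(alpha=1.0)
        with pytest.raises(ValueError):
            sc.CCFPrior(n_bins=5)


def base_call(**overrides):
    defaults = dict(
        chrom="c", pos=100, ref="A", alt="C", haplotype=0, qual=35.0,
        p_somatic=0.999, p_het=0.0005, p_reference=0.0005,
        hap_depths=(15, 15), other_hap_alt=2, other_hap_depth=20,
        alt_strand_counts=(5, 4), ref_strand_counts=(3, 3),
        artifact_read_fraction=0.0,
    )
    defaults.update(overrides)
    return sc.MutationCall(**defaults)


class TestFilters:
    def test_clean_call_passes(self):
        call = sc.apply_filters(base_call())
        assert call.is_pass

    @pytest.mark.parametrize(
        "overrides,expected",
        [
            (dict(other_hap_alt=3), "MaxOtherHaplotypeObservations"),
            (dict(other_hap_alt=2, other_hap_depth=8), "MaxOtherHaplotypeObservations"),
            (dict(alt_strand_counts=(9, 0)), "MinObsPerStrand"),
            (dict(artifact_read_fraction=0.6), "PossibleAlignmentArtifact"),
            (dict(qual=12.0), "LowQual"),
            (dict(hap_depths=(9, 30)), "MinHaplotypeDepth"),
            (
                dict(alt_strand_counts=(25, 0), ref_strand_counts=(0, 25)),
                "StrandBias",
            ),
        ],
    )
    def test_each_filter_fires_independently(self, overrides, expected):
        call = sc.apply_filters(base_call(**overrides))
        assert expected in call.filters

    def test_filters_idempotent(self):
        call = sc.apply_filters(base_call(other_hap_alt=5, qual=10.0))
        again = sc.apply_filters(call)
        assert call.filters == again.filters


class TestCallWindow:
    def test_recovers_clonal_mutations(self, tumour_run):
        fx, config, calls, bed, _ = tumour_run
        mask = np.zeros(fx.region_length, dtype=bool)
        for s, e in bed:
            mask[s:e] = True
        truth = set(fx.somatic.positions.tolist())
        truth_callable = {p for p in truth if mask[p]}
        passing = {c.pos for c in calls if c.is_pass and c.qual >= 20}
        assert len(passing & truth_callable) >= 0.9 * len(truth_callable)
        assert len(passing - truth) == 0

    def test_calls_confined_to_callable_intervals(self, tumour_run):
        fx, config, calls, bed, _ = tumour_run
        mask = np.zeros(fx.region_length, dtype=bool)
        for s, e in bed:
            mask[s:e] = True
        assert all(mask[c.pos] for c in calls)

    def test_no_duplicate_positions(self, tumour_run):
        _, _, calls, _, _ = tumour_run
        positions = [c.pos for c in calls]
        assert len(positions) == len(set(positions))

    def test_vcf_round_trip_is_exact(self, tumour_run, tmp_path):
        fx, _, calls, _, _ = tumour_run
        path = str(tmp_path / "calls.vcf")
        sc.write_calls_vcf(calls, path, [(fx.chrom, fx.region_length)])
        back = sc.read_calls_vcf(path)
        assert back == calls

    def test_window_without_phased_snps_is_empty(self, fx_tumour, tmp_path):
        import pysam

        # a phased VCF whose records all lie outside the queried window
        empty = str(tmp_path / "empty.vcf")
        with pysam.VariantFile(fx_tumour.germline_vcf) as src:
            with pysam.VariantFile(empty, "w", header=src.header.copy()) as out:
                pass
        pysam.tabix_compress(empty, empty + ".gz", force=True)
        pysam.tabix_index(empty + ".gz", preset="vcf", force=True)
        calls, bed, assignments = sc.call_window(
            fx_tumour.bam,
            empty + ".gz",
            fx_tumour.reference_fasta,
            (fx_tumour.chrom, 0, 10_000),
        )
        assert calls == [] and bed == [] and assignments == {}

    def test_bed_round_trip(self, tumour_run, tmp_path):
        from hapsomatic import burden

        fx, _, _, bed, _ = tumour_run
        path = str(tmp_path / "call.bed")
        sc.write_bed(bed, fx.chrom, path)
        assert [(fx.chrom, s, e) for s, e in bed] == burden.read_bed(path)
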
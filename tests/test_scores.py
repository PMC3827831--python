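"""Gene eligibility, degrees, classification, metagene and convergent pairs."""

import numpy as np
import pandas as pd
import pytest

from mosaicmeth import (
    GeneModel,
    ScoreConfig,
    degree_by_cpg_fraction,
    degree_by_domain_overlap,
    degree_histogram,
    detect_convergent_shared_domain_pairs,
    merge_intervals,
    metagene_domain_profile,
    sperm_gene_eligibility,
)
from mosaicmeth.scores import score_genes_cpg_fraction, score_genes_domain_overlap


def gene(gene_id="g", contig="c", strand="+", span=(1000, 2000), cds=None):
    cds = cds or (span[0] + 100, span[1] - 100)
    return GeneModel(gene_id, contig, strand, span[0], span[1], cds[0], cds[1])


def iset(*ivs, contig="c"):
    return merge_intervals({contig: list(ivs)})


class TestEligibility:
    def test_contained_span_eligible(self):
        assert sperm_gene_eligibility(gene(span=(100, 200), cds=(120, 180)), iset((0, 1000)))

    def test_partially_covered_ineligible(self):
        assert not sperm_gene_eligibility(gene(span=(100, 200), cds=(120, 180)), iset((0, 150)))

    def test_half_open_boundary_containment(self):
        # span ends exactly at the covered-region boundary
        assert sperm_gene_eligibility(gene(span=(100, 200), cds=(120, 180)), iset((100, 200)))


class TestDomainOverlapDegree:
    def test_half_overlap_intermediate(self):
        rec = degree_by_domain_overlap(gene(), iset((900, 1500)))
        assert rec.degree == 0.5
        assert rec.meth_class == "intermediate"

    def test_contained_is_methylated(self):
        rec = degree_by_domain_overlap(gene(), iset((0, 5000)))
        assert rec.degree == 1.0 and rec.meth_class == "methylated"

    @pytest.mark.parametrize(
        "domain_end, expected_class",
        [(1950, "methylated"), (1050, "unmethylated")],  # degrees 0.95 / 0.05
    )
    def test_bimodal_thresholds(self, domain_end, expected_class):
        rec = degree_by_domain_overlap(gene(), iset((1000, domain_end)))
        assert rec.meth_class == expected_class

    def test_ineligible_gene_gets_no_degree(self):
        rec = degree_by_domain_overlap(gene(), iset((0, 5000)), eligible=False)
        assert rec.degree is None and rec.meth_class == "ineligible" and not rec.eligible

    def test_sensitivity_thresholds_configurable(self):
        cfg = ScoreConfig(lo=0.05, hi=0.95)
        rec = degree_by_domain_overlap(gene(), iset((1000, 1930)), cfg)  # 0.93
        assert rec.meth_class == "intermediate"


def _sites(positions, X, m, contig="c", context="CpG"):
    n = len(positions)
    df = pd.DataFrame(
        {
            "contig": contig,
            "pos": positions,
            "strand": "+",
            "context": context,
            "X": X,
            "m": m,
        }
    )
    call = np.where(np.asarray(X) < 2, "unassessed", np.where(np.asarray(m) > 0, "methylated", "unmethylated"))
    df["call"] = call
    return df


class TestCpgFractionDegree:
    def test_assessed_denominator(self):
        # 5 CpGs, 4 assessed, 3 methylated -> eligible, degree 0.75
        sites = _sites([1100, 1200, 1300, 1400, 1500], [5, 5, 5, 5, 1], [3, 3, 3, 0, 0])
        rec = degree_by_cpg_fraction(gene(), sites)
        assert rec.eligible and rec.degree == 0.75
        assert rec.meth_class == "intermediate"

    def test_eligibility_strictly_above_60_percent(self):
        # 3 of 5 assessed = 0.6, NOT > 0.6
        sites = _sites([1100, 1200, 1300, 1400, 1500], [5, 5, 5, 1, 1], [3, 3, 3, 0, 0])
        rec = degree_by_cpg_fraction(gene(), sites)
        assert not rec.eligible and rec.meth_class == "ineligible"

    def test_all_methylated(self):
        sites = _sites([1100, 1200, 1300], [5, 5, 5], [5, 5, 5])
        rec = degree_by_cpg_fraction(gene(), sites)
        assert rec.degree == 1.0 and rec.meth_class == "methylated"

    def test_no_cpgs_ineligible(self):
        rec = degree_by_cpg_fraction(gene(), _sites([], [], []))
        assert not rec.eligible

    def test_literal_all_cpg_denominator_flag(self):
        sites = _sites([1100, 1200, 1300, 1400, 1500], [5, 5, 5, 5, 1], [3, 3, 3, 0, 0])
        rec = degree_by_cpg_fraction(gene(), sites, ScoreConfig(cpg_denominator="all"))
        assert rec.degree == pytest.approx(3 / 5)

    def test_non_cpg_contexts_ignored(self):
        cpg = _sites([1100, 1200], [5, 5], [5, 5])
        chh = _sites([1300, 1400, 1500], [5, 5, 5], [0, 0, 0], context="CHH")
        rec = degree_by_cpg_fraction(gene(), pd.concat([cpg, chh]))
        assert rec.degree == 1.0

    def test_batch_matches_single(self, small_genome, small_config):
        from mosaicmeth import call_sites, estimate_error_rate
        from mosaicmeth.simulate import simulate_bsseq

        bs = simulate_bsseq(small_genome, small_genome.truth, small_config, "muscle_like")
        model = estimate_error_rate(bs[bs.contig == "mito"])
        called = call_sites(bs, model.error_rate)
        batch = score_genes_cpg_fraction(small_genome.genes, called)
        for rec in batch[:10]:
            single = degree_by_cpg_fraction(
                small_genome.genes_by_id()[rec.gene_id], called
            )
            assert single == rec


class TestHistogram:
    def test_corner_bins(self):
        recs = score_genes_domain_overlap(
            [
                gene("a", span=(0, 100), cds=(10, 90)),
                gene("b", span=(200, 300), cds=(210, 290)),
                gene("c2", span=(400, 500), cds=(410, 490)),
                gene("d", span=(600, 700), cds=(610, 690)),
            ],
            iset((0, 5), (200, 300), (395, 500)),  # degrees 0.05, 1.0, 0.95... and 0.0
        )
        hist = degree_histogram(recs, n_bins=10)
        assert hist.sum() == 4
        assert hist[0] == 2 and hist[9] == 2

    def test_empty_input(self):
        assert degree_histogram([], n_bins=10).tolist() == [0] * 10

    def test_default_run_is_bimodal(self, small_genome):
        recs = score_genes_domain_overlap(small_genome.genes, small_genome.truth.domains)
        hist = degree_histogram(recs, n_bins=10)
        assert (hist[0] + hist[9]) / hist.sum() > 0.9


class TestMetagene:
    def test_counts_inside_and_upstream(self):
        genes = [
            gene("a", span=(1000, 3000), cds=(1100, 2900)),
            gene("b", span=(5000, 7000), cds=(5100, 6900)),
        ]
        domains = iset((1000, 3000), (5000, 7000))
        profile = metagene_domain_profile(genes, domains, align_at="five_prime", flank=600)
        prof = profile.set_index("rel_pos")["count"]
        assert prof.loc[50] == 2
        assert prof.loc[-500] == 0

    def test_minus_strand_flipped(self):
        g = GeneModel("m", "c", "-", 1000, 3000, 1100, 2900)
        domains = iset((1000, 3000))
        prof = metagene_domain_profile([g], domains, align_at="five_prime", flank=200)
        prof = prof.set_index("rel_pos")["count"]
        # downstream of the TSS (into the body) is leftward on the genome
        assert prof.loc[100] == 1 and prof.loc[-100] == 0

    def test_empty_gene_list(self):
        profile = metagene_domain_profile([], iset((0, 10)), flank=100)
        assert (profile["count"] == 0).all()

    def test_unknown_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            metagene_domain_profile([], iset((0, 10)), align_at="midpoint")

    def test_tss_dip_on_synthetic_truth(self, small_genome):
        genes = small_genome.genes
        domains = small_genome.truth.domains
        profile = metagene_domain_profile(genes, domains, align_at="five_prime", flank=600)
        prof = profile.set_index("rel_pos")["count"]
        lengths = [g.length for g in genes]
        lo, hi = int(0.2 * min(lengths)), int(0.5 * min(lengths))
        plateau = prof.loc[lo:hi].mean()
        assert plateau >= 5 * max(prof.loc[-500], 1)


class TestConvergentPairs:
    def _genes(self, gap_start=1000, gap_end=1600):
        return [
            GeneModel("g1", "c", "+", 0, gap_start, 100, gap_start - 100),
            GeneModel("g2", "c", "-", gap_end, gap_end + 1000, gap_end + 100, gap_end + 900),
        ]

    def test_shared_domain_detected(self):
        pairs = detect_convergent_shared_domain_pairs(self._genes(), iset((100, 2500)))
        assert pairs == [("g1", "g2")]

    def test_short_gap_rejected(self):
        genes = self._genes(gap_end=1400)  # gap 400 <= 500
        assert detect_convergent_shared_domain_pairs(genes, iset((100, 2300))) == []

    def test_interrupted_domain_rejected(self):
        pairs = detect_convergent_shared_domain_pairs(
            self._genes(), iset((100, 1200), (1400, 2500))
        )
        assert pairs == []

    def test_wrong_orientation_rejected(self):
        genes = [
            GeneModel("g1", "c", "-", 0, 1000, 100, 900),
            GeneModel("g2", "c", "+", 1600, 2600, 1700, 2500),
        ]
        assert detect_convergent_shared_domain_pairs(genes, iset((100, 2500))) == []


class TestThresholdSensitivity:
    def test_partition_stable_across_thresholds(self, small_genome):
        """Bimodal truth degrees are insensitive to the lo/hi cutoff choice."""
        genes = small_genome.genes
        domains = small_genome.truth.domains
        partitions = {}
        for lo, hi in [(0.1, 0.9), (0.05, 0.95), (0.2, 0.8)]:
            recs = score_genes_domain_overlap(genes, domains, config=ScoreConfig(lo=lo, hi=hi))
            partitions[(lo, hi)] = {r.gene_id: r.meth_class for r in recs}
        base = partitions[(0.1, 0.9)]
        for key in [(0.05, 0.95), (0.2, 0.8)]:
            changed = sum(base[g] != partitions[key][g] for g in base)
            assert changed / len(base) < 0.02

    def test_mode_agreement_on_truth(self, small_genome, small_config):
        from mosaicmeth import call_sites, estimate_error_rate
        from mosaicmeth.simulate import simulate_bsseq

        domain_recs = score_genes_domain_overlap(small_genome.genes, small_genome.truth.domains)
        bs = simulate_bsseq(small_genome, small_genome.truth, small_config, "muscle_like")
        model = estimate_error_rate(bs[bs.contig == "mito"])
        cpg_recs = score_genes_cpg_fraction(small_genome.genes, call_sites(bs, model.error_rate))
        d = {r.gene_id: r.meth_class for r in domain_recs if r.eligible}
        c = {r.gene_id: r.meth_class for r in cpg_recs if r.eligible}
        both = set(d) & set(c)
        agree = sum(d[g] == c[g] for g in both)
        assert agree / len(both) >= 0.99
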
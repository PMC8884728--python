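"""SNP filters, effect classification, pseudogenes, pN/pS, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from straindyn.io import GeneTable, SnpRecord, SnpTrajectory, ValidationError
from straindyn.simulate import generate_genes
from straindyn.variants import (
    DivergenceParams,
    EffectCall,
    SnpFilterConfig,
    assign_pseudogene_to_strain,
    category_enrichment,
    category_genome_fractions,
    classify_snp_effect,
    compute_pnps,
    detect_pseudogenes,
    divergence_time,
    filter_snps,
    flag_anomalous_genes,
    metagenome_species_abundance,
    nei_gojobori_sites,
)

T = 4  # time points used by the filter fixtures


def site_records(pos, quals=None, depths=None, alt_counts=None, n_alts=1, present=None):
    """A persistent biallelic site across T time points, customizable."""
    quals = quals or [50.0] * T
    depths = depths or [40] * T
    alt_counts = alt_counts if alt_counts is not None else [20] * T
    present = present if present is not None else [True] * T
    recs = []
    for t in range(T):
        if not present[t]:
            continue
        recs.append(
            SnpRecord(
                "sp_00", pos, "A", "G", t, quals[t],
                depth=depths[t], alt_count=alt_counts[t],
                ref_count=depths[t] - alt_counts[t], n_alts_at_site=n_alts,
            )
        )
    return recs


def anchor_site(pos=9999):
    """A clean site guaranteeing full time coverage for the genome."""
    return site_records(pos)


class TestFilterSnps:
    def test_toy_set_retains_only_clean_sites(self):
        records = (
            site_records(100, n_alts=2)                 # triallelic
            + site_records(200, quals=[15.0] * T)       # low quality
            + site_records(300, depths=[8] * T, alt_counts=[4] * T)  # low depth
            + site_records(400)                          # clean
            + site_records(500)                          # clean
        )
        retained, log = filter_snps(records)
        assert {t.position for t in retained} == {400, 500}
        reasons = dict(zip(log["position"], log["reason"]))
        assert reasons == {100: "triallelic", 200: "qual", 300: "depth"}

    def test_persistence_rejects_interrupted_detection(self):
        # detected at t1, absent at t2 while the species is still present
        records = site_records(50, present=[False, True, False, True]) + anchor_site()
        abundance = {"sp_00": [0.2, 0.2, 0.2, 0.2]}
        retained, log = filter_snps(records, species_abundance=abundance)
        assert 50 not in {t.position for t in retained}
        assert log.set_index("position")["reason"][50] == "persistence"

    def test_persistence_waived_after_species_extinction(self):
        records = site_records(60, present=[False, True, False, False]) + anchor_site()
        abundance = {"sp_00": [0.2, 0.2, 0.0, 0.0]}
        retained, _ = filter_snps(records, species_abundance=abundance)
        assert 60 in {t.position for t in retained}

    def test_major_allele_fixed_at_first_detection(self):
        # alt is minor at detection: trajectory reports the ref (major) allele
        records = site_records(70, alt_counts=[10, 12, 30, 35]) + anchor_site()
        retained, _ = filter_snps(records)
        traj = next(t for t in retained if t.position == 70)
        assert not traj.major_is_alt
        assert traj.freqs[0] == pytest.approx(30 / 40)
        assert traj.freqs[3] == pytest.approx(5 / 40)

    def test_missing_time_points_is_error(self):
        records = [r for r in site_records(10) if r.time_index != 2]
        with pytest.raises(ValidationError, match="missing time points"):
            filter_snps(records)

    def test_input_order_invariance(self, rng):
        records = (
            site_records(100, n_alts=2)
            + site_records(200, quals=[15.0] * T)
            + site_records(400)
            + site_records(500, present=[True, True, False, True])
        )
        base, _ = filter_snps(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        again, _ = filter_snps(shuffled)
        assert [t.snp_id for t in base] == [t.snp_id for t in again]


class TestCoverageFlags:
    def test_low_and_high_flags(self):
        cov = pd.DataFrame(
            {"s1": [4.0, 10.0, 31.0, 10.0], "s2": [10.0, 10.0, 10.0, 10.0]},
            index=["low", "ok", "high", "boundary"],
        )
        flags = flag_anomalous_genes(cov)
        assert flags.loc["low", "flagged"] and flags.loc["low", "low"]
        assert flags.loc["high", "flagged"] and flags.loc["high", "high"]
        assert not flags.loc["ok", "flagged"]

    def test_exact_half_median_not_flagged(self):
        cov = pd.DataFrame({"s1": [5.0, 10.0, 10.0, 10.0]}, index=list("abcd"))
        flags = flag_anomalous_genes(cov)  # median 10, gene at exactly 0.5x
        assert not flags.loc["a", "flagged"]

    def test_zero_median_sample_is_error(self):
        cov = pd.DataFrame({"s1": [0.0, 0.0, 1.0]})
        with pytest.raises(ValidationError, match="zero median"):
            flag_anomalous_genes(cov)


class TestSpeciesAbundance:
    @pytest.mark.parametrize(
        "reads,lengths,expected",
        [
            ({"a": 100, "b": 200}, {"a": 1e6, "b": 2e6}, {"a": 0.5, "b": 0.5}),
            ({"a": 300, "b": 100}, {"a": 1e6, "b": 1e6}, {"a": 0.75, "b": 0.25}),
            ({"a": 42}, {"a": 3e6}, {"a": 1.0}),
        ],
    )
    def test_length_normalized_fractions(self, reads, lengths, expected):
        out = metagenome_species_abundance(reads, lengths)
        for k, v in expected.items():
            assert out[k] == pytest.approx(v)

    def test_zero_total_is_error(self):
        with pytest.raises(ValidationError):
            metagenome_species_abundance({"a": 0}, {"a": 1e6})


def gene_table_from_cds(cds, strand="+", start=11, genome_id="sp_00"):
    """Embed one CDS (given on the coding strand) in a synthetic genome."""
    from straindyn.io import reverse_complement

    genomic = reverse_complement(cds) if strand == "-" else cds
    seq = "C" * (start - 1) + genomic + "C" * 10
    table = pd.DataFrame(
        [
            {
                "gene_id": "g1",
                "genome_id": genome_id,
                "start": start,
                "end": start + len(cds) - 1,
                "strand": strand,
                "frame": 0,
                "category": "other",
                "complete": True,
            }
        ]
    )
    return GeneTable(table, {genome_id: seq})


def snp_at(pos, ref, alt, freqs=(0.5,) * 4, genome_id="sp_00", first=0):
    return SnpTrajectory(
        f"{genome_id}:{pos}:{alt}", genome_id, pos, ref, alt,
        np.asarray(freqs, float), np.full(len(freqs), 50.0), first_detected=first,
    )


class TestEffectClassification:
    def test_synonymous_third_position(self):
        genes = gene_table_from_cds("ATGGAAGAATAA")  # M E E *
        # third base of the first GAA codon: GAA->GAG, still Glu
        eff = classify_snp_effect(snp_at(11 + 5, "A", "G"), genes)
        assert eff.effect == "synonymous"
        assert (eff.aa_before, eff.aa_after) == ("E", "E")

    def test_nonsense_call(self):
        genes = gene_table_from_cds("ATGTACGAATAA")  # M Y E *
        # TAC -> TAA premature stop (codon 2, third base)
        eff = classify_snp_effect(snp_at(11 + 5, "C", "A"), genes)
        assert eff.effect == "nonsense"
        assert eff.aa_after == "*"

    def test_minus_strand_reverse_complement(self):
        # coding CDS ATGGAAGAATAA on the minus strand; a genomic C->T at the
        # third base of codon 2 is G->A on the coding strand: GAA->AAA (E->K)
        genes = gene_table_from_cds("ATGGAAGAATAA", strand="-")
        row = genes.table.iloc[0]
        genomic_pos = row["end"] - 3  # first base of codon 2 (G on coding strand)
        eff = classify_snp_effect(snp_at(genomic_pos, "C", "T"), genes)
        assert eff.effect == "nonsynonymous"
        assert (eff.codon_before, eff.codon_after) == ("GAA", "AAA")

    def test_intergenic(self):
        genes = gene_table_from_cds("ATGGAAGAATAA")
        assert classify_snp_effect(snp_at(2, "C", "T"), genes).effect == "intergenic"

    def test_incomplete_frame_unclassified(self):
        genes = gene_table_from_cds("ATGGAAGAATAA")
        genes.table.loc[0, "complete"] = False
        assert classify_snp_effect(snp_at(12, "T", "G"), genes).effect == "unclassified"


class TestPseudogenes:
    def make_effects(self, genes):
        cds = "ATGTACGAATAA"
        traj_mid = snp_at(11 + 5, "C", "A", first=3)       # premature stop
        traj_term = snp_at(11 + 10, "A", "G", first=0)     # in terminal codon
        eff_mid = classify_snp_effect(traj_mid, genes)
        return traj_mid, traj_term, eff_mid

    def test_persistent_premature_stop_called(self):
        genes = gene_table_from_cds("ATGTACGAATAA")
        traj_mid, _, eff_mid = self.make_effects(genes)
        calls = detect_pseudogenes([eff_mid], {traj_mid.snp_id: traj_mid}, genes)
        assert len(calls) == 1
        assert calls.iloc[0]["first_detected"] == 3

    def test_terminal_codon_stop_excluded(self):
        genes = gene_table_from_cds("ATGTACGGATAA")  # TGA creatable in last codon
        # GGA (codon 3) -> TGA via G->T at its first base = premature? codon 3
        # of 4 is not terminal -> called; now craft one in the true final codon
        traj = snp_at(11 + 9 + 1, "A", "G", first=0)  # inside TAA, nonsensical
        eff = classify_snp_effect(traj, genes)
        calls = detect_pseudogenes(
            [e for e in [eff] if e.effect == "nonsense"], {traj.snp_id: traj}, genes
        )
        assert len(calls) == 0

    def test_strain_assignment_rules(self):
        f = np.array([0.7, 0.6, 0.5, 0.4])
        match_1 = snp_at(1, "A", "G", freqs=tuple(f))
        assert assign_pseudogene_to_strain(match_1, f, 2) == "strain_1"
        match_2 = snp_at(1, "A", "G", freqs=tuple(1 - f))
        assert assign_pseudogene_to_strain(match_2, f, 2) == "strain_2"
        # consistent with both strains at 50/50
        both = snp_at(1, "A", "G", freqs=(0.5,) * 4)
        assert assign_pseudogene_to_strain(both, np.full(4, 0.5), 2) == "unassigned"
        # fixed SNP while strains at 0.7/0.3
        neither = snp_at(1, "A", "G", freqs=(1.0,) * 4)
        assert assign_pseudogene_to_strain(neither, np.full(4, 0.7), 2) == "unassigned"
        with pytest.raises(ValidationError):
            assign_pseudogene_to_strain(match_1, f, 1)


class TestPnps:
    def test_site_counts_sum_to_codon_length(self, gene_fixture):
        for gene_id in gene_fixture.table["gene_id"][:10]:
            cds = gene_fixture.coding_sequence(gene_id)
            n, s = nei_gojobori_sites(cds)
            n_codons = len(cds) // 3 - 1  # terminal stop contributes nothing
            assert n + s == pytest.approx(3 * n_codons, abs=1e-9)

    def test_phe_codon_synonymous_sites(self):
        from straindyn.variants import _codon_site_counts

        n, s = _codon_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(3 - 1 / 3)

    def test_neutral_substitutions_give_unit_ratio(self, rng):
        # uniform random single-nt substitutions in random ORFs -> pN/pS ~ 1
        genes = generate_genes(40, 80, seed=17)
        effects = []
        rows = genes.table
        for _ in range(10_000):
            row = rows.iloc[rng.integers(len(rows))]
            offset = int(rng.integers(row["end"] - row["start"] + 1 - 3))  # skip stop
            if row["strand"] == "+":
                pos = row["start"] + offset
            else:
                pos = row["end"] - offset
            ref = genes.sequences[row["genome_id"]][pos - 1]
            alt = "ACGT"[rng.integers(4)]
            while alt == ref:
                alt = "ACGT"[rng.integers(4)]
            eff = classify_snp_effect(snp_at(pos, ref, alt), genes)
            if eff.effect in ("synonymous", "nonsynonymous", "nonsense"):
                effects.append(eff)
        res = compute_pnps(effects, genes)
        assert 0.9 < res.pnps < 1.1

    def test_all_synonymous_set_gives_zero(self):
        genes = gene_table_from_cds("ATGGAAGAATAA")
        eff = classify_snp_effect(snp_at(11 + 5, "A", "G"), genes)  # GAA->GAG
        res = compute_pnps([eff], genes)
        assert res.pnps == 0.0 if not res.undefined else False

    def test_undefined_when_no_synonymous(self):
        genes = gene_table_from_cds("ATGTACGAATAA")
        eff = classify_snp_effect(snp_at(11 + 5, "C", "A"), genes)  # nonsense
        res = compute_pnps([eff], genes)
        assert res.undefined and np.isnan(res.pnps)

    def test_empty_subset_is_error(self):
        genes = gene_table_from_cds("ATGGAAGAATAA")
        with pytest.raises(ValidationError):
            compute_pnps([], genes)


class TestEnrichment:
    def test_exact_binomial_tail(self):
        out = category_enrichment({"cat": 5}, {"cat": 0.1}, total_snps=10)
        # exact tail sum_{k=5..10} C(10,k) 0.1^k 0.9^(10-k)
        expected = sum(
            stats.binom.pmf(k, 10, 0.1) for k in range(5, 11)
        )
        assert expected == pytest.approx(1.635e-3, rel=0.01)
        assert out.iloc[0]["p_value"] == pytest.approx(expected)
        assert out.iloc[0]["enrichment_score"] == pytest.approx(1 / expected)

    def test_zero_observed_gives_p_one(self):
        out = category_enrichment({"cat": 0}, {"cat": 0.2}, total_snps=50)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)
        assert out.iloc[0]["enrichment_score"] == pytest.approx(1.0)

    def test_observed_at_expectation_is_near_half(self):
        out = category_enrichment({"cat": 1000}, {"cat": 0.1}, total_snps=10_000)
        assert out.iloc[0]["p_value"] == pytest.approx(0.5, abs=0.02)

    def test_zero_fraction_with_count_is_error(self):
        with pytest.raises(ValidationError):
            category_enrichment({"cat": 3}, {"cat": 0.0}, total_snps=10)

    def test_fractions_from_gene_lengths(self, gene_fixture):
        fracs = category_genome_fractions(gene_fixture)
        assert sum(fracs.values()) == pytest.approx(1.0)
        assert all(0 < v <= 1 for v in fracs.values())

    def test_pvalues_calibrated_under_uniform_placement(self, rng):
        # SNPs placed uniformly along the coding genome: P(p <= a) ~ a
        fracs = {"A": 0.25, "B": 0.35, "C": 0.4}
        n_snps, reps, alpha = 120, 400, 0.2
        hits = 0
        for _ in range(reps):
            cats = rng.choice(list(fracs), size=n_snps, p=list(fracs.values()))
            obs = int((cats == "A").sum())
            p = category_enrichment({"A": obs}, fracs, n_snps).iloc[0]["p_value"]
            hits += p <= alpha
        rate = hits / reps
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 4 * se + 0.03  # discreteness slack


class TestDivergence:
    def test_one_snp_is_100_generations(self):
        gens, years = divergence_time(1)
        assert gens == pytest.approx(100.0)
        assert years == pytest.approx(1.0)

    def test_zero_snps(self):
        assert divergence_time(0) == (0.0, 0.0)

    def test_scales_linearly(self):
        gens, years = divergence_time(186, DivergenceParams())
        assert gens == pytest.approx(18600.0)
        assert years == pytest.approx(186.0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            DivergenceParams(mu=0)
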
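"""GWAS significance, LD proxying and the shared-disease rule."""

import numpy as np
import pytest

from mirsnpflow import (
    CombinedCandidate,
    Config,
    GwasRecord,
    LdPair,
    Variant,
    attach_associations,
    ld_proxies,
    shared_disease_filter,
    significant_leads,
)


def _cand(rsid, mirna="hsa-miR-1", gene="G1"):
    return CombinedCandidate(
        variant=Variant(rsid, "1", 100, "A", "G", 0.2),
        mirna=mirna, gene=gene, unit_scores={"polymirts": 0.9},
        nbc_score=0.9, effect="disrupt",
    )


class TestSignificantLeads:
    def test_genome_wide_hit_included(self):
        leads = significant_leads(
            [GwasRecord("Inflammatory bowel disease", "rs727088", 4.6e-9, 1.08, True)])
        assert leads == {"Inflammatory bowel disease": {"rs727088"}}

    def test_exact_threshold_excluded(self):
        leads = significant_leads([GwasRecord("Crohn's disease", "rs1", 5e-8, 1.1, False)])
        assert leads == {}

    def test_min_p_merge_across_studies(self):
        leads = significant_leads([
            GwasRecord("Crohn's disease", "rs1", 1e-6, 1.1, False),
            GwasRecord("Crohn's disease", "rs1", 1e-9, 1.2, False),
        ])
        assert leads == {"Crohn's disease": {"rs1"}}

    def test_missing_p_contributes_nothing(self):
        assert significant_leads([GwasRecord("Psoriasis", "rs1", None, None, False)]) == {}


class TestLdProxies:
    def test_perfect_ld_is_proxy(self):
        got = ld_proxies("leadX", [LdPair("leadX", "rs60474474", 1.0, 1.0)])
        assert got == {"leadX", "rs60474474"}

    def test_below_r2_threshold_not_proxy(self):
        got = ld_proxies("leadX", [LdPair("leadX", "rs2", 0.79, 1.0)])
        assert got == {"leadX"}

    def test_dprime_below_one_not_proxy(self):
        got = ld_proxies("leadX", [LdPair("leadX", "rs2", 0.9, 0.98)])
        assert got == {"leadX"}

    def test_r2_exactly_at_threshold_is_proxy(self):
        got = ld_proxies("leadX", [LdPair("leadX", "rs2", 0.8, 1.0)])
        assert got == {"leadX", "rs2"}

    def test_symmetric_lookup(self):
        pair = [LdPair("rs2", "leadX", 1.0, 1.0)]
        assert "rs2" in ld_proxies("leadX", pair)
        assert "leadX" in ld_proxies("rs2", pair)

    def test_dprime_requirement_can_be_disabled(self):
        cfg = Config(require_dprime=False)
        got = ld_proxies("leadX", [LdPair("leadX", "rs2", 0.9, 0.5)], cfg)
        assert got == {"leadX", "rs2"}


class TestAttach:
    def test_direct_evidence_preferred(self):
        gwas = [GwasRecord("Systemic lupus erythematosus", "rs2070197", 3.0e-40, 1.7, True)]
        ld = [LdPair("rs2070197", "rsOther", 1.0, 1.0),
              LdPair("rsOther2", "rs2070197", 1.0, 1.0)]
        gwas.append(GwasRecord("Systemic lupus erythematosus", "rsOther2", 1e-10, 1.2, False))
        [(_, evidence)] = attach_associations([_cand("rs2070197")], gwas, ld)
        assert len(evidence) == 1
        assert evidence[0].support == "direct"
        assert evidence[0].p_value == pytest.approx(3.0e-40)

    def test_proxy_evidence_has_missing_p(self):
        gwas = [GwasRecord("Crohn's disease", "leadX", 2.2e-12, 1.2, True)]
        ld = [LdPair("leadX", "rs60474474", 1.0, 1.0)]
        [(_, evidence)] = attach_associations([_cand("rs60474474")], gwas, ld)
        assert evidence[0].support == "ld_proxy"
        assert evidence[0].proxy_lead_rsid == "leadX"
        assert evidence[0].p_value is None and evidence[0].odds_ratio is None
        assert evidence[0].proxy_r2 == 1.0

    def test_no_lead_no_proxy_empty(self):
        gwas = [GwasRecord("Crohn's disease", "leadX", 0.5, 1.0, False)]
        [(_, evidence)] = attach_associations([_cand("rs1")], gwas, [])
        assert evidence == []

    def test_best_proxy_highest_r2_then_lexicographic(self):
        gwas = [GwasRecord("Crohn's disease", "leadA", 1e-9, 1.1, True),
                GwasRecord("Crohn's disease", "leadB", 1e-9, 1.1, True),
                GwasRecord("Crohn's disease", "leadC", 1e-9, 1.1, True)]
        ld = [LdPair("leadA", "rs1", 0.9, 1.0),
              LdPair("leadB", "rs1", 1.0, 1.0),
              LdPair("leadC", "rs1", 1.0, 1.0)]
        [(_, evidence)] = attach_associations([_cand("rs1")], gwas, ld)
        assert evidence[0].proxy_lead_rsid == "leadB"  # r2 tie broken lexicographically

    def test_agrees_with_brute_force_double_loop(self):
        """Randomized instances of <= 50 SNPs checked against an
        independent exhaustive (candidate, disease, lead) loop."""
        rng = np.random.default_rng(17)
        diseases = ["Crohn's disease", "Type 1 diabetes mellitus", "Psoriasis"]
        cfg = Config()
        for _ in range(20):
            n = int(rng.integers(5, 51))
            rsids = [f"rs{i}" for i in range(n)]
            gwas = [
                GwasRecord(diseases[int(rng.integers(3))], rsids[int(rng.integers(n))],
                           float(10 ** -rng.uniform(2, 12)), 1.1, False)
                for _ in range(n)
            ]
            ld = [
                LdPair(rsids[int(rng.integers(n))], rsids[int(rng.integers(n))],
                       float(rng.uniform()), float(rng.choice([1.0, rng.uniform()])))
                for _ in range(n)
            ]
            cands = [_cand(r) for r in rng.choice(rsids, size=min(10, n), replace=False)]
            got = {
                (c.rsid, e.disease, e.support)
                for c, evs in attach_associations(cands, gwas, ld, cfg)
                for e in evs
            }
            # oracle: brute force over every (candidate, disease, lead)
            expected = set()
            for c in cands:
                for d in diseases:
                    lead_ps = {}
                    for g in gwas:
                        if g.disease == d and g.p_value is not None:
                            lead_ps[g.rsid] = min(g.p_value, lead_ps.get(g.rsid, 1.0))
                    leads = {r for r, p in lead_ps.items() if p < 5e-8}
                    if c.rsid in leads:
                        expected.add((c.rsid, d, "direct"))
                        continue
                    for lead in leads:
                        for pair in ld:
                            ends = {pair.rsid_a, pair.rsid_b}
                            if ends == {c.rsid, lead} and pair.r2 >= 0.8 \
                                    and abs(pair.dprime - 1.0) <= 1e-6:
                                expected.add((c.rsid, d, "ld_proxy"))
            assert got == expected

    def test_monotone_in_thresholds(self, small_bundle):
        """Relaxing the P or r2 threshold never shrinks the output."""
        from mirsnpflow import call_candidates, zscore_harmonize
        cands = call_candidates(zscore_harmonize(small_bundle.predictions), Config())

        def kept(cfg):
            return {c.rsid for c, _ in shared_disease_filter(
                attach_associations(cands, small_bundle.gwas, small_bundle.ld, cfg), cfg)}

        strict = kept(Config())
        assert strict <= kept(Config(gwas_p_threshold=1e-5))
        assert strict <= kept(Config(ld_r2_min=0.5))


class TestSharedDiseaseFilter:
    def _annotated(self, diseases):
        from mirsnpflow.models import AssociationEvidence
        ev = [AssociationEvidence(rsid="rs1", disease=d, p_value=1e-9, support="direct")
              for d in diseases]
        return [(_cand("rs1"), ev)]

    def test_single_disease_dropped(self):
        assert shared_disease_filter(self._annotated(["Crohn's disease"])) == []

    def test_two_diseases_kept(self):
        kept = shared_disease_filter(
            self._annotated(["Crohn's disease", "Type 1 diabetes mellitus"]))
        assert len(kept) == 1

    def test_ibd_cd_uc_count_separately(self):
        kept = shared_disease_filter(self._annotated(
            ["Inflammatory bowel disease", "Crohn's disease", "Ulcerative colitis"]))
        assert len(kept) == 1
        assert len({e.disease for e in kept[0][1]}) == 3

    def test_every_survivor_has_enough_diseases(self, small_bundle, config):
        from mirsnpflow import call_candidates, zscore_harmonize
        cands = call_candidates(zscore_harmonize(small_bundle.predictions), config)
        kept = shared_disease_filter(
            attach_associations(cands, small_bundle.gwas, small_bundle.ld, config), config)
        for _, evs in kept:
            assert len({e.disease for e in evs}) >= config.min_shared_diseases
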
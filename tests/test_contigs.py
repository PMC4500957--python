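"""Contig cascade, identity clustering, taxon assignment, EC/GO summaries."""

from math import comb

import numpy as np
import pandas as pd
import pytest

import trapmeta as tm
from trapmeta.contigs import (Contig, assign_taxon, category_of_assignment,
                              cluster_identity, filter_cascade, go_enrichment,
                              parse_ec_codes, select_annotation_window,
                              tally_functions)

RNG = np.random.default_rng(123)


def rand_seq(n, rng=RNG):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def mutate(seq, rate, rng=RNG):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


@pytest.fixture(scope="module")
def bundle(sim_config=None):
    cfg = tm.SimulationConfig(seed=31)
    tax = tm.make_taxonomy(cfg)
    return tm.make_contigs_and_hits(cfg, tax), tax


class TestCascade:
    def test_survivors_equal_planted_keepers(self, bundle):
        b, _ = bundle
        res = filter_cascade(b.trap_contigs, b.host_transcripts,
                             b.rrna_refs, b.leaf_contigs)
        assert sorted(c.contig_id for c in res.survivors) == \
            b.truth.planted_keepers

    def test_conservation_removed_plus_survivors(self, bundle):
        b, _ = bundle
        res = filter_cascade(b.trap_contigs, b.host_transcripts,
                             b.rrna_refs, b.leaf_contigs)
        assert len(res.removed) + len(res.survivors) == res.n_input

    def test_stage_tags_recorded(self, bundle):
        b, _ = bundle
        res = filter_cascade(b.trap_contigs, b.host_transcripts,
                             b.rrna_refs, b.leaf_contigs)
        by_stage = res.removed.set_index("contig_id")["stage"]
        origin = b.truth.contig_origin
        for cid, stage in by_stage.items():
            klass = origin[cid]
            expected = {"short": "min_length", "host": "host",
                        "rrna": "rrna",
                        "near-duplicate-member": "cluster",
                        "leaf-redundant": "leaf",
                        "mid": "final_min_length"}[klass]
            assert stage == expected, cid

    def test_host_identical_contig_removed_at_host_stage(self):
        host = {"h1": rand_seq(2500)}
        contig = Contig("c1", host["h1"][100:2100])
        res = filter_cascade([contig], host, {}, {})
        assert res.removed.iloc[0]["stage"] == "host"

    def test_short_clean_contig_removed_at_final_cut(self):
        contig = Contig("c1", rand_seq(900))
        res = filter_cascade([contig], {}, {}, {})
        assert res.removed.iloc[0]["stage"] == "final_min_length"

    def test_sub500_removed_first(self):
        contig = Contig("c1", rand_seq(499))
        res = filter_cascade([contig], {}, {}, {})
        assert res.removed.iloc[0]["stage"] == "min_length"

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            filter_cascade([Contig("c", rand_seq(600)),
                            Contig("c", rand_seq(600))], {}, {}, {})

    def test_hit_table_route_matches_search_route(self, bundle):
        b, _ = bundle
        # build a hit table encoding exactly the planted matches
        rows = []
        subjects = {"host": b.host_transcripts, "rrna": b.rrna_refs,
                    "leaf-redundant": b.leaf_contigs}
        for c in b.trap_contigs:
            klass = b.truth.contig_origin[c.contig_id]
            if klass in ("host", "rrna", "leaf-redundant"):
                sid = sorted(subjects[klass])[0]
                rows.append({"qseqid": c.contig_id, "sseqid": sid,
                             "pident": 100.0, "length": c.length,
                             "mismatch": 0, "gapopen": 0, "qstart": 1,
                             "qend": c.length, "sstart": 1, "send": c.length,
                             "evalue": 1e-30, "bitscore": 500.0,
                             "staxid": "NA"})
        hits = pd.DataFrame(rows)
        via_hits = filter_cascade(
            [Contig(c.contig_id, c.sequence) for c in b.trap_contigs],
            b.host_transcripts, b.rrna_refs, b.leaf_contigs, hits=hits)
        via_search = filter_cascade(
            [Contig(c.contig_id, c.sequence) for c in b.trap_contigs],
            b.host_transcripts, b.rrna_refs, b.leaf_contigs)
        assert sorted(c.contig_id for c in via_hits.survivors) == \
            sorted(c.contig_id for c in via_search.survivors)


class TestClustering:
    def test_identical_contigs_one_representative(self):
        seq = rand_seq(1200)
        reps, members = cluster_identity(
            [Contig("a", seq), Contig("b", seq)])
        assert len(reps) == 1
        assert sorted(members[reps[0].contig_id]) == ["a", "b"]

    def test_85pct_pair_clusters_at_080_not_090(self):
        rng = np.random.default_rng(7)
        a = rand_seq(1500, rng)
        b = mutate(a, 0.15, rng)
        pair = [Contig("a", a), Contig("b", b)]
        ident = tm.sequence_identity(a, b)
        assert 0.80 <= ident < 0.90  # constructed pair sits between thresholds
        reps80, _ = cluster_identity(pair, 0.80)
        reps90, _ = cluster_identity(pair, 0.90)
        assert len(reps80) == 1 and len(reps90) == 2

    def test_all_distinct_all_representatives(self):
        contigs = [Contig(f"c{i}", rand_seq(1000)) for i in range(5)]
        reps, _ = cluster_identity(contigs)
        assert len(reps) == 5

    def test_representative_count_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        base = [rand_seq(1200, rng) for _ in range(4)]
        contigs = []
        for i, s in enumerate(base):
            contigs.append(Contig(f"b{i}", s))
            contigs.append(Contig(f"m{i}", mutate(s, 0.12, rng)[:1100]))
        n80 = len(cluster_identity(contigs, 0.80)[0])
        n90 = len(cluster_identity(contigs, 0.90)[0])
        assert n90 >= n80

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        contigs = [Contig(f"c{i}", rand_seq(800, rng)) for i in range(6)]
        r1 = [c.contig_id for c in cluster_identity(contigs)[0]]
        r2 = [c.contig_id for c in cluster_identity(contigs)[0]]
        assert r1 == r2

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            cluster_identity([], 1.5)


class TestAnnotationWindow:
    def test_boundaries_inclusive(self):
        contigs = [Contig("lo", rand_seq(1500)), Contig("hi", rand_seq(8000)),
                   Contig("over", rand_seq(8001)), Contig("under", rand_seq(1499))]
        kept = {c.contig_id for c in select_annotation_window(contigs)}
        assert kept == {"lo", "hi"}

    def test_band_census_matches_planted(self, bundle):
        b, _ = bundle
        res = filter_cascade(b.trap_contigs, b.host_transcripts,
                             b.rrna_refs, b.leaf_contigs)
        window = select_annotation_window(res.survivors)
        n_mid_band = sum(
            1 for c in res.survivors if 1500 <= c.length <= 8000)
        assert len(window) == n_mid_band

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            select_annotation_window([], 2000, 1000)


class TestAssignTaxon:
    def hits(self, rows):
        return pd.DataFrame(rows, columns=["sseqid", "bitscore", "evalue",
                                           "staxid"])

    def test_below_min_bitscore_unassigned(self, bundle):
        _, tax = bundle
        genus = sorted(n.node_id for n in tax.genera())[0]
        h = self.hits([("p1", 49.9, 1e-20, genus)])
        assert assign_taxon(h, tax) is None

    def test_single_strong_hit_assigned(self, bundle):
        _, tax = bundle
        genus = sorted(n.node_id for n in tax.genera())[0]
        h = self.hits([("p1", 120.0, 1e-30, genus)])
        assert assign_taxon(h, tax) == genus

    def test_chordate_best_hit_bucketed_as_metazoa(self, bundle):
        _, tax = bundle
        chordate = next(g.node_id for g in tax.genera()
                        if tax.phylum_of(g.node_id)
                        and tax.phylum_of(g.node_id).name == "Chordata")
        h = self.hits([("p1", 200.0, 1e-40, chordate)])
        node = assign_taxon(h, tax)
        assert category_of_assignment(tax, node) == "Metazoa"

    def test_unknown_taxon_unassigned(self, bundle):
        _, tax = bundle
        h = self.hits([("p1", 200.0, 1e-40, "not_a_node")])
        assert assign_taxon(h, tax) is None

    def test_lca_mode_over_close_hits(self, bundle):
        _, tax = bundle
        bact = sorted(n.node_id for n in tax.genera()
                      if n.category == "Bacteria")
        h = self.hits([("p1", 100.0, 1e-30, bact[0]),
                       ("p2", 95.0, 1e-28, bact[1])])
        node = assign_taxon(h, tax, mode="lca")
        # LCA of two bacterial genera lies at or above their phylum
        lineage_ids = [n.node_id for n in tax.lineage(bact[0])]
        assert node in lineage_ids and node != bact[0]


class TestTallies:
    def test_published_hydrolase_fraction_arithmetic(self):
        """438 hydrolases of 1298 EC-assigned transcripts -> 33.7%."""
        rows = [{"contig_id": f"h{i}", "ec": "3.1.3.2", "category": "Metazoa"}
                for i in range(438)]
        rows += [{"contig_id": f"o{i}", "ec": "2.7.1.1", "category": "Metazoa"}
                 for i in range(1298 - 438)]
        out = tally_functions(pd.DataFrame(rows))
        assert out["n_ec_assigned"] == 1298
        assert out["n_hydrolase"] == 438
        assert out["hydrolase_pct"] == 33.7

    def test_ec_class_membership(self):
        out = tally_functions(pd.DataFrame(
            [{"contig_id": "c", "ec": "3.1.3.2", "category": "SAR"}]))
        assert out["n_phosphatase"] == 1 and out["n_peptidase"] == 0

    def test_multi_ec_transcript_counts_once_per_class(self):
        out = tally_functions(pd.DataFrame(
            [{"contig_id": "c", "ec": "3.1.3.46; 2.7.1.105",
              "category": "SAR"}]))
        assert out["ec_class_histogram"] == {"2": 1, "3": 1}
        assert out["n_ec_assigned"] == 1

    def test_empty_annotations(self):
        out = tally_functions(pd.DataFrame(columns=["contig_id", "ec",
                                                    "category"]))
        assert out["ec_class_histogram"] == {} and out["n_ec_assigned"] == 0

    def test_malformed_ec_skipped(self):
        assert parse_ec_codes("3.1.3.2; bogus.x") == ["3.1.3.2"]
        assert parse_ec_codes("EC:3.4; 1.2.3.-") == ["3.4", "1.2.3.-"]


def exact_two_sided_fisher(a, b, c, d):
    """Independent oracle: exact hypergeometric enumeration with integer
    arithmetic (sum of table probabilities <= the observed one)."""
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n + K - N), min(n, K)
    obs = comb(K, a) * comb(N - K, n - a)
    num = sum(comb(K, k) * comb(N - K, n - k)
              for k in range(lo, hi + 1)
              if comb(K, k) * comb(N - K, n - k) <= obs)
    return num / comb(N, n)


class TestGoEnrichment:
    def frame(self, pairs):
        return pd.DataFrame([{"contig_id": cid, "go": go}
                             for cid, go in pairs])

    def test_subset_equals_background_all_p_one(self):
        bg = self.frame([(f"c{i}", "GO:1") for i in range(10)])
        out = go_enrichment(bg, bg, ontology=None, propagate=False)
        assert (out["p"] == 1.0).all()

    def test_fisher_matches_hypergeometric_oracle(self):
        """Spec table (a=8, b=2, c=10, d=80) plus enumerated small tables,
        agreement to 1e-12."""
        from scipy.stats import fisher_exact
        assert fisher_exact([[8, 2], [10, 80]])[1] == pytest.approx(
            exact_two_sided_fisher(8, 2, 10, 80), abs=1e-12)
        for n in range(1, 19):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        assert fisher_exact([[a, b], [c, d]])[1] == \
                            pytest.approx(exact_two_sided_fisher(a, b, c, d),
                                          abs=1e-12)
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(20, 61))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = int(rng.integers(0, n - a - b + 1))
            d = n - a - b - c
            assert fisher_exact([[a, b], [c, d]])[1] == pytest.approx(
                exact_two_sided_fisher(a, b, c, d), abs=1e-12)

    def test_planted_tenfold_term_flagged(self):
        """A term at ~10x representation in the subset reaches q < 0.05 in
        every one of 20 seeded simulations."""
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            rows = []
            subset_ids = []
            for i in range(40):
                cid = f"s{i}"
                subset_ids.append(cid)
                go = "GO:hit" if rng.random() < 0.5 else "GO:other"
                rows.append({"contig_id": cid, "go": go})
            for i in range(160):
                go = "GO:hit" if rng.random() < 0.05 else "GO:other"
                rows.append({"contig_id": f"b{i}", "go": go})
            bg = pd.DataFrame(rows)
            sub = bg[bg["contig_id"].isin(subset_ids)]
            out = go_enrichment(sub, bg, ontology=None, propagate=False)
            hit = out.set_index("term").loc["GO:hit"]
            assert hit["significant"], f"seed {seed}"

    def test_ancestor_propagation(self):
        ontology = pd.DataFrame([{"term": "GO:root", "parent": ""},
                                 {"term": "GO:leaf", "parent": "GO:root"}])
        bg = self.frame([("c1", "GO:leaf"), ("c2", ""), ("c3", ""),
                         ("c4", "")])
        sub = bg[bg["contig_id"] == "c1"]
        out = go_enrichment(sub, bg, ontology=ontology, propagate=True)
        assert set(out["term"]) == {"GO:leaf", "GO:root"}
        counts = out.set_index("term")
        assert counts.at["GO:root", "subset_with"] == 1

    def test_subset_not_in_background_rejected(self):
        bg = self.frame([("c1", "GO:1")])
        sub = self.frame([("c9", "GO:1")])
        with pytest.raises(ValueError):
            go_enrichment(sub, bg, None, propagate=False)
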
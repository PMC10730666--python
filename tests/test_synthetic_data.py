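import math

import networkx as nx
import numpy as np
import pytest

from polyqnet.geometry import HyperbolicPoint, hyperbolic_distance
from polyqnet.net_io import PWM
from polyqnet.synthetic_data import (
    fit_tail_exponent,
    generate_de_table,
    generate_planted_motif_sequences,
    generate_ps_network,
    generate_sector_gene_sets,
)


class TestPSNetwork:
    def test_initial_clique(self):
        g, _ = generate_ps_network(4, 3, 2.5, 0.3, seed=0)
        assert g.number_of_edges() == 6  # complete graph on m+1 nodes

    def test_zero_temperature_connects_to_m_nearest(self):
        m = 3
        g, truth = generate_ps_network(40, m, 2.5, 0.0, seed=5)
        names = truth.birth_order
        # verify the attachment rule for one late node against a recomputed
        # snapshot of the geometry at its birth time
        t = 30
        beta = truth.beta
        birth_r = 2 * np.log(np.arange(1, 41))
        r_now = beta * birth_r[: t - 1] + (1 - beta) * birth_r[t - 1]
        thetas = np.array([truth.coords[v].theta for v in names])
        d = [
            hyperbolic_distance(
                HyperbolicPoint(birth_r[t - 1], thetas[t - 1]),
                HyperbolicPoint(r_now[s], thetas[s]),
            )
            for s in range(t - 1)
        ]
        nearest = set(np.argsort(d, kind="stable")[:m])
        attached = {
            names.index(v) for v in g.neighbors(names[t - 1])
            if names.index(v) < t - 1
        }
        assert attached == nearest

    def test_every_late_node_brings_exactly_m_links(self):
        m = 3
        g, truth = generate_ps_network(60, m, 2.5, 0.0, seed=2)
        expected = m * (60 - m - 1) + math.comb(m + 1, 2)
        assert g.number_of_edges() == expected

    def test_finite_temperature_keeps_the_edge_budget(self):
        m = 4
        g, _ = generate_ps_network(100, m, 2.7, 0.5, seed=9)
        assert g.number_of_edges() == m * (100 - m - 1) + math.comb(m + 1, 2)

    def test_connected_and_coordinates_cover_nodes(self):
        g, truth = generate_ps_network(120, 2, 3.0, 0.6, seed=3)
        assert nx.is_connected(g)
        assert set(truth.coords) == set(g.nodes)
        assert all(0 <= p.theta < 2 * math.pi for p in truth.coords.values())

    def test_same_seed_reproduces_the_network(self):
        g1, t1 = generate_ps_network(80, 3, 2.5, 0.4, seed=11)
        g2, t2 = generate_ps_network(80, 3, 2.5, 0.4, seed=11)
        assert set(g1.edges) == set(g2.edges)
        assert all(
            t1.coords[v].r == t2.coords[v].r
            and t1.coords[v].theta == t2.coords[v].theta
            for v in t1.coords
        )

    def test_degree_exponent_recovered(self):
        g, _ = generate_ps_network(2000, 3, 2.5, 0.4, seed=1)
        alpha = fit_tail_exponent([d for _, d in g.degree()])
        assert alpha == pytest.approx(2.5, abs=0.3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=3, m=3, gamma=2.5, temp=0.3, seed=0),
            dict(n=10, m=2, gamma=1.5, temp=0.3, seed=0),
            dict(n=10, m=2, gamma=2.5, temp=-0.1, seed=0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_ps_network(**kwargs)


class TestSectorGeneSets:
    @pytest.fixture
    def truth(self):
        _, truth = generate_ps_network(200, 3, 2.5, 0.2, seed=4)
        return truth

    def test_noiseless_planted_terms_equal_their_blocks(self, truth):
        coll, planted = generate_sector_gene_sets(
            truth, n_terms=20, enriched_fraction=0.2, seed=1, noise_rate=0.0
        )
        assert len(planted) == 4
        for term, block in planted.items():
            assert coll[term].genes == block

    def test_blocks_are_angularly_contiguous(self, truth):
        _, planted = generate_sector_gene_sets(truth, 10, 0.3, seed=1)
        edges = np.linspace(0, 2 * math.pi, len(planted) + 1)
        for i, term in enumerate(sorted(planted)):
            thetas = [truth.coords[v].theta for v in planted[term]]
            assert all(edges[i] <= t < edges[i + 1] for t in thetas)

    def test_same_seed_reproduces_collection(self, truth):
        c1, p1 = generate_sector_gene_sets(truth, 15, 0.2, seed=7, noise_rate=0.1)
        c2, p2 = generate_sector_gene_sets(truth, 15, 0.2, seed=7, noise_rate=0.1)
        assert p1 == p2
        assert {t: s.genes for t, s in c1.items()} == {t: s.genes for t, s in c2.items()}

    def test_fraction_out_of_range_rejected(self, truth):
        with pytest.raises(ValueError):
            generate_sector_gene_sets(truth, 10, 0.0, seed=0)

    def test_planted_term_beats_uniform_terms_in_its_block(self, truth):
        """The planted term's hypergeometric p in its own sector is below the
        median p of the uniform terms there (enrichment module as oracle)."""
        from polyqnet.enrichment import enrich_sectors
        from polyqnet.sectors import Sector, SectorPartition

        coll, planted = generate_sector_gene_sets(truth, 30, 0.1, seed=3)
        term, block = sorted(planted.items())[0]
        members = sorted(block, key=lambda v: truth.coords[v].theta)
        thetas = [truth.coords[v].theta for v in members]
        partition = SectorPartition(
            [Sector(1, members, thetas, thetas[0], thetas[-1])]
        )
        res = enrich_sectors(partition, coll, universe=set(truth.coords))
        res = res.set_index("term")
        uniform_p = res.loc[res.index.str.startswith("random"), "p"]
        assert res.loc[term, "p"] < uniform_p.median()


class TestPlantedMotifs:
    @pytest.fixture
    def sharp_pwm(self):
        # near-deterministic 6-mer ACGUAC
        eps = 1e-4
        rows = []
        for base in "ACGUAC":
            row = [eps, eps, eps, eps]
            row["ACGU".index(base)] = 1 - 3 * eps
            rows.append(row)
        return PWM(np.array(rows), threshold=6.0)

    def test_zero_plant_rate_logs_nothing(self, sharp_pwm):
        records, log = generate_planted_motif_sequences(20, 50, sharp_pwm, 0.0, seed=1)
        assert log == []
        assert len(records) == 20
        assert all(len(s) == 50 for _, s in records)

    def test_full_plant_rate_recovered_by_scanner(self, sharp_pwm):
        from polyqnet.motif import scan_pwm

        records, log = generate_planted_motif_sequences(50, 80, sharp_pwm, 1.0, seed=2)
        assert len(log) == 50
        by_id = dict((name, seq) for name, seq in records)
        found = 0
        for name, offset, _ in log:
            hits = scan_pwm((name, by_id[name]), sharp_pwm)
            if any(h.offset == offset for h in hits):
                found += 1
        assert found / len(log) >= 0.9

    def test_same_seed_reproduces_sequences(self, sharp_pwm):
        r1, l1 = generate_planted_motif_sequences(10, 60, sharp_pwm, 0.5, seed=5)
        r2, l2 = generate_planted_motif_sequences(10, 60, sharp_pwm, 0.5, seed=5)
        assert r1 == r2 and l1 == l2

    def test_sequence_shorter_than_motif_rejected(self, sharp_pwm):
        with pytest.raises(ValueError):
            generate_planted_motif_sequences(5, 3, sharp_pwm, 0.5, seed=0)


class TestDETable:
    def test_type_one_error_calibrated_under_the_null(self):
        de = generate_de_table(5000, 0.0, effect_size=1.0, seed=8)
        frac = (de["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_strong_effect_gives_high_power(self):
        de = generate_de_table(2000, 0.1, effect_size=6.0, seed=8)
        planted = de[de["planted"]]
        recovered = ((planted["p"] < 0.05) & (planted["log2FC"] > 0)).mean()
        assert recovered >= 0.95

    def test_same_seed_reproduces_table(self):
        d1 = generate_de_table(500, 0.2, 3.0, seed=13)
        d2 = generate_de_table(500, 0.2, 3.0, seed=13)
        assert d1.equals(d2)

    def test_adjusted_p_dominates_raw_p(self):
        de = generate_de_table(300, 0.1, 4.0, seed=2)
        assert (de["adj_p"] >= de["p"] - 1e-15).all()
        assert de["adj_p"].le(1.0).all()
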
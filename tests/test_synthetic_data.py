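import numpy as np
import pytest

from panagrokit import core_io, synthetic_data as sd
from panagrokit.core_io import node_label
from panagrokit.polyploid_origin import parse_leaf_label


class TestSimulateVariants:
    def test_homozygous_without_error_is_all_reference(self):
        spec = sd.PloidySimSpec("homozygous", n_sites=500, error_rate=0.0, seed=1)
        assert all(s.alt_count == 0 for s in sd.simulate_variants(spec))

    @pytest.mark.parametrize(
        "ploidy_class,kwargs,expected_p",
        [
            ("diploid_het", {}, 0.5),
            ("triploid", {"frac_two_thirds": 0.0}, 1.0 / 3.0),
            ("triploid", {"frac_two_thirds": 1.0}, 2.0 / 3.0),
        ],
    )
    def test_mean_alt_fraction_matches_design(self, ploidy_class, kwargs, expected_p):
        spec = sd.PloidySimSpec(
            ploidy_class, n_sites=10_000, mean_depth=50, error_rate=0.0,
            seed=5, **kwargs,
        )
        sites = sd.simulate_variants(spec)
        mean_f = np.mean([s.alt_fraction for s in sites])
        assert mean_f == pytest.approx(expected_p, abs=0.01)

    def test_law_of_large_numbers_with_error(self):
        """At n=1e5 the empirical mean is within 3 sigma of the blurred p."""
        e = 0.005
        spec = sd.PloidySimSpec(
            "diploid_het", n_sites=100_000, mean_depth=50, error_rate=e, seed=9
        )
        fractions = np.array([s.alt_fraction for s in sd.simulate_variants(spec)])
        p_eff = 0.5  # symmetric blur leaves p = 1/2 fixed
        sigma = fractions.std() / np.sqrt(len(fractions))
        assert abs(fractions.mean() - p_eff) < 3 * sigma

    def test_deterministic_under_fixed_seed(self):
        spec = sd.PloidySimSpec("triploid", n_sites=200, seed=42)
        assert sd.simulate_variants(spec) == sd.simulate_variants(spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            sd.PloidySimSpec("tetraploid")
        with pytest.raises(ValueError):
            sd.PloidySimSpec("triploid", error_rate=0.2)


class TestSimulateHitEvidence:
    def test_deterministic(self):
        spec = sd.HgtSimSpec(3, 2, 1, seed=4)
        assert sd.simulate_hit_evidence(spec) == sd.simulate_hit_evidence(spec)

    def test_single_native_gene_has_better_metazoan_hit(self):
        fx = sd.simulate_hit_evidence(sd.HgtSimSpec(1, 0, 0, seed=0))
        meta = [h for h in fx.hits if h.taxon_partition == "metazoan"]
        non = [h for h in fx.hits if h.taxon_partition == "non_metazoan"]
        assert meta and (not non or min(h.evalue for h in meta) < min(h.evalue for h in non))

    def test_hgt_genes_share_contigs_with_metazoan_hitting_genes(self):
        fx = sd.simulate_hit_evidence(sd.HgtSimSpec(0, 5, 0, seed=2))
        contigs_of_hgt = {
            g.contig for g in fx.genes if fx.truth[g.gene_id] == "hgt"
        }
        anchor_contigs = {
            g.contig for g in fx.genes if fx.truth[g.gene_id] == "anchor"
        }
        assert contigs_of_hgt <= anchor_contigs

    def test_contaminants_lack_introns_and_expression(self):
        fx = sd.simulate_hit_evidence(sd.HgtSimSpec(0, 0, 3, seed=3))
        for g in fx.genes:
            assert g.intron_count == 0
            assert fx.tpm[g.gene_id] < 10


class TestSimulatePresenceMatrix:
    def test_no_loss_presence_equals_gain_clade(self, species_tree):
        spec = sd.GainLossSimSpec(n_families=50, loss_rate=0.0, seed=6)
        matrix, truth = sd.simulate_presence_matrix(spec)
        for family in matrix.families:
            gain = core_io.find_node(species_tree, truth.gain_node[family])
            clade = {l.taxon.label for l in gain.leaf_iter()}
            assert set(matrix.present_species(family)) == clade

    def test_weights_concentrated_on_root(self):
        spec = sd.GainLossSimSpec(
            n_families=20, loss_rate=0.0, seed=6,
            gain_node_weights={"root": 1.0},
        )
        _, truth = sd.simulate_presence_matrix(spec)
        assert set(truth.gain_node.values()) == {"root"}

    def test_every_family_present_somewhere(self):
        spec = sd.GainLossSimSpec(n_families=100, loss_rate=0.8, seed=1)
        matrix, _ = sd.simulate_presence_matrix(spec)
        assert matrix.data.any(axis=1).all()

    def test_deterministic(self):
        spec = sd.GainLossSimSpec(n_families=30, loss_rate=0.2, seed=12)
        m1, t1 = sd.simulate_presence_matrix(spec)
        m2, t2 = sd.simulate_presence_matrix(spec)
        assert m1.data.equals(m2.data)
        assert t1 == t2


class TestSimulateGeneTrees:
    def test_auto_extra_copies_are_sisters_of_conspecifics(self):
        trees = sd.simulate_gene_trees(
            sd.OriginSimSpec("auto", n_trees=3, noise_nni=0, seed=1)
        )
        for tree in trees:
            for leaf in tree.leaf_node_iter():
                species, copy = parse_leaf_label(leaf.taxon.label)
                if copy == 2:
                    siblings = [
                        n for n in leaf.parent_node.child_nodes() if n is not leaf
                    ]
                    assert len(siblings) == 1 and siblings[0].is_leaf()
                    assert siblings[0].taxon.label == f"{species}|copy1"

    def test_allo_extra_copies_form_clade_on_donor_edge(self):
        trees = sd.simulate_gene_trees(
            sd.OriginSimSpec("allo", n_trees=3, noise_nni=0, seed=1)
        )
        for tree in trees:
            extras = [
                l.taxon.label for l in tree.leaf_node_iter()
                if parse_leaf_label(l.taxon.label)[1] == 2
            ]
            clade = core_io.mrca(tree, extras)
            assert {l.taxon.label for l in clade.leaf_iter()} == set(extras)
            # the clade's sister contains every copy-1 leaf of the donor-edge
            # clade (panagro: all congeners), i.e. the graft sits basal to it
            sister = [
                n for n in clade.parent_node.child_nodes() if n is not clade
            ]
            assert len(sister) == 1
            sister_leaves = {l.taxon.label for l in sister[0].leaf_iter()}
            assert {
                f"{s}|copy1"
                for s in ("PS1159", "PS1579", "DAW1", "ES5", "superbus")
            } == sister_leaves

    def test_nni_noise_preserves_leaf_set(self):
        ref = sd.simulate_gene_trees(
            sd.OriginSimSpec("allo", n_trees=1, noise_nni=0, seed=7)
        )[0]
        noisy = sd.simulate_gene_trees(
            sd.OriginSimSpec("allo", n_trees=1, noise_nni=5, seed=7)
        )[0]
        assert set(core_io.leaf_labels(ref)) == set(core_io.leaf_labels(noisy))

    def test_deterministic(self):
        spec = sd.OriginSimSpec("auto", n_trees=4, noise_nni=2, seed=3)
        t1 = [t.as_string(schema="newick") for t in sd.simulate_gene_trees(spec)]
        t2 = [t.as_string(schema="newick") for t in sd.simulate_gene_trees(spec)]
        assert t1 == t2


class TestSimulateAlignedPair:
    def test_mismatch_fraction_matches_designed_distance(self):
        d = 0.15
        a, b = sd.simulate_aligned_pair(100_000, d, seed=8)
        p_expected = 0.75 * (1 - np.exp(-4 * d / 3))
        p_obs = sum(x != y for x, y in zip(a, b)) / len(a)
        assert p_obs == pytest.approx(p_expected, abs=0.01)

    def test_zero_distance_identical(self):
        a, b = sd.simulate_aligned_pair(1000, 0.0, seed=1)
        assert a == b
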
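"""Synthetic-data generators: determinism, planted-truth recovery, contracts."""

import numpy as np
import pytest

from dosetrx import rbp
from dosetrx.simulate import (DEFAULT_SPECIES_IDENTITIES, _archetype_means,
                              simulate_counts, simulate_events,
                              simulate_genome_with_motifs, simulate_orthologs,
                              simulate_trait)
from dosetrx.types import GROUPS, Motif


class TestDesign:
    def test_layout(self, design24):
        assert len(design24) == 24
        assert {d.group for d in design24} == set(GROUPS)
        assert sum(d.is_reference for d in design24) == 6  # the N0 samples
        assert len({d.sample_id for d in design24}) == 24


class TestCounts:
    def test_same_seed_identical(self, design24):
        a, _, _ = simulate_counts(design24, n_genes=60, seed=7)
        b, _, _ = simulate_counts(design24, n_genes=60, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_different_seed_differs(self, design24):
        a, _, _ = simulate_counts(design24, n_genes=60, seed=7)
        b, _, _ = simulate_counts(design24, n_genes=60, seed=8)
        assert not np.array_equal(a.counts, b.counts)

    def test_poisson_limit_recovers_planted_means(self, design24):
        """phi -> 0 with large means: per-group sample means within 5% of truth."""
        cm, _, truth = simulate_counts(
            design24, n_genes=60, phi=0.0, seed=1,
            baseline_range=(1e4, 1e4), n_per_archetype=5, library_sigma=0.0)
        idx = {g: i for i, g in enumerate(cm.genes)}
        cols = {g: [j for j, d in enumerate(design24) if d.group == g]
                for g in GROUPS}
        for gene, arch in truth.profile_archetype.items():
            if arch == "null":
                continue
            fold = truth.deg_genes[gene]
            means = _archetype_means(1e4, 1e4 * fold, arch)
            for g in GROUPS:
                observed = cm.counts[idx[gene], cols[g]].mean()
                assert observed == pytest.approx(means[g], rel=0.05)

    def test_zero_planted_all_null(self, design24):
        _, _, truth = simulate_counts(design24, n_genes=60, seed=2,
                                      n_per_archetype=0)
        assert set(truth.profile_archetype.values()) == {"null"}
        assert truth.deg_genes == {} and truth.hub_gene is None

    def test_lengths_and_models_consistent(self, design24):
        cm, models, _ = simulate_counts(design24, n_genes=50, seed=0,
                                        n_per_archetype=5)
        by_id = {m.gene_id: m for m in models}
        for g, L in zip(cm.genes, cm.lengths):
            assert by_id[g].effective_length == int(L)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            _archetype_means(100.0, 300.0, "counter_effect")  # L8 = 2*100-300 < 0


class TestEvents:
    def test_psi_one_all_inclusion(self, design24):
        """True PSI 1.0 gives all-inclusion counts and a PSI estimate of exactly 1."""
        from dosetrx.splicing import compute_psi
        events, _ = simulate_events(design24, n_events=20, coverage=50,
                                    n_diff=0, seed=0, base_psi=1.0)
        for ev in events:
            for s in ev.inclusion:
                assert ev.inclusion[s] == 50 and ev.exclusion[s] == 0
                assert compute_psi(ev.inclusion[s], ev.exclusion[s]) == 1.0

    def test_planted_dpsi_recovered(self, design24):
        """True |dPSI| 0.4 at coverage 100: empirical mean within 0.05."""
        events, truth = simulate_events(design24, n_events=100, coverage=100,
                                        n_diff=100, dpsi=0.4, seed=5)
        deltas = []
        for ev in events:
            true_psi = truth.diff_events[ev.event_id]
            inc_c = [ev.inclusion[f"L0_{r}"] for r in range(1, 7)]
            inc_t = [ev.inclusion[f"N0_{r}"] for r in range(1, 7)]
            deltas.append(abs(np.mean(inc_t) - np.mean(inc_c)) / 100)
            assert abs(true_psi["N0"] - true_psi["L0"]) == pytest.approx(0.4, abs=1e-9)
        assert np.mean(deltas) == pytest.approx(0.4, abs=0.05)

    def test_low_coverage_rejected(self, design24):
        with pytest.raises(ValueError, match="coverage"):
            simulate_events(design24, n_events=5, coverage=0)

    def test_determinism(self, design24):
        a, _ = simulate_events(design24, n_events=10, n_diff=3, seed=4)
        b, _ = simulate_events(design24, n_events=10, n_diff=3, seed=4)
        assert all(x.inclusion == y.inclusion for x, y in zip(a, b))


class TestGenomeMotifs:
    @pytest.fixture()
    def events(self, design24):
        events, truth = simulate_events(design24, n_events=40, n_diff=15, seed=9)
        return events, set(truth.diff_events)

    def test_certain_plant_always_hits(self, events):
        evs, diff = events
        motif = Motif("RBP_A", "m1", consensus="GGAGGAA")
        genome, _ = simulate_genome_with_motifs(evs, diff, motif,
                                                p_diff=1.0, p_bg=0.0, seed=3)
        for ev in evs:
            if ev.event_id in diff:
                regions = rbp.build_binding_regions(ev, genome)
                assert any(rbp.scan_motif(r, motif) for r in regions), ev.event_id

    def test_plants_inside_untrimmed_intervals(self, events):
        evs, diff = events
        motif = Motif("RBP_A", "m1", consensus="GGAGGAA")
        genome, truth = simulate_genome_with_motifs(evs, diff, motif,
                                                    p_diff=1.0, p_bg=1.0, seed=3)
        by_id = {e.event_id: e for e in evs}
        for eid, start in truth.planted_motif["planted_positions"].items():
            ev = by_id[eid]
            region = rbp.build_binding_regions(ev, genome)[0]
            assert any(a <= start and start + motif.width <= b
                       for a, b in region.intervals)
            # trimmed splice-site-adjacent zones stay motif-free by construction
            s, e = ev.exon
            for z in (range(s - 10, s), range(e, e + 10)):
                assert not (start < z.stop and start + motif.width > z.start)

    def test_same_seed_identical_fasta(self, events):
        evs, diff = events
        motif = Motif("RBP_A", "m1", consensus="GGAGGAA")
        g1, _ = simulate_genome_with_motifs(evs, diff, motif, seed=11)
        g2, _ = simulate_genome_with_motifs(evs, diff, motif, seed=11)
        assert g1 == g2


class TestTrait:
    @pytest.fixture()
    def group_means(self):
        import pandas as pd
        return pd.DataFrame({"L0": [10.0], "L4": [20.0], "L8": [30.0],
                             "N0": [40.0]}, index=["hub"])

    def test_noiseless_perfect_correlation(self, design24, group_means):
        trait = simulate_trait(design24, group_means, "hub", slope=-0.5,
                               noise_sd=0.0, seed=0)
        tg = trait.set_index("sample_id")["tg_mg_dl"]
        group_tg = [tg[[f"{g}_{r}" for r in range(1, 7)]].mean() for g in GROUPS]
        r = np.corrcoef(group_means.loc["hub"].to_numpy(), group_tg)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_sign_follows_slope(self, design24, group_means):
        for slope, sign in ((2.0, 1), (-2.0, -1)):
            trait = simulate_trait(design24, group_means, "hub", slope=slope,
                                   noise_sd=1.0, seed=1)
            tg = trait.set_index("sample_id")["tg_mg_dl"]
            group_tg = [tg[[f"{g}_{r}" for r in range(1, 7)]].mean() for g in GROUPS]
            r = np.corrcoef(group_means.loc["hub"].to_numpy(), group_tg)[0, 1]
            assert np.sign(r) == sign

    def test_null_slope_mostly_uncorrelated(self, design24, group_means):
        """slope = 0: mean |r| over 200 seeds well below the edge threshold."""
        rs = []
        for seed in range(200):
            trait = simulate_trait(design24, group_means, "hub", slope=0.0,
                                   noise_sd=5.0, seed=seed)
            tg = trait.set_index("sample_id")["tg_mg_dl"]
            group_tg = [tg[[f"{g}_{r}" for r in range(1, 7)]].mean() for g in GROUPS]
            rs.append(abs(np.corrcoef(group_means.loc["hub"], group_tg)[0, 1]))
        assert np.mean(rs) < 0.9


class TestOrthologs:
    def test_full_identity(self):
        seqs, _ = simulate_orthologs(pig_length=300,
                                     species_identities={"human": 1.0}, seed=0)
        assert seqs["human"] == seqs["sus_scrofa"]

    def test_planted_identity_recovered(self):
        seqs, _ = simulate_orthologs(pig_length=1000,
                                     species_identities={"dog": 0.8}, seed=1)
        matches = sum(a == b for a, b in zip(seqs["sus_scrofa"], seqs["dog"]))
        assert matches / 1000 * 100 == pytest.approx(80.0, abs=1.0)

    def test_default_species_set(self):
        seqs, truth = simulate_orthologs(seed=2)
        assert set(seqs) == {"sus_scrofa", *DEFAULT_SPECIES_IDENTITIES}
        assert np.mean(list(truth.species_identities.values())) == pytest.approx(0.80)

    def test_identity_out_of_range(self):
        with pytest.raises(ValueError, match="identity"):
            simulate_orthologs(species_identities={"human": 1.2})

    def test_indels_change_length(self):
        seqs, _ = simulate_orthologs(pig_length=500,
                                     species_identities={"mouse": 0.9},
                                     seed=3, indel_rate=0.05)
        assert len(seqs["mouse"]) != 500 or seqs["mouse"] != seqs["sus_scrofa"]
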
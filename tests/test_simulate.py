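"""Synthetic-data generator: determinism, round-trips and planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crckit import io as cio
from crckit.circuitry import nucleosome_free_regions
from crckit.motifs import scan_regions
from crckit.screen import normalize_and_fc
from crckit.simulate import (
    ScreenConfig,
    SynthConfig,
    generate_regulatory_genome,
    simulate_expression,
    simulate_ppi,
    simulate_screen,
    simulate_tracks,
)
from conftest import mini_config


class TestDeterminism:
    def test_same_seed_identical_layout(self):
        a = generate_regulatory_genome(mini_config(seed=3))
        b = generate_regulatory_genome(mini_config(seed=3))
        assert a.assembly.sequence == b.assembly.sequence
        assert [(t.transcript_id, t.tss) for t in a.transcripts] \
            == [(t.transcript_id, t.tss) for t in b.transcripts]
        assert a.implant_map == b.implant_map

    def test_same_seed_identical_expression(self, mini_dataset):
        from crckit.simulate import simulate_dataset

        again = simulate_dataset(mini_config(seed=7))
        pd.testing.assert_frame_equal(mini_dataset.expression, again.expression)

    def test_screen_deterministic(self):
        a, down_a, _ = simulate_screen(ScreenConfig(), seed=5)
        b, down_b, _ = simulate_screen(ScreenConfig(), seed=5)
        assert down_a == down_b
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestLayoutStructure:
    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            generate_regulatory_genome(mini_config(genome_length=200_000))

    def test_no_atac_peaks_no_implants(self):
        cfg = mini_config(n_atac_peaks=0, driver_edge_count=0,
                          nondriver_edge_count=0)
        lay = generate_regulatory_genome(cfg)
        assert len(lay.atac) == 0
        assert all(v == [] for v in lay.implant_map.values())

    def test_implants_rediscovered_by_scanner(self, mini_dataset):
        lay = mini_dataset.layout
        nfr = nucleosome_free_regions(lay.atac, lay.landscape_elements)
        hits = scan_regions(lay.pwms, nfr, lay.assembly, q_max=1e-5)
        for tf, pidx in lay.implant_map.items():
            hit_peaks = set()
            for h in hits[tf]:
                for i in lay.atac.overlapping_indices(h.region):
                    hit_peaks.add(i)
            assert hit_peaks == set(pidx)

    def test_emitted_files_roundtrip(self, mini_dataset, tmp_path):
        from crckit.simulate import write_dataset

        write_dataset(mini_dataset, tmp_path)
        lay = mini_dataset.layout
        asm = cio.read_fasta(tmp_path / "genome.fa")
        assert asm.sequence == lay.assembly.sequence
        txs = cio.read_transcripts_tsv(tmp_path / "genes.tsv")
        assert [(t.transcript_id, t.tss, t.strand) for t in txs] \
            == [(t.transcript_id, t.tss, t.strand) for t in lay.transcripts]
        atac = cio.read_narrowpeak(tmp_path / "atac.narrowPeak")
        assert [(r.start, r.end) for r in atac] \
            == [(r.start, r.end) for r in lay.atac]
        motifs = cio.read_meme(tmp_path / "pwms.meme")
        assert [m[0] for m in motifs] == [m.name for m in lay.pwms]
        np.testing.assert_allclose(motifs[0][1], lay.pwms[0].probs, atol=2e-6)
        placements, total = cio.read_fragments_bed(
            tmp_path / "reads_brd4_hscp_1.bed")
        track = mini_dataset.tracks[("brd4", "hscp", 1)]
        assert total == track.total_mapped
        assert len(placements) == track.n_placements


class TestTracks:
    def test_no_gain_centers_fold_change_at_zero(self):
        cfg = mini_config(seed=9, driver_brd4_gain=1.0)
        lay = generate_regulatory_genome(cfg)
        tracks = simulate_tracks(lay)
        from crckit.signal import region_auc

        drv = set()
        for p in lay.implant_map[lay.driver_tf]:
            drv.update(lay.landscape_elements.overlapping_indices(lay.atac[p]))
        fcs = []
        for i in drv:
            ivr = lay.landscape_elements[i]
            a = np.mean([region_auc(tracks[("brd4", "hscp", r)], ivr).auc_rpm
                         for r in (1, 2)])
            b = np.mean([region_auc(tracks[("brd4", "lscp", r)], ivr).auc_rpm
                         for r in (1, 2)])
            fcs.append(np.log2((a + 1) / (b + 1)))
        assert np.mean(fcs) == pytest.approx(0.0, abs=0.1)

    def test_gain_two_recovers_near_unit_fold_change(self, mini_dataset):
        from crckit.signal import region_auc

        lay = mini_dataset.layout
        tracks = mini_dataset.tracks
        drv = set()
        for p in lay.implant_map[lay.driver_tf]:
            drv.update(lay.landscape_elements.overlapping_indices(lay.atac[p]))
        fcs = []
        for i in drv:
            ivr = lay.landscape_elements[i]
            a = np.mean([region_auc(tracks[("brd4", "hscp", r)], ivr).auc_rpm
                         for r in (1, 2)])
            b = np.mean([region_auc(tracks[("brd4", "lscp", r)], ivr).auc_rpm
                         for r in (1, 2)])
            fcs.append(np.log2((a + 1) / (b + 1)))
        assert abs(np.mean(fcs)) == pytest.approx(1.0, abs=0.15)


class TestExpression:
    def test_zero_noise_monotone_in_brd4(self):
        cfg = mini_config(seed=4, expression_noise_sd=0.0)
        lay = generate_regulatory_genome(cfg)
        tracks = simulate_tracks(lay)
        expr = simulate_expression(lay, tracks)
        from crckit.signal import gene_signal_table

        brd4 = {"hscp": [tracks[("brd4", "hscp", r)] for r in (1, 2)]}
        table = gene_signal_table(lay.transcripts, lay.landscape_elements, brd4,
                                  assembly=lay.assembly)
        active = set(lay.active_gene_names)
        mask = table["gene_name"].isin(active).to_numpy()
        rpm = table["hscp"].to_numpy()[mask]
        fpkm = expr["hscp_rep1"].to_numpy()[mask]
        order = np.argsort(rpm)
        assert (np.diff(fpkm[order]) >= -1e-9).all()

    def test_active_genes_at_least_ten_fpkm(self, mini_dataset):
        expr = mini_dataset.expression
        active = set(mini_dataset.layout.active_gene_names)
        mask = expr["gene_name"].isin(active)
        reps = [c for c in expr.columns if c != "gene_name"]
        assert (expr.loc[mask, reps].max(axis=1) >= 10.0).all()

    def test_driver_targets_upregulated_in_gain_condition(self, mini_dataset):
        expr = mini_dataset.expression
        targets = set(mini_dataset.truth.driver_target_genes)
        active = set(mini_dataset.layout.active_gene_names)
        lscp = [c for c in expr.columns if c.startswith("lscp")]
        hscp = [c for c in expr.columns if c.startswith("hscp")]
        fc = np.log2((expr[lscp].mean(axis=1) + 1)
                     / (expr[hscp].mean(axis=1) + 1))
        in_t = fc[expr["gene_name"].isin(targets)]
        out_t = fc[expr["gene_name"].isin(active - targets)]
        res = stats.mannwhitneyu(in_t, out_t, alternative="greater")
        assert res.pvalue < 0.01


class TestPpi:
    def test_zero_noise_two_components(self):
        import networkx as nx

        ppi, truth = simulate_ppi([f"T{i}" for i in range(16)], seed=2,
                                  inter_p=0.0)
        g = nx.Graph()
        g.add_nodes_from(truth)
        g.add_edges_from(zip(ppi["protein1"], ppi["protein2"]))
        comps = list(nx.connected_components(g))
        assert len(comps) == 2
        for comp in comps:
            assert len({truth[n] for n in comp}) == 1

    def test_every_tf_connected(self):
        ppi, truth = simulate_ppi([f"T{i}" for i in range(20)], seed=3)
        touched = set(ppi["protein1"]) | set(ppi["protein2"])
        assert touched == set(truth)


class TestScreenGenerator:
    def test_zero_effect_centered(self):
        cfg = ScreenConfig(planted_down=0, planted_up=0)
        table, down, up = simulate_screen(cfg, seed=8)
        assert down == [] and up == []
        fc = normalize_and_fc(table, "t1")
        assert fc.mean() == pytest.approx(0.0, abs=0.05)

    def test_planted_genes_depleted(self):
        table, down, up = simulate_screen(ScreenConfig(), seed=9)
        fc = normalize_and_fc(table, "t1")
        genes = pd.Series({s: table.sgrna_to_gene[s] for s in fc.index})
        down_fc = fc[genes.isin(down).to_numpy()].mean()
        neutral_fc = fc[~genes.isin(down + up).to_numpy()].mean()
        assert down_fc < neutral_fc - 1.0
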
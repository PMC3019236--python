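"""The synthetic-data generator: geometry, MTP structure, gradients, signals."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from poolanchor.core_io import BACRecord, PhysicalMap, ROW_LETTERS
from poolanchor.deconvolve import te_filter
from poolanchor.pooling import PoolLayout
from poolanchor.synthetic import (
    SimulationConfig,
    attenuation,
    inject_te_probes,
    place_genes,
    random_repeat_library,
    simulate,
    simulate_physical_map,
    simulate_signals,
)


def small_cfg(**overrides) -> SimulationConfig:
    base = dict(n_genes=300, seed=11)
    base.update(overrides)
    return SimulationConfig(**base)


NOISELESS = dict(
    background_lognormal=(0.0, 0.0),
    bac_abundance_cv=0.0,
    identity_distribution=("fixed", 1.0),
    duplicate_probability=0.0,
    n_te_probes=0,
)


class TestGeometry:
    def test_three_axis_pool_counts(self):
        cfg = small_cfg()
        pm, _ = simulate_physical_map(cfg)
        layout = PoolLayout.from_physical_map(pm, cfg.n_plates, cfg.n_rows, cfg.n_cols)
        assert len(layout.pool_ids("plate")) == 20
        assert len(layout.pool_ids("row")) == 16
        assert len(layout.pool_ids("column")) == 24
        assert len(layout.pool_ids()) == 60

    def test_full_plate_pool_sizes(self):
        # with every well of a 20 x 16 x 24 geometry occupied, each row pool
        # holds 20 x 24 = 480 BACs and each column pool 20 x 16 = 320
        records = []
        i = 0
        for plate in range(1, 21):
            for r in range(16):
                for col in range(1, 25):
                    records.append(
                        BACRecord(f"B{i:05d}", plate, ROW_LETTERS[r], col, None,
                                  None, None)
                    )
                    i += 1
        pm = PhysicalMap(records)
        layout = PoolLayout.from_physical_map(pm, 20, 16, 24)
        assert all(len(layout.pools[p].members) == 480 for p in layout.pool_ids("row"))
        assert all(
            len(layout.pools[p].members) == 320 for p in layout.pool_ids("column")
        )
        assert all(
            len(layout.pools[p].members) == 384 for p in layout.pool_ids("plate")
        )

    def test_each_bac_in_exactly_one_pool_per_axis(self):
        cfg = small_cfg()
        pm, _ = simulate_physical_map(cfg)
        layout = PoolLayout.from_physical_map(pm, cfg.n_plates, cfg.n_rows, cfg.n_cols)
        for bac_id in pm.bacs:
            axes = sorted(
                p.axis for p in layout.pools.values() if bac_id in p.members
            )
            assert axes == ["column", "plate", "row"]

    def test_capacity_exceeded_rejected(self):
        cfg = small_cfg(n_plates=2, n_rows=2, n_cols=2)
        with pytest.raises(ValueError, match="capacity"):
            simulate_physical_map(cfg)


class TestMTPStructure:
    def test_full_coverage_zero_overlap_tiles_exactly(self):
        cfg = small_cfg(
            mtp_coverage_fraction=1.0, mtp_overlap_fraction=0.0,
            chromosome_length_bp=50_000_000, unbinned_contig_fraction=0.0,
        )
        pm, _ = simulate_physical_map(cfg)
        total = sum(
            rec.end_bp - rec.start_bp for rec in pm.bacs.values()
        )
        assert total == cfg.chromosome_length_bp
        assert pm.overlaps == set()

    def test_default_coverage_and_overlap(self):
        cfg = small_cfg()
        pm, _ = simulate_physical_map(cfg)
        covered = sum(pm.contig_length_bp(c) for c in pm.contigs)
        assert covered / cfg.chromosome_length_bp == pytest.approx(0.82, abs=0.02)
        # consecutive BACs within each contig overlap by roughly 30%
        fracs = []
        for contig, members in pm.contigs.items():
            for a, b in zip(members, members[1:]):
                ra, rb = pm.bacs[a], pm.bacs[b]
                ov = ra.end_bp - rb.start_bp
                fracs.append(ov / (ra.end_bp - ra.start_bp))
        assert np.mean(fracs) == pytest.approx(0.30, abs=0.05)
        assert all(f > 0 for f in fracs)

    def test_contigs_tile_their_length(self):
        pm, _ = simulate_physical_map(small_cfg())
        for contig, members in pm.contigs.items():
            recs = sorted(
                (pm.bacs[b] for b in members), key=lambda r: r.start_bp
            )
            end = recs[0].start_bp
            for rec in recs:
                assert rec.start_bp <= end  # no internal gap
                end = max(end, rec.end_bp)
            assert end - recs[0].start_bp == pm.contig_length_bp(contig)


class TestGenePlacement:
    def test_degenerate_gradient_is_uniform(self):
        cfg = small_cfg(
            n_genes=5000, density_gradient_ratio=1.0,
            island_fraction_distal=0.0, island_fraction_proximal=0.0,
            duplicate_probability=0.0,
        )
        pm, truth = simulate_physical_map(cfg)
        place_genes(cfg, pm, truth)
        x = np.array(
            [g.placements[0].position_bp for g in truth.genes.values()]
        ) / cfg.chromosome_length_bp
        assert stats.kstest(x, "uniform").pvalue > 0.01

    def test_twofold_gradient_outer_vs_inner_density(self):
        ratios = []
        for seed in range(20):
            cfg = small_cfg(
                n_genes=5000, seed=seed,
                island_fraction_distal=0.0, island_fraction_proximal=0.0,
                duplicate_probability=0.0,
            )
            pm, truth = simulate_physical_map(cfg)
            place_genes(cfg, pm, truth)
            L = cfg.chromosome_length_bp
            x = np.array([g.placements[0].position_bp for g in truth.genes.values()])
            c = cfg.centromere_fraction * L
            outer = ((x < 0.05 * L) | (x > 0.95 * L)).sum()
            inner = ((x > c - 0.05 * L) & (x < c + 0.05 * L)).sum()
            ratios.append(outer / inner)
        # linear ramp with ratio 2: expected outer/inner density ~ 1.85
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.20)

    def test_pure_island_placement_recovered_in_closed_loop(self):
        from poolanchor.deconvolve import GeneLocus
        from poolanchor.genespace import detect_islands

        cfg = small_cfg(
            n_genes=200, island_fraction_distal=1.0, island_fraction_proximal=1.0,
            duplicate_probability=0.0, island_gap_bp=50_000,
        )
        pm, truth = simulate_physical_map(cfg)
        place_genes(cfg, pm, truth)
        loci = [
            GeneLocus(
                locus_id=pid, probe_id=pid,
                bac_ids=g.placements[0].bac_ids,
                contig_id=pm.contig_of(g.placements[0].bac_ids[0]),
            )
            for pid, g in truth.genes.items()
            if g.placements[0].bac_ids
        ]
        assignment = detect_islands(loci, pm, gap_bp=cfg.island_gap_bp)
        island_members = {
            lid for ids in assignment.members.values() for lid in ids
        }
        planted = {
            pid for pid, g in truth.genes.items()
            if g.island_id is not None and g.placements[0].bac_ids
        }
        assert planted <= island_members

    def test_identity_distribution_draws(self):
        cfg = small_cfg(identity_distribution=("fixed", 0.93))
        pm, truth = simulate_physical_map(cfg)
        place_genes(cfg, pm, truth)
        assert {g.identity for g in truth.genes.values()} == {0.93}


class TestSignals:
    def test_attenuation_anchor_points(self):
        assert attenuation(1.0, 0.86) == 0.0
        # probe-target pair at 90% identity with a drawn decrease of 0.86:
        # base signal 100 leaves 100 x (1 - 0.86) = 14.0 over background
        assert 100.0 * (1.0 - attenuation(0.90, 0.86)) == pytest.approx(14.0)
        assert attenuation(0.80, 0.86) == 1.0
        assert attenuation(0.70, 0.86) == 1.0
        assert 0.86 < attenuation(0.85, 0.86) < 1.0

    def test_noiseless_positive_pools_match_truth(self):
        cfg = small_cfg(**NOISELESS)
        pm, truth = simulate_physical_map(cfg)
        layout = PoolLayout.from_physical_map(pm, cfg.n_plates, cfg.n_rows, cfg.n_cols)
        place_genes(cfg, pm, truth)
        lib = random_repeat_library()
        inject_te_probes(truth, lib, cfg)
        sm = simulate_signals(truth, layout, pm, cfg)
        expected = truth.expected_pools(layout, pm)
        for probe_id, pools in expected.items():
            row = sm.data.loc[probe_id]
            assert set(row.index[row > 1.0]) == pools

    def test_gap_probe_is_background_only(self):
        cfg = small_cfg(**NOISELESS)
        pm, truth = simulate_physical_map(cfg)
        layout = PoolLayout.from_physical_map(pm, cfg.n_plates, cfg.n_rows, cfg.n_cols)
        place_genes(cfg, pm, truth)
        inject_te_probes(truth, random_repeat_library(), cfg)
        sm = simulate_signals(truth, layout, pm, cfg)
        gap_probes = [
            pid for pid, g in truth.genes.items() if not g.placements[0].bac_ids
        ]
        assert gap_probes, "the MTP leaves gaps, some genes must fall in them"
        for pid in gap_probes:
            if len(truth.genes[pid].placements) == 1:
                assert (sm.data.loc[pid] == 1.0).all()

    def test_reproducible_given_seed(self):
        cfg = small_cfg()
        b1 = simulate(cfg)
        b2 = simulate(dataclasses.replace(cfg))
        assert b1.truth.genes.keys() == b2.truth.genes.keys()
        for pid in b1.truth.genes:
            g1, g2 = b1.truth.genes[pid], b2.truth.genes[pid]
            assert g1.identity == g2.identity
            assert [p.position_bp for p in g1.placements] == [
                p.position_bp for p in g2.placements
            ]
        assert b1.signals.data.equals(b2.signals.data)
        assert b1.gmap.entries.equals(b2.gmap.entries)


class TestTEProbes:
    def test_zero_te_probes_leaves_truth_unchanged(self):
        cfg = small_cfg(n_te_probes=0)
        pm, truth = simulate_physical_map(cfg)
        place_genes(cfg, pm, truth)
        before = set(truth.genes)
        inject_te_probes(truth, random_repeat_library(), cfg)
        assert truth.te_probes == set()
        assert set(truth.genes) == before

    def test_injected_probes_are_flagged_by_te_filter(self):
        cfg = small_cfg(n_te_probes=5)
        pm, truth = simulate_physical_map(cfg)
        place_genes(cfg, pm, truth)
        lib = random_repeat_library()
        inject_te_probes(truth, lib, cfg)
        te_seqs = {pid: truth.probe_sequences[pid] for pid in truth.te_probes}
        flagged, _ = te_filter(te_seqs, lib)
        assert flagged == truth.te_probes

    def test_short_perfect_match_not_flagged(self, rng):
        # a 44-nt perfect window with an unrelated remainder stays below the
        # 45-nt span rule
        lib = random_repeat_library(rng=rng)
        rep = lib.sequences["REP01"]
        probe = rep[10:54] + "".join(rng.choice(list("ACGT"), size=16))
        flagged, table = te_filter({"p": probe}, lib)
        if table.iloc[0]["span_nt"] <= 44:
            assert flagged == set()


def test_reference_maps_have_expected_synteny_fractions():
    cfg = SimulationConfig(n_genes=2000, seed=5)
    bundle = simulate(cfg)
    ref = bundle.reference_truth
    barley = ref[ref["barley_chr"].notna()]
    syn = (barley["barley_chr"] == "3H").mean()
    assert syn == pytest.approx(1 - cfg.nonsyntenic_fraction_barley, abs=0.04)
    rice = ref[ref["rice_chr"].notna()]
    assert (rice["rice_chr"] == "Os01").mean() == pytest.approx(
        1 - cfg.nonsyntenic_fraction_rice, abs=0.04
    )
    assert len(barley) / len(ref) == pytest.approx(cfg.mapped_fraction_barley, abs=0.04)
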
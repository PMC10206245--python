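import math

import numpy as np
import pandas as pd
import pytest

from mircornet.enrich import hypergeom_test
from mircornet.qc import cpm, drop_zero_features
from mircornet.synthetic import (
    SyntheticConfig,
    generate_counts,
    generate_pathways,
    generate_sequences,
    generate_targetscan_table,
)
from mircornet.targets import scan_seed_sites

from conftest import SMALL_SYNTH

SMALL = dict(SMALL_SYNTH)


@pytest.fixture(scope="module")
def small_dataset():
    cfg = SyntheticConfig(seed=11, **SMALL)
    mir_cm, gene_cm, truth = generate_counts(cfg)
    mirna_seqs, utr_seqs = generate_sequences(truth, cfg)
    return cfg, mir_cm, gene_cm, truth, mirna_seqs, utr_seqs


class TestGenerateCounts:
    def test_shapes_and_groups(self, small_dataset):
        cfg, mir_cm, gene_cm, truth, *_ = small_dataset
        assert mir_cm.counts.shape == (
            cfg.n_mirna + cfg.n_low_mirna + cfg.n_zero_mirna,
            cfg.n_fh_mirna + cfg.n_sfh_mirna,
        )
        assert gene_cm.counts.shape == (cfg.n_gene, cfg.n_fh_mrna + cfg.n_sfh_mrna)
        assert len(gene_cm.samples_in("SFH")) == cfg.n_sfh_mrna

    def test_determinism_byte_identical(self):
        a = generate_counts(SyntheticConfig(seed=5, **SMALL))
        b = generate_counts(SyntheticConfig(seed=5, **SMALL))
        pd.testing.assert_frame_equal(a[0].counts, b[0].counts)
        pd.testing.assert_frame_equal(a[1].counts, b[1].counts)
        assert a[2].target_pairs == b[2].target_pairs

    def test_different_seed_different_data(self):
        a = generate_counts(SyntheticConfig(seed=5, **SMALL))
        b = generate_counts(SyntheticConfig(seed=6, **SMALL))
        assert not a[0].counts.equals(b[0].counts)

    def test_zero_row_bookkeeping(self, small_dataset):
        cfg, mir_cm, _, truth, *_ = small_dataset
        n_zero = int((mir_cm.counts.sum(axis=1) == 0).sum())
        # truth records the observed zero-row count (planted rows plus
        # low-abundance rows that drew all zeros)
        assert n_zero == truth.n_zero_mirna >= cfg.n_zero_mirna
        filtered = drop_zero_features(mir_cm)
        assert len(filtered.counts) == len(mir_cm.counts) - n_zero

    def test_frac_de_zero_means_no_de(self):
        cfg = SyntheticConfig(seed=3, **{**SMALL, 'frac_de_mirna': 0.0})
        *_, truth = generate_counts(cfg)
        assert truth.de_mirnas == []
        assert truth.target_pairs == []

    def test_nonpositive_coupling_slope_errors(self):
        with pytest.raises(ValueError, match="coupling_slope"):
            generate_counts(SyntheticConfig(seed=0, coupling_slope=0.0, **SMALL))

    def test_zero_group_errors(self):
        with pytest.raises(ValueError):
            generate_counts(SyntheticConfig(seed=0, n_sfh_mrna=0, **SMALL))

    def test_small_log2fc_floor_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            SyntheticConfig(seed=0, de_log2fc_range=(0.2, 2.0), **SMALL).validate()

    def test_counts_overdispersed(self):
        """Marginal NB check: per-feature variance exceeds the mean."""
        cfg = SyntheticConfig(
            seed=9, n_gene=1000, n_mirna=20, n_low_mirna=5, n_zero_mirna=2,
            frac_de_mirna=0.0, n_target_pairs=0,
            n_fh_mrna=40, n_sfh_mrna=40,
        )
        _, gene_cm, _ = generate_counts(cfg)
        vals = gene_cm.counts.to_numpy(float)
        mean = vals.mean(axis=1)
        var = vals.var(axis=1, ddof=1)
        big = mean > 50  # Poisson noise would swamp the check at low counts
        assert (var[big] > mean[big]).mean() > 0.95

    def test_planted_negative_correlation_strong_coupling(self):
        """With strong coupling and small noise, nearly every planted pair
        correlates below -0.6 in its active group (200 pairs, fixed seed)."""
        cfg = SyntheticConfig(
            seed=21,
            n_mirna=100,
            n_gene=300,
            n_low_mirna=0,
            n_zero_mirna=0,
            frac_de_mirna=0.5,
            n_regulators=50,
            n_target_pairs=200,
            rewired_fraction=0.0,
            coupling_slope=2.0,
            coupling_noise_sd=0.05,
            latent_sd=1.0,
        )
        mir_cm, gene_cm, truth = generate_counts(cfg)
        mcpm, gcpm = cpm(mir_cm), cpm(gene_cm)
        fh = [f"FH{i}" for i in range(1, 8)]
        rs = []
        for m, g in truth.pairs_active_in("FH"):
            x = np.log2(mcpm.cpm.loc[m, fh].to_numpy() + 1)
            y = np.log2(gcpm.cpm.loc[g, fh].to_numpy() + 1)
            rs.append(np.corrcoef(x, y)[0, 1])
        assert (np.array(rs) < -0.6).mean() >= 0.9

    def test_inactive_group_uncorrelated(self):
        """Rewired pairs carry no coupling in their inactive group.

        Measured at 30 samples per group: at the study's own n = 6/7 the
        null sampling floor alone puts ~16-21% of independent pairs past
        |r| = 0.6, which would mask the construction property."""
        cfg = SyntheticConfig(seed=17, **{**SMALL, "rewired_fraction": 1.0,
                                          "n_fh_mirna": 30, "n_sfh_mirna": 30,
                                          "n_fh_mrna": 30, "n_sfh_mrna": 30})
        mir_cm, gene_cm, truth = generate_counts(cfg)
        mcpm, gcpm = cpm(mir_cm), cpm(gene_cm)
        cols = {"FH": [f"FH{i}" for i in range(1, 31)],
                "SFH": [f"SFH{i}" for i in range(1, 31)]}
        rs = []
        for m, g, active in truth.target_pairs:
            inactive = "SFH" if active == ("FH",) else "FH"
            x = np.log2(mcpm.cpm.loc[m, cols[inactive]].to_numpy() + 1)
            y = np.log2(gcpm.cpm.loc[g, cols[inactive]].to_numpy() + 1)
            rs.append(np.corrcoef(x, y)[0, 1])
        assert (np.abs(np.array(rs)) < 0.6).mean() >= 0.9


class TestGenerateSequences:
    def test_determinism(self, small_dataset):
        cfg, *_ , truth, mirna_seqs, utr_seqs = small_dataset
        cfg2 = SyntheticConfig(seed=11, **SMALL)
        _, _, truth2 = generate_counts(cfg2)
        m2, u2 = generate_sequences(truth2, cfg2)
        assert m2 == mirna_seqs
        assert u2 == utr_seqs

    def test_mirna_lengths(self, small_dataset):
        *_, mirna_seqs, _ = small_dataset
        assert all(21 <= len(s) <= 22 for s in mirna_seqs.values())
        assert all(set(s) <= set("ACGU") for s in mirna_seqs.values())

    def test_scanner_full_recall_of_planted_sites(self, small_dataset):
        *_, truth, mirna_seqs, utr_seqs = small_dataset
        for m, tx, site_type, pos in truth.planted_sites:
            hits = scan_seed_sites(mirna_seqs[m], utr_seqs[tx], m, tx)
            assert any(
                h.site_type == site_type and h.utr_start == pos for h in hits
            )

    def test_decoy_utrs_clean(self, small_dataset):
        """100% precision: no planted miRNA has any hit in a decoy UTR."""
        *_, truth, mirna_seqs, utr_seqs = small_dataset
        target_tx = {tx for _, tx, _, _ in truth.planted_sites}
        decoys = [tx for tx in utr_seqs if tx not in target_tx]
        for m in truth.regulators:
            for tx in decoys:
                assert scan_seed_sites(mirna_seqs[m], utr_seqs[tx]) == []

    def test_unpopulated_truth_errors(self):
        from mircornet.synthetic import SyntheticTruth

        with pytest.raises(ValueError, match="populated"):
            generate_sequences(SyntheticTruth(), SyntheticConfig())


class TestTargetscanTable:
    def test_planted_pairs_pass_confidence_cut(self, small_dataset):
        *_, truth, mirna_seqs, utr_seqs = small_dataset
        table = generate_targetscan_table(truth, mirna_seqs, utr_seqs)
        scores = {
            (m, g): s for m, g, s in table.itertuples(index=False)
        }
        for m, g, _ in truth.target_pairs:
            assert scores[(m, g)] <= -0.4


class TestGeneratePathways:
    def test_enriched_term_composition(self, small_dataset):
        *_, truth, _, _ = small_dataset
        terms = generate_pathways(truth)
        assert truth.enriched_term in terms
        targets = {g for _, g, _ in truth.target_pairs}
        overlap = len(terms[truth.enriched_term] & targets)
        assert overlap == truth.enriched_overlap

    def test_planted_term_exact_tail_example(self):
        """10 of 15 members among 40 targets in a 741-gene universe is
        overwhelming evidence: exact tail below 1e-6."""
        universe = {f"g{i}" for i in range(741)}
        targets = {f"g{i}" for i in range(40)}
        term = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(700, 705)}
        assert hypergeom_test(targets, term, universe) < 1e-6

    def test_no_pairs_no_enriched_term(self):
        cfg = SyntheticConfig(seed=4, **{**SMALL, 'n_target_pairs': 0})
        *_, truth = generate_counts(cfg)
        terms = generate_pathways(truth)
        assert truth.enriched_term is None
        assert len(terms) >= 20

    def test_decoy_count_and_sizes(self, small_dataset):
        *_, truth, _, _ = small_dataset
        terms = generate_pathways(truth, n_decoys=22, decoy_size_range=(5, 30))
        decoys = [t for t in terms if t.startswith("DECOY")]
        assert len(decoys) == 22
        assert all(5 <= len(terms[t]) <= 30 for t in decoys)

    def test_universe_too_small_errors(self, small_dataset):
        *_, truth, _, _ = small_dataset
        with pytest.raises(ValueError, match="universe"):
            generate_pathways(truth, decoy_size_range=(10, 10_000))
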
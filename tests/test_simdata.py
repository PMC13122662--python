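import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score

from plurimap.demux import assign_tags, normalize_tags
from plurimap.embed import EnsembleConfig, clara, mds_embedding, preprocess
from plurimap.simdata import (
    PROGRAMS,
    STATES,
    SimConfig,
    inject_doublets,
    simulate_counts,
    simulate_dataset,
    simulate_tags,
)


class TestSimConfigValidation:
    def test_program_sizes_exceeding_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimConfig(n_genes=100, program_sizes={p: 50 for p in PROGRAMS})

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"doublet_rate": 0.7},
            {"tag_background_fraction": 0.9},
            {"nb_dispersion": 0.0},
            {"base_mean": -1.0},
            {"branch_noise_sd": -0.1},
            {"n_cells_per_state": {"not_a_state": 10}},
        ],
    )
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestSimulateCounts:
    def test_seeded_determinism(self, small_config):
        c1, t1 = simulate_counts(small_config)
        c2, t2 = simulate_counts(small_config)
        assert (c1.matrix != c2.matrix).nnz == 0
        assert t1.cells.equals(t2.cells)

    def test_truth_and_matrix_dimensions_agree(self, small_config):
        counts, truth = simulate_counts(small_config)
        assert list(truth.cells.index) == counts.barcodes
        assert list(truth.gene_programs.index) == counts.genes

    def test_no_signal_makes_states_exchangeable(self):
        cfg = SimConfig(
            seed=3,
            n_cells_per_state={s: 60 for s in STATES},
            program_logfc={p: 0.0 for p in PROGRAMS},
            branch_noise_sd=0.0,
            nb_dispersion=np.inf,
            base_mean=2.0,
            primed_heterogeneity=0.0,
            doublet_rate=0.0,
        )
        counts, truth = simulate_counts(cfg)
        means = {
            s: counts.matrix[:, (truth.cells["state"] == s).to_numpy()].mean()
            for s in STATES
        }
        vals = np.array(list(means.values()))
        # all states share mean 2.0; allow Monte-Carlo spread
        assert np.allclose(vals, 2.0, atol=0.05)

    def test_program_fold_change_matches_nb_model(self):
        # naive-program genes: activation 0.8 in naive cells (plateau mode),
        # 0 in primed -> expected ratio exp(logfc * 0.8)
        cfg = SimConfig(
            seed=5,
            n_cells_per_state={"primed": 500, "naive": 500},
            discrete_states=True,
            primed_heterogeneity=0.0,
            doublet_rate=0.0,
            base_mean=0.1,
            program_logfc={**{p: 0.0 for p in PROGRAMS}, "naive": 3.0},
        )
        counts, truth = simulate_counts(cfg)
        genes = truth.gene_programs == "naive"
        naive_cells = (truth.cells["state"] == "naive").to_numpy()
        m_naive = counts.matrix[genes.to_numpy()][:, naive_cells].mean()
        m_primed = counts.matrix[genes.to_numpy()][:, ~naive_cells].mean()
        mu_off, mu_on = 0.1, 0.1 * np.exp(3.0 * 0.8)
        # 3 Monte-Carlo SEs of each sample mean (NB variance mu + mu^2/r)
        n = 500 * 50
        se_on = np.sqrt((mu_on + mu_on**2 / cfg.nb_dispersion) / n)
        se_off = np.sqrt((mu_off + mu_off**2 / cfg.nb_dispersion) / n)
        assert abs(m_naive - mu_on) < 3 * se_on
        assert abs(m_primed - mu_off) < 3 * se_off
        assert m_naive / m_primed == pytest.approx(np.exp(2.4), rel=0.2)

    def test_latent_time_spans_each_lineage(self, small_config):
        _, truth = simulate_counts(small_config)
        for lin, grp in truth.cells.groupby("lineage"):
            assert grp["latent_time"].min() < 0.1
            assert grp["latent_time"].max() > 0.9


class TestInjectDoublets:
    def test_rate_zero_is_identity(self, small_config):
        counts, truth = simulate_counts(small_config)
        c2, t2 = inject_doublets(counts, truth, 0.0, seed=1)
        assert c2 is counts and t2 is truth

    def test_doublet_profile_is_sum_of_members(self, small_config):
        counts, truth = simulate_counts(small_config)
        c2, t2 = inject_doublets(counts, truth, 0.1, seed=1)
        n_d = int(np.floor(0.1 * counts.n_cells))
        assert t2.cells["is_doublet"].sum() == n_d
        assert c2.n_cells == counts.n_cells - n_d
        # doublet column total equals the sum of two original cells' totals
        totals_in = np.asarray(counts.matrix.sum(axis=0)).ravel()
        doublet_bc = t2.cells.index[t2.cells["is_doublet"]][0]
        col = c2.barcodes.index(doublet_bc)
        total_out = c2.matrix[:, col].sum()
        matches = np.isclose(
            totals_in[None, :] + totals_in[:, None], total_out
        ).any()
        assert matches and total_out > np.median(totals_in)

    def test_doublet_totals_stochastically_dominate(self):
        cfg = SimConfig(
            seed=9,
            n_cells_per_state={"primed": 500, "naive": 500},
            doublet_rate=0.0,
        )
        counts, truth = simulate_counts(cfg)
        c2, t2 = inject_doublets(counts, truth, 0.1, seed=2)
        totals = np.asarray(c2.matrix.sum(axis=0)).ravel()
        dbl = t2.cells["is_doublet"].to_numpy()
        stat = mannwhitneyu(totals[dbl], totals[~dbl], alternative="greater")
        assert stat.pvalue < 0.01

    def test_rate_out_of_range_rejected(self, small_config):
        counts, truth = simulate_counts(small_config)
        with pytest.raises(ValueError):
            inject_doublets(counts, truth, 0.9, seed=0)


class TestSimulateTags:
    def test_zero_background_gives_single_positive_tag(self):
        cfg = SimConfig(
            seed=2,
            n_cells_per_state={"primed": 300, "naive": 300},
            tag_background_fraction=0.0,
            doublet_rate=0.0,
        )
        _, truth = simulate_counts(cfg)
        tags = simulate_tags(truth, cfg)
        positive_tags = (tags.matrix > 0).sum(axis=0)
        assert (positive_tags == 1).all()

    def test_doublet_count_matches_configured_rate(self):
        cfg = SimConfig(
            seed=4,
            n_cells_per_state={"primed": 1000, "naive": 1000},
            doublet_rate=0.1,
        )
        counts, tags, truth = simulate_dataset(cfg)
        n_doublets = int(truth.cells["is_doublet"].sum())
        assert counts.n_cells == 2000
        # expected 200; must lie inside the binomial 99% interval
        assert 167 <= n_doublets <= 233

    def test_heavy_background_degrades_demux_accuracy(self):
        accs = {}
        for bg in (0.05, 0.5):
            cfg = SimConfig(
                seed=6,
                n_cells_per_state={"primed": 400, "naive": 400},
                tag_depth={"HT1": 300, "HT2": 300},
                tag_background_fraction=bg,
                doublet_rate=0.0,
            )
            _, truth = simulate_counts(cfg)
            tags = simulate_tags(truth, cfg)
            assign = assign_tags(normalize_tags(tags))
            accs[bg] = (
                assign["hashtag"].to_numpy() == truth.cells["hashtag"].to_numpy()
            ).mean()
        assert accs[0.5] < accs[0.05]

    def test_single_hashtag_with_doublets_rejected(self):
        cfg = SimConfig(
            seed=1,
            n_cells_per_state={"primed": 100},
            tag_depth={"HT1": 500},
            doublet_rate=0.1,
        )
        _, truth = simulate_counts(cfg)
        with pytest.raises(ValueError, match="hashtags"):
            simulate_tags(truth, cfg)


class TestStateRecovery:
    def test_clara_recovers_separable_states_perfectly(self, blob_config):
        """With flattened gradients, no heterogeneity and strong fold-changes,
        the seven states are separable blobs and CLARA at k = 7 matches the
        truth with ARI 1.0."""
        counts, truth = simulate_counts(blob_config)
        prep = preprocess(counts)
        emb = mds_embedding(prep.matrix)
        states = truth.cells.loc[prep.barcodes, "state"]
        ids = {s: i for i, s in enumerate(sorted(set(states)))}
        run = clara(emb, 7, EnsembleConfig(), seed=5)
        assert adjusted_rand_score([ids[s] for s in states], run.labels) == 1.0
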
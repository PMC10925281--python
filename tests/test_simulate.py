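"""Generator contracts: degenerate limits, determinism, generative means,
doublet construction, ambient bookkeeping, and the assay simulators."""

import numpy as np
import pytest

from rdnamag import LOW_RDNA, NORMAL_RDNA, ValidationError, estimate_concentration
from rdnamag.simulate import (
    CELL_TYPES,
    PlantedEffect,
    SimulationConfig,
    simulate_cross,
    simulate_ddpcr,
    simulate_experiment,
)


def bare_config(**overrides):
    """Minimal clean experiment: marker programs only, no noise processes."""
    programs = {
        "GSC": {"nos": 40.0, "ovo": 40.0},
        "SG": {"sg_gene": 40.0},
        "cyst": {"tj": 40.0, "zfh1": 40.0},
        "spermatocyte": {"fzo": 40.0},
        "spermatid": {"m-cup": 40.0},
    }
    defaults = dict(
        n_genes=50,
        n_cells_per_type_per_condition={t: 30 for t in CELL_TYPES},
        marker_programs=programs,
        shared_programs=[{"genes": {"vas": 40.0}, "types": ("GSC", "SG")}],
        planted_effects=[],
        ambient_fraction=0.0,
        doublet_rate=0.0,
        qc_outlier_rate=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestSimulateExperiment:
    def test_degenerate_parameters_make_pure_type_programs(self):
        """With rho=delta=outliers=0 and zero background, nonzero genes of
        every cell come only from its own type's (plus shared) program."""
        cfg = bare_config(baseline_mean=0.0, marker_baseline=0.0, planted_gene_mean=0.0)
        matrix, truth = simulate_experiment(cfg)
        assert not truth.doublet_barcodes
        program_of = {
            "GSC": {"nos", "ovo", "vas"},
            "SG": {"sg_gene", "vas"},
            "cyst": {"tj", "zfh1"},
            "spermatocyte": {"fzo"},
            "spermatid": {"m-cup"},
        }
        dense = np.asarray(matrix.counts.todense())
        for j, bc in enumerate(matrix.cell_barcodes):
            ctype = truth.cells.loc[bc, "cell_type"]
            nonzero = {matrix.gene_ids[i] for i in np.flatnonzero(dense[:, j])}
            assert nonzero <= program_of[ctype]

    def test_same_seed_identical_output(self):
        m1, t1 = simulate_experiment(bare_config(seed=7))
        m2, t2 = simulate_experiment(bare_config(seed=7))
        assert m1.equals(m2)
        assert t1.cells.equals(t2.cells)

    def test_planted_gsc_effect_recovers_generative_ratio(self):
        """A GSC-only log2FC=-1 halves the gene's mean in low-condition GSCs;
        the empirical ratio matches 0.5 within 3 SE at ~2,000 GSCs."""
        cfg = bare_config(
            n_cells_per_type_per_condition={"GSC": 1000, "SG": 50, "spermatocyte": 50,
                                            "spermatid": 50, "cyst": 50},
            planted_effects=[PlantedEffect("gene0001", ("GSC",), -1.0)],
            seed=11,
        )
        matrix, truth = simulate_experiment(cfg)
        g = matrix.gene_counts("gene0001")
        cond = matrix.cell_meta["condition"].to_numpy()
        is_gsc = truth.cells.loc[matrix.cell_barcodes, "cell_type"].to_numpy() == "GSC"
        low = g[is_gsc & (cond == LOW_RDNA)]
        normal = g[is_gsc & (cond == NORMAL_RDNA)]
        ratio = low.mean() / normal.mean()
        se = ratio * np.sqrt(
            low.var(ddof=1) / (len(low) * low.mean() ** 2)
            + normal.var(ddof=1) / (len(normal) * normal.mean() ** 2)
        )
        assert ratio == pytest.approx(0.5, abs=3 * se)

    def test_ambient_preserves_expected_library_size(self):
        """Mixing a fraction rho of the soup into each cell leaves the
        expected total counts unchanged."""
        cfg0 = bare_config(seed=3)
        cfg5 = bare_config(seed=3, ambient_fraction=0.5)
        m0, _ = simulate_experiment(cfg0)
        m5, _ = simulate_experiment(cfg5)
        t0, t5 = m0.counts_per_cell().mean(), m5.counts_per_cell().mean()
        # totals are random; compare means across ~300 cells
        assert t5 == pytest.approx(t0, rel=0.05)

    def test_doublets_carry_both_programs(self, doublet_experiment):
        """At delta > 0, doublet barcodes are GSC:cyst mixtures: positive for
        both germline and cyst markers at close to the doublet rate."""
        matrix, truth = doublet_experiment
        # threshold 2 keeps low-level ambient marker leakage out of the call
        vas = matrix.gene_counts("vas") >= 2
        nos = matrix.gene_counts("nos") >= 2
        tj = matrix.gene_counts("tj") >= 2
        zfh1 = matrix.gene_counts("zfh1") >= 2
        mixed = vas & nos & tj & zfh1
        dbl = np.array([b in truth.doublet_barcodes for b in matrix.cell_barcodes])
        assert dbl.mean() == pytest.approx(0.10, abs=0.02)
        # mixed-marker barcodes occur at ~ the doublet rate
        assert mixed.mean() == pytest.approx(0.10, abs=0.03)
        assert mixed[dbl].mean() > 0.95
        assert mixed[~dbl].mean() < 0.05
        assert truth.doublet_barcodes.isdisjoint(truth.singlet_barcodes)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValidationError):
            bare_config(ambient_fraction=0.6, doublet_rate=0.5)
        with pytest.raises(ValidationError):
            bare_config(planted_effects=[PlantedEffect("not_a_gene", ("GSC",), 1.0)],
                        n_genes=10)

    def test_shared_marker_in_two_programs_rejected(self):
        programs = {"GSC": {"vas": 10.0}, "SG": {"vas": 10.0}}
        with pytest.raises(ValidationError, match="disjoint"):
            SimulationConfig(n_genes=20, marker_programs=programs,
                             shared_programs=[], planted_effects=[])


class TestSimulateDdpcr:
    def test_zero_lambda_never_positive(self):
        wells = simulate_ddpcr({"t": 0.0}, 1000, n_replicates=20, seed=1)
        assert all(w.droplets_positive == 0 for w in wells)

    def test_huge_lambda_saturates(self):
        wells = simulate_ddpcr({"t": 50.0}, 1000, n_replicates=5, seed=1)
        assert all(w.droplets_positive == 1000 for w in wells)

    def test_ln2_lambda_gives_half_positive(self):
        """lambda = ln 2 means half the droplets are empty on average."""
        wells = simulate_ddpcr({"t": np.log(2)}, 20000, n_replicates=200, seed=2)
        fracs = np.array([w.droplets_positive / w.droplets_total for w in wells])
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert fracs.mean() == pytest.approx(0.5, abs=3 * se + 1e-9)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValidationError):
            simulate_ddpcr({"t": -0.1}, 1000)


class TestSimulateCross:
    @pytest.mark.parametrize("p,expect", [(0.0, 0), (1.0, 1000)])
    def test_deterministic_extremes(self, p, expect):
        c = simulate_cross(p, 1000, seed=0)
        assert c.n_wildtype == expect
        assert c.n_wildtype + c.n_bobbed == 1000

    def test_recovers_planted_frequency(self):
        """Mean scored frequency over 500 crosses matches the planted rate."""
        freqs = np.array([
            simulate_cross(0.345, 1000, seed=s).n_wildtype / 1000 for s in range(500)
        ])
        se = freqs.std(ddof=1) / np.sqrt(len(freqs))
        assert freqs.mean() == pytest.approx(0.345, abs=3 * se)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cross(0.5, 0)
        with pytest.raises(ValidationError):
            simulate_cross(1.5, 10)
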
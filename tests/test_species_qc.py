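import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from scstates.species_qc import (
    DoubletInputs,
    QcGates,
    apply_qc,
    call_species,
    consensus_doublets,
    density_gates,
)
from scstates.synthetic import generate_barnyard


class TestCallSpecies:
    def test_dominant_human_kept(self):
        h = np.concatenate([np.full(10, 10.0), np.linspace(3000, 4500, 10), [5000.0]])
        m = np.concatenate([np.full(10, 6000.0), np.full(10, 10.0), [10.0]])
        labels, thr = call_species(h, m)
        assert labels[-1] == "human"  # clears both thresholds and human > mouse

    def test_pure_mouse_excluded(self):
        h = np.array([0.0, 4000, 4000, 4000])
        m = np.array([800.0, 5, 5, 5])
        labels, _ = call_species(h, m)
        assert labels[0] == "excluded"

    def test_type7_quantile_threshold(self):
        # 10 human-major cells, human UMIs 100..1000 -> t_human = 190
        # (hand-computed linear-interpolation quantile); a probe cell with
        # human=150 sits below the threshold and is excluded
        h = np.concatenate([np.arange(100, 1001, 100.0), [1.0, 2.0]])
        m = np.concatenate([np.zeros(10), [2000.0, 3000.0]])
        labels, thr = call_species(h, m)
        assert thr.t_human == pytest.approx(190.0)

        h2 = np.concatenate([h, [150.0]])
        m2 = np.concatenate([m, [0.0]])
        labels2, thr2 = call_species(h2, m2)
        assert 150.0 <= thr2.t_human  # probe below threshold...
        assert labels2[-1] == "excluded"  # ...and therefore excluded

    def test_missing_side_warns(self):
        h = np.array([100.0, 200.0, 300.0])
        m = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="mouse threshold"):
            labels, thr = call_species(h, m)
        assert np.isinf(thr.t_mouse)
        assert (labels == np.array(["excluded", "human", "human"])).all()

    def test_recovers_barnyard_truth(self):
        # the 10th-percentile rule excludes ~10% of genuine human nuclei by
        # construction, so recovery is asserted as precision: cells kept as
        # human are overwhelmingly true human singlets
        adata, truth = generate_barnyard(300, 300, 0.0, seed=21)
        labels, _ = call_species(
            adata.obs["human_umi"].to_numpy(), adata.obs["mouse_umi"].to_numpy()
        )
        human_truth = (truth.cells["species"] == "human").to_numpy()
        called_human = labels == "human"
        assert human_truth[called_human].mean() >= 0.99
        assert called_human[human_truth].mean() >= 0.85  # 10% percentile loss

    def test_precision_with_doublets(self):
        adata, truth = generate_barnyard(300, 300, 0.05, seed=21)
        labels, _ = call_species(
            adata.obs["human_umi"].to_numpy(), adata.obs["mouse_umi"].to_numpy()
        )
        human_truth = (truth.cells["species"] == "human").to_numpy()
        called_human = labels == "human"
        assert human_truth[called_human].mean() >= 0.95


class TestDensityGates:
    def test_unimodal_pass_through(self, rng):
        v = rng.lognormal(8, 0.2, size=2000)
        low, high = density_gates(v)
        assert low == pytest.approx(v.min())
        assert high == pytest.approx(v.max())

    def test_bimodal_low_gate_between_modes(self, rng):
        # mixture 0.2 N(2.5, 0.15) + 0.8 N(4, 0.2) in log10 space
        n = 5000
        comp = rng.random(n) < 0.2
        logv = np.where(comp, rng.normal(2.5, 0.15, n), rng.normal(4.0, 0.2, n))
        v = 10 ** logv - 1
        low, high = density_gates(v)
        assert 10 ** 2.5 < low + 1 < 10 ** 4

    def test_duplication_near_invariant(self, rng):
        n = 2000
        comp = rng.random(n) < 0.3
        logv = np.where(comp, rng.normal(2.5, 0.15, n), rng.normal(4.0, 0.2, n))
        v = 10 ** logv - 1
        low1, _ = density_gates(v)
        low2, _ = density_gates(np.concatenate([v, v]))
        assert abs(np.log10(low1 + 1) - np.log10(low2 + 1)) < 0.15

    def test_constant_vector_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            low, high = density_gates(np.full(200, 500.0))
        assert low == high == 500.0

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            density_gates(np.arange(50.0))


class TestConsensusDoublets:
    def _inputs(self, n_expected, scores=None):
        barcodes = ["c1", "c2", "c3", "c4"]
        s = scores if scores is not None else [0.5, 0.9, 0.4, 0.8]
        return DoubletInputs(
            barcodes=barcodes,
            scores_primary=np.array(s),
            calls_primary=np.array([True, True, True, False]),
            calls_secondary=np.array([False, True, True, True]),
            n_expected=n_expected,
        )

    def test_small_intersection_all_removed(self):
        assert consensus_doublets(self._inputs(5)) == {"c2", "c3"}

    def test_capped_by_n_expected(self):
        assert consensus_doublets(self._inputs(1)) == {"c2"}

    def test_disjoint_calls(self):
        d = DoubletInputs(
            barcodes=["a", "b"],
            scores_primary=np.array([0.9, 0.9]),
            calls_primary=np.array([True, False]),
            calls_secondary=np.array([False, True]),
            n_expected=5,
        )
        assert consensus_doublets(d) == set()

    def test_tie_breaks_lexicographic(self):
        d = self._inputs(1, scores=[0.5, 0.7, 0.7, 0.8])
        assert consensus_doublets(d) == {"c2"}

    @given(
        n=st.integers(3, 30),
        n_expected=st.integers(0, 10),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_properties(self, n, n_expected, seed):
        r = np.random.default_rng(seed)
        d = DoubletInputs(
            barcodes=[f"b{i}" for i in range(n)],
            scores_primary=r.random(n),
            calls_primary=r.random(n) < 0.5,
            calls_secondary=r.random(n) < 0.5,
            n_expected=n_expected,
        )
        removed = consensus_doublets(d)
        inter = {f"b{i}" for i in range(n) if d.calls_primary[i] and d.calls_secondary[i]}
        assert removed <= inter
        if len(inter) > n_expected:
            assert len(removed) == n_expected
        else:
            assert removed == inter


def _toy_adata(umis, mito_fracs, n_genes=30):
    """Cells with target total UMI and mito fraction over a tiny universe."""
    rng = np.random.default_rng(0)
    genes = [f"MT-{i}" for i in range(3)] + [f"G{i}" for i in range(n_genes - 3)]
    x = np.zeros((len(umis), n_genes))
    for i, (total, mf) in enumerate(zip(umis, mito_fracs)):
        mito_total = int(round(total * mf))
        x[i, :3] = np.floor_divide(mito_total, 3)
        x[i, 0] += mito_total - 3 * (mito_total // 3)
        rest = total - mito_total
        x[i, 3:] = rest // (n_genes - 3)
        x[i, 3] += rest - (n_genes - 3) * (rest // (n_genes - 3))
    return ad.AnnData(
        X=sp.csr_matrix(x),
        obs=pd.DataFrame(index=[f"cell{i}" for i in range(len(umis))]),
        var=pd.DataFrame(index=genes),
    )


class TestApplyQc:
    def test_mito_strict_boundary(self):
        adata = _toy_adata([10000] * 10, [0.049] * 5 + [0.050] * 5)
        gates = QcGates(umi_low=0, umi_high=1e9)
        filtered, log = apply_qc(adata, gates, min_cells_per_gene=1)
        assert filtered.n_obs == 5
        assert log["pass_mito"].sum() == 5

    def test_gene_detection_boundary(self):
        x = np.zeros((10, 3))
        x[:, 0] = 5          # detected in 10 cells
        x[:4, 1] = 1         # 4 cells -> dropped
        x[:5, 2] = 1         # 5 cells -> kept
        adata = ad.AnnData(
            X=sp.csr_matrix(x),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(10)]),
            var=pd.DataFrame(index=["A", "B", "C"]),
        )
        gates = QcGates(umi_low=0, umi_high=100)
        filtered, _ = apply_qc(adata, gates)
        assert list(filtered.var_names) == ["A", "C"]

    def test_planted_outlier_removed(self):
        umis = [5000, 5200, 4800, 5100, 4900, 50000]
        adata = _toy_adata(umis, [0.01] * 6)
        gates = QcGates(umi_low=1000, umi_high=10000)
        filtered, _ = apply_qc(adata, gates, min_cells_per_gene=1)
        assert filtered.n_obs == 5

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        umis = rng.integers(2000, 8000, size=40)
        adata = _toy_adata(list(umis), list(rng.uniform(0, 0.08, size=40)))
        gates = QcGates(umi_low=2500, umi_high=7500)
        once, _ = apply_qc(adata, gates)
        twice, _ = apply_qc(once, gates)
        assert once.shape == twice.shape
        assert (once.X != twice.X).nnz == 0

    def test_all_fail_raises(self):
        adata = _toy_adata([5000] * 6, [0.5] * 6)
        with pytest.raises(ValueError, match="all cells fail"):
            apply_qc(adata, QcGates(umi_low=0, umi_high=1e9))

    def test_gate_validation(self):
        with pytest.raises(ValueError):
            QcGates(umi_low=10, umi_high=5)
        with pytest.raises(ValueError):
            QcGates(umi_low=0, umi_high=10, mito_max=0.0)
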
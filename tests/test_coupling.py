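"""MSA handling, KL conservation, mutual information, generalized correlation."""

import numpy as np
import pytest

from allokin.coupling import (
    Msa,
    column_mi,
    dynamic_rmi,
    edge_weight,
    filter_msa,
    gaussian_mi_1d,
    kl_conservation,
    read_msa,
    write_msa,
)
from allokin.synthetic import make_gaussian_ensemble, make_helix, make_synthetic_msa

UNIFORM = np.full(20, 0.05)


class TestMsaIO:
    def test_parse_two_records(self):
        msa = read_msa(">a\nACDE\n>b\nACDF\n")
        assert msa.n_sequences == 2
        assert msa.sequences == ["ACDE", "ACDF"]

    def test_roundtrip(self):
        msa = Msa(names=["x", "y"], sequences=["ACD-E", "AC-DE"])
        back = read_msa(write_msa(msa))
        assert back.sequences == msa.sequences
        assert back.names == msa.names

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged|length"):
            read_msa(">a\nACDE\n>b\nACD\n")

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            read_msa(">a\nACDE\n")


class TestFilterMsa:
    def test_low_coverage_removed_boundary_kept(self):
        ref = "A" * 10
        s40 = "A" * 4 + "-" * 6  # 40% coverage: removed
        s50 = "A" * 5 + "-" * 5  # exactly 50%: retained (< rule)
        msa = Msa(names=["ref", "s40", "s50"], sequences=[ref, s40, s50])
        out = filter_msa(msa)
        assert out.names == ["ref", "s50"]

    def test_gap_free_unchanged(self):
        msa = Msa(names=["a", "b", "c"], sequences=["ACDE", "ACDF", "ACDY"])
        assert filter_msa(msa).sequences == msa.sequences

    def test_reference_always_kept(self):
        msa = Msa(names=["ref", "b"], sequences=["A---", "AAAA"], reference=0)
        out = filter_msa(msa)
        assert "ref" in out.names


class TestKlConservation:
    def test_fully_conserved_ln20(self):
        msa = Msa(names=["a", "b", "c"], sequences=["AAA", "AAA", "AAA"])
        kl = kl_conservation(msa, background=UNIFORM)
        assert np.allclose(kl.scores, np.log(20), atol=1e-12)

    def test_matching_background_zero(self):
        from allokin.coupling import AMINO_ACIDS

        # column containing each amino acid exactly once: P = uniform = Q
        seqs = [a * 3 for a in AMINO_ACIDS]
        msa = Msa(names=[f"s{k}" for k in range(20)], sequences=seqs)
        kl = kl_conservation(msa, background=UNIFORM)
        assert np.allclose(kl.scores, 0.0, atol=1e-12)

    def test_planted_columns_rank_top(self):
        msa = make_synthetic_msa(500, 25, conserved_cols={4, 9, 14}, seed=2)
        kl = kl_conservation(msa, background=UNIFORM)
        assert set(np.argsort(kl.scores)[-3:]) == {4, 9, 14}

    def test_all_gap_column_warns(self):
        msa = Msa(names=["a", "b"], sequences=["A-", "A-"])
        with pytest.warns(UserWarning, match="all gaps"):
            kl = kl_conservation(msa, background=UNIFORM)
        assert kl.scores[1] == 0.0

    def test_permutation_invariance(self):
        msa1 = Msa(names=["a", "b", "c"], sequences=["AC", "AD", "AE"])
        msa2 = Msa(names=["c", "a", "b"], sequences=["AE", "AC", "AD"])
        a = kl_conservation(msa1, background=UNIFORM).scores
        b = kl_conservation(msa2, background=UNIFORM).scores
        assert np.allclose(a, b, atol=1e-15)


class TestColumnMi:
    def test_coupled_pair_ln2(self):
        msa = make_synthetic_msa(5000, 8, covarying_pairs=[(2, 5)], seed=1)
        mi = column_mi(msa).values
        assert abs(mi[2, 5] - np.log(2)) / np.log(2) < 0.05

    def test_symmetric(self):
        msa = make_synthetic_msa(100, 10, seed=0)
        v = column_mi(msa).values
        assert np.allclose(v, v.T, equal_nan=True)

    def test_sparse_pair_marked_missing(self):
        base = make_synthetic_msa(30, 4, seed=0)
        seqs = [s[:1] + ("-" if k > 4 else s[1]) + s[2:] for k, s in enumerate(base.sequences)]
        msa = Msa(names=base.names, sequences=seqs)
        v = column_mi(msa, min_pairs=10).values
        assert np.isnan(v[0, 1])

    def test_alphabet_relabeling_invariance(self):
        msa = make_synthetic_msa(300, 6, covarying_pairs=[(1, 4)], seed=5)
        trans = str.maketrans("ACDEFGHIKLMNPQRSTVWY", "YWVTSRQPNMLKIHGFEDCA")
        relabeled = Msa(
            names=msa.names, sequences=[s.translate(trans) for s in msa.sequences]
        )
        a = column_mi(msa, weighting=False).values
        b = column_mi(relabeled, weighting=False).values
        assert np.allclose(a, b, atol=1e-12, equal_nan=True)


class TestDynamicRmi:
    def test_self_correlation_one(self):
        h = make_helix(5)
        rng = np.random.default_rng(0)
        from allokin.structures import Ensemble

        ens = Ensemble(
            frames=h.coords[None] + rng.normal(0, 0.3, (200, 5, 3)),
            times=np.arange(200.0) + 1,
            residue_ids=list(h.residue_ids),
        )
        r = dynamic_rmi(ens, fit=False)
        assert np.allclose(np.diag(r.values), 1.0)

    def test_independent_noise_low_coupling(self):
        h = make_helix(5)
        rng = np.random.default_rng(1)
        from allokin.structures import Ensemble

        ens = Ensemble(
            frames=h.coords[None] + rng.normal(0, 0.3, (5000, 5, 3)),
            times=np.arange(5000.0) + 1,
            residue_ids=list(h.residue_ids),
        )
        r = dynamic_rmi(ens, fit=False).values
        off = r[np.triu_indices(5, 1)]
        assert np.nanmax(off) < 0.15

    def test_planted_covariance_closed_form(self):
        # residues 0,1 share a scalar mode on x plus isotropic noise:
        # x-correlation rho = 1/(1+sigma^2/s^2); remaining axes independent
        h = make_helix(6)
        v = np.zeros(18)
        v[0] = v[3] = 1 / np.sqrt(2)
        ens = make_gaussian_ensemble(h, [(v, 2.0)], 10_000, seed=5)
        ens.frames = ens.frames + np.random.default_rng(6).normal(0, 0.5, ens.frames.shape)
        r = dynamic_rmi(ens, fit=False).values
        rho = 1.0 / 1.25
        mi = -0.5 * np.log(1 - rho**2)
        expect = np.sqrt(1 - np.exp(-2 * mi / 3))
        assert abs(r[0, 1] - expect) < 0.03

    def test_too_few_frames(self):
        h = make_helix(4)
        from allokin.structures import Ensemble

        ens = Ensemble(
            frames=np.zeros((10, 4, 3)),
            times=np.arange(10.0) + 1,
            residue_ids=list(h.residue_ids),
        )
        with pytest.raises(ValueError):
            dynamic_rmi(ens)


class TestScalarGaussian:
    def test_1d_identity_exact(self):
        mi = gaussian_mi_1d(0.8)
        assert np.sqrt(1 - np.exp(-2 * mi)) == pytest.approx(0.8, abs=1e-15)

    def test_rmi_matches_pearson_1d(self, rng):
        # Gaussian pair: the MI-derived correlation equals |Pearson|
        z = rng.standard_normal((10_000, 2))
        x = z[:, 0]
        y = 0.8 * z[:, 0] + np.sqrt(1 - 0.64) * z[:, 1]
        rho = np.corrcoef(x, y)[0, 1]
        mi = -0.5 * np.log(1 - rho**2)
        assert np.sqrt(1 - np.exp(-2 * mi)) == pytest.approx(abs(rho), abs=1e-12)
        assert rho == pytest.approx(0.8, abs=0.01)


class TestEdgeWeight:
    @pytest.mark.parametrize(
        "r,expect",
        [(1.0, 0.0), (np.exp(-1), 1.0), (0.0, -np.log(1e-4))],
    )
    def test_values(self, r, expect):
        assert edge_weight(r) == pytest.approx(expect, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            edge_weight(1.2)
        with pytest.raises(ValueError):
            edge_weight(-0.1)
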
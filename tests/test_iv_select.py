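"""Instrument selection: thresholding, clumping, exclusion, strength metrics."""

import numpy as np
import pytest

from mrpath.errors import ConfigurationError, ValidationError
from mrpath.iv_select import (
    LDMatrix,
    assemble_instruments,
    clump,
    exclude_snps,
    filter_by_pvalue,
    instrument_strength,
)

from conftest import make_pair


class TestPvalueFilter:
    def test_strict_threshold(self):
        pairs = [make_pair("rs1", pval_exp=1e-6), make_pair("rs2", pval_exp=1e-4)]
        kept = filter_by_pvalue(pairs, 1e-5)
        assert [p.snp_id for p in kept] == ["rs1"]

    def test_threshold_one_is_vacuous(self):
        pairs = [make_pair("rs1", pval_exp=0.99), make_pair("rs2", pval_exp=1e-9)]
        assert filter_by_pvalue(pairs, 1.0) == pairs

    def test_empty_input(self):
        assert filter_by_pvalue([], 1e-5) == []

    @pytest.mark.parametrize("bad", [0.0, -1e-5, 1.5])
    def test_invalid_threshold_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            filter_by_pvalue([], bad)


def _ld(snp_ids, r2):
    return LDMatrix(snp_ids, np.asarray(r2, dtype=float))


class TestLDMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            _ld(["rs1", "rs2"], [[1, 0.5], [0.4, 1]])  # asymmetric
        with pytest.raises(ValidationError):
            _ld(["rs1", "rs2"], [[0.9, 0.5], [0.5, 1]])  # diagonal
        with pytest.raises(ValidationError):
            _ld(["rs1", "rs2"], [[1, 1.5], [1.5, 1]])  # out of range

    def test_missing_snp_lookup_is_none(self):
        ld = _ld(["rs1"], [[1.0]])
        assert ld.lookup("rs1", "rs99") is None

    def test_tsv_round_trip(self, tmp_path):
        ld = _ld(["rs1", "rs2"], [[1, 0.8], [0.8, 1]])
        path = tmp_path / "ld.tsv"
        ld.to_tsv(path)
        back = LDMatrix.from_tsv(path)
        assert back.snp_ids == ld.snp_ids
        np.testing.assert_allclose(back.r2, ld.r2)


class TestClump:
    def test_linked_neighbour_eliminated(self):
        pairs = [
            make_pair("rs1", pos=1_000_000, pval_exp=1e-8),
            make_pair("rs2", pos=1_500_000, pval_exp=1e-6),
        ]
        ld = _ld(["rs1", "rs2"], [[1, 0.5], [0.5, 1]])
        assert [p.snp_id for p in clump(pairs, ld)] == ["rs1"]

    def test_window_never_spans_chromosomes(self):
        pairs = [
            make_pair("rs1", chrom="1", pos=100, pval_exp=1e-8),
            make_pair("rs2", chrom="2", pos=100, pval_exp=1e-6),
        ]
        ld = _ld(["rs1", "rs2"], [[1, 0.9], [0.9, 1]])
        assert len(clump(pairs, ld)) == 2

    def test_boundary_r2_eliminates(self):
        pairs = [
            make_pair("rs1", pos=1_000_000, pval_exp=1e-8),
            make_pair("rs2", pos=1_000_100, pval_exp=1e-6),
        ]
        ld = _ld(["rs1", "rs2"], [[1, 0.001], [0.001, 1]])
        assert len(clump(pairs, ld)) == 1

    def test_missing_ld_entries_retain_both_with_warning(self):
        pairs = [
            make_pair("rs1", pos=1_000_000, pval_exp=1e-8),
            make_pair("rs2", pos=1_000_100, pval_exp=1e-6),
        ]
        ld = _ld(["rs1"], [[1.0]])
        with pytest.warns(UserWarning, match="missing"):
            assert len(clump(pairs, ld)) == 2

    def test_retained_snp_beats_every_snp_it_eliminated(self, rng):
        pairs, ld = _random_instance(rng, n=10)
        kept = {p.snp_id for p in clump(pairs, ld)}
        by_id = {p.snp_id: p for p in pairs}
        for gone_id in set(by_id) - kept:
            gone = by_id[gone_id]
            conflicts = [
                k for k in kept
                if by_id[k].chrom == gone.chrom
                and abs(by_id[k].pos - gone.pos) <= 1_000_000
                and (ld.lookup(k, gone_id) or 0) >= 0.001
            ]
            assert conflicts, f"{gone_id} eliminated with no retained conflict"
            assert min(by_id[k].pval_exp for k in conflicts) <= gone.pval_exp

    def test_input_order_invariance(self, rng):
        pairs, ld = _random_instance(rng, n=10)
        kept = {p.snp_id for p in clump(pairs, ld)}
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        assert {p.snp_id for p in clump(shuffled, ld)} == kept

    def test_matches_bruteforce_oracle_on_ld_blocks(self, rng):
        """Greedy clumping equals an independent step-by-step enumeration."""
        pairs, ld = _random_instance(rng, n=10, n_blocks=3)
        expected = _bruteforce_clump(pairs, ld)
        assert {p.snp_id for p in clump(pairs, ld)} == expected


def _random_instance(rng, n=10, n_blocks=None):
    """Random clumping instance; block-structured LD when n_blocks given."""
    ids = [f"rs{i}" for i in range(n)]
    if n_blocks:
        block = rng.integers(0, n_blocks, size=n)
        r2 = np.where(block[:, None] == block[None, :], 0.8, 0.0)
        pos = 1_000_000 + block * 200_000 + rng.integers(0, 50_000, size=n)
    else:
        raw = rng.uniform(0, 1, size=(n, n))
        r2 = (raw + raw.T) / 2
        pos = rng.integers(1, 3_000_000, size=n)
    np.fill_diagonal(r2, 1.0)
    pairs = [
        make_pair(ids[i], chrom="1", pos=int(pos[i]), pval_exp=float(rng.uniform(1e-10, 1e-5)))
        for i in range(n)
    ]
    return pairs, LDMatrix(ids, r2)


def _bruteforce_clump(pairs, ld, window_bp=1_000_000, r2_threshold=0.001):
    """Independent oracle: explicit candidate-set recursion, no shared code."""
    todo = {p.snp_id: p for p in pairs}
    kept = set()
    while todo:
        index_id = min(todo, key=lambda s: (todo[s].pval_exp, s))
        index = todo.pop(index_id)
        kept.add(index_id)
        for other_id in list(todo):
            other = todo[other_id]
            same_chrom = other.chrom == index.chrom
            near = abs(other.pos - index.pos) <= window_bp
            linked = (ld.lookup(index_id, other_id) or 0.0) >= r2_threshold
            if same_chrom and near and linked:
                del todo[other_id]
    return kept


class TestExclusion:
    def test_empty_list_is_identity(self):
        pairs = [make_pair("rs1"), make_pair("rs2")]
        kept, log = exclude_snps(pairs, {})
        assert kept == pairs and log == {}

    def test_absent_id_logged_not_found(self):
        pairs = [make_pair("rs1")]
        kept, log = exclude_snps(pairs, {"rs99": "af_associated"})
        assert kept == pairs
        assert log == {"not_found": 1}

    def test_listed_snps_removed_with_reason_counts(self):
        pairs = [make_pair(f"rs{i}") for i in range(1, 6)]
        kept, log = exclude_snps(
            pairs, {"rs1": "confounder", "rs3": "confounder"}
        )
        assert len(kept) == 3
        assert log == {"confounder": 2}


class TestInstrumentStrength:
    def test_r2_formula(self):
        r2, _ = instrument_strength(make_pair(beta_exp=0.1, eaf_exp=0.3))
        assert r2 == pytest.approx(2 * 0.3 * 0.7 * 0.01)

    def test_f_formula(self):
        _, f = instrument_strength(make_pair(beta_exp=0.1, se_exp=0.02))
        assert f == pytest.approx(25.0)

    def test_maf_folding_symmetry(self):
        r2_low, _ = instrument_strength(make_pair(eaf_exp=0.3))
        r2_high, _ = instrument_strength(make_pair(eaf_exp=0.7))
        assert r2_low == pytest.approx(r2_high)

    def test_f_invariant_under_beta_sign(self):
        _, f_pos = instrument_strength(make_pair(beta_exp=0.1))
        _, f_neg = instrument_strength(make_pair(beta_exp=-0.1))
        assert f_pos == f_neg

    def test_missing_eaf_gives_none_r2_but_f(self):
        r2, f = instrument_strength(make_pair(eaf_exp=None))
        assert r2 is None and f > 0


def test_assemble_instruments_stage_counts():
    pairs = [
        make_pair("rs1", pos=1_000_000, pval_exp=1e-8),
        make_pair("rs2", pos=1_000_100, pval_exp=1e-6),
        make_pair("rs3", pos=5_000_000, pval_exp=1e-7),
        make_pair("rs4", pos=9_000_000, pval_exp=1e-3),
    ]
    r2 = np.eye(4)
    r2[0, 1] = r2[1, 0] = 0.9
    ld = _ld(["rs1", "rs2", "rs3", "rs4"], r2)
    instruments, log = assemble_instruments(
        pairs, ld=ld, exclusion_list={"rs3": "confounder"}
    )
    assert log["n_after_pvalue"] == 3
    assert log["n_after_clump"] == 2  # rs2 clumped away by rs1
    assert log["n_final"] == 1
    assert [p.snp_id for p in instruments.pairs] == ["rs1"]
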
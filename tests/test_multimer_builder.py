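import numpy as np
import pytest

from regseq.motif_model import (
    MotifRecord,
    PositionMatrix,
    information_content,
    reverse_complement,
)
from regseq.multimer_builder import (
    AlignmentResult,
    ChainingError,
    DimerAnnotation,
    align_pfms,
    enumerate_chains,
    extend_multimer,
    merge_dimers,
    write_chain_table,
)

from .conftest import make_record, one_hot_matrix, random_matrix


# -- independent brute-force oracle ----------------------------------------

def oracle_align(a, b, min_overlap):
    """Exhaustive re-implementation using np.corrcoef directly."""

    def col_pcc(x, y):
        if x.std() < 1e-12 and y.std() < 1e-12:
            return 1.0
        if x.std() < 1e-12 or y.std() < 1e-12:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    best = None
    for orientation, mat in (("forward", b), ("reverse-complement", reverse_complement(b))):
        for offset in range(-(b.length - min_overlap), a.length - min_overlap + 1):
            lo, hi = max(0, offset), min(a.length, offset + mat.length)
            if hi - lo < min_overlap:
                continue
            score = sum(col_pcc(a.probs[i], mat.probs[i - offset]) for i in range(lo, hi))
            key = (score, hi - lo, orientation == "forward", -offset)
            if best is None or key > best[0]:
                best = (key, AlignmentResult(offset, orientation, hi - lo, score))
    return best[1]


def dimer(name_a, name_b, mat, spans, pal=(True, True)):
    rec = MotifRecord(id=f"{name_a}-{name_b}", tf_members=(name_a, name_b), matrix=mat)
    return DimerAnnotation(motif=rec, half_spans=spans, palindromic_halves=pal,
                           member_order=(name_a, name_b))


def synthetic_dimer(rng, name_a, name_b, half_len=6, pal=(True, True)):
    """A + gap + B where B's columns are self-palindromic one-hots."""
    left = random_matrix(rng, half_len)
    pal_half = one_hot_matrix("CACGTG")
    cols = np.vstack([left.probs, pal_half.probs])
    return dimer(name_a, name_b, PositionMatrix(cols),
                 ((0, half_len), (half_len, half_len + 6)), pal)


class TestAlign:
    def test_self_alignment(self, rng):
        a = random_matrix(rng, 8)
        res = align_pfms(a, a, min_overlap=4)
        assert res.offset == 0
        assert res.orientation == "forward"
        assert res.overlap_length == 8
        assert res.score == pytest.approx(8.0, abs=1e-6)

    def test_reverse_complement_alignment(self, rng):
        a = random_matrix(rng, 8)  # non-palindromic w.h.p.
        res = align_pfms(a, reverse_complement(a), min_overlap=4)
        assert res.orientation == "reverse-complement"
        assert res.offset == 0
        assert res.score == pytest.approx(8.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_matrix(rng, 10)
        b = random_matrix(rng, 10)
        got = align_pfms(a, b, min_overlap=3)
        want = oracle_align(a, b, min_overlap=3)
        assert got.score == pytest.approx(want.score, abs=1e-9)
        assert (got.offset, got.orientation, got.overlap_length) == (
            want.offset,
            want.orientation,
            want.overlap_length,
        )

    def test_min_overlap_too_large(self, rng):
        with pytest.raises(ValueError, match="min_overlap"):
            align_pfms(random_matrix(rng, 5), random_matrix(rng, 8), min_overlap=6)


class TestMerge:
    def test_overlap_columns_are_averaged(self, rng):
        # two dimers with identical palindromic right half -> align there;
        # check a disagreeing overlap column averages per base
        d1 = synthetic_dimer(rng, "A", "B")
        d2 = synthetic_dimer(rng, "C", "B")
        rec = merge_dimers(d1, d2, min_overlap=4)
        assert rec.arity == 3
        assert rec.tf_members == ("A", "B", "C")
        assert rec.matrix.length <= d1.motif.matrix.length + d2.motif.matrix.length - 4
        # every column remains a distribution
        assert np.allclose(rec.matrix.probs.sum(axis=1), 1.0)

    def test_forced_averaging_rule(self):
        # identical matrices except one overlap column: (1,0,0,0) vs (0,0,0,1)
        base = one_hot_matrix("CACGTGAC")
        other = base.probs.copy()
        other[6] = [0, 0, 0, 1]  # A -> T at column 6
        d1 = dimer("A", "B", base, ((0, 4), (4, 8)))
        d2 = dimer("C", "B", PositionMatrix(other), ((0, 4), (4, 8)))
        rec = merge_dimers(d1, d2, min_overlap=4)
        aligned = align_pfms(base, PositionMatrix(other), 4)
        assert aligned.offset == 0 and aligned.orientation == "forward"
        assert np.allclose(rec.matrix.probs[6], [0.5, 0, 0, 0.5])

    def test_identical_matrix_merge_is_identity(self):
        mat = one_hot_matrix("CACGTGTG")
        d1 = dimer("A", "B", mat, ((0, 4), (4, 8)))
        d2 = dimer("C", "B", mat, ((0, 4), (4, 8)))
        rec = merge_dimers(d1, d2, min_overlap=4)
        assert rec.matrix.isclose(mat)

    def test_shared_member_mismatch(self, rng):
        d1 = synthetic_dimer(rng, "A", "B")
        d2 = synthetic_dimer(rng, "C", "D")
        with pytest.raises(ChainingError):
            merge_dimers(d1, d2)

    def test_non_palindromic_shared_member_refused(self, rng):
        d1 = synthetic_dimer(rng, "A", "B", pal=(False, False))
        d2 = synthetic_dimer(rng, "C", "B", pal=(False, False))
        with pytest.raises(ChainingError, match="palindromic"):
            merge_dimers(d1, d2)

    def test_merge_symmetric_up_to_rc(self, rng):
        d1 = synthetic_dimer(rng, "A", "B")
        d2 = synthetic_dimer(rng, "C", "B")
        m12 = merge_dimers(d1, d2).matrix
        m21 = merge_dimers(d2, d1).matrix
        assert m12.isclose(m21) or m12.isclose(reverse_complement(m21))

    def test_merged_ic_bounded_by_component_sum(self, rng):
        d1 = synthetic_dimer(rng, "A", "B")
        d2 = synthetic_dimer(rng, "C", "B")
        rec = merge_dimers(d1, d2)
        assert information_content(rec.matrix) <= (
            information_content(d1.motif.matrix) + information_content(d2.motif.matrix) + 1e-9
        )


class TestExtend:
    def _three(self, rng):
        return merge_dimers(synthetic_dimer(rng, "A", "B"), synthetic_dimer(rng, "C", "B"))

    def test_extend_to_arity_four(self, rng):
        three = self._three(rng)
        # dimer C-D with palindromic C half so chaining through C is legal
        left = one_hot_matrix("CACGTG")
        right = random_matrix(rng, 6)
        cd = dimer("C", "D", PositionMatrix(np.vstack([left.probs, right.probs])),
                   ((0, 6), (6, 12)), pal=(True, False))
        four = extend_multimer(three, cd)
        assert four.arity == 4
        assert four.tf_members in (("A", "B", "C", "D"), ("D", "A", "B", "C"))

    def test_extend_without_terminal_member(self, rng):
        three = self._three(rng)
        xy = synthetic_dimer(rng, "X", "Y")
        with pytest.raises(ChainingError):
            extend_multimer(three, xy)

    def test_iterated_extension_keeps_normalization(self, dimers):
        chains = enumerate_chains(dimers, max_arity=6, limit=5, seed=0)
        assert chains, "fixture catalog should yield chains"
        for rec in chains:
            assert np.allclose(rec.matrix.probs.sum(axis=1), 1.0, atol=1e-9)
            assert rec.matrix.length < 100  # even the longest stay under 100 bp


class TestEnumerate:
    def test_two_dimer_catalog_single_chain(self, rng):
        cat = [synthetic_dimer(rng, "A", "B"), synthetic_dimer(rng, "C", "B")]
        chains = enumerate_chains(cat, max_arity=3)
        assert len(chains) == 1  # A-B-C and C-B-A collapse up to reversal
        assert set(chains[0].tf_members) == {"A", "B", "C"}

    def test_no_palindromic_members_no_chains(self, rng):
        cat = [
            synthetic_dimer(rng, "A", "B", pal=(False, False)),
            synthetic_dimer(rng, "C", "B", pal=(False, False)),
        ]
        assert enumerate_chains(cat, max_arity=3) == []

    def test_outputs_satisfy_preconditions(self, dimers):
        known = {d.motif.tf_members[i] for d in dimers for i in (0, 1)}
        chains = enumerate_chains(dimers, max_arity=3, limit=50, seed=1)
        assert chains
        for rec in chains:
            assert rec.arity == 3
            assert set(rec.tf_members) <= known
            assert len(set(rec.tf_members)) == 3

    def test_limit_is_deterministic(self, dimers):
        a = enumerate_chains(dimers, max_arity=3, limit=3, seed=42)
        b = enumerate_chains(dimers, max_arity=3, limit=3, seed=42)
        assert [r.id for r in a] == [r.id for r in b]

    def test_empty_catalog(self):
        assert enumerate_chains([], max_arity=3) == []


def test_chain_provenance_sidecar(dimers, tmp_path):
    chains = enumerate_chains(dimers, max_arity=3, limit=4, seed=0)
    path = tmp_path / "chains.tsv"
    write_chain_table(chains, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["chain_id", "arity", "members", "source_dimers"]
    assert len(lines) == len(chains) + 1
    assert all(len(l.split("\t")) == 4 for l in lines[1:])
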
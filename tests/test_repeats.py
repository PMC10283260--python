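import numpy as np
import pytest

from fusionscreen._errors import ValidationError
from fusionscreen.io_formats import SequenceRecord
from fusionscreen.repeats import (
    MASK_SYMBOL,
    ScoringScheme,
    check_triad,
    count_domain_copies,
    local_align,
    screen_by_length,
)

from oracles import naive_local_score

SCHEME = ScoringScheme.blosum62()
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _rand_protein(rng, n):
    return "".join(rng.choice(list(AA20), size=n))


def _mutate_protein(rng, seq, rate, keep=()):
    chars = list(seq)
    for i in range(len(chars)):
        if i in keep:
            continue
        if rng.random() < rate:
            chars[i] = rng.choice([a for a in AA20 if a != chars[i]])
    return "".join(chars)


class TestScreenByLength:
    def test_strict_boundary(self):
        p500 = SequenceRecord("p500", "A" * 500, alphabet="protein")
        p501 = SequenceRecord("p501", "A" * 501, alphabet="protein")
        assert screen_by_length([p500, p501]) == [p501]

    def test_empty_input(self):
        assert screen_by_length([]) == []

    def test_hand_enumerated_fixture(self):
        lengths = [120, 500, 501, 499, 1200, 777]
        prots = [
            SequenceRecord(f"p{n}", "M" * n, alphabet="protein") for n in lengths
        ]
        survivors = screen_by_length(prots)
        assert [len(p) for p in survivors] == [501, 1200, 777]


class TestLocalAlign:
    def test_identity_alignment_self_score(self):
        rng = np.random.default_rng(0)
        seq = _rand_protein(rng, 40)
        rec = SequenceRecord("p", seq, alphabet="protein")
        hit = local_align(rec, rec, SCHEME)
        assert hit.score == SCHEME.self_score(rec)
        assert (hit.subject_start, hit.subject_end) == (0, 40)
        assert (hit.query_start, hit.query_end) == (0, 40)

    def test_nothing_alignable_gives_empty_hit(self):
        q = SequenceRecord("q", "AAAAAAA", alphabet="protein")
        s = SequenceRecord("s", "WWWWWWW", alphabet="protein")
        hit = local_align(q, s, SCHEME)
        assert hit.score == 0.0
        assert hit.empty

    def test_unknown_symbol_rejected(self):
        q = SequenceRecord("q", "AC1T", alphabet="protein")
        s = SequenceRecord("s", "ACDE", alphabet="protein")
        with pytest.raises(ValidationError):
            local_align(q, s, SCHEME)

    def test_matches_naive_dp_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(15):
            q = _rand_protein(rng, int(rng.integers(10, 60)))
            s = _rand_protein(rng, int(rng.integers(10, 60)))
            hit = local_align(
                SequenceRecord("q", q, alphabet="protein"),
                SequenceRecord("s", s, alphabet="protein"),
                SCHEME,
            )
            expected = naive_local_score(
                q, s, SCHEME.substitution, SCHEME.gap_open, SCHEME.gap_extend
            )
            assert hit.score == pytest.approx(expected)

    def test_gapped_alignment_scores_like_oracle(self):
        q = "MKVLITGAAGFIGS"
        s = "MKVLITGAA" + "QQQQQ" + "GFIGS"  # forces a 5-residue gap
        hit = local_align(
            SequenceRecord("q", q, alphabet="protein"),
            SequenceRecord("s", s, alphabet="protein"),
            SCHEME,
        )
        expected = naive_local_score(
            q, s, SCHEME.substitution, SCHEME.gap_open, SCHEME.gap_extend
        )
        assert hit.score == pytest.approx(expected)


class TestCountDomainCopies:
    def _domain(self, rng, n=80):
        return SequenceRecord("dom", _rand_protein(rng, n), alphabet="protein")

    def test_exact_copy_counts_one(self):
        rng = np.random.default_rng(1)
        dom = self._domain(rng)
        scan = count_domain_copies(dom, SequenceRecord("p", dom.residues, alphabet="protein"), SCHEME)
        assert scan.copy_count == 1

    @pytest.mark.parametrize("k", [1, 2, 3])
    @pytest.mark.parametrize("divergence", [0.0, 0.10])
    def test_concatenated_copies(self, k, divergence):
        rng = np.random.default_rng(10 * k + int(divergence * 100))
        dom = self._domain(rng)
        linker = "GGSSGGSSGG"
        parts = [
            _mutate_protein(rng, dom.residues, divergence) for _ in range(k)
        ]
        protein = SequenceRecord("p", linker.join(parts), alphabet="protein")
        scan = count_domain_copies(dom, protein, SCHEME)
        assert scan.copy_count == k

    def test_unrelated_protein_counts_zero(self):
        rng = np.random.default_rng(2)
        dom = self._domain(rng)
        other = SequenceRecord("p", _rand_protein(rng, len(dom)), alphabet="protein")
        scan = count_domain_copies(dom, other, SCHEME)
        assert scan.copy_count == 0
        # verify via the oracle that the best score is genuinely sub-threshold
        best = naive_local_score(
            dom.residues, other.residues,
            SCHEME.substitution, SCHEME.gap_open, SCHEME.gap_extend,
        )
        assert best < 0.3 * SCHEME.self_score(dom)

    def test_hits_never_overlap(self):
        rng = np.random.default_rng(3)
        dom = self._domain(rng)
        protein = SequenceRecord("p", dom.residues * 3, alphabet="protein")
        scan = count_domain_copies(dom, protein, SCHEME)
        spans = sorted((s, e) for s, e, _ in scan.hits)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_copy_order_invariance(self):
        rng = np.random.default_rng(4)
        dom = self._domain(rng)
        a = _mutate_protein(rng, dom.residues, 0.05)
        b = _mutate_protein(rng, dom.residues, 0.05)
        fwd = count_domain_copies(dom, SequenceRecord("p", a + b, alphabet="protein"), SCHEME)
        rev = count_domain_copies(dom, SequenceRecord("p", b + a, alphabet="protein"), SCHEME)
        assert fwd.copy_count == rev.copy_count == 2

    def test_simulator_decoy_triplication(self, sim_truth, sim_config):
        scan = count_domain_copies(sim_truth.domain_ref, sim_truth.proteins[-1])
        assert scan.copy_count == sim_config.n_copies


class TestCheckTriad:
    def _reference(self, rng, n=60):
        seq = list(_rand_protein(rng, n))
        seq[10], seq[25], seq[40] = "C", "H", "N"
        return SequenceRecord("ref", "".join(seq), alphabet="protein"), (10, 25, 40)

    def test_self_is_conserved(self):
        rng = np.random.default_rng(5)
        ref, pos = self._reference(rng)
        result = check_triad(ref, pos, ref, SCHEME)
        assert result.conserved
        assert result.positions_in_subject == pos
        assert result.residues == ("C", "H", "N")

    def test_mutated_cysteine_not_conserved(self):
        rng = np.random.default_rng(6)
        ref, pos = self._reference(rng)
        subject = SequenceRecord(
            "sub", ref.residues[:10] + "S" + ref.residues[11:], alphabet="protein"
        )
        result = check_triad(ref, pos, subject, SCHEME)
        assert not result.conserved
        assert result.residues == ("S", "H", "N")

    def test_insertion_shifts_positions(self):
        rng = np.random.default_rng(7)
        ref, pos = self._reference(rng)
        subject = SequenceRecord(
            "sub", ref.residues[:5] + "GGSSG" + ref.residues[5:], alphabet="protein"
        )
        result = check_triad(ref, pos, subject, SCHEME)
        assert result.conserved
        assert result.positions_in_subject == (15, 30, 45)

    def test_bad_reference_triad_rejected(self):
        rng = np.random.default_rng(8)
        ref, _ = self._reference(rng)
        with pytest.raises(ValidationError):
            check_triad(ref, (0, 1, 2), ref, SCHEME)

    def test_simulator_paralogs_conserve_triad(self, sim_truth):
        for prot in sim_truth.proteins[:-1]:
            result = check_triad(
                sim_truth.domain_ref, sim_truth.triad_positions, prot
            )
            assert result.conserved


class TestScoringScheme:
    def test_mask_symbol_is_dead(self):
        m = SCHEME.substitution
        assert m[MASK_SYMBOL, MASK_SYMBOL] <= -10_000
        assert m["A", MASK_SYMBOL] <= -10_000

    def test_gap_order_enforced(self):
        with pytest.raises(ValidationError):
            ScoringScheme.blosum62(gap_open=-1, gap_extend=-11)
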
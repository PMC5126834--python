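"""Viterbi engines, Gumbel calibration, E-values and search drivers."""

import dataclasses
import math
from itertools import product

import numpy as np
import pytest

from bruteforce import brute_force_glocal, brute_force_local_multihit
from conftest import random_profile
from xcal.engine import (
    MULTIHIT_RESTART_BITS,
    EVDParams,
    calibrate_evd,
    evalue,
    fit_gumbel,
    hits_to_frame,
    read_domtblout_table,
    read_hit_table,
    scan_sequence,
    search_model_vs_seqdb,
    viterbi_glocal,
    viterbi_local_multihit,
    write_hit_table,
)
from xcal.library import ProfileHMM, uniform_background


def _single_position_model(mode: str, q: float = 0.5, residue: str = "C") -> ProfileHMM:
    """L=1 model with deterministic entry and emission mass q on one residue."""
    em = np.full((1, 20), (1 - q) / 19)
    em[0, "ACDEFGHIKLMNPQRSTVWY".index(residue)] = q
    one = np.ones(1)
    return ProfileHMM(
        model_id="m1",
        mode=mode,
        match_emissions=em,
        insert_emissions=np.tile(uniform_background(), (1, 1)),
        t_mm=one, t_mi=one, t_md=one, t_im=one, t_ii=one, t_dm=one, t_dd=one,
        begin_to_match=1.0,
        begin_to_delete=0.0,
    )


class TestGlocalViterbi:
    def test_single_position_closed_form(self):
        hmm = _single_position_model("glocal", q=0.5)
        aln = viterbi_glocal(hmm, "C")
        assert aln.bit_score == pytest.approx(math.log2(20 * 0.5))
        assert aln.model_span == (1, 1)
        assert aln.seq_span == (1, 1)

    def test_length_two_model_one_residue_enumerates_delete_paths(self):
        rng = np.random.default_rng(7)
        hmm = random_profile(2, "glocal", rng)
        seq = "C"
        x = 1  # index of 'C'
        lg = math.log2
        em = lambda k: lg(hmm.match_emissions[k][x] / 0.05)
        # only two legal paths: M1->D2 and D1->M2
        path_md = lg(hmm.begin_to_match) + em(0) + lg(hmm.t_md[0])
        path_dm = lg(hmm.begin_to_delete) + lg(hmm.t_dm[0]) + em(1)
        # plus the all-delete path ignoring the residue entirely
        path_dd = lg(hmm.begin_to_delete) + lg(hmm.t_dd[0])
        expected = max(path_md, path_dm, path_dd)
        assert viterbi_glocal(hmm, seq).bit_score == pytest.approx(expected, abs=1e-9)

    def test_empty_sequence_takes_all_delete_path(self):
        rng = np.random.default_rng(3)
        hmm = random_profile(3, "glocal", rng)
        aln = viterbi_glocal(hmm, "")
        expected = math.log2(hmm.begin_to_delete) + sum(
            math.log2(hmm.t_dd[k]) for k in range(2)
        )
        assert aln.bit_score == pytest.approx(expected, abs=1e-9)
        assert all(state == "D" for state, _, _ in aln.state_path)

    def test_full_model_span_contract_and_score_decomposition(self, small_library):
        for model in small_library.models[:3]:
            aln = viterbi_glocal(model.glocal_build, model.consensus)
            assert aln.model_span == (1, model.length)
            assert aln.per_position_scores.sum() == pytest.approx(aln.bit_score, abs=1e-6)


class TestBruteForceEquivalence:
    """Both engines equal exhaustive max-over-paths on all tiny instances."""

    ALPHABET = "ACDE"

    @pytest.mark.parametrize("L,model_seed", [(1, 0), (1, 1), (2, 0), (2, 1), (3, 0), (3, 1)])
    def test_glocal_matches_enumeration(self, L, model_seed):
        hmm = random_profile(L, "glocal", np.random.default_rng(100 + model_seed))
        for n in range(5):
            for letters in product(self.ALPHABET, repeat=n):
                seq = "".join(letters)
                expected = brute_force_glocal(hmm, seq)
                got = viterbi_glocal(hmm, seq).bit_score
                assert got == pytest.approx(expected, abs=1e-6), seq

    @pytest.mark.parametrize("L,model_seed", [(1, 0), (2, 0), (2, 1), (3, 0), (3, 1)])
    def test_local_multihit_matches_enumeration(self, L, model_seed):
        hmm = random_profile(L, "local", np.random.default_rng(200 + model_seed))
        for n in range(1, 5):
            for letters in product(self.ALPHABET, repeat=n):
                seq = "".join(letters)
                expected = brute_force_local_multihit(hmm, seq, MULTIHIT_RESTART_BITS)
                doms = viterbi_local_multihit(hmm, seq)
                got = sum(d.bit_score for d in doms) - (len(doms) - 1) * MULTIHIT_RESTART_BITS
                assert got == pytest.approx(expected, abs=1e-6), seq


class TestLocalMultihit:
    def test_single_position_differs_from_glocal_only_by_entry_exit(self):
        g = _single_position_model("glocal")
        l = _single_position_model("local")
        ag = viterbi_glocal(g, "C")
        doms = viterbi_local_multihit(l, "C")
        assert len(doms) == 1
        # L=1: local entry log2(1/1)=0 and free exit, so scores coincide
        assert doms[0].bit_score == pytest.approx(ag.bit_score)

    def test_two_implants_give_two_domains(self, small_library):
        model = small_library.models[0]
        seq = model.consensus + "ACDEFGHIKL" + model.consensus
        doms = viterbi_local_multihit(model.local_build, seq)
        assert len(doms) == 2
        assert doms[0].seq_span[1] < doms[1].seq_span[0]  # ordered, non-overlapping
        for d in doms:
            assert 1 <= d.model_span[0] <= d.model_span[1] <= model.length

    def test_empty_sequence_yields_no_domains(self, small_library):
        assert viterbi_local_multihit(small_library.models[0].local_build, "") == []

    def test_determinism(self, small_library):
        model = small_library.models[1]
        seq = model.consensus[: model.length // 2] + "AAAA" + model.consensus
        a = viterbi_local_multihit(model.local_build, seq)
        b = viterbi_local_multihit(model.local_build, seq)
        assert [dataclasses.asdict(x) | {"per_position_scores": x.per_position_scores.tolist()}
                for x in a] == [
            dataclasses.asdict(x) | {"per_position_scores": x.per_position_scores.tolist()}
            for x in b
        ]


class TestGumbel:
    def test_parameter_recovery_from_direct_draws(self):
        from scipy import stats

        true_lam = 0.693
        draws = stats.gumbel_r.rvs(
            loc=0.0, scale=1.0 / true_lam, size=5000,
            random_state=np.random.default_rng(42),
        )
        mu, lam = fit_gumbel(draws)
        assert abs(lam - true_lam) / true_lam < 0.10
        assert abs(mu) < 0.2

    def test_location_equivariance(self):
        rng = np.random.default_rng(1)
        scores = rng.gumbel(loc=3.0, scale=2.0, size=500)
        mu1, lam1 = fit_gumbel(scores)
        mu2, lam2 = fit_gumbel(scores + 4.25)
        assert mu2 - mu1 == pytest.approx(4.25, abs=1e-6)
        assert lam2 == pytest.approx(lam1, abs=1e-6)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_gumbel(np.full(100, 3.0))

    def test_calibrate_evd_deterministic_and_seed_sensitive(self, small_library):
        hmm = small_library.models[0].glocal_build
        a = calibrate_evd(hmm, n_samples=60, rng_seed=5)
        b = calibrate_evd(hmm, n_samples=60, rng_seed=5)
        c = calibrate_evd(hmm, n_samples=60, rng_seed=6)
        assert (a.mu, a.lam) == (b.mu, b.lam)
        assert (a.mu, a.lam) != (c.mu, c.lam)

    def test_calibrate_evd_rejects_tiny_samples(self, small_library):
        with pytest.raises(ValueError):
            calibrate_evd(small_library.models[0].glocal_build, n_samples=10)


class TestEvalue:
    EVD = EVDParams(mu=10.0, lam=0.7, n_samples=100)

    def test_closed_form_at_mu(self):
        assert evalue(10.0, self.EVD, 16295) == pytest.approx(16295 * (1 - math.exp(-1)))

    def test_monotone_decreasing_in_score(self):
        es = [evalue(s, self.EVD, 100) for s in np.linspace(-20, 80, 50)]
        assert all(a >= b for a, b in zip(es, es[1:]))

    def test_linear_in_database_size(self):
        assert evalue(15.0, self.EVD, 200) == pytest.approx(2 * evalue(15.0, self.EVD, 100))

    def test_vanishes_for_huge_scores(self):
        assert evalue(1e4, self.EVD, 16295) == 0.0


class TestSearchDrivers:
    def test_implanted_consensus_is_recovered(self, small_library, small_calibrations):
        target = small_library.models[2]
        seq = "GGGG" + target.consensus + "GGGG"
        builds = {m.model_id: "local" for m in small_library}
        hits = scan_sequence(
            small_library, builds, seq, Z=small_library.n_total,
            e_cutoffs={"local": 0.1, "glocal": 24.0},
        )
        assert hits and hits[0].model_id == target.model_id
        assert hits[0].evalue < 1e-3

    def test_no_selected_builds_means_no_hits(self, small_library):
        assert scan_sequence(small_library, {}, "ACDEF", 10, {"local": 1.0, "glocal": 1.0}) == []

    def test_zero_cutoff_filters_everything(self, small_library):
        target = small_library.models[0]
        builds = {target.model_id: "glocal"}
        hits = scan_sequence(
            small_library, builds, target.consensus, small_library.n_total,
            {"local": 0.0, "glocal": 0.0},
        )
        assert hits == []

    def test_model_vs_own_seeds_hits_every_seed(self, small_library):
        model = small_library.models[0]
        seqs = [(f"s{i}", s) for i, s in enumerate(model.seed.ungapped_rows())]
        hits = search_model_vs_seqdb(model, "glocal", seqs, Z=small_library.n_total)
        assert {h.query_id for h in hits} == {qid for qid, _ in seqs}

    def test_permissive_cutoff_is_superset_of_strict(self, small_library):
        model = small_library.models[1]
        others = [(m.model_id, m.consensus) for m in small_library if m is not model]
        wide = search_model_vs_seqdb(model, "glocal", others, 8, e_cutoff=1000)
        narrow = search_model_vs_seqdb(model, "glocal", others, 8, e_cutoff=0.1)
        wide_keys = {(h.query_id, h.alignment.seq_span) for h in wide}
        narrow_keys = {(h.query_id, h.alignment.seq_span) for h in narrow}
        assert narrow_keys <= wide_keys and len(wide) >= len(narrow)

    def test_empty_seqdb(self, small_library):
        assert search_model_vs_seqdb(small_library.models[0], "local", [], 8) == []

    def test_uncalibrated_model_raises(self, weakened_library):
        model = weakened_library.models[0]
        model.evd_glocal = None
        try:
            with pytest.raises(ValueError):
                search_model_vs_seqdb(model, "glocal", [("q", "ACD")], 8)
        finally:
            model.evd_glocal = None  # leave fixture untouched


class TestHitTables:
    def test_round_trip(self, tmp_path, small_library):
        model = small_library.models[0]
        hits = search_model_vs_seqdb(
            model, "glocal", [("q1", model.consensus)], Z=small_library.n_total
        )
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, path)
        df = read_hit_table(path)
        assert list(df.columns) == [
            "query_id", "model_id", "build", "seq_from", "seq_to",
            "hmm_from", "hmm_to", "bit_score", "evalue",
        ]
        assert df.loc[0, "hmm_from"] == 1 and df.loc[0, "hmm_to"] == model.length

    def test_domtblout_adapter(self, tmp_path):
        line = (
            "PF00001 PF00001.1 120 queryA - 300 1e-10 50.0 0.1 1 1 "
            "2e-9 1e-9 48.0 0.1 5 100 10 110 8 115 0.9 desc"
        )
        p = tmp_path / "dom.tbl"
        p.write_text("# comment\n" + line + "\n")
        hits = read_domtblout_table(p)
        assert len(hits) == 1
        h = hits[0]
        assert (h.model_id, h.query_id) == ("PF00001", "queryA")
        assert h.alignment.model_span == (5, 100)
        assert h.alignment.seq_span == (10, 110)
        assert h.evalue == pytest.approx(1e-9)
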
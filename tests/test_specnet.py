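"""MGF I/O, modified cosine, network topology and census."""

import numpy as np
import pytest
from oracles import best_matching_score, connected_components

from bgcnet import specnet, synthetic_data
from bgcnet.specnet import NetworkParams, Spectrum


def _spec(sid, precursor, peaks, source="sample"):
    return Spectrum(sid, precursor, np.asarray(peaks, dtype=float), source=source)


class TestMgfIO:
    def test_two_block_fixture(self, tmp_path):
        spectra = [
            _spec("s1", 500.25, [[100.1, 10.0], [200.2, 5.0]]),
            _spec("s2", 600.5, [[150.0, 1.0]], source="blank"),
        ]
        path = tmp_path / "two.mgf"
        specnet.write_mgf(spectra, path)
        got = specnet.read_mgf(path)
        assert [s.spectrum_id for s in got] == ["s1", "s2"]
        assert got[0].precursor_mz == pytest.approx(500.25)
        assert np.allclose(got[0].peaks, spectra[0].peaks)
        assert got[1].source == "blank"
        assert got[0].charge == 1

    def test_peaks_sorted_on_construction(self):
        s = _spec("s", 300.0, [[200.0, 1.0], [100.0, 2.0]])
        assert list(s.peaks[:, 0]) == [100.0, 200.0]

    def test_round_trip_50_synthetic(self, tmp_path):
        spectra, _ = synthetic_data.gen_spectra(n_families=10, analogs_per_family=5,
                                                n_blank_families=0, seed=4)
        assert len(spectra) == 50
        path = tmp_path / "r.mgf"
        specnet.write_mgf(spectra, path)
        got = specnet.read_mgf(path)
        assert len(got) == 50
        for a, b in zip(spectra, got):
            assert a.spectrum_id == b.spectrum_id
            assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=1e-9)
            assert np.allclose(a.peaks, b.peaks, atol=1e-9)

    def test_missing_pepmass_errors(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text("BEGIN IONS\nTITLE=x\n100.0 1.0\nEND IONS\n")
        with pytest.raises(ValueError, match="PEPMASS"):
            specnet.read_mgf(path)


class TestPreprocess:
    def test_few_peaks_only_rescaled(self):
        s = _spec("s", 500.0, [[100.0, 4.0], [200.0, 9.0]])
        out = specnet.preprocess(s)
        assert out.n_peaks == 2
        assert np.linalg.norm(out.peaks[:, 1]) == pytest.approx(1.0)
        # sqrt then L2: ratio preserved as sqrt(4)/sqrt(9)
        assert out.peaks[0, 1] / out.peaks[1, 1] == pytest.approx(2 / 3)

    def test_window_keeps_top_six(self):
        peaks = [[100.0 + i, float(i + 1)] for i in range(10)]  # all within 50 Da
        out = specnet.preprocess(_spec("s", 500.0, peaks))
        assert out.n_peaks == 6
        assert set(out.peaks[:, 0]) == {104.0, 105.0, 106.0, 107.0, 108.0, 109.0}

    def test_unit_norm(self, rng):
        peaks = np.column_stack([np.sort(rng.uniform(100, 900, 20)), rng.uniform(0.1, 1, 20)])
        out = specnet.preprocess(_spec("s", 950.0, peaks))
        assert np.linalg.norm(out.peaks[:, 1]) == pytest.approx(1.0)


class TestModifiedCosine:
    def test_self_similarity_one(self, rng):
        peaks = np.column_stack([np.sort(rng.uniform(100, 800, 12)), rng.uniform(0.2, 1, 12)])
        s = specnet.preprocess(_spec("s", 900.0, peaks))
        cos, n = specnet.modified_cosine(s, s)
        assert cos == pytest.approx(1.0, abs=1e-9)
        assert n == s.n_peaks

    def test_no_candidates(self):
        a = specnet.preprocess(_spec("a", 500.0, [[100.0, 1.0]]))
        b = specnet.preprocess(_spec("b", 500.0, [[300.0, 1.0]]))
        assert specnet.modified_cosine(a, b) == (0.0, 0)

    def test_precursor_shift_matches(self):
        # second spectrum's peak is offset by exactly the precursor difference
        a = specnet.preprocess(_spec("a", 500.0, [[100.0, 1.0], [250.0, 1.0]]))
        b = specnet.preprocess(_spec("b", 510.0, [[110.0, 1.0], [250.0, 1.0]]))
        cos, n = specnet.modified_cosine(a, b)
        assert n == 2
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(20):
            na, nb = rng.integers(5, 9), rng.integers(5, 9)
            a = specnet.preprocess(
                _spec("a", float(rng.uniform(400, 600)),
                      np.column_stack([rng.choice(np.arange(100, 400, 10), na, replace=False)
                                       + rng.normal(0, 0.005, na),
                                       rng.uniform(0.1, 1, na)]))
            )
            b = specnet.preprocess(
                _spec("b", float(rng.uniform(400, 600)),
                      np.column_stack([rng.choice(np.arange(100, 400, 10), nb, replace=False)
                                       + rng.normal(0, 0.005, nb),
                                       rng.uniform(0.1, 1, nb)]))
            )
            ca, na_ = specnet.modified_cosine(a, b)
            cb, nb_ = specnet.modified_cosine(b, a)
            assert ca == pytest.approx(cb, abs=1e-9)
            assert na_ == nb_

    def test_optimal_matches_exhaustive_oracle(self, rng):
        from bgcnet.specnet import _candidate_pairs

        for _ in range(30):
            n = int(rng.integers(4, 7))
            grid = np.arange(100, 200, 5.0)
            a = specnet.preprocess(
                _spec("a", 300.0,
                      np.column_stack([rng.choice(grid, n, replace=False), rng.uniform(0.1, 1, n)]))
            )
            b = specnet.preprocess(
                _spec("b", 305.0,
                      np.column_stack([rng.choice(grid, n, replace=False), rng.uniform(0.1, 1, n)]))
            )
            cos_opt, _ = specnet.modified_cosine(a, b, method="optimal")
            pairs = _candidate_pairs(a, b, 0.02)
            assert cos_opt == pytest.approx(min(1.0, best_matching_score(pairs)), abs=1e-9)

    def test_against_matchms_reference(self, rng):
        # independent implementation cross-check on well-separated peaks,
        # where the one-to-one matching is unambiguous
        from matchms import Spectrum as MatchmsSpectrum
        from matchms.similarity import ModifiedCosine

        scorer = ModifiedCosine(tolerance=0.02)
        for _ in range(10):
            specs_ours, specs_ref = [], []
            prec = [float(rng.uniform(900, 950)), float(rng.uniform(900, 950))]
            for sid in (0, 1):
                n = int(rng.integers(6, 10))
                mz = np.sort(rng.choice(np.arange(100.0, 880.0, 60.0), n, replace=False)
                             + rng.uniform(-0.004, 0.004, n))
                inten = rng.uniform(0.1, 1.0, n)
                specs_ours.append(
                    specnet.preprocess(
                        _spec(str(sid), prec[sid], np.column_stack([mz, inten])),
                        sqrt_intensity=False,
                    )
                )
                specs_ref.append(
                    MatchmsSpectrum(mz=mz, intensities=inten,
                                    metadata={"precursor_mz": prec[sid]},
                                    metadata_harmonization=False)
                )
            cos, n_matched = specnet.modified_cosine(*specs_ours)
            ref = scorer.pair(*specs_ref)
            assert cos == pytest.approx(float(ref["score"]), abs=1e-6)
            assert n_matched == int(ref["matches"])

    def test_zero_peak_rejected(self):
        a = _spec("a", 500.0, np.empty((0, 2)))
        b = specnet.preprocess(_spec("b", 500.0, [[100.0, 1.0]]))
        with pytest.raises(ValueError):
            specnet.modified_cosine(a, b)


class TestNetwork:
    def test_identical_trio_forms_triangle(self, rng):
        peaks = np.column_stack([np.sort(rng.uniform(100, 700, 10)), rng.uniform(0.2, 1, 10)])
        spectra = [_spec(f"s{i}", 800.0, peaks.copy()) for i in range(3)]
        net = specnet.build_network(spectra)
        assert net.graph.number_of_edges() == 3
        assert [len(c) for c in net.components()] == [3]

    def test_subthreshold_cosine_gives_no_edge(self):
        # 5 shared peaks of 9 -> cosine ~5/9 < 0.70 after equal intensities
        shared = [[100.0 + 10 * i, 1.0] for i in range(5)]
        only_a = [[300.0 + 10 * i, 1.0] for i in range(4)]
        only_b = [[400.0 + 10 * i, 1.0] for i in range(4)]
        a = _spec("a", 500.0, shared + only_a)
        b = _spec("b", 500.0, shared + only_b)
        net = specnet.build_network([a, b])
        assert net.graph.number_of_edges() == 0

    def test_retained_edges_satisfy_thresholds(self):
        spectra, _ = synthetic_data.gen_spectra(n_families=8, seed=6)
        params = NetworkParams()
        net = specnet.build_network(spectra, params)
        for e in net.edges():
            assert e.cosine >= params.min_cosine
            assert e.n_matched >= params.min_matched

    def test_component_cap(self):
        spectra, _ = synthetic_data.gen_spectra(
            n_families=1, analogs_per_family=12, n_blank_families=0, seed=8,
        )
        params = NetworkParams(max_component=5, top_k=0)
        net = specnet.build_network(spectra, params)
        assert max(len(c) for c in net.components()) <= 5

    def test_blank_component_removal(self):
        spectra, truth = synthetic_data.gen_spectra(n_families=6, n_blank_families=2, seed=10)
        net = specnet.build_network(spectra)
        curated = specnet.remove_blank_components(net, spectra)
        surviving_families = {truth.assignment[n] for n in curated.graph.nodes}
        assert surviving_families == set(range(2, 6))  # planted blank families 0,1 removed

    def test_component_with_no_blank_untouched(self):
        spectra, _ = synthetic_data.gen_spectra(n_families=4, n_blank_families=0, seed=12)
        net = specnet.build_network(spectra)
        curated = specnet.remove_blank_components(net, spectra)
        assert set(curated.graph.nodes) == set(net.graph.nodes)


class TestCensus:
    def test_counts_match_independent_components(self, rng):
        import networkx as nx

        nodes = [f"n{i}" for i in range(40)]
        edges = []
        for _ in range(30):
            a, b = rng.choice(40, size=2, replace=False)
            edges.append((f"n{a}", f"n{b}"))
        graph = nx.Graph()
        graph.add_nodes_from(nodes)
        for a, b in edges:
            graph.add_edge(a, b, cosine=0.9, n_matched=6)
        census = specnet.family_census(specnet.SpectralNetwork(graph, NetworkParams()))
        comps = connected_components(nodes, edges)
        assert census.n_nodes == 40
        assert census.n_singletons == sum(1 for c in comps if len(c) == 1)
        assert census.n_families == sum(1 for c in comps if len(c) >= 2)
        assert census.n_singletons + census.n_connected_nodes == census.n_nodes
        assert census.n_families <= census.n_connected_nodes / 2

    def test_empty_network(self):
        import networkx as nx

        census = specnet.family_census(specnet.SpectralNetwork(nx.Graph(), NetworkParams()))
        assert census.as_dict() == {
            "n_nodes": 0, "n_singletons": 0, "n_connected_nodes": 0, "n_families": 0,
        }
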
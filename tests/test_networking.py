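"""Modified-cosine scoring and molecular network construction."""

import math

import numpy as np
import pytest

from cassanet.networking import build_network, cosine_score, export_graphml
from cassanet.simulate import homologous_family, simulate_fragments
from cassanet.spectra import Peak, Spectrum


def spec(sid, precursor, peaks):
    return Spectrum(sid, precursor, 1.0, tuple(Peak(m, i) for m, i in peaks))


# --------------------------------------------------------------------------
# independent oracle: exhaustive search over one-to-one peak matchings


def exhaustive_modified_cosine(a, b, tol=0.02, modified=True):
    wa = np.sqrt(np.asarray(a.intensities, float))
    wb = np.sqrt(np.asarray(b.intensities, float))
    wa /= math.sqrt(float(wa @ wa)) if wa.size else 1.0
    wb /= math.sqrt(float(wb @ wb)) if wb.size else 1.0
    shift = a.precursor_mz - b.precursor_mz
    pairs = []
    for i, mza in enumerate(a.mzs):
        for j, mzb in enumerate(b.mzs):
            d = mza - mzb
            if abs(d) <= tol or (modified and abs(d - shift) <= tol):
                pairs.append((i, j, wa[i] * wb[j]))

    best = [0.0]

    def recurse(k, used_a, used_b, acc):
        if acc > best[0]:
            best[0] = acc
        if k == len(pairs):
            return
        i, j, w = pairs[k]
        recurse(k + 1, used_a, used_b, acc)  # skip this pair
        if i not in used_a and j not in used_b:
            recurse(k + 1, used_a | {i}, used_b | {j}, acc + w)

    recurse(0, frozenset(), frozenset(), 0.0)
    return best[0]


def random_spectrum(rng, sid, n_peaks, base_mzs):
    """Random spectrum whose peaks cluster near shared positions so that
    direct and shifted candidates genuinely conflict."""
    mzs = rng.choice(base_mzs, size=n_peaks, replace=False) + rng.uniform(
        -0.03, 0.03, size=n_peaks
    )
    intens = rng.uniform(1.0, 100.0, size=n_peaks)
    return spec(sid, float(rng.uniform(300, 500)), list(zip(mzs, intens)))


class TestCosineScore:
    def test_self_similarity_is_one(self):
        s = spec("s", 400.0, [(100.0, 3.0), (200.0, 7.0), (350.0, 1.0)])
        cs, n = cosine_score(s, s)
        assert cs == pytest.approx(1.0, abs=1e-12)
        assert n == 3

    def test_disjoint_peaks_score_zero(self):
        a = spec("a", 400.0, [(100.0, 1.0), (200.0, 1.0)])
        b = spec("b", 400.0, [(150.0, 1.0), (250.0, 1.0)])
        assert cosine_score(a, b) == (0.0, 0)

    def test_half_overlap_hand_computed(self):
        # one matched pair of equal sqrt-weights in two 2-peak spectra: 0.5
        a = spec("a", 400.0, [(100.00, 1.0), (200.00, 1.0)])
        b = spec("b", 400.0, [(100.01, 1.0), (300.00, 1.0)])
        cs, n = cosine_score(a, b, frag_tol=0.02)
        assert cs == pytest.approx(0.5)
        assert n == 1

    def test_empty_spectrum_scores_zero_without_error(self):
        a = spec("a", 400.0, [])
        b = spec("b", 400.0, [(100.0, 1.0)])
        assert cosine_score(a, b) == (0.0, 0)

    def test_precursor_shifted_match(self):
        # analog pair: fragment ladders offset by the precursor difference
        a = spec("a", 400.0, [(100.0, 1.0), (250.0, 2.0)])
        b = spec("b", 414.0, [(114.0, 1.0), (264.0, 2.0)])
        cs, n = cosine_score(a, b, modified=True)
        assert cs == pytest.approx(1.0, abs=1e-12)
        assert n == 2
        cs_plain, _ = cosine_score(a, b, modified=False)
        assert cs_plain == 0.0

    def test_symmetry_and_intensity_scale_invariance(self):
        rng = np.random.default_rng(7)
        base = np.arange(100, 400, 12.5)
        for _ in range(20):
            a = random_spectrum(rng, "a", 6, base)
            b = random_spectrum(rng, "b", 6, base)
            cs_ab, n_ab = cosine_score(a, b)
            cs_ba, n_ba = cosine_score(b, a)
            assert cs_ab == pytest.approx(cs_ba, abs=1e-9)
            assert n_ab == n_ba
            scaled = Spectrum(
                b.id, b.precursor_mz, b.rt,
                tuple(Peak(p.mz, p.intensity * 37.5) for p in b.peaks),
            )
            cs_scaled, _ = cosine_score(a, scaled)
            assert cs_scaled == pytest.approx(cs_ab, abs=1e-9)

    def test_assignment_is_optimal_against_exhaustive_oracle(self):
        """The chosen one-to-one peak assignment must achieve the score of
        an exhaustive search over all matchings (small random spectra)."""
        rng = np.random.default_rng(42)
        base = np.arange(100, 400, 10.0)
        for _ in range(200):
            a = random_spectrum(rng, "a", int(rng.integers(2, 9)), base)
            b = random_spectrum(rng, "b", int(rng.integers(2, 9)), base)
            cs, _ = cosine_score(a, b)
            assert cs == pytest.approx(
                exhaustive_modified_cosine(a, b), abs=1e-9
            )

    def test_agrees_with_matchms_on_separated_peaks(self):
        """Cross-check against the reference implementation where its greedy
        assignment is provably optimal (well-separated peaks)."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(3)
        sim = ModifiedCosine(tolerance=0.02)
        for _ in range(20):
            n1, n2 = rng.integers(3, 9, size=2)
            mz1 = np.sort(rng.choice(np.arange(100, 600, 2.0), n1, replace=False))
            mz2 = np.sort(rng.choice(np.arange(100, 600, 2.0), n2, replace=False))
            i1 = rng.uniform(1, 100, n1)
            i2 = rng.uniform(1, 100, n2)
            p1, p2 = float(rng.uniform(300, 700)), float(rng.uniform(300, 700))
            ours, n_ours = cosine_score(
                spec("a", p1, list(zip(mz1, i1))), spec("b", p2, list(zip(mz2, i2)))
            )
            # matchms scores raw intensity products; feed it sqrt intensities
            ref = sim.pair(
                matchms.Spectrum(mz=mz1, intensities=np.sqrt(i1),
                                 metadata={"precursor_mz": p1}, metadata_harmonization=False),
                matchms.Spectrum(mz=mz2, intensities=np.sqrt(i2),
                                 metadata={"precursor_mz": p2}, metadata_harmonization=False),
            )
            assert ours == pytest.approx(float(ref["score"]), abs=1e-6)
            assert n_ours == int(ref["matches"])


class TestBuildNetwork:
    def family_spectra(self):
        fam1 = homologous_family("F1", "C24H37NO5", 3, "NME",
                                 {"ester60": 1, "oxo": 1}, {"hydroxy": 1})
        fam2 = homologous_family("F2", "C28H43NO7", 3, "NME",
                                 {"tigloyl": 1, "glucosyl": 1})
        return [simulate_fragments(s) for s in fam1], [simulate_fragments(s) for s in fam2]

    def test_empty_input_yields_empty_network(self):
        net = build_network([])
        assert net.nodes == {} and net.edges == [] and net.components == []

    def test_single_spectrum_is_singleton_component(self):
        s = spec("only", 400.0, [(100.0, 1.0)])
        net = build_network([s])
        assert net.components == [{"only"}]

    def test_one_compound_family_forms_one_component(self):
        fam1, _ = self.family_spectra()
        net = build_network(fam1)
        assert len(net.components) == 1
        assert all(e.cs > 0.55 for e in net.edges)

    def test_families_with_disjoint_losses_stay_separate(self):
        fam1, fam2 = self.family_spectra()
        net = build_network(fam1 + fam2)
        comps = {frozenset(c) for c in net.components}
        assert frozenset(s.id for s in fam1) in comps
        assert frozenset(s.id for s in fam2) in comps
        assert len(comps) == 2

    def test_top_k_degree_bound(self):
        fam1, fam2 = self.family_spectra()
        net = build_network(fam1 + fam2, top_k=1)
        degree = {}
        for e in net.edges:
            degree[e.node_a] = degree.get(e.node_a, 0) + 1
            degree[e.node_b] = degree.get(e.node_b, 0) + 1
        assert max(degree.values(), default=0) <= 1

    def test_component_cap_enforced(self):
        fam1, fam2 = self.family_spectra()
        net = build_network(fam1 + fam2, max_component=2)
        assert all(len(c) <= 2 for c in net.components)

    def test_edges_monotone_in_thresholds(self):
        fam1, fam2 = self.family_spectra()
        spectra = fam1 + fam2
        loose = build_network(spectra, cs_min=0.3, min_matched=2)
        tight_cs = build_network(spectra, cs_min=0.7, min_matched=2)
        tight_matched = build_network(spectra, cs_min=0.3, min_matched=12)
        as_set = lambda net: {(e.node_a, e.node_b) for e in net.edges}
        assert as_set(tight_cs) <= as_set(loose)
        assert as_set(tight_matched) <= as_set(loose)

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        fam1, _ = self.family_spectra()
        net = build_network(fam1, node_attrs={fam1[0].id: {"profile": "9/48/33/11"}})
        path = tmp_path / "net.graphml"
        export_graphml(net, path)
        g = nx.read_graphml(path)
        assert set(g.nodes) == set(net.nodes)
        assert g.number_of_edges() == len(net.edges)
        for e in net.edges:
            attrs = g.edges[e.node_a, e.node_b]
            assert attrs["cs"] == pytest.approx(e.cs, abs=1e-4)
            assert int(attrs["n_matched"]) == e.n_matched
        assert g.nodes[fam1[0].id]["profile"] == "9/48/33/11"

    def test_empty_network_graphml_is_valid(self, tmp_path):
        import networkx as nx

        path = tmp_path / "empty.graphml"
        export_graphml(build_network([]), path)
        assert nx.read_graphml(path).number_of_nodes() == 0
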
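"""Seed-site scanning against an independent brute-force oracle, and the
DE-intersection / anticorrelation screens."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cernet import diffexpr
from cernet.synth import SynthConfig, generate_dataset
from cernet.targets import (
    SeedSite,
    TargetRelation,
    anticorrelation_filter,
    find_seed_sites,
    intersect_with_de,
    predict_targets,
)

MIR21 = "UAGCUUAUCAGACUGAUGUUGA"

_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}


def oracle_scan(mirna: str, utr: str):
    """Naive window scan checking Watson–Crick pairing position by position.

    Deliberately structured differently from the scanner: it tests pairing
    per nucleotide instead of searching for precomputed site texts.
    """
    m = mirna.upper().replace("T", "U")
    u = utr.upper().replace("T", "U")

    def pairs(utr_idx: int, mir_pos: int) -> bool:  # both 0-based
        return u[utr_idx] == _PAIR[m[mir_pos]]

    def seed_match(start: int, first: int, last: int) -> bool:
        # UTR window pairing miRNA positions first..last (1-based), with
        # the higher miRNA position opposite the lower UTR coordinate
        length = last - first + 1
        if start + length > len(u):
            return False
        return all(
            pairs(start + k, last - 1 - k) for k in range(length)
        )

    eights = [
        (i + 1, i + 8)
        for i in range(len(u))
        if seed_match(i, 2, 8) and i + 7 < len(u) and u[i + 7] == "A"
    ]

    def inside_8mer(s, e):
        return any(a <= s and e <= b for a, b in eights)

    found = [("8mer", s, e) for s, e in eights]
    sevens = {}  # span -> type, 7mer-m8 winning over 7mer-A1 on the same span
    for i in range(len(u)):
        span = (i + 1, i + 7)
        if inside_8mer(*span):
            continue
        if seed_match(i, 2, 8) and not (i + 7 < len(u) and u[i + 7] == "A"):
            sevens[span] = "7mer-m8"
        elif seed_match(i, 2, 7) and i + 6 < len(u) and u[i + 6] == "A":
            sevens.setdefault(span, "7mer-A1")
    found += [(t, s, e) for (s, e), t in sevens.items()]
    return sorted(found)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestFindSeedSites:
    def test_mir21_8mer_example(self):
        sites = find_seed_sites(MIR21, "GGGAUAAGCUAGGG")
        assert len(sites) == 1
        s = sites[0]
        assert (s.site_type, s.utr_start, s.utr_end) == ("8mer", 4, 11)
        assert s.site_sequence == "AUAAGCUA"

    def test_poly_a_utr_has_no_sites(self):
        assert find_seed_sites(MIR21, "AAAAAAAA") == []

    def test_bare_7mer_m8(self):
        sites = find_seed_sites(MIR21, "AUAAGCU")
        assert [(s.site_type, s.utr_start, s.utr_end) for s in sites] == [
            ("7mer-m8", 1, 7)
        ]

    def test_7mer_a1(self):
        sites = find_seed_sites(MIR21, "CCUAAGCUACC")
        assert [(s.site_type, s.utr_start, s.utr_end) for s in sites] == [
            ("7mer-A1", 3, 9)
        ]

    def test_8mer_suppresses_contained_7mers(self):
        sites = find_seed_sites(MIR21, "CCAUAAGCUACC")
        assert [s.site_type for s in sites] == ["8mer"]

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            mirna = random_rna(rng, 22)
            utr = random_rna(rng, 500)
            got = sorted(
                (s.site_type, s.utr_start, s.utr_end)
                for s in find_seed_sites(mirna, utr)
            )
            assert got == oracle_scan(mirna, utr)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_dna_alphabet_equivalent_to_rna(self, seed):
        rng = np.random.default_rng(seed)
        mirna = random_rna(rng, 22)
        utr = random_rna(rng, 120)
        assert find_seed_sites(mirna, utr) == find_seed_sites(
            mirna.replace("U", "T"), utr.replace("U", "T")
        )

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_seed_sites("UAGCUUA", "A" * 20)

    def test_alphabet_violation_rejected(self):
        with pytest.raises(ValueError):
            find_seed_sites(MIR21, "ANNNAAAA")

    def test_compensatory_mode_off_by_default(self):
        # seed match of positions 2-7 with one mismatch at its centre,
        # plus perfect pairing to miRNA positions 13-17 upstream
        from cernet.targets import reverse_complement

        seed6 = reverse_complement(MIR21[1:7])
        broken = seed6[:3] + ("A" if seed6[3] != "A" else "C") + seed6[4:]
        comp3p = reverse_complement(MIR21[12:17])
        utr = "CC" + comp3p + "GGGGG" + broken + "CC"
        start = len("CC" + comp3p + "GGGGG") + 1
        assert find_seed_sites(MIR21, utr) == []
        sites = find_seed_sites(MIR21, utr, include_compensatory=True)
        assert [(s.site_type, s.utr_start) for s in sites] == [
            ("3p-compensatory", start)
        ]


class TestPredictTargets:
    def test_one_mirna_two_utrs_two_relations(self):
        utr = "GGGAUAAGCUAGGG"
        rels = predict_targets({"mir": MIR21}, {"u1": utr, "u2": "CC" + utr})
        assert [(r.mirna_id, r.mrna_id) for r in rels] == [("mir", "u1"), ("mir", "u2")]
        assert all(len(r.sites) == 1 for r in rels)

    def test_no_complementarity_gives_empty_list(self):
        assert predict_targets({"mir": MIR21}, {"u": "A" * 30}) == []

    def test_every_planted_pair_predicted(self, default_dataset):
        rels = predict_targets(default_dataset.mirna_seqs, default_dataset.utr_seqs)
        predicted = {(r.mirna_id, r.mrna_id) for r in rels}
        assert set(default_dataset.truth.planted_pairs) <= predicted

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            predict_targets({}, {"u": "AAAA"})


def _rel(mirna, mrna):
    return TargetRelation(mirna, mrna, [SeedSite("8mer", 1, 8, "N" * 8)])


class TestIntersectWithDe:
    def test_hand_enumerated_mixed_set(self):
        rels = [
            _rel("m1", "g1"),  # both DE -> kept
            _rel("m1", "g2"),  # mRNA not DE
            _rel("m2", "g1"),  # miRNA not DE
            _rel("m2", "g3"),  # neither
            _rel("m3", "g4"),  # both DE -> kept
        ]
        kept = intersect_with_de(rels, {"g1", "g4"}, {"m1", "m3"})
        assert [(r.mirna_id, r.mrna_id) for r in kept] == [("m1", "g1"), ("m3", "g4")]
        assert all(r.passed_de_intersection for r in kept)

    def test_all_de_is_identity(self):
        rels = [_rel("m1", "g1"), _rel("m2", "g2")]
        kept = intersect_with_de(rels, {"g1", "g2"}, {"m1", "m2"})
        assert len(kept) == len(rels)


class TestAnticorrelationFilter:
    def _matrices(self):
        import pandas as pd
        from cernet.matrix import ExpressionMatrix

        samples = [f"s{i}" for i in range(6)]
        design = pd.DataFrame(
            {"sample_id": samples, "condition": ["a"] * 3 + ["b"] * 3, "replicate": range(6)}
        ).set_index("sample_id")
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        mirna = ExpressionMatrix(
            values=pd.DataFrame([base], index=["m1"], columns=samples), design=design
        )
        mrna = ExpressionMatrix(
            values=pd.DataFrame(
                [-base, base + np.array([0, 0.1, -0.1, 0.2, 0, 0])],
                index=["g_neg", "g_pos"],
                columns=samples,
            ),
            design=design,
        )
        return mirna, mrna

    def test_negative_pair_kept_positive_removed(self):
        mirna, mrna = self._matrices()
        rels = [_rel("m1", "g_neg"), _rel("m1", "g_pos")]
        kept = anticorrelation_filter(
            rels,
            mirna,
            mrna,
            mirna_directions={"m1": "up"},
            mrna_directions={"g_neg": "down", "g_pos": "down"},
        )
        assert [(r.mirna_id, r.mrna_id) for r in kept] == [("m1", "g_neg")]
        assert kept[0].correlation_r == pytest.approx(-1.0)
        assert kept[0].passed_anticorrelation

    def test_same_direction_pair_removed(self):
        mirna, mrna = self._matrices()
        kept = anticorrelation_filter(
            [_rel("m1", "g_neg")],
            mirna,
            mrna,
            mirna_directions={"m1": "up"},
            mrna_directions={"g_neg": "up"},
        )
        assert kept == []

    def test_tightening_r_max_never_enlarges_output(self):
        rng = np.random.default_rng(0)
        import pandas as pd
        from cernet.matrix import ExpressionMatrix

        samples = [f"s{i}" for i in range(6)]
        design = pd.DataFrame(
            {"sample_id": samples, "condition": ["a"] * 3 + ["b"] * 3, "replicate": range(6)}
        ).set_index("sample_id")
        mirna = ExpressionMatrix(
            values=pd.DataFrame(rng.normal(size=(5, 6)),
                                index=[f"m{i}" for i in range(5)], columns=samples),
            design=design,
        )
        mrna = ExpressionMatrix(
            values=pd.DataFrame(rng.normal(size=(5, 6)),
                                index=[f"g{i}" for i in range(5)], columns=samples),
            design=design,
        )
        rels = [_rel(f"m{i}", f"g{j}") for i in range(5) for j in range(5)]
        sizes = []
        for r_max in (0.5, 0.0, -0.5, -0.9):
            kept = anticorrelation_filter(
                rels, mirna, mrna, r_max=r_max, require_opposite_direction=False
            )
            sizes.append(len(kept))
        assert sizes == sorted(sizes, reverse=True)

    def test_sample_mismatch_rejected(self):
        mirna, mrna = self._matrices()
        with pytest.raises(ValueError):
            anticorrelation_filter(
                [], mirna.subset_samples(mirna.sample_ids[:4]), mrna,
                require_opposite_direction=False,
            )

    def test_planted_pairs_recovered_with_high_precision(self):
        precisions, recalls = [], []
        for seed in range(1, 6):
            ds = generate_dataset(SynthConfig(seed=seed))
            rels = predict_targets(ds.mirna_seqs, ds.utr_seqs)
            truth = ds.truth
            inter = intersect_with_de(rels, truth.de_ids("mRNA"), truth.de_ids("miRNA"))
            kept = anticorrelation_filter(
                inter,
                ds.mirna,
                ds.mrna,
                mirna_directions=truth.de_labels["miRNA"],
                mrna_directions=truth.de_labels["mRNA"],
            )
            planted = set(truth.planted_pairs)
            got = {(r.mirna_id, r.mrna_id) for r in kept}
            recalls.append(len(got & planted) / len(planted))
            precisions.append(len(got & planted) / max(len(got), 1))
        assert np.mean(recalls) >= 0.9
        assert np.mean(precisions) >= 0.9
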
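"""Grouping, uniqueness, spectral balancing and nSpC normalization."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from holoquant import (
    ProteinRecord,
    ValidationError,
    balance_spectra,
    compute_nspc,
    greedy_cluster,
    pairwise_identity,
    reassess_uniqueness,
    taxon_fractions,
)
from holoquant.quant import ProteinGroup, group_lengths


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEFGHIK", "ACDEFGHIK") == 1.0

    def test_single_substitution(self):
        assert np.isclose(pairwise_identity("ACDEFGHIK", "ACDEFGHIR"), 8 / 9)

    def test_prefix_extension_is_full_identity(self):
        assert pairwise_identity("ACDEF", "ACDEFGGGGG") == 1.0

    def test_symmetry(self):
        a, b = "MKRAAAKGGGWYV", "MKRAAAKGGGWYVHHQQ"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_x_never_matches(self):
        assert pairwise_identity("AXC", "AXC") == 2 / 3

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_identity("", "ACD")


def brute_force_greedy(records, threshold):
    """Independent greedy assignment: precomputed all-pairs identity matrix,
    explicit scan over seeds in founding order."""
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    ident = {
        (a.id, b.id): pairwise_identity(a.sequence, b.sequence)
        for a in ordered
        for b in ordered
    }
    clusters: list[tuple[str, list[str]]] = []  # (seed_id, member_ids)
    for rec in ordered:
        for seed_id, members in clusters:
            if ident[(rec.id, seed_id)] >= threshold:
                members.append(rec.id)
                break
        else:
            clusters.append((rec.id, [rec.id]))
    return [(seed, sorted(members)) for seed, members in clusters]


def random_instance(rng, n_max=20):
    """Random sequences salted with near-duplicate families."""
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    n_base = rng.integers(1, max(2, n_max // 2))
    records = []
    k = 0
    for _ in range(n_base):
        length = int(rng.integers(10, 40))
        seq = "".join(rng.choice(aa, size=length))
        records.append(ProteinRecord(f"p{k:03d}", seq))
        k += 1
        for _ in range(int(rng.integers(0, 3))):
            if len(records) >= n_max:
                break
            variant = list(seq)
            n_sub = int(rng.integers(0, max(1, length // 8) + 1))
            for pos in rng.choice(length, size=n_sub, replace=False):
                variant[pos] = str(rng.choice(aa))
            records.append(ProteinRecord(f"p{k:03d}", "".join(variant)))
            k += 1
        if len(records) >= n_max:
            break
    return records


class TestGreedyCluster:
    def test_identical_sequences_form_one_group(self):
        recs = [ProteinRecord(f"p{i}", "MKRAAAKGGGWYVHH") for i in range(3)]
        groups = greedy_cluster(recs, 0.9)
        assert len(groups) == 1
        assert sorted(groups[0].member_ids) == ["p0", "p1", "p2"]

    def test_variant_joins_seed_and_stranger_stays_out(self):
        rng = np.random.default_rng(0)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aa, size=100))
        a_var = list(a)
        for pos in rng.choice(100, size=5, replace=False):  # 95% identity
            a_var[pos] = "W" if a_var[pos] != "W" else "Y"
        b = "".join(rng.choice(aa, size=60))
        groups = greedy_cluster(
            [ProteinRecord("A", a), ProteinRecord("Avar", "".join(a_var)), ProteinRecord("B", b)],
            0.9,
        )
        by_seed = {g.seed_id: sorted(g.member_ids) for g in groups}
        assert by_seed == {"A": ["A", "Avar"], "B": ["B"]}

    def test_threshold_one_on_distinct_sequences_gives_singletons(self):
        recs = [
            ProteinRecord("a", "MKRAAAKGGGWYVHH"),
            ProteinRecord("b", "MKRAAAKGGGWYVHQ"),
            ProteinRecord("c", "CCDDEEFFWWYYPPS"),
        ]
        assert len(greedy_cluster(recs, 1.0)) == 3

    def test_seed_is_longest_member(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            records = random_instance(rng)
            for g in greedy_cluster(records, 0.9):
                assert g.seed_id in g.member_ids
                assert all(len(g.member_sequences[m]) <= g.seed_length for m in g.member_ids)

    def test_members_reach_threshold_identity_with_seed(self):
        rng = np.random.default_rng(2)
        records = random_instance(rng)
        for g in greedy_cluster(records, 0.9):
            for m in g.member_ids:
                assert pairwise_identity(g.member_sequences[m], g.seed_sequence) >= 0.9

    def test_agrees_with_brute_force_oracle_smoke(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            records = random_instance(rng)
            got = [(g.seed_id, sorted(g.member_ids)) for g in greedy_cluster(records, 0.9)]
            assert got == brute_force_greedy(records, 0.9)


class TestReassessUniqueness:
    def make_groups(self):
        recs = [
            ProteinRecord("a1", "MKRAAAKGGGWYVHHQQLL"),
            ProteinRecord("a2", "MKRAAAKGGGWYVHHQQLV"),  # same family as a1
            ProteinRecord("b", "CCDDEEFFWWYYPPSSTTV"),
        ]
        return greedy_cluster(recs, 0.9)

    def test_peptide_in_one_protein_is_unique(self):
        groups = self.make_groups()
        assignment = reassess_uniqueness(["CCDDEEFF"], groups)
        assert assignment["CCDDEEFF"] == ["b"]

    def test_peptide_in_two_proteins_of_one_group_is_unique(self):
        groups = self.make_groups()
        assignment = reassess_uniqueness(["MKRAAAKGGG"], groups)
        assert len(assignment["MKRAAAKGGG"]) == 1  # group level, not protein level

    def test_peptide_spanning_groups_is_shared(self):
        recs = [
            ProteinRecord("a", "MKRAAAKGGGWYVHHQQLL"),
            ProteinRecord("b", "CCDDEEFFWWMKRAAAKGG"),
        ]
        groups = greedy_cluster(recs, 0.9)
        assignment = reassess_uniqueness(["MKRAAAKGG"], groups)
        assert sorted(assignment["MKRAAAKGG"]) == sorted(g.group_id for g in groups)

    def test_orphan_peptides_excluded_with_warning(self, caplog):
        groups = self.make_groups()
        with caplog.at_level(logging.WARNING):
            assignment = reassess_uniqueness(["WWWWWWWW"], groups)
        assert "WWWWWWWW" not in assignment
        assert "matched no database protein" in caplog.text

    def test_merging_groups_never_decreases_unique_peptides(self):
        recs = [
            ProteinRecord("a", "MKRAAAKGGGWYVHHQQLL"),
            ProteinRecord("b", "CCDDEEFFWWMKRAAAKGG"),
        ]
        groups = greedy_cluster(recs, 0.9)
        peptides = ["MKRAAAKGG", "WYVHHQQLL", "CCDDEEFF"]
        reassess_uniqueness(peptides, groups)
        separate_unique = {g.group_id: set(g.unique_peptides) for g in groups}
        merged = ProteinGroup(
            group_id="m",
            seed_id=groups[0].seed_id,
            seed_sequence=groups[0].seed_sequence,
        )
        for g in groups:
            merged.member_ids += g.member_ids
            merged.member_sequences.update(g.member_sequences)
        reassess_uniqueness(peptides, [merged])
        assert merged.unique_peptides >= set().union(*separate_unique.values())


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "peptide", "count"])


def singleton_groups(ids):
    return [
        ProteinGroup(group_id=i, seed_id=i, seed_sequence="M" * 10, member_ids=[i])
        for i in ids
    ]


class TestBalanceSpectra:
    def test_proportional_split_by_unique_counts(self):
        groups = singleton_groups(["g1", "g2"])
        assignment = {"u1": ["g1"], "u2": ["g2"], "sh": ["g1", "g2"]}
        counts = counts_frame([("s", "u1", 2), ("s", "u2", 1), ("s", "sh", 6)])
        balanced = balance_spectra(counts, assignment, groups)
        assert np.isclose(balanced.loc["g1", "s"], 2 + 4)
        assert np.isclose(balanced.loc["g2", "s"], 1 + 2)

    def test_zero_unique_everywhere_splits_equally(self):
        groups = singleton_groups(["g1", "g2"])
        counts = counts_frame([("s", "sh", 6)])
        balanced = balance_spectra(counts, {"sh": ["g1", "g2"]}, groups)
        assert balanced.loc["g1", "s"] == balanced.loc["g2", "s"] == 3

    def test_all_spectra_to_the_only_evidenced_group(self):
        groups = singleton_groups(["g1", "g2"])
        assignment = {"u1": ["g1"], "sh": ["g1", "g2"]}
        counts = counts_frame([("s", "u1", 3), ("s", "sh", 6)])
        balanced = balance_spectra(counts, assignment, groups)
        assert np.isclose(balanced.loc["g1", "s"], 9)
        assert balanced.loc["g2", "s"] == 0

    def test_negative_counts_rejected(self):
        groups = singleton_groups(["g1"])
        with pytest.raises(ValidationError):
            balance_spectra(counts_frame([("s", "u1", -1)]), {"u1": ["g1"]}, groups)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_conservation_on_random_sharing_structures(self, seed):
        rng = np.random.default_rng(seed)
        n_groups = int(rng.integers(1, 6))
        gids = [f"g{i}" for i in range(n_groups)]
        groups = singleton_groups(gids)
        assignment = {}
        rows = []
        for p in range(int(rng.integers(1, 12))):
            pep = f"pep{p}"
            k = int(rng.integers(1, n_groups + 1))
            assignment[pep] = list(rng.choice(gids, size=k, replace=False))
            for s in ("s1", "s2"):
                rows.append((s, pep, int(rng.integers(0, 8))))
        counts = counts_frame(rows)
        balanced = balance_spectra(counts, assignment, groups)
        totals = counts.groupby("sample_id")["count"].sum()
        for s in totals.index:
            assert np.isclose(balanced[s].sum(), totals[s], rtol=1e-9)


class TestComputeNspc:
    def test_equal_counts_equal_lengths_split_evenly(self):
        balanced = pd.DataFrame({"s": [5.0, 5.0]}, index=["g1", "g2"])
        qm = compute_nspc(balanced, {"g1": 100, "g2": 100}, {"g1": "host", "g2": "host"})
        assert np.allclose(qm.values["s"], [0.5, 0.5])
        qm4 = compute_nspc(
            balanced, {"g1": 100, "g2": 100}, {"g1": "host", "g2": "host"}, scale="per_10000"
        )
        assert np.allclose(qm4.values["s"], [5000, 5000])

    def test_length_correction(self):
        balanced = pd.DataFrame({"s": [10.0, 20.0]}, index=["g1", "g2"])
        qm = compute_nspc(balanced, {"g1": 100, "g2": 400}, {"g1": "host", "g2": "host"})
        assert np.allclose(qm.values["s"], [2 / 3, 1 / 3])

    def test_single_group_universe_is_one(self):
        balanced = pd.DataFrame({"s": [7.0]}, index=["g1"])
        qm = compute_nspc(balanced, {"g1": 50}, {"g1": "host"})
        assert qm.values.loc["g1", "s"] == 1.0

    def test_host_universe_scales_symbionts_by_the_host_denominator(self):
        balanced = pd.DataFrame({"s": [10.0, 10.0, 10.0]}, index=["h1", "h2", "y1"])
        lengths = {"h1": 100, "h2": 100, "y1": 100}
        taxa = {"h1": "host", "h2": "host", "y1": "symbiont"}
        qm = compute_nspc(balanced, lengths, taxa, universe="host", scale="per_10000")
        host_sum = qm.values.loc[["h1", "h2"], "s"].sum()
        assert np.isclose(host_sum, 10_000, rtol=1e-9)
        assert np.isclose(qm.values.loc["y1", "s"], 5_000)  # same scale factor

    def test_per_taxon_universe_sums_to_one_within_each_taxon(self):
        balanced = pd.DataFrame({"s": [10.0, 30.0, 10.0]}, index=["h1", "h2", "y1"])
        lengths = dict.fromkeys(balanced.index, 100)
        taxa = {"h1": "host", "h2": "host", "y1": "symbiont"}
        qm = compute_nspc(balanced, lengths, taxa, universe="per_taxon")
        assert np.isclose(qm.values.loc[["h1", "h2"], "s"].sum(), 1.0)
        assert np.isclose(qm.values.loc["y1", "s"], 1.0)

    def test_zero_signal_sample_emits_zeros_and_warns(self, caplog):
        balanced = pd.DataFrame({"s": [0.0, 0.0]}, index=["g1", "g2"])
        with caplog.at_level(logging.WARNING):
            qm = compute_nspc(balanced, {"g1": 10, "g2": 10}, {"g1": "host", "g2": "host"})
        assert (qm.values["s"] == 0).all()
        assert "zero total SAF" in caplog.text

    def test_invalid_length_rejected(self):
        balanced = pd.DataFrame({"s": [1.0]}, index=["g1"])
        with pytest.raises(ValidationError):
            compute_nspc(balanced, {"g1": 0}, {"g1": "host"})


class TestTaxonFractions:
    def make_quant(self, host_vals, sym_vals, cont_vals=()):
        idx, vals, taxa = [], [], {}
        for i, v in enumerate(host_vals):
            idx.append(f"h{i}"); vals.append(v); taxa[f"h{i}"] = "host"
        for i, v in enumerate(sym_vals):
            idx.append(f"y{i}"); vals.append(v); taxa[f"y{i}"] = "symbiont"
        for i, v in enumerate(cont_vals):
            idx.append(f"c{i}"); vals.append(v); taxa[f"c{i}"] = "contaminant"
        from holoquant.quant import QuantMatrix

        values = pd.DataFrame({"s": vals}, index=idx)
        return QuantMatrix(values=values, taxa=pd.Series(taxa), universe="all", scale="fraction")

    def test_simple_fraction(self):
        out = taxon_fractions(self.make_quant([0.8], [0.2]))
        assert np.isclose(out.loc["s", "symbiont_fraction"], 0.2)

    def test_zero_symbiont_signal(self):
        out = taxon_fractions(self.make_quant([1.0], [0.0]))
        assert out.loc["s", "symbiont_fraction"] == 0.0

    def test_contaminants_excluded(self):
        out = taxon_fractions(self.make_quant([0.4], [0.4], cont_vals=[0.2]))
        assert np.isclose(out.loc["s", "symbiont_fraction"], 0.5)

    def test_zero_holobiont_signal_is_missing(self):
        out = taxon_fractions(self.make_quant([0.0], [0.0], cont_vals=[1.0]))
        assert np.isnan(out.loc["s", "symbiont_fraction"])

    def test_condition_summary_attached_with_design(self):
        qm = self.make_quant([0.8], [0.2])
        design = pd.DataFrame(
            {"sample_id": ["s"], "condition": ["fresh"], "replicate": [1]}
        )
        out = taxon_fractions(qm, design)
        summary = out.attrs["condition_summary"]
        assert list(summary["condition"]) == ["fresh"]
        assert summary["n"].iloc[0] == 1
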
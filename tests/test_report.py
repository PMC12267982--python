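"""Genome-size-corrected profiles, thresholding, and BioBoxes output."""

import numpy as np
import pytest

from metabloom.reassign import Assignment
from metabloom.report import (profile, read_binning, read_bioboxes_profile,
                              threshold_profile, write_binning,
                              write_bioboxes_profile, write_tree_report)
from metabloom.simulate import RANK_LADDER, CommunitySpec, simulate_community


def assignments_of(counts):
    out = []
    i = 0
    for target, n in counts.items():
        for _ in range(n):
            out.append(Assignment(f"r{i}", target, "unique"))
            i += 1
    return out


@pytest.fixture(scope="module")
def big_tree():
    return simulate_community(
        CommunitySpec(n_species=16, genome_length=(1000, 1000),
                      n_reads=10, paired=False, seed=2)).tree


def random_profile(tree, rng, n_reads=500, unclassified_frac=0.2):
    species = [t for t in tree.nodes if tree.rank(t) == "species"]
    sizes = {t: float(rng.integers(5e5, 5e6)) for t in tree.nodes}
    counts = rng.multinomial(int(n_reads * (1 - unclassified_frac)),
                             rng.dirichlet(np.ones(len(species))))
    assigns = assignments_of({s: int(c) for s, c in zip(species, counts)
                              if c > 0})
    return profile(assigns, tree, sizes, total_reads=n_reads), sizes, assigns


class TestProfile:
    def test_closed_form_size_correction(self, ladder_tree):
        sizes = {t: 1e6 for t in ladder_tree.nodes}
        sizes["spB"] = 2e6
        prof = profile(assignments_of({"spA": 100, "spB": 100}),
                       ladder_tree, sizes, total_reads=200)
        ab = prof.abundances("species")
        assert ab["spA"] == pytest.approx(66.6667, abs=1e-3)
        assert ab["spB"] == pytest.approx(33.3333, abs=1e-3)

    def test_equal_sizes_proportional_to_counts(self, ladder_tree):
        sizes = {t: 3e6 for t in ladder_tree.nodes}
        prof = profile(assignments_of({"spA": 30, "spB": 10, "spC": 60}),
                       ladder_tree, sizes, total_reads=100)
        ab = prof.abundances("species")
        assert ab == pytest.approx({"spA": 30, "spB": 10, "spC": 60})

    def test_rank_sums_plus_unclassified_are_100(self, big_tree):
        rng = np.random.default_rng(0)
        prof, _, _ = random_profile(big_tree, rng)
        assert prof.unclassified_pct == pytest.approx(20.0)
        for rank in RANK_LADDER:
            total = sum(prof.abundances(rank).values()) + prof.unclassified_pct
            assert total == pytest.approx(100.0, abs=1e-6)

    def test_doubling_genome_size_strictly_decreases_abundance(self, big_tree):
        rng = np.random.default_rng(1)
        prof, sizes, assigns = random_profile(big_tree, rng)
        target = next(iter(prof.abundances("species")))
        sizes2 = dict(sizes)
        sizes2[target] = sizes[target] * 2
        prof2 = profile(assigns, big_tree, sizes2, total_reads=500)
        assert prof2.abundances("species")[target] < \
            prof.abundances("species")[target]

    def test_parent_counts_cumulate_children(self, big_tree):
        rng = np.random.default_rng(2)
        prof, _, _ = random_profile(big_tree, rng)
        rows = prof.rows.set_index("taxid")
        for taxid in rows.index:
            kids = [c for c in big_tree.children(taxid) if c in rows.index]
            if kids:
                expect = rows.loc[taxid, "direct_count"] + \
                    sum(rows.loc[c, "read_count"] for c in kids)
                assert rows.loc[taxid, "read_count"] == expect


class TestThreshold:
    def test_zero_threshold_is_identity(self, big_tree):
        prof, _, _ = random_profile(big_tree, np.random.default_rng(3))
        out = threshold_profile(prof, 0.0)
        assert out.rows.equals(prof.rows)
        assert out.filtered_pct == {}

    def test_rows_at_or_below_threshold_removed(self, ladder_tree):
        sizes = {t: 1e6 for t in ladder_tree.nodes}
        prof = profile(assignments_of({"spA": 99_996, "spB": 4}),
                       ladder_tree, sizes, total_reads=100_000)
        out = threshold_profile(prof, 0.005)  # spB sits at 0.004%
        assert "spB" not in set(out.rows["taxid"])
        assert "spA" in set(out.rows["taxid"])

    def test_conservation_with_filtered_mass(self, big_tree):
        prof, _, _ = random_profile(big_tree, np.random.default_rng(4))
        out = threshold_profile(prof, 1.0)
        for rank in RANK_LADDER:
            total = (sum(out.abundances(rank).values())
                     + out.filtered_pct.get(rank, 0.0)
                     + out.unclassified_pct)
            assert total == pytest.approx(100.0, abs=1e-6)


class TestBioBoxes:
    def test_profile_roundtrip_and_taxpath(self, big_tree, tmp_path):
        prof, _, _ = random_profile(big_tree, np.random.default_rng(5))
        path = tmp_path / "p.cami"
        write_bioboxes_profile(prof, "s1", path)
        rows, unclassified, sample_id = read_bioboxes_profile(path)
        assert sample_id == "s1"
        assert unclassified == pytest.approx(prof.unclassified_pct, abs=1e-6)
        for _, row in rows.iterrows():
            expect = prof.rows.set_index("taxid").loc[row["taxid"],
                                                      "abundance"]
            assert row["abundance"] == pytest.approx(expect, abs=1e-6)
            # TAXPATH is the rank-restricted lineage of the taxonomy
            path_ids = [p for p in row["taxpath"].split("|") if p]
            lineage = big_tree.lineage(row["taxid"])
            assert path_ids == [t for t in lineage
                                if big_tree.rank(t) in RANK_LADDER]

    def test_empty_profile_writes_header_only(self, big_tree, tmp_path):
        prof = profile([], big_tree, {}, total_reads=0)
        path = tmp_path / "empty.cami"
        write_bioboxes_profile(prof, "s0", path)
        rows, _, _ = read_bioboxes_profile(path)
        assert rows.empty

    def test_binning_rows_match_classified_reads(self, ladder_tree, tmp_path):
        assigns = assignments_of({"spA": 5, "spB": 3})
        path = tmp_path / "b.cami"
        write_binning(assigns, "s1", path)
        pred, sample_id = read_binning(path)
        assert sample_id == "s1"
        assert len(pred) == 8
        assert all(taxid in ladder_tree for taxid in pred.values())

    def test_tree_report_contains_unclassified_line(self, big_tree, tmp_path):
        prof, _, _ = random_profile(big_tree, np.random.default_rng(6))
        path = tmp_path / "t.tsv"
        write_tree_report(prof, big_tree, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("taxid\t")
        assert lines[-1].startswith("unclassified\t")
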
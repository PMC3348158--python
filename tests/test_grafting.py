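"""MRCA grafting: attachment rules, escalation ladder, invariants."""

import numpy as np
import pandas as pd
import pytest

import divtime as dt
from divtime.chronogram_io import ChronogramError
from divtime.grafting import GraftRequest, LEVELS


def _table(rows):
    return dt.TaxonTable(pd.DataFrame(
        rows, columns=["species", "genus", "family", "order", "status"]
    ))


@pytest.fixture
def t1_genus_taxa():
    # A and B share a genus; C is the sole member of another
    return _table([
        ("A", "Ga", "Fa", "Oa", "native"),
        ("B", "Ga", "Fa", "Oa", "native"),
        ("C", "Gc", "Fa", "Oa", "native"),
    ])


class TestFindAttachment:
    def test_two_congeners_attach_at_their_mrca(self, t1, t1_genus_taxa):
        req = GraftRequest("X", "Ga", "Fa", "Oa")
        node = dt.find_attachment(t1, t1_genus_taxa, req, "two_congeners")
        assert node.age == 10.0

    def test_single_congener_attaches_at_its_parent(self, t1, t1_genus_taxa):
        req = GraftRequest("Y", "Gc", "Fa", "Oa")
        assert dt.find_attachment(t1, t1_genus_taxa, req, "two_congeners") is None
        node = dt.find_attachment(t1, t1_genus_taxa, req, "one_congener")
        assert node.age == 40.0  # parent of C is the root

    def test_family_attaches_at_family_mrca(self, t1, t1_genus_taxa):
        req = GraftRequest("Z", "Gz", "Fa", "Oa")
        node = dt.find_attachment(t1, t1_genus_taxa, req, "family")
        assert node.age == 40.0  # MRCA of A, B, C

    def test_absent_rank_returns_none(self, t1, t1_genus_taxa):
        req = GraftRequest("W", "Gw", "Fw", "Ow")
        for level in LEVELS:
            assert dt.find_attachment(t1, t1_genus_taxa, req, level) is None


class TestApplyGrafts:
    def test_graft_congener_makes_polytomy(self, t1, t1_genus_taxa):
        req = GraftRequest("X", "Ga", "Fa", "Oa")
        out, report = dt.apply_grafts(t1, t1_genus_taxa, [req])
        assert out.n_tips == 4
        node10 = [n for n in out.internal_nodes() if n.age == 10.0][0]
        assert len(node10.children) == 3
        assert dt.split_events(out).total_weight == 3
        p = report.placements[0]
        assert p.level == "two_congeners"
        assert p.branch_length == p.node_age == 10.0
        assert dt.validate_chronogram(out) == []
        assert t1.n_tips == 3  # input untouched

    def test_escalation_stops_at_first_success(self, t1, t1_genus_taxa):
        req = GraftRequest("X", "Ga", "Fa", "Oa")  # matches genus AND family
        _, report = dt.apply_grafts(t1, t1_genus_taxa, [req], escalation=LEVELS)
        assert report.placements[0].level == "two_congeners"

    def test_unplaceable_reported_not_fatal(self, t1, t1_genus_taxa):
        req = GraftRequest("W", "Gw", "Fw", "Ow")
        out, report = dt.apply_grafts(t1, t1_genus_taxa, [req])
        assert out.n_tips == 3
        assert report.placements[0].level == "unplaced"
        assert report.count_by_level()["unplaced"] == 1

    def test_duplicate_requests_rejected(self, t1, t1_genus_taxa):
        req = GraftRequest("X", "Ga", "Fa", "Oa")
        with pytest.raises(ChronogramError, match="duplicate"):
            dt.apply_grafts(t1, t1_genus_taxa, [req, req])

    def test_existing_label_rejected(self, t1, t1_genus_taxa):
        req = GraftRequest("A", "Ga", "Fa", "Oa")
        with pytest.raises(ChronogramError, match="already"):
            dt.apply_grafts(t1, t1_genus_taxa, [req])

    def test_backbone_policy_is_order_independent(self, random_tree):
        tree = random_tree(n_tips=40, seed=21)
        taxa = dt.assign_categories(tree, dt.LabelScheme(), seed=22)
        genera = taxa.frame["genus"].unique()
        requests = [
            GraftRequest(f"new_{i}", g, taxa.frame.loc[
                taxa.frame["genus"] == g, "family"].iloc[0], "Order00")
            for i, g in enumerate(genera[:6])
        ]
        fwd, _ = dt.apply_grafts(tree, taxa, requests)
        rev, _ = dt.apply_grafts(tree, taxa, requests[::-1])
        assert {t.label for t in fwd.tips()} == {t.label for t in rev.tips()}
        for label in (r.species for r in requests):
            ages_f = [n.age for n in fwd.preorder()
                      if any(c.label == label for c in n.children)]
            ages_r = [n.age for n in rev.preorder()
                      if any(c.label == label for c in n.children)]
            assert ages_f == ages_r

    @pytest.mark.parametrize("seed", range(25))
    def test_grafting_preserves_backbone(self, random_tree, seed):
        """Conservation: tip count grows by the number of placed requests,
        no pre-existing node age changes, the tree stays ultrametric, and
        pruning back to the backbone tips recovers the backbone."""
        tree = random_tree(n_tips=20, seed=seed)
        taxa = dt.assign_categories(tree, dt.LabelScheme(), seed=seed)
        rng = np.random.default_rng(seed)
        requests = []
        for i in range(rng.integers(1, 8)):
            if rng.random() < 0.7:  # taxonomy drawn from the backbone pool
                row = taxa.frame.iloc[rng.integers(len(taxa.frame))]
                requests.append(GraftRequest(
                    f"new_{i}", row["genus"], row["family"], row["order"]))
            else:  # unplaceable
                requests.append(GraftRequest(f"new_{i}", "Gx", "Fx", "Ox"))
        out, report = dt.apply_grafts(tree, taxa, requests)
        n_placed = len(report.placed())
        assert out.n_tips == tree.n_tips + n_placed
        before = sorted(n.age for n in tree.internal_nodes())
        after_backbone = dt.prune_to_taxa(out, tree.tip_labels())
        assert after_backbone == tree
        assert set(before) <= {n.age for n in out.internal_nodes()}
        assert dt.validate_chronogram(out) == []
        for p in report.placed():
            assert p.branch_length == p.node_age


class TestSeries:
    def test_all_level1_requests_give_identical_series(self, t1, t1_genus_taxa):
        requests = [GraftRequest("X", "Ga", "Fa", "Oa")]
        series = dt.chronogram_series(t1, t1_genus_taxa, requests)
        assert len(series) == 4
        trees = [s[0] for s in series]
        assert all(dt.write_chronogram(t) == dt.write_chronogram(trees[0])
                   for t in trees)

    def test_empty_requests_give_backbone_copies(self, t1, t1_genus_taxa):
        series = dt.chronogram_series(t1, t1_genus_taxa, [])
        for tree, report in series:
            assert tree == t1
            assert not report.placements

    def test_tip_counts_nondecreasing_with_coverage(self, random_tree):
        tree = random_tree(n_tips=50, seed=31)
        taxa = dt.assign_categories(tree, dt.LabelScheme(), seed=32)
        frame = taxa.frame
        rng = np.random.default_rng(33)
        requests = []
        # mix: congeners, confamilials with novel genus, co-ordinals with
        # novel family, and strangers -> strictly increasing coverage
        for i in range(40):
            row = frame.iloc[rng.integers(len(frame))]
            kind = i % 4
            if kind == 0:
                requests.append(GraftRequest(
                    f"n{i}", row["genus"], row["family"], row["order"]))
            elif kind == 1:
                requests.append(GraftRequest(
                    f"n{i}", f"NovelG{i}", row["family"], row["order"]))
            elif kind == 2:
                requests.append(GraftRequest(
                    f"n{i}", f"NovelG{i}", f"NovelF{i}", row["order"]))
            else:
                requests.append(GraftRequest(f"n{i}", "Gx", "Fx", "Ox"))
        series = dt.chronogram_series(tree, taxa, requests)
        counts = [t.n_tips for t, _ in series]
        assert counts == sorted(counts)
        assert counts[-1] > counts[0]
        for t, _ in series:
            assert dt.validate_chronogram(t) == []
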
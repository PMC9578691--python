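"""QC and CPM filters, neural/DV categorization, abundance, pseudo-bulk."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gastruquant import (
    CellSimParams,
    CellTable,
    RuleSet,
    classify_dv,
    classify_neural,
    cpm_filter,
    pseudo_bulk,
    qc_filter,
    relative_abundance,
    simulate_cell_table,
)


def table_from_dict(rows: dict[str, dict[str, int]], genes: list[str], meta=None) -> CellTable:
    counts = np.array([[rows[c].get(g, 0) for g in genes] for c in rows], dtype=np.int64)
    return CellTable(counts, genes, list(rows), cell_meta=meta)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

class TestQCFilter:
    @staticmethod
    def random_table(rng, n_cells=50, n_genes=400):
        # heavy-tailed counts so n_features spans the 200/2500 bounds
        counts = rng.poisson(rng.random((n_cells, n_genes)) * 3)
        genes = [f"mt-G{j}" if j < 5 else f"G{j}" for j in range(n_genes)]
        return CellTable(counts, genes, [f"c{i}" for i in range(n_cells)])

    def test_boundary_cells(self):
        genes = [f"G{j}" for j in range(3000)] + ["mt-Nd1"]
        counts = np.zeros((4, 3001), dtype=np.int64)
        counts[0, :150] = 1  # 150 features -> dropped
        counts[1, :200] = 1  # exactly 200 -> kept
        counts[2, :2500] = 1  # exactly 2500 -> kept
        counts[3, :300] = 1
        counts[3, -1] = 19  # mito fraction 19/319 ~ 6% -> dropped
        table = CellTable(counts, genes, list("abcd"))
        kept, report = qc_filter(table)
        assert kept.cell_ids == ["b", "c"]
        assert report.loc["a", "too_few_features"]
        assert report.loc["d", "high_mito"]

    def test_cell_inside_all_bounds_kept(self):
        genes = [f"G{j}" for j in range(400)] + ["mt-Nd1"]
        counts = np.zeros((1, 401), dtype=np.int64)
        counts[0, :300] = 1
        counts[0, -1] = 12  # 12/312 ~ 0.038 mito
        kept, _ = qc_filter(CellTable(counts, genes, ["x"]))
        assert kept.n_cells == 1

    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        table = self.random_table(rng)
        min_f, max_f, max_m = 200, 800, 0.05
        kept, _ = qc_filter(table, min_f, max_f, max_m)
        expected = []
        for i, cid in enumerate(table.cell_ids):  # independent per-cell scan
            row = table.counts[i]
            nf = int((row > 0).sum())
            total = row.sum()
            mito = row[[g.lower().startswith("mt-") for g in table.gene_names]].sum()
            frac = mito / total if total else 0.0
            if min_f <= nf <= max_f and frac <= max_m:
                expected.append(cid)
        assert kept.cell_ids == expected

    def test_empty_table_errors(self):
        table = CellTable(np.zeros((0, 3), dtype=int), ["a", "b", "c"], [])
        with pytest.raises(ValueError):
            qc_filter(table)


# ---------------------------------------------------------------------------
# CPM filter
# ---------------------------------------------------------------------------

class TestCPMFilter:
    def test_all_zero_gene_dropped(self):
        counts = pd.DataFrame({"g0": [0, 0], "g1": [10, 10]}, index=["s1", "s2"])
        assert cpm_filter(counts) == ["g1"]

    def test_exactly_threshold_cpm_dropped(self):
        # total 1e6 counts per sample so CPM == raw count: gene at exactly 0.4 CPM
        n_genes = 5
        counts = np.full((6, n_genes), (1e6 - 0.4 * 4) / (n_genes - 4))
        counts[:, :4] = 0.4
        got = cpm_filter(counts, min_cpm=0.4, min_samples=2, gene_names=list("abcde"))
        assert "a" not in got and "e" in got

    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(1.0, size=(6, 40)).astype(float) + (rng.random((6, 40)) < 0.05)
        counts[:, 0] += 1  # keep all sample totals positive
        names = [f"g{j}" for j in range(40)]
        got = cpm_filter(counts, gene_names=names)
        expected = []
        for j, g in enumerate(names):  # independent per-gene scan
            n_above = sum(
                counts[i, j] / counts[i].sum() * 1e6 > 0.4 for i in range(6)
            )
            if n_above >= 2:
                expected.append(g)
        assert got == expected

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame({"g0": [1, 0]}, index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            cpm_filter(counts)


# ---------------------------------------------------------------------------
# neural categorization
# ---------------------------------------------------------------------------

class TestClassifyNeural:
    def test_precedence_and_rules(self, tiny_rules):
        genes = (
            tiny_rules.hox_genes
            + tiny_rules.brain_markers
            + [tiny_rules.spinal_exclusion_gene, "other"]
        )
        cells = {
            # one Hox gene on plus all brain markers: Hox wins by precedence
            "hox_and_brain": {"Hoxa1": 3, **{g: 2 for g in tiny_rules.brain_markers}},
            "brain": {"Otx2": 1, "Six3": 1, "Foxg1": 2},
            "brain_but_fgfbp3": {"Otx2": 1, "Six3": 1, "Fgfbp3": 2},
            "too_few_brain": {"Otx2": 1},
            "all_zero": {},
        }
        table = table_from_dict(cells, genes)
        labels = classify_neural(table, tiny_rules)
        assert labels["hox_and_brain"] == "hox_positive"
        assert labels["brain"] == "brain_like"
        assert labels["brain_but_fgfbp3"] == "spinal_like"
        assert labels["too_few_brain"] == "spinal_like"
        assert labels["all_zero"] == "spinal_like"

    def test_every_cell_labeled_exactly_once(self, rules):
        table, _ = simulate_cell_table(CellSimParams(dropout_rate=0.3, seed=1), rules)
        labels = classify_neural(table, rules)
        assert len(labels) == table.n_cells
        assert set(labels) <= {"hox_positive", "brain_like", "spinal_like"}

    def test_expressed_threshold_configurable(self, tiny_rules):
        rules2 = RuleSet(
            hox_genes=tiny_rules.hox_genes,
            brain_markers=tiny_rules.brain_markers,
            brain_min_markers=2,
            dv_modules=tiny_rules.dv_modules,
            expressed_threshold=3,
        )
        table = table_from_dict(
            {"weak_hox": {"Hoxa1": 2}}, tiny_rules.hox_genes + tiny_rules.brain_markers + ["Fgfbp3"]
        )
        assert classify_neural(table, rules2)["weak_hox"] == "spinal_like"

    def test_unresolvable_gene_raises(self, tiny_rules):
        table = table_from_dict({"c": {}}, ["unrelated"])
        with pytest.raises(KeyError, match="hox_genes"):
            classify_neural(table, tiny_rules)


class TestClassifyDV:
    def test_exclusive_module_rules(self, tiny_rules):
        genes = ["Pax3", "Shh", "Nkx2-2", "Olig2", "other"]
        cells = {
            "ventral_only": {"Nkx2-2": 1},
            "ventral_both_genes": {"Nkx2-2": 1, "Olig2": 4},
            "dorsal_only": {"Pax3": 2},
            "ventral_and_dorsal": {"Nkx2-2": 1, "Pax3": 1},
            "nothing": {"other": 5},
        }
        labels = classify_dv(table_from_dict(cells, genes), tiny_rules)
        assert labels["ventral_only"] == "ventral"
        assert labels["ventral_both_genes"] == "ventral"
        assert labels["dorsal_only"] == "dorsal"
        assert labels["ventral_and_dorsal"] == "unassigned"
        assert labels["nothing"] == "unassigned"

    def test_assigned_plus_unassigned_partition(self, rules):
        table, _ = simulate_cell_table(CellSimParams(dropout_rate=0.2, seed=2), rules)
        labels = classify_dv(table, rules)
        n_assigned = (labels != "unassigned").sum()
        assert n_assigned + (labels == "unassigned").sum() == table.n_cells

    def test_overlapping_module_lists_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RuleSet(dv_modules={"dorsal": ["Pax3"], "ventral": ["Pax3"]})


class TestPlantedRecovery:
    def test_zero_dropout_recovers_all_planted_labels(self, rules):
        table, truth = simulate_cell_table(CellSimParams(dropout_rate=0.0, seed=0), rules)
        neural = classify_neural(table, rules)
        dv = classify_dv(table, rules)
        for cls in ("hox_positive", "brain_like", "spinal_like"):
            assert (neural[truth == cls] == cls).all()
        for cls in ("dorsal", "midline", "ventral"):
            assert (dv[truth == cls] == cls).all()

    def test_dropout_cannot_improve_accuracy(self, rules):
        def accuracy(dropout, seed):
            table, truth = simulate_cell_table(
                CellSimParams(dropout_rate=dropout, seed=seed), rules
            )
            neural = classify_neural(table, rules)
            dv = classify_dv(table, rules)
            mask_n = truth.isin(["hox_positive", "brain_like", "spinal_like"])
            mask_d = truth.isin(["dorsal", "midline", "ventral"])
            hits = (neural[mask_n] == truth[mask_n]).sum() + (dv[mask_d] == truth[mask_d]).sum()
            return hits / (mask_n.sum() + mask_d.sum())

        acc0 = np.mean([accuracy(0.0, s) for s in range(20)])
        acc3 = np.mean([accuracy(0.3, s) for s in range(20)])
        assert acc0 == 1.0
        assert acc0 >= acc3


# ---------------------------------------------------------------------------
# abundance and pseudo-bulk
# ---------------------------------------------------------------------------

class TestRelativeAbundance:
    def test_identical_proportions_give_zero(self):
        ann = pd.Series(["a"] * 10 + ["b"] * 10 + ["a"] * 10 + ["b"] * 10)
        cond = pd.Series(["ref"] * 20 + ["alt"] * 20)
        res = relative_abundance(ann, cond, "ref")
        np.testing.assert_allclose(res["log2_ratio"], 0.0)

    def test_twofold_enrichment_is_log2_one(self):
        ann = pd.Series(["a"] * 5 + ["b"] * 95 + ["a"] * 10 + ["b"] * 90)
        cond = pd.Series(["ref"] * 100 + ["alt"] * 100)
        res = relative_abundance(ann, cond, "ref")
        row = res[(res.state == "a") & (res.condition == "alt")].iloc[0]
        assert row.log2_ratio == pytest.approx(1.0)

    def test_low_count_states_excluded(self):
        ann = pd.Series(["rare"] * 9 + ["common"] * 91 + ["common"] * 100)
        cond = pd.Series(["ref"] * 100 + ["alt"] * 100)
        res = relative_abundance(ann, cond, "ref", min_cells=10)
        assert "rare" not in set(res.state)

    def test_one_sided_absence_flagged_infinite(self):
        ann = pd.Series(["only_alt"] * 12 + ["both"] * 50 + ["both"] * 50)
        cond = pd.Series(["alt"] * 62 + ["ref"] * 50)
        res = relative_abundance(ann, cond, "ref")
        row = res[res.state == "only_alt"].iloc[0]
        assert np.isinf(row.log2_ratio) and row.infinite

    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_proportions(self, seed):
        rng = np.random.default_rng(seed)
        states = rng.choice(["a", "b", "c"], size=120)
        conds = rng.choice(["ref", "x", "y"], size=120)
        res = relative_abundance(pd.Series(states), pd.Series(conds), "ref", min_cells=1)
        for _, row in res.iterrows():
            pc = np.mean(states[conds == row.condition] == row.state)
            pr = np.mean(states[conds == "ref"] == row.state)
            with np.errstate(divide="ignore"):
                assert row.log2_ratio == pytest.approx(np.log2(pc / pr), nan_ok=True)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(3)
        ann = pd.Series(rng.choice(["a", "b", "c"], size=100))
        cond = pd.Series(rng.choice(["ref", "alt"], size=100))
        r1 = relative_abundance(ann, cond, "ref", min_cells=1)
        r2 = relative_abundance(
            pd.concat([ann, ann], ignore_index=True),
            pd.concat([cond, cond], ignore_index=True),
            "ref",
            min_cells=1,
        )
        np.testing.assert_allclose(r1["log2_ratio"], r2["log2_ratio"])

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            relative_abundance(pd.Series(["a"]), pd.Series(["alt"]), "ref")


class TestPseudoBulk:
    def test_single_cell_group_equals_cell_values(self):
        meta = pd.DataFrame({"condition": ["x"]}, index=["c0"])
        table = CellTable(np.array([[2, 8]]), ["g0", "g1"], ["c0"], meta)
        out = pseudo_bulk(table, ["condition"], normalization="counts")
        np.testing.assert_allclose(out.loc["x"], [2.0, 8.0])

    def test_mean_of_two_cells(self):
        meta = pd.DataFrame({"condition": ["x", "x"]}, index=["c0", "c1"])
        table = CellTable(np.array([[2], [4]]), ["g0"], ["c0", "c1"], meta)
        out = pseudo_bulk(table, ["condition"], normalization="counts")
        assert out.loc["x", "g0"] == pytest.approx(3.0)

    def test_two_key_grouping_matches_brute_force(self):
        rng = np.random.default_rng(0)
        n = 40
        counts = rng.poisson(5, size=(n, 6))
        meta = pd.DataFrame(
            {
                "condition": rng.choice(["NN", "NH"], n),
                "annotation": rng.choice(["s1", "s2"], n),
            },
            index=[f"c{i}" for i in range(n)],
        )
        table = CellTable(counts, [f"g{j}" for j in range(6)], list(meta.index), meta)
        out = pseudo_bulk(table, ["condition", "annotation"], normalization="counts")
        for (cond, ann), row in out.iterrows():
            sel = (meta.condition == cond) & (meta.annotation == ann)
            np.testing.assert_allclose(row.to_numpy(), counts[sel.to_numpy()].mean(axis=0))

    def test_lognorm_scales_each_cell_to_ten_thousand(self):
        meta = pd.DataFrame({"condition": ["x"]}, index=["c0"])
        table = CellTable(np.array([[10, 30]]), ["g0", "g1"], ["c0"], meta)
        out = pseudo_bulk(table, ["condition"], normalization="lognorm")
        assert out.loc["x", "g0"] == pytest.approx(np.log1p(10 / 40 * 1e4))

    def test_unknown_group_key_errors(self):
        table = CellTable(np.array([[1]]), ["g0"], ["c0"])
        with pytest.raises(KeyError):
            pseudo_bulk(table, ["nope"])
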
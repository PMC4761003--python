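"""Welch's t-test, DataSet selection rules, and bundle I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shrnascan.errors import InsufficientReplicatesError, SchemaError
from shrnascan.expression import (
    ExpressionDataSet,
    filter_datasets,
    load_dataset,
    load_dataset_collection,
    significant_profiles,
    welch_t,
    write_dataset,
)
from shrnascan.simulate import FixtureSpec, generate_datasets


def _ds(ds_id="D1", organism="Homo sapiens", sizes=(3, 3), n_subsets=2, genes=("g1",), seed=0):
    rng = np.random.default_rng(seed)
    labels = [f"s{i}" for i in range(n_subsets)]
    subsets, cols = [], []
    for i, label in enumerate(labels):
        size = sizes[i] if i < len(sizes) else sizes[-1]
        ids = [f"{ds_id}_{label}_{j}" for j in range(size)]
        subsets.append((label, ids))
        cols.extend(ids)
    values = pd.DataFrame(rng.normal(0, 1, (len(genes), len(cols))), index=list(genes), columns=cols)
    return ExpressionDataSet(ds_id, organism, "agent", subsets, values)


class TestWelch:
    def test_identical_groups_are_null(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 3.5], [2.0, 4.0, 4.5, 5.0]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)
        assert r1.df == pytest.approx(r2.df)

    def test_matches_reference_routine(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            na, nb = rng.integers(2, 12), rng.integers(2, 12)
            a = rng.normal(0, rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nb)
            mine = welch_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert mine.df == pytest.approx(ref.df, abs=1e-10)

    def test_scale_invariance(self):
        a, b = [1.0, 2.0, 3.0, 2.5], [4.0, 5.0, 5.5]
        r1, r2 = welch_t(a, b), welch_t([x * 37.0 for x in a], [x * 37.0 for x in b])
        assert r1.t == pytest.approx(r2.t) and r1.p == pytest.approx(r2.p)

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            welch_t([1.0], [1.0, 2.0])

    def test_degenerate_conventions(self):
        equal = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (equal.t, equal.p, equal.degenerate) == (0.0, 1.0, True)
        apart = welch_t([2.0, 2.0], [5.0, 5.0])
        assert apart.p == 0.0 and math.isinf(apart.t) and apart.degenerate


class TestFilter:
    def test_rules(self):
        keep1 = _ds("K1")
        keep2 = _ds("K2", sizes=(5, 4))
        drops = [
            _ds("D_org", organism="Mus musculus"),
            _ds("D_three", n_subsets=3),
            _ds("D_small", sizes=(3, 2)),
        ]
        selected = filter_datasets([keep1, drops[0], keep2, drops[1], drops[2]], "Homo sapiens")
        assert [d.dataset_id for d in selected] == ["K1", "K2"]

    def test_threshold_is_parameterised(self):
        ds = _ds("D_small", sizes=(3, 2))
        permissive = filter_datasets([ds], "Homo sapiens", min_samples_per_subset=2)
        assert len(permissive) == 1 and permissive[0] is ds
        assert filter_datasets([ds], "Homo sapiens", min_samples_per_subset=3) == []

    def test_idempotent(self):
        sets = [_ds("A"), _ds("B", organism="Mus musculus"), _ds("C")]
        once = filter_datasets(sets, "Homo sapiens")
        twice = filter_datasets(once, "Homo sapiens")
        assert [d.dataset_id for d in twice] == [d.dataset_id for d in once] == ["A", "C"]

    def test_generated_violators_are_excluded_with_known_rule(self):
        spec = FixtureSpec(n_datasets=4, seed=2)
        datasets, truth = generate_datasets(spec, ["GENE1"])
        selected = filter_datasets(datasets, "Homo sapiens")
        expected = set(truth.loc[truth["passes"], "dataset_id"])
        assert {d.dataset_id for d in selected} == expected
        assert set(truth.loc[~truth["passes"], "failed_rule"]) == {
            "organism",
            "n_subsets",
            "min_samples",
        }


class TestSignificantProfiles:
    def test_planted_shift_is_detected_with_high_power(self):
        spec = FixtureSpec(n_datasets=20, samples_per_group=5, effect_size=3.0, seed=3)
        datasets, _ = generate_datasets(spec, ["HIT1"])
        selected = filter_datasets(datasets, "Homo sapiens")
        found = significant_profiles("HIT1", selected, alpha=0.01)
        # Welch power at delta=3 SD, n=5/group, alpha=0.01 is ~0.82;
        # 3-sigma floor for 20 datasets is ~11
        assert len(found) >= 11
        assert all(r.significant and r.p_value < 0.01 for r in found)
        assert all(r.source_url.startswith("https://") for r in found)

    def test_null_gene_flag_rate_is_near_alpha(self):
        spec = FixtureSpec(n_datasets=200, samples_per_group=5, effect_size=0.0,
                           n_background_genes=5, seed=4)
        datasets, _ = generate_datasets(spec, [])
        selected = filter_datasets(datasets, "Homo sapiens")
        hits = sum(len(significant_profiles(f"BG{i+1}", selected, 0.01)) for i in range(5))
        # 1000 null tests at alpha=0.01: expect ~10, 3-sigma band ~[1, 20]
        assert 0 <= hits <= 25

    def test_absent_gene_yields_empty_list(self):
        assert significant_profiles("NOPE", [_ds()], 0.01) == []


class TestBundleIO:
    def test_round_trip(self, tmp_path):
        ds = _ds("GDS_X", sizes=(3, 4), genes=("g1", "g2"))
        ds.source_url = "https://example.org/geo/GDS_X"
        write_dataset(ds, tmp_path / "GDS_X")
        back = load_dataset(tmp_path / "GDS_X")
        assert back.dataset_id == "GDS_X"
        assert back.subsets == ds.subsets
        assert back.source_url == ds.source_url
        pd.testing.assert_frame_equal(back.values, ds.values, check_names=False)

    def test_collection_loader_sorted(self, tmp_path):
        for name in ("B", "A"):
            write_dataset(_ds(name), tmp_path / name)
        assert [d.dataset_id for d in load_dataset_collection(tmp_path)] == ["A", "B"]

    def test_meta_schema_enforced(self, tmp_path):
        d = tmp_path / "bad"
        d.mkdir()
        (d / "matrix.tsv").write_text("gene\ts1\ng1\t1.0\n")
        (d / "meta.tsv").write_text("dataset_id\tbad\n")
        with pytest.raises(SchemaError, match="organism"):
            load_dataset(d)

    def test_subset_referencing_missing_sample_rejected(self):
        with pytest.raises(SchemaError, match="missing"):
            ExpressionDataSet(
                "X", "Homo sapiens", "agent",
                subsets=[("a", ["s1"]), ("b", ["ghost"])],
                values=pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"]),
            )
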
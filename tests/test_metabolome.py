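"""Metabolite preprocessing, PLS-DA/VIP, module detection, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from guildomics.containers import MetaboliteTable
from guildomics.metabolome import (
    detect_modules,
    pathway_enrichment,
    plsda_fit,
    preprocess,
    select_differential_metabolites,
)


def _met_table(matrix, samples=None, mets=None, compartment="fecal", **kw):
    matrix = np.asarray(matrix, dtype=float)
    samples = samples or [f"s{i}" for i in range(matrix.shape[0])]
    mets = mets or [f"m{j}" for j in range(matrix.shape[1])]
    return MetaboliteTable(pd.DataFrame(matrix, index=samples, columns=mets),
                           compartment=compartment, **kw)


class TestPreprocess:
    def test_hand_computed_log_scale(self):
        t = _met_table([[10.0, 100.0], [100.0, 10000.0], [1000.0, 1000000.0]])
        out = preprocess(t)
        # log10 -> columns (1,2,3) and (2,4,6); autoscale to mean 0 sd 1
        expected = (np.array([[1, 2], [2, 4], [3, 6]], dtype=float)
                    - [2, 4]) / [1.0, 2.0]
        assert np.allclose(out.data.to_numpy(), expected)
        assert out.processed

    def test_constant_metabolite_dropped(self):
        t = _met_table([[10.0, 5.0], [100.0, 5.0], [1000.0, 5.0]])
        out = preprocess(t)
        assert list(out.metabolite_ids) == ["m0"]
        assert out.transform["dropped_constant"] == ["m1"]

    def test_half_minimum_imputation(self):
        t = _met_table([[10.0, 0.0], [100.0, 8.0], [1000.0, 2.0]])
        out = preprocess(t)
        # missing entry became min/2 = 1.0 -> log10 = 0, then scaled; check
        # by reconstructing the imputed column
        col = np.log10([1.0, 8.0, 2.0])
        expected = (col - col.mean()) / col.std(ddof=1)
        assert np.allclose(out.data["m1"].to_numpy(), expected)

    def test_double_preprocess_errors(self):
        t = _met_table(np.abs(np.random.default_rng(0).lognormal(size=(5, 3))))
        out = preprocess(t)
        with pytest.raises(ValueError, match="already"):
            preprocess(out)

    def test_all_missing_dropped(self):
        t = _met_table([[10.0, 0.0], [12.0, 0.0], [20.0, 0.0]])
        out = preprocess(t)
        assert "m1" not in out.metabolite_ids
        assert out.transform["dropped_all_missing"] == ["m1"]


def _labeled_data(rng, n=60, p=40, shift=0.0, n_shifted=0):
    y = pd.Series(["case"] * (n // 2) + ["ctrl"] * (n // 2),
                  index=[f"s{i}" for i in range(n)])
    x = rng.lognormal(3.0, 0.3, size=(n, p))
    x[: n // 2, :n_shifted] *= np.exp(shift)
    t = _met_table(x, samples=list(y.index))
    return t, y


class TestPlsda:
    def test_vip_normalization_identity(self, rng):
        t, y = _labeled_data(rng, shift=0.5, n_shifted=5)
        model = plsda_fit(preprocess(t), y, n_perm=10, seed=0)
        assert (model.vip ** 2).mean() == pytest.approx(1.0, abs=1e-6)

    def test_null_labels_q2_low(self, rng):
        t, y = _labeled_data(rng)
        model = plsda_fit(preprocess(t), y, n_perm=30, seed=0)
        assert model.q2 <= 0.05
        assert np.median(model.perm_q2) >= model.q2 - 0.15

    def test_separating_metabolite_attains_max_vip(self, rng):
        t, y = _labeled_data(rng)
        data = t.data.copy()
        data["m0"] = np.where(y == "case", 1000.0, 10.0) * rng.lognormal(0, 0.05, len(y))
        t2 = _met_table(data.to_numpy(), samples=list(data.index),
                        mets=list(data.columns))
        model = plsda_fit(preprocess(t2), y, n_perm=5, seed=0)
        assert model.vip.idxmax() == "m0"
        assert model.vip["m0"] > 1.0

    def test_q2_drops_under_permutation_with_signal(self, rng):
        t, y = _labeled_data(rng, shift=1.0, n_shifted=10)
        model = plsda_fit(preprocess(t), y, n_perm=30, seed=1)
        assert model.q2 > np.median(model.perm_q2)

    def test_single_class_errors(self, rng):
        t, y = _labeled_data(rng)
        with pytest.raises(ValueError):
            plsda_fit(preprocess(t), pd.Series("case", index=y.index), n_perm=5)


class TestSelection:
    def test_planted_elevated_metabolite_selected(self, rng):
        t, y = _labeled_data(rng, shift=np.log(2), n_shifted=3)
        model = plsda_fit(preprocess(t), y, n_perm=5, seed=0)
        sel = select_differential_metabolites(model, t, y, "case", "ctrl")
        assert sel.loc["m0", "selected"]
        assert sel.loc["m0", "direction"] == "elevated"
        assert sel.loc["m0", "fold_change"] == pytest.approx(2.0, rel=0.2)

    def test_vip_boundary_strict(self, rng):
        t, y = _labeled_data(rng, shift=0.5, n_shifted=5)
        model = plsda_fit(preprocess(t), y, n_perm=5, seed=0)
        model.vip.iloc[:] = 1.0  # exactly at the threshold
        sel = select_differential_metabolites(model, t, y, "case", "ctrl")
        assert not sel["selected"].any()

    def test_null_selection_rate_small(self, rng):
        t, y = _labeled_data(rng)
        model = plsda_fit(preprocess(t), y, n_perm=5, seed=0)
        sel = select_differential_metabolites(model, t, y, "case", "ctrl")
        assert sel["selected"].mean() < 0.05


class TestModules:
    def _block_table(self, rng, n=80, sizes=(15, 15), noise=0.4):
        cols = []
        names = []
        for b, size in enumerate(sizes):
            latent = rng.normal(size=n)
            for j in range(size):
                cols.append(0.9 * latent + noise * rng.normal(size=n))
                names.append(f"b{b}_m{j}")
        x = 10 ** (np.array(cols).T * 0.3 + 4.0)
        return _met_table(x, mets=names)

    def test_two_block_recovery(self, rng):
        t = self._block_table(rng)
        mods = detect_modules(preprocess(t), min_module_size=5)
        truth = [n.split("_")[0] for n in mods.labels.index]
        assert adjusted_rand_score(truth, mods.labels) == 1.0
        assert mods.n_modules == 2

    def test_eigenmetabolite_sign_equivariance(self, rng):
        t = self._block_table(rng)
        pre = preprocess(t)
        mods = detect_modules(pre, min_module_size=5)
        flipped = MetaboliteTable(-pre.data, compartment=pre.compartment,
                                  transform=dict(pre.transform))
        mods2 = detect_modules(flipped, min_module_size=5)
        for m in mods.eigenmetabolites.columns:
            r = np.corrcoef(mods.eigenmetabolites[m], mods2.eigenmetabolites[m])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_metabolite_order_invariance(self, rng):
        t = self._block_table(rng)
        pre = preprocess(t)
        mods1 = detect_modules(pre, min_module_size=5)
        order = list(rng.permutation(pre.data.columns))
        pre2 = MetaboliteTable(pre.data[order], compartment="fecal",
                               transform=dict(pre.transform))
        mods2 = detect_modules(pre2, min_module_size=5)
        assert adjusted_rand_score(mods1.labels.sort_index(),
                                   mods2.labels.sort_index()) == 1.0

    def test_eigenmetabolite_maximizes_explained_variance(self, rng):
        t = self._block_table(rng, sizes=(20,))
        pre = preprocess(t)
        mods = detect_modules(pre, min_module_size=5)
        members = mods.labels.index[mods.labels == 1]
        sub = pre.data[members].to_numpy()
        sub = (sub - sub.mean(0)) / sub.std(0, ddof=1)
        eig = mods.eigenmetabolites["M1"].to_numpy()
        var_eig = np.var(sub @ (sub.T @ eig) / np.linalg.norm(sub.T @ eig))
        for _ in range(1000):
            w = rng.normal(size=sub.shape[1])
            w /= np.linalg.norm(w)
            assert np.var(sub @ w) <= var_eig + 1e-8

    def test_module_recovery_on_default_cohort(self, default_cohort):
        """Planted metabolite modules are recovered (ARI >= 0.8) and each
        eigen-metabolite tracks its planted latent (|cor| >= 0.9)."""
        for comp in ("fecal", "serum"):
            raw = getattr(default_cohort, comp)
            pre = preprocess(raw)
            mods = detect_modules(pre)
            planted = default_cohort.truth.module_labels[comp].loc[mods.labels.index]
            assert adjusted_rand_score(planted, mods.labels) >= 0.8
            latents = default_cohort.truth.module_latents[comp]
            for m in mods.eigenmetabolites.columns:
                members = mods.labels.index[mods.labels == int(m[1:])]
                maj = planted.loc[members].mode()[0]
                if maj == 0:
                    continue
                r = np.corrcoef(
                    mods.eigenmetabolites[m],
                    latents.loc[mods.eigenmetabolites.index, f"M{maj}"],
                )[0, 1]
                assert abs(r) >= 0.9


def _exhaustive_enrichment_p(universe_n, pathway, selected):
    """Oracle: exact upper-tail overlap probability by enumerating all
    selected-set draws of the same size from the universe."""
    universe = list(range(universe_n))
    k_obs = len(set(pathway) & set(selected))
    hits = total = 0
    for draw in itertools.combinations(universe, len(selected)):
        total += 1
        if len(set(draw) & set(pathway)) >= k_obs:
            hits += 1
    return hits / total


class TestEnrichment:
    def _annotation(self, mapping):
        return pd.Series(mapping, name="pathway")

    def test_exact_hypergeometric_value(self):
        # universe 10, pathway 4, selected 5, overlap 4 -> 6/252
        universe = [f"m{i}" for i in range(10)]
        ann = self._annotation({f"m{i}": ("pw" if i < 4 else "other")
                                for i in range(10)})
        selected = [f"m{i}" for i in range(4)] + ["m9"]
        res = pathway_enrichment(selected, ann, universe)
        assert res.loc["pw", "p"] == pytest.approx(6 / 252)
        assert res.loc["pw", "rich_factor"] == 1.0

    def test_zero_overlap_p_is_one(self):
        universe = [f"m{i}" for i in range(8)]
        ann = self._annotation({f"m{i}": ("pw" if i < 3 else "other")
                                for i in range(8)})
        res = pathway_enrichment(["m5", "m6"], ann, universe)
        assert res.loc["pw", "p"] == pytest.approx(1.0)

    def test_saturation(self):
        universe = [f"m{i}" for i in range(6)]
        ann = self._annotation({f"m{i}": f"pw{i % 2}" for i in range(6)})
        res = pathway_enrichment(universe, ann, universe)
        assert np.allclose(res["p"], 1.0)
        assert (res["hits"] == res["pathway_size"]).all()

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            n_u = int(rng.integers(8, 13))
            universe = [f"m{i}" for i in range(n_u)]
            pw_size = int(rng.integers(2, 6))
            ann = self._annotation({f"m{i}": ("pw" if i < pw_size else "bg")
                                    for i in range(n_u)})
            sel_n = int(rng.integers(2, 6))
            selected = list(rng.choice(universe, size=sel_n, replace=False))
            res = pathway_enrichment(selected, ann, universe)
            oracle = _exhaustive_enrichment_p(
                n_u, list(range(pw_size)),
                [int(s[1:]) for s in selected],
            )
            assert res.loc["pw", "p"] == pytest.approx(oracle, abs=1e-10)

    def test_empty_selection_noted(self):
        universe = ["m0", "m1"]
        ann = self._annotation({"m0": "pw", "m1": "pw"})
        res = pathway_enrichment([], ann, universe)
        assert len(res) == 0
        assert res.attrs["note"] == "empty selected set"

    def test_planted_pathways_enriched_on_default_cohort(self, default_cohort):
        c = default_cohort
        ann = c.annotation["fecal"]
        diff = [m for m, mod in c.truth.module_labels["fecal"].items()
                if mod in c.truth.disease_modules["fecal"]]
        res = pathway_enrichment(diff, ann, list(c.fecal.metabolite_ids))
        hits = res[res["p"] < 0.05].index
        assert set(c.truth.enriched_pathways["fecal"]) <= set(hits)
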
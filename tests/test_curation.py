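import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from betamarkers.curation import (
    CuratedPanel,
    curate_panel,
    remove_alpha_markers,
    remove_exocrine_markers,
    two_group_test,
)
from betamarkers.io import OrthologMap

from conftest import make_matrix


def two_tissue_matrix(group_a_rows, group_b_rows, a="alpha", b="beta"):
    """Rows are per-probe replicate triples for each group."""
    n = len(group_a_rows)
    cols = {}
    for r in range(3):
        cols[f"{a}.{r + 1}"] = [row[r] for row in group_a_rows]
        cols[f"{b}.{r + 1}"] = [row[r] for row in group_b_rows]
    return make_matrix(cols, probes=[f"p{i}" for i in range(n)])


class TestTwoGroupTest:
    def test_identical_groups(self):
        m = two_tissue_matrix([(8, 9, 10)], [(8, 9, 10)])
        res = two_group_test(m, "alpha", "beta")
        assert res.loc["p0", "fold_change"] == pytest.approx(1.0)
        assert res.loc["p0", "p_value"] == pytest.approx(1.0)
        assert res.loc["p0", "direction"] == "up"

    def test_exact_twofold_zero_variance(self):
        m = two_tissue_matrix([(8, 8, 8)], [(4, 4, 4)])
        res = two_group_test(m, "alpha", "beta")
        assert res.loc["p0", "fold_change"] == pytest.approx(2.0)
        assert res.loc["p0", "lcb"] == pytest.approx(2.0)
        assert res.loc["p0", "p_value"] == 1e-300

    def test_single_replicate_rejected(self):
        cols = {"alpha.1": [1.0], "beta.1": [1.0], "beta.2": [2.0]}
        m = make_matrix(cols, probes=["p0"])
        with pytest.raises(ValueError):
            two_group_test(m, "alpha", "beta")

    def test_welch_and_lcb_match_direct_formula(self):
        rng = np.random.default_rng(7)
        a_rows = rng.lognormal(4, 1, size=(200, 3))
        b_rows = rng.lognormal(4, 1, size=(200, 3))
        m = two_tissue_matrix([tuple(r) for r in a_rows], [tuple(r) for r in b_rows])
        res = two_group_test(m, "alpha", "beta", lcb_confidence=0.90, floor=1.0)
        for i in range(200):
            la = [math.log2(max(v, 1.0)) for v in a_rows[i]]
            lb = [math.log2(max(v, 1.0)) for v in b_rows[i]]
            ma, mb = np.mean(la), np.mean(lb)
            va, vb = np.var(la, ddof=1), np.var(lb, ddof=1)
            se2 = va / 3 + vb / 3
            t = (ma - mb) / math.sqrt(se2)
            df = se2**2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
            p = 2 * stats.t.sf(abs(t), df)
            lcb = 2 ** ((ma - mb) - stats.t.ppf(0.90, df) * math.sqrt(se2))
            probe = f"p{i}"
            assert res.loc[probe, "p_value"] == pytest.approx(p, abs=1e-10)
            assert res.loc[probe, "lcb"] == pytest.approx(lcb, rel=1e-10)
            assert res.loc[probe, "fold_change"] == pytest.approx(2 ** (ma - mb), rel=1e-10)

    def test_lcb_below_fold_when_fold_above_one(self):
        rng = np.random.default_rng(8)
        a_rows = rng.lognormal(5, 0.5, size=(50, 3))
        b_rows = rng.lognormal(4, 0.5, size=(50, 3))
        m = two_tissue_matrix([tuple(r) for r in a_rows], [tuple(r) for r in b_rows])
        res = two_group_test(m, "alpha", "beta")
        up = res[res["fold_change"] >= 1.0]
        assert (up["lcb"] <= up["fold_change"] + 1e-12).all()


def _omap(genes, species="rat"):
    rows = [(g, species, f"{g}_probe") for g in genes]
    return OrthologMap(pd.DataFrame(rows, columns=["gene", "species", "probe_id"]))


class TestAlphaRemoval:
    def _results(self, mapping):
        return pd.DataFrame(
            {
                "fold_change": [fc for fc, _ in mapping.values()],
                "p_value": [p for _, p in mapping.values()],
                "lcb": 1.0,
                "direction": "up",
            },
            index=list(mapping.keys()),
        )

    def test_planted_contaminants_removed(self):
        genes = ["gA", "gB", "gC"]
        res = self._results({"gA_probe": (2.0, 1e-6), "gB_probe": (1.0, 0.9),
                             "gC_probe": (1.6, 0.01)})
        retained, removed, untested = remove_alpha_markers(genes, res, _omap(genes), "rat")
        assert removed == ["gA", "gC"]
        assert retained == ["gB"]
        assert untested == []

    def test_no_contaminants_identity(self):
        genes = ["gA", "gB"]
        res = self._results({"gA_probe": (1.1, 0.5), "gB_probe": (0.7, 0.01)})
        retained, removed, _ = remove_alpha_markers(genes, res, _omap(genes), "rat")
        assert retained == genes and removed == []

    def test_untested_gene_retained_and_flagged(self):
        genes = ["gA", "missing"]
        res = self._results({"gA_probe": (1.0, 0.9)})
        retained, removed, untested = remove_alpha_markers(genes, res, _omap(["gA"]), "rat")
        assert "missing" in retained and untested == ["missing"]


def human_matrix(rows):
    """rows: gene -> (pancreas, islets, beta, duct) means; zero variance."""
    cols = {}
    for t_idx, tissue in enumerate(("pancreas", "islets", "beta", "duct")):
        for r in (1, 2, 3):
            cols[f"{tissue}.{r}"] = [v[t_idx] for v in rows.values()]
    return make_matrix(cols, probes=[f"{g}_probe" for g in rows], species="human")


class TestExocrineRemoval:
    def test_gradient_gene_removed_as_acinar(self):
        rows = {"gAcinar": (160.0, 40.0, 10.0, 10.0), "gBeta": (1.0, 1.0, 100.0, 1.0)}
        m = human_matrix(rows)
        retained, duct, acinar, _ = remove_exocrine_markers(
            list(rows), m, _omap(list(rows), "human"), species="human")
        assert acinar == ["gAcinar"]
        assert retained == ["gBeta"]

    def test_duct_dominant_gene_removed_as_duct(self):
        rows = {"gDuct": (1.0, 1.0, 2.0, 50.0), "gBeta": (1.0, 1.0, 100.0, 1.0)}
        m = human_matrix(rows)
        retained, duct, acinar, _ = remove_exocrine_markers(
            list(rows), m, _omap(list(rows), "human"), species="human")
        assert duct == ["gDuct"] and acinar == []
        assert retained == ["gBeta"]

    def test_missing_pancreas_is_error(self):
        cols = {f"beta.{r}": [1.0] for r in (1, 2, 3)}
        cols.update({f"islets.{r}": [1.0] for r in (1, 2, 3)})
        m = make_matrix(cols, probes=["p0"], species="human")
        with pytest.raises(ValueError):
            remove_exocrine_markers(["g"], m, _omap(["g"], "human"), species="human")

    def test_missing_duct_skips_duct_removal_with_warning(self):
        rows = {"gBeta": (1.0, 1.0, 100.0)}
        cols = {}
        for t_idx, tissue in enumerate(("pancreas", "islets", "beta")):
            for r in (1, 2, 3):
                cols[f"{tissue}.{r}"] = [rows["gBeta"][t_idx]]
        m = make_matrix(cols, probes=["gBeta_probe"], species="human")
        retained, duct, acinar, warnings = remove_exocrine_markers(
            ["gBeta"], m, _omap(["gBeta"], "human"), species="human")
        assert warnings and duct == []


@pytest.fixture(scope="module")
def curated(default_atlas):
    mats, omap, truth = default_atlas
    conserved = sorted(truth.genes.index[truth.genes["conserved"]])
    panel = curate_panel(conserved, mats["rat"], mats["human"], omap)
    return conserved, panel, truth


class TestCurationInvariants:
    def test_partition(self, curated):
        conserved, panel, _ = curated
        all_out = (panel.retained + panel.removed_alpha
                   + panel.removed_duct + panel.removed_acinar)
        assert sorted(all_out) == sorted(conserved)
        assert len(set(all_out)) == len(all_out)  # pairwise disjoint

    def test_idempotence(self, curated, default_atlas):
        _, panel, _ = curated
        mats, omap, _ = default_atlas
        again = curate_panel(panel.retained, mats["rat"], mats["human"], omap)
        assert again.retained == panel.retained
        assert not (again.removed_alpha or again.removed_duct or again.removed_acinar)

    def test_planted_contaminants_removed_markers_kept(self, curated):
        conserved, panel, truth = curated
        removed = set(panel.removed_alpha + panel.removed_acinar + panel.removed_duct)
        contaminants = {
            g for g in conserved
            if truth.class_of(g) in ("alpha_contaminant", "acinar_contaminant")
        }
        markers = {
            g for g in conserved
            if truth.class_of(g) in ("beta_selective", "neuro_shared", "immune_gut_shared")
        }
        assert len(removed & contaminants) / len(contaminants) >= 0.95
        assert len(removed & markers) / len(markers) <= 0.05
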
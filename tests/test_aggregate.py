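"""Category backfill, tallies, Venn intersections, PCA QC, treemap export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import subproteo as sp
from subproteo.aggregate import read_treemap, write_treemap


# --- backfill -------------------------------------------------------------


def test_backfill_repeats_deepest_label():
    out = sp.backfill_category_levels({"p1": [("Metabolism", "Carbon")]})
    assert out["p1"] == [("Metabolism", "Carbon", "Carbon", "Carbon")]


def test_backfill_full_path_unchanged():
    path = ("a", "b", "c", "d")
    assert sp.backfill_category_levels({"p": [path]})["p"] == [path]


def test_backfill_empty_path_unannotated():
    assert sp.backfill_category_levels({"p": [()]}) == {}


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.lists(st.sampled_from("abcdef"), min_size=1, max_size=4).map(tuple),
        min_size=1,
        max_size=3,
    )
)
def test_backfill_always_four_levels(paths):
    out = sp.backfill_category_levels({"p": paths})
    for path in out.get("p", []):
        assert len(path) == 4


# --- tallies --------------------------------------------------------------


def _classed_frame(rows):
    df = pd.DataFrame(rows, columns=["strain", "fraction", "protein", "class"])
    df["difference"] = np.where(
        df["class"] == "up", 1.0, np.where(df["class"] == "down", -1.0, np.nan)
    )
    return df


def test_tally_hand_counted():
    classed = _classed_frame(
        [
            ("168", "cytosolic", "p1", "up"),
            ("168", "cytosolic", "p2", "down"),
            ("168", "cytosolic", "p3", "unchanged"),
            ("168", "cytosolic", "p4", "ON"),
            ("168", "cytosolic", "p5", "unchanged"),
        ]
    )
    maps = sp.AnnotationMaps(
        categories={
            "p1": [("Metabolism",)],
            "p2": [("Metabolism",)],
            "p3": [("Metabolism",)],
            "p4": [("Info",)],
        }
    )
    tally = sp.tally_by_group(classed, maps, level=1)
    t = tally.set_index("group")
    assert t.loc["Metabolism", ["up", "down", "unchanged"]].tolist() == [1, 1, 1]
    assert t.loc["Info", "ON"] == 1
    assert t.loc["unannotated", "unchanged"] == 1
    assert t.loc["Metabolism", "frac_significant"] == pytest.approx(2 / 3)


def test_tally_empty_table():
    tally = sp.tally_by_group(
        _classed_frame([]), sp.AnnotationMaps(categories={"p": [("a",)]})
    )
    assert tally.empty


def test_multi_regulon_protein_counts_in_each():
    classed = _classed_frame([("168", "cytosolic", "p1", "up")])
    maps = sp.AnnotationMaps(
        regulons={"p1": [("SigB", "activation"), ("Spx", "repression")]}
    )
    tally = sp.tally_by_group(classed, maps, grouping="regulon")
    assert tally.set_index("group").loc[["SigB", "Spx"], "up"].tolist() == [1, 1]


def test_tally_incidence_conservation(small_dataset, small_pipeline):
    """Class counts per group sum to the (protein, group) incidences."""
    _, _, maps, _ = small_dataset
    _, _, classed = small_pipeline
    tally = sp.tally_by_group(classed, maps, level=2)
    groups = {
        p: sorted({path[1] for path in paths})
        for p, paths in sp.backfill_category_levels(maps.categories).items()
    }
    expected = 0
    for (strain, protein), _ in classed.groupby(["strain", "protein"]):
        expected += len(groups.get(protein, ["unannotated"]))
    assert tally["n"].sum() == expected


# --- Venn / core proteome -------------------------------------------------


def test_core_identical_sets():
    s = {"a", "b", "c"}
    venn = sp.core_proteome({f"s{i}": set(s) for i in range(4)})
    assert venn.core == 3
    assert venn.regions["s0&s1&s2&s3"] == 3
    assert sum(v for k, v in venn.regions.items() if k != "s0&s1&s2&s3") == 0


def test_core_disjoint_sets():
    venn = sp.core_proteome({f"s{i}": {f"x{i}"} for i in range(4)})
    assert venn.core == 0
    assert venn.union == 4


def test_venn_regions_match_bruteforce(rng):
    sets = {
        f"s{i}": {f"p{j}" for j in rng.choice(60, size=30, replace=False)}
        for i in range(4)
    }
    venn = sp.core_proteome(sets)
    # oracle: classify every protein by its exact membership pattern
    patterns = {}
    for p in set().union(*sets.values()):
        key = "&".join(k for k in sets if p in sets[k])
        patterns[key] = patterns.get(key, 0) + 1
    for region, count in venn.regions.items():
        assert count == patterns.get(region, 0)
    assert sum(venn.regions.values()) == venn.union


# --- total altered --------------------------------------------------------


def test_total_altered_counts():
    classed = _classed_frame(
        [
            ("168", "cytosolic", "p1", "up"),
            ("168", "cytosolic", "p2", "up"),
            ("168", "cytosolic", "p3", "down"),
            ("168", "cytosolic", "p4", "ON"),
            ("168", "cytosolic", "p5", "unchanged"),
        ]
    )
    assert sp.total_altered(classed) == {"168": 4}


def test_total_altered_deduplicates_across_fractions():
    classed = _classed_frame(
        [
            ("168", "cytosolic", "p1", "up"),
            ("168", "membrane", "p1", "up"),
        ]
    )
    assert sp.total_altered(classed) == {"168": 1}
    assert sp.total_altered(classed, per_fraction=True) == {
        ("168", "cytosolic"): 1,
        ("168", "membrane"): 1,
    }


def test_total_altered_row_order_invariant(small_pipeline, rng):
    _, _, classed = small_pipeline
    shuffled = classed.sample(frac=1, random_state=0).reset_index(drop=True)
    assert sp.total_altered(classed) == sp.total_altered(shuffled)


# --- PCA QC ---------------------------------------------------------------


def test_pca_separates_conditions():
    cfg = sp.SimConfig(
        n_proteins=300, frac_up=0.25, frac_down=0.25, frac_on=0, frac_off=0,
        effect_log2=3.0, detect_midpoint=-np.inf, strains=("168",), seed=21,
    )
    table, _, _ = sp.generate_quant_dataset(cfg)
    res = sp.pca_qc(sp.log_transform(table), "168", "cytosolic")
    assert res.separated
    cent = res.coordinates.groupby("condition")[["PC1"]].mean()
    within = res.coordinates.groupby("condition")["PC1"].std().mean()
    assert abs(cent.iloc[0, 0] - cent.iloc[1, 0]) > within


def test_pca_protein_order_invariance():
    cfg = sp.SimConfig(n_proteins=100, detect_midpoint=-np.inf, strains=("168",), seed=22)
    table, _, _ = sp.generate_quant_dataset(cfg)
    log2 = sp.log_transform(table)
    r1 = sp.pca_qc(log2, "168", "cytosolic")
    shuffled = log2.sample(frac=1, random_state=1).reset_index(drop=True)
    shuffled.attrs["is_log2"] = True
    r2 = sp.pca_qc(shuffled, "168", "cytosolic")
    # components are defined up to sign
    assert np.allclose(
        np.abs(r1.coordinates[["PC1", "PC2"]].to_numpy()),
        np.abs(r2.coordinates[["PC1", "PC2"]].to_numpy()),
        atol=1e-8,
    )


def test_pca_degenerate_identical_replicates():
    rows = []
    for cond in ("control", "induced"):
        for rep in (1, 2, 3):
            for p in range(10):
                rows.append((f"p{p}", "168", cond, "cytosolic", rep, 20.0, 3))
    table = pd.DataFrame(
        rows,
        columns=[
            "protein", "strain", "condition", "fraction", "replicate",
            "intensity", "unique_peptides",
        ],
    )
    table.attrs["is_log2"] = True
    res = sp.pca_qc(table, "168")
    assert res.degenerate
    assert all(e["degenerate"] for e in res.ellipses.values())


def test_pca_too_few_samples_rejected():
    table = pd.DataFrame(
        [("p1", "168", "control", "cytosolic", 1, 20.0, 3)],
        columns=[
            "protein", "strain", "condition", "fraction", "replicate",
            "intensity", "unique_peptides",
        ],
    )
    table.attrs["is_log2"] = True
    with pytest.raises(ValueError):
        sp.pca_qc(table, "168")


# --- treemap --------------------------------------------------------------


def _leaf_count(node):
    if "children" not in node:
        return 1
    return sum(_leaf_count(c) for c in node["children"])


def _check_weights(node):
    if "children" in node:
        assert node["weight"] == sum(c["weight"] for c in node["children"])
        for c in node["children"]:
            _check_weights(c)


def test_treemap_weights_and_sentinels(small_dataset, small_pipeline):
    _, _, maps, _ = small_dataset
    _, _, classed = small_pipeline
    tree = sp.treemap_export(classed, maps, "168")
    _check_weights(tree)
    assert tree["weight"] == _leaf_count(tree)

    def _colors(node, acc):
        if "children" in node:
            for c in node["children"]:
                _colors(c, acc)
        else:
            acc.setdefault(node["status"], set()).add(node["color"])
        return acc

    colors = _colors(tree, {})
    if "ON" in colors:
        assert colors["ON"] == {"#cc5500"}
    if "OFF" in colors:
        assert colors["OFF"] == {"#00868b"}


def test_treemap_zero_differences_midpoint_color():
    classed = _classed_frame([("168", "cytosolic", "p1", "unchanged")])
    classed["difference"] = 0.0
    maps = sp.AnnotationMaps(categories={"p1": [("Metabolism",)]})
    tree = sp.treemap_export(classed, maps, "168")
    node = tree
    while "children" in node:
        node = node["children"][0]
    assert node["color"] == "#ffffff"


def test_treemap_roundtrip(tmp_path, small_dataset, small_pipeline):
    _, _, maps, _ = small_dataset
    _, _, classed = small_pipeline
    tree = sp.treemap_export(classed, maps, "midi", grouping="regulon")
    write_treemap(tree, tmp_path / "tree.json")
    assert read_treemap(tmp_path / "tree.json") == tree
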
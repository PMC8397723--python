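"""Hit filtering, pathway calling, subspecies partitioning and subgrouping."""

import numpy as np
import pandas as pd
import pytest

from scfaphase.cohort import GENE_COLUMNS, SCFA_COLUMNS
from scfaphase.genotypes import (
    PathwayDefinition,
    assign_subgroups,
    assign_top_genome,
    call_butyrate_pathways,
    filter_hits,
    load_pathway_definitions,
    producer_abundance,
    subgroup_scfa_compare,
    subspecies_partition,
)


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["query", "subject", "pident", "evalue",
                                       "bitscore", "phylotype", "gene", "pathway"])


def random_hits(rng, n=200):
    return hits_frame([
        (f"q{i%20}", f"g{rng.integers(5)}", rng.uniform(40, 100),
         10.0 ** rng.uniform(-30, 0), rng.uniform(50, 900),
         f"p{i%20}", rng.choice(["thl", "bhbd", "cro", "bcd", "but", "buk"]),
         "acetyl-CoA")
        for i in range(n)
    ])


def test_filter_hits_boundary_semantics():
    table = hits_frame([
        ("q", "g", 75.0, 1e-10, 100, "p", "thl", "acetyl-CoA"),   # kept
        ("q", "g", 65.0, 1e-10, 100, "p", "thl", "acetyl-CoA"),   # identity below 70
        ("q", "g", 75.0, 1e-5, 100, "p", "thl", "acetyl-CoA"),    # e-value not strictly below
        ("q", "g", 70.0, 1e-6, 100, "p", "thl", "acetyl-CoA"),    # identity at cutoff kept
    ])
    out = filter_hits(table)
    assert len(out) == 2
    assert set(out["pident"]) == {75.0, 70.0}
    assert (out["evalue"] < 1e-5).all()


def test_filter_hits_empty_and_idempotent(rng):
    assert filter_hits(hits_frame([])).empty
    table = random_hits(rng)
    once = filter_hits(table)
    assert filter_hits(once).equals(once)


def test_tightening_cutoffs_never_adds_hits(rng):
    table = random_hits(rng)
    base = filter_hits(table, e_max=1e-3, id_min=50)
    tighter_e = filter_hits(table, e_max=1e-8, id_min=50)
    tighter_id = filter_hits(table, e_max=1e-3, id_min=80)
    assert set(tighter_e.index) <= set(base.index)
    assert set(tighter_id.index) <= set(base.index)


def test_assign_top_genome_max_ties_and_unmapped():
    table = hits_frame([
        ("p1", "gA", 90, 1e-20, 500, "p1", "x", "acetyl-CoA"),
        ("p1", "gB", 90, 1e-20, 450, "p1", "x", "acetyl-CoA"),
        ("p2", "gB", 90, 1e-20, 500, "p2", "x", "acetyl-CoA"),
        ("p2", "gA", 90, 1e-20, 500, "p2", "x", "acetyl-CoA"),
    ])
    mapping, unmapped = assign_top_genome(table, phylotypes=["p1", "p2", "p3"])
    assert mapping == {"p1": "gA", "p2": "gA"}  # p2 tie -> lexicographic
    assert unmapped == ["p3"]


ACOA_CORE = ["thl", "bhbd", "cro", "bcd"]


def pathway_hits(phylotype, genes):
    return hits_frame([
        (phylotype, "g", 90, 1e-20, 500, phylotype, g, "acetyl-CoA") for g in genes
    ])


def test_acetyl_coa_pathway_with_but_terminal():
    calls = call_butyrate_pathways(pathway_hits("p1", ACOA_CORE + ["but"]))
    row = calls.set_index("phylotype").loc["p1"]
    assert row["acetyl-CoA"] and row["producer"]
    assert row["acetyl-CoA_terminal"] == "but"


def test_acetyl_coa_pathway_with_buk_instead_of_but():
    calls = call_butyrate_pathways(pathway_hits("p1", ACOA_CORE + ["buk"]))
    row = calls.set_index("phylotype").loc["p1"]
    assert row["acetyl-CoA"]
    assert row["acetyl-CoA_terminal"] == "buk"


def test_core_without_terminal_is_negative():
    calls = call_butyrate_pathways(pathway_hits("p1", ACOA_CORE))
    row = calls.set_index("phylotype").loc["p1"]
    assert not row["acetyl-CoA"] and not row["producer"]


def test_unknown_pathway_tag_ignored_with_warning(caplog):
    table = pathway_hits("p1", ACOA_CORE + ["but"])
    table.loc[len(table)] = ("p1", "g", 90, 1e-20, 500, "p1", "zzz", "mystery")
    with caplog.at_level("WARNING"):
        calls = call_butyrate_pathways(table)
    assert "mystery" in caplog.text
    assert calls.set_index("phylotype").loc["p1", "acetyl-CoA"]


def test_adding_hits_never_removes_calls(rng):
    """Monotonicity: pathway calls on a subset of hits are a subset of calls
    on the full table."""
    defs = load_pathway_definitions()
    full = pd.concat([
        pathway_hits("p1", ACOA_CORE + ["but"]),
        pathway_hits("p2", ACOA_CORE + ["buk", "abfH", "abfD", "isom", "4hbt"]),
    ])
    sub = full.sample(frac=0.6, random_state=0)
    calls_sub = call_butyrate_pathways(sub, defs).set_index("phylotype")
    calls_full = call_butyrate_pathways(full, defs).set_index("phylotype")
    for p in calls_sub.index:
        for name in defs:
            if calls_sub.loc[p, name]:
                assert calls_full.loc[p, name]


def test_producer_abundance_extremes(default_cohort):
    comp = default_cohort.taxon_table()
    none = call_butyrate_pathways(hits_frame([]))
    assert (producer_abundance(none, comp) == 0).all()
    calls = pd.DataFrame({
        "phylotype": ["Clostridiales_producer", "Clostridiales_nonproducer"],
        "producer": [True, True],
    })
    total = producer_abundance(calls, comp)
    clost = comp[["Clostridiales_producer", "Clostridiales_nonproducer"]].sum(axis=1)
    assert np.allclose(total, clost)


def test_producer_fraction_tracks_butyrate_better(default_cohort):
    """Per-subject correlation of butyrate with the producer bin exceeds the
    non-producer bin (the generator couples butyrate to producers only)."""
    from scfaphase.associations import spearman

    comp = default_cohort.composition
    better = 0
    for sid, grp in comp.groupby("subject_id"):
        but = default_cohort.scfa.loc[grp.index, "butyrate"].to_numpy()
        r_prod, _ = spearman(grp["Clostridiales_producer"].to_numpy(), but)
        r_non, _ = spearman(grp["Clostridiales_nonproducer"].to_numpy(), but)
        better += r_prod > r_non
    assert better >= 9  # of 12 subjects


@pytest.mark.parametrize("abundance,ratio,expected", [
    (0.4, (3, 1), (0.3, 0.1)),
    (0.4, (0, 1), (0.0, 0.4)),
    (0.0, (2, 5), (0.0, 0.0)),
])
def test_subspecies_partition(abundance, ratio, expected):
    assert subspecies_partition(abundance, ratio) == pytest.approx(expected)


def test_subspecies_partition_conserves_total(rng):
    for _ in range(50):
        ab = rng.uniform(0, 1)
        ratio = rng.uniform(0, 5, size=2) + 1e-6
        inf, lon = subspecies_partition(ab, ratio)
        assert inf + lon == pytest.approx(ab, abs=1e-12)
        assert inf >= 0 and lon >= 0


def test_subspecies_partition_rejects_zero_ratio():
    with pytest.raises(ValueError):
        subspecies_partition(0.4, (0, 0))


# -- subgrouping -------------------------------------------------------------

def _subgroup_inputs():
    idx = [f"s{i}" for i in range(6)]
    feeding = pd.Series(["weaned", "breastfed", "breastfed", "breastfed",
                         "breastfed", "breastfed"], index=idx)
    bifido = pd.Series([0.5, 0.02, 0.5, 0.5, 0.5, 0.5], index=idx)
    genes = pd.DataFrame({
        "fl_sbp":     [1, 1, 1, 0, 0, 0],
        "fucp":       [0, 0, 0, 0, 1, 0],
        "fucosidase": [0, 0, 0, 0, 0, 1],
    }, index=idx)
    return feeding, bifido, genes


def test_subgroup_decision_list():
    feeding, bifido, genes = _subgroup_inputs()
    labels = assign_subgroups(feeding, bifido, genes)
    assert labels.to_dict() == {
        "s0": "weaned",               # rule 1 wins whatever the genes say
        "s1": "breastfed_low_bifido",
        "s2": "complete_route",       # FL-SBP alone completes the route
        "s3": "no_route",
        "s4": "partial_route",        # FucP without a fucosidase donor
        "s5": "partial_route",        # fucosidase without FucP
    }


def test_subgroup_complete_via_cross_feeding_genes():
    idx = ["s"]
    labels = assign_subgroups(
        pd.Series(["breastfed"], index=idx), pd.Series([0.5], index=idx),
        pd.DataFrame({"fl_sbp": [0], "fucp": [1], "fucosidase": [1]}, index=idx))
    assert labels["s"] == "complete_route"


def test_subgroup_missing_genotype_unclassified():
    idx = ["a", "b"]
    labels = assign_subgroups(
        pd.Series(["breastfed", "breastfed"], index=idx),
        pd.Series([0.5, 0.5], index=idx),
        pd.DataFrame({"fl_sbp": [1], "fucp": [0], "fucosidase": [0]}, index=["a"]))
    assert labels["a"] == "complete_route"
    assert labels["b"] == "unclassified"


def test_subgroup_order_invariance():
    feeding, bifido, genes = _subgroup_inputs()
    shuffled = feeding.index[::-1]
    a = assign_subgroups(feeding, bifido, genes)
    b = assign_subgroups(feeding.loc[shuffled], bifido.loc[shuffled], genes.loc[shuffled])
    assert a.sort_index().equals(b.sort_index())


def _cohort_subgroups(ds, threshold=0.1):
    orders = ds.order_table()
    wean = ds.events["wean_day"]
    feeding = pd.Series(
        np.where(ds.composition["day"].to_numpy()
                 < wean.loc[ds.composition["subject_id"]].to_numpy(),
                 "breastfed", "weaned"),
        index=ds.composition.index)
    return assign_subgroups(feeding, orders["Bifidobacteriales"],
                            ds.genes[GENE_COLUMNS], threshold), feeding


def test_complete_route_has_highest_median_formate(default_cohort):
    labels, _ = _cohort_subgroups(default_cohort)
    summaries, tests = subgroup_scfa_compare(labels, default_cohort.scfa[SCFA_COLUMNS])
    formate = summaries[summaries["metabolite"] == "formate"].set_index("subgroup")
    assert formate.loc["complete_route", "median"] == formate["median"].max()
    sig = tests[(tests["metabolite"] == "formate")]
    assert (sig["q"] < 0.05).any()


def test_subgroup_null_calibration(default_cohort):
    """Permuting subgroup labels kills the signal: across 100 permutation
    seeds the fraction of q < 0.05 stays within 0.05 + 3 SEs."""
    labels, _ = _cohort_subgroups(default_cohort)
    scfa = default_cohort.scfa[SCFA_COLUMNS]
    rng = np.random.default_rng(7)
    n_sig = n_tot = 0
    for _ in range(100):
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        _, tests = subgroup_scfa_compare(perm, scfa, metabolites=["formate", "butyrate"])
        n_sig += int((tests["q"] < 0.05).sum())
        n_tot += len(tests)
    rate = n_sig / n_tot
    se = np.sqrt(0.05 * 0.95 / n_tot)
    assert rate <= 0.05 + 3 * se


def test_pathway_definition_validation():
    with pytest.raises(ValueError):
        PathwayDefinition("acetyl-CoA", core_genes={"thl"}, terminal_genes=set())
    with pytest.raises(ValueError):
        PathwayDefinition("x", core_genes={"a"}, required_core_fraction=0.0)
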
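"""Synthetic cohort generator: schedule, truth draws, composition and SCFA models."""

import numpy as np
import pytest

import scfaphase as sp
from scfaphase.cohort import BIFIDO_SPECIES, SCFA_COLUMNS, TAXA
from scfaphase.synthetic import (
    ARCHETYPES,
    CohortConfig,
    ScfaParams,
    draw_subject_truth,
    expected_composition,
    fucose_access,
    generate_cohort,
    latent_regime,
    make_sampling_schedule,
    simulate_composition,
    simulate_scfa,
)


# -- sampling schedule -------------------------------------------------------

@pytest.mark.parametrize("end_day,n", [(730, 92), (7, 7), (364, 66)])
def test_schedule_counts(end_day, n):
    assert len(make_sampling_schedule(end_day)) == n


def test_schedule_block_structure():
    days = make_sampling_schedule(730).days
    assert days[:7] == tuple(range(1, 8))  # daily week 1
    assert days[7:18] == tuple(range(9, 30, 2))  # alternate days to 1 month
    assert days[18] == 35 and days[65] == 364  # weekly to 1 year
    assert days[66] == 378 and days[-1] == 728  # fortnightly thereafter
    assert all(b > a for a, b in zip(days, days[1:]))


def test_schedule_rejects_short_study():
    with pytest.raises(ValueError):
        make_sampling_schedule(6)


# -- subject truth -----------------------------------------------------------

def test_truth_draw_is_deterministic():
    cfg = CohortConfig()
    a = draw_subject_truth(cfg, np.random.default_rng(7))
    b = draw_subject_truth(cfg, np.random.default_rng(7))
    assert a == b


def test_truth_ranges_and_medians():
    """10 000 draws respect the configured ranges; empirical medians sit near
    the configured targets (Monte-Carlo tolerance)."""
    cfg = CohortConfig()
    rng = np.random.default_rng(0)
    t1s, t2s = [], []
    for _ in range(10_000):
        t = draw_subject_truth(cfg, rng)
        assert cfg.t1_range[0] <= t.T1 <= cfg.t1_range[1]
        assert cfg.t2_range[0] <= t.T2 <= cfg.t2_range[1]
        assert t.T1 < t.T2
        assert t.solid_food_day < t.wean_day
        t1s.append(t.T1)
        t2s.append(t.T2)
    assert abs(np.median(t1s) - cfg.t1_median) <= 2.0
    assert abs(np.median(t2s) - cfg.t2_median) <= 6.0


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        CohortConfig(t1_range=(180, 3)).validate()
    with pytest.raises(ValueError):
        CohortConfig(dominant_bifido_freqs={"B_infantis": 0.5}).validate()


def test_config_yaml_round_trip(tmp_path):
    cfg = CohortConfig(n_subjects=5, scfa=ScfaParams(bifido_hexose=33.0))
    path = tmp_path / "cohort.yaml"
    cfg.to_yaml(path)
    loaded = CohortConfig.from_yaml(path)
    assert loaded == cfg


# -- composition model -------------------------------------------------------

@pytest.fixture()
def truth():
    return draw_subject_truth(CohortConfig(), np.random.default_rng(3))


def test_expected_profile_archetype_dominance(truth):
    cfg = CohortConfig()
    idx = {t: i for i, t in enumerate(TAXA)}
    early = expected_composition(truth, 1, cfg)
    assert np.argmax(early) == idx["Enterobacterales"]
    mid = expected_composition(truth, (truth.T1 + truth.T2) // 2, cfg)
    bifido = sum(mid[idx[s]] for s in BIFIDO_SPECIES)
    assert bifido > mid[idx["Enterobacterales"]]
    assert bifido > sum(mid[idx[b]] for b in ("Clostridiales_producer", "Clostridiales_nonproducer"))


def test_dirichlet_concentrates_on_blend(truth):
    cfg = CohortConfig(dirichlet_concentration=1e6)
    rng = np.random.default_rng(0)
    day = (truth.T1 + truth.T2) // 2
    draw = simulate_composition(truth, day, rng, cfg)
    blend = expected_composition(truth, day, cfg)
    assert np.abs(draw - blend).sum() < 1e-2


def test_composition_day_bounds(truth):
    with pytest.raises(ValueError):
        simulate_composition(truth, 0, np.random.default_rng(0))


# -- SCFA model --------------------------------------------------------------

def test_zero_bacterial_load_gives_baselines_only():
    cfg = CohortConfig(scfa=ScfaParams(noise_sigma=0.0))
    out = simulate_scfa(np.zeros(len(TAXA)), {}, "breastfed", None, cfg)
    for acid in SCFA_COLUMNS:
        assert out[acid] == pytest.approx(cfg.scfa.baseline[acid])


def test_formate_requires_fucose_access():
    """A fucosidase donor without any FucP/pathway carrier cannot make formate;
    adding the consumer switches production on."""
    cfg = CohortConfig(scfa=ScfaParams(noise_sigma=0.0))
    comp = np.zeros(len(TAXA))
    comp[TAXA.index("B_bifidum")] = 0.7
    comp[TAXA.index("Other")] = 0.3
    bifidum_only = {"B_bifidum": dict(fl_sbp=False, fucp=False, fucosidase=True,
                                      fucose_pathway=False, shunt=True)}
    out = simulate_scfa(comp, bifidum_only, "breastfed", None, cfg)
    assert out["formate"] == pytest.approx(cfg.scfa.baseline["formate"])
    with_breve = dict(bifidum_only)
    with_breve["B_breve"] = dict(fl_sbp=False, fucp=True, fucosidase=False,
                                 fucose_pathway=True, shunt=True)
    out2 = simulate_scfa(comp, with_breve, "breastfed", None, cfg)
    assert out2["formate"] > out["formate"]


def test_scfa_zero_noise_is_deterministic():
    cfg = CohortConfig(scfa=ScfaParams(noise_sigma=0.0))
    comp = simulate_composition(
        draw_subject_truth(CohortConfig(), np.random.default_rng(1)), 100,
        np.random.default_rng(2))
    genotype = {"B_infantis": dict(fl_sbp=True, fucp=True, fucosidase=False,
                                   fucose_pathway=True, shunt=True)}
    a = simulate_scfa(comp, genotype, "breastfed", np.random.default_rng(5), cfg)
    b = simulate_scfa(comp, genotype, "breastfed", np.random.default_rng(99), cfg)
    assert a == b


def test_negative_composition_rejected():
    comp = np.zeros(len(TAXA))
    comp[0] = -0.1
    with pytest.raises(ValueError, match="negative"):
        simulate_scfa(comp, {}, "breastfed")


def test_fucose_access_rules():
    fl = dict(fl_sbp=True, fucp=False, fucosidase=False, fucose_pathway=True, shunt=True)
    fucp = dict(fl_sbp=False, fucp=True, fucosidase=False, fucose_pathway=True, shunt=True)
    donor = dict(fl_sbp=False, fucp=False, fucosidase=True, fucose_pathway=False, shunt=True)
    assert fucose_access({"a": fl})
    assert not fucose_access({"a": fucp})
    assert not fucose_access({"a": donor})
    assert fucose_access({"a": fucp, "b": donor})


# -- cohort assembly ---------------------------------------------------------

def test_default_cohort_dimensions(default_cohort):
    assert len(default_cohort.composition) == 12 * 92
    assert len(default_cohort.events) == 12
    assert default_cohort.truth is not None and len(default_cohort.truth) == 12


def test_composition_rows_sum_to_one(default_cohort):
    sums = default_cohort.taxon_table().sum(axis=1).to_numpy()
    assert np.all(np.abs(sums - 1.0) <= 1e-9)


def test_same_seed_byte_identical_exports(tmp_path):
    cfg = CohortConfig(n_subjects=3, end_day=60)
    for run in ("a", "b"):
        sp.write_cohort(generate_cohort(cfg, seed=11), tmp_path / run)
    for name in ("composition.tsv", "scfa.tsv", "events.tsv", "genes.tsv", "truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_cohort_round_trip(tmp_path, default_cohort):
    sp.write_cohort(default_cohort, tmp_path)
    back = sp.read_cohort(tmp_path)
    assert back.composition.shape == default_cohort.composition.shape
    assert np.allclose(back.taxon_table(), default_cohort.taxon_table(), atol=1e-5)
    assert [t.subject_id for t in back.truth] == [t.subject_id for t in default_cohort.truth]


def test_regime_recoverability(default_cohort):
    """Away from the transitions (> 14 d), the modal order matches the latent
    regime for >= 95% of samples at default noise."""
    truthmap = {t.subject_id: t for t in default_cohort.truth}
    orders = default_cohort.order_table()
    cols = ["Enterobacterales", "Bifidobacteriales", "Clostridiales"]
    ok = tot = 0
    for (sid, day), row in zip(
        default_cohort.composition[["subject_id", "day"]].itertuples(index=False),
        orders[cols].to_numpy(),
    ):
        t = truthmap[sid]
        if min(abs(day - t.T1), abs(day - t.T2)) <= 14:
            continue
        tot += 1
        ok += ["En", "Bi", "Cl"][int(np.argmax(row))] == latent_regime(t, day)
    assert tot > 500
    assert ok / tot >= 0.95


def test_scfa_phase_structure(default_cohort, latent_phase_fn):
    """Within-phase mean profiles reproduce the three-phase ordering:
    succinate highest pre-transition, lactate+formate peaking in the breastfed
    bifidobacterial phase, butyrate peaking after weaning."""
    truthmap = {t.subject_id: t for t in default_cohort.truth}
    scfa = default_cohort.scfa
    phases = np.array([
        latent_phase_fn(truthmap[s], d) for s, d in zip(scfa.subject_id, scfa.day)
    ])
    mean = {ph: scfa.loc[phases == ph, SCFA_COLUMNS].mean() for ph in (1, 2, 3)}
    assert mean[1]["succinate"] > mean[2]["succinate"]
    assert mean[1]["succinate"] > mean[3]["succinate"]
    lacfor = {ph: mean[ph]["lactate"] + mean[ph]["formate"] for ph in (1, 2, 3)}
    assert lacfor[2] == max(lacfor.values())
    assert mean[3]["butyrate"] == max(mean[ph]["butyrate"] for ph in (1, 2, 3))


def test_antibiotic_interval_depresses_bifido():
    cfg = CohortConfig(antibiotic_prob=1.0)
    rng = np.random.default_rng(12)
    t = draw_subject_truth(cfg, rng)
    assert t.antibiotic_intervals
    start, stop = t.antibiotic_intervals[0]
    mid = (start + stop) // 2
    idx = [TAXA.index(s) for s in BIFIDO_SPECIES]
    with_ab = expected_composition(t, mid, cfg)
    t_no = sp.SubjectTruth(**{**t.to_dict(), "antibiotic_intervals": []})
    without = expected_composition(t_no, mid, cfg)
    assert with_ab[idx].sum() < without[idx].sum()
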
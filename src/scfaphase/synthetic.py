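"""Seeded synthetic longitudinal infant-cohort generator.

Emulates the structure of a dense infant sampling design: 12 subjects followed
for two years on a fixed stool-collection cadence (daily in week 1, every
other day to one month, weekly to one year, fortnightly thereafter — 92
time points over 730 days), an Enterobacterales -> Bifidobacteriales ->
Clostridiales community succession with subject-specific transition days T1
and T2, three SCFA phases (succinate-high early, lactate/formate-high while
breastfed and bifidobacteria-dominated, propionate/butyrate-high after
weaning), genotype-dependent formate production (fucose access through the
2'-FL transporter, or through fucose cross-feeding when a fucosidase donor and
a FucP carrier co-reside), and weaning coupled to T2.

The composition model blends three regime archetypes with two logistic ramps
centred at T1 and T2 and draws each sample from a Dirichlet around the blend;
SCFA concentrations are linear combinations of producer terms whose yields
come from the stoichiometric fermentation model, with multiplicative
log-normal noise.  All magnitudes are order-of-magnitude placeholders held in
one config (see ``CohortConfig`` and the shipped ``cohort_default.yaml``),
not quantitative claims about real faeces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    BIFIDO_SPECIES,
    CLOSTRIDIALES_BINS,
    GENE_COLUMNS,
    ORDERS,
    SCFA_COLUMNS,
    TAXA,
    CohortDataset,
    SubjectTruth,
)
from . import stoichiometry as st

REGIMES = ["En", "Bi", "Cl"]

#: HMO-utilisation gene complement per bifidobacterial species.  B. infantis
#: imports 2'-FL intact (FL-SBP) and catabolises fucose; B. bifidum carries an
#: extracellular fucosidase but no fucose pathway; B. breve takes up free
#: fucose (FucP) and catabolises it; B. longum subsp. longum has no route.
SPECIES_GENOTYPES: dict[str, dict[str, bool]] = {
    "B_infantis": dict(fl_sbp=True, fucp=True, fucosidase=False, fucose_pathway=True, shunt=True),
    "B_bifidum": dict(fl_sbp=False, fucp=False, fucosidase=True, fucose_pathway=False, shunt=True),
    "B_breve": dict(fl_sbp=False, fucp=True, fucosidase=False, fucose_pathway=True, shunt=True),
    "B_longum": dict(fl_sbp=False, fucp=False, fucosidase=False, fucose_pathway=False, shunt=True),
}

#: within-Bifidobacteriales species split for each dominant-bifido scenario
BIFIDO_SPLITS: dict[str, list[float]] = {
    "B_infantis": [0.70, 0.10, 0.10, 0.10],
    "B_bifidum_breve": [0.05, 0.45, 0.40, 0.10],
    "B_breve": [0.05, 0.05, 0.70, 0.20],
    "none": [0.02, 0.03, 0.05, 0.90],
}

#: order-level regime archetypes (En-, Bi-, Cl-dominant expected profiles);
#: pre-transition guts carry little Bifidobacteriales, so the En archetype is
#: strongly Enterobacterales-dominant
ARCHETYPES: dict[str, dict[str, float]] = {
    "En": dict(Enterobacterales=0.76, Bifidobacteriales=0.05, Clostridiales=0.02,
               Bacteroidales=0.03, Lactobacillales=0.05, Other=0.09),
    "Bi": dict(Enterobacterales=0.06, Bifidobacteriales=0.72, Clostridiales=0.05,
               Bacteroidales=0.05, Lactobacillales=0.04, Other=0.08),
    "Cl": dict(Enterobacterales=0.04, Bifidobacteriales=0.18, Clostridiales=0.50,
               Bacteroidales=0.14, Lactobacillales=0.04, Other=0.10),
}


# ---------------------------------------------------------------------------
# Sampling schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered study days (day 1 = first day after birth)."""

    days: tuple[int, ...]

    def __post_init__(self):
        d = self.days
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("days must be strictly increasing")
        if d and d[0] < 1:
            raise ValueError("days start at 1")

    def __len__(self):
        return len(self.days)


def make_sampling_schedule(end_day: int, convention: str = "default") -> SamplingSchedule:
    """Stool-collection days: daily for week 1, every other day to day 29,
    weekly from day 35 to day 364, fortnightly from day 378 on.

    With ``end_day=730`` the default convention yields exactly 92 days.
    """
    if convention != "default":
        raise ValueError(f"unknown schedule convention {convention!r}")
    if end_day < 7:
        raise ValueError("end_day must be >= 7")
    days = list(range(1, 8))
    days += [d for d in range(9, 30, 2) if d <= end_day]
    days += [d for d in range(35, 365, 7) if d <= end_day]
    days += [d for d in range(378, end_day + 1, 14)]
    return SamplingSchedule(tuple(days))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ScfaParams:
    """Producer-term magnitudes (mM at unit producer fraction).

    Order-of-magnitude placeholders: medians fall in physiologically plausible
    faecal ranges but are parameters, not measurements.
    """

    baseline: dict[str, float] = field(default_factory=lambda: dict(
        acetate=2.0, propionate=0.2, butyrate=0.05, lactate=0.3,
        formate=0.1, succinate=0.3, isobutyrate=0.05, isovalerate=0.05,
    ))
    entero_succinate: float = 30.0
    entero_acetate: float = 6.0  # low: the early phase is acetate-poor
    bifido_hexose: float = 45.0  # mM hexose-equivalents fermented through the shunt
    fucose_flux: float = 14.0  # mM fucose when the genotype grants access
    wean_milk_factor: float = 0.1  # lactate/formate attenuation after weaning
    butyrate_coeff: float = 40.0
    butyrate_breastfed_factor: float = 0.2  # weaning multiplies butyrate up 5x
    butyrate_acetate_debit: float = 0.8  # mol acetate consumed per mol butyrate (but route)
    propionate_coeff: float = 32.0
    clost_acetate: float = 25.0
    branched_coeff: float = 1.5
    bacteroidales_succinate: float = 2.0
    noise_sigma: float = 0.3  # log-normal multiplicative noise
    ph_intercept: float = 7.6
    ph_slope_total: float = 0.02
    ph_slope_lactate: float = 0.015


@dataclass
class CohortConfig:
    """Generator configuration; defaults define the emulated study conditions."""

    n_subjects: int = 12
    end_day: int = 730
    # regime-change days: T1 log-normal with the configured median, T2 normal
    t1_range: tuple[int, int] = (3, 180)
    t1_median: float = 18.0  # ~0.6 months
    t1_log_sigma: float = 0.9
    t2_range: tuple[int, int] = (240, 730)
    t2_median: float = 396.0  # ~13 months
    t2_sigma: float = 90.0
    wean_jitter: float = 7.0  # SD of (wean day - T2), days
    solid_food_range: tuple[int, int] = (120, 210)
    ramp_width: float = 21.0  # 10-90% span of each regime ramp, days
    dirichlet_concentration: float = 200.0
    clostridiales_producer_fraction: float = 0.6
    dominant_bifido_freqs: dict[str, float] = field(default_factory=lambda: {
        "B_infantis": 0.30, "B_bifidum_breve": 0.30, "B_breve": 0.25, "none": 0.15,
    })
    species_presence_threshold: float = 0.05  # split fraction making a species resident
    gene_detection_fraction: float = 0.005  # leaf fraction for per-sample gene calls
    antibiotic_prob: float = 0.0  # optional transient perturbation, default off
    antibiotic_duration: tuple[int, int] = (5, 10)
    antibiotic_bifido_factor: float = 0.2
    antibiotic_recovery_tau: float = 7.0
    scfa: ScfaParams = field(default_factory=ScfaParams)

    def validate(self) -> None:
        for name, (lo, hi) in (("t1_range", self.t1_range), ("t2_range", self.t2_range),
                               ("solid_food_range", self.solid_food_range)):
            if lo > hi or lo < 1:
                raise ValueError(f"invalid {name}: {(lo, hi)}")
        if self.t1_range[1] >= self.t2_range[0]:
            raise ValueError("t1_range must end before t2_range begins")
        freqs = self.dominant_bifido_freqs
        if abs(sum(freqs.values()) - 1.0) > 1e-9 or any(v < 0 for v in freqs.values()):
            raise ValueError("dominant_bifido_freqs must be a probability distribution")
        if self.n_subjects < 1 or self.end_day < 7:
            raise ValueError("need n_subjects >= 1 and end_day >= 7")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        scfa = ScfaParams(**doc.pop("scfa", {}))
        for key in ("t1_range", "t2_range", "solid_food_range", "antibiotic_duration"):
            if key in doc:
                doc[key] = tuple(doc[key])
        cfg = cls(scfa=scfa, **doc)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        for key in ("t1_range", "t2_range", "solid_food_range", "antibiotic_duration"):
            doc[key] = list(doc[key])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Subject truth
# ---------------------------------------------------------------------------

def draw_subject_truth(
    config: CohortConfig, rng: np.random.Generator, subject_id: str = "S01"
) -> SubjectTruth:
    """Draw latent subject parameters (reproducible for a fixed generator state)."""
    config.validate()
    t1 = int(np.clip(round(rng.lognormal(np.log(config.t1_median), config.t1_log_sigma)),
                     *config.t1_range))
    t2 = int(np.clip(round(rng.normal(config.t2_median, config.t2_sigma)),
                     *config.t2_range))
    solid = int(rng.integers(config.solid_food_range[0], config.solid_food_range[1] + 1))
    solid = min(solid, config.end_day - 1)  # short studies truncate the range
    wean = int(np.clip(round(t2 + rng.normal(0.0, config.wean_jitter)),
                       solid + 1, config.end_day))
    names = list(config.dominant_bifido_freqs)
    dominant = str(rng.choice(names, p=[config.dominant_bifido_freqs[n] for n in names]))
    split = BIFIDO_SPLITS[dominant]
    genotype = {
        sp: dict(SPECIES_GENOTYPES[sp])
        for sp, frac in zip(BIFIDO_SPECIES, split)
        if frac >= config.species_presence_threshold
    }
    intervals: list[tuple[int, int]] = []
    if rng.random() < config.antibiotic_prob:
        start = int(rng.integers(30, config.end_day - 30))
        dur = int(rng.integers(config.antibiotic_duration[0], config.antibiotic_duration[1] + 1))
        intervals.append((start, start + dur))
    return SubjectTruth(
        subject_id=subject_id, T1=t1, T2=t2, solid_food_day=solid, wean_day=wean,
        genotype=genotype, dominant_bifido=dominant, antibiotic_intervals=intervals,
    )


def latent_regime(truth: SubjectTruth, day: int) -> str:
    """The regime whose archetype dominates the blend at ``day``."""
    if day < truth.T1:
        return "En"
    return "Bi" if day < truth.T2 else "Cl"


def fucose_access(genotype: dict[str, dict[str, bool]]) -> bool:
    """Whether resident species can channel HMO fucose into the fucose pathway:
    either an intact-FL importer with the pathway, or a FucP carrier with the
    pathway plus a co-resident extracellular-fucosidase donor."""
    direct = any(f.get("fl_sbp") and f.get("fucose_pathway") for f in genotype.values())
    consumer = any(f.get("fucp") and f.get("fucose_pathway") for f in genotype.values())
    donor = any(f.get("fucosidase") for f in genotype.values())
    return direct or (consumer and donor)


# ---------------------------------------------------------------------------
# Composition model
# ---------------------------------------------------------------------------

def _leaf_archetypes(truth: SubjectTruth, config: CohortConfig) -> np.ndarray:
    """Expand the three order-level archetypes to leaf bins for one subject."""
    split = np.asarray(BIFIDO_SPLITS[truth.dominant_bifido])
    pf = config.clostridiales_producer_fraction
    rows = []
    for regime in REGIMES:
        arch = ARCHETYPES[regime]
        leaf = dict.fromkeys(TAXA, 0.0)
        leaf["Enterobacterales"] = arch["Enterobacterales"]
        for sp, frac in zip(BIFIDO_SPECIES, split):
            leaf[sp] = arch["Bifidobacteriales"] * frac
        leaf["Clostridiales_producer"] = arch["Clostridiales"] * pf
        leaf["Clostridiales_nonproducer"] = arch["Clostridiales"] * (1 - pf)
        for col in ("Bacteroidales", "Lactobacillales", "Other"):
            leaf[col] = arch[col]
        rows.append([leaf[t] for t in TAXA])
    return np.asarray(rows)


#: a logistic completes 10% -> 90% of its rise over 2 ln(9) scale units
_LOGISTIC_SPAN = 2.0 * np.log(9.0)


def regime_weights(truth: SubjectTruth, day, width: float) -> np.ndarray:
    """Logistic blend weights (wEn, wBi, wCl) at ``day`` (vectorised over day).

    ``width`` is the 10-90% span of each ramp in days.  The first ramp's span
    is additionally capped at T1/2: a succession completed by day T1 cannot
    have taken longer than the infant's age, so early transitions are
    necessarily sharp while late ones keep the configured width.
    """
    day = np.asarray(day, dtype=float)
    s1_scale = min(width, truth.T1 / 2.0) / _LOGISTIC_SPAN
    s2_scale = width / _LOGISTIC_SPAN
    s1 = 1.0 / (1.0 + np.exp(-(day - truth.T1) / s1_scale))
    s2 = 1.0 / (1.0 + np.exp(-(day - truth.T2) / s2_scale))
    return np.stack([1.0 - s1, s1 * (1.0 - s2), s1 * s2], axis=-1)


def expected_composition(truth: SubjectTruth, day: int, config: CohortConfig | None = None) -> np.ndarray:
    """Deterministic expected leaf profile: logistic blend of the archetypes,
    with the optional transient antibiotic knock-down of Bifidobacteriales."""
    config = config or CohortConfig()
    w = regime_weights(truth, day, config.ramp_width)
    blend = w @ _leaf_archetypes(truth, config)
    factor = 1.0
    for start, stop in truth.antibiotic_intervals:
        if start <= day <= stop:
            factor = config.antibiotic_bifido_factor
        elif day > stop:
            rec = 1.0 - (1.0 - config.antibiotic_bifido_factor) * np.exp(
                -(day - stop) / config.antibiotic_recovery_tau
            )
            factor = min(factor, rec)
    if factor < 1.0:
        idx = [TAXA.index(sp) for sp in BIFIDO_SPECIES]
        blend[idx] = blend[idx] * factor
        blend = blend / blend.sum()
    return blend


def simulate_composition(
    truth: SubjectTruth, day: int, rng: np.random.Generator,
    config: CohortConfig | None = None,
) -> np.ndarray:
    """One Dirichlet draw around the expected blend at ``day``."""
    config = config or CohortConfig()
    if not 1 <= day <= config.end_day:
        raise ValueError(f"day must be in [1, {config.end_day}]")
    blend = expected_composition(truth, day, config)
    alpha = config.dirichlet_concentration * blend + 1e-9
    return rng.dirichlet(alpha)


# ---------------------------------------------------------------------------
# SCFA model
# ---------------------------------------------------------------------------

def _fermentation_yields() -> tuple[dict[str, float], dict[str, float]]:
    shunt, fucose, _ = st.build_default_networks()
    y_shunt = st.ferment(shunt, "glucose", 1.0).yields
    y_fucose = st.ferment(fucose, "fucose", 1.0).yields
    return y_shunt, y_fucose


_YIELDS_CACHE: tuple[dict, dict] | None = None


def _yields() -> tuple[dict[str, float], dict[str, float]]:
    global _YIELDS_CACHE
    if _YIELDS_CACHE is None:
        _YIELDS_CACHE = _fermentation_yields()
    return _YIELDS_CACHE


def simulate_scfa(
    composition,
    genotype: dict[str, dict[str, bool]],
    feeding_state: str,
    rng: np.random.Generator | None = None,
    config: CohortConfig | None = None,
    yields: tuple[dict, dict] | None = None,
) -> dict[str, float]:
    """Expected SCFA profile (mM) for one sample, with log-normal noise.

    Producer terms: Enterobacterales release succinate and acetate;
    Bifidobacteriales ferment milk hexose through the bifid shunt
    (acetate:lactate 3:2 per 2 hexose, from the stoichiometric model) and,
    when the genotype grants fucose access and the infant is breastfed,
    HMO fucose to formate + acetate; butyrate-producer Clostridiales make
    butyrate (amplified after weaning, drawing down acetate via the but
    route); Bacteroidales/Clostridiales contribute propionate and acetate.
    pH is a decreasing affine function of total acid with extra lactate
    weight, clipped to [4.0, 8.5].  Returns a dict of the eight acids + pH.
    """
    config = config or CohortConfig()
    p = config.scfa
    if feeding_state not in ("breastfed", "weaned"):
        raise ValueError("feeding_state must be 'breastfed' or 'weaned'")
    comp = np.asarray(composition, dtype=float)
    if np.any(comp < 0):
        raise ValueError("negative composition")
    frac = dict(zip(TAXA, comp))
    f_en = frac["Enterobacterales"]
    f_bi = sum(frac[sp] for sp in BIFIDO_SPECIES)
    f_cl = sum(frac[b] for b in CLOSTRIDIALES_BINS)
    f_prod = frac["Clostridiales_producer"]
    f_ba = frac["Bacteroidales"]

    y_shunt, y_fuc = yields if yields is not None else _yields()
    breastfed = feeding_state == "breastfed"
    milk = 1.0 if breastfed else p.wean_milk_factor

    conc = dict(p.baseline)
    conc["succinate"] += p.entero_succinate * f_en + p.bacteroidales_succinate * f_ba
    conc["acetate"] += p.entero_acetate * f_en

    hexose = p.bifido_hexose * f_bi
    conc["acetate"] += hexose * y_shunt.get("acetate", 0.0)
    conc["lactate"] += hexose * y_shunt.get("lactate", 0.0) * milk
    if fucose_access(genotype):
        fuc = p.fucose_flux * f_bi * milk
        conc["formate"] += fuc * y_fuc.get("formate", 0.0)
        conc["acetate"] += fuc * y_fuc.get("acetate", 0.0)

    but = p.butyrate_coeff * f_prod * (1.0 if not breastfed else p.butyrate_breastfed_factor)
    conc["butyrate"] += but
    conc["acetate"] = max(0.0, conc["acetate"] - p.butyrate_acetate_debit * but)

    conc["propionate"] += p.propionate_coeff * (f_ba + 0.5 * f_cl)
    conc["acetate"] += p.clost_acetate * (f_cl + f_ba)
    branched = p.branched_coeff * f_cl * (0.2 if breastfed else 1.0)
    conc["isobutyrate"] += branched
    conc["isovalerate"] += branched

    if rng is not None and p.noise_sigma > 0:
        noise = rng.lognormal(0.0, p.noise_sigma, size=len(SCFA_COLUMNS))
        for acid, z in zip(SCFA_COLUMNS, noise):
            conc[acid] *= z

    total = sum(conc[a] for a in SCFA_COLUMNS)
    ph = p.ph_intercept - p.ph_slope_total * total - p.ph_slope_lactate * conc["lactate"]
    conc["pH"] = float(np.clip(ph, 4.0, 8.5))
    return {k: float(v) for k, v in conc.items()}


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortDataset:
    """Generate a full synthetic cohort with ground truth attached."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    schedule = make_sampling_schedule(config.end_day)
    yields = _yields()

    truths: list[SubjectTruth] = []
    comp_rows, scfa_rows, gene_rows, index = [], [], [], []
    events_rows = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        truth = draw_subject_truth(config, rng, subject_id=sid)
        truths.append(truth)
        events_rows.append({
            "subject_id": sid,
            "solid_food_day": truth.solid_food_day,
            "wean_day": truth.wean_day,
            "antibiotic_intervals": truth.antibiotic_intervals,
        })
        for day in schedule.days:
            comp = simulate_composition(truth, day, rng, config)
            feeding = "breastfed" if day < truth.wean_day else "weaned"
            scfa = simulate_scfa(comp, truth.genotype, feeding, rng, config, yields)
            sample_id = f"{sid}_d{day:03d}"
            index.append(sample_id)
            comp_rows.append([sid, day, *comp])
            scfa_rows.append([sid, day] + [scfa[a] for a in SCFA_COLUMNS] + [scfa["pH"]])
            detected = {
                sp for sp, f in zip(BIFIDO_SPECIES, comp[1:5])
                if f > config.gene_detection_fraction and sp in truth.genotype
            }
            flags = {
                g: int(any(SPECIES_GENOTYPES[sp][g] for sp in detected))
                for g in GENE_COLUMNS
            }
            gene_rows.append([sid, day, flags["fl_sbp"], flags["fucp"], flags["fucosidase"]])

    composition = pd.DataFrame(
        comp_rows, index=pd.Index(index, name="sample_id"),
        columns=["subject_id", "day", *TAXA],
    )
    scfa = pd.DataFrame(
        scfa_rows, index=pd.Index(index, name="sample_id"),
        columns=["subject_id", "day", *SCFA_COLUMNS, "pH"],
    )
    genes = pd.DataFrame(
        gene_rows, index=pd.Index(index, name="sample_id"),
        columns=["subject_id", "day", *GENE_COLUMNS],
    )
    events = pd.DataFrame(events_rows).set_index("subject_id")
    ds = CohortDataset(
        composition=composition, scfa=scfa, events=events, genes=genes, truth=truths
    )
    ds.validate()
    return ds
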
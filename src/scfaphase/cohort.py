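"""Cohort data container and its tab-separated on-disk layout.

A cohort is a set of per-sample tables aligned on ``sample_id``: taxon
composition (leaf-level relative abundances summing to 1), SCFA concentrations
in mM plus faecal pH, per-subject life events, per-sample marker-gene
detection flags, and — for synthetic cohorts — the ground-truth subject
parameters used to generate them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: leaf-level taxon bins: order level, with Bifidobacteriales resolved to the
#: four infant-type species and Clostridiales split by butyrate-producer status
BIFIDO_SPECIES = ["B_infantis", "B_bifidum", "B_breve", "B_longum"]
CLOSTRIDIALES_BINS = ["Clostridiales_producer", "Clostridiales_nonproducer"]
TAXA = (
    ["Enterobacterales"]
    + BIFIDO_SPECIES
    + CLOSTRIDIALES_BINS
    + ["Bacteroidales", "Lactobacillales", "Other"]
)
ORDERS = [
    "Enterobacterales",
    "Bifidobacteriales",
    "Clostridiales",
    "Bacteroidales",
    "Lactobacillales",
    "Other",
]
SCFA_COLUMNS = [
    "acetate",
    "propionate",
    "butyrate",
    "lactate",
    "formate",
    "succinate",
    "isobutyrate",
    "isovalerate",
]
GENE_COLUMNS = ["fl_sbp", "fucp", "fucosidase"]
META_COLUMNS = ["subject_id", "day"]

_FLOAT_FMT = "%.6g"


@dataclass
class SubjectTruth:
    """Latent per-subject parameters of a synthetic cohort.

    T1 / T2 are the days of the Enterobacterales->Bifidobacteriales and
    Bifidobacteriales->Clostridiales regime changes; weaning is coupled to T2
    within a configured jitter, and solid food starts before weaning.
    ``genotype`` maps each resident bifidobacterial species to its
    HMO-utilisation gene flags.
    """

    subject_id: str
    T1: int
    T2: int
    solid_food_day: int
    wean_day: int
    genotype: dict[str, dict[str, bool]]
    dominant_bifido: str
    antibiotic_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not 1 <= self.T1 < self.T2:
            raise ValueError("requires 1 <= T1 < T2")
        if not self.solid_food_day < self.wean_day:
            raise ValueError("solid food must start before weaning")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["antibiotic_intervals"] = [list(iv) for iv in self.antibiotic_intervals]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectTruth":
        d = dict(d)
        d["antibiotic_intervals"] = [tuple(iv) for iv in d.get("antibiotic_intervals", [])]
        return cls(**d)


def order_level(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a leaf-level taxon table to bacterial-order resolution."""
    out = pd.DataFrame(index=table.index)
    out["Enterobacterales"] = table["Enterobacterales"]
    out["Bifidobacteriales"] = table[BIFIDO_SPECIES].sum(axis=1)
    out["Clostridiales"] = table[CLOSTRIDIALES_BINS].sum(axis=1)
    for col in ("Bacteroidales", "Lactobacillales", "Other"):
        out[col] = table[col]
    return out


@dataclass
class CohortDataset:
    """Aligned per-sample composition, SCFA, event and gene tables."""

    composition: pd.DataFrame  # index sample_id; subject_id, day, *TAXA
    scfa: pd.DataFrame  # index sample_id; subject_id, day, *SCFA_COLUMNS, pH
    events: pd.DataFrame  # index subject_id; solid_food_day, wean_day, antibiotic_intervals
    genes: pd.DataFrame  # index sample_id; subject_id, day, *GENE_COLUMNS
    truth: list[SubjectTruth] | None = None

    def validate(self) -> None:
        comp = self.taxon_table().to_numpy()
        if np.any(comp < 0):
            raise ValueError("negative taxon fraction")
        if np.any(np.abs(comp.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("composition rows must sum to 1")
        conc = self.scfa[SCFA_COLUMNS].to_numpy()
        if np.any(conc < 0):
            raise ValueError("negative concentration")
        ph = self.scfa["pH"].to_numpy()
        if np.any((ph < 4.0) | (ph > 8.5)):
            raise ValueError("pH out of [4.0, 8.5]")
        if not self.composition.index.equals(self.scfa.index):
            raise ValueError("composition and scfa sample sets differ")

    def taxon_table(self) -> pd.DataFrame:
        return self.composition[TAXA]

    def order_table(self) -> pd.DataFrame:
        return order_level(self.composition)

    def subjects(self) -> list[str]:
        return list(self.events.index)


def _intervals_to_str(intervals) -> str:
    return ";".join(f"{a}-{b}" for a, b in intervals)


def _intervals_from_str(s) -> list[tuple[int, int]]:
    if not isinstance(s, str) or not s:
        return []
    return [tuple(int(x) for x in part.split("-")) for part in s.split(";")]


def write_cohort(ds: CohortDataset, outdir) -> None:
    """Write the TSV layout: composition.tsv, scfa.tsv, events.tsv, genes.tsv,
    truth.json (when ground truth is attached).  Deterministic float
    formatting makes same-seed exports byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.composition.to_csv(
        outdir / "composition.tsv", sep="\t", float_format=_FLOAT_FMT,
        index_label="sample_id",
    )
    ds.scfa.to_csv(
        outdir / "scfa.tsv", sep="\t", float_format=_FLOAT_FMT,
        index_label="sample_id",
    )
    ev = ds.events.copy()
    ev["antibiotic_intervals"] = [
        _intervals_to_str(iv) for iv in ev["antibiotic_intervals"]
    ]
    ev.to_csv(outdir / "events.tsv", sep="\t", index_label="subject_id")
    ds.genes.to_csv(outdir / "genes.tsv", sep="\t", index_label="sample_id")
    if ds.truth is not None:
        with open(outdir / "truth.json", "w") as fh:
            json.dump([t.to_dict() for t in ds.truth], fh, indent=1, sort_keys=True)


def read_cohort(indir) -> CohortDataset:
    indir = Path(indir)
    composition = pd.read_csv(indir / "composition.tsv", sep="\t", index_col="sample_id")
    scfa = pd.read_csv(indir / "scfa.tsv", sep="\t", index_col="sample_id")
    events = pd.read_csv(indir / "events.tsv", sep="\t", index_col="subject_id")
    events["antibiotic_intervals"] = [
        _intervals_from_str(s) for s in events["antibiotic_intervals"].fillna("")
    ]
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", index_col="sample_id")
    truth = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = [SubjectTruth.from_dict(d) for d in json.load(fh)]
    return CohortDataset(
        composition=composition, scfa=scfa, events=events, genes=genes, truth=truth
    )
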
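"""Rule-based genotype calling from gene-catalogue hit tables.

Covers: filtering sequence-similarity hits at the e-value/identity cutoffs,
mapping amplicon phylotypes to their top-hit genomes, calling butyrate-
production pathways per phylotype against editable pathway definitions,
summing butyrate-producer abundance per sample, partitioning the combined
B. longum amplicon fraction into subspecies with a qPCR ratio, the five-way
sample subgrouping by feeding / bifidobacterial colonisation / fucosylated-HMO
gene complement, and rank-based subgroup comparisons of SCFA concentrations.

Boundary semantics for the hit filter: e-value strictly below the cutoff,
identity at or above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu

from .associations import bh_adjust
from .cohort import GENE_COLUMNS, SCFA_COLUMNS

logger = logging.getLogger(__name__)

SUBGROUPS = [
    "weaned",
    "breastfed_low_bifido",
    "no_route",
    "partial_route",
    "complete_route",
]
UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# Hit filtering and genome assignment
# ---------------------------------------------------------------------------

def filter_hits(hits: pd.DataFrame, e_max: float = 1e-5, id_min: float = 70.0) -> pd.DataFrame:
    """Keep hits with e-value < ``e_max`` and percent identity >= ``id_min``."""
    if e_max <= 0 or not 0 <= id_min <= 100:
        raise ValueError("require e_max > 0 and id_min in [0, 100]")
    if hits.empty:
        return hits.copy()
    keep = (hits["evalue"] < e_max) & (hits["pident"] >= id_min)
    return hits.loc[keep].copy()


def assign_top_genome(hits: pd.DataFrame, phylotypes=None) -> tuple[dict[str, str], list[str]]:
    """Map each phylotype to the genome with the highest bit score.

    Ties go to the lexicographically smallest genome id (logged).  Returns
    (mapping, unmapped phylotypes); ``phylotypes`` optionally supplies the full
    universe so queries without hits are reported as unmapped.
    """
    mapping: dict[str, str] = {}
    for query, grp in hits.groupby("query"):
        best = grp["bitscore"].max()
        winners = sorted(grp.loc[grp["bitscore"] == best, "subject"].unique())
        if len(winners) > 1:
            logger.info("top-genome tie for %s: %s -> %s", query, winners, winners[0])
        mapping[str(query)] = winners[0]
    universe = set(map(str, phylotypes)) if phylotypes is not None else set()
    unmapped = sorted(universe - set(mapping))
    return mapping, unmapped


# ---------------------------------------------------------------------------
# Butyrate pathway calling
# ---------------------------------------------------------------------------

@dataclass
class PathwayDefinition:
    """Core genes plus terminal alternatives for one butyrate-production route."""

    name: str
    core_genes: frozenset[str]
    terminal_genes: frozenset[str] = frozenset()
    required_core_fraction: float = 1.0

    def __post_init__(self):
        self.core_genes = frozenset(self.core_genes)
        self.terminal_genes = frozenset(self.terminal_genes)
        if not 0 < self.required_core_fraction <= 1:
            raise ValueError("required_core_fraction must be in (0, 1]")
        if self.name == "acetyl-CoA" and not self.terminal_genes:
            raise ValueError("the acetyl-CoA pathway needs terminal alternatives")


def load_pathway_definitions(path=None) -> dict[str, PathwayDefinition]:
    """Load pathway definitions from YAML (the shipped default covers the four
    butyrate routes: acetyl-CoA with but/buk terminals, glutarate,
    4-aminobutyrate and lysine)."""
    if path is None:
        ref = resources.files("scfaphase.data") / "butyrate_pathways.yaml"
        doc = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    defs = {}
    for entry in doc["pathways"]:
        d = PathwayDefinition(
            name=entry["name"],
            core_genes=frozenset(entry["core_genes"]),
            terminal_genes=frozenset(entry.get("terminal_genes", [])),
            required_core_fraction=float(entry.get("required_core_fraction", 1.0)),
        )
        defs[d.name] = d
    return defs


def call_butyrate_pathways(
    hits: pd.DataFrame, definitions: dict[str, PathwayDefinition] | None = None
) -> pd.DataFrame:
    """Per-phylotype pathway presence from a filtered hit table.

    ``hits`` needs columns ``phylotype``, ``gene`` and ``pathway``.  A pathway
    is present when at least ``required_core_fraction`` of its core genes are
    hit and, where terminal alternatives are defined, at least one terminal
    gene is hit (the terminal that fired is recorded, e.g. but vs buk).  A
    phylotype is a producer when any pathway is present.  Hits tagged with an
    unknown pathway are ignored with a warning.
    """
    definitions = definitions or load_pathway_definitions()
    known = set(definitions)
    if not hits.empty:
        bad = set(hits["pathway"].unique()) - known
        if bad:
            logger.warning("ignoring hits with unknown pathway tag(s): %s", sorted(bad))
            hits = hits[hits["pathway"].isin(known)]
    rows = []
    for phylotype, grp in hits.groupby("phylotype"):
        genes = set(grp["gene"])
        rec: dict = {"phylotype": phylotype}
        producer = False
        for name, pdef in definitions.items():
            n_core = len(pdef.core_genes & genes)
            core_ok = (
                len(pdef.core_genes) > 0
                and n_core / len(pdef.core_genes) >= pdef.required_core_fraction - 1e-12
            )
            terminals = sorted(pdef.terminal_genes & genes)
            terminal_ok = bool(terminals) if pdef.terminal_genes else True
            present = core_ok and terminal_ok
            rec[name] = present
            rec[f"{name}_terminal"] = terminals[0] if (present and terminals) else ""
            producer = producer or present
        rec["producer"] = producer
        rows.append(rec)
    cols = ["phylotype"]
    for name in definitions:
        cols += [name, f"{name}_terminal"]
    cols.append("producer")
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def producer_abundance(
    calls: pd.DataFrame,
    composition: pd.DataFrame,
    phylotype_to_taxon: dict[str, str] | None = None,
) -> pd.Series:
    """Per-sample summed relative abundance of butyrate-producer phylotypes.

    ``composition`` columns are phylotype (or taxon-bin) abundances;
    ``phylotype_to_taxon`` optionally maps call-table phylotype ids onto
    composition columns.
    """
    producers = set(calls.loc[calls["producer"], "phylotype"])
    if phylotype_to_taxon:
        producers = {phylotype_to_taxon.get(p, p) for p in producers}
    cols = [c for c in composition.columns if c in producers]
    if not cols:
        return pd.Series(0.0, index=composition.index, name="producer_abundance")
    return composition[cols].sum(axis=1).rename("producer_abundance")


# ---------------------------------------------------------------------------
# Subspecies partitioning
# ---------------------------------------------------------------------------

def subspecies_partition(amplicon_abundance: float, qpcr_ratio) -> tuple[float, float]:
    """Split a combined B. longum amplicon fraction into (infantis, longum)
    proportional to the qPCR enumeration ratio; the parts sum to the input."""
    a, b = float(qpcr_ratio[0]), float(qpcr_ratio[1])
    if amplicon_abundance < 0 or a < 0 or b < 0:
        raise ValueError("abundance and ratio components must be >= 0")
    if a == 0 and b == 0:
        raise ValueError("qPCR ratio components cannot both be zero")
    infantis = amplicon_abundance * a / (a + b)
    return infantis, amplicon_abundance - infantis


# ---------------------------------------------------------------------------
# Five-way subgrouping and SCFA comparison
# ---------------------------------------------------------------------------

def assign_subgroups(
    feeding: pd.Series,
    bifido_fraction: pd.Series,
    genes: pd.DataFrame,
    bifido_threshold: float = 0.1,
) -> pd.Series:
    """Ordered decision list mapping each sample to one of five subgroups.

    1. weaned;
    2. breastfed with Bifidobacteriales below ``bifido_threshold``;
    then, breastfed and colonised, by fucosylated-HMO gene complement:
    3. no route gene, 4. partial route (some but not all of a complete set),
    5. complete route (FL-SBP, or extracellular fucosidase together with FucP).
    Samples missing their genotype record are labelled 'unclassified'.
    """
    labels = {}
    for sample in feeding.index:
        if feeding.loc[sample] == "weaned":
            labels[sample] = "weaned"
            continue
        if bifido_fraction.loc[sample] < bifido_threshold:
            labels[sample] = "breastfed_low_bifido"
            continue
        if sample not in genes.index or genes.loc[sample, GENE_COLUMNS].isna().any():
            labels[sample] = UNCLASSIFIED
            continue
        g = genes.loc[sample]
        fl_sbp, fucp, fucosidase = (bool(g[c]) for c in GENE_COLUMNS)
        if fl_sbp or (fucosidase and fucp):
            labels[sample] = "complete_route"
        elif fl_sbp or fucp or fucosidase:
            labels[sample] = "partial_route"
        else:
            labels[sample] = "no_route"
    out = pd.Series(labels, name="subgroup").reindex(feeding.index)
    n_uncl = int((out == UNCLASSIFIED).sum())
    if n_uncl:
        logger.info("%d sample(s) unclassified (missing genotype record)", n_uncl)
    return out


def subgroup_scfa_compare(
    labels: pd.Series,
    scfa: pd.DataFrame,
    metabolites=SCFA_COLUMNS,
    reference: str = "complete_route",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median/IQR per subgroup per metabolite, plus Mann-Whitney comparisons of
    the reference subgroup against every other, BH-corrected across all tests.

    Returns (summaries, tests); comparisons against empty subgroups are
    skipped and noted in the log.
    """
    labels = labels.reindex(scfa.index)
    summaries = []
    for sub, grp in scfa.groupby(labels):
        for met in metabolites:
            v = grp[met]
            summaries.append({
                "subgroup": sub, "metabolite": met, "n": int(len(v)),
                "median": float(v.median()),
                "q25": float(v.quantile(0.25)), "q75": float(v.quantile(0.75)),
            })
    summaries = pd.DataFrame(summaries)

    tests = []
    ref_mask = labels == reference
    if not ref_mask.any():
        logger.info("reference subgroup %r empty; no comparisons run", reference)
        return summaries, pd.DataFrame(
            columns=["metabolite", "subgroup", "statistic", "p", "q"]
        )
    others = [s for s in labels.dropna().unique() if s not in (reference, UNCLASSIFIED)]
    for sub in sorted(others):
        mask = labels == sub
        if not mask.any():
            logger.info("subgroup %r empty; comparison skipped", sub)
            continue
        for met in metabolites:
            stat, p = mannwhitneyu(
                scfa.loc[ref_mask, met], scfa.loc[mask, met], alternative="two-sided"
            )
            tests.append({"metabolite": met, "subgroup": sub,
                          "statistic": float(stat), "p": float(p)})
    tests = pd.DataFrame(tests)
    if not tests.empty:
        tests["q"] = bh_adjust(tests["p"].to_numpy())
    return summaries, tests
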
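"""Seeded synthetic source data for end-to-end testing without downloads.

The generators emulate the two upstream corpora at the schema subset the
pipeline's filters actually read:

* a DrugBank-dialect XML file of drugs with group, molecule type, SMILES and
  interaction descriptions (some mentioning metabolism, some not);
* FooDB-dialect JSON tables (``Content``, ``Compound``, ``HealthEffect``)
  mixing valid composition rows with rows that the filters must reject
  (non-DATABASE citations, unmapped compounds, missing amounts, compounds
  without health effects or SMILES).

Each generator writes a manifest naming exactly the records that must
survive the corresponding parser, so parser correctness is a round-trip
property.  A catalogue of tiny named graphs with hand-computed scorer values
and a planted two-cluster random graph support the link-prediction and
evaluation tests.

All output is deterministic: the same spec (including seed) reproduces the
files byte for byte.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from lxml import etree

from fdinet.ingest import food_compound_node_id

logger = logging.getLogger(__name__)

#: Vetted valid SMILES; ethanol first by convention.  Small drug-like and
#: food-constituent molecules, all parseable by RDKit.
VETTED_SMILES: tuple[str, ...] = (
    "CCO",                                        # ethanol
    "CC(=O)Oc1ccccc1C(=O)O",                      # aspirin
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",               # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                 # ibuprofen
    "C(C(=O)O)N",                                 # glycine
    "CC(N)C(=O)O",                                # alanine
    "NCCCCC(N)C(=O)O",                            # lysine
    "OC(=O)CCCCCCCC=CCCCCCCCC",                   # oleic-acid-like C18:1
    "OC(=O)CCCCCCCC=CCC=CCCCCC",                  # linoleic-acid-like
    "Oc1ccc(cc1OC)CC=C",                          # eugenol
    "Cc1ccc(cc1)C(C)C",                           # p-cymene
    "Cc1ccc(C(C)C)cc1O",                          # carvacrol
    "OCC1OC(O)C(O)C(O)C1O",                       # glucose
    "OC(=O)c1ccccc1",                             # benzoic acid
    "O=C(O)C=Cc1ccccc1",                          # cinnamic acid
    "Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2",    # catechin-like flavanol
    "O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12",    # kaempferol
    "CC(C)=CCCC(C)=CCO",                          # geraniol
    "CC1=CCC(CC1)C(C)C",                          # terpinene-like
    "C1CCCCC1",                                   # cyclohexane
    "c1ccccc1",                                   # benzene
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                 # theobromine-like
    "NC(CO)C(=O)O",                               # serine
    "CC(C)C(N)C(=O)O",                            # valine
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",                 # citric acid
    "OC(=O)C(O)C(O)C(=O)O",                       # tartaric acid
    "CSCCC(N)C(=O)O",                             # methionine
    "NC(Cc1ccccc1)C(=O)O",                        # phenylalanine
    "OCC(O)CO",                                   # glycerol
    "CC(=O)NC1C(O)OC(CO)C(O)C1O",                 # N-acetylglucosamine-like
)

#: Homologous series used to extend the pool combinatorially; each template
#: stays syntactically valid for any chain length >= 1.
_SERIES_TEMPLATES: tuple[str, ...] = (
    "{chain}O",          # alcohols
    "{chain}C(=O)O",     # carboxylic acids
    "{chain}N",          # amines
    "{chain}c1ccccc1",   # alkylbenzenes
)
_MAX_CHAIN = 40


def generate_smiles_pool(n: int, seed: int) -> list[str]:
    """Return ``n`` valid SMILES, deterministically for a given seed.

    The vetted list is used first; further strings come from homologous
    series (alcohols, acids, amines, alkylbenzenes) with growing chain
    length.  If ``n`` exceeds the pool capacity the pool cycles and a
    warning is logged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = list(VETTED_SMILES)
    chain = 2
    while len(pool) < n and chain <= _MAX_CHAIN:
        for template in _SERIES_TEMPLATES:
            candidate = template.format(chain="C" * chain)
            if candidate not in pool:
                pool.append(candidate)
        chain += 1
    if n > len(pool):
        logger.warning("requested %d SMILES exceeds pool capacity %d; cycling", n, len(pool))
        pool = [pool[i % len(pool)] for i in range(n)]
    rng = random.Random(seed)
    head, tail = pool[: len(VETTED_SMILES)], pool[len(VETTED_SMILES):]
    rng.shuffle(tail)  # vetted molecules keep their order; series order varies by seed
    return (head + tail)[:n]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic corpus.

    ``fraction_metabolism_ddi`` is the fraction of approved small molecules
    given a metabolism-related interaction description (the survivors of the
    drug filter).  ``fraction_approved`` and ``fraction_biotech`` control the
    group/type mix so filter rejection paths are exercised.
    """

    n_drugs: int = 20
    n_foods: int = 8
    compounds_per_food: tuple[int, int] = (2, 6)
    fraction_metabolism_ddi: float = 0.6
    seed: int = 0
    fraction_approved: float = 0.85
    fraction_biotech: float = 0.15

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_foods < 1:
            raise ValueError("n_drugs and n_foods must be >= 1")
        lo, hi = self.compounds_per_food
        if lo < 1 or hi < lo:
            raise ValueError("compounds_per_food must be a range with 1 <= lo <= hi")
        for name in ("fraction_metabolism_ddi", "fraction_approved", "fraction_biotech"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# DrugBank-dialect XML
# ---------------------------------------------------------------------------

def _drug_smiles_pool(n: int, seed: int) -> list[str]:
    """Drug SMILES mixing diverse vetted molecules with analog series.

    Approved-drug chemical space contains families of close structural
    analogs; interleaving homologous-series members (chain length >= 4,
    where neighboring homologs exceed the usual 0.6 Tanimoto band) with the
    diverse vetted list reproduces that clustered similarity structure, so
    thresholded fixture graphs have a non-trivial drug-drug subnetwork.
    """
    series = [
        template.format(chain="C" * c)
        for c in range(5, 6 + n // 6)
        for template in _SERIES_TEMPLATES
    ]
    rng = random.Random(seed)
    vetted = list(VETTED_SMILES)
    rng.shuffle(vetted)
    pool = []
    n_series = n_vetted = 0
    for i in range(max(n, 1)):
        if i % 3 == 0:  # one diverse molecule per two analog-family members
            pool.append(vetted[n_vetted % len(vetted)])
            n_vetted += 1
        else:
            pool.append(series[n_series % len(series)])
            n_series += 1
    return pool


_METABOLISM_TEXTS = (
    "The metabolism of {other} can be decreased when combined with {this}.",
    "The metabolism of {other} can be increased when combined with {this}.",
)
_OTHER_TEXTS = (
    "The risk or severity of adverse effects can be increased when {this} is combined with {other}.",
    "{this} may decrease the excretion rate of {other}.",
)


def generate_drugbank_fixture(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write ``drugbank.xml`` and ``drugbank_manifest.tsv`` under ``out_dir``.

    The manifest lists every drug id with a ``survives`` flag: 1 exactly when
    the drug is an approved small molecule with a metabolism-related
    interaction description (the drug-filter survivors).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    smiles_pool = _drug_smiles_pool(spec.n_drugs, spec.seed)

    n = spec.n_drugs
    n_biotech = round(n * spec.fraction_biotech)
    n_approved = round(n * spec.fraction_approved)
    is_biotech = [i < n_biotech for i in range(n)]
    is_approved = [i < n_approved for i in range(n)]
    rng.shuffle(is_biotech)
    rng.shuffle(is_approved)

    qualified = [i for i in range(n) if is_approved[i] and not is_biotech[i]]
    n_metab = round(spec.fraction_metabolism_ddi * len(qualified))
    metab_set = set(qualified[:n_metab])  # qualified order is already seed-shuffled

    root = etree.Element("drugbank")
    manifest_rows = []
    for i in range(n):
        drug_id = f"DB{i + 1:05d}"
        drug = etree.SubElement(
            root, "drug", type="biotech" if is_biotech[i] else "small molecule"
        )
        etree.SubElement(drug, "drugbank-id").text = drug_id
        etree.SubElement(drug, "name").text = f"Drug{i + 1}"
        groups = etree.SubElement(drug, "groups")
        etree.SubElement(groups, "group").text = "approved" if is_approved[i] else "experimental"
        if not is_biotech[i]:
            etree.SubElement(drug, "smiles").text = smiles_pool[i % len(smiles_pool)]
        interactions = etree.SubElement(drug, "drug-interactions")
        other = f"Drug{(i + 2) % n + 1}"
        texts = _METABOLISM_TEXTS if i in metab_set else _OTHER_TEXTS
        for text in texts[: rng.randint(1, len(texts))]:
            interaction = etree.SubElement(interactions, "drug-interaction")
            etree.SubElement(interaction, "name").text = other
            etree.SubElement(interaction, "description").text = text.format(
                this=f"Drug{i + 1}", other=other
            )
        survives = is_approved[i] and not is_biotech[i] and i in metab_set
        manifest_rows.append((drug_id, int(survives)))

    xml_path = out_dir / "drugbank.xml"
    etree.ElementTree(root).write(str(xml_path), pretty_print=True, encoding="utf-8")
    with open(out_dir / "drugbank_manifest.tsv", "w") as fh:
        fh.write("drug_id\tsurvives\n")
        for drug_id, survives in manifest_rows:
            fh.write(f"{drug_id}\t{survives}\n")
    return xml_path


# ---------------------------------------------------------------------------
# FooDB-dialect JSON
# ---------------------------------------------------------------------------

def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def generate_foodb_fixture(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write ``Content.json``, ``Compound.json``, ``HealthEffect.json`` and
    ``foodb_manifest.tsv`` under ``out_dir``.

    Content amounts are uniform on [1, 1000] mg/100 g.  Besides valid rows
    the tables contain rows each filter must reject: ARTICLE citations,
    EXPERIMENT source types, rows without any amount, compounds lacking a
    health-effect link, and one compound without a SMILES.  Some valid rows
    report a (min, max) range instead of a scalar amount.  The manifest lists
    the node ids that must survive parsing under the default configuration
    (health-effect filter on, ranges collapsed to their maximum).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed + 1)

    lo, hi = spec.compounds_per_food
    n_compounds = max(hi + 2, spec.n_foods)
    smiles_pool = generate_smiles_pool(n_compounds, spec.seed + 1)

    compounds = []
    no_effect_ids: set[int] = set()
    for j in range(n_compounds):
        cid = j + 1
        row = {
            "id": cid,
            "public_id": f"FDB{cid:06d}",
            "name": f"Compound{cid}",
            "moldb_smiles": smiles_pool[j],
        }
        if j == n_compounds - 1 and n_compounds > 2:
            row["moldb_smiles"] = ""  # unmapped structure: must be rejected
        compounds.append(row)
    # last quarter of compounds carry no health effect
    n_no_effect = max(1, n_compounds // 4) if n_compounds > 2 else 0
    no_effect_ids = {n_compounds - 1 - k for k in range(n_no_effect)}
    effects = [
        {"id": k + 1, "compound_id": c["id"], "health_effect": f"effect_{(k % 5) + 1}"}
        for k, c in enumerate(compounds)
        if (c["id"] - 1) not in no_effect_ids
    ]

    content = []
    manifest_rows = []
    row_id = 0
    for f in range(spec.n_foods):
        food_id = f"FOOD{f + 1:05d}"
        k = rng.randint(lo, min(hi, n_compounds))
        chosen = rng.sample(range(n_compounds), k)
        for j in chosen:
            compound = compounds[j]
            row_id += 1
            row = {
                "id": row_id,
                "food_id": food_id,
                "source_id": compound["id"],
                "source_type": "COMPOUND",
                "citation_type": "DATABASE",
                "orig_unit": "mg/100g",
            }
            amount = round(rng.uniform(1.0, 1000.0), 3)
            style = rng.random()
            if style < 0.2:  # range-style row; max collapse keeps it
                row["orig_min"] = round(amount * rng.uniform(0.0, 0.9), 3)
                row["orig_max"] = amount
            elif style < 0.3:  # no amount at all: rejected
                pass
            else:
                row["orig_content"] = amount
            content.append(row)
            has_amount = "orig_content" in row or "orig_max" in row
            survives = (
                has_amount
                and bool(compound["moldb_smiles"])
                and (compound["id"] - 1) not in no_effect_ids
            )
            if survives:
                node_id = food_compound_node_id(food_id, compound["public_id"], compound["name"])
                manifest_rows.append((node_id, food_id, compound["public_id"], amount))
        # noise rows that every run must reject
        row_id += 1
        content.append(
            {
                "id": row_id,
                "food_id": food_id,
                "source_id": compounds[rng.randrange(n_compounds)]["id"],
                "source_type": "COMPOUND",
                "citation_type": "ARTICLE",
                "orig_content": round(rng.uniform(1.0, 1000.0), 3),
                "orig_unit": "mg/100g",
            }
        )
        row_id += 1
        content.append(
            {
                "id": row_id,
                "food_id": food_id,
                "source_id": compounds[rng.randrange(n_compounds)]["id"],
                "source_type": "EXPERIMENT",
                "citation_type": "DATABASE",
                "orig_content": round(rng.uniform(1.0, 1000.0), 3),
                "orig_unit": "mg/100g",
            }
        )

    _dump_json(content, out_dir / "Content.json")
    _dump_json(compounds, out_dir / "Compound.json")
    _dump_json(effects, out_dir / "HealthEffect.json")
    with open(out_dir / "foodb_manifest.tsv", "w") as fh:
        fh.write("node_id\tfood_id\tcompound_id\torig_content\n")
        for node_id, food_id, public_id, amount in manifest_rows:
            fh.write(f"{node_id}\t{food_id}\t{public_id}\t{amount!r}\n")
    return out_dir


def read_manifest(path: str | Path) -> list[dict]:
    """Read a fixture manifest TSV into a list of dict rows."""
    rows = []
    with open(path) as fh:
        header = next(fh).rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows


# ---------------------------------------------------------------------------
# Toy graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyGraph:
    """A tiny named graph with hand-computed scorer values.

    ``expected`` maps a scorer name to ``{(node_a, node_b): value}`` for the
    pairs whose score was worked out by hand when the graph was catalogued.
    """

    name: str
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    labels: dict[str, str] = field(default_factory=dict)
    expected: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)


def _toy_catalogue() -> dict[str, ToyGraph]:
    import math

    return {
        "triangle": ToyGraph(
            name="triangle",
            nodes=("a", "b", "c"),
            edges=(("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)),
            labels={"a": "drug", "b": "drug", "c": "drug"},
            expected={},  # no non-adjacent pair exists
        ),
        "two_components": ToyGraph(
            name="two_components",
            nodes=("a", "b", "c", "d"),
            edges=(("a", "b", 0.9), ("c", "d", 0.8)),
            labels={"a": "drug", "b": "drug", "c": "food_compound", "d": "food_compound"},
            expected={"cn": {("a", "c"): 0.0, ("a", "d"): 0.0}},
        ),
        "l3_path": ToyGraph(
            # single 3-edge path a-u-v-b with unit weights: L3 = 1/sqrt(2*2)
            name="l3_path",
            nodes=("a", "u", "v", "b"),
            edges=(("a", "u", 1.0), ("u", "v", 1.0), ("v", "b", 1.0)),
            labels={"a": "drug", "u": "food_compound", "v": "food_compound", "b": "drug"},
            expected={"l3": {("a", "b"): 0.5}, "sp3": {("a", "b"): 3.0}, "cn": {("a", "v"): 1.0}},
        ),
        "square": ToyGraph(
            # 4-cycle: each diagonal pair has two common neighbors of degree 2
            name="square",
            nodes=("a", "b", "c", "d"),
            edges=(("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("d", "a", 1.0)),
            labels={"a": "drug", "b": "drug", "c": "drug", "d": "drug"},
            expected={
                "cn": {("a", "c"): 2.0},
                "aa": {("a", "c"): 2.0 / math.log(2.0)},
                "ra": {("a", "c"): 1.0},
                "jaccard": {("a", "c"): 1.0},
                "dice": {("a", "c"): 1.0},
                "sp2": {("a", "c"): 2.0},
            },
        ),
        "kite": ToyGraph(
            # z joins a and b; z also touches c and d, so k_z = 4
            name="kite",
            nodes=("a", "b", "z", "c", "d"),
            edges=(("a", "z", 0.7), ("b", "z", 0.6), ("z", "c", 1.0), ("z", "d", 1.0)),
            labels={n: "drug" for n in ("a", "b", "z", "c", "d")},
            expected={
                "cn": {("a", "b"): 1.0},
                "aa": {("a", "b"): 1.0 / math.log(4.0)},
                "ra": {("a", "b"): 0.25},
                "jaccard": {("a", "b"): 1.0},
                "sp2": {("a", "b"): 1.3},
            },
        ),
        "planted_partition": ToyGraph(
            # two 4-cliques joined by a single weak edge
            name="planted_partition",
            nodes=tuple("abcdefgh"),
            edges=tuple(
                [(x, y, 1.0) for x, y in
                 [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]]
                + [(x, y, 1.0) for x, y in
                   [("e", "f"), ("e", "g"), ("e", "h"), ("f", "g"), ("f", "h"), ("g", "h")]]
                + [("d", "e", 0.6)]
            ),
            labels={n: "drug" for n in "abcdefgh"},
            expected={"cn": {("a", "e"): 1.0, ("a", "f"): 0.0}},
        ),
    }


TOY_GRAPH_NAMES: tuple[str, ...] = tuple(_toy_catalogue())


def generate_toy_graph(name: str) -> ToyGraph:
    """Return a catalogued toy graph by name; unknown names raise KeyError."""
    catalogue = _toy_catalogue()
    if name not in catalogue:
        raise KeyError(f"unknown toy graph {name!r}; known: {sorted(catalogue)}")
    return catalogue[name]


def write_toy_catalogue(path: str | Path) -> None:
    """Dump the toy-graph catalogue (without expected values) as JSON."""
    out = {
        g.name: {"nodes": list(g.nodes), "edges": [list(e) for e in g.edges], "labels": g.labels}
        for g in _toy_catalogue().values()
    }
    _dump_json(out, Path(path))


def generate_planted_graph(
    n_nodes: int = 150,
    n_clusters: int = 2,
    p_in: float = 0.7,
    p_out: float = 0.05,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.6, 1.0),
) -> ToyGraph:
    """A seeded planted-partition graph for recovery experiments.

    Nodes split evenly into ``n_clusters`` communities; an edge appears with
    probability ``p_in`` inside a community and ``p_out`` across, weighted
    uniformly on ``weight_range`` (the post-threshold similarity band).
    The dense ``p_in`` emulates the near-clique blocks that Tanimoto
    thresholding leaves among close structural analogs, against a sparse
    cross-cluster background; node kinds are assigned at random so all
    three subnetwork labels occur.
    """
    rng = random.Random(seed)
    nodes = tuple(f"N{i:04d}" for i in range(n_nodes))
    cluster = {nodes[i]: i % n_clusters for i in range(n_nodes)}
    labels = {n: ("drug" if rng.random() < 0.5 else "food_compound") for n in nodes}
    lo, hi = weight_range
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            p = p_in if cluster[nodes[i]] == cluster[nodes[j]] else p_out
            if rng.random() < p:
                edges.append((nodes[i], nodes[j], round(rng.uniform(lo, hi), 6)))
    return ToyGraph(name="planted", nodes=nodes, edges=tuple(edges), labels=labels)
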
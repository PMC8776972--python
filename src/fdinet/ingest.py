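"""Parsing and filtering of drug and food-composition source tables.

Two source dialects are read:

* a DrugBank-style XML subset carrying, per drug: primary id, name, group
  memberships (approved / experimental / ...), molecule type (small molecule
  vs biotech), a SMILES string, and free-text interaction descriptions;
* a FooDB-style JSON subset of three tables -- ``Content`` (food-to-compound
  composition rows with provenance fields and amounts), ``Compound``
  (compound id, public FDB id, name, SMILES) and ``HealthEffect``
  (compound-to-health-effect links).

Drugs are kept only when they are approved small molecules with at least one
metabolism-related interaction description and a parseable SMILES.  Content
rows are kept only when cited from a reference database (``citation_type ==
"DATABASE"``), sourced from a compound record (``source_type == "COMPOUND"``),
mapped to a compound with a SMILES and an amount, and (optionally) linked to a
reported health effect.

Each surviving (food, compound) pair becomes its own graph node named
``FOODxxxx_FDBxxxxxx_CompoundName`` so that the same compound appearing in two
foods yields two distinct nodes, each carrying the contribution of the
compound within that particular food: its content amount divided by the total
content of all included compounds of the food.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

DRUG = "drug"
FOOD_COMPOUND = "food_compound"

#: Keyword deciding whether an interaction description is metabolism-related.
METABOLISM_PATTERN = re.compile(r"metabolism", re.IGNORECASE)

CONTENT_RANGE_MODES = ("min", "max", "mean")


@dataclass(frozen=True, order=True)
class ChemNode:
    """A chemical entity in the homogeneous graph.

    ``node_id`` is the drug accession for drugs, or
    ``FOODxxxx_FDBxxxxxx_CompoundName`` for a compound instance within one
    food.  Food-compound nodes carry both ``food_id`` and ``compound_id``;
    drug nodes carry neither.
    """

    node_id: str
    kind: str
    smiles: str
    food_id: str | None = None
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (DRUG, FOOD_COMPOUND):
            raise ValueError(f"unknown node kind: {self.kind!r}")
        if self.kind == FOOD_COMPOUND and (self.food_id is None or self.compound_id is None):
            raise ValueError(f"food-compound node {self.node_id!r} needs food_id and compound_id")
        if self.kind == DRUG and (self.food_id is not None or self.compound_id is not None):
            raise ValueError(f"drug node {self.node_id!r} must not carry food/compound ids")


@dataclass(frozen=True)
class CompositionEntry:
    """One compound's amount and normalized contribution within one food.

    ``orig_content`` is in mg/100 g.  ``contribution`` is the amount divided
    by the summed amounts of all included compounds of the food, so per-food
    contributions sum to 1.
    """

    food_id: str
    compound_id: str
    orig_content: float
    contribution: float | None = None


class IngestError(ValueError):
    """Raised for malformed or degenerate source data."""


def sanitize_name(name: str) -> str:
    """Make a compound name safe for whitespace-delimited node ids."""
    return re.sub(r"\s+", "_", name.strip())


def food_compound_node_id(food_id: str, public_id: str, name: str) -> str:
    return f"{food_id}_{public_id}_{sanitize_name(name)}"


# ---------------------------------------------------------------------------
# DrugBank-style XML
# ---------------------------------------------------------------------------

def parse_drugbank(xml_path: str | Path) -> list[ChemNode]:
    """Parse a DrugBank-dialect XML file into drug nodes.

    Keeps drugs that are in the ``approved`` group, of type
    ``small molecule``, and have at least one interaction description
    mentioning metabolism.  Drugs without a SMILES are dropped with a
    warning; duplicate ids are collapsed to the first occurrence.
    """
    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except etree.XMLSyntaxError as exc:
        raise IngestError(f"malformed XML in {xml_path}: {exc}") from exc

    nodes: list[ChemNode] = []
    seen: set[str] = set()
    for drug in tree.getroot().iterfind("drug"):
        drug_id = drug.findtext("drugbank-id", default="").strip()
        if not drug_id or drug_id in seen:
            continue
        groups = {g.text.strip() for g in drug.iterfind("groups/group") if g.text}
        drug_type = (drug.get("type") or "").strip()
        if "approved" not in groups or drug_type != "small molecule":
            continue
        descriptions = [
            d.text for d in drug.iterfind("drug-interactions/drug-interaction/description") if d.text
        ]
        if not any(METABOLISM_PATTERN.search(d) for d in descriptions):
            continue
        smiles = drug.findtext("smiles", default="").strip()
        if not smiles:
            logger.warning("drug %s has no SMILES; excluded", drug_id)
            continue
        seen.add(drug_id)
        nodes.append(ChemNode(node_id=drug_id, kind=DRUG, smiles=smiles))
    return nodes


# ---------------------------------------------------------------------------
# FooDB-style JSON
# ---------------------------------------------------------------------------

def _load_table(json_dir: Path, name: str) -> list[dict]:
    path = json_dir / f"{name}.json"
    if not path.exists():
        raise IngestError(f"missing table {name}.json in {json_dir}")
    with open(path) as fh:
        return json.load(fh)


def _scalar_content(row: Mapping, mode: str) -> float | None:
    """Collapse a content value or (min, max) range to one amount in mg/100 g."""
    value = row.get("orig_content")
    lo, hi = row.get("orig_min"), row.get("orig_max")
    if value is not None:
        return float(value)
    if lo is None or hi is None:
        return None
    lo, hi = float(lo), float(hi)
    if mode == "min":
        return lo
    if mode == "max":
        return hi
    return (lo + hi) / 2.0


def parse_foodb(
    json_dir: str | Path,
    *,
    health_effect_filter: bool = True,
    content_range_mode: str = "max",
) -> tuple[list[ChemNode], list[CompositionEntry]]:
    """Parse FooDB-dialect JSON tables into food-compound nodes and entries.

    Parameters
    ----------
    json_dir:
        Directory containing ``Content.json``, ``Compound.json`` and
        ``HealthEffect.json``.
    health_effect_filter:
        When true (default) a content row is kept only if its compound has at
        least one health-effect link.
    content_range_mode:
        How a reported (min, max) content range collapses to one amount:
        ``"min"``, ``"max"`` (default; the conservative exposure choice) or
        ``"mean"``.  Rows reporting a plain ``orig_content`` are used as-is.

    Returns the nodes (one per surviving food x compound pair, named
    ``FOODxxxx_FDBxxxxxx_CompoundName``) and composition entries with
    contributions already normalized per food.
    """
    if content_range_mode not in CONTENT_RANGE_MODES:
        raise ValueError(f"content_range_mode must be one of {CONTENT_RANGE_MODES}")
    json_dir = Path(json_dir)
    content = _load_table(json_dir, "Content")
    compounds = {row["id"]: row for row in _load_table(json_dir, "Compound")}
    effects = _load_table(json_dir, "HealthEffect")
    compounds_with_effects = {row["compound_id"] for row in effects}

    nodes: list[ChemNode] = []
    entries: list[CompositionEntry] = []
    seen: set[str] = set()
    for row in content:
        if row.get("citation_type") != "DATABASE" or row.get("source_type") != "COMPOUND":
            continue
        compound = compounds.get(row.get("source_id"))
        if compound is None or not compound.get("moldb_smiles"):
            continue
        if health_effect_filter and compound["id"] not in compounds_with_effects:
            continue
        amount = _scalar_content(row, content_range_mode)
        if amount is None:
            logger.warning(
                "content row for food %s compound %s has no amount; excluded",
                row.get("food_id"), compound.get("public_id"),
            )
            continue
        node_id = food_compound_node_id(row["food_id"], compound["public_id"], compound["name"])
        if node_id in seen:
            continue
        seen.add(node_id)
        nodes.append(
            ChemNode(
                node_id=node_id,
                kind=FOOD_COMPOUND,
                smiles=compound["moldb_smiles"],
                food_id=row["food_id"],
                compound_id=compound["public_id"],
            )
        )
        entries.append(
            CompositionEntry(
                food_id=row["food_id"],
                compound_id=compound["public_id"],
                orig_content=amount,
            )
        )
    return nodes, compute_contributions(entries)


# ---------------------------------------------------------------------------
# Contribution scores
# ---------------------------------------------------------------------------

def compute_contributions(entries: Sequence[CompositionEntry]) -> list[CompositionEntry]:
    """Fill normalized per-food contribution scores.

    Within each food, a compound's contribution is its content divided by the
    total content of all included compounds of that food, so contributions
    lie in [0, 1] and sum to 1 per food.  A food whose included contents sum
    to zero (or are negative) is an error.
    """
    totals: dict[str, float] = {}
    for entry in entries:
        totals[entry.food_id] = totals.get(entry.food_id, 0.0) + entry.orig_content
    for food_id, total in totals.items():
        if total <= 0.0:
            raise IngestError(f"food {food_id}: total content is {total}; cannot normalize")
    return [replace(e, contribution=e.orig_content / totals[e.food_id]) for e in entries]


def contribution_map(entries: Iterable[CompositionEntry]) -> dict[tuple[str, str], float]:
    """Index contributions by (food_id, compound_id)."""
    out: dict[tuple[str, str], float] = {}
    for entry in entries:
        if entry.contribution is None:
            raise IngestError(
                f"entry ({entry.food_id}, {entry.compound_id}) lacks a contribution"
            )
        out[(entry.food_id, entry.compound_id)] = entry.contribution
    return out


def pair_contribution(
    node_a: ChemNode,
    node_b: ChemNode,
    contributions: Mapping[tuple[str, str], float],
) -> float:
    """Scaling factor applied when re-weighting a similarity edge.

    Drug-drug pairs are left untouched (factor 1).  A drug paired with a food
    compound is scaled by that compound's contribution within its food.  Two
    food compounds are scaled by the larger of their two contributions.
    """
    def _contribution(node: ChemNode) -> float:
        key = (node.food_id, node.compound_id)
        try:
            return contributions[key]
        except KeyError:
            raise IngestError(f"no contribution for food-compound node {node.node_id!r}") from None

    kinds = (node_a.kind, node_b.kind)
    if kinds == (DRUG, DRUG):
        return 1.0
    if kinds == (FOOD_COMPOUND, FOOD_COMPOUND):
        return max(_contribution(node_a), _contribution(node_b))
    food_node = node_a if node_a.kind == FOOD_COMPOUND else node_b
    return _contribution(food_node)


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def write_nodes_tsv(nodes: Sequence[ChemNode], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tkind\tsmiles\tfood_id\tcompound_id\n")
        for n in nodes:
            fh.write(
                f"{n.node_id}\t{n.kind}\t{n.smiles}\t{n.food_id or ''}\t{n.compound_id or ''}\n"
            )


def read_nodes_tsv(path: str | Path) -> list[ChemNode]:
    nodes = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            node_id, kind, smiles, food_id, compound_id = line.rstrip("\n").split("\t")
            nodes.append(
                ChemNode(node_id, kind, smiles, food_id or None, compound_id or None)
            )
    return nodes


def write_contributions_tsv(entries: Sequence[CompositionEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("food_id\tcompound_id\torig_content\tcontribution\n")
        for e in entries:
            fh.write(f"{e.food_id}\t{e.compound_id}\t{e.orig_content!r}\t{e.contribution!r}\n")


def read_contributions_tsv(path: str | Path) -> list[CompositionEntry]:
    entries = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            food_id, compound_id, content, contribution = line.rstrip("\n").split("\t")
            entries.append(
                CompositionEntry(food_id, compound_id, float(content), float(contribution))
            )
    return entries
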
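"""Structure similarity profile: circular fingerprints and Tanimoto scores.

Every chemical node is fingerprinted from its SMILES with the Morgan
(extended-connectivity) algorithm at radius 2 hashed to 2048 bits -- the
standard ECFP4 configuration.  The structure similarity profile (SSP) is the
set of pairwise Tanimoto coefficients |A∩B| / |A∪B| over all unordered node
pairs, each edge labelled by the kinds of its endpoints: DD (drug-drug),
FF (food-food) or FD (food-drug).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from fdinet.ingest import DRUG, ChemNode

RDLogger.DisableLog("rdApp.*")

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048

SUBNETWORKS = ("DD", "FF", "FD")


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass(frozen=True)
class Fingerprint:
    """Set-bit indices of a fixed-length binary substructure fingerprint."""

    bits: frozenset[int]
    n_bits: int = DEFAULT_N_BITS
    node_id: str | None = None


@dataclass(frozen=True)
class SimilarityEdge:
    """An undirected similarity edge in canonical (node_a < node_b) form."""

    node_a: str
    node_b: str
    score: float
    subnetwork: str

    def __post_init__(self) -> None:
        if self.node_a >= self.node_b:
            raise ValueError(f"edge not canonical: {self.node_a!r} !< {self.node_b!r}")
        if self.subnetwork not in SUBNETWORKS:
            raise ValueError(f"unknown subnetwork {self.subnetwork!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.node_a, self.node_b)


def fingerprint(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    node_id: str | None = None,
) -> Fingerprint:
    """Morgan/circular fingerprint of a molecule given as SMILES.

    Deterministic: two SMILES spellings of the same molecule hash to the same
    bit set.  An unparseable SMILES raises :class:`SmilesError`.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), n_bits=n_bits, node_id=node_id)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B|; 0 when both bit sets are empty."""
    if fp_a.n_bits != fp_b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {fp_a.n_bits} vs {fp_b.n_bits}")
    union = len(fp_a.bits | fp_b.bits)
    if union == 0:
        return 0.0
    return len(fp_a.bits & fp_b.bits) / union


def subnetwork_label(node_a: ChemNode, node_b: ChemNode) -> str:
    n_drugs = (node_a.kind == DRUG) + (node_b.kind == DRUG)
    return {2: "DD", 1: "FD", 0: "FF"}[n_drugs]


def build_ssp(
    nodes: Sequence[ChemNode],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> list[SimilarityEdge]:
    """All-pairs Tanimoto similarity edges over the given chemical nodes.

    One edge per unordered pair (no self-pairs), canonically ordered and
    labelled DD/FF/FD.  Nodes whose SMILES yields an empty fingerprint score
    0 against everything rather than raising, so one exotic molecule cannot
    abort a batch.  Distinct nodes sharing a SMILES (the same compound in two
    foods) are deliberately kept as separate entries.
    """
    fps = {n.node_id: fingerprint(n.smiles, radius, n_bits, n.node_id) for n in nodes}
    kinds = {n.node_id: n for n in nodes}
    edges = []
    for na, nb in combinations(sorted(fps), 2):
        edges.append(
            SimilarityEdge(
                node_a=na,
                node_b=nb,
                score=tanimoto(fps[na], fps[nb]),
                subnetwork=subnetwork_label(kinds[na], kinds[nb]),
            )
        )
    return edges


def write_edges_tsv(edges: Sequence[SimilarityEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tscore\tsubnetwork\n")
        for e in edges:
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.score!r}\t{e.subnetwork}\n")


def read_edges_tsv(path: str | Path) -> list[SimilarityEdge]:
    edges = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            node_a, node_b, score, subnetwork = line.rstrip("\n").split("\t")
            edges.append(SimilarityEdge(node_a, node_b, float(score), subnetwork))
    return edges
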
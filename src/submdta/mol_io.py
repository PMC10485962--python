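"""Molecule and affinity-table I/O plus seeded synthetic fixtures.

SMILES strings are parsed with RDKit into heavy-atom graphs with the
DeepChem/GraphDTA atom featurization: one-hot atom symbol over a fixed
44-symbol list (last slot = "other"), one-hot degree 0-10, one-hot total
hydrogen count 0-10, one-hot implicit valence 0-10, and an aromaticity
flag — 78 features per atom.  Hydrogens are implicit; only heavy atoms
become nodes.  Every bond is stored as two directed edges.

Affinity tables follow the GraphDTA CSV convention with header
``compound_iso_smiles,target_sequence,affinity``.  Davis-style raw
dissociation constants (nanomolar) are converted to pK_d with

    pK_d = -log10(K_d / 1e9)

The synthetic fixture generator assembles SMILES from a small template
grammar (chains, rings, substituents) so that parseability is guaranteed
by construction, and plants a known linear generating function into the
affinity labels:  affinity = base + w_drug * (# aromatic rings in the
drug) + w_prot * (motif present in the protein) + N(0, noise_sd).  The
planted truth is returned alongside so tests can recompute labels exactly.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit warnings are noise for batch parsing

logger = logging.getLogger(__name__)

__all__ = [
    "SmilesParseError", "SchemaError", "MolecularGraph", "AffinityRecord",
    "FixtureSpec", "SyntheticTruth", "ATOM_SYMBOLS", "ATOM_FEATURE_DIM",
    "smiles_to_graph", "kd_to_pkd", "load_dta_table", "write_dta_table",
    "read_smiles_file", "write_smiles_file", "read_fasta",
    "generate_fixture_molecules", "generate_fixture_proteins",
    "generate_synthetic_dta", "count_aromatic_rings",
]

CSV_COLUMNS = ("compound_iso_smiles", "target_sequence", "affinity")

# protein alphabet: 20 standard residues + B, Z, U, O, with X as the unknown
AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZUO"
UNKNOWN_RESIDUE = "X"
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, smiles: str, context: str = ""):
        self.smiles = smiles
        msg = f"unparseable SMILES: {smiles!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class SchemaError(ValueError):
    """Raised when a table is missing one of the expected columns."""


# --------------------------------------------------------------------------
# atom featurization (DeepChem/GraphDTA convention, frozen layout)
# --------------------------------------------------------------------------

ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "Unknown",
]
_DEGREE_CHOICES = list(range(11))
_NUM_H_CHOICES = list(range(11))
_VALENCE_CHOICES = list(range(11))

# layout: [symbol 44 | degree 11 | total H 11 | implicit valence 11 | aromatic 1]
ATOM_FEATURE_DIM = len(ATOM_SYMBOLS) + 11 + 11 + 11 + 1  # = 78


def _one_hot(value, choices, other_last: bool = False) -> list[float]:
    if value not in choices:
        if not other_last:
            raise ValueError(f"value {value!r} outside encoding range {choices}")
        value = choices[-1]
    return [1.0 if value == c else 0.0 for c in choices]


def atom_features(atom: Chem.Atom) -> np.ndarray:
    feats = (
        _one_hot(atom.GetSymbol(), ATOM_SYMBOLS, other_last=True)
        + _one_hot(atom.GetDegree(), _DEGREE_CHOICES)
        + _one_hot(atom.GetTotalNumHs(), _NUM_H_CHOICES)
        + _one_hot(atom.GetImplicitValence(), _VALENCE_CHOICES)
        + [1.0 if atom.GetIsAromatic() else 0.0]
    )
    return np.array(feats, dtype=np.float64)


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph of one molecule with fixed-layout node features."""

    smiles: str
    node_features: np.ndarray  # (n_atoms, ATOM_FEATURE_DIM)
    edges: tuple  # directed (i, j) pairs, both directions present
    n_atoms: int


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse one SMILES string into a featurized :class:`MolecularGraph`."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    n = mol.GetNumAtoms()
    feats = np.zeros((n, ATOM_FEATURE_DIM), dtype=np.float64)
    for atom in mol.GetAtoms():
        feats[atom.GetIdx()] = atom_features(atom)
    edges = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((i, j))
        edges.append((j, i))
    return MolecularGraph(smiles=smiles, node_features=feats,
                          edges=tuple(sorted(edges)), n_atoms=n)


def count_aromatic_rings(smiles: str) -> int:
    """Number of rings whose atoms are all aromatic (the planted drug feature)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    ring_info = mol.GetRingInfo()
    count = 0
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            count += 1
    return count


# --------------------------------------------------------------------------
# affinity transform and tables
# --------------------------------------------------------------------------

def kd_to_pkd(kd: float) -> float:
    """Transform a dissociation constant in nanomolar units to pK_d.

    pK_d = -log10(kd / 1e9); kd must be strictly positive.
    """
    if not (kd > 0):
        raise ValueError(f"K_d must be positive, got {kd}")
    return -math.log10(kd / 1e9)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map residues outside the declared alphabet to X."""
    seq = seq.strip().upper()
    return "".join(c if c in AMINO_ALPHABET else UNKNOWN_RESIDUE for c in seq)


@dataclass(frozen=True)
class AffinityRecord:
    """One labelled drug-target pair."""

    drug_smiles: str
    target_sequence: str
    affinity: float


def load_dta_table(path, raw_kd: bool = False,
                   validate_smiles: bool = True) -> list[AffinityRecord]:
    """Read a GraphDTA-convention CSV into affinity records, row order kept.

    With ``raw_kd=True`` the affinity column is interpreted as a raw
    nanomolar K_d and transformed to pK_d on load.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; "
                          f"expected header {','.join(CSV_COLUMNS)}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        smiles = str(getattr(row, "compound_iso_smiles"))
        if validate_smiles and Chem.MolFromSmiles(smiles) is None:
            raise SmilesParseError(smiles, context=f"{path} row {idx}")
        affinity = float(getattr(row, "affinity"))
        if raw_kd:
            affinity = kd_to_pkd(affinity)
        if not math.isfinite(affinity):
            raise ValueError(f"{path} row {idx}: non-finite affinity")
        seq = normalize_sequence(str(getattr(row, "target_sequence")))
        if not seq:
            raise ValueError(f"{path} row {idx}: empty target sequence")
        records.append(AffinityRecord(smiles, seq, affinity))
    logger.info("loaded %d affinity records from %s", len(records), path)
    return records


def write_dta_table(records: list[AffinityRecord], path) -> None:
    # affinities written with repr so tables round-trip bit-exactly
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow([r.drug_smiles, r.target_sequence, repr(r.affinity)])


def read_smiles_file(path) -> list[str]:
    """One SMILES per line; blank lines and ``#`` comments are skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def write_smiles_file(smiles: list[str], path) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")


def read_fasta(path) -> dict[str, str]:
    """FASTA records as {description: normalized sequence}, order preserved."""
    from Bio import SeqIO

    return {rec.description: normalize_sequence(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------------------------
# synthetic fixtures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for one synthetic drug-target study."""

    n_molecules: int = 200
    n_proteins: int = 20
    protein_length_range: tuple = (50, 120)
    seed: int = 0
    noise_sd: float = 0.3
    effect_sizes: tuple = (1.0, 1.0)  # (drug ring-count weight, motif weight)


# template grammar pieces: every assembly below is a valid SMILES by
# construction, so the generator needs no chemistry dependency itself
_CHAINS = ["CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "CCO", "CCN", "CCOCC",
           "CC(C)O", "CCCN"]
_AROMATIC_CORES = ["c1ccccc1", "c1ccncc1"]
_ALIPHATIC_CORES = ["C1CCCCC1", "C1CCNCC1", "C1CCOC1"]
_PREFIXES = ["", "C", "CC", "CCC", "O", "N", "OC", "Cl", "F", "Br"]
_SUFFIXES = ["", "C", "CC", "O", "N", "Cl", "F"]

PROTEIN_MOTIF = "HKLMW"


def generate_fixture_molecules(n: int, seed: int) -> list[str]:
    """n deterministic, chemically valid SMILES from the template grammar."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        kind = rng.choice(["chain", "ring", "biaryl"], p=[0.3, 0.5, 0.2])
        if kind == "chain":
            out.append(str(rng.choice(_CHAINS)))
        elif kind == "ring":
            core = str(rng.choice(_AROMATIC_CORES + _ALIPHATIC_CORES))
            prefix = str(rng.choice(_PREFIXES))
            suffix = str(rng.choice(_SUFFIXES))
            out.append(prefix + core + suffix)
        else:
            a = str(rng.choice(_AROMATIC_CORES))
            b = str(rng.choice(_AROMATIC_CORES))
            out.append(a + "C" + b)
    return out


def generate_fixture_proteins(n: int, length_range: tuple, seed: int,
                              motif: str = PROTEIN_MOTIF) -> tuple[list[str], list[int]]:
    """n random sequences over the 20 standard residues; a seeded half carry
    the motif at a random interior position.  Returns (sequences, flags)."""
    lo, hi = length_range
    if lo < len(motif):
        raise ValueError(f"protein_length_range minimum {lo} is shorter than "
                         f"the planted motif ({len(motif)} residues)")
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_RESIDUES))
    seqs, flags = [], []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length))
        has_motif = int(rng.random() < 0.5)
        if has_motif:
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        # guard against the motif arising by chance in the background
        flags.append(1 if motif in seq else 0)
        seqs.append(seq)
    return seqs, flags


@dataclass(frozen=True)
class SyntheticTruth:
    """The planted generating function of a synthetic affinity table."""

    base: float
    drug_weight: float
    motif_weight: float
    motif: str
    noise_sd: float
    drug_feature: dict = field(repr=False)   # smiles -> aromatic ring count
    protein_flag: dict = field(repr=False)   # sequence -> motif indicator

    def expected(self, smiles: str, sequence: str) -> float:
        """Noiseless affinity for one pair under the planted function."""
        return (self.base
                + self.drug_weight * self.drug_feature[smiles]
                + self.motif_weight * self.protein_flag[sequence])

    def to_manifest(self) -> dict:
        return {
            "base": self.base, "drug_weight": self.drug_weight,
            "motif_weight": self.motif_weight, "motif": self.motif,
            "noise_sd": self.noise_sd,
            "drug_feature": self.drug_feature,
            "protein_flag": self.protein_flag,
        }


AFFINITY_BASE = 5.0  # pK_d-like offset for the synthetic scale


def generate_synthetic_dta(spec: FixtureSpec) -> tuple[list[AffinityRecord], SyntheticTruth]:
    """Full factorial synthetic study: every drug paired with every protein.

    affinity = base + w_d * aromatic_ring_count(drug)
                    + w_p * motif_indicator(protein) + N(0, noise_sd)

    Deterministic: identical specs give bit-identical tables.
    """
    drugs = generate_fixture_molecules(spec.n_molecules, spec.seed)
    proteins, flags = generate_fixture_proteins(
        spec.n_proteins, spec.protein_length_range, spec.seed + 1)
    drug_feature = {s: count_aromatic_rings(s) for s in dict.fromkeys(drugs)}
    protein_flag = {p: f for p, f in zip(proteins, flags)}
    truth = SyntheticTruth(
        base=AFFINITY_BASE, drug_weight=spec.effect_sizes[0],
        motif_weight=spec.effect_sizes[1], motif=PROTEIN_MOTIF,
        noise_sd=spec.noise_sd, drug_feature=drug_feature,
        protein_flag=protein_flag,
    )
    rng = np.random.default_rng(spec.seed + 2)
    records = []
    for smiles in drugs:
        for seq in proteins:
            noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            records.append(AffinityRecord(
                smiles, seq, truth.expected(smiles, seq) + noise))
    return records, truth


def write_fixture_manifest(path, spec: FixtureSpec, truth: SyntheticTruth) -> None:
    manifest = {
        "spec": {
            "n_molecules": spec.n_molecules, "n_proteins": spec.n_proteins,
            "protein_length_range": list(spec.protein_length_range),
            "seed": spec.seed, "noise_sd": spec.noise_sd,
            "effect_sizes": list(spec.effect_sizes),
        },
        "truth": truth.to_manifest(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
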
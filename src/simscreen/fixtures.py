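"""Deterministic synthetic SMILES datasets with controlled similarity
structure: clustered families of structurally related molecules plus a
diverse background, so training and evaluation are testable offline.

Molecules are built as random valence-checked atom trees (optionally with one
5/6-membered ring) via RDKit and emitted as canonical SMILES; families are
produced by applying small local edits to a scaffold, which moves
Morgan-fingerprint Tanimoto smoothly with the number of edits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem import MoleculeRecord, canonical_smiles

logger = logging.getLogger(__name__)

# single-bond valence budget per element in the generator's alphabet
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}
_HALOGENS = ("F", "Cl", "Br")


@dataclass(frozen=True)
class FixtureSpec:
    n_families: int = 20
    family_size: int = 10
    n_background: int = 100
    seed: int = 7
    max_heavy_atoms: int = 16
    min_heavy_atoms: int = 11
    max_edits: int = 2
    elements: tuple = ("C", "C", "C", "C", "N", "O", "S")

    def __post_init__(self):
        if min(self.n_families, self.family_size, self.n_background) < 1:
            raise ValueError("all counts must be >= 1")
        if self.min_heavy_atoms < 4:
            raise ValueError("min_heavy_atoms must be >= 4")


SPEC_PRESETS = {
    "default": FixtureSpec(),
    "tiny": FixtureSpec(n_families=3, family_size=5, n_background=10,
                        max_heavy_atoms=12, min_heavy_atoms=8),
    "benchmark": FixtureSpec(n_families=20, family_size=10, n_background=100),
}


def _degree_capacity(mol: Chem.RWMol, idx: int) -> int:
    atom = mol.GetAtomWithIdx(idx)
    return _VALENCE[atom.GetSymbol()] - atom.GetDegree()


def _random_mol(rng: np.random.Generator, spec: FixtureSpec) -> Chem.RWMol:
    """Random atom tree with optional ring closure, respecting valence."""
    n_atoms = int(rng.integers(spec.min_heavy_atoms, spec.max_heavy_atoms + 1))
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom("C"))  # root is carbon so branching is possible
    for _ in range(n_atoms - 1):
        open_sites = [i for i in range(mol.GetNumAtoms())
                      if _degree_capacity(mol, i) > 0]
        if not open_sites:
            break
        parent = int(rng.choice(open_sites))
        # halogens appear sparsely as terminal decorations
        if rng.random() < 0.12:
            symbol = str(rng.choice(_HALOGENS))
        else:
            symbol = str(rng.choice(spec.elements))
        new = mol.AddAtom(Chem.Atom(symbol))
        mol.AddBond(parent, new, Chem.BondType.SINGLE)
    # close one 5- or 6-membered carbocycle/heterocycle when possible
    if rng.random() < 0.7:
        ring_size = int(rng.choice([5, 6]))
        paths = Chem.FindAllPathsOfLengthN(mol, ring_size, useBonds=False)
        candidates = []
        for path in paths:
            a, b = path[0], path[-1]
            if (mol.GetBondBetweenAtoms(a, b) is None
                    and _degree_capacity(mol, a) > 0
                    and _degree_capacity(mol, b) > 0):
                candidates.append((a, b))
        if candidates:
            a, b = candidates[int(rng.integers(len(candidates)))]
            mol.AddBond(int(a), int(b), Chem.BondType.SINGLE)
    return mol


def generate_scaffold(rng: np.random.Generator, spec: FixtureSpec,
                      mol_id: str = "scaffold") -> MoleculeRecord:
    """One random valence-valid molecule, canonical SMILES, deterministic."""
    for _ in range(50):
        mol = _random_mol(rng, spec)
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover - valence bookkeeping prevents this
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles:
            return MoleculeRecord(smiles=smiles, mol_id=mol_id)
    raise RuntimeError("scaffold generation failed after bounded retries")


def _edit_once(mol: Chem.RWMol, rng: np.random.Generator) -> bool:
    """Apply one local edit in place; returns False if no site was found."""
    moves = list(rng.permutation(["halogen_swap", "hetero_swap", "extend",
                                  "truncate"]))
    for move in moves:
        if move == "halogen_swap":
            sites = [a.GetIdx() for a in mol.GetAtoms()
                     if a.GetSymbol() in _HALOGENS]
            if sites:
                idx = int(rng.choice(sites))
                cur = mol.GetAtomWithIdx(idx).GetSymbol()
                new = str(rng.choice([h for h in _HALOGENS if h != cur]))
                mol.GetAtomWithIdx(idx).SetAtomicNum(
                    Chem.Atom(new).GetAtomicNum())
                return True
        elif move == "hetero_swap":
            # N<->O at valence-compatible (degree <= 2) sites
            sites = [a.GetIdx() for a in mol.GetAtoms()
                     if a.GetSymbol() in ("N", "O") and a.GetDegree() <= 2]
            if sites:
                idx = int(rng.choice(sites))
                cur = mol.GetAtomWithIdx(idx).GetSymbol()
                mol.GetAtomWithIdx(idx).SetAtomicNum(8 if cur == "N" else 7)
                return True
        elif move == "extend":
            sites = [i for i in range(mol.GetNumAtoms())
                     if _degree_capacity(mol, i) > 0]
            if sites:
                parent = int(rng.choice(sites))
                new = mol.AddAtom(Chem.Atom(str(rng.choice(["C", "C", "N", "O"]))))
                mol.AddBond(parent, new, Chem.BondType.SINGLE)
                return True
        elif move == "truncate":
            sites = [a.GetIdx() for a in mol.GetAtoms()
                     if a.GetDegree() == 1 and mol.GetNumAtoms() > 5]
            if sites:
                mol.RemoveAtom(int(rng.choice(sites)))
                return True
    return False


def _attach_tail(smiles: str, length: int) -> str:
    """Append an n-alkyl tail to a terminal (or any open) carbon.

    Repeated chain environments hash to the same Morgan bits, so later
    one-atom tail edits barely move the fingerprint — this is what gives
    families their near-duplicate (sim >= 0.9) members.
    """
    mol = Chem.RWMol(Chem.MolFromSmiles(smiles))
    sites = [a.GetIdx() for a in mol.GetAtoms()
             if a.GetSymbol() == "C" and a.GetDegree() == 1]
    if not sites:
        sites = [i for i in range(mol.GetNumAtoms())
                 if _degree_capacity(mol, i) > 0]
    if not sites:
        return smiles
    prev = sites[0]
    for _ in range(length):
        new = mol.AddAtom(Chem.Atom("C"))
        mol.AddBond(prev, new, Chem.BondType.SINGLE)
        prev = new
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _tail_edit(smiles: str, rng: np.random.Generator) -> str:
    """Extend (1-2 C) or truncate (1 C) a terminal chain carbon."""
    mol = Chem.RWMol(Chem.MolFromSmiles(smiles))
    terminals = [a.GetIdx() for a in mol.GetAtoms()
                 if a.GetSymbol() == "C" and a.GetDegree() == 1]
    if not terminals:
        return smiles
    idx = int(rng.choice(terminals))
    if rng.random() < 0.5 and mol.GetNumAtoms() > 6:
        mol.RemoveAtom(idx)
    else:
        prev = idx
        for _ in range(int(rng.integers(1, 3))):
            new = mol.AddAtom(Chem.Atom("C"))
            mol.AddBond(prev, new, Chem.BondType.SINGLE)
            prev = new
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _relocate(smiles: str, rng: np.random.Generator, n_moves: int = 1) -> str:
    """Detach terminal atoms and reattach them elsewhere (positional isomer).

    Keeps the atom composition identical while changing local environments,
    so fingerprint similarity drops although token content is unchanged —
    the case a composition-only embedding cannot rank.
    """
    mol = Chem.RWMol(Chem.MolFromSmiles(smiles))
    for _ in range(n_moves):
        terminals = [a.GetIdx() for a in mol.GetAtoms() if a.GetDegree() == 1]
        if not terminals:
            break
        idx = int(rng.choice(terminals))
        symbol = mol.GetAtomWithIdx(idx).GetSymbol()
        neighbor = mol.GetAtomWithIdx(idx).GetNeighbors()[0].GetIdx()
        mol.RemoveAtom(idx)
        sites = [i for i in range(mol.GetNumAtoms())
                 if _degree_capacity(mol, i) > 0
                 and i != (neighbor if neighbor < idx else neighbor - 1)]
        if not sites:
            return smiles
        parent = int(rng.choice(sites))
        new = mol.AddAtom(Chem.Atom(symbol))
        mol.AddBond(parent, new, Chem.BondType.SINGLE)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def mutate(parent: MoleculeRecord, n_edits: int,
           rng: np.random.Generator, mol_id: str | None = None) -> MoleculeRecord:
    """Apply `n_edits` local edits; similarity to parent decays with edits."""
    mol_id = mol_id or f"{parent.mol_id}_m"
    if n_edits == 0:
        return MoleculeRecord(smiles=parent.smiles, mol_id=mol_id)
    mol = Chem.RWMol(Chem.MolFromSmiles(parent.smiles))
    applied = 0
    for _ in range(n_edits):
        if _edit_once(mol, rng):
            applied += 1
    if applied == 0:
        logger.warning("no applicable edit site for %s; returning parent",
                       parent.mol_id)
        return MoleculeRecord(smiles=parent.smiles, mol_id=mol_id)
    try:
        Chem.SanitizeMol(mol)
        smiles = Chem.MolToSmiles(mol)
    except Exception:
        logger.warning("edit invalidated %s; returning parent", parent.mol_id)
        return MoleculeRecord(smiles=parent.smiles, mol_id=mol_id)
    return MoleculeRecord(smiles=smiles, mol_id=mol_id)


def generate_dataset(spec: FixtureSpec) -> tuple:
    """Families of mutants around scaffolds plus diverse background.

    Returns (records, manifest); manifest records family membership and the
    generating spec. Deterministic per seed; canonical duplicates across the
    dataset are regenerated with bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    families: dict[str, list] = {}

    def admit(rec: MoleculeRecord) -> bool:
        if rec.smiles in seen:
            return False
        seen.add(rec.smiles)
        records.append(rec)
        return True

    for fam in range(spec.n_families):
        fam_name = f"fam{fam:02d}"
        members: list[str] = []
        for attempt in range(60):
            raw = generate_scaffold(rng, spec, mol_id=f"{fam_name}_s")
            tailed = _attach_tail(raw.smiles, int(rng.integers(3, 6)))
            scaffold = MoleculeRecord(smiles=tailed, mol_id=raw.mol_id)
            if len(canonical_smiles(scaffold.smiles)) >= 8 and admit(scaffold):
                members.append(scaffold.mol_id)
                break
        else:
            raise RuntimeError(f"could not build scaffold for {fam_name}")
        made, attempts = 0, 0
        while made < spec.family_size - 1 and attempts < 40 * spec.family_size:
            attempts += 1
            mol_id = f"{fam_name}_v{made:02d}"
            if made < 3:
                # similarity ladder: +1C/+2C/+3C tail homologues of the
                # scaffold guarantee near-duplicate (sim >~ 0.95) pairs in
                # every family, populating the highest thresholds
                cand = MoleculeRecord(
                    smiles=_attach_tail(scaffold.smiles, made + 1),
                    mol_id=mol_id)
                if admit(cand):
                    members.append(cand.mol_id)
                    made += 1
                continue
            roll = rng.random()
            if roll < 0.25:
                # near-duplicate: tail-only edit, sim typically >= 0.9
                cand = MoleculeRecord(smiles=_tail_edit(scaffold.smiles, rng),
                                      mol_id=mol_id)
            elif roll < 0.6:
                # positional isomer: identical composition, mid similarity
                cand = MoleculeRecord(
                    smiles=_relocate(scaffold.smiles, rng,
                                     n_moves=int(rng.integers(1, 3))),
                    mol_id=mol_id)
            elif roll < 0.85:
                cand = mutate(scaffold, 1, rng, mol_id=mol_id)
            else:
                cand = mutate(scaffold, spec.max_edits, rng, mol_id=mol_id)
            if admit(cand):
                members.append(cand.mol_id)
                made += 1
        if made < spec.family_size - 1:
            raise RuntimeError(f"family {fam_name} exhausted mutation retries")
        families[fam_name] = members

    background: list[str] = []
    attempts = 0
    while len(background) < spec.n_background and attempts < 60 * spec.n_background:
        attempts += 1
        cand = generate_scaffold(rng, spec, mol_id=f"bg{len(background):03d}")
        if admit(cand):
            background.append(cand.mol_id)
    if len(background) < spec.n_background:
        raise RuntimeError("background generation exhausted retries")

    manifest = {
        "spec": asdict(spec),
        "families": families,
        "background": background,
        "n_molecules": len(records),
    }
    return records, manifest


def write_dataset(records, manifest, out_dir) -> tuple:
    """Write `data.smi` + `manifest.json`; byte-stable for a fixed spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    smi_path = out_dir / "data.smi"
    smi_path.write_text("".join(f"{r.smiles}\t{r.mol_id}\n" for r in records))
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return smi_path, manifest_path


def family_of(manifest: dict) -> dict:
    """mol_id -> family name (background molecules map to None)."""
    out = {}
    for fam, members in manifest["families"].items():
        for m in members:
            out[m] = fam
    for m in manifest["background"]:
        out[m] = None
    return out
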
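"""Synthetic molecule corpora with controllable stereochemistry.

Generates valid, diverse organic molecules over the element set
{B, C, N, O, F, P, S, Cl, Br, I} with a configurable heavy-atom range,
a target fraction of molecules bearing one tetrahedral stereocenter, and
a target balance between the two parity tokens "@" and "@@" in the
canonical SMILES. The corpus plays the role of a desk-scale training and
evaluation set for the SMILES translation experiments, with no download.

Molecules are assembled as random trees (optionally closed into one ring,
optionally with one double bond) from a weighted element palette; a
stereocenter, when requested, is forced by attaching four pairwise-distinct
substituent chains to a central carbon. The printed parity token is
controlled exactly: if the canonical SMILES shows the wrong token, the
enantiomer (inverted chiral tag) is emitted instead.

Downstream property labels are synthetic functions of structure so that
descriptor quality can be probed without external datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: maximum single-bond valence used when growing skeletons
VALENCE = {
    "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1,
}

#: sampling weights for a loosely drug-like element distribution
_ELEMENT_WEIGHTS = {
    "C": 0.60, "N": 0.12, "O": 0.12, "S": 0.04, "F": 0.04,
    "Cl": 0.03, "Br": 0.015, "P": 0.01, "B": 0.005, "I": 0.01,
}

DEFAULT_ELEMENTS = frozenset(VALENCE)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corpus.

    ``chiral_fraction`` is the probability that a molecule carries one
    tetrahedral stereocenter; ``at_at_balance`` is the probability that a
    chiral molecule's canonical SMILES shows "@@" rather than "@".
    """

    n_molecules: int = 1000
    heavy_atom_range: tuple[int, int] = (3, 50)
    chiral_fraction: float = 0.0
    at_at_balance: float = 0.5
    element_set: frozenset = DEFAULT_ELEMENTS
    seed: int = 0
    ring_probability: float = 0.25
    double_bond_probability: float = 0.2
    linearity: float = 0.5
    n_stereocenters: int = 1
    n_randomized: int = 2
    enantiomer_pairs: bool = False
    enumerate_stereoisomers: bool = False

    def __post_init__(self):
        lo, hi = self.heavy_atom_range
        if not (1 <= lo <= hi <= 200):
            raise ValueError("heavy_atom_range must satisfy 1 <= low <= high <= 200")
        if not 0.0 <= self.chiral_fraction <= 1.0:
            raise ValueError("chiral_fraction must be in [0, 1]")
        if not 0.0 <= self.at_at_balance <= 1.0:
            raise ValueError("at_at_balance must be in [0, 1]")
        bad = set(self.element_set) - set(VALENCE)
        if bad:
            raise ValueError(f"elements outside the supported set: {sorted(bad)}")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be non-negative")
        object.__setattr__(self, "element_set", frozenset(self.element_set))


@dataclass
class MoleculeRecord:
    canonical_smiles: str
    randomized_smiles: list[str] = field(default_factory=list)
    inchi: str | None = None
    has_stereocenter: bool = False
    n_heavy_atoms: int = 0

    @property
    def smiles_length(self) -> int:
        return len(self.canonical_smiles)


def _weights_for(elements: list[str]) -> np.ndarray:
    w = np.array([_ELEMENT_WEIGHTS[e] for e in elements], dtype=float)
    return w / w.sum()


def _grow_tree(n: int, elements: list[str], rng: np.random.Generator,
               ring_p: float, double_p: float, linearity: float = 0.5) -> Chem.Mol | None:
    """Random valence-respecting tree of ``n`` heavy atoms, optionally with
    one ring closure and one double bond. Returns None if assembly fails."""
    multi = [e for e in elements if VALENCE[e] >= 2]
    if n > 1 and not multi:
        return None
    probs = _weights_for(elements)
    probs_multi = _weights_for(multi) if multi else None

    mol = Chem.RWMol()
    free: list[int] = []  # remaining single-bond valence per atom index
    first = str(rng.choice(multi, p=probs_multi)) if n > 1 else str(rng.choice(elements, p=probs))
    mol.AddAtom(Chem.Atom(first))
    free.append(VALENCE[first] if n > 1 else 0)
    last = 0
    for _ in range(n - 1):
        open_sites = [i for i, f in enumerate(free) if f > 0]
        if not open_sites:
            return None
        # `linearity` biases growth toward chain extension over branching
        if free[last] > 0 and rng.random() < linearity:
            parent = last
        else:
            parent = int(rng.choice(open_sites))
        sym = str(rng.choice(elements, p=probs))
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        free[parent] -= 1
        free.append(VALENCE[sym] - 1)
        last = idx

    if n >= 4 and rng.random() < ring_p:
        open_sites = [i for i, f in enumerate(free) if f > 0]
        rng.shuffle(open_sites)
        done = False
        for a in open_sites:
            if done:
                break
            for b in open_sites:
                if b <= a or mol.GetBondBetweenAtoms(a, b) is not None:
                    continue
                path = Chem.GetShortestPath(mol, a, b)
                if 3 <= len(path) <= 7:
                    mol.AddBond(a, b, Chem.BondType.SINGLE)
                    free[a] -= 1
                    free[b] -= 1
                    done = True
                    break

    if rng.random() < double_p:
        candidates = []
        for bond in mol.GetBonds():
            a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            pair = {mol.GetAtomWithIdx(a).GetSymbol(), mol.GetAtomWithIdx(b).GetSymbol()}
            if free[a] >= 1 and free[b] >= 1 and pair <= {"C", "N", "O", "S"}:
                candidates.append(bond.GetIdx())
        if candidates:
            bond = mol.GetBondWithIdx(int(rng.choice(candidates)))
            bond.SetBondType(Chem.BondType.DOUBLE)

    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _random_chain(size: int, elements: list[str], rng: np.random.Generator) -> tuple[str, ...] | None:
    """Linear substituent chain as a tuple of element symbols, attachment at
    the first atom. Interior atoms need valence >= 2."""
    multi = [e for e in elements if VALENCE[e] >= 2]
    if size > 1 and not multi:
        return None
    syms = []
    for i in range(size):
        pool = elements if i == size - 1 else multi
        syms.append(str(rng.choice(pool, p=_weights_for(pool))))
    return tuple(syms)


def _build_chiral(n: int, elements: list[str], rng: np.random.Generator,
                  want_at_at: bool) -> Chem.Mol | None:
    """Central carbon with four pairwise-distinct substituent chains; the
    canonical SMILES is guaranteed to print the requested parity token."""
    if "C" not in elements:
        return None
    remaining = n - 1  # atoms besides the center
    if remaining < 4:
        return None
    for _ in range(60):
        # random composition of `remaining` into 4 parts, each >= 1
        cuts = np.sort(rng.choice(np.arange(1, remaining), size=3, replace=False))
        sizes = np.diff(np.concatenate([[0], cuts, [remaining]]))
        chains = [_random_chain(int(s), elements, rng) for s in sizes]
        if any(c is None for c in chains):
            continue
        if len(set(chains)) != 4:
            continue
        subs = ["".join(c) for c in chains]
        for tag in ("@", "@@"):
            smi = f"[C{tag}]({subs[0]})({subs[1]})({subs[2]}){subs[3]}"
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                break
            canonical = Chem.MolToSmiles(mol)
            has_at_at = "@@" in canonical
            has_at = "@" in canonical
            if not has_at:
                break  # substituents were not actually distinct to the toolkit
            if has_at_at == want_at_at:
                return mol
    return None


def _build_chiral2(n: int, elements: list[str], rng: np.random.Generator) -> Chem.Mol | None:
    """Two adjacent stereocenters, each with pairwise-distinct substituent
    chains; parities assigned randomly (enumeration replaces them anyway)."""
    if "C" not in elements:
        return None
    remaining = n - 2  # atoms besides the two centers
    if remaining < 6:
        return None
    for _ in range(60):
        cuts = np.sort(rng.choice(np.arange(1, remaining), size=5, replace=False))
        sizes = np.diff(np.concatenate([[0], cuts, [remaining]]))
        chains = [_random_chain(int(s), elements, rng) for s in sizes]
        if any(c is None for c in chains):
            continue
        if len(set(chains[:3])) != 3 or len(set(chains[3:])) != 3:
            continue
        subs = ["".join(c) for c in chains]
        tag1, tag2 = rng.choice(["@", "@@"], size=2)
        smi = (f"[C{tag1}]({subs[0]})({subs[1]})({subs[2]})"
               f"[C{tag2}]({subs[3]})({subs[4]}){subs[5]}")
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        # both centers must survive canonicalization as genuine stereocenters
        n_parity = canonical.replace("@@", "^").count("^") + \
            canonical.replace("@@", "^").count("@")
        if n_parity != 2:
            continue
        return mol
    return None


def generate_molecule(cfg: GeneratorConfig, rng: np.random.Generator) -> MoleculeRecord:
    """Draw one molecule satisfying the configuration.

    Raises ``ValueError`` when a stereocenter is demanded but the
    heavy-atom budget cannot host a carbon with four distinct substituents.
    """
    lo, hi = cfg.heavy_atom_range
    min_heavy = 5 if cfg.n_stereocenters == 1 else 8
    if cfg.chiral_fraction > 0 and hi < min_heavy:
        raise ValueError(
            f"chiral_fraction > 0 requires heavy_atom_range upper bound >= "
            f"{min_heavy} (each stereocenter needs four distinct substituents)"
        )
    elements = sorted(cfg.element_set)
    want_chiral = bool(rng.random() < cfg.chiral_fraction)
    for _ in range(200):
        if want_chiral:
            n = int(rng.integers(max(lo, min_heavy), hi + 1))
            if cfg.n_stereocenters == 2:
                mol = _build_chiral2(n, elements, rng)
            else:
                want_at_at = bool(rng.random() < cfg.at_at_balance)
                mol = _build_chiral(n, elements, rng, want_at_at)
        else:
            n = int(rng.integers(lo, hi + 1))
            mol = _grow_tree(n, elements, rng, cfg.ring_probability,
                             cfg.double_bond_probability, cfg.linearity)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if want_chiral != ("@" in canonical):
            continue
        if mol.GetNumHeavyAtoms() != n:
            continue
        from .corpus import randomize_smiles  # local import avoids a cycle

        variants = [randomize_smiles(canonical, rng) for _ in range(cfg.n_randomized)]
        try:
            inchi = Chem.MolToInchi(mol) or None
        except Exception:
            inchi = None
        return MoleculeRecord(
            canonical_smiles=canonical,
            randomized_smiles=variants,
            inchi=inchi,
            has_stereocenter="@" in canonical,
            n_heavy_atoms=n,
        )
    raise RuntimeError("could not assemble a molecule under the given configuration")


def mirror_record(rec: MoleculeRecord, rng: np.random.Generator,
                  n_randomized: int = 2) -> MoleculeRecord:
    """The enantiomer of a chiral molecule (all tetrahedral parities
    inverted); its canonical SMILES differs only in the parity tokens."""
    mol = Chem.MolFromSmiles(rec.canonical_smiles)
    flipped = False
    for atom in mol.GetAtoms():
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
            flipped = True
        elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
            flipped = True
    if not flipped:
        raise ValueError("molecule has no assigned stereocenter to mirror")
    canonical = Chem.MolToSmiles(mol)
    from .corpus import randomize_smiles

    try:
        inchi = Chem.MolToInchi(mol) or None
    except Exception:
        inchi = None
    return MoleculeRecord(
        canonical_smiles=canonical,
        randomized_smiles=[randomize_smiles(canonical, rng)
                           for _ in range(n_randomized)],
        inchi=inchi,
        has_stereocenter=True,
        n_heavy_atoms=rec.n_heavy_atoms,
    )


def generate_corpus(cfg: GeneratorConfig) -> list[MoleculeRecord]:
    """``cfg.n_molecules`` unique molecules (unique canonical SMILES),
    reproducible from ``cfg.seed``.

    With ``enantiomer_pairs`` every chiral molecule is accompanied by its
    mirror image, so the parity token of a skeleton cannot be recalled
    from the skeleton alone -- the regime in which enantiomer
    discrimination must genuinely be learned.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    max_attempts = max(1000, 50 * cfg.n_molecules)
    attempts = 0
    while len(records) < cfg.n_molecules:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not reach {cfg.n_molecules} unique molecules "
                f"after {attempts} attempts"
            )
        attempts += 1
        rec = generate_molecule(cfg, rng)
        if rec.canonical_smiles in seen:
            continue
        seen.add(rec.canonical_smiles)
        records.append(rec)
        if rec.has_stereocenter and len(records) < cfg.n_molecules:
            siblings: list[MoleculeRecord] = []
            if cfg.enumerate_stereoisomers:
                siblings = stereoisomer_records(rec, rng, cfg.n_randomized)
            elif cfg.enantiomer_pairs:
                siblings = [mirror_record(rec, rng, cfg.n_randomized)]
            for twin in siblings:
                if (twin.canonical_smiles not in seen
                        and len(records) < cfg.n_molecules):
                    seen.add(twin.canonical_smiles)
                    records.append(twin)
    return records


def stereoisomer_records(rec: MoleculeRecord, rng: np.random.Generator,
                         n_randomized: int = 2) -> list[MoleculeRecord]:
    """All other stereoisomers of a molecule (every combination of
    tetrahedral parities), so a skeleton carries no information about its
    parity tokens."""
    from rdkit.Chem.EnumerateStereoisomers import (EnumerateStereoisomers,
                                                   StereoEnumerationOptions)
    from .corpus import randomize_smiles

    mol = Chem.MolFromSmiles(rec.canonical_smiles)
    opts = StereoEnumerationOptions(onlyUnassigned=False, unique=True)
    out = []
    for iso in EnumerateStereoisomers(mol, options=opts):
        canonical = Chem.MolToSmiles(iso)
        if canonical == rec.canonical_smiles or "@" not in canonical:
            continue
        try:
            inchi = Chem.MolToInchi(iso) or None
        except Exception:
            inchi = None
        out.append(MoleculeRecord(
            canonical_smiles=canonical,
            randomized_smiles=[randomize_smiles(canonical, rng)
                               for _ in range(n_randomized)],
            inchi=inchi,
            has_stereocenter=True,
            n_heavy_atoms=rec.n_heavy_atoms,
        ))
    return out


def synthetic_labels(records: list[MoleculeRecord], rng: np.random.Generator,
                     noise_sd: float = 1.0) -> pd.DataFrame:
    """Structure-derived downstream labels.

    regression: heavy-atom count + 2 x (number of oxygens) + Gaussian noise;
    classification: presence of a stereocenter.
    """
    rows = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.canonical_smiles)
        n_ox = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "O")
        rows.append({
            "canonical_smiles": rec.canonical_smiles,
            "regression": rec.n_heavy_atoms + 2.0 * n_ox + rng.normal(0.0, noise_sd),
            "classification": int(rec.has_stereocenter),
        })
    return pd.DataFrame(rows)


def write_smiles(records: list[MoleculeRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.canonical_smiles + "\n")


def write_csv(records: list[MoleculeRecord], path) -> None:
    df = pd.DataFrame({
        "canonical_smiles": [r.canonical_smiles for r in records],
        "randomized_smiles": [";".join(r.randomized_smiles) for r in records],
        "inchi": [r.inchi or "" for r in records],
        "has_stereocenter": [r.has_stereocenter for r in records],
        "n_heavy_atoms": [r.n_heavy_atoms for r in records],
    })
    df.to_csv(path, index=False)


def read_csv(path) -> list[MoleculeRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        MoleculeRecord(
            canonical_smiles=row.canonical_smiles,
            randomized_smiles=[s for s in str(row.randomized_smiles).split(";") if s],
            inchi=row.inchi or None,
            has_stereocenter=bool(row.has_stereocenter),
            n_heavy_atoms=int(row.n_heavy_atoms),
        )
        for row in df.itertuples()
    ]
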
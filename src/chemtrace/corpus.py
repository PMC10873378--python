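"""Data pathway from raw SMILES to model-ready batches.

Covers element/heavy-atom filtering with fragment stripping, stratified
sampling by SMILES length, atom-renumbering SMILES randomization, greedy
longest-match tokenization with special tokens, token-budget batching with
length bucketing, and chirality-enriched resampling.

Tokenization treats multi-character SMILES symbols -- two-letter elements
("Cl", "Br"), the "@@" parity token and "%NN" ring closures -- as single
tokens; bracket-atom interiors are tokenized symbol-wise, so "[C@@H]"
becomes "[", "C", "@@", "H", "]". The vocabulary is the token inventory
observed in a corpus plus the four special tokens.
"""

from __future__ import annotations

import json
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .synthetic import MoleculeRecord

logger = logging.getLogger(__name__)

START, END, PAD, UNK = "<s>", "</s>", "<pad>", "<unk>"
SPECIAL_TOKENS = (PAD, START, END, UNK)

ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"]
)

_TOKEN_RE = re.compile(r"Cl|Br|@@|%\d{2}|.")


def split_tokens(s: str) -> list[str]:
    """Greedy longest-match split of a SMILES/InChI string into tokens."""
    return _TOKEN_RE.findall(s)


@dataclass
class Vocabulary:
    """Ordered token inventory with contiguous ids; specials come first."""

    tokens: list[str]
    token_to_id: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.token_to_id = {t: i for i, t in enumerate(self.tokens)}
        if len(self.token_to_id) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for t in SPECIAL_TOKENS:
            if t not in self.token_to_id:
                raise ValueError(f"missing special token {t!r}")

    @classmethod
    def build(cls, strings: list[str]) -> "Vocabulary":
        observed: dict[str, None] = {}
        for s in strings:
            for t in split_tokens(s):
                observed.setdefault(t, None)
        return cls(list(SPECIAL_TOKENS) + sorted(observed))

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def start_id(self) -> int:
        return self.token_to_id[START]

    @property
    def end_id(self) -> int:
        return self.token_to_id[END]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def encode(self, s: str, on_unknown: str = "unk") -> np.ndarray:
        """Integer-encode with start/end tokens attached.

        ``on_unknown`` is "unk" (map to the unknown token) or "raise".
        """
        if not s:
            raise ValueError("cannot tokenize an empty string")
        ids = [self.start_id]
        for t in split_tokens(s):
            i = self.token_to_id.get(t)
            if i is None:
                if on_unknown == "raise":
                    raise KeyError(f"token {t!r} not in vocabulary")
                i = self.unk_id
            ids.append(i)
        ids.append(self.end_id)
        return np.asarray(ids, dtype=np.int32)

    def decode(self, ids) -> str:
        """Back to a string: specials stripped, stops at the first end token."""
        return "".join(self.content_tokens(ids))

    def content_tokens(self, ids) -> list[str]:
        """Token strings between the start token and the first end token."""
        out = []
        for i in np.asarray(ids).tolist():
            if i == self.end_id:
                break
            if i in (self.start_id, self.pad_id):
                continue
            out.append(self.tokens[i])
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"tokens": self.tokens}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh)["tokens"])


def canonicalize(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def filter_molecules(smiles_stream, min_heavy: int = 3, max_heavy: int = 50,
                     element_set=ALLOWED_ELEMENTS) -> list[str]:
    """Keep valid molecules inside the element set and heavy-atom window.

    Multi-fragment inputs (salts etc.) are stripped to their largest
    fragment before the checks; invalid lines are dropped and counted.
    """
    kept: list[str] = []
    n_invalid = n_filtered = 0
    for line in smiles_stream:
        mol = Chem.MolFromSmiles(line.strip())
        if mol is None:
            n_invalid += 1
            continue
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        if not all(a.GetSymbol() in element_set for a in mol.GetAtoms()):
            n_filtered += 1
            continue
        n = mol.GetNumHeavyAtoms()
        if not min_heavy <= n <= max_heavy:
            n_filtered += 1
            continue
        kept.append(Chem.MolToSmiles(mol))
    if n_invalid or n_filtered:
        logger.info("filter_molecules: dropped %d invalid and %d out-of-scope lines",
                    n_invalid, n_filtered)
    return kept


def stratified_sample(pool: list[str], per_length_cap: int,
                      rng: np.random.Generator) -> list[str]:
    """At most ``per_length_cap`` molecules per SMILES-string length,
    sampled uniformly without replacement; short groups are taken whole."""
    if per_length_cap < 1:
        raise ValueError("per_length_cap must be >= 1")
    groups: dict[int, list[str]] = defaultdict(list)
    for s in pool:
        groups[len(s)].append(s)
    out: list[str] = []
    for length in sorted(groups):
        members = groups[length]
        if len(members) <= per_length_cap:
            out.extend(members)
        else:
            idx = rng.choice(len(members), size=per_length_cap, replace=False)
            out.extend(members[i] for i in sorted(idx))
    return out


def randomize_smiles(canonical: str, rng: np.random.Generator) -> str:
    """A SMILES of the same molecule from a uniformly random atom renumbering."""
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {canonical!r}")
    perm = rng.permutation(mol.GetNumAtoms()).tolist()
    mol = Chem.RenumberAtoms(mol, perm)
    return Chem.MolToSmiles(mol, canonical=False)


def rooted_smiles(canonical: str, rng: np.random.Generator) -> str:
    """A restricted randomization: the canonical traversal started from a
    uniformly chosen root atom. The variant space per molecule is at most
    the number of atoms (versus factorial for full renumbering), which
    makes representation generalization attainable for small models."""
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {canonical!r}")
    root = int(rng.integers(mol.GetNumAtoms()))
    return Chem.MolToSmiles(mol, rootedAtAtom=root)


def chirality_enriched_resample(records: list[MoleculeRecord],
                                keep_prob_achiral: float,
                                rng: np.random.Generator) -> list[MoleculeRecord]:
    """Keep every molecule whose SMILES bears "@" or "@@"; keep each other
    molecule independently with probability ``keep_prob_achiral``."""
    if not 0.0 <= keep_prob_achiral <= 1.0:
        raise ValueError("keep_prob_achiral must be in [0, 1]")
    out = []
    for rec in records:
        if "@" in rec.canonical_smiles or rng.random() < keep_prob_achiral:
            out.append(rec)
    return out


def train_test_split(records: list[MoleculeRecord], test_fraction: float,
                     rng: np.random.Generator) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Random split; default test fraction in the pipeline is 3%."""
    n_test = int(round(test_fraction * len(records)))
    idx = rng.permutation(len(records))
    test_idx = set(idx[:n_test].tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


@dataclass
class TranslationPair:
    source: np.ndarray  # token ids, randomized SMILES (or InChI)
    target: np.ndarray  # token ids, canonical SMILES
    molecule_index: int


@dataclass
class Batch:
    source: np.ndarray  # (B, Ls) padded
    target: np.ndarray  # (B, Lt) padded
    molecule_indices: np.ndarray


def make_pairs(records: list[MoleculeRecord], src_vocab: Vocabulary,
               tgt_vocab: Vocabulary, rng: np.random.Generator,
               source_mode: str = "randomized") -> list[TranslationPair]:
    """One translation pair per molecule; the randomized source is drawn
    fresh on every call (one new variant per visit)."""
    pairs = []
    for i, rec in enumerate(records):
        if source_mode == "randomized":
            src = randomize_smiles(rec.canonical_smiles, rng)
        elif source_mode == "rooted":
            src = rooted_smiles(rec.canonical_smiles, rng)
        elif source_mode == "canonical":
            src = rec.canonical_smiles
        elif source_mode == "inchi":
            if not rec.inchi:
                continue
            src = rec.inchi
        else:
            raise ValueError(f"unknown source_mode {source_mode!r}")
        pairs.append(TranslationPair(
            source=src_vocab.encode(src),
            target=tgt_vocab.encode(rec.canonical_smiles),
            molecule_index=i,
        ))
    return pairs


def _pad(seqs: list[np.ndarray], pad_id: int) -> np.ndarray:
    width = max(len(s) for s in seqs)
    out = np.full((len(seqs), width), pad_id, dtype=np.int32)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


def make_batches(pairs: list[TranslationPair], token_budget: int,
                 bucketing: bool, rng: np.random.Generator,
                 pad_id: int = 0) -> list[Batch]:
    """Batches whose padded source token count stays within ``token_budget``.

    With bucketing, pairs are grouped into source-length deciles so that
    batches mix similar lengths and carry less padding. Every pair appears
    exactly once; ordering is reproducible from ``rng``.
    """
    if not pairs:
        return []
    lengths = np.array([len(p.source) for p in pairs])
    longest = int(lengths.max())
    if longest > token_budget:
        raise ValueError(
            f"token_budget {token_budget} below longest source ({longest} tokens)"
        )
    if bucketing:
        qs = np.quantile(lengths, np.linspace(0.1, 0.9, 9), method="nearest")
        bucket_of = np.searchsorted(np.unique(qs), lengths, side="left")
        buckets = defaultdict(list)
        for p, b in zip(pairs, bucket_of):
            buckets[int(b)].append(p)
        ordered: list[TranslationPair] = []
        keys = sorted(buckets)
        for k in rng.permutation(len(keys)):
            members = buckets[keys[int(k)]]
            for j in rng.permutation(len(members)):
                ordered.append(members[int(j)])
    else:
        ordered = [pairs[int(i)] for i in rng.permutation(len(pairs))]

    batches: list[Batch] = []
    current: list[TranslationPair] = []
    cur_max = 0
    for p in ordered:
        new_max = max(cur_max, len(p.source))
        if current and (len(current) + 1) * new_max > token_budget:
            batches.append(_make_batch(current, pad_id))
            current, cur_max = [], 0
            new_max = len(p.source)
        current.append(p)
        cur_max = new_max
    if current:
        batches.append(_make_batch(current, pad_id))
    order = rng.permutation(len(batches))
    return [batches[int(i)] for i in order]


def _make_batch(pairs: list[TranslationPair], pad_id: int) -> Batch:
    return Batch(
        source=_pad([p.source for p in pairs], pad_id),
        target=_pad([p.target for p in pairs], pad_id),
        molecule_indices=np.array([p.molecule_index for p in pairs]),
    )


def padding_fraction(batches: list[Batch], pad_id: int = 0) -> float:
    """Fraction of padding among all source tokens across batches."""
    total = pad = 0
    for b in batches:
        total += b.source.size
        pad += int((b.source == pad_id).sum())
    return pad / total if total else 0.0
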
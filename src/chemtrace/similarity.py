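"""Fingerprint-based structural comparison of predicted vs target molecules.

Predictions that fail to parse as valid SMILES (toolkit sanitization,
i.e. grammar plus valence rules) are excluded; in multi-step analyses a
molecule whose prediction is invalid at any evaluated step is excluded at
every step, so the averaged subset is fixed across the training trajectory.

Fingerprints: MACCS keys (167 bits as emitted by the toolkit) and Morgan
(ECFP-like) fingerprints of radius 1-3 folded to a power-of-two width
(default 2048).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator


@dataclass(frozen=True)
class FingerprintConfig:
    kind: str  # "maccs" or "ecfp"
    radius: int | None = None
    n_bits: int = 2048

    def __post_init__(self):
        if self.kind not in ("maccs", "ecfp"):
            raise ValueError("kind must be 'maccs' or 'ecfp'")
        if self.kind == "ecfp":
            if self.radius not in (1, 2, 3):
                raise ValueError("ECFP radius must be 1, 2 or 3")
            if self.n_bits < 1 or self.n_bits & (self.n_bits - 1):
                raise ValueError("n_bits must be a power of two")

    @property
    def label(self) -> str:
        return "maccs" if self.kind == "maccs" else f"ecfp{self.radius}"


DEFAULT_CONFIGS = (
    FingerprintConfig("maccs"),
    FingerprintConfig("ecfp", 1),
    FingerprintConfig("ecfp", 2),
    FingerprintConfig("ecfp", 3),
)


@dataclass
class SimilarityReport:
    mean_tanimoto: dict[str, float]
    n_evaluated: int
    n_invalid: int
    step: int | None = None


def mol_from_smiles(smiles: str) -> Chem.Mol | None:
    """Parse with full sanitization; None means invalid."""
    if not smiles:
        return None
    return Chem.MolFromSmiles(smiles)


def fingerprint(mol: Chem.Mol, cfg: FingerprintConfig) -> np.ndarray:
    if cfg.kind == "maccs":
        bv = MACCSkeys.GenMACCSKeys(mol)
    else:
        gen = _morgan_generator(cfg.radius, cfg.n_bits)
        bv = gen.GetFingerprint(mol)
    arr = np.zeros(bv.GetNumBits(), dtype=bool)
    arr[list(bv.GetOnBits())] = True
    return arr


_GENERATORS: dict[tuple[int, int], object] = {}


def _morgan_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits)
    return _GENERATORS[key]


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """|intersection| / |union|; two empty bit-sets give 0 by convention."""
    fp_a = np.asarray(fp_a, dtype=bool)
    fp_b = np.asarray(fp_b, dtype=bool)
    if fp_a.shape != fp_b.shape:
        raise ValueError(f"fingerprint widths differ: {fp_a.shape} vs {fp_b.shape}")
    union = int(np.logical_or(fp_a, fp_b).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(fp_a, fp_b).sum()) / union


def similarity_report(pred_smiles: list[str], target_smiles: list[str],
                      cfgs=DEFAULT_CONFIGS, step: int | None = None,
                      include: np.ndarray | None = None) -> SimilarityReport:
    """Mean Tanimoto similarity per fingerprint config over pairs whose
    prediction is a valid SMILES.

    ``include`` optionally restricts the evaluation to a fixed subset of
    pair indices (used by the multi-step analysis).
    """
    if len(pred_smiles) != len(target_smiles):
        raise ValueError("prediction and target lists must align")
    sums = {cfg.label: 0.0 for cfg in cfgs}
    n_eval = n_invalid = 0
    for i, (ps, ts) in enumerate(zip(pred_smiles, target_smiles)):
        if include is not None and not include[i]:
            continue
        pm = mol_from_smiles(ps)
        if pm is None:
            n_invalid += 1
            continue
        tm = mol_from_smiles(ts)
        if tm is None:
            n_invalid += 1
            continue
        for cfg in cfgs:
            sums[cfg.label] += tanimoto(fingerprint(pm, cfg), fingerprint(tm, cfg))
        n_eval += 1
    if n_eval == 0:
        raise ValueError("no valid prediction-target pairs to evaluate")
    return SimilarityReport(
        mean_tanimoto={k: v / n_eval for k, v in sums.items()},
        n_evaluated=n_eval, n_invalid=n_invalid, step=step,
    )


def multi_step_similarity(preds_by_step: dict[int, list[str]],
                          target_smiles: list[str],
                          cfgs=DEFAULT_CONFIGS) -> pd.DataFrame:
    """Trajectory of mean similarity over a fixed molecule subset: any
    molecule whose prediction is invalid at any evaluated step is excluded
    at every step. Tidy rows (step, fingerprint, radius, mean_tanimoto,
    n_evaluated)."""
    n = len(target_smiles)
    always_valid = np.ones(n, dtype=bool)
    for preds in preds_by_step.values():
        if len(preds) != n:
            raise ValueError("every step must predict every molecule")
        for i, ps in enumerate(preds):
            if mol_from_smiles(ps) is None:
                always_valid[i] = False
    rows = []
    for step in sorted(preds_by_step):
        rep = similarity_report(preds_by_step[step], target_smiles, cfgs,
                                step=step, include=always_valid)
        for cfg in cfgs:
            rows.append({
                "step": step,
                "fingerprint": cfg.kind,
                "radius": cfg.radius if cfg.kind == "ecfp" else 0,
                "mean_tanimoto": rep.mean_tanimoto[cfg.label],
                "n_evaluated": rep.n_evaluated,
            })
    return pd.DataFrame(rows)


def maccs_bitwise_agreement(pred_smiles: list[str],
                            target_smiles: list[str]) -> pd.DataFrame:
    """Per-bit MACCS agreement.

    For bit value 1: among target molecules with the bit set, the fraction
    whose prediction is valid AND has the bit set; the complementary table
    conditions on target bits of 0. Bits with no qualifying targets are
    omitted. Columns: bit_index, bit_value, fraction, n_targets.
    """
    if len(pred_smiles) != len(target_smiles):
        raise ValueError("prediction and target lists must align")
    cfg = FingerprintConfig("maccs")
    tgt_fps, pred_fps = [], []
    for ps, ts in zip(pred_smiles, target_smiles):
        tm = mol_from_smiles(ts)
        if tm is None:
            raise ValueError(f"invalid target SMILES: {ts!r}")
        tgt_fps.append(fingerprint(tm, cfg))
        pm = mol_from_smiles(ps)
        pred_fps.append(fingerprint(pm, cfg) if pm is not None else None)
    T = np.array(tgt_fps)
    valid = np.array([p is not None for p in pred_fps])
    P = np.array([p if p is not None else np.zeros(T.shape[1], dtype=bool)
                  for p in pred_fps])
    rows = []
    for value in (1, 0):
        want = T if value == 1 else ~T
        match = (P if value == 1 else ~P) & valid[:, None]
        n_targets = want.sum(axis=0)
        agree = (want & match).sum(axis=0)
        for bit in np.nonzero(n_targets)[0]:
            rows.append({
                "bit_index": int(bit),
                "bit_value": value,
                "fraction": agree[bit] / n_targets[bit],
                "n_targets": int(n_targets[bit]),
            })
    return pd.DataFrame(rows)
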
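"""Translation accuracy metrics and chirality-error diagnostics.

All metrics operate at the level of vocabulary tokens (so "@@" and "Cl"
are single units), on the content tokens between the start token and the
first end token. Free-running (greedy) predictions feed perfect, partial
and masked accuracy and the chirality-error classification; teacher-forced
predictions feed the per-token accuracy table.

perfect accuracy      fraction of pairs whose content tokens match exactly
partial accuracy      micro-averaged position-wise token agreement over all
                      target content positions (missing prediction
                      positions count as mismatches)
masked accuracy       perfect accuracy with positions bearing one chosen
                      target token exempted from the match requirement
per-token accuracy    for each token, the fraction of its target positions
                      predicted correctly under teacher forcing
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .corpus import SPECIAL_TOKENS

TokenList = list


@dataclass
class ChiralityErrorBreakdown:
    frac_correct: float
    frac_chirality_only: float
    frac_other: float

    def __post_init__(self):
        total = self.frac_correct + self.frac_chirality_only + self.frac_other
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")


@dataclass
class EvalSnapshot:
    """All metrics of one model checkpoint at one training step."""

    step: int
    perfect_accuracy: float
    partial_accuracy: float
    mean_loss: float
    masked_accuracy: dict = field(default_factory=dict)
    per_token_accuracy: dict = field(default_factory=dict)
    tf_micro_accuracy: float = float("nan")  # position-weighted TF accuracy
    chirality_breakdown: ChiralityErrorBreakdown | None = None
    mean_tanimoto: dict = field(default_factory=dict)


@dataclass
class StagnationSummary:
    step_07: int
    step_095: int
    stagnated: bool
    end_step: int

    def __post_init__(self):
        if not self.step_07 <= self.step_095 <= self.end_step:
            raise ValueError("expected step_07 <= step_095 <= end_step")


def _check_pairs(predictions, targets):
    if len(predictions) != len(targets):
        raise ValueError("predictions and targets must have equal length")
    if len(targets) == 0:
        raise ValueError("metrics are undefined on empty input")


def perfect_accuracy(predictions: list[TokenList], targets: list[TokenList]) -> float:
    """Fraction of pairs translated exactly (all content tokens, in order)."""
    _check_pairs(predictions, targets)
    hits = sum(1 for p, t in zip(predictions, targets) if list(p) == list(t))
    return hits / len(targets)


def partial_accuracy(predictions: list[TokenList], targets: list[TokenList]) -> float:
    """Position-wise token agreement, averaged per molecule.

    Each pair contributes the fraction of its target positions predicted
    correctly; the batch value is the mean over pairs. This per-molecule
    (macro) averaging keeps the guarantee that an exact translation scores
    1 for both metrics, hence perfect accuracy never exceeds partial
    accuracy on any batch.
    """
    _check_pairs(predictions, targets)
    fractions = []
    for p, t in zip(predictions, targets):
        if len(t) == 0:
            raise ValueError("empty target sequence")
        hits = sum(1 for i, tok in enumerate(t) if i < len(p) and p[i] == tok)
        fractions.append(hits / len(t))
    return float(sum(fractions) / len(fractions))


def micro_token_accuracy(predictions: list[TokenList],
                         targets: list[TokenList]) -> float:
    """Token agreement pooled over all target positions (position-weighted)."""
    _check_pairs(predictions, targets)
    hits = total = 0
    for p, t in zip(predictions, targets):
        total += len(t)
        hits += sum(1 for i, tok in enumerate(t) if i < len(p) and p[i] == tok)
    if total == 0:
        raise ValueError("no target positions to score")
    return hits / total


def masked_perfect_accuracy(predictions: list[TokenList], targets: list[TokenList],
                            masked_token: str) -> float:
    """Perfect accuracy with target positions bearing ``masked_token``
    exempted from the match requirement."""
    if masked_token in SPECIAL_TOKENS:
        raise ValueError(f"cannot mask special token {masked_token!r}")
    _check_pairs(predictions, targets)
    hits = 0
    for p, t in zip(predictions, targets):
        if len(p) != len(t):
            continue
        if all(tok == masked_token or p[i] == tok for i, tok in enumerate(t)):
            hits += 1
    return hits / len(targets)


def per_token_accuracy(tf_predictions: list[TokenList],
                       targets: list[TokenList]) -> dict[str, float]:
    """Teacher-forced accuracy per target token type.

    ``tf_predictions[i][j]`` is the model's prediction for target position j
    of pair i given the correct preceding tokens; tokens never occurring in
    the targets are omitted from the result.
    """
    _check_pairs(tf_predictions, targets)
    hits: dict[str, int] = {}
    counts: dict[str, int] = {}
    for p, t in zip(tf_predictions, targets):
        for i, tok in enumerate(t):
            counts[tok] = counts.get(tok, 0) + 1
            if i < len(p) and p[i] == tok:
                hits[tok] = hits.get(tok, 0) + 1
    return {tok: hits.get(tok, 0) / n for tok, n in counts.items()}


def classify_chirality_errors(predictions: list[TokenList],
                              targets: list[TokenList]) -> ChiralityErrorBreakdown:
    """Classify each pair as correct, wrong solely by parity-token swaps
    ("@" predicted for "@@" or vice versa), or wrong for other reasons."""
    _check_pairs(predictions, targets)
    n_correct = n_chir = n_other = 0
    swaps = {("@", "@@"), ("@@", "@")}
    for p, t in zip(predictions, targets):
        p, t = list(p), list(t)
        if p == t:
            n_correct += 1
        elif len(p) == len(t) and all(
            a == b or (b, a) in swaps for a, b in zip(p, t)
        ):
            n_chir += 1
        else:
            n_other += 1
    n = len(targets)
    return ChiralityErrorBreakdown(n_correct / n, n_chir / n, n_other / n)


def extract_threshold_step(series: list[tuple[int, float]], threshold: float,
                           end_step: int) -> int:
    """Smallest evaluated step whose accuracy reaches ``threshold``; the
    end-of-training step when the threshold is never reached."""
    if not series:
        raise ValueError("empty accuracy series")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    for step, acc in series:
        if acc >= threshold:
            return step
    return end_step


def stagnation_summary(series: list[tuple[int, float]], end_step: int,
                       stagnation_fraction: float = 0.5) -> StagnationSummary:
    """Threshold steps plus an explicit operational stagnation flag:
    a run is called stagnated when step-0.7 exceeds the given fraction of
    the end-of-training step."""
    s07 = extract_threshold_step(series, 0.7, end_step)
    s095 = extract_threshold_step(series, 0.95, end_step)
    return StagnationSummary(
        step_07=s07, step_095=max(s07, s095),
        stagnated=s07 > stagnation_fraction * end_step, end_step=end_step,
    )


def snapshots_to_frame(snapshots: list[EvalSnapshot]) -> pd.DataFrame:
    """Run-metrics table, one row per evaluation."""
    rows = []
    for s in snapshots:
        row = {
            "step": s.step,
            "perfect_accuracy": s.perfect_accuracy,
            "partial_accuracy": s.partial_accuracy,
            "tf_micro_accuracy": s.tf_micro_accuracy,
            "mean_loss": s.mean_loss,
        }
        if s.chirality_breakdown is not None:
            row["frac_correct"] = s.chirality_breakdown.frac_correct
            row["frac_chirality_only"] = s.chirality_breakdown.frac_chirality_only
            row["frac_other"] = s.chirality_breakdown.frac_other
        for key, value in s.mean_tanimoto.items():
            row[f"tanimoto_{key}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def token_table(snapshots: list[EvalSnapshot], which: str) -> pd.DataFrame:
    """Tidy (step, token, value) table for masked or per-token accuracy."""
    if which not in ("masked_accuracy", "per_token_accuracy"):
        raise ValueError("which must be masked_accuracy or per_token_accuracy")
    rows = []
    for s in snapshots:
        for tok, value in getattr(s, which).items():
            rows.append({"step": s.step, "token": tok, "value": value})
    return pd.DataFrame(rows)
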
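"""Fold-error model acceptance: predicted/observed within [0.5, 2.0]."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .errors import InvalidInputError

TWOFOLD = (0.5, 2.0)


def fold_error(predicted: float, observed: float) -> float:
    """Predicted over observed; both must be positive."""
    if predicted <= 0 or observed <= 0:
        raise InvalidInputError("fold_error needs positive values")
    return predicted / observed


def within_twofold(fe: float, band: tuple = TWOFOLD) -> dict:
    """Inclusive band check; returns a verdict record."""
    if fe <= 0:
        raise InvalidInputError("fold-error must be positive")
    lo, hi = band
    return {"fold_error": fe, "band": band, "within": lo <= fe <= hi}


@dataclass(frozen=True)
class ValidationReport:
    rows: list              # per-metric dicts
    overall_pass: Optional[bool]  # None when nothing was evaluated

    def __str__(self):
        lines = []
        for r in self.rows:
            if r["fold_error"] is None:
                lines.append(f"{r['metric']}: not evaluated (no observation)")
            else:
                verdict = "PASS" if r["within"] else "FAIL"
                lines.append(f"{r['metric']}: predicted={r['predicted']:.6g} "
                             f"observed={r['observed']:.6g} "
                             f"fold-error={r['fold_error']:.1f} {verdict}")
        lines.append(f"overall: {self.overall_pass}")
        return "\n".join(lines)


def validation_report(predictions: Mapping[str, float],
                      observations: Mapping[str, float],
                      band: tuple = TWOFOLD) -> ValidationReport:
    """Per-metric fold-errors and verdicts against matched observations.

    Prediction keys with no observation are listed as not evaluated, never
    silently dropped.  Display rounds to one decimal; the verdict uses the
    unrounded value.
    """
    rows = []
    evaluated = []
    for metric, pred in predictions.items():
        if metric in observations:
            fe = fold_error(pred, observations[metric])
            verdict = within_twofold(fe, band)
            rows.append({"metric": metric, "predicted": pred,
                         "observed": observations[metric],
                         "fold_error": fe, "within": verdict["within"]})
            evaluated.append(verdict["within"])
        else:
            rows.append({"metric": metric, "predicted": pred,
                         "observed": None, "fold_error": None,
                         "within": None})
    overall = all(evaluated) if evaluated else None
    return ValidationReport(rows=rows, overall_pass=overall)
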
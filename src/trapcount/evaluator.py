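"""Counting accuracy: the α metric, prediction rounding, and per-class reports.

The trap's counting accuracy for one image is

    α = 1 − |Mc − Ac| / Mc

where Mc is the true number of insects composed into the image and Ac the
model's predicted count after rounding.  As printed, the formula is undefined
for empty scenes (Mc = 0); this module substitutes the denominator
``max(Mc, 1)``, which reduces α to exact-match for the background class and is
continuous with the Mc = 1 case.  α is deliberately NOT floored at zero — a
wildly wrong count yields a negative score — so the exact-match rate is
reported alongside for interpretability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "round_prediction",
    "count_accuracy",
    "evaluate_counts",
    "evaluate_dataset",
    "EvaluationReport",
]

ZERO_CLASS_RULE = "alpha = 1 - |Mc - Ac| / max(Mc, 1)"
ROUNDING_RULE = "Ac = max(0, round half away from zero(y_hat))"


def round_prediction(y_hat: float) -> int:
    """Turn the regressor's raw scalar into a count: round half away from
    zero, then clip at zero (a trap cannot contain a negative number of
    insects)."""
    y = float(y_hat)
    if not math.isfinite(y):
        raise ValueError("prediction is not finite")
    rounded = math.floor(abs(y) + 0.5) * (1 if y >= 0 else -1)
    return max(0, int(rounded))


def count_accuracy(mc: int, ac: int) -> float:
    """Per-image counting accuracy α (may be negative for large miscounts)."""
    if mc < 0 or ac < 0:
        raise ValueError("counts must be non-negative")
    return 1.0 - abs(int(mc) - int(ac)) / max(int(mc), 1)


@dataclass
class EvaluationReport:
    """Per-class and overall counting accuracy of one model on one test set."""

    per_class_alpha: dict[int, float]
    mean_alpha: float
    exact_match_rate: float
    n_per_class: dict[int, int]
    rounding_rule: str = ROUNDING_RULE
    zero_class_rule: str = ZERO_CLASS_RULE
    model_id: str = ""
    per_image: list[tuple[int, int, float]] = field(default_factory=list)  # (Mc, Ac, alpha)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model_id": self.model_id,
            "mean_alpha": self.mean_alpha,
            "exact_match_rate": self.exact_match_rate,
            "per_class_alpha": {str(k): v for k, v in sorted(self.per_class_alpha.items())},
            "n_per_class": {str(k): v for k, v in sorted(self.n_per_class.items())},
            "rounding_rule": self.rounding_rule,
            "zero_class_rule": self.zero_class_rule,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def format_table(self) -> str:
        lines = ["Number of insects per image    Accuracy (alpha)"]
        for cls in sorted(self.per_class_alpha):
            lines.append(f"{cls:>28d}    {self.per_class_alpha[cls]:.3f}")
        lines.append(f"{'Mean accuracy':>28s}    {self.mean_alpha:.3f}")
        lines.append(f"{'Exact-match rate':>28s}    {self.exact_match_rate:.3f}")
        return "\n".join(lines)


def evaluate_counts(true_counts, predictions, model_id: str = "") -> EvaluationReport:
    """Score raw predictions against ground-truth counts.

    ``predictions`` are the regressor's raw scalars; rounding happens here.
    The overall mean is the unweighted per-image mean of α.
    """
    true_counts = np.asarray(true_counts)
    predictions = np.asarray(predictions, dtype=np.float64)
    if true_counts.size == 0:
        raise ValueError("empty evaluation set")
    if true_counts.shape[0] != predictions.shape[0]:
        raise ValueError("true_counts and predictions differ in length")
    per_image = []
    by_class: dict[int, list[float]] = {}
    exact = 0
    for mc, y in zip(true_counts.tolist(), predictions.tolist()):
        ac = round_prediction(y)
        a = count_accuracy(mc, ac)
        per_image.append((int(mc), ac, a))
        by_class.setdefault(int(mc), []).append(a)
        exact += int(ac == int(mc))
    alphas = [a for _, _, a in per_image]
    return EvaluationReport(
        per_class_alpha={c: float(np.mean(v)) for c, v in by_class.items()},
        mean_alpha=float(np.mean(alphas)),
        exact_match_rate=exact / len(alphas),
        n_per_class={c: len(v) for c, v in by_class.items()},
        model_id=model_id,
        per_image=per_image,
    )


def evaluate_dataset(model, test_manifest, bank=None, model_id: str = "") -> EvaluationReport:
    """Render a manifest's test split, predict with ``model``, and score it.

    ``model`` is anything with a ``predict(images) -> raw scalars`` method
    (float or quantized regressor alike).
    """
    from .scene_composer import render_split  # local import; avoids cycle

    images, counts = render_split(test_manifest, "test", bank=bank)
    preds = model.predict(images)
    return evaluate_counts(counts, preds, model_id=model_id or getattr(model, "model_id", ""))
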
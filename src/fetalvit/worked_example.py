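"""The dual-head reference calculation on small printed numbers.

A 3-feature transformer output x = [2.0, −1.5, 0.5] is pushed through both
heads: the classification head softmax(W·x + b) with b = [0.1, −0.2, 0.3]
yields probabilities ≈ [0.273, 0.021, 0.706], and the severity head
w·x + b with w = [0.4, −0.5, 0.6], b = 0.2 yields the score 2.05.  The weight
matrix below realizes the reference logits [1.0, −1.55, 1.95] for this x.
"""

from __future__ import annotations

import numpy as np

from .model import classification_head, severity_head

__all__ = ["WORKED_EXAMPLE", "run_worked_example", "format_worked_example"]

WORKED_EXAMPLE = {
    "transformer_output": np.array([2.0, -1.5, 0.5]),
    "w_class": np.array(
        [
            [0.2, -0.3, 0.1],
            [-0.3, 0.5, 0.0],
            [0.5, -0.3, 0.4],
        ]
    ),
    "b_class": np.array([0.1, -0.2, 0.3]),
    "w_severity": np.array([0.4, -0.5, 0.6]),
    "b_severity": 0.2,
}


def run_worked_example() -> dict:
    """Compute logits, class probabilities and severity score for the
    reference inputs using the package's head operations."""
    x = WORKED_EXAMPLE["transformer_output"]
    logits = WORKED_EXAMPLE["w_class"] @ x + WORKED_EXAMPLE["b_class"]
    probs = classification_head(x, WORKED_EXAMPLE["w_class"], WORKED_EXAMPLE["b_class"])
    score = severity_head(x, WORKED_EXAMPLE["w_severity"], WORKED_EXAMPLE["b_severity"])
    return {"logits": logits, "class_probs": probs, "severity_score": score}


def format_worked_example() -> str:
    res = run_worked_example()
    probs = ", ".join(f"{p:.3f}" for p in res["class_probs"])
    return (
        "Dual-head worked example\n"
        f"  transformer output : {WORKED_EXAMPLE['transformer_output'].tolist()}\n"
        f"  logits             : [{', '.join(f'{v:.2f}' for v in res['logits'])}]\n"
        f"  class probabilities: [{probs}]\n"
        f"  severity score     : {res['severity_score']:.2f}\n"
    )
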
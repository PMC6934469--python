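"""Minimal ROC plotting helpers (optional figure export)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_mean_rocs(results, path=None, stage: str = "test", ax=None):
    """Overlay the mean ROC curves of several experiment results.

    ``results`` is an iterable of :class:`~vesseltort.evaluate.ExperimentResult`;
    ``stage`` selects the train or test mean curve.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for res in results:
        curve = res.mean_train_curve if stage == "train" else res.mean_test_curve
        ax.plot(curve.fpr, curve.tpr, label=f"{res.variant} (AUC {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.set_title(f"mean {stage} ROC across splits")
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
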
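"""Group-stratified evaluation: per (diagnosis x age-bin) accuracies,
worst-group extraction, precision/recall per age bin, target-age histograms,
and side-by-side comparison tables across methods.

Age bins are half-open [lo, hi) with the last bin closed on the right, so a
90-year-old falls in the top bin.  The decision threshold is fixed at 0.5
and AD is the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .toyworld import images_of, labels_of, ages_of

__all__ = ["GroupReport", "group_metrics", "age_histogram", "compare_runs",
           "plot_age_histograms"]

DIAG_NAMES = {0: "CN", 1: "AD"}


def _bin_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}"


def _bin_index(ages: np.ndarray, age_bins) -> np.ndarray:
    """Half-open bin assignment, last bin closed; -1 for out-of-range ages."""
    idx = np.full(len(ages), -1, dtype=int)
    for j, (lo, hi) in enumerate(age_bins):
        last = j == len(age_bins) - 1
        mask = (ages >= lo) & ((ages <= hi) if last else (ages < hi))
        idx[mask] = np.where(idx[mask] == -1, j, idx[mask])
    return idx


@dataclass
class GroupReport:
    """Stratified metrics of one classifier on one split.

    ``cells`` maps (diagnosis name, bin label) -> {n, accuracy}; empty cells
    hold ``accuracy=None`` and never enter the worst-group minimum.  The
    overall accuracy equals the n-weighted mean of cell accuracies.
    """

    age_bins: list
    cells: dict = field(default_factory=dict)
    bin_precision: dict = field(default_factory=dict)
    bin_recall: dict = field(default_factory=dict)
    overall: dict = field(default_factory=dict)
    worst_group: tuple = ("", np.nan)

    def cell_accuracy(self, diag: str, bin_label: str):
        return self.cells[(diag, bin_label)]["accuracy"]

    def to_row(self) -> dict:
        """Flat dict in Table-2 layout: one column per cell + overall + worst."""
        row = {}
        for (diag, lab), cell in self.cells.items():
            row[f"{diag} {lab}"] = cell["accuracy"]
        row["overall"] = self.overall["accuracy"]
        row["worst_group"] = self.worst_group[1]
        return row

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (diag, lab), cell in self.cells.items():
            rows.append(dict(diagnosis=diag, age_bin=lab, n=cell["n"],
                             accuracy=cell["accuracy"]))
        return pd.DataFrame(rows)


def group_metrics(classifier, test_samples, age_bins=None) -> GroupReport:
    """Evaluate a classifier stratified by diagnosis and age bin.

    Per-cell accuracy at threshold 0.5; per-age-bin precision and recall with
    AD positive (pooling both labels inside the bin); overall metrics; the
    worst group is the non-empty cell with minimal accuracy.
    """
    age_bins = age_bins or [(60.0, 70.0), (70.0, 80.0), (80.0, 90.0)]
    y = labels_of(test_samples)
    ages = ages_of(test_samples)
    pred = (classifier.predict_proba(images_of(test_samples)) > 0.5).astype(int)
    bidx = _bin_index(ages, age_bins)

    report = GroupReport(age_bins=list(age_bins))
    worst_name, worst_acc = "", np.inf
    for d in (0, 1):
        for j, (lo, hi) in enumerate(age_bins):
            lab = _bin_label(lo, hi)
            mask = (y == d) & (bidx == j)
            n = int(mask.sum())
            if n == 0:
                report.cells[(DIAG_NAMES[d], lab)] = {"n": 0, "accuracy": None}
                continue
            acc = float(np.mean(pred[mask] == y[mask]))
            report.cells[(DIAG_NAMES[d], lab)] = {"n": n, "accuracy": acc}
            if acc < worst_acc:
                worst_name, worst_acc = f"{DIAG_NAMES[d]} {lab}", acc
    report.worst_group = (worst_name, float(worst_acc))

    def _prec_rec(mask):
        tp = int(np.sum((pred == 1) & (y == 1) & mask))
        fp = int(np.sum((pred == 1) & (y == 0) & mask))
        fn = int(np.sum((pred == 0) & (y == 1) & mask))
        prec = tp / (tp + fp) if tp + fp else None
        rec = tp / (tp + fn) if tp + fn else None
        return prec, rec

    for j, (lo, hi) in enumerate(age_bins):
        lab = _bin_label(lo, hi)
        report.bin_precision[lab], report.bin_recall[lab] = _prec_rec(bidx == j)

    full = np.ones(len(y), dtype=bool)
    prec, rec = _prec_rec(full)
    report.overall = {"accuracy": float(np.mean(pred == y)),
                      "precision": prec, "recall": rec, "n": len(y)}
    return report


def age_histogram(ages, bin_edges) -> np.ndarray:
    """Counts per half-open bin [lo, hi), last bin closed; sums to n for ages
    within the edges."""
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(np.asarray(ages, dtype=float), bins=edges)
    return counts


def compare_runs(reports: dict) -> pd.DataFrame:
    """Methods as rows, group cells + overall + worst-group as columns.

    The returned frame carries a boolean companion ``frame.attrs['best']``
    flagging the best entry per column.
    """
    df = pd.DataFrame({name: rep.to_row() for name, rep in reports.items()}).T
    best = pd.DataFrame(False, index=df.index, columns=df.columns)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.notna().any():
            best[col] = vals == vals.max()
    df.attrs["best"] = best
    return df


def plot_age_histograms(before: np.ndarray, after: np.ndarray, labels: np.ndarray,
                        path, bin_edges=None) -> None:
    """Side-by-side target-age histograms (before vs after the adversarial
    game) for AD and CN hard samples."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = np.asarray(bin_edges if bin_edges is not None
                       else np.arange(60.0, 91.0, 2.5))
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, d, name in zip(axes, (1, 0), ("AD", "CN")):
        m = labels == d
        ax.hist(before[m], bins=edges, alpha=0.6, label="before")
        ax.hist(after[m], bins=edges, alpha=0.6, label="after")
        ax.set_title(f"{name} hard samples")
        ax.set_xlabel("target age (years)")
        ax.legend()
    axes[0].set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
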
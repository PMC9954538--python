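"""Per-subject training/evaluation protocol and statistical comparison.

The protocol mirrors common within-subject BCI evaluation practice: trials
are split either by rotating 4-fold cross-validation (50% train / 25%
validation / 25% test per fold, stratified by label) or by keeping a given
test set fixed and drawing a seeded 80/20 train/validation split from the
remainder.  Networks train with Adam (weight decay 0.001, other settings at
their defaults) on the softmax cross-entropy loss, batch size 32, with
minimum-validation-loss checkpointing: validation loss is evaluated once per
epoch and the model state is saved only on strict improvement; the
checkpointed state is restored for testing.

Variant comparisons use two-tailed paired t-tests over per-subject mean
accuracies.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .montage import EpochSet

__all__ = [
    "TrainingConfig",
    "SplitScheme",
    "Fold",
    "RunResult",
    "PairedTestReport",
    "split",
    "train_eval",
    "select_checkpoint",
    "compare",
    "summarize",
]


@dataclass(frozen=True)
class TrainingConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("batch size, epochs and learning rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass(frozen=True)
class SplitScheme:
    """Trial-partition scheme: ``cv4`` or ``fixed-test``.

    cv4 partitions trials into 4 stratified quarters; fold i tests on
    quarter i, validates on quarter (i+1) mod 4 and trains on the rest.
    fixed-test keeps ``test_indices`` untouched and splits the remainder
    80/20 into train/validation, reshuffled per repeat.
    """

    mode: str = "cv4"
    n_repeats: int = 4
    seed: int = 0
    shuffle: bool = True
    test_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cv4", "fixed-test"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "fixed-test" and self.test_indices is None:
            raise ValueError("fixed-test mode requires test_indices")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class Fold:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def _stratified_quarters(labels: np.ndarray, rng: np.random.Generator,
                         shuffle: bool) -> list[np.ndarray]:
    quarters: list[list[int]] = [[] for _ in range(4)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 4:
            raise ValueError(
                f"stratification error: class {cls!r} has only {len(idx)} trials, "
                "cv4 needs at least 4 per class"
            )
        if shuffle:
            idx = rng.permutation(idx)
        for q, part in enumerate(np.array_split(idx, 4)):
            quarters[q].extend(part.tolist())
    return [np.sort(np.array(q, dtype=int)) for q in quarters]


def _check_all_classes(labels: np.ndarray, fold: Fold) -> None:
    classes = set(np.unique(labels))
    for role, idx in (("train", fold.train), ("val", fold.val), ("test", fold.test)):
        present = set(np.unique(labels[idx]))
        if present != classes:
            raise ValueError(
                f"stratification error: class(es) {sorted(classes - present)} "
                f"absent from the {role} set"
            )


def split(epochs: EpochSet, scheme: SplitScheme) -> list[Fold]:
    """Partition trials into (train, val, test) index sets per fold."""
    labels = epochs.labels
    rng = np.random.default_rng(scheme.seed)
    folds: list[Fold] = []
    if scheme.mode == "cv4":
        quarters = _stratified_quarters(labels, rng, scheme.shuffle)
        for i in range(4):
            test = quarters[i]
            val = quarters[(i + 1) % 4]
            train = np.sort(np.concatenate([quarters[(i + 2) % 4], quarters[(i + 3) % 4]]))
            folds.append(Fold(train, val, test))
    else:
        test = np.asarray(scheme.test_indices, dtype=int)
        pool = np.setdiff1d(np.arange(epochs.n_trials), test)
        for _ in range(scheme.n_repeats):
            tr_parts, va_parts = [], []
            for cls in np.unique(labels[pool]):
                idx = rng.permutation(pool[labels[pool] == cls])
                n_val = max(int(round(0.2 * len(idx))), 1)
                va_parts.append(idx[:n_val])
                tr_parts.append(idx[n_val:])
            folds.append(Fold(np.sort(np.concatenate(tr_parts)),
                              np.sort(np.concatenate(va_parts)), test))
    for fold in folds:
        _check_all_classes(labels, fold)
    return folds


def select_checkpoint(val_losses: Sequence[float]) -> int:
    """Epoch index (0-based) of the checkpointed model: the last epoch that
    strictly improved on all previous validation losses."""
    best, best_epoch = np.inf, 0
    for i, v in enumerate(val_losses):
        if v < best:
            best, best_epoch = v, i
    return best_epoch


@dataclass
class RunResult:
    """Per-fold outcomes of one (network, subject) training run."""

    fold_accuracies: list[float]            # percent, successful folds only
    train_curves: list[list[float]]
    val_curves: list[list[float]]
    best_epochs: list[int]                  # 1-based epoch of minimum val loss
    parameter_count: int
    failed_folds: list[int] = field(default_factory=list)
    wall_time_s: float = 0.0                # informational only

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies)) if self.fold_accuracies else np.nan

    @property
    def sd_accuracy(self) -> float:
        if len(self.fold_accuracies) < 2:
            return 0.0
        return float(np.std(self.fold_accuracies, ddof=1))


def _batched_loss(network: nn.Module, loss_fn: nn.CrossEntropyLoss,
                  x: np.ndarray, y: np.ndarray, batch: int) -> tuple[float, float]:
    """(mean loss, accuracy %) over a dataset in inference mode."""
    network.eval()
    total_loss, correct = 0.0, 0
    for s in range(0, len(x), batch):
        xb, yb = x[s:s + batch], y[s:s + batch]
        logits = network.forward(xb)
        total_loss += loss_fn(logits, yb) * len(xb)
        correct += int((logits.argmax(axis=1) == yb).sum())
    return total_loss / len(x), 100.0 * correct / len(x)


def train_eval(
    network: nn.Module | Callable[[int], nn.Module],
    splits: Sequence[Fold],
    epochs: EpochSet,
    config: TrainingConfig = TrainingConfig(),
) -> RunResult:
    """Train/evaluate one network over the given folds.

    ``network`` may be a module (its initial state is restored before every
    fold) or a factory ``fold_seed -> module`` building a fresh instance per
    fold.  Per fold: train ``max_epochs`` epochs, checkpoint on strict
    validation-loss improvement, restore the best checkpoint and report test
    accuracy in percent.  Folds whose loss turns non-finite are excluded
    with a warning.  Identical seeds give identical results.
    """
    t0 = time.perf_counter()
    classes = np.unique(epochs.labels)
    class_index = {c: i for i, c in enumerate(classes)}
    y_all = np.array([class_index[c] for c in epochs.labels])
    x_all = epochs.data
    loss_fn = nn.CrossEntropyLoss()
    factory = network if callable(network) and not isinstance(network, nn.Module) else None
    init_state = nn.get_state(network) if factory is None else None

    result = RunResult([], [], [], [], parameter_count=0)
    for fold_i, fold in enumerate(splits):
        net = factory(config.seed + fold_i) if factory else network
        if factory is None:
            nn.set_state(net, init_state)
        result.parameter_count = nn.count_trainable(net)
        opt = nn.Adam(net.parameters(), lr=config.learning_rate,
                      weight_decay=config.weight_decay)
        rng = np.random.default_rng(config.seed * 100003 + fold_i)
        xt, yt = x_all[fold.train], y_all[fold.train]
        train_curve: list[float] = []
        val_curve: list[float] = []
        best_val, best_state = np.inf, nn.get_state(net)
        diverged = False
        for _epoch in range(config.max_epochs):
            net.train()
            order = rng.permutation(len(xt))
            batch_losses = []
            for s in range(0, len(order), config.batch_size):
                sel = order[s:s + config.batch_size]
                opt.zero_grad()
                logits = net.forward(xt[sel])
                loss = loss_fn(logits, yt[sel])
                if not np.isfinite(loss):
                    diverged = True
                    break
                net.backward(loss_fn.backward())
                opt.step()
                batch_losses.append(loss)
            if diverged:
                break
            val_loss, _ = _batched_loss(net, loss_fn, x_all[fold.val], y_all[fold.val],
                                        config.batch_size)
            train_curve.append(float(np.mean(batch_losses)))
            val_curve.append(val_loss)
            if val_loss < best_val:  # strict improvement only
                best_val = val_loss
                best_state = nn.get_state(net)
        if diverged or not np.isfinite(best_val):
            warnings.warn(f"fold {fold_i} diverged (non-finite loss); excluded",
                          stacklevel=2)
            result.failed_folds.append(fold_i)
            continue
        nn.set_state(net, best_state)
        _, test_acc = _batched_loss(net, loss_fn, x_all[fold.test], y_all[fold.test],
                                    config.batch_size)
        result.fold_accuracies.append(test_acc)
        result.train_curves.append(train_curve)
        result.val_curves.append(val_curve)
        result.best_epochs.append(select_checkpoint(val_curve) + 1)
    result.wall_time_s = time.perf_counter() - t0
    return result


@dataclass(frozen=True)
class PairedTestReport:
    n: int
    mean_difference: float
    t_statistic: float
    p_value: float
    degenerate: bool = False


def compare(results_a: Sequence[float], results_b: Sequence[float]) -> PairedTestReport:
    """Two-tailed paired t-test on paired per-subject accuracies.

    t = mean(d) / (sd(d) / sqrt(n)) with d = a - b and the sample standard
    deviation (ddof=1); p from the t distribution with n-1 degrees of
    freedom.  Identical vectors give p = 1; zero-variance differences with a
    nonzero mean are degenerate (p undefined, reported as NaN).
    """
    a = np.asarray(results_a, dtype=np.float64)
    b = np.asarray(results_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("pairing error: inputs must be equal-length 1-D vectors")
    n = len(a)
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTestReport(n, 0.0, 0.0, 1.0)
        return PairedTestReport(n, mean_d, np.inf if mean_d > 0 else -np.inf,
                                np.nan, degenerate=True)
    t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return PairedTestReport(n, mean_d, float(t), p)


@dataclass
class Summary:
    """Comparison table across subjects and run configurations."""

    table: pd.DataFrame          # per subject: "mean ± sd" strings
    means: pd.DataFrame          # per subject: mean accuracy (float)
    averages: pd.Series          # per configuration: average over subjects
    deltas: pd.Series            # TRM variant mean - original mean
    p_values: pd.Series          # paired t-test vs original, per variant

    def __str__(self) -> str:  # pragma: no cover - formatting
        lines = [self.table.to_string(), "", "Average: ",
                 self.averages.to_string(), "", "Delta vs original:",
                 self.deltas.to_string(), "", "p (two-tailed paired t):",
                 self.p_values.to_string()]
        return "\n".join(lines)


def summarize(results: Mapping[tuple[str, str], RunResult]) -> Summary:
    """Tabulate runs keyed by (subject, configuration identifier).

    Configuration identifiers follow the registry naming (e.g. ``shallow``,
    ``shallow+trm-5``).  Deltas and p-values compare each TRM variant with
    its original backbone over the common subjects; missing cells are left
    as explicit gaps.
    """
    subjects = sorted({s for s, _ in results})
    configs = sorted({c for _, c in results})
    means = pd.DataFrame(index=subjects, columns=configs, dtype=float)
    cells = pd.DataFrame(index=subjects, columns=configs, dtype=object)
    for (subj, cfg), run in results.items():
        means.loc[subj, cfg] = run.mean_accuracy
        sd_flag = " (single fold)" if len(run.fold_accuracies) == 1 else ""
        cells.loc[subj, cfg] = f"{run.mean_accuracy:.2f} ± {run.sd_accuracy:.2f}{sd_flag}"
    averages = means.mean(axis=0)
    deltas, pvals = {}, {}
    for cfg in configs:
        if "+" not in cfg:
            continue
        base = cfg.split("+", 1)[0]
        if base not in means.columns:
            continue
        both = means[[base, cfg]].dropna()
        if both.empty:
            continue
        deltas[cfg] = float(both[cfg].mean() - both[base].mean())
        if len(both) >= 2:
            pvals[cfg] = compare(both[cfg].to_numpy(), both[base].to_numpy()).p_value
        else:
            pvals[cfg] = np.nan
    return Summary(cells, means, averages, pd.Series(deltas, dtype=float),
                   pd.Series(pvals, dtype=float))
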
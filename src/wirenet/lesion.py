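"""Module-lesion experiments and task/module specialization statistics.

A lesion silences every hidden unit of one structural module (zeroing its
recurrent, input, and output projections) and re-evaluates the trained
model per subtask without retraining. Specialization is quantified by the
population variances of the relative per-subtask accuracy changes, taken
across subtasks for a fixed module (task variance) or across modules for
a fixed subtask (module variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import SparseRecurrentModel

__all__ = [
    "LesionReport",
    "lesion_module",
    "relative_accuracy_change",
    "task_variance",
    "module_variance",
    "per_class_accuracy",
    "lesion_report",
    "compare_conditions",
]


@dataclass
class LesionReport:
    """acc(i, beta) for every (subtask i, module beta) plus derived variances."""

    acc_matrix: pd.DataFrame          # rows: subtasks, columns: modules
    task_variance: pd.Series          # sigma^2_task(beta), one per module
    module_variance: pd.Series        # sigma^2_module(i), one per subtask
    avg_task_variance: float          # mean over modules of sigma_task(beta)
    avg_module_variance: float        # mean over subtasks of sigma_module(i)

    def to_csv(self, path) -> None:
        long = self.acc_matrix.reset_index().melt(
            id_vars="index", var_name="module", value_name="acc_change"
        )
        long.rename(columns={"index": "subtask"}).to_csv(path, index=False)


def lesion_module(
    model: SparseRecurrentModel,
    partition: dict[int, int],
    beta: int,
) -> SparseRecurrentModel:
    """Copy of the model with module beta silenced (no retraining).

    All incoming/outgoing recurrent weights, input projections, and
    output projections of the module's units are zeroed; tensors keep
    their shapes so unit indexing is preserved. Idempotent.
    """
    units = np.array([u for u, c in partition.items() if c == beta], dtype=int)
    lesioned = model.clone()
    if len(units) == 0:
        return lesioned
    if len(units) >= model.hidden_size:
        raise ValueError("lesion would remove every hidden unit")
    for name in lesioned.recurrent_param_names:
        lesioned.params[name].data[units, :] = 0.0
        lesioned.params[name].data[:, units] = 0.0
    input_names = ("W_R", "W_Q", "W_S") if model.cell_type == "gru" else ("U",)
    bias_names = ("b_R", "b_Q", "b_S") if model.cell_type == "gru" else ("b",)
    for name in input_names:
        lesioned.params[name].data[:, units] = 0.0
    for name in bias_names:
        lesioned.params[name].data[units] = 0.0
    lesioned.params["V"].data[units, :] = 0.0
    return lesioned


def relative_accuracy_change(acc_full: np.ndarray, acc_lesioned: np.ndarray) -> np.ndarray:
    """acc(i, beta) = (lesioned - full) / full, per subtask.

    Subtasks with zero baseline accuracy yield NaN with a warning; callers
    exclude them.
    """
    acc_full = np.asarray(acc_full, dtype=np.float64)
    acc_lesioned = np.asarray(acc_lesioned, dtype=np.float64)
    out = np.full(acc_full.shape, np.nan)
    ok = acc_full > 0
    if not ok.all():
        warnings.warn(
            f"excluding {np.count_nonzero(~ok)} subtask(s) with zero baseline accuracy"
        )
    out[ok] = (acc_lesioned[ok] - acc_full[ok]) / acc_full[ok]
    return out


def _population_variance(values) -> float:
    v = np.asarray(values, dtype=np.float64)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("variance needs at least 2 values")
    return float(np.mean((v - v.mean()) ** 2))


def task_variance(acc_row) -> float:
    """Population variance of acc(., beta) across subtasks for one module."""
    return _population_variance(acc_row)


def module_variance(acc_col) -> float:
    """Population variance of acc(i, .) across modules for one subtask."""
    return _population_variance(acc_col)


def per_class_accuracy(model: SparseRecurrentModel, X, y) -> pd.Series:
    """Recall per class label (the per-subtask accuracy of a classifier)."""
    y = np.asarray(y)
    pred = model.predict(X)
    return pd.Series(
        {cls: float(np.mean(pred[y == cls] == cls)) for cls in np.unique(y)}
    )


def lesion_report(
    model: SparseRecurrentModel,
    partition: dict[int, int],
    X,
    y,
    relative: bool = True,
) -> LesionReport:
    """Lesion every module in turn and assemble the specialization report."""
    acc_full = per_class_accuracy(model, X, y)
    modules = sorted(set(partition.values()))
    cols = {}
    for beta in modules:
        acc_les = per_class_accuracy(lesion_module(model, partition, beta), X, y)
        if relative:
            cols[beta] = pd.Series(
                relative_accuracy_change(acc_full.values, acc_les.values),
                index=acc_full.index,
            )
        else:
            cols[beta] = acc_les - acc_full
    acc_matrix = pd.DataFrame(cols).dropna(axis=0)

    tv = acc_matrix.apply(task_variance, axis=0)
    mv = acc_matrix.apply(module_variance, axis=1)
    return LesionReport(
        acc_matrix=acc_matrix,
        task_variance=tv,
        module_variance=mv,
        avg_task_variance=float(np.sqrt(tv).mean()),
        avg_module_variance=float(np.sqrt(mv).mean()),
    )


def compare_conditions(
    reports_with_cost: list[LesionReport],
    reports_without: list[LesionReport],
) -> pd.DataFrame:
    """Two-sample t-tests on the average variances across runs.

    Significance levels 5, 1, 0.1, and 0.01 % map to one to four stars.
    """
    if len(reports_with_cost) < 2 or len(reports_without) < 2:
        raise ValueError("need at least 2 reports per condition")
    rows = []
    for stat_name in ("avg_task_variance", "avg_module_variance"):
        a = np.array([getattr(r, stat_name) for r in reports_with_cost])
        b = np.array([getattr(r, stat_name) for r in reports_without])
        degenerate = a.var() == 0 and b.var() == 0
        if degenerate:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b)
        stars = sum(p < level for level in (0.05, 0.01, 1e-3, 1e-4))
        rows.append(
            {
                "statistic": stat_name,
                "mean_with_cost": a.mean(),
                "mean_without_cost": b.mean(),
                "t": float(t),
                "p": float(p),
                "stars": "*" * stars,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
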
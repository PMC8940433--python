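"""Two-group expression comparison of the key target genes.

Emulates a tumor-vs-normal microarray contrast at the level of the statistic:
for each requested gene, a two-sided Welch (unequal-variance) t-test between
the case and control columns of a pre-summarized expression matrix. Welch is
the default because the emulated dataset has unbalanced groups; a
pooled-variance mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NetpharmError

GROUPS = ("control", "case")


@dataclass
class ExpressionMatrix:
    """genes × samples matrix plus per-sample group labels.

    values : DataFrame with gene rows and sample columns, no missing entries.
    labels : Series indexed by sample id with values in {"control", "case"},
             at least two samples per group.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        if set(self.labels.index) != set(self.values.columns):
            raise NetpharmError("label sample ids do not match matrix columns")
        levels = set(self.labels.unique())
        if levels != set(GROUPS):
            raise NetpharmError(f"labels must have exactly the levels {GROUPS}, got {sorted(levels)}")
        for g in GROUPS:
            if (self.labels == g).sum() < 2:
                raise NetpharmError(f"group {g!r} has fewer than 2 samples")
        if self.values.isna().any().any():
            raise NetpharmError("expression matrix contains missing values")

    def group_columns(self, group: str) -> pd.DataFrame:
        return self.values[self.labels.index[self.labels == group]]


def two_group_test(
    matrix: ExpressionMatrix,
    genes: Iterable[str] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sided t-test, case minus control.

    Returns a DataFrame indexed by gene with columns mean_diff, t, p and a
    ``degenerate`` flag for genes whose values are constant within both groups
    (t is then 0 with p = 1 when the constants agree, ±inf with p = 0 when
    they differ).
    """
    if genes is None:
        genes = list(matrix.values.index)
    else:
        genes = list(genes)
        missing = [g for g in genes if g not in matrix.values.index]
        if missing:
            raise NetpharmError(f"genes absent from expression matrix: {missing}")

    ctl = matrix.group_columns("control").loc[genes].to_numpy(float)
    cas = matrix.group_columns("case").loc[genes].to_numpy(float)

    diff = cas.mean(axis=1) - ctl.mean(axis=1)
    degenerate = (ctl.var(axis=1) == 0) & (cas.var(axis=1) == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(cas, ctl, axis=1, equal_var=equal_var)

    t = np.asarray(t, float)
    p = np.asarray(p, float)
    # both groups constant: the test statistic is 0/0; report the limit
    same = degenerate & (diff == 0)
    t[same], p[same] = 0.0, 1.0
    differ = degenerate & (diff != 0)
    t[differ] = np.sign(diff[differ]) * np.inf
    p[differ] = 0.0

    return pd.DataFrame(
        {"mean_diff": diff, "t": t, "p": p, "degenerate": degenerate}, index=pd.Index(genes, name="gene")
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, values_path: str | Path, labels_path: str | Path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="gene")
    matrix.labels.rename("group").to_csv(labels_path, sep="\t", index_label="sample")


def read_expression(values_path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    labels = pd.read_csv(labels_path, sep="\t", index_col="sample")["group"]
    return ExpressionMatrix(values=values, labels=labels)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t")
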
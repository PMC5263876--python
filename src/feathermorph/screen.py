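"""Differential-expression candidate screen for vane-shape regulators.

Narrow-vane tissue (lateral primary remige, dorsal plume) is compared
against wide-vane tissue (medial primary remige, breast plume) on TPM
abundance tables.  Because replicate transcriptomes are nearly identical,
the screen uses hard thresholds instead of a variance-based test: a gene
passes when

* fold change of the higher group over the lower exceeds 1.8 (strict),
* the higher group's mean TPM exceeds 25 (strict), and
* both replicate pairs change in the same direction.

Fold change is higher mean / lower mean with the lower mean floored at a
pseudocount of 1 TPM, which handles zeros and leaves the verdict
scale-invariant once abundances are comfortably above the floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("narrow_vane", "wide_vane")


@dataclass
class ExpressionTable:
    """Gene x sample TPM matrix with a two-group replicate design."""

    values: pd.DataFrame            # index: genes, columns: sample names
    sample_sheet: pd.DataFrame      # columns: sample, group, replicate

    def __post_init__(self) -> None:
        ss = self.sample_sheet
        required = {"sample", "group", "replicate"}
        if not required.issubset(ss.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        if set(ss["group"]) != set(GROUPS):
            raise ValueError(f"groups must be exactly {GROUPS}")
        if list(ss["sample"]) != list(self.values.columns):
            raise ValueError("sample sheet order must match value columns")
        counts = ss.groupby("group")["replicate"].agg(["size", "nunique"])
        if (counts["size"] < 2).any():
            raise ValueError("need >= 2 replicates per group")
        reps = {g: sorted(ss.loc[ss.group == g, "replicate"]) for g in GROUPS}
        if reps[GROUPS[0]] != reps[GROUPS[1]]:
            raise ValueError("replicate indices must pair up across groups")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("TPM values must be finite and non-negative")

    def group_columns(self, group: str) -> list[str]:
        ss = self.sample_sheet
        sub = ss[ss.group == group].sort_values("replicate")
        return list(sub["sample"])


def apply_candidate_filter(
    table: ExpressionTable,
    fc_min: float = 1.8,
    tpm_min: float = 25.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Evaluate the three screen conditions per gene.

    Returns a frame indexed by gene with columns ``fold_change``,
    ``max_group_mean``, ``direction_consistent``, ``passed`` and
    ``failure_reasons`` (semicolon-joined, empty when passed).
    """
    cols_a = table.group_columns(GROUPS[0])
    cols_b = table.group_columns(GROUPS[1])
    a = table.values[cols_a].to_numpy()
    b = table.values[cols_b].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    hi = np.maximum(mean_a, mean_b)
    lo = np.minimum(mean_a, mean_b)
    fc = hi / np.maximum(lo, pseudocount)

    diffs = b - a                       # replicate-paired differences
    signs = np.sign(diffs)
    consistent = np.all(signs == signs[:, :1], axis=1) & np.all(signs != 0, axis=1)

    passed = (fc > fc_min) & (hi > tpm_min) & consistent
    reasons = []
    for f, h, c in zip(fc, hi, consistent):
        r = []
        if not f > fc_min:
            r.append(f"fold_change<={fc_min}")
        if not h > tpm_min:
            r.append(f"max_group_mean<={tpm_min}")
        if not c:
            r.append("direction_inconsistent")
        reasons.append(";".join(r))
    return pd.DataFrame(
        {
            "fold_change": fc,
            "max_group_mean": hi,
            "direction_consistent": consistent,
            "passed": passed,
            "failure_reasons": reasons,
        },
        index=table.values.index,
    )


def read_expression_table(values_tsv, sample_sheet_tsv) -> ExpressionTable:
    values = pd.read_csv(values_tsv, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_tsv, sep="\t")
    return ExpressionTable(values=values, sample_sheet=sheet)


def write_screen_result(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index_label="gene")
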
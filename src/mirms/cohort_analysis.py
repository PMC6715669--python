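"""Downstream stages: RIP-Seq consensus intersection, paired group
comparison, and biomarker ROC analysis.

The RIP-Seq methylation call (RPM and IP/input enrichment thresholds) is an
explicit analysis decision — both thresholds are required parameters with
no silent defaults, because published criteria for such calls vary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, List, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConsensusResult",
    "consensus_methylated",
    "paired_test",
    "roc_auc",
]

RPM_FLOOR = 0.5  # pseudo-RPM floor for the input channel in enrichment ratios


@dataclass(frozen=True)
class ConsensusResult:
    per_sample: Tuple[Tuple[str, FrozenSet[str]], ...]
    intersection: FrozenSet[str]
    venn_counts: Tuple[Tuple[Tuple[str, ...], int], ...]  # sample combo -> |∩|

    def sets(self) -> Dict[str, FrozenSet[str]]:
        return dict(self.per_sample)


def _rpm(counts: pd.Series) -> pd.Series:
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero library size")
    return counts / total * 1e6


def consensus_methylated(
    tables: Mapping[str, pd.DataFrame],
    min_rpm: float,
    min_enrichment: float,
    rpm_floor: float = RPM_FLOOR,
) -> ConsensusResult:
    """Call methylated miRNAs per sample and intersect across samples.

    Each table must have integer-count columns ``IP`` and ``input`` indexed
    by miRNA id.  A miRNA is called methylated in a sample iff
    ``RPM_IP >= min_rpm`` and ``RPM_IP / max(RPM_input, rpm_floor) >=
    min_enrichment``.  Returns per-sample sets, intersection counts for
    every sample combination of size >= 2 (Venn counts), and the full
    intersection.
    """
    if not tables:
        raise ValueError("at least one sample table is required")
    per_sample: List[Tuple[str, FrozenSet[str]]] = []
    for name, tab in tables.items():
        for channel in ("IP", "input"):
            if channel not in tab.columns:
                raise ValueError(f"sample {name!r} is missing channel {channel!r}")
        if (tab[["IP", "input"]] < 0).any().any():
            raise ValueError(f"sample {name!r} has negative counts")
        rpm_ip = _rpm(tab["IP"].astype(float))
        rpm_in = _rpm(tab["input"].astype(float))
        enrichment = rpm_ip / np.maximum(rpm_in, rpm_floor)
        called = tab.index[(rpm_ip >= min_rpm) & (enrichment >= min_enrichment)]
        per_sample.append((str(name), frozenset(map(str, called))))

    names = [n for n, _ in per_sample]
    sets = dict(per_sample)
    venn: List[Tuple[Tuple[str, ...], int]] = []
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = frozenset.intersection(*(sets[n] for n in combo))
            venn.append((combo, len(inter)))
    intersection = frozenset.intersection(*(s for _, s in per_sample))
    return ConsensusResult(tuple(per_sample), intersection, tuple(venn))


def _extract_pairs(table: pd.DataFrame, value: str) -> Tuple[np.ndarray, np.ndarray]:
    required = {"group", "pair_id", value}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns {sorted(missing)}")
    case = table[table["group"] == "case"].set_index("pair_id")[value]
    ctrl = table[table["group"] == "control"].set_index("pair_id")[value]
    if case.index.duplicated().any() or ctrl.index.duplicated().any():
        raise ValueError("a pair id appears more than once within a group")
    common = case.index.intersection(ctrl.index)
    common = common[common != ""]
    return case.loc[common].to_numpy(float), ctrl.loc[common].to_numpy(float)


def paired_test(
    table: pd.DataFrame, value: str = "fraction", method: str = "t"
) -> Tuple[float, int, float]:
    """Paired two-sided comparison of case vs control values.

    ``method='t'`` computes the paired t statistic from the closed form
    (mean difference over its standard error) with ``n - 1`` degrees of
    freedom.  ``method='wilcoxon'`` runs the signed-rank alternative
    (statistic, df = n - 1, p-value).  Zero variance of non-zero differences
    yields t = +/-inf with p = 0 (documented convention).
    """
    case, ctrl = _extract_pairs(table, value)
    n = len(case)
    if n < 2:
        raise ValueError("paired test requires >= 2 complete pairs")
    diff = case - ctrl
    if method == "wilcoxon":
        res = stats.wilcoxon(case, ctrl, zero_method="wilcox")
        return float(res.statistic), n - 1, float(res.pvalue)
    if method != "t":
        raise ValueError(f"unknown method {method!r}")
    mean = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, n - 1, 1.0
        return math.copysign(math.inf, mean), n - 1, 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), n - 1, float(p)


def roc_auc(
    table: pd.DataFrame,
    marker: str = "fraction",
    below_detection_as_zero: bool = True,
) -> Tuple[pd.DataFrame, float]:
    """ROC curve and AUC for a marker separating case from control.

    AUC uses the Mann-Whitney identity with tie correction (ties count
    one half).  Missing marker values are treated as below the detection
    limit and set to 0 when ``below_detection_as_zero``.  Returns the ROC
    points (one row per distinct threshold, columns fpr/tpr/threshold) and
    the AUC.
    """
    if marker not in table.columns:
        raise ValueError(f"cohort table has no column {marker!r}")
    values = table[marker].astype(float)
    if below_detection_as_zero:
        values = values.fillna(0.0)
    elif values.isna().any():
        raise ValueError("missing marker values")
    labels = table["group"]
    cases = values[labels == "case"].to_numpy()
    controls = values[labels == "control"].to_numpy()
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")

    # Mann-Whitney identity via midranks
    pooled = np.concatenate([cases, controls])
    ranks = stats.rankdata(pooled)  # midranks handle ties as 1/2
    r_case = ranks[: len(cases)].sum()
    n1, n0 = len(cases), len(controls)
    auc = (r_case - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    thresholds = np.unique(pooled)[::-1]
    rows = [{"threshold": math.inf, "fpr": 0.0, "tpr": 0.0}]
    for thr in thresholds:
        rows.append(
            {
                "threshold": float(thr),
                "fpr": float(np.mean(controls >= thr)),
                "tpr": float(np.mean(cases >= thr)),
            }
        )
    roc = pd.DataFrame(rows)
    return roc, float(auc)
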
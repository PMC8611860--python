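"""Paired tumor/normal differential-expression screening on microarray data.

Implements the screening route used for candidate lncRNA discovery:
quantile normalization, a paired two-tailed t-test on per-pair log2
differences, geometric-mean fold change, Benjamini–Hochberg adjustment,
threshold-based up/down calls, set intersection between screening routes,
and a five-rule candidate filter (fold-change ranking, signal-intensity
floor, autosome restriction, transcript-length cap, exclusion of exonic
sense lncRNAs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, MatrixError

FEATURE_CLASSES = ("lncRNA", "mRNA", "miRNA")


@dataclass(frozen=True)
class Thresholds:
    """Up/down call thresholds on linear fold change and raw p."""

    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    inclusive_fc: bool = True  # fc_up itself counts as up


#: Named threshold presets.  ``microarray`` is the discovery screen
#: (FC >= 2 or <= 0.5, p < 0.05, boundary inclusive); ``validation`` is the
#: external-cohort screen written as |log2FC| > 1, p < 0.05 (boundary
#: strict).  The two rules coincide everywhere except exactly at FC = 2.
PRESETS: dict[str, Thresholds] = {
    "microarray": Thresholds(inclusive_fc=True),
    "validation": Thresholds(inclusive_fc=False),
}


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common reference distribution.

    The reference is the vector of row means of the column-sorted matrix;
    each column's values are replaced by the reference values at their
    within-column ranks (ties receive the mean of their tied reference
    positions).  Ranks within each column are preserved.
    """
    v = matrix.values.to_numpy(float)
    order = np.sort(v, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        ranks = stats.rankdata(v[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, v.shape[0] + 1), reference)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=values, meta=matrix.meta)


def paired_t_test(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Two-tailed paired t-test per feature on tumor-minus-normal log2 diffs.

    Returns a frame indexed by feature with columns ``p_value`` and
    ``degenerate``.  Degenerate cases: all differences zero gives p = 1
    (no signal); zero variance with a nonzero mean has an infinite t
    statistic and is reported as the limiting value p = 0 with the
    ``degenerate`` flag set.
    """
    tum, nor, pids = matrix.paired_arrays()
    n = len(pids)
    if n < 2:
        raise MatrixError("paired t-test needs >=2 complete pairs")
    d = tum - nor
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    p = np.ones(d.shape[0])
    degenerate = np.zeros(d.shape[0], dtype=bool)
    ok = sd > 0
    t = np.zeros(d.shape[0])
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    zero_var_signal = (~ok) & (mean != 0)
    p[zero_var_signal] = 0.0
    degenerate[zero_var_signal] = True
    return pd.DataFrame(
        {"p_value": p, "degenerate": degenerate}, index=matrix.values.index
    )


def fold_change(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Geometric-mean tumor/normal fold change per feature.

    fc = 2^(mean log2 tumor - mean log2 normal); always positive.
    """
    tum, nor, _ = matrix.paired_arrays()
    mt = tum.mean(axis=1)
    mn = nor.mean(axis=1)
    log2fc = mt - mn
    return pd.DataFrame(
        {
            "fc": np.exp2(log2fc),
            "log2fc": log2fc,
            "mean_log2_tumor": mt,
            "mean_log2_normal": mn,
        },
        index=matrix.values.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_de(matrix: ExpressionMatrix, mode: str = "microarray") -> pd.DataFrame:
    """Call each feature up / down / ns under a named threshold preset.

    up:   fc >= fc_up  (or > when the preset is boundary-strict) and p < alpha
    down: fc <= fc_down (or <)                                   and p < alpha
    ns:   everything else.

    The call uses the raw p-value; BH q-values are reported alongside but
    do not enter the call.
    """
    if mode not in PRESETS:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(PRESETS)}")
    thr = PRESETS[mode]
    fc = fold_change(matrix)
    tt = paired_t_test(matrix)
    df = fc.join(tt)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    if thr.inclusive_fc:
        up = df["fc"] >= thr.fc_up
        down = df["fc"] <= thr.fc_down
    else:
        up = df["fc"] > thr.fc_up
        down = df["fc"] < thr.fc_down
    sig = df["p_value"] < thr.alpha
    reg = np.where(up & sig, "up", np.where(down & sig, "down", "ns"))
    df["regulation"] = reg
    df.index.name = "accession"
    return df[
        [
            "fc",
            "log2fc",
            "p_value",
            "q_value",
            "regulation",
            "mean_log2_tumor",
            "mean_log2_normal",
            "degenerate",
        ]
    ]


def regulated_ids(de: pd.DataFrame, direction: str | None = None) -> list[str]:
    """Sorted accessions called up, down, or (default) either."""
    if direction is None:
        mask = de["regulation"] != "ns"
    else:
        mask = de["regulation"] == direction
    return sorted(de.index[mask])


def intersect_sets(a, b) -> list[str]:
    """Exact set intersection, returned in deterministic sorted order."""
    return sorted(set(a) & set(b))


# ---------------------------------------------------------------------------
# Candidate filter
# ---------------------------------------------------------------------------

_FILTER_RULES = (
    "intensity",  # higher-expressing condition must exceed the log2 floor
    "sex_chromosome",  # chrX / chrY excluded
    "length",  # >= max_length_nt excluded
    "exonic_sense",  # exonic sense lncRNAs excluded
)


def candidate_filter(
    de: pd.DataFrame,
    annotation: pd.DataFrame,
    intensity_floor: float = 7.0,
    max_length_nt: float = 2000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank DE features by |log2FC| and apply the candidate screening rules.

    Rules, in order, on features called up or down:

    1. sort by |log2fc| descending (ties: ascending p, then accession);
    2. signal-intensity floor — downregulated features need
       mean_log2_normal > ``intensity_floor``, upregulated features need
       mean_log2_tumor > ``intensity_floor``;
    3. drop features on chrX or chrY;
    4. drop features with length >= ``max_length_nt``;
    5. drop lncRNAs in the exonic-sense positional category.

    Returns ``(candidates, removals)``; removals lists each discarded
    feature with the first rule that removed it.
    """
    called = de[de["regulation"] != "ns"].copy()
    missing = set(called.index) - set(annotation.index)
    if missing:
        raise KeyError(f"features without annotation: {sorted(missing)}")
    ann = annotation.loc[called.index]
    called["_abs"] = called["log2fc"].abs()
    # |log2FC| descending; ties broken by ascending p, then accession
    called = called.loc[
        sorted(called.index, key=lambda a: (-called.at[a, "_abs"], called.at[a, "p_value"], a))
    ]
    removals: list[tuple[str, str]] = []
    keep: list[str] = []
    for acc in called.index:
        row = called.loc[acc]
        a = ann.loc[acc]
        high = row["mean_log2_normal"] if row["regulation"] == "down" else row["mean_log2_tumor"]
        if not high > intensity_floor:
            removals.append((acc, "intensity"))
            continue
        if str(a["chromosome"]) in ("chrX", "chrY"):
            removals.append((acc, "sex_chromosome"))
            continue
        if float(a["length_nt"]) >= max_length_nt:
            removals.append((acc, "length"))
            continue
        if str(a.get("lnc_category", "")) == "exonic-sense":
            removals.append((acc, "exonic_sense"))
            continue
        keep.append(acc)
    candidates = called.loc[keep].drop(columns="_abs")
    removal_df = pd.DataFrame(removals, columns=["accession", "rule"]).set_index("accession")
    return candidates, removal_df


def validate_annotation(annotation: pd.DataFrame) -> None:
    """Check the feature-annotation invariants (class vocabulary, length)."""
    bad_class = set(annotation["feature_class"]) - set(FEATURE_CLASSES)
    if bad_class:
        raise ValueError(f"unknown feature classes: {sorted(bad_class)}")
    if (annotation["length_nt"] <= 0).any():
        raise ValueError("length_nt must be positive")
    if (annotation["chromosome"].astype(str).str.len() == 0).any():
        raise ValueError("chromosome must be non-empty")
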
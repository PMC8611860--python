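"""ceRNA triplet inference and miRNA-mediated interaction (MMI) networks.

Workflow: Pearson-correlate every lncRNA–mRNA pair within each condition
(normal and tumor), keep pairs whose correlation strictly exceeds the
nearest-rank percentile threshold of the condition's overall correlation
distribution in both conditions, then for every miRNA whose 6-mer seed
(positions 2–7 of the mature sequence) has a perfect Watson–Crick
complement in both transcripts, compute the first-order partial
correlation

    rho_XY|Z = (rho_XY - rho_XZ rho_ZY) / (sqrt(1-rho_XZ^2) sqrt(1-rho_ZY^2))

and retain the triplet when the sensitivity correlation
rho_XY - rho_XY|Z meets the threshold delta.  Retained triplets are
assembled into a bipartite lncRNA/mRNA network whose edges carry the
mediating miRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .matrix import ExpressionMatrix

SEED_START = 1  # 0-based: mature positions 2..7 -> slice [1:7]
SEED_LEN = 6

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class DegenerateCorrelationError(ValueError):
    """A correlation of magnitude 1 makes the partial correlation undefined."""


# ---------------------------------------------------------------------------
# Sequences and seed matching
# ---------------------------------------------------------------------------

def normalize_rna(sequence: str) -> str:
    """Uppercase and convert T→U; reject anything outside {A,C,G,U}."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid nucleotides after T→U normalization: {sorted(bad)}")
    return seq


def reverse_complement_rna(sequence: str) -> str:
    return normalize_rna(sequence).translate(_RNA_COMPLEMENT)[::-1]


def seed_of(mirna_sequence: str) -> str:
    """The 6-mer seed: positions 2–7 from the 5' end of the mature miRNA."""
    seq = normalize_rna(mirna_sequence)
    if len(seq) < SEED_START + SEED_LEN:
        raise ValueError(f"mature miRNA shorter than {SEED_START + SEED_LEN} nt")
    return seq[SEED_START:SEED_START + SEED_LEN]


@dataclass(frozen=True)
class SeedMatch:
    mirna_id: str
    target_id: str
    positions: tuple[int, ...]  # 0-based starts, strictly increasing
    site: str  # the 6-nt target substring (reverse complement of the seed)


def seed_match_sites(mirna_sequence: str, target_sequence: str) -> tuple[int, ...]:
    """All 0-based start offsets of the seed's reverse complement in the target.

    Watson–Crick only (no G:U wobble); overlapping occurrences are all
    reported; only the target sense strand is searched.
    """
    site = reverse_complement_rna(seed_of(mirna_sequence))
    target = normalize_rna(target_sequence)
    positions = []
    start = target.find(site)
    while start != -1:
        positions.append(start)
        start = target.find(site, start + 1)
    return tuple(positions)


def has_seed_match(
    mirna_id: str, mirna_sequence: str, target_id: str, target_sequence: str
) -> SeedMatch | None:
    """SeedMatch for all sites of the miRNA in the target, or None."""
    positions = seed_match_sites(mirna_sequence, target_sequence)
    if not positions:
        return None
    site = reverse_complement_rna(seed_of(mirna_sequence))
    return SeedMatch(mirna_id=mirna_id, target_id=target_id, positions=positions, site=site)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an id → sequence map (sequence kept verbatim)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")


# ---------------------------------------------------------------------------
# Correlation machinery
# ---------------------------------------------------------------------------

def pairwise_correlation(
    lnc: ExpressionMatrix, mrna: ExpressionMatrix, condition: str
) -> pd.DataFrame:
    """Pearson correlation of every (lncRNA, mRNA) pair within one condition.

    Rows are lncRNAs, columns mRNAs.  Constant features give NaN (an
    undefined correlation), never a number.
    """
    samples = lnc.condition_samples(condition)
    if samples != mrna.condition_samples(condition):
        raise ValueError("lncRNA and mRNA matrices must share the condition's samples")
    if len(samples) < 3:
        raise ValueError("need >=3 samples per condition for correlation")
    x = lnc.values[samples].to_numpy(float)
    y = mrna.values[samples].to_numpy(float)
    xz = _standardize_rows(x)
    yz = _standardize_rows(y)
    corr = xz @ yz.T / x.shape[1]
    return pd.DataFrame(corr, index=lnc.values.index, columns=mrna.values.index)


def _standardize_rows(a: np.ndarray) -> np.ndarray:
    mean = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    out = np.full_like(a, np.nan)
    ok = (sd > 0).ravel()
    out[ok] = (a[ok] - mean[ok]) / sd[ok]
    return out


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """The ceil(q/100 * n)-th order statistic of the defined values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no defined correlations")
    if not 0 < q <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    k = max(1, math.ceil(q / 100.0 * v.size))
    return float(np.sort(v)[k - 1])


def percentile_threshold(
    correlations: dict[str, pd.DataFrame],
    q: float = 99.0,
    rule: str = "both",
) -> tuple[dict[str, float], list[tuple[str, str]]]:
    """Per-condition nearest-rank thresholds and the selected pairs.

    A pair is selected iff its correlation strictly exceeds the
    condition's threshold in both conditions (``rule='both'``, the
    default) or in at least one (``rule='either'``).  Pairs undefined in a
    required condition are never selected.
    """
    if rule not in ("both", "either"):
        raise ValueError("rule must be 'both' or 'either'")
    thresholds = {
        cond: nearest_rank_percentile(df.to_numpy().ravel(), q)
        for cond, df in correlations.items()
    }
    masks = []
    for cond, df in correlations.items():
        arr = df.to_numpy()
        with np.errstate(invalid="ignore"):
            masks.append(arr > thresholds[cond])
    combined = np.logical_and.reduce(masks) if rule == "both" else np.logical_or.reduce(masks)
    first = next(iter(correlations.values()))
    rows, cols = np.nonzero(combined)
    selected = sorted(
        (str(first.index[i]), str(first.columns[j])) for i, j in zip(rows, cols)
    )
    return thresholds, selected


def partial_correlation(rho_xy: float, rho_xz: float, rho_zy: float) -> float:
    """First-order partial correlation of X and Y given Z.

    Raises DegenerateCorrelationError when |rho_xz| or |rho_zy| is 1
    (zero denominator).  Results outside [-1, 1] by more than 1e-12 are
    clamped to the interval.
    """
    for r in (rho_xy, rho_xz, rho_zy):
        if not np.isfinite(r) or abs(r) > 1:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    # a denominator below ~1e-6 (|rho| within 1e-12 of 1) means the
    # conditioning variable is numerically collinear with X or Y
    if (1 - rho_xz**2) < 1e-12 or (1 - rho_zy**2) < 1e-12:
        raise DegenerateCorrelationError(
            "partial correlation undefined: conditioning variable is collinear"
        )
    value = (rho_xy - rho_xz * rho_zy) / (
        math.sqrt(1 - rho_xz**2) * math.sqrt(1 - rho_zy**2)
    )
    return float(min(1.0, max(-1.0, value)))


# ---------------------------------------------------------------------------
# Triplet assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CeRNATriplet:
    """A (lncRNA, miRNA, mRNA) candidate with its correlation statistics."""

    lncrna: str
    mirna: str
    mrna: str
    rho_xy_normal: float
    rho_xy_tumor: float
    rho_xz: float
    rho_zy: float
    rho_xy_given_z: float
    sensitivity: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def assemble_triplets(
    selected_pairs: list[tuple[str, str]],
    mirna_sequences: dict[str, str],
    lnc_sequences: dict[str, str],
    mrna_sequences: dict[str, str],
    lnc: ExpressionMatrix,
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    delta: float = 0.2,
    sensitivity_condition: str = "tumor",
) -> tuple[list[CeRNATriplet], list[tuple[str, str, str, str]]]:
    """Seed-match-restricted, sensitivity-filtered triplets for selected pairs.

    For each selected (lncRNA X, mRNA Y) pair and each miRNA Z with at
    least one perfect 6-mer seed match in both transcripts, computes
    rho_XZ, rho_ZY and rho_XY|Z in the sensitivity condition and keeps the
    triplet iff sensitivity = rho_XY - rho_XY|Z >= delta.  Degenerate or
    undefined correlations exclude the triplet with a logged reason.

    Returns (triplets, exclusions); each exclusion is
    (lncRNA, miRNA, mRNA, reason).
    """
    if not 0 <= delta <= 2:
        raise ValueError("delta must lie in [0, 2]")
    if sensitivity_condition not in ("tumor", "normal"):
        raise ValueError("sensitivity_condition must be 'tumor' or 'normal'")
    samples = lnc.condition_samples(sensitivity_condition)
    if samples != mirna.condition_samples(sensitivity_condition) or samples != mrna.condition_samples(
        sensitivity_condition
    ):
        raise ValueError("expression matrices must share the condition's samples")
    other = "normal" if sensitivity_condition == "tumor" else "tumor"
    other_samples = lnc.condition_samples(other)

    # precompute matched miRNA sets per transcript
    seeds_rc = {mid: reverse_complement_rna(seed_of(s)) for mid, s in mirna_sequences.items()}

    def matched(target_seq: str) -> set[str]:
        t = normalize_rna(target_seq)
        return {mid for mid, rc in seeds_rc.items() if rc in t}

    lnc_hits = {x: matched(_require(lnc_sequences, x, "lncRNA sequence")) for x in {p[0] for p in selected_pairs}}
    mrna_hits = {y: matched(_require(mrna_sequences, y, "mRNA sequence")) for y in {p[1] for p in selected_pairs}}

    triplets: list[CeRNATriplet] = []
    exclusions: list[tuple[str, str, str, str]] = []
    for x, y in selected_pairs:
        xv = _profile(lnc, x, samples)
        yv = _profile(mrna, y, samples)
        rho_xy = _pearson(xv, yv)
        rho_xy_other = _pearson(
            _profile(lnc, x, other_samples), _profile(mrna, y, other_samples)
        ) if other_samples else float("nan")
        stats_by_cond = {sensitivity_condition: rho_xy, other: rho_xy_other}
        for z in sorted(lnc_hits[x] & mrna_hits[y]):
            zv = _profile(mirna, z, samples)
            rho_xz = _pearson(xv, zv)
            rho_zy = _pearson(zv, yv)
            if any(np.isnan(r) for r in (rho_xy, rho_xz, rho_zy)):
                exclusions.append((x, z, y, "undefined correlation (constant profile)"))
                continue
            try:
                rho_xy_z = partial_correlation(rho_xy, rho_xz, rho_zy)
            except DegenerateCorrelationError:
                exclusions.append((x, z, y, "degenerate partial correlation"))
                continue
            sens = rho_xy - rho_xy_z
            if sens < delta:
                exclusions.append((x, z, y, f"sensitivity {sens:.4f} < delta {delta}"))
                continue
            triplets.append(
                CeRNATriplet(
                    lncrna=x, mirna=z, mrna=y,
                    rho_xy_normal=stats_by_cond["normal"],
                    rho_xy_tumor=stats_by_cond["tumor"],
                    rho_xz=rho_xz, rho_zy=rho_zy,
                    rho_xy_given_z=rho_xy_z, sensitivity=sens,
                )
            )
    return triplets, exclusions


def _require(mapping: dict[str, str], key: str, what: str) -> str:
    if key not in mapping:
        raise KeyError(f"missing {what} for feature {key!r}")
    return mapping[key]


def _profile(em: ExpressionMatrix, feature: str, samples: list[str]) -> np.ndarray:
    if feature not in em.values.index:
        raise KeyError(f"missing expression profile for feature {feature!r}")
    return em.values.loc[feature, samples].to_numpy(float)


def triplets_to_frame(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    cols = ["lncrna", "mirna", "mrna", "rho_xy_normal", "rho_xy_tumor",
            "rho_xz", "rho_zy", "rho_xy_given_z", "sensitivity"]
    if not triplets:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([t.__dict__ for t in triplets])[cols]


# ---------------------------------------------------------------------------
# MMI network
# ---------------------------------------------------------------------------

def build_network(triplets: list[CeRNATriplet]) -> nx.Graph:
    """Bipartite lncRNA/mRNA graph; each edge carries its mediating miRNAs.

    One node per distinct transcript (attribute ``kind``), one edge per
    distinct (lncRNA, mRNA) pair with attribute ``mediators`` =
    comma-joined sorted miRNA ids.  Node and edge insertion order is
    deterministic.
    """
    mediators: dict[tuple[str, str], set[str]] = {}
    stats: dict[tuple[str, str], CeRNATriplet] = {}
    for t in triplets:
        key = (t.lncrna, t.mrna)
        mediators.setdefault(key, set()).add(t.mirna)
        stats.setdefault(key, t)
    g = nx.Graph()
    for x in sorted({k[0] for k in mediators}):
        g.add_node(x, kind="lncRNA")
    for y in sorted({k[1] for k in mediators}):
        g.add_node(y, kind="mRNA")
    for (x, y) in sorted(mediators):
        t = stats[(x, y)]
        g.add_edge(
            x, y,
            mediators=",".join(sorted(mediators[(x, y)])),
            rho_xy_tumor=float(t.rho_xy_tumor),
            rho_xy_normal=float(t.rho_xy_normal),
        )
    return g


def export_network(network: nx.Graph, path: str | Path, fmt: str = "sif") -> None:
    """Write the network as SIF or GraphML (byte-deterministic)."""
    fmt = fmt.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for x, y in sorted(network.edges()):
                a, b = (x, y) if network.nodes[x]["kind"] == "lncRNA" else (y, x)
                fh.write(f"{a}\tmediates:{network.edges[a, b]['mediators']}\t{b}\n")
    elif fmt == "graphml":
        nx.write_graphml(network, str(path), infer_numeric_types=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}; use 'sif' or 'graphml'")


def network_from_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
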
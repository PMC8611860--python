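"""Synthetic paired tumor/normal cohorts with planted ground truth.

Every downstream stage of the pipeline can be exercised against a known
answer: expression matrices with planted log2 fold changes, ceRNA systems
in which a latent miRNA activity represses both a lncRNA and an mRNA
(producing the positive lncRNA–mRNA correlation that vanishes once the
miRNA is conditioned on), transcript sequences with the miRNA seed's
reverse complement inserted at a recorded position, survival cohorts with
a group-dependent exponential hazard, and categorical clinical tables.

All generation is driven by a single integer seed; identical specs give
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cerna import SEED_LEN, reverse_complement_rna, seed_of
from .enrich import GeneSet
from .matrix import ExpressionMatrix

RNA_ALPHABET = np.array(list("ACGU"))
MIRNA_LEN = 22


class SynthSpecError(ValueError):
    """Raised for an internally inconsistent generator specification."""


@dataclass(frozen=True)
class SynthSpec:
    """Study-design parameters for the synthetic cohort.

    ``planted_de`` maps feature ids to true log2 fold changes (tumor vs
    normal); ``planted_triplets`` lists (lncRNA, miRNA, mRNA, beta) with
    beta the repression strength in log2 units per unit latent activity.
    """

    n_pairs: int = 4
    n_lnc: int = 200
    n_mrna: int = 200
    n_mirna: int = 40
    planted_de: tuple[tuple[str, float], ...] = ()
    planted_triplets: tuple[tuple[str, str, str, float], ...] = ()
    noise_sd: float = 0.3
    pair_sd: float = 0.5
    baseline_mean: float = 8.0
    seq_len: int = 500
    hazard_ratio: float = 2.0
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pairs, self.n_lnc, self.n_mrna, self.n_mirna) < 0:
            raise SynthSpecError("counts must be >= 0")
        if self.noise_sd < 0 or self.pair_sd < 0:
            raise SynthSpecError("noise_sd and pair_sd must be >= 0")
        if self.hazard_ratio <= 0:
            raise SynthSpecError("hazard_ratio must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise SynthSpecError("censor_rate must lie in [0, 1)")
        declared = set(self.lnc_ids()) | set(self.mrna_ids())
        for feat, _fc in self.planted_de:
            if feat not in declared:
                raise SynthSpecError(f"planted DE feature {feat!r} not declared")
        mirnas = set(self.mirna_ids())
        seen = set()
        for x, z, y, _beta in self.planted_triplets:
            if x not in set(self.lnc_ids()) or y not in set(self.mrna_ids()) or z not in mirnas:
                raise SynthSpecError(f"planted triplet ({x},{z},{y}) references undeclared features")
            if (x, z, y) in seen:
                raise SynthSpecError(f"duplicate planted triplet ({x},{z},{y})")
            seen.add((x, z, y))

    def lnc_ids(self) -> list[str]:
        return [f"LNC{i:04d}" for i in range(1, self.n_lnc + 1)]

    def mrna_ids(self) -> list[str]:
        return [f"MRNA{i:04d}" for i in range(1, self.n_mrna + 1)]

    def mirna_ids(self) -> list[str]:
        return [f"MIR{i:04d}" for i in range(1, self.n_mirna + 1)]

    def sample_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(1, self.n_pairs + 1):
            rows.append((f"P{i:02d}_T", "tumor", f"P{i:02d}"))
            rows.append((f"P{i:02d}_N", "normal", f"P{i:02d}"))
        return pd.DataFrame(rows, columns=["sample_id", "condition", "pair_id"]).set_index("sample_id")


@dataclass
class GroundTruth:
    """The planted answers against which recovery is scored."""

    true_de: dict[str, float] = field(default_factory=dict)
    true_triplets: set[tuple[str, str, str]] = field(default_factory=set)
    true_seed_sites: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    true_group_hazards: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_de": self.true_de,
            "true_triplets": sorted(list(t) for t in self.true_triplets),
            "true_seed_sites": {k: sorted(map(list, v)) for k, v in self.true_seed_sites.items()},
            "true_group_hazards": self.true_group_hazards,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            true_de=dict(payload["true_de"]),
            true_triplets={tuple(t) for t in payload["true_triplets"]},
            true_seed_sites={k: [tuple(s) for s in v] for k, v in payload["true_seed_sites"].items()},
            true_group_hazards=dict(payload["true_group_hazards"]),
        )


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_de_spec(
    seed: int = 0,
    n_planted_per_direction: int = 20,
    n_lnc: int = 2000,
    n_mrna: int = 2000,
) -> SynthSpec:
    """The paired-screening study: 4 tumor/normal pairs, planted |log2FC| = 2.

    Twenty lncRNAs and twenty mRNAs are planted up (log2FC = +2) and the
    same number down (-2), with log2 noise 0.3 — a strong microarray
    effect over a small paired design.  The planted features are a small
    fraction (~2%) of the array so that quantile normalization's
    mostly-unchanged assumption holds, as on a genome-scale array.
    """
    spec0 = SynthSpec(n_lnc=n_lnc, n_mrna=n_mrna, seed=seed)
    k = n_planted_per_direction
    planted: list[tuple[str, float]] = []
    for ids in (spec0.lnc_ids(), spec0.mrna_ids()):
        planted += [(f, 2.0) for f in ids[:k]]
        planted += [(f, -2.0) for f in ids[k:2 * k]]
    return SynthSpec(n_pairs=4, n_lnc=n_lnc, n_mrna=n_mrna, noise_sd=0.3,
                     planted_de=tuple(planted), seed=seed)


def default_cerna_spec(seed: int = 0) -> SynthSpec:
    """The ceRNA recovery study: 50 sample pairs, 20 planted triplets.

    Twenty (lncRNA, miRNA, mRNA) triplets with repression strength
    beta = 0.8 and log2 noise 0.5 are planted alongside 200 decoy
    lncRNA/mRNA feature pairs (and 20 decoy miRNAs) that carry no
    co-expression signal and no planted seed sites.
    """
    n_planted, n_decoy_pairs, n_decoy_mirna = 20, 200, 20
    n_feat = n_planted + n_decoy_pairs
    ids = SynthSpec(n_lnc=n_feat, n_mrna=n_feat, n_mirna=n_planted + n_decoy_mirna, seed=seed)
    triplets = tuple(
        (ids.lnc_ids()[i], ids.mirna_ids()[i], ids.mrna_ids()[i], 0.8)
        for i in range(n_planted)
    )
    return SynthSpec(
        n_pairs=50, n_lnc=n_feat, n_mrna=n_feat, n_mirna=n_planted + n_decoy_mirna,
        planted_triplets=triplets, noise_sd=0.5, seed=seed,
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_expression(spec: SynthSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Paired tumor/normal log2 expression with planted fold changes.

    Per feature f and sample s of pair p:
    value = baseline + pair_effect(p) + [log2FC(f) if tumor and planted]
    + N(0, noise_sd).  The pair effect is shared by both members of a
    pair, so per-pair differences recover the planted log2FC exactly at
    zero noise.
    """
    if spec.n_pairs < 1:
        raise SynthSpecError("need >=1 sample pair")
    features = spec.lnc_ids() + spec.mrna_ids()
    if not features:
        raise SynthSpecError("need >=1 feature")
    rng = np.random.default_rng(spec.seed)
    meta = spec.sample_frame()
    n_feat, n_samp = len(features), len(meta)
    pair_effect = rng.normal(0.0, spec.pair_sd, size=spec.n_pairs)
    pair_idx = {p: i for i, p in enumerate(sorted(meta["pair_id"].unique()))}
    values = np.full((n_feat, n_samp), spec.baseline_mean)
    planted = dict(spec.planted_de)
    feat_fc = np.array([planted.get(f, 0.0) for f in features])
    for j, (sid, row) in enumerate(meta.iterrows()):
        values[:, j] += pair_effect[pair_idx[row["pair_id"]]]
        if row["condition"] == "tumor":
            values[:, j] += feat_fc
    values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    em = ExpressionMatrix(
        values=pd.DataFrame(values, index=features, columns=meta.index), meta=meta
    )
    return em, GroundTruth(true_de=dict(planted))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA_ALPHABET, size=length))


def generate_cerna_system(
    spec: SynthSpec,
) -> tuple[
    ExpressionMatrix, ExpressionMatrix, ExpressionMatrix,
    dict[str, str], dict[str, str], dict[str, str], GroundTruth,
]:
    """Expression + sequences for a planted ceRNA system.

    For each planted triplet (X, Z, Y, beta) a per-sample latent miRNA
    activity z ~ N(0,1) drives

        x = baseline - beta*z + e,   y = baseline - beta*z + e',
        mirna = baseline + z + e'',

    so corr(x, y) > 0 while corr(x, y | z) ~ 0.  The reverse complement
    of Z's 6-mer seed is written into both X's and Y's transcript at a
    uniformly drawn, recorded 0-based position.  Decoy features are
    independent noise with variance matched to the planted features and
    carry no planted seed site.

    Returns (lnc_expr, mirna_expr, mrna_expr, lnc_seqs, mrna_seqs,
    mirna_seqs, truth).
    """
    if spec.n_pairs < 1:
        raise SynthSpecError("need >=1 sample pair")
    if spec.seq_len < SEED_LEN:
        raise SynthSpecError(f"seq_len must be >= {SEED_LEN}")
    rng = np.random.default_rng(spec.seed)
    meta = spec.sample_frame()
    n_samp = len(meta)
    lnc_ids, mrna_ids, mirna_ids = spec.lnc_ids(), spec.mrna_ids(), spec.mirna_ids()

    # latent activity per miRNA per sample
    z = {m: rng.standard_normal(n_samp) for m in mirna_ids}

    betas = {m: b for _x, m, _y, b in spec.planted_triplets}
    sd_planted = float(np.sqrt(max(betas.values(), default=0.8) ** 2 + spec.noise_sd**2))

    def expr_frame(ids: list[str], build_row) -> pd.DataFrame:
        return pd.DataFrame(
            np.vstack([build_row(f) for f in ids]) if ids else np.empty((0, n_samp)),
            index=ids, columns=meta.index,
        )

    lnc_driver = {x: (m, b) for x, m, _y, b in spec.planted_triplets}
    mrna_driver: dict[str, list[tuple[str, float]]] = {}
    for _x, m, y, b in spec.planted_triplets:
        mrna_driver.setdefault(y, []).append((m, b))

    def lnc_row(f: str) -> np.ndarray:
        if f in lnc_driver:
            m, b = lnc_driver[f]
            return spec.baseline_mean - b * z[m] + rng.normal(0, spec.noise_sd, n_samp)
        return spec.baseline_mean + rng.normal(0, sd_planted, n_samp)

    def mrna_row(f: str) -> np.ndarray:
        if f in mrna_driver:
            out = np.full(n_samp, spec.baseline_mean) + rng.normal(0, spec.noise_sd, n_samp)
            for m, b in mrna_driver[f]:
                out -= b * z[m]
            return out
        return spec.baseline_mean + rng.normal(0, sd_planted, n_samp)

    planted_mirnas = {m for _x, m, _y, _b in spec.planted_triplets}

    def mirna_row(f: str) -> np.ndarray:
        if f in planted_mirnas:
            return spec.baseline_mean + z[f] + rng.normal(0, spec.noise_sd, n_samp)
        return spec.baseline_mean + rng.normal(0, float(np.sqrt(1 + spec.noise_sd**2)), n_samp)

    lnc_em = ExpressionMatrix(values=expr_frame(lnc_ids, lnc_row), meta=meta)
    mrna_em = ExpressionMatrix(values=expr_frame(mrna_ids, mrna_row), meta=meta)
    mirna_em = ExpressionMatrix(values=expr_frame(mirna_ids, mirna_row), meta=meta)

    # mature miRNA sequences with mutually distinct 6-mer seeds
    mirna_seqs: dict[str, str] = {}
    used_seeds: set[str] = set()
    for m in mirna_ids:
        while True:
            seq = _random_rna(rng, MIRNA_LEN)
            s = seed_of(seq)
            if s not in used_seeds:
                used_seeds.add(s)
                mirna_seqs[m] = seq
                break

    lnc_seqs = {f: _random_rna(rng, spec.seq_len) for f in lnc_ids}
    mrna_seqs = {f: _random_rna(rng, spec.seq_len) for f in mrna_ids}

    truth = GroundTruth()
    for x, m, y, _b in spec.planted_triplets:
        site = reverse_complement_rna(seed_of(mirna_seqs[m]))
        for target, seqs in ((x, lnc_seqs), (y, mrna_seqs)):
            pos = int(rng.integers(0, spec.seq_len - SEED_LEN + 1))
            seqs[target] = seqs[target][:pos] + site + seqs[target][pos + SEED_LEN:]
            truth.true_seed_sites.setdefault(target, []).append((m, pos))
        truth.true_triplets.add((x, m, y))
    return lnc_em, mirna_em, mrna_em, lnc_seqs, mrna_seqs, mirna_seqs, truth


def generate_survival(
    spec: SynthSpec,
    groups: pd.Series,
    base_hazard: float = 0.2,
    elevated: str | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Exponential survival with a group-dependent hazard.

    ``groups`` maps subject id -> one of exactly two labels.  The
    ``elevated`` label (default: the lexicographically second) gets
    hazard = base_hazard * hazard_ratio; the other gets base_hazard.
    Censoring times are independent exponentials with rate chosen so the
    expected censored fraction equals ``censor_rate``.
    """
    labels = sorted(pd.Series(groups).unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    if (pd.Series(groups).value_counts() == 0).any():
        raise ValueError("empty group")
    if elevated is None:
        elevated = labels[1]
    if elevated not in labels:
        raise ValueError(f"elevated label {elevated!r} not among {labels}")
    hazards = {
        lab: base_hazard * (spec.hazard_ratio if lab == elevated else 1.0) for lab in labels
    }
    rng = np.random.default_rng(spec.seed)
    rows = []
    for subject in groups.index:
        lam = hazards[groups[subject]]
        t_event = rng.exponential(1.0 / lam)
        if spec.censor_rate > 0:
            lam_c = lam * spec.censor_rate / (1.0 - spec.censor_rate)
            t_cens = rng.exponential(1.0 / lam_c)
        else:
            t_cens = np.inf
        observed = t_event <= t_cens
        rows.append(
            {
                "subject_id": subject,
                "time": float(min(t_event, t_cens)),
                "event": bool(observed),
                "group": groups[subject],
            }
        )
    records = pd.DataFrame(rows).set_index("subject_id")
    return records, GroundTruth(true_group_hazards=hazards)


DEFAULT_CLINICAL_PROPORTIONS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.467, "female": 0.533},
    "age_group": {"<68": 0.545, ">=68": 0.455},
    "stage": {"I": 0.543, "II": 0.237, "III": 0.152, "IV": 0.068},
}


def generate_clinical(
    spec: SynthSpec,
    n: int,
    proportions: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Categorical clinical covariates drawn with fixed proportions.

    Category counts per variable always sum to ``n``.  Default
    proportions emulate a large lung-adenocarcinoma cohort.
    """
    if n < 1:
        raise SynthSpecError("need n >= 1 subjects")
    props = proportions if proportions is not None else DEFAULT_CLINICAL_PROPORTIONS
    rng = np.random.default_rng(spec.seed)
    data: dict[str, np.ndarray] = {}
    for var, cats in props.items():
        names = sorted(cats)
        p = np.array([cats[c] for c in names], dtype=float)
        p = p / p.sum()
        data[var] = rng.choice(np.array(names, dtype=object), size=n, p=p)
    idx = pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="subject_id")
    return pd.DataFrame(data, index=idx)


def generate_gene_sets(
    truth: GroundTruth,
    background: list[str],
    n_terms: int = 20,
    term_size: int = 25,
    seed: int = 0,
) -> list[GeneSet]:
    """A planted-signal term (the DE features) plus random decoy terms."""
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    planted = sorted(set(truth.true_de) & set(background))
    if planted:
        sets.append(
            GeneSet(term_id="T_PLANTED", term_name="planted differential features",
                    members=frozenset(planted), category="custom")
        )
    bg = np.array(sorted(background), dtype=object)
    for i in range(1, n_terms + 1):
        members = rng.choice(bg, size=min(term_size, len(bg)), replace=False)
        sets.append(
            GeneSet(term_id=f"T{i:03d}", term_name=f"random term {i}",
                    members=frozenset(map(str, members)), category="custom")
        )
    return sets
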
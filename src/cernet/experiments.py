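"""Self-contained validation experiments with independent oracles.

Each function runs one calibration or recovery study end to end —
generating its own inputs, running the package's estimators, and scoring
them against an independently computed reference (exact combinatorics,
residual regressions, naive string search, or planted ground truth) —
and returns plain numbers.  Used by the verification suite and the
reproduction script.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import cerna, clinstats, diffexpr, enrich, pipeline, synthdata


def cohort_worked_example() -> dict[str, float]:
    """Percentages for a 514-patient cohort with printed category counts."""
    total = 514
    counts = {"male": 240, "female": 274, "stage_i": 279, "age_ge68": 224}
    return {k: clinstats.category_percent(c, total) for k, c in counts.items()}


def hypergeom_sweep(max_n: int = 60) -> tuple[float, int]:
    """Max |error| of the upper-tail p against exact integer summation.

    Exhaustive over all (N <= max_n, M <= N, n <= N, m <= min(M, n)); the
    reference sums exact integer binomial products and divides once.
    """
    worst, cases = 0.0, 0
    for N in range(1, max_n + 1):
        comb_Nn = [math.comb(N, n) for n in range(N + 1)]
        for M in range(N + 1):
            for n in range(N + 1):
                lo_all = max(0, n - (N - M))
                hi = min(M, n)
                denom = comb_Nn[n]
                terms = [math.comb(M, i) * math.comb(N - M, n - i)
                         for i in range(lo_all, hi + 1)]
                tails: dict[int, float] = {}
                suffix = 0
                for i in range(hi, lo_all - 1, -1):
                    suffix += terms[i - lo_all]
                    tails[i] = suffix / denom
                for m in range(hi + 1):
                    expected = 1.0 if m <= lo_all else tails[m]
                    err = abs(enrich.hypergeom_p(N, M, n, m) - expected)
                    if err > worst:
                        worst = err
                    cases += 1
    return worst, cases


def partial_correlation_check(seed: int, reps: int = 200, n: int = 80) -> tuple[float, int]:
    """Max |formula - residual-correlation oracle| over seeded Gaussian draws.

    The oracle regresses X on Z and Y on Z by least squares and
    correlates the residuals — an exact-arithmetic identity with the
    closed-form partial correlation on sample statistics.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(reps):
        z = rng.standard_normal(n)
        x = -rng.uniform(0.2, 1.2) * z + rng.uniform(0.3, 1.0) * rng.standard_normal(n)
        y = -rng.uniform(0.2, 1.2) * z + rng.uniform(0.3, 1.0) * rng.standard_normal(n)
        c = np.corrcoef([x, y, z])
        got = cerna.partial_correlation(c[0, 1], c[0, 2], c[2, 1])
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        oracle = float(np.corrcoef(rx, ry)[0, 1])
        worst = max(worst, abs(got - oracle))
    return worst, reps


def seed_match_check(seed: int, n_pairs: int = 1000, target_len: int = 120) -> tuple[int, int]:
    """(agreements, trials) of seed matching vs a naive substring scan."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))
    agree = 0
    for _ in range(n_pairs):
        mirna = "".join(rng.choice(alphabet, 22))
        target = "".join(rng.choice(alphabet, target_len))
        site = cerna.reverse_complement_rna(cerna.seed_of(mirna))
        naive = tuple(p for p in range(len(target) - 5) if target[p:p + 6] == site)
        if cerna.seed_match_sites(mirna, target) == naive:
            agree += 1
    return agree, n_pairs


def cerna_recovery(seed: int, percentile: float = 99.0, delta: float = 0.2) -> dict[str, float]:
    """Planted-triplet recovery under the default ceRNA study conditions.

    50 sample pairs, 20 planted triplets (beta = 0.8, log2 noise 0.5)
    among 200 decoy lncRNA/mRNA feature pairs; runs the full selection →
    seed-match → sensitivity pipeline and scores against the truth.
    """
    spec = synthdata.default_cerna_spec(seed)
    lnc, mir, mrna, lseq, mseq, miseq, truth = synthdata.generate_cerna_system(spec)
    corr = {c: cerna.pairwise_correlation(lnc, mrna, c) for c in ("normal", "tumor")}
    _, selected = cerna.percentile_threshold(corr, q=percentile, rule="both")
    trips, _ = cerna.assemble_triplets(
        selected, miseq, lseq, mseq, lnc, mir, mrna, delta=delta)
    found = {(t.lncrna, t.mirna, t.mrna) for t in trips}
    tp = len(found & truth.true_triplets)
    return {
        "precision": tp / len(found) if found else 0.0,
        "recall": tp / len(truth.true_triplets),
        "n_found": float(len(found)),
        "n_true": float(len(truth.true_triplets)),
    }


def de_recovery(seed: int) -> dict[str, float]:
    """Planted-DE recovery under the default paired-screening conditions.

    4 tumor/normal pairs, planted |log2FC| = 2 over log2 noise 0.3;
    quantile-normalizes, screens at FC >= 2 or <= 0.5 with p < 0.05, and
    scores direction-aware recovery plus the null p-value rate.
    """
    spec = synthdata.default_de_spec(seed)
    em, truth = synthdata.generate_expression(spec)
    de = diffexpr.screen_de(diffexpr.quantile_normalize(em), mode="microarray")
    hits = sum(
        de.loc[f, "regulation"] == ("up" if fc > 0 else "down")
        for f, fc in truth.true_de.items()
    )
    nulls = de.drop(index=list(truth.true_de))
    return {
        "recovery": hits / len(truth.true_de),
        "null_p_rate": float((nulls["p_value"] < 0.05).mean()),
        "n_planted": float(len(truth.true_de)),
        "n_null": float(len(nulls)),
    }


def logrank_null_calibration(seed: int, reps: int = 1000, n: int = 100) -> dict[str, float]:
    """Type-I error of the log-rank test under equal hazards."""
    hits = 0
    groups = pd.Series(["high"] * (n // 2) + ["low"] * (n - n // 2),
                       index=[f"S{i}" for i in range(n)])
    for r in range(reps):
        spec = synthdata.SynthSpec(hazard_ratio=1.0, censor_rate=0.2,
                                   seed=(seed + r) % 2**31)
        records, _ = synthdata.generate_survival(spec, groups)
        _, p = clinstats.logrank_test(records)
        hits += p < 0.05
    return {"type1": hits / reps, "reps": float(reps)}


def logrank_power(seed: int, reps: int = 200, n: int = 200,
                  hazard_ratio: float = 3.0) -> dict[str, float]:
    """Fraction of replicates with p < 0.01 under a strong group hazard."""
    hits = 0
    groups = pd.Series(["high"] * (n // 2) + ["low"] * (n - n // 2),
                       index=[f"S{i}" for i in range(n)])
    for r in range(reps):
        spec = synthdata.SynthSpec(hazard_ratio=hazard_ratio, censor_rate=0.2,
                                   seed=(seed + r) % 2**31)
        records, _ = synthdata.generate_survival(spec, groups)
        _, p = clinstats.logrank_test(records)
        hits += p < 0.01
    return {"power": hits / reps, "reps": float(reps)}


def dunnett_null_fwer(seed: int, reps: int = 1000, n_groups: int = 6,
                      n_per_group: int = 10) -> dict[str, float]:
    """Family-wise error rate of Dunnett comparisons under the global null."""
    hits = 0
    names = ["ctrl"] + [f"g{i}" for i in range(1, n_groups)]
    for r in range(reps):
        rng = np.random.default_rng((seed + r) % 2**31)
        groups = {g: rng.normal(0.0, 1.0, n_per_group) for g in names}
        _, _, res = clinstats.anova_dunnett(groups, "ctrl", seed=(seed + r) % 2**31)
        hits += bool((res["p_adjusted"] < 0.05).any())
    return {"fwer": hits / reps, "reps": float(reps)}


def pipeline_determinism(seed: int, workdir: str | Path) -> dict[str, float]:
    """1.0 iff two identically configured runs give identical checksums."""
    workdir = Path(workdir)
    small = {
        "sim": {
            "de": {"n_lnc": 300, "n_mrna": 300, "n_planted_per_direction": 5},
            "cerna": {"n_pairs": 20, "n_planted": 3, "n_decoy_pairs": 20,
                      "n_decoy_mirnas": 3, "seq_len": 200},
            "survival": {"n_subjects": 60},
        }
    }
    manifests = []
    for name in ("run_a", "run_b"):
        cfg = pipeline.load_config(
            overrides={"seed": int(seed), "outdir": str(workdir / name), **small})
        manifests.append(pipeline.run_pipeline(cfg))
    identical = manifests[0]["stages"] == manifests[1]["stages"]
    n_artifacts = sum(len(v) for v in manifests[0]["stages"].values())
    return {"identical": float(identical), "n_artifacts": float(n_artifacts)}
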
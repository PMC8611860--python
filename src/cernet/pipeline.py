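"""End-to-end orchestration: simulate → normalize → DE → intersect →
enrich → candidates → ceRNA network → survival.

A single YAML config drives every stage; unknown keys are errors.  Each
stage reads the previous stage's files and writes its own artifact into
the output directory, and a run manifest records the effective config,
per-artifact SHA-256 checksums, and the seed, so that two runs with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cerna, clinstats, diffexpr, enrich as enrich_mod, synthdata
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "de", "intersect", "enrich", "candidates", "cerna", "survival")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "cernet_out",
    "simulate": True,
    "inputs": {
        "matrix": None, "meta": None, "annotation": None,
        "lnc_matrix": None, "mirna_matrix": None, "mrna_matrix": None,
        "cerna_meta": None,
        "lnc_fasta": None, "mirna_fasta": None, "mrna_fasta": None,
        "gmt": None, "background": None, "survival": None,
    },
    "sim": {
        "de": {"n_pairs": 4, "noise_sd": 0.3, "n_planted_per_direction": 10,
               "n_lnc": 1000, "n_mrna": 1000},
        "cerna": {"n_pairs": 30, "n_planted": 5, "n_decoy_pairs": 40,
                  "n_decoy_mirnas": 5, "beta": 0.8, "noise_sd": 0.5, "seq_len": 500},
        "survival": {"n_subjects": 200, "hazard_ratio": 2.0, "censor_rate": 0.2},
        "gene_sets": {"n_terms": 20, "term_size": 25},
    },
    "de": {"mode": "microarray", "validation_mode": "validation"},
    "enrichment": {"min_hits": 2, "top_k": 30},
    "cerna": {"percentile": 99.0, "delta": 0.2, "condition_rule": "both",
              "sensitivity_condition": "tumor"},
    "survival": {"split": "median", "cutpoint": None, "time_unit": "years",
                 "base_hazard": 0.2},
}


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in the pipeline config."""


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file over the defaults; unknown keys are errors."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    user = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
    _merge(cfg, user, trail="")
    if overrides:
        _merge(cfg, overrides, trail="")
    _validate_config(cfg)
    return cfg


def _merge(base: dict, user: dict, trail: str) -> None:
    for key, val in user.items():
        if key not in base:
            raise ConfigError(f"unknown config key {trail + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            _merge(base[key], val, trail=f"{trail}{key}.")
        else:
            base[key] = val


def _validate_config(cfg: dict) -> None:
    c = cfg["cerna"]
    if not 0 < float(c["percentile"]) < 100:
        raise ConfigError("cerna.percentile must lie in (0, 100)")
    if not 0 <= float(c["delta"]) <= 2:
        raise ConfigError("cerna.delta must lie in [0, 2]")
    if c["condition_rule"] not in ("both", "either"):
        raise ConfigError("cerna.condition_rule must be 'both' or 'either'")
    if cfg["de"]["mode"] not in diffexpr.PRESETS:
        raise ConfigError(f"unknown DE mode {cfg['de']['mode']!r}")
    if cfg["survival"]["time_unit"] not in ("years", "days"):
        raise ConfigError("survival.time_unit must be 'years' or 'days'")
    if int(cfg["seed"]) < 0:
        raise ConfigError("seed must be a non-negative integer")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Pipeline:
    """Stage runner bound to one config; every artifact lands in outdir."""

    def __init__(self, config: dict):
        self.cfg = config
        self.outdir = Path(config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.inputs_dir = self.outdir / "inputs"
        self.artifacts: dict[str, list[str]] = {}

    # -- paths ----------------------------------------------------------
    def _input(self, key: str, simulated_name: str | None = None) -> Path:
        if self.cfg["simulate"]:
            assert simulated_name is not None
            return self.inputs_dir / simulated_name
        p = self.cfg["inputs"].get(key)
        if not p:
            raise ConfigError(f"inputs.{key} is required when simulate is false")
        path = Path(p)
        if not path.exists():
            raise FileNotFoundError(f"inputs.{key}: no such file {path}")
        return path

    def _register(self, stage: str, *paths: Path) -> None:
        self.artifacts.setdefault(stage, []).extend(str(p) for p in paths)

    # -- stages ---------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.cfg["sim"]
        self.inputs_dir.mkdir(parents=True, exist_ok=True)
        seed = derive_seed(int(self.cfg["seed"]), "simulate")
        rng = np.random.default_rng(seed)

        d = cfg["de"]
        base_spec = synthdata.default_de_spec(
            seed, int(d["n_planted_per_direction"]), n_lnc=int(d["n_lnc"]),
            n_mrna=int(d["n_mrna"]),
        )
        de_spec = synthdata.SynthSpec(
            n_pairs=int(d["n_pairs"]), n_lnc=int(d["n_lnc"]), n_mrna=int(d["n_mrna"]),
            noise_sd=float(d["noise_sd"]), planted_de=base_spec.planted_de, seed=seed,
        )
        em, truth = synthdata.generate_expression(de_spec)
        em.to_tsv(self.inputs_dir / "expression.tsv", self.inputs_dir / "samples.tsv")
        self._write_annotation(de_spec, rng)
        truth.to_json(self.inputs_dir / "truth_de.json")

        background = de_spec.mrna_ids()
        (self.inputs_dir / "background.txt").write_text("\n".join(background) + "\n")
        gs_cfg = cfg["gene_sets"]
        sets = synthdata.generate_gene_sets(
            truth, background, n_terms=int(gs_cfg["n_terms"]),
            term_size=int(gs_cfg["term_size"]), seed=derive_seed(seed, "gene_sets"),
        )
        enrich_mod.write_gmt(sets, self.inputs_dir / "gene_sets.gmt")

        c = cfg["cerna"]
        n_feat = int(c["n_planted"]) + int(c["n_decoy_pairs"])
        base = synthdata.SynthSpec(
            n_lnc=n_feat, n_mrna=n_feat,
            n_mirna=int(c["n_planted"]) + int(c["n_decoy_mirnas"]), seed=seed,
        )
        triplets = tuple(
            (base.lnc_ids()[i], base.mirna_ids()[i], base.mrna_ids()[i], float(c["beta"]))
            for i in range(int(c["n_planted"]))
        )
        cerna_spec = synthdata.SynthSpec(
            n_pairs=int(c["n_pairs"]), n_lnc=n_feat, n_mrna=n_feat,
            n_mirna=int(c["n_planted"]) + int(c["n_decoy_mirnas"]),
            planted_triplets=triplets, noise_sd=float(c["noise_sd"]),
            seq_len=int(c["seq_len"]), seed=derive_seed(seed, "cerna_system"),
        )
        lnc_em, mirna_em, mrna_em, lnc_seqs, mrna_seqs, mirna_seqs, ctruth = (
            synthdata.generate_cerna_system(cerna_spec)
        )
        lnc_em.to_tsv(self.inputs_dir / "lnc_expr.tsv", self.inputs_dir / "cerna_samples.tsv")
        mirna_em.to_tsv(self.inputs_dir / "mirna_expr.tsv")
        mrna_em.to_tsv(self.inputs_dir / "mrna_expr.tsv")
        cerna.write_fasta(lnc_seqs, self.inputs_dir / "lnc.fasta")
        cerna.write_fasta(mrna_seqs, self.inputs_dir / "mrna.fasta")
        cerna.write_fasta(mirna_seqs, self.inputs_dir / "mirna.fasta")
        ctruth.to_json(self.inputs_dir / "truth_cerna.json")
        self._register("simulate", *sorted(self.inputs_dir.iterdir()))

    def _write_annotation(self, spec: synthdata.SynthSpec, rng: np.random.Generator) -> None:
        chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
        cats = ["intergenic", "antisense", "exonic-sense"]
        rows = []
        for f in spec.lnc_ids():
            rows.append((f, "", str(rng.choice(chroms)), "lncRNA",
                         int(rng.integers(400, 3001)), str(rng.choice(cats))))
        for f in spec.mrna_ids():
            rows.append((f, f.lower(), str(rng.choice(chroms)), "mRNA",
                         int(rng.integers(500, 5001)), ""))
        ann = pd.DataFrame(
            rows, columns=["accession", "symbol", "chromosome", "feature_class",
                           "length_nt", "lnc_category"],
        ).set_index("accession")
        ann.to_csv(self.inputs_dir / "annotation.tsv", sep="\t")

    def _load_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix.from_tsv(
            self._input("matrix", "expression.tsv"), self._input("meta", "samples.tsv")
        )

    def stage_normalize(self) -> None:
        em = self._load_matrix()
        norm = diffexpr.quantile_normalize(em)
        out = self.outdir / "normalized.tsv"
        norm.to_tsv(out)
        self._register("normalize", out)

    def _normalized_matrix(self) -> ExpressionMatrix:
        path = self.outdir / "normalized.tsv"
        if not path.exists():
            raise FileNotFoundError("normalize stage has not run (normalized.tsv missing)")
        meta = pd.read_csv(self._input("meta", "samples.tsv"), sep="\t", index_col=0,
                           dtype={"pair_id": str})
        values = pd.read_csv(path, sep="\t", index_col=0)
        return ExpressionMatrix(values=values, meta=meta)

    def stage_de(self) -> None:
        em = self._normalized_matrix()
        outs = []
        for label, mode in (("discovery", self.cfg["de"]["mode"]),
                            ("validation", self.cfg["de"]["validation_mode"])):
            de = diffexpr.screen_de(em, mode=mode)
            out = self.outdir / f"de_{label}.tsv"
            de.to_csv(out, sep="\t")
            outs.append(out)
            for direction in ("up", "down"):
                ids = diffexpr.regulated_ids(de, direction)
                p = self.outdir / f"de_{label}_{direction}.txt"
                p.write_text("\n".join(ids) + ("\n" if ids else ""))
                outs.append(p)
        self._register("de", *outs)

    def stage_intersect(self) -> None:
        outs = []
        for direction in ("up", "down"):
            a = _read_ids(self.outdir / f"de_discovery_{direction}.txt")
            b = _read_ids(self.outdir / f"de_validation_{direction}.txt")
            ids = diffexpr.intersect_sets(a, b)
            p = self.outdir / f"intersect_{direction}.txt"
            p.write_text("\n".join(ids) + ("\n" if ids else ""))
            outs.append(p)
        self._register("intersect", *outs)

    def stage_enrich(self) -> None:
        de = pd.read_csv(self.outdir / "de_discovery.tsv", sep="\t", index_col=0)
        background = _read_ids(self._input("background", "background.txt"))
        query = [f for f in diffexpr.regulated_ids(de) if f in set(background)]
        sets = enrich_mod.read_gmt(self._input("gmt", "gene_sets.gmt"))
        res = enrich_mod.enrich(query, sets, background,
                                min_hits=int(self.cfg["enrichment"]["min_hits"]))
        res = enrich_mod.top_terms(res, k=int(self.cfg["enrichment"]["top_k"]))
        out = self.outdir / "enrichment.tsv"
        res.to_csv(out, sep="\t", index=False)
        self._register("enrich", out)

    def stage_candidates(self) -> None:
        de = pd.read_csv(self.outdir / "de_discovery.tsv", sep="\t", index_col=0)
        ann = pd.read_csv(self._input("annotation", "annotation.tsv"), sep="\t", index_col=0)
        ann = ann.fillna({"lnc_category": "", "symbol": ""})
        lnc = de.loc[[f for f in de.index if f in set(ann.index[ann["feature_class"] == "lncRNA"])]]
        cands, removals = diffexpr.candidate_filter(lnc, ann)
        out1, out2 = self.outdir / "candidates.tsv", self.outdir / "candidate_removals.tsv"
        cands.to_csv(out1, sep="\t")
        removals.to_csv(out2, sep="\t")
        self._register("candidates", out1, out2)

    def stage_cerna(self) -> None:
        meta = pd.read_csv(self._input("cerna_meta", "cerna_samples.tsv"), sep="\t",
                           index_col=0, dtype={"pair_id": str})

        def load(key, name):
            values = pd.read_csv(self._input(key, name), sep="\t", index_col=0)
            return ExpressionMatrix(values=values, meta=meta)
        lnc_em = load("lnc_matrix", "lnc_expr.tsv")
        mirna_em = load("mirna_matrix", "mirna_expr.tsv")
        mrna_em = load("mrna_matrix", "mrna_expr.tsv")
        lnc_seqs = cerna.read_fasta(self._input("lnc_fasta", "lnc.fasta"))
        mrna_seqs = cerna.read_fasta(self._input("mrna_fasta", "mrna.fasta"))
        mirna_seqs = cerna.read_fasta(self._input("mirna_fasta", "mirna.fasta"))
        ccfg = self.cfg["cerna"]
        corr = {
            cond: cerna.pairwise_correlation(lnc_em, mrna_em, cond)
            for cond in ("normal", "tumor")
        }
        thresholds, selected = cerna.percentile_threshold(
            corr, q=float(ccfg["percentile"]), rule=ccfg["condition_rule"]
        )
        triplets, exclusions = cerna.assemble_triplets(
            selected, mirna_seqs, lnc_seqs, mrna_seqs, lnc_em, mirna_em, mrna_em,
            delta=float(ccfg["delta"]),
            sensitivity_condition=ccfg["sensitivity_condition"],
        )
        net = cerna.build_network(triplets)
        outs = []
        p = self.outdir / "cerna_thresholds.json"
        p.write_text(json.dumps({k: thresholds[k] for k in sorted(thresholds)},
                                indent=2) + "\n")
        outs.append(p)
        p = self.outdir / "triplets.tsv"
        cerna.triplets_to_frame(triplets).to_csv(p, sep="\t", index=False)
        outs.append(p)
        p = self.outdir / "triplet_exclusions.tsv"
        pd.DataFrame(exclusions, columns=["lncrna", "mirna", "mrna", "reason"]).to_csv(
            p, sep="\t", index=False)
        outs.append(p)
        for fmt, name in (("sif", "network.sif"), ("graphml", "network.graphml")):
            p = self.outdir / name
            cerna.export_network(net, p, fmt)
            outs.append(p)
        self._register("cerna", *outs)

    def stage_survival(self) -> None:
        scfg = self.cfg["survival"]
        seed = derive_seed(int(self.cfg["seed"]), "survival")
        if self.cfg["simulate"]:
            sim = self.cfg["sim"]["survival"]
            n = int(sim["n_subjects"])
            spec = synthdata.SynthSpec(
                hazard_ratio=float(sim["hazard_ratio"]),
                censor_rate=float(sim["censor_rate"]), seed=seed,
            )
            rng = np.random.default_rng(seed)
            expr = pd.Series(rng.normal(8, 1, n),
                             index=[f"S{i:04d}" for i in range(1, n + 1)])
            groups = clinstats.median_split(expr)
            records, truth = synthdata.generate_survival(spec, groups,
                                                         base_hazard=float(scfg["base_hazard"]))
            truth.to_json(self.outdir / "truth_survival.json")
        else:
            records = pd.read_csv(self._input("survival", "survival.tsv"), sep="\t",
                                  index_col=0)
            if scfg["time_unit"] == "days":
                records = records.assign(time=records["time"] / 365.25)
            if "group" not in records.columns:
                raise ConfigError("survival table needs a 'group' column "
                                  "(or use the simulated cohort)")
        outs = [self.outdir / "survival_records.tsv"]
        records.to_csv(outs[0], sep="\t")
        for grp, sub in sorted(records.groupby("group")):
            curve = clinstats.km_estimate(sub)
            p = self.outdir / f"km_{grp}.tsv"
            pd.DataFrame({"time": curve.event_times, "survival": curve.survival,
                          "at_risk": curve.at_risk}).to_csv(p, sep="\t", index=False)
            outs.append(p)
        chi2, pval = clinstats.logrank_test(records)
        p = self.outdir / "logrank.json"
        p.write_text(json.dumps({"chi2": chi2, "p_value": pval}, indent=2) + "\n")
        outs.append(p)
        self._register("survival", *outs)

    # -- driver ---------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> dict:
        todo = list(stages) if stages else [
            s for s in STAGES if s != "simulate" or self.cfg["simulate"]
        ]
        for s in todo:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}")
        for s in todo:
            log.info("[%s] running", s)
            t0 = time.time()
            try:
                getattr(self, f"stage_{s}")()
            except Exception as exc:
                raise RuntimeError(f"stage {s!r} failed: {exc}") from exc
            log.info("[%s] done in %.2fs", s, time.time() - t0)
        manifest = self.write_manifest()
        return manifest

    def write_manifest(self) -> dict:
        manifest = {
            "version": __version__,
            "seed": int(self.cfg["seed"]),
            "config": self.cfg,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": {
                stage: {Path(p).name: _sha256(Path(p)) for p in paths}
                for stage, paths in self.artifacts.items()
            },
        }
        (self.outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
        return manifest


def _read_ids(path: Path) -> list[str]:
    text = Path(path).read_text()
    return [line for line in text.splitlines() if line.strip()]


def run_pipeline(config: dict, stages: list[str] | None = None) -> dict:
    """Run the configured stages and return the manifest."""
    return Pipeline(config).run(stages)


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(config: dict) -> list[str]:
    """Pre-flight checks on user-supplied input files.

    Returns a list of human-readable violations (empty = valid).  Only
    meaningful when ``simulate`` is false; a simulated run validates
    trivially.
    """
    violations: list[str] = []
    if config["simulate"]:
        return violations
    inputs = config["inputs"]
    mat, meta = inputs.get("matrix"), inputs.get("meta")
    for key in ("matrix", "meta"):
        if not inputs.get(key):
            violations.append(f"inputs.{key} missing")
    if mat and meta and Path(mat).exists() and Path(meta).exists():
        try:
            em = ExpressionMatrix.from_tsv(mat, meta)
            em.pairs()
        except Exception as exc:
            violations.append(f"expression matrix/metadata: {exc}")
    elif mat and not Path(str(mat)).exists():
        violations.append(f"inputs.matrix: no such file {mat}")
    for key in ("lnc_fasta", "mirna_fasta", "mrna_fasta"):
        p = inputs.get(key)
        if p and Path(p).exists():
            try:
                seqs = cerna.read_fasta(p)
                for name, seq in seqs.items():
                    try:
                        cerna.normalize_rna(seq)
                    except ValueError as exc:
                        violations.append(f"inputs.{key} record {name!r}: {exc}")
            except Exception as exc:
                violations.append(f"inputs.{key}: {exc}")
    gmt = inputs.get("gmt")
    if gmt and Path(gmt).exists():
        try:
            enrich_mod.read_gmt(gmt)
        except Exception as exc:
            violations.append(f"inputs.gmt: {exc}")
    return violations
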
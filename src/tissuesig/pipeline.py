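"""End-to-end orchestration: simulate -> select -> summarize -> evaluate.

A single declarative config (YAML-able dict, one section per stage) drives
the whole analysis, and a manifest records every parameter, seed, output
path and file digest so a run can be reproduced byte-for-byte from its
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bvs import BVSConfig, pool_chains, run_chain
from .datasets import (
    ExpressionDataset,
    SyntheticConfig,
    check_paired,
    generate_paired,
    read_dataset,
    write_dataset,
)
from .enrichment import read_gmt, score_gene_sets, univariate_rank
from .evaluation import SelectorConfig, ga_mlhd_selector, pca_contributions, specificity_test
from .ga import GAConfig, ModelPopulation, evolve, final_population_accuracy
from .mlhd import CVConfig
from .summary import forward_select_representative, gene_frequency, make_overlap_test

log = logging.getLogger("tissuesig")

STAGES = (
    "simulate",
    "select-ga",
    "select-bvs",
    "summarize",
    "specificity",
    "pca",
    "enrich",
    "report",
)

_DEPS = {
    "simulate": (),
    "select-ga": ("simulate",),
    "select-bvs": ("simulate",),
    "summarize": ("select-ga", "select-bvs"),
    "specificity": ("simulate",),
    "pca": ("summarize",),
    "enrich": ("summarize",),
    "report": (),
}


def default_config() -> dict:
    """A desk-scale configuration exercising every stage on synthetic data."""
    return {
        "seed": 0,
        "stages": list(STAGES),
        "endpoints": ["gleason"],
        "tissues": ["normal", "tumour"],
        "simulate": {
            "n_patients": 40,
            "n_genes": 150,
            "n_informative": 5,
            "effect_size": 2.0,
            "signal_tissue": "normal",
            "endpoints": ["gleason", "capsular_penetration"],
        },
        "cv": {"inner_k": 5, "outer_splits": 40},
        "ga": {"population_size": 20, "generations": 8, "n_runs": 2, "chromosome_size": 5},
        "bvs": {"expected_model_size": 10, "n_iterations": 2000, "burn_in": 500, "n_chains": 2},
        "summary": {"top_fraction": 0.01, "max_size": 10, "top_k_overlap": 50},
        "specificity": {"n_repeats": 3, "signature_tissue": "normal", "ga": {"n_runs": 8}},
        "pca": {"n_components": 2, "threshold": 0.3},
        "enrich": {"gmt": None, "universe_size": None},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _expand_config(cfg: dict) -> dict:
    """Fill every stage section with its full dataclass defaults.

    The manifest must record the complete effective configuration, not just
    the keys the caller happened to set.
    """
    out = dict(cfg)
    seed = int(out.get("seed", 0))
    if not out.get("data"):
        sim = dict(out.get("simulate", {}))
        if "endpoints" in sim:
            sim["endpoints"] = tuple(sim["endpoints"])
        scfg = SyntheticConfig(**{**sim, "seed": sim.get("seed", seed)})
        out["simulate"] = {**dataclasses.asdict(scfg), "endpoints": list(scfg.endpoints)}
    out["cv"] = dataclasses.asdict(CVConfig(**{**out.get("cv", {}), "seed": seed}))
    out["ga"] = dataclasses.asdict(GAConfig(**{**out.get("ga", {}), "seed": seed}))
    bvs = dataclasses.asdict(BVSConfig(**{**out.get("bvs", {}), "seed": seed}))
    bvs["move_probs"] = list(bvs["move_probs"])
    out["bvs"] = bvs
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Complete provenance record of one pipeline invocation."""

    config: dict
    seed: int
    version: str
    stages: list[str]
    outputs: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    digests: dict[str, str] = dataclasses.field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _closure(requested: list[str]) -> list[str]:
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage name(s) {unknown}; valid stages: {list(STAGES)}")
    need: set[str] = set()

    def add(stage: str) -> None:
        if stage not in need:
            for d in _DEPS[stage]:
                add(d)
            need.add(stage)

    for s in requested:
        add(s)
    return [s for s in STAGES if s in need]


class _Run:
    """Mutable state threaded through the stages of one invocation."""

    def __init__(self, cfg: dict, outdir: Path, seed: int):
        self.cfg = cfg
        self.outdir = outdir
        self.seed = seed
        self.datasets: dict[str, ExpressionDataset] = {}
        self.populations: dict[tuple[str, str], ModelPopulation] = {}
        self.bvs_summaries: dict[tuple[str, str], list] = {}
        self.representatives: list[dict] = []
        self.rankings: dict[tuple[str, str, str], list[str]] = {}
        self.outputs: dict[str, list[str]] = {}

    def record(self, stage: str, *paths: Path) -> None:
        self.outputs.setdefault(stage, []).extend(str(p) for p in paths)

    # -- stages -------------------------------------------------------------

    def simulate(self) -> None:
        sim = dict(self.cfg.get("simulate", {}))
        if self.cfg.get("data"):
            d = self.cfg["data"]
            self.datasets["normal"] = read_dataset(d["normal_prefix"])
            self.datasets["tumour"] = read_dataset(d["tumour_prefix"])
            check_paired(self.datasets["normal"], self.datasets["tumour"])
            return
        if "endpoints" in sim:
            sim["endpoints"] = tuple(sim["endpoints"])
        scfg = SyntheticConfig(**{**sim, "seed": sim.get("seed", self.seed)})
        normal, tumour = generate_paired(scfg)
        self.datasets = {"normal": normal, "tumour": tumour}
        paths = []
        for tissue, ds in self.datasets.items():
            paths.extend(write_dataset(ds, str(self.outdir / tissue)))
        gmt = self.outdir / "planted_sets.gmt"
        with open(gmt, "w") as fh:
            for ep, genes in (normal.informative or {}).items():
                if genes:
                    fh.write(f"planted_{ep}\tinformative genes for {ep}\t" + "\t".join(genes) + "\n")
            rng = np.random.default_rng(self.seed)
            for j in range(3):
                pick = rng.choice(normal.gene_ids, size=max(len(genes), 5), replace=False)
                fh.write(f"random_set_{j}\trandom control set\t" + "\t".join(pick) + "\n")
        paths.append(str(gmt))
        self.record("simulate", *paths)

    def _each(self):
        for tissue in self.cfg.get("tissues", ["normal", "tumour"]):
            if tissue not in self.datasets:
                raise ValueError(f"no dataset for tissue {tissue!r}")
            ds = self.datasets[tissue]
            for ep in self.cfg.get("endpoints", sorted(ds.labels)):
                if ep not in ds.labels:
                    raise ValueError(f"endpoint column {ep!r} missing from {tissue} dataset")
                yield tissue, ep, ds

    def cv_config(self, seed_offset: int = 0) -> CVConfig:
        return CVConfig(**{**self.cfg.get("cv", {}), "seed": self.seed + seed_offset})

    def select_ga(self) -> None:
        cv = self.cv_config()
        for tissue, ep, ds in self._each():
            ga_cfg = GAConfig(**{**self.cfg.get("ga", {}), "seed": self.seed})
            log.info("GA-MLHD selection: tissue=%s endpoint=%s %s", tissue, ep, ga_cfg)
            pop = evolve(ds, ep, ga_cfg, cv)
            top = pop.sorted_by_fitness()
            n_top = max(1, int(np.ceil(0.01 * len(top.records))))
            annotated = final_population_accuracy(
                ModelPopulation(top.records[:n_top]), ds, ep, cv
            )
            rows = [
                {
                    "run": r.run,
                    "generation": r.generation,
                    "fitness": r.fitness,
                    "outer_accuracy": r.outer_mean if r.outer_mean is not None else "",
                    "genes": ",".join(ds.gene_ids[g] for g in r.chromosome.genes),
                }
                for r in annotated.records + top.records[n_top:]
            ]
            path = self.outdir / f"ga_models_{tissue}_{ep}.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            self.populations[(tissue, ep)] = pop
            self.record("select-ga", path)

    def select_bvs(self) -> None:
        for tissue, ep, ds in self._each():
            bvs_section = dict(self.cfg.get("bvs", {}))
            if "move_probs" in bvs_section:
                bvs_section["move_probs"] = tuple(bvs_section["move_probs"])
            bcfg = BVSConfig(**{**bvs_section, "seed": self.seed})
            log.info("BVS selection: tissue=%s endpoint=%s %s", tissue, ep, bcfg)
            summaries = [
                run_chain(ds, ep, bcfg, chain_seed=bcfg.seed * 1000 + 7 * i + 1)
                for i in range(bcfg.n_chains)
            ]
            self.bvs_summaries[(tissue, ep)] = summaries
            trace_rows = []
            for ci, s in enumerate(summaries):
                trace_rows.extend(
                    {"chain": ci, "iteration": it, "model_size": ms, "log_marginal": lm}
                    for it, ms, lm in s.trace[:: max(1, len(s.trace) // 500)]
                )
            tpath = self.outdir / f"bvs_trace_{tissue}_{ep}.tsv"
            pd.DataFrame(trace_rows).to_csv(tpath, sep="\t", index=False)
            sub_rows = []
            for ci, s in enumerate(summaries):
                for subset, visits in s.top_subsets(20):
                    sub_rows.append(
                        {
                            "chain": ci,
                            "genes": ",".join(ds.gene_ids[g] for g in subset),
                            "visits": visits,
                        }
                    )
            spath = self.outdir / f"bvs_subsets_{tissue}_{ep}.tsv"
            pd.DataFrame(sub_rows).to_csv(spath, sep="\t", index=False)
            self.record("select-bvs", tpath, spath)

    def summarize(self) -> None:
        scfg = self.cfg.get("summary", {})
        cv = self.cv_config()
        freq_paths, reps = [], []
        for tissue, ep, ds in self._each():
            pop = self.populations[(tissue, ep)]
            freq = gene_frequency(pop, scfg.get("top_fraction", 0.01))
            freq_named = freq.assign(gene=[ds.gene_ids[g] for g in freq["gene"]])
            fpath = self.outdir / f"gene_frequency_{tissue}_{ep}.tsv"
            freq_named.to_csv(fpath, sep="\t", index=False)
            freq_paths.append(fpath)

            rep_ga = forward_select_representative(
                freq["gene"].tolist(), ds, ep, cv, max_size=scfg.get("max_size", 10)
            )
            rep_bvs = pool_chains(
                self.bvs_summaries[(tissue, ep)], ds, ep, tissue=tissue, cv_seed=self.seed
            )
            reps.extend([rep_ga, rep_bvs])

            k = scfg.get("top_k_overlap", 50)
            top_ga = freq_named["gene"].head(k).tolist()
            incl = np.mean([s.marginal_inclusion for s in self.bvs_summaries[(tissue, ep)]], axis=0)
            order = np.lexsort((ds.gene_ids, -incl))
            top_bvs = [ds.gene_ids[i] for i in order[:k]]
            ov = make_overlap_test(top_ga, top_bvs, universe_size=ds.n_genes)
            self.representatives.append(
                {
                    "tissue": tissue,
                    "endpoint": ep,
                    "overlap_top_k": k,
                    "overlap": ov.overlap,
                    "overlap_p": ov.p_value,
                }
            )
            self.rankings[(tissue, ep, "GA-MLHD")] = top_ga
            self.rankings[(tissue, ep, "BVS")] = top_bvs

        rep_rows = [
            {
                "endpoint_tissue": f"{r.endpoint}+{r.tissue}",
                "method": r.method,
                "genes": ",".join(r.genes),
                "accuracy_pct": round(100.0 * r.accuracy, 1),
                "inner_accuracy_pct": ""
                if r.inner_accuracy is None
                else round(100.0 * r.inner_accuracy, 1),
                "size": r.size,
            }
            for r in reps
        ]
        rpath = self.outdir / "representative_models.tsv"
        pd.DataFrame(rep_rows).to_csv(rpath, sep="\t", index=False)
        opath = self.outdir / "overlap_tests.tsv"
        pd.DataFrame(self.representatives).to_csv(opath, sep="\t", index=False)
        self.reps = reps
        self.record("summarize", rpath, opath, *freq_paths)

    def specificity(self) -> None:
        sp = self.cfg.get("specificity", {})
        ga_over = {**self.cfg.get("ga", {}), **sp.get("ga", {}), "seed": self.seed}
        sel_cfg = SelectorConfig(
            ga=GAConfig(**ga_over),
            cv=self.cv_config(),
            max_size=self.cfg.get("summary", {}).get("max_size", 10),
        )
        rows = []
        for ep in self.cfg.get("endpoints", sorted(self.datasets["normal"].labels)):
            for sig_tissue in [sp.get("signature_tissue", "normal")]:
                res = specificity_test(
                    self.datasets["normal"],
                    self.datasets["tumour"],
                    ep,
                    signature_tissue=sig_tissue,
                    selector=ga_mlhd_selector(sel_cfg),
                    n_repeats=sp.get("n_repeats", 3),
                    seed=self.seed,
                )
                for rep in range(res.n_repeats):
                    rows.append(
                        {
                            "endpoint": ep,
                            "signature_tissue": sig_tissue,
                            "direction": "same",
                            "repeat": rep,
                            "accuracy": res.same_tissue_accuracies[rep],
                        }
                    )
                    rows.append(
                        {
                            "endpoint": ep,
                            "signature_tissue": sig_tissue,
                            "direction": "cross",
                            "repeat": rep,
                            "accuracy": res.cross_tissue_accuracies[rep],
                        }
                    )
        path = self.outdir / "specificity.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        self.record("specificity", path)

    def pca(self) -> None:
        pcfg = self.cfg.get("pca", {})
        rows = []
        for r in self.reps:
            ds = self.datasets[r.tissue]
            if r.size < 2:
                continue
            idx = ds.gene_indices(r.genes)
            n_comp = min(pcfg.get("n_components", 2), r.size, ds.n_samples)
            profiles, _ = pca_contributions(
                ds, idx, n_components=n_comp, threshold=pcfg.get("threshold", 0.3)
            )
            for prof in profiles:
                for g, l in zip(prof.genes, prof.loadings):
                    rows.append(
                        {
                            "endpoint_tissue": f"{r.endpoint}+{r.tissue}",
                            "method": r.method,
                            "component": prof.component_index,
                            "gene": g,
                            "loading": l,
                            "highlighted": abs(l) > prof.threshold,
                            "explained_variance_fraction": prof.explained_variance_fraction,
                        }
                    )
        path = self.outdir / "pca_loadings.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        self.record("pca", path)

    def enrich(self) -> None:
        ecfg = self.cfg.get("enrich", {})
        gmt_path = ecfg.get("gmt") or str(self.outdir / "planted_sets.gmt")
        if not Path(gmt_path).exists():
            raise ValueError(f"enrich stage needs a GMT file; {gmt_path} does not exist")
        gene_sets = read_gmt(gmt_path)
        frames = []
        for (tissue, ep, method), focus in self.rankings.items():
            universe = ecfg.get("universe_size") or self.datasets[tissue].n_genes
            df = score_gene_sets(focus, gene_sets, universe_size=universe)
            df.insert(0, "method", method)
            df.insert(0, "endpoint_tissue", f"{ep}+{tissue}")
            frames.append(df)
        path = self.outdir / "enrichment.tsv"
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
        urows = []
        for tissue, ep, ds in self._each():
            rank = univariate_rank(ds, ep).head(50)
            rank.insert(0, "endpoint_tissue", f"{ep}+{tissue}")
            urows.append(rank)
        upath = self.outdir / "univariate_rank.tsv"
        pd.concat(urows, ignore_index=True).to_csv(upath, sep="\t", index=False)
        self.record("enrich", path, upath)


def run_pipeline(config: dict | str | Path | None = None, outdir=".", seed: int | None = None,
                 stages: list[str] | None = None) -> RunManifest:
    """Execute the requested stages (plus dependencies) and write a manifest.

    ``config`` may be a dict, a YAML path, or None for the defaults; all
    randomness flows from the single manifest seed.
    """
    if config is None:
        cfg = default_config()
    elif isinstance(config, (str, Path)):
        cfg = _merge(default_config(), load_config(config))
    else:
        cfg = _merge(default_config(), config)
    if seed is not None:
        cfg["seed"] = int(seed)
    cfg = _expand_config(cfg)
    requested = stages if stages is not None else cfg.get("stages", list(STAGES))
    ordered = _closure(list(requested))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    run = _Run(cfg, outdir, int(cfg["seed"]))
    impl = {
        "simulate": run.simulate,
        "select-ga": run.select_ga,
        "select-bvs": run.select_bvs,
        "summarize": run.summarize,
        "specificity": run.specificity,
        "pca": run.pca,
        "enrich": run.enrich,
    }
    for stage in ordered:
        if stage == "report":
            continue
        log.info("stage %s", stage)
        try:
            impl[stage]()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config=cfg,
        seed=int(cfg["seed"]),
        version=__version__,
        stages=ordered,
        outputs=run.outputs,
    )
    for paths in run.outputs.values():
        for p in paths:
            manifest.digests[p] = _sha256(Path(p))
    if "report" in ordered:
        rpaths = report(manifest, outdir)
        manifest.outputs["report"] = [str(p) for p in rpaths]
        for p in rpaths:
            manifest.digests[str(p)] = _sha256(Path(p))
    manifest.write(outdir / "manifest.json")
    return manifest


def report(manifest: RunManifest, outdir=".") -> list[Path]:
    """Consolidate completed-stage outputs into one TSV and one JSON summary.

    Both carry identical values; stages absent from the manifest appear as
    explicit gaps rather than being silently dropped.
    """
    outdir = Path(outdir)
    sections: dict[str, object] = {}
    rows = []
    tables = {
        "representative_models": ("summarize", "representative_models.tsv"),
        "overlap_tests": ("summarize", "overlap_tests.tsv"),
        "specificity": ("specificity", "specificity.tsv"),
        "enrichment": ("enrich", "enrichment.tsv"),
    }
    for name, (stage, fname) in tables.items():
        match = [p for p in manifest.outputs.get(stage, []) if p.endswith(fname)]
        if not match:
            sections[name] = None
            rows.append({"section": name, "key": "status", "value": "missing"})
            continue
        df = pd.read_csv(match[0], sep="\t")
        sections[name] = df.to_dict(orient="records")
        for i, rec in enumerate(df.to_dict(orient="records")):
            for k, v in rec.items():
                rows.append({"section": name, "key": f"{i}.{k}", "value": v})
    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(sections, indent=2, sort_keys=True, default=str) + "\n")
    tsv_path = outdir / "report.tsv"
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    return [tsv_path, json_path]
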
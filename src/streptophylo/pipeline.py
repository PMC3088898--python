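"""Config-driven end-to-end runs: screen -> concatenate -> infer -> support
-> cross-validate -> composition -> recoded re-analysis -> taxon-deletion
reruns, with per-stage seeds, deterministic output names and a JSON run
report.

Every stochastic stage derives its seed from the master seed, so a rerun
with the same config is seed-identical.  A non-converged MCMC (between-chain
bipartition maxdiff >= 0.1) is flagged in the report, never silently
passed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import Alignment, GeneAlignment
from .composition import (composition_matrix, dayhoff_recode,
                          heterogeneity_score, pca_composition)
from .crossval import cv_table, make_cv_splits
from .inference import bootstrap, mcmc_sample, nj_start_tree, nni_search
from .likelihood import TreeLikelihood
from .screen import screen_genes
from .simulate import make_study_like_dataset
from .substmodels import make_model
from .supermatrix import (apply_chimeras, concatenate, filter_gene_occupancy,
                          missing_fraction, read_chimera_rules,
                          read_gene_alignments, subsample_taxa)
from .trees import (Tree, parse_newick, rf_distance, restrict, write_newick)

DEFAULTS: dict = {
    "seed": 0,
    "screen": {"enabled": False, "bp_threshold": 70.0, "replicates": 100,
               "model": "lg"},
    "concat": {"max_missing": 16, "chimera_file": None},
    "ml": {"model": "lg", "gamma_categories": 4, "classes": 10,
           "bootstrap_replicates": 100},
    "mcmc": {"enabled": False, "model": "cat", "classes": 10,
             "cycles": 10000, "thin": 10, "burnin": 1000, "chains": 2},
    "cv": {"enabled": False, "models": ["gtr", "lg"], "baseline": "lg",
           "replicates": 10, "classes": 10},
    "composition": {"enabled": True},
    "recode": {"enabled": False, "model": "gtr"},
    "taxon_deletion": [],
}


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Effective pipeline configuration (defaults merged with user input)."""

    raw: dict

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        cfg = _merge(DEFAULTS, data)
        if not (0 <= cfg["screen"]["bp_threshold"] <= 101):
            raise ValueError("bp_threshold outside [0, 101]")
        if cfg["concat"]["max_missing"] < 0:
            raise ValueError("max_missing must be >= 0")
        return cls(cfg)

    def __getitem__(self, key):
        return self.raw[key]

    def stage_seed(self, stage: str) -> int:
        base = int(self.raw.get("seed", 0))
        return (base * 7_654_321 + sum(ord(c) for c in stage) * 97) % (2 ** 31)


@dataclass
class RunReport:
    """Per-stage digest of one pipeline run."""

    config: dict
    stages: dict = field(default_factory=dict)
    version: str = ""

    def add(self, name: str, **info) -> None:
        self.stages[name] = info

    def write(self, path) -> None:
        def clean(x):
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {str(k): clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            return x
        payload = {"version": self.version, "config": clean(self.config),
                   "stages": clean(self.stages)}
        Path(path).write_text(json.dumps(payload, indent=2))


def _load_genes(cfg: PipelineConfig) -> tuple[list, Tree | None]:
    inp = cfg.raw.get("input", {})
    if "simulate" in inp:
        sim = dict(inp["simulate"])
        sim.setdefault("seed", cfg.stage_seed("simulate"))
        ds = make_study_like_dataset(**sim)
        return ds.genes, ds.tree
    genes = read_gene_alignments(
        sorted(Path(inp["genes_dir"]).glob(inp.get("glob", "*.fasta"))),
        inp.get("format", "fasta"))
    return genes, None


def _infer_block(alignment: Alignment, model_kind: str, cfg_ml: Mapping,
                 seed: int, outdir: Path, tag: str, report: RunReport):
    """One ML inference + bootstrap block on a (possibly recoded or
    taxon-reduced) supermatrix alignment."""
    model = _make_stage_model(alignment, model_kind, cfg_ml, seed)
    t0 = time.time()
    boot = bootstrap(alignment, model,
                     replicates=int(cfg_ml["bootstrap_replicates"]), seed=seed)
    tree_path = outdir / f"{tag}.ml.nwk"
    tree_path.write_text(write_newick(boot.ml_tree) + "\n")
    report.add(f"ml_{tag}", model=model_kind, seed=seed,
               loglik=None, tree=str(tree_path),
               supports={str(k): v for k, v in boot.supports.items()},
               wall_time=round(time.time() - t0, 2))
    return boot


def _make_stage_model(alignment: Alignment, kind: str, cfg_ml: Mapping,
                      seed: int):
    tl = TreeLikelihood(alignment, nj_start_tree(
        alignment, make_model("poisson", alignment.alphabet,
                              gamma_categories=1)), kind,
        n_classes=int(cfg_ml.get("classes", 10)),
        gamma_categories=int(cfg_ml.get("gamma_categories", 4)), seed=seed)
    res = tl.fit(max_rounds=2, outer_rounds=1)
    return res.submodel


def run_pipeline(cfg: PipelineConfig, outdir) -> RunReport:
    """Execute the configured stages in order, writing all artifacts under
    ``outdir`` with deterministic names.  Returns the run report (also
    written as ``report.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=cfg.raw, version=__version__)
    t_start = time.time()

    genes, true_tree = _load_genes(cfg)
    report.add("input", n_genes=len(genes),
               taxa=sorted({t for g in genes for t in g.taxa}),
               simulated=true_tree is not None)

    # chimeras
    rules = []
    if cfg["concat"]["chimera_file"]:
        rules = read_chimera_rules(cfg["concat"]["chimera_file"])
        genes, donors = apply_chimeras(genes, rules)
        report.add("chimeras", rules=[r.target for r in rules], donors=donors)

    taxa = sorted({t for g in genes for t in g.taxa})

    # reference tree for screening
    reference = None
    if cfg.raw.get("reference_tree"):
        reference = parse_newick(Path(cfg.raw["reference_tree"]).read_text())
    elif cfg["screen"]["enabled"]:
        # quick proxy reference: ML on the unscreened concatenation
        sm0 = concatenate(genes, taxa)
        aln0 = sm0.to_alignment()
        model0 = make_model("lg", alpha=0.8)
        start = nj_start_tree(aln0, model0)
        reference, _ = nni_search(aln0, start, model0)
        (outdir / "reference.nwk").write_text(write_newick(reference) + "\n")

    if cfg["screen"]["enabled"]:
        scr = screen_genes(genes, reference, cfg["screen"]["model"],
                           bp_threshold=float(cfg["screen"]["bp_threshold"]),
                           replicates=int(cfg["screen"]["replicates"]),
                           seed=cfg.stage_seed("screen"))
        scr.write_tsv(outdir / "screen.tsv")
        scr.write_json(outdir / "screen.json")
        keep = set(scr.kept)
        genes = [g for g in genes if g.gene_id in keep]
        report.add("screen", kept=len(scr.kept), discarded=len(scr.discarded),
                   seed=cfg.stage_seed("screen"))

    kept, occ = filter_gene_occupancy(genes, taxa,
                                      int(cfg["concat"]["max_missing"]))
    sm = concatenate(kept, taxa)
    sm.write_phylip(outdir / "supermatrix.phy")
    sm.write_partitions(outdir / "supermatrix.partitions.txt")
    occ.write_tsv(outdir / "occupancy.tsv")
    report.add("concat", genes=len(kept), columns=sm.n_columns,
               taxa=sm.n_taxa, missing_fraction=missing_fraction(sm))

    aln = sm.to_alignment()
    ml_seed = cfg.stage_seed("ml")
    blocks = {"full": _infer_block(aln, cfg["ml"]["model"], cfg["ml"],
                                   ml_seed, outdir, "full", report)}

    if cfg["mcmc"]["enabled"]:
        model = _make_stage_model(aln, cfg["mcmc"]["model"], cfg["mcmc"],
                                  cfg.stage_seed("mcmc_model"))
        mc = mcmc_sample(aln, model, cycles=int(cfg["mcmc"]["cycles"]),
                         thin=int(cfg["mcmc"]["thin"]),
                         burnin=int(cfg["mcmc"]["burnin"]),
                         seed=cfg.stage_seed("mcmc"),
                         chains=int(cfg["mcmc"]["chains"]))
        (outdir / "mcmc.consensus.nwk").write_text(
            write_newick(mc.consensus) + "\n")
        report.add("mcmc", maxdiff=mc.maxdiff, converged=mc.converged,
                   acceptance=mc.acceptance, seed=cfg.stage_seed("mcmc"),
                   flag="OK" if mc.converged else
                   "WARNING: maxdiff >= 0.1, chains not converged")

    if cfg["cv"]["enabled"]:
        ref = blocks["full"].ml_tree
        splits = make_cv_splits(aln.length, int(cfg["cv"]["replicates"]),
                                seed=cfg.stage_seed("cv"))
        table = cv_table(list(cfg["cv"]["models"]), cfg["cv"]["baseline"],
                         splits, aln, ref,
                         n_classes=int(cfg["cv"]["classes"]),
                         max_rounds=2, outer_rounds=1, em_iterations=4)
        table.to_csv(outdir / "cv.tsv", sep="\t", index=False)
        report.add("cv", table=table.to_dict("records"),
                   seed=cfg.stage_seed("cv"))

    if cfg["composition"]["enabled"]:
        comp = composition_matrix(sm)
        comp.to_frame().to_csv(outdir / "composition.tsv", sep="\t")
        pca = pca_composition(comp)
        out = pca.to_frame(2)
        out["explained_1"] = pca.explained_variance[0]
        out["explained_2"] = pca.explained_variance[1]
        out.to_csv(outdir / "pca.tsv", sep="\t")
        het = heterogeneity_score(comp)
        het.to_csv(outdir / "heterogeneity.tsv", sep="\t", header=["score"])
        report.add("composition",
                   pca_axes12=float(pca.explained_variance[:2].sum()),
                   top_outliers=list(het.index[:5]))

    if cfg["recode"]["enabled"]:
        rec = dayhoff_recode(aln)
        rec.write(outdir / "supermatrix.dayhoff6.phy", "phylip-sequential")
        assert rec.alphabet.size == 6          # no silent 20-state fallback
        blocks["dayhoff6"] = _infer_block(
            rec, cfg["recode"]["model"], cfg["ml"],
            cfg.stage_seed("recode"), outdir, "dayhoff6", report)

    for k, drop in enumerate(cfg["taxon_deletion"]):
        sub = subsample_taxa(sm, drop)
        tag = f"drop{k + 1}"
        blocks[tag] = _infer_block(sub.to_alignment(), cfg["ml"]["model"],
                                   cfg["ml"], cfg.stage_seed(tag), outdir,
                                   tag, report)

    concord = compare_topologies({k: b.ml_tree for k, b in blocks.items()})
    concord.to_csv(outdir / "concordance.tsv", sep="\t")
    report.add("concordance", table=concord.to_dict())
    report.add("run", wall_time=round(time.time() - t_start, 2))
    if true_tree is not None:
        shared = blocks["full"].ml_tree.taxa & true_tree.taxa
        report.add("truth", rf_to_generating_topology=rf_distance(
            restrict(blocks["full"].ml_tree, shared),
            restrict(true_tree, shared)))
    report.write(outdir / "report.json")
    return report


def compare_topologies(trees: Mapping) -> pd.DataFrame:
    """Pairwise RF distances between inference blocks after restriction to
    shared taxa; 0 marks identical topologies."""
    names = list(trees)
    if len(names) < 1:
        raise ValueError("nothing to compare")
    out = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ta, tb = trees[a], trees[b]
            shared = ta.taxa & tb.taxa
            if len(shared) < 4:
                raise ValueError(f"{a} and {b} share fewer than 4 taxa")
            d = rf_distance(restrict(ta, shared), restrict(tb, shared))
            out.loc[a, b] = out.loc[b, a] = d
    return out
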
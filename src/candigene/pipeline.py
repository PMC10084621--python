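"""End-to-end orchestration: synth/load -> trait prep -> CCA -> extreme-score
contrasts -> differential expression -> directional overlap -> enrichment.

Every run is driven by one :class:`RunConfig` and one root seed; all stage
randomness flows from named substreams of that seed, so a rerun with the same
config and seed is byte-identical. The run report records every effective
parameter, the Wilks table and per-axis candidate counts (no wall-clock
timestamps, so the report itself is reproducible).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cca as cca_mod
from . import de as de_mod
from . import extremes as ex_mod
from . import io as io_mod
from . import ontology as onto_mod
from . import synth as synth_mod
from . import traits as traits_mod
from .io import ValidationError

logger = logging.getLogger("candigene")


def _substream(seed: int, name: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    h = np.uint32(2166136261)
    for ch in f"{name}:{seed}".encode():
        h = np.uint32((int(h) ^ ch) * 16777619 % 2**32)
    return int(h) % (2**31 - 1)


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run.

    With ``phenotypes_path``/``counts_path`` unset, inputs are simulated with
    the planted-axis generator (``rho`` = planted canonical correlations;
    ``planted_genes`` maps axis -> number of affected genes). When counts are
    read from disk, ``drop_chromosomes`` must be given explicitly (there is
    no universal sex-chromosome label).
    """

    seed: int = 0
    out_dir: str | None = None

    # file inputs (optional; otherwise synthetic)
    phenotypes_path: str | None = None
    counts_path: str | None = None
    ontology_path: str | None = None
    annotation_path: str | None = None
    reference_path: str | None = None
    drop_chromosomes: tuple[str, ...] | None = None

    # synthetic-data parameters
    p_second_larva: float = 0.7
    rho: tuple[float, float, float] = (0.85, 0.5, 0.25)
    n_genes: int = 2000
    planted_genes: dict[int, int] = field(default_factory=dict)
    effect_size: float = 1.5
    lib_median: float = 1e6
    with_ontology: bool = False

    # analysis parameters
    spearman_threshold: float = 0.9
    loading_threshold: float = 0.30
    significance_alpha: float = 0.05
    axes: str | tuple[int, ...] = "significant"   # "significant" or explicit axes
    n_tail: int = 10
    fdr: float = 0.05
    min_cpm: float = 1.0
    prior_df: float = 10.0
    min_term_size: int = 3
    categorize_level: int = 2

    def __post_init__(self) -> None:
        for name, val in (("significance_alpha", self.significance_alpha),
                          ("fdr", self.fdr)):
            if not (0 < val <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.n_tail < 1:
            raise ValueError("n_tail must be >= 1")


def _load_inputs(cfg: RunConfig):
    """Return (phenotypes, counts, ontology, annotation, truth_or_None)."""
    if cfg.phenotypes_path:
        pheno = io_mod.read_phenotypes(cfg.phenotypes_path)
        counts = io_mod.read_counts(cfg.counts_path) if cfg.counts_path else None
        if counts is not None:
            if cfg.drop_chromosomes is None:
                raise ValidationError(
                    "drop_chromosomes must be set explicitly when reading counts "
                    "from disk (name the sex chromosome, or pass an empty tuple)")
            counts = io_mod.exclude_chromosomes(counts, set(cfg.drop_chromosomes))
        truth = axes = None
    else:
        design = synth_mod.generate_design(synth_mod.DesignConfig(
            p_second_larva=cfg.p_second_larva, seed=_substream(cfg.seed, "design")))
        pheno, axes = synth_mod.simulate_planted_axes(
            design, rho=cfg.rho, seed=_substream(cfg.seed, "phenotypes"))
        truth = synth_mod.make_expression_truth(
            n_genes=cfg.n_genes, planted=dict(cfg.planted_genes),
            effect=cfg.effect_size, lib_median=cfg.lib_median,
            seed=_substream(cfg.seed, "truth"))
        counts = synth_mod.simulate_counts(
            list(pheno["individual_id"]), axes[["z1", "z2", "z3"]], truth,
            seed=_substream(cfg.seed, "counts"))
        pheno = io_mod.validate_phenotypes(pheno)

    onto = ann_ref = None
    if cfg.ontology_path:
        onto = io_mod.read_ontology(cfg.ontology_path)
        target_ann = (io_mod.read_annotation(cfg.annotation_path, onto)
                      if cfg.annotation_path else {})
        ann_ref = target_ann
    elif cfg.with_ontology and counts is not None:
        onto, ann, _ = synth_mod.generate_ontology_fixture(
            n_terms=40, n_genes=counts.shape[0], seed=_substream(cfg.seed, "ontology"))
        ann_ref = ann
    return pheno, counts, onto, ann_ref, truth


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the run report (also written to
    ``out_dir`` along with all stage artifacts when set)."""
    report: dict = {"config": _jsonable(dataclasses.asdict(cfg)), "stages": []}
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        pheno, counts, onto, ann, truth = _load_inputs(cfg)
        report["stages"].append({"stage": stage, "n_individuals": len(pheno),
                                 "n_genes": int(counts.shape[0]) if counts is not None else 0})

        stage = "trait_prep"
        pheno = traits_mod.derive_growth_rates(pheno)
        tcfg = traits_mod.TraitConfig(spearman_threshold=cfg.spearman_threshold)
        tm = traits_mod.transform_traits(pheno, tcfg)
        tm, dropped, corr = traits_mod.collinearity_screen(tm, cfg.spearman_threshold)
        report["stages"].append({"stage": stage, "retained_traits": list(tm.columns),
                                 "dropped_traits": dropped})

        stage = "cca"
        env = cca_mod.code_environment(pheno)
        res = cca_mod.fit_cca(tm, env)
        ladder = cca_mod.wilks_ladder(res.rho, res.n, res.p, res.q)
        wtab = cca_mod.wilks_table(ladder)
        wtab.insert(0, "rho", res.rho)
        loadings = cca_mod.significant_loadings(res, cfg.loading_threshold)
        scores = cca_mod.canonical_scores(res)
        report["wilks"] = wtab.reset_index().to_dict(orient="records")
        report["stages"].append({"stage": stage, "rho": [float(r) for r in res.rho]})

        if cfg.axes == "significant":
            run_axes = [t.k for t in ladder if t.p_value < cfg.significance_alpha]
        else:
            run_axes = [int(a) for a in cfg.axes]
        report["axes_run"] = run_axes

        candidates: dict[int, ex_mod.CandidateGeneSet] = {}
        enrichments: dict = {}
        if counts is not None:
            for axis in run_axes:
                stage = f"axis{axis}"
                c_ccp = ex_mod.select_extremes(scores, axis, "CCp", cfg.n_tail)
                c_cce = ex_mod.select_extremes(scores, axis, "CCe", cfg.n_tail)
                # one gene universe for both contrasts: filter on the pooled
                # tail samples so the directional overlap is well defined
                pool = sorted(set(c_ccp.high_ids + c_ccp.low_ids
                                  + c_cce.high_ids + c_cce.low_ids))
                filtered = de_mod.filter_low_expression(
                    counts.counts[pool], min_cpm=cfg.min_cpm,
                    min_samples=cfg.n_tail)
                de_tables = {}
                for con in (c_ccp, c_cce):
                    ids = con.high_ids + con.low_ids
                    sub = filtered[ids]
                    grp = pd.Series(["high"] * cfg.n_tail + ["low"] * cfg.n_tail,
                                    index=ids)
                    norm = de_mod.tmm_factors(sub)
                    model = de_mod.estimate_dispersions(sub, grp, norm,
                                                        prior_df=cfg.prior_df)
                    de_tables[con.basis] = de_mod.exact_test(
                        sub, con.high_ids, con.low_ids, norm, model)
                cand = ex_mod.directional_overlap(de_tables["CCp"], de_tables["CCe"],
                                                  axis=axis, fdr=cfg.fdr)
                candidates[axis] = cand
                report["stages"].append({
                    "stage": stage, "n_tested": int(filtered.shape[0]),
                    "n_up": len(cand.up), "n_down": len(cand.down),
                    "n_conflicting": len(cand.conflicting),
                })
                if out:
                    for basis, tab in de_tables.items():
                        tab.to_csv(out / f"de_axis{axis}_{basis.lower()}.csv")
                    cand.table.to_csv(out / f"candidates_axis{axis}.csv")

                if onto is not None and ann:
                    stage = f"enrichment_axis{axis}"
                    prop = onto_mod.propagate(ann, onto)
                    background = {g for g in filtered.index if g in prop}
                    enrichments[axis] = {}
                    for direction, genes in (("up", cand.up), ("down", cand.down)):
                        tab = onto_mod.enrich(genes & background, background, prop,
                                              onto, fdr=cfg.fdr,
                                              min_term_size=cfg.min_term_size)
                        enrichments[axis][direction] = tab
                        if out:
                            tab.to_csv(out / f"enrichment_axis{axis}_{direction}.csv",
                                       index=False)

        report["candidates"] = {
            int(axis): {"up": sorted(c.up), "down": sorted(c.down),
                        "conflicting": sorted(c.conflicting)}
            for axis, c in candidates.items()
        }
        if truth is not None:
            report["truth"] = {"planted_up": truth.planted_up,
                               "planted_down": truth.planted_down}
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    if out:
        corr.to_csv(out / "spearman.csv")
        tm.to_csv(out / "traits_transformed.csv")
        wtab.to_csv(out / "wilks.csv")
        loadings.to_csv(out / "loadings.csv", index=False)
        scores.to_csv(out / "scores.csv")
        io_mod.write_phenotypes(pheno, out / "phenotypes.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_jsonable(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
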
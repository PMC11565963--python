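"""Configuration, validation, orchestration and reporting.

The pipeline binds the stages end to end on a synthetic bundle with known
ground truth: simulate -> fitness inference -> population statistics &
matching -> co-occurrence -> enrichment -> summary.  Re-running with the
same config and seeds reproduces outputs; stages whose outputs already
exist are skipped unless an upstream stage re-ran.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import fitness, io, popgen
from .simulate import CompetitionDesign, PopulationSimConfig, simulate_competition, simulate_population

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline", "summarize"]

STAGES = ["simulate", "fitness", "popgen", "enrichment", "summary"]


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end synthetic run.

    Analysis constants follow the standard definitions: a variant is
    "common" when carried by more than ``common_strain_count`` strains, the
    focal set requires non-neutral calls in at least
    ``focal_condition_count`` conditions, and "strong effect" means an
    absolute fitness more than ``strong_effect_multiplier`` times the mean
    absolute fitness.
    """

    outdir: str = "pipeline_out"
    design: CompetitionDesign = field(default_factory=CompetitionDesign)
    population: PopulationSimConfig = field(default_factory=PopulationSimConfig)
    model: fitness.ModelConfig = field(default_factory=fitness.ModelConfig)
    interval_mass: float = 0.95
    n_boot: int = 1000
    common_strain_count: int = 10
    focal_condition_count: int = 2
    strong_effect_multiplier: float = 2.0
    remove_outliers: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "design" in kwargs:
            d = dict(kwargs["design"])
            for key in ("conditions",):
                if key in d:
                    d[key] = tuple(d[key])
            if "s_range" in d:
                d["s_range"] = tuple(d["s_range"])
            kwargs["design"] = CompetitionDesign(**d)
        if "population" in kwargs:
            p = dict(kwargs["population"])
            if "clade_spec" in p:
                p["clade_spec"] = [tuple(c) for c in p["clade_spec"]]
            kwargs["population"] = PopulationSimConfig(**p)
        if "model" in kwargs:
            kwargs["model"] = fitness.ModelConfig(**kwargs["model"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def validate_inputs(
    counts: pd.DataFrame | None = None,
    design_table: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
    tree=None,
) -> list[str]:
    """Cross-file consistency checks; returns an itemized list of failures.

    Checks: each barcode maps to exactly one edit; the design covers every
    barcode in the counts and marks at least one neutral anchor; VCF samples
    are a subset of the metadata strains; tree tips equal the metadata
    strains.
    """
    errors: list[str] = []
    if counts is not None:
        dup = counts.groupby("barcode_id")["edit_id"].nunique()
        for bc in dup[dup > 1].index:
            errors.append(f"barcode {bc} maps to multiple edits")
        if (counts.reads < 0).any():
            errors.append("negative read counts present")
    if counts is not None and design_table is not None:
        known = set(design_table.barcode_id)
        unknown = sorted(set(counts.barcode_id) - known)
        for bc in unknown[:10]:
            errors.append(f"barcode {bc} absent from edit-design table")
        if "is_neutral" in design_table and not design_table.is_neutral.any():
            errors.append("edit-design table marks no neutral anchors")
    if genotypes is not None and meta is not None:
        extra = sorted(set(genotypes.columns) - set(meta.strain_id))
        for s in extra[:10]:
            errors.append(f"VCF sample {s} absent from strain metadata")
    if tree is not None and meta is not None:
        tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        for s in sorted(tips ^ set(meta.strain_id))[:10]:
            errors.append(f"tree tip set and metadata strains differ on {s}")
    return errors


def _stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    design = dataclasses.replace(cfg.design, seed=cfg.seed)
    table, truth = simulate_competition(design)
    io.write_counts(table, out / "counts.tsv")
    io.write_truth(truth, out / "truth.json")
    design_rows = (
        table[["barcode_id", "edit_id"]]
        .drop_duplicates()
        .assign(is_neutral=lambda d: d.edit_id.str.startswith("neutral"))
    )
    io.write_tsv(design_rows, out / "edit_design.tsv")

    pop = dataclasses.replace(cfg.population, seed=cfg.seed + 1)
    G, meta, tree = simulate_population(pop)
    io.write_vcf(G, meta, out / "population.vcf")
    io.write_tsv(meta, out / "strain_metadata.tsv")
    io.write_newick(tree, out / "tree.nwk")
    return {"n_barcodes": int(design_rows.shape[0]), "n_strains": int(meta.shape[0])}


def _stage_fitness(cfg: PipelineConfig, out: Path) -> dict:
    counts = io.read_counts(out / "counts.tsv")
    design_table = io.read_tsv(out / "edit_design.tsv")
    neutral = set(design_table.loc[design_table.is_neutral, "edit_id"])
    errors = validate_inputs(counts=counts, design_table=design_table)
    if errors:
        raise ValueError("input validation failed: " + "; ".join(errors))
    if cfg.remove_outliers:
        counts = fitness.remove_outlier_barcodes(counts, neutral_ids=neutral)
    agg = fitness.aggregate(counts)
    model = dataclasses.replace(cfg.model, seed=cfg.seed, interval_mass=cfg.interval_mass)
    post, mean_fit, diags = fitness.fit_hierarchical(agg, neutral, model, tau=cfg.design.tau)
    post = fitness.classify(post, cfg.interval_mass)
    table = post.summary.merge(post.edit_flags, on="edit_id")
    io.write_tsv(table, out / "fitness.tsv")
    io.write_tsv(mean_fit, out / "mean_fitness.tsv")
    (out / "fitness_diagnostics.json").write_text(json.dumps(diags, indent=1))
    return {"n_edits": int(table.edit_id.nunique())}


def _variant_bridge(fit_table: pd.DataFrame, G: pd.DataFrame, rng: np.random.Generator):
    """Assign population variants to screened edits' classifications.

    The synthetic population and competition are generated independently, so
    the bridge maps edits onto variant ids at random (a stand-in for the
    shared variant identifiers of a real screen); planted beneficial
    variants (ids starting with "ben") are mapped to beneficial edits first
    so that planted enrichment is carried through to the fitness calls.
    """
    flags = fit_table.drop_duplicates("edit_id")
    beneficial = flags.loc[flags.beneficial_ge1.astype(bool), "edit_id"].tolist()
    variants = list(G.index)
    planted = [v for v in variants if v.startswith("ben")]
    rest = [v for v in variants if not v.startswith("ben")]
    mapping = {}
    for v, e in zip(planted, beneficial):
        mapping[v] = e
    pool = [e for e in flags.edit_id if e not in set(mapping.values())]
    rng.shuffle(rest)
    for v, e in zip(rest, pool):
        mapping[v] = e
    return mapping


def _stage_popgen(cfg: PipelineConfig, out: Path) -> dict:
    G_df = io.read_vcf(out / "population.vcf")
    fit_table = io.read_tsv(out / "fitness.tsv")
    G = popgen.GenotypeMatrix(G_df)
    stats_table = popgen.presence_stats(G)
    io.write_tsv(stats_table, out / "variant_stats.tsv")

    rng = np.random.default_rng(cfg.seed + 2)
    mapping = _variant_bridge(fit_table, G_df, rng)
    edit_of = pd.Series(mapping)
    flags = fit_table.drop_duplicates("edit_id").set_index("edit_id")
    mapped = edit_of[edit_of.isin(flags.index)]
    beneficial_variants = [
        v for v, e in mapped.items() if bool(flags.loc[e, "beneficial_ge1"])
    ]
    neutral_variants = [
        v for v, e in mapped.items() if int(flags.loc[e, "n_conditions_non_neutral"]) == 0
    ]
    pairs = popgen.match_controls(beneficial_variants, neutral_variants, G, seed=cfg.seed + 3)
    io.write_tsv(pairs.pairs, out / "matched_pairs.tsv")
    pd.Series(mapping, name="edit_id").rename_axis("variant").reset_index().pipe(
        io.write_tsv, out / "variant_edit_map.tsv"
    )

    result = None
    if len(pairs.pairs) >= 2:
        result = popgen.cooccurrence_test(
            pairs.pairs.focal.tolist(),
            pairs.pairs.control.tolist(),
            G,
            n_boot=cfg.n_boot,
            seed=cfg.seed + 4,
        )
        (out / "cooccurrence.json").write_text(json.dumps(result.__dict__, indent=1))
    return {
        "n_beneficial_variants": len(beneficial_variants),
        "n_matched": int(len(pairs.pairs)),
    }


def _stage_enrichment(cfg: PipelineConfig, out: Path) -> dict:
    G = popgen.GenotypeMatrix(io.read_vcf(out / "population.vcf"))
    meta = io.read_tsv(out / "strain_metadata.tsv")
    pairs_df = io.read_tsv(out / "matched_pairs.tsv")
    pairs = popgen.MatchedPairs(pairs=pairs_df, unmatched=[])
    if len(pairs_df) < 2:
        (out / "enrichment.tsv").write_text("strain_id\tn_beneficial\tn_control\tdiff\n")
        return {"n_pairs": int(len(pairs_df)), "skipped": True}
    res = enr.per_strain_enrichment(pairs_df.focal.tolist(), pairs, G)
    io.write_tsv(res.per_strain, out / "enrichment.tsv")
    comp = enr.group_comparison(res, meta, grouping="clade_class")
    io.write_tsv(comp, out / "group_comparison.tsv")
    sweep = enr.frequency_sweep(pairs_df.focal.tolist(), pairs, G, meta)
    io.write_tsv(sweep, out / "frequency_sweep.tsv")
    try:
        model = enr.ecology_mixed_model(res, meta)
    except ValueError as err:
        model = {"error": str(err)}
    (out / "ecology_model.json").write_text(json.dumps(model, indent=1))
    return {"n_pairs": int(len(pairs_df))}


def summarize(fit_table: pd.DataFrame, variant_stats: pd.DataFrame | None = None,
              common_strain_count: int = 10) -> dict:
    """Deterministic report: classification counts per condition and focal sets."""
    per_cond = (
        fit_table[~fit_table.is_neutral_anchor.astype(bool)]
        .groupby(["condition", "classification"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["beneficial", "deleterious", "neutral"], fill_value=0)
    )
    flags = fit_table.drop_duplicates("edit_id")
    out = {
        "per_condition_counts": {c: per_cond.loc[c].to_dict() for c in per_cond.index},
        "n_edits": int(flags.edit_id.nunique()),
        "n_non_neutral_ge1": int(flags.non_neutral_ge1.astype(bool).sum()),
        "n_non_neutral_ge2": int(flags.non_neutral_ge2.astype(bool).sum()),
        "n_beneficial_ge1": int(flags.beneficial_ge1.astype(bool).sum()),
    }
    if variant_stats is not None and len(variant_stats):
        common = (variant_stats.n_strains > common_strain_count).mean()
        out["fraction_common_variants"] = float(common)
    return out


def _stage_summary(cfg: PipelineConfig, out: Path) -> dict:
    fit_table = io.read_tsv(out / "fitness.tsv")
    variant_stats = io.read_tsv(out / "variant_stats.tsv")
    report = summarize(fit_table, variant_stats, cfg.common_strain_count)
    (out / "summary.json").write_text(json.dumps(report, indent=1))
    return report


_STAGE_FUNCS = {
    "simulate": (_stage_simulate, ["counts.tsv", "truth.json", "edit_design.tsv",
                                   "population.vcf", "strain_metadata.tsv", "tree.nwk"]),
    "fitness": (_stage_fitness, ["fitness.tsv", "mean_fitness.tsv", "fitness_diagnostics.json"]),
    "popgen": (_stage_popgen, ["variant_stats.tsv", "matched_pairs.tsv", "variant_edit_map.tsv"]),
    "enrichment": (_stage_enrichment, ["enrichment.tsv"]),
    "summary": (_stage_summary, ["summary.json"]),
}


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> dict:
    """Run all stages in dependency order and write a run manifest.

    A stage is skipped when all of its outputs already exist and no upstream
    stage re-ran; deleting an intermediate therefore regenerates only that
    stage and everything downstream.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
    }
    upstream_ran = force
    for stage in STAGES:
        func, outputs = _STAGE_FUNCS[stage]
        have_all = all((out / f).exists() for f in outputs)
        if have_all and not upstream_ran:
            manifest["stages"][stage] = {"status": "cached"}
            continue
        logger.info("running stage %s", stage)
        info = func(cfg, out)
        upstream_ran = True
        manifest["stages"][stage] = {"status": "ran", **info}
        for f in outputs:
            if (out / f).exists():
                manifest["outputs"][f] = {"stage": stage, "sha256": _sha256(out / f)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
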
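"""End-to-end validation experiments with known ground truth.

Each function simulates data under the study conditions, runs the package's
own analysis path, and measures how well truth is recovered.  They back both
the acceptance test suite and ``scripts/acceptance.py``; all take an explicit
seed and return plain dicts of scalars.

Study conditions (defaults) follow the screen layout: 300 edited variants
with 10 barcodes each plus 30 non-editing neutral anchors, three replicates,
seven timepoints at tau = 4.3 generations, 5e6 reads per timepoint, and a
1e7-cell transfer bottleneck.  True selection coefficients are a mixture of
a point mass at zero (20%) and Uniform(-0.15, 0.15).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import enrichment as enr
from .fitness import (
    ModelConfig,
    aggregate,
    classify,
    fit_hierarchical,
    remove_outlier_barcodes,
    replicate_concordance,
)
from .popgen import GenotypeMatrix, cooccurrence_test, jaccard, match_controls
from .simulate import (
    CompetitionDesign,
    PopulationSimConfig,
    simulate_competition,
    simulate_population,
    simulate_structure,
)
from .structure import packing_density

__all__ = [
    "STUDY_DESIGN",
    "fitness_recovery",
    "null_calibration",
    "outlier_robustness",
    "jaccard_oracle_check",
    "cooccurrence_calibration",
    "matching_audit",
    "enrichment_null",
    "enrichment_power",
    "sweep_attenuation",
    "mixed_model_recovery",
    "packing_density_check",
]

STUDY_DESIGN = dict(
    n_edits=300,
    barcodes_per_edit=10,
    n_neutral_barcodes=30,
    n_replicates=3,
    conditions=("2D",),
    n_timepoints=7,
    tau=4.3,
    reads_per_timepoint=5_000_000,
    bottleneck_cells=10_000_000,
    p_neutral=0.2,
    s_range=(-0.15, 0.15),
)


def _fit(table, design, remove_outliers=True, seed=0):
    neutral = set(design.neutral_ids)
    if remove_outliers:
        table = remove_outlier_barcodes(table, neutral_ids=neutral)
    agg = aggregate(table)
    post, mean_fit, diags = fit_hierarchical(
        agg, neutral, ModelConfig(seed=seed), tau=design.tau
    )
    return classify(post), mean_fit, diags


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in np.random.SeedSequence(seed).spawn(n)]


def fitness_recovery(seed: int = 0, n_screens: int = 2, **overrides) -> dict:
    """Simulate the study design and measure parameter recovery.

    Reports the Pearson correlation and RMSE between true selection
    coefficients and posterior-mean hyperfitness, empirical coverage of the
    95% credible interval, the correlation of the inferred mean-fitness
    series with its simulated truth, and the mean between-replicate Spearman
    correlation of non-neutral fitness estimates.  Quantities are pooled
    over ``n_screens`` independently simulated screens: the mean-fitness
    nuisance level is identified only through the 30 anchor lineages, so the
    error it induces is shared by every edit of a screen and averaging over
    screens is the appropriate estimator of coverage.
    """
    errors, sds, s_all, est_all, mf_r, conc_r = [], [], [], [], [], []
    for s_i in _spawn_seeds(seed, n_screens):
        design = CompetitionDesign(**{**STUDY_DESIGN, **overrides}, seed=s_i)
        table, truth = simulate_competition(design)
        post, mean_fit, _ = _fit(table, design, seed=s_i)
        cond = design.conditions[0]
        s_true = truth.s_vector(cond, design.edit_ids)
        ss = post.summary.set_index("edit_id")
        est = ss.loc[design.edit_ids, "phi_mean"].to_numpy()
        sd = ss.loc[design.edit_ids, "phi_sd"].to_numpy()
        errors.append(s_true - est)
        sds.append(sd)
        s_all.append(s_true)
        est_all.append(est)
        m = mean_fit.merge(truth.true_mean_fitness, on=["replicate", "condition", "timepoint"])
        mf_r.append(np.corrcoef(m.mean_fitness_x, m.mean_fitness_y)[0, 1])
        conc_r.append(replicate_concordance(post).spearman_rho.mean())
    errors = np.concatenate(errors)
    sds = np.concatenate(sds)
    z = stats.norm.ppf(0.975)
    return {
        "n_edits": len(errors),
        "pearson_r": float(np.corrcoef(np.concatenate(s_all), np.concatenate(est_all))[0, 1]),
        "rmse": float(np.sqrt(np.mean(errors**2))),
        "coverage_95": float(np.mean(np.abs(errors) <= z * sds)),
        "mean_fitness_pearson_r": float(np.mean(mf_r)),
        "replicate_spearman_mean": float(np.mean(conc_r)),
    }


def null_calibration(seed: int = 0, n_screens: int = 5, **overrides) -> dict:
    """All-neutral simulations: fraction of edits called non-neutral at 95%.

    The false-call rate is pooled over ``n_screens`` independent screens
    because the anchor-identified mean-fitness level makes classification
    errors correlated within a screen; a single screen's rate is a noisy
    estimate of the method's false-positive rate.
    """
    n_flagged = 0
    n_total = 0
    for s_i in _spawn_seeds(seed, n_screens):
        design = CompetitionDesign(**{**STUDY_DESIGN, **overrides}, seed=s_i)
        table, _ = simulate_competition(design, true_s={e: 0.0 for e in design.edit_ids})
        post, _, _ = _fit(table, design, seed=s_i)
        sub = post.summary[~post.summary.is_neutral_anchor]
        n_flagged += int((sub.classification != "neutral").sum())
        n_total += len(sub)
    return {
        "n_edits": n_total,
        "fraction_non_neutral": n_flagged / n_total,
    }


def outlier_robustness(seed: int = 0, rate: float = 0.05, effect: float = 0.1, **overrides) -> dict:
    """Hitchhiker-barcode stress test: bias with vs without top-barcode removal.

    A fraction ``rate`` of edits carries one barcode with an extra fitness
    ``effect``.  Reports the median absolute estimation error on affected
    edits when the highest-count barcode is removed versus retained, and the
    achieved reduction.
    """
    design = CompetitionDesign(
        **{**STUDY_DESIGN, **overrides}, outlier_rate=rate, outlier_effect=effect, seed=seed
    )
    table, truth = simulate_competition(design)
    cond = design.conditions[0]
    affected = sorted({b.rsplit(".", 1)[0] for b in truth.outlier_barcodes})
    results = {}
    for label, remove in (("with_removal", True), ("without_removal", False)):
        post, _, _ = _fit(table, design, remove_outliers=remove, seed=seed)
        ss = post.summary.set_index("edit_id")
        bias = ss.loc[affected, "phi_mean"].to_numpy() - truth.s_vector(cond, affected)
        results[label] = float(np.median(np.abs(bias)))
    results["n_affected"] = len(affected)
    results["bias_reduction"] = 1.0 - results["with_removal"] / results["without_removal"]
    return results


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------


def _unstructured_matrix(rng, n_variants, n_strains, mean_extra_carriers=3.0):
    """Exchangeable placement: carrier count ~ 1 + Poisson, strains uniform."""
    M = np.zeros((n_variants, n_strains), dtype=np.int8)
    for i in range(n_variants):
        k = min(1 + rng.poisson(mean_extra_carriers), n_strains)
        M[i, rng.choice(n_strains, size=k, replace=False)] = 2
    return M


def jaccard_oracle_check(seed: int = 0, n_pairs: int = 1000) -> dict:
    """Exact agreement of the Jaccard routine with direct set arithmetic."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_pairs):
        a = frozenset(rng.choice(30, size=rng.integers(1, 12), replace=False).tolist())
        b = frozenset(rng.choice(30, size=rng.integers(1, 12), replace=False).tolist())
        expected = len(a & b) / len(a | b)
        agree += jaccard(a, b) == expected
    return {"n_pairs": n_pairs, "agreement": agree / n_pairs}


def cooccurrence_calibration(
    seed: int = 0, n_datasets: int = 200, set_size: int = 20, n_strains: int = 80,
    n_boot: int = 1000, alpha: float = 0.05,
) -> dict:
    """Type-I error of the co-occurrence test under the exchangeable null.

    Both variant sets are drawn from the same placement process, so the test
    should reject at ~alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_datasets):
        M = _unstructured_matrix(rng, 2 * set_size, n_strains)
        ids = [f"x{i}" for i in range(set_size)] + [f"y{i}" for i in range(set_size)]
        G = GenotypeMatrix(pd.DataFrame(M, index=ids, columns=[f"s{j}" for j in range(n_strains)]))
        res = cooccurrence_test(
            ids[:set_size], ids[set_size:], G, n_boot=n_boot, seed=int(rng.integers(2**31))
        )
        rejections += res.p_value < alpha
    return {"n_datasets": n_datasets, "rejection_rate": rejections / n_datasets}


def matching_audit(
    seed: int = 0, n_matrices: int = 50, n_focal: int = 20, n_candidates: int = 200,
    n_strains: int = 60,
) -> dict:
    """Step-wise exhaustive audit of greedy frequency matching.

    Replays the greedy order on independent random matrices and verifies, by
    scanning every still-unmatched candidate, that each chosen control
    minimizes |allele-frequency difference| with the Jaccard tie-break, and
    that no control is reused.
    """
    rng = np.random.default_rng(seed)
    n_checked = 0
    n_optimal = 0
    af_diffs = []
    for m in range(n_matrices):
        M = _unstructured_matrix(rng, n_focal + n_candidates, n_strains)
        ids = [f"v{i:04d}" for i in range(n_focal + n_candidates)]
        G = GenotypeMatrix(pd.DataFrame(M, index=ids, columns=[f"s{j}" for j in range(n_strains)]))
        focal, candidates = ids[:n_focal], ids[n_focal:]
        pairs = match_controls(focal, candidates, G, seed=int(rng.integers(2**31)))
        af = dict(zip(ids, G.allele_frequency(ids)))
        sets = {v: G.presence_set(v) for v in ids}
        chosen = pairs.pairs.set_index("focal")["control"]
        assert chosen.is_unique
        used: set = set()
        for f in sorted(focal, key=lambda v: (-af[v], str(v))):
            c = chosen[f]
            remaining = [x for x in candidates if x not in used]
            best_d = min(abs(af[x] - af[f]) for x in remaining)
            tied = [x for x in remaining if abs(af[x] - af[f]) == best_d]
            best_j = min(jaccard(sets[x], sets[f]) for x in tied)
            ok = (
                abs(af[c] - af[f]) == best_d
                and abs(jaccard(sets[c], sets[f]) - best_j) < 1e-12
            )
            n_checked += 1
            n_optimal += ok
            used.add(c)
            af_diffs.append(abs(af[c] - af[f]))
    return {
        "n_selections": n_checked,
        "optimal_fraction": n_optimal / n_checked,
        "mean_abs_af_diff": float(np.mean(af_diffs)),
    }


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

_CLADE_LABELS = (
    ["dom1"] * 25 + ["dom2"] * 20 + ["dom3"] * 15
    + ["wild1"] * 10 + ["wild2"] * 10 + ["wild3"] * 10 + ["other1"] * 30
)
_CLASS_LABELS = ["domesticated"] * 60 + ["wild"] * 30 + ["other"] * 30


def _flat_meta(n_strains=120):
    return pd.DataFrame(
        {
            "strain_id": [f"s{i}" for i in range(n_strains)],
            "clade": _CLADE_LABELS,
            "clade_class": _CLASS_LABELS,
            "ecology_class": "natural",
            "ploidy": 2,
        }
    )


def _dom_vs_wild_p(res, meta):
    comp = enr.group_comparison(res, meta)
    dw = comp[(comp.group_a == "domesticated") & (comp.group_b == "wild")]
    return float(dw.p_value.iloc[0])


def enrichment_null(seed: int = 0, n_runs: int = 100, alpha: float = 0.05) -> dict:
    """Exchangeable focal/control sets: per-strain diff ~ 0, test rejects at ~alpha.

    Uses unstructured variant placement so per-strain diffs are independent;
    with clade-structured placement the strain-level rank test is
    anti-conservative because presence sets are clades (within-clade
    correlation), which is why the analysis also carries a clade
    random-intercept model.
    """
    rng = np.random.default_rng(seed)
    meta = _flat_meta()
    rejections = 0
    mean_diffs = []
    for r in range(n_runs):
        M = _unstructured_matrix(rng, 400, 120)
        ids = [f"v{i}" for i in range(400)]
        G = GenotypeMatrix(pd.DataFrame(M, index=ids, columns=meta.strain_id))
        order = rng.permutation(400)
        focal = [ids[i] for i in order[:40]]
        pool = [ids[i] for i in order[40:]]
        pairs = match_controls(focal, pool, G, seed=int(rng.integers(2**31)))
        res = enr.per_strain_enrichment(focal, pairs, G)
        mean_diffs.append(res.per_strain["diff"].mean())
        rejections += _dom_vs_wild_p(res, meta) < alpha
    return {
        "n_runs": n_runs,
        "mean_diff": float(np.mean(mean_diffs)),
        "se_mean_diff": float(np.std(mean_diffs) / np.sqrt(n_runs)),
        "rejection_rate": rejections / n_runs,
    }


def _planted_population(seed, planted=40, bias=1.0):
    cfg = PopulationSimConfig(seed=seed, planted_beneficial=planted, bias_strength=bias)
    G_df, meta, _ = simulate_population(cfg)
    G = GenotypeMatrix(G_df)
    focal = [v for v in G.variants if v.startswith("ben")]
    pool = [v for v in G.variants if not v.startswith("ben")]
    pairs = match_controls(focal, pool, G, seed=seed + 1)
    return G, meta, focal, pairs


def enrichment_power(seed: int = 0, n_runs: int = 100, alpha: float = 0.05) -> dict:
    """Detection rate of domestication-exclusive planted beneficial variants.

    The planted effect mirrors the near-exclusive domestication bias of
    common beneficial variants in real panels (bias strength 1.0, 40 planted
    variants among 600).
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for r in range(n_runs):
        G, meta, focal, pairs = _planted_population(int(rng.integers(2**31 - 2)))
        res = enr.per_strain_enrichment(focal, pairs, G)
        rejections += _dom_vs_wild_p(res, meta) < alpha
    return {"n_runs": n_runs, "power": rejections / n_runs}


def sweep_attenuation(seed: int = 0, n_runs: int = 10) -> dict:
    """Frequency sweep on planted populations: signal fades as the threshold drops.

    Planted enrichment is carried by common (clade-level) variants, so the
    domesticated-strain mean diff should shrink as common variants are
    removed.  Reports the mean ratio of the lowest-threshold to the
    highest-threshold group difference and the mean Spearman correlation of
    threshold vs difference.
    """
    rng = np.random.default_rng(seed)
    ratios, spearmans = [], []
    for r in range(n_runs):
        G, meta, focal, pairs = _planted_population(int(rng.integers(2**31 - 2)))
        sweep = enr.frequency_sweep(focal, pairs, G, meta)
        ok = sweep[~sweep.flagged.astype(bool)].dropna(subset=["mean_diff_domesticated"])
        if len(ok) < 3:
            continue
        first = float(ok.mean_diff_domesticated.iloc[0])
        last = float(ok.mean_diff_domesticated.iloc[-1])
        ratios.append(last / first if first != 0 else np.nan)
        spearmans.append(
            stats.spearmanr(ok.threshold, ok.mean_diff_domesticated).statistic
        )
    return {
        "n_runs": len(ratios),
        "mean_attenuation_ratio": float(np.nanmean(ratios)),
        "mean_threshold_spearman": float(np.nanmean(spearmans)),
    }


def mixed_model_recovery(
    seed: int = 0, n_runs: int = 100, beta: float = 0.9, clade_sd: float = 0.5,
    n_clades: int = 8, n_per_clade: int = 12,
) -> dict:
    """Recovery of a planted industrial-vs-natural fixed effect under REML.

    Per-strain diffs are beta * industrial + clade intercept (SD
    ``clade_sd``) + unit Gaussian noise.  Reports the fraction of runs whose
    estimate falls within 2 SE of truth and the mean estimate.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    estimates = []
    for run in range(n_runs):
        rows = []
        for c in range(n_clades):
            u = rng.normal(0, clade_sd)
            for s in range(n_per_clade):
                ind = s < n_per_clade // 2
                rows.append(
                    (f"c{c}_s{s}", f"c{c}", "domesticated",
                     "industrial" if ind else "natural", 2,
                     beta * ind + u + rng.normal(0, 1))
                )
        meta = pd.DataFrame(
            rows, columns=["strain_id", "clade", "clade_class", "ecology_class", "ploidy", "diff"]
        )
        res = enr.EnrichmentResult(
            per_strain=meta[["strain_id", "diff"]].assign(n_beneficial=0, n_control=0),
            n_focal=0, n_control=0,
        )
        out = enr.ecology_mixed_model(res, meta.drop(columns="diff"))
        estimates.append(out["estimate"])
        hits += abs(out["estimate"] - beta) <= 2 * out["se"]
    return {
        "n_runs": n_runs,
        "within_2se_fraction": hits / n_runs,
        "mean_estimate": float(np.mean(estimates)),
        "true_beta": beta,
    }


def packing_density_check(seed: int = 0, n_residues: int = 200) -> dict:
    """Packing density vs the quadratic definition, plus rigid-motion invariance."""
    coords = simulate_structure(n_residues, seed=seed)
    out = packing_density(coords, radius=10.0)
    xyz = coords[["x", "y", "z"]].to_numpy()
    D = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
    brute = (D <= 10.0).sum(axis=1) - 1
    agree = float((out.packing_density.to_numpy() == brute).mean())
    rng = np.random.default_rng(seed + 1)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    moved = coords.copy()
    moved[["x", "y", "z"]] = xyz @ q.T + rng.uniform(-50, 50, 3)
    invariant = bool(
        (packing_density(moved).packing_density.to_numpy() == out.packing_density.to_numpy()).all()
    )
    return {"n_residues": n_residues, "brute_force_agreement": agree, "rigid_invariant": invariant}
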
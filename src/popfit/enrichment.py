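"""Per-strain enrichment of beneficial variants relative to matched controls.

The enrichment statistic for a strain is N_beneficial - N_control: the number
of focal-set variants it carries minus the number of frequency-matched
control variants it carries.  Because controls are matched to the focal set's
allele-frequency distribution, the expectation is ~0 for every strain unless
focal variants are concentrated in particular lineages.  Group structure
(domesticated/wild/other clades; industrial/natural ecology) is tested with
Wilcoxon rank-sum comparisons, an allele-frequency threshold sweep, and a
linear mixed model with clade random intercepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import GenotypeMatrix, MatchedPairs

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "per_strain_enrichment",
    "group_comparison",
    "frequency_sweep",
    "ecology_mixed_model",
]


@dataclass
class EnrichmentResult:
    """Per-strain focal/control carriage counts and their difference."""

    per_strain: pd.DataFrame  # strain_id, n_beneficial, n_control, diff
    n_focal: int
    n_control: int

    def with_metadata(self, meta: pd.DataFrame) -> pd.DataFrame:
        return self.per_strain.merge(meta, on="strain_id", how="left")


def per_strain_enrichment(
    focal, pairs: MatchedPairs, G: GenotypeMatrix
) -> EnrichmentResult:
    """Count focal and matched-control variants carried by each strain.

    Focal variants without a matched control are excluded (with a log entry)
    so the two counted sets have equal size.
    """
    focal = list(focal)
    matched = set(pairs.pairs.focal)
    use_focal = [v for v in focal if v in matched]
    skipped = len(focal) - len(use_focal)
    if skipped:
        logger.warning("excluding %d unmatched focal variants from enrichment", skipped)
    controls = pairs.pairs.set_index("focal").loc[use_focal, "control"].tolist()
    nb = G.presence_matrix(use_focal).sum(axis=0)
    nc = G.presence_matrix(controls).sum(axis=0)
    df = pd.DataFrame(
        {
            "strain_id": G.strains,
            "n_beneficial": nb.astype(int),
            "n_control": nc.astype(int),
            "diff": (nb - nc).astype(int),
        }
    )
    return EnrichmentResult(per_strain=df, n_focal=len(use_focal), n_control=len(controls))


def group_comparison(
    res: EnrichmentResult,
    meta: pd.DataFrame,
    grouping: str = "clade_class",
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of per-strain diff between groups.

    Groups below ``min_group_size`` strains are flagged and skipped.  Uses
    the exact null distribution for small samples without ties and the
    tie-corrected normal approximation otherwise (scipy's policy).
    """
    df = res.with_metadata(meta)
    if grouping not in df:
        raise ValueError(f"grouping column {grouping!r} missing from metadata")
    groups = {g: sub["diff"].to_numpy(dtype=float) for g, sub in df.groupby(grouping, observed=True)}
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(groups[a]) < min_group_size or len(groups[b]) < min_group_size:
                logger.warning("group comparison %s vs %s skipped: group too small", a, b)
                rows.append((a, b, len(groups[a]), len(groups[b]), np.nan, np.nan, np.nan, np.nan, True))
                continue
            r = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided", method="auto")
            rows.append(
                (
                    a,
                    b,
                    len(groups[a]),
                    len(groups[b]),
                    float(np.median(groups[a])),
                    float(np.median(groups[b])),
                    float(r.statistic),
                    float(r.pvalue),
                    False,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group_a",
            "group_b",
            "n_a",
            "n_b",
            "median_a",
            "median_b",
            "statistic",
            "p_value",
            "skipped",
        ],
    )


def frequency_sweep(
    focal,
    pairs: MatchedPairs,
    G: GenotypeMatrix,
    meta: pd.DataFrame,
    thresholds=None,
    grouping: str = "clade_class",
) -> pd.DataFrame:
    """Re-test group enrichment while iteratively removing common variants.

    At each carrier-count threshold, focal/control variants present in more
    strains than the threshold are dropped (pairs are kept fixed — no
    re-matching) and per-strain enrichment plus the group comparison are
    recomputed.  Thresholds default to the carrier counts observed among the
    matched focal variants, traversed in decreasing order, which makes the
    retained variant sets nested.
    """
    matched = pairs.pairs[pairs.pairs.focal.isin(set(focal))]
    counts_f = pd.Series(G.carrier_counts(matched.focal.tolist()), index=matched.focal)
    counts_c = pd.Series(G.carrier_counts(matched.control.tolist()), index=matched.control)
    if thresholds is None:
        thresholds = sorted(set(counts_f.to_numpy()), reverse=True)
    else:
        thresholds = sorted(set(int(t) for t in thresholds), reverse=True)
    rows = []
    for th in thresholds:
        keep = matched[
            (counts_f.loc[matched.focal].to_numpy() <= th)
            & (counts_c.loc[matched.control].to_numpy() <= th)
        ]
        if len(keep) < 2:
            rows.append({"threshold": th, "n_variants": len(keep), "flagged": True})
            continue
        sub_pairs = MatchedPairs(pairs=keep.reset_index(drop=True), unmatched=[])
        res = per_strain_enrichment(keep.focal.tolist(), sub_pairs, G)
        comp = group_comparison(res, meta, grouping=grouping)
        dom_wild = comp[
            ((comp.group_a == "domesticated") & (comp.group_b == "wild"))
            | ((comp.group_a == "wild") & (comp.group_b == "domesticated"))
        ]
        by_group = res.with_metadata(meta).groupby(grouping, observed=True)["diff"].mean()
        row = {
            "threshold": th,
            "n_variants": int(len(keep)),
            "flagged": False,
            "p_dom_vs_wild": float(dom_wild.p_value.iloc[0]) if len(dom_wild) else np.nan,
        }
        for g, m in by_group.items():
            row[f"mean_diff_{g}"] = float(m)
        rows.append(row)
    return pd.DataFrame(rows)


def ecology_mixed_model(
    res: EnrichmentResult, meta: pd.DataFrame, reml: bool = True
) -> dict:
    """Linear mixed model: per-strain diff ~ ecology + (1 | clade).

    Fixed effect: industrial vs natural ecological origin (strains with
    ecology "other" are excluded); random intercept per clade; fitted by
    REML.  Reports the fixed-effect estimate, its standard error, and a Wald
    z p-value (the p-value method is recorded in the output).  A singular
    random-effect fit falls back to ordinary least squares with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = res.with_metadata(meta)
    df = df[df.ecology_class.isin(["industrial", "natural"])].copy()
    if df.clade.nunique() < 2 or df.ecology_class.nunique() < 2:
        raise ValueError("need >= 2 ecology classes present across >= 2 clades")
    df["industrial"] = (df.ecology_class == "industrial").astype(float)

    out: dict = {"formula": "diff ~ industrial + (1 | clade)", "n_strains": int(len(df))}
    import warnings as _warnings

    try:
        with _warnings.catch_warnings(), np.errstate(all="ignore"):
            _warnings.simplefilter("ignore")
            model = smf.mixedlm("diff ~ industrial", df, groups=df["clade"])
            fit = model.fit(reml=reml)
        singular = not np.isfinite(fit.bse["industrial"])
    except Exception as err:  # singular/non-converging random effects
        logger.warning("mixed model failed (%s); falling back to OLS", err)
        fit, singular = None, True
    if fit is not None and not singular:
        est = float(fit.params["industrial"])
        se = float(fit.bse["industrial"])
        z = est / se
        out.update(
            estimate=est,
            se=se,
            p_value=float(2 * stats.norm.sf(abs(z))),
            clade_intercept_sd=float(np.sqrt(fit.cov_re.iloc[0, 0])),
            method="mixedlm_reml_wald_z",
            singular=False,
        )
        return out
    ols = sm.OLS(df["diff"], sm.add_constant(df["industrial"])).fit()
    out.update(
        estimate=float(ols.params["industrial"]),
        se=float(ols.bse["industrial"]),
        p_value=float(ols.pvalues["industrial"]),
        clade_intercept_sd=0.0,
        method="ols_fallback",
        singular=True,
    )
    logger.warning("random-effect fit singular; reporting fixed-effects-only fallback")
    return out
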
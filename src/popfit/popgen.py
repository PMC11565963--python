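"""Population-genetic statistics on a variant × strain genotype matrix.

Covers presence/frequency summaries, frequency-matched neutral controls,
Jaccard co-occurrence bootstrap tests, singleton counts as a strain-age
proxy, and binary-trait parsimony statistics on a rooted tree.

Allele frequency throughout is the carrier-strain fraction (number of
strains in which the variant is present divided by the number of strains),
since every downstream threshold rule operates on strain counts; allele
dosage frequency is available via ``mode="dosage"`` in
:func:`presence_stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "MatchedPairs",
    "CooccurrenceResult",
    "presence_stats",
    "jaccard",
    "mean_pairwise_jaccard",
    "match_controls",
    "cooccurrence_test",
    "singletons_per_strain",
    "strain_age_comparison",
    "fitch_parsimony",
    "retention_index",
]


class GenotypeMatrix:
    """Variant × strain genotype matrix with values 0 = absent, 1 = het, 2 = hom.

    Haploid strains use {0, 2} (present counts as non-heterozygous).  Wraps a
    pandas DataFrame (variants as rows, strains as columns) and exposes
    presence sets and carrier-fraction allele frequencies.
    """

    def __init__(self, df: pd.DataFrame):
        if df.empty:
            raise ValueError("genotype matrix is empty")
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1, 2)).all():
            raise ValueError("genotype values must be 0 (absent), 1 (het) or 2 (hom)")
        self.df = df
        self._presence = df.to_numpy() > 0

    @property
    def variants(self) -> list:
        return list(self.df.index)

    @property
    def strains(self) -> list:
        return list(self.df.columns)

    @property
    def n_strains(self) -> int:
        return self.df.shape[1]

    def presence_matrix(self, variants=None) -> np.ndarray:
        if variants is None:
            return self._presence
        idx = self.df.index.get_indexer(list(variants))
        if (idx < 0).any():
            missing = [v for v, i in zip(variants, idx) if i < 0]
            raise KeyError(f"variants not in matrix: {missing[:5]}")
        return self._presence[idx]

    def presence_set(self, variant) -> frozenset:
        row = self.df.loc[variant]
        return frozenset(row.index[row.to_numpy() > 0])

    def carrier_counts(self, variants=None) -> np.ndarray:
        return self.presence_matrix(variants).sum(axis=1)

    def allele_frequency(self, variants=None) -> np.ndarray:
        return self.carrier_counts(variants) / self.n_strains


@dataclass
class MatchedPairs:
    """Frequency-matched focal/control variant pairs (controls unique)."""

    pairs: pd.DataFrame  # columns: focal, control, abs_af_diff, pair_jaccard
    unmatched: list

    @property
    def controls(self) -> list:
        return list(self.pairs.control)


@dataclass
class CooccurrenceResult:
    mean_jaccard_focal: float
    mean_jaccard_control: float
    difference: float
    ratio: float
    p_value: float
    n_boot: int
    seed: int


def presence_stats(G: GenotypeMatrix, mode: str = "carrier") -> pd.DataFrame:
    """Per-variant allele frequency, carrier count, singleton and het fraction.

    Variants absent from every strain are excluded and logged.  ``mode``
    selects carrier-strain fraction (default) or allele-dosage frequency
    (dosage sums genotype values over 2x the strain count).
    """
    if mode not in ("carrier", "dosage"):
        raise ValueError("mode must be 'carrier' or 'dosage'")
    vals = G.df.to_numpy()
    carriers = (vals > 0).sum(axis=1)
    dead = carriers == 0
    if dead.any():
        logger.warning("excluding %d variants absent from all strains", int(dead.sum()))
    het = (vals == 1).sum(axis=1)
    if mode == "carrier":
        af = carriers / G.n_strains
    else:
        af = vals.sum(axis=1) / (2.0 * G.n_strains)
    out = pd.DataFrame(
        {
            "variant": G.variants,
            "allele_frequency": af,
            "n_strains": carriers,
            "is_singleton": carriers == 1,
            "het_fraction": np.divide(
                het, carriers, out=np.full(len(carriers), np.nan), where=carriers > 0
            ),
        }
    )
    return out[~dead].reset_index(drop=True)


def jaccard(A, B) -> float:
    """Jaccard similarity |A ∩ B| / |A ∪ B| of two carrier-strain sets."""
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("Jaccard similarity is undefined for empty sets")
    return len(A & B) / len(A | B)


def _pairwise_jaccard_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard among the rows of a boolean presence matrix."""
    Xf = X.astype(float)
    inter = Xf @ Xf.T
    sizes = Xf.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, inter / union, np.nan)


def mean_pairwise_jaccard(X: np.ndarray) -> float:
    """Mean Jaccard over all unordered pairs of rows of a presence matrix."""
    if X.shape[0] < 2:
        raise ValueError("need >= 2 variants")
    J = _pairwise_jaccard_matrix(X)
    iu = np.triu_indices(X.shape[0], k=1)
    return float(np.nanmean(J[iu]))


def match_controls(
    focal, candidates, G: GenotypeMatrix, seed: int = 0
) -> MatchedPairs:
    """Greedily match each focal variant to a unique frequency-matched control.

    Focal variants are processed in descending allele frequency (ties by
    variant id).  For each, the unmatched candidate with the smallest
    |allele frequency difference| is chosen; ties are broken by minimal
    Jaccard similarity to the focal variant (to avoid pairing linked
    variants with identical phylogenetic distributions), and residual ties
    uniformly at random under ``seed``.  Exhausted pools leave focal
    variants explicitly unmatched.
    """
    focal = list(focal)
    candidates = list(candidates)
    if set(focal) & set(candidates):
        raise ValueError("candidate pool must be disjoint from the focal set")
    rng = np.random.default_rng(seed)
    af_f = G.allele_frequency(focal)
    af_c = G.allele_frequency(candidates)
    Pf = G.presence_matrix(focal).astype(float)
    Pc = G.presence_matrix(candidates).astype(float)
    order = sorted(range(len(focal)), key=lambda i: (-af_f[i], str(focal[i])))

    available = np.ones(len(candidates), dtype=bool)
    rows, unmatched = [], []
    for i in order:
        if not available.any():
            unmatched.append(focal[i])
            continue
        d = np.abs(af_c - af_f[i])
        d[~available] = np.inf
        best = d.min()
        tied = np.flatnonzero(d == best)
        if len(tied) > 1:
            inter = Pc[tied] @ Pf[i]
            union = Pc[tied].sum(axis=1) + Pf[i].sum() - inter
            jac = np.where(union > 0, inter / union, np.nan)
            tied = tied[jac == np.nanmin(jac)]
        j = int(tied[0]) if len(tied) == 1 else int(rng.choice(tied))
        available[j] = False
        inter = float(Pc[j] @ Pf[i])
        union = float(Pc[j].sum() + Pf[i].sum() - inter)
        rows.append((focal[i], candidates[j], float(abs(af_c[j] - af_f[i])), inter / union))
    if unmatched:
        logger.warning("%d focal variants left unmatched", len(unmatched))
    return MatchedPairs(
        pairs=pd.DataFrame(rows, columns=["focal", "control", "abs_af_diff", "pair_jaccard"]),
        unmatched=unmatched,
    )


def cooccurrence_test(
    setX,
    setY,
    G: GenotypeMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> CooccurrenceResult:
    """Resampling test comparing mean pairwise Jaccard within two variant sets.

    Statistic: mean pairwise Jaccard within ``setX`` minus within ``setY``
    (the ratio is also reported).  The default ``permutation`` method builds
    the null by randomly re-assigning the pooled variants to the two set
    labels ``n_boot`` times, which is exactly calibrated under the
    exchangeable null.  ``method="bootstrap"`` instead resamples variants
    with replacement within each set (pairs formed by the same resampled
    variant are excluded); note that for sparse presence sets the pairwise
    kernel is nearly degenerate, for which the naive bootstrap is known to
    overestimate the sampling variance and hence to be conservative.
    Two-sided p in both cases.
    """
    if method not in ("permutation", "bootstrap"):
        raise ValueError("method must be 'permutation' or 'bootstrap'")
    X = G.presence_matrix(setX)
    Y = G.presence_matrix(setY)
    nx, ny = X.shape[0], Y.shape[0]
    if nx < 2 or ny < 2:
        raise ValueError("each set needs >= 2 variants")
    JX = _pairwise_jaccard_matrix(X)
    JY = _pairwise_jaccard_matrix(Y)
    if np.isnan(JX[np.triu_indices(nx, 1)]).all() or np.isnan(
        JY[np.triu_indices(ny, 1)]
    ).all():
        raise ValueError("degenerate sets: all pairwise Jaccard values undefined")
    mx = float(np.nanmean(JX[np.triu_indices(nx, 1)]))
    my = float(np.nanmean(JY[np.triu_indices(ny, 1)]))
    obs = mx - my

    rng = np.random.default_rng(seed)
    if method == "permutation":
        J = _pairwise_jaccard_matrix(np.vstack([X, Y]))
        iu_x = np.triu_indices(nx, 1)
        iu_y = np.triu_indices(ny, 1)
        count = 0
        n_eff = 0
        for _ in range(n_boot):
            perm = rng.permutation(nx + ny)
            ix, iy = perm[:nx], perm[nx:]
            dx = np.nanmean(J[np.ix_(ix, ix)][iu_x])
            dy = np.nanmean(J[np.ix_(iy, iy)][iu_y])
            d = dx - dy
            if np.isfinite(d):
                n_eff += 1
                if abs(d) >= abs(obs) - 1e-15:
                    count += 1
        p = (count + 1) / (n_eff + 1)
    else:

        def boot_means(J: np.ndarray, n: int) -> np.ndarray:
            out = np.empty(n_boot)
            iu = np.triu_indices(n, k=1)
            for b in range(n_boot):
                idx = rng.integers(n, size=n)
                vals = J[np.ix_(idx, idx)][iu]
                keep = (idx[:, None] != idx[None, :])[iu] & np.isfinite(vals)
                out[b] = vals[keep].mean() if keep.any() else np.nan
            return out

        diff = boot_means(JX, nx) - boot_means(JY, ny)
        diff = diff[np.isfinite(diff)]
        p_lo = (np.sum(diff <= 0) + 1) / (len(diff) + 1)
        p_hi = (np.sum(diff >= 0) + 1) / (len(diff) + 1)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    return CooccurrenceResult(
        mean_jaccard_focal=mx,
        mean_jaccard_control=my,
        difference=obs,
        ratio=mx / my if my > 0 else np.inf,
        p_value=float(p),
        n_boot=n_boot,
        seed=seed,
    )


def singletons_per_strain(G: GenotypeMatrix) -> pd.Series:
    """Number of singleton variants carried by each strain (strain-age proxy)."""
    P = G.presence_matrix()
    singleton = P.sum(axis=1) == 1
    counts = P[singleton].sum(axis=0)
    return pd.Series(counts, index=G.strains, name="n_singletons")


def strain_age_comparison(
    variantsA,
    variantsB,
    G: GenotypeMatrix,
    meta: pd.DataFrame | None = None,
    ploidy: int | None = None,
) -> dict:
    """Rank-sum comparison of carrier-strain singleton counts for two sets.

    Both sets must contain only singleton variants, so each variant has one
    carrier strain whose total singleton count proxies its age (terminal
    branch length).  Optionally restricts to strains of a given ploidy when
    ``meta`` (with strain_id/ploidy) is supplied.
    """
    n_singles = singletons_per_strain(G)

    def carrier_ages(vs) -> np.ndarray:
        P = G.presence_matrix(vs)
        counts = P.sum(axis=1)
        if (counts != 1).any():
            raise ValueError("strain_age_comparison requires singleton variants only")
        strains = [G.strains[int(np.flatnonzero(row)[0])] for row in P]
        if ploidy is not None:
            if meta is None:
                raise ValueError("ploidy stratification requires strain metadata")
            pl = meta.set_index("strain_id")["ploidy"]
            strains = [s for s in strains if pl[s] == ploidy]
        if not strains:
            raise ValueError("no carrier strains after filtering")
        return n_singles[strains].to_numpy(dtype=float)

    a = carrier_ages(variantsA)
    b = carrier_ages(variantsB)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {
        "n_a": len(a),
        "n_b": len(b),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }


# ---------------------------------------------------------------------------
# binary-trait tree statistics
# ---------------------------------------------------------------------------


def _fitch_sets(tree: dendropy.Tree, trait: dict) -> int:
    """Bottom-up small-parsimony pass (Hartigan); exact for polytomies too.

    Each node keeps the set of states attained by the maximum number of
    children's optimal sets; the added cost at a node is (number of children
    minus that maximum).  On binary trees this reduces to the classic Fitch
    union/intersection count.
    """
    changes = 0
    state: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in trait:
                raise ValueError(f"tip {label!r} has no trait value")
            state[id(node)] = frozenset([int(trait[label])])
        else:
            sets = [state[id(c)] for c in node.child_nodes()]
            counts = {st: sum(st in s for s in sets) for st in (0, 1)}
            k = max(counts.values())
            state[id(node)] = frozenset(st for st, c in counts.items() if c == k)
            changes += len(sets) - k
    return changes


def fitch_parsimony(tree: dendropy.Tree, trait: dict) -> int:
    """Minimum number of state changes of a binary trait on a rooted tree.

    ``trait`` maps tip label -> 0/1.  Polytomies are resolved implicitly by
    counting one change per union event (the standard Fitch generalization).
    """
    vals = set(int(v) for v in trait.values())
    if not vals <= {0, 1}:
        raise ValueError("trait must be binary (0/1)")
    return _fitch_sets(tree, trait)


def retention_index(tree: dendropy.Tree, trait: dict) -> float:
    """Retention index (MaxSteps - ObservedSteps) / (MaxSteps - MinSteps).

    For a binary trait MinSteps = 1 and MaxSteps is the minority-state tip
    count.  Returns NaN (flagged via log) when MaxSteps equals MinSteps, and
    raises for an invariant trait.
    """
    values = [int(trait[lf.taxon.label]) for lf in tree.leaf_node_iter()]
    ones = sum(values)
    zeros = len(values) - ones
    if ones == 0 or zeros == 0:
        raise ValueError("retention index undefined for an invariant trait")
    max_steps = min(ones, zeros)
    min_steps = 1
    if max_steps == min_steps:
        logger.warning("retention index undefined: MaxSteps == MinSteps")
        return float("nan")
    obs = fitch_parsimony(tree, trait)
    return (max_steps - obs) / (max_steps - min_steps)
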
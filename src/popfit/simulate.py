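"""Synthetic data generators with known ground truth.

Three generators cover the inputs of the analysis pipeline:

* :func:`simulate_competition` — serial-dilution pooled growth competitions
  read out by barcode sequencing (multinomial transfer bottleneck +
  multinomial sequencing noise, multiple barcodes per edit, non-editing
  neutral anchor barcodes, optional hitchhiker-mutation outlier barcodes).
* :func:`simulate_population` — a clade-structured strain panel: a rooted
  tree, a variant × strain genotype matrix whose presence sets are clades of
  the tree, a singleton-skewed site-frequency spectrum, ploidy labels, and
  optionally beneficial variants planted preferentially in domesticated
  clades.
* :func:`simulate_structure` — a self-avoiding Cα chain for packing-density
  fixtures.

Every generator takes an explicit seed and is reproducible bit-for-bit.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CompetitionDesign",
    "SimulationTruth",
    "PopulationSimConfig",
    "propagate_frequencies",
    "simulate_competition",
    "inject_outliers",
    "simulate_population",
    "simulate_structure",
]

#: column order of a barcode count table
COUNT_COLUMNS = ["barcode_id", "edit_id", "replicate", "condition", "timepoint", "reads"]


@dataclass
class CompetitionDesign:
    """Design of a pooled serial-dilution competition experiment.

    Parameters mirror the experimental layout: ``n_edits`` edited variants,
    each represented by ``barcodes_per_edit`` independently edited barcode
    lineages, plus ``n_neutral_barcodes`` non-editing anchor barcodes whose
    fitness is zero by construction.  The pool is sampled at ``n_timepoints``
    timepoints separated by ``tau`` generations; each transfer passes
    ``bottleneck_cells`` cells and each sequencing sample draws
    ``reads_per_timepoint`` reads.
    """

    n_edits: int = 100
    barcodes_per_edit: int = 10
    n_neutral_barcodes: int = 30
    n_replicates: int = 3
    conditions: Sequence[str] = ("1D", "2D", "3D", "5D")
    n_timepoints: int = 7
    tau: float = 4.3
    bottleneck_cells: int | None = 10_000_000
    reads_per_timepoint: int = 5_000_000
    outlier_rate: float = 0.0
    outlier_effect: float = 0.1
    # mixture used when true fitness values are not supplied
    p_neutral: float = 0.2
    s_range: tuple[float, float] = (-0.15, 0.15)
    init_log_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_edits < 1 or self.barcodes_per_edit < 1:
            raise ValueError("n_edits and barcodes_per_edit must be >= 1")
        if self.n_neutral_barcodes < 1:
            raise ValueError("at least one neutral anchor barcode is required")
        if self.n_replicates < 1 or not self.conditions:
            raise ValueError("need >= 1 replicate and >= 1 condition")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if self.reads_per_timepoint < 1:
            raise ValueError("reads_per_timepoint must be >= 1")
        if self.bottleneck_cells is not None and self.bottleneck_cells < 1:
            raise ValueError("bottleneck_cells must be >= 1 or None")

    @property
    def edit_ids(self) -> list[str]:
        return [f"edit{i:05d}" for i in range(self.n_edits)]

    @property
    def neutral_ids(self) -> list[str]:
        return [f"neutral{i:04d}" for i in range(self.n_neutral_barcodes)]


@dataclass
class SimulationTruth:
    """Ground truth of a simulated competition.

    ``true_s`` maps edit id -> condition -> per-generation selection
    coefficient (neutral anchors are present with s = 0 exactly);
    ``true_mean_fitness`` holds the realized population mean fitness
    s̄_t = Σ_j f_t(j) s(j) at the start of every transition, per replicate
    and condition.
    """

    true_s: dict[str, dict[str, float]]
    outlier_barcodes: set[str]
    outlier_effect: float
    true_mean_fitness: pd.DataFrame  # columns: replicate, condition, timepoint, mean_fitness
    seed: int
    design: CompetitionDesign | None = None

    def s_vector(self, condition: str, edit_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.true_s[e][condition] for e in edit_ids])


class ExtinctionError(RuntimeError):
    """All lineages went extinct during propagation."""


def propagate_frequencies(f0: np.ndarray, s: np.ndarray, tau: float, n_steps: int) -> np.ndarray:
    """Deterministically propagate lineage frequencies through ``n_steps`` cycles.

    Each cycle multiplies frequencies by exp(s * tau) and renormalizes, which
    is the relative-growth update f <- f exp((s - s̄) tau) followed by exact
    normalization.  Returns an (n_steps + 1, n_lineages) array of
    frequencies; row 0 is ``f0`` normalized.
    """
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 < 0) or f0.sum() <= 0:
        raise ValueError("initial frequencies must be non-negative with positive sum")
    f = f0 / f0.sum()
    out = np.empty((n_steps + 1, f.size))
    out[0] = f
    growth = np.exp(np.asarray(s, dtype=float) * tau)
    for t in range(n_steps):
        raw = out[t] * growth
        tot = raw.sum()
        if tot <= 0:
            raise ExtinctionError(f"all lineages extinct at cycle {t + 1}")
        out[t + 1] = raw / tot
    return out


def _draw_true_s(design: CompetitionDesign, rng: np.random.Generator) -> dict[str, dict[str, float]]:
    """Mixture draw: point mass at zero with probability p_neutral, else uniform."""
    lo, hi = design.s_range
    true_s: dict[str, dict[str, float]] = {}
    for e in design.edit_ids:
        true_s[e] = {}
        for c in design.conditions:
            if rng.random() < design.p_neutral:
                true_s[e][c] = 0.0
            else:
                true_s[e][c] = float(rng.uniform(lo, hi))
    for z in design.neutral_ids:
        true_s[z] = {c: 0.0 for c in design.conditions}
    return true_s


def _normalize_true_s(
    design: CompetitionDesign, true_s: Mapping[str, float | Mapping[str, float]]
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for e in design.edit_ids:
        v = true_s[e]
        if isinstance(v, Mapping):
            out[e] = {c: float(v[c]) for c in design.conditions}
        else:
            out[e] = {c: float(v) for c in design.conditions}
    for z in design.neutral_ids:
        out[z] = {c: 0.0 for c in design.conditions}
    return out


def _barcode_layout(design: CompetitionDesign) -> tuple[list[str], list[str]]:
    """Barcode ids and their edit ids, neutral anchors last (one barcode each)."""
    barcode_ids: list[str] = []
    edit_of: list[str] = []
    for e in design.edit_ids:
        for b in range(design.barcodes_per_edit):
            barcode_ids.append(f"{e}.bc{b:02d}")
            edit_of.append(e)
    for z in design.neutral_ids:
        barcode_ids.append(f"{z}.bc00")
        edit_of.append(z)
    return barcode_ids, edit_of


def _select_outliers(
    design: CompetitionDesign, rate: float, rng: np.random.Generator
) -> set[str]:
    """One outlier barcode per affected editing edit; edits hit with prob ``rate``."""
    out: set[str] = set()
    if rate <= 0:
        return out
    for e in design.edit_ids:
        if rng.random() < rate:
            b = int(rng.integers(design.barcodes_per_edit))
            out.add(f"{e}.bc{b:02d}")
    return out


def _simulate_counts(
    design: CompetitionDesign,
    true_s: dict[str, dict[str, float]],
    outliers: set[str],
    outlier_effect: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Core generative loop over (replicate, condition) streams."""
    barcode_ids, edit_of = _barcode_layout(design)
    n_lin = len(barcode_ids)
    is_outlier = np.array([b in outliers for b in barcode_ids])

    root = np.random.SeedSequence([seed, 0])
    streams = root.spawn(design.n_replicates * len(design.conditions) + 1)
    init_rng = np.random.default_rng(streams[-1])
    # shared initial pool composition across replicates (one transformation pool)
    base_init = np.exp(init_rng.normal(0.0, design.init_log_sd, size=n_lin))
    base_init /= base_init.sum()

    frames = []
    sbar_rows = []
    k = 0
    for rep in range(1, design.n_replicates + 1):
        for cond in design.conditions:
            rng = np.random.default_rng(streams[k])
            k += 1
            s_edit = np.array([true_s[e][cond] for e in edit_of])
            s_eff = s_edit + outlier_effect * is_outlier
            growth = np.exp(s_eff * design.tau)

            f = base_init.copy()
            reads = np.empty((design.n_timepoints, n_lin), dtype=np.int64)
            for t in range(design.n_timepoints):
                reads[t] = rng.multinomial(design.reads_per_timepoint, f)
                if t == design.n_timepoints - 1:
                    break
                sbar_rows.append((rep, cond, t, float(np.dot(f, s_eff))))
                raw = f * growth
                tot = raw.sum()
                if tot <= 0:
                    raise ExtinctionError(f"all lineages extinct at cycle {t + 1}")
                f = raw / tot
                if design.bottleneck_cells is not None:
                    n = rng.multinomial(design.bottleneck_cells, f)
                    f = n / n.sum()

            df = pd.DataFrame(
                {
                    "barcode_id": np.tile(barcode_ids, design.n_timepoints),
                    "edit_id": np.tile(edit_of, design.n_timepoints),
                    "replicate": rep,
                    "condition": cond,
                    "timepoint": np.repeat(np.arange(design.n_timepoints), n_lin),
                    "reads": reads.ravel(),
                }
            )
            frames.append(df)

    table = pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]
    sbar = pd.DataFrame(sbar_rows, columns=["replicate", "condition", "timepoint", "mean_fitness"])
    return table, sbar


def simulate_competition(
    design: CompetitionDesign,
    true_s: Mapping[str, float | Mapping[str, float]] | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a barcode count table under serial-dilution competition.

    Per replicate × condition stream and cycle: deterministic relative growth
    f <- f exp((s_eff - s̄) tau), a multinomial bottleneck of
    ``design.bottleneck_cells`` (skipped when None), and a multinomial
    sequencing draw of ``design.reads_per_timepoint`` at every timepoint.
    Barcodes within an edit share s except outlier barcodes, which add
    ``design.outlier_effect``.

    Returns the count table (long TSV layout) and a :class:`SimulationTruth`.
    """
    design.validate()
    s_draw_rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    if true_s is None:
        s_map = _draw_true_s(design, s_draw_rng)
    else:
        s_map = _normalize_true_s(design, true_s)
    outliers = _select_outliers(design, design.outlier_rate, s_draw_rng)
    table, sbar = _simulate_counts(design, s_map, outliers, design.outlier_effect, design.seed)
    truth = SimulationTruth(
        true_s=s_map,
        outlier_barcodes=outliers,
        outlier_effect=design.outlier_effect,
        true_mean_fitness=sbar,
        seed=design.seed,
        design=design,
    )
    return table, truth


def inject_outliers(
    table: pd.DataFrame,
    truth: SimulationTruth,
    rate: float,
    effect: float,
    seed: int,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Re-simulate the competition with hitchhiker barcodes added at ``rate``.

    Each editing edit acquires, with probability ``rate``, one barcode whose
    effective fitness is s + ``effect`` (a spontaneous beneficial mutation on
    that lineage's background).  ``rate = 0`` returns the inputs unchanged.
    The whole table is regenerated under ``seed`` so that the hitchhiker's
    growth feeds back on every other lineage's frequency, as it would in the
    flask.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0:
        return table, truth
    if truth.design is None:
        raise ValueError("truth must carry its CompetitionDesign to re-simulate")
    design = truth.design
    rng = np.random.default_rng(seed)
    outliers = _select_outliers(design, rate, rng)
    new_table, sbar = _simulate_counts(design, truth.true_s, outliers, effect, seed)
    new_truth = SimulationTruth(
        true_s=truth.true_s,
        outlier_barcodes=outliers,
        outlier_effect=effect,
        true_mean_fitness=sbar,
        seed=seed,
        design=design,
    )
    return new_table, new_truth


# ---------------------------------------------------------------------------
# clade-structured population
# ---------------------------------------------------------------------------

_DEFAULT_ECOLOGY = {
    "domesticated": (0.80, 0.15, 0.05),
    "wild": (0.10, 0.85, 0.05),
    "other": (0.50, 0.45, 0.05),
}


@dataclass
class PopulationSimConfig:
    """Configuration of a clade-structured strain panel.

    ``clade_spec`` lists (clade id, clade_class, n strains); sizes must sum to
    ``n_strains``.  ``ecology_assignment`` maps clade_class to
    (P industrial, P natural, P other) for per-strain ecology labels.
    ``planted_beneficial`` variants are placed on tree branches with
    probability ``bias_strength`` restricted to domesticated-clade branches
    (``bias_strength = 1`` confines them entirely to domesticated strains).
    ``singleton_skew`` (>= 1) multiplies terminal-branch weights during
    mutation placement, skewing the site-frequency spectrum toward
    singletons.
    """

    n_strains: int = 120
    n_variants: int = 600
    clade_spec: Sequence[tuple[str, str, int]] = (
        ("dom1", "domesticated", 25),
        ("dom2", "domesticated", 20),
        ("dom3", "domesticated", 15),
        ("wild1", "wild", 10),
        ("wild2", "wild", 10),
        ("wild3", "wild", 10),
        ("other1", "other", 30),
    )
    ecology_assignment: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_ECOLOGY)
    )
    planted_beneficial: int = 0
    bias_strength: float = 0.8
    ploidy_fraction_haploid: float = 0.3
    het_prob: float = 0.5
    singleton_skew: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        sizes = sum(n for _, _, n in self.clade_spec)
        if sizes != self.n_strains:
            raise ValueError(
                f"clade sizes sum to {sizes}, expected n_strains = {self.n_strains}"
            )
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.singleton_skew < 1:
            raise ValueError("singleton_skew must be >= 1")
        for _, cls, _ in self.clade_spec:
            if cls not in ("domesticated", "wild", "other"):
                raise ValueError(f"unknown clade_class {cls!r}")


def _random_clade_tree(labels: list[str], rng: np.random.Generator, tns: dendropy.TaxonNamespace) -> dendropy.Node:
    """Random coalescent-shaped subtree over ``labels``; returns its root node."""
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab) or tns.new_taxon(lab)
        nd.age = 0.0
        nodes.append(nd)
    k = len(nodes)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.age = t
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = t - child.age
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    return nodes[0]


def simulate_population(
    cfg: PopulationSimConfig,
) -> tuple["pd.DataFrame", pd.DataFrame, dendropy.Tree]:
    """Simulate a genotype matrix, strain metadata and a rooted tree.

    Variants are mutations placed on tree branches, so each presence set is a
    clade.  Returns (genotype matrix DataFrame with values 0 = absent,
    1 = het, 2 = hom/haploid-present; variants as rows, strains as columns),
    strain metadata, and the rooted dendropy tree with branch lengths.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tns = dendropy.TaxonNamespace()

    strain_ids: list[str] = []
    clade_of: dict[str, str] = {}
    class_of_clade = {cid: cls for cid, cls, _ in cfg.clade_spec}
    clade_roots = []
    for cid, _cls, n in cfg.clade_spec:
        labels = [f"{cid}_s{i:03d}" for i in range(n)]
        strain_ids.extend(labels)
        for lab in labels:
            clade_of[lab] = cid
        if n == 1:
            nd = dendropy.Node()
            nd.taxon = tns.new_taxon(labels[0])
            nd.age = 0.0
            clade_roots.append(nd)
        else:
            clade_roots.append(_random_clade_tree(labels, rng, tns))

    # attach clade subtrees to a root with stem branches
    root = dendropy.Node()
    max_age = max(getattr(nd, "age", 0.0) for nd in clade_roots)
    root_age = max_age + 1.0
    for nd in clade_roots:
        root.add_child(nd)
        nd.edge.length = root_age - getattr(nd, "age", 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True

    # strain metadata
    ploidy = np.where(rng.random(len(strain_ids)) < cfg.ploidy_fraction_haploid, 1, 2)
    eco_labels = []
    for sid in strain_ids:
        probs = cfg.ecology_assignment.get(class_of_clade[clade_of[sid]], (1 / 3,) * 3)
        eco_labels.append(rng.choice(["industrial", "natural", "other"], p=np.asarray(probs) / sum(probs)))
    meta = pd.DataFrame(
        {
            "strain_id": strain_ids,
            "clade": [clade_of[s] for s in strain_ids],
            "clade_class": [class_of_clade[clade_of[s]] for s in strain_ids],
            "ecology_class": eco_labels,
            "ploidy": ploidy,
        }
    )

    # mutation placement on edges; leaf sets precomputed
    edges = []
    for edge in tree.preorder_edge_iter():
        if edge.head_node is root or edge.length is None or edge.length <= 0:
            continue
        leaves = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        edges.append((edge, leaves))
    lengths = np.array([e.length for e, _ in edges])
    terminal = np.array([len(lv) == 1 for _, lv in edges])
    weights = lengths * np.where(terminal, cfg.singleton_skew, 1.0)
    weights = weights / weights.sum()

    dom_strains = set(meta.loc[meta.clade_class == "domesticated", "strain_id"])
    dom_edge_idx = np.array(
        [i for i, (_, lv) in enumerate(edges) if lv <= dom_strains], dtype=int
    )

    n_neutral = cfg.n_variants - cfg.planted_beneficial
    if n_neutral < 0:
        raise ValueError("planted_beneficial exceeds n_variants")
    variant_ids = [f"var{i:05d}" for i in range(n_neutral)] + [
        f"ben{i:04d}" for i in range(cfg.planted_beneficial)
    ]
    strain_index = {s: i for i, s in enumerate(strain_ids)}
    geno = np.zeros((cfg.n_variants, len(strain_ids)), dtype=np.int8)

    def place_one(row: int, edge_idx: int) -> None:
        _, leaves = edges[edge_idx]
        for lab in leaves:
            j = strain_index[lab]
            if ploidy[j] == 1:
                geno[row, j] = 2
            else:
                geno[row, j] = 1 if rng.random() < cfg.het_prob else 2

    for row in range(n_neutral):
        place_one(row, int(rng.choice(len(edges), p=weights)))
    if cfg.planted_beneficial > 0 and len(dom_edge_idx) == 0:
        raise ValueError("cannot plant beneficial variants: no domesticated-clade branches")
    for k in range(cfg.planted_beneficial):
        row = n_neutral + k
        if rng.random() < min(cfg.bias_strength, 1.0):
            w = weights[dom_edge_idx]
            place_one(row, int(dom_edge_idx[rng.choice(len(dom_edge_idx), p=w / w.sum())]))
        else:
            place_one(row, int(rng.choice(len(edges), p=weights)))

    G = pd.DataFrame(geno, index=variant_ids, columns=strain_ids)
    return G, meta, tree


def simulate_structure(n_residues: int, seed: int = 0) -> pd.DataFrame:
    """Self-avoiding random-walk Cα chain with 3.8 Å consecutive spacing.

    Returns a DataFrame with columns (chain, residue, x, y, z); residue
    indices are 1-based.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    step = 3.8
    min_sep = 3.8  # hard-sphere exclusion against non-consecutive residues
    coords = np.zeros((n_residues, 3))
    i = 1
    while i < n_residues:
        placed = False
        for _ in range(500):
            v = rng.normal(size=3)
            v *= step / np.linalg.norm(v)
            cand = coords[i - 1] + v
            if i < 2:
                placed = True
            else:
                d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                placed = bool(np.all(d >= min_sep))
            if placed:
                coords[i] = cand
                break
        if not placed:
            # chain trapped itself; back up one residue and retry
            i = max(1, i - 1)
            continue
        i += 1
    return pd.DataFrame(
        {
            "chain": "A",
            "residue": np.arange(1, n_residues + 1),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )
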
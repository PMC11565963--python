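"""Residue packing density from Cα coordinates and annotation threshold rules.

Packing density of a residue is the number of other residues' Cα atoms
within 10 Å (inclusive) of its own Cα — a simple burial/contact measure that
complements solvent accessibility.  SIFT scores, FoldX ΔΔG values and
relative solvent accessibility are ingested from precomputed tables; this
module only validates ranges and applies the standard threshold flags
(SIFT < 0.05 strongly deleterious prediction; ΔΔG > 2 kcal/mol
destabilizing).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "read_calpha_coordinates",
    "packing_density",
    "annotate_flags",
    "property_comparison",
    "map_variant_to_residue",
]

SIFT_THRESHOLD = 0.05
DDG_THRESHOLD = 2.0


def read_calpha_coordinates(path: str) -> pd.DataFrame:
    """Extract Cα coordinates from a PDB or mmCIF file.

    Returns a DataFrame with columns (chain, residue, x, y, z).  Residues
    without a Cα atom are excluded and logged.
    """
    import biotite.structure as struc

    if str(path).endswith((".cif", ".mmcif")):
        import biotite.structure.io.pdbx as pdbx

        f = pdbx.CIFFile.read(str(path))
        atoms = pdbx.get_structure(f, model=1)
    else:
        import biotite.structure.io.pdb as pdb

        atoms = pdb.PDBFile.read(str(path)).get_structure(model=1)
    ca = atoms[atoms.atom_name == "CA"]
    n_res = len(np.unique(atoms[struc.filter_amino_acids(atoms)].res_id))
    if len(ca) < n_res:
        logger.warning("%d residues lack a Calpha atom; excluded", n_res - len(ca))
    return pd.DataFrame(
        {
            "chain": ca.chain_id,
            "residue": ca.res_id,
            "x": ca.coord[:, 0],
            "y": ca.coord[:, 1],
            "z": ca.coord[:, 2],
        }
    )


def packing_density(coords: pd.DataFrame, radius: float = 10.0) -> pd.DataFrame:
    """Count other Cα atoms within ``radius`` Å (inclusive) of each residue.

    Residues with non-finite coordinates are excluded from both the counted
    and counting sets (silently zero-filling them would bias comparisons
    downward) and reported via log.  Uses a KD-tree; results equal the
    quadratic pairwise definition exactly.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(coords) < 1:
        raise ValueError("need at least one residue")
    xyz = coords[["x", "y", "z"]].to_numpy(dtype=float)
    ok = np.isfinite(xyz).all(axis=1)
    if not ok.all():
        logger.warning("excluding %d residues with missing coordinates", int((~ok).sum()))
    sub = coords.loc[ok].reset_index(drop=True)
    pts = xyz[ok]
    tree = cKDTree(pts)
    # query_ball_point includes the residue itself, hence the -1
    counts = np.array([len(tree.query_ball_point(p, r=radius)) - 1 for p in pts])
    out = sub[["chain", "residue"]].copy()
    out["packing_density"] = counts
    return out


def annotate_flags(table: pd.DataFrame) -> pd.DataFrame:
    """Apply threshold flags to a raw per-variant annotation table.

    ``sift_strong`` is SIFT < 0.05 and ``destabilizing`` is ΔΔG > 2 kcal/mol,
    both strict.  Missing scores yield missing (pd.NA) flags, never False.
    SIFT values outside [0, 1] are a validation failure.
    """
    out = table.copy()
    if "sift" in out:
        sift = pd.to_numeric(out["sift"], errors="coerce")
        bad = sift.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("SIFT scores must lie in [0, 1]")
        out["sift_strong"] = pd.array(sift < SIFT_THRESHOLD, dtype="boolean")
        out.loc[sift.isna(), "sift_strong"] = pd.NA
    if "ddg" in out:
        ddg = pd.to_numeric(out["ddg"], errors="coerce")
        out["destabilizing"] = pd.array(ddg > DDG_THRESHOLD, dtype="boolean")
        out.loc[ddg.isna(), "destabilizing"] = pd.NA
    return out


def property_comparison(
    annot: pd.DataFrame,
    classification: pd.Series,
    numeric_properties=("sift", "ddg", "solvent_accessibility", "packing_density"),
    flag_properties=("sift_strong", "destabilizing"),
    missense_only=("sift", "ddg", "solvent_accessibility", "packing_density"),
) -> pd.DataFrame:
    """Compare each annotation property between non-neutral and neutral variants.

    Numeric properties get a Wilcoxon rank-sum test (restricted to missense
    variants where appropriate, since protein-level scores are undefined
    otherwise); boolean flags get Fisher's exact test with an odds ratio.
    ``classification`` is indexed by variant id with values neutral /
    beneficial / deleterious.  Empty strata are skipped with a warning.
    """
    df = annot.set_index("variant") if "variant" in annot else annot
    cls = classification.reindex(df.index)
    non_neutral = cls.isin(["beneficial", "deleterious"])
    rows = []
    for prop in numeric_properties:
        if prop not in df:
            continue
        sub = df
        if prop in missense_only and "consequence" in df:
            sub = df[df.consequence == "missense"]
        mask_nn = non_neutral.reindex(sub.index).fillna(False).astype(bool)
        x = pd.to_numeric(sub.loc[mask_nn, prop], errors="coerce").dropna()
        y = pd.to_numeric(sub.loc[~mask_nn, prop], errors="coerce").dropna()
        if len(x) < 2 or len(y) < 2:
            logger.warning("property %s: empty stratum, skipped", prop)
            continue
        r = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append(
            (prop, "wilcoxon", len(x), len(y), float(np.median(x) - np.median(y)), float(r.pvalue))
        )
    for prop in flag_properties:
        if prop not in df:
            continue
        flag = df[prop]
        ok = flag.notna()
        tab = pd.crosstab(non_neutral[ok], flag[ok].astype(bool))
        tab = tab.reindex(index=[True, False], columns=[True, False], fill_value=0)
        if tab.to_numpy().sum() == 0:
            logger.warning("flag %s: empty stratum, skipped", prop)
            continue
        oddsratio, p = stats.fisher_exact(tab.to_numpy())
        rows.append((prop, "fisher", int(tab.loc[True].sum()), int(tab.loc[False].sum()), float(oddsratio), float(p)))
    return pd.DataFrame(
        rows, columns=["property", "test", "n_non_neutral", "n_neutral", "effect", "p_value"]
    )


def map_variant_to_residue(cds_position: int, cds_length: int | None = None) -> int | None:
    """Map a 1-based CDS nucleotide position to a 1-based residue index.

    Returns None (with a log entry) when the position falls outside the CDS.
    """
    if cds_position < 1 or (cds_length is not None and cds_position > cds_length):
        logger.info("position %s outside CDS", cds_position)
        return None
    return math.ceil(cds_position / 3)
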
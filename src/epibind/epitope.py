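"""Structural epitope mapping.

Maps mutagenesis binding-loss calls onto protein structures: solvent
accessibility (Shrake-Rupley quadrature) to select surface residues for
scanning mutagenesis, per-residue loss annotation into the temperature-
factor column for visualisation, a permutation test for spatial clustering
of loss residues, and set arithmetic for binding-site overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Structure",
    "AccessibilityRecord",
    "OverlapReport",
    "ClusterTestResult",
    "read_structure",
    "write_structure",
    "solvent_accessibility",
    "select_surface_residues",
    "annotate_structure",
    "clustering_test",
    "site_overlap",
    "sphere_points",
    "shrake_rupley",
]

# van der Waals radii (Å) by element; Bondi values, carbon default for
# unknown elements
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70

# Maximum accessible surface area (Å²) per residue type in a Gly-X-Gly
# tripeptide (theoretical values, Tien et al. 2013); used to express a
# residue's SASA as a fraction of its fully exposed reference.
MAX_SASA_GXG = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class Structure:
    """Atomic structure: parallel per-atom arrays.

    Residues are identified by ``(chain_id, res_id)``; van der Waals radii
    are assigned by element on read.
    """

    chain_id: np.ndarray    # str per atom
    res_id: np.ndarray      # int per atom
    res_name: np.ndarray    # str per atom
    atom_name: np.ndarray   # str per atom
    element: np.ndarray     # str per atom
    coord: np.ndarray       # (n, 3) float Å
    b_factor: np.ndarray    # float per atom
    radius: np.ndarray      # float Å per atom

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("atom coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.res_id)

    def residues(self) -> list[tuple[str, int]]:
        """Unique (chain_id, res_id) pairs in file order."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_id, self.res_id):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_mask(self, chain: str, res: int) -> np.ndarray:
        return (self.chain_id == chain) & (self.res_id == res)

    def ca_coords(self, residue_ids, chain: str | None = None) -> np.ndarray:
        """Cα coordinates for the given residue numbers (one per residue)."""
        out = []
        for rid in residue_ids:
            mask = (self.res_id == rid) & (self.atom_name == "CA")
            if chain is not None:
                mask &= self.chain_id == chain
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                raise KeyError(f"no CA atom for residue {rid}")
            out.append(self.coord[idx[0]])
        return np.asarray(out, dtype=float)


def _from_atom_array(atoms: struc.AtomArray) -> Structure:
    elements = np.asarray([e.upper() for e in atoms.element])
    radii = np.asarray([VDW_RADII.get(e, DEFAULT_RADIUS) for e in elements])
    b = (np.asarray(atoms.b_factor, dtype=float)
         if "b_factor" in atoms.get_annotation_categories()
         else np.zeros(atoms.array_length()))
    return Structure(
        chain_id=np.asarray(atoms.chain_id, dtype="U4"),
        res_id=np.asarray(atoms.res_id, dtype=int),
        res_name=np.asarray(atoms.res_name, dtype="U4"),
        atom_name=np.asarray(atoms.atom_name, dtype="U5"),
        element=elements,
        coord=np.asarray(atoms.coord, dtype=float),
        b_factor=b,
        radius=radii,
    )


def read_structure(path, keep_hetero: bool = False) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    HETATM records and waters are skipped unless ``keep_hetero``; only the
    first model of a multi-model file is read.
    """
    try:
        pdb = PDBFile.read(path)
        atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])
    except Exception as exc:
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    mask = ~np.isin(atoms.res_name, list(_WATER_NAMES))
    if not keep_hetero:
        mask &= ~atoms.hetero
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise ValueError(f"no ATOM records found in {path}")
    return _from_atom_array(atoms)


def write_structure(s: Structure, path) -> None:
    """Write a :class:`Structure` back to PDB (ATOM records, B-factor kept)."""
    atoms = struc.AtomArray(s.n_atoms)
    atoms.chain_id = s.chain_id
    atoms.res_id = s.res_id
    atoms.res_name = s.res_name
    atoms.atom_name = s.atom_name
    atoms.element = s.element
    atoms.coord = s.coord.astype(np.float32)
    atoms.set_annotation("b_factor", np.round(s.b_factor, 2))
    atoms.hetero = np.zeros(s.n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(path)


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley)
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """``n`` nearly uniform points on the unit sphere (golden-spiral
    lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i      # golden angle
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(coord: np.ndarray, radii: np.ndarray,
                  probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area by quadrature.

    Each atom's solvent sphere (vdW radius + probe) is sampled at
    ``n_points``; a point counts as exposed when it lies outside every
    neighbouring atom's solvent sphere.  Returns Å² per atom.
    """
    coord = np.asarray(coord, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coord.shape[0] == 0:
        raise ValueError("structure has no atoms")
    coord = _canonical_frame(coord)
    ext = radii + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coord)
    areas = np.empty(len(coord))
    for i in range(len(coord)):
        exposed = np.ones(n_points, dtype=bool)
        pts = None
        for j in tree.query_ball_point(coord[i], ext[i] + ext.max()):
            if j == i:
                continue
            dc2 = float(np.dot(coord[j] - coord[i], coord[j] - coord[i]))
            if dc2 >= (ext[i] + ext[j]) ** 2:
                continue
            if dc2 < 1e-16 and ext[j] >= ext[i]:
                # coincident atoms: the lower-index one keeps the sphere
                if ext[j] > ext[i] or j < i:
                    exposed[:] = False
                    break
                continue
            if pts is None:
                pts = coord[i] + ext[i] * unit
            d2 = np.sum((pts - coord[j]) ** 2, axis=1)
            exposed &= d2 > ext[j] ** 2
            if not exposed.any():
                break
        areas[i] = 4.0 * math.pi * ext[i] ** 2 * exposed.mean()
    return areas


def _canonical_frame(coord: np.ndarray) -> np.ndarray:
    """Rotate/translate coordinates into a deterministic principal-axis
    frame so the quadrature result is exactly rigid-transform invariant."""
    centered = coord - coord.mean(axis=0)
    if len(centered) < 2:
        return centered
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending variance
    proj = centered @ v
    skew = (proj ** 3).sum(axis=0)
    flip = skew < 0  # orient each axis by the sign of its third moment
    v[:, flip] = -v[:, flip]
    if np.linalg.det(v) < 0:  # restore handedness on the least-skewed axis
        k = int(np.argmin(np.abs(skew)))
        v[:, k] = -v[:, k]
    return centered @ v


@dataclass(frozen=True)
class AccessibilityRecord:
    """Per-residue solvent accessibility.

    ``relative`` is absolute SASA divided by the residue type's Gly-X-Gly
    reference maximum (NaN for nonstandard residues with no reference).
    """

    chain: str
    res_id: int
    res_name: str
    sasa: float
    relative: float


def solvent_accessibility(s: Structure, probe_radius: float = 1.4,
                          n_points: int = 960) -> list[AccessibilityRecord]:
    """Shrake-Rupley SASA summed per residue, absolute and relative."""
    atom_sasa = shrake_rupley(s.coord, s.radius, probe_radius, n_points)
    records = []
    for chain, rid in s.residues():
        mask = s.residue_mask(chain, rid)
        total = float(atom_sasa[mask].sum())
        res_name = str(s.res_name[mask][0])
        ref = MAX_SASA_GXG.get(res_name)
        rel = total / ref if ref else float("nan")
        records.append(AccessibilityRecord(chain=chain, res_id=rid,
                                           res_name=res_name, sasa=total,
                                           relative=rel))
    return records


def select_surface_residues(records, cutoff: float = 0.2) -> set[int]:
    """Residue numbers whose relative SASA strictly exceeds ``cutoff``."""
    return {r.res_id for r in records
            if np.isfinite(r.relative) and r.relative > cutoff}


# ---------------------------------------------------------------------------
# Loss annotation
# ---------------------------------------------------------------------------

def annotate_structure(s: Structure, calls, path=None, offset: int = 0,
                       ) -> tuple[Structure, list[str]]:
    """Write per-residue binding-loss values into the B-factor column.

    ``calls`` is an iterable of loss calls (objects with ``mutant`` like
    ``"N82E"`` and ``loss``); residue numbers are parsed from the mutant id
    and shifted by ``offset`` to match structure numbering (construct vs
    crystal numbering differences are configured, never guessed).
    Unmapped residues get 0; call residues absent from the structure are
    returned in a skip report rather than raising.  When ``path`` is given
    the annotated structure is also written to it.
    """
    b = np.zeros(s.n_atoms)
    skipped: list[str] = []
    for call in calls:
        digits = "".join(ch for ch in call.mutant if ch.isdigit())
        if not digits:
            skipped.append(call.mutant)
            continue
        rid = int(digits) + offset
        mask = s.res_id == rid
        if not mask.any():
            skipped.append(call.mutant)
            continue
        b[mask] = call.loss
    out = Structure(chain_id=s.chain_id, res_id=s.res_id, res_name=s.res_name,
                    atom_name=s.atom_name, element=s.element, coord=s.coord,
                    b_factor=b, radius=s.radius)
    if path is not None:
        write_structure(out, path)
    return out, skipped


def read_annotation(s: Structure) -> dict[int, float]:
    """Recover the per-residue annotation value from the B-factor column."""
    return {rid: float(s.b_factor[s.residue_mask(chain, rid)][0])
            for chain, rid in s.residues()}


# ---------------------------------------------------------------------------
# Spatial clustering of loss residues
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterTestResult:
    """Spatial clustering test for a flagged residue set.

    The statistic is the mean pairwise Cα distance among flagged residues;
    the null is the same statistic for equally sized draws from the
    background set; small p means tighter clustering than chance.
    ``exact`` marks full enumeration of subsets instead of sampling.
    """

    observed: float
    p_value: float
    n_permutations: int
    exact: bool
    seed: int | None = None


def _mean_pairwise(coords: np.ndarray) -> float:
    d = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((d ** 2).sum(-1))
    n = len(coords)
    return float(dist[np.triu_indices(n, 1)].mean())


def clustering_test(s: Structure, flagged, background, n_perm: int = 10_000,
                    seed: int = 0, chain: str | None = None,
                    enumeration_limit: int = 100_000) -> ClusterTestResult:
    """Test whether flagged residues cluster in space.

    ``flagged`` must be a subset of ``background`` (residue numbers with Cα
    atoms in the structure) with at least two members.  When the number of
    possible subsets C(|background|, |flagged|) is at most
    ``enumeration_limit`` the null is enumerated exactly (p = fraction of
    subsets at least as tight as observed); otherwise ``n_perm`` random
    draws give p = (1 + #{null <= observed}) / (1 + n_perm).
    """
    flagged = sorted(set(flagged))
    background = sorted(set(background))
    if not set(flagged) <= set(background):
        raise ValueError("flagged residues must be a subset of the background")
    k = len(flagged)
    if k < 2:
        raise ValueError("need at least two flagged residues")
    bg_coords = s.ca_coords(background, chain=chain)
    index = {rid: i for i, rid in enumerate(background)}
    obs = _mean_pairwise(bg_coords[[index[r] for r in flagged]])

    n_total = math.comb(len(background), k)
    if n_total <= enumeration_limit:
        count = sum(
            _mean_pairwise(bg_coords[list(subset)]) <= obs + 1e-12
            for subset in combinations(range(len(background)), k))
        return ClusterTestResult(observed=obs, p_value=count / n_total,
                                 n_permutations=n_total, exact=True)
    rng = np.random.default_rng(seed)
    count = sum(
        _mean_pairwise(bg_coords[rng.choice(len(background), k,
                                            replace=False)]) <= obs + 1e-12
        for _ in range(n_perm))
    return ClusterTestResult(observed=obs, p_value=(1 + count) / (1 + n_perm),
                             n_permutations=n_perm, exact=False, seed=seed)


# ---------------------------------------------------------------------------
# Binding-site overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapReport:
    intersection: frozenset
    union: frozenset
    jaccard: float


def site_overlap(a, b) -> OverlapReport:
    """Intersection, union and Jaccard index of two residue sets (same
    numbering scheme)."""
    a, b = set(a), set(b)
    union = a | b
    inter = a & b
    jaccard = len(inter) / len(union) if union else 1.0
    return OverlapReport(intersection=frozenset(inter),
                         union=frozenset(union), jaccard=jaccard)
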
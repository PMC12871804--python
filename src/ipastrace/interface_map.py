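"""Solvent-accessible surface area and protein-protein interface mapping.

SASA is computed with the Shrake-Rupley method: each atom's van der Waals
sphere is inflated by the probe radius (1.4 A, a water molecule) and covered
with a deterministic golden-spiral point set; the accessible area is the
sphere area times the fraction of points not occluded by any neighboring
inflated sphere.  From SASA follow:

- the *buried fraction* of a chain: (SASA alone - SASA in complex) / SASA
  alone — the figure of merit for how much of a subunit is interface;
- the per-residue *interface map*: for each residue of a target chain, the
  area buried against each partner chain computed pairwise (target + one
  partner at a time), the "main interacting subunit" being the partner
  burying the most area.

Everything is deterministic: fixed quadrature, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: van der Waals radii (A) for common elements (Bondi-style values).
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 1.80,
    "ZN": 1.39,
    "MG": 1.73,
}
DEFAULT_RADIUS = 1.70


@dataclass
class AtomSet:
    """Structure-of-arrays atom container for SASA computations."""

    coords: np.ndarray  # (n, 3) A
    radii: np.ndarray  # (n,) vdW radii, A
    chains: np.ndarray  # (n,) chain ids (str)
    residues: np.ndarray  # (n,) residue sequence numbers (int)
    elements: np.ndarray  # (n,) element symbols

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("atom coordinates must be finite")
        if (self.radii <= 0).any():
            raise ValueError("van der Waals radii must be positive")
        self.chains = np.asarray(self.chains)
        self.residues = np.asarray(self.residues, dtype=int)
        self.elements = np.asarray(self.elements)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def select_chains(self, chain_ids) -> "AtomSet":
        mask = np.isin(self.chains, list(chain_ids))
        return AtomSet(
            coords=self.coords[mask],
            radii=self.radii[mask],
            chains=self.chains[mask],
            residues=self.residues[mask],
            elements=self.elements[mask],
        )

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chains:
            seen.setdefault(str(c), None)
        return list(seen)


@dataclass
class SasaResult:
    """Per-atom accessible areas (A^2) with residue/chain aggregation."""

    atoms: AtomSet
    atom_area: np.ndarray

    @property
    def total(self) -> float:
        return float(self.atom_area.sum())

    def per_chain(self) -> pd.Series:
        return pd.Series(self.atom_area).groupby(pd.Series(self.atoms.chains)).sum()

    def per_residue(self) -> pd.Series:
        idx = pd.MultiIndex.from_arrays(
            [self.atoms.chains, self.atoms.residues], names=["chain", "residue"]
        )
        return pd.Series(self.atom_area, index=idx).groupby(level=[0, 1]).sum()


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(
    atoms: AtomSet, probe_radius: float = 1.4, n_points: int = 960
) -> SasaResult:
    """Shrake-Rupley SASA with a golden-spiral quadrature.

    Per-atom area = 4*pi*(r + probe)^2 * (unoccluded points / n_points).
    Neighbor search uses a KD-tree over atom centers with the maximal
    possible contact distance.
    """
    if len(atoms) == 0:
        raise ValueError("need at least one atom")
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    sphere = golden_spiral_points(n_points)
    expanded = atoms.radii + probe_radius
    tree = cKDTree(atoms.coords)
    rmax = expanded.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        ri = expanded[i]
        pts = atoms.coords[i] + ri * sphere
        free = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(atoms.coords[i], ri + rmax):
            if j == i:
                continue
            rj = expanded[j]
            d2 = ((pts - atoms.coords[j]) ** 2).sum(axis=1)
            free &= d2 > rj * rj
        areas[i] = 4.0 * np.pi * ri * ri * free.mean()
    return SasaResult(atoms=atoms, atom_area=areas)


def buried_fraction(
    atoms: AtomSet,
    target_chain: str,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Fraction of a chain's isolated SASA buried within the complex."""
    if target_chain not in set(map(str, atoms.chains)):
        raise ValueError(f"chain {target_chain!r} not in structure")
    alone = shrake_rupley(
        atoms.select_chains([target_chain]), probe_radius, n_points
    )
    if alone.total <= 0:
        raise ValueError("target chain has zero isolated SASA (degenerate input)")
    in_complex = shrake_rupley(atoms, probe_radius, n_points)
    mask = atoms.chains == target_chain
    buried = alone.total - float(in_complex.atom_area[mask].sum())
    return max(0.0, buried) / alone.total


@dataclass
class InterfaceMap:
    """Per-residue buried areas of a target chain against each partner."""

    target_chain: str
    table: pd.DataFrame  # index residue; columns: buried_<partner>..., main_partner
    unresolved: list[int]  # residue numbers absent from the model (gaps)


def residue_interface_map(
    atoms: AtomSet,
    target_chain: str,
    partner_chains: list[str] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> InterfaceMap:
    """Map each target-chain residue to its main interacting partner chain.

    Buried area against a partner is computed pairwise: SASA of the target
    alone minus its SASA with only that partner present.  The main partner
    maximizes buried area; ties resolve to the earliest chain in
    ``partner_chains`` order; residues burying nothing stay unassigned.
    Residue numbers missing between the chain's first and last modelled
    residue form the unresolved mask.
    """
    chains = set(map(str, atoms.chains))
    if target_chain not in chains:
        raise ValueError(f"unknown chain {target_chain!r}")
    if partner_chains is None:
        partner_chains = [c for c in atoms.chain_ids if c != target_chain]
    unknown = [c for c in partner_chains if c not in chains]
    if unknown:
        raise ValueError(f"unknown partner chain(s): {unknown}")
    if target_chain in partner_chains:
        raise ValueError("target chain cannot be its own partner")

    target = atoms.select_chains([target_chain])
    alone = shrake_rupley(target, probe_radius, n_points).per_residue()
    alone = alone.droplevel("chain")

    buried = {}
    for partner in partner_chains:
        pair = atoms.select_chains([target_chain, partner])
        res = shrake_rupley(pair, probe_radius, n_points)
        mask = pair.chains == target_chain
        idx = pd.Index(pair.residues[mask], name="residue")
        with_partner = (
            pd.Series(res.atom_area[mask], index=idx).groupby(level=0).sum()
        )
        buried[f"buried_{partner}"] = (alone - with_partner).clip(lower=0.0)

    table = pd.DataFrame(buried)
    vals = table.to_numpy()
    main = []
    for row in vals:
        if row.max() <= 0:
            main.append(None)
        else:
            main.append(partner_chains[int(np.argmax(row))])
    table["main_partner"] = main

    present = sorted(set(int(r) for r in target.residues))
    unresolved = [
        r for r in range(present[0], present[-1] + 1) if r not in set(present)
    ]
    return InterfaceMap(target_chain=target_chain, table=table, unresolved=unresolved)


def load_structure(
    path: str,
    heavy_only: bool = True,
    radii: dict[str, float] | None = None,
) -> AtomSet:
    """Read a PDB or mmCIF file into an :class:`AtomSet` (first model).

    Alternate locations keep the highest-occupancy conformer; hydrogens are
    dropped by default (cryo-EM models typically lack them anyway).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()  # keeps highest occupancy
    if heavy_only:
        st.remove_hydrogens()
    radii = {**VDW_RADII, **(radii or {})}
    coords, rad, chains, residues, elements = [], [], [], [], []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                el = atom.element.name.upper()
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                rad.append(radii.get(el, DEFAULT_RADIUS))
                chains.append(chain.name)
                residues.append(residue.seqid.num)
                elements.append(el)
    if not coords:
        raise ValueError(f"no atoms read from {path}")
    return AtomSet(
        coords=np.array(coords),
        radii=np.array(rad),
        chains=np.array(chains),
        residues=np.array(residues),
        elements=np.array(elements),
    )
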
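"""Structures, solvent accessibility, and complex interfaces.

Parses PDB files (isolated chains or biological assemblies) into a light
per-chain residue representation, computes per-residue solvent-accessible
surface area (SASA) with a Shrake–Rupley sphere-sampling algorithm,
normalises it into relative solvent accessibility (RSA), classifies
residues as accessible (RSA >= 0.2) or buried, and detects interface
residues of a complex as those accessible in the isolated chain but
buried in the assembly.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from ._aa_data import (
    AA3_TO_AA1,
    MAX_ACC,
    STANDARD_AA,
    VDW_DEFAULT_RADIUS,
    VDW_RADII,
)
from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

ISOLATED_CHAIN = "isolated_chain"
BIOLOGICAL_ASSEMBLY = "biological_assembly"

ACCESSIBLE = "accessible"
BURIED = "buried"

#: Default RSA threshold separating accessible from buried residues.
RSA_THRESHOLD = 0.2


@dataclass
class AtomRecord:
    """One atom: label, element, Cartesian coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValidationError(f"atom {self.name}: empty element")


@dataclass
class ResidueSite:
    """One residue position within a chain.

    ``rsa`` is the reporting value, clamped to [0, 1]; ``rsa_raw`` keeps the
    unclamped ratio (extended conformations can exceed the tabulated maximum
    area).  Both stay ``None`` until computed.
    """

    chain_id: str
    seq_pos: int
    aa: str                      # one-letter code, "X" for non-standard
    atoms: list[AtomRecord] = field(default_factory=list)
    is_standard: bool = True
    sasa: float | None = None
    rsa: float | None = None
    rsa_raw: float | None = None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        heavy = self.heavy_atoms()
        if not heavy:
            return np.empty((0, 3))
        return np.stack([a.coords for a in heavy])


@dataclass
class Structure:
    """Chains of residues plus the metadata the analyses need."""

    id: str
    assembly_kind: str
    chains: dict[str, list[ResidueSite]]
    resolution: float | None = None

    def iter_residues(self):
        for residues in self.chains.values():
            yield from residues

    def get_residue(self, chain_id: str, seq_pos: int) -> ResidueSite:
        try:
            residues = self.chains[chain_id]
        except KeyError:
            raise InputError(f"chain {chain_id!r} not present in structure {self.id}") from None
        for res in residues:
            if res.seq_pos == seq_pos:
                return res
        raise InputError(f"no residue at position {seq_pos} in chain {chain_id} of {self.id}")


def _check_coordinate_lines(pdb_text: str) -> None:
    """Fail early, naming the offending line, on malformed ATOM records."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise InputError(f"malformed coordinate line {lineno}: too short")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise InputError(
                    f"malformed coordinate line {lineno}: unparseable coordinates"
                ) from None


def _pick_altloc(atom):
    """Resolve a possibly disordered atom: highest occupancy, ties by altloc id."""
    if not atom.is_disordered():
        return atom
    children = sorted(
        atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def parse_structure(
    pdb_text: str,
    assembly_kind: str = ISOLATED_CHAIN,
    structure_id: str = "struct",
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Hydrogens are parsed (and flagged); HETATM residues, including waters,
    are excluded.  Alternate locations collapse to the highest-occupancy
    atom.  The resolution is read from the REMARK 2 / header record when
    present.  Only the first model of a multi-model file is used.
    """
    if assembly_kind not in (ISOLATED_CHAIN, BIOLOGICAL_ASSEMBLY):
        raise InputError(f"unknown assembly_kind {assembly_kind!r}")
    _check_coordinate_lines(pdb_text)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_struct = parser.get_structure(structure_id, io.StringIO(pdb_text))
    models = list(bio_struct)
    if not models:
        raise InputError("no model found in PDB text")
    model = models[0]

    chains: dict[str, list[ResidueSite]] = {}
    for chain in model:
        residues: list[ResidueSite] = []
        last_pos = None
        for res in chain:
            hetflag, resseq, _icode = res.id
            if hetflag != " ":
                continue  # HETATM (ligands, waters, modified residues)
            resname = res.get_resname().strip()
            aa = AA3_TO_AA1.get(resname, "X")
            atoms = []
            for atom in res:
                a = _pick_altloc(atom)
                element = (a.element or "").strip().upper() or a.get_name().strip()[0]
                atoms.append(
                    AtomRecord(
                        name=a.get_name(),
                        element=element,
                        coords=np.array(a.get_coord(), dtype=float),
                        is_hydrogen=element in ("H", "D"),
                    )
                )
            if last_pos is not None and resseq <= last_pos:
                raise ValidationError(
                    f"chain {chain.id}: residue positions not strictly increasing at {resseq}"
                )
            last_pos = resseq
            residues.append(
                ResidueSite(
                    chain_id=chain.id,
                    seq_pos=resseq,
                    aa=aa,
                    atoms=atoms,
                    is_standard=aa in STANDARD_AA,
                )
            )
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise InputError("PDB text contains no ATOM records")

    resolution = None
    header = getattr(bio_struct, "header", None) or {}
    if header.get("resolution") is not None:
        resolution = float(header["resolution"])
    return Structure(
        id=structure_id, assembly_kind=assembly_kind, chains=chains, resolution=resolution
    )


def read_position_map(text: str) -> dict[tuple[str, int], int]:
    """Read a TSV position map (chain, pdb_pos, seq_pos), header optional."""
    mapping: dict[tuple[str, int], int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise InputError(f"position map line {lineno}: expected 3 columns")
        if lineno == 1 and not parts[1].lstrip("-").isdigit():
            continue  # header row
        chain, pdb_pos, seq_pos = parts
        mapping[(chain, int(pdb_pos))] = int(seq_pos)
    return mapping


def apply_position_map(s: Structure, mapping: dict[tuple[str, int], int]) -> Structure:
    """Renumber residues in place from author numbering to sequence positions."""
    for chain_id, residues in s.chains.items():
        for res in residues:
            key = (chain_id, res.seq_pos)
            if key in mapping:
                res.seq_pos = mapping[key]
    return s


# ---------------------------------------------------------------------------
# Shrake-Rupley solvent accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def atom_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), VDW_DEFAULT_RADIUS)


def shrake_rupley_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (Å²) by sphere sampling.

    A sample point on atom i's expanded sphere (radius r_i + probe) is
    buried if it falls inside any neighbour's expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    sphere = _sphere_points(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    rmax = expanded.max() if n_atoms else 0.0
    areas = np.zeros(n_atoms)
    for i in range(n_atoms):
        candidates = tree.query_ball_point(coords[i], expanded[i] + rmax)
        neighbours = [
            j
            for j in candidates
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]
        ]
        pts = coords[i] + expanded[i] * sphere
        if neighbours:
            nb_coords = coords[neighbours]
            nb_radii = expanded[neighbours]
            d2 = np.sum((pts[:, None, :] - nb_coords[None, :, :]) ** 2, axis=2)
            exposed = np.all(d2 >= nb_radii[None, :] ** 2, axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return areas


def compute_sasa(
    s: Structure, probe_radius: float = 1.4, n_points: int = 960
) -> Structure:
    """Fill per-residue ``sasa`` on every residue of ``s`` (in place).

    All heavy atoms of the whole structure occlude each other; hydrogens
    are excluded from the calculation entirely.
    """
    residues = list(s.iter_residues())
    coords_list, radii_list, owner = [], [], []
    for idx, res in enumerate(residues):
        heavy = res.heavy_atoms()
        if not heavy:
            raise InputError(
                f"residue {res.chain_id}:{res.seq_pos} ({res.aa}) has no heavy atoms"
            )
        for atom in heavy:
            coords_list.append(atom.coords)
            radii_list.append(atom_radius(atom.element))
            owner.append(idx)
    areas = shrake_rupley_areas(
        np.asarray(coords_list), np.asarray(radii_list), probe_radius, n_points
    )
    totals = np.zeros(len(residues))
    np.add.at(totals, np.asarray(owner), areas)
    for res, total in zip(residues, totals):
        res.sasa = float(total)
    return s


def relative_accessibility(
    s: Structure, max_acc: dict[str, float] | None = None
) -> Structure:
    """Fill per-residue RSA from SASA (in place).

    RSA is SASA divided by the residue type's maximum accessible area;
    values above 1 are clamped to 1.0 for reporting and classification,
    with the raw ratio retained in ``rsa_raw``.  Non-standard residues are
    flagged by leaving RSA undefined.
    """
    table = max_acc if max_acc is not None else MAX_ACC
    for res in s.iter_residues():
        if res.sasa is None:
            raise InputError(
                f"residue {res.chain_id}:{res.seq_pos}: SASA not computed"
            )
        if not res.is_standard:
            res.rsa = None
            res.rsa_raw = None
            logger.warning(
                "residue %s:%s is non-standard; RSA undefined", res.chain_id, res.seq_pos
            )
            continue
        raw = res.sasa / table[res.aa]
        res.rsa_raw = raw
        res.rsa = min(raw, 1.0)
    return s


def classify_accessibility(rsa: float | None, threshold: float = RSA_THRESHOLD) -> str:
    """Classify an RSA value: accessible iff RSA >= threshold (default 0.2)."""
    if rsa is None:
        raise InputError("RSA undefined; cannot classify accessibility")
    return ACCESSIBLE if rsa >= threshold else BURIED


def interface_residues(
    isolated: Structure,
    complex_structure: Structure,
    chain_id: str,
    threshold: float = RSA_THRESHOLD,
) -> set[int]:
    """Positions accessible in the isolated chain and buried in the complex.

    Both structures must carry computed RSA for the requested chain, and
    the chain must hold the same residues (position and type) in both.
    """
    for s, role in ((isolated, "isolated"), (complex_structure, "complex")):
        if chain_id not in s.chains:
            raise InputError(f"chain {chain_id!r} missing from {role} structure {s.id}")
    iso = {r.seq_pos: r for r in isolated.chains[chain_id]}
    cpx = {r.seq_pos: r for r in complex_structure.chains[chain_id]}
    mismatched = sorted(
        set(iso) ^ set(cpx)
    ) + sorted(p for p in set(iso) & set(cpx) if iso[p].aa != cpx[p].aa)
    if mismatched:
        raise ValidationError(
            f"chain {chain_id}: positions differ between isolated chain and complex: "
            f"{mismatched}"
        )
    result = set()
    for pos in iso:
        rsa_iso, rsa_cpx = iso[pos].rsa, cpx[pos].rsa
        if rsa_iso is None or rsa_cpx is None:
            if iso[pos].is_standard:
                raise InputError(f"chain {chain_id} position {pos}: RSA not computed")
            continue
        if rsa_iso >= threshold and rsa_cpx < threshold:
            result.add(pos)
    return result


def write_rsa_tsv(s: Structure, path: str | Path, threshold: float = RSA_THRESHOLD) -> None:
    """Write the per-residue accessibility table (chain, pos, aa, sasa, rsa, class)."""
    with open(path, "w") as fh:
        fh.write("chain\tpos\taa\tsasa\trsa\tclass\n")
        for res in s.iter_residues():
            if res.rsa is None:
                rsa_s, cls = "NA", "NA"
            else:
                rsa_s = f"{res.rsa:.4f}"
                cls = classify_accessibility(res.rsa, threshold)
            sasa_s = "NA" if res.sasa is None else f"{res.sasa:.2f}"
            fh.write(f"{res.chain_id}\t{res.seq_pos}\t{res.aa}\t{sasa_s}\t{rsa_s}\t{cls}\n")
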
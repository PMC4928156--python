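"""Synthetic fixtures: toy structures, planted-signal training sets,
annotation sets, interaction files, and the packaged reference tables.

Everything here is seeded and byte-reproducible.  The training-set
generator plants a known linear relation between the nine features and
ΔΔG so that regression tests can check parameter recovery; the toy
structures use idealised backbone geometry (3.6 residues/turn, 1.5 Å
rise for the helix) and emit valid PDB text that round-trips through the
parser.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._aa_data import AA1, AA1_TO_AA3
from .analysis import (
    CELLS,
    DISEASE,
    POLYMORPHISM,
    CrossTab,
    VariantAnnotation,
)
from .errors import InputError
from .features import (
    FeatureVector,
    VariantSpec,
    kd_hydropathy,
    molecular_weight,
    mutability,
    blosum62_score,
)
from .regression import TrainingRecord
from .structure import AtomRecord, ResidueSite, Structure, parse_structure

HELIX = "ideal_helix"
EXTENDED = "extended"

# Ideal alpha-helix: 3.6 residues per turn, 1.5 Å rise per residue,
# CA atoms on a 2.3 Å cylinder.
_HELIX_TWIST = 2.0 * np.pi / 3.6
_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_EXTENDED_STEP = 3.5


@dataclass
class SyntheticConfig:
    """Conditions for the planted-signal ΔΔG training generator.

    ``beta`` are the linear coefficients on the (centred) nine features;
    ``sigma`` is the Gaussian noise on ΔΔG in kcal/mol.  The defaults give
    ΔΔG values spread over roughly [-4, +4] kcal/mol, the range typical of
    experimental stability datasets.
    """

    seed: int = 0
    n_proteins: int = 10
    variants_per_protein: int = 50
    beta: tuple = (0.2, 0.15, -0.15, 0.005, 0.002, -0.002, 0.3, -1.0, 0.25)
    sigma: float = 0.1
    fraction_accessible: float = 0.5
    degree_scale: float = 50.0

    #: centring constants (approximate scale means) so planted ΔΔG has mean ~0
    feature_center: tuple = (-1.0, 0.0, 0.0, 76.0, 136.7, 136.7, 0.0, 0.5, 0.0)


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

def _atom_line(serial, name, resname, chain, resseq, xyz, element) -> str:
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {padded:<4s} {resname:<3s} {chain}{resseq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def _ca_trace(n_res: int, geometry: str) -> np.ndarray:
    i = np.arange(n_res)
    if geometry == HELIX:
        theta = _HELIX_TWIST * i
        return np.column_stack(
            [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * i]
        )
    if geometry == EXTENDED:
        return np.column_stack(
            [_EXTENDED_STEP * i, 0.9 * (-1.0) ** i, np.zeros(n_res)]
        )
    raise InputError(f"unknown geometry {geometry!r}")


def toy_pdb_text(
    n_res: int,
    geometry: str = HELIX,
    sequence: str | None = None,
    chain_id: str = "A",
    resolution: float | None = None,
    offset: np.ndarray | None = None,
    start_serial: int = 1,
    start_resseq: int = 1,
) -> str:
    """PDB text for an idealised backbone (N, CA, C, O, and CB except Gly)."""
    if n_res < 1:
        raise InputError("n_res must be >= 1")
    seq = (sequence or "A" * n_res).upper()
    if len(seq) != n_res:
        raise InputError("sequence length must equal n_res")
    ca = _ca_trace(n_res, geometry)
    if offset is not None:
        ca = ca + np.asarray(offset, dtype=float)
    lines = []
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.")
    serial = start_serial
    for i in range(n_res):
        if n_res == 1:
            prev_u = np.array([-1.0, 0.0, 0.0])
            next_u = np.array([1.0, 0.0, 0.0])
        else:
            prev_dir = ca[i] - ca[i - 1] if i > 0 else ca[i] - ca[i + 1]
            next_dir = ca[i + 1] - ca[i] if i < n_res - 1 else ca[i] - ca[i - 1]
            prev_u = prev_dir / np.linalg.norm(prev_dir)
            next_u = next_dir / np.linalg.norm(next_dir)
        radial = ca[i] - np.array([0.0, 0.0, ca[i][2]])
        norm = np.linalg.norm(radial)
        radial_u = radial / norm if norm > 1e-6 else np.array([0.0, 0.0, 1.0])
        resname = AA1_TO_AA3.get(seq[i], "ALA")
        # backbone placed in a local frame built from the CA trace
        atoms = [
            ("N", "N", ca[i] - 1.46 * prev_u),
            ("CA", "C", ca[i]),
            ("C", "C", ca[i] + 1.52 * next_u),
            ("O", "O", ca[i] + 1.52 * next_u + 1.23 * radial_u),
        ]
        if seq[i] != "G":
            atoms.append(("CB", "C", ca[i] + 1.53 * radial_u))
        for name, element, xyz in atoms:
            lines.append(
                _atom_line(serial, name, resname, chain_id, start_resseq + i, xyz, element)
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_structure(
    n_res: int,
    geometry: str = HELIX,
    seed: int = 0,
    sequence: str | None = None,
    resolution: float | None = None,
) -> tuple[Structure, str]:
    """Build a toy chain and return it parsed together with its PDB text.

    The structure is obtained by round-tripping the emitted text through
    :func:`stabilis.structure.parse_structure`, so the pair is guaranteed
    consistent.  ``seed`` is accepted for interface uniformity; the
    geometry itself is deterministic.
    """
    del seed  # geometry is deterministic
    text = toy_pdb_text(n_res, geometry, sequence=sequence, resolution=resolution)
    return parse_structure(text, structure_id=f"toy_{geometry}_{n_res}"), text


def _shell_pdb_lines(
    center: np.ndarray,
    radius: float,
    n_shell: int,
    chain_id: str,
    start_serial: int = 1000,
) -> list[str]:
    """ATOM lines for a spherical cage of CA-only glycine pseudo-residues."""
    i = np.arange(n_shell)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_shell
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = center + radius * np.column_stack(
        [rho * np.cos(theta), rho * np.sin(theta), z]
    )
    return [
        _atom_line(start_serial + k, "CA", "GLY", chain_id, k + 1, pts[k], "C")
        for k in range(n_shell)
    ]


def make_toy_complex(
    n_res: int = 9, site: int = 5, radius: float = 5.5, n_shell: int = 150
) -> tuple[Structure, Structure, str, str]:
    """An isolated helix and a 'biological assembly' that buries one site.

    The assembly adds a second chain (B): a cage of pseudo-residues around
    the heavy-atom centroid of residue ``site`` of chain A, so that site —
    solvent accessible in the isolated chain — becomes buried in the
    complex, the defining signature of an interface residue.  Chain A
    coordinates are identical in both structures.  Returns
    ``(isolated, complex, isolated_pdb_text, complex_pdb_text)``.
    """
    text_a = toy_pdb_text(n_res, HELIX, chain_id="A")
    isolated = parse_structure(text_a, assembly_kind="isolated_chain",
                               structure_id="toy_mono")
    center = isolated.get_residue("A", site).heavy_coords().mean(axis=0)
    shell = _shell_pdb_lines(center, radius, n_shell, "B")
    complex_text = text_a.replace("END\n", "") + "\n".join(shell) + "\nEND\n"
    cpx = parse_structure(complex_text, assembly_kind="biological_assembly",
                          structure_id="toy_complex")
    return isolated, cpx, text_a, complex_text


def add_occluder_shell(
    s: Structure,
    chain_id: str,
    seq_pos: int,
    radius: float = 6.0,
    n_shell: int = 250,
    shell_chain: str = "Z",
) -> Structure:
    """Return a copy of ``s`` with a spherical cage of dummy atoms around a site.

    The cage is a chain of single-atom pseudo-residues on a sphere centred
    at the target residue's heavy-atom centroid; dense enough shells bury
    the site completely.  Used to construct burial fixtures.
    """
    target = s.get_residue(chain_id, seq_pos)
    center = target.heavy_coords().mean(axis=0)
    i = np.arange(n_shell)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_shell
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = center + radius * np.column_stack(
        [rho * np.cos(theta), rho * np.sin(theta), z]
    )
    shell_residues = [
        ResidueSite(
            chain_id=shell_chain,
            seq_pos=k + 1,
            aa="G",
            atoms=[AtomRecord(name="CA", element="C", coords=pts[k])],
        )
        for k in range(n_shell)
    ]
    chains = {cid: list(residues) for cid, residues in s.chains.items()}
    chains[shell_chain] = shell_residues
    return Structure(
        id=s.id + "_shelled",
        assembly_kind=s.assembly_kind,
        chains=chains,
        resolution=s.resolution,
    )


# ---------------------------------------------------------------------------
# Training sets with a planted linear signal
# ---------------------------------------------------------------------------

def make_training_set(cfg: SyntheticConfig) -> list[TrainingRecord]:
    """Seeded training records with ΔΔG = β·(f − center) + N(0, σ).

    Features f1–f6 are derived from randomly drawn wild-type/mutant residue
    pairs through the real scales (BLOSUM62, hydropathy, mutability,
    molecular weight); the profile difference is N(0, 2), RSA is uniform
    within the accessible or buried range according to
    ``fraction_accessible``, and the contact-energy difference is N(0, 3).
    """
    rng = np.random.default_rng(cfg.seed)
    beta = np.asarray(cfg.beta, dtype=float)
    center = np.asarray(cfg.feature_center, dtype=float)
    records = []
    aa = list(AA1)
    for p in range(cfg.n_proteins):
        protein_id = f"SYN{p:04d}"
        for j in range(cfg.variants_per_protein):
            wt, mut = rng.choice(aa, size=2, replace=False)
            if rng.random() < cfg.fraction_accessible:
                rsa = rng.uniform(0.2, 1.0)
            else:
                rsa = rng.uniform(0.0, 0.2)
            fv = FeatureVector(
                blosum62_score=blosum62_score(wt, mut),
                kd_wt=kd_hydropathy(wt),
                kd_mut=kd_hydropathy(mut),
                mutability_wt=mutability(wt),
                mw_wt=molecular_weight(wt),
                mw_mut=molecular_weight(mut),
                profile_score_diff=rng.normal(0.0, 2.0),
                rsa_mut_site=rsa,
                contact_energy_diff=rng.normal(0.0, 3.0),
            )
            ddg = float(beta @ (fv.as_array() - center) + rng.normal(0.0, cfg.sigma))
            records.append(
                TrainingRecord(
                    protein_id=protein_id,
                    variant=VariantSpec(protein_id, j + 1, wt, mut),
                    features=fv,
                    ddg_exp=ddg,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Annotation sets and interactomes
# ---------------------------------------------------------------------------

def make_annotations(
    n_proteins: int = 20,
    variants_per_protein: int = 20,
    seed: int = 0,
    poly_fraction: float = 0.15,
) -> list[VariantAnnotation]:
    """Seeded annotated variants for exercising the downstream statistics.

    Disease variants draw ΔΔG from N(-1.0, 1.5) and polymorphisms from
    N(-0.3, 0.7) — a wider, more destabilising distribution for disease,
    the qualitative pattern the analyses are designed to detect.  RSA is
    uniform on [0, 1]; patch flags are likely (p = 0.7) on accessible
    sites and rare (p = 0.03) on buried ones.
    """
    rng = np.random.default_rng(seed)
    annots = []
    for p in range(n_proteins):
        protein_id = f"ANN{p:04d}"
        for j in range(variants_per_protein):
            label = POLYMORPHISM if rng.random() < poly_fraction else DISEASE
            ddg = (
                rng.normal(-0.3, 0.7) if label == POLYMORPHISM else rng.normal(-1.0, 1.5)
            )
            rsa_mono = rng.uniform(0.0, 1.0)
            rsa_cplx = max(0.0, rsa_mono - rng.uniform(0.0, 0.3))
            in_patch = rng.random() < (0.7 if rsa_mono >= 0.2 else 0.03)
            wt, mut = rng.choice(list(AA1), size=2, replace=False)
            annots.append(
                VariantAnnotation(
                    variant=VariantSpec(protein_id, j + 1, wt, mut),
                    label=label,
                    ddg_pred=float(ddg),
                    rsa_monomer=float(rsa_mono),
                    rsa_complex=float(rsa_cplx),
                    in_interface=rsa_mono >= 0.2 and rsa_cplx < 0.2,
                    in_patch=bool(in_patch),
                )
            )
    return annots


def write_annotations_tsv(annots: list[VariantAnnotation], path) -> None:
    rows = []
    for a in annots:
        rows.append(
            {
                "protein_id": a.variant.protein_id,
                "pos": a.variant.seq_pos,
                "wt": a.variant.wt,
                "mut": a.variant.mut,
                "label": a.label,
                "ddg_pred": a.ddg_pred,
                "rsa_monomer": a.rsa_monomer,
                "rsa_complex": a.rsa_complex,
                "in_interface": a.in_interface,
                "in_patch": a.in_patch,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def make_mitab_text(interactions: list[tuple[str, str, bool]]) -> str:
    """Format (id_a, id_b, negative) triples as PSI-MITAB 2.7-style lines."""
    lines = []
    for id_a, id_b, negative in interactions:
        cols = ["-"] * 42
        cols[0] = f"uniprotkb:{id_a}"
        cols[1] = f"uniprotkb:{id_b}"
        cols[11] = 'psi-mi:"MI:0915"(physical association)'
        cols[35] = "true" if negative else "false"
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def make_degree_testbed(
    n_proteins: int = 40,
    seed: int = 0,
    degree_scale: float = 50.0,
    min_variants: int = 5,
    noise_sd: float = 2.0,
) -> tuple[str, pd.DataFrame]:
    """A synthetic interactome with a planted monotone fraction–degree relation.

    Each protein gets a variant fraction uniform on [0, 1] and
    ``round(degree_scale * fraction) + N(0, noise_sd)`` distinct partners
    (floored at 0).  Returns the MITAB text together with the per-protein
    table expected by :func:`stabilis.interactome.bin_by_fraction`.
    """
    rng = np.random.default_rng(seed)
    interactions = []
    rows = []
    for p in range(n_proteins):
        pid = f"Q{p:05d}"
        fraction = rng.uniform(0.0, 1.0)
        degree = max(0, int(round(degree_scale * fraction + rng.normal(0.0, noise_sd))))
        for k in range(degree):
            interactions.append((pid, f"PART{p:04d}_{k:03d}", False))
        rows.append(
            {
                "protein_id": pid,
                "fraction": fraction,
                "n_disease_variants": int(rng.integers(min_variants, 30)),
                "true_degree": degree,
            }
        )
    return make_mitab_text(interactions), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

def load_reference_tables() -> dict[str, CrossTab]:
    """The packaged published cross-tabulation counts.

    Keys: ``monomeric_disease``, ``monomeric_polymorphism``,
    ``multimeric_disease_monomer``, ``multimeric_disease_complex``,
    ``multimeric_polymorphism_monomer``, ``multimeric_polymorphism_complex``.
    """
    raw = json.loads(
        importlib.resources.files("stabilis.data")
        .joinpath("reference_crosstabs.json")
        .read_text()
    )
    tables = {}
    for assembly in ("monomeric", "multimeric"):
        for name, entry in raw[assembly].items():
            if name == "n_proteins":
                continue
            label = DISEASE if name.startswith("disease") else POLYMORPHISM
            counts, patch = {}, {}
            for key, cell in entry["cells"].items():
                ddg_class, rsa_class = key.split("|")
                counts[(ddg_class, rsa_class)] = int(cell["count"])
                patch[(ddg_class, rsa_class)] = int(cell["patch"])
            tables[f"{assembly}_{name}"] = CrossTab.from_counts(
                label=label,
                rsa_source=entry["rsa_source"],
                counts=counts,
                patch=patch,
            )
    return tables
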
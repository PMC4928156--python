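"""The nine-dimensional input encoding of a single residue variation.

Seven sequence-derived features (BLOSUM62 substitution score, wild-type and
mutant Kyte–Doolittle hydropathy, wild-type relative mutability, wild-type
and mutant molecular weight, and the evolutionary-profile score difference)
plus two structure-derived ones: the relative solvent accessibility of the
varied site and the contact-energy difference

    sum_r [ P(r, w) - P(r, m) ]

where P is a 20x20 statistical contact potential, w and m are the wild-type
and mutant residues, and r runs over the residues whose minimal heavy-atom
distance from the varied residue is <= 5 Å in the native structure.  Mutant
coordinates are never modelled: the native structure alone enters the
encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from ._aa_data import (
    AA1,
    DAYHOFF_MUTABILITY,
    KD_HYDROPATHY,
    MOLECULAR_WEIGHT,
    check_standard,
)
from .errors import InputError, ValidationError
from .structure import ResidueSite, Structure, compute_sasa, relative_accessibility

logger = logging.getLogger(__name__)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

FEATURE_NAMES = (
    "blosum62_score",
    "kd_wt",
    "kd_mut",
    "mutability_wt",
    "mw_wt",
    "mw_mut",
    "profile_score_diff",
    "rsa_mut_site",
    "contact_energy_diff",
)


@dataclass(frozen=True)
class VariantSpec:
    """One substitution: protein, 1-based position, wild-type and mutant residue."""

    protein_id: str
    seq_pos: int
    wt: str
    mut: str

    def __post_init__(self):
        check_standard(self.wt)
        check_standard(self.mut)
        if self.seq_pos < 1:
            raise ValidationError(f"seq_pos must be 1-based positive, got {self.seq_pos}")

    def __str__(self):
        return f"{self.protein_id}:{self.wt}{self.seq_pos}{self.mut}"


@dataclass(frozen=True)
class FeatureVector:
    blosum62_score: float
    kd_wt: float
    kd_mut: float
    mutability_wt: float
    mw_wt: float
    mw_mut: float
    profile_score_diff: float
    rsa_mut_site: float
    contact_energy_diff: float

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("feature vector contains non-finite entries")
        if not 0.0 <= self.rsa_mut_site <= 1.0:
            raise ValidationError(
                f"rsa_mut_site must lie in [0, 1], got {self.rsa_mut_site}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def blosum62_score(wt: str, mut: str) -> float:
    """Symmetric BLOSUM62 substitution score."""
    check_standard(wt)
    check_standard(mut)
    return float(_BLOSUM62[wt, mut])


def kd_hydropathy(aa: str) -> float:
    """Kyte–Doolittle hydropathy of a standard residue."""
    return KD_HYDROPATHY[check_standard(aa)]


def mutability(aa: str) -> float:
    """Relative mutability index (Dayhoff convention, Ala = 100)."""
    return float(DAYHOFF_MUTABILITY[check_standard(aa)])


def molecular_weight(aa: str) -> float:
    """Average mass of the free amino acid, Da."""
    return MOLECULAR_WEIGHT[check_standard(aa)]


# ---------------------------------------------------------------------------
# Evolutionary profile
# ---------------------------------------------------------------------------

class SequenceProfile:
    """Per-position 20-vector of emission log-odds scores.

    ``scores`` has shape (L, 20) with columns in :data:`AA1` order.  When no
    alignment-derived profile is available, :meth:`pseudo_from_sequence`
    builds a single-sequence stand-in from BLOSUM62 rows; such profiles are
    flagged via ``is_pseudo`` so downstream output can note the fallback.
    """

    def __init__(self, scores: np.ndarray, is_pseudo: bool = False):
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise InputError("profile must have shape (L, 20)")
        if not np.all(np.isfinite(scores)):
            raise InputError("profile contains non-finite scores")
        self.scores = scores
        self.is_pseudo = is_pseudo

    def __len__(self):
        return self.scores.shape[0]

    def score(self, seq_pos: int, aa: str) -> float:
        if not 1 <= seq_pos <= len(self):
            raise InputError(
                f"position {seq_pos} outside profile of length {len(self)}"
            )
        return float(self.scores[seq_pos - 1, AA1.index(check_standard(aa))])

    @classmethod
    def from_tsv(cls, text: str) -> "SequenceProfile":
        """Read a per-position 20-column TSV of log-odds (header = AA order)."""
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        if not lines:
            raise InputError("empty profile file")
        header = lines[0].split("\t")
        if len(header) == 20 and all(h in AA1 for h in header):
            order = [AA1.index(h) for h in header]
            rows = lines[1:]
        else:
            order = list(range(20))
            rows = lines
        mat = []
        for lineno, row in enumerate(rows, start=1):
            parts = row.split("\t")
            if len(parts) != 20:
                raise InputError(f"profile line {lineno}: expected 20 columns")
            vals = np.array([float(p) for p in parts])
            out = np.empty(20)
            out[order] = vals
            mat.append(out)
        return cls(np.vstack(mat))

    @classmethod
    def pseudo_from_sequence(cls, seq: str) -> "SequenceProfile":
        """Single-sequence fallback: BLOSUM62 row of the residue at each site."""
        rows = []
        for aa in seq:
            check_standard(aa)
            rows.append([blosum62_score(aa, other) for other in AA1])
        return cls(np.asarray(rows), is_pseudo=True)

    @classmethod
    def from_hmm(cls, path: str | Path) -> "SequenceProfile":
        """Optional adapter: match-state emission log-odds from an HMMER3 .hmm file."""
        try:
            import pyhmmer
        except ImportError as exc:  # pragma: no cover
            raise InputError("pyhmmer is required to read .hmm profiles") from exc
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            hmm = fh.read()
        alphabet = hmm.alphabet.symbols[: hmm.alphabet.K]
        emissions = np.asarray(hmm.match_emissions)[1:]  # row 0 is the BEGIN state
        background = np.asarray(pyhmmer.plan7.Background(hmm.alphabet).residue_frequencies)
        with np.errstate(divide="ignore"):
            logodds = np.log2(np.clip(emissions, 1e-12, None) / background)
        cols = [alphabet.index(aa) for aa in AA1]
        return cls(logodds[:, cols])


def profile_score_diff(profile: SequenceProfile, v: VariantSpec) -> float:
    """Emission log-odds difference native minus mutant at the varied site.

    Because native and mutant sequences differ at a single position, the
    alignment-score difference reduces to the emission difference there
    (assuming the alignment path is unchanged).
    """
    return profile.score(v.seq_pos, v.wt) - profile.score(v.seq_pos, v.mut)


# ---------------------------------------------------------------------------
# Contact potential and the contact-energy difference
# ---------------------------------------------------------------------------

class ContactPotential:
    """Symmetric 20x20 matrix of pairwise residue contact energies."""

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (20, 20):
            raise InputError("contact potential must be 20x20")
        if not np.all(np.isfinite(matrix)):
            raise InputError("contact potential contains non-finite entries")
        if not np.allclose(matrix, matrix.T):
            raise InputError("contact potential must be symmetric")
        self.matrix = matrix

    def energy(self, aa1: str, aa2: str) -> float:
        return float(
            self.matrix[AA1.index(check_standard(aa1)), AA1.index(check_standard(aa2))]
        )

    @classmethod
    def from_tsv(cls, text: str) -> "ContactPotential":
        """Read a 20x20 TSV; first row/column may carry amino-acid labels."""
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        labelled = lines and lines[0].split("\t")[-1].strip() in set(AA1)
        if labelled:
            order = [c.strip() for c in lines[0].split("\t") if c.strip()]
            if sorted(order) != sorted(AA1):
                raise InputError("labelled contact potential must cover the 20 residues")
            mat = np.zeros((20, 20))
            for row in lines[1:]:
                parts = row.split("\t")
                r = parts[0].strip()
                vals = [float(p) for p in parts[1:]]
                for c, val in zip(order, vals):
                    mat[AA1.index(r), AA1.index(c)] = val
        else:
            mat = np.array([[float(p) for p in row.split("\t")] for row in lines])
        return cls(mat)

    @classmethod
    def default(cls) -> "ContactPotential":
        """Packaged default: a hydropathy-derived quasi-chemical potential.

        Pairs of hydrophobic residues receive favourable (negative) contact
        energies and polar/charged pairs unfavourable ones, via
        ``P(a, b) = -(kd(a) + kd(b)) / 3 - 1``, giving energies on the
        few-unit scale typical of statistical contact potentials.  Any
        published 20x20 potential can be substituted through
        :meth:`from_tsv`.
        """
        kd = np.array([KD_HYDROPATHY[a] for a in AA1])
        mat = -(kd[:, None] + kd[None, :]) / 3.0 - 1.0
        return cls(mat)


def contact_neighbors(
    s: Structure,
    chain_id: str,
    seq_pos: int,
    cutoff: float = 5.0,
    exclude_window: int = 0,
) -> list[ResidueSite]:
    """Residues whose minimal heavy-atom distance from the site is <= cutoff.

    Contacts are collected across all chains of the structure; the residue
    itself is never its own neighbour.  Sequence-adjacent residues are
    included by default (``exclude_window=0``); setting a window > 0 drops
    same-chain residues within that many sequence positions.
    """
    target = s.get_residue(chain_id, seq_pos)
    target_coords = target.heavy_coords()
    if target_coords.shape[0] == 0:
        raise InputError(f"residue {chain_id}:{seq_pos} has no heavy atoms")
    neighbours = []
    for res in s.iter_residues():
        if res is target:
            continue
        if (
            exclude_window > 0
            and res.chain_id == chain_id
            and abs(res.seq_pos - seq_pos) <= exclude_window
        ):
            continue
        coords = res.heavy_coords()
        if coords.shape[0] == 0:
            continue
        d2 = np.sum((target_coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
        if np.sqrt(d2.min()) <= cutoff:
            neighbours.append(res)
    return neighbours


def contact_energy_diff(
    potential: ContactPotential, neighbors: list[ResidueSite], v: VariantSpec
) -> float:
    """Sum over neighbours r of P(r, wt) - P(r, mut), native coordinates only.

    Multiple neighbours of the same residue type each contribute a term.
    Non-standard neighbours are skipped with a warning rather than erroring,
    since real chains contain them.
    """
    check_standard(v.wt)
    check_standard(v.mut)
    total = 0.0
    for res in neighbors:
        if not res.is_standard:
            logger.warning(
                "skipping non-standard neighbour %s:%s in contact energy",
                res.chain_id,
                res.seq_pos,
            )
            continue
        total += potential.energy(res.aa, v.wt) - potential.energy(res.aa, v.mut)
    return total


def build_feature_vector(
    seq: str,
    profile: SequenceProfile,
    structure: Structure,
    potential: ContactPotential,
    v: VariantSpec,
    chain_id: str | None = None,
    cutoff: float = 5.0,
) -> FeatureVector:
    """Assemble the nine features for one variant.

    The wild-type residue must match both the sequence and the structure at
    the varied position (guarding against numbering drift).  RSA is computed
    on demand if the structure does not carry it yet.
    """
    if not 1 <= v.seq_pos <= len(seq):
        raise InputError(f"position {v.seq_pos} outside sequence of length {len(seq)}")
    if seq[v.seq_pos - 1] != v.wt:
        raise ValidationError(
            f"{v}: sequence has {seq[v.seq_pos - 1]} at position {v.seq_pos}, expected {v.wt}"
        )
    if chain_id is None:
        chain_id = next(iter(structure.chains))
    site = structure.get_residue(chain_id, v.seq_pos)
    if site.aa != v.wt:
        raise ValidationError(
            f"{v}: structure has {site.aa} at {chain_id}:{v.seq_pos}, expected {v.wt}"
        )
    if site.rsa is None:
        compute_sasa(structure)
        relative_accessibility(structure)
    neighbours = contact_neighbors(structure, chain_id, v.seq_pos, cutoff=cutoff)
    return FeatureVector(
        blosum62_score=blosum62_score(v.wt, v.mut),
        kd_wt=kd_hydropathy(v.wt),
        kd_mut=kd_hydropathy(v.mut),
        mutability_wt=mutability(v.wt),
        mw_wt=molecular_weight(v.wt),
        mw_mut=molecular_weight(v.mut),
        profile_score_diff=profile_score_diff(profile, v),
        rsa_mut_site=site.rsa,
        contact_energy_diff=contact_energy_diff(potential, neighbours, v),
    )
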
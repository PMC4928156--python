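"""Downstream statistics relating predicted ΔΔG to structural properties.

Variants are classified as perturbing (|ΔΔG| > 1 kcal/mol) or
non-perturbing (|ΔΔG| <= 1), and as solvent accessible (RSA >= 0.2) or
buried, then cross-tabulated per phenotype label (disease vs polymorphism)
with per-cell percentages and interaction-patch counts.  Headline
fractions pool the monomeric- and multimeric-assembly tables.  Percentage
rounding is half-up: one decimal for table cells, nearest integer for
headline values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .features import VariantSpec
from .structure import RSA_THRESHOLD

logger = logging.getLogger(__name__)

DISEASE = "disease"
POLYMORPHISM = "polymorphism"

PERTURBING = "perturbing"
NON_PERTURBING = "non_perturbing"

#: CrossTab cell keys: (ΔΔG class, RSA class)
CELLS = (
    (NON_PERTURBING, "accessible"),
    (NON_PERTURBING, "buried"),
    (PERTURBING, "accessible"),
    (PERTURBING, "buried"),
)

PERTURB_THRESHOLD = 1.0  # kcal/mol on |ΔΔG|


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention behind printed tables)."""
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(exp, rounding=ROUND_HALF_UP))


def classify_perturbing(ddg_pred: float, threshold: float = PERTURB_THRESHOLD) -> str:
    """Non-perturbing iff |ΔΔG| <= threshold (boundary inside non-perturbing)."""
    if not np.isfinite(ddg_pred):
        raise InputError(f"ddg_pred must be finite, got {ddg_pred}")
    return NON_PERTURBING if abs(ddg_pred) <= threshold else PERTURBING


@dataclass
class VariantAnnotation:
    """One annotated variant — the row atom of every downstream statistic."""

    variant: VariantSpec
    label: str
    ddg_pred: float
    rsa_monomer: float
    rsa_complex: float | None = None
    in_interface: bool | None = None
    in_patch: bool | None = None

    def __post_init__(self):
        if self.label not in (DISEASE, POLYMORPHISM):
            raise InputError(f"unknown label {self.label!r}")
        if not np.isfinite(self.ddg_pred):
            raise InputError("ddg_pred must be finite")
        for name in ("rsa_monomer", "rsa_complex"):
            val = getattr(self, name)
            if val is not None and not 0.0 <= val <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {val}")


@dataclass
class ProteinMeta:
    """Per-protein structural metadata used by the dataset filters."""

    protein_id: str
    structure_coverage: float
    resolution: float | None
    assembly: str = "monomeric"
    n_disease_variants: int = 0
    n_poly_variants: int = 0

    def __post_init__(self):
        if not 0.0 <= self.structure_coverage <= 1.0:
            raise InputError("structure_coverage must lie in [0, 1]")


def filter_structural(
    metas: list[ProteinMeta],
    min_coverage: float = 0.70,
    max_resolution: float = 3.0,
) -> list[ProteinMeta]:
    """Keep proteins with coverage >= 70 % and resolution strictly below 3.0 Å."""
    kept = []
    for meta in metas:
        if meta.resolution is None:
            logger.warning("%s: missing resolution; excluded", meta.protein_id)
            continue
        if meta.structure_coverage >= min_coverage and meta.resolution < max_resolution:
            kept.append(meta)
    return kept


@dataclass
class CrossTab:
    """2x2 counts over ΔΔG class x RSA class, with patch counts per cell."""

    label: str
    rsa_source: str  # "monomer" or "complex"
    counts: dict = field(default_factory=dict)
    patch: dict = field(default_factory=dict)

    def __post_init__(self):
        for cell in CELLS:
            self.counts.setdefault(cell, 0)
            self.patch.setdefault(cell, 0)

    @property
    def total(self) -> int:
        return sum(self.counts[c] for c in CELLS)

    def percentages(self) -> dict:
        """Per-cell percentage of table total, half-up to one decimal."""
        if self.total == 0:
            raise InputError("cannot compute percentages of an empty cross-tabulation")
        return {c: round_half_up(100.0 * self.counts[c] / self.total, 1) for c in CELLS}

    def to_dict(self) -> dict:
        pct = self.percentages() if self.total else {c: None for c in CELLS}
        return {
            "label": self.label,
            "rsa_source": self.rsa_source,
            "total": self.total,
            "cells": {
                f"{ddg}|{rsa}": {
                    "count": self.counts[(ddg, rsa)],
                    "pct": pct[(ddg, rsa)],
                    "patch": self.patch[(ddg, rsa)],
                }
                for ddg, rsa in CELLS
            },
        }

    @classmethod
    def from_counts(cls, label, rsa_source, counts, patch=None) -> "CrossTab":
        tab = cls(label=label, rsa_source=rsa_source)
        tab.counts.update(counts)
        if patch:
            tab.patch.update(patch)
        return tab


def crosstab(
    annotations: list[VariantAnnotation],
    label: str,
    rsa_source: str = "monomer",
    perturb_threshold: float = PERTURB_THRESHOLD,
    rsa_threshold: float = RSA_THRESHOLD,
) -> CrossTab:
    """Cross-tabulate annotations of one phenotype label.

    ``rsa_source`` selects whether accessibility refers to the isolated
    chain ("monomer") or the biological assembly ("complex").
    """
    tab = CrossTab(label=label, rsa_source=rsa_source)
    for ann in annotations:
        if ann.label != label:
            continue
        if rsa_source == "monomer":
            rsa = ann.rsa_monomer
        elif rsa_source == "complex":
            if ann.rsa_complex is None:
                raise InputError(f"{ann.variant}: rsa_complex requested but missing")
            rsa = ann.rsa_complex
        else:
            raise InputError(f"unknown rsa_source {rsa_source!r}")
        ddg_class = classify_perturbing(ann.ddg_pred, perturb_threshold)
        rsa_class = "accessible" if rsa >= rsa_threshold else "buried"
        tab.counts[(ddg_class, rsa_class)] += 1
        if ann.in_patch:
            tab.patch[(ddg_class, rsa_class)] += 1
    if tab.total == 0:
        raise InputError(f"no annotations with label {label!r}")
    return tab


def _sum_cells(tabs: list[CrossTab], ddg_class=None, rsa_class=None, patch=False) -> int:
    total = 0
    for tab in tabs:
        for ddg, rsa in CELLS:
            if ddg_class is not None and ddg != ddg_class:
                continue
            if rsa_class is not None and rsa != rsa_class:
                continue
            total += tab.patch[(ddg, rsa)] if patch else tab.counts[(ddg, rsa)]
    return total


def headline_fractions(
    disease_tabs: list[CrossTab], poly_tabs: list[CrossTab]
) -> dict:
    """Pool cross-tabulations into the headline percentages.

    Non-perturbing / perturbing fractions per label (integer percent,
    half-up) plus the accessible share among non-perturbing disease
    variants (one decimal — its printed counterpart is a rounded
    approximation, so the exact value is exposed rather than asserted).
    """
    out = {}
    for name, tabs in (("disease", disease_tabs), ("polymorphism", poly_tabs)):
        total = sum(t.total for t in tabs)
        if total == 0:
            raise InputError(f"no {name} annotations to summarise")
        nonpert = _sum_cells(tabs, ddg_class=NON_PERTURBING)
        out[f"nonperturbing_{name}_pct"] = round_half_up(100.0 * nonpert / total)
        out[f"perturbing_{name}_pct"] = round_half_up(100.0 * (total - nonpert) / total)
    nonpert_disease = _sum_cells(disease_tabs, ddg_class=NON_PERTURBING)
    acc_nonpert = _sum_cells(disease_tabs, ddg_class=NON_PERTURBING, rsa_class="accessible")
    out["accessible_share_of_nonperturbing_disease_pct"] = round_half_up(
        100.0 * acc_nonpert / nonpert_disease, 1
    )
    return out


def patch_fraction_accessible(disease_tabs: list[CrossTab]) -> float:
    """Percent of accessible disease variants predicted inside an interaction patch.

    Pools the accessible cells (both ΔΔG classes) of the given disease
    tables; integer percent, half-up.
    """
    patch = _sum_cells(disease_tabs, rsa_class="accessible", patch=True)
    count = _sum_cells(disease_tabs, rsa_class="accessible")
    if count == 0:
        raise InputError("no accessible variants in the given tables")
    return round_half_up(100.0 * patch / count)


# ---------------------------------------------------------------------------
# Figure-data summaries
# ---------------------------------------------------------------------------

def ddg_distribution(
    annotations: list[VariantAnnotation], bin_edges
) -> pd.DataFrame:
    """Per-label frequency distribution of |ΔΔG| over the given bins.

    Frequencies within each label sum to 1 (variants outside the binned
    range are clipped into the end bins).
    """
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for label in (DISEASE, POLYMORPHISM):
        vals = np.array([abs(a.ddg_pred) for a in annotations if a.label == label])
        if vals.size == 0:
            continue
        clipped = np.clip(vals, edges[0], np.nextafter(edges[-1], -np.inf))
        hist, _ = np.histogram(clipped, bins=edges)
        freqs = hist / vals.size
        for lo, hi, freq in zip(edges[:-1], edges[1:], freqs):
            rows.append({"label": label, "bin_lo": lo, "bin_hi": hi, "freq": freq})
    return pd.DataFrame(rows, columns=["label", "bin_lo", "bin_hi", "freq"])


def rsa_by_ddg_bins(
    annotations: list[VariantAnnotation], bin_edges, rsa_source: str = "monomer"
) -> pd.DataFrame:
    """Median and quartiles of RSA per signed-ΔΔG interval (boxplot data).

    Quartiles use the linear-interpolation (type-7) convention.
    """
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        rsas = []
        for a in annotations:
            rsa = a.rsa_monomer if rsa_source == "monomer" else a.rsa_complex
            if rsa is None:
                continue
            inside = lo <= a.ddg_pred < hi or (last and a.ddg_pred == hi)
            if inside:
                rsas.append(rsa)
        if rsas:
            q1, med, q3 = np.percentile(rsas, [25, 50, 75])
            rows.append(
                {"bin_lo": lo, "bin_hi": hi, "n": len(rsas),
                 "q1": q1, "median": med, "q3": q3}
            )
        else:
            rows.append(
                {"bin_lo": lo, "bin_hi": hi, "n": 0,
                 "q1": np.nan, "median": np.nan, "q3": np.nan}
            )
    return pd.DataFrame(rows)


def accessible_fraction_by_ddg(
    annotations: list[VariantAnnotation],
    bin_edges,
    rsa_threshold: float = RSA_THRESHOLD,
) -> pd.DataFrame:
    """Fraction of solvent-accessible variants per |ΔΔG| bin and label."""
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for label in (DISEASE, POLYMORPHISM):
        subset = [a for a in annotations if a.label == label]
        for lo, hi in zip(edges[:-1], edges[1:]):
            last = hi == edges[-1]
            in_bin = [
                a for a in subset
                if lo <= abs(a.ddg_pred) < hi or (last and abs(a.ddg_pred) == hi)
            ]
            if in_bin:
                frac = np.mean([a.rsa_monomer >= rsa_threshold for a in in_bin])
            else:
                frac = np.nan
            rows.append(
                {"label": label, "bin_lo": lo, "bin_hi": hi,
                 "n": len(in_bin), "accessible_fraction": frac}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Annotation table I/O
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("protein_id", "pos", "wt", "mut", "label", "ddg_pred", "rsa_monomer")


def read_annotations(path: str | Path) -> list[VariantAnnotation]:
    """Read an annotation TSV; optional columns rsa_complex, in_interface, in_patch."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"annotation table missing columns: {missing}")
    annots = []
    for row in df.itertuples(index=False):
        annots.append(
            VariantAnnotation(
                variant=VariantSpec(row.protein_id, int(row.pos), row.wt, row.mut),
                label=row.label,
                ddg_pred=float(row.ddg_pred),
                rsa_monomer=float(row.rsa_monomer),
                rsa_complex=(
                    float(row.rsa_complex)
                    if "rsa_complex" in df.columns and pd.notna(row.rsa_complex)
                    else None
                ),
                in_interface=(
                    bool(row.in_interface)
                    if "in_interface" in df.columns and pd.notna(row.in_interface)
                    else None
                ),
                in_patch=(
                    bool(row.in_patch)
                    if "in_patch" in df.columns and pd.notna(row.in_patch)
                    else None
                ),
            )
        )
    return annots


def write_crosstabs_json(tabs: dict, headlines: dict, path: str | Path) -> None:
    payload = {
        "tables": {name: tab.to_dict() for name, tab in tabs.items()},
        "headlines": headlines,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
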
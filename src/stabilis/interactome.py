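"""Partner counting from PSI-MITAB interaction records.

Physical-interaction partners per protein are counted as distinct
interactor accessions over non-negative records, matching queries by
UniProtKB accession (isoform suffixes collapsed to the parent entry).
Per-protein partner counts are then related to per-protein variant
statistics by binning proteins on a variant fraction and summarising the
degree distribution inside each bin.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

#: Minimum MITAB column count accepted (PSI-MITAB 2.5).
_MIN_COLUMNS = 15
#: 0-based index of the "negative" column in PSI-MITAB 2.6+.
_NEGATIVE_COLUMN = 35


@dataclass(frozen=True)
class InteractionRecord:
    """One binary interaction line: two interactor ids and a negative flag."""

    id_a: str
    id_b: str
    negative: bool = False
    line_no: int = 0

    def __post_init__(self):
        if not self.id_a or not self.id_b:
            raise InputError(f"line {self.line_no}: empty interactor id")


def _extract_accession(fields: str) -> str:
    """Pull the UniProtKB accession out of a MITAB identifier field.

    Fields look like ``uniprotkb:P12345`` (possibly ``|``-separated
    alternatives).  Isoform suffixes (``P12345-2``) collapse to the parent
    accession; non-UniProt ids are kept verbatim.
    """
    for part in fields.split("|"):
        part = part.strip()
        if part.lower().startswith("uniprotkb:"):
            acc = part.split(":", 1)[1]
            return acc.split("-")[0]
    return fields.strip()


def parse_mitab(text: str) -> list[InteractionRecord]:
    """Parse PSI-MITAB 2.5/2.7 text; short lines are skipped with a warning."""
    records = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if cols[0].lower().startswith(("id(s) interactor", "#id")):
            continue  # header
        if len(cols) < _MIN_COLUMNS:
            logger.warning(
                "MITAB line %d: expected >= %d columns, got %d; skipped",
                line_no, _MIN_COLUMNS, len(cols),
            )
            continue
        negative = False
        if len(cols) > _NEGATIVE_COLUMN:
            negative = cols[_NEGATIVE_COLUMN].strip().lower() == "true"
        records.append(
            InteractionRecord(
                id_a=_extract_accession(cols[0]),
                id_b=_extract_accession(cols[1]),
                negative=negative,
                line_no=line_no,
            )
        )
    return records


@dataclass
class DegreeTable:
    """Distinct-partner counts per query protein.

    ``has_data`` marks proteins that appear in at least one non-negative
    record; proteins absent from the interaction file keep count 0 and are
    flagged so downstream filters can exclude them ("no interactomic
    data").  A self-interaction contributes the protein itself as one
    partner.
    """

    counts: dict
    has_data: dict

    def degree(self, protein_id: str) -> int:
        return self.counts.get(protein_id, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": list(self.counts),
                "degree": [self.counts[p] for p in self.counts],
                "has_data": [self.has_data[p] for p in self.counts],
            }
        )


def count_partners(
    records: list[InteractionRecord], protein_ids: list[str]
) -> DegreeTable:
    """Distinct interaction partners per query id over non-negative records."""
    partners: dict[str, set] = {p: set() for p in protein_ids}
    seen: dict[str, bool] = {p: False for p in protein_ids}
    for rec in records:
        if rec.negative:
            continue
        for query, other in ((rec.id_a, rec.id_b), (rec.id_b, rec.id_a)):
            if query in partners:
                partners[query].add(other)
                seen[query] = True
    for p, found in seen.items():
        if not found:
            logger.warning("%s: no interactomic data", p)
    return DegreeTable(
        counts={p: len(s) for p, s in partners.items()},
        has_data=seen,
    )


def bin_by_fraction(
    per_protein: pd.DataFrame,
    bin_edges=None,
    min_variants: int = 5,
) -> pd.DataFrame:
    """Degree statistics per variant-fraction bin.

    ``per_protein`` needs columns ``fraction`` (in [0, 1]), ``degree`` and
    ``n_disease_variants``; an optional boolean ``has_data`` column marks
    proteins with interactomic evidence.  Proteins with fewer than
    ``min_variants`` disease variants or without interactomic data are
    excluded.  Bins are right-closed deciles by default; each kept bin
    reports median, quartiles (type-7) and mean of the partner count.
    """
    required = {"fraction", "degree", "n_disease_variants"}
    missing = required - set(per_protein.columns)
    if missing:
        raise InputError(f"per-protein table missing columns: {sorted(missing)}")
    frac = per_protein["fraction"].to_numpy(float)
    if np.any((frac < 0) | (frac > 1)):
        raise InputError("fractions must lie in [0, 1]")
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 11)
    edges = np.asarray(bin_edges, dtype=float)

    keep = per_protein["n_disease_variants"].to_numpy() >= min_variants
    if "has_data" in per_protein.columns:
        keep &= per_protein["has_data"].to_numpy(bool)
    keep &= np.isfinite(per_protein["degree"].to_numpy(float))
    kept = per_protein[keep]
    n_excluded = len(per_protein) - len(kept)
    logger.info("binning %d proteins (%d excluded)", len(kept), n_excluded)

    rows = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        if i == 0:
            mask = (kept["fraction"] >= lo) & (kept["fraction"] <= hi)
        else:  # right-closed bins (lo, hi]
            mask = (kept["fraction"] > lo) & (kept["fraction"] <= hi)
        degrees = kept.loc[mask, "degree"].to_numpy(float)
        if degrees.size:
            q1, med, q3 = np.percentile(degrees, [25, 50, 75])
            rows.append(
                {"bin_lo": lo, "bin_hi": hi, "n": degrees.size,
                 "q1": q1, "median": med, "q3": q3, "mean": degrees.mean()}
            )
        else:
            rows.append(
                {"bin_lo": lo, "bin_hi": hi, "n": 0,
                 "q1": np.nan, "median": np.nan, "q3": np.nan, "mean": np.nan}
            )
    result = pd.DataFrame(rows)
    result.attrs["n_binned"] = int(len(kept))
    result.attrs["n_excluded"] = int(n_excluded)
    return result


def write_degree_tsv(table: DegreeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_bin_stats_json(stats: pd.DataFrame, path: str | Path) -> None:
    payload = {
        "n_binned": stats.attrs.get("n_binned"),
        "n_excluded": stats.attrs.get("n_excluded"),
        "bins": stats.where(pd.notna(stats), None).to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
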
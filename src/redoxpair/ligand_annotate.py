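"""Overlay chemoproteomic ligandability annotations onto scored pairs.

Ligandability tables are sequence-indexed (accession + canonical 1-based
residue), as chemoproteomic competition datasets report them, so the join is
exact on the canonical coordinates assigned by the mapping module.  A pair
is ligandable when either of its cysteines is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "LigandabilityRecord",
    "load_ligandability_table",
    "annotate",
    "export_results",
]

_TRUE_TOKENS = {"true", "1", "yes", "y", "t"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f"}


@dataclass
class LigandabilityRecord:
    accession: str
    residue: int
    ligandable: bool
    compound_ids: tuple[str, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        if self.residue < 1:
            raise ValueError("residue numbering is 1-based")
        if self.ligandable and not self.compound_ids:
            raise ValueError(
                f"{self.accession}:{self.residue} marked ligandable without compounds"
            )


def _parse_bool(token: str) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ValueError(f"unrecognised ligandable flag {token!r}")


def load_ligandability_table(
    path: str | Path,
) -> tuple[list[LigandabilityRecord], list[str]]:
    """Load and validate a ligandability TSV.

    Expected columns: accession, residue, ligandable, compounds
    (';'-separated), source.  Malformed rows are reported, not fatal;
    duplicate (accession, residue) rows merge their compound sets.
    Returns ``(records, row_errors)``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"accession", "residue", "ligandable"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ligandability table lacks columns {sorted(missing)}")
    merged: dict[tuple[str, int], LigandabilityRecord] = {}
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            residue = int(str(row["residue"]).strip())
            ligandable = _parse_bool(row["ligandable"])
            compounds = tuple(
                sorted({c.strip() for c in str(row.get("compounds", "")).split(";") if c.strip()})
            )
            rec = LigandabilityRecord(
                accession=str(row["accession"]).strip(),
                residue=residue,
                ligandable=ligandable,
                compound_ids=compounds,
                source=str(row.get("source", "")).strip(),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
            continue
        key = (rec.accession, rec.residue)
        if key in merged:
            prev = merged[key]
            merged[key] = LigandabilityRecord(
                accession=rec.accession,
                residue=rec.residue,
                ligandable=prev.ligandable or rec.ligandable,
                compound_ids=tuple(sorted(set(prev.compound_ids) | set(rec.compound_ids))),
                source=prev.source if prev.source else rec.source,
            )
        else:
            merged[key] = rec
    return list(merged.values()), errors


def annotate(
    pairs: pd.DataFrame, records: Sequence[LigandabilityRecord]
) -> pd.DataFrame:
    """Join ligandability onto scored pairs by (accession, canonical residue).

    ``pairs`` must carry accession_a/canon_res_a and accession_b/canon_res_b
    columns.  Unmatched sides are not ligandable with no compounds.  Scores
    and descriptors are never altered.
    """
    index = {(r.accession, r.residue): r for r in records}
    out = pairs.copy()
    lig_a, lig_b, lig_pair, compounds = [], [], [], []
    for _, row in out.iterrows():
        rec_a = index.get((row["accession_a"], int(row["canon_res_a"])))
        rec_b = index.get((row["accession_b"], int(row["canon_res_b"])))
        a = bool(rec_a.ligandable) if rec_a else False
        b = bool(rec_b.ligandable) if rec_b else False
        merged: set[str] = set()
        if rec_a:
            merged |= set(rec_a.compound_ids)
        if rec_b:
            merged |= set(rec_b.compound_ids)
        lig_a.append(a)
        lig_b.append(b)
        lig_pair.append(a or b)
        compounds.append(";".join(sorted(merged)))
    out["ligandable_a"] = lig_a
    out["ligandable_b"] = lig_b
    out["pair_ligandable"] = lig_pair
    out["compounds"] = compounds
    return out


def export_results(
    annotated: pd.DataFrame,
    path: str | Path,
    format: str = "tsv",
    provenance: dict | None = None,
) -> Path:
    """Write annotated pairs, sorted by descending redox score then pair key.

    TSV output carries the provenance block (model hash, config) as leading
    '#' comment lines; JSON mirrors the same fields.  An empty result set is
    an error: no empty files are written.
    """
    if annotated.empty:
        raise ValueError("refusing to export an empty result set")
    sort_cols = [c for c in ("redox_score",) if c in annotated.columns]
    key_cols = [
        c
        for c in ("accession_a", "canon_res_a", "accession_b", "canon_res_b")
        if c in annotated.columns
    ]
    out = annotated.sort_values(
        sort_cols + key_cols,
        ascending=[False] * len(sort_cols) + [True] * len(key_cols),
        kind="mergesort",
    ).reset_index(drop=True)
    path = Path(path)
    if format == "tsv":
        with path.open("w") as fh:
            if provenance:
                fh.write(f"# provenance: {json.dumps(provenance, sort_keys=True)}\n")
            out.to_csv(fh, sep="\t", index=False)
    elif format == "json":
        payload = {
            "provenance": provenance or {},
            "pairs": out.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path
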
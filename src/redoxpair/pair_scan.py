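"""Enumerate cysteine pairs whose thiols fall within the screening threshold.

The screen keeps every unordered pair of resolved S gamma atoms strictly
closer than ``max_distance`` (default 10 A), classifies each pair as
intramolecular (same chain) or intermolecular, and flags pairs that are
disulphide-bound — either geometrically (S gamma separation at or below
``ss_max``, default 2.5 A; a covalent S-S bond is ~2.05 A) or by a declared
SSBOND / struct_conn record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import CysteineSite, Structure, extract_cysteine_sites

__all__ = ["CysteinePair", "scan_pairs", "is_disulphide_bound", "pairs_to_frame"]


@dataclass
class CysteinePair:
    site_a: CysteineSite
    site_b: CysteineSite
    sg_distance: float
    topology: str  # "intramolecular" | "intermolecular"
    disulphide_bound: bool = False
    hetero_entity: bool = False

    @property
    def key(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        return (self.site_a.key, self.site_b.key)


def _order_sites(a: CysteineSite, b: CysteineSite) -> tuple[CysteineSite, CysteineSite]:
    return (a, b) if (a.chain_id, a.auth_seq, a.icode) <= (b.chain_id, b.auth_seq, b.icode) else (b, a)


def is_disulphide_bound(
    pair: "CysteinePair", s: Structure, ss_max: float = 2.5
) -> bool:
    """True iff the pair is covalently bonded by geometry or declared record."""
    if ss_max <= 0:
        raise ValueError("ss_max must be positive")
    if pair.sg_distance <= ss_max:
        return True
    return s.has_ss_bond(pair.site_a.key, pair.site_b.key)


def scan_pairs(
    s: Structure,
    max_distance: float = 10.0,
    ss_max: float = 2.5,
    include_modified: bool = False,
    sites: list[CysteineSite] | None = None,
) -> list[CysteinePair]:
    """All unordered cysteine pairs with S gamma separation < ``max_distance``.

    Modified cysteines (oxidised, alkylated, selenocysteine) are excluded by
    default; sites without a resolved S gamma never pair.  Output order is
    deterministic: sorted by the canonical (chain, residue) keys of the pair.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    if sites is None:
        sites = extract_cysteine_sites(s)
    usable = [
        site
        for site in sites
        if site.has_resolved_sg and (include_modified or not site.modified)
    ]
    usable.sort(key=lambda x: x.key)
    if len(usable) < 2:
        return []

    coords = np.array([site.sg.coords for site in usable])
    tree = cKDTree(coords)
    pairs: list[CysteinePair] = []
    for i, j in tree.query_pairs(max_distance):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if not (0.0 < d < max_distance):  # strict threshold; coincident SG is degenerate
            continue
        a, b = _order_sites(usable[i], usable[j])
        ent_a = s.chain_entity.get(a.chain_id)
        ent_b = s.chain_entity.get(b.chain_id)
        pair = CysteinePair(
            site_a=a,
            site_b=b,
            sg_distance=d,
            topology="intramolecular" if a.chain_id == b.chain_id else "intermolecular",
            hetero_entity=ent_a is not None and ent_b is not None and ent_a != ent_b,
        )
        pair.disulphide_bound = is_disulphide_bound(pair, s, ss_max=ss_max)
        pairs.append(pair)
    pairs.sort(key=lambda p: p.key)
    return pairs


def pairs_to_frame(s: Structure, pairs: list[CysteinePair]):
    """Tabulate scanned pairs (one row per pair) for TSV interchange.

    Carries the flanking windows and source organisms so downstream mapping
    and taxonomy filtering need not re-read the structure files.
    """
    import pandas as pd

    rows = []
    for p in pairs:
        rows.append(
            {
                "structure_id": s.structure_id,
                "chain_a": p.site_a.chain_id,
                "auth_seq_a": p.site_a.auth_seq,
                "icode_a": p.site_a.icode,
                "chain_b": p.site_b.chain_id,
                "auth_seq_b": p.site_b.auth_seq,
                "icode_b": p.site_b.icode,
                "sg_distance": p.sg_distance,
                "topology": p.topology,
                "disulphide_bound": p.disulphide_bound,
                "hetero_entity": p.hetero_entity,
                "flank_a": p.site_a.flank,
                "flank_b": p.site_b.flank,
                "flank_halfwidth": p.site_a.flank_halfwidth,
                "source_organisms": ";".join(s.source_organisms),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "structure_id", "chain_a", "auth_seq_a", "icode_a",
            "chain_b", "auth_seq_b", "icode_b", "sg_distance", "topology",
            "disulphide_bound", "hetero_entity", "flank_a", "flank_b",
            "flank_halfwidth", "source_organisms",
        ],
    )
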
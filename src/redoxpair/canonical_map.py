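"""Map structure-local cysteines onto canonical reference numbering.

Author numbering in deposited structures rarely matches the reference
(UniProt-style) sequence coordinate system, so cysteines are located in the
reference by exact matching of their observed-sequence flanking window, with
'X' (unresolved) treated as a wildcard.  Window half-widths escalate
(default 10, 15, 20) until exactly one match across all supplied references
is found; zero or multiple matches at every width leave the site unmapped —
ambiguity is surfaced, never guessed.

Pairs seen in several structures are de-duplicated onto their canonical key,
keeping the structure with the shortest thiol separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .config import MAMMAL_KEYWORDS
from .structure_io import CysteineSite

__all__ = [
    "ReferenceSequence",
    "CanonicalPair",
    "read_reference_fasta",
    "map_site_to_reference",
    "deduplicate_pairs",
    "taxonomy_filter",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYUX")


@dataclass
class ReferenceSequence:
    accession: str
    sequence: str
    description: str = ""
    taxon: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty reference sequence {self.accession}")
        bad = set(self.sequence) - _AA_ALPHABET
        if bad:
            raise ValueError(f"{self.accession}: invalid residue codes {sorted(bad)}")


def _parse_header_accession(header: str) -> str:
    # UniProt-style "sp|P12955|PEPD_HUMAN ..." or "tr|...|..." or bare accession
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in {"sp", "tr"}:
        return parts[1]
    return token


def _parse_header_taxon(header: str) -> str | None:
    if "OS=" in header:
        tail = header.split("OS=", 1)[1]
        for stop in (" OX=", " GN=", " PE=", " SV="):
            if stop in tail:
                tail = tail.split(stop, 1)[0]
        return tail.strip() or None
    return None


def read_reference_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read reference sequences; accepts UniProt-style and bare headers."""
    refs = []
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.description
        refs.append(
            ReferenceSequence(
                accession=_parse_header_accession(header),
                sequence=str(record.seq),
                description=header,
                taxon=_parse_header_taxon(header),
            )
        )
    if not refs:
        raise ValueError(f"no sequences in {path}")
    return refs


def _window_matches(window: str, sequence: str) -> list[int]:
    """0-based start offsets where window matches exactly, 'X' wildcard."""
    w = len(window)
    solid = [(i, c) for i, c in enumerate(window) if c != "X"]
    hits = []
    for start in range(len(sequence) - w + 1):
        if all(sequence[start + i] == c for i, c in solid):
            hits.append(start)
    return hits


def map_site_to_reference(
    site: CysteineSite,
    refs: Sequence[ReferenceSequence],
    halfwidths: Sequence[int] = (10, 15, 20),
) -> tuple[str, int] | None:
    """Locate a cysteine in the references by its flanking window.

    Returns ``(accession, 1-based position)`` when exactly one reference
    position matches at some half-width, or None.  The matched reference
    residue must itself be a cysteine (or selenocysteine).
    """
    if not refs:
        raise ValueError("no reference sequences supplied")
    for hw in halfwidths:
        window = site.flank_window(hw)
        # terminal wildcards may overhang the reference ends: match only the
        # solid-flanked core and keep track of the centre offset
        n_lead = len(window) - len(window.lstrip("X"))
        trimmed = window.strip("X")
        if not trimmed:
            continue
        hits: list[tuple[str, int]] = []
        for ref in refs:
            for start in _window_matches(trimmed, ref.sequence):
                pos = start + (hw - n_lead) + 1  # centre, 1-based
                if ref.sequence[pos - 1] in {"C", "U"}:
                    hits.append((ref.accession, pos))
        unique = sorted(set(hits))
        if len(unique) == 1:
            return unique[0]
    return None


@dataclass
class CanonicalPair:
    accession_a: str
    canon_res_a: int
    accession_b: str
    canon_res_b: int
    topology: str
    representative_structure_id: str
    representative_distance: float
    n_structures_observed: int = 1
    disulphide_bound: bool = False
    source_organisms: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, int, str, int]:
        return canonical_pair_key(
            self.accession_a, self.canon_res_a, self.accession_b, self.canon_res_b
        )


def canonical_pair_key(
    acc_a: str, res_a: int, acc_b: str, res_b: int
) -> tuple[str, int, str, int]:
    """Order-independent pair key (lexicographic canonicalisation)."""
    if (acc_a, res_a) <= (acc_b, res_b):
        return (acc_a, res_a, acc_b, res_b)
    return (acc_b, res_b, acc_a, res_a)


def deduplicate_pairs(records: Iterable[dict]) -> list[dict]:
    """Collapse multi-structure observations onto one record per canonical key.

    Each record is a mapping with at least ``key`` (canonical pair key),
    ``structure_id`` and ``distance``.  The record with minimal distance is
    kept (ties break to the lexicographically smallest structure_id) and
    annotated with ``n_structures_observed``.
    """
    groups: dict[tuple, list[dict]] = {}
    for rec in records:
        groups.setdefault(tuple(rec["key"]), []).append(rec)
    out = []
    for key in sorted(groups):
        group = groups[key]
        best = min(group, key=lambda r: (r["distance"], r["structure_id"]))
        kept = dict(best)
        kept["n_structures_observed"] = len(group)
        out.append(kept)
    return out


def taxonomy_filter(
    records: Sequence,
    taxa: Sequence[str] = MAMMAL_KEYWORDS,
    organisms_of=None,
) -> tuple[list, int]:
    """Keep records whose source organism matches any keyword (substring,
    case-insensitive).  Records with no organism metadata are excluded and
    counted.  An empty keyword list is the identity filter.

    Returns ``(kept, n_unknown_excluded)``.
    """
    if organisms_of is None:
        organisms_of = lambda r: getattr(r, "source_organisms", None) or (
            r.get("source_organisms") if isinstance(r, dict) else None
        )
    if not taxa:
        return list(records), 0
    keywords = [t.lower() for t in taxa]
    kept: list = []
    unknown = 0
    for rec in records:
        orgs = organisms_of(rec)
        if not orgs:
            unknown += 1
            continue
        if any(kw in org.lower() for org in orgs for kw in keywords):
            kept.append(rec)
    return kept, unknown
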
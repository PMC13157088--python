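"""Per-pair structural descriptors feeding the composite redox score.

Five descriptors are computed for every proximal cysteine pair:

* ``sg_distance`` — inter-cysteine S gamma - S gamma distance (A);
* ``pct_buried`` — 100 x (1 - relative solvent accessibility) averaged over
  the two cysteines, from Shrake-Rupley SASA in full structure context
  against a tripeptide reference state for CYS;
* ``hse_total`` — half-sphere exposure summed over both cysteines: the number
  of neighbouring residues (by CA) inside a 12 A sphere, split into the
  hemisphere along the CA->CB (side-chain) direction ("up") and its
  complement ("down");
* ``min_pka`` — the smaller of the two predicted thiol pKa values, from a
  pluggable prediction engine (PROPKA3-style adapter, or a deterministic
  table-backed provider);
* ``avg_b`` — mean isotropic B-factor (A^2) over all heavy atoms of both
  cysteine residues.

Missing values (unresolved atoms, provider failure) are flagged, never
silently zeroed.
"""

from __future__ import annotations

import logging
import math
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig, DEFAULT_CONFIG
from .structure_io import Atom, CysteineSite, Residue, Structure, write_pdb
from .pair_scan import CysteinePair

logger = logging.getLogger(__name__)

__all__ = [
    "DESCRIPTOR_NAMES",
    "HseResult",
    "DescriptorVector",
    "sg_distance",
    "half_sphere_exposure",
    "pct_buried",
    "min_pka",
    "pair_descriptors",
    "TablePkaProvider",
    "PropkaProvider",
]

#: Descriptor order used by the score model.
DESCRIPTOR_NAMES = ("sg_distance", "pct_buried", "hse_total", "min_pka", "avg_b")


def sg_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance in A between two S gamma positions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# half-sphere exposure


@dataclass
class HseResult:
    hse_up: int
    hse_down: int
    radius: float
    basis: str  # "cb_vector" | "pseudo_cb"

    @property
    def total(self) -> int:
        return self.hse_up + self.hse_down


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    k = axis / np.linalg.norm(axis)
    return (
        v * math.cos(angle)
        + np.cross(k, v) * math.sin(angle)
        + k * np.dot(k, v) * (1.0 - math.cos(angle))
    )


def _side_chain_vector(site: CysteineSite) -> tuple[np.ndarray, str] | None:
    """Unit vector from CA toward CB, or a pseudo-CB for CB-less residues.

    The pseudo-CB is the N->CA vector rotated -120 degrees about the CA->C
    axis, the standard tetrahedral construction used for glycine.
    """
    if site.ca is None:
        return None
    if site.cb is not None:
        u = site.cb.coords - site.ca.coords
        n = np.linalg.norm(u)
        if n > 0:
            return u / n, "cb_vector"
    if site.n is None or site.c is None:
        return None
    n_v = site.n.coords - site.ca.coords
    c_v = site.c.coords - site.ca.coords
    if np.linalg.norm(n_v) == 0 or np.linalg.norm(c_v) == 0:
        return None
    u = _rodrigues(n_v, c_v, math.radians(-120.0))
    norm = np.linalg.norm(u)
    if norm == 0:
        return None
    return u / norm, "pseudo_cb"


def half_sphere_exposure(
    site: CysteineSite, s: Structure, radius: float = 12.0
) -> HseResult | None:
    """Count neighbouring residues' CA atoms in the side-chain half-sphere.

    Neighbours are CA atoms of all *other* polymer residues, any chain, with
    |CA_j - CA_i| strictly < ``radius``.  A neighbour exactly on the dividing
    plane counts as "down".  Returns None when the site lacks the atoms
    needed to place the plane.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    basis = _side_chain_vector(site)
    if basis is None or site.ca is None:
        return None
    u, basis_name = basis
    ca_i = site.ca.coords
    up = down = 0
    for r in s.residues():
        if not r.polymer or r.key == site.key:
            continue
        ca_j = r.atom("CA")
        if ca_j is None:
            continue
        d = ca_j.coords - ca_i
        if np.linalg.norm(d) >= radius:
            continue
        if float(np.dot(d, u)) > 0.0:
            up += 1
        else:
            down += 1
    return HseResult(hse_up=up, hse_down=down, radius=radius, basis=basis_name)


# ---------------------------------------------------------------------------
# % buried (Shrake-Rupley SASA via biotite)


def _to_atom_array(s: Structure):
    """Convert to a biotite AtomArray of all heavy atoms (SASA occluders)."""
    import biotite.structure as struc

    atoms = []
    for r in s.residues():
        for a in r.atoms:
            atoms.append((r, a))
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a.coords for _, a in atoms], dtype=np.float32)
    arr.chain_id = np.array([r.chain_id for r, _ in atoms])
    arr.res_id = np.array([r.auth_seq for r, _ in atoms])
    arr.ins_code = np.array([r.icode for r, _ in atoms])
    arr.res_name = np.array([r.res_name for r, _ in atoms])
    arr.atom_name = np.array([a.name for _, a in atoms])
    arr.element = np.array([(a.element or "C").upper() for _, a in atoms])
    arr.hetero = np.array([not r.polymer for r, _ in atoms])
    return arr


def pct_buried(
    site: CysteineSite,
    s: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    max_asa: float = DEFAULT_CONFIG.cys_max_asa,
) -> float:
    """Percent burial of one cysteine residue in full structure context.

    Shrake-Rupley SASA (deterministic Fibonacci point set) of the residue's
    heavy atoms, with every heavy atom of the structure as occluder, divided
    by the reference maximum ASA for cysteine; burial is the complement,
    clamped to [0, 100].
    """
    import biotite.structure as struc

    arr = _to_atom_array(s)
    mask = (
        (arr.chain_id == site.chain_id)
        & (arr.res_id == site.auth_seq)
        & (arr.ins_code == site.icode)
    )
    if not mask.any():
        raise ValueError(f"site {site.key} not found in structure {s.structure_id}")
    per_atom = struc.sasa(
        arr,
        probe_radius=probe,
        atom_filter=mask,
        ignore_ions=False,
        point_number=n_points,
        vdw_radii="Single",
    )
    sasa = float(np.nansum(per_atom[mask]))
    rel = sasa / max_asa
    return float(np.clip(100.0 * (1.0 - rel), 0.0, 100.0))


# ---------------------------------------------------------------------------
# pKa providers


class TablePkaProvider:
    """Deterministic pKa lookup from an in-memory table or a TSV file.

    TSV columns: ``chain``, ``residue`` and ``pka`` (an optional
    ``structure_id`` column restricts rows to one entry).  In-memory mappings
    are keyed by ``(chain_id, auth_seq)`` or ``(chain_id, auth_seq, icode)``.
    """

    def __init__(self, table: dict | str | Path):
        self._table: dict[tuple[str, int, str], float] = {}
        self._by_structure: dict[str, dict[tuple[str, int, str], float]] = {}
        if isinstance(table, (str, Path)):
            import pandas as pd

            df = pd.read_csv(table, sep="\t", dtype={"chain": str})
            for _, row in df.iterrows():
                key = (str(row["chain"]), int(row["residue"]), str(row.get("icode", "") or ""))
                if "structure_id" in df.columns and not (
                    isinstance(row["structure_id"], float) and math.isnan(row["structure_id"])
                ):
                    self._by_structure.setdefault(str(row["structure_id"]), {})[key] = float(
                        row["pka"]
                    )
                else:
                    self._table[key] = float(row["pka"])
        else:
            for key, value in table.items():
                if len(key) == 2:
                    key = (key[0], key[1], "")
                self._table[tuple(key)] = float(value)

    def predict(self, s: Structure) -> dict[tuple[str, int, str], float]:
        merged = dict(self._table)
        merged.update(self._by_structure.get(s.structure_id, {}))
        return merged


class PropkaProvider:
    """Adapter to the PROPKA3 prediction engine (optional dependency).

    Writes the structure to a temporary PDB file, runs a single PROPKA
    calculation and harvests the CYS side-chain pKa values.  Raises
    ImportError when propka is not installed; callers route failures into a
    missing descriptor.
    """

    def __init__(self) -> None:
        import propka.run  # noqa: F401  (fail fast if absent)

        self._cache: dict[str, dict[tuple[str, int, str], float]] = {}

    def predict(self, s: Structure) -> dict[tuple[str, int, str], float]:
        if s.structure_id in self._cache:
            return self._cache[s.structure_id]
        import propka.run

        with tempfile.TemporaryDirectory() as tmp:
            pdb = Path(tmp) / f"{s.structure_id or 'model'}.pdb"
            write_pdb(s, pdb)
            mol = propka.run.single(str(pdb), optargs=["--quiet"], write_pka=False)
        out: dict[tuple[str, int, str], float] = {}
        conformation = mol.conformations.get("AVR") or next(iter(mol.conformations.values()))
        for group in conformation.groups:
            if group.residue_type == "CYS" and group.pka_value is not None:
                atom = group.atom
                out[(str(atom.chain_id), int(atom.res_num), "")] = float(group.pka_value)
        self._cache[s.structure_id] = out
        return out


def min_pka(pair: CysteinePair, s: Structure, provider) -> float | None:
    """Minimum predicted thiol pKa over the pair; None when unavailable.

    Provider failures are logged and converted to a missing value — a broken
    external engine must not abort the screen.
    """
    if provider is None:
        return None
    try:
        table = provider.predict(s)
    except Exception as exc:  # provider crash -> missing, never propagates
        logger.warning("pKa provider failed on %s: %s", s.structure_id, exc)
        return None
    values = [
        table.get(site.key, table.get((site.chain_id, site.auth_seq, "")))
        for site in (pair.site_a, pair.site_b)
    ]
    values = [v for v in values if v is not None]
    if not values:
        return None
    return float(min(values))


# ---------------------------------------------------------------------------
# per-pair assembly


@dataclass
class DescriptorVector:
    sg_distance: float | None = None
    pct_buried: float | None = None
    hse_total: int | None = None
    hse_up_pair: int | None = None
    hse_down_pair: int | None = None
    min_pka: float | None = None
    avg_b: float | None = None
    missing: dict[str, bool] = field(default_factory=dict)
    imputed: dict[str, bool] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}

    def __post_init__(self) -> None:
        for name in DESCRIPTOR_NAMES:
            self.missing.setdefault(name, getattr(self, name) is None)
            self.imputed.setdefault(name, False)


def _residue_of(site: CysteineSite, s: Structure) -> Residue | None:
    return s.find_residue(site.chain_id, site.auth_seq, site.icode)


def pair_descriptors(
    pair: CysteinePair,
    s: Structure,
    config: RunConfig = DEFAULT_CONFIG,
    pka_provider=None,
) -> DescriptorVector:
    """Assemble the five-descriptor vector for one cysteine pair.

    Pair aggregation: % buried is averaged over the two sites, HSE counts are
    summed, B is averaged over all heavy atoms of both residues.
    """
    burial = []
    for site in (pair.site_a, pair.site_b):
        burial.append(
            pct_buried(
                site,
                s,
                probe=config.sasa_probe,
                n_points=config.sasa_points,
                max_asa=config.cys_max_asa,
            )
        )
    hse_a = half_sphere_exposure(pair.site_a, s, radius=config.hse_radius)
    hse_b = half_sphere_exposure(pair.site_b, s, radius=config.hse_radius)

    b_values: list[float] = []
    for site in (pair.site_a, pair.site_b):
        res = _residue_of(site, s)
        if res is not None:
            b_values.extend(a.b_factor for a in res.atoms)

    vec = DescriptorVector(
        sg_distance=pair.sg_distance,
        pct_buried=float(np.mean(burial)) if burial else None,
        hse_total=None if (hse_a is None or hse_b is None) else hse_a.total + hse_b.total,
        hse_up_pair=None if (hse_a is None or hse_b is None) else hse_a.hse_up + hse_b.hse_up,
        hse_down_pair=(
            None if (hse_a is None or hse_b is None) else hse_a.hse_down + hse_b.hse_down
        ),
        min_pka=min_pka(pair, s, pka_provider),
        avg_b=float(np.mean(b_values)) if b_values else None,
    )
    return vec
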
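"""Read PDB / PDBx-mmCIF structures into a uniform model and pull out cysteines.

The in-memory model is deliberately small: chains of residues of heavy atoms,
plus the metadata the screen needs (declared disulphide bridges, experimental
method, resolution, source organisms).  Parsing is delegated to gemmi; the
policies applied on top are:

* first model only for multi-model (NMR) entries;
* per atom name, the highest-occupancy alternate location is kept
  (ties break to the lexicographically first altloc identifier);
* hydrogens are dropped; HETATM residues are retained but flagged non-polymer.

Residues are addressed by author numbering ``(chain_id, auth_seq, icode)``
throughout; canonical reference numbering is assigned elsewhere.
"""

from __future__ import annotations

import math
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "CysteineSite",
    "StructureFormatError",
    "read_structure",
    "fetch_structure",
    "write_pdb",
    "extract_cysteine_sites",
    "observed_sequence",
    "MODIFIED_CYS_NAMES",
]


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed or contains no residues."""


#: Chemically modified cysteine residue names (oxidised, alkylated, ...).
#: Detected and flagged, but excluded from thiol pairing: the screen concerns
#: free thiols.
MODIFIED_CYS_NAMES = frozenset(
    {"CSO", "CSD", "CSX", "CME", "OCS", "CSS", "SNC", "CSU", "CAS", "SMC", "YCM"}
)


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) in Angstrom
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    auth_seq: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    polymer: bool = True
    het: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.auth_seq, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    structure_id: str
    chains: dict[str, list[Residue]]
    exp_method: str = ""
    resolution: float | None = None
    source_organisms: list[str] = field(default_factory=list)
    ss_bonds: list[tuple[tuple[str, int, str], tuple[str, int, str]]] = field(
        default_factory=list
    )
    dangling_ss_bonds: list[tuple[tuple[str, int, str], tuple[str, int, str]]] = field(
        default_factory=list
    )
    #: protein-entity identifier per chain (identical observed sequences share
    #: an entity when the file declares none)
    chain_entity: dict[str, str] = field(default_factory=dict)

    def residues(self) -> Iterable[Residue]:
        for chain in self.chains.values():
            yield from chain

    def find_residue(self, chain_id: str, auth_seq: int, icode: str = "") -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.auth_seq == auth_seq and r.icode == icode:
                return r
        return None

    def has_ss_bond(self, key_a: tuple[str, int, str], key_b: tuple[str, int, str]) -> bool:
        pair = frozenset((key_a, key_b))
        return any(frozenset(b) == pair for b in self.ss_bonds)


@dataclass
class CysteineSite:
    """A cysteine residue prepared for thiol-pair screening.

    ``sg`` is None when the side-chain sulfur is unresolved; such sites are
    kept (for audit) but excluded from distance screening.  ``flank`` is the
    observed-sequence window centred on the cysteine, with 'X' at unmodelled
    positions; its half-width is recorded so narrower windows can be derived.
    """

    structure_id: str
    chain_id: str
    auth_seq: int
    icode: str
    res_name: str
    sg: Atom | None
    ca: Atom | None
    cb: Atom | None
    n: Atom | None
    c: Atom | None
    flank: str
    flank_halfwidth: int
    modified: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.auth_seq, self.icode)

    @property
    def has_resolved_sg(self) -> bool:
        return self.sg is not None

    def flank_window(self, halfwidth: int) -> str:
        """Return the flank trimmed (or X-padded) to the given half-width."""
        centre = self.flank_halfwidth
        if halfwidth <= self.flank_halfwidth:
            return self.flank[centre - halfwidth : centre + halfwidth + 1]
        pad = "X" * (halfwidth - self.flank_halfwidth)
        return pad + self.flank + pad


# ---------------------------------------------------------------------------
# reading


def _sniff_format(text: str) -> str:
    head = text[:4000]
    if head.lstrip().startswith("data_") or "_atom_site" in head or "loop_" in head:
        return "mmcif"
    return "pdb"


def _gemmi_from_source(source: str | Path, fmt: str) -> tuple[gemmi.Structure, str]:
    """Parse with gemmi, returning the structure and the raw text (PDB only)."""
    text: str | None = None
    path: Path | None = None
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(source)
        text = path.read_text()
    else:
        text = str(source)

    if fmt == "auto":
        if path is not None and path.suffix.lower() in {".cif", ".mmcif"}:
            fmt = "mmcif"
        elif path is not None and path.suffix.lower() in {".pdb", ".ent"}:
            fmt = "pdb"
        else:
            fmt = _sniff_format(text)

    name = path.stem if path is not None else ""
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        elif fmt == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(
            f"cannot parse {name or '<text>'} as {fmt}: {exc}"
        ) from exc
    if name:
        st.name = name  # file stem is the structure id (accession-style)
    elif st.name in {"", "string"}:
        st.name = "structure"
    return st, text


_ORG_RE = re.compile(r"ORGANISM_SCIENTIFIC:\s*([^;]+);?", re.IGNORECASE)

_SRC_CIF_TAGS = (
    ("_entity_src_gen.pdbx_gene_src_scientific_name",),
    ("_entity_src_nat.pdbx_organism_scientific",),
    ("_pdbx_entity_src_syn.organism_scientific",),
)


def _parse_organisms(text: str, fmt: str) -> list[str]:
    orgs: list[str] = []
    if fmt == "pdb":
        for line in text.splitlines():
            if line.startswith("SOURCE"):
                m = _ORG_RE.search(line)
                if m:
                    orgs.append(m.group(1).strip().title())
    else:
        try:
            block = gemmi.cif.read_string(text).sole_block()
        except (RuntimeError, ValueError):
            return []
        for (tag,) in _SRC_CIF_TAGS:
            for val in block.find_values(tag):
                s = gemmi.cif.as_string(val).strip()
                if s and s not in {".", "?"}:
                    orgs.append(s.title())
    seen: dict[str, None] = {}
    for o in orgs:
        seen.setdefault(o, None)
    return list(seen)


def _select_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties -> first altloc id."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        if atom.is_hydrogen():
            continue
        by_name.setdefault(atom.name, []).append(atom)
    chosen = []
    for cands in by_name.values():
        cands.sort(key=lambda a: (-a.occ, a.altloc))
        chosen.append(cands[0])
    return chosen


def read_structure(path_or_text: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or PDBx/mmCIF file (or raw text) into a :class:`Structure`.

    Applies the module's altloc / first-model / no-hydrogen policies.  Raises
    :class:`StructureFormatError` on unparseable input or an empty model.
    """
    st, text = _gemmi_from_source(path_or_text, format)
    fmt = _sniff_format(text) if format == "auto" else format
    if fmt not in {"pdb", "mmcif"}:
        fmt = _sniff_format(text)
    if len(st) == 0:
        raise StructureFormatError(f"{st.name or '<text>'}: no models / no residues")
    model = st[0]  # first model only (NMR ensembles)

    chains: dict[str, list[Residue]] = {}
    n_res = 0
    for ch in model:
        out: list[Residue] = []
        seen_keys: set[tuple[int, str]] = set()
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = bool(info and info.is_amino_acid())
            key = (res.seqid.num, res.seqid.icode.strip())
            if key in seen_keys and is_aa:
                continue  # residue-level microheterogeneity: first wins
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    b_factor=a.b_iso,
                    occupancy=a.occ,
                    altloc=a.altloc or "",
                )
                for a in _select_altlocs(res)
            ]
            if not atoms:
                continue
            seen_keys.add(key)
            out.append(
                Residue(
                    chain_id=ch.name,
                    auth_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    res_name=res.name,
                    atoms=atoms,
                    polymer=is_aa,
                    het=res.het_flag == "H",
                )
            )
            n_res += 1
        if out:
            out.sort(key=lambda r: (r.auth_seq, r.icode))
            chains[ch.name] = out
    if n_res == 0:
        raise StructureFormatError(f"{st.name or '<text>'}: no residues")

    out_st = Structure(
        structure_id=st.name or "structure",
        chains=chains,
        exp_method=st.info["_exptl.method"] if "_exptl.method" in st.info else "",
        resolution=st.resolution if st.resolution > 0 else None,
        source_organisms=_parse_organisms(text, fmt),
    )

    for con in st.connections:
        if con.type != gemmi.ConnectionType.Disulf:
            continue
        a1, a2 = con.partner1, con.partner2
        k1 = (a1.chain_name, a1.res_id.seqid.num, a1.res_id.seqid.icode.strip())
        k2 = (a2.chain_name, a2.res_id.seqid.num, a2.res_id.seqid.icode.strip())
        bond = (k1, k2)
        if out_st.find_residue(*k1) is not None and out_st.find_residue(*k2) is not None:
            out_st.ss_bonds.append(bond)
        else:
            out_st.dangling_ss_bonds.append(bond)

    # entity assignment: identical observed polymer sequences share an entity
    seq_to_entity: dict[str, str] = {}
    for cid in chains:
        seq = observed_sequence(out_st, cid) if any(r.polymer for r in chains[cid]) else ""
        if not seq:
            continue
        ent = seq_to_entity.setdefault(seq, str(len(seq_to_entity) + 1))
        out_st.chain_entity[cid] = ent
    return out_st


def fetch_structure(accession: str, format: str = "pdb", timeout: float = 30.0) -> Structure:
    """Download an entry from the RCSB PDB by accession and parse it."""
    ext = "pdb" if format == "pdb" else "cif"
    url = f"https://files.rcsb.org/download/{accession.upper()}.{ext}"
    with urllib.request.urlopen(url, timeout=timeout) as fh:  # noqa: S310
        text = fh.read().decode()
    st = read_structure(text, format="pdb" if ext == "pdb" else "mmcif")
    st.structure_id = accession.upper()
    return st


# ---------------------------------------------------------------------------
# sequences and cysteine sites

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "SEC": "U", "MSE": "M",
}


def _one_letter(res_name: str) -> str:
    if res_name in _THREE_TO_ONE:
        return _THREE_TO_ONE[res_name]
    if res_name in MODIFIED_CYS_NAMES:
        return "C"  # parent residue
    info = gemmi.find_tabulated_residue(res_name)
    if info and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def observed_sequence(s: Structure, chain_id: str) -> str:
    """One-letter sequence over the author-numbering span; gaps as 'X'.

    The string covers max(auth_seq) - min(auth_seq) + 1 positions; residues
    with insertion codes share their author number's slot (first wins).
    """
    if chain_id not in s.chains:
        raise KeyError(f"unknown chain {chain_id!r} in {s.structure_id}")
    poly = [r for r in s.chains[chain_id] if r.polymer]
    if not poly:
        return ""
    lo = min(r.auth_seq for r in poly)
    hi = max(r.auth_seq for r in poly)
    seq = ["X"] * (hi - lo + 1)
    for r in poly:
        idx = r.auth_seq - lo
        if seq[idx] == "X":
            seq[idx] = _one_letter(r.res_name)
    return "".join(seq)


def extract_cysteine_sites(s: Structure, flank_halfwidth: int = 20) -> list[CysteineSite]:
    """One :class:`CysteineSite` per cysteine residue (modified ones flagged).

    Sites whose S gamma is unresolved are returned with ``sg=None``; the
    pair scan skips them.
    """
    if flank_halfwidth < 1:
        raise ValueError("flank_halfwidth must be >= 1")
    sites: list[CysteineSite] = []
    for chain_id, residues in s.chains.items():
        poly = [r for r in residues if r.polymer]
        if not poly:
            continue
        lo = min(r.auth_seq for r in poly)
        seq = observed_sequence(s, chain_id)
        for r in poly:
            is_cys = r.res_name == "CYS"
            modified = r.res_name in MODIFIED_CYS_NAMES or r.res_name == "SEC"
            if not (is_cys or modified):
                continue
            centre = r.auth_seq - lo
            left = seq[max(0, centre - flank_halfwidth) : centre]
            right = seq[centre + 1 : centre + 1 + flank_halfwidth]
            flank = (
                "X" * (flank_halfwidth - len(left))
                + left
                + seq[centre]
                + right
                + "X" * (flank_halfwidth - len(right))
            )
            sg = r.atom("SG") or (r.atom("SE") if r.res_name == "SEC" else None)
            if sg is not None and sg.element not in {"S", "SE", "Se"}:
                sg = None
            sites.append(
                CysteineSite(
                    structure_id=s.structure_id,
                    chain_id=chain_id,
                    auth_seq=r.auth_seq,
                    icode=r.icode,
                    res_name=r.res_name,
                    sg=sg,
                    ca=r.atom("CA"),
                    cb=r.atom("CB"),
                    n=r.atom("N"),
                    c=r.atom("C"),
                    flank=flank,
                    flank_halfwidth=flank_halfwidth,
                    modified=modified,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# PDB writing (sufficient for fixtures; read back through gemmi)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(s: Structure, path: str | Path) -> Path:
    """Write a fixed-column PDB file for a :class:`Structure`."""
    lines: list[str] = []
    if s.exp_method:
        lines.append(f"EXPDTA    {s.exp_method.upper()}")
    if s.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {s.resolution:7.2f} ANGSTROMS.")
    cont = 0
    for i, org in enumerate(s.source_organisms, start=1):
        for text in (f"MOL_ID: {i};", f"ORGANISM_SCIENTIFIC: {org.upper()};"):
            cont += 1
            num = "  " if cont == 1 else f"{cont:2d}"
            lines.append(f"SOURCE  {num} {text}")
    for i, (k1, k2) in enumerate(s.ss_bonds, start=1):
        lines.append(
            f"SSBOND {i:3d} CYS {k1[0]:>1s} {k1[1]:4d}{k1[2] or ' ':1s}"
            f"   CYS {k2[0]:>1s} {k2[1]:4d}{k2[2] or ' ':1s}"
        )
    serial = 0
    for chain_id, residues in s.chains.items():
        for r in residues:
            record = "HETATM" if not r.polymer or r.het else "ATOM  "
            for a in r.atoms:
                serial += 1
                x, y, z = a.coords
                lines.append(
                    f"{record}{serial:5d} {_format_atom_name(a.name, a.element)}"
                    f"{a.altloc or ' ':1s}{r.res_name:>3s} {chain_id:1s}"
                    f"{r.auth_seq:4d}{r.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                    f"          {a.element:>2s}"
                )
        serial += 1
        last = residues[-1]
        lines.append(
            f"TER   {serial:5d}      {last.res_name:>3s} {chain_id:1s}{last.auth_seq:4d}"
        )
    lines.append("END")
    out = Path(path)
    out.write_text("\n".join(lines) + "\n")
    return out
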
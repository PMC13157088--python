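"""Synthetic structures and tables with controlled geometry and statistics.

Everything the pipeline consumes can be generated here without downloads:

* idealised poly-Ala/Gly scaffold chains carrying cysteines whose S gamma -
  S gamma separations are set exactly (to machine precision), optionally with
  occluding burial shells, per-residue B-factor plans and SSBOND records;
* labelled descriptor tables emulating a training library of redox-active
  and inert cysteine pairs, with class shifts in the directions seen for
  known redox-regulated disulphides (shorter thiol distance, lower burial and
  half-sphere exposure, lower minimum pKa, higher B-factor for positives);
* matched reference sequences and ligandability tables.

Scaffold geometry is idealised (no Ramachandran realism): the descriptors
exercised on these fixtures are geometric and counting quantities, not
energetics.  A fixed seed gives byte-identical output.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structure_io import Atom, Residue, Structure, write_pdb

__all__ = [
    "ChainSpec",
    "FixtureSpec",
    "make_cys_pair_structure",
    "make_disulphide_structure",
    "make_three_distance_fixture",
    "make_random_cys_structure",
    "make_training_set",
    "make_reference_for_structure",
    "make_ligandability_population",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "U": "SEC",
}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ChainSpec:
    chain_id: str
    sequence: str  # one-letter; every 'C' becomes a CYS with an SG atom
    start: int = 1  # author number of the first residue
    origin: tuple[float, float, float] | None = None  # CA of first residue


@dataclass
class FixtureSpec:
    chains: list[ChainSpec]
    #: ((chain, auth_seq), (chain, auth_seq), distance A): after scaffold
    #: construction the second site's SG is relocated along the existing
    #: direction so the separation equals `distance` exactly.
    sg_constraints: list[tuple[tuple[str, int], tuple[str, int], float]] = field(
        default_factory=list
    )
    #: ((chain, auth_seq), shell_radius A, n_atoms): occluding dummy-atom shell
    burial_shells: list[tuple[tuple[str, int], float, int]] = field(default_factory=list)
    #: per-residue B override; default applies elsewhere
    b_factor_plan: dict[tuple[str, int], float] = field(default_factory=dict)
    default_b: float = 20.0
    ss_bonds: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)
    source_organisms: list[str] = field(default_factory=lambda: ["Homo sapiens"])
    structure_id: str = "fixture"
    seed: int = 0


def _build_residue(
    chain_id: str, auth_seq: int, one_letter: str, ca: np.ndarray, b: float
) -> Residue:
    res_name = _ONE_TO_THREE.get(one_letter, "ALA")
    atoms = [
        Atom("N", "N", ca + np.array([-1.20, 0.80, 0.30]), b_factor=b),
        Atom("CA", "C", ca.copy(), b_factor=b),
        Atom("C", "C", ca + np.array([1.20, 0.80, -0.30]), b_factor=b),
        Atom("O", "O", ca + np.array([1.40, 2.00, -0.30]), b_factor=b),
    ]
    if res_name != "GLY":
        cb = ca + np.array([0.0, -0.77, 1.33])  # |CB-CA| ~ 1.54 A
        atoms.append(Atom("CB", "C", cb, b_factor=b))
        if res_name == "CYS":
            atoms.append(Atom("SG", "S", cb + np.array([0.0, -0.90, 1.55]), b_factor=b))
        elif res_name == "SEC":
            atoms.append(Atom("SE", "SE", cb + np.array([0.0, -0.90, 1.55]), b_factor=b))
    return Residue(chain_id, auth_seq, "", res_name, atoms)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_cys_pair_structure(
    spec: FixtureSpec, path: str | Path | None = None
) -> Structure:
    """Build a scaffold structure per spec; optionally write it as PDB.

    Raises on infeasible geometry (distinct residues whose CA atoms end up
    closer than 0.5 A).
    """
    chains: dict[str, list[Residue]] = {}
    for idx, chain in enumerate(spec.chains):
        residues = []
        origin = (
            np.array(chain.origin, dtype=float)
            if chain.origin is not None
            else np.array([0.0, 30.0 * idx, 0.0])
        )
        for j, letter in enumerate(chain.sequence):
            auth = chain.start + j
            ca = origin + np.array([3.8 * j, 0.0, 0.0])
            b = spec.b_factor_plan.get((chain.chain_id, auth), spec.default_b)
            residues.append(_build_residue(chain.chain_id, auth, letter, ca, b))
        chains[chain.chain_id] = residues

    s = Structure(
        structure_id=spec.structure_id,
        chains=chains,
        exp_method="X-RAY DIFFRACTION",
        resolution=2.0,
        source_organisms=list(spec.source_organisms),
        ss_bonds=[((a[0], a[1], ""), (b[0], b[1], "")) for a, b in spec.ss_bonds],
    )

    for (key_a, key_b, dist) in spec.sg_constraints:
        if dist <= 0:
            raise ValueError("requested SG-SG distance must be positive")
        res_a = s.find_residue(key_a[0], key_a[1])
        res_b = s.find_residue(key_b[0], key_b[1])
        if res_a is None or res_b is None:
            raise ValueError(f"constraint references missing residue {key_a} / {key_b}")
        sg_a, sg_b = res_a.atom("SG"), res_b.atom("SG")
        if sg_a is None or sg_b is None:
            raise ValueError("constraint endpoints must be cysteines with SG atoms")
        direction = sg_b.coords - sg_a.coords
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        sg_b.coords = sg_a.coords + direction * dist

    shells: list[Residue] = []
    for n_shell, ((cid, seq), radius, n_atoms) in enumerate(spec.burial_shells):
        res = s.find_residue(cid, seq)
        if res is None:
            raise ValueError(f"burial shell references missing residue ({cid}, {seq})")
        centre_atom = res.atom("SG") or res.atom("CA")
        pts = centre_atom.coords + radius * _fibonacci_sphere(n_atoms)
        shell_res = Residue(
            chain_id="Z",
            auth_seq=900 + n_shell,
            icode="",
            res_name="DUM",
            atoms=[
                Atom(f"C{k % 99 + 1}", "C", p, b_factor=spec.default_b)
                for k, p in enumerate(pts)
            ],
            polymer=False,
            het=True,
        )
        shells.append(shell_res)
    if shells:
        s.chains["Z"] = shells

    ca_coords = np.array(
        [r.atom("CA").coords for cid in chains for r in chains[cid] if r.atom("CA")]
    )
    if len(ca_coords) > 1:
        from scipy.spatial.distance import pdist

        if pdist(ca_coords).min() < 0.5:
            raise ValueError("infeasible geometry: overlapping chains")

    # identical sequences share an entity
    seqs: dict[str, str] = {}
    for chain in spec.chains:
        ent = seqs.setdefault(chain.sequence, str(len(seqs) + 1))
        s.chain_entity[chain.chain_id] = ent

    if path is not None:
        write_pdb(s, path)
    return s


def make_disulphide_structure(seed: int = 0, path: str | Path | None = None) -> Structure:
    """Interchain cystine: S gamma separation exactly 2.05 A + SSBOND record."""
    spec = FixtureSpec(
        chains=[
            ChainSpec("A", "AAACAAA", start=55),
            ChainSpec("B", "AAACAAA", start=155),
        ],
        sg_constraints=[(("A", 58), ("B", 158), 2.05)],
        ss_bonds=[(("A", 58), ("B", 158))],
        structure_id="ssfix",
        seed=seed,
    )
    return make_cys_pair_structure(spec, path)


def make_three_distance_fixture(path: str | Path | None = None) -> Structure:
    """Dimer with three interchain S gamma separations: 2.05, 9.9 and 10.1 A.

    Only the first two pass a strict 10 A screen.  Cysteine pairs other than
    the three constructed ones are > 30 A apart.
    """
    seq = "AC" + "A" * 9 + "C" + "A" * 9 + "CA"  # CYS at offsets 1, 11, 21
    spec = FixtureSpec(
        chains=[ChainSpec("A", seq, start=1), ChainSpec("B", seq, start=1)],
        sg_constraints=[
            (("A", 2), ("B", 2), 2.05),
            (("A", 12), ("B", 12), 9.9),
            (("A", 22), ("B", 22), 10.1),
        ],
        structure_id="three_distances",
    )
    return make_cys_pair_structure(spec, path)


def make_random_cys_structure(
    n_cys: int, seed: int, box: float = 40.0, chain_id: str = "A"
) -> Structure:
    """Random cysteine cloud for brute-force oracle comparisons.

    ``n_cys`` CYS residues with random CA positions in a cube of side
    ``box`` A, random CB and SG orientations and random B-factors.
    """
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(n_cys):
        ca = rng.uniform(0.0, box, size=3)
        cb_dir = rng.normal(size=3)
        cb_dir /= np.linalg.norm(cb_dir)
        cb = ca + 1.54 * cb_dir
        sg_dir = rng.normal(size=3)
        sg_dir /= np.linalg.norm(sg_dir)
        b = float(rng.uniform(5.0, 80.0))
        residues.append(
            Residue(
                chain_id,
                i + 1,
                "",
                "CYS",
                atoms=[
                    Atom("N", "N", ca + np.array([-1.2, 0.8, 0.3]), b_factor=b),
                    Atom("CA", "C", ca, b_factor=b),
                    Atom("C", "C", ca + np.array([1.2, 0.8, -0.3]), b_factor=b),
                    Atom("CB", "C", cb, b_factor=b),
                    Atom("SG", "S", cb + 1.8 * sg_dir, b_factor=b),
                ],
            )
        )
    s = Structure(structure_id=f"random{seed}", chains={chain_id: residues})
    s.chain_entity[chain_id] = "1"
    return s


# ---------------------------------------------------------------------------
# labelled training tables

#: Class means (negative, strong-positive) per descriptor.  Positives follow
#: the directions observed for known redox-regulated disulphides: shorter
#: thiol separation, less burial / lower half-sphere exposure, lower minimum
#: pKa, higher B-factor.
_PROFILE_MEANS = {
    "sg_distance": (7.0, 3.8),
    "pct_buried": (75.0, 42.0),
    "hse_total": (54.0, 36.0),
    "min_pka": (9.3, 5.8),
    "avg_b": (25.0, 48.0),
}
_PROFILE_SD = {
    "sg_distance": 1.2,
    "pct_buried": 10.0,
    "hse_total": 9.0,
    "min_pka": 1.0,
    "avg_b": 8.0,
}
#: Fraction of the negative-to-positive mean shift applied per profile.
_PROFILE_STRENGTH = {"strong": 1.0, "moderate": 0.5, "null": 0.0}

#: Direction of each descriptor's association with the positive class
#: (+1: larger in positives), implied by the means above.
EFFECT_DIRECTIONS = {
    name: (1.0 if pos > neg else -1.0) for name, (neg, pos) in _PROFILE_MEANS.items()
}

_CLIPS = {
    "sg_distance": (2.2, 9.95),
    "pct_buried": (0.0, 100.0),
    "hse_total": (2.0, 120.0),
    "min_pka": (2.5, 14.0),
    "avg_b": (2.0, 150.0),
}


def _draw_class(rng: np.random.Generator, n: int, positive: bool, strength: float) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    # shared burial latent couples % buried and HSE total (they are grouped
    # descriptors in real structures)
    z = rng.normal(size=n)
    for name in ("sg_distance", "pct_buried", "hse_total", "min_pka", "avg_b"):
        neg_mu, pos_mu = _PROFILE_MEANS[name]
        mu = neg_mu + strength * (pos_mu - neg_mu) if positive else neg_mu
        sd = _PROFILE_SD[name]
        if name == "pct_buried":
            x = mu + sd * z
        elif name == "hse_total":
            e = rng.normal(size=n)
            x = mu + sd * (0.92 * z + 0.392 * e)
        else:
            x = rng.normal(mu, sd, size=n)
        lo, hi = _CLIPS[name]
        x = np.clip(x, lo, hi)
        if name == "hse_total":
            x = np.round(x)
        cols[name] = x
    df = pd.DataFrame(cols)
    df["hse_up_pair"] = np.round(0.55 * df["hse_total"])
    df["hse_down_pair"] = df["hse_total"] - df["hse_up_pair"]
    return df


def _random_sequence(rng: np.random.Generator, length: int, no_cys: bool = True) -> str:
    alphabet = _AA20.replace("C", "") if no_cys else _AA20
    return "".join(rng.choice(list(alphabet), size=length))


def make_training_set(
    n_pos: int = 20,
    n_neg: int = 20,
    effect_profile: str = "strong",
    seed: int = 0,
    ligandable_fraction: float = 0.3,
    ref_length: int = 240,
) -> dict:
    """Synthetic labelled training library + matched references + ligandability.

    Returns a dict with keys ``training`` (DataFrame: canonical pair key,
    five descriptors, label), ``references`` (FASTA text, one synthetic
    accession per example) and ``ligandability`` (DataFrame in the
    chemoproteomics table schema, annotating a configurable fraction of the
    cysteines).
    """
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 examples per class")
    strength = _PROFILE_STRENGTH[effect_profile]
    rng = np.random.default_rng(seed)
    pos = _draw_class(rng, n_pos, True, strength)
    neg = _draw_class(rng, n_neg, False, strength)
    frames = []
    fasta = io.StringIO()
    lig_rows = []
    compound_counter = 1
    for label, frame in (("positive", pos), ("negative", neg)):
        frame = frame.copy()
        frame["label"] = label
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)

    accs, res_a_list, res_b_list = [], [], []
    for i in range(len(table)):
        acc = f"SYN{seed % 1000:03d}{i:04d}"
        res_a = int(rng.integers(20, ref_length // 2))
        res_b = int(rng.integers(ref_length // 2 + 10, ref_length - 20))
        seq = list(_random_sequence(rng, ref_length))
        seq[res_a - 1] = "C"
        seq[res_b - 1] = "C"
        fasta.write(f">sp|{acc}|{acc}_SYN synthetic reference OS=Homo sapiens OX=9606\n")
        fasta.write("".join(seq) + "\n")
        accs.append(acc)
        res_a_list.append(res_a)
        res_b_list.append(res_b)
        for res in (res_a, res_b):
            if rng.random() < ligandable_fraction:
                compounds = ";".join(
                    f"CL{compound_counter + k:03d}" for k in range(int(rng.integers(1, 4)))
                )
                compound_counter += 3
                lig_rows.append(
                    {
                        "accession": acc,
                        "residue": res,
                        "ligandable": "true",
                        "compounds": compounds,
                        "source": "synthetic-chemoproteomics",
                    }
                )
    table.insert(0, "accession_a", accs)
    table.insert(1, "canon_res_a", res_a_list)
    table.insert(2, "accession_b", accs)
    table.insert(3, "canon_res_b", res_b_list)

    ligandability = pd.DataFrame(
        lig_rows, columns=["accession", "residue", "ligandable", "compounds", "source"]
    )
    return {"training": table, "references": fasta.getvalue(), "ligandability": ligandability}


def make_reference_for_structure(
    s: Structure,
    chain_id: str,
    accession: str,
    offset: int = 40,
    total_length: int = 300,
    seed: int = 0,
) -> str:
    """A synthetic reference FASTA embedding a chain's observed sequence.

    The chain's sequence is placed at 1-based position ``offset + 1`` inside
    random background, so structure author numbering maps to canonical
    numbering with a known shift.  'X' positions are replaced by random
    residues (the mapper treats structure-side 'X' as a wildcard).
    """
    from .structure_io import observed_sequence

    rng = np.random.default_rng(seed)
    core = observed_sequence(s, chain_id)
    core = "".join(
        c if c != "X" else rng.choice(list(_AA20.replace("C", ""))) for c in core
    )
    tail = total_length - offset - len(core)
    if tail < 0:
        raise ValueError("total_length too short for the observed sequence")
    seq = _random_sequence(rng, offset) + core + _random_sequence(rng, tail)
    return f">sp|{accession}|{accession}_SYN synthetic reference OS=Homo sapiens OX=9606\n{seq}\n"


def make_ligandability_population(
    n: int = 400,
    bound_fraction: float = 0.35,
    ligandable_fraction: float = 0.45,
    seed: int = 0,
) -> pd.DataFrame:
    """Candidate-pair population for the ligandability-vs-distance analysis.

    A ``bound_fraction`` subpopulation is disulphide-bound (S gamma
    separation ~2.05 A) and never ligandable — chemoproteomic probes cannot
    engage a thiol locked in a disulphide.  Free pairs draw their separation
    from one distribution regardless of ligandability.  The resulting table
    shows a ligandable-vs-non-ligandable distance difference that vanishes
    once disulphide-bound pairs are removed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        bound = rng.random() < bound_fraction
        if bound:
            dist = float(np.clip(rng.normal(2.05, 0.03), 1.9, 2.2))
            ligandable = False
        else:
            dist = float(np.clip(rng.normal(6.5, 1.5), 2.6, 9.95))
            ligandable = bool(rng.random() < ligandable_fraction)
        rows.append(
            {
                "accession_a": f"POP{i:05d}",
                "canon_res_a": 10 + i,
                "accession_b": f"POP{i:05d}",
                "canon_res_b": 110 + i,
                "sg_distance": dist,
                "disulphide_bound": bound,
                "pair_ligandable": ligandable,
            }
        )
    return pd.DataFrame(rows)


def make_candidate_set(k: int = 8, seed: int = 0) -> dict:
    """Candidate structures + matched references, pKa table and ligandability.

    Each of the ``k`` structures is a single chain with two cysteines whose
    S gamma separation, burial and B-factors vary across the set, plus a
    synthetic reference sequence embedding the chain at a known offset, a
    table-backed pKa prediction for both thiols, and ligandability rows for a
    subset of the mapped cysteines.  Drives the scan -> map -> descriptors ->
    score -> annotate chain end to end without downloads.
    """
    rng = np.random.default_rng(seed)
    structures: list[Structure] = []
    fasta_parts: list[str] = []
    pka_rows: list[dict] = []
    lig_rows: list[dict] = []
    distances = np.linspace(3.0, 9.5, k)
    for i in range(k):
        seq = list(_random_sequence(rng, 60))
        pos_a, pos_b = 20, 40  # 0-based offsets in the chain
        seq[pos_a] = "C"
        seq[pos_b] = "C"
        start = 5
        spec = FixtureSpec(
            chains=[ChainSpec("A", "".join(seq), start=start)],
            sg_constraints=[
                (("A", start + pos_a), ("A", start + pos_b), float(distances[i]))
            ],
            burial_shells=(
                [(("A", start + pos_a), 6.0, 160)] if i % 3 == 0 else []
            ),
            b_factor_plan={
                ("A", start + pos_a): float(rng.uniform(10.0, 70.0)),
                ("A", start + pos_b): float(rng.uniform(10.0, 70.0)),
            },
            structure_id=f"cand{i:03d}",
            seed=seed + i,
        )
        s = make_cys_pair_structure(spec)
        structures.append(s)
        acc = f"SYNC{i:04d}"
        offset = int(rng.integers(10, 60))
        fasta_parts.append(
            make_reference_for_structure(
                s, "A", acc, offset=offset, total_length=200, seed=seed + 1000 + i
            )
        )
        for auth in (start + pos_a, start + pos_b):
            pka_rows.append(
                {
                    "structure_id": s.structure_id,
                    "chain": "A",
                    "residue": auth,
                    "pka": round(float(rng.uniform(4.0, 11.0)), 2),
                }
            )
            if rng.random() < 0.5:
                canon = offset + (auth - start) + 1
                lig_rows.append(
                    {
                        "accession": acc,
                        "residue": canon,
                        "ligandable": "true",
                        "compounds": f"CL{i:03d}A;CL{i:03d}B",
                        "source": "synthetic-chemoproteomics",
                    }
                )
    return {
        "structures": structures,
        "references": "".join(fasta_parts),
        "pka_table": pd.DataFrame(pka_rows),
        "ligandability": pd.DataFrame(
            lig_rows, columns=["accession", "residue", "ligandable", "compounds", "source"]
        ),
    }
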
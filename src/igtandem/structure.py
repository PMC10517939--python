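"""Backbone-centric structure representation and PDB I/O.

A :class:`StructureModel` holds ordered residues grouped by chain, each with
N/CA/C/O coordinates, optional side-chain atoms and an optional per-residue
confidence score (read from the B-factor column of predicted models, where
AlphaFold2 stores pLDDT).  Non-protein heteroatoms (metal ions, ligands) are
retained separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .geometry import dihedral, superpose, rmsd_fixed

logger = logging.getLogger(__name__)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

#: CA-CA distance beyond which two consecutive residues are treated as a
#: chain break (no torsions computed across it).
CHAIN_BREAK_CA_CA = 4.5


@dataclass
class ResidueBackbone:
    """One residue's backbone (and optionally side-chain) atoms."""

    chain_id: str
    residue_number: int
    amino_acid: str
    n: np.ndarray | None = None
    ca: np.ndarray | None = None
    c: np.ndarray | None = None
    o: np.ndarray | None = None
    sidechain: dict[str, np.ndarray] = field(default_factory=dict)
    confidence: float | None = None
    insertion_code: str = ""

    @property
    def complete(self) -> bool:
        """All four backbone atoms present with sane N-CA / CA-C bonds."""
        if any(x is None for x in (self.n, self.ca, self.c, self.o)):
            return False
        for a, b in ((self.n, self.ca), (self.ca, self.c)):
            d = float(np.linalg.norm(a - b))
            if not 1.2 <= d <= 1.8:
                return False
        return True

    def atom(self, name: str) -> np.ndarray | None:
        name = name.upper()
        if name in ("N", "CA", "C", "O"):
            return getattr(self, name.lower())
        return self.sidechain.get(name)


@dataclass
class TorsionTriple:
    """Backbone torsions in degrees, (-180, 180]; None where undefined
    (chain termini, breaks, incomplete residues)."""

    phi: float | None
    psi: float | None
    omega: float | None

    @property
    def is_cis(self) -> bool | None:
        if self.omega is None:
            return None
        return abs(self.omega) < 90.0


@dataclass
class HeteroAtom:
    name: str
    element: str
    xyz: np.ndarray
    residue_name: str = ""
    chain_id: str = ""


class StructureModel:
    """Ordered residues grouped by chain, plus retained heteroatoms."""

    def __init__(self, chains: dict[str, list[ResidueBackbone]],
                 label: str = "", source: str = "",
                 heteroatoms: list[HeteroAtom] | None = None):
        for cid, residues in chains.items():
            if not residues:
                raise ValueError(f"chain {cid} has no residues")
            keys = [(r.residue_number, r.insertion_code) for r in residues]
            if keys != sorted(keys):
                raise ValueError(f"chain {cid}: residues not in increasing order")
        self.chains = chains
        self.label = label
        self.source = source
        self.heteroatoms = heteroatoms or []

    # -- accessors ---------------------------------------------------------
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chain_id: str | None = None) -> list[ResidueBackbone]:
        if chain_id is not None:
            return self.chains[chain_id]
        return [r for residues in self.chains.values() for r in residues]

    def __len__(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def ca_coords(self, selection: list[tuple[int, int]] | None = None) -> np.ndarray:
        """CA coordinates of complete residues, optionally restricted to
        inclusive residue-number ranges."""
        rows = [r.ca for r in self.residues()
                if r.ca is not None and _in_selection(r, selection)]
        return np.array(rows)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A rigidly transformed copy."""
        def tx(p):
            return None if p is None else np.asarray(rotation) @ p + np.asarray(translation)

        chains = {}
        for cid, residues in self.chains.items():
            chains[cid] = [ResidueBackbone(
                r.chain_id, r.residue_number, r.amino_acid,
                tx(r.n), tx(r.ca), tx(r.c), tx(r.o),
                {k: tx(v) for k, v in r.sidechain.items()},
                r.confidence, r.insertion_code) for r in residues]
        het = [HeteroAtom(h.name, h.element, tx(h.xyz), h.residue_name, h.chain_id)
               for h in self.heteroatoms]
        return StructureModel(chains, self.label, self.source, het)


def _in_selection(res: ResidueBackbone, selection: list[tuple[int, int]] | None) -> bool:
    if selection is None:
        return True
    return any(lo <= res.residue_number <= hi for lo, hi in selection)


def parse_selection(text: str) -> list[tuple[int, int]]:
    """Parse '1-60,75-140' into inclusive residue-number ranges."""
    out = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk[1:]:
            cut = chunk.index("-", 1)
            out.append((int(chunk[:cut]), int(chunk[cut + 1:])))
        else:
            v = int(chunk)
            out.append((v, v))
    return out


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_structure(path: str, model_index: int = 1) -> StructureModel:
    """Read a PDB file into a StructureModel.

    ``model_index`` selects among MODEL records (1-based, default first).
    B-factors are surfaced as per-residue confidence (mean over backbone
    atoms).  Residues missing backbone atoms are kept but flagged incomplete
    (and logged); non-protein heteroatoms are retained separately.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparsable PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if not 1 <= model_index <= len(st):
        raise ValueError(f"model_index {model_index} out of range (file has {len(st)})")
    st.setup_entities()
    model = st[model_index - 1]
    chains: dict[str, list[ResidueBackbone]] = {}
    het: list[HeteroAtom] = []
    for chain in model:
        residues: list[ResidueBackbone] = []
        for res in chain:
            if res.name not in _THREE_TO_ONE:
                for atom in res:
                    het.append(HeteroAtom(atom.name, atom.element.name,
                                          np.array(atom.pos.tolist()),
                                          res.name, chain.name))
                continue
            rb = ResidueBackbone(chain.name, res.seqid.num,
                                 _THREE_TO_ONE[res.name],
                                 insertion_code=(res.seqid.icode or "").strip())
            bvals = []
            best_alt: dict[str, float] = {}
            for atom in res:
                # altloc: keep highest occupancy, first encountered on ties
                key = atom.name
                if key in best_alt and atom.occ <= best_alt[key]:
                    continue
                best_alt[key] = atom.occ
                pos = np.array(atom.pos.tolist())
                if atom.name in ("N", "CA", "C", "O"):
                    setattr(rb, atom.name.lower(), pos)
                    bvals.append(atom.b_iso)
                elif atom.element.name != "H":
                    rb.sidechain[atom.name] = pos
            if bvals:
                rb.confidence = float(np.mean(bvals))
            if not rb.complete:
                logger.warning("residue %s%d (%s) incomplete; excluded from "
                               "torsion/secondary-structure analysis",
                               chain.name, rb.residue_number, rb.amino_acid)
            residues.append(rb)
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise ValueError(f"no protein residues found in {path}")
    return StructureModel(chains, label=str(path), source=str(path), heteroatoms=het)


def write_structure(model: StructureModel, path: str) -> None:
    """Write a StructureModel to a PDB file (backbone + stored sidechains)."""
    st = gemmi.Structure()
    st.name = model.label or "igtandem"
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        ch = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = _ONE_TO_THREE.get(r.amino_acid, "GLY")
            gr.seqid = gemmi.SeqId(r.residue_number, r.insertion_code or " ")
            for name, pos in (("N", r.n), ("CA", r.ca), ("C", r.c), ("O", r.o)):
                if pos is None:
                    continue
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(name[0])
                at.pos = gemmi.Position(*map(float, pos))
                at.b_iso = r.confidence if r.confidence is not None else 0.0
                at.occ = 1.0
                gr.add_atom(at)
            for name, pos in r.sidechain.items():
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(name[0])
                at.pos = gemmi.Position(*map(float, pos))
                at.b_iso = r.confidence if r.confidence is not None else 0.0
                at.occ = 1.0
                gr.add_atom(at)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def backbone_torsions(model: StructureModel) -> dict[str, list[TorsionTriple]]:
    """Per-residue (phi, psi, omega) per chain.

    phi is undefined for the first residue of a segment, psi/omega for the
    last; torsions are never computed across chain breaks (CA-CA > 4.5 Å)
    or through incomplete residues.
    """
    out: dict[str, list[TorsionTriple]] = {}
    for cid, residues in model.chains.items():
        n = len(residues)
        linked = [False] * max(n - 1, 0)  # residue i bonded to i+1
        for i in range(n - 1):
            a, b = residues[i], residues[i + 1]
            if a.complete and b.complete and \
                    float(np.linalg.norm(a.ca - b.ca)) <= CHAIN_BREAK_CA_CA:
                linked[i] = True
        triples = []
        for i, r in enumerate(residues):
            phi = psi = omega = None
            if r.complete:
                if i > 0 and linked[i - 1]:
                    p = residues[i - 1]
                    phi = dihedral(p.c, r.n, r.ca, r.c)
                if i < n - 1 and linked[i]:
                    nx = residues[i + 1]
                    psi = dihedral(r.n, r.ca, r.c, nx.n)
                    omega = dihedral(r.ca, r.c, nx.n, nx.ca)
            triples.append(TorsionTriple(phi, psi, omega))
        out[cid] = triples
    return out


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def ca_rmsd(model_a: StructureModel, model_b: StructureModel,
            selection: list[tuple[int, int]] | None = None,
            fit: bool = True) -> float:
    """CA RMSD between two models over an optional residue-number selection.

    With ``fit=True`` (default) the optimal rigid superposition is applied;
    with ``fit=False`` coordinates are compared in their current frames.
    Both models must resolve the selection to equal-length CA sets.
    """
    ca_a = model_a.ca_coords(selection)
    ca_b = model_b.ca_coords(selection)
    if len(ca_a) == 0 or len(ca_b) == 0:
        raise ValueError("selection resolves to no residues")
    if len(ca_a) != len(ca_b):
        missing = abs(len(ca_a) - len(ca_b))
        raise ValueError(
            f"selection resolves to unequal CA sets ({len(ca_a)} vs {len(ca_b)}; "
            f"{missing} residues unmatched)")
    if fit:
        return superpose(ca_a, ca_b)[2]
    return rmsd_fixed(ca_a, ca_b)
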
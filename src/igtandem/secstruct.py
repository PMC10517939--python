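"""Hydrogen-bond, strand, sheet and β-sandwich geometry detection, plus
ABEGO torsion classification.

Backbone hydrogen bonds use the DSSP-style electrostatic model
``E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)`` kcal/mol with the
amide hydrogen reconstructed geometrically, so input structures need no
explicit hydrogens.  β-bridges follow the Kabsch-Sander patterns; strands
are maximal runs of bridge-forming residues (extended to residues whose
N/O participate in the same ladders), sheets are connected components of
the strand-pairing graph, and a β-sandwich is exactly two sheets facing
each other, summarized by the inter-sheet separation d and rotation θ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .geometry import amide_hydrogen
from .structure import StructureModel, ResidueBackbone, TorsionTriple

HB_ENERGY_CUTOFF = -0.5      # kcal/mol
HB_Q_FACTOR = 0.084 * 332.0
MIN_STRAND_LEN = 3
MIN_PAIR_HBONDS = 2
MAX_PEPTIDE_C_N = 2.0        # Å; peptide-bond continuity check


@dataclass(frozen=True)
class BackboneHBond:
    """N-H...O=C hydrogen bond between residue indices (global order)."""

    donor: int
    acceptor: int
    energy: float


@dataclass
class StrandSegment:
    """Maximal β-strand: half-open residue-index range [start, stop)."""

    strand_id: int
    start: int
    stop: int
    sheet_id: int = -1
    is_edge: bool = False
    direction: np.ndarray | None = None

    @property
    def residues(self) -> range:
        return range(self.start, self.stop)

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass
class StrandPairing:
    strand_a: int
    strand_b: int
    orientation: str          # 'parallel' | 'antiparallel'
    register: int             # antiparallel: i+j; parallel: j-i (global indices)
    hbond_count: int


@dataclass
class SandwichGeometry:
    """Two facing β-sheets: separation d (Å) and rotation θ (deg, [0, 90])."""

    sheets: tuple[list[int], list[int]]
    separation: float
    rotation: float
    edge_strands: tuple[list[int], list[int]]

    @property
    def all_edge_strands(self) -> list[int]:
        return self.edge_strands[0] + self.edge_strands[1]


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _flat_residues(model: StructureModel) -> list[ResidueBackbone]:
    return model.residues()


def _peptide_linked(prev: ResidueBackbone, res: ResidueBackbone) -> bool:
    if prev is None or prev.c is None or res.n is None:
        return False
    if prev.chain_id != res.chain_id:
        return False
    return float(np.linalg.norm(prev.c - res.n)) <= MAX_PEPTIDE_C_N


def _segments(residues: list[ResidueBackbone]) -> tuple[np.ndarray, list[bool]]:
    """Covalently continuous segment id per residue, plus the per-gap
    peptide-link flags (cont[i]: residue i bonded to i+1)."""
    n = len(residues)
    cont = [_peptide_linked(residues[i], residues[i + 1]) for i in range(n - 1)]
    seg = np.zeros(n, dtype=int)
    for i in range(1, n):
        seg[i] = seg[i - 1] + (0 if cont[i - 1] else 1)
    return seg, cont


def hbond_energy(n: np.ndarray, h: np.ndarray, c: np.ndarray, o: np.ndarray) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:   # overlapping atoms: not a bond
        return 0.0
    return float(HB_Q_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def detect_hbonds(model: StructureModel,
                  energy_cutoff: float = HB_ENERGY_CUTOFF) -> list[BackboneHBond]:
    """All backbone N-H...O=C bonds with energy below the cutoff.

    Donor/acceptor are global residue indices (model order).  Bonds between
    residues closer than 2 positions in the same covalently continuous
    segment are excluded; the amide H is reconstructed from the preceding
    carbonyl, so segment-initial residues cannot donate.
    """
    residues = _flat_residues(model)
    seg, _ = _segments(residues)
    hyd: list[np.ndarray | None] = [None] * len(residues)
    for i, r in enumerate(residues):
        prev = residues[i - 1] if i > 0 else None
        if r.complete and prev is not None and prev.complete and _peptide_linked(prev, r):
            hyd[i] = amide_hydrogen(prev.c, r.n, r.ca)
    donors = [i for i in range(len(residues)) if hyd[i] is not None]
    acceptors = [i for i, r in enumerate(residues) if r.complete]
    if not donors or not acceptors:
        return []
    acc_o = np.array([residues[j].o for j in acceptors])
    tree = cKDTree(acc_o)
    bonds = []
    for i in donors:
        ri = residues[i]
        for k in tree.query_ball_point(ri.n, 5.2):
            j = acceptors[k]
            rj = residues[j]
            if i == j:
                continue
            if seg[i] == seg[j] and abs(i - j) < 2:
                continue
            e = hbond_energy(ri.n, hyd[i], rj.c, rj.o)
            if e < energy_cutoff:
                bonds.append(BackboneHBond(i, j, e))
    return bonds


# ---------------------------------------------------------------------------
# Strands, pairings, sheets
# ---------------------------------------------------------------------------

def _bridges(model: StructureModel, hbonds: list[BackboneHBond]) -> list[tuple[int, int, str]]:
    """Kabsch-Sander β-bridges (i, j, orientation), i < j."""
    residues = _flat_residues(model)
    n = len(residues)
    has = {(b.donor, b.acceptor) for b in hbonds}
    seg, cont = _segments(residues)

    def interior(i: int) -> bool:
        return 0 < i < n - 1 and cont[i - 1] and cont[i]

    out = []
    near = {x + d for b in hbonds for x in (b.donor, b.acceptor) for d in (-1, 0, 1)}
    for i in range(n):
        if i not in near:
            continue
        for j in range(i + 1, n):
            if j not in near:
                continue
            if seg[i] == seg[j] and j - i < 3:
                continue
            anti = ((i, j) in has and (j, i) in has)
            if not anti and interior(i) and interior(j):
                anti = ((j + 1, i - 1) in has and (i + 1, j - 1) in has)
            if anti:
                out.append((i, j, "antiparallel"))
                continue
            if interior(i) and interior(j):
                para = (((j, i - 1) in has and (i + 1, j) in has) or
                        ((i, j - 1) in has and (j + 1, i) in has))
                if para:
                    out.append((i, j, "parallel"))
    return out


def assign_strands_and_sheets(model: StructureModel,
                              hbonds: list[BackboneHBond] | None = None
                              ) -> tuple[list[StrandSegment], list[StrandPairing]]:
    """Strand segments and their pairings from backbone H-bonds.

    Strands are maximal consecutive runs of bridged residues, extended by
    residues that participate in the same inter-strand ladders; pairings are
    labelled parallel/antiparallel with a register offset (sum of paired
    indices for antiparallel, difference for parallel) and require at least
    two hydrogen bonds.  Sheet ids are connected components of the pairing
    graph, numbered by their lowest residue index.
    """
    if hbonds is None:
        hbonds = detect_hbonds(model)
    residues = _flat_residues(model)
    n = len(residues)
    bridges = _bridges(model, hbonds)
    bridged = np.zeros(n, dtype=bool)
    for i, j, _ in bridges:
        bridged[i] = bridged[j] = True

    # ladder participation: bonded to a residue beyond helical range, i.e.
    # in another covalent segment or more than 4 positions away
    seg, cont = _segments(residues)
    participates = np.zeros(n, dtype=bool)
    for b in hbonds:
        if seg[b.donor] != seg[b.acceptor] or abs(b.donor - b.acceptor) > 4:
            participates[b.donor] = participates[b.acceptor] = True

    # β-compatible torsions (extended bin, allowing undefined at segment ends)
    from .structure import backbone_torsions
    torsion_map = backbone_torsions(model)
    flat_torsions = []
    for cid in model.chains:
        flat_torsions.extend(torsion_map[cid])
    beta_ok = np.zeros(n, dtype=bool)
    for i, t in enumerate(flat_torsions):
        if t.phi is None and t.psi is None:
            continue
        phi_ok = t.phi is None or t.phi < 0.0
        psi_ok = t.psi is None or not (-75.0 < t.psi <= 50.0)
        beta_ok[i] = phi_ok and psi_ok

    in_strand = bridged.copy()
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if in_strand[i] or not (participates[i] or beta_ok[i]):
                continue
            prev_ok = i > 0 and cont[i - 1] and in_strand[i - 1]
            next_ok = i < n - 1 and cont[i] and in_strand[i + 1]
            if prev_ok or next_ok:
                in_strand[i] = True
                changed = True

    strands: list[StrandSegment] = []
    i = 0
    while i < n:
        if not in_strand[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and in_strand[j + 1] and cont[j]:
            j += 1
        if j - i + 1 >= MIN_STRAND_LEN:
            seg = StrandSegment(len(strands), i, j + 1)
            ca = np.array([residues[k].ca for k in range(i, j + 1)])
            d = ca[-1] - ca[0]
            seg.direction = d / np.linalg.norm(d)
            strands.append(seg)
        i = j + 1

    def strand_of(idx: int) -> int | None:
        for s in strands:
            if s.start <= idx < s.stop:
                return s.strand_id
        return None

    # pairings from bridges + bond counts
    pair_bridges: dict[tuple[int, int], list[tuple[int, int, str]]] = {}
    for i, j, orient in bridges:
        a, b = strand_of(i), strand_of(j)
        if a is None or b is None or a == b:
            continue
        key = (min(a, b), max(a, b))
        pair_bridges.setdefault(key, []).append((i, j, orient))
    bond_count: dict[tuple[int, int], int] = {}
    for hb in hbonds:
        a, b = strand_of(hb.donor), strand_of(hb.acceptor)
        if a is None or b is None or a == b:
            continue
        key = (min(a, b), max(a, b))
        bond_count[key] = bond_count.get(key, 0) + 1

    pairings = []
    for (a, b), brs in pair_bridges.items():
        if bond_count.get((a, b), 0) < MIN_PAIR_HBONDS:
            continue
        orients = {o for _, _, o in brs}
        orient = "antiparallel" if "antiparallel" in orients else "parallel"
        regs = [i + j if orient == "antiparallel" else j - i
                for i, j, o in brs if o == orient]
        register = int(np.median(regs))
        pairings.append(StrandPairing(a, b, orient, register, bond_count[(a, b)]))

    # sheets: connected components of pairing graph
    g = nx.Graph()
    g.add_nodes_from(s.strand_id for s in strands)
    g.add_edges_from((p.strand_a, p.strand_b) for p in pairings)
    comps = sorted(nx.connected_components(g), key=min)
    for sheet_id, comp in enumerate(comps):
        for sid in comp:
            strands[sid].sheet_id = sheet_id
    # edge strands: at most one pairing partner within the sheet
    degree = {s.strand_id: 0 for s in strands}
    for p in pairings:
        degree[p.strand_a] += 1
        degree[p.strand_b] += 1
    for s in strands:
        s.is_edge = degree[s.strand_id] <= 1
    return strands, pairings


# ---------------------------------------------------------------------------
# Sandwich geometry
# ---------------------------------------------------------------------------

def _sheet_frame(model: StructureModel, strands: list[StrandSegment]
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(centroid, unit normal, mean strand direction) of one sheet."""
    residues = _flat_residues(model)
    ca = np.array([residues[k].ca for s in strands for k in s.residues])
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    normal = vt[2]
    ref = strands[0].direction
    dirs = [s.direction if np.dot(s.direction, ref) >= 0 else -s.direction
            for s in strands]
    mean_dir = np.mean(dirs, axis=0)
    mean_dir = mean_dir / np.linalg.norm(mean_dir)
    return centroid, normal, mean_dir


def detect_sandwich(model: StructureModel,
                    hbonds: list[BackboneHBond] | None = None) -> SandwichGeometry:
    """Detect a two-sheet β-sandwich and measure its global geometry.

    Requires exactly two sheets of >= 2 strands facing each other (sheet
    normals anti-aligned within 60° once oriented toward the partner sheet).
    Separation d is the centroid distance along the mean normal; rotation θ
    is the unsigned acute angle between the sheets' mean strand directions.
    """
    strands, pairings = assign_strands_and_sheets(model, hbonds)
    sheets: dict[int, list[StrandSegment]] = {}
    for s in strands:
        sheets.setdefault(s.sheet_id, []).append(s)
    big = {k: v for k, v in sheets.items() if len(v) >= 2}
    if len(big) != 2:
        raise ValueError(f"not a two-sheet sandwich: found {len(big)} sheets "
                         f"with >= 2 strands")
    (ka, sa), (kb, sb) = sorted(big.items())
    c_a, n_a, d_a = _sheet_frame(model, sa)
    c_b, n_b, d_b = _sheet_frame(model, sb)
    sep_vec = c_b - c_a
    # orient normals toward the partner sheet
    if np.dot(n_a, sep_vec) < 0:
        n_a = -n_a
    if np.dot(n_b, -sep_vec) < 0:
        n_b = -n_b
    cos_face = np.clip(np.dot(n_a, -n_b), -1.0, 1.0)
    if np.degrees(np.arccos(cos_face)) > 60.0:
        raise ValueError("not a two-sheet sandwich: sheets do not face each other")
    mean_normal = n_a - n_b
    mean_normal = mean_normal / np.linalg.norm(mean_normal)
    separation = abs(float(np.dot(sep_vec, mean_normal)))
    cos_t = abs(float(np.dot(d_a, d_b)))
    rotation = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))
    edge = ([s.strand_id for s in sa if s.is_edge],
            [s.strand_id for s in sb if s.is_edge])
    return SandwichGeometry(( [s.strand_id for s in sa], [s.strand_id for s in sb] ),
                            separation, rotation, edge)


@dataclass
class CompatibilityResult:
    compatible: bool
    delta_separation: float
    delta_rotation: float


def sandwich_compatibility(geom_a: SandwichGeometry, geom_b: SandwichGeometry,
                           tol_separation: float = 1.5,
                           tol_rotation: float = 15.0) -> CompatibilityResult:
    """Are two sandwich geometries similar enough for two-layer pairing?

    Passes iff |Δd| <= tol_separation and |Δθ| <= tol_rotation (inclusive).
    """
    dd = abs(geom_a.separation - geom_b.separation)
    dt = abs(geom_a.rotation - geom_b.rotation)
    return CompatibilityResult(dd <= tol_separation and dt <= tol_rotation, dd, dt)


# ---------------------------------------------------------------------------
# ABEGO
# ---------------------------------------------------------------------------

def abego_letter(phi: float | None, psi: float | None, omega: float | None) -> str:
    """ABEGO torsion bin of one residue ('-' where undefined)."""
    if omega is not None and abs(omega) < 90.0:
        return "O"
    if phi is None or psi is None:
        return "-"
    if phi < 0.0:
        return "A" if -75.0 < psi <= 50.0 else "B"
    return "G" if -100.0 < psi <= 100.0 else "E"


def abego_string(torsions: list[TorsionTriple]) -> str:
    """ABEGO string over {A, B, E, G, O}; '-' where torsions are undefined."""
    return "".join(abego_letter(t.phi, t.psi, t.omega) for t in torsions)


ALLOWED_BA_LOOPS = ("BAB",)
ALLOWED_AB_LOOPS = ("BA", "GB", "AGB", "GBA")
HELIX_LENGTH_RANGE = (12, 16)


def validate_connector_geometry(abego_ba: str, abego_ab: str, helix_length: int) -> bool:
    """βαβ connector admissibility: βα loop BAB, αβ loop in {BA, GB, AGB,
    GBA}, helix length 12-16 residues."""
    return (abego_ba in ALLOWED_BA_LOOPS
            and abego_ab in ALLOWED_AB_LOOPS
            and HELIX_LENGTH_RANGE[0] <= helix_length <= HELIX_LENGTH_RANGE[1])
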
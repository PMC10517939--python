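"""Geometric realization of edge-to-edge fusions and the face-to-face
pose sampler.

Edge-to-edge poses place domain B so that its designated terminal strands
adopt ideal inter-strand geometry against domain A's terminal edge in both
sheet layers simultaneously; candidate registers are scored by realized
cross-domain hydrogen bonds minus a clash penalty.  The face-to-face sampler
reproduces the alternative (antibody-like) arrangement: domains separated by
20 Å between centers of mass, then randomized rotation (100-160°),
translation (-15 to -5 Å) and tilt (-50 to -25°), with loop-closure
feasibility screened for 2-3-residue linkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import superpose, build_backbone, ABEGO_TORSIONS, BOND_C_N
from .structure import StructureModel, ResidueBackbone
from .secstruct import (detect_hbonds, assign_strands_and_sheets,
                        detect_sandwich, SandwichGeometry, StrandSegment)
from .topology import FusionArrangement

# ideal paired-strand geometry (canonical β-sheet values)
ANTIPARALLEL_CA_CA = 4.9
PARALLEL_CA_CA = 4.8
STRAND_RUNG = 3.465
CLASH_CUTOFF = 3.0
CLASH_PENALTY = 2.0
MAX_LOOP_SPAN_PER_RESIDUE = 3.8


@dataclass
class RigidPose:
    """A scored rigid placement of domain B against domain A."""

    rotation: np.ndarray
    translation: np.ndarray
    register: int
    hbond_count: int
    clash_count: int
    paired_layers: int
    hbond_energy: float = 0.0      # summed cross-domain bond energies, kcal/mol

    @property
    def score(self) -> float:
        return self.hbond_count - CLASH_PENALTY * self.clash_count

    @property
    def exposed_edge_strands(self) -> int:
        return 8 - 2 * self.paired_layers


@dataclass
class ConnectorSpec:
    """Interdomain connector: βαβ helix (parallel fusions) or β-hairpin
    (antiparallel fusions)."""

    kind: str                            # 'beta_alpha_beta' | 'beta_hairpin'
    helix_length: int = 14
    abego_ba: str = "BAB"
    abego_ab: str = "GBA"
    hairpin_loop_length: int = 2
    hairpin_abego: str = ""
    n_strand_extension: int = 0

    def __post_init__(self):
        if self.kind == "beta_alpha_beta":
            if not 12 <= self.helix_length <= 16:
                raise ValueError("helix length must be 12-16 residues")
        elif self.kind == "beta_hairpin":
            if not 2 <= self.hairpin_loop_length <= 5:
                raise ValueError("hairpin loop must be 2-5 residues")
        else:
            raise ValueError(f"unknown connector kind {self.kind!r}")
        if not 0 <= self.n_strand_extension <= 3:
            raise ValueError("N-strand extension must be 0-3 residues")


@dataclass
class ClosureReport:
    gap: float                 # end-to-end deviation from the target anchor (Å)
    n_residues: int
    closable: bool


@dataclass
class FaceToFaceSample:
    trial: int
    rotation: float
    translation: float
    tilt: float
    separation: float
    termini_gap: float
    closable: bool
    linker_length: int | None


# ---------------------------------------------------------------------------
# closure feasibility
# ---------------------------------------------------------------------------

def closure_feasible(gap: float, n_residues: int) -> bool:
    """Can a loop of n residues span the gap?  Conservative screen:
    0 <= gap <= 3.8 Å * (n + 1)."""
    if gap < 0 or n_residues < 1:
        raise ValueError("gap must be >= 0 and n_residues >= 1")
    return gap <= MAX_LOOP_SPAN_PER_RESIDUE * (n_residues + 1)


# ---------------------------------------------------------------------------
# edge-to-edge pose construction
# ---------------------------------------------------------------------------

def _terminal_edge_strands(model: StructureModel,
                           strands: list[StrandSegment]) -> tuple[StrandSegment, StrandSegment]:
    """(first, last) strand in sequence order; both must be edge strands."""
    first, last = strands[0], strands[-1]
    if not (first.is_edge and last.is_edge):
        raise ValueError("terminal strands are not edge strands; cannot build "
                         "an edge-to-edge fusion")
    return first, last


def _strand_ca(model: StructureModel, seg: StrandSegment) -> np.ndarray:
    residues = model.residues()
    return np.array([residues[k].ca for k in seg.residues])


def _sheet_outward(model: StructureModel, seg: StrandSegment,
                   strands: list[StrandSegment]) -> np.ndarray:
    """In-sheet unit vector pointing from the sheet body toward (and past)
    the edge strand ``seg``."""
    residues = model.residues()
    mates = [s for s in strands if s.sheet_id == seg.sheet_id and s is not seg]
    body = np.array([residues[k].ca for s in mates for k in s.residues]).mean(axis=0)
    cen = _strand_ca(model, seg).mean(axis=0)
    w = cen - body
    u = seg.direction
    w = w - np.dot(w, u) * u
    return w / np.linalg.norm(w)


def merge_models(domain_a: StructureModel, domain_b: StructureModel
                 ) -> StructureModel:
    """Two domains as one model with chains A and B."""
    ra = [ResidueBackbone("A", r.residue_number, r.amino_acid, r.n, r.ca, r.c,
                          r.o, r.sidechain, r.confidence, r.insertion_code)
          for r in domain_a.residues()]
    rb = [ResidueBackbone("B", r.residue_number, r.amino_acid, r.n, r.ca, r.c,
                          r.o, r.sidechain, r.confidence, r.insertion_code)
          for r in domain_b.residues()]
    return StructureModel({"A": ra, "B": rb}, label="fused")


def build_edge_to_edge_pose(domain_a: StructureModel, domain_b: StructureModel,
                            arrangement: FusionArrangement,
                            register_window: int = 2) -> list[RigidPose]:
    """Scored rigid poses of B against A's terminal edge, one per register.

    For each register shift the designated terminal strands of B are placed
    at ideal inter-strand geometry (CA-CA 4.9 Å antiparallel / 4.8 Å
    parallel) next to A's terminal strands in both layers; poses are ranked
    by cross-domain hydrogen bonds minus a clash penalty.
    """
    geom_a = detect_sandwich(domain_a)
    geom_b = detect_sandwich(domain_b)
    strands_a, _ = assign_strands_and_sheets(domain_a)
    strands_b, _ = assign_strands_and_sheets(domain_b)
    a_n, a_c = _terminal_edge_strands(domain_a, strands_a)
    b_n, b_c = _terminal_edge_strands(domain_b, strands_b)

    by_term_a = {"N": a_n, "C": a_c}
    by_term_b = {"N": b_n, "C": b_c}
    layers = []
    for term_a, term_b, orientation in arrangement.paired_termini:
        layers.append((by_term_a[term_a], by_term_b[term_b], orientation))

    poses = []
    shift_axis = layers[0][0].direction     # common strand axis for registers
    for shift in range(-register_window, register_window + 1):
        targets = []
        sources = []
        for seg_a, seg_b, orientation in layers:
            ca_a = _strand_ca(domain_a, seg_a)
            ca_b = _strand_ca(domain_b, seg_b)
            w = _sheet_outward(domain_a, seg_a, strands_a)
            u = seg_a.direction
            nrm = np.cross(u, w)
            c = ca_a.mean(axis=0)
            la = len(ca_a)
            k = min(la, len(ca_b))
            if orientation == "antiparallel":
                # ideal partner: 180° flip about the sheet normal through the
                # strand center, then out by the canonical spacing; even
                # strand lengths get a one-rung shift so that donors face
                # acceptors of matching pleat parity
                flip = 2.0 * np.outer(nrm, nrm) - np.eye(3)
                mapped = (ca_a - c) @ flip.T + c + ANTIPARALLEL_CA_CA * w
                tgt = mapped[:k]
                if la % 2 == 0:
                    tgt = tgt - STRAND_RUNG * u
            else:
                tgt = ca_a[:k] + PARALLEL_CA_CA * w
            tgt = tgt + shift * STRAND_RUNG * shift_axis
            src = ca_b[:k]
            targets.append(tgt)
            sources.append(src)
        R, t, _ = superpose(np.vstack(targets), np.vstack(sources))
        placed = domain_b.transformed(R, t)
        merged = merge_models(domain_a, placed)
        hbonds = detect_hbonds(merged)
        na = len(domain_a.residues())
        cross = [b for b in hbonds
                 if (b.donor < na) != (b.acceptor < na)]
        # bonds per designated layer pairing
        paired_layers = 0
        for seg_a, seg_b, _ in layers:
            count = sum(1 for b in cross
                        if _bond_touches(b, seg_a, seg_b, na))
            if count >= 2:
                paired_layers += 1
        exclude_a = {k for seg_a, _, _ in layers for k in seg_a.residues}
        exclude_b = {k for _, seg_b, _ in layers for k in seg_b.residues}
        clashes = clash_count(domain_a, placed, CLASH_CUTOFF,
                              exclude_a=exclude_a, exclude_b=exclude_b)
        poses.append(RigidPose(R, t, shift, len(cross), clashes, paired_layers,
                               sum(b.energy for b in cross)))
    poses.sort(key=lambda p: (-p.score, abs(p.register)))
    return poses


def _bond_touches(bond, seg_a: StrandSegment, seg_b: StrandSegment, na: int) -> bool:
    i, j = bond.donor, bond.acceptor
    if i >= na:
        i, j = j, i
    return i in seg_a.residues and (j - na) in seg_b.residues


def clash_count(domain_a: StructureModel, domain_b: StructureModel,
                cutoff: float = CLASH_CUTOFF,
                exclude_a: set[int] | None = None,
                exclude_b: set[int] | None = None) -> int:
    """Inter-domain backbone atom pairs closer than the cutoff, excluding
    residues of intentionally paired strands."""
    def atoms(model, exclude):
        pts = []
        for idx, r in enumerate(model.residues()):
            if exclude and idx in exclude:
                continue
            for p in (r.n, r.ca, r.c, r.o):
                if p is not None:
                    pts.append(p)
        return np.array(pts) if pts else np.empty((0, 3))

    pa = atoms(domain_a, exclude_a)
    pb = atoms(domain_b, exclude_b)
    if len(pa) == 0 or len(pb) == 0:
        return 0
    tree = cKDTree(pa)
    return int(sum(len(hits) for hits in tree.query_ball_point(pb, cutoff)))


def count_exposed_edge_strands(obj) -> int:
    """Solvent-exposed edge strands.

    Accepts a RigidPose (8 minus two per hydrogen-bonded interface layer),
    a FusionArrangement ('edge-to-edge': both layers paired, 4 exposed),
    the string 'face_to_face' (nothing paired, 8), or a single
    SandwichGeometry (4).
    """
    if isinstance(obj, RigidPose):
        return obj.exposed_edge_strands
    if isinstance(obj, FusionArrangement):
        return 4
    if isinstance(obj, SandwichGeometry):
        return len(obj.all_edge_strands)
    if isinstance(obj, str):
        key = obj.replace("-", "_")
        if key == "face_to_face":
            return 8
        if key in ("edge_to_edge", "single_domain"):
            return 4
    raise TypeError(f"cannot count edge strands for {obj!r}")


# ---------------------------------------------------------------------------
# connector backbone
# ---------------------------------------------------------------------------

def connector_torsions(spec: ConnectorSpec) -> list[tuple[float, float, float]]:
    if spec.kind == "beta_alpha_beta":
        letters = spec.abego_ba + "A" * spec.helix_length + spec.abego_ab
    else:
        letters = spec.hairpin_abego or "G" * spec.hairpin_loop_length
    return [ABEGO_TORSIONS[c] + (180.0,) for c in letters]


def build_connector_backbone(spec: ConnectorSpec,
                             anchor_a: np.ndarray,
                             anchor_b: np.ndarray
                             ) -> tuple[dict[str, np.ndarray], ClosureReport]:
    """Generate a connector backbone from ideal per-letter torsions.

    ``anchor_a``/``anchor_b`` are (3, 3) arrays of the flanking residues'
    (N, CA, C).  The fragment grows from anchor_a; the closure report gives
    the deviation of its C-terminal carbonyl carbon from anchor_b's expected
    amide position, and a feasibility flag for that many residues.
    Infeasible closures are reported, never raised.
    """
    torsions = connector_torsions(spec)
    anchor_a = np.asarray(anchor_a)
    anchor_b = np.asarray(anchor_b)
    frag = build_backbone(torsions, start=anchor_a)
    span = float(np.linalg.norm(anchor_b[0] - anchor_a[2]))
    deviation = max(float(np.linalg.norm(frag["C"][-1] - anchor_b[0])) - BOND_C_N, 0.0)
    report = ClosureReport(deviation, len(torsions),
                           closure_feasible(span, len(torsions)))
    return frag, report


def connector_gap_closable(anchor_a_c: np.ndarray, anchor_b_n: np.ndarray,
                           n_residues: int) -> bool:
    """Loop-closure screen straight from anchor coordinates."""
    gap = float(np.linalg.norm(np.asarray(anchor_b_n) - np.asarray(anchor_a_c)))
    return closure_feasible(gap, n_residues)


# ---------------------------------------------------------------------------
# face-to-face sampler
# ---------------------------------------------------------------------------

ROTATION_RANGE = (100.0, 160.0)
TRANSLATION_RANGE = (-15.0, -5.0)
TILT_RANGE = (-50.0, -25.0)
FF_SEPARATION = 20.0
FF_LINKERS = (2, 3)


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def sample_face_to_face(domain_a: StructureModel, domain_b: StructureModel,
                        n_trials: int, seed: int = 0,
                        rotation_range: tuple[float, float] = ROTATION_RANGE,
                        translation_range: tuple[float, float] = TRANSLATION_RANGE,
                        tilt_range: tuple[float, float] = TILT_RANGE,
                        separation: float = FF_SEPARATION
                        ) -> list[FaceToFaceSample]:
    """Randomized face-to-face dimer poses with loop-closure screening.

    Domain B is first moved ``separation`` Å away from A along the
    center-of-mass axis (the mean sheet normal), then each trial applies a
    random rotation about that axis, a translation back along it (negative
    values pull the domains together again) and a tilt about the in-plane
    axis perpendicular to the mean strand direction, all drawn uniformly
    from the given ranges.  A trial is closable if the termini gap can be
    spanned by a 2- or 3-residue linker.
    """
    rng = np.random.default_rng(seed)
    ca_a = domain_a.ca_coords()
    ca_b = domain_b.ca_coords()
    com_a, com_b = ca_a.mean(axis=0), ca_b.mean(axis=0)

    try:
        strands_a, _ = assign_strands_and_sheets(domain_a)
        dirs = [s.direction if np.dot(s.direction, strands_a[0].direction) >= 0
                else -s.direction for s in strands_a]
        axis_u = np.mean(dirs, axis=0)
        axis_u = axis_u / np.linalg.norm(axis_u)
    except (ValueError, IndexError):
        axis_u = np.array([1.0, 0.0, 0.0])
    _, _, vt = np.linalg.svd(ca_a - com_a)
    normal = vt[2]
    if abs(np.dot(normal, axis_u)) > 0.9:
        normal = vt[1]
    normal = normal - np.dot(normal, axis_u) * axis_u
    normal = normal / np.linalg.norm(normal)
    tilt_axis = np.cross(normal, axis_u)

    base_shift = com_a + separation * normal - com_b
    a_cterm = domain_a.residues()[-1].c
    samples = []
    for trial in range(n_trials):
        rot = float(rng.uniform(*rotation_range))
        trans = float(rng.uniform(*translation_range))
        tilt = float(rng.uniform(*tilt_range))
        center = com_b + base_shift
        R = _axis_rotation(normal, rot) @ _axis_rotation(tilt_axis, tilt)
        b_nterm = domain_b.residues()[0].n + base_shift
        b_nterm = R @ (b_nterm - center) + center + trans * normal
        gap = float(np.linalg.norm(b_nterm - a_cterm))
        linker = next((nl for nl in FF_LINKERS if closure_feasible(gap, nl)), None)
        samples.append(FaceToFaceSample(trial, rot, trans, tilt, separation,
                                        gap, linker is not None, linker))
    return samples


def closable_fraction(samples: list[FaceToFaceSample]) -> float:
    if not samples:
        return 0.0
    return sum(s.closable for s in samples) / len(samples)
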
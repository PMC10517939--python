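"""Synthetic test fixtures with exact ground truth.

Generates idealized β-sheets and two-sheet β-sandwiches whose strand
ranges, pairings, hydrogen-bond ladders, edge strands and global geometry
(separation d, rotation θ) are known by construction; plus abstract fused
topologies, perturbed model pairs, conformational ensembles and noisy
binding titrations with known ground truth.

Strands are built from ideal antiparallel-sheet torsions (φ, ψ) =
(-139°, +135°); neighbouring strands are placed with frozen pair transforms
(derived once from the hydrogen-bond energy model and kept as constants)
that realize clean N-H...O=C ladders at canonical ~4.8-5.0 Å strand spacing.
The planned ladder follows closed-form parity rules, so detectors are tested
against bookkeeping that is independent of the detection code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .binding import TitrationSeries
from .geometry import build_backbone, amide_hydrogen, random_rotation
from .structure import StructureModel, ResidueBackbone
from . import topology as topo

# frozen strand/pair geometry (Å, degrees)
STRAND_PHI, STRAND_PSI = -139.0, 135.0
ANTI_DX, ANTI_DY = 0.14, 4.95          # antiparallel neighbour: flip + translate
PARA_DX, PARA_DY, PARA_DZ = -0.02, 4.65, -0.95
RUNG = 3.465                            # one strand rung (half the 2-residue repeat)
_FLIP = np.diag([-1.0, -1.0, 1.0])      # 180° about the sheet normal

MAX_LOOP_SPAN_PER_RESIDUE = 3.8


@dataclass
class SandwichRecipe:
    """Recipe for an idealized two-sheet β-sandwich."""

    strands_per_sheet: int = 6
    strand_length: int = 7
    sheet_separation: float = 10.0
    sheet_rotation: float = 25.0
    loop_length: int | None = None     # residues implied between strands (numbering gap)
    strand_order: list[tuple[int, int]] | None = None  # sequence order of (sheet, slot)
    seed: int = 0

    def __post_init__(self):
        if self.strands_per_sheet < 2:
            raise ValueError("need at least 2 strands per sheet")
        if self.strand_length < 3:
            raise ValueError("strand length must be >= 3")
        if self.sheet_separation <= 0:
            raise ValueError("sheet separation must be positive")


@dataclass
class PairingTruth:
    strand_a: int
    strand_b: int
    orientation: str
    register: int
    bonds: list[tuple[int, int]]       # (donor, acceptor) global residue indices


@dataclass
class SheetTruth:
    """Ground truth for one generated sheet/sandwich."""

    strand_ranges: list[tuple[int, int]]   # half-open global index ranges
    sheet_of: list[int]
    directions: list[int]
    pairings: list[PairingTruth]
    edge_strands: list[int]
    separation: float | None = None
    rotation: float | None = None

    @property
    def planned_bonds(self) -> list[tuple[int, int]]:
        return [b for p in self.pairings for b in p.bonds]


# ---------------------------------------------------------------------------
# strand template
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _strand_template(n: int) -> tuple[np.ndarray, ...]:
    """Ideal strand of n residues, centered, axis +x, H-bond direction ±y."""
    bb = build_backbone([(STRAND_PHI, STRAND_PSI, 180.0)] * n)
    N, CA, C, O = bb["N"], bb["CA"], bb["C"], bb["O"]
    cen = CA.mean(axis=0)
    x = CA[-1] - CA[0]
    x = x / np.linalg.norm(x)
    acc = np.zeros(3)
    for i in range(1, n):
        h = amide_hydrogen(C[i - 1], N[i], CA[i])
        acc += ((-1) ** i) * (h - N[i])
    y = acc - np.dot(acc, x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    R = np.vstack([x, y, z])
    return tuple((a - cen) @ R.T for a in (N, CA, C, O))


def _pair_plan(length: int, f_lower: int, step: str) -> list[tuple[str, int, int]]:
    """Planned H-bonds for one adjacent strand pair, strand-local indices.

    Returns (direction, donor, acceptor) with direction 'lu' (lower strand
    donates to upper) or 'ul'.  Parity rules derived from the frozen pair
    geometry: antiparallel donors share the parity of the lower strand's
    flip state and bond across the pair's two-fold axis; parallel donors
    alternate between the strands and bond one rung down.
    """
    plan = []
    if step == "anti":
        m = 0 if length % 2 == 1 else (-1 if f_lower == 0 else 1)
        for i in range(1, length):
            if i % 2 != f_lower % 2:
                continue
            j = length - 1 - i + m
            if 0 <= j <= length - 1:
                plan.append(("lu", i, j))
                plan.append(("ul", i, j))
    else:
        for i in range(1, length):
            if i % 2 == f_lower % 2:       # lower donors: even if unflipped
                if 0 <= i - 1 <= length - 1:
                    plan.append(("lu", i, i - 1))
            else:                           # upper donors: the other parity
                if 0 <= i - 1 <= length - 1:
                    plan.append(("ul", i, i - 1))
    return plan


def _build_sheet_atoms(n_strands: int, length: int,
                       directions: list[int] | None = None
                       ) -> tuple[list[tuple[np.ndarray, ...]], list[int], list[dict]]:
    """Place strands of one flat sheet; returns (atom sets, flip states,
    per-pair plans with local indices and orientation/register info)."""
    if directions is None:
        directions = [1 if k % 2 == 0 else -1 for k in range(n_strands)]
    if len(directions) != n_strands:
        raise ValueError("directions length mismatch")
    template = _strand_template(length)
    flips = [0 if d > 0 else 1 for d in directions]
    offsets = [np.zeros(3)]
    pair_meta = []
    for k in range(n_strands - 1):
        f = flips[k]
        anti = directions[k + 1] != directions[k]
        if anti:
            sigma = 1.0 if f == 0 else -1.0
            dx = sigma * ANTI_DX - (RUNG if length % 2 == 0 else 0.0)
            delta = np.array([dx, ANTI_DY, 0.0])
            step = "anti"
        else:
            dz = PARA_DZ if f == 0 else -PARA_DZ
            delta = np.array([PARA_DX, PARA_DY, dz])
            step = "para"
        offsets.append(offsets[-1] + delta)
        pair_meta.append({"step": step, "f_lower": f,
                          "plan": _pair_plan(length, f, step)})
    atom_sets = []
    for k in range(n_strands):
        R = _FLIP if flips[k] else np.eye(3)
        atom_sets.append(tuple(a @ R.T + offsets[k] for a in template))
    return atom_sets, flips, pair_meta


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def _assemble_model(strand_atoms: list[tuple[np.ndarray, ...]],
                    loop_gap: int, label: str) -> StructureModel:
    """Single-chain model from strand atom sets, with numbering gaps in
    place of loops (chain breaks between strands)."""
    residues = []
    num = 1
    for atoms in strand_atoms:
        N, CA, C, O = atoms
        for i in range(len(N)):
            residues.append(ResidueBackbone("A", num, "V", N[i].copy(), CA[i].copy(),
                                            C[i].copy(), O[i].copy()))
            num += 1
        num += loop_gap
    return StructureModel({"A": residues}, label=label)


def _pairing_truths(pair_meta: list[dict], starts: list[int], length: int,
                    seq_of_slot: list[int]) -> list[PairingTruth]:
    """Convert per-pair local plans to global-index bond lists and registers.

    ``starts[s]`` is the first global residue index of the strand at spatial
    slot position given by ``seq_of_slot``.
    """
    out = []
    for k, meta in enumerate(pair_meta):
        lo, up = seq_of_slot[k], seq_of_slot[k + 1]
        s_lo, s_up = starts[lo], starts[up]
        bonds = []
        for direction, i, j in meta["plan"]:
            if direction == "lu":
                bonds.append((s_lo + i, s_up + j))
            else:
                bonds.append((s_up + i, s_lo + j))
        if meta["step"] == "anti":
            m = 0 if length % 2 == 1 else (-1 if meta["f_lower"] == 0 else 1)
            register = s_lo + s_up + length - 1 + m
            orientation = "antiparallel"
        else:
            register = abs(s_up - s_lo)
            orientation = "parallel"
        a, b = sorted((lo, up))
        out.append(PairingTruth(a, b, orientation, register, bonds))
    return out


def make_ideal_sheet(n_strands: int = 2, strand_length: int = 7,
                     directions: list[int] | None = None,
                     loop_gap: int = 3,
                     label: str = "ideal-sheet") -> tuple[StructureModel, SheetTruth]:
    """One flat ideal β-sheet (sequence order = spatial order)."""
    atoms, flips, pair_meta = _build_sheet_atoms(n_strands, strand_length, directions)
    model = _assemble_model(atoms, loop_gap, label)
    starts = [k * strand_length for k in range(n_strands)]
    truth = SheetTruth(
        strand_ranges=[(s, s + strand_length) for s in starts],
        sheet_of=[0] * n_strands,
        directions=[1 if f == 0 else -1 for f in flips],
        pairings=_pairing_truths(pair_meta, starts, strand_length,
                                 list(range(n_strands))),
        edge_strands=[0, n_strands - 1] if n_strands > 1 else [0],
    )
    return model, truth


def make_ideal_sandwich(recipe: SandwichRecipe
                        ) -> tuple[StructureModel, SheetTruth]:
    """Idealized two-sheet β-sandwich with exact ground-truth annotation.

    Sheet 1 is rotated by the recipe's rotation about the sandwich normal
    and offset by the sheet separation.  Sequence order is by sheet (sheet 0
    strands then sheet 1), or as given by ``strand_order``; loops are
    represented as residue-numbering gaps.  Raises if an explicit loop
    length cannot span a junction (3.8 Å per residue plus one).
    """
    r = recipe
    S, L = r.strands_per_sheet, r.strand_length
    # Sheet 1 is the same construction rotated 180° about the in-sheet axis
    # perpendicular to the strands: pleats face inward (the sheets pack
    # face-to-face) and the terminal strands (slot 0 of each sheet) run
    # antiparallel, as the even total strand count demands.  This also makes
    # a sequence-local edge-to-edge fusion of two copies exactly realizable.
    dirs0 = [1 if k % 2 == 0 else -1 for k in range(S)]
    dirs1 = [-d for d in dirs0]
    atoms0, flips0, meta0 = _build_sheet_atoms(S, L, dirs0)
    atoms1, flips1, meta1 = _build_sheet_atoms(S, L, dirs0)
    roty = np.diag([-1.0, 1.0, -1.0])
    atoms1 = [tuple(x @ roty.T for x in a) for a in atoms1]

    def center(sets):
        allxyz = np.vstack([np.vstack(a) for a in sets])
        c = allxyz.mean(axis=0)
        return [tuple(x - c for x in a) for a in sets]

    atoms0 = center(atoms0)
    atoms1 = center(atoms1)
    th = np.radians(r.sheet_rotation)
    Rz = np.array([[np.cos(th), -np.sin(th), 0.0],
                   [np.sin(th), np.cos(th), 0.0],
                   [0.0, 0.0, 1.0]])
    shift = np.array([0.0, 0.0, r.sheet_separation])
    atoms1 = [tuple(x @ Rz.T + shift for x in a) for a in atoms1]

    # Ig-like default: the chain enters sheet 0 at one edge and returns along
    # sheet 1, so the N- and C-terminal strands pack face-to-face on the same
    # edge of the sandwich.
    order = r.strand_order or ([(0, k) for k in range(S)] +
                               [(1, k) for k in reversed(range(S))])
    if sorted(order) != sorted([(sh, k) for sh in (0, 1) for k in range(S)]):
        raise ValueError("strand_order must list every (sheet, slot) exactly once")
    slot_atoms = {0: atoms0, 1: atoms1}
    seq_atoms = [slot_atoms[sh][k] for sh, k in order]

    gap = r.loop_length if r.loop_length is not None else 2
    if r.loop_length is not None:
        for a, b in zip(seq_atoms[:-1], seq_atoms[1:]):
            span = float(np.linalg.norm(b[0][0] - a[2][-1]))  # N(first) - C(last)
            if span > MAX_LOOP_SPAN_PER_RESIDUE * (r.loop_length + 1):
                raise ValueError(
                    f"infeasible recipe: loop of {r.loop_length} residues cannot "
                    f"span {span:.1f} Å between consecutive strands")
    model = _assemble_model(seq_atoms, gap, f"sandwich-{S}x2-L{L}")

    # sequence position of each (sheet, slot)
    seq_of = {key: i for i, key in enumerate(order)}
    starts = [i * L for i in range(2 * S)]
    pairings = []
    for sheet_id, meta in ((0, meta0), (1, meta1)):
        seq_of_slot = [seq_of[(sheet_id, k)] for k in range(S)]
        pairings.extend(_pairing_truths(meta, starts, L, seq_of_slot))
    truth = SheetTruth(
        strand_ranges=[(i * L, (i + 1) * L) for i in range(2 * S)],
        sheet_of=[sh for sh, _ in order],
        directions=[(dirs0 if sh == 0 else dirs1)[k] for sh, k in order],
        pairings=pairings,
        edge_strands=sorted(seq_of[(sh, k)] for sh in (0, 1) for k in (0, S - 1)),
        separation=r.sheet_separation,
        rotation=r.sheet_rotation,
    )
    return model, truth


def make_helix(n_residues: int = 12, label: str = "ideal-helix") -> StructureModel:
    """Ideal α-helix (φ, ψ) = (-57°, -47°)."""
    bb = build_backbone([(-57.0, -47.0, 180.0)] * n_residues)
    residues = [ResidueBackbone("A", i + 1, "A", bb["N"][i], bb["CA"][i],
                                bb["C"][i], bb["O"][i])
                for i in range(n_residues)]
    return StructureModel({"A": residues}, label=label)


# ---------------------------------------------------------------------------
# abstract topologies
# ---------------------------------------------------------------------------

def make_topology(preset: str | tuple[int, int]) -> topo.IgTopology:
    """Abstract fused topology: 'scIg12', 'scIg14', or a custom (n_a, n_b)
    pair of strand counts fused through the sequence-local arrangement."""
    if isinstance(preset, str):
        return topo.preset_topology(preset)
    n_a, n_b = preset
    return topo.fuse_topologies(_generic_ig(n_a), _generic_ig(n_b),
                                name=f"scIg{n_a + n_b}")


def _generic_ig(n: int) -> topo.IgTopology:
    if n == 6:
        return topo.six_stranded_ig()
    if n == 7:
        return topo.seven_stranded_ig()
    if n == 8:
        seven = topo.seven_stranded_ig()
        return topo.IgTopology(
            n_strands=8,
            sheet_of=(0,) + seven.sheet_of,
            direction=(-1,) + seven.direction,
            loops=(topo.HAIRPIN,) + seven.loops,
            name="dIg8",
        )
    raise ValueError(f"no generic Ig preset for {n} strands")


# ---------------------------------------------------------------------------
# perturbations, ensembles, titrations
# ---------------------------------------------------------------------------

def perturb_model(model: StructureModel, sigma: float,
                  selection: list[tuple[int, int]] | None = None,
                  seed: int = 0) -> StructureModel:
    """I.i.d. Gaussian displacement (per coordinate, Å) of the selected
    residues' atoms; seed-reproducible."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    chains = {}
    for cid, residues in model.chains.items():
        new = []
        for r in residues:
            hit = selection is None or any(lo <= r.residue_number <= hi
                                           for lo, hi in selection)

            def jig(p):
                if p is None:
                    return None
                q = p.copy()
                if hit and sigma > 0:
                    q = q + rng.normal(0.0, sigma, 3)
                return q

            new.append(ResidueBackbone(r.chain_id, r.residue_number, r.amino_acid,
                                       jig(r.n), jig(r.ca), jig(r.c), jig(r.o),
                                       {k: jig(v) for k, v in r.sidechain.items()},
                                       r.confidence, r.insertion_code))
        chains[cid] = new
    return StructureModel(chains, model.label + f"+noise{sigma}", model.source)


def random_sandwich_recipe(rng: np.random.Generator) -> SandwichRecipe:
    """Randomized recipe within the study's fixture ranges."""
    return SandwichRecipe(
        strands_per_sheet=int(rng.integers(2, 7)),
        strand_length=int(rng.integers(5, 10)),
        sheet_separation=float(rng.uniform(8.0, 12.0)),
        sheet_rotation=float(rng.uniform(0.0, 45.0)),
    )


def make_ensemble(model: StructureModel, rmsf_profile: np.ndarray,
                  n_frames: int, seed: int = 0) -> list[StructureModel]:
    """Synthetic conformational ensemble whose per-residue RMSF matches the
    profile in expectation (isotropic Gaussian jitter, σ = RMSF/√3)."""
    profile = np.asarray(rmsf_profile, dtype=float)
    if len(profile) != len(model.residues()):
        raise ValueError("profile length must equal residue count")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        chains = {}
        idx = 0
        for cid, residues in model.chains.items():
            new = []
            for r in residues:
                s = profile[idx] / np.sqrt(3.0)
                idx += 1
                d = rng.normal(0.0, s, 3) if s > 0 else np.zeros(3)

                def mv(p):
                    return None if p is None else p + d

                new.append(ResidueBackbone(r.chain_id, r.residue_number,
                                           r.amino_acid, mv(r.n), mv(r.ca),
                                           mv(r.c), mv(r.o),
                                           {k: mv(v) for k, v in r.sidechain.items()},
                                           r.confidence, r.insertion_code))
            chains[cid] = new
        frames.append(StructureModel(chains, model.label + "-frame"))
    return frames


def bound_fraction_depletion(conc: np.ndarray, k_d: float, protein: float) -> np.ndarray:
    """Exact 1:1 bound fraction with ligand depletion."""
    s = protein + conc + k_d
    return (s - np.sqrt(s ** 2 - 4.0 * protein * conc)) / (2.0 * protein)


def simulate_titration(k_d: float, protein_conc: float,
                       concentrations: np.ndarray,
                       noise_sd: float = 0.02, replicates: int = 3,
                       amplitude: float = 1000.0,
                       seed: int = 0) -> TitrationSeries:
    """Depletion-corrected 1:1 titration with multiplicative Gaussian noise.

    Intensities are ``amplitude * f_bound * (1 + ε)``, ε ~ N(0, noise_sd);
    concentrations are repeated per replicate.  Ground truth (k_d) is the
    input.
    """
    if k_d <= 0:
        raise ValueError("k_d must be positive")
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    f = bound_fraction_depletion(conc, k_d, protein_conc)
    all_conc, all_int, all_rep = [], [], []
    for rep in range(replicates):
        noise = rng.normal(0.0, noise_sd, len(conc)) if noise_sd > 0 else 0.0
        all_conc.append(conc)
        all_int.append(amplitude * f * (1.0 + noise))
        all_rep.append(np.full(len(conc), rep))
    return TitrationSeries(
        concentrations=np.concatenate(all_conc),
        intensities=np.concatenate(all_int),
        replicates=np.concatenate(all_rep),
        protein_conc=protein_conc,
    )


def random_rigid_copy(model: StructureModel, seed: int = 0) -> StructureModel:
    """The same model under a random proper rigid transform."""
    rng = np.random.default_rng(seed)
    R = random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, 3)
    return model.transformed(R, t)
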
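"""EF-hand motif insertion planning at β-hairpin sites.

The 12-residue EF-hand metal-binding loop (DKDGDGYISAAE) is integrated
into a scaffold hairpin through an N-terminal linker held in extended
conformation and a C-terminal linker in α-helical conformation; the default
grid samples N-linkers of 2-3 residues and C-linkers of 0-8 residues
(18 plans, total insertions of 14-23 residues).  Successful grafts are
stabilized by a salt bridge between a linker aspartate/glutamate and the
motif's position-2 lysine; this module also screens that interaction and
the mutual compatibility of loop pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel
from .topology import HairpinSite

EF_HAND_SEQUENCE = "DKDGDGYISAAE"
#: 1-based motif positions that chelate the metal, and how.
EF_HAND_CHELATORS = {1: "sidechain-acid", 3: "sidechain-acid",
                     5: "sidechain-acid", 7: "backbone-carbonyl",
                     12: "sidechain-acid"}
SALT_BRIDGE_LYS_POSITION = 2          # the K of DKDG...
SALT_BRIDGE_CUTOFF = 4.0              # Å, N-O
LOOP_CONTACT_CUTOFF = 3.0             # Å, inter-loop clash screen
N_LINKER_RANGE = (2, 3)
C_LINKER_RANGE = tuple(range(0, 9))

_ACID_OXYGENS = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}


@dataclass(frozen=True)
class MotifSpec:
    """A graftable binding motif."""

    sequence: str = EF_HAND_SEQUENCE
    chelators: dict[int, str] = field(default_factory=lambda: dict(EF_HAND_CHELATORS))
    source: str = "EF-hand Ca/Tb loop"

    def __post_init__(self):
        for pos in self.chelators:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"chelating position {pos} outside motif")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GraftPlan:
    """One motif-insertion variant at a hairpin site."""

    site: HairpinSite
    motif: MotifSpec
    n_linker: int              # residues, extended conformation
    c_linker: int              # residues, α-helical conformation
    scaffold: str = "scIg12"
    variant: str = ""

    @property
    def total_length(self) -> int:
        return len(self.motif) + self.n_linker + self.c_linker

    @property
    def name(self) -> str:
        return design_name(self.scaffold, self.site.index, self.variant)


def enumerate_graft_plans(site: HairpinSite, motif: MotifSpec | None = None,
                          n_range: tuple[int, ...] = N_LINKER_RANGE,
                          c_range: tuple[int, ...] = C_LINKER_RANGE,
                          scaffold: str = "scIg12") -> list[GraftPlan]:
    """All linker-length combinations: |n_range| x |c_range| plans.

    With the default grid this yields 18 plans with total insertion lengths
    of 14-23 residues.
    """
    if not n_range or not c_range:
        raise ValueError("linker ranges must be non-empty")
    motif = motif or MotifSpec()
    variants = "abcdefghijklmnopqrstuvwxyz"
    plans = []
    for k, (n, c) in enumerate(product(sorted(n_range), sorted(c_range))):
        plans.append(GraftPlan(site, motif, n, c, scaffold,
                               variants[k % len(variants)]))
    return plans


def design_name(scaffold: str, site_index: int, variant: str | None = None) -> str:
    """Design naming: scaffold + EF<site><variant>, e.g. 'scIg12+EF3a'."""
    if site_index < 1:
        raise ValueError("site index is 1-based")
    return f"{scaffold}+EF{site_index}{variant or ''}"


def combined_design_name(scaffold: str, *site_tokens: str) -> str:
    """Multi-loop designs join site tokens with '+': 'scIg12+EF1a+EF3a'."""
    return "+".join([scaffold, *site_tokens])


@dataclass
class SaltBridgeResult:
    present: bool
    distance: float
    donor_residue: int | None = None


def detect_anchor_salt_bridge(model: StructureModel,
                              linker_residues: list[int],
                              lysine_residue: int,
                              cutoff: float = SALT_BRIDGE_CUTOFF) -> SaltBridgeResult:
    """Screen for the linker-Asp/Glu — motif-Lys anchor salt bridge.

    ``linker_residues`` are the residue numbers of the N-terminal linker;
    ``lysine_residue`` that of the motif's position-2 lysine.  Reports the
    minimum distance between any linker carboxylate oxygen (OD1/OD2 or
    OE1/OE2) and the lysine terminal nitrogen (NZ), and whether it is within
    the cutoff.
    """
    by_number = {r.residue_number: r for r in model.residues()}
    try:
        lys = by_number[lysine_residue]
    except KeyError:
        raise ValueError(f"lysine residue {lysine_residue} not in model") from None
    if lys.amino_acid != "K" or "NZ" not in lys.sidechain:
        raise ValueError(f"residue {lysine_residue} is not a lysine with an NZ atom")
    nz = lys.sidechain["NZ"]
    best = np.inf
    best_res = None
    found_acid = False
    for num in linker_residues:
        res = by_number.get(num)
        if res is None or res.amino_acid not in _ACID_OXYGENS:
            continue
        for oxy in _ACID_OXYGENS[res.amino_acid]:
            if oxy not in res.sidechain:
                continue
            found_acid = True
            d = float(np.linalg.norm(res.sidechain[oxy] - nz))
            if d < best:
                best, best_res = d, num
    if not found_acid:
        raise ValueError("no linker aspartate/glutamate carboxylate found among "
                         f"residues {linker_residues}")
    return SaltBridgeResult(best <= cutoff, best, best_res)


def loop_combination_compatible(plan_a: GraftPlan, plan_b: GraftPlan,
                                model: StructureModel,
                                loop_residues_a: list[int],
                                loop_residues_b: list[int],
                                cutoff: float = LOOP_CONTACT_CUTOFF) -> bool:
    """Are two grafted loops sterically compatible in the combined model?

    True iff the plans target distinct sites and no atom pair between the
    two loops is closer than the cutoff.
    """
    if plan_a.site.index == plan_b.site.index:
        raise ValueError("plans target the same site")

    def atoms(nums):
        pts = []
        for r in model.residues():
            if r.residue_number in nums:
                for p in (r.n, r.ca, r.c, r.o, *r.sidechain.values()):
                    if p is not None:
                        pts.append(p)
        return np.array(pts) if pts else np.empty((0, 3))

    pa = atoms(set(loop_residues_a))
    pb = atoms(set(loop_residues_b))
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("loop residues not found in model")
    tree = cKDTree(pa)
    return not any(tree.query_ball_point(p, cutoff) for p in pb)
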
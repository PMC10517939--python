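"""Abstract immunoglobulin-fold topology algebra.

An Ig domain is modelled as a two-sheet β-sandwich whose N- and C-terminal
strands pack face-to-face on one edge of the sandwich.  The strand-count
parity fixes the relative orientation of the two terminal strands (odd: same
direction, even: opposite), and only two rigid edge-to-edge placements of a
second domain exist: the symmetric head-to-head arrangement, and the
sequence-local arrangement in which the C-terminal strand of the first
domain pairs the N-terminal strand of the second in the same sheet layer.
For the local arrangement the pairing is parallel when the (equal) strand
count is odd — bridged by a βαβ helix connector — and antiparallel when it
is even — bridged by a short β-hairpin.

Functionalization sites are the β-hairpin loops of the fused sandwich,
numbered EF1..EFk along the sequence; "top" sites sit opposite the
termini/bridge side of the sandwich.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

__all__ = [
    "IgTopology", "FusionArrangement", "HairpinSite",
    "terminal_orientation", "enumerate_fusions", "fused_strand_count",
    "fuse_topologies", "enumerate_hairpin_sites", "diversified_site_spacing",
    "six_stranded_ig", "seven_stranded_ig", "preset_topology",
    "trim_topology", "diversified_fusion",
]

HAIRPIN = "hairpin"
ARCH = "arch"
HELIX_BRIDGE = "helix_bridge"


@dataclass(frozen=True)
class IgTopology:
    """Strand-level description of a (possibly fused) Ig β-sandwich.

    ``sheet_of[i]`` gives the sheet (0/1) of strand i in sequence order,
    ``direction[i]`` its direction (+1 "up" / -1 "down") along the shared
    strand axis, and ``loops[i]`` classifies the loop between strands i and
    i+1 as hairpin (same sheet), arch (crossing sheets) or the helix bridge
    of a parallel fusion.
    """

    n_strands: int
    sheet_of: tuple[int, ...]
    direction: tuple[int, ...]
    loops: tuple[str, ...]
    name: str = ""
    domain_of: tuple[int, ...] = ()  # per strand: source domain (0/1); empty = single domain

    def __post_init__(self):
        if self.n_strands < 4:
            raise ValueError("an Ig topology needs at least 4 strands")
        if len(self.sheet_of) != self.n_strands or len(self.direction) != self.n_strands:
            raise ValueError("sheet/direction length mismatch")
        if len(self.loops) != self.n_strands - 1:
            raise ValueError("need n_strands - 1 loop classifications")
        if any(s not in (0, 1) for s in self.sheet_of):
            raise ValueError("sheet membership must be 0 or 1")

    @property
    def terminal_strands(self) -> tuple[int, int]:
        return (0, self.n_strands - 1)

    @property
    def terminal_parity(self) -> int:
        """+1 if the terminal strands run in the same direction, else -1."""
        return 1 if self.n_strands % 2 == 1 else -1

    def loop_side(self, i: int) -> str:
        """Side of loop i: 'top' if the preceding strand runs up, else 'bottom'."""
        return "top" if self.direction[i] > 0 else "bottom"


@dataclass(frozen=True)
class FusionArrangement:
    """One admissible edge-to-edge placement of domain B against domain A.

    ``paired_termini`` lists the two interface layers as
    (terminus of A, terminus of B, orientation) with termini 'N'/'C'.
    """

    orientation: str                       # of the A_C-containing pairing
    connector: str | None                  # 'beta_alpha_beta' | 'beta_hairpin' | None
    paired_termini: tuple[tuple[str, str, str], tuple[str, str, str]]
    is_local: bool
    fused_strand_count: int

    def __post_init__(self):
        if self.is_local:
            pairs = {(a, b) for a, b, _ in self.paired_termini}
            if ("C", "N") not in pairs:
                raise ValueError("local arrangement must pair A:C with B:N in one layer")


@dataclass(frozen=True)
class HairpinSite:
    """A functionalization site (β-hairpin loop), named EF<index>."""

    index: int                      # 1-based, sequence order
    flanking_strands: tuple[int, int]
    side: str                       # 'top' | 'bottom'
    is_bridge: bool = False
    symmetry_partner: int | None = None

    @property
    def name(self) -> str:
        return f"EF{self.index}"


# ---------------------------------------------------------------------------
# Parity and counting rules
# ---------------------------------------------------------------------------

def terminal_orientation(n_strands: int) -> str:
    """Orientation of the two terminal strands of an Ig domain.

    Odd strand counts orient them in the same direction, even counts in
    opposite directions.
    """
    if n_strands < 4:
        raise ValueError("need at least 4 strands")
    return "same" if n_strands % 2 == 1 else "opposite"


def fused_strand_count(n_a: int, n_b: int, inserted: int = 0, deleted: int = 0) -> int:
    """Strand count of the fused sandwich: n_a + n_b + inserted - deleted."""
    if inserted < 0 or deleted < 0:
        raise ValueError("inserted/deleted must be non-negative")
    if deleted > min(n_a, n_b):
        raise ValueError("cannot delete more strands than a domain contributes")
    return n_a + n_b + inserted - deleted


# ---------------------------------------------------------------------------
# Fusion enumeration
# ---------------------------------------------------------------------------

def _orient(sign: int) -> str:
    return "parallel" if sign > 0 else "antiparallel"


def enumerate_fusions(topo_a: IgTopology, topo_b: IgTopology) -> list[FusionArrangement]:
    """All edge-to-edge arrangements of the four terminal strands in two layers.

    Placements that would force both terminal strands of one domain into the
    same layer collapse the domains and are excluded; what remains are the
    two rigid placements of B against A's terminal edge.  Orientations follow
    from the terminal parities p = terminal_parity of each domain, anchored
    by the head-to-head placement in which the two N-terminal strands pair
    antiparallel (the two-fold-symmetric dimer geometry).
    """
    p_a = topo_a.terminal_parity
    p_b = topo_b.terminal_parity
    n_fused = topo_a.n_strands + topo_b.n_strands
    out = []

    # head-to-head: (A_N, B_N) antiparallel; (A_C, B_C) with sign -p_a*p_b
    out.append(FusionArrangement(
        orientation=_orient(-p_a * p_b),
        connector=None,
        paired_termini=(("N", "N", "antiparallel"),
                        ("C", "C", _orient(-p_a * p_b))),
        is_local=False,
        fused_strand_count=n_fused,
    ))

    # local: (A_C, B_N) with sign p_a; (A_N, B_C) with sign p_b
    local_orient = _orient(p_a)
    connector = "beta_alpha_beta" if local_orient == "parallel" else "beta_hairpin"
    out.append(FusionArrangement(
        orientation=local_orient,
        connector=connector,
        paired_termini=(("C", "N", local_orient),
                        ("N", "C", _orient(p_b))),
        is_local=True,
        fused_strand_count=n_fused,
    ))
    return out


def fuse_topologies(topo_a: IgTopology, topo_b: IgTopology,
                    arrangement: FusionArrangement | None = None,
                    name: str = "") -> IgTopology:
    """Fused-sandwich topology for the sequence-local arrangement.

    Domain B's strands are re-expressed in the fused frame: the local
    placement puts B's N-terminal strand in the same layer as A's C-terminal
    strand, with B's sheets swapped relative to its standalone labelling and
    its strand directions kept; the bridge loop is a hairpin for antiparallel
    fusions and the βαβ helix connector for parallel ones.
    """
    if arrangement is None:
        arrangement = next(a for a in enumerate_fusions(topo_a, topo_b) if a.is_local)
    if not arrangement.is_local:
        raise ValueError("only the sequence-local arrangement can be realized as "
                         "a single-chain topology")
    a_c_sheet = topo_a.sheet_of[-1]
    # map B sheet 0 (holding B_N) onto A_C's sheet
    if a_c_sheet == topo_b.sheet_of[0]:
        b_sheets = topo_b.sheet_of
    else:
        b_sheets = tuple(1 - s for s in topo_b.sheet_of)
    # orientation of the bridge pairing fixes B's direction frame
    bridge_sign = 1 if arrangement.orientation == "parallel" else -1
    flip = 1 if topo_a.direction[-1] * topo_b.direction[0] == bridge_sign else -1
    b_dirs = tuple(flip * d for d in topo_b.direction)
    bridge = HELIX_BRIDGE if arrangement.connector == "beta_alpha_beta" else HAIRPIN
    return IgTopology(
        n_strands=topo_a.n_strands + topo_b.n_strands,
        sheet_of=topo_a.sheet_of + b_sheets,
        direction=topo_a.direction + b_dirs,
        loops=topo_a.loops + (bridge,) + topo_b.loops,
        name=name or f"{topo_a.name}+{topo_b.name}",
        domain_of=tuple([0] * topo_a.n_strands + [1] * topo_b.n_strands),
    )


# ---------------------------------------------------------------------------
# Hairpin sites
# ---------------------------------------------------------------------------

def enumerate_hairpin_sites(fused_topo: IgTopology) -> list[HairpinSite]:
    """β-hairpin functionalization sites of a fused topology, EF1..EFk.

    The interdomain β-hairpin bridge of antiparallel fusions counts as a
    site.  Symmetry partners are filled for internally symmetric fusions of
    two equal domains (site k of domain A partners the corresponding site of
    domain B).
    """
    if not fused_topo.loops:
        raise ValueError("topology lacks loop classification")
    sites = []
    idx = 0
    for i, cls in enumerate(fused_topo.loops):
        if cls != HAIRPIN:
            continue
        idx += 1
        dom = fused_topo.domain_of[i] if fused_topo.domain_of else 0
        is_bridge = bool(fused_topo.domain_of) and \
            fused_topo.domain_of[i] != fused_topo.domain_of[i + 1]
        sites.append(HairpinSite(index=idx,
                                 flanking_strands=(i, i + 1),
                                 side=fused_topo.loop_side(i),
                                 is_bridge=is_bridge))
    # symmetry partners for equal-domain fusions
    if fused_topo.domain_of:
        half = fused_topo.domain_of.count(0)
        if half * 2 == fused_topo.n_strands:
            by_local = {}
            for s in sites:
                if s.is_bridge:
                    continue
                dom = fused_topo.domain_of[s.flanking_strands[0]]
                local = s.flanking_strands[0] - (0 if dom == 0 else half)
                by_local.setdefault(local, {})[dom] = s
            partnered = []
            partner_of = {}
            for local, doms in by_local.items():
                if 0 in doms and 1 in doms:
                    partner_of[doms[0].index] = doms[1].index
                    partner_of[doms[1].index] = doms[0].index
            sites = [HairpinSite(s.index, s.flanking_strands, s.side, s.is_bridge,
                                 partner_of.get(s.index)) for s in sites]
    return sites


def diversified_site_spacing(fused_topo: IgTopology) -> dict[tuple[int, int], int]:
    """Strand separation between top-side sites from different domains.

    For each cross-domain pair of top sites, counts the strands strictly
    between the two sites' inner flanking strands along the sequence path
    through the interface.  Growing the interface (12 → 16 strands) widens
    every entry.
    """
    sites = enumerate_hairpin_sites(fused_topo)
    if not fused_topo.domain_of:
        raise ValueError("need a fused (two-domain) topology")
    out = {}
    top = [s for s in sites if s.side == "top" and not s.is_bridge]
    for s1, s2 in product(top, top):
        d1 = fused_topo.domain_of[s1.flanking_strands[0]]
        d2 = fused_topo.domain_of[s2.flanking_strands[0]]
        if d1 == 0 and d2 == 1:
            gap = s2.flanking_strands[0] - s1.flanking_strands[1] - 1
            out[(s1.index, s2.index)] = gap
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def six_stranded_ig(name: str = "dIg6") -> IgTopology:
    """Idealized 6-stranded Ig domain (trimmed 7-stranded fold): two
    CDR-like top hairpins, terminal strands in opposite directions."""
    return IgTopology(
        n_strands=6,
        sheet_of=(0, 0, 1, 1, 0, 1),
        direction=(1, -1, 1, -1, 1, -1),
        loops=(HAIRPIN, ARCH, HAIRPIN, ARCH, ARCH),
        name=name,
    )


def seven_stranded_ig(name: str = "dIg7") -> IgTopology:
    """Idealized 7-stranded Ig domain: two top hairpins, one bottom hairpin,
    terminal strands in the same direction."""
    return IgTopology(
        n_strands=7,
        sheet_of=(0, 0, 1, 1, 0, 1, 1),
        direction=(1, -1, 1, -1, 1, -1, 1),
        loops=(HAIRPIN, ARCH, HAIRPIN, ARCH, ARCH, HAIRPIN),
        name=name,
    )


def trim_topology(topo: IgTopology, from_n: int = 0, from_c: int = 0) -> IgTopology:
    """Remove terminal strands (and their adjoining loops) from a domain."""
    if from_n + from_c >= topo.n_strands - 3:
        raise ValueError("trimming would leave fewer than 4 strands")
    lo, hi = from_n, topo.n_strands - from_c
    return IgTopology(
        n_strands=hi - lo,
        sheet_of=topo.sheet_of[lo:hi],
        direction=topo.direction[lo:hi],
        loops=topo.loops[lo:hi - 1],
        name=topo.name + "-trim",
    )


def diversified_fusion(inserted: int = 0, deleted: int = 0) -> IgTopology:
    """Fusions of two 7-stranded Ig domains spanning 12-16 strands.

    ``deleted`` removes one terminal strand per interface layer (1: the
    first domain's C-strand; 2: additionally the second domain's C-strand,
    which reproduces the scIg12 construction); ``inserted`` adds 1-2 extra
    interface strands through additional β-hairpin loops, one per layer.
    Models the diversification series in which growing the interface
    separates the two domains' top hairpin sites.
    """
    if not 0 <= inserted <= 2 or not 0 <= deleted <= 2:
        raise ValueError("inserted and deleted must be in 0..2")
    if inserted and deleted:
        raise ValueError("use either insertions or deletions, not both")
    a = seven_stranded_ig("dIg7a")
    b = seven_stranded_ig("dIg7b")
    if deleted >= 1:
        a = trim_topology(a, from_c=1)
    if deleted >= 2:
        b = trim_topology(b, from_c=1)
    if inserted == 0:
        return fuse_topologies(a, b, name=f"scIg{a.n_strands + b.n_strands}")
    a_c_sheet = a.sheet_of[-1]
    prev_sheet, prev_dir = a_c_sheet, a.direction[-1]
    ins_sheets, ins_dirs, bridge_loops = [], [], []
    for k in range(inserted):
        s = a_c_sheet if k == 0 else 1 - prev_sheet
        d = -prev_dir
        bridge_loops.append(HAIRPIN if s == prev_sheet else ARCH)
        ins_sheets.append(s)
        ins_dirs.append(d)
        prev_sheet, prev_dir = s, d
    # B's N-strand joins A_C's layer, pairing the neighbouring interface strand
    if b.sheet_of[0] == a_c_sheet:
        b_sheets = b.sheet_of
    else:
        b_sheets = tuple(1 - s for s in b.sheet_of)
    neighbour_dir = ins_dirs[0]  # strand spatially adjacent to B_N in its layer
    flip = 1 if b.direction[0] == -neighbour_dir else -1
    b_dirs = tuple(flip * d for d in b.direction)
    bridge_loops.append(HAIRPIN if prev_sheet == a_c_sheet else ARCH)
    n = a.n_strands + inserted + b.n_strands
    return IgTopology(
        n_strands=n,
        sheet_of=a.sheet_of + tuple(ins_sheets) + b_sheets,
        direction=a.direction + tuple(ins_dirs) + b_dirs,
        loops=a.loops + tuple(bridge_loops) + b.loops,
        name=f"scIg{n}",
        # inserted interface strands belong to neither domain
        domain_of=tuple([0] * a.n_strands + [-1] * inserted + [1] * b.n_strands),
    )


def preset_topology(preset: str) -> IgTopology:
    """Named topologies: 'scIg12' (6+6 antiparallel, hairpin bridge),
    'scIg14' (7+7 parallel, βαβ bridge), or bare domains 'ig6'/'ig7'."""
    key = preset.lower()
    if key == "scig12":
        return fuse_topologies(six_stranded_ig(), six_stranded_ig(), name="scIg12")
    if key == "scig14":
        return fuse_topologies(seven_stranded_ig(), seven_stranded_ig(), name="scIg14")
    if key == "ig6":
        return six_stranded_ig()
    if key == "ig7":
        return seven_stranded_ig()
    raise ValueError(f"unknown preset {preset!r}")
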
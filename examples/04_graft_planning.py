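"""Plan EF-hand motif insertions at the hairpin sites of a 12-stranded
single-chain Ig dimer.

The scaffold exposes five β-hairpin sites (four on top, one bridging the
two domains at the bottom); the 12-residue metal-binding loop is integrated
through an extended N-linker (2-3 residues) and a helical C-linker (0-8
residues), giving the default 18-plan grid.
"""

from igtandem.grafting import enumerate_graft_plans, combined_design_name
from igtandem.topology import enumerate_hairpin_sites, preset_topology

topo = preset_topology("scIg12")
sites = enumerate_hairpin_sites(topo)
print(f"{topo.name}: {len(sites)} hairpin sites")
for s in sites:
    extra = " (interdomain bridge)" if s.is_bridge else ""
    partner = f", equivalent to EF{s.symmetry_partner}" if s.symmetry_partner else ""
    print(f"  {s.name}: strands {s.flanking_strands[0] + 1}-"
          f"{s.flanking_strands[1] + 1}, {s.side}{extra}{partner}")

bridge = next(s for s in sites if s.is_bridge)
plans = enumerate_graft_plans(bridge)
lengths = sorted({p.total_length for p in plans})
print(f"\n{len(plans)} graft plans at {bridge.name}; total insertion lengths "
      f"{lengths[0]}-{lengths[-1]} residues (12-residue motif + linkers)")
print("first three:", ", ".join(
    f"{p.name} (N{p.n_linker}/C{p.c_linker}, {p.total_length} aa)"
    for p in plans[:3]))
print("a two-loop combination is named",
      combined_design_name("scIg12", "EF1a", "EF3a"))
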
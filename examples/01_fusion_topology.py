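"""Enumerate edge-to-edge fusion arrangements for Ig domain pairs.

Two Ig β-sandwich domains can pair edge-to-edge in exactly two rigid
arrangements; only one of them connects the C-terminal strand of the first
domain to the N-terminal strand of the second within the same sheet layer
(a sequence-local fusion).  The strand-count parity decides the pairing
orientation and hence the connector type.
"""

from igtandem.topology import (enumerate_fusions, fused_strand_count,
                               six_stranded_ig, seven_stranded_ig)

for name, domain in [("7-stranded", seven_stranded_ig()),
                     ("6-stranded", six_stranded_ig())]:
    print(f"two {name} Ig domains "
          f"(terminal strands point the same way: {domain.terminal_parity > 0}):")
    for arr in enumerate_fusions(domain, domain):
        tag = "sequence-local" if arr.is_local else "head-to-head"
        conn = arr.connector or "no short connector"
        print(f"  {tag:15s} pairing {arr.orientation:12s} via {conn}; "
              f"fused sandwich has "
              f"{fused_strand_count(domain.n_strands, domain.n_strands)} strands")
    print()

print("The local 7+7 fusion is parallel and needs a βαβ helix connector "
      "(14 strands); the local 6+6 fusion is antiparallel and closes with "
      "a short β-hairpin (12 strands).")
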
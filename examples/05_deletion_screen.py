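"""Deletion analyses: presets, pattern screen, coupled designs, NADH sink.

On the Crabtree-negative toy: evaluate the mechanistic presets (NDH1+AOX,
COX), screen all pruned single deletions for the all-excess availability
pattern (the transhydrogenase knockout flips it), search for growth-coupled
ethanol designs, and build the NADH-sink modified model.
"""

from redoxplane import (
    fba,
    growth_coupled_search,
    nadh_sink_variant,
    pattern_screen,
    prune_candidates,
    toy_stipitis,
)
from redoxplane.deletion_screen import a_priori_presets

ss = toy_stipitis()
print("a-priori presets:")
for r in a_priori_presets(ss):
    frac = None if r.pattern is None else f"{r.pattern.fraction_excess:.2f}"
    print(f"  {'+'.join(r.deletion_set):>10}: growth {r.max_growth:.3f} 1/h, "
          f"ethanol {r.coupling}, excess fraction {frac}")

candidates = prune_candidates(ss)
print(f"\npattern screen over {len(candidates)} pruned singles:")
for s in pattern_screen(ss, candidates, min_growth=0.1):
    print(f"  survivor: {'+'.join(s.deletion_set)} "
          f"(growth {s.max_growth:.3f}, excess fraction "
          f"{s.pattern.fraction_excess:.2f})")
# deleting the ATP-coupled transhydrogenase removes the route that makes
# cytosolic NADH growth-useful, recreating the all-excess pattern.

print("\ntop growth-coupled ethanol designs (<=2 deletions):")
designs = growth_coupled_search(ss, "EX_eth", max_deletions=2)
for r in sorted(designs, key=lambda r: -r.coupling_strength)[:3]:
    print(f"  {'+'.join(r.deletion_set):>12}: min ethanol at max growth "
          f"{r.coupling_strength:.2f} mmol/gDW/h ({r.provenance})")

variant = nadh_sink_variant(ss)
print(f"\nNADH-sink variant (drain 0.1-0.6, growth floor 0.20): "
      f"max growth {fba(variant, check_degeneracy=False).objective:.3f} 1/h")
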
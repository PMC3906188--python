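"""Ethanol-growth production envelopes: coupled vs non-coupled regimes.

With unbounded oxygen both toys can grow at maximal rate without making
any ethanol (non-coupled).  Capping oxygen at half the line-of-optimality
value forces the Crabtree-positive toy to ferment even at maximal growth:
the minimum ethanol flux at Z* becomes positive, i.e. growth-coupled.
"""

from redoxplane import (
    line_of_optimality,
    production_envelope,
    set_uptake,
    toy_cerevisiae,
    toy_stipitis,
)

sc = toy_cerevisiae()
loo = float(line_of_optimality(sc, [10.0])[0])
print(f"line of optimality at glucose 10: O2 uptake {loo:.2f} mmol/gDW/h")

for label, model in [
    ("SC, unbounded O2", sc),
    (f"SC, O2 <= {loo / 2:.2f}", set_uptake(sc, "EX_o2", loo / 2)),
    ("SS, unbounded O2", toy_stipitis()),
]:
    env = production_envelope(model, "EX_eth")
    print(
        f"{label:>18}: max growth {env.max_growth:.3f} 1/h, ethanol at Z* "
        f"in [{env.min_product[-1]:.3f}, {env.max_product[-1]:.3f}] "
        f"-> {env.coupling}"
    )
# a positive lower ethanol bound at maximal growth means the network cannot
# grow optimally without secreting ethanol - the overflow signature.
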
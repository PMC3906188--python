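"""FBA with reducing-capacity shadow prices on the Crabtree-positive toy.

Sets an oxygen-limited condition (glucose 10, oxygen 6 mmol/gDW/h), solves
for maximal growth and asks whether the cytosolic NAD(H) pool is limiting
or in excess, cross-checking the LP dual with a finite-difference probe.
"""

from redoxplane import fba, gamma_red, set_uptake, toy_cerevisiae, verify_fd
from redoxplane.shadow_redox import gamma_red_fd

model = set_uptake(toy_cerevisiae(), "EX_o2", 6.0)
sol = fba(model)
print(f"growth: {sol.objective:.4f} 1/h")
print(f"ethanol secretion: {sol.flux('EX_eth'):.3f} mmol/gDW/h")

verdict = gamma_red(sol, "c")
print(f"gamma_red (cytosol) = {verdict.gamma_red:+.5f} -> {verdict.classification}")
# positive gamma_red: reducing equivalents exceed the growth demand; the
# network must re-oxidise them (here: fermentation to ethanol), the flux
# signature of overflow metabolism.

fd = gamma_red_fd(model, "c", base_solution=sol)
print(f"finite-difference check: {fd.gamma_red:+.5f} ({fd.classification})")

fd_o2, agrees = verify_fd(model, "o2_c", base_solution=sol)
print(f"oxygen shadow price {sol.dual('o2_c'):+.5f} vs probe {fd_o2:+.5f} "
      f"(agree: {agrees}) -> oxygen is growth-limiting here")
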
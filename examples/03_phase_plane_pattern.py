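"""Phenotypic phase planes and the NAD(H) availability pattern.

Scans a 20x20 glucose x oxygen uptake grid for both toys, classifies each
oxygen-limited phenotype by the sign of gamma_red, and prints the pattern
summary: the Crabtree-positive toy shows excess reducing capacity at every
oxygen-limited point, the Crabtree-negative toy only in a low-oxygen
sub-region (limiting near its line of optimality).
"""

from redoxplane import availability_pattern, scan, toy_cerevisiae, toy_stipitis

for model in (toy_cerevisiae(), toy_stipitis()):
    grid = scan(model)
    pattern = availability_pattern(grid)
    print(f"{model.model_id}:")
    print(f"  oxygen-limited grid points: {pattern.n_o2_limited}")
    print(f"  excess fraction: {pattern.fraction_excess:.3f} "
          f"(excess {pattern.n_excess}, limiting {pattern.n_limiting})")
    print(f"  all-excess pattern: {pattern.all_excess_o2_limited}; "
          f"subset pattern: {pattern.subset_excess}")
    # one row of the map, low -> high oxygen at the highest glucose uptake
    row = grid.classification[-1]
    symbols = {"excess": "+", "limiting": "-", "neutral": "0", "infeasible": "."}
    print("  glc=10 row (low->high O2):", "".join(symbols[c] for c in row))
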